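"""Event-level n-gram language models and surprisal in bits.

The primitive expressions of these models are not words but canonical
event labels, so a scenario's vocabulary is the set of distinct events
its contributors mentioned, and a bigram model's conditional probability
p(e_j | e_i) estimates how likely event e_j is to immediately follow
e_i in the script.  Surprisal is the usual −log2 p(target | context),
interpreted here as the predictability of an utterance referring to the
target event given the script context.

Defaults follow the study conditions: bigrams (roughly 100 sequences
per scenario cannot support higher orders) and raw maximum-likelihood
estimation, because the stimulus-construction stage explicitly relies on
events having probability exactly 0 in a context — a notion additive
smoothing would destroy.  Add-k smoothing is available behind the
``smoothing`` argument for robustness experiments.

Zero probabilities surface as an infinite-surprisal sentinel
(``math.inf``), never as an exception, so chains and reports can carry
them.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "BOS",
    "EOS",
    "TransitionModel",
    "SurprisalValue",
    "Smoothing",
    "fit_ngram",
    "surprisal",
    "sequence_surprisals",
    "mean_surprisal",
    "bits_to_percent",
    "vocab_stats",
    "VocabStats",
    "write_counts",
    "read_counts",
    "write_arpa",
]

#: Begin/end-of-sequence boundary markers (conventional n-gram sentence markers).
BOS = "<s>"
EOS = "</s>"

_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class Smoothing:
    """Smoothing spec: ``Smoothing.mle()`` or ``Smoothing.add_k(k)``."""

    kind: str = "mle"
    k: float = 0.0

    @classmethod
    def mle(cls) -> "Smoothing":
        return cls("mle", 0.0)

    @classmethod
    def add_k(cls, k: float) -> "Smoothing":
        if k <= 0:
            raise ValueError("add_k requires k > 0")
        return cls("add_k", k)


@dataclass(frozen=True)
class SurprisalValue:
    """A probability and its surprisal −log2 p in bits (inf when p = 0)."""

    bits: float
    probability: float

    @classmethod
    def from_probability(cls, p: float) -> "SurprisalValue":
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} outside [0, 1]")
        bits = math.inf if p == 0.0 else -math.log(p) / _LOG2
        return cls(bits=max(bits, 0.0), probability=p)

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.bits)


Context = tuple[str, ...]


@dataclass(frozen=True)
class TransitionModel:
    """Fitted event n-gram model for one scenario.

    ``unigram_counts`` include boundary markers; ``ngram_counts`` map a
    context tuple of ``order − 1`` labels plus target to a count, and
    ``context_counts`` hold the matching denominator totals.  For the
    default bigram case ``bigram_counts`` exposes the pair counts
    directly.
    """

    scenario: str
    order: int
    unigram_counts: dict[str, int]
    ngram_counts: dict[tuple[Context, str], int]
    context_counts: dict[Context, int]
    smoothing: Smoothing = field(default_factory=Smoothing.mle)

    @property
    def vocabulary(self) -> set[str]:
        """All labels including boundary markers."""
        return set(self.unigram_counts)

    @property
    def event_vocabulary(self) -> set[str]:
        """Event labels only — boundary markers excluded."""
        return {w for w in self.unigram_counts if w not in (BOS, EOS)}

    @property
    def bigram_counts(self) -> dict[tuple[str, str], int]:
        if self.order != 2:
            raise ValueError("bigram_counts only defined for order-2 models")
        return {(ctx[0], tgt): c for (ctx, tgt), c in self.ngram_counts.items()}

    def _as_context(self, context: str | Sequence[str]) -> Context:
        ctx = (context,) if isinstance(context, str) else tuple(context)
        if len(ctx) != self.order - 1:
            raise ValueError(
                f"context length {len(ctx)} does not match order-{self.order} model"
            )
        return ctx

    def p(self, target: str, context: str | Sequence[str] = ()) -> float:
        """Conditional probability p(target | context)."""
        ctx = self._as_context(context)
        for lab in ctx:
            if lab not in self.unigram_counts:
                raise KeyError(f"unknown context label {lab!r}")
        denom = self.context_counts.get(ctx, 0)
        num = self.ngram_counts.get((ctx, target), 0)
        if self.smoothing.kind == "mle":
            if denom == 0:
                raise KeyError(f"context {ctx!r} never observed")
            return num / denom
        # add-k: spread k pseudo-counts over every possible continuation
        # (events plus EOS; BOS can never be a continuation).
        v = len(self.vocabulary) - 1
        k = self.smoothing.k
        return (num + k) / (denom + k * v)


def fit_ngram(sequences: Iterable[Sequence[str]], order: int = 2,
              smoothing: Smoothing | None = None,
              scenario: str = "") -> TransitionModel:
    """Count-based n-gram fit over labeled event sequences.

    Every sequence is wrapped in ``order − 1`` begin markers and one end
    marker, so the first event of a script has a defined conditional
    probability.  Counts are exact; MLE probabilities are count ratios.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    smoothing = smoothing or Smoothing.mle()
    seqs = [list(s) for s in sequences]
    if not seqs:
        raise ValueError("cannot fit a model on an empty sequence set")
    for i, seq in enumerate(seqs):
        if not seq:
            raise ValueError(f"sequence {i} is empty")
        for lab in seq:
            if "PLACEHOLDER" in lab:
                raise ValueError(
                    f"placeholder label {lab!r} in sequence {i}: resolve or "
                    "exclude the ESD before model fitting"
                )

    unigrams: Counter[str] = Counter()
    ngrams: Counter[tuple[Context, str]] = Counter()
    contexts: Counter[Context] = Counter()
    n_ctx = order - 1
    for seq in seqs:
        padded = [BOS] * n_ctx + seq + [EOS]
        unigrams.update(padded)
        if order == 1:
            for w in padded:
                ngrams[((), w)] += 1
                contexts[()] += 1
        else:
            for i in range(n_ctx, len(padded)):
                ctx = tuple(padded[i - n_ctx:i])
                ngrams[(ctx, padded[i])] += 1
                contexts[ctx] += 1
    return TransitionModel(
        scenario=scenario, order=order,
        unigram_counts=dict(unigrams),
        ngram_counts=dict(ngrams),
        context_counts=dict(contexts),
        smoothing=smoothing,
    )


def surprisal(model: TransitionModel, context: str | Sequence[str],
              target: str) -> SurprisalValue:
    """Surprisal of ``target`` following ``context``, in bits.

    An unknown context label raises; an unseen (context, target) pair
    under MLE yields probability 0 and the infinite-surprisal sentinel —
    the two situations are deliberately distinct.
    """
    return SurprisalValue.from_probability(model.p(target, context))


def sequence_surprisals(model: TransitionModel,
                        chain: Sequence[str]) -> list[SurprisalValue]:
    """Per-transition surprisal along a chain (no boundary transitions)."""
    if len(chain) < 2:
        raise ValueError("need at least two events to score transitions")
    if model.order != 2:
        raise ValueError("sequence scoring is defined for bigram models")
    return [surprisal(model, chain[i], chain[i + 1]) for i in range(len(chain) - 1)]


def mean_surprisal(model: TransitionModel, chain: Sequence[str]) -> float:
    """Arithmetic mean of per-transition surprisal in bits; inf if any transition is."""
    values = sequence_surprisals(model, chain)
    if any(v.is_infinite for v in values):
        return math.inf
    return sum(v.bits for v in values) / len(values)


def bits_to_percent(bits: float, decimals: int | None = 1) -> float:
    """Convert surprisal in bits to a probability percentage, 100 · 2^(−bits).

    >>> bits_to_percent(2.13)
    22.8
    """
    if bits < 0:
        raise ValueError(f"surprisal must be non-negative, got {bits}")
    if math.isinf(bits):
        return 0.0
    pct = 100.0 * 2.0 ** (-bits)
    return round(pct, decimals) if decimals is not None else pct


@dataclass(frozen=True)
class VocabStats:
    unigram_vocab_size: int
    bigram_count: int
    total_events: int
    n_sequences: int


def vocab_stats(model: TransitionModel,
                include_boundary_bigrams: bool = False) -> VocabStats:
    """Vocabulary size (distinct events, boundaries excluded) and distinct bigrams.

    ``include_boundary_bigrams`` switches the bigram-counting convention
    to also count pairs touching the begin/end markers; the default
    counts event–event pairs only.
    """
    if model.order != 2:
        raise ValueError("vocab_stats is defined for bigram models")
    events = model.event_vocabulary
    pairs = [
        (c, t) for (c, t) in model.bigram_counts
        if include_boundary_bigrams or (c not in (BOS, EOS) and t not in (BOS, EOS))
    ]
    return VocabStats(
        unigram_vocab_size=len(events),
        bigram_count=len(pairs),
        total_events=sum(model.unigram_counts[w] for w in events),
        n_sequences=model.unigram_counts.get(EOS, 0),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_counts(model: TransitionModel, path: str | Path) -> None:
    """Plain-text count format, one record per line, tab-separated.

    Unigram lines are ``label<TAB>count``; n-gram lines tab-separate the
    component labels and end with the count (labels may contain spaces,
    so tab is the only reserved character).  Sections are introduced by
    ``# unigrams`` / ``# ngrams`` comment lines; a header comment records
    scenario, order and smoothing.
    """
    lines = [
        f"# scriptsurp counts scenario={model.scenario} order={model.order} "
        f"smoothing={model.smoothing.kind} k={model.smoothing.k}",
        "# unigrams",
    ]
    for lab, c in sorted(model.unigram_counts.items()):
        lines.append(f"{lab}\t{c}")
    lines.append("# ngrams")
    for (ctx, tgt), c in sorted(model.ngram_counts.items()):
        lines.append("\t".join(ctx + (tgt, str(c))))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_counts(path: str | Path) -> TransitionModel:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    header = lines[0]
    meta = dict(kv.split("=", 1) for kv in header.split()[3:])
    order = int(meta.get("order", "2"))
    smoothing = (Smoothing.add_k(float(meta["k"]))
                 if meta.get("smoothing") == "add_k" else Smoothing.mle())
    unigrams: dict[str, int] = {}
    ngrams: dict[tuple[Context, str], int] = {}
    contexts: dict[Context, int] = {}
    section = None
    for line in lines[1:]:
        if line.startswith("#"):
            section = line.strip("# ").strip()
            continue
        if not line.strip():
            continue
        parts = line.split("\t")
        count = int(parts[-1])
        if section == "unigrams":
            unigrams[parts[0]] = count
        else:
            labs = tuple(parts[:-1])
            ctx, tgt = labs[:-1], labs[-1]
            ngrams[(ctx, tgt)] = count
            contexts[ctx] = contexts.get(ctx, 0) + count
    return TransitionModel(
        scenario=meta.get("scenario", ""), order=order,
        unigram_counts=unigrams, ngram_counts=ngrams,
        context_counts=contexts, smoothing=smoothing,
    )


def write_arpa(model: TransitionModel, path: str | Path) -> None:
    """Export a bigram model in the ARPA n-gram interchange format.

    Log probabilities are base 10, as the format prescribes.  Whitespace
    delimits tokens in ARPA files, so internal spaces in event labels
    are rendered as underscores ("boil water" → "boil_water").  Unseen
    n-grams are simply absent; under MLE no backoff mass exists, so
    backoff weights are written as 0 (= no discounting), which keeps the
    file readable by standard toolkits while representing the raw
    count-ratio model faithfully.
    """
    if model.order != 2:
        raise ValueError("ARPA export implemented for bigram models")
    uni_total = sum(c for w, c in model.unigram_counts.items() if w != BOS)

    def log10(p: float) -> str:
        return "-99" if p <= 0 else f"{math.log10(p):.6f}"

    def tok(label: str) -> str:
        return label.replace(" ", "_")

    lines = ["\\data\\",
             f"ngram 1={len(model.unigram_counts)}",
             f"ngram 2={len(model.ngram_counts)}",
             "",
             "\\1-grams:"]
    for w, c in sorted(model.unigram_counts.items()):
        p = 0.0 if w == BOS else c / uni_total
        lines.append(f"{log10(p)}\t{tok(w)}\t0")
    lines += ["", "\\2-grams:"]
    for (ctx, tgt), c in sorted(model.ngram_counts.items()):
        lines.append(f"{log10(model.p(tgt, ctx))}\t{tok(ctx[0])} {tok(tgt)}")
    lines += ["", "\\end\\", ""]
    Path(path).write_text("\n".join(lines), encoding="utf-8")
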
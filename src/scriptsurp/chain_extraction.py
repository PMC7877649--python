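"""Maximum-likelihood event chains and experimental stimulus specs.

A script is represented as a probabilistic event network: the fitted
bigram model's conditional probabilities are the edge weights.  A chain
is extracted by a greedy walk — from a start event, repeatedly move to
the eligible, not-yet-visited successor with the highest conditional
probability.  Eligibility removes overall-rare events (fewer than 8
mentions by default), so that an event mentioned by one contributor out
of a hundred is never taken to represent population script knowledge.

From a chain of at least four events a stimulus specification is built:
the first three events form the context story, the fourth is the
predictable target (by construction the most likely successor of the
last context event), and the unpredictable target is chosen from
human-proposed candidates that have probability 0 in that context or are
absent from the scenario's vocabulary altogether.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from scriptsurp.event_lm import (
    BOS,
    SurprisalValue,
    TransitionModel,
    bits_to_percent,
    surprisal,
)

__all__ = [
    "EventChain",
    "StimulusSpec",
    "StimulusSummary",
    "eligible_events",
    "extract_chain",
    "build_stimulus",
    "propose_unpredictable",
    "stimulus_report",
    "chain_to_json",
]


@dataclass(frozen=True)
class EventChain:
    """A linear sequence of most-likely-successor events with its probabilities."""

    scenario: str
    events: tuple[str, ...]
    transition_probs: tuple[float, ...]
    transition_bits: tuple[float, ...]
    early_stop: bool = False

    def __post_init__(self) -> None:
        if len(self.transition_probs) != len(self.events) - 1:
            raise ValueError("need exactly one probability per transition")
        if len(set(self.events)) != len(self.events):
            raise ValueError("an event label may not repeat within a chain")

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class StimulusSpec:
    """One experimental item: three context events plus the two targets.

    ``target_bits`` is the surprisal of the predictable target given the
    last context event; ``mean_context_bits`` averages the surprisal of
    all transitions of the underlying chain (the bookkeeping quantity
    reported for the materials).
    """

    scenario: str
    context_events: tuple[str, str, str]
    target_predictable: str
    target_unpredictable: str | None
    target_bits: float
    mean_context_bits: float
    script_type: str | None = None


def eligible_events(model: TransitionModel, min_count: int = 8) -> set[str]:
    """Event labels mentioned at least ``min_count`` times (boundaries excluded)."""
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    out = {w for w in model.event_vocabulary
           if model.unigram_counts[w] >= min_count}
    if not out:
        warnings.warn(
            f"min_count={min_count} leaves no eligible events "
            f"(max observed count {max(model.unigram_counts.values(), default=0)})",
            stacklevel=2,
        )
    return out


def _best_successor(model: TransitionModel, current: str,
                    allowed: set[str]) -> tuple[str, float] | None:
    """Argmax successor among allowed labels; lexicographic tie-break; None if all p=0."""
    best: tuple[str, float] | None = None
    for cand in sorted(allowed):
        p = model.p(cand, current)
        if p <= 0.0:
            continue
        if best is None or p > best[1]:
            best = (cand, p)
    return best


def auto_start(model: TransitionModel, min_count: int = 8) -> str:
    """Default chain start: the eligible event most likely to open a script."""
    allowed = eligible_events(model, min_count)
    best = _best_successor(model, BOS, allowed)
    if best is None:
        raise ValueError("no eligible event ever begins a sequence")
    return best[0]


def extract_chain(model: TransitionModel, start: str, length: int,
                  min_count: int = 8) -> EventChain:
    """Greedy maximum-likelihood walk through the event network.

    At each step the eligible, unvisited successor with maximal
    conditional probability is chosen (ties broken lexicographically on
    the label string).  The walk stops early — flagged on the returned
    chain — when no eligible unvisited successor has positive
    probability, which also guards against cycles.
    """
    if length < 2:
        raise ValueError(f"chain length must be >= 2, got {length}")
    allowed = eligible_events(model, min_count)
    if start not in allowed:
        raise ValueError(
            f"start event {start!r} is not eligible under min_count={min_count}"
        )
    events = [start]
    probs: list[float] = []
    early_stop = False
    while len(events) < length:
        remaining = allowed - set(events)
        best = _best_successor(model, events[-1], remaining)
        if best is None:
            early_stop = True
            break
        events.append(best[0])
        probs.append(best[1])
    bits = tuple(SurprisalValue.from_probability(p).bits for p in probs)
    return EventChain(
        scenario=model.scenario,
        events=tuple(events),
        transition_probs=tuple(probs),
        transition_bits=bits,
        early_stop=early_stop,
    )


def build_stimulus(model: TransitionModel, chain: EventChain,
                   script_type: str | None = None) -> StimulusSpec:
    """Context story + predictable target from the first four chain events.

    The unpredictable slot is left empty; fill it from
    :func:`propose_unpredictable` (candidate plausibility is a human
    judgment outside this package's scope).
    """
    if len(chain) < 4:
        raise ValueError(
            f"need a chain of >= 4 events (3 context + target), got {len(chain)}"
        )
    context = chain.events[:3]
    target = chain.events[3]
    target_bits = surprisal(model, context[2], target).bits
    chain_bits = chain.transition_bits
    mean_bits = (math.inf if any(math.isinf(b) for b in chain_bits)
                 else sum(chain_bits) / len(chain_bits))
    return StimulusSpec(
        scenario=chain.scenario,
        context_events=(context[0], context[1], context[2]),
        target_predictable=target,
        target_unpredictable=None,
        target_bits=target_bits,
        mean_context_bits=mean_bits,
        script_type=script_type,
    )


def propose_unpredictable(model: TransitionModel, context: str,
                          candidates: Sequence[str]) -> list[str]:
    """Filter human-proposed candidates down to zero-probability ones.

    A candidate qualifies when it is absent from the scenario's
    vocabulary or has MLE probability 0 after ``context``.  Order is
    preserved so the caller's plausibility ranking survives.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    out = []
    for cand in candidates:
        if cand not in model.vocabulary or model.p(cand, context) == 0.0:
            out.append(cand)
    return out


@dataclass(frozen=True)
class StimulusSummary:
    n_specs: int
    mean_target_bits: float
    mean_target_percent: float
    mean_context_bits: float
    mean_context_percent: float
    n_infinite_excluded: int


def stimulus_report(specs: Sequence[StimulusSpec]) -> StimulusSummary:
    """Mean surprisal bookkeeping across a stimulus set.

    Infinite values (zero-probability transitions that slipped through)
    are excluded from the means and counted, never averaged over
    silently.
    """
    if not specs:
        raise ValueError("need at least one stimulus spec")
    finite_t = [s.target_bits for s in specs if not math.isinf(s.target_bits)]
    finite_c = [s.mean_context_bits for s in specs if not math.isinf(s.mean_context_bits)]
    n_inf = (len(specs) - len(finite_t)) + (len(specs) - len(finite_c))
    mean_t = sum(finite_t) / len(finite_t) if finite_t else math.inf
    mean_c = sum(finite_c) / len(finite_c) if finite_c else math.inf
    return StimulusSummary(
        n_specs=len(specs),
        mean_target_bits=mean_t,
        mean_target_percent=bits_to_percent(mean_t),
        mean_context_bits=mean_c,
        mean_context_percent=bits_to_percent(mean_c),
        n_infinite_excluded=n_inf,
    )


def chain_to_json(chain: EventChain, path: str | Path | None = None) -> str:
    """Serialize a chain as a structured JSON document (returned; optionally written)."""
    doc = json.dumps(
        {
            "scenario": chain.scenario,
            "events": list(chain.events),
            "transition_probs": list(chain.transition_probs),
            "transition_bits": [None if math.isinf(b) else b for b in chain.transition_bits],
            "early_stop": chain.early_stop,
        },
        indent=2,
    )
    if path is not None:
        Path(path).write_text(doc + "\n", encoding="utf-8")
    return doc
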
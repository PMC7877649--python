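"""Ground-truth generators for every pipeline stage.

Two simulators live here:

* :func:`sample_esd_corpus` draws event-sequence descriptions from a
  known probabilistic script graph and renders them as text through
  controlled lexical noise (synonym choice, pronominalization, object
  ellipsis, event skipping), returning the canonical label sequences
  alongside — so labeling, model fitting and chain extraction can be
  validated against known truth;
* :func:`sample_ratings` draws 7-point Likert ratings from a known
  cumulative-logit mixed model over a 2 × 2 Latin-square design, so the
  ordinal analysis can be validated by parameter recovery.

Both are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scriptsurp.esd_corpus import ESD, EventDescription, ScriptCorpus
from scriptsurp.event_labeling import NormalizationLexicon, label_corpus, lemmatize
from scriptsurp.event_lm import EOS, fit_ngram

__all__ = [
    "ScriptGraph",
    "NoiseSpec",
    "RatingSimSpec",
    "sample_esd_corpus",
    "make_lexicon",
    "recover_transitions",
    "RecoveryReport",
    "latin_square_design",
    "sample_ratings",
    "TERMINAL",
]

#: Name of the implicit terminal state (last transition-matrix column).
TERMINAL = "<end>"

# Object pronouns the rule-based parser recognizes; each distinct noun of a
# graph is assigned one, so lexicon lookup can invert pronominalization.
_PRONOUN_INVENTORY = (
    "it", "them", "him", "her", "us", "me", "everything", "something",
    "anything", "you", "they", "he", "she", "we",
)


@dataclass(frozen=True)
class ScriptGraph:
    """A script as a probabilistic event network with an explicit terminal.

    ``states`` are canonical "verb noun" event labels.  Row ``i`` of the
    ``(S, S+1)`` ``transition_matrix`` gives p(successor | states[i]);
    the final column is the probability of the script ending.  The
    explicit terminal makes sequence lengths vary realistically.
    """

    states: tuple[str, ...]
    transition_matrix: np.ndarray
    start_distribution: np.ndarray

    def __post_init__(self) -> None:
        s = len(self.states)
        tm = np.asarray(self.transition_matrix, dtype=float)
        sd = np.asarray(self.start_distribution, dtype=float)
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(self, "start_distribution", sd)
        if len(set(self.states)) != s:
            raise ValueError("states must be unique")
        if tm.shape != (s, s + 1):
            raise ValueError(f"transition_matrix must be ({s}, {s + 1}), got {tm.shape}")
        if sd.shape != (s,):
            raise ValueError(f"start_distribution must have length {s}")
        if (tm < 0).any() or (sd < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition-matrix rows must sum to 1")
        if not np.isclose(sd.sum(), 1.0, atol=1e-9):
            raise ValueError("start distribution must sum to 1")
        for st in self.states:
            parts = st.split(" ")
            if len(parts) != 2:
                raise ValueError(f"state {st!r} is not a 'verb noun' label")
            for part in parts:
                if lemmatize(part) != part:
                    raise ValueError(
                        f"state {st!r}: {part!r} is not a lemma fixed point; "
                        "round-trip recovery would be undefined"
                    )
        # every state must be able to reach the terminal
        reach = {s}  # column index s == terminal
        frontier = [s]
        incoming = [set(np.nonzero(tm[:, j] > 0)[0]) for j in range(s + 1)]
        while frontier:
            j = frontier.pop()
            for i in incoming[j]:
                if i not in reach:
                    reach.add(i)
                    frontier.append(i)
        unreachable = [self.states[i] for i in range(s) if i not in reach]
        if unreachable:
            raise ValueError(f"no path to terminal from state(s) {unreachable}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def modal_path(self, max_len: int = 50) -> list[str]:
        """Greedy most-likely path from the modal start (no revisits)."""
        idx = int(np.argmax(self.start_distribution))
        path = [idx]
        while len(path) < max_len:
            row = self.transition_matrix[path[-1]].copy()
            for v in path:
                row[v] = 0.0
            nxt = int(np.argmax(row))
            if row[nxt] <= 0 or nxt == self.n_states:
                break
            path.append(nxt)
        return [self.states[i] for i in path]


@dataclass(frozen=True)
class NoiseSpec:
    """Lexical/structural noise applied when rendering events as text.

    ``synonym_sets`` maps a canonical lemma to alternative surface
    lemmas with selection probabilities (the canonical form itself may
    appear among the alternatives).  ``pronoun_rate`` replaces the
    object noun by its scenario-assigned pronoun; ``ellipsis_rate``
    drops the object entirely (only for verbs whose object is unique in
    the graph, so a default-object lexicon can restore it);
    ``skip_rate`` omits whole events from an ESD.
    """

    synonym_sets: dict[str, tuple[tuple[str, ...], tuple[float, ...]]] = field(
        default_factory=dict
    )
    pronoun_rate: float = 0.0
    ellipsis_rate: float = 0.0
    skip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (("pronoun_rate", self.pronoun_rate),
                           ("ellipsis_rate", self.ellipsis_rate),
                           ("skip_rate", self.skip_rate)):
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        for canon, (alts, probs) in self.synonym_sets.items():
            if len(alts) != len(probs):
                raise ValueError(f"synonym set for {canon!r}: lengths differ")
            if not np.isclose(sum(probs), 1.0, atol=1e-9):
                raise ValueError(f"synonym probabilities for {canon!r} must sum to 1")


def _assign_pronouns(graph: ScriptGraph) -> dict[str, str]:
    """Deterministically assign one pronoun per distinct graph noun."""
    nouns = sorted({st.split(" ")[1] for st in graph.states})
    if len(nouns) > len(_PRONOUN_INVENTORY):
        raise ValueError(
            f"graph has {len(nouns)} distinct nouns but only "
            f"{len(_PRONOUN_INVENTORY)} pronouns are available"
        )
    return {noun: _PRONOUN_INVENTORY[i] for i, noun in enumerate(nouns)}


def _unique_object_verbs(graph: ScriptGraph) -> dict[str, str]:
    """Verbs whose object noun is unique across the graph (ellipsis-safe)."""
    verb_nouns: dict[str, set[str]] = {}
    for st in graph.states:
        v, n = st.split(" ")
        verb_nouns.setdefault(v, set()).add(n)
    return {v: next(iter(ns)) for v, ns in verb_nouns.items() if len(ns) == 1}


def make_lexicon(graph: ScriptGraph, noise: NoiseSpec,
                 scenario: str) -> NormalizationLexicon:
    """The normalization lexicon that exactly inverts the rendering noise."""
    synonym_map = {}
    for canon, (alts, _) in noise.synonym_sets.items():
        for alt in alts:
            if alt != canon:
                synonym_map[alt] = canon
    pronoun_map = {(scenario, pron): noun
                   for noun, pron in _assign_pronouns(graph).items()}
    # entries for surface verb variants too: elided objects are looked up
    # before synonym pooling rewrites the verb
    default_object_map = {}
    for verb, noun in _unique_object_verbs(graph).items():
        default_object_map[(scenario, verb)] = noun
        if verb in noise.synonym_sets:
            for alt in noise.synonym_sets[verb][0]:
                default_object_map[(scenario, alt)] = noun
    return NormalizationLexicon(
        synonym_map=synonym_map,
        pronoun_map=pronoun_map,
        default_object_map=default_object_map,
    )


def _sample_path(graph: ScriptGraph, rng: np.random.Generator,
                 max_len: int = 50) -> list[int]:
    state = int(rng.choice(graph.n_states, p=graph.start_distribution))
    path = [state]
    while len(path) < max_len:
        nxt = int(rng.choice(graph.n_states + 1, p=graph.transition_matrix[path[-1]]))
        if nxt == graph.n_states:
            break
        path.append(nxt)
    return path


def _render_event(label: str, noise: NoiseSpec, pronouns: dict[str, str],
                  ellipsis_ok: set[str], rng: np.random.Generator) -> str:
    verb, noun = label.split(" ")
    surf_verb, surf_noun = verb, noun
    if verb in noise.synonym_sets:
        alts, probs = noise.synonym_sets[verb]
        surf_verb = str(rng.choice(list(alts), p=list(probs)))
    if noun in noise.synonym_sets:
        alts, probs = noise.synonym_sets[noun]
        surf_noun = str(rng.choice(list(alts), p=list(probs)))
    # pronoun and ellipsis are mutually exclusive; pronoun takes priority
    if noise.pronoun_rate > 0 and rng.random() < noise.pronoun_rate:
        return f"{surf_verb} {pronouns[noun]}"
    if noise.ellipsis_rate > 0 and verb in ellipsis_ok and rng.random() < noise.ellipsis_rate:
        return surf_verb
    return f"{surf_verb} the {surf_noun}"


def sample_esd_corpus(graph: ScriptGraph, n_esds: int, noise: NoiseSpec,
                      scenario: str = "synthetic") -> tuple[ScriptCorpus, list[list[str]]]:
    """Sample an ESD corpus from a script graph, with its ground truth.

    Returns the rendered corpus and the canonical label sequences of the
    events actually rendered (event skipping applies to both, so truth
    and corpus always align one-to-one).
    """
    if n_esds < 1:
        raise ValueError(f"n_esds must be >= 1, got {n_esds}")
    rng = np.random.default_rng(noise.seed)
    pronouns = _assign_pronouns(graph)
    ellipsis_ok = set(_unique_object_verbs(graph))
    esds: list[ESD] = []
    truth: list[list[str]] = []
    for i in range(n_esds):
        path = _sample_path(graph, rng)
        if noise.skip_rate > 0:
            kept = [s for s in path if rng.random() >= noise.skip_rate]
            if not kept:
                kept = [path[0]]
            path = kept
        labels = [graph.states[s] for s in path]
        esd_id = f"esd{i + 1:03d}"
        events = tuple(
            EventDescription(
                text=_render_event(lab, noise, pronouns, ellipsis_ok, rng),
                esd_id=esd_id,
                position=j + 1,
            )
            for j, lab in enumerate(labels)
        )
        esds.append(ESD(esd_id=esd_id, events=events, contributor=f"w{i + 1:03d}"))
        truth.append(labels)
    corpus = ScriptCorpus(scenario=scenario, esds=tuple(esds), script_type="adapted")
    return corpus, truth


@dataclass(frozen=True)
class RecoveryReport:
    """Fitted-vs-true transition probabilities on a noise-free sample."""

    n_esds: int
    max_abs_error: float
    mean_abs_error: float
    n_cells: int


def recover_transitions(graph: ScriptGraph, n_esds: int, seed: int = 0) -> RecoveryReport:
    """Noise-free sample → label → bigram fit → error against the graph rows.

    Every (state, successor-or-terminal) cell of the transition matrix
    is compared for states that were observed as a bigram context; the
    fitted terminal probability is p(end-of-sequence | state).
    """
    scenario = "recovery"
    noise = NoiseSpec(seed=seed)
    corpus, _ = sample_esd_corpus(graph, n_esds, noise, scenario=scenario)
    labeled = label_corpus(corpus, make_lexicon(graph, noise, scenario))
    model = fit_ngram(labeled.label_sequences, order=2, scenario=scenario)
    errors = []
    for i, state in enumerate(graph.states):
        if model.context_counts.get((state,), 0) == 0:
            continue
        for j, succ in enumerate(graph.states):
            errors.append(abs(model.p(succ, state) - graph.transition_matrix[i, j]))
        errors.append(abs(model.p(EOS, state) - graph.transition_matrix[i, -1]))
    if not errors:
        raise ValueError("no state was ever observed as a context; increase n_esds")
    return RecoveryReport(
        n_esds=n_esds,
        max_abs_error=float(np.max(errors)),
        mean_abs_error=float(np.mean(errors)),
        n_cells=len(errors),
    )


# ---------------------------------------------------------------------------
# Likert rating simulation
# ---------------------------------------------------------------------------

#: Sum coding used throughout: the marked level of each factor is +1.
CODING = {
    "sententiality": {"sentence": -1.0, "fragment": 1.0},
    "predictability": {"predictable": -1.0, "unpredictable": 1.0},
    "script_type": {"two_participant": -1.0, "adapted": 1.0},
}

_CONDITIONS = (
    ("sentence", "predictable"),
    ("sentence", "unpredictable"),
    ("fragment", "predictable"),
    ("fragment", "unpredictable"),
)


def latin_square_design(n_subjects: int = 48, n_items: int = 24) -> pd.DataFrame:
    """2 × 2 Latin-square assignment of items to condition per subject.

    Subjects rotate through four lists; within a list, item ``i`` is
    shown in condition ``(i + list) mod 4``, so each subject sees every
    item exactly once and each quarter of the items in each condition.
    """
    if n_items % 4 != 0:
        raise ValueError("n_items must be divisible by 4 for a 2 x 2 Latin square")
    rows = []
    for s in range(n_subjects):
        lst = s % 4
        for i in range(n_items):
            sent, pred = _CONDITIONS[(i + lst) % 4]
            rows.append(
                {"subject": f"s{s + 1:02d}", "item": f"i{i + 1:02d}",
                 "list": lst + 1, "sententiality": sent, "predictability": pred}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RatingSimSpec:
    """Generating model for a simulated acceptability-rating experiment.

    Defaults reproduce the reference study's conditions: 48 subjects,
    24 items in a 2 × 2 Latin square, 7-point scale, fixed effects at
    the published final-model estimates (on the latent logit scale, with
    sum-coded ±1 factors), by-subject and by-item random intercepts and
    slopes for the two manipulated factors, standard-logistic residual
    noise, and five ungrammatical control trials per subject.
    """

    n_subjects: int = 48
    n_items: int = 24
    fixed_effects: dict[str, float] = field(
        default_factory=lambda: {
            "sententiality": -0.958,
            "predictability": -0.554,
            "script_familiarity": -0.012,
            "position": -0.021,
            "script_type": 0.0,
            "sententiality:predictability": -0.22,
            "predictability:script_familiarity": -0.206,
            "sententiality:script_familiarity": 0.0,
            "sententiality:predictability:script_familiarity": 0.0,
        }
    )
    random_sds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "subject": {"1": 1.0, "sententiality": 0.3, "predictability": 0.3},
            "item": {"1": 0.5, "sententiality": 0.2, "predictability": 0.2},
        }
    )
    thresholds: tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
    n_controls: int = 5
    control_shift: float = -4.0
    n_missing_familiarity: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        th = list(self.thresholds)
        if len(th) != 6 or any(b <= a for a, b in zip(th, th[1:])):
            raise ValueError("need 6 strictly increasing thresholds for a 7-point scale")
        for group, terms in self.random_sds.items():
            for t, sd in terms.items():
                if sd < 0:
                    raise ValueError(f"random SD for {group}/{t} must be >= 0")


def sample_ratings(spec: RatingSimSpec,
                   design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Simulate a trial-level Likert rating table from a known CLMM.

    The latent response is the sum of the fixed effects (±1 sum-coded
    factors, pooled z-scored familiarity, raw presentation position),
    the sampled normal random effects and a standard-logistic residual;
    the rating is the ordinal category the thresholds assign.  Control
    trials get a strongly negative latent shift, emulating ungrammatical
    fillers competent subjects reject.
    """
    rng = np.random.default_rng(spec.seed)
    if design is None:
        design = latin_square_design(spec.n_subjects, spec.n_items)
    else:
        counts = design.groupby(["subject", "item"]).size()
        if (counts != 1).any():
            raise ValueError("design must assign each (subject, item) pair exactly once")
    subjects = sorted(design["subject"].unique())
    items = sorted(design["item"].unique())

    # random effects: independent normal, one coefficient per group level & term
    u: dict[tuple[str, str, str], float] = {}
    for term, sd in spec.random_sds.get("subject", {}).items():
        for s in subjects:
            u[("subject", s, term)] = rng.normal(0.0, sd)
    for term, sd in spec.random_sds.get("item", {}).items():
        for it in items:
            u[("item", it, term)] = rng.normal(0.0, sd)

    # scenario-level attributes: script type alternates; familiarity raw 1-5
    script_type = {it: ("two_participant" if k % 2 == 0 else "adapted")
                   for k, it in enumerate(items)}
    missing_items = set(items[: spec.n_missing_familiarity])
    fam_item = {it: rng.normal(0.0, 0.7) for it in items}
    fam_raw: dict[tuple[str, str], float] = {}
    for s in subjects:
        leniency = rng.normal(0.0, 0.5)
        for it in items:
            raw = 4.2 + fam_item[it] + leniency + rng.normal(0.0, 0.6)
            fam_raw[(s, it)] = float(np.clip(round(raw), 1, 5))
    fam_values = [fam_raw[(s, it)] for s in subjects for it in items
                  if it not in missing_items]
    fam_mean = float(np.mean(fam_values))
    fam_sd = float(np.std(fam_values, ddof=1))

    # presentation order: a fresh permutation per subject
    positions = {
        s: {it: int(p) for it, p in zip(items, rng.permutation(len(items)) + 1)}
        for s in subjects
    }

    beta = spec.fixed_effects
    th = np.asarray(spec.thresholds)
    rows = []
    for _, trial in design.iterrows():
        s, it = trial["subject"], trial["item"]
        sent = CODING["sententiality"][trial["sententiality"]]
        pred = CODING["predictability"][trial["predictability"]]
        stype = CODING["script_type"][script_type[it]]
        missing = it in missing_items
        fam_z = 0.0 if missing else (fam_raw[(s, it)] - fam_mean) / fam_sd
        pos = positions[s][it]
        eta = (
            beta.get("sententiality", 0.0) * sent
            + beta.get("predictability", 0.0) * pred
            + beta.get("script_familiarity", 0.0) * fam_z
            + beta.get("position", 0.0) * pos
            + beta.get("script_type", 0.0) * stype
            + beta.get("sententiality:predictability", 0.0) * sent * pred
            + beta.get("sententiality:script_familiarity", 0.0) * sent * fam_z
            + beta.get("predictability:script_familiarity", 0.0) * pred * fam_z
            + beta.get("sententiality:predictability:script_familiarity", 0.0)
            * sent * pred * fam_z
        )
        for term, x in (("1", 1.0), ("sententiality", sent), ("predictability", pred)):
            eta += u.get(("subject", s, term), 0.0) * x
            eta += u.get(("item", it, term), 0.0) * x
        latent = eta + rng.logistic(0.0, 1.0)
        rating = 1 + int(np.sum(latent > th))
        rows.append(
            {
                "subject": s, "item": it, "scenario": it, "rating": rating,
                "sententiality": trial["sententiality"],
                "predictability": trial["predictability"],
                "script_type": script_type[it], "position": pos,
                "familiarity_raw": (np.nan if missing else fam_raw[(s, it)]),
                "is_control": False, "control_kind": "",
            }
        )

    for s in subjects:
        intercept = u.get(("subject", s, "1"), 0.0)
        for c in range(spec.n_controls):
            latent = spec.control_shift + intercept + rng.logistic(0.0, 1.0)
            rating = 1 + int(np.sum(latent > th))
            rows.append(
                {
                    "subject": s, "item": f"ctrl{c + 1}", "scenario": "control",
                    "rating": rating, "sententiality": "sentence",
                    "predictability": "unpredictable", "script_type": "adapted",
                    "position": 0, "familiarity_raw": np.nan,
                    "is_control": True, "control_kind": "ungrammatical",
                }
            )
    return pd.DataFrame(rows)
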
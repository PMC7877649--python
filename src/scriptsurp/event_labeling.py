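"""Canonical verb–noun event labels from raw event descriptions.

Each event description ("Put the pot on the stove") is reduced to an
event label consisting of the main verb and its post-verbal object noun
("put pot").  Labels only need to *distinguish* events for language
modeling, so the representation is deliberately coarse.  The pipeline is

1. parse — find the main verb and its direct object (a pluggable
   provider contract; :func:`fallback_parse` is the deterministic
   rule-based default),
2. extract — lemmatize and lowercase both, inserting a ``PLACEHOLDER``
   sentinel when no object is found (intransitives, object ellipsis),
3. normalize — resolve pronouns and elided objects and pool synonyms
   through a machine-readable :class:`NormalizationLexicon`, so that
   "boil the pasta for 8 minutes", "boil them" and "boil" all map to one
   label,
4. screen — a :class:`UniquenessReport` lists near-duplicate labels and
   unresolved placeholders for curation, replacing interactive manual
   review with versioned lexicon data.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol

import edlib

from scriptsurp.esd_corpus import ScriptCorpus

__all__ = [
    "PLACEHOLDER",
    "ParseResult",
    "EventLabel",
    "NormalizationLexicon",
    "UniquenessReport",
    "LabeledCorpus",
    "ParseUnavailableError",
    "LabelUnavailableError",
    "LexiconInvariantError",
    "parse_description",
    "fallback_parse",
    "extract_label",
    "normalize_label",
    "label_corpus",
    "lemmatize",
]

#: Sentinel object noun used when no post-verbal noun could be found.
PLACEHOLDER = "PLACEHOLDER"


class ParseUnavailableError(RuntimeError):
    """A parsing provider failed on a description; carries the text for the manual queue."""

    def __init__(self, text: str, reason: str = "") -> None:
        super().__init__(f"parse unavailable for {text!r}" + (f": {reason}" if reason else ""))
        self.text = text


class LabelUnavailableError(RuntimeError):
    """No head verb could be identified; the item is routed to the manual queue."""

    def __init__(self, text: str) -> None:
        super().__init__(f"no head verb found in {text!r}")
        self.text = text


class LexiconInvariantError(ValueError):
    """A lexicon map is not idempotent (a canonical value maps onward)."""


@dataclass(frozen=True)
class ParseResult:
    tokens: tuple[str, ...]
    pos_tags: tuple[str, ...]
    head_verb_index: int | None = None
    object_noun_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.pos_tags):
            raise ValueError("pos_tags must align 1:1 with tokens")
        for idx in (self.head_verb_index, self.object_noun_index):
            if idx is not None and not (0 <= idx < len(self.tokens)):
                raise ValueError(f"index {idx} outside token range")


@dataclass(frozen=True)
class EventLabel:
    """Canonical verb+noun pair; rendered as ``"verb noun"``."""

    verb: str
    noun: str
    source_text: str = ""

    def __post_init__(self) -> None:
        if not self.verb:
            raise ValueError("verb must be non-empty")

    def __str__(self) -> str:
        return f"{self.verb} {self.noun}"

    @property
    def is_placeholder(self) -> bool:
        return self.noun == PLACEHOLDER


class ParserProvider(Protocol):
    """Contract for parsing providers: description text in, ParseResult out."""

    def __call__(self, text: str) -> ParseResult: ...


# ---------------------------------------------------------------------------
# Rule-based fallback parser
# ---------------------------------------------------------------------------
# Small closed-class word lists; the open verb list covers everyday-activity
# imperatives.  Sentence-initial unknown tokens are still treated as verbs
# (crowd-sourced ESDs are overwhelmingly verb-first imperatives), so the list
# only matters for verbs in non-initial position.

_DETERMINERS = {
    "a", "an", "the", "this", "that", "these", "those", "some", "any", "all",
    "each", "every", "no", "your", "my", "his", "her", "its", "our", "their",
    "another", "both", "few", "several", "many", "much", "more", "most", "one",
    "two", "three", "four", "five", "half",
}
_PREPOSITIONS = {
    "in", "on", "at", "to", "into", "onto", "from", "with", "without", "for",
    "of", "by", "over", "under", "about", "after", "before", "until", "till",
    "during", "through", "off", "out", "up", "down", "near", "behind", "inside",
    "outside", "around", "across", "along", "upon",
}
_PRONOUNS = {"it", "them", "him", "her", "us", "me", "you", "they", "he", "she",
             "we", "i", "everything", "something", "anything"}
_CONJUNCTIONS = {"and", "or", "but", "then", "so", "while", "when", "if", "as",
                 "because", "once"}
_ADVERBS = {
    "carefully", "slowly", "quickly", "gently", "well", "thoroughly", "again",
    "first", "next", "now", "also", "just", "already", "together", "back",
    "away", "there", "here", "not",
}
_ADJECTIVES = {
    "hot", "cold", "warm", "boiling", "large", "small", "big", "little", "new",
    "old", "clean", "dirty", "fresh", "dry", "wet", "empty", "full", "whole",
    "right", "left", "good", "correct", "appropriate", "necessary", "desired",
    "remaining", "other", "own",
}
_COMMON_VERBS = {
    "add", "answer", "arrive", "ask", "bake", "beat", "begin", "board", "boil",
    "break", "bring", "brush", "buy", "call", "carry", "change", "check",
    "choose", "chop", "clean", "close", "collect", "combine", "come", "cook",
    "cool", "count", "cover", "crack", "cut", "decide", "dial", "drain",
    "dress", "drink", "drive", "drop", "dry", "eat", "empty", "enjoy", "enter",
    "exit", "fill", "find", "finish", "fix", "flip", "fold", "follow", "fry",
    "gather", "get", "give", "go", "grab", "grate", "greet", "hang", "heat",
    "hold", "insert", "keep", "knock", "leave", "let", "lift", "light",
    "listen", "look", "make", "measure", "melt", "mix", "move", "open",
    "order", "pack", "paint", "pay", "peel", "pick", "place", "plan", "plug",
    "pour", "preheat", "prepare", "press", "purchase", "push", "put", "read",
    "receive", "remove", "repeat", "return", "ride", "rinse", "salt", "scoop",
    "scramble", "scrub", "season", "select", "serve", "set", "shake", "shop",
    "sit", "slice", "spread", "sprinkle", "stand", "start", "stir", "stop",
    "strain", "switch", "take", "talk", "taste", "tell", "throw", "tip",
    "toss", "transfer", "turn", "unplug", "use", "wait", "walk", "wash",
    "watch", "wear", "whisk", "wipe",
}

_TOKEN_RE = re.compile(r"[A-Za-z][A-Za-z'.-]*")

# Irregular / awkward lemmas the suffix rules would get wrong.
_LEMMA_EXCEPTIONS = {
    "children": "child", "men": "man", "women": "woman", "feet": "foot",
    "teeth": "tooth", "knives": "knife", "loaves": "loaf", "leaves": "leaf",
    "shelves": "shelf", "dishes": "dish", "glasses": "glass", "boxes": "box",
    "potatoes": "potato", "tomatoes": "tomato", "groceries": "grocery",
    "utensils": "utensil", "noodles": "noodle", "eggs": "egg",
    "has": "have", "had": "have", "done": "do", "made": "make", "got": "get",
    "took": "take", "put": "put", "set": "set", "left": "leave", "bought": "buy",
    "chose": "choose", "chosen": "choose", "went": "go", "gone": "go",
    "pasta": "pasta", "water": "water", "is": "be", "are": "be", "was": "be",
}

_DOUBLED_FINAL = re.compile(r"(.)\1$")


def lemmatize(word: str) -> str:
    """Lowercase dictionary-plus-suffix-rule lemmatizer.

    Handles regular plurals (-s, -es, -ies) and common verb inflection
    (-ing, -ed, third-person -s) deterministically; irregular forms come
    from a small exception table.  Intentionally conservative: unknown
    short words pass through unchanged.
    """
    w = word.lower().strip(".,!?;:'\"")
    if not w:
        return w
    if w in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[w]
    if w in _DETERMINERS or w in _PREPOSITIONS or w in _PRONOUNS:
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses") or w.endswith("shes") or w.endswith("ches") or w.endswith("xes") or w.endswith("zes"):
        return w[:-2]
    if w.endswith("ss") or w.endswith("us"):
        return w
    if w.endswith("ing") and len(w) > 5:
        stem = w[:-3]
        if _DOUBLED_FINAL.search(stem):
            stem = stem[:-1]
        if stem in _COMMON_VERBS or stem + "e" in _COMMON_VERBS:
            return stem if stem in _COMMON_VERBS else stem + "e"
        return w
    if w.endswith("ed") and len(w) > 4:
        stem = w[:-2]
        if _DOUBLED_FINAL.search(stem):
            stem = stem[:-1]
        if stem in _COMMON_VERBS:
            return stem
        if w[:-1] in _COMMON_VERBS:  # e.g. "placed" -> "place"
            return w[:-1]
        return w
    if w.endswith("s") and len(w) > 3:
        return w[:-1]
    return w


def _guess_tag(token: str, index: int) -> str:
    w = token.lower()
    if w in _DETERMINERS:
        return "DT"
    if w in _PREPOSITIONS:
        return "IN"
    if w in _PRONOUNS:
        return "PRP"
    if w in _CONJUNCTIONS:
        return "CC"
    if w in _ADVERBS:
        return "RB"
    if w in _ADJECTIVES:
        return "JJ"
    lemma = lemmatize(w)
    if lemma in _COMMON_VERBS:
        return "VB"
    if index == 0:
        # Verb-first imperatives dominate ESD data; trust sentence position.
        return "VB"
    return "NN"


def fallback_parse(text: str) -> ParseResult:
    """Deterministic rule-based parse tuned to imperative event descriptions.

    The head verb is the first token tagged as a verb (known verb list,
    or any sentence-initial open-class token).  The object is the first
    noun or pronoun after the verb, skipping determiners, adjectives and
    adverbs; a preposition, conjunction or clause boundary before any
    noun means the verb has no direct object (e.g. "Pour in pan").
    """
    if not text or not text.strip():
        raise ValueError("fallback_parse requires non-empty text")
    tokens = tuple(_TOKEN_RE.findall(text))
    if not tokens:
        raise ValueError(f"no alphabetic tokens in {text!r}")
    tags = tuple(_guess_tag(t, i) for i, t in enumerate(tokens))

    verb_idx: int | None = None
    for i, tag in enumerate(tags):
        if tag == "VB":
            verb_idx = i
            break

    obj_idx: int | None = None
    if verb_idx is not None:
        for j in range(verb_idx + 1, len(tokens)):
            tag = tags[j]
            if tag in ("DT", "JJ", "RB"):
                continue
            if tag in ("IN", "CC", "VB"):
                break  # direct object position closed
            if tag in ("NN", "PRP"):
                obj_idx = j
                break
    return ParseResult(tokens=tokens, pos_tags=tags,
                       head_verb_index=verb_idx, object_noun_index=obj_idx)


def parse_description(text: str, parser: ParserProvider | None = None) -> ParseResult:
    """Parse one description through a provider, wrapping provider failures.

    A statistical parser can be plugged in through ``parser``; the
    default is :func:`fallback_parse`.
    """
    if not text or not text.strip():
        raise ValueError("parse_description requires non-empty text")
    provider = parser or fallback_parse
    try:
        return provider(text)
    except ValueError:
        raise
    except Exception as exc:  # provider contract: any failure -> manual queue
        raise ParseUnavailableError(text, str(exc)) from exc


def extract_label(parse: ParseResult, source_text: str = "") -> EventLabel:
    """Lemmatized verb+noun label from a parse; sentinel noun when objectless."""
    if parse.head_verb_index is None:
        raise LabelUnavailableError(source_text or " ".join(parse.tokens))
    verb = lemmatize(parse.tokens[parse.head_verb_index])
    if parse.object_noun_index is not None:
        noun = lemmatize(parse.tokens[parse.object_noun_index])
    else:
        noun = PLACEHOLDER
    return EventLabel(verb=verb, noun=noun,
                      source_text=source_text or " ".join(parse.tokens))


# ---------------------------------------------------------------------------
# Normalization lexicon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationLexicon:
    """Scenario-scoped maps that standardize event labels.

    ``synonym_map``
        surface participant/action lemma → canonical lemma (pan ← skillet);
    ``event_map``
        whole raw label string → canonical label string ("put content" →
        "pour egg"), applied last to pool syntactically different
        descriptions of one event;
    ``pronoun_map``
        (scenario, pronoun) → canonical noun;
    ``default_object_map``
        (scenario, verb) → canonical noun supplied when the object was
        elided.

    All maps must be idempotent: canonical values are fixed points.
    """

    synonym_map: dict[str, str] = field(default_factory=dict)
    event_map: dict[str, str] = field(default_factory=dict)
    pronoun_map: dict[tuple[str, str], str] = field(default_factory=dict)
    default_object_map: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.synonym_map.items():
            if value in self.synonym_map and self.synonym_map[value] != value:
                raise LexiconInvariantError(
                    f"synonym_map: canonical lemma {value!r} maps onward to "
                    f"{self.synonym_map[value]!r}"
                )
        for key, value in self.event_map.items():
            if value in self.event_map and self.event_map[value] != value:
                raise LexiconInvariantError(
                    f"event_map: canonical label {value!r} maps onward to "
                    f"{self.event_map[value]!r}"
                )

    # -- file I/O ----------------------------------------------------------
    @classmethod
    def from_dir(cls, directory: str | Path) -> "NormalizationLexicon":
        """Load the four lexicon tables from a directory of TSV files.

        Expected files (absent files mean empty maps): ``synonyms.tsv``
        (surface, canonical), ``events.tsv`` (raw_label, canonical_label),
        ``pronouns.tsv`` (scenario, pronoun, noun), ``default_objects.tsv``
        (scenario, verb, noun).
        """
        directory = Path(directory)

        def rows(fname: str) -> list[list[str]]:
            p = directory / fname
            if not p.exists():
                return []
            with open(p, encoding="utf-8", newline="") as fh:
                reader = csv.reader(fh, delimiter="\t")
                header = next(reader, None)
                return [r for r in reader if r and any(cell.strip() for cell in r)]

        return cls(
            synonym_map={r[0]: r[1] for r in rows("synonyms.tsv")},
            event_map={r[0]: r[1] for r in rows("events.tsv")},
            pronoun_map={(r[0], r[1]): r[2] for r in rows("pronouns.tsv")},
            default_object_map={(r[0], r[1]): r[2] for r in rows("default_objects.tsv")},
        )

    def to_dir(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)

        def dump(fname: str, header: list[str], rows: Iterable[Iterable[str]]) -> None:
            with open(directory / fname, "w", encoding="utf-8", newline="") as fh:
                w = csv.writer(fh, delimiter="\t")
                w.writerow(header)
                w.writerows(rows)

        dump("synonyms.tsv", ["surface", "canonical"], sorted(self.synonym_map.items()))
        dump("events.tsv", ["raw_label", "canonical_label"], sorted(self.event_map.items()))
        dump("pronouns.tsv", ["scenario", "pronoun", "noun"],
             sorted((s, p, n) for (s, p), n in self.pronoun_map.items()))
        dump("default_objects.tsv", ["scenario", "verb", "noun"],
             sorted((s, v, n) for (s, v), n in self.default_object_map.items()))


def normalize_label(label: EventLabel, lexicon: NormalizationLexicon,
                    scenario: str) -> EventLabel:
    """Resolve pronouns/ellipsis and pool synonyms; idempotent by construction."""
    verb, noun = label.verb, label.noun
    if (scenario, noun) in lexicon.pronoun_map:
        noun = lexicon.pronoun_map[(scenario, noun)]
    if noun == PLACEHOLDER and (scenario, verb) in lexicon.default_object_map:
        noun = lexicon.default_object_map[(scenario, verb)]
    verb = lexicon.synonym_map.get(verb, verb)
    if noun != PLACEHOLDER:
        noun = lexicon.synonym_map.get(noun, noun)
    raw = f"{verb} {noun}"
    canon = lexicon.event_map.get(raw, raw)
    cverb, _, cnoun = canon.partition(" ")
    return EventLabel(verb=cverb, noun=cnoun or PLACEHOLDER,
                      source_text=label.source_text)


# ---------------------------------------------------------------------------
# Corpus-level labeling + uniqueness screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UniquenessReport:
    """Screening output replacing the manual curation pass.

    ``merge_candidates`` groups distinct labels that plausibly denote one
    event (same verb with nouns within edit distance 2, or same noun with
    near-identical verbs); ``unresolved_placeholders`` lists labels whose
    object could not be resolved; inventories enumerate the canonical
    participants and actions for closed-class screening.
    """

    merge_candidates: tuple[tuple[str, ...], ...]
    unresolved_placeholders: tuple[EventLabel, ...]
    participant_inventory: frozenset[str]
    action_inventory: frozenset[str]
    manual_queue: tuple[str, ...] = ()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["kind", "detail"])
            for group in self.merge_candidates:
                w.writerow(["merge_candidate", " | ".join(group)])
            for lab in self.unresolved_placeholders:
                w.writerow(["unresolved_placeholder", f"{lab} <= {lab.source_text}"])
            for text in self.manual_queue:
                w.writerow(["manual_queue", text])


@dataclass(frozen=True)
class LabeledCorpus:
    scenario: str
    sequences: tuple[tuple[EventLabel, ...], ...]
    esd_ids: tuple[str, ...]
    report: UniquenessReport

    @property
    def label_sequences(self) -> list[list[str]]:
        """Sequences as plain label strings, ready for n-gram fitting."""
        return [[str(lab) for lab in seq] for seq in self.sequences]


def _edit_distance(a: str, b: str) -> int:
    if a == b:
        return 0
    return edlib.align(a, b, task="distance")["editDistance"]


def _merge_candidates(labels: set[EventLabel]) -> tuple[tuple[str, ...], ...]:
    """Disjoint groups of distinct label strings that likely co-denote one event."""
    strings = sorted({str(lab) for lab in labels})
    parent = {s: s for s in strings}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    parts = {s: tuple(s.split(" ", 1)) for s in strings}
    for i, a in enumerate(strings):
        va, na = parts[a][0], parts[a][1] if len(parts[a]) > 1 else ""
        for b in strings[i + 1:]:
            vb, nb = parts[b][0], parts[b][1] if len(parts[b]) > 1 else ""
            if va == vb and na != nb and _edit_distance(na, nb) <= 2:
                union(a, b)
            elif na == nb and na != "" and va != vb and _edit_distance(va, vb) <= 2:
                union(a, b)
    groups: dict[str, list[str]] = {}
    for s in strings:
        groups.setdefault(find(s), []).append(s)
    return tuple(tuple(g) for g in groups.values() if len(g) > 1)


def label_corpus(corpus: ScriptCorpus, lexicon: NormalizationLexicon,
                 parser: ParserProvider | None = None) -> LabeledCorpus:
    """Label every ESD of a corpus; failures go to the report, never dropped.

    Order within each ESD is preserved and one label is produced per
    description (descriptions whose parse fails are kept as
    ``PLACEHOLDER``-noun labels with verb ``UNPARSED`` and queued), so
    the total label count always equals the total description count.
    """
    sequences: list[tuple[EventLabel, ...]] = []
    manual_queue: list[str] = []
    all_labels: set[EventLabel] = set()
    unresolved: list[EventLabel] = []
    for esd in corpus.esds:
        seq: list[EventLabel] = []
        for ev in esd.events:
            try:
                parse = parse_description(ev.text, parser)
                label = extract_label(parse, source_text=ev.text)
            except (ParseUnavailableError, LabelUnavailableError):
                manual_queue.append(ev.text)
                label = EventLabel(verb="UNPARSED", noun=PLACEHOLDER, source_text=ev.text)
                seq.append(label)
                continue
            label = normalize_label(label, lexicon, corpus.scenario)
            if label.is_placeholder:
                unresolved.append(label)
            seq.append(label)
            all_labels.add(label)
        sequences.append(tuple(seq))

    clean = {lab for lab in all_labels if not lab.is_placeholder}
    report = UniquenessReport(
        merge_candidates=_merge_candidates(clean),
        unresolved_placeholders=tuple(unresolved),
        participant_inventory=frozenset(lab.noun for lab in clean),
        action_inventory=frozenset(lab.verb for lab in clean),
        manual_queue=tuple(manual_queue),
    )
    return LabeledCorpus(
        scenario=corpus.scenario,
        sequences=tuple(sequences),
        esd_ids=tuple(esd.esd_id for esd in corpus.esds),
        report=report,
    )
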
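"""Readers, writers and validation for event-sequence-description corpora.

An event-sequence description (ESD) is one contributor's ordered list of
short textual descriptions of the events of a script (a stereotyped
everyday activity such as cooking pasta).  A :class:`ScriptCorpus`
bundles the roughly one hundred ESDs collected for one scenario.

Two on-disk dialects are supported:

* an XML dialect — a ``<corpus>`` root holding one or more
  ``<scenario name="..." title="..." script_type="...">`` elements, each
  containing ``<esd id="..." contributor="...">`` elements whose ordered
  ``<event position="N">text</event>`` children carry the descriptions;
* a delimited-text dialect (TSV or CSV) with header columns
  ``scenario``, ``esd_id``, ``position``, ``text`` and optional
  ``contributor``, ``script_type``, ``title`` — the canonical fixture
  format, chosen because plain tables are diffable and trivially
  round-trippable.

Text is kept faithful at this layer: surrounding whitespace is trimmed
and internal whitespace runs collapsed to a single space, but case and
wording are preserved so downstream normalization stays auditable.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from lxml import etree

__all__ = [
    "EventDescription",
    "ESD",
    "ScriptCorpus",
    "CorpusValidationError",
    "CorpusParseError",
    "read_corpus_xml",
    "read_corpora_xml",
    "write_corpus_xml",
    "read_corpus_table",
    "write_corpus_table",
    "corpus_summary",
]

ScriptType = Literal["two_participant", "adapted"]

_WS_RUN = re.compile(r"\s+")


class CorpusParseError(ValueError):
    """Raised when a corpus file cannot be parsed at all (bad XML, bad schema)."""


class CorpusValidationError(ValueError):
    """Raised when a parsed corpus violates a structural invariant."""


def _clean_text(raw: str) -> str:
    return _WS_RUN.sub(" ", raw.strip())


@dataclass(frozen=True)
class EventDescription:
    """One raw textual event description within an ESD.

    ``position`` is 1-based and consecutive within the owning ESD,
    matching the narrative ordering of events.
    """

    text: str
    esd_id: str
    position: int

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise CorpusValidationError(
                f"empty event text at position {self.position} of ESD {self.esd_id!r}"
            )
        if self.position < 1:
            raise CorpusValidationError(
                f"position must be >= 1, got {self.position} in ESD {self.esd_id!r}"
            )


@dataclass(frozen=True)
class ESD:
    """One contributor's ordered event-sequence description."""

    esd_id: str
    events: tuple[EventDescription, ...]
    contributor: str = ""

    def __post_init__(self) -> None:
        if len(self.events) == 0:
            raise CorpusValidationError(f"ESD {self.esd_id!r} has no events")
        positions = [e.position for e in self.events]
        if positions != list(range(1, len(positions) + 1)):
            raise CorpusValidationError(
                f"ESD {self.esd_id!r}: positions must be consecutive from 1, got {positions}"
            )
        for e in self.events:
            if e.esd_id != self.esd_id:
                raise CorpusValidationError(
                    f"event at position {e.position} carries esd_id {e.esd_id!r}, "
                    f"expected {self.esd_id!r}"
                )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def texts(self) -> list[str]:
        return [e.text for e in self.events]


@dataclass(frozen=True)
class ScriptCorpus:
    """All ESDs collected for one scenario."""

    scenario: str
    esds: tuple[ESD, ...]
    script_type: ScriptType | None = None
    title: str = ""

    def __post_init__(self) -> None:
        if not self.scenario.strip():
            raise CorpusValidationError("scenario name must be non-empty")
        ids = [e.esd_id for e in self.esds]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CorpusValidationError(
                f"duplicate esd_id(s) in scenario {self.scenario!r}: {sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.esds)

    @property
    def n_events(self) -> int:
        return sum(len(e) for e in self.esds)


def _build_esd(esd_id: str, contributor: str, texts: Sequence[str]) -> ESD:
    events = tuple(
        EventDescription(text=_clean_text(t), esd_id=esd_id, position=i + 1)
        for i, t in enumerate(texts)
    )
    return ESD(esd_id=esd_id, events=events, contributor=contributor)


def _corpus_from_scenario_element(scen: etree._Element) -> ScriptCorpus:
    name = _clean_text(scen.get("name", ""))
    if not name:
        raise CorpusValidationError(
            f"scenario element at line {scen.sourceline} has no name attribute"
        )
    script_type = scen.get("script_type") or None
    if script_type is not None and script_type not in ("two_participant", "adapted"):
        raise CorpusValidationError(
            f"unknown script_type {script_type!r} in scenario {name!r}"
        )
    esds = []
    for esd_el in scen.iterfind("esd"):
        esd_id = esd_el.get("id", "")
        if not esd_id:
            raise CorpusValidationError(
                f"esd element at line {esd_el.sourceline} has no id attribute"
            )
        texts = []
        for ev in esd_el.iterfind("event"):
            pos_attr = ev.get("position")
            if pos_attr is not None and int(pos_attr) != len(texts) + 1:
                raise CorpusValidationError(
                    f"ESD {esd_id!r}: event at line {ev.sourceline} declares position "
                    f"{pos_attr}, expected {len(texts) + 1}"
                )
            texts.append(ev.text or "")
        esds.append(_build_esd(esd_id, esd_el.get("contributor", ""), texts))
    if not esds:
        raise CorpusValidationError(f"scenario {name!r} contains no ESDs")
    return ScriptCorpus(
        scenario=name,
        esds=tuple(esds),
        script_type=script_type,  # type: ignore[arg-type]
        title=_clean_text(scen.get("title", "")),
    )


def read_corpora_xml(path: str | Path) -> list[ScriptCorpus]:
    """Read every scenario in an XML corpus file, one :class:`ScriptCorpus` each."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag == "scenario":
        scenarios = [root]
    else:
        scenarios = list(root.iterfind("scenario"))
    if not scenarios:
        raise CorpusParseError(f"{path}: no scenario elements found")
    return [_corpus_from_scenario_element(s) for s in scenarios]


def read_corpus_xml(path: str | Path, scenario: str | None = None) -> ScriptCorpus:
    """Read a single scenario's corpus from an XML file.

    Parameters
    ----------
    path:
        XML file in the documented dialect.
    scenario:
        Scenario name to select when the file holds several; may be
        omitted for single-scenario files.
    """
    corpora = read_corpora_xml(path)
    if scenario is None:
        if len(corpora) > 1:
            raise CorpusValidationError(
                f"{path} holds {len(corpora)} scenarios; pass scenario= to select one"
            )
        return corpora[0]
    for c in corpora:
        if c.scenario == scenario:
            return c
    raise CorpusValidationError(f"scenario {scenario!r} not found in {path}")


def write_corpus_xml(corpora: ScriptCorpus | Iterable[ScriptCorpus], path: str | Path) -> None:
    """Write one or more corpora to the XML dialect (UTF-8, indented)."""
    if isinstance(corpora, ScriptCorpus):
        corpora = [corpora]
    root = etree.Element("corpus")
    for corpus in corpora:
        scen = etree.SubElement(root, "scenario", name=corpus.scenario)
        if corpus.title:
            scen.set("title", corpus.title)
        if corpus.script_type is not None:
            scen.set("script_type", corpus.script_type)
        for esd in corpus.esds:
            esd_el = etree.SubElement(scen, "esd", id=esd.esd_id)
            if esd.contributor:
                esd_el.set("contributor", esd.contributor)
            for ev in esd.events:
                ev_el = etree.SubElement(esd_el, "event", position=str(ev.position))
                ev_el.text = ev.text
    etree.ElementTree(root).write(
        str(path), encoding="utf-8", xml_declaration=True, pretty_print=True
    )


_REQUIRED_COLS = ("scenario", "esd_id", "position", "text")


def read_corpus_table(path: str | Path, scenario: str | None = None) -> ScriptCorpus:
    """Read a corpus from the delimited-text dialect.

    The delimiter is sniffed from the header line (tab preferred,
    comma otherwise).  Rows belonging to one ESD must appear with
    consecutive positions 1, 2, ... in file order.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8")
    header_line = raw.splitlines()[0] if raw else ""
    delim = "\t" if "\t" in header_line else ","
    reader = csv.DictReader(io.StringIO(raw), delimiter=delim)
    cols = reader.fieldnames or []
    missing = [c for c in _REQUIRED_COLS if c not in cols]
    if missing:
        raise CorpusParseError(f"{path}: missing required column(s) {missing}")

    scenarios: dict[str, dict] = {}
    for lineno, row in enumerate(reader, start=2):
        scen = _clean_text(row["scenario"])
        if scenario is not None and scen != scenario:
            continue
        info = scenarios.setdefault(
            scen,
            {"esds": {}, "script_type": None, "title": ""},
        )
        st = _clean_text(row.get("script_type") or "")
        if st:
            if st not in ("two_participant", "adapted"):
                raise CorpusValidationError(f"{path}:{lineno}: unknown script_type {st!r}")
            info["script_type"] = st
        title = _clean_text(row.get("title") or "")
        if title:
            info["title"] = title
        esd_id = row["esd_id"]
        entry = info["esds"].setdefault(esd_id, {"texts": [], "contributor": ""})
        contributor = _clean_text(row.get("contributor") or "")
        if contributor:
            entry["contributor"] = contributor
        try:
            pos = int(row["position"])
        except (TypeError, ValueError):
            raise CorpusValidationError(
                f"{path}:{lineno}: non-integer position {row['position']!r}"
            ) from None
        if pos != len(entry["texts"]) + 1:
            raise CorpusValidationError(
                f"{path}:{lineno}: ESD {esd_id!r} position {pos} breaks the "
                f"consecutive-from-1 ordering (expected {len(entry['texts']) + 1})"
            )
        entry["texts"].append(row["text"])

    if not scenarios:
        raise CorpusValidationError(f"{path}: no rows for scenario {scenario!r}")
    if scenario is None and len(scenarios) > 1:
        raise CorpusValidationError(
            f"{path} holds scenarios {sorted(scenarios)}; pass scenario= to select one"
        )
    name, info = next(iter(scenarios.items())) if scenario is None else (scenario, scenarios[scenario])
    esds = tuple(
        _build_esd(esd_id, entry["contributor"], entry["texts"])
        for esd_id, entry in info["esds"].items()
    )
    return ScriptCorpus(
        scenario=name, esds=esds, script_type=info["script_type"], title=info["title"]
    )


def write_corpus_table(corpus: ScriptCorpus, path: str | Path, delimiter: str = "\t") -> None:
    """Write a corpus in the delimited-text dialect (round-trips with the reader)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(
            ["scenario", "esd_id", "position", "text", "contributor", "script_type", "title"]
        )
        for esd in corpus.esds:
            for ev in esd.events:
                writer.writerow(
                    [
                        corpus.scenario,
                        esd.esd_id,
                        ev.position,
                        ev.text,
                        esd.contributor,
                        corpus.script_type or "",
                        corpus.title,
                    ]
                )


@dataclass(frozen=True)
class CorpusSummary:
    scenario: str
    esd_count: int
    event_count: int
    mean_esd_length: float
    min_esd_length: int
    max_esd_length: int
    distinct_descriptions: int


def corpus_summary(corpus: ScriptCorpus) -> CorpusSummary:
    """Summary statistics of a corpus (ESD count, length range, distinct texts)."""
    lengths = [len(e) for e in corpus.esds]
    distinct = {ev.text for esd in corpus.esds for ev in esd.events}
    return CorpusSummary(
        scenario=corpus.scenario,
        esd_count=len(corpus.esds),
        event_count=sum(lengths),
        mean_esd_length=sum(lengths) / len(lengths),
        min_esd_length=min(lengths),
        max_esd_length=max(lengths),
        distinct_descriptions=len(distinct),
    )
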
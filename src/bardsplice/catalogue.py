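"""Multi-assay, multi-tissue splicing-event catalogue algebra.

The catalogue is a table with one row per splicing event (plus the
full-length reference row) and one detection column per
(assay, source, tissue) triple.  Assays are NS (nanopore sequencing of
full-length transcripts), RS (whole-transcriptome short-read RNA-seq),
TRS (targeted short-read RNA-seq) and RP (RT-PCR).  Cell values are
``+`` (detected), ``N`` (assayed, reported as N) or ``-`` (blank);
only ``+`` counts as a detection in every operation — the packaged
BARD1 catalogue's headline counts are only consistent under that
reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

import pandas as pd

from .errors import InputError, ModelError
from .events import SpliceEvent, decompose_compound, parse_event_code

ASSAYS = ("NS", "RS", "TRS", "RP")
SEQUENCING_ASSAYS = ("NS", "RS", "TRS")


@dataclass(frozen=True)
class DetectionColumn:
    assay: str
    source: str
    tissue: str

    @property
    def key(self) -> str:
        return f"{self.assay}|{self.source}|{self.tissue}"


@dataclass(frozen=True)
class CatalogueEntry:
    event: SpliceEvent
    functional: str                       # printed symbol: 'IF' | 'FS' | '?'
    novel_in_study: bool
    detections: dict                      # DetectionColumn -> '+' | 'N' | '-'

    @property
    def code(self) -> str:
        return self.event.code

    def positive_columns(self) -> list[DetectionColumn]:
        return [c for c, v in self.detections.items() if v == "+"]


@dataclass(frozen=True)
class Catalogue:
    entries: tuple[CatalogueEntry, ...]
    reference: Optional[CatalogueEntry]
    columns: tuple[DetectionColumn, ...]

    def __post_init__(self):
        codes = [e.code for e in self.entries]
        dupes = {c for c in codes if codes.count(c) > 1}
        if dupes:
            raise InputError(f"duplicate event codes in catalogue: {sorted(dupes)}")
        if self.reference is not None and self.reference.novel_in_study:
            raise InputError("the full-length reference row cannot be flagged novel")
        for e in self.entries:
            if not e.positive_columns():
                raise InputError(f"catalogue entry {e.code} has no '+' detection")

    @property
    def tissues(self) -> list[str]:
        seen = []
        for c in self.columns:
            if c.tissue not in seen:
                seen.append(c.tissue)
        return seen

    def entry(self, code: str) -> CatalogueEntry:
        for e in self.entries:
            if e.code == code:
                return e
        raise KeyError(code)

    def __contains__(self, code: str) -> bool:
        return any(e.code == code for e in self.entries)


def load_catalogue(source) -> Catalogue:
    """Read a catalogue TSV (event_code, r_description, functional, novel,
    then one ``assay|source|tissue`` column per detection context)."""
    df = pd.read_csv(source, sep="\t", dtype=str).fillna("-")
    fixed = ["event_code", "functional", "novel"]
    if not set(fixed) <= set(df.columns):
        raise InputError(f"catalogue needs columns {fixed}")
    det_cols = [c for c in df.columns if "|" in c]
    if not det_cols:
        raise InputError("catalogue has no assay|source|tissue detection columns")
    columns = []
    for c in det_cols:
        assay, src, tissue = c.split("|")
        if assay not in ASSAYS:
            raise InputError(f"unknown assay {assay!r} in column {c!r}")
        columns.append(DetectionColumn(assay, src, tissue))
    entries, reference = [], None
    for _, row in df.iterrows():
        code = row["event_code"].strip()
        rdesc = row.get("r_description", "")
        event = parse_event_code(code, None if rdesc in ("", "-") else rdesc)
        det = {}
        for col, name in zip(columns, det_cols):
            v = row[name].strip()
            if v not in ("+", "N", "-"):
                raise InputError(f"bad detection symbol {v!r} for {code}/{name}")
            det[col] = v
        entry = CatalogueEntry(
            event=event,
            functional=row["functional"].strip(),
            novel_in_study=row["novel"].strip().lower() in ("yes", "true", "1"),
            detections=det,
        )
        if event.kind == "ref":
            reference = entry
        else:
            entries.append(entry)
    return Catalogue(entries=tuple(entries), reference=reference, columns=tuple(columns))


def bard1_catalogue() -> Catalogue:
    """The packaged BARD1 catalogue (62 alternative events + reference)."""
    with resources.as_file(resources.files("bardsplice.data").joinpath("bard1_catalogue.tsv")) as p:
        return load_catalogue(p)


# ---------------------------------------------------------------------------
# counting operations
# ---------------------------------------------------------------------------


def count_alternative_events(cat: Catalogue) -> int:
    """Number of alternative splicing events (reference row excluded)."""
    return len(cat.entries)


def novel_events(cat: Catalogue) -> list[CatalogueEntry]:
    """Entries first described by the contributing laboratories."""
    return [e for e in cat.entries if e.novel_in_study]


def tissue_specific(cat: Catalogue, tissue: str) -> list[CatalogueEntry]:
    """Entries whose detections ('+') all fall in the given tissue."""
    if tissue not in cat.tissues:
        raise KeyError(f"unknown tissue {tissue!r}; catalogue has {cat.tissues}")
    out = []
    for e in cat.entries:
        pos = e.positive_columns()
        if pos and all(c.tissue == tissue for c in pos):
            out.append(e)
    return out


def assay_exclusive(
    cat: Catalogue, assay_set_a: Iterable[str], assay_set_b: Iterable[str]
) -> list[CatalogueEntry]:
    """Entries detected by at least one assay in set A and by none in set B."""
    a, b = set(assay_set_a), set(assay_set_b)
    for s in a | b:
        if s not in ASSAYS:
            raise InputError(f"unknown assay {s!r}")
    if a & b:
        raise InputError(f"assay sets overlap: {sorted(a & b)}")
    out = []
    for e in cat.entries:
        assays = {c.assay for c in e.positive_columns()}
        if assays & a and not assays & b:
            out.append(e)
    return out


def compound_entries(cat: Catalogue) -> list[CatalogueEntry]:
    """Entries whose event combines two or more non-contiguous events."""
    return [e for e in cat.entries if e.event.is_compound]


def isoform_event_coverage(cat: Catalogue, assay: str) -> tuple[int, int]:
    """(isoforms detected by the assay, distinct single events they account for).

    A compound isoform contributes both its own code and those of its
    constituent single events that are themselves catalogue entries —
    the reading under which full-length-transcript sequencing of 16
    isoforms accounts for 18 of the catalogued events.
    """
    if assay not in ASSAYS:
        raise InputError(f"unknown assay {assay!r}")
    isoforms = [e for e in cat.entries
                if any(c.assay == assay for c in e.positive_columns())]
    events: set[str] = set()
    for e in isoforms:
        events.add(e.code)
        for single in decompose_compound(e.event):
            if single in cat:
                events.add(single)
    return len(isoforms), len(events)


def consistency_report(cat: Catalogue) -> list[str]:
    """Warnings for compound entries whose constituent singles are catalogued
    but never detected where sequencing resolved the compound (report mode)."""
    warnings = []
    for e in compound_entries(cat):
        seq_cols = {c for c in e.positive_columns() if c.assay in SEQUENCING_ASSAYS}
        if not seq_cols:
            continue
        for single in decompose_compound(e.event):
            if single in cat and not cat.entry(single).positive_columns():
                warnings.append(f"{e.code}: constituent {single} never detected")
    return warnings


def summary(cat: Catalogue) -> dict:
    """Headline catalogue statistics as a flat dict (report payload)."""
    rp_only = assay_exclusive(cat, {"RP"}, set(SEQUENCING_ASSAYS))
    ns_only = assay_exclusive(cat, {"NS"}, {"RS", "TRS", "RP"})
    iso, ev = isoform_event_coverage(cat, "NS")
    return {
        "alternative_events": count_alternative_events(cat),
        "novel_events": len(novel_events(cat)),
        "lcl_specific": len(tissue_specific(cat, "LCL")) if "LCL" in cat.tissues else 0,
        "rtpcr_only": len(rp_only),
        "rtpcr_only_compound": sum(1 for e in rp_only if e.event.is_compound),
        "nanopore_exclusive": len(ns_only),
        "compound_entries": len(compound_entries(cat)),
        "max_events_per_isoform": max(
            (len(e.event.terms) for e in cat.entries), default=0),
        "nanopore_isoforms": iso,
        "nanopore_distinct_events": ev,
    }
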
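"""Reference transcript model in cDNA coordinates.

The model is an ordered list of exons whose c. intervals tile the coding
sequence contiguously (c. numbering runs across junctions without gaps),
plus the CDS extent and the encoded protein length.  For BARD1 the
packaged default reconstructs the 11-exon reference transcript
(NM_000465.3-equivalent exon boundaries, 777-residue protein, CDS end at
c.2334 including the stop codon).

Functional domains (RING, ARD, BRCT) are represented either at codon
resolution or — the authoritative mode for classifier logic — as exon
ranges.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .errors import ModelError


@dataclass(frozen=True)
class Exon:
    index: int
    start: int  # c. position of the first exonic nucleotide
    end: int    # c. position of the last exonic nucleotide

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure, CDS extent and protein length of one transcript."""

    exons: tuple[Exon, ...]
    cds_start: int = 1
    cds_end: int = 0
    protein_length: int = 0

    def __post_init__(self):
        if len(self.exons) < 2:
            raise ModelError("a transcript model needs at least two exons")
        prev = None
        for ex in self.exons:
            if ex.start > ex.end:
                raise ModelError(f"exon {ex.index}: start {ex.start} > end {ex.end}")
            if prev is not None:
                if ex.index != prev.index + 1:
                    raise ModelError(f"exon indices not consecutive: {prev.index} -> {ex.index}")
                if ex.start != prev.end + 1:
                    raise ModelError(
                        f"exons {prev.index} and {ex.index} are not contiguous in c. space: "
                        f"c.{prev.end} followed by c.{ex.start}"
                    )
            prev = ex
        if self.cds_end != 3 * (self.protein_length + 1):
            raise ModelError(
                f"cds_end {self.cds_end} inconsistent with protein length "
                f"{self.protein_length} (expected {3 * (self.protein_length + 1)})"
            )
        if self.exons[-1].end != self.cds_end:
            raise ModelError(
                f"last exon ends at c.{self.exons[-1].end} but cds_end is c.{self.cds_end}"
            )

    # -- lookups ---------------------------------------------------------

    def exon(self, index: int) -> Exon:
        for ex in self.exons:
            if ex.index == index:
                return ex
        raise ModelError(f"no exon {index} in model")

    def exon_length(self, index: int) -> int:
        return self.exon(index).length

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_of_position(self, pos: int) -> Exon:
        for ex in self.exons:
            if ex.start <= pos <= ex.end:
                return ex
        raise ModelError(f"c.{pos} outside the transcript (1..{self.cds_end})")

    def codon_of_position(self, pos: int) -> int:
        """1-based codon index containing c. position ``pos``."""
        if not (self.cds_start <= pos <= self.cds_end):
            raise ModelError(f"c.{pos} outside the CDS ({self.cds_start}..{self.cds_end})")
        return math.ceil(pos / 3)

    def natural_junctions(self) -> list[tuple[int, int]]:
        """The (donor, acceptor) c. positions of every natural junction."""
        return [
            (self.exons[i].end, self.exons[i + 1].start)
            for i in range(len(self.exons) - 1)
        ]

    def is_natural_junction(self, donor: int, acceptor: int) -> bool:
        return (donor, acceptor) in set(self.natural_junctions())

    def boundary_site(self, pos: int) -> tuple[int, str] | None:
        """If ``pos`` is an exon boundary, return (exon index, 'donor'|'acceptor')."""
        for ex in self.exons:
            if pos == ex.end and ex.index < self.n_exons:
                return ex.index, "donor"
            if pos == ex.start and ex.index > 1:
                return ex.index, "acceptor"
        return None


@dataclass(frozen=True)
class DomainInterval:
    name: str
    start: int  # codon or exon index depending on the map level
    end: int


@dataclass(frozen=True)
class DomainMap:
    """Functional-domain intervals, at codon or exon resolution."""

    domains: tuple[DomainInterval, ...]
    level: str = "exon"  # 'exon' | 'codon'

    def __post_init__(self):
        if self.level not in ("exon", "codon"):
            raise ModelError(f"unknown domain map level {self.level!r}")
        prev_end = 0
        for d in sorted(self.domains, key=lambda d: d.start):
            if d.start > d.end:
                raise ModelError(f"domain {d.name}: start {d.start} > end {d.end}")
            if d.start <= prev_end:
                raise ModelError(f"domain intervals overlap at {d.name}")
            prev_end = d.end

    def names(self) -> list[str]:
        return [d.name for d in self.domains]

    def affected_by_exons(self, exons: Iterable[int]) -> list[str]:
        """Domains whose exon interval intersects any of ``exons`` (exon-level map)."""
        exset = set(exons)
        hits = []
        for d in self.domains:
            if exset & set(range(d.start, d.end + 1)):
                hits.append(d.name)
        return hits

    def affected_by_codons(self, start: int, end: int) -> list[str]:
        return [d.name for d in self.domains if not (end < d.start or start > d.end)]

    def downstream_of(self, pos: int) -> list[str]:
        """Domains lying at or downstream of codon/exon ``pos``."""
        return [d.name for d in self.domains if d.end >= pos]


# -- loaders -------------------------------------------------------------


def load_transcript_model(source, protein_length: int | None = None) -> TranscriptModel:
    """Build a TranscriptModel from an exon-boundary table.

    ``source`` is a path or file-like object holding a TSV with header
    ``exon  c_start  c_end``.  The CDS is taken to start at c.1 and end at
    the last exon's end; ``protein_length`` defaults to cds_end/3 - 1.
    """
    df = pd.read_csv(source, sep="\t")
    required = {"exon", "c_start", "c_end"}
    if not required <= set(df.columns):
        raise ModelError(f"exon table must have columns {sorted(required)}")
    exons = tuple(
        Exon(int(r.exon), int(r.c_start), int(r.c_end))
        for r in df.sort_values("exon").itertuples()
    )
    cds_end = exons[-1].end
    if protein_length is None:
        if cds_end % 3:
            raise ModelError(f"cds_end c.{cds_end} is not a codon multiple")
        protein_length = cds_end // 3 - 1
    return TranscriptModel(exons=exons, cds_end=cds_end, protein_length=protein_length)


def load_domain_map(source) -> DomainMap:
    """Load a domain table (TSV, codon- or exon-level columns)."""
    df = pd.read_csv(source, sep="\t")
    if {"domain", "codon_start", "codon_end"} <= set(df.columns):
        level, s, e = "codon", "codon_start", "codon_end"
    elif {"domain", "exon_start", "exon_end"} <= set(df.columns):
        level, s, e = "exon", "exon_start", "exon_end"
    else:
        raise ModelError("domain table needs domain + codon_/exon_ start/end columns")
    doms = tuple(
        DomainInterval(str(r["domain"]), int(r[s]), int(r[e])) for _, r in df.iterrows()
    )
    return DomainMap(domains=doms, level=level)


def load_model_config(source) -> tuple[TranscriptModel, DomainMap]:
    """Load model + domain map from a single YAML/JSON config."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    cfg = yaml.safe_load(text)
    exons = tuple(Exon(int(e["exon"]), int(e["c_start"]), int(e["c_end"])) for e in cfg["exons"])
    cds_end = exons[-1].end
    model = TranscriptModel(
        exons=exons, cds_end=cds_end,
        protein_length=int(cfg.get("protein_length", cds_end // 3 - 1)),
    )
    level = cfg.get("domain_level", "exon")
    doms = tuple(
        DomainInterval(d["domain"], int(d["start"]), int(d["end"]))
        for d in cfg.get("domains", [])
    )
    return model, DomainMap(domains=doms, level=level)


def _data(name: str):
    return resources.files("bardsplice.data").joinpath(name)


def bard1_model() -> TranscriptModel:
    """The packaged 11-exon BARD1 reference transcript model."""
    with resources.as_file(_data("bard1_exons.tsv")) as p:
        return load_transcript_model(p)


def bard1_domains(level: str = "exon") -> DomainMap:
    """Packaged BARD1 RING/ARD/BRCT domain map ('exon' or 'codon' level)."""
    name = "bard1_domains_exon.tsv" if level == "exon" else "bard1_domains_codon.tsv"
    with resources.as_file(_data(name)) as p:
        return load_domain_map(p)
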
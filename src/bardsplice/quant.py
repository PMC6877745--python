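"""Quantify splicing events from junction read-count tables.

An event's level is expressed relative to the natural junctions its
alternative junction overlaps: with ``a`` the reads supporting the
event's novel junction(s) and ``n̄`` the mean reads over overlapping
natural junctions,

* ``ratio``   percentage = 100 · a / n̄        (default; reads as
  "percentage of overlapping natural junctions"),
* ``bounded`` percentage = 100 · a / (a + n̄)  (a proportion, always in
  [0, 100]).

"Overlapping" natural junctions are those whose c. interval intersects
the closed interval spanned by the event's novel junction.  Compound
(multi-junction) events aggregate support conservatively as the minimum
of their junction read counts, flagged in the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd

from .errors import InputError
from .events import SpliceEvent, junctions_of_event
from .positions import CPos, as_cpos
from .transcript import TranscriptModel

CONDITIONS = ("untreated", "NMD_inhibited")

JUNCTION_COLUMNS = ["sample", "condition", "donor", "acceptor", "reads"]


@dataclass(frozen=True)
class JunctionCount:
    """Reads observed on one exon-exon (or cryptic) junction in one sample."""

    sample_id: str
    condition: str
    donor: CPos
    acceptor: CPos
    reads: int
    natural: bool

    @property
    def key(self) -> tuple[str, str]:
        return (str(self.donor), str(self.acceptor))


@dataclass
class EventQuantification:
    """Per-sample and pooled percentages for one event."""

    event_code: str
    formula: str
    per_sample: dict                  # sample_id -> percentage (or nan)
    pooled: float
    supporting_reads: int
    natural_junctions: tuple[tuple[str, str], ...]
    flags: tuple[str, ...] = ()


def load_junction_table(
    source,
    model: TranscriptModel,
    column_map: Mapping[str, str] | None = None,
    allow_cryptic: bool = True,
) -> list[JunctionCount]:
    """Read a junction read-count TSV into JunctionCount records.

    Expected columns: ``sample condition donor acceptor reads``; a
    ``column_map`` (ours -> theirs) adapts reduced aligner splice-junction
    dialects.  Donor/acceptor accept intronic offsets ("1395+3").
    Junction rows at non-boundary positions are rejected unless
    ``allow_cryptic``.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    if column_map:
        df = df.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"junction table missing columns {missing}")
    boundary_donors = {d for d, _ in model.natural_junctions()}
    boundary_acceptors = {a for _, a in model.natural_junctions()}
    out: list[JunctionCount] = []
    for i, row in enumerate(df.itertuples(), start=2):  # 1-based incl. header
        try:
            reads = int(row.reads)
        except ValueError:
            raise InputError(f"row {i}: reads {row.reads!r} is not an integer")
        if reads < 0:
            raise InputError(f"row {i}: negative read count {reads}")
        donor, acceptor = as_cpos(row.donor), as_cpos(row.acceptor)
        if donor.axis() >= acceptor.axis():
            raise InputError(f"row {i}: donor {donor} not upstream of acceptor {acceptor}")
        natural = (donor.exonic and acceptor.exonic
                   and model.is_natural_junction(donor.base, acceptor.base))
        # c. numbering is contiguous across junctions, so *natural* junctions
        # are adjacent position pairs; any other adjacent pair is mid-exon
        # adjacency, not a junction.
        if (not natural and donor.exonic and acceptor.exonic
                and acceptor.base == donor.base + 1):
            raise InputError(f"row {i}: adjacent positions {donor}_{acceptor} are not a junction")
        if not natural and not allow_cryptic:
            exonic_boundary = (donor.exonic and donor.base in boundary_donors
                               and acceptor.exonic and acceptor.base in boundary_acceptors)
            if not exonic_boundary:
                raise InputError(f"row {i}: junction {donor}_{acceptor} not at model boundaries")
        cond = str(row.condition)
        out.append(JunctionCount(str(row.sample), cond, donor, acceptor, reads, natural))
    return out


def _overlapping_naturals(event: SpliceEvent, model: TranscriptModel):
    """Natural junctions whose span intersects any of the event's novel junctions."""
    novel = junctions_of_event(event, model)
    naturals = []
    for d, a in model.natural_junctions():
        lo, hi = float(d), float(a)
        for nd, na in novel:
            if not (hi < nd.axis() or lo > na.axis()):
                naturals.append((str(d), str(a)))
                break
    return novel, naturals


def _percent(a: float, n_mean: float, formula: str) -> float:
    if formula == "ratio":
        return 100.0 * a / n_mean if n_mean > 0 else math.inf if a > 0 else 0.0
    if formula == "bounded":
        return 100.0 * a / (a + n_mean) if (a + n_mean) > 0 else 0.0
    raise InputError(f"unknown formula {formula!r} (use 'ratio' or 'bounded')")


def percent_of_natural(
    event: SpliceEvent,
    counts: Sequence[JunctionCount],
    model: TranscriptModel,
    formula: Literal["ratio", "bounded"] = "ratio",
    condition: str | None = None,
) -> EventQuantification:
    """Quantify one event as a percentage of its overlapping natural junctions.

    Per-sample percentages use each sample's own counts; the pooled
    percentage uses counts summed over samples (so pooling samples first
    and quantifying gives the same number).
    """
    if condition is not None:
        counts = [c for c in counts if c.condition == condition]
    novel, naturals = _overlapping_naturals(event, model)
    novel_keys = {(str(d), str(a)) for d, a in novel}
    nat_keys = set(naturals)
    flags = []
    if len(novel_keys) > 1:
        flags.append("multi_junction_min_support")

    def tally(rows):
        per_novel = {k: 0 for k in novel_keys}
        per_nat = {k: 0 for k in nat_keys}
        for c in rows:
            if c.key in per_novel:
                per_novel[c.key] += c.reads
            if c.key in per_nat:
                per_nat[c.key] += c.reads
        a = min(per_novel.values()) if per_novel else 0
        n_mean = (sum(per_nat.values()) / len(per_nat)) if per_nat else 0.0
        return a, n_mean

    samples = sorted({c.sample_id for c in counts})
    per_sample = {}
    for s in samples:
        a_s, n_s = tally([c for c in counts if c.sample_id == s])
        per_sample[s] = _percent(a_s, n_s, formula)
    a, n_mean = tally(counts)
    if a == 0:
        flags.append("zero_support")
    if n_mean == 0 and a > 0:
        flags.append("undefined_high")
    return EventQuantification(
        event_code=event.code, formula=formula, per_sample=per_sample,
        pooled=_percent(a, n_mean, formula), supporting_reads=a,
        natural_junctions=tuple(sorted(nat_keys)), flags=tuple(flags),
    )


def compare_conditions(
    quant_untreated: Iterable[EventQuantification],
    quant_inhibited: Iterable[EventQuantification],
) -> pd.DataFrame:
    """Pair per-event percentages across the NMD-inhibition contrast.

    Returns a table with columns event, percent_untreated,
    percent_inhibited, ratio, flags; events absent from one side get 0
    with a flag.  No hypothesis test is attached.
    """
    qa = {q.event_code: q for q in quant_untreated}
    qb = {q.event_code: q for q in quant_inhibited}
    rows = []
    for code in sorted(set(qa) | set(qb)):
        pa = qa[code].pooled if code in qa else 0.0
        pb = qb[code].pooled if code in qb else 0.0
        flags = []
        if code not in qa:
            flags.append("absent_untreated")
        if code not in qb:
            flags.append("absent_inhibited")
        if pa > 0:
            ratio = pb / pa
        else:
            ratio = math.nan
            if pb == 0:
                flags.append("undetected_both")
        rows.append({"event": code, "percent_untreated": pa,
                     "percent_inhibited": pb, "ratio": ratio,
                     "flags": ";".join(flags)})
    return pd.DataFrame(rows, columns=["event", "percent_untreated",
                                       "percent_inhibited", "ratio", "flags"])


def filter_detected(
    counts: Sequence[JunctionCount],
    min_samples: int = 3,
    min_mean_reads: float = 4.0,
) -> list[tuple[str, str]]:
    """Junctions passing the targeted-sequencing detection rule:
    found in at least ``min_samples`` samples with mean reads per sample
    strictly greater than ``min_mean_reads``."""
    by_junc: dict[tuple[str, str], dict[str, int]] = {}
    for c in counts:
        if c.reads > 0:
            by_junc.setdefault(c.key, {}).setdefault(c.sample_id, 0)
            by_junc[c.key][c.sample_id] += c.reads
    out = []
    for key, per_sample in sorted(by_junc.items()):
        n = len(per_sample)
        mean = sum(per_sample.values()) / n
        if n >= min_samples and mean > min_mean_reads:
            out.append(key)
    return out


def quantification_table(quants: Iterable[EventQuantification]) -> pd.DataFrame:
    """Flatten quantifications to the output TSV layout
    (event, sample, a_reads, n_mean, percent, flags; 'pooled' row per event)."""
    rows = []
    for q in quants:
        for s, pct in q.per_sample.items():
            rows.append({"event": q.event_code, "sample": s, "percent": pct,
                         "flags": ";".join(q.flags)})
        rows.append({"event": q.event_code, "sample": "pooled", "percent": q.pooled,
                     "flags": ";".join(q.flags)})
    return pd.DataFrame(rows, columns=["event", "sample", "percent", "flags"])
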
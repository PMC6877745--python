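"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators make every pipeline stage testable without external
data:

* junction read-count tables — multinomial reads over the natural
  junctions and the novel junctions of configured events, with an
  NMD-inhibition contrast that scales NMD-targeted events (targeting is
  taken from the package's own NMD prediction, so the simulator is a
  closed-loop test of that logic);
* long-read junction chains — full-length isoforms combining up to a
  configurable number of non-contiguous events, with an exact
  chain → event-set decomposition for round-trip checks;
* transcript FASTA — random coding sequence, stop-free in the reference
  frame except where planned, with optional planted stops and stop-free
  windows in shifted frames for frameshift/PTC tests.

Reads are allocated at the junction level; there is no base-level error
model, matching what the quantification stage consumes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EventParseError
from .events import (
    Deletion, Insertion, SpliceEvent, junctions_of_event, merge_del_codes,
    nmd_prediction, parse_event_code, resolve_primitives,
)
from .positions import CPos
from .quant import _overlapping_naturals, _percent
from .transcript import TranscriptModel

STOPS = ("TAA", "TAG", "TGA")
BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators."""

    model: TranscriptModel
    event_profile: Mapping[str, float]        # event code -> transcript fraction
    total_junction_reads: int = 50_000
    n_samples: int = 1
    nmd_inhibition_factor: float = 1.0        # applied to NMD-targeted events
    assay_dropout: float = 0.0                # P(an expressed event is missed in a sample)
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.nmd_inhibition_factor < 1:
            raise ConfigError("nmd_inhibition_factor must be >= 1")
        for code, f in self.event_profile.items():
            if f < 0:
                raise ConfigError(f"negative abundance for {code}")
        self._events = {c: parse_event_code(c) for c in self.event_profile}
        self._nmd_targeted = {
            c for c, ev in self._events.items()
            if nmd_prediction(ev, self.model).nmd == "NMD_predicted"
        }
        for cond in ("untreated", "NMD_inhibited"):
            tot = sum(self.abundance(c, cond) for c in self.event_profile)
            if tot > 1:
                raise ConfigError(
                    f"event abundances sum to {tot:.3f} > 1 under {cond}")

    def abundance(self, code: str, condition: str) -> float:
        f = self.event_profile[code]
        if condition == "NMD_inhibited" and code in self._nmd_targeted:
            f *= self.nmd_inhibition_factor
        return f

    def event(self, code: str) -> SpliceEvent:
        return self._events[code]


# ---------------------------------------------------------------------------
# junction count tables
# ---------------------------------------------------------------------------


def _junction_weights(cfg: SimulationConfig, condition: str,
                      active: Iterable[str] | None = None) -> dict[tuple[str, str], float]:
    """Expected read fraction per junction under the transcript mixture.

    Each transcript carries at most one event; an event removes the
    natural junctions its novel junction overlaps and contributes reads
    to its own junction(s).
    """
    codes = list(cfg.event_profile) if active is None else list(active)
    weights: dict[tuple[str, str], float] = {}
    removal: dict[tuple[str, str], float] = {}
    for code in codes:
        f = cfg.abundance(code, condition)
        ev = cfg.event(code)
        novel, naturals = _overlapping_naturals(ev, cfg.model)
        for d, a in novel:
            weights[(str(d), str(a))] = weights.get((str(d), str(a)), 0.0) + f
        for key in naturals:
            removal[key] = removal.get(key, 0.0) + f
    for d, a in cfg.model.natural_junctions():
        key = (str(d), str(a))
        weights[key] = max(0.0, 1.0 - removal.get(key, 0.0))
    return weights


def simulate_junction_counts(cfg: SimulationConfig) -> pd.DataFrame:
    """Draw junction read counts per sample and condition.

    Returns the junction-table dialect consumed by the quantification
    stage (columns sample, condition, donor, acceptor, reads); total
    reads per sample/condition equal ``cfg.total_junction_reads``.
    Bit-reproducible for a fixed config.
    """
    rows = []
    for si in range(cfg.n_samples):
        sample = f"s{si + 1}"
        for ci, cond in enumerate(("untreated", "NMD_inhibited")):
            rng = np.random.default_rng((cfg.seed, si, ci))
            active = [
                c for c in cfg.event_profile
                if cfg.assay_dropout == 0 or rng.random() >= cfg.assay_dropout
            ]
            weights = _junction_weights(cfg, cond, active)
            keys = sorted(weights)
            w = np.array([weights[k] for k in keys], dtype=float)
            p = w / w.sum()
            reads = rng.multinomial(cfg.total_junction_reads, p)
            for (donor, acceptor), n in zip(keys, reads):
                if n > 0:
                    rows.append({"sample": sample, "condition": cond,
                                 "donor": donor, "acceptor": acceptor, "reads": int(n)})
    return pd.DataFrame(rows, columns=["sample", "condition", "donor", "acceptor", "reads"])


def expected_percent(cfg: SimulationConfig, code: str, formula: str = "ratio",
                     condition: str = "untreated") -> float:
    """Analytic ground-truth percentage implied by the configured abundances."""
    weights = _junction_weights(cfg, condition)
    ev = cfg.event(code)
    novel, naturals = _overlapping_naturals(ev, cfg.model)
    a = min(weights.get((str(d), str(a)), 0.0) for d, a in novel)
    n_mean = (sum(weights[k] for k in naturals) / len(naturals)) if naturals else 0.0
    return _percent(a, n_mean, formula)


# ---------------------------------------------------------------------------
# long-read junction chains
# ---------------------------------------------------------------------------


def _altered_span(ev: SpliceEvent, model: TranscriptModel) -> tuple[int, int]:
    prims = resolve_primitives(ev, model)
    lo = min(p.start if isinstance(p, Deletion) else p.anchor for p in prims)
    hi = max(p.end if isinstance(p, Deletion) else p.anchor + 1 for p in prims)
    return lo, hi


def _compatible(ev_a: SpliceEvent, ev_b: SpliceEvent, model: TranscriptModel) -> bool:
    """Events can co-occur on one transcript only when their altered
    regions are separated by at least one intact exon (non-contiguous)."""
    lo_a, hi_a = _altered_span(ev_a, model)
    lo_b, hi_b = _altered_span(ev_b, model)
    if not (hi_a < lo_b or hi_b < lo_a):
        return False
    lo, hi = (hi_a, lo_b) if hi_a < lo_b else (hi_b, lo_a)
    between = [ex.index for ex in model.exons if lo < ex.start and ex.end < hi]
    return len(between) >= 1


def chain_of_events(codes: Sequence[str], model: TranscriptModel) -> list[tuple[str, str]]:
    """Ordered junction list of the transcript carrying ``codes`` jointly."""
    removed: set[tuple[str, str]] = set()
    novel: list[tuple[CPos, CPos]] = []
    for code in codes:
        ev = parse_event_code(code)
        nov, nats = _overlapping_naturals(ev, model)
        novel.extend(nov)
        removed |= set(nats)
    chain = [(CPos(d), CPos(a)) for d, a in model.natural_junctions()
             if (str(d), str(a)) not in removed]
    chain.extend(novel)
    chain.sort(key=lambda j: j[0].axis())
    return [(str(d), str(a)) for d, a in chain]


def decompose_chain(chain: Sequence[tuple[str, str]], model: TranscriptModel) -> str:
    """Collapse a junction chain back to its isoform code.

    Novel exonic junctions become Δ terms (full skips, p/q shifts or
    interstitial deletions); junctions with intronic positions become
    retention (▼) or pseudoexon (IVS) events.  All Δ terms merge into
    one compound code; other events are joined with '+'.  The reference
    chain returns 'Full length'.
    """
    natural = {(str(d), str(a)) for d, a in model.natural_junctions()}
    del_codes: list[str] = []
    other: list[str] = []
    pending_pseudo: Optional[tuple[CPos, CPos]] = None
    for d_s, a_s in chain:
        if (d_s, a_s) in natural:
            continue
        d, a = CPos.parse(d_s), CPos.parse(a_s)
        if pending_pseudo is not None:
            open_d, seg_start = pending_pseudo
            pending_pseudo = None
            seg_end = d
            intron = model.exon_of_position(open_d.base).index
            if seg_start.offset > 0:
                other.append(f"IVS{intron}+{seg_start.offset}▼{seg_end.offset - seg_start.offset + 1}")
            else:
                other.append(f"IVS{intron}-{-seg_start.offset}▼{seg_end.offset - seg_start.offset + 1}")
            continue
        if d.exonic and a.exonic:
            del_codes.append(_deletion_code(d.base + 1, a.base - 1, model))
        elif d.exonic and not a.exonic:
            if a.offset < -1:
                intron = model.exon_of_position(d.base).index
                other.append(f"▼(I{intron}p{-a.offset})")
            elif a.offset == -1:
                other.append(f"▼(I{model.exon_of_position(d.base).index}p1)")
            else:  # opening junction of a donor-anchored pseudoexon
                pending_pseudo = (d, a)
        elif not d.exonic and a.exonic:
            if d.offset >= 1:
                intron = model.exon_of_position(d.base).index
                other.append(f"▼(I{intron}q{d.offset})")
            else:
                raise EventParseError(f"cannot interpret junction {d_s}_{a_s}")
        else:
            raise EventParseError(f"cannot interpret junction {d_s}_{a_s}")
    codes = ([merge_del_codes(del_codes)] if del_codes else []) + sorted(other)
    if not codes:
        return "Full length"
    return "+".join(codes)


def _deletion_code(s: int, e: int, model: TranscriptModel) -> str:
    s_ex, e_ex = model.exon_of_position(s), model.exon_of_position(e)
    if s == s_ex.start and e == e_ex.end:
        if s_ex.index == e_ex.index:
            return f"Δ(E{s_ex.index})"
        return f"Δ(E{s_ex.index}_E{e_ex.index})"
    if s_ex.index == e_ex.index:
        if s == s_ex.start:
            return f"Δ(E{s_ex.index}p{e - s + 1})"
        if e == s_ex.end:
            return f"Δ(E{s_ex.index}q{e - s + 1})"
        return f"Δ(E{s_ex.index}int{e - s + 1})"
    left = f"E{s_ex.index}" if s == s_ex.start else f"E{s_ex.index}q{s_ex.end - s + 1}"
    right = f"E{e_ex.index}" if e == e_ex.end else f"E{e_ex.index}p{e - e_ex.start + 1}"
    return f"Δ({left}_{right})"


def simulate_long_read_chains(
    cfg: SimulationConfig, max_events_per_isoform: int = 2, n_reads: int | None = None
) -> pd.DataFrame:
    """Draw full-length reads as junction chains with their isoform codes.

    Events enter a read independently with their configured abundance,
    subject to pairwise compatibility (non-contiguous altered regions)
    and the per-isoform cap; full-length transcripts make up the rest.
    """
    if max_events_per_isoform < 0:
        raise ConfigError("max_events_per_isoform must be >= 0")
    n = cfg.total_junction_reads if n_reads is None else n_reads
    rng = np.random.default_rng((cfg.seed, 97))
    codes = sorted(cfg.event_profile)
    events = {c: cfg.event(c) for c in codes}
    rows = []
    for i in range(n):
        chosen: list[str] = []
        for c in codes:
            if len(chosen) >= max_events_per_isoform:
                break
            if rng.random() < cfg.event_profile[c]:
                if all(_compatible(events[c], events[o], cfg.model) for o in chosen):
                    chosen.append(c)
        chain = chain_of_events(chosen, cfg.model)
        iso = decompose_chain(chain, cfg.model)
        rows.append({"read_id": f"r{i + 1}",
                     "junction_list": ";".join(f"{d}>{a}" for d, a in chain),
                     "isoform_code": iso})
    return pd.DataFrame(rows, columns=["read_id", "junction_list", "isoform_code"])


# ---------------------------------------------------------------------------
# transcript FASTA
# ---------------------------------------------------------------------------


def simulate_transcript_fasta(
    model: TranscriptModel,
    stop_plan: Sequence[tuple[int, bool]] = (),
    seed: int = 0,
    planted_shift_stops: Sequence[int] = (),
    stop_free_windows: Sequence[tuple[int, int, int]] = (),
    planted_bases: Mapping[int, str] | None = None,
    name: str = "synthetic_transcript",
) -> str:
    """Generate a synthetic CDS (FASTA text) of length ``cds_end``.

    The reference frame is stop-free except at codons planned via
    ``stop_plan`` (list of (codon index, make-stop flag)) and the
    mandatory final stop codon.  ``planted_shift_stops`` places a TAA at
    arbitrary c. positions (for frameshift tests) and
    ``stop_free_windows`` — (start_c, end_c, phase) with phase = start_c
    mod 3 of the constrained triplet frame — keeps a shifted frame free
    of stops inside a window; ``planted_bases`` pins individual
    positions.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    L = model.cds_end
    n_codons = model.protein_length + 1
    seq = np.empty(L, dtype="<U1")
    seq[:] = ""

    planted: set[int] = set()

    def plant(pos: int, triplet: str):
        if pos < 1 or pos + 2 > L:
            raise ConfigError(f"planted stop at c.{pos} outside the CDS")
        for k, b in enumerate(triplet):
            seq[pos - 1 + k] = b
            planted.add(pos + k)

    for codon, make in stop_plan:
        if not make:
            continue
        if codon <= 1:
            raise ConfigError("cannot plant a stop at the initiator codon")
        if codon > n_codons:
            raise ConfigError(f"codon {codon} beyond the CDS ({n_codons} codons)")
        plant(3 * codon - 2, STOPS[rng.integers(len(STOPS))])
    for pos in planted_shift_stops:
        plant(pos, "TAA")
    for pos, base in (planted_bases or {}).items():
        plant(pos, base)
    plant(3 * n_codons - 2, STOPS[rng.integers(len(STOPS))])  # mandatory final stop
    seq[0:3] = list("ATG")
    planted.update((1, 2, 3))

    ref_stop_free = (1, 3 * n_codons - 3, 1)  # sense codons, phase 1 (1, 4, 7, ...)
    windows = [ref_stop_free] + [tuple(w) for w in stop_free_windows]

    def constrained_phase(p: int) -> bool:
        """Is the triplet [p-2, p] protected against forming a stop?"""
        start = p - 2
        for a, b, phase in windows:
            if a <= start and p <= b + 2 and start % 3 == phase % 3:
                if not ({start, start + 1, start + 2} & planted):
                    return True
        return False

    for p in range(1, L + 1):
        if seq[p - 1]:
            continue
        allowed = list("ACGT")
        if p >= 3 and constrained_phase(p):
            prefix = seq[p - 3] + seq[p - 2]
            allowed = [b for b in allowed if (prefix + b) not in STOPS]
        seq[p - 1] = allowed[rng.integers(len(allowed))]

    s = "".join(seq)
    body = "\n".join(s[i:i + 60] for i in range(0, len(s), 60))
    return f">{name} synthetic CDS length={L}\n{body}\n"
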
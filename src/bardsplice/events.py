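"""Alternative-splicing events: parsing, HGVS r. descriptions, annotation.

Events are written in a compact coding scheme: ``Δ`` marks skipping of
reference exonic sequence and ``▼`` inclusion of reference intronic
sequence; ``E``/``I`` name exons and introns; ``p`` and ``q`` mark
acceptor- and donor-side partial shifts; ``int`` an interstitial deletion
inside an exon; ``IVSk±off▼len`` a pseudoexon of ``len`` nucleotides
inside intron ``k``.  Compound events join non-contiguous deletions with
a comma, e.g. ``Δ(E2_E4,E8)``.

ASCII aliases are accepted on input for shell safety: a leading ``d`` for
``Δ`` and ``v`` for ``▼`` (``dE4q408``, ``v(I5q3)``, ``IVS9+5946v1015``),
and ``-`` may stand for ``_`` in exon ranges.  Canonical output always
uses the Unicode symbols.

Each event resolves, against a transcript model, to a set of primitives —
contiguous deletions of exonic c. intervals and insertions of intronic
segments — from which the HGVS r. description, net length change,
reading frame, NMD prediction, affected domains and novel junctions are
derived.  Events whose breakpoints are unknown (``?``) parse and format
but refuse coordinate-level annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from .errors import EventParseError, InputError, ModelError, UnresolvableEventError
from .positions import CPos, as_cpos
from .transcript import DomainMap, TranscriptModel

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: Distance from the final exon-exon junction within which a premature
#: termination codon is assumed to escape nonsense-mediated decay.
NMD_WINDOW_NT = 50


# ---------------------------------------------------------------------------
# term structures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DelTerm:
    """One contiguous deletion term of a Δ code."""

    start_exon: int
    end_exon: int
    start_kind: str = "full"      # 'full' | 'q' (donor-side shift on start exon)
    start_n: Optional[int] = None  # nt count for the q shift; None = unnumbered
    end_kind: str = "full"        # 'full' | 'p' (acceptor-side shift on end exon)
    end_n: Optional[int] = None
    int_n: Optional[int] = None    # interstitial deletion length (single exon)

    def format(self) -> str:
        if self.start_exon == self.end_exon:
            k = self.start_exon
            if self.int_n is not None:
                return f"E{k}int{self.int_n}"
            if self.start_kind == "q":
                return f"E{k}q{self.start_n if self.start_n is not None else ''}"
            if self.end_kind == "p":
                return f"E{k}p{self.end_n if self.end_n is not None else ''}"
            return f"E{k}"
        left = f"E{self.start_exon}"
        if self.start_kind == "q":
            left += "q" + (str(self.start_n) if self.start_n is not None else "")
        right = f"E{self.end_exon}"
        if self.end_kind == "p":
            right += "p" + (str(self.end_n) if self.end_n is not None else "")
        return f"{left}_{right}"


@dataclass(frozen=True)
class RetTerm:
    """Retention of intronic sequence adjacent to a junction (▼)."""

    intron: int
    side: Optional[str] = None     # 'q' donor side | 'p' acceptor side | None = full intron
    n: Optional[int] = None

    def format(self) -> str:
        if self.side is None:
            return f"I{self.intron}"
        return f"I{self.intron}{self.side}{self.n if self.n is not None else ''}"


@dataclass(frozen=True)
class PseudoTerm:
    """Inclusion of a pseudoexon inside an intron (IVSk±off▼len)."""

    intron: int
    sign: int      # +1: offset from the upstream donor; -1: from the downstream acceptor
    offset: int
    length: int

    def format(self) -> str:
        s = "+" if self.sign > 0 else "-"
        return f"IVS{self.intron}{s}{self.offset}▼{self.length}"


Term = Union[DelTerm, RetTerm, PseudoTerm]


# ---------------------------------------------------------------------------
# primitives (model-resolved)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Deletion:
    start: int  # first deleted c. position
    end: int    # last deleted c. position

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Insertion:
    anchor: int          # c. position after which the segment is inserted
    seg_start: CPos
    seg_end: CPos
    length: int


Primitive = Union[Deletion, Insertion]


# ---------------------------------------------------------------------------
# the event itself
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpliceEvent:
    """A parsed alternative-splicing event."""

    kind: str                      # 'del' | 'ret' | 'pseudo' | 'ref'
    terms: tuple[Term, ...]
    r_verbatim: Optional[str] = None   # printed r. description, kept for re-emission

    @property
    def code(self) -> str:
        if self.kind == "ref":
            return "Full length"
        if self.kind == "del":
            return "Δ(" + ",".join(t.format() for t in self.terms) + ")"
        if self.kind == "ret":
            return "▼(" + self.terms[0].format() + ")"
        return self.terms[0].format()

    @property
    def is_compound(self) -> bool:
        return len(self.terms) > 1

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code


REFERENCE_CODES = {"full length", "reference", "-", "fl"}


# ---------------------------------------------------------------------------
# code parsing
# ---------------------------------------------------------------------------

_PART_RE = re.compile(r"^E(\d+)(?:(int|p|q)(\d*))?$")
_RET_RE = re.compile(r"^I(\d+)(?:([pq])(\d*))?$")
_PSEUDO_RE = re.compile(r"^IVS(\d+)([+-])(\d+)[▼v](\d+)$")


def _parse_del_term(text: str) -> DelTerm:
    parts = text.split("_")
    if not 1 <= len(parts) <= 2:
        raise EventParseError(f"bad deletion term {text!r}")
    left = _PART_RE.match(parts[0])
    if not left:
        raise EventParseError(f"bad exon token {parts[0]!r} in {text!r}")
    l_ex, l_mod, l_n = int(left.group(1)), left.group(2), left.group(3)
    if len(parts) == 1:
        if l_mod == "int":
            if not l_n:
                raise EventParseError(f"interstitial term {text!r} needs a length")
            return DelTerm(l_ex, l_ex, int_n=int(l_n))
        if l_mod == "q":
            return DelTerm(l_ex, l_ex, start_kind="q", start_n=int(l_n) if l_n else None)
        if l_mod == "p":
            return DelTerm(l_ex, l_ex, end_kind="p", end_n=int(l_n) if l_n else None)
        return DelTerm(l_ex, l_ex)
    right = _PART_RE.match(parts[1])
    if not right:
        raise EventParseError(f"bad exon token {parts[1]!r} in {text!r}")
    r_ex, r_mod, r_n = int(right.group(1)), right.group(2), right.group(3)
    if l_mod == "p" or r_mod == "q" or l_mod == "int" or r_mod == "int":
        raise EventParseError(f"misplaced p/q/int modifier in range term {text!r}")
    if r_ex <= l_ex:
        raise EventParseError(f"exon range not increasing in {text!r}")
    return DelTerm(
        l_ex, r_ex,
        start_kind="q" if l_mod == "q" else "full",
        start_n=int(l_n) if (l_mod == "q" and l_n) else None,
        end_kind="p" if r_mod == "p" else "full",
        end_n=int(r_n) if (r_mod == "p" and r_n) else None,
    )


def parse_event_code(code: str, r_description: str | None = None) -> SpliceEvent:
    """Parse an event code (optionally with its r. description as a hint).

    The r. description, when given, supplies breakpoints that the code
    leaves unnumbered (e.g. ``Δ(E2q)`` with ``r.212_215del``) and is kept
    verbatim for re-emission by :func:`to_hgvs_r`.
    """
    raw = code.strip()
    if raw.lower() in REFERENCE_CODES:
        return SpliceEvent(kind="ref", terms=())
    text = raw.replace(" ", "")
    verbatim = r_description.strip() if r_description else None

    if text.startswith("IVS"):
        m = _PSEUDO_RE.match(text)
        if not m:
            raise EventParseError(f"bad pseudoexon code {raw!r}")
        term = PseudoTerm(int(m.group(1)), 1 if m.group(2) == "+" else -1,
                          int(m.group(3)), int(m.group(4)))
        return SpliceEvent(kind="pseudo", terms=(term,), r_verbatim=verbatim)

    sym, body = text[0], text[1:]
    if body.startswith("(") :
        if not body.endswith(")"):
            raise EventParseError(f"unbalanced parentheses in {raw!r}", position=len(text) - 1)
        body = body[1:-1]
    if sym in ("Δ", "d", "D"):
        # hyphen alias for exon ranges: Δ(E2,E4-E9)
        body = re.sub(r"-(?=E\d)", "_", body)
        terms = tuple(_parse_del_term(t) for t in body.split(",") if t)
        if not terms:
            raise EventParseError(f"empty deletion code {raw!r}")
        return SpliceEvent(kind="del", terms=terms, r_verbatim=verbatim)
    if sym in ("▼", "v", "V"):
        m = _RET_RE.match(body)
        if not m:
            raise EventParseError(f"bad retention code {raw!r}")
        n = int(m.group(3)) if m.group(3) else None
        term = RetTerm(int(m.group(1)), m.group(2), n)
        return SpliceEvent(kind="ret", terms=(term,), r_verbatim=verbatim)
    raise EventParseError(f"unrecognised event code {raw!r}", position=0)


# ---------------------------------------------------------------------------
# r. description parsing
# ---------------------------------------------------------------------------

_R_INS_RE = re.compile(r"^(\S+?)_(\S+?)ins(\S+?)_(\S+)$")


def _parse_r_segments(text: str):
    """Parse an r. deletion/insertion description into coordinate pairs.

    Returns ``('del', [(start, end), ...])`` (entries are CPos or None for
    '?') or ``('ins', (anchor_left, anchor_right, seg_start, seg_end))``.
    """
    t = text.strip().replace("−", "-")
    if not t.startswith("r."):
        raise EventParseError(f"r. description must start with 'r.': {text!r}")
    body = t[2:]
    m = _R_INS_RE.match(body)
    if m:
        vals = [None if "?" in g else CPos.parse(g) for g in m.groups()]
        return "ins", tuple(vals)
    if body.endswith("del"):
        body = body[:-3]
    pairs = []
    for seg in body.split("+"):
        ends = seg.split("_")
        if len(ends) != 2:
            raise EventParseError(f"bad r. segment {seg!r} in {text!r}")
        pairs.append(tuple(None if "?" in e else CPos.parse(e) for e in ends))
    return "del", pairs


# ---------------------------------------------------------------------------
# resolution to primitives
# ---------------------------------------------------------------------------


def resolve_primitives(event: SpliceEvent, model: TranscriptModel) -> list[Primitive]:
    """Resolve an event to coordinate-level primitives.

    Raises :class:`UnresolvableEventError` for events with '?' or
    unnumbered breakpoints that the r. description does not pin down.
    """
    if event.kind == "ref":
        return []
    r_kind = r_pairs = None
    if event.r_verbatim:
        if "?" in event.r_verbatim:
            raise UnresolvableEventError(f"{event.code}: breakpoints unknown ('?')")
        r_kind, r_pairs = _parse_r_segments(event.r_verbatim)

    if event.kind == "del":
        hints: Sequence = r_pairs if (r_kind == "del" and r_pairs and
                                      len(r_pairs) == len(event.terms)) else [None] * len(event.terms)
        prims: list[Primitive] = []
        for term, hint in zip(event.terms, hints):
            prims.append(_resolve_del_term(event, term, model, hint))
        return prims

    term = event.terms[0]
    if isinstance(term, RetTerm):
        if term.side is None:
            raise UnresolvableEventError(f"{event.code}: full intron retention has no defined length")
        don = model.exon(term.intron)
        acc = model.exon(term.intron + 1)
        if term.n is None:
            raise UnresolvableEventError(f"{event.code}: retention length unknown")
        if term.side == "q":
            seg = (CPos(don.end, +1), CPos(don.end, +term.n))
        else:
            seg = (CPos(acc.start, -term.n), CPos(acc.start, -1))
        return [Insertion(anchor=don.end, seg_start=seg[0], seg_end=seg[1], length=term.n)]

    assert isinstance(term, PseudoTerm)
    don = model.exon(term.intron)
    acc = model.exon(term.intron + 1)
    if term.sign > 0:
        seg = (CPos(don.end, term.offset), CPos(don.end, term.offset + term.length - 1))
    else:
        seg = (CPos(acc.start, -term.offset), CPos(acc.start, -(term.offset - term.length + 1)))
    return [Insertion(anchor=don.end, seg_start=seg[0], seg_end=seg[1], length=term.length)]


def _resolve_del_term(event, term: DelTerm, model, hint) -> Deletion:
    s_ex, e_ex = model.exon(term.start_exon), model.exon(term.end_exon)
    start = end = None
    if term.int_n is not None:
        if hint and all(hint):
            start, end = hint[0].base, hint[1].base
            if end - start + 1 != term.int_n:
                raise EventParseError(
                    f"{event.code}: r. segment {start}_{end} inconsistent with int{term.int_n}")
        else:
            raise UnresolvableEventError(
                f"{event.code}: interstitial deletion position needs an r. description")
    else:
        if term.start_kind == "q":
            if term.start_n is not None:
                start = s_ex.end - term.start_n + 1
            elif hint and hint[0]:
                start = hint[0].base
        else:
            start = s_ex.start
        if term.end_kind == "p":
            if term.end_n is not None:
                end = e_ex.start + term.end_n - 1
            elif hint and hint[1]:
                end = hint[1].base
        else:
            end = e_ex.end
    if start is None or end is None:
        raise UnresolvableEventError(f"{event.code}: term {term.format()} has unnumbered breakpoints")
    if hint and all(hint) and (hint[0].base, hint[1].base) != (start, end):
        raise EventParseError(
            f"{event.code}: r. segment {hint[0]}_{hint[1]} conflicts with code-derived "
            f"{start}_{end}")
    if not (s_ex.start <= start <= s_ex.end and e_ex.start <= end <= e_ex.end):
        raise ModelError(f"{event.code}: deletion {start}_{end} outside exons "
                         f"{term.start_exon}..{term.end_exon}")
    return Deletion(start, end)


# ---------------------------------------------------------------------------
# derived annotation
# ---------------------------------------------------------------------------


def _term_delta(event: SpliceEvent, term: Term, model: TranscriptModel) -> Optional[int]:
    """Signed net length change of one term, or None if unknowable."""
    if isinstance(term, PseudoTerm):
        return term.length
    if isinstance(term, RetTerm):
        return term.n if term.n is not None else None
    if term.int_n is not None:
        return -term.int_n
    try:
        prim = _resolve_del_term(event, term, model, _hint_for(event, term, model))
        return -prim.length
    except UnresolvableEventError:
        return None


def _hint_for(event, term, model):
    if not event.r_verbatim or "?" in event.r_verbatim:
        return None
    kind, pairs = _parse_r_segments(event.r_verbatim)
    if kind != "del" or len(pairs) != len(event.terms):
        return None
    return pairs[list(event.terms).index(term)]


def net_length_change(event: SpliceEvent, model: TranscriptModel) -> int:
    """Signed change in transcript length (inserted minus deleted nt)."""
    if event.kind == "ref":
        return 0
    total = 0
    for term in event.terms:
        d = _term_delta(event, term, model)
        if d is None:
            raise UnresolvableEventError(
                f"{event.code}: net length change unknown; mark frame as 'unknown'")
        total += d
    return total


def frame_annotation(event: SpliceEvent, model: TranscriptModel) -> str:
    """'IF' if the net length change is a codon multiple, 'FS' otherwise,
    'unknown' for events with unresolvable breakpoints."""
    try:
        return "IF" if net_length_change(event, model) % 3 == 0 else "FS"
    except UnresolvableEventError:
        return "unknown"


def to_hgvs_r(event: SpliceEvent, model: TranscriptModel, prefer_verbatim: bool = True) -> str:
    """HGVS-style r. description of the event.

    Catalogue-loaded events re-emit their stored (printed) description
    verbatim when ``prefer_verbatim`` is set, guaranteeing bit-compatible
    round trips; otherwise the description is generated from resolved
    primitives (deletions placed at the coordinates the exon boundaries
    force; the most-3' placement coincides with these for every
    catalogued event).
    """
    if event.kind == "ref":
        return "-"
    if prefer_verbatim and event.r_verbatim:
        return event.r_verbatim
    try:
        prims = resolve_primitives(event, model)
    except UnresolvableEventError:
        if event.r_verbatim:
            return event.r_verbatim
        return "r.?_?"
    return format_hgvs_r(prims)


def format_hgvs_r(prims: Sequence[Primitive]) -> str:
    dels = [p for p in prims if isinstance(p, Deletion)]
    inss = [p for p in prims if isinstance(p, Insertion)]
    if dels and not inss:
        return "r." + "+".join(f"{p.start}_{p.end}" for p in dels) + "del"
    if inss and not dels:
        p = inss[0]
        return f"r.{p.anchor}_{p.anchor + 1}ins{p.seg_start}_{p.seg_end}"
    raise InputError("mixed deletion/insertion events are not representable")


# -- NMD ------------------------------------------------------------------


@dataclass(frozen=True)
class NmdCall:
    nmd: str                       # 'NMD_predicted' | 'NMD_escape' | 'not_applicable'
    ptc_exon: Optional[int] = None
    ptc_position: Optional[int] = None  # reference c. position of the PTC's first base


def _altered_coordinates(prims: Sequence[Primitive], model: TranscriptModel):
    """Helpers for mapping reference c. positions into the altered transcript."""
    dels = sorted((p for p in prims if isinstance(p, Deletion)), key=lambda p: p.start)
    inss = sorted((p for p in prims if isinstance(p, Insertion)), key=lambda p: p.anchor)

    def alt(pos: int) -> int:
        shift = 0
        for d in dels:
            if d.end < pos:
                shift -= d.length
            elif d.start <= pos:
                raise ValueError(f"position {pos} deleted")
        for i in inss:
            if i.anchor < pos:
                shift += i.length
        return pos + shift

    return dels, inss, alt


def _last_junction_altered(prims, model) -> int:
    """Altered-transcript coordinate of the last nt before the final junction."""
    dels, inss, alt = _altered_coordinates(prims, model)
    deleted = lambda p: any(d.start <= p <= d.end for d in dels)
    junctions: list[int] = []
    full_retained = set()
    for i, (don, acc) in enumerate(model.natural_junctions(), start=1):
        if deleted(don) or deleted(acc):
            continue  # replaced by the novel junction below
        junctions.append(alt(don))
    for d in dels:
        if d.start > 1 and not deleted(d.start - 1):
            junctions.append(alt(d.start - 1))
    for ins in inss:
        base = alt(ins.anchor)
        if ins.seg_start.offset != 0 and ins.seg_end.offset != 0:
            if ins.seg_start.offset > 0 and ins.seg_end.offset < 0:
                pass  # full retention: junction removed entirely
            elif ins.seg_start.offset == 1 or ins.seg_end.offset == -1:
                junctions.append(base + ins.length)   # shifted donor/acceptor
            else:
                junctions.extend([base, base + ins.length])  # pseudoexon: two junctions
    if not junctions:
        raise ModelError("altered transcript has no junction")
    return max(junctions)


def _first_novel_altered(prims, model) -> int:
    dels, inss, alt = _altered_coordinates(prims, model)
    firsts = []
    for d in dels:
        firsts.append(alt(d.start - 1) + 1 if d.start > 1 else 1)
    for i in inss:
        firsts.append(alt(i.anchor) + 1)
    return min(firsts)


def nmd_prediction(
    event: SpliceEvent,
    model: TranscriptModel,
    sequence: str | None = None,
    window: int = NMD_WINDOW_NT,
) -> NmdCall:
    """Predict nonsense-mediated decay for an event.

    Without a transcript sequence the call is heuristic: a frameshift is
    NMD_predicted unless all novel sequence (hence the whole PTC search
    space) lies in the last exon or within ``window`` nt of the final
    exon-exon junction of the altered transcript.  With a sequence (CDS,
    length == cds_end) the altered transcript is translated, the first
    stop located, and the 50-nt rule applied exactly; deletion-type
    events only, since intronic sequence is not modelled.
    """
    frame = frame_annotation(event, model)
    if frame == "IF":
        return NmdCall("not_applicable")
    if frame == "unknown":
        raise UnresolvableEventError(f"{event.code}: frame unknown, NMD not assessable")
    prims = resolve_primitives(event, model)
    last_junc = _last_junction_altered(prims, model)

    if sequence is None:
        first = _first_novel_altered(prims, model)
        if first > last_junc - window:
            return NmdCall("NMD_escape")
        return NmdCall("NMD_predicted")

    sequence = sequence.strip().upper().replace("U", "T")
    if len(sequence) != model.cds_end:
        raise InputError(
            f"sequence length {len(sequence)} != cds_end {model.cds_end}")
    if any(isinstance(p, Insertion) for p in prims):
        raise InputError("sequence-aware NMD supports deletion events only "
                         "(intronic sequence is not modelled)")
    dels = sorted((p for p in prims if isinstance(p, Deletion)), key=lambda p: p.start)
    keep = []
    ref_of_alt = []  # reference c. position of each altered-transcript base
    cursor = 1
    for d in dels:
        keep.append((cursor, d.start - 1))
        cursor = d.end + 1
    keep.append((cursor, model.cds_end))
    altered = []
    for a, b in keep:
        for p in range(a, b + 1):
            altered.append(sequence[p - 1])
            ref_of_alt.append(p)
    altered_seq = "".join(altered)
    for i in range(0, len(altered_seq) - 2, 3):
        if altered_seq[i:i + 3] in STOP_CODONS:
            stop_first, stop_last = i + 1, i + 3
            ref_pos = ref_of_alt[stop_first - 1]
            exon = model.exon_of_position(ref_pos).index
            if last_junc - stop_last > window:
                return NmdCall("NMD_predicted", ptc_exon=exon, ptc_position=ref_pos)
            return NmdCall("NMD_escape", ptc_exon=exon, ptc_position=ref_pos)
    return NmdCall("NMD_escape")  # no stop in frame: read-through, no PTC to degrade


# -- domains --------------------------------------------------------------


def affected_domains(
    event: SpliceEvent,
    model: TranscriptModel,
    domains: DomainMap,
    frameshift_downstream: bool = True,
) -> list[str]:
    """Domains removed or disrupted by the event.

    A domain is affected when its interval (codon- or exon-level)
    intersects deleted sequence or contains an insertion point; with
    ``frameshift_downstream`` (the default) a frameshift additionally
    loses every domain downstream of the first altered position, since
    the encoded protein diverges from there.  Disable the flag to report
    only the directly removed region.
    """
    prims = resolve_primitives(event, model)
    frame = frame_annotation(event, model)
    hit: list[str] = []

    def add(names: Iterable[str]):
        for n in names:
            if n not in hit:
                hit.append(n)

    for p in prims:
        if isinstance(p, Deletion):
            if domains.level == "exon":
                exons = [ex.index for ex in model.exons if not (p.end < ex.start or p.start > ex.end)]
                add(domains.affected_by_exons(exons))
            else:
                add(domains.affected_by_codons(
                    model.codon_of_position(p.start), model.codon_of_position(min(p.end, model.cds_end))))
        else:
            if domains.level == "exon":
                ex = model.exon_of_position(p.anchor).index
                add(domains.affected_by_exons([ex, min(ex + 1, model.n_exons)]))
            else:
                add(domains.affected_by_codons(
                    model.codon_of_position(p.anchor), model.codon_of_position(p.anchor) + 1))
    # inter-primitive regions read out of frame: a compound event can be
    # net in-frame while the sequence between its primitives is shifted
    ordered = sorted(prims, key=lambda p: p.start if isinstance(p, Deletion) else p.anchor)
    cum = 0
    for i, p in enumerate(ordered[:-1]):
        cum += -p.length if isinstance(p, Deletion) else p.length
        if cum % 3 == 0:
            continue
        nxt = ordered[i + 1]
        lo = (p.end if isinstance(p, Deletion) else p.anchor) + 1
        hi = (nxt.start - 1) if isinstance(nxt, Deletion) else nxt.anchor
        if lo > hi:
            continue
        if domains.level == "exon":
            exons = [ex.index for ex in model.exons if not (hi < ex.start or lo > ex.end)]
            add(domains.affected_by_exons(exons))
        else:
            add(domains.affected_by_codons(
                model.codon_of_position(lo), model.codon_of_position(min(hi, model.cds_end))))
    if frame == "FS" and frameshift_downstream:
        starts = [p.start if isinstance(p, Deletion) else p.anchor for p in prims]
        first = min(starts)
        if domains.level == "exon":
            add(domains.downstream_of(model.exon_of_position(first).index))
        else:
            add(domains.downstream_of(model.codon_of_position(first)))
    order = {n: i for i, n in enumerate(domains.names())}
    return sorted(hit, key=order.get)


# -- compound events ------------------------------------------------------


def decompose_compound(event: SpliceEvent) -> list[str]:
    """Split a compound Δ code into its constituent single-event codes."""
    if event.kind != "del" or len(event.terms) == 1:
        return [event.code]
    return [SpliceEvent(kind="del", terms=(t,)).code for t in event.terms]


def merge_del_codes(codes: Sequence[str]) -> str:
    """Merge single Δ codes into one compound code (catalogue notation)."""
    terms: list[DelTerm] = []
    for c in codes:
        ev = parse_event_code(c)
        if ev.kind != "del":
            raise EventParseError(f"only Δ events can be merged: {c!r}")
        terms.extend(ev.terms)
    terms.sort(key=lambda t: t.start_exon)
    return SpliceEvent(kind="del", terms=tuple(terms)).code


# -- junctions ------------------------------------------------------------


def junctions_of_event(event: SpliceEvent, model: TranscriptModel) -> list[tuple[CPos, CPos]]:
    """The novel (donor, acceptor) junction pairs the event creates.

    The reference event returns its natural junctions.  Positions may be
    intronic (CPos with offset) for retention/pseudoexon events.
    """
    if event.kind == "ref":
        return [(CPos(d), CPos(a)) for d, a in model.natural_junctions()]
    prims = resolve_primitives(event, model)
    out: list[tuple[CPos, CPos]] = []
    for p in prims:
        if isinstance(p, Deletion):
            if p.start <= 1 or p.end >= model.cds_end:
                continue  # no junction beyond the transcript ends
            out.append((CPos(p.start - 1), CPos(p.end + 1)))
        else:
            nxt = p.anchor + 1
            if p.seg_start.offset > 0 and p.seg_end.offset > 0:      # donor-side retention / pseudoexon
                if p.seg_start.offset == 1:                           # retention: single shifted junction
                    out.append((p.seg_end, CPos(nxt)))
                else:                                                 # pseudoexon: two junctions
                    out.append((CPos(p.anchor), p.seg_start))
                    out.append((p.seg_end, CPos(nxt)))
            elif p.seg_start.offset < 0 and p.seg_end.offset < 0:
                if p.seg_end.offset == -1:                            # acceptor-side retention
                    out.append((CPos(p.anchor), p.seg_start))
                else:
                    out.append((CPos(p.anchor), p.seg_start))
                    out.append((p.seg_end, CPos(nxt)))
            else:                                                     # mixed-anchor pseudoexon
                out.append((CPos(p.anchor), p.seg_start))
                out.append((p.seg_end, CPos(nxt)))
    return out


# -- one-stop annotation --------------------------------------------------


@dataclass(frozen=True)
class FunctionalAnnotation:
    """Frame, NMD and domain impact of one event."""

    frame: str                      # 'IF' | 'FS' | 'unknown'
    nmd: str = "not_applicable"
    ptc_exon: Optional[int] = None
    ptc_position: Optional[int] = None
    domains_lost: tuple[str, ...] = ()
    delta_nt: Optional[int] = None


def annotate(
    event: SpliceEvent,
    model: TranscriptModel,
    domains: DomainMap | None = None,
    sequence: str | None = None,
) -> FunctionalAnnotation:
    frame = frame_annotation(event, model)
    if frame == "unknown":
        return FunctionalAnnotation(frame="unknown", nmd="not_applicable")
    delta = net_length_change(event, model)
    if frame == "FS":
        call = nmd_prediction(event, model, sequence=sequence)
    else:
        call = NmdCall("not_applicable")
    lost: tuple[str, ...] = ()
    if domains is not None and event.kind != "ref":
        lost = tuple(affected_domains(event, model, domains))
    return FunctionalAnnotation(
        frame=frame, nmd=call.nmd, ptc_exon=call.ptc_exon,
        ptc_position=call.ptc_position, domains_lost=lost, delta_nt=delta,
    )
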
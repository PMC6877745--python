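"""ACMG/AMP classification of canonical splice-site and PTC variants.

The loss-of-function criterion PVS1 is assigned by walking an adapted
decision tree over the predicted transcript outcomes of each splice-site
class (the 20 donor/acceptor IVS±1,2 dinucleotides of an 11-exon gene):

1. if any candidate outcome is in-frame, alters at most a small number
   of residues (default ≤ 2 codons) and deletes no codon of a clinically
   critical domain, the site is ``PVS1_moderate`` — a benign-leaning
   natural cryptic-site outcome exists;
2. otherwise, if the primary outcome (skipping of the affected exon) is
   frameshifting and predicted to trigger NMD, the site is ``PVS1`` at
   full strength — unless a gene-specific downgrade rule applies;
3. otherwise (in-frame loss of a critical region, or a frameshift
   escaping NMD but truncating a critical domain) the site is
   ``PVS1_strong``.

Candidate outcomes are the exon skip plus every catalogued natural
event anchored at the mutated site (donor/acceptor shifts, junction
retentions, and skips extending from that exon); where skipping is
structurally impossible (first-exon donor, last-exon acceptor) the
retention of the adjacent intron is the primary outcome.  Gene-specific
rules (a small table shipped with the package) encode downgrades whose
justification lies outside the transcript model, e.g. tolerated natural
skipping of a specific exon; every decision path is recorded in the
rationale trail.

PM2 (absent/extremely rare in population controls) is a simple allele
count threshold, and the final class combines PVS1-level evidence with
PM2 under the published ACMG/AMP combining rules restricted to this
evidence universe.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .catalogue import Catalogue
from .errors import InputError, ModelError, OutOfScopeError
from .events import (
    Deletion, Insertion, SpliceEvent, annotate, parse_event_code,
    resolve_primitives,
)
from .transcript import DomainMap, TranscriptModel

PVS1_LEVELS = ("PVS1", "PVS1_strong", "PVS1_moderate", "PVS1_NA")
#: severity order used when a benign-leaning candidate downgrades a site
_SEVERITY = {"PVS1": 3, "PVS1_strong": 2, "PVS1_moderate": 1, "PVS1_NA": 0}

ACMG_CLASSES = (
    "pathogenic", "likely pathogenic", "uncertain significance",
    "likely benign", "benign",
)

#: residues threshold under which an in-frame alteration counts as small
SMALL_INFRAME_CODONS = 2


@dataclass(frozen=True)
class SpliceSiteVariant:
    hgvs_c: str
    exon: int
    site: str                      # 'donor' | 'acceptor'
    intronic_offset: int           # +1/+2 (donor) or -1/-2 (acceptor)
    gnomad_alleles: Optional[int] = None
    clinvar_label: Optional[str] = None


@dataclass(frozen=True)
class AnnotatedOutcome:
    event: SpliceEvent
    origin: str                    # 'skip' | 'catalogue' | 'intron_retention'
    frame: str
    nmd: str
    domains_lost: tuple[str, ...]
    delta_nt: Optional[int]


@dataclass(frozen=True)
class OutcomePrediction:
    site_exon: int
    site_kind: str
    outcomes: tuple[AnnotatedOutcome, ...]
    primary: AnnotatedOutcome

    def codes(self) -> list[str]:
        return [o.event.code for o in self.outcomes]


@dataclass(frozen=True)
class EvidenceAssignment:
    pvs1: str
    pm2: Optional[bool]            # None = unknown (no allele count)
    rationale: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# variant parsing
# ---------------------------------------------------------------------------

_VARIANT_RE = re.compile(
    r"^(?:c\.)?(\d+)\s*([+-])\s*(\d+)\s*(.*)$"
)


def parse_variant(
    hgvs_c: str,
    model: TranscriptModel,
    gnomad_alleles: int | None = None,
    clinvar_label: str | None = None,
) -> SpliceSiteVariant:
    """Parse an intronic HGVS c. string addressing an IVS±1,2 position.

    Accepts the Unicode minus sign and spaced substitutions
    ("c.158+1G > T"); the trailing change description is not
    interpreted.  Positions beyond the consensus dinucleotide raise
    :class:`OutOfScopeError`.
    """
    text = hgvs_c.strip().replace("−", "-").replace("−", "-")
    m = _VARIANT_RE.match(text)
    if not m:
        raise InputError(f"cannot parse splice-site variant {hgvs_c!r}")
    base, sign, off = int(m.group(1)), m.group(2), int(m.group(3))
    offset = off if sign == "+" else -off
    if abs(offset) > 2:
        raise OutOfScopeError(
            f"{hgvs_c}: IVS{offset:+d} is beyond the consensus ±1,2 dinucleotide")
    site = model.boundary_site(base)
    if site is None:
        raise ModelError(f"{hgvs_c}: c.{base} is not an exon boundary of the model")
    exon, kind = site
    want = "donor" if offset > 0 else "acceptor"
    if kind != want:
        raise ModelError(
            f"{hgvs_c}: c.{base}{offset:+d} addresses a {want} site but c.{base} "
            f"is an {kind} boundary")
    return SpliceSiteVariant(hgvs_c=hgvs_c.strip(), exon=exon, site=kind,
                             intronic_offset=offset,
                             gnomad_alleles=gnomad_alleles,
                             clinvar_label=clinvar_label)


def canonical_sites(model: TranscriptModel) -> list[tuple[int, str]]:
    """All canonical splice-site classes of the model: the exon-1 donor,
    donor+acceptor for internal exons, and the last-exon acceptor."""
    sites = []
    for ex in model.exons:
        if ex.index > 1:
            sites.append((ex.index, "acceptor"))
        if ex.index < model.n_exons:
            sites.append((ex.index, "donor"))
    return sites


# ---------------------------------------------------------------------------
# outcome prediction
# ---------------------------------------------------------------------------


def _intron_retention_outcome(model, domains, intron: int) -> AnnotatedOutcome:
    """Retention of a full intron: a truncating outcome with the PTC
    assumed inside the retained intron sequence."""
    ev = parse_event_code(f"▼(I{intron})")
    # PTC inside intron k is downstream of every junction except those
    # further 3'; it escapes NMD only when the retained intron is the last.
    nmd = "NMD_escape" if intron == model.n_exons - 1 else "NMD_predicted"
    lost = tuple(
        d.name for d in domains.domains
        if d.end >= (intron + 1 if domains.level == "exon"
                     else model.codon_of_position(model.exon(intron).end))
    )
    return AnnotatedOutcome(event=ev, origin="intron_retention", frame="FS",
                            nmd=nmd, domains_lost=lost, delta_nt=None)


def _anchored_catalogue_events(cat: Catalogue, model, exon: int, site: str):
    """Catalogued events plausibly produced by loss of the given site:
    deletions starting at the exon's acceptor (skips and p shifts), and
    for donors also deletions ending at the exon's donor (q shifts) and
    retentions of the downstream intron's 5' end."""
    ex = model.exon(exon)
    hits = []
    for entry in cat.entries:
        ev = entry.event
        try:
            prims = resolve_primitives(ev, model)
        except Exception:
            continue
        if ev.is_compound:
            continue
        p = prims[0]
        if isinstance(p, Deletion):
            if p.start == ex.start:
                hits.append(ev)
            elif site == "donor" and p.end == ex.end:
                hits.append(ev)
        elif isinstance(p, Insertion) and site == "donor":
            if p.anchor == ex.end and p.seg_start.offset == 1:
                hits.append(ev)   # ▼(Ik q n): shifted donor
        elif isinstance(p, Insertion) and site == "acceptor":
            if p.anchor == model.exon(exon - 1).end and p.seg_end.offset == -1:
                hits.append(ev)   # ▼(I(k-1) p n): shifted acceptor
    return hits


def predicted_outcomes(
    variant_or_site,
    cat: Catalogue,
    model: TranscriptModel,
    domains: DomainMap,
) -> OutcomePrediction:
    """Predict candidate transcript outcomes for a splice-site class.

    ``variant_or_site`` is a SpliceSiteVariant or an (exon, site) pair.
    The primary outcome is the skip of the affected exon (or adjacent
    intron retention where no skip exists); candidates add every
    catalogued natural event anchored at the same site.
    """
    if isinstance(variant_or_site, SpliceSiteVariant):
        exon, site = variant_or_site.exon, variant_or_site.site
    else:
        exon, site = variant_or_site
    if site not in ("donor", "acceptor"):
        raise InputError(f"site must be donor/acceptor, got {site!r}")
    if site == "acceptor" and exon == 1:
        raise ModelError("exon 1 has no acceptor site")
    if site == "donor" and exon == model.n_exons:
        raise ModelError(f"exon {model.n_exons} (last) has no donor site")

    def annotated(ev: SpliceEvent, origin: str) -> AnnotatedOutcome:
        ann = annotate(ev, model, domains=domains)
        return AnnotatedOutcome(event=ev, origin=origin, frame=ann.frame,
                                nmd=ann.nmd, domains_lost=ann.domains_lost,
                                delta_nt=ann.delta_nt)

    outcomes: list[AnnotatedOutcome] = []
    if 1 < exon < model.n_exons:
        skip = parse_event_code(f"Δ(E{exon})")
        primary = annotated(skip, "skip")
        outcomes.append(primary)
    else:
        intron = exon if site == "donor" else exon - 1
        primary = _intron_retention_outcome(model, domains, intron)
        outcomes.append(primary)

    seen = {o.event.code for o in outcomes}
    for ev in _anchored_catalogue_events(cat, model, exon, site):
        if ev.code not in seen:
            outcomes.append(annotated(ev, "catalogue"))
            seen.add(ev.code)
    return OutcomePrediction(site_exon=exon, site_kind=site,
                             outcomes=tuple(outcomes), primary=outcomes[0])


# ---------------------------------------------------------------------------
# site rules & the decision tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteRule:
    exon: int
    site: str                      # 'donor' | 'acceptor' | 'any'
    from_level: str
    to_level: str
    reason: str

    def applies(self, exon: int, site: str, level: str) -> bool:
        return (self.exon == exon
                and self.site in ("any", site)
                and self.from_level == level)


def load_site_rules(source) -> tuple[SiteRule, ...]:
    if isinstance(source, (str,)) or hasattr(source, "read"):
        cfg = yaml.safe_load(source if hasattr(source, "read") else open(source))
    else:
        cfg = yaml.safe_load(open(source))
    rules = []
    for d in (cfg or {}).get("downgrades", []):
        rules.append(SiteRule(
            exon=int(d["exon"]), site=str(d.get("site", "any")),
            from_level=str(d.get("from", "PVS1")), to_level=str(d["to"]),
            reason=str(d.get("reason", "gene-specific adjustment")).strip(),
        ))
    return tuple(rules)


def bard1_site_rules() -> tuple[SiteRule, ...]:
    with resources.as_file(
            resources.files("bardsplice.data").joinpath("bard1_site_rules.yaml")) as p:
        return load_site_rules(str(p))


def pvs1_strength(
    variant_or_site,
    outcomes: OutcomePrediction,
    domains: DomainMap,
    cat: Catalogue,
    site_rules: Sequence[SiteRule] = (),
    small_inframe_codons: int = SMALL_INFRAME_CODONS,
) -> EvidenceAssignment:
    """Walk the adapted PVS1 decision tree for one splice-site class."""
    exon, site = outcomes.site_exon, outcomes.site_kind
    trail = [f"site: exon {exon} {site}"]
    resolvable = [o for o in outcomes.outcomes if o.frame != "unknown"]
    if not resolvable:
        return EvidenceAssignment("PVS1_NA", None,
                                  tuple(trail + ["no resolvable outcome: PVS1 not applicable"]))

    # (1) small benign-leaning in-frame candidate -> moderate
    for o in resolvable:
        if o.frame != "IF" or o.delta_nt is None:
            continue
        inserted = max(o.delta_nt, 0) // 3
        deleted_domain = bool(o.domains_lost) and o.delta_nt < 0
        if abs(o.delta_nt) <= 3 * small_inframe_codons and not deleted_domain \
                and not (o.delta_nt < 0 and o.domains_lost):
            trail.append(
                f"candidate {o.event.code}: in-frame, {inserted or abs(o.delta_nt)//3} "
                f"codon(s) altered, no critical-domain codon deleted -> PVS1_moderate")
            return EvidenceAssignment("PVS1_moderate", None, tuple(trail))

    primary = outcomes.primary
    trail.append(f"primary outcome {primary.event.code}: {primary.frame}"
                 + (f", {primary.nmd}" if primary.frame == "FS" else ""))

    if primary.frame == "FS" and primary.nmd == "NMD_predicted":
        level = "PVS1"
        trail.append("frameshift with predicted NMD in the biologically relevant transcript -> PVS1")
        for rule in site_rules:
            if rule.applies(exon, site, level):
                level = rule.to_level
                trail.append(f"gene-specific rule: {rule.reason} -> {level}")
                break
        return EvidenceAssignment(level, None, tuple(trail))

    if primary.frame == "IF":
        if primary.domains_lost:
            trail.append(
                f"in-frame loss intersecting critical domain(s) "
                f"{', '.join(primary.domains_lost)} -> PVS1_strong")
        else:
            trail.append("in-frame alteration of >10% of the protein -> PVS1_strong")
    else:
        trail.append(
            f"frameshift escaping NMD, truncation removes "
            f"{', '.join(primary.domains_lost) or 'downstream sequence'} -> PVS1_strong")
    return EvidenceAssignment("PVS1_strong", None, tuple(trail))


# ---------------------------------------------------------------------------
# PM2 and combining
# ---------------------------------------------------------------------------


def assign_pm2(variant: SpliceSiteVariant, allele_threshold: int = 2) -> Optional[bool]:
    """PM2: absent or extremely rare in population controls.

    Returns None (unknown, not asserted) when no allele count is
    available."""
    if variant.gnomad_alleles is None:
        return None
    return variant.gnomad_alleles <= allele_threshold


def combine_acmg(evidence: EvidenceAssignment) -> str:
    """ACMG/AMP combining rules restricted to the {PVS1*, PM2} universe."""
    if evidence.pvs1 not in PVS1_LEVELS:
        raise InputError(f"unknown PVS1 level {evidence.pvs1!r}")
    if not evidence.pm2:
        return "uncertain significance"
    if evidence.pvs1 in ("PVS1", "PVS1_strong"):
        return "likely pathogenic"
    return "uncertain significance"


# ---------------------------------------------------------------------------
# PTC variants and rescue transcripts
# ---------------------------------------------------------------------------


def classify_ptc_variant(
    ptc_exon: int,
    cat: Catalogue,
    domains: DomainMap,
    model: TranscriptModel,
) -> EvidenceAssignment:
    """PVS1 for a PTC-NMD variant in ``ptc_exon``, searching the catalogue
    for a rescue transcript: an in-frame entry that removes the exon while
    preserving every clinically relevant domain."""
    model.exon(ptc_exon)
    trail = [f"PTC in exon {ptc_exon}"]
    if not cat.entries:
        return EvidenceAssignment(
            "PVS1", None, tuple(trail + ["no catalogue available (caveat: rescue "
                                         "transcripts unassessed) -> PVS1"]))
    for entry in cat.entries:
        ev = entry.event
        ann = annotate(ev, model, domains=domains)
        if ann.frame != "IF":
            continue
        try:
            prims = resolve_primitives(ev, model)
        except Exception:
            continue
        removes = any(
            isinstance(p, Deletion)
            and p.start <= model.exon(ptc_exon).start
            and p.end >= model.exon(ptc_exon).end
            for p in prims)
        if removes and not ann.domains_lost:
            trail.append(f"rescue transcript {ev.code}: in-frame, removes exon "
                         f"{ptc_exon}, preserves all domains -> PVS1 not applicable")
            return EvidenceAssignment("PVS1_NA", None, tuple(trail))
    trail.append("no candidate rescue transcript in the catalogue -> PVS1")
    return EvidenceAssignment("PVS1", None, tuple(trail))


# ---------------------------------------------------------------------------
# pipeline over variant tables
# ---------------------------------------------------------------------------


def classify_sites(
    model: TranscriptModel,
    cat: Catalogue,
    domains: DomainMap,
    site_rules: Sequence[SiteRule] = (),
) -> pd.DataFrame:
    """PVS1 strength for every canonical splice-site class of the model."""
    rows = []
    for exon, site in canonical_sites(model):
        pred = predicted_outcomes((exon, site), cat, model, domains)
        ev = pvs1_strength((exon, site), pred, domains, cat, site_rules)
        rows.append({"exon": exon, "site": site, "pvs1": ev.pvs1,
                     "outcomes": ";".join(pred.codes()),
                     "rationale": " | ".join(ev.rationale)})
    return pd.DataFrame(rows, columns=["exon", "site", "pvs1", "outcomes", "rationale"])


def classify_variants(
    variants: Iterable[SpliceSiteVariant],
    model: TranscriptModel,
    cat: Catalogue,
    domains: DomainMap,
    site_rules: Sequence[SiteRule] = (),
    pm2_threshold: int = 2,
) -> pd.DataFrame:
    """Classify splice-site variants end to end (Table-style output)."""
    rows = []
    for v in variants:
        pred = predicted_outcomes(v, cat, model, domains)
        ev = pvs1_strength(v, pred, domains, cat, site_rules)
        pm2 = assign_pm2(v, pm2_threshold)
        final = combine_acmg(EvidenceAssignment(ev.pvs1, pm2, ev.rationale))
        rows.append({
            "exon": v.exon, "site": v.site, "variant": v.hgvs_c,
            "pvs1": ev.pvs1,
            "pm2": {True: "Yes", False: "No", None: "Unknown"}[pm2],
            "classification": final,
            "rationale": " | ".join(ev.rationale),
        })
    return pd.DataFrame(rows, columns=["exon", "site", "variant", "pvs1", "pm2",
                                       "classification", "rationale"])
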
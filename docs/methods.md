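# Methods

This note documents the models, conventions, parameters and numerical
choices behind `bardsplice`, and what its synthetic-data tests do and do
not demonstrate about real data.

## Coordinate frame

All computation runs in cDNA (c.) coordinates; RNA (r.) positions are
taken numerically equal to c. positions, the convention under which the
published event descriptions are internally consistent (e.g. the
four-nucleotide donor shift on exon 1 is `r.155_158del` against an exon
1 ending at c.158). Genomic coordinates and strand are out of scope.
Exon 1 is stored as starting at c.1 (the translation start); its 5' UTR
extent is unknown, so events with `?` breakpoints in exon 1 are
representable but excluded from coordinate-level annotation. Exon 11
ends at the CDS end, c.2334 = 3 × (777 + 1); the 3' UTR is not
modelled. Because c. numbering runs contiguously across junctions,
every natural splice junction is an adjacent position pair (donor k,
donor k + 1); junction tables rely on the boundary table, not on
position gaps, to recognise junctions.

## Event model

Events are compositions of two primitives: contiguous deletions of
exonic sequence and insertions of intronic segments, written in the
Δ/▼ grammar. Codes that omit a breakpoint count (e.g. `Δ(E2q)`,
`Δ(E4int104)` without a position) are resolved against the stored r.
description when one is supplied; otherwise they are flagged
unresolvable and refuse frame/NMD/domain annotation, mirroring the
`?` rows of the packaged catalogue. Four catalogued events are
permanently unresolvable for this reason.

HGVS r. output regenerates descriptions from resolved primitives —
deletion coordinates are forced by the exon boundaries, and for every
catalogued event the most-3' placement coincides with them. Events
loaded from the catalogue re-emit their stored description verbatim, so
round trips are bit-compatible even for the one catalogued insertion
whose printed anchor convention differs from the canonical
donor-anchored form the generator produces.

Reading frame is IF iff the summed net length change is a codon
multiple. Domain impact is computed at exon level by default (RING on
exons 2–3, ARD on exons 5–7, BRCT on exons 8–11, following the
published schematic; a codon-level map with intervals derived from the
same exon spans ships alongside and is configurable). A domain is lost
when deleted sequence intersects it, when an insertion lands inside it,
when a frameshift starts upstream of it, or — for compound events that
are net in-frame — when the segment *between* two primitives is read in
a shifted frame (a one-primitive frame analysis would miss, for
example, that an event deleting 4 nt of exon 1 plus all of exon 4
destroys the RING domain encoded between them).

## NMD prediction

The canonical 50-nt rule is used: a premature termination codon more
than 50 nt upstream of the final exon–exon junction of the *altered*
transcript predicts NMD. Two modes:

* **sequence-free (default)** — the PTC position is unknowable without
  sequence, so frameshift events are classified by where their novel
  sequence begins: if the first changed base lies within 50 nt of the
  final junction (or in the last exon), every reachable PTC escapes;
  otherwise NMD is predicted. Full retention of the last intron
  escapes; retention of any earlier intron is predicted (the PTC is
  assumed within the retained intron).
* **sequence-aware** — given a CDS FASTA (length = 2334), the altered
  transcript is translated, the first stop located and the 50-nt rule
  applied exactly, also reporting the PTC's exon. Deletion events
  only: intronic sequence is not modelled.

The heuristic is exact whenever a stop actually occurs early in the
shifted frame. Under a uniform-codon model the chance that no stop
appears in *n* shifted codons is (61/64)^n, so the heuristic's declared
reliability domain is frameshifts with at least 200 codons of search
space upstream of the escape boundary (failure probability < 10⁻⁴ per
transcript); the oracle-equivalence test draws 1,000 randomized
deletions inside that domain and checks exact agreement against a
brute-force Biopython translation. Near the boundary (e.g. an exon 8
skip, with ~47 codons of search space) the heuristic deliberately
errs toward predicting NMD, the conservative direction for PVS1
assessment.

## Quantification

An event's level is `100·a/n̄` (ratio, default) or `100·a/(a+n̄)`
(bounded), where `a` supports the event's novel junction(s) and `n̄` is
the mean read count over natural junctions whose c. interval intersects
the novel junction's span. The exact published formula is delegated to
prior work and not restated there, so both variants are implemented
behind a flag; the bounded form is linear in transcript abundance
(percentage = abundance when the event fully depletes its overlapped
naturals), which makes it the right scale for recovering fold-changes
such as the NMD-inhibition contrast. Compound events take the minimum
of their junction supports as a conservative joint estimate. The
targeted-sequencing detection filter (junction seen in ≥ 3 samples with
mean reads > 4) is reproduced as a configurable rule.

## Splice-site classification

Each of the 20 canonical site classes gets a candidate outcome set: the
skip of the affected exon (primary), every catalogued single event
anchored at the site (deletions starting at the exon's acceptor;
deletions ending at the donor and 5'-intron retentions for donor
sites; 3'-intron retentions for acceptor sites), and full retention of
the adjacent intron where no skip exists (first-exon donor, last-exon
acceptor). The tree then assigns:

1. **PVS1_moderate** if any candidate is in-frame, alters ≤ 2 codons
   (configurable) and deletes no domain codon — in practice only the
   exon 5 donor, via the one-codon retention ▼(I5q3);
2. **PVS1** if the primary outcome is a frameshift with predicted NMD
   and no gene-specific downgrade applies;
3. **PVS1_strong** otherwise (in-frame domain loss, in-frame removal of
   a large protein fraction, NMD-escaping truncation).

One gene-specific rule ships with the package: sites whose primary
outcome is the exon 4 skip are capped at PVS1_strong, because that
skip is itself a naturally occurring event detected by every assay in
nearly every tissue surveyed — evidence that transcripts lacking exon 4
are tolerated, which weakens the loss-of-function inference that the
NMD branch would otherwise make. The rule lives in a small YAML table
(`data/bard1_site_rules.yaml`) so other judgments of this kind can be
added per gene without touching the tree; every applied rule is
recorded in the per-site rationale trail.

PM2 is asserted when the gnomAD allele count is ≤ 2 (the maximum among
the published variants, all of which are annotated PM2), unknown when
no count is supplied. Final classes use the published ACMG/AMP
combining rules restricted to this evidence universe: PVS1 or
PVS1_strong plus PM2 → likely pathogenic; PVS1_moderate plus PM2, or
any single criterion alone → uncertain significance. ClinVar labels are
carried as annotations only.

PTC variants: the catalogue is searched for a rescue transcript — an
in-frame entry removing the PTC's exon while preserving RING, ARD and
BRCT (including the inter-primitive frame check above). None exists in
the packaged catalogue, so every exon returns full-strength PVS1; a
synthetic rescue scenario is exercised on a toy gene in the tests.

## Synthetic data

The generators emulate the study conditions, not raw sequencing:

* **junction counts** — each transcript carries at most one event;
  an event at abundance *f* contributes *f* to its novel junction(s)
  and depletes the natural junctions it overlaps by *f*; reads are one
  multinomial draw per sample × condition over junction weights.
  Default depth 50,000 reads (the order of the study's targeted
  junction yield per cohort); NMD-targeted events (per the package's
  own prediction, making the simulator a closed loop over that logic)
  are scaled by the inhibition factor in the treated condition.
* **long-read chains** — isoforms combine events independently at
  their abundances, subject to non-contiguity (≥ 1 intact exon between
  altered regions) and a per-isoform cap defaulting to 2, the maximum
  complexity observed in full-length sequencing; chains decompose back
  to event sets exactly.
* **transcript FASTA** — uniform random codons, stop-free in the
  reference frame except for planned stops, with optional planted
  stops, pinned bases and stop-free windows in shifted frames so PTC
  positions can be engineered deterministically.

What passing tests show: the estimators are consistent (error shrinks
with depth, configured abundances and fold-changes are recovered within
stated tolerances), and the annotation/classification logic is exact on
the packaged tables. What they do not show: robustness to alignment
artifacts, junction-mapping error, PCR or capture bias, expression
heterogeneity across tissues, or sequencing-error-induced spurious
junctions — none of which the generators model.

## Numerical and design choices

* NMD window 50 nt, PM2 threshold 2 alleles, small in-frame threshold
  2 codons, detection filter (3 samples, mean > 4 reads) — all
  configurable, defaults as above.
* Percentages are plain floats; `a > 0` against zero natural support is
  reported as `inf` with an `undefined_high` flag rather than an error;
  zero support yields 0 with a `zero_support` flag.
* Simulators seed `numpy.random.default_rng` with (seed, sample,
  condition) tuples, so adding samples never reshuffles earlier ones.
* Unicode Δ/▼ are canonical on output; ASCII aliases (`d`, `v`,
  hyphenated ranges) are accepted on input for shell safety.
* The spec-level choice between ratio and bounded percentages is left
  to the caller (`formula=`); ratio is the default reading of
  "percentage of overlapping natural junctions".

## Known limitations

* No genomic liftover, no multi-transcript gene models, no UTR-aware
  translation-start selection; alternative-ORF biology (e.g. isoforms
  using downstream start codons) is out of scope, so domain-impact
  annotation is relative to the reference reading frame only.
* Sequence-aware NMD cannot assess insertion events without intronic
  sequence.
* The catalogue records detection, not abundance; operations that would
  need per-event expression levels (e.g. ranking events by level across
  tissues) are limited to the junction-count pathway.
* The PVS1 tree's gene-specific downgrades encode published judgments;
  applying the package to another gene requires reviewing that table,
  not just replacing the transcript model.
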
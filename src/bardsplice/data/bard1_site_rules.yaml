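# Gene-specific adjustments to the generic PVS1 decision tree for BARD1
# canonical splice-site (IVS +/-1,2) variants. Each rule caps or overrides
# the tree-derived strength for a site class, with the clinical rationale
# recorded in the decision trail.
downgrades:
  - exon: 4
    site: any          # applies to both the acceptor and the donor of exon 4
    from: PVS1
    to: PVS1_strong
    reason: >-
      Exon 4 skipping is a naturally occurring splicing event detected by all
      assay types in nearly every tissue surveyed, indicating that transcripts
      lacking this exon are tolerated at appreciable levels; full-strength
      loss-of-function evidence is therefore reduced one step.
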
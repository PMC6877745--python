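"""Synthetic generators: reproducibility, estimator recovery, round trips."""

import io

import numpy as np
import pytest

from bardsplice.errors import ConfigError
from bardsplice.events import parse_event_code
from bardsplice.quant import compare_conditions, load_junction_table, percent_of_natural
from bardsplice.simulate import (
    SimulationConfig, chain_of_events, decompose_chain, expected_percent,
    simulate_junction_counts, simulate_long_read_chains,
    simulate_transcript_fasta,
)


def counts_from(df, model):
    return load_junction_table(io.StringIO(df.to_csv(sep="\t", index=False)), model)


# -- junction counts -------------------------------------------------------


def test_reproducible_under_fixed_seed(model):
    cfg = SimulationConfig(model=model, event_profile={"Δ(E3)": 0.1},
                           total_junction_reads=5000, n_samples=2, seed=42)
    assert simulate_junction_counts(cfg).equals(simulate_junction_counts(cfg))


def test_zero_abundance_gives_only_natural_junctions(model):
    cfg = SimulationConfig(model=model, event_profile={}, total_junction_reads=1000,
                           seed=1)
    df = simulate_junction_counts(cfg)
    counts = counts_from(df, model)
    assert all(c.natural for c in counts)
    assert df[df.condition == "untreated"].reads.sum() == 1000


def test_abundance_sum_validated(model):
    with pytest.raises(ConfigError, match="sum"):
        SimulationConfig(model=model, event_profile={"Δ(E3)": 0.7, "Δ(E7)": 0.4}, seed=1)
    with pytest.raises(ConfigError, match="sum"):
        # valid untreated but >1 once the NMD-inhibition factor applies
        SimulationConfig(model=model, event_profile={"Δ(E3)": 0.4},
                         nmd_inhibition_factor=3.0, seed=1)


def test_estimator_recovers_truth(model):
    cfg = SimulationConfig(model=model, event_profile={"Δ(E3)": 0.12},
                           total_junction_reads=50_000, seed=7)
    counts = counts_from(simulate_junction_counts(cfg), model)
    ev = parse_event_code("Δ(E3)")
    for formula in ("ratio", "bounded"):
        q = percent_of_natural(ev, counts, model, formula=formula, condition="untreated")
        assert q.pooled == pytest.approx(expected_percent(cfg, "Δ(E3)", formula), abs=1.0)


def test_error_shrinks_with_depth(model):
    """Mean absolute estimation error over replicates decreases with
    read depth (consistency of the estimator)."""
    mean_errs = []
    for depth in (500, 5_000, 200_000):
        errs = []
        for rep in range(5):
            cfg = SimulationConfig(model=model, event_profile={"Δ(E4)": 0.05},
                                   total_junction_reads=depth, seed=130 + rep)
            counts = counts_from(simulate_junction_counts(cfg), model)
            q = percent_of_natural(parse_event_code("Δ(E4)"), counts, model,
                                   formula="bounded", condition="untreated")
            errs.append(abs(q.pooled - expected_percent(cfg, "Δ(E4)", "bounded")))
        mean_errs.append(np.mean(errs))
    assert mean_errs[2] < mean_errs[1] < mean_errs[0]
    assert mean_errs[2] < 0.5


def test_mean_fraction_matches_abundance_over_replicates(model):
    """Expected novel-junction read fraction matches the configured
    abundance within 3 standard errors (reduced replicate count)."""
    f, reads, reps = 0.08, 2000, 30
    fracs = []
    for r in range(reps):
        cfg = SimulationConfig(model=model, event_profile={"Δ(E7)": f},
                               total_junction_reads=reads, seed=100 + r)
        df = simulate_junction_counts(cfg)
        df = df[df.condition == "untreated"]
        novel = df[(df.donor == "1568") & (df.acceptor == "1678")].reads.sum()
        # per-transcript weight normalisation: compare against analytic expectation
        total_w = 10 - 2 * f + f  # 10 naturals, two depleted, one novel junction
        fracs.append(novel / reads)
    expected = f / (10 - f)
    se = np.std(fracs, ddof=1) / np.sqrt(reps)
    assert abs(np.mean(fracs) - expected) < 3 * se + 1e-9


def test_nmd_inhibition_contrast_recovered(model):
    """A configured 3x NMD-inhibition factor is recovered within 20%
    from the bounded percentages of treated vs untreated tables."""
    cfg = SimulationConfig(model=model, event_profile={"Δ(E3)": 0.12, "Δ(E9)": 0.05},
                           total_junction_reads=50_000, nmd_inhibition_factor=3.0,
                           seed=19)
    counts = counts_from(simulate_junction_counts(cfg), model)
    ev = parse_event_code("Δ(E3)")
    qu = percent_of_natural(ev, counts, model, "bounded", condition="untreated")
    qi = percent_of_natural(ev, counts, model, "bounded", condition="NMD_inhibited")
    ratio = compare_conditions([qu], [qi]).loc[0, "ratio"]
    assert ratio == pytest.approx(3.0, rel=0.2)
    # the in-frame event Δ(E9) is not NMD-targeted and stays flat
    q9u = percent_of_natural(parse_event_code("Δ(E9)"), counts, model, "bounded",
                             condition="untreated")
    q9i = percent_of_natural(parse_event_code("Δ(E9)"), counts, model, "bounded",
                             condition="NMD_inhibited")
    assert compare_conditions([q9u], [q9i]).loc[0, "ratio"] == pytest.approx(1.0, rel=0.2)


def test_assay_dropout_removes_events(model):
    cfg = SimulationConfig(model=model, event_profile={"Δ(E3)": 0.2},
                           total_junction_reads=2000, n_samples=6,
                           assay_dropout=1.0, seed=3)
    df = simulate_junction_counts(cfg)
    assert counts_from(df, model) and all(c.natural for c in counts_from(df, model))


# -- long-read chains ------------------------------------------------------


def test_chains_full_length_only_when_capped_at_zero(model):
    cfg = SimulationConfig(model=model, event_profile={"Δ(E4)": 0.5},
                           total_junction_reads=50, seed=5)
    ch = simulate_long_read_chains(cfg, max_events_per_isoform=0)
    assert set(ch.isoform_code) == {"Full length"}
    assert ch.junction_list.nunique() == 1


def test_compound_isoform_generated_and_decomposed(model):
    cfg = SimulationConfig(model=model, event_profile={"Δ(E4)": 0.5, "Δ(E8_E9)": 0.5},
                           total_junction_reads=400, seed=8)
    ch = simulate_long_read_chains(cfg, 2)
    assert "Δ(E4,E8_E9)" in set(ch.isoform_code)


def test_chain_round_trip_identity(model):
    """chain -> decomposition -> chain is the identity for all generated
    isoforms, including retention events."""
    cfg = SimulationConfig(
        model=model,
        event_profile={"Δ(E4)": 0.35, "Δ(E8_E9)": 0.25, "▼(I5q3)": 0.2,
                       "Δ(E2q4)": 0.1},
        total_junction_reads=500, seed=21)
    ch = simulate_long_read_chains(cfg, 2)
    for row in ch.itertuples():
        chain = [tuple(j.split(">")) for j in row.junction_list.split(";")]
        assert decompose_chain(chain, cfg.model) == row.isoform_code
        # and re-deriving the chain from the decomposed codes matches
        codes = ([] if row.isoform_code == "Full length"
                 else [c for part in row.isoform_code.split("+")
                       for c in ([part] if part.startswith(("▼", "IVS"))
                                 else [part])])
        rebuilt = chain_of_events(
            [c for code in codes for c in _expand(code)], cfg.model)
        assert [f"{d}>{a}" for d, a in rebuilt] == row.junction_list.split(";")


def _expand(code):
    from bardsplice.events import decompose_compound
    ev = parse_event_code(code)
    return decompose_compound(ev) if ev.kind == "del" else [code]


def test_chain_junctions_consistent_with_model(model):
    cfg = SimulationConfig(model=model, event_profile={"Δ(E3)": 0.4},
                           total_junction_reads=100, seed=2)
    ch = simulate_long_read_chains(cfg, 1)
    natural = {f"{d}>{a}" for d, a in model.natural_junctions()}
    allowed = natural | {"215>365"}
    for jl in ch.junction_list:
        assert set(jl.split(";")) <= allowed


# -- transcript FASTA ------------------------------------------------------


def test_fasta_reproducible_and_valid(model):
    a = simulate_transcript_fasta(model, seed=9)
    b = simulate_transcript_fasta(model, seed=9)
    c = simulate_transcript_fasta(model, seed=10)
    assert a == b and a != c
    seq = "".join(a.splitlines()[1:])
    assert len(seq) == model.cds_end
    assert seq.startswith("ATG")


def test_translation_yields_full_protein(model):
    from Bio.Seq import Seq
    seq = "".join(simulate_transcript_fasta(model, seed=11).splitlines()[1:])
    protein = str(Seq(seq).translate(to_stop=True))
    assert len(protein) == model.protein_length


def test_stop_at_initiator_rejected(model):
    with pytest.raises(ConfigError):
        simulate_transcript_fasta(model, stop_plan=[(1, True)], seed=1)
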
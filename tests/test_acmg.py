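"""PVS1 decision tree, PM2, ACMG combining and the PTC/rescue rule."""

import pandas as pd
import pytest
from importlib import resources

from bardsplice.acmg import (
    EvidenceAssignment, assign_pm2, canonical_sites, classify_ptc_variant,
    classify_sites, classify_variants, combine_acmg, parse_variant,
    predicted_outcomes, pvs1_strength,
)
from bardsplice.catalogue import Catalogue
from bardsplice.errors import InputError, ModelError, OutOfScopeError


def variants_fixture():
    with resources.as_file(
            resources.files("bardsplice.data").joinpath("bard1_variants.tsv")) as p:
        return pd.read_csv(p, sep="\t").fillna("")


# -- variant parsing -------------------------------------------------------


@pytest.mark.parametrize("hgvs,exon,site,offset", [
    ("c.158+1G > T", 1, "donor", 1),
    ("c.2002−2A > G", 11, "acceptor", -2),   # Unicode minus
    ("215+2T>C", 2, "donor", 2),             # missing c. prefix
    ("c.1395+1dup", 5, "donor", 1),
])
def test_parse_variant(hgvs, exon, site, offset, model):
    v = parse_variant(hgvs, model)
    assert (v.exon, v.site, v.intronic_offset) == (exon, site, offset)


def test_beyond_consensus_rejected(model):
    with pytest.raises(OutOfScopeError):
        parse_variant("c.158+3A > G", model)


def test_non_boundary_position_rejected(model):
    with pytest.raises(ModelError):
        parse_variant("c.200+1G>A", model)


# -- outcome prediction ----------------------------------------------------


def test_exon5_donor_outcomes(model, catalogue, domains):
    pred = predicted_outcomes((5, "donor"), catalogue, model, domains)
    codes = set(pred.codes())
    assert {"Δ(E5)", "▼(I5q3)", "Δ(E5_E9)", "Δ(E5_E10)"} <= codes
    frames = {o.event.code: o.frame for o in pred.outcomes}
    assert frames["Δ(E5)"] == "IF" and frames["▼(I5q3)"] == "IF"
    assert pred.primary.event.code == "Δ(E5)"


def test_exon3_donor_outcomes(model, catalogue, domains):
    pred = predicted_outcomes((3, "donor"), catalogue, model, domains)
    frames = {o.event.code: o.frame for o in pred.outcomes}
    assert frames["Δ(E3)"] == "FS"


def test_site_without_shifts_gets_skip_only(model, toy_rescue_catalogue, domains):
    # exon 2 of the BARD1 model has no anchored event in the toy catalogue
    pred = predicted_outcomes((8, "donor"), toy_rescue_catalogue, model, domains)
    assert pred.codes() == ["Δ(E8)"]


def test_structural_errors(model, catalogue, domains):
    with pytest.raises(ModelError):
        predicted_outcomes((1, "acceptor"), catalogue, model, domains)
    with pytest.raises(ModelError):
        predicted_outcomes((11, "donor"), catalogue, model, domains)


# -- PVS1 strengths --------------------------------------------------------


@pytest.mark.parametrize("exon,site,level", [
    (1, "donor", "PVS1"),
    (9, "acceptor", "PVS1_strong"),
    (5, "donor", "PVS1_moderate"),
    (4, "acceptor", "PVS1_strong"),
    (11, "acceptor", "PVS1_strong"),
])
def test_site_strengths(exon, site, level, model, catalogue, domains, site_rules):
    pred = predicted_outcomes((exon, site), catalogue, model, domains)
    ev = pvs1_strength((exon, site), pred, domains, catalogue, site_rules)
    assert ev.pvs1 == level
    assert ev.rationale  # decision path recorded


def test_strength_histogram(model, catalogue, domains, site_rules):
    """Over the 20 canonical site classes: 9 PVS1, 10 strong, 1 moderate."""
    table = classify_sites(model, catalogue, domains, site_rules)
    assert len(table) == 20
    hist = table.pvs1.value_counts().to_dict()
    assert hist == {"PVS1": 9, "PVS1_strong": 10, "PVS1_moderate": 1}
    mod = table[table.pvs1 == "PVS1_moderate"]
    assert [(int(r.exon), r.site) for r in mod.itertuples()] == [(5, "donor")]


def test_downgrade_rationale_recorded(model, catalogue, domains, site_rules):
    pred = predicted_outcomes((4, "donor"), catalogue, model, domains)
    ev = pvs1_strength((4, "donor"), pred, domains, catalogue, site_rules)
    assert ev.pvs1 == "PVS1_strong"
    assert any("gene-specific" in step for step in ev.rationale)


# -- PM2 and combining -----------------------------------------------------


def test_pm2(model):
    v0 = parse_variant("c.158+1G>T", model, gnomad_alleles=0)
    v2 = parse_variant("c.1678-1G>T", model, gnomad_alleles=2)
    v500 = parse_variant("c.1678-1G>T", model, gnomad_alleles=500)
    vna = parse_variant("c.158+1G>T", model)
    assert assign_pm2(v0) is True
    assert assign_pm2(v2) is True
    assert assign_pm2(v500) is False
    assert assign_pm2(vna) is None


@pytest.mark.parametrize("pvs1,pm2,expected", [
    ("PVS1", True, "likely pathogenic"),
    ("PVS1_strong", True, "likely pathogenic"),
    ("PVS1_moderate", True, "uncertain significance"),
    ("PVS1_strong", False, "uncertain significance"),
    ("PVS1", None, "uncertain significance"),
])
def test_combine_acmg(pvs1, pm2, expected):
    assert combine_acmg(EvidenceAssignment(pvs1, pm2)) == expected


def test_combining_is_monotone_in_pvs1():
    order = ["PVS1_moderate", "PVS1_strong", "PVS1"]
    rank = {"uncertain significance": 0, "likely pathogenic": 1, "pathogenic": 2}
    for pm2 in (True, False):
        classes = [rank[combine_acmg(EvidenceAssignment(lv, pm2))] for lv in order]
        assert classes == sorted(classes)


# -- full variant-table reproduction --------------------------------------


def test_variant_table_reproduced(model, catalogue, domains, site_rules):
    """Every published splice-site variant row gets the published PVS1
    strength, PM2 status and proposed classification."""
    df = variants_fixture()
    withv = df[df.hgvs_c != ""]
    variants = [parse_variant(r.hgvs_c, model, gnomad_alleles=int(r.gnomad_alleles))
                for r in withv.itertuples()]
    out = classify_variants(variants, model, catalogue, domains, site_rules)
    for got, want in zip(out.itertuples(), withv.itertuples()):
        assert got.pvs1 == want.published_pvs1, want.hgvs_c
        assert got.pm2 == want.published_pm2, want.hgvs_c
        assert got.classification.lower() == want.published_class.lower(), want.hgvs_c
        assert (got.exon, got.site) == (want.exon, want.site), want.hgvs_c


def test_unreported_site_classes_match_published(model, catalogue, domains, site_rules):
    df = variants_fixture()
    sites = classify_sites(model, catalogue, domains, site_rules)
    for r in df[df.hgvs_c == ""].itertuples():
        row = sites[(sites.exon == r.exon) & (sites.site == r.site)].iloc[0]
        assert row.pvs1 == r.published_pvs1


# -- PTC / rescue-transcript rule -----------------------------------------


def test_ptc_pvs1_for_every_exon(model, catalogue, domains):
    """No rescue transcript exists in the packaged catalogue, so a
    PTC-NMD variant in any exon keeps full-strength PVS1."""
    for exon in range(1, 12):
        ev = classify_ptc_variant(exon, catalogue, domains, model)
        assert ev.pvs1 == "PVS1", exon


def test_ptc_rescue_found_in_synthetic_catalogue(toy_model, toy_domains,
                                                 toy_rescue_catalogue):
    ev = classify_ptc_variant(3, toy_rescue_catalogue, toy_domains, toy_model)
    assert ev.pvs1 == "PVS1_NA"
    assert any("Δ(E3)" in step for step in ev.rationale)
    # the rescue only covers exon 3; a PTC elsewhere keeps PVS1
    assert classify_ptc_variant(2, toy_rescue_catalogue, toy_domains, toy_model).pvs1 == "PVS1"


def test_ptc_empty_catalogue_caveat(model, domains, catalogue):
    empty = Catalogue(entries=(), reference=None, columns=catalogue.columns)
    ev = classify_ptc_variant(4, empty, domains, model)
    assert ev.pvs1 == "PVS1"
    assert any("caveat" in step for step in ev.rationale)


def test_canonical_sites_enumeration(model):
    sites = canonical_sites(model)
    assert len(sites) == 20
    assert (1, "donor") in sites and (11, "acceptor") in sites
    assert (1, "acceptor") not in sites and (11, "donor") not in sites
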
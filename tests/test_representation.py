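import math

import numpy as np
import pytest

import dendropy

from barcodegap.errors import DegenerateFitError, ValidationError
from barcodegap.markers import MarkerRegion
from barcodegap.records import TaxLevel
from barcodegap.representation import (
    CauchyFit,
    RepresentationFlag,
    annotate_phylogeny,
    cauchy_interval,
    classify_representation,
    fit_cauchy,
    priority_index,
    priority_table,
    proportion_deltas,
)

from conftest import mk_accession, mk_species

RBCL = MarkerRegion.RBCL


# ---------------------------------------------------------------------------
# proportion deltas

def test_deltas_direct_arithmetic():
    flora = [mk_species("Aus a", family="Xaceae"), mk_species("Aus b", family="Xaceae"),
             mk_species("Bus c", family="Yaceae"), mk_species("Bus d", family="Yaceae")]
    acc = [mk_accession("Aus a", RBCL), mk_accession("Aus b", RBCL)]
    deltas = {d.taxon: d.delta for d in proportion_deltas(flora, acc, TaxLevel.FAMILY)}
    assert deltas["Yaceae"] == pytest.approx(0.5)   # flora share 0.5, barcode share 0
    assert deltas["Xaceae"] == pytest.approx(-0.5)


def test_deltas_sum_to_zero(small_inputs):
    for level in (TaxLevel.FAMILY, TaxLevel.GENUS):
        deltas = proportion_deltas(small_inputs["checklist"],
                                   small_inputs["accessions"], level)
        assert sum(d.delta for d in deltas) == pytest.approx(0.0, abs=1e-12)


def test_deltas_need_barcoded_species():
    flora = [mk_species("Aus a"), mk_species("Bus b"), mk_species("Cus c")]
    with pytest.raises(ValidationError):
        proportion_deltas(flora, [], TaxLevel.FAMILY)


# ---------------------------------------------------------------------------
# Cauchy fit and intervals

def test_cauchy_symmetric_sample_centred():
    fit = fit_cauchy([-1.0, 0.0, 1.0])
    assert fit.location == pytest.approx(0.0, abs=1e-3)


def test_cauchy_degenerate_sample_rejected():
    with pytest.raises(DegenerateFitError):
        fit_cauchy([0.0, 0.0, 0.0])
    with pytest.raises(ValidationError):
        fit_cauchy([0.0, 1.0])


def test_cauchy_parameter_recovery_seeded():
    """MLE recovers (location, scale) of Cauchy(0.02, 0.005) at n=10,000."""
    rng = np.random.default_rng(20180101)
    x = 0.02 + 0.005 * rng.standard_cauchy(10_000)
    fit = fit_cauchy(x)
    assert fit.location == pytest.approx(0.02, abs=0.001)
    assert fit.scale == pytest.approx(0.005, rel=0.20)


def test_cauchy_interval_closed_form():
    fit = CauchyFit(location=0.0, scale=1.0, loglik=0.0)
    lo, hi = cauchy_interval(fit, 0.95)
    assert hi == pytest.approx(math.tan(0.475 * math.pi), abs=1e-4)
    assert hi == pytest.approx(12.7062, abs=1e-3) and lo == -hi
    lo90, hi90 = cauchy_interval(fit, 0.90)
    assert hi90 == pytest.approx(6.3138, abs=1e-3)
    with pytest.raises(ValidationError):
        cauchy_interval(fit, 1.5)


def test_cauchy_interval_location_scale_equivariance():
    base = CauchyFit(0.0, 1.0, 0.0)
    shifted = CauchyFit(0.3, 0.02, 0.0)
    lo0, hi0 = cauchy_interval(base, 0.95)
    lo1, hi1 = cauchy_interval(shifted, 0.95)
    assert lo1 == pytest.approx(0.3 + 0.02 * lo0)
    assert hi1 == pytest.approx(0.3 + 0.02 * hi0)


# ---------------------------------------------------------------------------
# flags

def _delta_fixture():
    from barcodegap.representation import RepresentationDelta
    rng = np.random.default_rng(5)
    values = 0.001 * rng.standard_cauchy(80)
    return [RepresentationDelta(f"T{i}", float(v)) for i, v in enumerate(values)]


def test_classification_tail_flags():
    deltas = _delta_fixture()
    fit = fit_cauchy([d.delta for d in deltas])
    flagged = classify_representation(deltas, fit)
    lo95, hi95 = cauchy_interval(fit, 0.95)
    lo90, hi90 = cauchy_interval(fit, 0.90)
    for d in flagged:
        if d.delta > hi95:
            assert d.flag is RepresentationFlag.STRONG_UNDER
        elif d.delta > hi90:
            assert d.flag is RepresentationFlag.UNDER
        elif d.delta < lo95:
            assert d.flag is RepresentationFlag.STRONG_OVER
        elif d.delta < lo90:
            assert d.flag is RepresentationFlag.OVER
        else:
            assert d.flag is RepresentationFlag.TYPICAL


def test_location_at_centre_is_typical():
    deltas = _delta_fixture()
    fit = fit_cauchy([d.delta for d in deltas])
    from barcodegap.representation import RepresentationDelta
    centred = classify_representation([RepresentationDelta("c", fit.location)], fit)
    assert centred[0].flag is RepresentationFlag.TYPICAL


def test_flags_shift_equivariant():
    """Adding a constant to all deltas and the fit location leaves flags fixed."""
    deltas = _delta_fixture()
    fit = fit_cauchy([d.delta for d in deltas])
    flags = [d.flag for d in classify_representation(deltas, fit)]
    from dataclasses import replace
    shift = 0.37
    shifted = [replace(d, delta=d.delta + shift) for d in deltas]
    fit2 = CauchyFit(fit.location + shift, fit.scale, fit.loglik)
    flags2 = [d.flag for d in classify_representation(shifted, fit2)]
    assert flags == flags2


def test_unsequenced_large_genera_flagged_under(small_config):
    """Genus-level run on a flora where the ten largest genera were left
    deliberately unsequenced: those genera must be flagged under."""
    from barcodegap.simulate import generate_checklist
    checklist = generate_checklist(small_config)
    sizes: dict[str, int] = {}
    for r in checklist:
        sizes[r.genus] = sizes.get(r.genus, 0) + 1
    big_ten = sorted(sizes, key=sizes.get, reverse=True)[:10]
    acc = [mk_accession(r.binomial, RBCL) for r in checklist
           if r.genus not in big_ten]
    deltas = proportion_deltas(checklist, acc, TaxLevel.GENUS)
    fit = fit_cauchy([d.delta for d in deltas])
    flagged = {d.taxon: d.flag for d in classify_representation(deltas, fit)}
    for g in big_ten:
        assert flagged[g] in (RepresentationFlag.UNDER,
                              RepresentationFlag.STRONG_UNDER)


# ---------------------------------------------------------------------------
# priority index

def _priority_flora():
    return [
        mk_species("Aus a", family="Faceae", threat="VU", dist="local_endemic"),
        mk_species("Aus b", family="Faceae", threat="EN", dist="non_endemic"),
        mk_species("Bus c", family="Faceae"),
        mk_species("Bus d", family="Faceae"),
        mk_species("Cus e", family="Gaceae", threat="CR", dist="local_endemic"),
    ]


def test_priority_fully_barcoded_family_is_zero():
    flora = _priority_flora()
    acc = [mk_accession(r.binomial, RBCL) for r in flora if r.family == "Faceae"]
    assert priority_index(flora, acc, "Faceae").P == 0.0


def test_priority_monospecific_maximum():
    """A monospecific family whose species is unbarcoded, threatened and
    locally endemic reaches the maximum P = 3."""
    flora = _priority_flora()
    score = priority_index(flora, [], "Gaceae")
    assert score.P == pytest.approx(3.0)


def test_priority_component_arithmetic():
    """4 species, 2 unbarcoded; 1 of 2 threatened unbarcoded; the only
    endemic is barcoded -> P = 0.5 + 0.5 + 0 = 1.0."""
    flora = _priority_flora()
    acc = [mk_accession("Aus a", RBCL), mk_accession("Bus c", RBCL)]
    s = priority_index(flora, acc, "Faceae")
    assert s.p_nobarcode == pytest.approx(0.5)   # b, d unbarcoded
    assert s.p_threat == pytest.approx(0.5)      # of {a(VU), b(EN)}, b unbarcoded
    assert s.p_endemic == pytest.approx(0.0)     # only endemic (a) is barcoded
    assert s.P == pytest.approx(1.0)


def test_priority_unknown_family():
    with pytest.raises(ValidationError):
        priority_index(_priority_flora(), [], "Nosuchaceae")


def test_priority_monotone_under_sequence_removal(small_inputs):
    """Removing a family's sequences never lowers its P."""
    cl, acc = small_inputs["checklist"], small_inputs["accessions"]
    fam = cl[0].family
    with_seqs = priority_index(cl, acc, fam).P
    fam_species = {r.binomial for r in cl if r.family == fam}
    pruned = [a for a in acc if a.species not in fam_species]
    assert priority_index(cl, pruned, fam).P >= with_seqs


def test_priority_table_ranked_with_alphabetical_ties(small_inputs):
    scores = priority_table(small_inputs["checklist"], small_inputs["accessions"])
    for a, b in zip(scores, scores[1:]):
        assert (-a.P, a.family) <= (-b.P, b.family)


# ---------------------------------------------------------------------------
# phylogeny annotation

def test_annotate_phylogeny_roundtrip():
    flora = _priority_flora()
    scores = priority_table(flora, [mk_accession("Aus a", RBCL)])
    newick = "(Faceae:1,(Gaceae:1,Haceae:1):1);"
    out, table, report = annotate_phylogeny(newick, scores)
    assert "[&P=" in out
    assert dict(table).keys() == {"Faceae", "Gaceae"}
    assert report.tips_missing_scores == ["Haceae"]
    assert report.families_missing_from_tree == []
    # output must stay parseable
    reparsed = dendropy.Tree.get(data=out, schema="newick")
    assert len(reparsed.leaf_nodes()) == 3


def test_annotate_phylogeny_plain_output():
    flora = _priority_flora()
    scores = priority_table(flora, [])
    out, _, _ = annotate_phylogeny("(Faceae:1,Gaceae:1);", scores, plain=True)
    assert "[&" not in out


def test_annotate_phylogeny_malformed_newick():
    with pytest.raises(ValidationError):
        annotate_phylogeny("(((", [])
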
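import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap.coverage import (
    aggregate_survey_coverage,
    pielou_evenness,
    marker_table,
    survey_coverage,
    taxon_coverage,
    venn_overlap,
)
from barcodegap.errors import ValidationError
from barcodegap.io import load_surveys
from barcodegap.markers import MarkerRegion
from barcodegap.names import parse_taxon_name
from barcodegap.records import CommunitySurvey, TaxLevel

from conftest import mk_accession, mk_species

RBCL, MATK, ITS = MarkerRegion.RBCL, MarkerRegion.MATK, MarkerRegion.ITS


# ---------------------------------------------------------------------------
# Pielou evenness

def shannon_brute_force(counts, S):
    """Independent oracle: direct loop over the Shannon sum."""
    total = sum(counts)
    H = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            H -= p * math.log(p)
    return H / math.log(S)


@pytest.mark.parametrize(
    "counts, S, expected",
    [
        ([3, 3, 3, 3], 4, 1.0),            # uniform allocation: maximum
        ([10, 0, 0, 0], 4, 0.0),           # single taxon: minimum
        ([5, 3, 2, 0], 4, 1.02965 / math.log(4)),  # hand-evaluated Shannon sum
    ],
)
def test_pielou_known_values(counts, S, expected):
    assert pielou_evenness(counts, S) == pytest.approx(expected, abs=1e-5)


def test_pielou_undefined_cases():
    assert pielou_evenness([5], 1) is None          # S < 2
    assert pielou_evenness([0, 0, 0], 3) is None    # no sequences
    with pytest.raises(ValidationError):
        pielou_evenness([-1, 2], 2)


@given(
    counts=st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=30),
    k=st.integers(min_value=1, max_value=7),
)
@settings(deadline=None, max_examples=200)
def test_pielou_matches_brute_force_and_invariances(counts, k):
    """J equals the brute-force Shannon computation, is permutation-
    invariant, and is scale-invariant in the counts."""
    S = len(counts)
    j = pielou_evenness(counts, S)
    if sum(counts) == 0:
        assert j is None
        return
    assert j == pytest.approx(shannon_brute_force(counts, S), abs=1e-12)
    assert 0.0 <= j <= 1.0 + 1e-12
    perm = list(reversed(counts))
    assert pielou_evenness(perm, S) == pytest.approx(j, abs=1e-12)
    scaled = [c * k for c in counts]
    assert pielou_evenness(scaled, S) == pytest.approx(j, abs=1e-12)


# ---------------------------------------------------------------------------
# taxon coverage

def _tiny_flora():
    return [
        mk_species("Aus alpha", family="Aaceae"),
        mk_species("Aus beta", family="Aaceae"),
        mk_species("Bus gamma", family="Baceae"),
        mk_species("Cus delta", family="Caceae"),
    ]


def test_taxon_coverage_counts_and_rounding():
    flora = _tiny_flora()
    acc = [mk_accession("Aus alpha", RBCL), mk_accession("Bus gamma", MATK)]
    r = taxon_coverage(flora, acc, TaxLevel.SPECIES)
    assert (r.covered, r.total) == (2, 4) and r.percent == 50
    g = taxon_coverage(flora, acc, TaxLevel.GENUS)
    assert (g.covered, g.total) == (2, 3)
    f = taxon_coverage(flora, acc, TaxLevel.FAMILY)
    assert (f.covered, f.total) == (2, 3)
    assert taxon_coverage(flora, [], TaxLevel.SPECIES).proportion == 0.0
    with pytest.raises(ValidationError):
        taxon_coverage([], acc)


def test_coverage_monotone_under_added_accession():
    """Covering a previously uncovered taxon never lowers any proportion."""
    flora = _tiny_flora()
    acc = [mk_accession("Aus alpha", RBCL)]
    before = {lv: taxon_coverage(flora, acc, lv).proportion for lv in TaxLevel}
    acc.append(mk_accession("Cus delta", ITS))
    after = {lv: taxon_coverage(flora, acc, lv).proportion for lv in TaxLevel}
    for lv in TaxLevel:
        assert after[lv] >= before[lv]


def test_marker_table_conserves_sequences(small_inputs):
    """Per-marker sequence counts sum to the independently tallied total of
    resolved barcode accessions."""
    rows = marker_table(small_inputs["checklist"], small_inputs["accessions"])
    assert len(rows) == 10
    independent_total = sum(
        1 for a in small_inputs["accessions"] if a.resolved and a.is_barcode)
    assert sum(r["n_sequences"] for r in rows) == independent_total
    for r in rows:
        if r["n_sequences"] == 0:
            assert r["n_species"] == 0 and r["J_species"] is None


def test_marker_table_species_counts():
    flora = _tiny_flora()
    acc = [mk_accession("Aus alpha", RBCL), mk_accession("Aus beta", RBCL),
           mk_accession("Aus beta", MATK)]
    rows = {r["marker"]: r for r in marker_table(flora, acc)}
    assert rows["rbcL"]["n_species"] == 2
    assert rows["matK"]["n_species"] == 1


# ---------------------------------------------------------------------------
# Venn overlaps

def brute_force_venn(sets):
    """Oracle: enumerate every membership pattern over the union."""
    union = set().union(*sets)
    out = {}
    for pattern in product([True, False], repeat=len(sets)):
        if not any(pattern):
            continue
        n = 0
        for sp in union:
            if all((sp in s) == inc for s, inc in zip(sets, pattern)):
                n += 1
        out[pattern] = n
    return out


def test_venn_small_example():
    flora = [mk_species(b) for b in ("Aus a", "Aus b", "Aus c")]
    acc = [mk_accession("Aus a", RBCL), mk_accession("Aus b", RBCL),
           mk_accession("Aus b", MATK), mk_accession("Aus c", MATK)]
    v = venn_overlap(flora, acc, [RBCL, MATK])
    assert v.regions[(True, False)] == 1
    assert v.regions[(False, True)] == 1
    assert v.regions[(True, True)] == 1
    assert v.union == 3 and v.intersection == 1


def test_venn_rejects_bad_requests():
    flora = [mk_species("Aus a")]
    with pytest.raises(ValidationError):
        venn_overlap(flora, [], [RBCL, RBCL])
    with pytest.raises(ValidationError):
        venn_overlap(flora, [], [RBCL])


def test_venn_matches_brute_force_enumeration():
    """Random 3-marker library on 100 species: disjoint regions equal the
    brute-force membership enumeration and partition the union."""
    rng = np.random.default_rng(7)
    flora = [mk_species(f"Gen{i:03d} sp{i:03d}") for i in range(100)]
    markers = [RBCL, MATK, ITS]
    acc = []
    for r in flora:
        for m in markers:
            if rng.random() < 0.4:
                acc.append(mk_accession(r.binomial, m))
    v = venn_overlap(flora, acc, markers)
    sets = [{a.species for a in acc if a.marker is m} for m in markers]
    oracle = brute_force_venn(sets)
    assert v.regions == oracle
    assert sum(v.regions.values()) == v.union


# ---------------------------------------------------------------------------
# survey coverage

def _survey(rows):
    return CommunitySurvey(
        survey_id="S", records=[(parse_taxon_name(t), n) for t, n in rows])


def test_survey_coverage_direct_ratio():
    flora = [mk_species("Aus alpha"), mk_species("Bus beta")]
    acc = [mk_accession("Aus alpha", RBCL)]
    sc = survey_coverage(_survey([("Aus alpha", 60), ("Bus beta", 40)]),
                         flora, acc, TaxLevel.SPECIES)
    assert sc.proportion_covered == pytest.approx(0.60)
    sc_all = survey_coverage(_survey([("Aus alpha", 10)]), flora, acc)
    assert sc_all.proportion_covered == 1.0


def test_aff_records_count_only_at_genus_level():
    """'Ocotea aff. puberula' is excluded from the species-level numerator
    even though O. puberula is barcoded, but counts at genus level."""
    flora = [mk_species("Ocotea puberula"), mk_species("Aus alpha")]
    acc = [mk_accession("Ocotea puberula", RBCL), mk_accession("Aus alpha", RBCL)]
    survey = _survey([("Ocotea aff. puberula", 10), ("Aus alpha", 10)])
    sp = survey_coverage(survey, flora, acc, TaxLevel.SPECIES)
    assert sp.proportion_covered == pytest.approx(0.5)
    assert sp.proportion_unidentified == pytest.approx(0.5)
    gen = survey_coverage(survey, flora, acc, TaxLevel.GENUS)
    assert gen.proportion_covered == pytest.approx(1.0)


def test_cf_records_resolve_to_suggested_species():
    flora = [mk_species("Eugenia pyriformis")]
    acc = [mk_accession("Eugenia pyriformis", RBCL)]
    sc = survey_coverage(_survey([("Eugenia cf. pyriformis", 5)]), flora, acc)
    assert sc.proportion_covered == 1.0


def test_zero_individual_survey_rejected():
    flora = [mk_species("Aus alpha")]
    with pytest.raises(ValidationError):
        survey_coverage(CommunitySurvey("S", []), flora, [])


def test_survey_coverage_monotone_in_level(small_inputs):
    """Coarser matching only adds individuals: family >= genus >= species."""
    cl, acc = small_inputs["checklist"], small_inputs["accessions"]
    for s in small_inputs["surveys"]:
        p_sp = survey_coverage(s, cl, acc, TaxLevel.SPECIES).proportion_covered
        p_ge = survey_coverage(s, cl, acc, TaxLevel.GENUS).proportion_covered
        p_fa = survey_coverage(s, cl, acc, TaxLevel.FAMILY).proportion_covered
        assert p_fa >= p_ge >= p_sp


# ---------------------------------------------------------------------------
# aggregation

def _cov(p):
    from barcodegap.coverage import SurveyCoverage
    return SurveyCoverage("s", TaxLevel.SPECIES, p, 0.0)


def test_aggregate_descriptives():
    s = aggregate_survey_coverage([_cov(0.6), _cov(0.8), _cov(1.0)], n_boot=500)
    assert s.mean == pytest.approx(0.8)
    assert s.median == pytest.approx(0.8)
    assert (s.min, s.max) == (0.6, 1.0)
    assert s.min <= s.median <= s.max


def test_aggregate_single_survey_degenerate_ci():
    s = aggregate_survey_coverage([_cov(0.91)], n_boot=200)
    assert s.mean == s.median == s.ci_low == s.ci_high == pytest.approx(0.91)


def test_aggregate_empty_rejected():
    with pytest.raises(ValidationError):
        aggregate_survey_coverage([])


def test_bootstrap_ci_covers_true_mean():
    """Surveys drawn around a true mean coverage of 0.89: the seeded
    percentile bootstrap CI contains the truth in >=90% of replications."""
    true_mean = 0.89
    hits = 0
    reps = 20
    for rep in range(reps):
        rng = np.random.default_rng(1000 + rep)
        # Beta with mean 0.89 and realistic between-survey spread
        a, b = 20 * true_mean, 20 * (1 - true_mean)
        props = rng.beta(a, b, size=135)
        s = aggregate_survey_coverage([_cov(p) for p in props],
                                      n_boot=2000, seed=rep)
        if s.ci_low <= true_mean <= s.ci_high:
            hits += 1
    assert hits >= 0.9 * reps
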
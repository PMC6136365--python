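"""Seeded generators for synthetic checklist, accession, survey and
phylogeny inputs.

The defaults emulate a species-rich regional tree flora and its barcode
library: 2,097 species in 508 genera, 107 families and 36 orders; 227
threatened species; 237 local and 493 regional endemics; 12,104 barcode
accessions whose quarterly totals grow exponentially (rate 0.063 per
trimester) from late 1993, with a heavily skewed per-species allocation
(a few species exceed 500 sequences); and 135 community surveys with
lognormal species-abundance distributions.

Species-level barcode coverage is induced per distribution class
(widespread species best covered, local endemics worst), and within each
class the *abundant* species are preferentially covered — herbaria and
sequencing campaigns sample common species first — which is what makes
individual-weighted survey coverage far exceed species-level coverage.

All generators are fully deterministic under the config seed.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .markers import MarkerRegion
from .records import DistributionClass, GrowthForm, SpeciesRecord, ThreatClass

# ---------------------------------------------------------------------------
# configuration

#: GenBank-like marker frequencies among barcode accessions (shares of the
#: ten regions; ITS, rbcL, psbA-trnH, matK and trnL dominate).
DEFAULT_MARKER_PROBS = {
    MarkerRegion.ITS: 0.279,
    MarkerRegion.RBCL: 0.199,
    MarkerRegion.PSBA_TRNH: 0.189,
    MarkerRegion.MATK: 0.169,
    MarkerRegion.TRNL: 0.128,
    MarkerRegion.RPOC1: 0.0141,
    MarkerRegion.RPOB: 0.0102,
    MarkerRegion.ATPF_ATPH: 0.0061,
    MarkerRegion.PSBK_PSBI: 0.0055,
    MarkerRegion.YCF1: 0.0020,
}

#: Marker mix for the local sequencing campaign (rbcL/matK for all
#: families, ITS for recalcitrant groups).
LOCAL_MARKER_PROBS = {
    MarkerRegion.RBCL: 0.56,
    MarkerRegion.MATK: 0.365,
    MarkerRegion.ITS: 0.075,
}


@dataclass
class SyntheticConfig:
    """Generating parameters; the defaults are the study conditions."""

    seed: int = 0
    n_species: int = 2097
    n_genera: int = 508
    n_families: int = 107
    n_orders: int = 36
    frac_threatened: float = 227 / 2097
    frac_local_endemic: float = 237 / 2097
    frac_regional_endemic: float = 493 / 2097
    frac_eastern_endemic: float = 0.30
    #: species-level barcode coverage per distribution class
    coverage_by_class: dict = field(default_factory=lambda: {
        DistributionClass.NON_ENDEMIC: 0.74,
        DistributionClass.EASTERN_SA_ENDEMIC: 0.62,
        DistributionClass.REGIONAL_ENDEMIC: 0.42,
        DistributionClass.LOCAL_ENDEMIC: 0.30,
    })
    n_accessions: int = 12104
    #: fraction of accessions from the local sequencing campaign
    local_fraction: float = 1611 / 12104
    growth_rate_per_trimester: float = 0.063
    start_date: dt.date = dt.date(1993, 12, 1)
    genbank_end_date: dt.date = dt.date(2015, 12, 31)
    local_batch_date: dt.date = dt.date(2016, 1, 16)
    #: Zipf exponent for per-species sequence allocation (0.9 puts the top
    #: species above 500 sequences at the default accession total)
    allocation_skew: float = 0.9
    #: within-class preference for covering abundant species
    #: (selection weight = abundance ** abundance_bias); the default puts
    #: the expected individual-weighted survey coverage near 0.89
    abundance_bias: float = 0.8
    n_surveys: int = 135
    individuals_per_survey: int = 2000
    abundance_sigma: float = 1.5
    #: between-survey lognormal noise on species abundances
    survey_sigma: float = 0.75
    #: fraction of survey records carrying aff./sp. qualifiers
    qualifier_fraction: float = 0.015
    #: fraction of accession taxon labels deliberately corrupted
    misspelling_fraction: float = 0.0

    def validate(self) -> None:
        if not (self.n_species >= self.n_genera >= self.n_families >= self.n_orders >= 1):
            raise ValidationError("taxon counts must nest: species >= genera >= families >= orders")
        fr = (self.frac_local_endemic + self.frac_regional_endemic
              + self.frac_eastern_endemic)
        if fr > 1.0:
            raise ValidationError("endemism fractions sum above 1")
        for name in ("frac_threatened", "frac_local_endemic",
                     "frac_regional_endemic", "frac_eastern_endemic",
                     "local_fraction", "qualifier_fraction", "misspelling_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.genbank_end_date <= self.start_date:
            raise ValidationError("genbank_end_date must be after start_date")
        if self.individuals_per_survey < 1:
            raise ValidationError("individuals_per_survey must be >= 1")
        if self.abundance_sigma <= 0 or self.allocation_skew <= 0:
            raise ValidationError("abundance_sigma and allocation_skew must be positive")


# ---------------------------------------------------------------------------
# deterministic pseudo-Latin name factory

_SYL1 = ["Myr", "Oco", "Eug", "Tab", "Cro", "Sola", "Psy", "Mico", "Ing",
         "Cec", "Fic", "Neo", "Cal", "Hand", "Vir", "Xylo", "Zan", "Gua",
         "Lon", "Pip", "Rau", "Sap", "Ter", "Vit", "Al", "Bra", "Cam"]
_SYL2 = ["ci", "ro", "ta", "be", "do", "lu", "mi", "na", "pe", "qui", "ra",
         "se", "ti", "vo", "xa", "ze", "ga", "he", "jo", "ko"]
_SYL3 = ["nia", "dora", "carpus", "phyllum", "anthus", "ria", "sia", "tia",
         "lea", "mea", "nthera", "begia", "chys", "ndra", "psis", "stigma"]
_EP1 = ["al", "bi", "cor", "den", "el", "fla", "gra", "hir", "in", "la",
        "ma", "ni", "ob", "pu", "ru", "sub", "to", "ve", "au", "cam"]
_EP2 = ["ba", "ci", "da", "fo", "gi", "li", "mo", "nu", "pe", "ri", "se",
        "tu", "va", "xi"]
_EP3 = ["tum", "ris", "flora", "folia", "carpa", "cens", "osa", "ana",
        "ata", "ila", "ense", "oides", "ula", "ifera"]


def _alpha_suffix(k: int) -> str:
    """0 -> 'a', 1 -> 'b', ..., 26 -> 'aa', ... (letters only)."""
    out = []
    k += 1
    while k > 0:
        k, rem = divmod(k - 1, 26)
        out.append(chr(ord("a") + rem))
    return "".join(reversed(out))


def _unique_names(rng: np.random.Generator, n: int,
                  parts: list[list[str]], suffix: str = "") -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        name = "".join(p[rng.integers(len(p))] for p in parts) + suffix
        k = 0
        while name in seen:  # deterministic de-collision, letters only
            name = f"{name}{_alpha_suffix(k)}"
            k += 1
        seen.add(name)
        names.append(name)
    return names


def _zipf_partition(rng: np.random.Generator, n_items: int, n_groups: int,
                    exponent: float = 1.1) -> np.ndarray:
    """Sizes (each >= 1, summing to n_items) for a Zipf-skewed partition;
    group order is shuffled so size is independent of label order."""
    if n_items < n_groups:
        raise ValidationError("cannot partition fewer items than groups")
    w = 1.0 / np.arange(1, n_groups + 1) ** exponent
    extra = rng.multinomial(n_items - n_groups, w / w.sum())
    sizes = 1 + extra
    rng.shuffle(sizes)
    return sizes


# ---------------------------------------------------------------------------
# generators

def generate_checklist(config: SyntheticConfig) -> list[SpeciesRecord]:
    """Synthetic species checklist with nested Zipf-skewed taxonomy and
    exact-quota threat/endemism composition."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    order_names = _unique_names(rng, config.n_orders, [_SYL1, _SYL2], "ales")
    family_names = _unique_names(rng, config.n_families, [_SYL1, _SYL2], "aceae")
    genus_names = _unique_names(rng, config.n_genera, [_SYL1, _SYL2, _SYL3])
    epithets = _unique_names(rng, config.n_species, [_EP1, _EP2, _EP3])
    epithets = [e.lower() for e in epithets]

    fam_per_order = _zipf_partition(rng, config.n_families, config.n_orders)
    gen_per_family = _zipf_partition(rng, config.n_genera, config.n_families)
    sp_per_genus = _zipf_partition(rng, config.n_species, config.n_genera)

    family_order: dict[str, str] = {}
    i = 0
    for o, k in zip(order_names, fam_per_order):
        for f in family_names[i:i + k]:
            family_order[f] = o
        i += k
    genus_family: dict[str, str] = {}
    i = 0
    for f, k in zip(family_names, gen_per_family):
        for g in genus_names[i:i + k]:
            genus_family[g] = f
        i += k

    n = config.n_species
    # exact-quota composition draws
    perm = rng.permutation(n)
    n_threat = round(config.frac_threatened * n)
    threatened = np.zeros(n, dtype=bool)
    threatened[perm[:n_threat]] = True
    threat_pool = [ThreatClass.VU, ThreatClass.EN, ThreatClass.CR,
                   ThreatClass.EW, ThreatClass.EX]
    threat_codes = rng.choice(len(threat_pool), size=n,
                              p=[0.55, 0.30, 0.12, 0.02, 0.01])
    safe_pool = [ThreatClass.LC, ThreatClass.NT, ThreatClass.DD, ThreatClass.NONE]
    safe_codes = rng.choice(len(safe_pool), size=n, p=[0.55, 0.10, 0.10, 0.25])

    perm2 = rng.permutation(n)
    n_local = round(config.frac_local_endemic * n)
    n_regional = round(config.frac_regional_endemic * n)
    n_eastern = round(config.frac_eastern_endemic * n)
    dist = np.empty(n, dtype=object)
    dist[:] = DistributionClass.NON_ENDEMIC
    dist[perm2[:n_local]] = DistributionClass.LOCAL_ENDEMIC
    dist[perm2[n_local:n_local + n_regional]] = DistributionClass.REGIONAL_ENDEMIC
    dist[perm2[n_local + n_regional:n_local + n_regional + n_eastern]] = \
        DistributionClass.EASTERN_SA_ENDEMIC

    growth_pool = list(GrowthForm)
    growth = rng.choice(len(growth_pool), size=n,
                        p=[0.80, 0.13, 0.02, 0.01, 0.005, 0.015, 0.02])
    naturalized = rng.random(n) < 55 / 2097

    records: list[SpeciesRecord] = []
    idx = 0
    for g, k in zip(genus_names, sp_per_genus):
        fam = genus_family[g]
        for _ in range(k):
            records.append(SpeciesRecord(
                binomial=f"{g} {epithets[idx]}",
                genus=g,
                family=fam,
                order=family_order[fam],
                growth_form=growth_pool[growth[idx]],
                naturalized=bool(naturalized[idx]),
                threat_class=threat_pool[threat_codes[idx]] if threatened[idx]
                else safe_pool[safe_codes[idx]],
                distribution_class=dist[idx],
            ))
            idx += 1
    return records


def draw_abundances(checklist: list[SpeciesRecord],
                    config: SyntheticConfig) -> pd.Series:
    """Lognormal regional relative abundances, one weight per species."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    w = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=len(checklist))
    return pd.Series(w, index=[r.binomial for r in checklist], name="abundance")


def select_barcoded_species(
    checklist: list[SpeciesRecord],
    config: SyntheticConfig,
    abundances: pd.Series,
) -> set[str]:
    """Species that will hold >=1 barcode sequence.

    Within each distribution class an exact quota (coverage * class size)
    is selected by weighted sampling without replacement with weight
    ``abundance ** abundance_bias`` (Efraimidis-Spirakis keys), so common
    species are covered preferentially.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    chosen: set[str] = set()
    for cls, frac in config.coverage_by_class.items():
        members = [r.binomial for r in checklist if r.distribution_class is cls]
        k = round(frac * len(members))
        if k == 0 or not members:
            continue
        w = abundances.loc[members].to_numpy() ** config.abundance_bias
        keys = rng.random(len(members)) ** (1.0 / w)
        order = np.argsort(-keys)
        chosen.update(members[i] for i in order[:k])
    return chosen


def generate_accessions(
    checklist: list[SpeciesRecord],
    config: SyntheticConfig,
    abundances: Optional[pd.Series] = None,
    barcoded: Optional[set[str]] = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Accession metadata table with exponential submission growth and a
    Zipf-skewed per-species sequence allocation.

    Every selected species receives at least one sequence; quarterly
    cumulative totals follow ``exp(growth_rate * t)`` between start and
    end dates; the local-campaign batch is pinned to its fixed date.
    Returns the table and the barcoded-species set actually used.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    if abundances is None:
        abundances = draw_abundances(checklist, config)
    if barcoded is None:
        barcoded = select_barcoded_species(checklist, config, abundances)
    species = sorted(barcoded)
    if not species:
        raise ValidationError("no barcoded species selected")
    if config.n_accessions < len(species):
        raise ValidationError("n_accessions smaller than the barcoded-species set")

    # one guaranteed sequence each, remainder Zipf over a random species order
    ranks = rng.permutation(len(species)) + 1
    w = 1.0 / ranks.astype(float) ** config.allocation_skew
    extra = rng.multinomial(config.n_accessions - len(species), w / w.sum())
    counts = 1 + extra
    slots = np.repeat(np.arange(len(species)), counts)
    rng.shuffle(slots)

    n_total = config.n_accessions
    n_local = round(config.local_fraction * n_total)
    is_local = np.zeros(n_total, dtype=bool)
    is_local[:n_local] = True  # slots are shuffled, so this is a random subset

    # GenBank dates: density proportional to exp(r t) over the study window
    r = config.growth_rate_per_trimester
    T = (config.genbank_end_date - config.start_date).days / 91.3125  # trimesters
    u = rng.random(n_total)
    if abs(r) < 1e-12:
        tq = u * T
    else:
        tq = np.log1p(u * np.expm1(r * T)) / r
    gb_dates = [config.start_date + dt.timedelta(days=float(t) * 91.3125)
                for t in tq]

    gb_markers = list(DEFAULT_MARKER_PROBS)
    gb_p = np.array(list(DEFAULT_MARKER_PROBS.values()))
    gb_p = gb_p / gb_p.sum()
    loc_markers = list(LOCAL_MARKER_PROBS)
    loc_p = np.array(list(LOCAL_MARKER_PROBS.values()))
    loc_p = loc_p / loc_p.sum()
    gb_pick = rng.choice(len(gb_markers), size=n_total, p=gb_p)
    loc_pick = rng.choice(len(loc_markers), size=n_total, p=loc_p)

    misspell = rng.random(n_total) < config.misspelling_fraction

    rows = []
    for i in range(n_total):
        sp = species[slots[i]]
        taxon = sp + "x" if misspell[i] else sp
        if is_local[i]:
            marker = loc_markers[loc_pick[i]]
            date = config.local_batch_date
            source = "local_study"
        else:
            marker = gb_markers[gb_pick[i]]
            date = min(gb_dates[i], config.genbank_end_date)
            source = "genbank"
        rows.append((f"SYN{i + 1:07d}", taxon, marker.value,
                     date.isoformat(), source))
    df = pd.DataFrame(rows, columns=["accession_id", "taxon", "marker",
                                     "submission_date", "source"])
    return df, barcoded


def generate_surveys(
    checklist: list[SpeciesRecord],
    barcoded: set[str],
    config: SyntheticConfig,
    abundances: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, dict]:
    """Long-format community-survey table.

    Each survey draws a multinomial sample of individuals over the species
    pool with per-survey lognormal perturbations of the regional
    abundances; a small fraction of records carries aff./sp. qualifiers.
    The analytic expectation of individual-weighted coverage (the barcoded
    species' share of total abundance mass) is computed and the realized
    mean across surveys is checked against it (within 0.03).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    if abundances is None:
        abundances = draw_abundances(checklist, config)
    binomials = [r.binomial for r in checklist]
    w = abundances.loc[binomials].to_numpy()
    covered_mask = np.array([b in barcoded for b in binomials])
    expected_coverage = float(w[covered_mask].sum() / w.sum())

    rows = []
    realized = []
    for s in range(config.n_surveys):
        v = w * rng.lognormal(0.0, config.survey_sigma, size=len(w))
        counts = rng.multinomial(config.individuals_per_survey, v / v.sum())
        present = np.nonzero(counts)[0]
        realized.append(counts[covered_mask].sum() / counts.sum())
        sid = f"SURV{s + 1:03d}"
        for i in present:
            genus, epithet = binomials[i].split(" ", 1)
            u = rng.random()
            if u < config.qualifier_fraction / 2:
                taxon = f"{genus} aff. {epithet}"
            elif u < config.qualifier_fraction:
                taxon = f"{genus} sp."
            else:
                taxon = binomials[i]
            rows.append((sid, taxon, int(counts[i])))
    df = pd.DataFrame(rows, columns=["survey_id", "taxon", "count"])
    realized_mean = float(np.mean(realized))
    info = {
        "expected_individual_coverage": expected_coverage,
        "realized_individual_coverage": realized_mean,
    }
    if abs(realized_mean - expected_coverage) > 0.03:
        raise ValidationError(
            f"realized survey coverage {realized_mean:.3f} deviates from the "
            f"analytic expectation {expected_coverage:.3f} by more than 0.03"
        )
    return df, info


def generate_family_tree(checklist: list[SpeciesRecord],
                         config: SyntheticConfig) -> str:
    """Random fully resolved family-level topology in Newick, tips =
    checklist families, unit branch lengths."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6]))
    families = sorted({r.family for r in checklist})
    nodes = list(families)
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a}:1,{b}:1)")
    return nodes[0] + ";"


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    checklist: list[SpeciesRecord]
    abundances: pd.Series
    barcoded: set[str]
    accessions: pd.DataFrame
    surveys: pd.DataFrame
    survey_info: dict
    tree_newick: str


def generate_bundle(config: Optional[SyntheticConfig] = None) -> SyntheticBundle:
    """Generate all four inputs with shared abundance structure."""
    config = config or SyntheticConfig()
    checklist = generate_checklist(config)
    abundances = draw_abundances(checklist, config)
    barcoded = select_barcoded_species(checklist, config, abundances)
    accessions, barcoded = generate_accessions(checklist, config, abundances, barcoded)
    surveys, info = generate_surveys(checklist, barcoded, config, abundances)
    tree = generate_family_tree(checklist, config)
    return SyntheticBundle(config, checklist, abundances, barcoded,
                           accessions, surveys, info, tree)


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict[str, Path]:
    """Write checklist.csv, accessions.csv, surveys.csv, families.nwk and
    truth.json (the generating parameters, for recovery tests)."""
    from .io import write_checklist

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "checklist": out / "checklist.csv",
        "accessions": out / "accessions.csv",
        "surveys": out / "surveys.csv",
        "tree": out / "families.nwk",
        "truth": out / "truth.json",
    }
    write_checklist(bundle.checklist, paths["checklist"])
    bundle.accessions.to_csv(paths["accessions"], index=False)
    bundle.surveys.to_csv(paths["surveys"], index=False)
    paths["tree"].write_text(bundle.tree_newick + "\n")
    truth = asdict(bundle.config)
    truth["coverage_by_class"] = {k.value: v for k, v in
                                  bundle.config.coverage_by_class.items()}
    for key in ("start_date", "genbank_end_date", "local_batch_date"):
        truth[key] = truth[key].isoformat()
    truth["n_barcoded_species"] = len(bundle.barcoded)
    truth.update(bundle.survey_info)
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
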
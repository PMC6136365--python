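"""Reference-library coverage, evenness, marker overlap and
abundance-weighted survey coverage.

A taxon (species, genus, family or order) is *covered* when at least one
resolved accession for a marker in the chosen set maps into it.  Library
coverage is the fraction of covered taxa; survey coverage weights species
by their abundance in tree-community surveys, which is the quantity that
determines whether DNA-based identification is usable in practice.

Pielou's evenness ``J = (-sum p_i ln p_i) / ln S`` measures how evenly a
marker's sequences are spread across the ``S`` taxa at a level (``p_i`` =
the share of the marker's sequences held by taxon ``i``); J = 1 is a
perfectly even allocation.  All ``S`` checklist taxa enter the
denominator, including those with zero sequences (with ``0 ln 0 := 0``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ValidationError
from .markers import ALL_MARKERS, MarkerRegion
from .names import MatchLevel, Qualifier
from .records import (
    AccessionRecord,
    CommunitySurvey,
    SpeciesRecord,
    TaxLevel,
    UNRESOLVED,
)

_LEVEL_ATTR = {
    TaxLevel.SPECIES: "binomial",
    TaxLevel.GENUS: "genus",
    TaxLevel.FAMILY: "family",
    TaxLevel.ORDER: "order",
}


@dataclass(frozen=True)
class CoverageResult:
    level: TaxLevel
    covered: int
    total: int

    @property
    def proportion(self) -> float:
        return self.covered / self.total

    @property
    def percent(self) -> int:
        """Whole-percent report rounding."""
        return round(100 * self.proportion)


@dataclass(frozen=True)
class EvennessResult:
    marker: MarkerRegion
    level: TaxLevel
    J: Optional[float]
    S: int
    n_sequences: int


@dataclass(frozen=True)
class SurveyCoverage:
    survey_id: str
    level: TaxLevel
    proportion_covered: float
    proportion_unidentified: float


@dataclass(frozen=True)
class CoverageSummary:
    mean: float
    median: float
    ci_low: float
    ci_high: float
    min: float
    max: float
    n_surveys: int


def _barcoded_species(
    accessions: Iterable[AccessionRecord],
    markers: Sequence[MarkerRegion],
    checklist_binomials: set[str],
) -> set[str]:
    mset = set(markers)
    return {
        a.species
        for a in accessions
        if a.species != UNRESOLVED and a.marker in mset and a.species in checklist_binomials
    }


def barcoded_species_set(
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
    markers: Sequence[MarkerRegion] = ALL_MARKERS,
) -> set[str]:
    """Checklist species holding >=1 resolved sequence of the given markers."""
    return _barcoded_species(accessions, markers, {r.binomial for r in checklist})


def taxon_coverage(
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
    level: TaxLevel = TaxLevel.SPECIES,
    markers: Sequence[MarkerRegion] = ALL_MARKERS,
) -> CoverageResult:
    """Fraction of taxa at `level` with at least one barcode sequence."""
    if not checklist:
        raise ValidationError("empty checklist")
    attr = _LEVEL_ATTR[level]
    total = {getattr(r, attr) for r in checklist}
    covered_species = barcoded_species_set(checklist, accessions, markers)
    by_binomial = {r.binomial: r for r in checklist}
    covered = {getattr(by_binomial[s], attr) for s in covered_species}
    return CoverageResult(level=level, covered=len(covered), total=len(total))


def pielou_evenness(counts_by_taxon: Sequence[float], S: int) -> Optional[float]:
    """Pielou's J for a vector of per-taxon sequence counts.

    ``counts_by_taxon`` may omit trailing zero taxa (``len(counts) <= S``);
    missing taxa count as zeros.  Returns ``None`` when J is undefined
    (fewer than two taxa, or no sequences at all).
    """
    counts = np.asarray(counts_by_taxon, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("negative sequence count")
    if len(counts) > S:
        raise ValidationError(f"{len(counts)} counts for S={S} taxa")
    total = counts.sum()
    if S < 2 or total == 0:
        return None
    p = counts[counts > 0] / total
    H = float(-(p * np.log(p)).sum())
    return H / np.log(S)


def marker_table(
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
) -> list[dict]:
    """Per-marker summary: sequence and species counts, species percentage
    of the checklist, and Pielou J at family/genus/species level.

    One row per marker region, including zero rows for unused markers; the
    sequence counts across rows sum to the total of resolved barcode
    accessions.
    """
    accessions = list(accessions)
    binomials = {r.binomial for r in checklist}
    by_binomial = {r.binomial: r for r in checklist}
    n_species_total = len(binomials)
    totals = {
        TaxLevel.FAMILY: len({r.family for r in checklist}),
        TaxLevel.GENUS: len({r.genus for r in checklist}),
        TaxLevel.SPECIES: n_species_total,
    }
    rows = []
    for marker in ALL_MARKERS:
        recs = [
            a for a in accessions
            if a.marker is marker and a.species != UNRESOLVED and a.species in binomials
        ]
        species = {a.species for a in recs}
        row = {
            "marker": marker.value,
            "n_sequences": len(recs),
            "n_species": len(species),
            "species_pct": 100.0 * len(species) / n_species_total,
        }
        for level in (TaxLevel.FAMILY, TaxLevel.GENUS, TaxLevel.SPECIES):
            attr = _LEVEL_ATTR[level]
            counts: dict[str, int] = {}
            for a in recs:
                key = getattr(by_binomial[a.species], attr)
                counts[key] = counts.get(key, 0) + 1
            row[f"J_{level.value}"] = pielou_evenness(list(counts.values()), totals[level])
        rows.append(row)
    return rows


@dataclass(frozen=True)
class VennResult:
    """Disjoint-region species counts for a 2- or 3-marker overlap."""

    markers: tuple[MarkerRegion, ...]
    #: pattern (bool per marker, at least one True) -> species count
    regions: dict[tuple[bool, ...], int]
    union: int
    intersection: int
    intersection_pct: float  # of the whole checklist


def venn_overlap(
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
    markers: Sequence[MarkerRegion],
) -> VennResult:
    """Species-set Venn decomposition for 2 or 3 markers.

    Region counts are over disjoint membership patterns and sum to the
    union; the all-markers intersection is also reported as a percentage
    of the checklist (the "rbcL+matK (33%)" style statistic).
    """
    markers = tuple(markers)
    if len(set(markers)) != len(markers):
        raise ValidationError("duplicate markers in Venn request")
    if not 2 <= len(markers) <= 3:
        raise ValidationError("venn_overlap needs 2 or 3 markers")
    accessions = list(accessions)
    binomials = {r.binomial for r in checklist}
    sets = [_barcoded_species(accessions, [m], binomials) for m in markers]
    regions: dict[tuple[bool, ...], int] = {}
    for pattern in product([True, False], repeat=len(markers)):
        if not any(pattern):
            continue
        members = set.intersection(
            *(s for s, inc in zip(sets, pattern) if inc)
        ) if any(pattern) else set()
        for s, inc in zip(sets, pattern):
            if not inc:
                members = members - s
        regions[pattern] = len(members)
    union = len(set.union(*sets))
    intersection = len(set.intersection(*sets))
    return VennResult(
        markers=markers,
        regions=regions,
        union=union,
        intersection=intersection,
        intersection_pct=100.0 * intersection / len(binomials),
    )


def survey_coverage(
    survey: CommunitySurvey,
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
    level: TaxLevel = TaxLevel.SPECIES,
    markers: Sequence[MarkerRegion] = ALL_MARKERS,
) -> SurveyCoverage:
    """Proportion of a survey's individuals belonging to covered taxa.

    Matching rules: *cf.* records resolve to the suggested species; *aff.*
    and *sp.* records are usable only from genus level up; family-level
    determinations only at family level.  Individuals not identifiable at
    the requested level stay in the denominator (so species-level coverage
    is, if anything, underestimated) and are reported as
    ``proportion_unidentified``.
    """
    if level is TaxLevel.ORDER:
        raise ValidationError("survey coverage is defined at species/genus/family level")
    total = survey.total_individuals
    if total <= 0:
        raise ValidationError(f"survey {survey.survey_id} has no individuals")
    covered_species = barcoded_species_set(checklist, accessions, markers)
    by_binomial = {r.binomial: r for r in checklist}
    genus_family = {r.genus: r.family for r in checklist}
    covered_genera = {by_binomial[s].genus for s in covered_species}
    covered_families = {by_binomial[s].family for s in covered_species}
    required = {
        TaxLevel.SPECIES: MatchLevel.SPECIES,
        TaxLevel.GENUS: MatchLevel.GENUS,
        TaxLevel.FAMILY: MatchLevel.FAMILY,
    }[level]

    n_covered = 0
    n_unident = 0
    for taxon, count in survey.records:
        if taxon.match_level < required:
            n_unident += count
            continue
        if level is TaxLevel.SPECIES:
            hit = taxon.binomial is not None and taxon.binomial in covered_species
        elif level is TaxLevel.GENUS:
            hit = taxon.genus in covered_genera
        else:  # FAMILY
            family = taxon.family or genus_family.get(taxon.genus)
            hit = family in covered_families
        if hit:
            n_covered += count
    return SurveyCoverage(
        survey_id=survey.survey_id,
        level=level,
        proportion_covered=n_covered / total,
        proportion_unidentified=n_unident / total,
    )


def aggregate_survey_coverage(
    coverages: Sequence[SurveyCoverage],
    n_boot: int = 10_000,
    seed: int = 20180101,
) -> CoverageSummary:
    """Descriptive statistics of per-survey coverage across sites.

    The 95% CI of the mean is a seeded percentile bootstrap
    (default 10,000 resamples).
    """
    if not coverages:
        raise ValidationError("no surveys to aggregate")
    p = np.array([c.proportion_covered for c in coverages])
    rng = np.random.default_rng(seed)
    boot = rng.choice(p, size=(n_boot, len(p)), replace=True).mean(axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return CoverageSummary(
        mean=float(p.mean()),
        median=float(np.median(p)),
        ci_low=float(lo),
        ci_high=float(hi),
        min=float(p.min()),
        max=float(p.max()),
        n_surveys=len(p),
    )
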
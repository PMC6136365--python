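"""Under/over-representation of taxa in the barcode library, and the
family-level sequencing priority index.

For each family (or genus) the *representation delta* is

    delta = (taxon's share of checklist species)
          - (taxon's share of barcoded species),

so positive deltas mark taxa underrepresented in the library.  The deltas
are centred on zero by construction (they sum to zero); a Cauchy
distribution — symmetric but heavy-tailed, hence robust to the handful of
genuinely extreme taxa — is fitted by maximum likelihood, and taxa outside
the fitted distribution's central 90%/95% quantile intervals are flagged.

The priority index P in [0, 3] is the sum of three within-family
proportions: species without barcodes; threatened species without
barcodes; endemic (regional + local) species without barcodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .coverage import barcoded_species_set
from .errors import DegenerateFitError, ValidationError
from .markers import ALL_MARKERS, MarkerRegion
from .records import AccessionRecord, SpeciesRecord, TaxLevel


class RepresentationFlag(Enum):
    STRONG_UNDER = "strong_under"
    UNDER = "under"
    TYPICAL = "typical"
    OVER = "over"
    STRONG_OVER = "strong_over"


@dataclass(frozen=True)
class RepresentationDelta:
    taxon: str
    delta: float
    flag: Optional[RepresentationFlag] = None


@dataclass(frozen=True)
class CauchyFit:
    location: float
    scale: float
    loglik: float


@dataclass(frozen=True)
class PriorityScore:
    family: str
    p_nobarcode: float
    p_threat: float
    p_endemic: float

    @property
    def P(self) -> float:
        return self.p_nobarcode + self.p_threat + self.p_endemic


def proportion_deltas(
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
    level: TaxLevel = TaxLevel.FAMILY,
    markers: Sequence[MarkerRegion] = ALL_MARKERS,
) -> list[RepresentationDelta]:
    """Checklist-share minus barcoded-share per taxon; deltas sum to zero."""
    if level not in (TaxLevel.FAMILY, TaxLevel.GENUS):
        raise ValidationError("representation deltas are defined at family/genus level")
    attr = level.value
    covered = barcoded_species_set(checklist, accessions, markers)
    n_total = len(checklist)
    n_covered = len(covered)
    if n_covered == 0:
        raise ValidationError("no barcoded species: barcoded share undefined")
    checklist_counts: dict[str, int] = {}
    covered_counts: dict[str, int] = {}
    for r in checklist:
        key = getattr(r, attr)
        checklist_counts[key] = checklist_counts.get(key, 0) + 1
        if r.binomial in covered:
            covered_counts[key] = covered_counts.get(key, 0) + 1
    return [
        RepresentationDelta(
            taxon=t,
            delta=checklist_counts[t] / n_total - covered_counts.get(t, 0) / n_covered,
        )
        for t in sorted(checklist_counts)
    ]


def fit_cauchy(values: Sequence[float]) -> CauchyFit:
    """Maximum-likelihood Cauchy fit, initialised at (median, IQR/2)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValidationError("need at least 3 values to fit a Cauchy")
    if np.ptp(x) == 0:
        raise DegenerateFitError("all values identical: Cauchy scale degenerates to 0")
    loc0 = float(np.median(x))
    q75, q25 = np.percentile(x, [75, 25])
    scale0 = max((q75 - q25) / 2.0, 1e-12)
    loc, scale = stats.cauchy.fit(x, loc=loc0, scale=scale0)
    if scale <= 0:
        raise DegenerateFitError(f"non-positive fitted scale {scale}")
    loglik = float(stats.cauchy.logpdf(x, loc, scale).sum())
    return CauchyFit(location=float(loc), scale=float(scale), loglik=loglik)


def cauchy_interval(fit: CauchyFit, level: float) -> tuple[float, float]:
    """Central quantile interval of the fitted Cauchy:
    location +/- scale * tan(pi * (q - 1/2)) with q = (1 + level)/2."""
    if not 0.0 < level < 1.0:
        raise ValidationError(f"interval level must be in (0, 1), got {level}")
    q = (1.0 + level) / 2.0
    half = fit.scale * math.tan(math.pi * (q - 0.5))
    return (fit.location - half, fit.location + half)


def classify_representation(
    deltas: Sequence[RepresentationDelta],
    fit: CauchyFit,
) -> list[RepresentationDelta]:
    """Flag each delta against the fitted distribution's 90/95% intervals.

    Beyond the 95% interval: STRONG_UNDER (positive tail = more flora share
    than barcode share) / STRONG_OVER; between the 90% and 95% bounds:
    UNDER / OVER; otherwise TYPICAL.  Two-sided by construction.
    """
    lo90, hi90 = cauchy_interval(fit, 0.90)
    lo95, hi95 = cauchy_interval(fit, 0.95)
    out = []
    for d in deltas:
        if d.delta > hi95:
            flag = RepresentationFlag.STRONG_UNDER
        elif d.delta > hi90:
            flag = RepresentationFlag.UNDER
        elif d.delta < lo95:
            flag = RepresentationFlag.STRONG_OVER
        elif d.delta < lo90:
            flag = RepresentationFlag.OVER
        else:
            flag = RepresentationFlag.TYPICAL
        out.append(replace(d, flag=flag))
    return out


def priority_index(
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
    family: str,
    markers: Sequence[MarkerRegion] = ALL_MARKERS,
) -> PriorityScore:
    """Priority score for one family (see :func:`_priority_components`)."""
    members = [r for r in checklist if r.family == family]
    if not members:
        raise ValidationError(f"unknown family {family!r}")
    covered = barcoded_species_set(checklist, accessions, markers)
    return _priority_components(family, members, covered)


def _priority_components(
    family: str,
    members: list[SpeciesRecord],
    covered: set[str],
) -> PriorityScore:
    """The three components of the priority index.

    Denominators are the family's species / threatened-species /
    endemic-species counts; a component with an empty denominator is 0.
    Isolated here so the reading can be revised in one place.
    """
    def frac_unbarcoded(pool: list[SpeciesRecord]) -> float:
        if not pool:
            return 0.0
        return sum(1 for r in pool if r.binomial not in covered) / len(pool)

    return PriorityScore(
        family=family,
        p_nobarcode=frac_unbarcoded(members),
        p_threat=frac_unbarcoded([r for r in members if r.threatened]),
        p_endemic=frac_unbarcoded([r for r in members if r.endemic]),
    )


def priority_table(
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
    markers: Sequence[MarkerRegion] = ALL_MARKERS,
) -> list[PriorityScore]:
    """Priority scores for every family, ranked by descending P
    (ties broken alphabetically by family)."""
    accessions = list(accessions)
    covered = barcoded_species_set(checklist, accessions, markers)
    by_family: dict[str, list[SpeciesRecord]] = {}
    for r in checklist:
        by_family.setdefault(r.family, []).append(r)
    scores = [
        _priority_components(fam, members, covered)
        for fam, members in by_family.items()
    ]
    return sorted(scores, key=lambda s: (-s.P, s.family))


@dataclass
class TreeAnnotationReport:
    families_missing_from_tree: list[str]
    tips_missing_scores: list[str]


def annotate_phylogeny(
    newick: str,
    scores: Sequence[PriorityScore],
    plain: bool = False,
) -> tuple[str, list[tuple[str, float]], TreeAnnotationReport]:
    """Attach priority scores to the tips of a family-level phylogeny.

    Returns the annotated Newick string (tips carry ``[&P=...]`` comments
    unless ``plain``), a (family, P) tip table, and a reconciliation
    report of families missing on either side.  Malformed Newick raises.
    """
    import dendropy

    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise ValidationError(f"malformed Newick: {exc}") from exc
    score_map = {s.family: s.P for s in scores}
    tip_labels = []
    table: list[tuple[str, float]] = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if label is None:
            continue
        tip_labels.append(label)
        if label in score_map:
            p = round(score_map[label], 6)
            if not plain:
                leaf.annotations.add_new("P", p)
            table.append((label, p))
    report = TreeAnnotationReport(
        families_missing_from_tree=sorted(set(score_map) - set(tip_labels)),
        tips_missing_scores=sorted(set(tip_labels) - set(score_map)),
    )
    out = tree.as_string(
        schema="newick",
        suppress_annotations=plain,
        suppress_rooting=True,
    ).strip()
    return out, sorted(table), report
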
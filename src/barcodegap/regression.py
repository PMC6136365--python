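"""Does geographical range predict barcode availability?

The response is the number of *distinct* barcode regions with at least one
sequence per species (0 to 10 for the full marker set) — a skewed count
with many zeros, modelled with a negative binomial regression (NB2:
``Var = mu + mu^2 / theta``, theta estimated by MLE) on the
distribution-class factor, with NON_ENDEMIC as the reference level.
Significance is assessed with a likelihood-ratio test against the
intercept-only model.

A companion presence/absence contrast asks whether endemics (regional +
local) are less likely to hold a core-barcode (rbcL or matK) sequence,
using binomial logistic regression, since that quantity is a proportion
of species rather than a count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .coverage import barcoded_species_set
from .errors import ValidationError
from .markers import ALL_MARKERS, CORE_MARKERS, MarkerRegion
from .records import (
    AccessionRecord,
    DistributionClass,
    ENDEMIC_CLASSES,
    SpeciesRecord,
    UNRESOLVED,
)

#: Factor level order: widespread first (reference), then increasingly
#: restricted ranges.
CLASS_ORDER = [
    DistributionClass.NON_ENDEMIC,
    DistributionClass.EASTERN_SA_ENDEMIC,
    DistributionClass.REGIONAL_ENDEMIC,
    DistributionClass.LOCAL_ENDEMIC,
]


@dataclass
class NBRegressionResult:
    coefficients: dict[str, float]   # class -> log-mean effect vs reference
    dispersion: float                # theta; Var = mu + mu^2/theta
    loglik: float
    fitted_means: dict[str, float]   # class -> expected marker count
    n: int
    classes: list[str]
    overdispersion_flag: bool        # True when data look Poisson (huge theta)


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df_model: int
    df_residual: int
    p_value: float


@dataclass(frozen=True)
class ShareContrast:
    """Presence/absence of core barcodes, endemics vs the rest."""

    share_endemic: float
    share_other: float
    n_endemic: int
    n_other: int
    lrt: LRTResult


def barcode_counts_per_species(
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
    markers: Sequence[MarkerRegion] = ALL_MARKERS,
) -> pd.Series:
    """Distinct markers with >=1 sequence, per checklist species (0..len(markers))."""
    mset = set(markers)
    per_species: dict[str, set] = {r.binomial: set() for r in checklist}
    for a in accessions:
        if a.species != UNRESOLVED and a.marker in mset and a.species in per_species:
            per_species[a.species].add(a.marker)
    return pd.Series(
        {sp: len(ms) for sp, ms in per_species.items()}, name="n_markers"
    ).loc[[r.binomial for r in checklist]]


def _design(classes: Sequence[DistributionClass]) -> tuple[np.ndarray, list[str]]:
    levels = [c for c in CLASS_ORDER if c in set(classes)]
    if len(levels) < 2:
        raise ValidationError("need at least two distribution classes present")
    cols = [np.ones(len(classes))]
    names = ["intercept"]
    for lv in levels[1:]:
        cols.append(np.array([1.0 if c is lv else 0.0 for c in classes]))
        names.append(lv.value)
    return np.column_stack(cols), names


def fit_nb_regression(
    counts: Sequence[int],
    classes: Sequence[DistributionClass],
) -> NBRegressionResult:
    """One-way negative binomial regression of counts on distribution class.

    In this saturated one-way design the fitted group means equal the
    observed group means.  A class whose counts are all zero drives its
    coefficient to a large negative value; a warning is emitted and the
    fit proceeds.
    """
    y = np.asarray(counts, dtype=float)
    if len(y) != len(classes):
        raise ValidationError("counts and classes differ in length")
    if len(y) < 20:
        raise ValidationError("need n >= 20 for the NB regression")
    X, names = _design(classes)
    present = [c for c in CLASS_ORDER if c in set(classes)]
    for lv in present:
        sel = np.array([c is lv for c in classes])
        if y[sel].sum() == 0:
            warnings.warn(
                f"class {lv.value} has all-zero counts; its coefficient is unbounded below",
                RuntimeWarning,
                stacklevel=2,
            )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.NegativeBinomial(y, X, loglike_method="nb2")
        res = model.fit(disp=0, maxiter=500)
    beta = res.params[:-1]
    alpha = float(res.params[-1])
    theta = 1.0 / alpha if alpha > 1e-8 else np.inf
    coeffs = dict(zip(names, beta))
    fitted = {}
    for lv in present:
        eta = coeffs["intercept"] + coeffs.get(lv.value, 0.0)
        fitted[lv.value] = float(np.exp(eta))
    return NBRegressionResult(
        coefficients={k: float(v) for k, v in coeffs.items() if k != "intercept"}
        | {"intercept": float(coeffs["intercept"])},
        dispersion=theta,
        loglik=float(res.llf),
        fitted_means=fitted,
        n=len(y),
        classes=[lv.value for lv in present],
        overdispersion_flag=bool(theta > 50),
    )


def _nb_null_loglik(counts: Sequence[int]) -> float:
    y = np.asarray(counts, dtype=float)
    X = np.ones((len(y), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.NegativeBinomial(y, X, loglike_method="nb2").fit(disp=0, maxiter=500)
    return float(res.llf)


def likelihood_ratio_test(
    full: NBRegressionResult,
    counts: Sequence[int],
) -> LRTResult:
    """LRT of the class model against the intercept-only NB model.

    ``df_model`` = number of class contrasts; the residual df (n minus the
    number of classes) is reported alongside, as is conventional for
    regression summaries.
    """
    if len(counts) != full.n:
        raise ValidationError("counts do not match the fitted model's data")
    ll0 = _nb_null_loglik(counts)
    stat = max(2.0 * (full.loglik - ll0), 0.0)
    df_model = len(full.classes) - 1
    df_residual = full.n - len(full.classes)
    p = float(stats.chi2.sf(stat, df_model))
    return LRTResult(statistic=float(stat), df_model=df_model,
                     df_residual=df_residual, p_value=p)


def run_nb_analysis(
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
    markers: Sequence[MarkerRegion] = ALL_MARKERS,
) -> tuple[NBRegressionResult, LRTResult]:
    """Distinct-marker counts regressed on distribution class, with LRT."""
    counts = barcode_counts_per_species(checklist, list(accessions), markers)
    classes = [r.distribution_class for r in checklist]
    full = fit_nb_regression(counts.to_numpy(), classes)
    lrt = likelihood_ratio_test(full, counts.to_numpy())
    return full, lrt


def core_barcode_share_test(
    checklist: list[SpeciesRecord],
    accessions: Iterable[AccessionRecord],
    markers: Sequence[MarkerRegion] = CORE_MARKERS,
) -> ShareContrast:
    """Share of species with >=1 core-barcode sequence: endemics vs others.

    Logistic regression on the endemic indicator, LRT against the
    intercept-only binomial model.
    """
    accessions = list(accessions)
    covered = barcoded_species_set(checklist, accessions, markers)
    y = np.array([1.0 if r.binomial in covered else 0.0 for r in checklist])
    g = np.array([1.0 if r.distribution_class in ENDEMIC_CLASSES else 0.0
                  for r in checklist])
    n_end = int(g.sum())
    n_other = len(g) - n_end
    if n_end == 0 or n_other == 0:
        raise ValidationError("both endemic and non-endemic species are required")
    X = np.column_stack([np.ones_like(g), g])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        null = sm.GLM(y, np.ones_like(y)[:, None],
                      family=sm.families.Binomial()).fit()
    stat = max(2.0 * (full.llf - null.llf), 0.0)
    lrt = LRTResult(
        statistic=float(stat),
        df_model=1,
        df_residual=len(y) - 2,
        p_value=float(stats.chi2.sf(stat, 1)),
    )
    return ShareContrast(
        share_endemic=float(y[g == 1].mean()),
        share_other=float(y[g == 0].mean()),
        n_endemic=n_end,
        n_other=n_other,
        lrt=lrt,
    )
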
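"""Accumulation of barcode sequences and taxa through time, growth-curve
fits, and saturation-date projection.

Submissions are binned by *trimester* (calendar quarter, January-anchored)
because sequence databases release accessions in bursts rather than
continuously.  Two growth models are fitted by nonlinear least squares:

* exponential, ``N(t) = N0 exp(r t)``, describing the raw sequence count;
* logistic with a *fixed* asymptote, ``N(t) = a / (1 + c exp(b t))`` with
  ``c > 0, b < 0``, for taxon counts — the saturation parameter ``a`` is
  pinned to the known checklist total, so the fit answers *when* the curve
  reaches it rather than *whether*.

The projected saturation date is the quarter where the fitted curve comes
within half a taxon of ``a`` (the last whole-taxon step), obtained in
closed form:  t* = ln( (0.5/(a-0.5)) / c ) / b.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateFitError, FitConvergenceError, ValidationError
from .records import AccessionRecord, SpeciesRecord, UNRESOLVED


class SeriesKind(str, Enum):
    SEQUENCES = "sequences"
    SPECIES = "species"
    GENERA = "genera"
    FAMILIES = "families"


def quarter_index(date: dt.date) -> int:
    """Absolute quarter index: year*4 + quarter-of-year (0-based)."""
    return date.year * 4 + (date.month - 1) // 3


def quarter_label(qidx: int) -> str:
    return f"{qidx // 4}Q{qidx % 4 + 1}"


def parse_quarter(label: str) -> int:
    """Parse a ``1995Q3`` label to an absolute quarter index."""
    year, q = label.upper().split("Q")
    q = int(q)
    if not 1 <= q <= 4:
        raise ValidationError(f"bad quarter in {label!r}")
    return int(year) * 4 + q - 1


@dataclass
class AccumulationSeries:
    """Cumulative counts per quarter.  ``t`` is the quarter index relative
    to ``origin_qidx`` (the first quarter with data); dense, so quarters
    without submissions repeat the previous cumulative value."""

    kind: SeriesKind
    origin_qidx: int
    t: np.ndarray  # int, strictly increasing from 0
    N: np.ndarray  # non-decreasing cumulative counts

    def window(self, t_start_qidx: Optional[int]) -> "AccumulationSeries":
        """Restrict to quarters at or after an absolute quarter index."""
        if t_start_qidx is None:
            return self
        mask = (self.t + self.origin_qidx) >= t_start_qidx
        return AccumulationSeries(self.kind, self.origin_qidx,
                                  self.t[mask], self.N[mask])


@dataclass(frozen=True)
class ExponentialFit:
    N0: float
    r: float  # per trimester
    rss: float
    t_ref_qidx: int  # absolute quarter where the fitted t=0 sits

    @property
    def doubling_time_trimesters(self) -> float:
        if self.r <= 0:
            return math.inf
        return math.log(2) / self.r

    @property
    def doubling_time_years(self) -> float:
        return self.doubling_time_trimesters / 4.0


@dataclass(frozen=True)
class LogisticFit:
    a: float
    b: float  # < 0
    c: float  # > 0
    rss: float
    t_ref_qidx: int


@dataclass(frozen=True)
class SaturationDate:
    t_star: float  # trimesters after the fit's t=0
    qidx: float    # absolute (fractional) quarter index
    year: int
    quarter: int


def bin_by_trimester(
    accessions: Iterable[AccessionRecord],
    kind: SeriesKind = SeriesKind.SEQUENCES,
    checklist: Optional[list[SpeciesRecord]] = None,
) -> AccumulationSeries:
    """Cumulative quarterly series of sequences or of newly barcoded taxa.

    Only resolved barcode accessions count.  For taxon series a taxon
    accumulates at the quarter of its first accession; genus/family series
    need the checklist for the species -> genus/family map.
    """
    recs = [a for a in accessions if a.species != UNRESOLVED and a.is_barcode]
    if not recs:
        raise ValidationError("no resolved barcode accessions to bin")
    if kind is SeriesKind.SEQUENCES:
        events = [quarter_index(a.submission_date) for a in recs]
    else:
        if kind is SeriesKind.SPECIES:
            def taxon_of(a): return a.species
        else:
            if checklist is None:
                raise ValidationError(f"{kind.value} series needs a checklist")
            by_binomial = {r.binomial: r for r in checklist}
            attr = "genus" if kind is SeriesKind.GENERA else "family"

            def taxon_of(a):
                rec = by_binomial.get(a.species)
                return getattr(rec, attr) if rec is not None else None
        first: dict[str, int] = {}
        for a in recs:
            tx = taxon_of(a)
            if tx is None:
                continue
            q = quarter_index(a.submission_date)
            if tx not in first or q < first[tx]:
                first[tx] = q
        events = list(first.values())
    origin = min(events)
    last = max(events)
    t = np.arange(0, last - origin + 1)
    increments = np.zeros_like(t)
    for q in events:
        increments[q - origin] += 1
    return AccumulationSeries(kind, origin, t, np.cumsum(increments))


def fit_exponential(
    series: AccumulationSeries,
    t_start_qidx: Optional[int] = None,
) -> ExponentialFit:
    """NLS fit of ``N = N0 exp(r t)`` on the (windowed) series."""
    s = series.window(t_start_qidx)
    if len(s.t) < 3:
        raise ValidationError("need at least 3 points to fit an exponential")
    t0 = s.t[0]
    tt = (s.t - t0).astype(float)
    N = s.N.astype(float)
    try:
        popt, _ = curve_fit(
            lambda t, n0, r: n0 * np.exp(r * t),
            tt, N, p0=(max(N[0], 1.0), 0.05), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"exponential fit did not converge: {exc}") from exc
    n0, r = popt
    rss = float(((n0 * np.exp(r * tt) - N) ** 2).sum())
    return ExponentialFit(N0=float(n0), r=float(r), rss=rss,
                          t_ref_qidx=int(s.origin_qidx + t0))


def fit_logistic_fixed_a(
    series: AccumulationSeries,
    a: float,
    t_start_qidx: Optional[int] = None,
) -> LogisticFit:
    """NLS fit of ``N = a / (1 + c exp(b t))`` with the asymptote fixed.

    Only (b, c) are free; initialised at ``c = a/N(t_start) - 1``,
    ``b = -0.05``.  Requires ``a >= max N``; the sign convention (growth
    toward ``a``: c > 0, b < 0) is enforced by bounds.
    """
    s = series.window(t_start_qidx)
    if len(s.t) < 4:
        raise ValidationError("need at least 4 points to fit the logistic")
    N = s.N.astype(float)
    if a < N.max():
        raise ValidationError(f"fixed asymptote a={a} below max N={N.max()}")
    if N.max() == N.min():
        raise DegenerateFitError("series is constant; logistic fit undefined")
    if N[0] >= a:
        raise DegenerateFitError("series already at the asymptote")
    t0 = s.t[0]
    tt = (s.t - t0).astype(float)
    c0 = max(a / N[0] - 1.0, 1e-9)
    try:
        popt, _ = curve_fit(
            lambda t, b, c: a / (1.0 + c * np.exp(b * t)),
            tt, N, p0=(-0.05, c0),
            bounds=([-10.0, 1e-12], [-1e-12, 1e12]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitConvergenceError(f"logistic fit did not converge: {exc}") from exc
    b, c = popt
    rss = float(((a / (1.0 + c * np.exp(b * tt)) - N) ** 2).sum())
    return LogisticFit(a=float(a), b=float(b), c=float(c), rss=rss,
                       t_ref_qidx=int(s.origin_qidx + t0))


def saturation_date(fit: LogisticFit, a: Optional[float] = None) -> SaturationDate:
    """Quarter where the fitted curve reaches ``a - 0.5`` (last whole
    taxon), solved in closed form."""
    a = fit.a if a is None else a
    if a < 1:
        raise ValidationError("asymptote must be >= 1")
    if fit.b >= 0:
        raise ValidationError("b >= 0: curve does not saturate")
    # N(t) = a - 0.5  <=>  c exp(b t) = 0.5 / (a - 0.5)
    t_star = math.log((0.5 / (a - 0.5)) / fit.c) / fit.b
    qidx = fit.t_ref_qidx + t_star
    q_whole = math.ceil(qidx)
    return SaturationDate(
        t_star=t_star,
        qidx=qidx,
        year=q_whole // 4,
        quarter=q_whole % 4 + 1,
    )
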
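"""Gestational-age trend analyses in the term-delivery group.

Two complementary analyses of how phylotype relative abundance changes with
gestational age (GA):

1. **Three-interval analysis.**  The interval between the 5th and 95th GA
   percentiles is trisected into equal-width windows, with the outer windows
   extended to the observed GA range so every sample is covered.  The model
   ladder (PLME/NBLME/ZINBLME) is fitted with the interval as a three-level
   factor, and the three between-interval contrasts (2v1, 3v2, 3v1) are
   tested, with BH adjustment across phylotypes at FDR 10%.

2. **Continuous analysis.**  Orthogonal-polynomial terms in GA (degree 1-7,
   selected by AIC) enter an NBLME model; per-term p-values are BH-adjusted
   across phylotypes within each term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core_data import CountTable, SampleMetadata, log_offsets
from .count_models import ModelSpec, fit, wald_linear
from .differential import bh_adjust, fit_ladder, fold_change, select_best

__all__ = [
    "IntervalSpec",
    "ContrastResult",
    "TrendResult",
    "build_intervals",
    "orthogonal_basis",
    "interval_contrasts",
    "polynomial_trend",
    "run_trend_analysis",
    "trend_results_to_frame",
]

CONTRAST_NAMES = ("2v1", "3v2", "3v1")


@dataclass(frozen=True)
class IntervalSpec:
    """Three GA windows from percentile trisection, covering the data range."""

    cutpoints: tuple[float, float]  # interior boundaries (weeks)
    window_bounds: tuple[tuple[float, float], ...]  # three [lo, hi) windows
    percentile_bounds: tuple[float, float]  # (5th, 95th) GA percentiles

    def assign(self, ga) -> np.ndarray:
        """Window index (0, 1, 2) per sample; a partition of the GA range."""
        ga = np.asarray(ga, dtype=float)
        c1, c2 = self.cutpoints
        return np.where(ga < c1, 0, np.where(ga < c2, 1, 2))

    def display_cutpoints(self) -> tuple[float, float]:
        return tuple(round(c, 1) for c in self.cutpoints)


def build_intervals(ga) -> IntervalSpec:
    """Trisect [5th, 95th GA percentile] into equal windows; extend the outer
    windows to the observed min/max so every sample maps to one window."""
    ga = np.asarray(ga, dtype=float)
    if len(np.unique(ga)) < 3:
        raise ValueError("need at least 3 distinct gestational ages")
    p5, p95 = np.percentile(ga, [5, 95])
    if p95 - p5 <= 0:
        raise ValueError("degenerate gestational-age spread")
    width = (p95 - p5) / 3.0
    c1, c2 = p5 + width, p5 + 2 * width
    lo, hi = float(ga.min()), float(ga.max())
    return IntervalSpec(
        cutpoints=(float(c1), float(c2)),
        window_bounds=((lo, float(c1)), (float(c1), float(c2)), (float(c2), hi)),
        percentile_bounds=(float(p5), float(p95)),
    )


def orthogonal_basis(ga, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis in GA, excluding the constant column.

    Gram-Schmidt (QR) on the Vandermonde matrix of centered GA: the returned
    columns satisfy X'X = I and are orthogonal to the constant vector, like
    R's poly().
    """
    ga = np.asarray(ga, dtype=float)
    if not 1 <= degree:
        raise ValueError("degree must be >= 1")
    if degree >= len(np.unique(ga)):
        raise ValueError(
            f"degree {degree} requires more than {degree} distinct GA values"
        )
    centered = ga - ga.mean()
    V = np.vander(centered, N=degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    # fix signs so the leading coefficient of each column is positive
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    return Q[:, 1:]


@dataclass
class ContrastResult:
    name: str  # "2v1", "3v2", "3v1"
    estimate: float
    ci_lower: float
    ci_upper: float
    fold_change: float
    p_value: float
    q_value: Optional[float] = None
    significant: bool = False


@dataclass
class TrendResult:
    """Combined three-interval and polynomial trend result for one taxon."""

    taxon: str
    interval_means: tuple[float, float, float]  # mean log relative abundance
    best_family: Optional[str] = None
    contrasts: list[ContrastResult] = field(default_factory=list)
    poly_degree: Optional[int] = None
    poly_coefs: list[float] = field(default_factory=list)
    poly_term_p: list[float] = field(default_factory=list)
    poly_term_q: list[Optional[float]] = field(default_factory=list)
    interval_direction: str = "flat"  # from the three-interval contrasts
    poly_direction: str = "flat"  # from the linear polynomial term
    direction: str = "flat"  # interval finding confirmed by the continuous analysis
    fitted: bool = True


def _interval_means(counts, totals, idx) -> tuple[float, float, float]:
    out = []
    for w in range(3):
        m = idx == w
        rel = counts[m].sum() / totals[m].sum() if m.any() else np.nan
        out.append(float(np.log(rel)) if rel and rel > 0 else float("nan"))
    return tuple(out)


def interval_contrasts(
    counts: np.ndarray,
    ga: np.ndarray,
    offset: np.ndarray,
    subjects: np.ndarray,
    intervals: IntervalSpec,
    n_restarts: int = 3,
    restart_seed: int = 0,
    quad_points: int = 25,
):
    """Model-ladder fit with interval as a 3-level factor; the three pairwise
    contrasts.  Returns (best_family, list[ContrastResult]) or (None, [])
    when no family converges."""
    idx = intervals.assign(ga)
    occupied = np.bincount(idx, minlength=3)
    if (occupied == 0).any():
        empty = [w for w in range(3) if occupied[w] == 0]
        raise ValueError(f"gestational-age interval(s) {empty} contain no samples")
    X = np.c_[np.ones(len(ga)), (idx == 1).astype(float), (idx == 2).astype(float)]
    spec_kwargs = dict(
        X=X, offset=offset, subjects=subjects,
        colnames=("intercept", "interval2", "interval3"), quad_points=quad_points,
    )
    fits = fit_ladder(spec_kwargs, counts, n_restarts=n_restarts, restart_seed=restart_seed)
    best = select_best(fits)
    if best is None:
        return None, []
    bf = fits[best]
    contrast_vectors = {"2v1": [0, 1, 0], "3v2": [0, -1, 1], "3v1": [0, 0, 1]}
    out = []
    for name in CONTRAST_NAMES:
        est, lo, hi, p = wald_linear(bf, contrast_vectors[name])
        out.append(ContrastResult(name, est, lo, hi, fold_change(est), p))
    return best, out


def polynomial_trend(
    counts: np.ndarray,
    ga: np.ndarray,
    offset: np.ndarray,
    subjects: np.ndarray,
    max_degree: int = 7,
    n_restarts: int = 1,
    restart_seed: int = 0,
    quad_points: int = 25,
):
    """NBLME with orthogonal-polynomial GA terms, degree chosen by AIC.

    Returns (degree, coefs, per-term p-values) for the AIC-minimizing degree
    in 1..max_degree, or (None, [], []) if no degree converges.
    """
    if not 1 <= max_degree <= 7:
        raise ValueError("max_degree must be in 1..7")
    best_deg, best_fit, best_aic = None, None, np.inf
    for deg in range(1, max_degree + 1):
        if deg >= len(np.unique(ga)):
            break
        B = orthogonal_basis(ga, deg)
        X = np.c_[np.ones(len(ga)), B]
        spec = ModelSpec(
            family="NBLME", X=X, offset=offset, subjects=subjects,
            colnames=("intercept",) + tuple(f"poly{d}" for d in range(1, deg + 1)),
            quad_points=quad_points,
        )
        f = fit(spec, counts, n_restarts=n_restarts, restart_seed=restart_seed,
                compute_se=False)
        if f.converged and np.isfinite(f.aic) and f.aic < best_aic - 1e-9:
            best_deg, best_aic = deg, f.aic
    if best_deg is None:
        return None, [], []
    B = np.c_[np.ones(len(ga)), orthogonal_basis(ga, best_deg)]
    spec = ModelSpec(
        family="NBLME", X=B, offset=offset, subjects=subjects,
        colnames=("intercept",) + tuple(f"poly{d}" for d in range(1, best_deg + 1)),
        quad_points=quad_points,
    )
    f = fit(spec, counts, n_restarts=n_restarts, restart_seed=restart_seed, compute_se=True)
    coefs, pvals = [], []
    for j in range(1, best_deg + 1):
        try:
            est, _, _, p = wald_linear(f, np.eye(best_deg + 1)[j])
        except ValueError:
            est, p = float(f.beta[j]), float("nan")
        coefs.append(est)
        pvals.append(p)
    return best_deg, coefs, pvals


def _direction_from_contrasts(contrasts: list[ContrastResult]) -> str:
    signs = {np.sign(c.estimate) for c in contrasts if c.significant}
    if not signs:
        return "flat"
    if len(signs) == 1:
        return "up" if signs.pop() > 0 else "down"
    final = next(c for c in contrasts if c.name == "3v1")
    if final.significant:
        return "up" if final.estimate > 0 else "down"
    return "flat"


def _direction_from_poly(result: TrendResult, fdr_threshold: float) -> str:
    if (
        result.poly_term_q
        and result.poly_term_q[0] is not None
        and result.poly_term_q[0] < fdr_threshold
    ):
        return "up" if result.poly_coefs[0] > 0 else "down"
    return "flat"


def run_trend_analysis(
    table: CountTable,
    meta: list[SampleMetadata],
    fdr_threshold: float = 0.1,
    fc_threshold: float = 1.5,
    max_degree: int = 7,
    n_restarts: int = 3,
    restart_seed: int = 0,
    quad_points: int = 25,
    term_only: bool = True,
) -> tuple[IntervalSpec, list[TrendResult]]:
    """Full GA-trend analysis over all taxa (term-delivery subjects only).

    Contrast p-values are BH-adjusted across phylotypes per contrast, and
    polynomial-term p-values across phylotypes within each term, both at the
    supplied FDR.  A contrast is significant when q < FDR and its fold
    change exceeds ``fc_threshold`` in magnitude (the same rule as the group
    comparison).  The reported ``direction`` is the interval-analysis call
    confirmed by the continuous analysis: "up"/"down" only when the
    significant contrasts and the linear polynomial term agree in sign.
    """
    by_id = {m.sample_id: m for m in meta}
    meta_ordered = [by_id[s] for s in table.samples]
    if term_only:
        keep = [m.group == "term" for m in meta_ordered]
        table = table.select_samples([s for s, k in zip(table.samples, keep) if k])
        meta_ordered = [m for m, k in zip(meta_ordered, keep) if k]
    ga = np.array([m.gestational_age for m in meta_ordered])
    offset = log_offsets(meta_ordered)
    subjects = np.array([m.subject_id for m in meta_ordered])
    totals = table.totals()
    intervals = build_intervals(ga)
    idx = intervals.assign(ga)

    results: list[TrendResult] = []
    for j, taxon in enumerate(table.taxa):
        counts = table.counts[:, j]
        res = TrendResult(taxon, _interval_means(counts, totals, idx))
        best, contrasts = interval_contrasts(
            counts, ga, offset, subjects, intervals,
            n_restarts=n_restarts, restart_seed=restart_seed, quad_points=quad_points,
        )
        res.best_family = best
        res.contrasts = contrasts
        deg, coefs, pvals = polynomial_trend(
            counts, ga, offset, subjects, max_degree=max_degree,
            n_restarts=min(n_restarts, 1), restart_seed=restart_seed,
            quad_points=quad_points,
        )
        res.poly_degree = deg
        res.poly_coefs = coefs
        res.poly_term_p = pvals
        res.poly_term_q = [None] * len(pvals)
        res.fitted = best is not None or deg is not None
        results.append(res)

    # BH across phylotypes, per contrast
    for name in CONTRAST_NAMES:
        rows = [
            next(c for c in r.contrasts if c.name == name)
            for r in results
            if r.contrasts
        ]
        if rows:
            q = bh_adjust([c.p_value for c in rows])
            for c, qv in zip(rows, q):
                c.q_value = float(qv)
                c.significant = bool(
                    qv < fdr_threshold and abs(c.fold_change) > fc_threshold
                )

    # BH across phylotypes, within each polynomial term
    max_terms = max((len(r.poly_term_p) for r in results), default=0)
    for t in range(max_terms):
        rows = [r for r in results if len(r.poly_term_p) > t and np.isfinite(r.poly_term_p[t])]
        if rows:
            q = bh_adjust([r.poly_term_p[t] for r in rows])
            for r, qv in zip(rows, q):
                r.poly_term_q[t] = float(qv)

    for r in results:
        r.interval_direction = _direction_from_contrasts(r.contrasts)
        r.poly_direction = _direction_from_poly(r, fdr_threshold)
        r.direction = (
            r.interval_direction
            if r.interval_direction != "flat" and r.interval_direction == r.poly_direction
            else "flat"
        )
    return intervals, results


def trend_results_to_frame(results: list[TrendResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row: dict = {
            "taxon": r.taxon,
            "mean_log_relab_interval1": r.interval_means[0],
            "mean_log_relab_interval2": r.interval_means[1],
            "mean_log_relab_interval3": r.interval_means[2],
            "best_family": r.best_family,
            "interval_direction": r.interval_direction,
            "poly_direction": r.poly_direction,
            "direction": r.direction,
            "poly_degree": r.poly_degree,
            "fitted": r.fitted,
        }
        for c in r.contrasts:
            row[f"contrast_{c.name}_estimate"] = c.estimate
            row[f"contrast_{c.name}_fold_change"] = c.fold_change
            row[f"contrast_{c.name}_p"] = c.p_value
            row[f"contrast_{c.name}_q"] = c.q_value
            row[f"contrast_{c.name}_significant"] = c.significant
        for t, (p, q) in enumerate(zip(r.poly_term_p, r.poly_term_q), start=1):
            row[f"poly_term{t}_p"] = p
            row[f"poly_term{t}_q"] = q
        rows.append(row)
    return pd.DataFrame(rows)
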
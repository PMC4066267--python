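"""Per-phylotype differential abundance between study groups.

For each phylotype the three-model ladder (PLME, NBLME, ZINBLME) is fitted
with fixed effects {intercept, group} and a log-total-reads offset; the
model with the smallest AIC among converged fits is retained, its group
coefficient is turned into a signed fold change, and p-values are
Benjamini-Hochberg adjusted across phylotypes.  A taxon is called
significant when q < 0.1 and |fold change| > 1.5.

Signed fold-change convention: exp(estimate) for estimate >= 0, and
-exp(-estimate) for estimate < 0, so a negative value is the magnitude of
the fold *decrease* carried with a minus sign (e.g. an estimate of -0.864
reports as -2.4, a 2.4-fold decrease).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_data import CountTable, SampleMetadata, log_offsets
from .count_models import FAMILIES, ModelFit, ModelSpec, fit, wald

__all__ = [
    "TaxonResult",
    "fold_change",
    "bh_adjust",
    "fit_ladder",
    "run_group_comparison",
    "results_to_frame",
]


@dataclass
class TaxonResult:
    """Best-model group comparison for one phylotype (one output-table row)."""

    taxon: str
    aic_plme: Optional[float]
    aic_nblme: Optional[float]
    aic_zinblme: Optional[float]
    best_family: Optional[str]
    estimate: Optional[float]  # natural-log scale
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    fold_change: Optional[float]
    p_value: Optional[float]
    q_value: Optional[float]
    significant: bool
    fitted: bool  # False when no family converged


def fold_change(estimate: float) -> float:
    """Signed fold change from a natural-log-scale coefficient.

    exp(b) for b >= 0; -exp(-b) for b < 0 (fold-decrease magnitude, minus
    sign).  |fold_change| >= 1 always and the sign matches the estimate.
    """
    if not np.isfinite(estimate):
        raise ValueError("estimate must be finite")
    if estimate >= 0:
        return float(np.exp(estimate))
    return float(-np.exp(-estimate))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_ladder(
    spec_kwargs: dict,
    counts: np.ndarray,
    families=FAMILIES,
    n_restarts: int = 3,
    restart_seed: int = 0,
) -> dict[str, ModelFit]:
    """Fit every family on the same design; SEs only for the AIC winner.

    Non-converged families are excluded from the AIC comparison; ties break
    toward the family with fewer parameters (the ladder order).
    """
    fits: dict[str, ModelFit] = {}
    for fam in families:
        spec = ModelSpec(family=fam, **spec_kwargs)
        fits[fam] = fit(
            spec, counts, n_restarts=n_restarts, restart_seed=restart_seed, compute_se=False
        )
    best = select_best(fits)
    if best is not None:
        spec = ModelSpec(family=best, **spec_kwargs)
        fits[best] = fit(
            spec, counts, n_restarts=n_restarts, restart_seed=restart_seed, compute_se=True
        )
    return fits


def select_best(fits: dict[str, ModelFit]) -> Optional[str]:
    """Family with smallest AIC among converged fits (ties -> fewer params)."""
    candidates = [
        (f.aic, f.n_params, fam)
        for fam, f in fits.items()
        if f.converged and np.isfinite(f.aic)
    ]
    if not candidates:
        return None
    return min(candidates)[2]


def run_group_comparison(
    table: CountTable,
    meta: list[SampleMetadata],
    fdr_threshold: float = 0.1,
    fc_threshold: float = 1.5,
    n_restarts: int = 3,
    restart_seed: int = 0,
    quad_points: int = 25,
    group_column: Optional[dict[str, int]] = None,
) -> list[TaxonResult]:
    """Run the full per-phylotype ladder + AIC selection + BH adjustment.

    ``table`` should already be prevalence-filtered.  The group indicator is
    1 for preterm, 0 for term unless ``group_column`` supplies another
    binary coding keyed by group label.  Unfit taxa (no converged family)
    are excluded from the BH family.
    """
    by_id = {m.sample_id: m for m in meta}
    meta_ordered = [by_id[s] for s in table.samples]
    coding = group_column or {"term": 0, "preterm": 1}
    group = np.array([coding[m.group] for m in meta_ordered], dtype=float)
    X = np.c_[np.ones(table.n_samples), group]
    offset = log_offsets(meta_ordered)
    subjects = np.array([m.subject_id for m in meta_ordered])
    spec_kwargs = dict(
        X=X, offset=offset, subjects=subjects,
        colnames=("intercept", "group"), quad_points=quad_points,
    )

    rows: list[TaxonResult] = []
    for j, taxon in enumerate(table.taxa):
        counts = table.counts[:, j]
        fits = fit_ladder(
            spec_kwargs, counts, n_restarts=n_restarts, restart_seed=restart_seed
        )
        best = select_best(fits)
        aics = {
            fam: (float(f.aic) if f.converged and np.isfinite(f.aic) else None)
            for fam, f in fits.items()
        }
        if best is None:
            rows.append(
                TaxonResult(taxon, aics["PLME"], aics["NBLME"], aics["ZINBLME"],
                            None, None, None, None, None, None, None, False, False)
            )
            continue
        try:
            est, lo, hi, p = wald(fits[best], coef_index=1)
        except ValueError:
            rows.append(
                TaxonResult(taxon, aics["PLME"], aics["NBLME"], aics["ZINBLME"],
                            best, None, None, None, None, None, None, False, False)
            )
            continue
        rows.append(
            TaxonResult(taxon, aics["PLME"], aics["NBLME"], aics["ZINBLME"],
                        best, est, lo, hi, fold_change(est), p, None, False, True)
        )

    fitted = [r for r in rows if r.fitted]
    if fitted:
        q = bh_adjust([r.p_value for r in fitted])
        for r, qv in zip(fitted, q):
            r.q_value = float(qv)
            r.significant = bool(qv < fdr_threshold and abs(r.fold_change) > fc_threshold)
    return rows


def results_to_frame(results: list[TaxonResult]) -> pd.DataFrame:
    """Result table mirroring the per-family-AIC / estimate / CI / fold-change
    / p / q column structure, sorted by estimate (descending)."""
    df = pd.DataFrame([asdict(r) for r in results])
    cols = [
        "taxon", "aic_plme", "aic_nblme", "aic_zinblme", "best_family",
        "estimate", "ci_lower", "ci_upper", "fold_change", "p_value",
        "q_value", "significant", "fitted",
    ]
    df = df[cols]
    return df.sort_values("estimate", ascending=False, na_position="last").reset_index(drop=True)
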
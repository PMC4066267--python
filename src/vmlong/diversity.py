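"""Shannon diversity per sample and the between-group mixed-model comparison.

The Shannon Diversity Index (SDI) of a community state is -sum p_i ln p_i
(natural log): 0 for a monodominant sample, ln(n_taxa) at the uniform
maximum.  Group comparison follows the study procedure: log-transform the
SDI (to improve normality; monodominant samples are floored at a small
constant first) and fit a Gaussian linear mixed-effects model with a
subject random intercept and a term/preterm fixed effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .core_data import CommunityState, SampleMetadata

__all__ = ["DiversityResult", "shannon_index", "compare_diversity"]


@dataclass
class DiversityResult:
    per_sample: pd.DataFrame  # sample_id, subject_id, group, sdi, log_sdi
    group_summary: pd.DataFrame  # median and IQR of raw SDI per group
    lme_estimate: float  # preterm - term difference on the log-SDI scale
    lme_se: float
    lme_p: float


def shannon_index(state: CommunityState) -> float:
    """-sum_{p_i > 0} p_i ln p_i (natural log)."""
    p = state.abundances
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def compare_diversity(
    states: list[CommunityState],
    meta: list[SampleMetadata],
    sdi_floor: float = 1e-6,
) -> DiversityResult:
    """Gaussian LME on log SDI: subject random intercept, group fixed effect.

    SDI values below ``sdi_floor`` (monodominant samples) are floored before
    the log-transform.  Raises when either group has fewer than 2 subjects
    or the log-SDI values are constant.
    """
    by_id = {m.sample_id: m for m in meta}
    rows = []
    for s in states:
        m = by_id[s.sample_id]
        sdi = shannon_index(s)
        rows.append(
            {
                "sample_id": s.sample_id,
                "subject_id": m.subject_id,
                "group": m.group,
                "sdi": sdi,
                "log_sdi": np.log(max(sdi, sdi_floor)),
            }
        )
    df = pd.DataFrame(rows)
    n_subj = df.groupby("group")["subject_id"].nunique()
    if len(n_subj) < 2 or (n_subj < 2).any():
        raise ValueError("need at least 2 subjects in each group")
    if np.ptp(df["log_sdi"].to_numpy()) < 1e-12:
        raise ValueError("log-SDI has zero variance; group comparison undefined")

    summary = (
        df.groupby("group")["sdi"]
        .agg(median="median", q25=lambda x: x.quantile(0.25), q75=lambda x: x.quantile(0.75))
        .reset_index()
    )
    model = smf.mixedlm(
        "log_sdi ~ C(group, Treatment(reference='term'))", df, groups=df["subject_id"]
    )
    res = model.fit(reml=True, method="lbfgs")
    coef_name = next(n for n in res.params.index if "preterm" in n)
    return DiversityResult(
        per_sample=df,
        group_summary=summary,
        lme_estimate=float(res.params[coef_name]),
        lme_se=float(res.bse[coef_name]),
        lme_p=float(res.pvalues[coef_name]),
    )
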
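"""Arm-level comparison of decline slopes and descriptive cohort curves.

The treatment contrast is estimated in two stages: censored-ML fits per
patient, then a Wald z test on the arm means of the per-patient estimates.
``alpha`` is compared on the log scale (it is positivity-constrained and
right-skewed), ``beta`` on the raw scale (it may take either sign).
Standard errors come from the empirical between-patient variance, so the
test treats the per-patient estimation error as part of the between-patient
spread.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biexp import BiExpFit
from .timecourse import ARMS, Cohort


@dataclass
class ArmComparison:
    parameter: str
    mean: dict[str, float]          # per arm, on the working scale
    se: dict[str, float]
    n: dict[str, int]
    z: float
    p_value: float
    scale: str                      # "log" or "identity"


def compare_arms(fits_by_arm: dict[str, list[BiExpFit]],
                 parameter: str) -> ArmComparison:
    """Wald z test of equal arm means of the per-patient estimates."""
    if parameter not in ("alpha", "beta"):
        raise ValueError("parameter must be 'alpha' or 'beta'")
    log_scale = parameter == "alpha"
    mean, se, n = {}, {}, {}
    for arm in ARMS:
        fits = [f for f in fits_by_arm.get(arm, []) if f.converged]
        if len(fits) < 2:
            raise ValueError(f"arm {arm!r} needs >= 2 converged fits")
        vals = np.array([getattr(f.params, parameter) for f in fits])
        if log_scale:
            vals = np.log(vals)
        m, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
        if sd == 0.0:
            raise ValueError(f"degenerate (zero) variance in arm {arm!r}")
        mean[arm], se[arm], n[arm] = m, sd / math.sqrt(len(vals)), len(vals)
    z = (mean[ARMS[1]] - mean[ARMS[0]]) / math.hypot(se[ARMS[0]], se[ARMS[1]])
    p = 2.0 * stats.norm.sf(abs(z))
    return ArmComparison(parameter=parameter, mean=mean, se=se, n=n,
                         z=float(z), p_value=float(p),
                         scale="log" if log_scale else "identity")


def alpha_beta_correlation(fits: list[BiExpFit], n_boot: int = 1000,
                           seed: int = 0) -> dict:
    """Spearman correlation between initial and secondary slope with a
    percentile-bootstrap 95% CI (the 'no early-late correlation' check)."""
    if len(fits) < 10:
        raise ValueError(f"need >= 10 fits, got {len(fits)}")
    a = np.array([f.params.alpha for f in fits])
    b = np.array([f.params.beta for f in fits])
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return {"r": math.nan, "ci_low": math.nan, "ci_high": math.nan,
                "n": len(fits), "defined": False}
    r = float(stats.spearmanr(a, b).statistic)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        k = rng.integers(0, len(a), len(a))
        boots[i] = stats.spearmanr(a[k], b[k]).statistic
    lo, hi = np.nanquantile(boots, [0.025, 0.975])
    return {"r": r, "ci_low": float(lo), "ci_high": float(hi),
            "n": len(fits), "defined": True}


def mean_response_curve(cohort: Cohort, window_months: float = 2.0,
                        max_months: float = 60.0) -> pd.DataFrame:
    """Binned mean +- SD of the observed LRATIO per arm.

    Censored values contribute at the QL and the bin is flagged with its
    censored count; a bin containing only censored values is flagged
    all_censored.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for p in cohort:
        for m in p.measurements:
            rows.append((p.arm, m.time, math.log10(m.ratio_percent),
                         m.censored))
    df = pd.DataFrame(rows, columns=["arm", "time", "lratio", "censored"])
    edges = np.arange(0.0, max_months + window_months, window_months)
    out = []
    for arm, grp in df.groupby("arm"):
        which = np.clip(np.digitize(grp["time"], edges) - 1, 0, len(edges) - 2)
        for b in np.unique(which):
            sel = grp[which == b]
            out.append({
                "arm": arm,
                "bin_start": edges[b], "bin_end": edges[b + 1],
                "mean_lratio": float(sel["lratio"].mean()),
                "sd": float(sel["lratio"].std(ddof=0)),
                "n": int(len(sel)),
                "n_censored": int(sel["censored"].sum()),
                "all_censored": bool(sel["censored"].all()),
            })
    return pd.DataFrame(out).sort_values(["arm", "bin_start"]).reset_index(drop=True)
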
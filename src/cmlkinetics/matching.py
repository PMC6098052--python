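"""Patient-to-model matching, prediction intervals and cross-validation.

For patient *i* with data up to month tau, the suitable set Theta_i^tau
collects every screened configuration whose summarised kinetic lies fully
inside the patient's point-wise confidence band on [0, tau]; members are
ranked by the root-mean-square distance of their curve to the patient's own
fit rho_i^tau.  Envelopes of the suitable curves give the peripheral-blood
prediction interval at five years, and the spread of the members'
stem-cell series gives the residual-LSC interval

    delta_lsc     = log10(lsc_max)     - log10(lsc_min)
    delta_bcr_abl = log10(bcrabl_max)  - log10(bcrabl_min).

Prediction accuracy under reduced follow-up compares the suitable sets of
truncated data (tau = 2, 3, 4 years) against the full five-year set: a
configuration's five-year value can fall inside both envelopes (TP),
neither (TN), only the reduced one (FP) or only the full one (FN).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .biexp import BiExpFit, ConfidenceBand, biexp_lratio
from .config import load_defaults
from .screen import LookupTable


class MatchingError(ValueError):
    pass


@dataclass
class SuitableSet:
    patient_id: str
    tau: float
    config_indices: np.ndarray   # indices into table.entries, best first
    distances: np.ndarray        # RMS curve distance to the patient fit

    def __post_init__(self):
        self.config_indices = np.asarray(self.config_indices, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(np.diff(self.distances) < -1e-12):
            raise ValueError("distances must be non-decreasing")

    @property
    def best(self) -> int | None:
        return int(self.config_indices[0]) if len(self.config_indices) else None

    def __len__(self) -> int:
        return len(self.config_indices)


@dataclass
class PredictionInterval:
    time: float
    pb_lower: float = math.nan      # LRATIO scale
    pb_upper: float = math.nan
    lsc_min: float = math.nan
    lsc_max: float = math.nan
    delta_bcr_abl: float = math.nan
    delta_lsc: float = math.nan
    delta_lsc_defined: bool = True
    empty: bool = False


@dataclass
class AccuracyCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    unclassifiable: bool = False

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def fp_rate(self) -> float:
        return self.fp / self.total if self.total else math.nan

    @property
    def fn_rate(self) -> float:
        return self.fn / self.total if self.total else math.nan

    def __add__(self, other: "AccuracyCounts") -> "AccuracyCounts":
        return AccuracyCounts(self.tp + other.tp, self.tn + other.tn,
                              self.fp + other.fp, self.fn + other.fn)


def _containment_grid(band: ConfidenceBand, tau: float) -> np.ndarray:
    grid = band.times[band.times <= tau + 1e-9]
    if len(grid) == 0:
        raise MatchingError("confidence-band grid is empty on [0, tau]")
    return grid


def find_suitable(table: LookupTable, band: ConfidenceBand, tau: float,
                  fit: BiExpFit | None = None,
                  patient_id: str = "") -> SuitableSet:
    """All biphasic-valid entries whose curve lies inside the band at every
    grid point up to tau, ranked by distance to the patient fit (when
    given; otherwise by distance to the band midline)."""
    grid = _containment_grid(band, tau)
    idx, curves = table.curves(band.times)
    m = len(grid)
    lo, hi = band.lower[:m], band.upper[:m]
    inside = np.all((curves[:, :m] >= lo - 1e-12)
                    & (curves[:, :m] <= hi + 1e-12), axis=1)
    sel = idx[inside]
    if fit is not None:
        ref = biexp_lratio(grid, fit.params, fit.exp_base)
    else:
        ref = 0.5 * (lo + hi)
    d = np.sqrt(np.mean((curves[inside, :m] - ref) ** 2, axis=1))
    order = np.argsort(d, kind="stable")
    return SuitableSet(patient_id=patient_id, tau=float(tau),
                       config_indices=sel[order], distances=d[order])


def rank_distance(rho_sim, rho_hat, grid, exp_base: str = "e") -> float:
    """RMS difference of two bi-exponential LRATIO curves on *grid*."""
    grid = np.asarray(grid, dtype=float)
    a = biexp_lratio(grid, rho_sim, exp_base)
    b = biexp_lratio(grid, rho_hat, exp_base)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pb_prediction_interval(suitable: SuitableSet, table: LookupTable,
                           t: float) -> PredictionInterval:
    """Envelope of the suitable curves (LRATIO) at time t."""
    if len(suitable) == 0:
        return PredictionInterval(time=float(t), empty=True)
    vals = np.array([table.entries[i].curve(t, table.exp_base)
                     for i in suitable.config_indices])
    lo, hi = float(vals.min()), float(vals.max())
    return PredictionInterval(time=float(t), pb_lower=lo, pb_upper=hi,
                              delta_bcr_abl=hi - lo)


def lsc_prediction_interval(suitable: SuitableSet, table: LookupTable,
                            t: float) -> PredictionInterval:
    """Range of predicted residual leukemic stem-cell counts at time t."""
    if len(suitable) == 0:
        return PredictionInterval(time=float(t), empty=True)
    j = int(np.argmin(np.abs(table.sample_times - t)))
    vals = np.array([table.entries[i].lsc_series[j]
                     for i in suitable.config_indices])
    lsc_min, lsc_max = float(vals.min()), float(vals.max())
    out = PredictionInterval(time=float(t), lsc_min=lsc_min, lsc_max=lsc_max)
    if lsc_min > 0:
        out.delta_lsc = math.log10(lsc_max) - math.log10(lsc_min)
    else:
        out.delta_lsc_defined = False
    return out


def classify(set_reduced: SuitableSet, set_full: SuitableSet,
             table: LookupTable, t: float = 60.0,
             universe: str = "union") -> AccuracyCounts:
    """Configuration-level five-year prediction accuracy.

    Each configuration in the chosen universe is evaluated at t and tested
    against the peripheral-blood envelopes of the reduced-data and the
    full-data suitable sets: inside both -> TP, neither -> TN, reduced only
    -> FP, full only -> FN.
    """
    if len(set_reduced) == 0 or len(set_full) == 0:
        return AccuracyCounts(unclassifiable=True)
    if universe == "union":
        members = np.union1d(set_reduced.config_indices,
                             set_full.config_indices)
    elif universe == "table":
        members = table.valid_indices()
    else:
        raise ValueError(f"unknown universe {universe!r}")
    red = pb_prediction_interval(set_reduced, table, t)
    full = pb_prediction_interval(set_full, table, t)
    counts = AccuracyCounts()
    for i in members:
        v = float(table.entries[i].curve(t, table.exp_base))
        in_red = red.pb_lower - 1e-12 <= v <= red.pb_upper + 1e-12
        in_full = full.pb_lower - 1e-12 <= v <= full.pb_upper + 1e-12
        if in_red and in_full:
            counts.tp += 1
        elif in_red:
            counts.fp += 1
        elif in_full:
            counts.fn += 1
        else:
            counts.tn += 1
    return counts


def accuracy_curve(per_patient: dict[str, dict[float, SuitableSet]],
                   table: LookupTable,
                   tau_list=None, full_tau: float | None = None,
                   t: float | None = None,
                   universe: str = "union",
                   defaults: dict | None = None) -> pd.DataFrame:
    """Pooled and per-patient FP/FN rates per reduced observation period.

    *per_patient* maps patient_id -> {tau: SuitableSet} and must include the
    full-follow-up tau.
    """
    cfg = (defaults or load_defaults())["matching"]
    tau_list = cfg["tau_list_months"] if tau_list is None else tau_list
    full_tau = cfg["full_tau_months"] if full_tau is None else full_tau
    t = cfg["classify_time_months"] if t is None else t
    rows = []
    for tau in tau_list:
        pooled = AccuracyCounts()
        n_cls = 0
        for pid, sets in per_patient.items():
            if tau not in sets or full_tau not in sets:
                continue
            c = classify(sets[tau], sets[full_tau], table, t, universe)
            if c.unclassifiable:
                continue
            pooled = pooled + c
            n_cls += 1
            rows.append({"tau": tau, "patient_id": pid, "tp": c.tp,
                         "tn": c.tn, "fp": c.fp, "fn": c.fn,
                         "fp_rate": c.fp_rate, "fn_rate": c.fn_rate,
                         "pooled": 0})
        rows.append({"tau": tau, "patient_id": "__pooled__", "tp": pooled.tp,
                     "tn": pooled.tn, "fp": pooled.fp, "fn": pooled.fn,
                     "fp_rate": pooled.fp_rate, "fn_rate": pooled.fn_rate,
                     "pooled": 1})
    return pd.DataFrame(rows)


def _spearman_with_ci(x, y, n_boot: int = 1000, seed: int = 0):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return {"r": math.nan, "ci_low": math.nan, "ci_high": math.nan,
                "n": len(x), "defined": False}
    r = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        k = rng.integers(0, n, n)
        if len(np.unique(x[k])) < 2 or len(np.unique(y[k])) < 2:
            boots[b] = np.nan
            continue
        boots[b] = stats.spearmanr(x[k], y[k]).statistic
    lo, hi = np.nanquantile(boots, [0.025, 0.975])
    return {"r": r, "ci_low": float(lo), "ci_high": float(hi), "n": n,
            "defined": True}


def summary_correlations(fits: dict[str, BiExpFit],
                         suitable_sets: dict[str, SuitableSet],
                         table: LookupTable, t: float = 60.0,
                         n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Spearman correlations linking statistical and mechanistic summaries:

    (alpha, best r_trans), (beta, best f_omega_cml), (sigma2, delta_lsc),
    (delta_bcr_abl, delta_lsc), (beta, lsc_max).
    """
    ids = [pid for pid in fits
           if pid in suitable_sets and len(suitable_sets[pid]) > 0]
    if len(ids) < 10:
        raise MatchingError(f"need >= 10 matched patients, got {len(ids)}")
    alpha = [fits[p].params.alpha for p in ids]
    beta = [fits[p].params.beta for p in ids]
    sigma2 = [fits[p].sigma2 for p in ids]
    best_rt, best_fo, dlsc, dpb, lscmax = [], [], [], [], []
    for p in ids:
        s = suitable_sets[p]
        best_cfg = table.entries[s.best].config
        best_rt.append(best_cfg.r_trans)
        best_fo.append(best_cfg.f_omega_cml)
        li = lsc_prediction_interval(s, table, t)
        pi = pb_prediction_interval(s, table, t)
        dlsc.append(li.delta_lsc if li.delta_lsc_defined else np.nan)
        dpb.append(pi.delta_bcr_abl)
        lscmax.append(li.lsc_max)
    pairs = {
        "alpha_vs_best_r_trans": (alpha, best_rt),
        "beta_vs_best_f_omega_cml": (beta, best_fo),
        "sigma2_vs_delta_lsc": (sigma2, dlsc),
        "delta_bcr_abl_vs_delta_lsc": (dpb, dlsc),
        "beta_vs_lsc_max": (beta, lscmax),
    }
    rows = []
    for name, (x, y) in pairs.items():
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        res = _spearman_with_ci(x[ok], y[ok], n_boot=n_boot, seed=seed)
        res["pair"] = name
        rows.append(res)
    return pd.DataFrame(rows)[["pair", "r", "ci_low", "ci_high", "n", "defined"]]
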
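"""Bi-exponential decline model with left-censoring and bootstrap bands.

The tumor-load time course on the log10 scale is modelled as

    LRATIO(t) = log10( A exp(-alpha t) + B exp(-beta t) )

with intercepts ``A > B >= 0`` (percent scale), initial slope ``alpha > 0``
and secondary slope ``beta`` of either sign (per month).  On the log scale
this resembles a smoothed piecewise-linear curve with one break: the first
segment reflects the rapid depletion of cycling leukemic cells, the second
the slow elimination of quiescent leukemic stem cells.  A config switch
allows base-10 exponentials instead of base e.

Estimation maximises a censored-Gaussian (Tobit-type) likelihood on the
LRATIO scale: observed points contribute normal densities, values below the
quantification limit contribute ``Phi((log10 QL - mu)/sigma)``, each term
weighted by its measurement weight.  The constraints ``A > B >= 0`` and
``alpha > 0`` are enforced by the reparameterisation ``A = B + exp(u)``,
``B = exp(v)``, ``alpha = exp(w)``.  When no point is censored the
likelihood collapses to weighted least squares and the fit dispatches to a
trust-region least-squares solver.

Point-wise confidence bands for the mean curve come from a parametric
bootstrap: replicate data sets are simulated from the fitted curve at the
patient's own design (censoring re-applied at the QL), refitted, and
percentile envelopes of the refitted curves taken per grid point.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .config import DAYS_PER_MONTH, load_defaults
from .timecourse import PatientTimeCourse

LN10 = math.log(10.0)


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class BiExpParams:
    A: float
    alpha: float
    B: float
    beta: float

    def __post_init__(self):
        if not (self.A > self.B >= 0.0):
            raise ValueError(f"need A > B >= 0, got A={self.A}, B={self.B}")
        if self.alpha <= 0:
            raise ValueError(f"need alpha > 0, got {self.alpha}")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.alpha, self.B, self.beta])


@dataclass
class BiExpFit:
    """Fitted parameter tuple rho = (A, alpha, B, beta) for one patient.

    sigma2 is the ML residual variance on the LRATIO scale; tau the
    observation horizon (months of data used).
    """

    params: BiExpParams
    sigma2: float
    tau: float
    n_obs: int
    n_censored: int
    loglik: float
    converged: bool
    ql_percent: float | None = None
    exp_base: str = "e"


@dataclass
class ConfidenceBand:
    times: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_boot: int
    seed: int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("band grid must be strictly increasing")
        if np.any(self.lower > self.upper + 1e-12):
            raise ValueError("lower band above upper band")

    def restrict(self, tau: float) -> "ConfidenceBand":
        keep = self.times <= tau + 1e-9
        return ConfidenceBand(self.times[keep], self.lower[keep],
                              self.upper[keep], self.level, self.n_boot, self.seed)


def _rate_scale(exp_base: str) -> float:
    # slopes are quoted per month for exp(-rate*t); with base 10 the decline
    # 10^(-rate*t) corresponds to exp(-rate*ln10*t)
    if exp_base == "e":
        return 1.0
    if exp_base == "10":
        return LN10
    raise ValueError(f"exp_base must be 'e' or '10', got {exp_base!r}")


def biexp_lratio(t, params: BiExpParams, exp_base: str = "e"):
    """Mean LRATIO at time(s) t (months)."""
    s = _rate_scale(exp_base)
    t = np.asarray(t, dtype=float)
    la = math.log(params.A) - params.alpha * s * t
    if params.B > 0.0:
        lb = math.log(params.B) - params.beta * s * t
        hi = np.maximum(la, lb)
        out = (hi + np.log(np.exp(la - hi) + np.exp(lb - hi))) / LN10
    else:
        out = la / LN10
    if np.any(~np.isfinite(out)):
        raise ValueError("bi-exponential mean is not finite (overflow?)")
    return out if out.ndim else float(out)


def halving_time(fit: BiExpFit | BiExpParams) -> float:
    """First-phase tumor-load halving time in days, ln(2)/alpha."""
    p = fit.params if isinstance(fit, BiExpFit) else fit
    if p.alpha <= 0:
        raise ValueError("halving time needs alpha > 0")
    return math.log(2.0) / p.alpha * DAYS_PER_MONTH


# ---------------------------------------------------------------------------
# internal parameterisation: x = (u, v, w, beta) with A=B+e^u, B=e^v, alpha=e^w

_B_FLOOR = -30.0  # v below this is treated as B = 0


def _unpack(x):
    u, v, w, beta = x
    B = math.exp(v) if v > _B_FLOOR else 0.0
    # keep A strictly above B even when the first phase degenerates
    gap = max(math.exp(u), B * 1e-12 + 1e-300)
    return B + gap, math.exp(w), B, beta


def _pack(params: BiExpParams):
    u = math.log(params.A - params.B)
    v = math.log(params.B) if params.B > 0 else _B_FLOOR - 10.0
    return np.array([u, v, math.log(params.alpha), params.beta])


def _mu_and_grad(x, t, s):
    """Mean curve on LRATIO scale and its gradient wrt (u, v, w, beta)."""
    u, v, w, beta = x
    alpha = math.exp(min(w, 20.0))

    def _e(arg):
        return np.exp(np.clip(arg, -745.0, 300.0))

    ea = _e(u - alpha * s * t)              # exp(u) * e^{-alpha s t}
    eb = _e(v - beta * s * t) if v > _B_FLOOR else np.zeros_like(t)
    # second exponential also carries the e^v part of A at time scaling alpha
    ga = _e(v - alpha * s * t) if v > _B_FLOOR else np.zeros_like(t)
    tot = ea + eb + ga
    mu = np.log(tot) / LN10
    d_u = ea / tot / LN10
    d_v = (eb + ga) / tot / LN10
    d_w = -(alpha * s * t) * (ea + ga) / tot / LN10
    d_beta = -(s * t) * eb / tot / LN10
    return mu, np.stack([d_u, d_v, d_w, d_beta], axis=1)


def _mu(x, t, s):
    return _mu_and_grad(x, t, s)[0]


def _heuristic_starts(t, y, n_starts, rng):
    """Two-phase log-linear starts: split the series at candidate breaks,
    fit a line to each side, map slopes/intercepts to (A, alpha, B, beta)."""
    starts = []
    n = len(t)
    breaks = sorted({max(2, int(round(f * n))) for f in (0.2, 0.3, 0.45)})
    for k in breaks:
        if k >= n - 1:
            continue
        s1, i1 = np.polyfit(t[:k + 1], y[:k + 1], 1)
        s2, i2 = np.polyfit(t[k:], y[k:], 1)
        alpha = max(-s1 * LN10, 1e-3)
        beta = -s2 * LN10
        B = 10 ** min(i2, i1 - 0.3)
        A = max(10 ** i1 - B, B * 1.05 + 1e-8)
        starts.append(np.array([math.log(max(A - B, 1e-8)),
                                math.log(max(B, 1e-12)),
                                math.log(alpha), beta]))
    if not starts:  # short series: single-phase fallback
        s1, i1 = np.polyfit(t, y, 1)
        starts.append(np.array([i1 * LN10, _B_FLOOR - 10.0,
                                math.log(max(-s1 * LN10, 1e-3)), 0.01]))
    base = starts[:]
    while len(starts) < n_starts:
        x0 = base[rng.integers(len(base))].copy()
        x0 += rng.normal(0.0, [0.5, 1.0, 0.5, 0.02])
        starts.append(x0)
    return starts[:n_starts]


def _fit_ls(t, y, wts, s, x0, max_iter):
    """Weighted nonlinear least squares (no censoring): exact Tobit MLE."""
    sw = np.sqrt(wts)

    def resid(x):
        return sw * (_mu(x, t, s) - y)

    def jac(x):
        return sw[:, None] * _mu_and_grad(x, t, s)[1]

    sol = optimize.least_squares(resid, x0, jac=jac, method="lm",
                                 max_nfev=max_iter * 4)
    rss = float(np.sum(sol.fun ** 2))
    return sol.x, rss, bool(sol.success)


def _negll_tobit(theta, t, y, cens, wts, s, lql):
    """Weighted negative log-likelihood; theta = (u, v, w, beta, log_sigma).

    log_sigma is clamped to a numerically safe range; outside it the
    objective is effectively flat and the optimiser turns back.
    """
    x, logsig = theta[:4], float(np.clip(theta[4], -15.0, 10.0))
    sig = math.exp(logsig)
    mu, grad = _mu_and_grad(x, t, s)
    z = (y - mu) / sig
    nll = 0.0
    g = np.zeros(5)
    obs = ~cens
    if obs.any():
        zo, wo = z[obs], wts[obs]
        nll += float(np.sum(wo * (0.5 * zo ** 2 + logsig + 0.5 * math.log(2 * math.pi))))
        coef = wo * zo / sig  # d nll / d mu
        g[:4] -= grad[obs].T @ coef
        g[4] += float(np.sum(wo * (1.0 - zo ** 2)))
    if cens.any():
        zc = (lql - mu[cens]) / sig
        wc = wts[cens]
        logphi = special.log_ndtr(zc)
        nll -= float(np.sum(wc * logphi))
        # Mills-ratio term phi/Phi; asymptotically -z for far-left z
        with np.errstate(over="ignore"):
            ratio = np.where(
                zc < -30.0, -zc,
                np.exp(np.minimum(stats.norm.logpdf(zc) - logphi, 700.0)))
        coef = wc * ratio / sig
        g[:4] += grad[cens].T @ coef  # d(-logPhi)/dmu = +ratio/sig; dmu/dx = grad
        g[4] += float(np.sum(wc * ratio * zc))
    return nll, g


def fit_individual(patient: PatientTimeCourse,
                   init: BiExpParams | None = None,
                   weights: np.ndarray | None = None,
                   tau: float | None = None,
                   n_starts: int | None = None,
                   exp_base: str | None = None,
                   seed: int = 0,
                   defaults: dict | None = None) -> BiExpFit:
    """Censored-ML bi-exponential fit to one patient's LRATIO series.

    Measurements after *tau* (months) are ignored, giving the
    reduced-follow-up estimate rho_i^tau.  *init* and *n_starts* control the
    multi-start optimisation (deterministic given *seed*).
    """
    cfg = (defaults or load_defaults())["biexp"]
    exp_base = exp_base or cfg["exp_base"]
    n_starts = cfg["n_starts"] if n_starts is None else n_starts
    s = _rate_scale(exp_base)

    meas = patient.measurements
    if tau is not None:
        meas = [m for m in meas if m.time <= tau + 1e-9]
    if not meas:
        raise FitError("no measurements within tau")
    t = np.array([m.time for m in meas])
    y = np.array([math.log10(m.ratio_percent) for m in meas])
    cens = np.array([m.censored for m in meas])
    wts = np.array([m.weight for m in meas]) if weights is None \
        else np.asarray(weights, dtype=float)[: len(meas)]
    keep = wts > 0
    t, y, cens, wts = t[keep], y[keep], cens[keep], wts[keep]
    if cens.all():
        raise FitError("all measurements censored: likelihood uninformative")
    if int((~cens).sum()) < 2:
        raise FitError("need at least two uncensored measurements")
    lql = math.log10(patient.ql_percent)
    tau_out = float(t.max()) if tau is None else float(tau)

    rng = np.random.default_rng(seed)
    starts = ([_pack(init)] if init is not None else []) + \
        _heuristic_starts(t[~cens], y[~cens], n_starts, rng)
    starts = starts[:max(n_starts, 1)]

    n_eff = float(np.sum(wts))
    best = None
    if not cens.any():
        for x0 in starts:
            try:
                x, rss, ok = _fit_ls(t, y, wts, s, x0, cfg["max_iter"])
            except (ValueError, FloatingPointError):
                continue
            if best is None or rss < best[1] - 1e-12:
                best = (x, rss, ok)
        if best is None:
            raise FitError("all optimisation starts failed")
        x, rss, ok = best
        sigma2 = rss / n_eff
        ll = -0.5 * n_eff * (math.log(2 * math.pi * max(sigma2, 1e-300)) + 1.0)
    else:
        for x0 in starts:
            sig0 = max(np.std(y) * 0.3, 0.05)
            th0 = np.append(x0, math.log(sig0))
            try:
                sol = optimize.minimize(
                    _negll_tobit, th0, args=(t, y, cens, wts, s, lql),
                    jac=True, method="L-BFGS-B",
                    options={"maxiter": cfg["max_iter"]})
            except (ValueError, FloatingPointError):
                continue
            if np.isfinite(sol.fun) and (best is None or sol.fun < best[1] - 1e-9):
                best = (sol.x, sol.fun, bool(sol.success))
        if best is None:
            raise FitError("all optimisation starts failed")
        th, nll, ok = best
        x, sigma2, ll = th[:4], math.exp(th[4]) ** 2, -nll
    A, alpha, B, beta = _unpack(x)
    params = BiExpParams(A=A, alpha=alpha, B=B, beta=beta)
    return BiExpFit(params=params, sigma2=float(sigma2), tau=tau_out,
                    n_obs=int(len(t)), n_censored=int(cens.sum()),
                    loglik=float(ll), converged=ok,
                    ql_percent=patient.ql_percent, exp_base=exp_base)


def bootstrap_band(fit: BiExpFit, patient: PatientTimeCourse,
                   times: np.ndarray | None = None,
                   level: float | None = None,
                   n_boot: int | None = None,
                   seed: int = 0,
                   defaults: dict | None = None) -> ConfidenceBand:
    """Parametric-bootstrap point-wise band for the mean LRATIO curve.

    Replicates are simulated at the patient's observed design (times and
    weights up to fit.tau) with Gaussian noise of SD sigma_hat corrected for
    the fitted degrees of freedom, re-censored at the QL, refitted from the
    point estimate, and summarised by percentile envelopes.
    """
    cfg = (defaults or load_defaults())["biexp"]["bootstrap"]
    level = cfg["level"] if level is None else level
    n_boot = cfg["n_boot"] if n_boot is None else n_boot
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if not fit.converged:
        raise FitError("cannot bootstrap a non-converged fit")
    if times is None:
        times = np.arange(cfg["grid_start_months"],
                          cfg["grid_stop_months"] + 1e-9, cfg["grid_step_months"])
    times = np.asarray(times, dtype=float)
    s = _rate_scale(fit.exp_base)

    meas = [m for m in patient.measurements if m.time <= fit.tau + 1e-9]
    t = np.array([m.time for m in meas])
    wts = np.array([m.weight for m in meas])
    keep = wts > 0
    t, wts = t[keep], wts[keep]
    lql = math.log10(patient.ql_percent)
    x_hat = _pack(fit.params)
    mu_hat = _mu(x_hat, t, s)
    n, p = len(t), 4
    df = max(n - p, 1)
    sigma_hat = math.sqrt(fit.sigma2 * n / df)  # df-corrected noise SD

    # the replicate loop (simulate, re-censor, warm-started refit) runs in
    # a numba kernel; each replicate's noise SD is drawn from the scaled
    # inverse-chi-square law of the variance estimate, propagating the
    # sampling uncertainty of sigma_hat itself into the band
    from ._boot_core import band_curves

    curves = np.empty((n_boot, len(times)))
    band_curves(x_hat, t, wts, s, lql,
                sigma_hat if fit.sigma2 > 0 else 0.0, float(df),
                times.astype(float), n_boot, int(seed) % (2 ** 31 - 1),
                curves)
    bad = ~np.all(np.isfinite(curves), axis=1)
    n_fail = int(bad.sum())
    if n_fail:
        curves[bad] = np.nan
    fail_rate = n_fail / n_boot
    if fail_rate > cfg["max_refit_failure_rate"]:
        raise FitError(f"bootstrap refit failure rate {fail_rate:.1%} exceeds "
                       f"{cfg['max_refit_failure_rate']:.0%}")
    qlo, qhi = (1 - level) / 2, 1 - (1 - level) / 2
    lower = np.nanquantile(curves, qlo, axis=0)
    upper = np.nanquantile(curves, qhi, axis=0)
    return ConfidenceBand(times, lower, upper, level, n_boot, seed)


def fit_curve(times, lratio, weights=None, n_starts: int = 3,
              exp_base: str = "e", seed: int = 0,
              max_iter: int = 300) -> tuple[BiExpParams, float, bool]:
    """Uncensored weighted least-squares bi-exponential fit to a plain
    LRATIO series (used to summarise simulated trajectories).

    Returns (params, weighted RSS, converged).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(lratio, dtype=float)
    wts = np.ones_like(t) if weights is None else np.asarray(weights, float)
    s = _rate_scale(exp_base)
    rng = np.random.default_rng(seed)
    best = None
    for x0 in _heuristic_starts(t, y, n_starts, rng):
        try:
            x, rss, ok = _fit_ls(t, y, wts, s, x0, max_iter)
        except (ValueError, FloatingPointError):
            continue
        if best is None or rss < best[1] - 1e-12:
            best = (x, rss, ok)
    if best is None:
        raise FitError("all starts failed on the simulated series")
    x, rss, ok = best
    A, alpha, B, beta = _unpack(x)
    return BiExpParams(A=A, alpha=alpha, B=B, beta=beta), rss, ok


def fits_to_frame(fits: dict[str, BiExpFit]):
    """Fit results as a tidy table (patient_id, tau, A, alpha, ...)."""
    import pandas as pd

    rows = []
    for pid, f in fits.items():
        rows.append({
            "patient_id": pid, "tau": f.tau, "A": f.params.A,
            "alpha": f.params.alpha, "B": f.params.B, "beta": f.params.beta,
            "sigma2": f.sigma2, "n_obs": f.n_obs, "n_censored": f.n_censored,
            "converged": int(f.converged),
        })
    return pd.DataFrame(rows)
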
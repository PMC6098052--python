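"""Single-cell-based clonal-competition model of CML under TKI therapy.

Normal hematopoietic and leukemic stem cells share a niche and alternate
between a quiescent state A and a proliferative state Omega.  Each cell
carries an affinity ``a`` (propensity to remain in the pool): in A the
affinity grows by a fixed factor per step, in Omega it decays; cells whose
affinity falls below ``a_min`` while cycling differentiate out of the pool
and feed a mature (peripheral-blood) compartment through a fixed
amplification and an exponential lifespan.  Transition intensities are

    omega(a) = f_omega(N_Omega) * (a_min / a)      activation into cycle
    alpha(a) = f_alpha(N_A)     * (a / a_max)      return to quiescence

with decreasing sigmoids f of the compartment totals for normal cells.
Leukemic cells activate at an unregulated, crowding-insensitive rate
(``f_omega_leuk``) and cycle faster — the clonal advantage.  TKI exposure
(after a gradual naive->affected onset at rate ``r_trans``) adds a per-step
kill probability ``r_deg`` for affected leukemic cells in cycle and rescales
their activation/deactivation by ``f_omega_cml`` / ``f_alpha_cml``.

The measured BCR-ABL/ABL transcript ratio is approximated from the mature
compartments as ``n1 / (n1 + 2 n2) * 100`` % (the leukemic transcript is
counted once against two control-gene copies).
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._mech_core import run_core
from .config import HOURS_PER_MONTH, load_defaults


class MechConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MechBaseParams:
    """Base (non-screened) model parameters; see defaults.yaml."""

    n_stem: int
    a_min: float
    a_max: float
    bin_factor: float
    cycle_hours_normal: float
    cycle_hours_leukemic: float
    step_hours: float
    f_omega: tuple          # (min, max, half_frac, hill) vs N_Omega
    f_alpha: tuple          # (min, max, half_frac, hill) vs N_A
    f_omega_leuk: float
    pb_amplification: float
    pb_lifespan_days: float
    burn_in_steps: int
    kill_in_quiescence: bool = False

    def __post_init__(self):
        if not (0 < self.a_min < self.a_max):
            raise MechConfigError("need 0 < a_min < a_max")
        if self.bin_factor <= 1.0:
            raise MechConfigError("bin_factor (regeneration/differentiation "
                                  "factor) must exceed 1")
        if self.n_stem < 100:
            raise MechConfigError("n_stem must be at least 100")

    @classmethod
    def from_defaults(cls, defaults: dict | None = None) -> "MechBaseParams":
        b = (defaults or load_defaults())["mechanistic"]["base"]
        return cls(
            n_stem=int(b["n_stem"]), a_min=b["a_min"], a_max=b["a_max"],
            bin_factor=b["bin_factor"],
            cycle_hours_normal=b["cycle_hours_normal"],
            cycle_hours_leukemic=b["cycle_hours_leukemic"],
            step_hours=b["step_hours"],
            f_omega=(b["f_omega"]["min"], b["f_omega"]["max"],
                     b["f_omega"]["half_frac"], b["f_omega"]["hill"]),
            f_alpha=(b["f_alpha"]["min"], b["f_alpha"]["max"],
                     b["f_alpha"]["half_frac"], b["f_alpha"]["hill"]),
            f_omega_leuk=b["f_omega_leuk"],
            pb_amplification=b["pb_amplification"],
            pb_lifespan_days=b["pb_lifespan_days"],
            burn_in_steps=int(b["burn_in_steps"]),
            kill_in_quiescence=bool(b["kill_in_quiescence"]),
        )

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def n_bins(self) -> int:
        return int(math.floor(math.log(self.a_max / self.a_min)
                              / math.log(self.bin_factor))) + 1

    def affinity_grid(self) -> np.ndarray:
        return np.minimum(self.a_min * self.bin_factor ** np.arange(self.n_bins),
                          self.a_max)


@dataclass(frozen=True)
class MechConfig:
    """One screened parameter configuration theta."""

    f_omega_cml: float
    f_alpha_cml: float
    r_deg: float
    lratio_init: float
    r_trans: float

    def __post_init__(self):
        if not 0.0 <= self.r_deg < 1.0:
            raise MechConfigError("r_deg must lie in [0, 1)")
        if self.r_trans < 0:
            raise MechConfigError("r_trans must be >= 0")
        if self.f_omega_cml < 0 or self.f_alpha_cml < 0:
            raise MechConfigError("TKI multipliers must be >= 0")
        if self.lratio_init > 2.0 + 1e-12:
            raise MechConfigError("lratio_init above 2 (100%) is unattainable")

    def as_tuple(self):
        return (self.f_omega_cml, self.f_alpha_cml, self.r_deg,
                self.lratio_init, self.r_trans)


@dataclass
class MechState:
    nA: np.ndarray   # float, normal quiescent per affinity bin
    nO: np.ndarray   # float, normal cycling
    lA: np.ndarray   # int, leukemic TKI-naive quiescent
    lO: np.ndarray
    xA: np.ndarray   # int, leukemic TKI-affected quiescent
    xO: np.ndarray
    mature: np.ndarray  # [normal, leukemic] mature-cell counts
    tallies: np.ndarray = field(
        default_factory=lambda: np.zeros(6, dtype=np.int64))

    def copy(self) -> "MechState":
        return MechState(self.nA.copy(), self.nO.copy(), self.lA.copy(),
                         self.lO.copy(), self.xA.copy(), self.xO.copy(),
                         self.mature.copy(), self.tallies.copy())

    @property
    def lsc(self) -> int:
        return int(self.lA.sum() + self.lO.sum() + self.xA.sum() + self.xO.sum())


@dataclass
class SimTrajectory:
    times: np.ndarray               # months
    n1: np.ndarray                  # leukemic mature counts
    n2: np.ndarray                  # normal mature counts
    lsc: np.ndarray                 # leukemic stem-cell counts
    pb_ratio_percent: np.ndarray
    seed: int


def pb_ratio(n1: float, n2: float) -> float:
    """BCR-ABL/ABL in percent from mature cell counts."""
    if n1 < 0 or n2 < 0:
        raise ValueError("cell counts must be nonnegative")
    if n1 + n2 <= 0:
        raise ValueError("pb_ratio undefined for an empty mature compartment")
    return n1 / (n1 + 2.0 * n2) * 100.0


# ---------------------------------------------------------------------------
# mean-field engine (burn-in / initial condition)

def _mf_step(pools, base: MechBaseParams, a, leukemic_advantage: bool,
             renorm_to: float | None = None):
    """One mean-field step of a two-clone float system (untreated)."""
    nA, nO, lA, lO, m = pools
    K = len(a)
    fw_lo, fw_hi, fw_hf, fw_hill = base.f_omega
    fa_lo, fa_hi, fa_hf, fa_hill = base.f_alpha
    dt = base.step_hours
    N_A = nA.sum() + lA.sum()
    N_O = nO.sum() + lO.sum()
    fw = fw_lo if fw_hi <= fw_lo else \
        fw_lo + (fw_hi - fw_lo) / (1 + (N_O / (fw_hf * base.n_stem)) ** fw_hill)
    fa = fa_lo + (fa_hi - fa_lo) / (1 + (N_A / (fa_hf * base.n_stem)) ** fa_hill)
    inv_a, rel_a = base.a_min / a, a / base.a_max
    pa = 1 - np.exp(-fa * rel_a * dt)
    pw_n = 1 - np.exp(-fw * inv_a * dt)
    pw_l = 1 - np.exp(-base.f_omega_leuk * inv_a * dt) if leukemic_advantage else pw_n
    pdiv_n = dt / base.cycle_hours_normal
    pdiv_l = dt / base.cycle_hours_leukemic if leukemic_advantage else pdiv_n
    flux = [0.0, 0.0]
    res = []
    for i, (A, O, pw, pd) in enumerate([(nA, nO, pw_n, pdiv_n),
                                        (lA, lO, pw_l, pdiv_l)]):
        act, dea = A * pw, O * pa
        A2, O2 = A - act + dea, O - dea + act
        A3 = np.zeros(K)
        A3[1:] = A2[:-1]
        A3[-1] += A2[-1]
        O3 = np.zeros(K)
        O3[:-1] = O2[1:]
        flux[i] = O2[0]
        O3 *= (1 + pd)
        res.append((A3, O3))
    (nA, nO), (lA, lO) = res
    dec = math.exp(-dt / (base.pb_lifespan_days * 24.0))
    m = [m[0] * dec + base.pb_amplification * flux[0],
         m[1] * dec + base.pb_amplification * flux[1]]
    if renorm_to is not None:
        tot = lA.sum() + lO.sum()
        if tot > 0:
            f = renorm_to / tot
            lA, lO, m[1] = lA * f, lO * f, m[1] * f
    return [nA, nO, lA, lO, m]


_BURNIN_CACHE: dict[str, tuple] = {}


def _burned_in_pools(base: MechBaseParams):
    """Normal steady state and leukemic quasi-stationary shape (cached)."""
    key = base.digest()
    if key in _BURNIN_CACHE:
        return _BURNIN_CACHE[key]
    a = base.affinity_grid()
    K = len(a)
    nA = np.zeros(K)
    nA[-1] = float(base.n_stem)
    pools = [nA, np.zeros(K), np.zeros(K), np.zeros(K), [0.0, 0.0]]
    for _ in range(base.burn_in_steps):
        pools = _mf_step(pools, base, a, leukemic_advantage=False)
    norm = (pools[0].copy(), pools[1].copy(), pools[4][0])
    # leukemic quasi-stationary shape, renormalised each step, on top of the
    # frozen-size normal background
    ref = 100.0
    lA = np.zeros(K)
    lA[-1] = ref
    pools = [pools[0], pools[1], lA, np.zeros(K), [norm[2], 0.0]]
    for _ in range(base.burn_in_steps):
        pools = _mf_step(pools, base, a, leukemic_advantage=True, renorm_to=ref)
    leuk = (pools[2].copy(), pools[3].copy(), pools[4][1])
    _BURNIN_CACHE[key] = (norm, leuk)
    return norm, leuk


def init_state(config: MechConfig, base: MechBaseParams,
               rng: np.random.Generator) -> MechState:
    """Initial state: untreated quasi-steady pools mixed so that the mature
    readout matches ``10**lratio_init`` percent at t=0; all leukemic cells
    start TKI-naive."""
    (nA_s, nO_s, m_n_s), (lA_s, lO_s, m_l_s) = _burned_in_pools(base)
    n_norm = nA_s.sum() + nO_s.sum()
    n_leuk = lA_s.sum() + lO_s.sum()
    mn_pc = m_n_s / n_norm
    ml_pc = m_l_s / n_leuk
    R = 10.0 ** config.lratio_init / 100.0
    if R >= 1.0 - 1e-12:
        s = 1.0
    else:
        rho = 2.0 * R / (1.0 - R)          # target mature ratio m_l / m_n
        s = rho * mn_pc / (ml_pc + rho * mn_pc)
    scale_n = (1.0 - s) * base.n_stem / n_norm
    n_leuk_cells = int(round(s * base.n_stem))
    if n_leuk_cells < 1:
        raise MechConfigError(
            f"lratio_init={config.lratio_init} needs less than one leukemic "
            "stem cell at this n_stem; increase n_stem or lratio_init")
    shape = np.concatenate([lA_s, lO_s])
    shape = shape / shape.sum()
    counts = rng.multinomial(n_leuk_cells, shape)
    K = len(lA_s)
    lA = counts[:K].astype(np.int64)
    lO = counts[K:].astype(np.int64)
    m_n = m_n_s * scale_n
    m_l = (2.0 * R / (1.0 - R)) * m_n if s < 1.0 else ml_pc * n_leuk_cells
    return MechState(
        nA=nA_s * scale_n, nO=nO_s * scale_n,
        lA=lA, lO=lO,
        xA=np.zeros(K, dtype=np.int64), xO=np.zeros(K, dtype=np.int64),
        mature=np.array([m_n, m_l]),
    )


def _core_args(config: MechConfig, base: MechBaseParams):
    a = base.affinity_grid()
    fw_lo, fw_hi, fw_hf, fw_hill = base.f_omega
    fa_lo, fa_hi, fa_hf, fa_hill = base.f_alpha
    dt = base.step_hours
    return dict(
        inv_a=base.a_min / a, rel_a=a / base.a_max,
        fw_lo=fw_lo, fw_hi=fw_hi, fw_half=fw_hf * base.n_stem, fw_hill=fw_hill,
        fa_lo=fa_lo, fa_hi=fa_hi, fa_half=fa_hf * base.n_stem, fa_hill=fa_hill,
        fw_leuk=base.f_omega_leuk,
        f_omega_cml=config.f_omega_cml, f_alpha_cml=config.f_alpha_cml,
        r_deg=config.r_deg, r_trans=config.r_trans,
        kill_quiescent=base.kill_in_quiescence,
        p_div_n=dt / base.cycle_hours_normal,
        p_div_l=dt / base.cycle_hours_leukemic,
        dt=dt,
        mat_decay=math.exp(-dt / (base.pb_lifespan_days * 24.0)),
        amp=base.pb_amplification,
    )


def step(state: MechState, config: MechConfig, base: MechBaseParams,
         rng: np.random.Generator) -> MechState:
    """One simulation step (default 1 h); returns a new state and updates
    the event tallies (activations, deactivations, divisions, kills,
    differentiations, conversions) of the leukemic clone."""
    new = state.copy()
    args = _core_args(config, base)
    seed = int(rng.integers(2 ** 31 - 1))
    dummy = np.empty(0, dtype=np.int64)
    run_core(new.nA, new.nO, new.lA, new.lO, new.xA, new.xO, new.mature,
             n_steps=1, record_steps=dummy,
             out_n1=np.empty(0), out_n2=np.empty(0),
             out_lsc=np.empty(0, dtype=np.int64),
             seed=seed, tallies=new.tallies, **args)
    return new


def simulate(config: MechConfig, base: MechBaseParams | None = None,
             horizon_months: float = 60.0,
             sample_times: np.ndarray | None = None,
             seed: int = 0,
             defaults: dict | None = None) -> SimTrajectory:
    """Run the model from the treatment start and record (n1, n2, lsc,
    pb_ratio) at *sample_times* (months).  Deterministic given *seed*."""
    cfg = defaults or load_defaults()
    base = base or MechBaseParams.from_defaults(cfg)
    if sample_times is None:
        step_m = cfg["mechanistic"]["sim"]["sample_step_months"]
        sample_times = np.arange(0.0, horizon_months + 1e-9, step_m)
    sample_times = np.asarray(sample_times, dtype=float)
    if horizon_months < sample_times.max() - 1e-9:
        raise ValueError("horizon shorter than the last sample time")
    rng = np.random.default_rng(seed)
    state = init_state(config, base, rng)
    steps_per_month = HOURS_PER_MONTH / base.step_hours
    record_steps = np.round(sample_times * steps_per_month).astype(np.int64)
    n_steps = int(record_steps.max())
    out_n1 = np.empty(len(sample_times))
    out_n2 = np.empty(len(sample_times))
    out_lsc = np.empty(len(sample_times), dtype=np.int64)
    args = _core_args(config, base)
    run_core(state.nA, state.nO, state.lA, state.lO, state.xA, state.xO,
             state.mature, n_steps=n_steps, record_steps=record_steps,
             out_n1=out_n1, out_n2=out_n2, out_lsc=out_lsc,
             seed=int(rng.integers(2 ** 31 - 1)), tallies=state.tallies,
             **args)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = out_n1 + 2.0 * out_n2
        pb = np.where(denom > 0, out_n1 / np.where(denom > 0, denom, 1.0) * 100.0, 0.0)
    return SimTrajectory(times=sample_times, n1=out_n1, n2=out_n2,
                         lsc=out_lsc, pb_ratio_percent=pb, seed=seed)


def residual_lsc(trajectory: SimTrajectory, t: float) -> int:
    """Leukemic stem-cell count at the recorded time nearest to t months."""
    times = trajectory.times
    if t < times.min() - 1e-9 or t > times.max() + 1e-9:
        raise ValueError(f"t={t} outside recorded range "
                         f"[{times.min()}, {times.max()}]")
    return int(trajectory.lsc[int(np.argmin(np.abs(times - t)))])
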
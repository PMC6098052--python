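"""Virtual patient cohorts with the monitoring design of a five-year
first-line TKI trial: baseline, quarterly sampling to month 24, then
semi-annual sampling to month 60.

Each patient gets individual bi-exponential parameters drawn around the
arm's fixed effects (lognormal perturbations for the positive parameters
A, alpha, B; additive normal for beta, which may be negative), and the
observed LRATIO is the patient's curve plus Gaussian residual noise on the
log10 scale, left-censored at the quantification limit.  Ground-truth
parameters are retained so estimator recovery can be measured.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .biexp import BiExpParams, biexp_lratio
from .config import load_defaults
from .timecourse import ARMS, Cohort, Measurement, PatientTimeCourse


@dataclass
class PopulationParams:
    fixed: dict[str, BiExpParams]
    omega: dict[str, float]          # log_A, log_alpha, log_B, beta
    sigma_res: float
    ql_percent: float
    schedule: np.ndarray
    dropout_hazard: float = 0.0
    max_param_redraws: int = 10000

    def __post_init__(self):
        self.schedule = np.asarray(self.schedule, dtype=float)
        if self.sigma_res < 0 or any(v < 0 for v in self.omega.values()):
            raise ValueError("variability parameters must be >= 0")
        if self.schedule[0] != 0.0 or np.any(np.diff(self.schedule) <= 0):
            raise ValueError("schedule must start at 0 and strictly increase")

    @classmethod
    def from_defaults(cls, defaults: dict | None = None) -> "PopulationParams":
        cfg = defaults or load_defaults()
        pop = cfg["population"]
        fixed = {arm: BiExpParams(**pop[arm]) for arm in ARMS}
        return cls(fixed=fixed, omega=dict(pop["omega"]),
                   sigma_res=pop["sigma_res"], ql_percent=pop["ql_percent"],
                   schedule=default_schedule(cfg),
                   dropout_hazard=pop["dropout_hazard"],
                   max_param_redraws=pop["max_param_redraws"])


@dataclass
class TruePatientRecord:
    patient_id: str
    arm: str
    true_params: BiExpParams
    timecourse: PatientTimeCourse


def default_schedule(defaults: dict | None = None) -> np.ndarray:
    """Monitoring times in months: 0, 3, ..., 24, 30, ..., 60."""
    cfg = (defaults or load_defaults())["schedule"]
    dense = np.arange(0.0, cfg["dense_until_months"] + 1e-9, cfg["dense_step_months"])
    sparse = np.arange(cfg["dense_until_months"] + cfg["sparse_step_months"],
                       cfg["end_months"] + 1e-9, cfg["sparse_step_months"])
    return np.concatenate([dense, sparse])


def sample_patient_params(pop: PopulationParams, arm: str,
                          rng: np.random.Generator) -> BiExpParams:
    """Draw one patient's parameter tuple; redraws until A > B and alpha > 0
    (lognormal draws satisfy alpha > 0 by construction)."""
    fx = pop.fixed[arm]
    om = pop.omega
    for _ in range(pop.max_param_redraws):
        A = fx.A * np.exp(om["log_A"] * rng.standard_normal())
        alpha = fx.alpha * np.exp(om["log_alpha"] * rng.standard_normal())
        B = fx.B * np.exp(om["log_B"] * rng.standard_normal())
        beta = fx.beta + om["beta"] * rng.standard_normal()
        if A > B and alpha > 0:
            return BiExpParams(A=float(A), alpha=float(alpha),
                               B=float(B), beta=float(beta))
    raise ValueError("rejection sampling failed: A > B constraint "
                     "essentially never satisfied under these omegas")


def generate_timecourse(true_params: BiExpParams, pop: PopulationParams,
                        rng: np.random.Generator,
                        patient_id: str = "p0", arm: str = "imatinib",
                        exp_base: str = "e") -> PatientTimeCourse:
    """Sample the schedule, add residual noise, apply dropout and censoring."""
    times = pop.schedule
    if pop.dropout_hazard > 0:
        n_keep = 1
        for _ in times[1:]:
            if rng.uniform() < pop.dropout_hazard:
                break
            n_keep += 1
        times = times[:n_keep]
    mu = np.atleast_1d(biexp_lratio(times, true_params, exp_base))
    y = mu + pop.sigma_res * rng.standard_normal(len(times))
    lql = np.log10(pop.ql_percent)
    meas = [
        Measurement(time=float(t),
                    ratio_percent=pop.ql_percent if yi < lql else float(10 ** yi),
                    censored=bool(yi < lql))
        for t, yi in zip(times, y)
    ]
    return PatientTimeCourse(patient_id, arm, meas, pop.ql_percent)


def generate_cohort(n_per_arm: int, pop: PopulationParams | None = None,
                    seed: int = 0,
                    defaults: dict | None = None
                    ) -> tuple[Cohort, list[TruePatientRecord]]:
    """Seeded two-arm cohort plus the ground-truth records."""
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    pop = pop or PopulationParams.from_defaults(defaults)
    rng = np.random.default_rng(seed)
    patients, truth = [], []
    for arm in ARMS:
        for i in range(n_per_arm):
            pid = f"{arm[:3]}{i:04d}"
            params = sample_patient_params(pop, arm, rng)
            tc = generate_timecourse(params, pop, rng, patient_id=pid, arm=arm)
            patients.append(tc)
            truth.append(TruePatientRecord(pid, arm, params, tc))
    cohort = Cohort(patients, {"generator": "biexp-population", "seed": str(seed),
                               "ql_percent": repr(pop.ql_percent)})
    return cohort, truth


def generate_from_mechanistic(config, base=None, pop_noise: dict | None = None,
                              seed: int = 0,
                              patient_id: str = "m0", arm: str = "imatinib",
                              defaults: dict | None = None) -> PatientTimeCourse:
    """A virtual patient whose underlying kinetics come from the
    single-cell clonal-competition model rather than the bi-exponential
    population: the simulated peripheral-blood ratio is sampled at the
    monitoring schedule, noise and censoring applied as usual.

    *pop_noise* keys: sigma_res, ql_percent (defaults from the population
    block).
    """
    from .mechanistic import MechBaseParams, simulate

    cfg = defaults or load_defaults()
    base = base or MechBaseParams.from_defaults(cfg)
    noise = {"sigma_res": cfg["population"]["sigma_res"],
             "ql_percent": cfg["population"]["ql_percent"]}
    noise.update(pop_noise or {})
    schedule = default_schedule(cfg)
    rng = np.random.default_rng(seed)
    sim_seed = int(rng.integers(2 ** 31 - 1))
    traj = simulate(config, base, horizon_months=float(schedule[-1]),
                    sample_times=schedule, seed=sim_seed, defaults=cfg)
    floor = cfg["mechanistic"]["sim"]["pb_floor_percent"]
    y = np.log10(np.maximum(traj.pb_ratio_percent, floor))
    y = y + noise["sigma_res"] * rng.standard_normal(len(schedule))
    ql = noise["ql_percent"]
    lql = np.log10(ql)
    meas = [Measurement(time=float(t),
                        ratio_percent=ql if yi < lql else float(10 ** yi),
                        censored=bool(yi < lql))
            for t, yi in zip(schedule, y)]
    return PatientTimeCourse(patient_id, arm, meas, ql)


def truth_to_frame(truth: list[TruePatientRecord]):
    import pandas as pd

    return pd.DataFrame([
        {"patient_id": r.patient_id, "arm": r.arm, "A": r.true_params.A,
         "alpha": r.true_params.alpha, "B": r.true_params.B,
         "beta": r.true_params.beta}
        for r in truth
    ])
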
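"""Shared fixtures.

The coarse screen table and the end-to-end cross-validation run are
expensive (minutes); they are session-scoped and shared by the simulator
sign-structure, cross-validation and stem-cell-interval tests.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

from cmlkinetics.biexp import bootstrap_band, fit_individual
from cmlkinetics.config import load_defaults
from cmlkinetics.matching import find_suitable
from cmlkinetics.mechanistic import MechBaseParams
from cmlkinetics.screen import GridSpec, run_screen
from cmlkinetics.synthetic import generate_cohort, generate_from_mechanistic
from cmlkinetics.timecourse import model_filter

ACCEPT_SEED = 1

_hyp_settings.register_profile("repro", derandomize=True, deadline=None)
_hyp_settings.load_profile("repro")


@pytest.fixture(scope="session")
def defaults():
    return load_defaults()


@pytest.fixture(scope="session")
def mech_base(defaults):
    return MechBaseParams.from_defaults(defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(5, seed=42)


@pytest.fixture(scope="session")
def coarse_table(mech_base, defaults):
    """3^5 screen at the package's desk-scale settings (3 replicates)."""
    grid = GridSpec.from_defaults("coarse_grid", defaults, replicates=3)
    return run_screen(grid, mech_base, seed=ACCEPT_SEED, defaults=defaults)


@pytest.fixture(scope="session")
def crossval_run(coarse_table, defaults):
    """20 virtual patients generated from the mechanistic model, fitted and
    matched at tau = 24, 36, 48 and 60 months (reduced-follow-up study)."""
    rng = np.random.default_rng(ACCEPT_SEED)
    valid = coarse_table.valid_indices()
    n_boot = defaults["crossval"]["n_boot_band"]
    taus = list(defaults["matching"]["tau_list_months"]) + \
        [defaults["matching"]["full_tau_months"]]
    patients, fits, sets = {}, {}, {}
    i = 0
    while len(patients) < 20:
        idx = int(rng.choice(valid))
        pid = f"cv{i:03d}"
        i += 1
        patient = generate_from_mechanistic(
            coarse_table.entries[idx].config,
            seed=int(rng.integers(2 ** 31 - 1)), patient_id=pid,
            defaults=defaults)
        try:
            fit = fit_individual(patient, n_starts=3, seed=ACCEPT_SEED,
                                 defaults=defaults)
        except Exception:  # noqa: BLE001
            continue
        if not model_filter(fit):
            continue
        per_tau = {}
        for tau in taus:
            f_tau = fit_individual(patient, tau=tau, n_starts=3,
                                   seed=ACCEPT_SEED, defaults=defaults)
            if not model_filter(f_tau):
                continue
            band = bootstrap_band(f_tau, patient, n_boot=n_boot,
                                  seed=ACCEPT_SEED, defaults=defaults)
            per_tau[tau] = find_suitable(coarse_table, band, tau,
                                         fit=f_tau, patient_id=pid)
        if 60.0 not in per_tau or len(per_tau[60.0]) == 0:
            continue
        patients[pid] = patient
        fits[pid] = fit
        sets[pid] = per_tau
    return {"patients": patients, "fits": fits, "sets": sets,
            "table": coarse_table}
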
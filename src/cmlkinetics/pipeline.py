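"""End-to-end, configuration-driven orchestration of the analysis.

Stages (in run order): screen (for mechanistically generated cohorts),
synth, filter, fit, band, match, predict, crossval, report.  Every stage
seeds its randomness from the root seed through named SeedSequence spawns,
so a rerun with the same config reproduces every CSV byte-for-byte.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .biexp import FitError, bootstrap_band, fit_individual, fits_to_frame
from .cohort_stats import alpha_beta_correlation, compare_arms, mean_response_curve
from .config import load_defaults, merge_config
from .matching import (accuracy_curve, find_suitable, lsc_prediction_interval,
                       pb_prediction_interval, summary_correlations)
from .mechanistic import MechBaseParams
from .screen import GridSpec, LookupTable, load_table, run_screen, save_table
from .synthetic import (generate_cohort, generate_from_mechanistic,
                        truth_to_frame)
from .timecourse import (Cohort, apply_statistics_filter, model_filter,
                         prediction_filter, read_cohort, write_cohort)

log = logging.getLogger("cmlkinetics.pipeline")

STAGES = ("screen", "synth", "filter", "fit", "band", "match", "predict",
          "crossval", "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _stage_seed(root_seed: int, stage: str) -> int:
    import zlib

    ss = np.random.SeedSequence([root_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def default_run_config() -> dict:
    """Desk-scale demo configuration (20 patients, coarse screen)."""
    return {
        "seed": 0,
        "out_dir": "results",
        "cohort": {
            "source": "mechanistic",      # population | mechanistic | file
            "path": None,                 # for source=file
            "n_per_arm": 10,
        },
        "screen": {
            "enabled": True,
            "grid": "coarse_grid",
            "table_dir": None,            # load instead of simulate
            "n_jobs": 1,
        },
        "fitting": {"n_starts": 5},
        "band": {"n_boot": 300},
        "matching": {},
    }


class PipelineRun:
    def __init__(self, run_config: dict | None = None,
                 defaults: dict | None = None):
        self.cfg = merge_config(default_run_config(), run_config)
        self.defaults = defaults or load_defaults()
        self.out = Path(self.cfg["out_dir"])
        self.seed = int(self.cfg["seed"])
        self.manifest: dict = {"config": self.cfg, "version": __version__,
                               "stages": {}}
        self.table: LookupTable | None = None
        self.cohort: Cohort | None = None
        self.retained: list[str] = []
        self.fits: dict = {}
        self.bands: dict = {}
        self.suitable: dict = {}
        self.crossval_sets: dict = {}

    # -- helpers ------------------------------------------------------------
    def _record(self, stage: str, t0: float, **info):
        self.manifest["stages"][stage] = {
            "seed": _stage_seed(self.seed, stage),
            "wall_time_s": round(time.time() - t0, 3), **info}
        log.info("stage %s done: %s", stage, info)

    def _write_manifest(self):
        self.out.mkdir(parents=True, exist_ok=True)
        (self.out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, default=str))

    # -- stages -------------------------------------------------------------
    def stage_screen(self):
        t0 = time.time()
        sc = self.cfg["screen"]
        base = MechBaseParams.from_defaults(self.defaults)
        if sc.get("table_dir"):
            try:
                self.table = load_table(sc["table_dir"], base)
            except Exception as exc:  # noqa: BLE001
                raise PipelineError("screen", str(exc)) from exc
        elif sc.get("enabled", True):
            g = sc.get("grid", "coarse_grid")
            if isinstance(g, dict):      # inline axis-value lists
                grid = GridSpec(values=g["values"],
                                replicates=g.get("replicates", 3))
            else:
                grid = GridSpec.from_defaults(g, self.defaults)
            self.table = run_screen(grid, base, seed=_stage_seed(self.seed, "screen"),
                                    n_jobs=sc.get("n_jobs", 1),
                                    defaults=self.defaults)
            save_table(self.table, self.out / "table")
        else:
            raise PipelineError("screen",
                                "screen disabled and no table_dir given")
        self._record("screen", t0, n_entries=len(self.table.entries),
                     n_valid=int(len(self.table.valid_indices())))

    def stage_synth(self):
        t0 = time.time()
        co = self.cfg["cohort"]
        seed = _stage_seed(self.seed, "synth")
        if co["source"] == "file":
            if not co.get("path"):
                raise PipelineError("synth", "source=file needs cohort.path")
            ql = self.defaults["population"]["ql_percent"]
            self.cohort = read_cohort(co["path"], ql)
        elif co["source"] == "population":
            self.cohort, truth = generate_cohort(co["n_per_arm"], seed=seed,
                                                 defaults=self.defaults)
            truth_to_frame(truth).to_csv(self.out / "truth.csv", index=False)
        elif co["source"] == "mechanistic":
            if self.table is None:
                raise PipelineError("synth", "mechanistic cohort needs the "
                                    "screen stage (or a table_dir) first")
            rng = np.random.default_rng(seed)
            valid = self.table.valid_indices()
            if len(valid) == 0:
                raise PipelineError("synth", "no biphasic-valid table entries")
            patients, rows = [], []
            n_tot = 2 * co["n_per_arm"]
            for i in range(n_tot):
                idx = int(rng.choice(valid))
                mech = self.table.entries[idx].config
                arm = "imatinib" if i % 2 == 0 else "dasatinib"
                pid = f"mech{i:04d}"
                patients.append(generate_from_mechanistic(
                    mech, seed=int(rng.integers(2 ** 31 - 1)),
                    patient_id=pid, arm=arm, defaults=self.defaults))
                rows.append({"patient_id": pid, "config_index": idx,
                             **{k: getattr(mech, k) for k in
                                ("f_omega_cml", "f_alpha_cml", "r_deg",
                                 "lratio_init", "r_trans")}})
            self.cohort = Cohort(patients, {"generator": "mechanistic",
                                            "seed": str(seed)})
            pd.DataFrame(rows).to_csv(self.out / "truth_configs.csv",
                                      index=False)
        else:
            raise PipelineError("synth", f"unknown source {co['source']!r}")
        self.out.mkdir(parents=True, exist_ok=True)
        write_cohort(self.cohort, self.out / "cohort.csv")
        self._record("synth", t0, n_patients=len(self.cohort))

    def stage_filter(self):
        t0 = time.time()
        report = apply_statistics_filter(self.cohort, self.defaults)
        report.to_frame().to_csv(self.out / "filter_report.csv", index=False)
        self.retained = report.retained_ids
        self._record("filter", t0, n_in=len(self.cohort),
                     n_retained=len(self.retained))

    def stage_fit(self):
        t0 = time.time()
        n_starts = self.cfg["fitting"].get("n_starts")
        seed = _stage_seed(self.seed, "fit")
        n_fail = 0
        for pid in self.retained:
            try:
                self.fits[pid] = fit_individual(
                    self.cohort.by_id(pid), n_starts=n_starts,
                    seed=seed, defaults=self.defaults)
            except FitError:
                n_fail += 1
        fits_to_frame(self.fits).to_csv(self.out / "fits.csv", index=False)
        self._record("fit", t0, n_fits=len(self.fits), n_failed=n_fail)

    def stage_band(self):
        t0 = time.time()
        n_boot = self.cfg["band"].get("n_boot")
        seed = _stage_seed(self.seed, "band")
        rows = []
        for pid, fit in self.fits.items():
            band = bootstrap_band(fit, self.cohort.by_id(pid),
                                  n_boot=n_boot, seed=seed,
                                  defaults=self.defaults)
            self.bands[pid] = band
            for tt, lo, hi in zip(band.times, band.lower, band.upper):
                rows.append({"patient_id": pid, "time": tt, "lower": lo,
                             "upper": hi, "level": band.level})
        pd.DataFrame(rows).to_csv(self.out / "bands.csv", index=False)
        self._record("band", t0, n_bands=len(self.bands))

    def stage_match(self):
        t0 = time.time()
        if self.table is None:
            raise PipelineError("match", "no look-up table available")
        full_tau = self.defaults["matching"]["full_tau_months"]
        for pid, fit in self.fits.items():
            if not model_filter(fit):
                continue
            self.suitable[pid] = find_suitable(
                self.table, self.bands[pid], min(fit.tau, full_tau),
                fit=fit, patient_id=pid)
        self._record("match", t0, n_matched=sum(
            1 for s in self.suitable.values() if len(s) > 0),
            n_unmatched=sum(1 for s in self.suitable.values() if len(s) == 0))

    def stage_predict(self):
        t0 = time.time()
        t_pred = self.defaults["matching"]["classify_time_months"]
        rows = []
        for pid, s in self.suitable.items():
            pb = pb_prediction_interval(s, self.table, t_pred)
            lsc = lsc_prediction_interval(s, self.table, t_pred)
            best = self.table.entries[s.best].config if len(s) else None
            rows.append({
                "patient_id": pid, "tau": s.tau, "n_suitable": len(s),
                "best_r_deg": best.r_deg if best else np.nan,
                "best_r_trans": best.r_trans if best else np.nan,
                "best_f_omega_cml": best.f_omega_cml if best else np.nan,
                "best_f_alpha_cml": best.f_alpha_cml if best else np.nan,
                "best_lratio_init": best.lratio_init if best else np.nan,
                "pb_lower": pb.pb_lower, "pb_upper": pb.pb_upper,
                "delta_bcr_abl": pb.delta_bcr_abl,
                "lsc_min": lsc.lsc_min, "lsc_max": lsc.lsc_max,
                "delta_lsc": lsc.delta_lsc,
            })
        pd.DataFrame(rows).to_csv(self.out / "predictions.csv", index=False)
        # cohort-level descriptives
        fits_by_arm = {}
        for pid, f in self.fits.items():
            fits_by_arm.setdefault(self.cohort.by_id(pid).arm, []).append(f)
        try:
            comp = [compare_arms(fits_by_arm, p) for p in ("alpha", "beta")]
            pd.DataFrame([{
                "parameter": c.parameter, "scale": c.scale, "z": c.z,
                "p_value": c.p_value,
                **{f"mean_{a}": c.mean[a] for a in c.mean},
                **{f"se_{a}": c.se[a] for a in c.se},
                **{f"n_{a}": c.n[a] for a in c.n},
            } for c in comp]).to_csv(self.out / "arm_comparison.csv",
                                     index=False)
        except ValueError as exc:
            log.warning("arm comparison skipped: %s", exc)
        mean_response_curve(self.cohort).to_csv(
            self.out / "mean_response.csv", index=False)
        if len(self.fits) >= 10:
            corr = alpha_beta_correlation(list(self.fits.values()))
            (self.out / "alpha_beta_corr.json").write_text(
                json.dumps(corr, indent=1))
        self._record("predict", t0, n_predictions=len(rows))

    def stage_crossval(self):
        t0 = time.time()
        taus = list(self.defaults["matching"]["tau_list_months"])
        full_tau = self.defaults["matching"]["full_tau_months"]
        n_boot = self.cfg.get("crossval", {}).get(
            "n_boot_band", self.defaults["crossval"]["n_boot_band"])
        seed = _stage_seed(self.seed, "crossval")
        eligible = [pid for pid in self.fits
                    if prediction_filter(self.cohort.by_id(pid),
                                         defaults=self.defaults)]
        per_patient: dict[str, dict[float, object]] = {}
        for pid in eligible:
            patient = self.cohort.by_id(pid)
            sets = {}
            for tau in taus + [full_tau]:
                try:
                    fit = fit_individual(
                        patient, tau=tau,
                        n_starts=self.cfg["fitting"].get("n_starts"),
                        seed=seed, defaults=self.defaults)
                    if not model_filter(fit):
                        continue
                    band = bootstrap_band(fit, patient, n_boot=n_boot,
                                          seed=seed, defaults=self.defaults)
                    sets[tau] = find_suitable(self.table, band, tau,
                                              fit=fit, patient_id=pid)
                except FitError:
                    continue
            per_patient[pid] = sets
        acc = accuracy_curve(per_patient, self.table, tau_list=taus,
                             full_tau=full_tau, defaults=self.defaults)
        acc.to_csv(self.out / "accuracy.csv", index=False)
        full_sets = {pid: s[full_tau] for pid, s in per_patient.items()
                     if full_tau in s}
        try:
            corr = summary_correlations(self.fits, full_sets, self.table,
                                        seed=seed)
            corr.to_csv(self.out / "correlations.csv", index=False)
        except Exception as exc:  # noqa: BLE001 - optional summary
            log.warning("summary correlations skipped: %s", exc)
        self.crossval_sets = per_patient
        self._record("crossval", t0, n_eligible=len(eligible))

    def stage_report(self):
        t0 = time.time()
        make_report(self.out)
        self._record("report", t0)

    def run(self, stages: list[str] | None = None) -> Path:
        order = list(STAGES) if stages is None else stages
        if self.cfg["cohort"]["source"] != "mechanistic" and stages is None:
            # screening is only a prerequisite for mechanistic cohorts
            order = [s for s in order if s != "screen"]
            if self.cfg["screen"].get("enabled", True) or \
                    self.cfg["screen"].get("table_dir"):
                order.insert(4, "screen")   # before match
        self.out.mkdir(parents=True, exist_ok=True)
        for stage in order:
            try:
                getattr(self, f"stage_{stage}")()
            except PipelineError:
                self._write_manifest()
                raise
            except Exception as exc:  # noqa: BLE001
                self._write_manifest()
                raise PipelineError(stage, str(exc)) from exc
            self._write_manifest()
        return self.out


def run_pipeline(run_config: dict | None = None,
                 defaults: dict | None = None,
                 stages: list[str] | None = None) -> Path:
    """Run the configured stages and return the results directory."""
    return PipelineRun(run_config, defaults).run(stages)


def make_report(results_dir: str | Path) -> Path:
    """Render a static summary (markdown + PNG panels) from stage outputs.

    Missing stages are listed rather than fatal; an empty results directory
    is an error.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(results_dir)
    if not out.exists() or not any(out.iterdir()):
        raise FileNotFoundError(f"no pipeline outputs in {out}")
    missing, lines = [], ["# Treatment-response analysis report", ""]

    def _png(name):
        return out / f"panel_{name}.png"

    # panel 1: mean response curves
    if (out / "mean_response.csv").exists():
        df = pd.read_csv(out / "mean_response.csv")
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for arm, grp in df.groupby("arm"):
            mid = (grp["bin_start"] + grp["bin_end"]) / 2
            ax.errorbar(mid, grp["mean_lratio"], yerr=grp["sd"], label=arm,
                        capsize=2)
        ax.set_xlabel("months"), ax.set_ylabel("LRATIO"), ax.legend()
        fig.tight_layout(), fig.savefig(_png("mean_response")), plt.close(fig)
        lines.append("![mean response](panel_mean_response.png)")
    else:
        missing.append("mean_response")
    # panel 2: alpha-beta scatter
    if (out / "fits.csv").exists():
        df = pd.read_csv(out / "fits.csv")
        fig, ax = plt.subplots(figsize=(4, 3.2))
        ax.scatter(df["alpha"], df["beta"], s=12)
        ax.set_xlabel("alpha (/month)"), ax.set_ylabel("beta (/month)")
        ax.set_xscale("log")
        fig.tight_layout(), fig.savefig(_png("alpha_beta")), plt.close(fig)
        lines.append("![alpha vs beta](panel_alpha_beta.png)")
    else:
        missing.append("fits")
    # panel 3: FP/FN vs tau
    if (out / "accuracy.csv").exists():
        df = pd.read_csv(out / "accuracy.csv")
        pooled = df[df["pooled"] == 1]
        fig, ax = plt.subplots(figsize=(4, 3.2))
        ax.plot(pooled["tau"], 100 * pooled["fp_rate"], "o-", label="FP")
        ax.plot(pooled["tau"], 100 * pooled["fn_rate"], "s-", label="FN")
        ax.set_xlabel("observation period (months)"), ax.set_ylabel("rate (%)")
        ax.legend()
        fig.tight_layout(), fig.savefig(_png("accuracy")), plt.close(fig)
        lines.append("![accuracy](panel_accuracy.png)")
    else:
        missing.append("accuracy")
    # panel 4: LSC interval width vs fit variance
    if (out / "predictions.csv").exists():
        df = pd.read_csv(out / "predictions.csv")
        fits = pd.read_csv(out / "fits.csv") if (out / "fits.csv").exists() else None
        fig, ax = plt.subplots(figsize=(4, 3.2))
        if fits is not None:
            merged = df.merge(fits, on="patient_id")
            ax.scatter(merged["sigma2"], merged["delta_lsc"], s=12)
            ax.set_xlabel("residual variance"), ax.set_ylabel("delta lsc")
        fig.tight_layout(), fig.savefig(_png("lsc_intervals")), plt.close(fig)
        lines.append("![lsc intervals](panel_lsc_intervals.png)")
    else:
        missing.append("predictions")
    # panel 5: example band
    if (out / "bands.csv").exists():
        df = pd.read_csv(out / "bands.csv")
        pid = df["patient_id"].iloc[0]
        sel = df[df["patient_id"] == pid]
        fig, ax = plt.subplots(figsize=(4, 3.2))
        ax.fill_between(sel["time"], sel["lower"], sel["upper"], alpha=0.4)
        ax.set_title(f"confidence band: {pid}")
        ax.set_xlabel("months"), ax.set_ylabel("LRATIO")
        fig.tight_layout(), fig.savefig(_png("band")), plt.close(fig)
        lines.append("![band](panel_band.png)")
    else:
        missing.append("bands")
    if missing:
        lines += ["", "Missing stage outputs: " + ", ".join(missing)]
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
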
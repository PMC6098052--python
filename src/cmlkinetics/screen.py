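"""Five-parameter simulation screen and its persistent look-up table.

Each screened configuration theta = (f_omega_cml, f_alpha_cml, r_deg,
lratio_init, r_trans) is simulated a few times, the replicate-mean
peripheral-blood ratio is summarised by an (uncensored) bi-exponential fit,
and the fitted tuple is stored together with the leukemic stem-cell series.
The table is what patient matching searches: a population of "virtual
patients" covering the plausible response space.  The full-scale default
grid (10 x 16 x 13 x 10 x 13 values) contains 270,400 configurations; a
3^5 coarse grid is provided for desk-scale runs.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .biexp import BiExpParams, FitError, biexp_lratio, fit_curve
from .config import load_defaults
from .mechanistic import MechBaseParams, MechConfig, simulate
from .timecourse import model_filter

GRID_AXES = ("lratio_init", "r_deg", "r_trans", "f_omega_cml", "f_alpha_cml")


class TableFormatError(ValueError):
    pass


def _axis_values(ax: dict) -> list[float]:
    n = int(ax["num"])
    if ax.get("scale", "linear") == "log":
        vals = np.geomspace(ax["start"], ax["stop"], n)
    else:
        vals = np.linspace(ax["start"], ax["stop"], n)
    return [float(v) for v in vals]


@dataclass
class GridSpec:
    """Value lists for the five screened parameters plus replication."""

    values: dict[str, list[float]]
    replicates: int = 3

    def __post_init__(self):
        for axis in GRID_AXES:
            if axis not in self.values or not self.values[axis]:
                raise ValueError(f"grid axis {axis!r} missing or empty")

    @classmethod
    def from_defaults(cls, which: str = "default_grid",
                      defaults: dict | None = None,
                      replicates: int | None = None) -> "GridSpec":
        cfg = defaults or load_defaults()
        grid = cfg["screen"][which]
        reps = cfg["mechanistic"]["sim"]["replicates"] if replicates is None \
            else replicates
        return cls(values={ax: _axis_values(grid[ax]) for ax in GRID_AXES},
                   replicates=reps)

    @property
    def size(self) -> int:
        n = 1
        for axis in GRID_AXES:
            n *= len(self.values[axis])
        return n

    def to_jsonable(self) -> dict:
        return {"values": self.values, "replicates": self.replicates}


def build_grid(spec: GridSpec) -> list[MechConfig]:
    """Cartesian product in fixed lexicographic order, lratio_init
    outermost (validates every value against the model's ranges)."""
    configs = []
    for li, rd, rt, fo, fa in itertools.product(
            *(spec.values[ax] for ax in GRID_AXES)):
        configs.append(MechConfig(f_omega_cml=fo, f_alpha_cml=fa, r_deg=rd,
                                  lratio_init=li, r_trans=rt))
    return configs


@dataclass
class LookupEntry:
    config: MechConfig
    rho_sim: BiExpParams | None
    fit_rss: float
    biphasic_valid: bool
    lsc_series: np.ndarray

    def curve(self, times, exp_base: str = "e"):
        if self.rho_sim is None:
            raise FitError("entry has no valid bi-exponential summary")
        return biexp_lratio(times, self.rho_sim, exp_base)


@dataclass
class LookupTable:
    entries: list[LookupEntry]
    grid: GridSpec
    base_params_digest: str
    sample_times: np.ndarray
    exp_base: str = "e"
    _curve_cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if len(self.entries) != self.grid.size:
            raise TableFormatError(
                f"entry count {len(self.entries)} != grid size {self.grid.size}")

    def valid_indices(self) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.entries)
                         if e.biphasic_valid], dtype=int)

    def curves(self, times) -> tuple[np.ndarray, np.ndarray]:
        """(valid entry indices, matrix of their LRATIO curves at *times*).

        Cached per time grid: matching evaluates the same monthly grid for
        every patient.
        """
        times = np.asarray(times, dtype=float)
        key = (round(float(times[0]), 6), round(float(times[-1]), 6), len(times))
        if key not in self._curve_cache:
            idx = self.valid_indices()
            mat = np.empty((len(idx), len(times)))
            for row, i in enumerate(idx):
                mat[row] = self.entries[i].curve(times, self.exp_base)
            self._curve_cache[key] = (idx, mat)
        return self._curve_cache[key]

    def lsc_at(self, t: float) -> np.ndarray:
        """LSC counts of all entries at the sample time nearest t."""
        j = int(np.argmin(np.abs(self.sample_times - t)))
        return np.array([e.lsc_series[j] for e in self.entries])


def _screen_one(config: MechConfig, base: MechBaseParams, sample_times,
                replicates: int, seed: int, index: int,
                floor: float, exp_base: str) -> LookupEntry:
    pb = np.zeros(len(sample_times))
    lsc = np.zeros(len(sample_times))
    for rep in range(replicates):
        rep_seed = int(np.random.SeedSequence([seed, index, rep])
                       .generate_state(1)[0] % (2 ** 31 - 1))
        traj = simulate(config, base, horizon_months=float(sample_times[-1]),
                        sample_times=sample_times, seed=rep_seed)
        pb += traj.pb_ratio_percent
        lsc += traj.lsc
    pb /= replicates
    lsc /= replicates
    # summarise only the quantifiable part of the trajectory: once the
    # replicate-mean ratio falls below the floor the series carries no
    # information about the decline any more
    quant = pb >= floor
    y = np.log10(np.maximum(pb, floor))
    try:
        if quant.sum() < 8:
            raise FitError("trajectory below the quantification floor")
        rho, rss, ok = fit_curve(sample_times[quant], y[quant],
                                 exp_base=exp_base, seed=index)
        valid = bool(ok and model_filter(rho))
    except FitError:
        rho, rss, valid = None, float("nan"), False
    return LookupEntry(config=config, rho_sim=rho, fit_rss=float(rss),
                       biphasic_valid=valid, lsc_series=lsc)


def run_screen(grid: GridSpec, base: MechBaseParams | None = None,
               sim_opts: dict | None = None, seed: int = 0,
               n_jobs: int = 1, defaults: dict | None = None,
               chunk_dir: str | Path | None = None) -> LookupTable:
    """Simulate and summarise every configuration of *grid*.

    Per-config seeds are derived from (seed, config index, replicate), so
    the table is reproducible independently of chunking or parallelism.
    With *chunk_dir*, finished chunks are written to disk and re-used on a
    rerun (resumable screen).
    """
    cfg = defaults or load_defaults()
    base = base or MechBaseParams.from_defaults(cfg)
    opts = dict(cfg["mechanistic"]["sim"])
    opts.update(sim_opts or {})
    sample_times = np.arange(0.0, opts["horizon_months"] + 1e-9,
                             opts["sample_step_months"])
    exp_base = cfg["biexp"]["exp_base"]
    configs = build_grid(grid)
    # warm the burn-in cache once before forking workers
    from .mechanistic import _burned_in_pools
    _burned_in_pools(base)

    def work(i, c):
        return _screen_one(c, base, sample_times, grid.replicates, seed, i,
                           opts["pb_floor_percent"], exp_base)

    chunk = 2000
    entries: list[LookupEntry] = []
    for start in range(0, len(configs), chunk):
        part = configs[start:start + chunk]
        cpath = None
        if chunk_dir is not None:
            cpath = Path(chunk_dir) / f"chunk_{start:07d}.csv"
            if cpath.exists():
                df = pd.read_csv(cpath)
                entries.extend(_entries_from_frame(df, part))
                continue
        if n_jobs == 1:
            got = [work(start + j, c) for j, c in enumerate(part)]
        else:
            got = Parallel(n_jobs=n_jobs)(
                delayed(work)(start + j, c) for j, c in enumerate(part))
        entries.extend(got)
        if cpath is not None:
            cpath.parent.mkdir(parents=True, exist_ok=True)
            _entries_to_frame(got).to_csv(cpath, index=False)
    return LookupTable(entries=entries, grid=grid,
                       base_params_digest=base.digest(),
                       sample_times=sample_times, exp_base=exp_base)


def _entries_to_frame(entries: list[LookupEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        c = e.config
        p = e.rho_sim
        rows.append({
            "f_omega_cml": c.f_omega_cml, "f_alpha_cml": c.f_alpha_cml,
            "r_deg": c.r_deg, "lratio_init": c.lratio_init,
            "r_trans": c.r_trans,
            "A": p.A if p else np.nan, "alpha": p.alpha if p else np.nan,
            "B": p.B if p else np.nan, "beta": p.beta if p else np.nan,
            "fit_rss": e.fit_rss, "biphasic_valid": int(e.biphasic_valid),
            "lsc_series": ";".join(f"{v:.10g}" for v in e.lsc_series),
        })
    return pd.DataFrame(rows)


def _entries_from_frame(df: pd.DataFrame,
                        configs: list[MechConfig]) -> list[LookupEntry]:
    entries = []
    for row, config in zip(df.itertuples(index=False), configs):
        if np.isfinite(row.A):
            rho = BiExpParams(A=row.A, alpha=row.alpha, B=row.B, beta=row.beta)
        else:
            rho = None
        lsc = np.array([float(v) for v in str(row.lsc_series).split(";")])
        entries.append(LookupEntry(config=config, rho_sim=rho,
                                   fit_rss=float(row.fit_rss),
                                   biphasic_valid=bool(row.biphasic_valid),
                                   lsc_series=lsc))
    return entries


def save_table(table: LookupTable, path: str | Path) -> None:
    """Persist as a directory: meta.json + entries.csv (lossless)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "base_params_digest": table.base_params_digest,
        "sample_times": [float(t) for t in table.sample_times],
        "grid": table.grid.to_jsonable(),
        "exp_base": table.exp_base,
        "n_entries": len(table.entries),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    _entries_to_frame(table.entries).to_csv(path / "entries.csv", index=False)


def load_table(path: str | Path,
               base: MechBaseParams | None = None) -> LookupTable:
    """Load a saved table; if *base* is given its digest must match the one
    the table was built with."""
    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
        df = pd.read_csv(path / "entries.csv")
    except (OSError, json.JSONDecodeError, pd.errors.ParserError) as exc:
        raise TableFormatError(f"cannot read look-up table at {path}: {exc}") \
            from exc
    if base is not None and base.digest() != meta["base_params_digest"]:
        raise TableFormatError(
            "look-up table was built with different base parameters "
            f"(digest {meta['base_params_digest']} != {base.digest()})")
    grid = GridSpec(values=meta["grid"]["values"],
                    replicates=meta["grid"]["replicates"])
    configs = build_grid(grid)
    if len(df) != len(configs):
        raise TableFormatError(
            f"table at {path} is truncated: {len(df)} rows, "
            f"expected {len(configs)}")
    return LookupTable(entries=_entries_from_frame(df, configs), grid=grid,
                       base_params_digest=meta["base_params_digest"],
                       sample_times=np.array(meta["sample_times"]),
                       exp_base=meta.get("exp_base", "e"))
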
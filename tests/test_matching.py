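"""Matching and prediction logic on constructed look-up tables, where every
expected outcome can be computed by hand or by brute force."""
import math

import numpy as np
import pytest

from cmlkinetics.biexp import BiExpFit, BiExpParams, ConfidenceBand, biexp_lratio
from cmlkinetics.matching import (accuracy_curve, classify,
                                  find_suitable, lsc_prediction_interval,
                                  pb_prediction_interval, rank_distance,
                                  summary_correlations)
from cmlkinetics.mechanistic import MechConfig
from cmlkinetics.screen import GridSpec, LookupEntry, LookupTable

TIMES = np.arange(0.0, 61.0)


def _entry(params, lsc_level=1000.0, valid=True, **cfg):
    base_cfg = dict(f_omega_cml=0.3, f_alpha_cml=1.0, r_deg=0.1,
                    lratio_init=1.5, r_trans=0.01)
    base_cfg.update(cfg)
    return LookupEntry(config=MechConfig(**base_cfg), rho_sim=params,
                       fit_rss=0.0, biphasic_valid=valid,
                       lsc_series=np.full(len(TIMES), lsc_level))


def _table(entries):
    grid = GridSpec(values={
        "lratio_init": [float(i) / 100 for i in range(len(entries))],
        "r_deg": [0.1], "r_trans": [0.01], "f_omega_cml": [0.3],
        "f_alpha_cml": [1.0]})
    return LookupTable(entries=entries, grid=grid, base_params_digest="x",
                       sample_times=TIMES)


def _flat_entry(level_lratio, **kw):
    """Entry whose curve is (essentially) constant at level_lratio."""
    B = 10 ** level_lratio
    return _entry(BiExpParams(A=B * 1e-6 + B, alpha=50.0, B=B, beta=0.0), **kw)


def _band(center_params, width, times=TIMES, level=0.95):
    mid = biexp_lratio(times, center_params)
    return ConfidenceBand(times, mid - width, mid + width, level, 100, 0)


P1 = BiExpParams(A=40.0, alpha=0.8, B=0.2, beta=0.03)
P2 = BiExpParams(A=40.0, alpha=0.8, B=0.2, beta=0.06)
P3 = BiExpParams(A=4.0, alpha=0.4, B=0.02, beta=0.01)


def _fit(params, sigma2=0.04):
    return BiExpFit(params=params, sigma2=sigma2, tau=60.0, n_obs=15,
                    n_censored=0, loglik=0.0, converged=True)


class TestFindSuitable:
    def test_infinite_band_keeps_all_valid(self):
        table = _table([_entry(P1), _entry(P2), _entry(P3, valid=False)])
        band = ConfidenceBand(TIMES, np.full_like(TIMES, -1e6),
                              np.full_like(TIMES, 1e6), 0.95, 100, 0)
        s = find_suitable(table, band, 60.0, fit=_fit(P1))
        assert set(s.config_indices) == {0, 1}

    def test_zero_width_band_keeps_exact_match_only(self):
        table = _table([_entry(P1), _entry(P2)])
        s = find_suitable(table, _band(P1, 0.0), 60.0, fit=_fit(P1))
        assert list(s.config_indices) == [0]

    def test_constructed_band_selects_the_one_inside(self):
        table = _table([_entry(P1), _entry(P2), _entry(P3)])
        band = _band(P2, 0.12)
        s = find_suitable(table, band, 60.0, fit=_fit(P2))
        # brute-force pointwise oracle
        expected = []
        for i, p in enumerate((P1, P2, P3)):
            curve = biexp_lratio(TIMES, p)
            if np.all((curve >= band.lower) & (curve <= band.upper)):
                expected.append(i)
        assert sorted(s.config_indices) == expected == [1]

    def test_distance_ranking_best_first(self):
        table = _table([_entry(P1), _entry(P2)])
        s = find_suitable(table, _band(P1, 2.0), 60.0, fit=_fit(P1))
        assert s.best == 0
        assert s.distances[0] <= s.distances[1]

    def test_band_widening_is_monotone(self):
        table = _table([_entry(P1), _entry(P2), _entry(P3)])
        narrow = find_suitable(table, _band(P1, 0.3), 60.0, fit=_fit(P1))
        wide = find_suitable(table, _band(P1, 1.0), 60.0, fit=_fit(P1))
        assert set(narrow.config_indices) <= set(wide.config_indices)

    def test_nested_tau_shrinks_set(self):
        # with the same band, a longer containment horizon can only remove
        table = _table([_entry(P1), _entry(P2), _entry(P3)])
        band = _band(P1, 0.4)
        s24 = find_suitable(table, band, 24.0, fit=_fit(P1))
        s60 = find_suitable(table, band, 60.0, fit=_fit(P1))
        assert set(s60.config_indices) <= set(s24.config_indices)


class TestRankDistance:
    def test_identical_curves(self):
        assert rank_distance(P1, P1, TIMES) == 0.0

    def test_constant_offset(self):
        c = 0.7
        shifted = BiExpParams(A=P1.A * 10 ** c, alpha=P1.alpha,
                              B=P1.B * 10 ** c, beta=P1.beta)
        assert rank_distance(shifted, P1, TIMES) == pytest.approx(c, rel=1e-9)

    def test_matches_direct_summation(self):
        grid = np.arange(0.0, 25.0)
        got = rank_distance(P1, P3, grid)
        acc = 0.0
        for t in grid:
            d = (math.log10(P1.A * math.exp(-P1.alpha * t)
                            + P1.B * math.exp(-P1.beta * t))
                 - math.log10(P3.A * math.exp(-P3.alpha * t)
                              + P3.B * math.exp(-P3.beta * t)))
            acc += d * d
        assert got == pytest.approx(math.sqrt(acc / len(grid)), rel=1e-12)


class TestPredictionIntervals:
    def test_singleton_pb_interval_zero_width(self):
        table = _table([_entry(P1)])
        s = find_suitable(table, _band(P1, 0.5), 60.0, fit=_fit(P1))
        pi = pb_prediction_interval(s, table, 60.0)
        assert pi.delta_bcr_abl == 0.0

    def test_envelope_is_minmax(self):
        entries = [_flat_entry(-1.0), _flat_entry(-2.0), _flat_entry(-1.5)]
        table = _table(entries)
        s = find_suitable(table, ConfidenceBand(
            TIMES, np.full_like(TIMES, -10.0), np.full_like(TIMES, 10.0),
            0.95, 100, 0), 60.0)
        pi = pb_prediction_interval(s, table, 60.0)
        assert pi.pb_lower == pytest.approx(-2.0, abs=1e-6)
        assert pi.pb_upper == pytest.approx(-1.0, abs=1e-6)
        assert pi.delta_bcr_abl == pytest.approx(1.0, abs=1e-6)

    def test_superset_envelope_never_narrower(self):
        entries = [_flat_entry(-1.0), _flat_entry(-2.0), _flat_entry(-3.0)]
        table = _table(entries)
        from cmlkinetics.matching import SuitableSet
        sub = SuitableSet("p", 60.0, [0, 1], [0.0, 0.1])
        sup = SuitableSet("p", 60.0, [0, 1, 2], [0.0, 0.1, 0.2])
        w_sub = pb_prediction_interval(sub, table, 60.0).delta_bcr_abl
        w_sup = pb_prediction_interval(sup, table, 60.0).delta_bcr_abl
        assert w_sup >= w_sub

    def test_lsc_interval_log_width(self):
        entries = [_entry(P1, lsc_level=100.0), _entry(P2, lsc_level=10000.0)]
        table = _table(entries)
        from cmlkinetics.matching import SuitableSet
        s = SuitableSet("p", 60.0, [0, 1], [0.0, 0.1])
        li = lsc_prediction_interval(s, table, 60.0)
        assert li.lsc_min == 100.0 and li.lsc_max == 10000.0
        assert li.delta_lsc == pytest.approx(2.0)
        assert li.delta_lsc_defined

    def test_extinct_clone_flags_undefined_delta(self):
        entries = [_entry(P1, lsc_level=0.0), _entry(P2, lsc_level=500.0)]
        table = _table(entries)
        from cmlkinetics.matching import SuitableSet
        s = SuitableSet("p", 60.0, [0, 1], [0.0, 0.1])
        li = lsc_prediction_interval(s, table, 60.0)
        assert not li.delta_lsc_defined
        assert li.lsc_min == 0.0 and li.lsc_max == 500.0

    def test_empty_set_flagged(self):
        table = _table([_entry(P1)])
        from cmlkinetics.matching import SuitableSet
        empty = SuitableSet("p", 60.0, [], [])
        assert pb_prediction_interval(empty, table, 60.0).empty
        assert lsc_prediction_interval(empty, table, 60.0).empty


class TestClassify:
    def _setup(self):
        # flat curves with known five-year values
        levels = [-2.0, -1.0, -1.5, -2.5, -0.5, -0.8, -3.0]
        table = _table([_flat_entry(v) for v in levels])
        from cmlkinetics.matching import SuitableSet
        reduced = SuitableSet("p", 24.0, [0, 1, 2], [0.0, 0.1, 0.2])  # env [-2,-1]
        full = SuitableSet("p", 60.0, [3, 4, 5], [0.0, 0.1, 0.2])     # env [-2.5,-0.5]
        return table, reduced, full

    def test_printed_membership_semantics(self):
        table, reduced, full = self._setup()
        c = classify(reduced, full, table, t=60.0)
        # members: -2,-1,-1.5 inside both -> TP; -2.5,-0.5,-0.8 inside full
        # only -> FN
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 3, 0, 0)
        assert c.total == 6

    def test_identical_sets_no_errors(self):
        table, reduced, _ = self._setup()
        c = classify(reduced, reduced, table, t=60.0)
        assert c.fp == 0 and c.fn == 0 and c.tp == len(reduced)

    def test_margin_member_is_false_positive(self):
        # reduced envelope strictly wider than full: the margin member is FP
        levels = [-3.0, -0.5, -2.0, -1.2, -2.8]
        table = _table([_flat_entry(v) for v in levels])
        from cmlkinetics.matching import SuitableSet
        reduced = SuitableSet("p", 24.0, [0, 1, 4], [0.0, 0.1, 0.2])  # [-3,-0.5]
        full = SuitableSet("p", 60.0, [2, 3], [0.0, 0.1])             # [-2,-1.2]
        c = classify(reduced, full, table, t=60.0)
        # -2.8 inside reduced only -> FP
        assert c.fp >= 1
        assert c.total == 5

    def test_empty_set_unclassifiable(self):
        table, reduced, _ = self._setup()
        from cmlkinetics.matching import SuitableSet
        empty = SuitableSet("p", 60.0, [], [])
        assert classify(reduced, empty, table).unclassifiable

    def test_partition_counts(self):
        table, reduced, full = self._setup()
        c = classify(reduced, full, table, t=60.0)
        union = set(reduced.config_indices) | set(full.config_indices)
        assert c.total == len(union)


class TestAccuracyCurve:
    def test_identical_sets_zero_rates_and_single_patient_pooling(self):
        table, reduced, full = TestClassify()._setup()
        per_patient = {"p": {24.0: reduced, 36.0: reduced, 48.0: reduced,
                             60.0: reduced}}
        df = accuracy_curve(per_patient, table, tau_list=[24.0, 36.0, 48.0],
                            full_tau=60.0)
        pooled = df[df["pooled"] == 1]
        assert np.allclose(pooled["fp_rate"], 0.0)
        assert np.allclose(pooled["fn_rate"], 0.0)
        single = df[df["pooled"] == 0]
        for tau in (24.0, 36.0, 48.0):
            p = pooled[pooled["tau"] == tau].iloc[0]
            s = single[single["tau"] == tau].iloc[0]
            assert p["fp_rate"] == s["fp_rate"]


class TestSummaryCorrelations:
    def test_monotone_pairs_give_r_one(self):
        n = 12
        entries, fits, sets = [], {}, {}
        from cmlkinetics.matching import SuitableSet
        for i in range(n):
            entries.append(_entry(P1, lsc_level=100.0 * (i + 1),
                                  r_trans=0.001 * (i + 1),
                                  f_omega_cml=0.05 * (i + 1)))
        table = _table(entries)
        for i in range(n):
            pid = f"p{i}"
            params = BiExpParams(A=40, alpha=0.1 * (i + 1), B=0.2,
                                 beta=0.005 * (i + 1))
            fits[pid] = _fit(params, sigma2=0.01 * (i + 1))
            sets[pid] = SuitableSet(pid, 60.0, [i], [0.0])
        df = summary_correlations(fits, sets, table, n_boot=100)
        by = df.set_index("pair")
        assert by.loc["alpha_vs_best_r_trans", "r"] == pytest.approx(1.0)
        assert by.loc["beta_vs_best_f_omega_cml", "r"] == pytest.approx(1.0)
        assert by.loc["beta_vs_lsc_max", "r"] == pytest.approx(1.0)

    def test_independent_pairs_ci_covers_zero(self):
        rng = np.random.default_rng(0)
        n = 100
        entries, fits, sets = [], {}, {}
        from cmlkinetics.matching import SuitableSet
        rts = rng.permutation(np.linspace(0.001, 0.02, n))
        for i in range(n):
            entries.append(_entry(P1, lsc_level=1000.0, r_trans=float(rts[i])))
        table = _table(entries)
        alphas = rng.permutation(np.linspace(0.2, 1.5, n))
        for i in range(n):
            pid = f"p{i}"
            fits[pid] = _fit(BiExpParams(A=40, alpha=float(alphas[i]), B=0.2,
                                         beta=0.03))
            sets[pid] = SuitableSet(pid, 60.0, [i], [0.0])
        df = summary_correlations(fits, sets, table, n_boot=300, seed=1)
        row = df.set_index("pair").loc["alpha_vs_best_r_trans"]
        assert abs(row["r"]) < 0.25
        assert row["ci_low"] <= 0.0 <= row["ci_high"]

    def test_too_few_patients_rejected(self):
        table = _table([_entry(P1)])
        from cmlkinetics.matching import MatchingError, SuitableSet
        with pytest.raises(MatchingError):
            summary_correlations({"p": _fit(P1)},
                                 {"p": SuitableSet("p", 60.0, [0], [0.0])},
                                 table)
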
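"""FRAP assembly, normalization chain, exponential fit and group summaries."""

import numpy as np
import pytest

from ehtkit import frap
from ehtkit import stats as st
from ehtkit.exceptions import (
    AssemblyError,
    NoBleachDetected,
    NonPositivePrebleach,
    WindowError,
)
from ehtkit.synthetic import (
    FrapSimConfig,
    make_frap_dataset,
    make_scaled_recovery_traces,
)


def _recordings(design=None):
    design = design or frap.PhaseDesign()
    pre, fast, slow = design.times()
    return {
        "prebleach": {"times": pre, "roi": np.full(pre.size, 110.0), "background": np.full(pre.size, 10.0)},
        "fast": {"times": fast, "roi": np.full(fast.size, 50.0), "background": np.full(fast.size, 10.0)},
        "slow": {"times": slow, "roi": np.full(slow.size, 60.0), "background": np.full(slow.size, 10.0)},
    }


class TestAssembly:
    def test_default_design_sample_counts(self):
        pre, fast, slow = frap.PhaseDesign().times()
        assert (pre.size, fast.size, slow.size) == (30, 180, 21)
        trace = frap.assemble_trace(_recordings())
        assert trace.times.size == 231
        assert (trace.phases == "prebleach").sum() == 30

    def test_missing_phase_rejected(self):
        rec = _recordings()
        del rec["fast"]
        with pytest.raises(AssemblyError):
            frap.assemble_trace(rec)

    def test_overlapping_fast_slow_rejected(self):
        rec = _recordings()
        rec["slow"]["times"] = rec["fast"]["times"] + 0.5
        with pytest.raises(AssemblyError):
            frap.assemble_trace(rec)

    def test_drift_flag_truncates_slow_phase(self):
        with pytest.warns(UserWarning, match="drift"):
            trace = frap.assemble_trace(_recordings(), drift_flagged=True)
        assert (trace.phases == "slow").sum() == 0
        assert trace.drift_flagged


class TestNormalization:
    def test_worked_example(self):
        # prebleach 110, post 50, background 10 -> I_normalized = 0.4
        trace = frap.assemble_trace(_recordings())
        norm = frap.normalize_trace(trace)
        assert norm.i_normalized[0] == pytest.approx(0.4)
        assert norm.i_fsn.min() == pytest.approx(0.0)

    def test_no_bleach_detected(self):
        rec = _recordings()
        rec["fast"]["roi"][:] = 110.0
        rec["slow"]["roi"][:] = 110.0
        with pytest.raises(NoBleachDetected):
            frap.normalize_trace(frap.assemble_trace(rec))

    def test_nonpositive_prebleach(self):
        rec = _recordings()
        rec["prebleach"]["background"][:] = 120.0
        with pytest.raises(NonPositivePrebleach):
            frap.normalize_trace(frap.assemble_trace(rec))

    def test_zero_floor_scaling_identity(self):
        rec = _recordings()
        rec["fast"]["roi"][0] = 10.0  # background-subtracted minimum is 0
        norm = frap.normalize_trace(frap.assemble_trace(rec))
        assert np.allclose(norm.i_fsn, norm.i_normalized)

    @pytest.mark.parametrize("scale,offset", [(3.7, 0.0), (1.0, 55.0), (2.1, -4.0)])
    def test_scale_offset_invariance(self, scale, offset):
        traces, _ = make_frap_dataset(FrapSimConfig(noise_sd=0.03, seed=8))
        base = frap.normalize_trace(traces[0]).i_fsn
        t = traces[0]
        t2 = frap.FrapTrace(
            times=t.times,
            i_roi=scale * t.i_roi + offset,
            i_background=scale * t.i_background + offset,
            phases=t.phases,
        )
        assert np.max(np.abs(frap.normalize_trace(t2).i_fsn - base)) < 1e-10


class TestFitRecovery:
    def test_noise_free_identity(self):
        traces, _ = make_scaled_recovery_traces(
            FrapSimConfig(a_true=0.6, tau_true=0.01, noise_sd=0.0, seed=1)
        )
        fit = frap.fit_recovery(traces[0])
        assert abs(fit.A - 0.6) < 1e-4
        assert abs(fit.tau - 0.01) < 1e-6

    def test_flat_zero_trace(self):
        _, fast, slow = frap.PhaseDesign().times()
        t = np.concatenate([fast, slow])
        norm = frap.NormalizedTrace(
            times=t, i_fsn=np.zeros_like(t), i_normalized=np.zeros_like(t),
            floor=0.0, prebleach_mean=1.0,
        )
        assert frap.fit_recovery(norm).A < 0.01

    def test_thalf_tau_identity(self):
        traces, _ = make_scaled_recovery_traces(
            FrapSimConfig(a_true=0.5, tau_true=np.log(2) / 30.0, noise_sd=0.0, seed=2)
        )
        fit = frap.fit_recovery(traces[0])
        assert fit.t_half == pytest.approx(30.0, abs=1e-6)
        assert fit.t_half * fit.tau == pytest.approx(np.log(2.0), abs=0.0)

    def test_parameter_recovery_under_noise(self):
        cfg = FrapSimConfig(a_true=0.5, tau_true=0.005, noise_sd=0.05, n_traces=40, seed=9)
        traces, ledger = make_scaled_recovery_traces(cfg)
        fits = [frap.fit_recovery(t, compute_early_slope=False) for t in traces]
        assert np.median([abs(f.A - 0.5) / 0.5 for f in fits]) < 0.05
        assert np.median([abs(f.tau - 0.005) / 0.005 for f in fits]) < 0.10

    def test_noise_monotonicity_of_rmse(self):
        rmses = []
        for sd in (0.10, 0.05, 0.02):
            traces, _ = make_scaled_recovery_traces(
                FrapSimConfig(a_true=0.5, tau_true=0.01, noise_sd=sd, n_traces=30, seed=4)
            )
            fits = [frap.fit_recovery(t, compute_early_slope=False) for t in traces]
            rmses.append(np.sqrt(np.mean([(f.A - 0.5) ** 2 for f in fits])))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_too_few_samples(self):
        norm = frap.NormalizedTrace(
            times=np.arange(5.0) + 1, i_fsn=np.zeros(5), i_normalized=np.zeros(5),
            floor=0.0, prebleach_mean=1.0,
        )
        with pytest.raises(WindowError):
            frap.fit_recovery(norm)


class TestEarlySlope:
    def _norm(self, t, y):
        return frap.NormalizedTrace(
            times=t, i_fsn=y, i_normalized=y, floor=0.0, prebleach_mean=1.0
        )

    def test_exact_line(self):
        t = np.arange(31.0)
        assert frap.early_slope(self._norm(t, 0.02 * t)) == pytest.approx(0.02, abs=1e-12)

    def test_matches_closed_form_ls_oracle(self):
        t = np.arange(31.0)
        y = 0.5 * (1 - np.exp(-0.01 * t))
        slope = frap.early_slope(self._norm(t, y))
        tc = t - t.mean()
        oracle = float((tc @ y) / (tc @ tc))
        assert slope == pytest.approx(oracle, abs=1e-9)

    def test_too_few_samples_in_window(self):
        t = np.array([1.0, 2.0, 100.0, 120.0])
        with pytest.raises(WindowError):
            frap.early_slope(self._norm(t, np.zeros(4)), window_s=5.0)


class TestGroupSummaries:
    def test_two_group_ordering_and_test(self):
        fits = []
        for jt, a, seed in (("pol+-EC", 0.50, 21), ("pol--EC", 0.39, 22)):
            traces, _ = make_scaled_recovery_traces(
                FrapSimConfig(a_true=a, tau_true=0.01, noise_sd=0.05, n_traces=30,
                              junction_type=jt, seed=seed)
            )
            fits += [frap.fit_recovery(t) for t in traces]
        summary, tests = frap.summarize_groups(fits)
        med = summary.set_index("junction_type")["A"]
        assert med["pol+-EC"] > med["pol--EC"]
        p = tests[(tests["metric"] == "A")]["pvalue"].iloc[0]
        assert p < 0.05

    def test_single_observation_group_not_applicable(self):
        traces, _ = make_scaled_recovery_traces(FrapSimConfig(n_traces=5, seed=1))
        fits = [frap.fit_recovery(t) for t in traces]
        lone = frap.fit_recovery(
            make_scaled_recovery_traces(FrapSimConfig(n_traces=1, junction_type="HE-EC", seed=2))[0][0]
        )
        _, tests = frap.summarize_groups(fits + [lone])
        assert (tests["method"] == "not-applicable").all()

    def test_empty_input(self):
        summary, tests = frap.summarize_groups([])
        assert summary.empty and tests.empty

    def test_group_mean_curves_shared_time_base(self):
        traces, _ = make_scaled_recovery_traces(FrapSimConfig(n_traces=4, noise_sd=0.05, seed=3))
        curves = frap.group_mean_curves(traces)
        assert curves["time_s"].nunique() == traces[0].times.size
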
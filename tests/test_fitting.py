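"""Curve fitting: printed-cell round trips, information criteria, selection."""

import math

import numpy as np
import pytest

from iegkin.fitting import (
    FitConfig,
    adjusted_r_squared,
    aic,
    fit_dac,
    fit_results_frame,
    fit_sac,
    select_model,
)
from iegkin.kinetics import DualActivationParams, KineticParams
from iegkin.synthetic import NOISELESS, NoiseModel, SamplingProtocol, gen_trace
from iegkin.traces import FluorescenceTrace

# Published per-cell fit parameters (non-degenerate rows only): single
# activations on the 20-180 min session grid, double activations on the
# 90-300 min dual-exposure grid.
SAC_CELLS = [
    ("28", 541.0, 0.03675, 0.00514, "IS1"),
    ("11", 1050.0, 0.02585, 0.00895, "IS1"),
    ("03", 596.0, 0.02569, 0.00592, "IS1"),
    ("38", 461.0, 0.03473, 0.00487, "IS1"),
    ("501", 1183.0, 0.0593, 0.01404, "IS1"),
    ("486", 1089.0, 0.10002, 0.014, "IS1"),
    ("430", 1471.0, 0.07198, 0.0079, "IS1"),
    ("233", 4894.0, 0.09777, 0.02089, "IS2"),
    ("228", 4856.0, 0.11699, 0.01537, "IS2"),
    ("66", 1164.0, 0.07322, 0.017, "IS2"),
    ("232", 1802.0, 0.04495, 0.02197, "IS2"),
]
DAC_CELLS = [
    ("420", 564.0, 0.27809, 0.01378, 88.38919),
    ("328", 1689.0, 0.05502, 0.01523, 76.87335),
]

PROTO = {"IS1": SamplingProtocol.is1(), "IS2": SamplingProtocol.is2()}


class TestRoundTrips:
    @pytest.mark.parametrize("cell,amp,kf,kd,session", SAC_CELLS)
    def test_sac_roundtrip_of_printed_cells(self, cell, amp, kf, kd, session):
        tr = gen_trace("SAC", KineticParams(amp, kf, kd), PROTO[session], NOISELESS)
        r = fit_sac(tr)
        assert r.converged and not r.degenerate_rates
        assert r.params.amplitude == pytest.approx(amp, rel=1e-3)
        assert r.params.k_f == pytest.approx(kf, rel=1e-3)
        assert r.params.k_d == pytest.approx(kd, rel=1e-3)

    @pytest.mark.parametrize("cell,amp,kf,kd,td", DAC_CELLS)
    def test_dac_roundtrip_of_printed_cells(self, cell, amp, kf, kd, td):
        tr = gen_trace("DAC", DualActivationParams(amp, kf, kd, t_d=td), PROTO["IS2"], NOISELESS)
        r = fit_dac(tr)
        assert r.converged
        assert r.params.amplitude == pytest.approx(amp, rel=1e-3)
        assert r.params.k_f == pytest.approx(kf, rel=1e-3)
        assert r.params.k_d == pytest.approx(kd, rel=1e-3)
        assert r.params.t_d == pytest.approx(td, rel=1e-3)

    def test_initialisation_robustness(self):
        # adding more deterministic restarts does not change the optimum
        tr = gen_trace("SAC", KineticParams(1183.0, 0.0593, 0.01404), PROTO["IS1"], NOISELESS)
        base = fit_sac(tr)
        extra = tuple((10 ** u, 10 ** v) for u in (-2.5, -1.5, -0.7) for v in (-3.0, -1.8))
        wide = fit_sac(tr, FitConfig(extra_rate_starts=extra))
        assert wide.params.k_f == pytest.approx(base.params.k_f, rel=1e-3)
        assert wide.params.k_d == pytest.approx(base.params.k_d, rel=1e-3)


class TestGoodnessOfFit:
    def test_adjusted_r_squared_examples(self):
        assert adjusted_r_squared(0.0, 1.0, 17, 3) == 1.0
        assert adjusted_r_squared(5.0, 5.0, 20, 2) <= 0.0
        assert adjusted_r_squared(0.04, 1.0, 17, 3) == pytest.approx(1 - 0.04 * 16 / 13)

    def test_adjusted_r_squared_degenerate_inputs(self):
        assert math.isnan(adjusted_r_squared(1.0, 0.0, 17, 3))
        with pytest.raises(ValueError):
            adjusted_r_squared(1.0, 1.0, 4, 3)

    def test_aic_examples(self):
        assert aic(1700.0, 17, 3) == pytest.approx(17 * math.log(100) + 8)
        assert aic(10.0, 20, 4) - aic(10.0, 20, 3) == pytest.approx(2.0)
        assert aic(5.0, 20, 3) - aic(10.0, 20, 3) == pytest.approx(-20 * math.log(2))
        assert aic(0.0, 17, 3) == -math.inf
        with pytest.raises(ValueError):
            aic(-1.0, 17, 3)


class TestFitBehaviour:
    def test_all_zero_trace_not_activated(self, is1):
        tr = FluorescenceTrace("z", is1.time_points, np.zeros(17))
        r = fit_sac(tr)
        assert (not r.converged) or math.isnan(r.adj_r2) or r.params.amplitude < 1e-6
        assert select_model([r]) is None

    def test_stderr_positive_on_noisy_trace(self, is1, rng):
        p = KineticParams(1000.0, 0.0369, 0.016)
        tr = gen_trace("SAC", p, is1, NoiseModel(scale=0.01, floor_du=0.0), rng)
        r = fit_sac(tr)
        errs = np.array(list(r.stderr.values()))
        assert np.all(np.isfinite(errs)) and np.all(errs > 0)

    def test_too_few_points_rejected(self):
        tr = FluorescenceTrace("s", np.arange(4.0), np.ones(4))
        with pytest.raises(ValueError):
            fit_sac(tr)
        tr5 = FluorescenceTrace("s", np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            fit_dac(tr5)

    def test_equal_rate_trace_triggers_shared_rate_refit(self, is1):
        k = 0.03
        vals = 1000.0 * k * is1.time_points * np.exp(-k * is1.time_points)
        tr = FluorescenceTrace("d", is1.time_points, vals)
        r = fit_sac(tr)
        assert r.degenerate_rates
        assert r.n_params == 2
        assert r.params.k_f == r.params.k_d == pytest.approx(k, rel=1e-3)

    def test_delayed_fit_shifts_origin(self, is2):
        p = KineticParams(900.0, 0.05, 0.012)
        tr = gen_trace("SAC_DELAYED", p, is2, NOISELESS, time_origin=60.0)
        r = fit_sac(tr, time_origin_offset=60.0)
        assert r.model_kind == "SAC_DELAYED"
        assert r.params.k_f == pytest.approx(0.05, rel=1e-3)

    def test_zero_delay_dac_is_twice_sac(self, is1):
        p = DualActivationParams(700.0, 0.06, 0.01, t_d=0.0)
        tr = gen_trace("DAC", p, is1, NOISELESS)
        r = fit_sac(tr)  # 2x amplitude single activation fits exactly
        assert r.params.amplitude == pytest.approx(1400.0, rel=1e-3)


class TestSelection:
    def test_sac_truth_selects_sac(self, is1):
        rng = np.random.default_rng(0)
        p = KineticParams(2000.0, 0.0369, 0.016)
        tr = gen_trace("SAC", p, is1, NoiseModel(scale=0.01, floor_du=1.0), rng)
        sel = select_model([fit_sac(tr), fit_dac(tr)])
        assert sel is not None and sel.model_kind == "SAC"

    def test_dac_truth_selects_dac(self, is1):
        rng = np.random.default_rng(0)
        p = DualActivationParams(2000.0, 0.0369, 0.016, t_d=60.0)
        tr = gen_trace("DAC", p, is1, NoiseModel(scale=0.05, floor_du=2.0), rng)
        sel = select_model([fit_sac(tr), fit_dac(tr)])
        assert sel is not None and sel.model_kind == "DAC"

    def test_flat_noise_trace_selects_nothing(self, is1):
        rng = np.random.default_rng(1)
        tr = FluorescenceTrace("n", is1.time_points, rng.normal(0.0, 5.0, 17))
        assert select_model([fit_sac(tr), fit_dac(tr)]) is None

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_model([])

    def test_threshold_monotonicity(self, is1):
        rng = np.random.default_rng(2)
        activated = {}
        traces = [
            gen_trace(
                "SAC",
                KineticParams(rng.uniform(50, 500), 0.0369, 0.016),
                is1,
                NoiseModel(scale=0.4, floor_du=10.0),
                rng,
                roi_id=f"r{i}",
            )
            for i in range(20)
        ]
        for thr in (0.3, 0.8):
            cfg = FitConfig(adj_r2_threshold=thr)
            activated[thr] = {
                tr.roi_id for tr in traces if select_model([fit_sac(tr, cfg)], cfg) is not None
            }
        assert activated[0.8] <= activated[0.3]


def test_fit_results_frame_columns(is1):
    tr = gen_trace("SAC", KineticParams(541.0, 0.03675, 0.00514), is1, NOISELESS)
    df = fit_results_frame({"28": fit_sac(tr), "none": None})
    assert "Amplitude(D.U.)" in df.columns and "Adj-R-sq" in df.columns
    assert df.loc[df["Cell No"] == "none", "flags"].iloc[0] == "not_activated"
    assert df.loc[df["Cell No"] == "28", "k_f(min^-1)"].iloc[0] == pytest.approx(0.03675, rel=1e-3)
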
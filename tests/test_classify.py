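"""Category truth table, ensemble fractions and reactivation statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from iegkin.classify import (
    ActivationTriple,
    ReactivationBin,
    SessionOutcome,
    categorize,
    chance_overlap,
    dac_fraction_comparison,
    ensemble_fractions,
    reactivation_probability,
    session_flags,
)


def _outcome(roi, session, kind):
    return SessionOutcome(roi, session, kind, None)


class TestTruthTable:
    def test_bijection_over_all_triples(self):
        cats = set()
        for a1, a2, b in itertools.product([0, 1], repeat=3):
            cats.add(categorize(ActivationTriple(bool(a1), bool(a2), bool(b))).category)
        assert cats == set(range(1, 9))

    @pytest.mark.parametrize(
        "triple,cat",
        [
            ((1, 1, 1), 1),
            ((1, 1, 0), 2),
            ((1, 0, 0), 3),
            ((0, 1, 0), 4),
            ((0, 0, 1), 5),
            ((1, 0, 1), 6),
            ((0, 1, 1), 7),
            ((0, 0, 0), 8),
        ],
    )
    def test_published_rows(self, triple, cat):
        assert categorize(ActivationTriple(*map(bool, triple))).category == cat


class TestSessionFlags:
    def test_is1_sac_is2_dac_is_all_contexts(self):
        t = session_flags(_outcome("r", "IS1", "SAC"), _outcome("r", "IS2", "DAC"))
        assert t.as_tuple() == (1, 1, 1)

    def test_delayed_only_is_context_b_only(self):
        t = session_flags(_outcome("r", "IS1", None), _outcome("r", "IS2", "SAC_DELAYED"))
        assert t.as_tuple() == (0, 0, 1)

    def test_nothing_selected(self):
        t = session_flags(_outcome("r", "IS1", None), _outcome("r", "IS2", None))
        assert t.as_tuple() == (0, 0, 0)

    def test_is1_dac_flags_context_a_only(self):
        # a double activation in the single-exposure session is a context
        # event plus a spontaneous one: it does not set a context-B flag
        t = session_flags(_outcome("r", "IS1", "DAC"), _outcome("r", "IS2", None))
        assert t.as_tuple() == (1, 0, 0)

    def test_roi_mismatch_rejected(self):
        with pytest.raises(ValueError):
            session_flags(_outcome("a", "IS1", None), _outcome("b", "IS2", None))


def _classified(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "roi_id",
            "a1",
            "a2",
            "b",
            "category",
            "is1_model",
            "is2_model",
            "is1_amplitude",
            "is1_adj_r2",
            "is2_adj_r2",
        ],
    )


class TestFractions:
    def test_all_category_3(self):
        df = _classified(
            [(f"r{i}", 1, 0, 0, 3, "SAC", "none", 800.0, 0.9, np.nan) for i in range(10)]
        )
        f = ensemble_fractions(df)
        assert f["frac_active_is1"] == 1.0
        assert f["frac_active_is2"] == 0.0
        assert f["frac_overlap_of_total"] == 0.0

    def test_single_category_1_roi(self):
        df = _classified([("r0", 1, 1, 1, 1, "SAC", "DAC", 800.0, 0.9, 0.9)])
        f = ensemble_fractions(df)
        for key in ("frac_active_is1", "frac_active_is2", "frac_overlap_of_total", "frac_ctxtB"):
            assert f[key] == 1.0

    def test_category_fractions_sum_to_one(self):
        rows = [(f"r{i}", 1, 0, 0, 3, "SAC", "none", 1.0, 0.9, np.nan) for i in range(3)]
        rows += [(f"s{i}", 0, 0, 0, 8, "none", "none", np.nan, np.nan, np.nan) for i in range(5)]
        f = ensemble_fractions(_classified(rows))
        assert sum(f["category_fractions"].values()) == pytest.approx(1.0)

    def test_overlap_bounded_by_session_fractions(self, rng):
        rows = []
        for i in range(200):
            a1, a2, b = rng.integers(0, 2, 3)
            cat = categorize(ActivationTriple(bool(a1), bool(a2), bool(b))).category
            rows.append((f"r{i}", a1, a2, b, cat, "SAC" if a1 else "none",
                         "DAC" if (a2 and b) else ("SAC" if a2 else ("SAC_DELAYED" if b else "none")),
                         1.0, 0.9, 0.9))
        f = ensemble_fractions(_classified(rows))
        assert f["frac_overlap_of_total"] <= min(f["frac_active_is1"], f["frac_active_is2"]) + 1e-12
        for k, v in f.items():
            if isinstance(v, float):
                assert -1e-12 <= v <= 1 + 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ensemble_fractions(_classified([]))


class TestChanceOverlap:
    def test_reported_fractions_product(self):
        assert chance_overlap(0.44, 0.42) == pytest.approx(0.1848)

    def test_edge_cases(self):
        assert chance_overlap(0.0, 0.7) == 0.0
        assert chance_overlap(1.0, 0.37) == pytest.approx(0.37)
        with pytest.raises(ValueError):
            chance_overlap(1.2, 0.5)


class TestDacComparison:
    def test_extreme_fractions(self):
        rows = [(f"r{i}", 1, 1, 1, 1, "SAC", "DAC", 1.0, 0.9, 0.9) for i in range(10)]
        df = _classified(rows)
        dual, single, p, _ = dac_fraction_comparison(df)
        assert dual == 1.0 and single == 0.0
        assert np.isnan(p)  # one replicate only

    def test_identical_groups_p_half(self):
        rows = []
        for rep, frac in (("m1", 0.3), ("m2", 0.5)):
            n_dac = int(10 * frac)
            for i in range(10):
                is2 = "DAC" if i < n_dac else "SAC"
                is1 = "DAC" if i < n_dac else "SAC"
                rows.append((f"{rep}r{i}", 1, 1, 0, 2, is1, is2, 1.0, 0.9, 0.9))
        df = _classified(rows)
        df["replicate"] = [r[0:2] for r in df["roi_id"]]
        dual, single, p, _ = dac_fraction_comparison(df)
        assert dual == pytest.approx(single)
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_separated_groups_significant(self, rng):
        rows = []
        for rep in ("m1", "m2", "m3"):
            jitter = rng.integers(-2, 3)
            n_dual = 29 + jitter  # ~58% of 50
            n_single = 7 + jitter  # ~13% of 50
            for i in range(50):
                is2 = "DAC" if i < n_dual else "SAC"
                is1 = "DAC" if i < n_single else "SAC"
                rows.append((f"{rep}r{i}", 1, 1, 1, 1, is1, is2, 1.0, 0.9, 0.9))
        df = _classified(rows)
        df["replicate"] = [r[0:2] for r in df["roi_id"]]
        dual, single, p, per_rep = dac_fraction_comparison(df)
        assert dual == pytest.approx(0.58, abs=0.1)
        assert single == pytest.approx(0.13, abs=0.1)
        assert p < 0.05


class TestReactivation:
    def test_bin_invariants(self):
        with pytest.raises(ValueError):
            ReactivationBin(0.0, 500.0, 3, 5)

    def test_all_refit_gives_unit_probability(self):
        rows = [(f"r{i}", 1, 1, 0, 2, "SAC", "SAC", 100.0 + 600 * i, 0.9, 0.9) for i in range(12)]
        bins, stats = reactivation_probability(_classified(rows))
        assert all(b.probability == 1.0 for b in bins)
        assert stats["zero_variance"]

    def test_none_refit_gives_zero(self):
        rows = [(f"r{i}", 1, 0, 0, 3, "SAC", "none", 100.0 + 600 * i, 0.9, np.nan) for i in range(12)]
        bins, _ = reactivation_probability(_classified(rows))
        assert all(b.probability == 0.0 for b in bins)

    def test_monotone_synthetic_population_positive_correlation(self, rng):
        rows = []
        for i in range(600):
            amp = rng.uniform(0, 5000)
            p_refit = 0.2 + 0.6 * amp / 5000.0
            refit = rng.uniform() < p_refit
            rows.append(
                (f"r{i}", 1, int(refit), 0, 2 if refit else 3, "SAC",
                 "SAC" if refit else "none", amp, 0.9, 0.9 if refit else np.nan)
            )
        bins, stats = reactivation_probability(_classified(rows))
        assert stats["pearson_r"] > 0.6
        assert abs(stats["adj_r2_slope"]) < 1e-6  # constant adj R^2 control

    def test_half_open_binning(self):
        rows = [
            ("r0", 1, 1, 0, 2, "SAC", "SAC", 499.999, 0.9, 0.9),
            ("r1", 1, 1, 0, 2, "SAC", "SAC", 500.0, 0.9, 0.9),
        ]
        bins, _ = reactivation_probability(_classified(rows))
        assert [(b.amplitude_lo, b.amplitude_hi) for b in bins] == [(0.0, 500.0), (500.0, 1000.0)]

    def test_no_activated_rois_rejected(self):
        rows = [("r0", 0, 0, 0, 8, "none", "none", np.nan, np.nan, np.nan)]
        with pytest.raises(ValueError):
            reactivation_probability(_classified(rows))
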
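import numpy as np
import pandas as pd
import pytest

from _oracles import ipf_cells
from cartrake.errors import DivergenceError, ValidationError
from cartrake.margins import margin_from_sample, tabulate_sample
from cartrake.raking import (
    PHASE_FULL,
    PHASE_REDUCED,
    RakingControl,
    margin_discrepancy,
    rake,
    rescale_weights,
    trim_weights,
    two_phase_weights,
)
from conftest import make_margin


def _sample(counts: dict) -> pd.DataFrame:
    """Expand a cell->count dict into one row per unit."""
    rows = []
    for key, n in counts.items():
        key = key if isinstance(key, tuple) else (key,)
        rows.extend([key] * n)
    cols = [f"v{i}" for i in range(len(rows[0]))]
    return pd.DataFrame(rows, columns=cols)


class TestRakeClosedForm:
    def test_single_margin_one_sweep(self):
        sample = _sample({"a": 60, "b": 40})
        margin = make_margin(["v0"], {"a": 500, "b": 500})
        res = rake(sample, [margin])
        assert res.converged and res.iterations == 1
        w = res.weights
        assert np.allclose(w[sample["v0"] == "a"], 500 / 60)
        assert np.allclose(w[sample["v0"] == "b"], 500 / 40)
        assert res.total == pytest.approx(1000)

    def test_fixed_point_weights_unchanged(self):
        sample = _sample({"a": 60, "b": 40})
        margin = make_margin(["v0"], {"a": 60, "b": 40})
        res = rake(sample, [margin])
        assert res.converged
        assert res.iterations == 0  # already within tolerance at start
        assert np.allclose(res.weights, 1.0)

    def test_two_one_way_margins_match_cell_ipf_oracle(self):
        counts = {("a", "u"): 20, ("a", "v"): 10, ("b", "u"): 5, ("b", "v"): 15}
        sample = _sample(counts)
        row_m = make_margin(["v0"], {"a": 120, "b": 80})
        col_m = make_margin(["v1"], {"u": 90, "v": 110})
        res = rake(sample, [row_m, col_m])
        assert res.converged
        fitted = tabulate_sample(sample, ["v0", "v1"], weights=res.weights).table
        oracle = ipf_cells(
            [[counts[("a", "u")], counts[("a", "v")]], [counts[("b", "u")], counts[("b", "v")]]],
            [120, 80],
            [90, 110],
        )
        assert fitted.loc[("a", "u")] == pytest.approx(oracle[0, 0], rel=1e-6)
        assert fitted.loc[("b", "v")] == pytest.approx(oracle[1, 1], rel=1e-6)

    def test_missing_margin_variable_rejected(self):
        sample = _sample({"a": 3, "b": 2})
        sample.loc[0, "v0"] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            rake(sample, [make_margin(["v0"], {"a": 5, "b": 5})])

    def test_zero_weighted_cell_diverges(self):
        sample = _sample({"a": 5})
        margin = make_margin(["v0"], {"a": 5, "b": 5})
        with pytest.raises(DivergenceError, match="zero weighted"):
            rake(sample, [margin])


class TestRakeProperties:
    def test_ipf_oracle_equivalence_random_instances(self, rng):
        """Unit raking == cell-level IPF for exchangeable units, 100 trials."""
        for _ in range(100):
            nr = int(rng.integers(2, 5))
            nc = int(rng.integers(2, 5))
            seed = rng.integers(1, 6, size=(nr, nc))
            row_t = rng.integers(50, 150, size=nr).astype(float)
            col_t = row_t.sum() * rng.dirichlet(np.ones(nc) * 5)
            counts = {
                (f"r{i}", f"c{j}"): int(seed[i, j]) for i in range(nr) for j in range(nc)
            }
            sample = _sample(counts)
            row_m = make_margin(["v0"], {f"r{i}": row_t[i] for i in range(nr)})
            col_m = make_margin(["v1"], {f"c{j}": col_t[j] for j in range(nc)})
            res = rake(sample, [row_m, col_m], RakingControl(tolerance=1e-10, max_iterations=2000))
            assert res.converged
            fitted = tabulate_sample(sample, ["v0", "v1"], weights=res.weights).table
            oracle = ipf_cells(seed, row_t, col_t)
            for i in range(nr):
                for j in range(nc):
                    assert fitted.loc[(f"r{i}", f"c{j}")] == pytest.approx(
                        oracle[i, j], rel=1e-7, abs=1e-9
                    )

    def test_margin_reproduction_all_cells(self, rng):
        n = 800
        sample = pd.DataFrame(
            {
                "v0": rng.choice(["a", "b"], n, p=[0.7, 0.3]),
                "v1": rng.choice(["u", "v", "w"], n),
            }
        )
        m1 = make_margin(["v0"], {"a": 5000, "b": 5000})
        m2 = make_margin(["v1"], {"u": 2000, "v": 3000, "w": 5000})
        res = rake(sample, [m1, m2])
        assert res.converged
        for m in (m1, m2):
            fitted = tabulate_sample(sample, list(m.variables), weights=res.weights).table
            rel = np.abs(fitted.reindex(m.table.index) - m.table) / m.table
            assert rel.max() <= 1e-7

    def test_odds_ratio_preserved_2x2(self):
        counts = {("a", "u"): 20, ("a", "v"): 10, ("b", "u"): 5, ("b", "v"): 15}
        sample = _sample(counts)
        res = rake(
            sample,
            [make_margin(["v0"], {"a": 100, "b": 100}), make_margin(["v1"], {"u": 80, "v": 120})],
            RakingControl(tolerance=1e-12, max_iterations=5000),
        )
        t = tabulate_sample(sample, ["v0", "v1"], weights=res.weights).table
        odds_before = (20 * 15) / (10 * 5)
        odds_after = (t[("a", "u")] * t[("b", "v")]) / (t[("a", "v")] * t[("b", "u")])
        assert odds_after == pytest.approx(odds_before, rel=1e-8)

    def test_order_robustness(self, rng):
        n = 500
        sample = pd.DataFrame(
            {
                "v0": rng.choice(["a", "b"], n),
                "v1": rng.choice(["u", "v"], n),
                "v2": rng.choice(["x", "y", "z"], n),
            }
        )
        margins = [
            make_margin(["v0", "v1"], {(a, u): 250.0 for a in "ab" for u in "uv"}),
            make_margin(["v2"], {"x": 300, "y": 300, "z": 400}),
        ]
        ctrl = RakingControl(tolerance=1e-9, max_iterations=1000)
        res_fwd = rake(sample, margins, ctrl)
        res_rev = rake(sample, margins[::-1], ctrl)
        rel = np.abs(res_fwd.weights - res_rev.weights) / res_fwd.weights
        assert rel.max() < 10 * ctrl.tolerance * 1e2  # well within 10x-tolerance regime

    def test_nonconvergence_warns(self, rng):
        n = 200
        sample = pd.DataFrame(
            {"v0": rng.choice(["a", "b"], n), "v1": rng.choice(["u", "v"], n)}
        )
        margins = [
            make_margin(["v0"], {"a": 900, "b": 100}),
            make_margin(["v1"], {"u": 100, "v": 900}),
        ]
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = rake(sample, margins, RakingControl(max_iterations=1, tolerance=1e-12))
        assert not res.converged
        assert res.iterations == 1


class TestTrimRescale:
    def test_paper_range_clamped(self):
        w = pd.Series([0.04, 5.0, 82.4])
        trimmed, n_low, n_high = trim_weights(w, 0.1, 10.0)
        assert list(trimmed) == [0.1, 5.0, 10.0]
        assert (n_low, n_high) == (1, 1)

    def test_identity_inside_bounds(self):
        w = pd.Series([0.5, 1.0, 9.9])
        trimmed, n_low, n_high = trim_weights(w)
        pd.testing.assert_series_equal(trimmed, w)
        assert (n_low, n_high) == (0, 0)

    def test_all_above_upper(self):
        w = pd.Series([50.0, 60.0])
        trimmed, _, n_high = trim_weights(w, 9.999999, 10.0)
        assert np.allclose(trimmed, 10.0)
        assert n_high == 2

    def test_trim_preserves_order(self, rng):
        w = pd.Series(rng.lognormal(0, 2, 500))
        trimmed, _, _ = trim_weights(w, 0.1, 10.0)
        order = np.argsort(w.to_numpy())
        assert (np.diff(trimmed.to_numpy()[order]) >= 0).all()

    def test_rescale_example(self):
        out = rescale_weights(pd.Series([1.0, 1.0, 2.0]), 8.0)
        assert list(out) == [2.0, 2.0, 4.0]

    def test_rescale_identity(self):
        w = pd.Series([1.0, 2.0, 3.0])
        pd.testing.assert_series_equal(rescale_weights(w, 6.0), w)

    def test_rescale_sum_property(self, rng):
        for _ in range(20):
            w = pd.Series(rng.lognormal(0, 1, int(rng.integers(1, 50))))
            total = float(rng.uniform(0.5, 1e6))
            out = rescale_weights(w, total)
            assert abs(out.sum() - total) / total <= 1e-8
            ratios = out / w
            assert np.allclose(ratios, ratios.iloc[0])

    def test_rescale_zero_sum_errors(self):
        with pytest.raises(ValidationError):
            rescale_weights(pd.Series([0.0, 0.0]), 5.0)


class TestMarginDiscrepancy:
    def test_hand_2x2(self):
        sample = _sample({("a", "u"): 2, ("a", "v"): 1, ("b", "u"): 1, ("b", "v"): 1})
        m = make_margin(["v0"], {"a": 6, "b": 4})
        # unit weights: cell totals a=3, b=2 -> |3-6|/6 = 0.5, |2-4|/4 = 0.5
        w = np.ones(5)
        assert margin_discrepancy(sample, w, [m]) == pytest.approx(0.5)

    def test_converged_below_tolerance(self):
        sample = _sample({"a": 60, "b": 40})
        m = make_margin(["v0"], {"a": 500, "b": 500})
        res = rake(sample, [m])
        assert margin_discrepancy(sample, res.weights, [m]) <= 1e-7

    def test_biased_sample_positive(self):
        sample = _sample({"a": 60, "b": 40})
        m = make_margin(["v0"], {"a": 50, "b": 50})
        assert margin_discrepancy(sample, np.ones(100), [m]) > 0


class TestTwoPhase:
    def _margins_totaling_n(self, n):
        full = [make_margin(["v0"], {"a": 0.6 * n, "b": 0.4 * n})]
        reduced = [make_margin(["v1"], {"u": 0.5 * n, "v": 0.5 * n})]
        return full, reduced

    def test_no_missing_matches_single_phase(self, rng):
        n = 200
        sample = pd.DataFrame(
            {"v0": rng.choice(["a", "b"], n), "v1": rng.choice(["u", "v"], n)}
        )
        full, reduced = self._margins_totaling_n(n)
        res = two_phase_weights(sample, full, reduced)
        direct = rake(sample, full)
        w1 = direct.weights / direct.weights.mean()
        trimmed, _, _ = trim_weights(w1, 0.1, 10.0)
        expected = rescale_weights(trimmed, float(n))
        assert np.allclose(res.weights, expected)
        assert (res.phase == PHASE_FULL).all()

    def test_all_missing_full_variable_uses_reduced(self, rng):
        n = 100
        sample = pd.DataFrame(
            {"v0": [np.nan] * n, "v1": rng.choice(["u", "v"], n)}
        )
        full, reduced = self._margins_totaling_n(n)
        res = two_phase_weights(sample, full, reduced)
        assert (res.phase == PHASE_REDUCED).all()
        assert res.total == pytest.approx(n)

    def test_partial_missingness_contract(self, rng):
        """~23% questionnaire missingness: everyone eligible gets a weight,
        units missing the reduced variables are excluded, sum = eligible n."""
        n = 2000
        sample = pd.DataFrame(
            {
                "v0": rng.choice(["a", "b"], n),
                "v1": rng.choice(["u", "v"], n, p=[0.6, 0.4]),
            }
        )
        missing_q = rng.random(n) < 0.23
        sample.loc[missing_q, "v0"] = np.nan
        missing_reduced = rng.choice(n, size=4, replace=False)
        sample.loc[missing_reduced, "v1"] = np.nan
        full = [make_margin(["v0", "v1"], {(a, u): n / 4 for a in "ab" for u in "uv"})]
        reduced = [make_margin(["v1"], {"u": 0.55 * n, "v": 0.45 * n})]
        res = two_phase_weights(sample, full, reduced)
        eligible = sample["v1"].notna()
        assert res.n_excluded == (~eligible).sum()
        assert set(res.weights.index) == set(sample.index[eligible])
        assert res.weights.notna().all()
        assert res.total == pytest.approx(eligible.sum())
        incomplete = eligible & sample["v0"].isna()
        assert (res.phase[incomplete[incomplete].index] == PHASE_REDUCED).all()

    def test_inverse_probability_recovery(self, rng):
        """Selection on the cells of a single raked margin: converged
        weights are cell-constant and proportional to inverse empirical
        inclusion probability."""
        n_pop = 60_000
        pop = pd.DataFrame(
            {
                "sex": rng.choice(["woman", "man"], n_pop, p=[0.51, 0.49]),
                "age": rng.choice(["young", "mid", "old"], n_pop, p=[0.3, 0.4, 0.3]),
            }
        )
        p_by_cell = {
            ("woman", "young"): 0.02, ("woman", "mid"): 0.08, ("woman", "old"): 0.05,
            ("man", "young"): 0.01, ("man", "mid"): 0.05, ("man", "old"): 0.03,
        }
        p = np.array([p_by_cell[t] for t in zip(pop["sex"], pop["age"])])
        take = rng.random(n_pop) < p
        sample = pop.loc[take].reset_index(drop=True)
        margin = margin_from_sample(pop, ["sex", "age"])
        res = rake(sample, [margin], RakingControl(tolerance=1e-10))
        assert res.converged
        for cell, grp in sample.groupby(["sex", "age"]):
            w = res.weights[grp.index]
            assert w.std() == pytest.approx(0.0, abs=1e-9)
            emp_incl = len(grp) / margin.table.loc[cell]
            assert w.iloc[0] == pytest.approx(1.0 / emp_incl, rel=1e-6)
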
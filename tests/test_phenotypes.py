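"""Line means, variance components, heritability, derived traits, framework."""

import numpy as np
import pandas as pd
import pytest

import nilqtl as nq
from nilqtl.phenotypes import correlation_stars


def plot_frame(records):
    return pd.DataFrame(records,
                        columns=["line_id", "population", "environment",
                                 "replicate", "y"])


class TestLineMeans:
    def test_balanced_equals_arithmetic_mean(self):
        plots = plot_frame([
            ("A", "P", "e1", 1, 10.0), ("A", "P", "e1", 2, 12.0),
            ("A", "P", "e2", 1, 14.0), ("A", "P", "e2", 2, 16.0),
            ("B", "P", "e1", 1, 1.0), ("B", "P", "e1", 2, 3.0),
            ("B", "P", "e2", 1, 5.0), ("B", "P", "e2", 2, 7.0),
        ])
        means = nq.compute_line_means(plots).set_index("line_id")["y"]
        assert means["A"] == pytest.approx(13.0)
        assert means["B"] == pytest.approx(4.0)

    def test_environment_shift_leaves_line_differences(self):
        base = plot_frame([
            ("A", "P", "e1", 1, 10.0), ("A", "P", "e2", 1, 11.0),
            ("B", "P", "e1", 1, 14.0), ("B", "P", "e2", 1, 13.0),
        ])
        shifted = base.copy()
        shifted.loc[shifted["environment"] == "e2", "y"] += 5.0
        m0 = nq.compute_line_means(base).set_index("line_id")["y"]
        m1 = nq.compute_line_means(shifted).set_index("line_id")["y"]
        assert (m1["A"] - m1["B"]) == pytest.approx(m0["A"] - m0["B"])

    def test_unbalanced_matches_hand_solved_least_squares(self):
        # line B missing environment e2; solve the same normal equations
        # directly from an explicitly written design matrix
        plots = plot_frame([
            ("A", "P", "e1", 1, 10.0), ("A", "P", "e2", 1, 14.0),
            ("B", "P", "e1", 1, 6.0),
            ("C", "P", "e1", 1, 8.0), ("C", "P", "e2", 1, 9.0),
        ])
        # columns: mu_A, mu_B, mu_C, env (sum-coded: e1=+1, e2=-1)
        X = np.array([
            [1, 0, 0, 1],
            [1, 0, 0, -1],
            [0, 1, 0, 1],
            [0, 0, 1, 1],
            [0, 0, 1, -1],
        ], dtype=float)
        y = np.array([10.0, 14.0, 6.0, 8.0, 9.0])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        with pytest.warns(UserWarning, match="single plot"):
            means = nq.compute_line_means(plots).set_index("line_id")["y"]
        assert means["A"] == pytest.approx(beta[0])
        assert means["B"] == pytest.approx(beta[1])
        assert means["C"] == pytest.approx(beta[2])

    def test_missing_values_dropped_listwise(self):
        plots = plot_frame([
            ("A", "P", "e1", 1, 10.0), ("A", "P", "e1", 2, np.nan),
            ("A", "P", "e2", 1, 12.0), ("A", "P", "e2", 2, 14.0),
        ])
        means = nq.compute_line_means(plots)
        assert np.isfinite(means["y"]).all()


class TestVarianceComponents:
    @staticmethod
    def simulate_plots(rng, n_lines=500, E=2, R=2, s_g=2.0, s_ge=1.0, s_e=2.0):
        g = rng.normal(0, np.sqrt(s_g), n_lines)
        ge = rng.normal(0, np.sqrt(s_ge), (n_lines, E))
        rows = []
        for j in range(E):
            for k in range(R):
                eps = rng.normal(0, np.sqrt(s_e), n_lines)
                for i in range(n_lines):
                    rows.append((f"L{i}", "P", f"e{j}", k + 1,
                                 g[i] + ge[i, j] + eps[i]))
        return plot_frame(rows)

    def test_component_recovery_within_10pct(self, rng):
        # mean over 5 replicates of 500 lines: the sampling sd of the G
        # component at 500 lines is ~0.19, so single draws fluctuate
        est = [nq.estimate_variance_components(self.simulate_plots(rng)).table.loc["y"]
               for _ in range(5)]
        mean = pd.concat(est, axis=1).mean(axis=1)
        assert mean["sigma2_g"] == pytest.approx(2.0, rel=0.10)
        assert mean["sigma2_ge"] == pytest.approx(1.0, rel=0.15)
        assert mean["sigma2_err"] == pytest.approx(2.0, rel=0.10)

    def test_line_effects_only_gives_zero_noise_components(self, rng):
        plots = self.simulate_plots(rng, n_lines=40, s_g=3.0, s_ge=0.0, s_e=0.0)
        vc = nq.estimate_variance_components(plots).table.loc["y"]
        assert vc["sigma2_ge"] == pytest.approx(0.0, abs=1e-12)
        assert vc["sigma2_err"] == pytest.approx(0.0, abs=1e-12)
        assert vc["sigma2_g"] > 0

    def test_constant_data_gives_all_zero(self):
        plots = plot_frame([("A", "P", "e1", 1, 5.0), ("A", "P", "e1", 2, 5.0),
                            ("B", "P", "e1", 1, 5.0), ("B", "P", "e1", 2, 5.0),
                            ("A", "P", "e2", 1, 5.0), ("B", "P", "e2", 1, 5.0)])
        vc = nq.estimate_variance_components(plots).table.loc["y"]
        assert (vc == 0).all()

    def test_single_environment_flags_ge(self):
        plots = plot_frame([("A", "P", "e1", 1, 4.0), ("A", "P", "e1", 2, 6.0),
                            ("B", "P", "e1", 1, 8.0), ("B", "P", "e1", 2, 9.0)])
        vc = nq.estimate_variance_components(plots)
        assert vc.table.loc["y", "sigma2_ge"] == 0.0
        assert any("GE" in f for f in vc.flags["y"])


class TestHeritability:
    def test_closed_form(self):
        vc = nq.VarianceComponents(
            pd.DataFrame({"sigma2_g": [2.0], "sigma2_ge": [1.0],
                          "sigma2_err": [2.0]}, index=pd.Index(["y"], name="trait")),
            n_environments=2, r_effective=2.0, flags={"y": []})
        assert nq.heritability(vc)["y"] == pytest.approx(2 / 3, abs=1e-12)

    @pytest.mark.parametrize("sg, sge, serr, expected", [
        (5.0, 0.0, 0.0, 1.0),
        (0.0, 1.0, 2.0, 0.0),
    ])
    def test_degenerate_cases(self, sg, sge, serr, expected):
        vc = nq.VarianceComponents(
            pd.DataFrame({"sigma2_g": [sg], "sigma2_ge": [sge],
                          "sigma2_err": [serr]}, index=pd.Index(["y"], name="trait")),
            n_environments=2, r_effective=2.0, flags={"y": []})
        assert nq.heritability(vc)["y"] == pytest.approx(expected)

    def test_monotone_in_genetic_variance_and_replication(self):
        def h2(sg, R):
            vc = nq.VarianceComponents(
                pd.DataFrame({"sigma2_g": [sg], "sigma2_ge": [1.0],
                              "sigma2_err": [2.0]},
                             index=pd.Index(["y"], name="trait")),
                n_environments=2, r_effective=R, flags={"y": []})
            return nq.heritability(vc)["y"]
        vals_g = [h2(s, 2.0) for s in (0.5, 1.0, 2.0, 4.0)]
        vals_r = [h2(2.0, r) for r in (1.0, 2.0, 3.0, 5.0)]
        assert np.all(np.diff(vals_g) > 0)
        assert np.all(np.diff(vals_r) > 0)


class TestDerivedTraits:
    def test_ffd_from_typical_kernel_values(self):
        means = pd.DataFrame({"line_id": ["a"], "population": ["P"],
                              "Wt50k": [12.65], "area": [58.13]})
        out = nq.derive_traits(means)
        # 12.65 g / 50 kernels = 253 mg per kernel; / 58.13 mm^2
        assert out["FFD"].iloc[0] == pytest.approx(4.35, abs=0.005)

    def test_length_width_ratio(self):
        means = pd.DataFrame({"line_id": ["a", "b"], "population": "P",
                              "length": [10.99, 7.0], "width": [6.51, 7.0]})
        out = nq.derive_traits(means)
        assert out["LW"].iloc[0] == pytest.approx(1.69, abs=0.005)
        assert out["LW"].iloc[1] == pytest.approx(1.0)

    def test_zero_denominators_give_missing(self):
        means = pd.DataFrame({"line_id": ["a"], "population": ["P"],
                              "Wt50k": [12.0], "area": [0.0],
                              "length": [10.0], "width": [0.0]})
        out = nq.derive_traits(means)
        assert np.isnan(out["FFD"].iloc[0])
        assert np.isnan(out["LW"].iloc[0])


class TestTraitFramework:
    def test_self_correlation_and_exact_negative(self):
        n = 200
        x = np.linspace(0, 1, n)
        means = pd.DataFrame({"line_id": [f"L{i}" for i in range(n)],
                              "population": "P", "a": x, "b": -x})
        _, rmat, pmat = nq.trait_framework(means, ["a", "b"])
        assert rmat.loc["a", "a"] == 1.0
        assert rmat.loc["a", "b"] == pytest.approx(-1.0)
        assert pmat.loc["a", "b"] < 0.001

    def test_hand_computed_pearson(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 4.0, 5.0, 9.0])
        r_hand = (np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        means = pd.DataFrame({"line_id": list("abcd"), "population": "P",
                              "x": x, "y": y})
        _, rmat, _ = nq.trait_framework(means, ["x", "y"])
        assert rmat.loc["x", "y"] == pytest.approx(r_hand, abs=1e-12)

    def test_constant_trait_gives_missing_correlation(self):
        means = pd.DataFrame({"line_id": list("abcd"), "population": "P",
                              "x": [1.0, 2.0, 3.0, 4.0], "c": 1.0})
        _, rmat, _ = nq.trait_framework(means, ["x", "c"])
        assert np.isnan(rmat.loc["x", "c"])

    def test_stars_formatting(self):
        rmat = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=list("ab"),
                            columns=list("ab"))
        pmat = pd.DataFrame([[0.0, 0.0005], [0.0005, 0.0]], index=list("ab"),
                            columns=list("ab"))
        stars = correlation_stars(rmat, pmat)
        assert stars.loc["a", "b"] == "0.900**"
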
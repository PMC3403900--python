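import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coregrn as cg
from coregrn.scalefree_cutoff import DegreeDistribution, best_fit


def dist_from_probs(support, probs, direction="out"):
    probs = np.asarray(probs, float)
    return DegreeDistribution(
        direction=direction,
        support=np.asarray(support, float),
        probs=probs / probs.sum(),
    )


class TestDegreeDistribution:
    def test_star_out_and_in(self):
        g = nx.DiGraph((0, i) for i in range(1, 6))
        out = cg.degree_distribution(g, "out")
        np.testing.assert_array_equal(out.support, [5])
        np.testing.assert_array_equal(out.probs, [1.0])
        inn = cg.degree_distribution(g, "in")
        np.testing.assert_array_equal(inn.support, [1])  # leaves only; hub excluded

    def test_directed_cycle_symmetric(self):
        g = nx.cycle_graph(6, create_using=nx.DiGraph)
        for direction in ("in", "out"):
            dist = cg.degree_distribution(g, direction)
            np.testing.assert_array_equal(dist.support, [1])
            np.testing.assert_array_equal(dist.probs, [1.0])

    def test_single_edge(self):
        g = nx.DiGraph([("a", "b")])
        out = cg.degree_distribution(g, "out")
        np.testing.assert_array_equal(out.support, [1])

    def test_no_edges_raises(self):
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        with pytest.raises(ValueError):
            cg.degree_distribution(g, "out")


class TestPowerLawFit:
    @pytest.mark.parametrize("gamma", [2.0, 1.3])
    def test_exact_power_law_recovered(self, gamma):
        k = np.arange(1, 51, dtype=float)
        fit = cg.fit_power_law(dist_from_probs(k, k**-gamma))
        assert fit.params["gamma"] == pytest.approx(gamma, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_uniform_distribution_r2_zero_by_convention(self):
        k = np.arange(1, 21, dtype=float)
        fit = cg.fit_power_law(dist_from_probs(k, np.ones_like(k)))
        assert fit.params["gamma"] == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == 0.0

    def test_degenerate_support_reports_zero(self):
        fit = cg.fit_power_law(dist_from_probs([1, 2], [0.5, 0.5]))
        assert fit.r_squared == 0.0


class TestTruncatedFit:
    def test_exact_truncated_recovered(self):
        k = np.arange(1, 41, dtype=float)
        fit = cg.fit_truncated_power_law(
            dist_from_probs(k, k**-1.5 * np.exp(-0.1 * k))
        )
        assert fit.params["lambda"] == pytest.approx(1.5, abs=1e-9)
        assert fit.params["alpha_trunc"] == pytest.approx(0.1, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_nests_pure_power_law(self):
        k = np.arange(1, 30, dtype=float)
        fit = cg.fit_truncated_power_law(dist_from_probs(k, k**-1.7))
        assert fit.params["alpha_trunc"] == pytest.approx(0.0, abs=1e-9)
        assert fit.params["lambda"] == pytest.approx(1.7, abs=1e-9)

    def test_nests_pure_exponential(self):
        k = np.arange(1, 30, dtype=float)
        fit = cg.fit_truncated_power_law(dist_from_probs(k, np.exp(-0.5 * k)))
        assert fit.params["lambda"] == pytest.approx(0.0, abs=1e-8)
        assert fit.params["alpha_trunc"] == pytest.approx(0.5, abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_extra_regressor_never_lowers_r2(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(4, 30))
        support = np.sort(rng.choice(np.arange(1, 100), size=size, replace=False))
        probs = rng.uniform(0.01, 1.0, size=size)
        dist = dist_from_probs(support, probs)
        assert (
            cg.fit_truncated_power_law(dist).r_squared
            >= cg.fit_power_law(dist).r_squared - 1e-12
        )


def test_generated_scalefree_graph_fits_power_law():
    g = cg.generate_scalefree_digraph(1700, 4200, seed=11)
    fit = cg.fit_power_law(cg.degree_distribution(g, "out"))
    assert fit.r_squared > 0.8


class TestScan:
    def test_sizes_monotone_and_models_reported(self, default_bundle, default_ratios):
        _, _, candidates, _ = default_bundle
        scan = cg.scan_cutoffs(
            candidates, default_ratios, "TF", grid=[0.2, 0.4, 0.6]
        )
        sizes = scan.table["n_edges"].values
        assert (np.diff(sizes) <= 0).all()
        assert set(scan.table.columns) >= {
            "cutoff",
            "r2_in",
            "r2_out",
            "model_in",
            "model_out",
            "n_nodes",
            "n_edges",
            "n_regulators",
        }

    def test_single_point_grid(self, default_bundle, default_ratios):
        _, _, candidates, _ = default_bundle
        scan = cg.scan_cutoffs(candidates, default_ratios, "miRNA", grid=[0.3])
        assert len(scan.table) == 1

    def test_empty_network_rows_kept(self, default_bundle, default_ratios):
        _, _, candidates, _ = default_bundle
        scan = cg.scan_cutoffs(candidates, default_ratios, "TF", grid=[0.1, 0.89])
        last = scan.table.iloc[-1]
        assert last["n_edges"] == 0
        assert last["r2_in"] == 0.0 and last["r2_out"] == 0.0

    def test_mirna_scan_applies_sign_rule(self, default_bundle, default_ratios):
        _, _, candidates, _ = default_bundle
        scan0 = cg.scan_cutoffs(candidates, default_ratios, "miRNA", grid=[0.0])
        n_mirna_candidates = sum(
            1 for r in candidates if r.regulator_class == "miRNA"
        )
        # positive-correlation miRNA candidates are excluded even at cutoff 0
        assert 0 < scan0.table.loc[0, "n_edges"] < n_mirna_candidates


def scan_result(r2_in, r2_out=None, start=0.0, step=0.1):
    r2_out = r2_in if r2_out is None else r2_out
    n = len(r2_in)
    table = pd.DataFrame(
        {
            "cutoff": start + step * np.arange(n),
            "r2_in": r2_in,
            "r2_out": r2_out,
            "model_in": ["power_law"] * n,
            "model_out": ["power_law"] * n,
            "n_nodes": [10] * n,
            "n_edges": list(range(n, 0, -1)),
            "n_regulators": [3] * n,
        }
    )
    return cg.CutoffScanResult(regulator_class="TF", table=table)


class TestSelectCutoff:
    def test_first_steady_point(self):
        scan = scan_result([0.0, 0.2, 0.8, 0.85, 0.86, 0.86])
        assert cg.select_cutoff(scan, tol=0.05, window=2) == pytest.approx(0.3)

    def test_constant_curves_pick_first_point(self):
        scan = scan_result([0.7] * 5)
        assert cg.select_cutoff(scan) == pytest.approx(0.0)

    def test_strictly_increasing_falls_back_to_argmax(self):
        scan = scan_result([0.0, 0.1, 0.2, 0.3, 0.4, 0.5])
        assert cg.select_cutoff(scan) == pytest.approx(0.5)

    def test_invariant_to_appended_grid_points(self):
        base = [0.0, 0.2, 0.8, 0.85, 0.86, 0.86]
        extended = base + [0.87, 0.2]
        assert cg.select_cutoff(scan_result(base)) == pytest.approx(
            cg.select_cutoff(scan_result(extended))
        )

    def test_both_directions_must_settle(self):
        scan = scan_result(
            [0.8, 0.8, 0.8, 0.8, 0.8], [0.0, 0.3, 0.6, 0.9, 0.9]
        )
        # out-direction only settles at index 3
        assert cg.select_cutoff(scan, tol=0.05, window=1) == pytest.approx(0.3)


def test_scan_tsv_and_plot(tmp_path):
    scan = scan_result([0.1, 0.5, 0.6, 0.6])
    cg.scalefree_cutoff.write_scan(scan, tmp_path / "scan.tsv")
    back = pd.read_csv(tmp_path / "scan.tsv", sep="\t")
    assert list(back["regulator_class"].unique()) == ["TF"]
    cg.scalefree_cutoff.plot_scan(scan, tmp_path / "scan.png")
    assert (tmp_path / "scan.png").stat().st_size > 0
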
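"""Grid enumeration/counting, impact scoring, estimate PCA, batch runs."""

import numpy as np
import pandas as pd
import pytest

from braintx.errors import IncompleteGridError, ParameterError
from braintx.multiverse import (
    OptionSpec,
    ParameterGrid,
    config_hash,
    count_grid,
    enumerate_grid,
    impact_scores,
    matched_tuple_count,
    pca_estimates,
    reduced_grid,
    run_multiverse,
    smoke_grid,
    table_grid,
)


def _toy_grid():
    """Option B collapses to 'p' when A takes the value 'x'."""
    return ParameterGrid([
        OptionSpec("A", ("x", "y"), "binary"),
        OptionSpec("B", ("p", "q"), "binary",
                   collapse_when={"A": ("x",)}, collapse_to="p"),
    ])


class TestEnumeration:
    def test_plain_product(self):
        grid = ParameterGrid([
            OptionSpec("A", ("a", "b"), "binary"),
            OptionSpec("B", (1, 2, 3), "ordinal"),
        ])
        configs = list(enumerate_grid(grid))
        assert len(configs) == 6
        assert count_grid(grid) == 6
        assert configs[0] == {"A": "a", "B": 1}

    def test_redundancy_collapse_by_hand(self):
        # A=x forces B=p: {x,p}, {y,p}, {y,q} -> 3 configs
        configs = list(enumerate_grid(_toy_grid()))
        assert configs == [
            {"A": "x", "B": "p"},
            {"A": "y", "B": "p"},
            {"A": "y", "B": "q"},
        ]
        assert count_grid(_toy_grid()) == 3

    def test_count_equals_enumeration_on_random_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_options = int(rng.integers(2, 5))
            options = []
            for i in range(n_options):
                k = int(rng.integers(1, 4))
                scale = "binary" if k == 2 else "categorical"
                options.append(
                    OptionSpec(f"O{i}", tuple(range(k)), scale)
                )
            # maybe attach one redundancy rule between two distinct options
            if n_options >= 2 and rng.random() < 0.7:
                target = int(rng.integers(1, n_options))
                trigger = int(rng.integers(0, target))
                trig_opt = options[trigger]
                n_trig = int(rng.integers(1, len(trig_opt.choices) + 1))
                trig_vals = tuple(
                    rng.choice(trig_opt.choices, size=n_trig, replace=False)
                )
                old = options[target]
                options[target] = OptionSpec(
                    old.name, old.choices, old.scale,
                    collapse_when={trig_opt.name: trig_vals},
                    collapse_to=old.choices[0],
                )
            grid = ParameterGrid(options)
            assert count_grid(grid) == len(list(enumerate_grid(grid)))

    def test_standard_grid_count(self):
        grid = table_grid()
        assert count_grid(grid) == 746_496

    def test_presets_have_expected_sizes(self):
        assert count_grid(smoke_grid()) == 16
        assert count_grid(reduced_grid()) == 96

    def test_binary_iff_two_choices(self):
        with pytest.raises(ParameterError):
            OptionSpec("A", (1, 2, 3), "binary")
        with pytest.raises(ParameterError):
            OptionSpec("A", (1, 2), "ordinal")


class TestMatchedTuples:
    def test_binary_option_pairs_on_standard_grid(self):
        grid = table_grid()
        assert matched_tuple_count(grid, "metric") == 373_248

    def test_matches_brute_force_on_toy_grids(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n_c = int(rng.integers(1, 4))
            options = [
                OptionSpec("A", ("x", "y", "z")),
                OptionSpec("B", ("p", "q"), "binary",
                           collapse_when={"A": ("x",)}, collapse_to="p"),
                OptionSpec("C", tuple(range(n_c)),
                           "binary" if n_c == 2 else "categorical"),
            ]
            grid = ParameterGrid(options)
            for name in ("A", "B", "C"):
                option = grid[name]
                if len(option.choices) < 2:
                    assert matched_tuple_count(grid, name) == 0
                    continue
                configs = list(enumerate_grid(grid))
                others = [n for n in grid.names if n != name]
                groups = {}
                for c in configs:
                    key = tuple(c[o] for o in others)
                    groups.setdefault(key, set()).add(c[name])
                brute = sum(
                    1 for vals in groups.values()
                    if vals == set(option.choices)
                )
                assert matched_tuple_count(grid, name) == brute


class TestImpactScores:
    def _estimates(self, grid, fn):
        rows = []
        for cfg in enumerate_grid(grid):
            rows.append({**cfg, "cge_rho": fn(cfg),
                         "gce_silhouette": 0.0, "rge_rho": 0.0})
        return pd.DataFrame(rows)

    def test_binary_mean_absolute_difference(self):
        grid = ParameterGrid([
            OptionSpec("A", ("a", "b"), "binary"),
            OptionSpec("B", ("u", "v"), "binary"),
        ])
        values = {("a", "u"): 0.2, ("b", "u"): 0.5,
                  ("a", "v"): 0.1, ("b", "v"): 0.1}
        table = self._estimates(grid, lambda c: values[(c["A"], c["B"])])
        out = impact_scores(table, grid)
        assert out.loc["A", "cge_rho_impact"] == pytest.approx(0.15)

    def test_ordinal_adjacent_differences(self):
        grid = ParameterGrid([OptionSpec("T", (0, 1, 2), "ordinal")])
        table = self._estimates(
            grid, lambda c: {0: 0.1, 1: 0.2, 2: 0.4}[c["T"]]
        )
        out = impact_scores(table, grid)
        assert out.loc["T", "cge_rho_impact"] == pytest.approx(0.15)

    def test_categorical_all_pairs(self):
        grid = ParameterGrid([OptionSpec("M", ("m1", "m2", "m3"))])
        table = self._estimates(
            grid, lambda c: {"m1": 1.0, "m2": 2.0, "m3": 4.0}[c["M"]]
        )
        out = impact_scores(table, grid)
        assert out.loc["M", "cge_rho_impact"] == pytest.approx(2.0)

    def test_null_option_has_exactly_zero_impact(self):
        grid = ParameterGrid([
            OptionSpec("A", ("a", "b"), "binary"),
            OptionSpec("B", ("u", "v"), "binary"),
        ])
        table = self._estimates(grid, lambda c: 1.0 if c["A"] == "a" else 3.0)
        out = impact_scores(table, grid)
        assert out.loc["B", "cge_rho_impact"] == 0.0
        assert out.loc["A", "cge_rho_rank"] == 1

    def test_collapsed_cells_skipped_not_counted(self):
        grid = _toy_grid()
        table = self._estimates(
            grid, lambda c: {"p": 0.0, "q": 1.0}[c["B"]]
        )
        out = impact_scores(table, grid)
        # B varies only in the A=y context: one tuple, impact |0-1| = 1
        assert out.loc["B", "n_tuples"] == 1
        assert out.loc["B", "cge_rho_impact"] == pytest.approx(1.0)

    def test_incomplete_factorial_rejected(self):
        grid = ParameterGrid([
            OptionSpec("A", ("a", "b"), "binary"),
            OptionSpec("B", ("u", "v"), "binary"),
        ])
        table = self._estimates(grid, lambda c: 0.0).iloc[:-1]
        with pytest.raises(IncompleteGridError):
            impact_scores(table, grid)

    def test_shift_invariance_and_scale_equivariance(self):
        grid = ParameterGrid([
            OptionSpec("A", ("a", "b"), "binary"),
            OptionSpec("B", (0, 1, 2), "ordinal"),
        ])
        rng = np.random.default_rng(2)
        values = {
            (c["A"], c["B"]): rng.normal() for c in enumerate_grid(grid)
        }
        base_table = self._estimates(grid, lambda c: values[(c["A"], c["B"])])
        base = impact_scores(base_table, grid)
        shifted = self._estimates(
            grid, lambda c: values[(c["A"], c["B"])] + 7.0
        )
        scaled = self._estimates(
            grid, lambda c: values[(c["A"], c["B"])] * -3.0
        )
        np.testing.assert_allclose(
            impact_scores(shifted, grid)["cge_rho_impact"],
            base["cge_rho_impact"],
        )
        np.testing.assert_allclose(
            impact_scores(scaled, grid)["cge_rho_impact"],
            base["cge_rho_impact"] * 3.0,
        )

    def test_ranks_are_a_permutation(self):
        grid = ParameterGrid([
            OptionSpec("A", ("a", "b"), "binary"),
            OptionSpec("B", (0, 1, 2), "ordinal"),
            OptionSpec("C", ("u", "v"), "binary"),
        ])
        rng = np.random.default_rng(3)
        table = self._estimates(grid, lambda c: rng.normal())
        out = impact_scores(table, grid)
        assert sorted(out["cge_rho_rank"]) == [1, 2, 3]


class TestPCA:
    def test_identical_columns_put_everything_on_pc1(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=50)
        table = pd.DataFrame(
            {"cge_rho": col, "gce_silhouette": col, "rge_rho": col}
        )
        _, fractions = pca_estimates(table)
        assert fractions[0] == pytest.approx(1.0)
        assert fractions[1] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_noise_splits_variance_evenly(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            rng.normal(size=(20000, 3)),
            columns=["cge_rho", "gce_silhouette", "rge_rho"],
        )
        _, fractions = pca_estimates(table)
        assert fractions[0] == pytest.approx(1 / 3, abs=0.02)
        assert fractions[1] == pytest.approx(1 / 3, abs=0.02)

    def test_scores_invariant_to_row_order(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(
            rng.normal(size=(40, 3)),
            columns=["cge_rho", "gce_silhouette", "rge_rho"],
        )
        scores, _ = pca_estimates(table)
        perm = rng.permutation(40)
        scores_p, _ = pca_estimates(table.iloc[perm])
        # same rows end up with the same coordinates (up to component sign)
        for col in range(2):
            direct = scores[perm, col]
            err = min(np.abs(scores_p[:, col] - direct).max(),
                      np.abs(scores_p[:, col] + direct).max())
            assert err < 1e-9

    def test_matches_covariance_eigendecomposition_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            table = pd.DataFrame(
                rng.normal(size=(int(rng.integers(5, 40)), 3)),
                columns=["cge_rho", "gce_silhouette", "rge_rho"],
            )
            scores, fractions = pca_estimates(table)
            centered = table.to_numpy() - table.to_numpy().mean(0)
            w = np.linalg.eigvalsh(centered.T @ centered)[::-1]
            np.testing.assert_allclose(fractions, (w / w.sum())[:2],
                                       atol=1e-9)


class TestRunMultiverse:
    def _fake_pipeline(self, dataset):
        from braintx.pipeline import PipelineConfig, run_pipeline

        def fn(assignment):
            config = PipelineConfig.from_dict(assignment)
            return run_pipeline(
                config, dataset.bundles, dataset.atlas,
                corrected_coords=dataset.corrected_coordinates,
            ).expression

        return fn

    def test_single_config_grid_equals_direct_run(self, small_dataset,
                                                  centroids=None):
        from braintx import io as btio
        from braintx.analyses import compute_estimates
        from braintx.pipeline import PipelineConfig, run_pipeline

        ds = small_dataset
        cent = btio.region_centroids(ds.atlas)
        grid = ParameterGrid([
            OptionSpec(name, (getattr(PipelineConfig(), name),))
            for name in PipelineConfig.option_names()
        ])
        table = run_multiverse(
            grid, ds.bundles, ds.atlas, cent,
            phenotype=ds.ground_truth.phenotype,
            corrected_coords=ds.corrected_coordinates,
        )
        assert len(table) == 1
        direct = run_pipeline(
            PipelineConfig(), ds.bundles, ds.atlas,
            corrected_coords=ds.corrected_coordinates,
        ).expression
        expected = compute_estimates(direct, cent,
                                     phenotype=ds.ground_truth.phenotype)
        assert table["cge_rho"].iloc[0] == pytest.approx(expected.cge_rho)
        assert table["rge_rho"].iloc[0] == pytest.approx(expected.rge_rho)

    def test_failed_configs_recorded_not_dropped(self, small_dataset):
        from braintx import io as btio
        from braintx.pipeline import PipelineConfig

        ds = small_dataset
        cent = btio.region_centroids(ds.atlas)
        grid = ParameterGrid([OptionSpec("metric", ("mean", "median"),
                                         "binary")])
        good = self._fake_pipeline(ds)

        def fn(assignment):
            if assignment["metric"] == "median":
                raise ValueError("boom")
            full = PipelineConfig(metric=assignment["metric"]).to_dict()
            return good(PipelineConfig.from_dict(full).__dict__)

        table = run_multiverse(grid, None, None, cent, pipeline_fn=fn)
        assert len(table) == 2
        failed = table[table["error"].notna()]
        assert len(failed) == 1 and "boom" in failed["error"].iloc[0]

    def test_config_hash_stable_under_key_order(self):
        a = config_hash({"x": 1, "y": "b"})
        b = config_hash({"y": "b", "x": 1})
        assert a == b
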
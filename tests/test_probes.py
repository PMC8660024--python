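"""Probe reannotation, intensity filtering, and the six selection methods."""

import numpy as np
import pandas as pd
import pytest

from braintx.errors import ConfigurationError, FormatError, ParameterError
from braintx.probes import (
    ProbeSelectionSpec,
    filter_probes_by_intensity,
    reannotate_probes,
    select_probes,
)
from braintx.types import DonorBundle
from conftest import make_samples


def _bundle(donor_id, probe_rows, expr, pacall=None, samples=None,
            rnaseq=None):
    """Assemble a toy bundle.  probe_rows: (probe_id, gene) pairs; expr:
    probe x sample array."""
    expr = np.asarray(expr, float)
    probe_ids = [p for p, _ in probe_rows]
    probes = pd.DataFrame(
        {
            "probe_name": [f"P{p}" for p in probe_ids],
            "gene_symbol": [g for _, g in probe_rows],
            "entrez_id": pd.array(
                [None if g is None else hash(g) % 1000 for _, g in probe_rows],
                dtype="Int64",
            ),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    n_samples = expr.shape[1]
    if samples is None:
        samples = make_samples(
            [(i + 1, donor_id, "L", -10.0, float(i), 0.0)
             for i in range(n_samples)]
        )
    expression = pd.DataFrame(expr, index=probes.index, columns=samples.index)
    if pacall is None:
        pacall = np.ones_like(expr, int)
    pacall = pd.DataFrame(np.asarray(pacall, int), index=probes.index,
                          columns=samples.index)
    return DonorBundle(
        donor_id=donor_id, expression=expression, pacall=pacall,
        probes=probes, samples=samples, rnaseq=rnaseq,
    )


class TestReannotation:
    def test_mapping_replaces_gene(self):
        probes = pd.DataFrame(
            {"probe_name": ["P1"], "gene_symbol": ["GENE1"],
             "entrez_id": pd.array([1], dtype="Int64")},
            index=pd.Index([1], name="probe_id"),
        )
        mapping = pd.DataFrame(
            {"probe_name": ["P1"], "gene_symbol": ["GENE9"], "entrez_id": [9]}
        )
        out = reannotate_probes(probes, mapping)
        assert out.loc[1, "gene_symbol"] == "GENE9"
        assert out.loc[1, "entrez_id"] == 9

    def test_null_mapping_is_identity(self):
        probes = pd.DataFrame(
            {"probe_name": ["P1"], "gene_symbol": ["GENE1"],
             "entrez_id": pd.array([1], dtype="Int64")},
            index=pd.Index([1], name="probe_id"),
        )
        pd.testing.assert_frame_equal(reannotate_probes(probes, None), probes)

    def test_omitted_probe_gets_null_gene(self):
        probes = pd.DataFrame(
            {"probe_name": ["P1", "P2"], "gene_symbol": ["G1", "G2"],
             "entrez_id": pd.array([1, 2], dtype="Int64")},
            index=pd.Index([1, 2], name="probe_id"),
        )
        mapping = pd.DataFrame(
            {"probe_name": ["P1"], "gene_symbol": ["G1"], "entrez_id": [1]}
        )
        out = reannotate_probes(probes, mapping)
        assert pd.isna(out.loc[2, "gene_symbol"])
        assert pd.isna(out.loc[2, "entrez_id"])

    def test_duplicate_mapping_raises(self):
        probes = pd.DataFrame(
            {"probe_name": ["P1"], "gene_symbol": ["G1"],
             "entrez_id": pd.array([1], dtype="Int64")},
            index=pd.Index([1], name="probe_id"),
        )
        mapping = pd.DataFrame(
            {"probe_name": ["P1", "P1"], "gene_symbol": ["A", "B"],
             "entrez_id": [1, 2]}
        )
        with pytest.raises(FormatError, match="duplicate"):
            reannotate_probes(probes, mapping)


class TestIntensityFilter:
    def _bundles(self):
        # probe 1 flagged in 2/5 pooled samples (40%), probe 2 in 4/5
        b1 = _bundle("D1", [(1, "G1"), (2, "G2")],
                     [[1, 1], [1, 1]], pacall=[[1, 0], [1, 1]])
        b2 = _bundle("D2", [(1, "G1"), (2, "G2")],
                     [[1, 1, 1], [1, 1, 1]], pacall=[[1, 0, 0], [1, 1, 0]])
        return [b1, b2]

    def test_threshold_logic_on_pooled_fraction(self):
        bundles = self._bundles()
        assert filter_probes_by_intensity(bundles, 0.25) == {1, 2}
        assert filter_probes_by_intensity(bundles, 0.5) == {2}

    def test_disabled_keeps_all_probes(self):
        bundles = self._bundles()
        assert filter_probes_by_intensity(bundles, None) == {1, 2}

    def test_exactly_at_threshold_is_dropped(self):
        # flagged in exactly half the samples: strict > drops it at 0.5
        bundle = _bundle("D1", [(1, "G1")], [[1, 1, 1, 1]],
                         pacall=[[1, 1, 0, 0]])
        assert filter_probes_by_intensity([bundle], 0.5) == set()
        assert filter_probes_by_intensity([bundle], 0.25) == {1}

    def test_monotone_in_threshold(self, dataset):
        kept_50 = filter_probes_by_intensity(dataset.bundles, 0.5)
        kept_25 = filter_probes_by_intensity(dataset.bundles, 0.25)
        kept_all = filter_probes_by_intensity(dataset.bundles, None)
        assert kept_50 <= kept_25 <= kept_all
        assert len(kept_50) < len(kept_all)

    def test_invalid_threshold_raises(self, dataset):
        with pytest.raises(ParameterError):
            filter_probes_by_intensity(dataset.bundles, 1.0)


class TestSelectionMethods:
    def test_max_intensity_picks_highest_mean(self):
        bundle = _bundle("D1", [(1, "G1"), (2, "G1")],
                         [[5.0, 5.0], [7.0, 7.0]])
        per_donor, report = select_probes(
            [bundle], ProbeSelectionSpec("max_intensity"), [1, 2]
        )
        assert report.loc["G1", "D1"] == 2
        np.testing.assert_allclose(per_donor["D1"].loc["G1"], [7.0, 7.0])

    def test_average_equals_brute_force_mean(self, dataset):
        kept = [int(p) for p in dataset.bundles[0].probes.index]
        per_donor, report = select_probes(
            dataset.bundles, ProbeSelectionSpec("average"), kept
        )
        bundle = dataset.bundles[0]
        annotated = bundle.probes[bundle.probes["gene_symbol"].notna()]
        gene = sorted(annotated["gene_symbol"].unique())[0]
        rows = annotated.index[annotated["gene_symbol"] == gene]
        expected = bundle.expression.loc[rows].to_numpy().mean(axis=0)
        np.testing.assert_allclose(
            per_donor[bundle.donor_id].loc[gene].to_numpy(), expected
        )
        assert (report == "average").all().all()

    def test_corr_intensity_prefers_concordant_probe(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        # probes 1 and 2 track each other; probe 3 is anticorrelated
        expr = np.vstack([base, base + 0.01 * rng.normal(size=12), -base])
        bundle = _bundle("D1", [(1, "G1"), (2, "G1"), (3, "G1")], expr)
        _, report = select_probes(
            [bundle], ProbeSelectionSpec("corr_intensity"), [1, 2, 3]
        )
        assert report.loc["G1", "D1"] in (1, 2)

    def test_two_probe_gene_falls_back_to_intensity_or_variance(self):
        # probe 1 brighter, probe 2 more variable
        expr = np.array([[9.0, 9.0, 9.0], [0.0, 4.0, 8.0]])
        bundle = _bundle("D1", [(1, "G1"), (2, "G1")], expr)
        _, rep_int = select_probes(
            [bundle], ProbeSelectionSpec("corr_intensity"), [1, 2]
        )
        _, rep_var = select_probes(
            [bundle], ProbeSelectionSpec("corr_variance"), [1, 2]
        )
        assert rep_int.loc["G1", "D1"] == 1
        assert rep_var.loc["G1", "D1"] == 2

    def test_diff_stability_prefers_cross_donor_consistent_probe(self):
        # two donors, three shared structures; probe 1 reproduces its
        # profile across donors (Spearman 1), probe 2 reverses (-1)
        samples = [
            make_samples([(1, d, "L", -10, 0, 0), (2, d, "L", -10, 10, 0),
                          (3, d, "L", -10, 20, 0)])
            for d in ("D1", "D2")
        ]
        for s in samples:
            s["structure_acronym"] = ["S1", "S2", "S3"]
        b1 = _bundle("D1", [(1, "G1"), (2, "G1")],
                     [[1, 2, 3], [1, 2, 3]], samples=samples[0])
        b2 = _bundle("D2", [(1, "G1"), (2, "G1")],
                     [[1, 2, 3], [3, 2, 1]], samples=samples[1])
        _, report = select_probes(
            [b1, b2], ProbeSelectionSpec("diff_stability"), [1, 2]
        )
        assert (report.loc["G1"] == 1).all()

    def test_rnaseq_selects_probe_tracking_reference(self):
        rng = np.random.default_rng(1)
        signal = rng.normal(size=10)
        expr = np.vstack([signal, rng.normal(size=10)])
        samples = make_samples(
            [(i + 1, "D1", "L", -10.0, float(i), 0.0) for i in range(10)]
        )
        rnaseq = pd.DataFrame(
            [np.power(2.0, signal)],
            index=pd.Index(["G1"], name="gene_symbol"),
            columns=samples.index,
        )
        bundle = _bundle("D1", [(1, "G1"), (2, "G1")], expr,
                         samples=samples, rnaseq=rnaseq)
        _, report = select_probes(
            [bundle], ProbeSelectionSpec("rnaseq"), [1, 2]
        )
        assert report.loc["G1", "D1"] == 1

    def test_rnaseq_without_data_raises(self):
        bundle = _bundle("D1", [(1, "G1")], [[1.0, 2.0]])
        with pytest.raises(ConfigurationError, match="RNAseq"):
            select_probes([bundle], ProbeSelectionSpec("rnaseq"), [1])

    def test_rnaseq_drops_genes_absent_from_reference(self):
        samples = make_samples(
            [(i + 1, "D1", "L", -10.0, float(i), 0.0) for i in range(5)]
        )
        rnaseq = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, 5.0]],
            index=pd.Index(["G1"], name="gene_symbol"), columns=samples.index,
        )
        bundle = _bundle("D1", [(1, "G1"), (2, "G2")],
                         np.arange(10.0).reshape(2, 5), samples=samples,
                         rnaseq=rnaseq)
        per_donor, _ = select_probes(
            [bundle], ProbeSelectionSpec("rnaseq"), [1, 2]
        )
        assert list(per_donor["D1"].index) == ["G1"]


class TestDonorModes:
    def _three_donors(self):
        # donor-wise max-intensity picks differ: D1, D2 -> probe 1; D3 -> 2
        bundles = []
        picks = {"D1": [[9, 9], [1, 1]], "D2": [[9, 9], [1, 1]],
                 "D3": [[1, 1], [9, 9]]}
        for donor, expr in picks.items():
            bundles.append(_bundle(donor, [(1, "G1"), (2, "G1")], expr))
        return bundles

    def test_common_mode_applies_modal_probe(self):
        bundles = self._three_donors()
        _, report = select_probes(
            bundles, ProbeSelectionSpec("max_intensity", "common"), [1, 2]
        )
        assert (report.loc["G1"] == 1).all()

    def test_independent_mode_allows_different_probes(self):
        bundles = self._three_donors()
        _, report = select_probes(
            bundles, ProbeSelectionSpec("max_intensity", "independent"), [1, 2]
        )
        assert report.loc["G1", "D1"] == 1
        assert report.loc["G1", "D3"] == 2

    def test_donor_independent_methods_force_aggregate(self):
        spec = ProbeSelectionSpec("average", "independent")
        assert spec.donor_mode == "aggregate"
        spec = ProbeSelectionSpec("diff_stability", "common")
        assert spec.donor_mode == "aggregate"


class TestInvariants:
    @pytest.mark.parametrize(
        "method", ["max_intensity", "corr_intensity", "corr_variance",
                   "diff_stability", "rnaseq", "average"]
    )
    def test_single_probe_genes_identical_across_methods(self, method,
                                                         small_dataset):
        bundles = small_dataset.bundles
        probes = bundles[0].probes
        counts = probes["gene_symbol"].value_counts()
        singles = set(counts.index[counts == 1])
        assert singles
        kept = [int(p) for p in probes.index]
        per_donor, _ = select_probes(
            bundles, ProbeSelectionSpec(method), kept
        )
        reference, _ = select_probes(
            bundles, ProbeSelectionSpec("max_intensity"), kept
        )
        for donor in per_donor:
            common = sorted(singles & set(per_donor[donor].index))
            pd.testing.assert_frame_equal(
                per_donor[donor].loc[common], reference[donor].loc[common]
            )

    @pytest.mark.parametrize("method", ["diff_stability", "rnaseq"])
    def test_selection_invariant_to_donor_order(self, method, small_dataset):
        bundles = small_dataset.bundles
        kept = [int(p) for p in bundles[0].probes.index]
        _, fwd = select_probes(bundles, ProbeSelectionSpec(method), kept)
        _, rev = select_probes(bundles[::-1], ProbeSelectionSpec(method), kept)
        pd.testing.assert_frame_equal(fwd, rev)
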
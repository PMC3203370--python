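"""Component scoring, gene selection, classification, biclustering, overlap."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from genefactor import (
    ExpressionMatrix,
    ParameterError,
    RunConfig,
    bicluster_sort,
    classify_samples,
    default_labels,
    fastica_consensus,
    integrate_gene_sets,
    score_components,
    select_discriminating_components,
    select_genes_ica,
    select_genes_nmf,
    simulate_ica_dataset,
    standardize_samples,
)
from genefactor.ica import ICAResult
from genefactor.nsnmf import NsNMFResult


def _labels():
    return default_labels()  # groups ("AD", "control"), 5 + 8 samples


def _nmf_result(w, h, gene_ids=(), sample_ids=()):
    w = np.asarray(w, dtype=float)
    h = np.asarray(h, dtype=float)
    return NsNMFResult(
        metagenes=w, encodings=h, theta=0.5, objective_trace=np.zeros(1),
        restart_id=0, seed=0, converged=True,
        sparseness=np.zeros(2 * w.shape[1]),
        gene_ids=tuple(gene_ids), sample_ids=tuple(sample_ids),
    )


class TestScoreComponents:
    def test_perfect_sign_separation(self):
        labels = _labels()
        col = np.array([-1, -2, -1.5, -1, -2, 1, 1.5, 0.5, 1, 2, 1, 0.5, 1.5],
                       dtype=float)
        scores = score_components(col[:, None], labels)
        assert scores[0].sign_separation == 1.0
        assert abs(scores[0].t_statistic) > 5

    def test_constant_column_scores_zero_t_and_ranks_last(self):
        labels = _labels()
        rng = np.random.default_rng(0)
        mixing = np.column_stack([np.full(13, 2.0), rng.normal(size=13)])
        scores = score_components(mixing, labels)
        assert scores[0].t_statistic == 0.0
        assert scores[0].rank == 2
        assert scores[0].sign_separation == pytest.approx(8 / 13)

    def test_invariant_to_sample_reordering_and_sign_flips(self):
        labels = _labels()
        rng = np.random.default_rng(1)
        mixing = rng.normal(size=(13, 4))
        base = score_components(mixing, labels)

        flipped = score_components(mixing * -1.0, labels)
        for a, b in zip(base, flipped):
            assert a.sign_separation == b.sign_separation
            assert a.t_statistic == pytest.approx(-b.t_statistic)
            assert a.rank == b.rank

        perm = rng.permutation(13)
        ids = labels.sample_ids
        reordered = score_components(
            mixing[perm], labels, tuple(ids[i] for i in perm)
        )
        for a, b in zip(base, reordered):
            assert a.t_statistic == pytest.approx(b.t_statistic)
            assert a.rank == b.rank

    def test_permutation_null_rarely_beats_planted_top(self):
        labels = _labels()
        matrix, truth = simulate_ica_dataset(200, labels, n_modes=4, seed=30)
        planted_top = max(
            abs(s.t_statistic)
            for s in score_components(truth.mixing_matrix, labels)
        )
        rng = np.random.default_rng(31)
        gauss_mixing = rng.normal(size=(13, 13))
        ids = labels.sample_ids
        exceed = 0
        for _ in range(1000):
            perm = rng.permutation(13)
            null_scores = score_components(
                gauss_mixing, labels, tuple(ids[i] for i in perm)
            )
            if max(abs(s.t_statistic) for s in null_scores) > planted_top:
                exceed += 1
        assert exceed / 1000 < 0.05

    def test_select_discriminating_prefers_perfect_separation(self):
        labels = _labels()
        group0 = labels.mask(labels.sample_ids, labels.groups[0])
        perfect = np.where(group0, 1.0, -1.0)
        rng = np.random.default_rng(2)
        mixing = np.column_stack([rng.normal(size=13), perfect,
                                  rng.normal(size=13)])
        scores = score_components(mixing, labels)
        assert select_discriminating_components(scores) == [1]


def _ica_result_from_sources(sources, mixing, gene_ids, sample_ids):
    sources = np.asarray(sources, dtype=float)
    c = sources.shape[0]
    return ICAResult(
        mixing=np.asarray(mixing, dtype=float), sources=sources,
        whitening=None, stability=np.ones(c), restart_count=1,
        converged_count=1, objective=np.zeros(c),
        gene_ids=tuple(gene_ids), sample_ids=tuple(sample_ids),
    )


class TestSelectGenesICA:
    def _setup(self, loadings, flip_mixing=False):
        labels = _labels()
        n = len(loadings)
        gene_ids = tuple(f"g{i + 1}" for i in range(n))
        group0 = labels.mask(labels.sample_ids, labels.groups[0])
        mixing = np.where(group0, 1.0, -1.0)[:, None]
        if flip_mixing:
            mixing = -mixing
        res = _ica_result_from_sources(
            np.asarray(loadings)[None, :], mixing, gene_ids, labels.sample_ids
        )
        return labels, res

    def test_threshold_rule_with_boundary_inclusive(self):
        rng = np.random.default_rng(3)
        loadings = np.concatenate([[9.0, -8.0, 0.1, 7.0], rng.normal(size=200)])
        labels, res = self._setup(loadings)
        z = (loadings - loadings.mean()) / loadings.std(ddof=1)
        boundary = abs(z[3])  # threshold set exactly at gene g4's |z|
        table = select_genes_ica(res, [0], float(boundary), labels)
        got = dict(zip(table.gene_id, table.direction))
        assert got["g1"] == "up" and got["g2"] == "down" and got["g4"] == "up"
        assert "g3" not in got

    def test_orientation_absorbs_sign_indeterminacy(self):
        rng = np.random.default_rng(4)
        loadings = np.concatenate([[9.0, -8.0], rng.normal(size=100)])
        labels, res = self._setup(loadings)
        flipped_res = dataclasses.replace(
            res, sources=-res.sources, mixing=-res.mixing
        )
        a = select_genes_ica(res, [0], 2.5, labels)
        b = select_genes_ica(flipped_res, [0], 2.5, labels)
        pd.testing.assert_frame_equal(a, b)

    def test_threshold_above_max_gives_empty_table(self):
        rng = np.random.default_rng(5)
        labels, res = self._setup(rng.normal(size=50))
        table = select_genes_ica(res, [0], 50.0, labels)
        assert table.empty
        assert list(table.columns) == [
            "gene_id", "method", "component", "loading", "zscore", "direction"
        ]

    def test_empty_component_list_rejected(self):
        rng = np.random.default_rng(6)
        labels, res = self._setup(rng.normal(size=50))
        with pytest.raises(ParameterError):
            select_genes_ica(res, [], 2.5, labels)

    def test_planted_sensitivity_and_fpr(self):
        labels = _labels()
        matrix, truth = simulate_ica_dataset(
            2000, labels, n_modes=4, frac_significant=0.02, signal_z=4.0,
            noise_sd=0.5, seed=40,
        )
        cfg = RunConfig(seed=40, ica_n_restarts=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fastica_consensus(standardize_samples(matrix), cfg)
        from genefactor.ica import _row_corr_abs, greedy_match

        pairs = greedy_match(_row_corr_abs(truth.mode_matrix, res.sources))
        for mode, comp, _ in pairs:
            planted = truth.significant_ids(mode)
            selected = set(
                select_genes_ica(res, [comp], 2.5, labels).gene_id
            )
            sens = len(selected & planted) / len(planted)
            fpr = len(selected - planted) / (matrix.n_genes - len(planted))
            assert sens >= 0.9
            assert fpr <= 0.02


class TestSelectGenesNMF:
    def test_extreme_spike_selected_alone(self):
        labels = _labels()
        n = 100
        gene_ids = tuple(f"g{i + 1}" for i in range(n))
        rng = np.random.default_rng(7)
        w = np.full((n, 1), 0.01)
        w[41, 0] = 10.0
        data = ExpressionMatrix(rng.random((n, 13)) + 0.5, gene_ids,
                                labels.sample_ids)
        res = _nmf_result(w, np.ones((1, 13)), gene_ids, labels.sample_ids)
        table = select_genes_nmf(res, 2.5, data, labels)
        assert list(table.gene_id) == ["g42"]

    def test_direction_from_group_means_with_tie_down(self):
        labels = _labels()
        n = 50
        gene_ids = ("up_gene", "down_gene", "tie_gene") + tuple(
            f"bg{i}" for i in range(n - 3))
        group0 = labels.mask(labels.sample_ids, labels.groups[0])
        values = np.ones((n, 13))
        values[0, group0] = 5.0   # higher in the group of interest
        values[1, ~group0] = 5.0  # higher in the other group
        data = ExpressionMatrix(values, gene_ids, labels.sample_ids)
        w = np.full((n, 1), 0.01)
        w[:3, 0] = 5.0
        res = _nmf_result(w, np.ones((1, 13)), gene_ids, labels.sample_ids)
        table = select_genes_nmf(res, 2.5, data, labels)
        got = dict(zip(table.gene_id, table.direction))
        assert got == {"up_gene": "up", "down_gene": "down", "tie_gene": "down"}


class TestClassifySamples:
    @pytest.mark.parametrize(
        "column, expected",
        [((0.9, 0.1), 0), ((0.1, 0.9), 1), ((0.5, 0.5), 0)],
    )
    def test_argmax_with_tie_to_lowest(self, column, expected):
        h = np.array(column)[:, None]
        assert classify_samples(h) == [expected]

    def test_negative_encoding_rejected(self):
        with pytest.raises(ParameterError):
            classify_samples(np.array([[0.5], [-0.1]]))


class TestBiclusterSort:
    def _data(self, n, labels):
        rng = np.random.default_rng(8)
        return ExpressionMatrix(
            rng.random((n, 13)), tuple(f"g{i}" for i in range(n)),
            labels.sample_ids,
        )

    def test_descending_order_with_index_ties(self):
        labels = _labels()
        data = self._data(3, labels)
        res = _nmf_result(
            np.array([[0.1, 0.3], [0.9, 0.3], [0.5, 0.3]]),
            np.tile(np.arange(13.0)[::-1], (2, 1)),
            data.gene_ids, labels.sample_ids,
        )
        rows, cols = bicluster_sort(data, res, 0)
        assert list(rows) == [1, 2, 0]
        rows2, _ = bicluster_sort(data, res, 1)
        assert list(rows2) == [0, 1, 2]  # all-tied column keeps input order
        assert list(cols) == list(range(13))

    def test_pure_permutation_and_idempotence(self):
        labels = _labels()
        data = self._data(30, labels)
        rng = np.random.default_rng(9)
        res = _nmf_result(rng.random((30, 2)), rng.random((2, 13)),
                          data.gene_ids, labels.sample_ids)
        rows, cols = bicluster_sort(data, res, 1)
        assert sorted(rows) == list(range(30))
        assert sorted(cols) == list(range(13))
        view = data.values[np.ix_(rows, cols)]
        assert sorted(view.ravel()) == sorted(data.values.ravel())

    def test_gene_shuffle_invariance(self):
        labels = _labels()
        data = self._data(30, labels)
        rng = np.random.default_rng(10)
        w = rng.random((30, 2))
        h = rng.random((2, 13))
        res = _nmf_result(w, h, data.gene_ids, labels.sample_ids)
        rows, _ = bicluster_sort(data, res, 0)
        base_ids = [data.gene_ids[i] for i in rows]

        perm = rng.permutation(30)
        shuffled = ExpressionMatrix(
            data.values[perm], tuple(data.gene_ids[i] for i in perm),
            labels.sample_ids,
        )
        res_shuffled = _nmf_result(w[perm], h, shuffled.gene_ids,
                                   labels.sample_ids)
        rows_s, _ = bicluster_sort(shuffled, res_shuffled, 0)
        # Identical loadings => identical gene_id sequence (ties aside).
        shuffled_ids = [shuffled.gene_ids[i] for i in rows_s]
        assert shuffled_ids == base_ids

    def test_factor_out_of_range(self):
        labels = _labels()
        data = self._data(5, labels)
        res = _nmf_result(np.ones((5, 2)), np.ones((2, 13)),
                          data.gene_ids, labels.sample_ids)
        with pytest.raises(ParameterError):
            bicluster_sort(data, res, 2)


class TestIntegrate:
    @staticmethod
    def _table(method, entries):
        return pd.DataFrame(
            [
                {"gene_id": g, "method": method, "component": 0,
                 "loading": 1.0, "zscore": 3.0, "direction": d}
                for g, d in entries
            ]
        )

    def test_overlap_and_jaccard(self):
        ica = self._table("ica", [("a", "up"), ("b", "up"), ("c", "down")])
        nmf = self._table("nmf", [("b", "up"), ("c", "down"), ("d", "up")])
        report = integrate_gene_sets(ica, nmf)
        assert report["intersection"] == ["b", "c"]
        assert report["jaccard"] == pytest.approx(0.5)
        prov = {g["gene_id"]: g["provenance"] for g in report["genes"]}
        assert prov == {"a": "ica-only", "b": "both", "c": "both",
                        "d": "nmf-only"}

    def test_disjoint_sets(self):
        report = integrate_gene_sets(
            self._table("ica", [("a", "up")]),
            self._table("nmf", [("b", "down")]),
        )
        assert report["jaccard"] == 0.0
        assert report["intersection"] == []

    def test_direction_conflict_flagged(self):
        report = integrate_gene_sets(
            self._table("ica", [("a", "up")]),
            self._table("nmf", [("a", "down")]),
        )
        (entry,) = report["genes"]
        assert entry["direction_conflict"] is True
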
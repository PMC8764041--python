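import json

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from digestnet.community import (
    AbundanceTable,
    GroupAssignment,
    alpha_diversity,
    bray_curtis,
    network_filter,
    pcoa,
    propose_groups,
    read_abundance_tsv,
    read_biom_json,
    subsample_steady_state,
    to_relative,
)


def table_from(arr, samples=None, taxa=None, **kw):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"S{i}" for i in range(arr.shape[0])]
    taxa = taxa or [f"T{j}" for j in range(arr.shape[1])]
    return AbundanceTable(pd.DataFrame(arr, index=samples, columns=taxa), **kw)


class TestNormalization:
    def test_counts_to_proportions(self):
        rel = to_relative(table_from([[2, 2], [1, 3]]))
        assert rel.relative
        np.testing.assert_allclose(rel.data.to_numpy(), [[0.5, 0.5], [0.25, 0.75]])

    def test_idempotent_on_relative_input(self):
        rel = to_relative(table_from([[2, 2], [1, 3]]))
        assert to_relative(rel) is rel

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        rel = to_relative(table_from(rng.integers(0, 50, size=(10, 30))
                                     + (rng.random((10, 30)) < 0.2)))
        np.testing.assert_allclose(rel.data.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError, match="zero-total"):
            to_relative(table_from([[0, 0], [1, 1]]))

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            table_from([[-1, 2]])
        with pytest.raises(ValueError, match="duplicate taxon"):
            table_from([[1, 2]], taxa=["a", "a"])


class TestNetworkFilter:
    def test_kept_and_dropped_rules(self):
        # taxon A: 0.2% in 3 of 8 samples -> kept; taxon B: 5% in 2 samples -> dropped
        n = 8
        data = np.full((n, 3), 0.0)
        data[:, 2] = 1.0  # filler taxon, always abundant
        data[:3, 0] = 0.002
        data[:2, 1] = 0.05
        t = table_from(data / data.sum(1, keepdims=True), taxa=["A", "B", "filler"])
        kept, report = network_filter(t)
        assert "A" in kept.taxon_ids and "filler" in kept.taxon_ids
        assert "B" not in kept.taxon_ids
        assert set(report["taxon_id"]) == {"B"}

    def test_hand_labelled_ten_taxon_fixture(self):
        # 6 samples; hand count: taxa 0-4 qualify (>0.1% in >=3 samples), 5-9 fail
        rows = 6
        m = np.zeros((rows, 10))
        m[:, 0] = 0.10          # always abundant
        m[:3, 1] = 0.05         # exactly 3 samples
        m[:4, 2] = 0.002        # low but above threshold in 4
        m[:, 3] = 0.0011        # barely above in all
        m[[0, 2, 4], 4] = 0.01  # 3 scattered samples
        m[:2, 5] = 0.30         # only 2 samples
        m[:, 6] = 0.0009        # always below 0.1%
        m[:, 7] = 0.001         # exactly at threshold: "higher than" excludes
        m[0, 8] = 0.5           # single sample
        # taxon 9 absent everywhere
        filler = 1.0 - m.sum(axis=1)
        t = AbundanceTable(pd.DataFrame(
            np.column_stack([m, filler]),
            index=[f"S{i}" for i in range(rows)],
            columns=[f"T{j}" for j in range(10)] + ["filler"]), relative=True)
        kept, report = network_filter(t)
        assert set(kept.taxon_ids) == {"T0", "T1", "T2", "T3", "T4", "filler"}
        assert set(report["taxon_id"]) == {"T5", "T6", "T7", "T8", "T9"}

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        t = to_relative(table_from(rng.pareto(1.2, size=(8, 40)) + 0.01))
        once, _ = network_filter(t)
        twice, rep = network_filter(once)
        assert list(twice.taxon_ids) == list(once.taxon_ids)
        assert len(rep) == 0

    def test_too_few_samples_refused(self):
        with pytest.raises(ValueError, match="samples"):
            network_filter(to_relative(table_from(np.ones((3, 5)))))


class TestAlphaDiversity:
    def test_uniform_and_single_taxon(self):
        d = alpha_diversity(table_from([[1, 1, 1, 1], [4, 0, 0, 0]]))
        assert d.loc["S0", "shannon"] == pytest.approx(np.log(4))
        assert d.loc["S0", "evenness"] == pytest.approx(1.0)
        assert d.loc["S0", "richness"] == 4
        assert d.loc["S1", "shannon"] == 0.0
        assert d.loc["S1", "evenness"] == 0.0  # degenerate richness=1

    def test_against_independent_summation(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 100, size=(5, 25))
        counts[:, 0] += 1
        d = alpha_diversity(table_from(counts))
        for i in range(5):
            p = counts[i] / counts[i].sum()
            h = -sum(pi * np.log(pi) for pi in p if pi > 0)
            assert d["shannon"].iloc[i] == pytest.approx(h)
            assert d["richness"].iloc[i] == (counts[i] > 0).sum()


class TestBrayCurtis:
    def test_identical_and_disjoint(self):
        d = bray_curtis(table_from([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)
        assert d.iloc[0, 2] == pytest.approx(1.0)

    def test_three_sample_hand_computation(self):
        # x=(.5,.5), y=(.2,.8): BC = (|.3|+|.3|)/2 = 0.3
        d = bray_curtis(table_from([[0.5, 0.5], [0.2, 0.8]], relative=True))
        assert d.iloc[0, 1] == pytest.approx(0.3)

    def test_metric_axioms_on_random_pairs(self):
        rng = np.random.default_rng(3)
        t = to_relative(table_from(rng.random((50, 20)) + 1e-6))
        d = bray_curtis(t).to_numpy()
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all((d >= 0) & (d <= 1 + 1e-12))


class TestPCoA:
    def test_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 3))
        dist = pd.DataFrame(squareform(pdist(pts)))
        res = pcoa(dist)
        coords = res.coordinates.to_numpy()[:, :3]
        rec = squareform(pdist(coords))
        np.testing.assert_allclose(rec, squareform(pdist(pts)), atol=1e-8)
        assert res.n_negative == 0

    def test_collinear_points_need_one_axis(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        res = pcoa(pd.DataFrame(squareform(pdist(pts))))
        assert (res.eigenvalues > 1e-8).sum() == 1

    def test_group_separation_on_first_axis(self):
        rng = np.random.default_rng(5)
        a = rng.dirichlet([5, 5, 1, 1], size=10)
        b = rng.dirichlet([1, 1, 5, 5], size=10)
        t = AbundanceTable(pd.DataFrame(np.vstack([a, b]),
                                        index=[f"S{i}" for i in range(20)],
                                        columns=list("wxyz")), relative=True)
        res = pcoa(bray_curtis(t))
        ax1 = res.coordinates.iloc[:, 0].to_numpy()
        between = abs(ax1[:10].mean() - ax1[10:].mean())
        within = max(ax1[:10].std(), ax1[10:].std())
        assert between > within

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            pcoa(pd.DataFrame(np.ones((2, 3))))
        m = pd.DataFrame([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(m)


class TestSubsample:
    def make(self, n, steady, stages):
        t = to_relative(table_from(np.ones((n, 3)) + np.arange(n)[:, None]))
        meta = pd.DataFrame({"group": "g", "steady_state": steady, "stage": stages},
                            index=t.data.index)
        return t, meta

    def test_group_at_cap_unchanged(self):
        t, meta = self.make(8, [True] * 8, list(range(8)))
        out, dropped = subsample_steady_state(t, meta, max_per_group=8)
        assert list(out.data.index) == list(t.data.index)
        assert len(dropped) == 0

    def test_steady_samples_preferred(self):
        steady = [True] * 8 + [False] * 12
        t, meta = self.make(20, steady, list(range(20)))
        out, dropped = subsample_steady_state(t, meta, max_per_group=8)
        assert set(out.data.index) == set(t.data.index[:8])
        assert len(dropped) == 12

    def test_tie_break_deterministic_across_runs(self):
        t, meta = self.make(10, [True] * 10, [1] * 10)  # all tied
        out1, _ = subsample_steady_state(t, meta, max_per_group=4)
        out2, _ = subsample_steady_state(t, meta, max_per_group=4)
        assert list(out1.data.index) == list(out2.data.index)
        assert list(out1.data.index) == sorted(out1.data.index)


class TestIO:
    def test_tsv_roundtrip_both_orientations(self, tmp_path):
        t = to_relative(table_from([[1, 2, 3], [4, 5, 6]]))
        p = tmp_path / "a.tsv"
        t.to_tsv(p, header_comment="stage=test")
        back = read_abundance_tsv(p)
        pd.testing.assert_frame_equal(back.data, t.data, check_names=False)
        assert back.relative
        pt = tmp_path / "b.tsv"
        t.data.T.rename_axis("taxon_id").to_csv(pt, sep="\t")
        back_t = read_abundance_tsv(pt, orientation="taxa_by_samples")
        np.testing.assert_allclose(back_t.data.to_numpy(), t.data.to_numpy())

    def test_biom_json_sparse(self, tmp_path):
        doc = {
            "rows": [{"id": "g__A", "metadata": {"taxonomy": ["k__B", "g__A"]}},
                     {"id": "g__B", "metadata": None}],
            "columns": [{"id": "S1"}, {"id": "S2"}, {"id": "S3"}],
            "matrix_type": "sparse",
            "data": [[0, 0, 5], [0, 2, 1], [1, 1, 7]],
        }
        p = tmp_path / "t.biom"
        p.write_text(json.dumps(doc))
        t = read_biom_json(p)
        assert t.data.shape == (3, 2)
        assert t.data.loc["S1", "g__A"] == 5
        assert t.data.loc["S2", "g__B"] == 7
        assert t.lineage["g__A"] == "k__B; g__A"

    def test_group_assignment_roundtrip(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("sample_id\tgroup\nS1\ta\nS2\tb\n")
        ga = GroupAssignment.from_tsv(p)
        assert ga.labels() == ["a", "b"]
        assert ga.samples_in("a") == ["S1"]


def test_propose_groups_recovers_two_clear_clusters():
    rng = np.random.default_rng(6)
    a = rng.dirichlet([20, 20, 1, 1], size=6)
    b = rng.dirichlet([1, 1, 20, 20], size=6)
    t = AbundanceTable(pd.DataFrame(np.vstack([a, b]),
                                    index=[f"S{i}" for i in range(12)],
                                    columns=list("wxyz")), relative=True)
    ga = propose_groups(t, k=2)
    assert ga.provenance == "clustering-assisted"
    first = {ga.groups[f"S{i}"] for i in range(6)}
    second = {ga.groups[f"S{i}"] for i in range(6, 12)}
    assert len(first) == 1 and len(second) == 1 and first != second
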
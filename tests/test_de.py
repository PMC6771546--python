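import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import grouping_from_labels, make_norm
from ikap.candidates import CandidateSet
from ikap.de import (
    DE_COLUMNS,
    aggregate_errors,
    classification_error,
    compute_auroc,
    find_de_genes,
    summarize,
)


def brute_force_auroc(a, b):
    """Oracle: enumerate all pairs, ties worth 0.5."""
    wins = sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    return wins / (len(a) * len(b))


class TestComputeAuroc:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([5, 6], [1, 2], 1.0),
            ([2, 2, 2], [2, 2], 0.5),
            ([3, 1], [2, 0], 0.75),
            ([1, 2], [5, 6], 0.0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert compute_auroc(a, b) == pytest.approx(expected)

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            compute_auroc([], [1.0])

    @given(
        st.lists(st.integers(0, 5), min_size=1, max_size=30),
        st.lists(st.integers(0, 5), min_size=1, max_size=30),
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_pair_enumeration(self, a, b):
        assert compute_auroc(a, b) == pytest.approx(brute_force_auroc(a, b))


def _three_group_norm(n_per=40, seed=0):
    """Normalized matrix with planted per-group markers plus noise genes.

    gene0: constant 5 in group 0, zero elsewhere (perfect marker).
    gene1: identical distribution everywhere.
    gene2: lower in group 0 than elsewhere (downregulated).
    gene3/gene4: markers of groups 1 / 2.
    """
    rng = np.random.default_rng(seed)
    n = 3 * n_per
    labels = np.repeat([0, 1, 2], n_per)
    mat = np.zeros((8, n))
    mat[0, labels == 0] = 5.0
    mat[1] = rng.gamma(2.0, 0.5, n)
    mat[2] = np.where(labels == 0, 0.1, 3.0) + rng.normal(0, 0.01, n)
    mat[2] = np.clip(mat[2], 0, None)
    mat[3, labels == 1] = 4.0
    mat[4, labels == 2] = 4.0
    for i in (5, 6, 7):
        mat[i] = np.clip(rng.normal(0.5, 0.2, n), 0, None)
    return make_norm(mat), grouping_from_labels(labels)


class TestFindDeGenes:
    def test_perfect_marker_reported_with_auroc_one(self):
        norm, grouping = _three_group_norm()
        de = find_de_genes(norm, grouping)
        row = de[(de["gene"] == "gene0") & (de["group"] == 0)]
        assert len(row) == 1
        assert row["auroc"].iloc[0] == pytest.approx(1.0)
        assert row["avg_logFC"].iloc[0] > 2.0
        assert row["pct_in"].iloc[0] == 1.0 and row["pct_out"].iloc[0] == 0.0

    def test_uninformative_gene_not_reported(self):
        norm, grouping = _three_group_norm()
        de = find_de_genes(norm, grouping)
        assert "gene1" not in set(de["gene"])

    def test_downregulated_gene_not_reported_for_its_group(self):
        norm, grouping = _three_group_norm()
        de = find_de_genes(norm, grouping)
        sub = de[(de["gene"] == "gene2") & (de["group"] == 0)]
        assert len(sub) == 0  # only upregulated genes are reported
        assert ((de["avg_logFC"] > 0).all())

    def test_small_group_skipped_with_warning(self, caplog):
        norm, _ = _three_group_norm(n_per=40)
        labels = np.zeros(120, dtype=int)
        labels[:2] = 1  # 2-cell group
        grouping = grouping_from_labels(labels)
        with caplog.at_level("WARNING", logger="ikap.de"):
            find_de_genes(norm, grouping)
        assert any("skipping DE" in r.message for r in caplog.records)

    def test_needs_two_groups(self):
        norm, _ = _three_group_norm()
        with pytest.raises(ValueError):
            find_de_genes(norm, grouping_from_labels(np.zeros(120, dtype=int)))


class TestClassificationError:
    def test_hand_built_aggregation(self):
        """One group at fraction 0.3 with relative error 0.2 at every nsplit,
        all other groups at zero: final error = 0.2 * 0.3 = 0.06 exactly."""
        nsplits = np.arange(5, 16)
        rel = {0: np.full(11, 0.2), 1: np.zeros(11), 2: np.zeros(11)}
        frac = {0: 0.3, 1: 0.4, 2: 0.3}
        set_err, final = aggregate_errors(rel, frac, nsplits)
        assert np.allclose(set_err, 0.06)
        assert final == pytest.approx(0.06, abs=1e-15)

    def test_perfectly_separable_gives_zero(self):
        norm, grouping = _three_group_norm()
        de = find_de_genes(norm, grouping)
        report = classification_error(norm, grouping, de)
        assert report.final_error == 0.0
        assert np.all(report.set_error_by_nsplit == 0.0)

    def test_relative_errors_nonincreasing_in_nsplit(self, rng):
        n = 150
        labels = rng.integers(0, 3, n)
        labels[:3] = [0, 1, 2]
        mat = rng.gamma(1.0, 1.0, (12, n))
        mat[0] += 1.5 * (labels == 0)  # noisy marker
        mat[1] += 1.5 * (labels == 1)
        mat[2] += 1.5 * (labels == 2)
        norm = make_norm(mat)
        grouping = grouping_from_labels(labels)
        de = pd.DataFrame(
            [(f"gene{i}", i, 0.5, 1e-4, 1e-3, 0.9, 0.5, 0.9) for i in range(3)],
            columns=DE_COLUMNS,
        )
        report = classification_error(norm, grouping, de)
        for rel in report.relative_errors.values():
            assert np.all(np.diff(rel) <= 1e-12)
            assert np.all((rel >= 0) & (rel <= 1))
        assert 0.0 <= report.final_error <= 1.0

    def test_no_de_genes_errors(self):
        norm, grouping = _three_group_norm()
        with pytest.raises(ValueError, match="cannot evaluate"):
            classification_error(norm, grouping, pd.DataFrame(columns=DE_COLUMNS))


def _candidate(name, npc, k, de_rows, final_error):
    import dataclasses

    from ikap.de import ClassifierReport

    labels = np.arange(max(2 * k, k)) % k
    report = ClassifierReport(
        nsplits=np.arange(5, 16),
        relative_errors={},
        group_fractions={},
        set_error_by_nsplit=np.full(11, final_error),
        final_error=final_error,
    )
    return CandidateSet(
        name=name, nPC=npc, k=k, gap_increase=0.1,
        grouping=grouping_from_labels(labels),
        de=pd.DataFrame(de_rows, columns=DE_COLUMNS),
        report=report,
    )


def _de_rows(counts_above, group_offset=0):
    """counts_above: per group, number of genes with auroc 0.95."""
    rows = []
    for g, c in enumerate(counts_above):
        for i in range(c):
            rows.append(
                (f"g{g}_{i}", g + group_offset, 1.0 + 0.01 * i, 1e-6, 1e-5, 0.9, 0.1, 0.95)
            )
    return rows


class TestSummarize:
    def test_median_counts_across_groups(self):
        cand = _candidate("PC5K3", 5, 3, _de_rows([10, 20, 30]), 0.05)
        s = summarize([cand])
        assert s["n_de_auroc_0.8"].iloc[0] == 20.0
        assert s["n_de_auroc_0.9"].iloc[0] == 20.0

    def test_top10_rule_uses_all_when_fewer(self):
        # one group with 4 qualifying genes -> mean over those 4
        rows = [
            ("a", 0, 2.0, 1e-6, 1e-5, 0.9, 0.1, 0.95),
            ("b", 0, 1.0, 1e-6, 1e-5, 0.9, 0.1, 0.95),
            ("c", 0, 0.5, 1e-6, 1e-5, 0.9, 0.1, 0.9),
            ("d", 0, 0.3, 1e-6, 1e-5, 0.9, 0.1, 0.85),
            ("low", 0, 9.0, 1e-6, 1e-5, 0.9, 0.1, 0.7),  # auroc <= 0.8: excluded
        ]
        cand = _candidate("PC5K1", 5, 1, rows, 0.05)
        cand.grouping = grouping_from_labels([0, 0])
        cand.k = 1
        s = summarize([cand])
        assert s["median_top10_avg_logFC"].iloc[0] == pytest.approx((2 + 1 + 0.5 + 0.3) / 4)
        assert s["median_top10_avg_log2FC"].iloc[0] == pytest.approx(
            (2 + 1 + 0.5 + 0.3) / 4 / np.log(2)
        )

    def test_lowest_error_marked_best(self):
        a = _candidate("PC5K3", 5, 3, _de_rows([5, 5, 5]), 0.04)
        b = _candidate("PC9K4", 9, 4, _de_rows([5, 5, 5, 5]), 0.02)
        s = summarize([a, b])
        assert list(s["is_best"]) == [False, True]
        assert s["is_best"].sum() == 1

    def test_error_tie_goes_to_smaller_k(self):
        a = _candidate("PC9K4", 9, 4, _de_rows([5] * 4), 0.02)
        b = _candidate("PC5K3", 5, 3, _de_rows([5] * 3), 0.02)
        s = summarize([a, b])
        assert s.loc[s["is_best"], "candidate"].iloc[0] == "PC5K3"

    def test_group_relabeling_leaves_metrics_invariant(self):
        rows = _de_rows([3, 8, 15])
        perm = {0: 2, 1: 0, 2: 1}
        rows_perm = [(g, perm[grp], *rest) for g, grp, *rest in rows]
        a = _candidate("PC5K3", 5, 3, rows, 0.03)
        b = _candidate("PC5K3", 5, 3, rows_perm, 0.03)
        sa, sb = summarize([a]), summarize([b])
        metric_cols = [c for c in sa.columns if c.startswith(("n_de", "median_"))]
        assert sa[metric_cols].equals(sb[metric_cols])

    def test_empty_candidate_list_errors(self):
        with pytest.raises(ValueError):
            summarize([])
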
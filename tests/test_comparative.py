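"""Expression matrices, UPGMA against a brute-force oracle, HEC ratios."""

import warnings

import numpy as np
import pandas as pd
import pytest

from picevo import comparative as cmp
from picevo.comparative import (
    expression_matrix,
    group_read_shares,
    group_transposon_divergence,
    hec_pingpong_ratio,
    hec_sets,
    hierarchical_cluster,
    pearson_distance_matrix,
)
from picevo.core_io import MappedRead, RepeatFeature
from picevo.homology import HomologGroup


def _group(gid, members, present, expressed):
    return HomologGroup(gid, members, present, expressed)


def brute_force_upgma(dist: pd.DataFrame):
    """Naive UPGMA: cophenetic distance matrix by repeated merging."""
    clusters = {i: [lbl] for i, lbl in enumerate(dist.index)}
    d = {
        (i, j): dist.iloc[i, j]
        for i in clusters
        for j in clusters
        if i < j
    }
    coph = pd.DataFrame(0.0, index=dist.index, columns=dist.index)
    nxt = len(clusters)
    while len(clusters) > 1:
        (i, j), h = min(d.items(), key=lambda kv: kv[1])
        for a in clusters[i]:
            for b in clusters[j]:
                coph.loc[a, b] = coph.loc[b, a] = h
        merged = clusters[i] + clusters[j]
        ni, nj = len(clusters[i]), len(clusters[j])
        new = {}
        for k in clusters:
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            new[k] = (ni * dik + nj * djk) / (ni + nj)
        del clusters[i], clusters[j]
        d = {
            (a, b): v
            for (a, b), v in d.items()
            if i not in (a, b) and j not in (a, b)
        }
        clusters[nxt] = merged
        for k, v in new.items():
            d[(min(k, nxt), max(k, nxt))] = v
        nxt += 1
    return coph


class TestExpressionMatrix:
    def test_absent_member_is_zero(self):
        g = _group(
            "h1", {"a": "c1"}, {"a": True, "b": False}, {"a": True, "b": False}
        )
        mat = expression_matrix([g], {"a": {"c1": 50.0}, "b": {}})
        assert mat.loc["h1", "a"] == 50.0
        assert mat.loc["h1", "b"] == 0.0

    def test_non_expressed_member_zeroed(self):
        g = _group(
            "h1", {"a": "c1", "b": "c2"},
            {"a": True, "b": True}, {"a": True, "b": False},
        )
        mat = expression_matrix([g], {"a": {"c1": 5.0}, "b": {"c2": 9.0}})
        assert mat.loc["h1", "b"] == 0.0

    def test_species_mismatch_raises(self):
        g = _group("h1", {"a": "c1", "z": "c9"}, {"a": True}, {"a": True})
        with pytest.raises(ValueError, match="missing"):
            expression_matrix([g], {"a": {"c1": 5.0}})

    def test_column_sums_bounded_by_1e6(self, default_study, lenient_calls):
        from picevo.workflows import truth_expression_matrix

        mat = truth_expression_matrix(default_study, lenient_calls)
        assert (mat.sum(axis=0) <= 1e6 + 1e-6).all()

    def test_planted_expression_shift_recovered(self, default_study, lenient_calls):
        from picevo.workflows import truth_expression_matrix

        mat = truth_expression_matrix(default_study, lenient_calls)
        planted = default_study.expression
        for sp in mat.columns:
            active = mat[mat[sp] > 0]
            got = active[sp]
            want = planted.loc[active.index, sp]
            want = want / want.sum() * got.sum()
            # planted relative levels recovered within sampling noise
            r = np.corrcoef(np.log10(got), np.log10(want))[0, 1]
            assert r > 0.95


class TestHierarchicalCluster:
    def test_duplicated_column_merges_first_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.random(20)
        mat = pd.DataFrame(
            {"a": base, "b": base, "c": rng.random(20)},
            index=[f"g{i}" for i in range(20)],
        )
        dend = hierarchical_cluster(mat, axis="columns")
        assert dend.first_merge() == ("a", "b")
        assert dend.merge_heights()[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n_items", [4, 7, 10])
    def test_matches_brute_force_upgma(self, n_items):
        rng = np.random.default_rng(n_items)
        mat = pd.DataFrame(
            rng.random((30, n_items)),
            columns=[f"s{i}" for i in range(n_items)],
        )
        dend = hierarchical_cluster(mat, axis="columns")
        dist = pearson_distance_matrix(mat, axis="columns")
        oracle = brute_force_upgma(dist)
        got = dend.cophenetic().loc[oracle.index, oracle.columns]
        assert np.allclose(got.to_numpy(), oracle.to_numpy(), atol=1e-9)

    def test_species_dendrogram_topology_matches_simulation_tree(
        self, default_study, lenient_calls
    ):
        from picevo.workflows import truth_expression_matrix

        mat = truth_expression_matrix(default_study, lenient_calls)
        dend = hierarchical_cluster(mat, axis="columns")
        # ladder tree: the two species with the smallest divergence-from-
        # root times (spcA at 1 My, spcB at 25 My) must merge first
        assert dend.first_merge() == ("spcA", "spcB")

    def test_single_item_raises(self):
        mat = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            hierarchical_cluster(mat, axis="columns")

    def test_constant_profile_distance_flagged_as_one(self):
        mat = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.5, 1.2, 3.0]})
        with pytest.warns(UserWarning, match="constant"):
            dist = pearson_distance_matrix(mat, axis="columns")
        assert dist.loc["a", "b"] == 1.0


class TestGroupShares:
    def test_all_category_one_gives_unit_share(self):
        groups = [
            _group(
                f"h{i}", {"a": f"c{i}"}, {"a": True}, {"a": True}
            )
            for i in range(3)
        ]
        shares = group_read_shares(
            groups, {"a": {f"c{i}": 10.0 for i in range(3)}}
        )
        assert shares.loc["a", "category_1"] == pytest.approx(1.0)

    def test_shares_sum_to_one(self, default_study, lenient_calls):
        from picevo.workflows import (
            match_loci_to_truth,
            truth_homolog_groups,
        )

        groups = truth_homolog_groups(default_study)
        weights = {}
        for sp, loci in lenient_calls.items():
            matched = match_loci_to_truth(loci, default_study, sp)
            weights[sp] = {
                cid: l.weighted_read_count for cid, l in matched.items()
            }
        shares = group_read_shares(groups, weights)
        for sp in weights:
            assert shares.loc[sp].sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_category_mixture_recovered(self, default_study, lenient_calls):
        from picevo.workflows import (
            match_loci_to_truth,
            truth_homolog_groups,
        )

        groups = truth_homolog_groups(default_study)
        weights = {}
        for sp, loci in lenient_calls.items():
            matched = match_loci_to_truth(loci, default_study, sp)
            weights[sp] = {
                cid: l.weighted_read_count for cid, l in matched.items()
            }
        shares = group_read_shares(groups, weights)
        truth_cat = {c.cluster_id: c.category for c in default_study.clusters}
        for sp in weights:
            total = sum(weights[sp].values())
            for k in (1, 2, 3):
                want = (
                    sum(
                        w
                        for cid, w in weights[sp].items()
                        if truth_cat[cid] == k
                    )
                    / total
                )
                assert shares.loc[sp, f"category_{k}"] == pytest.approx(want)


class TestHec:
    def _matrix(self):
        return pd.DataFrame(
            {
                "a": [100.0, 10.0, 1.0, 50.0],
                "b": [10.0, 10.0, 5.0, 50.0],
                "c": [1.0, 10.0, 20.0, 50.0],
            },
            index=["h1", "h2", "h3", "h4"],
        )

    def test_identical_expression_no_hec_at_fold_2(self):
        mat = pd.DataFrame({"a": [5.0, 7.0], "b": [5.0, 7.0]},
                           index=["h1", "h2"])
        sets = hec_sets(mat, (2,))
        assert sets[2] == {"a": [], "b": []}

    def test_fold_one_uses_cross_species_maximum(self):
        sets = hec_sets(self._matrix(), (1,))
        assert sets[1]["a"] == ["h1", "h2", "h4"]
        assert sets[1]["c"] == ["h2", "h3", "h4"]

    def test_monotone_in_fold(self):
        mat = self._matrix()
        sets = hec_sets(mat, (1, 2, 5, 10))
        for sp in mat.columns:
            for f_lo, f_hi in [(1, 2), (2, 5), (5, 10)]:
                assert set(sets[f_hi][sp]) <= set(sets[f_lo][sp])

    def test_doubled_pingpong_in_hecs_gives_ratio_near_two(self):
        rng = np.random.default_rng(0)

        def reads_with_share(n, with_partner_frac, offset):
            reads = []
            n_pairs = int(n * with_partner_frac / 2)
            for i in range(n_pairs):
                p = offset + i * 100
                s1 = "".join(rng.choice(list("ACGT"), size=26))
                s2 = "".join(rng.choice(list("ACGT"), size=26))
                reads.append(MappedRead(s1, [("chr1", p, "+")]))
                reads.append(MappedRead(s2, [("chr1", p - 16, "-")]))
            for i in range(n - 2 * n_pairs):
                s = "".join(rng.choice(list("ACGT"), size=26))
                reads.append(
                    MappedRead(s, [("chr1", offset + 50_000 + i * 100, "+")])
                )
            return reads

        mat = pd.DataFrame(
            {"a": [100.0, 10.0], "b": [10.0, 10.0]}, index=["h1", "h2"]
        )
        reads_per_cluster = {
            "a": {
                "h1": reads_with_share(400, 0.4, 0),       # the HEC
                "h2": reads_with_share(400, 0.2, 200_000),
            },
            "b": {},
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = hec_pingpong_ratio(mat, reads_per_cluster, (2,))
        row = table[(table.species == "a") & (table.fold == 2)].iloc[0]
        assert row.n_hec == 1
        assert row.ratio == pytest.approx(2.0, rel=0.15)


class TestTransposonDivergence:
    def test_planted_older_repeats_in_category_one(self, default_study):
        groups = [
            HomologGroup(
                c.cluster_id,
                {sp: c.cluster_id for sp, ok in c.present.items() if ok},
                dict(c.present),
                dict(c.expressed),
            )
            for c in default_study.clusters
        ]
        intervals = {
            sp: {
                c.cluster_id: (c.chrom, c.start, c.end)
                for c in default_study.clusters
                if c.present[sp]
            }
            for sp in default_study.species
        }
        repeats = {
            sp: fx.repeats for sp, fx in default_study.species.items()
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df, tests = group_transposon_divergence(
                groups, intervals, repeats
            )
        means = df.groupby("category").mean_divergence.mean()
        if 1 in means.index and 3 in means.index:
            assert means[1] > means[3]
        if 1 in means.index and 2 in means.index:
            assert means[1] > means[2]

    def test_single_species_skips_paired_test(self):
        g = _group("h1", {"a": "c1"}, {"a": True}, {"a": True})
        reps = [RepeatFeature("chr1", 10, 110, "+", "SINE/Alu", 12.0)]
        df, tests = group_transposon_divergence(
            [g], {"a": {"c1": ("chr1", 0, 1_000)}}, {"a": reps}
        )
        assert tests == {}
        assert len(df) == 1
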
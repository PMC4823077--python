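"""Distances, clustering, parsimony tree, origin classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mlclonal import phylo
from conftest import make_manifest, make_matrix


class TestBinaryDistance:
    def test_identical_samples_at_distance_zero(self):
        manifest = make_manifest({"T1": ["S1", "S2"]})
        m = make_matrix({"m1": {"S1", "S2"}, "m2": {"S1", "S2"}}, manifest)
        d = phylo.binary_distance(m)
        assert d.loc["S1", "S2"] == 0.0

    def test_disjoint_samples_at_distance_one(self):
        manifest = make_manifest({"T1": ["S1", "S2"]})
        m = make_matrix({"m1": {"S1"}, "m2": {"S2"}}, manifest)
        assert phylo.binary_distance(m).loc["S1", "S2"] == 1.0

    def test_three_sample_jaccard_by_hand(self):
        manifest = make_manifest({"T1": ["S1", "S2", "S3"]})
        m = make_matrix({"m1": {"S1", "S2"}, "m2": {"S1"}, "m3": {"S2", "S3"}},
                        manifest)
        d = phylo.binary_distance(m)
        assert d.loc["S1", "S2"] == pytest.approx(1 - 1 / 3)
        assert d.loc["S1", "S3"] == pytest.approx(1.0)
        assert d.loc["S2", "S3"] == pytest.approx(1 - 1 / 2)

    def test_low_coverage_rows_excluded_from_both_sides(self):
        from mlclonal.io_formats import MutationRecord
        from mlclonal.mutmatrix import build_matrix
        manifest = make_manifest({"T1": ["S1", "S2"]})
        records = [
            # shared mutation, well covered
            MutationRecord(chrom="chr1", pos=1, ref="C", alt="T",
                           depths={"S1": (40, 20), "S2": (40, 20), "NORMAL": (40, 0)}),
            # would-be difference, but S2 has no usable coverage there
            MutationRecord(chrom="chr1", pos=2, ref="C", alt="T",
                           depths={"S1": (40, 20), "S2": (3, 0), "NORMAL": (40, 0)}),
        ]
        m = build_matrix(records, manifest)
        assert phylo.binary_distance(m).loc["S1", "S2"] == 0.0


def brute_force_average_linkage(dist: pd.DataFrame):
    """Naive agglomerative average linkage; returns frozenset merge partitions."""
    clusters = [frozenset([s]) for s in dist.index]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = np.mean([dist.loc[x, y] for x in a for y in b])
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
        merges.append((round(d, 10), a | b))
    return merges


class TestHierarchicalCluster:
    def test_identical_pair_merges_first(self):
        manifest = make_manifest({"T1": ["S1", "S2", "S3"]})
        m = make_matrix({"m1": {"S1", "S2"}, "m2": {"S3"}}, manifest)
        res = phylo.hierarchical_cluster(phylo.binary_distance(m))
        assert "(S1:0,S2:0)" in res.newick.replace(" ", "")

    def test_matches_brute_force_merge_order(self):
        rng = np.random.default_rng(3)
        labels = [f"S{i}" for i in range(5)]
        for _ in range(5):
            d = rng.uniform(0.1, 1.0, size=(5, 5))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            dist = pd.DataFrame(d, index=labels, columns=labels)
            expected = brute_force_average_linkage(dist)
            res = phylo.hierarchical_cluster(dist)
            got_heights = sorted(round(h, 10) for h in res.linkage[:, 2])
            assert got_heights == sorted(h for h, _ in expected)

    def test_invariant_to_sample_order(self, fixture_matrix):
        d = phylo.binary_distance(fixture_matrix)
        shuffled = d.iloc[::-1, ::-1]
        assert phylo.hierarchical_cluster(d).newick == \
               phylo.hierarchical_cluster(shuffled).newick

    def test_fixture_seeding_primary_clusters_with_recurrences(self, fixture_matrix):
        res = phylo.hierarchical_cluster(phylo.binary_distance(fixture_matrix))
        import dendropy
        tree = dendropy.Tree.get(data=res.newick, schema="newick")
        clades = {frozenset(l.taxon.label for l in n.leaf_iter())
                  for n in tree.preorder_node_iter()}
        assert frozenset(["HCC-A1", "HCC-A2", "HCC-A3", "IM1", "IM2"]) in clades


def random_conflict_free_matrix(rng, n_leaves):
    """Random binary tree over samples; >=1 mutation per edge; returns
    (pattern map, set of internal clades)."""
    samples = [f"S{i}" for i in range(n_leaves)]
    clusters = [frozenset([s]) for s in samples]
    clades = set()
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
        clades.add(merged)
    patterns = {}
    idx = 0
    for clade in sorted(clades | {frozenset([s]) for s in samples},
                        key=lambda c: sorted(c)):
        for _ in range(int(rng.integers(1, 4))):
            patterns[f"m{idx:03d}"] = set(clade)
            idx += 1
    return samples, patterns, clades


class TestParsimonyTree:
    def test_single_shared_mutation_sits_on_trunk(self):
        manifest = make_manifest({"T1": ["S1", "S2"], "T2": ["S3"]})
        m = make_matrix({"m1": {"S1", "S2", "S3"}}, manifest)
        with pytest.warns(UserWarning, match="star"):
            tree = phylo.build_parsimony_tree(m, manifest)
        assert tree.branch_counts()[frozenset(["S1", "S2", "S3"])] == 1

    def test_recovers_nested_four_leaf_topology(self):
        samples = ["S1", "S2", "S3", "S4"]
        manifest = make_manifest({"T1": samples})
        patterns = {"t1": set(samples), "p12": {"S1", "S2"}, "p34": {"S3", "S4"},
                    "s1": {"S1"}, "s3": {"S3"}}
        tree = phylo.build_parsimony_tree(make_matrix(patterns, manifest), manifest)
        assert tree.has_clade(["S1", "S2"]) and tree.has_clade(["S3", "S4"])
        assert not tree.conflicts

    def test_conservation_of_mutation_counts(self, fixture_matrix, patient):
        tree = phylo.build_parsimony_tree(fixture_matrix, patient.manifest)
        total = sum(tree.branch_counts().values())
        n_supported = sum(
            1 for mid in fixture_matrix.mutation_ids
            if (fixture_matrix.status.loc[mid, list(tree.leaves)] == "present").any())
        assert total == n_supported

    def test_exact_recovery_on_random_conflict_free_matrices(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            n = int(rng.integers(4, 9))
            samples, patterns, clades = random_conflict_free_matrix(rng, n)
            manifest = make_manifest({"T1": samples})
            tree = phylo.build_parsimony_tree(make_matrix(patterns, manifest),
                                              manifest)
            for clade in clades:
                assert tree.has_clade(clade)
            assert not tree.conflicts
            # branch counts equal the number of mutations supporting each clade
            support_counts: dict[frozenset, int] = {}
            for pat in patterns.values():
                key = frozenset(pat)
                support_counts[key] = support_counts.get(key, 0) + 1
            for clade, count in support_counts.items():
                assert len(tree.clades[clade]) == count

    def test_mutation_relabeling_invariance(self):
        manifest = make_manifest({"T1": ["S1", "S2", "S3"]})
        patterns = {"a": {"S1", "S2", "S3"}, "b": {"S1", "S2"}, "c": {"S3"}}
        renamed = {"zz_" + k: v for k, v in patterns.items()}
        t1 = phylo.build_parsimony_tree(make_matrix(patterns, manifest), manifest)
        t2 = phylo.build_parsimony_tree(make_matrix(renamed, manifest), manifest)
        assert t1.branch_counts() == t2.branch_counts()


class TestClassifyOrigin:
    def _case(self, rec_pattern, primary_patterns, extra=None):
        manifest = make_manifest(
            {"P1": ["P1a", "P1b"], "P2": ["P2a"], "R1": ["R1s"]},
            recurrences={"R1"})
        patterns = dict(primary_patterns)
        patterns.update(rec_pattern)
        if extra:
            patterns.update(extra)
        return make_matrix(patterns, manifest), manifest

    def test_disjoint_recurrence_is_de_novo(self):
        m, manifest = self._case(
            {f"r{i}": {"R1s"} for i in range(10)},
            {f"p{i}": {"P1a", "P1b"} for i in range(10)})
        (call,) = phylo.classify_origin(m, manifest)
        assert call.origin == "de_novo"

    def test_shared_profile_with_reciprocal_privates_is_sibling(self):
        shared = {f"s{i}": {"P1a", "P1b", "R1s"} for i in range(20)}
        p_private = {f"pp{i}": {"P1a", "P1b"} for i in range(4)}
        r_private = {f"rp{i}": {"R1s"} for i in range(4)}
        m, manifest = self._case(r_private, {**shared, **p_private})
        (call,) = phylo.classify_origin(m, manifest)
        assert call.origin == "intrahepatic_metastasis"
        assert call.best_primary == "P1"
        assert call.relationship == "sibling"
        assert len(call.evidence["primary_private_covered_absent"]) == 4

    def test_recurrence_superset_is_linear_descendant(self):
        shared = {f"s{i}": {"P1a", "P1b", "R1s"} for i in range(20)}
        r_private = {f"rp{i}": {"R1s"} for i in range(4)}
        m, manifest = self._case(r_private, shared)
        (call,) = phylo.classify_origin(m, manifest)
        assert call.origin == "intrahepatic_metastasis"
        assert call.relationship == "linear_descendant"

    def test_adding_shared_mutations_never_flips_toward_de_novo(self):
        base_shared = {f"s{i}": {"P1a", "P1b", "R1s"} for i in range(3)}
        r_private = {f"rp{i}": {"R1s"} for i in range(10)}
        m1, manifest = self._case(r_private, base_shared)
        (c1,) = phylo.classify_origin(m1, manifest)
        more = {f"extra{i}": {"P1a", "P1b", "R1s"} for i in range(30)}
        m2, _ = self._case(r_private, {**base_shared, **more})
        (c2,) = phylo.classify_origin(m2, manifest)
        rank = {"de_novo": 0, "ambiguous": 1, "intrahepatic_metastasis": 2}
        assert rank[c2.origin] >= rank[c1.origin]

    def test_fixture_origin_calls(self, fixture_matrix, patient):
        calls = phylo.classify_origin(fixture_matrix, patient.manifest)
        assert {c.recurrence_id for c in calls} == {"IM1", "IM2"}
        for c in calls:
            assert c.origin == "intrahepatic_metastasis"
            assert c.best_primary == "HCC-A"
            assert c.relationship == "sibling"
            marker = [m for m in c.evidence["primary_private_covered_absent"]
                      if fixture_matrix.meta.loc[m, "gene"] == "AXIN1"]
            assert marker  # the seeding primary's marker is covered-absent in IMs
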
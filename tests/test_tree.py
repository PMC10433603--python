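"""CST construction: leaf filtering, node k-mer assignment, augmentation,
and index serialization."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainsift.cluster import ClusterAssignment, DendroNode
from strainsift.config import RunConfig
from strainsift.errors import IndexError_, InputError, ParameterError
from strainsift.index import load_index, serialize_index
from strainsift.kmer import KmerSet
from strainsift.pipeline import build_index
from strainsift.tree import (
    augment_weak_nodes,
    build_cst,
    build_leaf_sets,
    set_formula_node_kmers,
    LeafKmerSet,
)


def kset(name, elems):
    return KmerSet(genome_id=name, k=5, kmers=set(elems))


def leaf(cid):
    return DendroNode(height=1.0, genome_id=cid)


def join(a, b, h=0.5):
    return DendroNode(height=h, children=[a, b])


class TestLeafSets:
    def test_single_strain_keeps_all(self):
        assign = ClusterAssignment(clusters={"C1": ["a"]}, H=0.95)
        out = build_leaf_sets(assign, {"a": kset("a", {1, 2, 3})})
        assert out["C1"].kmers == {1, 2, 3}

    def test_prevalence_boundary_inclusive(self):
        # k-mer 7 in 9/10 strains: kept at alpha=90; k-mer 8 in 8/10: dropped
        genomes = {f"g{i}": kset(f"g{i}", {7} if i < 9 else set()) for i in range(10)}
        for i in range(8):
            genomes[f"g{i}"].kmers.add(8)
        assign = ClusterAssignment(clusters={"C1": sorted(genomes)}, H=0.95)
        out = build_leaf_sets(assign, genomes, alpha=90.0)
        assert 7 in out["C1"].kmers
        assert 8 not in out["C1"].kmers

    def test_bad_alpha(self):
        assign = ClusterAssignment(clusters={"C1": ["a"]}, H=0.95)
        with pytest.raises(ParameterError):
            build_leaf_sets(assign, {"a": kset("a", {1})}, alpha=0.0)


def leaf_sets_of(d):
    return {cid: LeafKmerSet(cluster_id=cid, kmers=set(v), n_strains=1)
            for cid, v in d.items()}


class TestBuildCST:
    def test_two_leaf_promotion(self):
        tree = join(leaf("C1"), leaf("C2"))
        cst = build_cst(tree, leaf_sets_of({"C1": {1, 2, 3}, "C2": {2, 3, 4}}))
        by_cluster = {n.cluster_id: n.kmers for n in cst.leaves}
        assert cst.root.kmers == {2, 3}
        assert by_cluster == {"C1": {1}, "C2": {4}}

    def test_single_leaf_degenerate(self):
        cst = build_cst(leaf("C1"), leaf_sets_of({"C1": {1, 2}}))
        assert cst.root.is_leaf and cst.root.kmers == {1, 2}

    def test_three_leaf_caterpillar_matches_formula(self):
        sets = {"C1": {1, 2, 3, 9}, "C2": {2, 3, 4, 9}, "C3": {3, 5, 9}}
        tree = join(join(leaf("C1"), leaf("C2")), leaf("C3"))
        ls = leaf_sets_of(sets)
        cst = build_cst(tree, ls)
        oracle = set_formula_node_kmers(cst, ls)
        for node in cst.nodes:
            assert node.kmers == oracle[node.node_id]

    def test_leaf_cluster_mismatch(self):
        with pytest.raises(InputError):
            build_cst(join(leaf("C1"), leaf("CX")), leaf_sets_of({"C1": {1}, "C2": {2}}))

    @given(st.integers(0, 10_000))
    @settings(max_examples=100)
    def test_promotion_equals_set_formula_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        n_leaves = int(rng.integers(2, 9))
        nodes = [leaf(f"C{i}") for i in range(n_leaves)]
        while len(nodes) > 1:  # random binary topology
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            b = nodes.pop(j)
            a = nodes.pop(i)
            nodes.append(join(a, b))
        ls = leaf_sets_of(
            {
                f"C{i}": set(rng.choice(40, size=rng.integers(1, 15), replace=False).tolist())
                for i in range(n_leaves)
            }
        )
        cst = build_cst(nodes[0], ls)
        oracle = set_formula_node_kmers(cst, ls)
        for node in cst.nodes:
            assert node.kmers == oracle[node.node_id], f"node {node.node_id}"
        # global disjointness
        seen = set()
        for node in cst.nodes:
            assert not (node.kmers & seen)
            seen |= node.kmers


class TestAugmentation:
    def _setup(self):
        # two clusters of two strains each; cluster-private strain variation
        genomes = {
            "a1": kset("a1", {1, 2, 3, 10}),
            "a2": kset("a2", {1, 2, 3, 11}),
            "b1": kset("b1", {1, 2, 4, 20}),
            "b2": kset("b2", {1, 2, 4, 21}),
        }
        assign = ClusterAssignment(
            clusters={"C1": ["a1", "a2"], "C2": ["b1", "b2"]}, H=0.95
        )
        ls = build_leaf_sets(assign, genomes, alpha=90.0)
        cst = build_cst(join(leaf("C1"), leaf("C2")), ls)
        return genomes, assign, cst

    def test_strong_node_unchanged(self):
        genomes, assign, cst = self._setup()
        before = {n.node_id: set(n.kmers) for n in cst.nodes}
        augment_weak_nodes(cst, genomes, assign, min_kmers=0)
        assert {n.node_id: n.kmers for n in cst.nodes} == before

    def test_weak_node_gains_private_kmers_only(self):
        genomes, assign, cst = self._setup()
        augment_weak_nodes(cst, genomes, assign, min_kmers=5)
        strain_sets = {g: ks.kmers for g, ks in genomes.items()}
        members = assign.clusters
        for node in cst.nodes:
            inside = [g for l in node.subtree_leaves() for g in members[l.cluster_id]]
            outside = set(strain_sets) - set(inside)
            for x in node.augmented:
                assert any(x in strain_sets[g] for g in inside)  # (i)
                assert all(x not in strain_sets[g] for g in outside)  # (ii)
        # (iii) still globally disjoint
        seen = set()
        for node in cst.nodes:
            assert not (node.kmers & seen)
            seen |= node.kmers

    def test_no_eligible_kmers_warns(self, caplog):
        genomes = {"a": kset("a", {1, 2}), "b": kset("b", {1, 2, 3})}
        assign = ClusterAssignment(clusters={"C1": ["a"], "C2": ["b"]}, H=0.95)
        ls = build_leaf_sets(assign, genomes)
        cst = build_cst(join(leaf("C1"), leaf("C2")), ls)
        # C1's leaf can only hold k-mers absent from b: none beyond Eq-1's
        with caplog.at_level("WARNING"):
            augment_weak_nodes(cst, genomes, assign, min_kmers=10)
        assert any("weak" in r.message for r in caplog.records)


def dir_digest(path: Path) -> dict[str, str]:
    out = {}
    for p in sorted(path.rglob("*")):
        if p.is_file():
            out[str(p.relative_to(path))] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


@pytest.fixture(scope="module")
def small_index():
    rng = np.random.default_rng(5)
    genomes = {}
    base = set(rng.choice(100_000, 2000, replace=False).tolist())
    for c in range(3):
        core = set(rng.choice(100_000, 500, replace=False).tolist()) | base
        for s in range(2):
            private = set(rng.choice(200_000, 60, replace=False).tolist())
            gid = f"g{c}{s}"
            genomes[gid] = KmerSet(gid, 31, core | private)
    return build_index(genomes, RunConfig(min_kmers=50, single_strain_cap=500))


class TestSerialization:
    def test_round_trip_identity(self, small_index, tmp_path):
        serialize_index(small_index, tmp_path / "idx")
        loaded = load_index(tmp_path / "idx")
        assert loaded.config == small_index.config
        assert sorted(loaded.manifest) == sorted(small_index.manifest)
        for a, b in zip(small_index.cst.nodes, loaded.cst.nodes):
            assert (a.node_id, a.depth, a.cluster_id) == (b.node_id, b.depth, b.cluster_id)
            assert a.kmers == b.kmers and a.augmented == b.augmented
        for cid, m in small_index.matrices.items():
            lm = loaded.matrices[cid]
            assert lm.strain_ids == m.strain_ids
            assert np.array_equal(lm.kmer_keys, m.kmer_keys)
            assert np.array_equal(lm.X, m.X)
            assert lm.pattern_class == m.pattern_class
            assert np.array_equal(loaded.cluster_kmers[cid], m.kmer_keys) or np.array_equal(
                loaded.cluster_kmers[cid], small_index.cluster_kmers[cid]
            )

    def test_serialization_deterministic(self, small_index, tmp_path):
        serialize_index(small_index, tmp_path / "a")
        serialize_index(small_index, tmp_path / "b")
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")

    def test_truncated_file_errors(self, small_index, tmp_path):
        serialize_index(small_index, tmp_path / "idx")
        node_file = next((tmp_path / "idx" / "nodes").glob("node_*.tsv"))
        content = node_file.read_text().splitlines()
        node_file.write_text("\n".join(content[: len(content) // 2]) + "\n")
        with pytest.raises(IndexError_):
            load_index(tmp_path / "idx")

    def test_version_mismatch_errors(self, small_index, tmp_path):
        serialize_index(small_index, tmp_path / "idx")
        cfg = tmp_path / "idx" / "config.json"
        cfg.write_text(cfg.read_text().replace('"format_version": 1', '"format_version": 99'))
        with pytest.raises(IndexError_, match="version"):
            load_index(tmp_path / "idx")
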
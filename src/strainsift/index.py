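"""Serialized index layout and round-trip loading.

Directory layout (all plain text, deterministically ordered so identical
inputs produce byte-identical indexes):

    config.json          run parameters + format version
    manifest.tsv         genome_id, cluster_id, n_kmers
    tree.json            CST topology and per-node statistics
    nodes/node_<id>.tsv  sorted "kmer<TAB>augmented(0/1)" per CST node
    clusters/<cid>.matrix.tsv   strain matrix: header + kmer/pattern/class
    clusters/<cid>.kmers.txt    sorted union of member strains' k-mers
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .errors import IndexError_
from .resolve import StrainMatrix
from .tree import CST, CSTNode

FORMAT_VERSION = 1


@dataclass
class Index:
    config: RunConfig
    cst: CST
    manifest: list[tuple[str, str, int]]  # genome_id, cluster_id, n_kmers
    matrices: dict[str, StrainMatrix]
    cluster_kmers: dict[str, np.ndarray]  # sorted union of member raw k-mers
    _query: np.ndarray | None = field(default=None, repr=False)

    def cluster_members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid, cid, _n in self.manifest:
            out.setdefault(cid, []).append(gid)
        return out

    def query_kmers(self) -> np.ndarray:
        """Sorted union of all node and matrix k-mers (the count query)."""
        if self._query is None:
            parts = [n.sorted_kmers() for n in self.cst.nodes]
            parts += [m.kmer_keys for m in self.matrices.values()]
            parts = [p for p in parts if p.size]
            self._query = (
                np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)
            )
        return self._query


def serialize_index(index: Index, path: str | Path) -> Path:
    path = Path(path)
    (path / "nodes").mkdir(parents=True, exist_ok=True)
    (path / "clusters").mkdir(parents=True, exist_ok=True)
    meta = {"format_version": FORMAT_VERSION, "config": index.config.to_dict()}
    (path / "config.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )
    with open(path / "manifest.tsv", "w") as out:
        out.write("genome_id\tcluster_id\tn_kmers\n")
        for gid, cid, n in sorted(index.manifest):
            out.write(f"{gid}\t{cid}\t{n}\n")
    nodes_meta = []
    for node in index.cst.nodes:
        nodes_meta.append(
            {
                "id": node.node_id,
                "parent": node.parent.node_id if node.parent else None,
                "children": [c.node_id for c in node.children],
                "depth": node.depth,
                "cluster_id": node.cluster_id,
                "members": node.members,
                "n_kmers": len(node.kmers),
                "n_augmented": len(node.augmented),
            }
        )
        with open(path / "nodes" / f"node_{node.node_id}.tsv", "w") as out:
            aug = node.augmented
            for x in sorted(node.kmers):
                out.write(f"{x}\t{1 if x in aug else 0}\n")
    (path / "tree.json").write_text(
        json.dumps({"nodes": nodes_meta}, indent=2, sort_keys=True) + "\n"
    )
    for cid in sorted(index.matrices):
        m = index.matrices[cid]
        with open(path / "clusters" / f"{cid}.matrix.tsv", "w") as out:
            out.write("#k=%d\tstrains=%s\n" % (m.k, ",".join(m.strain_ids)))
            for x, row, cls in zip(m.kmer_keys, m.X, m.pattern_class):
                pattern = int(sum(int(b) << j for j, b in enumerate(row)))
                out.write(f"{x}\t{pattern}\t{cls}\n")
        with open(path / "clusters" / f"{cid}.kmers.txt", "w") as out:
            for x in index.cluster_kmers[cid]:
                out.write(f"{x}\n")
    return path


def _load_kmer_tsv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    kmers, flags = [], []
    for line in path.read_text().splitlines():
        a, b = line.split("\t")
        kmers.append(int(a))
        flags.append(int(b))
    return np.array(kmers, dtype=np.uint64), np.array(flags, dtype=bool)


def load_index(path: str | Path) -> Index:
    path = Path(path)
    try:
        meta = json.loads((path / "config.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise IndexError_(f"cannot read index config at {path}: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise IndexError_(
            f"index format version {meta.get('format_version')!r} unsupported "
            f"(expected {FORMAT_VERSION})"
        )
    config = RunConfig.from_dict(meta["config"])
    try:
        tree_meta = json.loads((path / "tree.json").read_text())["nodes"]
    except (OSError, json.JSONDecodeError, KeyError) as exc:
        raise IndexError_(f"corrupt tree.json in {path}: {exc}") from exc
    nodes: dict[int, CSTNode] = {}
    for nm in tree_meta:
        nodes[nm["id"]] = CSTNode(
            node_id=nm["id"],
            depth=nm["depth"],
            cluster_id=nm["cluster_id"],
            members=list(nm["members"]),
        )
    roots = []
    for nm in tree_meta:
        node = nodes[nm["id"]]
        if nm["parent"] is None:
            roots.append(node)
        else:
            node.parent = nodes[nm["parent"]]
        node.children = [nodes[c] for c in nm["children"]]
    if len(roots) != 1:
        raise IndexError_(f"index tree has {len(roots)} roots")
    for nm in tree_meta:
        node = nodes[nm["id"]]
        node_path = path / "nodes" / f"node_{node.node_id}.tsv"
        try:
            kmers, aug = _load_kmer_tsv(node_path)
        except (OSError, ValueError) as exc:
            raise IndexError_(f"corrupt node file {node_path}: {exc}") from exc
        if kmers.size != nm["n_kmers"] or int(aug.sum()) != nm["n_augmented"]:
            raise IndexError_(f"node file {node_path} is truncated or inconsistent")
        node.kmers = set(int(x) for x in kmers)
        node.augmented = set(int(x) for x in kmers[aug])
    order = sorted(nodes.values(), key=lambda n: n.node_id)
    cst = CST(root=roots[0], nodes=order)
    manifest = []
    lines = (path / "manifest.tsv").read_text().splitlines()[1:]
    for line in lines:
        gid, cid, n = line.split("\t")
        manifest.append((gid, cid, int(n)))
    cluster_kmers: dict[str, np.ndarray] = {}
    mats: dict[str, StrainMatrix] = {}
    for mp in sorted((path / "clusters").glob("*.matrix.tsv")):
        cid = mp.name[: -len(".matrix.tsv")]
        lines = mp.read_text().splitlines()
        header = lines[0]
        try:
            k_part, strains_part = header.lstrip("#").split("\t")
            k = int(k_part.split("=")[1])
            strain_ids = strains_part.split("=")[1].split(",")
        except (IndexError, ValueError) as exc:
            raise IndexError_(f"corrupt matrix header in {mp}: {exc}") from exc
        keys, patterns, classes = [], [], []
        for line in lines[1:]:
            a, b, c = line.split("\t")
            keys.append(int(a))
            patterns.append(int(b))
            classes.append(c)
        keys_arr = np.array(keys, dtype=np.uint64)
        X = np.zeros((len(keys), len(strain_ids)), dtype=np.uint8)
        for j in range(len(strain_ids)):
            X[:, j] = [(p >> j) & 1 for p in patterns]
        mats[cid] = StrainMatrix(
            cluster_id=cid,
            k=k,
            kmer_keys=keys_arr,
            strain_ids=strain_ids,
            X=X,
            pattern_class=classes,
        )
        kp = path / "clusters" / f"{cid}.kmers.txt"
        cluster_kmers[cid] = np.array(
            [int(x) for x in kp.read_text().split()], dtype=np.uint64
        )
    return Index(
        config=config,
        cst=cst,
        manifest=manifest,
        matrices=mats,
        cluster_kmers=cluster_kmers,
    )
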
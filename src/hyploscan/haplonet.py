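"""Haplotype collapsing and minimum-spanning networks.

Haploid genotype strings (e.g. chloroplast SNP genotypes) are collapsed
to unique haplotypes; the complete graph weighted by Hamming distance
(mutational steps) is then reduced to a minimum spanning tree by Kruskal
with deterministic tie-breaking, optionally keeping equal-weight
alternative edges (minimum-spanning-network mode).  Cluster separation
between two labelled groups is the smallest Hamming distance across any
haplotype pair spanning them — reported alongside the MST because a
network path through intermediates can be longer than the direct
pairwise distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_MISSING_CHARS = set("Nn?-.")


@dataclass
class HaplotypeTable:
    ids: list[str]  # H01, H02, ... in order of first appearance
    seqs: list[str]
    members: dict  # hap id -> list of sample names

    @property
    def counts(self) -> dict:
        return {h: len(m) for h, m in self.members.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "haplotype": self.ids,
                "count": [len(self.members[h]) for h in self.ids],
                "samples": [",".join(self.members[h]) for h in self.ids],
                "genotype": self.seqs,
            }
        )


@dataclass
class HaplotypeNetwork:
    table: HaplotypeTable
    edges: list  # (hap_i, hap_j, steps, is_alternate)
    distances: np.ndarray  # full pairwise Hamming matrix
    spanning: bool = True

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["hap_i", "hap_j", "steps", "alternate"])

    def mst_weight(self) -> int:
        return int(sum(st for _, _, st, alt in self.edges if not alt))


def collapse_haplotypes(haplotypes: dict) -> HaplotypeTable:
    """Merge identical genotype strings; preserve sample membership.

    Input maps sample name -> haploid genotype string (equal lengths, no
    missing data).  Missing characters (N, ?, -, .) raise: filter sites
    to a complete matrix first.
    """
    if not haplotypes:
        raise ValueError("no haplotypes supplied")
    lengths = {len(s) for s in haplotypes.values()}
    if len(lengths) != 1:
        raise ValueError("haplotype strings differ in length")
    ids: list[str] = []
    seqs: list[str] = []
    members: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    for name, seq in haplotypes.items():
        if _MISSING_CHARS & set(seq):
            raise ValueError(
                f"haplotype {name!r} contains missing characters; "
                "filter to complete sites before collapsing"
            )
        if seq not in seen:
            hid = f"H{len(ids) + 1:02d}"
            seen[seq] = hid
            ids.append(hid)
            seqs.append(seq)
            members[hid] = []
        members[seen[seq]].append(name)
    return HaplotypeTable(ids=ids, seqs=seqs, members=members)


def hamming_matrix(seqs: list[str]) -> np.ndarray:
    arr = np.array([list(s) for s in seqs])
    n = len(seqs)
    d = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        d[i] = (arr != arr[i]).sum(axis=1)
    return d


def build_msn(table: HaplotypeTable, mode: str = "msn") -> HaplotypeNetwork:
    """Minimum spanning tree / network over haplotype Hamming distances.

    ``mode="mst"``: Kruskal with deterministic tie-breaking (edges sorted
    by (steps, hap_i, hap_j)); the edge set is a spanning tree.
    ``mode="msn"``: at each distinct weight, every edge joining two
    distinct components (as they stood before merging at that weight) is
    retained; edges beyond the first spanning set are marked alternate.
    """
    if mode not in ("msn", "mst"):
        raise ValueError("mode must be 'msn' or 'mst'")
    n = len(table.ids)
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    d = hamming_matrix(table.seqs)
    all_edges = sorted(
        (int(d[i, j]), table.ids[i], table.ids[j], i, j)
        for i in range(n)
        for j in range(i + 1, n)
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: list[tuple[str, str, int, bool]] = []
    if mode == "mst":
        for w, hi, hj, i, j in all_edges:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                edges.append((hi, hj, w, False))
    else:
        k = 0
        while k < len(all_edges):
            w = all_edges[k][0]
            batch = []
            while k < len(all_edges) and all_edges[k][0] == w:
                batch.append(all_edges[k])
                k += 1
            roots_before = {i: find(i) for i in range(n)}
            for _, hi, hj, i, j in batch:
                if roots_before[i] == roots_before[j]:
                    continue  # joined already at a strictly lower weight
                if find(i) != find(j):
                    parent[find(i)] = find(j)
                    edges.append((hi, hj, w, False))
                else:
                    # spans components merged at this same weight: keep as
                    # an equal-weight alternative connection
                    edges.append((hi, hj, w, True))
    return HaplotypeNetwork(table=table, edges=edges, distances=d, spanning=True)


def cluster_separation(network: HaplotypeNetwork, labels: dict) -> int:
    """Minimum mutational distance between two labelled clusters.

    ``labels`` maps sample name -> cluster label (exactly two labels).
    A haplotype shared by samples of both clusters gives separation 0.
    """
    table = network.table
    lab_values = sorted(set(labels.values()))
    if len(lab_values) != 2:
        raise ValueError(f"need exactly two cluster labels, got {lab_values}")
    a_label, b_label = lab_values
    hap_sets: dict[str, set] = {a_label: set(), b_label: set()}
    for hid in table.ids:
        for s in table.members[hid]:
            if s in labels:
                hap_sets[labels[s]].add(hid)
    if not hap_sets[a_label] or not hap_sets[b_label]:
        raise ValueError("a cluster has no haplotypes")
    idx = {h: i for i, h in enumerate(table.ids)}
    return int(
        min(
            network.distances[idx[ha], idx[hb]]
            for ha in hap_sets[a_label]
            for hb in hap_sets[b_label]
        )
    )
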
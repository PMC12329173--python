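"""Clone-mate (ramet) detection and collapse to unique genets.

Two samples are called ramets of one genet when they share nearly all of
their heterozygous calls and show essentially no fixed (opposite
homozygote) differences — the pattern expected when the only source of
disagreement is genotyping error.  Shared heterozygosity is a Dice-style
coefficient over het calls:

    SH(i, j) = 2 * n_both_het / (n_het_i + n_het_j)

computed over loci genotyped in both samples.  Clone pairs (edges where
SH >= threshold and fixed differences are at noise level) are merged by
connected components (single linkage); each genet keeps the ramet with
the lowest missing rate as its representative.  Single linkage is
deliberate — clone chains with missing data are common — but means one
spurious edge can merge two genets; the pairwise table is emitted so the
decision can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vcfio import MISSING, GenotypeMatrix


@dataclass
class GenetAssignment:
    """Partition of samples into genets."""

    genet_of: dict  # sample id -> genet id
    ramets: dict  # genet id -> list of sample ids
    representatives: dict  # genet id -> sample id (lowest missing rate)

    @property
    def representative_samples(self) -> list[str]:
        return [self.representatives[g] for g in sorted(self.ramets)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genet_id": g,
                "n_ramets": len(members),
                "ramets": ",".join(members),
                "representative": self.representatives[g],
            }
            for g, members in sorted(self.ramets.items())
        ]
        return pd.DataFrame(rows)


def _pairwise_arrays(gm: GenotypeMatrix):
    """Vectorised building blocks for all pairwise clone statistics."""
    valid = (gm.g != MISSING).astype(np.float64)
    het = ((gm.g == 1) & (gm.g != MISSING)).astype(np.float64)
    hom_ref = (gm.g == 0).astype(np.float64)
    hom_alt = (gm.g == 2).astype(np.float64)
    n_shared = valid @ valid.T
    both_het = het @ het.T
    het_i_shared = het @ valid.T  # het in i, genotyped in j
    fixed = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    return n_shared, both_het, het_i_shared, fixed


def shared_het_index(gm: GenotypeMatrix, i, j) -> float:
    """Dice coefficient of heterozygous calls between two samples.

    Computed over loci genotyped in both; returns NaN when neither sample
    has a heterozygous call there (denominator zero).
    """
    i, j = _resolve(gm, i, j)
    if i == j:
        raise ValueError("shared_het_index requires two distinct samples")
    gi, gj = gm.g[i], gm.g[j]
    both = (gi != MISSING) & (gj != MISSING)
    het_i = int(((gi == 1) & both).sum())
    het_j = int(((gj == 1) & both).sum())
    if het_i + het_j == 0:
        return float("nan")
    both_het = int(((gi == 1) & (gj == 1) & both).sum())
    return 2.0 * both_het / (het_i + het_j)


def fixed_diff_count(gm: GenotypeMatrix, i, j) -> int:
    """Number of loci where the two samples are opposite homozygotes."""
    i, j = _resolve(gm, i, j)
    gi, gj = gm.g[i], gm.g[j]
    return int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())


def _resolve(gm: GenotypeMatrix, *names):
    out = []
    for s in names:
        out.append(s if isinstance(s, (int, np.integer)) else gm.sample_index(s))
    return tuple(out)


def pairwise_table(gm: GenotypeMatrix) -> pd.DataFrame:
    """All-pairs SH / fixed-difference / shared-locus table."""
    n_shared, both_het, het_i_shared, fixed = _pairwise_arrays(gm)
    rows = []
    n = gm.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            denom = het_i_shared[i, j] + het_i_shared[j, i]
            sh = 2.0 * both_het[i, j] / denom if denom > 0 else float("nan")
            rows.append(
                {
                    "sample_i": gm.samples[i],
                    "sample_j": gm.samples[j],
                    "n_shared_loci": int(n_shared[i, j]),
                    "sh": sh,
                    "fixed_diffs": int(fixed[i, j]),
                }
            )
    return pd.DataFrame(rows)


def assign_genets(
    gm: GenotypeMatrix,
    sh_threshold: float = 0.9,
    max_fixed_diff_frac: float = 0.001,
) -> GenetAssignment:
    """Group samples into genets by shared heterozygosity.

    An edge joins samples i and j when SH(i, j) >= ``sh_threshold`` and
    their fixed-difference count is at most ``max_fixed_diff_frac`` of the
    loci compared (clones differ only by genotyping error).  Genets are
    the connected components; the representative is the ramet with the
    lowest missing rate, ties broken by lexicographic sample id.
    """
    import networkx as nx

    n = gm.n_samples
    n_shared, both_het, het_i_shared, fixed = _pairwise_arrays(gm)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = het_i_shared[i, j] + het_i_shared[j, i]
            if denom <= 0:
                continue
            sh = 2.0 * both_het[i, j] / denom
            if sh >= sh_threshold and fixed[i, j] <= max_fixed_diff_frac * n_shared[i, j]:
                graph.add_edge(i, j)

    miss = gm.missing_rate()
    genet_of: dict[str, str] = {}
    ramets: dict[str, list[str]] = {}
    reps: dict[str, str] = {}
    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    for k, comp in enumerate(comps):
        gid = f"G{k + 1:03d}"
        members = sorted((gm.samples[i] for i in comp))
        for s in members:
            genet_of[s] = gid
        ramets[gid] = members
        reps[gid] = min(members, key=lambda s: (miss[gm.sample_index(s)], s))
    return GenetAssignment(genet_of=genet_of, ramets=ramets, representatives=reps)


def prune_to_representatives(gm: GenotypeMatrix, assignment: GenetAssignment) -> GenotypeMatrix:
    """Keep one ramet per genet (the representative), preserving input order."""
    keep = set(assignment.representatives.values())
    return gm.take_samples([s for s in gm.samples if s in keep])
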
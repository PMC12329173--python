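"""Genome-wide sample structure: 1-IBS distances, neighbour joining, PCA.

Identity by state between two samples is scored per locus from diploid
dosages: 1 for identical genotypes, 0.5 when they differ by one ALT
copy, 0 for opposite homozygotes; the pairwise distance is 1 minus the
mean score over loci called in both samples.  Note that 1-IBS is a
dissimilarity, not a metric — it can violate the triangle inequality.

The neighbour-joining implementation is the canonical Saitou–Nei
agglomeration with Q-matrix joins, deterministic tie-breaking (smallest
(i, j) index pair) and negative branch lengths clamped to zero with the
deficit moved to the sister branch, so the patristic distance of the
joined pair is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vcfio import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    samples: list[str]
    d: np.ndarray  # symmetric, zero diagonal
    n_loci: np.ndarray  # per-pair count of compared loci

    def __post_init__(self) -> None:
        n = len(self.samples)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")


def ibs_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs 1-IBS distances over loci non-missing in both samples."""
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    g = gm.g.astype(np.float64)
    valid = (gm.g != MISSING).astype(np.float64)
    gv = np.where(gm.g == MISSING, 0, gm.g).astype(np.float64)

    n_shared = valid @ valid.T
    # sum over shared loci of |g_i - g_j| via expansion of (g_i - g_j)^2
    # for dosages in {0,1,2}: |a-b| in {0,1,2} and (a-b)^2 in {0,1,4};
    # |a-b| = ((a-b)^2 + is_opposite_hom*(-2)) ... simpler: |a-b| =
    # (a-b)^2 - 2*opp where opp = 1 iff (a,b) opposite homozygotes.
    sq = (gv ** 2) * valid
    cross = gv * valid
    sum_sq = sq @ valid.T + valid @ sq.T - 2 * (cross @ cross.T)
    hom_ref = ((gm.g == 0).astype(np.float64))
    hom_alt = ((gm.g == 2).astype(np.float64))
    opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    sum_abs = sum_sq - 2 * opp
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = (sum_abs / 2.0) / n_shared  # mean of |diff|/2 = 1 - IBS score
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(samples=list(gm.samples), d=dist, n_loci=n_shared.astype(np.int64))


def neighbor_joining(dm: DistanceMatrix) -> str:
    """Saitou–Nei neighbour joining; returns an unrooted Newick string.

    The final three lineages are joined at a trifurcating root; branch
    lengths are written with six decimals.  Raises on incomplete (NaN)
    matrices or fewer than three taxa.
    """
    d = np.array(dm.d, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains missing entries")

    nodes = [(name, None) for name in dm.samples]  # (newick fragment, _)
    labels = [f"{name}" for name in dm.samples]
    active = list(range(n))
    # grow d as nodes are added
    d = d.copy()

    def fmt(label: str, length: float) -> str:
        return f"{label}:{max(length, 0.0):.6f}"

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest (i, j) among minima
        qmin = q.min()
        ii, jj = min(
            (int(a), int(b))
            for a, b in zip(*np.where(np.isclose(q, qmin, rtol=0, atol=1e-12)))
            if a < b
        )
        i_glob, j_glob = active[ii], active[jj]
        dij = sub[ii, jj]
        bi = 0.5 * dij + (r[ii] - r[jj]) / (2 * (m - 2))
        bj = dij - bi
        # clamp negatives, transfer deficit to sister branch
        if bi < 0:
            bj, bi = dij, 0.0
        elif bj < 0:
            bi, bj = dij, 0.0
        new_label = f"({fmt(labels[i_glob], bi)},{fmt(labels[j_glob], bj)})"
        new_dist = 0.5 * (d[i_glob, :] + d[j_glob, :] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_dist
        d[:-1, -1] = new_dist
        d[-1, -1] = 0.0
        labels.append(new_label)
        active = [a for a in active if a not in (i_glob, j_glob)] + [d.shape[0] - 1]

    a, b, c = active
    # three-point formulas for the final trifurcation
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    return f"({fmt(labels[a], la)},{fmt(labels[b], lb)},{fmt(labels[c], lc)});"


def genotype_pca(gm: GenotypeMatrix, n_components: int = 10, scale: bool = False):
    """PCA of the genotype matrix (samples as observations).

    Missing dosages are imputed to the per-SNP mean; SNPs are
    mean-centred and, when ``scale`` is set, divided by their standard
    deviation (SNPs with zero variance are dropped).  Returns
    ``(coords, var_frac)`` with variance fractions non-increasing.
    """
    if gm.n_samples < 2 or gm.n_variants < 2:
        raise ValueError("PCA needs at least 2 samples and 2 SNPs")
    g = gm.g.astype(float)
    g[g == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    x = np.where(np.isnan(g), col_mean[None, :], g) - col_mean[None, :]
    if scale:
        sd = x.std(axis=0)
        keep = sd > 0
        x = x[:, keep] / sd[keep][None, :]
    if not np.any(x):
        raise ValueError("degenerate genotype matrix: no variance")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, s.size)
    coords = u[:, :k] * s[:k]
    var_frac = s[:k] ** 2 / (s ** 2).sum()
    return coords, var_frac
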
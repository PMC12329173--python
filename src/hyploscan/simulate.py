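"""Synthetic two-clade SNP panels with hybrids, triploids and clones.

The generator emulates the statistical structure a cryptic-species
resequencing panel presents to downstream inference: two diverged clades
("S" and "N") with a chosen fraction of reciprocally fixed SNPs plus
within-clade polymorphism; F1, F2 and backcross offspring; triploids
formed by an unreduced (both-haplotype) F1 gamete fusing with a normal
haploid gamete from the N clade; clonal ramets that share underlying
dosages and differ only through per-ramet genotyping error and missing
data; and per-site read counts drawn binomially around the
dosage-determined allele fraction.

Loci are unlinked: a gamete is drawn independently per locus, so no
linkage disequilibrium or recombination map is modelled.  Triploid
genotypes are emitted through a diploid-caller convention (het when the
variant-read fraction falls inside a configurable window), mirroring how
triploid samples appear in a jointly-called diploid VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vcfio import MISSING, GenotypeMatrix, write_vcf

PARENT_S = "PARENT_S"
PARENT_N = "PARENT_N"
F1 = "F1"
F2 = "F2"
BC_S = "BC_S"
BC_N = "BC_N"
TRIPLOID = "TRIPLOID"

HYBRID_CLASSES = (F1, F2, BC_S, BC_N, TRIPLOID)

_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Knobs of the panel generator.

    Defaults describe a two-clade panel in which roughly a third of SNPs
    are reciprocally fixed between clades (the divergence regime the
    analyses target), sequenced at 30x with small genotyping error and
    missingness.

    Parameters
    ----------
    n_loci : number of biallelic SNPs.
    prop_fixed : fraction of loci reciprocally fixed between the clades.
    prop_shared_poly : fraction polymorphic within clades, ALT frequency
        drawn independently per clade from Beta(0.5, 0.5).  Any remainder
        is given a single Beta(0.5, 0.5) frequency shared by both clades.
    n_S, n_N : diploid parental sample counts per clade.
    hybrid_spec : list of (class, count) with class in
        {"F1", "F2", "BC_S", "BC_N", "TRIPLOID"}.
    clone_spec : list of (source sample id, n_ramets); ramets copy the
        source's dosages, then error/missingness is applied per ramet.
    mean_depth : expected reads per call (Poisson).
    error_rate : per-read base-miscall probability.
    genotype_error_rate : per-call probability that the emitted dosage is
        miscalled by one step (het<->hom; a het miscall goes to either
        homozygote with equal probability).  Opposite-homozygote flips do
        not occur in one error, matching how joint callers actually err.
    missing_rate : per-call dropout probability (GT and AD dropped jointly).
    het_low, het_high : diploid-caller het window on the variant-read
        fraction, used to emit GT for triploid samples (inclusive bounds).
    chrom_lengths : chromosome name -> length in bp; loci are placed
        uniformly at random.
    inversion : optional (chrom, start, end), 1-based inclusive.  Loci in
        the interval are forced into the reciprocally-fixed class,
        emulating recombination suppression between inversion orientations.
    """

    n_loci: int = 10_000
    prop_fixed: float = 0.33
    prop_shared_poly: float = 0.67
    n_S: int = 10
    n_N: int = 10
    hybrid_spec: tuple = ()
    clone_spec: tuple = ()
    mean_depth: float = 30.0
    error_rate: float = 0.001
    genotype_error_rate: float = 0.002
    missing_rate: float = 0.02
    het_low: float = 0.2
    het_high: float = 0.8
    seed: int = 0
    chrom_lengths: dict = field(default_factory=lambda: {"Chr01": 30_000_000})
    inversion: tuple | None = None

    def __post_init__(self) -> None:
        if self.n_loci <= 0:
            raise SimConfigError("n_loci must be positive")
        if not (0 <= self.prop_fixed <= 1 and 0 <= self.prop_shared_poly <= 1):
            raise SimConfigError("locus-class proportions must lie in [0, 1]")
        if self.prop_fixed + self.prop_shared_poly > 1 + 1e-9:
            raise SimConfigError("prop_fixed + prop_shared_poly must be <= 1")
        if self.n_S < 0 or self.n_N < 0:
            raise SimConfigError("parental counts must be >= 0")
        if self.mean_depth <= 0:
            raise SimConfigError("mean_depth must be positive")
        for name in ("error_rate", "genotype_error_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v < 0.5:
                raise SimConfigError(f"{name} must lie in [0, 0.5)")
        if not 0 <= self.het_low < self.het_high <= 1:
            raise SimConfigError("need 0 <= het_low < het_high <= 1")
        for cls, count in self.hybrid_spec:
            if cls not in HYBRID_CLASSES:
                raise SimConfigError(f"unknown hybrid class {cls!r}")
            if count < 0:
                raise SimConfigError("hybrid counts must be >= 0")
            if count > 0 and (self.n_S == 0 or self.n_N == 0):
                raise SimConfigError(
                    f"{cls} individuals require at least one parent in each clade"
                )
        if self.inversion is not None:
            chrom, start, end = self.inversion
            if chrom not in self.chrom_lengths:
                raise SimConfigError(f"inversion chromosome {chrom!r} not declared")
            if not 1 <= start <= end <= self.chrom_lengths[chrom]:
                raise SimConfigError("inversion interval outside chromosome")


@dataclass
class DosagePanel:
    """True ALT-allele copy numbers before any error is applied.

    ``dosage[i, j]`` is the number of ALT copies sample ``i`` carries at
    locus ``j`` (0..ploidy_i).  ``s_is_alt`` records, per locus, whether
    the ALT allele is the S-clade allele; it is meaningful at truth-fixed
    loci (``is_fixed``) and set from the clade frequencies elsewhere.
    """

    samples: list[str]
    ploidy: np.ndarray  # per sample, 2 or 3
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray  # int8, (n_samples, n_loci)
    s_is_alt: np.ndarray  # bool per locus
    is_fixed: np.ndarray  # bool per locus (truth: reciprocally fixed)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.pos)


@dataclass
class Reads:
    """Per-call simulated read support."""

    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray


def _sample_positions(length: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct sorted 1-based positions on a chromosome of ``length`` bp."""
    if k > length:
        raise SimConfigError(f"cannot place {k} loci on {length} bp")
    pos = np.unique(rng.integers(1, length + 1, size=k + k // 10 + 16))
    while pos.size < k:
        extra = rng.integers(1, length + 1, size=k)
        pos = np.unique(np.concatenate([pos, extra]))
    if pos.size > k:
        pos = np.sort(rng.permutation(pos)[:k])
    return pos


def _place_loci(cfg: SimConfig, rng: np.random.Generator):
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    counts = rng.multinomial(cfg.n_loci, lengths / lengths.sum())
    chrom_col, pos_col = [], []
    for c, L, k in zip(chroms, lengths, counts):
        k = int(k)
        if k == 0:
            continue
        pos = _sample_positions(int(L), k, rng)
        chrom_col.extend([c] * k)
        pos_col.append(pos)
    chrom_arr = np.array(chrom_col, dtype=object)
    pos_arr = np.concatenate(pos_col) if pos_col else np.empty(0, dtype=np.int64)
    return chrom_arr, pos_arr.astype(np.int64)


def _gamete(dosage_row: np.ndarray, ploidy: int, rng: np.random.Generator) -> np.ndarray:
    """One haploid gamete: per locus, ALT with probability dosage/ploidy."""
    return rng.binomial(1, dosage_row / ploidy).astype(np.int8)


def simulate_panel(cfg: SimConfig) -> tuple[DosagePanel, pd.DataFrame]:
    """Generate true dosages and the ground-truth table.

    Returns ``(panel, truth)`` where ``truth`` is a DataFrame indexed by
    sample id with columns ``ploidy``, ``class`` and ``genet_id``.  Ramets
    of one genet share identical dosages (error is applied downstream).
    """
    rng = np.random.default_rng(cfg.seed)
    chrom, pos = _place_loci(cfg, rng)
    m = cfg.n_loci

    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    ref = _BASES[ref_idx].astype(object)
    alt = _BASES[alt_idx].astype(object)

    # locus classes: fixed quota allocated preferentially inside a declared
    # inversion interval, then at random; shared-poly from the remainder
    n_fixed = int(round(cfg.prop_fixed * m))
    n_poly = int(round(cfg.prop_shared_poly * m))
    is_fixed = np.zeros(m, dtype=bool)
    if cfg.inversion is not None:
        c, start, end = cfg.inversion
        inv_mask = (chrom == c) & (pos >= start) & (pos <= end)
        is_fixed[inv_mask] = True
    free = np.flatnonzero(~is_fixed)
    extra = n_fixed - int(is_fixed.sum())
    if extra > 0:
        is_fixed[rng.choice(free, size=min(extra, free.size), replace=False)] = True
    remaining = np.flatnonzero(~is_fixed)
    n_poly = min(n_poly, remaining.size)
    poly_idx = rng.choice(remaining, size=n_poly, replace=False) if n_poly else np.empty(0, int)
    is_poly = np.zeros(m, dtype=bool)
    is_poly[poly_idx] = True

    s_is_alt = rng.random(m) < 0.5
    p_S = np.empty(m)
    p_N = np.empty(m)
    # fixed: clades carry opposite alleles with certainty
    p_S[is_fixed] = np.where(s_is_alt[is_fixed], 1.0, 0.0)
    p_N[is_fixed] = 1.0 - p_S[is_fixed]
    # shared polymorphism: independent U-shaped frequencies per clade
    p_S[is_poly] = rng.beta(0.5, 0.5, size=int(is_poly.sum()))
    p_N[is_poly] = rng.beta(0.5, 0.5, size=int(is_poly.sum()))
    # remainder: one undiverged frequency shared by both clades
    rest = ~(is_fixed | is_poly)
    shared = rng.beta(0.5, 0.5, size=int(rest.sum()))
    p_S[rest] = shared
    p_N[rest] = shared

    samples: list[str] = []
    ploidy: list[int] = []
    classes: list[str] = []
    dosage_rows: list[np.ndarray] = []

    def add(name: str, pl: int, cls: str, d: np.ndarray) -> None:
        samples.append(name)
        ploidy.append(pl)
        classes.append(cls)
        dosage_rows.append(d.astype(np.int8))

    for k in range(cfg.n_S):
        add(f"S{k + 1:02d}", 2, PARENT_S, rng.binomial(2, p_S))
    for k in range(cfg.n_N):
        add(f"N{k + 1:02d}", 2, PARENT_N, rng.binomial(2, p_N))

    s_rows = dosage_rows[: cfg.n_S]
    n_rows = dosage_rows[cfg.n_S : cfg.n_S + cfg.n_N]

    def s_gamete() -> np.ndarray:
        return _gamete(s_rows[rng.integers(len(s_rows))], 2, rng)

    def n_gamete() -> np.ndarray:
        return _gamete(n_rows[rng.integers(len(n_rows))], 2, rng)

    def f1_dosage() -> np.ndarray:
        return s_gamete() + n_gamete()

    counters = dict.fromkeys(HYBRID_CLASSES, 0)
    for cls, count in cfg.hybrid_spec:
        for _ in range(int(count)):
            counters[cls] += 1
            name = f"{cls}_{counters[cls]:02d}"
            if cls == F1:
                add(name, 2, F1, f1_dosage())
            elif cls == F2:
                add(name, 2, F2, _gamete(f1_dosage(), 2, rng) + _gamete(f1_dosage(), 2, rng))
            elif cls == BC_S:
                add(name, 2, BC_S, _gamete(f1_dosage(), 2, rng) + s_gamete())
            elif cls == BC_N:
                add(name, 2, BC_N, _gamete(f1_dosage(), 2, rng) + n_gamete())
            elif cls == TRIPLOID:
                # unreduced F1 gamete (both haplotypes) + haploid N gamete
                add(name, 3, TRIPLOID, f1_dosage() + n_gamete())

    genet_id = {s: f"g_{s}" for s in samples}
    by_name = dict(zip(samples, range(len(samples))))
    for source, n_ramets in cfg.clone_spec:
        if source not in by_name:
            raise SimConfigError(f"clone source {source!r} is not a simulated sample")
        src = by_name[source]
        for r in range(int(n_ramets)):
            name = f"{source}_r{r + 1:02d}"
            add(name, int(ploidy[src]), classes[src], dosage_rows[src].copy())
            genet_id[name] = genet_id[source]

    panel = DosagePanel(
        samples=samples,
        ploidy=np.array(ploidy, dtype=np.int8),
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        dosage=np.vstack(dosage_rows),
        s_is_alt=s_is_alt,
        is_fixed=is_fixed,
    )
    truth = pd.DataFrame(
        {
            "sample": samples,
            "ploidy": ploidy,
            "class": classes,
            "genet_id": [genet_id[s] for s in samples],
        }
    ).set_index("sample")
    return panel, truth


def simulate_reads(
    panel: DosagePanel,
    mean_depth: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> Reads:
    """Draw per-call read counts around the dosage-determined allele fraction.

    DP ~ Poisson(mean_depth); AD_alt ~ Binomial(DP, p) with
    p = (d/ploidy)(1 - e) + (1 - d/ploidy) e, where e is the per-read
    miscall probability; AD_ref = DP - AD_alt.
    """
    rng = np.random.default_rng(seed)
    dp = rng.poisson(mean_depth, size=panel.dosage.shape).astype(np.int32)
    frac = panel.dosage / panel.ploidy[:, None]
    p = frac * (1 - error_rate) + (1 - frac) * error_rate
    ad_alt = rng.binomial(dp, p).astype(np.int32)
    return Reads(ad_ref=dp - ad_alt, ad_alt=ad_alt, dp=dp)


def to_genotype_matrix(
    panel: DosagePanel,
    reads: Reads,
    genotype_error_rate: float = 0.0,
    missing_rate: float = 0.0,
    het_low: float = 0.2,
    het_high: float = 0.8,
    seed: int = 0,
) -> GenotypeMatrix:
    """Emit diploid-caller genotypes for the panel.

    Diploid samples receive their true dosage; triploid samples are
    genotyped from the variant-read fraction with a het window
    [het_low, het_high] (inclusive), mimicking a diploid joint caller.
    Genotype error then replaces a call with one of the other two dosages;
    missingness drops GT and AD jointly.  Calls with DP = 0 are missing.
    """
    rng = np.random.default_rng(seed)
    n, m = panel.dosage.shape
    g = np.empty((n, m), dtype=np.int8)

    dip = panel.ploidy == 2
    g[dip] = panel.dosage[dip]
    tri = ~dip
    if tri.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            vrf = np.where(reads.dp[tri] > 0, reads.ad_alt[tri] / reads.dp[tri], np.nan)
        g_tri = np.where(vrf < het_low, 0, np.where(vrf > het_high, 2, 1)).astype(np.int8)
        g_tri[~np.isfinite(vrf)] = MISSING
        g[tri] = g_tri

    if genotype_error_rate > 0:
        err = (rng.random((n, m)) < genotype_error_rate) & (g != MISSING)
        # adjacent-dosage miscall: 0->1, 2->1, 1->0 or 2
        direction = np.where(rng.random((n, m)) < 0.5, -1, 1).astype(np.int8)
        step = np.where(g == 0, 1, np.where(g == 2, -1, direction)).astype(np.int8)
        g[err] = g[err] + step[err]

    ad_ref = reads.ad_ref.astype(np.int32).copy()
    ad_alt = reads.ad_alt.astype(np.int32).copy()
    dp = reads.dp.astype(np.int32).copy()

    zero_dp = dp == 0
    g[zero_dp] = MISSING
    drop = rng.random((n, m)) < missing_rate
    g[drop] = MISSING
    gone = g == MISSING
    ad_ref[gone] = MISSING
    ad_alt[gone] = MISSING
    dp[gone & zero_dp] = MISSING

    return GenotypeMatrix(
        samples=list(panel.samples),
        chrom=panel.chrom,
        pos=panel.pos,
        ref=panel.ref,
        alt=panel.alt,
        g=g,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        dp=dp,
    )


def simulate_dataset(cfg: SimConfig):
    """Full pipeline: panel -> reads -> caller genotypes.

    Returns ``(gm, truth, panel)``.  All randomness derives from
    ``cfg.seed``; repeated calls are byte-identical.
    """
    panel, truth = simulate_panel(cfg)
    reads = simulate_reads(panel, cfg.mean_depth, cfg.error_rate, seed=cfg.seed + 1)
    gm = to_genotype_matrix(
        panel,
        reads,
        genotype_error_rate=cfg.genotype_error_rate,
        missing_rate=cfg.missing_rate,
        het_low=cfg.het_low,
        het_high=cfg.het_high,
        seed=cfg.seed + 2,
    )
    return gm, truth, panel


def emit_vcf(gm: GenotypeMatrix, out_path: str) -> None:
    """Write the emitted genotypes as VCF v4.2 (FORMAT GT:AD:DP)."""
    write_vcf(gm, out_path)


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    truth.reset_index().to_csv(path, sep="\t", index=False)


def simulate_chloroplast(
    n_hap_S: int,
    n_hap_N: int,
    steps_between: int = 126,
    intra_steps: int = 3,
    seed: int = 0,
    n_sites: int = 427,
):
    """Two star-like clusters of haploid genotype strings.

    The first haplotype of each cluster is its center; the two centers
    differ at exactly ``steps_between`` sites, and every other haplotype
    differs from its center at 1..``intra_steps`` private sites (0 when
    ``intra_steps`` is 0).  Private-site sets are disjoint, so the closest
    inter-cluster pair is exactly the two centers.

    Returns ``(haplotypes, labels)``: an ordered dict name -> genotype
    string, and name -> cluster ("S" or "N").
    """
    if steps_between < 1:
        raise ValueError("steps_between must be >= 1")
    if n_hap_S < 1 or n_hap_N < 1:
        raise ValueError("each cluster needs at least one haplotype")
    rng = np.random.default_rng(seed)
    budget = steps_between + intra_steps * (n_hap_S + n_hap_N)
    if n_sites < budget:
        raise ValueError(
            f"n_sites={n_sites} too short for {budget} requested mutations"
        )
    center_S = _BASES[rng.integers(0, 4, size=n_sites)]
    site_pool = rng.permutation(n_sites)
    cursor = 0

    def mutate(seq: np.ndarray, k: int) -> np.ndarray:
        nonlocal cursor
        out = seq.copy()
        sites = site_pool[cursor : cursor + k]
        cursor += k
        out[sites] = _BASES[(np.searchsorted(_BASES, out[sites]) + rng.integers(1, 4, size=k)) % 4]
        return out

    center_N = mutate(center_S, steps_between)
    haplotypes: dict[str, str] = {}
    labels: dict[str, str] = {}
    for cluster, center, count in (("S", center_S, n_hap_S), ("N", center_N, n_hap_N)):
        for k in range(count):
            if k == 0 or intra_steps == 0:
                seq = center.copy()
            else:
                seq = mutate(center, int(rng.integers(1, intra_steps + 1)))
            name = f"cp{cluster}{k + 1:02d}"
            haplotypes[name] = "".join(seq)
            labels[name] = cluster
    return haplotypes, labels


def write_fasta(haplotypes: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in haplotypes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    haps: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    haps[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        haps[name] = "".join(chunks)
    return haps
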
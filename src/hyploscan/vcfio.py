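"""VCF input/output and SNP-panel housekeeping.

The central in-memory container is :class:`GenotypeMatrix`: samples x
biallelic SNPs with diploid-call ALT dosages (0/1/2, -1 missing), per-call
allele depths and total depth.  Coordinates are 1-based in VCF records and
in the public ``pos`` array, matching the convention of the files we read
and write; window arithmetic converts internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=hyploscan
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


class VcfFormatError(ValueError):
    """Raised for VCFs the reader cannot interpret (e.g. no GT FORMAT)."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-SNP genotype panel under diploid calls.

    Attributes
    ----------
    samples : list of sample ids (row order of the matrices).
    chrom, pos, ref, alt : per-variant arrays; ``pos`` is 1-based.
    g : int8 array (n_samples, n_variants); ALT-allele dosage 0/1/2,
        ``-1`` for a missing call.
    ad_ref, ad_alt, dp : int32 arrays, same shape; ``-1`` where absent.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    g: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    dp: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.samples), len(self.pos)
        for name in ("g", "ad_ref", "ad_alt", "dp"):
            arr = getattr(self, name)
            if arr.shape != (n, m):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected ({n}, {m})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def missing_rate(self) -> np.ndarray:
        """Per-sample fraction of missing genotype calls."""
        if self.n_variants == 0:
            return np.zeros(self.n_samples)
        return (self.g == MISSING).mean(axis=1)

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            g=self.g[:, idx],
            ad_ref=self.ad_ref[:, idx],
            ad_alt=self.ad_alt[:, idx],
            dp=self.dp[:, idx],
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        rows = [self.sample_index(s) for s in names]
        return GenotypeMatrix(
            samples=list(names),
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            g=self.g[rows],
            ad_ref=self.ad_ref[rows],
            ad_alt=self.ad_alt[rows],
            dp=self.dp[rows],
        )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained; multiallelic records and
    indels are dropped (a summary count is logged).  The FORMAT must
    contain GT; AD and DP are optional and filled with ``-1`` if absent.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VcfFormatError(f"{path}: no GT FORMAT declared in header")
    samples = list(vcf.samples)
    n = len(samples)
    has_ad = "##FORMAT=<ID=AD" in vcf.raw_header
    has_dp = "##FORMAT=<ID=DP" in vcf.raw_header

    chrom, pos, ref, alt = [], [], [], []
    g_rows, adr_rows, ada_rows, dp_rows = [], [], [], []
    n_dropped = 0
    bases = {"A", "C", "G", "T"}
    for var in vcf:
        if len(var.ALT) != 1 or var.REF not in bases or var.ALT[0] not in bases:
            n_dropped += 1
            continue
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        # gts012=True: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        g_rows.append(gt)
        ad = var.format("AD") if has_ad else None
        if ad is not None and ad.shape[1] >= 2:
            adr = ad[:, 0].astype(np.int32)
            ada = ad[:, 1].astype(np.int32)
            adr[adr < 0] = MISSING
            ada[ada < 0] = MISSING
        else:
            adr = np.full(n, MISSING, dtype=np.int32)
            ada = np.full(n, MISSING, dtype=np.int32)
        adr_rows.append(adr)
        ada_rows.append(ada)
        dpf = var.format("DP") if has_dp else None
        if dpf is not None:
            dp = dpf[:, 0].astype(np.int32)
            dp[dp < 0] = MISSING
        else:
            dp = np.full(n, MISSING, dtype=np.int32)
        dp_rows.append(dp)
    if n_dropped:
        logger.info("read_vcf(%s): dropped %d non-biallelic-SNP records", path, n_dropped)

    m = len(pos)
    stack = lambda rows, dt: (
        np.array(rows, dtype=dt).T if m else np.empty((n, 0), dtype=dt)
    )
    return GenotypeMatrix(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        g=stack(g_rows, np.int8),
        ad_ref=stack(adr_rows, np.int32),
        ad_alt=stack(ada_rows, np.int32),
        dp=stack(dp_rows, np.int32),
    )


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 with GT:AD:DP.

    Missing calls are written as ``./.`` with AD and DP ``.``, so a
    read/write round trip is lossless for this container.
    """
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in dict.fromkeys(str(c) for c in gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j in range(gm.n_variants):
            fields = [
                str(gm.chrom[j]),
                str(int(gm.pos[j])),
                ".",
                str(gm.ref[j]),
                str(gm.alt[j]),
                ".",
                "PASS",
                ".",
                "GT:AD:DP",
            ]
            for i in range(gm.n_samples):
                g = int(gm.g[i, j])
                ar, aa, dp = int(gm.ad_ref[i, j]), int(gm.ad_alt[i, j]), int(gm.dp[i, j])
                ad = f"{ar},{aa}" if ar != MISSING and aa != MISSING else "."
                fields.append(f"{gt_str[g]}:{ad}:{dp if dp != MISSING else '.'}")
            fh.write("\t".join(fields) + "\n")


def filter_variants(
    gm: GenotypeMatrix,
    max_missing: float = 1.0,
    min_maf: float = 0.0,
    min_dp: int = 0,
) -> GenotypeMatrix:
    """Remove variants by missingness and minor-allele-frequency criteria.

    Calls with DP < ``min_dp`` are set to missing first; per-variant
    missingness and MAF are then computed on the masked matrix.  An empty
    result is returned (with a warning), never raised.
    """
    if not 0 <= max_missing <= 1 or not 0 <= min_maf <= 0.5 or min_dp < 0:
        raise ValueError("filter thresholds out of range")
    g = gm.g.copy()
    ad_ref = gm.ad_ref.copy()
    ad_alt = gm.ad_alt.copy()
    dp = gm.dp.copy()
    if min_dp > 0:
        low = (dp != MISSING) & (dp < min_dp) | (dp == MISSING)
        g[low] = MISSING
        ad_ref[low] = MISSING
        ad_alt[low] = MISSING
    valid = g != MISSING
    n_valid = valid.sum(axis=0)
    miss_frac = 1.0 - n_valid / max(gm.n_samples, 1)
    with np.errstate(invalid="ignore"):
        af = np.where(valid, g, 0).sum(axis=0) / np.maximum(2 * n_valid, 1)
    maf = np.minimum(af, 1 - af)
    keep = (miss_frac <= max_missing) & (maf >= min_maf) & (n_valid > 0)
    if min_maf > 0:
        keep &= maf > 0  # monomorphic sites never pass a positive MAF bar
    if not keep.any():
        logger.warning("filter_variants: no variants survive; returning empty matrix")
    out = GenotypeMatrix(
        samples=list(gm.samples),
        chrom=gm.chrom,
        pos=gm.pos,
        ref=gm.ref,
        alt=gm.alt,
        g=g,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        dp=dp,
    )
    return out.take_variants(np.flatnonzero(keep))


def thin_by_window(gm: GenotypeMatrix, window_bp: int = 3000):
    """Keep one SNP per non-overlapping window of ``window_bp``.

    Each chromosome is partitioned into consecutive windows anchored at
    position 1 ([1, w], [w+1, 2w], ...).  Within every occupied window the
    SNP with the lowest missing rate is kept, ties broken by lowest
    position.  Input must be sorted by (chrom, pos).

    Returns ``(thinned GenotypeMatrix, report DataFrame)`` where the report
    has columns chrom, window_start, kept_pos, n_candidates.
    """
    import pandas as pd

    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    chroms = np.asarray([str(c) for c in gm.chrom], dtype=object)
    for c in np.unique(chroms):
        p = gm.pos[chroms == c]
        if np.any(np.diff(p) < 0):
            raise ValueError(f"variants on {c} are not sorted by position")
    win = (gm.pos - 1) // window_bp
    miss = (gm.g == MISSING).mean(axis=0) if gm.n_samples else np.zeros(gm.n_variants)

    kept: list[int] = []
    rows = []
    # group by (chrom, window); order of first appearance == genomic order
    df = pd.DataFrame({"j": np.arange(gm.n_variants), "chrom": chroms, "win": win})
    for (c, w), grp in df.groupby(["chrom", "win"], sort=True):
        j = grp["j"].to_numpy()
        best = j[np.lexsort((gm.pos[j], miss[j]))][0]
        kept.append(best)
        rows.append(
            {
                "chrom": c,
                "window_start": int(w) * window_bp + 1,
                "kept_pos": int(gm.pos[best]),
                "n_candidates": len(j),
            }
        )
    kept_arr = np.sort(np.array(kept, dtype=int))
    report = pd.DataFrame(rows, columns=["chrom", "window_start", "kept_pos", "n_candidates"])
    return gm.take_variants(kept_arr), report
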
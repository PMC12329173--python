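"""End-to-end orchestration of the analysis stages.

Stage order mirrors how such panels are analysed in practice: simulate
or load genotypes, filter, detect clones and prune to genet
representatives, then run the population-level stages (ploidy, hybrid
classification, inversion genotyping, structure, chloroplast network) on
the pruned sample set.  Every output TSV carries a comment header naming
the stage, seed and parameters; a machine-readable JSON manifest lists
the stage reports.  All randomness derives from the single configured
seed, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clonality, haplonet, hybrid, inversion, ploidy, popstruct, simulate, vcfio

logger = logging.getLogger("hyploscan")

STAGES = (
    "simulate",
    "filter",
    "clones",
    "ploidy",
    "hybrids",
    "inversion",
    "structure",
    "haplonet",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Flat configuration for a full run (YAML-loadable).

    Either ``vcf`` points at an input VCF or ``simulate`` holds keyword
    arguments for :class:`hyploscan.simulate.SimConfig` (the simulated
    panel is then written into the output directory and analysed).
    """

    out_dir: str = "hyploscan_out"
    seed: int = 0
    vcf: str | None = None
    chloroplast_fasta: str | None = None
    metadata: str | None = None  # TSV: sample, population[, parental_group]
    group_s: list = field(default_factory=list)
    group_n: list = field(default_factory=list)
    inversion_interval: str | None = None  # "chrom:start-end", 1-based
    chloroplast_labels: dict = field(default_factory=dict)
    simulate: dict | None = None
    # per-stage parameters
    max_missing: float = 0.2
    min_maf: float = 0.0
    min_dp_filter: int = 0
    thin_window_bp: int = 3000
    sh_threshold: float = 0.9
    max_fixed_diff_frac: float = 0.001
    vrf_min_dp: int = 10
    vrf_min_sites: int = 500
    f1_threshold: float = 0.99
    freq_tol: float = 0.0
    network_mode: str = "msn"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg: RunConfig, params: dict) -> None:
    with open(path, "w") as fh:
        fh.write(f"# hyploscan stage={stage} seed={cfg.seed} ")
        fh.write(" ".join(f"{k}={v}" for k, v in sorted(params.items())) + "\n")
        df.to_csv(fh, sep="\t")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all applicable stages; return the run manifest.

    A stage failure aborts the run with :class:`StageError`; partial
    outputs are retained and the manifest (written regardless) marks the
    stage FAILED.  Stages without the inputs they need are SKIPPED with a
    logged reason.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}}

    def record(stage: str, status: str, detail: str = "", outputs: list | None = None):
        manifest["stages"][stage] = {
            "status": status,
            "detail": detail,
            "outputs": outputs or [],
        }

    def finish() -> dict:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest

    gm = None
    truth = None
    current = "simulate"
    try:
        # --- simulate or load -------------------------------------------
        t0 = time.perf_counter()
        if cfg.simulate is not None:
            sim_cfg = simulate.SimConfig(seed=cfg.seed, **cfg.simulate)
            gm, truth, _panel = simulate.simulate_dataset(sim_cfg)
            vcf_path = out / "simulated.vcf"
            simulate.emit_vcf(gm, str(vcf_path))
            simulate.write_truth_table(truth, str(out / "truth.tsv"))
            record("simulate", "OK", f"{gm.n_samples} samples x {gm.n_variants} SNPs",
                   ["simulated.vcf", "truth.tsv"])
        elif cfg.vcf:
            gm = vcfio.read_vcf(cfg.vcf)
            record("simulate", "SKIPPED", "input VCF supplied")
        else:
            raise ValueError("config must set either 'vcf' or 'simulate'")
        logger.info("stage simulate/load done in %.2fs", time.perf_counter() - t0)

        # --- filter ------------------------------------------------------
        current = "filter"
        t0 = time.perf_counter()
        params = {
            "max_missing": cfg.max_missing,
            "min_maf": cfg.min_maf,
            "min_dp": cfg.min_dp_filter,
        }
        gm = vcfio.filter_variants(
            gm, max_missing=cfg.max_missing, min_maf=cfg.min_maf, min_dp=cfg.min_dp_filter
        )
        vcfio.write_vcf(gm, str(out / "filtered.vcf"))
        record("filter", "OK", f"{gm.n_variants} variants retained", ["filtered.vcf"])
        logger.info("stage filter done in %.2fs", time.perf_counter() - t0)

        # --- clones ------------------------------------------------------
        current = "clones"
        t0 = time.perf_counter()
        assignment = clonality.assign_genets(
            gm, sh_threshold=cfg.sh_threshold, max_fixed_diff_frac=cfg.max_fixed_diff_frac
        )
        params = {"sh_threshold": cfg.sh_threshold, "max_fixed_diff_frac": cfg.max_fixed_diff_frac}
        _write_tsv(clonality.pairwise_table(gm).set_index("sample_i"),
                   out / "clone_pairs.tsv", "clones", cfg, params)
        _write_tsv(assignment.to_frame().set_index("genet_id"),
                   out / "genets.tsv", "clones", cfg, params)
        pruned = clonality.prune_to_representatives(gm, assignment)
        record("clones", "OK",
               f"{len(assignment.ramets)} genets from {gm.n_samples} samples",
               ["clone_pairs.tsv", "genets.tsv"])
        logger.info("stage clones done in %.2fs", time.perf_counter() - t0)

        # --- ploidy ------------------------------------------------------
        current = "ploidy"
        t0 = time.perf_counter()
        ploidy_df = ploidy.classify_all(
            pruned, min_dp=cfg.vrf_min_dp, min_sites=cfg.vrf_min_sites
        )
        _write_tsv(ploidy_df, out / "ploidy.tsv", "ploidy", cfg,
                   {"min_dp": cfg.vrf_min_dp, "min_sites": cfg.vrf_min_sites})
        ploidy_calls = ploidy_df["call"].to_dict()
        record("ploidy", "OK", f"{(ploidy_df['call'] == 'TRIPLOID').sum()} triploid calls",
               ["ploidy.tsv"])
        logger.info("stage ploidy done in %.2fs", time.perf_counter() - t0)

        # --- hybrids -----------------------------------------------------
        current = "hybrids"
        t0 = time.perf_counter()
        group_s, group_n = _resolve_groups(cfg, truth, pruned)
        if group_s and group_n:
            thinned, _report = vcfio.thin_by_window(pruned, cfg.thin_window_bp)
            panel = hybrid.ascertain_fixed(
                pruned, group_s, group_n,
                freq_tol=cfg.freq_tol, max_missing=cfg.max_missing,
            )
            hybrid_df = hybrid.score_all(
                pruned, panel, ploidy_calls=ploidy_calls, f1_threshold=cfg.f1_threshold
            )
            _write_tsv(hybrid_df, out / "hybrids.tsv", "hybrids", cfg,
                       {"freq_tol": cfg.freq_tol, "f1_threshold": cfg.f1_threshold,
                        "n_diagnostic": panel.n_loci})
            record("hybrids", "OK", f"{panel.n_loci} diagnostic loci", ["hybrids.tsv"])
        else:
            record("hybrids", "SKIPPED", "no parental groups configured")
            logger.warning("hybrid stage skipped: no parental groups configured")
        logger.info("stage hybrids done in %.2fs", time.perf_counter() - t0)

        # --- inversion ---------------------------------------------------
        current = "inversion"
        t0 = time.perf_counter()
        interval = _resolve_interval(cfg)
        if interval is not None:
            chrom, start, end = interval
            inv_df = inversion.genotype_region(pruned, chrom, start, end)
            _write_tsv(inv_df, out / "inversion.tsv", "inversion", cfg,
                       {"interval": f"{chrom}:{start}-{end}"})
            record("inversion", "OK", f"PC1 {inv_df.attrs['pc1_var_frac']:.3f} of variance",
                   ["inversion.tsv"])
        else:
            record("inversion", "SKIPPED", "no inversion interval configured")
        logger.info("stage inversion done in %.2fs", time.perf_counter() - t0)

        # --- structure ---------------------------------------------------
        current = "structure"
        t0 = time.perf_counter()
        dm = popstruct.ibs_distance(pruned)
        dist_df = pd.DataFrame(dm.d, index=pruned.samples, columns=pruned.samples)
        _write_tsv(dist_df, out / "distances.tsv", "structure", cfg, {"metric": "1-ibs"})
        outputs = ["distances.tsv"]
        if pruned.n_samples >= 3:
            newick = popstruct.neighbor_joining(dm)
            (out / "nj_tree.nwk").write_text(newick + "\n")
            outputs.append("nj_tree.nwk")
        coords, var_frac = popstruct.genotype_pca(pruned)
        pca_df = pd.DataFrame(
            coords, index=pruned.samples,
            columns=[f"PC{k + 1}" for k in range(coords.shape[1])],
        )
        _write_tsv(pca_df, out / "pca.tsv", "structure", cfg,
                   {"pc1_var_frac": round(float(var_frac[0]), 6)})
        outputs.append("pca.tsv")
        record("structure", "OK", f"PC1 {var_frac[0]:.4f} of variance", outputs)
        logger.info("stage structure done in %.2fs", time.perf_counter() - t0)

        # --- haplonet ----------------------------------------------------
        current = "haplonet"
        t0 = time.perf_counter()
        if cfg.chloroplast_fasta:
            haps = simulate.read_fasta(cfg.chloroplast_fasta)
            table = haplonet.collapse_haplotypes(haps)
            net = haplonet.build_msn(table, mode=cfg.network_mode)
            _write_tsv(net.edge_frame().set_index("hap_i"),
                       out / "haplonet_edges.tsv", "haplonet", cfg,
                       {"mode": cfg.network_mode})
            _write_tsv(table.to_frame().set_index("haplotype"),
                       out / "haplotypes.tsv", "haplonet", cfg, {})
            detail = f"{len(table.ids)} haplotypes"
            if cfg.chloroplast_labels:
                sep = haplonet.cluster_separation(net, cfg.chloroplast_labels)
                detail += f"; cluster separation {sep} steps"
                manifest["cluster_separation_steps"] = sep
            record("haplonet", "OK", detail, ["haplonet_edges.tsv", "haplotypes.tsv"])
        else:
            record("haplonet", "SKIPPED", "no chloroplast input configured")
        logger.info("stage haplonet done in %.2fs", time.perf_counter() - t0)

    except Exception as exc:  # noqa: BLE001 - manifest must record the failure
        record(current, "FAILED", str(exc))
        finish()
        raise StageError(current, exc) from exc

    for stage in STAGES:
        manifest["stages"].setdefault(stage, {"status": "SKIPPED", "detail": "", "outputs": []})
    return finish()


def _resolve_groups(cfg: RunConfig, truth, gm):
    """Parental groups from config, metadata, or the simulator's truth table."""
    group_s, group_n = list(cfg.group_s), list(cfg.group_n)
    if not (group_s and group_n) and cfg.metadata:
        meta = pd.read_csv(cfg.metadata, sep="\t")
        if "parental_group" in meta.columns:
            group_s = meta.loc[meta["parental_group"] == "S", "sample"].tolist()
            group_n = meta.loc[meta["parental_group"] == "N", "sample"].tolist()
    if not (group_s and group_n) and truth is not None:
        group_s = truth.index[truth["class"] == simulate.PARENT_S].tolist()
        group_n = truth.index[truth["class"] == simulate.PARENT_N].tolist()
    present = set(gm.samples)
    return [s for s in group_s if s in present], [s for s in group_n if s in present]


def _resolve_interval(cfg: RunConfig):
    if cfg.inversion_interval:
        return inversion.parse_interval(cfg.inversion_interval)
    if cfg.simulate and cfg.simulate.get("inversion"):
        return tuple(cfg.simulate["inversion"])
    return None
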
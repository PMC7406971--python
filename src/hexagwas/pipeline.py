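"""End-to-end workflow orchestration.

Stages: simulate (optional) -> genotype -> distortion -> heritability ->
association scans (correlation, partial correlation, LMM) -> LD around the
top compensated peak.  All stage tables are TSV; a machine-readable summary
records marker counts surviving each filter, the thresholds used and the
top hits per scan.  All randomness flows from the single seed in RunConfig.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import assoc, distortion as dist_mod, genotypes, ld as ld_mod, relatedness, simulate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "summarize_phenotypes", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Workflow configuration.  Threshold defaults are the standard values
    of the analysis: per-genotype coverage > 20, MAF > 0.05, data for at
    least 50% of individuals, 5%/95% diploidization, Bonferroni alpha 0.1,
    distortion significance P < 1e-10."""

    outdir: str = "hexagwas_run"
    seed: int = 0
    # inputs (either a VCF + phenotype table, or simulate=True)
    vcf: str | None = None
    phenotypes: str | None = None
    covariate_tsv: str | None = None
    parent_ids: tuple[str, str] = ("mother", "father")
    phenotype_column: str = "rate_cumulative"
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # forwarded to simulate.random_cross / models
    # genotyping filters
    min_genotype_depth: int = 20
    maf_min: float = 0.05
    max_missing_frac: float = 0.5
    het_low: float = 0.05
    het_high: float = 0.95
    # distortion filters
    distortion_p: float = 1e-10
    dist_mean_cov: tuple[float, float] = (60.0, 200.0)
    dist_parent_cov: float = 60.0
    dist_maf_min: float = 0.01
    # association
    alpha: float = 0.1
    proxy_marker: tuple[str, int] | None = None  # covariate = called dosage here
    # LD
    ld_threshold: float = 0.15
    ld_window_bp: float = 5e6
    stages: tuple[str, ...] = (
        "genotype", "distortion", "h2", "gwas-corr", "gwas-partial", "gwas-lmm", "ld",
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("parent_ids", "dist_mean_cov", "proxy_marker", "stages"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _write_matrix(path: Path, markers: pd.DataFrame, ids: list[str], M: np.ndarray, fmt="%.6g"):
    df = pd.DataFrame(M, columns=ids)
    out = pd.concat([markers[["chrom", "pos"]].reset_index(drop=True), df], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format=fmt, na_rep=".")


def summarize_phenotypes(pheno: pd.DataFrame) -> dict:
    """Descriptive phenotype report: yearly means, cumulative ability counts,
    monoecious vs female-only counts."""
    required = {"individual_id", "ability_cumulative", "rate_cumulative"}
    if not required.issubset(pheno.columns):
        raise ValueError(f"phenotype table must contain columns {sorted(required)}")
    year_cols = sorted(c for c in pheno.columns if c.startswith("rate_y"))
    n = len(pheno)
    monoecious = int((pheno["rate_cumulative"] > 0).sum())
    return {
        "n_individuals": n,
        "yearly_mean_rate": {c: round(float(pheno[c].mean()), 6) for c in year_cols},
        "mean_rate_cumulative": round(float(pheno["rate_cumulative"].mean()), 6),
        "n_ability_positive": int((pheno["ability_cumulative"] == 1).sum()),
        "n_monoecious": monoecious,
        "n_female_only": n - monoecious,
    }


def _simulate_stage(cfg: RunConfig, outdir: Path) -> tuple[Path, Path]:
    sim = dict(cfg.sim)
    pheno_keys = {f.name for f in simulate.PhenoModel.__dataclass_fields__.values()}
    read_keys = {f.name for f in simulate.ReadModel.__dataclass_fields__.values()}
    pheno_kwargs = {k: sim.pop(k) for k in list(sim) if k in pheno_keys}
    read_kwargs = {k: sim.pop(k) for k in list(sim) if k in read_keys}
    if "modifier_loci" in pheno_kwargs:
        loci = [tuple(t) for t in pheno_kwargs["modifier_loci"]]
        pheno_kwargs["modifier_loci"] = loci
        sim.setdefault("modifier_loci", [(c, p) for c, p, _ in loci])
    cross = simulate.random_cross(seed=cfg.seed, **sim)
    pop = simulate.simulate_population(
        cross,
        read_model=simulate.ReadModel(**read_kwargs),
        pheno_model=simulate.PhenoModel(**pheno_kwargs),
    )
    vcf = outdir / "simulated.vcf"
    pheno = outdir / "phenotypes.tsv"
    truth = outdir / "truth.tsv"
    simulate.write_population(pop, vcf, pheno, truth)
    return vcf, pheno


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages and return the run summary.

    The summary is also written to <outdir>/summary.json (byte-identical
    across reruns with the same config and seed); a log with seeds and
    versions goes to <outdir>/run.log.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("hexagwas")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("hexagwas %s, seed %d", __version__, cfg.seed)

    summary: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    try:
        vcf_path, pheno_path = cfg.vcf, cfg.phenotypes
        if cfg.simulate:
            vcf_path, pheno_path = _simulate_stage(cfg, outdir)
            summary["stages"]["simulate"] = {"vcf": vcf_path.name, "phenotypes": pheno_path.name}
        if vcf_path is None or pheno_path is None:
            raise PipelineError("input", "provide a VCF and phenotype table, or simulate=true")
        if cfg.simulate and not cfg.stages:
            _write_summary(outdir, summary)
            return summary

        # --- genotype ---------------------------------------------------
        try:
            ad = genotypes.read_allele_depths(vcf_path, cfg.min_genotype_depth)
        except Exception as err:
            raise PipelineError("genotype", str(err)) from err
        pheno = pd.read_csv(pheno_path, sep="\t")
        prog_ids = [s for s in ad.individuals if s not in cfg.parent_ids]
        pheno = pheno.set_index("individual_id").loc[prog_ids].reset_index()
        y = pheno[cfg.phenotype_column].to_numpy(dtype=float)

        ad_prog = ad.subset_individuals(prog_ids)
        quant = genotypes.allele_ratio(ad_prog)
        quant.dosage = genotypes.call_dosage(quant.ratio)
        geno = genotypes.diploidize(quant.ratio, cfg.het_low, cfg.het_high)
        dip_all = genotypes.DiploidizedMatrix(quant.markers, prog_ids, geno)
        keep = genotypes.filter_markers(dip_all, cfg.maf_min, cfg.max_missing_frac)
        summary["stages"]["genotype"] = {
            "n_markers_raw": ad.n_markers,
            "n_multiallelic_skipped": ad.n_skipped_multiallelic,
            "n_markers_post_maf_missing": int(keep.sum()),
            "n_individuals": len(prog_ids),
        }
        if keep.sum() == 0:
            raise PipelineError("genotype", "no markers survive the MAF/missingness filters")
        kidx = np.flatnonzero(keep)
        dip = genotypes.DiploidizedMatrix(
            quant.markers.iloc[kidx].reset_index(drop=True), prog_ids, geno[kidx]
        )
        quant_f = genotypes.QuantGenotypeMatrix(
            dip.markers, prog_ids, quant.ratio[kidx], quant.dosage[kidx]
        )
        _write_matrix(outdir / "ratio.tsv", quant_f.markers, prog_ids, quant_f.ratio)
        _write_matrix(outdir / "dosage.tsv", quant_f.markers, prog_ids, quant_f.dosage, fmt="%.0f")
        _write_matrix(outdir / "diploidized.tsv", dip.markers, prog_ids, dip.geno, fmt="%.0f")
        summary["phenotypes"] = summarize_phenotypes(pheno)

        # covariate: measured table, else called dosage at the proxy marker
        O = None
        if cfg.covariate_tsv:
            cov = pd.read_csv(cfg.covariate_tsv, sep="\t").set_index("individual_id")
            O = cov.loc[prog_ids].iloc[:, 0].to_numpy(dtype=float)
        elif cfg.proxy_marker:
            chrom, pos = cfg.proxy_marker
            hit = np.flatnonzero(
                (quant_f.markers["chrom"] == chrom) & (quant_f.markers["pos"] == pos)
            )
            if hit.size == 0:
                raise PipelineError("covariate", f"proxy marker {chrom}:{pos} not in filtered set")
            O = quant_f.dosage[int(hit[0])]
            if np.any(np.isnan(O)):  # proxy must be complete for the scans
                O = np.where(np.isnan(O), np.nanmedian(O), O)
            summary["covariate"] = {"proxy": f"{chrom}:{pos}"}

        # --- distortion ---------------------------------------------------
        if "distortion" in cfg.stages:
            didx = dist_mod.distortion_filter(
                ad, cfg.parent_ids, cfg.dist_mean_cov, cfg.dist_parent_cov, cfg.dist_maf_min
            )
            if didx.sum() > 0:
                dres = dist_mod.distortion_scan(ad, cfg.parent_ids, didx, cfg.distortion_p)
                dres.table.to_csv(outdir / "distortion.tsv", sep="\t", index=False,
                                  float_format="%.6g")
                summary["stages"]["distortion"] = {
                    "n_markers_tested": int(len(dres.table)),
                    "n_significant": int(dres.table["significant"].sum()),
                    "p_threshold": cfg.distortion_p,
                }
            else:
                summary["stages"]["distortion"] = {"n_markers_tested": 0, "n_significant": 0,
                                                   "p_threshold": cfg.distortion_p}

        # --- heritability -------------------------------------------------
        K = None
        if "h2" in cfg.stages or "gwas-lmm" in cfg.stages:
            K = relatedness.grm(dip)
            pd.DataFrame(K.A, index=prog_ids, columns=prog_ids).to_csv(
                outdir / "kinship.tsv", sep="\t", float_format="%.6g"
            )
        if "h2" in cfg.stages:
            vc = relatedness.reml_fit(y, K)
            summary["stages"]["h2"] = {
                "sigma_g2": round(vc.sigma_g2, 6),
                "sigma_e2": round(vc.sigma_e2, 6),
                "h2": round(vc.h2, 4),
                "flags": vc.flags,
            }

        # --- scans ----------------------------------------------------------
        def _record(res: assoc.AssociationResult, name: str, path: str):
            res.table.to_csv(outdir / path, sep="\t", index=False, float_format="%.6g")
            top = res.top(5)
            summary["stages"][name] = {
                "n_tests": res.n_tests,
                "neglog10_threshold": round(res.neglog10_threshold, 2),
                "n_pass": int(res.table["pass_threshold"].sum()),
                "top_hits": [
                    {"chrom": str(r.chrom), "pos": int(r.pos),
                     "stat": round(float(r.stat), 4), "neglog10p": round(float(r.neglog10p), 3)}
                    for r in top.itertuples()
                ],
            }

        corr_keep = genotypes.filter_correlation_set(quant_f.dosage)
        summary["stages"]["correlation_set"] = {"n_markers": int(corr_keep.sum())}
        qsub = genotypes.QuantGenotypeMatrix(
            quant_f.markers.iloc[np.flatnonzero(corr_keep)].reset_index(drop=True),
            prog_ids,
            quant_f.ratio[corr_keep],
        )
        if "gwas-corr" in cfg.stages:
            if corr_keep.sum() == 0:
                raise PipelineError("gwas-corr", "no markers survive the correlation-set filter")
            _record(assoc.correlation_scan(qsub, y, cfg.alpha), "gwas-corr", "scan_corr.tsv")
        partial_res = None
        if "gwas-partial" in cfg.stages and O is not None:
            partial_res = assoc.partial_correlation_scan(qsub, y, O, cfg.alpha)
            _record(partial_res, "gwas-partial", "scan_partial.tsv")
        lmm_res = None
        if "gwas-lmm" in cfg.stages:
            lmm_res = assoc.lmm_scan(dip, y, K, O=O, alpha=cfg.alpha)
            _record(lmm_res, "gwas-lmm", "scan_lmm.tsv")

        # --- LD around the strongest compensated peak ----------------------
        if "ld" in cfg.stages:
            src = lmm_res if lmm_res is not None else partial_res
            if src is not None and len(src.table):
                peak = src.table.nlargest(1, "neglog10p").iloc[0]
                try:
                    block = ld_mod.haploblock_span(
                        dip, str(peak["chrom"]), int(peak["pos"]),
                        cfg.ld_threshold, cfg.ld_window_bp,
                    )
                    block.partners.to_csv(outdir / "ld_peak.tsv", sep="\t", index=False,
                                          float_format="%.6g")
                    summary["stages"]["ld"] = {
                        "focal": f"{block.focal_chrom}:{block.focal_pos}",
                        "span_bp": block.span_bp,
                        "span": f"{block.span_start}-{block.span_end}",
                        "threshold": cfg.ld_threshold,
                    }
                except ValueError as err:
                    summary["stages"]["ld"] = {"error": str(err)}
    except PipelineError as err:
        # clean abort: keep partial outputs and record the failing stage
        summary["error"] = str(err)
        logger.error("%s", err)
        _write_summary(outdir, summary)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    _write_summary(outdir, summary)
    return summary


def _write_summary(outdir: Path, summary: dict) -> None:
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
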
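"""End-to-end orchestration: simulate/ingest -> phenotype -> map -> regions
-> heritability -> effects, with a manifest for reproducibility.

The stages form an acyclic chain; no stage reads a downstream stage's
output.  A run directory collects one sub-product per stage plus a
``manifest.json`` with the seed, configuration and SHA-256 hashes of every
file written, so two runs with the same config and seed are byte-identical
for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import effects as fx
from . import geno, herit, lmm, morpho, regions, simdata

logger = logging.getLogger("molarmap")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclasses.dataclass
class PipelineConfig:
    """Single config for a full run; defaults follow the mapping protocol."""

    seed: int
    out_dir: str
    # either simulate-block sizes ...
    simulate: dict[str, Any] | None = None
    # ... or paths to existing inputs
    shapes_csv: str | None = None
    genotypes: str | None = None
    ages_tsv: str | None = None
    # protocol settings
    wear_free: bool = True
    cut_margin_frac: float = 0.05
    slide: bool = True
    retain_threshold_pct: float = 1.0
    n_perm: int = 10_000
    perm_quantile: float = 0.95
    r2_threshold: float = 0.8
    fallback_halfwidth: int = 250_000
    n_kinship_pcs: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not 0 < self.retain_threshold_pct < 100:
            raise ValueError("retention threshold must be in (0, 100)%")
        if not 0 < self.perm_quantile <= 1:
            raise ValueError("permutation quantile must be in (0, 1]")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2 threshold must be in [0, 1]")
        if self.simulate is None and (
            self.shapes_csv is None or self.genotypes is None
        ):
            raise ValueError(
                "provide either a simulate block or shapes + genotypes paths"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    On stage failure the partial outputs are kept next to a ``FAILED``
    marker naming the stage, and the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "init"
    try:
        # -- stage: simulate / ingest -----------------------------------
        stage = "ingest"
        logger.info("[%s] starting", stage)
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            template_kwargs = sim_kwargs.pop("template", {})
            sc = simdata.SimConfig(**sim_kwargs)
            template = simdata.make_tooth_template(
                seed=config.seed, **template_kwargs
            )
            panel = simdata.simulate_genotypes(sc)
            configs, ages, truth = simdata.simulate_shapes(panel, sc, template)
            simdata.write_simulation(out / "sim", panel, configs, ages, truth)
            written += sorted((out / "sim").iterdir())
            ids = list(panel.individual_ids)
        else:
            assert config.shapes_csv and config.genotypes
            configs, ids = morpho.read_landmark_csv(config.shapes_csv)
            gpath = str(config.genotypes)
            panel = (
                geno.read_vcf(gpath)
                if gpath.endswith(".vcf")
                else geno.read_dosage_tsv(gpath)
            )
            ages = None
            if config.ages_tsv:
                ages = (
                    pd.read_csv(config.ages_tsv, sep="\t")
                    .set_index("specimen_id")
                    .loc[ids, "age_weeks"]
                    .to_numpy()
                )
            template = simdata.make_tooth_template(seed=config.seed)

        # -- stage: genotype QC + pruning --------------------------------
        stage = "genotype-qc"
        logger.info("[%s] starting", stage)
        full_panel = panel
        qc_panel, report = geno.apply_qc_filters(panel)
        mapped_panel, _pruned = geno.prune_perfect_ld(qc_panel)
        report.to_tsv(out / "qc_report.tsv")
        written.append(out / "qc_report.tsv")

        # -- stage: phenotype --------------------------------------------
        stage = "phenotype"
        logger.info("[%s] starting", stage)
        if config.wear_free:
            cut = morpho.suggest_cut_height(configs, config.cut_margin_frac)
            template_used = morpho.build_wear_free_template(template, cut)
            pheno_configs = np.stack(
                [morpho.phenotype_config(template_used, c) for c in configs]
            )
        else:
            template_used = template
            pheno_configs = np.asarray(configs, dtype=float)
        if config.slide:
            _, aligned, _ = morpho.slide_semilandmarks(
                pheno_configs, template_used, max_iter=2
            )
        else:
            aligned = morpho.gpa_align(pheno_configs)
        aligned.specimen_ids = ids
        model = morpho.compute_pca(aligned, config.retain_threshold_pct)
        morpho.write_landmark_csv(out / "aligned_shapes.csv", aligned.configs, ids)
        written.append(out / "aligned_shapes.csv")
        pheno = pd.DataFrame(
            model.retained_scores,
            columns=[f"PC{i+1}" for i in range(model.n_retained)],
        )
        pheno.insert(0, "CS", model.centroid_sizes)
        pheno.index = pd.Index(ids, name="specimen_id")
        pheno.to_csv(out / "phenotypes.tsv", sep="\t")
        written.append(out / "phenotypes.tsv")

        # -- stage: map ---------------------------------------------------
        stage = "map"
        logger.info("[%s] starting", stage)
        K = lmm.centered_kinship(mapped_panel)
        assoc, fits = lmm.association_scan(pheno, mapped_panel, K)
        thresholds = lmm.permutation_thresholds(
            pheno,
            mapped_panel,
            K,
            n_perm=config.n_perm,
            quantile=config.perm_quantile,
            seed=config.seed,
        )
        is_x = assoc["chromosome"].astype(str) == "X"
        thr = assoc.apply(
            lambda row: thresholds.thresholds[row["phenotype"]][
                "X" if str(row["chromosome"]) == "X" else "autosome"
            ],
            axis=1,
        )
        assoc["significant"] = (
            assoc["p"] < thr.astype(float).fillna(-1.0)
        )
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        thresholds.to_json(out / "thresholds.json")
        written += [out / "associations.tsv", out / "thresholds.json"]

        # -- stage: regions ----------------------------------------------
        stage = "regions"
        logger.info("[%s] starting", stage)
        chrom_len = dict(
            config.simulate.get("chromosomes", simdata.MOUSE_CHROMOSOMES)
            if config.simulate
            else simdata.MOUSE_CHROMOSOMES
        )
        hits = assoc[assoc["significant"]]
        region_list = []
        for _, row in hits.iterrows():
            region_list.append(
                regions.delimit_region(
                    row["snp_id"],
                    full_panel,
                    r2_threshold=config.r2_threshold,
                    fallback_halfwidth=config.fallback_halfwidth,
                    chromosome_length=chrom_len.get(str(row["chromosome"])),
                    best_p=row["p"],
                    phenotype=row["phenotype"],
                )
            )
        merged = regions.merge_regions(region_list)
        merged = [
            dataclasses.replace(
                r,
                effect_size=regions.effect_size(
                    model.retained_scores,
                    geno.mean_impute(full_panel)[
                        :, full_panel.snp_index(r.best_snp)
                    ],
                ),
            )
            for r in merged
        ]
        regions.regions_table(merged).to_csv(
            out / "regions.tsv", sep="\t", index=False
        )
        written.append(out / "regions.tsv")

        # -- stage: heritability ------------------------------------------
        stage = "heritability"
        logger.info("[%s] starting", stage)
        w = model.retained_variance_pct
        h = np.array([fits[f"PC{i+1}"].pve for i in range(model.n_retained)])
        se = np.array(
            [fits[f"PC{i+1}"].pve_se for i in range(model.n_retained)]
        )
        H = herit.weighted_shape_heritability(w, h)
        H_se = herit.aggregate_heritability_se(w, se)
        per_pc = pd.DataFrame(
            {"PC": np.arange(1, model.n_retained + 1), "var_pct": w,
             "pve": h, "se": se, "molar_herit": w * h}
        )
        per_pc.to_csv(out / "heritability_per_pc.tsv", sep="\t", index=False)
        shares = herit.chromosome_shape_shares(
            model.retained_scores, w, mapped_panel, config.n_kinship_pcs
        )
        lengths = np.array(
            [chrom_len[str(c)] for c in shares["chromosome"]], dtype=float
        )
        autosomal = shares["chromosome"].astype(str) != "X"
        if autosomal.sum() >= 3:
            r_len, p_len = herit.length_share_correlation(
                shares.loc[autosomal, "share"].to_numpy(),
                lengths[autosomal.to_numpy()],
            )
        else:
            r_len, p_len = float("nan"), float("nan")
        shares.to_csv(out / "heritability_per_chromosome.tsv", sep="\t",
                      index=False)
        json_out = {
            "aggregate_heritability_pct": H,
            "aggregate_se_pct": H_se,
            "length_share_correlation_r": r_len,
            "length_share_correlation_p": p_len,
        }
        (out / "heritability.json").write_text(json.dumps(json_out, indent=1))
        written += [
            out / "heritability_per_pc.tsv",
            out / "heritability_per_chromosome.tsv",
            out / "heritability.json",
        ]

        # -- stage: effects ----------------------------------------------
        stage = "effects"
        logger.info("[%s] starting", stage)
        comparisons = []
        if model.n_retained >= 3 and len(merged) > 0:
            baseline, _sigs = fx.pc_baseline(model, template_used)
            for r in merged:
                g = geno.mean_impute(full_panel)[
                    :, full_panel.snp_index(r.best_snp)
                ]
                if not (np.any(g == 0.0) and np.any(g == 2.0)):
                    continue
                sig = fx.signature_for_snp(
                    model, g, aligned.configs, template_used, label=r.name
                )
                for i in range(model.n_retained):
                    pc_sig = fx.signature_for_pc(model, i, template_used)
                    corr = fx.compare_signatures(sig, pc_sig)
                    res = fx.place_in_baseline(
                        corr, baseline, r.name, f"PC{i+1}"
                    )
                    comparisons.append(
                        (r.name, f"PC{i+1}", corr, res.percentile)
                    )
        pd.DataFrame(
            comparisons,
            columns=["effect_a", "effect_b", "correlation",
                     "baseline_percentile"],
        ).to_csv(out / "effect_comparisons.tsv", sep="\t", index=False)
        written.append(out / "effect_comparisons.tsv")

        # -- manifest -----------------------------------------------------
        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "files": {str(p.relative_to(out)): _sha256(p) for p in written},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception:
        (out / "FAILED").write_text(f"stage: {stage}\n")
        raise
    return out
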
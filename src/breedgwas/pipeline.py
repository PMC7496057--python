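"""End-to-end orchestration of the across-breed scan.

``run_pipeline`` chains the stages — simulate (or load) -> QC -> candidate
extraction -> trait residualization -> three association experiments (body
weight on all SNPs; cancer residuals on cancer candidates; longevity
residuals on longevity candidates) -> resampling robustness -> per-breed
MAF/trait scan — into one reproducible run directory with a manifest.

All randomness flows from one root seed expanded into named per-stage
substreams, so any stage can be re-run independently yet reproducibly; a
rerun from the same config yields byte-identical tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .association import run_association_experiment
from .candidates import snps_near_genes
from .errors import BreedGWASError, ConfigError
from .qc import QCConfig, run_qc
from .robustness import lowest_correlations, maf_trait_correlation, per_breed_maf, resample_robustness
from .simulate import SimulationConfig, simulate_cohort, simulate_gene_set
from .traits import add_residual_traits, correlation_report

#: stage order defines the named seed substreams
STAGES = ("simulate", "qc", "candidates", "traits", "associate", "robustness", "maf_scan")


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the root seed (< 2^31)."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF, idx]).generate_state(1)[0] & 0x7FFFFFFF)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: pipeline config must be a mapping")
    return cfg


def run_pipeline(config: dict | str | Path, outdir, seed: int | None = None) -> Path:
    """Execute the full pipeline; returns the run directory.

    ``config`` is a mapping (or path to a YAML file) with optional sections
    ``simulate`` (SimulationConfig fields), ``inputs`` (ped/map/phenotypes
    paths, alternative to simulate), ``qc`` (QCConfig fields),
    ``candidates`` (window_bp, gene-table paths or synthetic-set sizes),
    ``association`` (n_perm, alpha, marginal) and ``robustness``
    (frac, reps). ``seed`` overrides the config's root seed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root_seed = int(seed if seed is not None else config.get("seed", 0))
    manifest: dict = {
        "package": "breedgwas",
        "version": __version__,
        "root_seed": root_seed,
        "stage_seeds": {s: stage_seed(root_seed, s) for s in STAGES},
        "config": config,
        "stages": {},
    }

    # -- inputs ----------------------------------------------------------
    if "simulate" in config or "inputs" not in config:
        sim_cfg = SimulationConfig(
            **{**config.get("simulate", {}), "seed": stage_seed(root_seed, "simulate")}
        )
        geno, pheno, truth = simulate_cohort(sim_cfg)
        io.write_plink_text(geno, outdir / "cohort")
        io.write_phenotypes(pheno, outdir / "phenotypes.tsv")
        io.write_truth_table(truth, outdir / "truth.tsv")
    else:
        inputs = config["inputs"]
        geno = io.read_plink_text(inputs["ped"], inputs["map"])
        pheno = io.read_phenotypes(inputs["phenotypes"])
    manifest["stages"]["input"] = {"samples": geno.n_samples, "snps": geno.n_snps}

    # -- qc --------------------------------------------------------------
    qc_cfg = QCConfig(**{**config.get("qc", {}), "seed": stage_seed(root_seed, "qc")})
    geno, report = run_qc(geno, qc_cfg)
    report.to_frame().to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    io.write_plink_text(geno, outdir / "filtered")
    manifest["stages"]["qc"] = {
        "samples": geno.n_samples,
        "snps": geno.n_snps,
        "per_stage": report.to_frame().to_dict(orient="records"),
    }

    # restrict phenotypes to breeds surviving QC
    pheno = pheno[pheno["breed"].isin(geno.breeds)].reset_index(drop=True)

    # -- candidates ------------------------------------------------------
    cand_cfg = config.get("candidates", {})
    window = int(cand_cfg.get("window_bp", 20_000))
    gene_sets: dict[str, pd.DataFrame] = {}
    for name in ("cancer", "longevity"):
        if f"{name}_genes" in cand_cfg:
            gene_sets[name] = io.read_gene_table(cand_cfg[f"{name}_genes"])
        else:
            gene_sets[name] = simulate_gene_set(
                geno,
                n_genes=int(cand_cfg.get(f"n_{name}_genes", 20)),
                seed=stage_seed(root_seed, "candidates") + (0 if name == "cancer" else 1),
                prefix=name,
            )
            io.write_gene_table(gene_sets[name], outdir / f"genes_{name}.tsv")
    cand: dict[str, list[str]] = {}
    for name, genes in gene_sets.items():
        tab = snps_near_genes(geno, genes, window)
        tab.to_csv(outdir / f"candidates_{name}.tsv", sep="\t", index=False)
        cand[name] = tab["snp"].tolist()
    manifest["stages"]["candidates"] = {k: len(v) for k, v in cand.items()}

    # -- traits ----------------------------------------------------------
    pheno = add_residual_traits(pheno)
    io.write_phenotypes(pheno, outdir / "traits.tsv")
    correlation_report(pheno).to_csv(
        outdir / "correlation_report.tsv", sep="\t", index=False, float_format="%.17g"
    )

    # -- association x3 --------------------------------------------------
    assoc_cfg = config.get("association", {})
    n_perm = int(assoc_cfg.get("n_perm", 1000))
    alpha = float(assoc_cfg.get("alpha", 0.05))
    marginal = float(assoc_cfg.get("marginal", 0.1))
    experiments = [
        ("bodyweight", "body_weight_kg", None),
        ("cancer", "cancer_residual", cand["cancer"]),
        ("longevity", "longevity_residual", cand["longevity"]),
    ]
    assoc_seed = stage_seed(root_seed, "associate")
    results = {}
    for i, (name, trait, snps) in enumerate(experiments):
        if snps is not None and not snps:
            raise BreedGWASError(f"association '{name}': empty candidate set")
        res = run_association_experiment(
            geno, pheno, trait, snps, n_perm, assoc_seed + i, alpha, marginal
        )
        results[name] = res
        io.write_association_table(res.table, outdir / f"assoc_{name}.tsv")
        io.write_manhattan_table(res.manhattan_table(), outdir / f"manhattan_{name}.tsv")
        np.savetxt(outdir / f"null_{name}.txt", res.null.min_p, fmt="%.17g")
        manifest["stages"].setdefault("associate", {})[name] = {
            "snps": res.model.genotypes.n_snps,
            "significant": int(len(res.significant)),
            "marginal_or_better": int(len(res.marginally_significant)),
            "n_perm": n_perm,
        }

    # -- robustness ------------------------------------------------------
    rob_cfg = config.get("robustness", {})
    frac = float(rob_cfg.get("frac", 0.10))
    reps = int(rob_cfg.get("reps", 10))
    rob_seed = stage_seed(root_seed, "robustness")
    for i, (name, trait, snps) in enumerate(experiments[1:]):
        rob = resample_robustness(
            geno, pheno, trait, snps, frac, reps, n_perm, rob_seed + i, alpha, marginal
        )
        rob.stability.to_csv(outdir / f"robustness_{name}.tsv", sep="\t", index=False)
        manifest["stages"].setdefault("robustness", {})[name] = {
            "frac": frac,
            "reps": reps,
            "samples_per_rep": rob.replicates[0].model.genotypes.n_samples,
        }

    # -- per-breed MAF scan ---------------------------------------------
    maf = per_breed_maf(geno)
    trait_by_breed = pheno.set_index("breed")
    for name, trait, snps in experiments[1:]:
        sub = maf[snps] if snps is not None else maf
        corr = maf_trait_correlation(sub, trait_by_breed[trait])
        corr.to_csv(outdir / f"mafscan_{name}.tsv", sep="\t", index=False, float_format="%.17g")
        lowest_correlations(corr).to_csv(
            outdir / f"mafscan_{name}_lowest30.tsv", sep="\t", index=False, float_format="%.17g"
        )
        manifest["stages"].setdefault("maf_scan", {})[name] = {"snps_tested": int(len(corr))}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
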
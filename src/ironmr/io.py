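"""File readers/writers, configuration, and the end-to-end pipeline driver."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import results_to_frame, per_allele_associations, stratified_analysis
from .cohort import CohortConfig, OutcomeMix, generate_cohort
from .collider import ColliderSimConfig, run_collider_simulation, summarize_collider
from .exceptions import ConfigError, GenotypeError
from .genotypes import GenotypeMatrix
from .mr import assemble_mr_summary, all_estimates, estimates_to_frame
from .scores import build_risk_score, orient_to_biomarker
from .validation import hwe_test_matrix, pairwise_ld_r2, proxy_validation
from .weights import BIOMARKERS, SnpWeightTable, bundled_weight_table

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- genotypes

def read_genotypes(
    path: str | Path,
    fmt: str,
    weight_table: SnpWeightTable,
) -> GenotypeMatrix:
    """Read genotypes as risk-allele dosages from VCF or a TSV matrix.

    VCF dosages come from the ``DS`` FORMAT field when present, otherwise
    from the GT allele count; multiallelic records are rejected.  Each
    SNP's dosage is oriented to its primary risk allele (flipping
    ``2 - d`` when the VCF ALT is the other allele, logged); an allele pair
    that matches neither orientation is an error.  Every weight-table SNP
    must be present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "tsv":
        counted = {r.snp_id: r.primary_risk_allele for r in weight_table}
        geno = GenotypeMatrix.from_tsv(path, counted_allele=counted)
    elif fmt == "vcf":
        geno = _read_vcf(path, weight_table)
    else:
        raise ConfigError(f"unknown genotype format {fmt!r} (expected vcf or tsv)")
    missing = [s for s in weight_table.snp_ids if s not in geno.snp_ids]
    if missing:
        raise GenotypeError(f"required SNP(s) missing from {path.name}: {missing}")
    return geno


def _read_vcf(path: Path, table: SnpWeightTable) -> GenotypeMatrix:
    from cyvcf2 import VCF

    wanted = set(table.snp_ids)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    counted: dict[str, str] = {}
    for var in vcf:
        if var.ID not in wanted:
            continue
        if len(var.ALT) != 1:
            raise GenotypeError(f"{var.ID}: multiallelic record not supported")
        ref, alt = var.REF, var.ALT[0]
        try:
            ds = var.format("DS")
        except KeyError:  # DS not declared in the header
            ds = None
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(-1)
        else:
            dose = np.empty(len(samples))
            for i, gt in enumerate(var.genotypes):
                alleles = [a for a in gt[:-1] if a >= 0]
                dose[i] = np.nan if not alleles else float(sum(a == 1 for a in alleles))
        risk = table[var.ID].primary_risk_allele
        if alt == risk:
            counted[var.ID] = alt
        elif ref == risk:
            logger.info("%s: counted allele %s opposite risk allele %s; flipping dosages",
                        var.ID, alt, risk)
            dose = 2.0 - dose
            counted[var.ID] = ref
        else:
            raise GenotypeError(
                f"{var.ID}: VCF alleles {ref}/{alt} do not match risk allele {risk}"
            )
        columns[var.ID] = dose
    vcf.close()
    snp_ids = [s for s in table.snp_ids if s in columns]
    if not snp_ids:
        raise GenotypeError(f"no weight-table SNPs found in {path.name}")
    dosage = np.column_stack([columns[s] for s in snp_ids])
    return GenotypeMatrix(
        individual_ids=samples, snp_ids=snp_ids, dosage=dosage, counted_allele=counted
    )


# ------------------------------------------------------------------ configs

def cohort_config_from_dict(d: dict[str, Any]) -> CohortConfig:
    d = dict(d)
    mix = d.pop("outcome_mix", None)
    if isinstance(mix, dict):
        d["outcome_mix"] = OutcomeMix(**mix)
    try:
        cfg = CohortConfig(**d)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a JSON or YAML config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _config_digest(cfg: CohortConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


# ----------------------------------------------------------------- pipeline

def run_full_pipeline(
    outdir: str | Path,
    config: CohortConfig | None = None,
    collider_replicates: int = 200,
    collider_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0),
    mr_outcomes: tuple[str, ...] = ("fev1_sd", "fvc_sd"),
    n_boot: int = 2000,
    force: bool = False,
    run_collider: bool = True,
) -> dict[str, Path]:
    """simulate → score → validate → associate → mr → collider-sim.

    Writes haemoglobin-validation, score-outcome, MR-estimate and
    collider-simulation tables under ``outdir`` plus a manifest recording
    the seed, configuration hash and output digests.  Refuses to overwrite
    an existing manifest unless ``force``.
    """
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{manifest_path} exists; pass force=True to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    config = config or CohortConfig()
    config.validate()
    table = bundled_weight_table()
    outputs: dict[str, Path] = {}

    # 1. simulate
    sc = generate_cohort(config, table=table)
    cohort_path = outdir / "cohort.tsv"
    sc.cohort.to_csv(cohort_path, sep="\t")
    sc.maternal_genotypes.to_tsv(outdir / "maternal_genotypes.tsv")
    sc.child_genotypes.to_tsv(outdir / "child_genotypes.tsv")
    outputs["cohort"] = cohort_path

    # 2. score
    scores = {bm: build_risk_score(sc.maternal_genotypes, table, bm) for bm in BIOMARKERS}
    score_df = pd.DataFrame(
        {f"{bm}_score": s.standardized for bm, s in scores.items()},
        index=sc.maternal_genotypes.individual_ids,
    )
    score_path = outdir / "scores.tsv"
    score_df.to_csv(score_path, sep="\t", index_label="individual_id")
    outputs["scores"] = score_path

    # 3. validate
    hwe = hwe_test_matrix(sc.maternal_genotypes)
    pd.DataFrame(
        [
            {"snp_id": h.snp_id, "n_AA": h.counts[0], "n_Aa": h.counts[1],
             "n_aa": h.counts[2], "lrt_stat": h.lrt_stat, "p": h.p_value,
             "monomorphic": h.monomorphic}
            for h in hwe
        ]
    ).to_csv(outdir / "hwe.tsv", sep="\t", index=False)
    pairwise_ld_r2(sc.maternal_genotypes).to_csv(outdir / "ld_r2.tsv", sep="\t")
    proxy_rows = pd.concat(
        [proxy_validation(scores[bm], sc.cohort) for bm in BIOMARKERS],
        ignore_index=True,
    )
    proxy_path = outdir / "proxy_validation.tsv"
    proxy_rows.to_csv(proxy_path, sep="\t", index=False)
    outputs["proxy_validation"] = proxy_path

    # 4. associate (score-outcome battery, overall + strata)
    analysis = sc.cohort.copy()
    for bm in BIOMARKERS:
        analysis[f"{bm}_score"] = scores[bm].standardized
    pcs = [c for c in analysis.columns if c.startswith("pc")]
    assoc = stratified_analysis(
        analysis, [f"{bm}_score" for bm in BIOMARKERS], covariates=pcs
    )
    assoc_path = outdir / "score_outcome_associations.tsv"
    results_to_frame(assoc).to_csv(assoc_path, sep="\t", index=False)
    outputs["associations"] = assoc_path

    # 5. summary-data MR (unsupplemented stratum, per the sensitivity analysis)
    unsupp = analysis[analysis["supp_late"] == 0]
    mr_rows = []
    for bm in BIOMARKERS:
        oriented = orient_to_biomarker(sc.maternal_genotypes, table, bm)
        for outcome in mr_outcomes:
            per_snp = per_allele_associations(
                oriented, unsupp, outcome, covariates=pcs, model="linear",
                stratum="unsupplemented",
            )
            summ = assemble_mr_summary(table, per_snp, bm)
            ests = estimates_to_frame(all_estimates(summ, n_boot=n_boot, seed=config.seed))
            ests.insert(0, "outcome", outcome)
            ests.insert(0, "biomarker", bm)
            mr_rows.append(ests)
    mr_path = outdir / "mr_estimates.tsv"
    pd.concat(mr_rows, ignore_index=True).to_csv(mr_path, sep="\t", index=False)
    outputs["mr_estimates"] = mr_path

    # 6. collider simulation
    if run_collider:
        csim = ColliderSimConfig(
            base=dataclasses.replace(config, causal_effect=0.0),
            gamma_grid=collider_grid,
            n_replicates=collider_replicates,
            seed=config.seed,
        )
        cres = run_collider_simulation(csim, table=table)
        collider_path = outdir / "collider_sim.tsv"
        summarize_collider(cres, tsv_path=collider_path,
                           figure_path=outdir / "collider_sim.svg")
        outputs["collider_sim"] = collider_path

    manifest = {
        "package": "ironmr",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_digest": _config_digest(config),
        "outputs": {k: {"path": p.name, "sha256": _file_digest(p)} for k, p in outputs.items()},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    outputs["manifest"] = manifest_path
    return outputs
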
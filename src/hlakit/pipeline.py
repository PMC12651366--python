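"""End-to-end pipeline: simulate or load inputs, then run every stage in
dependency order and write diffable outputs plus a run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .accuracy import evaluate_cohort, round_pct
from .ase import (
    compute_maf,
    count_ase_loss_samples,
    homozygosity_frequency,
    sample_min_maf,
)
from .consensus import reconcile
from .expression import log_transform, pooled_median
from .io import (
    RunConfig,
    ase_records_from_frame,
    ase_records_to_frame,
    calls_from_frame,
    consensus_to_frame,
    highres_from_frame,
    highres_to_frame,
    read_gene_sets,
    read_table,
    read_validated_epitopes,
    write_matrix,
    write_table,
)
from .neoepitope import (
    FilterThresholds,
    aggregate_scores,
    baseline_filter,
    cross_reference,
    summarize_catalog,
)
from .nomenclature import assign_supertype, parse_allele
from .simulate import CohortSimParams, simulate_cohort

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _thresholds(config: RunConfig) -> FilterThresholds:
    return FilterThresholds(
        weak_ic50=config.weak_ic50,
        strong_ic50=config.strong_ic50,
        elution_weak=config.elution_weak,
        elution_strong=config.elution_strong,
        min_coverage=config.min_coverage,
        min_vaf=config.min_vaf,
        min_expression=config.min_expression,
        max_tsl=config.max_tsl,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk).

    With no input paths in the config, a synthetic cohort is generated at the
    configured seed. Any stage error aborts with the stage name attached.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "load-inputs"
    try:
        if config.inputs:
            calls = calls_from_frame(
                read_table(config.inputs["genotype_calls"], "genotype_calls",
                           config.column_maps.get("genotype_calls"))
            )
            truth = highres_from_frame(read_table(config.inputs["highres"], "highres"))
            counts_df = read_table(config.inputs["allele_counts"], "allele_counts")
            candidates = read_table(config.inputs["candidates"], "candidates")
            metadata = read_table(config.inputs["metadata"], "metadata")
            tpm = read_table(config.inputs["tpm_matrix"], "tpm_matrix")
        else:
            cohort = simulate_cohort(
                CohortSimParams(n_models=config.n_models, seed=config.seed)
            )
            calls = cohort.calls
            truth = cohort.highres_truth
            counts_df = cohort.ase_counts
            candidates = cohort.candidates
            metadata = cohort.metadata
            tpm = cohort.tpm

        stage = "consensus"
        by_model: dict[str, list] = {}
        for c in calls:
            by_model.setdefault(c.model_id, []).append(c)
        results = [reconcile(cs) for _, cs in sorted(by_model.items())]
        consensus_df = consensus_to_frame(results)
        write_table(consensus_df, out_dir / "consensus.tsv", sort_by=["model_id"])

        stage = "supertypes"
        st_rows = []
        for _, r in consensus_df.iterrows():
            for col in ("A1", "A2", "B1", "B2"):
                if pd.isna(r[col]):
                    continue
                lab = assign_supertype(parse_allele(r[col]), on_hla_c="na")
                st_rows.append(
                    {"model_id": r["model_id"], "allele": r[col], "supertype": str(lab)}
                )
        write_table(pd.DataFrame(st_rows), out_dir / "supertypes.tsv",
                    sort_by=["model_id", "allele"])

        stage = "accuracy"
        derived = {
            r["model_id"]: r["parent_id"]
            for _, r in metadata.iterrows()
            if r.get("parent_id")
        }
        pred = {
            res.model_id: res.genotype
            for res in results
            if res.genotype is not None and res.model_id in truth
        }
        accuracy = None
        if truth and pred:
            # evaluate inference (WGS/RNA solution 0) against gold standard:
            # use wgs solution 0 where present, else rna solution 0
            inferred = {}
            for model_id in truth:
                model_calls = by_model.get(model_id, [])
                for source in ("wgs", "rna"):
                    sol0 = [c for c in model_calls if c.source == source and c.solution == 0]
                    if sol0:
                        inferred[model_id] = sol0[0].genotype
                        break
            if inferred:
                accuracy = evaluate_cohort(truth, inferred, derived)
        if accuracy is not None:
            acc_df = pd.DataFrame(
                [
                    {
                        "model_id": m.model_id,
                        "accuracy_2d": m.accuracy_2d,
                        "accuracy_4d": m.accuracy_4d,
                        "zygosity": m.zygosity,
                    }
                    for m in accuracy.per_model
                ]
            )
            write_table(acc_df, out_dir / "accuracy.tsv", sort_by=["model_id"])

        stage = "ase"
        records = [
            compute_maf(r, threshold=config.maf_loss_threshold, min_depth=config.min_depth)
            for r in ase_records_from_frame(counts_df)
        ]
        write_table(ase_records_to_frame(records), out_dir / "ase.tsv",
                    sort_by=["sample_id", "gene"])
        per_gene, total = count_ase_loss_samples(records)
        by_sample: dict[str, list] = {}
        for r in records:
            by_sample.setdefault(r.sample_id, []).append(r)
        min_mafs = {s: sample_min_maf(rs) for s, rs in by_sample.items()}
        ctype = dict(zip(metadata["model_id"], metadata["cancer_class"]))
        zyg = homozygosity_frequency(results, ctype)
        zyg_df = pd.DataFrame(
            [
                {"cancer_type": z.cancer_type, "gene": z.gene, "n_models": z.n_models,
                 "n_homozygous": z.n_homozygous, "percent": z.percent}
                for z in zyg
            ]
        )
        write_table(zyg_df, out_dir / "homozygosity.tsv", sort_by=["cancer_type", "gene"])

        stage = "neoepitope"
        thresholds = _thresholds(config)
        scored = aggregate_scores(candidates, thresholds)
        catalog = baseline_filter(scored, thresholds)
        write_table(catalog, out_dir / "catalog.tsv", sort_by=["model_id", "variant_key"])
        summary = summarize_catalog(catalog, metadata) if not catalog.empty else None
        xref = cross_reference(catalog, read_validated_epitopes())
        write_table(xref, out_dir / "crossref.tsv", sort_by=["gene", "mt_peptide"])

        stage = "expression"
        expr = log_transform(tpm)
        write_matrix(expr, out_dir / "expression_log2.tsv")
        gene_sets = read_gene_sets()
        class1_median = pooled_median(expr, gene_sets["hla_class_I"])
        class2_median = pooled_median(expr, gene_sets["hla_class_II"])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "hlakit_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "maf_loss_threshold": config.maf_loss_threshold,
            "weak_ic50": config.weak_ic50,
            "strong_ic50": config.strong_ic50,
            "elution_weak": config.elution_weak,
            "elution_strong": config.elution_strong,
            "min_coverage": config.min_coverage,
            "min_vaf": config.min_vaf,
            "min_expression": config.min_expression,
            "max_tsl": config.max_tsl,
        },
        "summary": {
            "n_models": len(results),
            "result_type_counts": consensus_df["result_type"].value_counts().to_dict(),
            "ase_loss_per_gene": per_gene,
            "ase_loss_total_samples": total,
            "n_samples_with_min_maf": sum(v is not None for v in min_mafs.values()),
            "catalog_size": int(len(catalog)),
            "tier_counts": summary.tier_counts if summary else {},
            "crossref_matches": int(len(xref)),
            "hla_class_I_pooled_median": class1_median,
            "hla_class_II_pooled_median": class2_median,
        },
        "output_checksums": {},
    }
    if accuracy is not None:
        manifest["summary"]["mean_accuracy_2d_pct"] = round_pct(accuracy.mean_accuracy_2d)
        manifest["summary"]["mean_accuracy_4d_pct"] = round_pct(accuracy.mean_accuracy_4d)
        manifest["summary"]["zygosity_accuracy_pct"] = round_pct(accuracy.zygosity_accuracy)
    for p in sorted(out_dir.glob("*.tsv")):
        manifest["output_checksums"][p.name] = _sha256(p)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
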
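"""Neoepitope filter cascade, catalog summaries, and validated-epitope lookup.

Candidate neoepitopes (8-11-mer mutant peptides paired with an HLA allele)
arrive with per-algorithm binding predictions (IC50, nM; three algorithms)
and elution-likelihood percentile ranks (two algorithms). Scores are
aggregated by taking the best (minimum) value over algorithms, matching the
"lowest" scoring convention of aggregated prediction reports. Tiers:

* weak binder: best IC50 < 500 nM; strong binder: < 50 nM
* elution percentile rank < 2% and < 0.5%

(all strict). The baseline gate requires tumor DNA coverage > 10 reads,
DNA variant allele frequency > 0.25, gene expression > 1 TPM and transcript
support level <= 1; candidates without a TSL (fusion/splice-derived) pass the
TSL gate. Within each variant only the top epitope (best IC50, ties broken by
elution percentile, peptide length, then lexicographically) is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_CLASSES = ("snv", "inframe_indel", "frameshift", "fusion", "splice")

IC50_COLUMNS = ("ic50_netmhcpan_ba", "ic50_mhcflurry", "ic50_mhcnuggets")
PCT_COLUMNS = ("pct_netmhcpan_el", "pct_mhcflurry_el")

WEAK_IC50_NM = 500.0
STRONG_IC50_NM = 50.0
ELUTION_WEAK_PCT = 2.0
ELUTION_STRONG_PCT = 0.5
MIN_COVERAGE = 10.0
MIN_VAF = 0.25
MIN_EXPRESSION = 1.0
MAX_TSL = 1.0


@dataclass
class FilterThresholds:
    """Gate parameters; defaults are the standard prioritization settings."""

    weak_ic50: float = WEAK_IC50_NM
    strong_ic50: float = STRONG_IC50_NM
    elution_weak: float = ELUTION_WEAK_PCT
    elution_strong: float = ELUTION_STRONG_PCT
    min_coverage: float = MIN_COVERAGE
    min_vaf: float = MIN_VAF
    min_expression: float = MIN_EXPRESSION
    max_tsl: float = MAX_TSL
    elution_mode: str = "best"  # "best" (min over algorithms) or "all"


def aggregate_scores(
    candidates: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    ic50_columns: tuple[str, ...] = IC50_COLUMNS,
    pct_columns: tuple[str, ...] = PCT_COLUMNS,
) -> pd.DataFrame:
    """Add best-score and tier columns to a candidate table.

    ``best_ic50`` is the minimum over available binding algorithms and
    ``best_elution_pct`` the minimum over elution algorithms (or the maximum
    in "all" mode, requiring every algorithm to pass). A row with no binding
    score at all is an error.
    """
    t = thresholds or FilterThresholds()
    ic50_cols = [c for c in ic50_columns if c in candidates.columns]
    pct_cols = [c for c in pct_columns if c in candidates.columns]
    if not ic50_cols:
        raise ValueError("no binding-affinity (IC50) columns present")
    if not pct_cols:
        raise ValueError("no elution-percentile columns present")
    out = candidates.copy()
    best_ic50 = out[ic50_cols].min(axis=1)
    if best_ic50.isna().any():
        bad = out.index[best_ic50.isna()].tolist()
        raise ValueError(f"rows without any binding score: {bad[:5]}")
    if t.elution_mode == "all":
        best_pct = out[pct_cols].max(axis=1)
    else:
        best_pct = out[pct_cols].min(axis=1)
    out["best_ic50"] = best_ic50
    out["best_elution_pct"] = best_pct
    out["weak_binder"] = best_ic50 < t.weak_ic50
    out["strong_binder"] = best_ic50 < t.strong_ic50
    out["elution_2pct"] = best_pct < t.elution_weak
    out["elution_0_5pct"] = best_pct < t.elution_strong
    return out


def baseline_filter(
    candidates: pd.DataFrame,
    thresholds: FilterThresholds | None = None,
    include_binding_gate: bool = True,
) -> pd.DataFrame:
    """Apply the baseline gates and keep only the top epitope per variant.

    Expects the tier columns from :func:`aggregate_scores` (added on the fly
    otherwise). Gates are strict >: coverage, VAF, expression; <= for TSL
    (missing TSL passes). Candidates must also be weak binders (IC50 < 500 nM)
    to enter the catalog.
    """
    t = thresholds or FilterThresholds()
    df = candidates
    if "best_ic50" not in df.columns:
        df = aggregate_scores(df, t)
    tsl = pd.to_numeric(df["tsl"], errors="coerce")
    mask = (
        (df["dna_coverage"] > t.min_coverage)
        & (df["vaf"] > t.min_vaf)
        & (df["expression_tpm"] > t.min_expression)
        & (tsl.isna() | (tsl <= t.max_tsl))
    )
    if include_binding_gate:
        mask &= df["weak_binder"]
    surv = df.loc[mask].copy()
    if surv.empty:
        return surv
    # top epitope per variant: best IC50, then best elution, shorter peptide,
    # then lexicographic (deterministic)
    surv["_len"] = surv["mt_peptide"].str.len()
    surv = surv.sort_values(
        ["variant_key", "best_ic50", "best_elution_pct", "_len", "mt_peptide"],
        kind="mergesort",
    )
    surv = surv.drop_duplicates(subset="variant_key", keep="first")
    return surv.drop(columns="_len").sort_index()


@dataclass
class CatalogSummary:
    total: int
    by_class: dict[str, int]
    tier_counts: dict[str, int]
    per_model_counts: pd.Series
    median_per_model_by_cancer_class: pd.Series
    top_recurrent_genes: pd.DataFrame
    per_allele_counts: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))


def summarize_catalog(
    catalog: pd.DataFrame, metadata: pd.DataFrame, k: int = 20
) -> CatalogSummary:
    """Summarize a filtered catalog: class/tier counts, per-model medians by
    cancer class, top-k recurrent genes (a gene counted once per model), and
    per-HLA-allele counts of the strong-binding + strongly-eluting subset."""
    if catalog.empty:
        raise ValueError("empty catalog")
    by_class = catalog["variant_class"].value_counts().to_dict()
    tier_counts = {
        "weak_binder": int(catalog["weak_binder"].sum()),
        "strong_binder": int(catalog["strong_binder"].sum()),
        "elution_2pct": int(catalog["elution_2pct"].sum()),
        "elution_0_5pct": int(catalog["elution_0_5pct"].sum()),
        "strong_and_eluting": int(
            (catalog["strong_binder"] & catalog["elution_0_5pct"]).sum()
        ),
    }
    per_model = catalog.groupby("model_id").size()
    meta = metadata.set_index("model_id") if "model_id" in metadata.columns else metadata
    classes = per_model.index.map(meta["cancer_class"])
    medians = per_model.groupby(classes).median().sort_index()

    # recurrence: number of distinct models contributing the gene
    rec = (
        catalog.groupby("gene")["model_id"].nunique().rename("n_models").reset_index()
    )
    rec = rec.sort_values(["n_models", "gene"], ascending=[False, True], kind="mergesort")
    top = rec.head(k).reset_index(drop=True)
    breakdown = []
    for gene in top["gene"]:
        models = catalog.loc[catalog["gene"] == gene, "model_id"].unique()
        ct = pd.Series(sorted(models)).map(meta["cancer_class"]).value_counts()
        breakdown.append(";".join(f"{c}:{n}" for c, n in sorted(ct.items())))
    top["cancer_type_breakdown"] = breakdown

    strong = catalog[catalog["strong_binder"] & catalog["elution_0_5pct"]]
    per_allele = strong.groupby("hla_allele").size().sort_values(ascending=False)
    return CatalogSummary(
        total=len(catalog),
        by_class=by_class,
        tier_counts=tier_counts,
        per_model_counts=per_model,
        median_per_model_by_cancer_class=medians,
        top_recurrent_genes=top,
        per_allele_counts=per_allele,
    )


def cross_reference(
    catalog: pd.DataFrame, validated: pd.DataFrame
) -> pd.DataFrame:
    """Match validated epitopes (IEDB-style table) against the catalog.

    Match levels: ``peptide+allele`` (mutant peptide and the predicted HLA
    allele equal the validated restriction), or ``peptide`` with
    ``restriction_mismatch=True`` when the peptide matches under a different
    allele. The catalog's best IC50 for the matching row is attached.
    """
    rows = []
    for _, v in validated.iterrows():
        hits = catalog[catalog["mt_peptide"] == v["mt_sequence"]]
        for _, h in hits.iterrows():
            same_allele = (
                pd.notna(v.get("hla_restriction"))
                and str(h["hla_allele"]) == str(v["hla_restriction"])
            )
            rows.append(
                {
                    "gene": v["gene"],
                    "mutation": v["mutation"],
                    "mt_peptide": v["mt_sequence"],
                    "validated_restriction": v.get("hla_restriction", np.nan),
                    "model_id": h["model_id"],
                    "predicted_allele": h["hla_allele"],
                    "match_level": "peptide+allele" if same_allele else "peptide",
                    "restriction_mismatch": not same_allele,
                    "best_ic50": h["best_ic50"],
                }
            )
    cols = [
        "gene",
        "mutation",
        "mt_peptide",
        "validated_restriction",
        "model_id",
        "predicted_allele",
        "match_level",
        "restriction_mismatch",
        "best_ic50",
    ]
    return pd.DataFrame(rows, columns=cols)
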
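"""Readers and writers for every table dialect, plus the run configuration.

All tables are UTF-8, tab-separated with a header row; missing values are
written as "NA"; allele strings are always canonical ``HLA-X*NN:NN``. Writers
emit deterministic column order and row sort so outputs are diffable.
Malformed rows are rejected with row-level context, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .ase import ASERecord
from .consensus import GENES, ConsensusResult, GenotypeCall, Genotype
from .nomenclature import parse_allele

NA = "NA"

DIALECTS: dict[str, list[str]] = {
    "genotype_calls": [
        "model_id", "source", "solution", "A1", "A2", "B1", "B2", "C1", "C2",
        "objective",
    ],
    "highres": ["model_id", "gene", "allele1", "allele2"],
    "allele_counts": ["sample_id", "gene", "allele1", "allele2", "count1", "count2"],
    "candidates": [
        "model_id", "variant_class", "gene", "mutation", "mt_peptide", "wt_peptide",
        "hla_allele", "ic50_netmhcpan_ba", "ic50_mhcflurry", "ic50_mhcnuggets",
        "pct_netmhcpan_el", "pct_mhcflurry_el", "dna_coverage", "vaf",
        "expression_tpm", "tsl", "variant_key",
    ],
    "metadata": ["model_id", "cancer_class", "is_control"],
    "validated_epitopes": [
        "gene", "mutation", "mt_sequence", "wt_sequence", "hla_restriction",
        "assay_type",
    ],
    "geneset": ["pathway", "gene"],
}

_UNIQUE_KEYS = {
    "genotype_calls": ["model_id", "source", "solution"],
    "highres": ["model_id", "gene"],
    "allele_counts": ["sample_id", "gene"],
}


def read_table(
    path: str | Path,
    dialect: str,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a table in one of the known dialects.

    ``column_map`` renames input columns to the dialect's names (input name ->
    dialect name). Missing required columns, empty files and duplicate keys
    are errors naming the offender.
    """
    if dialect == "tpm_matrix":
        return read_tpm_matrix(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[NA], dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    if df.empty:
        raise ValueError(f"{path}: empty table")
    required = DIALECTS[dialect]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    key = _UNIQUE_KEYS.get(dialect)
    if key:
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise ValueError(f"{path}: duplicated key {tuple(first)}")
    return _coerce(df, dialect)


_NUMERIC = {
    "genotype_calls": {"solution": int, "objective": float},
    "allele_counts": {"count1": int, "count2": int},
    "candidates": {
        "ic50_netmhcpan_ba": float, "ic50_mhcflurry": float, "ic50_mhcnuggets": float,
        "pct_netmhcpan_el": float, "pct_mhcflurry_el": float, "dna_coverage": float,
        "vaf": float, "expression_tpm": float, "tsl": float,
    },
}


def _coerce(df: pd.DataFrame, dialect: str) -> pd.DataFrame:
    for col, typ in _NUMERIC.get(dialect, {}).items():
        try:
            df[col] = pd.to_numeric(df[col])
            if typ is int:
                df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"column {col!r}: non-numeric value ({exc})") from exc
    if dialect == "metadata" and "is_control" in df.columns:
        df["is_control"] = df["is_control"].map(
            {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
        )
    if "parent_id" in df.columns:
        df["parent_id"] = df["parent_id"].fillna("")
    return df


def read_tpm_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"{path}: empty TPM matrix")
    return df


def write_table(df: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None) -> None:
    """Write a TSV with deterministic row order and NA encoding."""
    out = df.copy()
    if sort_by is None:
        sort_by = [c for c in out.columns if out[c].dtype == object][:2]
    if sort_by:
        out = out.sort_values(sort_by, kind="mergesort")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, na_rep=NA)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.sort_index().sort_index(axis=1).to_csv(path, sep="\t", na_rep=NA)


# ---------------------------------------------------------------------------
# conversions between table dialects and domain objects


def calls_from_frame(df: pd.DataFrame) -> list[GenotypeCall]:
    """genotype_calls dialect -> GenotypeCall objects (genes may be missing)."""
    calls = []
    for _, r in df.iterrows():
        genotype: Genotype = {}
        for gene in GENES:
            a1, a2 = r.get(f"{gene}1"), r.get(f"{gene}2")
            if pd.isna(a1) or pd.isna(a2):
                continue
            pair = tuple(sorted((parse_allele(a1), parse_allele(a2)), key=lambda a: a.name))
            genotype[gene] = pair  # type: ignore[assignment]
        conf = r.get("objective")
        calls.append(
            GenotypeCall(
                model_id=r["model_id"],
                source=r["source"],
                solution=int(r["solution"]),
                genotype=genotype,
                confidence=None if pd.isna(conf) else float(conf),
            )
        )
    return calls


def calls_to_frame(calls: list[GenotypeCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        row: dict = {"model_id": c.model_id, "source": c.source, "solution": c.solution}
        for gene in GENES:
            pair = c.genotype.get(gene)
            row[f"{gene}1"] = pair[0].name if pair else None
            row[f"{gene}2"] = pair[1].name if pair else None
        row["objective"] = c.confidence
        rows.append(row)
    return pd.DataFrame(rows, columns=DIALECTS["genotype_calls"])


def highres_from_frame(df: pd.DataFrame) -> dict[str, Genotype]:
    """highres dialect -> per-model truth genotypes."""
    out: dict[str, Genotype] = {}
    for _, r in df.iterrows():
        pair = tuple(
            sorted((parse_allele(r["allele1"]), parse_allele(r["allele2"])),
                   key=lambda a: a.name)
        )
        out.setdefault(r["model_id"], {})[r["gene"]] = pair  # type: ignore[index]
    return out


def highres_to_frame(truth: dict[str, Genotype]) -> pd.DataFrame:
    rows = [
        {"model_id": m, "gene": g, "allele1": p[0].name, "allele2": p[1].name}
        for m, geno in sorted(truth.items())
        for g, p in sorted(geno.items())
    ]
    return pd.DataFrame(rows, columns=DIALECTS["highres"])


def ase_records_from_frame(df: pd.DataFrame) -> list[ASERecord]:
    return [
        ASERecord(
            sample_id=r["sample_id"],
            gene=r["gene"],
            allele1=parse_allele(r["allele1"]),
            allele2=parse_allele(r["allele2"]),
            count1=int(r["count1"]),
            count2=int(r["count2"]),
        )
        for _, r in df.iterrows()
    ]


def ase_records_to_frame(records: list[ASERecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id, "gene": r.gene,
            "allele1": r.allele1.name, "allele2": r.allele2.name,
            "count1": r.count1, "count2": r.count2,
            "maf": r.maf, "ase_loss": r.ase_loss,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "gene", "allele1", "allele2", "count1", "count2",
                 "maf", "ase_loss"],
    )


def consensus_to_frame(results: list[ConsensusResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        row: dict = {"model_id": res.model_id, "result_type": res.result_type}
        for gene in GENES:
            pair = (res.genotype or {}).get(gene)
            row[f"{gene}1"] = pair[0].name if pair else None
            row[f"{gene}2"] = pair[1].name if pair else None
        flags = sorted(res.flags)
        if res.ase_loss_genes:
            flags.append("potential_ase_loss:" + ",".join(res.ase_loss_genes))
        row["flags"] = ";".join(f for f in flags if f != "potential_ase_loss") or None
        rows.append(row)
    cols = ["model_id", "A1", "A2", "B1", "B2", "C1", "C2", "result_type", "flags"]
    return pd.DataFrame(rows, columns=cols)


def read_gene_sets(path: str | Path | None = None) -> dict[str, list[str]]:
    """Pathway -> gene list; defaults to the packaged panels."""
    if path is None:
        text = resources.files("hlakit.data").joinpath("gene_sets.tsv").read_text()
        lines = text.splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    out: dict[str, list[str]] = {}
    for line in lines:
        if not line.strip() or line.startswith("#") or line.startswith("pathway\t"):
            continue
        pathway, gene = line.split("\t")
        out.setdefault(pathway, []).append(gene)
    return out


def read_validated_epitopes(path: str | Path | None = None) -> pd.DataFrame:
    """Validated-epitope table; defaults to the packaged IEDB-derived set."""
    if path is None:
        with resources.as_file(
            resources.files("hlakit.data").joinpath("validated_epitopes.tsv")
        ) as p:
            return read_table(p, "validated_epitopes")
    return read_table(path, "validated_epitopes")


@dataclass
class RunConfig:
    """Pipeline configuration; threshold defaults are the standard settings."""

    out_dir: str = "results"
    seed: int = 0
    maf_loss_threshold: float = 0.25
    min_depth: int = 10
    weak_ic50: float = 500.0
    strong_ic50: float = 50.0
    elution_weak: float = 2.0
    elution_strong: float = 0.5
    min_coverage: float = 10.0
    min_vaf: float = 0.25
    min_expression: float = 1.0
    max_tsl: float = 1.0
    n_models: int = 200
    inputs: dict = dc_field(default_factory=dict)
    column_maps: dict = dc_field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("maf_loss_threshold", "weak_ic50", "strong_ic50",
                     "elution_weak", "elution_strong", "min_coverage",
                     "min_vaf", "min_expression", "max_tsl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
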
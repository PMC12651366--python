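"""Synthetic cohort generator.

Produces cohorts with the statistical structure the analysis modules assume:
germline class I genotypes drawn from a packaged allele-frequency table with
extra genomic homozygosity (LOH) injected at rate ``p_loh`` per gene;
allele-level RNA read counts with ASE-loss events (one allele suppressed to an
expression ratio ``ase_suppression``) at rate ``p_ase`` per heterozygous gene;
two inference sources (WGS and RNA) with three ranked solutions each, a
per-allele 4-digit miscall rate and a deterministic RNA homozygous-collapse of
heterozygous genes whose simulated MAF falls below a threshold; and candidate
neoepitope tables with correlated binding/elution scores.

Everything is driven by one :class:`numpy.random.Generator`, so a fixed seed
gives bit-identical cohorts. The allele-frequency table is an illustrative
fixture, not a population estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import norm

from .consensus import GENES, GenotypeCall, Genotype
from .nomenclature import HLAAllele, parse_allele

# source availability mirroring a cohort where ~10% of models carry
# gold-standard typing, ~72% both inference sources, the rest one source
SOURCE_PATTERNS = ("highres", "both", "wgs_only", "rna_only")
SOURCE_PROBS = (0.10, 0.72, 0.06, 0.12)

CANCER_CLASSES = (
    ("pHGG", 0.34),
    ("bone_soft_tissue_sarcoma", 0.12),
    ("neuroblastoma", 0.10),
    ("medulloblastoma", 0.08),
    ("ATRT", 0.06),
    ("ependymoma", 0.06),
    ("ETMR", 0.04),
    ("neuroendocrine", 0.04),
    ("other", 0.11),
    ("control", 0.05),
)

_SNV_GENES = ("TP53", "H3-3A", "PLEC", "PDGFRA", "NF1", "ARID1A", "BCOR",
              "ACVR1", "EGFR", "KRAS", "NRAS", "ALK", "ATRX", "TERT")
_SPLICE_GENES = ("PSPH", "MET", "CDKN2A")
_FUSION_GENES = ("EWSR1::FLI1", "PAX3::FOXO1", "KIAA1549::BRAF")
_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CohortSimParams:
    """Study-condition parameters for the synthetic cohort."""

    n_models: int = 200
    seed: int = 0
    p_loh: float = 0.10
    p_ase: float = 0.15
    ase_suppression: float = 0.10
    depth_mean: float = 100.0
    depth_dispersion: float = 10.0
    miscall_rate: float = 0.05
    group_preserving_fraction: float = 1.0
    collapse_threshold: float = 0.10
    candidates_per_model: float = 12.0
    variant_class_mix: tuple[tuple[str, float], ...] = (
        ("snv", 0.70), ("inframe_indel", 0.03), ("frameshift", 0.02),
        ("splice", 0.045), ("fusion", 0.205),
    )
    ic50_log10_mean: float = 2.3
    ic50_log10_sd: float = 0.8
    binding_correlation: float = 0.8
    elution_correlation: float = 0.5
    n_derived: int = 2
    source_probs: tuple[float, ...] = SOURCE_PROBS
    # recurrent driver-mutation epitopes with validated counterparts injected
    # into this many models (emulates shared/public neoantigens)
    spike_validated: int = 5

    def __post_init__(self) -> None:
        for p in (self.p_loh, self.p_ase, self.miscall_rate,
                  self.group_preserving_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0 < self.ase_suppression <= 1:
            raise ValueError("ase_suppression must be in (0, 1]")


def load_allele_frequencies() -> dict[str, tuple[list[HLAAllele], np.ndarray]]:
    """Packaged per-gene allele frequency table (frequencies sum to 1)."""
    text = resources.files("hlakit.data").joinpath("allele_frequencies.tsv").read_text()
    per_gene: dict[str, tuple[list[HLAAllele], list[float]]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
            continue
        gene, allele, freq = line.split("\t")
        alleles, freqs = per_gene.setdefault(gene, ([], []))
        alleles.append(parse_allele(allele))
        freqs.append(float(freq))
    out = {}
    for gene, (alleles, freqs) in per_gene.items():
        f = np.asarray(freqs)
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies for gene {gene} do not sum to 1")
        out[gene] = (alleles, f)
    return out


@dataclass
class SyntheticCohort:
    """All tables for one simulated cohort."""

    params: CohortSimParams
    truth: dict[str, Genotype]
    metadata: pd.DataFrame
    highres_truth: dict[str, Genotype]
    calls: list[GenotypeCall]
    ase_counts: pd.DataFrame
    ase_loss_truth: dict[tuple[str, str], bool] = field(default_factory=dict)
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)
    tpm: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_genotypes(
    params: CohortSimParams, rng: np.random.Generator
) -> tuple[dict[str, Genotype], pd.DataFrame]:
    """Draw truth genotypes and cohort metadata.

    Two alleles per gene i.i.d. from the frequency table; with probability
    ``p_loh`` the second allele is replaced by the first (genomic
    homozygosity beyond Hardy-Weinberg).
    """
    freqs = load_allele_frequencies()
    if not freqs:
        raise ValueError("empty allele-frequency table")
    class_names = [c for c, _ in CANCER_CLASSES]
    class_p = np.array([p for _, p in CANCER_CLASSES])
    class_p = class_p / class_p.sum()
    truth: dict[str, Genotype] = {}
    meta_rows = []
    for i in range(params.n_models):
        model_id = f"SYN{i:04d}"
        geno: Genotype = {}
        for gene in GENES:
            alleles, f = freqs[gene]
            idx = rng.choice(len(alleles), size=2, p=f)
            a1, a2 = alleles[idx[0]], alleles[idx[1]]
            if rng.random() < params.p_loh:
                a2 = a1
            geno[gene] = tuple(sorted((a1, a2), key=lambda a: a.name))  # type: ignore[assignment]
        truth[model_id] = geno
        ctype = class_names[rng.choice(len(class_names), p=class_p)]
        pattern = SOURCE_PATTERNS[
            rng.choice(len(SOURCE_PATTERNS), p=np.asarray(params.source_probs))
        ]
        meta_rows.append(
            {
                "model_id": model_id,
                "cancer_class": ctype,
                "is_control": ctype == "control",
                "source_pattern": pattern,
                "parent_id": "",
            }
        )
    meta = pd.DataFrame(meta_rows)

    # engineered derivative lines sharing a parental genome (excluded from
    # accuracy averaging downstream)
    highres_models = meta.loc[meta["source_pattern"] == "highres", "model_id"]
    for j, parent in enumerate(highres_models.head(params.n_derived)):
        child = f"{parent}-KO{j}"
        truth[child] = dict(truth[parent])
        meta = pd.concat(
            [
                meta,
                pd.DataFrame(
                    [{
                        "model_id": child,
                        "cancer_class": meta.loc[meta.model_id == parent, "cancer_class"].iloc[0],
                        "is_control": False,
                        "source_pattern": "highres",
                        "parent_id": parent,
                    }]
                ),
            ],
            ignore_index=True,
        )
    return truth, meta


def simulate_ase_counts(
    truth: dict[str, Genotype],
    metadata: pd.DataFrame,
    params: CohortSimParams,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[tuple[str, str], bool]]:
    """Allele-level RNA read counts for every model with RNA data.

    Heterozygous genes draw a total depth from a negative binomial
    (mean ``depth_mean``, size ``depth_dispersion``); the allele-1 count is
    binomial with proportion 0.5 normally, or s/(1+s) under an injected ASE
    loss (s = ``ase_suppression``, applied to a randomly chosen allele).
    """
    rna_models = metadata.loc[
        metadata["source_pattern"].isin(("both", "rna_only", "highres")), "model_id"
    ]
    rows = []
    loss_truth: dict[tuple[str, str], bool] = {}
    n = params.depth_dispersion
    p_nb = n / (n + params.depth_mean)
    s = params.ase_suppression
    for model_id in rna_models:
        geno = truth[model_id]
        for gene in GENES:
            a1, a2 = geno[gene]
            depth = int(rng.negative_binomial(n, p_nb))
            if a1.name == a2.name:
                c1, c2 = depth, 0
                loss = False
            else:
                loss = bool(rng.random() < params.p_ase)
                loss_truth[(model_id, gene)] = loss
                if loss:
                    prop1 = s / (1 + s) if rng.random() < 0.5 else 1 / (1 + s)
                else:
                    prop1 = 0.5
                c1 = int(rng.binomial(depth, prop1)) if depth > 0 else 0
                c2 = depth - c1
            rows.append(
                {
                    "sample_id": model_id,
                    "gene": gene,
                    "allele1": a1.name,
                    "allele2": a2.name,
                    "count1": c1,
                    "count2": c2,
                }
            )
    return pd.DataFrame(rows), loss_truth


def _miscall(
    allele: HLAAllele,
    gene: str,
    freqs: dict[str, tuple[list[HLAAllele], np.ndarray]],
    params: CohortSimParams,
    rng: np.random.Generator,
) -> HLAAllele:
    """Replace an allele with a miscalled one (4-digit swap, optionally
    preserving the 2-digit group)."""
    alleles, _ = freqs[gene]
    if rng.random() < params.group_preserving_fraction:
        same_group = [
            a for a in alleles if a.field1 == allele.field1 and a.name != allele.name
        ]
        if same_group:
            return same_group[int(rng.integers(len(same_group)))]
        # no table-mate in the group: fabricate a protein-level variant
        new_f2 = f"{(int(allele.field2 or 1) % 98) + 1:02d}"
        if new_f2 == allele.field2:
            new_f2 = f"{(int(new_f2) % 98) + 1:02d}"
        return HLAAllele(gene=allele.gene, field1=allele.field1, field2=new_f2)
    others = [a for a in alleles if a.field1 != allele.field1]
    return others[int(rng.integers(len(others)))]


def simulate_caller_calls(
    truth: dict[str, Genotype],
    metadata: pd.DataFrame,
    ase_counts: pd.DataFrame,
    params: CohortSimParams,
    rng: np.random.Generator,
) -> list[GenotypeCall]:
    """Multi-source solution-0..2 genotype calls with the error model applied.

    WGS solution 0 is truth with per-allele miscalls; RNA solution 0 also
    collapses heterozygous genes to homozygous (keeping the expressed major
    allele) whenever the simulated MAF is below ``collapse_threshold``.
    Solutions 1-2 perturb solution 0 with decreasing confidence.
    """
    freqs = load_allele_frequencies()
    maf_lookup: dict[tuple[str, str], tuple[float | None, str]] = {}
    for _, r in ase_counts.iterrows():
        total = r["count1"] + r["count2"]
        maf = min(r["count1"], r["count2"]) / total if total > 0 else None
        major = r["allele1"] if r["count1"] >= r["count2"] else r["allele2"]
        maf_lookup[(r["sample_id"], r["gene"])] = (maf, major)

    calls: list[GenotypeCall] = []
    for _, m in metadata.iterrows():
        model_id, pattern = m["model_id"], m["source_pattern"]
        geno = truth[model_id]
        if pattern == "highres":
            calls.append(GenotypeCall(model_id, "highres", 0, dict(geno), None))
            continue
        sources = {"both": ("wgs", "rna"), "wgs_only": ("wgs",), "rna_only": ("rna",)}[
            pattern
        ]
        for source in sources:
            sol0: Genotype = {}
            for gene in GENES:
                pair = list(geno[gene])
                if source == "rna" and pair[0].name != pair[1].name:
                    maf, major = maf_lookup.get((model_id, gene), (None, None))
                    if maf is not None and maf < params.collapse_threshold:
                        kept = next(a for a in pair if a.name == major)
                        pair = [kept, kept]
                pair = [
                    _miscall(a, gene, freqs, params, rng)
                    if rng.random() < params.miscall_rate
                    else a
                    for a in pair
                ]
                sol0[gene] = tuple(sorted(pair, key=lambda a: a.name))  # type: ignore[assignment]
            calls.append(GenotypeCall(model_id, source, 0, sol0, confidence=1.0))
            prev = sol0
            for sol in (1, 2):
                perturbed: Genotype = {}
                for gene, pair in prev.items():
                    new_pair = list(pair)
                    if rng.random() < 0.5:
                        slot = int(rng.integers(2))
                        new_pair[slot] = _miscall(new_pair[slot], gene, freqs, params, rng)
                    perturbed[gene] = tuple(sorted(new_pair, key=lambda a: a.name))  # type: ignore[assignment]
                calls.append(
                    GenotypeCall(model_id, source, sol, perturbed, confidence=1.0 - 0.1 * sol)
                )
                prev = perturbed
    return calls


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[i] for i in rng.integers(len(_AA), size=length))


def simulate_candidate_table(
    truth: dict[str, Genotype],
    metadata: pd.DataFrame,
    params: CohortSimParams,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Candidate neoepitope table with correlated binding/elution scores.

    Each candidate carries a latent binding strength z; per-algorithm log10
    IC50 values share it with correlation ``binding_correlation``, and elution
    percentile ranks are tied to the same latent with
    ``elution_correlation`` (so strong binders tend to elute well).
    """
    class_names = [c for c, _ in params.variant_class_mix]
    class_p = np.array([p for _, p in params.variant_class_mix])
    class_p = class_p / class_p.sum()
    rho_b, rho_e = params.binding_correlation, params.elution_correlation
    rows = []
    for _, m in metadata.iterrows():
        if m["parent_id"]:
            continue
        model_id = m["model_id"]
        model_alleles = sorted(
            {a.name for pair in truth[model_id].values() for a in pair}
        )
        n_variants = int(rng.poisson(params.candidates_per_model))
        for v in range(n_variants):
            vclass = class_names[rng.choice(len(class_names), p=class_p)]
            if vclass == "fusion":
                gene = _FUSION_GENES[int(rng.integers(len(_FUSION_GENES)))]
            elif vclass == "splice":
                gene = _SPLICE_GENES[int(rng.integers(len(_SPLICE_GENES)))]
            else:
                gene = _SNV_GENES[int(rng.integers(len(_SNV_GENES)))]
            variant_key = f"{model_id}:{gene}:{v}"
            coverage = int(rng.poisson(60))
            vaf = float(rng.beta(4, 3))
            expr = float(rng.lognormal(1.5, 1.2))
            tsl = np.nan if vclass in ("fusion", "splice") else (
                1 if rng.random() < 0.7 else int(rng.integers(2, 6))
            )
            mutation = f"{gene.split('::')[0]}_{vclass}_{v}"
            for _ in range(int(rng.integers(1, 4))):  # 1-3 peptides per variant
                length = int(rng.integers(8, 12))
                wt = _random_peptide(rng, length)
                pos = int(rng.integers(length))
                mt_aa = _AA[int(rng.integers(len(_AA)))]
                mt = wt[:pos] + mt_aa + wt[pos + 1:]
                z = rng.normal()
                log_ic50 = params.ic50_log10_mean + params.ic50_log10_sd * (
                    np.sqrt(rho_b) * z + np.sqrt(1 - rho_b) * rng.normal(size=3)
                )
                pct = 100.0 * norm.cdf(
                    np.sqrt(rho_e) * z + np.sqrt(1 - rho_e) * rng.normal(size=2)
                )
                pct = np.clip(pct, 1e-6, 100.0)
                rows.append(
                    {
                        "model_id": model_id,
                        "variant_class": vclass,
                        "gene": gene,
                        "mutation": mutation,
                        "mt_peptide": mt,
                        "wt_peptide": wt,
                        "hla_allele": model_alleles[int(rng.integers(len(model_alleles)))],
                        "ic50_netmhcpan_ba": float(10 ** log_ic50[0]),
                        "ic50_mhcflurry": float(10 ** log_ic50[1]),
                        "ic50_mhcnuggets": float(10 ** log_ic50[2]),
                        "pct_netmhcpan_el": float(pct[0]),
                        "pct_mhcflurry_el": float(pct[1]),
                        "dna_coverage": coverage,
                        "vaf": vaf,
                        "expression_tpm": expr,
                        "tsl": tsl,
                        "variant_key": variant_key,
                    }
                )
    # public neoantigens: spike validated driver-mutation epitopes into a few
    # models with scores that pass the cascade, so cross-referencing is
    # exercised end-to-end
    if params.spike_validated > 0:
        from .io import read_validated_epitopes

        validated = read_validated_epitopes()
        models = [m for m in metadata.loc[metadata["parent_id"] == "", "model_id"]]
        n_spike = min(params.spike_validated, len(validated), len(models))
        picks = rng.choice(len(models), size=n_spike, replace=False)
        for j in range(n_spike):
            v = validated.iloc[j]
            model_id = models[int(picks[j])]
            rows.append(
                {
                    "model_id": model_id,
                    "variant_class": "snv",
                    "gene": v["gene"],
                    "mutation": v["mutation"],
                    "mt_peptide": v["mt_sequence"],
                    "wt_peptide": v["wt_sequence"],
                    "hla_allele": v["hla_restriction"],
                    "ic50_netmhcpan_ba": float(10 ** rng.normal(1.2, 0.3)),
                    "ic50_mhcflurry": float(10 ** rng.normal(1.4, 0.3)),
                    "ic50_mhcnuggets": float(10 ** rng.normal(1.6, 0.3)),
                    "pct_netmhcpan_el": float(rng.uniform(0.05, 0.4)),
                    "pct_mhcflurry_el": float(rng.uniform(0.1, 1.0)),
                    "dna_coverage": int(rng.poisson(60)) + 11,
                    "vaf": float(rng.uniform(0.3, 0.7)),
                    "expression_tpm": float(rng.uniform(5, 50)),
                    "tsl": 1,
                    "variant_key": f"{model_id}:{v['gene']}:{v['mutation']}",
                }
            )
    return pd.DataFrame(rows)


def simulate_tpm_matrix(
    metadata: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """TPM matrix over the packaged antigen-presentation gene panels.

    Class I genes are simulated highly expressed (median log2(TPM+1) around
    8), class II near silence, other panels intermediate, emulating cultured
    tumor lines lacking immune stimulation.
    """
    from .io import read_gene_sets

    gene_sets = read_gene_sets()
    base_log2 = {
        "hla_class_I": 8.2,
        "hla_class_II": 0.15,
        "app_core": 6.0,
        "app_hsp": 7.0,
        "proteasome": 6.5,
        "t_cell_markers": 0.5,
        "immune_tf": 5.0,
    }
    samples = metadata.loc[metadata["parent_id"] == "", "model_id"].tolist()
    genes = sorted({g for genes in gene_sets.values() for g in genes})
    gene_pathway = {g: p for p, gs in gene_sets.items() for g in gs}
    data = np.empty((len(genes), len(samples)))
    for i, g in enumerate(genes):
        mu = base_log2.get(gene_pathway[g], 4.0)
        log2_vals = np.maximum(rng.normal(mu, 0.9, size=len(samples)), 0.0)
        data[i] = 2 ** log2_vals - 1
    return pd.DataFrame(data, index=genes, columns=samples)


def simulate_cohort(params: CohortSimParams | None = None) -> SyntheticCohort:
    """Generate a full cohort (genotypes, ASE counts, caller calls,
    candidates, TPM) from one seeded generator."""
    params = params or CohortSimParams()
    rng = np.random.default_rng(params.seed)
    truth, metadata = simulate_genotypes(params, rng)
    ase_counts, loss_truth = simulate_ase_counts(truth, metadata, params, rng)
    calls = simulate_caller_calls(truth, metadata, ase_counts, params, rng)
    candidates = simulate_candidate_table(truth, metadata, params, rng)
    tpm = simulate_tpm_matrix(metadata, rng)
    highres = {
        m: truth[m]
        for m in metadata.loc[metadata["source_pattern"] == "highres", "model_id"]
    }
    return SyntheticCohort(
        params=params,
        truth=truth,
        metadata=metadata,
        highres_truth=highres,
        calls=calls,
        ase_counts=ase_counts,
        ase_loss_truth=loss_truth,
        candidates=candidates,
        tpm=tpm,
    )


def with_params(**overrides) -> CohortSimParams:
    """Convenience: default parameters with selected overrides."""
    return replace(CohortSimParams(), **overrides)
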
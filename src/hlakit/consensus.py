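"""Hierarchical consensus of class I HLA genotypes from multiple sources.

Each cell-line model may carry up to three kinds of genotype evidence: a
high-resolution NGS typing assay (gold standard), WGS-based inference and
RNA-seq-based inference, the latter two with up to three ranked solutions
(solution 0 optimal). :func:`reconcile` merges them into one reported
genotype per model with a result-type label:

1. High-resolution typing present -> reported verbatim (``high_resolution``).
2. Exactly one inference source -> its solution 0 (``single_result``).
3. Both sources, solution-0 genotypes identical at 4-digit resolution across
   all genes -> ``match``.
4. RNA solution 0 homozygous at a gene where WGS solution 0 is heterozygous,
   with the RNA allele a member of the WGS pair: the classic signature of
   allele-specific-expression loss (only one allele of the heterozygous pair
   is transcribed). The WGS genotype is reported and the gene flagged
   ``potential_ase_loss``; the remaining genes decide match vs curation.
5. Otherwise the ranked alternative solutions are mined by :func:`curate`;
   full 2-digit agreement after curation is a ``partial_match``, anything
   less is ``manual_curation`` with an ambiguity flag.
6. A model judged unreliable upstream can be forced to ``undetermined``.

Allele pairs are always compared as unordered multisets; a pair of identical
alleles is a homozygous call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .nomenclature import HLAAllele, truncate

GENES = ("A", "B", "C")
SOURCES = ("highres", "wgs", "rna")

RESULT_TYPES = (
    "high_resolution",
    "match",
    "partial_match",
    "manual_curation",
    "single_result",
    "undetermined",
)

Pair = tuple[HLAAllele, HLAAllele]
Genotype = dict[str, Pair]


@dataclass(frozen=True)
class GenotypeCall:
    """One source/solution genotype for one model."""

    model_id: str
    source: str
    solution: int
    genotype: Genotype
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if not 0 <= self.solution <= 2:
            raise ValueError("solution must be 0..2")
        if self.source == "highres" and self.solution != 0:
            raise ValueError("high-resolution typing has solution 0 only")

    @property
    def rank_confidence(self) -> float:
        """Caller objective, defaulting to solution rank when absent."""
        return self.confidence if self.confidence is not None else -float(self.solution)


@dataclass
class ConsensusResult:
    """Final reported genotype for one model."""

    model_id: str
    genotype: Genotype | None
    result_type: str
    flags: set[str] = field(default_factory=set)
    ase_loss_genes: tuple[str, ...] = ()
    provenance: dict[str, str] = field(default_factory=dict)
    ambiguity_notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.result_type not in RESULT_TYPES:
            raise ValueError(f"unknown result_type {self.result_type!r}")
        if (self.result_type == "undetermined") != (self.genotype is None):
            raise ValueError("undetermined iff no genotype reported")


def _trunc(allele: HLAAllele, digits: int) -> HLAAllele:
    # comparisons tolerate 2-digit-only alleles at digits=4 (compared as-is)
    if digits == 4 and allele.field2 is None:
        return allele
    return truncate(allele, digits)


def _trunc_pair(pair: Pair, digits: int) -> tuple[str, str]:
    return tuple(sorted(_trunc(a, digits).name for a in pair))  # type: ignore[return-value]


def is_homozygous(pair: Pair) -> bool:
    return pair[0].name == pair[1].name


def pairs_equal(p1: Pair, p2: Pair, digits: int = 4) -> bool:
    return _trunc_pair(p1, digits) == _trunc_pair(p2, digits)


def _matched_alleles(p1: Pair, p2: Pair, digits: int) -> int:
    """Maximum bipartite matching size between two unordered allele pairs.

    For 2x2 this is the better of the two slot pairings.
    """
    a = [_trunc(x, digits).name for x in p1]
    b = [_trunc(x, digits).name for x in p2]
    straight = (a[0] == b[0]) + (a[1] == b[1])
    crossed = (a[0] == b[1]) + (a[1] == b[0])
    return max(straight, crossed)


def concordance_rate(
    call_a: Genotype, call_b: Genotype, digits: int = 4
) -> float:
    """Fraction of alleles matched between two genotypes at the given resolution.

    Per gene, alleles are matched by maximum bipartite matching between the
    two unordered pairs after truncation; genes missing from either genotype
    are excluded from numerator and denominator.
    """
    matched = total = 0
    for gene in sorted(set(call_a) & set(call_b)):
        matched += _matched_alleles(call_a[gene], call_b[gene], digits)
        total += 2
    if total == 0:
        raise ValueError("no genes shared between the two genotypes")
    return matched / total


def _by_source(calls: list[GenotypeCall]) -> dict[str, dict[int, GenotypeCall]]:
    out: dict[str, dict[int, GenotypeCall]] = {}
    for c in calls:
        sols = out.setdefault(c.source, {})
        if c.solution in sols:
            if c.source == "highres":
                raise ValueError(f"conflicting duplicate high-resolution calls for {c.model_id}")
            raise ValueError(
                f"duplicate ({c.model_id}, {c.source}, solution {c.solution}) call"
            )
        sols[c.solution] = c
    return out


def _ase_pattern_genes(wgs0: Genotype, rna0: Genotype) -> list[str]:
    """Genes showing the WGS-het / RNA-hom pattern with a shared allele."""
    genes = []
    for gene in sorted(set(wgs0) & set(rna0)):
        wpair, rpair = wgs0[gene], rna0[gene]
        if is_homozygous(rpair) and not is_homozygous(wpair):
            rname = rpair[0].name
            if rname in (wpair[0].name, wpair[1].name):
                genes.append(gene)
    return genes


_CURATION_LEVELS = (
    "consistent across all solutions",
    "present in both sources' solution sets",
    "WGS solution-0 fallback",
)


def curate(
    wgs_solutions: list[GenotypeCall], rna_solutions: list[GenotypeCall]
) -> tuple[Genotype, list[str]]:
    """Resolve a non-concurrent genotype from the ranked alternative solutions.

    Per gene and allele slot, preference order: (1) an allele predicted in
    every solution of both sources; (2) an allele appearing somewhere in both
    sources' solution sets; (3) the WGS solution-0 allele. Any pick below the
    first level appends an ambiguity note. Ties are broken deterministically
    by source priority (WGS over RNA), solution rank, then allele name.
    """
    wgs = sorted(wgs_solutions, key=lambda c: c.solution)
    rna = sorted(rna_solutions, key=lambda c: c.solution)
    genotype: Genotype = {}
    notes: list[str] = []
    genes = sorted(set(wgs[0].genotype) & set(rna[0].genotype))
    for gene in genes:
        all_pairs = [c.genotype[gene] for c in wgs + rna if gene in c.genotype]
        wgs_pairs = [c.genotype[gene] for c in wgs if gene in c.genotype]
        rna_pairs = [c.genotype[gene] for c in rna if gene in c.genotype]
        wgs0_pair = wgs_pairs[0]

        def names(pair: Pair) -> set[str]:
            return {pair[0].name, pair[1].name}

        wgs_union = set().union(*(names(p) for p in wgs_pairs))
        rna_union = set().union(*(names(p) for p in rna_pairs))

        # first-appearance key: (source rank, solution index, name)
        order: dict[str, tuple[int, int, str]] = {}
        for src_rank, sols in ((0, wgs_pairs), (1, rna_pairs)):
            for sol_idx, pair in enumerate(sols):
                for a in pair:
                    order.setdefault(a.name, (src_rank, sol_idx, a.name))

        allele_by_name = {
            a.name: a for c in wgs + rna if gene in c.genotype for a in c.genotype[gene]
        }

        def level(name: str) -> int | None:
            if all(name in names(p) for p in all_pairs):
                return 0
            if name in wgs_union and name in rna_union:
                return 1
            if name in names(wgs0_pair):
                return 2
            return None

        candidates = sorted(
            (n for n in allele_by_name if level(n) is not None),
            key=lambda n: (level(n), order[n]),
        )
        if len(candidates) == 1:
            chosen = [candidates[0], candidates[0]]  # inherits WGS sol-0 zygosity
        else:
            chosen = candidates[:2]
        for name in dict.fromkeys(chosen):
            lv = level(name)
            if lv and lv > 0:
                notes.append(f"{gene}: {name} chosen via {_CURATION_LEVELS[lv]}")
        genotype[gene] = tuple(sorted((allele_by_name[c] for c in chosen), key=lambda a: a.name))  # type: ignore[assignment]
    return genotype, notes


def reconcile(
    calls: list[GenotypeCall], force_undetermined: bool = False
) -> ConsensusResult:
    """Apply the hierarchical decision tree to all calls for one model."""
    if not calls:
        raise ValueError("no genotype calls supplied")
    model_id = calls[0].model_id
    if any(c.model_id != model_id for c in calls):
        raise ValueError("calls span multiple models")
    sources = _by_source(calls)

    if force_undetermined:
        return ConsensusResult(model_id, None, "undetermined", flags={"unreliable"})

    result: ConsensusResult
    if "highres" in sources:
        geno = sources["highres"][0].genotype
        result = ConsensusResult(
            model_id,
            geno,
            "high_resolution",
            provenance={g: "highres:0" for g in geno},
        )
    elif ("wgs" in sources) != ("rna" in sources):
        src = "wgs" if "wgs" in sources else "rna"
        geno = sources[src][0].genotype
        result = ConsensusResult(
            model_id, geno, "single_result", provenance={g: f"{src}:0" for g in geno}
        )
    else:
        result = _reconcile_dual(model_id, sources)

    if result.genotype is not None and set(result.genotype) >= set(GENES):
        if all(is_homozygous(result.genotype[g]) for g in GENES):
            result.flags.add("all_homozygous")
    return result


def _reconcile_dual(
    model_id: str, sources: dict[str, dict[int, GenotypeCall]]
) -> ConsensusResult:
    wgs0 = sources["wgs"][0].genotype
    rna0 = sources["rna"][0].genotype
    shared = sorted(set(wgs0) & set(rna0))
    if not shared:
        raise ValueError(f"{model_id}: WGS and RNA calls share no genes")

    ase_genes = _ase_pattern_genes(wgs0, rna0)
    other = [g for g in shared if g not in ase_genes]
    all_other_match = all(pairs_equal(wgs0[g], rna0[g], 4) for g in other)

    if all_other_match:
        # rules 3/4: full concordance, possibly modulo ASE-pattern genes,
        # reported from WGS solution 0
        flags = {"potential_ase_loss"} if ase_genes else set()
        return ConsensusResult(
            model_id,
            dict(wgs0),
            "match",
            flags=flags,
            ase_loss_genes=tuple(ase_genes),
            provenance={g: "wgs:0" for g in wgs0},
        )

    # rule 5: manual curation over the ranked solutions
    geno, notes = curate(
        list(sources["wgs"].values()), list(sources["rna"].values())
    )
    # ASE-pattern genes keep the WGS solution-0 pair
    for g in ase_genes:
        geno[g] = wgs0[g]
    two_digit_ok = all(
        pairs_equal(wgs0[g], rna0[g], 2) for g in other
    )
    result_type = "partial_match" if two_digit_ok else "manual_curation"
    flags = set()
    if notes or result_type == "manual_curation":
        flags.add("ambiguity")
    if ase_genes:
        flags.add("potential_ase_loss")
    return ConsensusResult(
        model_id,
        geno,
        result_type,
        flags=flags,
        ase_loss_genes=tuple(ase_genes),
        provenance={g: "curation" for g in geno},
        ambiguity_notes=notes,
    )
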
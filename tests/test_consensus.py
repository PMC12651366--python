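"""Consensus decision tree, curation rules, and concordance counting."""

import itertools

import pytest

from hlakit.consensus import (
    GenotypeCall,
    concordance_rate,
    curate,
    reconcile,
)
from tests.conftest import genotype, pair


HET = genotype("A*02:01", "A*01:01", "B*07:02", "B*08:01", "C*07:01", "C*07:02")


def _call(model, source, solution, geno, conf=None):
    return GenotypeCall(model, source, solution, geno, conf)


def test_highres_wins_over_discordant_inference():
    other = genotype("A*03:01", "A*11:01", "B*44:02", "B*44:03", "C*04:01", "C*05:01")
    res = reconcile(
        [
            _call("m", "highres", 0, HET),
            _call("m", "wgs", 0, other),
            _call("m", "rna", 0, other),
        ]
    )
    assert res.result_type == "high_resolution"
    assert res.genotype == HET


def test_single_source_reports_solution_zero():
    res = reconcile([_call("m", "rna", 0, HET), _call("m", "rna", 1, HET)])
    assert res.result_type == "single_result"
    assert res.genotype == HET


def test_dual_source_exact_match():
    res = reconcile([_call("m", "wgs", 0, HET), _call("m", "rna", 0, dict(HET))])
    assert res.result_type == "match"
    assert not res.flags


def test_ase_pattern_reports_wgs_and_flags_gene():
    """RNA homozygous at A for one member of the WGS heterozygous pair."""
    rna = dict(HET)
    rna["A"] = pair("A*02:01", "A*02:01")
    res = reconcile([_call("m", "wgs", 0, HET), _call("m", "rna", 0, rna)])
    assert res.result_type == "match"
    assert res.ase_loss_genes == ("A",)
    assert "potential_ase_loss" in res.flags
    assert res.genotype["A"] == HET["A"]  # WGS solution 0 reported


def test_rna_hom_allele_outside_wgs_pair_goes_to_curation():
    rna = dict(HET)
    rna["A"] = pair("A*03:01", "A*03:01")  # not in WGS pair
    res = reconcile(
        [
            _call("m", "wgs", 0, HET),
            _call("m", "wgs", 1, HET),
            _call("m", "wgs", 2, HET),
            _call("m", "rna", 0, rna),
            _call("m", "rna", 1, rna),
            _call("m", "rna", 2, rna),
        ]
    )
    assert res.result_type in ("partial_match", "manual_curation")
    assert res.ase_loss_genes == ()


def test_two_digit_agreement_is_partial_match():
    rna = dict(HET)
    rna["A"] = pair("A*02:05", "A*01:01")  # same 2-digit group, different protein
    calls = [
        _call("m", "wgs", s, HET) for s in range(3)
    ] + [_call("m", "rna", s, rna) for s in range(3)]
    res = reconcile(calls)
    assert res.result_type == "partial_match"


def test_no_two_digit_agreement_is_manual_curation_with_ambiguity():
    rna = dict(HET)
    rna["A"] = pair("A*03:01", "A*11:01")
    calls = [
        _call("m", "wgs", s, HET) for s in range(3)
    ] + [_call("m", "rna", s, rna) for s in range(3)]
    res = reconcile(calls)
    assert res.result_type == "manual_curation"
    assert "ambiguity" in res.flags


def test_all_homozygous_flag():
    hom = genotype("A*02:01", "A*02:01", "B*07:02", "B*07:02", "C*07:01", "C*07:01")
    res = reconcile([_call("m", "wgs", 0, hom), _call("m", "rna", 0, dict(hom))])
    assert "all_homozygous" in res.flags


def test_force_undetermined():
    res = reconcile([_call("m", "wgs", 0, HET)], force_undetermined=True)
    assert res.result_type == "undetermined" and res.genotype is None


def test_errors():
    with pytest.raises(ValueError):
        reconcile([])
    with pytest.raises(ValueError):
        reconcile([_call("m", "highres", 0, HET), _call("m", "highres", 0, HET)])


# --- curation -------------------------------------------------------------


def test_curate_consistent_allele_plus_wgs_fallback():
    """Allele X in all 6 solutions is kept without a note; the discordant
    second slot falls back to the WGS solution-0 allele with a note."""
    x, y, y2 = "A*02:01", "A*01:01", "A*01:02"
    wgs = [
        _call("m", "wgs", s, {"A": pair(x, y)}) for s in range(3)
    ]
    rna = [
        _call("m", "rna", s, {"A": pair(x, y2)}) for s in range(3)
    ]
    geno, notes = curate(wgs, rna)
    names = {a.name for a in geno["A"]}
    assert names == {"HLA-A*02:01", "HLA-A*01:01"}
    assert any("HLA-A*01:01" in n for n in notes)


def test_curate_prefers_cross_source_consensus_over_discordant_sol0():
    """Both sources agree in solution 1 but not solution 0: the shared
    solution-1 alleles beat the WGS solution-0 alleles."""
    agreed = pair("A*03:01", "A*11:01")
    wgs = [
        _call("m", "wgs", 0, {"A": pair("A*02:01", "A*01:01")}),
        _call("m", "wgs", 1, {"A": agreed}),
        _call("m", "wgs", 2, {"A": pair("A*02:01", "A*01:01")}),
    ]
    rna = [
        _call("m", "rna", 0, {"A": pair("A*24:02", "A*26:01")}),
        _call("m", "rna", 1, {"A": agreed}),
        _call("m", "rna", 2, {"A": pair("A*24:02", "A*26:01")}),
    ]
    geno, notes = curate(wgs, rna)
    assert {a.name for a in geno["A"]} == {"HLA-A*03:01", "HLA-A*11:01"}
    assert notes  # below-top-level fallback is flagged


def test_curate_total_disagreement_falls_back_to_wgs_sol0():
    wgs = [_call("m", "wgs", s, {"A": pair("A*02:01", "A*01:01")}) for s in range(3)]
    rna = [_call("m", "rna", s, {"A": pair("A*24:02", "A*26:01")}) for s in range(3)]
    geno, notes = curate(wgs, rna)
    assert {a.name for a in geno["A"]} == {"HLA-A*02:01", "HLA-A*01:01"}
    assert len(notes) == 2  # both slots ambiguous


def test_curated_alleles_never_invented():
    """reconcile never reports an allele absent from every input solution."""
    wgs = [_call("m", "wgs", s, HET) for s in range(3)]
    rna_geno = genotype("A*03:01", "A*11:01", "B*44:02", "B*40:01", "C*04:01", "C*05:01")
    rna = [_call("m", "rna", s, rna_geno) for s in range(3)]
    res = reconcile(wgs + rna)
    seen = {
        a.name for c in wgs + rna for p in c.genotype.values() for a in p
    }
    assert all(a.name in seen for p in res.genotype.values() for a in p)


# --- concordance ----------------------------------------------------------


def _brute_force_matched(p1, p2, digits):
    """Oracle: best assignment over all slot permutations of a 2x2 pairing."""
    from hlakit.consensus import _trunc

    a = [_trunc(x, digits).name for x in p1]
    b = [_trunc(x, digits).name for x in p2]
    return max(
        sum(x == y for x, y in zip(a, perm)) for perm in itertools.permutations(b)
    )


def test_concordance_identical_and_single_mismatch():
    assert concordance_rate(HET, HET, 4) == 1.0
    other = dict(HET)
    other["A"] = pair("A*02:05", "A*01:01")
    assert concordance_rate(HET, other, 4) == pytest.approx(5 / 6)
    assert concordance_rate(HET, other, 2) == 1.0


def test_concordance_hom_vs_het_counts_one_of_two():
    hom = {"A": pair("A*02:01", "A*02:01")}
    het = {"A": pair("A*02:01", "A*01:01")}
    assert concordance_rate(hom, het, 4) == 0.5


def test_concordance_matches_brute_force_oracle(rng):
    from hlakit.simulate import load_allele_frequencies

    freqs = load_allele_frequencies()
    for _ in range(200):
        g1, g2 = {}, {}
        for gene in "ABC":
            alleles, f = freqs[gene]
            g1[gene] = tuple(sorted(rng.choice(alleles, 2, p=f), key=lambda a: a.name))
            g2[gene] = tuple(sorted(rng.choice(alleles, 2, p=f), key=lambda a: a.name))
        for digits in (2, 4):
            expected = sum(
                _brute_force_matched(g1[g], g2[g], digits) for g in "ABC"
            ) / 6
            assert concordance_rate(g1, g2, digits) == pytest.approx(expected)
            # symmetry
            assert concordance_rate(g2, g1, digits) == pytest.approx(expected)
        # non-increasing as resolution sharpens
        assert concordance_rate(g1, g2, 4) <= concordance_rate(g1, g2, 2)
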
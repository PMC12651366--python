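"""Filter cascade vs brute-force oracle, tier nesting, summaries, crossref."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlakit.io import read_validated_epitopes
from hlakit.neoepitope import (
    FilterThresholds,
    IC50_COLUMNS,
    PCT_COLUMNS,
    aggregate_scores,
    baseline_filter,
    cross_reference,
    summarize_catalog,
)


def brute_force_cascade(df: pd.DataFrame, t: FilterThresholds) -> pd.DataFrame:
    """Row-wise oracle: apply every gate explicitly, then keep the single best
    epitope per variant by exhaustive comparison."""
    keep = []
    for idx, r in df.iterrows():
        best_ic50 = min(r[c] for c in IC50_COLUMNS)
        best_pct = min(r[c] for c in PCT_COLUMNS)
        if not (best_ic50 < t.weak_ic50):
            continue
        if not (r["dna_coverage"] > t.min_coverage):
            continue
        if not (r["vaf"] > t.min_vaf):
            continue
        if not (r["expression_tpm"] > t.min_expression):
            continue
        if not (pd.isna(r["tsl"]) or r["tsl"] <= t.max_tsl):
            continue
        keep.append((idx, r["variant_key"], best_ic50, best_pct,
                     len(r["mt_peptide"]), r["mt_peptide"]))
    best: dict[str, tuple] = {}
    for row in keep:
        key = row[1]
        rank = (row[2], row[3], row[4], row[5])
        if key not in best or rank < best[key][1]:
            best[key] = (row[0], rank)
    return df.loc[sorted(idx for idx, _ in best.values())]


def test_aggregate_scores_min_rule_and_tiers():
    df = pd.DataFrame(
        {
            "ic50_netmhcpan_ba": [120.0, 600.0, 500.0],
            "ic50_mhcflurry": [40.0, 700.0, 520.0],
            "ic50_mhcnuggets": [600.0, 800.0, 510.0],
            "pct_netmhcpan_el": [1.9, 3.0, 0.4],
            "pct_mhcflurry_el": [3.0, 5.0, 0.6],
        }
    )
    out = aggregate_scores(df)
    assert list(out["best_ic50"]) == [40.0, 600.0, 500.0]
    assert list(out["strong_binder"]) == [True, False, False]
    assert list(out["weak_binder"]) == [True, False, False]  # 500 exactly fails
    assert list(out["elution_2pct"]) == [True, False, True]
    assert list(out["elution_0_5pct"]) == [False, False, True]


def test_aggregate_requires_binding_scores():
    df = pd.DataFrame({"pct_netmhcpan_el": [1.0], "pct_mhcflurry_el": [2.0]})
    with pytest.raises(ValueError):
        aggregate_scores(df)


def test_removing_an_algorithm_only_raises_best_ic50(random_candidates):
    full = aggregate_scores(random_candidates)["best_ic50"]
    subset = aggregate_scores(
        random_candidates, ic50_columns=("ic50_netmhcpan_ba", "ic50_mhcflurry")
    )["best_ic50"]
    assert (subset >= full).all()


def test_boundary_coverage_fails_strict_gate(random_candidates):
    row = random_candidates.iloc[[0]].copy()
    row["dna_coverage"] = 10  # strict >
    row["vaf"], row["expression_tpm"], row["tsl"] = 0.5, 5.0, 1.0
    for c in IC50_COLUMNS:
        row[c] = 30.0
    assert baseline_filter(row).empty


def test_top_per_variant_keeps_best_ic50():
    base = {
        "model_id": "m", "variant_class": "snv", "gene": "TP53", "mutation": "x",
        "wt_peptide": "AAAAAAAAA", "hla_allele": "HLA-A*02:01",
        "pct_netmhcpan_el": 1.0, "pct_mhcflurry_el": 1.5, "dna_coverage": 50,
        "vaf": 0.5, "expression_tpm": 10.0, "tsl": 1.0, "variant_key": "v1",
    }
    df = pd.DataFrame(
        [
            {**base, "mt_peptide": "AAAAAAAAC", "ic50_netmhcpan_ba": 45.0,
             "ic50_mhcflurry": 60.0, "ic50_mhcnuggets": 70.0},
            {**base, "mt_peptide": "AAAAAAAAD", "ic50_netmhcpan_ba": 30.0,
             "ic50_mhcflurry": 60.0, "ic50_mhcnuggets": 70.0},
        ]
    )
    out = baseline_filter(df)
    assert len(out) == 1
    assert out.iloc[0]["best_ic50"] == 30.0


def test_cascade_matches_brute_force_oracle(random_candidates):
    t = FilterThresholds()
    ours = baseline_filter(aggregate_scores(random_candidates, t), t)
    oracle = brute_force_cascade(random_candidates, t)
    assert list(ours.index) == list(oracle.index)


def test_tier_nesting_on_random_draws(random_candidates):
    out = aggregate_scores(random_candidates)
    assert (out["strong_binder"] <= out["weak_binder"]).all()
    assert (out["elution_0_5pct"] <= out["elution_2pct"]).all()
    cat = baseline_filter(out)
    assert cat["strong_binder"].sum() <= cat["weak_binder"].sum()
    assert cat["elution_0_5pct"].sum() <= cat["elution_2pct"].sum()


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_tier_nesting_property(seed):
    gen = np.random.default_rng(seed)
    n = 50
    df = pd.DataFrame(
        {
            "ic50_netmhcpan_ba": 10 ** gen.uniform(0, 4, n),
            "ic50_mhcflurry": 10 ** gen.uniform(0, 4, n),
            "ic50_mhcnuggets": 10 ** gen.uniform(0, 4, n),
            "pct_netmhcpan_el": gen.uniform(0.01, 100, n),
            "pct_mhcflurry_el": gen.uniform(0.01, 100, n),
        }
    )
    out = aggregate_scores(df)
    assert (out["strong_binder"] <= out["weak_binder"]).all()
    assert (out["elution_0_5pct"] <= out["elution_2pct"]).all()


def test_summarize_catalog(random_candidates):
    catalog = baseline_filter(aggregate_scores(random_candidates))
    meta = pd.DataFrame(
        {
            "model_id": [f"M{i}" for i in range(30)],
            "cancer_class": ["pHGG" if i % 2 else "sarcoma" for i in range(30)],
            "is_control": [False] * 30,
        }
    )
    s = summarize_catalog(catalog, meta, k=3)
    assert sum(s.by_class.values()) == s.total == len(catalog)
    assert s.tier_counts["strong_binder"] <= s.tier_counts["weak_binder"]
    assert len(s.top_recurrent_genes) <= 3
    # per-allele counts equal a brute-force group-by on the strong subset
    strong = catalog[catalog["strong_binder"] & catalog["elution_0_5pct"]]
    expected = strong.groupby("hla_allele").size()
    assert s.per_allele_counts.sort_index().equals(expected.sort_index())
    # recurrence counts a gene once per model
    for _, row in s.top_recurrent_genes.iterrows():
        n = catalog.loc[catalog["gene"] == row["gene"], "model_id"].nunique()
        assert row["n_models"] == n


def test_summarize_is_row_order_invariant(random_candidates):
    catalog = baseline_filter(aggregate_scores(random_candidates))
    meta = pd.DataFrame(
        {"model_id": [f"M{i}" for i in range(30)],
         "cancer_class": ["pHGG"] * 30, "is_control": [False] * 30}
    )
    s1 = summarize_catalog(catalog, meta)
    s2 = summarize_catalog(catalog.sample(frac=1, random_state=5), meta)
    assert s1.by_class == s2.by_class
    assert s1.tier_counts == s2.tier_counts
    assert s1.top_recurrent_genes.equals(s2.top_recurrent_genes)


def test_cross_reference_match_levels():
    validated = read_validated_epitopes()
    catalog = pd.DataFrame(
        [
            {  # peptide + identical predicted allele
                "model_id": "m1", "mt_peptide": "YSFGVTCV",
                "hla_allele": "HLA-C*02:02", "best_ic50": 8.5,
            },
            {  # peptide under a different allele -> restriction mismatch
                "model_id": "m2", "mt_peptide": "ILDTAGKEEY",
                "hla_allele": "HLA-A*02:01", "best_ic50": 120.0,
            },
        ]
    )
    out = cross_reference(catalog, validated)
    assert len(out) == 2
    egfr = out[out["gene"] == "EGFR"].iloc[0]
    assert egfr["match_level"] == "peptide+allele"
    assert not egfr["restriction_mismatch"]
    assert egfr["best_ic50"] == pytest.approx(8.5)
    nras = out[out["gene"] == "NRAS"].iloc[0]
    assert nras["match_level"] == "peptide"
    assert nras["restriction_mismatch"]


def test_cross_reference_concordant_restriction():
    validated = read_validated_epitopes()
    catalog = pd.DataFrame(
        [{"model_id": "m", "mt_peptide": "ILDTAGKEEY",
          "hla_allele": "HLA-A*01:01", "best_ic50": 39.7}]
    )
    out = cross_reference(catalog, validated)
    assert out.iloc[0]["match_level"] == "peptide+allele"


def test_cross_reference_absent_peptide_yields_no_row():
    validated = read_validated_epitopes()
    catalog = pd.DataFrame(
        [{"model_id": "m", "mt_peptide": "WWWWWWWWW",
          "hla_allele": "HLA-A*01:01", "best_ic50": 10.0}]
    )
    assert cross_reference(catalog, validated).empty
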
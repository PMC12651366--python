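import numpy as np
import pandas as pd
import pytest

from hlakit.nomenclature import parse_allele


def pair(a: str, b: str):
    """Unordered allele pair from two short allele names."""
    return tuple(sorted((parse_allele(a), parse_allele(b)), key=lambda x: x.name))


def genotype(a1, a2, b1, b2, c1, c2):
    return {"A": pair(a1, a2), "B": pair(b1, b2), "C": pair(c1, c2)}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def random_candidates():
    """1,000 randomized neoepitope candidates spanning the full gate space."""
    gen = np.random.default_rng(7)
    n = 1000
    classes = gen.choice(["snv", "inframe_indel", "frameshift", "fusion", "splice"], n)
    tsl = np.where(
        np.isin(classes, ["fusion", "splice"]),
        np.nan,
        gen.integers(1, 6, n).astype(float),
    )
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    peptides = ["".join(gen.choice(aa, gen.integers(8, 12))) for _ in range(n)]
    return pd.DataFrame(
        {
            "model_id": gen.choice([f"M{i}" for i in range(30)], n),
            "variant_class": classes,
            "gene": gen.choice(["TP53", "KRAS", "EWSR1::FLI1", "PSPH", "NF1"], n),
            "mutation": [f"mut{i}" for i in range(n)],
            "mt_peptide": peptides,
            "wt_peptide": peptides,
            "hla_allele": gen.choice(["HLA-A*02:01", "HLA-B*07:02", "HLA-C*07:02"], n),
            "ic50_netmhcpan_ba": 10 ** gen.uniform(0, 4, n),
            "ic50_mhcflurry": 10 ** gen.uniform(0, 4, n),
            "ic50_mhcnuggets": 10 ** gen.uniform(0, 4, n),
            "pct_netmhcpan_el": gen.uniform(0.01, 100, n),
            "pct_mhcflurry_el": gen.uniform(0.01, 100, n),
            "dna_coverage": gen.integers(0, 100, n),
            "vaf": gen.uniform(0, 1, n),
            "expression_tpm": 10 ** gen.uniform(-2, 3, n),
            "tsl": tsl,
            "variant_key": gen.choice([f"v{i}" for i in range(400)], n),
        }
    )
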
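"""Class I HLA allele nomenclature: parsing, truncation, and supertype assignment.

Class I HLA alleles (genes HLA-A, HLA-B, HLA-C) are named with colon-delimited
fields: the first field ("2-digit" resolution) is the allele group and the
second field ("4-digit" resolution) identifies the protein. Before April 2010
the fields were concatenated without colons ("A0201"); this module converts
such legacy designations to the current form. Higher fields (synonymous and
intronic variation) and expression suffixes are stripped on parse and retained
only in ``raw``.

Supertypes are functional groupings of HLA-A and HLA-B alleles that share
peptide-binding specificity (Sidney et al., 2008). A handful of alleles carry
dual specificity (e.g. "A01 A03"); alleles absent from the classification are
reported as unclassified. HLA-C alleles are not supertyped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

CLASS_I_GENES = ("A", "B", "C")

# Class II (and non-classical) gene names rejected explicitly so the error
# message can say *why* rather than "unparseable".
_NON_CLASS_I = re.compile(
    r"^(HLA-)?(D[RPQMO][AB]\d?|DRA|E|F|G|H|J|K|L|V|MICA|MICB|TAP\d)\b", re.IGNORECASE
)

_CANONICAL = re.compile(
    r"^(?:HLA-)?(?P<gene>[ABC])w?\*(?P<f1>\d{2,3})(?::(?P<f2>\d{2,3}))?"
    r"(?P<rest>(?::\d{2,3})*[NLSCAQ]?)$",
    re.IGNORECASE,
)
# Legacy pre-2010 concatenated form: gene letter (optionally Cw) + 4 digits,
# or 2 digits for group-level typing. "A0201" -> A*02:01, "Cw0702" -> C*07:02.
_LEGACY = re.compile(r"^(?:HLA-)?(?P<gene>[ABC])w?(?P<digits>\d{2}|\d{4})$", re.IGNORECASE)


class AlleleParseError(ValueError):
    """Raised when a string cannot be interpreted as a class I HLA allele."""


@dataclass(frozen=True, order=True)
class HLAAllele:
    """A class I HLA allele at 2- or 4-digit resolution.

    ``field1`` is the allele group; ``field2`` (optional) the protein-level
    field. Both are zero-padded strings so lexicographic order matches
    nomenclature order.
    """

    gene: str
    field1: str
    field2: str | None = None
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.gene not in CLASS_I_GENES:
            raise AlleleParseError(f"not a class I gene: {self.gene!r}")
        if not self.field1:
            raise AlleleParseError("field1 must be non-empty")

    @property
    def name(self) -> str:
        """Canonical form, e.g. ``HLA-A*02:01`` or ``HLA-B*44``."""
        if self.field2 is not None:
            return f"HLA-{self.gene}*{self.field1}:{self.field2}"
        return f"HLA-{self.gene}*{self.field1}"

    @property
    def short(self) -> str:
        """Canonical form without the HLA- prefix, e.g. ``A*02:01``."""
        return self.name[4:]

    @property
    def resolution(self) -> int:
        return 4 if self.field2 is not None else 2

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class SupertypeLabel:
    """Supertype assignment for an HLA-A or HLA-B allele: 1-2 labels, or none."""

    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.labels) > 2:
            raise ValueError("at most 2 supertype labels")

    @property
    def unclassified(self) -> bool:
        return not self.labels

    def __str__(self) -> str:
        return " ".join(self.labels) if self.labels else "unclassified"


def _load_tsv_map(filename: str) -> dict[str, tuple[str, ...]]:
    text = resources.files("hlakit.data").joinpath(filename).read_text()
    out: dict[str, tuple[str, ...]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "allele" or parts[0] == "legacy":
            continue
        out[parts[0]] = tuple(p for p in parts[1:] if p)
    return out


@lru_cache(maxsize=None)
def supertype_table() -> dict[str, tuple[str, ...]]:
    """Packaged Sidney-2008-style A/B supertype mapping (editable TSV)."""
    return _load_tsv_map("supertypes.tsv")


@lru_cache(maxsize=None)
def legacy_alias_table() -> dict[str, str]:
    """Packaged aliases for legacy designations that were renamed, not merely
    re-delimited, in the 2010 nomenclature revision."""
    return {k: v[0] for k, v in _load_tsv_map("legacy_aliases.tsv").items()}


def parse_allele(name: str) -> HLAAllele:
    """Parse an allele string in any common dialect into a canonical HLAAllele.

    Accepts "HLA-A*02:01", "A*02:01", higher-resolution names (extra fields
    and expression suffixes are stripped), and legacy concatenated forms
    ("A0201", "Cw0702"). Class II names and unrecognised strings raise
    :class:`AlleleParseError` naming the offending token.
    """
    token = name.strip()
    if not token:
        raise AlleleParseError("empty allele string")
    if _NON_CLASS_I.match(token):
        raise AlleleParseError(f"not a class I (A/B/C) allele: {token!r}")

    alias = legacy_alias_table().get(token.upper().replace("HLA-", ""))
    if alias is not None:
        return _parse_canonical(alias, raw=token)

    m = _CANONICAL.match(token)
    if m:
        return HLAAllele(
            gene=m.group("gene").upper(),
            field1=m.group("f1").zfill(2),
            field2=m.group("f2").zfill(2) if m.group("f2") else None,
            raw=token,
        )

    m = _LEGACY.match(token)
    if m:
        digits = m.group("digits")
        f1, f2 = (digits, None) if len(digits) == 2 else (digits[:2], digits[2:])
        return HLAAllele(gene=m.group("gene").upper(), field1=f1, field2=f2, raw=token)

    raise AlleleParseError(f"unparseable HLA allele string: {token!r}")


def _parse_canonical(name: str, raw: str) -> HLAAllele:
    m = _CANONICAL.match(name)
    if not m:  # malformed alias table entry
        raise AlleleParseError(f"bad alias target {name!r} for {raw!r}")
    return HLAAllele(
        gene=m.group("gene").upper(),
        field1=m.group("f1").zfill(2),
        field2=m.group("f2").zfill(2) if m.group("f2") else None,
        raw=raw,
    )


def truncate(allele: HLAAllele, digits: int) -> HLAAllele:
    """Truncate to 2-digit (allele group) or keep 4-digit resolution.

    ``digits=2`` drops field2; ``digits=4`` is the identity but errors on an
    allele that only carries 2-digit information.
    """
    if digits == 2:
        if allele.field2 is None:
            return allele
        return HLAAllele(gene=allele.gene, field1=allele.field1, raw=allele.raw)
    if digits == 4:
        if allele.field2 is None:
            raise ValueError(f"{allele.name} has no 4-digit resolution")
        return allele
    raise ValueError(f"digits must be 2 or 4, got {digits}")


def assign_supertype(
    allele: HLAAllele,
    table: dict[str, tuple[str, ...]] | None = None,
    on_hla_c: str = "raise",
) -> SupertypeLabel:
    """Assign the Sidney-2008 supertype label(s) to an HLA-A or HLA-B allele.

    Alleles absent from the table are unclassified (never silently dropped).
    HLA-C is outside the classification: ``on_hla_c="raise"`` errors,
    ``on_hla_c="na"`` returns an unclassified label.
    """
    if allele.gene == "C":
        if on_hla_c == "na":
            return SupertypeLabel()
        raise ValueError("HLA-C alleles are not covered by the supertype classification")
    if allele.field2 is None:
        raise ValueError(f"supertype assignment needs 4-digit resolution: {allele.name}")
    table = supertype_table() if table is None else table
    labels = table.get(allele.short, ())
    return SupertypeLabel(labels=tuple(labels))
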
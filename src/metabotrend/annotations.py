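"""Compound annotation: lipid shorthand parsing, chain-length and
unsaturation binning, amino-acid categories, and the annotation table.

Lipid shorthand follows the common sum-composition dialect
``CLASS C:D[;modifier]*`` (e.g. ``TAG 58:8``, ``ST 28:1;O;S``), with the
parenthesised spelling ``TG(58:8)`` accepted via a normaliser. C is the
total acyl carbon count, D the total double-bond count; sn-positions
and individual chains are out of scope. ``O-``/``P-`` prefixes mark
ether (plasmanyl/plasmenyl) species; any ``O``-family suffix modifier
marks oxygenation.

Chemical taxonomy (superclass/subclass) is assigned by a packaged
rule-plus-lookup classifier: lipids through the shorthand grammar,
everything else through a name table shipped with (and extensible
beyond) the synthetic compound universe. No network service is called.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "LipidDescriptor",
    "CompoundAnnotation",
    "ChainLengthBin",
    "UnsaturationBin",
    "LipidParseError",
    "UnknownLipidClassError",
    "UnsupportedLipidClassError",
    "parse_lipid_shorthand",
    "chain_length_bin",
    "unsaturation_bin",
    "classify_amino_acid",
    "annotate_compound",
    "build_annotation_table",
    "read_annotation_table",
    "write_annotation_table",
]

log = logging.getLogger(__name__)


class LipidParseError(ValueError):
    """Shorthand string does not match the CLASS C:D[;mod]* grammar."""


class UnknownLipidClassError(LipidParseError):
    """Class code is syntactically valid but not in the registry."""


class UnsupportedLipidClassError(ValueError):
    """Binning requested for a class without configured boundaries."""


# class code -> (long subclass name, bears acyl chains). Aliases map common
# alternative spellings onto the canonical code.
LIPID_CLASS_REGISTRY: dict[str, tuple[str, bool]] = {
    "TAG": ("triacylglycerols", True),
    "DAG": ("diacylglycerols", True),
    "MAG": ("monoacylglycerols", True),
    "PC": ("phosphatidylcholines", True),
    "LPC": ("lysophosphatidylcholines", True),
    "PE": ("phosphatidylethanolamines", True),
    "LPE": ("lysophosphatidylethanolamines", True),
    "PS": ("phosphatidylserines", True),
    "PI": ("phosphatidylinositols", True),
    "PG": ("phosphatidylglycerols", True),
    "SM": ("sphingomyelins", True),
    "Cer": ("ceramides", True),
    "HexCer": ("hexosylceramides", True),
    "CE": ("cholesteryl esters", True),
    "FA": ("free fatty acids", True),
    "CAR": ("acylcarnitines", True),
    "ST": ("sterols", False),
}

LIPID_CLASS_ALIASES: dict[str, str] = {
    "TG": "TAG",
    "DG": "DAG",
    "MG": "MAG",
    "LysoPC": "LPC",
    "LysoPE": "LPE",
    "CER": "Cer",
    "HEXCER": "HexCer",
    "CHE": "CE",
    "FFA": "FA",
    "AC": "CAR",
}


@dataclass(frozen=True)
class LipidDescriptor:
    """Sum-composition lipid descriptor parsed from shorthand."""

    lipid_class: str
    total_carbons: int
    total_double_bonds: int
    is_ether: bool = False
    is_oxidized: bool = False
    modifiers: tuple[str, ...] = ()

    # A zero-carbon descriptor for an acyl-bearing class is syntactically
    # valid ("TAG 0:0" parses) but fails the binning precondition.

    @property
    def subclass(self) -> str:
        """Subclass label; oxidized species form derived ox_ subclasses."""
        return f"ox_{self.lipid_class}" if self.is_oxidized else self.lipid_class

    def serialize(self) -> str:
        """Canonical shorthand: CLASS [O-]C:D[;mod]*."""
        ether = "O-" if self.is_ether else ""
        mods = "".join(f";{m}" for m in self.modifiers)
        return f"{self.lipid_class} {ether}{self.total_carbons}:{self.total_double_bonds}{mods}"


_SHORTHAND_RE = re.compile(
    r"""^(?P<cls>[A-Za-z][A-Za-z0-9]*)        # class code
        (?:\s+|\()\s*                          # separator: space or '('
        (?P<ether>[OP]-)?
        (?P<c>\d+):(?P<d>\d+)
        (?P<mods>(?:;[A-Za-z0-9]+)*)
        \)?\s*$""",
    re.VERBOSE,
)


def _normalize_text(s: str) -> str:
    s = unicodedata.normalize("NFKC", s)
    # unify the dash/space zoo that arrives from copy-pasted documents
    for dash in "‐‑‒–—−":
        s = s.replace(dash, "-")
    return s.replace(" ", " ").strip()


def parse_lipid_shorthand(name: str) -> LipidDescriptor:
    """Parse sum-composition shorthand into a :class:`LipidDescriptor`.

    Raises :class:`LipidParseError` naming the offending token for
    malformed strings and :class:`UnknownLipidClassError` for class codes
    outside the registry (never guesses).

    >>> parse_lipid_shorthand("ST 28:1;O;S").modifiers
    ('O', 'S')
    """
    norm = _normalize_text(name)
    m = _SHORTHAND_RE.match(norm)
    if not m:
        token = norm.split()[0] if norm.split() else norm
        raise LipidParseError(
            f"cannot parse lipid shorthand {name!r}: offending token {token!r}")
    code = m.group("cls")
    code = LIPID_CLASS_ALIASES.get(code, code)
    if code not in LIPID_CLASS_REGISTRY:
        raise UnknownLipidClassError(f"unknown lipid class code {m.group('cls')!r}")
    mods = tuple(t for t in m.group("mods").split(";") if t)
    oxidized = any(t == "O" or t.startswith("O") and t[1:].isdigit() or t == "OH"
                   for t in mods)
    return LipidDescriptor(
        lipid_class=code,
        total_carbons=int(m.group("c")),
        total_double_bonds=int(m.group("d")),
        is_ether=m.group("ether") is not None,
        is_oxidized=oxidized,
        modifiers=mods,
    )


class ChainLengthBin(str, Enum):
    SHORT = "short"
    LONG = "long"
    VERY_LONG = "very_long"


class UnsaturationBin(str, Enum):
    SATURATED = "saturated_0_2"
    INTERMEDIATE = "intermediate"
    PUFA = "pufa_enriched"


# (short_below, very_long_from): short < a, long a..b-1, very_long >= b.
# TAG: very-long means total carbons > 57; classic long-chain 48-56 (totals
# of 57 are folded into the long band so the bins partition the integers).
# DAG and PC share boundaries: very-long > 38, long 33-38, short < 33.
DEFAULT_CHAIN_BOUNDS: dict[str, tuple[int, int]] = {
    "TAG": (48, 58),
    "DAG": (33, 39),
    "PC": (33, 39),
}

# (intermediate_from, pufa_from): saturated below a, intermediate a..b-1,
# PUFA-enriched >= b. A PUFA acyl chain carries >= 3 double bonds; the
# PUFA-enriched band is the complement of the printed 0-2 and 3-5 (TAG)
# or 3-4 (DAG/PC) total-double-bond bands.
DEFAULT_UNSAT_BOUNDS: dict[str, tuple[int, int]] = {
    "TAG": (3, 6),
    "DAG": (3, 5),
    "PC": (3, 5),
}


def chain_length_bin(d: LipidDescriptor,
                     bounds: Mapping[str, tuple[int, int]] | None = None) -> ChainLengthBin:
    """Total-carbon bin (short / long / very_long) for a lipid descriptor."""
    table = DEFAULT_CHAIN_BOUNDS if bounds is None else bounds
    if d.lipid_class not in table:
        raise UnsupportedLipidClassError(
            f"no chain-length boundaries configured for class {d.lipid_class!r}")
    if d.total_carbons <= 0:
        raise ValueError("chain-length binning needs total_carbons > 0")
    lo, hi = table[d.lipid_class]
    if d.total_carbons < lo:
        return ChainLengthBin.SHORT
    if d.total_carbons < hi:
        return ChainLengthBin.LONG
    return ChainLengthBin.VERY_LONG


def unsaturation_bin(d: LipidDescriptor,
                     bounds: Mapping[str, tuple[int, int]] | None = None) -> UnsaturationBin:
    """Total-double-bond bin (saturated / intermediate / PUFA-enriched)."""
    table = DEFAULT_UNSAT_BOUNDS if bounds is None else bounds
    if d.lipid_class not in table:
        raise UnsupportedLipidClassError(
            f"no unsaturation boundaries configured for class {d.lipid_class!r}")
    if d.total_carbons <= 0:
        raise ValueError("unsaturation binning needs total_carbons > 0")
    lo, hi = table[d.lipid_class]
    if d.total_double_bonds < lo:
        return UnsaturationBin.SATURATED
    if d.total_double_bonds < hi:
        return UnsaturationBin.INTERMEDIATE
    return UnsaturationBin.PUFA


# ---------------------------------------------------------------------------
# Amino-acid categories
# ---------------------------------------------------------------------------

PROTEINOGENIC: frozenset[str] = frozenset({
    "alanine", "arginine", "asparagine", "aspartic acid", "cysteine",
    "glutamic acid", "glutamine", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "phenylalanine", "proline",
    "serine", "threonine", "tryptophan", "tyrosine", "valine",
})

# residue (acyl) prefixes used in dipeptide nomenclature
_RESIDUE_PREFIXES: tuple[str, ...] = (
    "glycyl", "alanyl", "arginyl", "asparaginyl", "aspartyl", "cysteinyl",
    "glutamyl", "glutaminyl", "histidyl", "isoleucyl", "leucyl", "lysyl",
    "methionyl", "phenylalanyl", "prolyl", "seryl", "threonyl",
    "tryptophyl", "tyrosyl", "valyl",
)

DERIVATIVE_MARKERS: tuple[str, ...] = (
    "acetyl", "methyl", "dimethyl", "trimethyl", "hydroxy", "formyl",
    "sulfoxide", "carboxy", "phospho", "glutaryl",
)

KNOWN_NON_PROTEINOGENIC: frozenset[str] = frozenset({
    "taurine", "ornithine", "citrulline", "beta-alanine",
    "gamma-aminobutyric acid", "sarcosine", "homoserine", "homocysteine",
    "kynurenine", "creatine", "betaine", "aminoadipic acid",
    "n-omega-acetylhistamine", "5-aminovaleric acid", "allothreonine",
})

AA_CATEGORIES = ("dipeptide", "proteinogenic", "non_proteinogenic", "derivative")


def classify_amino_acid(name: str,
                        proteinogenic: frozenset[str] = PROTEINOGENIC,
                        non_proteinogenic: frozenset[str] = KNOWN_NON_PROTEINOGENIC,
                        derivative_markers: Iterable[str] = DERIVATIVE_MARKERS) -> str:
    """Assign an amino-acid-like compound to one of four categories.

    Dipeptides are recognised by two-residue naming (residue-yl prefix
    followed by a proteinogenic name); derivatives by a proteinogenic
    root plus a modification marker (methylated, acetylated, hydroxylated,
    sulfoxide, ...). Unmatched names default to non-proteinogenic and are
    logged. Total function: never raises on free text.
    """
    s = _normalize_text(name).lower()
    if s in proteinogenic:
        return "proteinogenic"
    for prefix in _RESIDUE_PREFIXES:
        if s.startswith(prefix):
            rest = s[len(prefix):].lstrip("- ")
            if rest in proteinogenic:
                return "dipeptide"
    if s in non_proteinogenic:
        return "non_proteinogenic"
    has_root = any(aa in s for aa in proteinogenic)
    has_marker = any(m in s for m in derivative_markers)
    if has_root and has_marker:
        return "derivative"
    if has_root:
        # e.g. "allo-isoleucine": amino-acid root without a standard marker
        return "non_proteinogenic"
    log.info("amino-acid category fallback for %r -> non_proteinogenic", name)
    return "non_proteinogenic"


# ---------------------------------------------------------------------------
# Compound annotation
# ---------------------------------------------------------------------------

SUPERCLASSES = ("lipid", "amino acid/peptide", "carbohydrate", "organic acid",
                "organoheterocyclic", "nucleotide", "other")


@dataclass(frozen=True)
class CompoundAnnotation:
    """One compound's chemical classification."""

    compound_id: str
    name: str
    superclass: str
    subclass: str
    lipid: LipidDescriptor | None = None
    aa_category: str | None = None


def annotate_compound(compound_id: str, name: str,
                      lookup: Mapping[str, tuple[str, str]] | None = None,
                      shorthand: str | None = None) -> CompoundAnnotation:
    """Classify one compound by rules (lipids) plus name lookup (the rest).

    ``lookup`` maps lowercase names to (superclass, subclass);
    ``shorthand`` overrides name-based lipid parsing when the annotation
    table carries an explicit shorthand column.
    """
    lookup = lookup or {}
    descriptor: LipidDescriptor | None = None
    for candidate in (shorthand, name):
        if not candidate:
            continue
        try:
            descriptor = parse_lipid_shorthand(candidate)
            break
        except LipidParseError:
            continue
    if descriptor is not None:
        return CompoundAnnotation(compound_id, name, "lipid",
                                  descriptor.subclass, lipid=descriptor)
    key = _normalize_text(name).lower()
    if key in lookup:
        superclass, subclass = lookup[key]
        aa = classify_amino_acid(name) if superclass == "amino acid/peptide" else None
        return CompoundAnnotation(compound_id, name, superclass, subclass,
                                  aa_category=aa)
    log.info("no classification rule for %r; assigning other/unclassified", name)
    return CompoundAnnotation(compound_id, name, "other", "unclassified")


ANNOTATION_COLUMNS = ["compound_id", "name", "superclass", "subclass",
                      "lipid_shorthand", "aa_category"]


def build_annotation_table(compounds: Iterable[tuple[str, str]],
                           lookup: Mapping[str, tuple[str, str]] | None = None) -> pd.DataFrame:
    """Annotate (compound_id, name) pairs into the standard table."""
    rows = []
    for cid, name in compounds:
        a = annotate_compound(cid, name, lookup=lookup)
        rows.append({
            "compound_id": a.compound_id,
            "name": a.name,
            "superclass": a.superclass,
            "subclass": a.subclass,
            "lipid_shorthand": a.lipid.serialize() if a.lipid else "",
            "aa_category": a.aa_category or "",
        })
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def read_annotation_table(path) -> pd.DataFrame:
    """Read an annotation TSV, normalising unicode dashes in names."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("compound_id", "name", "superclass", "subclass")
               if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    df["name"] = df["name"].map(_normalize_text)
    for col in ("lipid_shorthand", "aa_category"):
        if col not in df.columns:
            df[col] = ""
    return df[ANNOTATION_COLUMNS]


def write_annotation_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def descriptors_from_table(annotations: pd.DataFrame) -> dict[str, LipidDescriptor]:
    """compound_id -> parsed descriptor for rows with a lipid shorthand."""
    out: dict[str, LipidDescriptor] = {}
    for cid, sh in zip(annotations["compound_id"], annotations["lipid_shorthand"]):
        if sh:
            try:
                out[cid] = parse_lipid_shorthand(sh)
            except LipidParseError:
                log.warning("unparseable shorthand %r for %s", sh, cid)
    return out
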
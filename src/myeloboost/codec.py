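"""Variant annotation parsing and the 14-feature numeric encoding.

A myeloid-panel variant arrives as one row of a tab-separated annotation
export (chromosome, position, gene, HGVS coding/protein change, allele
frequencies, coverage, effect class, optional expert label).  The encoder
turns each row into the fixed 14-dimensional numeric vector consumed by
the gradient-boosted classifier:

``chr POS TypeBin Exon Freq MAFbin Coverage Protbin aarefbin aamutbin
aarefChemical aamutChemicalVal Grantham varEffectBin`` (+ ``isMut`` label).

Categorical codes:

* ``TypeBin``: SNV = 0, MNV = 1, INDEL = 2
* ``Protbin``: intronic/splice ``p.?`` = 0, synonymous ``p.(=)`` = 1,
  amino-acid change = 2
* ``varEffectBin``: synonymous = 0, missense = 1, nonsense = 2,
  frameshift = 3, unknown = -1
* ``MAFbin``: the minor allele frequency, or -1 when the variant has no
  population-frequency entry (a strong pathogenicity cue)
* ``Grantham``: physico-chemical substitution distance in [5, 215],
  0 for an identical pair, -1 when no single-residue substitution applies

Sentinel policy: when a record carries no residue on one side (intronic,
synonymous, frameshift/stop/indel outcomes) the ordinal for that side is
0, its polarity code 0.0, and Grantham -1.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .aatables import (
    AA_INDEX_MUT,
    AA_INDEX_REF,
    CHEMICAL_VALUE,
    GRANTHAM,
    NON_RESIDUE_TOKENS,
    normalize_residue,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CodecError",
    "ParseError",
    "ConfigError",
    "VariantRecord",
    "ColumnDialect",
    "FEATURE_COLUMNS",
    "LABEL_COLUMN",
    "parse_protein_change",
    "encode_chromosome",
    "encode_variant_type",
    "encode_maf",
    "encode_aa_index",
    "chemical_value",
    "grantham_distance",
    "encode_variant_effect",
    "build_feature_vector",
    "build_feature_table",
    "load_annotation_table",
    "write_feature_table",
]


class CodecError(ValueError):
    """Base class for encoding failures."""


class ParseError(CodecError):
    """An HGVS or field value that could not be interpreted."""


class ConfigError(CodecError):
    """The reader configuration does not match the input table."""


FEATURE_COLUMNS: tuple[str, ...] = (
    "chr", "POS", "TypeBin", "Exon", "Freq", "MAFbin", "Coverage",
    "Protbin", "aarefbin", "aamutbin", "aarefChemical", "aamutChemicalVal",
    "Grantham", "varEffectBin",
)
LABEL_COLUMN = "isMut"

VARIANT_TYPES = ("SNV", "MNV", "INDEL")
EFFECT_CODES: Mapping[str, int] = {
    "synonymous": 0, "missense": 1, "nonsense": 2, "frameshift": 3,
    "unknown": -1,
}


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One annotated variant, prior to numeric encoding."""

    chrom: str
    pos: int
    gene: str
    variant_type: str
    exon: int
    coding: str
    protein: str
    vaf: float
    maf: Optional[float]
    coverage: int
    effect: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.variant_type.upper() not in VARIANT_TYPES:
            raise CodecError(f"unknown variant type {self.variant_type!r}")
        if self.exon < 0:
            raise CodecError(f"exon must be >= 0, got {self.exon}")
        if self.coverage < 0:
            raise CodecError(f"coverage must be >= 0, got {self.coverage}")
        if not 0.0 <= self.vaf <= 1.0:
            raise CodecError(f"VAF out of [0, 1]: {self.vaf}")
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise CodecError(f"MAF out of [0, 1]: {self.maf}")
        if self.label is not None and self.label not in (0, 1):
            raise CodecError(f"label must be 0/1, got {self.label}")


@dataclasses.dataclass(frozen=True)
class ColumnDialect:
    """How to read an annotation table.

    ``columns`` maps VariantRecord field names to column headers in the
    file; ``vaf_unit`` declares whether the frequency columns are
    fractions in [0, 1] or percentages in [0, 100].
    """

    columns: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: {f.name: f.name for f in
                                 dataclasses.fields(VariantRecord)})
    vaf_unit: str = "fraction"

    def __post_init__(self) -> None:
        if self.vaf_unit not in ("fraction", "percent"):
            raise ConfigError(f"vaf_unit must be fraction|percent, "
                              f"got {self.vaf_unit!r}")


# --- HGVS p. parsing -------------------------------------------------------

_AA = r"(?:[A-Z][a-z]{2}|[A-Z*])"
_RE_SYNONYMOUS = re.compile(rf"^({_AA})?(\d+)?=$")
_RE_SUB = re.compile(
    rf"^({_AA})(\d+)((?:{_AA})?fs.*|del(?:ins.*)?|dup.*|{_AA})$")
_RE_RANGE = re.compile(rf"^({_AA})(\d+)_({_AA})(\d+)(del(?:ins.*)?|dup|fs.*)$")


def _norm_mut_token(raw: str) -> str:
    """Collapse a raw mutant-side token to a residue or outcome class."""
    if re.match(rf"^(?:{_AA})?fs", raw):
        return "fs"
    if raw.startswith("delins"):
        # substitution of a run of residues: treated as the deletion class
        return "del"
    if raw.startswith("del"):
        return "del"
    if raw.startswith("dup"):
        return "dup"
    if raw in ("Ter", "*", "X"):
        return "Ter"
    return normalize_residue(raw)


def parse_protein_change(protein: str) -> tuple[str, str, int]:
    """Classify an HGVS ``p.`` string.

    Returns ``(ref_token, mut_token, prot_class)`` where ``prot_class``
    is 0 for intronic/splice (``p.?``), 1 for synonymous (``p.(=)`` or
    ``p.Xaa123=``), 2 for an amino-acid change.  Tokens that do not apply
    are the sentinel ``"NA"``.
    """
    if not isinstance(protein, str) or not protein.strip():
        raise ParseError("empty protein change")
    body = protein.strip()
    if not body.startswith("p."):
        raise ParseError(f"not an HGVS p. string: {protein!r}")
    body = body[2:].strip()
    if body.startswith("(") and body.endswith(")"):
        body = body[1:-1]
    if body == "?":
        return ("NA", "NA", 0)
    m = _RE_SYNONYMOUS.match(body)
    if m:
        ref = m.group(1)
        if ref is None:
            return ("NA", "NA", 1)
        try:
            return (normalize_residue(ref), "NA", 1)
        except ValueError as exc:
            raise ParseError(f"bad residue in {protein!r}") from exc
    m = _RE_RANGE.match(body)
    if m:
        try:
            ref = normalize_residue(m.group(1))
            normalize_residue(m.group(3))
        except ValueError as exc:
            raise ParseError(f"bad residue in {protein!r}") from exc
        return (ref, _norm_mut_token(m.group(5)), 2)
    m = _RE_SUB.match(body)
    if m:
        try:
            ref = normalize_residue(m.group(1))
            mut = _norm_mut_token(m.group(3))
        except ValueError as exc:
            raise ParseError(f"bad residue in {protein!r}") from exc
        return (ref, mut, 2)
    raise ParseError(f"unparseable protein change: {protein!r}")


# --- scalar encoders -------------------------------------------------------

def encode_chromosome(chrom: str) -> int:
    """Numeric chromosome code: 1-22 as printed, X -> 23, Y -> 24."""
    tok = str(chrom).strip()
    if tok.lower().startswith("chr"):
        tok = tok[3:]
    if tok.upper() == "X":
        return 23
    if tok.upper() == "Y":
        return 24
    try:
        value = int(tok)
    except ValueError:
        raise CodecError(f"unknown chromosome {chrom!r}") from None
    if not 1 <= value <= 22:
        raise CodecError(f"chromosome out of range: {chrom!r}")
    return value


def encode_variant_type(token: str) -> int:
    try:
        return VARIANT_TYPES.index(str(token).strip().upper())
    except ValueError:
        raise CodecError(f"unknown variant type {token!r}") from None


def encode_maf(maf: Optional[float]) -> float:
    """The MAF value when present, the sentinel -1.0 otherwise."""
    if maf is None or (isinstance(maf, float) and np.isnan(maf)):
        return -1.0
    value = float(maf)
    if not 0.0 <= value <= 1.0:
        raise CodecError(f"MAF out of [0, 1]: {maf}")
    return value


def encode_aa_index(token: str, dialect: str = "ref") -> int:
    """Ordinal residue code (Arg = 1 ... Cys = 21; mut side adds 22)."""
    if dialect not in ("ref", "mut"):
        raise CodecError(f"dialect must be ref|mut, got {dialect!r}")
    tok = str(token).strip()
    if tok in NON_RESIDUE_TOKENS:
        if dialect == "mut":
            return AA_INDEX_MUT[tok]
        raise CodecError(f"{tok!r} is not valid on the reference side")
    table = AA_INDEX_MUT if dialect == "mut" else AA_INDEX_REF
    return table[normalize_residue(tok)]


def chemical_value(token: str) -> float:
    """Side-chain polarity code; 0.0 for every non-residue token."""
    tok = str(token).strip()
    if tok in CHEMICAL_VALUE:
        return CHEMICAL_VALUE[tok]
    canon = normalize_residue(tok)  # raises on garbage
    try:
        return CHEMICAL_VALUE[canon]
    except KeyError:
        raise CodecError(f"no polarity code for {token!r}") from None


def grantham_distance(aa1: str, aa2: str) -> int:
    """Grantham distance between two residues.

    0 for an identical pair, the published value (in [5, 215]) for a true
    substitution, and -1 when either token is not one of the 20 standard
    residues (frameshift/stop/indel outcomes and the NA sentinel).
    """
    tokens = []
    for raw in (aa1, aa2):
        tok = str(raw).strip()
        if tok == "NA" or tok in NON_RESIDUE_TOKENS:
            return -1
        tokens.append(normalize_residue(tok))
    pair = (tokens[0], tokens[1])
    if pair not in GRANTHAM:
        return -1  # selenocysteine: a residue, but outside the 20x20 table
    return GRANTHAM[pair]


def encode_variant_effect(token: str) -> int:
    tok = str(token).strip().lower()
    if tok not in EFFECT_CODES:
        raise CodecError(f"unknown variant effect {token!r}")
    return EFFECT_CODES[tok]


# --- record -> vector ------------------------------------------------------

def build_feature_vector(record: VariantRecord,
                         binarize_coverage: Optional[int] = None,
                         ) -> dict[str, float]:
    """Encode one record into the named 14-feature mapping (+ label).

    ``binarize_coverage``, when given, replaces the raw read depth by a
    0/1 indicator of depth above that threshold.
    """
    try:
        ref_tok, mut_tok, prot_class = parse_protein_change(record.protein)
        if prot_class == 2:
            aaref = encode_aa_index(ref_tok, "ref")
            aamut = encode_aa_index(mut_tok, "mut")
            aaref_chem = chemical_value(ref_tok)
            aamut_chem = chemical_value(mut_tok)
            grantham = grantham_distance(ref_tok, mut_tok)
        else:
            aamut, aamut_chem, grantham = 0, 0.0, -1
            if ref_tok != "NA":
                aaref = encode_aa_index(ref_tok, "ref")
                aaref_chem = chemical_value(ref_tok)
            else:
                aaref, aaref_chem = 0, 0.0
        coverage: float = float(record.coverage)
        if binarize_coverage is not None:
            coverage = 1.0 if record.coverage > binarize_coverage else 0.0
        vector = {
            "chr": float(encode_chromosome(record.chrom)),
            "POS": float(record.pos),
            "TypeBin": float(encode_variant_type(record.variant_type)),
            "Exon": float(record.exon),
            "Freq": float(record.vaf),
            "MAFbin": encode_maf(record.maf),
            "Coverage": coverage,
            "Protbin": float(prot_class),
            "aarefbin": float(aaref),
            "aamutbin": float(aamut),
            "aarefChemical": aaref_chem,
            "aamutChemicalVal": aamut_chem,
            "Grantham": float(grantham),
            "varEffectBin": float(encode_variant_effect(record.effect)),
        }
        if record.label is not None:
            vector[LABEL_COLUMN] = float(record.label)
        return vector
    except CodecError as exc:
        raise CodecError(
            f"{record.gene} {record.chrom}:{record.pos} "
            f"{record.coding}/{record.protein}: {exc}") from exc


def build_feature_table(records: Sequence[VariantRecord],
                        binarize_coverage: Optional[int] = None,
                        ) -> pd.DataFrame:
    """Encode a record list into a feature matrix, preserving row order.

    Any failing rows are collected and reported together in a single
    ``CodecError`` listing the offending row numbers.
    """
    if len(records) == 0:
        raise CodecError("no records to encode")
    rows, failures = [], []
    for i, record in enumerate(records):
        try:
            rows.append(build_feature_vector(record, binarize_coverage))
        except CodecError as exc:
            failures.append((i, str(exc)))
    if failures:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in failures[:20])
        raise CodecError(f"{len(failures)} row(s) failed to encode: {detail}")
    table = pd.DataFrame(rows)
    for name in FEATURE_COLUMNS:
        summary = table[name]
        logger.debug("feature %s: min=%s max=%s", name,
                     summary.min(), summary.max())
    return table


# --- I/O -------------------------------------------------------------------

_MANDATORY = ("chrom", "pos", "gene", "variant_type", "exon", "coding",
              "protein", "vaf", "coverage", "effect")


def load_annotation_table(path: str | Path,
                          dialect: Optional[ColumnDialect] = None,
                          ) -> list[VariantRecord]:
    """Read a tab-separated annotation table into records.

    Rows whose values cannot be coerced raise a ``CodecError`` naming the
    1-based data line numbers; a missing mandatory column raises a
    ``ConfigError`` naming the column.
    """
    dialect = dialect or ColumnDialect()
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field in _MANDATORY:
        column = dialect.columns.get(field, field)
        if column not in frame.columns:
            raise ConfigError(f"missing mandatory column {column!r} "
                              f"(record field {field!r})")
    if frame.empty:
        logger.warning("annotation table %s has no data rows", path)
        return []

    scale = 100.0 if dialect.vaf_unit == "percent" else 1.0
    maf_col = dialect.columns.get("maf", "maf")
    label_col = dialect.columns.get("label", "label")
    records, failures = [], []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        data = dict(zip(frame.columns, row))
        try:
            maf_raw = data.get(maf_col, "")
            label_raw = data.get(label_col, "")
            records.append(VariantRecord(
                chrom=data[dialect.columns.get("chrom", "chrom")],
                pos=int(data[dialect.columns.get("pos", "pos")]),
                gene=data[dialect.columns.get("gene", "gene")],
                variant_type=data[dialect.columns.get("variant_type",
                                                      "variant_type")],
                exon=int(data[dialect.columns.get("exon", "exon")]),
                coding=data[dialect.columns.get("coding", "coding")],
                protein=data[dialect.columns.get("protein", "protein")],
                vaf=float(data[dialect.columns.get("vaf", "vaf")]) / scale,
                maf=None if maf_raw == "" else float(maf_raw) / scale,
                coverage=int(data[dialect.columns.get("coverage",
                                                      "coverage")]),
                effect=data[dialect.columns.get("effect", "effect")],
                label=None if label_raw == "" else int(label_raw),
            ))
        except (ValueError, KeyError, CodecError) as exc:
            failures.append((i, str(exc)))
    if failures:
        detail = "; ".join(f"line {i}: {msg}" for i, msg in failures[:20])
        raise CodecError(f"{len(failures)} row(s) failed to parse: {detail}")
    return records


def write_feature_table(table: pd.DataFrame, path: str | Path,
                        sep: str = "\t") -> None:
    """Write an encoded feature table with the canonical column order."""
    columns = [c for c in (*FEATURE_COLUMNS, LABEL_COLUMN)
               if c in table.columns]
    table.loc[:, columns].to_csv(path, sep=sep, index=False)
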
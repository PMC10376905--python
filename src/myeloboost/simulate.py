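"""Seeded synthetic myeloid-panel cohorts.

The study cohort (15,977 expert-labeled variants from a 24-gene myeloid
amplicon panel) is not public, so every pipeline stage is exercised on
synthetic cohorts that reproduce its coarse statistical structure:

* the exact variant-type composition (13,221 SNV / 73 MNV / 2,683 INDEL
  by default) and class balance (14,957 benign / 1,020 pathogenic);
* a minor allele frequency that is the dominant class signal: benign
  variants usually carry a population-frequency entry while pathogenic
  somatic variants usually have none (encoded -1), mirroring how absence
  from population databases flags candidate drivers;
* variant allele fractions with mass on both sides of the 5% wet-lab
  validation threshold - germline-like peaks near 0.5/1.0 for benign
  rows, a broad subclonal-to-clonal spread for pathogenic rows;
* read depth floored at the 300x panel QC bound;
* effect classes enriched for missense/nonsense/frameshift outcomes in
  pathogenic rows and synonymous/intronic outcomes in benign rows, with
  missense substitutions skewed toward higher Grantham distances when
  pathogenic;
* HGVS-style protein strings consumable by the variant codec.

Cohorts are built from a catalogue of *distinct* variants that recur
across patients, as they do in a diagnostic panel (the same hotspot or
polymorphism is observed in many runs).  Variant-level attributes
(position, protein change, population MAF, typical allele fraction) are
fixed per distinct variant; each observation adds per-patient VAF and
coverage noise.  Population MAF is therefore a per-variant constant -
exactly the structure that makes it the classifier's dominant feature.

The feature->label mapping is intentionally probabilistic: a configurable
fraction of distinct variants ("label noise") draws its features from
the opposite class-conditional distribution while keeping its label, so
class counts stay exact but classes are not perfectly separable.

Gene coordinates are dummy per-gene intervals on the gene's chromosome;
no real transcript positions are claimed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .aatables import GRANTHAM
from .codec import VariantRecord

__all__ = ["CohortConfig", "GENE_PANEL", "generate_cohort",
           "generate_toy_run", "write_tsv"]

# 24-gene myeloid panel: symbol -> (chromosome, dummy interval start).
# Intervals are 200 kb wide, synthetic stand-ins for the amplicon loci.
GENE_PANEL: dict[str, tuple[str, int]] = {
    "ASXL1": ("20", 31_000_000), "CALR": ("19", 13_000_000),
    "CBL": ("11", 119_000_000), "CEBPA": ("19", 33_000_000),
    "CXCR4": ("2", 136_000_000), "DNMT3A": ("2", 25_000_000),
    "EZH2": ("7", 148_000_000), "FLT3": ("13", 28_000_000),
    "GATA2": ("3", 128_000_000), "IDH1": ("2", 208_000_000),
    "IDH2": ("15", 90_000_000), "JAK2": ("9", 5_000_000),
    "KIT": ("4", 55_000_000), "KRAS": ("12", 25_000_000),
    "MPL": ("1", 43_000_000), "NPM1": ("5", 170_000_000),
    "NRAS": ("1", 114_000_000), "PTEN": ("10", 89_000_000),
    "RUNX1": ("21", 36_000_000), "SF3B1": ("2", 198_000_000),
    "SRSF2": ("17", 74_000_000), "TET2": ("4", 106_000_000),
    "TP53": ("17", 7_000_000), "WT1": ("11", 32_000_000),
}
_GENE_SPAN = 200_000
_AMPLICONS_PER_GENE = 8

_RESIDUES = tuple(sorted({a for a, _ in GRANTHAM}))


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Knobs of the cohort generator (defaults = study-scale cohort)."""

    n_snv: int = 13_221
    n_mnv: int = 73
    n_indel: int = 2_683
    n_benign: int = 14_957
    n_pathogenic: int = 1_020
    genes: tuple[str, ...] = tuple(GENE_PANEL)
    maf_missing_rate_pathogenic: float = 0.60
    maf_missing_rate_benign: float = 0.03
    coverage_floor: int = 300
    coverage_mean: int = 1_500
    recurrence_benign: float = 12.0
    recurrence_pathogenic: float = 8.0
    label_noise: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_snv", "n_mnv", "n_indel", "n_benign",
                     "n_pathogenic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("maf_missing_rate_pathogenic",
                     "maf_missing_rate_benign", "label_noise"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.recurrence_benign < 1 or self.recurrence_pathogenic < 1:
            raise ValueError("recurrence must be >= 1")
        if not self.genes:
            raise ValueError("gene panel must be non-empty")
        if self.n_snv + self.n_mnv + self.n_indel != \
                self.n_benign + self.n_pathogenic:
            raise ValueError(
                "per-type counts must sum to per-class counts "
                f"({self.n_snv + self.n_mnv + self.n_indel} vs "
                f"{self.n_benign + self.n_pathogenic})")

    @property
    def total(self) -> int:
        return self.n_snv + self.n_mnv + self.n_indel


def _grantham_weighted_mut(rng: np.random.Generator, ref: str,
                           pathogenic: bool) -> str:
    """Pick a substitution partner, skewed to high (pathogenic) or low
    (benign) Grantham distance."""
    others = [aa for aa in _RESIDUES if aa != ref]
    dist = np.array([GRANTHAM[(ref, aa)] for aa in others], dtype=float)
    sign = 1.0 if pathogenic else -1.0
    weights = np.exp(sign * dist / 60.0)
    weights /= weights.sum()
    return others[rng.choice(len(others), p=weights)]


def _effect_for(rng: np.random.Generator, vtype: str,
                pathogenic: bool) -> str:
    """Effect class conditional on variant type and class.

    "intronic" is an internal alias that becomes effect "unknown" with a
    p.? protein; "inframe" becomes effect "unknown" with a p.Xdel.
    """
    if vtype == "SNV":
        if pathogenic:
            choices = (("missense", 0.70), ("nonsense", 0.25),
                       ("intronic", 0.05))
        else:
            choices = (("synonymous", 0.40), ("missense", 0.30),
                       ("intronic", 0.28), ("nonsense", 0.02))
    elif vtype == "MNV":
        choices = (("missense", 0.90), ("intronic", 0.10))
    else:  # INDEL
        if pathogenic:
            choices = (("frameshift", 0.85), ("inframe", 0.15))
        else:
            choices = (("frameshift", 0.25), ("inframe", 0.35),
                       ("intronic", 0.40))
    names, probs = zip(*choices)
    return names[rng.choice(len(names), p=np.array(probs))]


@dataclasses.dataclass(frozen=True)
class _VariantProfile:
    """Fixed attributes of one distinct variant in the catalogue."""

    gene: str
    chrom: str
    pos: int
    exon: int
    coding: str
    protein: str
    effect: str
    maf: Optional[float]
    vaf_mean: float
    vaf_sd: float
    cov_mean: float


def _make_profile(rng: np.random.Generator, cfg: CohortConfig, vtype: str,
                  pathogenic: bool) -> _VariantProfile:
    gene = cfg.genes[rng.integers(len(cfg.genes))]
    chrom, start = GENE_PANEL.get(gene, ("1", 1_000_000))
    # variants sit on the panel's amplicon anchors: a handful of target
    # loci per gene, shared by many distinct variants
    pos = start + int(rng.integers(0, _AMPLICONS_PER_GENE)) * (
        _GENE_SPAN // _AMPLICONS_PER_GENE)

    effect_kind = _effect_for(rng, vtype, pathogenic)
    aa_pos = int(rng.integers(1, 900))
    if effect_kind == "intronic":
        exon = 0
        protein = "p.?"
        effect = "unknown"
    else:
        exon = int(rng.integers(1, 13))
        ref = _RESIDUES[rng.integers(len(_RESIDUES))]
        if effect_kind == "synonymous":
            protein = f"p.{ref}{aa_pos}="
            effect = "synonymous"
        elif effect_kind == "missense":
            mut = _grantham_weighted_mut(rng, ref, pathogenic)
            protein = f"p.{ref}{aa_pos}{mut}"
            effect = "missense"
        elif effect_kind == "nonsense":
            protein = f"p.{ref}{aa_pos}Ter"
            effect = "nonsense"
        elif effect_kind == "frameshift":
            mut = _RESIDUES[rng.integers(len(_RESIDUES))]
            protein = f"p.{ref}{aa_pos}{mut}fsTer{int(rng.integers(2, 60))}"
            effect = "frameshift"
        else:  # inframe deletion
            protein = f"p.{ref}{aa_pos}del"
            effect = "unknown"

    # Population MAF is a property of the distinct variant: usually
    # present for benign polymorphisms, usually absent (or tiny) for
    # somatic pathogenic variants.
    missing_rate = (cfg.maf_missing_rate_pathogenic if pathogenic
                    else cfg.maf_missing_rate_benign)
    if rng.uniform() < missing_rate:
        maf = None
    elif pathogenic:
        maf = round(float(rng.beta(1.05, 40.0)), 5)
    else:
        maf = round(float(rng.beta(1.3, 10.0)), 5)

    # Typical allele fraction: germline-like for benign (heterozygous
    # ~0.5 or homozygous ~1.0), a per-variant clonal level for somatic.
    if pathogenic:
        vaf_mean = float(rng.uniform(0.08, 0.60))
        vaf_sd = 0.10
    elif rng.uniform() < 0.60:
        vaf_mean, vaf_sd = 0.50, 0.04
    else:
        vaf_mean, vaf_sd = 0.97, 0.02

    # Per-amplicon typical depth, floored at the panel QC bound.
    cov_mean = cfg.coverage_floor + float(
        rng.gamma(4.0, max(cfg.coverage_mean - cfg.coverage_floor, 1) / 4.0))

    if vtype == "SNV":
        bases = ("A", "C", "G", "T")
        b1, b2 = rng.choice(4, size=2, replace=False)
        coding = f"c.{aa_pos * 3 - 1}{bases[b1]}>{bases[b2]}"
    elif vtype == "MNV":
        coding = f"c.{aa_pos * 3 - 2}_{aa_pos * 3}delinsNNN"
    else:
        coding = f"c.{aa_pos * 3 - 2}_{aa_pos * 3}del"

    return _VariantProfile(gene=gene, chrom=chrom, pos=pos, exon=exon,
                           coding=coding, protein=protein, effect=effect,
                           maf=maf, vaf_mean=vaf_mean, vaf_sd=vaf_sd,
                           cov_mean=cov_mean)


def _observe(rng: np.random.Generator, cfg: CohortConfig, vtype: str,
             profile: _VariantProfile, label: int) -> VariantRecord:
    # VAF reported at 1% resolution, depth QC-binned to the nearest 100x
    vaf = round(float(np.clip(rng.normal(profile.vaf_mean, profile.vaf_sd),
                              0.02, 1.0)), 2)
    coverage = max(cfg.coverage_floor, 100 * int(round(
        rng.normal(profile.cov_mean, profile.cov_mean / 8) / 100)))
    return VariantRecord(
        chrom=profile.chrom, pos=profile.pos, gene=profile.gene,
        variant_type=vtype, exon=profile.exon, coding=profile.coding,
        protein=profile.protein, vaf=vaf, maf=profile.maf,
        coverage=coverage, effect=profile.effect, label=label)


def _generate(rng: np.random.Generator, cfg: CohortConfig,
              types: np.ndarray, labels: np.ndarray) -> list[VariantRecord]:
    """Catalogue-then-observe: distinct variant profiles per
    (type, class) cell, observations multinomially spread over them."""
    records: list[VariantRecord] = []
    for vtype in VARIANT_TYPE_ORDER:
        for label in (0, 1):
            n_obs = int(np.sum((types == vtype) & (labels == label)))
            if n_obs == 0:
                continue
            recurrence = (cfg.recurrence_pathogenic if label == 1
                          else cfg.recurrence_benign)
            n_distinct = max(1, int(round(n_obs / recurrence)))
            profiles = []
            for _ in range(n_distinct):
                # label noise operates at the catalogue level: the
                # variant keeps its label but draws its features from
                # the opposite class-conditional distribution
                feature_class = label
                if rng.uniform() < cfg.label_noise:
                    feature_class = 1 - label
                profiles.append(_make_profile(rng, cfg, vtype,
                                              feature_class == 1))
            assignment = rng.integers(0, n_distinct, size=n_obs)
            records.extend(
                _observe(rng, cfg, vtype, profiles[k], label)
                for k in assignment)
    order = rng.permutation(len(records))
    return [records[i] for i in order]


VARIANT_TYPE_ORDER = ("SNV", "MNV", "INDEL")


def generate_cohort(cfg: CohortConfig = CohortConfig()
                    ) -> list[VariantRecord]:
    """Generate a labeled cohort with the configured exact per-type and
    per-class counts; deterministic under ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.total == 0:
        return []
    types = np.array(["SNV"] * cfg.n_snv + ["MNV"] * cfg.n_mnv
                     + ["INDEL"] * cfg.n_indel)
    labels = np.array([1] * cfg.n_pathogenic + [0] * cfg.n_benign)
    rng.shuffle(types)
    rng.shuffle(labels)
    return _generate(rng, cfg, types, labels)


def generate_toy_run(n_variants: int = 89, seed: int = 0,
                     labeled: bool = False) -> list[VariantRecord]:
    """A small sequencing-run-sized batch (default 89 variants) for
    predict/tier smoke tests; unlabeled unless ``labeled`` is set."""
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    n_path = max(1, int(round(0.10 * n_variants)))
    n_indel = int(round(n_variants * 0.15))
    cfg = CohortConfig(
        n_snv=n_variants - n_indel, n_mnv=0, n_indel=n_indel,
        n_benign=n_variants - n_path, n_pathogenic=n_path,
        recurrence_benign=2.0, recurrence_pathogenic=1.5, seed=seed)
    types = np.array(["SNV"] * cfg.n_snv + ["INDEL"] * cfg.n_indel)
    labels = np.array([1] * cfg.n_pathogenic + [0] * cfg.n_benign)
    rng.shuffle(types)
    rng.shuffle(labels)
    records = _generate(rng, cfg, types, labels)
    if not labeled:
        records = [dataclasses.replace(r, label=None) for r in records]
    return records


_TSV_COLUMNS = ("chrom", "pos", "gene", "variant_type", "exon", "coding",
                "protein", "vaf", "maf", "coverage", "effect", "label")


def write_tsv(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records as the codec's canonical annotation TSV.

    Optional fields (``maf``, ``label``) are written as empty cells;
    floats are written with full precision so the file round-trips
    losslessly through ``load_annotation_table``.
    """
    path = Path(path)
    lines = ["\t".join(_TSV_COLUMNS)]
    for r in records:
        row = [r.chrom, str(r.pos), r.gene, r.variant_type, str(r.exon),
               r.coding, r.protein, repr(r.vaf),
               "" if r.maf is None else repr(r.maf), str(r.coverage),
               r.effect, "" if r.label is None else str(r.label)]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
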
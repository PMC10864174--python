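"""Readers, writers and configuration for the tabular formats the pipeline touches.

Interchange dialects:

* GWAS summary statistics: tab-delimited with header columns
  ``SNP A1 A2 freq b se p N`` (order-free, case-insensitive). ``A1`` is the
  effect allele, ``freq`` its allele frequency, ``b``/``se`` the per-allele
  effect and standard error, ``p`` the association p-value and ``N`` the
  per-variant sample size.
* PGS scoring files: tab-delimited ``rsID effect_allele other_allele
  effect_weight`` (the PGS-Catalog scoring convention).
* Cohorts: TSV with an ``id`` column plus covariates, blood-trait
  phenotypes, ``vaf`` (variant allele fraction of the somatic mutation,
  missing when no mutant read was observed), ``diagnosis`` in
  {control, ET, PV, MF} and ``driver_class``.

Coordinates are 1-based throughout. Alleles are restricted to single
nucleotides: the pipeline scores common SNVs only, so indels are rejected
at parse time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, fields, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("clonalpgs")

VALID_BASES = frozenset("ACGT")
VALID_DIAGNOSES = ("control", "ET", "PV", "MF")
VALID_DRIVER_CLASSES = ("JAK2het", "CALR_MPL", "TN")

#: canonical column names of the summary-statistics dialect
SUMMARY_COLUMNS = ("SNP", "A1", "A2", "freq", "b", "se", "p", "N")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One per-variant association record (effect allele = ``effect_allele``).

    ``beta`` is the per-allele effect in trait-s.d. units for quantitative
    traits and log-odds units for binary outcomes. Monomorphic variants from
    an association scan are represented with ``beta``/``se``/``pvalue`` all
    NaN and are excluded downstream.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pvalue: float
    n: int

    def validate(self) -> None:
        if not self.variant_id:
            raise ValueError("empty variant_id")
        for allele in (self.effect_allele, self.other_allele):
            if len(allele) != 1 or allele not in VALID_BASES:
                raise ValueError(
                    f"{self.variant_id}: allele {allele!r} is not a single A/C/G/T base"
                )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: identical alleles")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant_id}: eaf {self.eaf} outside (0,1)")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be 1-based positive")
        if self.n <= 0:
            raise ValueError(f"{self.variant_id}: non-positive sample size")
        missing = [math.isnan(x) for x in (self.beta, self.se, self.pvalue)]
        if any(missing):
            if not all(missing):
                raise ValueError(
                    f"{self.variant_id}: beta/se/pvalue must be all present or all missing"
                )
            return  # all-missing statistics are allowed (monomorphic scan output)
        if not self.se > 0:
            raise ValueError(f"{self.variant_id}: se must be > 0")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"{self.variant_id}: pvalue {self.pvalue} outside (0,1]")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def has_stats(self) -> bool:
        return not math.isnan(self.se)

    @property
    def is_palindromic(self) -> bool:
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        return comp[self.effect_allele] == self.other_allele


@dataclass
class GwasSummary:
    """Per-variant association records for one trait in one cohort."""

    trait_name: str
    records: list[VariantRecord]
    cohort_label: str = ""

    def __post_init__(self) -> None:
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant ids: {dup[:5]}")
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos, r.variant_id))

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self) -> dict[str, VariantRecord]:
        return {r.variant_id: r for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the pipeline (defaults mirror the analysis design)."""

    vaf_threshold: float = 0.1      # small/large clone split on VAF
    maf_min: float = 0.01           # common-variant restriction
    gws_p: float = 5e-8             # genome-wide significance
    external_p: float = 0.05        # nominal replication threshold in the external cohort
    cojo_window_bp: int = 10_000_000
    ld_prune_r2: float = 0.05
    freq_diff_max: float = 0.2      # allele-frequency concordance guard
    fdr_alpha: float = 0.05
    reverse_p: float = 1e-6         # instrument threshold for reverse-direction MR
    mr_alpha_bonf: float = 0.0042   # 0.05 / (3 traits x 4 methods)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vaf_threshold", "maf_min", "ld_prune_r2", "freq_diff_max",
                     "fdr_alpha", "external_p"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name}={v} outside (0,1)")
        if self.cojo_window_bp <= 0:
            raise ValueError("cojo_window_bp must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


class CohortTable:
    """Per-individual covariates, phenotypes, VAF, diagnosis and driver class.

    Thin wrapper over a :class:`pandas.DataFrame` indexed 0..n-1 with an
    ``id`` column; missing values stay missing (a missing VAF means no
    mutant read was observed, which is distinct from VAF = 0).
    """

    def __init__(self, df: pd.DataFrame):
        if "id" not in df.columns:
            raise FormatError("cohort table requires an 'id' column")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise FormatError(f"duplicate individual id: {dup!r}")
        if "diagnosis" in df.columns:
            bad = set(df["diagnosis"].dropna()) - set(VALID_DIAGNOSES)
            if bad:
                raise FormatError(f"unknown diagnosis label: {sorted(bad)[0]!r}")
        if "driver_class" in df.columns:
            bad = set(df["driver_class"].dropna()) - set(VALID_DRIVER_CLASSES)
            if bad:
                raise FormatError(f"unknown driver class: {sorted(bad)[0]!r}")
        if "vaf" in df.columns:
            v = df["vaf"].dropna()
            if ((v <= 0) | (v > 1)).any():
                raise FormatError("vaf values must lie in (0, 1]")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _require_columns(present: Sequence[str], required: Sequence[str], path) -> dict[str, str]:
    lower = {c.lower(): c for c in present}
    mapping = {}
    for col in required:
        if col.lower() not in lower:
            raise FormatError(f"{path}: missing required column {col!r}")
        mapping[col] = lower[col.lower()]
    return mapping


def read_gwas_summary(path: str | Path, cohort_label: str = "",
                      trait_name: str | None = None) -> GwasSummary:
    """Read a tab-delimited summary-statistics file (SNP A1 A2 freq b se p N).

    Optional ``chrom``/``pos`` columns are used when present; otherwise
    variant order provides surrogate positions on a single chromosome.
    Rows violating the per-variant invariants are dropped with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise FormatError(f"{path}: empty summary-statistics file")
    colmap = _require_columns(df.columns, SUMMARY_COLUMNS, path)
    lower = {c.lower(): c for c in df.columns}
    has_coords = "chrom" in lower and "pos" in lower
    records, dropped = [], 0
    for i, row in enumerate(df.itertuples(index=False)):
        row = row._asdict()
        try:
            rec = VariantRecord(
                variant_id=str(row[colmap["SNP"]]),
                chrom=str(row[lower["chrom"]]) if has_coords else "1",
                pos=int(row[lower["pos"]]) if has_coords else i + 1,
                effect_allele=str(row[colmap["A1"]]).upper(),
                other_allele=str(row[colmap["A2"]]).upper(),
                eaf=float(row[colmap["freq"]]),
                beta=float(row[colmap["b"]]),
                se=float(row[colmap["se"]]),
                pvalue=float(row[colmap["p"]]),
                n=int(row[colmap["N"]]),
            )
            rec.validate()
            records.append(rec)
        except (ValueError, TypeError):
            dropped += 1
    if dropped:
        logger.info("read_gwas_summary: dropped %d invalid rows from %s", dropped, path)
    summary = GwasSummary(trait_name=trait_name or path.stem, records=records,
                          cohort_label=cohort_label)
    _log_stage("read_gwas_summary", path, rows=len(records), dropped=dropped)
    return summary


def write_gwas_summary(summary: GwasSummary, path: str | Path) -> None:
    rows = []
    for r in summary.records:
        rows.append({
            "SNP": r.variant_id, "A1": r.effect_allele, "A2": r.other_allele,
            "freq": _fmt(r.eaf), "b": _fmt(r.beta), "se": _fmt(r.se),
            "p": _fmt(r.pvalue), "N": r.n, "chrom": r.chrom, "pos": r.pos,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> CohortTable:
    """Read a cohort TSV; missing values stay missing, labels are validated."""
    df = pd.read_csv(path, sep="\t")
    table = CohortTable(df)
    _log_stage("read_cohort", path, rows=len(table))
    return table


def write_cohort(table: CohortTable, path: str | Path) -> None:
    df = table.df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(lambda x: "" if pd.isna(x) else _fmt(x))
    df.to_csv(path, sep="\t", index=False)


def read_scoring_file(path: str | Path, trait_name: str | None = None):
    """Read a PGS-Catalog-style scoring file into a PgsModel."""
    from .pgs_engine import PgsModel, PgsEntry

    df = pd.read_csv(path, sep="\t")
    colmap = _require_columns(
        df.columns, ("rsID", "effect_allele", "other_allele", "effect_weight"), path)
    entries = [
        PgsEntry(str(r[colmap["rsID"]]), str(r[colmap["effect_allele"]]).upper(),
                 str(r[colmap["other_allele"]]).upper(), float(r[colmap["effect_weight"]]))
        for _, r in df.iterrows()
    ]
    return PgsModel(trait_name=trait_name or Path(path).stem, entries=entries)


def write_scoring_file(model, path: str | Path) -> None:
    rows = [{"rsID": e.variant_id, "effect_allele": e.effect_allele,
             "other_allele": e.other_allele, "effect_weight": _fmt(e.weight)}
            for e in model.entries]
    pd.DataFrame(rows, columns=["rsID", "effect_allele", "other_allele",
                                "effect_weight"]).to_csv(path, sep="\t", index=False)


def read_ld_reference_vcf(path: str | Path):
    """Parse SNV genotypes from a VCF into an LD reference dosage panel.

    Requires the optional ``cyvcf2`` dependency. Multi-allelic sites and
    indels are skipped; VCF positions are already 1-based.
    """
    from cyvcf2 import VCF
    from .pgs_engine import LdReference
    from .synthetic_cohort import VariantStub

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    stubs, cols = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        ref, alt = v.REF.upper(), v.ALT[0].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES or alt not in VALID_BASES:
            continue
        gts = np.asarray(v.gt_types)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        dos = np.where(gts == 3, 2, gts).astype(np.int8)
        if (gts == 2).any():
            continue  # drop sites with missing genotypes
        eaf = float(dos.mean() / 2.0)
        if not (0.0 < eaf < 1.0):
            continue
        vid = v.ID if v.ID else f"{v.CHROM}:{v.POS}"
        stubs.append(VariantStub(vid, str(v.CHROM), int(v.POS), alt, ref, eaf))
        cols.append(dos)
    if not stubs:
        raise FormatError(f"{path}: no usable biallelic SNVs")
    return LdReference(dosages=np.column_stack(cols), variants=stubs, sample_ids=samples)


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    """Serialize a float at 10 significant digits (locale-independent)."""
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return format(float(x), ".10g")


def _to_plain(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(_fmt(float(obj)))
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    return obj


def write_results(results, path: str | Path, format: str = "json") -> None:
    """Serialize pipeline result objects deterministically.

    Floats are written at 10 significant digits; key order is fixed by the
    dataclass field order (JSON) or column order (TSV), so writing the same
    object twice yields byte-identical files.
    """
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(_to_plain(results), fh, indent=2)
            fh.write("\n")
    elif format == "tsv":
        items = results if isinstance(results, (list, tuple)) else [results]
        rows = [_to_plain(r) for r in items]
        df = pd.DataFrame(rows)
        for col in df.columns:
            if pd.api.types.is_float_dtype(df[col]):
                df[col] = df[col].map(_fmt)
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def _log_stage(stage: str, path=None, seed=None, **counts) -> None:
    """One structured log line per pipeline stage (auditable seeded runs)."""
    parts = [f"stage={stage}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if path is not None:
        p = Path(path)
        if p.exists() and p.is_file():
            digest = hashlib.sha256(p.read_bytes()).hexdigest()[:12]
            parts.append(f"input={p.name} sha256={digest}")
    parts += [f"{k}={v}" for k, v in counts.items()]
    logger.info(" ".join(parts))
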
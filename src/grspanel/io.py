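"""Readers and writers for the package's tabular formats, plus VCF import.

All tables are UTF-8 TSV with a mandatory header and ``NA`` for missing
values.  Numeric outputs carry full-precision columns; the association
table adds display-rounded columns following the conventions of printed
candidate-gene tables (2 dp effects and ORs, CI as a single string).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import AssocResult
from .grs import SchemeFit, ScoreSet, sensitivity_table
from .panel import Scheme, VariantDef
from .roc import RocCurve
from .simulate import Cohort, SimulationError

__all__ = [
    "ParseError",
    "read_genotype_table",
    "write_genotype_table",
    "import_vcf",
    "write_assoc_table",
    "read_assoc_table",
    "write_scores_table",
    "read_scores_table",
    "write_roc_tables",
    "read_roc_points",
    "read_roc_summary",
]

_FLOAT_FMT = "%.10g"
_DOSAGE_TOKENS = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}


class ParseError(ValueError):
    """Input file violates the expected schema; message names row/column."""


# ---------------------------------------------------------------------------
# genotype table: sample_id, phenotype, then one dosage column per variant

def write_genotype_table(cohort: Cohort, path) -> None:
    df = cohort.to_dataframe()
    for vid in cohort.variant_ids:
        col = df[vid]
        df[vid] = np.where(col.isna(), "NA",
                           col.fillna(0).astype(int).astype(str))
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_genotype_table(path) -> Cohort:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     encoding="utf-8")
    cols = list(df.columns)
    if cols[:2] != ["sample_id", "phenotype"]:
        raise ParseError(
            f"{path}: first two columns must be sample_id, phenotype, got {cols[:2]}"
        )
    variant_ids = cols[2:]
    if not variant_ids:
        raise ParseError(f"{path}: no variant columns")
    sample_ids = df["sample_id"].tolist()
    dupes = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dupes):
        raise ParseError(f"{path}: duplicate sample_id(s): {list(dupes)[:5]}")
    try:
        phenotype = df["phenotype"].astype(int).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer phenotype value ({exc})") from None
    if not np.all(np.isin(phenotype, (0, 1))):
        bad = df["phenotype"][~np.isin(phenotype, (0, 1))].iloc[0]
        raise ParseError(f"{path}: phenotype must be 0/1, got {bad!r}")
    dosage = np.empty((len(df), len(variant_ids)))
    for j, vid in enumerate(variant_ids):
        for i, token in enumerate(df[vid]):
            token = token.strip()
            if token not in _DOSAGE_TOKENS:
                raise ParseError(
                    f"{path}: invalid dosage {token!r} at row {i + 2} "
                    f"(sample {sample_ids[i]}), column {vid!r}"
                )
            dosage[i, j] = _DOSAGE_TOKENS[token]
    try:
        return Cohort(sample_ids, phenotype, variant_ids, dosage)
    except SimulationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def import_vcf(
    path,
    effect_allele_map: Mapping[str, str],
    phenotype_table: Mapping[str, int],
) -> Cohort:
    """Build a cohort from a biallelic VCF plus an external phenotype map.

    Dosage is the count of the effect allele in GT; missing GT becomes a
    missing dosage.  The effect allele must match REF or ALT verbatim
    (no strand flipping); variants failing that, multiallelic records and
    records absent from ``effect_allele_map`` are skipped with a warning.
    Samples absent from ``phenotype_table`` are dropped.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    keep = [s for s in vcf_samples if s in phenotype_table]
    if not keep:
        raise ParseError(f"{path}: no VCF sample has a phenotype")
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vf:
        vid = rec.id or f"{rec.chrom}:{rec.pos}"
        if rec.alts is None or len(rec.alts) != 1:
            warnings.warn(f"{vid}: skipping non-biallelic record", stacklevel=2)
            continue
        if vid not in effect_allele_map:
            warnings.warn(f"{vid}: no effect allele specified; skipped",
                          stacklevel=2)
            continue
        ea = effect_allele_map[vid]
        if ea == rec.ref:
            effect_index = 0
        elif ea == rec.alts[0]:
            effect_index = 1
        else:
            warnings.warn(
                f"{vid}: effect allele {ea!r} matches neither REF {rec.ref!r} "
                f"nor ALT {rec.alts[0]!r}; variant skipped", stacklevel=2)
            continue
        col = np.full(len(keep), np.nan)
        for i, s in enumerate(keep):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            col[i] = sum(1 for a in gt if a == effect_index)
        variant_ids.append(vid)
        columns.append(col)
    if not variant_ids:
        raise ParseError(f"{path}: no usable biallelic records")
    phenotype = np.array([phenotype_table[s] for s in keep], dtype=np.int8)
    return Cohort(keep, phenotype, variant_ids, np.column_stack(columns))


# ---------------------------------------------------------------------------
# association results table

def assoc_frame(results: Sequence[AssocResult],
                panel: Sequence[VariantDef] | None = None) -> pd.DataFrame:
    meta = {v.variant_id: v for v in panel} if panel else {}
    rows = []
    for r in results:
        v = meta.get(r.variant_id)
        rows.append({
            "variant_id": r.variant_id,
            "chrom_pos": v.chrom_pos if v else "NA",
            "ea": v.effect_allele if v else "NA",
            "nea": v.other_allele if v else "NA",
            "eaf_cases": r.eaf_cases,
            "eaf_controls": r.eaf_controls,
            "n_cases": r.n_cases,
            "n_controls": r.n_controls,
            "eae": r.beta,
            "se": r.se,
            "or": r.or_,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p,
            "status": r.status,
        })
    df = pd.DataFrame(rows)
    # display-rounded companions, printed-table style
    df["eae_2dp"] = df["eae"].round(2)
    df["or_ci_display"] = [
        "NA" if not np.isfinite(o) else f"{o:.2f} ({lo:.2f}, {hi:.2f})"
        for o, lo, hi in zip(df["or"], df["ci_low"], df["ci_high"])
    ]
    return df


def write_assoc_table(results: Sequence[AssocResult], path,
                      panel: Sequence[VariantDef] | None = None) -> None:
    assoc_frame(results, panel).to_csv(
        path, sep="\t", index=False, encoding="utf-8",
        float_format=_FLOAT_FMT, na_rep="NA")


def read_assoc_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8",
                     na_values=["NA"], keep_default_na=False)
    required = {"variant_id", "eae", "or", "ci_low", "ci_high", "p", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# score tables

def write_scores_table(scores: ScoreSet, path) -> None:
    scores.to_dataframe().to_csv(path, sep="\t", index=False, encoding="utf-8",
                                 float_format=_FLOAT_FMT, na_rep="NA")


def read_scores_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8",
                     na_values=["NA"], keep_default_na=False)
    required = {"sample_id", "m_genotyped", "raw_score", "corrected_score",
                "scheme"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_sensitivity_table(results: Mapping[Scheme, SchemeFit], path) -> None:
    sensitivity_table(results).to_csv(path, sep="\t", index=False,
                                      encoding="utf-8",
                                      float_format=_FLOAT_FMT, na_rep="NA")


# ---------------------------------------------------------------------------
# ROC tables

def write_roc_tables(curve: RocCurve, prefix) -> tuple[str, str]:
    """Write ``<prefix>_points.tsv`` and ``<prefix>_summary.tsv``."""
    points_path = f"{prefix}_points.tsv"
    summary_path = f"{prefix}_summary.tsv"
    pd.DataFrame({
        "threshold": curve.thresholds,
        "sensitivity": curve.sensitivity,
        "specificity": curve.specificity,
    }).to_csv(points_path, sep="\t", index=False, encoding="utf-8",
              float_format=_FLOAT_FMT, na_rep="NA")
    pd.DataFrame([{
        "auc": curve.auc,
        "ci_low": curve.auc_ci_low,
        "ci_high": curve.auc_ci_high,
        "best_threshold": curve.best_threshold,
        "best_sensitivity": curve.best_sensitivity,
        "best_specificity": curve.best_specificity,
    }]).to_csv(summary_path, sep="\t", index=False, encoding="utf-8",
               float_format=_FLOAT_FMT, na_rep="NA")
    return points_path, summary_path


def read_roc_points(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8",
                     na_values=["NA"], keep_default_na=False)
    if set(df.columns) != {"threshold", "sensitivity", "specificity"}:
        raise ParseError(f"{path}: unexpected columns {list(df.columns)}")
    return df


def read_roc_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8",
                     na_values=["NA"], keep_default_na=False)
    required = {"auc", "ci_low", "ci_high", "best_threshold"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return df
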
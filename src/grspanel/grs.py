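"""Per-sample genetic risk scores with a missingness correction.

The raw score of sample i is sum_j w_j * d_ij over the variants genotyped
in that sample.  Because panels are rarely typed completely in every
person, the raw score of a partially genotyped sample is rescaled by
M / m_i, where M is the panel size and m_i the number of variants
genotyped in sample i — so scores remain comparable across people with
different genotyping coverage.  Fully genotyped samples are untouched
(M/m = 1); samples with no genotyped variant cannot be scored and are
excluded with a report.

The score-phenotype association is an ordinary logistic regression of case
status on the corrected score as a single continuous covariate; its OR is
per unit of corrected score (no standardisation by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import AssocResult, fit_wald_logistic
from .panel import (
    Scheme,
    VariantDef,
    WeightConfigError,
    WeightScheme,
    build_weight_scheme,
)
from .simulate import Cohort

__all__ = [
    "ScoreSet",
    "SchemeFit",
    "compute_grs",
    "grs_association",
    "run_grs_sensitivity",
    "sensitivity_table",
]


@dataclass
class ScoreSet:
    """Raw and missingness-corrected scores for the retained samples.

    ``corrected_score = raw_score * M_total / m_genotyped`` exactly.
    ``excluded_samples`` lists sample_ids with zero genotyped scored
    variants; they carry no score.
    """

    sample_ids: list[str]
    raw_score: np.ndarray
    m_genotyped: np.ndarray
    corrected_score: np.ndarray
    M_total: int
    scheme: Scheme
    phenotype: np.ndarray | None = None
    excluded_samples: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "sample_id": self.sample_ids,
            "m_genotyped": self.m_genotyped,
            "raw_score": self.raw_score,
            "corrected_score": self.corrected_score,
        })
        df["scheme"] = self.scheme.value
        if self.phenotype is not None:
            df.insert(1, "phenotype", self.phenotype)
        return df


@dataclass
class SchemeFit:
    """One row of the weighting-scheme sensitivity analysis."""

    scheme: Scheme
    weights: WeightScheme
    scores: ScoreSet
    assoc: AssocResult


def compute_grs(
    cohort: Cohort,
    weights: WeightScheme,
    M_total: int | None = None,
) -> ScoreSet:
    """Score every sample over the weight scheme's variants.

    Missing dosages contribute nothing to the raw score and decrement the
    per-sample genotyped count m; the corrected score multiplies by
    ``M_total / m``.  ``M_total`` defaults to the number of weighted
    variants (12 for the default RPL panel after LD exclusion).
    """
    vids = weights.variant_ids
    missing_from_cohort = [v for v in vids if v not in cohort.variant_ids]
    if missing_from_cohort:
        raise WeightConfigError(
            f"weighted variants absent from cohort: {missing_from_cohort}"
        )
    if M_total is None:
        M_total = len(vids)
    w = np.array([weights.weights[v] for v in vids], dtype=float)
    cols = [cohort.variant_ids.index(v) for v in vids]
    d = cohort.dosage[:, cols]
    genotyped = ~np.isnan(d)
    m = genotyped.sum(axis=1)
    raw = np.nansum(d * w, axis=1)

    scored = m >= 1
    excluded = [sid for sid, keep in zip(cohort.sample_ids, scored) if not keep]
    if excluded:
        warnings.warn(
            f"{len(excluded)} sample(s) with zero genotyped scored variants "
            f"excluded from scoring: {excluded[:5]}{'...' if len(excluded) > 5 else ''}",
            stacklevel=2,
        )
    raw = raw[scored]
    m = m[scored]
    corrected = raw * M_total / m  # exact algebraic form, bit-stable
    return ScoreSet(
        sample_ids=[sid for sid, keep in zip(cohort.sample_ids, scored) if keep],
        raw_score=raw,
        m_genotyped=m.astype(int),
        corrected_score=corrected,
        M_total=int(M_total),
        scheme=weights.scheme,
        phenotype=cohort.phenotype[scored],
        excluded_samples=excluded,
    )


def grs_association(
    scores: ScoreSet,
    phenotype: np.ndarray | None = None,
    standardize: bool = False,
) -> AssocResult:
    """Logistic regression of case status on the corrected score.

    The reported OR is per unit of corrected score; with
    ``standardize=True`` the score is divided by its sample SD first, so
    the OR is per SD instead.
    """
    y = scores.phenotype if phenotype is None else np.asarray(phenotype)
    if y is None:
        raise ValueError("phenotype required: ScoreSet carries none")
    if len(y) != len(scores.corrected_score):
        raise ValueError("phenotype length does not match scored samples")
    x = scores.corrected_score.astype(float)
    label = f"GRS[{scores.scheme.value}]"
    if standardize:
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError("cannot standardise a constant score")
        x = x / sd
        label += "/sd"
    res = fit_wald_logistic(x, y, label=label)
    # the per-group "EAF" slots are meaningless for a continuous score:
    # report group mean scores instead of mean(x)/2
    res.eaf_cases = float(x[y == 1].mean()) if res.n_cases else float("nan")
    res.eaf_controls = float(x[y == 0].mean()) if res.n_controls else float("nan")
    return res


def run_grs_sensitivity(
    cohort: Cohort,
    panel12: Sequence[VariantDef],
    study_betas: Mapping[str, float] | None = None,
    standardize: bool = False,
) -> dict[Scheme, SchemeFit]:
    """Score-phenotype association under all three weighting schemes.

    ``study_betas`` are the in-study per-variant log-odds estimates
    (typically the beta column of :func:`~grspanel.association.run_panel_association`
    on the same cohort); if omitted they are computed here.  Variants whose
    per-variant fit is flagged yield no study beta, which is a
    configuration error for the schemes that need them.
    """
    if study_betas is None:
        from .association import run_panel_association

        study_betas = {
            r.variant_id: r.beta for r in run_panel_association(cohort, panel12)
            if r.ok
        }
    out: dict[Scheme, SchemeFit] = {}
    for scheme in (Scheme.PUBLISHED_MIXED, Scheme.STUDY, Scheme.UNIT):
        ws = build_weight_scheme(panel12, scheme, study_betas)
        scores = compute_grs(cohort, ws)
        assoc = grs_association(scores, standardize=standardize)
        out[scheme] = SchemeFit(scheme, ws, scores, assoc)
    return out


def sensitivity_table(results: Mapping[Scheme, SchemeFit]) -> pd.DataFrame:
    """Flatten the sensitivity analysis into a 3-row table."""
    rows = []
    for scheme, fit in results.items():
        a = fit.assoc
        rows.append({
            "scheme": scheme.value,
            "n_cases": a.n_cases,
            "n_controls": a.n_controls,
            "beta": a.beta,
            "se": a.se,
            "or": a.or_,
            "ci_low": a.ci_low,
            "ci_high": a.ci_high,
            "p": a.p,
            "status": a.status,
        })
    return pd.DataFrame(rows)
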
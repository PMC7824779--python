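"""Per-variant case-control association under the log-additive model.

Each variant is tested by maximum-likelihood logistic regression of case
status on effect-allele dosage, logit P(case) = alpha + beta * d, on the
complete cases for that variant (no imputation; per-variant sample sizes
may differ, as they do when genotyping campaigns are staggered).  Inference
is Wald: SE from the observed information, 95% CI exp(beta +/- z * SE),
two-sided p from the normal approximation.  No multiple-testing correction
is applied; p-values are nominal.

Degenerate inputs are flagged, not silently reported: constant dosage,
a single phenotype class, and (quasi-)complete separation all yield a
result whose ``status`` names the problem and whose numeric fields are NaN.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .panel import VariantDef
from .simulate import Cohort

__all__ = [
    "AssocResult",
    "AssociationError",
    "ConvergenceError",
    "eaf",
    "fit_logistic_dosage",
    "run_panel_association",
    "fit_wald_logistic",
]

Z95 = norm.ppf(0.975)

#: absolute linear-predictor magnitude beyond which a non-converged fit is
#: treated as separation rather than a numerical failure
_SEPARATION_ETA = 15.0


class AssociationError(ValueError):
    """Invalid input to an association fit."""


class ConvergenceError(RuntimeError):
    """The ML fit did not converge within the iteration cap."""


@dataclass
class AssocResult:
    """One logistic fit: a per-variant test or a per-score test.

    ``beta`` is the estimated allelic effect (log odds per effect-allele
    copy, or per score unit); ``or_`` = exp(beta) with its Wald 95% CI and
    two-sided p.  ``status`` is ``"ok"`` for a clean fit, otherwise a
    diagnostic token (``constant_dosage``, ``single_class``,
    ``separation``, ``error:<msg>``) and the inferential fields are NaN.
    """

    variant_id: str
    n_cases: int
    n_controls: int
    eaf_cases: float
    eaf_controls: float
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def eaf(cohort: Cohort, variant_id: str, group: str) -> float:
    """Effect-allele frequency in one phenotype group, complete cases only.

    ``group`` is ``"cases"`` or ``"controls"``.  The frequency is
    (sum of dosages) / (2 x genotyped samples in the group).
    """
    if group not in ("cases", "controls"):
        raise AssociationError(f"group must be 'cases' or 'controls', got {group!r}")
    d = cohort.column(variant_id)
    mask = (cohort.phenotype == (1 if group == "cases" else 0)) & ~np.isnan(d)
    n = int(mask.sum())
    if n == 0:
        raise AssociationError(
            f"{variant_id}: no genotyped {group}; frequency undefined"
        )
    return float(d[mask].sum() / (2.0 * n))


def _flagged(variant_id: str, n_cases: int, n_controls: int,
             eaf_ca: float, eaf_co: float, status: str) -> AssocResult:
    nan = float("nan")
    return AssocResult(variant_id, n_cases, n_controls, eaf_ca, eaf_co,
                       nan, nan, nan, nan, nan, nan, status=status)


def fit_wald_logistic(
    x: np.ndarray,
    y: np.ndarray,
    label: str = "x",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> AssocResult:
    """ML logistic fit of binary ``y`` on a single covariate ``x``.

    Shared engine behind the per-variant and per-score tests.  ``x`` and
    ``y`` must already be complete cases.  Group EAFs in the result are the
    mean of x/2 per group (the allele frequency when x is a dosage).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise AssociationError("x and y must be 1-D arrays of equal length")
    n_cases = int((y == 1).sum())
    n_controls = int((y == 0).sum())
    eaf_ca = float(x[y == 1].mean() / 2.0) if n_cases else float("nan")
    eaf_co = float(x[y == 0].mean() / 2.0) if n_controls else float("nan")
    if n_cases == 0 or n_controls == 0:
        return _flagged(label, n_cases, n_controls, eaf_ca, eaf_co, "single_class")
    if np.ptp(x) == 0:
        return _flagged(label, n_cases, n_controls, eaf_ca, eaf_co,
                        "constant_dosage")

    X = sm.add_constant(x)
    model = sm.Logit(y, X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(method="newton", maxiter=maxiter, tol=tol,
                            disp=0, warn_convergence=False)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return _flagged(label, n_cases, n_controls, eaf_ca, eaf_co, "separation")
    if not fit.mle_retvals.get("converged", False):
        eta = X @ fit.params
        if np.max(np.abs(eta)) > _SEPARATION_ETA:
            return _flagged(label, n_cases, n_controls, eaf_ca, eaf_co,
                            "separation")
        raise ConvergenceError(
            f"{label}: logistic fit did not converge in {maxiter} iterations"
        )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se <= 0 or abs(beta) > _SEPARATION_ETA:
        return _flagged(label, n_cases, n_controls, eaf_ca, eaf_co, "separation")
    z = beta / se
    p = float(2.0 * norm.sf(abs(z)))
    return AssocResult(
        variant_id=label,
        n_cases=n_cases,
        n_controls=n_controls,
        eaf_cases=eaf_ca,
        eaf_controls=eaf_co,
        beta=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p=p,
    )


def fit_logistic_dosage(cohort: Cohort, variant_id: str,
                        maxiter: int = 100, tol: float = 1e-8) -> AssocResult:
    """Log-additive association of one variant with case status.

    Complete-case: samples missing this variant's genotype are dropped from
    both the fit and the reported group sizes/EAFs.
    """
    d = cohort.column(variant_id)
    keep = ~np.isnan(d)
    if not keep.any():
        raise AssociationError(f"{variant_id}: no genotyped samples")
    return fit_wald_logistic(d[keep], cohort.phenotype[keep], label=variant_id,
                             maxiter=maxiter, tol=tol)


def run_panel_association(
    cohort: Cohort, panel: Sequence[VariantDef]
) -> list[AssocResult]:
    """Per-variant association for every non-excluded panel variant.

    Each variant is fit on its own complete cases, so sample sizes may
    differ across rows.  A failing variant yields a flagged row instead of
    aborting the table; a panel variant absent from the cohort raises.
    """
    results: list[AssocResult] = []
    for v in panel:
        if v.ld_excluded:
            continue
        if v.variant_id not in cohort.variant_ids:
            raise KeyError(f"panel variant {v.variant_id!r} not in cohort")
        try:
            results.append(fit_logistic_dosage(cohort, v.variant_id))
        except Exception as exc:  # noqa: BLE001 - per-variant isolation
            results.append(_flagged(v.variant_id, 0, 0, float("nan"),
                                    float("nan"), f"error:{exc}"))
    return results
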
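"""ROC evaluation of a risk score: empirical curve, AUC, DeLong CI, Youden point.

The classification rule is fixed to risk-score semantics: predict "case"
when score >= threshold, so higher scores mean higher predicted risk and
the direction is never auto-flipped.  The empirical curve has one point
per distinct score value plus +/-infinity sentinels; the AUC is the
trapezoidal area, which for this construction equals the Mann-Whitney
statistic P(case score > control score) + 0.5 P(equal).

The AUC confidence interval is DeLong's nonparametric interval from the
variance of placement values, the default of the standard ROC tooling in
this field; a stratified bootstrap interval is available as an
alternative.  The "best discriminating point" maximises the Youden index
(sensitivity + specificity - 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "RocCurve",
    "RocError",
    "roc_curve",
    "auc",
    "auc_ci_delong",
    "auc_ci_bootstrap",
    "best_point_youden",
    "plot_roc",
]


class RocError(ValueError):
    """Invalid input to a ROC computation."""


@dataclass
class RocCurve:
    """Empirical ROC curve with summary statistics.

    ``thresholds`` is strictly decreasing, starting at +inf (nothing
    predicted case: sens 0, spec 1) and ending at -inf (everything
    predicted case: sens 1, spec 0).
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    best_threshold: float
    best_sensitivity: float
    best_specificity: float

    @property
    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise RocError("scores and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(scores)):
        raise RocError("scores must be finite")
    if not np.all(np.isin(labels, (0, 1))):
        raise RocError("labels must be 0/1")
    if labels.min() == labels.max():
        raise RocError("need at least one case and one control")
    return scores, labels


def _curve_points(scores, labels):
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    uniq = np.unique(scores)[::-1]  # descending
    thresholds = np.r_[np.inf, uniq, -np.inf]
    sens = np.empty_like(thresholds)
    spec = np.empty_like(thresholds)
    for i, t in enumerate(thresholds):
        if np.isposinf(t):
            predicted_case_cases = 0
            predicted_case_controls = 0
        else:
            predicted_case_cases = int((cases >= t).sum())
            predicted_case_controls = int((controls >= t).sum())
        sens[i] = predicted_case_cases / len(cases)
        spec[i] = 1.0 - predicted_case_controls / len(controls)
    return thresholds, sens, spec


def auc(scores, labels) -> float:
    """Trapezoidal area under the empirical ROC curve."""
    scores, labels = _validate(scores, labels)
    _, sens, spec = _curve_points(scores, labels)
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(sens[order], fpr[order]))


def _placements(scores, labels):
    """DeLong placement values: per-case and per-control mid-rank probabilities."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    # psi(X_i, Y_j) = 1 if X_i > Y_j, 0.5 if equal, 0 otherwise
    cmp = (cases[:, None] > controls[None, :]).astype(float)
    cmp += 0.5 * (cases[:, None] == controls[None, :])
    v10 = cmp.mean(axis=1)  # one per case
    v01 = cmp.mean(axis=0)  # one per control
    return v10, v01


def auc_ci_delong(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation CI for the empirical AUC, truncated to [0,1]."""
    scores, labels = _validate(scores, labels)
    if (labels == 1).sum() < 2 or (labels == 0).sum() < 2:
        raise RocError("DeLong CI needs at least 2 samples per class")
    v10, v01 = _placements(scores, labels)
    a = v10.mean()
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    if var <= 0:
        warnings.warn("degenerate DeLong variance; CI collapses to the point AUC",
                      stacklevel=2)
        return float(a), float(a)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, a - half)), float(min(1.0, a + half))


def auc_ci_bootstrap(
    scores,
    labels,
    level: float = 0.95,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Stratified percentile-bootstrap CI for the AUC."""
    scores, labels = _validate(scores, labels)
    gen = rng if rng is not None else np.random.default_rng(0)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    stats = np.empty(n_boot)
    lab = np.r_[np.ones(len(cases), dtype=int), np.zeros(len(controls), dtype=int)]
    for b in range(n_boot):
        sc = np.r_[gen.choice(cases, len(cases)), gen.choice(controls, len(controls))]
        v10, _ = _placements(sc, lab)
        stats[b] = v10.mean()
    lo, hi = np.quantile(stats, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def best_point_youden(curve: RocCurve) -> tuple[float, float, float]:
    """Threshold maximising sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity, then lower threshold, so
    the choice is deterministic.
    """
    j = curve.youden
    best = 0
    for i in range(1, len(j)):
        if (j[i] > j[best]
                or (j[i] == j[best] and curve.sensitivity[i] > curve.sensitivity[best])
                or (j[i] == j[best] and curve.sensitivity[i] == curve.sensitivity[best]
                    and curve.thresholds[i] < curve.thresholds[best])):
            best = i
    return (float(curve.thresholds[best]), float(curve.sensitivity[best]),
            float(curve.specificity[best]))


def roc_curve(scores, labels, ci: str = "delong", level: float = 0.95,
              n_boot: int = 2000,
              rng: np.random.Generator | None = None) -> RocCurve:
    """Full ROC analysis of a score vector against binary labels."""
    scores, labels = _validate(scores, labels)
    thresholds, sens, spec = _curve_points(scores, labels)
    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    a = float(np.trapezoid(sens[order], fpr[order]))
    if ci == "delong":
        lo, hi = auc_ci_delong(scores, labels, level)
    elif ci == "bootstrap":
        lo, hi = auc_ci_bootstrap(scores, labels, level, n_boot, rng)
    elif ci is None or ci == "none":
        lo = hi = float("nan")
    else:
        raise RocError(f"unknown CI method {ci!r}")
    curve = RocCurve(thresholds, sens, spec, a, lo, hi,
                     float("nan"), float("nan"), float("nan"))
    t, s, sp = best_point_youden(curve)
    curve.best_threshold = t
    curve.best_sensitivity = s
    curve.best_specificity = sp
    return curve


def plot_roc(curve: RocCurve, path) -> None:
    """Write a simple ROC plot (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(1.0 - curve.specificity, curve.sensitivity, drawstyle="steps-post",
            label=f"AUC {curve.auc:.2f} "
                  f"({curve.auc_ci_low:.2f}, {curve.auc_ci_high:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.plot(1.0 - curve.best_specificity, curve.best_sensitivity, "o", c="C3",
            label=f"best point: sens {curve.best_sensitivity:.2f}, "
                  f"spec {curve.best_specificity:.2f}")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
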
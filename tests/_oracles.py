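"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the logistic oracle is
an exhaustive grid search over the two-parameter log-likelihood, the AUC
oracle counts case-control pairs directly, and the population-AUC oracle
convolves exact genotype distributions.
"""

from __future__ import annotations

import numpy as np


def loglik(alpha: np.ndarray, beta: np.ndarray, d: np.ndarray, y: np.ndarray):
    """Bernoulli log-likelihood of logit P(y=1) = alpha + beta*d, broadcast."""
    eta = alpha[..., None] + beta[..., None] * d
    return (y * eta - np.logaddexp(0.0, eta)).sum(axis=-1)


def grid_logistic(d, y, span: float = 8.0) -> tuple[float, float]:
    """ML (alpha, beta) by nested exhaustive grid search, refined to <=1e-4.

    Scans a [-span, span]^2 grid at progressively finer resolution; each
    pass is an explicit enumeration of the log-likelihood, never a
    derivative-based step.
    """
    d = np.asarray(d, float)
    y = np.asarray(y, float)
    ca, cb, width, step = 0.0, 0.0, span, 0.05
    for _ in range(4):
        a = np.arange(ca - width, ca + width + step / 2, step)
        b = np.arange(cb - width, cb + width + step / 2, step)
        A, B = np.meshgrid(a, b, indexing="ij")
        ll = loglik(A, B, d, y)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        ca, cb = float(a[i]), float(b[j])
        width, step = 2 * step, step / 40
    return ca, cb


def pair_count_auc(scores, labels) -> float:
    """Mann-Whitney AUC by brute-force O(n^2) pair counting (ties = 0.5)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for u in controls:
            if c > u:
                total += 1.0
            elif c == u:
                total += 0.5
    return total / (len(cases) * len(controls))


def youden_scan(scores, labels) -> tuple[float, float, float]:
    """Best (threshold, sens, spec) by exhaustive scan over all thresholds."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    best = None
    for t in [np.inf, *sorted(set(scores), reverse=True), -np.inf]:
        sens = float(np.mean(cases >= t)) if np.isfinite(t) else (0.0 if t > 0 else 1.0)
        spec = float(np.mean(controls < t)) if np.isfinite(t) else (1.0 if t > 0 else 0.0)
        j = sens + spec - 1.0
        key = (j, sens, -t)
        if best is None or key > best[0]:
            best = (key, (float(t), sens, spec))
    return best[1]


def hwe_dosage_pmf(p: float) -> np.ndarray:
    """Genotype distribution [P(0), P(1), P(2)] under Hardy-Weinberg."""
    q = 1.0 - p
    return np.array([q * q, 2 * p * q, p * p])


def sum_score_pmf(eafs: list[float], weights: list[float] | None = None):
    """Exact PMF of an integer-weighted dosage sum over independent variants.

    With unit weights the support is 0..2M.  Returns (support, pmf).
    """
    if weights is None:
        weights = [1.0] * len(eafs)
    if any(w != int(w) for w in weights):
        raise ValueError("exact convolution oracle needs integer weights")
    pmf = np.array([1.0])
    for p, w in zip(eafs, weights):
        w = int(w)
        geno = hwe_dosage_pmf(p)
        step = np.zeros(2 * abs(w) + 1)
        for dose, prob in enumerate(geno):
            step[dose * abs(w)] += prob
        pmf = np.convolve(pmf, step)
    support = np.arange(len(pmf), dtype=float)
    return support, pmf


def population_auc(eaf_cases, eaf_controls) -> float:
    """P(case score > control score) + 0.5 P(equal) for unit-weight scores.

    Exact, from the convolved score distributions of each group.
    """
    s1, p1 = sum_score_pmf(list(eaf_cases))
    s0, p0 = sum_score_pmf(list(eaf_controls))
    gt = (s1[:, None] > s0[None, :]).astype(float)
    gt += 0.5 * (s1[:, None] == s0[None, :])
    return float(p1 @ gt @ p0)
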
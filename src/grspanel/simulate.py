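"""Synthetic case-control cohorts with the structure the GRS analysis assumes.

Two generation modes:

``frequency_matched``
    Each group's genotypes are drawn independently per variant under
    Hardy-Weinberg equilibrium at a group-specific effect-allele frequency
    (dosage ~ Binomial(2, EAF)).  This reproduces a printed case/control
    EAF table by construction and is the mode behind the REPLIK study
    template.

``logistic_liability``
    Genotypes are drawn at population EAFs under HWE and case status from a
    logistic model logit P(case) = intercept + sum_j beta_j * d_ij; samples
    are rejection-sampled until the configured numbers of cases and
    controls are reached.  Used for parameter-recovery experiments, where
    the true per-variant effects are known.

Variants are simulated independently (no LD) and missingness is injected
missing-completely-at-random within each phenotype group, with exact
per-variant genotyped quotas — emulating a genotyping campaign where assay
availability, not genotype, determined who was typed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationMode",
    "SimulationConfig",
    "Cohort",
    "SimulationError",
    "GenerationFailureError",
    "simulate_frequency_matched",
    "simulate_logistic",
    "inject_missingness",
    "replik_template_config",
    "TEMPLATE_EAF_CASES",
    "TEMPLATE_EAF_CONTROLS",
    "TEMPLATE_GENOTYPED_COUNTS",
]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


class GenerationFailureError(RuntimeError):
    """The generator could not satisfy its guarantees within the attempt cap."""


class SimulationMode(str, Enum):
    FREQUENCY_MATCHED = "frequency_matched"
    LOGISTIC_LIABILITY = "logistic_liability"


@dataclass
class SimulationConfig:
    n_cases: int
    n_controls: int
    mode: SimulationMode | str = SimulationMode.FREQUENCY_MATCHED
    eaf_cases: Mapping[str, float] | None = None
    eaf_controls: Mapping[str, float] | None = None
    eaf_population: Mapping[str, float] | None = None
    true_betas: Mapping[str, float] | None = None
    intercept: float = 0.0
    genotyped_counts: Mapping[str, tuple[int, int]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode = SimulationMode(self.mode)
        if self.n_cases < 1 or self.n_controls < 1:
            raise SimulationError("n_cases and n_controls must be positive")
        if self.mode is SimulationMode.FREQUENCY_MATCHED:
            if self.eaf_cases is None or self.eaf_controls is None:
                raise SimulationError(
                    "frequency_matched mode requires eaf_cases and eaf_controls"
                )
            if set(self.eaf_cases) != set(self.eaf_controls):
                raise SimulationError(
                    "eaf_cases and eaf_controls must cover the same variants"
                )
            freqs = list(self.eaf_cases.values()) + list(self.eaf_controls.values())
        else:
            if self.eaf_population is None or self.true_betas is None:
                raise SimulationError(
                    "logistic_liability mode requires eaf_population and true_betas"
                )
            if not set(self.eaf_population) <= set(self.true_betas):
                missing = set(self.eaf_population) - set(self.true_betas)
                raise SimulationError(f"true_betas missing for {sorted(missing)}")
            freqs = list(self.eaf_population.values())
        if any(not 0.0 <= f <= 1.0 for f in freqs):
            raise SimulationError("all effect-allele frequencies must lie in [0, 1]")
        if self.genotyped_counts is not None:
            for vid, (nca, nco) in self.genotyped_counts.items():
                if nca > self.n_cases or nco > self.n_controls:
                    raise SimulationError(
                        f"{vid}: genotyped counts ({nca}, {nco}) exceed group sizes "
                        f"({self.n_cases}, {self.n_controls})"
                    )

    @property
    def variant_ids(self) -> list[str]:
        if self.mode is SimulationMode.FREQUENCY_MATCHED:
            return list(self.eaf_cases)  # type: ignore[arg-type]
        return list(self.eaf_population)  # type: ignore[arg-type]


@dataclass
class Cohort:
    """Sample x variant dosage matrix with a binary phenotype.

    ``dosage`` is float with entries in {0, 1, 2, NaN}; NaN encodes a
    missing genotype.  ``phenotype`` is 1 for cases, 0 for controls.
    """

    sample_ids: list[str]
    phenotype: np.ndarray
    variant_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if n != len(self.sample_ids) or n != len(self.phenotype):
            raise SimulationError("dosage rows must match sample_ids/phenotype")
        if m != len(self.variant_ids):
            raise SimulationError("dosage columns must match variant_ids")
        if len(set(self.sample_ids)) != n:
            raise SimulationError("duplicate sample_ids")
        if not np.all(np.isin(self.phenotype, (0, 1))):
            raise SimulationError("phenotype must be 0/1")
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise SimulationError(
                f"invalid dosage {self.dosage[tuple(bad)]!r} at "
                f"sample {self.sample_ids[bad[0]]}, variant {self.variant_ids[bad[1]]}"
            )

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    def column(self, variant_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in cohort") from None
        return self.dosage[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosage, columns=self.variant_ids)
        df.insert(0, "phenotype", self.phenotype)
        df.insert(0, "sample_id", self.sample_ids)
        return df


def _rng(config_seed: int, rng: np.random.Generator | None) -> np.random.Generator:
    return rng if rng is not None else np.random.default_rng(config_seed)


def simulate_frequency_matched(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Cohort:
    """Draw a cohort with group-specific EAFs under Hardy-Weinberg.

    Dosages are Binomial(2, EAF_group[variant]), independent across samples
    and variants.  Bit-reproducible given the config seed (or an explicit
    generator).
    """
    if config.mode is not SimulationMode.FREQUENCY_MATCHED:
        raise SimulationError("config.mode must be frequency_matched")
    gen = _rng(config.seed, rng)
    vids = config.variant_ids
    p_case = np.array([config.eaf_cases[v] for v in vids])
    p_ctrl = np.array([config.eaf_controls[v] for v in vids])
    d_case = gen.binomial(2, p_case, size=(config.n_cases, len(vids)))
    d_ctrl = gen.binomial(2, p_ctrl, size=(config.n_controls, len(vids)))
    sample_ids = [f"case_{i + 1:04d}" for i in range(config.n_cases)] + [
        f"control_{i + 1:04d}" for i in range(config.n_controls)
    ]
    phenotype = np.r_[np.ones(config.n_cases, dtype=np.int8),
                      np.zeros(config.n_controls, dtype=np.int8)]
    return Cohort(sample_ids, phenotype, vids,
                  np.vstack([d_case, d_ctrl]).astype(float))


def simulate_logistic(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    max_attempt_factor: int = 100,
) -> Cohort:
    """Case-control sample from a logistic disease model with known effects.

    Candidates are drawn at population EAFs under HWE; each becomes a case
    with probability expit(intercept + beta . dosage).  Drawing stops when
    both group quotas are filled; extras are discarded.  If the quotas are
    not reached within ``max_attempt_factor`` times the target sample size,
    a :class:`GenerationFailureError` is raised (e.g. when the case
    probability is numerically zero).
    """
    if config.mode is not SimulationMode.LOGISTIC_LIABILITY:
        raise SimulationError("config.mode must be logistic_liability")
    gen = _rng(config.seed, rng)
    vids = config.variant_ids
    p = np.array([config.eaf_population[v] for v in vids])
    beta = np.array([config.true_betas[v] for v in vids])
    need_cases, need_controls = config.n_cases, config.n_controls
    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    cap = max_attempt_factor * (need_cases + need_controls)
    drawn = 0
    batch = max(256, 4 * (need_cases + need_controls))
    while (len(cases) < need_cases or len(controls) < need_controls) and drawn < cap:
        k = min(batch, cap - drawn)
        d = gen.binomial(2, p, size=(k, len(vids))).astype(float)
        eta = config.intercept + d @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        y = gen.random(k) < prob
        drawn += k
        for row, is_case in zip(d, y):
            if is_case and len(cases) < need_cases:
                cases.append(row)
            elif not is_case and len(controls) < need_controls:
                controls.append(row)
    if len(cases) < need_cases or len(controls) < need_controls:
        raise GenerationFailureError(
            f"could not reach {need_cases} cases / {need_controls} controls "
            f"within {cap} draws (got {len(cases)}/{len(controls)}); "
            "check intercept and effect sizes"
        )
    sample_ids = [f"case_{i + 1:04d}" for i in range(need_cases)] + [
        f"control_{i + 1:04d}" for i in range(need_controls)
    ]
    phenotype = np.r_[np.ones(need_cases, dtype=np.int8),
                      np.zeros(need_controls, dtype=np.int8)]
    return Cohort(sample_ids, phenotype, vids, np.vstack(cases + controls))


def inject_missingness(
    cohort: Cohort,
    genotyped_counts: Mapping[str, tuple[int, int]],
    rng: np.random.Generator | None = None,
    max_attempts: int = 100,
) -> Cohort:
    """Set dosages missing so each variant hits exact per-group genotyped counts.

    For each variant and group, exactly ``group_size - genotyped_count``
    dosages end up missing, chosen uniformly at random (MCAR within group);
    cells that are already missing count toward the quota.  The returned
    cohort is guaranteed to leave every sample with at least one genotyped
    variant; if the quotas make that impossible even after ``max_attempts``
    random draws, a :class:`GenerationFailureError` is raised.
    """
    gen = rng if rng is not None else np.random.default_rng(0)
    case_rows = np.flatnonzero(cohort.phenotype == 1)
    ctrl_rows = np.flatnonzero(cohort.phenotype == 0)
    for vid, (nca, nco) in genotyped_counts.items():
        if vid not in cohort.variant_ids:
            raise SimulationError(f"genotyped_counts names unknown variant {vid!r}")
        if nca > len(case_rows) or nco > len(ctrl_rows):
            raise SimulationError(
                f"{vid}: genotyped counts ({nca}, {nco}) exceed group sizes "
                f"({len(case_rows)}, {len(ctrl_rows)})"
            )
    for _ in range(max_attempts):
        dosage = cohort.dosage.copy()
        for vid, (nca, nco) in genotyped_counts.items():
            j = cohort.variant_ids.index(vid)
            for rows, target in ((case_rows, nca), (ctrl_rows, nco)):
                quota = len(rows) - target  # total missing required
                already = rows[np.isnan(dosage[rows, j])]
                extra = quota - len(already)
                if extra < 0:
                    raise SimulationError(
                        f"{vid}: {len(already)} dosages already missing but quota "
                        f"allows only {quota}"
                    )
                candidates = rows[~np.isnan(dosage[rows, j])]
                if extra:
                    chosen = gen.choice(candidates, size=extra, replace=False)
                    dosage[chosen, j] = np.nan
        if np.all((~np.isnan(dosage)).sum(axis=1) >= 1):
            return Cohort(list(cohort.sample_ids), cohort.phenotype.copy(),
                          list(cohort.variant_ids), dosage)
    raise GenerationFailureError(
        f"could not leave every sample with >=1 genotyped variant after "
        f"{max_attempts} attempts; genotyped_counts are too sparse"
    )


# ---------------------------------------------------------------------------
# Study template: the REPLIK cohort's printed per-group effect-allele
# frequencies and per-variant genotyped counts (114 cases / 106 controls).

TEMPLATE_EAF_CASES: dict[str, float] = {
    "rs1799963": 0.018,
    "rs6025": 0.018,
    "rs6046": 0.89,
    "rs1126643": 0.63,
    "rs2234693": 0.49,
    "rs1042714": 0.60,
    "Intron-4 VNTR": 0.83,
    "rs1799752": 0.52,
    "rs1801133": 0.30,
    "14718": 0.59,
    "rs2227306": 0.40,
    "rs1800896": 0.59,
}

TEMPLATE_EAF_CONTROLS: dict[str, float] = {
    "rs1799963": 0.011,
    "rs6025": 0.022,
    "rs6046": 0.85,
    "rs1126643": 0.54,
    "rs2234693": 0.55,
    "rs1042714": 0.51,
    "Intron-4 VNTR": 0.80,
    "rs1799752": 0.53,
    "rs1801133": 0.24,
    "14718": 0.56,
    "rs2227306": 0.37,
    "rs1800896": 0.49,
}

TEMPLATE_GENOTYPED_COUNTS: dict[str, tuple[int, int]] = {
    "rs1799963": (110, 46),
    "rs6025": (114, 46),
    "rs6046": (75, 46),
    "rs1126643": (81, 46),
    "rs2234693": (110, 106),
    "rs1042714": (81, 46),
    "Intron-4 VNTR": (102, 46),
    "rs1799752": (100, 46),
    "rs1801133": (114, 46),
    "14718": (106, 106),
    "rs2227306": (114, 106),
    "rs1800896": (114, 106),
}


def replik_template_config(seed: int = 0) -> SimulationConfig:
    """Frequency-matched config reproducing the study cohort's structure.

    114 cases / 106 controls, the 12 scored variants with their printed
    per-group effect-allele frequencies, and the printed per-variant
    genotyped counts (from 75/46 for rs6046 up to the fully typed 114/106
    for rs2227306 and rs1800896).
    """
    return SimulationConfig(
        n_cases=114,
        n_controls=106,
        mode=SimulationMode.FREQUENCY_MATCHED,
        eaf_cases=dict(TEMPLATE_EAF_CASES),
        eaf_controls=dict(TEMPLATE_EAF_CONTROLS),
        genotyped_counts=dict(TEMPLATE_GENOTYPED_COUNTS),
        seed=seed,
    )
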
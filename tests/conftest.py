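from __future__ import annotations

import numpy as np
import pytest

from grspanel.panel import apply_ld_exclusion, build_default_panel
from grspanel.simulate import (
    Cohort,
    inject_missingness,
    replik_template_config,
    simulate_frequency_matched,
)


@pytest.fixture(scope="session")
def default_panel():
    return build_default_panel()


@pytest.fixture(scope="session")
def panel12(default_panel):
    return apply_ld_exclusion(default_panel)


@pytest.fixture()
def template_cohort():
    """One seeded REPLIK-template cohort with the printed missingness pattern."""
    cfg = replik_template_config(1)
    rng = np.random.default_rng(1)
    cohort = simulate_frequency_matched(cfg, rng)
    return inject_missingness(cohort, cfg.genotyped_counts, rng)


def make_cohort(dosages_cases, dosages_controls, variant_id="v1") -> Cohort:
    """Tiny single-variant cohort from explicit dosage lists."""
    d = np.array(list(dosages_cases) + list(dosages_controls), dtype=float)
    y = np.r_[np.ones(len(dosages_cases), dtype=np.int8),
              np.zeros(len(dosages_controls), dtype=np.int8)]
    ids = [f"s{i}" for i in range(len(d))]
    return Cohort(ids, y, [variant_id], d[:, None])
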
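"""End-to-end orchestration: simulate/load -> associate -> score -> ROC.

One seed governs every source of randomness through a single
``numpy.random.SeedSequence``; each stage draws from its own
deterministically derived substream, so the full run is bit-reproducible
and stages can be re-run independently.  The run manifest records the
seed, configuration echo, package version and per-stage status, enough to
re-run the pipeline identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .association import run_panel_association
from .grs import run_grs_sensitivity
from .io import (
    write_assoc_table,
    write_genotype_table,
    write_roc_tables,
    write_scores_table,
    write_sensitivity_table,
)
from .panel import Scheme, VariantDef, apply_ld_exclusion, build_default_panel, read_panel
from .roc import roc_curve
from .simulate import (
    Cohort,
    SimulationConfig,
    inject_missingness,
    simulate_frequency_matched,
    simulate_logistic,
    SimulationMode,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

_STAGES = ("simulate", "association", "grs", "roc")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the manifest flags partial outputs."""


@dataclass
class RunConfig:
    out_dir: str | Path
    seed: int = 0
    genotypes: str | Path | None = None
    sim_config: SimulationConfig | None = None
    panel_path: str | Path | None = None
    roc_scheme: Scheme = Scheme.PUBLISHED_MIXED
    ci_method: str = "delong"
    standardize: bool = False

    def __post_init__(self) -> None:
        self.roc_scheme = Scheme(self.roc_scheme)
        if (self.genotypes is None) == (self.sim_config is None):
            raise ValueError(
                "exactly one of genotypes / sim_config must be provided"
            )


def _substream(seed: int, stage: str) -> np.random.Generator:
    idx = _STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(len(_STAGES))[idx])


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all artifacts under ``out_dir``.

    Outputs: ``genotypes.tsv`` (simulated runs), ``association.tsv``,
    ``scores_<scheme>.tsv`` x3, ``grs_sensitivity.tsv``,
    ``roc_<scheme>_points.tsv``/``_summary.tsv`` for each scheme, and
    ``manifest.json``.  Returns the manifest dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "grspanel",
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": [],
        "config": {
            "genotypes": str(config.genotypes) if config.genotypes else None,
            "simulated": config.sim_config is not None,
            "panel_path": str(config.panel_path) if config.panel_path else None,
            "roc_scheme": config.roc_scheme.value,
            "ci_method": config.ci_method,
            "standardize": config.standardize,
        },
    }

    def _done(stage: str, status: str = "ok") -> None:
        manifest["stages"][stage] = status

    def _write_manifest() -> None:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    try:
        # ---- input stage -------------------------------------------------
        if config.sim_config is not None:
            rng = _substream(config.seed, "simulate")
            sc = config.sim_config
            if sc.mode is SimulationMode.FREQUENCY_MATCHED:
                cohort = simulate_frequency_matched(sc, rng)
            else:
                cohort = simulate_logistic(sc, rng)
            if sc.genotyped_counts:
                cohort = inject_missingness(cohort, sc.genotyped_counts, rng)
            write_genotype_table(cohort, out / "genotypes.tsv")
            manifest["outputs"].append("genotypes.tsv")
            manifest["config"]["sim"] = {
                "n_cases": sc.n_cases, "n_controls": sc.n_controls,
                "mode": sc.mode.value, "seed": sc.seed,
            }
        else:
            from .io import read_genotype_table

            cohort = read_genotype_table(config.genotypes)
        _done("simulate")

        panel = (read_panel(config.panel_path) if config.panel_path
                 else build_default_panel())
        panel12 = apply_ld_exclusion(panel)

        # ---- per-variant association ------------------------------------
        assoc = run_panel_association(cohort, panel12)
        write_assoc_table(assoc, out / "association.tsv", panel12)
        manifest["outputs"].append("association.tsv")
        _done("association")

        # ---- GRS sensitivity ---------------------------------------------
        study_betas = {r.variant_id: r.beta for r in assoc if r.ok}
        fits = run_grs_sensitivity(cohort, panel12, study_betas,
                                   standardize=config.standardize)
        for scheme, fit in fits.items():
            fname = f"scores_{scheme.value}.tsv"
            write_scores_table(fit.scores, out / fname)
            manifest["outputs"].append(fname)
        write_sensitivity_table(fits, out / "grs_sensitivity.tsv")
        manifest["outputs"].append("grs_sensitivity.tsv")
        _done("grs")

        # ---- ROC per scheme ----------------------------------------------
        rng = _substream(config.seed, "roc")
        for scheme, fit in fits.items():
            curve = roc_curve(fit.scores.corrected_score, fit.scores.phenotype,
                              ci=config.ci_method, rng=rng)
            pts, summ = write_roc_tables(curve, out / f"roc_{scheme.value}")
            manifest["outputs"] += [Path(pts).name, Path(summ).name]
        _done("roc")
    except Exception as exc:
        for stage in _STAGES:
            manifest["stages"].setdefault(stage, "not_run")
        failed = next(s for s in _STAGES if manifest["stages"][s] != "ok")
        manifest["stages"][failed] = f"failed: {exc}"
        _write_manifest()
        raise PipelineError(f"stage {failed!r} failed: {exc}") from exc

    _write_manifest()
    manifest["outputs"].append("manifest.json")
    return manifest
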
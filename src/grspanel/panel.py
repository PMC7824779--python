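"""Candidate-variant panel and weighting schemes for the RPL risk score.

The default panel holds the 13 variants genotyped in the REPLIK
(Recurrent Pregnancy Loss in Kiev) case-control study, spanning five
biological pathways implicated in pregnancy maintenance: blood coagulation
(F2, F5, F7, GP1A), hormonal regulation (ESR1, ADRB2), endometrial and
placental function (ENOS, ACE), folate metabolism (MTHFR) and inflammatory
response (IL6, IL8, IL10).  One of the two IL10 promoter SNPs (rs1800872)
is in strong LD with rs1800896 and is flagged for exclusion, leaving the
12-variant panel the genetic risk score is built on.

Weights for the score are log odds ratios.  Three schemes are supported:

``published_mixed``
    log(OR) from prior association studies where an ethnically usable
    published estimate exists (F2, F5, ESR1, ACE, MTHFR), substituted by
    in-study effect estimates otherwise.
``study``
    all weights taken from the in-study per-variant fits.
``unit``
    every weight 1, i.e. an unweighted risk-allele count.

Every operation accepts arbitrary user-supplied panels, so the machinery
generalises beyond the RPL panel; the fixture is just a well-tested default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VariantClass",
    "Population",
    "Scheme",
    "WeightSource",
    "VariantDef",
    "WeightScheme",
    "PanelError",
    "MalformedPanelError",
    "WeightConfigError",
    "build_default_panel",
    "apply_ld_exclusion",
    "weight_from_or",
    "build_weight_scheme",
    "read_panel",
    "write_panel",
]


class PanelError(ValueError):
    """Base class for panel construction/validation problems."""


class MalformedPanelError(PanelError):
    """Panel violates a structural requirement (e.g. missing the LD pair)."""


class WeightConfigError(PanelError):
    """A weight scheme cannot be built from the supplied inputs."""


class VariantClass(str, Enum):
    SNP = "SNP"
    INDEL = "indel"
    VNTR = "VNTR"
    STR = "STR"


class Population(str, Enum):
    """Ancestry of the population behind a published odds ratio."""

    EUROPEAN = "european"
    NON_EUROPEAN = "non_european"
    MULTI_ETHNIC = "multi_ethnic"
    NONE = "none"


class Scheme(str, Enum):
    PUBLISHED_MIXED = "published_mixed"
    STUDY = "study"
    UNIT = "unit"


class WeightSource(str, Enum):
    PUBLISHED = "published"
    STUDY = "study"
    UNIT = "unit"


@dataclass(frozen=True)
class VariantDef:
    """One panel entry.

    Parameters
    ----------
    variant_id
        rsID or conventional label (e.g. ``"Intron-4 VNTR"``, ``"14718"``).
    locus_name
        Gene symbol.
    chrom_pos
        ``chrom:pos`` string as conventionally printed; ``"NA"`` if unknown.
    effect_allele, other_allele
        Single-token allele labels; dosage counts copies of the effect
        allele.  Non-SNP variants use their conventional two-allele coding
        (e.g. ``D``/``I`` for an indel, ``B``/``A`` for a VNTR).
    published_or
        Odds ratio from a prior association study, or ``None`` when no
        prior study of this variant and the outcome exists.
    published_population
        Ancestry flag of the published estimate.
    ld_excluded
        True for variants dropped from the risk score because of LD with
        another panel member.
    use_published_weight
        Whether ``published_mixed`` weighting may use the published OR.
        ``None`` means "automatic": use it whenever ``published_or`` is
        present.  Set False for variants whose published estimate comes
        from a population too discordant from the study sample.
    """

    variant_id: str
    locus_name: str
    chrom_pos: str
    effect_allele: str
    other_allele: str
    variant_class: VariantClass = VariantClass.SNP
    published_or: float | None = None
    published_population: Population = Population.NONE
    ld_excluded: bool = False
    use_published_weight: bool | None = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise MalformedPanelError(
                f"{self.variant_id}: effect and other allele are identical "
                f"({self.effect_allele!r})"
            )
        if self.published_or is not None and self.published_or <= 0:
            raise MalformedPanelError(
                f"{self.variant_id}: published OR must be positive, "
                f"got {self.published_or}"
            )

    @property
    def weight_source(self) -> WeightSource:
        """Where ``published_mixed`` weighting takes this variant's weight from."""
        if self.use_published_weight is None:
            usable = self.published_or is not None
        else:
            usable = self.use_published_weight and self.published_or is not None
        return WeightSource.PUBLISHED if usable else WeightSource.STUDY


@dataclass(frozen=True)
class WeightScheme:
    """Resolved per-variant log-odds weights for one scheme."""

    scheme: Scheme
    weights: Mapping[str, float]
    source: Mapping[str, WeightSource]

    def __post_init__(self) -> None:
        if set(self.weights) != set(self.source):
            raise WeightConfigError("weights and source must cover the same variants")
        if self.scheme is Scheme.UNIT and any(w != 1.0 for w in self.weights.values()):
            raise WeightConfigError("unit scheme requires every weight to equal 1")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.weights)


# Published ORs and ancestry flags follow the study's summary of prior
# association studies; alleles and positions follow the study's own
# association table (its effect-allele orientation defines the dosage).
_DEFAULT_PANEL: tuple[VariantDef, ...] = (
    VariantDef("rs1799963", "F2", "11:46761055", "A", "G", VariantClass.SNP,
               2.00, Population.EUROPEAN),
    VariantDef("rs6025", "F5", "1:169519049", "A", "G", VariantClass.SNP,
               2.5, Population.MULTI_ETHNIC),
    VariantDef("rs6046", "F7", "13:113773159", "G", "A", VariantClass.SNP,
               None, Population.NONE),
    VariantDef("rs1126643", "GP1A", "5:52347369", "C", "T", VariantClass.SNP,
               None, Population.NONE),
    VariantDef("rs2234693", "ESR1", "6:152163335", "T", "C", VariantClass.SNP,
               1.10, Population.NON_EUROPEAN),
    VariantDef("rs1042714", "ADRB2", "5:148206473", "C", "G", VariantClass.SNP,
               None, Population.NONE),
    VariantDef("Intron-4 VNTR", "ENOS", "15:35147732-35262040", "B", "A",
               VariantClass.VNTR, 1.005, Population.NON_EUROPEAN,
               use_published_weight=False),
    VariantDef("rs1799752", "ACE", "17:61565890", "D", "I", VariantClass.INDEL,
               2.06, Population.MULTI_ETHNIC),
    VariantDef("rs1801133", "MTHFR", "1:11856378", "T", "C", VariantClass.SNP,
               1.25, Population.MULTI_ETHNIC),
    VariantDef("14718", "IL6", "7:22766840", "G", "C", VariantClass.STR,
               1.214, Population.MULTI_ETHNIC, use_published_weight=False),
    VariantDef("rs2227306", "IL8", "4:74607055", "T", "C", VariantClass.SNP,
               None, Population.NONE),
    VariantDef("rs1800896", "IL10", "1:206946897", "A", "G", VariantClass.SNP,
               1.27, Population.NON_EUROPEAN, use_published_weight=False),
    VariantDef("rs1800872", "IL10", "NA", "T", "G", VariantClass.SNP,
               3.01, Population.EUROPEAN, ld_excluded=True),
)

_IL10_PAIR = ("rs1800872", "rs1800896")


def build_default_panel() -> list[VariantDef]:
    """Return the 13-variant RPL candidate panel.

    Exactly one entry (rs1800872) is flagged ``ld_excluded``; exactly four
    entries (F7, GP1A, ADRB2, IL8) carry no published odds ratio because no
    prior study of their association with the outcome exists.
    """
    return list(_DEFAULT_PANEL)


def apply_ld_exclusion(
    panel: Sequence[VariantDef], *, strict: bool = True
) -> list[VariantDef]:
    """Drop variants flagged as LD-excluded.

    With ``strict=True`` (default) the panel must contain at least one of
    the IL10 LD pair (rs1800872 / rs1800896); a panel that lost both is
    considered malformed.  Pass ``strict=False`` for panels unrelated to
    the default RPL set.
    """
    ids = {v.variant_id for v in panel}
    if strict and not ids & set(_IL10_PAIR):
        raise MalformedPanelError(
            "panel contains neither rs1800872 nor rs1800896; pass strict=False "
            "if this is intentionally not the RPL panel"
        )
    return [v for v in panel if not v.ld_excluded]


def weight_from_or(or_value: float) -> float:
    """Natural log of an odds ratio: the log-additive per-allele weight."""
    if not or_value > 0:
        raise ValueError(f"odds ratio must be positive, got {or_value}")
    return math.log(or_value)


def build_weight_scheme(
    panel12: Sequence[VariantDef],
    scheme: Scheme | str,
    study_betas: Mapping[str, float] | None = None,
) -> WeightScheme:
    """Resolve per-variant weights for a scoring panel.

    Parameters
    ----------
    panel12
        The scoring panel *after* LD exclusion; passing a panel that still
        contains excluded entries is a configuration error.
    scheme
        ``published_mixed``, ``study`` or ``unit``.
    study_betas
        In-study log-odds estimates, keyed by variant_id.  Required for the
        ``study`` scheme (all variants) and for ``published_mixed``
        (variants whose source resolves to study).
    """
    scheme = Scheme(scheme)
    excluded = [v.variant_id for v in panel12 if v.ld_excluded]
    if excluded:
        raise WeightConfigError(
            f"scoring panel still contains LD-excluded variants: {excluded}; "
            "apply_ld_exclusion first"
        )
    ids = [v.variant_id for v in panel12]
    if len(set(ids)) != len(ids):
        raise MalformedPanelError("duplicate variant_id in panel")

    weights: dict[str, float] = {}
    source: dict[str, WeightSource] = {}
    if scheme is Scheme.UNIT:
        for vid in ids:
            weights[vid] = 1.0
            source[vid] = WeightSource.UNIT
        return WeightScheme(scheme, weights, source)

    for v in panel12:
        use_study = scheme is Scheme.STUDY or v.weight_source is WeightSource.STUDY
        if use_study:
            if study_betas is None or v.variant_id not in study_betas:
                raise WeightConfigError(
                    f"{v.variant_id}: study weight required for scheme "
                    f"{scheme.value!r} but no study beta supplied"
                )
            beta = float(study_betas[v.variant_id])
            if not math.isfinite(beta):
                raise WeightConfigError(
                    f"{v.variant_id}: study beta is not finite ({beta})"
                )
            weights[v.variant_id] = beta
            source[v.variant_id] = WeightSource.STUDY
        else:
            assert v.published_or is not None
            weights[v.variant_id] = weight_from_or(v.published_or)
            source[v.variant_id] = WeightSource.PUBLISHED
    return WeightScheme(scheme, weights, source)


# ---------------------------------------------------------------------------
# Panel TSV interface
#
# Columns: variant_id, locus, effect_allele, other_allele, variant_class,
# published_or (empty or "." = absent), population, ld_excluded (0/1) and an
# optional weight_rule column (published|study|auto) that records whether the
# mixed weighting may use the published OR.

_PANEL_COLUMNS = [
    "variant_id", "locus", "effect_allele", "other_allele", "variant_class",
    "published_or", "population", "ld_excluded", "weight_rule",
]


def write_panel(panel: Iterable[VariantDef], path) -> None:
    """Write a panel as a UTF-8 TSV with mandatory header."""
    rows = []
    for v in panel:
        if v.use_published_weight is None:
            rule = "auto"
        else:
            rule = "published" if v.use_published_weight else "study"
        rows.append({
            "variant_id": v.variant_id,
            "locus": v.locus_name,
            "effect_allele": v.effect_allele,
            "other_allele": v.other_allele,
            "variant_class": v.variant_class.value,
            "published_or": "" if v.published_or is None else repr(v.published_or),
            "population": v.published_population.value,
            "ld_excluded": int(v.ld_excluded),
            "weight_rule": rule,
            "chrom_pos": v.chrom_pos,
        })
    df = pd.DataFrame(rows, columns=_PANEL_COLUMNS + ["chrom_pos"])
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_panel(path) -> list[VariantDef]:
    """Read a panel TSV written by :func:`write_panel` (or hand-authored)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     encoding="utf-8")
    required = set(_PANEL_COLUMNS) - {"weight_rule"}
    missing = required - set(df.columns)
    if missing:
        raise MalformedPanelError(f"panel file missing columns: {sorted(missing)}")
    panel: list[VariantDef] = []
    for i, row in df.iterrows():
        or_token = row["published_or"].strip()
        published_or = None if or_token in ("", ".") else float(or_token)
        rule_token = row.get("weight_rule", "auto") or "auto"
        if rule_token == "auto":
            use_published = None
        elif rule_token == "published":
            use_published = True
        elif rule_token == "study":
            use_published = False
        else:
            raise MalformedPanelError(
                f"row {i}: unknown weight_rule {rule_token!r}"
            )
        try:
            panel.append(VariantDef(
                variant_id=row["variant_id"],
                locus_name=row["locus"],
                chrom_pos=row.get("chrom_pos", "NA") or "NA",
                effect_allele=row["effect_allele"],
                other_allele=row["other_allele"],
                variant_class=VariantClass(row["variant_class"]),
                published_or=published_or,
                published_population=Population(row["population"] or "none"),
                ld_excluded=row["ld_excluded"].strip() in ("1", "true", "True"),
                use_published_weight=use_published,
            ))
        except ValueError as exc:
            raise MalformedPanelError(f"row {i}: {exc}") from exc
    return panel
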
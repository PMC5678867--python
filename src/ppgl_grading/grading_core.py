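"""Clinical classifiers and the three PPGL scoring engines.

Pheochromocytomas and paragangliomas (PPGL) are catecholamine-secreting
neuroendocrine tumors whose malignancy can only be declared once metastases
appear, so histopathological scores are used at the initial operation to
stratify metastatic risk.  This module implements the three systems side by
side:

* **GAPP** — Grading system for Adrenal Pheochromocytoma and Paraganglioma:
  a 0-10 point sum over histological pattern (large/irregular nests +1,
  pseudorosettes +1), comedo-type necrosis (+2), cellularity (moderate +1 /
  high +2), Ki-67 labeling index (1-3% +1, >3% +2), vascular or capsular
  invasion (+1) and catecholamine secretory type (noradrenergic +1).
  Totals map to well (0-2), moderately (3-6) and poorly (7-10)
  differentiated classes.
* **PASS** — Pheochromocytoma of the Adrenal Scaled Score: a 0-20 point
  weighted sum of 12 histological features; a PASS >= 4 flags increased
  metastatic potential.
* **M-GAPP** — a modified GAPP that drops the weakly associated GAPP items
  (cellularity, capsular invasion) and adds loss of SDHB
  immunohistochemical staining, a surrogate for SDHx mutation.  Six binary
  parameters, one point each by default, dichotomized at >= 3.

All scoring functions are deterministic, total on complete inputs, and
raise :class:`~ppgl_grading.errors.MissingDataError` rather than silently
scoring a missing feature as absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional

import yaml

from .errors import ConfigError, DomainError, MissingDataError

__all__ = [
    "CatecholamineType",
    "Cellularity",
    "GappClass",
    "MetastasisTiming",
    "Sex",
    "TumorSite",
    "PASS_ITEMS",
    "PASS_WEIGHTS",
    "MGAPP_PARAMETERS",
    "BiochemistryProfile",
    "HistologyProfile",
    "PatientRecord",
    "ScorePanel",
    "ScoringConfig",
    "classify_catecholamine_type",
    "classify_gapp_differentiation",
    "classify_metastasis_timing",
    "classify_mgapp",
    "classify_pass",
    "compute_score_panel",
    "score_gapp",
    "score_mgapp",
    "score_pass",
]


class CatecholamineType(str, Enum):
    """Secretory phenotype from 24-h urinary fractionated metanephrines."""

    NON_FUNCTIONING = "non_functioning"
    ADRENERGIC = "adrenergic"
    NORADRENERGIC = "noradrenergic"


class Cellularity(str, Enum):
    """Cellularity class (cells per unit area: low <150, moderate 150-250, high >250)."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class GappClass(str, Enum):
    """GAPP differentiation class."""

    WD = "WD"  # well differentiated, score 0-2
    MD = "MD"  # moderately differentiated, score 3-6
    PD = "PD"  # poorly differentiated, score 7-10


class MetastasisTiming(str, Enum):
    SYNCHRONOUS = "synchronous"  # < 6 months from primary diagnosis
    METACHRONOUS = "metachronous"  # >= 6 months


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class TumorSite(str, Enum):
    PHEO = "PHEO"  # adrenal pheochromocytoma
    PGL = "PGL"  # extra-adrenal paraganglioma


# The 12 PASS items with their published weights (eight 2-point items and
# four 1-point items; maximum 20).  Vascular and capsular invasion are
# shared with the GAPP invasion item and live on HistologyProfile itself.
PASS_WEIGHTS: dict[str, int] = {
    "large_nests_or_diffuse_growth": 2,
    "central_or_confluent_necrosis": 2,
    "high_cellularity": 2,
    "cellular_monotony": 2,
    "tumor_cell_spindling": 2,
    "mitotic_count_gt3_per_10hpf": 2,
    "atypical_mitotic_figures": 2,
    "extension_into_adipose_tissue": 2,
    "vascular_invasion": 1,
    "capsular_invasion": 1,
    "profound_nuclear_pleomorphism": 1,
    "nuclear_hyperchromasia": 1,
}
PASS_ITEMS: tuple[str, ...] = tuple(PASS_WEIGHTS)
_SHARED_PASS_ITEMS = ("vascular_invasion", "capsular_invasion")
_OWN_PASS_ITEMS = tuple(k for k in PASS_ITEMS if k not in _SHARED_PASS_ITEMS)

#: The six M-GAPP parameters, in reporting order.
MGAPP_PARAMETERS: tuple[str, ...] = (
    "irregular_nest_or_pseudorosette",
    "comedo_necrosis",
    "vascular_invasion",
    "ki67_ge_1pct",
    "noradrenergic_type",
    "sdhb_loss",
)


@dataclass(frozen=True)
class BiochemistryProfile:
    """24-h urinary fractionated metanephrine (UMN) / normetanephrine (UNM).

    Elevation flags are judged upstream against symptom-dependent reference
    thresholds; only the flags are consumed here.  A tumor is functional
    when either metabolite is elevated.
    """

    umn_ug_day: Optional[float] = None
    unm_ug_day: Optional[float] = None
    umn_elevated: Optional[bool] = None
    unm_elevated: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("umn_ug_day", "unm_ug_day"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise DomainError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class HistologyProfile:
    """All slide-level parameters consumed by the three scoring systems.

    ``vascular_invasion`` and ``capsular_invasion`` are stored once and
    shared between the GAPP invasion item and the corresponding PASS items;
    the :attr:`pass_features` property always exposes the full 12-item map.
    """

    large_irregular_nest: Optional[bool] = None
    pseudorosette: Optional[bool] = None
    comedo_necrosis: Optional[bool] = None
    cellularity_class: Optional[Cellularity] = None
    ki67_percent: Optional[float] = None
    vascular_invasion: Optional[bool] = None
    capsular_invasion: Optional[bool] = None
    sdhb_ihc_positive: Optional[bool] = None
    pass_features_own: Mapping[str, Optional[bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ki67_percent is not None and not 0 <= self.ki67_percent <= 100:
            raise DomainError(
                f"ki67_percent must lie in [0, 100], got {self.ki67_percent}"
            )
        feats = dict(self.pass_features_own)
        for key in _SHARED_PASS_ITEMS:
            if key in feats:
                shared = getattr(self, key)
                if feats[key] is not None and shared is not None and feats[key] != shared:
                    raise DomainError(
                        f"pass feature {key!r} conflicts with the shared invasion flag"
                    )
                feats.pop(key)
        unknown = set(feats) - set(_OWN_PASS_ITEMS)
        if unknown:
            raise DomainError(f"unknown PASS features: {sorted(unknown)}")
        object.__setattr__(self, "pass_features_own", feats)

    @property
    def pass_features(self) -> dict[str, Optional[bool]]:
        """The 12 PASS items, merging the shared invasion flags."""
        out: dict[str, Optional[bool]] = {k: self.pass_features_own.get(k) for k in _OWN_PASS_ITEMS}
        out["vascular_invasion"] = self.vascular_invasion
        out["capsular_invasion"] = self.capsular_invasion
        return {k: out[k] for k in PASS_ITEMS}


@dataclass(frozen=True)
class PatientRecord:
    """One subject: demographics, biochemistry, histology and outcome.

    ``time_to_metastasis_months`` is present iff ``metastasis`` is true and
    measures metastasis-free survival (surgery to first metastasis).  It is
    *not* required to be below ``followup_months``: follow-up continues
    after a metastasis is found.
    """

    patient_id: str
    biochemistry: BiochemistryProfile
    histology: HistologyProfile
    metastasis: bool
    followup_months: float
    time_to_metastasis_months: Optional[float] = None
    age_years: Optional[float] = None
    sex: Optional[Sex] = None
    height_cm: Optional[float] = None
    weight_kg: Optional[float] = None
    bmi: Optional[float] = None
    tumor_site: Optional[TumorSite] = None
    tumor_size_cm: Optional[float] = None
    familial: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.followup_months < 0:
            raise DomainError("followup_months must be >= 0")
        if self.metastasis and self.time_to_metastasis_months is None:
            raise DomainError(
                "metastatic record requires time_to_metastasis_months"
            )
        if not self.metastasis and self.time_to_metastasis_months is not None:
            raise DomainError(
                "non-metastatic record must not carry time_to_metastasis_months"
            )
        if self.time_to_metastasis_months is not None and self.time_to_metastasis_months < 0:
            raise DomainError("time_to_metastasis_months must be >= 0")

    @property
    def mfs_time_months(self) -> float:
        """Observed metastasis-free survival time (event or censoring)."""
        if self.metastasis:
            return float(self.time_to_metastasis_months)  # type: ignore[arg-type]
        return float(self.followup_months)


@dataclass(frozen=True)
class ScorePanel:
    """The three scores plus their categorical classifications for one subject."""

    gapp_score: int
    gapp_class: GappClass
    pass_score: int
    pass_high: bool
    mgapp_score: int
    mgapp_high: bool
    catecholamine_type: CatecholamineType


_DEFAULT_GAPP_WEIGHTS = {
    "large_irregular_nest": 1,
    "pseudorosette": 1,
    "comedo_necrosis": 2,
    "cellularity_moderate": 1,
    "cellularity_high": 2,
    "ki67_1_to_3": 1,
    "ki67_gt_3": 2,
    "invasion": 1,
    "noradrenergic": 1,
}


@dataclass(frozen=True)
class ScoringConfig:
    """Score weights and classification thresholds, all overridable.

    The M-GAPP point scheme is not nailed down by its source beyond the
    parameter list, the observed medians and the >= 3 cutoff; the default of
    one point per parameter (range 0-6) is consistent with all three and is
    recorded in pipeline metadata so any reweighting is traceable.
    """

    gapp_weights: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_GAPP_WEIGHTS)
    )
    pass_weights: Mapping[str, int] = field(default_factory=lambda: dict(PASS_WEIGHTS))
    mgapp_weights: Mapping[str, int] = field(
        default_factory=lambda: {p: 1 for p in MGAPP_PARAMETERS}
    )
    pass_cutoff: int = 4
    mgapp_cutoff: int = 3
    gapp_wd_max: int = 2
    gapp_md_max: int = 6
    gapp_max: int = 10
    timing_cutoff_months: float = 6.0

    def __post_init__(self) -> None:
        for section_name, section, expected in (
            ("gapp", self.gapp_weights, set(_DEFAULT_GAPP_WEIGHTS)),
            ("pass", self.pass_weights, set(PASS_ITEMS)),
            ("mgapp", self.mgapp_weights, set(MGAPP_PARAMETERS)),
        ):
            if set(section) != expected:
                raise ConfigError(
                    f"{section_name} weights must have exactly the keys {sorted(expected)}"
                )
            for k, w in section.items():
                if not isinstance(w, int) or w < 0:
                    raise ConfigError(
                        f"{section_name} weight {k!r} must be a non-negative integer, got {w!r}"
                    )
        if not 0 <= self.gapp_wd_max < self.gapp_md_max < self.gapp_max:
            raise ConfigError("GAPP class bands must be ordered 0 <= WD < MD < max")

    @classmethod
    def from_yaml(cls, path) -> "ScoringConfig":
        """Load overrides from a flat YAML config (one section per system)."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for section, attr in (("gapp", "gapp_weights"), ("pass", "pass_weights"), ("mgapp", "mgapp_weights")):
            if section in raw:
                base = dict(getattr(cls(), attr))
                base.update(raw[section])
                kwargs[attr] = base
        for key in ("pass_cutoff", "mgapp_cutoff", "gapp_wd_max", "gapp_md_max", "gapp_max", "timing_cutoff_months"):
            if key in raw.get("thresholds", {}):
                kwargs[key] = raw["thresholds"][key]
        return cls(**kwargs)

    def with_mgapp_weights(self, weights: Mapping[str, int]) -> "ScoringConfig":
        merged = dict(self.mgapp_weights)
        merged.update(weights)
        return replace(self, mgapp_weights=merged)


DEFAULT_CONFIG = ScoringConfig()


def _require(value, field_name: str):
    if value is None:
        raise MissingDataError(field_name)
    return value


def classify_catecholamine_type(bio: BiochemistryProfile) -> CatecholamineType:
    """Secretory type from the urinary metanephrine elevation flags.

    Elevated UMN (with or without elevated UNM) is adrenergic; elevated UNM
    without elevated UMN is noradrenergic; neither elevated is a
    non-functioning tumor.
    """
    umn = _require(bio.umn_elevated, "umn_elevated")
    unm = _require(bio.unm_elevated, "unm_elevated")
    if umn:
        return CatecholamineType.ADRENERGIC
    if unm:
        return CatecholamineType.NORADRENERGIC
    return CatecholamineType.NON_FUNCTIONING


def is_functional(bio: BiochemistryProfile) -> bool:
    """A tumor is functional when UMN or UNM is elevated."""
    return classify_catecholamine_type(bio) is not CatecholamineType.NON_FUNCTIONING


def score_gapp(
    h: HistologyProfile,
    ctype: CatecholamineType,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> int:
    """GAPP total score (default weights: 0-10).

    The two histological-pattern items are additive — a tumor showing both
    large/irregular nests and pseudorosettes collects both points, which is
    what makes the stated maximum of 10 attainable.
    """
    w = config.gapp_weights
    score = 0
    if _require(h.large_irregular_nest, "large_irregular_nest"):
        score += w["large_irregular_nest"]
    if _require(h.pseudorosette, "pseudorosette"):
        score += w["pseudorosette"]
    if _require(h.comedo_necrosis, "comedo_necrosis"):
        score += w["comedo_necrosis"]
    cellularity = _require(h.cellularity_class, "cellularity_class")
    if cellularity is Cellularity.MODERATE:
        score += w["cellularity_moderate"]
    elif cellularity is Cellularity.HIGH:
        score += w["cellularity_high"]
    ki67 = _require(h.ki67_percent, "ki67_percent")
    if 1 <= ki67 <= 3:
        score += w["ki67_1_to_3"]
    elif ki67 > 3:
        score += w["ki67_gt_3"]
    if _require(h.vascular_invasion, "vascular_invasion") or _require(
        h.capsular_invasion, "capsular_invasion"
    ):
        score += w["invasion"]
    if ctype is CatecholamineType.NORADRENERGIC:
        score += w["noradrenergic"]
    return score


def classify_gapp_differentiation(
    score: int, config: ScoringConfig = DEFAULT_CONFIG
) -> GappClass:
    """Map a GAPP score to WD (0-2), MD (3-6) or PD (7-10)."""
    if not 0 <= score <= config.gapp_max:
        raise DomainError(f"GAPP score must lie in [0, {config.gapp_max}], got {score}")
    if score <= config.gapp_wd_max:
        return GappClass.WD
    if score <= config.gapp_md_max:
        return GappClass.MD
    return GappClass.PD


def score_pass(h: HistologyProfile, config: ScoringConfig = DEFAULT_CONFIG) -> int:
    """PASS weighted sum over the 12 items (default weights: 0-20)."""
    features = h.pass_features
    score = 0
    for item in PASS_ITEMS:
        present = features[item]
        if present is None:
            raise MissingDataError(item, "PASS item")
        if present:
            score += config.pass_weights[item]
    return score


def classify_pass(score: int, config: ScoringConfig = DEFAULT_CONFIG) -> bool:
    """True iff PASS >= 4 (increased metastatic potential)."""
    max_pass = sum(config.pass_weights.values())
    if not 0 <= score <= max_pass:
        raise DomainError(f"PASS must lie in [0, {max_pass}], got {score}")
    return score >= config.pass_cutoff


def mgapp_parameter_flags(
    h: HistologyProfile, ctype: CatecholamineType
) -> dict[str, bool]:
    """Presence of each of the six M-GAPP parameters.

    Unlike GAPP, only vascular (not capsular) invasion counts, the two
    pattern features form one combined item, and Ki-67 is dichotomized at
    >= 1%.  SDHB loss means no definite granular cytoplasmic staining.
    """
    return {
        "irregular_nest_or_pseudorosette": bool(
            _require(h.large_irregular_nest, "large_irregular_nest")
            or _require(h.pseudorosette, "pseudorosette")
        ),
        "comedo_necrosis": bool(_require(h.comedo_necrosis, "comedo_necrosis")),
        "vascular_invasion": bool(_require(h.vascular_invasion, "vascular_invasion")),
        "ki67_ge_1pct": _require(h.ki67_percent, "ki67_percent") >= 1,
        "noradrenergic_type": ctype is CatecholamineType.NORADRENERGIC,
        "sdhb_loss": not _require(h.sdhb_ihc_positive, "sdhb_ihc_positive"),
    }


def score_mgapp(
    h: HistologyProfile,
    ctype: CatecholamineType,
    config: ScoringConfig = DEFAULT_CONFIG,
) -> int:
    """M-GAPP weighted sum over its six parameters (default weights: 0-6)."""
    flags = mgapp_parameter_flags(h, ctype)
    return sum(config.mgapp_weights[p] for p in MGAPP_PARAMETERS if flags[p])


def classify_mgapp(score: int, cutoff: int = 3) -> bool:
    """True iff the M-GAPP score reaches the cutoff (default >= 3, the
    Youden-optimal threshold)."""
    if score < 0:
        raise DomainError(f"M-GAPP score must be >= 0, got {score}")
    return score >= cutoff


def classify_metastasis_timing(
    time_months: float, config: ScoringConfig = DEFAULT_CONFIG
) -> MetastasisTiming:
    """Synchronous (< 6 months after primary diagnosis) vs metachronous (>= 6)."""
    if time_months < 0:
        raise DomainError(f"time to metastasis must be >= 0, got {time_months}")
    if time_months < config.timing_cutoff_months:
        return MetastasisTiming.SYNCHRONOUS
    return MetastasisTiming.METACHRONOUS


def compute_score_panel(
    record: PatientRecord, config: ScoringConfig = DEFAULT_CONFIG
) -> ScorePanel:
    """All three scores and classifications for one subject."""
    ctype = classify_catecholamine_type(record.biochemistry)
    gapp = score_gapp(record.histology, ctype, config)
    pss = score_pass(record.histology, config)
    mg = score_mgapp(record.histology, ctype, config)
    return ScorePanel(
        gapp_score=gapp,
        gapp_class=classify_gapp_differentiation(gapp, config),
        pass_score=pss,
        pass_high=classify_pass(pss, config),
        mgapp_score=mg,
        mgapp_high=classify_mgapp(mg, config.mgapp_cutoff),
        catecholamine_type=ctype,
    )
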
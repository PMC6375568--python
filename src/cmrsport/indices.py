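"""Body-surface-area indexing, sport indices and cut-off classification.

The sport indices are ratios designed to separate physiological
(athlete's heart) from pathological (HCM) hypertrophy:

* ``EDWT/LVEDVi`` — maximal end-diastolic wall thickness (mm) over the
  BSA-indexed end-diastolic volume (ml/m^2), in mm*m^2/ml;
* ``LVM/LVEDV`` — myocardial mass over (unindexed) end-diastolic
  volume, in g/ml;
* ``TPM%`` — trabecular/papillary mass as a percentage of total
  myocardial mass (threshold-based method only);
* ``max/min EDWT`` — wall asymmetry ratio.

Each index has a configurable strict cut-off above which a subject is
labelled HCM-range; the defaults are the published accuracy-maximizing
cut-offs. Wall thickness between 13 and 16 mm (inclusive) flags the
diagnostic grey zone where the two conditions overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import ValidationError
from .quantify import VolumetricResult
from .wall import WallThicknessResult

GREY_ZONE_MM = (13.0, 16.0)  # inclusive bounds


@dataclass
class SubjectRecord:
    """Demographics of one subject; BSA is computed on construction."""

    id: str
    sex: str  # "M" or "F"
    group: str  # "athlete", "HCM" or "athlete-HCM"
    age: float
    height: float  # cm
    weight: float  # kg
    heart_rate: float  # bpm
    bsa: float = field(init=False)

    def __post_init__(self) -> None:
        self.bsa = compute_bsa(self.height, self.weight)


@dataclass
class SportIndexVector:
    """Per-subject sport indices; units noted per field."""

    max_edwt: float  # mm
    max_min_ratio: float
    edwt_over_lvedvi_cq: float | None = None  # mm*m^2/ml
    edwt_over_lvedvi_tq: float | None = None
    lvm_over_lvedv_cq: float | None = None  # g/ml
    lvm_over_lvedv_tq: float | None = None
    tpm_percent: float | None = None  # %

    def as_dict(self) -> dict[str, float | None]:
        return {
            "max_edwt": self.max_edwt,
            "maxmin_edwt": self.max_min_ratio,
            "edwt_over_lvedvi_cq": self.edwt_over_lvedvi_cq,
            "edwt_over_lvedvi_tq": self.edwt_over_lvedvi_tq,
            "lvm_over_lvedv_cq": self.lvm_over_lvedv_cq,
            "lvm_over_lvedv_tq": self.lvm_over_lvedv_tq,
            "tpm_percent": self.tpm_percent,
        }


@dataclass(frozen=True)
class CutoffRule:
    """Strictly-greater-than cut-off: value > threshold => HCM-range."""

    index: str
    threshold: float


#: Published accuracy-maximizing cut-offs per sport index.
DEFAULT_CUTOFF_RULES: tuple[CutoffRule, ...] = (
    CutoffRule("edwt_over_lvedvi_cq", 0.14),
    CutoffRule("edwt_over_lvedvi_tq", 0.17),
    CutoffRule("lvm_over_lvedv_cq", 0.82),
    CutoffRule("lvm_over_lvedv_tq", 1.27),
    CutoffRule("maxmin_edwt", 2.4),
)

HCM_RANGE = "HCM-range"
ATHLETE_RANGE = "athlete-range"


def compute_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area in m^2 by the Du Bois formula."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValidationError("height and weight must be positive")
    return 0.007184 * height_cm**0.725 * weight_kg**0.425


def index_to_bsa(value: float, bsa: float) -> float:
    """Standardize a volume (ml) or mass (g) to body surface area."""
    if bsa <= 0:
        raise ValidationError("BSA must be positive")
    return value / bsa


def compute_sport_indices(
    wall: WallThicknessResult,
    subject: SubjectRecord,
    cq: VolumetricResult | None = None,
    tq: VolumetricResult | None = None,
) -> SportIndexVector:
    """Assemble the per-subject sport-index vector from method results."""
    if cq is None and tq is None:
        raise ValidationError("at least one quantification result is required")
    vec = SportIndexVector(max_edwt=wall.max_edwt, max_min_ratio=wall.max_min_ratio)
    if cq is not None:
        lvedvi = index_to_bsa(cq.lvedv, subject.bsa)
        vec.edwt_over_lvedvi_cq = wall.max_edwt / lvedvi
        vec.lvm_over_lvedv_cq = cq.lvm / cq.lvedv
    if tq is not None:
        lvedvi = index_to_bsa(tq.lvedv, subject.bsa)
        vec.edwt_over_lvedvi_tq = wall.max_edwt / lvedvi
        vec.lvm_over_lvedv_tq = tq.lvm / tq.lvedv
        if tq.tpm_mass is None:
            raise ValidationError("TQ result lacks TPM mass; cannot compute TPM%")
        vec.tpm_percent = 100.0 * tq.tpm_mass / tq.lvm
    return vec


def in_grey_zone(max_edwt: float) -> bool:
    """True when the maximal EDWT falls in the 13-16 mm grey zone."""
    lo, hi = GREY_ZONE_MM
    return lo <= max_edwt <= hi


def classify_subject(
    indices: SportIndexVector | dict,
    rules: tuple[CutoffRule, ...] = DEFAULT_CUTOFF_RULES,
) -> dict:
    """Label each rule's index athlete-range or HCM-range.

    A value strictly above the rule threshold is HCM-range; a value
    exactly at the threshold falls to athlete-range. The returned dict
    maps index name to label and carries a ``grey_zone`` flag from the
    maximal EDWT.
    """
    values = indices.as_dict() if isinstance(indices, SportIndexVector) else dict(indices)
    labels: dict = {}
    for rule in rules:
        if rule.index not in values:
            raise ValidationError(f"unknown index in cut-off rule: {rule.index!r}")
        value = values[rule.index]
        if value is None:
            raise ValidationError(f"index {rule.index!r} missing for this subject")
        labels[rule.index] = HCM_RANGE if value > rule.threshold else ATHLETE_RANGE
    max_edwt = values.get("max_edwt")
    if max_edwt is not None:
        labels["grey_zone"] = in_grey_zone(max_edwt)
    return labels
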
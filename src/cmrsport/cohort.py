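"""Index-level simulated cohorts of athletes and HCM patients.

Each subject group (male/female x athlete/HCM) is described by per-index
Gaussian marginals (mean, SD). The defaults are the published group
statistics of a large elite-athlete vs HCM comparison cohort: 101 male
athletes, 108 male HCM patients, 49 female athletes, 86 female HCM
patients. Indices are drawn independently per subject — only marginal
means and SDs are available, so no between-index correlation structure
is imposed; joint-distribution quantities (e.g. exact empirical AUCs)
are therefore not reproduced, only marginal and ordering behaviour.

Non-positive draws are rejected and resampled, since every index is a
strictly positive physical quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ValidationError

INDEX_COLUMNS = (
    "edwt",
    "maxmin_edwt",
    "edwt_over_lvedvi_cq",
    "lvm_over_lvedv_cq",
    "edwt_over_lvedvi_tq",
    "lvm_over_lvedv_tq",
    "tpm_percent",
)

#: (mean, sd) per index for the four default groups.
DEFAULT_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "male_athlete": {
        "edwt": (12.6, 1.3),
        "maxmin_edwt": (1.93, 0.30),
        "edwt_over_lvedvi_cq": (0.10, 0.02),
        "lvm_over_lvedv_cq": (0.75, 0.13),
        "edwt_over_lvedvi_tq": (0.13, 0.02),
        "lvm_over_lvedv_tq": (1.13, 0.16),
        "tpm_percent": (19.0, 3.7),
    },
    "male_hcm": {
        "edwt": (22.1, 5.4),
        "maxmin_edwt": (3.56, 1.53),
        "edwt_over_lvedvi_cq": (0.25, 0.08),
        "lvm_over_lvedv_cq": (1.08, 0.30),
        "edwt_over_lvedvi_tq": (0.34, 0.10),
        "lvm_over_lvedv_tq": (1.93, 0.60),
        "tpm_percent": (22.1, 4.6),
    },
    "female_athlete": {
        "edwt": (10.4, 1.2),
        "maxmin_edwt": (2.17, 0.45),
        "edwt_over_lvedvi_cq": (0.10, 0.02),
        "lvm_over_lvedv_cq": (0.62, 0.10),
        "edwt_over_lvedvi_tq": (0.12, 0.02),
        "lvm_over_lvedv_tq": (0.95, 0.14),
        "tpm_percent": (21.1, 4.7),
    },
    "female_hcm": {
        "edwt": (19.7, 5.2),
        "maxmin_edwt": (3.86, 1.63),
        "edwt_over_lvedvi_cq": (0.25, 0.07),
        "lvm_over_lvedv_cq": (0.97, 0.25),
        "edwt_over_lvedvi_tq": (0.36, 0.12),
        "lvm_over_lvedv_tq": (1.83, 0.56),
        "tpm_percent": (23.1, 4.1),
    },
}

DEFAULT_GROUP_SIZES = {
    "male_athlete": 101,
    "male_hcm": 108,
    "female_athlete": 49,
    "female_hcm": 86,
}


@dataclass
class GroupSpec:
    """Size and per-index (mean, sd) of one simulated subject group."""

    n: int
    stats: dict[str, tuple[float, float]]

    def validate(self, name: str) -> None:
        if self.n < 0:
            raise ValidationError(f"group {name!r}: n must be non-negative")
        for index, (mean, sd) in self.stats.items():
            if sd <= 0:
                raise ValidationError(f"group {name!r}, index {index!r}: sd must be positive")


@dataclass
class CohortSpec:
    groups: dict[str, GroupSpec] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValidationError("cohort spec has no groups")
        if not any(g.n > 0 for g in self.groups.values()):
            raise ValidationError("all groups are empty")
        for name, group in self.groups.items():
            group.validate(name)


def default_cohort_spec(seed: int = 0) -> CohortSpec:
    """The published four-group cohort (101/108/49/86 subjects)."""
    groups = {
        name: GroupSpec(n=DEFAULT_GROUP_SIZES[name], stats=dict(stats))
        for name, stats in DEFAULT_GROUP_STATS.items()
    }
    return CohortSpec(groups=groups, seed=seed)


def _split_group_name(name: str) -> tuple[str, str]:
    """Map a group name like ``male_athlete`` to (sex, disease-group)."""
    lowered = name.lower()
    sex = "M" if "male" in lowered and not lowered.startswith("female") else "F"
    disease = "HCM" if "hcm" in lowered else "athlete"
    return sex, disease


def _sample_positive(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Gaussian draws, rejecting non-positive values."""
    values = rng.normal(mean, sd, size=n)
    for _ in range(1000):
        bad = values <= 0
        if not bad.any():
            return values
        values[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise ValidationError(f"could not draw positive values for mean={mean}, sd={sd}")


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one subject table from a :class:`CohortSpec`.

    Returns a DataFrame with ``subject_id``, ``group`` (athlete/HCM),
    ``sex`` and one column per index; reproducible under the spec seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    for name in sorted(spec.groups):
        group = spec.groups[name]
        if group.n == 0:
            continue
        sex, disease = _split_group_name(name)
        data = {
            "subject_id": [f"{name}_{i:04d}" for i in range(group.n)],
            "group": disease,
            "sex": sex,
        }
        for index in group.stats:
            mean, sd = group.stats[index]
            data[index] = _sample_positive(rng, mean, sd, group.n)
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)
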
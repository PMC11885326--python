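"""Body-size normalization and dilation-group classification.

Diameters are normalized to body size through a pluggable normative
reference giving, per measurement level, the population mean and standard
deviation of the diameter as a function of body surface area (BSA, Haycock
formula).  The Z-score is (measured - mean(BSA)) / sd(BSA); the dilation
class uses the maximum Z across levels:

    severe  : max Z >= 4
    mild    : 2 < max Z < 4
    normal  : max Z <= 2

The bundled reference is a synthetic affine-in-BSA model (non-clinical,
chosen so that normal adolescent anatomies score near zero); user-supplied
reference tables load from CSV with linear interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .anatomy import PhenotypeParams

__all__ = [
    "LEVELS",
    "Subject",
    "ReferenceModel",
    "SyntheticReference",
    "TableReference",
    "DilationClass",
    "haycock_bsa",
    "zscore",
    "classify_dilation",
    "generate_cohort",
]

LEVELS = ("annulus", "sinus", "stj", "mid_ascending")

_BSA_DOMAIN = (0.5, 2.5)  # m^2, validity range of the bundled reference


def haycock_bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area (m^2) by the Haycock formula.

    BSA = 0.024265 * weight^0.5378 * height^0.3964
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be positive")
    return 0.024265 * weight_kg**0.5378 * height_cm**0.3964


@dataclass
class Subject:
    """One synthetic subject with anthropometrics and hemodynamic targets."""

    subject_id: str
    group: str
    age: float  # years
    sex: str  # 'M' or 'F'
    weight: float  # kg
    height: float  # cm
    cardiac_output: float  # L/min
    systolic: float  # mmHg
    diastolic: float  # mmHg
    bsa: float = 0.0  # m^2, derived if not given
    diameters: Dict[str, float] = field(default_factory=dict)  # mm per level

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.weight <= 0 or self.height <= 0:
            raise ValueError("weight and height must be positive")
        if self.systolic <= self.diastolic:
            raise ValueError("systolic must exceed diastolic pressure")
        if self.bsa == 0.0:
            self.bsa = haycock_bsa(self.weight, self.height)


class ReferenceModel:
    """Normative diameter reference: mean and sd (mm) per level vs BSA."""

    levels: Tuple[str, ...] = LEVELS
    domain: Tuple[float, float] = _BSA_DOMAIN

    def mean_diameter(self, level: str, bsa: float) -> float:
        raise NotImplementedError

    def sd_diameter(self, level: str, bsa: float) -> float:
        raise NotImplementedError

    def _check(self, level: str, bsa: float) -> None:
        if level not in self.levels:
            raise ValueError(f"unknown level {level!r}")
        lo, hi = self.domain
        if not lo <= bsa <= hi:
            raise ValueError(f"BSA {bsa:.2f} m^2 outside reference domain [{lo}, {hi}]")


class SyntheticReference(ReferenceModel):
    """Bundled affine-in-BSA reference (synthetic, not clinically validated).

    mean(bsa) = a + b * bsa, constant sd; coefficients chosen so that
    normal adolescent neo-aortic dimensions score |Z| < ~1.
    """

    _COEF: Dict[str, Tuple[float, float, float]] = {
        # level: (intercept mm, slope mm per m^2, sd mm)
        "annulus": (12.0, 7.0, 1.8),
        "sinus": (16.0, 9.0, 2.0),
        "stj": (13.0, 8.0, 2.2),
        "mid_ascending": (13.0, 7.0, 2.0),
    }

    def mean_diameter(self, level: str, bsa: float) -> float:
        self._check(level, bsa)
        a, b, _ = self._COEF[level]
        return a + b * bsa

    def sd_diameter(self, level: str, bsa: float) -> float:
        self._check(level, bsa)
        return self._COEF[level][2]


class TableReference(ReferenceModel):
    """Reference loaded from a CSV table (level, bsa, mean_mm, sd_mm) with
    linear interpolation in BSA."""

    def __init__(self, table: pd.DataFrame):
        required = {"level", "bsa", "mean_mm", "sd_mm"}
        if not required.issubset(table.columns):
            raise ValueError(f"reference table needs columns {sorted(required)}")
        self._tab = {
            str(level): grp.sort_values("bsa")
            for level, grp in table.groupby("level")
        }
        self.levels = tuple(self._tab)
        bsas = table["bsa"]
        self.domain = (float(bsas.min()), float(bsas.max()))

    @classmethod
    def from_csv(cls, path) -> "TableReference":
        return cls(pd.read_csv(path))

    def mean_diameter(self, level: str, bsa: float) -> float:
        self._check(level, bsa)
        g = self._tab[level]
        return float(np.interp(bsa, g["bsa"], g["mean_mm"]))

    def sd_diameter(self, level: str, bsa: float) -> float:
        self._check(level, bsa)
        g = self._tab[level]
        return float(np.interp(bsa, g["bsa"], g["sd_mm"]))


def zscore(
    diameter_mm: float, level: str, subject: Subject, ref: ReferenceModel
) -> float:
    """Z-score of a measured diameter against the body-size-matched norm."""
    mean = ref.mean_diameter(level, subject.bsa)
    sd = ref.sd_diameter(level, subject.bsa)
    return (diameter_mm - mean) / sd


@dataclass
class DilationClass:
    value: str  # severe | mild | normal
    max_z: float
    level_of_max: str


def classify_dilation(zscores: Dict[str, float]) -> DilationClass:
    """Dilation class from per-level Z-scores (max across levels decides)."""
    if not zscores:
        raise ValueError("at least one level Z-score is required")
    level = max(zscores, key=lambda k: zscores[k])
    z = zscores[level]
    if z >= 4.0:
        value = "severe"
    elif z > 2.0:
        value = "mild"
    else:
        value = "normal"
    return DilationClass(value, float(z), level)


# ---------------------------------------------------------------------------
# synthetic cohort generation

# arch-angle sampling ranges per group: the printed group ranges (degrees)
_ARCH_RANGES = {
    "A_severe": (68.5, 77.2),
    "B_mild": (71.1, 85.2),
    "C_normal": (87.4, 99.0),
}
# max-Z sampling band per group; the max sits at the sinus of Valsalva
# (the level the severe group dilates most), other levels draw lower Z
_MAXZ_BANDS = {
    "A_severe": (4.0, 6.5),
    "B_mild": (2.3, 3.7),
    "C_normal": (-0.5, 1.8),
}
# default recirculation strengths per phenotype (dimensionless peak reverse
# fraction handed to the flow-field generator)
RECIRC_STRENGTH = {"A_severe": 0.6, "B_mild": 0.15, "C_normal": 0.0}


def _sample_anthropometrics(rng: np.random.Generator) -> Tuple[float, str, float, float]:
    """Age 8-18 y with age-increasing weight/height ranges."""
    age = rng.uniform(8.0, 18.0)
    sex = "M" if rng.random() < 0.5 else "F"
    frac = (age - 8.0) / 10.0
    weight = rng.uniform(28.0 + 30.0 * frac, 45.0 + 35.0 * frac)
    height = rng.uniform(125.0 + 35.0 * frac, 145.0 + 35.0 * frac)
    return age, sex, weight, height


def generate_cohort(
    n_per_group: int,
    seed: int,
    ref: Optional[ReferenceModel] = None,
) -> List[Tuple[Subject, PhenotypeParams]]:
    """Synthetic three-group cohort with guaranteed dilation labels.

    Diameters are drawn by sampling per-level Z-scores inside group-specific
    bands and inverting the reference at the subject's BSA, so every subject
    classifies into its intended group by construction.  Cardiac output is
    uniform on 3.8-6 L/min, systolic targets uniform on 100-130 mmHg and
    diastolic on 60-80 mmHg; arch angles draw from the printed group ranges.
    Deterministic per seed.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    ref = ref or SyntheticReference()
    rng = np.random.default_rng(seed)
    out: List[Tuple[Subject, PhenotypeParams]] = []
    for group in ("A_severe", "B_mild", "C_normal"):
        for i in range(n_per_group):
            age, sex, weight, height = _sample_anthropometrics(rng)
            bsa = haycock_bsa(weight, height)
            co = rng.uniform(3.8, 6.0)
            sys_p = rng.uniform(100.0, 130.0)
            dia_p = rng.uniform(60.0, 80.0)
            angle = rng.uniform(*_ARCH_RANGES[group])

            z_lo, z_hi = _MAXZ_BANDS[group]
            z_max = rng.uniform(z_lo, z_hi)
            zs = {}
            for level in LEVELS:
                if level == "sinus":
                    zs[level] = z_max
                else:
                    # strictly below both the group's max-Z and its class
                    # ceiling so the sinus always carries the class
                    ceiling = min(z_max - 0.3, 1.8)
                    zs[level] = rng.uniform(-1.0, ceiling)
            diam = {
                level: ref.mean_diameter(level, bsa)
                + zs[level] * ref.sd_diameter(level, bsa)
                for level in LEVELS
            }
            subj = Subject(
                subject_id=f"{group[0]}{i:03d}",
                group=group,
                age=age,
                sex=sex,
                weight=weight,
                height=height,
                cardiac_output=co,
                systolic=sys_p,
                diastolic=dia_p,
                bsa=bsa,
                diameters=diam,
            )
            params = PhenotypeParams(
                group=group,
                arch_angle_deg=angle,
                annulus_d=diam["annulus"],
                sinus_d=diam["sinus"],
                stj_d=diam["stj"],
                midAA_d=diam["mid_ascending"],
                recirculation_strength=RECIRC_STRENGTH[group],
            )
            out.append((subj, params))
    return out


def cohort_to_frame(cohort: Iterable[Tuple[Subject, PhenotypeParams]]) -> pd.DataFrame:
    rows = []
    for subj, params in cohort:
        row = {
            "subject_id": subj.subject_id,
            "group": subj.group,
            "age": subj.age,
            "sex": subj.sex,
            "weight": subj.weight,
            "height": subj.height,
            "bsa": subj.bsa,
            "cardiac_output": subj.cardiac_output,
            "systolic": subj.systolic,
            "diastolic": subj.diastolic,
            "arch_angle_deg": params.arch_angle_deg,
            "recirculation_strength": params.recirculation_strength,
        }
        for level in LEVELS:
            row[f"d_{level}_mm"] = subj.diameters[level]
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort(cohort, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        recs = cohort_to_frame(cohort).to_dict(orient="records")
        path.write_text(json.dumps(recs, indent=1))
    else:
        cohort_to_frame(cohort).to_csv(path, index=False)
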
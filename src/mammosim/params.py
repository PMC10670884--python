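"""Parameter sets and synthetic life tables.

The simulator is driven entirely by a :class:`ParameterSet`: a female
all-cause life table, an age-dependent breast-cancer onset hazard, tumor
growth and spread distributions, size-dependent screen sensitivity,
clinical-surfacing and false-positive rates, and stage-specific survival.
:func:`make_default_params` builds an internally consistent synthetic set
emulating a Western female population (lifetime breast-cancer risk near
12%, onset hazard peaking in the late 60s, right-skewed tumor growth
rates, survival worsening monotonically with stage).  It is an explicit
stand-in for a calibrated national parameter file, not a fit to any
country's registry data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .stages import SUBSTAGES

SCHEMA_VERSION = 1

MAX_AGE = 109  # histories end by this age; the life table forces it


class ValidationError(ValueError):
    """A parameter value violates an invariant; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(name, f"must be a probability in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# Life table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LifeTable:
    """Per-age conditional death probabilities qx for ages 0..109.

    qx[a] is the probability of dying in the year of age [a, a+1) given
    survival to a.  qx[109] must be 1 so every history terminates.
    """

    qx: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "qx", np.asarray(self.qx, dtype=float))

    @property
    def ages(self) -> np.ndarray:
        return np.arange(len(self.qx))

    def validate(self) -> "LifeTable":
        if len(self.qx) != MAX_AGE + 1:
            raise ValidationError("life_table.qx", f"must have {MAX_AGE + 1} entries, got {len(self.qx)}")
        if np.any(self.qx < 0) or np.any(self.qx > 1):
            raise ValidationError("life_table.qx", "all qx must lie in [0, 1]")
        if self.qx[MAX_AGE] != 1.0:
            raise ValidationError("life_table.qx", f"qx at age {MAX_AGE} must equal 1")
        return self

    def survival(self) -> np.ndarray:
        """P(alive at exact age a), a = 0..110; survival[0] = 1."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.qx)])

    def death_year_cdf(self) -> np.ndarray:
        """P(death age < a) on the yearly grid a = 0..110."""
        return 1.0 - self.survival()

    def life_expectancy(self, age: int = 0) -> float:
        """Expected remaining years at exact integer ``age``.

        Brute-force summation over the table with deaths placed uniformly
        within their year of age (the +0.5 term).
        """
        s = self.survival()
        cond = s[age + 1:] / s[age]          # P(alive at a+1, a+2, ... | alive at age)
        return float(cond.sum() + 0.5)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        import pandas as pd

        df = pd.read_csv(path)
        if not {"age", "qx"} <= set(df.columns):
            raise ValidationError("life_table", "CSV must have columns 'age' and 'qx'")
        df = df.sort_values("age")
        if not np.array_equal(df["age"].to_numpy(), np.arange(len(df))):
            raise ValidationError("life_table.age", "ages must be contiguous from 0")
        return cls(qx=df["qx"].to_numpy()).validate()


def make_life_table(makeham_a: float = 5e-4,
                    gompertz_b: float = 3e-5,
                    gompertz_c: float = 0.095) -> LifeTable:
    """Synthetic female life table from a Gompertz–Makeham hazard.

    qx(age) = 1 − exp(−(a + b·exp(c·age))), clamped to [0, 1], with
    qx(109) forced to 1.  Defaults give survival-to-40 ≈ 0.97 and median
    death age ≈ 81, a plausible stand-in for a contemporary female
    population.
    """
    for name, v in (("makeham_a", makeham_a), ("gompertz_b", gompertz_b),
                    ("gompertz_c", gompertz_c)):
        if v < 0:
            raise ValidationError(name, f"must be nonnegative, got {v}")
    ages = np.arange(MAX_AGE + 1)
    hazard = makeham_a + gompertz_b * np.exp(gompertz_c * ages)
    qx = np.clip(1.0 - np.exp(-hazard), 0.0, 1.0)
    qx[MAX_AGE] = 1.0
    return LifeTable(qx=qx).validate()


# ---------------------------------------------------------------------------
# Component parameter groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthParams:
    """Lognormal tumor growth-rate distribution and size bounds (Gompertz growth)."""

    log_mean: float    # mean of ln(gamma), gamma in 1/year
    log_sd: float      # sd of ln(gamma)
    d0: float          # initial diameter at invasive onset, mm
    dmax: float        # asymptotic diameter, mm

    def validate(self) -> "GrowthParams":
        if self.log_sd < 0:
            raise ValidationError("growth.log_sd", "must be nonnegative")
        if not (0 < self.d0 < self.dmax):
            raise ValidationError("growth.d0", f"need 0 < d0 < dmax, got d0={self.d0}, dmax={self.dmax}")
        return self


@dataclass(frozen=True)
class SpreadFunction:
    """Annual spread probability as a logistic function of diameter.

    p(d) = max_prob / (1 + exp(−k·(d − d50))).  A flat probability is the
    d50 → −inf limit (use a large negative d50).
    """

    max_prob: float
    d50: float   # mm
    k: float     # 1/mm

    def __call__(self, diameter: float) -> float:
        z = -self.k * (diameter - self.d50)
        # guard overflow for extreme d50 used to encode flat probabilities
        if z > 700:
            return 0.0
        return self.max_prob / (1.0 + math.exp(z))

    def validate(self, name: str) -> "SpreadFunction":
        _check_prob(self.max_prob, f"{name}.max_prob")
        if self.k < 0:
            raise ValidationError(f"{name}.k", "must be nonnegative")
        return self

    @classmethod
    def flat(cls, prob: float) -> "SpreadFunction":
        return cls(max_prob=prob, d50=-1e9, k=1.0)


@dataclass(frozen=True)
class StageModel:
    """Size thresholds (mm) and nodal/distant annual spread probabilities."""

    size_thresholds: tuple[float, float] = (20.0, 50.0)
    nodal: SpreadFunction = field(default_factory=lambda: SpreadFunction(0.45, 22.0, 0.15))
    distant: SpreadFunction = field(default_factory=lambda: SpreadFunction(0.35, 40.0, 0.12))

    def validate(self) -> "StageModel":
        t1, t2 = self.size_thresholds
        if not t1 < t2:
            raise ValidationError("stage_model.size_thresholds", f"must be strictly increasing, got {self.size_thresholds}")
        self.nodal.validate("stage_model.nodal")
        self.distant.validate("stage_model.distant")
        return self


@dataclass(frozen=True)
class SensitivityParams:
    """Size-dependent mammographic sensitivity (logistic in diameter)."""

    smax: float = 0.95    # asymptotic sensitivity
    d50: float = 11.0     # diameter of half-max sensitivity, mm
    k: float = 0.45       # logistic slope, 1/mm
    insitu: float = 0.25  # fixed sensitivity for in-situ lesions (no size)

    def validate(self) -> "SensitivityParams":
        _check_prob(self.smax, "sensitivity.smax")
        _check_prob(self.insitu, "sensitivity.insitu")
        if self.k < 0:
            raise ValidationError("sensitivity.k", "must be nonnegative")
        return self


@dataclass(frozen=True)
class ClinicalDetectionParams:
    """Diameter-proportional clinical surfacing hazard c0 · d / dref."""

    c0: float = 0.18    # hazard scale, 1/year, at d = dref
    dref: float = 15.0  # reference diameter, mm

    def validate(self) -> "ClinicalDetectionParams":
        if self.c0 < 0:
            raise ValidationError("clinical_detection.c0", "must be nonnegative")
        if self.dref <= 0:
            raise ValidationError("clinical_detection.dref", "must be positive")
        return self


@dataclass(frozen=True)
class SurvivalParams:
    """Stage-specific cure fraction and exponential death rate for non-cured.

    Cure must decrease and rate increase strictly along the stage order;
    the stage-shift mortality mechanism relies on this ordering, so it is
    enforced at validation, not assumed.
    """

    cure: dict[str, float]
    rate: dict[str, float]  # 1/year

    def validate(self) -> "SurvivalParams":
        for name, d in (("survival.cure", self.cure), ("survival.rate", self.rate)):
            if set(d) != set(SUBSTAGES):
                raise ValidationError(name, f"must have keys {SUBSTAGES}, got {sorted(d)}")
        cures = [self.cure[s] for s in SUBSTAGES]
        rates = [self.rate[s] for s in SUBSTAGES]
        for s, c in zip(SUBSTAGES, cures):
            _check_prob(c, f"survival.cure[{s}]")
        if any(r <= 0 for r in rates):
            raise ValidationError("survival.rate", "all rates must be positive")
        if any(a <= b for a, b in zip(cures, cures[1:])):
            raise ValidationError("survival.cure", "must be strictly decreasing with stage")
        if any(a >= b for a, b in zip(rates, rates[1:])):
            raise ValidationError("survival.rate", "must be strictly increasing with stage")
        return self


# ---------------------------------------------------------------------------
# Full parameter set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterSet:
    life_table: LifeTable
    onset_hazard: np.ndarray          # per-age rate (1/year), ages 0..109
    subtype_weights: dict[str, float]
    growth: GrowthParams
    insitu_fraction: float            # P(new cancer starts in situ)
    insitu_progression_prob: float    # annual P(in situ -> invasive)
    stage_model: StageModel
    sensitivity: SensitivityParams
    clinical_detection: ClinicalDetectionParams
    fp_recall_rate: float             # per-screen P(recall | no detectable cancer)
    biopsy_given_recall: float
    neg_biopsy_given_no_cancer: float
    survival: SurvivalParams
    seed: int

    def __post_init__(self):
        object.__setattr__(self, "onset_hazard", np.asarray(self.onset_hazard, dtype=float))

    def validate(self) -> "ParameterSet":
        self.life_table.validate()
        if len(self.onset_hazard) != MAX_AGE + 1:
            raise ValidationError("onset_hazard", f"must have {MAX_AGE + 1} entries")
        if np.any(self.onset_hazard < 0):
            raise ValidationError("onset_hazard", "rates must be nonnegative")
        if abs(sum(self.subtype_weights.values()) - 1.0) > 1e-9:
            raise ValidationError("subtype_weights", f"must sum to 1, got {sum(self.subtype_weights.values())}")
        if any(w < 0 for w in self.subtype_weights.values()):
            raise ValidationError("subtype_weights", "weights must be nonnegative")
        self.growth.validate()
        _check_prob(self.insitu_fraction, "insitu_fraction")
        _check_prob(self.insitu_progression_prob, "insitu_progression_prob")
        self.stage_model.validate()
        self.sensitivity.validate()
        self.clinical_detection.validate()
        _check_prob(self.fp_recall_rate, "fp_recall_rate")
        _check_prob(self.biopsy_given_recall, "biopsy_given_recall")
        _check_prob(self.neg_biopsy_given_no_cancer, "neg_biopsy_given_no_cancer")
        self.survival.validate()
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValidationError("seed", "must be an integer")
        return self

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "life_table": {"qx": [float(q) for q in self.life_table.qx]},
            "onset_hazard": [float(h) for h in self.onset_hazard],
            "subtype_weights": {k: float(v) for k, v in self.subtype_weights.items()},
            "growth": dataclasses.asdict(self.growth),
            "insitu_fraction": float(self.insitu_fraction),
            "insitu_progression_prob": float(self.insitu_progression_prob),
            "stage_model": {
                "size_thresholds": [float(t) for t in self.stage_model.size_thresholds],
                "nodal": dataclasses.asdict(self.stage_model.nodal),
                "distant": dataclasses.asdict(self.stage_model.distant),
            },
            "sensitivity": dataclasses.asdict(self.sensitivity),
            "clinical_detection": dataclasses.asdict(self.clinical_detection),
            "fp_recall_rate": float(self.fp_recall_rate),
            "biopsy_given_recall": float(self.biopsy_given_recall),
            "neg_biopsy_given_no_cancer": float(self.neg_biopsy_given_no_cancer),
            "survival": {"cure": dict(self.survival.cure), "rate": dict(self.survival.rate)},
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        data = dict(data)
        version = data.pop("schema_version", None)
        if version != SCHEMA_VERSION:
            raise ValidationError("schema_version", f"expected {SCHEMA_VERSION}, got {version}")
        required = {
            "life_table", "onset_hazard", "subtype_weights", "growth",
            "insitu_fraction", "insitu_progression_prob", "stage_model",
            "sensitivity", "clinical_detection", "fp_recall_rate",
            "biopsy_given_recall", "neg_biopsy_given_no_cancer", "survival", "seed",
        }
        missing = required - set(data)
        if missing:
            raise ValidationError(sorted(missing)[0], "missing from configuration")
        unknown = set(data) - required
        if unknown:
            raise ValidationError(sorted(unknown)[0], "unknown configuration key")
        try:
            ps = cls(
                life_table=LifeTable(qx=np.asarray(data["life_table"]["qx"], dtype=float)),
                onset_hazard=np.asarray(data["onset_hazard"], dtype=float),
                subtype_weights=dict(data["subtype_weights"]),
                growth=GrowthParams(**data["growth"]),
                insitu_fraction=data["insitu_fraction"],
                insitu_progression_prob=data["insitu_progression_prob"],
                stage_model=StageModel(
                    size_thresholds=tuple(data["stage_model"]["size_thresholds"]),
                    nodal=SpreadFunction(**data["stage_model"]["nodal"]),
                    distant=SpreadFunction(**data["stage_model"]["distant"]),
                ),
                sensitivity=SensitivityParams(**data["sensitivity"]),
                clinical_detection=ClinicalDetectionParams(**data["clinical_detection"]),
                fp_recall_rate=data["fp_recall_rate"],
                biopsy_given_recall=data["biopsy_given_recall"],
                neg_biopsy_given_no_cancer=data["neg_biopsy_given_no_cancer"],
                survival=SurvivalParams(cure=dict(data["survival"]["cure"]),
                                        rate=dict(data["survival"]["rate"])),
                seed=data["seed"],
            )
        except TypeError as exc:
            raise ValidationError("parameters", str(exc)) from exc
        return ps.validate()

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path: str | Path) -> "ParameterSet":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError("parameters", "configuration file must contain a mapping")
        return cls.from_dict(data)

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON form; identifies a run's inputs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Default synthetic parameter set
# ---------------------------------------------------------------------------

def default_onset_hazard() -> np.ndarray:
    """Age-dependent onset hazard: zero before 25, Gaussian bump peaking at 68.

    Cumulative hazard to age 80 is about 0.12, i.e. a lifetime risk near
    the familiar 1-in-9 figure for Western female populations.
    """
    ages = np.arange(MAX_AGE + 1, dtype=float)
    h = 0.004 * np.exp(-(((ages - 68.0) / 22.0) ** 2))
    h[ages < 25] = 0.0
    return h


def make_default_params(seed: int = 0) -> ParameterSet:
    """Build the default synthetic parameter set (deterministic given seed).

    The seed is carried into the set and used by the engine's random
    streams; the parameter values themselves are fixed constants, so two
    calls with the same seed serialize byte-identically.
    """
    ps = ParameterSet(
        life_table=make_life_table(),
        onset_hazard=default_onset_hazard(),
        subtype_weights={
            "luminal_a": 0.55,
            "luminal_b": 0.15,
            "her2_enriched": 0.10,
            "triple_negative": 0.20,
        },
        growth=GrowthParams(log_mean=math.log(0.25), log_sd=0.6, d0=1.0, dmax=128.0),
        insitu_fraction=0.40,
        insitu_progression_prob=0.35,
        stage_model=StageModel(),
        sensitivity=SensitivityParams(),
        clinical_detection=ClinicalDetectionParams(),
        fp_recall_rate=0.055,
        biopsy_given_recall=0.09,
        neg_biopsy_given_no_cancer=1.0,
        survival=SurvivalParams(
            cure={"0": 1.0, "1": 0.90, "2A": 0.80, "2B": 0.70, "3": 0.50, "4": 0.05},
            rate={"0": 0.02, "1": 0.04, "2A": 0.07, "2B": 0.11, "3": 0.20, "4": 0.45},
        ),
        seed=int(seed),
    )
    return ps.validate()
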
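"""Physiological trait summaries: relative water content and percent change.

RWC (%) = 100 * (FW - DW) / (TW - DW), from the fresh (FW), oven-dry (DW)
and turgid (TW) weights of the same leaf sample; bounded to [0, 100] when
DW <= FW <= TW. Percent reduction compares replicate means between two arms
— stressed vs well-watered control, or day 5 vs day 1 of the stress period —
with a negative value meaning an increase.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .errors import ComputationError, ValidationError
from .io_tables import Condition, _clean_str, _parse_enum, _positive_int, records_to_frame

logger = logging.getLogger("trioqpcr")

__all__ = ["TraitRecord", "relative_water_content", "percent_reduction",
           "trait_summary"]

#: trait columns summarised by :func:`trait_summary`
MEASURED_TRAITS = ("root_length", "spad_chlorophyll", "rwc")


def _optional_pos(value, field: str, positive: bool = True) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{field} is not numeric: {value!r}") from None
    if not math.isfinite(x):
        raise ValidationError(f"{field} is not finite")
    if positive and x <= 0:
        raise ValidationError(f"{field} must be > 0, got {x}")
    return x


@dataclass(frozen=True)
class TraitRecord:
    """One replicate's physiological measurements on a given day."""

    genotype_id: str
    condition: Condition
    day: int
    replicate: int
    fresh_weight: float | None = None   # g
    dry_weight: float | None = None     # g
    turgid_weight: float | None = None  # g
    root_length: float | None = None    # cm
    spad_chlorophyll: float | None = None  # SPAD units

    def __post_init__(self):
        object.__setattr__(self, "genotype_id", _clean_str(self.genotype_id, "genotype_id"))
        object.__setattr__(self, "condition", _parse_enum(Condition, self.condition, "condition"))
        object.__setattr__(self, "day", _positive_int(self.day, "day"))
        object.__setattr__(self, "replicate", _positive_int(self.replicate, "replicate"))
        for f in ("fresh_weight", "dry_weight", "turgid_weight", "root_length"):
            object.__setattr__(self, f, _optional_pos(getattr(self, f), f))
        object.__setattr__(self, "spad_chlorophyll",
                           _optional_pos(self.spad_chlorophyll, "spad_chlorophyll",
                                         positive=False))
        fw, dw, tw = self.fresh_weight, self.dry_weight, self.turgid_weight
        if None not in (fw, dw, tw) and not dw <= fw <= tw:
            raise ValidationError(
                f"genotype {self.genotype_id} day {self.day} rep {self.replicate}: "
                f"weights must satisfy DW <= FW <= TW, got DW={dw}, FW={fw}, TW={tw}")

    @property
    def rwc(self) -> float | None:
        """Relative water content (%), when all three weights are present."""
        if None in (self.fresh_weight, self.dry_weight, self.turgid_weight):
            return None
        return relative_water_content(self.fresh_weight, self.dry_weight,
                                      self.turgid_weight)


def relative_water_content(fw: float, dw: float, tw: float) -> float:
    """RWC (%) = 100 * (FW - DW) / (TW - DW); in [0, 100] for DW <= FW <= TW."""
    for v in (fw, dw, tw):
        if not math.isfinite(v):
            raise ComputationError(f"relative_water_content: non-finite weight {v!r}")
    if tw <= dw:
        raise ComputationError(
            f"turgid weight ({tw}) must exceed dry weight ({dw})")
    if not dw <= fw <= tw:
        raise ValidationError(
            f"fresh weight {fw} outside [dry={dw}, turgid={tw}]")
    return 100.0 * (fw - dw) / (tw - dw)


def percent_reduction(reference_value: float, observed_value: float) -> float:
    """100 * (reference - observed) / reference; negative means an increase."""
    for v in (reference_value, observed_value):
        if not math.isfinite(v):
            raise ComputationError(f"percent_reduction: non-finite input {v!r}")
    if reference_value <= 0:
        raise ComputationError(
            f"reference value must be > 0, got {reference_value}")
    return 100.0 * (reference_value - observed_value) / reference_value


def trait_summary(records: Iterable[TraitRecord],
                  comparison: str = "stress_vs_control") -> pd.DataFrame:
    """Percent change per genotype x trait between two arms of the design.

    ``comparison``:

    * ``"stress_vs_control"`` — reference arm is the well-watered control
      mean, observed arm the stress mean (same days pooled);
    * ``"day5_vs_day1"`` — within the stress condition, reference is the
      first day's mean and observed the last day's mean.

    Replicates are averaged *before* the ratio. Genotypes missing an arm are
    skipped with a warning. Returns a long frame with columns genotype_id,
    trait, reference_mean, observed_mean, percent_reduction.
    """
    if comparison not in ("stress_vs_control", "day5_vs_day1"):
        raise ValueError(f"unknown comparison {comparison!r}")
    records = list(records)
    df = records_to_frame(records)
    if df.empty:
        return pd.DataFrame(columns=["genotype_id", "trait", "reference_mean",
                                     "observed_mean", "percent_reduction"])
    df["rwc"] = [r.rwc for r in records]

    if comparison == "stress_vs_control":
        ref_mask = df["condition"] == Condition.CONTROL.value
        obs_mask = df["condition"] == Condition.STRESS.value
        arm_names = ("control", "stress")
    else:
        stress = df["condition"] == Condition.STRESS.value
        first, last = df.loc[stress, "day"].min(), df.loc[stress, "day"].max()
        ref_mask = stress & (df["day"] == first)
        obs_mask = stress & (df["day"] == last)
        arm_names = (f"stress day {first}", f"stress day {last}")

    rows = []
    for genotype in sorted(df["genotype_id"].unique()):
        mine = df["genotype_id"] == genotype
        ref_arm = df[mine & ref_mask]
        obs_arm = df[mine & obs_mask]
        if ref_arm.empty or obs_arm.empty:
            missing = arm_names[0] if ref_arm.empty else arm_names[1]
            logger.warning("genotype %s lacks the %s arm; skipped",
                           genotype, missing)
            continue
        for trait in MEASURED_TRAITS:
            ref_mean = ref_arm[trait].dropna().mean()
            obs_mean = obs_arm[trait].dropna().mean()
            if pd.isna(ref_mean) or pd.isna(obs_mean):
                continue
            rows.append({
                "genotype_id": genotype, "trait": trait,
                "reference_mean": float(ref_mean),
                "observed_mean": float(obs_mean),
                "percent_reduction": percent_reduction(float(ref_mean),
                                                       float(obs_mean)),
            })
    return pd.DataFrame(rows, columns=["genotype_id", "trait", "reference_mean",
                                       "observed_mean", "percent_reduction"])
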
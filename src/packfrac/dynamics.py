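"""Population-dynamics arithmetic: biovolume trajectories, species frequency,
plate-count titers, resistance frequency, and phage-adsorption curves.

Everything here is deliberately plain bookkeeping — the science lives in how
these quantities are combined: biovolume is normalized to its pre-phage
baseline to show killing and recovery, plate counts become titers with an
explicit detection limit, and the resistance frequency distinguishes
architectural protection (survivors remain phage-susceptible, frequency
~1e-5) from de novo resistance sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BiovolumeSeries",
    "AssayCounts",
    "TiterResult",
    "normalize_to_baseline",
    "species_frequency",
    "titer",
    "ResistanceResult",
    "resistance_frequency",
    "AdsorptionCurve",
    "ADSORPTION_CLASSES",
    "adsorption_curve",
]


@dataclass
class BiovolumeSeries:
    """Per-chamber biovolume trajectory for one species."""

    chamber_id: str
    species: str
    times_h: np.ndarray
    biovolumes_um3: np.ndarray
    phage_added_at: float | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.biovolumes_um3 = np.asarray(self.biovolumes_um3, dtype=float)
        if len(self.times_h) != len(self.biovolumes_um3):
            raise ValueError("times and biovolumes differ in length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.biovolumes_um3 < 0):
            raise ValueError("biovolumes must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chamber_id": self.chamber_id,
                "species": self.species,
                "time_h": self.times_h,
                "biovolume_um3": self.biovolumes_um3,
            }
        )


def normalize_to_baseline(series: BiovolumeSeries, baseline_time: float) -> BiovolumeSeries:
    """Fold change relative to the biovolume at ``baseline_time`` (typically
    the last pre-phage timepoint); the baseline sample maps to exactly 1."""
    match = np.isclose(series.times_h, baseline_time)
    if not match.any():
        raise ValueError(f"baseline time {baseline_time} h not present in series")
    base = float(series.biovolumes_um3[match][0])
    if base <= 0:
        raise ValueError("baseline biovolume is zero; fold change undefined")
    out = BiovolumeSeries(
        chamber_id=series.chamber_id,
        species=series.species,
        times_h=series.times_h,
        biovolumes_um3=series.biovolumes_um3 / base,
        phage_added_at=series.phage_added_at,
    )
    out.biovolumes_um3[match] = 1.0
    return out


def species_frequency(biovolumes: dict[str, float], focal: str) -> float:
    """Frequency of the focal species: focal biovolume over the total.

    Frequencies over all species sum to 1; NaN if the total is zero.
    """
    if focal not in biovolumes:
        raise KeyError(f"focal species {focal!r} not in {list(biovolumes)}")
    total = float(sum(biovolumes.values()))
    if total <= 0:
        return float("nan")
    return float(biovolumes[focal]) / total


@dataclass(frozen=True)
class AssayCounts:
    """One dilution-plating observation (CFU or PFU)."""

    sample_id: str
    count: int
    dilution_factor: float
    plated_volume_ul: float
    selection: str = "none"  # none | phage_saturated | antibiotic

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.plated_volume_ul <= 0:
            raise ValueError("plated_volume must be > 0")
        if self.selection not in ("none", "phage_saturated", "antibiotic"):
            raise ValueError(f"unknown selection {self.selection!r}")


@dataclass(frozen=True)
class TiterResult:
    """Concentration per mL with the plating detection limit annotated.

    A zero count is reported as 0 but flagged ``below_detection`` with the
    one-colony-equivalent detection limit, never silently treated as a true
    zero downstream.
    """

    per_ml: float
    detection_limit_per_ml: float
    below_detection: bool

    def __float__(self) -> float:
        return self.per_ml


def titer(counts: AssayCounts) -> TiterResult:
    """count x dilution / plated volume (mL)."""
    vol_ml = counts.plated_volume_ul / 1000.0
    limit = counts.dilution_factor / vol_ml
    return TiterResult(
        per_ml=counts.count * counts.dilution_factor / vol_ml,
        detection_limit_per_ml=limit,
        below_detection=counts.count == 0,
    )


@dataclass(frozen=True)
class ResistanceResult:
    """Resistance frequency; zero resistant counts carry an upper bound."""

    frequency: float
    upper_bound: float | None = None

    def __float__(self) -> float:
        return self.frequency


def resistance_frequency(resistant_titer: float, total_titer: float) -> ResistanceResult:
    """Fraction of the population resistant: resistant / total titers.

    An architectural-protection outcome leaves this at the pre-exposure
    mutation-supply level (~1e-5) rather than sweeping toward 1.
    """
    resistant = float(resistant_titer)
    total = float(total_titer)
    if total <= 0:
        raise ValueError("total titer must be > 0")
    if resistant > total:
        raise ValueError(
            f"inconsistent assay: resistant titer {resistant} exceeds total {total}"
        )
    if resistant == 0:
        return ResistanceResult(0.0, upper_bound=1.0 / total)
    return ResistanceResult(resistant / total)


ADSORPTION_CLASSES = ("no_adsorption", "adsorption_only", "adsorption_then_amplification")


@dataclass
class AdsorptionCurve:
    times_min: np.ndarray
    normalized_pfu: np.ndarray
    classification: str
    tolerance_log10: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times_min, "pfu_over_inoculum": self.normalized_pfu}
        )


def adsorption_curve(
    times_min,
    titers_per_ml,
    inoculum_titer: float,
    tolerance_log10: float = 0.3,
) -> AdsorptionCurve:
    """Classify a free-phage recovery time course.

    The trajectory of recovered PFU over the inoculum is classified as
    ``no_adsorption`` (all points within +-tolerance of 1 in log10 — the
    non-host / blank-media pattern), ``adsorption_only`` (leaves the band but
    never rises more than tolerance above the running minimum — the
    adsorb-but-abort pattern), or ``adsorption_then_amplification`` (some
    point exceeds an earlier minimum by more than tolerance — the productive
    host pattern).  The running minimum includes the implicit unity start, so
    the three classes partition all trajectories.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(titers_per_ml, dtype=float)
    if len(t) != len(y):
        raise ValueError("times and titers differ in length")
    if len(t) < 3:
        raise ValueError("need >= 3 timepoints to classify a trajectory")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if inoculum_titer <= 0:
        raise ValueError("inoculum titer must be > 0")
    ratio = y / inoculum_titer
    with np.errstate(divide="ignore"):
        log_r = np.log10(np.maximum(ratio, 1e-300))
    tol = tolerance_log10
    if np.all(np.abs(log_r) <= tol):
        cls = "no_adsorption"
    else:
        running_min = np.minimum.accumulate(np.concatenate([[0.0], log_r]))[:-1]
        if np.any(log_r > running_min + tol):
            cls = "adsorption_then_amplification"
        else:
            cls = "adsorption_only"
    return AdsorptionCurve(
        times_min=t, normalized_pfu=ratio, classification=cls, tolerance_log10=tol
    )
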
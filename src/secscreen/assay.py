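"""Reduction of pNPP kinetic plate-reader traces to volumetric enzyme activity.

The chromogenic assay follows p-nitrophenol (pNP) release at 410 nm: a
sample of culture supernatant (possibly pre-diluted) is mixed with substrate
solution in a microplate well and absorbance is read on a fixed interval
(nominally every 25 s).  Reduction to activity proceeds in three steps:

1. ``fit_slope`` — ordinary least squares of A410 against time, reported per
   minute together with the r² of the fit;
2. ``blank_correct`` — subtract the slope of a water blank run alongside;
3. ``activity_from_slope`` — convert the blanked slope to volumetric activity
   of the *undiluted* supernatant via Beer-Lambert:

       c'  [µmol pNP · mL⁻¹ · min⁻¹ in the well] = slope / (ε · d)
       activity [U/mL] = c' · (V_reaction / V_sample) · dilution_factor

   with ε the molar extinction coefficient of pNP (15 cm²/µmol at 410 nm,
   alkaline pH) and d the optical path length of the filled well in cm.
   1 U = 1 µmol/min, so U/mL is numerically identical to kU/L.

The well path length is not a property of the instrument but of the fill
volume and well geometry; the default 0.58 cm corresponds to 200 µL in a
cylindrical approximation of a standard 96-well plate and is recorded on
every measurement so results remain auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticTrace",
    "AssayConfig",
    "ActivityMeasurement",
    "fit_slope",
    "blank_correct",
    "activity_from_slope",
    "reduce_well",
]


@dataclass(frozen=True)
class KineticTrace:
    """One well's absorbance-vs-time series."""

    well_id: str
    role: str  # "sample" or "blank"
    times_s: np.ndarray
    absorbances: np.ndarray
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if self.role not in ("sample", "blank"):
            raise ValueError(f"trace role must be 'sample' or 'blank', got {self.role!r}")
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and absorbances must be 1-D arrays of equal length")
        if len(t) < 3:
            raise ValueError(f"a kinetic trace needs at least 3 points, got {len(t)}")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.dilution_factor < 1.0:
            raise ValueError(f"dilution factor must be >= 1, got {self.dilution_factor}")
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "absorbances", a)


@dataclass(frozen=True)
class AssayConfig:
    """Assay arithmetic constants.

    epsilon_cm2_per_umol : molar extinction coefficient of pNP at 410 nm.
    path_length_cm       : optical path of the filled well.
    sample_volume_uL / reaction_volume_uL : 20 µL supernatant + 180 µL
        reagent = 200 µL total by default.
    min_r2               : traces fitting worse than this are flagged
        (never silently dropped).
    """

    epsilon_cm2_per_umol: float = 15.0
    path_length_cm: float = 0.58
    sample_volume_uL: float = 20.0
    reaction_volume_uL: float = 200.0
    min_r2: float = 0.95

    def __post_init__(self) -> None:
        for name in ("epsilon_cm2_per_umol", "path_length_cm", "sample_volume_uL", "reaction_volume_uL"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sample_volume_uL > self.reaction_volume_uL:
            raise ValueError("sample volume cannot exceed total reaction volume")


@dataclass(frozen=True)
class ActivityMeasurement:
    """Volumetric activity of the undiluted supernatant, with provenance."""

    activity_U_per_mL: float
    slope_per_min: float
    fit_r2: float
    dilution_factor: float = 1.0
    path_length_cm: float = float("nan")
    flags: tuple[str, ...] = field(default=())

    @property
    def below_detection(self) -> bool:
        return "below_detection" in self.flags


def _ols(t: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    """Closed-form OLS slope (per unit of t) and r²; r² := 0 for flat data."""
    tc = t - t.mean()
    ss_t = float(tc @ tc)
    if ss_t == 0.0:
        raise ValueError("zero variance in time axis; cannot fit a slope")
    slope = float(tc @ (a - a.mean())) / ss_t
    ss_tot = float(((a - a.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return slope, 0.0
    resid = a - a.mean() - slope * tc
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return slope, r2


def fit_slope(
    trace: KineticTrace, *, trim_lag: bool = False, min_window: int = 5
) -> tuple[float, float]:
    """OLS slope of A410 vs time in 1/min, and the r² of the fit.

    With ``trim_lag=True`` leading points (mixing/temperature lag) are
    dropped: among all trailing windows of at least ``min_window`` points the
    one with maximal r² is used.  Default is to use every point.
    """
    t, a = trace.times_s, trace.absorbances
    if not trim_lag:
        slope_s, r2 = _ols(t, a)
        return slope_s * 60.0, r2
    if len(t) < min_window:
        raise ValueError(f"trace shorter than the minimum window of {min_window} points")
    best = None
    for start in range(0, len(t) - min_window + 1):
        slope_s, r2 = _ols(t[start:], a[start:])
        if best is None or r2 > best[0]:
            best = (r2, slope_s)
    r2, slope_s = best
    return slope_s * 60.0, r2


def blank_correct(sample_slope_per_min: float, blank_slope_per_min: float) -> float:
    """Subtract the water-blank slope from the sample slope (both 1/min)."""
    if not (math.isfinite(sample_slope_per_min) and math.isfinite(blank_slope_per_min)):
        raise ValueError("slopes must be finite")
    return sample_slope_per_min - blank_slope_per_min


def activity_from_slope(
    slope_per_min: float,
    cfg: AssayConfig,
    dilution_factor: float = 1.0,
    *,
    fit_r2: float = float("nan"),
) -> ActivityMeasurement:
    """Convert a blanked slope to activity of the undiluted supernatant.

    Activity is homogeneous of degree 1 in both slope and dilution factor.
    Non-positive slopes are reported as activity 0 with a ``below_detection``
    flag — never as a negative activity.
    """
    if dilution_factor < 1.0:
        raise ValueError(f"dilution factor must be >= 1, got {dilution_factor}")
    denom = cfg.epsilon_cm2_per_umol * cfg.path_length_cm
    flags: list[str] = []
    if slope_per_min <= 0.0:
        flags.append("below_detection")
        activity = 0.0
    else:
        well_rate = slope_per_min / denom  # µmol pNP / (mL well · min)
        activity = well_rate * (cfg.reaction_volume_uL / cfg.sample_volume_uL) * dilution_factor
    if not math.isnan(fit_r2) and fit_r2 < cfg.min_r2:
        flags.append("low_r2")
    return ActivityMeasurement(
        activity_U_per_mL=activity,
        slope_per_min=float(slope_per_min),
        fit_r2=float(fit_r2),
        dilution_factor=float(dilution_factor),
        path_length_cm=cfg.path_length_cm,
        flags=tuple(flags),
    )


def reduce_well(
    sample: KineticTrace,
    blank: KineticTrace,
    cfg: AssayConfig,
    *,
    trim_lag: bool = False,
) -> ActivityMeasurement:
    """Full per-well reduction: fit both traces, blank, convert."""
    s_slope, s_r2 = fit_slope(sample, trim_lag=trim_lag)
    b_slope, _ = fit_slope(blank, trim_lag=trim_lag)
    net = blank_correct(s_slope, b_slope)
    return activity_from_slope(net, cfg, sample.dilution_factor, fit_r2=s_r2)
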
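"""Targeted quantitation and method-validation statistics.

Calibration curves are ordinary least squares of detector response against
injected-vial concentration (µg/L), either raw peak area or area ratio to
the internal standard.  Sample results are converted from vial µg/L to
herb µg/kg through the sample-preparation factors (3.0 g of herb extracted
and reconstituted in 1 mL by default, so herb µg/kg = vial µg/L / 3 at
dilution 1).  Validation statistics follow the usual residue-method
definitions: LOD and LOQ at signal-to-noise 3:1 and 10:1, recovery
100*(C-A)/B for a spike B added to native amount A and determined as C,
and precision/stability as relative standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .errors import ConfigError, FitError
from .screening import ScreenHit

#: Default sample-preparation factors of the extraction protocol.
DEFAULT_SAMPLE_MASS_G = 3.0
DEFAULT_FINAL_VOLUME_ML = 1.0


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted response-vs-concentration line for one pesticide."""

    pesticide: str
    slope: float
    intercept: float
    r_squared: float
    levels: tuple[tuple[float, float], ...]
    response_mode: str = "area"  # or "area_ratio_to_IS"
    lod: float | None = None  # µg/L
    loq: float | None = None  # µg/L

    def __post_init__(self):
        if len(self.levels) < 3:
            raise FitError("calibration needs >= 3 levels")
        concs = [c for c, _ in self.levels]
        if len(set(concs)) != len(concs):
            raise FitError("calibration levels must have distinct concentrations")
        if not 0.0 <= self.r_squared <= 1.0:
            raise FitError("r_squared must be in [0, 1]")

    def response_at(self, conc: float) -> float:
        return self.slope * conc + self.intercept


class ConcEstimate(NamedTuple):
    """Inverted concentration; ``clipped`` flags a negative raw estimate."""

    ugl: float
    clipped: bool


@dataclass(frozen=True)
class RecoverySpec:
    """Spike-recovery bookkeeping, all in µg/kg.

    A: native analyte amount in the unspiked sample; B: standard amount
    added; C: amount determined in the spiked sample.
    """

    A: float
    B: float
    C: float

    def __post_init__(self):
        if self.B <= 0:
            raise ConfigError("spike amount B must be positive")
        if self.A < 0 or self.C < 0:
            raise ConfigError("amounts A and C must be non-negative")


@dataclass(frozen=True)
class QuantResult:
    sample_id: str
    pesticide: str
    vial_conc: float  # µg/L
    herb_conc: float  # µg/kg
    status: str  # ND | below_LOQ | quantified


@dataclass(frozen=True)
class ValidationStats:
    rsd_interday: float
    rsd_intraday: float
    stability_rsd: float
    lod: float
    loq: float
    recovery_pct: float

    def __post_init__(self):
        vals = (self.rsd_interday, self.rsd_intraday, self.stability_rsd,
                self.lod, self.loq)
        if any(v < 0 for v in vals):
            raise ConfigError("validation statistics must be non-negative")
        if self.loq <= self.lod:
            raise ConfigError("LOQ must exceed LOD")


def fit_calibration(
    levels: Sequence[tuple[float, float]],
    mode: str = "area",
    pesticide: str = "",
) -> CalibrationCurve:
    """Ordinary least squares ``response = slope * conc + intercept``.

    ``r_squared`` is 1 - SS_res/SS_tot (defined as 1.0 for an exactly
    degenerate zero-variance response).
    """
    levels = tuple((float(c), float(y)) for c, y in levels)
    if len(levels) < 3:
        raise FitError("calibration needs >= 3 levels")
    x = np.array([c for c, _ in levels])
    y = np.array([r for _, r in levels])
    if np.ptp(x) == 0 or len(set(x.tolist())) < 3:
        raise FitError("calibration levels must span distinct concentrations")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return CalibrationCurve(
        pesticide=pesticide,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=min(max(r2, 0.0), 1.0),
        levels=levels,
        response_mode=mode,
    )


def invert_calibration(curve: CalibrationCurve, response: float) -> ConcEstimate:
    """Algebraic inverse ``x = (y - intercept) / slope``; negative estimates
    are clipped to 0 and flagged."""
    if curve.slope == 0:
        raise FitError(f"{curve.pesticide}: zero slope cannot be inverted")
    x = (float(response) - curve.intercept) / curve.slope
    if x < 0:
        # flag only genuinely negative estimates, not float noise at zero
        return ConcEstimate(0.0, x < -1e-9)
    return ConcEstimate(float(x), False)


def vial_to_herb(
    vial_conc: float,
    sample_mass_g: float = DEFAULT_SAMPLE_MASS_G,
    final_volume_ml: float = DEFAULT_FINAL_VOLUME_ML,
    dilution_factor: float = 1.0,
) -> float:
    """Convert an injected-vial concentration (µg/L) to a herb residue
    (µg/kg): ``vial * volume_mL / mass_g * dilution``."""
    if sample_mass_g <= 0 or final_volume_ml <= 0:
        raise ConfigError("sample mass and final volume must be positive")
    return float(vial_conc) * final_volume_ml / sample_mass_g * dilution_factor


def recovery(spec: RecoverySpec) -> float:
    """Spike recovery in percent: ``100 * (C - A) / B``."""
    return 100.0 * (spec.C - spec.A) / spec.B


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ConfigError("RSD needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ConfigError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / abs(mean))


def lod_loq(noise: float, peak_height_per_conc: float) -> tuple[float, float]:
    """LOD and LOQ (µg/L) at S/N 3:1 and 10:1 for a given baseline noise
    and peak-height response slope (counts per µg/L); LOQ/LOD = 10/3."""
    if noise <= 0:
        raise ConfigError("noise must be positive")
    if peak_height_per_conc <= 0:
        raise ConfigError("height response slope must be positive")
    lod = 3.0 * noise / peak_height_per_conc
    loq = 10.0 * noise / peak_height_per_conc
    return lod, loq


def stability_series(areas: Sequence[tuple[float, float]]) -> float:
    """RSD (%) of responses recorded at a series of storage time points."""
    if len(areas) < 2:
        raise ConfigError("stability needs >= 2 time points")
    return rsd([y for _, y in areas])


def quantify_study(
    hits_by_sample: Mapping[str, Sequence[ScreenHit]],
    curves: Mapping[str, CalibrationCurve],
    is_areas: Mapping[str, float] | None = None,
    sample_mass_g: float = DEFAULT_SAMPLE_MASS_G,
    final_volume_ml: float = DEFAULT_FINAL_VOLUME_ML,
    dilution_factor: float = 1.0,
) -> list[QuantResult]:
    """Quantify every confirmed screened pesticide in every sample.

    The responses of a pesticide's confirmed isomer entries are pooled
    (summed quantifier areas) before inversion through its calibration
    curve, then converted to a herb concentration.  A pesticide with no
    confirmed hit in a sample, or whose estimate falls below the curve's
    LOD, is reported ND; estimates between LOD and LOQ are flagged
    ``below_LOQ``.
    """
    results: list[QuantResult] = []
    for sid in sorted(hits_by_sample.keys()):
        hits = hits_by_sample[sid]
        pooled: dict[str, float] = {}
        unconfirmed: set[str] = set()
        for h in hits:
            if h.confirmed:
                pooled[h.base_name] = pooled.get(h.base_name, 0.0) + h.quantifier_peak.area
            else:
                unconfirmed.add(h.base_name)
        for base in sorted(unconfirmed - set(pooled)):
            results.append(QuantResult(sid, base, 0.0, 0.0, "ND"))
        for base, area in pooled.items():
            if base not in curves:
                raise ConfigError(
                    f"no calibration curve for screened pesticide {base!r}"
                )
            curve = curves[base]
            response = area
            if curve.response_mode == "area_ratio_to_IS":
                if is_areas is None or sid not in is_areas:
                    raise ConfigError(
                        f"internal-standard response missing for sample {sid}"
                    )
                response = area / is_areas[sid]
            est = invert_calibration(curve, response)
            herb = vial_to_herb(
                est.ugl, sample_mass_g, final_volume_ml, dilution_factor
            )
            if est.clipped or (curve.lod is not None and est.ugl < curve.lod):
                status = "ND"
            elif curve.loq is not None and est.ugl < curve.loq:
                status = "below_LOQ"
            else:
                status = "quantified"
            results.append(
                QuantResult(
                    sample_id=sid,
                    pesticide=base,
                    vial_conc=est.ugl,
                    herb_conc=herb,
                    status=status,
                )
            )
    return results
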
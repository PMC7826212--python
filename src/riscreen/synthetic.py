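"""Fixture tables and seeded synthetic-data generators.

The package ships machine-readable transcriptions of the published method
tables: the 89-entry MRM panel, the retention-index/retention-time table,
the 40-sample residue survey, and the per-pesticide validation parameters
(regression equations, LOD/LOQ, precision RSDs).  On top of these this
module simulates what the instrument would have produced: an n-alkane
calibration run, and per-sample MRM traces in which each present pesticide
appears as a Gaussian peak whose area follows that pesticide's calibration
line, on top of baseline noise, with retention-time jitter, an
ever-present internal-standard peak, and optional decoy interference peaks
mimicking herb matrix components.

Every stochastic draw is governed by an explicit integer seed, so that
simulated studies are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chromatogram import MRMTrace
from .errors import ConfigError
from .pesticide_db import (
    AnnotatedPanel,
    MRMTransition,
    PesticideRecord,
    annotate_panel,
    packaged_panel,
)
from .quantitation import (
    DEFAULT_FINAL_VOLUME_ML,
    DEFAULT_SAMPLE_MASS_G,
    CalibrationCurve,
    fit_calibration,
)
from .ri_core import AlkaneLadder, LadderFit, fit_ladder_from_pairs

#: Six-level matrix-matched calibration series (vial µg/L) implied by the
#: spiking scheme: 50/100 µL of the 100 µg/L mix and 50/100/200/400 µL of
#: the 1000 µg/L mix, made up to 1 mL.
DEFAULT_CALIBRATION_LEVELS = (5.0, 10.0, 50.0, 100.0, 200.0, 400.0)

GAUSSIAN_SIGMA_MIN = 0.02  # chromatographic peak width (minutes)
DEFAULT_DT_MIN = 0.005  # sampling interval (minutes per point)
CHANNEL_HALF_WINDOW = 0.6  # simulated acquisition half-window per compound


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic components of the simulator.

    baseline_sigma
        Gaussian detector noise (counts) around ``baseline_level``.
    area_cv
        Relative (lognormal) dispersion of generated peak areas.
    rt_jitter_sigma
        Normal retention-time jitter (minutes) around the measured RT.
    """

    baseline_sigma: float = 20.0
    area_cv: float = 0.015
    rt_jitter_sigma: float = 0.005
    baseline_level: float = 100.0


@dataclass(frozen=True)
class StudyDesign:
    """A study layout: per sample, the true herb concentrations (µg/kg)."""

    samples: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]
    noise: NoiseModel = NoiseModel()
    seed: int = 0

    @classmethod
    def from_mapping(
        cls,
        truths: Mapping[str, Mapping[str, float]],
        noise: NoiseModel = NoiseModel(),
        seed: int = 0,
    ) -> "StudyDesign":
        samples = tuple(
            (sid, tuple(sorted(conc.items()))) for sid, conc in truths.items()
        )
        for _, concs in samples:
            if any(c < 0 for _, c in concs):
                raise ConfigError("designed concentrations must be >= 0")
        return cls(samples=samples, noise=noise, seed=seed)

    def truth(self, sample_id: str) -> dict[str, float]:
        for sid, concs in self.samples:
            if sid == sample_id:
                return dict(concs)
        raise KeyError(sample_id)


@dataclass
class SimulatedSample:
    sample_id: str
    traces: list[MRMTrace]
    truth: dict[str, float]


# ---------------------------------------------------------------------------
# packaged fixtures


def _data_text(name: str) -> str:
    return resources.files("riscreen.data").joinpath(name).read_text("utf-8")


@dataclass(frozen=True)
class FixtureTables:
    panel: tuple[PesticideRecord, ...]
    retention: pd.DataFrame  # database/predicted and measured RI/RT per entry
    study: pd.DataFrame  # 40-sample survey, µg/kg, NaN = not detected
    validation: pd.DataFrame  # regression/LOD/LOQ/RSD parameters


@lru_cache(maxsize=1)
def fixture_tables() -> FixtureTables:
    """The packaged method tables, loaded once and treated as immutable."""
    import io

    retention = pd.read_csv(io.StringIO(_data_text("retention_table.csv")))
    study = pd.read_csv(
        io.StringIO(_data_text("study_concentrations.csv")), na_values=["ND"]
    ).set_index("sample_id")
    validation = pd.read_csv(io.StringIO(_data_text("validation.csv")))
    return FixtureTables(
        panel=tuple(packaged_panel()),
        retention=retention,
        study=study,
        validation=validation,
    )


@lru_cache(maxsize=1)
def reference_ladder_fit() -> LadderFit:
    """The canonical C9-C33 ladder reconstructed from the retention table.

    Both printed (RI, RT) couples of every row - (database RI, predicted
    RT) and (measured RI, measured RT) - are samples of the one instrument
    ladder that produced the table, so the reconstruction pools all of them
    and relies on the robust (bisquare) fit to reject the occasional
    typographical inconsistency of the printed measured columns.
    """
    t2 = fixture_tables().retention
    pairs = list(zip(t2.ri_db, t2.rt_predicted_min)) + list(
        zip(t2.ri_measured, t2.rt_measured_min)
    )
    return fit_ladder_from_pairs(pairs, robust=True, carbons=range(9, 34))


def reference_ladder() -> AlkaneLadder:
    return reference_ladder_fit().ladder


@lru_cache(maxsize=1)
def annotated_reference_panel() -> AnnotatedPanel:
    return annotate_panel(
        list(fixture_tables().panel), reference_ladder(), ladder_id="table2-fit"
    )


@lru_cache(maxsize=1)
def printed_annotated_panel() -> AnnotatedPanel:
    """The panel annotated with the *printed* predicted retention times of
    the retention table (rather than re-derived from a fitted ladder)."""
    from .pesticide_db import RTPrediction

    t2 = fixture_tables().retention.set_index("entry_name")
    records = list(fixture_tables().panel)
    predictions = {
        r.entry_name: RTPrediction(
            r.entry_name, r.database_ri, float(t2.loc[r.entry_name, "rt_predicted_min"])
        )
        for r in records
    }
    return AnnotatedPanel(records=records, predictions=predictions, ladder_id="printed")


def default_curves(mode: str = "area") -> dict[str, CalibrationCurve]:
    """Calibration curves for the three survey pesticides, generated from
    the published regression equations at the six standard levels, with the
    published LOD/LOQ attached."""
    curves = {}
    for row in fixture_tables().validation.itertuples():
        levels = [
            (c, row.slope * c + row.intercept) for c in DEFAULT_CALIBRATION_LEVELS
        ]
        curve = fit_calibration(levels, mode=mode, pesticide=row.pesticide)
        curves[row.pesticide] = dataclasses.replace(
            curve, lod=row.lod_ugL, loq=row.loq_ugL
        )
    return curves


def default_study_design(
    noise: NoiseModel = NoiseModel(), seed: int = 0
) -> StudyDesign:
    """The 40-sample survey layout; not-detected cells mean concentration 0
    (absent), following the survey's detection-limit convention."""
    study = fixture_tables().study
    truths = {
        sid: {p: float(v) for p, v in row.items() if pd.notna(v)}
        for sid, row in study.iterrows()
    }
    return StudyDesign.from_mapping(truths, noise=noise, seed=seed)


# ---------------------------------------------------------------------------
# simulators


def _gaussian(t: np.ndarray, center: float, area: float, sigma: float) -> np.ndarray:
    h = area / (sigma * np.sqrt(2.0 * np.pi))
    return h * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def simulate_alkane_run(
    ladder: AlkaneLadder,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    dt: float = DEFAULT_DT_MIN,
    peak_area: float = 5.0e4,
    peak_sigma: float = GAUSSIAN_SIGMA_MIN,
) -> MRMTrace:
    """A TIC-like trace of the n-alkane calibration mixture: one Gaussian
    peak at every ladder node retention time."""
    rng = np.random.default_rng(seed)
    t0 = ladder.times[0] - 0.5
    t1 = ladder.times[-1] + 0.5
    t = np.arange(t0, t1 + dt / 2, dt)
    y = np.full(t.size, noise.baseline_level)
    if noise.baseline_sigma > 0:
        y = y + rng.normal(0.0, noise.baseline_sigma, t.size)
    for _, node_rt in ladder.nodes:
        y += _gaussian(t, node_rt, peak_area, peak_sigma)
    return MRMTrace(
        transition=None, times=t, intensities=np.clip(y, 0.0, None), sample_id="alkanes"
    )


def _merge_windows(windows: list[tuple[float, float]]) -> list[tuple[float, float]]:
    windows = sorted(windows)
    merged = [list(windows[0])]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def simulate_sample(
    truth: Mapping[str, float],
    panel: Sequence[PesticideRecord],
    curves: Mapping[str, CalibrationCurve],
    seed: int = 0,
    noise: NoiseModel = NoiseModel(),
    ion_ratio: float = 0.5,
    is_area: float = 5.0e4,
    n_decoys: int = 2,
    decoy_area: float = 2.0e4,
    sample_id: str = "S1",
    dt: float = DEFAULT_DT_MIN,
    peak_sigma: float = GAUSSIAN_SIGMA_MIN,
    sample_mass_g: float = DEFAULT_SAMPLE_MASS_G,
    final_volume_ml: float = DEFAULT_FINAL_VOLUME_ML,
    dilution_factor: float = 1.0,
    rng: np.random.Generator | None = None,
) -> SimulatedSample:
    """Simulate the MRM traces of one prepared sample.

    Each pesticide present in ``truth`` (herb µg/kg) is converted to its
    vial concentration, pushed through its calibration line to a total
    quantifier area (split equally over its isomer entries), and placed as
    a Gaussian peak at the entry's measured retention time plus jitter; the
    qualifier transition carries ``ion_ratio`` times the quantifier area.
    Every monitored transition gets a trace (time-segmented around the
    panel retention times), so absent compounds yield noise-only traces.
    Decoy interference peaks, when requested, land at least 0.15 min away
    from every panel retention time.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    records = list(panel)
    by_base: dict[str, list[PesticideRecord]] = {}
    for rec in records:
        if rec.measured_rt is None:
            raise ConfigError(f"{rec.entry_name}: no measured RT to simulate at")
        if not rec.is_internal_standard:
            by_base.setdefault(rec.base_name, []).append(rec)
    for base in truth:
        if base not in by_base:
            raise ConfigError(f"designed pesticide {base!r} not in panel")
        if truth[base] > 0 and base not in curves:
            raise ConfigError(f"designed pesticide {base!r} has no curve")

    # acquisition channels: one per distinct transition, split into
    # contiguous windows around the retention times it must cover
    channel_windows: dict[tuple[float, float], list[tuple[float, float]]] = {}
    channel_transition: dict[tuple[float, float], MRMTransition] = {}
    for rec in records:
        for tr in rec.transitions:
            channel_windows.setdefault(tr.key, []).append(
                (rec.measured_rt - CHANNEL_HALF_WINDOW, rec.measured_rt + CHANNEL_HALF_WINDOW)
            )
            channel_transition.setdefault(tr.key, tr)

    # (channel key, rt, area) peak injections
    injections: list[tuple[tuple[float, float], float, float]] = []
    for base, herb_conc in sorted(truth.items()):
        if herb_conc <= 0:
            continue
        entries = by_base[base]
        vial = herb_conc * sample_mass_g / (final_volume_ml * dilution_factor)
        curve = curves[base]
        response = curve.response_at(vial)
        if curve.response_mode == "area_ratio_to_IS":
            response *= is_area
        share = response / len(entries)
        for rec in entries:
            sigma_ln = np.sqrt(np.log1p(noise.area_cv**2))
            factor = rng.lognormal(-0.5 * sigma_ln**2, sigma_ln) if sigma_ln > 0 else 1.0
            quant_area = share * factor
            rt = rec.measured_rt + (
                rng.normal(0.0, noise.rt_jitter_sigma) if noise.rt_jitter_sigma > 0 else 0.0
            )
            injections.append((rec.quantifier.key, rt, quant_area))
            injections.append((rec.qualifier.key, rt, quant_area * ion_ratio))
    is_rec = next(r for r in records if r.is_internal_standard)
    injections.append((is_rec.quantifier.key, is_rec.measured_rt, is_area))
    injections.append((is_rec.qualifier.key, is_rec.measured_rt, is_area * ion_ratio))

    if n_decoys > 0:
        panel_rts = np.array([r.measured_rt for r in records])
        keys = sorted(channel_windows.keys())
        placed = 0
        for _ in range(50 * n_decoys):
            if placed >= n_decoys:
                break
            key = keys[int(rng.integers(len(keys)))]
            lo, hi = _merge_windows(channel_windows[key])[0]
            rt = float(rng.uniform(lo + 0.05, hi - 0.05))
            if np.min(np.abs(panel_rts - rt)) < 0.15:
                continue
            injections.append((key, rt, float(decoy_area * rng.uniform(0.5, 2.0))))
            placed += 1

    traces: list[MRMTrace] = []
    for key in sorted(channel_windows.keys()):
        for lo, hi in _merge_windows(channel_windows[key]):
            t = np.arange(lo, hi + dt / 2, dt)
            y = np.full(t.size, noise.baseline_level)
            if noise.baseline_sigma > 0:
                y = y + rng.normal(0.0, noise.baseline_sigma, t.size)
            for k, rt, area in injections:
                if k == key and lo - 0.2 <= rt <= hi + 0.2:
                    y += _gaussian(t, rt, area, peak_sigma)
            traces.append(
                MRMTrace(
                    transition=channel_transition[key],
                    times=t,
                    intensities=np.clip(y, 0.0, None),
                    sample_id=sample_id,
                )
            )
    return SimulatedSample(sample_id=sample_id, traces=traces, truth=dict(truth))


def simulate_study(
    design: StudyDesign,
    panel: Sequence[PesticideRecord] | None = None,
    curves: Mapping[str, CalibrationCurve] | None = None,
    **kwargs,
) -> list[SimulatedSample]:
    """Simulate every sample of a study design with per-sample seeded RNGs
    derived from the design seed."""
    panel = list(fixture_tables().panel) if panel is None else list(panel)
    curves = default_curves() if curves is None else curves
    children = np.random.SeedSequence(design.seed).spawn(len(design.samples))
    out = []
    for (sid, concs), ss in zip(design.samples, children):
        out.append(
            simulate_sample(
                dict(concs),
                panel,
                curves,
                noise=design.noise,
                sample_id=sid,
                rng=np.random.default_rng(ss),
                **kwargs,
            )
        )
    return out
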
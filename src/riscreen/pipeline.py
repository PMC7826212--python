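"""End-to-end orchestration: calibrate -> annotate -> detect -> screen ->
quantify, with reproducible seeding and file outputs.

The stages are the public functions of the sibling modules; this module
only wires them together so that a whole simulated (or file-based) study
can be processed with one call, and so the command line stays thin.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .chromatogram import MRMTrace, Peak, detect_peaks
from .errors import ConfigError
from .pesticide_db import AnnotatedPanel, MRMTransition, annotate_panel, load_panel
from .quantitation import QuantResult, quantify_study
from .ri_core import AlkaneLadder
from .screening import ScreenHit, positive_counts, screen_sample, summarize_study
from .synthetic import (
    NoiseModel,
    SimulatedSample,
    StudyDesign,
    annotated_reference_panel,
    default_curves,
    default_study_design,
    simulate_study,
)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (flat, file-serialisable)."""

    design: str = "table3"  # "table3" or a design CSV path
    seed: int = 0
    rt_window: float = 0.05
    min_snr: float = 3.0
    min_width: float = 0.01
    ion_ratio_tol: float | None = None
    sample_mass_g: float = 3.0
    final_volume_ml: float = 1.0
    dilution_factor: float = 1.0
    panel_path: str | None = None
    ladder_path: str | None = None

    def __post_init__(self):
        if self.rt_window <= 0 or self.min_snr <= 0 or self.min_width <= 0:
            raise ConfigError("tolerances must be positive")
        if self.sample_mass_g <= 0 or self.final_volume_ml <= 0 or self.dilution_factor <= 0:
            raise ConfigError("conversion factors must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """Everything the pipeline produced for one study."""

    hits_by_sample: dict[str, list[ScreenHit]]
    detection_matrix: pd.DataFrame
    results: list[QuantResult]
    config: RunConfig
    seed: int

    @property
    def detected_pesticides(self) -> list[str]:
        counts = positive_counts(self.detection_matrix)
        return sorted(counts[counts > 0].index)

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "pesticide": r.pesticide,
                    "vial_conc_ugL": r.vial_conc,
                    "herb_conc_ugkg": r.herb_conc,
                    "status": r.status,
                }
                for r in self.results
            ],
            columns=["sample_id", "pesticide", "vial_conc_ugL", "herb_conc_ugkg", "status"],
        )

    def hits_frame(self) -> pd.DataFrame:
        rows = []
        for sid in sorted(self.hits_by_sample):
            for h in self.hits_by_sample[sid]:
                rows.append(
                    {
                        "sample_id": sid,
                        "entry_name": h.entry_name,
                        "base_name": h.base_name,
                        "predicted_rt": h.predicted_rt,
                        "observed_rt": h.observed_rt,
                        "deviation": h.deviation,
                        "area_quant": h.quantifier_peak.area,
                        "area_qual": h.qualifier_peak.area if h.qualifier_peak else None,
                        "ion_ratio": h.ion_ratio,
                        "confirmed": h.confirmed,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id", "entry_name", "base_name", "predicted_rt",
                "observed_rt", "deviation", "area_quant", "area_qual",
                "ion_ratio", "confirmed",
            ],
        )


def detect_sample_peaks(
    traces: Sequence[MRMTrace],
    min_snr: float = 3.0,
    min_width: float = 0.01,
) -> dict[MRMTransition, list[Peak]]:
    """Run peak detection on every trace, pooling by transition."""
    peaks: dict[MRMTransition, list[Peak]] = {}
    for tr in traces:
        if tr.transition is None:
            continue
        found = detect_peaks(tr, min_snr=min_snr, min_width=min_width)
        peaks.setdefault(tr.transition, []).extend(found)
    return peaks


def load_design_csv(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a design file: CSV ``sample_id,pesticide,herb_conc_ugkg``."""
    df = pd.read_csv(path)
    required = {"sample_id", "pesticide", "herb_conc_ugkg"}
    if not required.issubset(df.columns):
        raise ConfigError(f"{path}: need columns {sorted(required)}")
    truths: dict[str, dict[str, float]] = {}
    for row in df.itertuples():
        truths.setdefault(str(row.sample_id), {})[str(row.pesticide)] = float(
            row.herb_conc_ugkg
        )
    return truths


def run_pipeline(config: RunConfig) -> StudyReport:
    """Execute the full assay on a (simulated) study.

    Stages: ladder calibration and panel annotation, study simulation,
    per-sample peak detection, RT-window screening, and internal-standard /
    matrix-matched quantitation.
    """
    if config.panel_path:
        records = load_panel(config.panel_path)
        if config.ladder_path:
            ladder = AlkaneLadder.from_csv(config.ladder_path)
        else:
            from .synthetic import reference_ladder

            ladder = reference_ladder()
        panel = annotate_panel(records, ladder, ladder_id=config.ladder_path or "table2-fit")
    else:
        panel = annotated_reference_panel()

    noise = NoiseModel()
    if config.design == "table3":
        design = default_study_design(noise=noise, seed=config.seed)
    else:
        design = StudyDesign.from_mapping(
            load_design_csv(config.design), noise=noise, seed=config.seed
        )
    curves = default_curves()
    samples = simulate_study(
        design,
        panel=panel.records,
        curves=curves,
        sample_mass_g=config.sample_mass_g,
        final_volume_ml=config.final_volume_ml,
        dilution_factor=config.dilution_factor,
    )
    hits_by_sample: dict[str, list[ScreenHit]] = {}
    for sample in samples:
        peaks = detect_sample_peaks(
            sample.traces, min_snr=config.min_snr, min_width=config.min_width
        )
        hits_by_sample[sample.sample_id] = screen_sample(
            peaks,
            panel,
            rt_window=config.rt_window,
            ion_ratio_tol=config.ion_ratio_tol,
            sample_id=sample.sample_id,
        )
    matrix = summarize_study(hits_by_sample, panel)
    results = quantify_study(
        hits_by_sample,
        curves,
        sample_mass_g=config.sample_mass_g,
        final_volume_ml=config.final_volume_ml,
        dilution_factor=config.dilution_factor,
    )
    return StudyReport(
        hits_by_sample=hits_by_sample,
        detection_matrix=matrix,
        results=results,
        config=config,
        seed=config.seed,
    )


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Write hits, results, the detection matrix and a provenance block."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.hits_frame().to_csv(out / "hits.csv", index=False)
    report.results_frame().to_csv(out / "results.csv", index=False)
    report.detection_matrix.to_csv(out / "detection_matrix.csv")
    provenance = {
        "riscreen_version": __version__,
        "seed": report.seed,
        "config_hash": report.config.config_hash,
        "config": dataclasses.asdict(report.config),
        "detected_pesticides": report.detected_pesticides,
    }
    (out / "run.json").write_text(json.dumps(provenance, indent=1))
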
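"""Pesticide panel data model and I/O.

A *panel* is the list of monitored pesticide entries: each entry carries the
two MRM transitions (quantifier first, qualifier second) with collision
energies, the database retention index used for retention-time prediction,
the measured RI/RT from the verification run, an isomer index for compounds
that elute as several stereo/positional isomers, and bookkeeping flags (the
internal standard, suspected typographical inconsistencies in the printed
source table).

Entry names follow the source tables ("Cypermethrin-3"); ``base_name`` is
the entry name with the trailing isomer suffix stripped, so the 89 monitored
entries collapse to 74 unique pesticides plus the fenthion-d6 internal
standard.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import PanelError, RIRangeError
from .ri_core import AlkaneLadder, predict_retention_time

#: Printed-name aliases resolved to the canonical entry name on load.
ALIASES = {
    "Lindane": "γ-BHC",
    "Quizalofop-ethy-l": "Quizalofop-ethyl",
}

PANEL_CSV_HEADER = (
    "entry_name,base_name,isomer_index,class,ri_db,ri_measured,rt_measured_min,"
    "precursor1,product1,ce1,precursor2,product2,ce2,is_internal_standard,suspect"
)

_CLASSES = {"organophosphorus", "organochlorine", "pyrethroid", "other"}

_ISOMER_SUFFIX = re.compile(r"-([1-9])$")


@dataclass(frozen=True)
class MRMTransition:
    """One MRM ion pair: precursor m/z > product m/z at a collision energy."""

    precursor_mz: float
    product_mz: float
    collision_energy: int | None = None

    def __post_init__(self):
        if not (self.precursor_mz > self.product_mz > 0):
            raise PanelError(
                f"invalid transition {self.precursor_mz} > {self.product_mz}: "
                "require precursor > product > 0"
            )
        if self.collision_energy is not None and self.collision_energy <= 0:
            raise PanelError("collision energy must be positive")

    @property
    def key(self) -> tuple[float, float]:
        """Matching key: (precursor, product) rounded to 0.1 m/z."""
        return (round(self.precursor_mz, 1), round(self.product_mz, 1))

    def __str__(self) -> str:
        return f"{self.precursor_mz:g}>{self.product_mz:g}"


@dataclass(frozen=True)
class PesticideRecord:
    """One monitored panel entry (a pesticide or one of its isomers)."""

    entry_name: str
    base_name: str
    pesticide_class: str
    database_ri: float
    transitions: tuple[MRMTransition, MRMTransition]
    isomer_index: int | None = None
    measured_ri: float | None = None
    measured_rt: float | None = None
    is_internal_standard: bool = False
    suspect: bool = False

    def __post_init__(self):
        if len(self.transitions) != 2:
            raise PanelError(
                f"{self.entry_name}: exactly 2 transitions required"
            )
        if self.pesticide_class not in _CLASSES:
            raise PanelError(
                f"{self.entry_name}: unknown class {self.pesticide_class!r}"
            )

    @property
    def quantifier(self) -> MRMTransition:
        return self.transitions[0]

    @property
    def qualifier(self) -> MRMTransition:
        return self.transitions[1]


@dataclass(frozen=True)
class RTPrediction:
    pesticide_name: str
    database_ri: float
    predicted_rt: float


@dataclass
class AnnotatedPanel:
    """A validated panel with a predicted retention time for every entry."""

    records: list[PesticideRecord]
    predictions: dict[str, RTPrediction]
    ladder_id: str = ""

    def __post_init__(self):
        missing = [r.entry_name for r in self.records if r.entry_name not in self.predictions]
        if missing:
            raise PanelError(f"records without prediction: {missing}")
        # ordering by predicted RT must agree with ordering by database RI
        by_ri = sorted(self.records, key=lambda r: r.database_ri)
        rts = [self.predictions[r.entry_name].predicted_rt for r in by_ri]
        if any(b < a - 1e-9 for a, b in zip(rts, rts[1:])):
            raise PanelError("predicted RTs are not monotone in database RI")

    def predicted_rt(self, entry_name: str) -> float:
        return self.predictions[entry_name].predicted_rt


def base_name_of(entry_name: str) -> str:
    """Strip a trailing ``-<digit>`` isomer suffix from an entry name."""
    return _ISOMER_SUFFIX.sub("", entry_name)


def _parse_bool(s: str) -> bool:
    s = s.strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no", ""}:
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _records_from_rows(rows: Iterable[Mapping[str, str]], source: str) -> list[PesticideRecord]:
    records: list[PesticideRecord] = []
    problems: list[str] = []
    for i, row in enumerate(rows, start=2):
        try:
            name = row["entry_name"].strip()
            name = ALIASES.get(name, name)
            iso = row.get("isomer_index", "") or ""
            rec = PesticideRecord(
                entry_name=name,
                base_name=(row.get("base_name") or base_name_of(name)).strip(),
                isomer_index=int(iso) if str(iso).strip() else None,
                pesticide_class=row["class"].strip(),
                database_ri=float(row["ri_db"]),
                measured_ri=float(row["ri_measured"]) if row.get("ri_measured") else None,
                measured_rt=float(row["rt_measured_min"]) if row.get("rt_measured_min") else None,
                transitions=(
                    MRMTransition(
                        float(row["precursor1"]), float(row["product1"]), int(row["ce1"])
                    ),
                    MRMTransition(
                        float(row["precursor2"]), float(row["product2"]), int(row["ce2"])
                    ),
                ),
                is_internal_standard=_parse_bool(str(row.get("is_internal_standard", "false"))),
                suspect=_parse_bool(str(row.get("suspect", "false"))),
            )
            records.append(rec)
        except (KeyError, ValueError, PanelError) as exc:
            problems.append(f"{source}:{i}: {exc}")
    if problems:
        raise PanelError("panel parse errors:\n" + "\n".join(problems))
    return records


def validate_panel(records: Sequence[PesticideRecord]) -> None:
    """Check panel-wide invariants; raise :class:`PanelError` listing offenders."""
    problems = []
    seen: dict[str, int] = {}
    for r in records:
        seen[r.entry_name] = seen.get(r.entry_name, 0) + 1
    dups = [n for n, k in seen.items() if k > 1]
    if dups:
        problems.append(f"duplicate entry names: {dups}")
    n_is = sum(r.is_internal_standard for r in records)
    if n_is != 1:
        problems.append(f"expected exactly 1 internal standard, found {n_is}")
    # isomer entries of one base must have database RI increasing with index
    groups: dict[str, list[PesticideRecord]] = {}
    for r in records:
        if r.isomer_index is not None:
            groups.setdefault(r.base_name, []).append(r)
    for base, grp in groups.items():
        grp = sorted(grp, key=lambda r: r.isomer_index)
        ris = [r.database_ri for r in grp]
        if any(b <= a for a, b in zip(ris, ris[1:])):
            problems.append(f"{base}: isomer RIs not strictly increasing with index")
    if problems:
        raise PanelError("panel validation failed:\n" + "\n".join(problems))


def load_panel(path: str | Path) -> list[PesticideRecord]:
    """Load and validate a panel from a CSV or JSON file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise PanelError(f"{path}: empty panel file")
    if path.suffix.lower() == ".json":
        records = _records_from_json(text, str(path))
    else:
        records = _records_from_csv_text(text, str(path))
    if not records:
        raise PanelError(f"{path}: no panel rows")
    validate_panel(records)
    return records


def _records_from_csv_text(text: str, source: str) -> list[PesticideRecord]:
    reader = csv.DictReader(io.StringIO(text))
    expected = PANEL_CSV_HEADER.split(",")
    if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != expected:
        raise PanelError(
            f"{source}: bad header; expected exactly: {PANEL_CSV_HEADER}"
        )
    return _records_from_rows(reader, source)


def _records_from_json(text: str, source: str) -> list[PesticideRecord]:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PanelError(f"{source}: invalid JSON: {exc}") from exc
    records = []
    for item in payload:
        records.append(
            PesticideRecord(
                entry_name=item["entry_name"],
                base_name=item["base_name"],
                isomer_index=item.get("isomer_index"),
                pesticide_class=item["pesticide_class"],
                database_ri=item["database_ri"],
                measured_ri=item.get("measured_ri"),
                measured_rt=item.get("measured_rt"),
                transitions=tuple(
                    MRMTransition(t["precursor_mz"], t["product_mz"], t.get("collision_energy"))
                    for t in item["transitions"]
                ),
                is_internal_standard=item.get("is_internal_standard", False),
                suspect=item.get("suspect", False),
            )
        )
    return records


def write_panel(records: Sequence[PesticideRecord], path: str | Path) -> None:
    """Write a panel to CSV (human editing) or JSON (lossless round trip)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = []
        for r in records:
            d = asdict(r)
            d["transitions"] = [asdict(t) for t in r.transitions]
            payload.append(d)
        path.write_text(json.dumps(payload, indent=1, ensure_ascii=False), encoding="utf-8")
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PANEL_CSV_HEADER.split(","))
        for r in records:
            q, c = r.transitions
            w.writerow(
                [
                    r.entry_name,
                    r.base_name,
                    r.isomer_index if r.isomer_index is not None else "",
                    r.pesticide_class,
                    f"{r.database_ri:g}",
                    f"{r.measured_ri:g}" if r.measured_ri is not None else "",
                    f"{r.measured_rt:.3f}" if r.measured_rt is not None else "",
                    f"{q.precursor_mz:.1f}", f"{q.product_mz:.1f}", q.collision_energy,
                    f"{c.precursor_mz:.1f}", f"{c.product_mz:.1f}", c.collision_energy,
                    "true" if r.is_internal_standard else "false",
                    "true" if r.suspect else "false",
                ]
            )


def packaged_panel() -> list[PesticideRecord]:
    """The panel shipped with the package (89 entries, 74 pesticides + IS)."""
    text = resources.files("riscreen.data").joinpath("panel.csv").read_text("utf-8")
    records = _records_from_csv_text(text, "riscreen/data/panel.csv")
    validate_panel(records)
    return records


def collapse_isomers(
    records: Sequence[PesticideRecord],
) -> dict[str, list[PesticideRecord]]:
    """Group entries by base name (isomer suffix stripped), excluding the
    internal standard.  Idempotent and order-independent."""
    groups: dict[str, list[PesticideRecord]] = {}
    for r in records:
        if r.is_internal_standard:
            continue
        groups.setdefault(r.base_name, []).append(r)
    for base in groups:
        groups[base] = sorted(groups[base], key=lambda r: (r.database_ri, r.entry_name))
    return groups


def annotate_panel(
    records: Sequence[PesticideRecord],
    ladder: AlkaneLadder,
    ladder_id: str = "",
) -> AnnotatedPanel:
    """Predict a retention time for every panel entry from its database RI."""
    predictions = {}
    for r in records:
        try:
            rt = predict_retention_time(ladder, r.database_ri)
        except RIRangeError as exc:
            raise RIRangeError(f"{r.entry_name}: {exc}") from exc
        predictions[r.entry_name] = RTPrediction(r.entry_name, r.database_ri, rt)
    return AnnotatedPanel(records=list(records), predictions=predictions, ladder_id=ladder_id)
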
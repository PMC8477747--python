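"""CSV interchange, unit normalisation and report rendering.

The canonical input is a per-row CSV with columns::

    mab_id, species, clearance_value, clearance_units,
    body_weight_kg (optional), doses_mgkg (semicolon-separated),
    human_dose_range (optional, e.g. "2-40"), reference (optional)

``clearance_units`` may be mL/day, mL/min, mL/day/kg or mL/min/kg;
everything is normalised to absolute mL/day at load (per-kg values are
multiplied by the row's body weight, defaulting to the species profile).
Malformed rows are logged and skipped, never fatal.

Report tables mirror the two standard layouts of the field: a
dose-projection table (one row per mab, the five method columns, the
observed clinical range and a within-range flag) and a clearance
evaluation table (per-species blocks of fold-error bins and AFE with the
seven method columns).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .dosing import DoseProjection, round_dose
from .evaluation import EvaluationSummary, check_dose_range
from .scaling import METHODS, ClearancePrediction, MabRecord
from .species import SpeciesProfile, round_half_away

logger = logging.getLogger("mabscale")

__all__ = [
    "LoadedDataset",
    "read_records",
    "write_records",
    "parse_dose_range",
    "predictions_frame",
    "write_predictions",
    "dose_table",
    "evaluation_table",
    "to_markdown",
]

_MINUTES_PER_DAY = 1440.0

#: Method column order of the evaluation report.
REPORT_METHOD_ORDER = (
    "allometric_0.90",
    "allometric_0.85",
    "allometric_0.80",
    "allometric_0.75",
    "mpbpk",
    "lymph_flow",
    "liver_blood_flow",
)

REPORT_METHOD_LABELS = {
    "allometric_0.90": "0.90",
    "allometric_0.85": "0.85",
    "allometric_0.80": "0.80",
    "allometric_0.75": "0.75",
    "mpbpk": "mPBPK",
    "lymph_flow": "Lymph Flow",
    "liver_blood_flow": "LBF",
}


@dataclass
class LoadedDataset:
    """Records plus per-mab clinical dose ranges and a skipped-row count."""

    records: list[MabRecord]
    dose_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_skipped: int = 0


def parse_dose_range(text: str) -> tuple[float, float]:
    """Parse a clinical dose range like ``2-40``, ``2–40`` or ``4 to 30``.

    A single number is treated as a degenerate range. Hyphen, en-dash and
    "to" separators are all accepted (published tables mix them).
    """
    parts = re.split(r"\s*(?:–|—|\bto\b|-)\s*", str(text).strip(), maxsplit=1)
    values = [float(p) for p in parts if p]
    if len(values) == 1:
        low = high = values[0]
    else:
        low, high = values
    if low <= 0 or low > high:
        raise ValueError(f"invalid dose range {text!r}")
    return low, high


def _to_ml_per_day(
    value: float, units: str, body_weight: float | None, profile: SpeciesProfile | None
) -> float:
    units = units.strip()
    per_kg = units.endswith("/kg")
    base = units.removesuffix("/kg")
    if base == "mL/day":
        cl = value
    elif base == "mL/min":
        cl = value * _MINUTES_PER_DAY
    else:
        raise ValueError(f"unsupported clearance units {units!r}")
    if per_kg:
        if body_weight is None:
            if profile is None:
                raise ValueError("per-kg clearance needs a body weight")
            body_weight = profile.body_weight
        cl *= body_weight
    return cl


def read_records(
    path: str | Path,
    profiles: Mapping[str, SpeciesProfile],
) -> LoadedDataset:
    """Read the canonical CSV, normalising clearance to absolute mL/day."""
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"mab_id", "species", "clearance_value", "clearance_units"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"input is missing required columns: {sorted(missing)}")
    dataset = LoadedDataset(records=[])
    for idx, row in frame.iterrows():
        try:
            species = str(row["species"]).strip().lower()
            if species not in profiles:
                raise ValueError(f"unknown species {species!r}")
            weight = row.get("body_weight_kg")
            weight = None if pd.isna(weight) else float(weight)
            cl = _to_ml_per_day(
                float(row["clearance_value"]),
                str(row["clearance_units"]),
                weight,
                profiles[species],
            )
            doses_raw = row.get("doses_mgkg", "")
            doses = tuple(
                float(d) for d in str(doses_raw).split(";") if d and not pd.isna(doses_raw)
            )
            reference = row.get("reference", "")
            record = MabRecord(
                mab_id=str(row["mab_id"]),
                species=species,
                clearance=cl,
                doses_mgkg=doses,
                reference="" if pd.isna(reference) else str(reference),
            )
        except (ValueError, TypeError) as exc:
            logger.warning("skipping row %d (%s): %s", idx, row.get("mab_id", "?"), exc)
            dataset.n_skipped += 1
            continue
        dataset.records.append(record)
        dose_range = row.get("human_dose_range")
        if dose_range is not None and not pd.isna(dose_range):
            dataset.dose_ranges[record.mab_id] = parse_dose_range(str(dose_range))
    if dataset.n_skipped:
        logger.warning("skipped %d malformed row(s)", dataset.n_skipped)
    return dataset


def write_records(
    records: Iterable[MabRecord],
    path: str | Path,
    dose_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> None:
    """Write records back to the canonical CSV schema (full precision)."""
    rows = []
    for r in records:
        row = {
            "mab_id": r.mab_id,
            "species": r.species,
            "clearance_value": repr(r.clearance),
            "clearance_units": "mL/day",
            "doses_mgkg": ";".join(repr(d) for d in r.doses_mgkg),
            "reference": r.reference,
        }
        if dose_ranges and r.mab_id in dose_ranges:
            low, high = dose_ranges[r.mab_id]
            row["human_dose_range"] = f"{low}-{high}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def predictions_frame(predictions: Iterable[ClearancePrediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mab_id": p.mab_id,
                "source_species": p.source_species,
                "method": p.method,
                "predicted_cl_human_mL_day": p.predicted_cl_human,
            }
            for p in predictions
        ]
    )


def write_predictions(
    predictions: Iterable[ClearancePrediction], path: str | Path
) -> None:
    predictions_frame(predictions).to_csv(path, index=False)


def dose_table(
    projections: Sequence[DoseProjection],
    dose_ranges: Mapping[str, tuple[float, float]] | None = None,
    rounded: bool = True,
) -> pd.DataFrame:
    """Dose-projection report: one row per mab x species, five method columns.

    When a clinical dose range is known for a mab, the row carries the
    range and an inclusive within-range flag for the Method I projection.
    """
    rows = []
    for p in projections:
        values = p.rounded() if rounded else p.as_tuple()
        row = {
            "mab_id": p.mab_id,
            "species": p.source_species,
            "animal_dose_mgkg": p.animal_dose_mgkg,
            "method_I_linear": values[0],
            "method_II_exp085": values[1],
            "method_III_hed_weight": values[2],
            "method_IV_hed_cl033": values[3],
            "method_V_hed_cl025": values[4],
        }
        if dose_ranges and p.mab_id in dose_ranges:
            low, high = dose_ranges[p.mab_id]
            check = check_dose_range(values[0], low, high, p.mab_id)
            row["human_dose_low"] = low
            row["human_dose_high"] = high
            row["within_range"] = check.within
        rows.append(row)
    return pd.DataFrame(rows)


def evaluation_table(summaries: Sequence[EvaluationSummary]) -> pd.DataFrame:
    """Evaluation report: per-species blocks, fold-error rows, method columns.

    Row order within a block: 0.5-2 fold, 0.5-1.5 fold, >2 fold, <0.5 fold,
    AFE. Counts are rendered "n (p%)"; AFE to two decimals.
    """
    by_key = {(s.species, s.method): s for s in summaries}
    species_order = []
    for s in summaries:
        if s.species not in species_order:
            species_order.append(s.species)
    methods = [m for m in REPORT_METHOD_ORDER if any(k[1] == m for k in by_key)]
    rows = []
    bin_rows = (
        ("0.5-2 fold", "n_within_2fold"),
        ("0.5-1.5 fold", "n_within_1p5fold"),
        (">2 fold", "n_over"),
        ("<0.5 fold", "n_under"),
    )
    for species in species_order:
        n = next(s.n for (sp, _), s in by_key.items() if sp == species)
        for label, attr in bin_rows:
            row = {"species": species, "n": n, "fold_error": label}
            for m in methods:
                s = by_key.get((species, m))
                if s is not None:
                    count = getattr(s, attr)
                    row[REPORT_METHOD_LABELS[m]] = f"{count} ({s.percent(count)}%)"
            rows.append(row)
        row = {"species": species, "n": n, "fold_error": "AFE"}
        for m in methods:
            s = by_key.get((species, m))
            if s is not None:
                row[REPORT_METHOD_LABELS[m]] = f"{round_half_away(s.afe, 2):.2f}"
        rows.append(row)
    return pd.DataFrame(rows)


def to_markdown(frame: pd.DataFrame) -> str:
    """Render a report frame as a GitHub-style markdown table."""
    cols = list(frame.columns)
    lines = ["| " + " | ".join(cols) + " |", "|" + "---|" * len(cols)]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join("" if pd.isna(v) else str(v) for v in row) + " |")
    return "\n".join(lines) + "\n"
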
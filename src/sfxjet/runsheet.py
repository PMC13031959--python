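"""Readers and writers for experiment run sheets.

A run sheet is a delimited table (CSV or TSV, sniffed from the extension)
with one row per run; units are encoded in the column names exactly as a
beamline scientist would keep them (µL/min, mg/min, MHz, µm) and everything
is converted to SI on read.  The sheath-flow cell may read ``NA`` for
single-liquid (GDVN) operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import units
from .hydro import diameter_from_continuity, velocity_from_displacement
from .params import BeamSpec, JetSpec, PulseTrain, ValidationError


class FormatError(ValueError):
    """Run sheet does not match the expected schema."""


MANDATORY_COLUMNS = (
    "sample",
    "sample_flow_ul_min",
    "sheath_flow_ul_min",
    "he_flow_mg_min",
    "intra_train_mhz",
    "pulses_per_train",
    "displacement_um",
)

DEFAULT_TRAINS_PER_S = 10.0  # facility train rate
DEFAULT_BEAM_UM = 0.6  # focused nano-KB configuration


@dataclass(frozen=True)
class RunRecord:
    """One parsed run: label, SI jet/pulse/beam specs, measured displacement."""

    label: str
    jet: JetSpec
    pulses: PulseTrain
    beam: BeamSpec
    displacement: float  # m, gap travel between consecutive pulses


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_experiment_table(path: str | Path) -> list[RunRecord]:
    """Parse a run sheet into SI records, preserving row order."""
    df = _read_table(path)
    if df.empty:
        return []
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"run sheet is missing mandatory column(s): {', '.join(missing)}")
    records = []
    for i, row in df.iterrows():
        label = str(row["sample"])
        Q_i = float(row["sample_flow_ul_min"]) * units.UL_PER_MIN
        sheath = row["sheath_flow_ul_min"]
        Q_o = 0.0 if (pd.isna(sheath) or str(sheath).strip().upper() == "NA") else float(sheath) * units.UL_PER_MIN
        if Q_i <= 0:
            raise ValidationError(f"row {i} ({label}): sample flow must be positive")
        gas = float(row["he_flow_mg_min"]) * units.MG_PER_MIN
        intra = float(row["intra_train_mhz"]) * units.MHZ
        pulses = PulseTrain(
            trains_per_second=float(row.get("trains_per_s", DEFAULT_TRAINS_PER_S) or DEFAULT_TRAINS_PER_S),
            pulses_per_train=int(row["pulses_per_train"]),
            intra_train_rate=intra,
        )
        displacement = float(row["displacement_um"]) * units.UM
        v = velocity_from_displacement(displacement, intra)
        d = diameter_from_continuity(Q_i + Q_o, v)
        jet = JetSpec(d_j=d, v_j=v, Q_i=Q_i, Q_o=Q_o, gas_mass_flow=gas)
        bx = float(row.get("beam_x_um", DEFAULT_BEAM_UM) or DEFAULT_BEAM_UM) * units.UM
        by = float(row.get("beam_y_um", DEFAULT_BEAM_UM) or DEFAULT_BEAM_UM) * units.UM
        energy = row.get("photon_energy_kev")
        eff = row.get("eff_pulse_energy_uj")
        beam = BeamSpec(
            width_x=bx,
            width_y=by,
            photon_energy_kev=None if pd.isna(energy) else float(energy),
            effective_pulse_energy_j=None if pd.isna(eff) else float(eff) * 1e-6,
        )
        records.append(RunRecord(label=label, jet=jet, pulses=pulses, beam=beam, displacement=displacement))
    return records


def write_experiment_table(records: Sequence[RunRecord], path: str | Path) -> None:
    """Inverse of :func:`read_experiment_table` (SI back to sheet units)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample": r.label,
                "sample_flow_ul_min": r.jet.Q_i / units.UL_PER_MIN,
                "sheath_flow_ul_min": r.jet.Q_o / units.UL_PER_MIN,
                "he_flow_mg_min": r.jet.gas_mass_flow / units.MG_PER_MIN,
                "intra_train_mhz": r.pulses.intra_train_rate / units.MHZ,
                "pulses_per_train": r.pulses.pulses_per_train,
                "trains_per_s": r.pulses.trains_per_second,
                "displacement_um": r.displacement / units.UM,
                "beam_x_um": r.beam.width_x / units.UM,
                "beam_y_um": r.beam.width_y / units.UM,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


REPORT_COLUMNS = (
    "sample",
    "jet_velocity_m_s",
    "jet_diameter_um",
    "dilution",
    "pulses_per_s",
)


def derived_row(r: RunRecord) -> dict:
    """The derived characterisation columns for one run."""
    return {
        "sample": r.label,
        "jet_velocity_m_s": r.jet.v_j,
        "jet_diameter_um": r.jet.d_j / units.UM,
        "dilution": r.jet.dilution,
        "pulses_per_s": r.pulses.pulses_per_second,
    }


def write_report(
    records: Sequence[RunRecord],
    derived: Mapping[str, Mapping[str, float]],
    path: str | Path,
) -> pd.DataFrame:
    """Write the derived-results table; extra per-label diagnostics welcome.

    ``derived`` maps run labels to extra columns (polymer or gas diagnostics);
    every key must match a record label.
    """
    labels = {r.label for r in records}
    unknown = set(derived) - labels
    if unknown:
        raise ValidationError(f"derived results for unknown label(s): {', '.join(sorted(unknown))}")
    rows = []
    for r in records:
        row = derived_row(r)
        row.update(derived.get(r.label, {}))
        rows.append(row)
    df = pd.DataFrame(rows)
    # deterministic column order: standard columns first, extras alphabetical
    extras = sorted(c for c in df.columns if c not in REPORT_COLUMNS)
    df = df[[c for c in REPORT_COLUMNS if c in df.columns] + extras]
    df.to_csv(path, index=False)
    return df
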
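"""Plain-text I/O: event-table CSV, spectrum CSV, JSON reports.

Event tables are CSV with the canonical column header and run-level
metadata (flow rate, duration, medium conductivity) in ``# key=value``
comment lines before the header.  Spectra are three-column CSV
(frequency_hz, re, im).  Reports and configs are JSON.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EVENT_COLUMNS, EventTable
from .materials import FrequencyGrid
from .spectrum_fit import PopulationSpectrum

__all__ = [
    "write_event_table",
    "read_event_table",
    "write_spectrum",
    "read_spectrum",
    "write_json",
    "read_json",
]


def write_event_table(table: EventTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# flow_rate_ul_min={table.flow_rate!r}\n")
        fh.write(f"# duration_s={table.duration!r}\n")
        fh.write(f"# medium_conductivity_s_m={table.medium_conductivity!r}\n")
        table.events.to_csv(fh, index=False, float_format="%.12g")


def read_event_table(path: str | Path) -> EventTable:
    path = Path(path)
    meta: dict[str, float] = {}
    lines = path.read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line[1:].strip().partition("=")
        meta[key.strip()] = float(value)
    try:
        df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed event table {path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"event table {path} (line {body_start + 1}) missing column(s): {missing}"
        )
    if "true_label" in df.columns:
        df["true_label"] = df["true_label"].astype(object).where(df["true_label"].notna(), None)
    return EventTable(
        df,
        flow_rate=meta.get("flow_rate_ul_min", 30.0),
        duration=meta.get("duration_s", 120.0),
        medium_conductivity=meta.get("medium_conductivity_s_m", 2.9),
    )


def write_spectrum(spectrum: PopulationSpectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# n_cells={spectrum.n_cells}\n")
        fh.write(f"# bead_diameter_um={spectrum.reference[0]!r}\n")
        fh.write(f"# ref_frequency_hz={spectrum.reference[1]!r}\n")
        pd.DataFrame(
            {
                "frequency_hz": spectrum.grid.frequencies,
                "re": spectrum.observed.real,
                "im": spectrum.observed.imag,
            }
        ).to_csv(fh, index=False, float_format="%.12g")


def read_spectrum(path: str | Path) -> PopulationSpectrum:
    path = Path(path)
    meta: dict[str, float] = {}
    lines = path.read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line[1:].strip().partition("=")
        meta[key.strip()] = float(value)
    df = pd.read_csv(_io.StringIO("".join(lines[body_start:])))
    for col in ("frequency_hz", "re", "im"):
        if col not in df.columns:
            raise ValueError(f"spectrum {path} missing column {col!r}")
    return PopulationSpectrum(
        FrequencyGrid(df["frequency_hz"].to_numpy()),
        df["re"].to_numpy() + 1j * df["im"].to_numpy(),
        n_cells=int(meta.get("n_cells", 1)),
        reference=(meta.get("bead_diameter_um", 5.0), meta.get("ref_frequency_hz", 80e6)),
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
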
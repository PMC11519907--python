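"""Per-event feature extraction for dual-frequency impedance cytometry.

Each particle transit yields a complex current at 1 MHz (size band: the
real part scales with particle volume in a high-conductivity medium) and
at 500 MHz (internal-composition band: the phase separates solid plastics
from membranous cells).  Events are carried in a pandas DataFrame inside
an :class:`EventTable`; the classifier consumes a two-column feature
matrix of (electrical diameter in um, baseline-subtracted 500 MHz phase
in radians).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "EventTable",
    "SizeCalibration",
    "calibrate_size",
    "calibrate_phase_baseline",
    "electrical_diameter",
    "phase_hf",
    "extract_features",
    "gate_beads",
]

#: Canonical event-table column order (CSV dialect).
EVENT_COLUMNS = [
    "timestamp_s",
    "re_1mhz",
    "im_1mhz",
    "re_500mhz",
    "im_500mhz",
    "velocity_m_s",
    "true_label",
]

#: Default limit of detection for electrical diameter, um.
DEFAULT_LOD_UM = 1.5


@dataclass
class EventTable:
    """Ordered per-event records plus run-level metadata.

    ``events`` holds one row per detected particle with the canonical
    columns; ``flow_rate`` is in uL/min, ``duration`` in seconds, and
    ``medium_conductivity`` in S/m.
    """

    events: pd.DataFrame
    flow_rate: float = 30.0
    duration: float = 120.0
    medium_conductivity: float = 2.9

    def __post_init__(self) -> None:
        if self.flow_rate <= 0 or self.duration <= 0:
            raise ValueError("flow rate and duration must be positive")
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"event table missing column(s): {missing}")
        self.events = self.events[EVENT_COLUMNS].reset_index(drop=True)

    @property
    def volume_ul(self) -> float:
        """Analysed sample volume in uL."""
        return self.flow_rate * self.duration / 60.0

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class SizeCalibration:
    """Bead-derived size and phase reference for one run."""

    bead_diameter: float  # um
    bead_median_signal: float  # arbitrary current units (re at 1 MHz)
    phase_baseline: float = 0.0  # radians, median bead phase at 500 MHz

    def __post_init__(self) -> None:
        if self.bead_diameter <= 0 or self.bead_median_signal <= 0:
            raise ValueError("bead diameter and median signal must be positive")


def calibrate_size(
    bead_events: pd.DataFrame,
    bead_diameter: float = 2.0,
    min_events: int = 10,
) -> SizeCalibration:
    """Build a :class:`SizeCalibration` from calibration-bead events.

    The size reference is the median 1 MHz real signal over the beads
    (median: robust against stray large particles inside the bead gate);
    the phase baseline is the median four-quadrant 500 MHz phase.
    """
    if len(bead_events) < min_events:
        raise ValueError(
            f"need at least {min_events} bead events for calibration, got {len(bead_events)}"
        )
    median_signal = float(np.median(bead_events["re_1mhz"]))
    baseline = float(
        np.median(np.arctan2(bead_events["im_500mhz"], bead_events["re_500mhz"]))
    )
    return SizeCalibration(bead_diameter, median_signal, baseline)


def calibrate_phase_baseline(bead_events: pd.DataFrame) -> float:
    """Median 500 MHz phase of the calibration beads, radians."""
    return float(np.median(np.arctan2(bead_events["im_500mhz"], bead_events["re_500mhz"])))


def electrical_diameter(re_1mhz, c: SizeCalibration):
    """Electrical diameter in um: bead_diameter * (signal/bead_median)^(1/3).

    The 1 MHz real signal is proportional to particle volume, so the cube
    root maps it to a diameter once anchored to beads of known size.
    Accepts scalars or arrays; non-positive signals yield NaN (flagged
    invalid) rather than raising.
    """
    s = np.asarray(re_1mhz, dtype=float)
    with np.errstate(invalid="ignore"):
        d = c.bead_diameter * np.cbrt(s / c.bead_median_signal)
    d = np.where(s > 0, d, np.nan)
    return float(d) if d.ndim == 0 else d


def phase_hf(re_500mhz, im_500mhz, baseline: float = 0.0):
    """Baseline-subtracted four-quadrant 500 MHz phase, radians.

    Events with a zero high-frequency vector are invalid and yield NaN.
    """
    re = np.asarray(re_500mhz, dtype=float)
    im = np.asarray(im_500mhz, dtype=float)
    ph = np.arctan2(im, re) - baseline
    ph = np.where((re == 0) & (im == 0), np.nan, ph)
    return float(ph) if ph.ndim == 0 else ph


def extract_features(
    t: EventTable,
    c: SizeCalibration,
    lod: float = DEFAULT_LOD_UM,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (n, 2) of (electrical diameter um, HF phase rad).

    Events with electrical diameter below the limit of detection ``lod``
    (boundary inclusive: d >= lod is kept) or with invalid signals are
    dropped.  Returns the features and the integer index of surviving rows
    in the original table, order preserved.
    """
    d = electrical_diameter(t.events["re_1mhz"].to_numpy(), c)
    ph = phase_hf(
        t.events["re_500mhz"].to_numpy(),
        t.events["im_500mhz"].to_numpy(),
        c.phase_baseline,
    )
    keep = np.isfinite(d) & np.isfinite(ph) & (d >= lod)
    idx = np.flatnonzero(keep)
    features = np.column_stack([d[idx], ph[idx]])
    return features, idx


def gate_beads(
    t: EventTable,
    c: SizeCalibration | None = None,
    diameter_window: tuple[float, float] = (1.8, 2.2),
) -> np.ndarray:
    """Boolean mask of calibration-bead events.

    Synthetic tables carry ground-truth labels, which are authoritative.
    For unlabeled (real-format) tables a rectangular electrical-diameter
    gate stands in for manual gating; it requires a calibration.
    """
    labels = t.events["true_label"]
    if labels.notna().any():
        return (labels == "bead").to_numpy()
    if c is None:
        raise ValueError("unlabeled table: a SizeCalibration is required for rectangular gating")
    d = electrical_diameter(t.events["re_1mhz"].to_numpy(), c)
    lo, hi = diameter_window
    mask = np.isfinite(d) & (d >= lo) & (d <= hi)
    if mask.any():
        # beads are solid plastics: keep the top phase quartile inside the window
        ph = phase_hf(
            t.events["re_500mhz"].to_numpy(),
            t.events["im_500mhz"].to_numpy(),
            c.phase_baseline,
        )
        q3 = np.nanquantile(ph[mask], 0.75)
        mask &= ph >= q3
    return mask
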
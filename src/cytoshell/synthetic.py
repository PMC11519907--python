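"""Seeded synthetic-data generators standing in for the instrument.

The generators emulate the statistical structure the analysis assumes,
not the electrode physics:

* particle arrivals are Poisson in time at concentration x flow rate;
* per-class sizes are lognormal (median, geometric SD) over ~1.5-10 um;
* the 1 MHz real signal is proportional to particle volume, anchored so a
  2 um bead gives one signal unit, with multiplicative measurement noise;
* the 500 MHz phase is a class-dependent offset plus Gaussian noise whose
  SD grows as diameter shrinks (sd = coeff / d^3, i.e. inversely with
  volume) — small particles smear out in phase, as real data do;
* phytoplankton cultures carry a fraction of coliving-bacteria events;
* calibration beads are spiked in at a known concentration;
* mixtures combine stocks at volumetric ratios, diluting each stock.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dielectric import cm_spectrum
from .events import EVENT_COLUMNS, EventTable
from .materials import DielectricMaterial, FrequencyGrid, HomogeneousParticle, ShelledParticle
from .spectrum_fit import PopulationSpectrum

__all__ = [
    "ClassGenSpec",
    "MixtureSpec",
    "BEAD_SPEC",
    "default_class_specs",
    "gen_monoculture",
    "gen_mixture",
    "gen_population_spectrum",
]

#: 1 MHz signal units per (bead diameter)^3; beads read exactly 1.0.
_BEAD_DIAMETER_UM = 2.0


@dataclass(frozen=True)
class ClassGenSpec:
    """Statistical description of one particle class.

    ``phase_offset`` is the mean 500 MHz phase (radians) of the class;
    ``phase_noise_coeff`` sets the phase SD as coeff / diameter^3
    (radians um^3), capturing the loss of phase precision for small
    particles.  ``contamination_fraction`` adds coliving-bacteria events
    at that fraction of the class's own event count.
    """

    label: str
    size_median: float  # um
    size_gsd: float  # geometric SD, >= 1
    phase_offset: float  # rad
    phase_noise_coeff: float = 0.2  # rad um^3
    amplitude_noise_cv: float = 0.05  # multiplicative 1 MHz noise CV
    contamination_fraction: float = 0.0
    contamination_spec: "ClassGenSpec | None" = None

    def __post_init__(self) -> None:
        if self.size_median <= 0:
            raise ValueError("size median must be positive")
        if self.size_gsd < 1:
            raise ValueError("geometric SD must be >= 1")
        if not 0 <= self.contamination_fraction < 1:
            raise ValueError("contamination fraction must lie in [0, 1)")
        if self.contamination_fraction > 0 and self.contamination_spec is None:
            raise ValueError("contamination fraction set but no contamination spec given")


@dataclass(frozen=True)
class MixtureSpec:
    """Stock concentrations (particles/uL) and volumetric mixing ratios."""

    components: dict[str, float]
    volumetric_ratio: dict[str, float]
    bead_concentration: float = 200.0

    def __post_init__(self) -> None:
        if set(self.components) != set(self.volumetric_ratio):
            raise ValueError("components and volumetric ratios must cover the same labels")
        total = sum(self.volumetric_ratio.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"volumetric ratios must sum to 1, got {total}")
        if any(c < 0 for c in self.components.values()) or self.bead_concentration < 0:
            raise ValueError("concentrations must be non-negative")


_BACTERIA_SPEC = ClassGenSpec(
    label="bacteria",
    size_median=1.3,
    size_gsd=1.25,
    phase_offset=0.09,
)

#: Calibration beads: tightly manufactured 2 um polystyrene, plastic-like phase.
BEAD_SPEC = ClassGenSpec(
    label="bead",
    size_median=2.0,
    size_gsd=1.03,
    phase_offset=0.30,
)


def default_class_specs() -> dict[str, ClassGenSpec]:
    """Default five-class world: a microplastic mix and four phytoplankton.

    Medians echo the monoculture experiments (2/3/5/8 um plastics; the
    smallest phytoplankton sits partly below the 1.5 um detection limit)
    and plastics carry a distinctly higher 500 MHz phase than cells.
    Phytoplankton cultures are non-axenic: 10% coliving-bacteria events.
    """
    bact = _BACTERIA_SPEC
    return {
        "microplastic": ClassGenSpec(
            label="microplastic",
            size_median=3.0,
            size_gsd=1.45,  # broad: stands in for the 2/3/5/8 um mixture
            phase_offset=0.30,
        ),
        "i_galbana": ClassGenSpec(
            label="i_galbana",
            size_median=5.0,
            size_gsd=1.2,
            phase_offset=0.05,
            contamination_fraction=0.10,
            contamination_spec=bact,
        ),
        "c_vulgaris": ClassGenSpec(
            label="c_vulgaris",
            size_median=3.5,
            size_gsd=1.2,
            phase_offset=0.08,
            contamination_fraction=0.10,
            contamination_spec=bact,
        ),
        "p_purpureum": ClassGenSpec(
            label="p_purpureum",
            size_median=6.0,
            size_gsd=1.2,
            phase_offset=0.03,
            contamination_fraction=0.10,
            contamination_spec=bact,
        ),
        "synechococcus": ClassGenSpec(
            label="synechococcus",
            size_median=1.2,
            size_gsd=1.3,
            phase_offset=0.10,
            contamination_fraction=0.10,
            contamination_spec=bact,
        ),
    }


def _draw_class_events(
    rng: np.random.Generator,
    spec: ClassGenSpec,
    concentration: float,
    volume_ul: float,
    duration: float,
    label: str | None = None,
) -> pd.DataFrame:
    """Poisson number of events for one class, with signals and timestamps."""
    n = rng.poisson(concentration * volume_ul)
    d = spec.size_median * np.exp(np.log(spec.size_gsd) * rng.standard_normal(n))
    amp = (d / _BEAD_DIAMETER_UM) ** 3 * (1.0 + spec.amplitude_noise_cv * rng.standard_normal(n))
    amp = np.abs(amp)  # physical events have positive volume signal
    phase = spec.phase_offset + (spec.phase_noise_coeff / d**3) * rng.standard_normal(n)
    # HF magnitude also tracks volume (same electronics path, different band)
    hf_mag = amp * (1.0 + spec.amplitude_noise_cv * rng.standard_normal(n))
    hf_mag = np.abs(hf_mag)
    t = np.sort(rng.uniform(0.0, duration, n))
    return pd.DataFrame(
        {
            "timestamp_s": t,
            "re_1mhz": amp,
            "im_1mhz": 0.02 * amp * rng.standard_normal(n),
            "re_500mhz": hf_mag * np.cos(phase),
            "im_500mhz": hf_mag * np.sin(phase),
            "velocity_m_s": rng.normal(0.2, 0.01, n),
            "true_label": label or spec.label,
        }
    )


def gen_monoculture(
    spec: ClassGenSpec,
    concentration: float,
    bead_concentration: float = 100.0,
    flow_rate: float = 30.0,
    duration: float = 120.0,
    seed: int = 0,
    medium_conductivity: float = 2.9,
) -> EventTable:
    """Synthesise one monodisperse run with bead spike-ins.

    ``concentration`` and ``bead_concentration`` are particles/uL;
    ``flow_rate`` uL/min; ``duration`` s.  Contamination events (coliving
    bacteria) are added at ``spec.contamination_fraction`` of the class's
    expected count.  Deterministic per (spec, parameters, seed).
    """
    if duration <= 0 or flow_rate <= 0:
        raise ValueError("duration and flow rate must be positive")
    if concentration < 0 or bead_concentration < 0:
        raise ValueError("concentrations must be non-negative")
    rng = np.random.default_rng(seed)
    volume_ul = flow_rate * duration / 60.0
    parts = [_draw_class_events(rng, spec, concentration, volume_ul, duration)]
    if spec.contamination_fraction > 0:
        parts.append(
            _draw_class_events(
                rng,
                spec.contamination_spec,
                spec.contamination_fraction * concentration,
                volume_ul,
                duration,
            )
        )
    if bead_concentration > 0:
        parts.append(_draw_class_events(rng, BEAD_SPEC, bead_concentration, volume_ul, duration))
    events = (
        pd.concat(parts, ignore_index=True)
        .sort_values("timestamp_s", kind="stable")
        .reset_index(drop=True)
    )
    return EventTable(events, flow_rate, duration, medium_conductivity)


def gen_mixture(
    mix: MixtureSpec,
    class_specs: Mapping[str, ClassGenSpec],
    flow_rate: float = 30.0,
    duration: float = 120.0,
    seed: int = 0,
    medium_conductivity: float = 2.9,
) -> tuple[EventTable, dict[str, float]]:
    """Synthesise a mixed sample and return it with realized truth.

    Each component's effective concentration is its stock concentration
    times its volumetric fraction (five equal stocks -> stock/5).  The
    returned truth map holds the *realized* per-label concentrations
    (generated event counts / volume), including contamination labels and
    beads, so classifier error can be separated from Poisson error.
    """
    missing = set(mix.components) - set(class_specs)
    if missing:
        raise ValueError(f"no generator spec for component(s): {sorted(missing)}")
    rng = np.random.default_rng(seed)
    volume_ul = flow_rate * duration / 60.0
    parts: list[pd.DataFrame] = []
    for label, stock in mix.components.items():
        spec = class_specs[label]
        eff = stock * mix.volumetric_ratio[label]
        parts.append(_draw_class_events(rng, spec, eff, volume_ul, duration))
        if spec.contamination_fraction > 0:
            parts.append(
                _draw_class_events(
                    rng,
                    spec.contamination_spec,
                    spec.contamination_fraction * eff,
                    volume_ul,
                    duration,
                )
            )
    if mix.bead_concentration > 0:
        parts.append(_draw_class_events(rng, BEAD_SPEC, mix.bead_concentration, volume_ul, duration))
    events = (
        pd.concat(parts, ignore_index=True)
        .sort_values("timestamp_s", kind="stable")
        .reset_index(drop=True)
    )
    truth = {
        label: count / volume_ul
        for label, count in events["true_label"].value_counts().items()
    }
    table = EventTable(events, flow_rate, duration, medium_conductivity)
    return table, truth


def gen_population_spectrum(
    particle: ShelledParticle | HomogeneousParticle,
    medium: DielectricMaterial,
    grid: FrequencyGrid,
    n_cells: int = 10000,
    noise_sd: float = 0.0,
    scale: float = 1.0,
    seed: int = 0,
    reference: tuple[float, float] = (5.0, 80e6),
) -> tuple[PopulationSpectrum, dict[str, float]]:
    """Noisy population-mean CM spectrum plus the generating truth.

    observed(f) = scale * f_CM(f) * (1 + complex Gaussian noise), with the
    per-frequency noise SD equal to noise_sd / sqrt(n_cells) — averaging
    n_cells independent single-cell measurements.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    clean = scale * cm_spectrum(particle, medium, grid).values
    sd = noise_sd / math.sqrt(n_cells)
    noise = sd * (rng.standard_normal(len(grid)) + 1j * rng.standard_normal(len(grid)))
    observed = clean * (1.0 + noise)
    spectrum = PopulationSpectrum(grid, observed, n_cells, reference)
    truth = {"scale": scale, "noise_sd": noise_sd}
    return spectrum, truth
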
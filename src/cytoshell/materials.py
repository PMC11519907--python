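"""Dielectric materials and particle geometries.

Particles suspended in a conductive medium are described by a small set of
frozen dataclasses: a :class:`DielectricMaterial` is a (relative permittivity,
conductivity) pair for any phase — cytoplasm, lipid, membrane, scale layer,
plastic, or the suspending medium; a :class:`HomogeneousParticle` is a solid
sphere of one material (calibration beads, microplastics); a
:class:`ShelledParticle` is a concentric-shell cell model whose core is a
host/inclusion mixture (cytoplasm with lipid vesicles) wrapped in ordered
shell layers (plasma membrane, then an outer organic scale layer).

Factory functions at the bottom build the default *Isochrysis galbana*
double-shell model and the standard seawater-like medium and bead materials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPS0",
    "DielectricMaterial",
    "ShellLayer",
    "ShelledParticle",
    "HomogeneousParticle",
    "FrequencyGrid",
    "seawater_medium",
    "polystyrene",
    "pmma",
    "lipid_inclusion",
    "isochrysis_galbana",
    "bead",
]

#: Vacuum permittivity, F/m.
EPS0 = 8.854e-12


@dataclass(frozen=True)
class DielectricMaterial:
    """A linear, isotropic dielectric phase.

    Parameters
    ----------
    relative_permittivity : float
        Dimensionless relative permittivity, >= 1 for passive matter.
    conductivity : float
        DC conductivity in S/m, >= 0.
    """

    relative_permittivity: float
    conductivity: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.relative_permittivity) and math.isfinite(self.conductivity)):
            raise ValueError("material properties must be finite")
        if self.relative_permittivity < 1:
            raise ValueError(f"relative permittivity must be >= 1, got {self.relative_permittivity}")
        if self.conductivity < 0:
            raise ValueError(f"conductivity must be >= 0, got {self.conductivity}")


@dataclass(frozen=True)
class ShellLayer:
    """A concentric shell of given material and radial thickness (m)."""

    material: DielectricMaterial
    thickness: float

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"shell thickness must be > 0, got {self.thickness}")


@dataclass(frozen=True)
class ShelledParticle:
    """Sphere with a mixed core and ordered concentric shells.

    The core is a host material (cytoplasm) carrying a volume fraction
    ``lipid_fraction`` of spherical lipid inclusions, homogenised by
    Maxwell-Garnett mixing.  ``shells`` are ordered innermost first
    (membrane before scale layer); their thicknesses are subtracted
    inward from ``outer_radius`` to locate the core boundary.
    """

    outer_radius: float
    core_host: DielectricMaterial
    lipid: DielectricMaterial
    lipid_fraction: float
    shells: tuple[ShellLayer, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shells", tuple(self.shells))
        if self.outer_radius <= 0:
            raise ValueError("outer radius must be > 0")
        if not 0 <= self.lipid_fraction < 1:
            raise ValueError(f"lipid fraction must lie in [0, 1), got {self.lipid_fraction}")
        if sum(s.thickness for s in self.shells) >= self.outer_radius:
            raise ValueError("total shell thickness must be smaller than the outer radius")

    @property
    def core_radius(self) -> float:
        return self.outer_radius - sum(s.thickness for s in self.shells)

    def interface_radii(self) -> list[float]:
        """Radii of the material interfaces, innermost (core surface) first."""
        radii = [self.core_radius]
        for s in self.shells:
            radii.append(radii[-1] + s.thickness)
        return radii


@dataclass(frozen=True)
class HomogeneousParticle:
    """Solid uniform sphere (calibration bead or microplastic)."""

    radius: float
    material: DielectricMaterial

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly ascending grid of positive frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise ValueError("frequency grid must be a non-empty 1-D array")
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly ascending")
        object.__setattr__(self, "frequencies", f)

    def __len__(self) -> int:
        return len(self.frequencies)

    @classmethod
    def log_spaced(cls, f_min: float, f_max: float, n: int) -> "FrequencyGrid":
        return cls(np.logspace(np.log10(f_min), np.log10(f_max), n))


# ---------------------------------------------------------------------------
# Standard materials and particles
# ---------------------------------------------------------------------------

def seawater_medium(conductivity: float = 2.9, relative_permittivity: float = 78.0) -> DielectricMaterial:
    """Seawater-like suspending medium (f/2 culture medium, ~2.9 S/m)."""
    return DielectricMaterial(relative_permittivity, conductivity)


def polystyrene() -> DielectricMaterial:
    """Polystyrene: low-loss solid, eps_r 2.55."""
    return DielectricMaterial(2.55, 0.0)


def pmma() -> DielectricMaterial:
    """PMMA: low-loss solid, eps_r 2.6 at RF."""
    return DielectricMaterial(2.6, 0.0)


def lipid_inclusion() -> DielectricMaterial:
    """Oil-like lipid vesicle phase: eps_r 2.2, essentially non-conducting."""
    return DielectricMaterial(2.2, 1e-6)


def bead(diameter_um: float, material: DielectricMaterial | None = None) -> HomogeneousParticle:
    """Polystyrene calibration bead of the given diameter in micrometres."""
    return HomogeneousParticle(diameter_um * 1e-6 / 2.0, material or polystyrene())


def isochrysis_galbana(
    radius: float = 2.5e-6,
    eps_core: float = 63.0,
    sigma_core: float = 1.12,
    lipid_fraction: float = 0.20,
    eps_membrane: float = 6.0,
    sigma_membrane: float = 5.0e-4,
    membrane_thickness: float = 5e-9,
    eps_scale: float = 13.0,
    sigma_scale: float = 9.9e-3,
    scale_thickness: float = 100e-9,
    lipid: DielectricMaterial | None = None,
) -> ShelledParticle:
    """Default double-shell *I. galbana* cell model.

    Cytoplasm host with 20% lipid vesicle inclusions, a 5 nm plasma
    membrane, and a 100 nm organic scale layer.  Core host permittivity
    and conductivity are the fitted population values; the radius is a
    configurable default (population mean size is not tightly known).
    """
    return ShelledParticle(
        outer_radius=radius,
        core_host=DielectricMaterial(eps_core, sigma_core),
        lipid=lipid or lipid_inclusion(),
        lipid_fraction=lipid_fraction,
        shells=(
            ShellLayer(DielectricMaterial(eps_membrane, sigma_membrane), membrane_thickness),
            ShellLayer(DielectricMaterial(eps_scale, sigma_scale), scale_thickness),
        ),
    )
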
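"""Concentric cylindrical geometry, radial grid, and region indicator masks.

The model domain is a cross-section through four concentric layers: the
vessel lumen (radius ``a``), the endothelium (thickness ``h``), the
remaining vascular structures plus extracellular space (thickness ``d``),
and a layer of neurons (thickness ``g``).  Concentrations live on the
nodes of an equispaced radial grid over ``[0, a+h+d+g]``; the Heaviside
factors of the mass balance are realized as boolean node masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Geometry", "RadialGrid", "RegionMasks", "build_grid", "region_masks"]

#: relative tolerance on r used to decide region membership at interfaces
INTERFACE_RTOL = 1e-12


@dataclass(frozen=True)
class Geometry:
    """Layer thicknesses of the concentric cylindrical domain, in meters.

    Attributes
    ----------
    a : float
        Lumen radius.
    h : float
        Endothelium thickness.
    d : float
        Vascular-structures / extracellular-space thickness.
    g : float
        Neuronal layer thickness.
    """

    a: float
    h: float
    d: float
    g: float

    def __post_init__(self) -> None:
        for name in ("a", "h", "d", "g"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"geometry field {name!r} must be strictly positive, got {v}")

    @property
    def total_radius(self) -> float:
        """Outer radius R = a + h + d + g."""
        return self.a + self.h + self.d + self.g

    # interface radii, from the axis outwards
    @property
    def r_endothelium(self) -> float:
        return self.a

    @property
    def r_extracellular(self) -> float:
        return self.a + self.h

    @property
    def r_neuronal(self) -> float:
        return self.a + self.h + self.d


@dataclass(frozen=True)
class RadialGrid:
    """Equispaced nodes ``r_0 = L < r_1 < ... < r_N = R``.

    The two end nodes carry the homogeneous Dirichlet condition; the
    interior nodes ``r_1 .. r_{N-1}`` carry the unknowns.
    """

    L: float
    R: float
    N: int
    dr: float = field(init=False)
    nodes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError(f"need at least 4 intervals, got N={self.N}")
        if not self.R > self.L:
            raise ValueError(f"grid endpoints must satisfy R > L, got L={self.L}, R={self.R}")
        object.__setattr__(self, "dr", (self.R - self.L) / self.N)
        object.__setattr__(self, "nodes", self.L + self.dr * np.arange(self.N + 1))

    @property
    def interior(self) -> np.ndarray:
        return self.nodes[1:-1]

    def nearest_node(self, r: float) -> int:
        """Index of the node closest to position ``r``."""
        return int(np.argmin(np.abs(self.nodes - r)))


@dataclass(frozen=True)
class RegionMasks:
    """Boolean node masks for the four layers plus the inactivation region.

    The four primary masks partition the nodes; ``inactivation`` is the
    union of ``extracellular`` and ``neuronal`` (the region where the
    saturable inactivation term acts).
    """

    lumen: np.ndarray
    endothelium: np.ndarray
    extracellular: np.ndarray
    neuronal: np.ndarray
    inactivation: np.ndarray


def build_grid(geometry: Geometry, n_intervals: int) -> RadialGrid:
    """Build the equispaced radial grid over ``[0, a+h+d+g]``.

    Parameters
    ----------
    geometry : Geometry
        Layer thicknesses.
    n_intervals : int
        Number of grid intervals N; the grid has N+1 nodes.

    Returns
    -------
    RadialGrid
        Grid with step ``dr = (a+h+d+g)/N``.
    """
    return RadialGrid(L=0.0, R=geometry.total_radius, N=int(n_intervals))


def _heaviside_ge(r: np.ndarray, threshold: float, scale: float) -> np.ndarray:
    """H(r - threshold) with H(0) = 1, robust to round-off on r."""
    return r >= threshold - INTERFACE_RTOL * scale


def region_masks(grid: RadialGrid, geometry: Geometry) -> RegionMasks:
    """Assign every node to exactly one layer.

    Interfaces follow the right-continuous Heaviside convention H(0) = 1:
    a node exactly at an interface radius belongs to the outer region.
    Membership comparisons use a relative tolerance of 1e-12 on r so a
    node that lands on an interface up to round-off is classified as if
    it were exactly there.

    Raises
    ------
    ValueError
        If the grid does not span ``[0, a+h+d+g]`` for this geometry.
    """
    R = geometry.total_radius
    if abs(grid.R - R) > INTERFACE_RTOL * R * grid.N or abs(grid.L) > INTERFACE_RTOL * R:
        raise ValueError(
            f"grid [{grid.L}, {grid.R}] does not match geometry total radius {R}"
        )
    r = grid.nodes
    past_endo = _heaviside_ge(r, geometry.r_endothelium, R)     # H(r - a)
    past_extra = _heaviside_ge(r, geometry.r_extracellular, R)  # H(r - (a+h))
    past_neuro = _heaviside_ge(r, geometry.r_neuronal, R)       # H(r - (a+h+d))

    lumen = ~past_endo
    endothelium = past_endo & ~past_extra
    extracellular = past_extra & ~past_neuro
    neuronal = past_neuro
    return RegionMasks(
        lumen=lumen,
        endothelium=endothelium,
        extracellular=extracellular,
        neuronal=neuronal,
        inactivation=past_extra,
    )
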
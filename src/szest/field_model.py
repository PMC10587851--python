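"""24-2 visual field geometry and the discrete probability masses used by ZEST.

The 24-2 test pattern covers the central 24 degrees of the visual field on a
6-degree lattice (54 points, extended to 27 degrees on two mid-horizontal
points), of which 52 remain after excluding the two locations falling on the
physiological blind spot.  Coordinates are stored internally in right-eye
convention; left-eye data are mirrored about the vertical meridian at I/O.

Sensitivities are expressed in perimetric decibels (dB of stimulus
attenuation): higher dB means a dimmer stimulus is still seen, i.e. higher
sensitivity.  Priors and posteriors over candidate sensitivities are discrete
probability mass functions (:class:`Pmf`) on an integer dB domain, by default
0..40 dB.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "GridLocation",
    "Grid",
    "NeighborGraph",
    "Pmf",
    "Field",
    "make_grid",
    "build_neighbor_graph",
    "make_pmf",
    "uniform_pmf",
    "pmf_mean",
    "pmf_sd",
    "default_domain",
]

# Row layout of the right-eye 24-2 pattern (54 points): y -> x values.
# The two nasal-extension points sit at x = +27 on the mid-horizontal rows;
# the blind-spot locations (15, +/-3) are excluded below.
_ROWS_RIGHT: dict[int, tuple[int, ...]] = {
    21: (-9, -3, 3, 9),
    15: (-15, -9, -3, 3, 9, 15),
    9: (-21, -15, -9, -3, 3, 9, 15, 21),
    3: (-21, -15, -9, -3, 3, 9, 15, 21, 27),
    -3: (-21, -15, -9, -3, 3, 9, 15, 21, 27),
    -9: (-21, -15, -9, -3, 3, 9, 15, 21),
    -15: (-15, -9, -3, 3, 9, 15),
    -21: (-9, -3, 3, 9),
}

BLIND_SPOT = ((15, 3), (15, -3))

N_LOCATIONS = 52


@dataclass(frozen=True)
class GridLocation:
    """One 24-2 test location."""

    id: int
    x_deg: float
    y_deg: float

    @property
    def hemifield(self) -> str:
        return "superior" if self.y_deg > 0 else "inferior"

    @property
    def eccentricity(self) -> float:
        return math.hypot(self.x_deg, self.y_deg)


@dataclass(frozen=True)
class Grid:
    """The 52-location 24-2 grid for one eye."""

    eye_side: str
    locations: tuple[GridLocation, ...]

    def __post_init__(self) -> None:
        if len(self.locations) != N_LOCATIONS:
            raise ValueError(f"grid must have {N_LOCATIONS} locations")

    @property
    def ids(self) -> np.ndarray:
        return np.array([loc.id for loc in self.locations])

    @property
    def x(self) -> np.ndarray:
        return np.array([loc.x_deg for loc in self.locations], dtype=float)

    @property
    def y(self) -> np.ndarray:
        return np.array([loc.y_deg for loc in self.locations], dtype=float)

    def coord_index(self) -> dict[tuple[float, float], int]:
        return {(loc.x_deg, loc.y_deg): loc.id for loc in self.locations}

    def location_at(self, x_deg: float, y_deg: float) -> GridLocation:
        for loc in self.locations:
            if loc.x_deg == x_deg and loc.y_deg == y_deg:
                return loc
        raise KeyError(f"no 24-2 location at ({x_deg}, {y_deg})")

    def to_json(self) -> str:
        return json.dumps(
            {
                "eye_side": self.eye_side,
                "locations": [
                    {"id": loc.id, "x_deg": loc.x_deg, "y_deg": loc.y_deg}
                    for loc in self.locations
                ],
            }
        )


def make_grid(eye_side: str = "right") -> Grid:
    """Build the 52-location 24-2 grid.

    Locations are ordered row-major from the superior-temporal corner, as on
    a perimeter printout.  For left eyes the x coordinates are mirrored
    (x -> -x) relative to the right-eye lattice.
    """
    if eye_side not in ("right", "left"):
        raise ValueError(f"eye_side must be 'right' or 'left', got {eye_side!r}")
    sign = 1 if eye_side == "right" else -1
    locs: list[GridLocation] = []
    idx = 0
    for yv in sorted(_ROWS_RIGHT, reverse=True):
        for xv in _ROWS_RIGHT[yv]:
            if (xv, yv) in BLIND_SPOT:
                continue
            locs.append(GridLocation(id=idx, x_deg=sign * xv, y_deg=float(yv)))
            idx += 1
    return Grid(eye_side=eye_side, locations=tuple(locs))


@dataclass(frozen=True)
class NeighborGraph:
    """Undirected adjacency between grid locations.

    Edges never cross the horizontal midline (the anatomical raphe): retinal
    nerve fibre bundles serving the superior and inferior hemifields are
    largely independent, so evidence is not shared across it.  ``weight`` is
    the scaling factor applied to the likelihood when a response at one
    location updates its neighbours.
    """

    edges: frozenset[tuple[int, int]]
    weight: float

    def neighbors(self) -> dict[int, tuple[int, ...]]:
        adj: dict[int, list[int]] = {}
        for i, j in self.edges:
            adj.setdefault(i, []).append(j)
            adj.setdefault(j, []).append(i)
        return {k: tuple(sorted(v)) for k, v in adj.items()}

    def to_json(self) -> str:
        return json.dumps(
            {"weight": self.weight, "edges": sorted(map(list, self.edges))}
        )


def build_neighbor_graph(
    grid: Grid, weight: float, neighbor_rule: str = "rook"
) -> NeighborGraph:
    """Connect nearest-neighbour locations, never across the horizontal midline.

    ``rook`` connectivity joins pairs exactly 6 degrees apart (4-neighbour on
    the lattice); ``queen`` additionally joins diagonal pairs 6*sqrt(2) apart.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    if neighbor_rule not in ("rook", "queen"):
        raise ValueError(f"neighbor_rule must be 'rook' or 'queen', got {neighbor_rule!r}")
    max_d2 = 36.0 if neighbor_rule == "rook" else 72.0
    edges: set[tuple[int, int]] = set()
    locs = grid.locations
    for a in locs:
        for b in locs:
            if b.id <= a.id:
                continue
            if (a.y_deg > 0) != (b.y_deg > 0):
                continue  # midline rule
            d2 = (a.x_deg - b.x_deg) ** 2 + (a.y_deg - b.y_deg) ** 2
            if d2 <= max_d2 + 1e-9:
                edges.add((a.id, b.id))
    return NeighborGraph(edges=frozenset(edges), weight=weight)


def default_domain(lo: int = 0, hi: int = 40, step: int = 1, pad: int = 0) -> np.ndarray:
    """Integer dB domain for priors/posteriors; ``pad`` extends both ends."""
    return np.arange(lo - pad, hi + pad + 1, step, dtype=float)


@dataclass(frozen=True)
class Pmf:
    """Discrete probability mass over candidate sensitivities (dB).

    ``domain`` is strictly increasing; ``mass`` is normalised to sum to one.
    """

    domain: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain", np.asarray(self.domain, dtype=float))
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=float))

    def mean(self) -> float:
        return float(np.dot(self.mass, self.domain))

    def sd(self) -> float:
        m = self.mean()
        var = float(np.dot(self.mass, self.domain**2)) - m * m
        return math.sqrt(max(var, 0.0))

    def normalized(self) -> "Pmf":
        return make_pmf(self.domain, self.mass)


def make_pmf(domain: Iterable[float], mass: Iterable[float]) -> Pmf:
    d = np.asarray(list(domain) if not isinstance(domain, np.ndarray) else domain, dtype=float)
    m = np.asarray(list(mass) if not isinstance(mass, np.ndarray) else mass, dtype=float)
    if d.shape != m.shape:
        raise ValueError("domain and mass must have equal length")
    if np.any(np.diff(d) <= 0):
        raise ValueError("domain must be strictly increasing")
    if np.any(m < 0):
        raise ValueError("mass must be nonnegative")
    total = m.sum()
    if total <= 0:
        raise ValueError("mass must not be all zero (degenerate posterior)")
    return Pmf(domain=d, mass=m / total)


def uniform_pmf(domain: np.ndarray | None = None) -> Pmf:
    d = default_domain() if domain is None else np.asarray(domain, dtype=float)
    return make_pmf(d, np.ones_like(d))


def pmf_mean(p: Pmf) -> float:
    return p.mean()


def pmf_sd(p: Pmf) -> float:
    return p.sd()


@dataclass
class Field:
    """A visual field: one sensitivity value (dB) per grid location."""

    values: dict[int, float]
    label: str = ""

    def as_array(self, grid: Grid) -> np.ndarray:
        try:
            return np.array([self.values[loc.id] for loc in grid.locations], dtype=float)
        except KeyError as exc:
            raise KeyError(f"field missing value for location {exc.args[0]}") from exc

    @classmethod
    def from_array(cls, values: np.ndarray, label: str = "") -> "Field":
        return cls(values={i: float(v) for i, v in enumerate(values)}, label=label)

    def clamped(self, lo: float = 0.0, hi: float = 40.0) -> "Field":
        return Field(
            values={k: min(max(v, lo), hi) for k, v in self.values.items()},
            label=self.label,
        )

    def copy(self, label: str | None = None) -> "Field":
        return Field(values=dict(self.values), label=self.label if label is None else label)
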
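"""Prior distributions for the ZEST strategies.

Two families of priors are provided:

* the *agnostic* prior of standard ZEST — at every location, a 4:1 mixture of
  a "normal" sensitivity distribution and a broad "abnormal" (damaged)
  distribution, so the strategy starts bimodal and commits quickly to one
  mode;
* the *structural* priors of S-ZEST — empirical conditional distributions of
  measured sensitivity given the (rounded, integer-dB) sensitivity predicted
  from structural imaging, built per subject with both eyes of that subject
  left out so a subject's own data never inform its own priors.

The normal and abnormal mixture components shipped here are synthetic
stand-ins parameterised on eccentricity (normative perimetric data are
proprietary); both can be overridden from files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .field_model import Grid, GridLocation, Pmf, default_domain, make_pmf

__all__ = [
    "PairedRecord",
    "PriorTable",
    "round_half_away",
    "make_mixture_prior",
    "normal_component",
    "abnormal_component",
    "agnostic_prior",
    "agnostic_priors",
    "build_structural_prior_table",
    "lookup_structural_prior",
]

#: Weight of the normal component relative to the abnormal one.
DEFAULT_MIXTURE_RATIO = 4.0

#: Default per-bin histogram smoothing SD (dB) and mass floor.
DEFAULT_SMOOTHING_SD = 1.0
DEFAULT_FLOOR = 1e-4

#: Bins built from fewer records than this fall back to the nearest
#: populated bin when looked up.
DEFAULT_MIN_COUNT = 10


def round_half_away(x: float) -> int:
    """Round half away from zero (so 19.5 -> 20, -19.5 -> -20)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class PairedRecord:
    """One (structurally predicted, measured) sensitivity pair."""

    subject_id: str
    eye_id: str
    location_id: int
    predicted_db: float
    observed_db: float


def make_mixture_prior(normal: Pmf, abnormal: Pmf, ratio: float = DEFAULT_MIXTURE_RATIO) -> Pmf:
    """Mix normal and abnormal components weighted ``ratio`` : 1."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if normal.domain.shape != abnormal.domain.shape or np.any(
        normal.domain != abnormal.domain
    ):
        raise ValueError("mixture components must share the same domain")
    w = ratio / (ratio + 1.0)
    return make_pmf(normal.domain, w * normal.mass + (1.0 - w) * abnormal.mass)


def normal_sensitivity_mean(location: GridLocation) -> float:
    """Synthetic normative mean sensitivity (dB) at a location.

    Sensitivity is highest near fixation and declines with eccentricity:
    33 dB on the innermost ring (eccentricity ~4.2 deg) falling 0.7 dB per
    6 deg of additional eccentricity.
    """
    inner = math.hypot(3.0, 3.0)
    return 33.0 - 0.7 * max(0.0, (location.eccentricity - inner)) / 6.0


def normal_component(
    location: GridLocation, domain: np.ndarray | None = None, sd: float = 2.0
) -> Pmf:
    """Discretised Gaussian around the normative mean for one location."""
    d = default_domain() if domain is None else np.asarray(domain, dtype=float)
    mu = normal_sensitivity_mean(location)
    mass = np.exp(-0.5 * ((d - mu) / sd) ** 2)
    return make_pmf(d, mass)


def abnormal_component(domain: np.ndarray | None = None) -> Pmf:
    """Broad low-sensitivity component: half-Gaussian at 0 dB (SD 8) mixed
    1:1 with a uniform over 0..25 dB.  A synthetic stand-in for an empirical
    distribution of glaucomatous thresholds."""
    d = default_domain() if domain is None else np.asarray(domain, dtype=float)
    half_gauss = np.where(d >= 0, np.exp(-0.5 * (d / 8.0) ** 2), 0.0)
    uniform = ((d >= 0) & (d <= 25)).astype(float)
    mass = half_gauss / half_gauss.sum() + uniform / uniform.sum()
    return make_pmf(d, mass)


def agnostic_prior(
    location: GridLocation,
    domain: np.ndarray | None = None,
    ratio: float = DEFAULT_MIXTURE_RATIO,
) -> Pmf:
    """Standard-ZEST prior for one location (4:1 normal:abnormal mixture)."""
    d = default_domain() if domain is None else np.asarray(domain, dtype=float)
    return make_mixture_prior(normal_component(location, d), abnormal_component(d), ratio)


def agnostic_priors(
    grid: Grid, domain: np.ndarray | None = None, ratio: float = DEFAULT_MIXTURE_RATIO
) -> dict[int, Pmf]:
    return {loc.id: agnostic_prior(loc, domain, ratio) for loc in grid.locations}


@dataclass
class PriorTable:
    """Conditional distributions of measured sensitivity given the rounded
    structurally predicted sensitivity."""

    domain: np.ndarray
    bins: dict[int, Pmf]
    counts: dict[int, int]
    fallback: Pmf
    meta: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "domain": self.domain.tolist(),
                "bins": {str(k): p.mass.tolist() for k, p in sorted(self.bins.items())},
                "counts": {str(k): c for k, c in sorted(self.counts.items())},
                "fallback": self.fallback.mass.tolist(),
                "meta": self.meta,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PriorTable":
        obj = json.loads(text)
        d = np.asarray(obj["domain"], dtype=float)
        return cls(
            domain=d,
            bins={int(k): make_pmf(d, m) for k, m in obj["bins"].items()},
            counts={int(k): int(c) for k, c in obj["counts"].items()},
            fallback=make_pmf(d, obj["fallback"]),
            meta=obj.get("meta", {}),
        )


def _smooth_and_floor(
    hist: np.ndarray, domain: np.ndarray, smoothing_sd: float, floor: float
) -> np.ndarray:
    mass = hist.astype(float)
    if smoothing_sd > 0:
        # discrete Gaussian kernel on the domain step
        step = float(domain[1] - domain[0])
        half = int(math.ceil(4 * smoothing_sd / step))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) * step / smoothing_sd) ** 2)
        k /= k.sum()
        mass = np.convolve(mass, k, mode="same")
    total = mass.sum()
    if total > 0:
        mass = mass / total
    mass = mass + floor
    return mass / mass.sum()


def build_structural_prior_table(
    records: Sequence[PairedRecord],
    excluded_subject: str | None = None,
    smoothing_sd: float = DEFAULT_SMOOTHING_SD,
    floor: float = DEFAULT_FLOOR,
    domain: np.ndarray | None = None,
) -> PriorTable:
    """Build the structural prior table from (predicted, observed) pairs.

    Records belonging to ``excluded_subject`` (both eyes) are dropped before
    binning, implementing the leave-one-subject-out construction.  Each bin
    ``k`` holds the histogram of observed sensitivities among records whose
    predicted sensitivity rounds to ``k``, smoothed with a discrete Gaussian
    kernel and floored so every domain value keeps nonzero mass (a zero-mass
    point could never be recovered by Bayesian updating).  The fallback is
    the pooled histogram of all observed values.
    """
    d = default_domain() if domain is None else np.asarray(domain, dtype=float)
    kept = [r for r in records if r.subject_id != excluded_subject]
    if not kept:
        raise ValueError("no records remain after subject exclusion")

    lo, hi = d[0], d[-1]
    idx_of = {float(v): i for i, v in enumerate(d)}

    def value_index(v: float) -> int:
        # nearest domain point (domain is a regular lattice)
        return int(np.clip(np.rint((v - d[0]) / (d[1] - d[0])), 0, len(d) - 1))

    hists: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    pooled = np.zeros(len(d))
    for r in kept:
        k = round_half_away(min(max(r.predicted_db, lo), hi))
        h = hists.get(k)
        if h is None:
            h = hists[k] = np.zeros(len(d))
            counts[k] = 0
        h[value_index(r.observed_db)] += 1
        counts[k] += 1
        pooled[value_index(r.observed_db)] += 1

    bins = {
        k: make_pmf(d, _smooth_and_floor(h, d, smoothing_sd, floor))
        for k, h in hists.items()
    }
    fallback = make_pmf(d, _smooth_and_floor(pooled, d, smoothing_sd, floor))
    return PriorTable(
        domain=d,
        bins=bins,
        counts=counts,
        fallback=fallback,
        meta={
            "n_records": len(kept),
            "smoothing_sd": smoothing_sd,
            "floor": floor,
            "excluded_subject": excluded_subject,
        },
    )


def lookup_structural_prior(
    table: PriorTable, predicted_db: float, min_count: int = DEFAULT_MIN_COUNT
) -> Pmf:
    """Prior for a location with a given structurally predicted sensitivity.

    Returns the bin for the rounded prediction; if that bin is missing or was
    built from fewer than ``min_count`` records, the nearest populated bin is
    used; if no bin qualifies, the pooled fallback.
    """
    k = round_half_away(min(max(predicted_db, table.domain[0]), table.domain[-1]))
    good = [b for b, c in table.counts.items() if c >= min_count]
    if k in table.bins and table.counts.get(k, 0) >= min_count:
        return table.bins[k]
    if good:
        nearest = min(good, key=lambda b: (abs(b - k), b))
        return table.bins[nearest]
    return table.fallback
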
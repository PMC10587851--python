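"""Simulated perimetric observer.

The probability of a "seen" response to a stimulus of intensity ``s`` dB at a
location with true sensitivity ``t`` dB is a Gaussian frequency-of-seeing
curve contaminated by guesses and lapses:

    P(seen) = FP + (1 - FP - FN) * (1 - Phi((s - t) / SD(t)))

where FP is the false-positive (guess) rate, FN the false-negative (lapse)
rate, and Phi the standard normal CDF.  The slope SD(t) follows the Henson
exponential relation SD = exp(A*t + B), capped at a maximum: response
variability grows steeply as sensitivity falls in glaucomatous damage.

A per-test *global visit effect* (GVE) shifts the whole field by a single
Gaussian offset drawn once per test, producing the correlated cross-location
errors seen in real test-retest series; without it, global indices such as
mean sensitivity would appear far more repeatable than they really are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .field_model import Field

__all__ = [
    "ObserverConfig",
    "PRESETS",
    "henson_sd",
    "response_probability",
    "simulate_response",
    "draw_global_offset",
    "estimate_gve_sigma",
]

# Henson combined (healthy + glaucoma) exponential slope coefficients, as
# used by the OPI simulated observers.
HENSON_A = -0.081
HENSON_B = 3.27


@dataclass(frozen=True)
class ObserverConfig:
    """Response-model parameters of a simulated patient.

    Parameters
    ----------
    fp, fn : float
        False-positive (guess) and false-negative (lapse) rates.
    sd_a, sd_b : float
        Coefficients of the exponential variability model SD = exp(a*t + b).
    sd_cap : float
        Upper bound on the psychometric slope SD, in dB.
    gve_sigma : float
        SD (dB) of the per-test global offset; 0 disables the visit effect.
    """

    fp: float = 0.05
    fn: float = 0.05
    sd_a: float = HENSON_A
    sd_b: float = HENSON_B
    sd_cap: float = 6.0
    gve_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.fp < 0 or self.fn < 0 or self.fp + self.fn >= 1:
            raise ValueError("need fp, fn >= 0 and fp + fn < 1")
        if self.sd_cap <= 0:
            raise ValueError("sd_cap must be positive")
        if self.gve_sigma < 0:
            raise ValueError("gve_sigma must be nonnegative")

    def with_gve(self, gve_sigma: float) -> "ObserverConfig":
        return replace(self, gve_sigma=gve_sigma)


#: Named reliability presets.  ``gardiner`` keeps the exponential slope model
#: but raises the cap to 10 dB, approximating the segmented-linear variability
#: model of Gardiner et al. for thresholds above 0 dB; its slope coefficients
#: are synthetic stand-ins (the refit values are not reproduced here).
PRESETS: dict[str, ObserverConfig] = {
    "reliable": ObserverConfig(fp=0.05, fn=0.05),
    "high_fp": ObserverConfig(fp=0.20, fn=0.05),
    "high_fn": ObserverConfig(fp=0.05, fn=0.20),
    "gardiner": ObserverConfig(fp=0.05, fn=0.05, sd_cap=10.0),
}


def henson_sd(true_db: float, cfg: ObserverConfig) -> float:
    """Psychometric slope SD (dB) at a given true sensitivity, capped."""
    return min(cfg.sd_cap, math.exp(cfg.sd_a * true_db + cfg.sd_b))


def response_probability(stimulus_db: float, true_db: float, cfg: ObserverConfig) -> float:
    """Probability of a 'seen' response to a stimulus at a location."""
    sd = henson_sd(true_db, cfg)
    z = (stimulus_db - true_db) / sd
    phi = 0.5 * math.erfc(-z / math.sqrt(2.0))
    return cfg.fp + (1.0 - cfg.fp - cfg.fn) * (1.0 - phi)


def simulate_response(p: float, rng: np.random.Generator) -> bool:
    """Bernoulli draw of the observer's response."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    return bool(rng.random() < p)


def draw_global_offset(cfg: ObserverConfig, rng: np.random.Generator) -> float:
    """Per-test global offset delta ~ N(0, gve_sigma^2), in dB.

    The effective true field for the test is clamp(true + delta, 0, 40) at
    every location, so estimation errors become positively correlated across
    locations within the same test.
    """
    if cfg.gve_sigma == 0.0:
        return 0.0
    return float(rng.normal(0.0, cfg.gve_sigma))


def estimate_gve_sigma(series: Sequence[Field], bae: Field) -> float:
    """Estimate the global-visit-effect SD from a test-retest series.

    For each test the mean deviation from the best available estimate (the
    pointwise median field) is computed across locations; the returned value
    is the SD across tests of those per-test means.  This captures the
    component of variability that moves the whole field together.
    """
    if len(series) < 2:
        raise ValueError("need at least two tests to estimate gve_sigma")
    ids = sorted(bae.values)
    ref = np.array([bae.values[i] for i in ids])
    shifts = [
        float(np.mean(np.array([f.values[i] for i in ids]) - ref)) for f in series
    ]
    return float(np.std(shifts, ddof=1))
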
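"""Synthetic eyes, structural predictions, and test-retest series.

The generator emulates the statistical structure the strategy-comparison
experiments rely on, standing in for a clinical test-retest cohort with
imaging-based sensitivity predictions:

* glaucoma-like "true" fields — archetypal defect patterns (arcuate, nasal
  step, altitudinal, diffuse) that respect the horizontal midline, carved out
  of an eccentricity-dependent normal field;
* several noisy structural predictions per eye, emulating a deep-learning
  predictor applied to repeated OCT scans;
* test-retest series of simulated measurements with a per-visit global
  offset, from which best-available-estimate (median) fields and paired
  (predicted, observed) records for prior construction are derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .field_model import Field, Grid, make_grid
from .observer import ObserverConfig
from .priors import PairedRecord, normal_sensitivity_mean
from .strategy import StrategyConfig, run_single_test

__all__ = [
    "SyntheticEye",
    "ARCHETYPES",
    "generate_true_field",
    "generate_predicted_fields",
    "generate_test_retest_series",
    "compute_bae",
    "generate_cohort",
    "paired_records_from_series",
    "cohort_paired_records",
    "realized_mean_deviation",
]

#: Maximum defect depth (dB) at severity 1.
MAX_DEFECT_DEPTH = 30.0

#: Per-location roughness added on top of the archetype (dB).
ROUGHNESS_SD = 1.0

ARCHETYPES = (
    "healthy",
    "superior_arcuate",
    "inferior_arcuate",
    "nasal_step",
    "altitudinal",
    "diffuse",
)


@dataclass
class SyntheticEye:
    """One simulated eye: truth, structural predictions, and visit-effect SD."""

    subject_id: str
    eye_id: str
    true_field: Field
    predicted_fields: list[Field]
    gve_sigma: float
    severity_label: str

    def __post_init__(self) -> None:
        if not self.predicted_fields:
            raise ValueError("an eye needs at least one predicted field")


def _normal_field(grid: Grid) -> np.ndarray:
    return np.array([normal_sensitivity_mean(loc) for loc in grid.locations])


def _defect_mask(grid: Grid, archetype: str, rng: np.random.Generator) -> np.ndarray:
    """Weight in [0, 1] per location; never crosses the midline except 'diffuse'."""
    x, y = grid.x, grid.y
    ecc = np.hypot(x, y)
    if archetype == "healthy":
        return np.zeros(len(x))
    if archetype in ("superior_arcuate", "inferior_arcuate"):
        hemi = y > 0 if archetype == "superior_arcuate" else y < 0
        # arcuate band sweeping around fixation at mid eccentricity
        band = np.exp(-0.5 * ((ecc - 14.0) / 5.0) ** 2)
        return np.where(hemi, band, 0.0)
    if archetype == "nasal_step":
        hemi = y > 0 if rng.random() < 0.5 else y < 0
        step = (x >= 9) & (np.abs(y) <= 9.1)
        return np.where(hemi & step, 1.0, 0.0)
    if archetype == "altitudinal":
        hemi = y > 0 if rng.random() < 0.5 else y < 0
        return np.where(hemi, 1.0, 0.0)
    if archetype == "diffuse":
        return np.full(len(x), 0.5)
    raise ValueError(f"unknown archetype {archetype!r}")


def generate_true_field(
    grid: Grid,
    archetype: str,
    severity: float,
    rng: np.random.Generator,
) -> Field:
    """A glaucoma-like true sensitivity field.

    Starts from the eccentricity-dependent normal field, subtracts the
    archetype defect scaled by ``severity`` (max depth 30 dB), adds Gaussian
    roughness (SD 1 dB), and clamps to [0, 40] dB.
    """
    if not 0.0 <= severity <= 1.0:
        raise ValueError("severity must be in [0, 1]")
    base = _normal_field(grid)
    mask = _defect_mask(grid, archetype, rng)
    values = base - severity * MAX_DEFECT_DEPTH * mask
    values = values + rng.normal(0.0, ROUGHNESS_SD, size=len(values))
    values = np.clip(values, 0.0, 40.0)
    return Field.from_array(values, label="true")


def generate_predicted_fields(
    true_field: Field,
    n_scans: int,
    noise_sd: float = 2.0,
    bias: float = 0.0,
    floor_db: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[Field]:
    """Noisy structural predictions of the true field, one per emulated scan."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = rng or np.random.default_rng()
    ids = sorted(true_field.values)
    t = np.array([true_field.values[i] for i in ids])
    out = []
    for s in range(n_scans):
        pred = t + bias + rng.normal(0.0, noise_sd, size=len(t))
        pred = np.clip(pred, floor_db, 40.0)
        out.append(
            Field(values=dict(zip(ids, map(float, pred))), label=f"predicted_{s}")
        )
    return out


def generate_test_retest_series(
    eye: SyntheticEye,
    observer: ObserverConfig,
    strategy: StrategyConfig,
    n_tests: int,
    rng: np.random.Generator,
    priors=None,
    graph=None,
) -> list[Field]:
    """Simulate ``n_tests`` independent tests of one eye; returns the
    estimated fields.  Defaults to the agnostic non-spatial strategy when no
    priors are given."""
    if n_tests < 3:
        raise ValueError("a test-retest series needs at least three tests")
    if priors is None:
        from .priors import agnostic_priors

        priors = agnostic_priors(make_grid(), strategy.domain())
    obs = observer.with_gve(eye.gve_sigma)
    out = []
    for _ in range(n_tests):
        res = run_single_test(
            eye.true_field, priors, graph, strategy, obs, rng, log_trials=False
        )
        out.append(res.estimates)
    return out


def compute_bae(series: Sequence[Field]) -> Field:
    """Best available estimate: pointwise median across the series (mean of
    the middle pair for even-length series)."""
    if not series:
        raise ValueError("empty series")
    ids = sorted(series[0].values)
    stack = np.array([[f.values[i] for i in ids] for f in series])
    med = np.median(stack, axis=0)
    return Field(values=dict(zip(ids, map(float, med))), label="bae")


def generate_cohort(
    n_subjects: int = 25,
    eyes_per_subject: int = 2,
    archetype_mix: dict[str, float] | None = None,
    severity_range: tuple[float, float] = (0.05, 0.8),
    n_scans: int = 10,
    pred_sd: float = 2.0,
    pred_bias: float = 0.0,
    gve_sigma: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
    grid: Grid | None = None,
) -> list[SyntheticEye]:
    """Generate a synthetic cohort of eyes.

    The default archetype mix leans towards early arcuate and nasal-step
    damage, the dominant patterns in a stable glaucoma cohort, and the
    severity distribution (Beta(1.5, 4) rescaled to ``severity_range``)
    keeps most eyes mildly to moderately damaged.
    """
    grid = grid or make_grid()
    mix = archetype_mix or {
        "healthy": 0.10,
        "superior_arcuate": 0.25,
        "inferior_arcuate": 0.20,
        "nasal_step": 0.20,
        "altitudinal": 0.10,
        "diffuse": 0.15,
    }
    names = list(mix)
    probs = np.array([mix[a] for a in names], dtype=float)
    probs = probs / probs.sum()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    lo, hi = severity_range
    eyes = []
    for s in range(n_subjects):
        for e in range(eyes_per_subject):
            archetype = names[int(rng.choice(len(names), p=probs))]
            severity = float(lo + (hi - lo) * rng.beta(1.5, 4.0))
            if archetype == "healthy":
                severity = 0.0
            true_field = generate_true_field(grid, archetype, severity, rng)
            preds = generate_predicted_fields(
                true_field, n_scans, noise_sd=pred_sd, bias=pred_bias, rng=rng
            )
            sev_label = (
                "normal"
                if archetype == "healthy"
                else "early"
                if severity < 0.3
                else "moderate"
                if severity < 0.6
                else "advanced"
            )
            eyes.append(
                SyntheticEye(
                    subject_id=f"S{s:03d}",
                    eye_id=f"S{s:03d}_E{e}",
                    true_field=true_field,
                    predicted_fields=preds,
                    gve_sigma=gve_sigma,
                    severity_label=sev_label,
                )
            )
    return eyes


def paired_records_from_series(
    eye: SyntheticEye, series: Sequence[Field]
) -> list[PairedRecord]:
    """Pair every predicted field of an eye with every measured test of its
    series, location by location."""
    recs = []
    for pred in eye.predicted_fields:
        for meas in series:
            for lid, pv in pred.values.items():
                recs.append(
                    PairedRecord(
                        subject_id=eye.subject_id,
                        eye_id=eye.eye_id,
                        location_id=lid,
                        predicted_db=pv,
                        observed_db=meas.values[lid],
                    )
                )
    return recs


def cohort_paired_records(
    cohort: Sequence[SyntheticEye],
    observer: ObserverConfig,
    strategy: StrategyConfig,
    n_tests: int = 3,
    seed: int = 0,
    use_bae: bool = False,
) -> list[PairedRecord]:
    """Paired (predicted, observed) records for a whole cohort.

    With ``use_bae`` the observed value is the true field itself (playing the
    role of the best available estimate); otherwise each eye contributes a
    short simulated test-retest series, which carries realistic measurement
    noise into the prior table.
    """
    ss = np.random.SeedSequence(seed)
    records: list[PairedRecord] = []
    for eye, child in zip(cohort, ss.spawn(len(cohort))):
        if use_bae:
            series: list[Field] = [eye.true_field]
        else:
            rng = np.random.default_rng(child)
            series = generate_test_retest_series(eye, observer, strategy, n_tests, rng)
        records.extend(paired_records_from_series(eye, series))
    return records


def realized_mean_deviation(cohort: Sequence[SyntheticEye], grid: Grid | None = None) -> np.ndarray:
    """Per-eye mean deviation of the true field from the normal field (dB);
    lets users check the generated damage range against a clinical cohort."""
    grid = grid or make_grid()
    base = _normal_field(grid)
    return np.array(
        [float(np.mean(eye.true_field.as_array(grid) - base)) for eye in cohort]
    )
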
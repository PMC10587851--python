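"""ZEST engine: Bayesian adaptive threshold estimation with optional
spatially enhanced updating.

At each location a discrete prior over candidate sensitivities (0..40 dB by
default) is updated after every stimulus presentation with a fixed-shape
likelihood — a Gaussian CDF (SD 1 dB) with asymptotes at 0.03 and 0.97
centred on the presented intensity.  The next stimulus is the mean of the
current posterior, and the location terminates when the posterior SD drops
to 1.5 dB or after 10 presentations.

With spatial enhancement, a response at one location also updates the
posteriors of its nearest neighbours (never across the horizontal midline)
with a *scaled* likelihood L^w, w < 1: the same evidence, discounted.  For
the structural strategy, neighbours whose structurally predicted
sensitivities differ by more than 3 dB are disconnected beforehand, so
evidence is not shared across a predicted scotoma edge, and the remaining
connections carry a larger weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping

import numpy as np
from scipy.special import ndtr

from .field_model import Field, NeighborGraph, Pmf, default_domain
from .observer import ObserverConfig, response_probability

__all__ = [
    "StrategyConfig",
    "LocationState",
    "TrialRecord",
    "TestResult",
    "likelihood_seen",
    "update_pmf",
    "select_stimulus",
    "is_terminated",
    "prune_edges_by_prediction",
    "run_single_test",
    "run_single_location",
]

log = logging.getLogger(__name__)

_POSTERIOR_EPS = 1e-300
_REFLOOR = 1e-12


@dataclass(frozen=True)
class StrategyConfig:
    """Tunable parameters of the ZEST loop.

    ``spatial_weight`` defaults depend on the prior mode: 0.2 for the
    agnostic strategy, 0.4 for the structural one (where edge pruning makes
    the remaining neighbour links more trustworthy).
    """

    prior_mode: str = "agnostic"  # {"agnostic", "structural"}
    spatial: bool = False
    spatial_weight: float | None = None
    disconnect_threshold: float = 3.0
    stop_sd: float = 1.5
    max_presentations: int = 10
    likelihood_sd: float = 1.0
    likelihood_floor: float = 0.03
    likelihood_ceiling: float = 0.97
    domain_lo: int = 0
    domain_hi: int = 40
    domain_step: int = 1
    domain_pad: int = 0
    neighbor_rule: str = "rook"  # {"rook", "queen"}
    neighbor_update: str = "power"  # {"power", "linear"}

    def __post_init__(self) -> None:
        if not 0 < self.likelihood_floor < self.likelihood_ceiling < 1:
            raise ValueError("need 0 < likelihood_floor < likelihood_ceiling < 1")
        if self.stop_sd <= 0:
            raise ValueError("stop_sd must be positive")
        if self.max_presentations < 1:
            raise ValueError("max_presentations must be >= 1")
        if self.prior_mode not in ("agnostic", "structural"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        if self.neighbor_update not in ("power", "linear"):
            raise ValueError(f"unknown neighbor_update {self.neighbor_update!r}")

    @property
    def effective_spatial_weight(self) -> float:
        if self.spatial_weight is not None:
            return self.spatial_weight
        return 0.4 if self.prior_mode == "structural" else 0.2

    def domain(self) -> np.ndarray:
        return default_domain(self.domain_lo, self.domain_hi, self.domain_step, self.domain_pad)


@dataclass
class LocationState:
    """Per-location ZEST state during a test."""

    pmf: Pmf
    n_presented: int = 0
    terminated: bool = False
    estimate: float | None = None


@dataclass(frozen=True)
class TrialRecord:
    presentation_index: int
    location_id: int
    stimulus_db: int
    seen: bool


@dataclass
class TestResult:
    """Outcome of one simulated perimetric test."""

    estimates: Field
    presentations_per_location: dict[int, int]
    total_presentations: int
    trials: list[TrialRecord]
    config: dict
    seed: int | None
    posterior_sd: dict[int, float] = field(default_factory=dict)
    global_offset: float = 0.0

    def summary(self) -> str:
        lines = [
            "Simulated perimetric test",
            f"  total presentations: {self.total_presentations}",
            f"  global visit offset: {self.global_offset:+.2f} dB",
            "  loc   estimate(dB)  post.SD  n",
        ]
        for i in sorted(self.estimates.values):
            lines.append(
                f"  {i:>3}   {self.estimates.values[i]:>9.2f}  "
                f"{self.posterior_sd.get(i, float('nan')):>7.2f}  "
                f"{self.presentations_per_location[i]:>2}"
            )
        return "\n".join(lines)


def likelihood_seen(stimulus_db: float, domain: np.ndarray, cfg: StrategyConfig) -> np.ndarray:
    """P(seen | true threshold = x) for each domain value x.

    A Gaussian CDF in x centred on the stimulus with asymptotes at the
    configured floor and ceiling: a patient whose threshold is far above the
    stimulus intensity almost always sees it (up to lapses), one far below
    almost never does (up to guesses).
    """
    lo, hi = cfg.likelihood_floor, cfg.likelihood_ceiling
    return lo + (hi - lo) * ndtr((np.asarray(domain, dtype=float) - stimulus_db) / cfg.likelihood_sd)


def _scaled_likelihood(lvec: np.ndarray, weight: float, mode: str) -> np.ndarray:
    if weight == 1.0:
        return lvec
    if mode == "power":
        return lvec**weight
    return weight * lvec + (1.0 - weight)


def update_pmf(
    p: Pmf,
    stimulus_db: float,
    seen: bool,
    weight: float = 1.0,
    cfg: StrategyConfig | None = None,
) -> Pmf:
    """Bayesian update: posterior ∝ prior × L(x)^weight, renormalised.

    ``weight`` = 1 is the tested-location update; weights below 1 scale the
    evidence for neighbour updates (power scaling by default, so updates
    compose additively in the exponent).
    """
    cfg = cfg or StrategyConfig()
    if not 0.0 <= weight <= 1.0:
        raise ValueError("weight must be in [0, 1]")
    lvec = likelihood_seen(stimulus_db, p.domain, cfg)
    if not seen:
        lvec = 1.0 - lvec
    post = p.mass * _scaled_likelihood(lvec, weight, cfg.neighbor_update)
    total = post.sum()
    if total < _POSTERIOR_EPS:
        log.warning("posterior underflow at stimulus %s; re-flooring", stimulus_db)
        post = post + _REFLOOR
        total = post.sum()
    return Pmf(domain=p.domain, mass=post / total)


def select_stimulus(p: Pmf, cfg: StrategyConfig | None = None) -> int:
    """Next stimulus: posterior mean, rounded half-up, clamped to the domain."""
    cfg = cfg or StrategyConfig()
    v = int(math.floor(p.mean() + 0.5))
    return int(min(max(v, cfg.domain_lo), cfg.domain_hi))


def is_terminated(state: LocationState, cfg: StrategyConfig) -> bool:
    """A location stops when its posterior SD reaches the criterion or the
    presentation cap is hit."""
    return state.pmf.sd() <= cfg.stop_sd or state.n_presented >= cfg.max_presentations


def prune_edges_by_prediction(
    graph: NeighborGraph, predicted: Field, threshold: float = 3.0
) -> NeighborGraph:
    """Drop edges whose endpoint predicted sensitivities differ by more than
    ``threshold`` dB (strict inequality), preserving predicted scotoma edges."""
    vals = predicted.values
    for i, j in graph.edges:
        if i not in vals or j not in vals:
            raise KeyError(f"predicted field missing value for location {i if i not in vals else j}")
    kept = frozenset(
        (i, j) for i, j in graph.edges if abs(vals[i] - vals[j]) <= threshold
    )
    return NeighborGraph(edges=kept, weight=graph.weight)


class _LikelihoodCache:
    """Per-config cache of likelihood vectors keyed by integer stimulus.

    Stimuli are integer dB, so the same vectors recur constantly; caching
    them (and their weighted forms) makes the bulk simulation loop cheap.
    """

    def __init__(self, domain: np.ndarray, cfg: StrategyConfig, weight: float):
        self.domain = domain
        self.cfg = cfg
        self.weight = weight
        self._full: dict[tuple[int, bool], np.ndarray] = {}
        self._scaled: dict[tuple[int, bool], np.ndarray] = {}

    def full(self, stim: int, seen: bool) -> np.ndarray:
        key = (stim, seen)
        v = self._full.get(key)
        if v is None:
            v = likelihood_seen(stim, self.domain, self.cfg)
            if not seen:
                v = 1.0 - v
            self._full[key] = v
        return v

    def scaled(self, stim: int, seen: bool) -> np.ndarray:
        key = (stim, seen)
        v = self._scaled.get(key)
        if v is None:
            v = _scaled_likelihood(self.full(stim, seen), self.weight, self.cfg.neighbor_update)
            self._scaled[key] = v
        return v


ResponseFn = Callable[[int, int, int], bool]


def run_single_test(
    true_field: Field,
    priors: Mapping[int, Pmf],
    graph: NeighborGraph | None,
    cfg: StrategyConfig,
    observer: ObserverConfig,
    rng_seed: int | np.random.Generator | None = 0,
    response_fn: ResponseFn | None = None,
    log_trials: bool = True,
) -> TestResult:
    """Run one full simulated test over all locations of the field.

    The loop picks a uniformly random non-terminated location, presents the
    mean of its current distribution, draws the observer's response against
    the (offset-shifted) true field, updates the tested location with full
    weight and — when spatial enhancement is on — each non-terminated
    neighbour with the scaled likelihood.  Termination is re-checked only
    for the tested location, so a location can never finish without at least
    one presentation of its own.  Deterministic given (seed, inputs).

    ``response_fn(location_id, stimulus_db, presentation_index) -> bool``
    overrides the stochastic observer, for scripted-response testing.
    """
    if cfg.spatial and graph is None:
        raise ValueError("spatial enhancement requires a neighbor graph")
    loc_ids = sorted(true_field.values)
    missing = [i for i in loc_ids if i not in priors]
    if missing:
        raise ValueError(f"priors missing for locations {missing}")

    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    domain = cfg.domain()
    weight = cfg.effective_spatial_weight
    cache = _LikelihoodCache(domain, cfg, weight)
    adjacency = graph.neighbors() if (cfg.spatial and graph is not None) else {}

    n = len(loc_ids)
    pos = {lid: k for k, lid in enumerate(loc_ids)}
    mass = np.stack([np.asarray(priors[lid].mass, dtype=float) for lid in loc_ids])
    d = domain
    d2 = domain**2

    # Per-test global visit effect: one offset for the whole field.
    delta = 0.0
    if observer.gve_sigma > 0:
        delta = float(rng.normal(0.0, observer.gve_sigma))
    eff_true = {
        lid: min(max(true_field.values[lid] + delta, cfg.domain_lo), cfg.domain_hi)
        for lid in loc_ids
    }

    n_pres = dict.fromkeys(loc_ids, 0)
    terminated = dict.fromkeys(loc_ids, False)
    estimates: dict[int, float] = {}
    post_sd: dict[int, float] = {}
    trials: list[TrialRecord] = []
    active = list(loc_ids)

    t = 0
    while active:
        lid = active[int(rng.integers(len(active)))]
        k = pos[lid]
        m = mass[k]
        mean = float(m @ d)
        stim = int(min(max(math.floor(mean + 0.5), cfg.domain_lo), cfg.domain_hi))

        if response_fn is not None:
            seen = bool(response_fn(lid, stim, t))
        else:
            p = response_probability(stim, eff_true[lid], observer)
            seen = bool(rng.random() < p)

        newm = m * cache.full(stim, seen)
        tot = newm.sum()
        if tot < _POSTERIOR_EPS:
            log.warning("posterior underflow at location %d; re-flooring", lid)
            newm = newm + _REFLOOR
            tot = newm.sum()
        mass[k] = newm / tot

        if adjacency:
            for nb in adjacency.get(lid, ()):
                if nb in terminated and not terminated[nb]:
                    kn = pos[nb]
                    nm = mass[kn] * cache.scaled(stim, seen)
                    ntot = nm.sum()
                    if ntot < _POSTERIOR_EPS:
                        nm = nm + _REFLOOR
                        ntot = nm.sum()
                    mass[kn] = nm / ntot

        n_pres[lid] += 1
        if log_trials:
            trials.append(TrialRecord(t, lid, stim, seen))
        t += 1

        m = mass[k]
        mu = float(m @ d)
        var = float(m @ d2) - mu * mu
        sd = math.sqrt(max(var, 0.0))
        if sd <= cfg.stop_sd or n_pres[lid] >= cfg.max_presentations:
            terminated[lid] = True
            estimates[lid] = mu
            post_sd[lid] = sd
            active.remove(lid)

    return TestResult(
        estimates=Field(values=estimates, label="estimated"),
        presentations_per_location=n_pres,
        total_presentations=t,
        trials=trials,
        config=asdict(cfg),
        seed=rng_seed if isinstance(rng_seed, int) else None,
        posterior_sd=post_sd,
        global_offset=delta,
    )


def run_single_location(
    true_db: float,
    prior: Pmf,
    cfg: StrategyConfig,
    observer: ObserverConfig,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Run an isolated single-location ZEST; returns (estimate, n_presented)."""
    state = LocationState(pmf=prior)
    while True:
        stim = select_stimulus(state.pmf, cfg)
        p = response_probability(stim, true_db, observer)
        seen = bool(rng.random() < p)
        state.pmf = update_pmf(state.pmf, stim, seen, 1.0, cfg)
        state.n_presented += 1
        if is_terminated(state, cfg):
            state.terminated = True
            state.estimate = state.pmf.mean()
            return state.estimate, state.n_presented
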
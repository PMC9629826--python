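"""Synthetic imaging-session generator with full ground truth.

Emulates a head-fixed grating experiment: a population of neurons, a
fraction of which carry 2-D Gaussian tuning over the orientation x
spatial-frequency lattice, observed as per-trial event counts.  Key
statistical features of the real data that the generator reproduces:

* count-valued responses (Poisson by default, with an optional
  variance-inflation factor for over-dispersion),
* all-or-none trial reliability: on each presentation a tuned neuron
  either expresses its tuned bump (probability ``reliability``) or emits
  baseline-only activity,
* gray-screen baseline samples used downstream as the reliability
  threshold reference,
* per-trial locomotion / eye-blink exclusion flags,
* session-to-session drift of preferred orientation (wrapped jitter on
  the 180-degree circle) and per-session reliability scaling, with a
  "rebound" schedule in which a session's parameters reset to the first
  session's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .grid import StimulusGrid
from .model import gaussian_surface, wrap_ori_delta

__all__ = [
    "GroundTruth",
    "SessionData",
    "SessionSpec",
    "FluorescenceTruth",
    "random_population",
    "generate_session",
    "generate_experiment",
    "generate_fluorescence",
]


@dataclass
class GroundTruth:
    """True generative parameters for a neuron population.

    All fields are arrays of length ``n_neurons``.  ``amplitude`` (A) is
    the integrated bump amplitude in events, ``baseline`` (B) the
    baseline event rate, ``(mu_theta, mu_sf)`` the preferred stimulus,
    ``(sigma_theta, sigma_sf)`` the tuning widths, ``rho`` the
    orientation/s.f. correlation of the bump, and ``reliability`` the
    per-trial probability that a tuned neuron expresses its bump.
    """

    is_tuned: np.ndarray
    amplitude: np.ndarray
    baseline: np.ndarray
    mu_theta: np.ndarray
    mu_sf: np.ndarray
    sigma_theta: np.ndarray
    sigma_sf: np.ndarray
    rho: np.ndarray
    reliability: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("is_tuned", "amplitude", "baseline", "mu_theta", "mu_sf",
                     "sigma_theta", "sigma_sf", "rho", "reliability"):
            a = np.atleast_1d(np.asarray(getattr(self, name)))
            arrays[name] = a if name == "is_tuned" else a.astype(float)
        n = arrays["is_tuned"].size
        for name, a in arrays.items():
            if a.size != n:
                raise ValueError(f"{name}: length {a.size} != n_neurons {n}")
            setattr(self, name, a)
        self.is_tuned = self.is_tuned.astype(bool)

    @property
    def n_neurons(self) -> int:
        return self.is_tuned.size

    def validate(self, grid: StimulusGrid | None = None) -> None:
        """Raise ValueError naming the first field violating an invariant."""
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude: must be non-negative")
        if np.any(self.baseline < 0):
            raise ValueError("baseline: must be non-negative")
        if np.any(self.sigma_theta < 1.0):
            raise ValueError("sigma_theta: lower bound is 1 degree")
        if np.any(self.sigma_sf < 0.001):
            raise ValueError("sigma_sf: lower bound is 0.001 cycles/deg")
        if np.any(np.abs(self.rho) >= 1.0):
            raise ValueError("rho: must satisfy |rho| < 1")
        if np.any((self.reliability < 0) | (self.reliability > 1)):
            raise ValueError("reliability: must lie in [0, 1]")
        if grid is not None:
            lo, hi = grid.spatial_freqs[0], grid.spatial_freqs[-1]
            tuned = self.is_tuned
            if np.any((self.mu_sf[tuned] < lo) | (self.mu_sf[tuned] > hi)):
                raise ValueError("mu_sf: outside the spatial-frequency range")

    def copy(self) -> "GroundTruth":
        return GroundTruth(**{
            name: getattr(self, name).copy()
            for name in ("is_tuned", "amplitude", "baseline", "mu_theta",
                         "mu_sf", "sigma_theta", "sigma_sf", "rho",
                         "reliability")
        })

    def mean_surface(self, grid: StimulusGrid) -> np.ndarray:
        """Expected response (including reliability gating) per stimulus.

        Returns an (n_neurons, n_stim) array of analytic means:
        ``B + reliability * bump`` for tuned neurons, ``B`` otherwise.
        """
        theta, sf = grid.stim_table()
        out = np.tile(self.baseline[:, None], (1, grid.n_stim))
        for i in np.flatnonzero(self.is_tuned):
            bump = gaussian_surface(
                theta, sf, self.amplitude[i], 0.0, self.mu_theta[i],
                self.mu_sf[i], self.sigma_theta[i], self.sigma_sf[i],
                self.rho[i])
            out[i] += self.reliability[i] * bump
        return out


@dataclass
class SessionData:
    """One imaging session's trial-structured responses.

    ``responses`` is (n_neurons, n_stim, n_trials) event counts; after
    trial filtering dropped trials are NaN-padded and ``n_retained``
    records the per-stimulus retained count.  ``baseline_samples``
    holds gray-screen response-window event counts per neuron.
    """

    responses: np.ndarray
    baseline_samples: np.ndarray
    locomotion: np.ndarray
    blink: np.ndarray
    neuron_ids: np.ndarray
    grid: StimulusGrid
    n_retained: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3:
            raise ValueError("responses must be (n_neurons, n_stim, n_trials)")
        if self.responses.shape[1] != self.grid.n_stim:
            raise ValueError("responses: stimulus axis does not match grid")
        if np.any(self.responses[np.isfinite(self.responses)] < 0):
            raise ValueError("responses: must be non-negative")
        self.locomotion = np.asarray(self.locomotion, dtype=bool)
        self.blink = np.asarray(self.blink, dtype=bool)
        self.neuron_ids = np.asarray(self.neuron_ids)
        if self.n_retained is None:
            self.n_retained = np.sum(np.isfinite(self.responses[0]), axis=1)

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_stim(self) -> int:
        return self.responses.shape[1]

    @property
    def n_trials(self) -> int:
        return self.responses.shape[2]

    @property
    def flagged(self) -> np.ndarray:
        """(n_stim, n_trials) boolean: trial excluded for any reason."""
        return self.locomotion | self.blink

    def copy(self) -> "SessionData":
        return SessionData(
            responses=self.responses.copy(),
            baseline_samples=self.baseline_samples.copy(),
            locomotion=self.locomotion.copy(),
            blink=self.blink.copy(),
            neuron_ids=self.neuron_ids.copy(),
            grid=self.grid,
            n_retained=None if self.n_retained is None else self.n_retained.copy(),
        )


@dataclass(frozen=True)
class SessionSpec:
    """Per-session drift specification for multi-session experiments.

    ``ori_jitter_deg`` / ``sf_jitter`` are the scales of the wrapped
    (orientation) and clipped (s.f.) Gaussian perturbations applied to
    the preferred stimulus relative to the *previous* session;
    ``reliability_multiplier`` scales the base reliability for this
    session; ``rebound=True`` resets tuning parameters to the first
    session's values (the light-reintroduction recovery scenario).
    """

    name: str = "session"
    ori_jitter_deg: float = 0.0
    sf_jitter: float = 0.0
    reliability_multiplier: float = 1.0
    rebound: bool = False


def random_population(grid: StimulusGrid, n_neurons: int, *,
                      tuned_fraction: float = 0.4,
                      amplitude_mean: float = 60.0,
                      baseline_mean: float = 0.5,
                      reliability_mean: float = 0.7,
                      seed: int | None = None) -> GroundTruth:
    """Draw a realistic population: 30-50% tuned at the default fraction.

    Amplitudes are log-normal around ``amplitude_mean`` (integrated
    events), baselines exponential around ``baseline_mean`` events,
    tuning widths log-uniform within physiological ranges, reliability
    Beta-distributed around ``reliability_mean``.
    """
    rng = np.random.default_rng(seed)
    tuned = rng.random(n_neurons) < tuned_fraction
    amp = amplitude_mean * rng.lognormal(0.0, 0.4, n_neurons)
    amp[~tuned] = 0.0
    base = rng.exponential(baseline_mean, n_neurons) + 0.05
    lo, hi = grid.spatial_freqs[0], grid.spatial_freqs[-1]
    kappa = 8.0  # Beta concentration for reliability draws
    truth = GroundTruth(
        is_tuned=tuned,
        amplitude=amp,
        baseline=base,
        mu_theta=rng.uniform(0.0, 180.0, n_neurons),
        mu_sf=rng.uniform(lo, hi, n_neurons),
        sigma_theta=np.exp(rng.uniform(np.log(8.0), np.log(30.0), n_neurons)),
        sigma_sf=np.exp(rng.uniform(np.log(0.02), np.log(0.08), n_neurons)),
        rho=rng.uniform(-0.3, 0.3, n_neurons),
        reliability=rng.beta(reliability_mean * kappa,
                             (1 - reliability_mean) * kappa, n_neurons),
    )
    truth.validate(grid)
    return truth


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 variance_inflation: float) -> np.ndarray:
    if variance_inflation < 1.0:
        raise ValueError("variance_inflation: must be >= 1")
    if variance_inflation == 1.0:
        return rng.poisson(mean).astype(float)
    # gamma-Poisson mixture: mean m, variance v*m
    m = np.maximum(mean, 1e-12)
    shape = m / (variance_inflation - 1.0)
    lam = rng.gamma(shape, variance_inflation - 1.0)
    return rng.poisson(lam).astype(float)


def generate_session(grid: StimulusGrid, truth: GroundTruth, n_trials: int,
                     seed: int | None, *,
                     locomotion_rate: float = 0.10,
                     blink_rate: float = 0.05,
                     n_baseline: int = 100,
                     variance_inflation: float = 1.0,
                     noise: str = "poisson") -> SessionData:
    """Simulate one session of per-trial event counts.

    On each presentation a tuned neuron is "responsive" with probability
    ``reliability``; responsive trials have Poisson mean ``B + bump``,
    non-responsive trials (and untuned neurons) mean ``B``.  With
    ``noise="none"`` the responses equal their means exactly (the
    noiseless limit used for self-consistency checks).
    """
    if n_trials < 1:
        raise ValueError("n_trials: must be >= 1")
    if not 0 <= locomotion_rate < 1 or not 0 <= blink_rate < 1:
        raise ValueError("flag rates must lie in [0, 1)")
    if noise not in ("poisson", "none"):
        raise ValueError(f"unknown noise model {noise!r}")
    truth.validate(grid)
    rng = np.random.default_rng(seed)

    theta, sf = grid.stim_table()
    n = truth.n_neurons
    bump = np.zeros((n, grid.n_stim))
    for i in np.flatnonzero(truth.is_tuned):
        bump[i] = gaussian_surface(
            theta, sf, truth.amplitude[i], 0.0, truth.mu_theta[i],
            truth.mu_sf[i], truth.sigma_theta[i], truth.sigma_sf[i],
            truth.rho[i])

    gate = rng.random((n, grid.n_stim, n_trials)) < truth.reliability[:, None, None]
    gate &= truth.is_tuned[:, None, None]
    mean = truth.baseline[:, None, None] + gate * bump[:, :, None]
    if noise == "none":
        responses = mean.copy()
        baseline_samples = np.tile(truth.baseline[:, None], (1, n_baseline))
    else:
        responses = _draw_counts(rng, mean, variance_inflation)
        baseline_samples = _draw_counts(
            rng, np.tile(truth.baseline[:, None], (1, n_baseline)),
            variance_inflation)

    locomotion = rng.random((grid.n_stim, n_trials)) < locomotion_rate
    blink = rng.random((grid.n_stim, n_trials)) < blink_rate
    if np.any(np.all(locomotion | blink, axis=1)):
        bad = int(np.flatnonzero(np.all(locomotion | blink, axis=1))[0])
        raise ValueError(
            f"stimulus {bad} has no unflagged trials; session rejected")

    return SessionData(
        responses=responses,
        baseline_samples=baseline_samples,
        locomotion=locomotion,
        blink=blink,
        neuron_ids=np.arange(n),
        grid=grid,
    )


def generate_experiment(grid: StimulusGrid, truth: GroundTruth,
                        schedule: Sequence[SessionSpec], n_trials: int,
                        seed: int | None, **session_kwargs
                        ) -> tuple[list[SessionData], list[GroundTruth]]:
    """Simulate a tracked multi-session experiment.

    Session 1 uses ``truth`` with the first spec's reliability
    multiplier; each later session perturbs the *previous* session's
    preferences by wrapped orientation jitter and clipped s.f. jitter of
    the spec's scales (``rebound`` resets to session 1).  Returns the
    sessions and the per-session evolved ground truths.
    """
    if len(schedule) < 2:
        raise ValueError("schedule must contain at least 2 sessions")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * len(schedule)).astype(np.int64)
    lo, hi = grid.spatial_freqs[0], grid.spatial_freqs[-1]

    sessions: list[SessionData] = []
    truths: list[GroundTruth] = []
    current = truth.copy()
    first: GroundTruth | None = None
    for i, spec in enumerate(schedule):
        jit_rng = np.random.default_rng(int(child_seeds[2 * i]) & 0x7FFFFFFF)
        if i == 0:
            current = truth.copy()
        elif spec.rebound:
            assert first is not None
            current = first.copy()
        else:
            current = truths[-1].copy()
            if spec.ori_jitter_deg > 0:
                jit = jit_rng.normal(0.0, spec.ori_jitter_deg, current.n_neurons)
                current.mu_theta = np.mod(current.mu_theta + jit, 180.0)
            if spec.sf_jitter > 0:
                jit = jit_rng.normal(0.0, spec.sf_jitter, current.n_neurons)
                current.mu_sf = np.clip(current.mu_sf + jit, lo, hi)
        sess_truth = current.copy()
        sess_truth.reliability = np.clip(
            truth.reliability * spec.reliability_multiplier, 0.0, 1.0)
        if i == 0:
            first = sess_truth.copy()
        sessions.append(generate_session(
            grid, sess_truth, n_trials,
            int(child_seeds[2 * i + 1]) & 0x7FFFFFFF, **session_kwargs))
        truths.append(sess_truth)
    return sessions, truths


@dataclass
class FluorescenceTruth:
    """Fluorescence trace plus every ground-truth component."""

    fluorescence: np.ndarray
    neuropil: np.ndarray
    events: np.ndarray
    kernel: np.ndarray
    neuropil_coef: float
    baseline: float
    noise_sd: float
    frame_rate: float


def exponential_kernel(tau: float, frame_rate: float) -> np.ndarray:
    """Causal single-exponential indicator kernel, unit amplitude at lag 0."""
    if tau <= 0:
        raise ValueError("kernel_tau: must be positive")
    if frame_rate <= 0:
        raise ValueError("frame_rate: must be positive")
    n = int(np.ceil(6.0 * tau * frame_rate)) + 1
    t = np.arange(n) / frame_rate
    return np.exp(-t / tau)


def generate_fluorescence(events: np.ndarray, kernel_tau: float,
                          frame_rate: float, *,
                          neuropil_coef: float = 0.7,
                          baseline: float = 1.0,
                          noise_sd: float = 0.05,
                          neuropil: np.ndarray | None = None,
                          seed: int | None = None) -> FluorescenceTruth:
    """Forward model: f = events * k + beta * neuropil + b + noise.

    ``events`` are per-frame event counts/amplitudes.  If ``neuropil``
    is not supplied a slow (~1 s autocorrelation) Gaussian-process-like
    trace is generated.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd: must be non-negative")
    events = np.asarray(events, dtype=float)
    rng = np.random.default_rng(seed)
    k = exponential_kernel(kernel_tau, frame_rate)
    n = events.size
    if neuropil is None:
        from scipy.ndimage import gaussian_filter1d
        raw = rng.normal(0.0, 1.0, n)
        smooth = gaussian_filter1d(raw, sigma=frame_rate, mode="reflect")
        sd = smooth.std()
        neuropil = 0.2 * smooth / sd if sd > 0 else np.zeros(n)
    else:
        neuropil = np.asarray(neuropil, dtype=float)
    clean = np.convolve(events, k)[:n]
    f = clean + neuropil_coef * neuropil + baseline
    if noise_sd > 0:
        f = f + rng.normal(0.0, noise_sd, n)
    return FluorescenceTruth(
        fluorescence=f, neuropil=neuropil, events=events, kernel=k,
        neuropil_coef=neuropil_coef, baseline=baseline, noise_sd=noise_sd,
        frame_rate=frame_rate)
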
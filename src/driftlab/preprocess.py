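"""From event traces to the neuron x stimulus x trial response tensor.

Covers the four preprocessing stages between raw (deconvolved) event
traces and tuning analysis: response-window extraction around each
stimulus onset, exclusion of flagged (locomotion / eye-blink) trials,
ANOVA screening for visually responsive neurons, and an L0 matching
pursuit deconvolution of synthetic fluorescence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .synthgen import SessionData

logger = logging.getLogger(__name__)

__all__ = [
    "ResponsivityResult",
    "DeconvModel",
    "extract_responses",
    "filter_trials",
    "test_responsiveness",
    "deconvolve",
]

#: Response window after stimulus onset, in milliseconds.  The window is
#: the latency band in which the stimulus-triggered event rate peaks.
RESPONSE_WINDOW_MS = (194.0, 320.0)


def window_frame_offsets(frame_rate: float,
                         window_ms: tuple[float, float] = RESPONSE_WINDOW_MS
                         ) -> np.ndarray:
    """Onset-relative frame indices whose frame interval overlaps the window.

    A frame starting at onset-relative time t covers [t, t + 1/rate); it
    contributes when that interval overlaps [w0, w1).  At 15.5 Hz with
    the default window this selects offsets {3, 4}.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    w0, w1 = window_ms
    if not w0 < w1:
        raise ValueError("window start must precede window end")
    dt_ms = 1000.0 / frame_rate
    first = int(np.ceil(w0 / dt_ms - 1.0 + 1e-9))   # frame end > w0
    last = int(np.ceil(w1 / dt_ms - 1e-9)) - 1       # frame start < w1
    first = max(first, 0)
    if last < first:
        # window narrower than one frame: take the frame containing w0
        first = last = int(w0 // dt_ms)
    return np.arange(first, last + 1)


def extract_responses(events: np.ndarray, stim_onsets: np.ndarray,
                      stim_ids: np.ndarray, frame_rate: float, n_stim: int,
                      window_ms: tuple[float, float] = RESPONSE_WINDOW_MS
                      ) -> np.ndarray:
    """Average event counts in the response window of each presentation.

    Parameters
    ----------
    events
        (n_neurons, n_frames) per-frame event counts.
    stim_onsets, stim_ids
        Onset frame index and stimulus id of each presentation.
    n_stim
        Total number of distinct stimuli; ids must lie in [0, n_stim).

    Returns
    -------
    (n_neurons, n_stim, n_trials) tensor; presentations are grouped per
    stimulus in order of occurrence.  Presentations whose window extends
    past the end of the trace are NaN and a warning is logged.  Stimuli
    presented fewer times than the maximum are NaN-padded.
    """
    events = np.atleast_2d(np.asarray(events, dtype=float))
    stim_onsets = np.asarray(stim_onsets, dtype=int)
    stim_ids = np.asarray(stim_ids, dtype=int)
    if stim_onsets.shape != stim_ids.shape:
        raise ValueError("stim_onsets and stim_ids must have equal length")
    if np.any(stim_onsets < 0) or np.any(stim_onsets >= events.shape[1]):
        raise ValueError("stimulus onsets must lie within the trace")
    offsets = window_frame_offsets(frame_rate, window_ms)
    n_frames = events.shape[1]

    counts = np.bincount(stim_ids, minlength=n_stim)
    n_trials = int(counts.max()) if counts.size else 0
    out = np.full((events.shape[0], n_stim, n_trials), np.nan)
    fill = np.zeros(n_stim, dtype=int)
    for onset, sid in zip(stim_onsets, stim_ids):
        frames = onset + offsets
        if frames[-1] >= n_frames:
            logger.warning(
                "presentation at frame %d: response window extends past end "
                "of trace; marked invalid", onset)
            fill[sid] += 1
            continue
        out[:, sid, fill[sid]] = events[:, frames].mean(axis=1)
        fill[sid] += 1
    return out


def filter_trials(session: SessionData) -> SessionData:
    """Drop trials flagged for locomotion or eye blinks.

    The retained responses are repacked per stimulus (NaN-padded to the
    largest retained count); ``n_retained`` records per-stimulus counts.
    Raises if any stimulus loses all of its trials.
    """
    flagged = session.flagged
    keep = ~flagged
    n_retained = keep.sum(axis=1)
    if np.any(n_retained == 0):
        bad = int(np.flatnonzero(n_retained == 0)[0])
        raise ValueError(f"all trials flagged for stimulus {bad}")
    n_stim, _ = flagged.shape
    max_keep = int(n_retained.max())
    new = np.full((session.n_neurons, n_stim, max_keep), np.nan)
    for s in range(n_stim):
        idx = np.flatnonzero(keep[s])
        new[:, s, :idx.size] = session.responses[:, s, idx]
    return SessionData(
        responses=new,
        baseline_samples=session.baseline_samples,
        locomotion=np.zeros((n_stim, max_keep), dtype=bool),
        blink=np.zeros((n_stim, max_keep), dtype=bool),
        neuron_ids=session.neuron_ids,
        grid=session.grid,
        n_retained=n_retained,
    )


@dataclass
class ResponsivityResult:
    """Per-neuron one-way ANOVA screen for visual responsiveness."""

    pvalues: np.ndarray
    alpha: float

    @property
    def responsive(self) -> np.ndarray:
        return self.pvalues < self.alpha

    @property
    def fraction_responsive(self) -> float:
        return float(np.mean(self.responsive))


def test_responsiveness(session: SessionData, alpha: float = 0.01
                        ) -> ResponsivityResult:
    """One-way ANOVA per neuron with stimulus identity as the factor.

    The default significance level follows the computation-level
    convention (alpha = 0.01); the screen is a gate for tuning analysis,
    not an inferential endpoint.  Degenerate neurons (zero within-group
    variance and equal means) receive p = 1 by convention.
    """
    resp = session.responses
    if resp.shape[2] < 2:
        raise ValueError("need >= 2 trials per stimulus for ANOVA")
    groups = [resp[:, s, :] for s in range(session.n_stim)]
    if np.any(np.isnan(resp)):
        pvals = np.empty(session.n_neurons)
        for i in range(session.n_neurons):
            gs = [g[i][np.isfinite(g[i])] for g in groups]
            gs = [g for g in gs if g.size >= 2]
            pvals[i] = _anova_p(gs)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pvals = stats.f_oneway(*[g.T for g in groups], axis=0)
        degenerate = ~np.isfinite(pvals)
        if np.any(degenerate):
            logger.info("%d neurons with degenerate ANOVA; p set to 1",
                        int(degenerate.sum()))
            pvals = np.where(degenerate, 1.0, pvals)
    return ResponsivityResult(pvalues=np.asarray(pvals, dtype=float),
                              alpha=alpha)


def _anova_p(groups: list[np.ndarray]) -> float:
    if len(groups) < 2:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*groups)
    return float(p) if np.isfinite(p) else 1.0


@dataclass
class DeconvModel:
    """Matching-pursuit deconvolution of a fluorescence trace.

    ``events`` is the inferred non-negative event-amplitude trace,
    ``kernel`` the causal temporal kernel, ``neuropil_coef`` and
    ``baseline`` the refit contamination scaling and offset, and
    ``residual`` the final model residual.
    """

    events: np.ndarray
    kernel: np.ndarray
    neuropil_coef: float
    baseline: float
    residual: np.ndarray
    noise_var: float
    converged: bool

    @property
    def event_frames(self) -> np.ndarray:
        return np.flatnonzero(self.events > 0)


def estimate_noise_var(f: np.ndarray) -> float:
    """Noise variance from the MAD of first differences of the trace."""
    d = np.diff(f)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    return float(sigma * sigma)


def deconvolve(f: np.ndarray, neuropil: np.ndarray | None, kernel: np.ndarray,
               *, tol: float = 0.0, max_events_per_s: float = 5.0,
               frame_rate: float = 15.5) -> DeconvModel:
    """Greedy L0 matching pursuit for event inference.

    Events (time, amplitude >= 0) are added one at a time at the
    position that maximally reduces the residual sum of squares; after
    each addition the neuropil coefficient and baseline are refit by
    least squares.  Iteration stops when the residual variance falls to
    (1 + tol) times the noise-variance estimate, or at the hard cap of
    ``max_events_per_s`` events per second of trace.
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("fluorescence trace contains non-finite values")
    kernel = np.asarray(kernel, dtype=float)
    if kernel.size == 0 or kernel[0] <= 0 or np.any(kernel < 0):
        raise ValueError("kernel must be causal with positive lag-0 value")
    n = f.size
    has_np = neuropil is not None
    p = np.asarray(neuropil, dtype=float) if has_np else np.zeros(n)

    events = np.zeros(n)
    k2 = float(kernel @ kernel)
    noise_var = estimate_noise_var(f)
    target = (1.0 + tol) * noise_var
    max_events = max(1, int(np.ceil(max_events_per_s * n / frame_rate)))

    def refit_nuisance(clean: np.ndarray) -> tuple[float, float]:
        y = f - clean
        if has_np:
            X = np.column_stack([p, np.ones(n)])
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(coef[0]), float(coef[1])
        return 0.0, float(y.mean())

    beta, b = refit_nuisance(np.zeros(n))
    conv = np.zeros(n)
    residual = f - conv - beta * p - b
    converged = False
    for _ in range(max_events):
        if residual.var() <= target:
            converged = True
            break
        # correlation of residual with the kernel at every candidate onset
        corr = np.correlate(residual, kernel, mode="full")[kernel.size - 1:]
        amp = corr / k2
        gain = np.where(amp > 0, corr * amp, -np.inf)  # RSS reduction a^2*k2
        t = int(np.argmax(gain))
        if not np.isfinite(gain[t]) or gain[t] <= 0:
            break
        a = amp[t]
        events[t] += a
        end = min(n, t + kernel.size)
        conv[t:end] += a * kernel[: end - t]
        beta, b = refit_nuisance(conv)
        residual = f - conv - beta * p - b
    else:
        converged = residual.var() <= target
    if residual.var() <= target:
        converged = True
    return DeconvModel(events=events, kernel=kernel, neuropil_coef=beta,
                       baseline=b, residual=residual, noise_var=noise_var,
                       converged=converged)
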
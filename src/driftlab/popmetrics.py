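"""Population-level metrics: signal correlation, matrix similarity,
and trial-to-trial response reliability."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import wrap_ori_distance
from .synthgen import SessionData
from .tuning import TuningFit

logger = logging.getLogger(__name__)

__all__ = [
    "SignalCorrMatrix",
    "ReliabilityResult",
    "signal_correlation",
    "similarity",
    "preferred_stimulus_index",
    "reliability",
]


@dataclass
class SignalCorrMatrix:
    """Pairwise Pearson correlations between neurons' stimulus-averaged
    response vectors (one entry per stimulus on the full lattice)."""

    values: np.ndarray
    neuron_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.neuron_ids = np.asarray(self.neuron_ids)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_neurons, k=1)
        return self.values[iu]

    def to_frame(self):
        """Matrix as a DataFrame indexed and labeled by neuron id."""
        import pandas as pd

        ids = [str(i) for i in self.neuron_ids]
        return pd.DataFrame(self.values, index=ids, columns=ids)


def signal_correlation(session: SessionData,
                       neuron_indices=None) -> SignalCorrMatrix:
    """Signal-correlation matrix over a neuron subset.

    The signal of each neuron is its mean response per stimulus over
    retained (finite) trials; entries are pairwise Pearson correlations
    of these 1 x n_stim vectors.  Neurons with a constant mean vector
    have undefined correlations and are dropped with a warning.
    """
    if neuron_indices is None:
        neuron_indices = np.arange(session.n_neurons)
    neuron_indices = np.asarray(list(neuron_indices), dtype=int)
    if neuron_indices.size < 2:
        raise ValueError("need at least 2 neurons for signal correlation")
    mean = np.nanmean(session.responses[neuron_indices], axis=2)
    sd = mean.std(axis=1)
    # relative tolerance: averaging identical trials leaves ~1e-16 jitter
    keep = sd > 1e-10 * np.maximum(np.abs(mean).max(axis=1), 1.0)
    if not np.all(keep):
        dropped = session.neuron_ids[neuron_indices[~keep]]
        logger.warning("dropping %d neurons with constant mean response: %s",
                       int((~keep).sum()), list(dropped))
        neuron_indices = neuron_indices[keep]
        mean = mean[keep]
    if mean.shape[0] < 2:
        raise ValueError("fewer than 2 usable neurons after dropping "
                         "constant-response neurons")
    values = np.corrcoef(mean)
    np.fill_diagonal(values, 1.0)
    return SignalCorrMatrix(values=values,
                            neuron_ids=session.neuron_ids[neuron_indices])


def similarity(m1: SignalCorrMatrix, m2: SignalCorrMatrix) -> float:
    """Similarity of two signal-correlation matrices (same neurons, same
    order): Pearson correlation over the vectorized strict upper
    triangles.  The diagonal is excluded -- self-correlations are
    identically 1 and would inflate agreement.
    """
    if m1.n_neurons != m2.n_neurons or \
            not np.array_equal(m1.neuron_ids, m2.neuron_ids):
        raise ValueError("matrices must cover the same neurons in the "
                         "same order")
    a, b = m1.upper_triangle(), m2.upper_triangle()
    if a.size < 2:
        raise ValueError("need >= 3 neurons for a meaningful similarity")
    return float(np.corrcoef(a, b)[0, 1])


def preferred_stimulus_index(fit: TuningFit, grid) -> int:
    """Grid stimulus nearest the fitted preference (wrapped orientation
    distance for theta, absolute distance for s.f.)."""
    return grid.index_of(fit.mu_theta, fit.mu_sf)


@dataclass
class ReliabilityResult:
    """Per-neuron trial-to-trial reliability at the preferred stimulus.

    Reliability is the fraction of preferred-stimulus trials whose
    response is at least ``n_sd`` (default 2) baseline SDs above the
    gray-screen baseline mean.
    """

    neuron_ids: np.ndarray
    values: np.ndarray
    baseline_mean: np.ndarray
    baseline_sd: np.ndarray
    n_sd: float = 2.0


def reliability(session: SessionData, fits: dict[int, TuningFit], *,
                n_sd: float = 2.0, require_tuned: bool = True
                ) -> ReliabilityResult:
    """Reliability of every (tuned) fitted neuron in a session.

    The threshold for a "successful" trial is baseline_mean + n_sd *
    baseline_SD, with both moments taken over the neuron's gray-screen
    baseline samples.  A degenerate all-zero baseline yields threshold
    0, so any positive response counts (logged).
    """
    if session.baseline_samples.size == 0:
        raise ValueError("session has no baseline samples")
    id_to_idx = {int(nid): i for i, nid in enumerate(session.neuron_ids)}
    ids, vals, bmeans, bsds = [], [], [], []
    for nid, fit in sorted(fits.items()):
        if require_tuned and not fit.tuned:
            continue
        idx = id_to_idx[int(nid)]
        bl = session.baseline_samples[idx]
        bmean, bsd = float(bl.mean()), float(bl.std())
        if bmean == 0.0 and bsd == 0.0:
            logger.info("neuron %s: zero baseline; threshold 0, any positive "
                        "response counts", nid)
        thr = bmean + n_sd * bsd
        pref = preferred_stimulus_index(fit, session.grid)
        trials = session.responses[idx, pref]
        trials = trials[np.isfinite(trials)]
        if trials.size == 0:
            continue
        frac = float(np.mean(trials >= thr)) if thr > 0 else \
            float(np.mean(trials > 0))
        ids.append(nid)
        vals.append(frac)
        bmeans.append(bmean)
        bsds.append(bsd)
    return ReliabilityResult(neuron_ids=np.asarray(ids),
                             values=np.asarray(vals, dtype=float),
                             baseline_mean=np.asarray(bmeans),
                             baseline_sd=np.asarray(bsds), n_sd=n_sd)
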
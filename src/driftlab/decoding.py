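"""KNN stimulus decoding with set-based cross-validation, and the
fixed-classifier representational-drift metric.

Decoding protocol: the trials of a session are divided into *sets*,
each holding exactly one trial (one population response vector) of
every stimulus, so the number of sets equals the per-stimulus trial
count.  Each set is held out in turn; every held-out vector is
classified by the majority stimulus label among its k nearest (by
Euclidean distance) vectors drawn from all *other* sets.  This keeps
the neighbor pool balanced across stimuli for every test vector.

Drift between two sessions is measured with a *fixed* classifier: the
training session provides all neighbors; held-out accuracy within the
training session (acc_x1, via the set-based CV) is compared with the
accuracy obtained when classifying the other session's vectors against
all training vectors (acc_x2).  drift = acc_x2 - acc_x1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .grid import StimulusGrid
from .synthgen import SessionData

__all__ = [
    "DecodeResult",
    "DriftResult",
    "make_sets",
    "knn_decode",
    "sf_split_decode",
    "subsample_match",
    "fixed_classifier_drift",
    "shuffle_labels",
]

DEFAULT_K = 4  # neighbor count used throughout


@dataclass
class DecodeResult:
    """Outcome of one KNN decoding run.

    ``confusion[i, j]`` counts true-stimulus-i vectors classified as j;
    rows sum to the number of tested trials per stimulus.  ``sf_curve``
    (when the full grid was decoded) is the mean accuracy over the
    orientations at each spatial frequency.
    """

    accuracy: float
    confusion: np.ndarray
    k: int
    chance: float
    sf_curve: np.ndarray | None = None

    @property
    def n_stim(self) -> int:
        return self.confusion.shape[0]


@dataclass
class DriftResult:
    """Fixed-classifier drift between a training and a test session."""

    acc_x1: float
    acc_x2: float
    k: int
    n_neurons: int
    n_sets: int

    @property
    def drift(self) -> float:
        return self.acc_x2 - self.acc_x1


def make_sets(responses: np.ndarray, *, n_sets: int | None = None,
              seed: int | None = None) -> np.ndarray:
    """Divide trials into sets of one response vector per stimulus.

    ``responses`` is (n_neurons, n_stim, n_trials); NaN entries mark
    filtered trials.  Every stimulus must retain at least ``n_sets``
    trials (default: the minimum retained count); when more are
    available, trials are randomly subsampled per stimulus with the run
    seed.  Returns (n_sets, n_stim, n_neurons) vectors.
    """
    resp = np.asarray(responses, dtype=float)
    n_neurons, n_stim, _ = resp.shape
    finite = np.isfinite(resp[0])
    counts = finite.sum(axis=1)
    if not np.array_equal(np.isfinite(resp).any(axis=0), finite):
        raise ValueError("trial validity differs across neurons")
    target = int(counts.min()) if n_sets is None else int(n_sets)
    if target < 1:
        raise ValueError("some stimulus has no retained trials")
    if np.any(counts < target):
        raise ValueError(
            f"requested {target} sets but some stimulus has only "
            f"{int(counts.min())} retained trials")
    rng = np.random.default_rng(seed)
    sets = np.empty((target, n_stim, n_neurons))
    for s in range(n_stim):
        avail = np.flatnonzero(finite[s])
        chosen = rng.permutation(avail)[:target]
        sets[:, s, :] = resp[:, s, chosen].T
    return sets


def _classify(test_vectors: np.ndarray, test_labels: np.ndarray,
              train_vectors: np.ndarray, train_labels: np.ndarray,
              train_order: np.ndarray, k: int, n_stim: int,
              confusion: np.ndarray) -> None:
    """Classify test vectors against a fixed neighbor pool (in place).

    Distance ties among neighbors break deterministically by the
    training vectors' (set index, stimulus index) order; vote ties by
    the tied class whose nearest member is closest.
    """
    d = cdist(test_vectors, train_vectors)
    # lexicographic: distance first, then the deterministic train order
    keys = np.broadcast_to(train_order, d.shape)
    order = np.lexsort((keys, d), axis=1)[:, :k]
    neigh = train_labels[order]
    for row in range(test_vectors.shape[0]):
        votes = np.bincount(neigh[row], minlength=n_stim)
        top = votes.max()
        tied = np.flatnonzero(votes == top)
        if tied.size == 1:
            pred = int(tied[0])
        else:
            # nearest neighbor among the tied classes decides
            for cls in neigh[row]:
                if cls in tied:
                    pred = int(cls)
                    break
        confusion[test_labels[row], pred] += 1


def knn_decode(session_or_sets, *, k: int = DEFAULT_K,
               n_sets: int | None = None, seed: int | None = None,
               grid: StimulusGrid | None = None) -> DecodeResult:
    """Set-based cross-validated KNN decoding of stimulus identity.

    Accepts a SessionData (sets are built with ``make_sets``) or a
    pre-built (n_sets, n_stim, n_neurons) set array.  Requires at least
    2 sets and k <= (n_sets - 1): with fewer sets every class pool is
    smaller than k.
    """
    if isinstance(session_or_sets, SessionData):
        grid = session_or_sets.grid
        sets = make_sets(session_or_sets.responses, n_sets=n_sets, seed=seed)
    else:
        sets = np.asarray(session_or_sets, dtype=float)
    n_set, n_stim, n_neurons = sets.shape
    if n_set < 2:
        raise ValueError("need >= 2 sets for set-based cross-validation")
    if k > n_set - 1:
        raise ValueError(f"k={k} exceeds per-class neighbor pool "
                         f"({n_set - 1} sets available as neighbors)")
    labels = np.tile(np.arange(n_stim), n_set)
    set_idx = np.repeat(np.arange(n_set), n_stim)
    vectors = sets.reshape(n_set * n_stim, n_neurons)

    confusion = np.zeros((n_stim, n_stim), dtype=int)
    for held in range(n_set):
        train_mask = set_idx != held
        _classify(vectors[~train_mask], labels[~train_mask],
                  vectors[train_mask], labels[train_mask],
                  np.arange(train_mask.sum()), k, n_stim, confusion)
    accuracy = float(np.trace(confusion) / confusion.sum())
    sf_curve = None
    if grid is not None and n_stim == grid.n_stim:
        per_stim = np.diag(confusion) / confusion.sum(axis=1)
        sf_curve = per_stim.reshape(grid.n_spatial_freqs,
                                    grid.n_orientations).mean(axis=1)
    return DecodeResult(accuracy=accuracy, confusion=confusion, k=k,
                        chance=1.0 / n_stim, sf_curve=sf_curve)


def sf_split_decode(session: SessionData, *, boundary: float = 0.1,
                    k: int = DEFAULT_K, n_sets: int | None = None,
                    seed: int | None = None
                    ) -> tuple[DecodeResult, DecodeResult]:
    """Independent decoders for low (<= boundary) and high (> boundary)
    spatial-frequency stimulus subsets.  On the default lattice the
    0.1 cycles/deg boundary yields 60 low and 120 high stimuli, with
    chance levels 1/60 and 1/120.
    """
    grid = session.grid
    _, sf = grid.stim_table()
    low = sf <= boundary
    if not low.any() or low.all():
        raise ValueError("boundary does not split the grid non-trivially")
    results = []
    ss = np.random.SeedSequence(seed)
    for mask, child in zip((low, ~low), ss.spawn(2)):
        sets = make_sets(session.responses[:, mask, :], n_sets=n_sets,
                         seed=child.generate_state(1)[0] & 0x7FFFFFFF)
        results.append(knn_decode(sets, k=k))
    return results[0], results[1]


def subsample_match(sessions: list[SessionData], seed: int | None = None
                    ) -> list[SessionData]:
    """Match neuron and trial counts across sessions.

    Neurons are reduced to a common random subset of the shared
    (tracked) neuron ids -- the *same* identities in every session;
    trials are randomly subsampled per session to the minimum retained
    per-stimulus count across sessions.
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions to match")
    shared = set(int(i) for i in sessions[0].neuron_ids)
    for s in sessions[1:]:
        shared &= set(int(i) for i in s.neuron_ids)
    if not shared:
        raise ValueError("no shared tracked neurons across sessions")
    shared_ids = np.array(sorted(shared))
    rng = np.random.default_rng(seed)
    min_trials = min(
        int(np.isfinite(s.responses[0]).sum(axis=1).min()) for s in sessions)

    out = []
    for s in sessions:
        id_to_idx = {int(nid): i for i, nid in enumerate(s.neuron_ids)}
        idx = np.array([id_to_idx[i] for i in shared_ids])
        resp = s.responses[idx]
        finite = np.isfinite(resp[0])
        already = resp.shape[2] == min_trials and bool(finite.all())
        if already:
            new_resp = resp
        else:
            new_resp = np.empty((idx.size, s.n_stim, min_trials))
            for stim in range(s.n_stim):
                avail = np.flatnonzero(finite[stim])
                chosen = rng.permutation(avail)[:min_trials]
                new_resp[:, stim, :] = resp[:, stim, chosen]
        out.append(SessionData(
            responses=new_resp,
            baseline_samples=s.baseline_samples[idx],
            locomotion=np.zeros((s.n_stim, min_trials), dtype=bool),
            blink=np.zeros((s.n_stim, min_trials), dtype=bool),
            neuron_ids=shared_ids.copy(),
            grid=s.grid,
        ))
    return out


def fixed_classifier_drift(train_session: SessionData,
                           test_session: SessionData, *, k: int = DEFAULT_K,
                           n_sets: int | None = None,
                           seed: int | None = None) -> DriftResult:
    """Representational drift via a classifier fixed on one session.

    acc_x1: held-out accuracy within the training session (set-based
    CV).  acc_x2: every test-session vector classified against *all*
    training-session vectors (no set exclusion).  When the test session
    *is* the training session, acc_x2 is computed with the same
    self-excluding CV, so it equals acc_x1 exactly.  Sessions must
    share tracked neurons; counts are matched before decoding.
    """
    self_test = test_session is train_session
    matched = subsample_match([train_session, test_session], seed=seed)
    tr, te = matched
    ss = np.random.SeedSequence(seed)
    s1, s2 = (c.generate_state(1)[0] & 0x7FFFFFFF for c in ss.spawn(2))
    train_sets = make_sets(tr.responses, n_sets=n_sets, seed=int(s1))
    res1 = knn_decode(train_sets, k=k)
    if self_test:
        res2_acc = res1.accuracy
        confusion2 = res1.confusion
    else:
        test_sets = make_sets(te.responses, n_sets=n_sets, seed=int(s2))
        n_set, n_stim, n_neurons = train_sets.shape
        train_vectors = train_sets.reshape(n_set * n_stim, n_neurons)
        train_labels = np.tile(np.arange(n_stim), n_set)
        confusion2 = np.zeros((n_stim, n_stim), dtype=int)
        test_vectors = test_sets.reshape(-1, n_neurons)
        test_labels = np.tile(np.arange(n_stim), test_sets.shape[0])
        _classify(test_vectors, test_labels, train_vectors, train_labels,
                  np.arange(train_vectors.shape[0]), k, n_stim, confusion2)
        res2_acc = float(np.trace(confusion2) / confusion2.sum())
    return DriftResult(acc_x1=res1.accuracy, acc_x2=res2_acc, k=k,
                       n_neurons=tr.n_neurons, n_sets=train_sets.shape[0])


def shuffle_labels(responses: np.ndarray, seed: int | None = None
                   ) -> np.ndarray:
    """Shuffle stimulus labels of all trials jointly across the
    (stimulus, trial) axes -- the chance-level control for decoding."""
    resp = np.asarray(responses, dtype=float)
    n_neurons, n_stim, n_trials = resp.shape
    rng = np.random.default_rng(seed)
    flat = resp.reshape(n_neurons, n_stim * n_trials)
    perm = rng.permutation(n_stim * n_trials)
    return flat[:, perm].reshape(n_neurons, n_stim, n_trials)
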
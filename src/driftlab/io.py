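"""Serialization: HDF5 session containers, JSON ground-truth sidecars,
and CSV exports of tables."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .grid import StimulusGrid
from .synthgen import GroundTruth, SessionData
from .tuning import TuningFit

__all__ = [
    "save_session", "load_session",
    "save_ground_truth", "load_ground_truth",
    "session_to_long_csv", "fits_to_frame",
]

_TRUTH_FIELDS = ("is_tuned", "amplitude", "baseline", "mu_theta", "mu_sf",
                 "sigma_theta", "sigma_sf", "rho", "reliability")


def save_session(session: SessionData, path) -> None:
    """Write a session to an HDF5 container with named datasets."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("responses", data=session.responses)
        h5.create_dataset("baseline_samples", data=session.baseline_samples)
        h5.create_dataset("flags/locomotion", data=session.locomotion)
        h5.create_dataset("flags/blink", data=session.blink)
        h5.create_dataset("neuron_ids",
                          data=np.asarray(session.neuron_ids, dtype=np.int64))
        h5.create_dataset("grid/orientations", data=session.grid.orientations)
        h5.create_dataset("grid/spatial_freqs",
                          data=session.grid.spatial_freqs)
        if session.n_retained is not None:
            h5.create_dataset("n_retained", data=session.n_retained)


def load_session(path) -> SessionData:
    with h5py.File(path, "r") as h5:
        grid = StimulusGrid(orientations=h5["grid/orientations"][:],
                            spatial_freqs=h5["grid/spatial_freqs"][:])
        return SessionData(
            responses=h5["responses"][:],
            baseline_samples=h5["baseline_samples"][:],
            locomotion=h5["flags/locomotion"][:],
            blink=h5["flags/blink"][:],
            neuron_ids=h5["neuron_ids"][:],
            grid=grid,
            n_retained=h5["n_retained"][:] if "n_retained" in h5 else None,
        )


def save_ground_truth(truth: GroundTruth, path) -> None:
    """JSON sidecar with the generator's true parameters."""
    payload = {name: np.asarray(getattr(truth, name)).tolist()
               for name in _TRUTH_FIELDS}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(**{name: np.asarray(payload[name])
                          for name in _TRUTH_FIELDS})


def session_to_long_csv(session: SessionData, path) -> pd.DataFrame:
    """Long-format CSV of the response tensor:
    (neuron, orientation, sf, trial, events); filtered trials omitted."""
    theta, sf = session.grid.stim_table()
    n, s, t = session.responses.shape
    nid = np.repeat(np.asarray(session.neuron_ids), s * t)
    ori = np.tile(np.repeat(theta, t), n)
    freq = np.tile(np.repeat(sf, t), n)
    trial = np.tile(np.arange(t), n * s)
    events = session.responses.reshape(-1)
    df = pd.DataFrame({"neuron": nid, "orientation": ori, "sf": freq,
                       "trial": trial, "events": events})
    df = df[np.isfinite(df["events"])]
    df.to_csv(path, index=False)
    return df


def fits_to_frame(fits: dict[int, TuningFit], session: str = "") -> pd.DataFrame:
    """Per-neuron fit table in the standard column layout."""
    rows = []
    for nid, f in sorted(fits.items()):
        rows.append({
            "neuron_id": nid, "session": session, "A": f.A, "B": f.B,
            "mu_theta": f.mu_theta, "mu_sf": f.mu_sf,
            "sigma_theta": f.sigma_theta, "sigma_sf": f.sigma_sf,
            "rho": f.rho, "r2": f.r2, "p_perm": f.p_perm, "sig": f.sig,
            "bw_theta": f.bw_theta, "bw_sf": f.bw_sf,
            "converged": f.converged,
        })
    return pd.DataFrame(rows)
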
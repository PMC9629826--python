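"""Stimulus lattice for static-grating experiments.

A session presents every combination of grating orientation (axial,
period 180 degrees) and spatial frequency (cycles per degree of visual
angle).  Stimuli are indexed spatial-frequency-major: index
``i_sf * n_orientations + i_ori``, so a confusion matrix ordered by
stimulus index groups the orientations of one spatial frequency together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusGrid", "default_grid"]


@dataclass(frozen=True)
class StimulusGrid:
    """Orientation x spatial-frequency stimulus lattice.

    Parameters
    ----------
    orientations
        Grating orientations in degrees, strictly ascending, unique in
        [0, 180).
    spatial_freqs
        Spatial frequencies in cycles/degree, strictly ascending, > 0.
    """

    orientations: np.ndarray
    spatial_freqs: np.ndarray

    def __post_init__(self) -> None:
        ori = np.asarray(self.orientations, dtype=float)
        sf = np.asarray(self.spatial_freqs, dtype=float)
        if ori.ndim != 1 or ori.size == 0:
            raise ValueError("orientations must be a non-empty 1-D array")
        if sf.ndim != 1 or sf.size == 0:
            raise ValueError("spatial_freqs must be a non-empty 1-D array")
        if np.any(ori < 0) or np.any(ori >= 180):
            raise ValueError("orientations must lie in [0, 180)")
        if np.any(np.diff(ori) <= 0):
            raise ValueError("orientations must be strictly ascending and unique")
        if np.any(sf <= 0):
            raise ValueError("spatial_freqs must be positive")
        if np.any(np.diff(sf) <= 0):
            raise ValueError("spatial_freqs must be strictly ascending and unique")
        object.__setattr__(self, "orientations", ori)
        object.__setattr__(self, "spatial_freqs", sf)

    @property
    def n_orientations(self) -> int:
        return self.orientations.size

    @property
    def n_spatial_freqs(self) -> int:
        return self.spatial_freqs.size

    @property
    def n_stim(self) -> int:
        return self.orientations.size * self.spatial_freqs.size

    def index_of(self, theta: float, sf: float) -> int:
        """Stimulus index of the grid point nearest to (theta, sf).

        Orientation distance is evaluated on the 180-degree circle.
        """
        d = np.abs(self.orientations - (theta % 180.0))
        i_ori = int(np.argmin(np.minimum(d, 180.0 - d)))
        i_sf = int(np.argmin(np.abs(self.spatial_freqs - sf)))
        return i_sf * self.n_orientations + i_ori

    def stim_table(self) -> tuple[np.ndarray, np.ndarray]:
        """(theta, sf) of every stimulus index, each of length n_stim."""
        theta = np.tile(self.orientations, self.n_spatial_freqs)
        sf = np.repeat(self.spatial_freqs, self.n_orientations)
        return theta, sf


def default_grid() -> StimulusGrid:
    """12 orientations (0-165 deg, step 15) x 15 s.f. (0.02-0.30, step 0.02)."""
    return StimulusGrid(
        orientations=np.arange(0.0, 180.0, 15.0),
        spatial_freqs=np.round(np.arange(1, 16) * 0.02, 10),
    )
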
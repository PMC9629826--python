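"""The 2-D Gaussian tuning surface and orientation wrapping helpers.

The mean response of a tuned neuron to a grating of orientation ``theta``
(degrees) and spatial frequency ``sf`` (cycles/deg) is modelled as a
bivariate Gaussian bump over the stimulus plane plus a baseline::

    R(theta, sf) = A / (2*pi*s_t*s_f*sqrt(1-rho^2))
                   * exp(-q / (2*(1-rho^2))) + B
    q = dt^2/s_t^2 + df^2/s_f^2 - 2*rho*dt*df/(s_t*s_f)

where ``dt`` is the orientation difference wrapped to (-90, 90] (axial
data, period 180), ``df = sf - mu_sf``, ``A`` is an amplitude in events,
``B`` the baseline event rate, and ``rho`` the orientation/s.f.
correlation of the bump.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_ori_delta", "wrap_ori_distance", "gaussian_surface"]


def wrap_ori_delta(delta_deg):
    """Map orientation differences (deg) onto (-90, 90], period 180."""
    d = np.mod(delta_deg, 180.0)
    return np.where(d > 90.0, d - 180.0, d)


def wrap_ori_distance(a_deg, b_deg):
    """Absolute wrapped orientation distance in [0, 90]."""
    return np.abs(wrap_ori_delta(np.asarray(a_deg, dtype=float) - b_deg))


def gaussian_surface(theta, sf, A, B, mu_theta, mu_sf,
                     sigma_theta, sigma_sf, rho, *, wrap: bool = True):
    """Evaluate the tuning surface at stimulus coordinates (theta, sf).

    ``theta`` in degrees, ``sf`` in cycles/deg; broadcastable arrays.
    With ``wrap=False`` the raw (non-periodic) orientation difference is
    used, which is the literal non-periodic form of the model.
    """
    theta = np.asarray(theta, dtype=float)
    sf = np.asarray(sf, dtype=float)
    dt = theta - mu_theta
    if wrap:
        dt = wrap_ori_delta(dt)
    df = sf - mu_sf
    omr2 = 1.0 - rho * rho
    q = (dt * dt) / (sigma_theta * sigma_theta) \
        + (df * df) / (sigma_sf * sigma_sf) \
        - 2.0 * rho * dt * df / (sigma_theta * sigma_sf)
    peak = A / (2.0 * np.pi * sigma_theta * sigma_sf * np.sqrt(omr2))
    return peak * np.exp(-q / (2.0 * omr2)) + B
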
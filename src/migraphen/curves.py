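"""Shared double-logistic curve forms.

Two parameterisations are used in the field and both appear here:

* migration NSD: ``delta / (1 + exp((theta - t)/phi))`` — ``theta`` is the
  inflection day, ``phi`` a timing scale in days;
* seasonal NDVI: ``1 / (1 + exp(-k (t - t0)))`` — ``k`` a rate per day.
"""
from __future__ import annotations

import numpy as np


def nsd_double_logistic(t, delta, theta_s, phi_s, theta_a, phi_a):
    """Net-squared-displacement profile of a round-trip migrant: rises at the
    spring inflection ``theta_s``, plateaus at ``delta`` (km^2), falls at the
    autumn inflection ``theta_a``."""
    t = np.asarray(t, dtype=float)
    zs = np.clip((theta_s - t) / phi_s, -700.0, 700.0)
    za = np.clip((theta_a - t) / phi_a, -700.0, 700.0)
    return delta / (1.0 + np.exp(zs)) - delta / (1.0 + np.exp(za))


def ndvi_double_logistic(t, vmin, vmax, t0, k, ta, ka):
    """Seasonal greenness curve: base level ``vmin``, amplitude
    ``vmax - vmin``, spring midpoint ``t0`` with rate ``k``, autumn midpoint
    ``ta`` with rate ``ka``."""
    t = np.asarray(t, dtype=float)
    spring = 1.0 / (1.0 + np.exp(np.clip(-k * (t - t0), -700.0, 700.0)))
    autumn = 1.0 / (1.0 + np.exp(np.clip(-ka * (t - ta), -700.0, 700.0)))
    return vmin + (vmax - vmin) * (spring - autumn)
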
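"""Steady-state fluorescence anisotropy arithmetic.

r = (I_VV - G I_VH) / (I_VV + 2 G I_VH), with the detection-path polarization
bias corrected by the G-factor G = I_HV / I_HH measured under horizontal
excitation.  Inputs are already-extracted intensities at the emission maxima.
"""

from __future__ import annotations

import numpy as np


def g_factor(i_hv, i_hh):
    """G = I_HV / I_HH from horizontal-excitation intensities."""
    i_hv = np.asarray(i_hv, dtype=float)
    i_hh = np.asarray(i_hh, dtype=float)
    if np.any(i_hh <= 0):
        raise ValueError("I_HH must be > 0")
    if np.any(i_hv < 0):
        raise ValueError("intensities must be >= 0")
    out = i_hv / i_hh
    return float(out) if out.ndim == 0 else out


def anisotropy(i_vv, i_vh, g):
    """r = (I_VV - G I_VH) / (I_VV + 2 G I_VH); r in (-0.5, 1] physically."""
    i_vv = np.asarray(i_vv, dtype=float)
    i_vh = np.asarray(i_vh, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(i_vv < 0) or np.any(i_vh < 0):
        raise ValueError("intensities must be >= 0")
    denom = i_vv + 2.0 * g * i_vh
    if np.any(denom <= 0):
        raise ValueError("total intensity I_VV + 2 G I_VH must be > 0")
    out = (i_vv - g * i_vh) / denom
    return float(out) if out.ndim == 0 else out
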
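"""Protein-induced fluorescence enhancement (PIFE) read out as S shifts.

A brightness increase of the donor dye (Cy3) caused by a nearby protein
domain raises the apparent stoichiometry S while leaving the apparent FRET
efficiency E* unchanged.  Under the donor-scaling model the fitted mean
stoichiometries of a construct series therefore encode the donor brightness
factor alpha through the odds transform

    S_obs/(1-S_obs) = alpha * S_ref/(1-S_ref),

which :func:`derive_pife_factor` inverts.  Cy3B, spectrally identical to Cy3
but insensitive to PIFE, provides the negative control: its construct series
must show no stoichiometry shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConstructFit:
    """Fitted state means for one construct (one labelling background)."""

    label: str
    mu_s: float
    se_s: float = 0.0
    mu_e: float = np.nan
    se_e: float = 0.0
    linker_delta: int = 0  # amino acids: negative = deletion, positive = insertion
    state: str = "apo"

    def __post_init__(self):
        if not 0.0 < self.mu_s < 1.0:
            raise ValueError("mu_s must be in (0, 1)")


def derive_pife_factor(s_ref: float, s_obs: float) -> float:
    """Donor brightness factor alpha from reference and observed mean S.

    alpha = [s_obs/(1-s_obs)] / [s_ref/(1-s_ref)]; the algebraic inverse of
    the donor-scaling forward model.
    """
    for s in (s_ref, s_obs):
        if not 0.0 < s < 1.0:
            raise ValueError("stoichiometries must be strictly inside (0, 1)")
    return (s_obs / (1.0 - s_obs)) / (s_ref / (1.0 - s_ref))


def stoichiometry_shift(
    fits: list[ConstructFit], reference: str
) -> pd.DataFrame:
    """Stoichiometry shifts ΔS* of each construct relative to a reference.

    Returns one row per construct with ΔS = mu_S - mu_S(reference), the
    propagated fit uncertainty, and the implied donor brightness factor.
    """
    by_label = {f.label: f for f in fits}
    if reference not in by_label:
        raise KeyError(f"reference construct {reference!r} not in fits")
    ref = by_label[reference]
    rows = []
    for f in fits:
        rows.append(
            {
                "construct": f.label,
                "state": f.state,
                "linker_delta": f.linker_delta,
                "mean_s": f.mu_s,
                "delta_s": f.mu_s - ref.mu_s,
                "delta_s_err": float(np.hypot(f.se_s, ref.se_s)),
                "alpha": derive_pife_factor(ref.mu_s, f.mu_s),
                "reference": reference,
            }
        )
    return pd.DataFrame(rows)


def null_control(shifts: pd.DataFrame, noise_bound: float = 0.01) -> dict:
    """Cy3B-style negative control: assert |ΔS| stays below a noise bound.

    Returns a report with the largest |ΔS| and a ``pife_detected`` flag that
    is raised when any construct exceeds the bound (PIFE leaked into the
    control series).
    """
    delta = shifts["delta_s"].to_numpy(dtype=float)
    max_abs = float(np.max(np.abs(delta))) if delta.size else 0.0
    worst = shifts.loc[np.abs(delta).argmax(), "construct"] if delta.size else None
    return {
        "max_abs_delta_s": max_abs,
        "noise_bound": noise_bound,
        "pife_detected": bool(max_abs > noise_bound),
        "worst_construct": worst,
        "n_constructs": int(len(shifts)),
    }


def linker_trend(shifts: pd.DataFrame) -> dict:
    """OLS slope of ΔS* versus number of deleted linker residues.

    Summarizes the (linear) distance dependence of the PIFE effect along the
    linker-deletion series; reports slope, intercept, standard error and a
    95% confidence interval on the slope.
    """
    x = -shifts["linker_delta"].to_numpy(dtype=float)  # deletions count positive
    y = shifts["delta_s"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct linker lengths for a trend")
    res = stats.linregress(x, y)
    dof = max(x.size - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "stderr": float(res.stderr),
        "ci95": (float(res.slope - tcrit * res.stderr),
                 float(res.slope + tcrit * res.stderr)),
        "r_value": float(res.rvalue),
        "n": int(x.size),
    }
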
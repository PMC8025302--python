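"""Burst variance analysis: observed E* spread vs the shot-noise limit.

For a static molecule emitting N donor-excitation photons per burst at mean
apparent FRET efficiency E*, the standard deviation of per-burst E* expected
from photon statistics alone is

    sigma_E* = sqrt( E* (1 - E*) / N_DD+DA ),

where N_DD+DA is the average number of donor-excitation photons per burst.
Populations whose observed spread exceeds this limit are heterogeneous
(static mixtures or dynamics on the diffusion time scale); static
single-state populations sit at the limit.

The primary mode compares the population-level width of selected bursts
against the limit.  A classic sub-burst variant (windowed E* along each
burst) is provided as an optional extension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class InsufficientDataError(RuntimeError):
    """Too few bursts survive the BVA selection."""


def shotnoise_sigma(e: float, n: float) -> float:
    """Shot-noise-limited std of per-burst E*: sqrt(e(1-e)/n)."""
    if not 0.0 <= e <= 1.0:
        raise ValueError("e must be in [0, 1]")
    if n <= 0:
        raise ValueError("n must be > 0")
    return float(np.sqrt(e * (1.0 - e) / n))


@dataclass(frozen=True)
class BVAResult:
    """Observed vs shot-noise-expected spread of per-burst E*."""

    mean_e: float
    observed_sigma: float
    shotnoise_sigma: float
    mean_n: float
    n_bursts: int

    @property
    def excess_ratio(self) -> float:
        return self.observed_sigma / self.shotnoise_sigma

    def to_dict(self) -> dict:
        return {
            "mean_e": self.mean_e,
            "observed_sigma": self.observed_sigma,
            "shotnoise_sigma": self.shotnoise_sigma,
            "mean_n": self.mean_n,
            "excess_ratio": self.excess_ratio,
            "n_bursts": self.n_bursts,
        }


def bva_compare(bursts: pd.DataFrame, min_bursts: int = 50) -> BVAResult:
    """Observed std of per-burst E* vs eq-of-state shot noise.

    ``bursts`` must already be pre-filtered with the BVA selection (total
    photons > 250, S in [0.3, 0.6]; see
    :func:`smalex.bursts.apply_burst_thresholds` mode ``"bva"``).  mean_n is
    the arithmetic mean of per-burst donor-excitation totals F(DD)+F(DA).
    """
    e = bursts["e_app"].to_numpy(dtype=float)
    n_dexc = (bursts["f_dd"] + bursts["f_da"]).to_numpy(dtype=float)
    ok = np.isfinite(e)
    e, n_dexc = e[ok], n_dexc[ok]
    if e.size < min_bursts:
        raise InsufficientDataError(
            f"need >= {min_bursts} bursts for BVA, got {e.size}"
        )
    mean_e = float(e.mean())
    mean_n = float(n_dexc.mean())
    return BVAResult(
        mean_e=mean_e,
        observed_sigma=float(e.std(ddof=1)),
        shotnoise_sigma=shotnoise_sigma(mean_e, mean_n),
        mean_n=mean_n,
        n_bursts=int(e.size),
    )


def bva_subburst(stream, bursts: pd.DataFrame, window: int = 100) -> pd.DataFrame:
    """Classic sub-burst BVA (optional extension to the population mode).

    Splits each burst's donor-excitation photons into consecutive windows of
    ``window`` photons, computes E* per window, and reports the per-burst std
    of windowed E* next to the shot-noise expectation at the window size.
    Requires the labelled photon stream the bursts were searched on.
    """
    masks = stream.stream_masks
    is_dexc = masks["DD"] | masks["DA"]
    is_da = masks["DA"]
    rows = []
    for _, b in bursts.iterrows():
        lo, hi = int(b["istart"]), int(b["istop"]) + 1
        sel = np.flatnonzero(is_dexc[lo:hi]) + lo
        n_win = sel.size // window
        if n_win < 2:
            continue
        e_win = [
            is_da[sel[i * window: (i + 1) * window]].mean() for i in range(n_win)
        ]
        e_mean = float(np.mean(e_win))
        rows.append(
            {
                "e_app": b["e_app"],
                "sub_sigma": float(np.std(e_win, ddof=1)),
                "expected_sigma": shotnoise_sigma(min(max(e_mean, 0.0), 1.0), window),
                "n_windows": n_win,
            }
        )
    return pd.DataFrame(rows)
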
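"""Ligand-titration analysis: closed-state fractions and one-site binding fit.

The titration protocol anchors the two conformational states on the endpoint
datasets (apo protein and fully saturating ligand), freezes their E*/S
Gaussian parameters, refits only the relative amplitudes at every
intermediate concentration, and fits the resulting closed-state fractions
f(L) with the one-site binding model

    f(L) = B_max * L / (K_D + L),

yielding the maximal closed fraction B_max and the dissociation constant K_D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar

from .populations import FitError, PopulationFit, assign_probabilities, fit_populations
from .synthetic import closed_fraction


class UnidentifiableFitError(RuntimeError):
    """Binding curve has no usable curvature (all fractions ~ constant)."""


@dataclass(frozen=True)
class TitrationPoint:
    """Closed-state fraction at one ligand concentration (µM)."""

    concentration: float
    fraction_closed: float
    fraction_closed_prob: float
    n_bursts: int
    converged: bool = True

    def __post_init__(self):
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if not 0.0 <= self.fraction_closed <= 1.0:
            raise ValueError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class BindingFit:
    """One-site binding parameters with asymptotic standard errors."""

    kd: float
    bmax: float
    kd_err: float
    bmax_err: float
    hill_h: float = 1.0
    model: str = "one_site"

    def __post_init__(self):
        if self.kd <= 0:
            raise ValueError("kd must be > 0")
        if not 0 < self.bmax <= 1.5:
            raise ValueError("bmax out of range")

    def to_dict(self) -> dict:
        return {
            "kd": self.kd, "kd_err": self.kd_err,
            "bmax": self.bmax, "bmax_err": self.bmax_err,
            "hill_h": self.hill_h, "model": self.model,
        }


def anchor_states(
    apo_points, sat_points, seed: int | None = 0
) -> tuple[PopulationFit, PopulationFit]:
    """Single-population fits of the endpoint (apo / saturated) datasets.

    These anchored fits define the fixed state parameters used at all
    intermediate concentrations.  Endpoint fit failures propagate as
    :class:`~smalex.populations.FitError` (the titration aborts); endpoints
    that are statistically indistinguishable trigger a warning.
    """
    open_fit = fit_populations(apo_points, 1, seed=seed)[0]
    closed_fit = fit_populations(sat_points, 1, seed=seed)[0]
    sep = abs(closed_fit.mu_e - open_fit.mu_e) / max(open_fit.w_e, closed_fit.w_e)
    if sep < 0.5:
        warnings.warn(
            "endpoint states are nearly indistinguishable in E* "
            f"(separation {sep:.2f} widths)",
            RuntimeWarning,
        )
    return open_fit, closed_fit


def _frozen_density(fit: PopulationFit, points: np.ndarray) -> np.ndarray:
    """Unit-weight bivariate normal density of an anchored state."""
    ze = (points[:, 0] - fit.mu_e) / fit.w_e
    zs = (points[:, 1] - fit.mu_s) / fit.w_s
    q = (ze**2 - 2 * fit.rho * ze * zs + zs**2) / (2 * (1 - fit.rho**2))
    return np.exp(-q) / (2 * np.pi * fit.w_e * fit.w_s * np.sqrt(1 - fit.rho**2))


def fraction_closed(
    points,
    open_fit: PopulationFit,
    closed_fit: PopulationFit,
    concentration: float = 0.0,
) -> TitrationPoint:
    """Closed-state fraction at one concentration from anchored states.

    Amplitudes-only refit: state means/widths/correlations stay frozen and
    the closed-state mixture weight pi is estimated by maximum likelihood on
    the (E*, S) points; the fraction is the closed area over the total area.
    The mean closed-assignment probability (the probabilistic burst
    assignment evaluated at the fitted amplitudes) is reported alongside.
    If the amplitude optimization fails, the probability-mean estimator under
    equal amplitudes is used and the point flagged (``converged=False``).
    """
    points = np.asarray(points, dtype=float)
    points = points[np.isfinite(points).all(axis=1)]
    n = points.shape[0]
    if n == 0:
        raise FitError("no finite E*/S points at this concentration")

    f_open = _frozen_density(open_fit, points)
    f_closed = _frozen_density(closed_fit, points)

    def nll(pi):
        mix = pi * f_closed + (1.0 - pi) * f_open
        return -np.sum(np.log(np.maximum(mix, 1e-300)))

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-10})
    if res.success:
        pi = float(res.x)
        converged = True
    else:  # pragma: no cover - bounded Brent essentially always succeeds
        pi = float(np.mean(f_closed / (f_closed + f_open)))
        converged = False

    mix_open = PopulationFit(max(1 - pi, 1e-12), open_fit.mu_e, open_fit.mu_s,
                             open_fit.w_e, open_fit.w_s, open_fit.rho)
    mix_closed = PopulationFit(max(pi, 1e-12), closed_fit.mu_e, closed_fit.mu_s,
                               closed_fit.w_e, closed_fit.w_s, closed_fit.rho)
    p = assign_probabilities(points, [mix_open, mix_closed])
    return TitrationPoint(
        concentration=float(concentration),
        fraction_closed=pi,
        fraction_closed_prob=float(p[:, 1].mean()),
        n_bursts=n,
        converged=converged,
    )


def fit_binding_curve(points: list[TitrationPoint], fix_hill: bool = True) -> BindingFit:
    """Weighted least-squares fit of f(L) = B_max L / (K_D + L).

    Weights are binomial standard errors sqrt(f(1-f)/n) per point (with a
    small-count floor).  The Hill exponent is fixed at 1 (one-site model) by
    default; ``fix_hill=False`` frees it as a diagnostic.  Raises
    :class:`UnidentifiableFitError` when the fractions carry no curvature.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 concentrations spanning K_D")
    conc = np.array([p.concentration for p in points])
    frac = np.array([p.fraction_closed for p in points])
    n = np.array([p.n_bursts for p in points], dtype=float)

    f_safe = np.clip(frac, 1.0 / (n + 2), 1.0 - 1.0 / (n + 2))
    sigma = np.sqrt(f_safe * (1.0 - f_safe) / n)

    if frac.max() - frac.min() < 5.0 * np.median(sigma):
        raise UnidentifiableFitError(
            "fractions are constant within noise; binding curve unidentifiable"
        )

    pos = conc[conc > 0]
    kd0 = float(np.median(pos)) if pos.size else 1.0
    bmax0 = min(float(frac.max()), 1.0) or 0.5

    if fix_hill:
        def model(L, kd, bmax):
            return closed_fraction(L, kd, bmax)
        p0 = [kd0, bmax0]
        bounds = ([1e-12, 1e-6], [np.inf, 1.0])
    else:
        def model(L, kd, bmax, h):
            L = np.asarray(L, dtype=float)
            return bmax * L**h / (kd**h + L**h)
        p0 = [kd0, bmax0, 1.0]
        bounds = ([1e-12, 1e-6, 0.1], [np.inf, 1.0, 10.0])

    popt, pcov = curve_fit(model, conc, frac, p0=p0, sigma=sigma,
                           absolute_sigma=True, bounds=bounds, maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    return BindingFit(
        kd=float(popt[0]), bmax=float(popt[1]),
        kd_err=float(perr[0]), bmax_err=float(perr[1]),
        hill_h=1.0 if fix_hill else float(popt[2]),
        model="one_site" if fix_hill else "hill",
    )


def titrate(
    datasets: list[tuple[float, np.ndarray]],
    apo_points,
    sat_points,
    seed: int | None = 0,
) -> tuple[BindingFit, list[TitrationPoint], tuple[PopulationFit, PopulationFit]]:
    """Endpoint-anchored titration analysis on (concentration, points) data.

    Convenience wrapper chaining :func:`anchor_states`,
    :func:`fraction_closed` per concentration and :func:`fit_binding_curve`.
    """
    open_fit, closed_fit = anchor_states(apo_points, sat_points, seed=seed)
    tps = [
        fraction_closed(pts, open_fit, closed_fit, concentration=conc)
        for conc, pts in datasets
    ]
    fit = fit_binding_curve(tps)
    return fit, tps, (open_fit, closed_fit)
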
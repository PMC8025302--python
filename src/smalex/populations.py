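"""Per-burst E*/S values and covariant bivariate Gaussian population fits.

Each sub-population in the 2D E*/S histogram is described by

    f(E, S) = A * exp{ -1/(2(1-rho^2)) * [ ((E-mu_E)/w_E)^2
              - 2 rho ((E-mu_E)/w_E)((S-mu_S)/w_S) + ((S-mu_S)/w_S)^2 ] }

with amplitude A, means mu_E/mu_S, widths w_E/w_S and E-S correlation rho.
Bursts are assigned to populations probabilistically by

    p_i(E, S) = f_i(E, S) / sum_j f_j(E, S).

Two fitting backends are provided: unbinned expectation-maximization on the
(E*, S) points (default; avoids bin-size sensitivity) and least squares on
the binned 2D histogram (the literal histogram-fitting procedure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

#: lower bound on fitted widths, prevents singular collapse
WIDTH_FLOOR = 1e-3


class FitError(RuntimeError):
    """Population fit failed (degenerate data or non-convergence)."""


@dataclass(frozen=True)
class ESPoint:
    """Apparent FRET efficiency and stoichiometry of one burst."""

    e_app: float
    s_app: float
    n_dexc: int
    n_total: int


def compute_es(f_dd: int, f_da: int, f_aa: int) -> ESPoint:
    """E*/S of a single burst; zero denominators raise (flag-and-exclude)."""
    n_dexc = f_dd + f_da
    n_total = n_dexc + f_aa
    if n_dexc <= 0 or n_total <= 0:
        raise FitError("burst has zero photons in a denominator; exclude it")
    return ESPoint(f_da / n_dexc, n_dexc / n_total, int(n_dexc), int(n_total))


def es_points(bursts: pd.DataFrame) -> np.ndarray:
    """(n, 2) array of finite (E*, S) points from a burst table."""
    pts = bursts[["e_app", "s_app"]].to_numpy(dtype=float)
    return pts[np.isfinite(pts).all(axis=1)]


@dataclass(frozen=True)
class PopulationFit:
    """Fitted parameters of one covariant bivariate Gaussian population."""

    weight: float
    mu_e: float
    mu_s: float
    w_e: float
    w_s: float
    rho: float

    def __post_init__(self):
        if self.w_e <= 0 or self.w_s <= 0:
            raise FitError("widths must be positive")
        if not -1.0 < self.rho < 1.0:
            raise FitError("rho must be in (-1, 1)")
        if self.weight <= 0:
            raise FitError("weight/amplitude must be positive")

    @property
    def amplitude(self) -> float:
        """Peak height of the weighted density (A of the histogram form)."""
        return self.weight / (
            2.0 * np.pi * self.w_e * self.w_s * np.sqrt(1.0 - self.rho**2)
        )

    def density(self, e, s) -> np.ndarray:
        """Weighted bivariate normal density at (e, s)."""
        return self.weight * gaussian2d(e, s, 1.0, self.mu_e, self.mu_s,
                                        self.w_e, self.w_s, self.rho) / (
            2.0 * np.pi * self.w_e * self.w_s * np.sqrt(1.0 - self.rho**2)
        )

    def to_dict(self) -> dict:
        return {
            "weight": self.weight, "mu_e": self.mu_e, "mu_s": self.mu_s,
            "w_e": self.w_e, "w_s": self.w_s, "rho": self.rho,
        }


def gaussian2d(e, s, amplitude, mu_e, mu_s, w_e, w_s, rho):
    """Unnormalized covariant bivariate Gaussian (the histogram-fit form)."""
    ze = (np.asarray(e, dtype=float) - mu_e) / w_e
    zs = (np.asarray(s, dtype=float) - mu_s) / w_s
    q = (ze**2 - 2.0 * rho * ze * zs + zs**2) / (2.0 * (1.0 - rho**2))
    return amplitude * np.exp(-q)


@dataclass
class PopulationsResult:
    """Fit result: populations sorted by mu_E, plus diagnostics."""

    populations: list[PopulationFit]
    converged: bool
    log_likelihood: float | None
    backend: str
    n_points: int
    n_iter: int | None = None
    residual: float | None = field(default=None)

    def __iter__(self):
        return iter(self.populations)

    def __getitem__(self, i) -> PopulationFit:
        return self.populations[i]

    def __len__(self) -> int:
        return len(self.populations)


def _from_gmm(gmm: GaussianMixture) -> list[PopulationFit]:
    fits = []
    for w, mu, cov in zip(gmm.weights_, gmm.means_, gmm.covariances_):
        w_e = float(np.sqrt(cov[0, 0]))
        w_s = float(np.sqrt(cov[1, 1]))
        rho = float(np.clip(cov[0, 1] / (w_e * w_s), -0.999, 0.999))
        fits.append(PopulationFit(float(w), float(mu[0]), float(mu[1]),
                                  max(w_e, WIDTH_FLOOR), max(w_s, WIDTH_FLOOR), rho))
    return sorted(fits, key=lambda f: f.mu_e)


def _check_points(points: np.ndarray, n_populations: int) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (E*, S)")
    points = points[np.isfinite(points).all(axis=1)]
    if points.shape[0] < 50 * n_populations:
        raise FitError(
            f"need >= {50 * n_populations} finite points for {n_populations} population(s),"
            f" got {points.shape[0]}"
        )
    if points.std(axis=0).max() < 10 * np.finfo(float).eps:
        raise FitError("degenerate input: all points identical (zero width)")
    return points


def fit_populations(
    points,
    n_populations: int = 1,
    backend: str = "em",
    seed: int | None = 0,
    init_means=None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> PopulationsResult:
    """Fit ``n_populations`` covariant bivariate Gaussians to (E*, S) points.

    ``backend="em"``: unbinned Gaussian-mixture EM (k-means initialized,
    seedable, width floor 1e-3).  ``backend="histogram"``: least squares of a
    sum of 2D Gaussians to the binned histogram.  Non-convergence and
    degenerate inputs raise :class:`FitError`; they are never silent.
    """
    if n_populations not in (1, 2):
        raise ValueError("n_populations must be 1 or 2")
    points = _check_points(points, n_populations)

    if backend == "em":
        gmm = GaussianMixture(
            n_components=n_populations,
            covariance_type="full",
            tol=tol,
            reg_covar=WIDTH_FLOOR**2,
            max_iter=max_iter,
            n_init=1 if init_means is not None else 3,
            means_init=init_means,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gmm.fit(points)
        if not gmm.converged_:
            raise FitError("EM did not converge within max_iter")
        return PopulationsResult(
            populations=_from_gmm(gmm),
            converged=True,
            log_likelihood=float(gmm.score(points) * points.shape[0]),
            backend="em",
            n_points=points.shape[0],
            n_iter=int(gmm.n_iter_),
        )
    if backend == "histogram":
        return _fit_histogram(points, n_populations, seed=seed, init_means=init_means)
    raise ValueError(f"unknown backend: {backend!r}")


def _fit_histogram(points, n_populations, seed=0, init_means=None, bins=41):
    """Least-squares fit of summed 2D Gaussians to the binned E*/S histogram."""
    from scipy.optimize import least_squares

    h, e_edges, s_edges = np.histogram2d(
        points[:, 0], points[:, 1], bins=bins, range=[[-0.1, 1.1], [-0.1, 1.1]]
    )
    ec = 0.5 * (e_edges[:-1] + e_edges[1:])
    sc = 0.5 * (s_edges[:-1] + s_edges[1:])
    ee, ss = np.meshgrid(ec, sc, indexing="ij")

    if init_means is None:
        # seed the histogram fit from a quick EM pass (amplitudes in counts)
        em = fit_populations(points, n_populations, backend="em", seed=seed)
        init = [(h.max() * p.weight, p.mu_e, p.mu_s, p.w_e, p.w_s, p.rho) for p in em]
    else:
        init = [(h.max() / n_populations, me, ms, 0.05, 0.05, 0.0) for me, ms in init_means]

    def unpack(x):
        return [x[6 * i: 6 * i + 6] for i in range(n_populations)]

    def model(x):
        out = np.zeros_like(ee)
        for a, me, ms, we, ws, rho in unpack(x):
            out += gaussian2d(ee, ss, a, me, ms, we, ws, rho)
        return out

    x0 = np.concatenate(init)
    lo = np.tile([0.0, -0.1, -0.1, WIDTH_FLOOR, WIDTH_FLOOR, -0.99], n_populations)
    hi = np.tile([np.inf, 1.1, 1.1, 1.0, 1.0, 0.99], n_populations)
    res = least_squares(lambda x: (model(x) - h).ravel(), x0, bounds=(lo, hi))
    if not res.success:
        raise FitError(f"histogram fit did not converge: {res.message}")

    fits = []
    total = 0.0
    areas = []
    for a, me, ms, we, ws, rho in unpack(res.x):
        area = a * 2 * np.pi * we * ws * np.sqrt(1 - rho**2)
        areas.append(area)
        total += area
    for (a, me, ms, we, ws, rho), area in zip(unpack(res.x), areas):
        fits.append(PopulationFit(float(area / total), float(me), float(ms),
                                  float(max(we, WIDTH_FLOOR)), float(max(ws, WIDTH_FLOOR)),
                                  float(rho)))
    return PopulationsResult(
        populations=sorted(fits, key=lambda f: f.mu_e),
        converged=True,
        log_likelihood=None,
        backend="histogram",
        n_points=points.shape[0],
        residual=float(np.sum(res.fun**2)),
    )


def assign_probabilities(points, fits) -> np.ndarray:
    """Population membership probabilities p_i = f_i(E,S) / sum_j f_j(E,S).

    ``points`` is (n, 2); returns (n, k) rows summing to 1.  Points where all
    densities underflow to zero get a uniform assignment with a warning.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    fits = list(fits)
    if len(fits) == 0:
        raise ValueError("at least one fitted population required")
    dens = np.column_stack([f.density(points[:, 0], points[:, 1]) for f in fits])
    total = dens.sum(axis=1)
    zero = total <= 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} point(s) had zero density under all populations; "
            "assigned uniformly",
            RuntimeWarning,
        )
        dens[zero] = 1.0
        total[zero] = len(fits)
    return dens / total[:, None]
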
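"""Isothermal titration calorimetry: isotherm models, fitting, thermodynamics.

Binding of a ligand (injected from the syringe) to a protein (in the cell) is
described by independent-site models.  For each injection the total
concentrations are updated with the standard perfusion (displacement)
correction - every injection of volume v displaces a fraction v/V0 of the
cell content - and the bound complex follows from mass balance:

* one site: closed-form root of the quadratic
  [ML] = ((nM + X + K_D) - sqrt((nM + X + K_D)^2 - 4 nM X)) / 2,
* two independent sites: the free-ligand concentration solves the monotone
  scalar equation X = L + M * sum_k n_k K_k L / (1 + K_k L) (bracketed root).

The heat of injection i is V0 * sum_k dH_k * ([ML]_k,i - [ML]_k,i-1 (1-v/V0))
and is reported per mole of injectant (instrument convention).  From the
fitted association constant K_A the package derives K_D = 1/K_A,
dG = -RT ln(K_A) and dS from dG = dH - T dS.

Units: concentrations µM, volumes µl, temperatures K, enthalpies kJ/mol on
the interface (calories accepted on input, 4.184 J/cal); heats are µJ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

import lmfit

R_GAS = 8.314462618  # J/(mol K)
JOULES_PER_CALORIE = 4.184


class ITCError(RuntimeError):
    """Invalid ITC input or a violated model contract."""


@dataclass(frozen=True)
class SiteParams:
    """Independent binding site: stoichiometry n, K_A (1/M), dH (kJ/mol)."""

    n: float
    ka: float
    dh: float

    def __post_init__(self):
        if self.n < 0:
            raise ITCError("site stoichiometry n must be >= 0")
        if self.ka <= 0:
            raise ITCError("association constant must be > 0")

    @property
    def kd_uM(self) -> float:
        return 1e6 / self.ka

    def delta_g(self, temperature: float = 298.15) -> float:
        """Standard binding free energy -RT ln K_A, kJ/mol."""
        return -R_GAS * temperature * np.log(self.ka) / 1e3

    def delta_s(self, temperature: float = 298.15) -> float:
        """Binding entropy from dG = dH - T dS, J/(mol K)."""
        return (self.dh - self.delta_g(temperature)) * 1e3 / temperature


@dataclass(frozen=True)
class ITCExperiment:
    """Injection series: design (volumes, concentrations, T) plus heats (µJ)."""

    cell_volume_ul: float
    cell_conc_uM: float
    syringe_conc_uM: float
    injection_volumes_ul: tuple[float, ...]
    heats_uJ: tuple[float, ...] | None = None
    temperature: float = 298.15

    def __post_init__(self):
        if min(self.cell_volume_ul, self.cell_conc_uM, self.syringe_conc_uM) <= 0:
            raise ITCError("volumes and concentrations must be > 0")
        if any(v <= 0 for v in self.injection_volumes_ul):
            raise ITCError("injection volumes must be > 0")
        if self.heats_uJ is not None and len(self.heats_uJ) != self.n_injections:
            raise ITCError("heats list must match the number of injections")
        if self.temperature <= 0:
            raise ITCError("temperature must be > 0 K")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_ul)

    def with_heats(self, heats_uJ, unit: str = "uJ") -> "ITCExperiment":
        heats = np.asarray(heats_uJ, dtype=float)
        if unit == "ucal":
            heats = heats * JOULES_PER_CALORIE
        elif unit != "uJ":
            raise ITCError(f"unknown heat unit: {unit!r}")
        return replace(self, heats_uJ=tuple(float(h) for h in heats))

    def heats_per_mole(self) -> np.ndarray:
        """Measured heats per mole of injectant, kJ/mol."""
        if self.heats_uJ is None:
            raise ITCError("experiment carries no measured heats")
        return np.asarray(self.heats_uJ) / self._moles_injected_umol() / 1e3

    def _moles_injected_umol(self) -> np.ndarray:
        v_l = np.asarray(self.injection_volumes_ul) * 1e-6
        return self.syringe_conc_uM * 1e-6 * v_l * 1e6  # µmol


def _totals(exp: ITCExperiment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Total cell protein and ligand (µM) after each injection.

    Index 0 is the pre-injection state; the displacement dilution multiplies
    existing cell contents by (1 - v/V0) per injection.
    """
    n = exp.n_injections
    m_tot = np.empty(n + 1)
    x_tot = np.empty(n + 1)
    m_tot[0] = exp.cell_conc_uM
    x_tot[0] = 0.0
    v0 = exp.cell_volume_ul
    for i, v in enumerate(exp.injection_volumes_ul, start=1):
        d = 1.0 - v / v0
        if d <= 0:
            raise ITCError("injection volume exceeds cell volume")
        m_tot[i] = m_tot[i - 1] * d
        x_tot[i] = x_tot[i - 1] * d + exp.syringe_conc_uM * (v / v0)
    return m_tot, x_tot, np.asarray(exp.injection_volumes_ul, dtype=float)


def _bound_one_site(site: SiteParams, m_tot, x_tot) -> np.ndarray:
    """Complex concentration [ML] (µM) from the one-site mass balance."""
    kd = 1e6 / site.ka  # µM
    b = site.n * m_tot
    disc = (b + x_tot + kd) ** 2 - 4.0 * b * x_tot
    if np.any(disc < 0):  # cannot occur for physical inputs
        raise ITCError("negative discriminant in one-site mass balance")
    return 0.5 * ((b + x_tot + kd) - np.sqrt(disc))


def _bound_two_site(site1: SiteParams, site2: SiteParams, m_tot, x_tot):
    """Per-site complex concentrations (µM) for two independent sites."""
    k1 = site1.ka * 1e-6  # 1/µM
    k2 = site2.ka * 1e-6
    ml1 = np.zeros_like(x_tot)
    ml2 = np.zeros_like(x_tot)
    for i, (m, x) in enumerate(zip(m_tot, x_tot)):
        if x <= 0:
            continue

        def excess(l_free):
            th1 = k1 * l_free / (1.0 + k1 * l_free)
            th2 = k2 * l_free / (1.0 + k2 * l_free)
            return l_free + m * (site1.n * th1 + site2.n * th2) - x

        # excess is strictly increasing in L with excess(0) = -x < 0 <= excess(x)
        l_free = brentq(excess, 0.0, x, xtol=1e-14, rtol=1e-14)
        ml1[i] = m * site1.n * k1 * l_free / (1.0 + k1 * l_free)
        ml2[i] = m * site2.n * k2 * l_free / (1.0 + k2 * l_free)
    return ml1, ml2


def _heats_from_bound(exp: ITCExperiment, bound_by_site, dh_by_site) -> np.ndarray:
    """Injection heats (µJ) from per-site complex series (µM)."""
    v0_l = exp.cell_volume_ul * 1e-6
    v = np.asarray(exp.injection_volumes_ul) / exp.cell_volume_ul  # v_i/V0
    q = np.zeros(exp.n_injections)
    for ml, dh in zip(bound_by_site, dh_by_site):
        delta = ml[1:] - ml[:-1] * (1.0 - v)
        q += v0_l * (dh * 1e3) * (delta * 1e-6) * 1e6  # -> µJ
    return q


def one_site_isotherm(site: SiteParams, exp: ITCExperiment) -> np.ndarray:
    """Predicted per-injection heats (µJ) for a single independent site."""
    m_tot, x_tot, _ = _totals(exp)
    ml = _bound_one_site(site, m_tot, x_tot)
    return _heats_from_bound(exp, [ml], [site.dh])


def two_site_isotherm(site1: SiteParams, site2: SiteParams, exp: ITCExperiment) -> np.ndarray:
    """Predicted per-injection heats (µJ) for two independent sites."""
    m_tot, x_tot, _ = _totals(exp)
    ml1, ml2 = _bound_two_site(site1, site2, m_tot, x_tot)
    return _heats_from_bound(exp, [ml1, ml2], [site1.dh, site2.dh])


def bound_series(exp: ITCExperiment, *sites: SiteParams):
    """Per-site complex concentrations (µM) after each injection (index 0 =
    pre-injection), for conservation checks and diagnostics."""
    m_tot, x_tot, _ = _totals(exp)
    if len(sites) == 1:
        return m_tot, x_tot, (_bound_one_site(sites[0], m_tot, x_tot),)
    if len(sites) == 2:
        return m_tot, x_tot, _bound_two_site(sites[0], sites[1], m_tot, x_tot)
    raise ITCError("one or two sites supported")


def simulate_itc(
    sites,
    exp_design: ITCExperiment,
    noise_sd_uJ: float = 0.0,
    noise_fraction: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> ITCExperiment:
    """Forward isotherm plus Gaussian heat noise; seedable.

    ``noise_sd_uJ`` adds a constant-sd term (µJ); ``noise_fraction`` adds a
    per-injection proportional term (sd = fraction * |predicted heat|).
    """
    sites = list(np.atleast_1d(sites))
    if noise_sd_uJ < 0 or noise_fraction < 0:
        raise ITCError("noise levels must be >= 0")
    if len(sites) == 1:
        q = one_site_isotherm(sites[0], exp_design)
    elif len(sites) == 2:
        q = two_site_isotherm(sites[0], sites[1], exp_design)
    else:
        raise ITCError("one or two sites supported")
    sd = np.hypot(noise_sd_uJ, noise_fraction * np.abs(q))
    if np.any(sd > 0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        q = q + rng.normal(0.0, 1.0, size=q.size) * sd
    return exp_design.with_heats(q)


@dataclass(frozen=True)
class FittedSite:
    """Fitted site parameters with asymptotic standard errors."""

    params: SiteParams
    n_err: float = np.nan
    ka_err: float = np.nan
    dh_err: float = np.nan

    @property
    def kd_uM(self) -> float:
        return self.params.kd_uM

    @property
    def kd_err_uM(self) -> float:
        # first-order propagation of the K_A error through K_D = 1/K_A
        return 1e6 * self.ka_err / self.params.ka**2


@dataclass
class ITCFit:
    """Result of an isotherm fit with derived thermodynamics."""

    sites: list[FittedSite]
    model: str
    temperature: float
    converged: bool
    at_bound: bool
    chisqr: float
    residuals: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "temperature_K": self.temperature,
            "converged": self.converged,
            "at_bound": self.at_bound,
            "chisqr_uJ2": self.chisqr,
            "sites": [],
        }
        for fs in self.sites:
            p = fs.params
            out["sites"].append(
                {
                    "n": p.n,
                    "n_err": fs.n_err,
                    "ka_per_M": p.ka,
                    "kd_uM": p.kd_uM,
                    "kd_err_uM": fs.kd_err_uM,
                    "dh_kJ_mol": p.dh,
                    "dh_err_kJ_mol": fs.dh_err,
                    "dg_kJ_mol": p.delta_g(self.temperature),
                    "tds_kJ_mol": p.dh - p.delta_g(self.temperature),
                }
            )
        return out


def _predict(params: lmfit.Parameters, exp: ITCExperiment, n_sites: int) -> np.ndarray:
    sites = []
    for k in range(1, n_sites + 1):
        sites.append(
            SiteParams(
                n=params[f"n{k}"].value,
                ka=10.0 ** params[f"logka{k}"].value,
                dh=params[f"dh{k}"].value,
            )
        )
    if n_sites == 1:
        return one_site_isotherm(sites[0], exp)
    return two_site_isotherm(sites[0], sites[1], exp)


def _make_params(n_sites, init, fixed: SiteParams | None) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for k in range(1, n_sites + 1):
        n0, logka0, dh0 = init[k - 1]
        params.add(f"n{k}", value=n0, min=1e-3, max=10.0)
        params.add(f"logka{k}", value=logka0, min=0.0, max=12.0)
        params.add(f"dh{k}", value=dh0, min=-500.0, max=500.0)
    if fixed is not None:
        # sequential procedure: one site characterized separately, held fixed
        params["n1"].set(value=fixed.n, vary=False)
        params["logka1"].set(value=np.log10(fixed.ka), vary=False)
        params["dh1"].set(value=fixed.dh, vary=False)
    return params


def fit_itc(
    exp: ITCExperiment,
    model: str = "one_site",
    fixed: SiteParams | None = None,
    exclude_first: bool = False,
    init: list[tuple[float, float, float]] | None = None,
) -> ITCFit:
    """Nonlinear least-squares fit of the measured heats.

    ``model`` is ``"one_site"`` or ``"two_site"``.  ``fixed`` holds one
    site's parameters constant during a two-site fit (the sequential
    fixed-parameter procedure used when one site has been characterized
    separately).  ``exclude_first`` drops the first injection (syringe-leak
    convention; off by default).  Without an explicit ``init`` a small
    multistart grid over log10 K_A is used and the best optimum kept.
    Fitted sites are reported sorted by affinity (largest K_A first).
    """
    if model not in ("one_site", "two_site"):
        raise ITCError(f"unknown model: {model!r}")
    n_sites = 1 if model == "one_site" else 2
    if fixed is not None and n_sites == 1:
        raise ITCError("fixed-site fitting requires the two-site model")
    if exp.heats_uJ is None:
        raise ITCError("experiment carries no measured heats")
    n_informative = exp.n_injections - (1 if exclude_first else 0)
    if n_informative < 10:
        raise ITCError("need >= 10 informative injections")

    heats = np.asarray(exp.heats_uJ, dtype=float)
    weight = np.ones_like(heats)
    if exclude_first:
        weight[0] = 0.0

    def residual(params):
        return (_predict(params, exp, n_sites) - heats) * weight

    # initial enthalpy from the first (most saturating-limit) injections
    ndh = exp.heats_per_mole()
    dh0 = float(ndh[0])

    if init is not None:
        starts = [init]
    else:
        if n_sites == 1:
            # c = n Ka M0 spanning ~1..1000
            grid = np.log10(np.array([1.0, 10.0, 100.0, 1000.0]) / (exp.cell_conc_uM * 1e-6))
            starts = [[(1.0, g, dh0)] for g in grid]
        else:
            g_hi = np.log10(np.array([10.0, 100.0, 1000.0]) / (exp.cell_conc_uM * 1e-6))
            g_lo = np.log10(np.array([0.1, 1.0, 10.0]) / (exp.cell_conc_uM * 1e-6))
            starts = [
                [(1.0, gh, dh0), (1.0, gl, 0.5 * dh0)]
                for gh in g_hi
                for gl in g_lo
                if gh > gl
            ]
            if fixed is not None:
                starts = [[(fixed.n, np.log10(fixed.ka), fixed.dh), s[1]] for s in starts]

    best = None
    for start in starts:
        params = _make_params(n_sites, start, fixed)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:  # singular steps on bad starts: try the next one
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise ITCError("isotherm fit failed from every starting point")

    at_bound = False
    sites = []
    for k in range(1, n_sites + 1):
        p = best.params
        n_v, logka_v, dh_v = p[f"n{k}"].value, p[f"logka{k}"].value, p[f"dh{k}"].value
        for name in (f"n{k}", f"logka{k}", f"dh{k}"):
            par = p[name]
            if par.vary and (
                np.isclose(par.value, par.min, atol=1e-9)
                or np.isclose(par.value, par.max, atol=1e-9)
            ):
                at_bound = True
        ka_v = 10.0**logka_v
        ka_err = (
            abs(np.log(10.0) * ka_v * p[f"logka{k}"].stderr)
            if p[f"logka{k}"].stderr is not None
            else np.nan
        )
        sites.append(
            FittedSite(
                params=SiteParams(n=n_v, ka=ka_v, dh=dh_v),
                n_err=p[f"n{k}"].stderr if p[f"n{k}"].stderr is not None else np.nan,
                ka_err=ka_err,
                dh_err=p[f"dh{k}"].stderr if p[f"dh{k}"].stderr is not None else np.nan,
            )
        )
    sites.sort(key=lambda fs: fs.params.ka, reverse=True)

    if not best.success:
        warnings.warn("ITC fit reported non-convergence; result flagged", RuntimeWarning)
    if at_bound:
        warnings.warn("ITC fit has a parameter at its bound; result flagged", RuntimeWarning)

    return ITCFit(
        sites=sites,
        model=model,
        temperature=exp.temperature,
        converged=bool(best.success),
        at_bound=at_bound,
        chisqr=float(best.chisqr),
        residuals=np.asarray(best.residual),
    )
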
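"""ITC isotherm models vs a bisection oracle, and parameter recovery."""

import numpy as np
import pytest
from scipy.optimize import bisect

from smalex import (
    ITCExperiment,
    SiteParams,
    fit_itc,
    one_site_isotherm,
    simulate_itc,
    two_site_isotherm,
)
from smalex.itc import ITCError, R_GAS, bound_series

DESIGN_1SITE = ITCExperiment(200.0, 50.0, 500.0, tuple([2.0] * 20))
DESIGN_2SITE = ITCExperiment(200.0, 60.0, 2400.0, tuple([1.5] * 30))


def _oracle_heats(sites, exp):
    """Independent forward model: per-injection heats via bisection roots.

    Re-derives the dilution bookkeeping and solves every mass balance (one or
    two sites alike) by scipy.optimize.bisect on the binding polynomial.
    """
    v0 = exp.cell_volume_ul
    m, x = exp.cell_conc_uM, 0.0
    bound_prev = np.zeros(len(sites))
    heats = []
    for v in exp.injection_volumes_ul:
        d = 1.0 - v / v0
        m *= d
        x = x * d + exp.syringe_conc_uM * v / v0

        def excess(l_free):
            tot = l_free
            for s in sites:
                k = s.ka * 1e-6
                tot += m * s.n * k * l_free / (1 + k * l_free)
            return tot - x

        l_free = bisect(excess, 0.0, x, xtol=1e-15) if x > 0 else 0.0
        bound = np.array(
            [m * s.n * (s.ka * 1e-6) * l_free / (1 + (s.ka * 1e-6) * l_free)
             for s in sites]
        )
        q = sum(
            (v0 * 1e-6) * (s.dh * 1e3) * ((b - bp * d) * 1e-6) * 1e6
            for s, b, bp in zip(sites, bound, bound_prev)
        )
        heats.append(q)
        bound_prev = bound
    return np.array(heats)


def test_zero_enthalpy_means_zero_heat():
    q = one_site_isotherm(SiteParams(1.0, 1e6, 0.0), DESIGN_1SITE)
    np.testing.assert_allclose(q, 0.0)


def test_stoichiometric_burnup_limit():
    # K_a -> inf: every early injection binds completely, heat/mole = dH
    site = SiteParams(1.0, 1e12, -40.0)
    exp = simulate_itc([site], DESIGN_1SITE)
    ndh = exp.heats_per_mole()
    np.testing.assert_allclose(ndh[:5], -40.0, rtol=1e-4)


def test_one_site_matches_bisection_oracle():
    site = SiteParams(0.8, 2.5e6, -35.0)
    q = one_site_isotherm(site, DESIGN_1SITE)
    np.testing.assert_allclose(q, _oracle_heats([site], DESIGN_1SITE), rtol=1e-9)


def test_two_site_matches_bisection_oracle():
    s1 = SiteParams(1.0, 1 / 0.6e-6, -30.0)
    s2 = SiteParams(1.0, 1 / 180e-6, -15.0)
    q = two_site_isotherm(s1, s2, DESIGN_2SITE)
    np.testing.assert_allclose(q, _oracle_heats([s1, s2], DESIGN_2SITE), rtol=1e-9)


def test_two_site_with_empty_site_reduces_to_one_site():
    s1 = SiteParams(1.0, 1e6, -30.0)
    empty = SiteParams(0.0, 1e3, -10.0)
    np.testing.assert_allclose(
        two_site_isotherm(s1, empty, DESIGN_1SITE),
        one_site_isotherm(s1, DESIGN_1SITE),
        rtol=1e-12,
    )


def test_equal_sites_equal_one_site_with_doubled_n():
    s = SiteParams(1.0, 1e6, -20.0)
    np.testing.assert_allclose(
        two_site_isotherm(s, s, DESIGN_2SITE),
        one_site_isotherm(SiteParams(2.0, 1e6, -20.0), DESIGN_2SITE),
        rtol=1e-10,
    )


def test_disparate_affinities_need_two_site_model():
    # K_a1 >> K_a2 gives a biphasic curve a single site cannot reproduce
    s1 = SiteParams(1.0, 1e8, -30.0)
    s2 = SiteParams(1.0, 1e4, -15.0)
    exp = simulate_itc([s1, s2], DESIGN_2SITE)
    fit1 = fit_itc(exp, "one_site")
    fit2 = fit_itc(exp, "two_site")
    assert fit2.chisqr < 0.01 * fit1.chisqr


def test_bound_fraction_monotone_in_total_ligand():
    # occupancy theta = [ML]/(n M_t) rises with total ligand even though the
    # absolute complex concentration falls late on as protein is diluted out
    site = SiteParams(1.0, 5e5, -25.0)
    m_tot, x_tot, (ml,) = bound_series(DESIGN_1SITE, site)
    theta = ml / (site.n * m_tot)
    assert np.all(np.diff(x_tot) > 0)
    assert np.all(np.diff(theta) >= -1e-12)


def test_cumulative_heat_conservation():
    # telescoping identity including the expelled-complex bookkeeping
    site = SiteParams(1.0, 2e6, -40.0)
    q = one_site_isotherm(site, DESIGN_1SITE)
    _, _, (ml,) = bound_series(DESIGN_1SITE, site)
    v0_l = DESIGN_1SITE.cell_volume_ul * 1e-6
    v = np.asarray(DESIGN_1SITE.injection_volumes_ul) / DESIGN_1SITE.cell_volume_ul
    expelled = np.sum(ml[:-1] * v)
    rhs = v0_l * (site.dh * 1e3) * ((ml[-1] + expelled) * 1e-6) * 1e6
    assert q.sum() == pytest.approx(rhs, rel=1e-9)


# ------------------------------------------------------------ fitting

def test_noiseless_one_site_round_trip_exact():
    site = SiteParams(1.0, 1 / 0.4e-6, -40.0)  # K_D = 400 nM
    exp = simulate_itc([site], DESIGN_1SITE)
    fit = fit_itc(exp, "one_site")
    assert fit.sites[0].kd_uM == pytest.approx(0.4, rel=1e-6)
    assert fit.sites[0].params.n == pytest.approx(1.0, rel=1e-6)
    assert fit.sites[0].params.dh == pytest.approx(-40.0, rel=1e-6)


def test_noiseless_two_site_round_trip():
    s_hi = SiteParams(1.0, 1 / 0.6e-6, -30.0)
    s_lo = SiteParams(1.0, 1 / 180e-6, -15.0)
    exp = simulate_itc([s_hi, s_lo], DESIGN_2SITE)
    fit = fit_itc(exp, "two_site")
    assert fit.sites[0].kd_uM == pytest.approx(0.6, rel=1e-4)
    assert fit.sites[1].kd_uM == pytest.approx(180.0, rel=1e-4)


def test_fixed_site_sequential_recovery_at_one_percent_noise():
    # hold the separately determined high-affinity site fixed; recover the
    # free low-affinity site within 5% (median over 20 seeds)
    s_fix = SiteParams(1.0, 1 / 0.6e-6, -30.0)
    s_free = SiteParams(1.0, 1 / 19e-6, -15.0)
    errs = []
    for seed in range(20):
        exp = simulate_itc([s_fix, s_free], DESIGN_2SITE,
                           noise_fraction=0.01, rng=seed)
        fit = fit_itc(exp, "two_site", fixed=s_fix)
        free = [s for s in fit.sites
                if abs(s.params.ka - s_fix.ka) / s_fix.ka > 1e-6][0]
        errs.append(abs(free.kd_uM - 19.0) / 19.0)
    assert np.median(errs) < 0.05


def test_replicate_seeds_differ_but_truth_is_fixed():
    site = SiteParams(1.0, 1e6, -30.0)
    e1 = simulate_itc([site], DESIGN_1SITE, noise_sd_uJ=5.0, rng=1)
    e2 = simulate_itc([site], DESIGN_1SITE, noise_sd_uJ=5.0, rng=2)
    assert e1.heats_uJ != e2.heats_uJ
    assert e1.injection_volumes_ul == e2.injection_volumes_ul


# ------------------------------------------------------------ thermodynamics

def test_derived_thermodynamics_consistent():
    site = SiteParams(1.0, 1 / 0.9e-6, -40.0)
    assert site.kd_uM * site.ka * 1e-6 == pytest.approx(1.0)
    dg = site.delta_g(298.15)
    expected = -R_GAS * 298.15 * np.log(1 / 0.9e-6) / 1e3  # ~ -34.5 kJ/mol
    assert dg == pytest.approx(expected)
    assert dg < 0 and abs(dg) == pytest.approx(34.5, abs=0.2)
    # dG = dH - T dS holds exactly by construction
    tds = site.delta_s(298.15) * 298.15 / 1e3
    assert site.dh - tds == pytest.approx(dg)


def test_fit_report_fields():
    site = SiteParams(1.0, 1 / 0.4e-6, -40.0)
    fit = fit_itc(simulate_itc([site], DESIGN_1SITE), "one_site")
    d = fit.to_dict()["sites"][0]
    assert d["kd_uM"] == pytest.approx(0.4, rel=1e-6)
    assert d["dg_kJ_mol"] == pytest.approx(d["dh_kJ_mol"] - d["tds_kJ_mol"], rel=1e-9)


# ------------------------------------------------------------ validation

def test_invalid_inputs_rejected():
    with pytest.raises(ITCError):
        ITCExperiment(200.0, -1.0, 500.0, (2.0,))
    with pytest.raises(ITCError):
        ITCExperiment(200.0, 50.0, 500.0, (2.0,), heats_uJ=(1.0, 2.0))
    with pytest.raises(ITCError):
        SiteParams(1.0, -5.0, -40.0)
    with pytest.raises(ITCError):
        fit_itc(simulate_itc([SiteParams(1.0, 1e6, -40.0)],
                             ITCExperiment(200.0, 50.0, 500.0, tuple([2.0] * 5))),
                "one_site")
    with pytest.raises(ITCError):
        fit_itc(simulate_itc([SiteParams(1.0, 1e6, -40.0)], DESIGN_1SITE), "bogus")


def test_calorie_heats_converted():
    exp = DESIGN_1SITE.with_heats(np.ones(20), unit="ucal")
    assert exp.heats_uJ[0] == pytest.approx(4.184)
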
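"""End-to-end pipelines chaining simulation, burst search and fitting.

These are the orchestration paths used by the command-line interface and the
analysis drivers: photon-level titrations (trace -> burst search -> anchored
population fits -> closed fractions -> one-site binding fit), single-dataset
population fits, BVA and PIFE construct series.  Every run is deterministic
under a fixed seed and emits a provenance record.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import bursts as bp
from . import io as sio
from .bva import bva_compare
from .pife import ConstructFit, linker_trend, null_control, stoichiometry_shift
from .populations import es_points, fit_populations
from .synthetic import (
    BurstSizeModel,
    FluorophoreState,
    SimulationConfig,
    simulate_bursts,
    simulate_timetrace,
    simulate_titration,
)
from .titration import anchor_states, fit_binding_curve, fraction_closed

logger = logging.getLogger("smalex")

#: generator conditions for photon-level titration pipelines: mean analyzed
#: burst intensity above the 150-photon selection, 50 pM-like burst rate
TITRATION_SIM = dict(mean_dexc_photons=200.0, burst_rate=20.0, burst_duration=1000.0)


def bursts_from_trace(
    stream: bp.PhotonStream,
    config: SimulationConfig,
    params: bp.BurstSearchParams | None = None,
    mode: str = "analysis",
) -> pd.DataFrame:
    """Assign excitation periods, burst-search a raw trace, apply selection."""
    labelled = bp.assign_excitation(
        stream.timestamps,
        stream.detector,
        alternation_period=config.alternation_period,
        donor_window=config.donor_window,
        acceptor_window=config.acceptor_window,
    )
    table = bp.all_photon_burst_search(labelled, params)
    logger.info("burst search: %d photons -> %d bursts", len(labelled), len(table))
    return bp.apply_burst_thresholds(table, params, mode=mode)


def _endpoint_points(state, config, n_bursts, params, rng):
    cfg = config.replace(states=(state,), weights=(1.0,),
                         duration=n_bursts / config.burst_rate)
    trace, _ = simulate_timetrace(cfg, rng=rng)
    return es_points(bursts_from_trace(trace, cfg, params))


def titration_photon_pipeline(
    kd_true: float,
    concentrations,
    open_state: FluorophoreState,
    closed_state: FluorophoreState,
    seed: int,
    n_bursts_per_point: int = 3000,
    bmax_true: float = 1.0,
    params: bp.BurstSearchParams | None = None,
    config: SimulationConfig | None = None,
) -> dict:
    """Full photon-level titration: K_D recovery through the whole pipeline.

    Simulates a photon trace per ligand concentration plus the two endpoint
    (apo / saturating) anchor traces, runs the all-photon burst search and
    intensity selection on each, anchors the open/closed states on the
    endpoints, extracts closed fractions by amplitude-only refits and fits
    the one-site binding curve.  Returns the binding fit, per-point
    fractions, anchors and ground truth.
    """
    if config is None:
        config = SimulationConfig(
            states=(open_state,), weights=(1.0,), seed=seed, **TITRATION_SIM
        )
    else:
        config = config.replace(seed=seed)
    if params is None:
        params = bp.BurstSearchParams()

    seq = np.random.SeedSequence(seed)
    rng_apo, rng_sat = (np.random.default_rng(s) for s in seq.spawn(2))
    apo_pts = _endpoint_points(open_state, config, n_bursts_per_point, params, rng_apo)
    sat_pts = _endpoint_points(closed_state, config, n_bursts_per_point, params, rng_sat)
    open_fit, closed_fit = anchor_states(apo_pts, sat_pts, seed=seed)

    series = simulate_titration(
        config, open_state, closed_state, concentrations,
        kd_true=kd_true, bmax_true=bmax_true,
        n_bursts_per_point=n_bursts_per_point, timetrace=True,
    )
    points = []
    for conc, trace, _truth in series:
        table = bursts_from_trace(trace, config, params)
        tp = fraction_closed(es_points(table), open_fit, closed_fit, concentration=conc)
        logger.info("L=%.4g: %d bursts, fraction=%.3f", conc, tp.n_bursts, tp.fraction_closed)
        points.append(tp)
    fit = fit_binding_curve(points)
    return {
        "binding_fit": fit,
        "points": points,
        "anchors": (open_fit, closed_fit),
        "kd_true": kd_true,
        "bmax_true": bmax_true,
    }


def single_state_mu(
    state: FluorophoreState,
    n_bursts: int = 10_000,
    seed: int = 0,
    mean_dexc_photons: float = 120.0,
    burst_size_model: BurstSizeModel | None = None,
    s_selection: tuple[float, float] | None = None,
    threshold: bool = True,
) -> dict:
    """Simulate one state at burst level and fit a single 2D Gaussian.

    Convenience used by the FRET-state and PIFE recovery studies: returns the
    fitted mu_E/mu_S (and widths) of a 10^4-burst single-population dataset.
    The standard intensity selection (both excitation sums above 150 photons)
    is applied before fitting, as in the measurement protocol, unless
    ``threshold=False``.
    """
    cfg = SimulationConfig(
        states=(state,), weights=(1.0,),
        mean_dexc_photons=mean_dexc_photons, seed=seed,
        burst_size_model=burst_size_model or BurstSizeModel(),
    )
    table, _ = simulate_bursts(cfg, n_bursts)
    if threshold:
        table = bp.apply_burst_thresholds(table, mode="analysis")
    if s_selection is not None:
        table = bp.select_stoichiometry(table, *s_selection)
    fit = fit_populations(es_points(table), 1, seed=seed)[0]
    return {
        "mu_e": fit.mu_e, "mu_s": fit.mu_s,
        "w_e": fit.w_e, "w_s": fit.w_s,
        "n_bursts": len(table),
    }


def pife_construct_series(
    constructs: list[dict],
    reference: str,
    n_bursts: int = 10_000,
    seed: int = 0,
    mean_dexc_photons: float = 120.0,
) -> pd.DataFrame:
    """Simulate and fit a PIFE construct series; return the ΔS* shift table.

    Each construct dict carries label, linker_delta, e_app, s_app and
    pife_alpha; all constructs share the baseline s_app (the single-domain
    reference) and differ in alpha (and possibly FRET state).
    """
    seq = np.random.SeedSequence(seed).spawn(len(constructs))
    fits = []
    for construct, child in zip(constructs, seq):
        state = FluorophoreState(
            label=construct["label"],
            e_app=construct.get("e_app", 0.6),
            s_app=construct["s_app"],
            pife_alpha=construct.get("pife_alpha", 1.0),
        )
        cfg = SimulationConfig(
            states=(state,), weights=(1.0,),
            mean_dexc_photons=mean_dexc_photons,
            seed=int(np.random.default_rng(child).integers(2**31 - 1)),
        )
        table, _ = simulate_bursts(cfg, n_bursts)
        table = bp.apply_burst_thresholds(table, mode="analysis")
        pop = fit_populations(es_points(table), 1, seed=0)[0]
        fits.append(
            ConstructFit(
                label=construct["label"],
                mu_s=pop.mu_s,
                se_s=pop.w_s / np.sqrt(len(table)),
                mu_e=pop.mu_e,
                se_e=pop.w_e / np.sqrt(len(table)),
                linker_delta=int(construct.get("linker_delta", 0)),
            )
        )
    return stoichiometry_shift(fits, reference)


# ----------------------------------------------------------- config-driven run

KNOWN_KEYS = {"mode", "seed", "out", "states", "weights", "simulation",
              "burst_search", "titration", "bva", "pife", "n_populations"}


def _states_from_config(cfg: dict):
    states = tuple(
        FluorophoreState(
            label=s.get("label", f"state{i}"),
            e_app=float(s["e_app"]),
            s_app=float(s["s_app"]),
            pife_alpha=float(s.get("pife_alpha", 1.0)),
        )
        for i, s in enumerate(cfg["states"])
    )
    weights = tuple(float(w) for w in cfg.get("weights", [1.0 / len(states)] * len(states)))
    return states, weights


def _sim_config(cfg: dict, seed: int | None) -> SimulationConfig:
    states, weights = _states_from_config(cfg)
    sim = dict(cfg.get("simulation", {}))
    if "burst_size_model" in sim:
        sim["burst_size_model"] = BurstSizeModel(**sim["burst_size_model"])
    allowed = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(sim) - allowed
    if unknown:
        raise sio.SchemaError(f"unknown simulation key(s): {sorted(unknown)}")
    return SimulationConfig(states=states, weights=weights, seed=seed, **sim)


def pipeline_run(cfg: dict, outdir, seed: int | None = None) -> dict:
    """Execute simulate -> burst-search -> fit -> (titrate|bva|pife).

    ``cfg`` is the run configuration mapping (see ``load_config``); ``seed``
    overrides ``cfg['seed']``.  All intermediates are persisted under
    ``outdir`` as CSV/JSON next to a provenance record; the returned dict
    mirrors the files.  Any stage failure raises with a stage-tagged message.
    """
    unknown = set(cfg) - KNOWN_KEYS
    if unknown:
        raise sio.SchemaError(f"unknown config key(s): {sorted(unknown)}")
    mode = cfg.get("mode", "populations")
    seed = seed if seed is not None else int(cfg.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sio.write_json(outdir / "provenance.json", sio.provenance(cfg, seed))

    sim_cfg = _sim_config(cfg, seed)
    bs = cfg.get("burst_search", {})
    params = bp.BurstSearchParams(
        m=int(bs.get("m", 15)), t=float(bs.get("t", 500.0)),
        l=int(bs.get("l", 25)),
        per_channel_threshold=int(bs.get("threshold", 150)),
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"[stage {name}] {exc}") from exc

    if mode == "populations":
        trace, _ = stage("simulate", simulate_timetrace, sim_cfg)
        sio.write_photons(outdir / "photons.h5", trace)
        table = stage("burst-search", bursts_from_trace, trace, sim_cfg, params)
        sio.write_bursts_csv(outdir / "bursts.csv", table)
        n_pop = int(cfg.get("n_populations", 1))
        fit = stage("fit", fit_populations, es_points(table), n_pop, seed=seed)
        payload = {"populations": [p.to_dict() for p in fit], "backend": fit.backend,
                   "n_bursts": len(table)}
        sio.write_json(outdir / "populations.json", payload)
        return payload

    if mode == "titration":
        t = cfg["titration"]
        states, _ = _states_from_config(cfg)
        if len(states) != 2:
            raise sio.SchemaError("titration mode needs exactly two states (open, closed)")
        result = stage(
            "titrate", titration_photon_pipeline,
            kd_true=float(t["kd_true"]),
            concentrations=[float(c) for c in t["concentrations"]],
            open_state=states[0], closed_state=states[1],
            seed=seed,
            n_bursts_per_point=int(t.get("n_bursts_per_point", 3000)),
            bmax_true=float(t.get("bmax_true", 1.0)),
            params=params,
            config=_sim_config(cfg, seed).replace(states=(states[0],), weights=(1.0,)),
        )
        fractions = pd.DataFrame(
            {
                "concentration": [p.concentration for p in result["points"]],
                "fraction_closed": [p.fraction_closed for p in result["points"]],
                "fraction_closed_prob": [p.fraction_closed_prob for p in result["points"]],
                "n_bursts": [p.n_bursts for p in result["points"]],
            }
        )
        fractions.to_csv(outdir / "fractions.csv", index=False)
        payload = result["binding_fit"].to_dict()
        sio.write_json(outdir / "binding_fit.json", payload)
        return payload

    if mode == "bva":
        trace, _ = stage("simulate", simulate_timetrace, sim_cfg)
        table = stage("burst-search", bursts_from_trace, trace, sim_cfg, params, mode="bva")
        res = stage("bva", bva_compare, table)
        sio.write_json(outdir / "bva.json", res.to_dict())
        return res.to_dict()

    if mode == "pife":
        p = cfg["pife"]
        shifts = stage(
            "pife", pife_construct_series,
            constructs=p["constructs"], reference=p["reference"],
            n_bursts=int(p.get("n_bursts", 10_000)), seed=seed,
        )
        shifts.to_csv(outdir / "pife_shifts.csv", index=False)
        payload = {"shifts": shifts.to_dict(orient="records")}
        if shifts["linker_delta"].nunique() > 1:
            payload["trend"] = linker_trend(shifts)
        payload["null_control"] = null_control(shifts)
        sio.write_json(outdir / "pife.json", payload)
        return payload

    raise sio.SchemaError(f"unknown pipeline mode: {mode!r}")
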
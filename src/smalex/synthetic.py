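"""Synthetic µs-ALEX photon data with known ground truth.

The generator emulates freely diffusing double-labelled molecules measured
with alternating-laser excitation: a mixture of conformational states (each
an apparent FRET efficiency E*, apparent stoichiometry S and an optional
donor-brightness PIFE factor alpha), Poisson photon statistics in the three
detection streams, and uniform background.

Per burst the forward model is

1. a state is drawn from the mixture weights;
2. a base donor-excitation brightness ``B`` (expected photons) is drawn from
   the burst-size model (default: shifted exponential, minimum 20 photons);
3. ``N_Dexc ~ Poisson(alpha * B)`` donor-excitation photons are split
   binomially into F(DA) with probability E* and F(DD) otherwise;
4. ``F(AA) ~ Poisson(B * (1 - S)/S)`` so that the expected stoichiometry of
   the state is S at alpha = 1 and follows the odds scaling
   ``S_alpha = alpha*odds / (1 + alpha*odds)`` (odds = S/(1-S)) otherwise -
   PIFE raises the donor-excitation intensity only, leaving E* unchanged;
5. background counts are added per stream in proportion to burst duration.

Timetrace mode places the same per-burst counts on a timeline: burst arrivals
are Poisson, each burst has a rectangular intensity envelope, photon
timestamps fall in the excitation window (donor or acceptor) matching their
stream, and background photons are uniform in time.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bursts import (
    DET_ACCEPTOR,
    DET_DONOR,
    PhotonStream,
    compute_es_arrays,
)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class FluorophoreState:
    """One conformational/photophysical state of a labelled molecule.

    ``e_app``/``s_app`` are the apparent (uncorrected) FRET efficiency and
    stoichiometry of the state at alpha = 1; ``pife_alpha >= 1`` multiplies
    the donor-excitation brightness (PIFE).
    """

    label: str
    e_app: float
    s_app: float
    pife_alpha: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.e_app <= 1.0:
            raise ConfigurationError("e_app must be in [0, 1]")
        if not 0.0 < self.s_app < 1.0:
            raise ConfigurationError("s_app must be in (0, 1)")
        if self.pife_alpha < 1.0:
            raise ConfigurationError("pife_alpha must be >= 1")

    @property
    def s_expected(self) -> float:
        """Expected apparent stoichiometry including the PIFE factor."""
        odds = self.pife_alpha * self.s_app / (1.0 - self.s_app)
        return odds / (1.0 + odds)


@dataclass(frozen=True)
class BurstSizeModel:
    """Distribution of the per-burst base brightness (expected Dexc photons).

    ``family="exponential"``: shifted exponential with the given minimum -
    diffusing-molecule burst sizes are heavy-tailed.  ``family="constant"``:
    every burst has the same intensity (counts are then Poisson about the
    mean), the fixed-N condition under which the shot-noise law for the
    per-burst E* spread is stated.
    """

    family: str = "exponential"
    min_photons: float = 20.0

    def __post_init__(self):
        if self.family not in ("exponential", "constant"):
            raise ConfigurationError(f"unknown burst-size family: {self.family!r}")
        if self.min_photons < 0:
            raise ConfigurationError("min_photons must be >= 0")

    def sample(self, rng: np.random.Generator, n: int, mean: float) -> np.ndarray:
        if self.family == "constant":
            return np.full(n, float(mean))
        if mean <= self.min_photons:
            raise ConfigurationError(
                "mean burst size must exceed the minimum for the exponential family"
            )
        return self.min_photons + rng.exponential(mean - self.min_photons, size=n)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic ALEX measurement.

    Units: times in µs (alternation period, burst duration), rates per
    second, photon counts per burst.  ``background_rates`` are (DD, DA, AA)
    counts/s; defaults are typical confocal background levels.  A single
    integer ``seed`` governs all randomness.
    """

    states: tuple[FluorophoreState, ...]
    weights: tuple[float, ...]
    mean_dexc_photons: float = 120.0
    mean_aexc_photons: float | None = None
    burst_size_model: BurstSizeModel = field(default_factory=BurstSizeModel)
    alternation_period: int = 50
    donor_window: tuple[float, float] = (0, 25)
    acceptor_window: tuple[float, float] = (25, 50)
    burst_rate: float = 20.0
    burst_duration: float = 1000.0
    background_rates: tuple[float, float, float] = (1000.0, 500.0, 1000.0)
    duration: float = 30.0
    seed: int | None = None

    def __post_init__(self):
        if len(self.states) == 0:
            raise ConfigurationError("at least one state required")
        if len(self.weights) != len(self.states):
            raise ConfigurationError("one mixture weight per state required")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ConfigurationError("mixture weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("mixture weights must sum to 1 (within 1e-9)")
        if self.mean_dexc_photons <= 0:
            raise ConfigurationError("mean_dexc_photons must be > 0")
        if self.mean_aexc_photons is not None and self.mean_aexc_photons < 0:
            raise ConfigurationError("mean_aexc_photons must be >= 0")
        if self.alternation_period <= 0:
            raise ConfigurationError("alternation_period must be > 0")
        if self.burst_rate < 0 or self.duration < 0 or self.burst_duration <= 0:
            raise ConfigurationError("rates and durations must be nonnegative")
        if any(r < 0 for r in self.background_rates):
            raise ConfigurationError("background rates must be nonnegative")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


#: columns of the per-burst ground-truth table
TRUTH_COLUMNS = ["state", "true_f_dd", "true_f_da", "true_f_aa", "bg_dd", "bg_da", "bg_aa"]


def _aa_intensity(config: SimulationConfig, state: FluorophoreState, base: np.ndarray):
    """Acceptor-excitation intensity coupled to the per-burst base brightness."""
    if config.mean_aexc_photons is not None:
        return base * (config.mean_aexc_photons / config.mean_dexc_photons)
    return base * (1.0 - state.s_app) / state.s_app


def _draw_counts(config: SimulationConfig, state_idx: np.ndarray, rng: np.random.Generator):
    """Per-burst true stream counts for bursts with given state indices."""
    n = state_idx.size
    base = config.burst_size_model.sample(rng, n, config.mean_dexc_photons)
    alpha = np.array([s.pife_alpha for s in config.states])[state_idx]
    e = np.array([s.e_app for s in config.states])[state_idx]
    n_dexc = rng.poisson(alpha * base)
    f_da = rng.binomial(n_dexc, e)
    f_dd = n_dexc - f_da
    lam_aa = np.empty(n)
    for k, state in enumerate(config.states):
        sel = state_idx == k
        lam_aa[sel] = _aa_intensity(config, state, base[sel])
    f_aa = rng.poisson(lam_aa)
    return f_dd, f_da, f_aa


def _draw_background(config: SimulationConfig, n: int, rng: np.random.Generator):
    dur_s = config.burst_duration * 1e-6
    return tuple(rng.poisson(rate * dur_s, size=n) for rate in config.background_rates)


def simulate_bursts(
    config: SimulationConfig,
    n_bursts: int,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Burst-level simulation: per-burst stream counts with ground truth.

    Returns ``(burst_table, ground_truth)``; the burst table carries the
    observed counts (truth + background) and apparent E*/S, the ground truth
    one row per burst with the state label and pre-background counts.
    Deterministic under a fixed ``config.seed`` (or an explicitly passed rng).
    """
    if n_bursts < 0:
        raise ValueError("n_bursts must be >= 0")
    if rng is None:
        rng = config.rng()
    state_idx = rng.choice(len(config.states), size=n_bursts, p=np.asarray(config.weights))
    f_dd, f_da, f_aa = _draw_counts(config, state_idx, rng)
    bg_dd, bg_da, bg_aa = _draw_background(config, n_bursts, rng)

    obs_dd = f_dd + bg_dd
    obs_da = f_da + bg_da
    obs_aa = f_aa + bg_aa
    e, s = compute_es_arrays(obs_dd, obs_da, obs_aa)

    start = (np.arange(n_bursts) * config.burst_duration).astype(np.int64)
    bursts = pd.DataFrame(
        {
            "start": start,
            "stop": start + int(config.burst_duration),
            "istart": -1,
            "istop": -1,
            "n_photons": obs_dd + obs_da + obs_aa,
            "f_dd": obs_dd,
            "f_da": obs_da,
            "f_aa": obs_aa,
            "e_app": e,
            "s_app": s,
        }
    )
    labels = np.array([st.label for st in config.states])
    truth = pd.DataFrame(
        {
            "state": labels[state_idx],
            "true_f_dd": f_dd,
            "true_f_da": f_da,
            "true_f_aa": f_aa,
            "bg_dd": bg_dd,
            "bg_da": bg_da,
            "bg_aa": bg_aa,
        }
    )
    return bursts, truth


def _window_times(
    rng: np.random.Generator,
    n: int,
    t0: np.ndarray,
    duration: float,
    period: int,
    window: tuple[float, float],
) -> np.ndarray:
    """Timestamps within [t0, t0+duration), folded into an excitation window."""
    t = t0 + rng.uniform(0.0, duration, size=n)
    period_base = np.floor(t / period) * period
    w0, w1 = window
    return (period_base + rng.uniform(w0, w1, size=n)).astype(np.int64)


def simulate_timetrace(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhotonStream, pd.DataFrame]:
    """Photon-level simulation of a full ALEX trace.

    Burst arrivals are Poisson(``burst_rate``) over ``duration`` seconds with
    rectangular envelopes of ``burst_duration`` µs; photon timestamps fall in
    the excitation window matching their stream; background photons are
    uniform in time.  The returned stream is sorted and unlabelled (run
    :func:`smalex.bursts.assign_excitation` to split streams); ground truth
    has one row per emitted burst including its envelope ``start``/``stop``.
    """
    if config.duration <= 0:
        raise ConfigurationError("duration must be > 0")
    if rng is None:
        rng = config.rng()

    duration_us = config.duration * 1e6
    n_bursts = rng.poisson(config.burst_rate * config.duration)
    starts = np.sort(rng.uniform(0.0, duration_us - config.burst_duration, size=n_bursts))
    state_idx = rng.choice(len(config.states), size=n_bursts, p=np.asarray(config.weights))
    f_dd, f_da, f_aa = _draw_counts(config, state_idx, rng)

    period = config.alternation_period
    ts_parts, det_parts = [], []
    for counts, window, det in (
        (f_dd, config.donor_window, DET_DONOR),
        (f_da, config.donor_window, DET_ACCEPTOR),
        (f_aa, config.acceptor_window, DET_ACCEPTOR),
    ):
        total = int(counts.sum())
        t0 = np.repeat(starts, counts)
        ts = _window_times(rng, total, t0, config.burst_duration, period, window)
        ts_parts.append(ts)
        det_parts.append(np.full(total, det, dtype=np.uint8))

    # uniform background per stream, folded into the matching window
    for rate, window, det in (
        (config.background_rates[0], config.donor_window, DET_DONOR),
        (config.background_rates[1], config.donor_window, DET_ACCEPTOR),
        (config.background_rates[2], config.acceptor_window, DET_ACCEPTOR),
    ):
        n_bg = rng.poisson(rate * config.duration)
        t0 = rng.uniform(0.0, duration_us, size=n_bg)
        period_base = np.floor(t0 / period) * period
        ts = (period_base + rng.uniform(window[0], window[1], size=n_bg)).astype(np.int64)
        ts_parts.append(ts)
        det_parts.append(np.full(n_bg, det, dtype=np.uint8))

    ts = np.concatenate(ts_parts)
    det = np.concatenate(det_parts)
    order = np.argsort(ts, kind="stable")

    labels = np.array([st.label for st in config.states]) if n_bursts else np.empty(0, dtype=str)
    truth = pd.DataFrame(
        {
            "state": labels[state_idx] if n_bursts else [],
            "true_f_dd": f_dd,
            "true_f_da": f_da,
            "true_f_aa": f_aa,
            "start": starts.astype(np.int64),
            "stop": (starts + config.burst_duration).astype(np.int64),
        }
    )
    stream = PhotonStream(
        timestamps=ts[order],
        detector=det[order],
        excitation=None,
        alternation_period=period,
    )
    return stream, truth


def closed_fraction(concentration, kd: float, bmax: float = 1.0):
    """One-site binding occupancy: bmax * L / (kd + L)."""
    conc = np.asarray(concentration, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be nonnegative")
    return bmax * conc / (kd + conc)


def simulate_titration(
    config: SimulationConfig,
    open_state: FluorophoreState,
    closed_state: FluorophoreState,
    concentrations,
    kd_true: float,
    bmax_true: float = 1.0,
    n_bursts_per_point: int = 3000,
    timetrace: bool = False,
):
    """Titration series: the closed-state weight follows one-site binding.

    At ligand concentration ``L`` the closed-state mixture weight is
    ``bmax_true * L / (kd_true + L)``.  Returns a list of
    ``(concentration, burst_table, ground_truth)`` tuples; with
    ``timetrace=True`` the burst table is replaced by a PhotonStream.
    Child random generators are spawned per concentration from
    ``config.seed`` so points are independent but reproducible.
    """
    if kd_true <= 0:
        raise ValueError("kd_true must be > 0")
    if not 0 < bmax_true <= 1:
        raise ValueError("bmax_true must be in (0, 1]")
    concentrations = np.asarray(list(concentrations), dtype=float)
    if np.any(concentrations < 0):
        raise ValueError("concentrations must be nonnegative")

    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(len(concentrations))
    out = []
    for conc, child in zip(concentrations, children):
        w_closed = float(closed_fraction(conc, kd_true, bmax_true))
        cfg = config.replace(
            states=(open_state, closed_state),
            weights=(1.0 - w_closed, w_closed),
        )
        rng = np.random.default_rng(child)
        if timetrace:
            duration = n_bursts_per_point / config.burst_rate
            cfg = cfg.replace(duration=duration)
            data, truth = simulate_timetrace(cfg, rng=rng)
        else:
            data, truth = simulate_bursts(cfg, n_bursts_per_point, rng=rng)
        truth.attrs["kd_true"] = kd_true
        truth.attrs["bmax_true"] = bmax_true
        truth.attrs["weight_closed"] = w_closed
        out.append((float(conc), data, truth))
    return out
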
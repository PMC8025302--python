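"""Photon streams, excitation-period assignment and all-photon burst search.

A µs-ALEX measurement alternates donor and acceptor excitation with a fixed
period (50 µs here).  Each detected photon carries a detector label (donor or
acceptor channel) and, after :func:`assign_excitation`, an excitation label
derived from its arrival time modulo the alternation period.  The three
photon streams used throughout are

* ``DD`` - donor excitation, donor detection,
* ``DA`` - donor excitation, acceptor detection,
* ``AA`` - acceptor excitation, acceptor detection.

Bursts (single molecules transiting the confocal volume) are located with the
all-photon burst search: photon *i* is "high rate" when the time spanned by
photons ``i .. i+M-1`` (forward window over all photons, regardless of
stream) is at most *T*; maximal runs of consecutive high-rate photons,
extended by the M-1 look-ahead photons of the last marked index, form
candidate bursts, and candidates with at least *L* photons are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# detector / excitation label codes
DET_DONOR = 0
DET_ACCEPTOR = 1
EXC_DONOR = 0
EXC_ACCEPTOR = 1

#: columns of a burst table (one row per burst)
BURST_COLUMNS = [
    "start", "stop", "istart", "istop", "n_photons",
    "f_dd", "f_da", "f_aa", "e_app", "s_app",
]


class BurstSearchError(ValueError):
    """Raised for invalid burst-search input (unsorted stream, bad params)."""


def compute_es_arrays(f_dd, f_da, f_aa):
    """Apparent FRET efficiency and stoichiometry from raw stream counts.

    E* = F(DA) / (F(DD) + F(DA)) and S = (F(DD)+F(DA)) / (F(DD)+F(DA)+F(AA)),
    computed without any correction factors.  Entries with a zero denominator
    are returned as NaN; callers flag/exclude them rather than propagating.
    """
    f_dd = np.asarray(f_dd, dtype=float)
    f_da = np.asarray(f_da, dtype=float)
    f_aa = np.asarray(f_aa, dtype=float)
    n_dexc = f_dd + f_da
    n_tot = n_dexc + f_aa
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(n_dexc > 0, f_da / n_dexc, np.nan)
        s = np.where(n_tot > 0, n_dexc / n_tot, np.nan)
    return e, s


@dataclass
class PhotonStream:
    """Timestamped photons with detector and (optional) excitation labels.

    Timestamps are integer clock ticks (µs in this package), sorted
    nondecreasing.  ``excitation`` is ``None`` until
    :func:`assign_excitation` has been applied.
    """

    timestamps: np.ndarray
    detector: np.ndarray
    excitation: np.ndarray | None = None
    alternation_period: int = 50
    n_dropped: int = field(default=0, repr=False)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.detector = np.asarray(self.detector, dtype=np.uint8)
        if self.excitation is not None:
            self.excitation = np.asarray(self.excitation, dtype=np.uint8)
        if self.timestamps.shape != self.detector.shape:
            raise ValueError("timestamps and detector must have equal length")
        if self.timestamps.size and np.any(np.diff(self.timestamps) < 0):
            raise BurstSearchError("photon timestamps must be sorted nondecreasing")

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def stream_masks(self) -> dict[str, np.ndarray]:
        """Boolean masks for the DD / DA / AA streams (requires excitation)."""
        if self.excitation is None:
            raise ValueError("excitation labels not assigned; run assign_excitation")
        d_exc = self.excitation == EXC_DONOR
        a_exc = self.excitation == EXC_ACCEPTOR
        return {
            "DD": d_exc & (self.detector == DET_DONOR),
            "DA": d_exc & (self.detector == DET_ACCEPTOR),
            "AA": a_exc & (self.detector == DET_ACCEPTOR),
        }


@dataclass(frozen=True)
class BurstSearchParams:
    """All-photon burst-search and selection parameters.

    Defaults follow the analysis settings used for the tandem-SBD data:
    M = 15 neighbours within T = 500 µs, minimum burst size L = 25, and an
    intensity selection of 150 photons per excitation channel.
    """

    m: int = 15
    t: float = 500.0
    l: int = 25
    per_channel_threshold: int = 150

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.t <= 0:
            raise ValueError("t must be > 0")
        if self.l < 1:
            raise ValueError("l must be >= 1")
        if self.per_channel_threshold < 0:
            raise ValueError("per_channel_threshold must be >= 0")


def assign_excitation(
    timestamps,
    detector,
    alternation_period: int = 50,
    donor_window: tuple[float, float] = (0, 25),
    acceptor_window: tuple[float, float] = (25, 50),
) -> PhotonStream:
    """Label photons by the excitation window containing ``t mod period``.

    Windows are half-open ``[start, stop)`` sub-intervals of one alternation
    period and must not overlap.  Photons outside both windows are dropped
    and counted in ``PhotonStream.n_dropped``.  Donor-detected photons in the
    acceptor-excitation window (the AD stream) are discarded by convention.
    """
    if alternation_period <= 0:
        raise ValueError("alternation_period must be > 0")
    d0, d1 = donor_window
    a0, a1 = acceptor_window
    for w0, w1 in ((d0, d1), (a0, a1)):
        if not (0 <= w0 < w1 <= alternation_period):
            raise ValueError("windows must be sub-intervals of [0, period]")
    if max(d0, a0) < min(d1, a1):
        raise ValueError("donor and acceptor excitation windows overlap")

    timestamps = np.asarray(timestamps, dtype=np.int64)
    detector = np.asarray(detector, dtype=np.uint8)
    if timestamps.size and np.any(np.diff(timestamps) < 0):
        raise BurstSearchError("photon timestamps must be sorted nondecreasing")

    phase = timestamps % int(alternation_period)
    in_donor = (phase >= d0) & (phase < d1)
    in_acceptor = (phase >= a0) & (phase < a1)
    # AD photons (donor detection during acceptor excitation) are discarded
    ad = in_acceptor & (detector == DET_DONOR)
    keep = (in_donor | in_acceptor) & ~ad
    n_dropped = int(timestamps.size - keep.sum())

    excitation = np.where(in_donor[keep], EXC_DONOR, EXC_ACCEPTOR).astype(np.uint8)
    return PhotonStream(
        timestamps=timestamps[keep],
        detector=detector[keep],
        excitation=excitation,
        alternation_period=int(alternation_period),
        n_dropped=n_dropped,
    )


def _burst_counts(stream: PhotonStream, istart: np.ndarray, istop: np.ndarray):
    """Per-stream photon counts for index ranges [istart, istop] (inclusive)."""
    masks = stream.stream_masks
    out = {}
    for name, mask in masks.items():
        csum = np.concatenate(([0], np.cumsum(mask)))
        out[name] = csum[istop + 1] - csum[istart]
    return out["DD"], out["DA"], out["AA"]


def all_photon_burst_search(
    stream: PhotonStream, params: BurstSearchParams | None = None
) -> pd.DataFrame:
    """All-photon burst search (M photons within T µs, burst size >= L).

    Returns a burst table (:data:`BURST_COLUMNS`), one row per burst with
    per-stream counts and apparent E*/S.  Candidate ranges that overlap after
    the M-1 look-ahead extension are merged, so output bursts are disjoint
    and ordered.
    """
    if params is None:
        params = BurstSearchParams()
    t = stream.timestamps
    n = t.size
    empty = pd.DataFrame(columns=BURST_COLUMNS)
    if n < max(params.m, params.l):
        return empty

    m = params.m
    # photon i is high-rate iff t[i+m-1] - t[i] <= T
    span = t[m - 1:] - t[: n - m + 1]
    marked = span <= params.t
    idx = np.flatnonzero(marked)
    if idx.size == 0:
        return empty

    # maximal runs of consecutive marked photons
    brk = np.flatnonzero(np.diff(idx) > 1)
    run_start = idx[np.concatenate(([0], brk + 1))]
    run_stop = idx[np.concatenate((brk, [idx.size - 1]))]
    istart = run_start
    istop = run_stop + m - 1  # include look-ahead photons of last marked index

    # merge candidate ranges that share photons (overlap after extension)
    merged_start = [int(istart[0])]
    merged_stop = [int(istop[0])]
    for a, b in zip(istart[1:], istop[1:]):
        if a <= merged_stop[-1]:
            merged_stop[-1] = max(merged_stop[-1], int(b))
        else:
            merged_start.append(int(a))
            merged_stop.append(int(b))
    istart = np.asarray(merged_start, dtype=np.int64)
    istop = np.asarray(merged_stop, dtype=np.int64)

    n_photons = istop - istart + 1
    big = n_photons >= params.l
    istart, istop, n_photons = istart[big], istop[big], n_photons[big]
    if istart.size == 0:
        return empty

    f_dd, f_da, f_aa = _burst_counts(stream, istart, istop)
    e, s = compute_es_arrays(f_dd, f_da, f_aa)
    return pd.DataFrame(
        {
            "start": t[istart],
            "stop": t[istop],
            "istart": istart,
            "istop": istop,
            "n_photons": n_photons,
            "f_dd": f_dd,
            "f_da": f_da,
            "f_aa": f_aa,
            "e_app": e,
            "s_app": s,
        }
    )


def apply_burst_thresholds(
    bursts: pd.DataFrame,
    params: BurstSearchParams | None = None,
    mode: str = "analysis",
    channel_rule: str | None = None,
    bva_threshold: int = 250,
    bva_s_range: tuple[float, float] = (0.3, 0.6),
) -> pd.DataFrame:
    """Intensity (and, for BVA, stoichiometry) selection of bursts.

    mode ``"analysis"``: keep bursts whose donor-excitation sum F(DD)+F(DA)
    and acceptor-excitation count F(AA) each exceed the threshold (150 by
    default) - the double-labelled-molecule reading of "all channels greater
    than 150 photons".  mode ``"bva"``: keep bursts with more than 250
    photons in total and S within [0.3, 0.6].

    ``channel_rule`` overrides the count rule: ``"sum_pairs"`` (excitation
    sums, the analysis default), ``"per_stream"`` (every stream above the
    threshold) or ``"total"`` (total photon count, the BVA default).
    """
    if params is None:
        params = BurstSearchParams()
    if mode not in ("analysis", "bva"):
        raise ValueError(f"unknown mode: {mode!r}")

    f_dd = bursts["f_dd"].to_numpy(dtype=float)
    f_da = bursts["f_da"].to_numpy(dtype=float)
    f_aa = bursts["f_aa"].to_numpy(dtype=float)
    dexc = f_dd + f_da
    total = dexc + f_aa

    if mode == "analysis":
        thr = params.per_channel_threshold
        rule = channel_rule or "sum_pairs"
    else:
        thr = bva_threshold
        rule = channel_rule or "total"

    if rule == "sum_pairs":
        keep = (dexc > thr) & (f_aa > thr)
    elif rule == "per_stream":
        keep = (f_dd > thr) & (f_da > thr) & (f_aa > thr)
    elif rule == "total":
        keep = total > thr
    else:
        raise ValueError(f"unknown channel_rule: {rule!r}")

    if mode == "bva":
        s = bursts["s_app"].to_numpy(dtype=float)
        lo, hi = bva_s_range
        keep &= (s >= lo) & (s <= hi)

    return bursts.loc[keep].reset_index(drop=True)


def select_stoichiometry(bursts: pd.DataFrame, s_min: float, s_max: float) -> pd.DataFrame:
    """Closed-interval stoichiometry selection ``s_min <= S <= s_max``."""
    if s_min > s_max:
        raise ValueError("s_min must not exceed s_max")
    s = bursts["s_app"].to_numpy(dtype=float)
    keep = (s >= s_min) & (s <= s_max)
    return bursts.loc[keep].reset_index(drop=True)
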
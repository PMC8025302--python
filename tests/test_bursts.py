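"""Excitation assignment and all-photon burst search vs brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from smalex import (
    BurstSearchParams,
    PhotonStream,
    all_photon_burst_search,
    apply_burst_thresholds,
    assign_excitation,
    select_stoichiometry,
    simulate_timetrace,
)
from smalex.bursts import EXC_ACCEPTOR, EXC_DONOR, BurstSearchError
from smalex.pipeline import bursts_from_trace

from conftest import make_config


# ------------------------------------------------------------ excitation

def test_excitation_assignment_modular_arithmetic():
    ts = np.array([10, 60, 75], dtype=np.int64)   # phases 10, 10, 25
    det = np.array([1, 1, 1], dtype=np.uint8)
    stream = assign_excitation(ts, det, 50)
    assert list(stream.excitation) == [EXC_DONOR, EXC_DONOR, EXC_ACCEPTOR]


def test_boundary_photon_goes_to_acceptor_window():
    # half-open windows: phase 25 belongs to the acceptor period [25, 50)
    stream = assign_excitation([25], [1], 50)
    assert stream.excitation[0] == EXC_ACCEPTOR


def test_ad_photons_discarded_and_counted():
    # donor-channel photon in the acceptor window is dropped by convention
    stream = assign_excitation([10, 30], [0, 0], 50)
    assert len(stream) == 1
    assert stream.n_dropped == 1


def test_overlapping_windows_rejected():
    with pytest.raises(ValueError):
        assign_excitation([1], [0], 50, donor_window=(0, 30), acceptor_window=(25, 50))


def test_unsorted_stream_rejected():
    with pytest.raises(BurstSearchError):
        assign_excitation([5, 1], [0, 0], 50)


def test_stream_counts_match_generator_tallies():
    cfg = make_config(seed=31, duration=2.0)
    trace, truth = simulate_timetrace(cfg)
    stream = assign_excitation(trace.timestamps, trace.detector, 50)
    masks = stream.stream_masks
    assert masks["DD"].sum() == truth.true_f_dd.sum()
    assert masks["DA"].sum() == truth.true_f_da.sum()
    assert masks["AA"].sum() == truth.true_f_aa.sum()
    assert stream.n_dropped == 0


# ------------------------------------------------------------ burst search

def _stream(ts):
    ts = np.asarray(ts, dtype=np.int64)
    det = np.zeros(ts.size, dtype=np.uint8)
    return PhotonStream(ts, det, excitation=det.copy(), alternation_period=50)


def test_crafted_burst_found_exactly_once():
    # 30 photons at 10 µs spacing flanked by 10 ms gaps: one burst of 30
    burst = 100_000 + 10 * np.arange(30)
    ts = np.concatenate(([0], burst, [10_000_000]))
    out = all_photon_burst_search(_stream(ts), BurstSearchParams())
    assert len(out) == 1
    assert out.n_photons.iloc[0] == 30
    assert out.start.iloc[0] == 100_000 and out.stop.iloc[0] == 100_290


def test_cluster_below_l_is_rejected():
    ts = np.sort(np.random.default_rng(0).integers(0, 100, 24))
    out = all_photon_burst_search(_stream(ts), BurstSearchParams())
    assert len(out) == 0


def test_background_only_produces_no_bursts():
    # 1 kHz Poisson background over 10 s never satisfies M=15 in T=500 µs
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        ts = np.sort(rng.uniform(0, 10e6, size=10_000)).astype(np.int64)
        out = all_photon_burst_search(_stream(ts), BurstSearchParams())
        assert len(out) == 0


def _brute_force_bursts(ts, m, t, l):
    """Independent re-implementation: explicit loops over the definition."""
    n = len(ts)
    marked = [ts[i + m - 1] - ts[i] <= t for i in range(n - m + 1)]
    ranges = []
    i = 0
    while i < len(marked):
        if marked[i]:
            j = i
            while j + 1 < len(marked) and marked[j + 1]:
                j += 1
            ranges.append([i, j + m - 1])
            i = j + 1
        else:
            i += 1
    merged = []
    for a, b in ranges:
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(a, b) for a, b in merged if b - a + 1 >= l]


@pytest.mark.parametrize("seed", range(8))
def test_burst_search_matches_brute_force_enumeration(seed):
    rng = np.random.default_rng(seed)
    # mixture of sparse background and dense clumps, <= 1000 photons
    parts = [np.sort(rng.uniform(0, 5e5, size=300))]
    for _ in range(rng.integers(1, 5)):
        t0 = rng.uniform(0, 5e5)
        parts.append(t0 + np.sort(rng.exponential(8.0, size=rng.integers(10, 120))).cumsum())
    ts = np.sort(np.concatenate(parts)).astype(np.int64)
    params = BurstSearchParams(m=10, t=300.0, l=20)
    got = all_photon_burst_search(_stream(ts), params)
    expected = _brute_force_bursts(ts, 10, 300.0, 20)
    assert list(zip(got.istart, got.istop)) == expected


def test_burst_search_translation_invariant():
    rng = np.random.default_rng(5)
    ts = np.sort(rng.integers(0, 200_000, size=600)).astype(np.int64)
    a = all_photon_burst_search(_stream(ts))
    b = all_photon_burst_search(_stream(ts + 777_000))
    assert list(a.istart) == list(b.istart) and list(a.istop) == list(b.istop)
    np.testing.assert_array_equal(b.start.to_numpy() - a.start.to_numpy(),
                                  777_000 * np.ones(len(a), dtype=np.int64))


def test_bursts_disjoint_ordered_and_satisfy_l():
    cfg = make_config(seed=41, duration=4.0, mean_dexc_photons=200.0,
                      background_rates=(1000.0, 500.0, 1000.0))
    trace, _ = simulate_timetrace(cfg)
    stream = assign_excitation(trace.timestamps, trace.detector, 50)
    out = all_photon_burst_search(stream)
    assert (out.n_photons >= 25).all()
    assert (out.istart.to_numpy()[1:] > out.istop.to_numpy()[:-1]).all()


def test_recall_of_bright_ground_truth_bursts():
    # >= 90% of generated bursts above the L threshold are recovered
    cfg = make_config(seed=43, duration=5.0, mean_dexc_photons=200.0)
    trace, truth = simulate_timetrace(cfg)
    stream = assign_excitation(trace.timestamps, trace.detector, 50)
    out = all_photon_burst_search(stream)
    bright = truth[(truth.true_f_dd + truth.true_f_da + truth.true_f_aa) >= 25]
    hits = 0
    for _, b in bright.iterrows():
        overlap = (out.start <= b.stop) & (out.stop >= b.start)
        hits += int(overlap.any())
    assert hits / len(bright) >= 0.90
    # and each recovered burst contains >= 95% of its true photons on average
    containment = []
    for _, b in bright.iterrows():
        sel = out[(out.start <= b.stop) & (out.stop >= b.start)]
        if len(sel):
            n_true = b.true_f_dd + b.true_f_da + b.true_f_aa
            containment.append(min(sel.n_photons.sum() / n_true, 1.0))
    assert np.mean(containment) >= 0.95


# ------------------------------------------------------------ selections

def _table(rows):
    df = pd.DataFrame(rows, columns=["f_dd", "f_da", "f_aa"])
    from smalex.bursts import compute_es_arrays
    df["e_app"], df["s_app"] = compute_es_arrays(df.f_dd, df.f_da, df.f_aa)
    return df


def test_analysis_threshold_rule():
    table = _table([(100, 80, 160),   # kept: 180 > 150 and 160 > 150
                    (200, 10, 100),   # rejected: f_aa <= 150
                    (10, 20, 400)])   # rejected: donor-excitation sum <= 150
    kept = apply_burst_thresholds(table, mode="analysis")
    assert len(kept) == 1
    assert kept.f_dd.iloc[0] == 100


def test_threshold_rules_match_brute_force_refilter():
    rng = np.random.default_rng(9)
    table = _table(rng.integers(0, 400, size=(300, 3)))
    thr = 150
    kept = apply_burst_thresholds(table, mode="analysis")
    brute = [i for i in range(len(table))
             if table.f_dd[i] + table.f_da[i] > thr and table.f_aa[i] > thr]
    assert list(kept.f_dd) == list(table.f_dd[brute])

    per = apply_burst_thresholds(table, mode="analysis", channel_rule="per_stream")
    brute_per = table[(table.f_dd > thr) & (table.f_da > thr) & (table.f_aa > thr)]
    assert len(per) == len(brute_per)


def test_bva_mode_uses_total_and_s_window():
    table = _table([(150, 50, 100),    # total 300, S 0.667 -> S cut
                    (100, 20, 160),    # total 280, S 0.429 -> kept
                    (60, 20, 100)])    # total 180 -> count cut
    kept = apply_burst_thresholds(table, mode="bva")
    assert len(kept) == 1 and kept.f_aa.iloc[0] == 160
    with pytest.raises(ValueError):
        apply_burst_thresholds(table, mode="nonsense")


def test_stoichiometry_selection_closed_interval():
    table = _table([(25, 25, 150), (50, 20, 80), (90, 10, 20)])
    # S values: 0.25, 0.467, 0.833
    kept = select_stoichiometry(table, 0.25, 0.6)
    assert len(kept) == 2 and kept.s_app.min() == pytest.approx(0.25)
    rng = np.random.default_rng(2)
    table = _table(rng.integers(0, 300, size=(200, 3)))
    kept = select_stoichiometry(table, 0.3, 0.6)
    brute = table[(table.s_app >= 0.3) & (table.s_app <= 0.6)]
    assert list(kept.s_app) == list(brute.s_app)
    with pytest.raises(ValueError):
        select_stoichiometry(table, 0.7, 0.3)


def test_pipeline_wrapper_runs_search_and_selection():
    cfg = make_config(seed=47, duration=3.0, mean_dexc_photons=200.0)
    trace, _ = simulate_timetrace(cfg)
    table = bursts_from_trace(trace, cfg)
    assert len(table) > 10
    assert ((table.f_dd + table.f_da) > 150).all() and (table.f_aa > 150).all()
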
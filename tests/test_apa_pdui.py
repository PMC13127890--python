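"""PDUI estimation: exact two-segment recovery, noise robustness, pooling."""

import numpy as np
import pytest

from paralogshare.apa_pdui import (
    estimate_pdui,
    estimate_pdui_multisample,
    estimates_to_frame,
    summarize_pdui,
    _fit_at_breakpoint,
)
from paralogshare.io_formats import CoverageTrack
from paralogshare.synthetic_data import SimulationConfig, simulate_dataset


def oracle_grid_fit(depth, min_segment=50):
    """Independent brute-force fit: loop every breakpoint, refit, track RSS."""
    best = None
    for b in range(min_segment, len(depth) - min_segment + 1):
        m1, m2 = depth[:b].mean(), depth[b:].mean()
        if m2 > m1:
            w = depth.mean()
            rss = ((depth - w) ** 2).sum()
            w_short, w_long = 0.0, w
        else:
            rss = ((depth[:b] - m1) ** 2).sum() + ((depth[b:] - m2) ** 2).sum()
            w_short, w_long = m1 - m2, m2
        if best is None or rss < best[0] - 1e-9:
            best = (rss, b, w_short, w_long)
    return best


def test_flat_track_full_distal_usage():
    track = CoverageTrack("G", "s", np.full(694, 50.0))
    est = estimate_pdui(track)
    assert est.qc_flag == "ok"
    assert est.pdui == 1.0
    assert est.w_short == 0.0


def test_exact_step_track(step_track):
    est = estimate_pdui(step_track)
    assert est.breakpoint == 300
    assert est.w_long == pytest.approx(40.0)
    assert est.w_short == pytest.approx(60.0)
    assert est.pdui == pytest.approx(0.4)


def test_oracle_equivalence_on_noisy_tracks():
    rng = np.random.default_rng(5)
    for _ in range(20):
        true = np.full(400, 80.0)
        true[rng.integers(60, 340):] *= rng.uniform(0.2, 0.9)
        depth = rng.poisson(true).astype(float)
        est = estimate_pdui(CoverageTrack("G", "s", depth))
        rss, b, w_short, w_long = oracle_grid_fit(depth)
        assert est.breakpoint == b
        assert est.pdui == pytest.approx(w_long / (w_long + w_short), abs=1e-12)


def test_scale_invariance(step_track):
    est1 = estimate_pdui(step_track)
    scaled = CoverageTrack("G", "s", step_track.depth * 7.5)
    est2 = estimate_pdui(scaled)
    assert est2.pdui == pytest.approx(est1.pdui, abs=1e-12)
    assert est2.breakpoint == est1.breakpoint


def test_monotonic_in_downstream_depth():
    # noiseless steps: raising depth after the breakpoint never lowers PDUI
    before = 100.0
    last = -1.0
    for after in [10, 30, 50, 70, 90, 100, 120]:
        depth = np.full(600, float(after))
        depth[:250] = before
        est = estimate_pdui(CoverageTrack("G", "s", depth))
        assert est.pdui >= last
        last = est.pdui


def test_low_coverage_and_all_zero_missing():
    est = estimate_pdui(CoverageTrack("G", "s", np.full(400, 2.0)),
                        min_coverage=10.0)
    assert est.pdui is None and est.qc_flag == "low_coverage"
    est0 = estimate_pdui(CoverageTrack("G", "s", np.zeros(400)))
    assert est0.pdui is None and est0.qc_flag == "low_coverage"


def test_track_too_short_rejected():
    with pytest.raises(ValueError):
        estimate_pdui(CoverageTrack("G", "s", np.full(60, 50.0)), min_segment=50)


def test_multisample_identical_tracks_match_single(step_track):
    single = estimate_pdui(step_track)
    ests = estimate_pdui_multisample([step_track, step_track])
    for e in ests:
        assert e.breakpoint == single.breakpoint
        assert e.pdui == pytest.approx(single.pdui, abs=1e-12)


def test_multisample_shared_breakpoint_two_pduis():
    # two noiseless tracks sharing a breakpoint at 300 with PDUI 0.2 and 0.8
    d1 = np.full(694, 20.0); d1[:300] = 100.0
    d2 = np.full(694, 80.0); d2[:300] = 100.0
    ests = estimate_pdui_multisample([
        CoverageTrack("G", "a", d1), CoverageTrack("G", "b", d2)])
    assert [e.breakpoint for e in ests] == [300, 300]
    assert ests[0].pdui == pytest.approx(0.2, abs=1e-12)
    assert ests[1].pdui == pytest.approx(0.8, abs=1e-12)


def test_multisample_flat_plus_step_uses_step_breakpoint(step_track):
    flat = CoverageTrack("CALM2", "flat", np.full(694, 70.0))
    ests = estimate_pdui_multisample([flat, step_track])
    by_sample = {e.sample_id: e for e in ests}
    assert by_sample["S0"].breakpoint == 300
    assert by_sample["flat"].pdui == pytest.approx(1.0)


def test_multisample_all_low_coverage_missing():
    tracks = [CoverageTrack("G", f"s{i}", np.full(300, 1.0)) for i in range(3)]
    ests = estimate_pdui_multisample(tracks)
    assert all(e.pdui is None and e.qc_flag == "low_coverage" for e in ests)


def test_synthetic_recovery_single_tracks():
    """Per-track recovery against generator truth under Poisson noise."""
    cfg = SimulationConfig(n_samples=25, depth=300.0,
                           size_factors=np.ones(25), seed=21)
    ds = simulate_dataset(cfg)
    errors = []
    truth = ds.truth.pdui
    for t in ds.coverage:
        est = estimate_pdui(t)
        if est.pdui is not None:
            errors.append(abs(est.pdui - truth.at[t.sample_id, t.gene_id]))
    assert len(errors) >= 70
    assert np.mean(errors) < 0.05


def test_summarize_pdui_median_and_range(step_track):
    ests = []
    for sid, p in [("a", 0.2), ("b", 0.4), ("c", 0.6)]:
        d = np.full(694, 100.0 * p); d[:300] = 100.0
        ests.append(estimate_pdui(CoverageTrack("G", sid, d)))
    summary = summarize_pdui(ests)
    row = summary.iloc[0]
    assert row["median"] == pytest.approx(0.4, abs=1e-12)
    assert (row["min"], row["max"]) == (pytest.approx(0.2), pytest.approx(0.6))
    single = summarize_pdui([ests[2]])
    assert single.iloc[0]["median"] == single.iloc[0]["min"] == single.iloc[0]["max"]


def test_summarize_all_missing_gives_empty_row():
    est = estimate_pdui(CoverageTrack("G", "s", np.zeros(400)))
    summary = summarize_pdui([est])
    assert summary.iloc[0]["n"] == 0 and np.isnan(summary.iloc[0]["median"])
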
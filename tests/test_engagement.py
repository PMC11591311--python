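"""Baseline integration, window construction, and physical engagement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sociorhythm import engagement as eng
from sociorhythm.interactions import InteractionEpisode
from sociorhythm.rhythm import RhythmStore


def ep(pair, minutes, episode_id=-1):
    return InteractionEpisode(pair=tuple(sorted(pair)),
                              minutes=tuple(sorted(minutes)),
                              episode_id=episode_id)


def oracle_integrate(episodes, extension=10, span=30):
    """Brute-force repeated full rescan until no baseline holds the partner."""
    by_pair = {}
    for e in episodes:
        by_pair.setdefault(e.pair, []).append(set(e.minutes))
    result = []
    for pair, sets in by_pair.items():
        sets = [set(s) for s in sets]
        while True:
            sets.sort(key=min)
            merged = False
            for b_idx in range(len(sets)):
                start = min(sets[b_idx])
                lo, hi = start - extension - span, start - extension
                for a_idx in range(len(sets)):
                    if a_idx == b_idx:
                        continue
                    if min(sets[a_idx]) >= start:
                        continue
                    if any(lo <= m < hi for m in sets[a_idx]):
                        sets[a_idx] |= sets[b_idx]
                        del sets[b_idx]
                        merged = True
                        break
                if merged:
                    break
            if not merged:
                break
        result.extend((pair, tuple(sorted(s))) for s in sets)
    return sorted(result, key=lambda x: (x[1][0], x[0]))


def store_with(br_by_person, n_minutes=2000):
    store = RhythmStore(sorted(br_by_person), n_minutes)
    for pid, values in br_by_person.items():
        store.values[store.index[pid], :] = values
    return store


class TestIntegrateBaselinePartner:
    def test_merges_episode_in_baseline(self):
        eps = [ep((1, 2), range(500, 506)), ep((1, 2), range(520, 526))]
        out = eng.integrate_baseline_partner(eps)
        assert len(out) == 1
        assert out[0].minutes == tuple(list(range(500, 506)) + list(range(520, 526)))

    def test_distant_episodes_untouched(self):
        eps = [ep((1, 2), range(500, 506)), ep((1, 2), range(680, 686))]
        out = eng.integrate_baseline_partner(eps)
        assert len(out) == 2

    def test_transitive_chain_reaches_fixpoint(self):
        # middle episode is not in the last baseline but chains via the first
        eps = [ep((1, 2), range(570, 576)), ep((1, 2), range(592, 596)),
               ep((1, 2), range(600, 611))]
        out = eng.integrate_baseline_partner(eps)
        assert len(out) == 1

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.lists(st.tuples(st.integers(100, 400), st.integers(1, 8)),
                    min_size=1, max_size=8))
    def test_matches_brute_force_oracle(self, raw):
        # build disjoint same-pair episodes from (start, length) seeds
        eps, cursor = [], 0
        for start, length in sorted(raw):
            s = max(start, cursor)
            eps.append(ep((1, 2), range(s, s + length)))
            cursor = s + length + 6
        out = eng.integrate_baseline_partner(eps)
        got = sorted(((e.pair, e.minutes) for e in out),
                     key=lambda x: (x[1][0], x[0]))
        assert got == oracle_integrate(eps)


class TestBuildWindows:
    def test_default_windows(self):
        tk, that = eng.build_windows(ep((1, 2), range(100, 111)))
        assert set(tk) == set(range(90, 121))
        assert list(that) == list(range(60, 90))

    def test_zero_extension_matches_unshifted_reading(self):
        _, that = eng.build_windows(ep((1, 2), range(100, 111)), extension=0)
        assert list(that) == list(range(70, 100))

    def test_gap_minutes_not_backfilled(self):
        tk, _ = eng.build_windows(ep((1, 2), [100, 101, 105]), extension=0)
        assert list(tk) == [100, 101, 105]

    def test_fill_gaps_option(self):
        tk, _ = eng.build_windows(ep((1, 2), [100, 101, 105]), extension=0,
                                  fill_gaps=True)
        assert list(tk) == list(range(100, 106))

    def test_clipped_at_day_start(self):
        tk, that = eng.build_windows(ep((1, 2), range(20, 26)))
        assert list(that) == list(range(0, 10))  # [-20, 10) clipped to the day
        assert tk.min() == 10

    def test_baseline_clipped_to_available_preminutes(self):
        # wear (BR presence) starting at minute 80 leaves <= 10 baseline minutes
        br = np.full(2000, np.nan)
        br[80:200] = 1.0
        store = store_with({1: br, 2: br})
        episode = ep((1, 2), range(100, 111), episode_id=0)
        rec = eng.compute_engagement(store, [episode])
        assert (rec["n_baseline_minutes_used"] == [10, 10]).all()


class TestPhysicalEngagement:
    def test_printed_means_difference(self):
        br = np.full(300, 1.10)
        br[100:121] = 1.36
        tk, that = np.arange(100, 121), np.arange(60, 90)
        pe, m_tk, m_that, *_ = eng.physical_engagement(br, tk, that)
        assert pe == pytest.approx(0.26)
        assert (m_tk, m_that) == (pytest.approx(1.36), pytest.approx(1.10))

    def test_constant_br_gives_zero(self):
        br = np.full(300, 2.0)
        pe, *_ = eng.physical_engagement(br, np.arange(100, 121),
                                         np.arange(60, 90))
        assert pe == 0.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.floats(-5, 5), st.floats(0.1, 10), st.integers(0, 2 ** 16))
    def test_shift_invariance_and_scale_covariance(self, c, a, seed):
        rng = np.random.default_rng(seed)
        br = rng.normal(1.2, 0.5, 300)
        tk, that = np.arange(100, 121), np.arange(60, 90)
        pe0, *_ = eng.physical_engagement(br, tk, that)
        pe_shift, *_ = eng.physical_engagement(br + c, tk, that)
        pe_scale, *_ = eng.physical_engagement(br * a, tk, that)
        assert abs(pe_shift - pe0) < 1e-9
        assert pe_scale == pytest.approx(a * pe0, rel=1e-9, abs=1e-12)

    def test_insufficient_minutes_omitted(self):
        br = np.full(300, np.nan)
        br[100:121] = 1.0
        br[85:88] = 1.0  # only 3 baseline minutes < default 5
        out = eng.physical_engagement(br, np.arange(100, 121), np.arange(60, 90))
        assert out is None


def test_mean_pe_recovers_planted_delta():
    """With rises confined to episode minutes (margin 0, extension 0) and
    contamination-free baselines, mean PE estimates the planted delta."""
    import sociorhythm as sr
    from dataclasses import replace
    cfg = sr.RunConfig(
        sim=sr.SimConfig(n_employees=300, n_orgs=3, n_days=6,
                         contact_rate_regular=1.0, contact_rate_hub=1.0,
                         br_rise_margin=0, rng_seed=21),
        extension=0)
    manifest, art = sr.run(cfg)
    rec = art["records"]
    clean = rec[rec["n_baseline_other_partner_records"] == 0]
    assert len(clean) > 1000
    se = clean["pe_hz"].std() / np.sqrt(len(clean))
    assert abs(clean["pe_hz"].mean() - 0.26) < 2 * se + 0.01


def test_contamination_report(small_run):
    _, art = small_run
    rep = eng.baseline_contamination_report(art["records"])
    assert np.isfinite(rep["mean"]) and np.isfinite(rep["median"])
    assert rep["mean"] > 0  # dense hub schedules overlap baselines


def test_contamination_zero_when_no_overlap():
    rec = pd.DataFrame({"n_baseline_other_partner_records": [0, 0, 0]})
    rep = eng.baseline_contamination_report(rec)
    assert rep == {"mean": 0.0, "median": 0.0}


def test_span_sweep_consistency_and_planted_sign(coupled_run):
    _, art = coupled_run
    from sociorhythm import stats
    ds = art["ds"]
    sweep = eng.baseline_span_sweep(art["store"], art["episodes"], ds,
                                    spans=(10, 30, 60))
    key = sweep[sweep["correlation"] == "self_pe__partner_ds"]
    # planted negative coupling shows up at every span
    assert (key["r"] < 0).all()
    # span 30 reproduces the default pipeline exactly
    from sociorhythm import features
    emp = art["employee_features"]
    default_r = stats.four_correlations(emp)["self_pe__partner_ds"].r
    r30 = key[key["span"] == 30]["r"].iloc[0]
    assert r30 == pytest.approx(default_r, abs=1e-12)
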
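"""Synthetic badge-data generator: planted structure and determinism."""

import numpy as np
import pandas as pd
import pytest

from sociorhythm import interactions as ia
from sociorhythm import stats
from sociorhythm import synthdata as sd


def cfg(**kw):
    base = dict(n_employees=40, n_orgs=2, n_days=2, rng_seed=3)
    base.update(kw)
    return sd.SimConfig(**base)


class TestConfig:
    @pytest.mark.parametrize("field, value", [
        ("n_employees", 0), ("hub_fraction", 1.5), ("dropout_prob", -0.1),
        ("br_baseline_sd", -1.0), ("episode_length_mean", 0.5),
        ("br_ar1_phi", 1.0),
    ])
    def test_invalid_field_named_in_error(self, field, value):
        with pytest.raises(sd.ConfigError, match=field):
            cfg(**{field: value})

    def test_org_sizes_must_be_at_least_two(self):
        with pytest.raises(sd.ConfigError):
            cfg(n_employees=10, n_orgs=8)


class TestPopulation:
    def test_even_split(self):
        pop = sd.generate_population(sd.SimConfig(n_employees=10, n_orgs=2,
                                                  rng_seed=1))
        sizes = pd.Series([p.org_id for p in pop]).value_counts()
        assert sorted(sizes) == [5, 5]

    def test_deterministic(self):
        a = sd.generate_population(cfg())
        b = sd.generate_population(cfg())
        assert a == b

    def test_study_scale(self):
        pop = sd.generate_population(sd.SimConfig(n_employees=449, n_orgs=10,
                                                  rng_seed=1))
        assert len(pop) == 449
        assert len({p.org_id for p in pop}) == 10

    def test_hub_count(self):
        pop = sd.generate_population(cfg(hub_fraction=0.25))
        assert sum(p.is_hub for p in pop) == 10


class TestCesdGeneration:
    def test_ceiling_at_maximal_latent(self):
        pop = [sd.LatentState(0, 0, 50.0, False),
               sd.LatentState(1, 0, 50.0, False)]
        items = sd.generate_cesd_items(pop, loading=1.0, config=cfg())
        scored = stats.score_cesd(items)
        assert (scored["total"] == 60).all()

    def test_zero_loading_gives_near_zero_alpha(self):
        pop = sd.generate_population(cfg(n_employees=2000, n_orgs=2))
        items = sd.generate_cesd_items(pop, loading=0.0, config=cfg())
        scored = stats.score_cesd(items)
        assert abs(stats.cronbach_alpha(scored.iloc[:, :20])) < 0.1

    def test_calibrated_loading_hits_target_interitem_r(self):
        loading = sd.loading_for_mean_interitem_r(0.25)
        pop = sd.generate_population(cfg(n_employees=4000, n_orgs=2,
                                         rng_seed=17))
        items = sd.generate_cesd_items(pop, loading, cfg(rng_seed=17))
        scored = stats.score_cesd(items).iloc[:, :20].to_numpy()
        corr = np.corrcoef(scored.T)
        rbar = corr[np.triu_indices(20, 1)].mean()
        assert rbar == pytest.approx(0.25, abs=0.02)

    def test_responses_in_range(self):
        items = sd.generate_cesd_items(sd.generate_population(cfg()), 0.5, cfg())
        assert items.to_numpy().min() >= 0 and items.to_numpy().max() <= 3


class TestSchedule:
    def test_zero_rates_give_empty_schedule(self):
        pop = sd.generate_population(cfg(contact_rate_hub=0.0,
                                         contact_rate_regular=0.0))
        sched = sd.generate_contact_schedule(pop, cfg(contact_rate_hub=0.0,
                                                      contact_rate_regular=0.0))
        assert sched == []

    def test_no_person_double_booked(self):
        config = cfg(n_employees=60, contact_rate_regular=4.0)
        sched = sd.generate_contact_schedule(sd.generate_population(config), config)
        seen: dict[int, set] = {}
        for ep in sched:
            for pid in ep.pair:
                mins = seen.setdefault(pid, set())
                assert not mins.intersection(ep.minutes)
                mins.update(ep.minutes)

    def test_same_pair_episodes_keep_min_gap(self):
        config = cfg(n_employees=10, contact_rate_regular=6.0, n_days=3)
        sched = sd.generate_contact_schedule(sd.generate_population(config), config)
        by_pair: dict = {}
        for ep in sched:
            by_pair.setdefault(ep.pair, []).append(ep)
        for eps in by_pair.values():
            eps.sort(key=lambda e: e.start)
            for a, b in zip(eps, eps[1:]):
                assert b.start - a.end > config.min_pair_gap

    def test_episodes_within_org_and_wear(self):
        config = cfg()
        pop = sd.generate_population(config)
        org = {p.person_id: p.org_id for p in pop}
        for ep in sd.generate_contact_schedule(pop, config):
            assert org[ep.pair[0]] == org[ep.pair[1]]
            day = ep.start // 1440
            lo, hi = config.wear_bounds(day)
            assert lo <= ep.start and ep.end < hi

    def test_hubs_interact_more(self):
        wins = 0
        for seed in range(10):
            config = cfg(n_employees=100, hub_fraction=0.1,
                         contact_rate_hub=6.0, contact_rate_regular=2.0,
                         n_days=3, rng_seed=seed)
            pop = sd.generate_population(config)
            sched = sd.generate_contact_schedule(pop, config)
            counts = {p.person_id: 0 for p in pop}
            for ep in sched:
                for pid in ep.pair:
                    counts[pid] += 1
            hubs = [counts[p.person_id] for p in pop if p.is_hub]
            regs = [counts[p.person_id] for p in pop if not p.is_hub]
            wins += np.mean(hubs) > np.mean(regs)
        assert wins >= 9

    def test_overbooked_schedule_raises(self):
        config = cfg(n_employees=4, n_orgs=2, contact_rate_regular=200.0,
                     episode_length_mean=30.0)
        with pytest.raises(sd.GenerationError, match="lower"):
            sd.generate_contact_schedule(sd.generate_population(config), config)


class TestDetections:
    def test_no_dropout_reconstructs_exactly(self):
        config = cfg(dropout_prob=0.0)
        pop = sd.generate_population(config)
        sched = sd.generate_contact_schedule(pop, config)
        recs = sd.degrade_to_detections(sched, config)
        pm = ia.records_to_minutes(recs)
        truth = {}
        for ep in sched:
            truth.setdefault(ep.pair, set()).update(ep.minutes)
        assert {k: set(v) for k, v in pm.items()} == truth

    @pytest.mark.parametrize("dropout", [0.3, 0.6])
    def test_gap_merge_repairs_episode_count(self, dropout):
        config = cfg(n_employees=60, contact_rate_regular=3.0,
                     dropout_prob=dropout)
        pop = sd.generate_population(config)
        sched = sd.generate_contact_schedule(pop, config)
        recs = sd.degrade_to_detections(sched, config)
        episodes = ia.merge_gaps(ia.records_to_minutes(recs), 5)
        assert len(episodes) == len(sched)

    def test_deterministic(self):
        config = cfg(dropout_prob=0.4)
        pop = sd.generate_population(config)
        sched = sd.generate_contact_schedule(pop, config)
        a = sd.degrade_to_detections(sched, config)
        b = sd.degrade_to_detections(sched, config)
        pd.testing.assert_frame_equal(a, b)


class TestBodyRhythm:
    def test_deterministic_and_nonnegative(self):
        config = cfg()
        pop = sd.generate_population(config)
        sched = sd.generate_contact_schedule(pop, config)
        s1, t1 = sd.generate_body_rhythm(pop, sched, config)
        s2, t2 = sd.generate_body_rhythm(pop, sched, config)
        assert np.array_equal(s1.values, s2.values, equal_nan=True)
        pd.testing.assert_frame_equal(t1, t2)
        assert np.nanmin(s1.values) >= 0

    def test_absent_outside_wear(self):
        config = cfg()
        pop = sd.generate_population(config)
        store, _ = sd.generate_body_rhythm(pop, [], config)
        lo, hi = config.wear_bounds(0)
        assert np.isnan(store.values[:, :lo]).all()
        assert not np.isnan(store.values[:, lo:hi]).any()

    def test_negative_coupling_lowers_rise_for_depressed_partners(self):
        config = cfg(n_employees=100, coupling_pe_partner_ds=-0.2,
                     contact_rate_regular=2.0)
        pop = sd.generate_population(config)
        sched = sd.generate_contact_schedule(pop, config)
        _, truth = sd.generate_body_rhythm(pop, sched, config)
        z = {p.person_id: p.latent_depression for p in pop}
        partner_z = truth["partner"].map(z)
        # planted rise is exactly delta + coupling * partner latent severity
        assert np.allclose(truth["true_rise"],
                           0.26 - 0.2 * partner_z, atol=1e-12)


def test_planted_effect_monotone_in_coupling():
    """|recovered self-PE x partner-DS correlation| grows with |coupling|."""
    import sociorhythm as sr
    from dataclasses import replace
    levels = [0.0, -0.12, -0.35]
    mean_abs_r = []
    for c in levels:
        rs = []
        for seed in range(3):
            config = sr.RunConfig(sim=sd.SimConfig(
                n_employees=150, n_orgs=3, n_days=4,
                coupling_pe_partner_ds=c, rng_seed=40 + seed))
            manifest, _ = sr.run(config)
            rs.append(manifest["correlations"]["self_pe__partner_ds"]["r"])
        mean_abs_r.append(abs(np.mean(rs)))
    assert mean_abs_r[0] < mean_abs_r[1] < mean_abs_r[2]
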
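"""Synthetic badge data with known planted structure.

The real study population (hundreds of employees in ten organizations,
observed for a working week or more) is confidential, so every
downstream stage is exercised on synthetic data that emulates it:

* a population split over organizations, with a small fraction of
  "hub" employees who initiate several times more contacts;
* dyadic within-organization contact schedules with geometric episode
  lengths, no double-booking, and same-pair episodes kept far enough
  apart that detection-level gap merging never fuses two true episodes;
* minute-level infrared detections degraded by per-direction dropout,
  with dropped runs kept short enough that 5-minute gap merging can
  repair them;
* per-minute body rhythm as person-level baseline + AR(1) noise, with
  a planted rise during interactions *and* in a +/-10-minute margin
  around them (body rhythm rises before and after interactions too:
  approach, greetings, and sensors acquiring each other late);
* CES-D item responses from a one-factor model on a latent depressive
  severity, the four positively phrased items generated reverse-coded.

Planted interpersonal structure: the rise of person i during an episode
with partner j is delta + coupling_partner * z_j (+ optional own-state
coupling), so the generator controls the population correlation between
an employee's engagement and their partners' depressive severity.
Every artifact is returned with its generating ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from functools import lru_cache
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq
from scipy.signal import lfilter

from .interactions import InteractionEpisode
from .rhythm import MINUTES_PER_DAY, RhythmStore

logger = logging.getLogger(__name__)

WORKDAY_START = 540  # 09:00, minutes after midnight

# marginal CES-D response probabilities for scored values 0..3 (community
# samples are bottom-heavy: most items rated "rarely or none of the time")
CESD_CATEGORY_PROBS = (0.55, 0.25, 0.15, 0.05)

# independent child-stream keys for the stage RNGs
_STAGE_POPULATION = 1
_STAGE_CESD = 2
_STAGE_SCHEDULE = 3
_STAGE_RHYTHM = 4
_STAGE_DETECT = 5


class ConfigError(ValueError):
    """A SimConfig field is out of its valid range."""


class GenerationError(RuntimeError):
    """The requested synthetic data cannot be generated."""


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate the study's scale.

    ~450 employees over 10 organizations, 10 observation days of an
    8-hour wear window, a hub tenth of the population initiating 3x the
    regular contact rate, ~9-minute mean episodes, 20% per-direction
    detection dropout with repairable (<5 min) gaps, baseline body
    rhythm near 1.10 Hz, and a 0.26 Hz mean interaction rise.
    """
    n_employees: int = 450
    n_orgs: int = 10
    n_days: int = 10
    workday_minutes: int = 480
    hub_fraction: float = 0.10
    contact_rate_hub: float = 6.0       # initiated events / person / day
    contact_rate_regular: float = 2.0
    episode_length_mean: float = 9.0    # minutes, geometric, >= 1
    dropout_prob: float = 0.2
    dropout_gap_max: int = 4            # dropped runs stay < this (repairable)
    br_baseline_mean: float = 1.10      # Hz
    br_baseline_sd: float = 0.60        # Hz, per-minute within-person noise
    br_between_sd: float = 0.30         # Hz, between-person baseline spread
    br_ar1_phi: float = 0.90            # minute-to-minute noise persistence
    br_interaction_delta: float = 0.26  # Hz, planted mean rise
    br_rise_margin: int = 10            # minutes of pre/post-episode rise
    coupling_pe_partner_ds: float = 0.0  # Hz per latent-DS unit of the partner
    coupling_pe_own_ds: float = 0.0      # Hz per own latent-DS unit
    coupling_own_hub_only: bool = False
    latent_ds_sd: float = 1.0
    min_pair_gap: int = 9               # minutes between same-pair episodes
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_employees", "n_orgs", "n_days", "workday_minutes",
                     "dropout_gap_max", "min_pair_gap"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("hub_fraction", "dropout_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("br_baseline_sd", "br_between_sd", "latent_ds_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("contact_rate_hub", "contact_rate_regular"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.episode_length_mean < 1:
            raise ConfigError("episode_length_mean must be >= 1 minute")
        if not 0 <= self.br_ar1_phi < 1:
            raise ConfigError("br_ar1_phi must be in [0, 1)")
        if self.n_employees < 2 * self.n_orgs:
            raise ConfigError("n_employees must allow org sizes >= 2")
        if self.workday_minutes > MINUTES_PER_DAY - WORKDAY_START:
            raise ConfigError("workday_minutes does not fit in a day")

    @property
    def total_minutes(self) -> int:
        return self.n_days * MINUTES_PER_DAY

    def wear_bounds(self, day: int) -> tuple[int, int]:
        """Half-open wear window [lo, hi) for one day."""
        lo = day * MINUTES_PER_DAY + WORKDAY_START
        return lo, lo + self.workday_minutes


@dataclass(frozen=True)
class LatentState:
    person_id: int
    org_id: int
    latent_depression: float
    is_hub: bool


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.rng_seed), stage])


# ------------------------------------------------------------ population

def generate_population(config: SimConfig) -> list[LatentState]:
    """Persons partitioned round-robin over organizations.

    ``floor(hub_fraction * n)`` persons are flagged as hubs (spread over
    organizations by the round-robin order); latent depressive severity
    is i.i.d. normal(0, latent_ds_sd).
    """
    rng = _rng(config, _STAGE_POPULATION)
    n = config.n_employees
    n_hubs = int(np.floor(config.hub_fraction * n))
    z = rng.normal(0.0, config.latent_ds_sd, size=n)
    return [LatentState(person_id=p, org_id=p % config.n_orgs,
                        latent_depression=float(z[p]), is_hub=p < n_hubs)
            for p in range(n)]


def population_frame(population: Sequence[LatentState]) -> pd.DataFrame:
    return pd.DataFrame([(p.person_id, p.org_id, p.latent_depression, p.is_hub)
                         for p in population],
                        columns=["person_id", "org_id", "latent_depression", "is_hub"])


# ----------------------------------------------------------------- CES-D

def _bvn_sf(a: float, b: float, rho: float) -> float:
    """P(X > a, Y > b) for standard bivariate normal with correlation rho."""
    cov = [[1.0, rho], [rho, 1.0]]
    f = sps.multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([a, b])
    return 1.0 - sps.norm.cdf(a) - sps.norm.cdf(b) + float(f)


def _discretized_corr(rho: float, thresholds: np.ndarray) -> float:
    """Pearson correlation of two equally thresholded normals with corr rho."""
    # scored value s = sum_c 1[y > t_c]; all moments follow from the cuts
    p_gt = sps.norm.sf(thresholds)
    mu = p_gt.sum()
    # same variable on both sides: P(X > a, X > b) = sf(max(a, b))
    e_s2 = sum(sps.norm.sf(max(a, b)) for a in thresholds for b in thresholds)
    var = e_s2 - mu ** 2
    e_xy = sum(_bvn_sf(a, b, rho) for a in thresholds for b in thresholds)
    return (e_xy - mu ** 2) / var


@lru_cache(maxsize=None)
def loading_for_mean_interitem_r(target_r: float,
                                 category_probs: tuple[float, ...] = CESD_CATEGORY_PROBS,
                                 ) -> float:
    """Factor loading whose discretized items show mean inter-item r = target.

    Items share one latent factor; the continuous item values of two
    items correlate at loading^2, and thresholding to the 0-3 response
    scale attenuates that.  The latent correlation rho solving
    discretized-corr(rho) = target is found exactly (bivariate-normal
    rectangle probabilities + root finding); the loading is sqrt(rho).
    """
    if not 0 <= target_r < 1:
        raise ValueError("target_r must be in [0, 1)")
    if target_r == 0:
        return 0.0
    cuts = np.cumsum(category_probs)[:-1]
    thresholds = sps.norm.ppf(cuts)
    rho = brentq(lambda r: _discretized_corr(r, thresholds) - target_r,
                 1e-6, 1 - 1e-6, xtol=1e-6)
    return float(np.sqrt(rho))


def generate_cesd_items(population: Sequence[LatentState],
                        loading: float,
                        config: SimConfig,
                        category_probs: Sequence[float] = CESD_CATEGORY_PROBS,
                        positive_items: Sequence[int] = (4, 8, 12, 16),
                        ) -> pd.DataFrame:
    """Raw 20-item CES-D responses from a one-factor model.

    Each item's continuous value is loading * z + sqrt(1-loading^2) * e
    with z the person's standardized latent severity, thresholded to the
    0-3 response scale.  Positively phrased items are emitted
    reverse-coded (raw = 3 - scored) so that standard scoring applies.
    Index: person_id; columns item01..item20.
    """
    if not 0 <= loading <= 1:
        raise ConfigError("loading must be in [0, 1]")
    rng = _rng(config, _STAGE_CESD)
    n = len(population)
    z = np.array([p.latent_depression for p in population])
    z_std = z / config.latent_ds_sd if config.latent_ds_sd > 0 else z
    eps = rng.standard_normal((n, 20))
    y = loading * z_std[:, None] + np.sqrt(max(0.0, 1 - loading ** 2)) * eps
    thresholds = sps.norm.ppf(np.cumsum(category_probs)[:-1])
    scored = (y[:, :, None] > thresholds[None, None, :]).sum(axis=2)
    raw = scored.copy()
    for pos in positive_items:
        raw[:, pos - 1] = 3 - raw[:, pos - 1]
    return pd.DataFrame(raw.astype(int),
                        index=pd.Index([p.person_id for p in population],
                                       name="person_id"),
                        columns=[f"item{k:02d}" for k in range(1, 21)])


# -------------------------------------------------------------- schedule

def generate_contact_schedule(population: Sequence[LatentState],
                              config: SimConfig,
                              max_attempts: int = 30,
                              ) -> list[InteractionEpisode]:
    """Dyadic within-organization episodes with no person double-booked.

    Each person initiates Poisson(rate) events per day (hub or regular
    rate); partners are drawn uniformly from the initiator's
    organization.  Episode lengths are geometric with the configured
    mean (>= 1 minute).  Same-pair episodes are kept >= min_pair_gap
    minutes apart so that downstream gap merging cannot fuse two true
    episodes even after dropout shortens their edges.
    """
    if not population:
        raise GenerationError("population is empty")
    rng = _rng(config, _STAGE_SCHEDULE)
    n = len(population)
    by_org: dict[int, list[int]] = {}
    for p in population:
        by_org.setdefault(p.org_id, []).append(p.person_id)
    rate = np.where([p.is_hub for p in population],
                    config.contact_rate_hub, config.contact_rate_regular)
    busy = np.zeros((n, config.total_minutes), dtype=bool)
    pair_spans: dict[tuple[int, int], list[tuple[int, int]]] = {}
    episodes: list[tuple[tuple[int, int], int, int]] = []
    n_events = 0
    n_placed = 0
    p_len = min(1.0, 1.0 / config.episode_length_mean)
    for day in range(config.n_days):
        lo, hi = config.wear_bounds(day)
        counts = rng.poisson(rate)
        initiators = np.repeat(np.arange(n), counts)
        rng.shuffle(initiators)
        for i in initiators:
            mates = by_org[population[i].org_id]
            if len(mates) < 2:
                continue
            n_events += 1
            j = i
            while j == i:
                j = mates[rng.integers(len(mates))]
            length = min(int(rng.geometric(p_len)), config.workday_minutes)
            placed = False
            for _ in range(max_attempts):
                start = int(rng.integers(lo, hi - length + 1))
                end = start + length - 1
                if busy[i, start:end + 1].any() or busy[j, start:end + 1].any():
                    continue
                pair = (min(i, j), max(i, j))
                gap_ok = all(start > e + config.min_pair_gap or end < s - config.min_pair_gap
                             for s, e in pair_spans.get(pair, ()))
                if not gap_ok:
                    continue
                busy[i, start:end + 1] = True
                busy[j, start:end + 1] = True
                pair_spans.setdefault(pair, []).append((start, end))
                episodes.append((pair, start, end))
                placed = True
                break
            if not placed:
                continue
        n_placed = len(episodes)
    if n_events and n_placed < 0.5 * n_events:
        raise GenerationError(
            f"could only place {n_placed}/{n_events} contact events; "
            "schedule too dense -- lower the contact rates or episode length")
    episodes.sort(key=lambda e: (e[1], e[0]))
    return [InteractionEpisode(pair=pair,
                               minutes=tuple(range(start, end + 1)),
                               episode_id=k)
            for k, (pair, start, end) in enumerate(episodes)]


# ------------------------------------------------------------ body rhythm

def generate_body_rhythm(population: Sequence[LatentState],
                         schedule: Sequence[InteractionEpisode],
                         config: SimConfig,
                         ) -> tuple[RhythmStore, pd.DataFrame]:
    """Per-minute BR with the planted interaction rise; plus ground truth.

    BR = person baseline + AR(1) noise, clipped at 0, NaN outside wear.
    During each episode's minutes and a +/- br_rise_margin margin
    (clipped to the day's wear window) person i's BR is raised by

        delta + coupling_partner * z_partner (+ own-state coupling)

    Returns (store, truth) where truth has one row per episode-person
    with the planted rise.
    """
    rng = _rng(config, _STAGE_RHYTHM)
    n = len(population)
    pids = [p.person_id for p in population]
    z = {p.person_id: p.latent_depression for p in population}
    hub = {p.person_id: p.is_hub for p in population}
    total = config.total_minutes
    store = RhythmStore(pids, total)
    sigma_e = config.br_baseline_sd * np.sqrt(1 - config.br_ar1_phi ** 2)
    noise = lfilter([1.0], [1.0, -config.br_ar1_phi],
                    rng.standard_normal((n, total)) * sigma_e, axis=1)
    baseline = config.br_baseline_mean + rng.normal(0.0, config.br_between_sd, n)
    values = baseline[:, None] + noise
    truth_rows = []
    for ep in schedule:
        day_lo, day_hi = config.wear_bounds(ep.start // MINUTES_PER_DAY)
        lo = max(ep.start - config.br_rise_margin, day_lo)
        hi = min(ep.end + config.br_rise_margin, day_hi - 1)
        for pid, partner in ((ep.pair[0], ep.pair[1]), (ep.pair[1], ep.pair[0])):
            rise = config.br_interaction_delta \
                + config.coupling_pe_partner_ds * z[partner]
            if config.coupling_pe_own_ds and (hub[pid] or not config.coupling_own_hub_only):
                rise += config.coupling_pe_own_ds * z[pid]
            values[store.index[pid], lo:hi + 1] += rise
            truth_rows.append((ep.episode_id, pid, partner, rise))
    np.maximum(values, 0.0, out=values)
    wear = np.zeros(total, dtype=bool)
    for day in range(config.n_days):
        lo, hi = config.wear_bounds(day)
        wear[lo:hi] = True
    values[:, ~wear] = np.nan
    store.values = values
    truth = pd.DataFrame(truth_rows,
                         columns=["episode_id", "person", "partner", "true_rise"])
    return store, truth


# -------------------------------------------------------------- dropout

def degrade_to_detections(schedule: Sequence[InteractionEpisode],
                          config: SimConfig) -> pd.DataFrame:
    """Directed minute-level detections with repairable dropout.

    Each episode minute yields records i->j and j->i, each independently
    dropped with dropout_prob.  Runs where *both* directions are dropped
    are capped below dropout_gap_max consecutive minutes (the run's
    capping minute is restored in one direction), and at least one
    minute of each episode always survives, so 5-minute gap merging
    downstream recovers the true episode count exactly.  The record list
    is returned shuffled.
    """
    rng = _rng(config, _STAGE_DETECT)
    obs, det, mins = [], [], []
    for ep in schedule:
        minutes = np.asarray(ep.minutes, dtype=np.int64)
        m = minutes.size
        keep_ij = rng.random(m) >= config.dropout_prob
        keep_ji = rng.random(m) >= config.dropout_prob
        union = keep_ij | keep_ji
        run = 0
        for t in range(m):
            if union[t]:
                run = 0
                continue
            run += 1
            if run == config.dropout_gap_max:
                keep_ij[t] = union[t] = True
                run = 0
        if not union.any():
            keep_ij[0] = True
        i, j = ep.pair
        obs.extend([i] * int(keep_ij.sum()) + [j] * int(keep_ji.sum()))
        det.extend([j] * int(keep_ij.sum()) + [i] * int(keep_ji.sum()))
        mins.extend(minutes[keep_ij].tolist() + minutes[keep_ji].tolist())
    records = pd.DataFrame({"observer": obs, "detected": det, "minute": mins})
    return records.iloc[rng.permutation(len(records))].reset_index(drop=True)


# ------------------------------------------------------------- raw accel

def generate_raw_accel(freq_by_minute: Mapping[int, float],
                       seed: int = 0,
                       sample_rate_hz: float = 50.0,
                       amplitude: float = 0.25,
                       noise_sd: float = 0.01) -> pd.DataFrame:
    """Small-sample raw 50 Hz tri-axial stream for exercising the accel path.

    Each requested minute carries a vertical sinusoid of the given
    frequency around 1 g plus small isotropic noise.  Phase is offset so
    no sample sits exactly on the window mean.
    """
    rng = np.random.default_rng(seed)
    rows = []
    per_minute = int(sample_rate_hz * 60)
    t = np.arange(per_minute) / sample_rate_hz
    for minute, f in sorted(freq_by_minute.items()):
        az = 1.0 + amplitude * np.sin(2 * np.pi * f * t + 0.37)
        ax = rng.normal(0, noise_sd, per_minute)
        ay = rng.normal(0, noise_sd, per_minute)
        rows.append(pd.DataFrame({"minute": minute, "ax": ax, "ay": ay,
                                  "az": az + rng.normal(0, noise_sd, per_minute)}))
    return pd.concat(rows, ignore_index=True)


# ------------------------------------------------------------ one-stop

def simulate_dataset(config: SimConfig,
                     cesd_loading: float | None = None) -> dict:
    """Generate the full synthetic bundle with its ground truth."""
    population = generate_population(config)
    if cesd_loading is None:
        cesd_loading = loading_for_mean_interitem_r(0.25)
    cesd = generate_cesd_items(population, cesd_loading, config)
    schedule = generate_contact_schedule(population, config)
    store, truth = generate_body_rhythm(population, schedule, config)
    detections = degrade_to_detections(schedule, config)
    return {
        "config": config,
        "population": population,
        "cesd_items": cesd,
        "schedule": schedule,
        "rhythm": store,
        "rise_truth": truth,
        "detections": detections,
    }
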
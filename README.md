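# sociorhythm

A tested, reusable pipeline for analyzing **sociometric-badge data**:
name-tag-shaped wearables that detect face-to-face interactions between
colleagues by infrared and record upper-body movement by accelerometer.
The package turns raw badge output — per-minute detection logs and
tri-axial acceleration — into *physical engagement*, a per-interaction
statistic of how much a person's body movement rises during an
encounter, and runs the interpersonal analyses that relate engagement
to depressive symptoms (CES-D) across a workplace: dyadic ego–alter
aggregation, key-partner identification, and correlation analyses with
bootstrap confidence bands.

It is aimed at researchers in organizational epidemiology and social
signal processing who want the full chain — signal extraction,
episode reconstruction, exclusion filters, baseline handling, and
statistics — as importable, unit-tested functions rather than ad-hoc
notebook code. Because real badge datasets of this kind are
confidential, the package ships a first-class synthetic-data generator
with planted, recoverable effects, so every stage is verifiable end to
end without any download.

## The statistics at the core

**Body rhythm.** The Euclidean norm of 50 Hz tri-axial acceleration is
reduced, per 10-second window, to the number of times it crosses the
window mean; the per-minute body rhythm is the mean over the minute's
windows of `crossings / (2 × 10 s)`, in Hz, so a pure f-Hz movement
reads f. Typical bands: 0–1 Hz sedentary, 1–2 Hz talking/typing,
2–3 Hz animated talking, 3–4 Hz excited discussion, >4 Hz running.

**Episodes.** A minute belongs to a pair if either badge detected the
other (union rule). Same-pair records separated by gaps of < 5 minutes
are merged into one episode (infrared misalignment causes short missed
runs); participants with < 5 h of wear or < 1 h of total interaction
are excluded.

**Physical engagement.** For participant *i* of episode *k*,

    PE_i(k) = mean BR_i over T_k − mean BR_i over T̂_k

where T_k is the episode's minutes extended ±10 min (body rhythm rises
around interactions), and T̂_k is a 30-minute baseline shifted to
[start−40, start−10). Same-pair episodes falling inside a baseline are
first integrated into one episode so the baseline never contains the
focal partner.

**Aggregation.** Each usable episode yields (PE_i, PE_j, DS_i, DS_j)
with DS the CES-D total (20 items, 0–3 each, four positive items
reverse-scored, totals 0–60). Per employee, episode-weighted means give
the 4-vector (mean PE_self, mean PE_partner, DS_self, mean DS_partner),
and the four pairwise correlations between the PE and DS coordinates
are the headline analysis, with partner-number control curves,
per-organization bootstrap bands, and tertile groups of "key partners"
(top-3 nomination counts).

## Worked example

```python
import sociorhythm as sr

cfg = sr.RunConfig(sim=sr.SimConfig(rng_seed=1))   # 450 employees, 10 orgs, 10 days
manifest, art = sr.run(cfg)

t = manifest["paired_t"]
print(f"rise: t({t['df']}) = {t['t']:.2f}, one-tailed p = {t['p']:.3g}")
print(f"mean PE = {manifest['pe_distribution']['mean']:.3f} Hz")
print(f"alpha = {manifest['cronbach_alpha']:.3f}")
```

prints, with the planted 0.26 Hz interaction rise of the default
configuration:

```
rise: t(20625) = 64.87, one-tailed p = 0
mean PE = 0.226 Hz
alpha = 0.867
```

i.e. body rhythm during interactions is decisively higher than in the
shifted baselines; the mean engagement of ~0.23 Hz sits slightly below
the planted 0.26 Hz rise because other-partner interactions elevate
some baselines (the pipeline reports that contamination:
`manifest["baseline_contamination"]`); and the synthetic CES-D items,
generated at a mean inter-item correlation of 0.25, show the
reliability that implies (Spearman–Brown: 0.87).

The numbered drivers under `analysis/` run the same stages as a
narrative sequence — cohort simulation, rhythm validation,
preprocessing audit, the four correlations with partner-number control,
key-partner groups, and robustness sweeps — writing small tables to
`results/`.

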
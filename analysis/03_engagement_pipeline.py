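#!/usr/bin/env python
"""Rebuild episodes from detections and audit the preprocessing chain.

Runs detection -> gap merging -> exclusions -> baseline integration ->
physical engagement on the default synthetic cohort and reports the
diagnostics the preprocessing is judged by: the fraction of short
(< 5 min) inter-event intervals absorbed by merging, how many
participants the wear/interaction filters drop, and how contaminated
the baseline windows are with other partners.
"""

import json
from pathlib import Path

import sociorhythm as sr
from sociorhythm import synthdata as sd

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    manifest, art = sr.run(sr.RunConfig(sim=sd.SimConfig(rng_seed=1)))
    counts = manifest["counts"]
    out = {
        "counts": counts,
        "merge_fraction_short_intervals": manifest["merge_fraction_short_intervals"],
        "baseline_contamination": manifest["baseline_contamination"],
        "records_per_episode": counts["n_engagement_records"]
        / counts["n_integrated_episodes"],
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "engagement_audit.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))
    print(f"\n{100 * out['merge_fraction_short_intervals']:.1f}% of adjacent "
          "same-pair events were < 5 min apart and merged (study: 38.8%).")
    print(f"Baselines contained a mean of "
          f"{out['baseline_contamination']['mean']:.2f} (median "
          f"{out['baseline_contamination']['median']:.0f}) other-partner "
          "records (study: 4.13, median 1).")
    print(f"{counts['n_employees'] - counts['n_retained']} of "
          f"{counts['n_employees']} employees excluded by the "
          "5 h wear / 1 h interaction filters.")


if __name__ == "__main__":
    main()
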
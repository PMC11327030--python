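"""Per-cell migration measures and the per-condition summary table.

Reads the track CSVs written by 01_simulate_cohorts.py, computes the
four migration measures per cell (mean instantaneous speed, static
classification at 75 μm total path, MSD log-log slope α, persistence)
and aggregates them into one row per collagen condition — the same
shape as a migration summary table of a 3D-culture study.
"""

from pathlib import Path

import pandas as pd

from gelquant import trajectory_metrics as tm

RESULTS = Path(__file__).resolve().parents[1] / "results"
LABELS = {"1mgml": "1 mg/mL", "3mgml": "3 mg/mL", "6mgml": "6 mg/mL"}


def main() -> None:
    params = tm.AnalysisParams()  # 75 μm static threshold, 25% max lag
    summaries, per_track = [], []
    for stem, label in LABELS.items():
        path = RESULTS / "tracks" / f"{stem}.csv"
        if not path.exists():
            raise SystemExit(f"{path} missing - run 01_simulate_cohorts.py first")
        tracks = tm.read_tracks(path, dialect="csv")
        metrics = [tm.compute_track_metrics(t, params) for t in tracks]
        table = tm.metrics_table(metrics)
        table.insert(0, "condition", label)
        per_track.append(table)
        s = tm.summarize_cohort(metrics, label)
        summaries.append(vars(s))
        print(f"{label}: n={s.n_tracks}  static={s.percent_static:.1f}%  "
              f"speed={s.mean_instant_speed:.2f} um/min  "
              f"alpha={s.mean_alpha:.2f}  persistence={s.percent_persistence:.1f}%")

    pd.concat(per_track).to_csv(RESULTS / "track_metrics.csv", index=False)
    pd.DataFrame(summaries).to_csv(RESULTS / "cohort_summary.csv", index=False)
    print(f"wrote {RESULTS / 'track_metrics.csv'} and "
          f"{RESULTS / 'cohort_summary.csv'}")


if __name__ == "__main__":
    main()
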
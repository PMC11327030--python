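"""Simulate migration cohorts for three collagen densities.

Builds synthetic track cohorts emulating cells embedded in 1, 3 and
6 mg/mL collagen: each condition mixes a static subpopulation (cells
stuck in the matrix) with motile cells whose anomalous exponent is set
through the fractional-Brownian Hurst parameter (α = 2H — subdiffusive
throughout, more confined at higher density) and whose displacement
scale sets the mean instantaneous speed.  Cohort sizes and set-points
follow the study conditions: n = 135 / 81 / 71 cells, static fractions
5.9 / 45.4 / 81.7 %, target α 0.9 / 0.6 / 0.3, target speeds
0.4 / 0.3 / 0.07 μm/min.  Tracks are written as CSV per condition.
"""

import sys
from pathlib import Path

import numpy as np

from gelquant import io as gio
from gelquant import synthetic_data as sd

RESULTS = Path(__file__).resolve().parents[1] / "results" / "tracks"

CONDITIONS = {
    # label: (n_cells, static fraction, hurst, target speed μm/min)
    "1mgml": (135, 0.059, 0.45, 0.40),
    "3mgml": (81, 0.454, 0.30, 0.30),
    "6mgml": (71, 0.817, 0.15, 0.07),
}


STATIC_JITTER_SPEED = 0.02  # μm/min: positional jitter of stuck cells


def build_cohort(label, n_cells, static_frac, hurst, speed, seed):
    config = sd.SimConfig(n_steps=144, frame_interval=10.0, seed=seed)
    rng = config.rng()
    n_static = int(round(static_frac * n_cells))
    n_motile = n_cells - n_static
    # the target speed is the cohort-wide mean (static cells included);
    # a 2D Gaussian step of per-axis sigma s has mean length s·sqrt(pi/2)
    motile_speed = max(
        (speed * n_cells - STATIC_JITTER_SPEED * n_static) / max(n_motile, 1),
        0.0)
    scale = motile_speed * config.frame_interval / np.sqrt(np.pi / 2)
    jitter_scale = (STATIC_JITTER_SPEED * config.frame_interval
                    / np.sqrt(np.pi / 2))
    tracks = []
    for i in range(n_motile):
        tracks.append(sd.simulate_fbm_track(
            config, hurst=hurst, scale=scale, rng=rng,
            track_id=f"{label}_motile_{i}"))
    for i in range(n_static):
        # stuck cells: tiny, strongly anti-persistent jitter around a point
        tracks.append(sd.simulate_fbm_track(
            config, hurst=0.1, scale=jitter_scale, rng=rng,
            track_id=f"{label}_static_{i}"))
    return tracks


def main(seed: int = 0) -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    for label, (n, frac, hurst, speed) in CONDITIONS.items():
        tracks = build_cohort(label, n, frac, hurst, speed, seed)
        path = gio.write_tracks_csv(tracks, RESULTS / f"{label}.csv")
        print(f"{label}: wrote {len(tracks)} tracks "
              f"(static set-point {100 * frac:.1f}%, alpha set-point "
              f"{2 * hurst:.1f}) -> {path}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
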
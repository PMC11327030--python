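"""Assay arithmetic: viability, apoptosis and degradation percentages.

Worked example on plausible field counts (100 reference cells per
field, 4 fields per condition, triplicate degradation readouts),
exercising the per-field-then-average convention and the
background/total normalization of the degradation assay.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gelquant import assay_stats as ast

RESULTS = Path(__file__).resolve().parents[1] / "results"

# (viability positives, apoptosis positives, degradation sample RFU) per condition
EXAMPLE = {
    "1 mg/mL": ([4, 6, 5, 3], [7, 9, 6, 8], 180.0),
    "3 mg/mL": ([5, 7, 6, 6], [9, 11, 8, 10], 120.0),
    "6 mg/mL": ([8, 6, 9, 7], [12, 14, 11, 13], 60.0),
}
BACKGROUND_RFU, TOTAL_RFU = 20.0, 220.0


def main() -> None:
    rows = []
    for label, (dead, apoptotic, sample_rfu) in EXAMPLE.items():
        reference = [100] * len(dead)
        viability = ast.viability_percent(ast.FieldCounts(reference, dead))
        apoptosis = ast.apoptosis_percent(ast.FieldCounts(reference, apoptotic))
        degradation = ast.degradation_percent(
            ast.DegradationReadout(sample_rfu, BACKGROUND_RFU, TOTAL_RFU))
        rows.append({
            "condition": label,
            "viability_pct": viability.mean,
            "viability_sd": viability.sd,
            "apoptosis_pct": apoptosis.mean,
            "apoptosis_sd": apoptosis.sd,
            "degradation_pct": degradation,
        })
        print(f"{label}: viability {viability.mean:.1f}±{viability.sd:.1f}%  "
              f"apoptosis {apoptosis.mean:.1f}±{apoptosis.sd:.1f}%  "
              f"degradation {degradation:.1f}%")
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "assays.csv", index=False)
    print(f"wrote {RESULTS / 'assays.csv'}")


if __name__ == "__main__":
    main()
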
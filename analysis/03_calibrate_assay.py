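#!/usr/bin/env python
"""Validate the assay against the control standards: confusion counts,
sensitivity/specificity with exact Clopper-Pearson intervals, and the
OddsPath evidence strength for both the full 20/46 set and the held-out
10/32 subset, in both evidence directions."""

import json
from pathlib import Path

from brca2hdr.calibration import calibration_report, read_controls
from brca2hdr.hdr_quant import read_estimates

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    controls = read_controls(RESULTS / "synthetic" / "controls.tsv")
    calls = {e.variant_id: e.call for e in read_estimates(RESULTS / "estimates.tsv")}
    report = calibration_report(controls, calls)
    (RESULTS / "calibration.json").write_text(json.dumps(report, indent=2))

    for label in ("full", "held_out"):
        entry = report[label]
        sens_lo, sens_hi = entry["sensitivity_ci"]
        spec_lo, spec_hi = entry["specificity_ci"]
        odds = entry["oddspath_pathogenic"]
        print(
            f"{label}: {entry['n_pathogenic']}P/{entry['n_benign']}B — "
            f"sensitivity {entry['sensitivity']:.0%} "
            f"({sens_lo:.0%}-{sens_hi:.0%}), "
            f"specificity {entry['specificity']:.0%} "
            f"({spec_lo:.0%}-{spec_hi:.0%}); "
            f"OddsPath {odds['oddspath']:.1f} -> {odds['strength']}"
        )
    benign = report["full"]["oddspath_benign"]
    print(
        f"benign direction (full set): OddsPath {benign['oddspath']:.3f} "
        f"(reciprocal {1 / benign['oddspath']:.1f}) -> {benign['strength']}"
    )


if __name__ == "__main__":
    main()
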
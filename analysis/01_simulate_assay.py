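#!/usr/bin/env python
"""Simulate the assay cohort: 252 DBD missense variants (90 truly
non-functional), 66 control standards, and replicate DR-GFP measurements
under the 4-clone x 2-replicate design. Writes the raw tables that the
later steps consume."""

from pathlib import Path

import pandas as pd

from brca2hdr.calibration import write_controls
from brca2hdr.synthetic_data import (
    SimulationConfig,
    _rng,
    simulate_control_sets,
    simulate_measurements,
    simulate_replicates,
)

SEED = 20210219
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)
    true_scores, measurements, anchors = simulate_replicates(config)
    controls, control_truth = simulate_control_sets(config)
    control_measurements = simulate_measurements(
        control_truth, config, _rng(config, stream=5)
    )

    pd.DataFrame(
        [
            {
                "variant_id": m.variant_id,
                "clone_id": m.clone_id,
                "replicate_id": m.replicate_id,
                "fold_change": m.value,
            }
            for m in measurements + control_measurements
        ]
    ).to_csv(OUT / "measurements.tsv", sep="\t", index=False)
    pd.Series(true_scores, name="true_score").rename_axis("variant_id").to_csv(
        OUT / "true_scores.tsv", sep="\t"
    )
    write_controls(controls, OUT / "controls.tsv")
    (OUT / "anchors.tsv").write_text(
        "pathogenic_control_mean\twildtype_mean\n"
        f"{anchors.pathogenic_control_mean}\t{anchors.wildtype_mean}\n"
    )

    n_wells = len(measurements) + len(control_measurements)
    print(f"simulated {len(true_scores)} cohort variants "
          f"({config.n_nonfunctional} truly non-functional) and "
          f"{len(controls.variants)} control standards: {n_wells} wells")
    print(f"anchor means: pathogenic {anchors.pathogenic_control_mean:.3f}, "
          f"wild-type {anchors.wildtype_mean:.3f}")
    print(f"tables under {OUT}")


if __name__ == "__main__":
    main()
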
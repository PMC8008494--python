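#!/usr/bin/env python
"""Apply the tailored ACMG/AMP framework: build evidence profiles for the
simulated cohort, classify before and after adding the functional code
(PS3/BS3), and tabulate the reclassification. Also replays the
transcribed published classification table through the engine and
reports its code-level concordance."""

from pathlib import Path

from brca2hdr.acmg_engine import (
    KNOWN_DIVERGENT_ROWS,
    combine_evidence,
    reclassification_summary,
    replay_table1,
)
from brca2hdr.hdr_quant import read_estimates
from brca2hdr.pipeline import profile_from_evidence_row
from brca2hdr.synthetic_data import SimulationConfig, simulate_evidence_profiles
from brca2hdr.variant_model import Tier

SEED = 20210219
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    estimates = [
        e for e in read_estimates(RESULTS / "estimates.tsv")
        if e.variant_id.startswith("var-")
    ]
    calls = {e.variant_id: e.call for e in estimates}
    config = SimulationConfig(seed=SEED)
    evidence = simulate_evidence_profiles(config, calls)
    evidence.to_csv(RESULTS / "synthetic" / "evidence.tsv", sep="\t", index=False)

    pairs = []
    rows = []
    for row in evidence.to_dict("records"):
        vid = row["variant_id"]
        before = combine_evidence(profile_from_evidence_row(row))
        after = combine_evidence(profile_from_evidence_row(row, calls[vid]))
        pairs.append((before.tier, after.tier))
        rows.append((vid, before.tier.value, after.tier.value))
    summary = reclassification_summary(pairs)
    summary.matrix.to_csv(RESULTS / "transition_matrix.tsv", sep="\t")

    import pandas as pd

    pd.DataFrame(rows, columns=["variant_id", "before_class", "final_class"]).to_csv(
        RESULTS / "classified.tsv", sep="\t", index=False
    )
    before_counts = {t.value: sum(b is t for b, _ in pairs) for t in Tier}
    after_counts = {t.value: sum(a is t for _, a in pairs) for t in Tier}
    print(f"before functional data: {before_counts}")
    print(f"after functional data:  {after_counts}")
    print(
        f"VUS resolution: {summary.n_vus_resolved}/{summary.n_vus_before} "
        f"({summary.resolution_rate:.0%}) — {summary.n_to_lpp} to LP/P, "
        f"{summary.n_to_lbb} to LB/B"
    )

    replay = replay_table1()
    replay.to_csv(RESULTS / "table1_replay.tsv", sep="\t", index=False)
    n_match = int(replay["match"].sum())
    print(
        f"published-table replay: {n_match}/{len(replay)} observed rows "
        f"reproduced from printed codes alone; {len(KNOWN_DIVERGENT_ROWS)} "
        f"divergent rows carry undisclosed internal evidence"
    )


if __name__ == "__main__":
    main()
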
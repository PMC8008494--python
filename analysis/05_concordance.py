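#!/usr/bin/env python
"""Compare final classifications with external assertion sets: a
simulated multi-submitter assertion table (conflict statuses after the
submission-filtering rules), a synthetic quantitative-model overlap
(48/49 concordant, sole outlier), and a synthetic PARP-inhibitor
drug-sensitivity overlap."""

from pathlib import Path

import pandas as pd

from brca2hdr.concordance import external_assay_crosstab, summarize_assertions
from brca2hdr.hdr_quant import FunctionCall
from brca2hdr.synthetic_data import (
    SimulationConfig,
    simulate_assertion_table,
    synthetic_drug_sensitivity_overlap,
    synthetic_quantitative_model_overlap,
)
from brca2hdr.variant_model import Tier

SEED = 20210219
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    finals_df = pd.read_csv(RESULTS / "classified.tsv", sep="\t")
    finals = {
        str(r.variant_id): Tier(str(r.final_class)) for r in finals_df.itertuples()
    }
    config = SimulationConfig(seed=SEED)
    assertions = simulate_assertion_table(config, finals)
    summary = summarize_assertions(assertions, finals)
    summary.table.to_csv(RESULTS / "concordance.tsv", sep="\t")
    print("final classification vs assertion status (counts):")
    print(summary.table.to_string())
    print(f"excluded variants: {len(summary.exclusions)} "
          f"({sorted({r.value for r in summary.exclusions.values()})})")

    calls, external = synthetic_quantitative_model_overlap()
    table, discordant = external_assay_crosstab(calls, external)
    n = int(table.to_numpy().sum())
    print(
        f"\nquantitative-model overlap: {n - len(discordant)}/{n} concordant "
        f"({(n - len(discordant)) / n:.0%}); outliers: {discordant}"
    )

    drug_calls, fclass = synthetic_drug_sensitivity_overlap()

    def agreement(call, ext):
        if call is FunctionCall.NON_FUNCTIONAL:
            return ext not in ("fClass1", "fClass2")
        if call is FunctionCall.FUNCTIONAL:
            return ext not in ("fClass4", "fClass5")
        return None

    drug_table, drug_discordant = external_assay_crosstab(
        drug_calls, fclass, agreement
    )
    drug_table.to_csv(RESULTS / "drug_sensitivity_crosstab.tsv", sep="\t")
    nf = drug_table.loc[FunctionCall.NON_FUNCTIONAL.value]
    resistant = int(nf.get("fClass1", 0) + nf.get("fClass2", 0))
    print(
        f"drug-sensitivity overlap: {int(drug_table.to_numpy().sum())} variants; "
        f"{resistant} non-functional variants resistant; "
        f"{len(drug_discordant)} functional variants drug-sensitive"
    )


if __name__ == "__main__":
    main()
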
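"""End-to-end orchestration: quantify -> calibrate -> classify -> concord.

Runs on synthetic inputs (the default; see :mod:`brca2hdr.synthetic_data`)
or on externally supplied tables, producing every stage's output plus a
machine-readable run manifest with the headline numbers: variants
assayed, functional / non-functional / indeterminate counts, OddsPath
for the full and held-out control sets, the before/after transition
matrix, and the VUS-resolution rate. Identical inputs and seed give an
identical manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from brca2hdr import acmg_engine, calibration, concordance, synthetic_data
from brca2hdr.acmg_engine import (
    CombinerConfig,
    EvidenceProfile,
    InSilicoVerdict,
    assign_frequency_code,
    assign_functional_code,
    assign_insilico_code,
    combine_evidence,
    reclassification_summary,
)
from brca2hdr.hdr_quant import (
    FitSettings,
    FunctionCall,
    FunctionThresholds,
    fit_hdr_model,
    write_estimates,
)
from brca2hdr.synthetic_data import (
    PATHOGENIC_CONTROL_ID,
    WILDTYPE_CONTROL_ID,
    SimulationConfig,
)
from brca2hdr.variant_model import EvidenceCode, Tier


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunManifest:
    seed: int
    config: dict
    input_digests: dict
    stage_counts: dict
    headline: dict

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)


def profile_from_evidence_row(
    row: Mapping, call: FunctionCall | None = None
) -> EvidenceProfile:
    """Build an :class:`EvidenceProfile` from one evidence-table row.

    ``call=None`` gives the before-functional-data profile; passing the HDR
    call adds PS3/BS3 (BS3 gated on the row's splice flag).
    """
    codes: list[EvidenceCode] = []
    flags: list[str] = []
    verdict = assign_insilico_code(bayesdel_score=float(row["bayesdel"]))
    if verdict is InSilicoVerdict.INCONCLUSIVE:
        flags.append("insilico_inconclusive")
    else:
        codes.append(EvidenceCode(verdict.value))
    freq = assign_frequency_code(float(row["faf"]), int(row["carrier_count"]))
    if freq is not None:
        codes.append(freq)
    for col in ("pm1", "pm5", "pp1", "pm3", "bp2"):
        label = str(row.get(col, "-"))
        if label not in ("-", "", "nan"):
            codes.append(EvidenceCode.parse(label))
    splice = bool(int(row.get("splice_impact", 0)))
    if call is not None:
        functional = assign_functional_code(call, splice)
        if functional is not None:
            # BP2-with-BS3 etc. stay legal: ids are distinct by construction
            codes.append(functional)
    return EvidenceProfile(
        variant_id=str(row["variant_id"]),
        codes=tuple(codes),
        inconclusive_flags=tuple(flags),
        splice_impact_predicted=splice,
    )


def run_pipeline(
    sim_config: SimulationConfig,
    out_dir: str | Path | None = None,
    fit_settings: FitSettings | None = None,
    thresholds: FunctionThresholds | None = None,
    combiner: CombinerConfig | None = None,
) -> tuple[RunManifest, dict]:
    """Synthetic end-to-end run; returns (manifest, stage outputs).

    Stages run in order; a failure raises :class:`StageError` naming the
    stage, leaving previously computed outputs intact in the returned
    ``out_dir`` (when given).
    """
    fit_settings = fit_settings or FitSettings(seed=sim_config.seed)
    thresholds = thresholds or FunctionThresholds()
    combiner = combiner or CombinerConfig()
    out_path = Path(out_dir) if out_dir else None
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    # -- simulate -----------------------------------------------------------
    try:
        true_scores, measurements, anchors = synthetic_data.simulate_replicates(sim_config)
        controls, control_truth = synthetic_data.simulate_control_sets(sim_config)
        control_rng = synthetic_data._rng(sim_config, stream=5)
        control_measurements = synthetic_data.simulate_measurements(
            control_truth, sim_config, control_rng
        )
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("simulate", str(exc)) from exc
    outputs["true_scores"] = true_scores
    outputs["anchors"] = anchors
    outputs["controls"] = controls

    # -- quantify -----------------------------------------------------------
    try:
        estimates = fit_hdr_model(
            measurements + control_measurements, anchors, fit_settings, thresholds
        )
    except Exception as exc:
        raise StageError("quantify", str(exc)) from exc
    cohort = [e for e in estimates if e.variant_id in true_scores]
    calls = {e.variant_id: e.call for e in estimates}
    outputs["estimates"] = estimates
    if out_path:
        write_estimates(estimates, out_path / "estimates.tsv")

    # -- calibrate ----------------------------------------------------------
    try:
        cal_report = calibration.calibration_report(controls, calls)
    except Exception as exc:
        raise StageError("calibrate", str(exc)) from exc
    outputs["calibration"] = cal_report
    if out_path:
        (out_path / "calibration.json").write_text(json.dumps(cal_report, indent=2))

    # -- classify -----------------------------------------------------------
    try:
        evidence = synthetic_data.simulate_evidence_profiles(
            sim_config, {e.variant_id: e.call for e in cohort}
        )
        pairs: list[tuple[Tier, Tier]] = []
        class_rows = []
        for row in evidence.to_dict("records"):
            vid = row["variant_id"]
            before = combine_evidence(profile_from_evidence_row(row), combiner)
            after = combine_evidence(
                profile_from_evidence_row(row, calls[vid]), combiner
            )
            pairs.append((before.tier, after.tier))
            class_rows.append(
                {
                    "variant_id": vid,
                    "call": calls[vid].value,
                    "codes_applied": ",".join(after.basis),
                    "before_class": before.tier.value,
                    "final_class": after.tier.value,
                    "conflict_flag": int(after.conflict_flag),
                }
            )
        classified = pd.DataFrame(class_rows)
        reclass = reclassification_summary(pairs)
    except Exception as exc:
        raise StageError("classify", str(exc)) from exc
    outputs["classified"] = classified
    outputs["reclassification"] = reclass
    if out_path:
        classified.to_csv(out_path / "classified.tsv", sep="\t", index=False)
        reclass.matrix.to_csv(out_path / "transition_matrix.tsv", sep="\t")

    # -- concord ------------------------------------------------------------
    try:
        finals = {
            r["variant_id"]: Tier(r["final_class"]) for r in class_rows
        }
        assertions = synthetic_data.simulate_assertion_table(sim_config, finals)
        summary = concordance.summarize_assertions(assertions, finals)
    except Exception as exc:
        raise StageError("concord", str(exc)) from exc
    outputs["concordance"] = summary
    if out_path:
        summary.table.to_csv(out_path / "concordance.tsv", sep="\t")

    # -- manifest -----------------------------------------------------------
    n_func = sum(e.call is FunctionCall.FUNCTIONAL for e in cohort)
    n_nonfunc = sum(e.call is FunctionCall.NON_FUNCTIONAL for e in cohort)
    n_indet = sum(e.call is FunctionCall.INDETERMINATE for e in cohort)
    manifest = RunManifest(
        seed=sim_config.seed,
        config=asdict(sim_config),
        input_digests={
            "measurements": _digest_measurements(measurements + control_measurements)
        },
        stage_counts={
            "simulate": {
                "cohort_variants": len(true_scores),
                "control_variants": len(controls.variants),
                "measurements": len(measurements) + len(control_measurements),
            },
            "quantify": {"estimates": len(estimates)},
            "classify": {"classified": len(classified)},
            "concord": {
                "variants_with_status": int(summary.table.to_numpy().sum()),
                "excluded": len(summary.exclusions),
            },
        },
        headline={
            "n_assayed": len(cohort),
            "n_functional": n_func,
            "n_nonfunctional": n_nonfunc,
            "n_indeterminate": n_indet,
            "oddspath_full": cal_report["full"]["oddspath_pathogenic"]["oddspath"],
            "oddspath_held_out": cal_report["held_out"]["oddspath_pathogenic"]["oddspath"],
            "n_vus_before": reclass.n_vus_before,
            "n_vus_resolved": reclass.n_vus_resolved,
            "vus_resolution_rate": reclass.resolution_rate,
            "n_to_lpp": reclass.n_to_lpp,
            "n_to_lbb": reclass.n_to_lbb,
            "transition_matrix": reclass.matrix.to_dict(),
        },
    )
    if manifest.headline["n_assayed"] != n_func + n_nonfunc + n_indet:
        raise StageError("manifest", "call counts do not reconcile")
    outputs["manifest"] = manifest
    if out_path:
        (out_path / "manifest.json").write_text(manifest.to_json())
    return manifest, outputs


def _digest_measurements(measurements) -> str:
    h = hashlib.sha256()
    for m in measurements:
        h.update(f"{m.variant_id}\t{m.clone_id}\t{m.replicate_id}\t{m.value:.12g}\n".encode())
    return h.hexdigest()


def report(manifest: RunManifest) -> str:
    """Human-readable summary of a run manifest."""
    h = manifest.headline
    if not h or h.get("n_assayed", 0) == 0:
        return "empty manifest: no variants assayed (warning)\n"
    lines = [
        f"variants assayed: {h['n_assayed']}",
        f"  non-functional: {h['n_nonfunctional']}",
        f"  functional:     {h['n_functional']}",
        f"  indeterminate:  {h['n_indeterminate']}",
        f"OddsPath (full controls):     {h['oddspath_full']:.1f}",
        f"OddsPath (held-out controls): {h['oddspath_held_out']:.1f}",
        f"VUS before functional data: {h['n_vus_before']}",
        (
            f"VUS resolved: {h['n_vus_resolved']} "
            f"({100 * h['vus_resolution_rate']:.0f}%) — "
            f"{h['n_to_lpp']} to LP/P, {h['n_to_lbb']} to LB/B"
        ),
    ]
    return "\n".join(lines) + "\n"
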
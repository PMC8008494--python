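"""Seedable generators for every input the pipeline consumes.

The generators emulate the assay's data-generating process: each variant
has a true HDR score drawn from a two-mode mixture anchored at the
pathogenic-control score (1) and the wild-type score (5); a replicate
measurement is ``raw_unit * true_score * exp(clone_effect + noise)``
with normal clone effects and replicate noise on the log scale
(fold changes are positive and the model works on log scores, so
lognormal noise is the natural choice). Control wells for both anchors
are always generated so normalization anchors can be estimated the same
way the assay does. Default design: two replicate experiments on each
of four independently derived clones (eight measurements per variant).

Everything is a pure function of (config, seed); distinct generator
functions draw from distinct seeded streams so adding one stage never
perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from brca2hdr.calibration import ControlSet, ControlVariant, Truth
from brca2hdr.concordance import AssertionRecord
from brca2hdr.hdr_quant import FunctionCall, HDRMeasurement, NormalizationAnchors
from brca2hdr.variant_model import Tier

PATHOGENIC_CONTROL_ID = "control-pathogenic"
WILDTYPE_CONTROL_ID = "control-wildtype"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the assayed cohort: 252 variants of which 90 are truly
    non-functional, scores at the anchor modes (1 and 5), and a 4-clone x
    2-replicate design. Noise scales are chosen so default credible-interval
    widths resemble the published per-variant intervals (upper bound roughly
    0.1-0.25 above the point score near the non-functional mode).
    """

    seed: int
    n_variants: int = 252
    n_nonfunctional: int = 90
    nonfunctional_mode: float = 1.0
    functional_mode: float = 5.0
    intermediate_fraction: float = 0.0
    intermediate_mode: float = 2.0
    true_score_sd: float = 0.04  # log-scale spread of true scores around a mode
    log_noise_sd: float = 0.12  # replicate noise, log scale
    clone_sd: float = 0.04  # clone random effect, log scale
    clones_per_variant: int = 4
    replicates_per_clone: int = 2
    raw_unit: float = 1.0  # raw fold change per unit true score
    n_pathogenic_controls: int = 20
    n_benign_controls: int = 46
    n_pathogenic_held_out: int = 10
    n_benign_held_out: int = 32
    # evidence-profile rates, conditional on the variant's functional call:
    # in-silico predictors and curated pathogenic codes correlate with true
    # function, so the non-functional rates are the observed shares among
    # the 63 observed rows of the transcribed classification table
    # (PP3 23/63, BP4 2/63; PM1 29/63, PM5 12/63, PP1 12/63, PM3 5/63),
    # while functional variants carry curated pathogenic codes only at
    # ``functional_curated_scale`` times those rates
    pp3_rate_nonfunctional: float = 0.37
    bp4_rate_nonfunctional: float = 0.03
    pp3_rate_functional: float = 0.05
    bp4_rate_functional: float = 0.40
    pm1_rate: float = 0.46
    pm1_supporting_share: float = 0.28
    pm5_rate: float = 0.19
    pp1_rate: float = 0.19
    pp1_moderate_share: float = 0.25
    pm3_rate: float = 0.08
    pm3_strong_share: float = 0.60
    functional_curated_scale: float = 0.05
    bp2_rate: float = 0.02
    splice_flag_rate: float = 0.0
    pm2_rate: float = 0.80
    bs1_rate: float = 0.04
    ba1_rate: float = 0.01
    # assertion-table parameters
    mean_submitters: float = 2.0
    conflict_rate: float = 0.30
    sharing_rate: float = 0.90
    collab_rate: float = 0.50

    def __post_init__(self) -> None:
        if self.n_nonfunctional > self.n_variants:
            raise ValueError("n_nonfunctional cannot exceed n_variants")
        for name in ("true_score_sd", "log_noise_sd", "clone_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.clones_per_variant < 1 or self.replicates_per_clone < 1:
            raise ValueError("design sizes must be >= 1")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_measurements(
    true_scores: Mapping[str, float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[HDRMeasurement]:
    """Replicate measurements for the given true scores under the design."""
    out: list[HDRMeasurement] = []
    for variant_id in true_scores:
        true = true_scores[variant_id]
        for c in range(config.clones_per_variant):
            clone_eff = rng.normal(0.0, config.clone_sd) if config.clone_sd else 0.0
            for r in range(config.replicates_per_clone):
                noise = rng.normal(0.0, config.log_noise_sd) if config.log_noise_sd else 0.0
                value = config.raw_unit * true * np.exp(clone_eff + noise)
                out.append(
                    HDRMeasurement(variant_id, f"clone-{c + 1}", f"rep-{r + 1}", float(value))
                )
    return out


def simulate_replicates(
    config: SimulationConfig,
) -> tuple[dict[str, float], list[HDRMeasurement], NormalizationAnchors]:
    """Cohort true scores, replicate measurements, and estimated anchors.

    The first ``n_nonfunctional`` variants sit at the non-functional mode,
    the rest at the functional mode (minus any intermediate mass). Control
    wells for the pathogenic and wild-type anchors are appended, and the
    returned anchors are their raw means — so the anchors carry sampling
    noise exactly as estimated anchors would.
    """
    rng = _rng(config, stream=1)
    n_int = int(round(config.intermediate_fraction * config.n_variants))
    true_scores: dict[str, float] = {}
    for i in range(config.n_variants):
        if i < config.n_nonfunctional:
            mode = config.nonfunctional_mode
        elif i < config.n_nonfunctional + n_int:
            mode = config.intermediate_mode
        else:
            mode = config.functional_mode
        spread = rng.normal(0.0, config.true_score_sd) if config.true_score_sd else 0.0
        true_scores[f"var-{i + 1:04d}"] = float(mode * np.exp(spread))
    measurements = simulate_measurements(true_scores, config, rng)
    control_truth = {
        PATHOGENIC_CONTROL_ID: config.nonfunctional_mode,
        WILDTYPE_CONTROL_ID: config.functional_mode,
    }
    control_wells = simulate_measurements(control_truth, config, rng)
    measurements.extend(control_wells)
    path_mean = float(
        np.mean([m.value for m in control_wells if m.variant_id == PATHOGENIC_CONTROL_ID])
    )
    wt_mean = float(
        np.mean([m.value for m in control_wells if m.variant_id == WILDTYPE_CONTROL_ID])
    )
    anchors = NormalizationAnchors(path_mean, wt_mean)
    return true_scores, measurements, anchors


def simulate_control_sets(
    config: SimulationConfig,
) -> tuple[ControlSet, dict[str, float]]:
    """Control standards with true scores at the anchor modes.

    Pathogenic controls draw near score 1, benign near score 5; the
    held-out flag marks the subset kept out of threshold identification
    (default 10 pathogenic, 32 benign).
    """
    rng = _rng(config, stream=2)
    variants: list[ControlVariant] = []
    true_scores: dict[str, float] = {}
    for i in range(config.n_pathogenic_controls):
        vid = f"ctrl-path-{i + 1:03d}"
        variants.append(
            ControlVariant(vid, Truth.PATHOGENIC, i < config.n_pathogenic_held_out)
        )
        true_scores[vid] = float(
            config.nonfunctional_mode * np.exp(rng.normal(0.0, config.true_score_sd))
        )
    for i in range(config.n_benign_controls):
        vid = f"ctrl-ben-{i + 1:03d}"
        variants.append(
            ControlVariant(vid, Truth.BENIGN, i < config.n_benign_held_out)
        )
        true_scores[vid] = float(
            config.functional_mode * np.exp(rng.normal(0.0, config.true_score_sd))
        )
    return ControlSet(tuple(variants)), true_scores


def simulate_evidence_profiles(
    config: SimulationConfig, calls: Mapping[str, FunctionCall]
) -> pd.DataFrame:
    """Evidence-table rows for the given variants.

    BayesDel scores are drawn inside the deleterious/tolerated/inconclusive
    bands at the configured rates; filtering allele frequencies span the
    BA1/BS1/PM2 bands; curated codes are sprinkled at configured rates with
    valid strength modifiers. Mutual-exclusion invariants hold by
    construction. Deterministic given (config, seed).
    """
    rng = _rng(config, stream=3)
    rows = []
    for variant_id in calls:
        if calls[variant_id] is FunctionCall.NON_FUNCTIONAL:
            pp3_rate, bp4_rate = (
                config.pp3_rate_nonfunctional, config.bp4_rate_nonfunctional
            )
        else:
            pp3_rate, bp4_rate = (
                config.pp3_rate_functional, config.bp4_rate_functional
            )
        u = rng.random()
        if u < pp3_rate:
            bayesdel = float(rng.uniform(0.44, 0.70))
        elif u < pp3_rate + bp4_rate:
            bayesdel = float(rng.uniform(-0.30, 0.05))
        else:
            bayesdel = float(rng.uniform(0.06, 0.43))
        v = rng.random()
        if v < config.ba1_rate:
            faf, carriers = float(rng.uniform(1.1e-3, 5e-3)), int(rng.integers(300, 1500))
        elif v < config.ba1_rate + config.bs1_rate:
            faf, carriers = float(rng.uniform(1.1e-4, 9e-4)), int(rng.integers(30, 280))
        elif v < config.ba1_rate + config.bs1_rate + config.pm2_rate:
            faf, carriers = float(rng.uniform(0.0, 0.9e-5)), int(rng.integers(0, 2))
        else:
            faf, carriers = float(rng.uniform(1.1e-5, 9e-5)), int(rng.integers(3, 25))
        scale = (
            1.0
            if calls[variant_id] is FunctionCall.NON_FUNCTIONAL
            else config.functional_curated_scale
        )
        pm1_rate = config.pm1_rate * scale
        pm1 = rng.choice(
            ["-", "PM1", "PM1_supp"],
            p=[
                1 - pm1_rate,
                pm1_rate * (1 - config.pm1_supporting_share),
                pm1_rate * config.pm1_supporting_share,
            ],
        )
        pm5 = "PM5" if rng.random() < config.pm5_rate * scale else "-"
        pp1_rate = config.pp1_rate * scale
        pp1 = rng.choice(
            ["-", "PP1", "PP1_mod"],
            p=[
                1 - pp1_rate,
                pp1_rate * (1 - config.pp1_moderate_share),
                pp1_rate * config.pp1_moderate_share,
            ],
        )
        pm3_rate = config.pm3_rate * scale
        pm3 = rng.choice(
            ["-", "PM3", "PM3_st"],
            p=[
                1 - pm3_rate,
                pm3_rate * (1 - config.pm3_strong_share),
                pm3_rate * config.pm3_strong_share,
            ],
        )
        bp2 = "BP2" if rng.random() < config.bp2_rate else "-"
        rows.append(
            {
                "variant_id": variant_id,
                "bayesdel": round(bayesdel, 4),
                "faf": faf,
                "carrier_count": carriers,
                "splice_impact": int(rng.random() < config.splice_flag_rate),
                "pm1": str(pm1),
                "pm5": pm5,
                "pp1": str(pp1),
                "pm3": str(pm3),
                "bp2": bp2,
            }
        )
    return pd.DataFrame(rows)


def simulate_assertion_table(
    config: SimulationConfig, finals: Mapping[str, Tier]
) -> list[AssertionRecord]:
    """Multi-submitter assertion rows with configurable conflict structure.

    Each variant gets one or more external submitters; with probability
    ``conflict_rate`` (and a non-VUS internal final) one submitter asserts
    VUS against the others' group assertion, producing a conflicting
    status downstream. A collaborating-lab row is added at ``collab_rate``
    so the exclusion paths are exercised; submitters fail the data-sharing
    requirement at ``1 - sharing_rate``.
    """
    rng = _rng(config, stream=4)
    records: list[AssertionRecord] = []
    for variant_id in finals:
        tier = finals[variant_id]
        n_sub = 1 + int(rng.poisson(max(config.mean_submitters - 1, 0.0)))
        conflicted = tier is not Tier.VUS and rng.random() < config.conflict_rate and n_sub >= 2
        for s in range(n_sub):
            asserted = tier
            if conflicted and s == n_sub - 1:
                asserted = Tier.VUS
            records.append(
                AssertionRecord(
                    variant_id=variant_id,
                    submitter_id=f"lab-{s + 1:02d}",
                    classification=asserted,
                    meets_sharing_requirements=bool(rng.random() < config.sharing_rate),
                    is_collaborating_lab=False,
                )
            )
        if rng.random() < config.collab_rate:
            records.append(
                AssertionRecord(
                    variant_id=variant_id,
                    submitter_id="collaborating-lab",
                    classification=tier,
                    meets_sharing_requirements=True,
                    is_collaborating_lab=True,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Synthetic stand-ins for external comparison datasets (composition built to
# the published marginals; the underlying per-variant tables are not public)


def synthetic_quantitative_model_overlap(
    n_overlap: int = 49,
    n_nonfunctional: int = 20,
    outlier_id: str = "p.Arg2502Cys",
) -> tuple[dict[str, FunctionCall], dict[str, str]]:
    """Synthetic 49-variant overlap with quantitative-model classifications.

    Constructed so that every variant's HDR call agrees with its external
    multifactorial class except the named outlier, which is functional in
    the assay but an unresolved VUS in the external model — matching the
    published marginals (48/49 concordant, one outlier). Per-variant
    composition of the real overlap is not published; the split between
    non-functional and functional agreements is arbitrary.
    """
    calls: dict[str, FunctionCall] = {outlier_id: FunctionCall.FUNCTIONAL}
    external: dict[str, str] = {outlier_id: "VUS"}
    for i in range(n_overlap - 1):
        vid = f"overlap-{i + 1:03d}"
        if i < n_nonfunctional:
            calls[vid] = FunctionCall.NON_FUNCTIONAL
            external[vid] = "LP/P"
        else:
            calls[vid] = FunctionCall.FUNCTIONAL
            external[vid] = "LB/B"
    return calls, external


def synthetic_drug_sensitivity_overlap(
    n_overlap: int = 63,
    n_nonfunctional: int = 25,
    n_functional_sensitive: int = 6,
) -> tuple[dict[str, FunctionCall], dict[str, str]]:
    """Synthetic overlap with a PARP-inhibitor drug-sensitivity study.

    fClass labels: 1/2 resistant (functional), 3 inconclusive, 4/5
    sensitive (non-functional). Built so no HDR-non-functional variant is
    resistant, and exactly ``n_functional_sensitive`` HDR-functional
    variants score sensitive for at least one drug.
    """
    calls: dict[str, FunctionCall] = {}
    fclass: dict[str, str] = {}
    for i in range(n_overlap):
        vid = f"drug-{i + 1:03d}"
        if i < n_nonfunctional:
            calls[vid] = FunctionCall.NON_FUNCTIONAL
            fclass[vid] = ["fClass4", "fClass5", "fClass3"][i % 3]
        elif i < n_nonfunctional + n_functional_sensitive:
            calls[vid] = FunctionCall.FUNCTIONAL
            fclass[vid] = ["fClass4", "fClass5"][i % 2]
        else:
            calls[vid] = FunctionCall.FUNCTIONAL
            fclass[vid] = ["fClass1", "fClass2", "fClass3"][i % 3]
    return calls, fclass
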
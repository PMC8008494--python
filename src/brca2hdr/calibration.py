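"""Assay validation against control standards and OddsPath evidence strength.

The assay is calibrated on missense control standards classified as
pathogenic or benign independently of functional data (full set: 20
pathogenic, 46 benign; held-out subset not used for threshold
identification: 10 and 32). Sensitivity/specificity come with exact
Clopper-Pearson intervals. The strength of evidence an abnormal (or
normal) readout confers is expressed as an odds of pathogenicity:

    OddsPath = [P2 * (1 - P1)] / [(1 - P2) * P1]

where P1 is the prior proportion of pathogenic variants among the
controls and P2 the proportion of pathogenic variants among controls
with the relevant readout. Under perfect separation P2 would be 1 (or 0
for the benign direction); the next-variant-misclassified correction
replaces it with TP/(TP+1) (resp. 1/(TN+1)), under which the pathogenic
OddsPath equals the number of benign controls exactly, and the
reciprocal benign OddsPath equals the number of pathogenic controls.
OddsPath > 18.7 maps to strong evidence.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from brca2hdr.hdr_quant import FunctionCall


class CalibrationInputError(ValueError):
    """Raised when controls and calls cannot be reconciled."""


class Truth(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class EvidenceStrength(str, enum.Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    INSUFFICIENT = "insufficient"


@dataclass(frozen=True)
class ControlVariant:
    variant_id: str
    truth: Truth
    held_out: bool = False


@dataclass(frozen=True)
class ControlSet:
    """Control standards with known pathogenic/benign labels."""

    variants: tuple[ControlVariant, ...]

    @property
    def n_pathogenic(self) -> int:
        return sum(v.truth is Truth.PATHOGENIC for v in self.variants)

    @property
    def n_benign(self) -> int:
        return sum(v.truth is Truth.BENIGN for v in self.variants)

    def held_out_subset(self) -> "ControlSet":
        return ControlSet(tuple(v for v in self.variants if v.held_out))

    @classmethod
    def from_counts(
        cls,
        n_pathogenic: int = 20,
        n_benign: int = 46,
        n_pathogenic_held_out: int = 10,
        n_benign_held_out: int = 32,
        prefix: str = "ctrl",
    ) -> "ControlSet":
        """Anonymous control set with the default 20/46 (held-out 10/32) design."""
        variants = [
            ControlVariant(f"{prefix}-path-{i:03d}", Truth.PATHOGENIC, i < n_pathogenic_held_out)
            for i in range(n_pathogenic)
        ] + [
            ControlVariant(f"{prefix}-ben-{i:03d}", Truth.BENIGN, i < n_benign_held_out)
            for i in range(n_benign)
        ]
        return cls(tuple(variants))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int
    n_indeterminate: int
    indeterminate_ids: tuple[str, ...] = ()
    misclassified_ids: tuple[str, ...] = ()

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class StrengthMap:
    """OddsPath cutoffs for pathogenic evidence tiers (strict '>').

    Only the strong cutoff (18.7) is fixed by the assay-validation
    recommendation this framework follows; the remaining tiers are the
    standard extrapolation and are overridable. Benign-direction tiers use
    the reciprocal cutoffs (OddsPath strictly below 1/cutoff).
    """

    very_strong: float = 350.0
    strong: float = 18.7
    moderate: float = 4.3
    supporting: float = 2.1

    def __post_init__(self) -> None:
        cuts = (self.very_strong, self.strong, self.moderate, self.supporting)
        if not all(a > b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cutoffs must be strictly decreasing")


@dataclass(frozen=True)
class OddsPathResult:
    p1: float
    p2: float
    oddspath: float
    strength: EvidenceStrength
    direction: str = "pathogenic"
    corrected: bool = False


def confusion_counts(
    calls: Mapping[str, FunctionCall], controls: ControlSet
) -> ConfusionCounts:
    """Tabulate calls against control truth.

    TP = pathogenic and NonFunctional; TN = benign and Functional.
    Indeterminate calls are counted separately and excluded from the
    sensitivity/specificity denominators. Every control must have a call.
    """
    missing = [v.variant_id for v in controls.variants if v.variant_id not in calls]
    if missing:
        raise CalibrationInputError(f"controls without a call: {missing}")
    tp = fn = tn = fp = 0
    indeterminate: list[str] = []
    misclassified: list[str] = []
    for v in controls.variants:
        call = calls[v.variant_id]
        if call is FunctionCall.INDETERMINATE:
            indeterminate.append(v.variant_id)
        elif v.truth is Truth.PATHOGENIC:
            if call is FunctionCall.NON_FUNCTIONAL:
                tp += 1
            else:
                fn += 1
                misclassified.append(v.variant_id)
        else:
            if call is FunctionCall.FUNCTIONAL:
                tn += 1
            else:
                fp += 1
                misclassified.append(v.variant_id)
    return ConfusionCounts(
        tp, fn, tn, fp, len(indeterminate), tuple(indeterminate), tuple(misclassified)
    )


def exact_binomial_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact binomial interval via beta quantiles."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside 0..{trials}")
    alpha = 1 - level
    lower = 0.0 if successes == 0 else float(
        stats.beta.ppf(alpha / 2, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes)
    )
    return lower, upper


def oddspath_to_strength(
    oddspath: float, strength_map: StrengthMap | None = None, direction: str = "pathogenic"
) -> EvidenceStrength:
    """Map an OddsPath value to an evidence tier (strict inequalities).

    Pathogenic direction reads the cutoffs as lower bounds (oddspath must
    exceed the cutoff); the benign direction uses the reciprocal scale
    (oddspath strictly below 1/cutoff). Values between the weakest cutoffs
    in both directions are insufficient.
    """
    if oddspath < 0:
        raise ValueError("oddspath must be >= 0")
    m = strength_map or StrengthMap()
    if direction == "pathogenic":
        tiers = [
            (m.very_strong, EvidenceStrength.VERY_STRONG),
            (m.strong, EvidenceStrength.STRONG),
            (m.moderate, EvidenceStrength.MODERATE),
            (m.supporting, EvidenceStrength.SUPPORTING),
        ]
        for cutoff, tier in tiers:
            if oddspath > cutoff:
                return tier
    elif direction == "benign":
        tiers = [
            (1 / m.very_strong, EvidenceStrength.VERY_STRONG),
            (1 / m.strong, EvidenceStrength.STRONG),
            (1 / m.moderate, EvidenceStrength.MODERATE),
            (1 / m.supporting, EvidenceStrength.SUPPORTING),
        ]
        for cutoff, tier in tiers:
            if oddspath < cutoff:
                return tier
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return EvidenceStrength.INSUFFICIENT


def compute_oddspath(
    controls: ControlSet,
    calls: Mapping[str, FunctionCall],
    direction: str = "pathogenic",
    strength_map: StrengthMap | None = None,
) -> OddsPathResult:
    """OddsPath conferred by an abnormal (or, mirrored, normal) readout.

    Pathogenic direction: P2 is the proportion of pathogenic controls among
    NonFunctional readouts; with perfect separation (no benign variant
    called NonFunctional) the next-variant-misclassified correction sets
    P2 = TP/(TP+1). Benign direction mirrors this on Functional readouts
    (P2 = 1/(TN+1) under perfect separation) and maps strength through the
    reciprocal cutoffs. Indeterminate controls reduce the effective set.
    """
    cc = confusion_counts(calls, controls)
    n_path = cc.tp + cc.fn
    n_ben = cc.tn + cc.fp
    if n_path == 0 or n_ben == 0:
        raise CalibrationInputError(
            "need at least one pathogenic and one benign control with a call"
        )
    p1 = n_path / (n_path + n_ben)
    corrected = False
    # Work in odds form: OddsPath = [P2/(1-P2)] / [P1/(1-P1)]. With P2 a
    # ratio of integer counts the posterior odds are an integer ratio, so the
    # perfect-separation identity (oddspath == n_benign) holds exactly in
    # floating point.
    if direction == "pathogenic":
        a, b = cc.tp, cc.fp  # pathogenic / benign among abnormal readouts
        if a + b == 0:
            raise CalibrationInputError("no abnormal readouts among controls")
        if b == 0 and a > 0:
            p2, odds2, corrected = a / (a + 1), float(a), True
        else:
            p2 = a / (a + b)
            odds2 = float("inf") if b == 0 else a / b
    elif direction == "benign":
        a, b = cc.fn, cc.tn  # pathogenic / benign among normal readouts
        if a + b == 0:
            raise CalibrationInputError("no normal readouts among controls")
        if a == 0 and b > 0:
            p2, odds2, corrected = 1 / (b + 1), 1.0 / b, True
        else:
            p2 = a / (a + b)
            odds2 = float("inf") if b == 0 else a / b
    else:
        raise ValueError(f"unknown direction {direction!r}")
    oddspath = odds2 * n_ben / n_path
    strength = oddspath_to_strength(oddspath, strength_map, direction)
    return OddsPathResult(
        p1=p1, p2=p2, oddspath=oddspath, strength=strength,
        direction=direction, corrected=corrected,
    )


# ---------------------------------------------------------------------------
# Tabular IO and report


def read_controls(path: str | Path) -> ControlSet:
    df = pd.read_csv(path, sep="\t", comment="#")
    variants = tuple(
        ControlVariant(
            str(row.variant_id), Truth(row.truth), bool(row.held_out)
        )
        for row in df.itertuples()
    )
    return ControlSet(variants)


def write_controls(controls: ControlSet, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"variant_id": v.variant_id, "truth": v.truth.value, "held_out": int(v.held_out)}
            for v in controls.variants
        ]
    ).to_csv(path, sep="\t", index=False)


def calibration_report(
    controls: ControlSet,
    calls: Mapping[str, FunctionCall],
    strength_map: StrengthMap | None = None,
) -> dict:
    """Full calibration summary: confusion counts, sens/spec with exact CIs,
    and OddsPath (both directions) for the full and held-out control sets."""
    report: dict = {}
    for label, cset in (("full", controls), ("held_out", controls.held_out_subset())):
        if not cset.variants:
            continue
        cc = confusion_counts(calls, cset)
        sens_ci = exact_binomial_ci(cc.tp, cc.tp + cc.fn) if cc.tp + cc.fn else None
        spec_ci = exact_binomial_ci(cc.tn, cc.tn + cc.fp) if cc.tn + cc.fp else None
        entry = {
            "n_pathogenic": cset.n_pathogenic,
            "n_benign": cset.n_benign,
            "confusion": {
                "TP": cc.tp, "FN": cc.fn, "TN": cc.tn, "FP": cc.fp,
                "indeterminate": cc.n_indeterminate,
            },
            "misclassified": list(cc.misclassified_ids),
            "sensitivity": cc.sensitivity if cc.tp + cc.fn else None,
            "sensitivity_ci": sens_ci,
            "specificity": cc.specificity if cc.tn + cc.fp else None,
            "specificity_ci": spec_ci,
        }
        for direction in ("pathogenic", "benign"):
            res = compute_oddspath(cset, calls, direction, strength_map)
            entry[f"oddspath_{direction}"] = {
                "p1": res.p1, "p2": res.p2, "oddspath": res.oddspath,
                "strength": res.strength.value, "corrected": res.corrected,
            }
        report[label] = entry
    return report
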
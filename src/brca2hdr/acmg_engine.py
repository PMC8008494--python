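"""Tailored ACMG/AMP evidence assignment and five-tier combination.

Quantitative inputs (HDR functional call, BayesDel/PROVEAN scores,
filtering allele frequency) are converted into evidence codes with
gene-specific thresholds; curated codes (PM1, PM5, PP1, PM3, BP2, with
strength modifiers) are consumed as assertions. Code sets are combined
into B / LB / VUS / LP / P by either of two backends:

``categorical``
    The standard combining rules of the five-tier framework, counting
    each code at its applied strength, with two sequence-variant-
    interpretation (SVI) modifications: PM2 is applied only as
    supporting, and a lone strong benign code (BS3) suffices for LB.

``points``
    A signed point sum (supporting 1, moderate 2, strong 4, very strong
    8; benign negative) with tier cutoff bands. A disclosed cross-check,
    not the primary backend.

Benign protein-function evidence is gated on predicted splice impact:
a variant with a splice flag keeps its BS3 code but the code cannot
contribute toward LB/B, since the assay reads out protein function only.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from brca2hdr.hdr_quant import FunctionCall, load_table1
from brca2hdr.variant_model import (
    Classification,
    Direction,
    EvidenceCode,
    Strength,
    Tier,
)


class EvidenceInputError(ValueError):
    """Raised for invalid quantitative evidence inputs."""


@dataclass(frozen=True)
class InSilicoThresholds:
    """Gene-specific BayesDel cutoffs (PROVEAN for non-SNVs)."""

    bayesdel_benign: float = 0.0560
    bayesdel_deleterious: float = 0.431
    provean_deleterious: float = -6.0

    def __post_init__(self) -> None:
        if not self.bayesdel_benign < self.bayesdel_deleterious:
            raise ValueError("bayesdel_benign must be < bayesdel_deleterious")


@dataclass(frozen=True)
class FrequencyThresholds:
    """Filtering-allele-frequency cutoffs for BA1 / BS1 / PM2_supporting.

    PM2_supporting additionally requires at most one carrier; 0.001%
    equates to <= 1 heterozygote at the maximum well-covered allele count
    of 282,912.
    """

    ba1: float = 0.001
    bs1: float = 0.0001
    pm2_supporting: float = 0.00001
    max_allele_count: int = 282_912

    def __post_init__(self) -> None:
        if not self.pm2_supporting < self.bs1 < self.ba1:
            raise ValueError("thresholds must satisfy pm2 < bs1 < ba1")


class InSilicoVerdict(str, enum.Enum):
    PP3 = "PP3"
    BP4 = "BP4"
    INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class EvidenceProfile:
    """The applied evidence-code set for one variant."""

    variant_id: str
    codes: tuple[EvidenceCode, ...]
    inconclusive_flags: tuple[str, ...] = ()
    splice_impact_predicted: bool = False

    def __post_init__(self) -> None:
        ids = [c.code_id for c in self.codes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.variant_id}: duplicate code ids in {ids}")
        if {"PP3", "BP4"} <= set(ids):
            raise ValueError(f"{self.variant_id}: PP3 and BP4 are mutually exclusive")
        if len({"BA1", "BS1", "PM2"} & set(ids)) > 1:
            raise ValueError(
                f"{self.variant_id}: at most one frequency code may apply"
            )


@dataclass(frozen=True)
class CombinerConfig:
    """Backend, conflict policy, and points weights/cutoffs.

    ``conflict_policy``: with evidence in both directions, ``strict_vus``
    always yields a conflicted VUS; ``pathogenic_dominant`` (default; the
    behaviour the transcribed classification table exhibits) lets a P/LP
    result stand when the benign side totals no more than one supporting
    code, and symmetrically lets an LB/B result stand when the pathogenic
    side is a single supporting code (rarity alone never blocks a benign
    call). ``svi_bs3_sufficient``: a lone strong benign code yields LB.
    """

    backend: str = "categorical"
    conflict_policy: str = "pathogenic_dominant"
    svi_bs3_sufficient: bool = True
    points_weights: Mapping[Strength, int] = field(
        default_factory=lambda: {
            Strength.SUPPORTING: 1,
            Strength.MODERATE: 2,
            Strength.STRONG: 4,
            Strength.VERY_STRONG: 8,
            Strength.STAND_ALONE: 8,
        }
    )
    points_p_min: int = 10
    points_lp_min: int = 6
    points_lb_max: int = -1
    points_b_max: int = -7


# ---------------------------------------------------------------------------
# Evidence assignment from quantitative inputs


def assign_functional_code(
    call: FunctionCall, splice_impact_predicted: bool = False
) -> EvidenceCode | None:
    """HDR call -> PS3 / BS3 (strong) / nothing.

    A Functional call with a predicted splice impact still emits BS3, but
    gated: the code is recorded yet cannot drive an LB/B classification.
    """
    if call is FunctionCall.NON_FUNCTIONAL:
        return EvidenceCode("PS3")
    if call is FunctionCall.FUNCTIONAL:
        return EvidenceCode("BS3", gated=splice_impact_predicted)
    return None


def assign_insilico_code(
    bayesdel_score: float | None = None,
    provean_score: float | None = None,
    thresholds: InSilicoThresholds | None = None,
) -> InSilicoVerdict:
    """BayesDel (SNVs) or PROVEAN (non-SNVs) -> PP3 / BP4 / inconclusive."""
    t = thresholds or InSilicoThresholds()
    if (bayesdel_score is None) == (provean_score is None):
        raise EvidenceInputError("exactly one of bayesdel/provean must be supplied")
    if bayesdel_score is not None:
        if bayesdel_score > t.bayesdel_deleterious:
            return InSilicoVerdict.PP3
        if bayesdel_score < t.bayesdel_benign:
            return InSilicoVerdict.BP4
        return InSilicoVerdict.INCONCLUSIVE
    if provean_score < t.provean_deleterious:
        return InSilicoVerdict.PP3
    return InSilicoVerdict.INCONCLUSIVE


def assign_frequency_code(
    faf: float,
    carrier_count: int,
    thresholds: FrequencyThresholds | None = None,
) -> EvidenceCode | None:
    """Filtering allele frequency -> BA1 / BS1 / PM2_supporting / nothing.

    ``faf`` must already be the lower of the genome/exome values.
    """
    t = thresholds or FrequencyThresholds()
    if faf < 0 or faf > 1 or carrier_count < 0:
        raise EvidenceInputError(f"invalid faf {faf} or carrier_count {carrier_count}")
    if faf >= t.ba1:
        return EvidenceCode("BA1", Strength.STAND_ALONE)
    if faf >= t.bs1:
        return EvidenceCode("BS1")
    if carrier_count <= 1:
        return EvidenceCode("PM2", Strength.SUPPORTING)
    return None


# ---------------------------------------------------------------------------
# Combination backends


def _strength_counts(codes: Iterable[EvidenceCode], direction: Direction) -> dict[Strength, int]:
    counts = {s: 0 for s in Strength}
    for c in codes:
        if c.direction is direction:
            counts[c.applied_strength] += 1
    return counts


def _pathogenic_tier(counts: dict[Strength, int]) -> Tier:
    vs = counts[Strength.VERY_STRONG]
    st = counts[Strength.STRONG]
    mod = counts[Strength.MODERATE]
    sup = counts[Strength.SUPPORTING]
    if vs >= 2:
        return Tier.P
    if vs == 1 and (st >= 1 or mod >= 2 or (mod >= 1 and sup >= 1) or sup >= 2):
        return Tier.P
    if st >= 2:
        return Tier.P
    if st == 1 and (mod >= 3 or (mod == 2 and sup >= 2) or (mod == 1 and sup >= 4)):
        return Tier.P
    if vs == 1 and mod >= 1:
        return Tier.LP
    if st == 1 and 1 <= mod <= 2:
        return Tier.LP
    if st == 1 and sup >= 2:
        return Tier.LP
    if mod >= 3:
        return Tier.LP
    if mod == 2 and sup >= 2:
        return Tier.LP
    if mod == 1 and sup >= 4:
        return Tier.LP
    return Tier.VUS


def _benign_tier(
    codes: Sequence[EvidenceCode], svi_bs3_sufficient: bool
) -> Tier:
    usable = [
        c for c in codes
        if c.direction is Direction.BENIGN and not c.gated
    ]
    if any(c.applied_strength is Strength.STAND_ALONE for c in usable):
        return Tier.B
    counts = _strength_counts(usable, Direction.BENIGN)
    st = counts[Strength.STRONG] + counts[Strength.VERY_STRONG]
    sup = counts[Strength.SUPPORTING] + counts[Strength.MODERATE]
    if st >= 2:
        return Tier.B
    if st == 1 and sup >= 1:
        return Tier.LB
    if sup >= 2:
        return Tier.LB
    if st == 1 and svi_bs3_sufficient:
        return Tier.LB
    return Tier.VUS


def combine_evidence(
    profile: EvidenceProfile, config: CombinerConfig | None = None
) -> Classification:
    """Combine a code set into a five-tier classification (categorical rules).

    Evidence in one direction only resolves directly. When both directions
    fire, the configured conflict policy decides; the conflict flag is set
    whenever both benign and pathogenic codes were present (a gated BS3
    still counts as present).
    """
    config = config or CombinerConfig()
    if config.backend == "points":
        return combine_evidence_points(profile, config)
    codes = profile.codes
    basis = tuple(c.label() for c in codes)
    has_path = any(c.direction is Direction.PATHOGENIC for c in codes)
    has_ben = any(c.direction is Direction.BENIGN for c in codes)
    path_tier = _pathogenic_tier(_strength_counts(codes, Direction.PATHOGENIC))
    ben_tier = _benign_tier(codes, config.svi_bs3_sufficient)
    if has_path and has_ben:
        ungated_benign = [
            c for c in codes if c.direction is Direction.BENIGN and not c.gated
        ]
        if config.conflict_policy == "strict_vus":
            return Classification(Tier.VUS, conflict_flag=True, basis=basis)
        if config.conflict_policy != "pathogenic_dominant":
            raise ValueError(f"unknown conflict policy {config.conflict_policy!r}")
        benign_minor = (
            len(ungated_benign) <= 1
            and all(
                c.applied_strength is Strength.SUPPORTING for c in ungated_benign
            )
        )
        if path_tier in (Tier.P, Tier.LP) and benign_minor:
            return Classification(path_tier, conflict_flag=True, basis=basis)
        # Mirrored clause: a benign result stands against at most one lone
        # supporting pathogenic code (e.g. BS3 with PM2_supporting — rarity
        # alone does not block a benign classification).
        path_codes = [c for c in codes if c.direction is Direction.PATHOGENIC]
        path_minor = len(path_codes) <= 1 and all(
            c.applied_strength is Strength.SUPPORTING for c in path_codes
        )
        if ben_tier in (Tier.B, Tier.LB) and path_minor:
            return Classification(ben_tier, conflict_flag=True, basis=basis)
        return Classification(Tier.VUS, conflict_flag=True, basis=basis)
    if has_path:
        return Classification(path_tier, basis=basis)
    if has_ben:
        return Classification(ben_tier, basis=basis)
    return Classification(Tier.VUS, basis=basis)


def combine_evidence_points(
    profile: EvidenceProfile, config: CombinerConfig | None = None
) -> Classification:
    """Signed point-sum backend; tiers by cutoff bands.

    Gated BS3 contributes no points (its weight would otherwise push the
    sum benign-ward on splice-ambiguous variants).
    """
    config = config or CombinerConfig()
    total = 0
    has_path = has_ben = False
    for c in profile.codes:
        if c.direction is Direction.PATHOGENIC:
            has_path = True
            total += config.points_weights[c.applied_strength]
        else:
            has_ben = True
            if not c.gated:
                total -= config.points_weights[c.applied_strength]
    if total >= config.points_p_min:
        tier = Tier.P
    elif total >= config.points_lp_min:
        tier = Tier.LP
    elif total > config.points_lb_max:
        tier = Tier.VUS
    elif total > config.points_b_max:
        tier = Tier.LB
    else:
        tier = Tier.B
    return Classification(
        tier,
        conflict_flag=has_path and has_ben,
        basis=tuple(c.label() for c in profile.codes),
    )


# ---------------------------------------------------------------------------
# Reclassification summaries

TIER_ORDER = [Tier.B, Tier.LB, Tier.VUS, Tier.LP, Tier.P]


@dataclass(frozen=True)
class ReclassificationSummary:
    matrix: pd.DataFrame
    n_vus_before: int
    n_vus_resolved: int
    n_to_lpp: int
    n_to_lbb: int

    @property
    def resolution_rate(self) -> float:
        return self.n_vus_resolved / self.n_vus_before if self.n_vus_before else float("nan")


def reclassification_summary(
    pairs: Sequence[tuple[Tier, Tier]]
) -> ReclassificationSummary:
    """5x5 before/after transition matrix plus the headline VUS-resolution
    rate (share of before-VUS variants leaving VUS) and per-direction counts."""
    labels = [t.value for t in TIER_ORDER]
    matrix = pd.DataFrame(0, index=labels, columns=labels)
    n_vus = resolved = to_lpp = to_lbb = 0
    for before, after in pairs:
        matrix.loc[before.value, after.value] += 1
        if before is Tier.VUS:
            n_vus += 1
            if after is not Tier.VUS:
                resolved += 1
                if after.group == "LP/P":
                    to_lpp += 1
                elif after.group == "LB/B":
                    to_lbb += 1
    return ReclassificationSummary(matrix, n_vus, resolved, to_lpp, to_lbb)


# ---------------------------------------------------------------------------
# Replay of the transcribed classification table

#: Table rows whose printed final class exceeds what the enumerated
#: combining rules support from the printed codes alone (P where the rules
#: yield LP, or LP where they yield VUS); the table encodes internal
#: laboratory evidence that is not disclosed, so these rows are expected
#: mismatches in :func:`replay_table1` and are never asserted row-level.
KNOWN_DIVERGENT_ROWS: frozenset[str] = frozenset(
    {
        "p.Asp2723Gly",
        "p.Asp2723His",
        "p.Asp3095Glu",
        "p.Asp3095Gly",
        "p.Glu2663Lys",
        "p.Gly2793Arg",
        "p.Gly2793Val",
        "p.Gly3076Glu",
        "p.Gly3076Val",
        "p.His2623Arg",
        "p.Ile2627Phe",
        "p.Leu2604Pro",
        "p.Leu2647Pro",
        "p.Leu2653Pro",
        "p.Leu2688Pro",
        "p.Asn3124Ile",
        "p.Arg2784Trp",
        "p.Arg3052Trp",
        "p.Thr2722Lys",
        "p.Thr2722Arg",
        "p.Trp2619Gly",
        "p.Trp2626Arg",
        "p.Tyr2726Cys",
    }
)


def table1_profiles() -> list[EvidenceProfile]:
    """Evidence profiles for the transcribed table's observed variants."""
    df = load_table1()
    profiles = []
    for row in df.itertuples():
        codes: list[EvidenceCode] = [EvidenceCode("PS3")]
        for col in ("pm1", "pm5", "pp1", "pm3"):
            label = getattr(row, col)
            if label != "-":
                codes.append(EvidenceCode.parse(label))
        flags = []
        if row.insilico in ("PP3", "BP4"):
            codes.append(EvidenceCode(row.insilico))
        elif row.insilico == "inc":
            flags.append("insilico_inconclusive")
        if row.freq_code != "-":
            codes.append(EvidenceCode.parse(row.freq_code))
        profiles.append(
            EvidenceProfile(
                variant_id=row.hgvs_p,
                codes=tuple(codes),
                inconclusive_flags=tuple(flags),
            )
        )
    return profiles


def replay_table1(config: CombinerConfig | None = None) -> pd.DataFrame:
    """Recompute final classes from the transcribed code sets and compare.

    Returns one row per observed variant (printed final class not N/O) with
    the engine's tier, the printed tier, and a match flag. Divergent rows
    are expected where the table encodes internal evidence beyond the
    printed codes; see :data:`KNOWN_DIVERGENT_ROWS`.
    """
    config = config or CombinerConfig()
    df = load_table1()
    finals = dict(zip(df["hgvs_p"], df["final_class"]))
    rows = []
    for profile in table1_profiles():
        printed = finals[profile.variant_id]
        if printed == "N/O":
            continue
        result = combine_evidence(profile, config)
        rows.append(
            {
                "hgvs_p": profile.variant_id,
                "engine_tier": result.tier.value,
                "printed_tier": printed,
                "match": result.tier.value == printed,
                "codes": ",".join(result.basis),
            }
        )
    return pd.DataFrame(rows)
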
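"""ClinVar-style assertion mining and cross-study concordance tables.

Assertion tables (variant, submitter, classification, data-sharing flag,
collaborating-lab flag) are filtered to qualifying submitters, reduced to
a per-variant conflict status on the grouped scale (LP/P vs VUS vs LB/B),
and cross-tabulated against the pipeline's internal final
classifications. A separate helper cross-tabulates HDR functional calls
against external assay or quantitative-model labels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from brca2hdr.hdr_quant import FunctionCall
from brca2hdr.variant_model import Tier


class ConflictStatus(str, enum.Enum):
    NO_CONFLICT_LPP = "no_conflict_LPP"
    NO_CONFLICT_VUS = "no_conflict_VUS"
    NO_CONFLICT_LBB = "no_conflict_LBB"
    CONFLICTING_LPP = "conflicting_LPP"
    CONFLICTING_LBB = "conflicting_LBB"
    OPPOSING = "opposing"


class ExclusionReason(str, enum.Enum):
    NO_QUALIFYING_SUBMITTER = "no qualifying submitter"
    COLLAB_SOLE_SUBMITTER = "collaborating-lab sole submitter"
    COLLAB_SOLE_OUTLIER = "collaborating-lab sole outlier"


@dataclass(frozen=True)
class AssertionRecord:
    variant_id: str
    submitter_id: str
    classification: Tier
    meets_sharing_requirements: bool = True
    is_collaborating_lab: bool = False


@dataclass(frozen=True)
class FilterResult:
    #: qualifying, non-collaborating-lab assertions for retained variants
    retained: tuple[AssertionRecord, ...]
    exclusions: Mapping[str, ExclusionReason]


def filter_assertions(records: Iterable[AssertionRecord]) -> FilterResult:
    """Apply the submission-filtering rules.

    Per variant: drop submitters not meeting the data-sharing requirements;
    exclude the variant when the collaborating laboratory is the only
    qualifying submitter, or when it is the sole classification outlier —
    its tier group (LP/P vs VUS vs LB/B) is unrepresented among the other
    qualifying submitters while those all share a single group. Ties are
    not outliers: the lab must be strictly alone in its group. Retained
    output carries only the non-collaborating-lab assertions. Deterministic
    and order-invariant.
    """
    by_variant: dict[str, list[AssertionRecord]] = {}
    for r in records:
        by_variant.setdefault(r.variant_id, []).append(r)
    retained: list[AssertionRecord] = []
    exclusions: dict[str, ExclusionReason] = {}
    for variant_id in sorted(by_variant):
        qualifying = [
            r for r in by_variant[variant_id] if r.meets_sharing_requirements
        ]
        if not qualifying:
            exclusions[variant_id] = ExclusionReason.NO_QUALIFYING_SUBMITTER
            continue
        others = [r for r in qualifying if not r.is_collaborating_lab]
        collab = [r for r in qualifying if r.is_collaborating_lab]
        if not others:
            exclusions[variant_id] = ExclusionReason.COLLAB_SOLE_SUBMITTER
            continue
        if collab:
            collab_groups = {r.classification.group for r in collab}
            other_groups = {r.classification.group for r in others}
            if len(other_groups) == 1 and collab_groups.isdisjoint(other_groups):
                exclusions[variant_id] = ExclusionReason.COLLAB_SOLE_OUTLIER
                continue
        retained.extend(sorted(others, key=lambda r: r.submitter_id))
    return FilterResult(tuple(retained), exclusions)


def conflict_status(assertions: Sequence[AssertionRecord]) -> ConflictStatus:
    """Reduce one variant's retained assertions to a conflict status.

    Grouping LP with P and LB with B: all assertions in one group give a
    no-conflict status; VUS mixed with exactly one non-VUS group gives the
    corresponding conflicting status; LP/P mixed with LB/B is reported as
    opposing (a category retained to verify its absence).
    """
    if not assertions:
        raise ValueError("need at least one retained assertion")
    groups = {r.classification.group for r in assertions}
    if groups == {"LP/P"}:
        return ConflictStatus.NO_CONFLICT_LPP
    if groups == {"VUS"}:
        return ConflictStatus.NO_CONFLICT_VUS
    if groups == {"LB/B"}:
        return ConflictStatus.NO_CONFLICT_LBB
    if "LP/P" in groups and "LB/B" in groups:
        return ConflictStatus.OPPOSING
    if groups == {"VUS", "LP/P"}:
        return ConflictStatus.CONFLICTING_LPP
    return ConflictStatus.CONFLICTING_LBB


@dataclass(frozen=True)
class ConcordanceSummary:
    #: counts: internal final group (rows) x conflict status (columns)
    table: pd.DataFrame
    statuses: Mapping[str, ConflictStatus]
    exclusions: Mapping[str, ExclusionReason]

    def fraction(self, final_group: str, status: ConflictStatus) -> tuple[int, int]:
        """(count, denominator) for one cell, denominator = row sum."""
        row = self.table.loc[final_group]
        return int(row[status.value]), int(row.sum())


def concordance_table(
    statuses: Mapping[str, ConflictStatus],
    internal_finals: Mapping[str, Tier],
    exclusions: Mapping[str, ExclusionReason] | None = None,
) -> ConcordanceSummary:
    """Cross-tabulate internal final groups against per-variant statuses.

    Every status key must have an internal final; mismatched keys raise
    with the offending variants listed.
    """
    missing = sorted(set(statuses) - set(internal_finals))
    if missing:
        raise KeyError(f"variants without internal finals: {missing}")
    groups = ["LP/P", "VUS", "LB/B"]
    cols = [s.value for s in ConflictStatus]
    table = pd.DataFrame(0, index=groups, columns=cols)
    for variant_id, status in statuses.items():
        table.loc[internal_finals[variant_id].group, status.value] += 1
    return ConcordanceSummary(table, dict(statuses), dict(exclusions or {}))


def summarize_assertions(
    records: Iterable[AssertionRecord], internal_finals: Mapping[str, Tier]
) -> ConcordanceSummary:
    """filter -> status -> table pipeline for one assertion set."""
    fr = filter_assertions(records)
    by_variant: dict[str, list[AssertionRecord]] = {}
    for r in fr.retained:
        by_variant.setdefault(r.variant_id, []).append(r)
    statuses = {v: conflict_status(rs) for v, rs in by_variant.items()}
    return concordance_table(statuses, internal_finals, fr.exclusions)


# ---------------------------------------------------------------------------
# External functional / quantitative-model comparisons


def _default_agreement(call: FunctionCall, external: str) -> bool | None:
    """Agreement between an HDR call and an external LP/P / VUS / LB/B label.

    Returns None (not comparable) when the HDR call is Indeterminate.
    """
    if call is FunctionCall.INDETERMINATE:
        return None
    if call is FunctionCall.NON_FUNCTIONAL:
        return external in ("LP", "P", "LP/P")
    return external in ("LB", "B", "LB/B")


def external_assay_crosstab(
    calls: Mapping[str, FunctionCall],
    external_classes: Mapping[str, str],
    agreement: Callable[[FunctionCall, str], bool | None] = _default_agreement,
) -> tuple[pd.DataFrame, list[str]]:
    """Contingency table of HDR calls vs external labels + discordant list.

    Only variants present in both mappings are compared; the discordant
    list names variants where ``agreement`` returns False.
    """
    shared = sorted(set(calls) & set(external_classes))
    rows = [
        {"variant_id": v, "call": calls[v].value, "external": external_classes[v]}
        for v in shared
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(), []
    table = pd.crosstab(df["call"], df["external"])
    discordant = [
        v for v in shared if agreement(calls[v], external_classes[v]) is False
    ]
    return table, discordant


# ---------------------------------------------------------------------------
# Tabular IO

_TIER_ALIASES = {t.value: t for t in Tier}


def read_assertions(path: str | Path) -> list[AssertionRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        AssertionRecord(
            variant_id=str(r.variant_id),
            submitter_id=str(r.submitter_id),
            classification=_TIER_ALIASES[str(r.classification)],
            meets_sharing_requirements=bool(r.meets_sharing_requirements),
            is_collaborating_lab=bool(r.is_collaborating_lab),
        )
        for r in df.itertuples()
    ]


def write_assertions(records: Iterable[AssertionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": r.variant_id,
                "submitter_id": r.submitter_id,
                "classification": r.classification.value,
                "meets_sharing_requirements": int(r.meets_sharing_requirements),
                "is_collaborating_lab": int(r.is_collaborating_lab),
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
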
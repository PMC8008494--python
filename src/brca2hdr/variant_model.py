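"""Domain types for BRCA2 missense variants, evidence codes, and classifications.

Protein-level HGVS ("HGVS-lite") parsing, annotation against the BRCA2
DNA-binding-domain (DBD) map, and readers/writers for the project's
tab-separated variant tables. Residue numbering is 1-based against the
BRCA2 protein (NP_000050.2, 3418 residues); no genomic coordinates are
used anywhere in the package. Coding-DNA names (``hgvs_c``) are carried
as opaque labels and never cross-checked against the protein name.
"""

from __future__ import annotations

import enum
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

BRCA2_PROTEIN_LENGTH = 3418

#: Standard three-letter amino-acid codes (20 canonical residues).
AMINO_ACIDS = frozenset(
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr Trp Tyr Val".split()
)

_HGVS_P_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


class VariantParseError(ValueError):
    """Raised for malformed or non-missense protein HGVS strings."""


class DomainConfigError(ValueError):
    """Raised for a domain map whose intervals are neither nested nor disjoint."""


class Tier(str, enum.Enum):
    """Five-tier variant classification."""

    B = "B"
    LB = "LB"
    VUS = "VUS"
    LP = "LP"
    P = "P"

    @property
    def group(self) -> str:
        """Collapse to the three-group scale: LB/B, VUS, LP/P."""
        if self in (Tier.LP, Tier.P):
            return "LP/P"
        if self in (Tier.LB, Tier.B):
            return "LB/B"
        return "VUS"


class Strength(enum.IntEnum):
    """ACMG/AMP evidence strength scale (ordered weakest to strongest)."""

    SUPPORTING = 1
    MODERATE = 2
    STRONG = 4
    VERY_STRONG = 8
    STAND_ALONE = 16


class Direction(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


#: Base strength and direction for every evidence code the engine accepts.
CODE_REGISTRY: dict[str, tuple[Direction, Strength]] = {
    "PS3": (Direction.PATHOGENIC, Strength.STRONG),
    "PM1": (Direction.PATHOGENIC, Strength.MODERATE),
    "PM2": (Direction.PATHOGENIC, Strength.MODERATE),
    "PM3": (Direction.PATHOGENIC, Strength.MODERATE),
    "PM5": (Direction.PATHOGENIC, Strength.MODERATE),
    "PP1": (Direction.PATHOGENIC, Strength.SUPPORTING),
    "PP3": (Direction.PATHOGENIC, Strength.SUPPORTING),
    "BA1": (Direction.BENIGN, Strength.STAND_ALONE),
    "BS1": (Direction.BENIGN, Strength.STRONG),
    "BS3": (Direction.BENIGN, Strength.STRONG),
    "BP2": (Direction.BENIGN, Strength.SUPPORTING),
    "BP4": (Direction.BENIGN, Strength.SUPPORTING),
}

_STRENGTH_SUFFIX = {
    "supp": Strength.SUPPORTING,
    "supporting": Strength.SUPPORTING,
    "mod": Strength.MODERATE,
    "moderate": Strength.MODERATE,
    "st": Strength.STRONG,
    "strong": Strength.STRONG,
    "vst": Strength.VERY_STRONG,
    "very_strong": Strength.VERY_STRONG,
}


@dataclass(frozen=True)
class EvidenceCode:
    """One applied ACMG/AMP criterion, possibly at a modified strength.

    ``applied_strength`` defaults to the code's base strength; a modifier such
    as PM1_supporting or PM3_strong overrides it. BA1 is the only stand-alone
    code. ``gated`` marks a BS3 that may not contribute toward LB/B (splice
    gate; see :mod:`brca2hdr.acmg_engine`).
    """

    code_id: str
    applied_strength: Strength | None = None
    gated: bool = False

    def __post_init__(self) -> None:
        if self.code_id not in CODE_REGISTRY:
            raise ValueError(f"unknown evidence code: {self.code_id!r}")
        if self.applied_strength is None:
            object.__setattr__(self, "applied_strength", self.base_strength)
        if self.applied_strength == Strength.STAND_ALONE and self.code_id != "BA1":
            raise ValueError("BA1 is the only stand-alone code")

    @property
    def direction(self) -> Direction:
        return CODE_REGISTRY[self.code_id][0]

    @property
    def base_strength(self) -> Strength:
        return CODE_REGISTRY[self.code_id][1]

    @classmethod
    def parse(cls, label: str) -> "EvidenceCode":
        """Parse labels like ``PS3``, ``PM1_supp``, ``PP1_mod``, ``PM3_st``."""
        base, _, suffix = label.strip().partition("_")
        if base not in CODE_REGISTRY:
            raise ValueError(f"unknown evidence code: {label!r}")
        if not suffix:
            return cls(base)
        if suffix.lower() not in _STRENGTH_SUFFIX:
            raise ValueError(f"unknown strength modifier in {label!r}")
        return cls(base, _STRENGTH_SUFFIX[suffix.lower()])

    def label(self) -> str:
        if self.applied_strength == self.base_strength:
            return self.code_id
        name = {
            Strength.SUPPORTING: "supp",
            Strength.MODERATE: "mod",
            Strength.STRONG: "st",
            Strength.VERY_STRONG: "vst",
        }[self.applied_strength]
        return f"{self.code_id}_{name}"


@dataclass(frozen=True)
class Classification:
    """Five-tier outcome with a conflict flag and the contributing codes."""

    tier: Tier
    conflict_flag: bool = False
    basis: tuple[str, ...] = ()


@dataclass(frozen=True)
class DomainMap:
    """Ordered (label, start, end) intervals, 1-based inclusive.

    Defaults carry only the boundaries used by the analysis: the DBD
    (2481-3186), the OB2 fold (2804-3054), and the Tower sub-domain within
    OB2 (2838-2962). Intervals must be nested or disjoint; the most specific
    (innermost) enclosing label wins.
    """

    intervals: tuple[tuple[str, int, int], ...] = (
        ("DBD", 2481, 3186),
        ("OB2", 2804, 3054),
        ("Tower", 2838, 2962),
    )
    outside_label: str = "outside-DBD"

    def __post_init__(self) -> None:
        for la, sa, ea in self.intervals:
            if sa > ea or sa < 1:
                raise DomainConfigError(f"bad interval {la}: [{sa}, {ea}]")
            for lb, sb, eb in self.intervals:
                if (la, sa, ea) == (lb, sb, eb):
                    continue
                disjoint = ea < sb or eb < sa
                nested = (sa <= sb and eb <= ea) or (sb <= sa and ea <= eb)
                if not (disjoint or nested):
                    raise DomainConfigError(
                        f"intervals {la} and {lb} overlap without nesting"
                    )


def annotate_domain(residue: int, domain_map: DomainMap | None = None) -> str:
    """Return the innermost domain label containing ``residue``.

    Residues outside every interval get the map's outside label. Total over
    residues >= 1 for any valid map.
    """
    if residue < 1:
        raise ValueError(f"residue must be >= 1, got {residue}")
    domain_map = domain_map or DomainMap()
    best: tuple[int, str] | None = None
    for label, start, end in domain_map.intervals:
        if start <= residue <= end:
            width = end - start
            if best is None or width < best[0]:
                best = (width, label)
    return best[1] if best else domain_map.outside_label


@dataclass(frozen=True)
class VariantRecord:
    """A BRCA2 missense variant with HGVS names and domain annotation."""

    hgvs_p: str
    residue: int
    ref_aa: str
    alt_aa: str
    hgvs_c: str = ""
    domain: str = ""

    def __post_init__(self) -> None:
        ref, pos, alt = parse_protein_hgvs(self.hgvs_p)
        if (ref, pos, alt) != (self.ref_aa, self.residue, self.alt_aa):
            raise VariantParseError(
                f"fields ({self.ref_aa}, {self.residue}, {self.alt_aa}) disagree "
                f"with hgvs_p {self.hgvs_p!r}"
            )
        if not 1 <= self.residue <= BRCA2_PROTEIN_LENGTH:
            raise VariantParseError(
                f"residue {self.residue} outside 1..{BRCA2_PROTEIN_LENGTH}"
            )

    @classmethod
    def from_hgvs_p(
        cls, hgvs_p: str, hgvs_c: str = "", domain_map: DomainMap | None = None
    ) -> "VariantRecord":
        ref, pos, alt = parse_protein_hgvs(hgvs_p)
        return cls(
            hgvs_p=hgvs_p,
            residue=pos,
            ref_aa=ref,
            alt_aa=alt,
            hgvs_c=hgvs_c,
            domain=annotate_domain(pos, domain_map),
        )

    @property
    def in_dbd(self) -> bool:
        return 2481 <= self.residue <= 3186


def parse_protein_hgvs(text: str) -> tuple[str, int, str]:
    """Parse ``p.<Aaa><pos><Aaa>`` into (ref_aa, residue, alt_aa).

    Only simple missense substitutions with three-letter codes are accepted;
    nonsense (Ter) and synonymous changes are rejected. Round-trips through
    :func:`format_protein_hgvs`.
    """
    m = _HGVS_P_RE.match(text.strip())
    if not m:
        raise VariantParseError(f"malformed protein HGVS: {text!r}")
    ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
    for aa in (ref, alt):
        if aa == "Ter":
            raise VariantParseError(f"nonsense change not supported: {aa!r} in {text!r}")
        if aa not in AMINO_ACIDS:
            raise VariantParseError(f"unknown amino-acid code {aa!r} in {text!r}")
    if ref == alt:
        raise VariantParseError(f"synonymous change is not a missense variant: {text!r}")
    return ref, pos, alt


def format_protein_hgvs(ref_aa: str, residue: int, alt_aa: str) -> str:
    return f"p.{ref_aa}{residue}{alt_aa}"


# ---------------------------------------------------------------------------
# Tabular IO

REQUIRED_COLUMNS = ("hgvs_p",)


def read_variant_table(
    path: str | Path, *, sep: str = "\t", domain_map: DomainMap | None = None
) -> list[VariantRecord]:
    """Read a delimited variant table into :class:`VariantRecord` rows.

    Requires an ``hgvs_p`` column; ``hgvs_c``, ``residue`` and ``domain`` are
    optional (recomputed when absent). Row order is preserved; duplicate
    ``hgvs_p`` entries trigger a warning, not an error.
    """
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str).fillna("")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    dupes = df["hgvs_p"][df["hgvs_p"].duplicated()].tolist()
    if dupes:
        warnings.warn(f"duplicate hgvs_p entries: {sorted(set(dupes))}", stacklevel=2)
    records = []
    for _, row in df.iterrows():
        rec = VariantRecord.from_hgvs_p(
            row["hgvs_p"], hgvs_c=row.get("hgvs_c", ""), domain_map=domain_map
        )
        if row.get("domain"):
            rec = VariantRecord(
                hgvs_p=rec.hgvs_p,
                residue=rec.residue,
                ref_aa=rec.ref_aa,
                alt_aa=rec.alt_aa,
                hgvs_c=rec.hgvs_c,
                domain=row["domain"],
            )
        records.append(rec)
    return records


def write_variant_table(
    records: Iterable[VariantRecord], path: str | Path, *, sep: str = "\t"
) -> None:
    """Write records losslessly; :func:`read_variant_table` round-trips."""
    rows = [
        {
            "hgvs_c": r.hgvs_c,
            "hgvs_p": r.hgvs_p,
            "residue": r.residue,
            "ref_aa": r.ref_aa,
            "alt_aa": r.alt_aa,
            "domain": r.domain,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["hgvs_c", "hgvs_p", "residue", "ref_aa", "alt_aa", "domain"]).to_csv(
        path, sep=sep, index=False
    )
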
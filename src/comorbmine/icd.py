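"""ICD-10 code parsing, intermediate-block mapping, and principal-diagnosis subgroups.

The unit of analysis for comorbidity mining is the ICD-10 *intermediate
classification block*: a contiguous range of 3-character categories such as
I10–I15 "Hypertensive diseases". Subdivision digits (the part after the
category, e.g. the ".9" in F03.9) never affect block membership.
"""

from __future__ import annotations

import bisect
import csv
import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

__all__ = [
    "ICDCode",
    "ICDBlock",
    "BlockTable",
    "PrincipalSubgroup",
    "ICDParseError",
    "parse_icd_code",
    "assign_block",
    "principal_subgroup",
    "default_block_table",
]

_CODE_RE = re.compile(r"^([A-Za-z])([0-9]{2})(?:\.?([0-9]+))?$")


class ICDParseError(ValueError):
    """Raised when a diagnosis-code string is not a valid ICD-10 code."""


@dataclass(frozen=True, order=True)
class ICDCode:
    """A parsed ICD-10 code: letter, 2-digit category, optional subdivision."""

    letter: str
    category: int
    subdivision: Optional[str] = field(default=None, compare=False)

    @property
    def key(self) -> tuple[str, int]:
        """(letter, category) pair — the total order used for block ranges."""
        return (self.letter, self.category)

    def __str__(self) -> str:
        base = f"{self.letter}{self.category:02d}"
        return base if self.subdivision is None else f"{base}.{self.subdivision}"


def parse_icd_code(text: str) -> ICDCode:
    """Parse a raw code string like ``"I10"`` or ``"F03.9"`` into an :class:`ICDCode`.

    The letter is uppercased; a trailing subdivision (with or without a dot)
    is retained but ignored by block mapping. Raises :class:`ICDParseError`
    naming the offending value on malformed input.
    """
    cleaned = text.strip() if isinstance(text, str) else ""
    m = _CODE_RE.match(cleaned)
    if not m:
        raise ICDParseError(f"not a valid ICD-10 code: {text!r}")
    letter, category, subdivision = m.groups()
    return ICDCode(letter.upper(), int(category), subdivision)


@dataclass(frozen=True)
class ICDBlock:
    """A contiguous closed range of 3-character ICD-10 categories."""

    start: ICDCode
    end: ICDCode
    label: str

    def __post_init__(self) -> None:
        if self.start.key > self.end.key:
            raise ValueError(f"block start {self.start} exceeds end {self.end}")

    @property
    def id(self) -> str:
        """ASCII identifier, e.g. ``"I10-I15"``."""
        return f"{self.start}-{self.end}"

    def contains(self, code: ICDCode) -> bool:
        return self.start.key <= code.key <= self.end.key

    def __str__(self) -> str:
        return self.id


class BlockTable:
    """An ordered, pairwise-disjoint set of ICD blocks forming the item universe.

    The default table ships with the package and covers the full ICD-10 block
    list at the granularity used for comorbidity classification (with the
    F00–F09 range split into dementia F00–F03 and other organic disorders
    F04–F09). It is replaceable by any CSV with columns ``start,end,label``.
    """

    def __init__(self, blocks: Iterable[ICDBlock]):
        blocks = sorted(blocks, key=lambda b: b.start.key)
        for prev, cur in zip(blocks, blocks[1:]):
            if cur.start.key <= prev.end.key:
                raise ValueError(f"blocks overlap: {prev.id} and {cur.id}")
        self.blocks: list[ICDBlock] = blocks
        self._starts = [b.start.key for b in blocks]
        self._by_id = {b.id: b for b in blocks}

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __getitem__(self, block_id: str) -> ICDBlock:
        return self._by_id[block_id]

    def __contains__(self, block_id: str) -> bool:
        return block_id in self._by_id

    def assign(self, code: ICDCode) -> Optional[ICDBlock]:
        """Return the unique block whose range contains ``code``, or ``None``."""
        i = bisect.bisect_right(self._starts, code.key) - 1
        if i >= 0 and self.blocks[i].contains(code):
            return self.blocks[i]
        return None

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "BlockTable":
        with open(path, newline="", encoding="utf-8") as fh:
            return cls._from_rows(csv.DictReader(fh))

    @classmethod
    def _from_rows(cls, rows: Iterable[dict]) -> "BlockTable":
        blocks = []
        for row in rows:
            blocks.append(
                ICDBlock(
                    parse_icd_code(row["start"]),
                    parse_icd_code(row["end"]),
                    row["label"].strip(),
                )
            )
        return cls(blocks)


def default_block_table() -> BlockTable:
    """Load the packaged ICD-10 intermediate-block table."""
    ref = resources.files("comorbmine.data").joinpath("icd10_blocks.csv")
    with ref.open("r", encoding="utf-8", newline="") as fh:
        return BlockTable._from_rows(csv.DictReader(fh))


def assign_block(code: ICDCode, table: BlockTable) -> Optional[ICDBlock]:
    """Map a code to its intermediate block, or ``None`` when unmapped."""
    return table.assign(code)


class PrincipalSubgroup(enum.Enum):
    """Principal-diagnosis strata of the mental and behavioral disorders chapter.

    Organic mental disorders other than dementia (F04–F09), mental retardation
    (F70–F79), disorders of psychological development (F80–F89), childhood-onset
    behavioral and emotional disorders (F90–F98), unspecified mental disorder
    (F99) and every non-F principal diagnosis are excluded from the analysis.
    """

    DEMENTIA = "F00-F03"
    SUBSTANCE_USE = "F10-F19"
    SCHIZOPHRENIA = "F20-F29"
    MOOD = "F30-F39"
    NEUROTIC = "F40-F48"
    BEHAVIORAL_SYNDROMES = "F50-F59"
    ADULT_PERSONALITY = "F60-F69"
    ALL = "ALL"
    EXCLUDED = "EXCLUDED"

    @property
    def label(self) -> str:
        return self.value

    @classmethod
    def strata(cls) -> tuple["PrincipalSubgroup", ...]:
        """The seven analyzable strata, in ICD order."""
        return (
            cls.DEMENTIA,
            cls.SUBSTANCE_USE,
            cls.SCHIZOPHRENIA,
            cls.MOOD,
            cls.NEUROTIC,
            cls.BEHAVIORAL_SYNDROMES,
            cls.ADULT_PERSONALITY,
        )

    @classmethod
    def from_label(cls, label: str) -> "PrincipalSubgroup":
        for member in cls:
            if member.value == label:
                return member
        valid = ", ".join(m.value for m in cls if m is not cls.EXCLUDED)
        raise ValueError(f"unknown subgroup {label!r}; valid: {valid}")


_SUBGROUP_RANGES = (
    (0, 3, PrincipalSubgroup.DEMENTIA),
    (10, 19, PrincipalSubgroup.SUBSTANCE_USE),
    (20, 29, PrincipalSubgroup.SCHIZOPHRENIA),
    (30, 39, PrincipalSubgroup.MOOD),
    (40, 48, PrincipalSubgroup.NEUROTIC),
    (50, 59, PrincipalSubgroup.BEHAVIORAL_SYNDROMES),
    (60, 69, PrincipalSubgroup.ADULT_PERSONALITY),
)


def principal_subgroup(code: ICDCode) -> PrincipalSubgroup:
    """Classify a principal diagnosis into its stratum, or ``EXCLUDED``."""
    if code.letter != "F":
        return PrincipalSubgroup.EXCLUDED
    for lo, hi, subgroup in _SUBGROUP_RANGES:
        if lo <= code.category <= hi:
            return subgroup
    return PrincipalSubgroup.EXCLUDED
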
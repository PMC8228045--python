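"""Discharge records, study eligibility rules, and descriptive statistics.

Eligibility follows the study design for adult psychiatric hospitalizations:
discharged 2006–2016, aged 19 or older, principal diagnosis in one of the
seven analyzable mental-disorder subgroups. A *comorbidity* is any additional
diagnosis recorded during the hospitalization besides the principal one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from scipy import stats

from ._util import round_half_up
from .icd import (
    BlockTable,
    ICDCode,
    PrincipalSubgroup,
    default_block_table,
    parse_icd_code,
    principal_subgroup,
)

__all__ = [
    "DischargeRecord",
    "Cohort",
    "FilterReport",
    "build_cohort",
    "has_comorbidity",
    "prevalence_by_subgroup",
    "chi_square",
    "welch_t",
    "frequent_blocks",
    "read_records_csv",
    "write_records_csv",
    "describe",
]

YEAR_MIN, YEAR_MAX = 2006, 2016
AGE_MIN = 19

CSV_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "year",
    "insurance",
    "admission_route",
    "outcome",
    "los",
    "bed_size",
    "principal_dx",
    "additional_dx",
]


@dataclass(frozen=True)
class DischargeRecord:
    """One hospitalization: demographics plus principal and additional diagnoses."""

    patient_id: str
    sex: str
    age: int
    year: int
    insurance: str
    admission_route: str
    outcome: str
    los: int
    bed_size: str
    principal_dx: ICDCode
    additional_dx: tuple[ICDCode, ...] = ()

    @property
    def subgroup(self) -> PrincipalSubgroup:
        return principal_subgroup(self.principal_dx)

    @property
    def n_comorbidities(self) -> int:
        """Distinct additional-diagnosis codes (diagnosis level, not block level)."""
        return len(set(self.additional_dx))


def has_comorbidity(record: DischargeRecord) -> bool:
    """True iff the patient carries at least one additional diagnosis."""
    return len(record.additional_dx) > 0


@dataclass
class FilterReport:
    """Counts of records removed by each eligibility rule, applied in order."""

    n_input: int = 0
    removed_age: int = 0
    removed_year: int = 0
    removed_principal: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.removed_age - self.removed_year - self.removed_principal


@dataclass
class Cohort:
    """Eligible records plus the block table used as the item universe."""

    records: list[DischargeRecord]
    block_table: BlockTable
    filter_report: FilterReport = field(default_factory=FilterReport)

    def __len__(self) -> int:
        return len(self.records)

    def stratum(self, subgroup: PrincipalSubgroup) -> list[DischargeRecord]:
        if subgroup is PrincipalSubgroup.ALL:
            return list(self.records)
        return [r for r in self.records if r.subgroup is subgroup]


def build_cohort(
    records: Iterable[DischargeRecord],
    table: Optional[BlockTable] = None,
) -> Cohort:
    """Apply the eligibility rules and return the analyzable cohort.

    Rules, in order: age >= 19; discharge year within 2006–2016; principal
    diagnosis in one of the seven subgroups. Each removal is attributed to
    the first rule it violates, tallied in the cohort's :class:`FilterReport`.
    """
    table = table if table is not None else default_block_table()
    report = FilterReport()
    kept = []
    for rec in records:
        report.n_input += 1
        if rec.age < AGE_MIN:
            report.removed_age += 1
        elif not (YEAR_MIN <= rec.year <= YEAR_MAX):
            report.removed_year += 1
        elif rec.subgroup is PrincipalSubgroup.EXCLUDED:
            report.removed_principal += 1
        else:
            kept.append(rec)
    return Cohort(kept, table, report)


def prevalence_by_subgroup(cohort: Cohort) -> pd.DataFrame:
    """Per-subgroup comorbidity prevalence, with an ALL summary row.

    ``pct_with`` is 100·n_with/stratum size; ``pct_of_total`` is the stratum's
    share of the cohort. Empty strata are omitted. Percentages are rounded
    half away from zero to 2 decimals.
    """
    if not cohort.records:
        raise ValueError("cohort is empty")
    rows = []
    total = len(cohort)
    order = list(PrincipalSubgroup.strata()) + [PrincipalSubgroup.ALL]
    for sg in order:
        members = cohort.stratum(sg)
        n = len(members)
        if n == 0:
            continue
        n_with = sum(1 for r in members if has_comorbidity(r))
        rows.append(
            {
                "subgroup": sg.label,
                "n_with": n_with,
                "n_without": n - n_with,
                "n_total": n,
                "pct_with": round_half_up(100.0 * n_with / n, 2),
                "pct_of_total": round_half_up(100.0 * n / total, 2),
            }
        )
    return pd.DataFrame(rows)


def chi_square(observed: Union[pd.DataFrame, Sequence[Sequence[int]]]) -> tuple[float, int, float]:
    """Pearson chi-square on an r×c contingency table, no continuity correction.

    Returns ``(statistic, df, p_value)``. Requires at least a 2×2 table with
    strictly positive expected counts (zero marginals raise a ``ValueError``).
    """
    table = pd.DataFrame(observed).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("contingency table counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero marginal row or column")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Unequal-variance two-sample t-test from summary statistics.

    Welch–Satterthwaite degrees of freedom, two-sided p. The statistic is
    (mean1 − mean2) over the unpooled standard error, so group order fixes
    the sign.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def frequent_blocks(cohort: Cohort, min_percent: float = 1.0) -> pd.DataFrame:
    """Per-block comorbidity frequency over the whole cohort.

    Each patient contributes at most once to a block however many of their
    additional codes fall in it. ``percent`` is 100·count/cohort size; rows
    below ``min_percent`` are dropped; sorted by descending count then block id.
    """
    if not 0.0 <= min_percent <= 100.0:
        raise ValueError("min_percent must be in [0, 100]")
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    counts: dict[str, int] = {}
    for rec in cohort.records:
        seen = {
            blk.id
            for code in rec.additional_dx
            if (blk := cohort.block_table.assign(code)) is not None
        }
        for bid in seen:
            counts[bid] = counts.get(bid, 0) + 1
    rows = [
        {
            "block": bid,
            "label": cohort.block_table[bid].label,
            "count": cnt,
            "percent": round_half_up(100.0 * cnt / n, 2),
        }
        for bid, cnt in counts.items()
        if 100.0 * cnt / n >= min_percent
    ]
    rows.sort(key=lambda r: (-r["count"], r["block"]))
    return pd.DataFrame(rows, columns=["block", "label", "count", "percent"])


# --- CSV interface -----------------------------------------------------------

def _parse_additional(cell: object) -> tuple[ICDCode, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if not text:
        return ()
    return tuple(parse_icd_code(part) for part in text.split(";") if part.strip())


def read_records_csv(path: Union[str, Path]) -> list[DischargeRecord]:
    """Read discharge records from the package's CSV dialect.

    ``additional_dx`` is a semicolon-delimited ICD code list and may be empty.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"input CSV is missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            DischargeRecord(
                patient_id=row.patient_id,
                sex=row.sex,
                age=int(row.age),
                year=int(row.year),
                insurance=row.insurance,
                admission_route=row.admission_route,
                outcome=row.outcome,
                los=int(row.los),
                bed_size=row.bed_size,
                principal_dx=parse_icd_code(row.principal_dx),
                additional_dx=_parse_additional(row.additional_dx),
            )
        )
    return records


def write_records_csv(records: Iterable[DischargeRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "age": r.age,
            "year": r.year,
            "insurance": r.insurance,
            "admission_route": r.admission_route,
            "outcome": r.outcome,
            "los": r.los,
            "bed_size": r.bed_size,
            "principal_dx": str(r.principal_dx),
            "additional_dx": ";".join(str(c) for c in r.additional_dx),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def describe(cohort: Cohort, min_percent: float = 1.0) -> dict[str, pd.DataFrame]:
    """Descriptive summaries: demographics by comorbidity status, subgroup
    prevalence, and the frequent-comorbidity table."""
    demo_rows = []
    variables = [
        ("sex", lambda r: r.sex),
        ("age_group", _age_group),
        ("insurance", lambda r: r.insurance),
        ("admission_route", lambda r: r.admission_route),
        ("outcome", lambda r: r.outcome),
        ("bed_size", lambda r: r.bed_size),
    ]
    for name, getter in variables:
        counts: dict[str, list[int]] = {}
        for rec in cohort.records:
            level = str(getter(rec))
            counts.setdefault(level, [0, 0])[0 if has_comorbidity(rec) else 1] += 1
        table = pd.DataFrame(counts, index=["with", "without"]).T
        stat = df = p = float("nan")
        if table.shape[0] >= 2 and (table.sum(axis=0) > 0).all():
            try:
                stat, df, p = chi_square(table)
            except ValueError:
                pass
        for level, row in table.iterrows():
            demo_rows.append(
                {
                    "variable": name,
                    "level": level,
                    "n_with": int(row["with"]),
                    "n_without": int(row["without"]),
                    "pct_with": round_half_up(
                        100.0 * row["with"] / max(row.sum(), 1), 2
                    ),
                    "chi2": round_half_up(stat, 3) if stat == stat else stat,
                    "p": p,
                }
            )
    return {
        "demographics": pd.DataFrame(demo_rows),
        "subgroups": prevalence_by_subgroup(cohort),
        "frequent_blocks": frequent_blocks(cohort, min_percent=min_percent),
    }


def _age_group(rec: DischargeRecord) -> str:
    if rec.age < 45:
        return "19-44"
    if rec.age < 65:
        return "45-64"
    if rec.age < 75:
        return "65-74"
    return ">=75"
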
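"""Shared fixtures: block table, record factories, and reconstructed strata."""

from __future__ import annotations

import pytest

from comorbmine import (
    Cohort,
    DischargeRecord,
    build_cohort,
    default_block_table,
    parse_icd_code,
)


@pytest.fixture(scope="session")
def block_table():
    return default_block_table()


def make_record(
    principal: str,
    additional: list[str] = (),
    *,
    patient_id: str = "p0",
    age: int = 50,
    year: int = 2010,
    sex: str = "female",
) -> DischargeRecord:
    return DischargeRecord(
        patient_id=patient_id,
        sex=sex,
        age=age,
        year=year,
        insurance="national_health",
        admission_route="outpatient",
        outcome="improved",
        los=10,
        bed_size="500-999",
        principal_dx=parse_icd_code(principal),
        additional_dx=tuple(parse_icd_code(c) for c in additional),
    )


def make_stratum(principal: str, n: int, groups: list[tuple[int, list[str]]]) -> list[DischargeRecord]:
    """``groups`` assigns additional-code lists to blocks of patients; the
    remainder up to ``n`` get no comorbidity."""
    records = []
    i = 0
    for count, codes in groups:
        for _ in range(count):
            records.append(make_record(principal, codes, patient_id=f"{principal}-{i}"))
            i += 1
    assert i <= n, "groups exceed stratum size"
    for _ in range(n - i):
        records.append(make_record(principal, [], patient_id=f"{principal}-{i}"))
        i += 1
    return records


@pytest.fixture(scope="session")
def dementia_cohort(block_table) -> Cohort:
    """A dementia stratum whose pairwise block counts reproduce the reference
    worked example: n=1361, |E10-E14|=238, |I10-I15|=436, |I60-I69|=267,
    |F00-F03 item|=27, |G30-G32|=39, overlaps E∩I=152, I∩I60=118, F∩G=14."""
    groups = [
        (152, ["E10", "I10"]),
        (86, ["E10"]),
        (118, ["I10", "I60"]),
        (166, ["I10"]),
        (149, ["I60"]),
        (14, ["F00", "G30"]),
        (13, ["F00"]),
        (25, ["G30"]),
    ]
    return build_cohort(make_stratum("F03", 1361, groups), block_table)
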
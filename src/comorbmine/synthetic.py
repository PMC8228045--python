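"""Synthetic discharge-record generator with plantable block–block associations.

The source registry is restricted, so the pipeline ships a generator that
emulates the cohort's *statistical* structure: the principal-diagnosis
subgroup mix, per-block marginal comorbidity prevalences, and — the part the
mining step is supposed to recover — planted pairwise dependencies with a
specified lift.

For a planted pair (A, B) with marginals pA, pB and target lift L, presence
indicators are drawn from the 2×2 law

    P11 = L·pA·pB,  P10 = pA − P11,  P01 = pB − P11,  P00 = 1 − pA − pB + P11,

which keeps both marginals exact and makes every rule measure available in
closed form: support = L·pA·pB, confidence(A→B) = L·pB, lift = L and
IS = L·sqrt(pA·pB). All other blocks are independent Bernoulli draws, so an
unplanted pair has true lift 1.

The generator is a stand-in, not a claim about the source registry: it has
no higher-order dependence, no demographic–comorbidity coupling, and emits
one representative code per present block.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort import DischargeRecord
from .icd import BlockTable, ICDCode, PrincipalSubgroup, default_block_table, parse_icd_code

__all__ = [
    "DEFAULT_MARGINALS",
    "DEFAULT_SUBGROUP_MIX",
    "MarginalSpec",
    "PlantedAssociation",
    "SyntheticConfig",
    "joint_bernoulli",
    "expected_metrics",
    "lift_standard_error",
    "calibrate_marginals",
    "generate_cohort",
]

MarginalSpec = dict[str, float]

# Default marginal prevalences: the observed frequencies of the 35 comorbidity
# blocks carried by more than 1% of the reference cohort (counts over 20,690).
_REFERENCE_N = 20690
_REFERENCE_COUNTS = {
    "I10-I15": 2289, "F30-F39": 1725, "E10-E14": 1651, "K20-K31": 1456,
    "F40-F48": 1383, "F00-F03": 1361, "K70-K77": 1098, "G40-G47": 797,
    "F10-F19": 662, "E70-E90": 590, "F20-F29": 575, "K55-K64": 552,
    "I60-I69": 540, "F60-F69": 523, "M40-M54": 520, "Z80-Z99": 503,
    "L20-L30": 423, "R50-R69": 398, "M60-M79": 358, "M00-M25": 344,
    "N30-N39": 340, "F50-F59": 329, "E00-E07": 316, "J00-J06": 314,
    "I30-I52": 271, "B35-B49": 265, "K00-K14": 263, "G20-G26": 262,
    "J40-J47": 254, "M80-M94": 238, "I20-I25": 236, "L80-L99": 227,
    "N40-N51": 219, "J09-J18": 211, "J30-J39": 208,
}
DEFAULT_MARGINALS: MarginalSpec = {
    k: v / _REFERENCE_N for k, v in _REFERENCE_COUNTS.items()
}

# Subgroup mix of the reference cohort (stratum sizes over 20,690).
_SUBGROUP_COUNTS = {
    PrincipalSubgroup.DEMENTIA: 1361,
    PrincipalSubgroup.SUBSTANCE_USE: 3457,
    PrincipalSubgroup.SCHIZOPHRENIA: 4539,
    PrincipalSubgroup.MOOD: 6569,
    PrincipalSubgroup.NEUROTIC: 4209,
    PrincipalSubgroup.BEHAVIORAL_SYNDROMES: 305,
    PrincipalSubgroup.ADULT_PERSONALITY: 250,
}
DEFAULT_SUBGROUP_MIX: dict[PrincipalSubgroup, float] = {
    k: v / _REFERENCE_N for k, v in _SUBGROUP_COUNTS.items()
}

_PRINCIPAL_CODE = {
    PrincipalSubgroup.DEMENTIA: "F03",
    PrincipalSubgroup.SUBSTANCE_USE: "F10",
    PrincipalSubgroup.SCHIZOPHRENIA: "F20",
    PrincipalSubgroup.MOOD: "F31",
    PrincipalSubgroup.NEUROTIC: "F41",
    PrincipalSubgroup.BEHAVIORAL_SYNDROMES: "F51",
    PrincipalSubgroup.ADULT_PERSONALITY: "F60",
}

# Demographic marginals of the reference cohort (independent of everything else).
_SEX = (("male", 0.4275), ("female", 0.5725))
_INSURANCE = (("national_health", 0.7965), ("medicaid1", 0.1484),
              ("medicaid2", 0.0242), ("other", 0.0309))
_ROUTE = (("emergency", 0.3281), ("outpatient", 0.6713), ("other", 0.0006))
_OUTCOME = (("improved", 0.9059), ("not_improved", 0.0858),
            ("death", 0.0054), ("other", 0.0029))
_BED = (("100-299", 0.2319), ("300-499", 0.1284), ("500-999", 0.4865),
        (">=1000", 0.1532))


@dataclass(frozen=True)
class PlantedAssociation:
    """A block pair whose presence indicators are coupled to a target lift."""

    block_a: str
    block_b: str
    target_lift: float

    def __post_init__(self) -> None:
        if self.block_a == self.block_b:
            raise ValueError("planted association needs two distinct blocks")
        if self.target_lift < 0:
            raise ValueError("target lift must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything the generator needs; the seed is mandatory."""

    n: int
    seed: int
    subgroup_mix: dict[PrincipalSubgroup, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_MIX)
    )
    marginals: MarginalSpec = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    planted: tuple[PlantedAssociation, ...] = ()
    year_range: tuple[int, int] = (2006, 2016)

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        total = sum(self.subgroup_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"subgroup mix must sum to 1, got {total}")
        for p in self.marginals.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("marginal prevalences must be in [0, 1]")
        seen: set[str] = set()
        for pa in self.planted:
            if pa.block_a in seen or pa.block_b in seen:
                raise ValueError("planted pairs must be pairwise disjoint")
            seen.update((pa.block_a, pa.block_b))
            _cell_probabilities(
                self.marginals[pa.block_a], self.marginals[pa.block_b], pa.target_lift
            )  # raises if infeasible


def _cell_probabilities(p_a: float, p_b: float, L: float) -> tuple[float, float, float, float]:
    """The 2×2 law (P11, P10, P01, P00); raises with the violated bound."""
    p11 = L * p_a * p_b
    if p11 > min(p_a, p_b) + 1e-12:
        raise ValueError(
            f"infeasible lift {L}: L*pA*pB = {p11:.6f} exceeds min(pA, pB) = {min(p_a, p_b):.6f}"
        )
    p00 = 1.0 - p_a - p_b + p11
    if p00 < -1e-12:
        raise ValueError(
            f"infeasible lift {L}: 1 - pA - pB + L*pA*pB = {p00:.6f} is negative"
        )
    return p11, p_a - p11, p_b - p11, max(p00, 0.0)


def joint_bernoulli(
    p_a: float, p_b: float, L: float, rng: np.random.Generator, size: Optional[int] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw coupled presence indicators (a, b) with marginals pA, pB and lift L.

    With ``size=None`` returns a pair of scalars (0/1 arrays of shape ()).
    """
    cells = _cell_probabilities(p_a, p_b, L)
    draw = rng.choice(4, size=size, p=cells)
    a = np.where((draw == 0) | (draw == 1), 1, 0)
    b = np.where((draw == 0) | (draw == 2), 1, 0)
    return a, b


def expected_metrics(p_a: float, p_b: float, L: float) -> tuple[float, float, float, float]:
    """Closed-form (support, confidence A→B, lift, IS scale) of the planted law."""
    _cell_probabilities(p_a, p_b, L)
    sup = L * p_a * p_b
    return sup, L * p_b, L, L * math.sqrt(p_a * p_b)


def lift_standard_error(p_a: float, p_b: float, L: float, n: int) -> float:
    """Delta-method standard error of the empirical lift of a planted pair.

    Treats the 2×2 cell counts as multinomial(n) and propagates through
    lift = p11/(pA·pB) on the log scale: SE(lift) ≈ L·sd(log lift).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    cells = np.array(_cell_probabilities(p_a, p_b, L))
    p11 = cells[0]
    if p11 <= 0:
        raise ValueError("lift SE undefined when the joint probability is zero")
    # gradient of log lift wrt the four cell probabilities
    g = np.array([1 / p11 - 1 / p_a - 1 / p_b, -1 / p_a, -1 / p_b, 0.0])
    var_log = (np.sum(cells * g**2) - np.sum(cells * g) ** 2) / n
    return L * math.sqrt(max(var_log, 0.0))


def calibrate_marginals(
    marginals: MarginalSpec, target_mean: float, tolerance: float = 0.05
) -> MarginalSpec:
    """Scale all marginals so the expected comorbidity-block count per patient
    (the sum of the prevalences, blocks being independent) hits ``target_mean``.

    Raises if the scaling would push any prevalence above 1 or if the achieved
    expected mean misses the target by more than ``tolerance`` (relative).
    """
    current = sum(marginals.values())
    if current <= 0:
        raise ValueError("cannot calibrate all-zero marginals")
    factor = target_mean / current
    scaled = {k: v * factor for k, v in marginals.items()}
    if any(p > 1.0 for p in scaled.values()):
        raise ValueError("calibration would require a prevalence above 1")
    achieved = sum(scaled.values())
    if abs(achieved - target_mean) > tolerance * target_mean:
        raise ValueError(
            f"calibration achieved mean {achieved:.4f}, outside {tolerance:.0%} of {target_mean}"
        )
    return scaled


def generate_cohort(
    config: SyntheticConfig, table: Optional[BlockTable] = None
) -> list[DischargeRecord]:
    """Generate ``config.n`` discharge records, reproducibly from ``config.seed``.

    Planted pairs are drawn from their coupled 2×2 laws, all other blocks as
    independent Bernoulli(marginal). A present block is emitted as its start
    code in ``additional_dx`` (or the next category when the start would
    collide with the patient's principal code).
    """
    table = table if table is not None else default_block_table()
    rng = np.random.default_rng(config.seed)
    n = config.n

    subgroups = list(config.subgroup_mix.keys())
    mix = np.array([config.subgroup_mix[s] for s in subgroups])
    sg_idx = rng.choice(len(subgroups), size=n, p=mix / mix.sum())

    planted_blocks = {b for pa in config.planted for b in (pa.block_a, pa.block_b)}
    independent = [b for b in config.marginals if b not in planted_blocks]

    presence: dict[str, np.ndarray] = {}
    for pa in config.planted:
        a, b = joint_bernoulli(
            config.marginals[pa.block_a], config.marginals[pa.block_b],
            pa.target_lift, rng, size=n,
        )
        presence[pa.block_a] = a
        presence[pa.block_b] = b
    for block in independent:
        presence[block] = (rng.random(n) < config.marginals[block]).astype(int)
    block_order = [b.id for b in table if b.id in presence]

    sex = rng.choice([s for s, _ in _SEX], size=n, p=[p for _, p in _SEX])
    age = np.clip(np.rint(rng.normal(48.3, 17.7, size=n)), 19, 99).astype(int)
    year = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)
    insurance = rng.choice([s for s, _ in _INSURANCE], size=n, p=[p for _, p in _INSURANCE])
    route = rng.choice([s for s, _ in _ROUTE], size=n, p=[p for _, p in _ROUTE])
    outcome = rng.choice([s for s, _ in _OUTCOME], size=n, p=[p for _, p in _OUTCOME])
    bed = rng.choice([s for s, _ in _BED], size=n, p=[p for _, p in _BED])
    los = np.rint(rng.lognormal(mean=2.8, sigma=1.1, size=n)).astype(int)

    records = []
    for i in range(n):
        sg = subgroups[sg_idx[i]]
        principal = parse_icd_code(_PRINCIPAL_CODE[sg])
        additional = tuple(
            _representative_code(table[bid], principal)
            for bid in block_order
            if presence[bid][i]
        )
        records.append(
            DischargeRecord(
                patient_id=f"S{i:06d}",
                sex=str(sex[i]),
                age=int(age[i]),
                year=int(year[i]),
                insurance=str(insurance[i]),
                admission_route=str(route[i]),
                outcome=str(outcome[i]),
                los=int(los[i]),
                bed_size=str(bed[i]),
                principal_dx=principal,
                additional_dx=additional,
            )
        )
    return records


def _representative_code(block, principal: ICDCode) -> ICDCode:
    """The block's start code, nudged to the next category if it would
    duplicate the principal diagnosis."""
    code = block.start
    if code.key == principal.key:
        bumped = ICDCode(code.letter, code.category + 1)
        code = bumped if block.contains(bumped) else code
    return code
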
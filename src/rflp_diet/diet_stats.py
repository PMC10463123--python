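"""Diet summary statistics over per-sample identification records.

Implements grouped success proportions with Wilson 95% intervals,
relative-difference arithmetic on group probabilities, paired-sample
agreement rates, the species-per-sample mean, the per-species
faecal-identification deviance table (with a minimum-sample filter),
a Pearson chi-squared contingency test, and ordinary least-squares
regression of deviance on species traits.

All percentages come from exact integer counts; rounding (half-up)
happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SampleRecord",
    "PairedSample",
    "SpeciesTraits",
    "DevianceRecord",
    "proportion_summary",
    "relative_difference",
    "paired_match_rates",
    "build_paired_samples",
    "mean_species_per_sample",
    "faecal_deviance_table",
    "pearson_chi_squared",
    "simple_linear_regression",
    "round_half_up",
]

SAMPLE_TYPES = ("faecal", "regurgitate")
SEXES = ("female", "male")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (presentation convention)."""
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return int(v) if ndigits == 0 else v


@dataclass(frozen=True)
class SampleRecord:
    """One faecal or regurgitate sample and its identification outcome.

    ``sequenced`` marks samples whose identification needed sequencing
    on top of the banding pattern (ambiguous or faint patterns).
    Invariants: identified implies amplified; a non-empty species set
    implies identified.
    """

    sample_id: str
    grasshopper_id: str
    mesocosm_id: str
    occasion: int
    sample_type: str
    sex: str
    amplified: bool
    identified: bool = False
    species_set: frozenset[str] = field(default_factory=frozenset)
    sequenced: bool = False

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"sample_type must be one of {SAMPLE_TYPES}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}")
        if not 1 <= self.occasion:
            raise ValueError("occasion must be >= 1")
        if self.identified and not self.amplified:
            raise ValueError(f"{self.sample_id}: identified but not amplified")
        object.__setattr__(self, "species_set", frozenset(self.species_set))
        if self.species_set and not self.identified:
            raise ValueError(f"{self.sample_id}: species assigned but not identified")


@dataclass(frozen=True)
class PairedSample:
    """Faecal and regurgitate identifications from one grasshopper and occasion."""

    grasshopper_id: str
    occasion: int
    faecal_set: frozenset[str]
    regurgitate_set: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "faecal_set", frozenset(self.faecal_set))
        object.__setattr__(self, "regurgitate_set", frozenset(self.regurgitate_set))
        if not self.faecal_set or not self.regurgitate_set:
            raise ValueError("paired samples require a non-empty species set on both sides")


@dataclass(frozen=True)
class SpeciesTraits:
    species_id: str
    provenance: str  # native | exotic
    functional_group: str  # herbaceous | woody
    specific_leaf_area: float

    def __post_init__(self) -> None:
        if self.provenance not in ("native", "exotic"):
            raise ValueError("provenance must be 'native' or 'exotic'")
        if self.functional_group not in ("herbaceous", "woody"):
            raise ValueError("functional_group must be 'herbaceous' or 'woody'")
        if self.specific_leaf_area <= 0:
            raise ValueError("specific_leaf_area must be positive")


@dataclass(frozen=True)
class DevianceRecord:
    """Per-species departure of faecal identification share from expectation."""

    species_id: str
    n_faecal_ids: int
    n_total_ids: int
    observed_prop: float
    expected_prop: float
    deviance: float
    ci_low: float
    ci_high: float


def _wilson(successes: int, total: int) -> tuple[float, float]:
    if total == 0:
        return (float("nan"), float("nan"))
    lo, hi = proportion_confint(successes, total, alpha=0.05, method="wilson")
    p = successes / total
    # guarantee containment of the point estimate despite float rounding
    return max(0.0, min(float(lo), p)), min(1.0, max(float(hi), p))


def _as_predicate(success: str | Callable[[SampleRecord], bool]) -> Callable[[SampleRecord], bool]:
    if callable(success):
        return success
    attr = success
    return lambda r: bool(getattr(r, attr))


def proportion_summary(
    records: Sequence[SampleRecord],
    group_by: str = "both",
    success: str | Callable[[SampleRecord], bool] = "amplified",
) -> pd.DataFrame:
    """Success proportion per group with a Wilson 95% interval.

    ``group_by`` is one of ``sample_type``, ``sex``, ``both`` or
    ``overall``. ``success`` is a record attribute name or predicate;
    restrict the denominator by filtering ``records`` first (e.g.
    identified-given-amplified). Empty groups are kept with NaN
    proportion and ``flagged`` set.
    """
    if not records:
        raise ValueError("records must be non-empty")
    pred = _as_predicate(success)

    if group_by == "overall":
        keys: list[tuple] = [("all",)]
        key_of = lambda r: ("all",)
        names = ["group"]
    elif group_by == "sample_type":
        keys = [(t,) for t in SAMPLE_TYPES]
        key_of = lambda r: (r.sample_type,)
        names = ["sample_type"]
    elif group_by == "sex":
        keys = [(s,) for s in SEXES]
        key_of = lambda r: (r.sex,)
        names = ["sex"]
    elif group_by == "both":
        keys = [(t, s) for t in SAMPLE_TYPES for s in SEXES]
        key_of = lambda r: (r.sample_type, r.sex)
        names = ["sample_type", "sex"]
    else:
        raise ValueError(f"unknown group_by {group_by!r}")

    rows = []
    for key in keys:
        members = [r for r in records if key_of(r) == key]
        n_total = len(members)
        n_success = sum(pred(r) for r in members)
        prop = n_success / n_total if n_total else float("nan")
        lo, hi = _wilson(n_success, n_total)
        rows.append(
            dict(zip(names, key))
            | {
                "n_success": n_success,
                "n_total": n_total,
                "proportion": prop,
                "ci_low": lo,
                "ci_high": hi,
                "flagged": n_total == 0,
            }
        )
    return pd.DataFrame(rows)


class RelativeDifference(NamedTuple):
    value: float  # unrounded percent
    rounded: int  # half-up integer percent


def relative_difference(p_a: float, p_b: float) -> RelativeDifference:
    """Percent by which p_a exceeds p_b: 100 * (p_a - p_b) / p_b."""
    if p_b <= 0:
        raise ValueError("reference proportion p_b must be positive")
    value = 100.0 * (p_a - p_b) / p_b
    return RelativeDifference(value, int(round_half_up(value)))


class PairedMatchRates(NamedTuple):
    n_pairs: int
    exact_count: int
    exact_pct: int
    partial_count: int
    partial_pct: int


def paired_match_rates(pairs: Sequence[PairedSample]) -> PairedMatchRates:
    """Agreement between paired faecal and regurgitate identifications.

    Exact means set equality; partial means a non-empty intersection, so
    every exact pair also counts as partial ("at least partial").
    Percentages are of the number of pairs, rounded half-up to whole
    percent.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    n = len(pairs)
    exact = sum(p.faecal_set == p.regurgitate_set for p in pairs)
    partial = sum(bool(p.faecal_set & p.regurgitate_set) for p in pairs)
    return PairedMatchRates(
        n,
        exact,
        int(round_half_up(100.0 * exact / n)),
        partial,
        int(round_half_up(100.0 * partial / n)),
    )


def build_paired_samples(records: Iterable[SampleRecord]) -> list[PairedSample]:
    """Pair faecal with regurgitate records per (grasshopper, occasion).

    Only records with a non-empty identified species set qualify; a pair
    forms when both types are present for the same grasshopper and
    occasion.
    """
    by_key: dict[tuple[str, int], dict[str, frozenset[str]]] = {}
    for r in records:
        if not r.species_set:
            continue
        by_key.setdefault((r.grasshopper_id, r.occasion), {})[r.sample_type] = r.species_set
    pairs = []
    for (gid, occ), sets in sorted(by_key.items()):
        if "faecal" in sets and "regurgitate" in sets:
            pairs.append(PairedSample(gid, occ, sets["faecal"], sets["regurgitate"]))
    return pairs


def mean_species_per_sample(count_distribution: dict[int, int]) -> float:
    """Weighted mean species count, reported to two decimals (half-up)."""
    if not count_distribution:
        raise ValueError("count distribution is empty")
    if any(k < 1 for k in count_distribution):
        raise ValueError("species counts must be >= 1")
    total = sum(count_distribution.values())
    if total == 0:
        raise ValueError("no samples in distribution")
    mean = sum(k * n for k, n in count_distribution.items()) / total
    return round_half_up(mean, 2)


def faecal_deviance_table(
    records: Sequence[SampleRecord],
    expected_prop: float = 0.66,
    min_samples: int = 5,
) -> list[DevianceRecord]:
    """Per-species share of identifications that came from faecal samples.

    One identification event per (sample, species) pair. Species with
    fewer than ``min_samples`` total identifications are excluded.
    Deviance is the observed faecal share minus ``expected_prop`` (a
    configured constant, not derived here); the 95% interval on the
    observed share is Wilson.
    """
    if not 0 <= expected_prop <= 1:
        raise ValueError("expected_prop must be in [0, 1]")
    totals: dict[str, int] = {}
    faecal: dict[str, int] = {}
    for r in records:
        for sid in r.species_set:
            totals[sid] = totals.get(sid, 0) + 1
            if r.sample_type == "faecal":
                faecal[sid] = faecal.get(sid, 0) + 1
    out = []
    for sid in sorted(totals):
        n_total = totals[sid]
        if n_total < min_samples:
            continue
        n_faecal = faecal.get(sid, 0)
        prop = n_faecal / n_total
        lo, hi = _wilson(n_faecal, n_total)
        out.append(
            DevianceRecord(sid, n_faecal, n_total, prop, expected_prop,
                           prop - expected_prop, lo, hi)
        )
    return out


class ChiSquaredResult(NamedTuple):
    statistic: float
    df: int
    p_value: float


def pearson_chi_squared(table: Sequence[Sequence[float]]) -> ChiSquaredResult:
    """Pearson chi-squared test of independence on a two-way count table."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("table has a zero row or column margin")
    res = sps.chi2_contingency(arr, correction=False)
    return ChiSquaredResult(float(res.statistic), int(res.dof), float(res.pvalue))


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    slope_t: float
    slope_p: float
    n: int


def simple_linear_regression(
    response: Sequence[float], predictor: Sequence[float]
) -> RegressionResult:
    """OLS of response on a single predictor (numeric or 0/1 group codes).

    Returns the slope, intercept, the slope's t statistic (slope over
    its standard error) and a two-sided p value on n - 2 degrees of
    freedom.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("response and predictor must be 1-D and the same length")
    n = len(y)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if np.allclose(x, x[0]):
        raise ValueError("predictor is constant")
    fit = sps.linregress(x, y)
    t = fit.slope / fit.stderr if fit.stderr > 0 else float("inf")
    return RegressionResult(float(fit.slope), float(fit.intercept), float(t),
                            float(fit.pvalue), n)
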
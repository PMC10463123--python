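"""Identify host species sets from observed gel banding patterns.

An observation is matched against the expected patterns of every
community subset up to a mixture limit. Exact explanations of minimal
cardinality win (parsimony); several tied explanations mean the call is
ambiguous and would need sequencing; when nothing matches exactly, the
best partial explanation is reported together with the unexplained
bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .digest_engine import ReferenceDatabase
from .panel_design import GelModel, visible_bands

__all__ = [
    "BandObservation",
    "MatchResult",
    "IdentificationResult",
    "expected_band_pattern",
    "pattern_explains",
    "identify_sample",
]


@dataclass(frozen=True)
class BandObservation:
    """Observed band sizes for one sample, keyed by enzyme.

    ``faint`` optionally flags per-band faintness, parallel to the band
    lists; faint bands can be excluded from matching.
    """

    sample_id: str
    bands: Mapping[str, tuple[float, ...]]
    faint: Mapping[str, tuple[bool, ...]] | None = None

    def __post_init__(self) -> None:
        frozen = {k: tuple(v) for k, v in self.bands.items()}
        object.__setattr__(self, "bands", frozen)
        if not frozen:
            raise ValueError(f"{self.sample_id}: observation lists no enzymes")
        for enz, sizes in frozen.items():
            if any(s <= 0 for s in sizes):
                raise ValueError(f"{self.sample_id}/{enz}: non-positive band size")
        if self.faint is not None:
            ffrozen = {k: tuple(v) for k, v in self.faint.items()}
            object.__setattr__(self, "faint", ffrozen)
            for enz, flags in ffrozen.items():
                if len(flags) != len(frozen.get(enz, ())):
                    raise ValueError(
                        f"{self.sample_id}/{enz}: faint flags do not align with bands"
                    )

    def effective_bands(self, include_faint: bool = True) -> dict[str, list[float]]:
        """Band lists sorted descending, optionally with faint bands removed."""
        out: dict[str, list[float]] = {}
        for enz, sizes in self.bands.items():
            if not include_faint and self.faint and enz in self.faint:
                sizes = tuple(
                    s for s, is_faint in zip(sizes, self.faint[enz]) if not is_faint
                )
            out[enz] = sorted(sizes, reverse=True)
        return out


@dataclass(frozen=True)
class MatchResult:
    """How well an expected pattern explains an observed band list."""

    kind: str  # exact | partial | none
    explained: int
    unexplained_observed: int
    unmatched_expected: int


@dataclass(frozen=True)
class IdentificationResult:
    sample_id: str
    status: str  # unique | ambiguous | no_match
    candidate_sets: tuple[frozenset[str], ...]
    best_partial: frozenset[str] | None = None
    unexplained_bands: Mapping[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status == "unique" and len(self.candidate_sets) != 1:
            raise ValueError("unique status requires exactly one candidate set")
        if self.status == "ambiguous" and len(self.candidate_sets) < 2:
            raise ValueError("ambiguous status requires >= 2 candidate sets")
        object.__setattr__(
            self, "unexplained_bands", {k: tuple(v) for k, v in self.unexplained_bands.items()}
        )

    @property
    def requires_sequencing(self) -> bool:
        return self.status != "unique"


def expected_band_pattern(
    species_set: frozenset[str] | set[str],
    db: ReferenceDatabase,
    gel: GelModel,
) -> dict[str, list[int]]:
    """Per-enzyme bands of a species mixture: pooled fragments, gel-filtered.

    The members' fragment lists are concatenated per enzyme, then passed
    through the detection window and comigration merge, so shared or
    near-identical fragments collapse into single bands exactly as they
    would on a gel.
    """
    if not species_set:
        raise ValueError("species_set must be non-empty")
    unknown = sorted(set(species_set) - set(db.entries))
    if unknown:
        raise KeyError(f"species not in database {db.community_id}: {', '.join(unknown)}")
    pattern: dict[str, list[int]] = {}
    for enzyme in db.panel:
        pooled: list[int] = []
        for sid in species_set:
            pooled.extend(db.entries[sid].fragments[enzyme])
        pattern[enzyme] = visible_bands(pooled, gel)
    return pattern


def _greedy_match(
    observed: Sequence[float], expected: Sequence[float], gel: GelModel
) -> tuple[list[bool], list[bool]]:
    """One-to-one greedy matching, largest first; returns consumption flags."""
    obs_matched = [False] * len(observed)
    exp_used = [False] * len(expected)
    for i, ob in enumerate(observed):
        for j, ex in enumerate(expected):
            if not exp_used[j] and gel.comigrates(ob, ex):
                obs_matched[i] = True
                exp_used[j] = True
                break
    return obs_matched, exp_used


def pattern_explains(
    observed: Sequence[float], expected: Sequence[float], gel: GelModel
) -> MatchResult:
    """Classify how an expected band list accounts for an observation.

    Both lists must be sorted descending. Matching is greedy and
    one-to-one from largest to smallest: each observed band consumes the
    largest unconsumed expected band it comigrates with. ``exact``
    requires every observed band explained and every expected band
    consumed; ``none`` means zero matches; otherwise ``partial``.
    """
    observed = list(observed)
    expected = list(expected)
    obs_matched, exp_used = _greedy_match(observed, expected, gel)
    explained = sum(obs_matched)
    unexplained = len(observed) - explained
    unmatched = len(expected) - sum(exp_used)
    if unexplained == 0 and unmatched == 0:
        kind = "exact"
    elif explained == 0:
        kind = "none"
    else:
        kind = "partial"
    return MatchResult(kind, explained, unexplained, unmatched)


def identify_sample(
    obs: BandObservation,
    db: ReferenceDatabase,
    gel: GelModel,
    max_mixture: int = 4,
    include_faint: bool = True,
) -> IdentificationResult:
    """Find the species set(s) whose pooled pattern explains an observation.

    All community subsets of size 1..max_mixture are enumerated. A
    subset is an exact explanation when its expected pattern is an exact
    match for every enzyme present in the observation. Candidate sets
    are the exact explanations of minimal cardinality: one gives status
    ``unique``, several give ``ambiguous``. With no exact explanation
    the status is ``no_match`` and ``best_partial`` holds the subset
    maximising explained observed bands (ties: smaller subset, fewer
    unmatched expected bands, lexicographic species order), with the
    observed bands it leaves unexplained.
    """
    observed = obs.effective_bands(include_faint)
    extra = sorted(set(observed) - set(db.panel))
    if extra:
        raise KeyError(
            f"{obs.sample_id}: observation uses enzyme(s) not in the panel: "
            f"{', '.join(extra)}"
        )
    species = sorted(db.entries)
    exact: list[frozenset[str]] = []
    scored: list[tuple[int, int, int, tuple[str, ...]]] = []
    for size in range(1, min(max_mixture, len(species)) + 1):
        for combo in combinations(species, size):
            pattern = expected_band_pattern(frozenset(combo), db, gel)
            results = {
                enz: pattern_explains(observed[enz], pattern[enz], gel)
                for enz in observed
            }
            if all(r.kind == "exact" for r in results.values()):
                exact.append(frozenset(combo))
            explained = sum(r.explained for r in results.values())
            unmatched = sum(r.unmatched_expected for r in results.values())
            scored.append((-explained, size, unmatched, combo))
    if exact:
        min_card = min(len(s) for s in exact)
        candidates = tuple(
            sorted((s for s in exact if len(s) == min_card), key=sorted)
        )
        status = "unique" if len(candidates) == 1 else "ambiguous"
        return IdentificationResult(obs.sample_id, status, candidates)
    # best partial explanation
    scored.sort()
    best_combo = scored[0][3]
    pattern = expected_band_pattern(frozenset(best_combo), db, gel)
    unexplained: dict[str, tuple[float, ...]] = {}
    for enz in observed:
        matched, _ = _greedy_match(observed[enz], pattern[enz], gel)
        leftover = tuple(b for b, ok in zip(observed[enz], matched) if not ok)
        if leftover:
            unexplained[enz] = leftover
    return IdentificationResult(
        obs.sample_id,
        "no_match",
        (),
        best_partial=frozenset(best_combo),
        unexplained_bands=unexplained,
    )
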
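"""Gel visibility model and minimal discriminating enzyme-panel search.

The GelModel encodes what an agarose gel can resolve: a detection
window (defaults 25-766 bp, the ladder range) and a relative sizing
tolerance under which two fragments comigrate as one band. Panel
selection is an exhaustive, deterministic search over enzyme subsets
ordered by size then name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .digest_engine import FragmentProfile

__all__ = [
    "GelModel",
    "PanelReport",
    "visible_bands",
    "bands_equal",
    "profiles_distinguishable",
    "select_panel",
]


def _round_half_up(x: float) -> int:
    import math

    return math.floor(x + 0.5)


@dataclass(frozen=True)
class GelModel:
    """Detection window plus comigration rule for band comparisons.

    Two sizes a, b comigrate when ``|a - b| <= rel_tol * max(a, b)``.
    """

    min_size: float = 25.0
    max_size: float = 766.0
    rel_tol: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.min_size < self.max_size:
            raise ValueError(
                f"need 0 < min_size < max_size, got [{self.min_size}, {self.max_size}]"
            )
        if not 0 <= self.rel_tol < 1:
            raise ValueError(f"rel_tol must be in [0, 1), got {self.rel_tol}")

    def comigrates(self, a: float, b: float) -> bool:
        return abs(a - b) <= self.rel_tol * max(a, b)

    def in_window(self, size: float) -> bool:
        return self.min_size <= size <= self.max_size


@dataclass(frozen=True)
class PanelReport:
    """Outcome of a panel search over one community."""

    panel: tuple[str, ...]
    distinguishable_pairs: int
    total_pairs: int
    indistinguishable: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.distinguishable_pairs + len(self.indistinguishable) != self.total_pairs:
            raise ValueError("pair counts are inconsistent")

    @property
    def fully_discriminating(self) -> bool:
        return self.distinguishable_pairs == self.total_pairs

    def to_dict(self) -> dict:
        return {
            "panel": list(self.panel),
            "distinguishable_pairs": self.distinguishable_pairs,
            "total_pairs": self.total_pairs,
            "fully_discriminating": self.fully_discriminating,
            "indistinguishable": [list(p) for p in self.indistinguishable],
        }


def visible_bands(fragments: Sequence[float], gel: GelModel,
                  transitive: bool = False) -> list[int]:
    """Bands a gel would show for a set of fragment lengths, descending.

    Fragments outside the detection window are dropped; comigrating
    fragments merge into one band whose size is the rounded mean of its
    members. By default a fragment joins the current band when it
    comigrates with the band's largest (anchor) member; ``transitive``
    instead chains on the previous member, merging more aggressively.
    """
    if len(fragments) == 0:
        raise ValueError("fragments must be non-empty")
    kept = sorted((f for f in fragments if gel.in_window(f)), reverse=True)
    bands: list[int] = []
    group: list[float] = []
    for f in kept:
        if not group:
            group = [f]
            continue
        ref = group[-1] if transitive else group[0]
        if gel.comigrates(ref, f):
            group.append(f)
        else:
            bands.append(_round_half_up(sum(group) / len(group)))
            group = [f]
    if group:
        bands.append(_round_half_up(sum(group) / len(group)))
    return bands


def bands_equal(a: Sequence[float], b: Sequence[float], gel: GelModel) -> bool:
    """Positional band-list equality under the comigration tolerance."""
    return len(a) == len(b) and all(gel.comigrates(x, y) for x, y in zip(a, b))


def profiles_distinguishable(
    a: FragmentProfile,
    b: FragmentProfile,
    gel: GelModel,
    enzymes: Sequence[str] | None = None,
    transitive: bool = False,
) -> bool:
    """True when at least one enzyme's visible band lists differ.

    ``enzymes`` restricts the comparison to a sub-panel; by default the
    profiles' full (shared) panel is used.
    """
    if enzymes is None:
        if set(a.panel) != set(b.panel):
            raise ValueError(
                f"panel mismatch: {sorted(a.panel)} vs {sorted(b.panel)}"
            )
        enzymes = sorted(a.panel)
    for enzyme in enzymes:
        if enzyme not in a.fragments or enzyme not in b.fragments:
            raise ValueError(f"enzyme {enzyme!r} missing from a profile")
        ba = visible_bands(a.fragments[enzyme], gel, transitive)
        bb = visible_bands(b.fragments[enzyme], gel, transitive)
        if not bands_equal(ba, bb, gel):
            return True
    return False


def select_panel(
    profiles: Mapping[str, FragmentProfile],
    candidates: Sequence[str] | None = None,
    gel: GelModel = GelModel(),
    max_enzymes: int = 3,
    transitive: bool = False,
) -> PanelReport:
    """Smallest enzyme subset under which all species pairs separate.

    Subsets of size 1..max_enzymes are tried in (size, lexicographic)
    order and the first fully discriminating one wins, making the
    result deterministic. When none discriminates every pair, the
    subset maximising distinguishable pairs (same ordering breaks ties)
    is returned with the residual pairs listed.
    """
    if candidates is None:
        candidates = sorted({e for p in profiles.values() for e in p.panel})
    if not candidates:
        raise ValueError("candidate enzyme list must be non-empty")
    species = sorted(profiles)
    pairs = list(combinations(species, 2))
    total = len(pairs)

    # Pre-split band lists once per (species, enzyme).
    bands = {
        (sid, enz): visible_bands(profiles[sid].fragments[enz], gel, transitive)
        for sid in species
        for enz in candidates
    }

    def separated(pair: tuple[str, str], subset: tuple[str, ...]) -> bool:
        a, b = pair
        return any(
            not bands_equal(bands[(a, enz)], bands[(b, enz)], gel) for enz in subset
        )

    best: PanelReport | None = None
    for size in range(1, max_enzymes + 1):
        for subset in combinations(sorted(candidates), size):
            unresolved = tuple(p for p in pairs if not separated(p, subset))
            report = PanelReport(subset, total - len(unresolved), total, unresolved)
            if report.fully_discriminating:
                return report
            if best is None or report.distinguishable_pairs > best.distinguishable_pairs:
                best = report
    assert best is not None
    return best
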
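"""Virtual restriction digestion and the per-community reference database.

Each enzyme is applied in its own reaction (single-enzyme digests; no
sequential double digests). Recognition-site search is single-strand:
the shipped enzymes (TaqI, HaeIII, MluCI) have palindromic sites, so
scanning the reverse strand would add nothing. Degenerate template
bases are treated as compatible matches for site finding; profiles
record how many sites touched a degenerate base so uncertain cuts can
be audited.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from ._iupac import VALID_CODES, first_invalid, is_compatible
from .seqio_amplicon import (
    Amplicon,
    PrimerPair,
    ReferenceSequence,
    AmpliconError,
    extract_amplicon,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RestrictionEnzyme",
    "FragmentProfile",
    "ReferenceDatabase",
    "BUILTIN_ENZYMES",
    "get_enzyme",
    "load_enzymes",
    "find_recognition_sites",
    "digest_fragments",
    "build_profile",
    "build_reference_db",
    "MissingReferenceError",
]

#: Conventional maximum community size; exceeding it warns, not errors.
MAX_COMMUNITY_SIZE = 8


class MissingReferenceError(KeyError):
    """A community lists a species with no reference sequence."""


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme's recognition site and cut geometry.

    ``cut_offset`` is measured in bases from the 5' end of the
    recognition site to the cut position on the scanned strand
    (TaqI T^CGA has offset 1). ``incubation_temp`` is metadata only.
    """

    name: str
    recognition: str
    cut_offset: int
    incubation_temp: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", self.recognition.upper())
        if len(self.recognition) < 4:
            raise ValueError(
                f"{self.name}: recognition site must be >= 4 nt, "
                f"got {len(self.recognition)}"
            )
        bad = first_invalid(self.recognition)
        if bad is not None:
            raise ValueError(
                f"{self.name}: invalid recognition base "
                f"{self.recognition[bad]!r} at position {bad}"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"{self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(self.recognition)}]"
            )


BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    "TaqI": RestrictionEnzyme("TaqI", "TCGA", 1, 65.0),
    "HaeIII": RestrictionEnzyme("HaeIII", "GGCC", 2, 37.0),
    "MluCI": RestrictionEnzyme("MluCI", "AATT", 0, 37.0),
}

_BUILTIN_LOWER = {k.lower(): v for k, v in BUILTIN_ENZYMES.items()}


def get_enzyme(name: str) -> RestrictionEnzyme:
    """Look up a built-in enzyme, case-insensitively."""
    try:
        return _BUILTIN_LOWER[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; built-ins: {', '.join(BUILTIN_ENZYMES)}"
        ) from None


def load_enzymes(path: str | Path) -> list[RestrictionEnzyme]:
    """Load enzyme definitions from a YAML or JSON config.

    The file holds a list of mappings with keys ``name``,
    ``recognition``, ``cut_offset`` and optional ``temp``.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, list):
        raise ValueError(f"{path}: expected a list of enzyme definitions")
    return [
        RestrictionEnzyme(
            d["name"], d["recognition"], int(d["cut_offset"]), d.get("temp")
        )
        for d in data
    ]


@dataclass(frozen=True)
class FragmentProfile:
    """Per-enzyme expected fragment lengths for one species' amplicon.

    fragments maps enzyme name to lengths sorted descending; each
    enzyme's fragments sum to ``amplicon_length``. ``degenerate_sites``
    counts recognition sites that overlapped a degenerate template base.
    """

    species_id: str
    fragments: Mapping[str, tuple[int, ...]]
    amplicon_length: int
    degenerate_sites: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        frozen = {k: tuple(v) for k, v in self.fragments.items()}
        object.__setattr__(self, "fragments", frozen)
        for enzyme, frags in frozen.items():
            if not frags:
                raise ValueError(f"{self.species_id}/{enzyme}: empty fragment list")
            if sum(frags) != self.amplicon_length:
                raise ValueError(
                    f"{self.species_id}/{enzyme}: fragments sum to {sum(frags)}, "
                    f"amplicon length is {self.amplicon_length}"
                )

    @property
    def panel(self) -> tuple[str, ...]:
        return tuple(self.fragments)


@dataclass(frozen=True)
class ReferenceDatabase:
    """Fragment profiles for one community over a fixed enzyme panel."""

    community_id: str
    entries: Mapping[str, FragmentProfile]
    panel: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        object.__setattr__(self, "panel", tuple(self.panel))
        panel_set = set(self.panel)
        for sid, prof in self.entries.items():
            if set(prof.panel) != panel_set:
                raise ValueError(
                    f"{self.community_id}: profile for {sid} covers "
                    f"{sorted(prof.panel)}, panel is {sorted(panel_set)}"
                )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(self.entries))


def find_recognition_sites(residues: str, enzyme: RestrictionEnzyme) -> list[int]:
    """All 0-based start positions of the recognition site, overlaps included.

    Every base of the site must be IUPAC-compatible with the template
    base; a template N therefore matches any recognition base.
    """
    residues = residues.upper()
    if not residues:
        raise ValueError("residues must be non-empty")
    site = enzyme.recognition
    m = len(site)
    return [
        i
        for i in range(len(residues) - m + 1)
        if all(is_compatible(residues[i + j], site[j]) for j in range(m))
    ]


def _residues_of(amplicon: Amplicon | str) -> str:
    return amplicon.residues if hasattr(amplicon, "residues") else str(amplicon)


def digest_fragments(amplicon: Amplicon | str, enzyme: RestrictionEnzyme) -> list[int]:
    """Expected fragment lengths from a single-enzyme digest, descending.

    Cut positions are site start + cut_offset. Fragment count equals
    site count + 1 unless a cut falls exactly at an end of the
    molecule, in which case the zero-length fragment is dropped and
    logged.
    """
    residues = _residues_of(amplicon)
    length = len(residues)
    if length < 1:
        raise ValueError("amplicon must be at least 1 base")
    cuts = sorted({s + enzyme.cut_offset for s in find_recognition_sites(residues, enzyme)})
    boundary = [c for c in cuts if c <= 0 or c >= length]
    if boundary:
        logger.debug(
            "%s: dropped zero-length fragment(s) from cut(s) at %s", enzyme.name, boundary
        )
        cuts = [c for c in cuts if 0 < c < length]
    edges = [0, *cuts, length]
    frags = [b - a for a, b in zip(edges, edges[1:])]
    return sorted(frags, reverse=True)


def _degenerate_site_count(residues: str, enzyme: RestrictionEnzyme) -> int:
    m = len(enzyme.recognition)
    return sum(
        1
        for s in find_recognition_sites(residues, enzyme)
        if any(residues[s + j] not in "ACGT" for j in range(m))
    )


def build_profile(amplicon: Amplicon, panel: Sequence[RestrictionEnzyme]) -> FragmentProfile:
    """Digest one amplicon with each enzyme of the panel independently."""
    if not panel:
        raise ValueError("enzyme panel must be non-empty")
    names = [e.name for e in panel]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate enzyme names in panel: {names}")
    residues = _residues_of(amplicon)
    fragments = {e.name: tuple(digest_fragments(amplicon, e)) for e in panel}
    degenerate = {
        e.name: n
        for e in panel
        if (n := _degenerate_site_count(residues.upper(), e))
    }
    return FragmentProfile(amplicon.species_id, fragments, len(residues), degenerate)


def build_reference_db(
    sequences: Iterable[ReferenceSequence],
    community: Sequence[str],
    primers: PrimerPair,
    panel: Sequence[RestrictionEnzyme],
    community_id: str = "community",
) -> ReferenceDatabase:
    """Extract, digest and index the amplicon profile of every community member.

    Raises MissingReferenceError when a listed species has no reference
    sequence, and propagates amplicon-extraction failures with the
    species named. Communities larger than 8 warn but are processed.
    """
    by_id = {s.species_id: s for s in sequences}
    missing = [sid for sid in community if sid not in by_id]
    if missing:
        raise MissingReferenceError(
            f"{community_id}: no reference sequence for {', '.join(missing)}"
        )
    if len(community) > MAX_COMMUNITY_SIZE:
        warnings.warn(
            f"{community_id}: {len(community)} species exceeds the usual "
            f"maximum of {MAX_COMMUNITY_SIZE}",
            stacklevel=2,
        )
    entries: dict[str, FragmentProfile] = {}
    for sid in community:
        try:
            amplicon = extract_amplicon(by_id[sid], primers)
        except AmpliconError as exc:
            raise type(exc)(f"{community_id}/{sid}: {exc}") from exc
        entries[sid] = build_profile(amplicon, panel)
    return ReferenceDatabase(community_id, entries, tuple(e.name for e in panel))
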
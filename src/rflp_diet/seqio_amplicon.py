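"""Reference sequence I/O and in-silico PCR amplicon extraction.

Reads reference marker sequences from FASTA, locates primer binding
sites under IUPAC-degenerate matching (zero mismatches), and extracts
the amplicon delimited by a primer pair. Coordinates are 0-based
half-open; reported lengths are in bases. The amplicon retains template
bases verbatim (degenerate codes are not resolved) and includes both
primer-binding regions, matching what is sized on a gel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._iupac import first_invalid, is_compatible, reverse_complement

__all__ = [
    "ReferenceSequence",
    "PrimerPair",
    "Amplicon",
    "DEFAULT_PRIMERS",
    "FastaError",
    "AmpliconError",
    "NoForwardSiteError",
    "NoReverseSiteError",
    "AmbiguousPrimingError",
    "read_fasta",
    "write_fasta",
    "find_primer_sites",
    "extract_amplicon",
]


class FastaError(ValueError):
    """Malformed or invalid FASTA input."""


class AmpliconError(ValueError):
    """Amplicon extraction failed for a template."""


class NoForwardSiteError(AmpliconError):
    pass


class NoReverseSiteError(AmpliconError):
    pass


class AmbiguousPrimingError(AmpliconError):
    """More than one candidate priming site on the template."""


@dataclass(frozen=True)
class ReferenceSequence:
    """A species' reference marker sequence.

    residues must be non-empty and drawn from the IUPAC nucleotide
    alphabet (ACGTRYSWKMBDHVN); lowercase input is normalised to
    uppercase.
    """

    species_id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValueError("species_id must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise FastaError(f"record {self.species_id!r}: empty sequence")
        bad = first_invalid(self.residues)
        if bad is not None:
            raise FastaError(
                f"record {self.species_id!r}: non-IUPAC character "
                f"{self.residues[bad]!r} at position {bad}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "ReferenceSequence":
        return ReferenceSequence(
            self.species_id, reverse_complement(self.residues), self.description
        )


@dataclass(frozen=True)
class PrimerPair:
    """Forward and reverse primers, both written 5'->3'."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for label, seq in (("forward", self.forward), ("reverse", self.reverse)):
            up = seq.upper()
            object.__setattr__(self, label, up)
            if len(up) < 10:
                raise ValueError(f"{label} primer must be at least 10 nt, got {len(up)}")
            bad = first_invalid(up)
            if bad is not None:
                raise ValueError(
                    f"{label} primer: non-IUPAC character {up[bad]!r} at position {bad}"
                )


#: ITS2F / ITS3R plant barcoding primer pair used by default.
DEFAULT_PRIMERS = PrimerPair(
    forward="ATGCGATACTTGGTGTGAAT",
    reverse="GACGCTTCTCCAGACTACAAT",
)


@dataclass(frozen=True)
class Amplicon:
    """In-silico PCR product: the template interval [start, end)."""

    species_id: str
    residues: str
    start: int = 0
    end: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.end == -1:
            object.__setattr__(self, "end", self.start + len(self.residues))
        if self.end - self.start != len(self.residues):
            raise ValueError("amplicon interval does not match residue length")

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read a multi-record FASTA file into ReferenceSequence objects.

    The header token before the first whitespace becomes ``species_id``;
    the remainder is kept as ``description``. Records are returned in
    file order. Raises FastaError on an empty file, a duplicate id, or
    a non-IUPAC character (naming the record and offset).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[ReferenceSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate species_id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(ReferenceSequence(rec.id, str(rec.seq), desc))
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ReferenceSequence | Amplicon], path: str | Path,
                width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = f">{rec.species_id}" + (f" {desc}" if desc else "")
            fh.write(header + "\n")
            seq = rec.residues
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _scan(template: str, query: str) -> list[int]:
    n, m = len(template), len(query)
    hits = []
    for i in range(n - m + 1):
        if all(is_compatible(template[i + j], query[j]) for j in range(m)):
            hits.append(i)
    return hits


def find_primer_sites(template: str, primer: str,
                      orientation: str = "forward") -> list[int]:
    """0-based start positions where the primer binds the template.

    Forward orientation matches the primer as written; reverse
    orientation matches the reverse complement of the primer (i.e. the
    site where the reverse primer anneals to the given strand's
    complement). Matching is exact-length with IUPAC compatibility at
    every position and zero mismatches.
    """
    template = template.upper()
    primer = primer.upper()
    if orientation == "forward":
        query = primer
    elif orientation == "reverse":
        query = reverse_complement(primer)
    else:
        raise ValueError(f"orientation must be 'forward' or 'reverse', got {orientation!r}")
    if len(query) > len(template):
        return []
    return _scan(template, query)


def extract_amplicon(template: ReferenceSequence, primers: PrimerPair = DEFAULT_PRIMERS,
                     ) -> Amplicon:
    """Extract the PCR product delimited by a primer pair.

    The amplicon spans from the first base of the forward primer site
    through the last base of the reverse-complemented reverse primer
    site, inclusive. Requires exactly one forward site and exactly one
    reverse site downstream of it; anything else raises the
    corresponding AmpliconError subclass.
    """
    fwd_sites = find_primer_sites(template.residues, primers.forward, "forward")
    if not fwd_sites:
        raise NoForwardSiteError(
            f"{template.species_id}: no forward primer site found"
        )
    if len(fwd_sites) > 1:
        raise AmbiguousPrimingError(
            f"{template.species_id}: {len(fwd_sites)} forward primer sites at {fwd_sites}"
        )
    start = fwd_sites[0]
    rev_sites = [
        p for p in find_primer_sites(template.residues, primers.reverse, "reverse")
        if p >= start + len(primers.forward)
    ]
    if not rev_sites:
        raise NoReverseSiteError(
            f"{template.species_id}: no reverse primer site downstream of forward site"
        )
    if len(rev_sites) > 1:
        raise AmbiguousPrimingError(
            f"{template.species_id}: {len(rev_sites)} reverse primer sites at {rev_sites}"
        )
    end = rev_sites[0] + len(primers.reverse)
    return Amplicon(template.species_id, template.residues[start:end], start, end)


def extract_amplicons(templates: Sequence[ReferenceSequence],
                      primers: PrimerPair = DEFAULT_PRIMERS) -> list[Amplicon]:
    """extract_amplicon over a collection, failures annotated with the species."""
    out = []
    for t in templates:
        try:
            out.append(extract_amplicon(t, primers))
        except AmpliconError as exc:
            raise type(exc)(f"extraction failed for {t.species_id}: {exc}") from exc
    return out
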
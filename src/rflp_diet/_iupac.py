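"""IUPAC nucleotide alphabet: code sets, compatibility, reverse complement."""

from __future__ import annotations

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

VALID_CODES = frozenset(IUPAC_CODES)


def is_compatible(a: str, b: str) -> bool:
    """True when two IUPAC codes can denote the same base.

    Compatibility is symmetric: the base sets intersect. ``N`` is
    compatible with everything, ``R`` with ``A``, ``G``, and any code
    whose set contains a purine, and so on.
    """
    try:
        return not IUPAC_CODES[a].isdisjoint(IUPAC_CODES[b])
    except KeyError as exc:  # pragma: no cover - guarded by callers
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None


def reverse_complement(seq: str) -> str:
    try:
        return "".join(COMPLEMENT[c] for c in reversed(seq))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code {exc.args[0]!r}") from None


def first_invalid(seq: str) -> int | None:
    """Index of the first character outside the IUPAC alphabet, or None."""
    for i, c in enumerate(seq):
        if c not in VALID_CODES:
            return i
    return None
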
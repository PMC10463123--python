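"""Shared fixtures: primer constants, template builders, tiny communities."""

from __future__ import annotations

import numpy as np
import pytest

from rflp_diet.seqio_amplicon import DEFAULT_PRIMERS, PrimerPair, ReferenceSequence
from rflp_diet._iupac import reverse_complement

# Independent IUPAC table for test-side oracles; kept separate from the
# package so oracle and implementation cannot share a bug.
ORACLE_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

ORACLE_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def oracle_revcomp(seq: str) -> str:
    return seq.translate(ORACLE_COMP)[::-1]


def oracle_compatible(a: str, b: str) -> bool:
    return bool(set(ORACLE_IUPAC[a]) & set(ORACLE_IUPAC[b]))


def oracle_scan(template: str, query: str) -> list[int]:
    """Exhaustive window-compatibility scan."""
    m = len(query)
    return [
        i
        for i in range(len(template) - m + 1)
        if all(oracle_compatible(template[i + j], query[j]) for j in range(m))
    ]


def oracle_digest(seq: str, recognition: str, cut_offset: int) -> list[int]:
    """Brute-force digestion: split the string at every cut position."""
    cuts = sorted(
        {s + cut_offset for s in oracle_scan(seq, recognition)} & set(range(1, len(seq)))
    )
    pieces = []
    prev = 0
    for c in cuts:
        pieces.append(seq[prev:c])
        prev = c
    pieces.append(seq[prev:])
    return sorted((len(p) for p in pieces), reverse=True)


@pytest.fixture
def primers() -> PrimerPair:
    return DEFAULT_PRIMERS


def make_template(insert: str, species_id: str = "sp",
                  prefix: str = "AAA", suffix: str = "CCC") -> ReferenceSequence:
    """prefix + forward primer + insert + revcomp(reverse primer) + suffix."""
    residues = (
        prefix + DEFAULT_PRIMERS.forward + insert
        + reverse_complement(DEFAULT_PRIMERS.reverse) + suffix
    )
    return ReferenceSequence(species_id, residues)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
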
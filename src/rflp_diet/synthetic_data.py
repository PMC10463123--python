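"""Synthetic references, communities and full simulated experiments.

Generates marker-like reference sequences flanked by the default primer
sites (so amplicon extraction always has a target), assembles replicated
communities, and simulates a sampling campaign: per-occasion faecal and
regurgitate samples from one female and one male grasshopper per
mesocosm, Bernoulli amplification by sample type and sex, per-sample
diet sets drawn from a configurable size distribution, and observed
bands derived from expected patterns with multiplicative sizing noise
inside the gel detection window. Everything is deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._iupac import reverse_complement
from .digest_engine import BUILTIN_ENZYMES, ReferenceDatabase, build_reference_db
from .diet_stats import SampleRecord, SpeciesTraits
from .panel_design import GelModel
from .pattern_match import BandObservation, expected_band_pattern, identify_sample
from .seqio_amplicon import DEFAULT_PRIMERS, PrimerPair, ReferenceSequence

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "generate_reference_sequences",
    "generate_communities",
    "generate_species_traits",
    "simulate_experiment",
    "simulate_amplification_records",
    "identify_experiment",
    "simulate_detection_bias",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the simulated mesocosm experiment.

    Defaults mirror the study design: 39 species (19 native, 20
    exotic), 20 communities of 8 replicated 4x, four sampling
    occasions, amplicons of 400-600 bp, per-group amplification
    probabilities, and a 335:133:31:1 weighting over 1-4 species per
    sample. ``shared_diet_prob`` interpolates between independent
    (0.0, default) and fully shared faecal/regurgitate diet sets;
    ``missing_prob`` thins samples to emulate missed captures.
    """

    seed: int = 0
    n_species: int = 39
    n_native: int = 19
    n_communities: int = 20
    community_size: int = 8
    replicates: int = 4
    occasions: int = 4
    amplicon_length_range: tuple[int, int] = (400, 600)
    divergence: float = 0.10
    near_identical_pairs: int = 1
    near_identical_divergence: float = 0.002
    amplification_probs: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("faecal", "female"): 0.773,
            ("regurgitate", "female"): 0.630,
            ("faecal", "male"): 0.801,
            ("regurgitate", "male"): 0.431,
        }
    )
    species_count_weights: Mapping[int, float] = field(
        default_factory=lambda: {1: 335, 2: 133, 3: 31, 4: 1}
    )
    sizing_noise_sd: float = 0.02
    shared_diet_prob: float = 0.0
    missing_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.community_size > self.n_species:
            raise ValueError("community_size cannot exceed n_species")
        if not all(0 <= p <= 1 for p in self.amplification_probs.values()):
            raise ValueError("amplification probabilities must be in [0, 1]")
        w = list(self.species_count_weights.values())
        if any(x < 0 for x in w) or sum(w) == 0:
            raise ValueError("species_count_weights must be non-negative, not all zero")
        if any(k < 1 for k in self.species_count_weights):
            raise ValueError("species counts must be >= 1")
        lo, hi = self.amplicon_length_range
        min_len = len(DEFAULT_PRIMERS.forward) + len(DEFAULT_PRIMERS.reverse) + 1
        if not min_len <= lo <= hi:
            raise ValueError(
                f"amplicon_length_range must satisfy {min_len} <= lo <= hi"
            )
        if not 0 <= self.divergence <= 1 or not 0 <= self.near_identical_divergence <= 1:
            raise ValueError("divergence rates must be in [0, 1]")
        if 2 * self.near_identical_pairs > self.n_species:
            raise ValueError("too many near-identical pairs for the species pool")


def _species_ids(n: int) -> list[str]:
    return [f"sp{i + 1:02d}" for i in range(n)]


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Independent per-base substitution; substituted bases always change."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_reference_sequences(config: SimulationConfig) -> list[ReferenceSequence]:
    """Marker-like templates: flank + forward site + insert + reverse site + flank.

    All species descend from one random ancestor insert by independent
    per-base substitution at ``divergence``; each designated
    near-identical pair's second member is instead derived from the
    first at ``near_identical_divergence``, emulating species a gel
    cannot separate. Primer regions are never mutated, so amplicon
    extraction always succeeds.
    """
    rng = np.random.default_rng(config.seed)
    primers = DEFAULT_PRIMERS
    lo, hi = config.amplicon_length_range
    insert_len = int(rng.integers(lo, hi + 1)) - len(primers.forward) - len(primers.reverse)
    ancestor = rng.choice(_BASES, size=insert_len)
    ids = _species_ids(config.n_species)

    # first 2k ids form the near-identical pairs: (0,1), (2,3), ...
    twins = {2 * i + 1: 2 * i for i in range(config.near_identical_pairs)}
    inserts: list[np.ndarray] = []
    for i in range(config.n_species):
        if i in twins:
            inserts.append(_mutate(inserts[twins[i]], config.near_identical_divergence, rng))
        else:
            inserts.append(_mutate(ancestor, config.divergence, rng))

    records = []
    rc_rev = reverse_complement(primers.reverse)
    for sid, insert in zip(ids, inserts):
        flank5 = "".join(rng.choice(_BASES, size=int(rng.integers(5, 31))))
        flank3 = "".join(rng.choice(_BASES, size=int(rng.integers(5, 31))))
        residues = flank5 + primers.forward + "".join(insert) + rc_rev + flank3
        records.append(ReferenceSequence(sid, residues, "synthetic marker"))
    return records


def generate_communities(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[tuple[str, ...]]:
    """Distinct communities of ``community_size`` species, uniform without replacement."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ids = np.array(_species_ids(config.n_species))
    communities: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    attempts = 0
    while len(communities) < config.n_communities:
        attempts += 1
        if attempts > 10_000 * config.n_communities:
            raise ValueError("cannot draw enough distinct communities; pool too small")
        members = tuple(sorted(rng.choice(ids, size=config.community_size, replace=False)))
        if members not in seen:
            seen.add(members)
            communities.append(members)
    return communities


def generate_species_traits(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[SpeciesTraits]:
    """Random provenance/functional-group/SLA traits for the species pool."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    traits = []
    for i, sid in enumerate(_species_ids(config.n_species)):
        provenance = "native" if i < config.n_native else "exotic"
        group = "woody" if rng.random() < 0.25 else "herbaceous"
        sla = float(np.exp(rng.normal(np.log(15.0), 0.4)))  # mm^2/mg scale
        traits.append(SpeciesTraits(sid, provenance, group, sla))
    return traits


@dataclass(frozen=True)
class SimulatedExperiment:
    """Everything a simulated campaign produced, keyed for downstream stages."""

    config: SimulationConfig
    sequences: tuple[ReferenceSequence, ...]
    communities: tuple[tuple[str, ...], ...]
    databases: tuple[ReferenceDatabase, ...]
    gel: GelModel
    records: tuple[SampleRecord, ...]
    observations: Mapping[str, BandObservation]
    truth: Mapping[str, frozenset[str]]
    sample_community: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observations", dict(self.observations))
        object.__setattr__(self, "truth", dict(self.truth))
        object.__setattr__(self, "sample_community", dict(self.sample_community))


def _iter_sample_frame(config: SimulationConfig):
    """Deterministic enumeration of (community, mesocosm, grasshopper, occasion, type)."""
    for c in range(config.n_communities):
        for r in range(config.replicates):
            mesocosm = f"c{c + 1:02d}r{r + 1}"
            for sex in ("female", "male"):
                grasshopper = f"{mesocosm}-{sex[0]}"
                for occ in range(1, config.occasions + 1):
                    for stype in ("faecal", "regurgitate"):
                        yield c, mesocosm, grasshopper, sex, occ, stype


def simulate_amplification_records(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[SampleRecord]:
    """Sample frame with Bernoulli amplification only (no sequences or bands).

    A fast path for studying amplification-proportion estimators at
    scale without paying for sequence simulation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    records = []
    for i, (c, mesocosm, ghopper, sex, occ, stype) in enumerate(_iter_sample_frame(config)):
        if config.missing_prob and rng.random() < config.missing_prob:
            continue
        amplified = bool(rng.random() < config.amplification_probs[(stype, sex)])
        records.append(
            SampleRecord(f"s{i + 1:05d}", ghopper, mesocosm, occ, stype, sex, amplified)
        )
    return records


def simulate_experiment(
    config: SimulationConfig,
    gel: GelModel | None = None,
    primers: PrimerPair = DEFAULT_PRIMERS,
    panel_names: Sequence[str] = ("TaqI", "HaeIII", "MluCI"),
) -> SimulatedExperiment:
    """Full campaign: sequences, communities, diets, amplification and bands.

    Per amplified sample the observation is the expected band pattern of
    the true diet set, each band perturbed multiplicatively by Gaussian
    noise of sd ``sizing_noise_sd`` and then filtered to the gel window.
    Records carry only the amplification outcome; run
    :func:`identify_experiment` to fill in identifications.
    """
    if gel is None:
        gel = GelModel()
    rng = np.random.default_rng(config.seed + 4)
    sequences = generate_reference_sequences(config)
    communities = generate_communities(config, rng)
    panel = [BUILTIN_ENZYMES[n] for n in panel_names]
    databases = [
        build_reference_db(sequences, list(comm), primers, panel, f"c{ci + 1:02d}")
        for ci, comm in enumerate(communities)
    ]

    sizes = np.array(sorted(config.species_count_weights))
    weights = np.array([config.species_count_weights[int(k)] for k in sizes], dtype=float)
    weights /= weights.sum()

    records: list[SampleRecord] = []
    observations: dict[str, BandObservation] = {}
    truth: dict[str, frozenset[str]] = {}
    sample_community: dict[str, int] = {}
    faecal_sets: dict[tuple[str, int], frozenset[str]] = {}

    for i, (c, mesocosm, ghopper, sex, occ, stype) in enumerate(_iter_sample_frame(config)):
        if config.missing_prob and rng.random() < config.missing_prob:
            continue
        sample_id = f"s{i + 1:05d}"
        community = communities[c]
        shared = (
            stype == "regurgitate"
            and config.shared_diet_prob
            and (ghopper, occ) in faecal_sets
            and rng.random() < config.shared_diet_prob
        )
        if shared:
            diet = faecal_sets[(ghopper, occ)]
        else:
            k = min(int(rng.choice(sizes, p=weights)), len(community))
            diet = frozenset(rng.choice(community, size=k, replace=False).tolist())
        if stype == "faecal":
            faecal_sets[(ghopper, occ)] = diet

        amplified = bool(rng.random() < config.amplification_probs[(stype, sex)])
        records.append(
            SampleRecord(sample_id, ghopper, mesocosm, occ, stype, sex, amplified)
        )
        truth[sample_id] = diet
        sample_community[sample_id] = c
        if amplified:
            pattern = expected_band_pattern(diet, databases[c], gel)
            noisy: dict[str, tuple[float, ...]] = {}
            for enz, bands in pattern.items():
                jittered = [
                    b * (1.0 + rng.normal(0.0, config.sizing_noise_sd))
                    for b in bands
                ] if config.sizing_noise_sd > 0 else [float(b) for b in bands]
                noisy[enz] = tuple(
                    sorted((b for b in jittered if gel.in_window(b)), reverse=True)
                )
            # a diet whose every band drifted out of window is still an observation
            noisy = {e: b for e, b in noisy.items() if b} or {
                panel_names[0]: (gel.min_size,)
            }
            observations[sample_id] = BandObservation(sample_id, noisy)

    return SimulatedExperiment(
        config,
        tuple(sequences),
        tuple(communities),
        tuple(databases),
        gel,
        tuple(records),
        observations,
        truth,
        sample_community,
    )


def identify_experiment(
    exp: SimulatedExperiment,
    max_mixture: int = 4,
) -> list[SampleRecord]:
    """Run band identification over an experiment and fill in the records.

    A unique call sets the identified species set directly. An
    ambiguous call is treated as resolved by follow-up sequencing
    (``sequenced=True``) to the true set, matching how ambiguous gels
    are handled in practice. A no-match stays unidentified.
    """
    out = []
    for rec in exp.records:
        obs = exp.observations.get(rec.sample_id)
        if obs is None:
            out.append(rec)
            continue
        db = exp.databases[exp.sample_community[rec.sample_id]]
        result = identify_sample(obs, db, exp.gel, max_mixture=max_mixture)
        if result.status == "unique":
            out.append(
                replace(rec, identified=True, species_set=result.candidate_sets[0])
            )
        elif result.status == "ambiguous":
            out.append(
                replace(
                    rec,
                    identified=True,
                    sequenced=True,
                    species_set=exp.truth[rec.sample_id],
                )
            )
        else:
            out.append(rec)
    return out


def simulate_detection_bias(
    traits: Sequence[SpeciesTraits],
    n_events: int = 2000,
    expected_prop: float = 0.66,
    bias: float = 1.0,
    rng: np.random.Generator | None = None,
) -> list[SampleRecord]:
    """Identification events where faecal detection favours low-SLA species.

    Each event picks a species uniformly, then assigns it to a faecal
    sample with probability ``sigmoid(logit(expected_prop) - bias * z)``
    where z is the species' standardised specific leaf area. With
    ``bias > 0`` low-SLA species are over-represented in faecal samples,
    so regressing per-species faecal-share deviance on SLA should give a
    negative slope; ``bias = 0`` recovers the unbiased null.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    sla = np.array([t.specific_leaf_area for t in traits])
    z = (sla - sla.mean()) / sla.std()
    logit = np.log(expected_prop / (1 - expected_prop)) - bias * z
    p_faecal = 1.0 / (1.0 + np.exp(-logit))
    records = []
    for i in range(n_events):
        j = int(rng.integers(len(traits)))
        stype = "faecal" if rng.random() < p_faecal[j] else "regurgitate"
        records.append(
            SampleRecord(
                f"e{i + 1:05d}",
                f"g{i + 1:05d}",
                "m00",
                1,
                stype,
                "female",
                amplified=True,
                identified=True,
                species_set=frozenset({traits[j].species_id}),
            )
        )
    return records
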
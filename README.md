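# rflp-diet

An in-silico RFLP (restriction fragment length polymorphism) toolkit for
inferring the plant diet of herbivores from gel banding patterns, built for
experiments where each enclosure holds a small, known community of candidate
host plants.

The package covers the full workflow:

- **`seqio_amplicon`** — read reference marker sequences from FASTA and
  extract the in-silico PCR amplicon delimited by a primer pair (default:
  ITS2F/ITS3R) with IUPAC-degenerate, zero-mismatch primer matching.
- **`digest_engine`** — virtually digest amplicons with restriction enzymes
  (TaqI, HaeIII and MluCI ship as built-ins; others load from YAML/JSON) and
  assemble the per-community reference database of fragment-length profiles.
- **`panel_design`** — a gel model (detection window 25–766 bp, relative
  comigration tolerance) plus exhaustive search for the smallest enzyme
  panel that distinguishes every species pair in a community.
- **`pattern_match`** — identify the species set in a sample by matching
  observed band sizes against expected single-species and mixture patterns,
  with unique / ambiguous / no-match statuses and a sequencing-needed flag.
- **`diet_stats`** — grouped success proportions with Wilson intervals,
  relative-difference arithmetic, paired faecal/regurgitate agreement
  rates, species-per-sample means, per-species faecal-detection deviance
  (with a minimum-sample filter), chi-squared contingency tests and simple
  linear regression of deviance on species traits.
- **`synthetic_data`** — seeded generators for reference sequences (with
  controllable divergence and near-identical species pairs), communities,
  and complete simulated sampling campaigns, plus a detection-bias harness.

## Command-line usage

```sh
# simulate a campaign (writes refs.fa, communities.csv, samples.csv, bands.csv, truth.csv)
rflp-diet simulate --seed 42 --out simdir/

# extract amplicons and build fragment profiles
rflp-diet amplicon --fasta simdir/refs.fa \
    --forward ATGCGATACTTGGTGTGAAT --reverse GACGCTTCTCCAGACTACAAT \
    --out amplicons.fa
rflp-diet digest --fasta amplicons.fa --enzymes taqI,haeIII,mluCI --out profiles.csv

# choose a minimal discriminating enzyme panel per community
rflp-diet design-panel --fasta simdir/refs.fa --community simdir/communities.csv

# identify species sets from observed bands (one community at a time)
rflp-diet identify --obs simdir/bands.csv --db profiles.csv \
    --community simdir/communities.csv --community-id c01 --out ids.csv

# diet summary statistics from sample records
rflp-diet stats --samples simdir/samples.csv --expected-prop 0.66 --out statsdir/
```

## Notes on conventions

- Coordinates are 0-based half-open; lengths are in bases; amplicons
  include both primer-binding regions (what a gel sizes).
- Each enzyme digests in its own reaction; no double digests.
- Two bands comigrate when `|a − b| ≤ rel_tol · max(a, b)`; merged bands
  take the rounded mean size. `rel_tol` defaults to 0.05 and is a
  configuration value everywhere.
- Percentages are computed from exact integer counts and rounded half-up
  only at presentation.
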
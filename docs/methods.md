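# Methods

This note documents the model implemented by `hfscan`, the parameter
defaults and their rationale, the scope of the synthetic-data generator,
and the numerical choices that affect results. Everything stated here is
either a definition or a property exercised by the test suite or
`scripts/acceptance.py`; no further empirical claims are made.

## Input model

The pipeline consumes 12-column BLAST tabular alignments
(query id, subject id, percent identity, alignment length, mismatches,
gap opens, query start/end, subject start/end, E-value, bit score).
Coordinates are 1-based inclusive on input and converted internally to
0-based half-open intervals. A subject interval with start > end encodes
a minus-strand hit and is normalised to an oriented interval. By default
the virus is the query and the host scaffold the subject;
`--swap-query-subject` handles the transposed orientation, and swapping
twice is the identity.

## Host-side HF identification

1. **Filter**: keep rows with E-value ≤ `evalue_cutoff` (default
   `1e-5`, the conventional BLAST screening threshold).
2. **Group**: rows whose host intervals describe the same fragment are
   grouped by single-linkage union-find. Two intervals are linked when
   their reciprocal overlap — shared bases divided by the length of the
   *longer* interval — is ≥ `min_reciprocal_overlap` (default 0.8).
   An `exact` policy (identical coordinates only) is selectable.
3. **Select**: within each group, all rows at the group's minimum
   E-value are retained (ties are never broken arbitrarily). The HF
   interval is the minimum-E row's interval, or the union span of the
   tied rows. Each HF records its supporting rows, best E-value, best
   bit score, and the set of matching viruses.

Output is sorted by (scaffold, start, end); identifiers `HF0001…` are
assigned in that order. The procedure is idempotent on its own
supporting rows, and no two output HFs group with each other.

## Virus-side HF identification

The mirrored procedure on viral (query) coordinates: filter, group by
same-viral-fragment reciprocal overlap, minimum-E retention, then two
extra steps per virus: hits whose gap is ≤ `merge_gap` bases (default
10) are merged into one fragment, and exact-coordinate duplicates are
collapsed. Merging is computed by a single sorted sweep and equals the
transitive closure of the gap relation; it is idempotent and
permutation-invariant.

## Annotation

Gene models come from GFF3 (via gffutils). One transcript — the first
mRNA per gene — is used; isoforms are not resolved. Seven region
categories are derived per scaffold:

- **gene**: the gene span;
- **exon**, **CDS**: as annotated (genes without exon children use the
  span as a single exon);
- **intron**: span minus the exon union;
- **promoter**: `promoter_len` bases upstream of the span (default
  2,000), strand-aware, clipped to the scaffold;
- **downstream**: `downstream_len` bases downstream (default 1,000),
  likewise;
- **intergenic**: the complement of the gene-span union.

The flank lengths are assumptions, not annotations, and every report
echoes them with an `(assumed)` marker. Categories are deliberately
**not** mutually exclusive: classification is multi-label, by interval
intersection (≥ 1 bp by default; a ≥ 50%-of-HF criterion is available).
Category base counts are computed on merged unions, so overlapping genes
are not double-counted. HFs are assigned to genes whose extended
footprint (promoter + span + downstream) they overlap; an HF touching k
footprints counts towards all k genes.

## Enrichment statistics

All analyses use the same two-cell, 1-degree-of-freedom chi-squared
goodness-of-fit statistic for a unit count `o` with expectation `e` out
of totals `O`, `E`:

```
chi2 = (o - e)^2 / e + ((O - o) - (E - e))^2 / (E - e)
```

with the p-value from the upper tail of the chi-squared(1) distribution
and no continuity correction. A unit with a zero expected cell is an
error ("drop or pool") rather than a silent exclusion.

- **Scaffold test**: expected counts proportional to scaffold length.
  Scaffolds with no observed HF or expected < 1 are reported but marked
  untested (the chi-squared approximation is unreliable there); the
  Bonferroni family is the tested scaffolds only. Enrichment requires
  adjusted p < 0.05 *and* observed > expected.
- **Window scan**: fixed 100-kb windows tiling each scaffold (disjoint
  by default; a smaller step is allowed and flagged in the unit id). An
  HF belongs to the window containing its midpoint, so each HF is
  counted once. Raw p-values are reported with no multiplicity
  adjustment; a window is flagged at p < 0.01 with observed > expected.
  An optional reporting filter restricts output to scaffolds with at
  least `min_hfs_per_scaffold` HFs and `min_scaffold_length` bases.
- **Neighbour-distance test**: distances are gaps between consecutive
  HFs on the same scaffold (0 when overlapping; singletons emit
  nothing), binned at 0–1 kb, 1–10 kb, 10–100 kb, ≥ 100 kb. The null
  preserves the number and lengths of the observed HFs and re-places
  them uniformly per-base `n_sim` times (default 1,000); expected bin
  ratios are the pooled simulated fractions. The simulation is seeded
  and reproducible.
- **Region test**: observed = HFs whose classification contains the
  category; expected ratio = category bases / genome length (the
  uniform per-base null). Because categories overlap, each is tested
  marginally with no cross-category correction.

### Calibration

Two properties are verified by simulation in the test suite:

- Under uniform placement (1,000 replicates of 100 fragments on five
  200-kb scaffolds), the Bonferroni scaffold test rejects in at most
  α + Monte-Carlo error of replicates, and the window scan flags at its
  nominal 0.01 rate. That regime puts 10 expected fragments in each of
  ten equal windows, inside the chi-squared validity range; the exact
  flag probability of the discrete count null there is 0.01001.
- Raw scaffold-test p-values under the null are approximately uniform.
  Because counts are discrete the p-values live on a lattice; with 500
  fragments per replicate the lattice's own Kolmogorov–Smirnov distance
  from uniform is ≈ 0.036, which the test budget of 0.05 accommodates.

Power is likewise verified: with 40 fragments planted 80% inside genes,
the gene category reaches p < 0.05 in ≥ 90% of replicates; with
clustered planting (gaps of 100–900 bp), the sub-kilobase distance bin
reaches p < 0.01 in ≥ 90%.

## Synthetic-data generator

The generator produces a complete, ground-truthed input bundle:

- **Host genome**: i.i.d. uniform-base scaffolds (default five of
  200 kb).
- **Genes**: non-overlapping models on random strands (default 60;
  2–8 kb; 2–5 exons; CDS = exons with ≤ 30 bp terminal UTR trims),
  placed by rejection sampling; infeasible packing raises an error.
- **Viruses**: default eight genomes of 30–50 kb.
- **Planted homologies**: default 40 fragments of 33–277 bp copied from
  random viral loci into the host under one of three placement models —
  `uniform` (per-base), `gene_biased` (default 80% inside genes), or
  `clustered` (runs separated by 100–900 bp gaps). Fragments receive
  point substitutions at rate 0.05 (no indels) and never overlap one
  another, so each detectable fragment corresponds to exactly one HF.
- **Alignment table**: one row per detectable fragment (about half
  encoded minus-strand), plus decoy rows constructed to fall above the
  E-value cutoff, plus tie scenarios that duplicate a row's host
  coordinates under a second virus at the identical E-value; rows are
  deterministically shuffled.

E-values are synthetic but monotone in the right directions:
`E = K · m · n · 2^(-s)` with score `s = 2·matches − 3·mismatches` and
`K = 0.1`, evaluated in log2 space to avoid overflow (values below
2^−1000 report as 0). A fragment is detectable iff its synthetic
E-value is ≤ the cutoff. These E-values are not BLAST's
Karlin–Altschul values; they exist so filtering and tie-handling can be
exercised with known answers.

Everything is driven by `numpy.random.default_rng` with explicit seeds;
identical seeds give byte-identical outputs.

**Not emulated**: insertions/deletions (so host and viral fragment
lengths always match), gapped alignments, low-complexity or repeat
sequence, GC bias, multi-copy segmental duplication of planted
fragments, isoform structure, and real BLAST scoring.

## Determinism and reporting

Every stage is a pure function of its inputs and the configuration. The
command line writes a `run_metadata.json` with the full configuration,
MD5 checksums of the inputs, and the package version — no timestamps —
and each output file starts with `# key = value` headers echoing the
parameters used. Running `hfscan all` twice with the same inputs and
seed produces byte-identical files, and the composed command equals the
stage-by-stage commands byte for byte.

## Limitations

- Grouping uses single linkage: chains of pairwise-similar intervals can
  join fragments whose extremes overlap by less than the threshold.
- The uniform per-base null ignores assembly gaps, repeat masking, and
  local compositional biases; enrichment against it should be read as
  departure from length-proportional uniformity, not as a full
  evolutionary null.
- One transcript per gene; UTR/isoform-level resolution is out of scope.
- The window scan reports raw p-values by design; its output is a
  screening list, not a multiplicity-controlled inventory.
- Default problem sizes (desk-scale genomes and fragment counts) were
  chosen so the full pipeline and its simulation-based checks run in
  seconds to minutes; all thresholds and defaults are configurable.
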
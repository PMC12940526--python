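# Methods

## Constraint model

The unit of analysis is one residue of a canonical coding transcript.
For residue *i* of a protein of length *L*, the window is the codon
interval `[i−15, i+15] ∩ [1, L]` (31 codons in the interior, truncated at
the termini so every residue is scored). Within the window:

- `E_m`, `E_s`: counts of possible missense/synonymous single-nucleotide
  changes, from exhaustive mutagenesis of the CDS under the standard
  genetic code. Every coding site contributes exactly 3 possible changes;
  changes that create or destroy a stop codon form a third class excluded
  from both `E_m` and `E_s`, and the terminal stop codon is excluded
  entirely (it encodes no residue to score).
- `O_m`, `O_s`: observed missense/synonymous single-nucleotide
  substitutions with `FILTER = PASS` in the population catalog. A
  qualifying allele counts once regardless of frequency; distinct ALT
  alleles at one site count separately. Multi-allelic records are
  decomposed, indels and other non-SNVs are dropped, and minus-strand
  exon maps are complemented during genome-to-CDS projection.

MTR is the ratio of observed to possible missense proportion. It is
undefined (NA) when `O_m + O_s = 0`; no pseudo-counts are used, because a
pseudo-counted window would report a tolerance score estimated from no
data. Depletion significance is a one-sided exact binomial tail,
`P(X ≤ O_m)` with `X ~ Binomial(O_m + O_s, E_m/(E_m+E_s))` — one-sided
because the analysis seeks intolerant regions only. Benjamini–Hochberg
q-values are computed over all tested residues of the run as one family
by default (`fdr_family="per_gene"` restricts the family to each gene;
each p-value always belongs to exactly one family per run).

Window semantics: sliding the 93-nucleotide window one nucleotide at a
time produces three nucleotide-phase windows per codon that coincide for
all interior residues once aggregated per codon; the engine therefore
computes the residue-centred codon window directly, which is the
granularity at which results are reported and joined with per-residue
annotations. A separate per-nucleotide profile mode was considered and
dropped: it triples the computation for a distinction that vanishes at
the reporting resolution.

## Structural states

Each residue gets exactly one of four states. Region annotations carry a
label and a source (curated, predicted, PDB-derived), and overlaps are
resolved by precedence:

    structural transition > curated disorder > predicted disorder
    > missing residues > order

Rationale: curated evidence outranks prediction, and transition is the
most specific curated label; order is the unannotated background, so
genes with no annotations are ordered-only. The precedence is a package
choice (upstream databases do not prescribe one) and is configurable.
Predicted disorder is merged into the disorder state rather than kept as
a fifth state. Painting proceeds from the lowest layer up, which makes
the result independent of annotation order and idempotent.

## Constraint classes and downstream statistics

Residues with defined MTR classify as Intolerant (< 0.4) or Tolerant
(≥ 0.4); the boundary value is Tolerant. NA-MTR residues are
Unclassified and excluded from class-based statistics (they also break
segment runs).

- **Composition enrichment**: per state and amino acid, a 2×2 table of
  (this aa vs others) × (Intolerant vs Tolerant); two-sided Fisher's
  exact test with the probability-ordering rule (mass of tables whose
  hypergeometric probability does not exceed the observed table's — the
  dominant convention, matching `scipy.stats.fisher_exact`); odds ratios
  use the Haldane–Anscombe correction (+0.5 to all four cells) only when
  a cell is zero. BH runs within each state (one 20-test family per
  state, mirroring a per-state heatmap). A state with no Intolerant
  residues yields NA rows — the contrast is undefined there.
- **Biophysics**: side-chain charge (K, R = +1; D, E = −1; H = 0 at
  neutral pH by default, configurable to a fractional charge),
  Kyte–Doolittle hydropathy, aromatic fraction (F/Y/W).
- **Segments**: maximal runs of consecutive residues sharing gene, state
  and constraint class. Aromatic spacing is the mean gap between
  consecutive aromatic positions in segment-local coordinates, NA with
  fewer than two aromatics; this consecutive-pair definition is declared
  and fixed here. Intolerant−Tolerant contrasts (Δ) use two-sided
  Mann–Whitney U tests: residue-level properties compare per-residue
  values, segment-level properties (length, spacing) compare per-segment
  values.
- **State summary**: per-state n/mean/SD plus adjusted Fisher–Pearson
  skewness and bias-corrected *excess* kurtosis (0 for a normal
  distribution; the convention is stated because reporting conventions
  differ). Global differences use a tie-corrected Kruskal–Wallis test;
  pairwise Dunn z-tests on pooled mid-ranks with tie correction are
  BH-adjusted, and the compact letter display assigns one letter per
  maximal clique of the non-significance graph — two groups share a
  letter exactly when their adjusted pairwise p ≥ α.
- **Clinical enrichment**: clinical catalogs stay separate from the
  population catalog (they never feed MTR observed counts, since a
  clinical archive is not a population sample). Significance strings map
  to pathogenic / benign / VUS; conflicting or other records are
  excluded. Each (state, class) is tested state-vs-all-other-states with
  Fisher + Haldane–Anscombe; one BH family spans all state × class tests.
  Wilson 95% score intervals and pooled two-proportion z-tests summarize
  prevalences.

## Synthetic data generator

The generator emulates the statistical structure of the real inputs, not
their biology:

- **Transcripts**: uniform draws over the 61 sense codons (optionally
  biased, e.g. toward disorder-promoting residues), terminal stop
  appended, no internal stops. Default 50 genes × 500 residues — the
  scale at which window statistics stabilise while a full run stays in
  seconds.
- **Population catalog**: every possible SNV is observed independently
  with probability `p_obs` (default 0.15; roughly the per-allele
  saturation regime of a large modern exome+genome catalog in a
  well-covered gene). Constraint is planted by thinning *missense*
  emission inside declared regions by a retention factor δ while
  synonymous sites are untouched, so the expected observed missense
  proportion in a fully depleted window is `δE_m/(δE_m+E_s)` and MTR is a
  known function of δ. A small fraction of records (default 5%) is
  flagged non-PASS, class-independently, to exercise the release-quality
  filter without biasing the null.
- **Annotations**: proteins are tiled with 5–25-residue blocks whose
  state is drawn from the configured fractions (default ≈ 69% order,
  25% disorder, 6% missing, <1% transition — the residue composition
  typical of a disorder-annotated neurodevelopmental gene set); some
  curated disorder blocks carry an inner predicted region to exercise
  precedence without changing the fractions.
- **Clinical labels**: positions sampled uniformly over residues, each
  with a concrete single-substitution amino-acid change; the class is
  drawn from per-state probabilities *solved* (in logit space, jointly)
  so that the planted state-vs-rest log2 odds ratios hold exactly at the
  population level despite the coupling through the complement mixture.
  Infeasible targets raise a config error. The truth table written
  alongside contains the solved probabilities and implied ORs, so
  recovery can be scored without re-reading the config.

Everything is a pure function of (config, seed); each stage draws from
its own seeded stream, so e.g. changing `p_obs` leaves the transcripts
unchanged.

What the generator does **not** model: mutation-rate heterogeneity (CpG
transitions, context effects), sequencing-coverage variation, the allele
frequency spectrum, population structure, and correlated annotation
errors. Passing tests therefore demonstrate correctness of the
estimator and test machinery under a clean observation model — not that
real gnomAD/ClinVar/DisProt data meet these assumptions. In particular,
the real expected counts of a production MTR would be mutation-rate
weighted; here the unweighted possible-SNV enumeration is both the model
and the truth, so the null MTR is exactly 1 by construction.

## Validation choices and problem sizes

- Null calibration uses 50 genes × 500 aa at `p_obs = 0.15` (25,000
  residues): the mean per-residue MTR must sit in [0.97, 1.03] and the
  FDR-flagged fraction must not exceed the nominal 0.05.
- Planted-region recovery uses δ = 0.2 over a 40-residue region at
  `p_obs = 0.3`, 20 seeded replicates of one 100-residue gene each,
  judged in aggregate (mean MTR gap vs flank ≥ 0.25; mean flagged
  fraction ≥ 0.8). The region sits at the N-terminus deliberately:
  window truncation at the terminus keeps edge windows inside the
  planted signal, whereas an interior region's edge windows mix planted
  and neutral codons and dilute per-residue sensitivity — a real property
  of sliding-window constraint scores worth keeping visible, but not one
  the recovery check should be confounded by. Flank residues start 15
  positions after the region so no flank window touches it.
- Exactness checks run against independent oracles: mutate-and-translate
  for the genetic code, full hypergeometric enumeration for Fisher p
  (all 2×2 tables with margins ≤ 30), textbook step-up for BH, a
  position-scan for segment extraction.
- The Dunn letter check plants four groups as two pairs of equal
  distributions (shift 3 SD between pairs, n = 150/group) and requires
  the {a, b, b, a} pattern in ≥ 19 of 20 fixed seeds; under equality each
  within-pair comparison retains its nominal false-positive probability,
  so occasional single-seed deviations are expected and tolerated.

## Numerical and degenerate-input conventions

- Fisher p-values compare pmf values with a 1 + 1e−7 relative tolerance
  to absorb floating-point ties; all-zero tables are NA.
- A pooled two-proportion z-test with pooled proportion 0 or 1 returns
  z = 0 with a warning.
- Mann–Whitney on completely tied data returns (n₁n₂/2, 1.0) directly;
  otherwise scipy's policy (exact for small tie-free samples, corrected
  normal approximation else) applies.
- Constant samples report SD 0 with NA skewness/kurtosis; moments need
  n ≥ 3 (skewness) and n ≥ 4 (kurtosis).
- Gene models failing validation (frame, alphabet, internal stop) are
  rejected with a logged warning, not silently skipped; variants whose
  REF disagrees with the transcript, or clinical rows whose stated
  amino-acid change disagrees with re-translation or is unreachable by
  one substitution, are dropped with warnings (transcript-version drift
  protection). Unknown gene joins in annotation or clinical inputs are a
  hard error listing the offenders.
- All output tables are TSV with fixed column order, `%.10g` floats and
  `NA` markers, making identical runs byte-identical.

## Known limitations

- Expected counts are unweighted possible-SNV enumerations; no
  mutation-rate model, coverage adjustment or ancestry stratification.
- Clinical target solving supports planting odds ratios on one clinical
  class at a time (per-state probabilities can be supplied directly for
  anything richer).
- Genomic-coordinate variant projection scans exon maps linearly, which
  is adequate for gene-panel scale but not genome-wide input.
- The compact letter display enumerates subsets, fine for the handful of
  groups this analysis compares, not for dozens.
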
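# mtrkit

Residue-level missense constraint profiling for disorder-annotated
proteins.

## The problem

Missense variants in intrinsically disordered regions (IDRs) are hard to
interpret: disordered sequence lacks a stable fold, is under-represented
in experimental and clinical annotation, and defeats predictors trained
on globular domains. Regional constraint metrics offer an orthogonal
signal — where human populations carry *fewer missense variants than the
genetic code makes possible*, selection is at work, fold or no fold.

`mtrkit` is a tested pipeline for that analysis. Given a set of coding
transcripts, a population variant catalog (gnomAD-style VCF), per-residue
structural annotations (DisProt/MobiDB-style) and optional clinically
labelled variants (ClinVar-style), it computes per-residue constraint,
assigns each residue one of four structural states, and runs the full
downstream statistical battery. A synthetic-data generator with known
planted structure stands in for the external databases, so every stage is
verifiable offline.

## The statistic

For each residue, a sliding window of 31 codons (truncated at the
termini) pools variant counts, and the **Missense Tolerance Ratio** is

```
        O_m / (O_m + O_s)
MTR = ---------------------
        E_m / (E_m + E_s)
```

where `O_m`, `O_s` are observed missense/synonymous PASS SNVs in the
window and `E_m`, `E_s` are the counts of *possible* missense/synonymous
single-nucleotide changes obtained by exhaustive mutagenesis of the CDS
(stop gains/losses excluded from both classes). MTR ≈ 1 means variation
appears at the rate mutation alone would produce; MTR < 1 means missense
depletion, i.e. purifying selection. Windows with no observed variants
get a missing MTR — absence of data is not evidence of tolerance.

On top of the profile:

- **significance of depletion** — one-sided exact binomial test of `O_m`
  against the expected proportion, Benjamini–Hochberg corrected across
  all residues of the run;
- **constraint classes** — Intolerant (MTR < 0.4) vs Tolerant (≥ 0.4);
- **four structural states** per residue — order, disorder, structural
  transition, missing residues — consolidated from curated and predicted
  region annotations by a configurable precedence;
- **composition enrichment** (per-state amino-acid log2 odds ratios,
  Fisher's exact test with Haldane–Anscombe correction), biophysical
  contrasts (side-chain charge, Kyte–Doolittle hydropathy, aromatic
  fraction; Mann–Whitney), segment patterning (run lengths, aromatic
  spacing), per-state MTR descriptives with Kruskal–Wallis + Dunn compact
  letters, and clinical-class-by-state enrichment with Wilson intervals
  and BH q-values.

## Worked example

Simulate a 10-gene bundle with one planted constrained region (missense
retention δ = 0.05 at residues 50–89 of the first gene) and planted
clinical odds ratios (+2 pathogenic in order, −2 in disorder), then run
the pipeline:

```python
from mtrkit.synthetic_data import SyntheticConfig, DepletionRegion, generate_bundle
from mtrkit.pipeline import RunConfig, run

cfg = SyntheticConfig(n_genes=10, protein_length=(200, 400), p_obs=0.3,
                      n_clinical_variants=3000,
                      depletion_regions=(DepletionRegion(0, 50, 89, 0.05),),
                      seed=1)
paths = generate_bundle(cfg, "example/bundle")
res = run(RunConfig(cds_fasta=paths["cds_fasta"],
                    population_vcf=paths["population_vcf"],
                    annotations_tsv=paths["annotations_tsv"],
                    clinical_path=paths["clinical_tsv"],
                    out_dir="example/out"))
print(res.state_summary.to_string(index=False))
```

prints

```
           state    n     mean   stddev  skewness  kurtosis dunn_letter
           order 1907 0.993961 0.077823 -2.765248 17.348728           a
        disorder  642 0.988241 0.098803 -3.011179 14.240926           a
missing_residues  165 1.014266 0.040213 -0.061265 -0.746624           b
```

— the three populated states sit near MTR 1 on average (the bundle is
null outside the planted region; the planted region drags the left tail,
hence the negative skew), and the Dunn letters group states whose MTR
distributions are statistically indistinguishable. The planted region is
recovered in the first gene's profile: its minimum MTR is 0.327 at
residue 74, 10 residues classify Intolerant, and 18 residues spanning
62–79 are flagged at q < 0.05. The clinical enrichment table recovers the
planted odds ratios:

```
   state clinical_class   log2_or            q significance
   order     pathogenic  2.290474 4.113297e-73          ***
disorder     pathogenic -2.320282 6.619437e-63          ***
```

The same analysis is available from the shell:

```
mtrkit simulate --out example/bundle --seed 1 --config overrides.yaml
mtrkit run --cds example/bundle/cds.fasta --vcf example/bundle/population.vcf \
           --annotations example/bundle/annotations.tsv \
           --clinical example/bundle/clinical.tsv --out example/out
```

Outputs are plain TSVs with fixed column order and `NA` markers
(`profiles.tsv`, `state_summary.tsv`, `composition_enrichment.tsv`,
`segments.tsv`, `delta_contrast.tsv`, `clinvar_enrichment.tsv`, …),
byte-identical across reruns with the same config and seed.

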
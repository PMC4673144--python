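# camlkit

Discovery of **cancer-associated microsatellite loci (CAML)** from
germline short-read cohorts: microsatellite cataloging, read-level
repeat-length genotyping, case–control association with FDR-gated
signature construction, and cross-cancer signature overlap statistics —
plus a synthetic-data generator so the whole pipeline is testable without
controlled-access data.

## Who this is for

Groups studying germline repeat-length polymorphism in disease cohorts:
you have a reference genome, per-sample aligned exomes (BAM), and a
control population, and you want the set of microsatellite loci whose
genotype distribution separates a disease cohort from controls, and how
those sets compare across diseases.

## The method

A **locus** is a maximal tandem tract of a primitive 1–7 nt motif.  An
**allele** is a tract length in nucleotides; a sample's **genotype** at a
locus is its unordered pair of allele lengths, measured per read by exact
flank anchoring and called with a stutter gate, a minimum spanning depth
of 15×, and rejection of loci showing more than two alleles in a sample.

The control cohort defines each locus's **predominant genotype** (the
modal pair).  For a cancer cohort, each locus yields a 2×2 table of
non-predominant vs predominant carriers which is tested with a two-sided
Fisher exact test; with Benjamini–Hochberg adjusted p-values `p̃`, a locus
is classed

- **signature** — `p ≤ α` (0.01) and `p̃ < 1/X`, where `X` = number of
  tested loci with `p < 1`;
- **non-signature** — `p ≤ α` but failing the `1/X` cutoff;
- non-significant otherwise.

Relative risk is the ratio of non-predominant carrier fractions
(cancer/control).  Signatures are compared across cancers by shared
percentage `100·|A∩B|/|A∪B|`, by the proportion of shared significant
loci that are non-signature in at least one cancer, and by an exact
two-stage hypergeometric tail test for three-set intersections.

## Worked example

Generate a synthetic desk-scale study (300 loci, 60 cases vs 60 controls,
10 loci planted with a variant-genotype frequency of 0.55 in cases vs 0.05
in controls) and run the full pipeline:

```python
from camlkit import default_fixture_config, end_to_end_fixture, run_study

bundle = end_to_end_fixture("study/", default_fixture_config(seed=42))
planted = {locus_id for locus_id, _, _ in bundle.truth.planted}
result = run_study(
    bundle.fasta, bundle.manifest, "study/out",
    reference_sets={"planted": planted},
)
s = result.associations["case"].summary
print(s["n_tested"], s["n_significant"], s["n_signature"])
print(sorted(result.signatures["case"].loci & planted))
```

prints

```
300 10 10
['sim1:1194-1211', 'sim1:12204-12219', 'sim1:14369-14386',
 'sim1:16592-16607', 'sim1:18788-18799', 'sim1:21006-21023',
 'sim1:3394-3407', 'sim1:5608-5616', 'sim1:7799-7810', 'sim1:9999-10014']
```

— all 300 loci were tested, 10 were significant at α = 0.01, all 10 passed
the FDR cutoff into the signature, and the signature is exactly the 10
planted loci (locus ids are 1-based inclusive coordinates on the simulated
contig).  `study/out/` then contains the catalog (BED + TSV), per-sample
genotype TSVs, the predominant-genotype table, the association table with
p-values, relative risks and class labels, the signature list, and the
overlap summaries.

The same stages are available as shell commands:

```bash
caml simulate --out study/ --seed 42
caml scan --fasta study/reference.fasta --out catalog.bed
caml genotype --bam study/bams/case0000.bam --catalog catalog.bed \
              --sample case0000 --out case0000.geno.tsv
caml run --fasta study/reference.fasta --manifest study/manifest.tsv --out study/out
```

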
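# mutpatterns

Genome-wide analysis of somatic base-substitution patterns.

Catalogues of somatic single-nucleotide variants are historical records of the
mutational processes that were active in a cell — UV damage, spontaneous
deamination of methylated cytosines, defective mismatch repair, and so on.
Each process leaves a characteristic mark that can be read out from several
angles: the spectrum of the six substitution types, the 96-channel
trinucleotide profile, transcriptional and replicative strand asymmetries, the
distribution of mutations over genomic regions, and clusters of closely spaced
mutations (kataegis). `mutpatterns` computes all of these from standard files
(VCF + reference FASTA + BED annotations), for cancer genomics and DNA-repair
researchers who want to dissect the processes behind a set of mutation calls.

## What it computes

* **96-channel mutation matrices.** Every SNV is expressed in the pyrimidine
  reference frame (C>A, C>G, C>T, T>A, T>C, T>G) with its 5′ and 3′ flanking
  bases taken from the reference genome, giving a 96 × samples count matrix
  `M`; the stranded variant (192 channels) additionally records whether the
  mutated pyrimidine lies on the transcribed or untranscribed strand of the
  overlapping gene (or leading/lagging replication strand).
* **De novo signature extraction.** Non-negative matrix factorization
  `M ≈ S·C` (multiplicative updates, generalized Kullback–Leibler objective,
  seeded multi-restart) decomposes a cohort into signatures `S` (96 × k,
  column-stochastic) and exposures `C`.
* **Refitting against known signatures.** For a single sample with profile
  `d`, the contribution vector solves

  ```
  min_x ‖S·x − d‖₂²  subject to  x ≥ 0
  ```

  via the Lawson–Hanson active-set NNLS algorithm. Unlike NMF this works per
  sample, independently of the rest of the cohort. Reconstruction quality is
  the cosine similarity α = Σᵢ dᵢrᵢ / (‖d‖‖r‖) between the original and
  reconstructed profile; samples with α < 0.95 are flagged.
* **Strand asymmetry tests.** Per substitution type, counts on the two
  strands are compared with the exact conditional form of the two-sided
  equal-rates Poisson test (binomial with p = ½); effect size is the log2
  strand ratio.
* **Regional enrichment/depletion.** Observed counts in a region are tested
  one-sided against `Binomial(n, |region ∩ surveyed| / |surveyed|)`, where
  "surveyed" are the callable bases of each sample — without this correction,
  low coverage masquerades as depletion.
* **Rainfall series** of intermutation distances for spotting kataegis.
* **Synthetic data.** A generator produces genomes, stranded gene/promoter
  annotations and SNV catalogues from known signature mixtures, with optional
  planted strand bias and regional rate multipliers, so every analysis can be
  validated against ground truth without downloading anything.

## Worked example

Simulate a small cohort from 3 known signatures, build the mutation matrix and
refit the true signatures:

```python
import mutpatterns as mp

spec = mp.SimulationSpec(seed=7, n_samples=4, mutations_per_sample=1500)
sim = mp.simulate_cohort(spec)

m = mp.build_mut_matrix(sim.catalogues, sim.genome)   # 96 x 4 counts
fit = mp.fit_to_signatures(m, sim.signatures)

print(fit.relative_contributions().round(3))
print(fit.diagnostics.round(4))
```

prints

```
           sample_1  sample_2  sample_3  sample_4
TrueSig_1     0.593     0.431     0.213     0.222
TrueSig_2     0.303     0.115     0.234     0.604
TrueSig_3     0.103     0.454     0.553     0.174

          cosine     rss  flagged
sample
sample_1  0.9989  0.0003    False
sample_2  0.9985  0.0005    False
sample_3  0.9983  0.0004    False
sample_4  0.9954  0.0009    False
```

The fitted relative contributions recover the generating mixture weights
(e.g. sample_1 was simulated with weights 0.596/0.303/0.101), and every
sample's profile is reconstructed with cosine similarity ≈ 0.995–0.999 — none
is flagged as unexplained.

The same pipeline is available from the shell:

```sh
mutpatterns --seed 7 simulate --out cohort/ --n-samples 4 --mutations 1500
mutpatterns matrix --ref cohort/genome.fa --vcf cohort/sample_1.vcf \
    --vcf cohort/sample_2.vcf --out m.tsv
mutpatterns fit --matrix m.tsv --signatures cohort/true_signatures.tsv \
    --out contributions.tsv --out-diagnostics diag.tsv
```

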
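# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `mutpatterns`.

## Coordinate and channel conventions

All internal coordinates are 1-based inclusive (the VCF convention); BED's
0-based half-open coordinates are converted at the I/O boundary only.
Substitutions are reported in the pyrimidine reference frame: a call with a
purine reference base is complemented (G>A becomes C>T) and its trinucleotide
context reverse-complemented. The 96 channels are ordered substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G), then 5′ base A<C<G<T, then 3′ base, matching
the column order of published signature catalogues so user-supplied signature
files interoperate directly; files with scrambled rows are reordered by their
channel labels on read. SNVs at chromosome termini or with an N in their
context cannot be assigned a channel; they are excluded and tallied rather
than treated as errors. A disagreement between the genome base and a
variant's REF allele *is* a hard error, because it almost always indicates a
wrong reference build and silent skipping would hide that systematically.

VCF import keeps only biallelic single-nucleotide substitutions; indels,
MNVs and symbolic alleles are counted per reason in `catalogue.skipped`.
Multi-allelic SNV records are split into one variant per alternate allele.
By default only PASS/unfiltered records are kept (`keep_filtered=True`
retains all): somatic pipelines conventionally pre-filter, and keeping
failed records silently would bias every downstream rate. Genotype columns
are ignored — one VCF is one sample catalogue.

A 96-channel profile built from fewer than 200 mutations is typically not
representative; matrix construction emits a warning (never a failure) below
that count.

## Signature refitting (NNLS)

For a sample profile `d` and signature matrix `S` (96 × k, columns sum to 1),
the contribution vector solves min‖S·x − d‖₂² with x ≥ 0, computed by the
Lawson–Hanson active-set method (scipy's implementation). The solution
satisfies the KKT conditions — gradient zero on the support, non-negative
elsewhere — which the test suite verifies to 1e-8 relative to ‖d‖, alongside
a brute-force oracle that scans the weight simplex at step 1e-3. Because
columns of `S` sum to 1, the fitted weights are on the scale of mutation
counts; "relative" contributions are weight / Σweights per sample, so a
stacked bar reaches 1 even when the fit does not fully explain the profile.

Per-sample diagnostics report the cosine similarity α between the original
and reconstructed profile and the residual sum of squares of the two
sum-1-normalized profiles. α < 0.95 flags a sample whose catalogue likely
contains processes absent from the provided signatures. Published signature
sets are correlated (several pairs have cosine ≥ 0.8), so refitted weights
of similar signatures trade off against each other; the refit finds *a*
parsimonious combination, not a unique attribution.

## De novo extraction (NMF)

`extract_signatures` factorizes the count matrix with multiplicative
updates. The default objective is the generalized Kullback–Leibler
divergence — the natural choice for count data and the default behaviour of
the standard NMF implementations used in this field; a Frobenius mode is
available. Numerical choices:

* initialization: entries uniform on [0.1, 1.1) scaled by √(mean(M)/rank),
  drawn from a PCG64 generator;
* restart r of `nrun` uses seed + r; the best run is the lowest final
  objective, ties broken by lowest run index — results are bit-identical
  across repeat calls with the same seed;
* convergence: relative objective decrease < 1e-8 or 5,000 iterations;
  divisions and logarithms are floored at 1e-12. The multiplicative updates
  make the objective non-increasing per iteration, which the tests assert;
* signature columns are normalized to sum 1 afterwards, with contributions
  rescaled so the product is unchanged.

`rank_survey` summarizes candidate ranks by best objective, mean per-sample
reconstruction cosine, and stability (mean cosine of Hungarian-matched
signatures between each restart and the best run). Recovery tests match
extracted to planted signatures by Hungarian assignment on the cosine
matrix. An independent cross-check against scikit-learn's multiplicative-
update KL NMF is part of the test suite; the hand-rolled implementation is
kept because the determinism and restart contract is part of this package's
interface.

## Strand asymmetry

Gene annotations report the coding (untranscribed) strand. A mutation whose
pyrimidine lies on the annotation strand is "untranscribed", opposite is
"transcribed". Positions covered by genes on both strands are ambiguous and
excluded; same-strand overlapping intervals are merged first. Replication
mode reuses the machinery with a replication-direction BED6 in which strand
"+" means a right-moving fork: pyrimidine on the fork-direction strand =
leading. Deriving replication direction from Repli-Seq timing profiles is
out of scope — the direction file is consumed, not computed.

The per-type test is the exact conditional form of the two-sided equal-rates
Poisson test: conditional on n = n₁ + n₂, n₁ ~ Binomial(n, ½) under the
null, and p = min(1, 2·min(P[X ≤ n₁], P[X ≥ n₁])) (doubling of the smaller
tail). Significance is flagged at raw P < 0.05 to mirror the usual figure
convention; a Benjamini–Hochberg column is always emitted alongside for
rigor. For stranded *signatures* the loadings are probabilities, so they are
scaled by the mutation total attributed to each signature and rounded to
pseudo-counts before the same test — an explicit modelling choice, since
there is no canonical count scale for a signature.

## Regional distribution

With surveyed (callable) bases per sample, expected counts are
`n_total · |region ∩ surveyed| / |surveyed|`, counting only mutations inside
the surveyed set. Regions and surveyed sets are merged (union) before
intersection so double-covered bases count once. The one-sided binomial test
uses π = |region ∩ surveyed| / |surveyed|; observed ≥ expected tests the
upper tail (enrichment), observed < expected the lower tail, and exact
equality is deterministically assigned to the enrichment branch (its tail
includes the observation, so it can never be spuriously significant).
Group-level tests pool counts and base totals across samples — a single
binomial on pooled data, not a combination of per-sample p-values.

Rainfall series report, per SNV in (chrom, pos) order, the distance to the
previous SNV on the same chromosome, coloured by the 6-category substitution
type. Kataegis detection remains visual; no segmentation is performed.

## Synthetic data: what it emulates, and what it does not

The generator's defaults define the study conditions used throughout the
tests: a 450 kb three-chromosome i.i.d. genome at 41% GC (human-like), 30
samples × 3,000 SNVs drawn from 3 signatures (Dirichlet concentration 0.05,
pairwise cosine < 0.5 enforced at generation), per-sample mixture weights
from Dirichlet(0.5), 60 genes of 1.5 kb with 300 bp promoters, and a
surveyed set covering 98% of the genome. Placement is context-conditional:
the channel is drawn first and the position uniformly among genome positions
whose plus- or minus-strand context matches, so the generating 96-channel
distribution is exact regardless of genome composition. Strand bias is
planted by re-choosing, for in-gene placements, the pyrimidine-vs-gene-strand
orientation with the stated probability; regional multipliers use rejection
sampling with acceptance probability multiplier/max-multiplier, capped at
100 retries per mutation (then an error, for deterministic failure).
Everything, including bytes on disk, is reproducible from (seed, spec).

One finite-genome caveat discovered during validation: duplicate
(chrom, pos, alt) draws are rejected, so at unrealistically high mutation
densities (thousands of mutations on a tens-of-kb genome) the favoured
strand's position pool saturates and planted strand ratios flatten toward
symmetry. Planted-effect tests therefore run at the default 450 kb scale,
where the mean recovered log2 ratio is unbiased (−1.589 vs −log2 3 = −1.585
over repeated seeds). Note also that with a multiplier m on a fraction f of
the genome, the expected log2(observed/expected) is
log2(m·f/(m·f + 1 − f)/f) — e.g. 1.447 for m = 3, f = 0.05, slightly below
log2 3 — because the enriched region inflates the sample's total.

The simulations do not emulate: realistic genome composition (repeats,
isochores, CpG islands), replication timing structure, clonal architecture
or variant allele fractions, sequencing error, or inter-sample coverage
variation. Passing the planted-effect tests demonstrates the estimators and
tests are correct under their own model assumptions, not that real tumour
data satisfy those assumptions.

## Problem sizes and scope choices

Test and acceptance runs use desk-scale problems chosen to exercise every
code path with comfortable statistical margins: 50 random NNLS instances,
a 30 × 3,000-mutation cohort for NMF recovery (matched cosines ≥ 0.999 in
practice against the ≥ 0.95 requirement), 3 pooled catalogues of 2,000
mutations for strand-bias recovery, and exhaustive enumeration of the exact
tests up to totals of 20–25. The CLI's `--threads` flag is accepted for
compatibility but reading is single-threaded; the correctness contract is
single-threaded-equivalent output. Figures are tested at the level of their
underlying `PlotData` tables, never pixels, since rendering backends are not
bit-stable across platforms.

## Known limitations

* No indel/MNV/doublet channels and no extended (1536-channel) contexts.
* No probabilistic/Bayesian signature extraction or bootstrapped signature
  uncertainty.
* Annotations are consumed as files (BED); no retrieval from Ensembl/UCSC
  and no GFF parsing (flatten to BED first).
* The refit's non-uniqueness under correlated signature sets (above) is
  inherent to the objective, not a solver artifact.
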
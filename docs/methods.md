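# Methods

This note documents the models, statistical procedures and design
choices behind `epicon`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Coordinates and chain mapping

All intervals are 0-based, half-open, BED-style. A chain file describes
a gapped pairwise alignment between a source assembly (always plus
strand) and a target assembly (either strand, minus-strand coordinates
stored as in the UCSC format). `map_interval` projects a query through
the aligned blocks of a single chain and reports the span from the first
to the last mapped base, converted to plus-strand target coordinates; a
query maps only when at least `min_mapped_fraction` of its bases fall in
aligned blocks of one chain (default 0.95, the liftOver `-minMatch`
default). Queries on chromosomes absent from the chain set are unmapped,
not errors. When several chains cover a query the one mapping the
largest fraction wins, ties broken by chain score. A deliberately naive
per-base reference mapper is kept in the package and the test suite
checks exact agreement between the two on randomly rearranged assembly
pairs.

Broad acetylation peaks (2–5 kb) often contain only a short alignable
core. `iterative_ortholog_search` therefore falls back to fixed-width
sub-windows evaluated center-outward at assay-specific increments:
300 bp windows every 300 bp for H3K27ac, 50 bp windows every 50 bp for
DNase and Foxp3 loci. The sub-window width is set equal to the step —
the smallest unit consistent with the scan increments — and the
`±k·step` tie is broken toward the lower coordinate. A progressive
window-shrinking scheme is a defensible alternative reading of this
procedure; the fixed-width scan was chosen for determinism and
testability, and the scan geometry is a plain dataclass so other
schemes can be swapped in.

## Union atlas

Peaks from each species are lifted into the other assembly. A human and
a mouse peak whose cross-mappings overlap reciprocally (≥ 1 bp both
ways) collapse into one genetically conserved locus; many-to-one
conflicts are resolved by largest total overlap, then lowest coordinate.
A peak that maps but meets no partner peak remains genetically conserved
— the partner species' signal is quantifiable at the mapped interval and
may simply be epigenetically inactive there. Unmappable peaks become
species-only loci, which by definition cannot be epigenetically
conserved and carry zero signal for the missing species. Overlapping
same-species peaks are merged (with a warning) before mapping, so every
input peak is represented exactly once.

## Signal model

Reads are reduced to start + strand. Each read is extended to 200 nt in
its sequencing direction and only the central 100 nt contribute: a
plus-strand read starting at *s* covers `[s+50, s+150)`, mirrored for
minus-strand reads. Quantification counts a read toward a peak when this
central window overlaps the peak by ≥ 1 bp (the overlap rule is not
dictated by the transform; ≥ 1 bp was chosen for consistency with the
track definition), and scales to reads per million aligned reads (RPM).
Peaks are dropped when below 1 RPM in every ChIP sample, above 0.5 RPM
in any input sample (max over input samples — the conservative reading),
or overlapping a blacklist. All log-scale signal work uses
`log2(RPM + 0.5)`; the symmetric pseudocount shrinks fold changes of
weakly covered loci toward zero.

## Conservation and lineage specificity

Cross-species epigenetic correlation is Pearson's r on `log2(RPM+0.5)`
over genetically conserved loci; biological replicates are averaged per
cell type first. Lineage specificity per species is
`lfc = log2((RPM_aTreg+0.5)/(RPM_Teff+0.5))` thresholded at τ = 1
(2-fold) into up/down/ns; the 9-way combined label partitions conserved
loci. Conservation of lineage specificity is a one-sided upper-tail
hypergeometric test of the per-species up (or down) sets over the
conserved-locus universe, and a rank-cutoff sweep repeats the test on
top-k sets so no single fold-change cutoff is privileged. Elements are
assigned to every gene whose body lies within 100 kb, with a
nearest-TSS fallback; expression concordance per element class is a
two-sample Kolmogorov–Smirnov test against all expressed genes.

The mobility analysis asks, per genic locus: (1) do lineage-specific
elements occur in both species at non-orthologous positions, and is the
gene's expression change concordant (empirical p by permuting expression
over genes); (2) how many lineage-specific elements have a genetically
conserved but epigenetically inactive ortholog (activity floor 1 RPM);
(3) with loosened rank cutoffs, taking the maximally lineage-specific
element per locus, how many genes show weak differential expression
(|log2 FC| > 0.5 — the fold threshold is read on the log2 scale — or
FDR q < 0.01, Benjamini–Hochberg).

## Foxp3 binding

Binding conservation at conserved loci is classified by an occupancy
floor (default 1 RPM) on both sides of the orthology map: both /
human-only / mouse-only; sites below the floor in both species lack
robust quantification and are excluded; unmappable sites are reported
separately. Acetylation change per class is a Welch two-sample t against
all acetylated loci. Motif enrichment compares presence of the forkhead
consensus (default `RYAAAYA`, any IUPAC pattern accepted) in bound sites
vs the two 200 nt flanks, both strands, one presence/absence call per
region, pooled flanks, Fisher's exact test with the sample odds ratio.
Repression of bound genes is a one-sided KS test of nearest-gene
expression change against all expressed genes.

## Polymorphism constraint

For each DHS a 150 bp window about the center is searched for SNPs; the
maximum minor allele frequency across the AFR/EUR/CEU/CHB/JPT
populations is binned at 0.05/0.15/0.25/0.35/0.45 (upper bins
left-closed, so MAF 0.05 joins the 0.1 bin). For each conservation
group the count of DHSs at or above each bin gives a decaying spectrum;
a linear fit of log10(count) on bin value (zero-count bins dropped)
summarises it, and the *steepness* of decay (negative slope) is the
constraint statistic. The test statistic is
Δ = steepness(conserved) − steepness(non-conserved), referred to a
permutation null that shuffles conservation labels with group sizes
preserved; p uses the add-one convention, (1 + #{Δperm ≥ Δobs}) /
(n_perm + 1). The direction convention — constraint at conserved DHSs
manifests as a *steeper* MAF-spectrum decay — is the package's
resolution of an ambiguity in how "greater slopes" can be read for a
decaying log-count response; the statistic is isolated behind
`decay_steepness` so alternates can be swapped.

## Allele-specific acetylation

Variants enter the analysis when every genotype call passes QC, they
are heterozygous in ≥ 2 donors *and* homozygous in ≥ 2 donors, and
their input (non-ChIPed) chromatin shows no imbalance (exact two-tailed
binomial p ≥ 0.05). ChIP duplicate reads are removed by keeping one
read per (chrom, start, strand) uniformly at random — avoiding the
reference bias of score-based dedup. Per-variant imbalance is an exact
two-tailed binomial at ratio 0.5 (minlike convention; at 0.5 this is
tail doubling), on ref/alt depths summed over heterozygous donors.
Within an element, variants in LD (r² > 0.99 in all five reference
populations) collapse to the highest-depth representative; collapse
happens *before* the evidence prefilter (p ≤ 0.2, boundary inclusive)
so the element's candidate set does not depend on the ChIP counts —
a requirement for the empirical null below. Surviving p-values combine
by Fisher's statistic, −2 Σ ln p.

Element-level significance is a Monte-Carlo empirical p against a null
that mirrors the observed procedure *at the observed depths*: each null
replicate redraws every candidate variant's ref count as
Binomial(depth, 0.5), recomputes the same discrete p-values, applies
the same prefilter, and aggregates the survivors; replicates where no
variant survives are discarded, matching the conditioning of tested
elements. Because exact binomial p-values are discrete, observed and
null statistics tie with real probability; ties are split uniformly at
random, which makes the empirical p exactly uniform for a null element.
An idealised aggregator against continuous Uniform(0,1) draws is also
provided; its empirical p converges to the chi-square survival function
with 2k degrees of freedom and the acceptance suite verifies that
limit. The idealised null is *not* used for element calling at
desk-scale depths, where p-value discreteness would make it severely
conservative and miscalibrated.

Genotype association across zygosity doubles heterozygous per-allele
RPMs, excludes individuals with ≤ 5 reads, mean-normalises, and either
(a) tests heterozygous imbalance and homozygous group differences
(two-sample t) separately and multiplies the p-values — the two donor
sets are disjoint, hence independent — or (b) regresses normalised
coverage on allele codes {0, 1, 2, 3}, heterozygous individuals
contributing their two allelic values at codes 1 and 2. Slope
differences between two groups are referred to t with n₁ + n₂ − 4
degrees of freedom (each group contributes a fitted slope and
intercept; "fixed intercept" is read as the intercept being common to
the cell types within a group).

## Disease-SNP enrichment

Studies with ≤ 5 independent associated SNPs are dropped. Elements
expand to ±100 kb regions, additionally stretched to cover the most
proximal gene body when it extends beyond the window (the window and
gene body augment each other rather than substitute); overlapping
regions merge, so a haplotype block shared by several elements is
counted once. Enrichment of a disease set is a one-tailed
hypergeometric test with all catalogued disease variants as the
universe. Risk elements partition into four nested categories —
genetically non-conserved, conserved, lineage-specific in human,
lineage-specific in both species — each element counted at its deepest
level.

## Synthetic data

The generators emulate the study design the pipeline targets, and their
defaults are the study conditions: human ChIP panel 7 aTreg / 4 rTreg /
2 Teff / 1 Tn samples from 7 donors, mouse panel 2/4/2/4 biological
replicates; atlas composition 85% conserved-active, 1.5%
lineage-specific per single species, 0.1% lineage-specific in both,
plus small discordant, single-species-active and species-only-genetic
classes; lineage-specific elements change 4-fold between aTreg and
Teff. Per-locus baseline log2 signal is bivariate normal across species
(sd 2, correlation 0.5 — matching the dynamic range and cross-species
correlation scale of acetylation data); counts are negative binomial
with mean 50 and size 50 (dispersion 0.02: replicate correlations
> 0.99 imply near-Poisson replicate noise at active elements).

Two genome-pair builders exist: a rate-based sampler of deletions,
insertions, inversions and chromosome breaks whose chain file encodes
the relation exactly (used for mapping correctness), and a
locus-anchored builder that allocates one alignment segment per planted
conserved locus (used at scale, so conservation truth is exact by
construction). Donor cohorts draw genotypes under Hardy–Weinberg at
Beta-distributed population frequencies; allele-specific elements give
heterozygous ChIP reads a reference-allele probability θ (default
0.75) while input stays at 0.5; panel haplotypes carry perfect-LD
blocks to exercise the r² collapse. GWAS catalogs place background
variants uniformly and enriched disease sets inside target regions at a
configured multiple of the chance rate, with study sizes straddling the
>5-SNP filter.

What the generators do *not* emulate: realistic sequence composition
(motif occurrences are planted explicitly where needed), mappability
artifacts and GC bias, reference-allele alignment bias beyond what
random dedup addresses, realistic human LD decay (blocks are perfect or
absent), linked selection, or peak-calling errors (peak presence equals
planted activity, since peak calling is upstream of this package).
Passing benchmarks therefore demonstrate correctness and calibration of
the statistical machinery under the stated generative model, not
robustness to these real-data complications.

## Estimators used in the recovery benchmark

The atlas-composition benchmark classifies epigenetic activity by peak
presence (exactly how the real pipeline consumes peak calls) and calls
a locus lineage-specific only when the fold change passes τ *and* an
exact binomial test of the pooled aTreg-vs-Teff count split (null
probability = the replicate-count ratio) rejects at α = 2×10⁻⁴. The
count-support condition exists because at weakly covered loci fold
changes are dominated by sampling noise; α is set so the expected
number of false lineage-specific calls across a 20,000-locus atlas
(~n·α ≈ 4 per species) is negligible against the planted class sizes
(~300). Cross-species correlation is estimated on conserved loci active
in both species — the population whose planted correlation is defined.

## Problem sizes and numerical conventions

The shipped benchmarks use: 1,000 mapping queries over ≤ 100 kb
assemblies; 10,000 null variants at depth 20 for binomial calibration;
1,000-element cohorts with 10,000-replicate empirical nulls for
element-level calibration; 300 elements for power; 100,000 null draws
for the chi-square-limit check; 1,000 runs × 100 permutations (null)
and 100 runs × 200 permutations (power) for the constraint test at
2,000 / 5,000 DHSs; 20,000 loci for composition recovery; and 100 / 50
catalog replicates for disease-enrichment calibration / power. The
analysis drivers narrate a single 1,000-locus study (seed 2026).
Monte-Carlo p-values use the add-one convention everywhere; empirical
nulls with discrete statistics use randomized tie-breaking; permutation
group sizes are preserved; every stochastic routine takes an explicit
seed and all generators are byte-reproducible for a fixed seed.

## Known limitations

- The union atlas resolves many-to-one mappings greedily; a reciprocal
  best-hit or graph-matching formulation could differ at dense loci.
- The constraint-test regression response (log10 exceed-count on bin
  value) is one defensible summary of the MAF spectrum; per-DHS
  regression on a conservation indicator is an alternative.
- LD collapse requires the representative's r² to exceed the threshold
  in *all* populations; variants missing from a panel are treated as
  independent (with a warning) rather than dropped.
- The joint (non-collapsed) aggregation mode for LD-linked variants is
  intentionally not the default; Fisher aggregation assumes
  independence, which the collapse step is there to protect.
- The mobility analysis on the synthetic study is structurally sterile
  (one gene per locus), so its planted-scenario behaviour is exercised
  in unit tests with constructed fixtures instead.
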
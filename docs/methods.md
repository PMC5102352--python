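# Methods

## The genetic model

The package targets a single locus with two alleles: a recurrent-parent
allele R (yellow seed coat) and a dominant donor allele D (brown). In a
backcross to the recurrent parent every plant is RR or RD at each locus,
so genotypes are stored as boolean donor-carrier matrices, and the
phenotype is brown iff the plant carries D at the trait locus — the only
dominance coding consistent with the 1:1 phenotype ratio a backcross
shows when the recurrent parent is yellow. A flag in `linkmap` allows the
recessive-donor alternative for other designs.

## Simulator (`popsim`)

**Crossovers.** Per meiosis the crossover count on a chromosome is
Poisson(L) with L the chromosome's map length in Morgans; positions are
uniform on the physical chromosome (uniform cM/bp, since no recombination
map is assumed) and there is no interference. This is the simplest model
consistent with the sub-centimorgan distances fine mapping estimates; the
sampling is isolated in `sample_crossovers` so an interference model could
be swapped in. Map length 0 is allowed and transmits chromosomes whole.

**Breeding scheme.** Starting from the F1 (heterozygous at every
parent-diagnostic SNP), each of the first n−1 backcross generations is
represented by a single offspring rejection-sampled to be heterozygous at
the selection locus; the n-th backcross produces the full unselected,
phenotyped population (default n = 4, 1,739 plants). Selection acts only
through the trait locus — no background (genome-wide) selection — so
unlinked heterozygosity decays as 2^(−n) in expectation while a long donor
segment is dragged along around the selected locus. How stringently real
programmes purge background heterozygosity is rarely reported;
`n_backcrosses` is the exposed knob.

An implication worth knowing when validating against marker data: over n
backcross meioses the marker–phenotype recombinant fraction is not r but
(1−r)^(n−1)·r + (1 − (1−r)^(n−1))/2 — once the donor allele at the marker
is lost in an early generation, half of the final plants score as
recombinant. Estimating r as k/n is exact for a single meiosis (BC1) and
the convention used for observed screen tables; the simulator tests check
the multi-generation expectation explicitly.

**Bulks and pooled sequencing.** Bulks are uniform samples without
replacement of 20 plants per phenotype (defaults). Per site and pool,
depth ~ Poisson(15) and each read reports the donor allele with
probability f(1−e) + (1−f)e, where f is the bulk's true donor-allele
frequency and e = 0.001 the symmetric per-read miscall rate. Zero-depth
sites are emitted and treated as missing downstream. Not modelled: read
mapping bias, indels, multi-allelic sites, FASTQ-level artifacts —
conclusions from passing tests therefore concern the sampling statistics
of BSA, not alignment artifacts of real pipelines.

## Polarization and SNP indices (`variantio`, `snpindex`)

Parent-diagnostic SNPs are sites where each parent is homozygous
(operationally: 100% of reads one allele at depth ≥ 4, a threshold exposed
as a flag since providers rarely publish theirs) for different alleles.
One parent — by convention the donor — is the reference; the *measured*
allele is the other parent's, and a pool's SNP index is measured reads /
total reads, missing at depth 0. Swapping the reference parent maps every
index i to 1−i and Δ to −Δ exactly (tested).

Two filters remove uninformative sites: (a) index < 0.3 with depth < 7
**in both pools** (strict inequalities, AND within and across pools — the
strictest reading, with per-rule tallies for audit); (b) index missing in
either pool. The sliding window (1 Mb window, 1 kb step, anchored at
position 1, 1-based inclusive spans, trailing windows clipped and flagged)
reports the **unweighted mean** index per pool — following the cited
QTL-seq practice of averaging per-SNP indices; a depth-weighted variant
would be a one-line change — and Δ = mean(brown) − mean(yellow). The
subtraction order is configurable; windows with fewer than 10 SNPs are
flagged and excluded from interval calling to guard against single-SNP
spikes.

## Null band and candidate intervals (`cibands`)

The 95% band reproduces the two sampling layers of a null window: (i)
bulk composition — each bulk's heterozygote count ~ Binomial(20, 1/2),
giving its allele frequency; (ii) sequencing — per pool a zero-truncated
Poisson depth around the grid value, then binomial reads. Two-stage
sampling (genotypes, then reads) preserves the bulk-size variance floor
that a single binomial on the expected frequency would lose. The
heterozygote probability 1/2 matches the 1:1 segregation at the selected
locus and is conservative for unlinked loci partially purged by earlier
backcrosses; it is exposed as `het_prob`.

Depth is drawn Poisson rather than fixed deliberately: at a fixed integer
depth d the null Δ lives on the lattice {j/d} with atoms of several
percent, and no deterministic quantile pair attains 95% coverage (at
d = 15, bulk 20 the achievable two-sided coverages bracket 0.95 at ~0.914
and ~0.964); Poisson depth matches the sequencing model and restores
near-continuous coverage (empirically 0.950 ± 0.003). Quantiles are the
empirical (1±c)/2 order statistics of 10,000 replicates on a depth grid
1..100 with nearest-neighbour lookup at each window's mean member depth.

Candidate intervals are maximal runs of significant windows (union of
member spans, peak Δ by absolute value); runs separated by at most
`merge_gap_bp` (default 0 — raw runs) are merged.

## Fine mapping (`linkmap`) and interval algebra (`intervals`)

Recombinants are genotype–phenotype discordant plants (missing calls drop
out of n); distances are Kosambi, reported to 3 decimals. The flanking
interval runs from the left flanking marker to the right one, using by
default each marker's **outer** span coordinate (the edge facing away from
the cosegregating block) — the convention that reproduces published
flanking intervals quoted from marker-span tables; the inner-edge
convention is available behind `boundary="inner"`. Missing flanks yield
open-ended intervals, flagged.

Interval lengths use end − start (coordinate difference), not the
inclusive base count: published region sizes quoted from coordinate pairs
follow this convention, and it is applied uniformly (kb rounded to
integer, Mb to 1 decimal). Gene counting uses any-overlap (≥ 1 bp), via an
interval tree, checked against a brute-force scan. BED I/O converts
to/from the internal 1-based inclusive coordinates.

## Pipeline, determinism and problem sizes

One master seed drives everything; per-stage generators derive from
(stage index, master seed) seed sequences, so stages re-run identically in
isolation. Summaries are JSON with sorted keys; byte-identical reruns are
tested. Plots (Manhattan panels per pool plus Δ with the band) are
optional artifacts; nothing downstream reads them.

Default simulated scans use one 30-Mb chromosome with 3,000 diagnostic
SNPs (100 per 1-Mb window) — enough for window means to be tight while
keeping a full 50-seed recovery study under a couple of minutes; real
datasets are denser, which only sharpens window means. The
locus-recovery test requires the top candidate to contain the truth in
≥ 90% of 50 seeded runs at the default study conditions.

## Known limitations

- The BC-lineage bottleneck (one parent per intermediate generation) makes
  between-run variance of marker retention large; population-level
  expectations hold, per-run outcomes are bimodal.
- Thresholds depend on `het_prob`; for highly purged backgrounds the
  default band is conservative (wider than necessary).
- No multi-point map ordering: markers are ordered by physical position.
- Sequencing error is symmetric and site-independent; allele-specific
  mapping bias would shift indices in ways the null does not model.
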
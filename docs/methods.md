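# Methods

`bsnptyper` implements SNP-panel typing of the chicken MHC-B region: the
~231 kb interval of reference sequence AB268588 between the *BG2* and
*CD1A1* genes, typed with a 101-SNP panel of which the 90 SNPs spanning
30,189–240,933 bp define haplotypes ("core" SNPs). The 11 5' SNPs
(9,551–27,791 bp) are excluded from haplotype definition because the
*BG2* segment they interrogate is duplicated or deleted on some
chromosomes. All coordinates are 1-based positions on the reference;
BED exports convert to 0-based half-open intervals.

## Genotype model

A diploid call at one SNP is one of seven states. Besides the usual
`XX`, `YY`, `XY` and `FAIL`, three states carry copy-number information:
`DUP_XXY` and `DUP_XYY` arise when one chromosome carries a duplicated
segment bearing both alleles, so a diploid presents three amplifiable
targets at allele ratios 2:1 or 1:2; `AMBIG_BOTH` records "both alleles
present" without a resolved configuration (IUPAC K/M/R/Y in tables).
Per chromosome, a haplotype carries `X`, `Y`, `BOTH` (duplicated, both
alleles) or `MISSING` (consistent assay failure, written `F`).

Diploid calls derive from the two chromosomes' allele content: a 1-copy
chromosome contributes its allele, a duplicated one contributes one copy
of each allele, a deleted one contributes nothing. Content (2,1) maps to
`DUP_XXY`, (2,2) to `AMBIG_BOTH`, (0,0) to `FAIL`, and so on. This
reproduces the observed cluster behaviour: a bird homozygous for a
duplicated haplotype reads at the heterozygote position, and a deleted
homozygote consistently fails.

## Endpoint-fluorescence calling

KASP genotyping reports each allele through one fluorophore (VIC for X,
FAM for Y); the genotype is read from the point's position on the
normalized two-dimensional intensity plane. Noiseless centroids are
XX=(1,0), YY=(0,1), XY=(0.5,0.5), DUP_XXY=(2/3,1/3), DUP_XYY=(1/3,2/3),
FAIL=(0,0). Classification is nearest-centroid with a rejection radius
(default 0.2) beyond which a point is `UNDEFINED`: the radius exceeds
half the minimal inter-centroid distance (≈0.118), so gating never
changes which centroid wins — it only rejects aberrant chemistry. At
Gaussian noise sd 0.05 per axis the expected rejection rate is ~e⁻⁸ and
measured concordance is ≥99%; the residual errors are XY↔DUP
confusions, whose centroids are only √2/6 apart. A fitted mixture model
was deliberately not used: the cluster geometry is fixed by the copy
model, and the vendor's clustering software is proprietary.

qPCR copy number uses the ddCq method with a single-copy internal
control (*RNAseP*-like) and a disomic calibrator:
`GE = eff^-(dCq_sample - dCq_calibrator)` with `dCq = mean Cq(target) -
mean Cq(control)`. Efficiency defaults to 2.0 (perfect doubling),
overridable. Replicates (six by default) are aggregated by arithmetic
mean after dropping outliers >1.5 Cq from the median, with a warning.
A target that never amplifies is reported as `NO_AMPLIFICATION`, the
signature of a homozygous deletion.

## Haplotype inference

Within each line in which MHC-B segregates: (1) birds with no
heterozygous core call define haplotypes directly; (2) each remaining
bird is compared with the known haplotypes — if exactly one is
compatible with its genotype, that pattern is subtracted and the
complement becomes a new haplotype; birds compatible with two or more
known haplotypes are considered explained; birds matching none wait for
the next round; (3) rounds repeat to a fixpoint (bounded by the number
of birds), and haplotypes are then reconciled across lines, merging
vectors identical over mutually non-missing positions and filling
missing positions from counterparts. Birds never explained are reported
as unresolved — a legitimate outcome, e.g. two haplotypes seen only
together in heterozygotes.

The procedure is greedy and assumes lines in which haplotypes are
anchored by homozygous birds (or reachable from them by unique
subtraction). On such lines it provably returns exactly the haplotypes
common to every minimum-cardinality consistent phasing, which the test
suite verifies against an exhaustive-search oracle on hundreds of random
tiny lines. Without that anchoring the greedy result can both miss
globally forced haplotypes and commit to complements that parsimony
leaves open; the package reports, it does not guess.

Naming: `BSNP-<family letter><two-digit index>` with an optional
variant-letter suffix for haplotypes distinguished only in the 5'
region, followed by `(LEI sizes[;serology])` when annotations exist.
Indices are assigned within a family by descending observation count,
ties broken by allele vector — the historical numbering is not
reconstructible, so a deterministic rule is used.

## Recombinant detection and hotspots

A candidate haplotype absent from its population's haplotype set is
scored as recombinant only if it is a single-breakpoint mosaic of two
haplotypes *both present in that population*; candidates with only one
identifiable parent go to a separate apparent-recombination report and
never enter rates. All ordered parent pairs are searched; up to
`max_mismatches` (default 1) discordant sites are tolerated and
annotated — an allele found in neither parent as a putative mutation, a
shared assay failure with one parent as a putative deletion. Among
valid pairs the call minimizes mismatches, then maximizes interval
width. Double crossovers are not searched.

Because crossovers fall inside runs of parental identity, a breakpoint
is localized to the interval between the last informative SNP (parents
differ, calls present) matching the 5' parent and the first informative
SNP matching the 3' parent. Hotspot profiling counts, for each 1000-bp
bin tiling the reference from coordinate 0, the number of unique
recombinant haplotypes whose breakpoint interval fully contains the bin
(an overlap mode is available); hotspots are maximal runs of bins with
count ≥4, lettered left to right. Note the resolution limit: intervals
end at informative SNPs, so counts smear roughly one informative-SNP
spacing beyond a true hotspot, and with weakly differentiated parents a
single hotspot can present as a broadened or occasionally split region.

Rates are exact binomial point estimates with Clopper–Pearson 95%
intervals: crossovers per 100 birds (7/1189 → 0.6, CI 0.24–1.21) and
LEI0258 mutations per 1000 birds (3/2667 → 1.1). Pedigree screening
flags an offspring LEI0258 allele attributable to neither parent and
records its signed distance to the nearest parental allele; changes
that are not multiples of the 12/13-bp repeat units are flagged but
still counted.

## Haplotype families

Haplotypes are clustered as taxa: pairwise uncorrected fractional
dissimilarity over core SNPs with pairwise deletion of missing calls
(`BOTH` is its own state; pairs sharing <50% of sites are refused), a
neighbor-joining topology (Saitou–Nei, negative branch lengths clamped
to zero, ties on the Q-criterion broken by the lexicographically
smallest label pair for determinism), and branch support from bootstrap
resampling of SNP columns (default 1000 replicates) with a
majority-rule consensus also exported. scikit-bio's independent NJ
implementation serves as a cross-check in the tests, never as the
implementation.

Family assignment follows the median pairwise patristic distance (MPPD)
rule: the NJ tree is midpoint-rooted, patristic distances are computed
between **all** nodes, internal and terminal, and the similarity
threshold is the 10th percentile of that distance distribution. A
family is a maximal clade whose within-clade MPPD is at or below the
threshold (preorder descent; qualifying clades are not subdivided);
leaves in no qualifying clade become singleton families, and letters
A, B, C, … are assigned in traversal order to multi-member and
singleton families alike. A second, non-membership-altering constraint
flags families whose subtending branch has bootstrap support below 70%.
One geometric consequence worth knowing: the percentile threshold can
only admit clades whose pairs are a small fraction (≲ the percentile)
of all node pairs, so on a topology consisting of exactly two tight
clades the 10% rule intentionally returns sub-structure; it is tuned
for diverse collections (tens of haplotypes, many families), which is
where it is used. Jackknife stability (random leaf deletion, default
20%) reports per-family co-clustering persistence.

## Synthetic populations

The simulator generates the structure the analysis assumes, with truth
tables for every stochastic event; all randomness flows from one seed
and outputs are byte-identical across reruns.

* **Founders.** Family centroids are codewords of a binary code with a
  guaranteed minimum Hamming distance (complementary vectors for two
  families; tiled Hadamard rows otherwise, minimum distance
  ⌊90/p⌋·p/2 for code order p), XORed onto a random base and
  column-permuted. Within-family variants flip ≤⌊w/2⌋ disjoint
  positions. Separation is therefore guaranteed, not sampled for:
  within-family pairs differ at ≤w SNPs, between-family pairs at ≥b,
  with feasibility checked up front.
* **Pedigree.** Defaults mirror the surveyed cross: 15 sires × 142
  dams → 1189 offspring; parents carry two distinct line haplotypes
  when available. With probability 0.006 per offspring (the observed
  7/1189) one randomly chosen transmission is a single-crossover mosaic
  at a position drawn from weighted hotspot bins (default: 80% of mass
  in the recombination-rich 35–100 kb stretch). At most one crossover
  per transmission, matching the single-breakpoint mosaics actually
  observed.
* **LEI0258.** A per-family allele from the observed 182–552 bp
  repertoire, placed at ≈128.5 kb so crossovers transmit the correct
  side's allele; mutations occur at 1.1/1000 offspring in one repeat
  step of 12 or 13 bp, upward by default (all pedigree-observed
  mutations were +12 bp increases).
* **5' CNV.** Each founder carries 0, 1 or 2 copies of the
  12,062–13,992 bp segment (drawn ≈0.19/0.66/0.15, the observed
  fractions of failing, normal and dual-allele haplotypes, unless a
  profile is given); 0 copies yield `MISSING`, 2 copies `BOTH` at the
  segment's SNPs, and diploid calls follow the allele-content model.
* **Assay channels.** Fluorescence is the centroid plus truncated
  Gaussian noise (sd 0.03 default); qPCR Cq values follow
  `-log_eff(copies/2)` around a base cycle with Gaussian noise. The
  source study states no quantitative noise model, so these defaults
  are free parameters chosen to be realistic, and the tests that depend
  on noise state their sd explicitly.

What the simulator does not emulate: genotyping error beyond symmetric
Gaussian fluorescence noise, allele dropout, linkage to loci outside
the panel, double crossovers, gene conversion, per-haplotype PCR
efficiency differences (observed for the reference junglefowl sample),
and real inter-SNP spacing (core SNPs are evenly spaced because no
per-SNP coordinate table is bundled). Passing recovery tests therefore
demonstrate correctness of the algorithms under the stated model, not
robustness to every artefact of real KASP data.

## Problem sizes used in the checks

The bundled checks run, per invocation: 200 simulated 1189-bird
populations for rate recovery (mean detected recombinants vs the
binomial expectation 7.13, slightly reduced by same-gap crossover
collisions, ≈0.24 expected per population); 500 exhaustively verified
tiny lines for phasing; 100 random additive matrices (≤10 taxa) for NJ;
20 seeds for hotspot recovery; 10 (tests) or 5 (script) seeds of
6 families × 4 haplotypes at 200 bootstrap replicates for clustering;
1000 noisy fluorescence cells for calling. These sizes were chosen so
the whole suite completes in about a minute while keeping Monte-Carlo
standard errors far from the asserted margins.

## Known limitations

* Reproducing the published 22-family partition or 78-haplotype table
  requires the study's supplementary tables, which are not
  redistributable here; the clustering convention (midpoint rooting,
  preorder maximal clades) is one documented reading of the MPPD
  method, and the exact published partition may be sensitive to it.
* The apparent-recombination report identifies the one matching parent
  heuristically (prefix scan); it is a triage list, not a call set.
* `reconcile_across_lines` merges into the earliest compatible
  haplotype when several could absorb a vector; with heavy missingness
  the merge order can matter.
* Haplotype inference is purely combinatorial: no EM/statistical
  phasing, and pedigree information is used only for LEI0258 mutation
  screening, not to phase genotypes.
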
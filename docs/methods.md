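# Methods

## Data model

The unit of analysis is one patient with several tumors, each sampled in
one or more regions, plus a matched normal. Inputs are a mutation table
(1-based positions, per-sample ref/alt read depths, gene and functional
class supplied by upstream annotation), an optional SEG-like segment
table (0-based half-open, per-segment logR, mirrored BAF and number of
informative SNPs), and a sample manifest. The package performs no
alignment, variant calling from reads, or annotation; the presence-call
layer is a deliberately simple read-count classifier standing in front of
whatever caller produced the table.

## Presence calling and its thresholds

Each matrix cell is classified from depths alone:

* *present*: alt reads ≥ `min_alt` (default 3) and VAF ≥ `min_vaf` (0.05);
* *covered-absent*: total depth ≥ `min_cov_absent` (10) and alt reads ≤
  `max_alt_absent` (1);
* *low-coverage* otherwise.

Defaults are ordinary whole-exome heuristics; `min_cov_absent` matches the
display filter of the VAF heatmap (coverage strictly greater than 10 in
every sample, non-synonymous SNVs only — the strict `>` is a deliberate
verbatim reading and is configurable). VAF at depth 0 is missing, never
0: claims of absence require coverage, because the sibling-vs-descendant
argument rests on covered zeros. Cells with 2 alt reads at high depth
satisfy neither rule and fall into low-coverage limbo rather than being
coerced either way. A mutation called present in the normal is flagged
suspect-germline and excluded from somatic sets (logged, kept in the
matrix).

## Set statistics

Intratumor statistics use the tumor union as denominator
(heterogeneity = 1 − |intersection over regions| / |union|), the strict
definition in which a mutation must be *called present* in every region
to be common. A coverage-aware variant (count a mutation as common if
present wherever covered) was considered and rejected as the default
because the strict definition is what the pinned region-common counts
reproduce; low-coverage cells instead matter in the distance metric and
the origin classifier, where they are treated as missing. SNVs and indels
are pooled for all "somatic alterations" statistics; substitution spectra
use SNVs only, collapsed to the six pyrimidine-reference classes, with
transitions = C>T + T>C.

## Phylogeny

Distances between samples are Jaccard on present sets, computed over rows
covered in both samples of each pair (missing cells leave both numerator
and denominator). Clustering is scipy average linkage; samples are sorted
lexicographically first so ties break deterministically.

The parsimony tree treats each mutation's support set (samples where it
is present) as a binary character split. Distinct splits are sorted by
support count (ties: lexicographic on sample ids) and accepted greedily
into a laminar family seeded with the root and the leaf singletons — on a
conflict-free matrix this is exactly the perfect phylogeny, which the
test suite verifies against 100 random topologies of 4–8 leaves. Each
incompatible minority split is assigned to the accepted clade minimising
the symmetric difference (character flips), ties to the smaller clade
then lexicographic. Branch lengths in the emitted Newick are mutation
counts per branch.

## Origin classification

Per recurrence, concordance with each primary is |R ∩ P| / |R| on union
sets. Origin is `intrahepatic_metastasis` when the best concordance is ≥
`t_met` (0.5) and beats the runner-up by `margin` (0.2); `de_novo` when
the best is < `t_denovo` (0.2); else ambiguous. The relationship call
uses only covered evidence: the seeding primary's private mutations
(unique to it among all tumors) that are covered-absent in every
recurrence sample, and the recurrence's private mutations (absent from
all primaries) covered-absent in every region of the seeding primary. At
least `k_private` (3) on both sides ⇒ `sibling`; exactly one side empty
under coverage ⇒ `linear_descendant`; otherwise ambiguous. The thresholds
are artifact decisions — the underlying reasoning is qualitative — chosen
once at round values and exposed in the config. Discordant segments from
the ASCN profile comparison are attached as supporting evidence but do
not change the call.

## Allele-specific copy number

Forward model for a segment with tumor allele counts (n_A, n_B), purity
ρ and ploidy normalisation ψ (fixed at 2 by default; the patient-scale
profiles this package targets are near-diploid, so whole-genome-duplication
search is off):

    BAF  = (1 − ρ + ρ n_B) / (2(1 − ρ) + ρ(n_A + n_B)),   mirrored ≤ 0.5
    logR = log2((2(1 − ρ) + ρ(n_A + n_B)) / ψ),            floored at −8

The fit is an ASCAT-style grid search: ρ ∈ {0.05, 0.06, …, 1.00}; per ρ
every segment takes the integer state (n_A ≥ n_B, n_A ≤ 4) minimising its
squared (logR, BAF) residual; the reported ρ̂ minimises the
SNP-count-weighted total, ties to the lowest ρ. Residuals weight logR and
BAF equally; segments without BAF contribute logR only.

Identifiability: an allele-balanced genome carries no purity signal (the
(1,1) state fits any ρ exactly), so a flat residual profile raises
`identifiable=False`. A subtler exact degeneracy maps (n_A, n_B) at ρ to
(2n_A − 1, 2n_B − 1) at ρ/2 whenever every state maps to valid integers;
any unbalanced segment with n_B = 0 (e.g. a deletion or copy-neutral LOH)
blocks the map, so recovery tests and the simulated profiles always
include one. Copy-neutral LOH is the fitted state (2, 0); profile
comparison intersects segment intervals by coordinates and compares
states directly (the mirrored minor-allele convention already aligns
allele labels).

## Synthetic data

`simulate_patient` emulates the study design: several synchronous primary
tumors, multiple regions per tumor, one matched normal. Architectures:
*multicentric* tumors take independent founder clones off the germline
(zero shared somatic mutations, the defining property of independent
origin); *metastatic* tumors share a trunk of `trunk_muts` mutations
exactly; *mixed* pairs the first two tumors and leaves the rest
independent. Within a tumor, regions 2…k share a subclone branch and
every region has a private clone; mixture weights default to 0.3 founder
/ 0.3 branch / 0.4 private, giving CCFs 1 / 0.7 / 0.4. Reads are
binomial: depth ~ Poisson(`mean_depth`, default 100 — a standard WES
approximation), alt ~ Binomial(depth, q + e(1 − q)) with q = ρ · CCF / 2
for a het SNV in a diploid region and e the sequencing error (0.001).
Mutation positions are laid on a deterministic genome grid; the read
model deliberately ignores mutation–CNV interplay (mutated copy number is
taken as 1 of 2), and indels are presence/absence records with read
counts, with no sequence-level realism. Segment observations add Gaussian
noise of sd `noise_sd / √n_snps` to the forward model and re-mirror BAF.

### The case fixture

`generate_case_fixture` is a 12-sample patient (HCC-A1–3, HCC-B1–3,
ICC-C1–3, IM1, IM2, NORMAL) built from 630 mutations in 29
support-pattern groups whose integer counts were solved by hand so that
every promised aggregate holds simultaneously and exactly: SNV unions
365/191/68 and indel unions 33/25/26 for HCC-A/B/ICC; region-common
counts 312/172/44; unique-to-tumor counts 327/145/21; recurrence totals
344 (IM1) and 350 (IM2) with intersection 327 and union 367; recurrence
overlap 316/56/58 with HCC-A/B/ICC; 104 non-synonymous of 322 IM1 SNVs;
HCC-A transition fraction 190/365 ≈ 0.52. Free choices the aggregates do
not determine were fixed once and documented here: the three-way overlap
among primaries is A∩B∩C = 1, A∩B-only = 34, A∩C-only = 36, B∩C-only =
36 (the unique integer solution with a single triple-shared mutation);
the recurrence union shares nothing exclusive to HCC-B-only or ICC-only
regions (its B/C overlaps flow through multi-tumor categories) and has 30
exclusive mutations. Purities are 0.75 (HCC-A, IMs), 0.50 (HCC-B), 0.35
(ICC); the normal is pure. Marker mutations: an AXIN1 SNV private to the
three HCC-A regions and covered-absent in both IMs, two distinct FAT4
SNVs (one in HCC-A + IMs, one in HCC-B), an NRAS SNV private to ICC-C1.

Copy-number truth on a shared 20-segment grid gives HCC-A and the IMs the
same gain/loss backbone plus a 14q copy-neutral (2, 0) segment; a chr16
loss appears only in HCC-A1 and a small chr11 deletion only in the IMs
(the reciprocal discordance the origin classifier surfaces). HCC-B and
ICC carry small unbalanced segments beyond their qualitative description
("only a 1q gain", "no large CNVs") because a purity fit is
unidentifiable on a balanced genome and contamination estimates for those
tumors are part of the fixture's targets; the events are small and the
license is deliberate.

Because the pinned counts must hold *exactly*, the fixture clamps each
simulated cell into its intended status: present cells get at least
max(3, ⌈0.05·depth⌉) alt reads, absent cells at most 1, and depth is
floored at 12 so every absence is a covered absence. The general
simulator never clamps. Consequences for interpretation: fixture-passing
tests demonstrate the pipeline's arithmetic and decision logic, not
robustness to borderline coverage, caller disagreement, subclonal VAF
structure, or CNV-distorted VAFs — the un-clamped simulator and the noisy
ASCN replicates cover the stochastic side.

## Numerical choices and problem sizes

The ρ grid step is 0.01 with ties to the lowest ρ; BAF is mirrored into
[0, 0.5] after noise; logR is floored at −8 for empty genomes; Newick
output is validated by re-parsing with a standard reader. Randomised test
sizes — 100 set-statistic instances of ≤ 200 mutations, 100 conflict-free
phylogenies of 4–8 leaves, 50 noisy purity replicates on 20 segments at
noise sd 0.02 — are the package's own verification scale, chosen so the
whole suite runs in seconds while exercising every code path.

## Known limitations

Single-patient design: no statistical comparison of heterogeneity across
patients. No subclonal deconvolution (CCF mixture models), no timing of
divergence, no non-integer copy states, no ploidy search beyond ψ = 2, no
BAM/FASTQ-level simulation, no germline genotyping. The origin
classifier's thresholds encode a qualitative argument as round numbers;
on data near those boundaries the honest output is `ambiguous`.
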
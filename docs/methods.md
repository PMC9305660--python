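# Methods

## Scope and data model

The package integrates four evidence modalities produced by routine
leukemia diagnostics into per-aberration cancer cell fractions (CCFs),
reconstructs all clone trees consistent with those fractions across time
points, classifies the evolution pattern, and renders fishplots. Variant
calling, karyotype reading, FISH scoring and array segmentation happen
upstream; the package consumes their tabular outputs (TSV/VCF, ISCN
clone strings with metaphase counts, probe nuclei counts, BED-like
segments with log2 ratios). No purity or ploidy correction is attempted
and hematologic samples are assumed to be predominantly tumor-derived,
as is usual for marrow aspirates in this setting.

## CCF estimation

**SNVs/indels.** CCF = 2·VAF under the autosomal heterozygous
assumption. VAFs above 50% therefore map to CCF = 1 with a
`capped_at_1` flag; we deliberately do not infer loss of heterozygosity
or copy-neutral events from a high VAF alone, because the evidence for
them belongs to the cytogenetic modalities. X/Y-linked variants in male
patients use CCF = VAF (`hemizygous_assumed`); the packaged cohort
contains an X-linked BCOR variant at VAF 66.8% that is impossible under
the diploid rule. Uncertainty: a Wilson 95% interval on alt_reads/depth
scaled by the same factor when read counts are available, otherwise a
fixed ±0.05 band on the VAF — clinical reports often state only a
percentage, and ±5 VAF points is a realistic reporting resolution.

**Cell counts.** Karyotype clone lines and FISH probes give direct
proportions with Wilson 95% intervals (statsmodels). An aberration
appearing in several clone lines at one time point is carried by the sum
of those lines' cells. When both metaphase and FISH estimates exist for
one aberration/time point they are combined by precision weighting.

**Array-CGH.** For events seen only on the array, the log2 ratio r is
inverted under a one-copy change in a diploid background:
f = 2 − 2^(r+1) (loss), f = 2^(r+1) − 2 (gain). This is the simplest
model consistent with a two-channel intensity ratio; it is flagged as
model-dependent and clipped (with a flag) outside [0, 1]. Counting
methods take precedence whenever they saw the event.

## The CNV/SNV overlap model

For a point mutation inside a CNV, cells split into fractions w (both
events), x (CNV only), y (SNV only), z (neither), with w+x+y+z = 1 and
CCF_CNV = w+x known. The observed allele frequency is
(cnv_value·w + y) / D with D = w + x + 2y + 2z for a deletion and
3w + 3x + 2y + 2z for a duplication — CNV cells carry 1 (resp. 3)
copies, all others 2, so D depends only on CCF_CNV. "Duplication" means
exactly one gained copy; higher amplifications are rejected. Three event
orderings give four solvable cases:

| case | ordering | structure | cnv_value |
|---|---|---|---|
| 1 | CNV first, same cells | y = 0, w free | 1 |
| 2a | SNV first, CNV hits the mutant allele | x = 0, y free | 0 (del) / 2 (dup) |
| 2b | SNV first, CNV hits the other allele | x = 0, y free | 1 |
| 3 | independent lineages | w = 0, y free | 1 |

Each case is linear in its single free fraction and solves in closed
form; CCF_SNV = w + y. A case is excluded when any fraction leaves
[0, 1] by more than ε (default 0.05). The tolerance is needed because
real VAFs and cell counts are noisy: demanding exact satisfaction of
w+x+y+z = 1 would exclude nearly everything. ε is configurable
(`--eps`). Two deliberate edge rules: a VAF of exactly 0 is treated as
variant-absent (case 2a would otherwise ascribe an unobservable deleted
variant the whole CNV clone as history), and CCF_CNV = 0 short-circuits
to the plain heterozygous rule. For a deletion, cases 2a and 3 share the
same feasibility constraint (y ≤ 1 − CCF_CNV), so they survive or fall
together even though they imply different CCFs and different lineages.

Ambiguity is preserved, never resolved: each surviving case contributes
its own CCF **and** its own lineage constraint to the reconstruction
(case 1: the CNV clone must be ancestral to the SNV clone; 2a/2b: the
reverse; 3: the two must sit in unrelated lineages), and one set of
alternative trees is emitted per case, labeled with the case that
produced it. Biological priors (e.g. the frequency of biallelic TP53
inactivation) are the user's to apply.

## Clustering and tree enumeration

Aberrations are clustered greedily in a deterministic order (first
appearance, then descending peak CCF, then id); an aberration joins the
first clone with which it agrees at every time point, where "agrees"
means |ΔCCF| ≤ tol (default 0.10) **or** overlapping 95% intervals,
whichever is more permissive. The 0.10 default reflects the VAF spread
seen within clearly co-clonal variant groups in real panels; the
interval rule lets a 20-metaphase karyotype estimate (SE ≈ 0.1) join a
deep-sequencing estimate it is statistically consistent with. Clone CCF
per time point is the precision-weighted mean of members; unobserved
members enter as 0 with a broad band. Consequences are documented rather
than hidden: with tol = 0.10, variants closer than ~10 CCF points merge
even when a published figure drew them separately.

Tree enumeration searches all parent assignments over the clones and
keeps those that are acyclic, respect first-appearance order (a child
cannot appear before its parent), and satisfy the subset sums at every
time point: children of a clone sum to at most its CCF + δ, root clones
to at most 1 + δ (δ default 0.05, for noisy counts). Lineage constraints
from overlap cases are enforced here. Output order is fixed: fewest
roots first, then lexicographic on the parent vector. The search is
exhaustive (tested against a brute-force scan of all (n+1)^n vectors up
to 6 clones) and capped at 10,000 results for pathological inputs.

Remission time points at which nothing was detected zero every clone;
clones reappearing after such a gap keep their original parent — the
relapse is treated as regrowth of the same lineage, not a new root.

Classification: neutral if at some time point ≥ 4 sibling subclones
coexist with none reaching CCF 0.5; otherwise linear if every clone
(including the implicit germline root) has at most one child; otherwise
branched. The k = 4 / 0.5 defaults encode "many small independent
subclones, no sweep" and are configurable.

**Known limitation (cohort patient 4).** Under the capped 2·VAF rule a
TP53 variant at VAF 90.9% yields CCF 1.0 while co-occurring variants
spread between 0.67 and 0.94; no tree satisfies δ = 0.05 and the
pipeline honestly refuses (CLI exit 3). The same patient reconstructs at
δ = 0.15. The real resolution would be allele-specific copy number at
the TP53 locus, which is out of scope by design.

## Synthetic data

The simulator realizes a clone tree as explicit cell populations per
time point: exclusive clone fractions (clone CCF minus children), a
normal-cell remainder, heterozygous genotypes for each clone's SNVs
inherited by descendants. Observations are drawn as
VAF ~ Binomial(depth, exact VAF)/depth, metaphases ~ Multinomial over
exclusive fractions, FISH ~ Binomial(nuclei, carrier fraction), and
log2 ratios from the forward one-copy model plus Gaussian noise. Random
streams are split per modality from one master seed, so enabling FISH
does not shift the sequencing draws. Defaults mirror routine practice:
depth 5000 (deep panel), 20 metaphases, 200 FISH nuclei. Variants with
zero sampled reads are not reported, emulating detection limits.

What the simulator does **not** emulate: sequencing error beyond
binomial sampling, mapping artifacts, subclonal copy number stacked on
simulated SNV loci, culture bias in metaphase counts, or probe-specific
FISH cut-offs. Passing recovery tests therefore demonstrates correctness
of the estimation/enumeration machinery under the stated sampling
models, not robustness to every artifact of real data.

An explicit population constructor for the four overlap cell classes
doubles as the oracle for the VAF equations: the population allele
fraction Σ(f·mutant)/Σ(f·total) must equal the closed-form equation
exactly, and the suite checks this to 1e-12 on a 0.05-step simplex grid
over every configuration.

## The packaged cohort fixture

Eight patients encode a published diagnostic overview table verbatim:
VAF percentages, ISCN clone strings (including the zero-width Unicode
characters such tables leak, which the parser strips), clinical statuses
and transplant markers. Per-clone metaphase counts are not printed in
that table; the fixture's counts are synthetic stand-ins chosen once to
match the narrative (a stemline shrinking to ~5% at progression, a
derivative-17 clone large enough that several TP53 orderings stay
admissible) and are labeled as such. One patient's table row enumerates
10 aberrations where the accompanying text counts 11; the fixture
follows the table. Unbalanced derivative translocations
der(N)t(A;B)(bandA;bandB) additionally contribute an inferred terminal
loss on the retained chromosome at the pipeline stage (the mechanism by
which a der(17)t(13;17) deletes TP53); the inferred loss shares its
source clone's cell counts and does not change aberration counts.

Band arithmetic is symbolic (arm + numeric band interval). For
coordinate-based array-CGH matching an approximate band map is generated
from per-chromosome lengths, centromere positions and terminal band
numbers by linear interpolation; simulated CGH files use the same map,
so round trips are self-consistent. It is not a curated cytoband
annotation and positions should not be interpreted as real boundaries.

## Numerical choices

* Fractions internally, percent in every file and plot.
* Presence threshold 0.005 CCF; Gaussian-equivalent SE floor 0.005.
* Wilson intervals at 95% throughout.
* Fishplot rendering uses monotone cubic (PCHIP) interpolation of each
  clone's bottom edge and height — PCHIP cannot overshoot its data, so
  heights stay non-negative and bodies never self-intersect. A clone
  present before and after an intermediate zero is floored at 0.1% at
  interior points (recorded in the export) to keep the drawn body
  connected. SVG output is byte-deterministic (fixed hash salt, no
  timestamp metadata).
* Test problem sizes: 0.05 simplex grid for the oracle equivalence,
  10,000 draws for the round trip, depth 5000 / 20 metaphases /
  200 nuclei for parameter recovery — the cohort-realistic operating
  point for a deep panel plus routine cytogenetics.
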
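# clonefish

Reconstruction and fishplot visualization of clonal evolution in myeloid
neoplasia (and other non-solid tumors) from the data routine diagnostics
actually produces: somatic SNV/indel tables from panel sequencing,
karyotype clone descriptions in ISCN notation with metaphase counts,
interphase FISH nuclei counts, and array-CGH log2 ratios. It is aimed at
diagnostic labs and researchers who have per-time-point aberration
evidence from several methods and want a single, auditable picture of
which clones existed, how they nest, and how they rose and fell over a
disease course.

## The model

Every aberration is first converted to a **cancer cell fraction** (CCF,
the fraction of analyzed cells carrying it):

* SNV/indel: CCF = 2·VAF, assuming an autosomal heterozygous variant
  (CCF = VAF for X/Y loci in males); values above 1 are capped and
  flagged, never silently rescaled.
* karyotype / FISH: CCF = counted cell proportion, with a 95% Wilson
  binomial interval.
* array-CGH only: CCF from inverting the one-copy-change ratio model,
  f = 2 − 2^(r+1) for a loss and f = 2^(r+1) − 2 for a gain, where r is
  the log2 ratio.

When a CNV covers the position of an SNV/indel the 2·VAF rule breaks
down. The cell population is split into fractions *w* (CNV + SNV),
*x* (CNV only), *y* (SNV only), *z* (neither), with *w+x+y+z = 1* and
the CNV clone size CCF_CNV = *w+x* known from cytogenetics. The measured
allele frequency is

    VAF = (cnv_value·w + y) / (w + x + 2y + 2z)      deletion
    VAF = (cnv_value·w + y) / (3w + 3x + 2y + 2z)    duplication

where `cnv_value` is the number of mutant copies in the doubly-affected
cells. Three event orderings (CNV first; SNV first, with the CNV hitting
either allele; independent lineages) give four cases in total, each
solvable in closed form for CCF_SNV = *w+y*. Cases whose cell fractions
leave [0, 1] beyond a tolerance ε are excluded; when several survive,
**all** of them propagate into alternative reconstructions — the package
never auto-selects an ordering.

CCF trajectories are then clustered into clones, every parent assignment
satisfying the subset-sum (pigeonhole) constraints of tumor phylogenies
is enumerated, and each admissible tree is classified as **linear**
(every clone ≤ 1 child), **branched**, or **neutral** (≥ 4 coexisting
sibling subclones, none dominant). Trees export to the classic fishplot
fraction-matrix + parent-vector form and render as nested stream graphs.

A simulator realizes any clone tree as an explicit cell population
(clone → fraction, per-locus allele copies) and draws binomial /
multinomial / Gaussian observations from it — both the synthetic-data
generator for end-to-end tests and the exact brute-force oracle for the
VAF equations.

## Worked example

The packaged cohort fixture (eight patients; VAFs and karyotypes
verbatim from the published overview table, cell counts synthetic
stand-ins) includes a patient whose TP53 point mutation (VAF 19.56% at
progression) lies under a derivative chromosome 17 that deletes the
TP53 locus in ~80% of cells. Solving the four overlap cases:

```
$ clonefish overlap --vaf 0.1956 --ccf-cnv 0.8 --type deletion
scenario  cnv_value  w       x       y       z        ccf_snv  feasible
1         1          0.2347  0.5653  0.0000  0.2000   0.2347   yes
2         0          0.8000  0.0000  0.2347  -0.0347  1.0000   yes
2         1          0.8000  0.0000  -0.5653 0.7653   0.2347   no (violation 0.5653)
3         1          0.0000  0.8000  0.2347  -0.0347  0.2347   yes
```

Reading the table: if the deletion came first (scenario 1), the TP53
clone is a 23% subclone nested inside the CNV clone; if the point
mutation came first and its allele was then deleted (scenario 2,
cnv_value 0), essentially every tumor cell carries the TP53 event;
scenario 2 / cnv_value 1 is impossible (it would need a negative SNV-only
fraction); the independent-lineages case is also admissible. Running the
whole pipeline keeps every surviving interpretation:

```
$ clonefish fixtures --patient 6 --out p6/
$ clonefish reconstruct --patient p6/ --out out/
3 alternative tree(s) -> out/trees.json
$ clonefish render --tree out/trees.json --index 1 --out plot.svg
```

`trees.json` holds three ranked alternatives — branched (CNV first,
TP53 on the other allele), linear (TP53 first, its allele then lost),
and branched (independent lineages) — each with its clone CCF matrix;
`reconstruct.log` records every excluded scenario with the magnitude by
which it violated *w+x+y+z = 1*. The JAK2 stemline sits at CCF 1.0
(capped from VAF 97.5%) throughout, with the derivative-17 clone at
0.80/0.75 at the two progression time points.

Simulated data round-trips the same way:

```
$ clonefish simulate --tree out/trees.json --index 1 --depth 5000 --seed 7 --out sim/
$ clonefish reconstruct --patient sim/ --out sim_out/
```

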
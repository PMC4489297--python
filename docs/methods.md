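# Methods

## Model and procedure

The package reconstructs the regulatory neighbourhood of one perturbed
regulator (a TF, a histone-modification change, or a named cellular
perturbation — the "center") from evidence layers that are each standard
on their own:

1. **Peak-to-gene assignment.** Every peak is assigned to every gene whose
   strand-aware promoter window it overlaps by ≥ 1 bp (a peak straddling
   two windows counts for both genes). Chromatin loops add a second route:
   a peak overlapping one anchor is assigned to any gene whose promoter
   overlaps the partner anchor, in either anchor orientation and across
   chromosomes. Loop assignments for a (gene, peak) pair already covered
   by a promoter assignment are suppressed.
2. **Direct-target detection.** Either the intersection of peak-bearing
   genes with DEGs, or rank-product scoring (below). With no expression
   table the peak-bearing set is returned as-is and the run is flagged
   binding-only; with no peaks, accessible PWM hits of the center's motif
   substitute for observed binding on the direct tier.
3. **Indirect expansion.** Direct targets present in the user-supplied TF
   registry are expanded: a candidate gene acquires an indirect edge
   TF→gene when it carries that TF's binding evidence in its promoter
   (curated peaks, or predicted TFBSs that survived the accessibility
   filter) *and* is a DEG under the original perturbation. Expansion is
   iterated to a configurable depth (default 1, hard cap 3 — each level
   compounds false positives). No indirect tier is inferred without
   expression data.
4. **Annotation and analysis.** Nodes carry the names of mark tracks
   overlapping their promoters (repressive marks included — this is
   descriptive, and it is how bivalent promoters are surfaced); factor
   pairs can be tested for co-occupancy; the network's genes can be tested
   for gene-set enrichment.

### Peak abundance

Binding strength per gene is `a_g = Σ_k s_k · e^(−d_k/d0)` over the gene's
assignments, with `s_k` the peak intensity (dialect-dependent units,
missing values default to 1 so score-less BED degrades to pure distance
weighting), `d_k` the distance from the peak reference point (summit if
recorded, else midpoint) to the TSS, and `d0` the decay constant
(default 5,000 bp — the conventional promoter-proximal scale, matched by
the default ±5 kb promoter window). The exponential-decay "regulatory
potential" form captures the three ingredients that matter — more peaks,
higher intensity, shorter TSS distance — and is additive over assignments.
Loop-linked peaks enter at `d = 0`: a loop collapses genomic distance, so
distal evidence wired to the promoter is treated as promoter-equivalent.

### Rank product

Candidates are genes with both binding and expression evidence. Each is
ranked descending by `a_g` and by `|log2FC|` (average ranks on ties;
absolute fold change is ranked, with the sign reserved for edge signs),
and scored `rp = √(r_peak · r_expr)` — the geometric mean keeps the score
on the rank scale and selects identically to the raw product. Output is
sorted ascending by rp with lexicographic tie-breaks for determinism;
selection is top-*k* or `rp ≤ cutoff`. No permutation null is attached to
rp: selection is by cutoff, and calibrating a null model is out of scope.

### Motif scanning and the accessibility filter

Count matrices are regularised with a background-distributed pseudocount
(default 0.8) and converted to log2-odds weights against a uniform
background (configurable; the appropriate genomic background depends on
the species and region set). Both strands are scanned; a window is a hit
at `score ≥ threshold · max_score`, with the threshold a fraction of the
maximal achievable score (defaults offered at 0.75–0.90, 0.85 used by the
pipeline) so that it is invariant to motif length. Windows containing N
are skipped. The accessibility filter keeps a predicted site only if it
overlaps the union of supplied open-chromatin and active-mark intervals
(DHS, H3K4me3, H3K4me1, H3K27ac by role assignment); passing a repressive
mark (H3K27me3, H3K9me3) as activity evidence is rejected outright —
repressive marks may only annotate promoters.

### Edge signs

Under a loss-of-function perturbation, a target that goes down was being
activated by the factor; under gain, a target that goes up is activated;
zero fold change gives "unknown". For an indirect edge TF→gene, the
center→TF sign propagates the perturbation: an activating center→TF edge
transmits the perturbation direction to the TF, a repressing edge flips
it, and the gene's fold change is read against that effective direction.
This composes the evidence chain into a single sign instead of reporting
an observed sign plus a separate consistency flag.

### Co-occupancy

The observed statistic is the number of A peaks whose reference point lies
within `window` bp (default 500) of any B reference point. The null
rotates A's points circularly within each chromosome by one uniform random
offset per chromosome per permutation, preserving inter-peak spacing, and
the empirical p is `(1 + #{null ≥ obs})/(n + 1)`, bounded below by
`1/(n+1)`. The Jaccard index of merged base coverage is reported
alongside as an effect size. This permutation design is the package's own
construction, chosen because it needs no parametric assumptions about
peak spacing.

### Enrichment

Hypergeometric upper tail per set (`scipy.stats.hypergeom.sf`), restricted
to a user-chosen universe (defaulting to the annotation's gene set — the
conservative choice; the expression table's genes are the alternative),
Benjamini–Hochberg adjustment, and a binary gene × set matrix over sets
with `p_adj ≤ 0.05`.

## Coordinate and format conventions

All internal coordinates are 0-based half-open; GFF and MACS tabular
(1-based) are converted at the parsing boundary, so a single convention
holds everywhere and off-by-one drift cannot accumulate. Peak-caller
outputs named by their tools (CisGenome, PePr, DBChIP, DiffBind) reduce to
BED-like tables with a configurable intensity column rather than bespoke
parsers; MACS's `.xls` dialect is handled by header name, including the
summit column. Differential-binding scores are preserved as-is — whether
they carry a sign is left to the caller. One TSS per gene is assumed;
multi-isoform genes must be collapsed upstream. DEG thresholds
(|log2FC| ≥ 1, stat ≤ 0.05 by default) are applied inclusively; duplicate
expression rows keep the smallest statistic; non-finite fold changes
(Cuffdiff's `inf`) are dropped with a warning because downstream ranking
needs finite values.

## The simulator: what it emulates and what it does not

The generator plants a known network and emits every file the pipeline
reads, as a deterministic function of the seed. Genes sit on one synthetic
chromosome at fixed 50 kb spacing (alternating strands); direct targets
get a promoter peak with log-normal intensity (ln-scale μ = 3, σ = 0.5),
except a stated fraction that instead get a distal peak wired to the
promoter by a loop — the first of these on a second chromosome to exercise
inter-chromosomal contacts. TF intermediates get a strong 15-bp motif
whose consensus is embedded in their targets' promoter sequences, with a
stated fraction of sites covered by a DHS track. True targets respond with
|log2FC| ~ N(3, 0.5) and significant statistics, the sign encoding a
planted activate/repress label; nulls fluctuate at N(0, 0.2) with
non-significant statistics; optional noise peaks land in intergenic space
and noise DEGs on non-target genes. H3K4me3 covers direct-target
promoters and H3K27me3 additionally covers the repressed ones, so
bivalency annotation is exercised.

The reference condition (the defaults, and the scale used by the test
suite and the acceptance script) is 200 genes, 40 direct targets with a
quarter loop-only, two TF intermediates with 10 indirect targets each,
half of the planted sites accessible, and no noise — large enough that
every code path runs, small enough that the whole benchmark completes in
seconds on one core.

Deliberately absent: realistic inter-gene distance distributions,
nucleosome-scale chromatin structure, read-level noise and peak-calling
artefacts, motif degeneracy and homotypic site clusters, correlated
expression noise, and multi-TSS genes. Exact recovery on these data
therefore demonstrates pipeline correctness — that the assignment, loop,
filtering, sign and expansion logic do precisely what they claim — not
expected performance on real chromatin biology, where thresholds and the
accessibility filter trade recall against precision.

## Numerical choices and degenerate inputs

* Ties in ranking get average ranks; final orderings break ties
  lexicographically by gene id, making every output deterministic.
* Score-less peaks get intensity 1.0; `a_g = 0` exactly when a gene has no
  assignments; an empty rank-product candidate set is an error rather than
  an empty result, since it means the two evidence layers do not intersect
  at all.
* Log-odds with pseudocount 0 can contain −∞ weights; hits themselves are
  always finite because a −∞ window cannot reach any nonnegative
  threshold fraction.
* Empirical p-values are never 0 by construction (`(1+x)/(n+1)`).
* Precision of an empty prediction set is defined as 1 (nothing asserted,
  nothing wrong); recall against an empty truth set is likewise 1.
* The "about 80 nodes" display cap familiar from interactive viewers is
  available as an optional export cap, keeping the center plus the
  highest-|log2FC| nodes and dropping dangling edges.

## Known limitations

* Promoter-"enrichment" is operationalised as ≥ 1 assigned peak; no
  binomial/Poisson background test of peak density is attempted.
* The rank-product score carries no significance estimate.
* Curated per-TF ChIP collections for indirect expansion are supported at
  the library level (`expand_indirect` accepts peak-assignment evidence),
  but the command-line pipeline derives indirect evidence from motifs +
  accessibility only.
* Gene-set collections, motif databases and genome annotation are user
  inputs; nothing is bundled or downloaded.
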
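# Methods

## MSAP state calling

A fragment (epilocus) is scored present/absent in two digests, EcoRI+HpaII
and EcoRI+MspI.  Fragments outside 95–500 bp are removed at load time
(capillary-electrophoresis co-migration guard); bounds are inclusive and
configurable.

Loci are classified by the fraction of samples whose two enzyme calls
disagree, computed over samples with non-missing calls in both enzymes
(pairwise-complete, never listwise).  Discordance above `error_threshold`
(default 0.05, the common MSAP convention) makes the locus
methylation-susceptible (MSL); at or below, non-methylated (NML); a locus
with no band in any sample with either enzyme is uninformative.  Raising
the threshold can only shrink the MSL set (tested monotonicity).

States at MSL follow the isoschizomer truth table — (1,1) unmethylated,
(1,0) hemimethylated, (0,1) internal CG methylation, (0,0) full methylation
*or* loss of the CCGG site; the technology cannot separate those last two,
and we do not try.  The binary "methylated" projection used for diversity
and distances maps hemi/internal to 1 and, by default, (0,0) to 1 as well:
these calls are dominated by methylation events and dropping them would
discard roughly two fifths of the informative cells.  The alternative
policy (`full_policy="missing"`) treats (0,0) as missing for users who want
the conservative view.

The NML binary view is band presence with either enzyme (`max` of the two
calls).  Within an NML the enzymes agree up to the error threshold by
construction, so the rare discordant cell reduces to "one enzyme saw the
band", which we score as presence; no tie-break is needed under this rule.

Shannon diversity per locus is S = −(p ln p + q ln q) with p the band
frequency among non-missing calls; group summaries report the mean and SD
over informative loci and the percentage of loci polymorphic within the
group.  Groups of fewer than two samples are excluded with a warning.

## Distances, PCoA, AMOVA and Φ(PT)

Binary profiles yield a squared-Euclidean (mismatch-count) distance:
mismatches over shared non-missing loci, rescaled by L/L_shared so partially
missing pairs stay on the all-loci scale.  A pair sharing no loci is an
error, not a silent zero.

PCoA Gower-centres −d²/2 and eigendecomposes.  Axis percentages use the sum
of positive eigenvalues; negative eigenvalues are kept in the result and
logged, never silently dropped.

AMOVA is distance-based in the dominant-marker convention: sums of squares
from pairwise squared distances (SS_total = Σ d²/N; within-group terms
Σ d²/n_g), variance components solved from expected mean squares with
coefficients that handle unequal group sizes, for either a two-level
(populations / individuals) or three-level (regions / populations /
individuals) hierarchy.  There is no within-individual level — presence/
absence markers carry no heterozygosity.  Φ(PT) is the share of total
variance above the individual level (with regions present it equals
(σ²_a + σ²_b)/σ²_total; Φ(RT) and Φ(PR) are reported alongside).  Negative
components are floored at zero before percentages and flagged.
Significance permutes individuals among populations; p = (x + 1)/(n + 1)
with ties counted as "at least as extreme", so p is never 0 and the test is
conservative at the margin.  Pairwise Φ(PT) runs the two-level analysis on
each population pair; p-values are reported unadjusted (a Bonferroni column
is trivial to add downstream, and the matrix report keeps raw values for
comparability with common practice).

Mantel correlation is the Pearson r of the vectorised upper triangles under
simultaneous row/column permutation of the second matrix, one-sided
("greater") by default since isolation by distance predicts a positive
sign.  A constant matrix is rejected as degenerate.  Geographic distances
are haversine on a 6371-km sphere — kilometre-scale accuracy is ample for a
wine region's extent — optionally log(1 + km); environmental matrices are
absolute differences of one site variable.  Vineyard-level matrices can be
expanded to sample level (samples inherit site coordinates), but the
default pairing is vineyard-level Φ(PT) against vineyard GeoD.

## msGBS differential methylation

Counts are normalised to CPM by library size only; no TMM-style composition
factor is applied.  With the strong planted signals and balanced synthetic
libraries this is exact, but on real data with heavily asymmetric
differential methylation a composition correction could shift logFCs — a
known discrepancy risk accepted for the smallest faithful model.

The abundance filter keeps loci with CPM ≥ 1 in ≥ 15 samples *within each*
of the two compared regions (configurable to "any region").  The test is a
two-group negative-binomial exact test: counts are scaled to the
geometric-mean library size; a single common dispersion φ is estimated by
maximising the conditional likelihood of the within-group counts given
their group sums (a Dirichlet-multinomial in r = 1/φ, in which the mean
parameter cancels); conditional on a locus's total, the group-A sum follows
a beta-binomial-type distribution with shapes (n_A·r, n_B·r), and the
p-value sums all outcomes no more likely than the observed split.  In the
Poisson limit (φ → 0, returned when the likelihood prefers the boundary)
the conditional law is binomial.  Tagwise dispersion and GLM designs are
out of scope; the common-dispersion model is the smallest one consistent
with the exact-test framework, and the estimator recovers a planted φ = 0.2
within a few percent at 40 samples × 1,000 loci.

logFC is log₂ of the shrunken group-mean ratio (pseudo-count 0.5 on the
common-library scale), so it is exactly antisymmetric under label swap.
Both Bonferroni and BH adjustments are recorded; Bonferroni at 0.01 is the
default significance rule.  **Sign convention:** reads come from enzyme
cutting, so *fewer* reads mean *more* methylation — a locus with logFC < 0
(lower CPM in region B) is *hyper*-methylated in B relative to A.  This is
pinned by a dedicated test.

PC-LDA ordination reduces log₂(CPM + 1) profiles by PCA (components capped
at n_samples − n_groups to keep the within-group scatter non-singular,
auto-reduced and logged when the request exceeds that) and projects onto
linear discriminant axes with per-axis discrimination shares.

## Gene annotation and GO enrichment

Coordinates are 1-based inclusive internally (GFF3); BED I/O converts at
the boundary (0-based half-open), with tests pinning both conventions.  A
gene is differentially methylated (DMG) when at least one significant DMM
lies within 5 kb of its span; a DMM may support several genes, and the
window profile counts DMM–gene *pairs* (a marker flanked by two genes
contributes once per gene).  Bins are strand-oriented: upstream distance
d ∈ (0, 5000] from the TSS maps to bin −⌈d/1000⌉, downstream of the TES to
+⌈d/1000⌉, and d = 0 (or any position inside the span) to bin 0 — the gene
body.  The profile is invariant under reflecting all coordinates and
strands, and its bin sum equals the number of in-range pairs (both are
tested).  DMGs split into hyper- and hypo-methylated sets by their
supporting markers' direction; genes with both directions enter both sets,
flagged.

GO over-representation is the one-sided hypergeometric upper tail per term,
over a universe of genes with ≥ 1 annotation — unannotated genes carry no
information under this model, so they are excluded rather than padding N.
Terms with zero overlap are excluded from testing and from the Bonferroni
divisor (m = terms actually tested); significance at Bonferroni-adjusted
p < 0.05.  No GO-graph ancestor propagation happens implicitly; a parent
map can be applied explicitly via `GeneToGO.propagate`.

## Synthetic generators

The generators define the study conditions rather than adapting to them.

*MSAP*: six sub-regions of four vineyards (four plants each) on a 1-D
north–south axis, region centroids 5 km apart with 1 km vineyard jitter,
altitude declining southward; ~215 fragments (160 MSL + 55 NML) with sizes
drawn in 95–500 bp.  Each MSL has a baseline methylation probability
uniform on 0.25–0.75 (headroom for the gradient in both directions) shifted
by `slope × km_south`; the default slope spans Δp = 0.2 between extreme
regions.  Methylated draws are fully methylated with probability 0.52, the
remainder hemi vs internal at 55:45 — proportions echoing commonly observed
MSAP class frequencies (full > hemi > internal); band pairs then follow the
inverse truth table.  NML band frequencies (uniform 0.3–0.95) are shared by
all regions: genetically unstructured by construction.  Symmetric call
errors flip each enzyme call at 1% — high enough to be visible, low enough
that expected NML discordance (≈ 2e) stays under the 0.05 classification
threshold.  Probability clipping beyond 5% of draws triggers a warning to
lower the slope.

*msGBS*: three regions × 30 samples by default (two regions for recovery
designs); per-locus baseline means log-normal (σ = 1) around 50 reads at a
1e6 library; library sizes uniform on 0.8–1.2 × 10⁶; NB counts at common
dispersion 0.2.  Planted DMMs scale log-linearly along the region index so
extreme regions differ by exactly the fold change; 70% gain reads southward
(southern hypomethylation), 30% the reverse.  Given a toy annotation, ~70%
of planted markers land within 3 kb of genes — preferentially the carriers
of the designated environment-response term — and the rest are placed ≥ 6 kb
from any gene.

*Annotation*: non-overlapping 1–4-kb genes, balanced strands, 12–20-kb
intergenic gaps (so 5-kb flanks rarely chain), 1–4 random GO terms per gene
plus one designated term on 30 genes.

What the generators deliberately omit: linkage between fragments,
vineyard-level random effects (all structure above the individual comes
from the geographic gradient, so simulated among-vineyard variance within
regions is ~0 — real surveys show more), fragment-size homoplasy,
count-composition biases, and any genome sequence.  Passing recovery tests
therefore demonstrates that the estimators find the planted signal under
the stated noise model, not that real electropherograms or alignments
would be this clean.

## Numerical and design choices

* Permutation p-values: +1/+1 correction everywhere; ties count against the
  null; every permutation consumer takes an explicit seed.
* Exact-test tie tolerance: outcomes within 1e-10 log-probability of the
  observed one count as ties (guards float noise in symmetric designs).
* Sums of squares and eigen-decompositions run in double precision; PhiPT
  is clipped at 0 when used as a distance for ordination/Mantel.
* Determinism: run directories contain no timestamps; the manifest records
  the config hash, seed and package versions, so identical configs
  reproduce byte-identical output.
* Problem sizes in the test suite (e.g. 500 calibration replicates at 999
  permutations, 200 null count datasets, 20-seed recovery panels) were
  chosen to give two-binomial-SD assertion bands that are meaningfully
  tight while keeping the whole suite around a minute on one core.

## Known limitations

* MSAP cannot separate full methylation from CCGG-site mutation; all
  downstream numbers inherit that ambiguity.
* The common-dispersion exact test is anticonservative when dispersion
  varies strongly across loci; tagwise shrinkage is the standard remedy and
  is out of scope here.
* Unadjusted pairwise-Φ(PT) p-values accumulate multiplicity across many
  population pairs; readers should apply their own correction when scanning
  large matrices.
* GO enrichment treats annotations as exchangeable and independent; without
  ancestor propagation, signal on specific terms does not surface on their
  parents.
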
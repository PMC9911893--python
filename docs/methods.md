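# Methods

## Model and procedure

The package reconstructs the signature of nested whole-genome
duplications from three lines of evidence and combines them into per-WGD
retained gene sets.

**Ks as a molecular clock.** The synonymous substitution rate Ks (dS)
between two coding sequences is used as a proxy for the age of their
divergence.  Paralog pairs created by the same WGD share one divergence
time, so the genome-wide paralog Ks distribution shows one peak per WGD;
interspecies ortholog pairs date speciations the same way.

**Counting estimators.** Two pairwise estimators are implemented.

* *NG86.*  Each codon position contributes one site, split among its
  three possible single-nucleotide changes; per-codon synonymous site
  fractions are averaged over both sequences, observed differences in
  multi-substitution codons are averaged over all substitution orders,
  and the proportions pS = Sd/S, pN = Nd/N are corrected with the
  Jukes–Cantor formula d = −(3/4)·ln(1 − (4/3)p).  Two conventions are
  fixed and used identically in the estimator and in its enumeration
  oracle: a change producing a stop codon counts as nonsynonymous (this
  makes S + N = 3 × counted codons hold exactly), and substitution paths
  through stop intermediates are excluded from averaging (falling back to
  all orders if every path is blocked).  Columns with gaps, Ns, or stop
  codons are excluded entirely.
* *YN00-style.*  Codon frequencies come from the F3×4 model (pooled
  position-specific nucleotide frequencies of the aligned pair).  The
  transition/transversion rate ratio κ is estimated from third positions
  that are fourfold degenerate in both codons, via the K80
  transition/transversion distances (κ = 2·d_ts/d_tv, clamped to
  [0.1, 20], falling back to 1 when fewer than 10 such sites exist).
  Site counting weights each possible change by (κ for transitions) ×
  (F3×4 frequency of the target codon), normalised per position;
  multi-substitution codons are resolved by weighting each substitution
  order by its product of step rates, with ω scaling nonsynonymous
  steps.  ω is updated from the current dN/dS and the difference counts
  are iterated to convergence (relative change < 1e-6, at most 100
  iterations; non-convergence marks the estimate invalid).  dS and dN are
  corrected per class with the K80 formula using their own
  transition/transversion split.  This is a counting approximation in the
  Yang–Nielsen spirit, not a line-for-line reproduction of PAML's yn00.

Both estimators are symmetric in their arguments and mark saturated
pairs invalid rather than clamping them, because silently clamped values
would distort the downstream mixture fit.  Known limitation: all
counting estimators of this family are biased upward at deep divergence
(twofold-degenerate positions carry a full observed difference but only
a fractional site), so a true dS of ~1.0 is typically estimated ~5–15%
high depending on κ.  This matters only for the *location* of the old
peak, not for young/old classification, and is why sample-level peak
recovery is validated on direct draws from the mixture while
genome-level recovery is validated as classification rates.

**Alignment.** Codon alignments are threaded from protein alignments
(pal2nal-style back-translation).  Equal-length pairs are aligned by
direct back-translation of their own translations; producing protein
alignments for length-divergent pairs is out of scope (an external
aligner's output can be supplied).

**Filters.** Paralog workflows keep valid estimates with
0.05 < Ks < 1.50 (strict bounds; the upper bound guards against
saturation).  The single-copy-ortholog workflow takes its own bounds,
default (0, 1.5), because interspecies orthologs of recently diverged
species can sit far below the paralog lower cutoff (peaks near
Ks ≈ 0.02 are expected and must not be filtered away).

**Synteny.** Anchors are homology pairs (E-value ≤ 1e-5) placed on the
gene-rank grid of their chromosome pair, after removing self-pairs and
tandem-flagged pairs.  Within each chromosome pair, maximal chains are
extracted by dynamic programming: a successor must advance by a rank gap
in (0, max_gap] on both axes, monotonically increasing on the first and
consistently increasing or decreasing on the second (block orientation).
The chain score is the anchor count, chains shorter than 5 anchors are
dropped, and anchors join at most one block (best-chain-first greedy
extraction).  Ties are broken deterministically: lexicographically
smallest (rank_a, rank_b) sequence, "same" orientation before
"inverted".  max_gap defaults to 25 ranks — a conventional chaining
window, configurable.  Two WGDI behaviours are deliberately not
reproduced: the "homo" similarity index and the block-significance
p-value; block age classification uses the median anchor Ks only and
block filtering uses the anchor count only.  A block is *young* when its
median Ks lies in (0.05, 0.6) and *old* in [0.6, 1.5] — a median of
exactly 0.6 classifies old (left-closed convention).

**Peak fitting.** The Ks sample (restricted to the open window
(0.05, 1.5)) is split at a fixed trough, default 0.6, chosen the way
practitioners choose it — by inspecting the distribution between the two
modes.  Each side is binned into 200 bins over its own data range and an
amplitude-free Gaussian A·exp(−(x−μ)²/2s²) is fitted by least squares,
with μ initialised at the subset median ("mode = median"), s at half the
interquartile range, and A at the maximum density.  The fitted μ is the
reported peak.  Fitting a plain Gaussian to a trough-clipped sample is
the procedure being reproduced; its truncation bias is accepted, not
corrected.  Subsets below 50 values are refused (the 200-bin density
would be mostly empty); the pipeline skips unfittable components, so a
single-WGD genome yields a one-component (or empty) result rather than
an error.

**Duplication events and retention.** Gene-tree nodes are classified by
the species-overlap criterion: a node is a duplication when its child
clades share at least one species.  This matches the reconciliation
style of OrthoFinder-type duplication calls; full DTL reconciliation is
not attempted because the downstream filters operate on such calls.
Candidate events then pass through ordered filters, each event receiving
exactly one terminal status: `rejected_composition` (orthogroup < 4
genes, no gene from outside the focal genus, a child branch without a
focal-species gene, or a polytomous node), `rejected_support`
(support < 0.5 on the 0–1 scale, after percent normalisation; exactly
0.5 is kept), `rejected_tandem` (any focal cross-child pair within the
5-gene rank window — read as rank distance ≤ 5, inclusive, and
strand-agnostic), `rejected_ks` (mean cross-child Ks outside (0.05,
1.50) or no valid pair), `rejected_nonsyntenic` (no cross-child pair
anchored in a classified block), or `accepted` with a σ/ρ assignment.
When an event's pairs anchor in both young and old blocks, the class of
the pair whose Ks is nearest the event mean wins — a tie-break this
package defines, since upstream tools do not document whether the case
occurs.  Internal nodes without a support label are treated as
unassessed and kept (support 1.0).  Retained gene sets are unions of
focal-species genes over accepted events per WGD; because a gene can
join events of both ages the summary reports raw and deduplicated
counts, with percentages rounded half-up to one decimal (the convention
used for all reported percentages).

**TF screening.** Family × species count matrices use 0 for absent
families.  Families with fewer than 10 members in any species are
screened out, then Shapiro–Wilk (scipy implementation, verified against
R's `shapiro.test` to 1e-6) at α = 0.05 — the α is assumed, as the
procedure it follows does not state one, and is configurable.
Zero-variance families are screened out rather than producing infinite
z-scores.  z = (x − μ)/σ uses the sample (n−1) standard deviation — the
source formula does not specify the denominator, so this is a documented,
switchable choice — and z > 1.5 flags enlarged families.

**Enrichment.** One-sided over-representation only: p = P(X ≥ k) for
X ~ Hypergeom(N, K, n), with N the annotated background (genes without
any GO term are excluded), BH adjustment, and significance requiring
p_adj < 0.05 and q < 0.2.  The q-value is approximated by the
BH-adjusted p (the π₀ = 1 limit of Storey's estimator) — a conservative,
documented divergence that avoids an undescribed π₀ estimator.
Annotations are optionally closed under the ontology's true-path rule
from a child→parent edge table (on by default when edges are supplied;
the operation is idempotent and rejects cyclic edge sets).

## Synthetic data generator

`simulate_genome` emulates the statistical structure the analysis
assumes, with ground truth for every quantity the pipeline estimates:

* An ancestral genome of `n_chromosomes × genes_per_chromosome` gene
  families (default 4 × 150), each family carrying a random sense-codon
  CDS (default 200 codons).
* WGD events applied oldest-first, each at per-lineage depth
  ks_depth/2: every chromosome is duplicated and appended as a new
  chromosome, and each duplicate is retained with the family's
  probability — defaults 0.25 (younger, Ks 0.27) and 0.10 (older,
  Ks 0.97) for background families, 0.5 for designated TF families.
  Lost duplicates are removed and ranks recomputed, so surviving
  duplicates keep ancestral neighbourhoods and collinear blocks exist by
  construction.
* A sister species splitting at ortholog Ks 0.02 (retention outcomes are
  shared, as losses precede the split), recent tandem duplications in
  the focal genome (rate 0.05 per gene, divergence Ks 0.01, inserted
  adjacent to the parent), and outgroup species without the WGDs at
  ortholog Ks 1.3 (just inside the saturation-safe range, and beyond the
  analysis window) with a 5% per-gene loss rate to exercise the
  outgroup-presence filter.
* Sequences evolve along each family's genealogy under a
  single-nucleotide mutation–selection sampler: per-position mutation
  weights carry the κ transition bias (default κ = 2, plant-typical),
  stop codons are never introduced, nonsynonymous events are scaled by
  ω (default 0.2), and the number of events per branch is Poisson with
  mean (branch dS) × (synonymous sites), so a pair's expected estimated
  dS equals twice its divergence depth.  Requesting more than one
  expected substitution per site per lineage (target > 2) raises a
  saturation error.
* Gene trees record the true topology with supports drawn
  Uniform(0.5, 1) for 90% of nodes and Uniform(0, 0.5) for the rest
  (exercising the support filter); homology pairs cover all intra-focal
  paralogs plus ~2% spurious pairs spanning the E-value threshold; GO
  terms are family-level with a marker term on TF families; a truth
  table labels every pair (sigma / rho / tandem / ortholog) and records
  per-event retention fractions.

Everything is drawn from one seeded generator, so a seed fully
determines the dataset, byte for byte.

What the generator does **not** emulate: gene gain/loss outside WGDs,
indels and alignment error, rate variation among sites and lineages,
genome rearrangement beyond whole-chromosome duplication, biased codon
usage, fractionation bias, or annotation noise.  Passing recovery tests
therefore shows the pipeline is correct under its own model assumptions
— clean collinearity, clock-like Ks, accurate trees — not that it is
robust to the messiness of real assemblies.

## Problem sizes and numerical choices

The default simulated genome (600 ancestral families, three species)
yields ~930 focal genes, ~450 paralog pairs and ~330 candidate events,
and the full pipeline runs in a few seconds; validation tests use this
scale, with peak-recovery tests on 4,000–5,000 draws per component where
fitting precision is the question.  Least-squares fits use
`scipy.optimize.curve_fit` with bounded parameters (μ inside the data
range, s > 0); Shapiro–Wilk, hypergeometric tails and BH adjustment
delegate to scipy/statsmodels.  Degenerate inputs follow explicit rules
stated above: empty histograms, zero-variance families, saturated pairs,
all-blocked substitution paths, single-WGD genomes, and orthogroups
without trees are all either rejected with a diagnostic or handled by a
documented convention, never silently repaired.

## Known limitations

* Counting-estimator bias at deep divergence shifts the old-peak
  location upward (see above); peak positions beyond Ks ≈ 1 should be
  read as ordinal, not absolute.
* The trough is fixed, not estimated; genomes whose WGD peaks straddle
  0.6 need a different configured trough (an automatic minimum-density
  mode is not provided).
* Species-overlap duplication calling over-calls under incomplete
  lineage sorting or tree error; the support and synteny filters are the
  mitigation, as in the procedure this package operationalises.
* The q-value approximation makes the significance flag conservative
  relative to a Storey-calibrated q.
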
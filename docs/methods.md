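# Methods

This note records the models, rules and numerical choices behind each
module, the assumptions of the synthetic-data generators, and the known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Conserved orthogroups and loss calling

The unit of analysis is the orthogroup: a set of genes across species
descended from one ancestral gene.  Orthogroup membership is an *input*
(an OrthoFinder-style gene-count table); the package does not build
orthogroups from sequences or trees.

An orthogroup is **conserved** when its count is ≥ 1 in the reference
species and ≥ 1 in at least `min_present` panel species (default 5 of a
6-species panel).  Presence is strictly binary — no abundance threshold —
because the rule is about retention, not family size.  Counts in any other
column (the heterotrophic targets) never affect conservation, so a target
can lose a family without disturbing the universe against which its losses
are measured.

A conserved orthogroup is **lost** in a target when the target's count is
exactly 0.  The loss fraction divides by the conserved-set size.  Two
targets' losses are partitioned by plain set algebra (joint = intersection);
both reports must derive from the identical conserved universe, which the
code enforces by carrying the universe in each report.

## The F-index

For family *g* and species *s*, with count *n* and all-species mean family
size *x̄* (the focal species included in the mean),

    F = n / (n + x̄).

This is the simplest form with the required semantics: F ∈ [0, 1); F = 0
exactly when the family is absent from the species but present elsewhere;
F = 0.5 exactly when *n* = *x̄*; F is strictly increasing in *n* with all
other counts fixed.  The form is kept in one place (`f_index` / `f_table`)
so an alternative definition can be swapped in.  All-zero families are
rejected rather than silently scored.

Distribution summaries use Tukey box conventions: quartiles by linear
interpolation between order statistics (the common "type 7" rule — stated
explicitly because several conventions exist), whiskers at the most extreme
data within 1.5 × IQR of the nearer quartile, points beyond listed as
outliers.  The below-average fraction is computed **from the counts**, not
from F: a family counts as below average when `n × n_species < row_total`,
an integer-exact comparison immune to floating-point ties; ties (count equal
to the mean) count as *not* below.

## PET and PEG classification

A tissue *t* is a principally expressed tissue of gene *g* when

    value(g, t) > 0   and   value(g, t) ≥ fold_threshold × mean_{t' ≠ t} value(g, t'),

i.e. the focal tissue is excluded from the comparison mean.  The phrase "at
least one-fold greater than the average" is read as *greater by one fold* —
at least **2 ×** the average — so `fold_threshold` defaults to 2.0; the
weaker reading (≥ 1 × the average) is available by passing 1.0.  The
positivity condition makes all-zero genes PET-free instead of
vacuously-everywhere-PET; no pseudocount is added anywhere.  A gene may have
several PETs; the rule as stated permits it.

Principally expressed genes generalise the rule to a focal tissue *set*
(mean over focal tissues vs. mean over all others); with a single focal
tissue the two rules coincide, which the tests assert.

The lost-orthogroup tabulation maps each lost orthogroup to its proxy-species
genes (one-to-many maps allowed; classes are unioned over mapped genes),
then counts orthogroups per tissue class {leaves, roots, flowers, other}
via a user-supplied tissue → class map.  Because the natural normalisation
is ambiguous, both are emitted, clearly labelled: percentage of the class's
*universe* (all mapped orthogroups whose PETs fall in that class, lost or
not) and percentage of the lost cohort.  Lost orthogroups missing from the
map, or whose proxies have no PET at all, are tallied separately rather than
raising.

Enrichment is the hypergeometric upper tail P(X ≥ k) for k query hits among
n query genes drawn from N universe genes of which K carry the term
(`scipy.stats.hypergeom`), with Benjamini–Hochberg adjustment
(`statsmodels`) across tested terms only; terms with zero query hits are
excluded before adjustment since they cannot be called enriched.

## Pseudogene lesion scan

Candidates are aligned to their reference CDS with global affine-gap
Needleman–Wunsch via Biopython's `PairwiseAligner`.  Scores default to
match +2, mismatch −3, gap open −5, gap extend −2 (recorded in output
headers); a gap of length L costs `open + L × extend`.  When several
alignments tie, the aligner's first traceback is used — deterministic for
fixed inputs.  An independent brute-force alignment oracle in the tests
confirms optimal scores on small pairs.

Lesions are read off the alignment:

* **Frameshift** — each maximal run of gap columns whose net indel length
  (insertions minus deletions) is not divisible by 3, reported at the first
  reference base the run touches with the signed net length as detail.
* **Premature stop** — the candidate's aligned bases are read in triplets
  from its start, so upstream indels shift the reading frame exactly as in
  translation; every TAA/TAG/TGA whose reference position strictly precedes
  the reference's terminal codon is reported.  No grace window near the 3′
  end is applied, because the defining criterion is simply "premature".

A candidate with ≥ 1 lesion is a pseudogene.  Two subtleties matter for
cohort-level evaluation.  First, within a homopolymer run every gap
placement denotes the same molecular event, so planted and detected
coordinates are compared up to sliding within such runs (and ±3 nt
otherwise).  Second, an optimal alignment can explain a dense substitution
cluster as a *canceling* insertion–deletion pair; the two frameshift lesions
then sum to a net frame offset of 0.  `LesionReport.frame_disrupted`
(net indel length mod 3 ≠ 0) distinguishes genuinely out-of-frame candidates
and is the quantity used when classifying a cohort into
frameshift / stop / intact.

Candidates are assumed sense-strand; `scan_revcomp` also tries the reverse
complement and keeps the higher-scoring strand.

## k-mer genome survey

The histogram model: single-copy sequence contributes a depth bump at the
per-base coverage *c*; ρ-copy repeats contribute a bump at ρ·*c*; sequencing
errors contribute a spike at depth 1–2.  The error threshold is the first
local minimum of count vs. depth (plateaus resolved to their first rising
edge); a histogram with no valley is rejected with advice to pass the
threshold manually, and the threshold is overridable everywhere.  The peak
is the maximal count above the threshold, smaller depth winning ties.  Then

    K = Σ_{depth > threshold} depth × count,   genome size G = K / peak.

Repeat content is the share of K at depth ≥ `repeat_multiplier` × peak.  The
default multiplier is **1.5**: the midpoint between the single-copy peak and
the first (two-copy) repeat bump, so essentially all repeat mass and almost
no single-copy mass falls above the cut.  A cut at exactly 2 × peak would
bisect the two-copy bump and halve the repeat estimate; users modelling
higher-copy repeat structures can raise the multiplier.  No mixture-model
fitting is attempted — the estimator is the transparent quotient formula,
which also means heterozygosity peaks (at c/2) are not modelled.

On one published-scale input, the quotient itself is informative: a total
17-mer mass of 11,700,637,064 at peak depth 42 gives 278.59 Mb *before* any
error filtering; threshold-filtered masses are necessarily smaller.  The
package always reports the mass it actually summed alongside the estimate.

## Synthetic data generators

All generators are pure functions of (parameters, seed).  A single global
seed expands into fixed per-generator substreams
(`SeedSequence([seed, offset])`), so stages regenerate independently and a
pipeline run is byte-reproducible.  Every generator returns a truth object
recording exactly what was planted, and truth files round-trip through TSV.

* **Count matrix** (default 2,000 orthogroups, 9 species): family sizes are
  shifted Poisson (1 + Poisson(λ), λ = mean − 1, default mean 3) where
  presence is planted; conserved rows satisfy the conservation rule by
  construction, the rest violate it through reference absence or a sparse
  panel (about 56% conserved, echoing the ratio of conserved to total
  orthogroups in nine-species plant panels).  Losses: a joint fraction
  (default 4%) is zeroed in both targets first, then each target loses
  further rows at a rate adjusted so its **marginal** loss rate equals the
  stated value — defaults 11.7% and 13.0%, the loss rates reported for a
  dodder and a bladderwort against ~12,000 conserved orthogroups.  Present
  target counts are biased low or high so that roughly 72% / 62% of
  conserved families end up below their mean size; the truth records the
  realised below/above sets integer-exactly, so planted-truth tests are
  exact rather than approximate.
* **Expression matrix** (default 500 genes × 6 tissues): planted-PET genes
  (30%) get base level 20 in non-focal tissues and fold × 20 (default 10×)
  in their planted tissue; multiplicative lognormal noise with CV 0.2
  (σ² = ln(1 + CV²), unit mean) models biological and technical variation.
  The generator plants at most one PET per gene; the classifier does not
  assume this.
* **CDS pairs** (default 200 pairs × 100 codons): references are random
  intact ORFs; candidates receive stop-free background substitutions (1%,
  rejection-sampled per codon in the reference frame) and one planted lesion
  per the mix 30% frameshift / 30% premature stop / 40% intact.  Frameshifts
  are single 1–2 nt indels away from the CDS ends.  Downstream of a planted
  frameshift the shifted frame naturally contains stop triplets; cohort
  classification therefore keys on net frame disruption (above).
* **k-mer histogram** (default 1 Mb genome, 42× coverage, 20% two-copy
  repeats, 1% errors, k = 17): per-k-mer Poisson depths for unique and
  repeat mass; error k-mers added deterministically at depth 1–2 with total
  count genome_size × coverage × error_rate × k (each base error corrupts up
  to k overlapping k-mers).

What the generators do **not** emulate — and hence what passing tests do not
show about real data: phylogenetic correlation of counts across species,
orthogroup-size heterogeneity beyond Poisson, mapping ambiguity and
condition structure in expression data, alignment uncertainty from diverged
(rather than recently pseudogenised) candidates, and GC- or
position-dependent sequencing error.  Planted-truth recovery demonstrates
correctness of the decision rules, not robustness to real-data noise beyond
the stated noise models.

## Pipeline and problem sizes

`run_all` executes simulate → conserved → losses → partition → F-index →
PET → PEG → tabulation → enrichment → pseudogene scan → k-mer survey →
report, writing plain-text TSVs with `# key=value` provenance headers, a
key-value summary and a YAML manifest (package version, config, seed — no
timestamps, so identical config + seed gives byte-identical runs).  Stage
failures raise a stage-named error; the CLI maps it to a per-stage exit
code.  Default run sizes (2,000 orthogroups, 500 genes, 60 CDS pairs of 80
codons, 1 Mb genome) are chosen so a full run and the entire test suite
complete in seconds on one core while keeping planted-event counts (~100
losses, ~20 lesions) large enough to be informative; all sizes scale up via
configuration.

## Known limitations

* Orthogroup construction, expansion/contraction significance testing
  (birth–death likelihood models), selection scans and divergence dating are
  out of scope; this package starts from count tables.
* The F-index form reproduces the documented semantics but a family-size
  statistic with the same range could be defined differently; the formula is
  isolated behind `f_index`/`f_table` for that reason.
* Genome-wide pseudogene *discovery* (locating candidate loci in an
  assembly) is not implemented — the scanner evaluates given
  reference/candidate pairs.
* The survey estimator assumes a unimodal single-copy bump above the error
  valley; heavily heterozygous or very-low-coverage histograms violate this
  and should use the manual threshold.
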
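# Methods

## Model and assumptions

`ampcna` treats CNA detection in a targeted panel as a per-amplicon outlier
problem. The observed coverage of amplicon *a* in sample *s* is modelled as
multiplicatively separable,

    coverage(a, s) ∝ depth(s) · efficiency(a) · CN(a, s) / 2 · noise(a, s),

where depth is a per-sample library factor, efficiency a per-amplicon PCR
factor, and CN the local copy number (diploid = 2). Two median scalings
remove the nuisance factors exactly: dividing each sample by its median
amplicon coverage cancels depth(s), and dividing each amplicon by its median
normalized coverage cancels efficiency(a). Both steps assume that the
*median* cell of every row and column is diploid — i.e. that fewer than half
of the samples carry an alteration at any one amplicon, and that no sample
is altered across half its panel. Medians use the midpoint convention for
even counts; all scaling is multiplicative on the linear scale, with no log
transform. When a reference (normal-DNA) cohort is supplied, the
per-amplicon medians are taken from it instead of the target cohort. The
reference cohort is itself sample-normalized first; without that step the
reference's depth distribution would leak into the copy-number scale.

The null model for each amplicon is normal, centred at CN = 2, with scale
σ_a = 1.4826 · median(|CN(a,·) − median(CN(a,·))|). The MAD is used instead
of the standard deviation so that amplified samples do not inflate their own
null; the 1.4826 factor makes σ_a consistent for normal data. Gains and
losses are tested with separate one-sided tails (upper and lower), so each
cell carries a gain p-value and a loss p-value summing to 1. This keeps the
two directions separately reportable in every output table.

Gene-level evidence combines the gene's amplicon p-values per direction with
Fisher's method: X² = −2 Σ ln p over the k non-degenerate amplicons, referred
to χ² with 2k degrees of freedom. Fisher's method assumes independent
p-values; amplicons of one gene share a sample's DNA, so the combined
p-value is approximate whenever within-gene correlation is present. Gene
copy number is the unweighted mean of the gene's amplicon CN values.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | significance threshold on the corrected p-value |
| `method` | `bonferroni` | `bonferroni` controls FWER; `bh` controls FDR |
| `scope` | `both` | correction family: `none`, `samples`, `genes`, or `both` (genes × samples) |
| `support` | `("none",)` | `("count", k)` requires k supporting amplicon calls; `("fraction", f)` requires ⌈f · n(g)⌉ |
| `mode` | `gene_wise` | `amplicon_wise` skips Fisher combination; each amplicon is its own unit |

Bonferroni multiplies each p-value by the number of tests in scope
(n_samples, n_units, or their product), capped at 1. Benjamini–Hochberg
applies the step-up adjustment (via `scipy.stats.false_discovery_control`)
to the pooled family of p-values in scope, separately per direction: for
scope `both` all gene × sample p-values of a direction form one family; for
scope `samples` each unit's row is a family; for scope `genes` each sample's
column. Corrected values are never below raw values, and BH-adjusted values
never exceed Bonferroni-adjusted ones, so FDR call sets contain the
corresponding FWER call sets at equal α.

An amplicon *supports* a gene call when its own amplicon-level p-value —
corrected with the same scope and method over the amplicon × sample family —
passes α in the matching direction. Counting corrected rather than raw
amplicon p-values makes "supported by two amplicon calls" mean exactly that
the supporting amplicons would have been called in amplicon-wise mode. The
fractional rule rounds up: 50% of a 3-amplicon gene demands 2 supporters.

## Degenerate inputs and numerical choices

* An amplicon whose CN row has MAD = 0 (more than half its values identical)
  has no usable spread estimate. It is flagged, reported in QC output, and
  made uncallable (p = 1 in both directions) rather than raising; genes
  whose amplicons are all degenerate are likewise uncallable.
* p-values of exactly 0 entering Fisher's method are clamped to the smallest
  positive double before the logarithm; the number of clamped values is
  recorded on the result table. Extremely strong signals can still underflow
  to a combined p of 0, which is reported as such.
* Amplicons with zero coverage in every sample make median scaling
  degenerate and are rejected at parse time with an actionable error, as are
  samples whose median coverage is 0 (failed libraries).
* The intra-gene inconsistency sums sample standard deviations (denominator
  n(g) − 1) over genes with at least two amplicons; single-amplicon genes
  are mathematically outside the formula and are excluded and listed in the
  QC report.
* TSV output writes floats with Python's shortest round-trip representation
  and reads them back with the `round_trip` parser, so write→read is
  bit-exact.

## Clustering

Heatmap ordering uses Manhattan (L1) distance with average linkage, where
the distance between clusters is the size-weighted mean of the merged
members' distances (equivalently the unweighted mean over all cross-pairs).
Agglomeration is implemented in-package to make it bit-reproducible: among
equal-distance candidates the pair whose lexicographically smallest member
ids compare lowest merges first, and at each merge the subtree containing
the smaller original row index is placed on the left. On inputs with
distinct pairwise distances the merge heights coincide with
`scipy.cluster.hierarchy.linkage(..., "average", "cityblock")`, which the
test suite uses as an independent cross-check. Unclustered mode preserves
the input order exactly — useful for spotting batch effects along the run
order.

## Synthetic cohorts

The generator draws per-sample depth factors and per-amplicon efficiency
factors as lognormals (sd of the log 0.5 each, a few-fold spread as seen
across real libraries and PCR efficiencies) around a base depth of 1000
reads, multiplies in the bulk copy number of each amplicon's gene, and
applies lognormal per-cell noise (default sd of the log 0.1, i.e. ~10%
multiplicative noise). Clonal alterations spiked as (gene, sample,
clonal CN) triples are diluted by tumour purity:
bulk CN = purity · clonal CN + (1 − purity) · 2. The generator rejects
configurations that spike half or more of the samples of a gene, since
median normalization would absorb the alteration into the baseline. Default
cohort shape is 48 genes × 2 amplicons × 100 samples.

What the simulation does **not** emulate: GC- and length-dependent
efficiency drift, within-run batch effects, correlated noise between
amplicons of a gene (real within-gene coverages are positively correlated,
which weakens Fisher's independence assumption), integer read counts at low
depth, subclonal heterogeneity, and genome-wide aneuploidy. Passing the
simulation studies therefore demonstrates correctness of the pipeline's
statistics under its own generative assumptions, not performance on any
real cohort.

## Study sizes and operating characteristics

The acceptance studies run the full pipeline end to end on generated
cohorts: 200 null replicates (48 × 2 amplicons, 100 samples, noise sd 0.03 —
small enough that the lognormal noise is well approximated by the normal
null) for the family-wise false-call rate; 10 replicates with clonal CN 6
spiked into 5% of samples per gene at purity 1 and noise sd 0.1 for
sensitivity and specificity; 5 shared-seed replicates per purity level
(1.0 / 0.5 / 0.3, clonal CN 4) for the purity study; and one 152-amplicon /
48-gene / 184-sample cohort with recurrent gains and losses for panel-scale
call counts.

Measured at these sizes: sensitivity 1.0 and specificity ≈ 0.9998 for
clonal CN 6 in pure tumours; sensitivity decays steeply with purity
(≈ 1.0 → 0.72 → 0.18 at purity 1.0 / 0.5 / 0.3 for clonal CN 4), matching
the expectation that coverage-based calling loses power below ~50% tumour
content, where spatially resolved assays (e.g. FISH) are preferable.

## Known limitations

* **Per-cohort FWER is not controlled at the nominal level.** Two effects
  compound. First, the plug-in σ_a estimated by the MAD from ~100 samples
  carries ~12% relative error, which inflates extreme-tail p-values of the
  fitted null 6–10× at the thresholds Bonferroni implies for thousands of
  cells (with the true σ the tails are exact; this was verified directly).
  Second, correcting the gain and loss families separately by
  n_genes · n_samples places the nominal family-wise rate near
  1 − e^(−2α) ≈ 0.095 rather than α. On 200 null replicates at the default
  cohort shape the observed fraction of cohorts with at least one corrected
  call is ≈ 0.5–0.6, and it rises with noise (lognormal skew adds further
  tail mass at noise sd ≥ 0.05). In practice the correction limits the
  *number* of false calls per cohort (≈ 1 cell in several thousand, hence
  the high specificity above) rather than the probability of any false
  call; the two-amplicon support filter removes most single-amplicon false
  positives, as in the worked example.
* Recurrent alterations present in ≥ 50% of samples (or cohorts of related
  samples) violate the median-diploid assumption and shift the baseline.
* No segmentation, no allele-specific copy number, no purity estimation:
  the method tests each amplicon/gene cell independently.
* Fisher combination treats a gene's amplicons as independent witnesses;
  correlated within-gene noise makes gene-level p-values anti-conservative.
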
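# Methods

This note documents the models, conventions and design decisions behind
braintx: what the processing pipeline computes, what the synthetic-data
generator emulates (and does not), and the numerical choices that make
results reproducible to the byte.

## The processing model

Donor microarray data arrive as probe × sample matrices of log2 intensities
with binary above-background flags, probe annotations, and sample
annotations carrying MNI-style stereotactic coordinates (mm; left hemisphere
x < 0). Expression values are treated as already normalized upstream by the
data provider; no background subtraction is performed. The pipeline converts
these into one region × gene matrix through a fixed stage order:

```
reannotate → intensity filter → probe selection → coordinate update →
mirror → similarity filter → assignment → sample normalization →
gene normalization → aggregation → missing-data handling
```

Intensity-based filtering must precede probe selection — selecting first
could promote noisy probes. The relative order of sample and gene
normalization is in principle interchangeable; we fix sample-then-gene and
expose no reordering, so a configuration uniquely determines the
computation.

Stage conventions that are not forced by the problem:

- **Intensity filter.** A probe is kept iff its above-background fraction,
  pooled over all donors' samples, *strictly* exceeds the threshold
  ("more than 50%" semantics). Disabled filtering is a distinct state, not
  a zero threshold: at threshold 0, probes never above background are still
  dropped.
- **Probe selection.** Six methods; `average`, `diff_stability` and
  `rnaseq` already integrate across donors (or ignore the distinction), so
  they force the donor mode to `aggregate`. This is the collapse that takes
  the full factorial from 1,119,744 to 746,496 pipelines. Inter-probe
  correlations inside `corr_intensity`/`corr_variance` are Pearson (a
  continuous intensity criterion); differential stability and RNAseq
  fidelity use Spearman, matching their rank-based definitions.
  Differential-stability profiles average samples within structures matched
  by `structure_acronym` across donor pairs. All argmax ties break to the
  lowest probe id; the modal probe in `common` mode breaks ties the same
  way.
- **Assignment.** Volumetric: the sample's containing voxel wins at
  distance 0 when labeled and compatible; otherwise the nearest compatible
  labeled voxel within the mm tolerance (ties: most frequent label among
  equidistant voxels, then lowest region id). A hemisphere and
  structure-class compatibility gate prevents cross-midline and cross-class
  matches — important after mirroring. Surface: nearest labeled vertex in
  the sample's hemisphere; samples farther than mean + k·sd of their
  donor's vertex distances are excluded (per-donor statistics; k = 0
  excludes everything above the mean).
- **Normalization.** Always per donor — its purpose is the removal of
  donor-specific differences. The scaled robust sigmoid is
  `1 / (1 + exp(−(x − median) / (IQR/1.35)))` rescaled to the unit
  interval; the 1.35 constant converts the IQR to a normal-equivalent sd,
  the sd substitutes when the IQR is zero, and a constant vector maps to
  0.5. Standard deviations use the (n−1) denominator package-wide.
  `matched_only` restricts both the statistics and the output to samples
  assigned to a region; `within_structures` partitions by structural class
  (cortex, subcortex/brainstem, cerebellum, white matter), passing classes
  with fewer than two samples through unchanged.
- **Aggregation.** `donors_first` applies the metric within region per
  donor, then across donors (donors absent from a region are skipped, not
  imputed); `pooled` applies it once, so donors with more samples weigh
  more. Rows are sorted by (region, donor, well) before reduction, making
  the result exactly invariant to donor ordering.
- **Missing regions.** `omit` keeps them flagged (analyses drop them);
  `nearest` fills from the tissue sample closest to the region centroid in
  each donor, aggregated with the pipeline's metric — nearest *sample*, not
  nearest filled region; the alternative (copying the nearest non-missing
  region's row) measures parcel similarity rather than local expression.

## Analyses

- **CGE–distance**: Pearson correlations between region rows (across
  genes), compared with inter-centroid Euclidean distances by Spearman over
  the strictly upper triangles. Pairs involving constant rows are
  undefined; more than 10% undefined aborts the analysis. The decay
  relationship is plausibly exponential, but a rank correlation captures
  its presence without a functional form.
- **GCE silhouette**: Euclidean distances between gene columns over
  non-missing regions, scored against gene-module labels with
  `s_i = (b_i − a_i)/max{a_i, b_i}`; singleton modules and the fully
  degenerate a = b = 0 case contribute 0. Absolute silhouettes are expected
  to be small or negative for modules defined on a different similarity
  (e.g. weighted co-expression networks); the informative comparison is
  against a label-permutation null, and between pipelines.
- **RGE PC1**: columns are mean-centered, the first principal component is
  extracted by SVD, and |Spearman ρ| against the phenotype is reported —
  absolute value because a principal component's sign is arbitrary.

## Multiverse and impact

A parameter grid lists each option's ordered choices, its scale (binary /
ordinal / categorical) and optional declarative redundancy rules, so the
pipeline count is auditable rather than hard-coded. Impact scores follow
the scale: |Δ| for binary options, mean |Δ| over adjacent choices for
ordinal, mean |Δ| over all unordered pairs for categorical; each matched
tuple holds every other option fixed. Tuples are built on *effective*
(post-collapse) configurations: contexts in which an option is collapsed
contribute no tuple and are never double counted, and options that trigger
a collapse only form tuples in contexts where every one of their choices
exists (e.g. probe-method tuples exist only at donor mode `aggregate`).
Ranks break ties by declaration order. The estimate-space PCA mean-centers
the pipelines × 3 estimate matrix and reports the first two components'
variance fractions.

## The synthetic-data generator

The generator plants known structure in the donor-directory dialect so that
every stage has a recoverable target. The latent regional signal for gene
*g* in region *r* is

```
G(r,g) = level_g + μ_mod(g) + amp_g · (0.55·l_g·grad(r) + 0.3·M_mod(g)(r) + 1.0·f_g(r))
```

with all spatial fields unit-variance Gaussian with covariance
`(1−h)·exp(−d/λ) + h·1[homotopic]` (λ = 20 mm, h = 0.35): similarity decays
with physical distance while homologous left/right partners stay correlated
— the minimal lateralization that makes hemispheric mirroring defensible.
Key emulated features, and why:

- **Expression-level heterogeneity**: per-gene baselines (sd 2 log2 units)
  and lognormal spatial amplitudes (log-sd 0.4). Without gene
  normalization, levels and amplitudes dominate distances and components —
  the data feature the normalization options exist to counteract.
- **A dominant expression gradient** `grad(r)` with zero-mean per-gene
  loadings `l_g`: the principal spatial axis of expression, well separated
  from the rest of the spectrum so PC1 is stable; being zero-mean across
  genes it survives sample-wise (common-mode) normalization — consistent
  with treating all-gene shifts as technical.
- **Gene modules** (4, balanced): a module-shared field plus module-mean
  offsets; module recovery is assessed against label permutations.
- **Low-rank donor batch effects**: each donor's offset is a donor factor
  times a gene-sensitivity direction shared across donors, plus an
  independent part, with a *systematic* factor contrast between the two
  bilaterally sampled donors and the remaining four — emulating their
  separate acquisition. With strong offsets and no gene normalization, the
  leading component of the aggregated matrix becomes this batch contrast
  rather than the expression gradient, which is precisely the mechanism
  that makes gene normalization the most impactful option.
- **Asymmetric sampling and coverage**: only the first two donors sample
  the right hemisphere (and carry RNAseq — a monotone 2^(G/2)-style
  transform of the sample signal plus noise); unilateral donors cover a
  random half of the left-hemisphere regions, so the donor composition
  behind each region varies.
- **Probe redundancy and quality**: 1–4 probes per gene with intensity
  biases, noise multipliers, and bimodal background-failure rates (a
  "dead" subset failing in most samples — what intensity filtering
  removes); a few unannotated probes; a reannotation table that drops ~5%
  of probes and remaps another ~5%. One donor carries a sample placed far
  outside the atlas to exercise unassigned-sample paths.

Default scale: 6 donors × 90 samples, 30 regions (15 per hemisphere on a
jittered 24 mm lattice painted as 15 mm cubes into a 3 mm-voxel volume),
200 genes. These sizes keep a 96-pipeline multiverse under a minute on one
CPU while leaving ~400 region pairs for rank statistics.

Two named experiment conditions fix the donor-offset magnitude:
`recovery_params` (offset sd 0.25) for parameter-recovery checks, where the
planted spatial structure should dominate; and `batch_effect_params`
(offset sd 2.5) for the processing-variability analysis, where unnormalized
aggregates must be visibly batch-dominated. The package default (1.5) sits
between them.

What the generator does **not** emulate: microarray hybridization physics,
dilution/composition effects, ontology structure beyond the four
structural classes, real gene identities, donor-specific anatomy
(individualized parcellations are out of scope), and realistic
cross-hemisphere sampling imbalance at full AHBA scale. Passing recovery
tests therefore demonstrates the correctness and sensitivity of the
*machinery*, not effect sizes transferable to the real dataset.

## Numerical and reproducibility choices

- One seeded `numpy` generator drives all simulation draws in a fixed
  order; equal seeds give byte-identical output trees (atlas volumes are
  written as uncompressed NIfTI — gzip would embed timestamps).
- Aggregation sorts before reducing (exact donor-order invariance); the
  noise-free reconstruction of the ground truth is exact to ~1e-15 (IEEE
  summation), and tests assert 1e-12.
- Ties anywhere (argmax, modal probe, nearest voxel) resolve to the lowest
  id; silhouette/PCA degeneracies have explicit conventions (s_i = 0,
  DegenerateInputError for zero-variance input).
- Expression TSVs round-trip at 6 decimals with `NA` rows for missing
  regions.
- The automated methods report is rendered from the same `executed_stages`
  helper the orchestrator logs, so the report and the run cannot disagree;
  disabled steps are omitted and the report is deterministic.

## Known limitations

- Volumetric assignment searches labeled voxels exhaustively per
  unassigned sample; fine for desk-scale atlases, not tuned for 1 mm
  whole-brain volumes.
- The surface pathway uses per-vertex labels and coordinates only; no mesh
  topology or geodesic distances.
- `impact_scores` requires a complete factorial (up to the declared
  collapses); partially executed grids raise rather than reweight.
- Nested redundancy rules (a collapse whose trigger is itself collapsible)
  are rejected at grid validation.
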
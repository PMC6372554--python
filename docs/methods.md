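# Methods

`modcoupling` implements a modular functional-connectivity analysis for a
two-group resting-state fMRI + single-voxel MRS study design, together with a
synthetic cohort generator that plants the statistical structure the analysis
is meant to detect. This note records the models, the tunable parameters and
their defaults, the numerical conventions, and what the synthetic world does
and does not establish.

## The analysis

### Connectivity networks

Each subject contributes a T x N table of region-averaged BOLD-like series
(default: T = 230 retained volumes at TR = 2 s, N = 90 cerebral regions of
the packaged parcellation). Conditioning follows the standard stream for
ROI-level data: OLS regression on the Friston 24-parameter motion design
(6 rigid-body parameters, their one-volume backshift, and both sets squared),
then linear detrending and an ideal frequency-domain band-pass on
0.01-0.1 Hz. A region-mean "global signal" proxy regressor is available but
**off by default**: true global-signal regression operates on whole-brain
voxel data, and at ROI scale the region mean is dominated by the planted
common block structure, so regressing it out distorts exactly the quantity
under study.

Subject networks are Pearson correlation matrices, Fisher z-transformed
(arctanh, |r| clamped at 1 - 1e-15), diagonal zeroed. To remove weak or
negative edges, each of the N(N-1)/2 edges gets a one-sample t-test of the
subjects' z values against zero, one-sided (greater), Benjamini-Hochberg
corrected at q = 0.05 over all edges; an edge survives when rejected with a
positive group mean. The retention test runs at group level; a two-sided
variant is available. The group-average weighted network is the mean of the
subjects' z matrices restricted to this mask.

### Sparsity and modular detection

Sparsity is the fraction of retained edges among all possible unordered
pairs. Proportional thresholding keeps the `floor(s * N(N-1)/2)` largest
positive edges, with ties at the cutoff broken toward the lexicographically
smaller node pair so every mask is deterministic and masks are nested in s.
The analysis sparsity is the smallest grid value (default grid 0.05-0.30,
step 0.01) at which every included subject's thresholded network is fully
connected.

Modularity of a partition p on a weighted network is

    Q(p) = (1/l) * sum_ij [ w_ij - k_i k_j / l ] * delta(m_i, m_j)

over ordered node pairs including i = j (w_ii = 0), with k_i the node
strength and l the ordered-pair total weight. This convention makes the
single-module partition score exactly 0 on every graph. (Descriptions of Q
sometimes state that the one-module partition scores 1; under the formula as
written it scores 0, and the implementation follows the formula.)

Detection is agglomerative greedy maximization: start from singletons,
repeatedly merge the connected module pair with the largest gain
`2 (e_ab - a_a a_b)`, track the best partition along the path, then run a
local refinement pass that reassigns single nodes to neighboring modules
while any move increases Q by more than 1e-12, alternating with a
module-split pass (re-detect communities inside each module's subgraph and
accept the split when it strictly raises global Q). The split pass matters:
plain agglomeration is known to glue genuinely distinct modules together
early, and single-node moves cannot undo that — on default synthetic
cohorts it mis-merged two planted modules in 13% of seeds, all repaired by
the split pass. All tie-breaks use index order, so detection is reproducible
without a seed and invariant (up to relabeling) under node permutation.
Disconnected inputs are handled per component with a warning. This
greedy + refine + split combination is a simple, deterministic member of the
greedy-optimization family; its Q never exceeds and is within 0.02 of the
exhaustive (Bell-enumeration) maximum on >= 95% of random small graphs in
the test battery. Louvain-style multi-level moves are deliberately out of
scope.

A sparsity sweep records max-Q and module count per grid value and the
integrated modularity (trapezoidal mean of Q over the grid span).

### Module-level connectivity

Under a reference partition (by default the control group's detected
partition, so both groups are scored on the same modular mask), intra-module
connectivity C_s is the mean weight of retained edges inside module s and
inter-module connectivity C_{s,t} the mean weight of retained edges bridging
s and t; sums and the edge counts l_s, l_{s,t} use unordered edges, so C is
exactly the mean weight of existing edges. A module (pair) with no surviving
edge scores 0 and is logged. Weights are Fisher z values by default; a raw-r
mode exists in the network layer.

The edge set for subject-level metrics is the subject's group FDR mask
(`PipelineParams.metrics_mask="fdr"`). Restricting metrics additionally to
the selected-sparsity group mask (`"combined"`) is supported but not the
default: on strongly modular networks the sparsity mask retains almost no
between-module edges, so inter-module C becomes a selection-biased mean over
a handful of edges — and exactly zero edges in a sizeable fraction of
simulated cohorts — which makes group contrasts and coupling correlations
unmeasurable. The FDR mask keeps every reliably positive edge and preserves
the metrics' interpretation as mean block connectivity.

Detected modules are named by maximal node overlap with the packaged
six-module reference, so contrasts can be phrased as "Frontoparietal-Central"
rather than by arbitrary module ids.

### Quality control

* Motion: exclusion when any |translation| > 2.5 mm or any |rotation| >
  2.5 degrees, or when mean framewise displacement exceeds the group mean
  + 2 SD. FD uses the 80 mm-sphere RMS form
  `sqrt(R^2/5 * tr(dA' dA) + |db|^2)` with dA the rotation-difference matrix
  minus identity, db the translation difference, FD[0] = 0. The group FD
  statistics are computed per diagnostic group over subjects that already
  pass the absolute rules (the source protocol does not say whether
  absolute-rule failures enter the FD statistics; excluding them first is the
  conservative reading and is what the implementation tests).
* MRS: metabolite records with CRLB >= 20% are dropped per metabolite; a
  subject with no surviving metabolite has no usable MRS and leaves the
  analysis cohort (the "incomplete MRS" analogue). Concentrations are CSF
  partial-volume corrected as `conc / (1 - f_csf)`; the water-relaxation
  terms of the full tissue-correction formula are intentionally omitted at
  this desk scale.
* Discarding of initial volumes is the data producer's responsibility and is
  declared in the cohort manifest, never re-applied.

### Statistics

Group contrasts use two-tailed independent t-tests, Welch by default (a
pooled-variance mode exists); Welch reproduces the worked-example p = 0.001
for the frontoparietal intra-module contrast from its printed summary
statistics, pooled does not. Pearson and Spearman correlations report
two-tailed p from `t = r sqrt((n-2)/(1-r^2))` on n-2 df; all three tests
also accept printed summary statistics (means/SDs/ns, or r and n) so
reported values can be re-checked without raw data. Note that a p-value
printed from an unrounded correlation can differ by one unit in the last
digit from the p recomputed at the printed (rounded) r. Before every
correlation both variables are screened by an iterative two-sided Grubbs
test at alpha = 0.05, removing at most floor(n/10) points, each removal
logged. No multiple-testing correction is applied across the correlation
family (matching how such studies report uncorrected r/p); a BH option
exists in the network layer only. Correlations whose inputs degenerate
(e.g. a metric that is constant zero in one group) are reported with NaN
estimates and a degeneracy flag rather than dropped silently.

## The synthetic world

`SyntheticConfig` states the simulated study: 20 patients / 26 controls
expected after QC from a recruited pool of 24 / 29 (3 + 3 planted motion
failures, 1 planted MRS failure), 90 regions in six modules of sizes
(18, 20, 17, 14, 10, 11) named Central, DefaultMode, Frontoparietal,
Occipital, Subcortical, Hippocampal, and T = 230 volumes.

Time series are zero-mean multivariate normal draws from a block correlation
matrix: r_intra = 0.5 inside every module, r_inter = 0.1 between modules,
plus white observation noise (obs_noise_sd = 0.1 on the unit-variance scale,
attenuating correlations by ~1%). The patient group carries additive deltas
-0.15 on Frontoparietal-Central and Frontoparietal-Hippocampal coupling and
+0.15 on Frontoparietal intra-module coupling. Each subject additionally
draws a personal offset (SD coupling_sd = 0.08) on those three blocks; these
realizations are the ground truth that metabolites and clinical scores couple
to. If deltas break positive semidefiniteness the matrix is repaired by
eigenvalue clipping at 1e-8 plus diagonal renormalization, and the Frobenius
size of the repair is reported rather than hidden. BOLD autocorrelation is
not simulated: the band-pass stage imposes it downstream, and white
generation keeps the planted correlations analyzable.

Motion traces are smooth, mean-reverting random walks jointly rescaled so
each clean subject's mean FD hits a target drawn from an arcsine law on
0.04-0.12 mm. The bathtub-shaped, bounded severity distribution is chosen
because the FD exclusion rule is group-relative (mean + 2 SD): any i.i.d.
severity distribution gets a clean subject flagged occasionally, and the
arcsine shape keeps that probability near 2% per cohort (a uniform law gives
~11%). Planted motion outliers get one translation axis rescaled to peak
between 2.8 and 4 mm.

Control-group NAA is `8.0 + 10.0 * eta_fc + N(0, 0.4)` institutional units,
where eta_fc is the subject's Frontoparietal-Central coupling offset;
patients draw NAA from the variance-matched decoupled distribution. The
slope/noise levels are unstated by the study design and were fixed once so
that the *measured* control correlation lands near the worked example
(r ~ 0.6) while inter-individual NAA spread stays ~11% of the mean —
physiologically plausible. GABA+ and Glx are uncoupled. Patient PANSS
general scores load negatively (-0.5) on the standardized FP-Central offset
and positively (+0.6) on the FP-Hippocampal offset, with subscale moments
taken from the study's demographics table; the total score is the subscale
sum, so it inherits a diluted version of the same monotone couplings.

### What a green synthetic run does not establish

The generator produces exchangeable Gaussian volumes: no autocorrelation,
scanner drift, physiological noise, motion-BOLD coupling, registration
error, or spatial smoothness. QC therefore exercises the decision rules, not
artifact detection. Planted effects are homogeneous within blocks, which is
why modular recovery is near-perfect (ARI ~ 1.0) — real networks have
overlapping, graded communities. Empirical group means and correlations from
the original raw data are not reproducible and are not targets; the
recovered quantities are directions, detection rates, and calibration.

### Known deviation of the synthetic world from quoted Q ranges

With the stated contrast (0.5 within vs 0.1 between), the group-average
network at the selected sparsity (typically 0.18-0.26 here) keeps ~96% of
its weight inside modules, and the detected Q lands in 0.63-0.77 (median
0.74 over 100 seeds) — slightly above the 0.3-0.7 band typically quoted for
empirical brain networks, which are far less cleanly modular. This is a
property of the stated world, not of the estimator: Q of the planted
partition itself sits in the same range, and Q is invariant to uniform
attenuation of the weights, so no observation-noise level changes it. The
acceptance test for the upper bound is kept as stated and is expected to
fail; weakening the planted contrast to pass it would change the stated
world after the fact.

## Numerical conventions

* 0-based node indexing internally; all file formats carry region labels.
* Fisher clamp at |r| = 1 - 1e-15; symmetry enforced to 1e-12; matrix
  diagonals exactly zero.
* Zero-variance edges in the FDR test degenerate to p = 0 (positive mean) or
  p = 1, logged.
* Refinement stops when no single-node move gains more than 1e-12.
* Rotations are consumed in degrees (converted internally); motion column
  order is fixed by the TSV header.
* All cohort randomness flows from `SyntheticConfig.seed`; detection and
  thresholding are seed-free and deterministic.

## Limitations

Single-voxel MRS is reduced to per-subject concentration records; spectra
are never synthesized. No nodal graph metrics, no null-model significance
testing of Q, no Louvain/consensus clustering, no dynamic connectivity, no
medication/demographic covariate adjustment. The effective n of
metabolite-clinical correlations follows the data actually present after
CRLB and outlier screening.
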
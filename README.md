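# modcoupling

Modular functional-connectivity analysis for two-group resting-state fMRI
studies with single-voxel MRS, plus a synthetic cohort generator so the whole
pipeline can be exercised and validated without any raw imaging data.

The package is aimed at researchers studying how the brain's modular network
organization relates to regional neurochemistry and clinical state — e.g.
whether frontoparietal intra-/inter-module connectivity differs between
patients and controls, and whether it couples to metabolite concentrations
(NAA, GABA+, Glx) in a network's core region and to symptom scores.

## The model

From each subject's T x N ROI time-series table the pipeline builds a
Fisher-z functional connectivity matrix, retains reliably positive edges by
edge-wise one-sample testing with Benjamini-Hochberg FDR control, and
averages within diagnostic group. Modular structure is found by maximizing
the weighted modularity

```
Q(p) = (1/l) Σ_ij [ w_ij − k_i k_j / l ] δ(m_i, m_j)
```

(k_i node strength, l total weight over ordered pairs) with a deterministic
greedy agglomeration plus node-move and module-split refinement, at the
smallest sparsity in 5-30% that leaves every subject's thresholded network
fully connected. Module-level coupling uses the mean edge weight within a
module (C_s) and between module pairs (C_{s,t}) under the control-group
partition, compared across groups by Welch t-tests and correlated with
CSF-corrected, CRLB-filtered metabolite concentrations (Pearson) and
PANSS/CGI scores (Spearman), with Grubbs outlier screening throughout.

The synthetic generator plants exactly this structure: six modules over a
packaged 90-region cerebral parcellation, group-specific deltas on
frontoparietal coupling, a metabolite linearly coupled to the planted
frontoparietal-central connectivity in controls only, clinically coupled
symptom scores in patients, and QC outliers (motion, CRLB) that the
exclusion rules must catch. See `docs/methods.md` for assumptions, defaults
and limitations.

## Worked example

```python
import modcoupling as mc

cohort = mc.generate_cohort(mc.SyntheticConfig(seed=42))
result = mc.analyze_cohort(cohort)

qc = result.qc
print(qc.n_included("patient"), qc.n_included("control"))
print(result.selected_sparsity)
ref = result.reference_partition
print(ref.n_modules, round(ref.q, 3))
print(result.stat("ttest_intra_Frontoparietal"))
print(result.stat("pearson_NAA_inter_Frontoparietal_Central_control"))
```

prints (trimmed):

```
included: 20 patients, 26 controls
selected sparsity: 0.21
control partition: 6 modules, Q = 0.731
ttest_intra_Frontoparietal:                diff = +0.202, t = 4.73,  p = 4.6e-05
ttest_inter_Frontoparietal_Central:        diff = -0.106, t = -7.49, p = 7.7e-08
ttest_inter_Frontoparietal_Hippocampal:    diff = -0.119, t = -6.66, p = 5.6e-07
control NAA ~ FP-Central: r = 0.722, p = 3.1e-05 (n = 26)
patient NAA ~ FP-Central: degenerate (no surviving patient FP-Central edges)
```

Reading it: QC removed exactly the planted motion/MRS outliers (20/26
retained); modular detection recovered the six planted modules; patients show
hyper-connectivity within the frontoparietal module and hypo-connectivity
from it to the central and hippocampal modules; and the metabolite couples to
frontoparietal-central connectivity in controls but not patients — the
planted functional-metabolic decoupling.

The same run is available from the shell:

```bash
modcoupling simulate --seed 42 --out cohort/
modcoupling qc --cohort cohort/
modcoupling run-all --cohort cohort/ --out results/
```

## Acceptance script

`scripts/acceptance.py` regenerates the default synthetic cohort for a given
seed, runs the full pipeline from scratch (QC, network construction,
connectedness-based sparsity selection, modular detection) and writes the
maximum modularity of the detected control-group partition as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/modcoupling/synthetic.py` — planted-covariance cohort generator
- `src/modcoupling/qc.py` — motion/FD exclusion, nuisance regression,
  band-pass, CRLB filter, CSF correction
- `src/modcoupling/network.py` — correlation, FDR edge retention, sparsity
  thresholding and selection
- `src/modcoupling/modularity.py` — weighted modularity, greedy detection,
  sweeps, partition matching
- `src/modcoupling/metrics.py` — intra/inter-module connectivity
- `src/modcoupling/stats.py` — t-tests, correlations, Grubbs screening
- `src/modcoupling/pipeline.py` — end-to-end orchestration and reports
- `src/modcoupling/cli.py` — `modcoupling` command-line interface
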
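"""End-to-end analysis: QC -> networks -> modules -> metrics -> statistics.

Pipeline conventions (fixed here so every stage composes unambiguously):

* per-subject weighted networks are Fisher-z matrices masked by that
  diagnostic group's edge-wise FDR mask;
* a single sparsity is selected over all included subjects (smallest grid
  value connecting every subject's thresholded network);
* modular detection runs on each group's FDR-masked average network further
  thresholded at the selected sparsity;
* subject-level module metrics use the subject's FDR-masked z matrix
  (optionally further restricted to their group's selected-sparsity mask),
  evaluated under the control-group partition so both groups are scored on
  the same modular mask;
* metabolite values are CRLB-filtered and CSF partial-volume corrected before
  correlation, and each correlation is preceded by Grubbs outlier screening
  of both variables.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import read_cohort
from .metrics import ModuleMetrics, subject_module_metrics
from .modularity import ModularPartition, detect_modules, match_partitions
from .network import (
    ConnectivityMatrix,
    EdgeMask,
    SparsitySelection,
    correlation_matrix,
    edgewise_fdr_mask,
    group_average,
    select_sparsity,
    sparsity_threshold,
)
from .qc import (
    QCReport,
    apply_qc,
    crlb_filter,
    csf_correct,
    detrend_bandpass,
    friston24,
    nuisance_regress,
)
from .stats import (
    StatResult,
    detect_outliers,
    pearson_corr,
    spearman_corr,
    two_sample_ttest,
)
from .synthetic import Cohort

__all__ = [
    "PipelineParams",
    "GroupNetwork",
    "AnalysisResult",
    "preprocess_subject",
    "analyze_cohort",
    "run_full_analysis",
]

REPORT_SCHEMA = "modcoupling-report/1"

# Module-level contrasts of primary interest (reference-partition names).
_CONTRASTS = [
    ("intra", ("Frontoparietal",)),
    ("inter", ("Frontoparietal", "Central")),
    ("inter", ("Frontoparietal", "Hippocampal")),
]


@dataclass(frozen=True)
class PipelineParams:
    q: float = 0.05
    sparsity_lo: float = 0.05
    sparsity_hi: float = 0.30
    sparsity_step: float = 0.01
    sparsity: float | None = None  # fixed value bypasses selection
    nuisance: bool = True
    bandpass: bool = True
    global_signal: bool = False
    low_hz: float = 0.01
    high_hz: float = 0.1
    max_trans_mm: float = 2.5
    max_rot_deg: float = 2.5
    fd_sd_mult: float = 2.0
    max_crlb_percent: float = 20.0
    outlier_alpha: float = 0.05
    ref_group: str = "control"
    #: Edge set for subject-level module metrics: the group FDR mask ("fdr",
    #: default) or additionally restricted to the group's selected-sparsity
    #: mask ("combined").  The sparsity restriction leaves very few
    #: between-module edges on strongly modular networks, which makes
    #: inter-module connectivity a noisy (possibly empty) selection-biased
    #: mean; the FDR mask keeps every reliably positive edge.
    metrics_mask: str = "fdr"

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class GroupNetwork:
    group: str
    fdr_mask: EdgeMask
    average: ConnectivityMatrix          # FDR-masked group-mean z
    sparsity_mask: EdgeMask | None = None
    masked_average: ConnectivityMatrix | None = None
    partition: ModularPartition | None = None


@dataclass
class AnalysisResult:
    qc: QCReport
    selection: SparsitySelection | None
    selected_sparsity: float
    networks: dict[str, GroupNetwork]
    reference_partition: ModularPartition
    metrics: pd.DataFrame
    subject_metrics: dict[str, ModuleMetrics]
    stats: list[StatResult]
    partition_agreement: float  # ARI between the two group partitions
    config_hash: str
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def stat(self, name: str) -> StatResult:
        for s in self.stats:
            if s.name == name:
                return s
        raise KeyError(name)

    def report_dict(self) -> dict:
        return {
            "schema": REPORT_SCHEMA,
            "version": __version__,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "selected_sparsity": self.selected_sparsity,
            "sparsity_all_connected":
                self.selection.all_connected if self.selection else True,
            "qc": {sid: {k: v for k, v in rec.items()}
                   for sid, rec in self.qc.records.items()},
            "partitions": {
                g: net.partition.to_dict() if net.partition else None
                for g, net in self.networks.items()
            },
            "partition_agreement_ari": self.partition_agreement,
            "stats": [s.to_dict() for s in self.stats],
        }


def preprocess_subject(
    ts: np.ndarray,
    motion: np.ndarray,
    tr_s: float,
    params: PipelineParams,
) -> np.ndarray:
    """Nuisance regression (Friston-24, optional region-mean global proxy)
    followed by detrending and band-pass filtering."""
    x = np.asarray(ts, dtype=float)
    if params.nuisance:
        design = friston24(motion)
        if params.global_signal:
            design = np.hstack([design, x.mean(axis=1, keepdims=True)])
        x = nuisance_regress(x, design)
    if params.bandpass:
        x = detrend_bandpass(x, tr_s, params.low_hz, params.high_hz)
    return x


def _named_partition(
    partition: ModularPartition, reference: np.ndarray, names: list[str]
) -> ModularPartition:
    """Attach names to detected modules by maximal node overlap with the
    planted reference modules (duplicates disambiguated by suffix)."""
    contingency, _ = match_partitions(partition.module_of, reference)
    used: dict[str, int] = {}
    module_names = []
    for row in contingency:
        base = names[int(np.argmax(row))] if row.sum() else "empty"
        if base in used:
            used[base] += 1
            module_names.append(f"{base}_{used[base]}")
        else:
            used[base] = 0
            module_names.append(base)
    partition.module_names = module_names
    return partition


def analyze_cohort(
    cohort: Cohort, params: PipelineParams | None = None
) -> AnalysisResult:
    """Run the full analysis on an in-memory cohort."""
    params = params or PipelineParams()
    cfg = cohort.config
    qc = apply_qc(
        cohort,
        max_trans_mm=params.max_trans_mm,
        max_rot_deg=params.max_rot_deg,
        fd_sd_mult=params.fd_sd_mult,
        max_crlb_percent=params.max_crlb_percent,
    )
    included = [s for s in cohort.subjects if qc.included[s.subject_id]]
    groups = sorted({s.group for s in included})
    if params.ref_group not in groups:
        raise ValueError(f"reference group {params.ref_group!r} has no "
                         "included subjects")

    # Per-subject Fisher-z matrices on conditioned series.
    zmats: dict[str, ConnectivityMatrix] = {}
    for s in included:
        clean = preprocess_subject(s.timeseries, s.motion, cfg.tr_s, params)
        zmats[s.subject_id] = correlation_matrix(
            clean, fisher=True, labels=cohort.region_labels
        )

    networks: dict[str, GroupNetwork] = {}
    masked_subject: dict[str, np.ndarray] = {}
    for group in groups:
        members = [s for s in included if s.group == group]
        mats = [zmats[s.subject_id] for s in members]
        fdr = edgewise_fdr_mask(mats, q=params.q)
        avg = group_average(mats, fdr)
        for s in members:
            masked_subject[s.subject_id] = np.where(
                fdr.values, zmats[s.subject_id].values, 0.0
            )
        networks[group] = GroupNetwork(group=group, fdr_mask=fdr, average=avg)

    # One sparsity for the whole cohort, from all subjects' masked networks.
    if params.sparsity is not None:
        selection = None
        sparsity = float(params.sparsity)
    else:
        selection = select_sparsity(
            [masked_subject[s.subject_id] for s in included],
            params.sparsity_lo, params.sparsity_hi, params.sparsity_step,
        )
        sparsity = selection.sparsity

    for group, net in networks.items():
        smask = sparsity_threshold(net.average, sparsity)
        net.sparsity_mask = smask
        masked = np.where(smask.values, net.average.values, 0.0)
        net.masked_average = ConnectivityMatrix(
            masked, labels=cohort.region_labels, kind="z"
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            part = detect_modules(net.masked_average)
        net.partition = _named_partition(
            part, cohort.planted_assignment, list(cohort.module_names)
        )

    reference = networks[params.ref_group].partition
    assert reference is not None
    if len(groups) == 2:
        other = [g for g in groups if g != params.ref_group][0]
        _, agreement = match_partitions(reference,
                                        networks[other].partition)
    else:
        agreement = 1.0

    # Subject metrics under the reference partition.
    subject_metrics: dict[str, ModuleMetrics] = {}
    frames = []
    for s in included:
        net = networks[s.group]
        if params.metrics_mask == "combined":
            combined = net.fdr_mask & net.sparsity_mask
        elif params.metrics_mask == "fdr":
            combined = net.fdr_mask
        else:
            raise ValueError("metrics_mask must be 'fdr' or 'combined'")
        sm = subject_module_metrics(
            masked_subject[s.subject_id], reference, combined,
            subject_id=s.subject_id, group=s.group,
            module_names=reference.module_names,
        )
        subject_metrics[s.subject_id] = sm
        frames.append(sm.to_frame())
    metrics = pd.concat(frames, ignore_index=True)

    stats = _cohort_statistics(cohort, qc, subject_metrics, params)

    cfg_payload = json.dumps(
        {"config": cfg.to_dict(), "params": params.to_dict()},
        sort_keys=True, default=str,
    )
    return AnalysisResult(
        qc=qc,
        selection=selection,
        selected_sparsity=sparsity,
        networks=networks,
        reference_partition=reference,
        metrics=metrics,
        subject_metrics=subject_metrics,
        stats=stats,
        partition_agreement=float(agreement),
        config_hash=hashlib.sha1(cfg_payload.encode()).hexdigest(),
        seed=cfg.seed,
    )


def _metric_series(
    subject_metrics: dict[str, ModuleMetrics], kind: str, which: tuple[str, ...]
) -> dict[str, float]:
    out = {}
    for sid, sm in subject_metrics.items():
        try:
            out[sid] = sm.intra_of(which[0]) if kind == "intra" \
                else sm.inter_of(*which)
        except KeyError:
            continue  # detection did not resolve this named module
    return out


def _metric_label(kind: str, which: tuple[str, ...]) -> str:
    return f"{kind}_" + "_".join(which)


def _screened_corr(x, y, corr_fn, name, alpha) -> StatResult:
    """Correlation preceded by Grubbs screening on both variables."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    removed = 0
    if len(x) >= 3:
        fx = detect_outliers(x, alpha=alpha).flags
        fy = detect_outliers(y, alpha=alpha).flags
        keep = ~(fx | fy)
        removed = int((~keep).sum())
        x, y = x[keep], y[keep]
    try:
        res = corr_fn(x, y, name=name)
    except ValueError as exc:
        res = StatResult(name, float("nan"), float("nan"), float(len(x)),
                         float("nan"), (len(x),),
                         {"degenerate": str(exc)})
    res.flags["outliers_removed"] = removed
    return res


def _cohort_statistics(
    cohort: Cohort,
    qc: QCReport,
    subject_metrics: dict[str, ModuleMetrics],
    params: PipelineParams,
) -> list[StatResult]:
    stats: list[StatResult] = []
    included = [s for s in cohort.subjects if qc.included[s.subject_id]]
    by_id = {s.subject_id: s for s in included}

    # Group comparisons of the primary module contrasts.
    for kind, which in _CONTRASTS:
        series = _metric_series(subject_metrics, kind, which)
        label = _metric_label(kind, which)
        pat = [v for sid, v in series.items() if by_id[sid].group == "patient"]
        con = [v for sid, v in series.items() if by_id[sid].group == "control"]
        if len(pat) >= 2 and len(con) >= 2:
            try:
                stats.append(two_sample_ttest(
                    pat, con, name=f"ttest_{label}"
                ))
            except ValueError as exc:
                stats.append(StatResult(
                    f"ttest_{label}", float("nan"), float("nan"), 1.0,
                    float("nan"), (len(pat), len(con)),
                    {"degenerate": str(exc)},
                ))

    # Corrected metabolite concentrations per subject.
    metabolite_values: dict[str, dict[str, float]] = {}
    for s in included:
        retained, _ = crlb_filter(s.metabolites, params.max_crlb_percent)
        for rec in retained:
            metabolite_values.setdefault(rec.metabolite, {})[s.subject_id] = \
                csf_correct(rec)

    # Metabolite-connectivity Pearson correlations, per group.
    for metabolite, values in sorted(metabolite_values.items()):
        for kind, which in _CONTRASTS:
            series = _metric_series(subject_metrics, kind, which)
            label = _metric_label(kind, which)
            for group in ("control", "patient"):
                sids = [sid for sid in series
                        if sid in values and by_id[sid].group == group]
                if len(sids) < 3:
                    continue
                x = [series[sid] for sid in sids]
                y = [values[sid] for sid in sids]
                safe = metabolite.replace("+", "plus")
                stats.append(_screened_corr(
                    x, y, pearson_corr,
                    f"pearson_{safe}_{label}_{group}", params.outlier_alpha,
                ))

    # Clinical Spearman correlations (patients).
    clinical_keys = ("panss_pos", "panss_neg", "panss_gen", "panss_total", "cgi")
    patients = [s for s in included
                if s.group == "patient" and s.clinical is not None]
    for kind, which in _CONTRASTS:
        series = _metric_series(subject_metrics, kind, which)
        label = _metric_label(kind, which)
        for key in clinical_keys:
            sids = [s.subject_id for s in patients if s.subject_id in series]
            if len(sids) < 4:
                continue
            x = [series[sid] for sid in sids]
            y = [by_id[sid].clinical[key] for sid in sids]
            stats.append(_screened_corr(
                x, y, spearman_corr,
                f"spearman_{label}_{key}_patient", params.outlier_alpha,
            ))
    for metabolite, values in sorted(metabolite_values.items()):
        for key in clinical_keys:
            sids = [s.subject_id for s in patients if s.subject_id in values]
            if len(sids) < 4:
                continue
            safe = metabolite.replace("+", "plus")
            stats.append(_screened_corr(
                [values[sid] for sid in sids],
                [by_id[sid].clinical[key] for sid in sids],
                spearman_corr,
                f"spearman_{safe}_{key}_patient", params.outlier_alpha,
            ))
    return stats


def run_full_analysis(
    cohort: Cohort | str | Path,
    out_dir: str | Path | None = None,
    params: PipelineParams | None = None,
) -> AnalysisResult:
    """Analyze a cohort (object or directory) and optionally write the
    machine-readable report, flat stats table and metrics table."""
    if not isinstance(cohort, Cohort):
        cohort = read_cohort(cohort)
    result = analyze_cohort(cohort, params)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(result.report_dict(), indent=1, default=_jsonify)
        )
        rows = [s.to_dict() for s in result.stats]
        pd.DataFrame(rows).to_csv(out / "stats.csv", index=False)
        result.metrics.to_csv(out / "metrics.csv", index=False)
        (out / "reference_partition.json").write_text(
            json.dumps(result.reference_partition.to_dict(), indent=1)
        )
        if result.selection is not None:
            result.selection.table.to_csv(out / "sparsity_sweep.csv",
                                          index=False)
    return result


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
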
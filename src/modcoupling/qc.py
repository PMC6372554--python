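"""Subject-level quality control and ROI time-series conditioning.

Covers the desk-scale portion of a resting-state preprocessing stream: rigid
body motion summaries (framewise displacement after Jenkinson's 80 mm-sphere
RMS formula), the 2.5 mm / 2.5 degree / mean-FD exclusion rules, Friston
24-parameter nuisance designs, OLS nuisance regression, linear detrending
with an ideal frequency-domain band-pass, and MRS quantification QC (CRLB
filtering and CSF partial-volume correction).

Image-space operations (realignment estimation, normalization, smoothing,
spectral fitting) are out of scope; this module starts from ROI tables and
quantified metabolite records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "MetaboliteRecord",
    "QCReport",
    "framewise_displacement",
    "motion_exclusion",
    "apply_qc",
    "friston24",
    "nuisance_regress",
    "detrend_bandpass",
    "crlb_filter",
    "csf_correct",
]


@dataclass(frozen=True)
class MetaboliteRecord:
    """One quantified metabolite for one subject.

    ``crlb`` is the relative fit uncertainty in percent; the tissue fractions
    must be a near-partition of the voxel.
    """

    metabolite: str  # NAA | GABA+ | Glx
    concentration: float
    crlb: float
    f_gm: float
    f_wm: float
    f_csf: float

    def __post_init__(self) -> None:
        if self.crlb < 0:
            raise ValueError("CRLB must be non-negative")
        for name, f in (("f_gm", self.f_gm), ("f_wm", self.f_wm),
                        ("f_csf", self.f_csf)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f} outside [0, 1]")
        if abs(self.f_gm + self.f_wm + self.f_csf - 1.0) >= 0.01:
            raise ValueError("tissue fractions must sum to 1 within 0.01")


@dataclass
class QCReport:
    """Per-subject inclusion decisions with the measurements behind them."""

    records: dict[str, dict] = field(default_factory=dict)

    @property
    def included(self) -> dict[str, bool]:
        return {sid: r["included"] for sid, r in self.records.items()}

    def n_included(self, group: str | None = None) -> int:
        return sum(
            r["included"]
            for r in self.records.values()
            if group is None or r.get("group") == group
        )

    def to_frame(self):
        import pandas as pd

        rows = [{"subject_id": sid, **r} for sid, r in self.records.items()]
        return pd.DataFrame(rows)


def _rotation_matrices(rot: np.ndarray, degrees: bool) -> np.ndarray:
    # x-y-z extrinsic composition of the three rotation parameters.
    return Rotation.from_euler("xyz", rot, degrees=degrees).as_matrix()


def framewise_displacement(
    motion: np.ndarray, head_radius_mm: float = 80.0, *, degrees: bool = True
) -> np.ndarray:
    """Per-volume framewise displacement (mm) of a T x 6 rigid-body trace.

    Columns are three translations (mm) then three rotations (degrees by
    default).  FD[t] is the RMS displacement over a solid sphere of radius
    ``head_radius_mm`` induced by the rigid transform taking volume t-1 to t:
    ``sqrt(R^2/5 * trace(dA.T dA) + |db|^2)`` with ``dA`` the rotation
    difference minus identity and ``db`` the translation difference.
    FD[0] is defined as 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    if not np.all(np.isfinite(motion)):
        raise ValueError("non-finite motion parameters")

    trans = motion[:, :3]
    rotmats = _rotation_matrices(motion[:, 3:], degrees=degrees)
    d_a = np.einsum("tij,tkj->tik", rotmats[1:], rotmats[:-1])  # R_t R_{t-1}^T
    d_a -= np.eye(3)
    rot_term = (head_radius_mm**2 / 5.0) * np.einsum("tij,tij->t", d_a, d_a)
    d_b = np.diff(trans, axis=0)
    fd = np.sqrt(rot_term + np.sum(d_b**2, axis=1))
    # exact zero when the parameters do not change (kills rotation round-off)
    fd[np.all(np.diff(motion, axis=0) == 0.0, axis=1)] = 0.0
    return np.concatenate([[0.0], fd])


def motion_exclusion(
    traces: dict[str, np.ndarray],
    groups: dict[str, str],
    *,
    max_trans_mm: float = 2.5,
    max_rot_deg: float = 2.5,
    fd_sd_mult: float = 2.0,
    head_radius_mm: float = 80.0,
) -> QCReport:
    """Apply the motion exclusion rules to a cohort of rigid-body traces.

    A subject is excluded if any |translation| exceeds ``max_trans_mm``, any
    |rotation| exceeds ``max_rot_deg``, or their mean FD exceeds the group
    mean + ``fd_sd_mult`` x SD of mean FD.  The FD-rule group statistics are
    computed per diagnostic group over the subjects that pass the first two
    rules (the absolute rules are order-independent; the FD rule is applied
    after them).
    """
    if not traces:
        raise ValueError("no motion traces supplied")
    report = QCReport()
    for sid, trace in traces.items():
        trace = np.asarray(trace, dtype=float)
        fd = framewise_displacement(trace, head_radius_mm)
        rec = {
            "group": groups.get(sid, "all"),
            "max_translation_mm": float(np.max(np.abs(trace[:, :3]))),
            "max_rotation_deg": float(np.max(np.abs(trace[:, 3:]))),
            "mean_fd": float(np.mean(fd)),
            "included": True,
            "reasons": [],
        }
        if rec["max_translation_mm"] > max_trans_mm:
            rec["reasons"].append("max_translation_mm")
        if rec["max_rotation_deg"] > max_rot_deg:
            rec["reasons"].append("max_rotation_deg")
        rec["included"] = not rec["reasons"]
        report.records[sid] = rec

    for group in {r["group"] for r in report.records.values()}:
        passers = [
            r for r in report.records.values()
            if r["group"] == group and r["included"]
        ]
        if not passers:
            raise ValueError(f"group {group!r} has no subjects passing the "
                             "absolute motion rules")
        fds = np.array([r["mean_fd"] for r in passers])
        limit = float(fds.mean() + fd_sd_mult * fds.std(ddof=1)) \
            if len(fds) > 1 else float("inf")
        for r in report.records.values():
            if r["group"] != group:
                continue
            r["fd_limit"] = limit
            if r["included"] and r["mean_fd"] > limit:
                r["reasons"].append("mean_fd")
                r["included"] = False
    return report


def apply_qc(
    cohort,
    *,
    max_trans_mm: float = 2.5,
    max_rot_deg: float = 2.5,
    fd_sd_mult: float = 2.0,
    max_crlb_percent: float = 20.0,
    head_radius_mm: float = 80.0,
) -> QCReport:
    """Cohort-level QC: motion rules plus an incomplete-MRS rule.

    A subject whose every metabolite fails the CRLB filter has no usable MRS
    quantification and is excluded from the analysis cohort; partial CRLB
    failures only drop the affected metabolites and are recorded per subject.
    """
    traces = {s.subject_id: s.motion for s in cohort.subjects}
    groups = {s.subject_id: s.group for s in cohort.subjects}
    report = motion_exclusion(
        traces, groups,
        max_trans_mm=max_trans_mm, max_rot_deg=max_rot_deg,
        fd_sd_mult=fd_sd_mult, head_radius_mm=head_radius_mm,
    )
    for s in cohort.subjects:
        rec = report.records[s.subject_id]
        retained, excluded = crlb_filter(s.metabolites, max_crlb_percent)
        rec["crlb_failures"] = [m.metabolite for m in excluded]
        if s.metabolites and not retained:
            rec["reasons"].append("no_metabolite_passes_crlb")
            rec["included"] = False
    return report


def friston24(motion: np.ndarray) -> np.ndarray:
    """Friston 24-parameter motion design: the 6 rigid-body parameters, their
    one-volume backshift (first row zero), and the squares of both sets."""
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be T x 6")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    lagged = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, lagged, motion**2, lagged**2])


def nuisance_regress(
    ts: np.ndarray, regressors: np.ndarray | None = None
) -> np.ndarray:
    """OLS residuals of each region's series after regressing on an intercept
    plus the given T x K nuisance design.

    Constant columns duplicating the intercept are dropped before fitting;
    remaining rank deficiency is an error that names the offending columns.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be T x N")
    t = ts.shape[0]
    design = np.ones((t, 1))
    kept: list[int] = []
    if regressors is not None:
        regressors = np.asarray(regressors, dtype=float)
        if regressors.ndim != 2 or regressors.shape[0] != t:
            raise ValueError("regressors must be T x K with matching T")
        for k in range(regressors.shape[1]):
            col = regressors[:, k]
            if np.ptp(col) == 0.0:  # constant: duplicates the intercept
                continue
            kept.append(k)
        design = np.hstack([design, regressors[:, kept]])
    if design.shape[1] >= t:
        raise ValueError("design has as many columns as timepoints")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _rank_deficient_columns(design)
        raise np.linalg.LinAlgError(
            f"rank-deficient nuisance design; offending columns "
            f"(0-based, intercept first): {bad}"
        )
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ beta


def _rank_deficient_columns(design: np.ndarray) -> list[int]:
    bad, rank = [], 0
    for k in range(design.shape[1]):
        new_rank = np.linalg.matrix_rank(design[:, : k + 1])
        if new_rank == rank:
            bad.append(k)
        rank = new_rank
    return bad


def detrend_bandpass(
    ts: np.ndarray,
    tr_s: float,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> np.ndarray:
    """Linear detrend per region, then an ideal FFT band-pass that retains
    frequency bins in [low_hz, high_hz] inclusive."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be T x N")
    t = ts.shape[0]
    if t < 16:
        raise ValueError("need at least 16 timepoints")
    nyquist = 0.5 / tr_s
    if not (0.0 <= low_hz < high_hz < nyquist):
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz outside (0, Nyquist={nyquist}) "
        )
    # least-squares linear trend removal
    x = np.arange(t, dtype=float)
    design = np.column_stack([np.ones(t), x])
    beta, *_ = np.linalg.lstsq(design, ts, rcond=None)
    detrended = ts - design @ beta

    freqs = np.fft.rfftfreq(t, d=tr_s)
    spectrum = np.fft.rfft(detrended, axis=0)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spectrum[~keep] = 0.0
    return np.fft.irfft(spectrum, n=t, axis=0)


def crlb_filter(
    records: list[MetaboliteRecord], max_crlb_percent: float = 20.0
) -> tuple[list[MetaboliteRecord], list[MetaboliteRecord]]:
    """Split records into (retained, excluded) by the strict CRLB criterion
    ``crlb < max_crlb_percent``; exclusions are per metabolite."""
    retained = [r for r in records if r.crlb < max_crlb_percent]
    excluded = [r for r in records if r.crlb >= max_crlb_percent]
    return retained, excluded


def csf_correct(record: MetaboliteRecord) -> float:
    """CSF partial-volume corrected concentration: ``conc / (1 - f_csf)``.

    This is the visibility correction only; water-relaxation terms of the
    full tissue-correction formula are intentionally omitted.
    """
    if record.f_csf >= 1.0:
        raise ValueError("f_csf must be < 1")
    return record.concentration / (1.0 - record.f_csf)
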
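"""Synthetic cohort generation with a planted modular correlation structure.

The generator emulates a two-group resting-state study: region-wise BOLD-like
time series drawn from a zero-mean multivariate normal whose correlation
matrix contains planted modules, rigid-body motion traces (with a configurable
number of subjects planted to fail motion QC), single-voxel MRS metabolite
quantifications (with planted uncertainty failures), and PANSS-like clinical
scores.  Group differences, metabolite coupling, and clinical coupling are all
planted at the level of specific module-pair correlations so that every
downstream stage of the analysis has a known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .parcellation import (
    AAL90_LABELS,
    DEFAULT_MODULE_SIZES,
    MODULE_NAMES,
    default_assignment,
)
from .qc import MetaboliteRecord

__all__ = [
    "SyntheticConfig",
    "SubjectRecord",
    "Cohort",
    "PlantedCovariance",
    "planted_covariance",
    "generate_cohort",
]

# Patient-group additive deltas on module-pair correlations, keyed by module
# name pairs ((m, m) is a within-module delta).
_DEFAULT_EFFECTS: dict[tuple[str, str], float] = {
    ("Frontoparietal", "Central"): -0.15,
    ("Frontoparietal", "Hippocampal"): -0.15,
    ("Frontoparietal", "Frontoparietal"): +0.15,
}

# Blocks whose correlation carries an additional per-subject random offset;
# these realizations drive the metabolite and clinical couplings.
_COUPLING_BLOCKS: tuple[tuple[str, str], ...] = (
    ("Frontoparietal", "Central"),
    ("Frontoparietal", "Hippocampal"),
    ("Frontoparietal", "Frontoparietal"),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Stated world of the simulated study.

    Sample sizes, module sizes, exclusion counts and effect directions mirror
    the target study design (20 patients / 26 controls retained out of a
    recruited pool of 24 / 29; six modules over 90 regions; 230 retained
    volumes).  ``n_patients`` / ``n_controls`` are the counts expected to
    survive QC; the planted outliers are generated on top of them.
    """

    n_patients: int = 20
    n_controls: int = 26
    n_regions: int = 90
    n_timepoints: int = 230
    tr_s: float = 2.0
    module_sizes: tuple[int, ...] = DEFAULT_MODULE_SIZES
    r_intra: float = 0.5
    r_inter: float = 0.1
    effect_map: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_EFFECTS)
    )
    #: SD of the per-subject random offset on each coupling block (r units).
    coupling_sd: float = 0.08
    #: NAA institutional units gained per unit of frontoparietal-central
    #: correlation, in the control group only.
    coupling_slope: float = 10.0
    coupling_noise_sd: float = 0.4
    naa_base: float = 8.0
    #: SD of white observation noise added on top of the latent signal
    #: (unit-variance scale); attenuates correlations by 1/(1+sd^2).
    obs_noise_sd: float = 0.1
    #: Weights of the standardized planted couplings in the PANSS general
    #: subscale (patients): negative on FP-Central, positive on FP-Hippocampal.
    clinical_coupling: Mapping[str, float] = field(
        default_factory=lambda: {"fp_central": -0.5, "fp_hippocampal": 0.6}
    )
    motion_outlier_patients: int = 3
    motion_outlier_controls: int = 3
    crlb_outlier_patients: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if sum(self.module_sizes) != self.n_regions:
            raise ValueError(
                f"module sizes {self.module_sizes} sum to "
                f"{sum(self.module_sizes)}, expected n_regions={self.n_regions}"
            )
        if not (0 <= self.r_inter < self.r_intra < 1):
            raise ValueError("need 0 <= r_inter < r_intra < 1")
        for name, value in (
            ("n_patients", self.n_patients),
            ("n_controls", self.n_controls),
            ("n_regions", self.n_regions),
            ("n_timepoints", self.n_timepoints),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")

    @property
    def module_names(self) -> tuple[str, ...]:
        if tuple(self.module_sizes) == DEFAULT_MODULE_SIZES:
            return MODULE_NAMES
        return tuple(f"M{i}" for i in range(len(self.module_sizes)))

    @property
    def region_labels(self) -> list[str]:
        if self.n_regions == 90 and tuple(self.module_sizes) == DEFAULT_MODULE_SIZES:
            return list(AAL90_LABELS)
        return [f"R{i + 1:03d}" for i in range(self.n_regions)]

    def planted_assignment(self) -> np.ndarray:
        """Module id per region, aligned with :meth:`region_labels`."""
        if self.n_regions == 90 and tuple(self.module_sizes) == DEFAULT_MODULE_SIZES:
            return default_assignment()
        return np.repeat(
            np.arange(len(self.module_sizes), dtype=np.intp), self.module_sizes
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_map"] = [
            {"a": a, "b": b, "delta": v} for (a, b), v in self.effect_map.items()
        ]
        d["clinical_coupling"] = dict(self.clinical_coupling)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        d = dict(d)
        if "effect_map" in d and not isinstance(d["effect_map"], Mapping):
            d["effect_map"] = {
                (e["a"], e["b"]): float(e["delta"]) for e in d["effect_map"]
            }
        if "module_sizes" in d:
            d["module_sizes"] = tuple(d["module_sizes"])
        return cls(**d)


@dataclass
class SubjectRecord:
    """One participant: time series, motion trace, metabolites, clinical
    scores, group label, and the planted ground truth used by tests."""

    subject_id: str
    group: str  # "patient" | "control"
    timeseries: np.ndarray  # T x N
    motion: np.ndarray  # T x 6 (mm, mm, mm, deg, deg, deg)
    metabolites: list[MetaboliteRecord]
    clinical: dict[str, float] | None
    truth: dict[str, float | bool]


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    region_labels: list[str]
    module_names: tuple[str, ...]
    planted_assignment: np.ndarray
    config: SyntheticConfig

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]


@dataclass
class PlantedCovariance:
    values: np.ndarray
    repaired: bool
    frobenius_change: float


def _effect_ids(
    effects: Mapping[tuple[str, str], float], names: Sequence[str]
) -> dict[tuple[int, int], float]:
    index = {n: i for i, n in enumerate(names)}
    out: dict[tuple[int, int], float] = {}
    for (a, b), delta in effects.items():
        if a not in index or b not in index:
            raise ValueError(f"unknown module in effect key ({a}, {b})")
        i, j = sorted((index[a], index[b]))
        out[(i, j)] = out.get((i, j), 0.0) + float(delta)
    return out


def planted_covariance(
    assignment: np.ndarray,
    r_intra: float | Sequence[float],
    r_inter: float,
    effect_deltas: Mapping[tuple[int, int], float] | None = None,
    *,
    min_eig: float = 1e-8,
) -> PlantedCovariance:
    """Block-structured correlation matrix with optional module-pair deltas.

    Entry (i, j) is ``r_intra[m] + delta`` when both nodes sit in module m and
    ``r_inter + delta`` otherwise, with a unit diagonal.  If the raw matrix is
    not positive semidefinite it is repaired by eigenvalue clipping at
    ``min_eig`` followed by diagonal renormalization; the Frobenius distance
    of the repair is reported rather than silently discarded.
    """
    assignment = np.asarray(assignment, dtype=np.intp)
    if assignment.ndim != 1:
        raise ValueError("assignment must be a 1-D module-id array")
    n = assignment.size
    n_mod = int(assignment.max()) + 1 if n else 0
    intra = np.broadcast_to(np.atleast_1d(np.asarray(r_intra, float)), (n_mod,)) \
        if np.ndim(r_intra) == 0 else np.asarray(r_intra, float)
    if intra.shape != (n_mod,):
        raise ValueError(f"r_intra must be scalar or length {n_mod}")

    same = assignment[:, None] == assignment[None, :]
    corr = np.where(same, intra[assignment][:, None], float(r_inter)).astype(float)
    if effect_deltas:
        for (a, b), delta in effect_deltas.items():
            if not (0 <= a < n_mod and 0 <= b < n_mod):
                raise ValueError(f"unknown module id in delta key ({a}, {b})")
            block = (assignment[:, None] == a) & (assignment[None, :] == b)
            block = block | block.T
            if a == b:
                block &= ~np.eye(n, dtype=bool)
            corr[block] += float(delta)
    np.fill_diagonal(corr, 1.0)

    off = corr[~np.eye(n, dtype=bool)]
    if off.size and np.max(np.abs(off)) >= 1.0:
        raise ValueError("a planted delta pushes |correlation| >= 1")

    eigval = np.linalg.eigvalsh(corr)
    if eigval[0] >= 0:
        return PlantedCovariance(corr, repaired=False, frobenius_change=0.0)

    w, v = np.linalg.eigh(corr)
    w = np.clip(w, min_eig, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return PlantedCovariance(
        fixed, repaired=True,
        frobenius_change=float(np.linalg.norm(fixed - corr)),
    )


def _smooth_walk(
    rng: np.random.Generator, n: int, k: int = 11, detrend_k: int = 41
) -> np.ndarray:
    """Smooth, mean-reverting random walk (arbitrary scale) starting at 0.

    A Hann-smoothed random walk with its slow drift (moving average over
    ``detrend_k`` volumes) removed: frame-to-frame motion is preserved while
    the overall excursion stays bounded, as for a head resting in padding.
    """
    steps = rng.normal(size=n + k)
    kernel = np.hanning(k)
    kernel /= kernel.sum()
    smoothed = np.convolve(steps, kernel, mode="same")[:n]
    walk = np.cumsum(smoothed)
    slow_kernel = np.hanning(detrend_k)
    slow_kernel /= slow_kernel.sum()
    pad = detrend_k // 2
    padded = np.pad(walk, pad, mode="edge")
    walk = walk - np.convolve(padded, slow_kernel, mode="same")[pad:pad + n]
    return walk - walk[0]

def _synth_motion(
    rng: np.random.Generator, n_t: int, outlier: bool
) -> np.ndarray:
    """T x 6 rigid-body trace (translations mm, rotations deg).

    Smooth random walks are jointly rescaled so the subject's mean framewise
    displacement lands on a target drawn from an arcsine law on 0.04-0.12 mm.
    The bounded, bathtub-shaped severity distribution keeps the across-subject
    SD large relative to the gap between its mean and upper bound, so the
    group-relative mean-FD exclusion rule (mean + 2 SD) almost never fires on
    a clean subject.  Planted outliers additionally get one translation axis
    rescaled to peak between 2.8 and 4 mm, violating the absolute rule.
    """
    from .qc import framewise_displacement

    rel = np.concatenate([
        rng.uniform(0.5, 1.0, size=3),   # translations, relative
        rng.uniform(0.2, 0.5, size=3),   # rotations, deg-scale relative
    ])
    cols = []
    for c in range(6):
        walk = _smooth_walk(rng, n_t)
        top = np.max(np.abs(walk))
        cols.append(walk * (rel[c] / top if top > 0 else 0.0))
    trace = np.column_stack(cols)
    target_fd = 0.04 + 0.08 * rng.beta(0.5, 0.5)
    mean_fd = framewise_displacement(trace).mean()
    if mean_fd > 0:
        trace *= target_fd / mean_fd  # FD is ~linear in scale at small angles
    max_trans = np.max(np.abs(trace[:, :3]))
    if max_trans > 2.0:  # safety margin below the 2.5 mm exclusion rule
        trace *= 2.0 / max_trans
    if outlier:
        axis = rng.integers(0, 3)
        peak = rng.uniform(2.8, 4.0)
        top = np.max(np.abs(trace[:, axis]))
        trace[:, axis] *= peak / top if top > 0 else 0.0
    return trace


def _metabolites(
    rng: np.random.Generator,
    *,
    group: str,
    eta_fc: float,
    cfg: SyntheticConfig,
    crlb_outlier: bool,
) -> list[MetaboliteRecord]:
    f_gm = rng.uniform(0.55, 0.70)
    f_csf = rng.uniform(0.05, 0.15)
    f_wm = 1.0 - f_gm - f_csf
    marginal_sd = float(np.hypot(cfg.coupling_slope * cfg.coupling_sd,
                                 cfg.coupling_noise_sd))
    if group == "control":
        naa = cfg.naa_base + cfg.coupling_slope * eta_fc \
            + rng.normal(0.0, cfg.coupling_noise_sd)
    else:  # decoupled, variance-matched
        naa = cfg.naa_base + rng.normal(0.0, marginal_sd)
    gaba = 2.0 + rng.normal(0.0, 0.25)
    glx = 10.0 + rng.normal(0.0, 1.2)
    if crlb_outlier:
        crlbs = rng.uniform(25.0, 50.0, size=3)
    else:
        crlbs = np.array([
            rng.uniform(2.0, 9.0),    # NAA
            rng.uniform(8.0, 19.0),   # GABA+
            rng.uniform(4.0, 14.0),   # Glx
        ])
    return [
        MetaboliteRecord("NAA", float(naa), float(crlbs[0]), f_gm, f_wm, f_csf),
        MetaboliteRecord("GABA+", float(gaba), float(crlbs[1]), f_gm, f_wm, f_csf),
        MetaboliteRecord("Glx", float(glx), float(crlbs[2]), f_gm, f_wm, f_csf),
    ]


def _clinical(
    rng: np.random.Generator, z_fc: float, z_fh: float, cfg: SyntheticConfig
) -> dict[str, float]:
    w_fc = float(cfg.clinical_coupling.get("fp_central", 0.0))
    w_fh = float(cfg.clinical_coupling.get("fp_hippocampal", 0.0))
    w_res = float(np.sqrt(max(0.0, 1.0 - w_fc**2 - w_fh**2)))
    gen = 39.2 + 5.3 * (w_fc * z_fc + w_fh * z_fh + w_res * rng.normal())
    pos = 22.4 + 5.8 * rng.normal()
    neg = 20.2 + 5.9 * rng.normal()
    pos = float(np.clip(round(pos), 7, 49))
    neg = float(np.clip(round(neg), 7, 49))
    gen = float(np.clip(round(gen), 16, 112))
    cgi = float(np.clip(round(rng.normal(5.0, 0.88)), 1, 7))
    return {
        "panss_pos": pos,
        "panss_neg": neg,
        "panss_gen": gen,
        "panss_total": pos + neg + gen,
        "cgi": cgi,
    }


def generate_cohort(config: SyntheticConfig | None = None) -> Cohort:
    """Draw a full synthetic cohort from ``config`` (all randomness flows from
    ``config.seed``; the same seed yields a bit-identical cohort).

    The recruited pool is ``n_patients + motion_outlier_patients +
    crlb_outlier_patients`` patients and ``n_controls +
    motion_outlier_controls`` controls, so that the default QC filters retain
    exactly ``n_patients`` / ``n_controls`` subjects.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    names = cfg.module_names
    assignment = cfg.planted_assignment()
    group_effects = {
        "patient": _effect_ids(cfg.effect_map, names),
        "control": {},
    }
    block_ids = _effect_ids(dict.fromkeys(_COUPLING_BLOCKS, 0.0), names) \
        if all(a in names and b in names for a, b in _COUPLING_BLOCKS) else {}
    coupling_keys = list(block_ids)

    pool = (
        [("patient", False, False)] * cfg.n_patients
        + [("patient", True, False)] * cfg.motion_outlier_patients
        + [("patient", False, True)] * cfg.crlb_outlier_patients
        + [("control", False, False)] * cfg.n_controls
        + [("control", True, False)] * cfg.motion_outlier_controls
    )
    # Shuffle within group so planted outliers do not occupy fixed slots.
    n_pat = cfg.n_patients + cfg.motion_outlier_patients + cfg.crlb_outlier_patients
    patients = [pool[i] for i in rng.permutation(n_pat)]
    controls = [pool[n_pat + i] for i in rng.permutation(len(pool) - n_pat)]

    subjects: list[SubjectRecord] = []
    for group_list, prefix in ((patients, "P"), (controls, "C")):
        for idx, (group, motion_out, crlb_out) in enumerate(group_list, start=1):
            etas = {key: float(rng.normal(0.0, cfg.coupling_sd))
                    for key in coupling_keys}
            deltas = dict(group_effects[group])
            for key, eta in etas.items():
                deltas[key] = deltas.get(key, 0.0) + eta
            planted = planted_covariance(
                assignment, cfg.r_intra, cfg.r_inter, deltas
            )
            chol = np.linalg.cholesky(
                planted.values + 1e-10 * np.eye(cfg.n_regions)
            )
            latent = rng.normal(size=(cfg.n_timepoints, cfg.n_regions)) @ chol.T
            ts = latent + cfg.obs_noise_sd * rng.normal(
                size=(cfg.n_timepoints, cfg.n_regions)
            )
            motion = _synth_motion(rng, cfg.n_timepoints, motion_out)

            index = {n: i for i, n in enumerate(names)}
            def _eta(a: str, b: str) -> float:
                i, j = sorted((index[a], index[b])) if a in index and b in index \
                    else (-1, -1)
                return etas.get((i, j), 0.0)

            eta_fc = _eta("Frontoparietal", "Central")
            eta_fh = _eta("Frontoparietal", "Hippocampal")
            eta_fp = _eta("Frontoparietal", "Frontoparietal")
            mets = _metabolites(
                rng, group=group, eta_fc=eta_fc, cfg=cfg, crlb_outlier=crlb_out
            )
            clinical = None
            if group == "patient":
                sd = cfg.coupling_sd if cfg.coupling_sd > 0 else 1.0
                clinical = _clinical(rng, eta_fc / sd, eta_fh / sd, cfg)
            subjects.append(SubjectRecord(
                subject_id=f"sub-{prefix}{idx:02d}",
                group=group,
                timeseries=ts,
                motion=motion,
                metabolites=mets,
                clinical=clinical,
                truth={
                    "motion_outlier": motion_out,
                    "crlb_outlier": crlb_out,
                    "fp_central": cfg.r_inter
                    + group_effects[group].get(
                        tuple(sorted((index.get("Frontoparietal", -1),
                                      index.get("Central", -2)))), 0.0)
                    + eta_fc,
                    "fp_hippocampal": cfg.r_inter
                    + group_effects[group].get(
                        tuple(sorted((index.get("Frontoparietal", -1),
                                      index.get("Hippocampal", -2)))), 0.0)
                    + eta_fh,
                    "fp_intra": cfg.r_intra
                    + group_effects[group].get(
                        (index.get("Frontoparietal", -1),) * 2, 0.0)
                    + eta_fp,
                    "covariance_repaired": planted.repaired,
                },
            ))
            if planted.repaired and planted.frobenius_change > 0.05:
                warnings.warn(
                    f"planted covariance for {subjects[-1].subject_id} needed "
                    f"a PSD repair of Frobenius size "
                    f"{planted.frobenius_change:.3g}",
                    stacklevel=2,
                )

    return Cohort(
        subjects=subjects,
        region_labels=cfg.region_labels,
        module_names=names,
        planted_assignment=assignment,
        config=cfg,
    )
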
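"""Cohort directory layout: plain-text serialization of a synthetic cohort.

Layout::

    DIR/
      manifest.json            subjects, group labels, file paths, seed, config
      metabolites.csv          subject_id, metabolite, concentration, crlb_percent,
                               f_gm, f_wm, f_csf
      clinical.csv             subject_id, panss_pos, panss_neg, panss_gen,
                               panss_total, cgi   (patients only)
      timeseries/<id>.tsv      T rows x N regions, header = region labels
      motion/<id>.tsv          T rows x 6, header = trans/rot parameter names

Motion rows cover the retained volumes only; the number of initially
discarded volumes is declared in the manifest rather than re-applied here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .qc import MetaboliteRecord
from .synthetic import Cohort, SubjectRecord, SyntheticConfig

__all__ = ["write_cohort", "read_cohort", "MOTION_COLUMNS"]

MOTION_COLUMNS = [
    "trans_x_mm", "trans_y_mm", "trans_z_mm",
    "rot_x_deg", "rot_y_deg", "rot_z_deg",
]

_MANIFEST_SCHEMA = "modcoupling-cohort/1"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Serialize a cohort to ``out_dir``; returns the directory path."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(exist_ok=True)

    subjects_meta, met_rows, clin_rows = [], [], []
    truth = {}
    for s in cohort.subjects:
        ts_rel = f"timeseries/{s.subject_id}.tsv"
        mo_rel = f"motion/{s.subject_id}.tsv"
        pd.DataFrame(s.timeseries, columns=cohort.region_labels).to_csv(
            out / ts_rel, sep="\t", index=False, float_format="%.6f"
        )
        pd.DataFrame(s.motion, columns=MOTION_COLUMNS).to_csv(
            out / mo_rel, sep="\t", index=False, float_format="%.6f"
        )
        subjects_meta.append({
            "subject_id": s.subject_id, "group": s.group,
            "timeseries": ts_rel, "motion": mo_rel,
        })
        truth[s.subject_id] = s.truth
        for m in s.metabolites:
            met_rows.append({
                "subject_id": s.subject_id, "metabolite": m.metabolite,
                "concentration": m.concentration, "crlb_percent": m.crlb,
                "f_gm": m.f_gm, "f_wm": m.f_wm, "f_csf": m.f_csf,
            })
        if s.clinical is not None:
            clin_rows.append({"subject_id": s.subject_id, **s.clinical})

    pd.DataFrame(met_rows).to_csv(out / "metabolites.csv", index=False)
    pd.DataFrame(clin_rows).to_csv(out / "clinical.csv", index=False)
    manifest = {
        "schema": _MANIFEST_SCHEMA,
        "seed": cohort.config.seed,
        "config": cohort.config.to_dict(),
        "discarded_volumes": 10,
        "motion_rows_include_discarded": False,
        "region_labels": cohort.region_labels,
        "module_names": list(cohort.module_names),
        "planted_assignment": cohort.planted_assignment.tolist(),
        "subjects": subjects_meta,
        "truth": truth,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def read_cohort(cohort_dir: str | Path) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    if manifest.get("schema") != _MANIFEST_SCHEMA:
        raise ValueError(f"unrecognized cohort schema {manifest.get('schema')!r}")
    config = SyntheticConfig.from_dict(manifest["config"])
    mets = pd.read_csv(root / "metabolites.csv")
    clin_path = root / "clinical.csv"
    clinical = pd.read_csv(clin_path) if clin_path.exists() else pd.DataFrame()

    subjects = []
    for meta in manifest["subjects"]:
        sid = meta["subject_id"]
        ts = pd.read_csv(root / meta["timeseries"], sep="\t").to_numpy(float)
        motion = pd.read_csv(root / meta["motion"], sep="\t")[
            MOTION_COLUMNS
        ].to_numpy(float)
        recs = [
            MetaboliteRecord(
                metabolite=row["metabolite"],
                concentration=float(row["concentration"]),
                crlb=float(row["crlb_percent"]),
                f_gm=float(row["f_gm"]), f_wm=float(row["f_wm"]),
                f_csf=float(row["f_csf"]),
            )
            for _, row in mets[mets["subject_id"] == sid].iterrows()
        ]
        clin = None
        if len(clinical) and sid in set(clinical["subject_id"]):
            row = clinical[clinical["subject_id"] == sid].iloc[0]
            clin = {k: float(row[k]) for k in
                    ("panss_pos", "panss_neg", "panss_gen", "panss_total", "cgi")}
        subjects.append(SubjectRecord(
            subject_id=sid, group=meta["group"], timeseries=ts, motion=motion,
            metabolites=recs, clinical=clin,
            truth=manifest.get("truth", {}).get(sid, {}),
        ))
    return Cohort(
        subjects=subjects,
        region_labels=list(manifest["region_labels"]),
        module_names=tuple(manifest["module_names"]),
        planted_assignment=np.asarray(manifest["planted_assignment"], dtype=np.intp),
        config=config,
    )
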
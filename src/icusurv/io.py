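"""Cohort serialization.

A cohort round-trips through three files in a directory:

* ``cohort.csv`` — one row per subject: identifier, the 15 risk factors,
  SAPS-II score, the 14 finding labels, observed time/event and the
  generator's latent times and true log-relative-hazard.
* ``embeddings.npz`` — per-subject token-embedding matrices (``tok_<id>``)
  and image vectors (``img_<id>``), written only when embeddings exist.
* ``config.json`` — the :class:`~icusurv.synthetic.CohortConfig` provenance
  sidecar plus the calibrated censoring parameter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import findings
from .saps import RiskFactorVector
from .synthetic import Cohort, CohortConfig, SubjectRecord, SurvivalOutcome

__all__ = ["save_cohort", "load_cohort", "cohort_frame"]

_FACTOR_FIELDS = [f.name for f in dataclasses.fields(RiskFactorVector)]


def cohort_frame(cohort: Cohort) -> pd.DataFrame:
    """Tabular view of a cohort (no embeddings)."""
    rows = []
    for rec, psi in zip(cohort.records, cohort.true_psi):
        row = {"subject_id": rec.subject_id}
        for name in _FACTOR_FIELDS:
            row[name] = getattr(rec.risk_factors, name)
        row["saps_score"] = rec.saps_score
        for j, lab in enumerate(findings.LABELS):
            row[f"label_{lab}"] = int(rec.labels[j])
        row["time"] = rec.outcome.observed_time
        row["event"] = rec.outcome.event
        row["latent_event_time"] = rec.outcome.latent_event_time
        row["latent_censor_time"] = rec.outcome.latent_censor_time
        row["true_psi"] = float(psi)
        rows.append(row)
    return pd.DataFrame(rows)


def save_cohort(cohort: Cohort, directory: str | Path) -> Path:
    """Write cohort.csv, config.json and (if present) embeddings.npz."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # %.17g round-trips float64 exactly
    cohort_frame(cohort).to_csv(directory / "cohort.csv", index=False, float_format="%.17g")

    sidecar = {
        "config": dataclasses.asdict(cohort.config),
        "censor_log_median": cohort.censor_log_median,
    }
    (directory / "config.json").write_text(json.dumps(sidecar, indent=2))

    if cohort.config.include_embeddings:
        arrays = {}
        for rec in cohort.records:
            arrays[f"tok_{rec.subject_id}"] = rec.token_embeddings
            arrays[f"img_{rec.subject_id}"] = rec.image_embedding
        np.savez_compressed(directory / "embeddings.npz", **arrays)
    return directory


def load_cohort(directory: str | Path) -> Cohort:
    """Inverse of :func:`save_cohort`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "config.json").read_text())
    cfg_dict = sidecar["config"]
    for key in ("true_beta", "label_betas", "token_count_range"):
        if cfg_dict.get(key) is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    config = CohortConfig(**cfg_dict)
    df = pd.read_csv(directory / "cohort.csv", float_precision="round_trip")

    emb = None
    if config.include_embeddings:
        emb = np.load(directory / "embeddings.npz")

    records = []
    for _, row in df.iterrows():
        kwargs = {name: row[name] for name in _FACTOR_FIELDS}
        if pd.isna(kwargs["pao2_fio2_ratio"]):
            kwargs["pao2_fio2_ratio"] = None
        kwargs["gcs"] = int(kwargs["gcs"])
        factors = RiskFactorVector(**kwargs)
        labels = np.array([int(row[f"label_{lab}"]) for lab in findings.LABELS])
        sid = str(row["subject_id"])
        records.append(
            SubjectRecord(
                subject_id=sid,
                risk_factors=factors,
                saps_score=int(row["saps_score"]),
                labels=labels,
                token_embeddings=emb[f"tok_{sid}"] if emb is not None else None,
                image_embedding=emb[f"img_{sid}"] if emb is not None else None,
                outcome=SurvivalOutcome(
                    observed_time=float(row["time"]),
                    event=int(row["event"]),
                    latent_event_time=float(row["latent_event_time"]),
                    latent_censor_time=float(row["latent_censor_time"]),
                ),
            )
        )
    return Cohort(
        records=records,
        config=config,
        true_psi=df["true_psi"].to_numpy(),
        censor_log_median=float(sidecar["censor_log_median"]),
    )
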
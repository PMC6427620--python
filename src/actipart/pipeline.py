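"""End-to-end orchestration: ingest, validate wear, compute metrics, fit
all three model families per outcome, and write report tables.

The pipeline mirrors a cohort analysis workflow: label streams plus a
covariate/outcome table go in; out come a per-subject metrics table
(composition parts and the three partitioning indices per class-set), a
pairwise reallocation grid per outcome, compositional fits with
hypothetical-profile contrasts, partitioning-index fits, and a run log
with exclusion accounting.  All randomness flows from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import composition as comp
from . import models as mdl
from .streams import (
    BEHAVIORS,
    CLASS_SETS,
    behavior_composition,
    partitioning_indices,
    read_epoch_csv,
    read_events_csv,
    validate_wear,
)

__all__ = ["PipelineConfig", "ReportBundle", "covariate_reduce", "run_pipeline", "compute_metrics"]

#: hypothetical time-budget archetypes, percent (lie, sit, stand, LPA, MVPA)
DEFAULT_PROFILES = {
    "couch potato": (30, 50, 10, 5, 5),
    "office worker": (5, 70, 10, 5, 10),
    "doorman": (5, 15, 70, 5, 5),
    "active": (5, 40, 30, 5, 20),
}


@dataclass
class PipelineConfig:
    epoch_length_s: float = 1.0
    min_bout_s: float = 60.0
    purity: float = 0.8
    min_day_hours: float = 10.0
    min_valid_days: int = 4
    outcomes: dict = field(
        default_factory=lambda: {"outcome": False}  # name -> log-transform flag
    )
    covariates: list = field(
        default_factory=lambda: ["sex", "age", "income", "education", "nutrition1", "nutrition2"]
    )
    bmi_covariate: str | None = None  # column added as control except for adiposity outcomes
    adiposity_outcomes: tuple = ("bmi", "waist")
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    seed: int = 0

    def __post_init__(self):
        if self.min_bout_s <= 0 or self.min_day_hours <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset also parses JSON
        return cls(**data)


@dataclass
class ReportBundle:
    metrics: pd.DataFrame
    reallocation: dict  # outcome -> DataFrame (lower-triangular grid)
    compositional: pd.DataFrame
    profile_contrasts: pd.DataFrame
    partitioning: pd.DataFrame
    log: list

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "metrics.csv", index=False)
        for name, df in self.reallocation.items():
            df.to_csv(outdir / f"reallocation_{name}.csv", index=False)
        self.compositional.to_csv(outdir / "compositional.csv", index=False)
        self.profile_contrasts.to_csv(outdir / "profile_contrasts.csv", index=False)
        self.partitioning.to_csv(outdir / "partitioning.csv", index=False)
        bundle = {
            "log": self.log,
            "compositional": self.compositional.to_dict(orient="records"),
            "profile_contrasts": self.profile_contrasts.to_dict(orient="records"),
            "partitioning": self.partitioning.to_dict(orient="records"),
            "reallocation": {k: v.to_dict(orient="records") for k, v in self.reallocation.items()},
        }
        (outdir / "results.json").write_text(json.dumps(bundle, indent=2, default=float))
        (outdir / "run.log").write_text("\n".join(self.log) + "\n")


def covariate_reduce(habit_table: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Reduce a block of habit variables to its first two principal
    component scores ('nutritional index 1/2').

    Columns are standardized first; constant columns are dropped with a
    warning in the returned frame's attrs.
    """
    df = habit_table.select_dtypes(include=[np.number])
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValueError("need at least two numeric columns and three rows")
    sd = df.std(ddof=0)
    dropped = list(sd.index[sd == 0])
    df = df.drop(columns=dropped)
    Xs = (df - df.mean()) / df.std(ddof=0)
    scores = PCA(n_components=min(n_components, Xs.shape[1])).fit_transform(Xs.to_numpy())
    out = pd.DataFrame(
        scores, columns=[f"nutritional index {i + 1}" for i in range(scores.shape[1])],
        index=habit_table.index,
    )
    out.attrs["dropped_constant_columns"] = dropped
    return out


def compute_metrics(streams, config: PipelineConfig):
    """Wear-validate each stream and compute composition + partitioning
    indices for valid subjects.  Returns (metrics frame, log lines)."""
    rows, log = [], []
    n_in = len(streams)
    for stream in streams:
        filtered, report = validate_wear(
            stream, min_day_hours=config.min_day_hours, min_valid_days=config.min_valid_days
        )
        if not report.subject_valid:
            log.append(
                f"excluded subject {stream.subject_id}: "
                f"{len(report.valid_days)} valid day(s) < {config.min_valid_days}"
            )
            continue
        x = behavior_composition(filtered)
        row = {"subject_id": stream.subject_id, "n_valid_days": len(report.valid_days)}
        row.update({b.lower(): x[i] for i, b in enumerate(BEHAVIORS)})
        for set_name, cs in CLASS_SETS.items():
            try:
                pi = partitioning_indices(
                    filtered, cs, min_bout_s=config.min_bout_s, purity=config.purity
                )
            except ValueError:
                pi = None
            prefix = set_name.lower()
            row[f"{prefix}_median_bout_min"] = pi.median_bout_min if pi else np.nan
            row[f"{prefix}_gini"] = pi.gini if pi else np.nan
            row[f"{prefix}_ratio"] = pi.ratio_bout_total if pi else np.nan
        rows.append(row)
    metrics = pd.DataFrame(rows)
    log.insert(
        0,
        f"subjects_in={n_in} subjects_valid={len(rows)} subjects_excluded={n_in - len(rows)}",
    )
    return metrics, log


def _zero_replace_block(P: np.ndarray) -> np.ndarray:
    """Dataset-level multiplicative zero replacement: delta = half the
    smallest nonzero proportion observed anywhere in the table."""
    if not (P == 0).any():
        return P
    delta = 0.5 * P[P > 0].min()
    out = np.array([comp.multiplicative_replacement(row, delta) for row in P])
    return out


def run_pipeline(
    config: PipelineConfig,
    streams,
    subject_table: pd.DataFrame,
    outdir=None,
) -> ReportBundle:
    """Full analysis: wear validation, metrics, then the three model
    families per outcome.  ``subject_table`` holds one row per subject
    with covariate and outcome columns.  Deterministic given the config.
    """
    metrics, log = compute_metrics(streams, config)
    if metrics.empty:
        raise ValueError("zero valid subjects after wear validation; " + "; ".join(log))

    df = metrics.merge(subject_table, on="subject_id", how="inner")
    if df.empty:
        raise ValueError("no overlap between streams and subject table")
    log.append(f"subjects_modelled={len(df)}")

    part_cols = [b.lower() for b in BEHAVIORS]
    P = _zero_replace_block(df[part_cols].to_numpy(dtype=float))
    if (df[part_cols].to_numpy() == 0).any():
        log.append("zero-replacement applied to composition table")
    basis = comp.pivot_basis(len(BEHAVIORS))
    center = comp.closed_geometric_mean(P)

    realloc, comp_rows, contrast_rows, part_rows = {}, [], [], []
    for outcome, log_flag in config.outcomes.items():
        y = df[outcome].to_numpy(dtype=float)
        if log_flag:
            y = np.log(y)
        covs = list(config.covariates)
        if config.bmi_covariate and outcome not in config.adiposity_outcomes:
            covs.append(config.bmi_covariate)
        Z = df[covs].to_numpy(dtype=float) if covs else None

        M = mdl.reallocation_matrix(y, P, part_cols, Z)
        grid = pd.DataFrame(M.estimate, index=part_cols, columns=part_cols)
        grid.insert(0, "to_behavior", part_cols)
        realloc[outcome] = grid

        fit = mdl.fit_compositional_lm(y, P, Z, basis)
        comp_rows.append(
            {
                "outcome": outcome,
                "log_transformed": log_flag,
                "n": fit.n,
                "beta_norm": fit.beta_norm,
                "model_p": fit.model_p,
                **{f"dir_{b}": fit.beta_direction[i] for i, b in enumerate(part_cols)},
            }
        )
        for pname, pct in config.profiles.items():
            val = mdl.profile_contrast(fit, np.asarray(pct, float), center, log_outcome=log_flag)
            contrast_rows.append(
                {
                    "outcome": outcome,
                    "profile": pname,
                    "kind": "ratio" if log_flag else "difference",
                    "value": val,
                }
            )
        for set_name in CLASS_SETS:
            for index_name in ("median_bout_min", "gini", "ratio"):
                col = f"{set_name.lower()}_{index_name}"
                idx = df[col].to_numpy(dtype=float)
                if np.isfinite(idx).sum() < len(part_cols) + (0 if Z is None else Z.shape[1]) + 3:
                    continue
                try:
                    pf = mdl.fit_partitioning(y, idx, P, Z, quadratic="auto", basis=basis)
                except ValueError:
                    continue
                part_rows.append(
                    {
                        "outcome": outcome,
                        "class_set": set_name,
                        "index": index_name,
                        "coef": pf.coef_index,
                        "ci_low": pf.ci_index[0],
                        "ci_high": pf.ci_index[1],
                        "p": pf.p_index,
                        "tier": pf.tier_index,
                        "coef_sq": pf.coef_index_sq,
                        "quadratic": pf.quadratic_included,
                        "n": pf.n,
                        "n_dropped": pf.n_dropped,
                    }
                )

    bundle = ReportBundle(
        metrics=metrics,
        reallocation=realloc,
        compositional=pd.DataFrame(comp_rows),
        profile_contrasts=pd.DataFrame(contrast_rows),
        partitioning=pd.DataFrame(part_rows),
        log=log,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def load_streams(path, config: PipelineConfig):
    """Dispatch on CSV schema: epoch files have an 'epoch_index' column,
    event files a 'start_s' column."""
    head = pd.read_csv(path, nrows=0)
    if "epoch_index" in head.columns:
        return read_epoch_csv(path, config.epoch_length_s)
    if "start_s" in head.columns:
        return read_events_csv(path, config.epoch_length_s)
    raise ValueError("unrecognized stream CSV schema")
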
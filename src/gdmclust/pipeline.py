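"""End-to-end orchestration: simulate -> split -> fit/select -> validate ->
outcomes -> assign, plus the single-patient assignment procedure.

A run is driven by a :class:`RunConfig` and emits a report bundle: the fitted
model as JSON (scaler + centroids, sufficient to assign new patients with no
raw training data), the k-selection and gate audit, validation reports, and
Table-style cluster profiles.  Every random draw is attributable to a seed
recorded in the run manifest, and a rerun with the same config reproduces the
reports byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterModel, assign_nearest_centroid
from .outcomes import cluster_profile, compare_outcomes
from .preprocessing import add_derived_variables, split_train_test, standardize_apply
from .selection import DEFAULT_ROSTER, GateConfig, select_model
from .synthetic import (
    INPUT_VARIABLES,
    PLAUSIBLE_RANGES,
    CohortConfig,
    default_config,
    generate_cohort,
)
from .validation import external_validate, twofold_crossval

logger = logging.getLogger(__name__)

PACKAGE_VERSION = "0.1.0"


# --------------------------------------------------------------------------- #
# Cohort table I/O (CSV, header, UTF-8, "." decimal, empty cell = missing)
# --------------------------------------------------------------------------- #


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cohort(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


# --------------------------------------------------------------------------- #
# Patient assignment
# --------------------------------------------------------------------------- #


class RecordError(ValueError):
    """A patient record is missing a field or outside plausible ranges."""


def assign_patient(model: ClusterModel, record: dict) -> tuple[int, dict[int, float]]:
    """Assign one new patient to a cluster.

    ``record`` must provide age (years), bmipg (kg/m^2) and ogtt0/ogtt60/
    ogtt120 (mmol/l).  Values are checked against plausibility windows
    (age 12-60, BMI 12-70, OGTT 2-25) and refused — not coerced — when out of
    range or missing.  The record is standardised with the model's scaler and
    assigned to the nearest centroid under the model's distance; the distances
    to all centroids are returned for transparency.
    """
    for var in INPUT_VARIABLES:
        if var not in record or record[var] is None or record[var] != record[var]:
            raise RecordError(f"missing input variable {var!r}")
        lo, hi = PLAUSIBLE_RANGES[var]
        if not lo <= float(record[var]) <= hi:
            raise RecordError(
                f"{var}={record[var]} outside plausible range [{lo}, {hi}]"
            )
    row = pd.DataFrame([{v: float(record[v]) for v in INPUT_VARIABLES}])
    part = assign_nearest_centroid(model, row)
    Z = standardize_apply(add_derived_variables(row), model.scaling)
    z = Z.to_numpy(dtype=float)[0]
    if model.distance == "manhattan":
        dists = np.abs(model.centroids - z).sum(axis=1)
    else:
        dists = np.linalg.norm(model.centroids - z, axis=1)
    return int(part.labels[0]), {c + 1: float(d) for c, d in enumerate(dists)}


def assign_table(model: ClusterModel, table: pd.DataFrame) -> pd.DataFrame:
    """Row-wise batch assignment; returns the table with a ``cluster`` column."""
    part = assign_nearest_centroid(model, table)
    out = table.loc[part.index].copy()
    out["cluster"] = part.labels
    return out


# --------------------------------------------------------------------------- #
# PCA projection for cluster plots
# --------------------------------------------------------------------------- #


def pca_project(X, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Project a standardised matrix onto its first principal components.

    Returns (scores, explained variance fractions).  Requires matrix rank of
    at least ``n_components``.
    """
    from sklearn.decomposition import PCA

    M = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    if M.shape[1] < n_components:
        raise ValueError(f"need at least {n_components} columns")
    if np.linalg.matrix_rank(M - M.mean(axis=0)) < n_components:
        raise ValueError(f"matrix rank below {n_components}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(M)
    return scores, pca.explained_variance_ratio_


# --------------------------------------------------------------------------- #
# Run configuration and end-to-end execution
# --------------------------------------------------------------------------- #


@dataclass
class RunConfig:
    """Reproducible configuration of one full pipeline run."""

    out_dir: str = "gdmclust_run"
    n: int = 1154
    seed: int = 0
    variable_set: str = "full5"
    train_fraction: float = 0.7
    roster: tuple = DEFAULT_ROSTER
    gap_B: int = 50
    bootstrap_B: int = 100
    n_starts: int = 10
    jaccard_threshold: float = 0.75
    min_cluster_silhouette: float = 0.0
    outcome_columns: tuple[str, ...] = ()
    cohort_csv: str | None = None  # use an existing cohort instead of simulating

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roster"] = [list(r) for r in self.roster]
        d["outcome_columns"] = list(self.outcome_columns)
        return d


@dataclass
class RunBundle:
    config: RunConfig
    model: ClusterModel | None
    accepted: bool
    reports: dict = field(default_factory=dict)
    failure: dict | None = None


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, dict):
        return {str(k): v for k, v in obj.items()}
    return str(obj)


def _dump(obj, path: Path) -> None:
    def normalise(o):
        if isinstance(o, dict):
            return {str(k): normalise(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [normalise(v) for v in o]
        return o

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(normalise(obj), fh, indent=2, default=_json_default, sort_keys=True)


def run_end_to_end(
    config: RunConfig, cohort_config: CohortConfig | None = None
) -> RunBundle:
    """Execute the full pipeline and write the report bundle to ``out_dir``.

    Stages: cohort acquisition (simulate or load), 70/30 split, gated model
    selection on the training set, twofold cross-validation and bootstrap-
    backed gate audit, external validation on the held-out split, outcome
    comparison and cluster profiles.  A stage failure yields a bundle with
    partial results and a machine-readable failure record instead of raising.
    """
    if not config.roster:
        raise ValueError("empty algorithm roster")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest = {"config": config.to_dict(), "version": PACKAGE_VERSION}
    bundle = RunBundle(config=config, model=None, accepted=False)

    def stage(name):
        logger.info("stage %s done at +%.2fs", name, time.time() - t_start)

    try:
        if config.cohort_csv:
            cohort = read_cohort(config.cohort_csv)
        else:
            cc = cohort_config or default_config(n=config.n, seed=config.seed)
            cohort = generate_cohort(cc)
        stage("cohort")
        outcome_cols = list(config.outcome_columns) or [
            c
            for c in cohort.columns
            if c not in ("id", "site", "true_cluster", *INPUT_VARIABLES)
        ]
        train, test = split_train_test(cohort, config.train_fraction, seed=config.seed)
        stage("split")

        gates = GateConfig(
            jaccard_threshold=config.jaccard_threshold,
            min_cluster_silhouette=config.min_cluster_silhouette,
            bootstrap_B=config.bootstrap_B,
        )
        sel = select_model(
            train,
            config.variable_set,
            roster=tuple(tuple(r) for r in config.roster),
            gates=gates,
            gap_B=config.gap_B,
            n_starts=config.n_starts,
            seed=config.seed,
        )
        stage("select")
        bundle.reports["k_selection"] = sel.k_report.to_dict()
        bundle.reports["gate_audit"] = [dataclasses.asdict(a) for a in sel.audit]
        _dump(bundle.reports["k_selection"], out / "k_selection.json")
        _dump(bundle.reports["gate_audit"], out / "gate_audit.json")
        if not sel.accepted:
            bundle.failure = {
                "stage": "select",
                "reason": "no acceptable clustering under the configured gates",
            }
            _dump(manifest, out / "manifest.json")
            _dump(bundle.failure, out / "failure.json")
            return bundle
        model, part = sel.model, sel.partition
        bundle.model = model
        bundle.accepted = True
        model.save(out / "model.json")

        cv = twofold_crossval(
            train, model, part.labels, outcome_columns=outcome_cols, seed=config.seed
        )
        bundle.reports["crossval"] = dataclasses.asdict(cv)
        _dump(bundle.reports["crossval"], out / "crossval.json")
        stage("crossval")

        ext = external_validate(model, test, seed=config.seed)
        bundle.reports["external_validation"] = {
            "mapping": ext.mapping,
            "cluster_jaccard": ext.cluster_jaccard,
            "ari": ext.ari,
            "accuracy": ext.accuracy,
            "proportion_chi2_p": ext.proportion_chi2_p,
            "transfer_only": ext.transfer_only,
        }
        _dump(bundle.reports["external_validation"], out / "external_validation.json")
        stage("external")

        comparisons = compare_outcomes(train, part.labels, outcome_cols, seed=config.seed)
        bundle.reports["outcomes"] = {
            name: dataclasses.asdict(c) for name, c in comparisons.items()
        }
        _dump(bundle.reports["outcomes"], out / "outcomes.json")
        profile = cluster_profile(train, part.labels, [*model.scaling.variables, *outcome_cols])
        profile.formatted.to_csv(out / "cluster_profile.csv")
        bundle.reports["profile"] = profile
        stage("outcomes")

        _dump(manifest, out / "manifest.json")
        return bundle
    except Exception as err:  # partial-results contract
        logger.exception("pipeline stage failed")
        bundle.failure = {"stage": "unknown", "error": str(err)}
        _dump(manifest, out / "manifest.json")
        _dump(bundle.failure, out / "failure.json")
        return bundle
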
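"""Train/test partitioning, input-variable-set selection and standardisation.

The five clustering inputs live on incommensurate scales (years, kg/m^2,
mmol/l), so all distance computations downstream operate on z-scores whose
centre and scale are learned on training data only and carried inside the
fitted model — the nearest-centroid assignment rule requires test records and
centroids to share one standardised space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """A selected input variable is constant on the training data."""


@dataclass(frozen=True)
class VariableSet:
    """A named roster of clustering input variables.

    ``age-bmi-meanOGTT`` replaces the three OGTT samples with their arithmetic
    mean (computed on the raw mmol/l scale, before standardisation).
    """

    id: str
    variables: tuple[str, ...]


VARIABLE_SETS: dict[str, VariableSet] = {
    "full5": VariableSet("full5", ("age", "bmipg", "ogtt0", "ogtt60", "ogtt120")),
    "no-age": VariableSet("no-age", ("bmipg", "ogtt0", "ogtt60", "ogtt120")),
    "age-bmi-meanOGTT": VariableSet("age-bmi-meanOGTT", ("age", "bmipg", "ogtt_mean")),
    "age-bmi-fasting": VariableSet("age-bmi-fasting", ("age", "bmipg", "ogtt0")),
}


def get_variable_set(variable_set: str | VariableSet) -> VariableSet:
    if isinstance(variable_set, VariableSet):
        return variable_set
    try:
        return VARIABLE_SETS[variable_set]
    except KeyError:
        raise ValueError(
            f"unknown variable set {variable_set!r}; choose from {sorted(VARIABLE_SETS)}"
        ) from None


def add_derived_variables(table: pd.DataFrame) -> pd.DataFrame:
    """Add ``ogtt_mean`` (raw-scale arithmetic mean of the three OGTT values)."""
    out = table.copy()
    if {"ogtt0", "ogtt60", "ogtt120"}.issubset(out.columns):
        out["ogtt_mean"] = out[["ogtt0", "ogtt60", "ogtt120"]].mean(axis=1)
    return out


def split_train_test(
    table: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random, disjoint, exhaustive row split.

    The training share takes ``floor(n * train_fraction)`` rows; the remainder
    goes to the test set.  Reproducible from ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * train_fraction))
    train = table.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = table.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return train, test


@dataclass(frozen=True)
class ScalingParams:
    """Per-variable centre (training mean) and scale (training SD, ddof=1)."""

    variables: tuple[str, ...]
    center: tuple[float, ...]
    scale: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "center": list(self.center),
            "scale": list(self.scale),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingParams":
        return cls(
            tuple(d["variables"]),
            tuple(float(x) for x in d["center"]),
            tuple(float(x) for x in d["scale"]),
        )


def standardize_fit(
    train: pd.DataFrame, variable_set: str | VariableSet = "full5"
) -> ScalingParams:
    """Learn z-score parameters (mean, SD with denominator n-1) on training data."""
    vs = get_variable_set(variable_set)
    table = add_derived_variables(train)
    missing_cols = [v for v in vs.variables if v not in table.columns]
    if missing_cols:
        raise ValueError(f"training table lacks input variables {missing_cols}")
    X = table[list(vs.variables)]
    if X.isna().any().any():
        raise ValueError("missing values in input variables; complete cases required")
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    for v in vs.variables:
        if not scale[v] > 0:
            raise ZeroVarianceError(f"input variable {v!r} has zero variance")
    return ScalingParams(
        vs.variables,
        tuple(float(center[v]) for v in vs.variables),
        tuple(float(scale[v]) for v in vs.variables),
    )


def standardize_apply(table: pd.DataFrame, params: ScalingParams) -> pd.DataFrame:
    """Apply z-scoring columnwise; rows with missing inputs are dropped and logged.

    Returns a DataFrame of z-values indexed like the (retained rows of the)
    input table, columns in the params' variable order.
    """
    full = add_derived_variables(table)
    missing_cols = [v for v in params.variables if v not in full.columns]
    if missing_cols:
        raise ValueError(f"table lacks input variables {missing_cols}")
    X = full[list(params.variables)]
    complete = ~X.isna().any(axis=1)
    if not complete.all():
        dropped = X.index[~complete].tolist()
        logger.warning("dropping %d rows with missing inputs: %s", len(dropped), dropped[:20])
        X = X.loc[complete]
    center = np.asarray(params.center)
    scale = np.asarray(params.scale)
    return (X - center) / scale


def destandardize(Z: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Inverse of :func:`standardize_apply` on a plain array."""
    return np.asarray(Z, dtype=float) * np.asarray(params.scale) + np.asarray(params.center)
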
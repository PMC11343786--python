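"""Synthetic GDM cohort generation.

Builds cohorts with a three-subgroup latent structure that mirrors the published
cluster profiles of a gestational-diabetes population: five routine clinical
input variables (maternal age, pre-pregnancy BMI, and OGTT glucose at 0/60/120
minutes), cluster-conditional binary pregnancy outcomes, and per-outcome
missingness.  Every marginal distribution is calibrated so that its quartiles
reproduce a target (Q1, median, Q3) triple exactly, and every generated row
satisfies the IADPSG diagnostic rule for GDM (fasting >= 5.1, 60 min >= 10 or
120 min >= 8.5 mmol/l), enforced by rejection sampling.

The default configuration carries the training-set cluster profiles of the
reference population (n=1154; cluster proportions 246/407/501) so that the
whole downstream pipeline — clustering, model selection, validation gates,
outcome statistics — can be exercised without access to any patient data.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------- #
# Constants
# --------------------------------------------------------------------------- #

#: The five routine clinical input variables, in canonical column order.
INPUT_VARIABLES = ["age", "bmipg", "ogtt0", "ogtt60", "ogtt120"]

#: IADPSG diagnostic cut-offs (mmol/l); GDM iff at least one is reached.
GDM_THRESHOLDS = {"ogtt0": 5.1, "ogtt60": 10.0, "ogtt120": 8.5}

#: Plausibility windows for generated / assigned values (units of the variable).
PLAUSIBLE_RANGES = {
    "age": (12.0, 60.0),
    "bmipg": (12.0, 70.0),
    "ogtt0": (2.0, 25.0),
    "ogtt60": (2.0, 25.0),
    "ogtt120": (2.0, 25.0),
}

_Z75 = float(stats.norm.ppf(0.75))  # 0.6744897501960817

# Per-cluster (Q1, median, Q3) calibration targets for the input variables,
# training-set profiles of the reference GDM population.  Cluster 1: obese,
# hyperglycaemic throughout the OGTT; cluster 2: elevated fasting glucose only;
# cluster 3: normal BMI, post-load hyperglycaemia.
TRAINING_QUARTILES: dict[int, dict[str, tuple[float, float, float]]] = {
    1: {
        "age": (30.25, 34.0, 37.0),
        "bmipg": (27.90, 32.30, 38.70),
        "ogtt0": (5.61, 5.99, 6.44),
        "ogtt60": (10.66, 11.60, 12.81),
        "ogtt120": (7.71, 8.66, 10.27),
    },
    2: {
        "age": (28.0, 33.0, 37.0),
        "bmipg": (23.25, 27.70, 32.85),
        "ogtt0": (5.22, 5.33, 5.61),
        "ogtt60": (7.19, 8.16, 9.10),
        "ogtt120": (5.52, 6.22, 6.94),
    },
    3: {
        "age": (30.0, 34.0, 38.0),
        "bmipg": (22.00, 24.90, 28.00),
        "ogtt0": (4.66, 5.05, 5.33),
        "ogtt60": (9.71, 10.32, 11.16),
        "ogtt120": (7.21, 8.32, 9.16),
    },
}

#: Training-set cluster sizes of the reference population.
TRAINING_CLUSTER_SIZES = (246, 407, 501)

#: Mixing proportions implied by the reference cluster sizes (sum to 1).
TRAINING_PROPORTIONS = tuple(s / sum(TRAINING_CLUSTER_SIZES) for s in TRAINING_CLUSTER_SIZES)

# Cluster-conditional binary outcome counts (numerator, available-case
# denominator) per cluster, training-set profiles.  Rates are numerator/denom.
TRAINING_OUTCOME_COUNTS: dict[str, tuple[tuple[int, int], ...]] = {
    "drugs_prescribed": ((84, 212), (47, 364), (44, 440)),
    "preeclampsia": ((18, 246), (27, 407), (21, 500)),
    "lga": ((75, 246), (91, 406), (110, 501)),
    "sga": ((15, 246), (32, 406), (39, 501)),
    "birthweight_gt4000": ((46, 233), (47, 389), (62, 472)),
}

# Per-outcome missingness implied by available-case totals over n=1154.
TRAINING_OUTCOME_NTOT = {
    "drugs_prescribed": 1016,
    "preeclampsia": 1153,
    "lga": 1153,
    "sga": 1153,
    "birthweight_gt4000": 1094,
}


class ConfigInfeasibleError(ValueError):
    """The generator configuration cannot satisfy the diagnostic constraint."""


# --------------------------------------------------------------------------- #
# Quantile-matched marginal distributions
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class DistributionSpec:
    """A univariate marginal pinned to three target quartiles.

    Two families are supported.  A three-parameter (shifted) log-normal is used
    when the quartile triple is right-skewed (``q1 + q3 > 2*median``), which is
    the typical shape of BMI and OGTT glucose; its shift, log-location and
    log-scale are solved in closed form so that the 25/50/75% quantiles equal
    the targets exactly.  A normal is used in the symmetric case, and as a
    flagged fallback when the skewed solution is infeasible (left-skewed
    triples put the required shift above Q1).

    Parameters are in the units of the target variable.
    """

    family: str  # "normal" | "shifted-lognormal"
    target_q1: float
    target_median: float
    target_q3: float
    mean: float = math.nan  # normal family
    sd: float = math.nan
    shift: float = math.nan  # shifted-lognormal family
    mu: float = math.nan
    sigma: float = math.nan
    fallback: bool = False  # True when normal was used because the skewed fit was infeasible

    def quantile(self, p):
        """Inverse CDF, vectorised over ``p``."""
        z = stats.norm.ppf(p)
        if self.family == "normal":
            return self.mean + self.sd * z
        return self.shift + np.exp(self.mu + self.sigma * z)

    def cdf(self, x):
        if self.family == "normal":
            return stats.norm.cdf(x, loc=self.mean, scale=self.sd)
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        above = x > self.shift
        out[above] = stats.norm.cdf((np.log(x[above] - self.shift) - self.mu) / self.sigma)
        return out

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "normal":
            return rng.normal(self.mean, self.sd, size)
        return self.shift + rng.lognormal(self.mu, self.sigma, size)


def fit_quantile_distribution(
    q1: float, median: float, q3: float, *, symmetry_tol: float = 1e-9
) -> DistributionSpec:
    """Fit a :class:`DistributionSpec` reproducing three quartiles exactly.

    The shifted log-normal branch solves the shift as
    ``c = (q1*q3 - median**2) / (q1 + q3 - 2*median)``, which makes
    ``(q1-c)*(q3-c) = (median-c)**2`` hold identically, so the residual
    quartiles are log-symmetric and the log-scale follows from the half
    log-IQR.  Symmetric triples (and infeasible left-skewed ones) use a normal
    with ``sd = IQR / (2 * z_0.75)``.

    Raises
    ------
    ValueError
        If the quartiles are not strictly increasing.
    """
    if not (q1 < median < q3):
        raise ValueError(f"quartiles must satisfy q1 < median < q3, got ({q1}, {median}, {q3})")
    span = q3 - q1
    asym = (q1 + q3) - 2.0 * median
    normal_sd = span / (2.0 * _Z75)
    if abs(asym) <= symmetry_tol * span:
        return DistributionSpec(
            "normal", q1, median, q3, mean=float(median), sd=float(normal_sd)
        )
    if asym > 0:
        shift = (q1 * q3 - median * median) / asym
        if shift < q1:  # always true analytically for right-skew; numeric guard
            mu = math.log(median - shift)
            sigma = (math.log(q3 - shift) - mu) / _Z75
            return DistributionSpec(
                "shifted-lognormal",
                q1,
                median,
                q3,
                shift=float(shift),
                mu=float(mu),
                sigma=float(sigma),
            )
    # Left-skewed (or numerically infeasible) triple: the required shift sits at
    # or above Q1, so the log-normal support cannot cover the targets.
    logger.warning(
        "quartiles (%s, %s, %s) infeasible for shifted log-normal; normal fallback", q1, median, q3
    )
    return DistributionSpec(
        "normal", q1, median, q3, mean=float(median), sd=float(normal_sd), fallback=True
    )


# --------------------------------------------------------------------------- #
# Cohort configuration
# --------------------------------------------------------------------------- #


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort.

    ``variables`` maps 1-based cluster index to a variable -> DistributionSpec
    map; ``outcome_rates`` gives the per-cluster Bernoulli rate of each binary
    outcome; ``missingness`` the independent per-outcome missing probability.
    ``correlation``, if given, is a p x p within-cluster Gaussian-copula
    correlation matrix over the input variables (identity = independence,
    the default).
    """

    n: int
    mixing_proportions: tuple[float, ...]
    variables: dict[int, dict[str, DistributionSpec]]
    outcome_rates: dict[str, tuple[float, ...]] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    site: str = "synthetic"
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        props = np.asarray(self.mixing_proportions, dtype=float)
        if abs(props.sum() - 1.0) > 1e-12:
            raise ValueError(f"mixing proportions must sum to 1, got {props.sum()!r}")
        if (props < 0).any():
            raise ValueError("mixing proportions must be non-negative")
        k = len(props)
        if set(self.variables) != set(range(1, k + 1)):
            raise ValueError("variables must be keyed by clusters 1..k")
        for name, rates in self.outcome_rates.items():
            r = np.asarray(rates, dtype=float)
            if len(r) != k or (r < 0).any() or (r > 1).any():
                raise ValueError(f"outcome {name!r}: need {k} rates in [0,1]")
        for name, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {name!r} outside [0,1]")

    @property
    def k(self) -> int:
        return len(self.mixing_proportions)

    @property
    def outcome_names(self) -> list[str]:
        return list(self.outcome_rates)


def default_config(n: int = 1154, seed: int = 0) -> CohortConfig:
    """The reference-population configuration (training-set calibration)."""
    variables = {
        c: {v: fit_quantile_distribution(*q) for v, q in TRAINING_QUARTILES[c].items()}
        for c in (1, 2, 3)
    }
    n_ref = sum(TRAINING_CLUSTER_SIZES)
    outcome_rates = {
        name: tuple(num / den for num, den in counts)
        for name, counts in TRAINING_OUTCOME_COUNTS.items()
    }
    missingness = {
        name: 1.0 - ntot / n_ref for name, ntot in TRAINING_OUTCOME_NTOT.items()
    }
    return CohortConfig(
        n=n,
        mixing_proportions=TRAINING_PROPORTIONS,
        variables=variables,
        outcome_rates=outcome_rates,
        missingness=missingness,
        seed=seed,
    )


# --------------------------------------------------------------------------- #
# Generation
# --------------------------------------------------------------------------- #


def _is_gdm(rows: pd.DataFrame) -> np.ndarray:
    """Row mask: satisfies the IADPSG rule (any threshold reached)."""
    mask = np.zeros(len(rows), dtype=bool)
    for var, thr in GDM_THRESHOLDS.items():
        mask |= rows[var].to_numpy() >= thr
    return mask


def _in_plausible_range(rows: pd.DataFrame, variables: list[str]) -> np.ndarray:
    mask = np.ones(len(rows), dtype=bool)
    for var in variables:
        lo, hi = PLAUSIBLE_RANGES[var]
        x = rows[var].to_numpy()
        mask &= (x > lo) & (x < hi)
    return mask


def _draw_cluster_rows(
    specs: dict[str, DistributionSpec],
    m: int,
    rng: np.random.Generator,
    correlation: np.ndarray | None,
) -> pd.DataFrame:
    names = list(specs)
    if correlation is None:
        data = {v: specs[v].sample(rng, m) for v in names}
        return pd.DataFrame(data)
    # Gaussian copula: correlated standard normals -> uniforms -> marginal quantiles
    chol = np.linalg.cholesky(np.asarray(correlation, dtype=float))
    z = rng.standard_normal((m, len(names))) @ chol.T
    u = stats.norm.cdf(z)
    return pd.DataFrame({v: specs[v].quantile(u[:, j]) for j, v in enumerate(names)})


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one cohort table.

    Cluster membership is multinomial over the mixing proportions; input
    variables are drawn from the cluster's marginals (independently unless a
    copula correlation is configured); rows violating the diagnostic rule or
    the plausibility windows are rejected and redrawn; binary outcomes are
    Bernoulli given the true cluster; missingness is applied independently per
    outcome cell.  Fully reproducible from ``config.seed``.

    Returns a DataFrame with columns: id, true_cluster, site, the input
    variables, and one float column (0/1/NaN) per configured outcome.
    """
    rng = np.random.default_rng(config.seed)
    var_names = list(config.variables[1]) if config.k else []
    out_cols = ["id", "true_cluster", "site", *var_names, *config.outcome_names]
    if config.n == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=float) for c in out_cols})
        empty["id"] = empty["id"].astype(int)
        empty["true_cluster"] = empty["true_cluster"].astype(int)
        empty["site"] = empty["site"].astype(str)
        return empty

    counts = rng.multinomial(config.n, np.asarray(config.mixing_proportions, dtype=float))
    frames = []
    for cluster, m in enumerate(counts, start=1):
        if m == 0:
            continue
        specs = config.variables[cluster]
        kept: list[pd.DataFrame] = []
        n_kept, n_drawn = 0, 0
        while n_kept < m:
            batch = max(2 * (m - n_kept), 32)
            rows = _draw_cluster_rows(specs, batch, rng, config.correlation)
            ok = _in_plausible_range(rows, var_names)
            if set(GDM_THRESHOLDS) & set(var_names):
                ok &= _is_gdm(rows)
            n_drawn += batch
            accepted = rows.loc[ok]
            n_kept += len(accepted)
            kept.append(accepted)
            if n_drawn >= 10000 and n_kept < 0.01 * n_drawn:
                raise ConfigInfeasibleError(
                    f"cluster {cluster}: acceptance rate "
                    f"{n_kept / n_drawn:.4f} below 1% — config infeasible"
                )
        part = pd.concat(kept, ignore_index=True).iloc[:m].copy()
        accept_rate = n_kept / n_drawn
        if accept_rate < 1.0:
            logger.info(
                "cluster %d: rejection sampling acceptance rate %.3f "
                "(quantile calibration holds only approximately under rejection)",
                cluster,
                accept_rate,
            )
        part.insert(0, "true_cluster", cluster)
        frames.append(part)

    table = pd.concat(frames, ignore_index=True)
    # Shuffle so that row order carries no cluster signal.
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    table.insert(0, "id", np.arange(1, len(table) + 1))
    table.insert(2, "site", config.site)

    for name in config.outcome_names:
        rates = np.asarray(config.outcome_rates[name], dtype=float)
        p = rates[table["true_cluster"].to_numpy() - 1]
        table[name] = (rng.random(len(table)) < p).astype(float)
    if config.missingness:
        table = inject_missingness(
            table, config.missingness, seed=int(rng.integers(2**31 - 1))
        )
    return table[out_cols]


def inject_missingness(
    table: pd.DataFrame, rates: dict[str, float], seed: int
) -> pd.DataFrame:
    """Independently blank outcome cells; input variables are never masked."""
    for name, rate in rates.items():
        if name in INPUT_VARIABLES:
            raise ValueError(f"refusing to mask input variable {name!r}")
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"missingness rate for {name!r} outside [0,1]: {rate}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for name, rate in rates.items():
        if name not in out.columns:
            raise ValueError(f"unknown outcome column {name!r}")
        mask = rng.random(len(out)) < rate
        col = out[name].astype(float).to_numpy(copy=True)
        col[mask] = np.nan
        out[name] = col
    return out


# --------------------------------------------------------------------------- #
# Config (de)serialisation — plain-text YAML
# --------------------------------------------------------------------------- #


def config_to_dict(config: CohortConfig) -> dict:
    """Plain-dict form of a config (specs reduced to their quartile targets)."""
    return {
        "n": config.n,
        "seed": config.seed,
        "site": config.site,
        "mixing_proportions": list(config.mixing_proportions),
        "quartiles": {
            cluster: {
                v: [s.target_q1, s.target_median, s.target_q3]
                for v, s in specs.items()
            }
            for cluster, specs in config.variables.items()
        },
        "outcome_rates": {k: list(v) for k, v in config.outcome_rates.items()},
        "missingness": dict(config.missingness),
    }


def config_from_dict(d: dict) -> CohortConfig:
    variables = {
        int(cluster): {v: fit_quantile_distribution(*q) for v, q in specs.items()}
        for cluster, specs in d["quartiles"].items()
    }
    return CohortConfig(
        n=int(d["n"]),
        mixing_proportions=tuple(float(x) for x in d["mixing_proportions"]),
        variables=variables,
        outcome_rates={k: tuple(v) for k, v in d.get("outcome_rates", {}).items()},
        missingness=dict(d.get("missingness", {})),
        seed=int(d.get("seed", 0)),
        site=str(d.get("site", "synthetic")),
    )


def load_config(path) -> CohortConfig:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: CohortConfig, path) -> None:
    import yaml

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
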
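"""Meta-analysis of admixture-time estimates across clusters.

Admixture dates (in generations, with standard errors) estimated per
cluster/reference pair by weighted-LD dating are combined by
inverse-variance fixed-effect meta-analysis; Cochran's Q tests whether
the dates are heterogeneous across clusters. A small calendar helper
converts generations to years before present.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetaResult",
    "read_estimate_table",
    "load_bundled_estimates",
    "fixed_effect_meta",
    "select_min_se",
    "generations_to_years",
    "bonferroni_reference_correction",
    "HONDO_CLUSTERS",
    "RYUKYU_CLUSTERS",
]

HONDO_CLUSTERS = ["Midland", "Fukuoka", "Ehime", "Shimane 1", "Shimane 2"]
RYUKYU_CLUSTERS = ["Ryukyu 1", "Ryukyu 2", "Ryukyu 3", "Ryukyu 4"]


@dataclass
class MetaResult:
    """Fixed-effect combined estimate with Cochran heterogeneity test."""

    estimate: float
    se: float
    q: float
    df: int
    p_het: float
    k: int


def read_estimate_table(path) -> pd.DataFrame:
    """Read a CSV of admixture-time estimates.

    Columns: cluster, reference, time_gen, se_gen, p_admixture; one row
    per (cluster, reference) pair; all SEs positive.
    """
    df = pd.read_csv(path)
    required = {"cluster", "reference", "time_gen", "se_gen", "p_admixture"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (df["se_gen"] <= 0).any():
        raise ValueError("all SEs must be positive")
    if df.duplicated(["cluster", "reference"]).any():
        raise ValueError("duplicate (cluster, reference) rows")
    return df


def load_bundled_estimates() -> pd.DataFrame:
    """The bundled per-cluster admixture-date table (generations ± SE)."""
    ref = importlib.resources.files("hapfine") / "data" / "table1.csv"
    with importlib.resources.as_file(ref) as path:
        return read_estimate_table(path)


def fixed_effect_meta(estimates, ses) -> MetaResult:
    """Inverse-variance fixed-effect combination with Cochran's Q.

    weights w_i = 1/se_i^2; combined = sum(w x)/sum(w); SE =
    sum(w)^(-1/2); Q = sum w (x - combined)^2 ~ chi-square(k-1) under
    homogeneity.
    """
    x = np.asarray(estimates, dtype=float)
    s = np.asarray(ses, dtype=float)
    if x.shape != s.shape or x.ndim != 1:
        raise ValueError("estimates and SEs must be 1-D and aligned")
    if len(x) < 2:
        raise ValueError("need at least two estimates")
    if (s <= 0).any():
        raise ValueError("all SEs must be positive")
    w = 1.0 / s**2
    combined = float(np.sum(w * x) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (x - combined) ** 2))
    df = len(x) - 1
    return MetaResult(combined, se, q, df, float(stats.chi2.sf(q, df)), len(x))


def meta_by_reference(table: pd.DataFrame, reference: str, clusters: list | None = None
                      ) -> MetaResult:
    """Fixed-effect meta-analysis of the rows for one reference cluster."""
    sub = table[table["reference"] == reference]
    if clusters is not None:
        sub = sub[sub["cluster"].isin(clusters)]
    if len(sub) < 2:
        raise ValueError(f"fewer than two rows for reference {reference!r}")
    return fixed_effect_meta(sub["time_gen"].to_numpy(), sub["se_gen"].to_numpy())


def select_min_se(table: pd.DataFrame, cluster_subset: list) -> pd.Series:
    """Row with the smallest SE among the given clusters.

    Ties go to the smaller time estimate, then to the lexicographically
    smaller reference label.
    """
    sub = table[table["cluster"].isin(cluster_subset)]
    if len(sub) == 0:
        raise ValueError("empty cluster subset")
    sub = sub.sort_values(["se_gen", "time_gen", "reference"], kind="stable")
    return sub.iloc[0]


def generations_to_years(gens: float, generation_time: float = 25.0) -> float:
    """Generations before present -> years before present."""
    if gens < 0:
        raise ValueError("generations must be non-negative")
    return float(gens * generation_time)


def bonferroni_reference_correction(p_raw: float, n_effective: int = 12) -> float:
    """Multiply by the effective number of reference populations, cap at 1."""
    if not 0 <= p_raw <= 1:
        raise ValueError("p must lie in [0, 1]")
    return min(1.0, p_raw * n_effective)
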
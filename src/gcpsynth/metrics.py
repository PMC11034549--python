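"""Real-vs-synthetic utility assessment.

Four families of checks, all comparing a real and a synthetic long table:

- per-variable Hellinger distance between marginal distributions (binned for
  continuous variables, category frequencies for coded ones);
- the vector of absolute pairwise-correlation differences over the widened
  patients x (variable, visit) matrix;
- RMSDC, the root mean square of those correlation differences (strict
  upper triangle) — lower means the dependency structure is better kept;
- per-variable descriptive summaries (min, quartiles, mean, sd, max,
  missing count) side by side.

Correlations are Pearson by default (Kendall selectable) and use
pairwise-complete observations; missing cells are never imputed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .longio import LongTable

__all__ = [
    "hellinger",
    "correlation_matrix",
    "rmsdc",
    "abs_corr_diffs",
    "descriptive_summary",
    "UtilityReport",
    "evaluate_utility",
]


def hellinger(
    real: np.ndarray,
    synthetic: np.ndarray,
    bins: int = 30,
    categorical: bool = False,
) -> float:
    """Hellinger distance in [0, 1]; 0 means identical distributions.

    Continuous samples are binned on ``bins`` shared equal-width bins over
    the pooled range; categorical samples use category frequencies.  Either
    way H = sqrt(1 - sum_b sqrt(p_b * q_b)) (the Bhattacharyya form).
    """
    real = np.asarray(real, dtype=float)
    real = real[~np.isnan(real)]
    synthetic = np.asarray(synthetic, dtype=float)
    synthetic = synthetic[~np.isnan(synthetic)]
    if real.size == 0 or synthetic.size == 0:
        raise ValueError("hellinger requires two non-empty samples")
    if categorical:
        cats = np.union1d(real, synthetic)
        p = np.array([(real == c).mean() for c in cats])
        q = np.array([(synthetic == c).mean() for c in cats])
    else:
        if bins < 2:
            raise ValueError("bins must be >= 2 for continuous samples")
        lo = min(real.min(), synthetic.min())
        hi = max(real.max(), synthetic.max())
        if hi == lo:  # all pooled values identical
            return 0.0
        edges = np.linspace(lo, hi, bins + 1)
        p = np.histogram(real, bins=edges)[0] / real.size
        q = np.histogram(synthetic, bins=edges)[0] / synthetic.size
    # 1 - sum(sqrt(p*q)) computed as 0.5*sum((sqrt(p)-sqrt(q))^2): exact at p=q
    return float(np.sqrt(0.5 * np.sum((np.sqrt(p) - np.sqrt(q)) ** 2)))


def _widen(t: LongTable) -> pd.DataFrame:
    """Patients x (variable, visit) wide matrix, NaN where missing."""
    wide = t.df.pivot_table(
        index="patient_id",
        columns=["variable", "visit"],
        values="value",
        aggfunc="first",
        dropna=False,
    )
    wide.columns = [f"{v}@{k}" for v, k in wide.columns]
    return wide.sort_index(axis=1)


def correlation_matrix(
    t: LongTable, method: str = "pearson", min_periods: int = 3
) -> pd.DataFrame:
    """Pairwise-complete correlations over the widened variable-visit columns.

    Columns with fewer than ``min_periods`` complete pairs against every
    other column are excluded with a warning.
    """
    if method not in ("pearson", "kendall"):
        raise ValueError("method must be 'pearson' or 'kendall'")
    wide = _widen(t)
    if len(wide) < 3:
        raise ValueError("correlation structure needs at least 3 patients")
    corr = wide.corr(method=method, min_periods=min_periods)
    dead = corr.columns[corr.isna().all(axis=0)]
    if len(dead):
        warnings.warn(
            f"excluding {len(dead)} column(s) with < {min_periods} complete pairs: "
            f"{list(dead)[:5]}"
        )
        corr = corr.drop(index=dead, columns=dead)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def _common_upper_triangle(
    c_real: pd.DataFrame | np.ndarray, c_syn: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(c_real, pd.DataFrame) and isinstance(c_syn, pd.DataFrame):
        common = [c for c in c_real.columns if c in set(c_syn.columns)]
        c_real = c_real.loc[common, common].to_numpy()
        c_syn = c_syn.loc[common, common].to_numpy()
    else:
        c_real = np.asarray(c_real, dtype=float)
        c_syn = np.asarray(c_syn, dtype=float)
    if c_real.shape != c_syn.shape:
        raise ValueError(f"shape mismatch: {c_real.shape} vs {c_syn.shape}")
    iu = np.triu_indices(c_real.shape[0], k=1)
    return c_real[iu], c_syn[iu]


def rmsdc(c_real, c_syn) -> float:
    """Root mean square difference of correlations (strict upper triangle)."""
    r, s = _common_upper_triangle(c_real, c_syn)
    d = r - s
    ok = ~np.isnan(d)
    if not ok.any():
        raise ValueError("no complete correlation pairs to compare")
    return float(np.sqrt(np.mean(d[ok] ** 2)))


def abs_corr_diffs(c_real, c_syn) -> np.ndarray:
    """|real - synthetic| correlation differences as a flat vector."""
    r, s = _common_upper_triangle(c_real, c_syn)
    d = np.abs(r - s)
    return d[~np.isnan(d)]


def descriptive_summary(t: LongTable) -> pd.DataFrame:
    """Per-variable min, quartiles, median, mean, sd, max and missing count."""
    if t.df.empty:
        raise ValueError("cannot summarize an empty table")
    rows = []
    for var in t.variables:
        vals = t.observed_values(var)
        n_missing = int(t.df[t.df["variable"] == var]["value"].isna().sum())
        if vals.size == 0:
            rows.append({"variable": var, "n_missing": n_missing})
            continue
        rows.append(
            {
                "variable": var,
                "min": float(vals.min()),
                "q1": float(np.quantile(vals, 0.25)),
                "median": float(np.median(vals)),
                "q3": float(np.quantile(vals, 0.75)),
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "max": float(vals.max()),
                "n_missing": n_missing,
            }
        )
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class UtilityReport:
    """Bundle of all utility metrics, JSON-serializable."""

    hellinger_by_variable: dict[str, float]
    abs_corr_diffs: list[float]
    rmsdc: float
    summary_real: pd.DataFrame
    summary_synthetic: pd.DataFrame
    n_patients_real: int
    n_patients_synthetic: int
    missing_fraction_real: float = 0.0
    missing_fraction_synthetic: float = 0.0
    metadata: dict = field(default_factory=dict)

    @property
    def median_hellinger(self) -> float:
        return float(np.median(list(self.hellinger_by_variable.values())))

    def to_dict(self) -> dict:
        return {
            "hellinger_by_variable": self.hellinger_by_variable,
            "median_hellinger": self.median_hellinger,
            "abs_corr_diffs": list(map(float, self.abs_corr_diffs)),
            "rmsdc": self.rmsdc,
            "summary_real": self.summary_real.reset_index().to_dict(orient="list"),
            "summary_synthetic": self.summary_synthetic.reset_index().to_dict(
                orient="list"
            ),
            "n_patients_real": self.n_patients_real,
            "n_patients_synthetic": self.n_patients_synthetic,
            "missing_fraction_real": self.missing_fraction_real,
            "missing_fraction_synthetic": self.missing_fraction_synthetic,
            "metadata": self.metadata,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, allow_nan=True))

    @classmethod
    def from_dict(cls, d: dict) -> "UtilityReport":
        return cls(
            hellinger_by_variable=dict(d["hellinger_by_variable"]),
            abs_corr_diffs=list(d["abs_corr_diffs"]),
            rmsdc=float(d["rmsdc"]),
            summary_real=pd.DataFrame(d["summary_real"]).set_index("variable"),
            summary_synthetic=pd.DataFrame(d["summary_synthetic"]).set_index(
                "variable"
            ),
            n_patients_real=int(d["n_patients_real"]),
            n_patients_synthetic=int(d["n_patients_synthetic"]),
            missing_fraction_real=float(d.get("missing_fraction_real", 0.0)),
            missing_fraction_synthetic=float(d.get("missing_fraction_synthetic", 0.0)),
            metadata=dict(d.get("metadata", {})),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "UtilityReport":
        return cls.from_dict(json.loads(Path(path).read_text()))


def evaluate_utility(
    real: LongTable,
    synthetic: LongTable,
    bins: int = 30,
    corr_method: str = "pearson",
    categorical_variables: set[str] | None = None,
    metadata: dict | None = None,
) -> UtilityReport:
    """Compute the full utility report for a real/synthetic table pair.

    Per-variable marginals pool observed values across patients and visits.
    """
    categorical_variables = categorical_variables or set()
    hell = {}
    for var in real.variables:
        if var not in synthetic.variables:
            continue
        hell[var] = hellinger(
            real.observed_values(var),
            synthetic.observed_values(var),
            bins=bins,
            categorical=var in categorical_variables,
        )
    c_real = correlation_matrix(real, method=corr_method)
    c_syn = correlation_matrix(synthetic, method=corr_method)
    return UtilityReport(
        hellinger_by_variable=hell,
        abs_corr_diffs=list(map(float, abs_corr_diffs(c_real, c_syn))),
        rmsdc=rmsdc(c_real, c_syn),
        summary_real=descriptive_summary(real),
        summary_synthetic=descriptive_summary(synthetic),
        n_patients_real=real.n_patients,
        n_patients_synthetic=synthetic.n_patients,
        missing_fraction_real=real.missing_fraction(),
        missing_fraction_synthetic=synthetic.missing_fraction(),
        metadata=metadata or {},
    )
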
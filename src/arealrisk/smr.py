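"""Indirect standardization, SMRs, and the covariate correlation screen.

The standardized morbidity ratio relates observed to expected cases:
SMR_i = y_i / e_i, where e_i is the count area i would record if every
area experienced the whole study region's overall rate,
e_i = population_i * (sum y / sum population).  By construction the
expected counts sum exactly to the observed total, so the population-
weighted mean SMR is 1.

The correlation screen is the simple pairwise correlation analysis run
on the high-prevalence covariate categories before factor analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AreaData",
    "expected_counts",
    "smr",
    "correlation_matrix",
    "plot_correlation_heatmap",
]


@dataclass
class AreaData:
    """Per-area observed counts, population at risk, expected counts and
    covariates, in one fixed area order."""

    area_ids: list[str]
    y: np.ndarray
    populations: np.ndarray
    e: np.ndarray | None = None
    X: np.ndarray | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.area_ids = [str(a) for a in self.area_ids]
        m = len(self.area_ids)
        self.y = np.asarray(self.y)
        self.populations = np.asarray(self.populations, dtype=float)
        if self.y.shape != (m,) or self.populations.shape != (m,):
            raise ValueError("y and populations must have one entry per area")
        if np.any(self.y < 0) or not np.allclose(self.y, np.round(self.y)):
            raise ValueError("observed counts must be non-negative integers")
        self.y = np.round(self.y).astype(int)
        if np.any(self.populations <= 0):
            bad = self.area_ids[int(np.argmax(self.populations <= 0))]
            raise ValueError(f"non-positive population for area '{bad}'")
        if self.e is not None:
            self.e = np.asarray(self.e, dtype=float)
            if self.e.shape != (m,):
                raise ValueError("e must have one entry per area")
        if self.X is not None:
            self.X = np.asarray(self.X, dtype=float)
            if self.X.ndim != 2 or self.X.shape[0] != m:
                raise ValueError("X must be an (m, M) matrix")
            if self.covariate_names is None:
                self.covariate_names = [f"cov_{j}" for j in range(self.X.shape[1])]
            elif len(self.covariate_names) != self.X.shape[1]:
                raise ValueError("covariate_names length must match X columns")

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    # -- CSV round trip (columns: area_id,population,observed[,expected][,cov_*])
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "area_id": self.area_ids,
                "population": self.populations,
                "observed": self.y,
            }
        )
        if self.e is not None:
            df["expected"] = self.e
        if self.X is not None:
            for j, name in enumerate(self.covariate_names):
                df[name] = self.X[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AreaData":
        required = {"area_id", "population", "observed"}
        if not required.issubset(df.columns):
            raise ValueError(f"area table needs columns {sorted(required)}")
        cov_cols = [
            c for c in df.columns
            if c not in ("area_id", "population", "observed", "expected")
        ]
        return cls(
            area_ids=list(df["area_id"].astype(str)),
            y=df["observed"].to_numpy(),
            populations=df["population"].to_numpy(),
            e=df["expected"].to_numpy() if "expected" in df.columns else None,
            X=df[cov_cols].to_numpy(dtype=float) if cov_cols else None,
            covariate_names=cov_cols or None,
        )

    @classmethod
    def from_csv(cls, path) -> "AreaData":
        return cls.from_dataframe(pd.read_csv(path))


def expected_counts(data: AreaData) -> AreaData:
    """Fill expected counts by indirect standardization.

    e_i = population_i * (sum y / sum population); sum(e) == sum(y)
    exactly up to floating rounding.  A single all-areas reference rate
    is used (no age stratification); externally stratified expectations
    can be supplied directly on :class:`AreaData` instead.
    """
    total_y = int(data.y.sum())
    if total_y == 0:
        raise ValueError("no observed cases in any area; the SMR is undefined")
    rate = total_y / data.populations.sum()
    e = data.populations * rate
    return AreaData(
        area_ids=list(data.area_ids),
        y=data.y.copy(),
        populations=data.populations.copy(),
        e=e,
        X=None if data.X is None else data.X.copy(),
        covariate_names=None
        if data.covariate_names is None
        else list(data.covariate_names),
    )


def smr(data: AreaData) -> np.ndarray:
    """Standardized morbidity ratio per area: SMR_i = y_i / e_i."""
    if data.e is None:
        raise ValueError("expected counts not computed; run expected_counts first")
    if np.any(data.e <= 0):
        bad = data.area_ids[int(np.argmax(data.e <= 0))]
        raise ValueError(f"non-positive expected count for area '{bad}'")
    return data.y / data.e


def correlation_matrix(
    X, names: Sequence[str] | None = None, method: str = "pearson"
) -> pd.DataFrame:
    """Pairwise covariate correlations (the pre-factor-analysis screen).

    Pearson product-moment by default; ``method="spearman"`` for the rank
    version.  Constant columns are rejected by name.
    """
    if isinstance(X, AreaData):
        if X.X is None:
            raise ValueError("AreaData has no covariates")
        names = names or X.covariate_names
        X = X.X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an (m, M) matrix with M >= 2 covariates")
    if names is None:
        names = [f"cov_{j}" for j in range(X.shape[1])]
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = names[int(np.argmax(sd == 0))]
        raise ValueError(f"covariate '{bad}' is constant; correlation undefined")
    if method == "pearson":
        r = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        from scipy import stats

        r = stats.spearmanr(X).statistic
        if np.ndim(r) == 0:  # scipy collapses the M=2 case to a scalar
            r = np.array([[1.0, float(r)], [float(r), 1.0]])
    else:
        raise ValueError(f"unknown method '{method}'")
    return pd.DataFrame(r, index=list(names), columns=list(names))


def plot_correlation_heatmap(corr: pd.DataFrame, path) -> None:
    """Write a plain heatmap of a correlation matrix to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(corr), 1 + 0.5 * len(corr)))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
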
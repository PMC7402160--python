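"""Arrayed-matrix analytics: percent-of-total normalization, condition
difference maps with marginal sums, and Fano-factor noise statistics.

These operate on the plate-style follow-up experiment: an n x m grid of
enhancer x promoter constructs measured by fluorimetry (replicate-averaged),
re-expressed as a percentage of the grid total so plates measured on
different days or instruments are comparable; and per-construct single-cell
cytometry vectors summarized by mean, variance and the Fano factor
(variance / mean — 1 for a Poisson process, > 1 for bursty expression).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class FluorMatrix:
    """Replicate-averaged fluorescence grid for one growth condition."""

    values: pd.DataFrame  # row genes x col genes, nonnegative
    condition: str = ""
    n_replicates: pd.DataFrame | int = 1

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("fluorescence values must be nonnegative")

    @classmethod
    def from_long(cls, df: pd.DataFrame, condition: str | None = None) -> "FluorMatrix":
        """Average replicates out of a long table with columns
        (row_gene, col_gene, replicate, fluorescence[, condition])."""
        if condition is not None and "condition" in df.columns:
            df = df[df["condition"] == condition]
        if df.empty:
            raise ValueError("no rows for the requested condition")
        mean = df.pivot_table(
            index="row_gene", columns="col_gene", values="fluorescence", aggfunc="mean"
        )
        nrep = df.pivot_table(
            index="row_gene", columns="col_gene", values="fluorescence", aggfunc="count"
        )
        return cls(values=mean, condition=condition or "", n_replicates=nrep)


def percent_of_total(m: FluorMatrix | pd.DataFrame) -> pd.DataFrame:
    """Each cell as a percentage of the grid total; output sums to 100.

    Invariant under uniform rescaling of the input, which is what makes
    cross-day and cross-instrument grids comparable.
    """
    values = m.values if isinstance(m, FluorMatrix) else m
    total = float(np.asarray(values).sum())
    if total <= 0:
        raise ValueError("matrix total must be positive")
    return values * (100.0 / total)


def condition_difference(
    a: FluorMatrix, b: FluorMatrix
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Elementwise difference of percent-of-total matrices, a minus b,
    plus row and column marginal sums.

    Because both inputs sum to 100, the difference grid sums to zero; a row
    whose marginal dominates flags an element that redistributed expression
    between the two conditions.
    """
    va, vb = a.values, b.values
    if not (va.index.equals(vb.index) and va.columns.equals(vb.columns)):
        raise ValueError("condition matrices must share row/column labels")
    diff = percent_of_total(a) - percent_of_total(b)
    row_marginal = diff.sum(axis=1)
    col_marginal = diff.sum(axis=0)
    row_marginal.name = "row_sum"
    col_marginal.name = "col_sum"
    return diff, row_marginal, col_marginal


@dataclass
class NoiseStat:
    """Mean, unbiased variance and Fano factor of one cytometry sample."""

    mean: float
    variance: float
    fano: float
    n_cells: int = 0
    label: str = ""


def fano(sample: Sequence[float] | np.ndarray, label: str = "") -> NoiseStat:
    """Noise summary of a per-cell fluorescence vector.

    Uses the unbiased (n-1) sample variance; requires n >= 2 cells and a
    positive mean.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 cells")
    mean = float(x.mean())
    if mean <= 0:
        raise ValueError("mean fluorescence must be positive")
    variance = float(x.var(ddof=1))
    return NoiseStat(mean=mean, variance=variance, fano=variance / mean,
                     n_cells=int(x.size), label=label)


def lognormal_fano(mu: float, sigma: float) -> float:
    """Closed-form Fano factor of a log-normal(log mu, sigma) population:
    mean * (exp(sigma^2) - 1)."""
    mean = mu * np.exp(sigma**2 / 2.0)
    return float(mean * np.expm1(sigma**2))


def fano_vs_mean_curve(noise_stats: Iterable[NoiseStat]) -> tuple[pd.DataFrame, float]:
    """Sort constructs by mean expression and report the monotone-trend
    statistic (Spearman rho of Fano vs mean; NaN when undefined, e.g. fewer
    than two distinct constructs)."""
    stats_list = list(noise_stats)
    if len(stats_list) < 2:
        raise ValueError("need at least 2 constructs")
    df = pd.DataFrame(
        {
            "label": [s.label for s in stats_list],
            "mean": [s.mean for s in stats_list],
            "variance": [s.variance for s in stats_list],
            "fano": [s.fano for s in stats_list],
        }
    ).sort_values(["mean", "label"], kind="mergesort", ignore_index=True)
    if df["mean"].nunique() < 2 or df["fano"].nunique() < 2:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(df["mean"], df["fano"]).statistic)
    return df, rho
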
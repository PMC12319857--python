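"""Mass-univariate linear modelling of spectral time-courses.

Every frequency point of a dynamics x frequency spectrogram is treated as
an independent time series and fitted by ordinary least squares against a
design containing an intercept, a (possibly lagged) task boxcar and an
optional lineshape-drift nuisance regressor built from the integrated
1.97-2.04 ppm region.  Per-point t statistics and two-sided Student-t
p-values feed Manhattan plots with a Bonferroni family-wise threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import MrsInputError, Spectrogram, TaskDesign, ppm_slice
from .quality import _moving_average


@dataclass
class DesignMatrix:
    """Time x regressor matrix with column labels.

    The intercept column of ones is always present; nuisance columns are
    demeaned.  The task column keeps its 0/1 scaling (demeaned) so the
    fitted beta is the task-locked signal change in spectrogram units.
    """

    values: np.ndarray
    labels: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.labels):
            raise MrsInputError("design shape does not match labels")
        if "intercept" not in self.labels:
            raise MrsInputError("design must contain an intercept column")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise MrsInputError(
                f"design matrix is rank deficient (columns: {self.labels})"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def df_residual(self) -> int:
        return self.n - self.k


@dataclass
class GlmResult:
    """Per-frequency OLS estimates and test statistics."""

    ppm: np.ndarray
    labels: List[str]
    beta: np.ndarray  # (n_freq, k)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    alpha: float
    bonferroni_p: float
    exact_fit: np.ndarray  # (n_freq,) bool

    def column(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no regressor labelled {label!r}") from None


def build_boxcar(task: TaskDesign, times_s: np.ndarray, lag_s: float = 0.0
                 ) -> np.ndarray:
    """0/1 task indicator at the given times, optionally delayed by lag_s.

    A sample is "task" iff ``rest1 + lag <= t < rest1 + task + lag``.
    """
    t = np.asarray(times_s, dtype=float)
    on = task.task_onset_s + lag_s
    off = task.task_offset_s + lag_s
    box = ((t >= on) & (t < off)).astype(float)
    if box.sum() == 0 or box.sum() == len(box):
        warnings.warn("degenerate boxcar (all zeros or all ones); it will be "
                      "rejected for rank reasons when used in a design")
    return box


def build_nuisance(
    spectrogram: Spectrogram,
    ppm_range: Tuple[float, float] = (1.97, 2.04),
    smooth_window: int = 51,
) -> np.ndarray:
    """Lineshape-drift nuisance regressor.

    Per-dynamic integral of the given spectral region, smoothed by a
    centred moving average, demeaned and scaled to unit variance.
    """
    sl = ppm_slice(spectrogram.ppm, *ppm_range)
    course = spectrogram.values[:, sl].sum(axis=1)
    course = _moving_average(course, smooth_window)
    course = course - course.mean()
    sd = course.std()
    return course / sd if sd > 0 else course


def build_design(
    task: TaskDesign,
    times_s: np.ndarray,
    lag_s: float = 0.0,
    nuisance: Optional[np.ndarray] = None,
) -> DesignMatrix:
    """Assemble intercept + (lagged) task boxcar + optional nuisance."""
    box = build_boxcar(task, times_s, lag_s)
    cols = [np.ones_like(box), box - box.mean()]
    labels = ["intercept", "task"]
    if nuisance is not None:
        nui = np.asarray(nuisance, dtype=float)
        if len(nui) != len(box):
            raise MrsInputError("nuisance length does not match times")
        cols.append(nui - nui.mean())
        labels.append("nuisance")
    return DesignMatrix(np.column_stack(cols), labels)


def t_to_p(t, df: int):
    """Two-sided tail probability of the Student t distribution."""
    if df < 1:
        raise MrsInputError("df must be >= 1")
    return 2.0 * stats.t.sf(np.abs(t), df)


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Per-test threshold controlling the family-wise error at ``alpha``."""
    if n_tests < 1:
        raise MrsInputError("n_tests must be >= 1")
    return alpha / n_tests


def fit_glm(
    spectrogram: Spectrogram,
    design: DesignMatrix,
    alpha: float = 0.05,
) -> GlmResult:
    """Ordinary least squares fit of the design to every frequency column.

    For each column y: ``beta = argmin ||y - X beta||^2``, standard errors
    from ``sigma2 * diag((X'X)^-1)`` with ``sigma2 = RSS / df``, t = beta/se
    and two-sided Student-t p-values.  Columns fitted exactly (RSS ~ 0)
    are flagged in ``exact_fit`` and get NaN statistics rather than p = 0.
    """
    X = design.values
    Y = spectrogram.values
    if X.shape[0] != Y.shape[0]:
        raise MrsInputError(
            f"design rows ({X.shape[0]}) != spectrogram dynamics ({Y.shape[0]})"
        )
    df = design.df_residual
    if df < 1:
        raise MrsInputError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Y  # (k, n_freq)
    resid = Y - X @ B
    rss = np.einsum("ij,ij->j", resid, resid)
    total = np.einsum("ij,ij->j", Y, Y)
    exact = rss <= 1e-12 * np.maximum(total, 1e-300)
    sigma2 = rss / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # (k, n_freq)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, B / se, np.inf * np.sign(B))
    p = t_to_p(t, df)
    t[:, exact] = np.nan
    p[:, exact] = np.nan
    n_freq = Y.shape[1]
    return GlmResult(
        ppm=spectrogram.ppm.copy(),
        labels=list(design.labels),
        beta=B.T.copy(),
        se=se.T.copy(),
        t=t.T.copy(),
        p=p.T.copy(),
        df=df,
        alpha=alpha,
        bonferroni_p=bonferroni_threshold(alpha, n_freq),
        exact_fit=exact,
    )


def manhattan_data(result: GlmResult, regressor_label: str = "task"
                   ) -> pd.DataFrame:
    """Table of (ppm, -log10 p, significant) for Manhattan plotting.

    Significance is strict: p must be *below* the Bonferroni threshold.
    """
    j = result.column(regressor_label)
    p = result.p[:, j]
    with np.errstate(divide="ignore"):
        neg = -np.log10(p)
    sig = p < result.bonferroni_p
    return pd.DataFrame({
        "ppm": result.ppm,
        "neg_log10_p": neg,
        "significant": sig,
        "beta": result.beta[:, j],
    })


def plot_manhattan(result: GlmResult, path, regressor_label: str = "task",
                   title: str = "") -> None:
    """Manhattan plot with the dashed Bonferroni threshold line."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tab = manhattan_data(result, regressor_label)
    fig, ax = plt.subplots(figsize=(9, 4))
    ax.plot(tab["ppm"], tab["neg_log10_p"], lw=0.8, color="0.3")
    sig = tab[tab["significant"]]
    ax.plot(sig["ppm"], sig["neg_log10_p"], ".", color="crimson", ms=4)
    ax.axhline(-np.log10(result.bonferroni_p), color="red", ls="--", lw=1)
    ax.set_xlim(tab["ppm"].max(), tab["ppm"].min())
    ax.set_xlabel("chemical shift (ppm)")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


__all__ = [
    "DesignMatrix",
    "GlmResult",
    "build_boxcar",
    "build_nuisance",
    "build_design",
    "fit_glm",
    "t_to_p",
    "bonferroni_threshold",
    "manhattan_data",
    "plot_manhattan",
]
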
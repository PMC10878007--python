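"""Autoscaling, deterministic PCA and grouped Pearson correlation.

GC fatty-acid class profiles are autoscaled (mean-centered, unit column
standard deviation) before PCA; preprocessed FTIR spectra are only
mean-centered. PCA is a plain singular-value decomposition of the
centered matrix with a deterministic sign convention, so repeated runs
are bit-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PCAResult",
    "autoscale",
    "pca",
    "pearson_by_group",
]


def autoscale(m: pd.DataFrame) -> pd.DataFrame:
    """Mean-center each column and divide by its standard deviation.

    Columns with zero variance carry no information on the correlation
    scale; they are dropped with a warning. Sample standard deviation
    (ddof=1) is used.
    """
    values = m.to_numpy(dtype=float)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1) if len(m) > 1 else \
        np.zeros(values.shape[1])
    keep = sds > 0
    if not keep.any():
        raise ValueError("every column has zero variance; nothing to scale")
    if not keep.all():
        dropped = list(m.columns[~keep])
        warnings.warn(
            f"autoscale: dropping zero-variance columns {dropped}",
            UserWarning, stacklevel=2,
        )
    scaled = (values[:, keep] - means[keep]) / sds[keep]
    return pd.DataFrame(scaled, index=m.index, columns=m.columns[keep])


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions.

    ``scores`` is samples x components, ``loadings`` features x
    components (orthonormal columns), ``explained_variance_fraction``
    the per-component share of total variance (non-increasing, sums to
    at most 1).
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(m: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """Principal component analysis of a samples x features frame.

    The matrix is column-centered (not rescaled — autoscale beforehand
    if required) and decomposed by SVD. Component k explains
    lambda_k / sum(lambda) of total variance. The sign of each component
    is fixed by making its largest-magnitude loading positive.
    """
    if m.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if m.shape[1] < 1:
        raise ValueError("PCA needs at least one feature")
    # fixed memory layout so the summation order and LAPACK results are
    # bit-identical regardless of how the frame was assembled
    values = np.ascontiguousarray(m.to_numpy(dtype=float))
    if np.isnan(values).any():
        raise ValueError("feature matrix contains missing values")
    centered = values - values.mean(axis=0)
    max_rank = min(m.shape[0] - 1, m.shape[1])
    if n_components is None:
        n_components = max_rank
    elif n_components > max_rank:
        warnings.warn(
            f"n_components={n_components} exceeds the available rank "
            f"{max_rank}; clipping", UserWarning, stacklevel=2,
        )
        n_components = max_rank

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s ** 2).sum())
    explained = (s[:n_components] ** 2) / total if total > 0 else \
        np.zeros(n_components)

    loadings = vt[:n_components].T  # features x components
    scores = u[:, :n_components] * s[:n_components]
    # Deterministic sign: largest-magnitude loading per component positive.
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
            scores[:, k] = -scores[:, k]

    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=m.columns,
                              columns=comp_names),
        explained_variance_fraction=explained,
    )


def pearson_by_group(
    data: pd.DataFrame,
    x: str = "L_over_P",
    y: str = "total_lipid_pct",
    grouping: str | None = None,
) -> pd.DataFrame:
    """Pearson r between two columns, overall or per metadata group.

    ``grouping=None`` (or ``"all"``) computes a single coefficient over
    the whole frame. Groups with fewer than two complete pairs, or zero
    variance in either variable, are reported with ``r`` NaN and flagged
    ``defined=False`` rather than dropped.
    """
    def one(frame: pd.DataFrame, label) -> dict:
        pairs = frame[[x, y]].dropna()
        n = len(pairs)
        if n < 2 or pairs[x].nunique() < 2 or pairs[y].nunique() < 2:
            return {"group": label, "r": float("nan"), "n": n,
                    "defined": False}
        r = float(stats.pearsonr(pairs[x], pairs[y]).statistic)
        return {"group": label, "r": r, "n": n, "defined": True}

    if grouping is None or grouping == "all":
        rows = [one(data, "all")]
    else:
        if grouping not in data.columns:
            raise KeyError(f"grouping column {grouping!r} not present")
        rows = [one(frame, key)
                for key, frame in data.groupby(grouping, sort=True)]
    return pd.DataFrame(rows)
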
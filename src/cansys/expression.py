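"""Expressed / not-expressed gating from a count matrix.

A univariate Gaussian mixture (default 5 components) is fitted to the
log2(count + 1) expression values, the components are split into a low
and a high group by k-means (k = 2) on the component parameter matrix
(weight, mean, sd), and the gate is the smallest expression value where
the posterior mass of the two groups balances. Genes below that cutoff
are considered not expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MixtureFit:
    """A fitted univariate Gaussian mixture with a low/high component split.

    ``cutoffs`` holds the decision boundaries between adjacent components
    belonging to different groups, sorted ascending; the smallest is the
    expression gate. ``group_labels`` marks each component "low" or "high".
    """

    n_components: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    cutoffs: tuple[float, ...] = ()
    group_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if abs(float(np.sum(self.weights)) - 1.0) > 1e-8:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("mixture sds must be positive")
        lo, hi = float(np.min(self.means)), float(np.max(self.means))
        for c in self.cutoffs:
            if not lo < c < hi:
                raise ValueError(f"cutoff {c} outside fitted mean range ({lo}, {hi})")

    @property
    def gate(self) -> float:
        """Smallest cutoff; genes below it are not expressed."""
        if not self.cutoffs:
            raise ValueError("no cutoff derived; run derive_cutoff first")
        return self.cutoffs[0]


def fit_expression_mixture(values: np.ndarray, ks: int = 5,
                           seed: int = 0, n_init: int = 10,
                           max_iter: int = 500) -> MixtureFit:
    """Fit a ks-component univariate Gaussian mixture to log-expression.

    EM is k-means initialized with ``n_init`` restarts, keeping the best
    likelihood; deterministic given ``seed``.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 10 * ks:
        raise ValueError(
            f"need >= {10 * ks} finite values for ks={ks} (got {len(values)}); "
            "lower ks or supply more genes")
    if np.ptp(values) == 0:
        raise ValueError("constant expression vector; mixture fit is degenerate")
    gmm = GaussianMixture(n_components=ks, covariance_type="diag",
                          n_init=n_init, max_iter=max_iter,
                          init_params="kmeans", random_state=seed,
                          reg_covar=1e-6)
    gmm.fit(values.reshape(-1, 1))
    if not gmm.converged_:
        raise RuntimeError(
            f"mixture EM did not converge in {max_iter} iterations "
            f"(lower bound {gmm.lower_bound_:.4f}); try a different seed or ks")
    order = np.argsort(gmm.means_.ravel())
    return MixtureFit(
        n_components=ks,
        weights=gmm.weights_[order].copy(),
        means=gmm.means_.ravel()[order].copy(),
        sds=np.sqrt(gmm.covariances_.ravel()[order]),
    )


def _map_boundary(fit: MixtureFit, low: np.ndarray, high: np.ndarray,
                  left: float, right: float, grid_points: int) -> float:
    """Expression value in (left, right) where the posterior mass of the
    low component group equals that of the high group, by grid scan."""
    # open interval: a boundary must lie strictly between the flanking means
    x = np.linspace(left, right, grid_points + 2)[1:-1]
    dens = norm.pdf(x[:, None], fit.means[None, :], fit.sds[None, :]) * fit.weights
    diff = dens[:, low].sum(axis=1) - dens[:, high].sum(axis=1)
    return float(x[np.argmin(np.abs(diff))])


def derive_cutoff(fit: MixtureFit, grid_points: int = 10001,
                  seed: int = 0) -> MixtureFit:
    """Split components into low/high groups and locate decision boundaries.

    k-means (k = 2) runs on the per-component (weight, mean, sd) matrix,
    standardized per column so no parameter dominates the distance. A
    boundary is computed between every adjacent pair of components (by
    mean) whose groups differ, using the maximum-a-posteriori balance
    point on a grid of ``grid_points`` values.
    """
    if fit.n_components < 2:
        raise ValueError("need >= 2 components to derive a cutoff")
    params = np.column_stack([fit.weights, fit.means, fit.sds])
    sd = params.std(axis=0)
    sd[sd == 0] = 1.0
    z = (params - params.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(z)
    labels = km.labels_
    if len(set(labels)) < 2:
        raise RuntimeError("k-means put all components in one group; "
                           "try a different seed or ks")
    # Group with the smaller mean-of-means is "low".
    mean0 = fit.means[labels == 0].mean()
    mean1 = fit.means[labels == 1].mean()
    low_label = 0 if mean0 <= mean1 else 1
    groups = tuple("low" if l == low_label else "high" for l in labels)

    low_idx = np.flatnonzero(labels == low_label)
    high_idx = np.flatnonzero(labels != low_label)
    cutoffs = []
    for a, b in zip(range(fit.n_components - 1), range(1, fit.n_components)):
        if groups[a] != groups[b]:
            cutoffs.append(_map_boundary(fit, low_idx, high_idx,
                                         fit.means[a], fit.means[b], grid_points))
    if not cutoffs:
        raise RuntimeError("component groups interleave with no adjacent "
                           "boundary; cannot derive a cutoff")
    return MixtureFit(
        n_components=fit.n_components,
        weights=fit.weights, means=fit.means, sds=fit.sds,
        cutoffs=tuple(sorted(cutoffs)), group_labels=groups,
    )


def gate_genes(expression: Mapping[str, float],
               cutoff: float) -> dict[str, bool]:
    """Map gene -> expressed flag: expressed iff value >= cutoff."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return {gene: bool(value >= cutoff) for gene, value in expression.items()}


def load_expression(path: str | Path,
                    sample: Optional[str] = None) -> pd.Series:
    """Load a tab-separated count table and return log2(count + 1) values.

    Gene identifiers are in the first column. With multiple expression
    columns, ``sample`` selects one; default is the first value column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"expression file {path} has no value columns")
    if sample is None:
        col = df.columns[0]
    elif sample in df.columns:
        col = sample
    else:
        raise ValueError(
            f"sample column {sample!r} not in {path}; has {list(df.columns)}")
    counts = pd.to_numeric(df[col], errors="coerce")
    return np.log2(counts + 1.0)


def expressed_flags(expression: Optional[pd.Series], genes,
                    ks: int = 5, seed: int = 0) -> dict[str, bool]:
    """End-to-end gate for a gene list.

    Without expression data every gene is expressed (the gate is the
    identity). Genes absent from the expression table are treated as
    expressed — there is no evidence of silence — and tallied in the log.
    """
    genes = list(genes)
    if expression is None:
        return {g: True for g in genes}
    fit = derive_cutoff(fit_expression_mixture(expression.values, ks=ks,
                                               seed=seed), seed=seed)
    gated = gate_genes(expression.to_dict(), fit.gate)
    missing = [g for g in genes if g not in gated]
    if missing:
        logger.info("%d genes absent from expression table; treated as expressed",
                    len(missing))
    return {g: gated.get(g, True) for g in genes}
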
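"""Cohort-level phenotypic convergence and pathway frequency tables.

Convergence of a pathway counts the sample pairs that share an altered
member gene: C(S) = sum over member genes of k_g * (k_g - 1) / 2, where
k_g is the number of cohort samples in which gene g is altered. The count
is normalized by the member-gene count and the number of possible sample
pairs, and compared to a null of size-matched random gene sets drawn from
the cohort's assessable gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FREQUENCY_BINS = ("<25%", "25-50%", "50-75%", ">=75%")


@dataclass(frozen=True)
class ConvergenceResult:
    pathway_id: str
    c_raw: int
    c_norm: float
    z: float  # NaN when the null has zero variance
    p_emp: float
    n_random: int


def _column_sums(matrix: pd.DataFrame) -> pd.Series:
    values = matrix.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise ValueError("alteration matrix entries must be 0/1")
    return matrix.sum(axis=0)


def convergence_raw(matrix: pd.DataFrame, members: Iterable[str]) -> int:
    """C(S): total sample pairs sharing an alteration in a member gene."""
    members = set(members)
    present = [g for g in matrix.columns if g in members]
    if not present:
        logger.warning("gene set has no overlap with the alteration matrix")
        return 0
    k = _column_sums(matrix[present]).to_numpy(dtype=np.int64)
    return int((k * (k - 1) // 2).sum())


def convergence_normalized(c_raw: int, n_s: int, m: int) -> float:
    """c_raw / (n_s * m*(m-1)/2): per-gene, per-sample-pair rate."""
    if n_s < 1:
        raise ValueError("n_s must be >= 1")
    if m < 2:
        raise ValueError("need at least 2 samples to form pairs")
    return c_raw / (n_s * m * (m - 1) / 2)


def convergence_null(matrix: pd.DataFrame, members: Iterable[str],
                     n_random: int = 1000, seed: int = 0,
                     pathway_id: str = "") -> ConvergenceResult:
    """Score a gene set against size-matched random sets from the cohort's
    gene universe (all genes in the alteration matrix).

    z = (C_obs - null mean) / null sd; p = plus-one-corrected fraction of
    null scores >= C_obs. Zero null variance leaves z as NaN.
    """
    members = set(members)
    universe = list(matrix.columns)
    present = [g for g in universe if g in members]
    n_s = len(present)
    if n_s < 1:
        raise ValueError("gene set has no overlap with the alteration matrix")
    if n_s >= len(universe):
        raise ValueError("gene universe must be larger than the set")
    m = matrix.shape[0]
    k_all = _column_sums(matrix).to_numpy(dtype=np.int64)
    pairs_all = k_all * (k_all - 1) // 2
    c_obs = convergence_raw(matrix, members)

    rng = np.random.default_rng(seed)
    null = np.empty(n_random, dtype=np.int64)
    for i in range(n_random):
        idx = rng.choice(len(universe), size=n_s, replace=False)
        null[i] = pairs_all[idx].sum()
    sd = float(null.std(ddof=0))
    if sd == 0:
        logger.warning("zero-variance convergence null for %s", pathway_id or "set")
        z = float("nan")
    else:
        z = (c_obs - float(null.mean())) / sd
    p_emp = (1 + int(np.sum(null >= c_obs))) / (n_random + 1)
    return ConvergenceResult(
        pathway_id=pathway_id, c_raw=c_obs,
        c_norm=convergence_normalized(c_obs, n_s, m),
        z=z, p_emp=p_emp, n_random=n_random)


def frequency_bin(fraction: float) -> str:
    if fraction < 0.25:
        return FREQUENCY_BINS[0]
    if fraction < 0.50:
        return FREQUENCY_BINS[1]
    if fraction < 0.75:
        return FREQUENCY_BINS[2]
    return FREQUENCY_BINS[3]


def cohort_frequency(records: Sequence[Mapping[str, pd.DataFrame]]) -> pd.DataFrame:
    """Pathway alteration frequencies across a cohort, per origin.

    ``records`` holds one dict per sample mapping origin -> result table
    (as returned by `run_sample`). Emits per pathway the fraction of
    samples significant per origin, the fraction significant in BOTH
    origins within the same sample, and frequency bins.
    """
    if not records:
        raise ValueError("need at least one sample result")
    sources: set[str] = set()
    per_sample_sig: list[dict[str, set[str]]] = []
    names: dict[str, str] = {}
    all_ids: set[str] = set()
    for sample in records:
        sig: dict[str, set[str]] = {}
        for origin, df in sample.items():
            if len(df):
                sources.update(df["source"].unique())
                names.update(zip(df["pathway_id"], df["name"]))
                all_ids.update(df["pathway_id"])
                sig[origin] = set(df.loc[df["significant"], "pathway_id"])
            else:
                sig[origin] = set()
        per_sample_sig.append(sig)
    if len(sources) > 1:
        raise ValueError(f"mixed annotation sources in one cohort call: {sources}")

    m = len(records)
    rows = []
    for pid in sorted(all_ids):
        row = {"pathway_id": pid, "name": names.get(pid, pid), "n_samples": m}
        for origin in ("somatic", "germline"):
            frac = sum(pid in s.get(origin, set()) for s in per_sample_sig) / m
            row[f"freq_{origin}"] = frac
            row[f"bin_{origin}"] = frequency_bin(frac)
        frac_both = sum(
            pid in s.get("somatic", set()) and pid in s.get("germline", set())
            for s in per_sample_sig) / m
        row["freq_both"] = frac_both
        row["bin_both"] = frequency_bin(frac_both)
        rows.append(row)
    return pd.DataFrame(rows)


def build_alteration_matrix(gene_lists: Mapping[str, Iterable[str]],
                            universe: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Samples x genes binary incidence from per-sample altered-gene lists."""
    samples = sorted(gene_lists)
    if universe is None:
        universe = sorted(set().union(*(set(g) for g in gene_lists.values())))
    else:
        universe = sorted(universe)
    data = np.zeros((len(samples), len(universe)), dtype=np.int8)
    col = {g: j for j, g in enumerate(universe)}
    for i, s in enumerate(samples):
        for g in gene_lists[s]:
            if g in col:
                data[i, col[g]] = 1
    return pd.DataFrame(data, index=samples, columns=universe)
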
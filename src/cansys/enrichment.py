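"""Modified GSEA over gene-level impact scores.

Genes are ranked by impact (descending); for a pathway S the running sum
accumulates P_Hit(S, i) = sum of member impacts up to rank i divided by
the impact total of ALL universe genes (a deliberate departure from
classical GSEA's within-set normalization), minus P_Miss(S, i) =
(#non-members up to i) / (N - N_S). The ES is the maximum of the signed
deviation floored at 0 (positive-scoring convention: only enrichment of
alteration counts as disturbance; a flag restores the absolute-value
form). Significance comes from a gene-permutation null of size-matched
random sets; NES is the ES divided by the null mean, and the pathway
disturbance score is NES times the mean member impact.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from cansys.expression import expressed_flags
from cansys.impact import DependencyTable, build_impact_table
from cansys.variants import AnnotatedVariant, FilterPolicy, apply_filters

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["pathway_id", "name", "source", "origin", "N_S", "ES",
                  "NES", "pval", "padj", "mean_impact", "CanSys", "significant"]


@dataclass(frozen=True)
class GeneSet:
    """One named pathway with its member genes."""

    id: str
    name: str
    genes: frozenset[str]


@dataclass(frozen=True)
class RankedUniverse:
    """Expressed universe genes ordered by impact (desc, symbol asc ties)."""

    genes: tuple[str, ...]
    impacts: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.impacts):
            raise ValueError("genes and impacts length mismatch")
        if np.any(np.diff(self.impacts) > 0):
            raise ValueError("impacts must be sorted non-increasing")
        if len(self.impacts) and self.impacts.min() < 0:
            raise ValueError("impacts must be non-negative")

    @property
    def n_total(self) -> int:
        return len(self.genes)

    @property
    def impact_total(self) -> float:
        return float(self.impacts.sum())

    def positions(self, members: Iterable[str]) -> np.ndarray:
        """Sorted 0-based ranks of the member genes present in the universe."""
        index = getattr(self, "_index", None)
        if index is None:
            index = {g: i for i, g in enumerate(self.genes)}
            object.__setattr__(self, "_index", index)
        pos = sorted(index[g] for g in members if g in index)
        return np.asarray(pos, dtype=np.int64)


@dataclass(frozen=True)
class PermutationResult:
    es_obs: float
    pval: float
    null_mean: float
    nperm: int


@dataclass
class EnrichmentConfig:
    """Knobs for the per-sample enrichment run."""

    nperm_somatic: int = 6000
    nperm_germline: int = 1000
    padj_threshold: float = 0.25
    min_set_size: int = 2
    score_type: str = "pos"  # "pos" | "abs"
    p_hit_denom: str = "total"  # "total" (printed form) | "set" (classical GSEA)
    seed: int = 0

    def nperm_for(self, origin: str) -> int:
        return self.nperm_somatic if origin == "somatic" else self.nperm_germline


def parse_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT file: one set per line, id <tab> description <tab> genes."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: fewer than 3 fields, skipped", path, lineno)
                continue
            set_id, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            sets[set_id] = GeneSet(id=set_id, name=name, genes=genes)
    return sets


def build_universe(impact_table: pd.DataFrame,
                   annotation_genes: Iterable[str],
                   expressed: Mapping[str, bool]) -> RankedUniverse:
    """Rank the expressed annotation-space genes by impact.

    Genes absent from the impact table score 0 but still occupy ranks as
    misses; unexpressed genes are excluded from the universe entirely
    (they do not enter the P_Miss denominator).
    """
    genes = sorted({g for g in annotation_genes if expressed.get(g, True)})
    if not genes:
        raise ValueError("empty expressed universe")
    impact_map = dict(zip(impact_table["gene"], impact_table["impact"])) \
        if len(impact_table) else {}
    order = sorted(genes, key=lambda g: (-impact_map.get(g, 0.0), g))
    impacts = np.array([impact_map.get(g, 0.0) for g in order], dtype=float)
    return RankedUniverse(genes=tuple(order), impacts=impacts)


def enrichment_score(universe: RankedUniverse, members: Iterable[str],
                     score_type: str = "pos",
                     p_hit_denom: str = "total") -> tuple[float, np.ndarray]:
    """Running-sum ES for one gene set, with the full deviation trace.

    Returns (es, trace) where trace[i] = P_Hit(S, i+1) - P_Miss(S, i+1)
    for every rank. Requires 1 <= N_S < N and a positive impact total.

    ``p_hit_denom`` selects the P_Hit normalization: ``"total"`` divides by
    the impact sum over ALL universe genes; ``"set"`` divides by the
    member-impact sum (the classical GSEA / fgsea statistic, whose null has
    no atom at 0 and therefore yields calibrated permutation p-values).
    """
    n = universe.n_total
    pos = universe.positions(members)
    n_s = len(pos)
    if not 1 <= n_s < n:
        raise ValueError(f"need 1 <= N_S < N (N_S={n_s}, N={n})")
    if p_hit_denom not in ("total", "set"):
        raise ValueError(f"unknown p_hit_denom {p_hit_denom!r}")
    if universe.impact_total <= 0:
        raise ValueError("impact_total must be positive")
    total = universe.impact_total if p_hit_denom == "total" \
        else float(universe.impacts[pos].sum())
    hit = np.zeros(n, dtype=bool)
    hit[pos] = True
    if total == 0:  # "set" mode with all-zero members: flat P_Hit
        p_hit = np.zeros(n)
    else:
        p_hit = np.cumsum(np.where(hit, universe.impacts, 0.0)) / total
    p_miss = np.cumsum(~hit) / (n - n_s)
    trace = p_hit - p_miss
    if score_type == "pos":
        es = max(0.0, float(trace.max()))
    elif score_type == "abs":
        es = float(np.abs(trace).max())
    else:
        raise ValueError(f"unknown score_type {score_type!r}")
    return es, trace


def _es_from_positions(positions: np.ndarray, impacts: np.ndarray,
                       impact_total: float, n: int,
                       score_type: str = "pos",
                       p_hit_denom: str = "total") -> np.ndarray:
    """Vectorized ES for rows of sorted member rank positions.

    Between hits the running deviation only decreases, so its maximum is
    attained immediately after a hit; evaluating the deviation at each hit
    suffices. ``positions`` is (n_rows, n_s), sorted ascending per row.
    """
    n_s = positions.shape[1]
    denom_miss = n - n_s
    cum_raw = np.cumsum(impacts[positions], axis=1)
    if p_hit_denom == "total":
        cum_hit = cum_raw / impact_total
    else:
        member_sum = cum_raw[:, -1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            cum_hit = np.where(member_sum > 0, cum_raw / member_sum, 0.0)
    t = np.arange(n_s)
    dev_at_hits = cum_hit - (positions - t) / denom_miss
    max_dev = dev_at_hits.max(axis=1)
    if score_type == "pos":
        return np.maximum(max_dev, 0.0)
    # abs convention: deepest trough occurs just before a hit or at the end.
    prev_cum_hit = np.concatenate(
        [np.zeros((cum_hit.shape[0], 1)), cum_hit[:, :-1]], axis=1)
    trough_before = prev_cum_hit - (positions - t) / denom_miss
    end_val = cum_hit[:, -1] - (n - n_s) / denom_miss  # = P_Hit(N) - 1
    min_dev = np.minimum(trough_before.min(axis=1), end_val)
    return np.maximum(max_dev, -min_dev)


def _sample_subsets(rng: np.random.Generator, nperm: int, n: int,
                    s: int) -> np.ndarray:
    """nperm uniform random s-subsets of range(n), rows sorted ascending.

    Uses rejection sampling (uniform with replacement conditioned on
    distinctness) when collisions are rare, else chunked argpartition of
    random keys; both are exactly uniform over subsets.
    """
    if s >= n:
        raise ValueError("subset size must be < universe size")
    if s * s <= n:  # collision probability ~ s^2 / 2n
        draws = rng.integers(0, n, size=(nperm, s))
        draws.sort(axis=1)
        while True:
            if s == 1:
                break
            bad = np.flatnonzero((np.diff(draws, axis=1) == 0).any(axis=1))
            if bad.size == 0:
                break
            redo = rng.integers(0, n, size=(bad.size, s))
            redo.sort(axis=1)
            draws[bad] = redo
        return draws
    out = np.empty((nperm, s), dtype=np.int64)
    chunk = max(1, int(2e7) // max(n, 1))
    for start in range(0, nperm, chunk):
        stop = min(start + chunk, nperm)
        keys = rng.random((stop - start, n))
        part = np.argpartition(keys, s - 1, axis=1)[:, :s]
        part.sort(axis=1)
        out[start:stop] = part
    return out


def permutation_test(universe: RankedUniverse, members: Iterable[str],
                     nperm: int, seed: int | np.random.SeedSequence,
                     score_type: str = "pos",
                     p_hit_denom: str = "total") -> PermutationResult:
    """Gene-permutation null: nperm size-matched random sets on the fixed
    ranking; plus-one-corrected empirical p and the null ES mean."""
    if nperm < 100:
        raise ValueError("nperm must be >= 100")
    pos = universe.positions(members)
    n, n_s = universe.n_total, len(pos)
    if n_s >= n:
        raise ValueError(f"N_S ({n_s}) must be < N ({n})")
    if n_s < 1:
        raise ValueError("gene set is disjoint from the universe")
    rng = np.random.default_rng(seed)
    perms = _sample_subsets(rng, nperm, n, n_s)
    es_obs = float(_es_from_positions(pos[None, :], universe.impacts,
                                      universe.impact_total, n, score_type,
                                      p_hit_denom)[0])
    es_null = _es_from_positions(perms, universe.impacts,
                                 universe.impact_total, n, score_type,
                                 p_hit_denom)
    n_ge = int(np.sum(es_null >= es_obs - 1e-12))
    pval = (1 + n_ge) / (nperm + 1)
    return PermutationResult(es_obs=es_obs, pval=pval,
                             null_mean=float(es_null.mean()), nperm=nperm)


def normalize_es(es_obs: float, null_mean: float) -> float:
    """NES = ES divided by the permutation-null mean ES."""
    if null_mean < 0:
        raise ValueError("null_mean must be non-negative")
    if null_mean == 0:
        if es_obs == 0:
            return 0.0
        logger.warning("null mean is 0 with positive ES; NES undefined")
        return float("nan")
    return es_obs / null_mean


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def cansys_score(nes: float, member_impacts: Sequence[float], n_s: int) -> float:
    """Pathway disturbance score: NES times the mean member impact."""
    if n_s < 1:
        raise ValueError("n_s must be >= 1")
    return nes * (float(np.sum(member_impacts)) / n_s)


def _pathway_seed(master_seed: int, pathway_id: str) -> np.random.SeedSequence:
    """Per-pathway RNG stream: master seed + stable id hash, so results do
    not depend on pathway iteration order."""
    return np.random.SeedSequence([master_seed, zlib.crc32(pathway_id.encode())])


def enrich_gene_sets(universe: RankedUniverse,
                     gene_sets: Mapping[str, GeneSet],
                     nperm: int,
                     config: EnrichmentConfig,
                     source: str,
                     origin: str) -> pd.DataFrame:
    """Score every gene set against one ranked universe.

    Sets with fewer than ``config.min_set_size`` universe members (or not
    strictly smaller than the universe) are skipped and logged. BH
    adjustment runs across the emitted family.
    """
    rows = []
    skipped = []
    degenerate = universe.impact_total <= 0
    for set_id in sorted(gene_sets):
        gs = gene_sets[set_id]
        pos = universe.positions(gs.genes)
        n_s = len(pos)
        if n_s < config.min_set_size or n_s >= universe.n_total:
            skipped.append(set_id)
            continue
        member_impacts = universe.impacts[pos]
        mean_impact = float(member_impacts.mean())
        if degenerate:
            rows.append({"pathway_id": set_id, "name": gs.name, "source": source,
                         "origin": origin, "N_S": n_s, "ES": 0.0, "NES": 0.0,
                         "pval": 1.0, "mean_impact": mean_impact})
            continue
        perm = permutation_test(universe, gs.genes, nperm,
                                _pathway_seed(config.seed, set_id),
                                score_type=config.score_type,
                                p_hit_denom=config.p_hit_denom)
        nes = normalize_es(perm.es_obs, perm.null_mean)
        rows.append({"pathway_id": set_id, "name": gs.name, "source": source,
                     "origin": origin, "N_S": n_s, "ES": perm.es_obs,
                     "NES": nes, "pval": perm.pval, "mean_impact": mean_impact})
    if skipped:
        logger.info("skipped %d gene sets outside [%d, N) universe overlap",
                    len(skipped), config.min_set_size)
    df = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS
                                     if c not in ("padj", "CanSys", "significant")])
    if len(df) == 0:
        for c in ("padj", "CanSys", "significant"):
            df[c] = []
        return df[RESULT_COLUMNS]
    df["padj"] = bh_adjust(df["pval"].to_numpy())
    df["CanSys"] = df["NES"] * df["mean_impact"]
    df["significant"] = df["padj"] < config.padj_threshold
    return df[RESULT_COLUMNS]


def run_sample(variants_by_origin: Mapping[str, list[AnnotatedVariant]],
               expression: Optional[pd.Series],
               gene_sets: Mapping[str, GeneSet],
               dependency: DependencyTable,
               config: EnrichmentConfig,
               policies: Optional[Mapping[str, FilterPolicy]] = None,
               source: str = "GO") -> dict[str, pd.DataFrame]:
    """Full single-sample pipeline per origin.

    ``variants_by_origin`` holds annotated (unfiltered) variants; each
    origin runs through its filter policy, gene scoring, ranking, and the
    permutation-based enrichment. Returns origin -> result table.
    """
    if policies is None:
        policies = {"somatic": FilterPolicy.somatic_default(),
                    "germline": FilterPolicy.germline_default()}
    annotation_genes = sorted(set().union(*(gs.genes for gs in gene_sets.values()))) \
        if gene_sets else []
    if not annotation_genes:
        raise ValueError("no annotation genes: empty gene set collection")

    results: dict[str, pd.DataFrame] = {}
    for origin, variants in variants_by_origin.items():
        retained, tally = apply_filters(variants, policies[origin])
        logger.info("%s: %s", origin, tally.as_dict())
        altered = {v.gene for v in retained if v.gene is not None}
        flags = expressed_flags(expression,
                                sorted(set(annotation_genes) | altered),
                                seed=config.seed)
        impact_table = build_impact_table(retained, dependency, flags)
        if len(impact_table) == 0:
            results[origin] = pd.DataFrame(columns=RESULT_COLUMNS)
            continue
        universe = build_universe(impact_table, annotation_genes, flags)
        results[origin] = enrich_gene_sets(
            universe, gene_sets, config.nperm_for(origin), config,
            source=source, origin=origin)
    return results


def write_records(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited per-sample results for spreadsheet import."""
    df.to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    return df
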
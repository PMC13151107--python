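"""Gene-level scoring: scaled mean CADD, dependency averages, impact.

The gene-level CADD score for a gene with N qualifying variants is
sum(CADD Phred) / (100 * N), so it lives in [0, 0.99]. The impact score
is that value multiplied by the gene's lineage-averaged DepMap dependency
probability, zeroed when the gene is not expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from cansys.variants import AnnotatedVariant

logger = logging.getLogger(__name__)

PAN_CANCER = "pan-cancer"


@dataclass(frozen=True)
class DependencyTable:
    """Per-gene dependency scores averaged over one lineage's cell lines."""

    scores: pd.Series  # gene -> score in [0, 1]
    lineage: str
    n_cell_lines: int

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy(dtype=float)
        if len(vals) and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
            raise ValueError("dependency scores must lie in [0, 1]")

    def get(self, gene: str) -> float:
        """Score for ``gene``; 0 for genes absent from the matrix."""
        val = self.scores.get(gene)
        return 0.0 if val is None or pd.isna(val) else float(val)


def gene_cadd_score(cadd_phreds: Sequence[float]) -> float:
    """Scaled mean CADD: sum of Phred scores over (100 * N)."""
    if len(cadd_phreds) == 0:
        raise ValueError("gene_cadd_score needs >= 1 contributing variant")
    return float(sum(cadd_phreds)) / (100.0 * len(cadd_phreds))


def gene_impact(gene_cadd: float, gene_depmap: float, expressed: bool) -> float:
    """Impact = gene_cadd * gene_depmap, forced to 0 when not expressed."""
    if not 0.0 <= gene_cadd <= 0.99:
        raise ValueError(f"gene_cadd out of [0, 0.99]: {gene_cadd}")
    if not 0.0 <= gene_depmap <= 1.0:
        raise ValueError(f"gene_depmap out of [0, 1]: {gene_depmap}")
    if not expressed:
        return 0.0
    return gene_cadd * gene_depmap


def average_dependency(dependency_matrix: pd.DataFrame,
                       lineage_map: Mapping[str, str],
                       lineage: str) -> DependencyTable:
    """Average a gene x cell-line dependency matrix over one lineage.

    The ``"pan-cancer"`` lineage averages over every cell line. Missing
    entries are excluded from the mean; genes with no data in the lineage
    get 0 and are flagged in the log.
    """
    if lineage == PAN_CANCER:
        cols = list(dependency_matrix.columns)
    else:
        cols = [c for c in dependency_matrix.columns
                if lineage_map.get(c) == lineage]
        if not cols:
            available = sorted(set(lineage_map.values()))
            raise ValueError(
                f"no cell lines labelled {lineage!r}; available lineages: "
                f"{available} (or {PAN_CANCER!r})")
    sub = dependency_matrix[cols].astype(float)
    scores = sub.mean(axis=1, skipna=True)
    n_empty = int(scores.isna().sum())
    if n_empty:
        logger.info("%d genes with no dependency data in lineage %s; scored 0",
                    n_empty, lineage)
    return DependencyTable(scores=scores.fillna(0.0), lineage=lineage,
                           n_cell_lines=len(cols))


def load_dependency_matrix(path: str | Path) -> pd.DataFrame:
    """Tab-separated gene x cell-line matrix, genes in rows."""
    return pd.read_csv(path, sep="\t", index_col=0)


def load_lineage_map(path: str | Path) -> dict[str, str]:
    """Two-column cell-line -> lineage label table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_dependency_table(path: str | Path,
                          lineage: str = "precomputed") -> DependencyTable:
    """Precomputed two-column gene -> lineage-averaged score table."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DependencyTable(scores=df.iloc[:, 0].astype(float),
                           lineage=lineage, n_cell_lines=0)


def build_impact_table(variants: Iterable[AnnotatedVariant],
                       dependency: DependencyTable,
                       expressed: Mapping[str, bool]) -> pd.DataFrame:
    """Per-gene impact table for one sample / origin.

    Only altered genes (>= 1 qualifying variant with a gene assignment and
    a CADD score) get a row; genes missing from ``expressed`` default to
    expressed. Columns: gene, n_variants, gene_cadd, gene_depmap,
    expressed, impact.
    """
    per_gene: dict[str, list[float]] = {}
    n_no_gene = 0
    for v in variants:
        if v.gene is None:
            n_no_gene += 1
            continue
        if v.cadd_phred is None:
            continue
        per_gene.setdefault(v.gene, []).append(v.cadd_phred)
    if n_no_gene:
        logger.info("%d retained variants map to no gene", n_no_gene)

    rows = []
    for gene in sorted(per_gene):
        cadds = per_gene[gene]
        gc = gene_cadd_score(cadds)
        gd = dependency.get(gene)
        is_expr = bool(expressed.get(gene, True))
        rows.append({
            "gene": gene, "n_variants": len(cadds), "gene_cadd": gc,
            "gene_depmap": gd, "expressed": is_expr,
            "impact": gene_impact(gc, gd, is_expr),
        })
    return pd.DataFrame(
        rows, columns=["gene", "n_variants", "gene_cadd", "gene_depmap",
                       "expressed", "impact"])
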
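"""Synthetic, self-consistent test inputs with controllable signal.

Generates VCFs, annotation lookup tables, dependency matrices, expression
counts, GMT gene sets, toy OBO ontologies and KEGG edge lists so every
pipeline stage is exercisable without downloads. Designated "disturbed"
pathways concentrate high-deleteriousness variants in essential genes so
ground truth is recoverable end to end; all output is byte-identical for
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from cansys.graphs import GO_ROOT

_CHROMS = ("chr1", "chr2", "chr3")
_BASES = ("A", "C", "G", "T")


@dataclass
class FixtureSpec:
    """Controls for synthetic sample / cohort generation."""

    n_genes: int = 400
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (8, 25)
    n_disturbed: int = 1
    n_variants_somatic: int = 150
    n_variants_germline: int = 150
    signal_fraction: float = 0.9  # share of passing variants in disturbed genes
    frac_silent: float = 0.15
    expr_low: tuple[float, float] = (0.5, 0.3)  # (mean, sd) of log2 counts
    expr_high: tuple[float, float] = (8.0, 1.0)
    cohort_size: int = 20
    n_convergent: int = 1
    convergent_genes_per_sample: int = 3
    background_genes_per_sample: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.pathway_size_range
        if hi > self.n_genes:
            raise ValueError("pathway size exceeds gene count")
        if not (0 <= self.signal_fraction <= 1):
            raise ValueError("signal_fraction must be in [0, 1]")
        for name in ("n_genes", "n_pathways", "n_disturbed", "cohort_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_disturbed > self.n_pathways:
            raise ValueError("more disturbed pathways than pathways")


@dataclass
class SampleFixture:
    """Paths and ground truth for one generated sample."""

    somatic_vcf: Path
    germline_vcf: Path
    expression: Path
    cadd_table: Path
    gnomad_table: Path
    gene_table: Path
    dependency_matrix: Path
    lineage_map: Path
    dependency_table: Path
    gmt: Path
    genes: list[str]
    gene_sets: dict[str, list[str]]
    disturbed_pathways: list[str]
    silent_genes: list[str]


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _make_gene_sets(rng: np.random.Generator, genes: list[str],
                    spec: FixtureSpec) -> dict[str, list[str]]:
    lo, hi = spec.pathway_size_range
    sets = {}
    for p in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"SET{p:04d}"] = sorted(genes[i] for i in members)
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: Path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(gene_sets):
            genes = "\t".join(gene_sets[set_id])
            fh.write(f"{set_id}\t{set_id} synthetic pathway\t{genes}\n")


def _write_vcf(path: Path, rows: list[tuple[str, int, str, str, int, int]]) -> None:
    """rows: (chrom, pos, ref, alt, allele_depth, total_depth)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in _CHROMS:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for chrom, pos, ref, alt, ad, dp in sorted(
                rows, key=lambda r: (_CHROMS.index(r[0]), r[1])):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
                     f"GT:AD:DP\t0/1:{dp - ad},{ad}:{dp}\n")


def _write_lookup(path: Path, entries: list[tuple[str, int, str, str, object]],
                  value_name: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"chrom\tpos\tref\talt\t{value_name}\n")
        for chrom, pos, ref, alt, value in sorted(entries, key=lambda e: (e[0], e[1])):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\t{value}\n")


def _draw_variants(rng: np.random.Generator, genes: list[str],
                   signal_genes: list[str], n_variants: int,
                   signal_fraction: float, origin: str,
                   positions: set[tuple[str, int]]):
    """Returns (vcf_rows, cadd_entries, gnomad_entries, gene_entries)."""
    vcf_rows, cadds, afs, gene_entries = [], [], [], []
    background = [g for g in genes if g not in set(signal_genes)]
    for _ in range(n_variants):
        while True:
            chrom = _CHROMS[int(rng.integers(len(_CHROMS)))]
            pos = int(rng.integers(1_000, 5_000_000))
            if (chrom, pos) not in positions:
                positions.add((chrom, pos))
                break
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        is_signal = bool(rng.random() < signal_fraction) and signal_genes
        if is_signal:
            gene = signal_genes[int(rng.integers(len(signal_genes)))]
            cadd = float(rng.uniform(25.0, 40.0))
        else:
            gene = background[int(rng.integers(len(background)))]
            # Mostly sub-threshold deleteriousness; a few pass the CADD gate.
            cadd = float(rng.uniform(15.0, 22.0)) if rng.random() < 0.3 \
                else float(rng.uniform(0.0, 10.0))
        dp = int(rng.integers(50, 200))
        vaf = float(rng.uniform(0.30, 0.60)) if origin == "germline" \
            else float(rng.uniform(0.10, 0.60))
        ad = max(5, int(round(dp * vaf)))
        af = float(rng.uniform(0.0, 0.001)) if origin == "germline" else \
            float(rng.uniform(0.0, 0.01))
        vcf_rows.append((chrom, pos, str(ref), str(alt), ad, dp))
        cadds.append((chrom, pos, str(ref), str(alt), f"{cadd:.3f}"))
        afs.append((chrom, pos, str(ref), str(alt), f"{af:.6f}"))
        gene_entries.append((chrom, pos, str(ref), str(alt), gene))
    return vcf_rows, cadds, afs, gene_entries


def make_sample(spec: FixtureSpec, outdir: str | Path) -> SampleFixture:
    """Write one synthetic sample's full input bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    gene_sets = _make_gene_sets(rng, genes, spec)
    disturbed = sorted(gene_sets)[:spec.n_disturbed]
    signal_genes = sorted(set().union(*(gene_sets[p] for p in disturbed)))

    # Dependency: essential in disturbed pathways, weak elsewhere; the
    # matrix carries 3 fixture cell lines whose mean is the target score.
    target = {}
    for g in genes:
        if g in set(signal_genes):
            target[g] = float(rng.uniform(0.75, 1.0))
        else:
            target[g] = float(rng.uniform(0.02, 0.5))
    cell_lines = ["CL1", "CL2", "CL3"]
    noise = rng.uniform(-0.02, 0.02, size=(len(genes), len(cell_lines)))
    matrix = np.clip(np.array([target[g] for g in genes])[:, None] + noise, 0.0, 1.0)
    dep_df = pd.DataFrame(matrix, index=genes, columns=cell_lines).round(6)
    dep_path = outdir / "depmap_matrix.tsv"
    dep_df.to_csv(dep_path, sep="\t", index_label="gene")
    lineage_path = outdir / "lineages.tsv"
    with open(lineage_path, "w") as fh:
        fh.write("cell_line\tlineage\n")
        for cl in cell_lines:
            fh.write(f"{cl}\tfixture\n")
    pre_path = outdir / "depmap_precomputed.tsv"
    dep_df.mean(axis=1).round(6).rename("score").to_csv(pre_path, sep="\t",
                                                        index_label="gene")

    # Expression: silent genes drawn from the low log-count component.
    non_signal = [g for g in genes if g not in set(signal_genes)]
    n_silent = int(round(spec.frac_silent * len(non_signal)))
    silent_idx = rng.choice(len(non_signal), size=n_silent, replace=False)
    silent = sorted(non_signal[i] for i in silent_idx)
    silent_set = set(silent)
    expr_path = outdir / "expression.tsv"
    with open(expr_path, "w") as fh:
        fh.write("gene\tSAMPLE\n")
        for g in genes:
            mu, sd = spec.expr_low if g in silent_set else spec.expr_high
            logval = max(0.0, float(rng.normal(mu, sd)))
            count = 2.0 ** logval - 1.0
            fh.write(f"{g}\t{count:.4f}\n")

    positions: set[tuple[str, int]] = set()
    som = _draw_variants(rng, genes, signal_genes, spec.n_variants_somatic,
                         spec.signal_fraction, "somatic", positions)
    germ = _draw_variants(rng, genes, signal_genes, spec.n_variants_germline,
                          spec.signal_fraction, "germline", positions)

    som_vcf = outdir / "somatic.vcf"
    germ_vcf = outdir / "germline.vcf"
    _write_vcf(som_vcf, som[0])
    _write_vcf(germ_vcf, germ[0])
    cadd_path = outdir / "cadd.tsv"
    gnomad_path = outdir / "gnomad.tsv"
    gene_path = outdir / "genes.tsv"
    _write_lookup(cadd_path, som[1] + germ[1], "cadd_phred")
    _write_lookup(gnomad_path, som[2] + germ[2], "gnomad_af")
    _write_lookup(gene_path, som[3] + germ[3], "gene")

    gmt_path = outdir / "pathways.gmt"
    write_gmt(gene_sets, gmt_path)

    return SampleFixture(
        somatic_vcf=som_vcf, germline_vcf=germ_vcf, expression=expr_path,
        cadd_table=cadd_path, gnomad_table=gnomad_path, gene_table=gene_path,
        dependency_matrix=dep_path, lineage_map=lineage_path,
        dependency_table=pre_path, gmt=gmt_path,
        genes=genes, gene_sets=gene_sets, disturbed_pathways=disturbed,
        silent_genes=silent,
    )


@dataclass
class CohortFixture:
    """Alteration incidence for a synthetic cohort with engineered
    convergence in designated pathways."""

    altered_genes: dict[str, list[str]]  # sample -> altered gene list
    gene_sets: dict[str, list[str]]
    convergent_pathways: list[str]
    genes: list[str]


def make_cohort(spec: FixtureSpec,
                outdir: Optional[str | Path] = None) -> CohortFixture:
    """Generate per-sample altered-gene lists for a cohort of size M.

    Samples alter different member genes of each designated convergent
    pathway (phenotypic convergence by construction) plus random
    background genes. With ``outdir`` set, the binary alteration matrix is
    written as a tab-separated file.
    """
    if spec.cohort_size < 2:
        raise ValueError("cohort needs M >= 2")
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    gene_sets = _make_gene_sets(rng, genes, spec)
    convergent = sorted(gene_sets)[:spec.n_convergent]

    altered: dict[str, list[str]] = {}
    for s in range(spec.cohort_size):
        sample = f"S{s:03d}"
        hit: set[str] = set()
        for p in convergent:
            members = gene_sets[p]
            k = min(spec.convergent_genes_per_sample, len(members))
            idx = rng.choice(len(members), size=k, replace=False)
            hit.update(members[i] for i in idx)
        idx = rng.choice(len(genes), size=spec.background_genes_per_sample,
                         replace=False)
        hit.update(genes[i] for i in idx)
        altered[sample] = sorted(hit)

    if outdir is not None:
        from cansys.convergence import build_alteration_matrix
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        build_alteration_matrix(altered, genes).to_csv(
            outdir / "alterations.tsv", sep="\t", index_label="sample")
        write_gmt(gene_sets, outdir / "pathways.gmt")
    return CohortFixture(altered_genes=altered, gene_sets=gene_sets,
                         convergent_pathways=convergent, genes=genes)


@dataclass
class OntologyFixture:
    obo: Path
    gmt: Path
    kegg_edges: Path
    terms: list[str]
    edges: list[tuple[str, str, str]]  # child, parent, relation


def make_toy_ontology(n_terms: int = 30, n_genes: int = 200,
                      seed: int = 0, outdir: str | Path = ".",
                      nested: bool = True) -> OntologyFixture:
    """Write a rooted toy DAG (OBO), a consistent GMT, and a KEGG edge list.

    Terms are arranged in levels under the standard biological-process
    root; each term links to 1-2 parents with mixed relation types. With
    ``nested=True`` a child term's genes are a subset of each parent's.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = _gene_names(n_genes)
    terms = [GO_ROOT] + [f"GO:{7_000_000 + i:07d}" for i in range(1, n_terms)]
    relations = ("is_a", "part_of", "regulates",
                 "positively_regulates", "negatively_regulates")

    edges: list[tuple[str, str, str]] = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = relations[int(rng.integers(len(relations)))] if p != 0 else "is_a"
            edges.append((terms[i], terms[int(p)], rel))

    # Gene assignment top-down so children nest inside parents.
    term_genes: dict[str, set[str]] = {GO_ROOT: set(genes)}
    parents_of: dict[str, list[str]] = {}
    for child, parent, _rel in edges:
        parents_of.setdefault(child, []).append(parent)
    for i in range(1, n_terms):
        term = terms[i]
        if nested:
            pool = sorted(set.intersection(
                *(term_genes[p] for p in parents_of[term])))
        else:
            pool = genes
        size = max(2, int(rng.integers(2, max(3, len(pool) // 2 + 1))))
        size = min(size, len(pool))
        chosen = rng.choice(len(pool), size=size, replace=False)
        term_genes[term] = {pool[j] for j in chosen}

    obo_path = outdir / "toy.obo"
    with open(obo_path, "w") as fh:
        fh.write("format-version: 1.4\nontology: toy\n\n")
        for term in terms:
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            name = "biological_process" if term == GO_ROOT else f"process {term[-5:]}"
            fh.write(f"name: {name}\n")
            fh.write("namespace: biological_process\n")
            for child, parent, rel in edges:
                if child == term:
                    if rel == "is_a":
                        fh.write(f"is_a: {parent} ! {parent}\n")
                    else:
                        fh.write(f"relationship: {rel} {parent} ! {parent}\n")
            fh.write("\n")

    gmt_path = outdir / "toy.gmt"
    write_gmt({t: sorted(g) for t, g in term_genes.items()}, gmt_path)

    kegg_path = outdir / "toy_kegg.tsv"
    with open(kegg_path, "w") as fh:
        n_kegg_edges = max(1, n_terms)
        seen = set()
        for _ in range(n_kegg_edges * 3):
            if len(seen) >= n_kegg_edges:
                break
            a, b = rng.choice(n_terms, size=2, replace=False)
            pair = tuple(sorted((f"hsa{a:05d}", f"hsa{b:05d}")))
            if pair not in seen:
                seen.add(pair)
                fh.write(f"{pair[0]}\t{pair[1]}\n")

    return OntologyFixture(obo=obo_path, gmt=gmt_path, kegg_edges=kegg_path,
                           terms=terms, edges=edges)
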
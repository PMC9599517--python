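"""Presence/absence accounting over orthogroups.

The presence matrix counts orthogroup members per genome (a cell may
exceed 1 when a genome carries paralogs).  A gene is *shared* iff its
orthogroup spans two or more genomes; paralog families confined to a
single genome count as unique, as do singletons.  The pairwise shared
orthogroup percentage is protein-weighted: out of all proteins of the
two genomes, the fraction belonging to orthogroups present in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .orthology import OrthoGroup
from .records import Gene

__all__ = [
    "build_presence_matrix",
    "core_orthogroups",
    "classify_shared_unique",
    "shared_og_percent",
    "shared_og_percent_unweighted",
    "pangenome_summary",
    "PangenomeSummary",
]


@dataclass
class PangenomeSummary:
    total_genes: int
    genes_in_orthogroups_pct: float
    n_orthogroups: int
    n_core: int
    shared_per_genome: dict[str, int]
    unique_per_genome: dict[str, int]


def build_presence_matrix(
    orthogroups: Sequence[OrthoGroup],
    genome_of: Mapping[str, str],
    genomes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Genome-by-orthogroup member-count matrix (0 = absent)."""
    genome_ids = sorted(genomes) if genomes is not None else sorted(
        {genome_of[m] for og in orthogroups for m in og.members}
    )
    mat = pd.DataFrame(
        0, index=pd.Index(genome_ids, name="genome"),
        columns=pd.Index([og.id for og in orthogroups], name="orthogroup"),
        dtype=int,
    )
    for og in orthogroups:
        for m in og.members:
            g = genome_of.get(m)
            if g is None:
                raise KeyError(f"gene {m} maps to no known genome")
            if g not in mat.index:
                raise KeyError(f"gene {m}: genome {g} not in matrix")
            mat.loc[g, og.id] += 1
    return mat


def core_orthogroups(matrix: pd.DataFrame) -> list[str]:
    """Orthogroups present (count > 0) in every genome."""
    if matrix.empty:
        raise ValueError("empty presence matrix")
    if len(matrix.index) == 1:
        warnings.warn("single-genome matrix: every orthogroup is trivially core")
    return [c for c in matrix.columns if (matrix[c] > 0).all()]


def classify_shared_unique(
    orthogroups: Sequence[OrthoGroup],
    genes: Sequence[Gene] | Sequence[str],
    genome_of: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Per-gene label: 'shared' iff its orthogroup spans >= 2 genomes.

    Genes absent from every orthogroup (singletons) and members of
    paralog families confined to one genome are 'unique'.
    """
    gene_ids = [g.id if isinstance(g, Gene) else g for g in genes]
    multi: set[str] = set()
    for og in orthogroups:
        if len(og.genomes) >= 2:
            multi.update(og.members)
    return {gid: ("shared" if gid in multi else "unique") for gid in gene_ids}


def shared_og_percent(
    matrix: pd.DataFrame, genome_a: str, genome_b: str
) -> float:
    """Protein-weighted shared-orthogroup percentage for one genome pair.

    100 x (proteins of a and b that belong to orthogroups present in
    both) / (total proteins of a and b counted in the matrix).  Genes
    outside any orthogroup contribute to neither numerator nor the
    matrix row sums; callers wanting unique genes in the denominator
    should pass total gene counts to :func:`pangenome_summary` instead.
    """
    for g in (genome_a, genome_b):
        if g not in matrix.index:
            raise KeyError(f"genome {g} not in matrix")
    a, b = matrix.loc[genome_a], matrix.loc[genome_b]
    mutual = (a > 0) & (b > 0)
    total = a.sum() + b.sum()
    if total == 0:
        return 0.0
    return 100.0 * (a[mutual].sum() + b[mutual].sum()) / total


def shared_og_percent_unweighted(
    matrix: pd.DataFrame, genome_a: str, genome_b: str
) -> float:
    """Jaccard (percent) over orthogroup sets, each group counted once."""
    a, b = matrix.loc[genome_a] > 0, matrix.loc[genome_b] > 0
    union = (a | b).sum()
    if union == 0:
        return 0.0
    return 100.0 * (a & b).sum() / union


def pangenome_summary(
    matrix: pd.DataFrame,
    orthogroups: Sequence[OrthoGroup],
    genes: Sequence[Gene] | Sequence[str],
    genome_of: Mapping[str, str],
) -> PangenomeSummary:
    """Aggregate pan/core/shared/unique statistics over all genes."""
    gene_ids = [g.id if isinstance(g, Gene) else g for g in genes]
    if not gene_ids:
        warnings.warn("no genes supplied; summary is all zeros")
        return PangenomeSummary(0, 0.0, 0, 0, {}, {})
    labels = classify_shared_unique(orthogroups, gene_ids)
    shared: dict[str, int] = {g: 0 for g in matrix.index}
    unique: dict[str, int] = {g: 0 for g in matrix.index}
    for gid in gene_ids:
        genome = genome_of[gid]
        shared.setdefault(genome, 0)
        unique.setdefault(genome, 0)
        if labels[gid] == "shared":
            shared[genome] += 1
        else:
            unique[genome] += 1
    total = len(gene_ids)
    n_shared = sum(shared.values())
    return PangenomeSummary(
        total_genes=total,
        genes_in_orthogroups_pct=100.0 * n_shared / total,
        n_orthogroups=sum(1 for og in orthogroups if len(og.genomes) >= 2),
        n_core=len(core_orthogroups(matrix)) if not matrix.empty else 0,
        shared_per_genome=shared,
        unique_per_genome=unique,
    )
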
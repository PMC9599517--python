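"""End-to-end analysis passes over a genome collection.

Chains the pipeline stages — circularization of linear contigs, ORF
statistics, marker-gene screening, orthogroup clustering, pan-genome
accounting, dual-tree clade delineation, and T8SS module analysis —
into one report.  Used by the command-line interface and by the
reproduction script; every number it returns is computed from its
inputs at call time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import circularize as circ
from . import genecall, modules, orthology, pangenome, phylo
from .records import Gene, GenomeRecord

__all__ = ["PangenomeAnalysis", "analyze_genomes", "marker_alignments"]


@dataclass
class PangenomeAnalysis:
    n_genomes: int
    presence: "object"
    orthogroups: list
    singletons: list[str]
    core: list[str]
    summary: "object"
    clades: list
    aai_within: float
    aai_between: float
    extras: dict = field(default_factory=dict)


def proteins_of(genomes: Sequence[GenomeRecord]) -> dict[str, dict[str, str]]:
    return {g.id: {x.id: x.protein for x in g.genes} for g in genomes}


def marker_alignments(
    genomes: Sequence[GenomeRecord],
    orthogroups,
    marker_label: str = "DNA polymerase A",
    n_multigene: int = 4,
) -> tuple[dict[str, str], dict[str, str]]:
    """Single-marker and concatenated multigene alignments from
    single-copy core orthogroups.

    The marker orthogroup is the core group whose members carry
    ``marker_label``; the multigene alignment concatenates the next
    ``n_multigene`` single-copy core groups.  Proteins within a group
    share a length by construction of the upstream steps (no-indel
    orthologs), so concatenation is a valid alignment.
    """
    gene_info = {x.id: x for g in genomes for x in g.genes}
    genome_ids = [g.id for g in genomes]
    single_copy_core = []
    for og in orthogroups:
        if set(og.genomes) != set(genome_ids):
            continue
        per_genome: dict[str, int] = {}
        lengths = set()
        for m in og.members:
            gene = gene_info[m]
            per_genome[gene.genome_id] = per_genome.get(gene.genome_id, 0) + 1
            lengths.add(len(gene.protein))
        if all(v == 1 for v in per_genome.values()) and len(lengths) == 1:
            single_copy_core.append(og)

    marker = None
    for og in single_copy_core:
        labels = {gene_info[m].label for m in og.members}
        if marker_label in labels:
            marker = og
            break
    if marker is None:
        raise ValueError(f"no single-copy core orthogroup labeled {marker_label!r}")
    others = [og for og in single_copy_core if og.id != marker.id][:n_multigene]
    if not others:
        raise ValueError("no core orthogroups left for the multigene alignment")

    def build(ogs) -> dict[str, str]:
        rows: dict[str, list[tuple[str, str]]] = {gid: [] for gid in genome_ids}
        for og in ogs:
            for m in og.members:
                gene = gene_info[m]
                rows[gene.genome_id].append((og.id, gene.protein))
        return {gid: "".join(p for _, p in sorted(parts)) for gid, parts in rows.items()}

    return build([marker]), build(others)


def _clade_aai(
    genomes: Sequence[GenomeRecord],
    clade_of: Mapping[str, str],
    rng: np.random.Generator,
    n_pairs: int = 30,
) -> tuple[float, float]:
    """Mean AAI over sampled within-clade and between-clade genome pairs."""
    prots = proteins_of(genomes)
    ids = [g.id for g in genomes if g.id in clade_of]
    within, between = [], []
    pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    order = rng.permutation(len(pairs))
    for k in order:
        a, b = pairs[k]
        same = clade_of[a] == clade_of[b]
        bucket = within if same else between
        if len(bucket) >= n_pairs:
            if len(within) >= n_pairs and len(between) >= n_pairs:
                break
            continue
        bucket.append(orthology.compute_aai(prots[a], prots[b]))
    return float(np.mean(within)), float(np.mean(between))


def analyze_genomes(
    genomes: Sequence[GenomeRecord],
    reference_proteins: Mapping[str, str] | None = None,
    min_screen_identity: float = 45.0,
    bootstrap_reps: int = 500,
    min_support: float = 90.0,
    min_members: int = 3,
    seed: int = 0,
) -> PangenomeAnalysis:
    """Screen, cluster, delineate, and summarize a genome collection.

    ``genomes`` carry gene records (called or imported).  When
    ``reference_proteins`` is given, genomes lacking a protein at
    ``min_screen_identity`` percent identity to a reference are dropped
    before analysis (the marker screen).
    """
    rng = np.random.default_rng(seed)
    if reference_proteins:
        kept = orthology.screen_by_reference(
            proteins_of(genomes), reference_proteins, min_screen_identity
        )
        genomes = [g for g in genomes if g.id in set(kept)]
    if not genomes:
        raise ValueError("no genomes pass the reference screen")

    prots = {x.id: x.protein for g in genomes for x in g.genes}
    genome_of = {x.id: g.id for g in genomes for x in g.genes}
    edges = orthology.build_edges(prots)
    ogs, singles = orthology.build_orthogroups(edges, genome_of, all_genes=prots)
    matrix = pangenome.build_presence_matrix(ogs, genome_of, [g.id for g in genomes])
    core = pangenome.core_orthogroups(matrix)
    summary = pangenome.pangenome_summary(matrix, ogs, sorted(prots), genome_of)

    aln_marker, aln_multi = marker_alignments(genomes, ogs)
    seed_a, seed_b = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))
    tree_a = phylo.bootstrap_supports(aln_marker, n_reps=bootstrap_reps, seed=seed_a)
    tree_b = phylo.bootstrap_supports(aln_multi, n_reps=bootstrap_reps, seed=seed_b)
    clades = phylo.delineate_clades(tree_a, tree_b, min_support, min_members)
    clade_of = {m: c.id for c in clades for m in c.members}
    aai_w, aai_b = _clade_aai(genomes, clade_of, rng)

    return PangenomeAnalysis(
        n_genomes=len(genomes), presence=matrix, orthogroups=ogs,
        singletons=singles, core=core, summary=summary, clades=clades,
        aai_within=aai_w, aai_between=aai_b,
    )


def circularize_and_call(
    contigs,
    min_overlap: int = 100,
    min_len: int = 10000,
    min_orf_len: int = 90,
) -> tuple[list[GenomeRecord], list[dict], list[list[Gene]]]:
    """Circularization pass plus per-genome ORF calling."""
    genomes, report = circ.circularize_contigs(
        contigs, min_overlap=min_overlap, min_len=min_len
    )
    called = [
        genecall.select_genes(genecall.find_orfs(g, min_len=min_orf_len))
        for g in genomes
    ]
    return genomes, report, called


def module_report(
    genomes: Sequence[GenomeRecord], max_gap_genes: int = 1
) -> tuple[list[modules.ModuleInstance], list[float]]:
    """Extract T8SS modules from genome gene tables and compute each
    module's genome-span percentage."""
    instances: list[modules.ModuleInstance] = []
    fractions: list[float] = []
    for g in genomes:
        for inst in modules.extract_modules(g.genes, contig_id=g.id, max_gap_genes=max_gap_genes):
            instances.append(inst)
            length = len(g.seq) if g.seq else (
                max(x.start + x.length for x in g.genes) + 25
            )
            fractions.append(modules.region_fraction(length, inst))
    return instances, fractions
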
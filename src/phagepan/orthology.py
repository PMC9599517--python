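"""Pairwise protein similarity, orthogroup clustering, AAI, and
reference screening.

Similarity is global (end-to-end) alignment under BLOSUM62 with affine
gaps; percent identity counts identical columns over *all* aligned
columns, gaps included in the denominator — a conservative convention
stated here because "amino-acid similarity" is used loosely in the
literature.  Orthogroups are connected components of the graph of
protein pairs passing identity and coverage thresholds; a k-mer Jaccard
prefilter keeps the all-vs-all step tractable.  AAI between two
proteomes is the mean identity over reciprocal best hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .records import AMINO_ACIDS

__all__ = [
    "SimilarityEdge",
    "OrthoGroup",
    "protein_similarity",
    "candidate_pairs",
    "build_edges",
    "build_orthogroups",
    "compute_aai",
    "screen_by_reference",
    "UndefinedAAIError",
]

_VALID_AA = set(AMINO_ACIDS)


class UndefinedAAIError(ValueError):
    """No reciprocal best hits between the two proteomes."""


@dataclass(frozen=True)
class SimilarityEdge:
    gene_a: str
    gene_b: str
    identity: float  # percent over aligned columns (gaps in denominator)
    coverage: float  # both-aligned columns / length of the shorter protein
    score: float


@dataclass
class OrthoGroup:
    id: str
    members: frozenset[str]
    genomes: frozenset[str]


def _make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def protein_similarity(
    prot_a: str,
    prot_b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    ids: tuple[str, str] = ("a", "b"),
    aligner: Align.PairwiseAligner | None = None,
) -> SimilarityEdge:
    """Global-alignment identity, coverage, and score for one pair."""
    if not prot_a or not prot_b:
        raise ValueError("empty protein")
    for p in (prot_a, prot_b):
        bad = set(p) - _VALID_AA
        if bad:
            raise ValueError(f"non-amino-acid characters: {sorted(bad)!r}")
    if aligner is None:
        aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(prot_a, prot_b)[0]
    counts = aln.counts()
    aligned_cols = aln.length  # includes gap columns
    both = counts.identities + counts.mismatches
    return SimilarityEdge(
        gene_a=ids[0], gene_b=ids[1],
        identity=100.0 * counts.identities / aligned_cols,
        coverage=both / min(len(prot_a), len(prot_b)),
        score=float(aln.score),
    )


def _kmer_set(protein: str, k: int) -> frozenset[str]:
    return frozenset(protein[i:i + k] for i in range(len(protein) - k + 1))


def candidate_pairs(
    proteins: Mapping[str, str], k: int = 5, jaccard_min: float = 0.02
) -> set[tuple[str, str]]:
    """Pairs of protein ids whose k-mer Jaccard reaches ``jaccard_min``.

    Built from an inverted k-mer index, so unrelated proteins are never
    compared.  At the default settings the filter retains all pairs in
    the identity regime the downstream thresholds accept (a validated
    property on the synthetic fixtures, not a proof).
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    kmers = {pid: _kmer_set(p, k) for pid, p in proteins.items()}
    index: dict[str, list[str]] = {}
    for pid, ks in kmers.items():
        for km in ks:
            index.setdefault(km, []).append(pid)
    shared: dict[tuple[str, str], int] = {}
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        bucket = sorted(bucket)
        for i in range(len(bucket)):
            for j in range(i + 1, len(bucket)):
                pair = (bucket[i], bucket[j])
                shared[pair] = shared.get(pair, 0) + 1
    out = set()
    for (a, b), n_shared in shared.items():
        union = len(kmers[a]) + len(kmers[b]) - n_shared
        if union and n_shared / union >= jaccard_min:
            out.add((a, b))
    return out


def build_edges(
    proteins: Mapping[str, str],
    pairs: Iterable[tuple[str, str]] | None = None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> list[SimilarityEdge]:
    """Align the given (or prefiltered) pairs and return symmetric edges."""
    if pairs is None:
        pairs = candidate_pairs(proteins)
    aligner = _make_aligner(gap_open, gap_extend)
    edges = []
    for a, b in sorted(set(tuple(sorted(p)) for p in pairs)):
        edges.append(
            protein_similarity(proteins[a], proteins[b], ids=(a, b), aligner=aligner)
        )
    return edges


def build_orthogroups(
    edges: Iterable[SimilarityEdge],
    genome_of: Mapping[str, str],
    min_identity: float = 30.0,
    min_coverage: float = 0.5,
    all_genes: Iterable[str] | None = None,
) -> tuple[list[OrthoGroup], list[str]]:
    """Connected components over thresholded similarity edges.

    Returns (orthogroups, singletons).  A component is an orthogroup
    only if it spans two or more genomes... — more precisely, only
    components with at least two members count; ``genome_of`` maps gene
    id to genome id.  Orthogroups are ordered (and numbered) by their
    smallest member id, so output is deterministic.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    genes = set(all_genes) if all_genes is not None else set()
    for e in edges:
        genes.update((e.gene_a, e.gene_b))
    for g in genes:
        parent[g] = g
    for e in edges:
        if e.identity >= min_identity and e.coverage >= min_coverage:
            union(e.gene_a, e.gene_b)

    comps: dict[str, set[str]] = {}
    for g in genes:
        comps.setdefault(find(g), set()).add(g)

    groups: list[OrthoGroup] = []
    singletons: list[str] = []
    for root in sorted(comps, key=lambda r: min(comps[r])):
        members = comps[root]
        if len(members) < 2:
            singletons.extend(members)
            continue
        groups.append(
            OrthoGroup(
                id=f"OG{len(groups):04d}",
                members=frozenset(members),
                genomes=frozenset(genome_of[m] for m in members),
            )
        )
    return groups, sorted(singletons)


def _best_hits(
    edges: Mapping[tuple[str, str], SimilarityEdge],
) -> dict[str, str]:
    """Best hit in b for each protein of a; ties by score, then gene id."""
    best: dict[str, tuple[float, str]] = {}
    for (a, b), e in edges.items():
        cur = best.get(a)
        if cur is None or e.score > cur[0] or (e.score == cur[0] and b < cur[1]):
            best[a] = (e.score, b)
    return {a: v[1] for a, v in best.items()}


def compute_aai(
    prots_a: Mapping[str, str],
    prots_b: Mapping[str, str],
    prefilter: bool = True,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Average amino-acid identity over reciprocal best hits (percent).

    Symmetric by construction; identical proteomes give 100.  Raises
    :class:`UndefinedAAIError` when no reciprocal best hit exists, which
    is distinct from an AAI of 0.
    """
    if not prots_a or not prots_b:
        raise ValueError("both genomes need at least one protein")
    # canonical orientation so AAI(a, b) == AAI(b, a) bit-for-bit
    if min(prots_b) < min(prots_a):
        prots_a, prots_b = prots_b, prots_a
    merged = {f"A::{k}": v for k, v in prots_a.items()}
    merged.update({f"B::{k}": v for k, v in prots_b.items()})
    if prefilter:
        pairs = {
            (x, y)
            for x, y in candidate_pairs(merged)
            if x.split("::", 1)[0] != y.split("::", 1)[0]
        }
    else:
        pairs = {
            (f"A::{a}", f"B::{b}") for a in prots_a for b in prots_b
        }
    aligner = _make_aligner(gap_open, gap_extend)
    cross: dict[tuple[str, str], SimilarityEdge] = {}
    for x, y in sorted(pairs):
        if x.startswith("B::"):
            x, y = y, x
        e = protein_similarity(merged[x], merged[y], ids=(x, y), aligner=aligner)
        cross[(x, y)] = e

    fwd = _best_hits(cross)
    rev = _best_hits({(b, a): e for (a, b), e in cross.items()})
    identities = [
        cross[(a, b)].identity for a, b in fwd.items() if rev.get(b) == a
    ]
    if not identities:
        raise UndefinedAAIError("no reciprocal best hits")
    return sum(identities) / len(identities)


def screen_by_reference(
    genome_proteins: Mapping[str, Mapping[str, str]],
    reference_proteins: Mapping[str, str] | Sequence[str],
    min_identity: float = 45.0,
) -> list[str]:
    """Retain genomes with >= 1 protein at ``min_identity`` percent
    identity to >= 1 reference protein (the marker-gene screen).

    ``genome_proteins`` maps genome id -> {gene id: protein}.  All
    genome-vs-reference pairs are aligned exhaustively: the screen sits
    at the entry of the pipeline and must be exact near the threshold.
    """
    if not reference_proteins:
        raise ValueError("reference set is empty")
    refs = (
        list(reference_proteins.values())
        if isinstance(reference_proteins, Mapping)
        else list(reference_proteins)
    )
    aligner = _make_aligner()
    kept = []
    for gid in sorted(genome_proteins):
        prots = genome_proteins[gid]
        hit = False
        for prot in prots.values():
            for ref in refs:
                e = protein_similarity(prot, ref, aligner=aligner)
                if e.identity >= min_identity:
                    hit = True
                    break
            if hit:
                break
        if hit:
            kept.append(gid)
    return kept
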
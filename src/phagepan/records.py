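"""Core record types shared across the pipeline.

Coordinates are 0-based half-open on the forward strand. A gene on a
circular genome may wrap the origin, in which case ``start + length``
exceeds the genome length and positions are taken modulo the genome
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class Gene:
    """A called or planted ORF with its translation and functional label."""

    id: str
    genome_id: str
    start: int
    length: int
    strand: str  # '+' or '-'
    protein: str = ""
    label: str | None = None
    category: str = "hypothetical"
    component: str = "none"  # T8SS component or 'none'

    @property
    def wraps_origin(self) -> bool:
        # resolved against the owning genome by the caller; genes built by
        # find_orfs set start < L, so wrapping is visible as start+length > L
        return False

    def end(self, genome_length: int | None = None) -> int:
        """Exclusive end coordinate; wraps modulo genome_length if given."""
        e = self.start + self.length
        if genome_length is not None and e > genome_length:
            e -= genome_length
        return e


@dataclass
class GenomeRecord:
    """A (possibly circular) nucleotide sequence with metadata."""

    id: str
    seq: str
    circular: bool = False
    source_station: str | None = None
    province: str | None = None
    clade: str | None = None
    genes: list[Gene] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        if not self.seq:
            return 0.0
        return (self.seq.count("G") + self.seq.count("C")) / len(self.seq)


@dataclass
class Contig:
    """A linear assembled contig."""

    id: str
    seq: str
    station: str | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"contig {self.id}: empty sequence")
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise ValueError(f"contig {self.id}: non-ACGTN characters {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gene_sequence(gene: Gene, genome: GenomeRecord) -> str:
    """Nucleotide sequence of a gene, honoring strand and origin wrap."""
    L = len(genome.seq)
    end = gene.start + gene.length
    if end <= L:
        nt = genome.seq[gene.start:end]
    else:
        if not genome.circular:
            raise ValueError(f"gene {gene.id} overruns linear genome {genome.id}")
        nt = genome.seq[gene.start:] + genome.seq[: end - L]
    if gene.strand == "-":
        nt = revcomp(nt)
    return nt
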
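"""Circular-aware ORF calling, translation, and gene-table I/O.

This is a deliberately simple caller: within every stop-bounded stretch
of a reading frame it reports the longest variant (first allowed start
codon ATG/GTG/TTG after the previous stop), under genetic code 11, on
both strands, with frames wrapping the origin on circular genomes.  It
does not score coding potential; externally produced gene calls can be
imported from GFF3 instead and take precedence in the pipeline.
"""

from __future__ import annotations

import io
import urllib.parse
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .records import NUCLEOTIDES, Gene, GenomeRecord, gene_sequence, revcomp

__all__ = [
    "find_orfs",
    "translate_gene",
    "select_genes",
    "write_gff3",
    "read_gff3",
    "write_protein_fasta",
]

START_CODONS = ("ATG", "GTG", "TTG")


def _stop_codons(genetic_code: int) -> frozenset[str]:
    return frozenset(CodonTable.unambiguous_dna_by_id[genetic_code].stop_codons)


def _scan_strand(
    seq: str,
    L: int,
    strand: str,
    circular: bool,
    min_len: int,
    stops: frozenset[str],
    out: list[tuple[int, int, str]],
) -> None:
    """Collect (forward_start, length, strand) ORFs from one strand.

    ``seq`` is the reading-direction sequence: the doubled sequence for
    circular genomes, the plain (or reverse-complemented) sequence
    otherwise.  Reading-direction coordinates are mapped back to forward
    strand coordinates modulo ``L``.
    """
    n = len(seq)
    for frame in range(3):
        starts: list[int] = []
        opened = not circular  # circular: skip the unbounded leading region
        for p in range(frame, n - 2, 3):
            codon = seq[p:p + 3]
            if codon in stops:
                if opened:
                    # longest variant that fits within one genome length
                    for s in starts:
                        length = p + 3 - s
                        if length > L:
                            continue
                        if length >= min_len:
                            s_mod = s % L
                            if strand == "+":
                                out.append((s_mod, length, "+"))
                            else:
                                # reading-direction start maps to the forward
                                # interval's rightmost base; store leftmost
                                fwd_left = (L - (s_mod + length)) % L
                                out.append((fwd_left, length, "-"))
                        break
                opened = True
                starts = []
            elif opened and codon in START_CODONS:
                starts.append(p)


def find_orfs(
    genome: GenomeRecord | str,
    min_len: int = 90,
    genetic_code: int = 11,
    circular: bool | None = None,
) -> list[Gene]:
    """Call ORFs on both strands; maximal per stop-bounded stretch.

    Returns genes sorted by (start, strand), with translations.  On
    circular genomes frames wrap the origin and an ORF longer than the
    genome is impossible by construction.
    """
    if isinstance(genome, GenomeRecord):
        seq, gid = genome.seq.upper(), genome.id
        is_circ = genome.circular if circular is None else circular
    else:
        seq, gid = genome.upper(), "seq"
        is_circ = bool(circular)
    if not seq:
        raise ValueError("empty genome")
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise ValueError(f"non-ACGTN characters: {sorted(bad)!r}")
    stops = _stop_codons(genetic_code)
    L = len(seq)

    raw: list[tuple[int, int, str]] = []
    fwd = seq + seq if is_circ else seq
    _scan_strand(fwd, L, "+", is_circ, min_len, stops, raw)
    rev = revcomp(seq)
    rev = rev + rev if is_circ else rev
    _scan_strand(rev, L, "-", is_circ, min_len, stops, raw)

    record = GenomeRecord(id=gid, seq=seq, circular=is_circ)
    genes: list[Gene] = []
    seen: set[tuple[int, str]] = set()
    for s, length, strand in sorted(set(raw)):
        if (s, strand) in seen:
            continue
        seen.add((s, strand))
        gene = Gene(
            id=f"{gid}_orf{len(genes) + 1:04d}", genome_id=gid, start=s,
            length=length, strand=strand,
        )
        prot = translate_gene(gene, record, genetic_code)
        # initiator codons GTG/TTG code for fMet
        gene.protein = "M" + prot[1:]
        genes.append(gene)
    return genes


def translate_gene(
    gene: Gene, genome: GenomeRecord, genetic_code: int = 11
) -> str:
    """Translate a gene (code 11 by default); stop codon excluded.

    Raises if the coding sequence contains an internal stop, which
    signals bad coordinates.
    """
    nt = gene_sequence(gene, genome)
    if len(nt) % 3:
        raise ValueError(f"gene {gene.id}: length {len(nt)} not divisible by 3")
    prot = str(Seq(nt).translate(table=genetic_code))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise ValueError(f"gene {gene.id}: internal stop codon")
    return prot


def select_genes(genes: Sequence[Gene], max_overlap: int = 0) -> list[Gene]:
    """Greedy longest-first selection of near-non-overlapping ORFs.

    A parsimonious gene map for densely coded phage genomes: spurious
    short ORFs embedded in (or antisense to) real genes are discarded
    because they overlap a longer accepted ORF by more than
    ``max_overlap`` bases.  Overlap is measured on forward coordinates,
    ignoring origin wrap-around, which is adequate for ranking.
    """
    chosen: list[Gene] = []
    for gene in sorted(genes, key=lambda g: (-g.length, g.start, g.strand)):
        a0, a1 = gene.start, gene.start + gene.length
        ok = True
        for kept in chosen:
            b0, b1 = kept.start, kept.start + kept.length
            if min(a1, b1) - max(a0, b0) > max_overlap:
                ok = False
                break
        if ok:
            chosen.append(gene)
    return sorted(chosen, key=lambda g: (g.start, g.strand))


# ---------------------------------------------------------------------------
# I/O

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def write_gff3(genes: Iterable[Gene], handle) -> None:
    """Write genes as GFF3 CDS features (1-based inclusive coordinates).

    For genes wrapping a circular origin, ``end`` exceeds the sequence
    length, following the GFF3 convention for circular genomes.
    """
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        handle.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={urllib.parse.quote(g.id)}"]
            if g.label:
                attrs.append(f"product={urllib.parse.quote(g.label)}")
            attrs.append(f"category={urllib.parse.quote(g.category)}")
            if g.component != "none":
                attrs.append(f"component={urllib.parse.quote(g.component)}")
            handle.write(
                "\t".join(
                    [
                        g.genome_id, "phagepan", "CDS", str(g.start + 1),
                        str(g.start + g.length), ".", g.strand, "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()


def read_gff3(source) -> list[Gene]:
    """Read CDS features from GFF3 into Gene records (no translations)."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(
        source, sep="\t", comment="#", names=GFF_COLUMNS, header=None, dtype=str
    )
    genes = []
    for _, row in df.iterrows():
        if row["type"] != "CDS":
            continue
        attrs = {}
        for field in str(row["attributes"]).split(";"):
            if "=" in field:
                k, v = field.split("=", 1)
                attrs[k.strip()] = urllib.parse.unquote(v.strip())
        start = int(row["start"]) - 1
        genes.append(
            Gene(
                id=attrs.get("ID", f"{row['seqid']}:{row['start']}"),
                genome_id=row["seqid"], start=start,
                length=int(row["end"]) - start, strand=row["strand"],
                label=attrs.get("product"),
                category=attrs.get("category", "hypothetical"),
                component=attrs.get("component", "none"),
            )
        )
    return genes


def write_protein_fasta(genes: Iterable[Gene], handle) -> None:
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        for g in genes:
            if g.protein:
                handle.write(f">{g.id}\n{g.protein}\n")
    finally:
        if close:
            handle.close()
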
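"""Synthetic genome and virome generation with planted, recoverable truth.

The generator emulates the statistical structure of an environmental
podovirus genome collection: ~58.8 kb circular genomes at ~42% G+C with
~82 ORFs each, organised into 10 phylogenetic clades, sharing a small
core gene set (13 orthogroups by default), clade-structured accessory
orthogroups, per-genome unique genes, and a Curli/T8SS gene module
planted in a minority of genomes.  Every planted fact (clade membership,
orthogroup of every gene, module composition and coordinates, terminal
repeat lengths) is recorded in a :class:`SyntheticTruth` so downstream
stages can be verified exactly.

Protein evolution is i.i.d. substitution over the 20-letter alphabet:
each orthogroup has a random ancestor, each clade a variant of it at
``between_clade_divergence``, and each genome a leaf copy at
``within_clade_divergence``.  There are no indels, no rate
heterogeneity, and no codon model — enough to create separable clades
and recoverable orthogroups, not a phylogenetic simulation.

Nucleotide sequences are built by packing genes head-to-tail with short
random intergenic spacers and back-translating proteins with synonymous
codon weights calibrated (numerically, once per configuration) so the
expected genome G+C matches the configured target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy.optimize import brentq

from .records import AMINO_ACIDS, Contig, Gene, GenomeRecord, revcomp

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "ViromeContig",
    "Station",
    "simulate_pangenome",
    "emit_linear_contigs",
    "simulate_virome_stations",
    "mutate_protein",
    "random_protein",
    "random_dna",
]

# T8SS component vocabulary, in the canonical operon order observed on
# the forward reading direction: histidine kinase(s), Curli chaperone,
# pore, fiber, ferric citrate regulator, optional second fiber copy and
# adenylate cyclase.
T8SS_COMPONENTS = ("HK", "CsgF", "CsgG", "CsgA/B", "FecR", "AC")

# Carrier module compositions and their mixture weights.
DEFAULT_MODULE_MIX: tuple[tuple[tuple[str, ...], float], ...] = (
    (("HK", "CsgF", "CsgG", "CsgA/B", "FecR"), 0.6),
    (("HK", "CsgF", "CsgG", "CsgA/B", "FecR", "CsgA/B", "AC"), 0.3),
    (("HK", "HK", "CsgF", "CsgG", "CsgA/B", "FecR"), 0.1),
)

CORE_LABELS = [
    ("DNA polymerase A", "core-viral"),
    ("terminase large subunit", "core-viral"),
    ("DEAD/DEAH box helicase", "core-viral"),
    ("primase", "core-viral"),
    ("major capsid protein", "core-viral"),
    ("co-chaperonin GroES", "core-viral"),
]

# (label, category, partner_index_offset) for the leading accessory
# orthogroups of every clade pool; partner pairs are laid out adjacently
# whenever a genome carries both.
ACCESSORY_LABELS = [
    ("ferrochelatase", "AMG-other"),
    ("2OG-Fe(II) oxygenase", "AMG-other"),
    ("2OG-Fe(II) oxygenase", "AMG-other"),
    ("thymidylate synthase", "AMG-hypermodification"),
    ("aG/PT-PPlase1", "AMG-hypermodification"),
    ("purM", "AMG-nucleotide"),
    ("peptide deformylase", "AMG-nucleotide"),
    ("glycosyltransferase", "AMG-other"),
]
# pairs of accessory pool indices placed adjacently (partner-AMGs)
PARTNER_PAIRS = ((0, 1), (3, 4))


@dataclass
class SimConfig:
    """Population parameters for the synthetic genome collection."""

    n_genomes: int = 82
    n_clades: int = 10
    mean_len: float = 58776.0
    sd_len: float = 2523.0
    gc: float = 0.421
    mean_orfs: float = 82.0
    sd_orfs: float = 9.0
    n_core: int = 13
    mean_unique: float = 17.0
    sd_unique: float = 9.0
    module_prevalence: float = 9 / 82
    within_clade_divergence: float = 0.02
    between_clade_divergence: float = 0.15
    seed: int = 0
    # mean protein length (aa) for orthogroup ancestors; chosen so that
    # mean_orfs genes plus spacers roughly fill mean_len bases
    mean_protein_len: float = 228.0
    sd_protein_len: float = 35.0
    accessory_pool_size: int = 60
    max_spacer: int = 50
    # explicit clade sizes (must sum to n_genomes); None = random partition
    clade_sizes: tuple[int, ...] | None = None

    def validate(self) -> None:
        if self.clade_sizes is not None:
            if len(self.clade_sizes) != self.n_clades:
                raise ValueError("clade_sizes length must equal n_clades")
            if sum(self.clade_sizes) != self.n_genomes:
                raise ValueError("clade_sizes must sum to n_genomes")
        if self.n_core < 0:
            raise ValueError("n_core must be >= 0")
        if not 0 < self.gc < 1:
            raise ValueError("gc must lie in (0, 1)")
        if self.within_clade_divergence < 0 or self.between_clade_divergence < 0:
            raise ValueError("divergences must be >= 0")
        if self.between_clade_divergence < self.within_clade_divergence:
            raise ValueError("between-clade divergence must be >= within-clade")
        if self.n_core > self.mean_orfs:
            raise ValueError("n_core exceeds mean ORFs per genome")
        if not 0 <= self.module_prevalence <= 1:
            raise ValueError("module_prevalence must lie in [0, 1]")
        if self.n_genomes < 1 or self.n_clades < 1 or self.n_clades > self.n_genomes:
            raise ValueError("need 1 <= n_clades <= n_genomes")


@dataclass
class PlantedModule:
    """A T8SS module planted on a genome or virome contig."""

    contig_id: str
    components: tuple[str, ...]  # canonical orientation
    strand: str
    start: int  # nt (genomes) or gene index (virome contigs)
    end: int
    gene_ids: tuple[str, ...] = ()
    truncated: bool = False
    family: str = "Podoviridae"


@dataclass
class SyntheticTruth:
    """Ground truth for everything the generator planted."""

    clade_of_genome: dict[str, str] = field(default_factory=dict)
    orthogroup_of_gene: dict[str, str] = field(default_factory=dict)
    planted_modules: list[PlantedModule] = field(default_factory=list)
    planted_repeats: dict[str, int] = field(default_factory=dict)
    rotation_offsets: dict[str, int] = field(default_factory=dict)
    contig_genome: dict[str, str] = field(default_factory=dict)
    # ancestral proteins per orthogroup id (the "cultured reference" set)
    reference_proteins: dict[str, str] = field(default_factory=dict)
    # (component, family) -> list of reference proteins with known taxonomy
    family_references: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    station_prevalence: float | None = None


# ---------------------------------------------------------------------------
# primitive sequence generators


def random_protein(length: int, rng: np.random.Generator, start_met: bool = True) -> str:
    """Random protein over the 20-letter alphabet; first residue M by default."""
    idx = rng.integers(0, 20, size=length)
    prot = "".join(AMINO_ACIDS[i] for i in idx)
    if start_met and length > 0:
        prot = "M" + prot[1:]
    return prot


def mutate_protein(protein: str, divergence: float, seed) -> str:
    """Substitute each position with probability ``divergence``.

    Replacements are drawn uniformly from the 19 other residues, so the
    expected fraction of changed positions equals ``divergence`` exactly.
    ``seed`` may be an integer or a numpy Generator.
    """
    if not protein:
        raise ValueError("empty protein")
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if divergence == 0:
        return protein
    arr = np.frombuffer(protein.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < divergence)[0]
    if hits.size:
        aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
        alpha_sorted = np.sort(aa)
        # uniform choice among the 19 other residues: draw from 0..18 and
        # skip past the slot holding the current residue
        cur = arr[hits]
        pick = rng.integers(0, 19, size=hits.size)
        slot = np.searchsorted(alpha_sorted, cur)
        pick = pick + (pick >= slot)
        arr[hits] = alpha_sorted[pick]
    return arr.tobytes().decode()


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join("ACGT"[i] for i in idx)


# Translation barrier embedded in every intergenic spacer: this 12-mer
# contains a stop codon in all six reading frames, so open reading
# stretches never run through gene boundaries (as real intergenic DNA
# between densely packed genes almost always terminates nearby frames).
STOP_WALL = "TTAATTAGTTAG"


def _spacer_dna(length: int, rng: np.random.Generator, gc: float) -> str:
    """Random spacer of ``length`` >= 12 nt with the six-frame stop wall
    embedded at a random offset.  Padding G+C is raised to offset the
    A/T-rich wall so the spacer meets the genome target in expectation."""
    pad = length - len(STOP_WALL)
    wall_gc = sum(b in "GC" for b in STOP_WALL)
    pad_gc = min(0.95, max(0.05, (length * gc - wall_gc) / pad)) if pad > 0 else gc
    left = int(rng.integers(0, pad + 1)) if pad > 0 else 0
    return (
        random_dna(left, rng, pad_gc)
        + STOP_WALL
        + random_dna(pad - left, rng, pad_gc)
    )


# ---------------------------------------------------------------------------
# codon model: synonymous choice calibrated to a target G+C


class CodonModel:
    """Back-translation under genetic code 11 with G+C-calibrated wobble."""

    def __init__(self, gc_target: float):
        table = CodonTable.unambiguous_dna_by_id[11]
        by_aa: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            by_aa.setdefault(aa, []).append(codon)
        self.stop_codons = sorted(table.stop_codons)
        self.by_aa = {aa: sorted(cods) for aa, cods in by_aa.items()}
        self.gc_target = gc_target
        self.q = brentq(lambda q: self._expected_gc(q) - gc_target, 1e-3, 1 - 1e-3)
        self._cum: dict[str, tuple[list[str], np.ndarray]] = {}
        for aa, cods in self.by_aa.items():
            w = np.array([self._codon_weight(c, self.q) for c in cods])
            w = w / w.sum()
            self._cum[aa] = (cods, np.cumsum(w))
        ws = np.array([self._codon_weight(c, self.q) for c in self.stop_codons])
        self._stop_cum = np.cumsum(ws / ws.sum())

    @staticmethod
    def _codon_weight(codon: str, q: float) -> float:
        w = 1.0
        for b in codon:
            w *= q / 2 if b in "GC" else (1 - q) / 2
        return w

    def _expected_gc(self, q: float) -> float:
        total = 0.0
        for cods in self.by_aa.values():
            ws = [self._codon_weight(c, q) for c in cods]
            gcs = [sum(b in "GC" for b in c) for c in cods]
            z = sum(ws)
            total += sum(w * g for w, g in zip(ws, gcs)) / z
        return total / len(self.by_aa) / 3.0

    def backtranslate(self, protein: str, rng: np.random.Generator) -> str:
        """Coding sequence (with stop codon) for a protein; ATG for leading M."""
        u = rng.random(len(protein) + 1)
        parts = []
        for i, aa in enumerate(protein):
            if i == 0 and aa == "M":
                parts.append("ATG")
                continue
            cods, cum = self._cum[aa]
            parts.append(cods[int(np.searchsorted(cum, u[i]))])
        parts.append(self.stop_codons[int(np.searchsorted(self._stop_cum, u[-1]))])
        return "".join(parts)


# ---------------------------------------------------------------------------
# orthogroup catalog


@dataclass
class _OGSpec:
    og_id: str
    label: str | None
    category: str
    component: str
    length: int  # protein length, aa
    ancestor: str
    clade_variants: dict[str, str]

    def leaf(self, clade: str, within: float, rng: np.random.Generator) -> str:
        return mutate_protein(self.clade_variants[clade], within, rng)


def _clade_sizes(n: int, k: int, rng: np.random.Generator, min_size: int = 3) -> list[int]:
    if n < k * min_size:
        # too few genomes for the minimum clade size; fall back to even split
        base = [n // k] * k
        for i in range(n - sum(base)):
            base[i] += 1
        return base
    extra = rng.multinomial(n - k * min_size, [1 / k] * k)
    return [min_size + int(e) for e in extra]


def _build_catalog(config: SimConfig, clades: list[str], rng: np.random.Generator):
    """Core, per-clade accessory, and T8SS orthogroup specifications."""

    def protein_len() -> int:
        return max(60, int(round(rng.normal(config.mean_protein_len, config.sd_protein_len))))

    def make_og(og_id, label, category, component="none", length=None) -> _OGSpec:
        L = length or protein_len()
        anc = random_protein(L, rng)
        variants = {
            c: mutate_protein(anc, config.between_clade_divergence, rng) for c in clades
        }
        return _OGSpec(og_id, label, category, component, L, anc, variants)

    core = []
    for i in range(config.n_core):
        label, cat = CORE_LABELS[i] if i < len(CORE_LABELS) else (None, "core-viral")
        core.append(make_og(f"COG{i:03d}", label, cat))

    accessory: dict[str, list[_OGSpec]] = {}
    for ci, clade in enumerate(clades):
        pool = []
        for j in range(config.accessory_pool_size):
            if j < len(ACCESSORY_LABELS):
                label, cat = ACCESSORY_LABELS[j]
            else:
                label, cat = None, "hypothetical"
            pool.append(make_og(f"AOG{ci:02d}_{j:03d}", label, cat))
        accessory[clade] = pool

    t8ss = {
        comp: make_og(f"T8SS_{comp.replace('/', '')}", comp, "AMG-T8SS", component=comp)
        for comp in T8SS_COMPONENTS
    }
    return core, accessory, t8ss


# ---------------------------------------------------------------------------
# genome assembly


def simulate_pangenome(
    config: SimConfig, make_sequences: bool = True
) -> tuple[list[GenomeRecord], SyntheticTruth]:
    """Generate a clade-structured genome collection with planted truth.

    Returns ``n_genomes`` circular genome records (with nucleotide
    sequences unless ``make_sequences`` is False) and the
    :class:`SyntheticTruth` mapping every gene to its orthogroup, every
    genome to its clade, and every planted T8SS module to its location.
    Deterministic for a given config.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_catalog, rng_layout, rng_genomes = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    clades = [f"clade{i + 1:02d}" for i in range(config.n_clades)]
    if config.clade_sizes is not None:
        sizes = list(config.clade_sizes)
    else:
        sizes = _clade_sizes(config.n_genomes, config.n_clades, rng_layout)
    clade_of: list[str] = []
    for clade, size in zip(clades, sizes):
        clade_of.extend([clade] * size)

    core, accessory, t8ss = _build_catalog(config, clades, rng_catalog)

    n_carriers = int(round(config.module_prevalence * config.n_genomes))
    carriers = set(
        rng_layout.choice(config.n_genomes, size=n_carriers, replace=False).tolist()
    )
    mix_comps = [m for m, _ in DEFAULT_MODULE_MIX]
    mix_w = np.array([w for _, w in DEFAULT_MODULE_MIX])
    mix_w = mix_w / mix_w.sum()

    codon_model = CodonModel(config.gc) if make_sequences else None

    truth = SyntheticTruth()
    truth.reference_proteins = {og.og_id: og.ancestor for og in core}
    truth.reference_proteins.update({og.og_id: og.ancestor for og in t8ss.values()})
    _make_family_references(t8ss, truth, rng_catalog, config)

    genomes: list[GenomeRecord] = []
    genome_streams = ss.spawn(config.n_genomes)
    for gi in range(config.n_genomes):
        rng = np.random.default_rng(genome_streams[gi])
        gid = f"envCVG{gi + 1:03d}"
        clade = clade_of[gi]
        truth.clade_of_genome[gid] = clade

        module_comps: tuple[str, ...] | None = None
        if gi in carriers:
            module_comps = mix_comps[int(rng.choice(len(mix_comps), p=mix_w))]

        genome = _assemble_genome(
            gid, clade, config, core, accessory[clade], t8ss, module_comps,
            codon_model, rng, truth,
        )
        genomes.append(genome)
    return genomes, truth


def _make_family_references(
    t8ss, truth: SyntheticTruth, rng: np.random.Generator, config: SimConfig
) -> None:
    """Reference T8SS proteins with known family labels, used to derive
    per-(component, family) identity floors.  References are drawn by
    the same clade-then-leaf process as genome copies, so they span the
    family's clade-level diversity; the Myoviridae family descends from
    a distant sister ancestor."""

    def draw(anc: str) -> str:
        clade_variant = mutate_protein(anc, config.between_clade_divergence, rng)
        return mutate_protein(clade_variant, config.within_clade_divergence, rng)

    for comp, og in t8ss.items():
        myo_anc = mutate_protein(og.ancestor, 0.45, rng)
        truth.family_references[(comp, "Podoviridae")] = [
            draw(og.ancestor) for _ in range(5)
        ]
        truth.family_references[(comp, "Myoviridae")] = [
            draw(myo_anc) for _ in range(5)
        ]


def _assemble_genome(
    gid: str,
    clade: str,
    config: SimConfig,
    core: list[_OGSpec],
    pool: list[_OGSpec],
    t8ss: dict[str, _OGSpec],
    module_comps: tuple[str, ...] | None,
    codon_model: CodonModel | None,
    rng: np.random.Generator,
    truth: SyntheticTruth,
) -> GenomeRecord:
    n_module = len(module_comps) if module_comps else 0
    target_orfs = int(round(rng.normal(config.mean_orfs, config.sd_orfs)))
    target_orfs = max(target_orfs, config.n_core + n_module + 2)

    n_unique = int(round(rng.normal(config.mean_unique, config.sd_unique)))
    n_unique = int(np.clip(n_unique, 0, target_orfs - config.n_core - n_module))
    n_accessory = target_orfs - config.n_core - n_module - n_unique
    if n_accessory > len(pool):
        n_unique += n_accessory - len(pool)
        n_accessory = len(pool)

    chosen = [pool[i] for i in sorted(rng.choice(len(pool), n_accessory, replace=False))]
    chosen_ids = {og.og_id for og in chosen}
    # partner-AMGs are retained together: a genome never carries one
    # member of a partner pair without the other (adjacent) member
    for a, b in PARTNER_PAIRS:
        have_a, have_b = pool[a].og_id in chosen_ids, pool[b].og_id in chosen_ids
        if have_a != have_b:
            missing = pool[b] if have_a else pool[a]
            swappable = [i for i, og in enumerate(chosen) if og.label is None]
            if swappable:
                out = chosen[int(rng.choice(swappable))]
                chosen_ids.discard(out.og_id)
                chosen[chosen.index(out)] = missing
            else:
                chosen.append(missing)
            chosen_ids.add(missing.og_id)

    # blocks: partner pairs stay adjacent; the T8SS module is one block
    blocks: list[list[tuple[_OGSpec | None, str]]] = []
    used = set()
    for a, b in PARTNER_PAIRS:
        ida, idb = pool[a].og_id, pool[b].og_id
        if ida in chosen_ids and idb in chosen_ids:
            blocks.append([(pool[a], "og"), (pool[b], "og")])
            used.update((ida, idb))
    for og in core:
        blocks.append([(og, "og")])
    for og in chosen:
        if og.og_id not in used:
            blocks.append([(og, "og")])
    for _ in range(n_unique):
        blocks.append([(None, "unique")])

    module_block: list[tuple[_OGSpec | None, str]] | None = None
    module_strand = "+"
    if module_comps:
        module_strand = "+" if rng.random() < 0.5 else "-"
        ordered = list(module_comps) if module_strand == "+" else list(module_comps)[::-1]
        module_block = [(t8ss[c], "module") for c in ordered]

    order = rng.permutation(len(blocks))
    plan = [blocks[i] for i in order]
    if module_block is not None:
        # interior insertion so the module never abuts the origin
        pos = int(rng.integers(1, len(plan)))
        plan.insert(pos, module_block)

    flat: list[tuple[_OGSpec | None, str]] = [item for block in plan for item in block]

    # length budget: unique genes absorb the slack between the target
    # genome length and the fixed orthogroup gene lengths
    target_len = rng.normal(config.mean_len, config.sd_len)
    min_spacer = len(STOP_WALL)
    spacers = rng.integers(min_spacer, config.max_spacer + 1, size=len(flat) + 1)
    fixed_nt = sum(3 * (og.length + 1) for og, kind in flat if og is not None)
    slack = target_len - fixed_nt - int(spacers.sum())
    if n_unique > 0:
        # exact-sum allocation: 50 aa base per unique gene, remaining
        # residues spread multinomially, so the genome length meets the
        # target whenever the budget allows
        min_aa = 50
        total_aa = max(n_unique * min_aa, int(round(slack / 3)) - n_unique)
        extra = total_aa - n_unique * min_aa
        unique_lens = min_aa + rng.multinomial(extra, [1 / n_unique] * n_unique)
    else:
        unique_lens = np.array([], dtype=int)

    genes: list[Gene] = []
    seq_parts: list[str] = []
    pos = 0
    ui = 0
    module_genes: list[Gene] = []
    for i, (og, kind) in enumerate(flat):
        spacer = int(spacers[i])
        if codon_model is not None and spacer:
            seq_parts.append(_spacer_dna(spacer, rng, config.gc))
        pos += spacer

        if og is None:
            plen = int(unique_lens[ui])
            protein = random_protein(plen, rng)
            og_id = None
            label, cat, comp = None, "hypothetical", "none"
            ui += 1
        else:
            protein = og.leaf(clade, config.within_clade_divergence, rng)
            og_id = og.og_id
            label, cat, comp = og.label, og.category, og.component

        nt_len = 3 * (len(protein) + 1)
        strand = module_strand if kind == "module" else ("+" if rng.random() < 0.5 else "-")
        gene_id = f"{gid}_g{len(genes) + 1:04d}"
        gene = Gene(
            id=gene_id, genome_id=gid, start=pos, length=nt_len, strand=strand,
            protein=protein, label=label, category=cat, component=comp,
        )
        genes.append(gene)
        if kind == "module":
            module_genes.append(gene)
        truth.orthogroup_of_gene[gene_id] = og_id if og_id else f"UNQ_{gene_id}"

        if codon_model is not None:
            cds = codon_model.backtranslate(protein, rng)
            if strand == "-":
                cds = revcomp(cds)
            seq_parts.append(cds)
        pos += nt_len
    tail_spacer = int(spacers[-1])
    if codon_model is not None and tail_spacer:
        seq_parts.append(_spacer_dna(tail_spacer, rng, config.gc))
    pos += tail_spacer

    seq = "".join(seq_parts) if codon_model is not None else ""
    genome = GenomeRecord(id=gid, seq=seq, circular=True, clade=clade, genes=genes)
    if codon_model is not None:
        assert len(seq) == pos

    if module_comps:
        start = module_genes[0].start
        end = module_genes[-1].start + module_genes[-1].length
        truth.planted_modules.append(
            PlantedModule(
                contig_id=gid,
                components=tuple(module_comps),
                strand=module_strand,
                start=start,
                end=end,
                gene_ids=tuple(g.id for g in module_genes),
                family="Podoviridae",
            )
        )
    return genome


# ---------------------------------------------------------------------------
# linear contig emission (assembly-like redundancy)


def emit_linear_contigs(
    genomes: Sequence[GenomeRecord],
    overlap_len: int = 100,
    seed: int = 0,
    truth: SyntheticTruth | None = None,
) -> list[Contig]:
    """Rotate each circular genome randomly and append its first
    ``overlap_len`` bases, producing a linear contig with an exact
    terminal direct repeat (the signature assembler output that the
    circularization stage detects and trims)."""
    rng = np.random.default_rng(seed)
    contigs = []
    for genome in genomes:
        L = len(genome.seq)
        if overlap_len >= L:
            raise ValueError(f"overlap {overlap_len} >= genome length {L}")
        offset = int(rng.integers(0, L))
        rotated = genome.seq[offset:] + genome.seq[:offset]
        seq = rotated + rotated[:overlap_len]
        cid = f"{genome.id}.contig"
        contigs.append(Contig(id=cid, seq=seq, station=genome.source_station))
        if truth is not None:
            truth.planted_repeats[cid] = overlap_len
            truth.rotation_offsets[cid] = offset
            truth.contig_genome[cid] = genome.id
    return contigs


# ---------------------------------------------------------------------------
# virome stations


@dataclass
class ViromeContig:
    """A virome contig represented at gene-table resolution.

    Only module-component genes carry informative labels; sequence-level
    detail is not generated at virome scale.  Gene i occupies
    ``[i*gene_pitch, i*gene_pitch + gene_len)``.
    """

    id: str
    station: str
    n_genes: int
    annotations: dict[int, tuple[str, str, str]] = field(default_factory=dict)
    gene_len: int = 700
    gene_pitch: int = 720

    def __len__(self) -> int:
        return self.n_genes * self.gene_pitch

    @property
    def genes(self) -> list[Gene]:
        out = []
        for i in range(self.n_genes):
            label, comp, strand = self.annotations.get(i, ("hypothetical", "none", "+"))
            cat = "AMG-T8SS" if comp != "none" else "hypothetical"
            out.append(
                Gene(
                    id=f"{self.id}_g{i + 1:04d}", genome_id=self.id,
                    start=i * self.gene_pitch, length=self.gene_len, strand=strand,
                    label=label, category=cat, component=comp,
                )
            )
        return out


@dataclass
class Station:
    id: str
    contigs: list[ViromeContig]
    total_orfs: int


def simulate_virome_stations(
    n_stations: int = 65,
    per_station_orfs: int = 10000,
    module_prevalence: float = 0.001,
    truncation_rate: float = 0.2,
    seed: int = 0,
    module_mix: tuple[tuple[tuple[str, ...], float], ...] = DEFAULT_MODULE_MIX,
) -> tuple[list[Station], SyntheticTruth]:
    """Generate per-station virome contig sets with planted T8SS modules.

    Each station receives contigs totalling ``per_station_orfs`` genes.
    The number of planted modules per station is Binomial(total ORFs,
    ``module_prevalence``), so each universal component's per-station
    frequency matches the prevalence up to binomial error.  A fraction
    ``truncation_rate`` of planted modules is cut by a contig terminus
    (flagged in truth); intact modules are always interior.
    """
    if not 0 <= module_prevalence <= 1:
        raise ValueError("module_prevalence must lie in [0, 1]")
    if not 0 <= truncation_rate <= 1:
        raise ValueError("truncation_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    comps = [m for m, _ in module_mix]
    weights = np.array([w for _, w in module_mix], dtype=float)
    weights = weights / weights.sum()

    truth = SyntheticTruth()
    truth.station_prevalence = module_prevalence
    stations: list[Station] = []
    for si in range(n_stations):
        st_id = f"station{si + 1:03d}"
        contigs: list[ViromeContig] = []
        remaining = per_station_orfs
        ci = 0
        while remaining > 0:
            n = int(rng.integers(15, 61))
            n = min(n, remaining) if remaining >= 15 else remaining
            ci += 1
            contigs.append(ViromeContig(id=f"{st_id}_c{ci:05d}", station=st_id, n_genes=n))
            remaining -= n

        n_modules = int(rng.binomial(per_station_orfs, module_prevalence))
        # track occupied gene slots per contig to keep modules separated
        occupied: dict[int, list[tuple[int, int]]] = {}
        for _ in range(n_modules):
            comp_full = comps[int(rng.choice(len(comps), p=weights))]
            truncated = bool(rng.random() < truncation_rate)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = False
            for _attempt in range(200):
                k = int(rng.integers(0, len(contigs)))
                contig = contigs[k]
                if truncated:
                    # keep a prefix or suffix of >=1 components, flush
                    # against a contig terminus
                    keep = int(rng.integers(1, len(comp_full)))
                    at_start = bool(rng.random() < 0.5)
                    comp = comp_full[-keep:] if at_start else comp_full[:keep]
                    span = len(comp)
                    lo = 0 if at_start else contig.n_genes - span
                    hi = lo + span
                    if hi > contig.n_genes or lo < 0:
                        continue
                else:
                    comp = comp_full
                    span = len(comp)
                    if contig.n_genes < span + 2:
                        continue
                    lo = int(rng.integers(1, contig.n_genes - span))
                    hi = lo + span
                # require a 2-gene buffer around existing placements
                clear = all(
                    hi + 2 <= a or lo >= b + 2 for a, b in occupied.get(k, [])
                )
                if not clear:
                    continue
                occupied.setdefault(k, []).append((lo, hi))
                laid = list(comp) if strand == "+" else list(comp)[::-1]
                for j, c in enumerate(laid):
                    contig.annotations[lo + j] = (c, c, strand)
                family = "Podoviridae" if rng.random() < 0.5 else "Myoviridae"
                truth.planted_modules.append(
                    PlantedModule(
                        contig_id=contig.id, components=tuple(comp), strand=strand,
                        start=lo, end=hi, truncated=truncated, family=family,
                    )
                )
                placed = True
                break
            if not placed:  # pragma: no cover - pathological densities only
                raise RuntimeError("could not place module; station too dense")
        stations.append(Station(id=st_id, contigs=contigs, total_orfs=per_station_orfs))
    return stations, truth
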
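"""Auxiliary metabolic genes (AMGs), partner-AMG colocation, and T8SS
(Curli) module extraction, typing, and station profiling.

AMGs are genes whose functional label maps to a cellular category
(nucleotide metabolism, DNA hypermodification, T8SS, other), as opposed
to core viral replication/packaging functions or unannotated genes.
Labels come from imported annotation tables, not from live database
searches.

A T8SS module instance is a maximal run of component genes (HK, CsgF,
CsgG, CsgA/B, FecR, AC) with at most ``max_gap_genes`` intervening
non-component genes.  Compositions are read in canonical orientation:
the orientation in which CsgF precedes CsgG, falling back to the
majority gene strand when undecidable.  Instances touching a contig
terminus are flagged (possible truncation) and excluded by the terminal
filter before composition statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .orthology import protein_similarity, _make_aligner
from .records import Gene

__all__ = [
    "ModuleInstance",
    "StationProfile",
    "classify_amgs",
    "adjacency_implication",
    "partner_amg_pairs",
    "extract_modules",
    "filter_terminal",
    "composition_table",
    "compute_family_floors",
    "assign_family",
    "station_frequencies",
    "region_fraction",
    "pairwise_count_ratio",
]

AMG_CATEGORIES = frozenset(
    {"AMG-nucleotide", "AMG-hypermodification", "AMG-T8SS", "AMG-other"}
)

COMPOSITION_SEP = "-"


@dataclass
class ModuleInstance:
    contig_id: str
    components: tuple[str, ...]  # canonical orientation
    gene_ids: tuple[str, ...]  # genome order (not reversed)
    start: int  # nt, first component gene start
    end: int  # nt, last component gene end
    terminal: bool
    family: str = "unassigned"

    @property
    def composition(self) -> str:
        return COMPOSITION_SEP.join(self.components)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class StationProfile:
    station_id: str
    total_viral_orfs: int
    hits: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def frequencies(self) -> dict[tuple[str, str], float]:
        return {k: v / self.total_viral_orfs for k, v in self.hits.items()}


def classify_amgs(genes: Iterable[Gene]) -> list[Gene]:
    """Genes with a cellular-function category; core viral and
    unannotated (hypothetical) genes are excluded."""
    return [g for g in genes if g.category in AMG_CATEGORIES]


def _positions_with_label(genes: Sequence[Gene], label: str) -> list[int]:
    return [i for i, g in enumerate(genes) if g.label == label]


def adjacency_implication(
    genomes: Mapping[str, Sequence[Gene]],
    label_x: str,
    label_y: str,
    max_gap_genes: int = 1,
    circular: bool = True,
) -> tuple[bool, list[str]]:
    """Does every genome carrying ``label_x`` place a ``label_y`` within
    ``max_gap_genes`` gene positions of some copy of x?

    Gene distance is measured on the gene order, wrapping around the
    origin when ``circular``.  Returns (holds, counterexample genomes).
    """
    counterexamples = []
    for gid in sorted(genomes):
        genes = list(genomes[gid])
        xs = _positions_with_label(genes, label_x)
        if not xs:
            continue
        ys = set(_positions_with_label(genes, label_y))
        n = len(genes)
        satisfied = False
        for x in xs:
            for d in range(1, max_gap_genes + 2):
                lo, hi = x - d, x + d
                if circular:
                    lo, hi = lo % n, hi % n
                if (0 <= lo < n and lo in ys) or (0 <= hi < n and hi in ys):
                    satisfied = True
                    break
            if satisfied:
                break
        if not satisfied:
            counterexamples.append(gid)
    return not counterexamples, counterexamples


def partner_amg_pairs(
    genes: Sequence[Gene], window_genes: int = 5, circular: bool = True
) -> list[tuple[str, str, int]]:
    """Unordered AMG pairs colocated within ``window_genes`` gene
    positions and sharing an AMG category (functionally related).

    Returns (gene id, gene id, gene distance) triples, each pair once.
    """
    n = len(genes)
    amg_idx = [i for i, g in enumerate(genes) if g.category in AMG_CATEGORIES]
    out = []
    for i, j in itertools.combinations(amg_idx, 2):
        if genes[i].category != genes[j].category:
            continue
        dist = j - i
        if circular and n:
            dist = min(dist, n - dist)
        if dist <= window_genes:
            out.append((genes[i].id, genes[j].id, dist))
    return out


def _orient(components: list[str], strands: list[str]) -> tuple[str, ...]:
    """Canonical orientation: CsgF before CsgG; else majority strand."""
    fwd = tuple(components)
    rev = tuple(reversed(components))
    if "CsgF" in components and "CsgG" in components:
        if components.index("CsgF") <= components.index("CsgG"):
            return fwd
        return rev
    n_minus = sum(1 for s in strands if s == "-")
    return rev if n_minus > len(strands) - n_minus else fwd


def extract_modules(
    genes: Sequence[Gene],
    contig_id: str | None = None,
    max_gap_genes: int = 1,
    contig_length: int | None = None,
) -> list[ModuleInstance]:
    """Maximal runs of T8SS component genes on one contig.

    ``genes`` must be in contig order.  Runs tolerate up to
    ``max_gap_genes`` intervening non-component genes; duplicate
    adjacent components (two HKs, a second CsgA/B) are preserved.  An
    instance is terminal when the contig's first or last gene belongs
    to it.
    """
    if not genes:
        return []
    cid = contig_id or genes[0].genome_id
    comp_idx = [i for i, g in enumerate(genes) if g.component != "none"]
    if not comp_idx:
        return []
    runs: list[list[int]] = [[comp_idx[0]]]
    for i in comp_idx[1:]:
        if i - runs[-1][-1] - 1 <= max_gap_genes:
            runs[-1].append(i)
        else:
            runs.append([i])
    out = []
    last = len(genes) - 1
    for run in runs:
        comps = [genes[i].component for i in run]
        strands = [genes[i].strand for i in run]
        out.append(
            ModuleInstance(
                contig_id=cid,
                components=_orient(comps, strands),
                gene_ids=tuple(genes[i].id for i in run),
                start=genes[run[0]].start,
                end=genes[run[-1]].start + genes[run[-1]].length,
                terminal=(run[0] == 0 or run[-1] == last),
            )
        )
    return out


def filter_terminal(instances: Iterable[ModuleInstance]) -> list[ModuleInstance]:
    """Drop instances whose run touches a contig terminus (possible
    truncation by an assembly break)."""
    return [m for m in instances if not m.terminal]


def composition_table(
    instances: Sequence[ModuleInstance],
    top_k: int = 10,
    by_family: bool = True,
) -> pd.DataFrame:
    """Ranked composition strings with per-family percentages.

    Percentages are relative to all modules of the same family.  Count
    ties rank lexicographically by composition, both reported.
    """
    rows = []
    key = (lambda m: m.family) if by_family else (lambda m: "all")
    groups: dict[str, list[ModuleInstance]] = {}
    for m in instances:
        groups.setdefault(key(m), []).append(m)
    for family in sorted(groups):
        mods = groups[family]
        counts: dict[str, int] = {}
        for m in mods:
            counts[m.composition] = counts.get(m.composition, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k]
        for rank, (comp, n) in enumerate(ranked, start=1):
            rows.append(
                {
                    "family": family, "rank": rank, "composition": comp,
                    "count": n, "percent": 100.0 * n / len(mods),
                }
            )
    return pd.DataFrame(rows, columns=["family", "rank", "composition", "count", "percent"])


def compute_family_floors(
    references: Mapping[tuple[str, str], Sequence[str]],
) -> dict[tuple[str, str], float]:
    """Identity floors per (component, family): the minimum pairwise
    identity among that combination's known-family reference proteins.

    A hit below the floor is less similar than the references are to
    each other, and is therefore unassignable to the family.
    """
    aligner = _make_aligner()
    floors = {}
    for key, prots in references.items():
        if len(prots) < 2:
            floors[key] = 0.0
            continue
        floors[key] = min(
            protein_similarity(a, b, aligner=aligner).identity
            for a, b in itertools.combinations(prots, 2)
        )
    return floors


def assign_family(
    protein: str,
    references: Mapping[tuple[str, str], Sequence[str]],
    floors: Mapping[tuple[str, str], float],
    component: str | None = None,
) -> str:
    """Family of the best-identity reference, or 'unassigned' when the
    best identity falls below that (component, family)'s floor."""
    if not references:
        raise ValueError("reference set is empty")
    aligner = _make_aligner()
    best: tuple[float, str, str] | None = None  # identity, family, comp
    for (comp, family), prots in sorted(references.items()):
        if component is not None and comp != component:
            continue
        for ref in prots:
            ident = protein_similarity(protein, ref, aligner=aligner).identity
            if best is None or ident > best[0]:
                best = (ident, family, comp)
    if best is None:
        raise ValueError(f"no references for component {component!r}")
    ident, family, comp = best
    if (comp, family) not in floors:
        raise KeyError(f"no identity floor for {(comp, family)!r}")
    if ident < floors[(comp, family)]:
        return "unassigned"
    return family


def station_frequencies(
    hits: Mapping[str, Mapping[tuple[str, str], int]],
    total_orfs: Mapping[str, int],
) -> list[StationProfile]:
    """Per-station normalized component frequencies.

    ``hits`` maps station -> {(component, family): count}; frequencies
    are counts divided by the station's total viral ORFs.
    """
    out = []
    for station in sorted(hits):
        total = total_orfs[station]
        if total <= 0:
            raise ValueError(f"station {station}: total ORFs must be > 0")
        out.append(
            StationProfile(
                station_id=station, total_viral_orfs=total,
                hits=dict(hits[station]),
            )
        )
    return out


def count_station_hits(
    contig_modules: Mapping[str, Sequence[ModuleInstance]],
    station_of_contig: Mapping[str, str],
) -> dict[str, dict[tuple[str, str], int]]:
    """Aggregate per-station (component, family) hit counts from
    extracted module instances."""
    hits: dict[str, dict[tuple[str, str], int]] = {}
    for cid, instances in contig_modules.items():
        st = station_of_contig[cid]
        bucket = hits.setdefault(st, {})
        for m in instances:
            for comp in m.components:
                key = (comp, m.family)
                bucket[key] = bucket.get(key, 0) + 1
    return hits


def region_fraction(genome_length: int, instance: ModuleInstance) -> float:
    """Module span (first component start to last component end) as a
    percentage of the genome length."""
    if instance.span <= 0 or instance.span > genome_length:
        raise ValueError("module span inconsistent with genome length")
    return 100.0 * instance.span / genome_length


def pairwise_count_ratio(counts: Mapping[str, float]) -> tuple[float, float]:
    """Mean and SD of min/max count ratios over all unordered gene pairs.

    Pairs where both counts are zero are skipped; a pair with exactly
    one zero contributes 0.  Raises when every pair is zero/zero.
    """
    if len(counts) < 2:
        raise ValueError("need counts for at least two genes")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    ratios = []
    for a, b in itertools.combinations(sorted(counts), 2):
        x, y = counts[a], counts[b]
        if x == 0 and y == 0:
            continue
        ratios.append(min(x, y) / max(x, y))
    if not ratios:
        raise ValueError("all pairs are zero/zero; ratio undefined")
    arr = np.asarray(ratios)
    return float(arr.mean()), float(arr.std(ddof=0))
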
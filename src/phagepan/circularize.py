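"""Terminal direct-repeat detection and circularization of linear contigs.

A complete phage genome assembled from a circular template shows up as a
linear contig whose start is repeated verbatim at its end.  Detecting
that terminal direct repeat (at least ``min_overlap`` bases, 100 by
default) and trimming one copy yields the circular genome.  Reverse
complement repeats are deliberately not accepted as circularization
evidence, and ``N`` never matches anything, including another ``N``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import Contig, GenomeRecord

__all__ = [
    "TerminalRepeat",
    "ContigTooShortError",
    "detect_terminal_repeat",
    "trim_to_circle",
    "length_filter",
]


class ContigTooShortError(ValueError):
    """Contig shorter than twice the minimum overlap: unevaluable."""


@dataclass(frozen=True)
class TerminalRepeat:
    """An exact or near-exact repeat shared by both ends of a contig."""

    contig_id: str
    length: int
    identity: float
    head_interval: tuple[int, int]  # starts at 0
    tail_interval: tuple[int, int]  # ends at contig length


def _prefix_function(s: str) -> np.ndarray:
    """Knuth-Morris-Pratt prefix (border) table."""
    b = np.frombuffer(s.encode(), dtype=np.uint8)
    pi = np.zeros(len(b), dtype=np.int64)
    k = 0
    for i in range(1, len(b)):
        while k > 0 and b[i] != b[k]:
            k = pi[k - 1]
        if b[i] == b[k]:
            k += 1
        pi[i] = k
    return pi


def detect_terminal_repeat(
    contig: Contig, min_overlap: int = 100, min_identity: float = 1.0
) -> TerminalRepeat | None:
    """Longest suffix-prefix overlap of ``contig`` meeting the thresholds.

    With ``min_identity`` = 1 (default) the repeat must be an exact
    match, found via the KMP border chain; candidates containing ``N``
    or covering more than half of the contig are skipped.  With a lower
    ``min_identity`` an ungapped end-to-end comparison is scanned from
    the longest candidate down and the first (hence longest) overlap
    whose identity clears the threshold is returned.
    """
    L = len(contig.seq)
    if L <= 2 * min_overlap:
        raise ContigTooShortError(
            f"contig {contig.id}: length {L} <= 2 x min_overlap {min_overlap}"
        )
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    if min_identity >= 1.0:
        pi = _prefix_function(contig.seq)
        k = int(pi[-1])
        while k >= min_overlap:
            if k <= L // 2 and "N" not in contig.seq[:k]:
                return TerminalRepeat(
                    contig_id=contig.id, length=k, identity=1.0,
                    head_interval=(0, k), tail_interval=(L - k, L),
                )
            k = int(pi[k - 1])
        return None

    arr = np.frombuffer(contig.seq.encode(), dtype=np.uint8)
    n_mask = arr == ord("N")
    for k in range(L // 2, min_overlap - 1, -1):
        head, tail = arr[:k], arr[L - k:]
        matches = int(np.count_nonzero((head == tail) & ~n_mask[:k] & ~n_mask[L - k:]))
        identity = matches / k
        if identity >= min_identity:
            return TerminalRepeat(
                contig_id=contig.id, length=k, identity=identity,
                head_interval=(0, k), tail_interval=(L - k, L),
            )
    return None


def trim_to_circle(contig: Contig, repeat: TerminalRepeat) -> GenomeRecord:
    """Remove one repeat copy and return the circular genome record."""
    if repeat.contig_id != contig.id:
        raise ValueError(
            f"repeat belongs to {repeat.contig_id}, not contig {contig.id}"
        )
    L = len(contig.seq)
    if repeat.tail_interval[1] != L or repeat.head_interval[0] != 0:
        raise ValueError("repeat intervals inconsistent with contig")
    if repeat.length * 2 > L:
        raise ValueError(
            f"degenerate repeat: {repeat.length} covers more than half of {L}"
        )
    return GenomeRecord(
        id=contig.id, seq=contig.seq[: L - repeat.length], circular=True,
        source_station=contig.station,
    )


def length_filter(contigs: Iterable[Contig], min_len: int = 10000) -> list[Contig]:
    """Keep contigs strictly larger than ``min_len`` bases."""
    return [c for c in contigs if len(c) > min_len]


def circularize_contigs(
    contigs: Sequence[Contig],
    min_overlap: int = 100,
    min_identity: float = 1.0,
    min_len: int = 10000,
) -> tuple[list[GenomeRecord], list[dict]]:
    """Length-filter, detect terminal repeats, and trim: the full
    circularization pass.  Returns the circular genomes plus a per-contig
    report (id, length, repeat length, identity, decision)."""
    genomes: list[GenomeRecord] = []
    report: list[dict] = []
    for contig in length_filter(contigs, min_len):
        row: dict = {"contig": contig.id, "length": len(contig)}
        try:
            rep = detect_terminal_repeat(contig, min_overlap, min_identity)
        except ContigTooShortError:
            row.update(repeat_len=0, identity=0.0, decision="unevaluable")
            report.append(row)
            continue
        if rep is None:
            row.update(repeat_len=0, identity=0.0, decision="linear")
        else:
            genomes.append(trim_to_circle(contig, rep))
            row.update(repeat_len=rep.length, identity=rep.identity, decision="circular")
        report.append(row)
    if not genomes:
        warnings.warn("no contig could be circularized")
    return genomes, report
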
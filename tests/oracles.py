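"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations of the definitions (direct
scans, textbook DP) kept separate from the library implementations they
check.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "GTG", "TTG"}


def brute_suffix_prefix(seq: str, min_overlap: int) -> int | None:
    """Longest k with seq[:k] == seq[-k:], scanning every length.

    N never matches; candidates over half the length are skipped."""
    L = len(seq)
    for k in range(L // 2, min_overlap - 1, -1):
        head, tail = seq[:k], seq[-k:]
        if "N" in head or "N" in tail:
            if any(h != t or h == "N" for h, t in zip(head, tail)):
                continue
        if head == tail:
            return k
    return None


def six_frame_orfs_circular(seq: str, min_len: int = 90) -> set[tuple[int, int, str]]:
    """All maximal ORFs on a circular genome via explicit cyclic codon
    walks; returns (forward_leftmost_start, length, strand) triples."""
    L = len(seq)
    out: set[tuple[int, int, str]] = set()
    for strand in "+-":
        t = seq if strand == "+" else str(Seq(seq).reverse_complement())
        visited = set()
        for f in range(3):
            if f in visited:
                continue
            # walk the cyclic codon sequence starting at offset f
            codon_pos = []
            p = f
            while p not in visited:
                visited.add(p)
                codon_pos.append(p)
                p = (p + 3) % L
            codons = [(q, (t[q:q + 3] if q + 3 <= L else t[q:] + t[: q + 3 - L]))
                      for q in codon_pos]
            n = len(codons)
            stop_idx = [i for i, (_, c) in enumerate(codons) if c in STOPS]
            if not stop_idx:
                continue
            for si, i in enumerate(stop_idx):
                j = stop_idx[(si + 1) % len(stop_idx)]
                # region is the codons strictly between stop i and stop j
                span = (j - i) % n
                if span == 0:
                    span = n  # single stop: region wraps the whole cycle
                for off in range(1, span):
                    q, c = codons[(i + off) % n]
                    if c not in STARTS:
                        continue
                    length = (span - off + 1) * 3
                    if length > L:
                        continue
                    if length >= min_len:
                        if strand == "+":
                            out.add((q, length, "+"))
                        else:
                            out.add(((L - (q + length)) % L, length, "-"))
                    break
    return out


def six_frame_orfs_linear(seq: str, min_len: int = 90) -> set[tuple[int, int, str]]:
    L = len(seq)
    out: set[tuple[int, int, str]] = set()
    for strand in "+-":
        t = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for f in range(3):
            codons = [(p, t[p:p + 3]) for p in range(f, L - 2, 3)]
            region_start = 0
            i = 0
            while i < len(codons):
                if codons[i][1] in STOPS:
                    for k in range(region_start, i):
                        if codons[k][1] in STARTS:
                            length = codons[i][0] + 3 - codons[k][0]
                            if length >= min_len:
                                if strand == "+":
                                    out.add((codons[k][0], length, "+"))
                                else:
                                    out.add((L - (codons[k][0] + length), length, "-"))
                            break
                    region_start = i + 1
                i += 1
    return out


_BLOSUM = substitution_matrices.load("BLOSUM62")


def gotoh_score(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Global affine-gap alignment score; a gap of length k costs
    open + (k-1) * extend (matching the convention where the opening
    position already includes its own extension)."""
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (moving along a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend,
                          X[i, j - 1] - gap_open)
    return float(max(M[n, m], X[n, m], Y[n, m]))


def exact_mutant(protein: str, n_subs: int, rng: np.random.Generator) -> str:
    """Copy of ``protein`` with exactly ``n_subs`` positions substituted
    to different residues (never back to the original)."""
    from phagepan.records import AMINO_ACIDS

    arr = list(protein)
    pos = rng.choice(len(arr), size=n_subs, replace=False)
    for p in pos:
        choices = [c for c in AMINO_ACIDS if c != arr[p]]
        arr[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(arr)
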
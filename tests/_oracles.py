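"""Brute-force reference implementations used only by the tests.

These are deliberately simple and slow: plain dynamic programming and
exhaustive enumeration, with no shortcuts shared with the package code.
"""

from __future__ import annotations

from functools import lru_cache
from typing import List, Optional, Tuple

from nanobarcode.clustering import alignment_identity
from nanobarcode.io_seq import Read, reverse_complement
from nanobarcode.primers import IUPAC


def iupac_match(primer_code: str, read_base: str) -> bool:
    """Primer-side degeneracy is free; a read-side N matches nothing."""
    if read_base == "N":
        return False
    return read_base in IUPAC[primer_code]


def _edit_row(core: str, text: str) -> List[List[int]]:
    """Full DP table of global edit distance core vs every prefix of text."""
    m, n = len(core), len(text)
    table = [list(range(n + 1))]
    for i in range(1, m + 1):
        row = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if iupac_match(core[i - 1], text[j - 1]) else 1
            row[j] = min(table[i - 1][j - 1] + cost, table[i - 1][j] + 1,
                         row[j - 1] + 1)
        table.append(row)
    return table


def oracle_find_primer(sequence: str, primer: str, max_error_rate: float = 0.20,
                       min_overlap: int = 15
                       ) -> Optional[Tuple[int, int, int, int]]:
    """Exhaustive semi-global primer search with free terminal overhang.

    Enumerates every overhang class (primer prefix/suffix hanging off a read
    end) and every start/end placement, scoring with IUPAC-aware unit edit
    costs; a placement qualifies when its read-side span reaches
    ``min_overlap`` and its edits stay within ``floor(rate * span)``.
    Returns (edits, start, span, end) of the fewest-edit qualifying
    placement (ties: leftmost start, longest span); None when nothing
    qualifies.
    """
    sequence = sequence.upper()
    primer = primer.upper()
    m, n = len(primer), len(sequence)

    def budget(length: int) -> int:
        return int(max_error_rate * length + 1e-9)

    best: Optional[Tuple[int, int, int, int]] = None
    for t_left in range(0, m - min_overlap + 1):
        for t_right in range(0, m - min_overlap - t_left + 1):
            if t_left and t_right and n >= m:
                continue            # both-end overhang needs a short read
            core = primer[t_left: m - t_right]
            starts = [0] if t_left else range(n + 1)
            for s in starts:
                table = _edit_row(core, sequence[s:])
                ends = [n] if t_right else range(s, n + 1)
                for e in ends:
                    span = e - s
                    d = table[len(core)][span]
                    if span < min_overlap or d > budget(span):
                        continue
                    key = (d, s, -span, e)
                    if best is None or key < best:
                        best = key
    if best is None:
        return None
    d, s, neg_span, e = best
    return d, s, -neg_span, e


def oracle_rescore(sequence: str, primer: str, start: int, end: int,
                   min_overlap: int = 15) -> int:
    """Minimum edits of any placement with exactly the given endpoints."""
    sequence = sequence.upper()
    primer = primer.upper()
    m, n = len(primer), len(sequence)
    best = None
    for t_left in range(0, m - min_overlap + 1):
        if t_left and start != 0:
            continue
        for t_right in range(0, m - min_overlap - t_left + 1):
            if t_right and end != n:
                continue
            core = primer[t_left: m - t_right]
            table = _edit_row(core, sequence[start:end])
            d = table[len(core)][end - start]
            if best is None or d < best:
                best = d
    return best


def oracle_greedy_cluster(reads: List[Read], threshold: float = 80.0,
                          both_strands: bool = True) -> List[List[str]]:
    """Plain greedy clustering: longest first, best representative wins.

    Uses the same identity metric as the package (so the comparison checks
    the clustering logic and the prescreen, not the aligner) but none of its
    shortcut machinery.
    """
    order = sorted(range(len(reads)), key=lambda i: -len(reads[i]))
    clusters: List[List[str]] = []
    reps: List[str] = []
    for idx in order:
        seq = reads[idx].sequence
        best_ident = -1.0
        best_ci = None
        for ci, rep in enumerate(reps):
            ident = alignment_identity(seq, rep)
            if both_strands:
                ident = max(ident,
                            alignment_identity(reverse_complement(seq), rep))
            if ident >= threshold and ident > best_ident:
                best_ident = ident
                best_ci = ci
        if best_ci is None:
            clusters.append([reads[idx].read_id])
            reps.append(seq)
        else:
            clusters[best_ci].append(reads[idx].read_id)
    return clusters


def oracle_unit_counts(query: str, target: str) -> Tuple[int, int, int]:
    """(mismatches, insertions, deletions) of the min-(cost, gaps) alignment.

    Recursive enumeration of the lexicographic (edit cost, gap columns)
    optimum; the counts follow from the optimum and the length difference.
    """
    @lru_cache(maxsize=None)
    def f(i: int, j: int) -> Tuple[int, int]:
        if i == 0:
            return (j, j)
        if j == 0:
            return (i, i)
        dc, dg = f(i - 1, j - 1)
        sub = 0 if query[i - 1] == target[j - 1] else 1
        best = (dc + sub, dg)
        for pc, pg in (f(i - 1, j), f(i, j - 1)):
            cand = (pc + 1, pg + 1)
            if cand < best:
                best = cand
        return best

    cost, gaps = f(len(query), len(target))
    diff = len(query) - len(target)
    return (cost - gaps, (gaps + diff) // 2, (gaps - diff) // 2)
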
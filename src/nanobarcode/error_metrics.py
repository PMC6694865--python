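"""Per-read and per-consensus error percentages from unit-cost alignment.

The error of a query against a target is taken from a global alignment with
unit penalties for substitutions and for every gapped position.  Among
cost-optimal alignments the one with the fewest gap columns is preferred,
which pins down the split of the optimum into mismatches, insertions (query
bases absent from the target) and deletions (target bases absent from the
query): with total cost d, gap columns g and length difference
diff = len(query) - len(target) = insertions - deletions, the counts follow
as insertions = (g + diff) / 2, deletions = (g - diff) / 2 and
mismatches = d - g, independent of where the gaps are placed.

The pooled error percentage is
100 * (mismatches + insertions + deletions) / (sum of query lengths).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

# Lexicographic (cost, gaps) packed into one integer per DP cell.  Both
# components are additive along an alignment path, so minimising the packed
# value minimises cost first and gap count second.  _GAP_BASE must exceed
# any possible gap count (sequence lengths are limited accordingly).
_GAP_BASE = 1 << 14
_SUB = _GAP_BASE          # one substitution: cost 1, no gap
_GAP = _GAP_BASE + 1      # one gapped position: cost 1, one gap
_INF = 1 << 40


@dataclass(frozen=True)
class ErrorCounts:
    """Error decomposition of one query/target alignment."""

    mismatches: int
    insertions: int
    deletions: int
    query_len: int

    @property
    def total(self) -> int:
        return self.mismatches + self.insertions + self.deletions


def _packed_min_cost(query: np.ndarray, target: np.ndarray) -> int:
    """Anti-diagonal DP over the packed (cost, gaps) objective."""
    m, n = len(query), len(target)
    prev2 = None
    prev1 = np.full(m + 1, _INF, dtype=np.int64)
    prev1[0] = 0
    for s in range(1, m + n + 1):
        cur = np.full(m + 1, _INF, dtype=np.int64)
        lo = max(0, s - n)
        hi = min(m, s)
        if lo == 0:
            cur[0] = s * _GAP            # first row: all deletions
        if hi == s and s <= m:
            cur[s] = s * _GAP            # first column: all insertions
        a = max(lo, 1)
        b = min(hi, s - 1)
        if a <= b:
            i = np.arange(a, b + 1)
            step = np.minimum(prev1[a - 1:b] + _GAP, prev1[a:b + 1] + _GAP)
            if s >= 2 and prev2 is not None:
                mismatch = (query[a - 1:b] != target[s - b - 1:s - a][::-1])
                diag = prev2[a - 1:b] + mismatch.astype(np.int64) * _SUB
                step = np.minimum(step, diag)
            cur[a:b + 1] = np.minimum(cur[a:b + 1], step)
        prev2, prev1 = prev1, cur
    return int(prev1[m])


def unit_cost_align(query: str, target: str) -> ErrorCounts:
    """Globally align two sequences with all-unit costs and count errors."""
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    if len(query) + len(target) >= _GAP_BASE:
        raise ValueError("sequences too long for the packed DP objective")
    q = np.frombuffer(query.upper().encode(), dtype=np.uint8)
    t = np.frombuffer(target.upper().encode(), dtype=np.uint8)
    packed = _packed_min_cost(q, t)
    cost, gaps = divmod(packed, _GAP_BASE)
    diff = len(q) - len(t)
    insertions = (gaps + diff) // 2
    deletions = (gaps - diff) // 2
    return ErrorCounts(mismatches=cost - gaps, insertions=insertions,
                       deletions=deletions, query_len=len(q))


def error_percentage(counts: Sequence[ErrorCounts] | ErrorCounts) -> float:
    """Pooled error percent: 100 * (mm + ins + del) / (sum of query lengths)."""
    if isinstance(counts, ErrorCounts):
        counts = [counts]
    counts = list(counts)
    if not counts:
        raise ValueError("no error counts supplied")
    total_len = sum(c.query_len for c in counts)
    if total_len <= 0:
        raise ValueError("total query length must be positive")
    return 100.0 * sum(c.total for c in counts) / total_len
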
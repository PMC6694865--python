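"""Quality/length filtering and terminal adapter removal for raw reads.

A read is kept when its arithmetic mean Phred score reaches ``min_mean_q``
and its length lies within [min_len, max_len], bounds inclusive.  Adapter
trimming searches each adapter with the error-tolerant primer matcher in a
window at either read end (ligation adapters are terminal; the window keeps
chance mid-read hits from truncating the insert) and removes the best hit
together with everything outward of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from .io_seq import Read
from .primers import PrimerHit, PrimerParams, find_primer

#: How far from a read end an adapter occurrence may start.
ADAPTER_WINDOW = 150


@dataclass(frozen=True)
class FilterParams:
    min_mean_q: float = 10.0
    min_len: int = 500
    max_len: int = 800

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if self.min_mean_q < 0:
            raise ValueError("min_mean_q must be >= 0")


@dataclass
class FilterStats:
    n_input: int = 0
    n_kept: int = 0
    n_dropped_quality: int = 0
    n_dropped_length: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_quality + self.n_dropped_length


def mean_quality(read: Read) -> float:
    """Arithmetic mean of the per-base Phred scores."""
    if len(read) == 0:
        raise ValueError(f"read {read.read_id!r} is empty")
    return sum(read.qualities) / len(read)


def filter_reads(reads: Iterable[Read], params: FilterParams = FilterParams()
                 ) -> Tuple[List[Read], FilterStats]:
    """Keep reads passing the mean-quality and length window.

    Length is checked first for bookkeeping; each dropped read is counted
    under exactly one reason.
    """
    kept: List[Read] = []
    stats = FilterStats()
    for read in reads:
        stats.n_input += 1
        if not (params.min_len <= len(read) <= params.max_len):
            stats.n_dropped_length += 1
        elif mean_quality(read) < params.min_mean_q:
            stats.n_dropped_quality += 1
        else:
            kept.append(read)
            stats.n_kept += 1
    return kept, stats


def _window_hit(read: Read, adapters: Sequence[str], params: PrimerParams,
                end: str) -> Optional[PrimerHit]:
    if end == "left":
        region = read.sequence[:ADAPTER_WINDOW + max(map(len, adapters))]
        offset = 0
    else:
        span = ADAPTER_WINDOW + max(map(len, adapters))
        region = read.sequence[-span:]
        offset = len(read) - len(region)
    best: Optional[PrimerHit] = None
    for idx, adapter in enumerate(adapters):
        hit = find_primer(region, adapter, params, primer_index=idx)
        if hit is None:
            continue
        if end == "left" and hit.read_start > ADAPTER_WINDOW:
            continue
        if end == "right" and offset + hit.read_end < len(read) - ADAPTER_WINDOW:
            continue
        if best is None or (hit.edits, -hit.matched_len) < (best.edits,
                                                            -best.matched_len):
            best = PrimerHit(hit.primer_index, hit.strand,
                             hit.read_start + offset, hit.read_end + offset,
                             hit.edits, hit.matched_len)
    return best


def trim_terminal_adapters(read: Read, adapters: Sequence[str],
                           max_error_rate: float = 0.20,
                           min_overlap: int = 15) -> Read:
    """Remove terminal adapter occurrences and everything outward of them.

    Each end is handled independently; a read without adapter hits is
    returned unchanged (same object).
    """
    if not adapters or len(read) == 0:
        return read
    params = PrimerParams(max_error_rate=max_error_rate,
                          min_overlap=min_overlap)
    left = _window_hit(read, adapters, params, "left")
    start = left.read_end if left is not None else 0
    right = _window_hit(read, adapters, params, "right")
    end = right.read_start if right is not None else len(read)
    if right is not None and end < start:
        end = start
    if start == 0 and end == len(read):
        return read
    return read.slice(start, end)
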
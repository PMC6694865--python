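"""Error-tolerant primer detection, marker classification and trimming.

A primer is located in a read by semi-global edit-distance alignment: the
primer must be aligned end to end *except* that it may overhang either end of
the read, in which case only the overlapping part counts and must still span
at least ``min_overlap`` bases.  A hit is accepted when its edit distance does
not exceed ``floor(max_error_rate * matched_len)`` — the integerised error
budget used by common adapter-trimming tools.  IUPAC degeneracy is free on the
primer side only; an ``N`` in the read matches nothing.

The search runs on a padded copy of the read: ``pad = primer_len -
min_overlap`` sentinel characters are appended to each end and declared equal
to every primer character, so a primer overhanging a read end aligns its
overhanging bases to the sentinels at zero cost.  This reduces the whole
free-overhang search to a single infix edit-distance query, served by edlib's
bit-parallel aligner.  In the rare case where every minimum-edit placement
fails its overlap-dependent error budget, the search falls back to explicit
per-overhang-class queries so that the returned hit is exactly the
fewest-edit placement that satisfies both thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import edlib

from .io_seq import Read, reverse_complement

#: IUPAC nucleotide codes and the bases each denotes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_PAD = "#"
# Read-side alphabet is ACGTN; substituting primer-side N with a private
# symbol keeps a read N from matching a literal primer base through the
# shared equality pair.
_PRIMER_N = "?"


@dataclass(frozen=True)
class PrimerParams:
    """Thresholds of the primer matcher."""

    max_error_rate: float = 0.20
    min_overlap: int = 15

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_error_rate <= 1.0:
            raise ValueError("max_error_rate must lie in [0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass(frozen=True)
class MarkerPrimerSet:
    """A barcode marker with forward/reverse primer cocktails (IUPAC allowed)."""

    marker: str
    forward: Tuple[str, ...]
    reverse: Tuple[str, ...]

    def __init__(self, marker: str, forward, reverse) -> None:
        if isinstance(forward, str):
            forward = (forward,)
        if isinstance(reverse, str):
            reverse = (reverse,)
        if not forward or not reverse:
            raise ValueError("at least one forward and one reverse primer required")
        object.__setattr__(self, "marker", marker)
        object.__setattr__(self, "forward", tuple(p.upper() for p in forward))
        object.__setattr__(self, "reverse", tuple(p.upper() for p in reverse))


@dataclass(frozen=True)
class PrimerHit:
    """One accepted primer placement on a read (0-based, half-open).

    ``matched_len`` is the read-side span of the hit (read_end -
    read_start): the number of read bases covered by the primer alignment.
    Both the minimum-overlap requirement and the error budget
    ``floor(max_error_rate * matched_len)`` are evaluated on this span.
    """

    primer_index: int
    strand: str          # "+" or "-"; filled in by the classifier
    read_start: int
    read_end: int
    edits: int
    matched_len: int


def _equalities(primer: str) -> list[Tuple[str, str]]:
    pairs = [(_PAD, c) for c in set(primer)]
    for code in set(primer):
        bases = IUPAC.get(code if code != _PRIMER_N else "N")
        if bases is None:
            raise ValueError(f"unknown IUPAC code {code!r} in primer")
        for b in bases:
            if b != code:
                pairs.append((code, b))
    return pairs


def _prepare_primer(primer: str) -> str:
    primer = primer.upper()
    if any(c not in IUPAC for c in primer):
        bad = sorted(set(primer) - set(IUPAC))
        raise ValueError(f"unknown IUPAC code(s) {bad} in primer {primer!r}")
    return primer.replace("N", _PRIMER_N)


def _budget(rate: float, span: int) -> int:
    return int(rate * span + 1e-9)


def _max_edits(rate: float, m: int) -> int:
    # a valid hit spans at most m + edits read bases, so
    # edits <= rate * (m + edits)  =>  edits <= rate * m / (1 - rate)
    if rate >= 1.0:
        return m
    return int(rate * m / (1.0 - rate) + 1e-9)


def _iupac_cost(primer_code: str, read_base: str) -> int:
    if read_base == "N":
        return 1
    code = "N" if primer_code == _PRIMER_N else primer_code
    return 0 if read_base in IUPAC[code] else 1


def _candidates_exact(primer: str, sequence: str,
                      params: PrimerParams) -> list[Tuple[int, int, int, int]]:
    """Enumerate (edits, start, end, span) of every admissible placement.

    Slow path: plain dynamic programming over every overhang class and
    start position.  Only reached when every optimal placement of the
    padded fast path violates its own span-dependent error budget, which
    essentially requires an adversarial read; quadratic cost in the read
    length is acceptable there.  For reads beyond 200 nt the enumeration
    narrows to per-overhang-class optima found with the bit-parallel
    aligner, which is threshold-exact but does not enumerate every
    start/end pair.
    """
    m, n = len(primer), len(sequence)
    if n > 200:
        return _candidates_by_class(primer, sequence, params)
    out: list[Tuple[int, int, int, int]] = []
    for t_left in range(0, m - params.min_overlap + 1):
        for t_right in range(0, m - params.min_overlap - t_left + 1):
            if t_left and t_right and n >= m:
                continue
            core = primer[t_left: m - t_right]
            starts = [0] if t_left else range(n + 1)
            for s in starts:
                window = sequence[s:]
                prev = list(range(len(window) + 1))
                for i, code in enumerate(core, 1):
                    cur = [i] + [0] * len(window)
                    for j in range(1, len(window) + 1):
                        cur[j] = min(prev[j - 1] + _iupac_cost(code,
                                                               window[j - 1]),
                                     prev[j] + 1, cur[j - 1] + 1)
                    prev = cur
                ends = [n] if t_right else range(s, n + 1)
                for e in ends:
                    out.append((prev[e - s], s, e, e - s))
    return out


def _candidates_by_class(primer: str, sequence: str,
                         params: PrimerParams) -> list[Tuple[int, int, int, int]]:
    """Per-overhang-class optima via edlib; fallback for long reads."""
    eq = _equalities(primer)
    m, n = len(primer), len(sequence)
    kmax = _max_edits(params.max_error_rate, m)
    out: list[Tuple[int, int, int, int]] = []
    res = edlib.align(primer, sequence, mode="HW", task="locations",
                      k=kmax, additionalEqualities=eq)
    if res["editDistance"] >= 0:
        for s, e in res["locations"]:
            out.append((res["editDistance"], s, e + 1, e + 1 - s))
    for t in range(1, m - params.min_overlap + 1):
        part = primer[t:]
        window = sequence[: len(part) + kmax]
        res = edlib.align(part, window, mode="SHW", task="locations",
                          k=kmax, additionalEqualities=eq)
        if res["editDistance"] >= 0:
            for _, e in res["locations"]:
                out.append((res["editDistance"], 0, e + 1, e + 1))
        part = primer[: m - t]
        window = sequence[-(len(part) + kmax):]
        off = n - len(window)
        res = edlib.align(part[::-1], window[::-1], mode="SHW",
                          task="locations", k=kmax, additionalEqualities=eq)
        if res["editDistance"] >= 0:
            for _, e in res["locations"]:
                start = off + len(window) - (e + 1)
                out.append((res["editDistance"], start, n, n - start))
    return out


def find_primer(sequence: str, primer: str,
                params: PrimerParams = PrimerParams(),
                primer_index: int = 0, strand: str = "+") -> Optional[PrimerHit]:
    """Locate the best occurrence of ``primer`` in ``sequence``.

    The primer may overhang either read end (the overhanging part is free);
    a placement qualifies when its read-side span reaches ``min_overlap``
    and its edit distance stays within ``floor(max_error_rate * span)``.
    Among qualifying placements the fewest-edit one is returned, ties
    broken by leftmost start, then longest span; placements that tie on all
    of edits, start and span are resolved deterministically.  ``None`` when
    no placement qualifies.
    """
    primer = _prepare_primer(primer)
    m = len(primer)
    if m < params.min_overlap:
        raise ValueError(
            f"primer length {m} is below the minimum overlap {params.min_overlap}"
        )
    sequence = sequence.upper()
    if not sequence:
        return None
    kmax = _max_edits(params.max_error_rate, m)
    pad = _PAD * min(m - 1, m - params.min_overlap + kmax)
    padded = pad + sequence + pad
    res = edlib.align(primer, padded, mode="HW", task="locations", k=kmax,
                      additionalEqualities=_equalities(primer))

    best: Optional[Tuple[int, int, int, int]] = None  # edits, start, -span, end

    def consider(edits: int, start: int, end: int, span: int) -> None:
        nonlocal best
        if span < params.min_overlap:
            return
        if edits > _budget(params.max_error_rate, span):
            return
        key = (edits, start, -span, end)
        if best is None or key < best:
            best = key

    if res["editDistance"] < 0:
        # no placement within kmax edits at all; since any qualifying hit
        # has edits <= rate * span <= rate * (m + edits), i.e. <= kmax,
        # none can exist
        return None
    p = len(pad)
    n = len(sequence)
    for s, e in res["locations"]:
        start = max(0, s - p)
        end = min(n, e + 1 - p)
        consider(res["editDistance"], start, end, end - start)

    if best is None:
        # all minimum-edit placements failed their budget; exact slow path
        for edits, start, end, span in _candidates_exact(primer, sequence,
                                                         params):
            consider(edits, start, end, span)

    if best is None:
        return None
    edits, start, neg_span, end = best
    return PrimerHit(primer_index=primer_index, strand=strand,
                     read_start=start, read_end=end, edits=edits,
                     matched_len=-neg_span)


def _best_of(sequence: str, primers: Sequence[str], params: PrimerParams,
             strand: str) -> Optional[PrimerHit]:
    best: Optional[PrimerHit] = None
    for idx, primer in enumerate(primers):
        hit = find_primer(sequence, primer, params, primer_index=idx,
                          strand=strand)
        if hit is None:
            continue
        if best is None or (hit.edits, hit.read_start, -hit.matched_len) < (
                best.edits, best.read_start, -best.matched_len):
            best = hit
    return best


@dataclass(frozen=True)
class Classification:
    marker: str                      # marker name or "unassigned"
    orientation: str                 # "+", "-", or "" when unassigned
    hits: Tuple[PrimerHit, ...]      # 0-2 accepted hits, 5'-most first


def _orientation_evidence(sequence: str, pset: MarkerPrimerSet,
                          params: PrimerParams, orientation: str
                          ) -> Tuple[Optional[PrimerHit], Optional[PrimerHit]]:
    """Best 5'- and 3'-side hits for one read orientation.

    On the plus strand the read runs forward-primer .. insert ..
    revcomp(reverse primer); on the minus strand it runs reverse primer ..
    revcomp(insert) .. revcomp(forward primer).
    """
    if orientation == "+":
        five = pset.forward
        three = tuple(reverse_complement(p) for p in pset.reverse)
    else:
        five = pset.reverse
        three = tuple(reverse_complement(p) for p in pset.forward)
    return (_best_of(sequence, five, params, orientation),
            _best_of(sequence, three, params, orientation))


def _score(h5: Optional[PrimerHit], h3: Optional[PrimerHit]
           ) -> Tuple[int, int, Tuple[PrimerHit, ...]]:
    """(n_hits, total_edits, ordered hits); incompatible pairs degrade to one hit."""
    if h5 is not None and h3 is not None:
        if h5.read_end <= h3.read_start:
            return 2, h5.edits + h3.edits, (h5, h3)
        h5, h3 = (h5, None) if (h5.edits, -h5.matched_len) <= (
            h3.edits, -h3.matched_len) else (None, h3)
    if h5 is not None:
        return 1, h5.edits, (h5,)
    if h3 is not None:
        return 1, h3.edits, (h3,)
    return 0, 0, ()


def classify_read(read: Read, markers: Sequence[MarkerPrimerSet],
                  params: PrimerParams = PrimerParams()) -> Classification:
    """Assign a read to the marker whose primers it carries.

    A read is assigned when at least one primer of a marker is found; when
    both ends are found they must be mutually compatible (5' hit before the
    3' hit).  Two-hit evidence beats one-hit evidence, then fewer total
    edits; an exact tie between markers leaves the read unassigned.
    """
    if not markers:
        raise ValueError("at least one marker primer set required")
    seq = read.sequence
    scored: list[Tuple[int, int, str, str, Tuple[PrimerHit, ...]]] = []
    for pset in markers:
        per_orient = []
        for orientation in ("+", "-"):
            h5, h3 = _orientation_evidence(seq, pset, params, orientation)
            n, edits, hits = _score(h5, h3)
            per_orient.append((n, edits, orientation, hits))
        n, edits, orientation, hits = max(
            per_orient, key=lambda t: (t[0], -t[1], t[2] == "+"))
        if n > 0:
            scored.append((n, edits, pset.marker, orientation, hits))
    if not scored:
        return Classification("unassigned", "", ())
    scored.sort(key=lambda t: (-t[0], t[1]))
    if len(scored) > 1 and scored[0][:2] == scored[1][:2]:
        return Classification("unassigned", "", ())
    n, edits, marker, orientation, hits = scored[0]
    return Classification(marker, orientation, hits)


def trim_primers(read: Read, hits: Sequence[PrimerHit]) -> Read:
    """Cut the read down to the interval strictly between its primer hits.

    Orientation is left as-is; strand normalisation happens at the MSA stage.
    A single hit trims that end only.  Overlapping hits indicate a degenerate
    amplicon and raise.
    """
    if not hits:
        return read
    if len(hits) == 1:
        h = hits[0]
        # a hit nearer the 5' end trims the prefix, else the suffix
        if h.read_start < len(read) - h.read_end:
            return read.slice(h.read_end, len(read))
        return read.slice(0, h.read_start)
    h5, h3 = sorted(hits, key=lambda h: h.read_start)[:2]
    if h5.read_end > h3.read_start:
        raise ValueError(
            f"primer hits overlap on read {read.read_id!r} "
            f"({h5.read_start}-{h5.read_end} vs {h3.read_start}-{h3.read_end})"
        )
    return read.slice(h5.read_end, h3.read_start)


@dataclass
class CarryoverReport:
    """Run-to-run carry-over: reads from a previous run's marker in this run."""

    n_total: int
    n_classified: int
    n_current: int
    n_other: int
    per_marker: dict

    @property
    def fraction_of_classified(self) -> Optional[float]:
        if self.n_classified == 0:
            return None
        return self.n_other / self.n_classified

    @property
    def fraction_of_total(self) -> Optional[float]:
        if self.n_total == 0:
            return None
        return self.n_other / self.n_total


def carryover_fraction(reads: Iterable[Read], current_marker: MarkerPrimerSet,
                       other_markers: Sequence[MarkerPrimerSet],
                       params: PrimerParams = PrimerParams()) -> CarryoverReport:
    """Fraction of marker-classified reads belonging to a *different* marker.

    Unassigned reads are excluded from the primary denominator; the
    fraction over all reads is also reported because published carry-over
    figures do not always state which denominator was used.
    """
    markers = [current_marker, *other_markers]
    names = {m.marker for m in markers}
    if len(names) != len(markers):
        raise ValueError("marker names must be disjoint")
    counts = {m.marker: 0 for m in markers}
    counts["unassigned"] = 0
    total = 0
    for read in reads:
        total += 1
        counts[classify_read(read, markers, params).marker] += 1
    n_current = counts[current_marker.marker]
    n_other = sum(counts[m.marker] for m in other_markers)
    return CarryoverReport(n_total=total, n_classified=n_current + n_other,
                           n_current=n_current, n_other=n_other,
                           per_marker=dict(counts))
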
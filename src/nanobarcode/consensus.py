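"""Cluster subsampling, strand normalisation, MSA and majority consensus.

Clusters of noisy nanopore reads are collapsed into one error-corrected
barcode each: at most 100 reads are sampled per cluster, reads are flipped
onto the strand of the cluster representative, aligned with a center-star
progressive MSA, and summarised column-by-column with a 30% majority rule —
a column's winning nucleotide is emitted only when its within-column
frequency exceeds the threshold, and columns won by a gap vanish, so the
consensus length tracks the true amplicon length.

The center-star MSA aligns every read pairwise to a center read (the read
with the highest summed identity to a sample of its cluster mates) with a
unit-cost global aligner and merges the pairwise gaps into shared
coordinates ("once a gap, always a gap").  Insertions relative to the center
that fall between the same two center positions are stacked left-justified.
For clusters of highly similar reads this recovers the dominant sequence;
it makes no attempt at iterative refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import edlib
import numpy as np

from .clustering import Cluster
from .io_seq import Read, reverse_complement
from .primers import MarkerPrimerSet, PrimerHit, PrimerParams, find_primer


@dataclass
class MSA:
    """Rows of equal length over {A,C,G,T,N,-}; de-gapping row i gives read i."""

    rows: List[str]
    row_ids: List[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA must have at least one row")
        width = len(self.rows[0])
        if any(len(r) != width for r in self.rows):
            raise ValueError("MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class ConsensusRecord:
    """An error-corrected barcode with per-emitted-column winning fractions."""

    consensus_id: str
    sequence: str
    n_reads_used: int
    column_support: List[float]
    marker: str = ""


def subsample_cluster(cluster: Cluster, cap: int = 100, seed: int = 0) -> List[str]:
    """Pick at most ``cap`` member ids, uniformly at random, keeping member order."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if cluster.size <= cap:
        return list(cluster.member_ids)
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(cluster.size, size=cap, replace=False))
    return [cluster.member_ids[i] for i in chosen]


def orient_reads(reads: Sequence[Read], reference: str
                 ) -> Tuple[List[Read], List[bool]]:
    """Flip each read onto the strand matching ``reference`` better.

    The strand decision compares unit-cost alignment distances (the wrong
    strand of an amplicon read is far from the reference, so the comparison
    is unambiguous); ties keep the read as-is.
    """
    oriented: List[Read] = []
    flags: List[bool] = []
    for read in reads:
        fwd = edlib.align(read.sequence, reference, mode="NW")["editDistance"]
        rc = reverse_complement(read.sequence)
        rev = edlib.align(rc, reference, mode="NW")["editDistance"]
        if rev < fwd:
            oriented.append(Read(read.read_id, rc,
                                 list(read.qualities)[::-1]))
            flags.append(True)
        else:
            oriented.append(read)
            flags.append(False)
    return oriented, flags


def _identity_bound(seq_a: str, seq_b: str) -> float:
    """Fast identity proxy from the edit distance alone.

    (len_a + len_b - d) / 2 bounds the number of identical columns of any
    cost-optimal alignment; for the near-equal-length, highly similar reads
    of one cluster it tracks true identity closely and ranks center
    candidates equally well at a fraction of the cost.
    """
    d = edlib.align(seq_a, seq_b, mode="NW")["editDistance"]
    return 100.0 * (len(seq_a) + len(seq_b) - d) / 2 / min(len(seq_a),
                                                           len(seq_b))


def _pick_center(seqs: Sequence[str], max_partners: int, seed: int) -> int:
    n = len(seqs)
    rng = np.random.default_rng(seed)
    totals = np.zeros(n)
    for i in range(n):
        if n - 1 <= max_partners:
            partners = [j for j in range(n) if j != i]
        else:
            partners = rng.choice([j for j in range(n) if j != i],
                                  size=max_partners, replace=False)
        for j in partners:
            totals[i] += _identity_bound(seqs[i], seqs[j])
        totals[i] /= max(1, len(partners))
    return int(np.argmax(totals))


def _align_to_center(seq: str, center: str) -> Tuple[List[str], Dict[int, str]]:
    """Project ``seq`` onto center coordinates.

    Returns (per-center-position characters, '-' for gaps) and a map of
    insertion slot -> inserted bases, where slot g sits between center
    positions g-1 and g.
    """
    res = edlib.align(seq, center, mode="NW", task="path")
    aligned = ["-"] * len(center)
    inserts: Dict[int, str] = {}
    qi = 0
    cj = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        length = int(num)
        num = ""
        if ch in "=X":
            for _ in range(length):
                aligned[cj] = seq[qi]
                qi += 1
                cj += 1
        elif ch == "I":          # bases present in the read only
            inserts[cj] = inserts.get(cj, "") + seq[qi:qi + length]
            qi += length
        elif ch == "D":          # center base missing from the read
            cj += length
    return aligned, inserts


def build_msa(reads: Sequence[Read], center_samples: int = 20,
              seed: int = 0) -> MSA:
    """Center-star multiple alignment of oriented, mutually similar reads."""
    if len(reads) < 2:
        raise ValueError("an MSA needs at least 2 reads")
    seqs = [r.sequence for r in reads]
    if any(not s for s in seqs):
        raise ValueError("cannot align empty reads")
    center_idx = _pick_center(seqs, center_samples, seed)
    center = seqs[center_idx]
    per_read: List[Tuple[List[str], Dict[int, str]]] = []
    widths = np.zeros(len(center) + 1, dtype=int)
    for i, seq in enumerate(seqs):
        if i == center_idx:
            per_read.append((list(center), {}))
            continue
        aligned, inserts = _align_to_center(seq, center)
        per_read.append((aligned, inserts))
        for slot, ins in inserts.items():
            widths[slot] = max(widths[slot], len(ins))
    rows: List[str] = []
    for aligned, inserts in per_read:
        parts: List[str] = []
        for slot in range(len(center) + 1):
            if widths[slot]:
                ins = inserts.get(slot, "")
                parts.append(ins.ljust(widths[slot], "-"))
            if slot < len(center):
                parts.append(aligned[slot])
        rows.append("".join(parts))
    return MSA(rows=rows, row_ids=[r.read_id for r in reads])


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def majority_consensus(msa: MSA, threshold: float = 0.30,
                       consensus_id: str = "consensus",
                       marker: str = "") -> ConsensusRecord:
    """Column-wise majority call with a winning-fraction cutoff.

    Per column the frequencies of A, C, G, T and '-' are computed over the
    non-N symbols.  The winning symbol is emitted when it is a base and its
    frequency strictly exceeds ``threshold``; columns won by a gap, or whose
    winner does not clear the cutoff, are dropped.  A base beats a gap on a
    frequency tie; base-base ties go to the alphabetically first base.
    """
    arr = np.frombuffer("".join(msa.rows).encode(), dtype=np.uint8)
    arr = arr.reshape(msa.n_rows, msa.n_columns)
    base_counts = np.stack([(arr == b).sum(axis=0) for b in _BASES])
    gap_counts = (arr == ord("-")).sum(axis=0)
    n_counts = (arr == ord("N")).sum(axis=0)
    denom = msa.n_rows - n_counts
    best_base = base_counts.max(axis=0)
    best_idx = base_counts.argmax(axis=0)          # first max = alphabetical
    with np.errstate(divide="ignore", invalid="ignore"):
        support = np.where(denom > 0, best_base / np.maximum(denom, 1), 0.0)
    emit = (denom > 0) & (best_base >= gap_counts) & (support > threshold) \
        & (best_base > 0)
    sequence = _BASES[best_idx[emit]].tobytes().decode()
    return ConsensusRecord(consensus_id=consensus_id, sequence=sequence,
                           n_reads_used=msa.n_rows,
                           column_support=[float(s) for s in support[emit]],
                           marker=marker)


def _terminal_hit(sequence: str, candidates: Sequence[str],
                  params: PrimerParams, end: str) -> Optional[PrimerHit]:
    """Best residue hit inside a terminal window; coordinates on ``sequence``."""
    if not sequence:
        return None
    window = 2 * max(len(p) for p in candidates)
    if end == "left":
        region = sequence[:window]
        offset = 0
    else:
        region = sequence[-window:]
        offset = len(sequence) - len(region)
    best: Optional[PrimerHit] = None
    for idx, primer in enumerate(candidates):
        hit = find_primer(region, primer, params, primer_index=idx)
        if hit is None:
            continue
        if best is None or (hit.edits, -hit.matched_len) < (best.edits,
                                                            -best.matched_len):
            best = PrimerHit(hit.primer_index, hit.strand,
                             hit.read_start + offset, hit.read_end + offset,
                             hit.edits, hit.matched_len)
    return best


def strip_primer_residues(consensus: ConsensusRecord,
                          markers: Sequence[MarkerPrimerSet],
                          params: PrimerParams = PrimerParams()
                          ) -> ConsensusRecord:
    """Remove leftover primer sequence from the consensus termini.

    Residues are searched with the same error-tolerant matcher used for
    demultiplexing, on either strand of every primer of the consensus's
    marker (all markers when the marker is unknown), in a window of twice
    the primer length at each end; interior occurrences are left alone.
    """
    relevant = [m for m in markers if m.marker == consensus.marker] or list(markers)
    candidates: List[str] = []
    for pset in relevant:
        for p in (*pset.forward, *pset.reverse):
            candidates.append(p)
            candidates.append(reverse_complement(p))
    if not candidates or not consensus.sequence:
        return consensus
    seq = consensus.sequence
    support = list(consensus.column_support)
    left = _terminal_hit(seq, candidates, params, "left")
    if left is not None:
        seq = seq[left.read_end:]
        support = support[left.read_end:]
    right = _terminal_hit(seq, candidates, params, "right")
    if right is not None:
        seq = seq[:right.read_start]
        support = support[:right.read_start]
    return ConsensusRecord(consensus_id=consensus.consensus_id, sequence=seq,
                           n_reads_used=consensus.n_reads_used,
                           column_support=support, marker=consensus.marker)
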
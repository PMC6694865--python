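"""Greedy incremental clustering of primer-trimmed reads.

Reads are processed longest-first; each read joins the existing cluster whose
representative it matches best at or above the identity threshold, otherwise
it founds a new cluster.  Identity follows the CD-HIT convention for
nucleotide clustering: matched columns of a unit-cost global alignment,
divided by the length of the shorter sequence.  Because nanopore amplicon
libraries contain both strands, a candidate is compared to each
representative on both strands by default and the better orientation counts.

A q-gram prescreen can skip representative comparisons that provably cannot
reach the threshold (each edit destroys at most *k* of a sequence's k-mers),
so enabling it never changes the clustering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import edlib

from .io_seq import Read, reverse_complement


@dataclass
class Cluster:
    cluster_id: int
    representative_id: str
    member_ids: List[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _cigar_matches(cigar: str) -> int:
    matches = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch == "=":
                matches += int(num)
            num = ""
    return matches


def alignment_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity of the unit-cost global alignment of two sequences.

    Identity = 100 * (identical aligned positions) / min(len_a, len_b).
    Cost-optimal alignments can differ in how many identical columns they
    contain; the pair is aligned in a canonical (sorted) argument order so
    the reported identity is deterministic and symmetric.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    res = edlib.align(seq_a, seq_b, mode="NW", task="path")
    return 100.0 * _cigar_matches(res["cigar"]) / min(len(seq_a), len(seq_b))


def strand_identity(seq: str, reference: str) -> float:
    """Identity of ``seq`` or its reverse complement to ``reference``,
    whichever is higher — the comparison used during clustering, where
    nanopore amplicon reads arrive on both strands."""
    return max(alignment_identity(seq, reference),
               alignment_identity(reverse_complement(seq), reference))


def pairwise_identity(seq_a: str, seq_b: str, both_strands: bool = False) -> float:
    """Percent identity between two sequences; optionally the better strand."""
    if both_strands:
        return strand_identity(seq_a, seq_b)
    return alignment_identity(seq_a, seq_b)


def _kmer_counter(seq: str, k: int) -> Counter:
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


def _shared_kmers(a: Counter, b: Counter) -> int:
    if len(b) < len(a):
        a, b = b, a
    return sum(min(n, b[kmer]) for kmer, n in a.items() if kmer in b)


def _identity_vs_rep(seq: str, seq_rc: str, rep: str, threshold: float,
                     kmers: Optional[Counter], rep_kmers, k: int,
                     both_strands: bool) -> float:
    """Best-strand identity of ``seq`` vs a representative, with prescreen.

    The maximum useful edit distance follows from the identity target: an
    alignment with M identical columns has edit distance at most
    len_a + len_b - 2M, so identities >= threshold require
    d <= len_a + len_b - 2 * ceil(threshold/100 * min_len).  That bound
    feeds a banded distance-only screen and, via the q-gram lemma
    (shared k-mers >= (min_len - k + 1) - k * d), the skip test.  Pairs
    passing the screen are re-aligned unbanded so the reported identity is
    exactly ``alignment_identity``; the screens only ever skip pairs that
    provably fall below the threshold.
    """
    min_len = min(len(seq), len(rep))
    need_matches = -(-int(threshold * min_len) // 100)  # ceil
    dmax = len(seq) + len(rep) - 2 * need_matches
    if dmax < 0:
        return 0.0
    best = 0.0
    strands = ((seq, kmers[0]), (seq_rc, kmers[1])) if both_strands else \
        ((seq, kmers[0]),)
    for s, counter in strands:
        if counter is not None and rep_kmers is not None:
            bound = (min_len - k + 1) - k * dmax
            if bound > 0 and _shared_kmers(counter, rep_kmers) < bound:
                continue
        res = edlib.align(s, rep, mode="NW", task="distance", k=dmax)
        if res["editDistance"] < 0:
            continue
        ident = alignment_identity(s, rep)
        if ident > best:
            best = ident
    return best


def greedy_cluster(reads: Sequence[Read], threshold: float = 80.0,
                   kmer_prescreen: Optional[int] = 5,
                   both_strands: bool = True) -> List[Cluster]:
    """Cluster reads greedily at ``threshold`` percent identity.

    Reads are sorted by length descending (ties keep input order); each read
    joins the cluster whose representative gives the highest identity at or
    above the threshold, ties going to the lowest cluster id, otherwise it
    founds a new cluster with itself as representative.
    ``kmer_prescreen`` gives the q-gram word size (None disables the
    prescreen; the result is identical either way).
    """
    if not reads:
        raise ValueError("no reads to cluster")
    order = sorted(range(len(reads)), key=lambda i: -len(reads[i]))
    clusters: List[Cluster] = []
    rep_seqs: List[str] = []
    rep_kmers: List[Optional[Counter]] = []
    k = kmer_prescreen
    for idx in order:
        read = reads[idx]
        seq = read.sequence
        seq_rc = reverse_complement(seq) if both_strands else ""
        if k is not None and len(seq) >= k:
            kmers = (_kmer_counter(seq, k), _kmer_counter(seq_rc, k)
                     if both_strands else None)
        else:
            kmers = (None, None)
        best_ident = -1.0
        best_cluster: Optional[Cluster] = None
        for cluster, rep, rk in zip(clusters, rep_seqs, rep_kmers):
            ident = _identity_vs_rep(seq, seq_rc, rep, threshold, kmers, rk,
                                     k or 0, both_strands)
            if ident >= threshold and ident > best_ident:
                best_ident = ident
                best_cluster = cluster
        if best_cluster is not None:
            best_cluster.member_ids.append(read.read_id)
        else:
            cluster = Cluster(cluster_id=len(clusters),
                              representative_id=read.read_id,
                              member_ids=[read.read_id])
            clusters.append(cluster)
            rep_seqs.append(seq)
            rep_kmers.append(_kmer_counter(seq, k)
                             if k is not None and len(seq) >= k else None)
    return clusters
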
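"""Taxonomic assignment of consensus barcodes and multi-marker combination.

Each consensus sequence is aligned locally (Smith-Waterman, match +1,
mismatch -2, linear gap -2) against every reference barcode of its marker,
on both strands.  Hits passing the identity and query-coverage thresholds
(defaults 98% and 90%) are candidates; among candidates only those within
``score_margin`` of the top raw score are kept, and the assignment is the
lowest common rank of the survivors: a single species gives a species-level
call, several species of one genus a genus-level call, several genera of
one family a family-level call, anything broader is left unassigned.

Reference sets here are small curated FASTA files, so exhaustive pairwise
alignment replaces heuristic database search; at fixed scoring parameters,
ranking by raw score is equivalent to ranking by bit score.

Across markers, species-level calls stand on their own: a species call is
final provided every other marker's call *for that lineage* is an ancestor
rank or absent.  Ancestor-rank calls (genus/family) that have a species
descendant among the calls are absorbed as corroboration; those without one
surface as their own genus- or family-level conclusions.  An optional
strict mode treats sibling species called by different markers, neither
corroborated by the other marker, as a conflict resolved at genus rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from skbio.alignment import pair_align

from .consensus import ConsensusRecord
from .io_seq import ReferenceRecord, reverse_complement

RANKS = ("species", "genus", "family")


@dataclass(frozen=True)
class Scoring:
    match: int = 1
    mismatch: int = -2
    gap: int = 2          # linear, subtracted per gapped position


@dataclass
class Hit:
    """One local alignment of a consensus against a reference barcode."""

    consensus_id: str
    accession: str
    lineage: Tuple[str, str, str]
    score: float
    identity: float            # percent over aligned columns
    coverage: float            # percent of the query spanned
    query_interval: Tuple[int, int]
    subject_interval: Tuple[int, int]
    strand: str = "+"


@dataclass
class TaxonomicAssignment:
    consensus_id: str
    rank: str                  # species | genus | family | unassigned
    taxon: str                 # empty when unassigned
    marker: str
    hits: List[Hit] = field(default_factory=list)


def _aligned_stats(path, query: str, subject: str) -> Tuple[int, int]:
    """(matches, aligned columns) of one alignment path."""
    aln_q, aln_s = path.to_aligned((query, subject))
    matches = sum(1 for a, b in zip(aln_q, aln_s)
                  if a == b and a != "-" and a != "N")
    return matches, len(aln_q)


def _align_one_strand(query: str, subject: str, scoring: Scoring):
    res = pair_align(query, subject, mode="local",
                     sub_score=(scoring.match, scoring.mismatch),
                     gap_cost=scoring.gap)
    return res


def align_to_reference(query: str, ref: ReferenceRecord,
                       scoring: Scoring = Scoring(),
                       consensus_id: str = "query") -> Hit:
    """Best local alignment of ``query`` against one reference, either strand."""
    if not query or not ref.sequence:
        raise ValueError("sequences must be non-empty")
    best = None
    for strand, seq in (("+", query), ("-", reverse_complement(query))):
        res = _align_one_strand(seq, ref.sequence, scoring)
        if best is None or res.score > best[1].score:
            best = (strand, res, seq)
    strand, res, seq = best
    if not res.paths or res.score <= 0:
        return Hit(consensus_id=consensus_id, accession=ref.accession,
                   lineage=ref.lineage, score=0.0, identity=0.0, coverage=0.0,
                   query_interval=(0, 0), subject_interval=(0, 0),
                   strand=strand)
    path = res.paths[0]
    (q0, q1), (s0, s1) = path.ranges
    matches, columns = _aligned_stats(path, seq, ref.sequence)
    identity = 100.0 * matches / columns if columns else 0.0
    coverage = 100.0 * (q1 - q0) / len(query)
    if strand == "-":
        q0, q1 = len(query) - q1, len(query) - q0
    return Hit(consensus_id=consensus_id, accession=ref.accession,
               lineage=ref.lineage, score=float(res.score), identity=identity,
               coverage=coverage, query_interval=(int(q0), int(q1)),
               subject_interval=(int(s0), int(s1)), strand=strand)


def assign(consensus: ConsensusRecord, refs: Sequence[ReferenceRecord],
           min_identity: float = 98.0, min_coverage: float = 90.0,
           score_margin: float = 0.0,
           scoring: Scoring = Scoring()) -> TaxonomicAssignment:
    """Resolve a consensus to the lowest common rank of its qualifying hits."""
    if not refs:
        raise ValueError("empty reference set")
    relevant = [r for r in refs if not consensus.marker
                or r.marker == consensus.marker]
    if not relevant:
        raise ValueError(
            f"no references for marker {consensus.marker!r}")
    hits = [align_to_reference(consensus.sequence, ref, scoring,
                               consensus_id=consensus.consensus_id)
            for ref in relevant]
    candidates = [h for h in hits
                  if h.identity >= min_identity and h.coverage >= min_coverage]
    if not candidates:
        return TaxonomicAssignment(consensus.consensus_id, "unassigned", "",
                                   consensus.marker, hits=[])
    top = max(h.score for h in candidates)
    kept = [h for h in candidates if h.score >= top - score_margin]
    species = {h.lineage[2] for h in kept}
    genera = {h.lineage[1] for h in kept}
    families = {h.lineage[0] for h in kept}
    if len(species) == 1:
        rank, taxon = "species", next(iter(species))
    elif len(genera) == 1:
        rank, taxon = "genus", next(iter(genera))
    elif len(families) == 1:
        rank, taxon = "family", next(iter(families))
    else:
        rank, taxon = "unassigned", ""
    return TaxonomicAssignment(consensus.consensus_id, rank, taxon,
                               consensus.marker, hits=kept)


@dataclass
class FinalConclusion:
    """Per-lineage verdict after combining the markers."""

    final_rank: str
    final_taxon: str
    lineage: Tuple[str, str, str]        # unknown trailing ranks empty
    per_marker: Dict[str, str]           # marker -> taxon label or absence code
    conflict: bool = False


def _lineage_of(assignment: TaxonomicAssignment) -> Tuple[str, str, str]:
    lineage = assignment.hits[0].lineage if assignment.hits else ("", "", "")
    if assignment.rank == "species":
        return lineage
    if assignment.rank == "genus":
        return (lineage[0], assignment.taxon, "")
    if assignment.rank == "family":
        return (assignment.taxon, "", "")
    return ("", "", "")


def _is_ancestor(anc: Tuple[str, str, str], desc: Tuple[str, str, str]) -> bool:
    for a, d in zip(anc, desc):
        if a and a != d:
            return False
    return True


def combine_markers(per_marker: Mapping[str, Sequence[TaxonomicAssignment]],
                    expected_markers: Sequence[str],
                    absence_labels: Optional[Mapping[Tuple[str, str], str]] = None,
                    strict_conflict: bool = False) -> List[FinalConclusion]:
    """Merge per-marker assignments into one conclusion per detected lineage.

    ``absence_labels`` optionally maps (taxon, marker) to a label such as
    "no reads" or "no amplicon" for markers that contributed nothing to a
    lineage; without a label such markers are reported as "not detected".
    """
    absence_labels = dict(absence_labels or {})
    calls: List[Tuple[str, TaxonomicAssignment, Tuple[str, str, str]]] = []
    for marker, assignments in per_marker.items():
        for a in assignments:
            if a.rank == "unassigned":
                continue
            calls.append((marker, a, _lineage_of(a)))

    conclusions: List[FinalConclusion] = []
    species_calls: Dict[str, List[Tuple[str, Tuple[str, str, str]]]] = {}
    for marker, a, lineage in calls:
        if a.rank == "species":
            species_calls.setdefault(a.taxon, []).append((marker, lineage))

    rank_order = {"species": 0, "genus": 1, "family": 2}

    def supporting_markers(lineage: Tuple[str, str, str]) -> Dict[str, str]:
        """Most specific ancestor-or-equal call per marker for this lineage."""
        support: Dict[str, Tuple[int, str]] = {}
        for marker, a, call_lineage in calls:
            if _is_ancestor(call_lineage, lineage):
                depth = rank_order[a.rank]
                if marker not in support or depth < support[marker][0]:
                    support[marker] = (depth, a.taxon)
        return {m: taxon for m, (_, taxon) in support.items()}
    for species, sightings in sorted(species_calls.items()):
        lineage = sightings[0][1]
        support = supporting_markers(lineage)
        per = {}
        for marker in expected_markers:
            if marker in support:
                per[marker] = support[marker]
            else:
                per[marker] = absence_labels.get((species, marker),
                                                 "not detected")
        conclusions.append(FinalConclusion("species", species, lineage, per))

    if strict_conflict:
        conclusions = _merge_sibling_conflicts(conclusions, calls,
                                               expected_markers)

    # ancestor-rank calls with no species descendant stand on their own
    species_lineages = [c.lineage for c in conclusions
                        if c.final_rank == "species"]
    seen_standalone: set = set()
    for marker, a, lineage in calls:
        if a.rank == "species":
            continue
        if any(_is_ancestor(lineage, sp) for sp in species_lineages):
            continue
        if strict_conflict and any(
                _is_ancestor(lineage, c.lineage) for c in conclusions):
            continue
        if (a.rank, a.taxon) in seen_standalone:
            continue
        seen_standalone.add((a.rank, a.taxon))
        support = supporting_markers(lineage)
        per = {m: support.get(m, absence_labels.get((a.taxon, m),
                                                    "not detected"))
               for m in expected_markers}
        conclusions.append(FinalConclusion(a.rank, a.taxon, lineage, per))
    return conclusions


def _merge_sibling_conflicts(conclusions, calls, expected_markers):
    """Strict mode: uncorroborated sibling species from different markers
    collapse into a single genus-level conclusion flagged as a conflict."""
    by_genus: Dict[Tuple[str, str], List[FinalConclusion]] = {}
    for c in conclusions:
        by_genus.setdefault(c.lineage[:2], []).append(c)
    merged: List[FinalConclusion] = []
    for (family, genus), group in by_genus.items():
        if len(group) < 2:
            merged.extend(group)
            continue
        def corroborated(c: FinalConclusion) -> bool:
            markers_with_species = {m for m, a, lin in calls
                                    if a.rank == "species"
                                    and a.taxon == c.final_taxon}
            ancestors = {m for m, a, lin in calls
                         if a.rank != "species"
                         and _is_ancestor(lin, c.lineage)}
            return bool(ancestors - markers_with_species)
        uncorroborated = [c for c in group if not corroborated(c)]
        if len(uncorroborated) >= 2:
            per: Dict[str, str] = {}
            for c in group:
                for m, label in c.per_marker.items():
                    if label not in ("not detected",) and (
                            m not in per):
                        per[m] = label
            for m in expected_markers:
                per.setdefault(m, "not detected")
            merged.append(FinalConclusion("genus", genus,
                                          (family, genus, ""), per,
                                          conflict=True))
        else:
            merged.extend(group)
    return merged
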
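"""Synthetic references, species mixtures and nanopore-like noisy reads.

The simulator makes every pipeline stage testable without any download: it
builds reference barcode sets with controlled divergence structure, attaches
primers to form amplicons, and corrupts amplicon copies with independent
per-base substitution/insertion/deletion errors totalling ~13% by default —
the error level of R9-era MinION reads this pipeline is designed to correct.
The split of the total across error kinds (0.08 substitution, 0.025
insertion, 0.025 deletion) reflects substitution-dominated nanopore error
profiles.  Reads are full-length amplicon copies on a random strand with
i.i.d. Phred qualities around a configurable mean; no positional quality or
homopolymer model is attempted.

All randomness flows through ``numpy.random.default_rng`` seeded explicitly,
so identical seeds give byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .io_seq import Read, ReferenceRecord, reverse_complement
from .primers import IUPAC, MarkerPrimerSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_STR = "ACGT"


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base error rates and the quality model of simulated reads."""

    sub_rate: float = 0.08
    ins_rate: float = 0.025
    del_rate: float = 0.025
    mean_q: float = 12.0
    q_sd: float = 3.0

    def __post_init__(self) -> None:
        if min(self.sub_rate, self.ins_rate, self.del_rate) < 0:
            raise ValueError("error rates must be non-negative")
        if self.sub_rate + self.ins_rate + self.del_rate >= 1:
            raise ValueError("combined error rate must stay below 1")

    @property
    def total(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate


PERFECT = ErrorProfile(sub_rate=0.0, ins_rate=0.0, del_rate=0.0)


@dataclass(frozen=True)
class Lineage:
    family: str
    genus: str
    species: str

    def as_tuple(self) -> Tuple[str, str, str]:
        return (self.family, self.genus, self.species)


@dataclass
class MixtureProfile:
    """Species weight fractions plus species/marker combinations that fail.

    ``marker_dropouts`` lists (species, marker) pairs that yield no amplicon
    (primer mismatch in the template); ``read_dropouts`` lists pairs whose
    amplicon sequences produce no reads passing the quality criteria.  Both
    contribute zero reads; the distinction only matters for reporting.
    """

    entries: List[Tuple[Lineage, float]]
    marker_dropouts: Set[Tuple[str, str]] = field(default_factory=set)
    read_dropouts: Set[Tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.entries)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weight fractions must sum to 1, got {total}")
        species = [lin.species for lin, _ in self.entries]
        if len(set(species)) != len(species):
            raise ValueError("every species may appear only once")

    @property
    def species(self) -> List[str]:
        return [lin.species for lin, _ in self.entries]

    def dropouts_for(self, marker: str) -> Set[str]:
        return ({s for s, m in self.marker_dropouts if m == marker}
                | {s for s, m in self.read_dropouts if m == marker})


def mixture_a() -> MixtureProfile:
    """Six-species flatfish mixture: one dominant species at 75% by weight."""
    entries = [
        (Lineage("Pleuronectidae", "Pleuronectes", "Pleuronectes platessa"), 0.75),
        (Lineage("Pleuronectidae", "Limanda", "Limanda limanda"), 0.05),
        (Lineage("Pleuronectidae", "Microstomus", "Microstomus kitt"), 0.05),
        (Lineage("Pleuronectidae", "Limanda", "Limanda aspera"), 0.05),
        (Lineage("Pleuronectidae", "Platichthys", "Platichthys flesus"), 0.05),
        (Lineage("Scophthalmidae", "Scophthalmus", "Scophthalmus rhombus"), 0.05),
    ]
    return MixtureProfile(
        entries=entries,
        marker_dropouts={("Scophthalmus rhombus", "COI")},
        read_dropouts={("Limanda aspera", "cytb")},
    )


def mixture_b() -> MixtureProfile:
    """Eleven-species mixture: 17% lemon sole plus ten species at 8.3% each."""
    lineages = [
        Lineage("Pleuronectidae", "Microstomus", "Microstomus kitt"),
        Lineage("Pleuronectidae", "Pleuronectes", "Pleuronectes platessa"),
        Lineage("Pleuronectidae", "Limanda", "Limanda limanda"),
        Lineage("Pleuronectidae", "Limanda", "Limanda aspera"),
        Lineage("Pleuronectidae", "Platichthys", "Platichthys flesus"),
        Lineage("Agonidae", "Agonus", "Agonus cataphractus"),
        Lineage("Cottidae", "Myoxocephalus", "Myoxocephalus scorpius"),
        Lineage("Pleuronectidae", "Hippoglossoides",
                "Hippoglossoides platessoides"),
        Lineage("Zoarcidae", "Zoarces", "Zoarces viviparus"),
        Lineage("Osmeridae", "Osmerus", "Osmerus eperlanus"),
        Lineage("Scophthalmidae", "Scophthalmus", "Scophthalmus maximus"),
    ]
    weights = [0.17] + [0.083] * 10
    entries = list(zip(lineages, weights))
    return MixtureProfile(
        entries=entries,
        marker_dropouts={("Scophthalmus maximus", "COI"),
                         ("Osmerus eperlanus", "cytb")},
        read_dropouts={("Limanda aspera", "cytb")},
    )


def default_primer_sets() -> List[MarkerPrimerSet]:
    """Synthetic demonstration primers for a cytb and a COI-like marker.

    These are arbitrary sequences with a couple of degenerate positions, not
    published primer sequences; real analyses supply their own primers.
    """
    return [
        MarkerPrimerSet("cytb",
                        forward=("GCTTACGGATTCATACGYAAGAACC",),
                        reverse=("CTGGATGAGAAGTTCRTCCGACA",)),
        MarkerPrimerSet("COI",
                        forward=("TCAACYAATCATAAAGACATCGGCAC",
                                 "TCAACCAACCACAAAGAYATTGGCAC"),
                        reverse=("ACTTCWGGGTGACCAAAGAATCA",)),
    ]


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int64)


def _mutate(rng: np.random.Generator, seq: np.ndarray,
            fraction: float) -> Tuple[np.ndarray, int]:
    """Substitute a ``fraction`` of positions to different bases."""
    n_sub = int(round(fraction * len(seq)))
    out = seq.copy()
    if n_sub == 0:
        return out, 0
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out[positions] = (out[positions] + rng.integers(1, 4, size=n_sub)) % 4
    return out, n_sub


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def generate_references(lineages: Sequence[Lineage],
                        markers: Sequence[str] = ("cytb", "COI"),
                        barcode_length: int = 600,
                        inter_species_divergence: float = 0.08,
                        seed: int = 0,
                        genus_divergence: Optional[float] = None,
                        divergence_overrides: Optional[
                            Mapping[str, float]] = None,
                        exclude: Iterable[Tuple[str, str]] = (),
                        ) -> Dict[str, List[ReferenceRecord]]:
    """Reference barcodes for explicit lineages, honouring shared ancestry.

    Species of one genus are derived from a common genus root so that
    congeners differ by about ``inter_species_divergence`` (optionally
    overridden per family via ``divergence_overrides``); genera of one
    family share a family root.  ``exclude`` drops (species, marker) pairs
    from the output, emulating database incompleteness while still
    generating the underlying barcode deterministically.
    """
    if not 0 < inter_species_divergence < 0.5:
        raise ValueError("inter_species_divergence must lie in (0, 0.5)")
    if genus_divergence is None:
        genus_divergence = min(0.45, 2.5 * inter_species_divergence)
    divergence_overrides = dict(divergence_overrides or {})
    exclude = set(exclude)
    rng = np.random.default_rng(seed)
    out: Dict[str, List[ReferenceRecord]] = {m: [] for m in markers}
    families: Dict[str, List[Lineage]] = {}
    for lin in lineages:
        families.setdefault(lin.family, []).append(lin)
    acc = 0
    for marker in markers:
        for family in sorted(families):
            members = families[family]
            fam_root = _random_sequence(rng, barcode_length)
            genera = sorted({lin.genus for lin in members})
            sp_div = divergence_overrides.get(family, inter_species_divergence)
            gen_div = min(0.45, 2.5 * sp_div) if family in divergence_overrides \
                else genus_divergence
            for genus in genera:
                genus_members = [lin for lin in members if lin.genus == genus]
                if len(genera) > 1:
                    # each root drifts half the target inter-genus divergence
                    genus_root, _ = _mutate(rng, fam_root, gen_div / 2)
                else:
                    genus_root = fam_root
                for lin in sorted(genus_members, key=lambda l: l.species):
                    if len(genus_members) > 1 and sp_div <= 0:
                        raise ValueError(
                            "zero divergence with multiple species per genus "
                            "would produce identical references")
                    species_seq, _ = _mutate(rng, genus_root, sp_div / 2)
                    acc += 1
                    if (lin.species, marker) in exclude:
                        continue
                    out[marker].append(ReferenceRecord(
                        accession=f"SYN{acc:04d}", marker=marker,
                        family=lin.family, genus=lin.genus,
                        species=lin.species, sequence=_to_str(species_seq)))
    return out


def generate_reference_set(n_families: int, species_per_genus: int,
                           barcode_length: int = 600,
                           inter_species_divergence: float = 0.08,
                           seed: int = 0,
                           markers: Sequence[str] = ("cytb", "COI"),
                           genera_per_family: int = 1,
                           ) -> Dict[str, List[ReferenceRecord]]:
    """Fully synthetic reference set with systematic lineage labels."""
    lineages = [
        Lineage(f"Family{f:02d}", f"Genus{f:02d}_{g:02d}",
                f"Species{f:02d}_{g:02d}_{s:02d}")
        for f in range(1, n_families + 1)
        for g in range(1, genera_per_family + 1)
        for s in range(1, species_per_genus + 1)
    ]
    return generate_references(lineages, markers=markers,
                               barcode_length=barcode_length,
                               inter_species_divergence=inter_species_divergence,
                               seed=seed)


def resolve_iupac(primer: str, rng: np.random.Generator) -> str:
    """Replace degenerate positions with one of their bases, uniformly."""
    out = []
    for code in primer.upper():
        bases = IUPAC[code]
        out.append(bases if len(bases) == 1
                   else bases[rng.integers(0, len(bases))])
    return "".join(out)


def make_amplicon(ref: ReferenceRecord, primers: MarkerPrimerSet,
                  rng: Optional[np.random.Generator] = None) -> str:
    """PCR product: forward primer + barcode + revcomp(reverse primer)."""
    if ref.marker != primers.marker:
        raise ValueError(
            f"reference marker {ref.marker!r} does not match primer set "
            f"{primers.marker!r}")
    rng = rng if rng is not None else np.random.default_rng()
    fwd = resolve_iupac(primers.forward[int(rng.integers(0, len(primers.forward)))], rng)
    rev = resolve_iupac(primers.reverse[int(rng.integers(0, len(primers.reverse)))], rng)
    return fwd + ref.sequence + reverse_complement(rev)


def _noisy_copy(template: np.ndarray, profile: ErrorProfile,
                rng: np.random.Generator) -> np.ndarray:
    """Corrupt one template: per position delete, substitute, then maybe insert."""
    n = len(template)
    u = rng.random(n)
    deleted = u < profile.del_rate
    substituted = (~deleted) & (u < profile.del_rate + profile.sub_rate)
    bases = template.copy()
    n_sub = int(substituted.sum())
    if n_sub:
        bases[substituted] = (bases[substituted]
                              + rng.integers(1, 4, size=n_sub)) % 4
    inserted = rng.random(n) < profile.ins_rate
    counts = (~deleted).astype(np.int64) + inserted
    total = int(counts.sum())
    out = np.empty(total, dtype=np.int64)
    # layout per position: (base if kept) then (inserted base if any)
    ends = np.cumsum(counts)
    starts = ends - counts
    keep_pos = starts[~deleted]
    out[keep_pos] = bases[~deleted]
    ins_pos = ends[inserted] - 1
    n_ins = int(inserted.sum())
    if n_ins:
        out[ins_pos] = rng.integers(0, 4, size=n_ins)
    return out


def simulate_reads(amplicon: str, n: int, profile: ErrorProfile = ErrorProfile(),
                   strand_flip_prob: float = 0.5, seed: int = 0,
                   id_prefix: str = "read") -> List[Read]:
    """Simulate ``n`` noisy full-length copies of an amplicon.

    Each copy walks the template once, deleting, substituting (to a
    uniformly chosen different base) or keeping each base and inserting a
    uniform base after a position with the profile's rates; with probability
    ``strand_flip_prob`` the read is reverse-complemented.  Qualities are
    integer draws around ``mean_q``, clipped to [1, 41].
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    template = np.frombuffer(amplicon.upper().encode(), dtype=np.uint8)
    codes = np.empty(len(template), dtype=np.int64)
    for value, base in enumerate(_BASE_STR):
        codes[template == ord(base)] = value
    reads: List[Read] = []
    for i in range(n):
        copy = _noisy_copy(codes, profile, rng)
        seq = _to_str(copy)
        flipped = bool(rng.random() < strand_flip_prob)
        if flipped:
            seq = reverse_complement(seq)
        quals = np.clip(np.rint(rng.normal(profile.mean_q, profile.q_sd,
                                           size=len(seq))), 1, 41).astype(int)
        strand = "-" if flipped else "+"
        reads.append(Read(f"{id_prefix}_{i:06d}:{strand}", seq, quals.tolist()))
    return reads


@dataclass
class TruthRecord:
    read_id: str
    species: str
    marker: str
    strand: str
    source: str = "mixture"      # "mixture" or "carryover"


def simulate_mixture_run(mixture: MixtureProfile,
                         refs: Sequence[ReferenceRecord],
                         primers: MarkerPrimerSet,
                         total_reads: int,
                         profile: ErrorProfile = ErrorProfile(),
                         carryover: Optional[
                             Tuple[Sequence[Read], float]] = None,
                         seed: int = 0,
                         strand_flip_prob: float = 0.5,
                         ) -> Tuple[List[Read], List[TruthRecord]]:
    """Simulate one sequencing run of a species mixture for one marker.

    Reads are allocated to species by a multinomial draw over the weight
    fractions; species listed as dropouts for this marker contribute zero
    reads.  When ``carryover = (other_reads, fraction)`` is given, that
    fraction of the output is replaced by reads sampled from a previous
    run's read set, mimicking incomplete flow-cell washing.
    """
    marker = primers.marker
    rng = np.random.default_rng(seed)
    by_species = {r.species: r for r in refs if r.marker == marker}
    dropouts = mixture.dropouts_for(marker)
    for lin, _ in mixture.entries:
        if lin.species not in dropouts and lin.species not in by_species:
            raise ValueError(
                f"species {lin.species!r} has no {marker} reference and is "
                f"not declared a dropout")
    n_carry = 0
    if carryover is not None:
        other_reads, fraction = carryover
        if not 0 <= fraction <= 1:
            raise ValueError("carry-over fraction must lie in [0, 1]")
        n_carry = int(round(fraction * total_reads))
    weights = np.array([w for _, w in mixture.entries])
    alloc = rng.multinomial(total_reads - n_carry, weights / weights.sum())
    reads: List[Read] = []
    truth: List[TruthRecord] = []
    for (lin, _), n_species in zip(mixture.entries, alloc):
        if lin.species in dropouts or n_species == 0:
            continue
        amplicon = make_amplicon(by_species[lin.species], primers, rng)
        species_seed = int(rng.integers(0, 2**31 - 1))
        tag = lin.species.replace(" ", "_")
        sp_reads = simulate_reads(amplicon, int(n_species), profile,
                                  strand_flip_prob=strand_flip_prob,
                                  seed=species_seed,
                                  id_prefix=f"{marker}_{tag}")
        for read in sp_reads:
            truth.append(TruthRecord(read.read_id, lin.species, marker,
                                     read.read_id.rsplit(":", 1)[1]))
        reads.extend(sp_reads)
    if n_carry:
        other_reads, _ = carryover
        picks = rng.choice(len(other_reads), size=n_carry,
                           replace=n_carry > len(other_reads))
        for j, idx in enumerate(picks):
            src = other_reads[int(idx)]
            rid = f"carry_{j:06d}_{src.read_id}"
            reads.append(Read(rid, src.sequence, list(src.qualities)))
            truth.append(TruthRecord(rid, "carryover", marker, "?",
                                     source="carryover"))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = [truth[i] for i in order]
    return reads, truth


def table_scenario(which: str, seed: int = 0,
                   markers: Sequence[str] = ("cytb", "COI"),
                   barcode_length: int = 600,
                   ) -> Tuple[MixtureProfile,
                              Dict[str, List[ReferenceRecord]],
                              Dict[str, List[ReferenceRecord]]]:
    """Mixture plus references for the six- or eleven-species benchmark.

    Returns ``(mixture, simulation_refs, database_refs)``.  Simulation
    references hold the true barcode of every mixture species; the
    assignment database differs for the eleven-species case ("b"), where
    the hook gurnard's (Agonus cataphractus) cytb barcode is withheld while
    two confamilial Agonidae genera with nearly identical cytb sequences
    are added — emulating a database that lacks the species itself but
    contains close relatives, which caps that marker at family rank.
    """
    if which == "a":
        mixture = mixture_a()
        lineages = [lin for lin, _ in mixture.entries]
        full = generate_references(lineages, markers=markers,
                                   barcode_length=barcode_length, seed=seed)
        return mixture, full, full
    if which == "b":
        mixture = mixture_b()
        ghosts = [Lineage("Agonidae", "Leptagonus", "Leptagonus decagonus"),
                  Lineage("Agonidae", "Podothecus", "Podothecus veternus")]
        lineages = [lin for lin, _ in mixture.entries] + ghosts
        full = generate_references(
            lineages, markers=markers, barcode_length=barcode_length,
            seed=seed, divergence_overrides={"Agonidae": 0.004})
        withheld = {("Agonus cataphractus", "cytb")}
        database = {m: [r for r in recs
                        if (r.species, m) not in withheld]
                    for m, recs in full.items()}
        return mixture, full, database
    raise ValueError(f"unknown scenario {which!r} (expected 'a' or 'b')")
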
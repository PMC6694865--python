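import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanobarcode.io_seq import Read, reverse_complement
from nanobarcode.primers import (MarkerPrimerSet, PrimerParams,
                                 carryover_fraction, classify_read,
                                 find_primer, trim_primers)
from nanobarcode.simdata import (ErrorProfile, PERFECT, default_primer_sets,
                                 generate_references, Lineage, make_amplicon,
                                 simulate_reads)

from _oracles import oracle_find_primer

PRIMER20 = "ACGGATTCATACGCAAGAAC"


def test_exact_substring_hit_has_zero_edits():
    seq = "T" * 30 + PRIMER20 + "G" * 30
    hit = find_primer(seq, PRIMER20)
    assert hit is not None
    assert (hit.edits, hit.read_start, hit.read_end) == (0, 30, 50)
    assert hit.matched_len == 20


def test_error_budget_boundary_at_four_of_twenty():
    """floor(0.20 * 20) = 4 edits pass; 5 edits do not."""
    def mutate(seq, k):
        out = list(seq)
        for i in range(k):
            pos = 3 * i
            out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
        return "".join(out)

    four = "T" * 20 + mutate(PRIMER20, 4) + "G" * 20
    five = "T" * 20 + mutate(PRIMER20, 5) + "G" * 20
    hit4 = find_primer(four, PRIMER20)
    assert hit4 is not None and hit4.edits == 4
    assert oracle_find_primer(four, PRIMER20)[0] == 4
    assert find_primer(five, PRIMER20) is None
    assert oracle_find_primer(five, PRIMER20) is None


def test_overhang_below_min_overlap_rejected():
    """A primer with only 14 nt inside the read does not count.

    Exact matching isolates the overlap boundary: a 15-base terminal
    occurrence qualifies, a 14-base one does not (error tolerance could
    otherwise stretch the 14-base occurrence past the boundary with gaps).
    """
    exact = PrimerParams(max_error_rate=0.0, min_overlap=15)
    seq = PRIMER20[6:] + "T" * 40          # 14 nt of primer at read start
    assert find_primer(seq, PRIMER20, exact) is None
    seq15 = PRIMER20[5:] + "T" * 40        # 15 nt inside: minimal overlap
    hit = find_primer(seq15, PRIMER20, exact)
    assert hit is not None and hit.matched_len == 15 and hit.read_start == 0
    # at the default 20% error rate the 14-base occurrence is reachable
    # only by gap-stretched placements, which their span budget must cover
    default_hit = find_primer(seq, PRIMER20)
    oracle = oracle_find_primer(seq, PRIMER20)
    assert (default_hit is None) == (oracle is None)


def test_iupac_degeneracy_matches_free_only_primer_side():
    # R matches A and G at no cost
    assert find_primer("T" * 20 + "ACGGATTCATACGCAAGAAC" + "T" * 20,
                       "ACGGATTCATACGYAAGAAC").edits == 0
    # read-side N is never a free match
    seq_n = "T" * 20 + PRIMER20[:10] + "N" + PRIMER20[11:] + "T" * 20
    hit = find_primer(seq_n, PRIMER20)
    assert hit is not None and hit.edits == 1


def test_primer_shorter_than_min_overlap_raises():
    with pytest.raises(ValueError):
        find_primer("ACGT" * 20, "ACGTACGTAC")   # 10 < 15


@st.composite
def _primer_search_instance(draw):
    n = draw(st.integers(16, 60))
    seq = draw(st.text(alphabet="ACGT", min_size=n, max_size=n))
    m = draw(st.integers(15, 22))
    primer = draw(st.text(alphabet="ACGTRYSWKM", min_size=m, max_size=m))
    # often plant a mutated copy so hits are common
    if draw(st.booleans()):
        pos = draw(st.integers(0, max(0, n - m)))
        n_mut = draw(st.integers(0, 4))
        planted = list(primer)
        for _ in range(n_mut):
            i = draw(st.integers(0, m - 1))
            planted[i] = draw(st.sampled_from("ACGT"))
        resolved = "".join(draw(st.sampled_from(
            {"R": "AG", "Y": "CT", "S": "CG", "W": "AT",
             "K": "GT", "M": "AC"}.get(c, c))) for c in planted)
        seq = seq[:pos] + resolved + seq[pos + m:]
        seq = seq[:n]
    return seq, primer


@settings(max_examples=120, deadline=None, derandomize=True)
@given(_primer_search_instance())
def test_find_primer_matches_bruteforce_oracle(instance):
    """The fast matcher agrees with exhaustive enumeration of placements.

    Agreement means: a hit exists iff the oracle finds one, the hit attains
    the oracle's optimal edit count, respects both thresholds, and its
    reported endpoints are achievable at that edit count (equal-edit
    placements are interchangeable, so exact endpoint ties are not pinned).
    """
    from _oracles import oracle_rescore
    seq, primer = instance
    hit = find_primer(seq, primer)
    oracle = oracle_find_primer(seq, primer)
    if oracle is None:
        assert hit is None
    else:
        assert hit is not None
        assert hit.edits == oracle[0]
        span = hit.read_end - hit.read_start
        assert hit.matched_len == span >= 15
        assert hit.edits <= int(0.20 * span + 1e-9)
        assert oracle_rescore(seq, primer, hit.read_start,
                              hit.read_end) == hit.edits


@pytest.fixture(scope="module")
def amplicons():
    psets = default_primer_sets()
    refs = generate_references(
        [Lineage("Fam", "Gen", "Gen speciesA"),
         Lineage("Fam", "Gen", "Gen speciesB")], seed=7)
    rng = np.random.default_rng(0)
    return psets, {m: [make_amplicon(r, p, rng) for r in refs[m]]
                   for m, p in zip(("cytb", "COI"), psets)}


def test_classify_error_free_amplicons_is_perfect(amplicons):
    psets, amps = amplicons
    for marker, pset in zip(("cytb", "COI"), psets):
        for amp in amps[marker]:
            reads = simulate_reads(amp, 3, PERFECT, strand_flip_prob=0.0,
                                   seed=1)
            for read in reads:
                cls = classify_read(read, psets)
                assert cls.marker == marker
                assert cls.orientation == "+"
                assert len(cls.hits) == 2


def test_classify_reverse_complemented_read(amplicons):
    psets, amps = amplicons
    reads = simulate_reads(amps["COI"][0], 3, PERFECT, strand_flip_prob=1.0,
                           seed=2)
    for read in reads:
        cls = classify_read(read, psets)
        assert (cls.marker, cls.orientation) == ("COI", "-")


def test_classify_noisy_reads_match_truth(amplicons):
    psets, amps = amplicons
    hits = 0
    for marker in ("cytb", "COI"):
        reads = simulate_reads(amps[marker][0], 25, ErrorProfile(), seed=3)
        for read in reads:
            if classify_read(read, psets).marker == marker:
                hits += 1
    assert hits >= 48          # >=96% of 50 noisy reads correctly assigned


def test_random_sequence_is_unassigned(rng, primer_sets):
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    read = Read("r", seq, [12] * 300)
    assert classify_read(read, primer_sets).marker == "unassigned"


def test_trim_primers_removes_both_flanks(cytb_primers):
    insert = "ACGT" * 100
    fwd = cytb_primers.forward[0].replace("Y", "C")
    rev_rc = reverse_complement(cytb_primers.reverse[0].replace("R", "A"))
    seq = fwd + insert + rev_rc
    read = Read("r", seq, [12] * len(seq))
    cls = classify_read(read, [cytb_primers])
    trimmed = trim_primers(read, cls.hits)
    assert trimmed.sequence == insert
    # no primer substring survives at the termini
    assert find_primer(trimmed.sequence[:40], cytb_primers.forward[0]) is None


def test_trim_primers_single_hit_trims_one_end(cytb_primers):
    insert = "ACGT" * 100
    fwd = cytb_primers.forward[0].replace("Y", "C")
    read = Read("r", fwd + insert, [12] * (len(fwd) + len(insert)))
    cls = classify_read(read, [cytb_primers])
    assert len(cls.hits) == 1
    assert trim_primers(read, cls.hits).sequence == insert


def test_trim_primers_zero_length_insert(cytb_primers):
    fwd = cytb_primers.forward[0].replace("Y", "C")
    rev_rc = reverse_complement(cytb_primers.reverse[0].replace("R", "A"))
    read = Read("r", fwd + rev_rc, [12] * (len(fwd) + len(rev_rc)))
    cls = classify_read(read, [cytb_primers])
    trimmed = trim_primers(read, cls.hits)
    assert len(trimmed) == 0          # flagged by emptiness, dropped downstream


def test_carryover_fraction_extremes(amplicons):
    psets, amps = amplicons
    cytb_reads = simulate_reads(amps["cytb"][0], 20, PERFECT, seed=4,
                                id_prefix="c")
    coi_reads = simulate_reads(amps["COI"][0], 20, PERFECT, seed=5,
                               id_prefix="m")
    pure = carryover_fraction(coi_reads, psets[1], [psets[0]])
    assert pure.fraction_of_classified == 0.0
    allover = carryover_fraction(cytb_reads, psets[1], [psets[0]])
    assert allover.fraction_of_classified == 1.0
    none = carryover_fraction([], psets[1], [psets[0]])
    assert none.fraction_of_classified is None


def test_carryover_estimate_recovers_injected_fraction(amplicons):
    psets, amps = amplicons
    coi = simulate_reads(amps["COI"][0], 170, ErrorProfile(), seed=6,
                         id_prefix="coi")
    cytb = simulate_reads(amps["cytb"][0], 30, ErrorProfile(), seed=7,
                          id_prefix="cytb")
    report = carryover_fraction(coi + cytb, psets[1], [psets[0]])
    assert report.fraction_of_classified == pytest.approx(0.15, abs=0.02)
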
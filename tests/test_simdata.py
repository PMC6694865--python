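from collections import Counter

import numpy as np
import pytest

from nanobarcode.clustering import pairwise_identity
from nanobarcode.error_metrics import error_percentage, unit_cost_align
from nanobarcode.io_seq import reverse_complement
from nanobarcode.primers import IUPAC, MarkerPrimerSet
from nanobarcode.simdata import (ErrorProfile, Lineage, MixtureProfile,
                                 PERFECT, default_primer_sets,
                                 generate_reference_set, generate_references,
                                 make_amplicon, mixture_a, mixture_b,
                                 simulate_mixture_run, simulate_reads,
                                 table_scenario)


def test_error_profile_validation():
    with pytest.raises(ValueError):
        ErrorProfile(sub_rate=0.6, ins_rate=0.3, del_rate=0.2)
    assert ErrorProfile().total == pytest.approx(0.13)


def test_mixture_weights_must_sum_to_one():
    with pytest.raises(ValueError):
        MixtureProfile(entries=[(Lineage("F", "G", "G s"), 0.5)])


def test_table_mixtures_are_well_formed():
    a, b = mixture_a(), mixture_b()
    assert len(a.entries) == 6 and len(b.entries) == 11
    assert [w for _, w in a.entries] == [0.75] + [0.05] * 5
    assert a.dropouts_for("COI") == {"Scophthalmus rhombus"}
    assert a.dropouts_for("cytb") == {"Limanda aspera"}
    assert b.dropouts_for("cytb") == {"Osmerus eperlanus", "Limanda aspera"}
    assert b.dropouts_for("COI") == {"Scophthalmus maximus"}


def test_congeners_diverge_as_requested():
    """Two species of one genus at divergence 0.10 are ~90% identical."""
    refs = generate_references(
        [Lineage("Fam", "Gen", "Gen a"), Lineage("Fam", "Gen", "Gen b")],
        markers=("cytb",), inter_species_divergence=0.10, seed=3)["cytb"]
    ident = pairwise_identity(refs[0].sequence, refs[1].sequence)
    assert ident == pytest.approx(90.0, abs=2.0)


def test_reference_generation_is_deterministic():
    kwargs = dict(n_families=2, species_per_genus=2, seed=9)
    first = generate_reference_set(**kwargs)
    second = generate_reference_set(**kwargs)
    assert first == second
    third = generate_reference_set(n_families=2, species_per_genus=2, seed=10)
    assert first != third


def test_minimal_reference_set_has_single_record_per_marker():
    refs = generate_reference_set(1, 1, seed=0)
    assert {m: len(v) for m, v in refs.items()} == {"cytb": 1, "COI": 1}


def test_families_diverge_more_than_congeners():
    refs = generate_reference_set(2, 2, seed=4, markers=("cytb",))["cytb"]
    within = pairwise_identity(refs[0].sequence, refs[1].sequence)
    across = pairwise_identity(refs[0].sequence, refs[2].sequence)
    assert across < within


def test_amplicon_layout():
    pset = MarkerPrimerSet("mk", "AAATTTAAATTTAAA", "GGGAAAGGGAAAGGG")
    refs = generate_references([Lineage("F", "G", "G s")], markers=("mk",),
                               seed=1)["mk"]
    amp = make_amplicon(refs[0], pset, np.random.default_rng(0))
    assert amp == pset.forward[0] + refs[0].sequence + \
        reverse_complement(pset.reverse[0])
    assert len(amp) == len(pset.forward[0]) + len(refs[0].sequence) + \
        len(pset.reverse[0])


def test_amplicon_resolves_iupac_uniformly():
    pset = MarkerPrimerSet("mk", "RAATTTAAATTTAAA", "GGGAAAGGGAAAGGG")
    refs = generate_references([Lineage("F", "G", "G s")], markers=("mk",),
                               seed=1)["mk"]
    rng = np.random.default_rng(2)
    first_bases = {make_amplicon(refs[0], pset, rng)[0] for _ in range(50)}
    assert first_bases == set(IUPAC["R"])


def test_zero_error_profile_copies_amplicon_exactly():
    amp = "ACGT" * 100
    reads = simulate_reads(amp, 5, PERFECT, strand_flip_prob=0.0, seed=1)
    assert all(r.sequence == amp for r in reads)
    assert simulate_reads(amp, 0, PERFECT) == []


def test_simulated_reads_are_deterministic_and_pass_quality_filter():
    amp = "ACGT" * 150
    a = simulate_reads(amp, 20, ErrorProfile(), seed=5)
    b = simulate_reads(amp, 20, ErrorProfile(), seed=5)
    assert [(r.read_id, r.sequence, list(r.qualities)) for r in a] == \
        [(r.read_id, r.sequence, list(r.qualities)) for r in b]
    means = [sum(r.qualities) / len(r) for r in a]
    assert all(m >= 10 for m in means)


def test_measured_error_matches_injected_rate():
    """Estimator recovery at >=1e5 bases for a moderate profile."""
    profile = ErrorProfile(sub_rate=0.10, ins_rate=0.05, del_rate=0.05)
    amp = "".join(np.array(list("ACGT"))[
        np.random.default_rng(3).integers(0, 4, 600)])
    reads = simulate_reads(amp, 170, profile, strand_flip_prob=0.0, seed=6)
    counts = [unit_cost_align(r.sequence, amp) for r in reads]
    assert error_percentage(counts) == pytest.approx(100 * profile.total,
                                                     abs=2.0)


@pytest.fixture(scope="module")
def mixture_setup():
    mixture, sim_refs, _ = table_scenario("a", seed=21)
    pset = default_primer_sets()[0]          # cytb
    return mixture, sim_refs, pset


def test_mixture_run_respects_dropouts(mixture_setup):
    mixture, sim_refs, pset = mixture_setup
    reads, truth = simulate_mixture_run(mixture, sim_refs["cytb"], pset,
                                        total_reads=400, seed=2)
    species_seen = {t.species for t in truth}
    assert "Limanda aspera" not in species_seen       # cytb read dropout
    # dropout shares are not reallocated: the run just yields fewer reads
    assert 300 < len(reads) == len(truth) <= 400
    assert len(species_seen) == 5


def test_coi_run_contains_no_rhombus_reads():
    mixture, sim_refs, _ = table_scenario("a", seed=21)
    pset = default_primer_sets()[1]          # COI
    reads, truth = simulate_mixture_run(mixture, sim_refs["COI"], pset,
                                        total_reads=400, seed=2)
    assert "Scophthalmus rhombus" not in {t.species for t in truth}


def test_mixture_allocation_follows_weights(mixture_setup):
    _, sim_refs, pset = mixture_setup
    mixture = MixtureProfile(entries=[
        (Lineage("Pleuronectidae", "Pleuronectes", "Pleuronectes platessa"),
         0.5),
        (Lineage("Pleuronectidae", "Limanda", "Limanda limanda"), 0.5)])
    _, truth = simulate_mixture_run(mixture, sim_refs["cytb"], pset,
                                    total_reads=1000, seed=13)
    counts = Counter(t.species for t in truth)
    for n in counts.values():
        assert abs(n - 500) < 80              # ~5 sigma of Binomial(1000, .5)


def test_missing_reference_without_dropout_raises(mixture_setup):
    mixture, sim_refs, pset = mixture_setup
    incomplete = [r for r in sim_refs["cytb"]
                  if r.species != "Pleuronectes platessa"]
    with pytest.raises(ValueError, match="Pleuronectes platessa"):
        simulate_mixture_run(mixture, incomplete, pset, total_reads=50,
                             seed=1)


def test_carryover_reads_injected_at_requested_fraction(mixture_setup):
    mixture, sim_refs, pset = mixture_setup
    other = simulate_reads("ACGT" * 150, 50, ErrorProfile(), seed=3,
                           id_prefix="other")
    reads, truth = simulate_mixture_run(
        mixture, sim_refs["cytb"], pset, total_reads=500,
        carryover=(other, 0.1), seed=4)
    n_carry = sum(1 for t in truth if t.source == "carryover")
    assert n_carry == 50
    none_reads, none_truth = simulate_mixture_run(
        mixture, sim_refs["cytb"], pset, total_reads=500,
        carryover=(other, 0.0), seed=4)
    plain_reads, _ = simulate_mixture_run(
        mixture, sim_refs["cytb"], pset, total_reads=500, seed=4)
    assert [r.sequence for r in none_reads] == \
        [r.sequence for r in plain_reads]


def test_species_counts_exchangeable_under_entry_permutation():
    pset = default_primer_sets()[0]
    lineages = [Lineage("F", f"G{i}", f"G{i} sp") for i in range(3)]
    refs = generate_references(lineages, markers=("cytb",), seed=8)["cytb"]
    mix1 = MixtureProfile(entries=[(lineages[0], 0.5), (lineages[1], 0.3),
                                   (lineages[2], 0.2)])
    mix2 = MixtureProfile(entries=[(lineages[2], 0.2), (lineages[0], 0.5),
                                   (lineages[1], 0.3)])
    _, t1 = simulate_mixture_run(mix1, refs, pset, 600, seed=5)
    _, t2 = simulate_mixture_run(mix2, refs, pset, 600, seed=55)
    c1 = Counter(t.species for t in t1)
    c2 = Counter(t.species for t in t2)
    for sp, w in (("G0 sp", 0.5), ("G1 sp", 0.3), ("G2 sp", 0.2)):
        assert abs(c1[sp] - 600 * w) < 80
        assert abs(c2[sp] - 600 * w) < 80


def test_scenario_b_database_withholds_agonid_cytb():
    mixture, sim_refs, db_refs = table_scenario("b", seed=1)
    sim_species = {r.species for r in sim_refs["cytb"]}
    db_species = {r.species for r in db_refs["cytb"]}
    assert "Agonus cataphractus" in sim_species
    assert "Agonus cataphractus" not in db_species
    # close confamilials are present to stand in at family rank
    agonids = [r for r in db_refs["cytb"] if r.family == "Agonidae"]
    assert len({r.genus for r in agonids}) >= 2
    truth = next(r for r in sim_refs["cytb"]
                 if r.species == "Agonus cataphractus")
    for ghost in agonids:
        assert pairwise_identity(truth.sequence, ghost.sequence) >= 98.0
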
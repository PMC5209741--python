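import numpy as np
import pytest

from its_screen.core import ItsScreenError, PAIRING
from its_screen.diversity import count_site_classes
from its_screen.screen import HELIX_ORDER, MOTIFS, forced_pairs
from its_screen.simulate import (
    SimParams,
    make_count_fixture,
    make_reference_unit,
    mutate_sequence,
    simulate_chimera_triplet,
    simulate_clone_set,
    simulate_null_triplet,
)


# ---------------------------------------------------------------------------
# Reference unit

def test_reference_unit_deterministic():
    assert make_reference_unit().sequence == make_reference_unit().sequence
    assert make_reference_unit(1).sequence != make_reference_unit(2).sequence


def test_reference_unit_motifs_unique_and_in_order(unit):
    s58 = unit.refs.ref_5_8S
    positions = []
    for name in ("M1", "M2", "M3"):
        assert s58.count(MOTIFS[name]) == 1
        positions.append(s58.find(MOTIFS[name]))
    assert positions == sorted(positions)


def test_reference_unit_satisfies_all_forced_pairs(unit):
    s58 = unit.refs.ref_5_8S
    for helix in HELIX_ORDER:
        for i, j in forced_pairs(helix):
            assert (s58[i - 1], s58[j - 1]) in PAIRING


def test_reference_unit_partition_matches_sequence(unit):
    p = unit.partition
    assert p.extract(unit.sequence, "5.8S") == unit.refs.ref_5_8S
    assert unit.sequence.startswith(unit.refs.ref_18S_tail)
    assert unit.sequence.endswith(unit.refs.ref_26S_head)
    assert unit.regions["ITS"] == p.entire


# ---------------------------------------------------------------------------
# Parameters

def test_simparams_validation():
    with pytest.raises(ItsScreenError):
        SimParams(base_rate=-0.1)
    with pytest.raises(ItsScreenError):
        SimParams(pseudo_fraction=1.5)
    with pytest.raises(ItsScreenError):
        SimParams(pseudo_fraction=0.7, recombinant_fraction=0.5)
    with pytest.raises(ItsScreenError):
        SimParams(n_samples=0)


# ---------------------------------------------------------------------------
# Mutation machinery

def test_mutate_sequence_rate_zero_and_one():
    seq = "ACGT" * 25
    rng = np.random.default_rng(0)
    assert mutate_sequence(seq, 0.0, rng) == seq
    mutated = mutate_sequence(seq, 1.0, rng)
    assert all(a != b for a, b in zip(seq, mutated))


def test_mutate_sequence_full_cpg_bias_deaminates():
    seq = "ACGCGCGT" * 10
    rng = np.random.default_rng(1)
    mutated = mutate_sequence(seq, 1.0, rng, cpg_bias=1.0)
    for old, new in zip(seq, mutated):
        if old == "C":
            assert new == "T"
        elif old == "G":
            assert new == "A"


def test_mutate_sequence_erodes_gc_with_bias():
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), size=2000, p=[0.2, 0.3, 0.3, 0.2]))
    gc = lambda s: (s.count("G") + s.count("C")) / len(s)
    biased = mutate_sequence(seq, 0.2, np.random.default_rng(3), cpg_bias=0.9)
    assert gc(biased) < gc(seq)


# ---------------------------------------------------------------------------
# Clone-set generator

def test_simulate_clone_set_deterministic(unit):
    params = SimParams(n_samples=3, clones_per_sample=4, seed=11)
    d1 = simulate_clone_set(params, reference=unit)
    d2 = simulate_clone_set(params, reference=unit)
    assert [c.sequence for c in d1.clones] == [c.sequence for c in d2.clones]
    assert d1.alignment.seqs == d2.alignment.seqs
    assert {k: vars(v) for k, v in d1.truth.items()} == {k: vars(v) for k, v in d2.truth.items()}


def test_simulate_clone_set_label_counts_exact(unit):
    params = SimParams(n_samples=5, clones_per_sample=4, pseudo_fraction=0.3,
                       recombinant_fraction=0.1, seed=2)
    ds = simulate_clone_set(params, reference=unit)
    labels = [t.label for t in ds.truth.values()]
    assert len(labels) == 20
    assert labels.count("recombinant") == 2   # round(20 * 0.1)
    assert labels.count("pseudogene") == 6    # round(20 * 0.3)
    assert labels.count("functional") == 12


def test_simulated_alignment_rows_match_clones(unit):
    ds = simulate_clone_set(SimParams(n_samples=3, clones_per_sample=4, seed=8),
                            reference=unit)
    assert ds.alignment.ids == [c.clone_id for c in ds.clones]
    for clone, row in zip(ds.clones, ds.alignment.seqs):
        assert row.replace("-", "") == clone.sequence
        assert len(row) == len(unit.sequence)


def test_simulated_partitions_project_regions(unit):
    ds = simulate_clone_set(SimParams(n_samples=3, clones_per_sample=4, seed=8),
                            reference=unit)
    for clone in ds.clones:
        assert clone.partition is not None
        # region lengths never exceed the ancestral ones (deletions only)
        for region in ("ITS1", "5.8S", "ITS2"):
            assert clone.partition.length(region) <= unit.partition.length(region)


def test_truth_records_recombinant_parents(unit):
    params = SimParams(n_samples=5, clones_per_sample=4, pseudo_fraction=0.3,
                       recombinant_fraction=0.1, seed=2)
    ds = simulate_clone_set(params, reference=unit)
    rows = dict(zip(ds.alignment.ids, ds.alignment.seqs))
    for t in ds.truth.values():
        if t.label != "recombinant":
            assert t.parent_a is None and t.breakpoint is None
            continue
        assert ds.truth[t.parent_a].label == "pseudogene"
        assert ds.truth[t.parent_b].label == "pseudogene"
        child = rows[t.clone_id]
        assert child[: t.breakpoint] == rows[t.parent_a][: t.breakpoint]
        assert child[t.breakpoint:] == rows[t.parent_b][t.breakpoint:]


def test_class_labels_exclude_recombinants(unit):
    params = SimParams(n_samples=5, clones_per_sample=4, pseudo_fraction=0.3,
                       recombinant_fraction=0.1, seed=2)
    ds = simulate_clone_set(params, reference=unit)
    labels = ds.alignment.class_labels
    for cid, t in ds.truth.items():
        if t.label == "recombinant":
            assert cid not in labels
        else:
            assert labels[cid] == ("F" if t.label == "functional" else "P")


def test_truth_tsv_and_fasta_outputs(unit, tmp_path):
    ds = simulate_clone_set(SimParams(n_samples=3, clones_per_sample=4, seed=8),
                            reference=unit)
    ds.write_fasta(tmp_path / "c.fasta")
    ds.write_truth_tsv(tmp_path / "t.tsv")
    ds.write_regions_tsv(tmp_path / "r.tsv")
    lines = (tmp_path / "t.tsv").read_text().splitlines()
    assert lines[0].split("\t") == ["clone_id", "label", "parent_a", "parent_b",
                                    "breakpoint", "lesions"]
    assert len(lines) == 1 + len(ds.clones)
    assert (tmp_path / "c.fasta").read_text().count(">") == len(ds.clones)


# ---------------------------------------------------------------------------
# Triplet fixtures

def test_triplet_fixtures_deterministic_and_distinct(unit):
    assert simulate_null_triplet(4, reference=unit) == simulate_null_triplet(4, reference=unit)
    c1 = simulate_chimera_triplet(4, reference=unit)
    assert c1 == simulate_chimera_triplet(4, reference=unit)
    child, pa, pb, bp = c1
    assert child[:bp] == pa[:bp] and child[bp:] == pb[bp:]
    assert 150 <= bp <= len(unit.sequence) - 150


# ---------------------------------------------------------------------------
# Count fixtures

def test_make_count_fixture_exact_counts():
    a = make_count_fixture(length=120, n_variable=30, n_pi=12, n_seqs=6, seed=3)
    S, PI, length, _ = count_site_classes(a)
    assert (S, PI, length) == (30, 12, 120)


def test_make_count_fixture_validation():
    with pytest.raises(ItsScreenError):
        make_count_fixture(100, 10, 20, 6)
    with pytest.raises(ItsScreenError):
        make_count_fixture(100, 10, 5, 3)
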
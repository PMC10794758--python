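"""Energy-table, transition-matrix and energy-feature tests with brute-force oracles."""

import itertools

import numpy as np
import pytest

from lncdisc import physchem

from .conftest import random_seq, toy_table


def write_table(path, entries):
    with open(path, "w") as fh:
        fh.write("kmer\tsolvation\tstacking\thbond\n")
        for m, (a, b, c) in entries.items():
            fh.write(f"{m}\t{a}\t{b}\t{c}\n")


class TestLoadEnergyTable:
    def test_complete_dinucleotide_table_loads(self, tmp_path):
        entries = {m: (-1.0, -2.0, -3.0) for m in physchem.all_kmers(2)}
        path = tmp_path / "t.tsv"
        write_table(path, entries)
        table = physchem.load_energy_table(path, 2)
        assert table.energies("AA") == (-1.0, -2.0, -3.0)

    def test_missing_kmer_named_in_error(self, tmp_path):
        entries = {m: (-1.0, -2.0, -3.0) for m in physchem.all_kmers(2) if m != "GT"}
        path = tmp_path / "t.tsv"
        write_table(path, entries)
        with pytest.raises(ValueError, match="GT"):
            physchem.load_energy_table(path, 2)

    def test_lowercase_keys_accepted(self, tmp_path):
        entries = {m.lower(): (-1.0, -2.0, -3.0) for m in physchem.all_kmers(2)}
        path = tmp_path / "t.tsv"
        write_table(path, entries)
        assert physchem.load_energy_table(path, 2).energies("AA") == (-1.0, -2.0, -3.0)

    def test_duplicate_kmer_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        with open(path, "w") as fh:
            fh.write("kmer\tsolvation\tstacking\thbond\n")
            for m in physchem.all_kmers(2):
                fh.write(f"{m}\t-1\t-2\t-3\n")
            fh.write("aa\t-1\t-2\t-3\n")
        with pytest.raises(ValueError, match="duplicate"):
            physchem.load_energy_table(path, 2)

    def test_non_numeric_energy_rejected(self, tmp_path):
        path = tmp_path / "t.tsv"
        with open(path, "w") as fh:
            fh.write("kmer\tsolvation\tstacking\thbond\n")
            for m in physchem.all_kmers(2):
                fh.write(f"{m}\t-1\t-2\tzzz\n")
        with pytest.raises(ValueError, match="non-numeric"):
            physchem.load_energy_table(path, 2)

    def test_bundled_example_tables_complete(self):
        for k in (2, 3):
            table = physchem.example_energy_table(k)
            assert len(table.entries) == 4**k


def brute_force_lower_order(table, km1):
    """Average over every occurrence of each (k-1)-mer inside order-k k-mers."""
    sums = {m: np.zeros(3) for m in physchem.all_kmers(km1)}
    counts = {m: 0 for m in sums}
    for big in physchem.all_kmers(table.k):
        for pos in range(table.k - km1 + 1):
            sub = big[pos : pos + km1]
            sums[sub] += np.asarray(table.entries[big])
            counts[sub] += 1
    return {m: tuple(sums[m] / counts[m]) for m in sums}


class TestDeriveLowerOrder:
    def test_constant_table_stays_constant(self):
        table = toy_table(3, values=-7.5)
        derived = physchem.derive_lower_order_table(table)
        assert derived.k == 2
        for m in physchem.all_kmers(2):
            assert derived.energies(m) == pytest.approx((-7.5, -7.5, -7.5))

    def test_aa_average_counts_aaa_twice(self):
        table = toy_table(3, seed=11)
        derived = physchem.derive_lower_order_table(table)
        # AA occurs in AAx (pos 0) and xAA (pos 1); AAA appears in both lists
        containing = [("AA" + x) for x in "ACGT"] + [(x + "AA") for x in "ACGT"]
        expected = np.mean([table.entries[m] for m in containing], axis=0)
        assert derived.energies("AA") == pytest.approx(tuple(expected))

    def test_double_derivation_matches_brute_force(self):
        table4 = toy_table(4, seed=5)
        via_chain = physchem.derive_lower_order_table(
            physchem.derive_lower_order_table(table4)
        )
        # independent check of each single averaging step
        oracle3 = brute_force_lower_order(table4, 3)
        table3 = physchem.EnergyTable(k=3, entries=oracle3)
        oracle2 = brute_force_lower_order(table3, 2)
        for m in physchem.all_kmers(2):
            assert via_chain.energies(m) == pytest.approx(oracle2[m], rel=1e-12)


class TestTransitionMatrix:
    def test_hand_enumerated_atgat(self):
        tm = physchem.transition_matrix("ATGAT", 2)
        idx = {m: i for i, m in enumerate(tm.states)}
        expected_pairs = [("AT", "TG"), ("TG", "GA"), ("GA", "AT")]
        assert tm.counts.sum() == 3
        for a, b in expected_pairs:
            assert tm.counts[idx[a], idx[b]] == 1
            assert tm.probs[idx[a], idx[b]] == 1.0

    def test_two_state_cycle(self):
        tm = physchem.transition_matrix("AT" * 50, 2)
        idx = {m: i for i, m in enumerate(tm.states)}
        nonzero = np.transpose(np.nonzero(tm.counts))
        assert {tuple(r) for r in nonzero} == {
            (idx["AT"], idx["TA"]),
            (idx["TA"], idx["AT"]),
        }
        assert tm.probs[idx["AT"], idx["TA"]] == 1.0

    def test_row_counts_equal_successor_occurrences(self, rng):
        seq = random_seq(rng, 200)
        tm = physchem.transition_matrix(seq, 2)
        idx = {m: i for i, m in enumerate(tm.states)}
        kmers = [seq[i : i + 2] for i in range(len(seq) - 1)]
        for m in set(kmers[:-1]):
            assert tm.counts[idx[m]].sum() == kmers[:-1].count(m)

    def test_rows_stochastic_or_zero(self, rng):
        for _ in range(5):
            tm = physchem.transition_matrix(random_seq(rng, 150, "ACGTN"), 2)
            sums = tm.probs.sum(axis=1)
            assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))

    def test_all_n_sequence_rejected(self):
        with pytest.raises(ValueError, match="no valid"):
            physchem.transition_matrix("N" * 50, 2)


class TestEnergyFeatures:
    def test_homopolymer_gives_single_kmer_energies(self):
        table = toy_table(2, seed=3)
        assert physchem.energy_features("A" * 100, table) == pytest.approx(
            table.energies("AA")
        )

    def test_constant_table_gives_constant_features(self, rng):
        table = toy_table(3, values=-4.25)
        seq = random_seq(rng, 300)
        assert physchem.energy_features(seq, table) == pytest.approx((-4.25,) * 3)

    def test_atgatg_hand_weighted_mean(self):
        table = toy_table(2, seed=9)
        expected = (
            0.4 * np.asarray(table.entries["AT"])
            + 0.4 * np.asarray(table.entries["TG"])
            + 0.2 * np.asarray(table.entries["GA"])
        )
        assert physchem.energy_features("ATGATG", table) == pytest.approx(tuple(expected))

    def test_weights_form_probability_distribution(self, rng):
        for _ in range(10):
            freqs = physchem.kmer_frequencies(random_seq(rng, 200, "ACGTN"), 3)
            assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_long_sequence_converges_to_analytic_expectation(self, rng):
        # i.i.d. uniform nucleotides: every dinucleotide has expected frequency 1/16
        table = toy_table(2, seed=21)
        energies = np.array([table.entries[m] for m in physchem.all_kmers(2)])
        expectation = energies.mean(axis=0)
        n = 30000
        feats = np.array(physchem.energy_features(random_seq(rng, n), table))
        # se of the weighted mean: sd of per-kmer energies over sqrt(#kmers)
        se = energies.std(axis=0) / np.sqrt(n - 1)
        assert np.all(np.abs(feats - expectation) < 3 * se + 1e-9)

    def test_stationary_weighting_close_to_empirical_on_long_sequences(self, rng):
        table = toy_table(2, seed=4)
        seq = random_seq(rng, 5000)
        emp = np.array(physchem.energy_features(seq, table, weighting="empirical"))
        stat = np.array(physchem.energy_features(seq, table, weighting="stationary"))
        assert np.allclose(emp, stat, atol=0.5)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            physchem.energy_features("N" * 30, toy_table(2, values=-1.0))
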
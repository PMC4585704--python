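"""Ground-truthed array simulation from the published consensuses."""

import numpy as np
import pytest

from alphoid import ConsensusEntry, SimParams, resolve_ambiguity, simulate_array
from alphoid.alphabet import revcomp


class TestResolveAmbiguity:
    def test_concrete_sequence_is_identity(self):
        entry = ConsensusEntry("x", "ACGT", 4)
        assert resolve_ambiguity(entry, 0) == "ACGT"

    def test_r_draws_both_purines(self):
        entry = ConsensusEntry("x", "R", 1)
        seen = {resolve_ambiguity(entry, s) for s in range(1000)}
        assert seen == {"A", "G"}

    def test_gap_code_j_draws_absent_or_g(self):
        entry = ConsensusEntry("x", "J", 1)
        seen = {resolve_ambiguity(entry, s) for s in range(1000)}
        assert seen == {"", "G"}

    def test_deterministic_per_seed(self, cset):
        a = resolve_ambiguity(cset["GGO_consensus_Atype"], 7)
        b = resolve_ambiguity(cset["GGO_consensus_Atype"], 7)
        assert a == b

    def test_unknown_symbol_rejected(self):
        entry = ConsensusEntry.__new__(ConsensusEntry)
        entry.name, entry.sequence, entry.declared_length = "x", "AZ", 2
        with pytest.raises(ValueError):
            resolve_ambiguity(entry, 0)


class TestSimulateArray:
    def test_sf2_zero_noise_length_5532(self, cset):
        # 4 x (171+168+189+171+171+171+171+171) from the printed sizes
        arr, truth = simulate_array(
            SimParams(sf="SF2", n_units=4, sub_rate=0.0, seed=0), cset
        )
        assert len(arr.sequence) == 5532
        assert truth.hor_period == 8

    def test_sf1_alternating_ab_labels(self, cset):
        arr, truth = simulate_array(
            SimParams(sf="SF1", n_units=6, sub_rate=0.0, seed=0), cset
        )
        assert len(truth.boundaries) == 12
        assert truth.ab_labels == ["A", "B"] * 6

    def test_determinism(self, cset):
        p = SimParams(sf="SF3", n_units=3, sub_rate=0.05, seed=11)
        a1, t1 = simulate_array(p, cset)
        a2, t2 = simulate_array(p, cset)
        assert a1.sequence == a2.sequence and t1 == t2

    def test_truth_slices_reproduce_monomers(self, cset):
        arr, truth = simulate_array(
            SimParams(sf="SF2", n_units=3, sub_rate=0.03, seed=2), cset
        )
        # boundaries tile the forward sequence exactly
        assert truth.boundaries[0][0] == 0
        assert truth.boundaries[-1][1] == len(arr.sequence)
        for (s, e), (s2, _) in zip(truth.boundaries, truth.boundaries[1:]):
            assert e == s2

    def test_revcomp_emits_minus_strand(self, cset):
        fwd, _ = simulate_array(SimParams(sf="SF1", n_units=3, sub_rate=0, seed=3), cset)
        rev, truth = simulate_array(
            SimParams(sf="SF1", n_units=3, sub_rate=0, revcomp=True, seed=3), cset
        )
        assert truth.strand == "reverse"
        assert rev.sequence == revcomp(fwd.sequence)

    def test_monomeric_rates_in_declared_range(self, cset):
        arr, truth = simulate_array(
            SimParams(sf="monomeric", n_units=12, sub_rate=0, seed=6), cset
        )
        gm1 = cset["gM1"].sequence
        for s, e in truth.boundaries:
            monomer = arr.sequence[s:e]
            div = sum(a != b for a, b in zip(monomer, gm1)) / len(gm1)
            assert 0.05 <= div <= 0.45  # rate drawn in [0.10, 0.40]

    def test_empirical_substitution_rate_matches(self, cset):
        rate = 0.02
        diffs = sites = 0
        for seed in range(100):
            clean, _ = simulate_array(
                SimParams(sf="SF1", n_units=1, sub_rate=0.0, seed=seed), cset
            )
            noisy, _ = simulate_array(
                SimParams(sf="SF1", n_units=1, sub_rate=rate, seed=seed), cset
            )
            diffs += sum(a != b for a, b in zip(clean.sequence, noisy.sequence))
            sites += len(clean.sequence)
        observed = diffs / sites
        se = np.sqrt(rate * (1 - rate) / sites)
        assert abs(observed - rate) < 3 * se

    def test_protect_motifs_keeps_prd_intact(self, cset):
        from alphoid import scan_prd

        for seed in range(5):
            arr, truth = simulate_array(
                SimParams(sf="SF1", n_units=4, sub_rate=0.10,
                          protect_motifs=True, seed=seed),
                cset,
            )
            for (s, e), source in zip(truth.boundaries, truth.sources):
                clean_hit = scan_prd(cset[source].sequence)
                noisy_hit = scan_prd(arr.sequence[s:e])
                assert noisy_hit is not None
                assert noisy_hit.mismatches <= clean_hit.mismatches

    def test_indels_shift_boundaries_consistently(self, cset):
        arr, truth = simulate_array(
            SimParams(sf="SF1", n_units=4, sub_rate=0.01, indel_rate=0.01, seed=9),
            cset,
        )
        assert truth.boundaries[-1][1] == len(arr.sequence)
        lengths = [e - s for s, e in truth.boundaries]
        assert all(150 <= l <= 195 for l in lengths)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(sf="SF1", sub_rate=0.9)
        with pytest.raises(ValueError):
            SimParams(sf="SF1", n_units=0)
        with pytest.raises(ValueError):
            SimParams(sf="SF2", insertion_copies=4)
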
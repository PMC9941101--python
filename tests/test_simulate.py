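import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribomod import (
    EndCountProfile,
    ProtocolParams,
    RnaReference,
    SimulationError,
    TruthProfile,
    read_profile,
    simulate_hydrapsi,
    simulate_rms,
    write_profile,
)
from ribomod.simulate import HYDRAPSI, RMS


@pytest.fixture(scope="module")
def ref20():
    return RnaReference("m", "ACGUACGUACGUACGUACGU")


class TestParameterDomain:
    def test_hyper_reactive_residual_rejected(self):
        with pytest.raises(SimulationError, match="residual"):
            ProtocolParams(protocol=HYDRAPSI, depth=100, residual=1.3)

    def test_bad_fragment_window_rejected(self):
        with pytest.raises(SimulationError, match="frag"):
            ProtocolParams(protocol=RMS, depth=100, frag_min=40, frag_max=20)

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(SimulationError, match="depth"):
            ProtocolParams(protocol=RMS, depth=0)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(SimulationError, match="fraction"):
            TruthProfile("m", {5: 1.2}, "Nm")

    def test_truth_outside_reference_rejected(self, ref20):
        truth = TruthProfile("m", {99: 0.5}, "Nm")
        params = ProtocolParams(protocol=RMS, depth=100)
        with pytest.raises(SimulationError, match="99"):
            simulate_rms(ref20, truth, params, 1)

    def test_psi_truth_on_non_u_rejected(self, ref20):
        assert ref20.residue(1) == "A"
        truth = TruthProfile("m", {1: 0.5}, "Psi")
        params = ProtocolParams(protocol=HYDRAPSI, depth=100)
        with pytest.raises(SimulationError, match="non-U"):
            simulate_hydrapsi(ref20, truth, params, 1)


class TestRms:
    def test_deterministic_and_stable_under_added_replicates(self, ref20):
        truth = TruthProfile("m", {10: 0.5}, "Nm")
        params = ProtocolParams(protocol=RMS, depth=500, seed=7)
        two = simulate_rms(ref20, truth, params, 2)
        three = simulate_rms(ref20, truth, params, 3)
        for a, b in zip(two, three):
            assert np.array_equal(a.counts5, b.counts5)
            assert np.array_equal(a.counts3, b.counts3)

    def test_full_protection_gives_exact_zeros(self, ref20):
        truth = TruthProfile("m", {10: 1.0}, "Nm")
        params = ProtocolParams(protocol=RMS, depth=2000, seed=0)
        for profile in simulate_rms(ref20, truth, params, 5):
            assert profile.counts3[9] == 0  # bond 10 = 3' end at nucleotide 10
            assert profile.counts5[10] == 0  # 5' end at nucleotide 11

    def test_half_methylation_halves_expected_cleavage(self, ref20):
        # Monte-Carlo mean at the protected bond vs flanking bonds ~ 0.5
        truth = TruthProfile("m", {10: 0.5}, "Nm")
        params = ProtocolParams(protocol=RMS, depth=1000, seed=3)
        profiles = simulate_rms(ref20, truth, params, 3000)
        at_bond = np.mean([p.counts3[9] for p in profiles])
        flank = np.mean([[p.counts3[7], p.counts3[11]] for p in profiles])
        ratio = at_bond / flank
        # 3 SE of the mean at the bond is ~0.0012 on the ratio scale
        assert abs(ratio - 0.5) < 0.005

    def test_protection_is_monotone_in_fraction(self, ref20):
        means = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            truth = TruthProfile("m", {10: f}, "Nm")
            params = ProtocolParams(protocol=RMS, depth=500, seed=11)
            profiles = simulate_rms(ref20, truth, params, 100)
            means.append(np.mean([p.counts3[9] for p in profiles]))
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_fragment_mode_conserves_end_counts(self):
        ref = RnaReference("long", "ACGU" * 50)
        truth = TruthProfile("long", {100: 0.8}, "Nm")
        params = ProtocolParams(
            protocol=RMS, depth=5000, seed=5, fragment_mode=True
        )
        for profile in simulate_rms(ref, truth, params, 3):
            assert profile.counts5.sum() == profile.counts3.sum() > 0


class TestHydraPsi:
    def test_non_u_positions_carry_background_rate_only(self, ref20):
        truth = TruthProfile("m", {}, "Psi")
        params = ProtocolParams(protocol=HYDRAPSI, depth=1000, seed=2, bg_rate=0.01)
        profiles = simulate_hydrapsi(ref20, truth, params, 500)
        stack = np.stack([p.counts5 for p in profiles])
        is_u = np.array([c == "U" for c in ref20.sequence])
        assert abs(stack[:, is_u].mean() - 1000) < 10
        assert abs(stack[:, ~is_u].mean() - 10) < 1

    def test_full_protection_gives_exact_zero(self, ref20):
        truth = TruthProfile("m", {4: 1.0}, "Psi")
        params = ProtocolParams(protocol=HYDRAPSI, depth=2000, seed=1)
        for profile in simulate_hydrapsi(ref20, truth, params, 5):
            assert profile.counts5[3] == 0

    def test_counts3_left_zero(self, ref20):
        truth = TruthProfile("m", {}, "Psi")
        params = ProtocolParams(protocol=HYDRAPSI, depth=100, seed=0)
        (profile,) = simulate_hydrapsi(ref20, truth, params, 1)
        assert profile.counts3.sum() == 0

    def test_end_offset_shifts_the_reported_end(self, ref20):
        truth = TruthProfile("m", {}, "Psi")
        base = ProtocolParams(protocol=HYDRAPSI, depth=500, seed=9)
        shifted = ProtocolParams(protocol=HYDRAPSI, depth=500, seed=9, end_offset=1)
        (a,) = simulate_hydrapsi(ref20, truth, base, 1)
        (b,) = simulate_hydrapsi(ref20, truth, shifted, 1)
        assert np.array_equal(a.counts5[:-1], b.counts5[1:])


class TestProfileIO:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 5000), st.integers(0, 5000)),
            min_size=1,
            max_size=30,
        )
    )
    def test_round_trip_is_lossless(self, counts, tmp_path_factory):
        profile = EndCountProfile(
            molecule="m",
            counts5=np.array([c[0] for c in counts]),
            counts3=np.array([c[1] for c in counts]),
            replicate_id="rep1",
            protocol=RMS,
        )
        path = tmp_path_factory.mktemp("io") / "p.tsv"
        write_profile(profile, path, seed=1)
        again = read_profile(path)
        assert again.molecule == profile.molecule
        assert again.protocol == profile.protocol
        assert again.replicate_id == profile.replicate_id
        assert np.array_equal(again.counts5, profile.counts5)
        assert np.array_equal(again.counts3, profile.counts3)

    def test_negative_count_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "# molecule=m\n# protocol=RMS\n# replicate_id=rep1\n"
            "position\tcount5\tcount3\n1\t-3\t0\n"
        )
        with pytest.raises(SimulationError, match="negative"):
            read_profile(path)

    def test_empty_profile_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text(
            "# molecule=m\n# protocol=RMS\n# replicate_id=rep1\n"
            "position\tcount5\tcount3\n"
        )
        with pytest.raises(SimulationError, match="empty"):
            read_profile(path)

    def test_zero_length_profile_rejected(self):
        with pytest.raises(SimulationError, match="empty"):
            EndCountProfile("m", np.array([], dtype=int), np.array([], dtype=int),
                            "rep1", RMS)
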
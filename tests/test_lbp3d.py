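import numpy as np
import pytest

from voxtex.volio import Volume3D
from voxtex.lbp3d import (
    N_CODES,
    N_NEIGHBORS,
    LBPConfig,
    neighbor_offsets,
    code_at,
    code_volume,
    circular_transitions,
    is_uniform,
    build_pattern_table,
    riu2_bin,
    lbp_histogram,
    variant_n_bins,
)


def _string_transitions(code: int, n_bits: int) -> int:
    """Independent oracle: count circular bit changes on the binary string."""
    s = format(code, f"0{n_bits}b")
    return sum(s[i] != s[i - 1] for i in range(n_bits))


class TestOffsets:
    def test_eighteen_unique_noncorner_offsets(self):
        offs = neighbor_offsets()
        assert len(offs) == 18
        assert len(set(offs)) == 18
        assert (0, 0, 0) not in offs
        for o in offs:
            assert all(c in (-1, 0, 1) for c in o)
            assert sum(c != 0 for c in o) <= 2  # corners (3 nonzero) excluded


class TestCodeAt:
    def test_all_neighbors_equal_centre_sets_every_bit(self):
        vol = Volume3D(np.full((3, 3, 3), 7.0))
        assert code_at(vol, (1, 1, 1)) == N_CODES - 1  # ties count as 1

    def test_centre_above_all_neighbors_gives_zero(self):
        data = np.zeros((3, 3, 3))
        data[1, 1, 1] = 10.0
        assert code_at(Volume3D(data), (1, 1, 1)) == 0

    def test_only_first_neighbor_above_centre_gives_code_one(self):
        data = np.full((3, 3, 3), 4.0)
        data[1, 1, 1] = 5.0
        dx, dy, dz = neighbor_offsets()[0]
        data[1 + dx, 1 + dy, 1 + dz] = 6.0
        assert code_at(Volume3D(data), (1, 1, 1)) == 1

    def test_boundary_voxel_rejected(self):
        vol = Volume3D(np.zeros((3, 3, 3)))
        with pytest.raises(IndexError):
            code_at(vol, (0, 1, 1))

    def test_scalar_and_vectorised_coders_agree(self, rng):
        vol = Volume3D(rng.standard_normal((6, 5, 7)))
        codes = code_volume(vol)
        for voxel in [(1, 1, 1), (2, 3, 4), (4, 2, 5), (3, 1, 2)]:
            x, y, z = voxel
            assert codes[x - 1, y - 1, z - 1] == code_at(vol, voxel)


class TestUniformity:
    @pytest.mark.parametrize(
        "code,expected",
        [
            (0, 0),                         # all zeros: no changes
            (1, 2),                         # one set bit: up and down
            (0b010101010101010101, 18),     # alternating: every step flips
            (N_CODES - 1, 0),               # all ones
        ],
    )
    def test_transition_counts(self, code, expected):
        assert circular_transitions(code) == expected

    def test_transitions_match_string_oracle_on_sample(self, rng):
        for code in rng.integers(0, N_CODES, 200):
            assert circular_transitions(int(code)) == _string_transitions(int(code), 18)

    def test_out_of_range_code_rejected(self):
        with pytest.raises(ValueError):
            circular_transitions(N_CODES)
        with pytest.raises(ValueError):
            riu2_bin(-1)

    def test_single_run_codes_are_uniform(self):
        # every circular run of k ones is uniform; alternating is not
        assert is_uniform(0)
        assert is_uniform(0b111)
        assert is_uniform((1 << 18) - 1)
        assert not is_uniform(0b010101010101010101)

    @pytest.mark.parametrize("n_bits", [4, 8, 12, 18])
    def test_uniform_code_count_formula(self, n_bits):
        """Brute force: n-bit circular-uniform codes number n(n-1)+2."""
        count = sum(
            _string_transitions(c, n_bits) <= 2 for c in range(1 << n_bits)
        )
        assert count == n_bits * (n_bits - 1) + 2


class TestPatternTables:
    def test_uniform_table_has_309_bins(self):
        t = build_pattern_table("uniform")
        assert t.n_bins == 309
        assert t.code_to_bin.shape == (N_CODES,)
        assert t.code_to_bin.max() == 308

    def test_riu_table_has_20_bins(self):
        t = build_pattern_table("riu")
        assert t.n_bins == 20
        assert set(np.unique(t.code_to_bin)) == set(range(20))

    def test_uniform_bins_ascend_with_code(self):
        t = build_pattern_table("uniform")
        uniform_codes = np.flatnonzero(t.code_to_bin < 308)
        bins = t.code_to_bin[uniform_codes]
        assert np.all(np.diff(bins) == 1)  # ascending code order, dense

    def test_riu_bin_examples(self):
        assert riu2_bin(0) == 0
        assert riu2_bin(N_CODES - 1) == 18
        assert riu2_bin(0b010101010101010101) == 19  # non-uniform sentinel

    def test_riu_bin_rotation_invariant_sampled(self, rng):
        mask = N_CODES - 1
        for code in map(int, rng.integers(0, N_CODES, 100)):
            for k in range(N_NEIGHBORS):
                rot = ((code >> k) | (code << (N_NEIGHBORS - k))) & mask
                assert riu2_bin(rot) == riu2_bin(code)

    def test_full_variant_has_no_table(self):
        with pytest.raises(ValueError):
            build_pattern_table("full")


class TestHistogram:
    def test_full_variant_length(self, rng):
        vol = Volume3D(rng.standard_normal((5, 5, 5)))
        h = lbp_histogram(vol, LBPConfig(variant="full", normalize=False))
        assert h.bins.size == 262_144

    def test_constant_volume_riu_mass_in_bin_18(self, constant_volume):
        h = lbp_histogram(constant_volume, LBPConfig(variant="riu"))
        assert h.bins[18] == pytest.approx(1.0)
        assert h.bins.sum() == pytest.approx(1.0, abs=1e-12)

    def test_unnormalized_sum_is_interior_count(self, rng):
        vol = Volume3D(rng.standard_normal((6, 7, 8)))
        h = lbp_histogram(vol, LBPConfig(variant="riu", normalize=False))
        assert h.bins.sum() == (6 - 2) * (7 - 2) * (8 - 2)
        assert h.n_coded == (6 - 2) * (7 - 2) * (8 - 2)

    def test_normalized_sum_is_one(self, rng):
        for variant in ("uniform", "riu"):
            vol = Volume3D(rng.standard_normal((6, 6, 6)))
            h = lbp_histogram(vol, LBPConfig(variant=variant))
            assert abs(h.bins.sum() - 1.0) < 1e-12

    def test_intensity_shift_leaves_histogram_unchanged(self, rng):
        data = rng.standard_normal((7, 7, 7))
        h1 = lbp_histogram(Volume3D(data), LBPConfig(variant="riu"))
        h2 = lbp_histogram(Volume3D(data + 42.0), LBPConfig(variant="riu"))
        np.testing.assert_array_equal(h1.bins, h2.bins)

    def test_uniform_histogram_refines_riu(self, rng):
        """Summing 309-variant bins grouped by riu bin reproduces LBP-20."""
        vol = Volume3D(rng.standard_normal((8, 8, 8)))
        h309 = lbp_histogram(vol, LBPConfig(variant="uniform", normalize=False))
        h20 = lbp_histogram(vol, LBPConfig(variant="riu", normalize=False))
        t_u = build_pattern_table("uniform")
        t_r = build_pattern_table("riu")
        # map each 309-bin to its riu bin via any representative code
        riu_of_bin = np.zeros(t_u.n_bins, dtype=int)
        reps = np.zeros(t_u.n_bins, dtype=np.int64)
        reps[t_u.code_to_bin[::-1]] = np.arange(N_CODES - 1, -1, -1)
        riu_of_bin = t_r.code_to_bin[reps]
        grouped = np.zeros(20)
        np.add.at(grouped, riu_of_bin, h309.bins)
        np.testing.assert_array_equal(grouped, h20.bins)

    def test_mask_restricts_coded_voxels(self, rng):
        data = rng.standard_normal((6, 6, 6))
        mask = np.zeros((6, 6, 6), bool)
        mask[2:4, 2:4, 2:4] = True
        h = lbp_histogram(Volume3D(data, mask=mask),
                          LBPConfig(variant="riu", normalize=False))
        assert h.n_coded == 8
        assert h.bins.sum() == 8

    def test_all_masked_interior_is_degenerate(self, rng):
        data = rng.standard_normal((5, 5, 5))
        mask = np.zeros((5, 5, 5), bool)
        mask[0, :, :] = True  # only boundary voxels pass the mask
        with pytest.raises(ValueError, match="mask"):
            lbp_histogram(Volume3D(data, mask=mask), LBPConfig(variant="riu"))

    def test_too_small_volume(self):
        with pytest.raises(ValueError, match="too small"):
            lbp_histogram(Volume3D(np.zeros((2, 5, 5))), LBPConfig())

    def test_variant_bin_counts(self):
        assert variant_n_bins("full") == 262_144
        assert variant_n_bins("uniform") == 309
        assert variant_n_bins("riu") == 20
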
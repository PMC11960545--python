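import numpy as np
import pandas as pd
import pytest

from scmeth import (BinaryStateTable, ClusterAssignment, ClusterProfile,
                    SiteCatalog, build_neighbor_tensor, encode_dna_window,
                    make_examples, neighbor_indices)
from scmeth.encoding import SENTINEL, GenomeEncoder


def _catalog(positions, chrom="s1"):
    n = len(positions)
    return SiteCatalog(np.array([chrom] * n, dtype=object),
                       np.asarray(positions),
                       np.array(["+"] * n, dtype=object))


class TestDnaWindow:
    def test_direct_onehot(self):
        # target C of "AC" with L=2: rows are A-hot then C-hot
        win = encode_dna_window({"c": "AC"}, "c", 2, "+", 2)
        np.testing.assert_array_equal(win, [[1, 0, 0, 0], [0, 1, 0, 0]])

    def test_target_base_at_center(self):
        genome = {"c": "AAAACGTTTT"}
        win = encode_dna_window(genome, "c", 5, "+", 6)  # C at 1-based 5
        assert win[3, 1] == 1  # center row L/2 is the C

    def test_out_of_range_padding(self):
        genome = {"c": "ACGTACGTACGT"}
        win = encode_dna_window(genome, "c", 4, "+", 10)
        assert np.all(win[:2] == 0)  # 2 positions before chromosome start
        assert win[2:].sum() == 8

    def test_n_bases_are_zero_rows(self):
        win = encode_dna_window({"c": "ANGT"}, "c", 1, "+", 4)
        # 0-based window [-2, 2): pad, pad, A, N
        assert np.all(win[:2] == 0) and np.all(win[3] == 0)
        assert win[2, 0] == 1
        row_sums = win.sum(axis=1)
        assert set(row_sums) <= {0.0, 1.0}

    def test_minus_strand_reverse_complement(self):
        genome = {"c": "TTCGAA"}
        # minus-strand target at the G (1-based 4); rc window reads the
        # complementary strand 5'->3', so its center is again a C
        plus = encode_dna_window(genome, "c", 3, "+", 4)
        minus = encode_dna_window(genome, "c", 4, "-", 4)
        assert minus[2, 1] == 1  # C at center
        # palindromic site: rc window equals the plus window here
        np.testing.assert_array_equal(plus, minus)

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            GenomeEncoder({"c": "ACGT"}).window("missing", 1, "+", 4)

    @pytest.mark.parametrize("length", [3, 5])
    def test_odd_length_rejected(self, length):
        with pytest.raises(ValueError):
            encode_dna_window({"c": "ACGTACGT"}, "c", 4, "+", length)


class TestNeighborIndices:
    def test_interior_symmetric(self):
        cat = _catalog([10, 20, 30, 40, 50, 60, 70])
        rows = neighbor_indices(cat, 2, 4)  # target = 3rd of 7
        np.testing.assert_array_equal(rows, [0, 1, 3, 4])

    def test_borrow_downstream_at_start(self):
        cat = _catalog([10, 20, 30, 40, 50, 60])
        rows = neighbor_indices(cat, 0, 4)
        np.testing.assert_array_equal(rows, [1, 2, 3, 4])

    def test_borrow_upstream_at_end(self):
        cat = _catalog([10, 20, 30, 40, 50, 60])
        rows = neighbor_indices(cat, 5, 4)
        np.testing.assert_array_equal(rows, [1, 2, 3, 4])

    def test_padding_when_chromosome_too_small(self):
        cat = _catalog([10, 20, 30])
        rows = neighbor_indices(cat, 1, 4)
        np.testing.assert_array_equal(rows, [0, 2, -1, -1])

    def test_positions_strictly_increasing_and_target_excluded(self, rng):
        cat = _catalog(np.sort(rng.choice(10_000, size=60, replace=False)) + 1)
        for target in [0, 7, 30, 59]:
            rows = neighbor_indices(cat, target, 10)
            real = rows[rows >= 0]
            assert target not in real
            assert np.all(np.diff(cat.pos[real]) > 0)


class TestNeighborTensor:
    def _profile(self, levels):
        """levels: (n_clusters, n_sites) with np.nan for undefined."""
        levels = np.asarray(levels, dtype=float)
        cov = np.where(np.isnan(levels), 0, 10).astype(int)
        mc = np.where(np.isnan(levels), 0, np.nan_to_num(levels) * 10).astype(int)
        cat = _catalog((np.arange(levels.shape[1]) + 1) * 10)
        return ClusterProfile(cat, mc, cov, list(range(1, len(levels) + 1)))

    def test_levels_and_target_row(self):
        prof = self._profile([[0.1, 0.2, 0.3, 0.4, 0.5]])
        tensor, tri = build_neighbor_tensor(prof, 2, 4)
        assert tri == 2
        np.testing.assert_allclose(tensor[:, 0], [0.1, 0.2, 0.4, 0.5])

    def test_no_sentinel_when_fully_defined(self):
        prof = self._profile(np.full((3, 8), 0.5))
        tensor, _ = build_neighbor_tensor(prof, 4, 6)
        assert not np.any(tensor == SENTINEL)

    def test_sentinel_for_missing_and_padding(self):
        prof = self._profile([[0.5, np.nan, 0.5]])
        tensor, _ = build_neighbor_tensor(prof, 0, 4)
        assert tensor[0, 0] == SENTINEL  # undefined level (site 2)
        assert np.all(tensor[2:] == SENTINEL)  # padding rows


class TestMakeExamples:
    @pytest.fixture
    def toy(self):
        genome = {"s1": "AA" + "CGTACGTACGAACGTTCGA" * 3}
        cat = SiteCatalog.from_genome(genome)
        cells = ["c1", "c2", "c3"]
        states = BinaryStateTable(pd.DataFrame({
            "cell": ["c1", "c3", "c1"],
            "chrom": ["s1"] * 3,
            "pos": [int(cat.pos[1])] * 2 + [int(cat.pos[2])],
            "strand": ["+"] * 3,
            "state": [1, 0, 1],
        }))
        asn = ClusterAssignment({"c1": 1, "c2": 1, "c3": 2})
        profile = ClusterProfile.from_states(states, asn, cat)
        return genome, cat, cells, states, profile

    def test_label_and_mask_mapping(self, toy):
        genome, cat, cells, states, profile = toy
        ex = make_examples(states, profile, genome, cells, k=4, length=8)
        # site observed in cells {c1, c3} with states {1, 0}
        i = list(ex.site_rows).index(1)
        np.testing.assert_array_equal(ex.mask[i], [True, False, True])
        assert ex.labels[i, 0] == 1 and ex.labels[i, 2] == 0

    def test_unobserved_sites_omitted_and_count(self, toy):
        genome, cat, cells, states, profile = toy
        ex = make_examples(states, profile, genome, cells, k=4, length=8)
        assert len(ex) == 2  # two distinct observed sites
        full = make_examples(states, profile, genome, cells, k=4, length=8,
                             require_observed=False)
        assert len(full) == len(cat)

    def test_pure_function(self, toy):
        genome, cat, cells, states, profile = toy
        a = make_examples(states, profile, genome, cells, k=4, length=8)
        b = make_examples(states, profile, genome, cells, k=4, length=8)
        np.testing.assert_array_equal(a.dna, b.dna)
        np.testing.assert_array_equal(a.neighbors, b.neighbors)

    def test_target_level_never_in_tensor(self, small_dataset, small_profile):
        ds = small_dataset
        assignment, profile = small_profile
        ex = make_examples(ds.states, profile, ds.genome, ds.cells,
                           k=8, length=16,
                           site_rows=np.arange(40))
        levels = profile.levels
        for i, row in enumerate(ex.site_rows[:10]):
            nbr = neighbor_indices(profile.catalog, row, 8)
            assert row not in nbr[nbr >= 0]
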
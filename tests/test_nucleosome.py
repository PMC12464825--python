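"""Linker-length rule and scale-regions pile-up."""

import numpy as np
import pytest

from ladkit.domains import DomainSet, LAD, ILAD
from ladkit.nucleosome import (
    DyadSet, linker_lengths, read_dyads_bed, scaled_region_pileup,
    write_dyads_bed,
)
from ladkit.tracks import BinGrid, BinnedTrack

from conftest import track_from_array

BS = 20_000


def single_lad_domains(start=0, end=1_000_000, chrom_len=2_000_000):
    return DomainSet.from_intervals([
        ("chr1", 0, start, ILAD) if start > 0 else None,
        ("chr1", start, end, LAD),
        ("chr1", end, chrom_len, ILAD),
    ][0 if start > 0 else 1:])


def linker_oracle(positions, domains_df, nuc_len=147, short_cut=100,
                  keep_min=1, keep_max=100):
    """Brute-force over all consecutive pairs, per domain."""
    out = {LAD: [], ILAD: []}
    for r in domains_df.itertuples():
        inside = sorted(p for p in positions if r.start <= p < r.end)
        for p, q in zip(inside, inside[1:]):
            d = q - p
            linker = d - nuc_len if d > short_cut else d
            if keep_min <= linker <= keep_max:
                out[r.state].append(linker)
    return out


class TestLinkerLengths:
    def micro_case(self, distance):
        domains = single_lad_domains(0, 1_000_000)
        dyads = DyadSet({"chr1": np.array([1000, 1000 + distance])})
        return linker_lengths(dyads, domains)[LAD]

    def test_distance_200_gives_53(self):
        np.testing.assert_array_equal(self.micro_case(200), [53])

    def test_distance_90_kept_raw(self):
        np.testing.assert_array_equal(self.micro_case(90), [90])

    def test_distance_147_excluded_linker_zero(self):
        assert self.micro_case(147).size == 0

    def test_distance_300_excluded_linker_153(self):
        assert self.micro_case(300).size == 0

    def test_cross_boundary_pairs_dropped(self):
        domains = DomainSet.from_intervals([
            ("chr1", 0, 1000, LAD), ("chr1", 1000, 2000, ILAD)])
        dyads = DyadSet({"chr1": np.array([950, 1150])})  # spans the border
        lengths = linker_lengths(dyads, domains)
        assert lengths[LAD].size == 0 and lengths[ILAD].size == 0

    def test_random_sets_match_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            edges = np.sort(rng.choice(np.arange(1, 100), 5, replace=False)) * 1000
            intervals, pos0 = [], 0
            for i, e in enumerate([*edges, 100_000]):
                intervals.append(
                    ("chr1", pos0, e, LAD if i % 2 == 0 else ILAD))
                pos0 = e
            domains = DomainSet.from_intervals(intervals)
            positions = np.unique(rng.integers(0, 100_000, 300))
            dyads = DyadSet({"chr1": positions})
            got = linker_lengths(dyads, domains)
            expected = linker_oracle(positions, domains.df)
            for state in (LAD, ILAD):
                np.testing.assert_array_equal(got[state],
                                              np.array(expected[state]))

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        positions = np.unique(rng.integers(0, 50_000, 200))
        domains = single_lad_domains(0, 50_000, 100_000)
        base = linker_lengths(DyadSet({"chr1": positions}), domains)
        shift = 1_000_000
        shifted_domains = DomainSet.from_intervals([
            ("chr1", shift, 50_000 + shift, LAD),
            ("chr1", 50_000 + shift, 100_000 + shift, ILAD),
        ])
        shifted = linker_lengths(
            DyadSet({"chr1": positions + shift}), shifted_domains)
        for state in (LAD, ILAD):
            np.testing.assert_array_equal(base[state], shifted[state])

    def test_injected_nrl_difference_recovered(self, small_config):
        from ladkit.simulate import simulate_dyads, simulate_genome

        truth = simulate_genome(small_config)
        dyads = DyadSet(simulate_dyads(truth, nrl_lad=197, nrl_ilad=187,
                                       jitter=15, seed=3))
        lengths = linker_lengths(dyads, truth.domains)
        med_lad = np.median(lengths[LAD])
        med_ilad = np.median(lengths[ILAD])
        assert med_lad > med_ilad  # longer linkers in LADs, as injected

    def test_bed_round_trip(self, tmp_path):
        dyads = DyadSet({"chr1": np.array([10, 500, 900]),
                         "chr2": np.array([42])})
        path = tmp_path / "dyads.bed"
        write_dyads_bed(dyads, path)
        back = read_dyads_bed(path)
        for chrom in dyads.positions:
            np.testing.assert_array_equal(back.positions[chrom],
                                          dyads.positions[chrom])


class TestScaledRegionPileup:
    def test_column_count_contract(self):
        domains = single_lad_domains(500_000, 1_500_000, 3_000_000)
        track = track_from_array(np.ones(150))
        m = scaled_region_pileup(track, domains.df.pipe(
            lambda df: DomainSet(df)), bs=10_000)
        assert m.matrix.shape[1] == 50 + 100 + 50

    def test_constant_track_constant_matrix(self):
        # flanks stay inside the genome, so every cell sees the constant
        domains = DomainSet.from_intervals([
            ("chr1", 600_000, 1_800_000, LAD),
            ("chr1", 1_800_000, 2_400_000, ILAD),
        ])
        track = track_from_array(np.full(150, 2.5))
        m = scaled_region_pileup(track, domains)
        np.testing.assert_allclose(m.matrix, 2.5, atol=1e-12)

    def test_step_track_body_vs_flanks(self):
        # domain exactly equals the region of value 1; flanks are 0
        domains = DomainSet.from_intervals([
            ("chr1", 0, 1_000_000, ILAD),
            ("chr1", 1_000_000, 2_000_000, LAD),
            ("chr1", 2_000_000, 3_000_000, ILAD),
        ])
        vals = np.zeros(150)
        vals[50:100] = 1.0
        track = track_from_array(vals)
        lad_only = DomainSet.from_intervals(
            [("chr1", 1_000_000, 2_000_000, LAD)])
        m = scaled_region_pileup(track, lad_only)
        row = m.matrix[0]
        np.testing.assert_allclose(row[50:150], 1.0, atol=1e-12)
        np.testing.assert_allclose(row[:50], 0.0, atol=1e-12)
        np.testing.assert_allclose(row[150:], 0.0, atol=1e-12)

    def test_missing_data_counts_as_zero(self):
        domains = DomainSet.from_intervals(
            [("chr1", 1_000_000, 2_000_000, LAD)])
        vals = np.full(150, 1.0)
        vals[60] = np.nan   # one missing bin inside the body
        track = track_from_array(vals)
        m = scaled_region_pileup(track, domains)
        body = m.matrix[0, 50:150]
        assert body.min() == 0.0
        assert body.max() == 1.0

    def test_outside_genome_counts_as_zero(self):
        # flank extends left of position 0: those columns average in zeros
        domains = DomainSet.from_intervals([("chr1", 0, 1_000_000, LAD)])
        grid = BinGrid({"chr1": 1_000_000}, BS)
        track = BinnedTrack(grid, {"chr1": np.ones(50)})
        m = scaled_region_pileup(track, domains)
        np.testing.assert_allclose(m.matrix[0, :50], 0.0, atol=1e-12)
        np.testing.assert_allclose(m.matrix[0, 50:150], 1.0, atol=1e-12)

    def test_area_weighted_resampling_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=150)
        track = track_from_array(vals)
        # domain of 37 bins: body columns have fractional spans
        start, end = 13 * BS, 50 * BS
        domains = DomainSet.from_intervals([("chr1", start, end, LAD)])
        m = scaled_region_pileup(track, domains, bs=10_000)
        body = m.matrix[0, 50:150]
        length = end - start
        # oracle: dense 1-bp resolution average per output column
        dense = np.repeat(vals, BS)
        oracle = np.empty(100)
        for j in range(100):
            x0 = start + j * length / 100
            x1 = start + (j + 1) * length / 100
            i0, i1 = int(np.floor(x0)), int(np.ceil(x1))
            weights = np.ones(i1 - i0)
            weights[0] -= x0 - i0
            weights[-1] -= i1 - x1
            oracle[j] = np.average(dense[i0:i1], weights=weights)
        np.testing.assert_allclose(body, oracle, atol=1e-9)

    def test_degenerate_short_domain_flagged(self):
        domains = DomainSet.from_intervals([("chr1", 40_000, 45_000, LAD)])
        track = track_from_array(np.arange(150.0))
        with pytest.warns(UserWarning, match="degenerate"):
            m = scaled_region_pileup(track, domains)
        assert np.all(np.isfinite(m.matrix))

    def test_skip_zeros_drops_empty_rows(self):
        domains = DomainSet.from_intervals([
            ("chr1", 600_000, 1_000_000, LAD),
            ("chr1", 1_000_000, 2_000_000, ILAD),
            ("chr1", 2_000_000, 2_400_000, LAD),
        ])
        vals = np.zeros(150)
        vals[100:120] = 1.0   # signal only inside the second LAD
        track = track_from_array(vals)
        m = scaled_region_pileup(track, domains, skip_zeros=True)
        # the first LAD's window is entirely signal-free and is dropped
        assert m.matrix.shape[0] == 2

    def test_tsv_output(self, tmp_path):
        import pandas as pd

        domains = DomainSet.from_intervals([("chr1", 1_000_000, 2_000_000, LAD)])
        track = track_from_array(np.ones(150))
        m = scaled_region_pileup(track, domains)
        path = tmp_path / "pileup.tsv"
        m.to_tsv(path)
        df = pd.read_csv(path, sep="\t", comment="#")
        assert df.shape == (1, 201)
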
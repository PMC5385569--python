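import numpy as np
import pandas as pd
import pytest

from dihmm import evaluate
from dihmm.types import GenomicSegment, ValidationError


def seg(start, end, state, level="nucleosome", chrom="chr1", cell=""):
    return GenomicSegment(chrom, start, end, level, state, cell)


def tiling_segments(states, bin_size=200, level="nucleosome"):
    """One segment per bin (stitching not required for these statistics)."""
    return [
        seg(i * bin_size, (i + 1) * bin_size, s, level=level)
        for i, s in enumerate(states)
    ]


class TestFoldEnrichment:
    def test_formula_on_hand_built_contingency(self):
        # m=10, n=100, M=20, N=1000 -> (10/100)/(20/1000) = 5.0
        states = np.zeros(1000, dtype=int)
        states[:20] = 1  # M = 20 bins of state 1
        segs = tiling_segments(states)
        # annotation covers bins 10..109 (n=100), overlapping state-1 bins 10..19
        table = evaluate.fold_enrichment(segs, [(10 * 200, 110 * 200)], bin_size=200)
        row = table[table.state == 1].iloc[0]
        assert (row.m, row.n, row.M, row.N) == (10, 100, 20, 1000)
        assert row.enrichment == pytest.approx(5.0)
        assert 0 <= row.fisher_p <= 1

    def test_state_covering_genome_has_unit_enrichment(self):
        segs = [seg(0, 200 * 500, 0)]
        table = evaluate.fold_enrichment(segs, [(1000, 9000)], bin_size=200)
        assert table.iloc[0].enrichment == pytest.approx(1.0)

    def test_zero_overlap_gives_zero(self):
        states = np.array([0] * 50 + [1] * 50)
        table = evaluate.fold_enrichment(
            tiling_segments(states), [(0, 10 * 200)], bin_size=200
        )
        assert table[table.state == 1].iloc[0].enrichment == 0.0

    def test_undefined_reported_not_silent(self):
        segs = [seg(0, 1000, 0)]
        table = evaluate.fold_enrichment(segs, [], bin_size=200)
        assert not table.iloc[0].defined
        assert np.isnan(table.iloc[0].enrichment)

    def test_matches_per_bin_membership_oracle(self):
        rng = np.random.default_rng(1)
        states = rng.integers(0, 3, size=2000)
        intervals = [(100 * 200, 400 * 200), (1200 * 200, 1300 * 200)]
        table = evaluate.fold_enrichment(
            tiling_segments(states), intervals, bin_size=200
        )
        member = np.zeros(2000, dtype=bool)
        for a, b in intervals:
            member[a // 200 : b // 200] = True
        for k in range(3):
            m = int((member & (states == k)).sum())
            expected = (m / member.sum()) / ((states == k).sum() / 2000)
            got = table[table.state == k].iloc[0].enrichment
            assert got == pytest.approx(expected)


class TestBoundaryEnrichment:
    @staticmethod
    def domain_segs_from_blocks(blocks, block_bp=4000):
        out = []
        start = 0
        for i, b in enumerate(blocks):
            end = (i + 1) * block_bp
            if i + 1 == len(blocks) or blocks[i + 1] != b:
                out.append(seg(start, end, b, level="domain"))
                start = end
        return out

    def test_whole_genome_interval_gives_unit_fold(self):
        rng = np.random.default_rng(2)
        blocks = rng.integers(0, 2, size=500)
        segs = self.domain_segs_from_blocks(blocks)
        res = evaluate.boundary_enrichment(
            segs, [(0, 500 * 4000)], bin_size=200, block_size=20
        )
        assert res["fold_change"] == pytest.approx(1.0)

    def test_transition_only_intervals_give_inverse_background(self):
        blocks = np.array([0, 0, 1, 1, 0, 0, 1, 1, 0, 0])
        segs = self.domain_segs_from_blocks(blocks)
        trans = [(p, p + 1) for p in [2 * 4000, 4 * 4000, 6 * 4000, 8 * 4000]]
        res = evaluate.boundary_enrichment(segs, trans, bin_size=200, block_size=20)
        assert res["fold_change"] == pytest.approx(1.0 / res["rate_genome"])

    def test_planted_double_density_measured(self):
        # domain transitions planted 2x denser inside the interval set
        rng = np.random.default_rng(3)
        n_blocks = 10_000
        inside = np.arange(n_blocks) < n_blocks // 2
        p_trans = np.where(inside, 0.4, 0.2)
        blocks = np.zeros(n_blocks, dtype=int)
        for i in range(1, n_blocks):
            change = rng.random() < p_trans[i]
            blocks[i] = blocks[i - 1] ^ change
        segs = self.domain_segs_from_blocks(blocks)
        res = evaluate.boundary_enrichment(
            segs, [(0, (n_blocks // 2) * 4000)], bin_size=200, block_size=20
        )
        expected = 0.4 / 0.3
        assert res["fold_change"] == pytest.approx(expected, rel=0.05)
        assert res["fisher_p"] < 1e-10

    def test_no_junction_in_intervals_reported_undefined(self):
        segs = [seg(0, 8000, 0, level="domain")]
        res = evaluate.boundary_enrichment(segs, [(0, 100)], bin_size=200, block_size=20)
        assert not res["defined"] or np.isnan(res["fold_change"]) or res["n_inside"] == 0


class TestTssProfile:
    def test_state_planted_at_tss_peaks_at_zero_offset(self):
        states = np.zeros(500, dtype=int)
        tss_bins = [100, 200, 300]
        for b in tss_bins:
            states[b] = 1
        tss = pd.DataFrame(
            {"tss": [b * 200 + 50 for b in tss_bins], "strand": ["+"] * 3}
        )
        prof, flat = evaluate.tss_enrichment_profile(
            tiling_segments(states), tss, window_bp=2000, step_bp=200
        )
        assert prof[1].idxmax() == 0
        assert prof[1].max() == 1.0 and prof[1].min() == 0.0

    def test_uniform_state_flagged_flat(self):
        states = np.zeros(300, dtype=int)
        tss = pd.DataFrame({"tss": [20_000], "strand": ["+"]})
        prof, flat = evaluate.tss_enrichment_profile(
            tiling_segments(states), tss, window_bp=2000, step_bp=200
        )
        assert flat == [0]

    def test_minus_strand_downstream_appears_upstream(self):
        # state planted genomically downstream (higher coords) of a minus TSS
        states = np.zeros(500, dtype=int)
        states[260:265] = 1  # downstream in genome coordinates
        tss = pd.DataFrame({"tss": [250 * 200], "strand": ["-"]})
        prof, _ = evaluate.tss_enrichment_profile(
            tiling_segments(states), tss, window_bp=4000, step_bp=200
        )
        peak_offset = prof[1].idxmax()
        assert peak_offset < 0  # flipped to upstream in the profile

    def test_no_tss_rejected(self):
        with pytest.raises(ValidationError):
            evaluate.tss_enrichment_profile(
                tiling_segments(np.zeros(10, dtype=int)),
                pd.DataFrame(columns=["tss", "strand"]),
            )


class TestExpressionByState:
    def test_two_point_z_scores(self):
        genes = pd.DataFrame(
            {"tss": [1000], "strand": ["+"], "c1": [1.0], "c2": [3.0]}
        )
        segs = [seg(800, 1200, 0)]
        table, counts = evaluate.expression_by_state(genes=genes, segments=segs,
                                                     cell_lines=["c1", "c2"])
        assert table.loc[0, "c1"] == pytest.approx(-1.0)
        assert table.loc[0, "c2"] == pytest.approx(1.0)
        assert counts[0] == 1

    def test_state_without_tss_window_reported_empty(self):
        genes = pd.DataFrame(
            {"tss": [100_000], "strand": ["+"], "c1": [1.0], "c2": [2.0]}
        )
        segs = [seg(0, 200, 0)]
        table, counts = evaluate.expression_by_state(segs, genes, ["c1", "c2"])
        assert counts[0] == 0 and np.isnan(table.loc[0, "c1"])

    def test_constant_gene_excluded_and_counted(self):
        genes = pd.DataFrame(
            {"tss": [1000, 1100], "strand": ["+", "+"],
             "c1": [2.0, 1.0], "c2": [2.0, 3.0]}
        )
        segs = [seg(800, 1200, 0)]
        table, counts = evaluate.expression_by_state(segs, genes, ["c1", "c2"])
        assert counts.attrs["n_excluded_constant"] == 1
        assert counts[0] == 1

    def test_planted_shift_ranks_state_highest(self):
        rng = np.random.default_rng(4)
        n = 60
        tss = np.arange(n) * 10_000 + 5_000
        base = rng.normal(0, 1, size=(n, 3))
        near_a = np.arange(n) < 30
        base[near_a, 0] += 1.5  # +1.5 sigma in cell line 1 for genes near state A
        genes = pd.DataFrame(
            {"tss": tss, "strand": "+", "c1": base[:, 0], "c2": base[:, 1],
             "c3": base[:, 2]}
        )
        segs = [seg(int(t) - 100, int(t) + 100, 0 if a else 1)
                for t, a in zip(tss, near_a)]
        table, _ = evaluate.expression_by_state(segs, genes, ["c1", "c2", "c3"])
        assert table.loc[0].idxmax() == "c1"
        assert table.loc[0, "c1"] > table.loc[1, "c1"]

    def test_z_convention_population_sd(self):
        genes = pd.DataFrame(
            {"tss": [1000], "strand": ["+"], "c1": [0.0], "c2": [1.0], "c3": [2.0]}
        )
        segs = [seg(900, 1100, 0)]
        table, _ = evaluate.expression_by_state(segs, genes, ["c1", "c2", "c3"])
        # population sd of (0,1,2) is sqrt(2/3)
        assert table.loc[0, "c3"] == pytest.approx(1.0 / np.sqrt(2 / 3))


class TestFrequencyVectors:
    def test_single_state_tiles_everything(self):
        segs = [seg(0, 40_000, 2, level="domain")]
        fv = evaluate.state_frequency_vectors(segs, window_size=4000)
        assert fv.states == (2,)
        np.testing.assert_allclose(fv.vectors, 1.0)

    def test_half_window_coverage(self):
        segs = [seg(0, 2000, 0, level="domain"), seg(2000, 8000, 1, level="domain")]
        fv = evaluate.state_frequency_vectors(segs, window_size=4000)
        i0 = fv.states.index(0)
        assert fv.vectors[i0, 0] == pytest.approx(0.5)

    def test_columns_sum_to_one_when_fully_annotated(self):
        rng = np.random.default_rng(5)
        states = rng.integers(0, 4, size=200)
        segs = tiling_segments(states, bin_size=200)
        fv = evaluate.state_frequency_vectors(segs, window_size=4000)
        np.testing.assert_allclose(fv.vectors.sum(axis=0), 1.0, atol=1e-9)


class TestGini:
    def test_uniform_is_zero(self):
        assert evaluate.gini_index(np.full(30, 1 / 30)) == pytest.approx(0.0)

    def test_point_mass_closed_form(self):
        p = np.zeros(30)
        p[4] = 1.0
        assert evaluate.gini_index(p) == pytest.approx(29 / 30)

    def test_against_double_sum_oracle(self):
        p = np.array([0.5, 0.5, 0.0, 0.0])
        K = 4
        oracle = sum(abs(a - b) for a in p for b in p) / (2 * K * K * (1 / K))
        assert evaluate.gini_index(p) == pytest.approx(oracle)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValidationError):
            evaluate.gini_index(np.zeros(3))


class TestSimilarityScore:
    @staticmethod
    def fv_from_states(states, n_states, window=4000):
        segs = [
            seg(i * window, (i + 1) * window, s, level="domain")
            for i, s in enumerate(states)
        ]
        return evaluate.state_frequency_vectors(segs, window_size=window)

    def test_identical_relabelled_segmentation_scores_one(self):
        rng = np.random.default_rng(6)
        states = rng.integers(0, 4, size=5000)
        perm = np.array([2, 0, 3, 1])
        fx = self.fv_from_states(states, 4)
        fy = self.fv_from_states(perm[states], 4)
        assert evaluate.similarity_score(fx, fy) == pytest.approx(1.0, abs=1e-9)

    def test_self_similarity_is_one(self):
        rng = np.random.default_rng(7)
        states = rng.integers(0, 3, size=2000)
        fx = self.fv_from_states(states, 3)
        assert evaluate.similarity_score(fx, fx) == pytest.approx(1.0, abs=1e-9)

    def test_independent_segmentations_score_near_zero(self):
        rng = np.random.default_rng(8)
        a = rng.integers(0, 4, size=50_000)
        b = rng.integers(0, 4, size=50_000)
        score = evaluate.similarity_score(
            self.fv_from_states(a, 4), self.fv_from_states(b, 4)
        )
        assert abs(score) < 0.1

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        a = rng.integers(0, 3, size=3000)
        b = rng.integers(0, 5, size=3000)
        fa, fb = self.fv_from_states(a, 3), self.fv_from_states(b, 5)
        assert evaluate.similarity_score(fa, fb) == pytest.approx(
            evaluate.similarity_score(fb, fa)
        )

    def test_mismatched_grids_rejected(self):
        fa = self.fv_from_states(np.zeros(10, dtype=int), 1)
        fb = self.fv_from_states(np.zeros(20, dtype=int), 1)
        with pytest.raises(ValidationError):
            evaluate.similarity_score(fa, fb)
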
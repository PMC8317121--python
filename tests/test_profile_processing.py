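"""Profile processing: QC filters, trimming, interpolation, smoothing."""

import numpy as np
import pytest

from ribocompare.alignment import PairAlignment, align_global
from ribocompare.io_formats import DomainAnnotation, GeneRecord
from ribocompare.profile_processing import (
    DEFAULT_PARAMS,
    ProcessingParams,
    ProfileRejection,
    RawDomainProfile,
    coverage,
    filter_domains,
    interpolate_profile,
    normalize_auc,
    process_pair,
    process_single,
    project_to_alignment,
    smooth,
    trim_gene_ends,
)


def make_raw(counts, gene_len=None, start=0, domain_id="d"):
    counts = np.asarray(counts)
    if gene_len is None:
        gene_len = start + len(counts)
    return RawDomainProfile(
        domain_id=domain_id,
        counts=counts,
        gene_codon_indices=np.arange(start, start + len(counts)),
        gene_len=gene_len,
    )


class TestCoverage:
    @pytest.mark.parametrize(
        "counts,expected",
        [([0, 0, 1, 2], 0.5), ([1, 2, 3], 1.0), ([0, 0, 0], 0.0)],
    )
    def test_fraction_of_covered_positions(self, counts, expected):
        assert coverage(make_raw(counts)) == expected


class TestFilterDomains:
    def _setup(self, n_codons, counts):
        cds = "ATG" + "GCT" * (n_codons - 1)
        gene = GeneRecord.from_cds("g", cds, np.asarray(counts))
        return {"g": gene}

    def test_short_domain_rejected(self):
        genes = self._setup(150, np.ones(150, dtype=int))
        dom = DomainAnnotation("d", "g", 1, 99, "F", "SF", "a")
        kept, log = filter_domains([dom], genes)
        assert kept == [] and log == [("d", "min_length")]

    def test_low_coverage_rejected(self):
        counts = np.ones(150, dtype=int)
        counts[: int(150 * 0.4)] = 0  # coverage 0.6 over the 120-res domain
        genes = self._setup(150, counts)
        dom = DomainAnnotation("d", "g", 1, 120, "F", "SF", "a")
        kept, log = filter_domains([dom], genes)
        assert kept == [] and log == [("d", "coverage")]

    def test_good_domain_retained(self):
        genes = self._setup(150, np.ones(150, dtype=int))
        dom = DomainAnnotation("d", "g", 1, 120, "F", "SF", "a")
        kept, log = filter_domains([dom], genes)
        assert kept == [dom] and log == []

    def test_multi_row_domain_rejected_as_non_contiguous(self):
        genes = self._setup(300, np.ones(300, dtype=int))
        rows = [
            DomainAnnotation("d", "g", 1, 120, "F", "SF", "a"),
            DomainAnnotation("d", "g", 150, 280, "F", "SF", "a"),
        ]
        kept, log = filter_domains(rows, genes)
        assert kept == []
        assert all(rule == "non-contiguous" for _, rule in log)


class TestTrimGeneEnds:
    def test_overlapping_domain_trimmed(self):
        # domain codons 30-150 (0-based) on a 160-codon gene
        raw = make_raw(np.ones(121), gene_len=160, start=30)
        trimmed = trim_gene_ends(raw)
        assert trimmed.gene_codon_indices[0] == 40
        assert trimmed.gene_codon_indices[-1] == 139
        assert len(trimmed.counts) == 100

    def test_interior_domain_unchanged(self):
        raw = make_raw(np.ones(121), gene_len=300, start=60)
        trimmed = trim_gene_ends(raw)
        np.testing.assert_array_equal(
            trimmed.gene_codon_indices, raw.gene_codon_indices
        )

    def test_fully_trimmed_signalled(self):
        raw = make_raw(np.ones(40), gene_len=200, start=0)
        with pytest.raises(ProfileRejection, match="fully_trimmed"):
            trim_gene_ends(raw)

    def test_domain_extent_preserved(self):
        raw = make_raw(np.ones(121), gene_len=160, start=30)
        trimmed = trim_gene_ends(raw)
        assert trimmed.domain_start == 30 and trimmed.domain_len == 121


class TestProjectToAlignment:
    def test_gapless_projection_copies_counts(self):
        a = make_raw([1, 2, 3, 4], gene_len=100, start=50)
        b = make_raw([5, 6, 7, 8], gene_len=100, start=50)
        aln = PairAlignment("MKVA", "MKVA", "protein", 0.0)
        proj = project_to_alignment(a, b, aln)
        np.testing.assert_array_equal(proj.values_a, [1, 2, 3, 4])
        np.testing.assert_array_equal(proj.values_b, [5, 6, 7, 8])
        assert all(proj.status_a == "observed")

    def test_gap_column_marked_missing(self):
        a = make_raw([1, 2, 3, 4], gene_len=100, start=50)
        b = make_raw([5, 6, 7], gene_len=100, start=50)
        aln = PairAlignment("MKVA", "MK-A", "protein", 0.0)
        proj = project_to_alignment(a, b, aln)
        assert proj.status_b[2] == "gap" and np.isnan(proj.values_b[2])

    def test_trimmed_positions_become_missing(self):
        a = make_raw(np.arange(1, 101), gene_len=200, start=30)
        trimmed = trim_gene_ends(a)  # first 10 positions trimmed
        b = make_raw(np.ones(100), gene_len=300, start=60)
        aln = PairAlignment("M" * 100, "M" * 100, "protein", 0.0)
        proj = project_to_alignment(trimmed, b, aln)
        assert all(proj.status_a[:10] == "trimmed")
        assert all(proj.status_a[10:] == "observed")

    def test_length_mismatch_rejected(self):
        a = make_raw([1, 2, 3], gene_len=100, start=50)
        b = make_raw([1, 2, 3, 4], gene_len=100, start=50)
        aln = PairAlignment("MKVA", "MKVA", "protein", 0.0)
        with pytest.raises(ValueError, match="residues"):
            project_to_alignment(a, b, aln)


class TestInterpolateProfile:
    def test_linear_fallback_two_anchors(self):
        out = interpolate_profile([2.0, 0.0, 4.0])
        np.testing.assert_allclose(out, [2, 3, 4])

    def test_all_positive_unchanged(self):
        v = np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        np.testing.assert_array_equal(interpolate_profile(v), v)

    def test_spline_reproduces_cubic(self):
        """An interpolating cubic spline recovers points sampled from a cubic."""
        x = np.arange(8.0)
        y = 0.5 * x**3 - 2 * x**2 + 3 * x + 20
        v = y.copy()
        v[[2, 4, 5]] = 0.0  # knock out three interior points
        out = interpolate_profile(v)
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_anchor_values_held_fixed(self):
        rng = np.random.default_rng(5)
        v = rng.integers(0, 6, 40).astype(float)
        out = interpolate_profile(v)
        anchors = v > 0
        np.testing.assert_array_equal(out[anchors], v[anchors])

    def test_edges_take_nearest_anchor(self):
        v = np.array([0.0, 0.0, 2.0, 5.0, 1.0, 4.0, 0.0])
        out = interpolate_profile(v)
        assert out[0] == out[1] == 2.0 and out[-1] == 4.0

    def test_no_negative_interpolants(self):
        v = np.array([5.0, 0.0, 0.1, 0.0, 5.0, 0.1, 0.0, 5.0])
        assert (interpolate_profile(v) >= 0).all()

    def test_fewer_than_two_anchors_signalled(self):
        with pytest.raises(ProfileRejection, match="uninterpolatable"):
            interpolate_profile([0.0, 3.0, 0.0])


class TestSmooth:
    def test_constant_unchanged(self):
        np.testing.assert_allclose(smooth(np.full(40, 2.5)), np.full(40, 2.5))

    def test_central_impulse(self):
        v = np.zeros(31)
        v[15] = 1.0
        out = smooth(v, window=15)
        np.testing.assert_allclose(out[8:23], np.full(15, 1 / 15))
        assert out[7] == 0 and out[23] == 0

    def test_edge_impulse_shrunken_window(self):
        v = np.zeros(31)
        v[0] = 1.0
        assert smooth(v, window=15)[0] == pytest.approx(1 / 8)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth(np.ones(5), window=4)


class TestNormalizeAuc:
    def test_uniform(self):
        np.testing.assert_allclose(normalize_auc([1, 1, 1, 1]), [0.25] * 4)

    def test_output_sums_to_one(self):
        rng = np.random.default_rng(2)
        v = rng.random(200)
        assert normalize_auc(v).sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            normalize_auc([0.0, 0.0])


class TestProcessPair:
    def _pair_raws(self, gene_len=260, start=60, n=140, seed=0):
        rng = np.random.default_rng(seed)
        a = make_raw(rng.poisson(20, n) + 1, gene_len=gene_len, start=start, domain_id="a")
        b = make_raw(rng.poisson(20, n) + 1, gene_len=gene_len, start=start, domain_id="b")
        return a, b

    def test_gappy_alignment_rejected(self):
        # internal 5-column gap run in one row triggers the gap filter
        a = make_raw(np.ones(145), gene_len=260, start=60, domain_id="a")
        b = make_raw(np.ones(140), gene_len=260, start=60, domain_id="b")
        aln = PairAlignment("M" * 145, "M" * 60 + "-" * 5 + "M" * 80, "protein", 0.0)
        with pytest.raises(ProfileRejection, match="gappy"):
            process_pair(a, b, aln)

    def test_short_final_profile_rejected(self):
        # 100-residue domains at codons 0-99 of a 109-codon gene: trimming
        # the first 40 and last 20 gene codons leaves 49 shared positions
        a = make_raw(np.ones(100), gene_len=109, start=0, domain_id="a")
        b = make_raw(np.ones(100), gene_len=109, start=0, domain_id="b")
        aln = PairAlignment("M" * 100, "M" * 100, "protein", 0.0)
        with pytest.raises(ProfileRejection, match="short_profile"):
            process_pair(a, b, aln)

    def test_profiles_share_columns_and_sum_to_one(self):
        a, b = self._pair_raws()
        aln = PairAlignment("M" * 140, "M" * 140, "protein", 0.0)
        pa, pb = process_pair(a, b, aln)
        np.testing.assert_array_equal(pa.alignment_columns, pb.alignment_columns)
        assert pa.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert pb.values.sum() == pytest.approx(1.0, abs=1e-9)
        assert len(pa) >= 50

    def test_deterministic(self):
        a, b = self._pair_raws()
        aln = PairAlignment("M" * 140, "M" * 140, "protein", 0.0)
        p1 = process_pair(a, b, aln)
        p2 = process_pair(a, b, aln)
        np.testing.assert_array_equal(p1[0].values, p2[0].values)
        np.testing.assert_array_equal(p1[1].values, p2[1].values)

    def test_high_depth_identical_dwell_profiles_converge(self):
        """With identical latent dwell, profiles agree as depth grows."""
        rng = np.random.default_rng(9)
        dwell = np.exp(rng.normal(0, 0.5, 150))
        diffs = []
        for depth in (20, 20000):
            lam = depth * dwell / dwell.mean()
            a = make_raw(rng.poisson(lam), gene_len=250, start=50, domain_id="a")
            b = make_raw(rng.poisson(lam), gene_len=250, start=50, domain_id="b")
            aln = PairAlignment("M" * 150, "M" * 150, "protein", 0.0)
            pa, pb = process_pair(a, b, aln)
            diffs.append(np.abs(pa.values - pb.values).max())
        assert diffs[1] < diffs[0] / 3


class TestProcessSingle:
    def test_matches_pair_processing_when_aligned_trivially(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(15, 140) + 1
        raw = make_raw(counts, gene_len=260, start=60)
        single = process_single(raw)
        aln = PairAlignment("M" * 140, "M" * 140, "protein", 0.0)
        pa, pb = process_pair(raw, raw, aln)
        np.testing.assert_allclose(single.values, pa.values)
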
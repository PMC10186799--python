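"""Hudson F_ST, pooling, Bray-Curtis, PCoA and differentiation bands."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import symbiopop as sp
from symbiopop.errors import ConfigurationError, PipelineError
from symbiopop.popstruct import (
    AlleleCounts,
    DistanceMatrix,
    axis_separates,
    bray_curtis_from_variants,
    make_groups,
)
from tests.conftest import run_study


def _vt(ref, alt, samples=None):
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    samples = samples or [f"s{i}" for i in range(ref.shape[1])]
    return sp.VariantTable(
        gene_ids=np.array(["g"] * ref.shape[0], dtype=object),
        positions=np.arange(ref.shape[0]),
        ref=np.array(["A"] * ref.shape[0], dtype=object),
        alt=np.array(["C"] * ref.shape[0], dtype=object),
        samples=samples,
        ref_counts=ref,
        alt_counts=alt,
        maf=np.zeros(ref.shape[0]),
    )


class TestAlleleFrequencies:
    def test_single_sample_frequency(self):
        vt = _vt([[6]], [[4]])
        assert sp.allele_frequencies(vt, ["s0"])[0] == pytest.approx(0.4)

    def test_pooling_is_count_conserving(self):
        vt = _vt([[6, 0]], [[4, 10]])
        assert sp.allele_frequencies(vt, ["s0", "s1"])[0] == pytest.approx(0.7)

    def test_pooling_associativity(self):
        rng = np.random.default_rng(2)
        vt = _vt(rng.integers(0, 30, (50, 6)), rng.integers(0, 30, (50, 6)))
        all_at_once = sp.allele_frequencies(vt, vt.samples)
        ac_left = sp.pooled_allele_counts(vt, vt.samples[:2])
        ac_right = sp.pooled_allele_counts(vt, vt.samples[2:])
        regrouped = (ac_left.alt + ac_right.alt) / (
            ac_left.depth + ac_right.depth
        )
        np.testing.assert_allclose(all_at_once, regrouped)

    def test_unknown_sample_rejected(self):
        vt = _vt([[6]], [[4]])
        with pytest.raises(KeyError):
            sp.allele_frequencies(vt, ["nope"])

    def test_zero_depth_site_is_missing(self):
        vt = _vt([[0]], [[0]])
        assert np.isnan(sp.allele_frequencies(vt, ["s0"])[0])


class TestHudsonFst:
    def test_fixed_difference_is_exactly_one(self):
        res = sp.hudson_fst(AlleleCounts([0], [10]), AlleleCounts([10], [0]))
        assert res.fst == 1.0
        assert res.per_site_num[0] == pytest.approx(1.0)
        assert res.per_site_den[0] == pytest.approx(1.0)

    def test_hand_computed_single_site(self):
        # p1=0.9, p2=0.1, n1=n2=10: num = 0.64-0.01-0.01, den = 0.82
        res = sp.hudson_fst(AlleleCounts([1], [9]), AlleleCounts([9], [1]))
        assert res.per_site_num[0] == pytest.approx(0.62)
        assert res.per_site_den[0] == pytest.approx(0.82)
        assert res.fst == pytest.approx(0.62 / 0.82)

    def test_identical_frequencies_give_nonpositive_fst(self):
        rng = np.random.default_rng(3)
        alt = rng.integers(1, 20, 100)
        ref = rng.integers(1, 20, 100)
        res = sp.hudson_fst(AlleleCounts(ref, alt), AlleleCounts(ref, alt))
        assert res.fst <= 0

    def test_self_comparison_nonpositive_via_pairwise(self):
        rng = np.random.default_rng(4)
        vt = _vt(rng.integers(2, 30, (80, 2)), rng.integers(2, 30, (80, 2)))
        res = sp.pairwise_fst(vt, {"a": ["s0"], "dup": ["s0"]})
        assert res.fst.loc["a", "dup"] <= 0

    def test_sites_with_n_below_two_excluded(self):
        res = sp.hudson_fst(AlleleCounts([1, 5], [0, 5]), AlleleCounts([5, 0], [5, 10]))
        assert np.isnan(res.per_site_num[0]) and res.n_sites_used == 1

    def test_no_usable_sites_raises(self):
        with pytest.raises(PipelineError, match="undefined"):
            sp.hudson_fst(AlleleCounts([10], [0]), AlleleCounts([10], [0]))

    def test_ratio_of_averages_not_average_of_ratios(self):
        pop1 = AlleleCounts([2, 40], [18, 10])
        pop2 = AlleleCounts([18, 10], [2, 40])
        res = sp.hudson_fst(pop1, pop2)
        num, den = res.per_site_num, res.per_site_den
        assert res.fst == pytest.approx(num.sum() / den.sum())
        assert res.fst != pytest.approx(np.mean(num / den))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_bruteforce_site_loop(self, data):
        n_sites = data.draw(st.integers(1, 50))
        draw_counts = st.lists(
            st.tuples(st.integers(0, 100), st.integers(0, 100)),
            min_size=n_sites, max_size=n_sites,
        )
        c1 = data.draw(draw_counts)
        c2 = data.draw(draw_counts)
        pop1 = AlleleCounts([r for r, _ in c1], [a for _, a in c1])
        pop2 = AlleleCounts([r for r, _ in c2], [a for _, a in c2])
        num_sum = den_sum = 0.0
        usable = 0
        for (r1, a1), (r2, a2) in zip(c1, c2):
            n1, n2 = r1 + a1, r2 + a2
            if n1 < 2 or n2 < 2:
                continue
            p1, p2 = a1 / n1, a2 / n2
            num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
            den = p1 * (1 - p2) + p2 * (1 - p1)
            if den > 0:
                num_sum += num
                den_sum += den
                usable += 1
        if usable == 0:
            with pytest.raises(PipelineError):
                sp.hudson_fst(pop1, pop2)
        else:
            res = sp.hudson_fst(pop1, pop2)
            assert res.fst == pytest.approx(num_sum / den_sum, abs=1e-12)
            assert res.n_sites_used == usable


class TestPairwiseFst:
    def test_pooling_invariance_against_manual_sums(self):
        rng = np.random.default_rng(7)
        vt = _vt(rng.integers(1, 30, (60, 4)), rng.integers(1, 30, (60, 4)))
        groups = {"A": ["s0", "s1"], "B": ["s2", "s3"]}
        res = sp.pairwise_fst(vt, groups)
        manual = sp.hudson_fst(
            AlleleCounts(
                vt.ref_counts[:, :2].sum(1), vt.alt_counts[:, :2].sum(1)
            ),
            AlleleCounts(
                vt.ref_counts[:, 2:].sum(1), vt.alt_counts[:, 2:].sum(1)
            ),
        )
        assert res.fst.loc["A", "B"] == pytest.approx(manual.fst)

    def test_matrix_symmetric_zero_diagonal_and_clamping(self):
        rng = np.random.default_rng(8)
        vt = _vt(rng.integers(2, 30, (40, 3)), rng.integers(2, 30, (40, 3)))
        res = sp.pairwise_fst(vt, {s: [s] for s in vt.samples})
        m = res.fst.to_numpy()
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)
        assert (res.fst_clamped.to_numpy() >= 0).all()

    def test_single_group_rejected(self):
        vt = _vt([[5, 5]], [[5, 5]])
        with pytest.raises(ConfigurationError):
            sp.pairwise_fst(vt, {"only": ["s0", "s1"]})

    def test_full_pipeline_recovery_twenty_strains(self):
        """Island-model F recovered through the whole pipeline with a
        20-strain pool per deme (moderate/strong differentiation)."""
        for target in (0.2, 0.4):
            ests = []
            for seed in range(5):
                cfg = sp.study_config(
                    fst_target=target, n_variant_sites=2000, strains_per_deme=20,
                    samples_per_group=3, lifestyles=("host_associated",),
                    seed=500 + seed,
                )
                study = run_study(cfg)
                vt = sp.call_variants(study["ncm"], study["qc"].retained)
                res = sp.pairwise_fst(vt, make_groups(study["metadata"], "vent_field"))
                ests.append(res.fst.iloc[0, 1])
            assert abs(np.mean(ests) - target) <= 0.05


class TestClassifyDifferentiation:
    @pytest.mark.parametrize(
        "value,band",
        [(0.0, "weak"), (0.19, "weak"), (0.2, "moderate"), (0.35, "moderate"),
         (0.5, "moderate"), (0.51, "strong"), (0.76, "strong"), (-0.02, "weak")],
    )
    def test_bands(self, value, band):
        assert sp.classify_differentiation(value) == band

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            sp.classify_differentiation(float("nan"))


class TestBrayCurtis:
    def _ncm(self, counts, samples=None):
        counts = np.asarray(counts)
        return sp.NucleotideCountMatrix(
            gene_ids=np.array(["g"] * counts.shape[0], dtype=object),
            positions=np.arange(counts.shape[0]),
            samples=samples or [f"s{i}" for i in range(counts.shape[1])],
            counts=counts,
        )

    def test_identical_profiles_distance_zero(self):
        ncm = self._ncm([[[3, 1, 0, 0], [3, 1, 0, 0]]])
        d = sp.bray_curtis_matrix(ncm)
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_hand_computed_raw_mode(self):
        # u=(1,2,3), v=(3,2,1) -> (2+0+2)/12 = 1/3
        ncm = self._ncm([[[1, 3, 0, 0], [2, 2, 0, 0]], [[3, 1, 0, 0], [0, 0, 0, 0]]])
        u = ncm.counts[:, 0, :].ravel()
        v = ncm.counts[:, 1, :].ravel()
        expected = np.abs(u - v).sum() / (u + v).sum()
        d = sp.bray_curtis_matrix(ncm, normalization="raw")
        assert d.matrix[0, 1] == pytest.approx(expected)
        simple = self._ncm([[[1, 2, 3, 0], [3, 2, 1, 0]]])
        assert sp.bray_curtis_matrix(simple, normalization="raw").matrix[0, 1] == pytest.approx(1 / 3)

    def test_disjoint_support_distance_one(self):
        ncm = self._ncm([[[5, 0, 0, 0], [0, 0, 5, 0]]])
        assert sp.bray_curtis_matrix(ncm).matrix[0, 1] == pytest.approx(1.0)

    def test_all_zero_sample_named_in_error(self):
        ncm = self._ncm([[[5, 0, 0, 0], [0, 0, 0, 0]]], samples=["ok", "empty"])
        with pytest.raises(ConfigurationError, match="empty"):
            sp.bray_curtis_matrix(ncm)

    def test_frequency_mode_removes_depth_artifacts(self):
        # same allele composition at 2x depth difference -> distance 0
        ncm = self._ncm([[[6, 2, 0, 0], [12, 4, 0, 0]]])
        assert sp.bray_curtis_matrix(ncm).matrix[0, 1] == pytest.approx(0.0)
        assert sp.bray_curtis_matrix(ncm, "raw").matrix[0, 1] > 0.3


class TestPCoA:
    def test_two_points_forced_geometry(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]), "test")
        res = sp.pcoa(d)
        coords = res.coordinates["PC1"].to_numpy()
        assert sorted(coords) == pytest.approx([-1.0, 1.0])

    def test_equilateral_triangle(self):
        m = np.ones((3, 3)) - np.eye(3)
        res = sp.pcoa(DistanceMatrix(["a", "b", "c"], m, "test"))
        pos = res.eigenvalues[res.eigenvalues > 1e-12]
        assert len(pos) == 2 and pos[0] == pytest.approx(pos[1])
        C = res.coordinates.to_numpy()
        for i in range(3):
            for j in range(i + 1, 3):
                assert np.linalg.norm(C[i] - C[j]) == pytest.approx(1.0)

    def test_euclidean_distances_reconstructed(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(6, 3))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        res = sp.pcoa(DistanceMatrix([f"p{i}" for i in range(6)], D, "euclid"))
        C = res.coordinates.to_numpy()
        D2 = np.linalg.norm(C[:, None] - C[None, :], axis=2)
        np.testing.assert_allclose(D2, D, atol=1e-9)

    def test_agrees_with_skbio_reference(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(7, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        mine = sp.pcoa(DistanceMatrix([f"p{i}" for i in range(7)], D, "euclid"))
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        k = mine.coordinates.shape[1]
        ref_eigs = np.asarray(ref.eigvals)[:k]
        np.testing.assert_allclose(
            mine.eigenvalues[:k], ref_eigs, rtol=1e-8, atol=1e-10
        )
        for ax in range(min(2, k)):
            a = mine.coordinates.iloc[:, ax].to_numpy()
            b = np.asarray(ref.samples.iloc[:, ax])
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_proportion_explained_uses_absolute_eigenvalue_mass(self):
        # triangle-inequality violation -> non-Euclidean, negative eigenvalue
        m = np.array([[0, 1, 2.2], [1, 0, 1], [2.2, 1, 0]], dtype=float)
        res = sp.pcoa(DistanceMatrix(list("abc"), m, "test"))
        assert (res.eigenvalues < -1e-9).any()
        assert res.proportion_explained.sum() <= 1.0 + 1e-12

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ConfigurationError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]), "bad")

    def test_n_axes_capped(self):
        d = DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]), "test")
        with pytest.raises(ConfigurationError):
            sp.pcoa(d, n_axes=5)


class TestVariantTableRoundTrip:
    def test_tsv_round_trip(self, tmp_path, variants_recovery):
        path = tmp_path / "v.tsv"
        variants_recovery.to_tsv(path)
        back = sp.VariantTable.from_tsv(path)
        assert back.samples == variants_recovery.samples
        np.testing.assert_array_equal(back.ref_counts, variants_recovery.ref_counts)
        np.testing.assert_array_equal(back.positions, variants_recovery.positions)
        # downstream results identical after the round trip
        a = bray_curtis_from_variants(variants_recovery).matrix
        b = bray_curtis_from_variants(back).matrix
        np.testing.assert_allclose(a, b)
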
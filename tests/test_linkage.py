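import math

import numpy as np
import pytest

from ataxmap.linkage import (
    DEFAULT_THETA_GRID,
    DiseaseModel,
    LodCurve,
    UnsupportedPedigreeError,
    _child_tensor,
    _haplotype_freqs,
    _transmission_tensor,
    linked_regions,
    lod_table,
    pedigree_log_likelihood,
    pedigree_log_likelihood_bruteforce,
    two_point_lod,
)
from ataxmap.pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    Individual,
    Pedigree,
)

from conftest import make_gm, make_mmap, nuclear_family, random_calls, random_loopfree_pedigree

RECESSIVE = DiseaseModel.fully_penetrant_recessive(0.1)


class TestModelValidation:
    def test_penetrance_bounds(self):
        with pytest.raises(ValueError):
            DiseaseModel((0.0, 0.0, 1.5), 0.1)

    def test_disease_freq_bounds(self):
        with pytest.raises(ValueError):
            DiseaseModel((0.0, 0.0, 1.0), 0.0)

    def test_recessive_preset(self):
        m = DiseaseModel.fully_penetrant_recessive(0.01)
        assert m.penetrances == (0.0, 0.0, 1.0)
        assert m.disease_allele_freq == 0.01


class TestTensors:
    def test_haplotype_freqs_sum_to_one(self):
        hf = _haplotype_freqs(0.2, 0.7)
        assert hf.sum() == pytest.approx(1.0)
        assert hf.shape == (4,)

    @pytest.mark.parametrize("theta", [0.0, 0.13, 0.5])
    def test_transmission_rows_normalized(self, theta):
        T = _transmission_tensor(theta)
        np.testing.assert_allclose(T.sum(axis=1), np.ones(16))

    def test_transmission_at_zero_theta_keeps_parental_haplotypes(self):
        T = _transmission_tensor(0.0)
        # ordered genotype 4 * hp + hm transmits hp or hm only
        for g in range(16):
            hp, hm = g // 4, g % 4
            support = set(np.flatnonzero(T[g] > 0))
            assert support <= {hp, hm}

    def test_child_tensor_normalized(self):
        T3 = _child_tensor(0.37)
        np.testing.assert_allclose(T3.sum(axis=2), np.ones((16, 16)))


class TestLikelihood:
    def test_single_founder_no_data_likelihood_one(self):
        ped = Pedigree([Individual("x", None, None, MALE)])
        assert pedigree_log_likelihood(ped, {}, 0.5, RECESSIVE, 0.1) == pytest.approx(0.0)

    def test_affected_founder_probability_q_squared(self):
        ped = Pedigree([Individual("x", None, None, MALE, AFFECTED)])
        logL = pedigree_log_likelihood(ped, {}, 0.5, RECESSIVE, 0.1)
        assert math.exp(logL) == pytest.approx(0.1**2)

    def test_marker_only_hardy_weinberg(self):
        ped = Pedigree([Individual("x", None, None, MALE)])
        # het call: 2 f (1 - f) with f the allele1 frequency
        logL = pedigree_log_likelihood(ped, {"x": 1}, 0.3, RECESSIVE, 0.1)
        assert math.exp(logL) == pytest.approx(2 * 0.3 * 0.7)

    def test_theta_and_freq_validation(self):
        ped = nuclear_family([AFFECTED])
        with pytest.raises(ValueError):
            pedigree_log_likelihood(ped, {}, 0.5, RECESSIVE, 0.6)
        with pytest.raises(ValueError):
            pedigree_log_likelihood(ped, {}, 1.0, RECESSIVE, 0.1)

    def test_looped_pedigree_rejected_by_peeling_handled_by_bruteforce(self):
        ped = Pedigree(
            [
                Individual("f", None, None, MALE),
                Individual("m", None, None, FEMALE),
                Individual("s", "f", "m", MALE),
                Individual("d", "f", "m", FEMALE),
                Individual("k", "s", "d", MALE, AFFECTED),
            ]
        )
        with pytest.raises(UnsupportedPedigreeError):
            pedigree_log_likelihood(ped, {}, 0.5, RECESSIVE, 0.1)
        logL = pedigree_log_likelihood_bruteforce(ped, {}, 0.5, RECESSIVE, 0.1)
        assert math.isfinite(logL)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            ped = random_loopfree_pedigree(rng)
            calls = random_calls(rng, ped)
            swapped = {i: (2 - c if c >= 0 else -1) for i, c in calls.items()}
            f = float(rng.uniform(0.1, 0.9))
            theta = float(rng.uniform(0, 0.5))
            a = pedigree_log_likelihood(ped, calls, f, RECESSIVE, theta)
            b = pedigree_log_likelihood(ped, swapped, 1 - f, RECESSIVE, theta)
            if math.isinf(a) and math.isinf(b):
                continue
            assert a == pytest.approx(b, abs=1e-10)

    def test_phase_symmetry_at_half(self):
        # at theta = 0.5 the disease locus decouples from the marker:
        # L factorizes into (disease-only) x (marker-only)
        ped = nuclear_family([AFFECTED, UNAFFECTED], (UNAFFECTED, UNAFFECTED))
        calls = {"sire": 1, "dam": 1, "kid1": 2, "kid2": 0}
        both = pedigree_log_likelihood(ped, calls, 0.4, RECESSIVE, 0.5)
        marker_only = pedigree_log_likelihood(
            Pedigree(
                [
                    Individual("sire", None, None, MALE),
                    Individual("dam", None, None, FEMALE),
                    Individual("kid1", "sire", "dam", FEMALE),
                    Individual("kid2", "sire", "dam", MALE),
                ]
            ),
            calls,
            0.4,
            RECESSIVE,
            0.5,
        )
        disease_only = pedigree_log_likelihood(ped, {}, 0.4, RECESSIVE, 0.5)
        assert both == pytest.approx(marker_only + disease_only)


class TestTwoPointLod:
    def _family_gm(self):
        ped = nuclear_family([AFFECTED, AFFECTED, UNAFFECTED])
        ids = ["sire", "dam", "kid1", "kid2", "kid3"]
        # marker 1 cosegregates perfectly; marker 2 is uninformative
        calls = [
            [1, 0],
            [1, 0],
            [2, 0],
            [2, 0],
            [0, 0],
        ]
        return ped, make_gm(ids, {"chr1": [1_000_000, 2_000_000]}, calls)

    def test_lod_at_half_is_exactly_zero(self):
        ped, gm = self._family_gm()
        curves, flagged = two_point_lod(ped, gm, RECESSIVE)
        assert flagged == []
        for c in curves.values():
            assert c.lods[-1] == 0.0
            assert c.thetas[-1] == 0.5

    def test_cosegregating_marker_has_positive_lod_at_zero(self):
        ped, gm = self._family_gm()
        curves, _ = two_point_lod(ped, gm, RECESSIVE)
        assert curves["chr1_m1"].lods[0] > 0.5
        assert curves["chr1_m1"].best_theta == 0.0

    def test_peeling_against_bruteforce_inside_scan(self):
        ped, gm = self._family_gm()
        curves, _ = two_point_lod(ped, gm, RECESSIVE)
        # recompute marker 1 LOD at theta = 0 with the brute-force evaluator
        freq = 0.5  # two founders, one het each -> allele1 freq 0.5... checked below
        calls = {i: int(gm.row(i)[0]) for i in gm.individual_ids}
        lo = pedigree_log_likelihood_bruteforce(ped, calls, freq, RECESSIVE, 0.0)
        hi = pedigree_log_likelihood_bruteforce(ped, calls, freq, RECESSIVE, 0.5)
        assert curves["chr1_m1"].lods[0] == pytest.approx((lo - hi) / math.log(10))

    def test_mendelian_inconsistent_marker_flagged_and_skipped(self):
        ped = nuclear_family([AFFECTED])
        gm = make_gm(
            ["sire", "dam", "kid1"], {"chr1": [100, 200]}, [[0, 1], [0, 1], [2, 2]]
        )
        curves, flagged = two_point_lod(ped, gm, RECESSIVE)
        assert flagged == ["chr1_m1"]
        assert set(curves) == {"chr1_m2"}

    def test_looped_pedigree_rejected(self):
        from ataxmap.simulate import template_pedigree

        ped, _, _ = template_pedigree(2)
        gm = make_gm(ped.ids, {"chr1": [100]}, [[0]] * len(ped.ids))
        with pytest.raises(UnsupportedPedigreeError):
            two_point_lod(ped, gm, RECESSIVE)

    def test_monomorphic_marker_is_neutral_not_crashing(self):
        ped = nuclear_family([AFFECTED])
        gm = make_gm(["sire", "dam", "kid1"], {"chr1": [100]}, [[0], [0], [0]])
        curves, flagged = two_point_lod(ped, gm, RECESSIVE)
        assert flagged == []
        assert curves["chr1_m1"].max_lod == pytest.approx(0.0, abs=1e-6)


class TestLinkedRegions:
    def _mmap(self, n, chrom="chr1"):
        return make_mmap({chrom: [1000 * (k + 1) for k in range(n)]})

    def test_anti_linked_marker_splits_runs(self):
        mmap = self._mmap(5)
        curves = {
            "chr1_m1": LodCurve("chr1_m1", np.array([0.0, 0.5]), np.array([1.0, 0.0])),
            "chr1_m2": LodCurve("chr1_m2", np.array([0.0, 0.5]), np.array([0.0, 0.0])),
            "chr1_m3": LodCurve("chr1_m3", np.array([0.0, 0.5]), np.array([-2.0, 0.0])),
            "chr1_m4": LodCurve("chr1_m4", np.array([0.0, 0.5]), np.array([0.5, 0.0])),
            "chr1_m5": LodCurve("chr1_m5", np.array([0.0, 0.5]), np.array([0.2, 0.0])),
        }
        regions = linked_regions(curves, mmap)
        assert len(regions) == 2
        assert (regions[0].interval.start, regions[0].interval.end) == (1000, 1000)
        assert (regions[1].interval.start, regions[1].interval.end) == (4000, 5000)
        assert regions[1].peak_lod == pytest.approx(0.5)
        assert regions[1].marker_ids == ["chr1_m4", "chr1_m5"]

    def test_uninformative_markers_do_not_split_but_do_not_extend(self):
        mmap = self._mmap(3)
        curves = {
            "chr1_m1": LodCurve("chr1_m1", np.array([0.0, 0.5]), np.array([0.8, 0.0])),
            "chr1_m2": LodCurve("chr1_m2", np.array([0.0, 0.5]), np.array([0.0, 0.0])),
            "chr1_m3": LodCurve("chr1_m3", np.array([0.0, 0.5]), np.array([0.9, 0.0])),
        }
        regions = linked_regions(curves, mmap)
        assert len(regions) == 1
        assert (regions[0].interval.start, regions[0].interval.end) == (1000, 3000)

    def test_all_uninformative_yields_no_region(self):
        mmap = self._mmap(3)
        curves = {
            f"chr1_m{k}": LodCurve(
                f"chr1_m{k}", np.array([0.0, 0.5]), np.array([0.0, 0.0])
            )
            for k in (1, 2, 3)
        }
        assert linked_regions(curves, mmap) == []

    def test_chromosomes_are_independent(self):
        mmap = make_mmap({"chr1": [1000], "chr2": [1000]})
        curves = {
            "chr1_m1": LodCurve("chr1_m1", np.array([0.0, 0.5]), np.array([1.0, 0.0])),
            "chr2_m1": LodCurve("chr2_m1", np.array([0.0, 0.5]), np.array([1.0, 0.0])),
        }
        regions = linked_regions(curves, mmap)
        assert [r.interval.chrom for r in regions] == ["chr1", "chr2"]


class TestLodTable:
    def test_columns_and_rows(self):
        ped = nuclear_family([AFFECTED])
        gm = make_gm(["sire", "dam", "kid1"], {"chr1": [100]}, [[1], [1], [2]])
        curves, _ = two_point_lod(ped, gm, RECESSIVE)
        table = lod_table(curves, gm.marker_map)
        assert table.shape[0] == 1
        assert {"marker", "chrom", "pos", "max_lod"} <= set(table.columns)
        for t in DEFAULT_THETA_GRID:
            assert f"lod_{t:g}" in table.columns
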
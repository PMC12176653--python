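"""Generators: determinism, geometric bookkeeping, statistical marginals."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphomap.archetypes import (
    DEFAULT_ARCHETYPES, MURINE_FAMILIES, PhenotypeArchetype, jitter_archetype,
)
from morphomap.synth import (
    CanvasError, generate_cohort, generate_count_matrix, generate_dose_response,
    generate_limiting_dilution, generate_organoid_image,
)
from morphomap.synth.dose import default_concentrations


class TestOrganoidImages:
    def test_clump_disk_geometry(self):
        """A 50 µm-radius clump at 1 µm/px is a plain disk: no branches,
        major axis equal to the diameter, core area pi r^2."""
        arch = PhenotypeArchetype(name="clump", core_radius_um=50)
        img, gt = generate_organoid_image(
            arch, canvas_px=(200, 200), pixel_size_um=1.0, seed=0)
        assert gt.n_main_branches == 0 and gt.n_nodes == 0 and gt.n_endpoints == 0
        assert gt.major_axis_um == pytest.approx(100.0)
        assert gt.core_area_um2 == pytest.approx(math.pi * 50**2)

    def test_tebbo_bud_bookkeeping(self):
        arch = DEFAULT_ARCHETYPES["TEBBO"]
        img, gt = generate_organoid_image(arch, seed=1)
        assert gt.n_terminal_end_buds == arch.n_terminal_end_buds == 5

    @pytest.mark.parametrize("name", MURINE_FAMILIES + ("scattered",))
    def test_deterministic_for_fixed_seed(self, name):
        a = DEFAULT_ARCHETYPES[name]
        img1, gt1 = generate_organoid_image(a, seed=7, noise_level=0.02)
        img2, gt2 = generate_organoid_image(a, seed=7, noise_level=0.02)
        assert np.array_equal(img1, img2)
        assert gt1 == gt2

    def test_geometry_exceeding_canvas_raises(self):
        arch = PhenotypeArchetype(name="clump", core_radius_um=600)
        with pytest.raises(CanvasError):
            generate_organoid_image(arch, canvas_px=(400, 400), pixel_size_um=1.0)

    def test_ground_truth_invariants(self):
        for name in MURINE_FAMILIES:
            _, gt = generate_organoid_image(DEFAULT_ARCHETYPES[name], seed=2)
            assert gt.major_axis_um >= gt.core_thickness_um
            assert min(gt.n_nodes, gt.n_endpoints, gt.n_lumens,
                       gt.n_terminal_end_buds, gt.n_spiky_branches) >= 0

    def test_scattered_disconnected(self):
        _, gt = generate_organoid_image(DEFAULT_ARCHETYPES["scattered"], seed=4)
        assert gt.n_components >= 2


class TestCohort:
    def test_zero_jitter_identical_geometry(self):
        cohort = generate_cohort({"clump": 3}, jitter=0.0, seed=0)
        majors = {round(t.major_axis_um, 6) for t in cohort.truths}
        assert len(majors) == 1
        seeds = {t.seed for t in cohort.truths}
        assert len(seeds) == 3  # distinct per-organoid seeds

    def test_label_histogram_matches_spec(self):
        spec = {f: 5 for f in MURINE_FAMILIES}
        cohort = generate_cohort(spec, jitter=0.15, seed=1)
        assert len(cohort) == 40
        counts = pd.Series(cohort.labels).value_counts().to_dict()
        assert counts == spec

    def test_manifest_deterministic(self, tmp_path):
        a = generate_cohort({"clump": 2, "firework": 2}, jitter=0.1, seed=9,
                            out_dir=tmp_path / "a")
        b = generate_cohort({"clump": 2, "firework": 2}, jitter=0.1, seed=9,
                            out_dir=tmp_path / "b")
        pd.testing.assert_frame_equal(a.manifest, b.manifest)
        assert (tmp_path / "a" / "manifest.csv").exists()

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort({}, seed=0)


class TestLimitingDilution:
    def test_saturating_frequency(self):
        t = generate_limiting_dilution(1.0, doses=(20,), wells_per_dose=24, seed=0)
        assert t.n_responding == (24,)  # P(respond) = 1 - e^-20 ~ 1

    def test_paper_design_invariants(self):
        t = generate_limiting_dilution(1 / 3, doses=(20, 10, 3, 1),
                                       wells_per_dose=8, seed=1)
        assert t.dose_cells == (20, 10, 3, 1)
        assert all(0 <= r <= 8 for r in t.n_responding)

    def test_binomial_marginal(self):
        """Responding fraction at dose 1, f=0.5 within 3 binomial sd of
        1 - e^-0.5 (oracle: exact binomial moments)."""
        n = 100_000
        t = generate_limiting_dilution(0.5, doses=(1,), wells_per_dose=n, seed=2)
        p = 1 - math.exp(-0.5)
        sd = math.sqrt(p * (1 - p) / n)
        assert abs(t.n_responding[0] / n - p) < 3 * sd

    def test_mean_over_replicates_matches_single_hit(self):
        """Mean responding fraction over 200 seeded replicates within 3 sd
        of 1 - exp(-f d) at every dose."""
        f, doses, w = 1 / 3, (20, 10, 3, 1), 8
        resp = np.array([
            generate_limiting_dilution(f, doses, w, seed=s).n_responding
            for s in range(200)
        ], float) / w
        p = 1 - np.exp(-f * np.array(doses))
        sd = np.sqrt(p * (1 - p) / (w * 200))
        assert np.all(np.abs(resp.mean(0) - p) < 3 * sd)

    def test_frequency_domain(self):
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                generate_limiting_dilution(bad, seed=0)


class TestCountMatrix:
    def test_null_has_no_expected_difference(self):
        ct = generate_count_matrix(n_genes=500, log2fc=0.0, seed=0)
        # planted genes are recorded but carry no shift: group means agree
        # within sampling noise for a large random subset
        counts = ct.counts.to_numpy(float) / ct.library_size_factors.to_numpy()
        ya = counts[:, (ct.phenotype_labels == "A").to_numpy()].mean(1)
        yr = counts[:, (ct.phenotype_labels != "A").to_numpy()].mean(1)
        ratio = np.log2((ya.mean() + 1) / (yr.mean() + 1))
        assert abs(ratio) < 0.1

    def test_poisson_limit(self):
        """With dispersion 0, per-gene variance tracks the mean (Poisson
        oracle): the median variance/mean ratio over many genes is ~1."""
        ct = generate_count_matrix(
            n_genes=2000, phenotypes=("A",), replicates=60,
            planted_per_phenotype=0, dispersion=0.0,
            depth_range=(1.0, 1.0), seed=1)
        X = ct.counts.to_numpy(float)
        m = X.mean(1)
        v = X.var(1, ddof=1)
        keep = m > 5
        ratio = np.median(v[keep] / m[keep])
        assert 0.9 < ratio < 1.1

    def test_nb_variance_matches_dispersion(self):
        alpha = 0.2
        ct = generate_count_matrix(
            n_genes=3000, phenotypes=("A",), replicates=50,
            planted_per_phenotype=0, dispersion=alpha,
            depth_range=(1.0, 1.0), seed=2)
        X = ct.counts.to_numpy(float)
        m = X.mean(1)
        v = X.var(1, ddof=1)
        keep = m > 20
        # var = m + alpha m^2  =>  (v - m)/m^2 ~ alpha
        est = np.median((v[keep] - m[keep]) / m[keep] ** 2)
        assert abs(est - alpha) < 0.05

    def test_planted_sets_disjoint(self):
        ct = generate_count_matrix(n_genes=400, planted_per_phenotype=30, seed=3)
        sets = [set(v) for v in ct.planted_genes.values()]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                assert not sets[i] & sets[j]

    def test_too_many_planted_rejected(self):
        with pytest.raises(ValueError):
            generate_count_matrix(n_genes=100, planted_per_phenotype=40, seed=0)


class TestDoseResponse:
    def test_midpoint(self):
        gi50 = 0.37
        c = default_concentrations()
        curve = generate_dose_response(gi50, hill=1.2, floor=0.2,
                                       concentrations=(gi50,) + c[3:], seed=0)
        assert curve.viability[0] == pytest.approx(0.2 + 0.8 / 2)

    def test_limit_at_zero_concentration(self):
        curve = generate_dose_response(1.0, concentrations=(1e-8, 1.0, 10.0))
        assert curve.viability[0] == pytest.approx(1.0, abs=1e-6)

    def test_hill1_closed_form(self):
        gi50 = 1.1
        curve = generate_dose_response(gi50, hill=1.0, floor=0.0, noise_sd=0.0)
        c = np.array(curve.concentrations)
        assert np.allclose(curve.viability, 1.0 / (1.0 + c / gi50))

    def test_seeded_noise_deterministic(self):
        a = generate_dose_response(1.0, noise_sd=0.1, seed=5)
        b = generate_dose_response(1.0, noise_sd=0.1, seed=5)
        assert a.viability == b.viability


def test_jitter_respects_family_floors():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = jitter_archetype(DEFAULT_ARCHETYPES["star_like"], 0.3, rng)
        assert a.n_main_branches >= 3
        t = jitter_archetype(DEFAULT_ARCHETYPES["TEBBO"], 0.3, rng)
        assert t.n_terminal_end_buds >= 1
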
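import numpy as np
import pytest

from brainmech.prony import (
    ModulusSample,
    PronyMaterial,
    SAS_MATERIAL,
    fit_prony,
    load_exvivo_curve,
    prony_moduli,
    region_materials,
    scale_exvivo,
)


def _complex_oracle(mat: PronyMaterial, f: float):
    """Independent route: complex modulus G*(w) = Ginf + sum G0 g (i w tau)/(1 + i w tau)."""
    w = 2 * np.pi * f
    gstar = complex(mat.Ginf_pa, 0.0)
    for g, tau in mat.terms:
        gstar += mat.G0_pa * g * (1j * w * tau) / (1 + 1j * w * tau)
    return gstar.real, gstar.imag


class TestMaterialInvariants:
    def test_ginf_identity(self):
        m = PronyMaterial(G0_pa=500.0, terms=((0.8, 0.0125),))
        np.testing.assert_allclose(m.Ginf_pa, 100.0, rtol=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(G0_pa=-1.0),
            dict(G0_pa=1.0, terms=((-0.1, 0.01),)),
            dict(G0_pa=1.0, terms=((0.6, 0.01), (0.6, 0.02))),
            dict(G0_pa=1.0, terms=((0.5, 0.0),)),
            dict(G0_pa=1.0, terms=((0.1, 0.01),) * 4),
        ],
    )
    def test_invalid_materials_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PronyMaterial(**kwargs)


class TestForwardModel:
    def test_zero_frequency_limit(self):
        m = PronyMaterial(G0_pa=2000.0, terms=((0.4, 0.01), (0.3, 0.1)))
        gp, gpp = prony_moduli(m, 0.0)
        np.testing.assert_allclose(gp, m.Ginf_pa, rtol=1e-12)
        assert gpp == 0.0

    def test_sas_card_at_50hz(self):
        """The subarachnoid-space card (G0=0.5 kPa, g1=0.8, tau1=12.5 ms)
        evaluated at 50 Hz, checked against the complex-arithmetic oracle."""
        gp, gpp = prony_moduli(SAS_MATERIAL, 50.0)
        ogp, ogpp = _complex_oracle(SAS_MATERIAL, 50.0)
        np.testing.assert_allclose([gp, gpp], [ogp, ogpp], rtol=1e-12)
        np.testing.assert_allclose(gp, 475.641, rtol=1e-5)
        np.testing.assert_allclose(gpp, 95.656, rtol=1e-5)

    def test_elastic_degenerate_material(self):
        m = PronyMaterial(G0_pa=750.0, terms=())
        for f in (0.0, 10.0, 1e4):
            gp, gpp = prony_moduli(m, f)
            assert gp == 750.0 and gpp == 0.0
        assert m.Ginf_pa == m.G0_pa

    def test_frequency_sweep_limits(self):
        m = PronyMaterial(G0_pa=4000.0, terms=((0.3, 0.02), (0.4, 0.001)))
        f = np.logspace(-3, 6, 200)
        gp, gpp = prony_moduli(m, f)
        assert np.all(np.diff(gp) >= -1e-9)            # monotone storage
        assert gp[0] == pytest.approx(m.Ginf_pa, rel=1e-4)
        assert gp[-1] == pytest.approx(m.G0_pa, rel=1e-4)
        assert gpp[0] < 1e-3 * gp[0] and gpp[-1] < 1e-3 * gp[-1]  # loss vanishes at both ends
        assert np.all(gpp >= 0)


class TestScaleExvivo:
    def _curve(self, mat, c=1.0):
        # includes the in-band sample frequencies so interpolation is exact there
        f = np.array([0.1, 1.0, 10.0, 30.0, 50.0, 70.0, 200.0, 1000.0])
        gp, gpp = prony_moduli(mat, f)
        return [ModulusSample(fi, c * a, c * b, source="exvivo") for fi, a, b in zip(f, gp, gpp)]

    def test_exact_proportionality(self):
        mat = PronyMaterial(G0_pa=2000.0, terms=((0.5, 0.01),))
        invivo = [ModulusSample(f, *prony_moduli(mat, f)) for f in (30.0, 50.0, 70.0)]
        _, c = scale_exvivo(self._curve(mat, 0.5), invivo)
        np.testing.assert_allclose(c, 2.0, rtol=1e-9)
        _, c1 = scale_exvivo(self._curve(mat, 1.0), invivo)
        np.testing.assert_allclose(c1, 1.0, rtol=1e-9)

    def test_matches_grid_search_oracle(self):
        mat = PronyMaterial(G0_pa=2000.0, terms=((0.5, 0.01),))
        rng = np.random.default_rng(8)
        invivo = [
            ModulusSample(f, gp * (1 + e1), gpp * (1 + e2))
            for f, (gp, gpp), e1, e2 in (
                (f, prony_moduli(mat, f), rng.normal(0, 0.05), rng.normal(0, 0.05))
                for f in (30.0, 50.0, 70.0)
            )
        ]
        ex = self._curve(mat, 1 / 1.5)
        scaled, c = scale_exvivo(ex, invivo)

        # dense 1-D grid search over the stated objective
        from brainmech.prony import _interp_exvivo

        fs = np.array([s.frequency_hz for s in invivo])
        egp, egpp = _interp_exvivo(ex, fs)
        grid = np.linspace(0.5 * c, 2.0 * c, 2_000_001)
        v = np.array([s.gprime_pa for s in invivo] + [s.gdoubleprime_pa for s in invivo])
        e = np.concatenate([egp, egpp])
        obj = (((grid[:, None] * e[None, :]) - v) / v) ** 2
        c_star = grid[np.argmin(obj.sum(axis=1))]
        np.testing.assert_allclose(c, c_star, atol=1e-6 * c)
        assert scaled[0].gprime_pa == pytest.approx(c * ex[0].gprime_pa)

    def test_band_coverage_required(self):
        mat = PronyMaterial(G0_pa=2000.0, terms=((0.5, 0.01),))
        ex = [ModulusSample(f, *prony_moduli(mat, f), source="exvivo") for f in (1.0, 10.0)]
        invivo = [ModulusSample(50.0, *prony_moduli(mat, 50.0))]
        with pytest.raises(ValueError, match="cover"):
            scale_exvivo(ex, invivo)


class TestFitProny:
    FREQS = np.logspace(0, np.log10(200), 8)

    def _samples(self, mat):
        gp, gpp = prony_moduli(mat, self.FREQS)
        return [ModulusSample(f, a, b) for f, a, b in zip(self.FREQS, gp, gpp)]

    def test_one_term_recovery(self):
        true = PronyMaterial(G0_pa=2000.0, terms=((0.6, 0.02),))
        fit, res = fit_prony(self._samples(true), n_terms_max=3)
        assert abs(fit.G0_pa - 2000.0) / 2000.0 < 0.01
        (g, tau) = fit.terms[0] if len(fit.terms) == 1 else max(fit.terms)
        assert abs(fit.g_sum - 0.6) < 0.01 * 0.6
        assert res < 1e-6

    def test_two_term_ground_truth_residual(self):
        true = PronyMaterial(G0_pa=5000.0, terms=((0.35, 0.05), (0.35, 0.003)))
        fit, res = fit_prony(self._samples(true), n_terms_max=3)
        assert res <= 1e-6  # ground truth is feasible
        np.testing.assert_allclose(fit.G0_pa, 5000.0, rtol=1e-3)

    def test_elastic_data_recovers_elastic_material(self):
        samples = [ModulusSample(f, 1500.0, 0.0) for f in self.FREQS]
        fit, _ = fit_prony(samples)
        assert fit.g_sum < 1e-3
        np.testing.assert_allclose(fit.G0_pa, 1500.0, rtol=1e-3)
        np.testing.assert_allclose(fit.Ginf_pa, 1500.0, rtol=2e-3)

    def test_fit_satisfies_invariants(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            true = PronyMaterial(
                G0_pa=float(rng.uniform(500, 8000)),
                terms=((float(rng.uniform(0.1, 0.6)), float(rng.uniform(0.002, 0.1))),),
            )
            gp, gpp = prony_moduli(true, self.FREQS)
            noisy = [
                ModulusSample(f, a * (1 + rng.normal(0, 0.02)), max(b * (1 + rng.normal(0, 0.02)), 0.0))
                for f, a, b in zip(self.FREQS, gp, gpp)
            ]
            fit, _ = fit_prony(noisy)
            # constructor re-validates every invariant
            PronyMaterial(G0_pa=fit.G0_pa, terms=fit.terms)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_prony([ModulusSample(10.0, 100.0, 10.0)] * 2)


class TestRegionMaterials:
    def test_uniform_phantom_recovers_material(self, subject, merged_labels):
        from brainmech import group_average_maps, make_modulus_maps
        from brainmech.phantom import REGION_NAMES

        true = PronyMaterial(G0_pa=3000.0, terms=((0.5, 0.01),))
        maps = make_modulus_maps(subject.labels, {r: true for r in REGION_NAMES})
        freq_maps = {
            m.frequency_hz: (
                group_average_maps([m.storage], [m.valid]),
                group_average_maps([m.loss], [m.valid]),
            )
            for m in maps
        }
        mats = region_materials(freq_maps, merged_labels, exvivo=None, region_ids=range(1, 7))
        for rid, mat in mats.items():
            assert abs(mat.G0_pa - 3000.0) / 3000.0 < 0.02, rid

    def test_absent_region_named_in_error(self, merged_labels):
        with pytest.raises(ValueError, match="99"):
            region_materials({}, merged_labels, region_ids=[99])


def test_packaged_exvivo_curve_loads():
    curve = load_exvivo_curve()
    freqs = [s.frequency_hz for s in curve]
    assert min(freqs) <= 30.0 and max(freqs) >= 70.0
    assert all(s.gprime_pa > 0 and s.gdoubleprime_pa >= 0 for s in curve)
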
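"""Co-refinement: objective construction, recovery, credible intervals."""

import numpy as np
import pytest

from nrpore.inference import (
    ContrastDataset,
    chi_squared,
    corefine,
    credible_interval,
    model_reflectivity,
    scale_ratio_fit,
)
from nrpore.materials import D2O, SolventContrast
from nrpore.synthetic import generate_contrast_set


@pytest.fixture(scope="module")
def before_model(catalog):
    return catalog["10CL_before"]


class TestContrastDataset:
    def test_rejects_nonmonotone_q(self):
        with pytest.raises(ValueError):
            ContrastDataset(
                q=[0.1, 0.05], r=[1, 1], dr=[0.1, 0.1], contrast=D2O
            )

    def test_rejects_nonpositive_errors(self):
        with pytest.raises(ValueError):
            ContrastDataset(q=[0.05, 0.1], r=[1, 1], dr=[0.1, 0.0], contrast=D2O)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            ContrastDataset(q=[0.05, 0.1], r=[1.0], dr=[0.1], contrast=D2O)


class TestChiSquared:
    def test_zero_on_noiseless_self_data(self, before_model):
        ds = generate_contrast_set(before_model, noise=(0.0, 0.0), seed=0)
        for d in ds:
            d.dr = np.full(len(d), 0.01)
        assert chi_squared(before_model, ds) == pytest.approx(0.0, abs=1e-16)

    def test_one_sigma_offsets_give_chi2_equal_n(self, before_model):
        ds = generate_contrast_set(before_model, noise=(0.0, 0.0), seed=0)
        shifted = []
        for d in ds:
            dr = 0.05 * np.abs(d.r) + 1e-9
            shifted.append(
                ContrastDataset(
                    q=d.q, r=d.r + dr, dr=dr, dq=d.dq,
                    contrast=d.contrast, protein_isotope=d.protein_isotope,
                )
            )
        n = sum(len(d) for d in shifted)
        assert chi_squared(before_model, shifted) == pytest.approx(n, rel=1e-9)

    def test_matches_hand_sum_on_five_points(self, before_model):
        ds = generate_contrast_set(
            before_model, contrasts=(D2O,), n_q=5, noise=(0.05, 1e-8), seed=3
        )[0]
        rm = model_reflectivity(before_model, ds)
        by_hand = sum(((rm[i] - ds.r[i]) / ds.dr[i]) ** 2 for i in range(5))
        assert chi_squared(before_model, [ds]) == pytest.approx(by_hand, rel=1e-12)


class TestCredibleInterval:
    def test_degenerate_chain(self):
        lo, hi = credible_interval(np.full(100, 3.7))
        assert lo == hi == 3.7

    def test_standard_normal_quantiles(self):
        rng = np.random.default_rng(7)
        chain = rng.standard_normal(1_000_000)
        lo, hi = credible_interval(chain, level=0.65)
        # z_{0.825} = 0.9346
        assert lo == pytest.approx(-0.9346, abs=5e-3)
        assert hi == pytest.approx(+0.9346, abs=5e-3)

    def test_level_one_clips_to_extrema(self):
        chain = np.array([1.0, 2.0, 5.0])
        assert credible_interval(chain, level=1.0) == (1.0, 5.0)

    def test_rejects_bad_level(self):
        with pytest.raises(ValueError):
            credible_interval(np.arange(10.0), level=1.5)


class TestCorefine:
    FREE = {"tails.thickness": (20.0, 40.0), "tails.frac.lipid_tail": (0.5, 1.0)}

    def test_recovers_generator_values_on_low_noise_data(self, before_model):
        ds = generate_contrast_set(before_model, noise=(0.001, 1e-9), seed=1)
        res = corefine(
            before_model, ds, self.FREE, seed=2, n_steps=250, de_maxiter=25
        )
        assert res.best_params["tails.thickness"] == pytest.approx(29.8, rel=5e-3)
        assert res.best_params["tails.frac.lipid_tail"] == pytest.approx(0.98, rel=5e-3)
        assert res.chi2 <= chi_squared(before_model, ds) * 1.5
        assert not res.flat_posterior

    def test_single_contrast_fit_has_wider_intervals(self, before_model):
        """Contrast variation is information: dropping to one curve must
        widen the posterior on tail coverage."""
        ds3 = generate_contrast_set(before_model, seed=4)
        h2o_only = [d for d in ds3 if d.contrast.name == "H2O"]
        kw = dict(seed=5, n_steps=250, de_maxiter=20)
        res3 = corefine(before_model, ds3, self.FREE, **kw)
        res1 = corefine(before_model, h2o_only, self.FREE, **kw)
        width = lambda r, p: r.ci65[p][1] - r.ci65[p][0]
        assert width(res1, "tails.frac.lipid_tail") > width(
            res3, "tails.frac.lipid_tail"
        )

    def test_invariant_to_dataset_order(self, before_model):
        ds = generate_contrast_set(before_model, seed=6)
        kw = dict(seed=7, n_steps=60, de_maxiter=10)
        res_a = corefine(before_model, ds, self.FREE, **kw)
        res_b = corefine(before_model, ds[::-1], self.FREE, **kw)
        assert res_a.best_params == res_b.best_params

    def test_requires_datasets(self, before_model):
        with pytest.raises(ValueError):
            corefine(before_model, [], self.FREE, seed=0)


@pytest.fixture(scope="module")
def endpoints(catalog):
    return catalog["10CL_before"], catalog["10CL_after"]


class TestScaleRatioFit:
    @pytest.mark.parametrize("alpha_true", [0.0, 1.0, 0.5])
    def test_recovers_mixing_coefficient(self, endpoints, alpha_true):
        from nrpore.inference import _blend_models, align_topology

        before, after = endpoints
        truth = _blend_models(align_topology(before, after), after, alpha_true)
        ds = generate_contrast_set(truth, contrasts=(D2O,), seed=8)[0]
        res = scale_ratio_fit(before, after, ds, seed=9, n_steps=300)
        assert res.best_params["alpha"] == pytest.approx(alpha_true, abs=0.03)

    def test_topology_mismatch_raises(self, endpoints):
        before, after = endpoints
        broken = after.copy()
        broken.layers = broken.layers[:-1]
        ds = generate_contrast_set(after, contrasts=(D2O,), seed=8)[0]
        with pytest.raises(ValueError):
            scale_ratio_fit(broken, after, ds, seed=0, n_steps=50)
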
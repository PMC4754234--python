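import numpy as np
import pytest

from cada.errors import EmptySegmentationError, SampleSizeError
from cada.segmentation import (GmmModel, fit_gmm_em, gmm_density,
                               label_voxels, segment_striata)
from cada.volume_io import Volume


def two_gaussian_sample(rng, n=5000, sep=10.0):
    """Two well-separated 4-D Gaussians (unit variance, sep in sigma)."""
    mu1 = np.zeros(4)
    mu2 = np.full(4, sep / 2.0)
    n1 = int(0.4 * n)
    x = np.vstack([rng.normal(mu1, 1.0, size=(n1, 4)),
                   rng.normal(mu2, 1.0, size=(n - n1, 4))])
    return x, mu1, mu2, 0.4


class TestDensity:
    def test_closed_form_at_mean(self):
        """For a single unit-covariance component, density at the mean is
        (2*pi)^(-d/2) with d = 4."""
        m = GmmModel([1.0], np.zeros((1, 4)), np.eye(4)[None])
        assert gmm_density(np.zeros(4), m)[0] == pytest.approx(
            (2 * np.pi) ** -2, rel=1e-12)

    def test_integrates_to_one(self):
        """Numeric quadrature over a compact support capturing >0.999 mass."""
        cov = np.diag([0.5, 1.0, 0.8, 1.2])
        m = GmmModel([1.0], np.zeros((1, 4)), cov[None])
        g = np.linspace(-4.5, 4.5, 25)
        step = g[1] - g[0]
        pts = np.stack(np.meshgrid(*(g * np.sqrt(np.diag(cov))[i]
                                     for i in range(4)), indexing="ij"),
                       axis=-1).reshape(-1, 4)
        # integrate with per-axis step scaled like the grid
        vol_el = np.prod(step * np.sqrt(np.diag(cov)))
        total = gmm_density(pts, m).sum() * vol_el
        assert total == pytest.approx(1.0, abs=5e-3)

    def test_duplicate_components_equal_single(self, rng):
        x = rng.normal(size=(50, 4))
        single = GmmModel([1.0], np.zeros((1, 4)), np.eye(4)[None])
        double = GmmModel([0.5, 0.5], np.zeros((2, 4)),
                          np.stack([np.eye(4)] * 2))
        assert np.allclose(gmm_density(x, single), gmm_density(x, double))


class TestEM:
    def test_parameter_recovery(self, rng):
        x, mu1, mu2, w1 = two_gaussian_sample(rng)
        model = fit_gmm_em(x, M=2, seed=0)
        order = np.argsort(model.means[:, 0])
        assert np.linalg.norm(model.means[order[0]] - mu1) < 0.2
        assert np.linalg.norm(model.means[order[1]] - mu2) < 0.2
        assert model.weights[order[0]] == pytest.approx(w1, abs=0.05)

    def test_loglik_monotone(self, rng):
        x, *_ = two_gaussian_sample(rng, n=2000, sep=3.0)
        model = fit_gmm_em(x, M=2, seed=3)
        diffs = np.diff(model.loglik_history)
        assert np.all(diffs >= -1e-7 * np.abs(model.loglik_history[0]))

    def test_weights_sum_to_one(self, rng):
        x, *_ = two_gaussian_sample(rng, n=1500)
        model = fit_gmm_em(x, M=2, seed=5)
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sample_size_guard(self, rng):
        with pytest.raises(SampleSizeError):
            fit_gmm_em(rng.normal(size=(30, 4)), M=2, seed=0)

    def test_determinism(self, rng):
        x, *_ = two_gaussian_sample(rng)
        a = fit_gmm_em(x, M=2, seed=42)
        b = fit_gmm_em(x, M=2, seed=42)
        assert np.array_equal(a.means, b.means)
        assert np.array_equal(a.weights, b.weights)


class TestLabeling:
    def brute_force_labels(self, x, model):
        """Exhaustive per-voxel evaluation of the normalized component
        likelihood (the printed labeling rule)."""
        out = []
        for xi in np.atleast_2d(x):
            scores = []
            for i in range(model.n_components):
                d = xi - model.means[i]
                S = model.covariances[i]
                maha = d @ np.linalg.inv(S) @ d
                scores.append(np.exp(-0.5 * maha) / np.sqrt(np.linalg.det(S)))
            out.append(int(np.argmax(scores)))
        return np.array(out)

    def test_matches_brute_force(self, rng):
        x, *_ = two_gaussian_sample(rng, n=800, sep=4.0)
        model = fit_gmm_em(x, M=2, seed=1)
        assert np.array_equal(label_voxels(x, model),
                              self.brute_force_labels(x, model))

    def test_tie_breaks_to_lower_index(self):
        model = GmmModel([0.5, 0.5], np.array([[-1.0, 0, 0, 0],
                                               [1.0, 0, 0, 0]]),
                         np.stack([np.eye(4)] * 2))
        assert label_voxels(np.zeros((1, 4)), model)[0] == 0

    def test_label_at_component_mean(self):
        model = GmmModel([0.5, 0.5], np.array([[0.0, 0, 0, 0],
                                               [10.0, 10, 10, 10]]),
                         np.stack([np.eye(4)] * 2))
        assert label_voxels(model.means[1][None], model)[0] == 1

    def test_affine_rescaling_invariance(self, rng):
        """ML labels are unchanged by a common affine map of features and
        model (Gaussian labeling equivariance)."""
        x, *_ = two_gaussian_sample(rng, n=300, sep=4.0)
        model = fit_gmm_em(x, M=2, seed=2)
        A = np.diag([3.0, 0.5, 2.0, 10.0])
        shift = np.array([1.0, -2.0, 0.5, 4.0])
        x2 = x @ A.T + shift
        model2 = GmmModel(model.weights, model.means @ A.T + shift,
                          np.stack([A @ S @ A.T for S in model.covariances]))
        assert np.array_equal(label_voxels(x, model),
                              label_voxels(x2, model2))


class TestSegmentStriata:
    def test_control_segmentation_localizes(self, control_phantom):
        v, truth = control_phantom
        seg = segment_striata(v, v, seed=17)
        for side in ("left", "right"):
            mask = getattr(seg, side)
            assert not mask.is_empty()
            t = truth.side(side).mask.data
            # the mask must cover most of the true striatum
            recall = (mask.data & t).sum() / t.sum()
            assert recall > 0.9

    def test_masks_disjoint_hemispheres(self, control_phantom):
        v, _ = control_phantom
        seg = segment_striata(v, v, seed=17)
        assert not np.any(seg.left.data & seg.right.data)

    def test_pd_masks_within_dilated_bbox(self, pd_phantom):
        v, truth = pd_phantom
        seg = segment_striata(v, v, seed=17)
        for side in ("left", "right"):
            m = np.argwhere(getattr(seg, side).data)
            t = np.argwhere(truth.side(side).mask.data)
            lo, hi = t.min(axis=0) - 3, t.max(axis=0) + 3
            frac_inside = np.all((m >= lo) & (m <= hi), axis=1).mean()
            assert frac_inside > 0.95

    def test_uniform_volume_raises(self):
        v = Volume(np.full((24, 24, 16), 1.0))
        with pytest.raises((EmptySegmentationError, SampleSizeError)):
            segment_striata(v, v, seed=17)

    def test_determinism(self, control_phantom):
        v, _ = control_phantom
        a = segment_striata(v, v, seed=17)
        b = segment_striata(v, v, seed=17)
        assert np.array_equal(a.left.data, b.left.data)
        assert np.array_equal(a.right.data, b.right.data)
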
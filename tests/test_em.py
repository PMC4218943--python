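"""EM-MRF segmentation: oracle equivalence, monotonicity, merging."""

import numpy as np
import pytest

from pmbrainvol.core import BRAINSTEM, CEREBELLUM, CEREBRUM, CSF, LabelMap, VolumeImage
from pmbrainvol.em import EMParams, SegmentationResult, em_segment, merge_classes
from pmbrainvol.phantom import PhantomSpec, atlas_from_truth, generate_phantom


def brute_force_em(y, priors, n_iter):
    """Independent textbook EM for a Gaussian mixture with per-voxel mixing
    proportions: plain loops over classes, no shared code with the
    implementation under test."""
    K = len(priors)
    pri = np.stack([p.ravel() for p in priors])
    pri = pri / pri.sum(axis=0)
    yv = y.ravel()
    # prior-weighted moment initialization
    means, variances = [], []
    for k in range(K):
        w = pri[k]
        mu = (w * yv).sum() / w.sum()
        var = (w * yv ** 2).sum() / w.sum() - mu ** 2
        means.append(mu)
        variances.append(var)
    means, variances = np.array(means), np.array(variances)
    var_floor = max(1e-12, 1e-6 * yv.var())
    variances = np.maximum(variances, var_floor)
    trace = []
    for _ in range(n_iter):
        resp = np.empty((K, yv.size))
        for k in range(K):
            g = np.exp(-0.5 * (yv - means[k]) ** 2 / variances[k]) / np.sqrt(
                2 * np.pi * variances[k])
            resp[k] = pri[k] * g
        total = resp.sum(axis=0)
        trace.append(np.log(total).sum())
        resp /= total
        for k in range(K):
            s = resp[k].sum()
            means[k] = (resp[k] * yv).sum() / s
            variances[k] = max((resp[k] * (yv - means[k]) ** 2).sum() / s, var_floor)
    return means, variances, resp, trace


@pytest.fixture(scope="module")
def small_instance():
    """8x8x8 two-class instance with informative priors."""
    rng = np.random.default_rng(42)
    shape = (8, 8, 8)
    half = np.zeros(shape, bool)
    half[:, :, :4] = True
    y = np.where(half, 30.0, 60.0) + rng.normal(0, 4.0, shape)
    p0 = np.where(half, 0.7, 0.3)
    priors = {CEREBRUM: p0, CSF: 1.0 - p0}
    return y, priors


def test_pure_em_matches_brute_force_oracle(small_instance):
    """With no MRF and no relaxation the E/M updates equal textbook EM."""
    y, priors = small_instance
    img = VolumeImage(y, spacing=(1, 1, 1))
    mask = LabelMap(np.ones(y.shape, dtype=np.int16), spacing=(1, 1, 1))
    n_iter = 7
    res = em_segment(img, priors, mask,
                     EMParams(max_iterations=n_iter, convergence_tolerance=0.0,
                              mrf_beta=0.0, relaxation_alpha=0.0))
    mu, var, resp, trace = brute_force_em(y, [priors[CEREBRUM], priors[CSF]], n_iter)
    np.testing.assert_allclose(res.means, mu, atol=1e-10)
    np.testing.assert_allclose(res.variances, var, atol=1e-10)
    np.testing.assert_allclose(res.posteriors.reshape(2, -1), resp, atol=1e-10)
    np.testing.assert_allclose(res.objective_trace, trace, atol=1e-8)


def test_pure_em_objective_monotone(phantom, truth_atlas, em_mask):
    img, _ = phantom
    res = em_segment(img, truth_atlas.priors, em_mask,
                     EMParams(mrf_beta=0.0, relaxation_alpha=0.0))
    diffs = np.diff(res.objective_trace)
    assert (diffs >= -1e-6 * np.abs(res.objective_trace[0])).all()


def test_well_separated_means_recovered_within_one_percent():
    rng = np.random.default_rng(8)
    shape = (12, 12, 12)
    half = np.zeros(shape, bool)
    half[:6] = True
    y = np.where(half, 200.0, 800.0) + rng.normal(0, 20.0, shape)
    flat = np.full(shape, 0.5)
    res = em_segment(VolumeImage(y, spacing=(1, 1, 1)),
                     {CEREBRUM: flat, CSF: flat},
                     LabelMap(np.ones(shape, dtype=np.int16), spacing=(1, 1, 1)),
                     EMParams(mrf_beta=0.0, relaxation_alpha=0.0))
    assert sorted(res.means) == pytest.approx([200.0, 800.0], rel=0.01)


def test_posteriors_normalized_and_labels_match_argmax(phantom, truth_atlas, em_mask):
    img, _ = phantom
    res = em_segment(img, truth_atlas.priors, em_mask, EMParams())
    inside = em_mask.data > 0
    np.testing.assert_allclose(res.posteriors.sum(axis=0)[inside], 1.0, atol=1e-9)
    assert (res.variances > 0).all()
    arg = np.asarray(res.class_labels)[np.argmax(res.posteriors, axis=0)]
    np.testing.assert_array_equal(res.hard_labels.data[inside], arg[inside])
    assert (res.hard_labels.data[~inside] == 0).all()


def test_mrf_removes_isolated_islands(head_mask):
    """Potts coupling suppresses single-voxel label islands on noisy data."""
    from scipy import ndimage
    img, _ = generate_phantom(PhantomSpec(seed=31, class_noise_sd=90, bias_amplitude=1.0))
    _, truth = generate_phantom(PhantomSpec(seed=31, class_noise_sd=0, bias_amplitude=1.0))
    atlas = atlas_from_truth([truth], smoothing_mm=2.0)

    def n_islands(labels):
        total = 0
        for lbl in (CEREBRUM, CEREBELLUM, BRAINSTEM, CSF):
            comp, n = ndimage.label(labels.data == lbl)
            sizes = np.bincount(comp.ravel())[1:]
            total += int((sizes == 1).sum())
        return total

    base = em_segment(img, atlas.priors, head_mask,
                      EMParams(mrf_beta=0.0, relaxation_alpha=0.0))
    mrf = em_segment(img, atlas.priors, head_mask,
                     EMParams(mrf_beta=0.5, relaxation_alpha=0.0))
    assert n_islands(mrf.hard_labels) < n_islands(base.hard_labels)


# -- class merging ---------------------------------------------------------

def _result_from_posteriors(post, labels):
    mask = np.ones(post.shape[1:], bool)
    grid = VolumeImage(np.zeros(post.shape[1:]), spacing=(1, 1, 1))
    from pmbrainvol.em import _hard_labels
    return SegmentationResult(
        posteriors=post, hard_labels=_hard_labels(post, labels, mask, grid),
        class_labels=labels, means=np.zeros(len(labels)),
        variances=np.ones(len(labels)), mixing=post)


def test_identity_grouping_preserves_labels(phantom, truth_atlas, em_mask):
    img, _ = phantom
    res = em_segment(img, truth_atlas.priors, em_mask, EMParams())
    merged, post = merge_classes(res, [(CEREBRUM,), (CEREBELLUM,), (BRAINSTEM,), (CSF,)])
    np.testing.assert_array_equal(merged.data, res.hard_labels.data)
    inside = em_mask.data > 0
    np.testing.assert_allclose(post.sum(axis=0)[inside], 1.0, atol=1e-9)


def test_merge_flips_argmax_for_split_majority():
    """cerebrum 0.3 + CSF 0.3 beats cerebellum 0.4 only after merging."""
    post = np.array([0.3, 0.4, 0.0, 0.3]).reshape(4, 1, 1, 1)
    res = _result_from_posteriors(post, (CEREBRUM, CEREBELLUM, BRAINSTEM, CSF))
    assert res.hard_labels.data[0, 0, 0] == CEREBELLUM
    merged, _ = merge_classes(res)
    assert merged.data[0, 0, 0] == CEREBRUM


def test_non_partition_grouping_rejected():
    post = np.full((4, 2, 2, 2), 0.25)
    res = _result_from_posteriors(post, (CEREBRUM, CEREBELLUM, BRAINSTEM, CSF))
    with pytest.raises(ValueError, match="partition"):
        merge_classes(res, [(CEREBRUM, CSF), (CEREBELLUM,)])
    with pytest.raises(ValueError, match="partition"):
        merge_classes(res, [(CEREBRUM, CSF), (CEREBELLUM,), (BRAINSTEM, CSF)])


def test_non_finite_image_rejected(truth_atlas, em_mask):
    bad = VolumeImage(np.full(em_mask.shape, np.nan), spacing=em_mask.spacing)
    with pytest.raises(ValueError, match="finite"):
        em_segment(bad, truth_atlas.priors, em_mask, EMParams())
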
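"""Vessel extraction: Frangi filter properties (with independent Hessian and
thinning oracles), adaptive thresholding, cleaning, and phantom recovery."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import measure
from skimage.feature import hessian_matrix, hessian_matrix_eigvals

from pamoct import phantom, quantify, reconstruct, vesselness
from pamoct.vesselness import FilterParams

from conftest import clean_enface


def gaussian_ridge(n=96, sigma_true=2.0):
    x = np.arange(n) - n / 2
    return np.tile(np.exp(-x ** 2 / (2 * sigma_true ** 2)), (n, 1))


# --------------------------------------------------------------------------
# Frangi vesselness
# --------------------------------------------------------------------------


def test_constant_image_has_zero_vesselness():
    assert np.all(vesselness.frangi_vesselness(np.full((32, 32), 3.0)) == 0)


def test_hessian_eigenvalues_match_skimage_oracle(rng):
    """The scale-normalized Hessian eigenvalues agree with an independent
    implementation (interior pixels; borders differ by padding convention)."""
    img = ndimage.gaussian_filter(rng.normal(size=(48, 48)), 2.0)
    sigma, gamma = 2.0, 1.5
    l1, l2 = vesselness._hessian_eigenvalues(img, sigma, gamma)
    H = hessian_matrix(img, sigma=sigma, order="rc", use_gaussian_derivatives=True,
                       mode="reflect")
    ev = hessian_matrix_eigvals(H) * sigma ** gamma  # sorted descending by value
    mine_sorted = np.sort(np.stack([l1, l2]), axis=0)[::-1]
    inner = (slice(None), slice(8, -8), slice(8, -8))
    assert np.allclose(mine_sorted[inner], ev[inner], atol=1e-3)


@pytest.mark.parametrize("sigma_true", [1.0, 2.0, 4.0])
def test_scale_selection_picks_true_ridge_width(sigma_true):
    """Mean on-centerline response over scales {1,2,4} peaks at sigma_true
    (probed at fixed structureness constant, brute-force over scales)."""
    img = gaussian_ridge(96, sigma_true)
    means = {s: vesselness.frangi_single_scale(img, s, 0.5, 0.5, 1.5)[:, 48].mean()
             for s in (1.0, 2.0, 4.0)}
    assert max(means, key=means.get) == sigma_true


def test_ridge_response_exceeds_blob_response():
    """Blobness suppression: an equal-intensity isotropic blob scores below
    a ridge at every scale."""
    n = 64
    x = np.arange(n) - n / 2
    ridge = np.tile(np.exp(-x ** 2 / 8.0), (n, 1))
    X, Y = np.meshgrid(x, x, indexing="ij")
    blob = np.exp(-(X ** 2 + Y ** 2) / 8.0)
    for s in (1.0, 2.0, 3.0, 4.0):
        r = vesselness.frangi_single_scale(ridge, s, 0.5, None, 1.5)[n // 2, n // 2]
        b = vesselness.frangi_single_scale(blob, s, 0.5, None, 1.5)[n // 2, n // 2]
        assert r > b


def test_vesselness_centerline_agrees_with_skimage_frangi():
    """Both this filter and the reference multiscale filter localize the
    same curved centerline (per-column argmax within 1 px)."""
    from skimage.filters import frangi as sk_frangi

    n = 96
    cols = np.arange(n)
    center = 48 + 10 * np.sin(2 * np.pi * cols / n)
    rows = np.arange(n)[:, None]
    img = np.exp(-((rows - center[None, :]) ** 2) / 8.0)
    mine = vesselness.frangi_vesselness(img, FilterParams(scales=(1.0, 2.0, 3.0)))
    theirs = sk_frangi(img, sigmas=(1.0, 2.0, 3.0), black_ridges=False)
    interior = cols[8:-8]
    am, at = mine[:, interior].argmax(axis=0), theirs[:, interior].argmax(axis=0)
    assert np.all(np.abs(am - at) <= 1)


def test_vesselness_range_and_input_validation():
    v = vesselness.frangi_vesselness(gaussian_ridge())
    assert v.min() >= 0.0 and v.max() == pytest.approx(1.0)
    with pytest.raises(vesselness.DataError):
        vesselness.frangi_vesselness(np.full((4, 4), 1.0))
    with pytest.raises(vesselness.DataError):
        vesselness.frangi_vesselness(np.full((16, 16), np.nan))


# --------------------------------------------------------------------------
# adaptive threshold
# --------------------------------------------------------------------------


def test_adaptive_threshold_constant_is_empty():
    assert not vesselness.adaptive_threshold(np.full((20, 20), 0.4), 15, 0.1).any()


def test_adaptive_threshold_step_image():
    """On a 0/1 step the local-mean rule marks only the bright side of the
    transition band: foreground is confined to high-plateau columns within
    half a window of the edge, and no background pixel fires."""
    img = np.zeros((40, 40))
    img[:, 20:] = 1.0
    mask = vesselness.adaptive_threshold(img, 15, 0.1)
    assert not mask[:, :20].any()  # dark side never foreground
    cols = np.where(mask.any(axis=0))[0]
    assert cols.min() == 20  # fires right at the step
    assert cols.max() <= 20 + 7  # and no further than window // 2


def test_adaptive_threshold_window_validation():
    with pytest.raises(ValueError):
        vesselness.adaptive_threshold(np.zeros((10, 10)), 4, 0.1)
    with pytest.raises(ValueError):
        vesselness.adaptive_threshold(np.zeros((10, 10)), 11, 0.1)


def test_threshold_recovers_phantom_mask_under_noise(retinal_scene):
    """Default extraction achieves Dice >= 0.7 against ground truth with
    additive image noise sigma = 0.1."""
    truth = phantom.rasterize_tree(retinal_scene.tree, "enface_mask")
    ef = clean_enface(retinal_scene)
    noisy = np.clip(ef.data + np.random.default_rng(0).normal(0, 0.1, ef.data.shape), 0, None)
    maps = vesselness.extract_vessels(
        reconstruct.normalize(reconstruct.EnFaceImage(noisy)))
    dice = 2 * np.sum(maps.binary & truth) / (maps.binary.sum() + truth.sum())
    assert dice >= 0.7


def test_extraction_degrades_monotonically_with_noise(retinal_scene):
    truth = phantom.rasterize_tree(retinal_scene.tree, "enface_mask")
    ef = clean_enface(retinal_scene)
    rng = np.random.default_rng(1)
    dices = []
    for sig in (0.0, 0.05, 0.1):
        noisy = np.clip(ef.data + rng.normal(0, sig, ef.data.shape), 0, None)
        maps = vesselness.extract_vessels(
            reconstruct.normalize(reconstruct.EnFaceImage(noisy)))
        dices.append(2 * np.sum(maps.binary & truth) / (maps.binary.sum() + truth.sum()))
    assert dices[0] >= dices[1] - 0.02 and dices[1] >= dices[2] - 0.02


# --------------------------------------------------------------------------
# cleaning
# --------------------------------------------------------------------------


def test_clean_removes_specks_and_bridges_gaps():
    m = np.zeros((30, 30), bool)
    m[5, 5] = True  # isolated speck
    m[15, 2:14] = True
    m[15, 15:28] = True  # 1-px gap at column 14
    out = vesselness.clean_binary(m, min_object_px=10, closing_radius=1)
    assert not out[5, 5]
    n_comp = measure.label(out, connectivity=2).max()
    assert n_comp == 1


def test_clean_never_increases_component_count(rng):
    m = rng.uniform(size=(48, 48)) > 0.6
    before = measure.label(m, connectivity=2).max()
    after = measure.label(vesselness.clean_binary(m, 10, 1), connectivity=2).max()
    assert after <= before
    assert not vesselness.clean_binary(np.zeros((8, 8), bool), 10, 1).any()


# --------------------------------------------------------------------------
# thinning
# --------------------------------------------------------------------------


def _textbook_zhang_suen(mask):
    """Independent reference: the classical two-subiteration thinning,
    written as the per-pixel textbook procedure."""
    img = np.pad(mask.astype(np.uint8), 1)
    changed = True
    while changed:
        changed = False
        for first in (True, False):
            to_del = []
            for r in range(1, img.shape[0] - 1):
                for c in range(1, img.shape[1] - 1):
                    if not img[r, c]:
                        continue
                    p = [img[r - 1, c], img[r - 1, c + 1], img[r, c + 1],
                         img[r + 1, c + 1], img[r + 1, c], img[r + 1, c - 1],
                         img[r, c - 1], img[r - 1, c - 1]]
                    B = sum(p)
                    A = sum(1 for i in range(8) if p[i] == 0 and p[(i + 1) % 8] == 1)
                    if not (2 <= B <= 6 and A == 1):
                        continue
                    if first and p[0] * p[2] * p[4] == 0 and p[2] * p[4] * p[6] == 0:
                        to_del.append((r, c))
                    elif not first and p[0] * p[2] * p[6] == 0 and p[0] * p[4] * p[6] == 0:
                        to_del.append((r, c))
            for r, c in to_del:
                img[r, c] = 0
            changed = changed or bool(to_del)
    return img[1:-1, 1:-1].astype(bool)


def shape_library():
    shapes = {}
    shapes["bar"] = np.pad(np.ones((5, 40), bool), 8)
    shapes["thick_bar"] = np.pad(np.ones((9, 30), bool), 8)
    X, Y = np.meshgrid(np.arange(64) - 32, np.arange(64) - 32, indexing="ij")
    shapes["ring"] = (X ** 2 + Y ** 2 <= 400) & (X ** 2 + Y ** 2 >= 144)
    shapes["disk"] = X ** 2 + Y ** 2 <= 200
    cross = np.zeros((50, 50), bool)
    cross[22:27, 5:45] = True
    cross[5:45, 22:27] = True
    shapes["cross"] = cross
    L = np.zeros((50, 50), bool)
    L[10:40, 10:15] = True
    L[35:40, 10:40] = True
    shapes["L"] = L
    T = np.zeros((50, 50), bool)
    T[10:15, 5:45] = True
    T[10:40, 22:27] = True
    shapes["T"] = T
    H = np.zeros((50, 50), bool)
    H[10:40, 10:15] = True
    H[10:40, 35:40] = True
    H[22:27, 10:40] = True
    shapes["H"] = H
    frame = np.zeros((40, 40), bool)
    frame[5:35, 5:35] = True
    frame[12:28, 12:28] = False
    shapes["frame"] = frame
    two = np.zeros((40, 60), bool)
    two[5:10, 5:55] = True
    two[25:30, 5:55] = True
    shapes["two_bars"] = two
    tree = np.zeros((60, 60), bool)
    tree[5:55, 28:32] = True
    tree[25:29, 5:55] = True
    tree[40:44, 30:55] = True
    shapes["tree"] = tree
    return shapes


def test_one_px_line_is_a_fixed_point():
    line = np.zeros((10, 20), bool)
    line[5, 2:18] = True
    assert np.array_equal(vesselness.skeletonize(line), line)


def test_bar_centerline_length():
    bar = np.zeros((21, 60), bool)
    bar[8:13, 10:50] = True  # 5 px wide, 40 px long
    sk = vesselness.skeletonize(bar)
    assert measure.label(sk, connectivity=2).max() == 1
    assert abs(int(sk.sum()) - 40) <= 3


def test_annulus_thins_to_single_closed_loop():
    X, Y = np.meshgrid(np.arange(64) - 32, np.arange(64) - 32, indexing="ij")
    ann = (X ** 2 + Y ** 2 <= 400) & (X ** 2 + Y ** 2 >= 144)
    sk = vesselness.skeletonize(ann)
    assert measure.label(sk, connectivity=2).max() == 1
    assert measure.euler_number(sk, connectivity=2) == measure.euler_number(ann, connectivity=2) == 0
    # unit width: no fully set 2x2 block
    assert not (sk[:-1, :-1] & sk[1:, :-1] & sk[:-1, 1:] & sk[1:, 1:]).any()


@pytest.mark.parametrize("name", sorted(shape_library()))
def test_thinning_topology_and_idempotence(name):
    m = shape_library()[name]
    sk = vesselness.skeletonize(m)
    assert not (sk & ~m).any()  # skeleton subset of mask
    assert measure.label(sk, connectivity=2).max() == measure.label(m, connectivity=2).max()
    assert measure.euler_number(sk, connectivity=2) == measure.euler_number(m, connectivity=2)
    assert np.array_equal(vesselness.skeletonize(sk), sk)


def test_thinning_matches_textbook_oracle_topology():
    """The package skeleton and an independently coded textbook thinning agree
    on topology and stay within 1 px of each other on simple shapes."""
    for name in ("bar", "cross", "ring"):
        m = shape_library()[name]
        ours = vesselness.skeletonize(m)
        ref = _textbook_zhang_suen(m)
        assert measure.euler_number(ours, connectivity=2) == measure.euler_number(ref, connectivity=2)
        assert measure.label(ours, connectivity=2).max() == measure.label(ref, connectivity=2).max()
        d = ndimage.distance_transform_edt(~ref)
        assert d[ours].max() <= 2.5  # variants differ near junctions/ends


# --------------------------------------------------------------------------
# full extraction
# --------------------------------------------------------------------------


def test_blank_image_gives_empty_maps():
    maps = vesselness.extract_vessels(np.zeros((32, 32)))
    assert not maps.binary.any() and not maps.skeleton.any()


def test_extraction_is_deterministic(retinal_scene):
    ef = clean_enface(retinal_scene)
    m1 = vesselness.extract_vessels(ef)
    m2 = vesselness.extract_vessels(ef)
    assert np.array_equal(m1.vesselness, m2.vesselness)
    assert np.array_equal(m1.binary, m2.binary)
    assert np.array_equal(m1.skeleton, m2.skeleton)


def test_skeleton_subset_invariant(retinal_scene):
    maps = vesselness.extract_vessels(clean_enface(retinal_scene))
    assert not (maps.skeleton & ~maps.binary).any()
    with pytest.raises(ValueError, match="subset"):
        vesselness.VesselMaps(np.zeros((4, 4)), np.zeros((4, 4), bool),
                              np.ones((4, 4), bool), FilterParams())


def test_rotation_robustness(retinal_scene):
    """VAD of the extraction on a 90-degree-rotated en face differs < 5 %."""
    ef = clean_enface(retinal_scene)
    v0 = quantify.vad(vesselness.extract_vessels(ef).binary)
    rot = reconstruct.EnFaceImage(np.rot90(ef.data).copy(), normalized=True)
    v90 = quantify.vad(vesselness.extract_vessels(rot).binary)
    assert abs(v90 - v0) / v0 < 0.05


def test_noise_free_dice_recovery():
    """Dice >= 0.85 against ground truth on noise-free phantoms."""
    for seed in range(3):
        scene = phantom.build_fundus_scene(seed=seed, with_choroid=False)
        truth = phantom.rasterize_tree(scene.tree, "enface_mask")
        maps = vesselness.extract_vessels(clean_enface(scene, seed=seed))
        dice = 2 * np.sum(maps.binary & truth) / (maps.binary.sum() + truth.sum())
        assert dice >= 0.85
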
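import numpy as np
import pandas as pd
import pytest

from celltyper import (
    CellRecord,
    CropSpec,
    ExpressionMatrix,
    ModelConfig,
    SimulationSpec,
    build_input_tensor,
    extract_cell_records,
    guided_backprop,
    landmark_gate,
    patch_overlap_analysis,
    radial_gradient_profile,
    radius_at_fraction,
    simulate_signal,
)
from celltyper.ensemble import TrainedModel
from celltyper.interpret import LandmarkOverride, cell_boundary
from celltyper.nn import SmallCNN
from celltyper.tensorization import CropTensor

from conftest import make_mask, make_stack
from oracles import dilate_square, flood_label_8, landmark_scan


# ---------------------------------------------------------------------------
# Guided backprop
# ---------------------------------------------------------------------------

class _LinearNet:
    """Purely linear scorer: logit_c = sum_kij W[c,k,i,j] * x[k,i,j]."""

    def __init__(self, w):
        self.w = w  # (n_classes, K, S, S)

    def forward(self, x):
        return np.einsum("nkij,ckij->nc", x, self.w)

    def backward(self, dlogits, guided=False):
        return np.einsum("nc,ckij->nkij", dlogits, self.w)


def _tensor_of(values, channels=None):
    values = np.asarray(values, dtype=np.float32)
    if channels is None:
        channels = [f"p{i}" for i in range(values.shape[0] - 2)]
        channels += ["target_mask", "environment_mask"]
    return CropTensor(values, channels, "fov0", 1)


def _wrap(net, vocab):
    model = TrainedModel.__new__(TrainedModel)
    model.net = net
    model.vocabulary = list(vocab)
    return model


class TestGuidedBackprop:
    def test_linear_positive_weights_recover_weight_map(self, rng):
        w = rng.uniform(0.1, 1.0, size=(2, 3, 6, 6))
        model = _wrap(_LinearNet(w), ["a", "b"])
        t = _tensor_of(rng.poisson(2, (3, 6, 6)))
        gmap = guided_backprop(model, t, "b")
        np.testing.assert_allclose(gmap, w[1])

    def test_negative_gradients_clipped_to_zero(self, rng):
        w = rng.uniform(-1.0, 1.0, size=(2, 3, 6, 6))
        model = _wrap(_LinearNet(w), ["a", "b"])
        gmap = guided_backprop(model, _tensor_of(np.zeros((3, 6, 6))), 0)
        assert gmap.min() >= 0.0
        np.testing.assert_allclose(gmap, np.maximum(w[0], 0.0))

    def test_shape_matches_input_and_nonnegative_for_cnn(self, rng):
        net = SmallCNN(4, 3, rng, widths=(4, 4, 4))
        model = _wrap(net, ["a", "b", "c"])
        t = _tensor_of(rng.poisson(2, (4, 8, 8)))
        gmap = guided_backprop(model, t, "c")
        assert gmap.shape == t.values.shape
        assert gmap.min() >= 0.0

    def test_unknown_class_raises(self, rng):
        model = _wrap(_LinearNet(np.ones((2, 3, 6, 6))), ["a", "b"])
        with pytest.raises(KeyError):
            guided_backprop(model, _tensor_of(np.zeros((3, 6, 6))), "zz")


# ---------------------------------------------------------------------------
# Radial profiles
# ---------------------------------------------------------------------------

def _cell(area=80, fov="fov0"):
    r = np.sqrt(area / np.pi)
    return CellRecord(fov, 1, (10.0, 10.0), area, (0, 0, 20, 20), 2 * r, 2 * r)


class TestRadialProfile:
    def test_central_mass_is_one_at_every_radius(self):
        grad = np.zeros((3, 20, 20))
        grad[:, 9, 9] = 5.0  # nearest pixel to the geometric center (9.5, 9.5)
        grad[:, 10, 10] = 5.0
        prof = radial_gradient_profile(grad, _cell())
        np.testing.assert_allclose(prof.profile, 1.0)

    def test_normalized_to_largest_radius(self, rng):
        grad = rng.uniform(0, 1, (2, 20, 20))
        prof = radial_gradient_profile(grad, _cell())
        np.testing.assert_allclose(prof.profile[:, -1], 1.0)
        assert (np.diff(prof.profile, axis=1) >= -1e-12).all()

    def test_uniform_map_matches_disk_pixel_counts(self):
        grad = np.ones((1, 20, 20))
        prof = radial_gradient_profile(grad, _cell())
        center = 9.5
        rr, cc = np.mgrid[:20, :20]
        dist = np.sqrt((rr - center) ** 2 + (cc - center) ** 2)
        counts = np.array([(dist <= r).sum() for r in range(1, 18, 2)], dtype=float)
        np.testing.assert_allclose(prof.profile[0], counts / counts[-1])

    def test_small_cells_filtered(self):
        grad = np.ones((1, 20, 20))
        assert radial_gradient_profile(grad, _cell(area=49)) is None

    def test_radius_axis_normalized_by_cell_radius(self):
        prof = radial_gradient_profile(np.ones((1, 20, 20)), _cell(area=100))
        cell_radius = np.sqrt(100 / np.pi)
        np.testing.assert_allclose(prof.normalized_radii,
                                   np.arange(1, 18, 2) / cell_radius)


class TestRadiusAtFraction:
    def test_interpolates_between_profiled_radii(self):
        radii = np.array([1.0, 2.0, 3.0])
        prof = np.array([0.2, 0.5, 1.0])
        # 0.6 sits 20% of the way from 0.5 to 1.0 -> radius 2.2
        assert radius_at_fraction(prof, radii, 0.6) == pytest.approx(2.2)

    def test_first_point_crossing(self):
        assert radius_at_fraction(np.array([0.9, 1.0]), np.array([1.0, 2.0]),
                                  0.6) == 1.0

    def test_nan_profile_gives_nan(self):
        assert np.isnan(radius_at_fraction(np.array([np.nan, 1.0]),
                                           np.array([1.0, 2.0])))


# ---------------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------------

def _disk_world(radius=9, size=40):
    rr, cc = np.ogrid[:size, :size]
    labels = (((rr - size // 2) ** 2 + (cc - size // 2) ** 2) <= radius ** 2
              ).astype(np.int32)
    mask = make_mask(labels)
    stack = make_stack(np.zeros((2, size, size)), ["cd20", "cd4"])
    cell = extract_cell_records(mask)[0]
    return stack, mask, cell


class TestSimulateSignal:
    def test_lambda_zero_only_zeroes_cognate_signal(self, rng):
        stack, mask, cell = _disk_world()
        stack.pixels[0] += 3.0
        stack.pixels[1] += 2.0
        spec = SimulationSpec("gaussian_patch", "cd20", lam=0.0, n_points=50,
                              zero_channels=("cd4",), crop_size_px=20)
        sim, info = simulate_signal(stack, mask, cell, spec, rng)
        assert info["added_total"] == 0
        # cognate channels zeroed within the crop window, untouched outside
        assert sim.channel("cd4")[20, 20] == 0.0
        assert sim.channel("cd4")[0, 0] == 2.0
        assert sim.channel("cd20")[0, 0] == 3.0

    def test_membrane_counts_confined_to_band(self, rng):
        stack, mask, cell = _disk_world()
        spec = SimulationSpec("membrane", "cd20", n_points=200, band_px=5)
        sim, info = simulate_signal(stack, mask, cell, spec, rng)
        added = np.argwhere(sim.channel("cd20") > 0)
        boundary = np.argwhere(cell_boundary(mask, cell.cell_id))
        cheb = np.abs(added[:, None, :] - boundary[None, :, :]).max(axis=2).min(axis=1)
        assert cheb.max() <= 5

    def test_mean_total_added_counts(self):
        stack, mask, cell = _disk_world()
        spec = SimulationSpec("gaussian_patch", "cd20", lam=4.0, n_points=100)
        rng = np.random.default_rng(0)
        totals = [simulate_signal(stack, mask, cell, spec, rng)[1]["added_total"]
                  for _ in range(300)]
        se = np.sqrt(100 * 4.0 * 5.0 / 300)  # compound Poisson variance n*lam*(1+lam)
        assert abs(np.mean(totals) - 400.0) < 3 * se

    def test_coverage_scaling_keeps_totals_constant(self):
        stack, mask, cell = _disk_world()
        means = {}
        for cov in (1.0, 0.125):
            rng = np.random.default_rng(1)
            spec = SimulationSpec("membrane", "cd20", n_points=150, coverage=cov)
            totals = [simulate_signal(stack, mask, cell, spec, rng)[1]["added_total"]
                      for _ in range(300)]
            means[cov] = np.mean(totals)
        assert abs(means[0.125] - means[1.0]) / means[1.0] < 0.10

    def test_border_patch_skips_thin_cells(self, rng):
        stack, mask, cell = _disk_world(radius=5)
        assert cell.minor_axis_px < 15
        spec = SimulationSpec("border_patch", "cd20")
        sim, info = simulate_signal(stack, mask, cell, spec, rng)
        assert info["skipped"]
        np.testing.assert_array_equal(sim.channel("cd20"), stack.channel("cd20"))

    def test_border_patch_adds_near_boundary(self, rng):
        stack, mask, cell = _disk_world(radius=9)
        assert cell.minor_axis_px >= 15
        spec = SimulationSpec("border_patch", "cd20", n_points=50)
        sim, info = simulate_signal(stack, mask, cell, spec, rng)
        assert not info["skipped"]
        assert sim.channel("cd20").sum() > 0

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec("membrane", "cd20", coverage=0.0)
        with pytest.raises(ValueError):
            SimulationSpec("membrane", "cd20", coverage=1.5)

    def test_unknown_channel_raises(self, rng):
        stack, mask, cell = _disk_world()
        with pytest.raises(KeyError):
            simulate_signal(stack, mask, cell,
                            SimulationSpec("membrane", "nope"), rng)


# ---------------------------------------------------------------------------
# Patch overlap
# ---------------------------------------------------------------------------

class TestPatchOverlap:
    def test_half_covered_cell(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:6, 2:6] = 1
        channel = np.zeros((10, 10))
        channel[2:4, 2:6] = 1.0
        overlaps, _, assignments = patch_overlap_analysis(channel, make_mask(labels))
        assert overlaps[1] == pytest.approx(0.5)
        assert assignments[1] != []

    def test_two_pixels_two_apart_merge_after_dilation(self):
        channel = np.zeros((12, 12))
        channel[5, 3] = 1.0
        channel[5, 5] = 1.0
        mask = make_mask(np.zeros((12, 12), dtype=np.int32))
        _, patches, _ = patch_overlap_analysis(channel, mask)
        assert patches.max() == 1
        ref = flood_label_8(dilate_square(channel > 0, 3))
        assert ref.max() == 1
        np.testing.assert_array_equal(patches > 0, ref > 0)

    def test_all_zero_channel_has_no_patches(self):
        labels = np.zeros((8, 8), dtype=np.int32)
        labels[2:4, 2:4] = 1
        overlaps, patches, assignments = patch_overlap_analysis(
            np.zeros((8, 8)), make_mask(labels)
        )
        assert patches.max() == 0
        assert overlaps[1] == 0.0
        assert assignments[1] == []

    def test_matches_bruteforce_on_random_fields(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            channel = (rng.random((16, 16)) < 0.1).astype(float)
            mask = make_mask(np.zeros((16, 16), dtype=np.int32))
            _, patches, _ = patch_overlap_analysis(channel, mask)
            ref = flood_label_8(dilate_square(channel > 0, 3))
            assert patches.max() == ref.max()
            np.testing.assert_array_equal(patches > 0, ref > 0)


# ---------------------------------------------------------------------------
# Landmark gating
# ---------------------------------------------------------------------------

def _matrix(values, columns):
    index = pd.MultiIndex.from_arrays(
        [["fov0"] * len(values), np.arange(1, len(values) + 1)],
        names=["fov_id", "cell_id"],
    )
    return ExpressionMatrix(pd.DataFrame(values, index=index, columns=columns))


class TestLandmarkGate:
    def test_all_zero_matrix_has_no_landmarks(self):
        mat = _matrix(np.zeros((10, 3)), ["a", "b", "c"])
        out = landmark_gate(mat, {"A": ["a"], "B": ["b"]})
        assert out.isna().all() or (out == None).all()  # noqa: E711

    def test_unique_high_cell_is_the_landmark(self, rng):
        values = rng.uniform(0.4, 0.6, size=(10, 3))
        values[3] = [5.0, 0.0, 0.0]  # high in the defining marker, low elsewhere
        mat = _matrix(values, ["a", "b", "c"])
        out = landmark_gate(mat, {"A": ["a"], "B": ["b"]})
        assert out.iloc[3] == "A"
        ref = landmark_scan(values, ["a", "b", "c"], {"A": ["a"], "B": ["b"]}, 20, 15)
        assert [v if v is not None else None for v in out] == ref

    def test_matches_percentile_scan_on_random_matrices(self):
        defs = {"X": ["a"], "Y": ["b", "c"]}
        for seed in range(40):
            rng = np.random.default_rng(seed)
            values = rng.uniform(0, 1, size=(25, 4))
            mat = _matrix(values, ["a", "b", "c", "d"])
            out = landmark_gate(mat, defs)
            ref = landmark_scan(values, ["a", "b", "c", "d"], defs, 20, 15)
            assert [v if v is not None else None for v in out] == ref

    def test_ignore_others_override(self, rng):
        values = rng.uniform(0.4, 0.6, size=(10, 2))
        values[2] = [5.0, 5.0]  # high in both: fails default, passes override
        mat = _matrix(values, ["a", "b"])
        strict = landmark_gate(mat, {"A": ["a"]})
        relaxed = landmark_gate(mat, {"A": ["a"]},
                                overrides={"A": LandmarkOverride(ignore_others=True)})
        assert strict.iloc[2] is None
        assert relaxed.iloc[2] == "A"

    def test_missing_defining_protein_raises(self):
        mat = _matrix(np.zeros((5, 2)), ["a", "b"])
        with pytest.raises(KeyError):
            landmark_gate(mat, {"A": ["zz"]})
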
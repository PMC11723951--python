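"""Segmentation and partition-coefficient analysis."""

import numpy as np
import pandas as pd
import pytest

from hrdquant import partition as part, simulate as sim


@pytest.fixture(scope="module")
def params():
    return sim.preset("retentive")


def _jaccard(a, b):
    return (a & b).sum() / (a | b).sum()


# ------------------------------------------------------------ segmentation

def test_noiseless_segmentation_recovers_ground_truth_exactly(params):
    fld, gt = sim.make_nucleus_field(params, pc_target=5.0)
    masks = part.segment_nucleus(fld, mode="protein")
    np.testing.assert_array_equal(masks.labels, gt.labels)


def test_counterstain_mode_for_non_partitioning_protein(params):
    """At PC=1 the protein channel is featureless; the DNA channel still
    recovers the chromocenter mask."""
    fld, gt = sim.make_nucleus_field(
        params, pc_target=1.0, noise="poisson", rng=np.random.default_rng(0)
    )
    masks = part.segment_nucleus(fld, mode="counterstain")
    cc_seg = masks.mask(sim.LABEL_CHROMOCENTER)
    cc_true = gt.labels == sim.LABEL_CHROMOCENTER
    assert _jaccard(cc_seg, cc_true) >= 0.9


def test_noisy_segmentation_pixel_accuracy(params):
    """Per-class pixel accuracy >= 95% at SNR ~ 10 (Poisson on ~100 counts)."""
    fld, gt = sim.make_nucleus_field(
        params, pc_target=5.0, mean_nuclear_intensity=200.0,
        noise="poisson", rng=np.random.default_rng(1),
    )
    masks = part.segment_nucleus(fld, mode="protein")
    for label in (sim.LABEL_BACKGROUND, sim.LABEL_NUCLEOPLASM, sim.LABEL_CHROMOCENTER):
        true = gt.labels == label
        acc = (masks.labels[true] == label).mean()
        assert acc >= 0.95, f"class {label}: accuracy {acc:.3f}"


def test_degenerate_histogram_rejected():
    fld = sim.ImagingField(data=np.full((32, 32), 7.0), pixel_size=0.1)
    with pytest.raises(ValueError, match="degenerate"):
        part.segment_nucleus(fld)


def test_counterstain_mode_requires_channel():
    fld = sim.ImagingField(data=np.random.default_rng(0).poisson(50, (16, 16)).astype(float),
                           pixel_size=0.1)
    with pytest.raises(ValueError, match="counterstain"):
        part.segment_nucleus(fld, mode="counterstain")


# ------------------------------------------------------------ PC formula

def test_pc_formula_arithmetic(params):
    """Constructed means 60/20/10 give PC = (60-10)/(20-10) = 5 exactly."""
    gt_labels = params.labels()
    img = np.full(params.grid_shape, 10.0)
    img[gt_labels == sim.LABEL_NUCLEOPLASM] = 20.0
    img[gt_labels == sim.LABEL_CHROMOCENTER] = 60.0
    fld = sim.ImagingField(data=img, pixel_size=params.pixel_size)
    rec = part.partition_coefficient(fld, part.LabelMasks(labels=gt_labels))
    assert rec.pc == 5.0
    assert rec.mean_cc == 60.0 and rec.mean_np == 20.0 and rec.mean_bg == 10.0


def test_pc_equal_means_is_exactly_one(params):
    fld, gt = sim.make_nucleus_field(params, pc_target=1.0)
    rec = part.partition_coefficient(fld, part.masks_from_ground_truth(gt))
    assert rec.pc == 1.0


def test_pc_rejects_empty_chromocenter_mask(params):
    labels = params.labels()
    labels[labels == sim.LABEL_CHROMOCENTER] = sim.LABEL_NUCLEOPLASM
    fld, _ = sim.make_nucleus_field(params, pc_target=2.0)
    with pytest.raises(ValueError, match="counterstain"):
        part.partition_coefficient(fld, part.LabelMasks(labels=labels))


def test_pc_rejects_nucleoplasm_below_background(params):
    labels = params.labels()
    img = np.full(params.grid_shape, 50.0)
    img[labels == sim.LABEL_NUCLEOPLASM] = 20.0
    img[labels == sim.LABEL_CHROMOCENTER] = 80.0
    fld = sim.ImagingField(data=img, pixel_size=params.pixel_size)
    with pytest.raises(ValueError, match="background"):
        part.partition_coefficient(fld, part.LabelMasks(labels=labels))


def test_near_noise_floor_cells_flagged(params):
    rng = np.random.default_rng(3)
    fld, gt = sim.make_nucleus_field(
        params, pc_target=5.0, mean_nuclear_intensity=12.0,
        background_level=10.0, noise="poisson", rng=rng,
    )
    rec = part.partition_coefficient(fld, part.masks_from_ground_truth(gt))
    assert "near_noise_floor" in rec.flags


@pytest.mark.parametrize("noise_scale", [60.0, 120.0, 300.0])
@pytest.mark.parametrize("n_cells", [5, 15, 45])
def test_pc_estimator_consistency(params, noise_scale, n_cells):
    """Mean recovered PC converges on the target across noise levels and
    replicate counts (Poisson SNR grows with intensity)."""
    rng = np.random.default_rng(int(noise_scale) * 100 + n_cells)
    target = 6.0
    pcs = []
    for _ in range(n_cells):
        fld, gt = sim.make_nucleus_field(
            params, pc_target=target, mean_nuclear_intensity=noise_scale,
            noise="poisson", rng=rng,
        )
        pcs.append(
            part.partition_coefficient(fld, part.masks_from_ground_truth(gt)).pc
        )
    assert np.mean(pcs) == pytest.approx(target, rel=0.05)


def test_segmented_vs_oracle_masks_agree(params):
    """PC through intensity segmentation stays within 5% of the
    ground-truth-mask PC at SNR ~ 10."""
    rng = np.random.default_rng(11)
    diffs = []
    for _ in range(10):
        fld, gt = sim.make_nucleus_field(
            params, pc_target=8.0, mean_nuclear_intensity=200.0,
            noise="poisson", rng=rng,
        )
        pc_seg = part.partition_coefficient(fld, part.segment_nucleus(fld)).pc
        pc_gt = part.partition_coefficient(fld, part.masks_from_ground_truth(gt)).pc
        diffs.append(abs(pc_seg - pc_gt) / pc_gt)
    assert np.mean(diffs) < 0.05


# ------------------------------------------------------------ scatter / bins

def _records_from_series(series):
    recs = []
    for i, (fld, gt) in enumerate(series):
        recs.append(
            part.partition_coefficient(
                fld, part.masks_from_ground_truth(gt),
                construct_id="wt", cell_id=f"c{i:02d}",
            )
        )
    return recs


def test_normalized_scatter_diagonal_at_pc_one(params):
    recs = []
    for i, level in enumerate((60.0, 120.0, 240.0)):
        fld, gt = sim.make_nucleus_field(params, pc_target=1.0,
                                         mean_nuclear_intensity=level)
        recs.append(
            part.partition_coefficient(fld, part.masks_from_ground_truth(gt),
                                       construct_id="inert", cell_id=f"c{i}")
        )
    out = part.normalized_scatter(recs)
    np.testing.assert_allclose(out["cc_norm"], out["np_norm"], rtol=1e-12)
    assert out.attrs["normalization"] == "shared_max"


def test_normalized_scatter_retentive_series_hugs_y_axis(params):
    """Chromocenter signal rises with expression while nucleoplasm stays low
    until saturation."""
    series = sim.make_expression_series(params, [200, 800, 3000, 9000])
    out = part.normalized_scatter(_records_from_series(series))
    out = out.sort_values("nuclear_intensity")
    assert out["cc_norm"].is_monotonic_increasing
    sub = out.iloc[:-1]  # below the saturated top level
    assert sub["np_norm"].max() <= 2.0 * max(sub["np_norm"].min(), 1e-12) + 0.05


def test_normalized_scatter_needs_two_records(params):
    fld, gt = sim.make_nucleus_field(params, pc_target=2.0)
    rec = part.partition_coefficient(fld, part.masks_from_ground_truth(gt))
    with pytest.raises(ValueError):
        part.normalized_scatter([rec])


def test_saturation_bins_single_record(params):
    fld, gt = sim.make_nucleus_field(params, pc_target=3.0)
    rec = part.partition_coefficient(fld, part.masks_from_ground_truth(gt),
                                     cell_id="only")
    out = part.saturation_bins([rec], bounds=[1e4, 2e4])
    assert out["n"].sum() == 1
    occupied = out[out["n"] > 0]
    assert len(occupied) == 1
    assert occupied.iloc[0]["mean_pc"] == pytest.approx(rec.pc)
    assert (out.loc[out["n"] == 0, "mean_pc"].isna()).all()


def test_saturation_bins_pc_nonincreasing_over_expression(params):
    sites = params.total_sites()
    series = sim.make_expression_series(
        params, [300, 600, 1500, sites, 3 * sites, 8 * sites]
    )
    recs = _records_from_series(series)
    nuclear = sorted(r.mean_nuclear - r.mean_bg for r in recs)
    bounds = [nuclear[2] + 1, nuclear[4] + 1]
    out = part.saturation_bins(recs, bounds=bounds)
    pcs = out.loc[out["n"] > 0, "mean_pc"].to_numpy()
    assert np.all(np.diff(pcs) <= 1e-9)


def test_saturation_bins_rejects_unsorted_bounds(params):
    with pytest.raises(ValueError, match="increasing"):
        part.saturation_bins(pd.DataFrame(), bounds=[5.0, 2.0])
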
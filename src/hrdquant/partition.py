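"""Chromocenter partition-coefficient analysis.

Segments single-nucleus images into chromocenter / nucleoplasm / background
classes, applies the partition-coefficient formula

    PC = (mean_cc - mean_bg) / (mean_np - mean_bg)

per cell, and derives the normalized chromocenter-vs-nucleoplasm scatter and
expression-saturation summaries.

Segmentation is a deterministic three-class intensity model (multi-Otsu
thresholds with small-object cleanup) rather than a trained pixel
classifier; for proteins with minimal chromocenter partitioning the DNA
counterstain channel is segmented instead and the labels transferred to the
protein channel (``mode="counterstain"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_multiotsu
from skimage.morphology import remove_small_objects

from .simulate import (
    LABEL_BACKGROUND,
    LABEL_CHROMOCENTER,
    LABEL_NUCLEOPLASM,
    GroundTruth,
    ImagingField,
)

__all__ = [
    "LabelMasks",
    "PartitionRecord",
    "segment_nucleus",
    "masks_from_ground_truth",
    "partition_coefficient",
    "records_to_frame",
    "normalized_scatter",
    "saturation_bins",
]


@dataclass(frozen=True)
class LabelMasks:
    """Per-pixel class labels (background=0, nucleoplasm=1, chromocenter=2)."""

    labels: np.ndarray
    source: str = "protein_channel"

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class PartitionRecord:
    """Corrected mean intensities and the partition coefficient for one nucleus."""

    mean_cc: float
    mean_np: float
    mean_bg: float
    mean_nuclear: float
    pc: float
    construct_id: str = ""
    cell_id: str = ""
    experiment_id: str = ""
    flags: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)


def masks_from_ground_truth(gt: GroundTruth) -> LabelMasks:
    """Segmentation-free oracle path: wrap the generator's true labels."""
    return LabelMasks(labels=gt.labels.copy(), source="ground_truth")


def _three_class(img: np.ndarray) -> np.ndarray:
    """Assign background/nucleoplasm/chromocenter by increasing intensity."""
    values = np.unique(img)
    if values.size < 2:
        raise ValueError("degenerate intensity histogram: single intensity level")
    if values.size == 2:
        raise ValueError(
            "degenerate intensity histogram: only two levels, cannot separate "
            "three classes"
        )
    if values.size == 3:
        # noiseless synthetic case: classes are the exact levels
        lo, mid = values[0], values[1]
        thresholds = ((lo + mid) / 2.0, (mid + values[2]) / 2.0)
    else:
        thresholds = threshold_multiotsu(img, classes=3)
    return np.digitize(img, bins=thresholds).astype(np.uint8)


def segment_nucleus(
    field_: ImagingField, mode: str = "protein", min_object_px: int = 5
) -> LabelMasks:
    """Three-class intensity segmentation of a single-nucleus image.

    ``mode="protein"`` thresholds the protein channel itself;
    ``mode="counterstain"`` thresholds the DNA channel (which marks
    chromocenters regardless of protein partitioning) and transfers the
    labels.  Chromocenter specks smaller than ``min_object_px`` pixels are
    reassigned to nucleoplasm.
    """
    if mode == "protein":
        img = field_.data
    elif mode == "counterstain":
        if field_.counterstain is None:
            raise ValueError("mode='counterstain' requires a counterstain channel")
        img = field_.counterstain
    else:
        raise ValueError(f"unknown segmentation mode {mode!r}")
    if img.ndim == 3:
        img = img.max(axis=0)  # reduce stacks by maximum projection

    lab = _three_class(np.asarray(img, dtype=float))
    cc = lab == 2
    cc_clean = remove_small_objects(cc, max_size=min_object_px - 1)
    lab = np.where(cc & ~cc_clean, 1, lab).astype(np.uint8)
    labels = np.full(lab.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[lab == 1] = LABEL_NUCLEOPLASM
    labels[lab == 2] = LABEL_CHROMOCENTER
    source = "protein_channel" if mode == "protein" else "counterstain"
    return LabelMasks(labels=labels, source=source)


def partition_coefficient(
    field_: ImagingField,
    masks: LabelMasks,
    construct_id: str = "",
    cell_id: str = "",
    experiment_id: str = "",
    noise_floor_sd: float = 3.0,
) -> PartitionRecord:
    """Partition coefficient for one nucleus from its class masks.

    ``PC = (mean_cc - mean_bg) / (mean_np - mean_bg)``.  Cells whose
    corrected nucleoplasm signal falls below ``noise_floor_sd`` background
    standard deviations are flagged ``"near_noise_floor"`` (exploding-ratio
    guard); callers decide whether to exclude them.
    """
    img = field_.data
    if img.ndim == 3:
        img = img.max(axis=0)
    cc = masks.mask(LABEL_CHROMOCENTER)
    npl = masks.mask(LABEL_NUCLEOPLASM)
    bg = masks.mask(LABEL_BACKGROUND)
    if not cc.any():
        raise ValueError(
            "empty chromocenter mask; consider segmenting the counterstain "
            "channel (mode='counterstain')"
        )
    if not npl.any() or not bg.any():
        raise ValueError("nucleoplasm and background masks must be non-empty")
    mean_cc = float(img[cc].mean())
    mean_np = float(img[npl].mean())
    mean_bg = float(img[bg].mean())
    if mean_np <= mean_bg:
        raise ValueError(
            f"nucleoplasm mean ({mean_np:.3g}) does not exceed background "
            f"({mean_bg:.3g}); partition coefficient undefined"
        )
    flags = []
    bg_sd = float(img[bg].std())
    if mean_np - mean_bg < noise_floor_sd * bg_sd:
        flags.append("near_noise_floor")
    nuc = cc | npl
    return PartitionRecord(
        mean_cc=mean_cc,
        mean_np=mean_np,
        mean_bg=mean_bg,
        mean_nuclear=float(img[nuc].mean()),
        pc=(mean_cc - mean_bg) / (mean_np - mean_bg),
        construct_id=construct_id,
        cell_id=cell_id,
        experiment_id=experiment_id,
        flags=tuple(flags),
        meta={"mask_source": masks.source},
    )


def records_to_frame(records: list[PartitionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "construct_id": [r.construct_id for r in records],
            "cell_id": [r.cell_id for r in records],
            "experiment_id": [r.experiment_id for r in records],
            "mean_cc": [r.mean_cc for r in records],
            "mean_np": [r.mean_np for r in records],
            "mean_bg": [r.mean_bg for r in records],
            "mean_nuclear": [r.mean_nuclear for r in records],
            "pc": [r.pc for r in records],
            "flags": [";".join(r.flags) for r in records],
        }
    )


def normalized_scatter(
    records: list[PartitionRecord] | pd.DataFrame,
    normalization: str = "shared_max",
) -> pd.DataFrame:
    """Per-cell normalized chromocenter vs nucleoplasm intensities.

    Background-corrected chromocenter and nucleoplasm means are divided,
    per construct, by a maximum so different expression levels are
    comparable: ``"shared_max"`` (default) uses the construct-wise maximum
    over both compartments (the y=x diagonal then marks PC = 1);
    ``"per_axis_max"`` normalizes each axis by its own maximum.  The chosen
    normalization and the diagonal reference are recorded in
    ``DataFrame.attrs``.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if len(df) < 2:
        raise ValueError("need at least 2 records")
    out = df.copy()
    out["cc_corr"] = out["mean_cc"] - out["mean_bg"]
    out["np_corr"] = out["mean_np"] - out["mean_bg"]
    out["nuclear_intensity"] = out["mean_nuclear"] - out["mean_bg"]

    def _norm(g: pd.DataFrame) -> pd.DataFrame:
        if normalization == "shared_max":
            m_cc = m_np = max(g["cc_corr"].max(), g["np_corr"].max())
        elif normalization == "per_axis_max":
            m_cc, m_np = g["cc_corr"].max(), g["np_corr"].max()
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        if m_cc <= 0 or m_np <= 0:
            raise ValueError("non-positive normalization maximum")
        g = g.copy()
        g["cc_norm"] = g["cc_corr"] / m_cc
        g["np_norm"] = g["np_corr"] / m_np
        return g

    out = (
        out.groupby("construct_id", group_keys=False)[out.columns]
        .apply(_norm)
        .reset_index(drop=True)
    )
    out.attrs["normalization"] = normalization
    out.attrs["diagonal"] = "y=x marks equal chromocenter and nucleoplasm intensity (PC=1)"
    return out


def saturation_bins(
    records: list[PartitionRecord] | pd.DataFrame,
    bounds: list[float],
    recovery: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group cells into nuclear-intensity bins and summarize each bin.

    ``bounds`` are strictly increasing interior cutpoints on the
    background-corrected mean nuclear intensity; bins are labeled
    ``bin_0 .. bin_k`` from low to high expression.  If ``recovery`` (a
    DataFrame with columns ``cell_id, recovery_100s``) is given, its mean
    per bin is joined.  Empty bins are reported with ``n = 0`` and no
    statistics.
    """
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValueError("bounds must be strictly increasing")
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df = df.copy()
    df["nuclear_corr"] = df["mean_nuclear"] - df["mean_bg"]
    edges = [-np.inf, *bounds, np.inf]
    labels = [f"bin_{i}" for i in range(len(edges) - 1)]
    df["bin"] = pd.cut(df["nuclear_corr"], bins=edges, labels=labels)
    if recovery is not None:
        df = df.merge(recovery, on="cell_id", how="left")

    rows = []
    for name in labels:
        g = df[df["bin"] == name]
        row = {"bin": name, "n": int(len(g))}
        if len(g):
            row["mean_nuclear_intensity"] = float(g["nuclear_corr"].mean())
            row["mean_pc"] = float(g["pc"].mean())
            row["median_pc"] = float(g["pc"].median())
            if "recovery_100s" in g and g["recovery_100s"].notna().any():
                row["mean_recovery_100s"] = float(g["recovery_100s"].mean())
        rows.append(row)
    return pd.DataFrame(rows)
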
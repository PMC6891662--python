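"""Hemocyte morphology, spreading, phagocytosis, and F-actin quantification.

Spreading hemocytes (plasmatocytes with fibroblast-like pseudopods,
granulocytes with short filopodia) lose the near-circular outline of
unspread cells, so spreading is classified from shape: low circularity
(4*pi*area/perimeter^2) or multiple convexity defects.  Phagocytosis is
scored by counting labelled-bacteria spots inside each cell mask; a cell is
phagocytic when it contains at least one spot.  Relative F-actin content is
the ratio of a sample's bound-phalloidin fluorescence to that of a blank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects
from skimage.segmentation import watershed

from .errors import DomainError

ELIGIBLE_TYPES = ("plasmatocyte", "granulocyte")


@dataclass
class CellRecord:
    """Morphology and assay readouts of one segmented hemocyte."""

    cell_id: int
    type: str = "other"  # plasmatocyte | granulocyte | other
    area: float = 0.0  # um^2
    perimeter: float = 0.0  # um
    circularity: float = 1.0  # 4*pi*area/perimeter^2
    convexity_defects: int = 0
    spread: bool = False
    engulfed_count: int = 0
    centroid: tuple = (0.0, 0.0)  # (row, col) px


@dataclass
class FieldSegmentation:
    records: "list[CellRecord]"
    labels: np.ndarray  # 0 = background, i = cell_id of records[i-1]


@dataclass(frozen=True)
class FActinSample:
    group: str
    intensity: float
    blank_intensity: float

    @property
    def relative_intensity(self) -> float:
        return self.intensity / self.blank_intensity


def _safe_otsu_mask(channel: np.ndarray, min_size: int) -> np.ndarray:
    channel = np.asarray(channel, dtype=float)
    if float(np.ptp(channel)) <= 1e-12:
        return np.zeros(channel.shape, dtype=bool)
    mask = channel > threshold_otsu(channel)
    # a threshold on a blank-but-noisy field marks ~half the pixels; reject
    if mask.mean() > 0.5:
        return np.zeros(channel.shape, dtype=bool)
    return remove_small_objects(mask, max_size=min_size)


def _count_convexity_defects(region_mask: np.ndarray, min_defect_area: int) -> int:
    """Concavities of a silhouette: components of (convex hull minus mask)."""
    hull = skmeasure.regionprops(region_mask.astype(int))[0].image_convex
    defects = hull & ~region_mask
    labels, n = ndi.label(defects)
    if n == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    return int((sizes >= min_defect_area).sum())


def extract_cell_features(
    dic_channel: np.ndarray,
    nuclei_channel: np.ndarray,
    pixel_size: float = 1.0,
    min_cell_area: int = 50,
    min_defect_area: int = 10,
) -> FieldSegmentation:
    """Segment hemocytes (nuclei-seeded watershed) and compute shape features.

    An empty field yields an empty record list, not an error.  Cell type is
    left as ``other``; on synthetic fields types come from ground truth and
    on real images a separate low-confidence heuristic would be needed.
    """
    dic = np.asarray(dic_channel, dtype=float)
    nuc = np.asarray(nuclei_channel, dtype=float)
    if dic.shape != nuc.shape:
        raise DomainError("DIC and nuclei channels must have identical shape")

    cell_mask = _safe_otsu_mask(dic, min_size=min_cell_area)
    if not cell_mask.any():
        return FieldSegmentation(records=[], labels=np.zeros(dic.shape, dtype=int))
    cell_mask = ndi.binary_fill_holes(cell_mask)

    nuc_mask = _safe_otsu_mask(nuc, min_size=9)
    markers, n_markers = ndi.label(nuc_mask)
    if n_markers == 0:
        # no usable seeds: fall back to plain connected components
        labels = skmeasure.label(cell_mask)
    else:
        distance = ndi.distance_transform_edt(cell_mask)
        labels = watershed(-distance, markers=markers, mask=cell_mask)
        # cells whose nucleus fell below threshold would vanish; keep them
        orphan = cell_mask & (labels == 0)
        if orphan.any():
            extra = skmeasure.label(orphan)
            extra[extra > 0] += labels.max()
            labels = labels + extra

    records: list[CellRecord] = []
    relabeled = np.zeros_like(labels)
    next_id = 0
    for prop in skmeasure.regionprops(labels):
        if prop.area < min_cell_area:
            continue
        next_id += 1
        relabeled[labels == prop.label] = next_id
        perim = prop.perimeter * pixel_size
        area = prop.area * pixel_size**2
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 1.0
        defects = _count_convexity_defects(prop.image, min_defect_area)
        records.append(
            CellRecord(
                cell_id=next_id,
                area=area,
                perimeter=perim,
                circularity=float(circ),
                convexity_defects=defects,
                centroid=prop.centroid,
            )
        )
    return FieldSegmentation(records=records, labels=relabeled)


def classify_spread(
    record: CellRecord,
    circularity_threshold: float = 0.6,
    defect_threshold: int = 3,
) -> bool:
    """A cell is spread when its outline is irregular enough.

    spread  <=>  circularity < c0  OR  convexity_defects >= d0.
    The thresholds are explicit configuration, calibrated against the
    synthetic renderer's spread/round silhouettes.
    """
    return (
        record.circularity < circularity_threshold
        or record.convexity_defects >= defect_threshold
    )


def apply_spread_classification(
    records: "list[CellRecord]",
    circularity_threshold: float = 0.6,
    defect_threshold: int = 3,
) -> "list[CellRecord]":
    for r in records:
        r.spread = classify_spread(r, circularity_threshold, defect_threshold)
    return records


def spreading_percentage(records: "list[CellRecord]") -> float:
    """Percent of spread cells among plasmatocytes + granulocytes.

    Cells typed ``other`` are excluded from both numerator and denominator,
    matching how the assay counts only the two spreading-competent classes.
    """
    eligible = [r for r in records if r.type in ELIGIBLE_TYPES]
    if not eligible:
        raise DomainError(
            "spreading percentage undefined: no plasmatocytes or granulocytes"
        )
    return 100.0 * sum(r.spread for r in eligible) / len(eligible)


def count_engulfed(
    seg: FieldSegmentation,
    bacteria_channel: np.ndarray,
    min_distance: int = 3,
    threshold: "float | None" = None,
) -> "list[CellRecord]":
    """Count labelled-bacteria spots inside each cell mask.

    Spots are local maxima of the bacteria channel above ``threshold``
    (midpoint between background and channel maximum by default).  A spot
    outside every cell mask is counted for no cell; a cell is phagocytic
    when its count is >= 1.
    """
    chan = np.asarray(bacteria_channel, dtype=float)
    if chan.shape != seg.labels.shape:
        raise DomainError("bacteria channel must match the segmented field shape")
    for r in seg.records:
        r.engulfed_count = 0
    if float(np.ptp(chan)) <= 1e-12:
        return seg.records
    dtype_max = {np.dtype("uint8"): 255, np.dtype("uint16"): 65535}.get(
        np.asarray(bacteria_channel).dtype
    )
    if dtype_max is not None and (np.asarray(bacteria_channel) >= dtype_max).mean() > 0.01:
        warnings.warn("bacteria channel appears saturated; counts may merge spots")
    # smooth so each flat-topped spot yields a single rounded maximum
    smooth = ndi.gaussian_filter(chan, sigma=1.0)
    if threshold is None:
        threshold = 0.5 * (float(np.median(smooth)) + float(smooth.max()))
    peaks = peak_local_max(smooth, min_distance=min_distance, threshold_abs=threshold)
    by_id = {r.cell_id: r for r in seg.records}
    for rr, cc in peaks:
        lab = int(seg.labels[rr, cc])
        if lab in by_id:
            by_id[lab].engulfed_count += 1
    return seg.records


def phagocytosis_percentage(records: "list[CellRecord]") -> float:
    """Percent of cells with at least one engulfed bacterium."""
    if not records:
        raise DomainError("phagocytosis percentage undefined on an empty field")
    return 100.0 * sum(r.engulfed_count >= 1 for r in records) / len(records)


def relative_fluorescence(
    readings: pd.DataFrame,
    blank: "str | float" = "blank",
) -> pd.DataFrame:
    """Per-group relative fluorescence intensity: sample / blank.

    Parameters
    ----------
    readings : DataFrame
        Long format with columns ``group`` and ``intensity``.
    blank : str or float
        Either the label of the blank group (its mean intensity becomes the
        divisor) or a blank intensity value directly.

    Returns
    -------
    DataFrame
        One row per non-blank group: n, mean and standard error of the
        per-replicate ratios intensity / blank.
    """
    if not {"group", "intensity"}.issubset(readings.columns):
        raise DomainError("readings need columns 'group' and 'intensity'")
    if isinstance(blank, str):
        blank_rows = readings[readings["group"] == blank]
        if blank_rows.empty:
            raise DomainError(f"no rows for blank group {blank!r}")
        blank_value = float(blank_rows["intensity"].mean())
        data = readings[readings["group"] != blank]
    else:
        blank_value = float(blank)
        data = readings
    if blank_value <= 0:
        raise DomainError("blank intensity must be positive")

    out = []
    for group, grp in data.groupby("group", sort=False):
        rel = grp["intensity"].to_numpy(dtype=float) / blank_value
        n = len(rel)
        out.append(
            {
                "group": group,
                "n": n,
                "relative_mean": float(rel.mean()),
                "relative_se": float(rel.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            }
        )
    return pd.DataFrame(out)


def match_records_to_truth(
    records: "list[CellRecord]",
    truth: pd.DataFrame,
    max_dist: float = 15.0,
    transfer_types: bool = True,
) -> "list[tuple[CellRecord, int]]":
    """Pair segmented cells with ground-truth cells by nearest centroid.

    Used to evaluate the pipeline on synthetic fields and to transfer the
    ground-truth type labels (the segmented features keep their measured
    values).  Returns (record, truth row index) pairs within ``max_dist`` px.
    """
    if not records:
        return []
    t_pos = truth[["row", "col"]].to_numpy(dtype=float)
    pairs = []
    taken: set[int] = set()
    for r in records:
        d = np.hypot(t_pos[:, 0] - r.centroid[0], t_pos[:, 1] - r.centroid[1])
        order = np.argsort(d)
        for j in order:
            if d[j] > max_dist:
                break
            if j in taken:
                continue
            taken.add(int(j))
            pairs.append((r, int(j)))
            if transfer_types:
                r.type = str(truth.iloc[j]["type"])
            break
    return pairs
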
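"""Puncta, plaque and dystrophy detection on fluorescence channels.

Pre-synaptic puncta are found by multi-scale Laplacian-of-Gaussian blob
detection with size/intensity filtering and sub-pixel centroid refinement.
Plaques are segmented by thresholding (Otsu or fixed) followed by
morphological cleanup.  Dystrophic swellings are the enlarged subset of the
detected puncta.  Detected puncta are snapped to manually annotated axon
traces by perpendicular distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import blob_log
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import disk
from shapely.geometry import Polygon

from typing import TYPE_CHECKING

if TYPE_CHECKING:
    from .spatial import AxonTrace

logger = logging.getLogger(__name__)

__all__ = [
    "PixelCalibration",
    "DetectionParams",
    "PlaqueRegion",
    "detect_puncta",
    "segment_plaques",
    "detect_dystrophies",
    "assign_puncta_to_axons",
]

#: columns of a puncta table
PUNCTA_COLUMNS = [
    "punctum_id",
    "x_um",
    "y_um",
    "equivalent_diameter_um",
    "peak_intensity",
    "area_um2",
    "channel",
]


@dataclass(frozen=True)
class PixelCalibration:
    """Pixel-to-micrometre mapping.  Pixel (i, j) centre sits at
    ((j + 0.5) * um_per_px_x, (i + 0.5) * um_per_px_y), origin top-left."""

    um_per_px_x: float
    um_per_px_y: float
    width_px: int
    height_px: int

    def __post_init__(self) -> None:
        if self.um_per_px_x <= 0 or self.um_per_px_y <= 0:
            raise ValueError("um_per_px must be > 0")

    @property
    def field_size_um(self) -> tuple[float, float]:
        return (self.width_px * self.um_per_px_x, self.height_px * self.um_per_px_y)

    def px_to_um(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return np.column_stack(
            [(np.asarray(cols) + 0.5) * self.um_per_px_x,
             (np.asarray(rows) + 0.5) * self.um_per_px_y]
        )


@dataclass(frozen=True)
class DetectionParams:
    """All detector thresholds, exposed for provenance.

    ``detection_threshold`` is relative to the image's robust noise scale
    (1.4826 * MAD): the LoG response must exceed
    ``detection_threshold * robust_sigma``.  ``blob_sigma_range_um`` spans
    the expected Gaussian scales of boutons through dystrophies; apparent
    object diameter is reported as 2*sqrt(2)*sigma of the best-responding
    scale.
    """

    blob_sigma_range_um: tuple[float, float] = (0.25, 1.4)
    n_sigma_scales: int = 6
    detection_threshold: float = 1.5
    min_punctum_area_um2: float = 0.05
    max_punctum_area_um2: float = 50.0
    plaque_threshold_method: str = "otsu"  # "otsu" | "fixed"
    plaque_fixed_threshold: float = 50.0
    plaque_min_area_um2: float = 10.0
    plaque_closing_radius_um: float = 0.5
    dystrophy_min_diameter_um: float = 2.5
    dystrophy_min_fill: float = 0.6
    snap_radius_um: float = 1.0
    coloc_max_dist_um: float = 0.5
    merge_radius_sigma: float = 1.0  # merge blobs closer than this many sigma
    saturation_warn_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.blob_sigma_range_um[0] >= self.blob_sigma_range_um[1]:
            raise ValueError("blob_sigma_range_um must be (min, max) with min < max")
        if self.min_punctum_area_um2 >= self.max_punctum_area_um2:
            raise ValueError("min_punctum_area_um2 must be below max")
        if self.snap_radius_um <= 0:
            raise ValueError("snap_radius_um must be > 0")

    def as_provenance(self) -> dict:
        return asdict(self)


@dataclass
class PlaqueRegion:
    """A segmented plaque: labelled mask reference, boundary polygon and area."""

    plaque_id: int
    boundary_polygon_um: Polygon
    area_um2: float
    centroid_um: tuple[float, float]
    label_value: int = 0


def _robust_sigma(image: np.ndarray) -> float:
    med = np.median(image)
    mad = np.median(np.abs(image - med))
    return float(1.4826 * mad)


def detect_puncta(
    channel_image: np.ndarray,
    calib: PixelCalibration,
    params: DetectionParams | None = None,
    channel: str = "HA",
    saturation_level: float | None = None,
) -> pd.DataFrame:
    """Detect bright puncta in a single channel.

    Multi-scale LoG blob detection; near-duplicate blobs within one sigma of
    each other are merged keeping the higher peak; centroids are refined to
    sub-pixel precision by local intensity-weighted averaging and reported
    in micrometres.  A flat or empty image yields an empty table.
    """
    params = params or DetectionParams()
    img = np.asarray(channel_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("detect_puncta expects a single-channel 2D image")

    if saturation_level is not None:
        frac = float(np.mean(img >= saturation_level))
        if frac > params.saturation_warn_fraction:
            warnings.warn(
                f"{frac:.1%} of pixels at or above saturation level", stacklevel=2
            )

    sigma_noise = _robust_sigma(img)
    if sigma_noise == 0 and img.max() == img.min():
        return _empty_puncta(channel)

    upp = calib.um_per_px_x
    s_min = params.blob_sigma_range_um[0] / upp
    s_max = params.blob_sigma_range_um[1] / upp
    # floor keeps noise-free images from tripping on numerical ripple
    floor = 1e-6 * float(img.max() - img.min())
    thr = params.detection_threshold * max(sigma_noise, floor, 1e-12)
    # overlap=1 disables skimage's internal pruning (it would discard a
    # resolved pair of fine blobs in favour of one coarse blob spanning
    # both); duplicate handling is done explicitly in _merge_duplicates.
    blobs = blob_log(
        img - np.median(img),
        min_sigma=s_min,
        max_sigma=s_max,
        num_sigma=params.n_sigma_scales,
        threshold=thr,
        overlap=1.0,
    )
    if len(blobs) == 0:
        return _empty_puncta(channel)

    rows_px, cols_px, sigmas_px = blobs[:, 0], blobs[:, 1], blobs[:, 2]
    peaks = img[rows_px.astype(int), cols_px.astype(int)]

    keep = _merge_duplicates(rows_px, cols_px, sigmas_px, peaks, params)
    rows_px, cols_px, sigmas_px, peaks = (
        rows_px[keep], cols_px[keep], sigmas_px[keep], peaks[keep]
    )

    rows_ref, cols_ref = _refine_centroids(img, rows_px, cols_px, sigmas_px)
    fill = _fill_factor(img, rows_px, cols_px, sigmas_px)
    diam_um = 2.0 * np.sqrt(2.0) * sigmas_px * upp
    area_um2 = np.pi * (diam_um / 2.0) ** 2

    ok = (area_um2 >= params.min_punctum_area_um2) & (
        area_um2 <= params.max_punctum_area_um2
    )
    xy = calib.px_to_um(rows_ref[ok], cols_ref[ok])
    out = pd.DataFrame(
        {
            "punctum_id": np.arange(int(ok.sum())),
            "x_um": xy[:, 0] if len(xy) else np.empty(0),
            "y_um": xy[:, 1] if len(xy) else np.empty(0),
            "equivalent_diameter_um": diam_um[ok],
            "peak_intensity": peaks[ok],
            "area_um2": area_um2[ok],
            "fill_factor": fill[ok],
            "channel": channel,
        }
    )
    return out


def _empty_puncta(channel: str) -> pd.DataFrame:
    out = pd.DataFrame({c: pd.Series(dtype=float) for c in PUNCTA_COLUMNS})
    out["channel"] = out["channel"].astype(object)
    out["punctum_id"] = out["punctum_id"].astype(int)
    return out


def _merge_duplicates(
    rows: np.ndarray,
    cols: np.ndarray,
    sigmas: np.ndarray,
    peaks: np.ndarray,
    params: DetectionParams,
) -> np.ndarray:
    """Two-stage suppression of redundant scale-space maxima.

    Stage 1 (duplicates): keep the higher-peak blob when two centroids lie
    closer than ``merge_radius_sigma`` times the smaller blob sigma.
    Stage 2 (containment): drop a coarse blob whose support already holds a
    kept, distinctly finer blob — the coarse maximum is the scale-space echo
    of an unresolved pair, not a separate object.
    """
    order = np.argsort(-peaks)
    pts = np.column_stack([rows, cols])
    tree = cKDTree(pts)
    keep = np.zeros(len(rows), dtype=bool)
    suppressed = np.zeros(len(rows), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep[i] = True
        r = params.merge_radius_sigma * sigmas[i]
        for j in tree.query_ball_point(pts[i], r=r * 2.0):
            if j == i or keep[j]:
                continue
            d = np.hypot(rows[i] - rows[j], cols[i] - cols[j])
            if d < params.merge_radius_sigma * min(sigmas[i], sigmas[j]):
                suppressed[j] = True

    kept_idx = np.flatnonzero(keep)
    for i in kept_idx[np.argsort(-sigmas[kept_idx])]:
        for j in tree.query_ball_point(pts[i], r=sigmas[i]):
            if j == i or not keep[j]:
                continue
            if sigmas[j] <= 0.7 * sigmas[i]:
                keep[i] = False
                break
    return keep


def _fill_factor(
    img: np.ndarray, rows: np.ndarray, cols: np.ndarray, sigmas: np.ndarray
) -> np.ndarray:
    """Flux consistency of a blob with a filled Gaussian of its detected scale.

    Score = (background-subtracted flux within 2.5 sigma) / (peak x 2 pi
    sigma^2).  A solid Gaussian profile scores ~1; a loose cluster of much
    smaller spots that merely triggers a coarse scale scores well below 1,
    because its flux is far less than its apparent size implies.
    """
    h, w = img.shape
    out = np.ones(len(rows))
    for n, (r, c, s) in enumerate(zip(rows, cols, sigmas)):
        half = max(3, int(np.ceil(2.5 * s)))
        i0, i1 = max(int(r) - half, 0), min(int(r) + half + 1, h)
        j0, j1 = max(int(c) - half, 0), min(int(c) + half + 1, w)
        win = img[i0:i1, j0:j1]
        if win.size < 9:
            continue
        border = np.concatenate([win[0], win[-1], win[1:-1, 0], win[1:-1, -1]])
        bg = float(np.median(border))
        ii, jj = np.mgrid[i0:i1, j0:j1]
        in_disk = (ii - r) ** 2 + (jj - c) ** 2 <= (2.5 * s) ** 2
        flux = float(np.clip(win - bg, 0, None)[in_disk].sum())
        peak = float(img[int(r), int(c)] - bg)
        if peak <= 0:
            out[n] = 0.0
            continue
        out[n] = flux / (peak * 2.0 * np.pi * s**2)
    return out


def _refine_centroids(
    img: np.ndarray, rows: np.ndarray, cols: np.ndarray, sigmas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-pixel refinement: background-subtracted intensity centroid in a
    window of ~2 sigma around the integer peak."""
    h, w = img.shape
    out_r = np.empty(len(rows))
    out_c = np.empty(len(cols))
    for n, (r, c, s) in enumerate(zip(rows, cols, sigmas)):
        half = max(2, int(np.ceil(2.0 * s)))
        i0, i1 = max(int(r) - half, 0), min(int(r) + half + 1, h)
        j0, j1 = max(int(c) - half, 0), min(int(c) + half + 1, w)
        win = img[i0:i1, j0:j1]
        wgt = np.clip(win - win.min(), 0, None)
        tot = wgt.sum()
        if tot == 0:
            out_r[n], out_c[n] = r, c
            continue
        ii, jj = np.mgrid[i0:i1, j0:j1]
        out_r[n] = float((wgt * ii).sum() / tot)
        out_c[n] = float((wgt * jj).sum() / tot)
    return out_r, out_c


def segment_plaques(
    x34_image: np.ndarray,
    calib: PixelCalibration,
    params: DetectionParams | None = None,
) -> list[PlaqueRegion]:
    """Segment dense-core plaques in the X34 channel.

    Threshold (Otsu or fixed) -> morphological closing -> hole filling ->
    connected components -> minimum-area filter.  Boundary polygons are
    extracted at the 0.5 iso-contour of each component and reported in um.
    """
    params = params or DetectionParams()
    img = np.asarray(x34_image, dtype=np.float64)
    if params.plaque_threshold_method == "otsu":
        if img.max() == img.min():
            logger.info("segment_plaques: flat image, no plaques")
            return []
        thr = threshold_otsu(img)
    elif params.plaque_threshold_method == "fixed":
        thr = params.plaque_fixed_threshold
    else:
        raise ValueError(
            f"unknown plaque_threshold_method {params.plaque_threshold_method!r}"
        )
    mask = img > thr
    r_px = max(1, int(round(params.plaque_closing_radius_um / calib.um_per_px_x)))
    mask = ndi.binary_closing(mask, structure=disk(r_px))
    mask = ndi.binary_fill_holes(mask)
    labels = label(mask)
    px_area = calib.um_per_px_x * calib.um_per_px_y
    regions: list[PlaqueRegion] = []
    for prop in regionprops(labels):
        area_um2 = prop.area * px_area
        if area_um2 < params.plaque_min_area_um2:
            continue
        comp = labels == prop.label
        contours = find_contours(comp.astype(float), 0.5)
        if not contours:
            continue
        contour = max(contours, key=len)
        xy = calib.px_to_um(contour[:, 0], contour[:, 1])
        poly = Polygon(xy)
        if not poly.is_valid:
            poly = poly.buffer(0)
        cy, cx = prop.centroid
        regions.append(
            PlaqueRegion(
                plaque_id=len(regions),
                boundary_polygon_um=poly,
                area_um2=area_um2,
                centroid_um=(
                    (cx + 0.5) * calib.um_per_px_x,
                    (cy + 0.5) * calib.um_per_px_y,
                ),
                label_value=prop.label,
            )
        )
    if not regions:
        logger.info("segment_plaques: no components above threshold/min area")
    return regions


def detect_dystrophies(
    ha_puncta: pd.DataFrame, params: DetectionParams | None = None
) -> pd.DataFrame:
    """Subset of HA puncta large enough to count as dystrophic swellings.

    Returns the puncta with equivalent diameter >= the dystrophy threshold,
    relabelled channel 'dystrophy'; disjoint by construction from the bouton
    set used in density analyses (callers should drop these ids from the
    bouton table).  When the table carries a ``fill_factor`` column (added
    by :func:`detect_puncta`), candidates must also be flux-consistent with
    a solid blob — this rejects loose multi-bouton clusters that trigger a
    coarse detection scale without being swellings.
    """
    params = params or DetectionParams()
    sel = ha_puncta["equivalent_diameter_um"] >= params.dystrophy_min_diameter_um
    if "fill_factor" in ha_puncta.columns:
        sel &= ha_puncta["fill_factor"] >= params.dystrophy_min_fill
    out = ha_puncta[sel].copy().reset_index(drop=True)
    out["channel"] = "dystrophy"
    return out


def assign_puncta_to_axons(
    puncta: pd.DataFrame,
    axons: "list[AxonTrace]",
    params: DetectionParams | None = None,
) -> pd.DataFrame:
    """Snap puncta to the nearest axon trace.

    Each punctum is assigned to the axon with the smallest perpendicular
    distance, provided that distance is within ``snap_radius_um``; the
    arc-length position of the orthogonal projection is recorded.  Ties are
    broken by lower axon id.  Adds columns axon_id (nullable Int64), arc_um
    and snap_dist_um; the number of ambiguous assignments (second axon also
    within the snap radius) is logged.
    """
    params = params or DetectionParams()
    out = puncta.copy().reset_index(drop=True)
    n = len(out)
    best_d = np.full(n, np.inf)
    second_d = np.full(n, np.inf)
    best_id = np.full(n, -1, dtype=int)
    best_arc = np.full(n, np.nan)
    if n:
        xy = out[["x_um", "y_um"]].to_numpy()
        for ax in sorted(axons, key=lambda a: a.axon_id):
            d, arc = ax.project(xy)
            better = d < best_d
            second_d = np.where(better, best_d, np.minimum(second_d, d))
            best_arc = np.where(better, arc, best_arc)
            best_id = np.where(better, ax.axon_id, best_id)
            best_d = np.where(better, d, best_d)
    assigned = best_d <= params.snap_radius_um
    ambiguous = int(np.sum(assigned & (second_d <= params.snap_radius_um)))
    if ambiguous:
        logger.info("assign_puncta_to_axons: %d ambiguous assignment(s)", ambiguous)
    out["axon_id"] = pd.array(
        np.where(assigned, best_id, -1), dtype="Int64"
    )
    out.loc[~assigned, "axon_id"] = pd.NA
    out["arc_um"] = np.where(assigned, best_arc, np.nan)
    out["snap_dist_um"] = np.where(assigned, best_d, np.nan)
    return out
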
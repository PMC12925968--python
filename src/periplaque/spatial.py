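"""Spatial statistics of boutons around plaques.

Implements the quantities behind the peri-plaque analysis: a signed
Euclidean distance field from segmented plaques, concentric-annulus density
profiles (plaque interior + rings, normalized to ROI area and expressed as
percentages per subject), per-axon closest approach to the nearest plaque,
mean distance to the three nearest same-axon boutons (NND-3), linear bouton
density, pre/post colocalization by greedy nearest-pair matching, and the
fraction of plaques bearing at least one dystrophic neurite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import distance_transform_edt
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "AxonTrace",
    "AnnulusBinSpec",
    "distance_field",
    "annulus_profile",
    "axon_closest_approach",
    "nnd3",
    "linear_density",
    "subject_linear_density",
    "coloc_fraction",
    "dn_per_plaque",
    "axon_metrics_table",
]

#: minimum bouton count for an axon to enter nearest-neighbour statistics
MIN_BOUTONS_FOR_NND = 4

#: minimum summed annotated axon length (um) for a subject to enter
#: subject-level bouton-density comparisons
MIN_SUBJECT_AXON_LENGTH_UM = 1000.0


@dataclass
class AxonTrace:
    """An annotated axon: ordered 2D polyline with arc-length parameterization."""

    axon_id: int
    vertices_um: np.ndarray  # (N, 2), N >= 2
    subject_id: str | None = None
    cumulative_arc_um: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices_um = np.asarray(self.vertices_um, dtype=float)
        if self.vertices_um.ndim != 2 or self.vertices_um.shape[0] < 2:
            raise ValueError("an axon trace needs at least 2 vertices")
        seg = np.diff(self.vertices_um, axis=0)
        steps = np.hypot(seg[:, 0], seg[:, 1])
        self.cumulative_arc_um = np.concatenate([[0.0], np.cumsum(steps)])
        if self.total_length_um <= 0:
            raise ValueError("axon trace has zero length")

    @property
    def total_length_um(self) -> float:
        return float(self.cumulative_arc_um[-1])

    def point_at(self, arc_um: np.ndarray) -> np.ndarray:
        """Interpolate xy positions at the given arc-length positions."""
        arc = np.atleast_1d(np.asarray(arc_um, dtype=float))
        x = np.interp(arc, self.cumulative_arc_um, self.vertices_um[:, 0])
        y = np.interp(arc, self.cumulative_arc_um, self.vertices_um[:, 1])
        return np.column_stack([x, y])

    def resample(self, step_um: float) -> tuple[np.ndarray, np.ndarray]:
        """Dense arc positions (spacing <= step_um) and their xy points."""
        n = max(2, int(np.ceil(self.total_length_um / step_um)) + 1)
        arc = np.linspace(0.0, self.total_length_um, n)
        return arc, self.point_at(arc)

    def project(self, xy_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Orthogonal projection of points onto the polyline.

        Returns (distance, arc_position) per query point, minimizing over
        all segments.
        """
        pts = np.atleast_2d(np.asarray(xy_um, dtype=float))
        a = self.vertices_um[:-1]  # (S, 2)
        b = self.vertices_um[1:]
        ab = b - a
        len2 = np.einsum("ij,ij->i", ab, ab)
        len2 = np.where(len2 == 0, 1.0, len2)
        # t: (P, S) clamped projection parameter
        diff = pts[:, None, :] - a[None, :, :]
        t = np.clip(np.einsum("psj,sj->ps", diff, ab) / len2, 0.0, 1.0)
        proj = a[None, :, :] + t[..., None] * ab[None, :, :]
        d = np.linalg.norm(pts[:, None, :] - proj, axis=2)
        best = np.argmin(d, axis=1)
        idx = np.arange(len(pts))
        seg_len = np.sqrt(np.einsum("ij,ij->i", ab, ab))
        arc = self.cumulative_arc_um[best] + t[idx, best] * seg_len[best]
        return d[idx, best], arc


@dataclass(frozen=True)
class AnnulusBinSpec:
    """Concentric distance bins around the plaque boundary.

    ``ring_edges_um`` are the outer-ring edges (starting at 0 = the plaque
    boundary); ``includes_interior`` adds a separate plaque-interior bin in
    front.  The defaults give five bins: plaque interior, 0-5, 5-15, 15-25
    and 25-35 um, with the outermost ring serving as the far-field reference.
    """

    includes_interior: bool = True
    ring_edges_um: tuple[float, ...] = (0.0, 5.0, 15.0, 25.0, 35.0)

    def __post_init__(self) -> None:
        e = np.asarray(self.ring_edges_um)
        if e[0] != 0 or np.any(np.diff(e) <= 0):
            raise ValueError("ring edges must start at 0 and increase strictly")

    @property
    def labels(self) -> list[str]:
        lab = [
            f"{_fmt(a)}-{_fmt(b)} um"
            for a, b in zip(self.ring_edges_um[:-1], self.ring_edges_um[1:])
        ]
        return (["plaque"] + lab) if self.includes_interior else lab

    @property
    def reference_label(self) -> str:
        return self.labels[-1]

    def classify(self, signed_dist_um: np.ndarray) -> np.ndarray:
        """Map signed plaque distances to bin indices (-1 = beyond last edge)."""
        d = np.asarray(signed_dist_um, dtype=float)
        edges = np.asarray(self.ring_edges_um)
        out = np.full(d.shape, -1, dtype=int)
        offset = 1 if self.includes_interior else 0
        if self.includes_interior:
            out[d < 0] = 0
        ring = np.searchsorted(edges, d, side="right") - 1
        in_ring = (d >= 0) & (ring < len(edges) - 1)
        out[in_ring] = ring[in_ring] + offset
        return out

    def axon_labels(self) -> list[str]:
        """Ring labels for axon closest-approach bins (interior folded into
        the first ring, since an axon entering a plaque passes within it)."""
        return [
            f"{_fmt(a)}-{_fmt(b)} um"
            for a, b in zip(self.ring_edges_um[:-1], self.ring_edges_um[1:])
        ]


def _fmt(x: float) -> str:
    return f"{x:g}"


# ---------------------------------------------------------------------------
# distance field


def distance_field(
    plaque_masks_or_polygons,
    calib,
) -> np.ndarray:
    """Signed Euclidean distance map (um) from the union plaque mask.

    Accepts either a boolean union mask or a list of boundary polygons (um);
    pixels inside a plaque carry negative distance to the boundary.
    Anisotropic pixel sizes are honoured via the EDT sampling argument.
    With no plaques the field is +inf everywhere (all points farther than
    any bin).
    """
    shape = (calib.height_px, calib.width_px)
    sampling = (calib.um_per_px_y, calib.um_per_px_x)
    if isinstance(plaque_masks_or_polygons, np.ndarray):
        mask = plaque_masks_or_polygons.astype(bool)
    else:
        polys = list(plaque_masks_or_polygons)
        if len(polys) == 0:
            logger.info("distance_field: no plaques, returning +inf field")
            return np.full(shape, np.inf)
        from .simulate import _rasterize_polygons  # local import: avoid cycle

        mask = _rasterize_polygons(polys, shape, calib.um_per_px_x)
    if not mask.any():
        logger.info("distance_field: empty plaque mask, returning +inf field")
        return np.full(shape, np.inf)
    outside = distance_transform_edt(~mask, sampling=sampling)
    inside = distance_transform_edt(mask, sampling=sampling)
    return np.where(mask, -inside, outside)


def _sample_field(dfield: np.ndarray, xy_um: np.ndarray, calib) -> np.ndarray:
    """Nearest-pixel lookup of the distance field at um coordinates."""
    jj = np.clip(
        np.round(xy_um[:, 0] / calib.um_per_px_x - 0.5).astype(int),
        0,
        dfield.shape[1] - 1,
    )
    ii = np.clip(
        np.round(xy_um[:, 1] / calib.um_per_px_y - 0.5).astype(int),
        0,
        dfield.shape[0] - 1,
    )
    return dfield[ii, jj]


# ---------------------------------------------------------------------------
# annulus profile


def annulus_profile(
    boutons: pd.DataFrame,
    dfield: np.ndarray,
    calib,
    bins: AnnulusBinSpec | None = None,
    roi_mask: np.ndarray | None = None,
    subject_id: str | None = None,
    bouton_distances_um: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-bin bouton counts, areas, densities and normalized percentages.

    Each bouton is classified by the distance-field value at its centroid,
    or by ``bouton_distances_um`` (exact signed plaque distances, e.g. from
    polygon geometry) when provided — exact distances avoid misclassifying
    boutons that sit within a pixel of a bin edge.  Bin area is the pixel
    count of the bin intersected with the ROI mask times the pixel area;
    density = count / area; the per-subject percentage normalizes each bin
    density by the sum of densities, so percentages sum to 100 when any
    bouton is present.  Zero-area bins are flagged and excluded from the
    normalization.  Bins whose pixels touch the image border are flagged
    ``clipped``.
    """
    bins = bins or AnnulusBinSpec()
    labels = bins.labels
    px_area = calib.um_per_px_x * calib.um_per_px_y
    if roi_mask is None:
        roi_mask = np.ones(dfield.shape, dtype=bool)

    pix_bin = bins.classify(dfield)
    areas = np.zeros(len(labels))
    clipped = np.zeros(len(labels), dtype=bool)
    border = np.zeros(dfield.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for k in range(len(labels)):
        sel = (pix_bin == k) & roi_mask
        areas[k] = sel.sum() * px_area
        clipped[k] = bool((sel & border).any())

    if len(boutons):
        if bouton_distances_um is not None:
            d_bouton = np.asarray(bouton_distances_um, dtype=float)
        else:
            xy = boutons[["x_um", "y_um"]].to_numpy()
            d_bouton = _sample_field(dfield, xy, calib)
        bb = bins.classify(d_bouton)
        counts = np.bincount(bb[bb >= 0], minlength=len(labels))[: len(labels)]
    else:
        counts = np.zeros(len(labels), dtype=int)

    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(areas > 0, counts / np.where(areas > 0, areas, 1), np.nan)
    valid = areas > 0
    if not valid.all():
        logger.warning(
            "annulus_profile: %d bin(s) with zero area excluded from "
            "percentage normalization",
            int((~valid).sum()),
        )
    total = np.nansum(density[valid])
    if total > 0:
        percentage = np.where(valid, density / total * 100.0, np.nan)
    else:
        percentage = np.full(len(labels), np.nan)

    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "bin_label": labels,
            "area_um2": areas,
            "bouton_count": counts,
            "density_per_um2": density,
            "percentage": percentage,
            "clipped": clipped,
        }
    )


def annulus_profile_exact(
    boutons: pd.DataFrame,
    plaque_polygons: list[Polygon],
    field_size_um: tuple[float, float],
    bins: AnnulusBinSpec | None = None,
    subject_id: str | None = None,
    bouton_distances_um: np.ndarray | None = None,
) -> pd.DataFrame:
    """Vector-geometry annulus profile (no rasterization).

    Bin areas come from buffered plaque-union polygons clipped to the field
    rectangle; bouton distances are exact signed distances to the plaque
    union boundary.  Counts and areas therefore share one geometric
    definition, which matters for the narrow interior and first-ring bins
    where pixelization bias is largest.  Output schema matches
    :func:`annulus_profile`; ``clipped`` flags rings that hit the field
    border.
    """
    from shapely.geometry import box

    bins = bins or AnnulusBinSpec()
    labels = bins.labels
    field = box(0.0, 0.0, field_size_um[0], field_size_um[1])
    union = shapely.union_all(plaque_polygons) if plaque_polygons else None

    areas = np.zeros(len(labels))
    clipped = np.zeros(len(labels), dtype=bool)
    if union is not None:
        interior_area = union.intersection(field).area
        edges = bins.ring_edges_um
        cum = [union.buffer(e).intersection(field) if e > 0 else union.intersection(field) for e in edges]
        ring_areas = [cum[i + 1].area - cum[i].area for i in range(len(edges) - 1)]
        ring_clip = [
            not field.contains(union.buffer(edges[i + 1]))
            for i in range(len(edges) - 1)
        ]
        if bins.includes_interior:
            areas[0] = interior_area
            clipped[0] = not field.contains(union)
            areas[1:] = ring_areas
            clipped[1:] = ring_clip
        else:
            areas[:] = ring_areas
            clipped[:] = ring_clip

    if len(boutons):
        if bouton_distances_um is not None:
            d_bouton = np.asarray(bouton_distances_um, dtype=float)
        elif union is not None:
            xy = boutons[["x_um", "y_um"]].to_numpy()
            pts = shapely.points(xy[:, 0], xy[:, 1])
            inside = shapely.contains(union, pts)
            dist = shapely.distance(pts, shapely.boundary(union))
            d_bouton = np.where(inside, -dist, dist)
        else:
            d_bouton = np.full(len(boutons), np.inf)
        bb = bins.classify(d_bouton)
        counts = np.bincount(bb[bb >= 0], minlength=len(labels))[: len(labels)]
    else:
        counts = np.zeros(len(labels), dtype=int)

    with np.errstate(divide="ignore", invalid="ignore"):
        density = np.where(areas > 0, counts / np.where(areas > 0, areas, 1), np.nan)
    valid = areas > 0
    total = np.nansum(density[valid])
    percentage = (
        np.where(valid, density / total * 100.0, np.nan)
        if total > 0
        else np.full(len(labels), np.nan)
    )
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "bin_label": labels,
            "area_um2": areas,
            "bouton_count": counts,
            "density_per_um2": density,
            "percentage": percentage,
            "clipped": clipped,
        }
    )


def depletion_radius_estimate(
    profile: pd.DataFrame, bins: AnnulusBinSpec | None = None,
    recovery_fraction: float = 0.9,
) -> float:
    """Estimate the spatial extent of bouton loss from an annulus profile.

    Returns the inner edge (um) of the first ring whose density reaches at
    least ``recovery_fraction`` of the reference (outermost) ring density —
    i.e. where the profile has recovered to baseline.  NaN when no ring
    recovers or the reference density is undefined.
    """
    bins = bins or AnnulusBinSpec()
    prof = profile.set_index("bin_label")
    ref = prof.loc[bins.reference_label, "density_per_um2"]
    if not np.isfinite(ref) or ref <= 0:
        return float("nan")
    ring_labels = bins.axon_labels()  # ring bins in order, interior excluded
    for label, inner_edge in zip(ring_labels, bins.ring_edges_um[:-1]):
        d = prof.loc[label, "density_per_um2"]
        if np.isfinite(d) and d >= recovery_fraction * ref:
            return float(inner_edge)
    return float("nan")


# ---------------------------------------------------------------------------
# per-axon statistics


def axon_closest_approach(
    axon: AxonTrace,
    dfield: np.ndarray,
    calib,
    bins: AnnulusBinSpec | None = None,
) -> tuple[float, str | None]:
    """Minimum signed plaque distance along the axon, with its ring label.

    The polyline is resampled at the pixel pitch or finer.  The interior is
    folded into the first ring (an axon entering a plaque passes within it);
    axons whose closest approach exceeds the outermost edge return label
    ``None`` and are excluded from plaque-conditioned analyses.
    """
    bins = bins or AnnulusBinSpec()
    step = min(calib.um_per_px_x, calib.um_per_px_y)
    _, xy = axon.resample(step_um=step)
    d = float(np.min(_sample_field(dfield, xy, calib)))
    edges = np.asarray(bins.ring_edges_um)
    if d >= edges[-1]:
        return d, None
    ring = max(int(np.searchsorted(edges, max(d, 0.0), side="right")) - 1, 0)
    ring = min(ring, len(edges) - 2)
    return d, bins.axon_labels()[ring]


def nnd3(
    arc_positions_um: np.ndarray,
    k: int = 3,
    xy_um: np.ndarray | None = None,
    mode: str = "geodesic",
) -> tuple[np.ndarray, float] | None:
    """Mean distance from each bouton to its *k* nearest same-axon boutons.

    ``mode='geodesic'`` measures along the trace (|arc_i - arc_j|);
    ``mode='euclidean'`` uses straight-line centroid distances (requires
    ``xy_um``).  Axons with fewer than k+1 boutons are excluded (returns
    ``None``), reflecting the minimum-of-four-synapses rule for k=3.
    Returns (per-bouton means, axon mean).
    """
    arc = np.asarray(arc_positions_um, dtype=float)
    n = len(arc)
    if n < k + 1:
        return None
    if mode == "geodesic":
        dmat = np.abs(arc[:, None] - arc[None, :])
    elif mode == "euclidean":
        if xy_um is None:
            raise ValueError("euclidean mode requires xy_um")
        xy = np.asarray(xy_um, dtype=float)
        dmat = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(np.abs(arc[:, None] - arc[None, :])[~np.eye(n, dtype=bool)] == 0):
        logger.info("nnd3: duplicate arc positions present (distance 0 allowed)")
    np.fill_diagonal(dmat, np.inf)
    nearest = np.sort(dmat, axis=1)[:, :k]
    per_bouton = nearest.mean(axis=1)
    return per_bouton, float(per_bouton.mean())


def linear_density(total_length_um: float, n_boutons: int) -> float:
    """Boutons per 100 um of axon."""
    if total_length_um <= 0:
        raise ValueError("axon length must be > 0")
    return 100.0 * n_boutons / total_length_um


def subject_linear_density(
    axon_table: pd.DataFrame,
    min_total_length_um: float = MIN_SUBJECT_AXON_LENGTH_UM,
) -> pd.DataFrame:
    """Per-subject bouton density: total boutons / total annotated length.

    Subjects whose summed annotated length does not exceed
    ``min_total_length_um`` are flagged ``included=False`` and drop out of
    group comparisons.  Expects columns subject_id, total_length_um,
    n_boutons.
    """
    g = axon_table.groupby("subject_id", sort=True).agg(
        total_length_um=("total_length_um", "sum"), n_boutons=("n_boutons", "sum")
    )
    g["density_per_100um"] = 100.0 * g["n_boutons"] / g["total_length_um"]
    g["included"] = g["total_length_um"] > min_total_length_um
    return g.reset_index()


def axon_metrics_table(
    axons: list[AxonTrace],
    boutons: pd.DataFrame,
    dfield: np.ndarray,
    calib,
    bins: AnnulusBinSpec | None = None,
    nnd_mode: str = "geodesic",
) -> pd.DataFrame:
    """Per-axon summary: closest approach + bin, bouton count, linear density,
    NND-3 (NaN when fewer than four boutons).

    ``boutons`` must carry axon_id and arc_um columns (e.g. from
    ``detect.assign_puncta_to_axons`` or simulator ground truth).
    """
    bins = bins or AnnulusBinSpec()
    rows = []
    for ax in axons:
        sub = boutons[boutons["axon_id"] == ax.axon_id]
        ca, label = axon_closest_approach(ax, dfield, calib, bins)
        res = nnd3(
            sub["arc_um"].to_numpy(),
            xy_um=sub[["x_um", "y_um"]].to_numpy() if len(sub) else None,
            mode=nnd_mode,
        )
        rows.append(
            {
                "axon_id": ax.axon_id,
                "subject_id": ax.subject_id,
                "closest_approach_um": ca,
                "distance_bin_label": label,
                "n_boutons": len(sub),
                "total_length_um": ax.total_length_um,
                "linear_density_per_100um": linear_density(
                    ax.total_length_um, len(sub)
                ),
                "nnd3_mean_um": np.nan if res is None else res[1],
                "included_in_nnd": res is not None,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# colocalization and dystrophy association


def coloc_fraction(
    pre_xy_um: np.ndarray,
    post_xy_um: np.ndarray,
    max_dist_um: float,
) -> tuple[float, np.ndarray]:
    """Percentage of pre-synaptic puncta with a matched post-synaptic punctum.

    Greedy one-to-one matching by ascending centroid distance, each post
    punctum used at most once, pairs farther than ``max_dist_um`` never
    matched.  Returns (percentage, matched pair index array of shape (M, 2)
    with columns [pre_index, post_index]).  With no pre puncta the fraction
    is undefined (NaN).
    """
    pre = np.atleast_2d(np.asarray(pre_xy_um, dtype=float))
    post = np.atleast_2d(np.asarray(post_xy_um, dtype=float))
    if pre.size == 0:
        return float("nan"), np.empty((0, 2), dtype=int)
    if post.size == 0:
        return 0.0, np.empty((0, 2), dtype=int)
    tree = cKDTree(post)
    cand = tree.query_ball_point(pre, r=max_dist_um)
    pairs = [
        (float(np.hypot(*(pre[i] - post[j]))), i, j)
        for i, js in enumerate(cand)
        for j in js
    ]
    pairs.sort()
    used_pre: set[int] = set()
    used_post: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_pre or j in used_post:
            continue
        used_pre.add(i)
        used_post.add(j)
        matched.append((i, j))
    frac = 100.0 * len(matched) / len(pre)
    return frac, np.asarray(matched, dtype=int).reshape(-1, 2)


def dn_per_plaque(
    plaque_polygons: list[Polygon],
    dystrophy_xy_um: np.ndarray,
    association_radius_um: float = 5.0,
) -> tuple[float, pd.DataFrame]:
    """Fraction (%) of plaques with at least one dystrophic neurite nearby.

    A plaque is DN-positive if any dystrophy centroid lies inside it or
    within ``association_radius_um`` of its boundary.  With zero plaques the
    fraction is undefined (NaN).
    """
    if len(plaque_polygons) == 0:
        return float("nan"), pd.DataFrame(columns=["plaque_id", "n_dystrophies"])
    xy = np.atleast_2d(np.asarray(dystrophy_xy_um, dtype=float))
    rows = []
    pts = (
        shapely.points(xy[:, 0], xy[:, 1]) if xy.size else np.empty(0, dtype=object)
    )
    for pid, poly in enumerate(plaque_polygons):
        if len(pts):
            d = shapely.distance(pts, poly)  # 0 inside the polygon
            n = int(np.sum(d <= association_radius_um))
        else:
            n = 0
        rows.append({"plaque_id": pid, "n_dystrophies": n})
    table = pd.DataFrame(rows)
    frac = 100.0 * float((table["n_dystrophies"] > 0).mean())
    return frac, table
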
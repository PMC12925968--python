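"""Forward simulation of peri-plaque synaptic fields.

Generates 2D scenes with the statistical structure the downstream analysis
assumes: irregular dense-core plaques, smoothly curving axons, pre-synaptic
boutons laid down by a gamma renewal process along each axon, plaque-proximal
bouton depletion, occasional dystrophic swellings where axons contact plaques,
and a simple optics/noise forward model that renders the scene to a
multi-channel image.  Every stochastic element is recorded in a ground-truth
table so detection and spatial statistics can be validated by recovery.

Coordinates are in micrometres with the origin at the image top-left corner;
pixel (i, j) is centred at ((j + 0.5) * um_per_px, (i + 0.5) * um_per_px).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from .detect import PixelCalibration
from .spatial import AxonTrace

__all__ = [
    "SceneConfig",
    "OpticsNoiseModel",
    "SceneGroundTruth",
    "sample_scene",
    "render_scene",
    "CHANNEL_NAMES",
]

#: Fixed channel order of rendered images.
CHANNEL_NAMES = ("HA", "X34", "Homer1", "AXON")

# sub-stream indices so geometry is unchanged when only the noise draw differs
_STREAM_PLAQUES = 0
_STREAM_AXONS = 1
_STREAM_BOUTONS = 2
_STREAM_DYSTROPHIES = 3
_STREAM_NOISE = 4


def _stream(seed: int, which: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), which)))


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of the synthetic field.

    Distances are in micrometres.  ``plaque_radius_um`` gives the median and
    log-space sigma of a lognormal radius distribution.  Depletion is
    piecewise constant: boutons strictly inside a plaque are removed with
    probability ``depletion_prob_inside``; boutons in the ring from the plaque
    boundary out to ``depletion_radius_um`` are removed with probability
    ``depletion_prob_ring``; boutons beyond the ring are never removed.
    """

    field_size_um: tuple[float, float] = (800.0, 800.0)
    pixel_size_um: float = 0.2
    n_plaques: int = 50
    plaque_radius_um: tuple[float, float] = (4.0, 0.25)  # (median, sigma_log)
    plaque_shape_irregularity: float = 0.3
    n_axons: int = 150
    axon_curvature: float = 0.08  # heading sd, rad per sqrt(um)
    mean_inter_bouton_um: float = 5.0
    spacing_cv: float = 0.5
    axon_rate_cv: float = 0.35  # between-axon bouton-rate variability
    depletion_radius_um: float = 5.0
    depletion_prob_inside: float = 0.8
    depletion_prob_ring: float = 0.8
    dystrophy_prob_per_plaque_axon: float = 0.11
    dystrophy_diameter_um: float = 3.0
    coloc_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "depletion_prob_inside",
            "depletion_prob_ring",
            "dystrophy_prob_per_plaque_axon",
            "coloc_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.depletion_radius_um < 0:
            raise ValueError("depletion_radius_um must be >= 0")
        if self.mean_inter_bouton_um <= 0:
            raise ValueError("mean_inter_bouton_um must be > 0")
        if self.spacing_cv < 0 or self.axon_rate_cv < 0:
            raise ValueError("spacing_cv and axon_rate_cv must be >= 0")
        if min(self.field_size_um) <= 0 or self.pixel_size_um <= 0:
            raise ValueError("field dimensions and pixel size must be > 0")


@dataclass(frozen=True)
class OpticsNoiseModel:
    """Imaging forward model: Gaussian PSF, Poisson shot noise, Gaussian read noise.

    ``amplitude_*`` are peak intensities (above background) of the rendered
    Gaussian profile of each object class.  ``poisson_scale`` converts
    intensity to expected photon counts; 0 disables shot noise.  Rendered
    images are clipped to ``[0, 2**bit_depth - 1]``.
    """

    psf_sigma_um: float = 0.3
    amplitude_bouton: float = 100.0
    amplitude_dystrophy: float = 120.0
    amplitude_plaque: float = 150.0
    amplitude_post: float = 100.0
    amplitude_axon: float = 40.0
    background_level: float = 20.0
    poisson_scale: float = 1.0
    read_noise_sd: float = 2.0
    bit_depth: int = 16
    homer_jitter_sd_um: float = 0.1
    bouton_diameter_um: float = 1.0

    def __post_init__(self) -> None:
        if self.psf_sigma_um <= 0:
            raise ValueError("psf_sigma_um must be > 0")
        if self.poisson_scale < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class SceneGroundTruth:
    """Complete truth record of a sampled scene.

    ``plaques``: DataFrame (plaque_id, area_um2, centroid_x_um, centroid_y_um)
    plus a parallel list of boundary polygons.  ``boutons``: DataFrame
    (bouton_id, axon_id, arc_um, x_um, y_um, dist_plaque_um, kept,
    paired_post).  ``dystrophies``: DataFrame (dystrophy_id, axon_id, x_um,
    y_um, diameter_um, plaque_id).
    """

    plaques: pd.DataFrame
    plaque_polygons: list[Polygon]
    axons: list[AxonTrace]
    boutons: pd.DataFrame
    dystrophies: pd.DataFrame
    config: SceneConfig
    seed_used: int = field(default=0)

    @property
    def kept_boutons(self) -> pd.DataFrame:
        return self.boutons[self.boutons["kept"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# geometry sampling


def _perturbed_circle(
    center: np.ndarray, radius: float, irregularity: float, rng: np.random.Generator
) -> Polygon:
    """Radius-perturbed polygon: Fourier-perturbed circle.

    irregularity 0 yields an (approximate) disk — a regular 64-gon — so
    analytic disk results hold to polygonization error.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    r = np.full_like(theta, radius)
    if irregularity > 0:
        for k in range(2, 7):
            amp = irregularity * radius * rng.normal(0.0, 1.0 / k)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            r = r + amp * np.cos(k * theta + phase)
    r = np.clip(r, 0.3 * radius, None)
    xy = np.column_stack([center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)])
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _sample_plaques(cfg: SceneConfig, rng: np.random.Generator) -> list[Polygon]:
    w, h = cfg.field_size_um
    med, sig = cfg.plaque_radius_um
    polys: list[Polygon] = []
    max_tries = 200 * max(cfg.n_plaques, 1)
    tries = 0
    while len(polys) < cfg.n_plaques:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {cfg.n_plaques} non-overlapping plaques in a "
                f"{w} x {h} um field after {max_tries} attempts; reduce n_plaques "
                "or plaque radius"
            )
        tries += 1
        radius = med * np.exp(sig * rng.standard_normal())
        margin = 1.5 * radius
        if 2 * margin >= min(w, h):
            continue
        center = np.array(
            [rng.uniform(margin, w - margin), rng.uniform(margin, h - margin)]
        )
        cand = _perturbed_circle(center, radius, cfg.plaque_shape_irregularity, rng)
        if any(cand.intersects(p) for p in polys):
            continue
        polys.append(cand)
    return polys


def _sample_axon(
    cfg: SceneConfig, rng: np.random.Generator, step_um: float = 1.0
) -> np.ndarray:
    """Random walk polyline entering from a random field edge.

    Heading is a Wiener process: per step of length ds the heading increment
    is N(0, curvature^2 * ds), i.e. ``axon_curvature`` is the heading sd per
    sqrt(um) of arc.
    """
    w, h = cfg.field_size_um
    edge = rng.integers(0, 4)
    if edge == 0:  # left
        pos = np.array([0.0, rng.uniform(0, h)])
        heading = 0.0
    elif edge == 1:  # right
        pos = np.array([w, rng.uniform(0, h)])
        heading = np.pi
    elif edge == 2:  # top
        pos = np.array([rng.uniform(0, w), 0.0])
        heading = np.pi / 2
    else:  # bottom
        pos = np.array([rng.uniform(0, w), h])
        heading = -np.pi / 2
    heading += rng.uniform(-np.pi / 3, np.pi / 3)

    max_len = 1.5 * float(np.hypot(w, h))
    n_steps = int(np.ceil(max_len / step_um))
    headings = heading + np.cumsum(
        cfg.axon_curvature * np.sqrt(step_um) * rng.standard_normal(n_steps)
    )
    steps = step_um * np.column_stack([np.cos(headings), np.sin(headings)])
    pts = pos[None, :] + np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    outside = (
        (pts[:, 0] < 0.0) | (pts[:, 0] > w) | (pts[:, 1] < 0.0) | (pts[:, 1] > h)
    )
    exits = np.flatnonzero(outside[1:])  # first vertex always on the border
    if len(exits):
        pts = pts[: exits[0] + 1]
    return pts


def _renewal_positions(
    length: float, mean: float, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma renewal process on [0, length], started far before 0 (burn-in)
    so the point process is approximately stationary on the interval."""
    burnin = 10.0 * mean
    if cv == 0:
        start = -burnin + rng.uniform(0.0, mean)
        pos = np.arange(start, length, mean)
        return pos[pos >= 0.0]
    shape = 1.0 / cv**2
    scale = mean * cv**2
    # draw enough gaps to cover burn-in + interval with headroom
    n_guess = max(16, int((length + burnin) / mean * 2 + 10 * np.sqrt(shape)))
    pos_list = []
    t = -burnin
    while t < length:
        gaps = rng.gamma(shape, scale, size=n_guess)
        pts = t + np.cumsum(gaps)
        pos_list.append(pts)
        t = pts[-1]
    pos = np.concatenate(pos_list)
    return pos[(pos >= 0.0) & (pos <= length)]


def _signed_distance_to_plaques(
    xy: np.ndarray, polygons: list[Polygon]
) -> np.ndarray:
    """Signed Euclidean distance (um) from points to the nearest plaque
    boundary; negative inside any plaque.  +inf when there are no plaques."""
    if len(polygons) == 0 or len(xy) == 0:
        return np.full(len(xy), np.inf)
    union = shapely.union_all(polygons)
    pts = shapely.points(xy[:, 0], xy[:, 1])
    inside = shapely.contains(union, pts)
    d = shapely.distance(pts, shapely.boundary(union))
    return np.where(inside, -d, d)


def sample_scene(config: SceneConfig) -> SceneGroundTruth:
    """Draw a complete scene (plaques, axons, boutons, dystrophies).

    Deterministic given ``config.seed``; separate random sub-streams per
    object class keep the geometry fixed when only the noise seed changes.
    """
    rng_p = _stream(config.seed, _STREAM_PLAQUES)
    rng_a = _stream(config.seed, _STREAM_AXONS)
    rng_b = _stream(config.seed, _STREAM_BOUTONS)
    rng_d = _stream(config.seed, _STREAM_DYSTROPHIES)

    polygons = _sample_plaques(config, rng_p)
    plaques = pd.DataFrame(
        {
            "plaque_id": np.arange(len(polygons)),
            "area_um2": [p.area for p in polygons],
            "centroid_x_um": [p.centroid.x for p in polygons],
            "centroid_y_um": [p.centroid.y for p in polygons],
        }
    )

    axons: list[AxonTrace] = []
    for i in range(config.n_axons):
        for _ in range(50):
            verts = _sample_axon(config, rng_a)
            if len(verts) >= 2 and _polyline_length(verts) >= 20.0:
                break
        axons.append(AxonTrace(axon_id=i, vertices_um=verts))

    rows = []
    for ax in axons:
        # per-axon bouton-rate factor, lognormal with unit mean so the
        # expected scene-wide count is unchanged by heterogeneity
        if config.axon_rate_cv > 0:
            s = np.sqrt(np.log1p(config.axon_rate_cv**2))
            rate = float(np.exp(rng_b.normal(-0.5 * s**2, s)))
        else:
            rate = 1.0
        arcs = _renewal_positions(
            ax.total_length_um,
            config.mean_inter_bouton_um / rate,
            config.spacing_cv,
            rng_b,
        )
        xy = ax.point_at(arcs)
        for a, (x, y) in zip(arcs, xy):
            rows.append((ax.axon_id, float(a), float(x), float(y)))
    boutons = pd.DataFrame(rows, columns=["axon_id", "arc_um", "x_um", "y_um"])
    boutons.insert(0, "bouton_id", np.arange(len(boutons)))

    d = _signed_distance_to_plaques(boutons[["x_um", "y_um"]].to_numpy(), polygons)
    boutons["dist_plaque_um"] = d
    p_remove = np.zeros(len(boutons))
    p_remove[d < 0] = config.depletion_prob_inside
    p_remove[(d >= 0) & (d <= config.depletion_radius_um)] = config.depletion_prob_ring
    boutons["kept"] = rng_b.random(len(boutons)) >= p_remove
    boutons["paired_post"] = rng_b.random(len(boutons)) < config.coloc_fraction

    # dystrophies: one Bernoulli trial per (plaque, contacting axon) pair;
    # an axon "contacts" a plaque if it passes within depletion_radius_um.
    drows = []
    if config.dystrophy_prob_per_plaque_axon > 0 and polygons:
        tree = shapely.STRtree(polygons)
        for ax in axons:
            dense_arc, dense_xy = ax.resample(step_um=0.5)
            line = shapely.linestrings(dense_xy)
            cand = tree.query(line, predicate="dwithin", distance=config.depletion_radius_um)
            if len(cand) == 0:
                continue
            pts = shapely.points(dense_xy[:, 0], dense_xy[:, 1])
            for pid in sorted(int(c) for c in cand):
                poly = polygons[pid]
                dist = shapely.distance(pts, shapely.boundary(poly))
                inside = shapely.contains(poly, pts)
                signed = np.where(inside, -dist, dist)
                k = int(np.argmin(signed))
                if signed[k] > config.depletion_radius_um:
                    continue
                if rng_d.random() < config.dystrophy_prob_per_plaque_axon:
                    drows.append(
                        (
                            ax.axon_id,
                            float(dense_xy[k, 0]),
                            float(dense_xy[k, 1]),
                            config.dystrophy_diameter_um,
                            pid,
                        )
                    )
    dystrophies = pd.DataFrame(
        drows, columns=["axon_id", "x_um", "y_um", "diameter_um", "plaque_id"]
    )
    dystrophies.insert(0, "dystrophy_id", np.arange(len(dystrophies)))

    return SceneGroundTruth(
        plaques=plaques,
        plaque_polygons=polygons,
        axons=axons,
        boutons=boutons,
        dystrophies=dystrophies,
        config=config,
        seed_used=config.seed,
    )


def _polyline_length(verts: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(verts, axis=0).T)))


# ---------------------------------------------------------------------------
# rendering


def _add_gaussian_spots(
    img: np.ndarray,
    xy_um: np.ndarray,
    sigma_um: float,
    amplitude: float,
    um_per_px: float,
) -> None:
    """Accumulate isotropic Gaussian profiles evaluated at pixel centres."""
    if len(xy_um) == 0:
        return
    h, w = img.shape
    s_px = sigma_um / um_per_px
    r = max(3, int(np.ceil(5 * s_px)))
    for x_um, y_um in xy_um:
        cx = x_um / um_per_px - 0.5
        cy = y_um / um_per_px - 0.5
        i0, i1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
        j0, j1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
        i0c, i1c = max(i0, 0), min(i1, h)
        j0c, j1c = max(j0, 0), min(j1, w)
        if i0c >= i1c or j0c >= j1c:
            continue
        ii = np.arange(i0c, i1c)
        jj = np.arange(j0c, j1c)
        gy = np.exp(-((ii - cy) ** 2) / (2 * s_px**2))
        gx = np.exp(-((jj - cx) ** 2) / (2 * s_px**2))
        img[i0c:i1c, j0c:j1c] += amplitude * np.outer(gy, gx)


def _effective_sigma_um(diameter_um: float, psf_sigma_um: float) -> float:
    """Object of physical diameter d modelled as a Gaussian of sigma
    d / (2*sqrt(2)), convolved with the PSF."""
    s_obj = diameter_um / (2.0 * np.sqrt(2.0))
    return float(np.hypot(s_obj, psf_sigma_um))


def _rasterize_polygons(
    polygons: list[Polygon], shape: tuple[int, int], um_per_px: float
) -> np.ndarray:
    from skimage.draw import polygon as draw_polygon

    mask = np.zeros(shape, dtype=bool)
    for poly in polygons:
        xs, ys = poly.exterior.coords.xy
        rr, cc = draw_polygon(
            np.asarray(ys) / um_per_px - 0.5,
            np.asarray(xs) / um_per_px - 0.5,
            shape=shape,
        )
        mask[rr, cc] = True
    return mask


def _rasterize_polyline(
    img: np.ndarray, verts_um: np.ndarray, um_per_px: float, value: float
) -> None:
    """Stamp unit-intensity line by dense sub-pixel sampling."""
    seg = np.diff(verts_um, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total == 0:
        return
    n = max(2, int(np.ceil(total / (0.25 * um_per_px))))
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    t = np.linspace(0.0, arc[-1], n)
    x = np.interp(t, arc, verts_um[:, 0])
    y = np.interp(t, arc, verts_um[:, 1])
    jj = np.round(x / um_per_px - 0.5).astype(int)
    ii = np.round(y / um_per_px - 0.5).astype(int)
    ok = (ii >= 0) & (ii < img.shape[0]) & (jj >= 0) & (jj < img.shape[1])
    img[ii[ok], jj[ok]] = value


def render_scene(
    scene: SceneGroundTruth,
    optics: OpticsNoiseModel | None = None,
    noise_seed: int | None = None,
) -> tuple[np.ndarray, PixelCalibration]:
    """Render a scene to a (4, H, W) float image (HA, X34, Homer1, AXON).

    Deterministic given the scene seed; pass ``noise_seed`` to redraw only
    the noise while keeping the geometry.
    """
    optics = optics or OpticsNoiseModel()
    cfg = scene.config
    upp = cfg.pixel_size_um
    if upp > optics.psf_sigma_um:
        warnings.warn(
            f"pixel size {upp} um exceeds PSF sigma {optics.psf_sigma_um} um: "
            "the PSF is undersampled",
            stacklevel=2,
        )
    w_px = int(round(cfg.field_size_um[0] / upp))
    h_px = int(round(cfg.field_size_um[1] / upp))
    img = np.zeros((4, h_px, w_px), dtype=np.float64)

    kept = scene.kept_boutons
    sig_b = _effective_sigma_um(optics.bouton_diameter_um, optics.psf_sigma_um)
    _add_gaussian_spots(
        img[0], kept[["x_um", "y_um"]].to_numpy(), sig_b, optics.amplitude_bouton, upp
    )
    if len(scene.dystrophies):
        for _, row in scene.dystrophies.iterrows():
            sig_d = _effective_sigma_um(row["diameter_um"], optics.psf_sigma_um)
            _add_gaussian_spots(
                img[0],
                np.array([[row["x_um"], row["y_um"]]]),
                sig_d,
                optics.amplitude_dystrophy,
                upp,
            )

    if scene.plaque_polygons:
        pm = _rasterize_polygons(scene.plaque_polygons, (h_px, w_px), upp)
        img[1] = gaussian_filter(
            pm.astype(np.float64) * optics.amplitude_plaque, optics.psf_sigma_um / upp
        )

    rng_n = _stream(
        scene.seed_used if noise_seed is None else noise_seed, _STREAM_NOISE
    )
    paired = kept[kept["paired_post"]]
    if len(paired):
        jitter = rng_n.normal(0.0, optics.homer_jitter_sd_um, size=(len(paired), 2))
        _add_gaussian_spots(
            img[2],
            paired[["x_um", "y_um"]].to_numpy() + jitter,
            sig_b,
            optics.amplitude_post,
            upp,
        )

    axon_hits = np.zeros((h_px, w_px), dtype=np.float64)
    for ax in scene.axons:
        _rasterize_polyline(axon_hits, ax.vertices_um, upp, optics.amplitude_axon)
    img[3] = gaussian_filter(axon_hits, optics.psf_sigma_um / upp)

    img += optics.background_level
    if optics.poisson_scale > 0:
        img = rng_n.poisson(img * optics.poisson_scale) / optics.poisson_scale
    if optics.read_noise_sd > 0:
        img = img + rng_n.normal(0.0, optics.read_noise_sd, size=img.shape)
    np.clip(img, 0.0, 2.0**optics.bit_depth - 1.0, out=img)

    calib = PixelCalibration(
        um_per_px_x=upp, um_per_px_y=upp, width_px=w_px, height_px=h_px
    )
    return img, calib


def null_config(config: SceneConfig | None = None, **overrides) -> SceneConfig:
    """A copy of ``config`` with all depletion switched off (control field)."""
    cfg = config or SceneConfig()
    return replace(
        cfg, depletion_prob_inside=0.0, depletion_prob_ring=0.0, **overrides
    )
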
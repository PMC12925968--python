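"""File formats, configuration and the end-to-end pipeline.

Images are TIFF/OME-TIFF (channel names and pixel size resolved from OME
metadata, with config overrides taking precedence).  Axon traces are SWC
(2D; z ignored) or a simple JSON list of polylines.  All result tables go
out as CSV with unit-bearing column names plus a JSON provenance record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect import (
    DetectionParams,
    PixelCalibration,
    assign_puncta_to_axons,
    detect_dystrophies,
    detect_puncta,
    segment_plaques,
)
from .spatial import (
    AnnulusBinSpec,
    AxonTrace,
    annulus_profile,
    axon_metrics_table,
    coloc_fraction,
    distance_field,
    dn_per_plaque,
    subject_linear_density,
)
from . import stats as plstats

logger = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_image",
    "read_traces",
    "write_traces_swc",
    "write_traces_json",
    "RunConfig",
    "run_pipeline",
    "write_fixture",
]


# ---------------------------------------------------------------------------
# images


def write_image(
    path: str | Path,
    image: np.ndarray,
    calib: PixelCalibration,
    channel_names: tuple[str, ...],
) -> None:
    """Write a (C, H, W) stack as OME-TIFF with named channels and pixel size."""
    img = np.asarray(image)
    if img.ndim == 2:
        img = img[None]
    tifffile.imwrite(
        str(path),
        img.astype(np.float32),
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": list(channel_names)},
            "PhysicalSizeX": calib.um_per_px_x,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": calib.um_per_px_y,
            "PhysicalSizeYUnit": "µm",
        },
    )


def read_image(
    path: str | Path,
    calib_override_um_per_px: float | None = None,
) -> tuple[np.ndarray, list[str], PixelCalibration]:
    """Read a TIFF/OME-TIFF into a (C, H, W) array with channel names.

    Channel names come from OME metadata when present, else positional
    fallbacks ("ch0", ...).  Pixel size comes from OME metadata unless an
    override is given (override wins; a disagreement is logged).  A plain
    TIFF without calibration and without an override is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        ome = tf.ome_metadata
    if arr.ndim == 2:
        arr = arr[None]
    elif arr.ndim != 3:
        raise ValueError(f"expected 2D or 3D (CYX) image, got shape {arr.shape}")

    names: list[str] = []
    meta_px: float | None = None
    if ome:
        root = ET.fromstring(ome)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        for ch in root.iter(f"{{{ns['ome']}}}Channel"):
            nm = ch.get("Name")
            if nm:
                names.append(nm)
        px = root.find(f".//{{{ns['ome']}}}Pixels")
        if px is not None and px.get("PhysicalSizeX"):
            meta_px = float(px.get("PhysicalSizeX"))
    if len(names) != arr.shape[0]:
        names = [f"ch{i}" for i in range(arr.shape[0])]

    if calib_override_um_per_px is not None:
        if meta_px is not None and not np.isclose(meta_px, calib_override_um_per_px):
            logger.warning(
                "calibration override %.4g um/px differs from metadata %.4g um/px; "
                "override wins",
                calib_override_um_per_px,
                meta_px,
            )
        upp = calib_override_um_per_px
    elif meta_px is not None:
        upp = meta_px
    else:
        raise ValueError(
            f"{path}: no pixel calibration in metadata and no override given"
        )
    calib = PixelCalibration(
        um_per_px_x=upp,
        um_per_px_y=upp,
        width_px=arr.shape[2],
        height_px=arr.shape[1],
    )
    return arr.astype(np.float64), names, calib


# ---------------------------------------------------------------------------
# axon traces


def write_traces_swc(path: str | Path, axons: list[AxonTrace]) -> None:
    """Write traces as SWC: one connected path per axon, z = 0.

    Multiple axons are written as separate root segments in one file."""
    lines = ["# index type x y z radius parent"]
    idx = 0
    for ax in axons:
        for i, (x, y) in enumerate(ax.vertices_um):
            idx += 1
            parent = -1 if i == 0 else idx - 1
            lines.append(f"{idx} 2 {x:.6f} {y:.6f} 0.000000 0.500000 {parent}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_traces_json(path: str | Path, axons: list[AxonTrace]) -> None:
    payload = {
        "axons": [
            {
                "axon_id": int(ax.axon_id),
                "subject_id": ax.subject_id,
                "vertices_um": np.round(ax.vertices_um, 6).tolist(),
            }
            for ax in axons
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_traces(path: str | Path) -> list[AxonTrace]:
    """Read SWC or JSON axon traces (micrometre coordinates).

    SWC trees are split into unbranched root-to-leaf paths — one AxonTrace
    per leaf, sharing the proximal segment — because all per-axon statistics
    assume simple paths.  Cyclic SWC files are rejected.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return [
            AxonTrace(
                axon_id=int(a["axon_id"]),
                vertices_um=np.asarray(a["vertices_um"], dtype=float),
                subject_id=a.get("subject_id"),
            )
            for a in payload["axons"]
        ]
    return _read_swc(path)


def _read_swc(path: Path) -> list[AxonTrace]:
    nodes: dict[int, tuple[float, float]] = {}
    parent: dict[int, int] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        i, x, y, par = int(f[0]), float(f[2]), float(f[3]), int(f[6])
        nodes[i] = (x, y)
        parent[i] = par

    children: dict[int, list[int]] = {i: [] for i in nodes}
    roots = []
    for i, par in parent.items():
        if par == -1:
            roots.append(i)
        else:
            if par not in nodes:
                raise ValueError(f"SWC node {i} has unknown parent {par}")
            children[par].append(i)
    if not roots:
        raise ValueError("SWC file has no root node (cycle?)")

    # cycle check: every node must be reachable from a root exactly once
    seen: set[int] = set()
    order: list[int] = list(roots)
    while order:
        i = order.pop()
        if i in seen:
            raise ValueError("SWC contains a cycle")
        seen.add(i)
        order.extend(children[i])
    if seen != set(nodes):
        raise ValueError("SWC contains a cycle (unreachable nodes)")

    traces: list[AxonTrace] = []
    for root in roots:
        # enumerate root-to-leaf paths
        stack = [[root]]
        while stack:
            p = stack.pop()
            kids = children[p[-1]]
            if not kids:
                if len(p) >= 2:
                    verts = np.array([nodes[i] for i in p])
                    traces.append(AxonTrace(axon_id=len(traces), vertices_um=verts))
                continue
            for kid in kids:
                stack.append(p + [kid])
    return traces


# ---------------------------------------------------------------------------
# fixtures (simulated scene -> file set)


def write_fixture(scene, image: np.ndarray, directory: str | Path) -> dict[str, Path]:
    """Persist a simulated scene: OME-TIFF image, ground-truth CSV tables,
    SWC axon traces, and a config echo.  Round-trips through this module."""
    from .simulate import CHANNEL_NAMES

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    upp = scene.config.pixel_size_um
    calib = PixelCalibration(
        um_per_px_x=upp,
        um_per_px_y=upp,
        width_px=image.shape[2],
        height_px=image.shape[1],
    )
    paths = {
        "image": directory / "scene.ome.tif",
        "boutons": directory / "boutons.csv",
        "plaques": directory / "plaques.csv",
        "dystrophies": directory / "dystrophies.csv",
        "axons": directory / "axons.swc",
        "config": directory / "scene_config.yaml",
    }
    write_image(paths["image"], image, calib, CHANNEL_NAMES)
    scene.boutons.round(6).to_csv(paths["boutons"], index=False)
    scene.plaques.round(6).to_csv(paths["plaques"], index=False)
    scene.dystrophies.round(6).to_csv(paths["dystrophies"], index=False)
    write_traces_swc(paths["axons"], scene.axons)
    paths["config"].write_text(
        yaml.safe_dump(dataclasses.asdict(scene.config), sort_keys=True)
    )
    return paths


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """End-to-end run configuration.

    Exactly one of ``image_path`` (analyze mode, with ``traces_path``) or
    ``simulate`` (a SceneConfig mapping) must be given.
    """

    output_dir: str = "periplaque_out"
    image_path: str | None = None
    traces_path: str | None = None
    roi_mask_path: str | None = None
    um_per_px: float | None = None
    simulate: dict | None = None
    optics: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    ring_edges_um: tuple[float, ...] = (0.0, 5.0, 15.0, 25.0, 35.0)
    subject_id: str = "subject-1"
    seed: int = 0
    qc_figures: bool = False

    def __post_init__(self) -> None:
        has_input = self.image_path is not None
        has_sim = self.simulate is not None
        if has_input == has_sim:
            raise ValueError(
                "config must contain exactly one of an input image path or a "
                "simulate block"
            )
        if has_input:
            for p in (self.image_path, self.traces_path):
                if p is not None and not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "ring_edges_um" in data:
            data["ring_edges_um"] = tuple(data["ring_edges_um"])
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> detect -> spatial analysis -> stats.

    Writes boutons, plaques, annulus-profile and per-axon CSV tables, a
    stats report, and a provenance record into ``config.output_dir``.
    Returns the in-memory results keyed by table name.
    """
    from . import __version__
    from .simulate import (
        CHANNEL_NAMES,
        OpticsNoiseModel,
        SceneConfig,
        render_scene,
        sample_scene,
    )

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = DetectionParams(**config.detection)
    bins = AnnulusBinSpec(ring_edges_um=config.ring_edges_um)

    stage = "simulate/load"
    try:
        if config.simulate is not None:
            scfg = SceneConfig(**{**config.simulate, "seed": config.seed})
            optics = OpticsNoiseModel(**config.optics)
            scene = sample_scene(scfg)
            image, calib = render_scene(scene, optics)
            channels = list(CHANNEL_NAMES)
            axons = scene.axons
        else:
            image, channels, calib = read_image(
                config.image_path, calib_override_um_per_px=config.um_per_px
            )
            axons = read_traces(config.traces_path) if config.traces_path else []

        stage = "detect"
        chan = {n: image[i] for i, n in enumerate(channels)}
        ha = chan.get("HA", image[0])
        puncta = detect_puncta(ha, calib, params, channel="HA")
        dystrophies = detect_dystrophies(puncta, params)
        boutons = puncta[
            puncta["equivalent_diameter_um"] < params.dystrophy_min_diameter_um
        ].reset_index(drop=True)
        plaques = (
            segment_plaques(chan["X34"], calib, params) if "X34" in chan else []
        )
        post = (
            detect_puncta(chan["Homer1"], calib, params, channel="Homer1")
            if "Homer1" in chan
            else None
        )
        boutons = assign_puncta_to_axons(boutons, axons, params)

        stage = "spatial_analysis"
        roi = None
        if config.roi_mask_path:
            roi_img, _, _ = read_image(
                config.roi_mask_path, calib_override_um_per_px=calib.um_per_px_x
            )
            roi = roi_img[0] > 0
        dfield = distance_field([p.boundary_polygon_um for p in plaques], calib)
        profile = annulus_profile(
            boutons, dfield, calib, bins, roi_mask=roi, subject_id=config.subject_id
        )
        on_axon = boutons[boutons["axon_id"].notna()]
        ax_metrics = axon_metrics_table(axons, on_axon, dfield, calib, bins)
        ax_metrics["subject_id"] = config.subject_id
        subj_density = subject_linear_density(ax_metrics)
        coloc_pct = float("nan")
        if post is not None and len(boutons):
            coloc_pct, _ = coloc_fraction(
                boutons[["x_um", "y_um"]].to_numpy(),
                post[["x_um", "y_um"]].to_numpy(),
                params.coloc_max_dist_um,
            )
        dn_pct, dn_table = dn_per_plaque(
            [p.boundary_polygon_um for p in plaques],
            dystrophies[["x_um", "y_um"]].to_numpy()
            if len(dystrophies)
            else np.empty((0, 2)),
            association_radius_um=bins.ring_edges_um[1],
        )

        stage = "stats"
        stats_rows = []
        by_bin = ax_metrics.dropna(subset=["distance_bin_label", "nnd3_mean_um"])
        groups = {
            g: v["nnd3_mean_um"].to_numpy()
            for g, v in by_bin.groupby("distance_bin_label")
        }
        if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
            res = plstats.oneway_anova_dunnett(groups, bins.axon_labels()[-1])
            stats_rows.append(res.to_frame())
        stats_report = (
            pd.concat(stats_rows, ignore_index=True)
            if stats_rows
            else pd.DataFrame(columns=["test", "term", "statistic", "p_value"])
        )

        stage = "write"
        tables = {
            "boutons": boutons,
            "dystrophies": dystrophies,
            "annulus_profile": profile,
            "axon_metrics": ax_metrics,
            "subject_density": subj_density,
            "dn_per_plaque": dn_table,
            "stats_report": stats_report,
        }
        for name, tab in tables.items():
            tab.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.6f")
        plaque_tab = pd.DataFrame(
            {
                "plaque_id [-]": [p.plaque_id for p in plaques],
                "area [um^2]": [p.area_um2 for p in plaques],
                "centroid_x [um]": [p.centroid_um[0] for p in plaques],
                "centroid_y [um]": [p.centroid_um[1] for p in plaques],
            }
        )
        plaque_tab.to_csv(out_dir / "plaques.csv", index=False, float_format="%.6f")
        provenance = {
            "software": f"periplaque {__version__}",
            "seed": config.seed,
            "detection_params": params.as_provenance(),
            "ring_edges_um": list(config.ring_edges_um),
            "coloc_percent": None if np.isnan(coloc_pct) else coloc_pct,
            "dn_positive_percent": None if np.isnan(dn_pct) else dn_pct,
            "config": dataclasses.asdict(config),
        }
        (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=1))
        if config.qc_figures:
            _qc_figures(out_dir, profile, ax_metrics)
    except Exception as exc:  # noqa: BLE001 — re-raise with stage context
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    tables["plaques"] = plaque_tab
    tables["coloc_percent"] = coloc_pct
    tables["dn_positive_percent"] = dn_pct
    return tables


def _qc_figures(out_dir: Path, profile: pd.DataFrame, ax_metrics: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    axes[0].bar(profile["bin_label"], profile["percentage"])
    axes[0].set_ylabel("% of pre-synapses (area-normalized)")
    axes[0].tick_params(axis="x", rotation=45)
    sub = ax_metrics.dropna(subset=["nnd3_mean_um"])
    axes[1].scatter(sub["closest_approach_um"], sub["nnd3_mean_um"], s=8)
    axes[1].set_xlabel("closest approach to plaque [um]")
    axes[1].set_ylabel("NND-3 [um]")
    fig.tight_layout()
    fig.savefig(out_dir / "qc_profile.png", dpi=120)
    plt.close(fig)
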
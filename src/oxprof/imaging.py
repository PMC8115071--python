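"""Image quantification: multichannel stacks, ROI rasterization, and
per-neuron cytoplasmic mean extraction.

A pixel inside a neuron outline is counted as cytoplasm iff its intensity
is <= threshold on every exclusion channel (nuclear marker and
Ir-intercalator by default); the per-target mean over those pixels is the
neuron's measurement.  The module also renders synthetic stacks from
planned cell geometry so extraction can be tested against generator truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
import tifffile
from shapely.geometry import Polygon

from oxprof import panel as panel_mod
from oxprof.errors import DataError, EmptyCytoplasmError, FormatError, GeometryError
from oxprof.synthetic import CellGeometry


@dataclass
class PanelEntry:
    channel_index: int
    metal_tag: str
    target: str
    role: str


@dataclass
class ImageStack:
    """Single-plane multichannel intensity image with panel metadata."""

    pixels: np.ndarray  # (channels, rows, cols), non-negative
    panel: list[PanelEntry]
    pixel_size: float = 1.0  # micrometres per pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3:
            raise FormatError(f"expected (C, H, W) array, got shape {self.pixels.shape}")
        if len(self.panel) != self.pixels.shape[0]:
            raise FormatError(
                f"panel has {len(self.panel)} entries but image has "
                f"{self.pixels.shape[0]} channels"
            )
        if self.pixels.shape[1] < 1 or self.pixels.shape[2] < 1:
            raise FormatError("image must have at least one row and column")
        if np.any(self.pixels < 0):
            raise FormatError("negative intensities are not allowed")
        targets = [e.target for e in self.panel]
        if len(set(targets)) != len(targets):
            raise FormatError("panel target names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]

    @property
    def targets(self) -> list[str]:
        return [e.target for e in self.panel]

    def channel(self, target: str) -> np.ndarray:
        for entry in self.panel:
            if entry.target == target:
                return self.pixels[entry.channel_index]
        raise DataError(f"target {target!r} not in panel")


@dataclass
class RoiPolygon:
    """Neuron outline in pixel coordinates (x=col, y=row, 0-based centers)."""

    neuron_id: str
    case_id: str
    vertices: np.ndarray  # (n, 2) floats, closed ring implied

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise GeometryError("polygon needs at least 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise GeometryError(f"polygon for {self.neuron_id} is not simple")
        if poly.area == 0:
            raise GeometryError(f"polygon for {self.neuron_id} has zero area")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ["channel_index", "metal_tag", "target", "role"]


def read_panel(path) -> list[PanelEntry]:
    df = pd.read_csv(path)
    missing = set(_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"panel file missing columns: {sorted(missing)}")
    entries = [
        PanelEntry(int(r.channel_index), str(r.metal_tag), str(r.target), str(r.role))
        for r in df.itertuples()
    ]
    mass = [e for e in entries if e.role == "mass"]
    if len(mass) != 1:
        raise FormatError(f"panel must contain exactly one mass target, found {len(mass)}")
    return entries


def write_panel(entries: list[PanelEntry], path) -> None:
    pd.DataFrame(
        [
            {
                "channel_index": e.channel_index,
                "metal_tag": e.metal_tag,
                "target": e.target,
                "role": e.role,
            }
            for e in entries
        ]
    ).to_csv(path, index=False)


def default_panel() -> list[PanelEntry]:
    return [
        PanelEntry(
            i,
            panel_mod.METAL_TAGS[t],
            t,
            panel_mod.ROLE_BY_TARGET[t],
        )
        for i, t in enumerate(panel_mod.DEFAULT_TARGET_ORDER)
    ]


def read_stack(path, panel_path) -> ImageStack:
    """Read a single-plane multichannel TIFF plus a panel sidecar CSV."""
    entries = read_panel(panel_path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise FormatError(f"expected a (C, H, W) TIFF, got shape {pixels.shape}")
    if pixels.shape[0] != len(entries):
        raise FormatError(
            f"image has {pixels.shape[0]} channels, panel lists {len(entries)}"
        )
    if np.any(pixels < 0):
        raise FormatError("negative intensities in image")
    return ImageStack(pixels=pixels, panel=entries)


def write_stack(stack: ImageStack, path, panel_path=None) -> None:
    tifffile.imwrite(path, stack.pixels, photometric="minisblack")
    if panel_path is not None:
        write_panel(stack.panel, panel_path)


def read_rois(path) -> list[RoiPolygon]:
    """GeoJSON FeatureCollection of polygons with neuron_id/case_id props."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise FormatError("ROI file must be a GeoJSON FeatureCollection")
    rois = []
    for feat in data.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise FormatError(f"unsupported geometry type {geom.get('type')!r}")
        ring = geom["coordinates"][0]
        props = feat.get("properties", {})
        if "neuron_id" not in props or "case_id" not in props:
            raise FormatError("ROI feature missing neuron_id/case_id properties")
        # GeoJSON rings repeat the first vertex; drop the duplicate
        verts = np.asarray(ring, dtype=float)
        if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        rois.append(RoiPolygon(str(props["neuron_id"]), str(props["case_id"]), verts))
    return rois


def write_rois(rois: list[RoiPolygon], path) -> None:
    features = []
    for roi in rois:
        ring = roi.vertices.tolist()
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"neuron_id": roi.neuron_id, "case_id": roi.case_id},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


# ---------------------------------------------------------------------------
# rasterization and extraction
# ---------------------------------------------------------------------------


def rasterize_roi(roi: RoiPolygon | Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie strictly inside the polygon.

    Pixel (r, c) has its center at x = c, y = r.  Restricted to the polygon
    bounding box for speed; deterministic.
    """
    poly = roi.polygon if isinstance(roi, RoiPolygon) else roi
    if not poly.is_valid or poly.area == 0:
        raise GeometryError("degenerate polygon")
    n_rows, n_cols = shape
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(np.floor(minx)))
    c1 = min(n_cols - 1, int(np.ceil(maxx)))
    r0 = max(0, int(np.floor(miny)))
    r1 = min(n_rows - 1, int(np.ceil(maxy)))
    mask = np.zeros(shape, dtype=bool)
    if c1 < c0 or r1 < r0:
        return mask
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    cc, rr = np.meshgrid(cols, rows)
    inside = shapely.contains_xy(poly, cc.ravel().astype(float), rr.ravel().astype(float))
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rr.shape)
    return mask


def cytoplasmic_mean(
    stack: ImageStack,
    mask: np.ndarray,
    exclusion_targets: tuple[str, ...] = panel_mod.DEFAULT_EXCLUSION_TARGETS,
    threshold: float = panel_mod.DEFAULT_EXCLUSION_THRESHOLD,
) -> tuple[dict[str, float], int, int]:
    """Per-target means over cytoplasmic pixels of ``mask``.

    Cytoplasmic = in the mask AND <= threshold on every exclusion channel
    (strictly greater excludes).  Returns (means, n_pixels_total,
    n_pixels_cytoplasm); raises EmptyCytoplasmError when nothing is left.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DataError("mask is empty")
    if threshold < 0:
        raise DataError("threshold must be >= 0")
    unknown = set(exclusion_targets) - set(stack.targets)
    if unknown:
        raise DataError(f"exclusion targets not in panel: {sorted(unknown)}")

    cyto = mask.copy()
    for target in exclusion_targets:
        cyto &= stack.channel(target) <= threshold
    n_total = int(mask.sum())
    n_cyto = int(cyto.sum())
    if n_cyto == 0:
        raise EmptyCytoplasmError("all mask pixels excluded as nucleus/neuromelanin")
    means = {
        e.target: float(stack.pixels[e.channel_index][cyto].mean()) for e in stack.panel
    }
    return means, n_total, n_cyto


def extract_neuron_table(
    stack: ImageStack,
    rois: list[RoiPolygon],
    metadata: dict[str, tuple[str, float]],
    exclusion_targets: tuple[str, ...] = panel_mod.DEFAULT_EXCLUSION_TARGETS,
    threshold: float = panel_mod.DEFAULT_EXCLUSION_THRESHOLD,
) -> tuple[pd.DataFrame, list[dict]]:
    """One row per ROI with non-empty cytoplasm, in ROI order.

    ``metadata`` maps case_id -> (group, age).  Returns (table, dropped)
    where dropped lists {neuron_id, reason} for excluded ROIs.
    """
    rows = []
    dropped: list[dict] = []
    shape = stack.shape
    measured = [
        e.target
        for e in stack.panel
        if e.role in ("oxphos_subunit", "mass", "neuronal")
    ]
    for roi in rois:
        if roi.case_id not in metadata:
            raise DataError(f"unknown case_id {roi.case_id!r} in ROI {roi.neuron_id}")
        group, age = metadata[roi.case_id]
        mask = rasterize_roi(roi, shape)
        if not mask.any():
            dropped.append({"neuron_id": roi.neuron_id, "reason": "empty_mask"})
            continue
        try:
            means, n_total, n_cyto = cytoplasmic_mean(
                stack, mask, exclusion_targets, threshold
            )
        except EmptyCytoplasmError:
            dropped.append({"neuron_id": roi.neuron_id, "reason": "empty_cytoplasm"})
            continue
        row = {
            "neuron_id": roi.neuron_id,
            "case_id": roi.case_id,
            "group": group,
            "age": age,
        }
        row.update({t: means[t] for t in measured})
        row["n_pixels_total"] = n_total
        row["n_pixels_cytoplasm"] = n_cyto
        rows.append(row)
    columns = ["neuron_id", "case_id", "group", "age", *measured,
               "n_pixels_total", "n_pixels_cytoplasm"]
    table = pd.DataFrame(rows, columns=columns)
    return table, dropped


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------


def _disc_mask(shape, cx: float, cy: float, radius: float) -> np.ndarray:
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return (cols - cx) ** 2 + (rows - cy) ** 2 <= radius**2


def render_image(
    geometry: list[CellGeometry],
    table: pd.DataFrame,
    shape: tuple[int, int],
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    relative_noise: bool = False,
    marker_value: float = 20.0,
    th_value: float = 8.0,
) -> tuple[ImageStack, list[RoiPolygon]]:
    """Render a 12-channel stack from planned geometry and a neuron table.

    Cytoplasm pixels carry max(0, Normal(mean, SD)) per measured channel
    (SD = noise_sd, or noise_sd * mean when ``relative_noise``); nucleus
    discs light the nuclear channel and neuromelanin blobs the Ir channel
    above the exclusion threshold.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    entries = default_panel()
    index = {e.target: e.channel_index for e in entries}
    pixels = np.zeros((len(entries), *shape), dtype=np.float32)
    by_id = table.set_index("neuron_id")
    measured = list(panel_mod.SUBUNITS) + [panel_mod.MASS_TARGET]

    rois = []
    for cell in geometry:
        mask = rasterize_roi(cell.polygon, shape)
        npix = int(mask.sum())
        if npix == 0:
            raise GeometryError(f"cell {cell.neuron_id} rasterizes to zero pixels")
        row = by_id.loc[cell.neuron_id]
        for target in measured:
            mean = float(row[target])
            sd = noise_sd * mean if relative_noise else noise_sd
            if sd > 0:
                values = np.maximum(0.0, rng.normal(mean, sd, size=npix))
            else:
                values = np.full(npix, mean)
            pixels[index[target]][mask] = values
        pixels[index[panel_mod.NEURONAL_TARGET]][mask] = th_value
        nmask = _disc_mask(shape, *cell.nucleus_center, cell.nucleus_radius) & mask
        pixels[index[panel_mod.NUCLEAR_TARGET]][nmask] = marker_value
        for bx, by, br in cell.nm_blobs:
            bmask = _disc_mask(shape, bx, by, br) & mask
            pixels[index[panel_mod.INTERCALATOR_TARGET]][bmask] = marker_value
        rois.append(
            RoiPolygon(
                cell.neuron_id,
                cell.case_id,
                np.asarray(cell.polygon.exterior.coords)[:-1],
            )
        )
    return ImageStack(pixels=pixels, panel=entries), rois
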
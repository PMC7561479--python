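"""Synthetic ground-truthed photographs of fly-strewn paper sheets.

The generator emulates the prescribed imaging setup: a bright paper sheet
of known physical size on a dark, contrasting background, photographed
roughly from above with mild perspective, uneven illumination and sensor
noise.  Flies are rendered as a dark filled body ellipse with a smaller
tangent head blob; touching clusters are chains of overlapping flies;
debris are sub-threshold dark specks.  Every scene carries its full
ground truth (positions, lengths, cluster sizes, the sheet's corner
pixels and the clean object mask), so the whole pipeline can be scored
without any real photographs.

All randomness flows from ``SceneSpec.seed`` through one generator
stream.  Draw order, per object: length, aspect, orientation, intensity,
then candidate positions — so a fixed seed gives a bit-identical scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import ProjectiveTransform, resize, warp

from .errors import PlacementFailure
from .sheet import SheetSpec

#: keep-out distance between object silhouettes, mm (edge-to-edge)
MIN_SEPARATION_MM = 1.5
#: object keep-out from the sheet edge, mm (beyond the 2 mm analysis margin)
EDGE_MARGIN_MM = 5.0
#: paper and background base intensities, 8-bit
SHEET_INTENSITY = 235.0
BACKGROUND_INTENSITY = 30.0
#: fraction of the frame width occupied by the (untilted) sheet
SHEET_FRAME_FRACTION = 0.85

_MAX_PLACEMENT_TRIES = 300


@dataclass(frozen=True)
class SceneSpec:
    """Ground-truth description of one synthetic sheet photograph.

    ``clusters`` is a list of ``(k, overlap_fraction)`` pairs: ``k`` flies
    chained with each member overlapping its neighbour by roughly that
    fraction of a single-fly area.  Fly lengths are silhouette lengths
    (body plus appendage extent), drawn uniformly from
    ``singles_length_mm``.  The default population is homogeneous adults:
    lengths sit safely inside the default 3-14 mm length filter even
    after rasterisation clips sub-pixel ellipse tips (up to ~0.5 mm), and
    the implied area spread (smallest ~0.8x the mean) is compatible with
    the 0.71 trash-area factor, as a real single-age population must be
    for that default to work — so the ground-truth count is exact.
    """

    sheet: SheetSpec = field(default_factory=lambda: SheetSpec.iso("A4"))
    n_singles: int = 50
    singles_length_mm: tuple[float, float] = (3.8, 4.4)
    aspect_ratio: tuple[float, float] = (0.40, 0.46)
    clusters: tuple[tuple[int, float], ...] = ()
    n_debris: int = 6
    debris_length_mm: tuple[float, float] = (0.3, 1.5)
    illumination_gradient: float = 0.10  # relative intensity span in [0, 0.3]
    noise_sd: float = 3.0  # Gaussian pixel noise, 8-bit units
    perspective_tilt_deg: float = 8.0  # in [0, 30]
    output_long_side_px: int = 2000
    seed: int = 0
    shadow: bool = False  # attach a low-contrast wing-shadow lobe per fly

    def __post_init__(self) -> None:
        if not 0.0 <= self.illumination_gradient <= 0.3:
            raise ValueError("illumination_gradient must be in [0, 0.3]")
        if not 0.0 <= self.perspective_tilt_deg <= 30.0:
            raise ValueError("perspective_tilt_deg must be in [0, 30]")
        for k, ov in self.clusters:
            if k < 2 or not 0.0 <= ov <= 0.3:
                raise ValueError("clusters need k >= 2 and overlap_fraction in [0, 0.3]")

    @property
    def true_fly_count(self) -> int:
        return self.n_singles + sum(k for k, _ in self.clusters)


@dataclass(frozen=True)
class TruthRecord:
    """One placed object: a single fly, a cluster member, or debris."""

    category: str  # "single" | "cluster-member" | "debris"
    x_mm: float
    y_mm: float
    length_mm: float
    cluster_id: int = -1  # >= 0 for cluster members


@dataclass
class GroundTruth:
    """Everything needed to score the pipeline on a generated scene."""

    true_fly_count: int
    records: list[TruthRecord]
    sheet_quad_px: np.ndarray  # (4, 2) (x, y) corners in the output frame
    object_mask: np.ndarray  # fronto-parallel sheet-raster object mask
    sheet_mm_per_px: float  # scale of object_mask


# ---------------------------------------------------------------------------
# placement

class _Placer:
    """Rejection-sampling placement with a guaranteed keep-out distance."""

    def __init__(self, sheet: SheetSpec, rng: np.random.Generator):
        self.sheet = sheet
        self.rng = rng
        self.xs: list[float] = []
        self.ys: list[float] = []
        self.rs: list[float] = []

    def place(self, radius_mm: float) -> tuple[float, float]:
        lo_x = EDGE_MARGIN_MM + radius_mm
        hi_x = self.sheet.width_mm - lo_x
        lo_y = EDGE_MARGIN_MM + radius_mm
        hi_y = self.sheet.height_mm - lo_y
        if hi_x <= lo_x or hi_y <= lo_y:
            raise PlacementFailure("object too large for the sheet")
        xs = np.array(self.xs)
        ys = np.array(self.ys)
        rs = np.array(self.rs)
        for _ in range(_MAX_PLACEMENT_TRIES):
            x = self.rng.uniform(lo_x, hi_x)
            y = self.rng.uniform(lo_y, hi_y)
            if len(xs) == 0 or np.all(
                np.hypot(xs - x, ys - y) >= rs + radius_mm + MIN_SEPARATION_MM
            ):
                self.xs.append(x)
                self.ys.append(y)
                self.rs.append(radius_mm)
                return x, y
        raise PlacementFailure(
            f"could not place an object of radius {radius_mm:.1f} mm after "
            f"{_MAX_PLACEMENT_TRIES} tries"
        )


# ---------------------------------------------------------------------------
# drawing


def _draw_fly(
    canvas: np.ndarray,
    mask: np.ndarray,
    x_mm: float,
    y_mm: float,
    length_mm: float,
    aspect: float,
    phi: float,
    intensity: float,
    s: float,
    shadow: bool = False,
) -> None:
    """Paint one fly (body ellipse + head blob) at scale ``s`` px/mm.

    ``phi`` is the body axis angle in radians, measured from +x towards +y.
    """
    h, w = canvas.shape
    half = length_mm / 2.0
    ux, uy = np.cos(phi), np.sin(phi)
    # body: centred 0.08 L behind the silhouette centre, spans [-0.5 L, 0.34 L]
    bx, by = x_mm - 0.08 * length_mm * ux, y_mm - 0.08 * length_mm * uy
    a_body = 0.42 * length_mm
    b_body = aspect * half
    # skimage's ellipse rotation is the angle of the r-axis; draw with
    # r_radius along the minor axis and rotation = -phi for the (row, col) grid
    rr, cc = draw_ellipse(by * s, bx * s, b_body * s, a_body * s, shape=(h, w), rotation=-phi)
    canvas[rr, cc] = intensity
    mask[rr, cc] = True
    # head blob reaching the front tip at +0.5 L
    hx, hy = x_mm + 0.37 * length_mm * ux, y_mm + 0.37 * length_mm * uy
    r_head = 0.13 * length_mm
    rr, cc = draw_ellipse(hy * s, hx * s, r_head * s, r_head * s, shape=(h, w))
    canvas[rr, cc] = intensity
    mask[rr, cc] = True
    if shadow:
        # faint gray lobe beside the body, emulating a wing shadow
        sx = bx - 0.35 * length_mm * uy
        sy = by + 0.35 * length_mm * ux
        rr, cc = draw_ellipse(sy * s, sx * s, 0.3 * half * s, 0.8 * half * s, shape=(h, w), rotation=-phi)
        keep = canvas[rr, cc] > 180  # only darken bare paper, never the fly
        canvas[rr[keep], cc[keep]] = 185.0


def _tilted_quad(w_mm: float, h_mm: float, tilt_deg: float, scale: float) -> np.ndarray:
    """Project the sheet rectangle under a camera tilt about its horizontal axis.

    Pinhole model: the sheet is rotated by ``tilt_deg`` about the x-axis
    through its centre and projected with focal length 2.5x its larger
    dimension.  Returns (4, 2) corner offsets in px relative to the sheet
    centre, ordered TL, TR, BR, BL.
    """
    t = np.radians(tilt_deg)
    f = 2.5 * max(w_mm, h_mm)
    corners_mm = np.array(
        [[-w_mm / 2, -h_mm / 2], [w_mm / 2, -h_mm / 2], [w_mm / 2, h_mm / 2], [-w_mm / 2, h_mm / 2]]
    )
    out = np.empty_like(corners_mm)
    for i, (x, y) in enumerate(corners_mm):
        z = y * np.sin(t)
        k = f / (f + z)
        out[i] = (x * k, y * np.cos(t) * k)
    return out * scale


def _ellipse_support(a: float, b: float, phi: float, theta: float) -> float:
    """Half-extent of an ellipse (semi-axes a, b, orientation phi) along theta."""
    d = theta - phi
    return float(np.sqrt((a * np.cos(d)) ** 2 + (b * np.sin(d)) ** 2))


def _compact_cluster(
    lengths: np.ndarray, aspects: np.ndarray, ov: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Member centres and orientations for a compact touching clump.

    Real clumps of anaesthetised flies are roundish aggregates, not
    straight chains (a straight chain of 4+ flies would exceed the 14 mm
    length filter).  Each member after the first attaches tip-first to a
    random earlier member, overlapping it by roughly ``ov`` of a body
    length (at least 0.35 mm so rasterisation keeps the clump connected),
    and centres are kept within a 3.5 mm core radius so the clump stays
    well below the maximum object length.
    """
    k = len(lengths)
    centres = np.zeros((k, 2))
    phis = np.empty(k)
    phis[0] = rng.uniform(0, np.pi)
    max_spread = 8.0  # max centre-to-centre span, keeps extent under 14 mm
    for i in range(1, k):
        for attempt in range(60):
            j = int(rng.integers(0, i))
            theta = rng.uniform(0, 2 * np.pi)
            a_j = 0.5 * lengths[j]
            b_j = 0.5 * lengths[j] * aspects[j]
            depth = max(ov * lengths[i], 0.5)
            d = _ellipse_support(a_j, b_j, phis[j], theta) + lengths[i] / 2 - depth
            cand = centres[j] + d * np.array([np.cos(theta), np.sin(theta)])
            dists = np.hypot(*(centres[:i] - cand).T)
            spread_ok = dists.max() <= max_spread
            # overlap only the anchor: stay clear of every other member
            others = np.delete(np.arange(i), j)
            clear_ok = all(
                dists[m] >= 0.85 * (lengths[i] + lengths[m]) / 2 for m in others
            )
            if (spread_ok and clear_ok) or attempt == 59:
                centres[i] = cand
                phis[i] = theta  # member points away from its anchor
                break
    centres -= centres.mean(axis=0)
    return centres, phis


# ---------------------------------------------------------------------------
# scene generation


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; deterministic for a fixed ``spec.seed``.

    Returns the 8-bit grayscale frame and its ground truth.  Raises
    ``PlacementFailure`` when the separation constraints cannot be met.
    """
    rng = np.random.default_rng(spec.seed)
    sheet = spec.sheet

    # feasibility: total silhouette footprint must stay below 40% of the sheet
    mean_len = float(np.mean(spec.singles_length_mm))
    n_flies = spec.true_fly_count
    footprint = n_flies * np.pi * (mean_len / 2) ** 2 + spec.n_debris * np.pi * 0.75**2
    if footprint >= 0.4 * sheet.width_mm * sheet.height_mm:
        raise PlacementFailure("object footprint exceeds 40% of the sheet area")

    # frame geometry: 4:3 landscape, sheet centred under mild perspective
    frame_w = int(spec.output_long_side_px)
    frame_h = int(round(frame_w * 3 / 4))
    quad_scale = SHEET_FRAME_FRACTION * frame_w / sheet.width_mm
    quad = _tilted_quad(sheet.width_mm, sheet.height_mm, spec.perspective_tilt_deg, quad_scale)
    quad += np.array([frame_w / 2, frame_h / 2])

    # fronto-parallel sheet raster at a scale matching the projected size,
    # drawn 2x supersampled so object edges resolve sub-pixel (a hard
    # rasterisation would alias object sizes by several percent)
    s = 2.0 * quad_scale  # px per mm, supersampled
    sheet_w_px = int(round(sheet.width_mm * quad_scale))
    sheet_h_px = int(round(sheet.height_mm * quad_scale))
    canvas = np.full(
        (int(round(sheet.height_mm * s)), int(round(sheet.width_mm * s))),
        SHEET_INTENSITY, dtype=np.float32,
    )
    obj_mask = np.zeros_like(canvas, dtype=bool)

    placer = _Placer(sheet, rng)
    records: list[TruthRecord] = []

    for _ in range(spec.n_singles):
        length = rng.uniform(*spec.singles_length_mm)
        aspect = rng.uniform(*spec.aspect_ratio)
        phi = rng.uniform(0, np.pi)
        intensity = rng.uniform(20, 60)
        x, y = placer.place(length / 2)
        _draw_fly(canvas, obj_mask, x, y, length, aspect, phi, intensity, s, spec.shadow)
        records.append(TruthRecord("single", x, y, length))

    for cid, (k, ov) in enumerate(spec.clusters):
        lengths = rng.uniform(*spec.singles_length_mm, size=k)
        aspects = rng.uniform(*spec.aspect_ratio, size=k)
        intensities = rng.uniform(20, 60, size=k)
        centres, phis = _compact_cluster(lengths, aspects, ov, rng)
        radius = float(np.hypot(centres[:, 0], centres[:, 1]).max() + lengths.max() / 2)
        cx, cy = placer.place(radius)
        for i in range(k):
            x, y = cx + centres[i, 0], cy + centres[i, 1]
            _draw_fly(
                canvas, obj_mask, x, y, lengths[i], aspects[i],
                phis[i], intensities[i], s, spec.shadow,
            )
            records.append(TruthRecord("cluster-member", x, y, float(lengths[i]), cid))

    for _ in range(spec.n_debris):
        length = rng.uniform(*spec.debris_length_mm)
        aspect = rng.uniform(0.4, 0.9)
        phi = rng.uniform(0, np.pi)
        intensity = rng.uniform(20, 80)
        x, y = placer.place(length / 2)
        rr, cc = draw_ellipse(
            y * s, x * s, aspect * length / 2 * s, length / 2 * s,
            shape=canvas.shape, rotation=-phi,
        )
        if rr.size == 0:  # sub-pixel speck: paint its nearest pixel
            rr = np.array([int(round(y * s))])
            cc = np.array([int(round(x * s))])
        canvas[rr, cc] = intensity
        obj_mask[rr, cc] = True
        records.append(TruthRecord("debris", x, y, length))

    # soften edges down to the projection scale, then warp into the frame
    canvas = resize(canvas, (sheet_h_px, sheet_w_px), order=1, anti_aliasing=True).astype(np.float32)
    src_corners = np.array(
        [[-0.5, -0.5], [sheet_w_px - 0.5, -0.5], [sheet_w_px - 0.5, sheet_h_px - 0.5], [-0.5, sheet_h_px - 0.5]]
    )
    # frame (x, y) -> sheet raster (x, y)
    tform = ProjectiveTransform.from_estimate(quad, src_corners)
    frame = warp(canvas, tform, output_shape=(frame_h, frame_w), order=1, cval=-1.0, mode="constant")
    coverage = frame >= 0
    frame = np.where(coverage, frame, BACKGROUND_INTENSITY).astype(np.float32)

    if spec.illumination_gradient > 0:
        psi = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:frame_h, 0:frame_w]
        t = (xx * np.cos(psi) + yy * np.sin(psi)).astype(np.float32)
        t = (t - t.min()) / max(t.max() - t.min(), 1.0)
        frame *= 1.0 + spec.illumination_gradient * (t - 0.5)

    if spec.noise_sd > 0:
        frame += rng.normal(0.0, spec.noise_sd, size=frame.shape).astype(np.float32)

    image = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    truth = GroundTruth(
        true_fly_count=spec.true_fly_count,
        records=records,
        sheet_quad_px=quad,
        object_mask=obj_mask,
        sheet_mm_per_px=1.0 / s,
    )
    return image, truth


def degrade_resolution(image: np.ndarray, megapixels: float) -> np.ndarray:
    """Simulate a lower-resolution capture of the same frame.

    Downsamples to the pixel count implied by the megapixel target (at the
    frame's own aspect ratio), then upsamples back to the original shape,
    so downstream geometry is unchanged while detail is lost.
    """
    if megapixels <= 0:
        raise ValueError("megapixels must be positive")
    h, w = image.shape[:2]
    native = h * w / 1e6
    if megapixels >= native:
        return image.copy()
    scale = np.sqrt(megapixels / native)
    low_shape = (max(1, int(round(h * scale))), max(1, int(round(w * scale))))
    low = resize(image, low_shape, order=1, anti_aliasing=True)
    back = resize(low, (h, w), order=1, anti_aliasing=False)
    return np.clip(np.round(back * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# benchmark scene construction


def benchmark_spec(
    n_flies: int,
    seed: int,
    sheet: SheetSpec | None = None,
    cluster_fly_fraction: float = 0.02,
    **overrides,
) -> SceneSpec:
    """Scene spec for the accuracy benchmark regime.

    Contacts between flies are minimised, as in the imaging protocol the
    package emulates: by default 2% of flies sit in 2-3-fly touching
    clusters and the rest are well separated singles.
    """
    rng = np.random.default_rng(seed)
    sheet = sheet or SheetSpec.iso("A4")
    n_cluster_flies = int(np.floor(cluster_fly_fraction * n_flies))
    clusters: list[tuple[int, float]] = []
    remaining = n_cluster_flies
    while remaining >= 2:
        k = 3 if (remaining >= 3 and rng.random() < 0.5) else 2
        clusters.append((k, float(rng.uniform(0.05, 0.15))))
        remaining -= k
    n_singles = n_flies - sum(k for k, _ in clusters)
    return replace(
        SceneSpec(sheet=sheet, seed=seed),
        n_singles=n_singles,
        clusters=tuple(clusters),
        **overrides,
    )
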
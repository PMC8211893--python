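"""Synthetic corpus-callosum cohort generator.

Emulates the data a mid-sagittal CC shape study consumes: one labeled 1-mm
mask slice per subject plus a covariate table (group, gender, age, TIV).
The base shape is a stylized arched band (a C opening downward) between two
smooth radial profiles, with thickened anterior (genu) and posterior
(splenium) ends; sub-region labels split the arc into angular thirds
(configurable fractions), a stand-in for atlas-defined boundaries.

Per subject, in order: (1) global scaling by (TIV / reference TIV)^(1/3)
(cube root: TIV is a volume, the slice is a 2D section); (2) a random smooth
stationary velocity field (sum of Gaussian bumps) integrated by scaling and
squaring, so the subject warp is a diffeomorphism; (3) for patients, an
inward displacement along the outline normal over a configured arc-length
window (tapered-cosine profile) -- the injected "disease effect", applied to
females at full amplitude and to males scaled by ``effect_gender_ratio``;
(4) a small random rigid jitter.  The deformed outline is re-rasterized with
labels carried along.

Every subject has its own RNG stream keyed by (seed, subject_id), so
cohorts are reproducible and order-independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from . import geometry
from .curves import BODY, GENU, SPLENIUM, LabelSlice

GROUPS = ("FES", "HC")
GENDERS = ("F", "M")

# Base-shape geometry (mm, degrees): mid radius, angular span, half-thickness
# profile with Gaussian-thickened ends.
_BASE = dict(
    r0=24.0,
    theta_anterior_deg=210.0,
    theta_posterior_deg=-30.0,
    half_body=2.9,
    half_genu=5.5,
    half_splenium=5.2,
    end_width_deg=25.0,
)


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic cohort (2 groups x 2 genders)."""

    n_per_cell: int = 25
    effect_amplitude_mm: float = 0.8
    effect_support: tuple = (0.10, 0.18)  # arc-length fractions, half-open
    effect_gender_ratio: float = 0.0  # 0 = female-only effect
    warp_smoothness_mm: float = 6.0
    warp_amplitude_mm: float = 0.5
    n_warp_bumps: int = 200
    jitter_rot_deg: float = 2.0
    jitter_trans_mm: float = 1.0
    tiv_mean_by_gender: dict = field(default_factory=lambda: {"F": 1.45e6, "M": 1.38e6})
    tiv_sd: float = 8.0e4
    age_range: tuple = (12.0, 43.0)
    grid_shape: tuple = (128, 128)
    pixel_size_mm: float = 1.0
    region_fractions: tuple = (1.0 / 3.0, 2.0 / 3.0)
    base_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.effect_amplitude_mm < 0:
            raise ValueError("effect_amplitude_mm must be >= 0")
        if self.warp_smoothness_mm <= 0:
            raise ValueError("warp kernel width must be > 0")
        a, b = self.effect_support
        if not (0.0 <= a < 1.0 and 0.0 <= b <= 1.0 and a < b):
            raise ValueError("effect_support must be a half-open interval within [0, 1)")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    @property
    def tiv_reference(self) -> float:
        """Reference TIV for the cube-root size coupling (mean of gender means)."""
        return float(np.mean(list(self.tiv_mean_by_gender.values())))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str  # FES | HC
    gender: str  # F | M
    age: float  # years
    tiv: float  # mm^3

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.gender not in GENDERS:
            raise ValueError(f"gender must be one of {GENDERS}")
        if self.tiv <= 0:
            raise ValueError("tiv must be positive")


def subject_rng(seed: int, subject_id: str, purpose: str = "shape") -> np.random.Generator:
    """Deterministic RNG stream keyed by (seed, subject_id, purpose).

    Separate streams for covariate draws and shape sampling keep cohorts
    reproducible and order-independent.
    """
    key = zlib.crc32(f"{subject_id}/{purpose}".encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def base_cc_outline(grid_shape=(128, 128), scale: float = 1.0,
                    region_fractions=(1.0 / 3.0, 2.0 / 3.0),
                    spacing_mm: float = 0.5):
    """Analytic pre-raster outline of the base CC shape.

    Returns (points, labels): a closed clockwise polygon (y-up) starting at
    the anterior (genu) outer end, with per-point sub-region labels assigned
    by angular position (anterior third genu, middle body, posterior
    splenium).  Exposed so tests can use exact polygon areas as oracles.
    """
    ny, nx = grid_shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    th_a = np.deg2rad(_BASE["theta_anterior_deg"])
    th_p = np.deg2rad(_BASE["theta_posterior_deg"])
    w = np.deg2rad(_BASE["end_width_deg"])

    def half_thickness(theta):
        return (
            _BASE["half_body"]
            + (_BASE["half_genu"] - _BASE["half_body"]) * np.exp(-(((theta - th_a) / w) ** 2))
            + (_BASE["half_splenium"] - _BASE["half_body"]) * np.exp(-(((theta - th_p) / w) ** 2))
        )

    r0 = _BASE["r0"] * scale
    n_arc = max(32, int(round(r0 * (th_a - th_p) / spacing_mm)))
    th_out = np.linspace(th_a, th_p, n_arc)  # decreasing theta = clockwise over the top
    th_in = th_out[::-1]
    h_out = half_thickness(th_out) * scale
    h_in = half_thickness(th_in) * scale
    outer = np.stack([cx + (r0 + h_out) * np.cos(th_out), cy + (r0 + h_out) * np.sin(th_out)], axis=1)
    inner = np.stack([cx + (r0 - h_in) * np.cos(th_in), cy + (r0 - h_in) * np.sin(th_in)], axis=1)

    def cap(p_from, p_to):
        n = max(2, int(round(np.linalg.norm(p_to - p_from) / spacing_mm)))
        t = np.linspace(0.0, 1.0, n + 1)[1:-1]
        return p_from[None, :] * (1 - t[:, None]) + p_to[None, :] * t[:, None]

    cap_post = cap(outer[-1], inner[0])   # posterior end
    cap_ant = cap(inner[-1], outer[0])    # anterior end, closes the loop

    pts = np.vstack([outer, cap_post, inner, cap_ant])

    # angular fraction from the anterior end, shared by both profiles and caps
    theta = np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx)
    theta = np.where(theta < th_p - 1e-9, theta + 2 * np.pi, theta)
    frac = np.clip((th_a - theta) / (th_a - th_p), 0.0, 1.0)
    f1, f2 = region_fractions
    labels = np.where(frac < f1, GENU, np.where(frac < f2, BODY, SPLENIUM))
    return pts, labels


def _check_clipping(points: np.ndarray, grid_shape, margin: float = 1.0):
    ny, nx = grid_shape
    over = []
    if points[:, 0].min() < margin:
        over.append("left")
    if points[:, 0].max() > nx - 1 - margin:
        over.append("right")
    if points[:, 1].min() < margin:
        over.append("bottom")
    if points[:, 1].max() > ny - 1 - margin:
        over.append("top")
    if over:
        raise ValueError(f"shape clipped by grid boundary: overflow toward {', '.join(over)}")


def make_base_cc_shape(grid_shape=(128, 128), scale: float = 1.0,
                       region_fractions=(1.0 / 3.0, 2.0 / 3.0)) -> LabelSlice:
    """Rasterize the base CC shape onto a 1-mm grid as a labeled slice."""
    pts, labels = base_cc_outline(grid_shape, scale, region_fractions)
    _check_clipping(pts, grid_shape)
    grid = geometry.rasterize_labeled_polygon(pts, labels, grid_shape)
    return LabelSlice(grid=grid, pixel_size_mm=1.0, subject_id="base",
                      outline=(pts, labels), meta={"scale": scale})


# ---------------------------------------------------------------------------
# random diffeomorphic warps (stationary velocity field, scaling & squaring)
# ---------------------------------------------------------------------------

def _svf_warp(points: np.ndarray, centers: np.ndarray, amps: np.ndarray,
              sigma: float, grid_spacing: float = 2.0):
    """Warp ``points`` by the flow of a stationary Gaussian-bump velocity field.

    The field is sampled on a subgrid covering the points (padded by 3 sigma),
    integrated by scaling and squaring, and the final displacement is
    interpolated at the points.  Returns (warped_points, min_jacobian_det)
    where the determinant is checked by finite differences on the grid.
    """
    lo = points.min(axis=0) - 3.0 * sigma
    hi = points.max(axis=0) + 3.0 * sigma
    xs = np.arange(lo[0], hi[0] + grid_spacing, grid_spacing)
    ys = np.arange(lo[1], hi[1] + grid_spacing, grid_spacing)
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    gpts = np.stack([gx.ravel(), gy.ravel()], axis=1)

    d2 = ((gpts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    k = np.exp(-d2 / sigma ** 2)
    v = (k @ amps).reshape(gy.shape + (2,))

    vmax = float(np.abs(v).max())
    if vmax == 0.0:
        return points.copy(), 1.0
    n_square = int(np.clip(np.ceil(np.log2(max(vmax / (0.25 * grid_spacing), 1e-12))) + 2, 3, 10))
    u = v / (2 ** n_square)

    def sample(field, q):
        # q: (..., 2) in mm; field (ny, nx); bilinear with edge clamping
        ci = (q[..., 0] - lo[0]) / grid_spacing
        ri = (q[..., 1] - lo[1]) / grid_spacing
        return ndimage.map_coordinates(field, [ri.ravel(), ci.ravel()], order=1,
                                       mode="nearest").reshape(q.shape[:-1])

    base = np.stack([gx, gy], axis=-1)
    for _ in range(n_square):
        q = base + u
        u = u + np.stack([sample(u[..., 0], q), sample(u[..., 1], q)], axis=-1)

    # fold check: Jacobian of x + u(x) by central differences on the grid
    duy_dy, duy_dx = np.gradient(u[..., 1], grid_spacing)
    dux_dy, dux_dx = np.gradient(u[..., 0], grid_spacing)
    det = (1.0 + dux_dx) * (1.0 + duy_dy) - dux_dy * duy_dx
    min_det = float(det.min())
    if min_det <= 0.0:
        raise ValueError(
            "random warp folds (non-positive Jacobian on the grid); "
            "reduce warp_amplitude_mm or increase warp_smoothness_mm"
        )
    disp = np.stack([sample(u[..., 0], points), sample(u[..., 1], points)], axis=-1)
    return points + disp, min_det


def _effect_window(frac: np.ndarray, support, taper: float = 0.5) -> np.ndarray:
    """Tapered-cosine (Tukey) window over an arc-fraction interval, integral
    0.75 x amplitude x support length for the default taper of 0.5."""
    a, b = support
    u = (frac - a) / (b - a)
    w = np.zeros_like(frac)
    inside = (u >= 0) & (u < 1)
    ui = u[inside]
    wi = np.ones_like(ui)
    half = taper / 2.0
    lo = ui < half
    hi = ui > 1 - half
    wi[lo] = 0.5 * (1 + np.cos(np.pi * (ui[lo] / half - 1)))
    wi[hi] = 0.5 * (1 + np.cos(np.pi * ((ui[hi] - 1 + half) / half)))
    w[inside] = wi
    return w


def sample_subject_outline(base: LabelSlice, record: SubjectRecord,
                           cfg: SyntheticConfig, rng: np.random.Generator):
    """Pre-raster deformed outline for one subject (points, labels, diagnostics).

    Applies, in order: TIV scaling, random diffeomorphic warp, group effect
    (inward normal displacement over the configured arc window; FES only,
    gender-weighted), rigid jitter.
    """
    if base.outline is not None:
        pts, labels = base.outline
        pts = pts.copy()
    else:
        from .curves import trace_boundary

        bc = trace_boundary(base)
        pts, labels = bc.points.copy(), bc.labels.copy()

    diag = {}
    centroid = pts.mean(axis=0)

    # (1) global TIV scaling (cube root: volume -> linear scale)
    s = (record.tiv / cfg.tiv_reference) ** (1.0 / 3.0)
    pts = centroid + (pts - centroid) * s
    diag["scale"] = float(s)

    # (2) random smooth diffeomorphic warp; the bump amplitudes are
    # normalized so warp_amplitude_mm is the RMS velocity (per component)
    # of the field along the outline -- the knob reads in mm of typical
    # boundary displacement regardless of bump count or box size.
    if cfg.warp_amplitude_mm > 0 and cfg.n_warp_bumps > 0:
        lo = pts.min(axis=0) - cfg.warp_smoothness_mm
        hi = pts.max(axis=0) + cfg.warp_smoothness_mm
        centers = rng.uniform(lo, hi, size=(cfg.n_warp_bumps, 2))
        amps = rng.normal(0.0, 1.0, size=(cfg.n_warp_bumps, 2))
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        v0 = np.exp(-d2 / cfg.warp_smoothness_mm ** 2) @ amps
        rms = float(np.sqrt(np.mean(v0 ** 2)))
        if rms > 0:
            amps *= cfg.warp_amplitude_mm / rms
            pts, min_det = _svf_warp(pts, centers, amps, cfg.warp_smoothness_mm)
            diag["warp_min_jacobian"] = min_det
    else:
        # keep the stream aligned whether or not the warp is applied
        rng.uniform(size=(cfg.n_warp_bumps, 2))
        rng.normal(size=(cfg.n_warp_bumps, 2))

    # (3) localized inward group effect (patients only)
    amp = 0.0
    if record.group == "FES" and cfg.effect_amplitude_mm > 0:
        amp = cfg.effect_amplitude_mm * (1.0 if record.gender == "F" else cfg.effect_gender_ratio)
    if amp > 0:
        cum = geometry.cumulative_arclength(pts)
        frac = cum[:-1] / cum[-1]
        window = _effect_window(frac, cfg.effect_support)
        normals = geometry.outward_normals(pts)
        pts = pts - amp * window[:, None] * normals
    diag["effect_amplitude"] = float(amp)

    # (4) rigid jitter
    theta = rng.normal(0.0, np.deg2rad(cfg.jitter_rot_deg)) if cfg.jitter_rot_deg > 0 else 0.0
    trans = rng.normal(0.0, cfg.jitter_trans_mm, size=2) if cfg.jitter_trans_mm > 0 else np.zeros(2)
    c = pts.mean(axis=0)
    pts = geometry.apply_rigid(pts - c, theta, trans) + c
    diag["jitter"] = (float(theta), trans.tolist())
    return pts, labels, diag


def sample_subject_shape(base: LabelSlice, record: SubjectRecord,
                         cfg: SyntheticConfig, rng: np.random.Generator) -> LabelSlice:
    """Rasterized labeled mask for one subject (see sample_subject_outline)."""
    pts, labels, diag = sample_subject_outline(base, record, cfg, rng)
    _check_clipping(pts, cfg.grid_shape)
    grid = geometry.rasterize_labeled_polygon(pts, labels, cfg.grid_shape)
    return LabelSlice(grid=grid, pixel_size_mm=cfg.pixel_size_mm,
                      subject_id=record.subject_id, outline=(pts, labels), meta=diag)


def generate_records(cfg: SyntheticConfig) -> list:
    """Draw the covariate records for a balanced 2 x 2 x n_per_cell cohort."""
    if cfg.n_per_cell < 2:
        raise ValueError("n_per_cell must be >= 2 (group statistics undefined otherwise)")
    records = []
    for group in GROUPS:
        for gender in GENDERS:
            for i in range(cfg.n_per_cell):
                sid = f"{group}-{gender}-{i:03d}"
                rng = subject_rng(cfg.seed, sid, "covariates")
                age = float(rng.uniform(*cfg.age_range))
                # mild age coupling so TIV (hence scale) correlates with age
                tiv = float(rng.normal(cfg.tiv_mean_by_gender[gender], cfg.tiv_sd)
                            - 600.0 * (age - np.mean(cfg.age_range)))
                tiv = max(tiv, 0.5 * cfg.tiv_mean_by_gender[gender])
                records.append(SubjectRecord(sid, group, gender, age, tiv))
    return records


def generate_cohort(cfg: SyntheticConfig):
    """Generate the full cohort: (list of LabelSlice, covariate DataFrame).

    Deterministic for a given config: every subject draws from its own
    (seed, subject_id)-keyed stream.
    """
    records = generate_records(cfg)
    base = make_base_cc_shape(cfg.grid_shape, cfg.base_scale, cfg.region_fractions)
    slices = []
    for rec in records:
        rng = subject_rng(cfg.seed, rec.subject_id, "shape")
        slices.append(sample_subject_shape(base, rec, cfg, rng))
    cov = pd.DataFrame(
        [(r.subject_id, r.group, r.gender, r.age, r.tiv) for r in records],
        columns=["subject_id", "group", "gender", "age", "tiv"],
    )
    return slices, cov


def effect_support_on_curve(curve_points: np.ndarray, base: LabelSlice,
                            cfg: SyntheticConfig) -> np.ndarray:
    """Map the injected effect support onto another curve's vertex indices.

    Projects the base-outline points inside the effect window onto the given
    curve (nearest vertex in space) and returns the boolean vertex mask.
    Useful as the localization oracle: the generator knows exactly where the
    effect was injected.
    """
    pts, _ = base.outline
    cum = geometry.cumulative_arclength(pts)
    frac = cum[:-1] / cum[-1]
    a, b = cfg.effect_support
    src = pts[(frac >= a) & (frac < b)]
    mask = np.zeros(len(curve_points), dtype=bool)
    if len(src) == 0:
        return mask
    mask[np.unique(geometry.nearest_vertex_index(curve_points, src))] = True
    return mask


def effect_localization_fraction(template, indices, base: LabelSlice,
                                 cfg: SyntheticConfig, sigma_mm: float) -> float:
    """Fraction of the given template-point indices that localize to the
    injected effect: they carry the genu label or lie within ``sigma_mm``
    cyclic arc distance of the support projected onto the template.

    The generator knows exactly where the effect was injected, so this is
    the localization oracle for recovery experiments.
    """
    indices = np.asarray(indices, dtype=int)
    if len(indices) == 0:
        return float("nan")
    pts = template.points
    labels = template.labels
    arc = geometry.cumulative_arclength(pts)[:-1]
    period = geometry.perimeter(pts)
    sup = effect_support_on_curve(pts, base, cfg)
    ok = labels[indices] == GENU
    if sup.any():
        sup_arc = arc[sup]
        d = np.abs(arc[indices][:, None] - sup_arc[None, :])
        d = np.minimum(d, period - d).min(axis=1)
        ok = ok | (d <= sigma_mm)
    return float(np.mean(ok))
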
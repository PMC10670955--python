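"""Synthetic calibrated phantoms, Ussing-chamber traces, and assay tables.

Every generator is a pure function of its parameter object (including the
seed), returns exact ground truth alongside the data, and uses one private
:class:`numpy.random.Generator` per call — no global random state.

The tissue phantom emulates a two-channel fluorescence micrograph of a
bladder section: channel 0 is the urothelium marker (a curved band of known
centerline length), channel 1 the nuclear stain (elliptical nuclei placed at
deterministic arc-length spacing so the true linear density is exact, plus
optional sub-threshold debris and out-of-band clutter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import integrate, ndimage
from skimage.draw import ellipse as draw_ellipse

from .density import Micrograph
from .teer import ElectroTrace

__all__ = [
    "TissuePhantomParams",
    "GroundTruth",
    "UssingSimParams",
    "AssayTableParams",
    "ElectroTrace",
    "default_schedule",
    "generate_tissue_phantom",
    "generate_ussing_trace_set",
    "generate_assay_tables",
]


# --------------------------------------------------------------------------
# tissue phantom
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TissuePhantomParams:
    """Parameters of a two-channel tissue phantom.

    Nucleus sizes are ellipse *semi*-axes in micrometres.  Debris objects
    are rendered with area < 1 um^2 (inside the A_min sweep range) so that
    the minimum-area filter has a visible, controllable effect; clutter
    objects are nucleus-sized but lie outside the band.
    """

    image_height_px: int = 256
    image_width_px: int = 512
    pixel_size_um: float = 0.5
    centerline_kind: Literal["straight", "sinusoid", "arc"] = "straight"
    amplitude_um: float = 20.0          # sinusoid only
    wavelength_um: float = 120.0        # sinusoid only
    arc_radius_um: float = 50.0         # arc only
    arc_span_rad: float = math.pi       # arc only
    band_thickness_um: float = 16.0
    target_density_per_um: float = 0.12
    nucleus_major_um: float = 3.0
    nucleus_minor_um: float = 2.0
    band_intensity: float = 200.0
    nucleus_intensity: float = 220.0
    background_intensity: float = 10.0
    gaussian_noise_sd: float = 0.0
    debris_count: int = 0
    clutter_count: int = 0
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.band_thickness_um <= 2 * self.nucleus_minor_um:
            raise ValueError(
                "band_thickness_um must exceed twice the nucleus minor semi-axis"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        vmax = 2 ** self.bit_depth - 1
        for name in ("band_intensity", "nucleus_intensity", "background_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= vmax:
                raise ValueError(f"{name}={v} outside bit depth range [0, {vmax}]")
        if self.gaussian_noise_sd < 0:
            raise ValueError("gaussian_noise_sd must be non-negative")
        if self.target_density_per_um < 0:
            raise ValueError("target_density_per_um must be non-negative")
        if self.debris_count < 0 or self.clutter_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Exact construction truth accompanying a tissue phantom."""

    centerline_length_um: float
    in_band_nucleus_count: int
    nucleus_areas_um2: list[float]
    true_density_per_um: float
    placed_centroids: np.ndarray        # (n, 2) float, (row, col) pixels
    band_mask: np.ndarray               # bool raster of the noise-free band


def _centerline_points(params: TissuePhantomParams) -> tuple[np.ndarray, float]:
    """Dense (x, y) centerline samples in um and the analytic curve length.

    Raises ``ValueError`` when the band (centerline inflated by half its
    thickness plus one nucleus) does not fit on the canvas.
    """
    h_um = params.image_height_px * params.pixel_size_um
    w_um = params.image_width_px * params.pixel_size_um
    margin = params.band_thickness_um / 2 + params.nucleus_major_um + 1.0
    step = params.pixel_size_um / 4.0

    if params.centerline_kind == "straight":
        x0, x1 = margin, w_um - margin
        if x1 <= x0 or 2 * margin >= h_um:
            raise ValueError("straight band does not fit the canvas")
        n = max(2, int((x1 - x0) / step))
        x = np.linspace(x0, x1, n)
        y = np.full_like(x, h_um / 2)
        length = x1 - x0
    elif params.centerline_kind == "sinusoid":
        a, lam = params.amplitude_um, params.wavelength_um
        if lam <= 0:
            raise ValueError("wavelength_um must be positive")
        x0, x1 = margin, w_um - margin
        if x1 <= x0 or h_um / 2 + a + margin > h_um or h_um / 2 - a - margin < 0:
            raise ValueError("sinusoid band does not fit the canvas")
        n = max(2, int((x1 - x0) / step))
        x = np.linspace(x0, x1, n)
        k = 2 * math.pi / lam
        y = h_um / 2 + a * np.sin(k * (x - x0))
        length = integrate.quad(
            lambda t: math.hypot(1.0, a * k * math.cos(k * (t - x0))), x0, x1,
            limit=200,
        )[0]
    elif params.centerline_kind == "arc":
        r, span = params.arc_radius_um, params.arc_span_rad
        if r <= 0 or not 0 < span <= 2 * math.pi:
            raise ValueError("arc radius must be positive and span in (0, 2*pi]")
        cx, cy = w_um / 2, h_um / 2 + r / 2
        phi = np.linspace(-span / 2, span / 2, max(2, int(r * span / step)))
        x = cx + r * np.sin(phi)
        y = cy - r * np.cos(phi)
        if (x.min() < margin or x.max() > w_um - margin
                or y.min() < margin or y.max() > h_um - margin):
            raise ValueError("arc band does not fit the canvas")
        length = r * span
    else:  # pragma: no cover - guarded by dataclass Literal
        raise ValueError(f"unknown centerline kind {params.centerline_kind!r}")

    return np.column_stack([x, y]), float(length)


def _rasterize_band(points_um: np.ndarray, params: TissuePhantomParams) -> np.ndarray:
    """Boolean band mask: pixels within half the band thickness of the
    centerline, with square-cut ends (no rounded caps), so the ribbon's
    ideal centerline length equals the analytic curve length."""
    from scipy.spatial import cKDTree

    shape = (params.image_height_px, params.image_width_px)
    px = params.pixel_size_um
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    pix_um = np.column_stack([cols.ravel() * px, rows.ravel() * px])
    tree = cKDTree(points_um)
    dist, idx = tree.query(pix_um, k=1)
    in_band = dist <= params.band_thickness_um / 2

    # trim the end caps: drop pixels beyond the terminal cross-sections
    t0 = points_um[1] - points_um[0]
    t0 /= np.linalg.norm(t0)
    t1 = points_um[-1] - points_um[-2]
    t1 /= np.linalg.norm(t1)
    at_start = idx == 0
    at_end = idx == len(points_um) - 1
    in_band[at_start] &= (pix_um[at_start] - points_um[0]) @ t0 >= 0
    in_band[at_end] &= (pix_um[at_end] - points_um[-1]) @ t1 <= 0
    return in_band.reshape(shape)


def _arc_length_param(points_um: np.ndarray) -> np.ndarray:
    seg = np.hypot(*np.diff(points_um, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(seg)])


def generate_tissue_phantom(
    params: TissuePhantomParams,
) -> tuple[Micrograph, GroundTruth]:
    """Render a two-channel phantom micrograph with exact ground truth.

    Channel 0 carries the urothelial band, channel 1 the nuclei plus any
    debris (< 1 um^2, in-band) and clutter (nucleus-like, out-of-band).
    Nuclei are centred at deterministic arc-length spacing 1/density with
    seeded jitter bounded so every nucleus stays fully inside the band;
    the reported count is exactly ``round(target_density * length)``.
    """
    rng = np.random.default_rng(params.seed)
    pts, length_um = _centerline_points(params)
    band = _rasterize_band(pts, params)
    px = params.pixel_size_um
    shape = (params.image_height_px, params.image_width_px)

    s = _arc_length_param(pts)
    total = s[-1]
    # unit tangents along the polyline, for orienting nuclei
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.hypot(*tang.T)[:, None], 1e-12)

    n_nuclei = int(round(params.target_density_per_um * length_um))
    centroids_px: list[tuple[float, float]] = []
    nuc_canvas = np.zeros(shape, dtype=bool)

    if n_nuclei > 0:
        spacing = length_um / n_nuclei
        # jitter bounds guaranteeing non-overlap along the curve (with at
        # least one pixel of clearance after rasterization) and full
        # containment in the band
        along_bound = max(0.0, 0.25 * (spacing - 2 * params.nucleus_major_um))
        cross_bound = max(
            0.0, params.band_thickness_um / 2 - params.nucleus_major_um - 0.5
        )
        for i in range(n_nuclei):
            si = (i + 0.5) * spacing * (total / length_um)
            si = si + rng.uniform(-along_bound, along_bound)
            si = float(np.clip(si, 0.0, total))
            xi = np.interp(si, s, pts[:, 0])
            yi = np.interp(si, s, pts[:, 1])
            j = int(np.searchsorted(s, si).clip(0, len(pts) - 1))
            tx, ty = tang[j]
            nx, ny = -ty, tx  # unit normal
            off = rng.uniform(-cross_bound, cross_bound)
            xi, yi = xi + off * nx, yi + off * ny
            theta = math.atan2(ty, tx) + rng.uniform(-0.3, 0.3)
            rr, cc = draw_ellipse(
                yi / px, xi / px,
                params.nucleus_minor_um / px, params.nucleus_major_um / px,
                shape=shape, rotation=theta,
            )
            nuc_canvas[rr, cc] = True
            centroids_px.append((yi / px, xi / px))

    areas: list[float] = []
    if centroids_px:
        lbl, _ = ndimage.label(nuc_canvas, structure=np.ones((3, 3), dtype=int))
        counts = np.bincount(lbl.ravel())
        for r, c in centroids_px:
            areas.append(float(counts[lbl[int(round(r)), int(round(c))]]) * px * px)

    occupied = ndimage.binary_dilation(nuc_canvas, iterations=max(2, int(2.0 / px)))

    debris_canvas = np.zeros(shape, dtype=bool)
    max_debris_px = max(1, int(math.floor(0.99 / (px * px))))
    band_free = np.argwhere(band & ~occupied)
    for _ in range(params.debris_count):
        if len(band_free) == 0:
            break
        r, c = band_free[rng.integers(len(band_free))]
        npx = int(rng.integers(1, max_debris_px + 1))
        debris_canvas[r, c:c + npx] = True  # sub-1 um^2 streak inside the band

    clutter_canvas = np.zeros(shape, dtype=bool)
    far = ndimage.distance_transform_edt(~band) * px > params.nucleus_major_um + 1.0
    far[: int(2 * params.nucleus_major_um / px), :] = False
    far[-int(2 * params.nucleus_major_um / px):, :] = False
    far[:, : int(2 * params.nucleus_major_um / px)] = False
    far[:, -int(2 * params.nucleus_major_um / px):] = False
    out_positions = np.argwhere(far)
    for _ in range(params.clutter_count):
        if len(out_positions) == 0:
            break
        r, c = out_positions[rng.integers(len(out_positions))]
        rr, cc = draw_ellipse(
            r, c, params.nucleus_minor_um / px, params.nucleus_major_um / px,
            shape=shape, rotation=rng.uniform(0, math.pi),
        )
        clutter_canvas[rr, cc] = True

    vmax = 2 ** params.bit_depth - 1
    ch_band = np.where(band, params.band_intensity, params.background_intensity)
    ch_nuc = np.where(
        nuc_canvas | debris_canvas | clutter_canvas,
        params.nucleus_intensity, params.background_intensity,
    )
    if params.gaussian_noise_sd > 0:
        ch_band = ch_band + rng.normal(0, params.gaussian_noise_sd, shape)
        ch_nuc = ch_nuc + rng.normal(0, params.gaussian_noise_sd, shape)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    channels = np.stack([
        np.clip(np.round(ch_band), 0, vmax).astype(dtype),
        np.clip(np.round(ch_nuc), 0, vmax).astype(dtype),
    ])

    micro = Micrograph(
        channels=channels, pixel_size_um=px, bit_depth=params.bit_depth,
        section_id="phantom", roi_index=0,
    )
    centroid_arr = np.asarray(centroids_px, dtype=float).reshape(-1, 2)
    # construction guarantee: every centroid lies inside the band mask
    for r, c in centroid_arr:
        if not band[int(round(r)), int(round(c))]:
            raise RuntimeError("internal error: nucleus centroid left the band")
    truth = GroundTruth(
        centerline_length_um=length_um,
        in_band_nucleus_count=n_nuclei,
        nucleus_areas_um2=areas,
        true_density_per_um=n_nuclei / length_um,
        placed_centroids=centroid_arr,
        band_mask=band,
    )
    return micro, truth


# --------------------------------------------------------------------------
# Ussing-chamber traces
# --------------------------------------------------------------------------

def default_schedule() -> list[int]:
    """Recording schedule (min): every 10 to 30, every 5 to 60, every 10 to
    120, every 20 thereafter up to 360."""
    return (
        list(range(0, 30, 10))
        + list(range(30, 60, 5))
        + list(range(60, 120, 10))
        + list(range(120, 361, 20))
    )


@dataclass(frozen=True)
class UssingSimParams:
    """Simulated Ussing-chamber experiment.

    The trace holds the baseline TEER through a 30 min equilibration
    plateau, drops to ``1 - pll_drop_fraction`` of baseline at 45 min
    (15 min polycation exposure starting at 30 min), then recovers
    exponentially toward ``recovery_plateau_fraction`` of baseline with the
    given half time.  Noise is multiplicative on the total resistance.
    """

    baseline_teer_ohm_cm2: float = 150.0
    blank_resistance_ohm: float = 100.0
    window_area_cm2: float = 0.0314
    pll_drop_fraction: float = 0.6
    recovery_half_time_min: float = 60.0
    recovery_plateau_fraction: float = 0.85
    noise_cv: float = 0.03
    schedule: tuple[int, ...] = field(default_factory=lambda: tuple(default_schedule()))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_teer_ohm_cm2 <= 0 or self.window_area_cm2 <= 0:
            raise ValueError("baseline TEER and window area must be positive")
        if self.blank_resistance_ohm < 0 or self.noise_cv < 0:
            raise ValueError("blank resistance and noise_cv must be non-negative")
        if not 0 <= self.pll_drop_fraction <= 1:
            raise ValueError("pll_drop_fraction must be in [0, 1]")
        if self.recovery_half_time_min <= 0:
            raise ValueError("recovery_half_time_min must be positive")
        if not 0 <= self.recovery_plateau_fraction <= 1:
            raise ValueError("recovery_plateau_fraction must be in [0, 1]")
        if self.recovery_plateau_fraction < 1 - self.pll_drop_fraction:
            raise ValueError("recovery plateau below the post-drop floor")
        sched = np.asarray(self.schedule, dtype=float)
        if len(sched) < 2 or np.any(np.diff(sched) <= 0):
            raise ValueError("schedule must be strictly increasing")
        if 30 not in self.schedule:
            raise ValueError("schedule must contain the 30 min anchor")


def _teer_profile(t: float, p: UssingSimParams) -> float:
    base = p.baseline_teer_ohm_cm2
    floor = base * (1 - p.pll_drop_fraction)
    if t <= 30:
        return base
    if t <= 45:  # linear decline over the 15 min exposure
        return base + (floor - base) * (t - 30) / 15
    plateau = base * p.recovery_plateau_fraction
    return floor + (plateau - floor) * (1 - 2 ** (-(t - 45) / p.recovery_half_time_min))


def generate_ussing_trace_set(
    params: UssingSimParams, n_chambers: int
) -> list[ElectroTrace]:
    """Simulate ``n_chambers`` chambers; sexes alternate, treatment Ctrl."""
    if n_chambers < 1:
        raise ValueError("n_chambers must be >= 1")
    rng = np.random.default_rng(params.seed)
    traces = []
    for i in range(n_chambers):
        readings = []
        for t in params.schedule:
            teer = _teer_profile(float(t), params)
            r_total = teer / params.window_area_cm2 + params.blank_resistance_ohm
            if params.noise_cv > 0:
                r_total *= 1 + params.noise_cv * rng.standard_normal()
                r_total = max(r_total, params.blank_resistance_ohm)
            readings.append((float(t), float(r_total)))
        traces.append(ElectroTrace(
            chamber_id=f"ch{i + 1:02d}",
            sex="male" if i % 2 == 0 else "female",
            treatment="Ctrl",
            readings=tuple(readings),
            blank_resistance_ohm=params.blank_resistance_ohm,
            window_area_cm2=params.window_area_cm2,
        ))
    return traces


# --------------------------------------------------------------------------
# assay tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayTableParams:
    """Parameters for synthetic qPCR, urine-chemistry, or DE tables.

    ``group_effect`` means: Ct shift added to group B's target gene (qpcr),
    multiplicative K+/creatinine ratio of group B vs A (urine), or the
    |log2 fold change| of planted deregulated genes (dge).
    """

    kind: Literal["qpcr", "urine", "dge"] = "qpcr"
    n_per_group: int = 4
    group_effect: float = 0.0
    n_genes: int = 100
    n_planted: int = 6
    n_planted_up: int | None = None
    noise_sd: float = 0.0
    contrast: str = "C1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("qpcr", "urine", "dge"):
            raise ValueError(f"unknown assay table kind {self.kind!r}")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.kind == "dge" and self.n_planted > self.n_genes:
            raise ValueError("n_planted must not exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_assay_tables(params: AssayTableParams):
    """Emit a :class:`pandas.DataFrame` of the requested assay kind."""
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    n = params.n_per_group

    if params.kind == "qpcr":
        rows = []
        for group, shift in (("A", 0.0), ("B", params.group_effect)):
            for i in range(n):
                tgt = 25.0 + shift
                ctl = 20.0
                rows.append({
                    "sample_id": f"{group}{i + 1}",
                    "group": group,
                    "target_ct_1": tgt + params.noise_sd * rng.standard_normal(),
                    "target_ct_2": tgt + params.noise_sd * rng.standard_normal(),
                    "control_ct_1": ctl + params.noise_sd * rng.standard_normal(),
                    "control_ct_2": ctl + params.noise_sd * rng.standard_normal(),
                })
        return pd.DataFrame(rows)

    if params.kind == "urine":
        ratio = params.group_effect if params.group_effect > 0 else 1.0
        rows = []
        for group, mult in (("A", 1.0), ("B", ratio)):
            for i in range(n):
                creat = max(0.1, 0.6 + 0.1 * params.noise_sd * rng.standard_normal())
                k = max(0.0, 150.0 * mult + params.noise_sd * rng.standard_normal())
                rows.append({
                    "sample_id": f"{group}{i + 1}",
                    "group": group,
                    "k_mmol_per_l": k,
                    "creatinine_g_per_l": creat,
                })
        return pd.DataFrame(rows)

    # dge
    n_up = params.n_planted_up
    if n_up is None:
        n_up = params.n_planted // 2
    if n_up > params.n_planted:
        raise ValueError("n_planted_up exceeds n_planted")
    n_down = params.n_planted - n_up
    effect = abs(params.group_effect) if params.group_effect else 2.0
    rows = []
    for i in range(n_up):
        rows.append({
            "gene": f"DEG_UP_{i + 1}", "contrast": params.contrast,
            "log2fc": effect + 0.1 * rng.standard_normal(),
            "p_adj": float(rng.uniform(1e-6, 0.049)),
        })
    for i in range(n_down):
        rows.append({
            "gene": f"DEG_DOWN_{i + 1}", "contrast": params.contrast,
            "log2fc": -(effect + 0.1 * rng.standard_normal()),
            "p_adj": float(rng.uniform(1e-6, 0.049)),
        })
    for i in range(params.n_genes - params.n_planted):
        rows.append({
            "gene": f"GENE_{i + 1}", "contrast": params.contrast,
            "log2fc": float(0.2 * rng.standard_normal()),
            "p_adj": float(rng.uniform(0.05, 1.0)),
        })
    import pandas as pd
    return pd.DataFrame(rows)
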
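"""Seeded ground-truthed generators for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes — ZO-1 ring fields over DAPI nuclei, branched 3D mitochondrial
tubes under a Gaussian PSF with a SOX2-positive region, marker/DAPI nuclei
fields with a known positive fraction, grouped Gaussian measurements with
planted gross outliers, and log-normal metabolite tables with planted
per-genotype fold changes — and returns the fixture together with a
GroundTruth record of every planted parameter.

Noise model: Gaussian background plus Poisson shot noise on the signal.
SNR is defined as (mean object intensity − background mean) / background
SD. Objects are rasterized on a 2× oversampled grid and downsampled to
reduce aliasing, so analytic-versus-measured comparisons are meaningful.
Identical (seed, parameters) produce identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, InvalidParameterError, PackingError
from .imaging_core import BinaryMask, ImageStack
from .metabolomics_stats import MetaboliteTable

GENERATOR_VERSION = "1.0"


@dataclass
class GroundTruth:
    """Planted-parameter record for one synthetic fixture."""

    fixture_kind: str  # rosette | mito | marker | grouped | metabolite
    planted_objects: list[dict]
    seed: int
    generator_version: str = GENERATOR_VERSION
    params: dict = field(default_factory=dict)


def _apply_noise(
    signal: np.ndarray, bg_mean: float, bg_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian background + Poisson shot noise, clipped to non-negative."""
    noisy = rng.normal(bg_mean, bg_sd, size=signal.shape)
    noisy += rng.poisson(np.clip(signal, 0, None)).astype(float)
    return np.clip(noisy, 0.0, None)


# ---------------------------------------------------------------------------
# 2D rasterization (oversampled coverage)

def _disc_coverage(
    shape: tuple[int, int], center: tuple[float, float], r_in: float, r_out: float,
    oversample: int = 2,
) -> np.ndarray:
    """Pixel coverage of the annulus r_in <= r <= r_out (r_in=0 gives a disc)."""
    cy, cx = center
    pad = int(np.ceil(r_out)) + 2
    y0, y1 = max(0, int(cy) - pad), min(shape[0], int(cy) + pad + 1)
    x0, x1 = max(0, int(cx) - pad), min(shape[1], int(cx) + pad + 1)
    out = np.zeros(shape)
    if y1 <= y0 or x1 <= x0:
        return out
    sub = (np.arange(oversample) + 0.5) / oversample - 0.5
    yy = (np.arange(y0, y1)[:, None] + sub[None, :]).ravel()
    xx = (np.arange(x0, x1)[:, None] + sub[None, :]).ravel()
    dy2 = (yy - cy)[:, None] ** 2
    dx2 = (xx - cx)[None, :] ** 2
    r2 = dy2 + dx2
    inside = (r2 >= r_in**2) & (r2 <= r_out**2)
    cov = inside.reshape(y1 - y0, oversample, x1 - x0, oversample).mean(axis=(1, 3))
    out[y0:y1, x0:x1] = cov
    return out


# ---------------------------------------------------------------------------
# Rosette fields

def gen_rosette_field(
    n_rosettes: int = 20,
    lumen_radius_range_um: tuple[float, float] = (6.0, 12.0),
    ring_thickness_um: float = 2.5,
    n_border: int = 3,
    n_subminimum: int = 3,
    subminimum_radius_um: float = 2.5,
    snr: float = 6.0,
    pixel_size_um: float = 1.0,
    field_size_px: int = 512,
    ring_amplitude: float = 150.0,
    bg_mean: float = 100.0,
    n_nuclei: int = 80,
    seed: int = 0,
    max_tries: int = 20000,
) -> tuple[ImageStack, GroundTruth]:
    """A 2D ZO-1/DAPI field of non-overlapping annular rosette rings.

    ``n_rosettes`` valid interior rings are planted together with
    ``n_border`` rings touching the field border and ``n_subminimum`` rings
    whose lumen is below typical minimum-size gates; the ground truth marks
    which objects should survive the standard border/size filters and
    records each lumen's analytic (πr²) and rasterized area.
    """
    if snr <= 0:
        raise InvalidParameterError("snr must be > 0")
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    shape = (field_size_px, field_size_px)
    thickness_px = ring_thickness_um / px

    objs: list[dict] = []  # center, r_in (px), kind
    def r_out_of(o): return o["r_in"] + thickness_px

    def try_place(r_in: float, kind: str) -> bool:
        r_out = r_in + thickness_px
        for _ in range(max_tries):
            if kind == "border":
                edge = rng.integers(4)
                off = rng.uniform(0, max(r_out - 2.0, 0.5))
                along = rng.uniform(r_out, field_size_px - r_out)
                cy, cx = {
                    0: (off, along), 1: (field_size_px - 1 - off, along),
                    2: (along, off), 3: (along, field_size_px - 1 - off),
                }[int(edge)]
            else:
                m = r_out + 3.0
                cy = rng.uniform(m, field_size_px - m)
                cx = rng.uniform(m, field_size_px - m)
            ok = all(
                np.hypot(cy - o["cy"], cx - o["cx"]) > r_out + r_out_of(o) + 4.0
                for o in objs
            )
            if ok:
                objs.append({"cy": cy, "cx": cx, "r_in": r_in, "kind": kind})
                return True
        return False

    for _ in range(n_rosettes):
        r_in = rng.uniform(*lumen_radius_range_um) / px
        if not try_place(r_in, "valid"):
            raise PackingError("could not pack valid rosettes; reduce count or radii")
    for _ in range(n_border):
        r_in = rng.uniform(*lumen_radius_range_um) / px
        if not try_place(r_in, "border"):
            raise PackingError("could not pack border decoys")
    for _ in range(n_subminimum):
        if not try_place(subminimum_radius_um / px, "subminimum"):
            raise PackingError("could not pack sub-minimum decoys")

    zo1 = np.zeros(shape)
    truth_objects = []
    for o in objs:
        ring = _disc_coverage(shape, (o["cy"], o["cx"]), o["r_in"], r_out_of(o))
        zo1 += ring
        interior = _disc_coverage(shape, (o["cy"], o["cx"]), 0.0, o["r_in"])
        r_in_um = o["r_in"] * px
        truth_objects.append(
            {
                "kind": o["kind"],
                "center_yx_um": (o["cy"] * px, o["cx"] * px),
                "lumen_radius_um": r_in_um,
                "lumen_area_um2": float(np.pi * r_in_um**2),
                "lumen_area_px": int(np.sum(interior >= 0.5)),
                "should_survive": o["kind"] == "valid",
            }
        )
    zo1_signal = ring_amplitude * np.clip(zo1, 0, 1)

    # decorative DAPI nuclei scattered between the rings
    dapi = np.zeros(shape)
    for _ in range(n_nuclei):
        cy, cx = rng.uniform(5, field_size_px - 5, size=2)
        r = rng.uniform(2.5, 4.5)
        dapi += _disc_coverage(shape, (cy, cx), 0.0, r)
    dapi_signal = ring_amplitude * np.clip(dapi, 0, 1)

    bg_sd = ring_amplitude / snr
    img = np.stack(
        [
            _apply_noise(zo1_signal, bg_mean, bg_sd, rng),
            _apply_noise(dapi_signal, bg_mean, bg_sd, rng),
        ],
        axis=-1,
    )[None]
    stack = ImageStack(img, (1.0, px, px), ["ZO1", "DAPI"], {"seed": seed})
    truth = GroundTruth(
        "rosette",
        truth_objects,
        seed,
        params={
            "n_rosettes": n_rosettes,
            "snr": snr,
            "pixel_size_um": px,
            "ring_amplitude": ring_amplitude,
            "bg_mean": bg_mean,
            "bg_sd": bg_sd,
            "ring_thickness_um": ring_thickness_um,
            "suggested_threshold": bg_mean + ring_amplitude / 2.0,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# 3D tube rasterization and mitochondrial volumes

def _segments_coverage(
    shape: tuple[int, int, int],
    segments: Sequence[tuple[np.ndarray, np.ndarray]],
    radius_um: float,
    voxel_size_um: tuple[float, float, float],
    oversample: int = 2,
) -> np.ndarray:
    """Voxel coverage of a union of capsules (tubes with spherical caps).

    Segment endpoints are physical µm coordinates in (z, y, x) order.
    """
    vs = np.asarray(voxel_size_um)
    cov = np.zeros(shape)
    sub = (np.arange(oversample) + 0.5) / oversample - 0.5
    for p0, p1 in segments:
        lo = np.minimum(p0, p1) - radius_um - vs
        hi = np.maximum(p0, p1) + radius_um + vs
        i0 = np.maximum(0, np.floor(lo / vs).astype(int))
        i1 = np.minimum(shape, np.ceil(hi / vs).astype(int) + 1)
        if np.any(i0 >= i1):
            continue
        axes = [
            ((np.arange(i0[d], i1[d])[:, None] + sub[None, :]).ravel() * vs[d])
            for d in range(3)
        ]
        zz, yy, xx = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([zz, yy, xx], axis=-1)
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0:
            dist = np.linalg.norm(pts - p0, axis=-1)
        else:
            t = np.clip(((pts - p0) @ d) / L2, 0.0, 1.0)
            proj = p0 + t[..., None] * d
            dist = np.linalg.norm(pts - proj, axis=-1)
        inside = dist <= radius_um
        ns = [i1[d_] - i0[d_] for d_ in range(3)]
        block = inside.reshape(ns[0], oversample, ns[1], oversample, ns[2], oversample)
        cov_crop = block.mean(axis=(1, 3, 5))
        region = cov[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        np.maximum(region, cov_crop, out=region)
    return cov


def digitize_ball(
    radius_um: float,
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1),
    oversample: int = 4,
) -> BinaryMask:
    """Rasterize a solid ball (coverage ≥ 0.5) for analytic-shape tests."""
    vs = np.asarray(voxel_size_um)
    n = (np.ceil(2 * radius_um / vs).astype(int)) + 5
    center = (n // 2).astype(float) * vs
    cov = _segments_coverage(tuple(n), [(center, center)], radius_um, tuple(vs), oversample)
    return BinaryMask(cov >= 0.5, tuple(voxel_size_um))


def digitize_cylinder(
    radius_um: float,
    length_um: float,
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1),
    oversample: int = 4,
) -> BinaryMask:
    """Rasterize a straight flat-ended cylinder along x, tip-to-tip length
    ``length_um`` (no spherical caps)."""
    vs = np.asarray(voxel_size_um)
    nz = int(np.ceil(2 * radius_um / vs[0])) + 5
    ny = int(np.ceil(2 * radius_um / vs[1])) + 5
    nx = int(np.ceil(length_um / vs[2])) + 5
    cz, cy = nz // 2 * vs[0], ny // 2 * vs[1]
    x0 = (nx * vs[2] - length_um) / 2
    sub = (np.arange(oversample) + 0.5) / oversample - 0.5
    axes = [
        ((np.arange(n)[:, None] + sub[None, :]).ravel() * v)
        for n, v in zip((nz, ny, nx), vs)
    ]
    zz = (axes[0] - cz)[:, None, None]
    yy = (axes[1] - cy)[None, :, None]
    xx = axes[2][None, None, :]
    inside = (zz**2 + yy**2 <= radius_um**2) & (xx >= x0) & (xx <= x0 + length_um)
    cov = inside.reshape(
        nz, oversample, ny, oversample, nx, oversample
    ).mean(axis=(1, 3, 5))
    return BinaryMask(cov >= 0.5, tuple(voxel_size_um))


def digitize_y_tube(
    arm_length_um: float = 2.0,
    radius_um: float = 0.25,
    voxel_size_um: tuple[float, float, float] = (0.1, 0.1, 0.1),
    oversample: int = 4,
) -> BinaryMask:
    """Rasterize a planar Y: three arms at 120° from a common junction."""
    vs = np.asarray(voxel_size_um)
    span = 2 * (arm_length_um + radius_um)
    nz = int(np.ceil(2 * radius_um / vs[0])) + 5
    ny = int(np.ceil(span / vs[1])) + 5
    nx = int(np.ceil(span / vs[2])) + 5
    c = np.array([nz // 2 * vs[0], ny // 2 * vs[1], nx // 2 * vs[2]])
    segs = []
    for ang in (90.0, 210.0, 330.0):
        d = np.array([0.0, np.sin(np.radians(ang)), np.cos(np.radians(ang))])
        segs.append((c, c + arm_length_um * d))
    cov = _segments_coverage((nz, ny, nx), segs, radius_um, tuple(vs), oversample)
    return BinaryMask(cov >= 0.5, tuple(voxel_size_um))


def gen_mito_volume(
    n_objects: int = 6,
    branch_counts: Sequence[int] = (1, 3),
    tube_radius_um: float = 0.4,
    segment_length_range_um: tuple[float, float] = (2.0, 3.0),
    shape_zyx: tuple[int, int, int] = (40, 288, 288),
    voxel_size_um: tuple[float, float, float] = (0.2, 0.1, 0.1),
    psf_sigma_um: float = 0.1,
    snr: float = 8.0,
    region_mask_fraction: float = 0.5,
    tube_amplitude: float = 150.0,
    bg_mean: float = 100.0,
    seed: int = 0,
    max_tries: int = 5000,
) -> tuple[ImageStack, BinaryMask, GroundTruth]:
    """A 3D TOM20/SOX2 stack of branched mitochondrial tubes.

    Each object is a straight tube (branch count 1) or a star of ``b`` arms
    radiating from one junction (branch count b ≥ 3), rendered as capsules,
    blurred by an anisotropic Gaussian PSF and noised. The SOX2 channel is
    a smooth blob mask covering ``region_mask_fraction`` of the volume.
    Returns ``(stack, sox2_mask, truth)``; the ground truth records each
    object's centerline length, branch and junction counts, analytic
    volume estimate, and whether it lies inside the SOX2 region.
    """
    vs = np.asarray(voxel_size_um)
    if tube_radius_um < min(vs):
        raise InvalidParameterError(
            f"tube radius {tube_radius_um} µm is below one voxel ({min(vs)} µm)"
        )
    rng = np.random.default_rng(seed)
    extent = np.array(shape_zyx) * vs
    max_len = segment_length_range_um[1]
    # farthest point of an object from its center: a star arm reaches max_len,
    # a straight tube only half of it
    clearance = 2 * (tube_radius_um + psf_sigma_um + 2 * max(vs))
    margin = max_len + tube_radius_um + psf_sigma_um + 2 * max(vs)
    if np.any(extent <= 2 * margin):
        raise PackingError("volume too small for the requested tube lengths")

    placed: list[dict] = []
    for _ in range(n_objects):
        b = int(rng.choice(list(branch_counts)))
        if b != 1 and b < 3:
            raise InvalidParameterError("branch counts must be 1 or >= 3")
        reach = max_len if b >= 3 else max_len / 2
        for _ in range(max_tries):
            center = np.array([rng.uniform(m, e - m) for m, e in zip([margin] * 3, extent)])
            if all(
                np.linalg.norm(center - p["center"]) > reach + p["reach"] + clearance
                for p in placed
            ):
                break
        else:
            raise PackingError("could not place mitochondrial objects without overlap")
        if b == 1:
            length = rng.uniform(*segment_length_range_um)
            theta = rng.uniform(0, np.pi)
            phi = rng.uniform(0, 2 * np.pi)
            d = np.array(
                [np.cos(theta) * 0.3, np.sin(theta) * np.sin(phi), np.sin(theta) * np.cos(phi)]
            )
            d /= np.linalg.norm(d)
            segs = [(center - d * length / 2, center + d * length / 2)]
            total_len = length
        else:
            # star: b arms at equal in-plane angles, each tilted modestly out
            # of plane — a perfectly planar fat star thins to a plate-like
            # medial surface and real networks are not planar either
            base = rng.uniform(0, 2 * np.pi)
            segs = []
            total_len = 0.0
            for i in range(b):
                ang = base + 2 * np.pi * i / b
                # alternating out-of-plane tilts bounded away from zero keep
                # the arms non-coplanar for any rotation draw
                tilt = (-1) ** i * rng.uniform(0.15, 0.35)
                d = np.array([tilt, np.sin(ang), np.cos(ang)])
                d /= np.linalg.norm(d)
                length = rng.uniform(*segment_length_range_um)
                segs.append((center.copy(), center + d * length))
                total_len += length
        placed.append(
            {"center": center, "branches": b, "segments": segs, "length": total_len, "reach": reach}
        )

    signal = np.zeros(shape_zyx)
    for p in placed:
        cov = _segments_coverage(shape_zyx, p["segments"], tube_radius_um, tuple(vs))
        np.maximum(signal, cov, out=signal)
    signal *= tube_amplitude
    if psf_sigma_um > 0:
        signal = ndimage.gaussian_filter(signal, sigma=psf_sigma_um / vs)

    # smooth SOX2 blob mask covering the requested volume fraction
    if not (0 <= region_mask_fraction <= 1):
        raise InvalidParameterError("region_mask_fraction must lie in [0, 1]")
    blob = ndimage.gaussian_filter(rng.standard_normal(shape_zyx), sigma=8.0 / vs * vs.min())
    if region_mask_fraction in (0.0, 1.0):
        mask = np.full(shape_zyx, bool(region_mask_fraction))
    else:
        thr = np.quantile(blob, 1 - region_mask_fraction)
        mask = blob >= thr
    sox2_mask = BinaryMask(mask, tuple(voxel_size_um))

    bg_sd = tube_amplitude / snr
    tom20 = _apply_noise(signal, bg_mean, bg_sd, rng)
    sox2 = _apply_noise(mask * tube_amplitude, bg_mean, bg_sd, rng)
    stack = ImageStack(
        np.stack([tom20, sox2], axis=-1), tuple(voxel_size_um), ["TOM20", "SOX2"], {"seed": seed}
    )

    truth_objects = []
    for p in placed:
        vox_center = np.round(p["center"] / vs).astype(int)
        inside = bool(mask[tuple(np.clip(vox_center, 0, np.array(shape_zyx) - 1))])
        b = p["branches"]
        truth_objects.append(
            {
                "center_um": tuple(float(v) for v in p["center"]),
                "n_branches": b,
                "n_junctions": 0 if b == 1 else 1,
                "centerline_length_um": float(p["length"]),
                "analytic_volume_um3": float(
                    np.pi * tube_radius_um**2 * p["length"] + 4 / 3 * np.pi * tube_radius_um**3
                ),
                "in_region": inside,
            }
        )
    truth = GroundTruth(
        "mito",
        truth_objects,
        seed,
        params={
            "tube_radius_um": tube_radius_um,
            "snr": snr,
            "psf_sigma_um": psf_sigma_um,
            "voxel_size_um": tuple(voxel_size_um),
            "tube_amplitude": tube_amplitude,
            "bg_mean": bg_mean,
            "bg_sd": bg_sd,
            "suggested_threshold": bg_mean + tube_amplitude / 2.0,
            "region_mask_fraction": region_mask_fraction,
        },
    )
    return stack, sox2_mask, truth


# ---------------------------------------------------------------------------
# Marker / DAPI fields

def gen_marker_field(
    n_nuclei: int = 30,
    positive_fraction: float = 0.4,
    n_background_spots: int = 5,
    snr: float = 8.0,
    nucleus_radius_um: float = 4.0,
    spot_radius_um: float = 1.5,
    pixel_size_um: float = 1.0,
    field_size_px: int = 512,
    amplitude: float = 150.0,
    bg_mean: float = 100.0,
    seed: int = 0,
    max_tries: int = 20000,
) -> tuple[ImageStack, GroundTruth]:
    """A 2D MARKER/DAPI field with a known marker-positive nucleus fraction.

    DAPI nuclei are non-overlapping discs; a planted fraction carries a
    coincident bright marker spot, and ``n_background_spots`` marker spots
    fall on background away from any nucleus (false-positive bait for the
    DAPI-overlap gate).
    """
    if not (0 <= positive_fraction <= 1):
        raise InvalidParameterError("positive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    px = pixel_size_um
    shape = (field_size_px, field_size_px)
    nuc_r = nucleus_radius_um / px
    spot_r = spot_radius_um / px

    centers: list[tuple[float, float]] = []
    for _ in range(n_nuclei):
        for _ in range(max_tries):
            cy, cx = rng.uniform(nuc_r + 3, field_size_px - nuc_r - 3, size=2)
            if all(np.hypot(cy - y, cx - x) > 2 * nuc_r + 3 for y, x in centers):
                centers.append((float(cy), float(cx)))
                break
        else:
            raise PackingError("could not pack nuclei; reduce n_nuclei or radius")

    n_pos = int(round(positive_fraction * n_nuclei))
    pos_idx = rng.choice(n_nuclei, size=n_pos, replace=False) if n_pos else np.array([], int)

    dapi = np.zeros(shape)
    for cy, cx in centers:
        dapi += _disc_coverage(shape, (cy, cx), 0.0, nuc_r)
    marker = np.zeros(shape)
    for i in pos_idx:
        marker += _disc_coverage(shape, centers[i], 0.0, spot_r)
    bg_spots = []
    for _ in range(n_background_spots):
        for _ in range(max_tries):
            cy, cx = rng.uniform(spot_r + 3, field_size_px - spot_r - 3, size=2)
            if all(np.hypot(cy - y, cx - x) > nuc_r + spot_r + 3 for y, x in centers):
                marker += _disc_coverage(shape, (cy, cx), 0.0, spot_r)
                bg_spots.append((float(cy), float(cx)))
                break
        else:
            raise PackingError("could not place background spots")

    bg_sd = amplitude / snr
    img = np.stack(
        [
            _apply_noise(amplitude * np.clip(marker, 0, 1), bg_mean, bg_sd, rng),
            _apply_noise(amplitude * np.clip(dapi, 0, 1), bg_mean, bg_sd, rng),
        ],
        axis=-1,
    )[None]
    stack = ImageStack(img, (1.0, px, px), ["MARKER", "DAPI"], {"seed": seed})
    truth = GroundTruth(
        "marker",
        [
            {
                "center_yx_px": c,
                "is_positive": bool(i in set(int(j) for j in pos_idx)),
            }
            for i, c in enumerate(centers)
        ],
        seed,
        params={
            "n_nuclei": n_nuclei,
            "n_positive": n_pos,
            "positive_fraction": positive_fraction,
            "n_background_spots": n_background_spots,
            "background_spot_centers": bg_spots,
            "snr": snr,
            "amplitude": amplitude,
            "bg_mean": bg_mean,
            "suggested_threshold": bg_mean + amplitude / 2.0,
            "nucleus_radius_um": nucleus_radius_um,
            "spot_radius_um": spot_radius_um,
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Grouped measurements and metabolite tables

def gen_group_measurements(
    group_means: Mapping[str, float] | None = None,
    group_sds: Mapping[str, float] | None = None,
    n_per_group: int = 50,
    outlier_magnitude_sigma: float = 8.0,
    n_outliers: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Grouped Gaussian measurements with optionally planted gross outliers.

    Outliers are planted by displacing randomly chosen rows by
    ``±outlier_magnitude_sigma`` group SDs. Returns a long-format frame
    with columns ``group, value, is_planted_outlier``.
    """
    if group_means is None:
        group_means = {"Control": 100.0, "Mutant": 120.0}
    if group_sds is None:
        group_sds = {g: 10.0 for g in group_means}
    if set(group_sds) != set(group_means):
        raise ConfigurationError("group_sds keys must match group_means keys")
    rng = np.random.default_rng(seed)
    rows = []
    for g in group_means:
        vals = rng.normal(group_means[g], group_sds[g], size=n_per_group)
        for v in vals:
            rows.append({"group": g, "value": float(v), "is_planted_outlier": False})
    df = pd.DataFrame(rows)
    outlier_idx: list[int] = []
    if n_outliers:
        outlier_idx = sorted(rng.choice(len(df), size=n_outliers, replace=False).tolist())
        for i in outlier_idx:
            g = df.at[i, "group"]
            sign = 1 if rng.random() < 0.5 else -1
            df.at[i, "value"] += sign * outlier_magnitude_sigma * group_sds[g]
            df.at[i, "is_planted_outlier"] = True
    truth = GroundTruth(
        "grouped",
        [{"outlier_indices": outlier_idx}],
        seed,
        params={
            "group_means": dict(group_means),
            "group_sds": dict(group_sds),
            "n_per_group": n_per_group,
            "outlier_magnitude_sigma": outlier_magnitude_sigma,
            "n_outliers": n_outliers,
        },
    )
    return df, truth


def default_dysregulated_spec(
    n_metabolites: int = 100,
    mutant_groups: Sequence[str] = ("PDH", "DLD", "MT-ATP6/PDH"),
    counts: Sequence[int] = (8, 16, 32),
    fold: float = 3.0,
) -> dict[str, list[tuple[str, float]]]:
    """Nested per-genotype effect plan: 8, 16 and 32 affected metabolites.

    The first ``max(counts)`` metabolites are affected in the most-affected
    line; nested prefixes of 16 and 8 are additionally affected in the
    other two, mirroring a per-genotype segregation structure. Directions
    alternate (even-index metabolites up by ``fold``, odd down by
    ``1/fold``), as dysregulation in real profiles runs both ways. Counts
    are capped at the table size for small fixtures.
    """
    counts = [min(c, n_metabolites) for c in counts]
    spec: dict[str, list[tuple[str, float]]] = {}
    ordered = sorted(zip(counts, mutant_groups))
    for j in range(max(counts)):
        name = f"M{j:03d}"
        f = fold if j % 2 == 0 else 1.0 / fold
        for count, grp in ordered:
            if j < count:
                spec.setdefault(name, []).append((grp, f))
    return spec


def gen_metabolite_table(
    n_samples_per_group: int = 4,
    n_metabolites: int = 100,
    groups: Sequence[str] = ("Control", "PDH", "DLD", "MT-ATP6/PDH"),
    dysregulated_spec: Mapping[str, Sequence[tuple[str, float]]] | None = None,
    cv: float = 0.10,
    tic_scale_range: tuple[float, float] = (0.5, 2.0),
    base_log_sigma: float = 1.0,
    planted_abundance_factor: float = 0.1,
    seed: int = 0,
) -> tuple[MetaboliteTable, GroundTruth]:
    """A log-normal peak-area table with planted per-genotype fold changes.

    Metabolite baselines are log-normal; each sample value is the baseline
    times the planted fold (when its group is affected), a log-normal
    biological noise term with coefficient of variation ``cv``, and a
    per-sample total-ion-current scale drawn log-uniformly from
    ``tic_scale_range``. Passing ``dysregulated_spec={}`` generates a null
    table; ``None`` selects the default 8/16/32 per-genotype plan at 3-fold.

    Peak tables are compositional: TIC normalization transfers any change
    in total signal onto every other metabolite. As in real profiles, the
    TIC here is dominated by abundant core metabolites while dysregulated
    species are minor peaks — planted metabolites' baselines are scaled by
    ``planted_abundance_factor`` — so planted folds survive normalization
    without inducing spurious table-wide shifts.
    """
    if cv <= 0:
        raise InvalidParameterError("cv must be > 0")
    if dysregulated_spec is None:
        dysregulated_spec = default_dysregulated_spec(n_metabolites, tuple(groups[1:]))
    rng = np.random.default_rng(seed)
    metabolites = [f"M{j:03d}" for j in range(n_metabolites)]
    unknown = set(dysregulated_spec) - set(metabolites)
    if unknown:
        raise ConfigurationError(f"dysregulated_spec names unknown metabolites: {sorted(unknown)}")
    for m, effects in dysregulated_spec.items():
        for grp, fold in effects:
            if grp not in groups:
                raise ConfigurationError(f"dysregulated_spec references unknown group {grp!r}")
            if fold <= 0:
                raise InvalidParameterError("fold changes must be > 0")

    base = np.exp(rng.normal(np.log(100.0), base_log_sigma, size=n_metabolites))
    for j, m in enumerate(metabolites):
        if m in dysregulated_spec:
            base[j] *= planted_abundance_factor
    sigma_cv = np.sqrt(np.log(1 + cv**2))
    sample_ids, group_labels = [], []
    rows = []
    lo, hi = tic_scale_range
    for g in groups:
        for i in range(n_samples_per_group):
            sid = f"{g}_{i + 1}"
            sample_ids.append(sid)
            group_labels.append(g)
            scale = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            folds = np.ones(n_metabolites)
            for j, m in enumerate(metabolites):
                for grp, fold in dysregulated_spec.get(m, ()):
                    if grp == g:
                        folds[j] *= fold
            noise = np.exp(rng.normal(0.0, sigma_cv, size=n_metabolites))
            rows.append(base * folds * noise * scale)
    values = pd.DataFrame(rows, index=sample_ids, columns=metabolites)
    table = MetaboliteTable(values, pd.Series(group_labels, index=sample_ids), "raw")
    truth = GroundTruth(
        "metabolite",
        [
            {
                "metabolite": m,
                "effects": [{"group": grp, "fold": fold} for grp, fold in effects],
            }
            for m, effects in dysregulated_spec.items()
        ],
        seed,
        params={
            "n_samples_per_group": n_samples_per_group,
            "n_metabolites": n_metabolites,
            "groups": list(groups),
            "cv": cv,
            "tic_scale_range": tuple(tic_scale_range),
        },
    )
    return table, truth
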
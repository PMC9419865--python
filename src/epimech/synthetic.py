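"""Synthetic-data generators with exact ground truth.

Every generator emulates one input modality of the analysis pipeline —
AFM force curves, SEM-like fiber mats, two-channel monolayer images,
AFM height maps and scratch-wound time series — and returns the artifact
together with a :class:`~epimech.datatypes.GroundTruth` sidecar holding
the generating parameters and per-object truths.  All randomness flows
from the explicit ``seed`` argument of each call (no global RNG state),
so identical (parameters, seed) reproduce an artifact bit-for-bit.

Design notes
------------
* Fibers are rendered as full-length straight ribbons with analytic
  anti-aliased coverage, so each fiber's true width and angle are exact.
* Cells are ellipses placed by minimum-distance rejection sampling,
  giving closed-form area/eccentricity truths.
* Wound frames use variance-coded texture: cell lawn = high-variance
  Gaussian grain, wound = near-flat band, matching the variance-based
  segmentation downstream.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .contact import composite_forward, jkr_min_depth
from .datatypes import (
    ContactModelParams,
    ForceCurve,
    GroundTruth,
    HeightMap,
    LabelImage,
    WoundSeries,
)
from .exceptions import CapacityError, InvalidParameterError, ResolutionError

__all__ = [
    "gen_force_curve",
    "gen_fiber_image",
    "gen_monolayer_image",
    "gen_height_map",
    "gen_wound_series",
]


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------

def gen_force_curve(
    model_params: ContactModelParams,
    z_range: float = 1.4,
    n_points: int = 500,
    noise_sd: float = 0.0,
    drift_slope: float = 0.0,
    contact_offset: float = 0.0,
    seed: int = 0,
    region: str = "cytoplasm",
    substrate_label: str = "NCCI",
    sample_id: str = "",
):
    """Simulate one AFM nanoindentation record (approach + retract).

    Parameters
    ----------
    model_params : ContactModelParams
        True mechanical parameters; ``model_params.z0`` plus
        ``contact_offset`` is the true contact point on the piezo axis.
    z_range : float
        Piezo span (um); the grid runs 0 -> ``z_range`` on approach and
        back on retract, and must bracket the contact point.
    n_points : int
        Samples per segment (>= 50).
    noise_sd : float
        Additive Gaussian force noise (nN).
    drift_slope : float
        Extra linear baseline drift (nN/um) on top of the params baseline.
    contact_offset : float
        Shift (um) added to the params contact point.
    seed : int
        RNG seed; identical (parameters, seed) give identical arrays.

    Returns
    -------
    (ForceCurve, GroundTruth)
    """
    if n_points < 50:
        raise InvalidParameterError(f"n_points must be >= 50, got {n_points}")
    z0_true = model_params.z0 + contact_offset
    if not (0.0 < z0_true < z_range):
        raise InvalidParameterError(
            f"z_range {z_range} um must bracket the contact point {z0_true} um"
        )
    true = ContactModelParams(
        E=model_params.E,
        R=model_params.R,
        nu=model_params.nu,
        w=model_params.w,
        K_m=model_params.K_m,
        z0=z0_true,
        baseline_offset=model_params.baseline_offset,
        baseline_slope=model_params.baseline_slope + drift_slope,
    )
    z_app = np.linspace(0.0, z_range, n_points)
    f_app = composite_forward(z_app, true)
    z_ret = z_app[::-1].copy()
    f_ret = composite_forward(z_ret, true, include_adhesive_sag=True)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        f_app = f_app + rng.normal(0.0, noise_sd, n_points)
        f_ret = f_ret + rng.normal(0.0, noise_sd, n_points)

    curve = ForceCurve(
        z=np.concatenate([z_app, z_ret]),
        force=np.concatenate([f_app, f_ret]),
        segment=np.array(["approach"] * n_points + ["retract"] * n_points),
        probe_radius=true.R * 1e6,
        region=region,
        substrate_label=substrate_label,
        sample_id=sample_id or f"sim-{seed}",
    )
    truth = GroundTruth(
        kind="force_curve",
        parameters={
            "E_Pa": true.E,
            "nu": true.nu,
            "w_J_per_m2": true.w,
            "K_m_N_per_m": true.K_m,
            "R_m": true.R,
            "z0_um": true.z0,
            "baseline_offset_nN": true.baseline_offset,
            "baseline_slope_nN_per_um": true.baseline_slope,
            "noise_sd_nN": noise_sd,
            "delta_min_um": jkr_min_depth(true) * 1e6,
            "beta": true.beta,
        },
        seed=seed,
    )
    return curve, truth


# ---------------------------------------------------------------------------
# fiber mats
# ---------------------------------------------------------------------------

def _sample_orientations(rng, n: int, kappa: float, mu: float = 0.0):
    """Axial orientations in [0, pi): von Mises on the doubled angle.

    ``kappa = 0`` gives uniformly random orientations (isotropic mat);
    large ``kappa`` concentrates fibers around ``mu``.
    """
    if kappa < 0:
        raise InvalidParameterError("orientation_kappa must be >= 0")
    if kappa == 0:
        return rng.uniform(0.0, np.pi, n)
    theta2 = rng.vonmises(2.0 * mu, kappa, n)
    return np.mod(theta2 / 2.0, np.pi)


def gen_fiber_image(
    n_fibers: int,
    diameter_mean: float = 622.0,
    diameter_sd: float = 31.0,
    orientation_kappa: float = 0.0,
    pixel_size: float = 50.0,
    image_size: int = 1024,
    noise_sd: float = 0.0,
    seed: int = 0,
    orientation_mu: float = 0.0,
):
    """Render an SEM-like mat of straight nanofibers.

    Parameters
    ----------
    n_fibers : int
        Number of fibers; each spans the full image.
    diameter_mean, diameter_sd : float
        Normal distribution of true fiber diameters (nm).  Defaults are
        the electrospun PCL/gelatin mat values (622 +/- 31 nm).
    orientation_kappa : float
        Axial von Mises concentration; 0 = isotropic.
    pixel_size : float
        nm per pixel.
    image_size : int
        Square image side (px).
    noise_sd : float
        Additive Gaussian grey noise on the [0, 1] intensity scale.

    Returns
    -------
    (image, GroundTruth)
        Float image in [0, 1+noise]; truth table has one row per fiber
        with its diameter (nm) and orientation (rad, from the x axis).
    """
    if diameter_mean <= 2.0 * pixel_size:
        raise ResolutionError(
            f"diameter_mean {diameter_mean} nm is not resolvable at "
            f"{pixel_size} nm/px (needs > 2 px)"
        )
    if n_fibers < 1:
        raise InvalidParameterError("n_fibers must be >= 1")
    rng = np.random.default_rng(seed)
    angles = _sample_orientations(rng, n_fibers, orientation_kappa, orientation_mu)
    diam_nm = rng.normal(diameter_mean, diameter_sd, n_fibers)
    diam_nm = np.clip(diam_nm, 2.5 * pixel_size, None)  # physical: no sub-resolution fibers
    cx = rng.uniform(0, image_size, n_fibers)
    cy = rng.uniform(0, image_size, n_fibers)

    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    img = np.zeros((image_size, image_size), dtype=float)
    for i in range(n_fibers):
        # signed distance from pixel center to the fiber axis
        nx, ny = -np.sin(angles[i]), np.cos(angles[i])
        dist = np.abs(nx * (xx - cx[i]) + ny * (yy - cy[i]))
        half_w = 0.5 * diam_nm[i] / pixel_size
        cover = np.clip(half_w + 0.5 - dist, 0.0, 1.0)
        np.maximum(img, cover, out=img)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)

    truth_tab = pd.DataFrame(
        {
            "fiber_id": np.arange(n_fibers),
            "diameter_nm": diam_nm,
            "angle_rad": angles,
            "center_x_px": cx,
            "center_y_px": cy,
        }
    )
    truth = GroundTruth(
        kind="fiber_image",
        parameters={
            "n_fibers": n_fibers,
            "diameter_mean_nm": diameter_mean,
            "diameter_sd_nm": diameter_sd,
            "orientation_kappa": orientation_kappa,
            "orientation_mu_rad": orientation_mu,
            "pixel_size_nm": pixel_size,
            "image_size_px": image_size,
            "noise_sd": noise_sd,
        },
        seed=seed,
        per_object_truth=truth_tab,
    )
    return img, truth


# ---------------------------------------------------------------------------
# monolayer images
# ---------------------------------------------------------------------------

def gen_monolayer_image(
    n_cells: int,
    mean_area: float = 400.0,
    eccentricity_target: float = 0.0,
    intensity_mean_per_group: Union[float, dict] = 100.0,
    pixel_size: float = 0.5,
    seed: int = 0,
    image_size: Optional[int] = None,
    area_cv: float = 0.1,
    intensity_cv: float = 0.1,
    nucleus_area_frac: float = 0.25,
    nucleus_intensity: float = 200.0,
    noise_sd: float = 0.0,
    max_tries: int = 400,
):
    """Render a two-channel (nucleus / cell body) monolayer image.

    Cells are ellipses of prescribed mean area (um^2) and eccentricity,
    placed without overlap by minimum-distance rejection sampling; each
    cell carries a concentric elliptical nucleus and a per-cell body
    intensity drawn lognormally around its group mean.

    ``intensity_mean_per_group`` may be a scalar (single group) or a
    ``{group_name: mean}`` mapping; cells are then assigned to groups
    round-robin and the truth table records the group of each cell.

    Returns
    -------
    (image, LabelImage, GroundTruth)
        ``image`` has shape (2, H, W): channel 0 = nuclei, channel 1 =
        cell bodies.  The LabelImage is the true per-cell mask.
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    if not (0.0 <= eccentricity_target < 1.0):
        raise InvalidParameterError("eccentricity_target must be in [0, 1)")
    rng = np.random.default_rng(seed)
    groups = (
        {"group": float(intensity_mean_per_group)}
        if np.isscalar(intensity_mean_per_group)
        else dict(intensity_mean_per_group)
    )
    group_names = list(groups)

    axis_ratio = np.sqrt(1.0 - eccentricity_target**2)  # b / a
    areas = mean_area * np.exp(rng.normal(0.0, area_cv, n_cells) - 0.5 * area_cv**2) \
        if area_cv > 0 else np.full(n_cells, mean_area)
    a_um = np.sqrt(areas / (np.pi * axis_ratio))
    b_um = a_um * axis_ratio
    a_max = float(np.max(a_um))

    if image_size is None:
        side_um = np.sqrt(n_cells * mean_area / 0.15) + 4 * a_max
        image_size = int(np.ceil(side_um / pixel_size))
    min_dist = 2.0 * a_max * 1.02 / pixel_size  # centers this far apart cannot overlap
    margin = a_max * 1.1 / pixel_size

    centers = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > max_tries * n_cells:
            raise CapacityError(
                f"could not place {n_cells} non-overlapping cells of mean area "
                f"{mean_area} um^2 in a {image_size} px image",
                limiting_parameter="n_cells * mean_area vs image_size",
            )
        cand = rng.uniform(margin, image_size - margin, 2)
        if all((cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= min_dist**2 for c in centers):
            centers.append(cand)
    centers = np.array(centers)  # (row, col) px

    orientations = rng.uniform(0.0, np.pi, n_cells)
    rows = []
    labels = np.zeros((image_size, image_size), dtype=np.int32)
    chan_nuc = np.zeros((image_size, image_size), dtype=float)
    chan_cell = np.zeros((image_size, image_size), dtype=float)
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)

    for i in range(n_cells):
        group = group_names[i % len(group_names)]
        mean_int = groups[group]
        cell_int = mean_int * np.exp(rng.normal(0.0, intensity_cv) - 0.5 * intensity_cv**2) \
            if intensity_cv > 0 else mean_int
        a_px, b_px = a_um[i] / pixel_size, b_um[i] / pixel_size
        r0, c0 = centers[i]
        ct, st = np.cos(orientations[i]), np.sin(orientations[i])
        xr = (xx - c0) * ct + (yy - r0) * st
        yr = -(xx - c0) * st + (yy - r0) * ct
        inside = (xr / a_px) ** 2 + (yr / b_px) ** 2 <= 1.0
        labels[inside] = i + 1
        chan_cell[inside] = cell_int
        # concentric nucleus, same orientation and axis ratio
        scale = np.sqrt(nucleus_area_frac)
        inside_n = (xr / (a_px * scale)) ** 2 + (yr / (b_px * scale)) ** 2 <= 1.0
        chan_nuc[inside_n] = nucleus_intensity
        rows.append(
            {
                "object_id": i + 1,
                "group": group,
                "area_um2": float(np.pi * a_um[i] * b_um[i]),
                "eccentricity": eccentricity_target,
                "orientation_rad": orientations[i],
                "centroid_row_px": r0,
                "centroid_col_px": c0,
                "nucleus_area_um2": float(np.pi * a_um[i] * b_um[i] * nucleus_area_frac),
                "mean_intensity": cell_int,
                "semi_major_um": a_um[i],
                "semi_minor_um": b_um[i],
            }
        )
    if noise_sd > 0:
        chan_nuc = chan_nuc + rng.normal(0.0, noise_sd, chan_nuc.shape)
        chan_cell = chan_cell + rng.normal(0.0, noise_sd, chan_cell.shape)

    image = np.stack([chan_nuc, chan_cell])
    truth = GroundTruth(
        kind="monolayer_image",
        parameters={
            "n_cells": n_cells,
            "mean_area_um2": mean_area,
            "eccentricity_target": eccentricity_target,
            "intensity_mean_per_group": groups,
            "pixel_size_um": pixel_size,
            "image_size_px": image_size,
            "area_cv": area_cv,
            "intensity_cv": intensity_cv,
            "nucleus_area_frac": nucleus_area_frac,
            "noise_sd": noise_sd,
        },
        seed=seed,
        per_object_truth=pd.DataFrame(rows),
    )
    return image, LabelImage(labels, pixel_size, "cell"), truth


# ---------------------------------------------------------------------------
# height maps
# ---------------------------------------------------------------------------

def gen_height_map(
    kind: str,
    amplitude: float = 0.5,
    correlation_length: float = 2.0,
    pixel_size: float = 0.1,
    seed: int = 0,
    shape: tuple = (256, 256),
    tilt: tuple = (0.05, -0.02),
):
    """Generate a synthetic topography map (um).

    kind = ``plane``: tilted plane of zero intrinsic roughness;
    ``sinusoid``: ``A sin(2 pi x / correlation_length)`` along one axis;
    ``gaussian_field``: Gaussian-filtered white noise rescaled so its
    sample SD equals ``amplitude`` exactly.
    """
    if amplitude < 0:
        raise InvalidParameterError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    x_um, y_um = xx * pixel_size, yy * pixel_size
    if kind == "plane":
        h = tilt[0] * x_um + tilt[1] * y_um
        rq_true = 0.0
    elif kind == "sinusoid":
        h = amplitude * np.sin(2.0 * np.pi * x_um / correlation_length)
        rq_true = amplitude / np.sqrt(2.0)
    elif kind == "gaussian_field":
        white = rng.normal(0.0, 1.0, shape)
        sigma_px = max(correlation_length / pixel_size, 1e-9)
        h = gaussian_filter(white, sigma_px, mode="wrap")
        sd = h.std()
        h = h * (amplitude / sd) if sd > 0 else h
        rq_true = amplitude
    else:
        raise InvalidParameterError(f"unknown height-map kind {kind!r}")
    truth = GroundTruth(
        kind="height_map",
        parameters={
            "kind": kind,
            "amplitude_um": amplitude,
            "correlation_length_um": correlation_length,
            "pixel_size_um": pixel_size,
            "shape": tuple(shape),
            "rq_true_um": rq_true,
        },
        seed=seed,
    )
    return HeightMap(h, pixel_size), truth


# ---------------------------------------------------------------------------
# wound series
# ---------------------------------------------------------------------------

def gen_wound_series(
    initial_width: float = 400.0,
    front_velocity: float = 10.0,
    timepoints: Sequence[float] = (0.0, 6.0, 12.0, 18.0, 24.0),
    pixel_size: float = 2.0,
    shape: tuple = (256, 384),
    cell_texture_sd: float = 0.15,
    wound_texture_sd: float = 0.01,
    base_grey: float = 0.5,
    seed: int = 0,
):
    """Simulate a closing rectangular scratch wound.

    The wound is a vertical low-variance band whose width shrinks as
    ``initial_width - 2 * front_velocity * t`` (two fronts advancing at
    ``front_velocity`` um/h each); the cell lawn is high-variance grain.

    Returns
    -------
    (WoundSeries, GroundTruth)
        Truth table: per timepoint the true wound width (um), area (um^2)
        and area fraction.
    """
    if front_velocity < 0:
        raise InvalidParameterError("front_velocity must be >= 0")
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints[0] != 0 or np.any(np.diff(timepoints) <= 0):
        raise InvalidParameterError("timepoints must ascend from 0")
    if initial_width <= 0:
        raise InvalidParameterError("initial_width must be positive")
    rng = np.random.default_rng(seed)
    n_rows, n_cols = shape
    center_col = n_cols / 2.0
    cols = np.arange(n_cols) + 0.5

    frames, rows = [], []
    for t in timepoints:
        width_um = max(initial_width - 2.0 * front_velocity * t, 0.0)
        half_px = 0.5 * width_um / pixel_size
        wound_cols = np.abs(cols - center_col) <= half_px
        frame = base_grey + rng.normal(0.0, cell_texture_sd, shape)
        if wound_cols.any():
            wound_block = base_grey + rng.normal(
                0.0, wound_texture_sd, (n_rows, int(wound_cols.sum()))
            )
            frame[:, wound_cols] = wound_block
        frames.append(frame)
        area_um2 = width_um * n_rows * pixel_size
        rows.append({"time_h": t, "width_um": width_um, "area_um2": area_um2})
    truth_tab = pd.DataFrame(rows)
    truth_tab["fraction"] = truth_tab["area_um2"] / truth_tab["area_um2"].iloc[0]

    series = WoundSeries(timepoints, frames, pixel_size, scratch_axis=0)
    truth = GroundTruth(
        kind="wound_series",
        parameters={
            "initial_width_um": initial_width,
            "front_velocity_um_per_h": front_velocity,
            "pixel_size_um": pixel_size,
            "shape": tuple(shape),
            "cell_texture_sd": cell_texture_sd,
            "wound_texture_sd": wound_texture_sd,
        },
        seed=seed,
        per_object_truth=truth_tab,
    )
    return series, truth
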
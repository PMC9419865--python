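"""Adhesive contact mechanics for AFM nanoindentation of soft matter.

Implements the classical JKR (Johnson-Kendall-Roberts) model of a rigid
sphere indenting an adhesive elastic half-space, extended with a linear
membrane-spring term that captures the resistance of a stretched cell
membrane, and the machinery to fit it to measured force curves:

* forward models (:func:`hertz_force`, :func:`jkr_forward`,
  :func:`composite_forward`),
* contact-point estimation (:func:`estimate_contact_point`),
* bounded nonlinear least-squares fitting with deterministic multi-start
  (:class:`ContactModel` / :class:`ContactResults`),
* adhesion energetics from the retract segment
  (:func:`adhesion_energetics`),
* per-region cohort aggregation (:func:`aggregate_by_region`).

Model
-----
With reduced modulus ``E* = E / (1 - nu^2)``, contact radius ``a`` and
probe radius ``R``, the JKR loading branch is parametrised by ``a``::

    F(a)     = 4 E* a^3 / (3 R) - sqrt(8 pi w E* a^3)
    delta(a) = a^2 / R - sqrt(2 pi w a / E*)

``w`` is the work of adhesion; ``w = 0`` recovers Hertz contact
``F = (4/3) E* sqrt(R) delta^(3/2)``.  The minimum of ``F`` on the branch
is the pull-off force ``-(3/2) pi w R``.  The measured force additionally
contains a membrane term ``K_m * delta`` and a linear instrumental
baseline.  All model arithmetic is SI; curve data live on the (um, nN)
scale and are converted at the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, brentq

from .datatypes import ContactModelParams, ForceCurve
from .exceptions import (
    DomainError,
    EmptyTableError,
    InvalidParameterError,
    NoContactError,
)

__all__ = [
    "hertz_force",
    "jkr_forward",
    "jkr_force_at_depth",
    "jkr_pulloff_force",
    "jkr_min_depth",
    "composite_forward",
    "estimate_contact_point",
    "ContactFitConfig",
    "ContactModel",
    "ContactResults",
    "adhesion_energetics",
    "aggregate_by_region",
    "fit_contact_model",
]

_NM = 1e-9
_UM = 1e-6
_NN = 1e-9


# ---------------------------------------------------------------------------
# forward models (SI units)
# ---------------------------------------------------------------------------

def hertz_force(delta, E: float, nu: float = 0.5, R: float = 2.6e-6):
    """Adhesionless Hertz force for a sphere on an elastic half-space.

    Parameters
    ----------
    delta : array-like
        Indentation depth (m). Non-positive depths give zero force.
    E : float
        Young's modulus (Pa).
    nu : float
        Poisson ratio.
    R : float
        Sphere radius (m).

    Returns
    -------
    ndarray or float
        Force (N): ``F = (4/3) [E/(1-nu^2)] sqrt(R) delta^(3/2)``.
    """
    if E <= 0:
        raise InvalidParameterError(f"E must be positive, got {E}")
    if R <= 0:
        raise InvalidParameterError(f"R must be positive, got {R}")
    delta = np.asarray(delta, dtype=float)
    e_star = E / (1.0 - nu**2)
    out = np.where(delta > 0, (4.0 / 3.0) * e_star * np.sqrt(R) * np.clip(delta, 0, None) ** 1.5, 0.0)
    return out if out.ndim else float(out)


def jkr_forward(a_grid, params: ContactModelParams):
    """Evaluate the JKR loading branch parametrically in contact radius.

    Parameters
    ----------
    a_grid : array-like
        Positive, increasing contact radii (m).
    params : ContactModelParams
        Uses ``E``, ``nu``, ``w``, ``R``; the membrane and baseline terms
        are *not* included here.

    Returns
    -------
    (delta, force) : pair of ndarrays
        Indentation depths (m) and forces (N) along the branch.
    """
    a = np.asarray(a_grid, dtype=float)
    if np.any(a <= 0):
        raise InvalidParameterError("contact radii must be positive")
    if a.size > 1 and np.any(np.diff(a) <= 0):
        raise InvalidParameterError("a_grid must be strictly increasing")
    e_star, R, w = params.E_star, params.R, params.w
    force = 4.0 * e_star * a**3 / (3.0 * R) - np.sqrt(8.0 * np.pi * w * e_star * a**3)
    delta = a**2 / R - np.sqrt(2.0 * np.pi * w * a / e_star)
    return delta, force


def jkr_pulloff_force(params: ContactModelParams) -> float:
    """Pull-off (most negative) force on the JKR branch: ``-(3/2) pi w R`` (N)."""
    return -1.5 * np.pi * params.w * params.R


def _branch_radii(params: ContactModelParams):
    """Contact radius and depth at the start of the stable (rising) branch."""
    e_star, R, w = params.E_star, params.R, params.w
    if w == 0:
        return 0.0, 0.0
    c = np.sqrt(2.0 * np.pi * w / e_star)  # delta(a) = a^2/R - c sqrt(a)
    a_dmin = (c * R / 4.0) ** (2.0 / 3.0)
    delta_min = a_dmin**2 / R - c * np.sqrt(a_dmin)
    return a_dmin, delta_min


def jkr_min_depth(params: ContactModelParams) -> float:
    """Smallest indentation depth (m) reachable on the stable JKR branch.

    Negative for ``w > 0``: the surface adheres to the retracting probe
    down to this depth before snap-off.
    """
    return _branch_radii(params)[1]


def _invert_depth(delta, params: ContactModelParams):
    """Contact radius a(delta) on the rising JKR branch (vectorised).

    ``delta(a)`` is strictly convex in ``a``, so a damped Newton iteration
    clamped to the branch converges to machine precision; a few stubborn
    points near the branch minimum fall back to bracketed root finding.
    """
    delta = np.asarray(delta, dtype=float)
    e_star, R, w = params.E_star, params.R, params.w
    if w == 0:
        return np.sqrt(R * np.clip(delta, 0.0, None))
    c = np.sqrt(2.0 * np.pi * w / e_star)
    a_dmin, delta_min = _branch_radii(params)
    tol = 1e-12 * max(abs(delta_min), float(np.max(np.abs(delta), initial=0.0)), 1e-30)
    bad = delta < delta_min - max(1e-9 * abs(delta_min), 1e-30)
    if np.any(bad):
        raise DomainError(
            f"indentation {float(np.min(delta[bad])):.3e} m below the JKR branch "
            f"minimum {delta_min:.3e} m"
        )
    delta = np.clip(delta, delta_min, None)
    # start above the root: delta(a0) >= delta guaranteed by adding the
    # full adhesive sag to a Hertz-like estimate
    a_hi = np.sqrt(R * (np.clip(delta, 0.0, None) - delta_min)) + 2.0 * a_dmin
    a = np.maximum(a_hi, a_dmin * (1.0 + 1e-9))
    for _ in range(100):
        f = a**2 / R - c * np.sqrt(a) - delta
        fp = 2.0 * a / R - c / (2.0 * np.sqrt(a))
        step = np.where(fp > 0, f / np.where(fp > 0, fp, 1.0), 0.0)
        a_new = np.maximum(a - step, a_dmin * (1.0 + 1e-12))
        if np.all(np.abs(a_new - a) <= 1e-14 * a_new + 1e-30):
            a = a_new
            break
        a = a_new
    resid = np.abs(a**2 / R - c * np.sqrt(a) - delta)
    rough = resid > 1e-9 * (np.abs(delta) + abs(delta_min))
    if np.any(rough):
        idx = np.flatnonzero(np.atleast_1d(rough))
        a_flat = np.atleast_1d(a).astype(float)
        d_flat = np.atleast_1d(delta)
        for i in idx:
            a_flat[i] = brentq(
                lambda x: x**2 / R - c * np.sqrt(x) - d_flat[i],
                a_dmin * (1.0 + 1e-15),
                max(a_flat[i] * 4.0, a_dmin * 10.0),
                xtol=1e-18,
                rtol=8.9e-16,
            )
        a = a_flat.reshape(np.shape(a))
    return a


def jkr_force_at_depth(delta, params: ContactModelParams):
    """JKR force (N) at indentation depth(s) ``delta`` (m) on the rising branch.

    Valid for ``delta >= jkr_min_depth(params)``; below that the branch
    does not exist and a :class:`DomainError` is raised.
    """
    a = _invert_depth(delta, params)
    e_star, R, w = params.E_star, params.R, params.w
    if w == 0:
        return hertz_force(delta, params.E, params.nu, R)
    return 4.0 * e_star * a**3 / (3.0 * R) - np.sqrt(8.0 * np.pi * w * e_star * a**3)


def composite_forward(z_grid, params: ContactModelParams, include_adhesive_sag: bool = False):
    """Full measured-force model on the piezo axis.

    Parameters
    ----------
    z_grid : array-like
        Piezo positions (um), increasing toward the sample.
    params : ContactModelParams
        All parameters, including contact point ``z0`` (um) and baseline
        (nN, nN/um).
    include_adhesive_sag : bool
        When True, the adhesive (negative-depth) part of the JKR branch
        between snap-off and the contact point is also evaluated; used to
        render retract segments. Approach curves use the default (contact
        begins at ``z0``).

    Returns
    -------
    ndarray
        Force (nN): baseline for ``z < z0``; baseline + JKR + ``K_m *
        delta`` beyond.
    """
    z = np.asarray(z_grid, dtype=float)
    baseline = params.baseline_offset + params.baseline_slope * z
    delta_m = (z - params.z0) * _UM
    delta_lo = jkr_min_depth(params) if include_adhesive_sag else 0.0
    contact = delta_m >= delta_lo
    out = baseline.copy()
    if np.any(contact):
        d = delta_m[contact]
        f_jkr = jkr_force_at_depth(d, params)
        f_mem = params.K_m * np.clip(d, 0.0, None)
        out[contact] = baseline[contact] + (f_jkr + f_mem) / _NN
    return out


# ---------------------------------------------------------------------------
# contact-point estimation
# ---------------------------------------------------------------------------

def _piecewise_sse(z, f, z0: float, membrane_column: bool = True):
    """SSE of a (line) + (Hertz-shaped contact) piecewise linear-in-coefficients fit."""
    pos = np.clip(z - z0, 0.0, None)
    cols = [np.ones_like(z), z, pos**1.5]
    if membrane_column:
        cols.append(pos)
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, f, rcond=None)
    resid = f - X @ coef
    return float(resid @ resid), coef


def estimate_contact_point(
    curve: ForceCurve,
    method: str = "piecewise",
    grid_step: Optional[float] = None,
    min_pre_points: int = 20,
    min_improvement: float = 0.05,
    rov_window: int = 25,
):
    """Estimate the contact point of an approach force curve.

    ``method="piecewise"`` (default) grid-searches candidate contact
    points: each candidate is scored by the total SSE of a least-squares
    fit of a straight baseline on the pre-contact side joined to a
    Hertz-plus-spring contact shape on the post-contact side, and the
    candidate minimising the SSE wins.  ``method="rov"`` locates the
    maximum of the ratio of local force variance after/before each point.

    Returns
    -------
    (z0, diagnostics) : float (um) and dict
        Diagnostics carry the candidate grid and SSE profile.

    Raises
    ------
    NoContactError
        If no candidate improves on an all-baseline fit, i.e. the curve
        shows no contact regime.
    """
    z, f = curve.approach
    if z.size == 0:
        raise NoContactError("curve has no approach segment")
    order = np.argsort(z)
    z, f = z[order], f[order]
    if z.size <= min_pre_points + 5:
        raise NoContactError(f"approach segment too short ({z.size} points)")

    if method == "rov":
        return _estimate_rov(z, f, rov_window)
    if method != "piecewise":
        raise InvalidParameterError(f"unknown contact-point method {method!r}")

    if grid_step is None:
        candidates = z[min_pre_points:-5]
    else:
        candidates = np.arange(z[min_pre_points], z[-5], grid_step)
    X0 = np.column_stack([np.ones_like(z), z])
    coef0, *_ = np.linalg.lstsq(X0, f, rcond=None)
    r0 = f - X0 @ coef0
    sse_baseline = float(r0 @ r0)

    sse = np.empty(candidates.size)
    for i, z0 in enumerate(candidates):
        sse[i], _ = _piecewise_sse(z, f, z0)
    best = int(np.argmin(sse))
    if not (sse[best] < (1.0 - min_improvement) * sse_baseline):
        raise NoContactError(
            "no candidate contact point improves on the all-baseline fit"
        )
    diagnostics = {
        "candidates": candidates,
        "sse_profile": sse,
        "sse_baseline": sse_baseline,
        "method": "piecewise",
    }
    return float(candidates[best]), diagnostics


def _estimate_rov(z, f, window: int):
    """Ratio-of-variance contact-point detector (config alternative)."""
    n = z.size
    if n < 3 * window:
        raise NoContactError("curve too short for the rov window")
    rov = np.full(n, np.nan)
    for i in range(window, n - window):
        v_after = np.var(f[i : i + window])
        v_before = np.var(f[i - window : i])
        rov[i] = v_after / max(v_before, 1e-30)
    best = int(np.nanargmax(rov))
    if not np.isfinite(rov[best]) or rov[best] < 2.0:
        raise NoContactError("no variance transition found (rov)")
    return float(z[best]), {"rov_profile": rov, "method": "rov"}


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class ContactFitConfig:
    """Configuration of the contact-model fit.

    Bounds follow soft-matter practice and are overridable; the start
    list is deterministic so a fit is reproducible bit-for-bit.
    """

    nu: float = 0.5
    fit_adhesion: bool = True
    fit_membrane: bool = True
    contact_method: str = "piecewise"      # piecewise | rov
    cofit_z0_window: float = 0.2           # um around the detected z0
    E_bounds: tuple = (0.1, 1e6)           # Pa
    w_bounds: tuple = (0.0, 1e-1)          # J/m^2
    K_m_bounds: tuple = (0.0, 1.0)         # N/m
    n_starts: int = 3
    tip_sample_separation_correction: bool = False
    max_indent_fraction: float = 0.4       # of cell height, when supplied
    cell_height: Optional[float] = None    # um
    ftol: float = 1e-14
    xtol: float = 1e-14


class ContactResults:
    """Results of a contact-model fit, statsmodels-style.

    Attributes
    ----------
    params : ContactModelParams
        Best-fit parameters.
    rmse : float
        Root-mean-square residual of the approach fit (nN).
    converged : bool
        Whether any start converged.
    beta : float
        Dimensionless membrane-to-bulk ratio ``K_m / (E R)``.
    indentation_max : float
        Maximum fitted indentation depth (um).
    w_pulloff, hysteresis_energy : float or nan
        Adhesion energetics from the retract segment, when present.
    warnings : list of str
        Non-fatal issues (indentation cap exceeded, n < 3 groups ...).
    """

    def __init__(self, model, params, rmse, converged, diagnostics):
        self.model = model
        self.curve = model.curve
        self.params = params
        self.rmse = float(rmse)
        self.converged = bool(converged)
        self.diagnostics = diagnostics
        self.warnings: list = list(diagnostics.get("warnings", []))

        z, _ = self.curve.approach
        self.indentation_max = float(np.max(z) - params.z0)
        self.beta = params.K_m / (params.E * params.R)

        self.w_pulloff = np.nan
        self.hysteresis_energy = np.nan
        if self.curve.has_retract:
            adh = adhesion_energetics(self.curve)
            self.w_pulloff = adh["w_pulloff"]
            self.hysteresis_energy = adh["hysteresis_energy"]

        cfg = model.config
        if cfg.cell_height is not None:
            cap = cfg.max_indent_fraction * cfg.cell_height
            if self.indentation_max > cap:
                self.warnings.append(
                    f"max indentation {self.indentation_max:.3f} um exceeds "
                    f"{cfg.max_indent_fraction:.0%} of cell height ({cap:.3f} um)"
                )

    def predict(self, z=None):
        """Model force (nN) on piezo positions ``z`` (default: the approach grid)."""
        if z is None:
            z, _ = self.curve.approach
        return composite_forward(z, self.params)

    def plot(self, ax=None):
        """Plot the measured approach/retract data and the fitted model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        z_a, f_a = self.curve.approach
        ax.plot(z_a, f_a, ".", ms=3, alpha=0.6, label="approach")
        if self.curve.has_retract:
            z_r, f_r = self.curve.retract
            ax.plot(z_r, f_r, ".", ms=3, alpha=0.4, label="retract")
        z_fit = np.linspace(z_a.min(), z_a.max(), 400)
        ax.plot(z_fit, self.predict(z_fit), "k-", lw=1.2,
                label=f"fit: E={self.params.E:.3g} Pa")
        ax.axvline(self.params.z0, color="grey", ls=":", lw=0.8)
        ax.set_xlabel("piezo position (um)")
        ax.set_ylabel("force (nN)")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        p = self.params
        lines = [
            "Contact-model fit (JKR + membrane spring)",
            "=" * 45,
            f"  sample           {self.curve.sample_id or '-'}",
            f"  region/substrate {self.curve.region}/{self.curve.substrate_label}",
            f"  converged        {self.converged}",
            f"  E       (Pa)     {p.E:.6g}",
            f"  w       (J/m^2)  {p.w:.6g}",
            f"  K_m     (N/m)    {p.K_m:.6g}",
            f"  beta = K_m/(E R) {self.beta:.6g}",
            f"  z0      (um)     {p.z0:.6g}",
            f"  baseline (nN)    {p.baseline_offset:.4g} + {p.baseline_slope:.4g} z",
            f"  rmse    (nN)     {self.rmse:.4g}",
            f"  max indent (um)  {self.indentation_max:.4g}",
        ]
        if np.isfinite(self.w_pulloff):
            lines.append(f"  w_pulloff (J/m^2) {self.w_pulloff:.6g}")
            lines.append(f"  hysteresis (J)    {self.hysteresis_energy:.6g}")
        for wmsg in self.warnings:
            lines.append(f"  warning: {wmsg}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.curve.sample_id,
            "region": self.curve.region,
            "substrate": self.curve.substrate_label,
            "E_Pa": self.params.E,
            "w_J_per_m2": self.params.w,
            "K_m_N_per_m": self.params.K_m,
            "beta": self.beta,
            "z0_um": self.params.z0,
            "rmse_nN": self.rmse,
            "converged": self.converged,
            "w_pulloff_J_per_m2": self.w_pulloff,
            "hysteresis_J": self.hysteresis_energy,
        }


class ContactModel:
    """JKR + membrane-spring model bound to one force curve.

    Usage mirrors statistical modelling packages: construct from data,
    call :meth:`fit`, inspect the returned :class:`ContactResults`.

    >>> res = ContactModel(curve).fit()       # doctest: +SKIP
    >>> print(res.summary())                  # doctest: +SKIP
    """

    def __init__(self, curve: ForceCurve, config: Optional[ContactFitConfig] = None):
        self.curve = curve
        self.config = config or ContactFitConfig()

    # -- internal ----------------------------------------------------------
    def _pack(self, E, w, K_m, z0, b0, b1):
        cfg = self.config
        x = [np.log10(E)]
        lo = [np.log10(cfg.E_bounds[0])]
        hi = [np.log10(cfg.E_bounds[1])]
        if cfg.fit_adhesion:
            x.append(w)
            lo.append(cfg.w_bounds[0])
            hi.append(cfg.w_bounds[1])
        if cfg.fit_membrane:
            x.append(K_m)
            lo.append(cfg.K_m_bounds[0])
            hi.append(cfg.K_m_bounds[1])
        x += [z0, b0, b1]
        lo += [z0 - cfg.cofit_z0_window, -np.inf, -np.inf]
        hi += [z0 + cfg.cofit_z0_window, np.inf, np.inf]
        return np.array(x, float), (np.array(lo), np.array(hi))

    def _unpack(self, x):
        cfg = self.config
        i = 0
        E = 10.0 ** x[i]; i += 1
        w = 0.0
        if cfg.fit_adhesion:
            w = max(x[i], 0.0); i += 1
        K_m = 0.0
        if cfg.fit_membrane:
            K_m = max(x[i], 0.0); i += 1
        z0, b0, b1 = x[i], x[i + 1], x[i + 2]
        return ContactModelParams(
            E=E, R=self.curve.probe_radius_m, nu=cfg.nu, w=w, K_m=K_m,
            z0=z0, baseline_offset=b0, baseline_slope=b1,
        )

    def _residuals(self, x, z, f):
        try:
            pred = composite_forward(z, self._unpack(x))
        except DomainError:
            return np.full(z.size, 1e6)
        return pred - f

    def fit(self) -> ContactResults:
        """Fit the model to the approach segment.

        Contact point is first located by grid search, then co-fitted in
        a bounded window; bounded least squares (trust-region reflective)
        runs from a deterministic list of ``n_starts`` starting points
        and the lowest-SSE converged solution wins.  Non-convergence on
        every start is flagged in the result, never silent.
        """
        cfg = self.config
        z, f = self.curve.approach
        order = np.argsort(z)
        z, f = z[order], f[order]

        z0_hat, diag = estimate_contact_point(self.curve, method=cfg.contact_method)

        pre = z < z0_hat
        if pre.sum() >= 2:
            b1, b0 = np.polyfit(z[pre], f[pre], 1)
        else:
            b0, b1 = float(np.median(f[:10])), 0.0

        # Hertz-scale starting modulus from the largest baseline-corrected force
        post = z >= z0_hat
        d_max = float(np.max(z[post] - z0_hat)) * _UM
        f_max = float(np.max(f[post] - (b0 + b1 * z[post]))) * _NN
        R = self.curve.probe_radius_m
        if d_max > 0 and f_max > 0:
            E0 = 3.0 * f_max * (1.0 - cfg.nu**2) / (4.0 * np.sqrt(R) * d_max**1.5)
        else:
            E0 = 100.0
        E0 = float(np.clip(E0, cfg.E_bounds[0] * 1.5, cfg.E_bounds[1] / 1.5))

        w0 = 1e-6 if cfg.fit_adhesion else 0.0
        K0 = min(1e-4, cfg.K_m_bounds[1] / 2) if cfg.fit_membrane else 0.0
        start_list = [
            (E0, 0.0, 0.0),
            (E0, w0, K0),
            (min(E0 * 10, cfg.E_bounds[1] / 1.5), w0, 0.0),
            (max(E0 / 10, cfg.E_bounds[0] * 1.5), 0.0, K0),
        ][: max(cfg.n_starts, 3)]

        best = None
        any_converged = False
        for E_s, w_s, K_s in start_list:
            x0, bounds = self._pack(E_s, w_s, K_s, z0_hat, b0, b1)
            x0 = np.clip(x0, bounds[0], bounds[1])
            try:
                sol = least_squares(
                    self._residuals, x0, bounds=bounds, args=(z, f),
                    method="trf", ftol=cfg.ftol, xtol=cfg.xtol, gtol=1e-14,
                    x_scale="jac", max_nfev=4000,
                )
            except Exception:
                continue
            sse = float(sol.fun @ sol.fun)
            any_converged |= bool(sol.success)
            if best is None or sse < best[0]:
                best = (sse, sol)
        if best is None:
            raise NoContactError("contact-model fit failed on every start")

        sse, sol = best
        params = self._unpack(sol.x)
        rmse = np.sqrt(sse / z.size)
        diag = dict(diag)
        diag["n_starts"] = len(start_list)
        diag["warnings"] = [] if any_converged else ["no start converged"]
        return ContactResults(self, params, rmse, any_converged, diag)


def fit_contact_model(curve: ForceCurve, config: Optional[ContactFitConfig] = None) -> ContactResults:
    """Functional wrapper: ``ContactModel(curve, config).fit()``."""
    return ContactModel(curve, config).fit()


# ---------------------------------------------------------------------------
# adhesion energetics
# ---------------------------------------------------------------------------

def adhesion_energetics(curve: ForceCurve, baseline_fraction: float = 0.2) -> dict:
    """Adhesion measures from the approach/retract pair.

    ``w_pulloff`` converts the deepest retract force excursion below the
    baseline into a work of adhesion via the JKR pull-off identity
    ``|F_pull| = (3/2) pi w R``, i.e. ``w = 2 |F_min - baseline| / (3 pi R)``.
    ``hysteresis_energy`` is the trapezoidal integral of (approach -
    retract) force over the overlapping piezo range, in joules.

    The baseline is the median retract force over the ``baseline_fraction``
    of samples farthest from the sample surface.
    """
    if not curve.has_retract:
        raise InvalidParameterError("adhesion energetics requires a retract segment")
    z_r, f_r = curve.retract
    order = np.argsort(z_r)
    z_r, f_r = z_r[order], f_r[order]
    n_tail = max(int(baseline_fraction * z_r.size), 3)
    baseline = float(np.median(f_r[:n_tail]))  # smallest z = farthest from sample

    f_min = float(np.min(f_r))
    R = curve.probe_radius_m
    zero_adhesion = f_min >= baseline
    if zero_adhesion:
        w_pulloff = 0.0
    else:
        w_pulloff = 2.0 * abs(f_min - baseline) * _NN / (3.0 * np.pi * R)

    z_a, f_a = curve.approach
    order = np.argsort(z_a)
    z_a, f_a = z_a[order], f_a[order]
    lo = max(z_a[0], z_r[0])
    hi = min(z_a[-1], z_r[-1])
    if hi <= lo:
        hysteresis = 0.0
    else:
        grid = np.linspace(lo, hi, 512)
        fa = np.interp(grid, z_a, f_a)
        fr = np.interp(grid, z_r, f_r)
        hysteresis = float(np.trapezoid(fa - fr, grid)) * _NN * _UM  # nN*um -> J
    return {
        "w_pulloff": w_pulloff,
        "hysteresis_energy": hysteresis,
        "zero_adhesion": zero_adhesion,
        "baseline_nN": baseline,
    }


# ---------------------------------------------------------------------------
# cohort aggregation
# ---------------------------------------------------------------------------

def aggregate_by_region(results: Sequence[ContactResults]) -> pd.DataFrame:
    """Per-(substrate, region) summary of fitted mechanics.

    Returns mean, SD and n of E, K_m, beta, w_pulloff and hysteresis per
    group.  SD is NaN for singleton groups; groups with n < 3 are flagged
    in the ``small_n`` column.
    """
    if len(results) == 0:
        raise EmptyTableError("no fit results to aggregate")
    rows = [r.to_dict() for r in results]
    df = pd.DataFrame(rows)
    metrics = ["E_Pa", "K_m_N_per_m", "beta", "w_pulloff_J_per_m2", "hysteresis_J"]
    agg = df.groupby(["substrate", "region"])[metrics].agg(["mean", "std", "count"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    agg = agg.reset_index()
    agg["n"] = agg[f"{metrics[0]}_count"]
    agg = agg.drop(columns=[f"{m}_count" for m in metrics])
    agg["small_n"] = agg["n"] < 3
    return agg
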
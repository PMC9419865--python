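"""Core data containers shared across pipeline stages.

Conventions
-----------
* Piezo position ``z`` is stored in micrometres and increases toward the
  sample on approach; force is stored in nanonewtons.
* Contact-model parameters are SI (Pa, J/m^2, N/m, m) except the contact
  point ``z0`` and the baseline, which live on the curve's (um, nN) scale
  so that fitted baselines are directly comparable with raw data.
* Images are numpy arrays indexed (row, col); pixel sizes are physical
  units per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "ForceCurve",
    "ContactModelParams",
    "HeightMap",
    "LabelImage",
    "GroundTruth",
    "WoundSeries",
]


@dataclass
class ContactModelParams:
    """Parameters of the adhesive sphere-on-half-space contact model.

    Attributes
    ----------
    E : float
        Young's modulus of the indented body (Pa); the bulk modulus of
        the cell in the cell-probing context.
    nu : float
        Poisson ratio. 0.5 (incompressible) is accepted as a limiting
        value and is the default for live cells.
    w : float
        Work of adhesion between probe and surface (J/m^2). 0 recovers
        the adhesionless Hertz model.
    K_m : float
        Effective membrane stiffness (N/m): a linear spring resisting
        indentation, representing stretch of the cell membrane.
    R : float
        Probe radius (m).
    z0 : float
        Contact point on the piezo axis (um).
    baseline_offset : float
        Force offset of the non-contact baseline (nN).
    baseline_slope : float
        Linear drift of the baseline (nN/um).
    """

    E: float
    R: float
    nu: float = 0.5
    w: float = 0.0
    K_m: float = 0.0
    z0: float = 0.0
    baseline_offset: float = 0.0
    baseline_slope: float = 0.0

    def __post_init__(self):
        if not (self.E > 0):
            raise InvalidParameterError(f"Young's modulus must be positive, got {self.E}")
        if not (self.R > 0):
            raise InvalidParameterError(f"probe radius must be positive, got {self.R}")
        if not (0.0 <= self.nu <= 0.5):
            raise InvalidParameterError(f"Poisson ratio must lie in [0, 0.5], got {self.nu}")
        if self.w < 0:
            raise InvalidParameterError(f"work of adhesion must be >= 0, got {self.w}")
        if self.K_m < 0:
            raise InvalidParameterError(f"membrane stiffness must be >= 0, got {self.K_m}")

    @property
    def E_star(self) -> float:
        """Reduced (plane-strain) modulus E / (1 - nu^2), Pa."""
        return self.E / (1.0 - self.nu**2)

    @property
    def beta(self) -> float:
        """Dimensionless membrane-to-bulk stiffness ratio K_m / (E * R)."""
        return self.K_m / (self.E * self.R)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ForceCurve:
    """A single AFM nanoindentation record (approach + retract).

    ``z`` and ``force`` hold both segments concatenated; ``segment`` labels
    each sample ``"approach"`` or ``"retract"``.
    """

    z: np.ndarray                 # um, increasing toward the sample on approach
    force: np.ndarray             # nN
    segment: np.ndarray           # str per point: approach | retract
    probe_radius: float           # um
    spring_constant: float = 0.01  # N/m
    region: str = "cytoplasm"     # cytoplasm | nucleus | junction | substrate
    substrate_label: str = "NCCI"  # TCPS | NCCI
    sample_id: str = ""

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment = np.asarray(self.segment)
        if self.z.shape != self.force.shape or self.z.shape != self.segment.shape:
            raise InvalidParameterError("z, force and segment must have equal length")
        if self.z.size < 50:
            raise InvalidParameterError(f"force curve needs >= 50 samples, got {self.z.size}")
        if not (np.all(np.isfinite(self.z)) and np.all(np.isfinite(self.force))):
            raise InvalidParameterError("force curve contains non-finite values")
        if not (self.probe_radius > 0):
            raise InvalidParameterError("probe radius must be positive")

    def _seg(self, name: str):
        mask = self.segment == name
        return self.z[mask], self.force[mask]

    @property
    def approach(self):
        """(z, force) arrays of the approach segment."""
        return self._seg("approach")

    @property
    def retract(self):
        """(z, force) arrays of the retract segment."""
        return self._seg("retract")

    @property
    def has_retract(self) -> bool:
        return bool(np.any(self.segment == "retract"))

    @property
    def probe_radius_m(self) -> float:
        return self.probe_radius * 1e-6


@dataclass
class HeightMap:
    """2D height field (um) with square pixels of known lateral size."""

    heights: np.ndarray  # um
    pixel_size: float    # um / px

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise InvalidParameterError("height map must be 2D")
        if not np.all(np.isfinite(self.heights)):
            raise InvalidParameterError("height map contains non-finite values")
        if not (self.pixel_size > 0):
            raise InvalidParameterError("pixel size must be positive")


@dataclass
class LabelImage:
    """Integer-labelled segmentation mask; 0 is background."""

    labels: np.ndarray
    pixel_size: float  # um / px
    channel_of_origin: str = "nucleus"  # nucleus | cell

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InvalidParameterError("label image must be 2D")
        if np.any(self.labels < 0):
            raise InvalidParameterError("labels must be non-negative")
        if not (self.pixel_size > 0):
            raise InvalidParameterError("pixel size must be positive")

    @property
    def n_objects(self) -> int:
        return int(len(np.unique(self.labels[self.labels > 0])))


@dataclass
class GroundTruth:
    """Ground-truth sidecar attached to every synthetic artifact."""

    kind: str  # force_curve | fiber_image | monolayer_image | height_map | wound_series
    parameters: dict
    seed: int
    per_object_truth: Optional[pd.DataFrame] = None

    _KINDS = ("force_curve", "fiber_image", "monolayer_image", "height_map", "wound_series")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise InvalidParameterError(f"unknown ground-truth kind {self.kind!r}")


@dataclass
class WoundSeries:
    """Time series of scratch-assay frames, one image per timepoint."""

    timepoints: np.ndarray       # hours, ascending, first == 0
    images: list                 # one 2D array per timepoint
    pixel_size: float            # um / px
    scratch_axis: int = 0        # image axis along which the wound runs

    def __post_init__(self):
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.timepoints.size < 2:
            raise InvalidParameterError("wound series needs >= 2 timepoints")
        if self.timepoints[0] != 0:
            raise InvalidParameterError("first timepoint must be 0 h")
        if np.any(np.diff(self.timepoints) <= 0):
            raise InvalidParameterError("timepoints must be strictly ascending")
        if len(self.images) != self.timepoints.size:
            raise InvalidParameterError("one image per timepoint required")
        shapes = {np.asarray(im).shape for im in self.images}
        if len(shapes) != 1:
            raise InvalidParameterError("all frames must share one shape")
        if self.scratch_axis not in (0, 1):
            raise InvalidParameterError("scratch_axis must be 0 or 1")
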
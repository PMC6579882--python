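"""Shared domain types, coordinate conventions and acquisition/paradigm presets.

Conventions used throughout the package:

* voxel indices are 0-based; world coordinates are millimetres obtained through
  the image affine (RAS-like: +X lateral-right, +Y anterior, +Z dorsal);
* the 3 x 3 factorial of MOVEMENT (foot, hand, face) x RESOLUTION
  (1.5, 2, 3 mm) is ordered resolution-major, movement-minor, i.e. cell
  ``i`` maps to ``(RESOLUTIONS[i // 3], BODY_PARTS[i % 3])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

BODY_PARTS: tuple[str, ...] = ("foot", "hand", "face")
SIDES: tuple[str, ...] = ("left", "right")
RESOLUTIONS: tuple[float, ...] = (1.5, 2.0, 3.0)

#: canonical condition labels, body part major: foot_left, foot_right, ...
CONDITIONS: tuple[str, ...] = tuple(f"{bp}_{sd}" for bp in BODY_PARTS for sd in SIDES)

ROI_STRUCTURES: tuple[str, ...] = ("M1", "SMA", "putamen", "pallidum", "thalamus")
CORTICAL_STRUCTURES: tuple[str, ...] = ("M1", "SMA")
SUBCORTICAL_STRUCTURES: tuple[str, ...] = ("putamen", "pallidum", "thalamus")

#: head-foot coverage (mm) retained by every acquisition preset
HEAD_FOOT_COVERAGE_MM = 90.0


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ProtocolSpec:
    """One EPI acquisition protocol (voxel size / timing / volume count).

    ``volume_tr_ms`` is the time to acquire one full volume, in milliseconds.
    ``retained_slices`` are the slices kept after discarding oversampled ones,
    so that ``retained_slices * slice_thickness_mm`` gives the common
    head-foot coverage shared by all presets.
    """

    name: str
    voxel_size_mm: float
    volume_tr_ms: float
    n_volumes: int
    encoding: str  # "2D" or "3D"
    retained_slices: int
    slice_thickness_mm: float

    def __post_init__(self) -> None:
        if self.volume_tr_ms <= 0:
            raise ValidationError(f"volume_tr_ms must be > 0, got {self.volume_tr_ms}")
        if self.n_volumes <= 0:
            raise ValidationError(f"n_volumes must be > 0, got {self.n_volumes}")
        if self.encoding not in ("2D", "3D"):
            raise ValidationError(f"encoding must be '2D' or '3D', got {self.encoding!r}")

    @property
    def tr_s(self) -> float:
        """Volume TR in seconds."""
        return self.volume_tr_ms / 1000.0

    @property
    def coverage_mm(self) -> float:
        """Head-foot coverage of the retained slab, in mm."""
        return self.retained_slices * self.slice_thickness_mm

    @property
    def scan_duration_s(self) -> float:
        return self.n_volumes * self.tr_s


@dataclass(frozen=True)
class ParadigmSpec:
    """Block paradigm: 6 movement conditions (body part x side), paced blocks
    alternating with rest, each active block preceded by a cued preparation
    period."""

    conditions: tuple[str, ...] = CONDITIONS
    blocks_per_condition: int = 3
    block_duration_s: float = 16.0
    rest_duration_s: float = 16.0
    prep_duration_s: float = 3.0
    pace_hz: float = 1.0
    order_seed: int = 0

    def __post_init__(self) -> None:
        if self.blocks_per_condition <= 0:
            raise ValidationError("blocks_per_condition must be >= 1")
        if len(self.conditions) == 0:
            raise ValidationError("at least one condition required")
        if self.block_duration_s <= 0 or self.rest_duration_s < 0 or self.prep_duration_s < 0:
            raise ValidationError("durations must be non-negative (block > 0)")

    @property
    def n_active_blocks(self) -> int:
        return len(self.conditions) * self.blocks_per_condition

    @property
    def total_duration_s(self) -> float:
        """Session length: each active block contributes rest + prep + active."""
        per_block = self.rest_duration_s + self.prep_duration_s + self.block_duration_s
        return self.n_active_blocks * per_block


@dataclass
class VolumeImage:
    """A 3D or 4D intensity array with a voxel-to-mm affine."""

    data: np.ndarray
    affine: np.ndarray
    space_label: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is singular")
        if self.data.ndim not in (3, 4):
            raise ValidationError(f"data must be 3D or 4D, got ndim={self.data.ndim}")

    @property
    def n_volumes(self) -> int:
        return 1 if self.data.ndim == 3 else self.data.shape[3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices to world mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        out = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return np.squeeze(out)


@dataclass
class ROISet:
    """Integer-labelled ROI mask volume; label ``i+1`` is ``names[i]``."""

    labels: np.ndarray
    names: list[str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("labels must be a 3D volume")
        for i, name in enumerate(self.names):
            if not np.any(self.labels == i + 1):
                raise ValidationError(f"ROI {name!r} (label {i + 1}) is empty")

    def mask(self, name: str) -> np.ndarray:
        """Boolean mask of one named ROI."""
        return self.labels == self.names.index(name) + 1

    def voxel_count(self, name: str) -> int:
        return int(self.mask(name).sum())

    def as_image(self) -> VolumeImage:
        return VolumeImage(self.labels, self.affine, space_label="roi-labels")


@dataclass(frozen=True)
class FactorialIndex:
    """The 9-cell MOVEMENT x RESOLUTION factorial, resolution-major."""

    movements: tuple[str, ...] = BODY_PARTS
    resolutions: tuple[float, ...] = RESOLUTIONS

    @property
    def p(self) -> int:
        return len(self.movements) * len(self.resolutions)

    def cell(self, index: int) -> tuple[str, float]:
        """Cell index -> (movement, resolution)."""
        if not 0 <= index < self.p:
            raise ValidationError(f"cell index {index} out of range 0..{self.p - 1}")
        n_mov = len(self.movements)
        return self.movements[index % n_mov], self.resolutions[index // n_mov]

    def cell_index(self, movement: str, resolution: float) -> int:
        """(movement, resolution) -> cell index (inverse of :meth:`cell`)."""
        i_mov = self.movements.index(movement)
        i_res = self.resolutions.index(resolution)
        return i_res * len(self.movements) + i_mov

    def labels(self) -> list[tuple[str, float]]:
        return [self.cell(i) for i in range(self.p)]

    def within_resolution_pairs(self) -> list[tuple[int, int]]:
        """Movement pairs at a fixed resolution: 3 pairs x 3 resolutions."""
        pairs = []
        for res in self.resolutions:
            idx = [self.cell_index(m, res) for m in self.movements]
            pairs.extend(combinations(idx, 2))
        return pairs

    def within_movement_pairs(self) -> list[tuple[int, int]]:
        """Resolution pairs at a fixed movement: C(3,2) x 3 movements."""
        pairs = []
        for mov in self.movements:
            idx = [self.cell_index(mov, r) for r in self.resolutions]
            pairs.extend(combinations(idx, 2))
        return pairs


def default_protocol_presets() -> list[ProtocolSpec]:
    """The three acquisition presets: 1.5 mm 3D, 2 mm 3D and 3 mm 2D EPI.

    All three retain a 90 mm head-foot slab after discarding oversampled
    slices; retained-slice counts are 60/45/30 so that
    ``retained_slices * slice_thickness`` equals that coverage.
    """
    return [
        ProtocolSpec("1.5mm", 1.5, 4032.0, 176, "3D", 60, 1.5),
        ProtocolSpec("2mm", 2.0, 2704.0, 263, "3D", 45, 2.0),
        ProtocolSpec("3mm", 3.0, 1980.0, 359, "2D", 30, 3.0),
    ]


def factorial_cells() -> FactorialIndex:
    """The default 3 x 3 MOVEMENT x RESOLUTION factorial (9 cells)."""
    return FactorialIndex()


def body_part_and_side(condition: str) -> tuple[str, str]:
    """Split a condition label like ``"hand_left"`` into (body part, side)."""
    bp, _, sd = condition.partition("_")
    if bp not in BODY_PARTS or sd not in SIDES:
        raise ValidationError(f"unrecognized condition label {condition!r}")
    return bp, sd


def contralateral(side: str) -> str:
    """Hemisphere contralateral to a movement side."""
    if side not in SIDES:
        raise ValidationError(f"unknown side {side!r}")
    return "right" if side == "left" else "left"
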
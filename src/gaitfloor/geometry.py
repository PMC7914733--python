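"""Geometry of a modular capacitive sensor floor.

The floor is tiled with square sensor modules. Each module carries a
microcontroller at its center and eight triangular sensor fields, obtained by
cutting the module square along both diagonals and both mid-lines. Every
triangle is right-angled with legs ``h`` and ``h`` where ``h = l_M / 2`` is
half the module edge, so its centroid sits at offsets ``(±2h/3, ±h/3)`` or
``(±h/3, ±2h/3)`` from the module center.

Field slots are numbered ``j = 1..8`` by enumerating the quadrants
counter-clockwise starting at (+x, +y); within each quadrant the x-major
triangle (centroid farther out in x) comes before the y-major one. The slot
order is a convention of this package — any fixed order works because the
downstream learning stage uses a fixed association of fields to inputs.

Coordinates are metres in a global floor frame with y increasing into the
room.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidGeometryError, UnknownModuleError, ValidationError

FIELDS_PER_MODULE = 8

# Centroid offsets in units of h = edge / 2, in slot order j = 1..8.
_UNIT_CENTROIDS = np.array(
    [
        (2 / 3, 1 / 3), (1 / 3, 2 / 3),      # quadrant (+x, +y)
        (-2 / 3, 1 / 3), (-1 / 3, 2 / 3),    # quadrant (-x, +y)
        (-2 / 3, -1 / 3), (-1 / 3, -2 / 3),  # quadrant (-x, -y)
        (2 / 3, -1 / 3), (1 / 3, -2 / 3),    # quadrant (+x, -y)
    ]
)

# Triangle vertices in units of h, matching the slot order above. The x-major
# triangle of quadrant (sx, sy) is (0,0)-(sx,0)-(sx,sy); the y-major one is
# (0,0)-(0,sy)-(sx,sy).
_UNIT_TRIANGLES = np.array(
    [
        [(0, 0), (1, 0), (1, 1)],
        [(0, 0), (0, 1), (1, 1)],
        [(0, 0), (-1, 0), (-1, 1)],
        [(0, 0), (0, 1), (-1, 1)],
        [(0, 0), (-1, 0), (-1, -1)],
        [(0, 0), (0, -1), (-1, -1)],
        [(0, 0), (1, 0), (1, -1)],
        [(0, 0), (0, -1), (1, -1)],
    ],
    dtype=float,
)


@dataclass(frozen=True)
class ModuleGeometry:
    """One square sensor module: identifier, center position and edge length."""

    module_id: str
    center: tuple[float, float]
    edge: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.edge) or self.edge <= 0:
            raise InvalidGeometryError(
                f"module {self.module_id!r}: edge length must be > 0, got {self.edge}"
            )
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))


def field_centroids(module: ModuleGeometry) -> np.ndarray:
    """Centroid positions of the 8 triangular fields, shape (8, 2), metres.

    All sign combinations of ``(±2h/3, ±h/3)`` and ``(±h/3, ±2h/3)`` with
    ``h = edge / 2``, added to the module center, in slot order j = 1..8.
    """
    h = module.edge / 2.0
    return np.asarray(module.center) + _UNIT_CENTROIDS * h


def field_triangles(module: ModuleGeometry) -> np.ndarray:
    """Vertex coordinates of the 8 field triangles, shape (8, 3, 2), metres."""
    h = module.edge / 2.0
    return np.asarray(module.center) + _UNIT_TRIANGLES * h


def fields_per_square_meter(l_x: float, l_y: float, fields_per_module: int = FIELDS_PER_MODULE) -> float:
    """Spatial sensor density of a module type: fields per square metre.

    Supports rectangular module outlines via separate x/y edge lengths.
    """
    if l_x <= 0 or l_y <= 0:
        raise InvalidGeometryError(f"module dimensions must be > 0, got {l_x} x {l_y}")
    if fields_per_module < 1:
        raise InvalidGeometryError("fields_per_module must be >= 1")
    return fields_per_module / (l_x * l_y)


def field_area(l_m: float, fields_per_module: int = FIELDS_PER_MODULE) -> float:
    """Area of one triangular field of a square module, m**2."""
    if l_m <= 0:
        raise InvalidGeometryError(f"edge length must be > 0, got {l_m}")
    if fields_per_module < 1:
        raise InvalidGeometryError("fields_per_module must be >= 1")
    return l_m * l_m / fields_per_module


def field_id(module_id: str, slot: int) -> str:
    """Deterministic unique field id from (module id, slot j in 1..8)."""
    if not 1 <= slot <= FIELDS_PER_MODULE:
        raise ValidationError(f"field slot must be in 1..8, got {slot}")
    return f"{module_id}#{slot}"


@dataclass(frozen=True)
class FloorLayout:
    """Ordered collection of modules plus the derived per-field index.

    Fields are indexed contiguously: the fields of ``modules[k]`` occupy rows
    ``8k .. 8k+7`` of :attr:`positions`, in slot order.
    """

    modules: tuple[ModuleGeometry, ...]
    _module_index: dict[str, int] = field(init=False, repr=False, compare=False)
    _positions: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        mods = tuple(self.modules)
        object.__setattr__(self, "modules", mods)
        ids = [m.module_id for m in mods]
        if len(set(ids)) != len(ids):
            raise InvalidGeometryError("module ids must be unique")
        object.__setattr__(self, "_module_index", {mid: k for k, mid in enumerate(ids)})
        if mods:
            pos = np.concatenate([field_centroids(m) for m in mods], axis=0)
        else:
            pos = np.zeros((0, 2))
        pos.setflags(write=False)
        object.__setattr__(self, "_positions", pos)

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def n_fields(self) -> int:
        return FIELDS_PER_MODULE * len(self.modules)

    @property
    def positions(self) -> np.ndarray:
        """Global centroid positions of all fields, shape (n_fields, 2)."""
        return self._positions

    @property
    def field_ids(self) -> list[str]:
        return [
            field_id(m.module_id, j)
            for m in self.modules
            for j in range(1, FIELDS_PER_MODULE + 1)
        ]

    def has_module(self, module_id: str) -> bool:
        return module_id in self._module_index

    def module_slice(self, module_id: str) -> slice:
        """Row slice of a module's 8 fields in the flat field arrays."""
        try:
            k = self._module_index[module_id]
        except KeyError:
            raise UnknownModuleError(f"module id {module_id!r} not in layout") from None
        return slice(FIELDS_PER_MODULE * k, FIELDS_PER_MODULE * (k + 1))

    # -- constructors ------------------------------------------------------

    @classmethod
    def grid(
        cls,
        n_x: int,
        n_y: int,
        edge: float = 0.38,
        origin: tuple[float, float] = (0.0, 0.0),
    ) -> "FloorLayout":
        """Rectangular floor of ``n_x`` by ``n_y`` square modules.

        Module ``m{ix}_{iy}`` is centred at
        ``origin + ((ix + 1/2) edge, (iy + 1/2) edge)``.
        """
        if n_x < 0 or n_y < 0:
            raise InvalidGeometryError("module counts must be >= 0")
        mods = [
            ModuleGeometry(
                f"m{ix}_{iy}",
                (origin[0] + (ix + 0.5) * edge, origin[1] + (iy + 0.5) * edge),
                edge,
            )
            for iy in range(n_y)
            for ix in range(n_x)
        ]
        return cls(tuple(mods))

    # -- layout file I/O ---------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "FloorLayout":
        """Read a layout file: columns module_id, center_x_m, center_y_m, edge_m."""
        df = pd.read_csv(path)
        required = {"module_id", "center_x_m", "center_y_m", "edge_m"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"layout file missing columns: {sorted(missing)}")
        mods = tuple(
            ModuleGeometry(str(r.module_id), (r.center_x_m, r.center_y_m), r.edge_m)
            for r in df.itertuples(index=False)
        )
        return cls(mods)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "module_id": [m.module_id for m in self.modules],
                "center_x_m": [m.center[0] for m in self.modules],
                "center_y_m": [m.center[1] for m in self.modules],
                "edge_m": [m.edge for m in self.modules],
            }
        ).to_csv(path, index=False)


def corridor_layout(n_long: int = 16, n_wide: int = 4, edge: float = 0.38) -> FloorLayout:
    """Corridor-shaped floor for straight-walk recordings.

    The long axis is y (the walking direction); the default 16 x 4 modules at
    the 0.38 m gait-resolution edge give a 1.52 m x 6.08 m strip.
    """
    return FloorLayout.grid(n_x=n_wide, n_y=n_long, edge=edge)
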
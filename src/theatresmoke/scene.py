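"""Operating-theatre geometry and its structured-grid discretization.

The modelled theatre is an 8 x 6 x 3 m room ventilated by a laminar
downflow curtain from a 2.4 x 2.6 m ceiling inlet, exhausted through two
4 x 0.3 m wall outlets whose lower edge sits 0.1 m above the floor on the
two opposite 8 m walls, with a 1.8 x 0.8 x 0.8 m operating table centred
on the floor.  The incision — the smoke source — sits 0.1 m above the
table centre (z = 0.9 m).

Coordinates: origin at a floor corner, x along the 8 m side, y along the
6 m side, z vertically upward.  The mesh is rectilinear Cartesian: by
default uniform, optionally graded (stretched) toward a focus point so
the sub-grid smoke source is resolved by much smaller cells than the room
average.  Table cells are masked solid, and every boundary face (domain
boundary or fluid-solid interface) carries exactly one patch label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TheatreScene", "Mesh", "GradingSpec", "build_mesh", "locate_cell",
           "Patch", "MeshError"]


class MeshError(ValueError):
    """A geometry patch cannot be resolved on the requested grid."""


class Patch:
    """Integer face-patch labels."""

    INTERIOR = 0
    INLET = 1
    OUTLET = 2
    SIDEWALL = 3     # the four vertical room walls (Robin heat condition)
    CEILING = 4      # ceiling outside the inlet (adiabatic)
    FLOOR = 5        # adiabatic
    TABLE = 6        # table surfaces (adiabatic)

    NAMES = {0: "interior", 1: "inlet", 2: "outlet", 3: "wall",
             4: "ceiling", 5: "floor", 6: "table-surface"}


@dataclass(frozen=True)
class TheatreScene:
    """Axis-aligned description of the room of the simulated surgery."""

    room: tuple[float, float, float] = (8.0, 6.0, 3.0)
    inlet_size: tuple[float, float] = (2.4, 2.6)          # (x, y) extent on ceiling
    outlet_size: tuple[float, float] = (4.0, 0.3)         # (width, height) on y walls
    outlet_bottom: float = 0.1
    table_size: tuple[float, float, float] = (1.8, 0.8, 0.8)
    incision_height_above_table: float = 0.1

    def __post_init__(self) -> None:
        lx, ly, lz = self.room
        if min(self.room) <= 0:
            raise ValueError("room dimensions must be positive")
        if self.inlet_size[0] > lx or self.inlet_size[1] > ly:
            raise ValueError("ceiling inlet larger than ceiling")
        if self.outlet_size[0] > lx:
            raise ValueError("outlet wider than wall")
        if any(t >= r for t, r in zip(self.table_size, self.room)):
            raise ValueError("table must fit inside the room")

    # -- derived geometry (all rectangles centred) --------------------------
    @property
    def inlet_rect(self) -> tuple[tuple[float, float], tuple[float, float]]:
        lx, ly, _ = self.room
        sx, sy = self.inlet_size
        return ((lx / 2 - sx / 2, lx / 2 + sx / 2), (ly / 2 - sy / 2, ly / 2 + sy / 2))

    @property
    def outlet_rect(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """(x-range, z-range) of each outlet on the y=0 and y=Ly walls."""
        lx, _, _ = self.room
        w, h = self.outlet_size
        return ((lx / 2 - w / 2, lx / 2 + w / 2),
                (self.outlet_bottom, self.outlet_bottom + h))

    @property
    def table_box(self) -> tuple[tuple[float, float], ...]:
        lx, ly, _ = self.room
        tx, ty, tz = self.table_size
        return ((lx / 2 - tx / 2, lx / 2 + tx / 2),
                (ly / 2 - ty / 2, ly / 2 + ty / 2),
                (0.0, tz))

    @property
    def incision_point(self) -> tuple[float, float, float]:
        lx, ly, _ = self.room
        return (lx / 2, ly / 2, self.table_size[2] + self.incision_height_above_table)


@dataclass(frozen=True)
class GradingSpec:
    """Smooth stretching of the mesh toward a focus point.

    Cell widths follow w(x) = 1 - (1-min_fraction) exp(-((x-x0)/width)^2),
    normalised so they sum to the room extent: cells near the focus are
    about ``min_fraction`` of the size they would have far from it.  The
    default focusses on the incision, where the physical smoke source is
    centimetres across — far below any affordable uniform spacing.
    """

    #: focus of the refinement (defaults to the incision point)
    focus: tuple[float, float, float] | None = None
    #: finest-to-coarse width ratio per axis; the default places ~6-8 cm
    #: cells at the incision on the standard 40x30x15 grid, matching the
    #: scale of the wound region the smoke emerges from
    min_fraction: tuple[float, float, float] = (0.2, 0.2, 0.2)
    width: tuple[float, float, float] = (1.2, 1.2, 0.7)

    def __post_init__(self):
        for f in self.min_fraction:
            if not 0 < f <= 1:
                raise ValueError("min_fraction components must lie in (0, 1]")
        if any(w <= 0 for w in self.width):
            raise ValueError("width components must be positive")


def _graded_faces(n: int, length: float, x0: float, min_frac: float,
                  width: float) -> np.ndarray:
    """Face coordinates of a graded 1-D axis (fixed-point iteration on the
    width profile evaluated at cell centres)."""
    faces = np.linspace(0.0, length, n + 1)
    for _ in range(30):
        centers = 0.5 * (faces[1:] + faces[:-1])
        w = 1.0 - (1.0 - min_frac) * np.exp(-(((centers - x0) / width) ** 2))
        w *= length / w.sum()
        faces = np.concatenate([[0.0], np.cumsum(w)])
        faces[-1] = length
    return faces


@dataclass
class Mesh:
    """Rectilinear structured mesh with solid mask and face patches.

    ``faces`` holds the three per-axis face-coordinate arrays (lengths
    nx+1, ny+1, nz+1); ``fluid`` is True on fluid cells; ``fx``, ``fy``,
    ``fz`` carry the patch label of every x-, y-, z-normal face (shapes
    (nx+1,ny,nz) etc.), with interior fluid-fluid faces ``Patch.INTERIOR``.
    """

    scene: TheatreScene
    n: tuple[int, int, int]
    faces: tuple[np.ndarray, np.ndarray, np.ndarray]
    fluid: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fz: np.ndarray

    @property
    def nx(self) -> int: return self.n[0]

    @property
    def ny(self) -> int: return self.n[1]

    @property
    def nz(self) -> int: return self.n[2]

    @property
    def uniform(self) -> bool:
        return all(np.allclose(np.diff(f), np.diff(f)[0]) for f in self.faces)

    def widths(self, axis: int) -> np.ndarray:
        """Cell widths along one axis."""
        return np.diff(self.faces[axis])

    @property
    def d(self) -> tuple[float, float, float]:
        """Mean cell spacing per axis (exact for uniform meshes)."""
        return tuple(self.scene.room[a] / self.n[a] for a in range(3))

    def centers(self, axis: int) -> np.ndarray:
        f = self.faces[axis]
        return 0.5 * (f[1:] + f[:-1])

    @property
    def volumes(self) -> np.ndarray:
        """Per-cell volumes, shape (nx, ny, nz)."""
        wx, wy, wz = (self.widths(a) for a in range(3))
        return wx[:, None, None] * wy[None, :, None] * wz[None, None, :]

    @property
    def cell_volume(self) -> float:
        """Mean cell volume (exact for uniform meshes)."""
        lx, ly, lz = self.scene.room
        return lx * ly * lz / self.n_cells

    def face_areas(self, axis: int) -> np.ndarray:
        """Cross-sectional area of the faces normal to ``axis``; shape is
        the transverse cell-count pair, e.g. (ny, nz) for x-faces."""
        w = [self.widths(a) for a in range(3)]
        t1, t2 = [a for a in range(3) if a != axis]
        return w[t1][:, None] * w[t2][None, :]

    @property
    def n_cells(self) -> int:
        return self.n[0] * self.n[1] * self.n[2]

    def patch_area(self, label: int) -> float:
        ax_area = self.face_areas(0)[None, :, :]
        ay_area = self.face_areas(1)[:, None, :]
        az_area = self.face_areas(2)[:, :, None]
        return float(((self.fx == label) * ax_area).sum()
                     + ((self.fy == label) * ay_area).sum()
                     + ((self.fz == label) * az_area).sum())

    @property
    def incision_cell(self) -> tuple[int, int, int]:
        return locate_cell(self, self.scene.incision_point)


def _rect_faces(centers_a, centers_b, rect) -> np.ndarray:
    (a0, a1), (b0, b1) = rect
    in_a = (centers_a >= a0) & (centers_a < a1)
    in_b = (centers_b >= b0) & (centers_b < b1)
    return np.outer(in_a, in_b)


def build_mesh(scene: TheatreScene, resolution: tuple[int, int, int],
               grading: GradingSpec | None = None) -> Mesh:
    """Discretize the scene on a ``resolution`` grid.

    With ``grading`` the axes are stretched toward the grading focus
    (default: the incision point); otherwise spacing is uniform.  A cell
    is solid when its centre lies inside the table box; boundary faces are
    labelled by which patch rectangle their centre falls in (half-open
    intervals, so each face gets exactly one label).  Raises
    :class:`MeshError` naming the first patch not resolved by at least one
    face.
    """
    nx, ny, nz = (int(v) for v in resolution)
    if min(nx, ny, nz) < 1:
        raise MeshError("resolution components must be positive")
    lx, ly, lz = scene.room
    if grading is None:
        faces = tuple(np.linspace(0.0, scene.room[a], (nx, ny, nz)[a] + 1)
                      for a in range(3))
    else:
        focus = grading.focus or scene.incision_point
        faces = tuple(
            _graded_faces((nx, ny, nz)[a], scene.room[a], focus[a],
                          grading.min_fraction[a], grading.width[a])
            for a in range(3))
    xc, yc, zc = (0.5 * (f[1:] + f[:-1]) for f in faces)

    (tx0, tx1), (ty0, ty1), (tz0, tz1) = scene.table_box
    solid = ((xc[:, None, None] >= tx0) & (xc[:, None, None] < tx1)
             & (yc[None, :, None] >= ty0) & (yc[None, :, None] < ty1)
             & (zc[None, None, :] >= tz0) & (zc[None, None, :] < tz1))
    fluid = ~solid

    fx = np.zeros((nx + 1, ny, nz), dtype=np.int8)
    fy = np.zeros((nx, ny + 1, nz), dtype=np.int8)
    fz = np.zeros((nx, ny, nz + 1), dtype=np.int8)

    # room walls
    fx[0, :, :] = Patch.SIDEWALL
    fx[-1, :, :] = Patch.SIDEWALL
    fy[:, 0, :] = Patch.SIDEWALL
    fy[:, -1, :] = Patch.SIDEWALL
    fz[:, :, 0] = Patch.FLOOR
    fz[:, :, -1] = Patch.CEILING

    # ceiling inlet
    inlet = _rect_faces(xc, yc, scene.inlet_rect)
    fz[:, :, -1][inlet] = Patch.INLET
    if not inlet.any():
        raise MeshError("ceiling inlet patch unresolved at this resolution")

    # outlets on the two y walls
    out = _rect_faces(xc, zc, scene.outlet_rect)
    for face in (fy[:, 0, :], fy[:, -1, :]):
        face[out] = Patch.OUTLET
    if not out.any():
        raise MeshError("wall outlet patch unresolved at this resolution")

    # table: label fluid-solid interface faces
    if not solid.any():
        raise MeshError("operating table unresolved at this resolution")
    sf = solid.astype(np.int8)
    fx[1:-1][(sf[1:] + sf[:-1]) == 1] = Patch.TABLE
    fy[:, 1:-1][(sf[:, 1:] + sf[:, :-1]) == 1] = Patch.TABLE
    fz[:, :, 1:-1][(sf[:, :, 1:] + sf[:, :, :-1]) == 1] = Patch.TABLE

    mesh = Mesh(scene=scene, n=(nx, ny, nz), faces=faces, fluid=fluid,
                fx=fx, fy=fy, fz=fz)

    # incision cell must be fluid
    ic = locate_cell(mesh, scene.incision_point)
    if not fluid[ic]:
        raise MeshError("incision point falls inside a solid cell")
    return mesh


def locate_cell(mesh: Mesh, point) -> tuple[int, int, int]:
    """Index of the cell containing ``point`` (half-open cells [lo, hi))."""
    idx = []
    for a in range(3):
        x = float(point[a])
        extent = mesh.scene.room[a]
        if x < 0 or x >= extent:
            raise ValueError(f"point {tuple(point)} outside room along axis {a}")
        i = int(np.searchsorted(mesh.faces[a], x, side="right")) - 1
        idx.append(min(max(i, 0), mesh.n[a] - 1))
    return tuple(idx)
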
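"""Exposure metrics: smoke ascent height, flow zones, profiles, thresholds.

The headline quantity is H_smoke, the maximum ascent height of the smoke
plume directly above the incision, defined as the height where the
time-averaged vertical velocity changes sign from upward to downward — the
level where the buoyant plume is turned back by the ceiling downflow.
Across the four canonical knife settings the relation between H_smoke and
tip temperature is well described by the quadratic

    H_smoke(T) = 1.14 - 6.37e-4 T + 2.45e-6 T^2   [m, T in degC]

(the published coefficients with their typeset-lost decimal exponents
restored; as printed, without the exponents, the curve would give ~1e5 m
at 200 degC, while the restored form reproduces the reported 1.1 m and
1.45 m endpoints at 200 and 500 degC).

Exposure thresholds carried by the report: EPA 8-hour CO limit 9 ppm plus
the 50 and 200 ppm levels discussed for the surgeon's operating zone, and
20 g/m^3 (tar) / 12 g/m^3 (particles) for the open wound.  The two
published CO statements (">50 ppm" in the discussion, ">200 ppm" in the
abstract) are mutually inconsistent, so the report carries a flag for each
and takes no side; absolute CO values also depend on the assumed waste-gas
composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from numpy.polynomial import polynomial as npoly

from .scene import Mesh, locate_cell
from .solver import FieldState

__all__ = [
    "HsmokeResult", "HsmokeFit", "ExposureReport", "ZONE_LABELS",
    "PUBLISHED_HSMOKE_COEFFS", "published_h_smoke", "compute_H_smoke",
    "classify_zones", "extract_profile", "co_ppm", "fit_H_smoke_curve",
    "build_report",
]

#: Exponent-restored quadratic coefficients of the published
#: H_smoke(T_tip) fit (ascending order; T in degC, H in m).
PUBLISHED_HSMOKE_COEFFS = (1.14, -6.37e-4, 2.45e-6)

M_AIR = 28.96   # g/mol, dilute-smoke mixture molar mass
M_CO = 28.01

ZONE_LABELS = {
    0: "other",
    1: "upwelling-above-incision",
    2: "laminar-downflow-above-table",
    4: "horizontal-toward-outlets",
    5: "downward-slow-peripheral",
    6: "horizontal-toward-blank-walls",
    7: "wall-natural-convection-up",
}


@dataclass
class HsmokeResult:
    height: float                  # m above floor
    status: str                    # ok | ceiling | undefined

    def __float__(self):
        return self.height


@dataclass
class HsmokeFit:
    coeffs: tuple[float, float, float]
    residuals: list[float]

    def __call__(self, tip_temp):
        return npoly.polyval(np.asarray(tip_temp, dtype=float), self.coeffs)


def published_h_smoke(tip_temp) -> float | np.ndarray:
    """Evaluate the published H_smoke(T_tip) quadratic (m)."""
    out = npoly.polyval(np.asarray(tip_temp, dtype=float), PUBLISHED_HSMOKE_COEFFS)
    return float(out) if np.isscalar(tip_temp) else out


def compute_H_smoke(state: FieldState, mesh: Mesh | None = None,
                    incision_point=None) -> HsmokeResult:
    """Smoke ascent height on the vertical line through the incision.

    Finds the lowest positive-to-negative sign change of vertical velocity
    at the cell centres above the incision and interpolates the zero
    linearly.  If the column is upward all the way to the ceiling the room
    height is returned with status ``"ceiling"``; if it is never upward the
    result is flagged ``"undefined"``.
    """
    mesh = mesh or state.mesh
    incision_point = incision_point or mesh.scene.incision_point
    i, j, k0 = locate_cell(mesh, incision_point)
    zc = mesh.centers(2)
    wcol = state.w[i, j, :]
    above = np.arange(k0, mesh.nz)
    pos = wcol[above] > 0
    if not pos.any():
        return HsmokeResult(height=float("nan"), status="undefined")
    # first index where an upward cell is followed by a downward one
    for idx in range(len(above) - 1):
        ka, kb = above[idx], above[idx + 1]
        if wcol[ka] > 0 and wcol[kb] <= 0:
            za, zb = zc[ka], zc[kb]
            wa, wb = wcol[ka], wcol[kb]
            z0 = za + wa * (zb - za) / (wa - wb)
            return HsmokeResult(height=float(z0), status="ok")
    return HsmokeResult(height=float(mesh.scene.room[2]), status="ceiling")


def classify_zones(state: FieldState, mesh: Mesh | None = None,
                   w_eps: float = 0.005, upwelling_radius: float = 0.5,
                   wall_layer: float | None = None) -> np.ndarray:
    """Label every fluid cell with one of the seven flow zones.

    Zones (by vertical-velocity sign and position; label 3 is unused and
    ``other`` absorbs anything not matched): upwelling above the incision,
    laminar downflow above the table, horizontal flow toward the outlet
    walls, slow peripheral downflow, horizontal flow toward the outlet-free
    walls, and the natural-convection updraft hugging those walls.  Rule
    thresholds (``w_eps`` m/s, upwelling radius, wall-layer thickness) are
    configurable; a zero-velocity field labels everything ``other``.
    """
    mesh = mesh or state.mesh
    if wall_layer is None:
        wall_layer = 1.5 * mesh.d[0]
    xc, yc, zc = (mesh.centers(a) for a in range(3))
    X = xc[:, None, None] + 0 * state.w
    Y = yc[None, :, None] + 0 * state.w
    Z = zc[None, None, :] + 0 * state.w
    ix, iy, iz = mesh.scene.incision_point
    lx, ly, lz = mesh.scene.room
    (tx0, tx1), (ty0, ty1), (_, tz1) = mesh.scene.table_box

    horiz = np.hypot(state.u, state.v)
    up = state.w > w_eps
    down = state.w < -w_eps
    horiz_dom = (horiz > np.abs(state.w)) & (horiz > w_eps)
    r_inc = np.hypot(X - ix, Y - iy)

    zones = np.zeros(mesh.n, dtype=np.int8)
    near_blank_wall = (X < wall_layer) | (X > lx - wall_layer)
    over_table = (X >= tx0) & (X < tx1) & (Y >= ty0) & (Y < ty1) & (Z > tz1)

    rules = [
        (1, up & (r_inc <= upwelling_radius) & (Z >= iz - mesh.d[2])),
        (7, up & near_blank_wall),
        (2, down & over_table),
        (4, horiz_dom & (np.abs(state.v) >= np.abs(state.u))),
        (6, horiz_dom & (np.abs(state.u) > np.abs(state.v))),
        (5, down),
    ]
    unassigned = mesh.fluid.copy()
    for label, mask in rules:
        take = mask & unassigned
        zones[take] = label
        unassigned &= ~take
    zones[~mesh.fluid] = -1
    return zones


def extract_profile(field3d: np.ndarray, mesh: Mesh, start, end,
                    n_samples: int = 100):
    """Sample a field along a straight segment by trilinear interpolation.

    Returns ``(s, values)`` with ``s`` the arc length (m) from ``start``.
    Raises if either endpoint leaves the room.
    """
    from scipy.interpolate import RegularGridInterpolator

    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    for pt in (start, end):
        for a in range(3):
            if pt[a] < 0 or pt[a] > mesh.scene.room[a]:
                raise ValueError(f"profile endpoint {tuple(pt)} outside room")
    interp = RegularGridInterpolator(
        tuple(mesh.centers(a) for a in range(3)), field3d,
        bounds_error=False, fill_value=None)   # linear extrapolation at edges
    t = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + t[:, None] * (end - start)[None, :]
    return t * np.linalg.norm(end - start), interp(pts)


def co_ppm(y_co, mixture_molar_mass: float = M_AIR,
           co_molar_mass: float = M_CO):
    """Volumetric ppm of CO from its mass fraction: Y * (M_mix/M_CO) * 1e6.

    Uses the dilute-smoke approximation of a fixed (air) mixture molar
    mass."""
    if mixture_molar_mass <= 0 or co_molar_mass <= 0:
        raise ValueError("molar masses must be positive")
    return np.asarray(y_co, dtype=float) * (mixture_molar_mass / co_molar_mass) * 1e6


def fit_H_smoke_curve(points) -> HsmokeFit:
    """Least-squares quadratic of H_smoke (m) against tip temperature (degC).

    ``points`` is a sequence of (T_tip, H_smoke) pairs; at least three
    distinct temperatures are required."""
    pts = [(float(t), float(h)) for t, h in points]
    temps = np.array([t for t, _ in pts])
    hs = np.array([h for _, h in pts])
    if np.unique(temps).size < 3:
        raise ValueError("need >= 3 distinct temperatures for the quadratic fit")
    c = npoly.polyfit(temps, hs, 2)
    resid = hs - npoly.polyval(temps, c)
    return HsmokeFit(coeffs=tuple(float(v) for v in c), residuals=resid.tolist())


# ---------------------------------------------------------------------------
# report assembly

DEFAULT_THRESHOLDS = {
    "co_ppm": (9.0, 50.0, 200.0),
    "tar_g_m3": 20.0,
    "particle_g_m3": 12.0,
}


@dataclass
class ExposureReport:
    """Everything the analysis derives from one converged case."""

    tip_temp: float
    h_smoke: float
    h_smoke_status: str
    patient_profiles: dict          # Z = 1.1 m, along the table centre line
    surgeon_profiles: dict          # Z = 1.5 m, along the table border
    peaks: dict
    surgeon_zone: dict
    wound_zone: dict
    threshold_flags: dict
    zone_volume_fractions: dict
    composition_dependent: bool = True   # CO numbers depend on assumed composition

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(asdict(self), indent=indent, default=_jsonify)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _zone_mask_box(mesh: Mesh, center_xy, half_width: float,
                   z_lo: float, z_hi: float) -> np.ndarray:
    xc, yc, zc = (mesh.centers(a) for a in range(3))
    mx = np.abs(xc - center_xy[0]) <= half_width
    my = np.abs(yc - center_xy[1]) <= half_width
    mz = (zc >= z_lo) & (zc <= z_hi)
    return mx[:, None, None] & my[None, :, None] & mz[None, None, :] & mesh.fluid


def _wound_mask(mesh: Mesh) -> np.ndarray:
    i, j, k = mesh.incision_cell
    m = np.zeros(mesh.n, dtype=bool)
    for di, dj, dk in ((0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0),
                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        ii, jj, kk = i + di, j + dj, k + dk
        if 0 <= ii < mesh.nx and 0 <= jj < mesh.ny and 0 <= kk < mesh.nz:
            m[ii, jj, kk] = True
    return m & mesh.fluid


def _peak(field3d: np.ndarray, mesh: Mesh) -> dict:
    masked = np.where(mesh.fluid, field3d, -np.inf)
    idx = np.unravel_index(int(np.argmax(masked)), mesh.n)
    return {"value": float(field3d[idx]),
            "location": [float(mesh.centers(a)[idx[a]]) for a in range(3)]}


def build_report(state: FieldState, tip_temp: float,
                 thresholds: dict | None = None,
                 surgeon_zone_height: tuple[float, float] = (1.1, 1.45),
                 surgeon_zone_halfwidth: float = 0.5,
                 patient_nose_height: float = 1.1,
                 surgeon_nose_height: float = 1.5,
                 n_samples: int = 80) -> ExposureReport:
    """Assemble the exposure report for one converged case.

    The surgeon operating zone is the box within ``surgeon_zone_halfwidth``
    horizontally of the incision between 1.1 and 1.45 m height (the
    counter-flow region a bowed-over surgeon breathes in); the wound zone
    is the incision cell plus its face neighbours.  All zone statistics
    are means over the zone's cells; threshold flags are strict
    comparisons of those means.
    """
    mesh = state.mesh
    thresholds = thresholds or DEFAULT_THRESHOLDS
    scene = mesh.scene
    ix, iy, _ = scene.incision_point
    (tx0, tx1), (ty0, ty1), _ = scene.table_box

    hres = compute_H_smoke(state, mesh)
    waste_gas = sum(state.species.values()) if state.species else np.zeros(mesh.n)

    # patient line: table centre line at nose height
    p0, p1 = (tx0, iy, patient_nose_height), (tx1 - 1e-9, iy, patient_nose_height)
    patient = {}
    for name, f in (("waste_gas_mass_fraction", waste_gas),
                    ("c_particle_g_m3", state.c_particle),
                    ("c_tar_g_m3", state.c_tar)):
        s, v = extract_profile(f, mesh, p0, p1, n_samples)
        patient[name] = {"position_m": s.tolist(), "value": np.asarray(v).tolist()}

    # surgeon line: rectangular border of the table at nose height
    corners = [(tx0, ty0), (tx1, ty0), (tx1, ty1), (tx0, ty1), (tx0, ty0)]
    surgeon = {}
    for name, f in (("c_particle_g_m3", state.c_particle),
                    ("c_tar_g_m3", state.c_tar)):
        ss, vv, offset = [], [], 0.0
        for (xa, ya), (xb, yb) in zip(corners[:-1], corners[1:]):
            s, v = extract_profile(
                f, mesh, (xa, ya, surgeon_nose_height),
                (xb, yb, surgeon_nose_height), n_samples // 4)
            ss.append(s + offset)
            vv.append(np.asarray(v))
            offset += s[-1]
        surgeon[name] = {"position_m": np.concatenate(ss).tolist(),
                         "value": np.concatenate(vv).tolist()}

    co_field = co_ppm(state.species.get("CO", np.zeros(mesh.n)))
    szone = _zone_mask_box(mesh, (ix, iy), surgeon_zone_halfwidth,
                           surgeon_zone_height[0], surgeon_zone_height[1])
    wzone = _wound_mask(mesh)

    def zone_stats(mask):
        if not mask.any():
            return {k: float("nan") for k in
                    ("co_ppm", "c_tar_g_m3", "c_particle_g_m3", "waste_gas_mass_fraction")}
        return {
            "co_ppm": float(co_field[mask].mean()),
            "c_tar_g_m3": float(state.c_tar[mask].mean()),
            "c_particle_g_m3": float(state.c_particle[mask].mean()),
            "waste_gas_mass_fraction": float(waste_gas[mask].mean()),
        }

    sstats, wstats = zone_stats(szone), zone_stats(wzone)
    co_limits = thresholds["co_ppm"]
    flags = {
        f"surgeon_co_gt_{int(limit)}ppm": bool(sstats["co_ppm"] > limit)
        for limit in co_limits
    }
    flags["wound_tar_gt_threshold"] = bool(wstats["c_tar_g_m3"] > thresholds["tar_g_m3"])
    flags["wound_particle_gt_threshold"] = bool(
        wstats["c_particle_g_m3"] > thresholds["particle_g_m3"])

    zones = classify_zones(state, mesh)
    n_fluid = int(mesh.fluid.sum())
    zone_frac = {ZONE_LABELS[lab]: float((zones == lab).sum() / n_fluid)
                 for lab in ZONE_LABELS}

    return ExposureReport(
        tip_temp=float(tip_temp),
        h_smoke=hres.height, h_smoke_status=hres.status,
        patient_profiles=patient, surgeon_profiles=surgeon,
        peaks={
            "c_tar_g_m3": _peak(state.c_tar, mesh),
            "c_particle_g_m3": _peak(state.c_particle, mesh),
            "co_ppm": _peak(co_field, mesh),
        },
        surgeon_zone=sstats, wound_zone=wstats, threshold_flags=flags,
        zone_volume_fractions=zone_frac)
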
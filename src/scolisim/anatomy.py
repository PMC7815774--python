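"""Parametric synthetic scoliotic spine generation.

A spine is assembled by stacking per-level vertebral templates along a 3D
centerline defined by three per-level angle profiles:

* coronal tilt ``phi`` — per curve, a sine profile over the curve span,
  whose integral is a raised-cosine lateral bump vanishing at the span
  ends (apex = most deviated, quarter points = most tilted);
* axial rotation ``theta`` — a raised-cosine copy of the lateral bump,
  peaking at the apex and tapering to zero at the span ends;
* sagittal tilt ``psi`` — per-segment increments realizing the requested
  T4-T12 kyphosis and L1-L5 lordosis with smooth sinusoidal weighting.

Because the measurement operators are mildly nonlinear in the profile
amplitudes (the projections couple), amplitudes are calibrated by a
fixed-point iteration until measured Cobb, apical rotation, TK and LL all
match the specification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import LEVELS, SpineGeometry, VertebraLandmarks, level_index
from . import metrics

__all__ = [
    "MORPHOMETRY",
    "CurveSpec",
    "SpineSpec",
    "CohortSpec",
    "CohortResult",
    "vertebra_template",
    "generate_spine",
    "generate_cohort",
]

# ---------------------------------------------------------------------------
# Morphometry: per-level vertebral dimensions (mm), single embedded table.
# Columns: endplate half-width, endplate half-depth, body height, disc height
# caudal to the level, pedicle half-separation.  Body half-width and
# half-depth increase monotonically from T1 to L5.
# ---------------------------------------------------------------------------
MORPHOMETRY: dict[str, tuple[float, float, float, float, float]] = {
    "T1": (14.0, 9.0, 16.0, 4.0, 12.0),
    "T2": (14.5, 9.6, 16.5, 4.2, 12.2),
    "T3": (15.0, 10.2, 17.0, 4.4, 12.4),
    "T4": (15.5, 10.8, 17.5, 4.6, 12.6),
    "T5": (16.0, 11.4, 18.0, 4.8, 12.8),
    "T6": (16.5, 12.0, 18.5, 5.0, 13.0),
    "T7": (17.0, 12.6, 19.0, 5.2, 13.2),
    "T8": (17.5, 13.2, 19.5, 5.4, 13.4),
    "T9": (18.0, 13.8, 20.0, 5.6, 13.6),
    "T10": (18.5, 14.4, 20.5, 5.8, 13.8),
    "T11": (19.0, 15.0, 21.0, 6.2, 14.0),
    "T12": (19.5, 15.6, 21.5, 7.0, 14.3),
    "L1": (20.5, 16.0, 23.0, 8.0, 14.8),
    "L2": (21.5, 16.4, 23.5, 9.0, 15.2),
    "L3": (22.5, 16.8, 24.0, 10.0, 15.6),
    "L4": (23.5, 17.2, 23.5, 10.5, 16.0),
    "L5": (24.5, 17.6, 23.0, 10.5, 16.4),
    "S1": (25.5, 18.0, 30.0, 0.0, 16.8),
}

_PED_DORSAL_MARGIN = 5.0  # pedicle center sits this far behind the body wall


def _nominal_spacings() -> np.ndarray:
    """Center-to-center distances (17,) of the unscaled template chain."""
    h = np.array([MORPHOMETRY[lv][2] for lv in LEVELS])
    d = np.array([MORPHOMETRY[lv][3] for lv in LEVELS])
    return 0.5 * h[:-1] + d[:-1] + 0.5 * h[1:]


NOMINAL_LENGTH = float(_nominal_spacings().sum())


def vertebra_template(level: str, scale: float = 1.0) -> VertebraLandmarks:
    """Deterministic anatomical template in the local frame (center at the
    origin, identity orientation), uniformly scaled."""
    if level not in MORPHOMETRY:
        raise ValueError(f"unknown vertebral level {level!r}")
    hw, hd, h, _, ps = (scale * x for x in MORPHOMETRY[level])
    px = -(hd + scale * _PED_DORSAL_MARGIN)
    return VertebraLandmarks(
        level=level,
        center=np.zeros(3),
        rotation=Rotation.identity(),
        ped_left=np.array([px, ps, 0.0]),
        ped_right=np.array([px, -ps, 0.0]),
        ep_sup=np.array([0.0, 0.0, h / 2]),
        ep_inf=np.array([0.0, 0.0, -h / 2]),
        half_width=hw,
        half_depth=hd,
    )


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CurveSpec:
    """One prescribed scoliotic curve."""

    apex: str
    cobb: float  # coronal Cobb magnitude, deg
    convexity: str = "dextro"  # 'levo' or 'dextro'
    rotation: float = 0.0  # apical axial rotation magnitude, deg
    span: int = 8  # segments covered by the curve

    def __post_init__(self) -> None:
        if self.cobb < 0:
            raise ValueError("Cobb must be non-negative")
        if self.rotation < 0:
            raise ValueError("rotation magnitude must be non-negative")
        if self.span < 4:
            raise ValueError("curve span must cover at least 4 levels")
        if self.convexity not in ("levo", "dextro"):
            raise ValueError("convexity must be 'levo' or 'dextro'")

    @property
    def span_indices(self) -> tuple[int, int]:
        a = level_index(self.apex)
        start = a - (self.span - self.span // 2)
        end = a + self.span // 2
        if start < 0 or end > level_index("L5"):
            raise ValueError(f"curve span exceeds T1-L5 for apex {self.apex}")
        return start, end


@dataclass(frozen=True)
class SpineSpec:
    """Full per-subject prescription."""

    curves: tuple[CurveSpec, ...] = ()
    tk: float = 25.9  # T4-T12 kyphosis, deg
    ll: float = 44.1  # L1-L5 lordosis, deg
    length: float = 430.0  # T1-S1 arc length scale, mm
    seed: int = 0

    def validate(self) -> None:
        spans = sorted(c.span_indices for c in self.curves)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError("overlapping curve spans")


@dataclass(frozen=True)
class CohortSpec:
    """Sampling distributions emulating the radiographic cohort.

    Cobb is drawn with one-stratum-per-subject stratified uniform sampling
    (shuffled) so that even small cohorts cover the severity range.
    Apical rotation is drawn conditionally on Cobb (a linear trend plus
    Gaussian scatter, clipped to ``rotation_range``), reflecting the
    well-documented clinical coupling between transverse rotation and
    coronal severity; the other parameters are plain uniform.
    """

    n_subjects: int = 64
    seed: int = 0
    cobb_range: tuple[float, float] = (36.8, 84.6)
    # triangular distributions whose medians match the reported cohort
    # medians (TK 25.9 deg, LL 44.1 deg)
    tk_range: tuple[float, float] = (0.2, 72.5)
    tk_mode: float = 18.5
    ll_range: tuple[float, float] = (3.2, 77.3)
    ll_mode: float = 48.3
    rotation_range: tuple[float, float] = (0.0, 40.0)
    rotation_slope: float = 0.5  # deg rotation per deg Cobb
    rotation_intercept: float = -14.0
    rotation_sd: float = 7.0
    apex_levels: tuple[str, ...] = tuple(LEVELS[level_index("T5") : level_index("L2") + 1])
    span_range: tuple[int, int] = (8, 12)
    length_range: tuple[float, float] = (400.0, 460.0)
    p_dextro: float = 0.6
    p_secondary: float = 0.5
    secondary_cobb_range: tuple[float, float] = (15.0, 45.0)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort needs at least one subject")


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _rot_xyz(phi: float, psi: float, theta: float) -> Rotation:
    """Vertebra orientation from coronal tilt phi, sagittal tilt psi and
    axial rotation theta (radians).  The composition is chosen so that the
    coronal endplate tilt equals phi exactly."""
    return (
        Rotation.from_euler("x", -phi)
        * Rotation.from_euler("y", psi)
        * Rotation.from_euler("z", theta)
    )


def assemble_spine(
    rotations: list[Rotation],
    spacings: np.ndarray,
    dims: list[tuple[float, float, float, float, float]] | None = None,
    scale: float = 1.0,
    s1_center: np.ndarray | None = None,
) -> SpineGeometry:
    """Stack vertebrae with the given orientations along the centerline.

    Walking caudally to cranially, each center-to-center step has length
    ``spacings[i]`` and direction bisecting the two adjacent local cranial
    axes.  S1 is anchored at ``s1_center`` (default origin).
    """
    n = len(LEVELS)
    if len(rotations) != n or len(spacings) != n - 1:
        raise ValueError("need 18 rotations and 17 spacings")
    zhat = np.array([[0.0, 0.0, 1.0]])
    axes = np.array([r.apply(zhat)[0] for r in rotations])
    centers = np.zeros((n, 3))
    centers[-1] = np.zeros(3) if s1_center is None else np.asarray(s1_center, float)
    for i in range(n - 2, -1, -1):
        d = axes[i] + axes[i + 1]
        d = d / np.linalg.norm(d)
        centers[i] = centers[i + 1] + spacings[i] * d
    vertebrae = []
    for i, lv in enumerate(LEVELS):
        tpl = vertebra_template(lv, scale) if dims is None else None
        if tpl is None:
            hw, hd, h, _, ps = dims[i]
            px = -(hd + _PED_DORSAL_MARGIN)
            local = {
                "ped_left": np.array([px, ps, 0.0]),
                "ped_right": np.array([px, -ps, 0.0]),
                "ep_sup": np.array([0.0, 0.0, h / 2]),
                "ep_inf": np.array([0.0, 0.0, -h / 2]),
            }
        else:
            hw, hd = tpl.half_width, tpl.half_depth
            local = {
                "ped_left": tpl.ped_left,
                "ped_right": tpl.ped_right,
                "ep_sup": tpl.ep_sup,
                "ep_inf": tpl.ep_inf,
            }
        R = rotations[i]
        vertebrae.append(
            VertebraLandmarks(
                level=lv,
                center=centers[i],
                rotation=R,
                half_width=hw,
                half_depth=hd,
                **{k: centers[i] + R.apply(v) for k, v in local.items()},
            )
        )
    s1 = vertebrae[-1]
    anchor = s1.center + s1.rotation.apply(np.array([0.0, 0.0, -60.0 * scale]))
    return SpineGeometry(vertebrae, anchor)


def _sagittal_increments(tk_rad: float, ll_rad: float) -> np.ndarray:
    """Per-segment sagittal tilt increments (17,) realizing TK and LL."""
    d = np.zeros(len(LEVELS) - 1)
    t4, t12 = level_index("T4"), level_index("T12")
    l1, l5 = level_index("L1"), level_index("L5")
    w = np.sin(np.pi * (np.arange(t12 - t4) + 0.5) / (t12 - t4))
    d[t4:t12] = -tk_rad * w / w.sum()
    w = np.sin(np.pi * (np.arange(l5 - l1) + 0.5) / (l5 - l1))
    d[l1:l5] = ll_rad * w / w.sum()
    return d


def _psi_from_increments(d: np.ndarray) -> np.ndarray:
    psi = np.concatenate([[0.0], np.cumsum(d)])
    return psi - psi.mean()


def _curve_profiles(spec: SpineSpec, amps: np.ndarray, rots: np.ndarray):
    """Coronal tilt and axial rotation profiles (radians, length 18)."""
    phi = np.zeros(len(LEVELS))
    theta = np.zeros(len(LEVELS))
    for c, A, TH in zip(spec.curves, amps, rots):
        start, end = c.span_indices
        i = np.arange(start, end + 1)
        t = (i - start) / (end - start)
        phi[i] += A * np.sin(2 * np.pi * t)
        theta[i] += TH * 0.5 * (1 - np.cos(2 * np.pi * t))
    return phi, theta


def _measure(geometry: SpineGeometry, spec: SpineSpec):
    """Measured (cobb_c, rot_c) per curve plus TK/LL, all in degrees."""
    tilts = metrics.coronal_tilts(geometry)
    cobbs, rotsm = [], []
    for c in spec.curves:
        start, end = c.span_indices
        seg = tilts[start : end + 1]
        cobbs.append(float(seg.max() - seg.min()))
        rotsm.append(metrics.apical_axial_rotation(geometry, c.apex))
    sag = metrics.measure_sagittal(geometry)
    return np.array(cobbs), np.array(rotsm), sag.tk, sag.ll


def _build(spec: SpineSpec, amps, rots, tk_eff, ll_eff) -> SpineGeometry:
    scale = spec.length / NOMINAL_LENGTH
    spacings = scale * _nominal_spacings()
    psi = _psi_from_increments(_sagittal_increments(np.radians(tk_eff), np.radians(ll_eff)))
    phi, theta = _curve_profiles(spec, amps, rots)
    rotations = [_rot_xyz(phi[i], psi[i], theta[i]) for i in range(len(LEVELS))]
    return assemble_spine(rotations, spacings, scale=scale)


#: positive coronal-tilt amplitude produces a dextro (convex-right) curve
_CONVEXITY_SIGN = {"dextro": 1.0, "levo": -1.0}

CALIBRATION_TOL = 0.1  # deg, internal; spec round-trip tolerance is 1.5 deg
MAX_CALIBRATION_ITER = 50


def generate_spine(spec: SpineSpec) -> SpineGeometry:
    """Generate a spine whose measured Cobb, apical rotation, TK and LL
    match the specification (fixed-point amplitude calibration)."""
    spec.validate()
    signs = np.array([_CONVEXITY_SIGN[c.convexity] for c in spec.curves])
    # axial rotation follows the convexity (vertebral body rotates into the
    # convexity): opposite sign convention to the lateral amplitude
    amps = signs * np.array([np.radians(c.cobb) / 2.0 for c in spec.curves])
    rots = -signs * np.array([np.radians(c.rotation) for c in spec.curves])
    targets_cobb = np.array([c.cobb for c in spec.curves])
    targets_rot = np.array([c.rotation for c in spec.curves])
    tk_eff, ll_eff = spec.tk, spec.ll
    for _ in range(MAX_CALIBRATION_ITER):
        geometry = _build(spec, amps, rots, tk_eff, ll_eff)
        cobbs, rotsm, tk_m, ll_m = _measure(geometry, spec)
        err = 0.0
        if len(spec.curves):
            err = max(
                np.max(np.abs(cobbs - targets_cobb)),
                np.max(np.abs(np.abs(rotsm) - targets_rot)),
            )
        err = max(err, abs(tk_m - spec.tk), abs(ll_m - spec.ll))
        if err <= CALIBRATION_TOL:
            break
        for k in range(len(spec.curves)):
            if targets_cobb[k] > 0:
                amps[k] *= np.clip(targets_cobb[k] / max(cobbs[k], 0.05), 0.2, 5.0)
            if targets_rot[k] > 0:
                rots[k] *= np.clip(targets_rot[k] / max(abs(rotsm[k]), 0.05), 0.2, 5.0)
        # additive updates: the sagittal response is affine in the profile
        # amplitude when large coronal tilts couple into the projection
        tk_eff += float(np.clip(spec.tk - tk_m, -15.0, 15.0))
        ll_eff += float(np.clip(spec.ll - ll_m, -15.0, 15.0))
    else:
        raise RuntimeError("shape calibration did not converge within 50 iterations")
    return geometry


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortResult:
    """Generated geometries plus a manifest of specified and measured
    deformity parameters, one row per subject."""

    subject_ids: list[str]
    geometries: list[SpineGeometry]
    specs: list[SpineSpec]
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.subject_ids)

    def __iter__(self):
        return iter(zip(self.subject_ids, self.geometries))


def _stratified(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    u = rng.uniform(size=n)
    vals = lo + (np.arange(n) + u) / n * (hi - lo)
    return rng.permutation(vals)


def _fit_span(apex_idx: int, span: int) -> int:
    l5 = level_index("L5")
    while span > 4 and (
        apex_idx - (span - span // 2) < 0 or apex_idx + span // 2 > l5
    ):
        span -= 1
    return span


def _draw_spec(cohort: CohortSpec, rng: np.random.Generator, cobb: float, rot: float, seed: int) -> SpineSpec:
    apex = str(rng.choice(list(cohort.apex_levels)))
    apex_idx = level_index(apex)
    span = _fit_span(apex_idx, int(rng.integers(cohort.span_range[0], cohort.span_range[1] + 1)))
    convexity = "dextro" if rng.uniform() < cohort.p_dextro else "levo"
    major = CurveSpec(apex=apex, cobb=cobb, convexity=convexity, rotation=rot, span=span)
    curves = [major]
    start, end = major.span_indices
    if rng.uniform() < cohort.p_secondary and cobb - 5.0 > cohort.secondary_cobb_range[0]:
        cobb2 = float(
            rng.uniform(cohort.secondary_cobb_range[0], min(cohort.secondary_cobb_range[1], cobb - 5.0))
        )
        span2 = int(rng.integers(4, 7))
        other = "levo" if convexity == "dextro" else "dextro"
        l5 = level_index("L5")
        if end + span2 <= l5:  # caudal compensatory curve
            apex2 = end + (span2 - span2 // 2)
            curves.append(
                CurveSpec(LEVELS[apex2], cobb2, other, 0.3 * rot, span2)
            )
        elif start - span2 >= 0:  # cranial (proximal thoracic) curve
            apex2 = start - span2 + (span2 - span2 // 2)
            curves.append(
                CurveSpec(LEVELS[apex2], cobb2, other, 0.3 * rot, span2)
            )
    return SpineSpec(
        curves=tuple(curves),
        tk=float(rng.triangular(cohort.tk_range[0], cohort.tk_mode, cohort.tk_range[1])),
        ll=float(rng.triangular(cohort.ll_range[0], cohort.ll_mode, cohort.ll_range[1])),
        length=float(rng.uniform(*cohort.length_range)),
        seed=seed,
    )


def generate_cohort(cohort: CohortSpec) -> CohortResult:
    """Generate a synthetic cohort and its manifest."""
    master = np.random.default_rng(cohort.seed)
    n = cohort.n_subjects
    cobbs = _stratified(master, *cohort.cobb_range, n)
    rotsv = np.clip(
        cohort.rotation_slope * cobbs
        + cohort.rotation_intercept
        + master.normal(0.0, cohort.rotation_sd, n),
        *cohort.rotation_range,
    )
    sub_seeds = master.integers(0, 2**31 - 1, size=n)
    ids, geoms, specs, rows = [], [], [], []
    for i in range(n):
        sid = f"S{i:03d}"
        rng = np.random.default_rng(int(sub_seeds[i]))
        try:
            spec = _draw_spec(cohort, rng, float(cobbs[i]), float(rotsv[i]), int(sub_seeds[i]))
            geom = generate_spine(spec)
            curves = metrics.detect_curves(geom, threshold_deg=10.0)
            major_m = max(curves, key=lambda c: c.cobb)
            lenke = metrics.classify_lenke(curves, metrics.measure_sagittal(geom))
        except Exception as exc:
            raise RuntimeError(f"subject {i} ({sid}): {exc}") from exc
        sag = metrics.measure_sagittal(geom)
        major = spec.curves[0]
        rows.append(
            {
                "subject_id": sid,
                "seed": int(sub_seeds[i]),
                "spec_cobb": major.cobb,
                "spec_rotation": major.rotation,
                "spec_tk": spec.tk,
                "spec_ll": spec.ll,
                "spec_apex": major.apex,
                "convexity": major.convexity,
                "span": major.span,
                "n_curves": len(spec.curves),
                "meas_cobb": major_m.cobb,
                "meas_rotation": abs(major_m.apical_rotation),
                "meas_tk": sag.tk,
                "meas_ll": sag.ll,
                "meas_apex": major_m.apex,
                "lenke": lenke,
            }
        )
        ids.append(sid)
        geoms.append(geom)
        specs.append(spec)
    return CohortResult(ids, geoms, specs, pd.DataFrame(rows))
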
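"""Deformity measurements on a :class:`~scolisim.geometry.SpineGeometry`.

Cobb angles are measured radiographically: the endplate line of a vertebra
in a planar projection is the edge of the (planar) endplate, i.e. the
in-plane direction perpendicular to the projected endplate normal.  Because
vertebrae are rigid, superior and inferior endplates share one normal, so a
vertebra has a single tilt angle per projection.  Projected endplate
normals are kept *directed* (cranially), so Cobb angles above 90 degrees
remain distinguishable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import LEVELS, SpineGeometry, level_index

logger = logging.getLogger(__name__)

#: Structurality threshold (deg) used in place of side-bending criteria.
STRUCTURAL_COBB = 25.0

# Region boundaries for the simplified curve typing (by apex level index):
# proximal thoracic T1-T5, main thoracic T6-T11, thoracolumbar/lumbar T12-L5.
_PT_MAX = level_index("T5")
_MT_MAX = level_index("T11")


@dataclass(frozen=True)
class CurveDescriptor:
    """One scoliotic curve: end vertebrae, apex, Cobb angle, convexity."""

    upper_end: str
    lower_end: str
    apex: str
    cobb: float
    convexity: str  # 'levo' (convex left) or 'dextro' (convex right)
    apical_rotation: float

    def __post_init__(self) -> None:
        if not (
            level_index(self.upper_end) < level_index(self.apex) < level_index(self.lower_end)
        ):
            raise ValueError("curve requires upper end < apex < lower end")
        if self.cobb < 0:
            raise ValueError("Cobb angle must be non-negative")


@dataclass(frozen=True)
class SagittalProfile:
    """Signed sagittal angles: positive = kyphotic TK / lordotic LL."""

    tk: float  # T4-T12 thoracic kyphosis, deg
    ll: float  # L1-L5 lumbar lordosis, deg


def _endplate_normals(geometry: SpineGeometry) -> np.ndarray:
    """(18, 3) cranial endplate normals (local z in global coordinates);
    cached on the geometry object (geometries are never mutated in place)."""
    cached = getattr(geometry, "_normals_cache", None)
    if cached is None:
        cached = np.array([v.rotation.as_matrix()[:, 2] for v in geometry.vertebrae])
        geometry._normals_cache = cached
    return cached


def coronal_tilts(geometry: SpineGeometry) -> np.ndarray:
    """Per-vertebra endplate tilt (deg) in the coronal (YZ) projection."""
    n = _endplate_normals(geometry)
    if np.any(np.hypot(n[:, 1], n[:, 2]) < 1e-12):
        raise ValueError("degenerate coronal projection of an endplate")
    return np.degrees(np.arctan2(n[:, 1], n[:, 2]))


def sagittal_tilts(geometry: SpineGeometry) -> np.ndarray:
    """Per-vertebra endplate tilt (deg) in the sagittal (XZ) projection."""
    n = _endplate_normals(geometry)
    if np.any(np.hypot(n[:, 0], n[:, 2]) < 1e-12):
        raise ValueError("degenerate sagittal projection of an endplate")
    return np.degrees(np.arctan2(n[:, 0], n[:, 2]))


def _angle_between(tilt_a: float, tilt_b: float) -> float:
    d = abs(tilt_a - tilt_b) % 360.0
    return 360.0 - d if d > 180.0 else d


def measure_cobb(geometry: SpineGeometry, upper: str, lower: str) -> float:
    """Coronal Cobb angle (deg) between the superior endplate line of
    ``upper`` and the inferior endplate line of ``lower``."""
    iu, il = level_index(upper), level_index(lower)
    if iu >= il:
        raise ValueError("upper vertebra must be strictly cranial to lower")
    tilts = coronal_tilts(geometry)
    return _angle_between(tilts[iu], tilts[il])


def measure_sagittal(geometry: SpineGeometry) -> SagittalProfile:
    """T4-T12 kyphosis and L1-L5 lordosis from the sagittal projection."""
    beta = sagittal_tilts(geometry)
    tk = beta[level_index("T4")] - beta[level_index("T12")]
    ll = beta[level_index("L5")] - beta[level_index("L1")]
    return SagittalProfile(tk=float(tk), ll=float(ll))


def apical_axial_rotation(geometry: SpineGeometry, vertebra: str) -> float:
    """Signed transverse-plane rotation (deg) of the vertebra's left-right
    axis about the global cranial axis; positive follows the right-hand
    rule about +Z."""
    i = level_index(vertebra)
    if LEVELS[i] == "S1":
        raise ValueError("axial rotation defined for T1-L5")
    y = geometry.vertebrae[i].rotation.as_matrix()[:, 1]
    if np.hypot(y[0], y[1]) < 1e-12:
        return 0.0
    return float(np.degrees(np.arctan2(-y[0], y[1])))


def _lateral_deviation(geometry: SpineGeometry) -> np.ndarray:
    """Lateral (y) offset of each body center from the T1-S1 chord in the
    coronal projection; positive = left."""
    c = geometry.centers
    y, z = c[:, 1], c[:, 2]
    denom = z[-1] - z[0]
    if abs(denom) < 1e-9:
        raise ValueError("degenerate spine: no craniocaudal extent")
    return y - (y[0] + (y[-1] - y[0]) * (z - z[0]) / denom)


def _apex_candidates(dev: np.ndarray, min_dev: float = 0.5) -> list[int]:
    """Local extrema of lateral deviation, pruned to alternating sign."""
    cand = [
        i
        for i in range(1, len(dev) - 1)
        if abs(dev[i]) > min_dev
        and (dev[i] - dev[i - 1]) * (dev[i + 1] - dev[i]) <= 0.0
        and abs(dev[i]) >= max(abs(dev[i - 1]), abs(dev[i + 1])) - 1e-12
    ]
    pruned: list[int] = []
    for i in cand:
        if pruned and np.sign(dev[i]) == np.sign(dev[pruned[-1]]):
            if abs(dev[i]) > abs(dev[pruned[-1]]):
                pruned[-1] = i
        else:
            pruned.append(i)
    return pruned


def detect_curves(geometry: SpineGeometry, threshold_deg: float = 10.0) -> list[CurveDescriptor]:
    """Detect scoliotic curves with Cobb angle >= ``threshold_deg``.

    Apexes are the most laterally deviated vertebrae (alternating sides);
    each curve's end vertebrae are the maximally tilted vertebrae between
    the apex and its neighbouring apexes (or the spine ends), ties broken
    toward the apex.
    """
    if threshold_deg < 0:
        raise ValueError("threshold must be non-negative")
    dev = _lateral_deviation(geometry)
    tilts = coronal_tilts(geometry)
    apexes = _apex_candidates(dev)
    curves: list[CurveDescriptor] = []
    for k, apex in enumerate(apexes):
        lo_bound = apexes[k - 1] + 1 if k > 0 else 0
        hi_bound = apexes[k + 1] - 1 if k + 1 < len(apexes) else len(LEVELS) - 1
        upper_rng = range(lo_bound, apex)
        lower_rng = range(apex + 1, hi_bound + 1)
        if not len(upper_rng) or not len(lower_rng):
            continue
        # maximal |tilt|, ties toward the apex
        upper = max(upper_rng, key=lambda i: (abs(tilts[i]), i))
        lower = max(lower_rng, key=lambda i: (abs(tilts[i]), -i))
        cobb = measure_cobb(geometry, LEVELS[upper], LEVELS[lower])
        if cobb < threshold_deg:
            continue
        curves.append(
            CurveDescriptor(
                upper_end=LEVELS[upper],
                lower_end=LEVELS[lower],
                apex=LEVELS[apex],
                cobb=float(cobb),
                convexity="levo" if dev[apex] > 0 else "dextro",
                apical_rotation=apical_axial_rotation(geometry, LEVELS[apex]),
            )
        )
    return curves


def _region(apex: str) -> str:
    i = level_index(apex)
    if i <= _PT_MAX:
        return "PT"
    if i <= _MT_MAX:
        return "MT"
    return "TLL"


def classify_lenke(curves: list[CurveDescriptor], sagittal: SagittalProfile) -> int:
    """Simplified curve type 1-6 from regional structurality.

    A curve is structural iff its Cobb angle >= 25 deg (the magnitude
    criterion; no side-bending films exist in silico).  Lumbar and sagittal
    modifiers are not computed.
    """
    if not curves:
        raise ValueError("no curves supplied")
    major = max(curves, key=lambda c: c.cobb)
    if major.cobb <= 35.0:
        raise ValueError("no curve above the 35 deg inclusion threshold")
    structural = {r: False for r in ("PT", "MT", "TLL")}
    for c in curves:
        if c.cobb >= STRUCTURAL_COBB:
            structural[_region(c.apex)] = True
    region = _region(major.apex)
    if region == "MT":
        pt, tl = structural["PT"], structural["TLL"]
        return {(False, False): 1, (True, False): 2, (False, True): 3, (True, True): 4}[
            (pt, tl)
        ]
    if region == "TLL":
        return 6 if structural["MT"] else 5
    # proximal-thoracic major curve: atypical; closest standard type
    return 4 if (structural["MT"] and structural["TLL"]) else 2
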
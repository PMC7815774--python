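"""Factorial design of the in-silico trial: target sagittal configurations,
pedicle-screw patterns, UIV/LIV placements, target geometries and ideal rod
contours.

The seven named screw patterns are defined by a small rule grammar so that
they can be overridden from a configuration file::

    rule     := part (',' part)*
    part     := side ':' selector
    side     := 'both' | 'concave' | 'convex' | 'zigzag'
    selector := base ['-apexband(' i '..' j ')']
    base     := 'all' | 'ends' | 'keys' | 'alt' | 'periapical'

``all`` = every level in [UIV, LIV]; ``ends`` = UIV and LIV; ``keys`` =
UIV, apex and LIV; ``alt`` = every other level starting at UIV, always
including LIV; ``periapical`` = apex and its immediate neighbours; the ``zigzag`` side
assigns one screw per selected level, alternating concave/convex starting
on the concave side at the UIV; ``-apexband(i..j)`` removes levels whose |offset from the
apex| lies in [i, j].  UIV and LIV are always instrumented bilaterally,
whatever the rule says.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import LEVELS, SpineGeometry, VertebraLandmarks, level_index
from .anatomy import assemble_spine
from .metrics import CurveDescriptor
from . import metrics

__all__ = [
    "TargetConfiguration",
    "SCREW_PATTERNS",
    "DEFAULT_PATTERN_TABLE",
    "ScrewPlacement",
    "InstrumentationPlan",
    "enumerate_targets",
    "build_target_geometry",
    "screw_placements",
    "enumerate_plans",
    "rod_contour",
]


@dataclass(frozen=True)
class TargetConfiguration:
    """Prescribed sagittal change: increases of TK and LL (deg)."""

    d_tk: float = 0.0
    d_ll: float = 0.0


TARGET_STEPS = (0.0, 10.0, 20.0, 30.0)


def enumerate_targets(steps=TARGET_STEPS) -> list[TargetConfiguration]:
    """Full grid of sagittal targets, the (0, 0) baseline included."""
    return [TargetConfiguration(d_tk, d_ll) for d_tk, d_ll in itertools.product(steps, steps)]


SCREW_PATTERNS = (
    "segmental",
    "convex_minimal",
    "apical_key_vertebrae",
    "alternate",
    "convex_alternate",
    "periapical_dropout",
    "convex_periapical_dropout",
)

DEFAULT_PATTERN_TABLE: dict[str, str] = {
    "segmental": "both:all",
    "convex_minimal": "concave:all,convex:ends",
    "apical_key_vertebrae": "both:keys",
    "alternate": "zigzag:all",
    "convex_alternate": "concave:all,convex:alt",
    "periapical_dropout": "concave:all,convex:all-apexband(0..3)",
    "convex_periapical_dropout": "concave:all,convex:alt-apexband(0..3)",
}


@dataclass(frozen=True)
class ScrewPlacement:
    level: str
    side: str  # 'left' or 'right'
    concave: bool  # placed on the concave side of the major curve


_RULE_RE = re.compile(r"^(all|ends|keys|alt|periapical)(?:-apexband\((\d+)\.\.(\d+)\))?$")


def _selector_levels(base: str, band, uiv: int, liv: int, apex: int) -> set[int]:
    if base == "all":
        idx = set(range(uiv, liv + 1))
    elif base == "ends":
        idx = {uiv, liv}
    elif base == "keys":
        idx = {uiv, apex, liv}
    elif base == "alt":
        idx = set(range(uiv, liv + 1, 2)) | {liv}
    elif base == "periapical":
        idx = {apex - 1, apex, apex + 1}
    else:  # pragma: no cover - guarded by the regex
        raise ValueError(base)
    if band is not None:
        i, j = band
        idx -= {k for k in idx if i <= abs(k - apex) <= j}
    return idx


def _parse_rule(rule: str, uiv: int, liv: int, apex: int) -> dict[str, set[int]]:
    out: dict[str, set[int]] = {"concave": set(), "convex": set()}
    for part in rule.split(","):
        try:
            side, sel = part.strip().split(":")
        except ValueError:
            raise ValueError(f"malformed pattern rule part {part!r}") from None
        m = _RULE_RE.match(sel)
        if side not in ("both", "concave", "convex", "zigzag") or not m:
            raise ValueError(f"malformed pattern rule part {part!r}")
        band = (int(m.group(2)), int(m.group(3))) if m.group(2) else None
        levels = _selector_levels(m.group(1), band, uiv, liv, apex)
        if side == "zigzag":
            for k in levels:
                out["concave" if (k - uiv) % 2 == 0 else "convex"].add(k)
        else:
            for s in ("concave", "convex") if side == "both" else (side,):
                out[s] |= levels
    # UIV and LIV are anchored bilaterally in every pattern
    out["concave"] |= {uiv, liv}
    out["convex"] |= {uiv, liv}
    return out


def screw_placements(
    pattern: str,
    uiv: str,
    liv: str,
    apex: str,
    convex_side: str,
    pattern_table: dict[str, str] | None = None,
) -> list[ScrewPlacement]:
    """Deterministic per-level, per-side screw map for a named pattern.

    ``convex_side`` is 'left' (levoscoliosis) or 'right' (dextroscoliosis).
    """
    table = dict(DEFAULT_PATTERN_TABLE)
    if pattern_table:
        table.update(pattern_table)
    if pattern not in table:
        raise ValueError(f"unknown screw pattern {pattern!r}")
    iu, il, ia = level_index(uiv), level_index(liv), level_index(apex)
    if not (iu < ia < il):
        raise ValueError("require UIV < apex < LIV")
    if convex_side not in ("left", "right"):
        raise ValueError("convex_side must be 'left' or 'right'")
    concave_side = "right" if convex_side == "left" else "left"
    sides = _parse_rule(table[pattern], iu, il, ia)
    placements = []
    for i in range(iu, il + 1):
        for role, side in (("concave", concave_side), ("convex", convex_side)):
            if i in sides[role]:
                placements.append(
                    ScrewPlacement(level=LEVELS[i], side=side, concave=(role == "concave"))
                )
    return placements


@dataclass(frozen=True)
class InstrumentationPlan:
    """Screw pattern + fixation span + placements + bilateral rod contours.

    Rod contours are polylines in the *target* configuration; they are
    ``None`` until attached with :meth:`with_contours`.
    """

    pattern: str
    uiv: str
    liv: str
    placements: tuple[ScrewPlacement, ...]
    rod_left: np.ndarray | None = None
    rod_right: np.ndarray | None = None

    @property
    def levels(self) -> list[str]:
        return [LEVELS[i] for i in range(level_index(self.uiv), level_index(self.liv) + 1)]

    @property
    def n_levels(self) -> int:
        return level_index(self.liv) - level_index(self.uiv) + 1

    def with_contours(self, target_geometry: SpineGeometry) -> "InstrumentationPlan":
        return replace(
            self,
            rod_left=rod_contour(target_geometry, self.uiv, self.liv, "left"),
            rod_right=rod_contour(target_geometry, self.uiv, self.liv, "right"),
        )


UIV_OFFSETS = (4, 5, 6)
LIV_OFFSETS = (4, 5, 6)


def enumerate_plans(
    geometry: SpineGeometry,
    major: CurveDescriptor,
    pattern_table: dict[str, str] | None = None,
    patterns=SCREW_PATTERNS,
    target_geometry: SpineGeometry | None = None,
) -> list[InstrumentationPlan]:
    """All pattern x UIV x LIV combinations for the major curve, dropping
    combinations whose UIV/LIV fall outside the T1-S1 range.

    If ``target_geometry`` is given, rod contours are attached from it.
    """
    ia = level_index(major.apex)
    convex_side = "left" if major.convexity == "levo" else "right"
    plans: list[InstrumentationPlan] = []
    for pattern in patterns:
        for du in UIV_OFFSETS:
            iu = ia - du
            if iu < 0:
                continue
            for dl in LIV_OFFSETS:
                il = ia + dl
                if il > level_index("S1"):
                    continue
                placements = tuple(
                    screw_placements(
                        pattern, LEVELS[iu], LEVELS[il], major.apex, convex_side, pattern_table
                    )
                )
                plan = InstrumentationPlan(pattern, LEVELS[iu], LEVELS[il], placements)
                if target_geometry is not None:
                    plan = plan.with_contours(target_geometry)
                plans.append(plan)
    return plans


def rod_contour(target_geometry: SpineGeometry, uiv: str, liv: str, side: str) -> np.ndarray:
    """Ideal rod polyline through the target-configuration pedicle centers
    of one side, one midpoint node per segment, cranial to caudal."""
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    iu, il = level_index(uiv), level_index(liv)
    if iu >= il:
        raise ValueError("require UIV strictly cranial to LIV")
    attr = "ped_left" if side == "left" else "ped_right"
    pts = np.array([getattr(target_geometry.vertebrae[i], attr) for i in range(iu, il + 1)])
    mids = 0.5 * (pts[:-1] + pts[1:])
    poly = np.empty((2 * len(pts) - 1, 3))
    poly[0::2] = pts
    poly[1::2] = mids
    return poly


def build_target_geometry(
    geometry: SpineGeometry, target: TargetConfiguration
) -> SpineGeometry:
    """Corrected spine: coronal Cobb and axial rotations zeroed, sagittal
    profile changed by (d_tk, d_ll) relative to the pre-operative spine.

    The sagittal increments are distributed over the T4-T12 / L1-L5
    segments proportionally to the baseline per-segment angles (uniformly
    when the baseline region is flat); per-segment arc length is preserved
    and S1 keeps its pre-operative pose.
    """
    beta = np.radians(metrics.sagittal_tilts(geometry))
    centers = geometry.centers
    spacings = np.linalg.norm(np.diff(centers, axis=0), axis=1)
    dseg = np.diff(beta)
    t4, t12 = level_index("T4"), level_index("T12")
    l1, l5 = level_index("L1"), level_index("L5")

    def _distribute(lo: int, hi: int, delta_deg: float, sense: float) -> None:
        # sense: -1 for kyphosis segments (tilt decreases), +1 for lordosis
        if delta_deg == 0.0:
            return
        seg = dseg[lo:hi]
        total = seg.sum()
        if abs(total) > np.radians(1.0):
            w = seg / total
        else:
            w = np.full(hi - lo, 1.0 / (hi - lo))
        dseg[lo:hi] = seg + sense * np.radians(delta_deg) * w

    _distribute(t4, t12, target.d_tk, -1.0)
    _distribute(l1, l5, target.d_ll, +1.0)

    psi = np.empty(len(LEVELS))
    psi[-1] = beta[-1]
    for i in range(len(LEVELS) - 2, -1, -1):
        psi[i] = psi[i + 1] - dseg[i]
    rotations = [Rotation.from_euler("y", p) for p in psi]

    skeleton = assemble_spine(
        rotations, spacings, s1_center=geometry.vertebrae[-1].center
    )
    # re-attach each vertebra's own local landmark offsets exactly
    rebuilt = []
    for v_old, v_new in zip(geometry.vertebrae, skeleton.vertebrae):
        R, c = v_new.rotation, v_new.center
        rebuilt.append(
            VertebraLandmarks(
                level=v_old.level,
                center=c,
                rotation=R,
                ped_left=c + R.apply(v_old.local_offset(v_old.ped_left)),
                ped_right=c + R.apply(v_old.local_offset(v_old.ped_right)),
                ep_sup=c + R.apply(v_old.local_offset(v_old.ep_sup)),
                ep_inf=c + R.apply(v_old.local_offset(v_old.ep_inf)),
                half_width=v_old.half_width,
                half_depth=v_old.half_depth,
            )
        )
    s1 = rebuilt[-1]
    anchor = s1.center + s1.rotation.apply(
        geometry.vertebrae[-1].local_offset(geometry.pelvis_anchor)
    )
    return SpineGeometry(rebuilt, anchor, geometry.frame)
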
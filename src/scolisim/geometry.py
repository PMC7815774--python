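"""Spine geometry containers and the landmark file format.

Global frame convention (right-handed): +X anterior, +Y subject-left,
+Z cranial.  The coronal plane is YZ, the sagittal plane XZ and the
transverse plane XY.  All lengths are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

FRAME_TAG = "X-anterior Y-left Z-cranial (mm)"

#: Vertebral levels in craniocaudal order, T1 first, first sacral last.
LEVELS: tuple[str, ...] = tuple(
    [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)] + ["S1"]
)

_LEVEL_INDEX = {lv: i for i, lv in enumerate(LEVELS)}


def level_index(level: str) -> int:
    """Craniocaudal index of a level label (T1 = 0 ... S1 = 17)."""
    try:
        return _LEVEL_INDEX[level]
    except KeyError:
        raise ValueError(f"unknown vertebral level {level!r}") from None


@dataclass
class VertebraLandmarks:
    """Landmark frame of one vertebra in the global patient frame.

    ``rotation`` maps local vertebra coordinates (x anterior, y left,
    z cranial when the spine is straight) to global coordinates.
    """

    level: str
    center: np.ndarray
    rotation: Rotation
    ped_left: np.ndarray
    ped_right: np.ndarray
    ep_sup: np.ndarray
    ep_inf: np.ndarray
    half_width: float
    half_depth: float

    def local_offset(self, point: np.ndarray) -> np.ndarray:
        """Express a global point in this vertebra's local frame."""
        return self.rotation.inv().apply(point - self.center)

    def validate(self) -> None:
        pl = self.local_offset(self.ped_left)
        pr = self.local_offset(self.ped_right)
        if abs(pl[1] + pr[1]) > 1e-9 or np.max(np.abs(pl[[0, 2]] - pr[[0, 2]])) > 1e-9:
            raise ValueError(f"{self.level}: pedicles not mirror-symmetric")
        if self.local_offset(self.ep_sup)[2] <= self.local_offset(self.ep_inf)[2]:
            raise ValueError(f"{self.level}: superior endplate not cranial")
        if self.half_width <= 0 or self.half_depth <= 0:
            raise ValueError(f"{self.level}: non-positive endplate half-axes")


@dataclass
class SpineGeometry:
    """Ordered landmark frames T1 -> S1 plus a pelvis anchor point."""

    vertebrae: list[VertebraLandmarks]
    pelvis_anchor: np.ndarray
    frame: str = FRAME_TAG

    def __post_init__(self) -> None:
        if len(self.vertebrae) != len(LEVELS):
            raise ValueError(
                f"expected {len(LEVELS)} vertebrae, got {len(self.vertebrae)}"
            )
        for v, lv in zip(self.vertebrae, LEVELS):
            if v.level != lv:
                raise ValueError(f"levels out of order: {v.level} at slot {lv}")

    def __getitem__(self, level: str) -> VertebraLandmarks:
        return self.vertebrae[level_index(level)]

    @property
    def centers(self) -> np.ndarray:
        """(18, 3) array of vertebral body centers, T1 first."""
        return np.array([v.center for v in self.vertebrae])

    def validate(self) -> None:
        for v in self.vertebrae:
            v.validate()
        z = self.centers[:, 2]
        if not np.all(np.diff(z) < 0):
            raise ValueError("body centers not strictly decreasing craniocaudally")


def mirror_geometry(geometry: SpineGeometry) -> SpineGeometry:
    """Coronal mirror image (left-right flip, y -> -y)."""
    flip = np.array([1.0, -1.0, 1.0])
    mirrored = []
    for v in geometry.vertebrae:
        mat = v.rotation.as_matrix()
        mat = flip[:, None] * mat * flip[None, :]  # M R M, still proper
        mirrored.append(
            VertebraLandmarks(
                level=v.level,
                center=v.center * flip,
                rotation=Rotation.from_matrix(mat),
                ped_left=v.ped_right * flip,
                ped_right=v.ped_left * flip,
                ep_sup=v.ep_sup * flip,
                ep_inf=v.ep_inf * flip,
                half_width=v.half_width,
                half_depth=v.half_depth,
            )
        )
    return SpineGeometry(mirrored, geometry.pelvis_anchor * flip, geometry.frame)


# ---------------------------------------------------------------------------
# Landmark file format
#
# Tab-delimited, one row per landmark:
#   subject_id  level  name  c1  c2  c3  c4
# Point rows (center, ped_left, ped_right, ep_sup, ep_inf) carry x, y, z in
# c1..c3 (c4 empty); 'orientation' rows carry the quaternion x, y, z, w;
# 'dims' rows carry half_width, half_depth; the single 'pelvis_anchor' row
# (level '-') carries the anchor point.  Floats are written with repr so the
# file round-trips bit-exactly.
# ---------------------------------------------------------------------------

_POINT_NAMES = ("center", "ped_left", "ped_right", "ep_sup", "ep_inf")
_HEADER = "subject_id\tlevel\tname\tc1\tc2\tc3\tc4"


def _fmt(values) -> str:
    return "\t".join(repr(float(x)) for x in values)


def _canonical_quat(rotation: Rotation) -> np.ndarray:
    # Fixed point of from_quat/as_quat so a written file re-reads and
    # re-writes to identical bytes despite renormalization on input.
    q = rotation.as_quat()
    for _ in range(5):
        q2 = Rotation.from_quat(q).as_quat()
        if np.array_equal(q2, q):
            break
        q = q2
    return q


def write_landmarks(path, geometries: dict[str, SpineGeometry]) -> None:
    """Write one or more subjects' landmark frames to a delimited file."""
    lines = [_HEADER]
    for sid, geom in geometries.items():
        for v in geom.vertebrae:
            for name in _POINT_NAMES:
                p = getattr(v, name if name != "center" else "center")
                lines.append(f"{sid}\t{v.level}\t{name}\t{_fmt(p)}\t")
            q = _canonical_quat(v.rotation)  # x, y, z, w
            lines.append(f"{sid}\t{v.level}\torientation\t{_fmt(q)}")
            lines.append(
                f"{sid}\t{v.level}\tdims\t{repr(float(v.half_width))}\t"
                f"{repr(float(v.half_depth))}\t\t"
            )
        lines.append(f"{sid}\t-\tpelvis_anchor\t{_fmt(geom.pelvis_anchor)}\t")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_landmarks(path) -> dict[str, SpineGeometry]:
    """Read a landmark file written by :func:`write_landmarks`."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _HEADER:
            raise ValueError(f"unexpected landmark header: {header!r}")
        raw: dict[str, dict[str, dict[str, list[float]]]] = {}
        anchors: dict[str, np.ndarray] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            sid, level, name = parts[:3]
            vals = [float(x) for x in parts[3:] if x != ""]
            if name == "pelvis_anchor":
                anchors[sid] = np.array(vals[:3])
                continue
            raw.setdefault(sid, {}).setdefault(level, {})[name] = vals
    out: dict[str, SpineGeometry] = {}
    for sid, levels in raw.items():
        vertebrae = []
        for lv in LEVELS:
            if lv not in levels:
                raise ValueError(f"subject {sid}: missing level {lv}")
            rec = levels[lv]
            try:
                vertebrae.append(
                    VertebraLandmarks(
                        level=lv,
                        center=np.array(rec["center"]),
                        rotation=Rotation.from_quat(rec["orientation"]),
                        ped_left=np.array(rec["ped_left"]),
                        ped_right=np.array(rec["ped_right"]),
                        ep_sup=np.array(rec["ep_sup"]),
                        ep_inf=np.array(rec["ep_inf"]),
                        half_width=rec["dims"][0],
                        half_depth=rec["dims"][1],
                    )
                )
            except KeyError as exc:
                raise ValueError(f"subject {sid} level {lv}: missing {exc}") from None
        if sid not in anchors:
            raise ValueError(f"subject {sid}: missing pelvis_anchor row")
        out[sid] = SpineGeometry(vertebrae, anchors[sid])
    return out
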
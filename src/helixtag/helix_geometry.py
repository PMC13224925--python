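"""Terminal-helix geometry.

The screen keys on four measurements per chain: where the first and last
helices sit relative to the termini, the axis of each helix, the
direction-aware angle between the two axes, and the Calpha separation of
the chain-terminal helix ends. A continuous score in [0, 1] ranks chains
against the design target — terminal helices close to antiparallel
(N-to-C axis angle near 180 degrees) with an end-to-end separation near
10 Angstrom, the geometry that lets a tag bridge the cytoplasmic ends of
TM5 and TM6.

When a file carries no secondary-structure annotation, helices are
assigned from Calpha distance geometry alone: residue i is helical iff
the Calpha(i)-Calpha(i+2), (i+3) and (i+4) distances each fall inside a
window around the ideal alpha-helical value. This is the same style of
distance criterion used by Calpha-only assigners such as P-SEA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateSegmentError, MeasurementError, ValidationError
from .structure_model import Chain, HelixSegment

# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class SseParams:
    """Calpha-distance windows for geometric helix assignment (Angstrom).

    Defaults bracket ideal alpha-helix values: d(i,i+2) = 5.5 +/- 0.6,
    d(i,i+3) = 5.3 +/- 0.6, d(i,i+4) = 6.4 +/- 0.7.
    """

    d13_range: tuple[float, float] = (4.9, 6.1)
    d14_range: tuple[float, float] = (4.7, 5.9)
    d15_range: tuple[float, float] = (5.7, 7.1)
    min_run: int = 4

    def __post_init__(self) -> None:
        for lo, hi in (self.d13_range, self.d14_range, self.d15_range):
            if not lo < hi:
                raise ValidationError("SSE distance window must be non-empty")
        if self.min_run < 4:
            raise ValidationError("min_run must be >= 4")


@dataclass(frozen=True)
class ScoreParams:
    """Geometry-score shape: target separation d0, half-width, angle floor."""

    d0: float = 10.0
    delta_d: float = 8.0
    theta_min: float = 90.0


@dataclass(frozen=True)
class AxisFit:
    """Least-squares helix axis: dominant principal direction of the Calpha
    cloud, oriented N to C."""

    centroid: np.ndarray
    direction: np.ndarray
    rmsd_to_axis: float
    n_atoms: int


@dataclass(frozen=True)
class TerminalHelixGeometry:
    """The N/C terminal-helix pair and its screen-relevant measurements.

    ``separation`` is the Calpha-Calpha distance between the chain-terminal
    ends: first residue of the N-helix to last residue of the C-helix —
    the atoms that would splice onto TM5/TM6. ``angle`` is direction-aware
    (N-to-C axis vectors), so antiparallel means angle near 180.
    """

    n_helix: HelixSegment
    c_helix: HelixSegment
    n_offset: int
    c_offset: int
    separation: float
    angle: float
    n_axis: AxisFit | None = None
    c_axis: AxisFit | None = None


#: machine-readable reasons why a chain has no usable terminal-helix pair
REASON_SINGLE_HELIX = "single_helix"
REASON_TOO_SHORT_N = "too_short_N"
REASON_TOO_SHORT_C = "too_short_C"
REASON_OFFSET_N = "offset_N"
REASON_OFFSET_C = "offset_C"


@dataclass(frozen=True)
class TerminalHelixResult:
    """Outcome of the terminal-helix gate: geometry, or reasons it failed."""

    geometry: TerminalHelixGeometry | None
    reasons: tuple[str, ...] = ()

    @property
    def reason(self) -> str | None:
        return self.reasons[0] if self.reasons else None


# ---------------------------------------------------------------------------
# secondary-structure assignment


def helical_mask(c: Chain, p: SseParams = SseParams()) -> list[bool]:
    """Per-residue helicity by the three-distance rule.

    Position i is helical iff residues i, i+2, i+3, i+4 all have a Calpha
    and the three distances fall in their windows; positions whose window
    runs off the chain end are non-helical by construction.
    """
    coords = c.ca_coords()
    n = len(coords)
    mask = [False] * n
    for i in range(n - 4):
        quad = (coords[i], coords[i + 2], coords[i + 3], coords[i + 4])
        if any(q is None for q in quad):
            continue
        a = quad[0]
        d13 = float(np.linalg.norm(quad[1] - a))
        d14 = float(np.linalg.norm(quad[2] - a))
        d15 = float(np.linalg.norm(quad[3] - a))
        if (p.d13_range[0] <= d13 <= p.d13_range[1]
                and p.d14_range[0] <= d14 <= p.d14_range[1]
                and p.d15_range[0] <= d15 <= p.d15_range[1]):
            mask[i] = True
    return mask


def assign_helices_geometric(c: Chain, p: SseParams = SseParams()) -> list[HelixSegment]:
    """Maximal helical runs of at least ``min_run`` residues, as segments."""
    if len(c.residues) < 5:
        return []
    mask = helical_mask(c, p)
    segments: list[HelixSegment] = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if j - i + 1 >= p.min_run:
                segments.append(HelixSegment(
                    c.chain_id,
                    c.residues[i].auth_num,
                    c.residues[j].auth_num,
                    j - i + 1,
                ))
            i = j + 1
        else:
            i += 1
    return segments


# ---------------------------------------------------------------------------
# axis fitting and measurements


def _segment_ca(c: Chain, seg: HelixSegment) -> np.ndarray:
    i0 = c.index_of_auth(seg.start_auth)
    i1 = c.index_of_auth(seg.end_auth)
    if i0 is None or i1 is None:
        raise MeasurementError(
            f"segment {seg.start_auth}-{seg.end_auth} not in chain {c.chain_id}"
        )
    pts = [r.ca.xyz for r in c.residues[i0:i1 + 1] if r.ca is not None]
    return np.asarray(pts, dtype=float)


def fit_helix_axis(c: Chain, seg: HelixSegment) -> AxisFit:
    """Fit a straight axis to a helix segment's Calpha atoms.

    The Calpha second-difference (curvature) vectors of a helix point
    radially inward, exactly perpendicular to the axis, so the axis is
    the least-variance direction of those vectors (smallest principal
    direction of the curvature cloud). This recovers the true axis of an
    ideal helix to machine precision at any length, where a plain
    principal-component fit of the Calpha cloud carries an O(1/n) tilt
    from the axial-radial cross-covariance of an incomplete final turn.
    Near-collinear segments (negligible curvature) fall back to the
    dominant principal direction of the points themselves. The direction
    is sign-fixed N to C; fit quality is the RMS perpendicular distance
    of the Calpha atoms to the axis line — about 2.3 Angstrom for an
    ideal alpha-helix, its Calpha radius.
    """
    pts = _segment_ca(c, seg)
    if len(pts) < 4:
        raise DegenerateSegmentError(
            f"segment {seg.start_auth}-{seg.end_auth} has {len(pts)} Calpha "
            "atoms; need >= 4 for an axis fit"
        )
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    curvature = np.diff(pts, n=2, axis=0)
    if np.sqrt((curvature ** 2).sum(axis=1)).mean() > 1e-6:
        # axis direction d minimizes sum of (c_i . d)^2 over curvature vectors
        _, _, vt = np.linalg.svd(curvature, full_matrices=True)
        direction = vt[-1]
    else:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        direction = vt[0]
    if float(direction @ (pts[-1] - pts[0])) < 0:
        direction = -direction
    perp = centered - np.outer(centered @ direction, direction)
    rmsd = float(np.sqrt((perp ** 2).sum(axis=1).mean()))
    return AxisFit(centroid=centroid, direction=direction, rmsd_to_axis=rmsd,
                   n_atoms=len(pts))


def inter_helix_angle(a: AxisFit, b: AxisFit) -> float:
    """Direction-aware angle between two N-to-C axes, degrees in [0, 180]."""
    cosang = float(np.clip(a.direction @ b.direction, -1.0, 1.0))
    return math.degrees(math.acos(cosang))


def terminal_separation(c: Chain, n_helix: HelixSegment, c_helix: HelixSegment,
                        anchors: str = "terminal") -> float:
    """Calpha-Calpha distance between the two helix anchor residues.

    ``anchors="terminal"`` (default) measures the chain-terminal-most ends:
    first residue of the N-helix to last residue of the C-helix.
    ``anchors="inner"`` measures the loop-facing ends instead.
    """
    if anchors == "terminal":
        a_auth, b_auth = n_helix.start_auth, c_helix.end_auth
    elif anchors == "inner":
        a_auth, b_auth = n_helix.end_auth, c_helix.start_auth
    else:
        raise ValidationError(f"unknown anchor mode {anchors!r}")
    ra = c.residue_by_auth(a_auth)
    rb = c.residue_by_auth(b_auth)
    if ra is None or ra.ca is None:
        raise MeasurementError(f"missing anchor Calpha at residue {a_auth}")
    if rb is None or rb.ca is None:
        raise MeasurementError(f"missing anchor Calpha at residue {b_auth}")
    return float(np.linalg.norm(ra.ca.xyz - rb.ca.xyz))


def measure_terminal_geometry(c: Chain, helices: list[HelixSegment],
                              anchors: str = "terminal") -> TerminalHelixGeometry | None:
    """Raw measurements on the first/last helix pair, without gating.

    Returns None when fewer than two distinct helices exist or either is
    too short for an axis fit. Used by the screen so that every gate can
    be evaluated and reported even when another gate fails.
    """
    if len(helices) < 2:
        return None
    ordered = sorted(helices, key=lambda h: h.start_auth)
    n_h, c_h = ordered[0], ordered[-1]
    try:
        n_axis = fit_helix_axis(c, n_h)
        c_axis = fit_helix_axis(c, c_h)
    except DegenerateSegmentError:
        return None
    i_start = c.index_of_auth(n_h.start_auth)
    i_end = c.index_of_auth(c_h.end_auth)
    if i_start is None or i_end is None:
        return None
    return TerminalHelixGeometry(
        n_helix=n_h,
        c_helix=c_h,
        n_offset=i_start,
        c_offset=len(c.residues) - 1 - i_end,
        separation=terminal_separation(c, n_h, c_h, anchors=anchors),
        angle=inter_helix_angle(n_axis, c_axis),
        n_axis=n_axis,
        c_axis=c_axis,
    )


def terminal_helices(c: Chain, helices: list[HelixSegment], min_len: int = 8,
                     max_offset: int = 5, anchors: str = "terminal") -> TerminalHelixResult:
    """Gatekeeper for the terminal-helix pair.

    Geometry is returned iff the chain has two distinct helices, the first
    starts within ``max_offset`` residues of the N-terminus, the last ends
    within ``max_offset`` of the C-terminus, and both span at least
    ``min_len`` residues. Otherwise the result carries machine-readable
    reason codes.
    """
    if len(helices) < 2:
        return TerminalHelixResult(None, (REASON_SINGLE_HELIX,))
    geom = measure_terminal_geometry(c, helices, anchors=anchors)
    if geom is None:
        return TerminalHelixResult(None, (REASON_SINGLE_HELIX,))
    reasons = []
    if geom.n_helix.length < min_len:
        reasons.append(REASON_TOO_SHORT_N)
    if geom.c_helix.length < min_len:
        reasons.append(REASON_TOO_SHORT_C)
    if geom.n_offset > max_offset:
        reasons.append(REASON_OFFSET_N)
    if geom.c_offset > max_offset:
        reasons.append(REASON_OFFSET_C)
    if reasons:
        return TerminalHelixResult(None, tuple(reasons))
    return TerminalHelixResult(geom, ())


# ---------------------------------------------------------------------------
# scoring


def geometry_score(separation: float, angle: float,
                   params: ScoreParams = ScoreParams()) -> float:
    """Continuous rank score in [0, 1] against the design target.

    score = max(0, 1 - |separation - d0| / delta_d)
          * max(0, (angle - theta_min) / (180 - theta_min))

    Equals 1 exactly at (d0, 180 degrees); decreases linearly with distance
    from the target separation and with departure from antiparallel.
    """
    if separation < 0:
        raise ValidationError("separation must be >= 0")
    if not 0.0 <= angle <= 180.0:
        raise ValidationError("angle must be in [0, 180] degrees")
    sep_term = max(0.0, 1.0 - abs(separation - params.d0) / params.delta_d)
    ang_term = max(0.0, (angle - params.theta_min) / (180.0 - params.theta_min))
    return sep_term * ang_term
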
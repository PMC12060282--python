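"""Helix-bundle geometry: axes, Z-shift, orientation topology, overhang.

The Z-shift between two adjacent helices of a coiled-coil barrel is the
distance between the projections of the two helix centroids onto the
superhelical (bundle) axis.  Parallel barrels are close to Cn-symmetric with
Z-shifts near zero; antiparallel barrels slide adjacent helices along the
axis to interdigitate side chains, producing Z-shifts of a few Angstroms.
Because a Z-shift of a whole helical turn (5.4 A) removes substantial
helix-helix contact, large required Z-shifts disfavour the antiparallel
state: above a threshold of about 4 A the parallel arrangement is preferred.

Axes are estimated by principal-direction fits: the dominant singular vector
of the centred Calpha cloud, per chain (sign-fixed N→C) and pooled over the
assembly (sign-fixed to the majority chain direction).  This is robust and
closed-form for near-straight helices of ~20 residues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import AssemblyModel

#: |cos| below which a helix is neither clearly up nor down the bundle axis.
ORIENTATION_TOLERANCE = 0.2

#: Z-shift (A) above which the antiparallel arrangement is disfavoured.
ZSHIFT_THRESHOLD = 4.0


class GeometryError(ValueError):
    """Degenerate or invalid geometry input."""


def _principal_direction(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    # right singular vector of the largest singular value
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _turn_smoothed(coords: np.ndarray, residues_per_turn: float = 3.6) -> np.ndarray:
    """Moving centroids over (approximately) a whole number of helical turns.

    Centroids of whole turns of an ideal helix lie exactly on its axis, so a
    principal-direction fit of the smoothed trace is free of the tilt bias a
    fractional final turn induces on the raw Calpha cloud.  The window is the
    integer best approximating m turns (m up to 7); for 3.6 residues/turn
    that is 18 residues = 5 exact turns.
    """
    n = len(coords)
    best_w, best_err = 0, np.inf
    for m in range(1, 8):
        w = round(m * residues_per_turn)
        if w > n - 1:
            break
        err = abs(w - m * residues_per_turn)
        if err < best_err - 1e-9 or (abs(err - best_err) < 1e-9 and w > best_w):
            best_w, best_err = w, err
    if best_w < 2:
        return coords
    kernel = np.ones(best_w) / best_w
    return np.column_stack(
        [np.convolve(coords[:, k], kernel, mode="valid") for k in range(3)]
    )


def helix_axis(coords: np.ndarray, chain_id: str = "?") -> tuple[np.ndarray, np.ndarray]:
    """Dominant principal direction (sign-fixed N→C) and centroid of a
    Calpha trace."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 8:
        raise GeometryError(
            f"chain {chain_id}: need at least 8 Calpha positions to fit an "
            f"axis, got {len(coords)}"
        )
    direction = _principal_direction(_turn_smoothed(coords))
    if np.dot(direction, coords[-1] - coords[0]) < 0:
        direction = -direction
    return direction, coords.mean(axis=0)


def bundle_axis(model: AssemblyModel) -> tuple[np.ndarray, np.ndarray]:
    """Superhelical axis through the global Calpha centroid.

    The direction is the sign-aligned average of the per-chain helix axes
    (each flipped, if needed, onto the dominant principal direction of the
    pooled cloud so antiparallel chains reinforce rather than cancel), then
    sign-fixed to the majority chain N→C direction.
    """
    if len(model.chains) < 2:
        raise GeometryError("need at least 2 chains for a bundle axis")
    pooled = model.coords
    rough = _principal_direction(pooled)
    dirs = [helix_axis(xyz, cid)[0] for cid, _, xyz in model.chains]
    aligned = sum(d if d @ rough >= 0 else -d for d in dirs)
    norm = np.linalg.norm(aligned)
    if norm < 1e-9:
        raise GeometryError("degenerate bundle: chain axes cancel")
    direction = aligned / norm
    majority = sum(np.sign(d @ direction) for d in dirs)
    if majority < 0:
        direction = -direction
    return direction, pooled.mean(axis=0)


def _ring_order(model: AssemblyModel, axis: np.ndarray, origin: np.ndarray) -> list[int]:
    """Chain indices ordered by azimuth about the bundle axis."""
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    phis = []
    for _, _, xyz in model.chains:
        r = xyz.mean(axis=0) - origin
        phis.append(np.arctan2(np.dot(r, e2), np.dot(r, e1)))
    return list(np.argsort(phis))


@dataclass
class ZShiftProfile:
    """Per-adjacent-pair axial offsets and their aggregate for one assembly.

    ``pair_shifts`` holds ``(chain_i, chain_j, |dz|)`` over ring-adjacent
    pairs; ``aggregate`` is their mean (min/max also reported, since a single
    per-model figure can be summarised either way).
    """

    pair_shifts: list[tuple[str, str, float]]
    aggregate: float
    min_shift: float
    max_shift: float
    axis: np.ndarray
    axis_point: np.ndarray


def z_shift(model: AssemblyModel, adjacency: str | list[tuple[int, int]] = "ring") -> ZShiftProfile:
    """Z-shift profile: |difference of helix-centroid projections onto the
    bundle axis| for each adjacent pair.

    ``adjacency="ring"`` orders chains by azimuth about the axis and pairs
    neighbours around the ring; an explicit list of chain-index pairs may be
    given instead.
    """
    axis, origin = bundle_axis(model)
    centroids = np.array([xyz.mean(axis=0) for _, _, xyz in model.chains])
    radial = centroids - origin
    radial -= np.outer(radial @ axis, axis)
    if np.max(np.linalg.norm(radial, axis=1)) < 1e-6:
        raise GeometryError("degenerate axis: all helix centroids coincide on it")
    proj = (centroids - origin) @ axis
    if adjacency == "ring":
        order = _ring_order(model, axis, origin)
        pairs = [(order[i], order[(i + 1) % len(order)]) for i in range(len(order))]
    else:
        pairs = list(adjacency)
    shifts = [
        (model.chains[i][0], model.chains[j][0], float(abs(proj[i] - proj[j])))
        for i, j in pairs
    ]
    values = [s for _, _, s in shifts]
    return ZShiftProfile(
        pair_shifts=shifts,
        aggregate=float(np.mean(values)),
        min_shift=float(np.min(values)),
        max_shift=float(np.max(values)),
        axis=axis,
        axis_point=origin,
    )


@dataclass(frozen=True)
class TopologyLabel:
    """Orientation topology of an assembly; a pure function of the per-chain
    signs of helix direction against the bundle axis."""

    label: str  # parallel | antiparallel_alternating | mixed
    signs: tuple[int, ...]

    @property
    def simple(self) -> str:
        """Collapse to the two-state vocabulary used in orientation reports."""
        return (
            "antiparallel" if self.label == "antiparallel_alternating" else self.label
        )


def orientation_topology(model: AssemblyModel) -> TopologyLabel:
    """Classify per-chain orientation against the bundle axis.

    All signs equal → parallel; strict sign alternation around the azimuthal
    ring → antiparallel_alternating; anything else → mixed.  A helix nearly
    perpendicular to the axis (|cos| < 0.2) is ambiguous and raises.
    """
    axis, origin = bundle_axis(model)
    signs = []
    for cid, _, xyz in model.chains:
        d = np.dot(helix_axis(xyz, cid)[0], axis)
        if abs(d) < ORIENTATION_TOLERANCE:
            raise GeometryError(
                f"ambiguous orientation: chain {cid} nearly perpendicular to "
                f"the bundle axis (|cos| = {abs(d):.3f})"
            )
        signs.append(1 if d > 0 else -1)
    signs_t = tuple(signs)
    if all(s == 1 for s in signs_t) or all(s == -1 for s in signs_t):
        return TopologyLabel("parallel", signs_t)
    order = _ring_order(model, axis, origin)
    ring_signs = [signs_t[i] for i in order]
    n = len(ring_signs)
    alternating = n % 2 == 0 and all(
        ring_signs[i] != ring_signs[(i + 1) % n] for i in range(n)
    )
    if alternating:
        return TopologyLabel("antiparallel_alternating", signs_t)
    return TopologyLabel("mixed", signs_t)


def overhang(model: AssemblyModel, pair: tuple[int, int]) -> tuple[float, float]:
    """Non-overlapping axial extent between two helices' projected spans.

    Returns ``(lower, upper)`` overhang in A: the axial distance by which
    one helix protrudes beyond the other at each end of the bundle.  For
    equal spans both ends equal the pair's |dz|; for equal centroids and
    spans differing by s, each end is s/2.
    """
    axis, origin = bundle_axis(model)
    i, j = pair
    ti = (model.chains[i][2] - origin) @ axis
    tj = (model.chains[j][2] - origin) @ axis
    lower = abs(ti.min() - tj.min())
    upper = abs(ti.max() - tj.max())
    return float(lower), float(upper)


def predict_orientation_preference(
    antiparallel_z_shift: float, threshold: float = ZSHIFT_THRESHOLD
) -> str:
    """Preferred helix orientation from the Z-shift the antiparallel state
    would require.

    Large Z-shifts mean large helical overhangs and fewer helix-helix
    contacts in the antiparallel state, so above ``threshold`` (strict
    inequality; exactly at threshold counts as antiparallel) the parallel
    state is favoured.
    """
    if antiparallel_z_shift < 0:
        raise GeometryError("z_shift must be >= 0")
    return "parallel" if antiparallel_z_shift > threshold else "antiparallel"
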
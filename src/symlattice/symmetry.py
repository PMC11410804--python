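"""Rotational-symmetry detection in oligomer models.

The chain-to-chain rigid transform of a homo-oligomer is a screw motion;
its rotation angle, axis direction, axis anchor and translation along
the axis (screw shift) are extracted from the least-squares (Kabsch)
superposition of matched CA atoms.  A consensus axis over all chain
pairs classifies the oligomer as a k-fold rotational symmetry complex
(k in {2,3,4,6}; 5 additionally on curved shells).  A trimer with a
60-degree step is a partial representation of a 6-fold axis (m = 3 of
k = 6 copies present), a dimer with a 90-degree step a half-filled
4-fold axis, and so on.  Axes are accepted only when every monomer
deviates at most `axis_dev_max` (default 5 A) from the position implied
by rotating its predecessor through 360/k about the consensus axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .config import PipelineConfig
from .io import ScoredOligomer
from .structure import Chain


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or np.abs(R @ R.T - np.eye(3)).max() > 1e-8:
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> self(other(x))."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray):
    """Least-squares superposition of A onto B.

    Returns (RigidTransform, rmsd): the proper rotation + translation
    minimizing the RMSD of (R a + t) against b.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be equal-length N x 3 arrays")
    if len(a) < 3:
        raise DegenerateGeometryError("need at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinear sets leave the rotation underdetermined
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] < 1e-8 * max(1.0, sv[0]):
        raise DegenerateGeometryError("points are collinear")
    H = a0.T @ b0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    rmsd = float(np.sqrt(np.mean(np.sum((a0 @ R.T - b0) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def _matched_ca(chain_i: Chain, chain_j: Chain):
    """CA coordinates matched by residue number."""
    shared = sorted(set(chain_i.res_ids) & set(chain_j.res_ids))
    cai = chain_i.ca_coords()
    caj = chain_j.ca_coords()
    pa, pb = [], []
    for rid in shared:
        a = cai[chain_i.res_index_of(rid)]
        b = caj[chain_j.res_index_of(rid)]
        if np.all(np.isfinite(a)) and np.all(np.isfinite(b)):
            pa.append(a)
            pb.append(b)
    if len(pa) < 3:
        raise DegenerateGeometryError("fewer than 3 matched CA atoms")
    return np.array(pa), np.array(pb)


def screw_decompose(tf: RigidTransform, near_point: np.ndarray):
    """Split a rigid motion into (angle_deg, axis_dir, anchor, screw_shift).

    angle in (0, 180]; the anchor is the axis point closest to
    `near_point`; screw_shift is the translation component along the
    axis per application of the transform.
    """
    rot = Rotation.from_matrix(tf.rotation)
    rotvec = rot.as_rotvec()
    angle = float(np.linalg.norm(rotvec))
    if angle < 1e-8:
        raise DegenerateGeometryError("no rotation component")
    d = rotvec / angle
    t = tf.translation
    shift = float(np.dot(d, t))
    t_perp = t - shift * d
    # solve (I - R) a = t_perp for a point on the axis
    A = np.eye(3) - tf.rotation
    a0 = np.linalg.lstsq(A, t_perp, rcond=None)[0]
    # move the anchor along the axis next to the structure
    a0 = a0 + d * np.dot(d, near_point - a0)
    return math.degrees(angle), d, a0, shift


def pairwise_rotation(oligomer: ScoredOligomer, chain_i: str, chain_j: str):
    """Screw parameters of the chain_i -> chain_j transform.

    Returns (angle_deg, axis_direction, axis_anchor, screw_shift_A).
    """
    ci = oligomer.model.get_chain(chain_i)
    cj = oligomer.model.get_chain(chain_j)
    pa, pb = _matched_ca(ci, cj)
    tf, _ = kabsch(pa, pb)
    centroid = 0.5 * (pa.mean(axis=0) + pb.mean(axis=0))
    return screw_decompose(tf, centroid)


@dataclass
class SymmetryAxis:
    """A k-fold rotational axis fitted to an oligomer model."""

    direction: np.ndarray
    anchor: np.ndarray
    order_k: int
    delta_phi: float          # observed mean inter-monomer angle, deg
    filled: float             # m / k
    per_monomer_dev: list[float] = field(default_factory=list)
    screw_shift: float = 0.0  # A per step

    def __post_init__(self):
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("axis direction must be a unit vector")
        self.anchor = np.asarray(self.anchor, dtype=float)
        if not 0.0 < self.filled <= 1.0:
            raise ValueError("filled fraction must be in (0, 1]")


@dataclass
class AxisRejection:
    reason: str
    detail: str = ""

    def __bool__(self):
        return False


def _canonical_sign(d: np.ndarray) -> np.ndarray:
    """Flip an axis direction into the +z hemisphere (then +x, +y)."""
    for comp in (2, 0, 1):
        if abs(d[comp]) > 1e-9:
            return d if d[comp] > 0 else -d
    return d


def _rotation_about(direction: np.ndarray, anchor: np.ndarray,
                    angle_deg: float) -> RigidTransform:
    R = Rotation.from_rotvec(np.radians(angle_deg) * direction).as_matrix()
    return RigidTransform(R, anchor - R @ anchor)


def classify_axis(oligomer: ScoredOligomer,
                  allowed_orders=frozenset({2, 3, 4, 6}),
                  config: PipelineConfig | None = None):
    """Fit a consensus rotational axis and deduce its order k.

    Returns a SymmetryAxis or an AxisRejection carrying a reason code in
    {no_rotation, angle_mismatch, deviation, screw}.
    """
    cfg = config or PipelineConfig()
    chains = oligomer.model.chains
    m = len(chains)
    if m < 2:
        raise ValueError("need at least 2 chains")

    dirs, anchors = [], []
    try:
        for i in range(m):
            for j in range(i + 1, m):
                _, d, a, _ = pairwise_rotation(
                    oligomer, chains[i].chain_id, chains[j].chain_id)
                dirs.append(_canonical_sign(d))
                anchors.append(a)
    except DegenerateGeometryError as exc:
        return AxisRejection("no_rotation", str(exc))

    # consensus direction: principal eigenvector of the orientation tensor
    M = sum(np.outer(d, d) for d in dirs)
    w, v = np.linalg.eigh(M)
    direction = _canonical_sign(v[:, -1] / np.linalg.norm(v[:, -1]))

    centroids = np.array([np.nanmean(ch.ca_coords(), axis=0) for ch in chains])
    center = centroids.mean(axis=0)
    # consensus anchor: mean of pairwise anchors projected onto the
    # plane through the centroid center, perpendicular to the axis
    proj = [a - direction * np.dot(direction, a - center) for a in anchors]
    anchor = np.mean(proj, axis=0)

    # order chains angularly around the axis
    ref = centroids[0] - anchor
    ref = ref - direction * np.dot(direction, ref)
    if np.linalg.norm(ref) < 1e-6:
        return AxisRejection("no_rotation", "centroid on axis")
    ref /= np.linalg.norm(ref)
    perp = np.cross(direction, ref)
    # small offset keeps the reference chain's azimuth from wrapping to 2*pi
    az = np.array([(math.atan2(np.dot(c - anchor, perp),
                               np.dot(c - anchor, ref)) + 1e-8)
                   % (2 * math.pi) for c in centroids])
    order = np.argsort(az)

    # mean adjacent rotation angle and screw shift
    angles, screws = [], []
    for a, b in zip(order[:-1], order[1:]):
        ang, _, _, s = pairwise_rotation(
            oligomer, chains[a].chain_id, chains[b].chain_id)
        angles.append(ang)
        screws.append(abs(s))
    delta_phi = float(np.mean(angles))

    # deduce k
    best_k, best_err = None, None
    for k in sorted(allowed_orders):
        if m > k:
            continue
        err = abs(delta_phi - 360.0 / k)
        if best_err is None or err < best_err - 1e-9:
            best_k, best_err = k, err
    if best_k is None or best_err > cfg.angle_tol:
        return AxisRejection(
            "angle_mismatch",
            f"delta_phi={delta_phi:.2f} fits no allowed order")
    k = best_k

    # per-monomer deviation: predecessor centroid rotated by 360/k must
    # land on the monomer centroid (both senses of rotation are tried).
    # Measured perpendicular to the axis -- the translation along the
    # axis is assessed separately as the screw shift.
    devs_best = None
    for sign in (+1.0, -1.0):
        step = _rotation_about(direction, anchor, sign * 360.0 / k)
        devs = []
        seq = list(order) + ([order[0]] if m == k else [])
        for a, b in zip(seq[:-1], seq[1:]):
            delta = step.apply(centroids[a]) - centroids[b]
            delta = delta - direction * np.dot(direction, delta)
            devs.append(float(np.linalg.norm(delta)))
        if devs_best is None or max(devs) < max(devs_best):
            devs_best = devs
    if max(devs_best) > cfg.axis_dev_max:
        return AxisRejection(
            "deviation",
            f"max per-monomer deviation {max(devs_best):.2f} A")

    screw = float(np.mean(screws)) if screws else 0.0
    if cfg.mode != "capsid" and screw > cfg.screw_tol:
        return AxisRejection("screw", f"screw shift {screw:.2f} A per step")

    return SymmetryAxis(direction=direction, anchor=anchor, order_k=k,
                        delta_phi=delta_phi, filled=m / k,
                        per_monomer_dev=devs_best, screw_shift=screw)


@dataclass
class SymmetryComplex:
    """An accepted oligomer with its rotational axis.

    `chain_order` lists chain ids sorted angularly around the axis; the
    interface distogram is attached by the clustering stage.
    """

    oligomer: ScoredOligomer
    axis: SymmetryAxis
    chain_order: list[str] = field(default_factory=list)
    interface = None

    @property
    def name(self) -> str:
        return self.oligomer.model.name

    @property
    def score(self) -> float:
        return self.oligomer.score.combined


def _angular_chain_order(oligomer: ScoredOligomer, axis: SymmetryAxis):
    chains = oligomer.model.chains
    centroids = np.array([np.nanmean(ch.ca_coords(), axis=0) for ch in chains])
    d, anchor = axis.direction, axis.anchor
    ref = centroids[0] - anchor
    ref = ref - d * np.dot(d, ref)
    ref /= np.linalg.norm(ref)
    perp = np.cross(d, ref)
    az = [(math.atan2(np.dot(c - anchor, perp), np.dot(c - anchor, ref))
           + 1e-8) % (2 * math.pi) for c in centroids]
    return [chains[i].chain_id for i in np.argsort(az)]


def detect(oligomer: ScoredOligomer, mode: str = "layer",
           config: PipelineConfig | None = None):
    """Full axis detection for one oligomer.

    Layer mode allows orders {2,3,4,6}; capsid mode adds 5-fold and
    drops the screw-shift restriction.  Returns a SymmetryComplex or an
    AxisRejection.
    """
    cfg = config or PipelineConfig()
    cfg_mode = PipelineConfig(**{**cfg.to_dict(), "mode": mode})
    allowed = cfg_mode.allowed_orders()
    result = classify_axis(oligomer, allowed, cfg_mode)
    if isinstance(result, AxisRejection):
        return result
    return SymmetryComplex(oligomer=oligomer, axis=result,
                           chain_order=_angular_chain_order(oligomer, result))
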
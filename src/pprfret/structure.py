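"""Alpha-solenoid geometry on PDB-format coordinates.

Covers superhelical parameter estimation (radius, rise per repeat, twist per
repeat, pitch, repeats per turn), inter-repeat rigid-body/hinge analysis via
screw decomposition of Kabsch superpositions, residue-pair distance series,
and Forster-based FRET prediction / FRET-pair screening between an extended
(apo) and compact (RNA-bound) conformation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CoordinateSet",
    "SolenoidParameters",
    "RigidTransform",
    "FretPairGeometry",
    "RepeatSpec",
    "read_structure",
    "fit_superhelix",
    "inter_repeat_transforms",
    "pair_distances",
    "adjacent_repeat_distances",
    "predict_fret_from_distance",
    "screen_fret_pairs",
    "kabsch",
]


class DegenerateGeometryError(ValueError):
    """Raised when centroids carry no superhelical information (e.g. collinear)."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CoordinateSet:
    """Atom records plus an ordered, non-overlapping repeat annotation.

    ``repeat_annotation`` is a list of inclusive residue-number ranges
    ``(start, end)``, one per repeat, in order along the solenoid.
    """

    chain: np.ndarray
    resnum: np.ndarray
    atom_name: np.ndarray
    xyz: np.ndarray
    repeat_annotation: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.chain = np.asarray(self.chain)
        self.atom_name = np.asarray(self.atom_name)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must be (N, 3)")
        prev_end = None
        for start, end in self.repeat_annotation:
            if end < start:
                raise ValueError(f"repeat range ({start}, {end}) reversed")
            if prev_end is not None and start <= prev_end:
                raise ValueError("repeat ranges overlap or are out of order")
            prev_end = end

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_annotation)

    def repeat_mask(self, k: int, atom_name: str | None = "CA") -> np.ndarray:
        start, end = self.repeat_annotation[k]
        m = (self.resnum >= start) & (self.resnum <= end)
        if atom_name is not None:
            m &= self.atom_name == atom_name
        return m

    def repeat_centroids(self, atom_name: str | None = "CA") -> np.ndarray:
        """Centroid of the named atoms of each annotated repeat."""
        cents = []
        for k in range(self.n_repeats):
            m = self.repeat_mask(k, atom_name)
            if not m.any():
                raise ValueError(f"repeat {k} has no '{atom_name}' atoms")
            cents.append(self.xyz[m].mean(axis=0))
        return np.array(cents)

    def atom(self, resnum: int, atom_name: str, chain: str | None = None) -> np.ndarray:
        m = (self.resnum == resnum) & (self.atom_name == atom_name)
        if chain is not None:
            m &= self.chain == chain
        idx = np.flatnonzero(m)
        if len(idx) == 0:
            raise KeyError(f"atom {atom_name} of residue {resnum} not found")
        return self.xyz[idx[0]]

    def transformed(self, R: np.ndarray, t: np.ndarray) -> "CoordinateSet":
        return CoordinateSet(
            chain=self.chain.copy(),
            resnum=self.resnum.copy(),
            atom_name=self.atom_name.copy(),
            xyz=self.xyz @ R.T + t,
            repeat_annotation=list(self.repeat_annotation),
        )

    def write_pdb(self, path) -> None:
        import gemmi

        st = gemmi.Structure()
        st.name = "pprfret"
        model = gemmi.Model("1")
        chains: dict[str, gemmi.Chain] = {}
        for ch, rn, an, pos in zip(self.chain, self.resnum, self.atom_name, self.xyz):
            ch = str(ch)
            if ch not in chains:
                chains[ch] = gemmi.Chain(ch)
            chain = chains[ch]
            res = None
            if len(chain) and chain[-1].seqid.num == int(rn):
                res = chain[-1]
            if res is None:
                res = gemmi.Residue()
                res.name = "ALA"
                res.seqid = gemmi.SeqId(int(rn), " ")
                chain.add_residue(res)
                res = chain[-1]
            atom = gemmi.Atom()
            atom.name = str(an)
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, pos))
            res.add_atom(atom)
        for chain in chains.values():
            model.add_chain(chain)
        st.add_model(model)
        st.setup_entities()
        st.write_pdb(str(path))


@dataclass
class RepeatSpec:
    """How to annotate repeats in a structure file.

    Either explicit ``ranges`` (inclusive residue-number pairs) or a regular
    layout ``first_residue`` + ``n_repeats`` x ``repeat_length`` (35-residue
    consensus motifs by default).
    """

    chain: str = "A"
    ranges: list | None = None
    first_residue: int = 1
    repeat_length: int = 35
    n_repeats: int | None = None

    def resolve(self) -> list:
        if self.ranges is not None:
            return list(self.ranges)
        if self.n_repeats is None:
            raise ValueError("either ranges or n_repeats must be given")
        return [
            (
                self.first_residue + k * self.repeat_length,
                self.first_residue + (k + 1) * self.repeat_length - 1,
            )
            for k in range(self.n_repeats)
        ]


def read_structure(path, repeat_spec: RepeatSpec) -> CoordinateSet:
    """Read a PDB-format file into a :class:`CoordinateSet`.

    Insertion codes are rejected; the annotation must cover >= 3 repeats and
    every range must contain at least one atom, else an error names the
    offending range.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    chains = [ch for ch in model if ch.name == repeat_spec.chain]
    if not chains:
        raise ValueError(f"chain {repeat_spec.chain!r} not found in {path}")
    chain_names, resnums, names, xyz = [], [], [], []
    for ch in chains:
        for res in ch:
            if res.seqid.icode not in (" ", ""):
                raise ValueError(
                    f"insertion code {res.seqid.icode!r} at residue "
                    f"{res.seqid.num} not supported"
                )
            for atom in res:
                chain_names.append(ch.name)
                resnums.append(res.seqid.num)
                names.append(atom.name)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
    resnums = np.array(resnums, dtype=int)
    ranges = repeat_spec.resolve()
    if len(ranges) < 3:
        raise ValueError("repeat annotation must cover >= 3 repeats")
    for start, end in ranges:
        if not np.any((resnums >= start) & (resnums <= end)):
            raise ValueError(f"no atoms found in repeat range ({start}, {end})")
    return CoordinateSet(
        chain=np.array(chain_names),
        resnum=resnums,
        atom_name=np.array(names),
        xyz=np.array(xyz),
        repeat_annotation=ranges,
    )


# ---------------------------------------------------------------------------
# superhelix fitting


@dataclass
class SolenoidParameters:
    """Superhelical radius, per-repeat rise/twist and the derived pitch.

    pitch = rise * 360 / twist; repeats_per_turn = 360 / twist.
    """

    radius: float  # Angstrom
    rise: float  # Angstrom / repeat
    twist: float  # degrees / repeat
    axis: np.ndarray | None = None  # unit vector, repeat 1 -> N
    axis_point: np.ndarray | None = None
    residual_rmsd: float = 0.0  # centroid-to-model RMSD, Angstrom

    @property
    def pitch(self) -> float:
        return self.rise * 360.0 / self.twist

    @property
    def repeats_per_turn(self) -> float:
        return 360.0 / self.twist


def _axis_from_centroids(c: np.ndarray) -> np.ndarray:
    """Axis direction from cross products of successive second differences.

    For points on an ideal helix the second differences of the centroid
    sequence are radial (axis-perpendicular) vectors of equal length whose
    successive cross products are exactly parallel to the helix axis.
    """
    d = np.diff(c, axis=0)
    s = np.diff(d, axis=0)
    if len(s) < 2:
        raise DegenerateGeometryError("need >= 4 repeat centroids to fit a superhelix")
    norms = np.linalg.norm(s, axis=1)
    scale = np.linalg.norm(d, axis=1).max()
    if np.all(norms < 1e-9 * max(scale, 1.0)):
        raise DegenerateGeometryError("centroids are collinear; no superhelix")
    crosses = np.cross(s[:-1], s[1:])
    cn = np.linalg.norm(crosses, axis=1)
    good = cn > 1e-12 * max(scale, 1.0) ** 2
    if not good.any():
        raise DegenerateGeometryError("degenerate centroid geometry (coplanar radial vectors)")
    ref = crosses[good][0]
    signs = np.sign(crosses[good] @ ref)
    v = (crosses[good] * signs[:, None]).mean(axis=0)
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise DegenerateGeometryError("axis direction undetermined")
    v = v / nv
    # orient along increasing repeat index
    if (d @ v).mean() < 0:
        v = -v
    return v


def _plane_basis(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0])
    if abs(v @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(v, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)
    return e1, e2


def _circle_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) circle fit; exact on noiseless circle points."""
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r = math.sqrt(max(c + cx * cx + cy * cy, 0.0))
    return float(cx), float(cy), r


def _helix_model(params: np.ndarray, n: int) -> np.ndarray:
    px, py, pz, th, ph, radius, rise, twist, phase = params
    v = np.array([math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)])
    e1, e2 = _plane_basis(v)
    k = np.arange(n)
    ang = phase + k * twist
    return (
        np.array([px, py, pz])
        + radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
        + (k * rise)[:, None] * v
    )


def fit_superhelix(
    coords: CoordinateSet, atom_name: str | None = "CA", refine: bool = True
) -> SolenoidParameters:
    """Estimate superhelical parameters from per-repeat centroids.

    A closed-form geometric estimate (axis from second-difference cross
    products, Kasa circle fit in the axis-normal plane, mean axial/angular
    increments) is optionally polished by nonlinear least squares against
    the full helix model. Exact on ideal solenoids; the residual centroid
    RMSD is reported for noisy input.
    """
    c = coords.repeat_centroids(atom_name)
    n = len(c)
    v = _axis_from_centroids(c)
    e1, e2 = _plane_basis(v)
    x = c @ e1
    y = c @ e2
    cx, cy, radius = _circle_fit(x, y)
    if radius < 1e-6:
        raise DegenerateGeometryError("zero superhelical radius")
    ang = np.unwrap(np.arctan2(y - cy, x - cx))
    twist = float(np.mean(np.diff(ang)))
    rise = float(np.mean(np.diff(c @ v)))
    phase = float(ang[0])
    center3 = cx * e1 + cy * e2  # axis point in the normal plane

    th = math.acos(np.clip(v[2], -1, 1))
    ph = math.atan2(v[1], v[0])
    params = np.array([*center3, th, ph, radius, rise, twist, phase])
    if refine:
        def resid(p):
            return (_helix_model(p, n) - c).ravel()

        sol = least_squares(resid, params, method="lm", xtol=1e-15, ftol=1e-15)
        params = sol.x
    model = _helix_model(params, n)
    rmsd = float(np.sqrt(np.mean(np.sum((model - c) ** 2, axis=1))))
    px, py, pz, th, ph, radius, rise, twist, phase = params
    v = np.array([math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)])
    # canonical form: positive rise along repeat 1 -> N, twist in (0, 180)
    twist_deg = math.degrees(twist)
    if rise < 0:
        rise, v = -rise, -v
        twist_deg = -twist_deg
    twist_deg = abs(((twist_deg + 180.0) % 360.0) - 180.0)
    if not 0 < twist_deg < 180:
        raise DegenerateGeometryError("twist outside (0, 180) degrees")
    return SolenoidParameters(
        radius=abs(float(radius)),
        rise=float(rise),
        twist=float(twist_deg),
        axis=v,
        axis_point=np.array([px, py, pz]),
        residual_rmsd=rmsd,
    )


# ---------------------------------------------------------------------------
# rigid-body / hinge analysis


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition mapping P onto Q.

    Returns (R, t, rmsd) with ``R @ p + t ~= q`` (proper rotation).
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


@dataclass
class RigidTransform:
    """Screw representation of a rigid transform (rotation about + translation
    along one axis), plus the underlying matrix form for exact recomposition."""

    rotation_angle: float  # degrees, in [0, 180]
    screw_axis: np.ndarray  # unit vector
    axial_translation: float  # Angstrom
    rmsd: float  # superposition RMSD of the reference repeat, Angstrom
    rotation: np.ndarray = None  # type: ignore[assignment]
    translation: np.ndarray = None  # type: ignore[assignment]
    axis_point: np.ndarray = None  # type: ignore[assignment]

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def apply_screw(self, points: np.ndarray) -> np.ndarray:
        """Apply the screw form (rotate about the axis through axis_point,
        then translate along the axis); equals :meth:`apply` up to round-off."""
        pts = np.asarray(points, float) - self.axis_point
        n = self.screw_axis
        ang = math.radians(self.rotation_angle)
        cos, sin = math.cos(ang), math.sin(ang)
        rot = (
            pts * cos
            + np.cross(n, pts) * sin
            + np.outer(pts @ n, n) * (1 - cos)
        )
        return rot + self.axis_point + self.axial_translation * n


def _screw_from_rt(R: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray, float, np.ndarray]:
    """Decompose (R, t) into rotation angle (deg), unit axis, axial translation
    and a point on the screw axis."""
    cos_th = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = math.acos(cos_th)
    if angle < 1e-12:
        # pure translation: axis along t (or arbitrary if t ~ 0)
        nt = np.linalg.norm(t)
        axis = t / nt if nt > 1e-12 else np.array([0.0, 0.0, 1.0])
        return 0.0, axis, float(t @ axis), np.zeros(3)
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.linalg.norm(w) > 1e-8:
        axis = w / np.linalg.norm(w)
    else:  # angle ~ pi
        M = (R + np.eye(3)) / 2.0
        axis = M[:, np.argmax(np.diag(M))]
        axis = axis / np.linalg.norm(axis)
    d = float(t @ axis)
    # axis point: solve (I - R) c = t - d*axis (rank 2; least squares)
    c, *_ = np.linalg.lstsq(np.eye(3) - R, t - d * axis, rcond=None)
    return math.degrees(angle), axis, d, c


def inter_repeat_transforms(
    coordsA: CoordinateSet,
    coordsB: CoordinateSet,
    atom_name: str | None = "CA",
) -> list[RigidTransform]:
    """Hinge analysis between two conformations of the same solenoid.

    For each adjacent repeat pair (i, i+1): superpose repeat i of A onto
    repeat i of B, then extract the residual rigid transform carrying repeat
    i+1 of A onto repeat i+1 of B as a screw. Atom correspondence is by
    (residue offset within the repeat, atom name).
    """
    if coordsA.n_repeats != coordsB.n_repeats:
        raise ValueError("conformations have different repeat counts")
    out = []
    for i in range(coordsA.n_repeats - 1):
        PA_i, PB_i = _matched_repeat(coordsA, coordsB, i, atom_name)
        PA_n, PB_n = _matched_repeat(coordsA, coordsB, i + 1, atom_name)
        R1, t1, rmsd1 = kabsch(PA_i, PB_i)
        PA_n_sup = PA_n @ R1.T + t1
        R2, t2, _ = kabsch(PA_n_sup, PB_n)
        angle, axis, d, c = _screw_from_rt(R2, t2)
        out.append(
            RigidTransform(
                rotation_angle=angle,
                screw_axis=axis,
                axial_translation=d,
                rmsd=rmsd1,
                rotation=R2,
                translation=t2,
                axis_point=c,
            )
        )
    return out


def _matched_repeat(A: CoordinateSet, B: CoordinateSet, k: int, atom_name):
    mA = A.repeat_mask(k, atom_name)
    mB = B.repeat_mask(k, atom_name)
    offA = A.resnum[mA] - A.repeat_annotation[k][0]
    offB = B.resnum[mB] - B.repeat_annotation[k][0]
    keyA = {(o, n): p for o, n, p in zip(offA, A.atom_name[mA], A.xyz[mA])}
    keyB = {(o, n): p for o, n, p in zip(offB, B.atom_name[mB], B.xyz[mB])}
    common = sorted(set(keyA) & set(keyB))
    missing = sorted(set(keyA) ^ set(keyB))
    if len(common) < 3:
        raise ValueError(
            f"repeat {k}: fewer than 3 matched atoms; unmatched: {missing[:10]}"
        )
    PA = np.array([keyA[c] for c in common])
    PB = np.array([keyB[c] for c in common])
    return PA, PB


# ---------------------------------------------------------------------------
# distances and FRET prediction


def pair_distances(
    coordsA: CoordinateSet,
    coordsB: CoordinateSet,
    pairs,
    atom_name: str = "CA",
) -> list[dict]:
    """Euclidean distances (Angstrom) of residue pairs in both conformations.

    ``pairs`` is an iterable of (resnum_1, resnum_2). Missing atoms produce a
    per-pair ``error`` entry; the other pairs are still computed.
    """
    out = []
    for r1, r2 in pairs:
        rec: dict = {"pair": (int(r1), int(r2))}
        try:
            a1, a2 = coordsA.atom(r1, atom_name), coordsA.atom(r2, atom_name)
            b1, b2 = coordsB.atom(r1, atom_name), coordsB.atom(r2, atom_name)
            rec["r_A"] = float(np.linalg.norm(a1 - a2))
            rec["r_B"] = float(np.linalg.norm(b1 - b2))
        except KeyError as exc:
            rec["error"] = str(exc)
        out.append(rec)
    return out


def adjacent_repeat_distances(
    coords: CoordinateSet, residue_offset: int, atom_name: str = "CA"
) -> np.ndarray:
    """Distance series between the same residue offset of consecutive repeats
    (e.g. the Lys13 side-chain nitrogen series along the solenoid)."""
    ds = []
    for k in range(coords.n_repeats - 1):
        r1 = coords.repeat_annotation[k][0] + residue_offset
        r2 = coords.repeat_annotation[k + 1][0] + residue_offset
        ds.append(float(np.linalg.norm(coords.atom(r1, atom_name) - coords.atom(r2, atom_name))))
    return np.array(ds)


def predict_fret_from_distance(r, r0: float):
    """Forster transfer efficiency E = 1 / (1 + (r/R0)^6)."""
    if r0 <= 0:
        raise ValueError("R0 must be > 0")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance must be >= 0")
    out = 1.0 / (1.0 + (r / r0) ** 6)
    return float(out) if out.ndim == 0 else out


@dataclass
class FretPairGeometry:
    residue_1: int
    residue_2: int
    r_apo: float
    r_bound: float
    r0: float

    @property
    def e_apo(self) -> float:
        return predict_fret_from_distance(self.r_apo, self.r0)

    @property
    def e_bound(self) -> float:
        return predict_fret_from_distance(self.r_bound, self.r0)

    @property
    def contrast(self) -> float:
        return abs(self.e_bound - self.e_apo)


def screen_fret_pairs(
    coordsA: CoordinateSet,
    coordsB: CoordinateSet,
    r0: float,
    separation: int,
    atom_name: str = "CA",
) -> list[FretPairGeometry]:
    """Screen residue pairs ``separation`` repeats apart for FRET contrast.

    Retains pairs whose apo distance exceeds the Forster radius while the
    bound distance falls below it (r_apo > R0 > r_bound), ranked by
    |E_bound - E_apo| descending. A is the extended (apo) conformation,
    B the compact (bound) one.
    """
    hits: list[FretPairGeometry] = []
    nrep = min(coordsA.n_repeats, coordsB.n_repeats)
    for k in range(nrep - separation):
        m1 = coordsA.repeat_mask(k, atom_name)
        m2 = coordsA.repeat_mask(k + separation, atom_name)
        for r1 in np.unique(coordsA.resnum[m1]):
            for r2 in np.unique(coordsA.resnum[m2]):
                try:
                    ra = float(
                        np.linalg.norm(coordsA.atom(r1, atom_name) - coordsA.atom(r2, atom_name))
                    )
                    rb = float(
                        np.linalg.norm(coordsB.atom(r1, atom_name) - coordsB.atom(r2, atom_name))
                    )
                except KeyError:
                    continue
                if ra > r0 > rb:
                    hits.append(FretPairGeometry(int(r1), int(r2), ra, rb, r0))
    hits.sort(key=lambda h: h.contrast, reverse=True)
    return hits
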
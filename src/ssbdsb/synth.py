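"""Synthetic fixtures with analytic ground truth.

Everything the test suite and the desk-scale experiments run on is generated
here: channel "phantoms" (atom-sphere geometries whose tunnel length,
curvature and bottleneck radius are known by construction), compact
template-like CA traces and decoy coils for the aligner, and two-class
feature populations that mimic the qualitative class differences observed
between single- and double-stranded DNA binders (SSBs: shorter and
straighter tunnels, higher OB-fold TM-score; bottleneck radii overlapping).

All generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import AtomRecord, ProteinChain

CA_BOND = 3.8  # Å, consecutive C-alpha spacing in real protein chains


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic channel phantom.

    kind: straight_channel | bent_channel | hollow_sphere | solid_ball.
    wall_radius: distance of wall-atom centers from the channel axis (Å);
        the analytic bottleneck is ``wall_radius - atom_radius``.
    axis_length: channel run for straight channels (Å).
    bend_radius: centerline bend radius for quarter-torus channels (Å).
    jacket: bury the closed end under a coaxial outer shell so the tunnel
        start lands there deterministically.
    """

    kind: str = "straight_channel"
    wall_radius: float = 4.0
    axis_length: float = 30.0
    bend_radius: float = 15.0
    atom_radius: float = 1.5
    atom_spacing: float = 1.6
    jitter: float = 0.08
    jacket: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"straight_channel", "bent_channel", "hollow_sphere", "solid_ball"}:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind in {"straight_channel", "bent_channel"} and \
                self.wall_radius <= self.atom_radius:
            raise ValueError("wall_radius must exceed atom_radius (no channel otherwise)")


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth of a phantom."""

    has_tunnel: bool
    bottleneck_radius: float = float("nan")
    curvature: float = float("nan")
    length_range: tuple[float, float] = (float("nan"), float("nan"))


def _ring(center: np.ndarray, normal_u: np.ndarray, normal_v: np.ndarray,
          radius: float, spacing: float, phase: float = 0.0) -> np.ndarray:
    if radius < spacing / 4:
        return center[None, :]
    n = max(int(math.ceil(2 * math.pi * radius / spacing)), 3)
    ang = phase + np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    return center + radius * (np.cos(ang)[:, None] * normal_u + np.sin(ang)[:, None] * normal_v)


def _disk(center: np.ndarray, u: np.ndarray, v: np.ndarray,
          r_outer: float, spacing: float, r_inner: float = 0.0) -> np.ndarray:
    pts = []
    r = r_inner
    if r_inner == 0.0:
        pts.append(center[None, :])
        r = spacing
    while r <= r_outer + 1e-9:
        pts.append(_ring(center, u, v, r, spacing))
        r += spacing
    return np.vstack(pts)


def chain_from_atoms(coords: np.ndarray, atom_radius: float,
                     chain_id: str = "P") -> ProteinChain:
    """Wrap bare sphere centers as a ProteinChain.

    Each sphere becomes the CA of its own one-atom residue, so phantom
    chains run through every pipeline stage (including alignment)."""
    coords = np.asarray(coords, float)
    atoms = tuple(
        AtomRecord(
            serial=i + 1, name="CA", element="C", residue_name="UNK",
            residue_index=i + 1, chain_id=chain_id,
            position=tuple(float(x) for x in p), radius=atom_radius,
        )
        for i, p in enumerate(coords)
    )
    residues = tuple((i + 1, "UNK") for i in range(len(coords)))
    return ProteinChain(chain_id=chain_id, atoms=atoms, residues=residues,
                        ca_coords=coords.copy())


def chain_from_ca(ca: np.ndarray, chain_id: str = "A",
                  atom_radius: float = 1.7) -> ProteinChain:
    """Wrap a CA trace as a ProteinChain of CA-only residues."""
    ca = np.asarray(ca, float)
    atoms = tuple(
        AtomRecord(
            serial=i + 1, name="CA", element="C", residue_name="GLY",
            residue_index=i + 1, chain_id=chain_id,
            position=tuple(float(x) for x in p), radius=atom_radius,
        )
        for i, p in enumerate(ca)
    )
    residues = tuple((i + 1, "GLY") for i in range(len(ca)))
    return ProteinChain(chain_id=chain_id, atoms=atoms, residues=residues, ca_coords=ca)


def make_phantom(spec: PhantomSpec) -> tuple[ProteinChain, PhantomTruth]:
    """Build a channel phantom and its analytic tunnel ground truth."""
    s = spec.atom_spacing
    ex, ey, ez = np.eye(3)
    pts: list[np.ndarray] = []

    if spec.kind == "straight_channel":
        L = spec.axis_length
        nz = max(int(round(L / s)), 2)
        for k in range(nz + 1):
            z = L * k / nz
            pts.append(_ring(np.array([0.0, 0.0, z]), ex, ey, spec.wall_radius, s))
        pts.append(_disk(np.array([0.0, 0.0, 0.0]), ex, ey, spec.wall_radius, s))
        if spec.jacket:
            jr = spec.wall_radius + 6.0
            ztop = 0.45 * L
            nj = max(int(round((ztop + 2.0) / s)), 2)
            for k in range(nj + 1):
                z = -2.0 + (ztop + 2.0) * k / nj
                pts.append(_ring(np.array([0.0, 0.0, z]), ex, ey, jr, s))
            pts.append(_disk(np.array([0.0, 0.0, -2.0]), ex, ey, jr, s))
        truth = PhantomTruth(
            has_tunnel=True,
            bottleneck_radius=spec.wall_radius - spec.atom_radius,
            curvature=1.0,
            length_range=(0.35 * L, 1.4 * L),
        )

    elif spec.kind == "bent_channel":
        R = spec.bend_radius
        arc = math.pi / 2 * R
        nseg = max(int(round(arc / s)), 2)
        for k in range(nseg + 1):
            th = (math.pi / 2) * k / nseg
            c = np.array([R * math.cos(th), 0.0, R * math.sin(th)])
            radial = np.array([math.cos(th), 0.0, math.sin(th)])
            pts.append(_ring(c, radial, ey, spec.wall_radius, s))
        c0 = np.array([R, 0.0, 0.0])
        pts.append(_disk(c0, np.array([1.0, 0.0, 0.0]), ey, spec.wall_radius, s))
        if spec.jacket:
            jr = spec.wall_radius + 6.0
            for k in range(max(nseg // 4, 2) + 1):
                th = (math.pi / 8) * k / max(nseg // 4, 2) - 0.08
                c = np.array([R * math.cos(th), 0.0, R * math.sin(th)])
                radial = np.array([math.cos(th), 0.0, math.sin(th)])
                pts.append(_ring(c, radial, ey, jr, s))
            pts.append(_disk(c0 + np.array([0.0, 0.0, -1.2]),
                             np.array([1.0, 0.0, 0.0]), ey, jr, s))
        # a 90-degree arc has arc/chord = (pi/2)/sqrt(2)
        truth = PhantomTruth(
            has_tunnel=True,
            bottleneck_radius=spec.wall_radius - spec.atom_radius,
            curvature=(math.pi / 2) / math.sqrt(2),
            length_range=(0.35 * arc, 1.5 * arc),
        )

    elif spec.kind == "hollow_sphere":
        R = spec.wall_radius
        nlat = max(int(round(math.pi * R / s)), 3)
        for k in range(nlat + 1):
            phi = math.pi * k / nlat
            z = R * math.cos(phi)
            r = R * math.sin(phi)
            pts.append(_ring(np.array([0.0, 0.0, z]), ex, ey, r, s))
        truth = PhantomTruth(has_tunnel=False,
                             bottleneck_radius=R - spec.atom_radius)

    else:  # solid_ball
        R = spec.wall_radius
        grid = np.arange(-R, R + 1e-9, s)
        gx, gy, gz = np.meshgrid(grid, grid, grid, indexing="ij")
        g = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
        pts.append(g[np.linalg.norm(g, axis=1) <= R])
        truth = PhantomTruth(has_tunnel=False)

    coords = np.vstack(pts)
    # deduplicate near-coincident atoms (disk/ring overlaps)
    _, keep = np.unique(np.round(coords / (s * 0.4)).astype(int), axis=0, return_index=True)
    coords = coords[np.sort(keep)]
    if spec.jitter > 0:
        # break the lattice symmetry: real structures are never degenerate,
        # and exact symmetry makes the Voronoi topology orientation-dependent
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(0.0, spec.jitter, coords.shape)
    return chain_from_atoms(coords, spec.atom_radius), truth


def _self_avoiding_walk(n: int, rng: np.random.Generator, compact: bool,
                        min_sep: float = 3.6) -> np.ndarray:
    pts = [np.zeros(3)]
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    pts.append(pts[0] + CA_BOND * d)
    while len(pts) < n:
        arr = np.array(pts)
        centroid = arr.mean(axis=0)
        prev_dir = (pts[-1] - pts[-2]) / CA_BOND
        cand = rng.standard_normal((40, 3))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        # keep bond angles in a protein-like range (no immediate backtrack)
        cosang = cand @ prev_dir
        cand = cand[(cosang > -0.55) & (cosang < 0.95)]
        best = None
        best_key = np.inf
        for c in cand:
            p = pts[-1] + CA_BOND * c
            dmin = np.linalg.norm(arr[:-1] - p, axis=1).min()
            if dmin < min_sep:
                continue
            key = np.linalg.norm(p - centroid) if compact else rng.random()
            if key < best_key:
                best_key, best = key, p
        if best is None:
            # restart the tail from a fresh direction
            d = rng.standard_normal(3)
            d /= np.linalg.norm(d)
            best = pts[-1] + CA_BOND * d
        pts.append(best)
    return np.array(pts)


def make_template_like(n_residues: int = 70, fold_seed: int = 0) -> ProteinChain:
    """Deterministic compact CA trace standing in for an OB-fold template.

    Consecutive CA spacing is exactly 3.8 Å; the walk is biased toward its
    centroid, giving a globular, self-avoiding coil.
    """
    if n_residues < 15:
        raise ValueError("need at least 15 residues")
    rng = np.random.default_rng(fold_seed)
    return chain_from_ca(_self_avoiding_walk(n_residues, rng, compact=True))


def make_random_coil(n_residues: int = 70, seed: int = 0) -> ProteinChain:
    """Unbiased self-avoiding coil (the aligner's empirical null)."""
    rng = np.random.default_rng(seed)
    return chain_from_ca(_self_avoiding_walk(n_residues, rng, compact=False))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix)."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def perturb_chain(chain: ProteinChain, rigid_seed: int = 0,
                  noise_sigma: float = 0.0) -> ProteinChain:
    """Random rigid motion plus i.i.d. Gaussian coordinate noise."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(rigid_seed)
    R = random_rotation(rng)
    t = rng.uniform(-20, 20, 3)
    coords = chain.coords @ R.T + t
    if noise_sigma > 0:
        coords = coords + rng.normal(0.0, noise_sigma, coords.shape)
    atoms = []
    ca = []
    for a, p in zip(chain.atoms, coords):
        rec = AtomRecord(a.serial, a.name, a.element, a.residue_name,
                         a.residue_index, a.chain_id,
                         tuple(float(x) for x in p), a.radius)
        atoms.append(rec)
        if a.name == "CA":
            ca.append(p)
    ca_arr = np.array(ca) if ca else np.zeros((0, 3))
    return ProteinChain(chain.chain_id, tuple(atoms),
                        chain.residues[: len(ca_arr)], ca_arr)


@dataclass(frozen=True)
class FeaturePopulationSpec:
    """Two-class feature population emulating the observed class trends.

    Class-conditional distributions are Gaussians (curvature uses a folded
    Gaussian above 1). At ``separation=1`` the three informative features
    (length, curvature, TM-score) give a Bayes accuracy of roughly 0.85;
    ``separation=0`` collapses both classes onto identical distributions.
    Defaults use the 75 SSB / 204 DSB mixed-set class sizes.
    """

    n_ssb: int = 75
    n_dsb: int = 204
    separation: float = 1.0
    form: str = "HOLO"
    length_shift: float = 0.0
    tm_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ssb < 0 or self.n_dsb < 0:
            raise ValueError("class sizes must be non-negative")


# class-conditional (mean_ssb, mean_dsb, sd) at separation = 1
_POP = {
    "length": (18.0, 30.0, 7.5),
    "curvature_excess": (0.35, 0.68, 0.30),   # folded above 1.0
    "tm_score": (0.55, 0.40, 0.12),
    "bottleneck_radius": (1.5, 1.5, 0.5),
}


def make_feature_population(spec: FeaturePopulationSpec) -> pd.DataFrame:
    """Sample a labelled feature table (columns of the feature TSV)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, n in (("SSB", spec.n_ssb), ("DSB", spec.n_dsb)):
        pick = 0 if label == "SSB" else 1
        for i in range(n):
            vals = {}
            for feat, (m_ssb, m_dsb, sd) in _POP.items():
                mid = 0.5 * (m_ssb + m_dsb)
                mean = mid + spec.separation * ((m_ssb, m_dsb)[pick] - mid)
                vals[feat] = rng.normal(mean, sd)
            length = max(vals["length"] + spec.length_shift, 2.0)
            curvature = 1.0 + abs(vals["curvature_excess"])
            tm = float(np.clip(vals["tm_score"] + spec.tm_shift, 0.05, 1.0))
            bottleneck = max(vals["bottleneck_radius"], 0.1)
            rows.append({
                "protein_id": f"{spec.form}_{label}_{i:04d}",
                "length": length,
                "curvature": curvature,
                "bottleneck_radius": bottleneck,
                "tm_score": tm,
                "label": label,
                "form": spec.form,
            })
    return pd.DataFrame(rows)
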
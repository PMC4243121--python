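"""OB-fold recognition by TM-score structural alignment.

Most single-stranded DNA binders carry one or more OB
(oligonucleotide/oligosaccharide-binding) folds: a five-stranded β-sheet
coiled into a closed β-barrel capped by an α-helix. The OB-fold feature of a
query chain is the maximal TM-score of the query against a small library of
OB-fold template chains (by default chain A of PDB 1QUQ, 1V1Q, 4GS3, 3ULL,
1O7I, and one domain of 1JMC).

The aligner is a from-scratch heuristic TM-score maximiser in the spirit of
TM-align: gapless-threading and fragment-superposition seeds, then iterative
rounds of (superpose on the current residue mapping) → (score matrix
``S_ij = 1/(1 + (d_ij/d0)^2)``) → (sequential dynamic-programming mapping
with a constant gap-opening penalty) until the mapping is stable. TM-scores
are normalised by the TEMPLATE length, so a full-coverage match of a small
OB-fold template inside a larger protein scores near 1. No numerical
identity with the TM-align executable is claimed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit

from .structure_io import ProteinChain, read_structure, select_chain

logger = logging.getLogger(__name__)

GAP_PENALTY = 0.6      # per gap opening in the DP, TM-align's convention
D0_FLOOR = 0.5         # Å, lower bound on the TM-score distance scale
MIN_RESIDUES = 15      # TM-score d0 domain of validity
FRAGMENT_LEN = 20
MAX_ITER = 30


class AlignmentError(ValueError):
    pass


def tm_d0(l_norm: int) -> float:
    """TM-score distance scale d0(L) = 1.24 (L-15)^(1/3) - 1.8, floored."""
    if l_norm < 1:
        raise ValueError("normalization length must be >= 1")
    if l_norm <= MIN_RESIDUES:
        return D0_FLOOR
    return max(D0_FLOOR, 1.24 * (l_norm - 15.0) ** (1.0 / 3.0) - 1.8)


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-RMSD proper rigid transform mapping P onto Q.

    Returns ``(R, t, rmsd)`` with ``Q ≈ P @ R.T + t``; a reflection in the
    SVD solution is corrected so det(R) = +1.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if len(P) < 3:
        raise AlignmentError("need at least 3 points for superposition")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Pc, tol=1e-8) < 2 or np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise AlignmentError("degenerate (collinear) point set")
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Q.mean(axis=0) - P.mean(axis=0) @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return R, t, rmsd


def tm_score_from_distances(d: np.ndarray, d0: float, l_norm: int) -> float:
    """Raw TM-score sum: (1/L_norm) Σ 1/(1 + (d_i/d0)^2)."""
    d = np.asarray(d, float)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_norm)


def tm_score(
    mapping: np.ndarray,
    query_ca: np.ndarray,
    template_ca: np.ndarray,
    l_norm: int | None = None,
) -> float:
    """TM-score of a fixed residue mapping, maximised over superpositions.

    The rotation search follows the TM-score convention: superpose on the
    full mapped set, then iteratively re-superpose on the subset of pairs
    closer than a shrinking distance cutoff, keeping the best score seen.
    ``l_norm`` defaults to the template length.
    """
    mapping = np.asarray(mapping, int)
    if mapping.size == 0:
        raise AlignmentError("empty mapping")
    if l_norm is None:
        l_norm = len(template_ca)
    d0 = tm_d0(l_norm)
    P = np.asarray(query_ca, float)[mapping[:, 0]]
    Q = np.asarray(template_ca, float)[mapping[:, 1]]
    k = len(P)
    if k < 3:
        # too few pairs to define a rotation; best achievable puts them at 0
        return tm_score_from_distances(np.zeros(k), d0, l_norm) if k else 0.0

    best = 0.0
    cuts = [np.inf, max(d0 + 2.5, 4.5), max(d0 + 1.0, 3.5), max(d0, 2.0), max(d0 - 0.5, 1.0)]
    # seed subsets: full set plus sliding windows of shrinking length
    seeds: list[np.ndarray] = [np.arange(k)]
    for frac in (2, 4):
        w = max(k // frac, 4)
        if w >= k:
            continue
        for s in range(0, k - w + 1, max(w // 2, 1)):
            seeds.append(np.arange(s, s + w))
    for seed in seeds:
        sub = seed
        for cut in cuts:
            if len(sub) < 3:
                break
            try:
                R, t, _ = kabsch_superpose(P[sub], Q[sub])
            except AlignmentError:
                break
            d = np.linalg.norm(P @ R.T + t - Q, axis=1)
            best = max(best, tm_score_from_distances(d, d0, l_norm))
            new = np.flatnonzero(d < cut)
            if len(new) < 3:
                break
            if len(new) == len(sub) and np.array_equal(new, sub) and cut != np.inf:
                break
            sub = new
    return min(best, 1.0)


@njit(cache=True)
def _dp_traceback(S, gap):  # pragma: no cover - exercised via align_structures
    """Affine DP (gap opening only, zero extension) with free terminal gaps.

    Returns the aligned-pair arrays (qi, ti) of the best sequential mapping.
    """
    n, m = S.shape
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)   # gap in template (query advances)
    Iy = np.full((n + 1, m + 1), NEG)   # gap in query
    pM = np.zeros((n + 1, m + 1), np.int8)
    pIx = np.zeros((n + 1, m + 1), np.int8)
    pIy = np.zeros((n + 1, m + 1), np.int8)
    M[0, 0] = 0.0
    for i in range(n + 1):
        Ix[i, 0] = 0.0
    for j in range(m + 1):
        Iy[0, j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # match state
            bm, pm = M[i - 1, j - 1], 0
            if Ix[i - 1, j - 1] > bm:
                bm, pm = Ix[i - 1, j - 1], 1
            if Iy[i - 1, j - 1] > bm:
                bm, pm = Iy[i - 1, j - 1], 2
            M[i, j] = bm + S[i - 1, j - 1]
            pM[i, j] = pm
            # gap states: opening costs `gap`, extension is free
            bx, px = M[i - 1, j] - gap, 0
            if Ix[i - 1, j] > bx:
                bx, px = Ix[i - 1, j], 1
            Ix[i, j] = bx
            pIx[i, j] = px
            by, py = M[i, j - 1] - gap, 0
            if Iy[i, j - 1] > by:
                by, py = Iy[i, j - 1], 2
            Iy[i, j] = by
            pIy[i, j] = py
    # free trailing gaps: best end anywhere on the last row/column of M
    bi, bj, bs = n, m, NEG
    for i in range(1, n + 1):
        if M[i, m] > bs:
            bi, bj, bs = i, m, M[i, m]
    for j in range(1, m + 1):
        if M[n, j] > bs:
            bi, bj, bs = n, j, M[n, j]
    qi = np.empty(min(n, m), np.int64)
    ti = np.empty(min(n, m), np.int64)
    k = 0
    i, j, state = bi, bj, 0
    if bs == NEG:
        return qi[:0], ti[:0]
    while i > 0 and j > 0:
        if state == 0:
            qi[k] = i - 1
            ti[k] = j - 1
            k += 1
            state = pM[i, j]
            i -= 1
            j -= 1
        elif state == 1:
            state = pIx[i, j]
            i -= 1
        else:
            state = pIy[i, j]
            j -= 1
    return qi[:k][::-1].copy(), ti[:k][::-1].copy()


def _best_mapping_exact(q: np.ndarray, t: np.ndarray, d0: float,
                        l_norm: int) -> tuple[np.ndarray, float]:
    """Exact small-problem solver: evaluate every sequential mapping of at
    least 3 pairs under its least-RMSD superposition. Only feasible for
    chains of a dozen residues or so; larger problems use the heuristic
    seeds."""
    from itertools import combinations

    n, m = len(q), len(t)
    best, best_map = -1.0, None
    for k in range(3, min(n, m) + 1):
        for a in combinations(range(n), k):
            P = q[list(a)]
            for b in combinations(range(m), k):
                Q = t[list(b)]
                try:
                    R, tr, _ = kabsch_superpose(P, Q)
                except AlignmentError:
                    continue
                d = np.linalg.norm(P @ R.T + tr - Q, axis=1)
                s = tm_score_from_distances(d, d0, l_norm)
                if s > best:
                    best, best_map = s, np.column_stack([a, b])
    if best_map is None:
        raise AlignmentError("no superposable mapping found")
    return best_map, best


@dataclass(frozen=True)
class AlignmentResult:
    mapping: np.ndarray      # (k, 2) strictly increasing in both columns
    rotation: np.ndarray     # (3, 3), det +1
    translation: np.ndarray  # (3,)
    tm_score: float
    aligned_length: int


def _score_matrix(q: np.ndarray, t: np.ndarray, R: np.ndarray, tr: np.ndarray,
                  d0: float) -> np.ndarray:
    moved = q @ R.T + tr
    d2 = np.sum((moved[:, None, :] - t[None, :, :]) ** 2, axis=2)
    return 1.0 / (1.0 + d2 / d0 ** 2)


def align_structures(query: ProteinChain | np.ndarray,
                     template: ProteinChain | np.ndarray,
                     l_norm: int | None = None,
                     gap_penalty: float = GAP_PENALTY,
                     enforce_min: bool = True) -> AlignmentResult:
    """Heuristic TM-score alignment of a query chain onto a template.

    Seeds come from gapless threading at every feasible offset and from
    fragment (20-residue window) superpositions; each seed is refined by
    alternating superposition and dynamic-programming remapping until
    stable (at most 30 rounds). The best mapping over all seeds is
    re-scored with the full TM-score rotation search.
    """
    q = query.ca_coords if isinstance(query, ProteinChain) else np.asarray(query, float)
    t = template.ca_coords if isinstance(template, ProteinChain) else np.asarray(template, float)
    n, m = len(q), len(t)
    if enforce_min and (n < MIN_RESIDUES or m < MIN_RESIDUES):
        raise AlignmentError(
            f"chains must have at least {MIN_RESIDUES} residues (got {n} and {m})")
    if n < 3 or m < 3:
        raise AlignmentError("chains of fewer than 3 residues cannot be superposed")
    if l_norm is None:
        l_norm = m
    d0 = tm_d0(l_norm)

    if min(n, m) <= 12:
        best_map, best_quick = _best_mapping_exact(q, t, d0, l_norm)
        score = tm_score(best_map, q, t, l_norm)
        R, tr, _ = kabsch_superpose(q[best_map[:, 0]], t[best_map[:, 1]])
        return AlignmentResult(best_map, R, tr, float(min(max(score, best_quick), 1.0)),
                               len(best_map))

    seeds: list[np.ndarray] = []
    overlap = max(min(n, m, MIN_RESIDUES), 4)
    offsets = range(-(m - overlap), n - overlap + 1)
    stride = max(1, len(offsets) // 60)
    for o in list(offsets)[::stride]:
        lo_q, lo_t = max(o, 0), max(-o, 0)
        k = min(n - lo_q, m - lo_t)
        seeds.append(np.column_stack([np.arange(lo_q, lo_q + k),
                                      np.arange(lo_t, lo_t + k)]))
    w = min(FRAGMENT_LEN, n, m)
    fs = max(1, (max(n, m) - w) // 8)
    for a in range(0, n - w + 1, fs):
        for b in range(0, m - w + 1, fs):
            seeds.append(np.column_stack([np.arange(a, a + w), np.arange(b, b + w)]))

    best_map: np.ndarray | None = None
    best_quick = -1.0
    for seed in seeds:
        for gap in (gap_penalty, 0.0):
            mapping = seed
            prev_key = None
            for _ in range(MAX_ITER):
                if len(mapping) < 3:
                    break
                try:
                    R, tr, _ = kabsch_superpose(q[mapping[:, 0]], t[mapping[:, 1]])
                except AlignmentError:
                    break
                S = _score_matrix(q, t, R, tr, d0)
                qi, ti = _dp_traceback(S, gap)
                if len(qi) == 0:
                    break
                mapping = np.column_stack([qi, ti])
                # score the new mapping under the carrier rotation and under
                # its own least-RMSD fit; either may be the better transform
                d = np.linalg.norm(q[qi] @ R.T + tr - t[ti], axis=1)
                quick = tm_score_from_distances(d, d0, l_norm)
                try:
                    R2, tr2, _ = kabsch_superpose(q[qi], t[ti])
                    d2 = np.linalg.norm(q[qi] @ R2.T + tr2 - t[ti], axis=1)
                    quick = max(quick, tm_score_from_distances(d2, d0, l_norm))
                except AlignmentError:
                    pass
                if quick > best_quick:
                    best_quick = quick
                    best_map = mapping
                key = (qi.tobytes(), ti.tobytes())
                if key == prev_key:
                    break
                prev_key = key

    if best_map is None:
        raise AlignmentError("alignment failed: no valid seed produced a mapping")
    score = tm_score(best_map, q, t, l_norm)
    R, tr, _ = kabsch_superpose(q[best_map[:, 0]], t[best_map[:, 1]])
    return AlignmentResult(best_map, R, tr, float(min(max(score, best_quick), 1.0)),
                           len(best_map))


@dataclass(frozen=True)
class TemplateLibrary:
    """Named OB-fold template chains."""

    templates: tuple[tuple[str, ProteinChain], ...]

    DEFAULT_NAMES = ("1QUQ_A", "1V1Q_A", "4GS3_A", "3ULL_A", "1O7I_A", "1JMC_A")

    def __post_init__(self) -> None:
        for name, ch in self.templates:
            if ch.length < MIN_RESIDUES:
                raise ValueError(f"template {name} has fewer than {MIN_RESIDUES} residues")

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    @classmethod
    def from_manifest(cls, path: str | Path) -> "TemplateLibrary":
        """Load templates from a TSV manifest.

        Columns: name, path, chain, residue_start, residue_end (the range
        columns may be blank for the whole chain; they select a single
        domain of multi-domain templates such as 1JMC_A by author residue
        numbering, inclusive).
        """
        templates = []
        base = Path(path).parent
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#") or line.startswith("name\t"):
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise ValueError(f"{path}:{lineno}: need name, path, chain columns")
                name, fpath, chain_id = cols[0], cols[1], cols[2]
                start = int(cols[3]) if len(cols) > 3 and cols[3].strip() else None
                end = int(cols[4]) if len(cols) > 4 and cols[4].strip() else None
                p = Path(fpath)
                if not p.is_absolute():
                    p = base / p
                chain = select_chain(read_structure(p), chain_id or None)
                if start is not None or end is not None:
                    chain = slice_chain(chain, start, end)
                templates.append((name, chain))
        return cls(tuple(templates))


def slice_chain(chain: ProteinChain, start: int | None, end: int | None) -> ProteinChain:
    """Restrict a chain to an author residue-number range (inclusive)."""
    lo = -np.inf if start is None else start
    hi = np.inf if end is None else end
    keep_res = [i for i, (num, _) in enumerate(chain.residues) if lo <= num <= hi]
    kept_nums = {chain.residues[i][0] for i in keep_res}
    atoms = tuple(a for a in chain.atoms if a.residue_index in kept_nums)
    return ProteinChain(
        chain_id=chain.chain_id,
        atoms=atoms,
        residues=tuple(chain.residues[i] for i in keep_res),
        ca_coords=chain.ca_coords[keep_res],
    )


def obfold_feature(query: ProteinChain, library: TemplateLibrary) -> float:
    """Maximal TM-score of the query over the OB-fold template library."""
    if len(library) == 0:
        raise ValueError("empty template library")
    best = None
    for name, tmpl in library:
        try:
            res = align_structures(query, tmpl)
        except AlignmentError as exc:
            logger.warning("template %s skipped: %s", name, exc)
            continue
        if best is None or res.tm_score > best:
            best = res.tm_score
    if best is None:
        raise AlignmentError("no template could be aligned against the query")
    return best


def per_template_scores(query: ProteinChain, library: TemplateLibrary) -> dict[str, float]:
    out = {}
    for name, tmpl in library:
        try:
            out[name] = align_structures(query, tmpl).tm_score
        except AlignmentError:
            out[name] = float("nan")
    return out
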
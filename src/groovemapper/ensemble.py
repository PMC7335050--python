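"""Conformer-population analysis of coordinate ensembles.

Frames are CA coordinates under an atom mask.  The pipeline is: best-fit
(Kabsch) pairwise RMSD -> average-linkage agglomerative clustering terminated
when the minimum inter-cluster distance exceeds ``epsilon`` -> population of
the most populated cluster, used as a relative stability statistic.

The default mask follows the receptor segments 102-125 and 147-177 plus
peptide residues 4-23, CA atoms only, with the clustering cutoff
``epsilon = 2.0`` angstrom.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AtomMask",
    "Ensemble",
    "ClusterResult",
    "DEFAULT_EPSILON",
    "default_mask",
    "read_ensemble",
    "read_ensemble_table",
    "read_ensemble_pdb",
    "write_ensemble_table",
    "write_ensemble_pdb",
    "kabsch_superpose",
    "pairwise_rmsd",
    "average_linkage_cluster",
    "top_population",
    "compare_sites",
]

DEFAULT_EPSILON = 2.0  # angstrom
MAX_FRAMES = 20_000


@dataclass(frozen=True)
class AtomMask:
    """CA-only mask: (role, first_residue, last_residue) segments, inclusive."""

    segments: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        by_role: dict[str, list[tuple[int, int]]] = {}
        for role, lo, hi in self.segments:
            if role not in ("receptor", "peptide"):
                raise ValueError(f"unknown mask role {role!r}")
            if hi < lo:
                raise ValueError(f"empty mask segment {lo}-{hi}")
            by_role.setdefault(role, []).append((lo, hi))
        for role, ranges in by_role.items():
            ranges.sort()
            for (a, b), (c, d) in zip(ranges, ranges[1:]):
                if c <= b:
                    raise ValueError(f"overlapping {role} mask segments")

    def residues(self, role: str) -> list[int]:
        out: list[int] = []
        for r, lo, hi in self.segments:
            if r == role:
                out.extend(range(lo, hi + 1))
        return sorted(out)

    @property
    def n_atoms(self) -> int:
        return len(self.residues("receptor")) + len(self.residues("peptide"))


def default_mask() -> AtomMask:
    return AtomMask(
        segments=(("receptor", 102, 125), ("receptor", 147, 177), ("peptide", 4, 23))
    )


@dataclass
class Ensemble:
    """Masked CA frames, shape (n_frames, n_atoms, 3), angstrom."""

    frames: np.ndarray
    frame_ids: Optional[list] = None
    mask: Optional[AtomMask] = None
    interval_ps: Optional[float] = None
    true_labels: Optional[np.ndarray] = None  # generator ground truth, evaluation only

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in ensemble")
        if self.frame_ids is None:
            self.frame_ids = list(range(len(self.frames)))
        if len(self.frame_ids) != len(self.frames):
            raise ValueError("frame_ids length mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster index per frame, 0 = most populated
    populations: list[float]  # descending
    epsilon: float
    representatives: list[int]  # medoid frame index per cluster
    linkage: str = "average"

    @property
    def n_clusters(self) -> int:
        return len(self.populations)

    def to_dict(self) -> dict:
        return {
            "n_frames": int(len(self.labels)),
            "n_clusters": self.n_clusters,
            "epsilon": self.epsilon,
            "linkage": self.linkage,
            "populations": self.populations,
            "representatives": self.representatives,
        }


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_ensemble_table(path: str | Path) -> Ensemble:
    """Read a whitespace table with columns: frame atom x y z (already masked)."""
    path = Path(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 5:
        raise ValueError(f"{path}: expected columns frame atom x y z")
    frames_col = data[:, 0].astype(int)
    atoms_col = data[:, 1].astype(int)
    frame_ids = sorted(set(frames_col.tolist()))
    n_atoms = len(set(atoms_col.tolist()))
    coords = np.empty((len(frame_ids), n_atoms, 3), float)
    index = {f: i for i, f in enumerate(frame_ids)}
    atom_index = {a: i for i, a in enumerate(sorted(set(atoms_col.tolist())))}
    seen = np.zeros((len(frame_ids), n_atoms), bool)
    for row in data:
        fi, ai = index[int(row[0])], atom_index[int(row[1])]
        coords[fi, ai] = row[2:5]
        seen[fi, ai] = True
    if not seen.all():
        bad = np.argwhere(~seen)[0]
        raise ValueError(f"{path}: frame {frame_ids[bad[0]]} missing atom {bad[1]}")
    return Ensemble(frames=coords, frame_ids=frame_ids)


def write_ensemble_table(ensemble: Ensemble, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# frame atom x y z\n")
        for fi, frame in zip(ensemble.frame_ids, ensemble.frames):
            for ai, (x, y, z) in enumerate(frame):
                fh.write(f"{fi} {ai} {x:.4f} {y:.4f} {z:.4f}\n")
    return path


def read_ensemble_pdb(
    path: str | Path,
    mask: Optional[AtomMask] = None,
    receptor_chain: str = "A",
    peptide_chain: str = "B",
) -> Ensemble:
    """Read a multi-model PDB, extracting masked CA atoms.

    Atom order is fixed: receptor segments in sequence order, then peptide.
    A model missing a masked CA is an error naming the frame and residue.
    """
    from Bio.PDB import PDBParser

    if mask is None:
        mask = default_mask()
    path = Path(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    wanted = [("receptor", receptor_chain, r) for r in mask.residues("receptor")]
    wanted += [("peptide", peptide_chain, r) for r in mask.residues("peptide")]
    frames = []
    for mi, model in enumerate(structure):
        chains = {c.id: c for c in model}
        coords = []
        for role, chain_id, rid in wanted:
            chain = chains.get(chain_id)
            atom = None
            if chain is not None:
                key = (" ", rid, " ")
                if key in chain and "CA" in chain[key]:
                    atom = chain[key]["CA"]
            if atom is None:
                raise ValueError(
                    f"{path}: model {mi} missing CA of {role} residue {rid} "
                    f"(chain {chain_id})"
                )
            coords.append(atom.get_coord())
        frames.append(np.asarray(coords, float))
    if not frames:
        raise ValueError(f"{path}: no models found")
    return Ensemble(frames=np.stack(frames), mask=mask)


def write_ensemble_pdb(
    ensemble: Ensemble,
    path: str | Path,
    receptor_chain: str = "A",
    peptide_chain: str = "B",
) -> Path:
    """Write frames as a CA-only multi-model PDB.

    When the ensemble has a mask, atoms get the masked residue numbers and
    roles map to the two chains; otherwise all atoms go to the receptor chain
    numbered from 1.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if ensemble.mask is not None:
        rec = ensemble.mask.residues("receptor")
        pep = ensemble.mask.residues("peptide")
        atom_meta = [(receptor_chain, r) for r in rec] + [(peptide_chain, r) for r in pep]
        if len(atom_meta) != ensemble.n_atoms:
            raise ValueError("mask size does not match frame atom count")
    else:
        atom_meta = [(receptor_chain, i + 1) for i in range(ensemble.n_atoms)]
    with open(path, "w") as fh:
        for mi, frame in enumerate(ensemble.frames, start=1):
            fh.write(f"MODEL     {mi:4d}\n")
            serial = 1
            for (chain, rid), (x, y, z) in zip(atom_meta, frame):
                fh.write(
                    f"ATOM  {serial:5d}  CA  ALA {chain}{rid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
                serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")
    return path


def read_ensemble(path: str | Path, mask: Optional[AtomMask] = None, **kwargs) -> Ensemble:
    """Dispatch on extension: ``.pdb`` -> multi-model PDB, else coordinate table."""
    path = Path(path)
    if path.suffix.lower() in (".pdb", ".ent"):
        return read_ensemble_pdb(path, mask=mask, **kwargs)
    return read_ensemble_table(path)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of X onto Y (proper rotations only).

    Returns ``(R, t, rmsd)`` with ``R @ x + t`` the fitted image of ``x``;
    ``rmsd`` is the minimum over all proper rotations and translations.
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both have shape (n_atoms, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms")
    xm, ym = X.mean(0), Y.mean(0)
    Xc, Yc = X - xm, Y - ym
    scale = max(np.abs(Xc).max(), np.abs(Yc).max(), 1e-300)
    for M in (Xc, Yc):
        sv = np.linalg.svd(M, compute_uv=False)
        if sv[1] <= 1e-9 * scale:
            raise ValueError("degenerate (collinear or coincident) coordinates")
    H = Xc.T @ Yc
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = ym - R @ xm
    # explicit residuals: immune to the cancellation of the trace formula
    msd = ((Xc @ R.T - Yc) ** 2).sum() / n
    return R, t, float(np.sqrt(max(msd, 0.0)))


def _sym3_eigvals(K: np.ndarray) -> np.ndarray:
    """Closed-form eigenvalues of batched symmetric 3x3 matrices, ascending."""
    a, b, c = K[..., 0, 0], K[..., 1, 1], K[..., 2, 2]
    d, e, f = K[..., 0, 1], K[..., 0, 2], K[..., 1, 2]
    q = (a + b + c) / 3.0
    p1 = d**2 + e**2 + f**2
    p2 = (a - q) ** 2 + (b - q) ** 2 + (c - q) ** 2 + 2.0 * p1
    p = np.sqrt(np.maximum(p2 / 6.0, 0.0))
    safe = p > 0
    ps = np.where(safe, p, 1.0)
    Bq = (K - q[..., None, None] * np.eye(3)) / ps[..., None, None]
    detB = (
        Bq[..., 0, 0] * (Bq[..., 1, 1] * Bq[..., 2, 2] - Bq[..., 1, 2] ** 2)
        - Bq[..., 0, 1] * (Bq[..., 0, 1] * Bq[..., 2, 2] - Bq[..., 1, 2] * Bq[..., 0, 2])
        + Bq[..., 0, 2] * (Bq[..., 0, 1] * Bq[..., 1, 2] - Bq[..., 1, 1] * Bq[..., 0, 2])
    )
    r = np.clip(detB / 2.0, -1.0, 1.0)
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    out = np.stack([e3, e2, e1], axis=-1)
    out[~safe] = q[~safe][..., None]
    return out


def _det3(H: np.ndarray) -> np.ndarray:
    return (
        H[..., 0, 0] * (H[..., 1, 1] * H[..., 2, 2] - H[..., 1, 2] * H[..., 2, 1])
        - H[..., 0, 1] * (H[..., 1, 0] * H[..., 2, 2] - H[..., 1, 2] * H[..., 2, 0])
        + H[..., 0, 2] * (H[..., 1, 0] * H[..., 2, 1] - H[..., 1, 1] * H[..., 2, 0])
    )


def pairwise_rmsd(ensemble: Ensemble, chunk: int = 64) -> np.ndarray:
    """Symmetric matrix of best-fit CA RMSDs between all frame pairs.

    Each entry is an independent Kabsch fit over the masked atoms (unweighted).
    Batched via a closed-form 3x3 eigen-solve; agrees with
    :func:`kabsch_superpose` to ~1e-6 angstrom.
    """
    F = ensemble.n_frames
    if F < 2:
        raise ValueError("need at least 2 frames")
    if F > MAX_FRAMES:
        raise ValueError(f"ensemble exceeds the {MAX_FRAMES}-frame cap")
    X = ensemble.frames - ensemble.frames.mean(axis=1, keepdims=True)
    n = ensemble.n_atoms
    G = (X**2).sum(axis=(1, 2))
    D = np.zeros((F, F), float)
    for i0 in range(0, F, chunk):
        A = X[i0 : i0 + chunk]
        H = np.einsum("ink,jnl->ijkl", A, X, optimize=True)
        eig = _sym3_eigvals(np.einsum("...ki,...kj->...ij", H, H))
        sv = np.sqrt(np.maximum(eig, 0.0))
        sign = np.sign(_det3(H))
        sign[sign == 0] = 1.0
        corr = sv[..., 2] + sv[..., 1] + sign * sv[..., 0]
        d2 = (G[i0 : i0 + chunk, None] + G[None, :] - 2.0 * corr) / n
        D[i0 : i0 + chunk] = np.sqrt(np.maximum(d2, 0.0))
    D = 0.5 * (D + D.T)  # symmetrize away round-off
    np.fill_diagonal(D, 0.0)
    if F <= 100:
        # best-fit RMSD under independent fits is not a metric; a high rate of
        # triangle violations on small inputs usually signals bad coordinates
        frac = triangle_violation_fraction(D)
        if frac > 0.10:
            import warnings

            warnings.warn(
                f"{frac:.1%} of frame triples violate the triangle inequality",
                stacklevel=2,
            )
    return D


def triangle_violation_fraction(D: np.ndarray, tol: float = 1e-9) -> float:
    """Fraction of unordered frame triples whose longest side exceeds the
    sum of the other two by more than ``tol``."""
    D = np.asarray(D, float)
    n = D.shape[0]
    if n < 3:
        return 0.0
    i, j, k = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
    sel = (i < j) & (j < k)
    a, b, c = D[i[sel], j[sel]], D[i[sel], k[sel]], D[j[sel], k[sel]]
    longest = np.maximum(a, np.maximum(b, c))
    viol = 2.0 * longest > a + b + c + tol
    return float(viol.mean())


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _validate_distance_matrix(dist: np.ndarray) -> np.ndarray:
    D = np.asarray(dist, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix has non-finite entries")
    if (D < 0).any():
        raise ValueError("distance matrix has negative entries")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    return 0.5 * (D + D.T)


def average_linkage_cluster(dist: np.ndarray, epsilon: float) -> ClusterResult:
    """Agglomerative average-linkage clustering terminated at ``epsilon``.

    Repeatedly merges the closest pair of clusters, where inter-cluster
    distance is the unweighted mean of all cross-pair distances, until the
    minimum inter-cluster distance exceeds ``epsilon``.  Clusters are
    identified by their lowest-numbered member; distance ties are broken by
    the lexicographically lowest (i, j) slot pair.  Output clusters are
    ordered by descending population (ties: lowest member index), with the
    medoid of each cluster as its representative.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    D0 = _validate_distance_matrix(dist)
    n = D0.shape[0]
    if n > MAX_FRAMES:
        raise ValueError(f"matrix exceeds the {MAX_FRAMES}-frame cap")
    work = D0.copy()
    np.fill_diagonal(work, np.inf)
    active = np.ones(n, bool)
    size = np.ones(n, dtype=np.int64)
    members: list[list[int]] = [[i] for i in range(n)]

    rowmin = work.min(axis=1) if n > 1 else np.full(n, np.inf)
    rowarg = work.argmin(axis=1) if n > 1 else np.zeros(n, int)

    def recompute_row(k: int) -> None:
        cols = np.flatnonzero(active)
        cols = cols[cols != k]
        if cols.size == 0:
            rowmin[k], rowarg[k] = np.inf, k
            return
        vals = work[k, cols]
        a = int(np.argmin(vals))
        rowmin[k], rowarg[k] = vals[a], int(cols[a])

    n_active = n
    while n_active > 1:
        act = np.flatnonzero(active)
        pos = int(np.argmin(rowmin[act]))
        i = int(act[pos])
        j = int(rowarg[i])
        d = rowmin[i]
        if d > epsilon:
            break
        a, b = (i, j) if i < j else (j, i)
        sa, sb = size[a], size[b]
        others = act[(act != a) & (act != b)]
        merged = (sa * work[a, others] + sb * work[b, others]) / (sa + sb)
        work[a, others] = merged
        work[others, a] = merged
        work[a, b] = work[b, a] = np.inf
        work[b, others] = np.inf
        work[others, b] = np.inf
        active[b] = False
        size[a] += sb
        members[a].extend(members[b])
        members[b] = []
        rowmin[b], rowarg[b] = np.inf, b
        n_active -= 1
        recompute_row(a)
        for k in others:
            k = int(k)
            if rowarg[k] == a or rowarg[k] == b:
                recompute_row(k)
            else:
                v = work[k, a]
                if v < rowmin[k] or (v == rowmin[k] and a < rowarg[k]):
                    rowmin[k], rowarg[k] = v, a

    slots = [s for s in np.flatnonzero(active)]
    order = sorted(slots, key=lambda s: (-size[s], min(members[s])))
    labels = np.empty(n, dtype=int)
    populations: list[float] = []
    representatives: list[int] = []
    for new_label, s in enumerate(order):
        mem = sorted(members[s])
        labels[mem] = new_label
        populations.append(len(mem) / n)
        sub = D0[np.ix_(mem, mem)]
        representatives.append(int(mem[int(np.argmin(sub.sum(axis=1)))]))
    return ClusterResult(
        labels=labels,
        populations=populations,
        epsilon=float(epsilon),
        representatives=representatives,
    )


def top_population(result: ClusterResult) -> tuple[float, int]:
    """Population of the most populated cluster and its medoid frame index."""
    return result.populations[0], result.representatives[0]


# ---------------------------------------------------------------------------
# Site comparison
# ---------------------------------------------------------------------------

def _bootstrap_top_population(
    labels: np.ndarray, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(labels)
    n_clusters = int(labels.max()) + 1
    out = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.integers(0, n, size=n)
        counts = np.bincount(labels[draw], minlength=n_clusters)
        out[b] = counts.max() / n
    return out


def compare_sites(
    ensembles: dict[str, Ensemble],
    epsilon: float = DEFAULT_EPSILON,
    n_boot: int = 200,
    seed: int = 0,
) -> dict:
    """Rank named ensembles by top-cluster population with bootstrap 95% CIs.

    Bootstrap resamples frames (labels) with replacement.  Adjacent ranks
    whose intervals overlap are flagged inconclusive.
    """
    if len(ensembles) < 2:
        raise ValueError("need at least 2 ensembles to compare")
    rng = np.random.default_rng(seed)
    entries = []
    for name in sorted(ensembles):
        ens = ensembles[name]
        result = average_linkage_cluster(pairwise_rmsd(ens), epsilon)
        pop, medoid = top_population(result)
        boots = _bootstrap_top_population(result.labels, n_boot, rng)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        entries.append(
            {
                "name": name,
                "top_population": pop,
                "ci95": [float(lo), float(hi)],
                "n_clusters": result.n_clusters,
                "representative_frame": medoid,
            }
        )
    entries.sort(key=lambda e: -e["top_population"])
    warnings: list[str] = []
    for e1, e2 in zip(entries, entries[1:]):
        if e2["ci95"][1] >= e1["ci95"][0]:
            warnings.append(
                f"ranking of {e1['name']} over {e2['name']} inconclusive "
                f"(bootstrap intervals overlap)"
            )
    return {
        "epsilon": epsilon,
        "n_boot": n_boot,
        "seed": seed,
        "ranking": entries,
        "warnings": warnings,
        "conclusive": not warnings,
    }
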
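"""Synthetic inputs with known ground truth for every analysis stage.

All generators draw from a single explicit seed (no global RNG state) and are
byte-deterministic.  The titration generator models the two perturbation
classes seen in HSQC titrations: focal dose-responsive shifts and intensity
loss toward the noise floor.  Peak displacement follows a saturation-like
dose response, r/(r+1) normalised so the highest ratio reaches the declared
maximum shift exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assays import BindingIsotherm, ReleaseTrace
from .csp import Peak, PeakList, TitrationSeries, write_peak_list
from .ensemble import Ensemble, kabsch_superpose

__all__ = [
    "PerturbationSpec",
    "EnsembleSpec",
    "gen_peak_titration",
    "gen_ensemble",
    "gen_isotherm",
    "gen_release_traces",
    "make_separated_centers",
    "write_titration",
    "write_isotherm_csv",
    "write_trace_csv",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """Ground-truth perturbation for one residue across the titration."""

    residue_id: int
    kind: str = "none"  # shift | attenuate | none
    max_dH: float = 0.0  # 1H shift (ppm) at the highest ratio
    max_dN: float = 0.0  # 15N shift (ppm) at the highest ratio
    intensity_floor: float = 1.0  # fraction of apo intensity at the highest ratio

    def __post_init__(self) -> None:
        if self.kind not in ("shift", "attenuate", "none"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.max_dH < 0 or self.max_dN < 0:
            raise ValueError("max_dH and max_dN must be non-negative")
        if not (0.0 <= self.intensity_floor <= 1.0):
            raise ValueError("intensity_floor must be in [0, 1]")


@dataclass
class EnsembleSpec:
    """Mixture of rigid conformer clusters with known populations."""

    n_frames: int
    centers: Sequence[np.ndarray]
    populations: Sequence[float]
    jitter_sd: float = 0.0  # isotropic per-atom displacement, angstrom
    rigid_transform: bool = False

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be positive")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        self.centers = [np.asarray(c, float) for c in self.centers]
        shapes = {c.shape for c in self.centers}
        if len(shapes) != 1:
            raise ValueError(f"conformer centers differ in shape: {shapes}")
        pops = np.asarray(self.populations, float)
        if len(pops) != len(self.centers):
            raise ValueError("populations/centers length mismatch")
        if (pops < 0).any() or not np.isclose(pops.sum(), 1.0):
            raise ValueError("populations must be non-negative and sum to 1")


def _saturation_fraction(ratio: float, ratio_max: float) -> float:
    # fast-exchange-like dose response, normalised to reach 1 at ratio_max
    return (ratio / (1.0 + ratio)) / (ratio_max / (1.0 + ratio_max))


def gen_peak_titration(
    n_residues: int,
    specs: Sequence[PerturbationSpec],
    ratios: Sequence[float],
    noise_sd: float = 0.0,
    intensity_noise: float = 0.0,
    seed: int = 0,
) -> TitrationSeries:
    """Generate an apo peak list plus titration points with known ground truth.

    ``ratios`` must be strictly increasing and start at 0 (the apo point).
    Apo peaks fall in realistic ppm windows (1H 6-10, 15N 100-135).  At each
    point every residue is displaced along its spec by the saturation
    fraction of the ratio, its intensity scaled toward ``intensity_floor``
    (geometric decay), and Gaussian noise of ``noise_sd`` ppm added to both
    coordinates; intensities get multiplicative noise of ``intensity_noise``.
    """
    ratios = list(ratios)
    if not ratios or ratios[0] != 0:
        raise ValueError("ratios must start at 0 (the apo point)")
    if any(b <= a for a, b in zip(ratios, ratios[1:])):
        raise ValueError("ratios must be strictly increasing")
    if len(ratios) < 2:
        raise ValueError("need at least one titration point beyond apo")
    ids = [s.residue_id for s in specs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate residue_id in perturbation specs")
    if any(not (1 <= i <= n_residues) for i in ids):
        raise ValueError("spec residue_id outside 1..n_residues")

    rng = np.random.default_rng(seed)
    apo_dH = rng.uniform(6.0, 10.0, n_residues)
    apo_dN = rng.uniform(100.0, 135.0, n_residues)
    apo_int = rng.uniform(0.5e6, 2.0e6, n_residues)
    apo = PeakList(
        peaks=[
            Peak(residue_id=i + 1, dH=float(apo_dH[i]), dN=float(apo_dN[i]),
                 intensity=float(apo_int[i]))
            for i in range(n_residues)
        ]
    )
    spec_by_id = {s.residue_id: s for s in specs}
    rmax = ratios[-1]
    points: list[tuple[float, PeakList]] = []
    for r in ratios[1:]:
        s = _saturation_fraction(r, rmax)
        peaks: list[Peak] = []
        for i in range(n_residues):
            rid = i + 1
            sp = spec_by_id.get(rid)
            dH, dN, inten = apo_dH[i], apo_dN[i], apo_int[i]
            if sp is not None and sp.kind == "shift":
                dH = dH + sp.max_dH * s
                dN = dN + sp.max_dN * s
            elif sp is not None and sp.kind == "attenuate":
                inten = inten * sp.intensity_floor**s
            nH, nN = rng.normal(0.0, 1.0, 2) if noise_sd > 0 else (0.0, 0.0)
            mult = 1.0 + intensity_noise * rng.normal() if intensity_noise > 0 else 1.0
            peaks.append(
                Peak(
                    residue_id=rid,
                    dH=float(dH + noise_sd * nH),
                    dN=float(dN + noise_sd * nN),
                    intensity=float(max(inten * mult, 0.0)),
                )
            )
        points.append((float(r), PeakList(peaks=peaks)))
    return TitrationSeries(apo=apo, points=points)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_separated_centers(
    n_centers: int,
    n_atoms: int,
    min_separation: float,
    seed: int = 0,
    scale: float = 5.0,
    max_tries: int = 1000,
) -> list[np.ndarray]:
    """Random conformer centers whose pairwise best-fit RMSD exceeds a floor.

    Centers are independent Gaussian clouds; candidates too close (in
    superposed RMSD) to an accepted center are rejected and redrawn.
    """
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = rng.normal(scale=scale, size=(n_atoms, 3))
        if all(kabsch_superpose(cand, c)[2] > min_separation for c in centers):
            centers.append(cand)
        if len(centers) == n_centers:
            return centers
    raise RuntimeError("could not place separated centers; increase scale or tries")


def gen_ensemble(spec: EnsembleSpec, seed: int = 0) -> Ensemble:
    """Draw frames from the conformer mixture; true labels kept for evaluation.

    Each frame picks a center by the population vector, gets isotropic
    Gaussian jitter of ``jitter_sd`` per coordinate, and (optionally) a random
    proper rotation plus translation.
    """
    rng = np.random.default_rng(seed)
    centers = np.stack(spec.centers)
    labels = rng.choice(len(centers), size=spec.n_frames, p=np.asarray(spec.populations))
    frames = centers[labels].astype(float)
    if spec.jitter_sd > 0:
        frames = frames + rng.normal(0.0, spec.jitter_sd, frames.shape)
    if spec.rigid_transform:
        for k in range(spec.n_frames):
            R = _random_rotation(rng)
            t = rng.uniform(-20.0, 20.0, 3)
            frames[k] = frames[k] @ R.T + t
    return Ensemble(frames=frames, true_labels=labels)


def gen_isotherm(
    kd: float,
    rmax: float,
    concentrations: Sequence[float],
    noise_frac: float = 0.0,
    seed: int = 0,
    analyte: str = "synthetic",
    ligand: str = "synthetic",
) -> BindingIsotherm:
    """Langmuir 1:1 steady-state isotherm with Gaussian noise of sd = noise_frac*rmax."""
    if kd <= 0 or rmax <= 0:
        raise ValueError("kd and rmax must be positive")
    conc = np.asarray(list(concentrations), float)
    if conc.size == 0:
        raise ValueError("empty concentration list")
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    resp = rmax * conc / (kd + conc)
    if noise_frac > 0:
        resp = resp + rng.normal(0.0, noise_frac * rmax, conc.shape)
    return BindingIsotherm(
        concentrations=conc, responses=resp, analyte=analyte, ligand=ligand
    )


def gen_release_traces(
    true_release: float,
    f_blank: float = 20.0,
    f_triton: float = 120.0,
    n_points: int = 100,
    noise_sd: float = 0.0,
    seed: int = 0,
    dt_s: float = 10.0,
    condition: str = "synthetic",
) -> ReleaseTrace:
    """Dequenching traces whose sample plateau encodes a known release fraction.

    The sample channel ramps linearly to its plateau at half the trace and
    sits exactly on ``f_blank + true_release*(f_triton - f_blank)`` afterward,
    so windowed plateau extraction recovers ``true_release`` at zero noise.
    """
    if f_triton <= f_blank:
        raise ValueError("f_triton must exceed f_blank")
    if not (0.0 <= true_release <= 1.0):
        raise ValueError("true_release must be in [0, 1]")
    if n_points < 2:
        raise ValueError("need at least 2 time points")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt_s
    ramp = np.minimum(1.0, t / (0.5 * t[-1]))
    plateau = f_blank + true_release * (f_triton - f_blank)
    sample = f_blank + (plateau - f_blank) * ramp
    blank = np.full(n_points, f_blank)
    triton = np.full(n_points, f_triton)
    if noise_sd > 0:
        sample = sample + rng.normal(0.0, noise_sd, n_points)
        blank = blank + rng.normal(0.0, noise_sd, n_points)
        triton = triton + rng.normal(0.0, noise_sd, n_points)
    return ReleaseTrace(
        time=t, f_sample=sample, f_blank=blank, f_triton=triton, condition=condition
    )


# ---------------------------------------------------------------------------
# Writers (same formats the analysis stages read)
# ---------------------------------------------------------------------------

def write_titration(series: TitrationSeries, outdir: str | Path) -> dict[str, Path]:
    """Write Sparky-style peak lists: apo.list plus point_<ratio>.list per point."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"apo": write_peak_list(series.apo, outdir / "apo.list")}
    for ratio, peaks in series.points:
        tag = f"{ratio:g}".replace(".", "p")
        paths[f"ratio_{ratio:g}"] = write_peak_list(peaks, outdir / f"point_{tag}.list")
    return paths


def write_isotherm_csv(iso: BindingIsotherm, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"conc_nM": iso.concentrations, "response_RU": iso.responses}
    ).to_csv(path, index=False, float_format="%.6f")
    return path


def write_trace_csv(trace: ReleaseTrace, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time_s": trace.time,
            "F_sample": trace.f_sample,
            "F_blank": trace.f_blank,
            "F_triton": trace.f_triton,
        }
    ).to_csv(path, index=False, float_format="%.6f")
    return path
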
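"""Chemical shift perturbation (CSP) analysis of HSQC titration series.

Peak lists are Sparky-style text files.  The combined per-residue CSP is

    csp = sqrt((ddH**2 + ddN**2 / 25) / 2)

where ``ddH`` and ``ddN`` are the amide 1H and 15N shift changes between the
apo spectrum and the highest titration point.  Residues are classified as
``attenuated`` (peak intensity fell to/below the noise floor), ``shifted``
(csp strictly above the mean+1SD threshold) or ``unperturbed``.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "PeakList",
    "TitrationSeries",
    "CSPRecord",
    "CSPProfile",
    "read_peak_list",
    "write_peak_list",
    "match_peaks",
    "compute_csp",
    "profile_titration",
    "classify_residues",
]

# 15N axis is compressed by this factor inside combined-shift distances.
N_SCALE = 5.0

_ASSIGNMENT_RE = re.compile(r"^[A-Za-z]{1,3}(\d+)[A-Za-z0-9'\-]*$")


@dataclass
class Peak:
    """One backbone amide cross-peak of a 1H,15N-HSQC spectrum."""

    residue_id: int
    dH: float  # 1H chemical shift, ppm
    dN: float  # 15N chemical shift, ppm
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.intensity is not None and self.intensity < 0:
            raise ValueError(f"negative intensity for residue {self.residue_id}")


@dataclass
class PeakList:
    """Assigned peaks plus any rows whose assignment could not be parsed."""

    peaks: list[Peak] = field(default_factory=list)
    unassigned: list[tuple[float, float, Optional[float]]] = field(default_factory=list)
    source: Optional[str] = None

    def __post_init__(self) -> None:
        ids = [p.residue_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate residue assignments in peak list: {dup}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_residue(self) -> dict[int, Peak]:
        return {p.residue_id: p for p in self.peaks}

    @property
    def has_intensity(self) -> bool:
        return all(p.intensity is not None for p in self.peaks) and bool(self.peaks)


@dataclass
class TitrationSeries:
    """Apo peak list plus perturbed lists at increasing protein:peptide ratios."""

    apo: PeakList
    points: list[tuple[float, PeakList]]

    def __post_init__(self) -> None:
        ratios = [r for r, _ in self.points]
        if any(b <= a for a, b in zip(ratios, ratios[1:])):
            raise ValueError(f"titration ratios must be strictly increasing: {ratios}")
        if ratios and ratios[0] <= 0:
            raise ValueError("titration points must have ratio > 0 (ratio 0 is the apo list)")

    @property
    def ratios(self) -> list[float]:
        return [r for r, _ in self.points]

    @property
    def highest(self) -> tuple[float, PeakList]:
        if not self.points:
            raise ValueError("titration series has no points beyond apo")
        return self.points[-1]


@dataclass
class CSPRecord:
    residue_id: int
    delta_dH: float
    delta_dN: float
    csp: float
    intensity_ratio: Optional[float]
    csp_by_ratio: Optional[list[float]] = None
    dose_responsive: Optional[bool] = None
    klass: str = "unclassified"  # shifted | attenuated | unperturbed | unassigned


@dataclass
class CSPProfile:
    records: list[CSPRecord]
    noise_floor: float
    mean_csp: float = 0.0
    sd_csp: float = 0.0
    threshold: float = 0.0
    intensity_available: bool = True

    def by_residue(self) -> dict[int, CSPRecord]:
        return {r.residue_id: r for r in self.records}

    def residues_in_class(self, klass: str) -> set[int]:
        return {r.residue_id for r in self.records if r.klass == klass}

    @property
    def perturbed(self) -> set[int]:
        return self.residues_in_class("shifted") | self.residues_in_class("attenuated")

    @property
    def assigned(self) -> set[int]:
        return {r.residue_id for r in self.records if r.klass != "unassigned"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue_id": [r.residue_id for r in self.records],
                "delta_dH": [r.delta_dH for r in self.records],
                "delta_dN": [r.delta_dN for r in self.records],
                "csp": [r.csp for r in self.records],
                "intensity_ratio": [r.intensity_ratio for r in self.records],
                "dose_responsive": [r.dose_responsive for r in self.records],
                "class": [r.klass for r in self.records],
            }
        ).sort_values("residue_id", ignore_index=True)

    def summary(self) -> dict:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.klass] = counts.get(r.klass, 0) + 1
        return {
            "n_records": len(self.records),
            "mean_csp": self.mean_csp,
            "sd_csp": self.sd_csp,
            "threshold": self.threshold,
            "noise_floor": self.noise_floor,
            "counts": counts,
        }

    def write(self, outdir: str | Path, stem: str = "csp_profile") -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        csv_path = outdir / f"{stem}.csv"
        json_path = outdir / f"{stem}.json"
        self.to_frame().to_csv(csv_path, index=False)
        json_path.write_text(json.dumps(self.summary(), indent=2, sort_keys=True) + "\n")
        return csv_path, json_path


def read_profile_csv(path: str | Path, noise_floor: float = 0.1) -> CSPProfile:
    """Rebuild a CSPProfile from a previously written profile CSV."""
    df = pd.read_csv(path)
    records = []
    for row in df.to_dict("records"):
        ratio = row.get("intensity_ratio")
        if ratio is not None and pd.isna(ratio):
            ratio = None
        records.append(
            CSPRecord(
                residue_id=int(row["residue_id"]),
                delta_dH=float(row["delta_dH"]),
                delta_dN=float(row["delta_dN"]),
                csp=float(row["csp"]),
                intensity_ratio=None if ratio is None else float(ratio),
                klass=str(row.get("class", "unclassified")),
            )
        )
    profile = CSPProfile(records=records, noise_floor=noise_floor)
    _set_threshold(profile)
    return profile


def parse_assignment(token: str) -> Optional[int]:
    """Extract the residue number from a Sparky assignment token (``G82N-H`` -> 82)."""
    m = _ASSIGNMENT_RE.match(token)
    return int(m.group(1)) if m else None


def read_peak_list(path: str | Path) -> PeakList:
    """Read a Sparky-style peak list.

    Data rows are ``<assignment> <w1/15N ppm> <w2/1H ppm> [height]``.  Rows
    whose assignment token carries no residue number are collected as
    unassigned.  A header line containing ``Assignment`` is skipped.
    """
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise ValueError(f"cannot read peak list {path}: {exc}") from exc

    peaks: list[Peak] = []
    unassigned: list[tuple[float, float, Optional[float]]] = []
    any_height = False
    missing_height = False
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("assignment"):
            continue
        fields = line.split()
        if len(fields) < 3:
            continue
        try:
            w1 = float(fields[1])  # 15N
            w2 = float(fields[2])  # 1H
        except ValueError:
            continue
        height: Optional[float] = None
        if len(fields) >= 4:
            try:
                height = abs(float(fields[3]))
                any_height = True
            except ValueError:
                height = None
        if height is None:
            missing_height = True
        rid = parse_assignment(fields[0])
        if rid is None:
            unassigned.append((w2, w1, height))
        else:
            peaks.append(Peak(residue_id=rid, dH=w2, dN=w1, intensity=height))
    if not peaks and not unassigned:
        raise ValueError(f"no valid peak rows in {path}")
    if any_height and missing_height:
        warnings.warn(f"{path}: some rows lack a height column", stacklevel=2)
    return PeakList(peaks=peaks, unassigned=unassigned, source=str(path))


def write_peak_list(peaks: PeakList, path: str | Path) -> Path:
    """Write a Sparky-style peak list (w1 = 15N, w2 = 1H)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = ["      Assignment         w1         w2   Data Height"]
    for p in sorted(peaks.peaks, key=lambda q: q.residue_id):
        h = "" if p.intensity is None else f" {p.intensity:14.6e}"
        rows.append(f"      X{p.residue_id}N-H {p.dN:10.4f} {p.dH:10.4f}{h}")
    path.write_text("\n".join(rows) + "\n")
    return path


def scaled_distance(dH1: float, dN1: float, dH2: float, dN2: float) -> float:
    """Euclidean peak distance with the 15N axis compressed by 1/5."""
    return math.hypot(dH1 - dH2, (dN1 - dN2) / N_SCALE)


def match_peaks(
    reference: PeakList,
    titrated: PeakList,
    tol_H: float = 0.05,
    tol_N: float = 0.25,
) -> dict[int, Optional[Peak]]:
    """Pair titrated peaks with reference peaks.

    When both lists carry assignments the pairing is by residue id.  When the
    titrated list is unlabeled (peaks landed in ``unassigned``), a greedy
    nearest-neighbour match on the scaled distance is used, each peak at most
    once, within ``sqrt(tol_H**2 + (tol_N/5)**2)``; matched peaks inherit the
    reference assignment.  Unmatched reference peaks map to ``None``
    (missing).  Equidistant candidates go to the lower residue id.
    """
    if tol_H <= 0 or tol_N <= 0:
        raise ValueError("tolerances must be positive")
    ref_by_id = reference.by_residue()
    tit_by_id = titrated.by_residue()
    if ref_by_id and tit_by_id:
        return {rid: tit_by_id.get(rid) for rid in sorted(ref_by_id)}

    # positional fallback for unlabeled titrated lists
    tol = math.hypot(tol_H, tol_N / N_SCALE)
    positions = [(p.dH, p.dN, p.intensity) for p in titrated.peaks]
    positions += list(titrated.unassigned)
    candidates = []
    for rp in sorted(reference.peaks, key=lambda p: p.residue_id):
        for j, (dH, dN, _h) in enumerate(positions):
            d = scaled_distance(rp.dH, rp.dN, dH, dN)
            if d <= tol:
                candidates.append((d, rp.residue_id, j))
    candidates.sort()
    pairing: dict[int, Optional[Peak]] = {p.residue_id: None for p in reference.peaks}
    used: set[int] = set()
    for d, rid, j in candidates:
        if pairing[rid] is None and j not in used:
            dH, dN, h = positions[j]
            pairing[rid] = Peak(residue_id=rid, dH=dH, dN=dN, intensity=h)
            used.add(j)
    return pairing


def compute_csp(delta_dH: float, delta_dN: float) -> float:
    """Combined amide chemical shift perturbation, sqrt((ddH^2 + ddN^2/25)/2)."""
    return math.sqrt((delta_dH**2 + delta_dN**2 / 25.0) / 2.0)


def profile_titration(
    series: TitrationSeries,
    noise_floor: float,
    tol_H: float = 0.05,
    tol_N: float = 0.25,
    monotonic_tol: Optional[float] = None,
) -> CSPProfile:
    """Compute per-residue CSPs between apo and the highest titration point.

    ``intensity_ratio`` is the highest-point intensity over the apo intensity;
    apo residues unmatched at the highest point get ratio 0 (and csp 0, since
    no displacement is measurable).  Intermediate points feed a per-residue
    dose-response check: csp must be non-decreasing across ratios within
    ``monotonic_tol`` (default: one scaled tolerance unit).
    """
    if not (0.0 < noise_floor < 1.0):
        raise ValueError("noise_floor must be in (0, 1)")
    if series.apo is None or not series.apo.peaks:
        raise ValueError("apo peak list missing or empty")
    _, top = series.highest

    intensity_available = series.apo.has_intensity and top.has_intensity
    if not intensity_available:
        warnings.warn(
            "peak intensities missing; attenuation classification disabled", stacklevel=2
        )
    if monotonic_tol is None:
        monotonic_tol = compute_csp(tol_H, tol_N)

    pairings = [match_peaks(series.apo, pl, tol_H, tol_N) for _, pl in series.points]
    records: list[CSPRecord] = []
    for apo_peak in sorted(series.apo.peaks, key=lambda p: p.residue_id):
        rid = apo_peak.residue_id
        trajectory: list[float] = []
        for pairing in pairings:
            mate = pairing.get(rid)
            if mate is None:
                trajectory.append(float("nan"))
            else:
                trajectory.append(compute_csp(mate.dH - apo_peak.dH, mate.dN - apo_peak.dN))
        top_peak = pairings[-1].get(rid)
        if top_peak is None:
            rec = CSPRecord(rid, 0.0, 0.0, 0.0, 0.0 if intensity_available else None)
        else:
            ddH = top_peak.dH - apo_peak.dH
            ddN = top_peak.dN - apo_peak.dN
            ratio = None
            if intensity_available and apo_peak.intensity:
                ratio = (top_peak.intensity or 0.0) / apo_peak.intensity
            rec = CSPRecord(rid, ddH, ddN, compute_csp(ddH, ddN), ratio)
        finite = [c for c in trajectory if not math.isnan(c)]
        rec.csp_by_ratio = trajectory
        rec.dose_responsive = all(
            b >= a - monotonic_tol for a, b in zip(finite, finite[1:])
        ) if len(finite) > 1 else None
        records.append(rec)

    for w2, w1, h in series.apo.unassigned:
        records.append(CSPRecord(-1, 0.0, 0.0, 0.0, None, klass="unassigned"))

    profile = CSPProfile(
        records=records, noise_floor=noise_floor, intensity_available=intensity_available
    )
    _set_threshold(profile)
    return profile


def _set_threshold(profile: CSPProfile) -> None:
    vals = np.array([r.csp for r in profile.records if r.klass != "unassigned"], float)
    profile.mean_csp = float(vals.mean()) if vals.size else 0.0
    # sample SD (n-1): conservative for small residue counts
    profile.sd_csp = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    profile.threshold = profile.mean_csp + profile.sd_csp


def classify_residues(profile: CSPProfile) -> CSPProfile:
    """Fill perturbation classes in place (and return the profile).

    Attenuation (intensity ratio at or below the noise floor) takes precedence
    over the shift test; the shift test is strict (csp > threshold).
    """
    for rec in profile.records:
        if rec.klass == "unassigned":
            continue
        if (
            profile.intensity_available
            and rec.intensity_ratio is not None
            and rec.intensity_ratio <= profile.noise_floor
        ):
            rec.klass = "attenuated"
        elif rec.csp > profile.threshold:
            rec.klass = "shifted"
        else:
            rec.klass = "unperturbed"
    return profile
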
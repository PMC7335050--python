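"""Steady-state binding-affinity estimation and liposome dye-release quantification.

The 1:1 Langmuir steady-state model is ``R_eq(C) = rmax * C / (kd + C)`` with
no bulk-offset term (responses are blank-subtracted upstream); an offset can
be fitted behind a flag.  A fit passes the saturation QC when the top analyte
concentration is at least threefold above the fitted K_D.

Dextran release is ``(F_sample - F_blank) / (F_Triton - F_blank) * 100%``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "BindingIsotherm",
    "FitResult",
    "ReleaseTrace",
    "ReleaseSummary",
    "read_isotherm_csv",
    "read_trace_csv",
    "fit_steady_state",
    "check_saturation",
    "release_percent",
    "summarize_release",
]

SATURATION_RATIO = 3.0
SATURATION_CAVEAT = (
    "top concentration is not at least threefold above the fitted K_D; "
    "the steady-state estimate may be unreliable"
)


@dataclass
class BindingIsotherm:
    """(concentration nM, equilibrium response RU) pairs."""

    concentrations: np.ndarray
    responses: np.ndarray
    analyte: str = ""
    ligand: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.responses = np.asarray(self.responses, float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentration/response length mismatch")
        if (self.concentrations <= 0).any():
            raise ValueError("concentrations must be positive")

    @property
    def cmax(self) -> float:
        return float(self.concentrations.max())

    def __len__(self) -> int:
        return len(self.concentrations)


@dataclass
class FitResult:
    kd: float  # nM
    rmax: float  # RU
    se_kd: float
    se_rmax: float
    residual_rms: float
    offset: float = 0.0
    saturation_ok: Optional[bool] = None
    cmax_over_kd: Optional[float] = None
    caveat: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "kd_nM": self.kd,
            "rmax_RU": self.rmax,
            "se_kd_nM": self.se_kd,
            "se_rmax_RU": self.se_rmax,
            "residual_rms_RU": self.residual_rms,
            "offset_RU": self.offset,
            "saturation_ok": self.saturation_ok,
            "cmax_over_kd": self.cmax_over_kd,
            "caveat": self.caveat,
        }

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


@dataclass
class ReleaseTrace:
    """Aligned fluorescence time series for sample, blank and Triton wells."""

    time: np.ndarray
    f_sample: np.ndarray
    f_blank: np.ndarray
    f_triton: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        arrs = [np.asarray(a, float) for a in (self.time, self.f_sample, self.f_blank, self.f_triton)]
        self.time, self.f_sample, self.f_blank, self.f_triton = arrs
        if not all(a.shape == self.time.shape for a in arrs[1:]):
            raise ValueError("trace channels must share the time base")


@dataclass
class ReleaseSummary:
    condition: str
    n_replicates: int
    mean_percent: float
    sd_percent: Optional[float]  # absent (None) for single replicates
    flagged: bool = False  # any replicate outside [0, 100]


def read_isotherm_csv(path: str | Path, analyte: str = "", ligand: str = "") -> BindingIsotherm:
    """Read a CSV with columns ``conc_nM`` and ``response_RU``."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "conc_nm" not in cols or "response_ru" not in cols:
        raise ValueError(f"{path}: expected columns conc_nM, response_RU")
    return BindingIsotherm(
        concentrations=df[cols["conc_nm"]].to_numpy(),
        responses=df[cols["response_ru"]].to_numpy(),
        analyte=analyte,
        ligand=ligand,
    )


def read_trace_csv(path: str | Path, condition: str = "") -> ReleaseTrace:
    """Read a CSV with columns ``time_s, F_sample, F_blank, F_triton``."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    needed = ["time_s", "f_sample", "f_blank", "f_triton"]
    if any(k not in cols for k in needed):
        raise ValueError(f"{path}: expected columns {needed}")
    return ReleaseTrace(
        time=df[cols["time_s"]].to_numpy(),
        f_sample=df[cols["f_sample"]].to_numpy(),
        f_blank=df[cols["f_blank"]].to_numpy(),
        f_triton=df[cols["f_triton"]].to_numpy(),
        condition=condition or Path(path).stem,
    )


def _langmuir(c, rmax, kd):
    return rmax * c / (kd + c)


def fit_steady_state(iso: BindingIsotherm, with_offset: bool = False) -> FitResult:
    """Least-squares fit of the 1:1 steady-state isotherm.

    Deterministic multi-start: kd starts on a fixed log-spaced grid spanning
    [cmin/10, cmax*10]; the start with the lowest residual sum of squares
    wins.  Negative parameter estimates are rejected (bounded fit).
    """
    if len(np.unique(iso.concentrations)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.allclose(iso.responses, 0.0):
        raise ValueError("all responses are zero; nothing to fit")
    c, r = iso.concentrations, iso.responses
    kd_grid = np.geomspace(c.min() / 10.0, c.max() * 10.0, 12)
    rmax0 = max(float(np.max(np.abs(r))), 1e-12)

    if with_offset:
        model = lambda x, rmax, kd, off: _langmuir(x, rmax, kd) + off
        bounds = ([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf])
        mk_p0 = lambda kd0: [rmax0, kd0, 0.0]
    else:
        model = _langmuir
        bounds = ([0.0, 0.0], [np.inf, np.inf])
        mk_p0 = lambda kd0: [rmax0, kd0]

    best = None
    for kd0 in kd_grid:
        try:
            popt, pcov = curve_fit(
                model, c, r, p0=mk_p0(kd0), bounds=bounds, maxfev=20000
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(((model(c, *popt) - r) ** 2).sum())
        if best is None or ssr < best[0] - 1e-12 * (1 + abs(best[0])):
            best = (ssr, popt, pcov)
    if best is None:
        raise RuntimeError("steady-state fit failed to converge from any start")
    ssr, popt, pcov = best
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    fit = FitResult(
        kd=float(popt[1]),
        rmax=float(popt[0]),
        se_kd=float(perr[1]),
        se_rmax=float(perr[0]),
        residual_rms=math.sqrt(ssr / len(c)),
        offset=float(popt[2]) if with_offset else 0.0,
    )
    return check_saturation(fit, iso.cmax)


def check_saturation(fit: FitResult, cmax: float) -> FitResult:
    """Apply the threefold-saturation QC rule (inclusive at exactly 3)."""
    ratio = cmax / fit.kd
    fit.cmax_over_kd = float(ratio)
    fit.saturation_ok = bool(ratio >= SATURATION_RATIO)
    fit.caveat = None if fit.saturation_ok else SATURATION_CAVEAT
    return fit


def release_percent(f_sample: float, f_blank: float, f_triton: float) -> float:
    """Percent dye release, ``(F_sample - F_blank)/(F_Triton - F_blank) * 100``.

    Not clipped: noisy inputs may yield values outside [0, 100] (callers flag).
    """
    denom = f_triton - f_blank
    if denom == 0:
        raise ValueError("F_Triton equals F_blank; release undefined")
    return (f_sample - f_blank) / denom * 100.0


def _plateau(values: np.ndarray, window: float) -> float:
    n = len(values)
    k = max(1, int(round(n * window)))
    return float(np.mean(values[-k:]))


def summarize_release(
    traces: Sequence[ReleaseTrace], window: float = 0.1
) -> list[ReleaseSummary]:
    """Per-condition mean +/- sample SD of percent release.

    Plateau fluorescence per channel is the mean over the final ``window``
    fraction of points.  Traces sharing ``condition`` are replicates; a single
    replicate reports SD as absent (None), not zero.
    """
    if not (0.0 < window <= 1.0):
        raise ValueError("window must be in (0, 1]")
    if not traces:
        raise ValueError("no traces given")
    by_condition: dict[str, list[float]] = {}
    flagged: dict[str, bool] = {}
    for tr in traces:
        pct = release_percent(
            _plateau(tr.f_sample, window),
            _plateau(tr.f_blank, window),
            _plateau(tr.f_triton, window),
        )
        by_condition.setdefault(tr.condition, []).append(pct)
        flagged[tr.condition] = flagged.get(tr.condition, False) or not (0 <= pct <= 100)
    out = []
    for cond in sorted(by_condition):
        vals = by_condition[cond]
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
        out.append(
            ReleaseSummary(
                condition=cond,
                n_replicates=len(vals),
                mean_percent=float(np.mean(vals)),
                sd_percent=sd,
                flagged=flagged[cond],
            )
        )
    return out
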
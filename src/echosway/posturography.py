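"""Center-of-pressure reconstruction and sway summaries from force-plate data.

COP is computed from the plate moments and the vertical force with the plate
surface as the moment origin (COP_ML = -My/Fz, COP_AP = Mx/Fz, with x the
medio-lateral axis and y the anterior-posterior axis).  The COP series is
band-pass filtered 0.1–10 Hz with a zero-phase 4th-order Butterworth design,
and stability is summarized as the standard deviation of the filtered COP
(sdCOP) per axis, optionally normalized by body height (mm of sway per m of
height).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "CONDITIONS",
    "ForcePlateRecording",
    "COPSeries",
    "SwaySummary",
    "compute_cop",
    "bandpass_cop",
    "sway_summary",
    "average_blocks",
    "read_forceplate_csv",
    "write_forceplate_csv",
]

#: the four standing-balance conditions: eyes open/closed on hard surface/foam
CONDITIONS = ("EOhard", "EChard", "EOfoam", "ECfoam")

#: minimum plausible vertical force during quiet stance (N)
FZ_FLOOR_N = 50.0


@dataclass(frozen=True)
class ForcePlateRecording:
    """Raw plate channels: forces (N) and moments (N·m) about the surface origin."""

    fs: float
    t: np.ndarray
    Fx: np.ndarray
    Fy: np.ndarray
    Fz: np.ndarray
    Mx: np.ndarray
    My: np.ndarray
    Mz: np.ndarray
    condition: str = "EOhard"
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 20:
            raise ValueError("sampling rate must exceed 20 Hz for the 0.1-10 Hz band")
        n = len(self.t)
        for name in ("Fx", "Fy", "Fz", "Mx", "My", "Mz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"channel {name} length {len(arr)} != time length {n}")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))


@dataclass(frozen=True)
class COPSeries:
    """COP trajectories in mm; ``filtered`` records the applied band."""

    cop_ap: np.ndarray
    cop_ml: np.ndarray
    fs: float
    filtered: bool = False
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        ap = np.asarray(self.cop_ap, dtype=float)
        ml = np.asarray(self.cop_ml, dtype=float)
        if ap.shape != ml.shape or ap.ndim != 1:
            raise ValueError("cop_ap and cop_ml must be 1-D and equally long")
        if not (np.isfinite(ap).all() and np.isfinite(ml).all()):
            raise ValueError("COP series must be finite")
        object.__setattr__(self, "cop_ap", ap)
        object.__setattr__(self, "cop_ml", ml)


@dataclass(frozen=True)
class SwaySummary:
    """Per-recording sdCOP in mm, plus height-normalized values (mm per m)."""

    sdCOP_AP: float
    sdCOP_ML: float
    sdCOP_AP_norm: float
    sdCOP_ML_norm: float
    height_m: float
    condition: str = ""
    subject_id: str = ""


def compute_cop(rec: ForcePlateRecording) -> COPSeries:
    """Reconstruct the COP (mm) from moments and vertical force.

    With the plate surface as moment origin: COP_ML = -My/Fz,
    COP_AP = Mx/Fz (meters), converted to millimeters.
    """
    bad = np.flatnonzero(np.abs(rec.Fz) <= FZ_FLOOR_N)
    if bad.size:
        head = ", ".join(map(str, bad[:5]))
        raise ValueError(
            f"|Fz| <= {FZ_FLOOR_N} N at {bad.size} samples (first indices: {head}); "
            "COP is unreliable outside quiet stance"
        )
    cop_ml_m = -rec.My / rec.Fz
    cop_ap_m = rec.Mx / rec.Fz
    return COPSeries(cop_ap=cop_ap_m * 1000.0, cop_ml=cop_ml_m * 1000.0, fs=rec.fs)


def _butter_sos(low: float, high: float, fs: float):
    return signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_cop(cop: COPSeries, low: float = 0.1, high: float = 10.0) -> COPSeries:
    """Zero-phase 4th-order Butterworth band-pass of both COP axes.

    Applied forward-backward (``sosfiltfilt``) with reflective edge padding,
    so DC and drift below ``low`` are removed without phase distortion.
    """
    if not (0 < low < high < cop.fs / 2):
        raise ValueError("band must satisfy 0 < low < high < fs/2")
    sos = _butter_sos(low, high, cop.fs)
    # sosfiltfilt needs a few times the filter's effective impulse length
    ntaps = 2 * (sos.shape[0] + 1) * 3
    min_len = 3 * ntaps
    if len(cop.cop_ap) < min_len:
        raise ValueError(f"series of {len(cop.cop_ap)} samples shorter than 3x filter warm-up ({min_len})")
    ap = signal.sosfiltfilt(sos, cop.cop_ap, padtype="even")
    ml = signal.sosfiltfilt(sos, cop.cop_ml, padtype="even")
    return COPSeries(cop_ap=ap, cop_ml=ml, fs=cop.fs, filtered=True, band=(low, high))


def sway_summary(cop: COPSeries, height_m: float, condition: str = "", subject_id: str = "") -> SwaySummary:
    """Sample SD (ddof=1) of each filtered COP axis, raw and height-normalized."""
    if not cop.filtered:
        raise ValueError("sway_summary requires a band-pass filtered COP series "
                         "(unfiltered DC offsets would inflate the SD)")
    if height_m <= 0:
        raise ValueError("height must be positive")
    sd_ap = float(np.std(cop.cop_ap, ddof=1))
    sd_ml = float(np.std(cop.cop_ml, ddof=1))
    return SwaySummary(
        sdCOP_AP=sd_ap,
        sdCOP_ML=sd_ml,
        sdCOP_AP_norm=sd_ap / height_m,
        sdCOP_ML_norm=sd_ml / height_m,
        height_m=height_m,
        condition=condition,
        subject_id=subject_id,
    )


def average_blocks(summaries: Sequence[SwaySummary]) -> SwaySummary:
    """Average repeated blocks of the same subject x condition.

    Order-invariant element-wise mean; subject and condition labels must
    agree across the blocks being averaged.
    """
    if not summaries:
        raise ValueError("no summaries to average")
    conds = {s.condition for s in summaries}
    subjs = {s.subject_id for s in summaries}
    if len(conds) > 1 or len(subjs) > 1:
        raise ValueError(f"block averaging requires one subject/condition, got {subjs}/{conds}")
    heights = {s.height_m for s in summaries}
    if len(heights) > 1:
        raise ValueError("blocks of one subject must share a height")
    mean = lambda attr: float(np.mean([getattr(s, attr) for s in summaries]))
    return SwaySummary(
        sdCOP_AP=mean("sdCOP_AP"),
        sdCOP_ML=mean("sdCOP_ML"),
        sdCOP_AP_norm=mean("sdCOP_AP_norm"),
        sdCOP_ML_norm=mean("sdCOP_ML_norm"),
        height_m=summaries[0].height_m,
        condition=summaries[0].condition,
        subject_id=summaries[0].subject_id,
    )


# ---------------------------------------------------------------------------
# CSV I/O: columns time_s,Fx,Fy,Fz,Mx,My,Mz
# ---------------------------------------------------------------------------

def write_forceplate_csv(rec: ForcePlateRecording, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_s": rec.t, "Fx": rec.Fx, "Fy": rec.Fy, "Fz": rec.Fz,
         "Mx": rec.Mx, "My": rec.My, "Mz": rec.Mz}
    )
    df.to_csv(path, index=False)


def read_forceplate_csv(path: str | Path, condition: str = "EOhard", subject_id: str = "") -> ForcePlateRecording:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("recording too short")
    fs = 1.0 / float(np.median(np.diff(t)))
    return ForcePlateRecording(
        fs=fs, t=t,
        Fx=df["Fx"].to_numpy(), Fy=df["Fy"].to_numpy(), Fz=df["Fz"].to_numpy(),
        Mx=df["Mx"].to_numpy(), My=df["My"].to_numpy(), Mz=df["Mz"].to_numpy(),
        condition=condition, subject_id=subject_id,
    )
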
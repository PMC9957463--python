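"""Extracted-ion chromatograms from centroided peak lists at ppm tolerance.

An extracted-ion chromatogram (EIC) traces, over retention time, the summed
intensity of all centroided peaks within a narrow m/z window around a
target ion. Windows are expressed in parts per million relative to the
target m/z (the convention of high-resolution Q-TOF searches; a typical
precursor tolerance is +-20 ppm) with inclusive boundaries. Presence of a
marker ion in a sample is called when the chromatogram exceeds an intensity
threshold over a minimum number of consecutive scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf


@dataclass
class Scan:
    """One centroided scan: retention time (minutes) and sorted peak arrays."""

    rt: float
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class PeakList:
    """An ordered list of scans with strictly increasing retention times."""

    scans: list[Scan]

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan retention times must be strictly increasing")

    @classmethod
    def read_mgf(cls, path) -> "PeakList":
        """Load an MGF peak list (TITLE/RTINSECONDS/PEPMASS blocks)."""
        scans = []
        with _mgf.MGF(str(path)) as reader:
            for spec in reader:
                rt_s = float(spec["params"]["rtinseconds"])
                order = np.argsort(spec["m/z array"], kind="stable")
                scans.append(
                    Scan(
                        rt=rt_s / 60.0,
                        mz=np.asarray(spec["m/z array"])[order],
                        intensity=np.asarray(spec["intensity array"])[order],
                    )
                )
        scans.sort(key=lambda s: s.rt)
        return cls(scans)


@dataclass
class Chromatogram:
    """An EIC: per-scan summed intensity within the ppm window."""

    target_mz: float
    tol_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"rt_min": self.rt, "intensity": self.intensity})


def ppm_window(target_mz: float, tol_ppm: float) -> tuple[float, float]:
    """Inclusive (low, high) m/z bounds of the ppm window around the target."""
    half = target_mz * tol_ppm * 1e-6
    return target_mz - half, target_mz + half


def extract_eic(
    peaks: PeakList, target_mz: float, tol_ppm: float = 20.0
) -> Chromatogram:
    """Per-scan summed intensity of peaks within +-tol_ppm of *target_mz*.

    The window is computed relative to the target m/z with inclusive
    boundaries; every scan contributes exactly one point (zero when no peak
    falls in the window). An empty peak list yields an empty chromatogram.
    """
    if target_mz <= 0:
        raise ValueError("target_mz must be positive")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    lo, hi = ppm_window(target_mz, tol_ppm)
    rts = np.array([s.rt for s in peaks.scans])
    vals = np.array(
        [
            s.intensity[(s.mz >= lo) & (s.mz <= hi)].sum() if len(s.mz) else 0.0
            for s in peaks.scans
        ]
    )
    return Chromatogram(target_mz=target_mz, tol_ppm=tol_ppm, rt=rts, intensity=vals)


@dataclass(frozen=True)
class PresenceCall:
    present: bool
    apex_rt: float | None
    area: float


def detect_ion(
    chrom: Chromatogram, min_intensity: float = 0.0, min_scans: int = 3
) -> PresenceCall:
    """Call an ion present when >= *min_scans* consecutive points exceed
    *min_intensity*.

    Reports the apex retention time (the maximum point within the first
    qualifying run) and the trapezoidal area of the whole chromatogram.
    """
    if min_intensity < 0 or min_scans < 0:
        raise ValueError("thresholds must be >= 0")
    above = chrom.intensity > min_intensity
    area = float(np.trapezoid(chrom.intensity, chrom.rt)) if len(chrom.rt) > 1 else 0.0
    run_start, run_len = None, 0
    for i, flag in enumerate(above):
        if flag:
            if run_start is None:
                run_start = i
            run_len += 1
            if run_len >= min_scans:
                # extend the run to its end before locating the apex
                j = i
                while j + 1 < len(above) and above[j + 1]:
                    j += 1
                seg = slice(run_start, j + 1)
                apex = int(np.argmax(chrom.intensity[seg])) + run_start
                return PresenceCall(True, float(chrom.rt[apex]), area)
        else:
            run_start, run_len = None, 0
    return PresenceCall(False, None, area)
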
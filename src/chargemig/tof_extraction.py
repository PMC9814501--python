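"""Time-of-flight trace extraction.

Turns delay-resolved ion time-of-flight spectra into delay-dependent
ion-yield traces: flight-time calibration (``t = k sqrt(m/z) + t0``),
mass-window peak integration, scan averaging with the standard error of
the mean, and time-zero determination from a prompt step channel (the
same role the Kr2+ reference and the fragment steps play in the
experiment).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

from .experiment_model import InstrumentResponse

__all__ = [
    "TofSpectrum",
    "IonTrace",
    "tof_calibration_fit",
    "extract_ion_trace",
    "average_scans",
    "find_time_zero",
    "mz_from_formula",
]


class CalibrationError(ValueError):
    pass


class NoStepError(RuntimeError):
    pass


@dataclass
class TofSpectrum:
    """Counts vs flight time with a sqrt-mass calibration.

    ``flight_times`` are bin centres in microseconds; ``k`` has units
    us/(u/e)^(1/2) and ``t_offset`` us.
    """

    flight_times: np.ndarray
    counts: np.ndarray
    k: float = 1.0
    t_offset: float = 0.0

    def __post_init__(self):
        self.flight_times = np.asarray(self.flight_times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.flight_times.shape != self.counts.shape:
            raise ValueError("flight_times and counts must match")
        if np.any(np.diff(self.flight_times) <= 0):
            raise ValueError("flight time bins must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")
        if self.k <= 0:
            raise ValueError("calibration k must be > 0")

    def time_of(self, mz):
        """Flight time (us) of a mass-to-charge ratio."""
        return self.k * np.sqrt(np.asarray(mz, dtype=float)) + self.t_offset

    def mz_of(self, t):
        """Back-converted m/z of a flight time (us)."""
        x = (np.asarray(t, dtype=float) - self.t_offset) / self.k
        return np.square(np.clip(x, 0.0, None))

    def window_counts(self, mz: float, half_width: float) -> float:
        """Total counts whose back-converted m/z lies in ``mz +/- half_width``."""
        mzs = self.mz_of(self.flight_times)
        mask = np.abs(mzs - mz) <= half_width
        return float(self.counts[mask].sum())


@dataclass
class IonTrace:
    """Delay-dependent yield of one ion channel with per-point SEM."""

    label: str
    mz: float
    delays: np.ndarray
    yields: np.ndarray
    sem: np.ndarray

    def __post_init__(self):
        self.delays = np.asarray(self.delays, dtype=float)
        self.yields = np.asarray(self.yields, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (self.delays.shape == self.yields.shape == self.sem.shape):
            raise ValueError("delays, yields and sem must have equal length")
        if np.any(self.sem < 0):
            raise ValueError("sem must be >= 0")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"delay_fs": self.delays, "yield": self.yields, "sem": self.sem})

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, label="", mz=float("nan")) -> "IonTrace":
        df = pd.read_csv(path)
        return cls(label, mz, df["delay_fs"].to_numpy(), df["yield"].to_numpy(), df["sem"].to_numpy())


def tof_calibration_fit(peaks):
    """Least-squares calibration ``t = k sqrt(m/z) + t_offset``.

    ``peaks`` is a sequence of ``(mz, flight_time)`` pairs; at least two
    distinct masses are required (two peaks give the exact solve).
    Returns ``(k, t_offset)``.
    """
    peaks = list(peaks)
    if len(peaks) < 2:
        raise CalibrationError("need at least two calibration peaks")
    mz = np.array([p[0] for p in peaks], dtype=float)
    t = np.array([p[1] for p in peaks], dtype=float)
    if np.unique(mz).size < 2:
        raise CalibrationError("calibration peaks must have distinct m/z")
    A = np.column_stack([np.sqrt(mz), np.ones_like(mz)])
    (k, t0), *_ = np.linalg.lstsq(A, t, rcond=None)
    return float(k), float(t0)


def extract_ion_trace(spectra: dict, mz: float, half_width: float = 0.25,
                      label: str | None = None) -> IonTrace:
    """Window-integrate calibrated spectra into a delay trace.

    ``spectra`` maps delay (fs) to :class:`TofSpectrum`. The yield at
    each delay is the total count whose back-converted m/z falls within
    ``mz +/- half_width`` (default 0.25 u/e, narrow enough to resolve
    the half-integer dication at 67.5 u/e from its 67/68 neighbours).
    SEM is zero here; it arises from scan averaging.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    delays = np.array(sorted(spectra), dtype=float)
    yields = np.array([spectra[d].window_counts(mz, half_width) for d in sorted(spectra)])
    if np.all(yields == 0.0):
        warnings.warn(f"integration window around m/z {mz} is empty at every delay")
    return IonTrace(label or f"mz{mz:g}", mz, delays, yields, np.zeros_like(yields))


def average_scans(traces) -> IonTrace:
    """Average repeated scans; SEM = sample sd / sqrt(n) (ddof=1)."""
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    d0 = traces[0].delays
    for tr in traces[1:]:
        if tr.delays.shape != d0.shape or not np.allclose(tr.delays, d0):
            raise ValueError("all scans must share the same delay grid")
    y = np.stack([tr.yields for tr in traces])
    mean = y.mean(axis=0)
    if len(traces) == 1:
        warnings.warn("single scan: SEM undefined, set to 0")
        sem = np.zeros_like(mean)
    else:
        sem = y.std(axis=0, ddof=1) / math.sqrt(len(traces))
    t0 = traces[0]
    return IonTrace(t0.label, t0.mz, d0.copy(), mean, sem)


def find_time_zero(reference: IonTrace, irf: InstrumentResponse):
    """Locate the pump-probe time zero from a prompt step channel.

    Fits ``yield = baseline + A * Phi((t - t0)/sigma_irf)`` with ``Phi``
    the standard normal CDF; the IRF width is fixed by ``irf``. Returns
    ``(t0, t0_stderr)`` in fs. Raises :class:`NoStepError` when the
    trace shows no step (range below 3x the median SEM).
    """
    y = reference.yields
    t = reference.delays
    med_sem = float(np.median(reference.sem))
    span = float(y.max() - y.min())
    if med_sem > 0 and span <= 3.0 * med_sem:
        raise NoStepError("reference trace exhibits no step above noise")
    if span == 0.0:
        raise NoStepError("reference trace is constant")
    sig = max(irf.sigma, 1e-6)

    def f(tt, t0, amp, base):
        return base + amp * special.ndtr((tt - t0) / sig)

    p0 = [float(t[np.argmax(np.abs(np.gradient(y)))]), float(y[-1] - y[0]), float(y[0])]
    popt, pcov = optimize.curve_fit(f, t, y, p0=p0, maxfev=20000)
    err = float(np.sqrt(max(pcov[0, 0], 0.0)))
    return float(popt[0]), err


_MASSES_NOMINAL = {"H": 1, "C": 12, "N": 14, "O": 16}


def mz_from_formula(formula: str, charge: int = 1) -> float:
    """Mass-to-charge ratio (u/e) of an ion from its molecular formula,
    using nominal integer isotope masses (e.g. adenine C5H5N5 at charge
    2 gives 67.5)."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    tokens = re.findall(r"([A-Z][a-z]?)(\d*)", formula)
    mass = 0
    seen = False
    for el, num in tokens:
        if not el:
            continue
        if el not in _MASSES_NOMINAL:
            raise ValueError(f"unknown element {el!r}")
        mass += _MASSES_NOMINAL[el] * (int(num) if num else 1)
        seen = True
    if not seen:
        raise ValueError(f"could not parse formula {formula!r}")
    return mass / charge
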
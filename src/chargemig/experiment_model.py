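"""Laser pulses and the pump-probe instrument response.

The experiment is an XUV-pump / NIR-probe ion-yield measurement: a
sub-femtosecond extreme-ultraviolet pulse ionises the molecule and a
few-femtosecond near-infrared pulse probes it after an adjustable delay.
This module holds the shared descriptions of the two pulses and of the
effective temporal resolution (the Gaussian cross-correlation of the two
pulse envelopes), which the kinetic curve models convolve with.

Positive delay means the NIR probe arrives after the XUV pump.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from ._units import HBAR_EV_FS, AU_INTENSITY_W_CM2

__all__ = [
    "LaserPulse",
    "InstrumentResponse",
    "irf_from_pulses",
    "field_at",
    "peak_field_from_intensity",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class LaserPulse:
    """A laser pulse described by envelope, carrier and intensity.

    Parameters
    ----------
    central_photon_energy : float
        Carrier photon energy in eV (1.77 eV for the NIR probe).
    fwhm_duration : float
        Full width at half maximum of the *field envelope* in fs.
    peak_intensity : float
        Peak intensity in W/cm^2.
    carrier_envelope_phase : float
        CEP in rad.
    envelope : str
        ``"cos2"`` (compact support, default) or ``"gaussian"``.
    polarization : sequence of 3 floats
        Unit polarization vector.
    center_time : float
        Envelope peak time in fs.
    """

    central_photon_energy: float
    fwhm_duration: float
    peak_intensity: float
    carrier_envelope_phase: float = 0.0
    envelope: str = "cos2"
    polarization: tuple = (0.0, 0.0, 1.0)
    center_time: float = 0.0

    def __post_init__(self):
        if self.fwhm_duration <= 0:
            raise ValueError("fwhm_duration must be > 0")
        if self.peak_intensity < 0:
            raise ValueError("peak_intensity must be >= 0")
        if self.envelope not in ("gaussian", "cos2"):
            raise ValueError(f"unknown envelope {self.envelope!r}")
        pol = np.asarray(self.polarization, dtype=float)
        n = np.linalg.norm(pol)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("polarization must be a unit vector")
        self.polarization = tuple(pol)

    # -- carrier / amplitude -------------------------------------------------

    @property
    def angular_frequency(self) -> float:
        """Carrier angular frequency in rad/fs."""
        return self.central_photon_energy / HBAR_EV_FS

    @property
    def peak_field(self) -> float:
        """Peak field amplitude in atomic units."""
        return peak_field_from_intensity(self.peak_intensity)

    def envelope_at(self, t) -> np.ndarray:
        """Unit-peak field envelope at time(s) ``t`` (fs).

        Both envelope shapes are parameterised by the FWHM of the
        envelope itself, so a Gaussian and a cos^2 pulse of equal
        ``fwhm_duration`` agree at the peak and at the half-maximum
        points by construction. The cos^2 envelope has compact support
        ``|t - center| <= fwhm_duration``.
        """
        x = (np.asarray(t, dtype=float) - self.center_time) / self.fwhm_duration
        if self.envelope == "gaussian":
            return np.exp(-4.0 * math.log(2.0) * x * x)
        env = np.where(np.abs(x) <= 1.0, np.cos(0.5 * math.pi * np.clip(x, -1, 1)) ** 2, 0.0)
        return env

    @property
    def support(self) -> tuple:
        """Times (fs) outside which the envelope is (numerically) zero."""
        if self.envelope == "cos2":
            return (self.center_time - self.fwhm_duration, self.center_time + self.fwhm_duration)
        # 1e-12 cut-off of the Gaussian envelope
        half = self.fwhm_duration * math.sqrt(12.0 * math.log(10.0) / (4.0 * math.log(2.0)))
        return (self.center_time - half, self.center_time + half)

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["polarization"] = [float(x) for x in self.polarization]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LaserPulse":
        return cls(**d)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "LaserPulse":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LaserPulse":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class InstrumentResponse:
    """Gaussian pump-probe cross-correlation of standard deviation ``sigma`` (fs)."""

    sigma: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    @property
    def fwhm(self) -> float:
        return self.sigma / _FWHM_TO_SIGMA


def irf_from_pulses(pump_fwhm, probe_fwhm=None) -> InstrumentResponse:
    """Instrument response from the pump and probe durations.

    Accepts either two :class:`LaserPulse` objects or two FWHM durations
    in fs. For Gaussian envelopes the cross-correlation is Gaussian with
    ``FWHM_cc = sqrt(FWHM_pump^2 + FWHM_probe^2)``; the same quadrature
    rule is used as the Gaussian-equivalent width for cos^2 envelopes.
    Zero durations are allowed as limiting (delta-pulse) cases.
    """
    if isinstance(pump_fwhm, LaserPulse):
        pump_fwhm = pump_fwhm.fwhm_duration
    if isinstance(probe_fwhm, LaserPulse):
        probe_fwhm = probe_fwhm.fwhm_duration
    if probe_fwhm is None:
        raise TypeError("irf_from_pulses requires a pump and a probe duration")
    if pump_fwhm < 0 or probe_fwhm < 0:
        raise ValueError("pulse durations must be >= 0")
    fwhm_cc = math.hypot(pump_fwhm, probe_fwhm)
    return InstrumentResponse(sigma=fwhm_cc * _FWHM_TO_SIGMA)


def field_at(pulse: LaserPulse, t) -> np.ndarray:
    """Electric field (a.u.) of ``pulse`` at time(s) ``t`` in fs.

    ``E(t) = E0 * env((t - c)/T) * cos(w (t - c) + CEP)`` with a
    unit-peak envelope; identically zero outside the cos^2 support.
    """
    t = np.asarray(t, dtype=float)
    phase = pulse.angular_frequency * (t - pulse.center_time) + pulse.carrier_envelope_phase
    return pulse.peak_field * pulse.envelope_at(t) * np.cos(phase)


def peak_field_from_intensity(intensity: float) -> float:
    """Peak field amplitude in a.u. from intensity in W/cm^2."""
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    return math.sqrt(intensity / AU_INTENSITY_W_CM2)
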
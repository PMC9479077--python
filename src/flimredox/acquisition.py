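"""TCSPC acquisition geometry: time binning, laser period and instrument response.

The acquisition model is the standard one for two-photon FLIM with a
pulsed laser: photons arrive in a repetition period ``period`` (ns), are
histogrammed into ``n_bins`` bins of ``bin_width`` (ps), and the true
decay is blurred by a Gaussian instrument response function (IRF) of
full width at half maximum ``irf_fwhm`` (ps) centred at ``irf_center``
(ns).  Defaults correspond to a typical 80 MHz commercial system:
12.5 ns period sampled as 250 x 50 ps bins, 150 ps IRF.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ParameterError

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Time-binning and IRF parameters of a (simulated) TCSPC acquisition.

    Parameters
    ----------
    n_bins : int
        Number of time bins in the recorded histogram window.
    bin_width : float
        Width of one bin, picoseconds.
    period : float
        Laser repetition period, nanoseconds.  The binned window must fit
        inside one period.
    irf_center : float
        Position of the IRF peak within the period, nanoseconds.
    irf_fwhm : float
        Full width at half maximum of the Gaussian IRF, picoseconds.
    background_rate : float
        Expected background (dark/ambient) photons per bin per pixel.
    """

    n_bins: int = 250
    bin_width: float = 50.0
    period: float = 12.5
    irf_center: float = 1.0
    irf_fwhm: float = 150.0
    background_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ParameterError("n_bins must be a positive integer")
        for name in ("bin_width", "period", "irf_center", "irf_fwhm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ParameterError(f"{name} must be finite and > 0, got {v!r}")
        if not math.isfinite(self.background_rate) or self.background_rate < 0:
            raise ParameterError("background_rate must be finite and >= 0")
        if self.n_bins * self.bin_width > self.period * 1000.0 + 1e-9:
            raise ParameterError(
                "binned window exceeds the laser period: "
                f"{self.n_bins} x {self.bin_width} ps > {self.period} ns"
            )
        if self.irf_fwhm >= self.period * 1000.0:
            raise ParameterError("irf_fwhm must be smaller than the period")

    @property
    def bin_width_ns(self) -> float:
        return self.bin_width / 1000.0

    @property
    def irf_sigma_ns(self) -> float:
        """Gaussian IRF standard deviation in ns."""
        return self.irf_fwhm / 1000.0 * _FWHM_TO_SIGMA

    def bin_times(self) -> np.ndarray:
        """Bin-centre arrival times in ns, strictly increasing."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionConfig":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


def default_acquisition() -> AcquisitionConfig:
    """The package-wide default acquisition settings."""
    return AcquisitionConfig()
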
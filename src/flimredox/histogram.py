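"""Per-ROI pooled photon-arrival histograms."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import AcquisitionConfig
from .errors import ParameterError


@dataclass
class DecayHistogram:
    """Photon counts versus arrival time for one ROI (or one pixel).

    Attributes
    ----------
    counts : ndarray of int
        Photons per time bin, non-negative.
    acq : AcquisitionConfig
        The acquisition that produced (or is assumed for) the histogram;
        supplies bin times and the IRF shape needed by fitting.
    """

    counts: np.ndarray
    acq: AcquisitionConfig
    bin_times: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.shape[0] != self.acq.n_bins:
            raise ParameterError(
                f"counts must be a 1-D array of length n_bins={self.acq.n_bins}"
            )
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ParameterError("counts must be finite and non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ParameterError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        self.bin_times = self.acq.bin_times()

    @property
    def n_photons(self) -> int:
        """Total photons pooled into this histogram."""
        return int(self.counts.sum())

    def __add__(self, other: "DecayHistogram") -> "DecayHistogram":
        if other.acq != self.acq:
            raise ParameterError("cannot add histograms from different acquisitions")
        return DecayHistogram(self.counts + other.counts, self.acq)
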
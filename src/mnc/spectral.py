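"""Band limiting, instantaneous phase and epoch segmentation.

The band-pass is a zero-phase FFT brick wall: every Fourier bin whose
frequency lies outside ``[lo_hz, hi_hz]`` (edges inclusive) is zeroed and
the signal inverse-transformed.  A brick wall distorts no phase inside the
band, which is what a phase-based connectivity statistic requires, and it
is exactly idempotent.  Instantaneous phase is the angle of the analytic
signal (Hilbert construction), computed per epoch so that edge artefacts
never leak across epoch boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.signal

from .errors import ConfigurationError, InputTooShortError, UndefinedPhaseError
from .io import RoiTimeSeries


@dataclass(frozen=True)
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ConfigurationError(
                f"band {self.name!r}: need 0 < lo < hi, got [{self.lo_hz}, {self.hi_hz}]"
            )

    def validate_for(self, sample_rate_hz: float) -> None:
        if self.hi_hz >= sample_rate_hz / 2:
            raise ConfigurationError(
                f"band {self.name!r} upper edge {self.hi_hz} Hz is at/above "
                f"Nyquist for fs={sample_rate_hz} Hz"
            )

    @property
    def center_hz(self) -> float:
        return 0.5 * (self.lo_hz + self.hi_hz)


#: the three analyzed bands: theta, lower alpha, upper alpha
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
)


@dataclass(frozen=True)
class PhaseEpoch:
    """Instantaneous phases (radians, wrapped to (-pi, pi]) for one epoch."""

    phases: np.ndarray  # N x epoch_samples
    band: BandDefinition
    epoch_index: int

    def __post_init__(self) -> None:
        p = np.asarray(self.phases, dtype=float)
        object.__setattr__(self, "phases", p)
        if p.ndim != 2:
            raise ValueError("phases must be N x T")


def bandpass(ts: RoiTimeSeries, band: BandDefinition) -> RoiTimeSeries:
    """FFT brick-wall band-pass, edges inclusive, zero-phase by construction."""
    band.validate_for(ts.sample_rate_hz)
    spectrum = np.fft.rfft(ts.data, axis=1)
    freqs = np.fft.rfftfreq(ts.n_samples, d=1.0 / ts.sample_rate_hz)
    keep = (freqs >= band.lo_hz) & (freqs <= band.hi_hz)
    spectrum[:, ~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=ts.n_samples, axis=1)
    return replace(ts, data=filtered)


def instantaneous_phase(ts: RoiTimeSeries | np.ndarray) -> np.ndarray:
    """Angle of the analytic signal per ROI, wrapped to (-pi, pi].

    Raises :class:`UndefinedPhaseError` for any identically-zero row, whose
    phase would be arbitrary.
    """
    data = ts.data if isinstance(ts, RoiTimeSeries) else np.asarray(ts, dtype=float)
    amp = np.abs(data).max(axis=1)
    if np.any(amp == 0.0):
        dead = np.nonzero(amp == 0.0)[0].tolist()
        raise UndefinedPhaseError(f"zero signal in rows {dead}: phase undefined")
    analytic = scipy.signal.hilbert(data, axis=1)
    phases = np.angle(analytic)
    # np.angle returns [-pi, pi]; fold the single excluded endpoint
    phases[phases == -np.pi] = np.pi
    return phases


def segment_epochs(ts: RoiTimeSeries, epoch_samples: int) -> list[RoiTimeSeries]:
    """Split into floor(T / epoch_samples) consecutive non-overlapping epochs.

    The trailing remainder is discarded; a record shorter than one epoch is
    an error.
    """
    if epoch_samples < 1:
        raise ConfigurationError("epoch_samples must be >= 1")
    n_epochs = ts.n_samples // epoch_samples
    if n_epochs == 0:
        raise InputTooShortError(
            f"record of {ts.n_samples} samples is shorter than one epoch "
            f"({epoch_samples} samples)"
        )
    return [
        replace(ts, data=ts.data[:, k * epoch_samples : (k + 1) * epoch_samples])
        for k in range(n_epochs)
    ]


def phase_epochs(
    ts: RoiTimeSeries, band: BandDefinition, epoch_samples: int
) -> list[PhaseEpoch]:
    """Band-pass, segment, and extract per-epoch instantaneous phase."""
    filtered = bandpass(ts, band)
    epochs = segment_epochs(filtered, epoch_samples)
    out = []
    for k, ep in enumerate(epochs):
        out.append(PhaseEpoch(phases=instantaneous_phase(ep), band=band, epoch_index=k))
    return out


def epoch_duration_s(epoch_samples: int, sample_rate_hz: float) -> float:
    """Duration of one epoch in seconds (samples / rate)."""
    if sample_rate_hz <= 0:
        raise ConfigurationError("sample_rate_hz must be > 0")
    return epoch_samples / sample_rate_hz
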
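"""Per-pulse spectral band levels for passive cavitation monitoring.

A passive cavitation detector records the acoustic emission of circulating
microbubbles during each sonication pulse.  Stable bubble oscillation shows up
as narrow lines at integer (n*f0) and half-integer ((n+1/2)*f0) multiples of
the excitation frequency f0; inertial collapse raises the spectral floor away
from those lines ("broadband emission").  This module turns a received pulse
(or a synthetic spectrum) into dB-scale band levels relative to a baseline
spectrum and applies the broadband event rule.

Band levels are power ratios: ``10*log10(mean band power / mean baseline band
power)``, with the band a closed interval ``[center - halfwidth, center +
halfwidth]``.  The band statistic is the mean over bins, not the peak, so the
result is robust to grid alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PulseSpectrum",
    "BandScheme",
    "BandLevels",
    "DetectionConfig",
    "compute_spectrum",
    "band_level",
    "extract_band_levels",
    "detect_broadband_event",
]


@dataclass(frozen=True)
class PulseSpectrum:
    """One-sided power spectrum of a single received pulse.

    Attributes
    ----------
    freqs : ndarray
        Frequency grid in MHz, uniform and strictly ascending.
    magnitude : ndarray
        Power per bin (linear units), non-negative.
    pulse_index : int
        Index of the pulse within its sonication.
    """

    freqs: np.ndarray
    magnitude: np.ndarray
    pulse_index: int = 0

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        mag = np.asarray(self.magnitude, dtype=float)
        if freqs.ndim != 1 or mag.shape != freqs.shape:
            raise ValueError("freqs and magnitude must be 1-D arrays of equal length")
        if freqs.size < 2 or np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly increasing with >= 2 points")
        if np.any(mag < 0):
            raise ValueError("magnitude must be non-negative")
        if self.pulse_index < 0:
            raise ValueError("pulse_index must be >= 0")
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "magnitude", mag)

    @property
    def nyquist(self) -> float:
        return float(self.freqs[-1])


@dataclass(frozen=True)
class BandScheme:
    """Frequency-bin layout for harmonic/ultra-harmonic/broadband bands.

    The k-th ultra-harmonic sits at ``(k + 0.5) * f0`` (so order 1 is 1.5*f0);
    harmonics at ``n * f0`` for the configured integer orders.  The broadband
    bin sits at ``broadband_multiple * f0`` (default 7.22, i.e. 3.61 MHz at
    f0 = 0.5 MHz), a line-free frequency near the detector's sensitivity peak.
    ``halfwidth_khz`` is the band half-width in kHz; with 11 ms pulses the grid
    step is ~91 Hz so the default +/-0.3 kHz spans about 7 bins.
    """

    f0: float = 0.5
    harmonic_orders: tuple[int, ...] = tuple(range(2, 9))
    ultraharmonic_orders: tuple[int, ...] = tuple(range(1, 8))
    broadband_multiple: float = 7.22
    halfwidth_khz: float = 0.3

    @property
    def halfwidth_mhz(self) -> float:
        return self.halfwidth_khz * 1e-3

    def center(self, kind: str, order: int = 0) -> float:
        """Band center in MHz for ('harmonic', n), ('ultraharmonic', k) or ('broadband', -)."""
        if kind == "harmonic":
            return order * self.f0
        if kind == "ultraharmonic":
            return (order + 0.5) * self.f0
        if kind == "broadband":
            return self.broadband_multiple * self.f0
        raise ValueError(f"unknown band kind: {kind!r}")

    def all_bands(self) -> list[tuple[str, int, float]]:
        bands = [("harmonic", n, self.center("harmonic", n)) for n in self.harmonic_orders]
        bands += [
            ("ultraharmonic", k, self.center("ultraharmonic", k))
            for k in self.ultraharmonic_orders
        ]
        bands.append(("broadband", 0, self.center("broadband")))
        return bands

    @property
    def max_center(self) -> float:
        return max(c for _, _, c in self.all_bands())


@dataclass
class BandLevels:
    """dB-re-baseline levels for one pulse: 7 harmonics (orders 2-8), 7
    ultra-harmonics (1.5*f0 .. 7.5*f0) and the broadband bin."""

    harmonics: np.ndarray = field(default_factory=lambda: np.zeros(7))
    ultraharmonics: np.ndarray = field(default_factory=lambda: np.zeros(7))
    broadband: float = 0.0

    def __post_init__(self) -> None:
        self.harmonics = np.asarray(self.harmonics, dtype=float)
        self.ultraharmonics = np.asarray(self.ultraharmonics, dtype=float)
        if not (np.all(np.isfinite(self.harmonics)) and np.all(np.isfinite(self.ultraharmonics))
                and np.isfinite(self.broadband)):
            raise ValueError("band levels must be finite")

    def harmonic(self, order: int) -> float:
        """Level of the n-th harmonic (n in 2..8)."""
        return float(self.harmonics[order - 2])

    def ultraharmonic(self, order: int) -> float:
        """Level of the k-th ultra-harmonic, centered at (k+0.5)*f0 (k in 1..7)."""
        return float(self.ultraharmonics[order - 1])


@dataclass(frozen=True)
class DetectionConfig:
    """Broadband event rule: an event is a broadband level strictly above
    ``event_threshold_db`` (default 6 dB, i.e. 3x the nominal 2 dB baseline
    noise SD)."""

    event_threshold_db: float = 6.0
    baseline_noise_sd_db: float = 2.0  # metadata only

    def __post_init__(self) -> None:
        if self.event_threshold_db <= 0:
            raise ValueError("event_threshold_db must be > 0")


def compute_spectrum(signal: np.ndarray, sample_rate_mhz: float,
                     pulse_index: int = 0,
                     scheme: BandScheme | None = None) -> PulseSpectrum:
    """One-sided power spectrum of a real time series.

    Bin powers are scaled so their sum equals the time-domain mean-square
    power (Parseval).  ``sample_rate_mhz`` must exceed twice the highest band
    center of ``scheme`` when one is given.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise ValueError("signal must contain at least 2 samples")
    if sample_rate_mhz <= 0:
        raise ValueError("sample_rate_mhz must be positive")
    if scheme is not None and sample_rate_mhz <= 2 * scheme.max_center:
        raise ValueError(
            f"sample rate {sample_rate_mhz} MHz is too low for the configured bands "
            f"(need > {2 * scheme.max_center} MHz)")
    n = x.size
    spec = np.fft.rfft(x)
    power = np.abs(spec) ** 2 / n**2
    # double the interior bins so the one-sided sum preserves total power
    power[1:] *= 2.0
    if n % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate_mhz)
    return PulseSpectrum(freqs=freqs, magnitude=power, pulse_index=pulse_index)


def _band_slice(spectrum: PulseSpectrum, center: float, halfwidth_mhz: float) -> np.ndarray:
    lo, hi = center - halfwidth_mhz, center + halfwidth_mhz
    if lo < spectrum.freqs[0] or hi > spectrum.freqs[-1]:
        raise ValueError(
            f"band [{lo:.6f}, {hi:.6f}] MHz falls outside the spectral grid "
            f"[{spectrum.freqs[0]:.6f}, {spectrum.freqs[-1]:.6f}]")
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if not mask.any():
        raise ValueError(
            f"no spectral bins inside band [{lo:.6f}, {hi:.6f}] MHz; "
            "grid resolution is coarser than the band width")
    return mask


def band_level(spectrum: PulseSpectrum, baseline: PulseSpectrum,
               center: float, halfwidth_mhz: float) -> float:
    """dB level of one band relative to baseline.

    Returns ``10*log10(mean power in band / mean baseline power in band)``
    over bins in the closed interval ``center +/- halfwidth_mhz``.
    """
    if spectrum.freqs.shape != baseline.freqs.shape or not np.allclose(
            spectrum.freqs, baseline.freqs):
        raise ValueError("spectrum and baseline must share the same frequency grid")
    mask = _band_slice(spectrum, center, halfwidth_mhz)
    p = spectrum.magnitude[mask].mean()
    p0 = baseline.magnitude[mask].mean()
    if p0 <= 0:
        raise ValueError("baseline power in band is zero; dB level undefined")
    if p <= 0:
        return -np.inf if p == 0 else float("nan")
    return float(10.0 * np.log10(p / p0))


def extract_band_levels(spectrum: PulseSpectrum, baseline: PulseSpectrum,
                        scheme: BandScheme) -> BandLevels:
    """All configured band levels for one pulse (harmonics, ultra-harmonics,
    broadband), each via :func:`band_level`."""
    hw = scheme.halfwidth_mhz
    harm = np.array([
        band_level(spectrum, baseline, scheme.center("harmonic", n), hw)
        for n in scheme.harmonic_orders
    ])
    uh = np.array([
        band_level(spectrum, baseline, scheme.center("ultraharmonic", k), hw)
        for k in scheme.ultraharmonic_orders
    ])
    bb = band_level(spectrum, baseline, scheme.center("broadband"), hw)
    return BandLevels(harmonics=harm, ultraharmonics=uh, broadband=bb)


def detect_broadband_event(levels: BandLevels,
                           config: DetectionConfig | None = None) -> bool:
    """True iff the broadband level strictly exceeds the event threshold.

    The comparison is strict: a level exactly at the threshold (6.0 dB by
    default) is a non-event.
    """
    config = config or DetectionConfig()
    if not np.isfinite(levels.broadband):
        raise ValueError("broadband level must be finite")
    return bool(levels.broadband > config.event_threshold_db)
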
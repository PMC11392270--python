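"""Band-limited spectral and entropy features of whole EHG signals.

Four features are computed per (signal, band) pair:

* **PF** -- peak frequency: the frequency of the largest power-spectrum bin
  inside the band.
* **MF** -- median frequency: the smallest in-band frequency at which the
  cumulative in-band power first reaches half of the total in-band power.
* **PA** -- normalized peak amplitude: the largest in-band spectral peak of
  the band-filtered signal, divided by the largest peak of the B0-filtered
  signal inside the reference band B0 (0.08-1.0 Hz).  By construction
  PA(B0) == 1 for every record.
* **SE** -- sample entropy: -ln(c_{m+1}/c_m) with embedding dimension m,
  Chebyshev distance, and tolerance r expressed as a fraction of the
  standard deviation of the analyzed (band-filtered) series.  Defaults
  m = 3, r = 0.15.

Signals are band-limited with a 4th-order Butterworth filter applied
forward-backward (zero phase); 15 s are trimmed from each end before any
spectrum or entropy computation to discard the filter transients.  The
spectrum estimator is the single full-signal periodogram (a Welch estimate
is available as configuration), whose bins P(k) at frequencies k*fs/M are
indexed half-open per band: k_L = ceil(f_lo/df), k_U = ceil(f_hi/df), so a
bin shared by two adjacent band edges is counted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .bands import REFERENCE_BAND, Band, get_band
from .errors import ParameterError, UndefinedValueError
from .records_io import EHGRecord

try:  # optional compiled kernel for the O(N^2) entropy pair count
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


VALID_FEATURES = ("PF", "MF", "PA", "SE")
VALID_SIGNALS = ("S2", "S3")
#: PA is identically 1.0 in these bands, so it is excluded from feature sets
PA_EXCLUDED_BANDS = ("B0", "B0b")


@dataclass(frozen=True)
class FeatureSpec:
    """One feature of one signal in one band, e.g. ``PA_S3_B0Lp``."""

    feature: str
    signal: str
    band: str

    def __post_init__(self) -> None:
        if self.feature not in VALID_FEATURES:
            raise ParameterError(f"unknown feature {self.feature!r}")
        if self.signal not in VALID_SIGNALS:
            raise ParameterError(f"unknown signal {self.signal!r}")
        get_band(self.band)
        if self.feature == "PA" and self.band in PA_EXCLUDED_BANDS:
            raise ParameterError(
                f"PA in band {self.band} is identically 1.0 and is disallowed"
            )

    @property
    def name(self) -> str:
        return f"{self.feature}_{self.signal}_{self.band}"

    @classmethod
    def from_name(cls, name: str) -> "FeatureSpec":
        parts = name.split("_", 2)
        if len(parts) != 3:
            raise ParameterError(f"malformed feature name {name!r}")
        return cls(*parts)


@dataclass(frozen=True)
class SEParams:
    m_embed: int = 3
    r_frac: float = 0.15
    #: the printed fallback -ln((N-m)/(N-m-1)) is negative; set True for the
    #: sign-corrected (positive) variant
    sign_corrected_fallback: bool = False

    def __post_init__(self) -> None:
        if self.m_embed < 1:
            raise ParameterError("m_embed must be >= 1")
        if self.r_frac <= 0:
            raise ParameterError("r_frac must be > 0")


@dataclass(frozen=True)
class ExtractionConfig:
    """Pre-processing and estimator knobs shared by all feature extractions."""

    trim_s: float = 15.0  # transient trim at each end, seconds
    se_params: SEParams = field(default_factory=SEParams)
    estimator: str = "periodogram"  # or "welch"
    welch_nperseg: int = 1024
    #: decimate the band-filtered series before sample entropy; the factor is
    #: chosen per band so the band stays below the decimated Nyquist
    se_decimate: bool = False

    def __post_init__(self) -> None:
        if self.estimator not in ("periodogram", "welch"):
            raise ParameterError(f"unknown estimator {self.estimator!r}")


@dataclass
class Spectrum:
    """One-sided power spectrum; bin k sits at frequency k * df."""

    power: np.ndarray
    df: float
    fs: float

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(len(self.power)) * self.df

    def band_slice(self, band: Band) -> slice:
        k_lo = int(math.ceil(band.f_lo / self.df - 1e-9))
        k_hi = int(math.ceil(band.f_hi / self.df - 1e-9))
        k_hi = min(k_hi, len(self.power))
        if k_hi <= k_lo:
            raise ParameterError(
                f"band {band.name} contains no spectral bins at df={self.df:g} Hz"
            )
        return slice(k_lo, k_hi)


def bandpass_filter(x: np.ndarray, band: Band | str, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass; same length as the input."""
    if isinstance(band, str):
        band = get_band(band)
    band.validate_against(fs)
    sos = sps.butter(order, [band.f_lo, band.f_hi], btype="bandpass", fs=fs, output="sos")
    if len(x) <= 3 * (2 * sos.shape[0] + 1):
        raise ParameterError("signal shorter than the filter transient")
    return sps.sosfiltfilt(sos, x)


def power_spectrum(x: np.ndarray, fs: float, config: ExtractionConfig | None = None) -> Spectrum:
    """One-sided power spectrum (periodogram by default, Welch optionally)."""
    if len(x) < 2:
        raise ParameterError("need at least 2 samples for a spectrum")
    config = config or ExtractionConfig()
    if config.estimator == "welch" and len(x) > config.welch_nperseg:
        f, p = sps.welch(
            x, fs=fs, window="hann", nperseg=config.welch_nperseg, detrend=False
        )
    else:
        f, p = sps.periodogram(x, fs=fs, window="boxcar", detrend=False)
    return Spectrum(power=p, df=float(f[1] - f[0]), fs=fs)


def peak_frequency(sp: Spectrum, band: Band | str) -> float:
    if isinstance(band, str):
        band = get_band(band)
    sl = sp.band_slice(band)
    k = sl.start + int(np.argmax(sp.power[sl]))
    return k * sp.df


def median_frequency(sp: Spectrum, band: Band | str) -> float:
    if isinstance(band, str):
        band = get_band(band)
    sl = sp.band_slice(band)
    p = sp.power[sl]
    total = p.sum()
    if total <= 0:
        raise UndefinedValueError(f"zero in-band power in {band.name}")
    cum = np.cumsum(p)
    j = int(np.searchsorted(cum, total / 2.0))
    return (sl.start + j) * sp.df


def peak_amplitude_normalized(
    x: np.ndarray,
    band: Band | str,
    fs: float,
    config: ExtractionConfig | None = None,
    reference_spectrum: Spectrum | None = None,
) -> float:
    """In-band spectral peak of the band-filtered signal over the B0 reference peak."""
    if isinstance(band, str):
        band = get_band(band)
    config = config or ExtractionConfig()
    sp = power_spectrum(_analysis_series(x, band, fs, config), fs, config)
    peak = float(np.max(sp.power[sp.band_slice(band)]))
    if reference_spectrum is None:
        reference_spectrum = power_spectrum(
            _analysis_series(x, REFERENCE_BAND, fs, config), fs, config
        )
    ref = float(
        np.max(reference_spectrum.power[reference_spectrum.band_slice(REFERENCE_BAND)])
    )
    if ref <= 0:
        raise UndefinedValueError("zero reference peak in band B0")
    return peak / ref


@njit(cache=True)
def _se_pair_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover - numba
    n = x.shape[0]
    n_m = n - m + 1  # number of length-m templates
    n_m1 = n - m  # number of length-(m+1) templates
    cm = 0
    cm1 = 0
    for i in range(n_m):
        for j in range(i + 1, n_m):
            d = 0.0
            ok = True
            for t in range(m):
                diff = abs(x[i + t] - x[j + t])
                if diff > d:
                    d = diff
                if d > r:
                    ok = False
                    break
            if ok:
                cm += 1
                if i < n_m1 and j < n_m1:
                    if abs(x[i + m] - x[j + m]) <= r:
                        cm1 += 1
    return cm, cm1


def sample_entropy(x: np.ndarray, params: SEParams | None = None) -> float:
    """Sample entropy in nats of a 1-D series.

    Counts unordered template pairs (i != j) within Chebyshev tolerance
    r = r_frac * SD(x) (population SD).  When either pair count is zero the
    printed fallback -ln((N-m)/(N-m-1)) is returned verbatim (negative);
    ``SEParams.sign_corrected_fallback`` flips its sign.
    """
    params = params or SEParams()
    m = params.m_embed
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    if n <= m + 1:
        raise ParameterError(f"series of {n} samples too short for m={m}")
    sd = float(np.std(x))
    if sd == 0.0:
        # constant series: every pair matches at every length
        return 0.0
    r = params.r_frac * sd
    cm, cm1 = _se_pair_counts(x, m, r)
    if cm1 != 0 and cm != 0:
        return float(-np.log(cm1 / cm))
    fallback = -math.log((n - m) / (n - m - 1))
    return -fallback if params.sign_corrected_fallback else fallback


# ---------------------------------------------------------------------------
# Per-record extraction
# ---------------------------------------------------------------------------


def _trim(x: np.ndarray, fs: float, trim_s: float) -> np.ndarray:
    k = int(round(trim_s * fs))
    if len(x) - 2 * k < 64:
        raise ParameterError(
            f"signal of {len(x)} samples too short for a {trim_s} s transient trim"
        )
    return x[k : len(x) - k] if k else x


def _analysis_series(x: np.ndarray, band: Band, fs: float, config: ExtractionConfig) -> np.ndarray:
    return _trim(bandpass_filter(x, band, fs), fs, config.trim_s)


def _se_series(y: np.ndarray, band: Band, fs: float, config: ExtractionConfig) -> np.ndarray:
    if not config.se_decimate:
        return y
    factor = max(1, int(fs / (2.5 * band.f_hi)))
    return y[::factor]


def extract_feature_vector(
    rec: EHGRecord,
    specs: Sequence[FeatureSpec],
    config: ExtractionConfig | None = None,
) -> dict[str, float]:
    """Compute every requested feature of one record; deterministic."""
    config = config or ExtractionConfig()
    series_cache: dict[tuple[str, str], np.ndarray] = {}
    spectrum_cache: dict[tuple[str, str], Spectrum] = {}

    def series(signal: str, band_name: str) -> np.ndarray:
        key = (signal, band_name)
        if key not in series_cache:
            series_cache[key] = _analysis_series(
                rec.signals[signal], get_band(band_name), rec.fs, config
            )
        return series_cache[key]

    def spectrum(signal: str, band_name: str) -> Spectrum:
        key = (signal, band_name)
        if key not in spectrum_cache:
            spectrum_cache[key] = power_spectrum(series(signal, band_name), rec.fs, config)
        return spectrum_cache[key]

    out: dict[str, float] = {}
    for spec in specs:
        band = get_band(spec.band)
        if spec.feature == "PF":
            out[spec.name] = peak_frequency(spectrum(spec.signal, spec.band), band)
        elif spec.feature == "MF":
            out[spec.name] = median_frequency(spectrum(spec.signal, spec.band), band)
        elif spec.feature == "PA":
            sp = spectrum(spec.signal, spec.band)
            ref = spectrum(spec.signal, REFERENCE_BAND.name)
            peak = float(np.max(sp.power[sp.band_slice(band)]))
            refpeak = float(np.max(ref.power[ref.band_slice(REFERENCE_BAND)]))
            if refpeak <= 0:
                raise UndefinedValueError(f"{rec.record_id}: zero B0 reference peak")
            out[spec.name] = peak / refpeak
        elif spec.feature == "SE":
            y = _se_series(series(spec.signal, spec.band), band, rec.fs, config)
            out[spec.name] = sample_entropy(y, config.se_params)
    return out


def specs_from_names(names: Sequence[str]) -> list[FeatureSpec]:
    return [FeatureSpec.from_name(n) for n in names]
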
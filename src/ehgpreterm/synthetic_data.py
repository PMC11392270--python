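"""Synthetic EHG record generator with planted class effects.

Each record is three channels of 20 Hz signal composed of

* a 1/f^alpha background (independent per channel) standing in for baseline
  abdominal-surface noise, whose low-frequency rise supplies the reference
  peak of the normalized-peak-amplitude feature in band B0;
* a very-low-frequency line (drift/breathing residue, ~0.095 Hz) that
  supplies the reference peak of the B0 band;
* a narrowband Fast-Wave-Low line at ~0.35 Hz (inside 0.125-0.575 Hz)
  whose *power* peak is multiplied by ``fwl_peak_gain`` in the premature
  class, elevating the normalized peak amplitude PA_S3_B0Lp exactly as
  premature records elevate it in real data; the component projects most
  strongly onto the horizontal channel S3;
* three harmonics of the maternal heart rate (fundamental ``mhr_base`` Hz,
  lowered by ``mhr_shift`` in the premature class, strongest on the
  vertical channel S2), so the third harmonic is a broad hump inside band
  B3 (3.5-5.0 Hz) and the premature class shows a lower B3 median
  frequency (MF_S2_B3);
* a mid-band (1.3-3.2 Hz) Fast-Wave-High-like burst of heavily dispersed,
  class-independent amplitude that realistically dominates the record-to-
  record variability of broad-band features.

The generator reproduces the spectral structure the features measure and
the study's group layout (PL and the four term delivery-mode groups, with
realistic class imbalance); it does not model contraction-burst morphology,
electrode artifacts, or non-stationarity beyond the frequency jitter.
All randomness flows from one seed through a documented splitting scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .records_io import (
    Dataset,
    DeliveryMode,
    EHGRecord,
    GroupLabel,
    RecordCollection,
    RecordMetadata,
    write_ehg_record,
)
from .util import child_seed

_MODE_BY_GROUP = {
    GroupLabel.PL: DeliveryMode.SPONTANEOUS,
    GroupLabel.TL: DeliveryMode.SPONTANEOUS,
    GroupLabel.IL: DeliveryMode.INDUCED,
    GroupLabel.CL: DeliveryMode.CESAREAN,
    GroupLabel.ICL: DeliveryMode.INDUCED_CESAREAN,
}


@dataclass(frozen=True)
class ClassEffectParams:
    """Class-contrast knobs of the generator.

    ``fwl_peak_gain`` multiplies the premature-class FWL spectral peak by
    narrowing the line width at unchanged power (1.0 = null effect);
    ``mhr_shift`` lowers the premature-class maternal heart rate in Hz
    (0.0 = null effect).
    """

    #: very-low-frequency component (baseline drift / maternal breathing
    #: residue) just below the FWL band; it supplies the B0 reference peak
    #: against which the FWL peak amplitude is normalized
    lf_center_hz: float = 0.095
    lf_amp: float = 0.9
    #: subject-specific FWL center: uniform in fwl_center_hz +/- jitter
    #: (class-independent), so the peak's location carries no class signal
    #: and only its height does
    fwl_center_hz: float = 0.35
    fwl_center_jitter: float = 0.05
    fwl_amp: float = 0.62
    #: stationary SD of the term-class FWL frequency jitter, Hz; the
    #: premature class narrows it by fwl_peak_gain (same power, taller peak)
    fwl_freq_sd: float = 0.10
    fwl_peak_gain: float = 3.0
    mhr_base: float = 1.35  # ~81 bpm resting maternal heart rate
    mhr_shift: float = 0.17
    harmonic_amps: tuple[float, float, float] = (0.10, 0.07, 0.35)
    #: fractional line width of the heart harmonics; the 3rd harmonic is a
    #: broad hump in B3, so the in-band median frequency tracks the heart
    #: rate while the exact peak location stays noise-dominated
    mhr_line_width: float = 0.14
    #: half-separation (Hz) of the heart-rate-variability sidebands the 3rd
    #: harmonic splits into (class-independent)
    mhr_sideband_hz: float = 0.0
    #: Fast-Wave-High-like mid-band activity (class-independent): a
    #: narrowband noise burst at a random per-record center frequency in
    #: [fwh_lo, fwh_hi] with a heavily dispersed amplitude.  It models the
    #: record-to-record variability of FWH/motion content and dominates the
    #: record-to-record variance of broad-band (Bb, B0b) features
    fwh_amp: float = 0.35
    fwh_amp_jitter_sd: float = 0.6
    fwh_lo: float = 1.3
    fwh_hi: float = 3.2
    fwh_bandwidth: float = 0.4
    noise_exponent: float = 1.2
    noise_scale: float = 1.0
    #: channel projections (S1, S2, S3): uterine FWL activity is strongest
    #: on the horizontal, cervix-adjacent S3; the maternal-heart component
    #: is strongest on the vertically oriented S2
    fwl_channel_gains: tuple[float, float, float] = (0.8, 0.25, 1.2)
    heart_channel_gains: tuple[float, float, float] = (0.85, 1.3, 0.12)
    #: per-record lognormal spread of the shared amplitude scale (class
    #: overlap); ratio features largely cancel it
    amp_jitter_sd: float = 0.10
    #: additional independent per-component amplitude jitter
    component_jitter_sd: float = 0.04
    #: per-record gaussian spread of the maternal heart rate, Hz
    mhr_record_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.fwl_peak_gain < 1.0:
            raise ParameterError("fwl_peak_gain must be >= 1")
        if self.mhr_shift < 0.0:
            raise ParameterError("mhr_shift must be >= 0")
        lo3 = 3.0 * (self.mhr_base - self.mhr_shift)
        hi3 = 3.0 * self.mhr_base
        if not (3.5 <= lo3 and hi3 <= 5.0):
            raise ParameterError(
                "third maternal-heart harmonic must stay inside B3 (3.5-5.0 Hz) "
                f"for both classes; got [{lo3:.3f}, {hi3:.3f}]"
            )


#: group sizes mirroring the study's later-record counts (32 premature vs
#: 196 term records across the four delivery modes)
DEFAULT_GROUP_SIZES: dict[GroupLabel, int] = {
    GroupLabel.PL: 32,
    GroupLabel.TL: 132,
    GroupLabel.IL: 43,
    GroupLabel.CL: 8,
    GroupLabel.ICL: 13,
}


@dataclass(frozen=True)
class SyntheticConfig:
    group_sizes: dict[GroupLabel, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    duration_s: float = 1800.0
    fs: float = 20.0
    effects: ClassEffectParams = field(default_factory=ClassEffectParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_sizes.get(GroupLabel.PL, 0) < 2:
            raise ParameterError("need at least 2 premature (PL) records")
        if sum(self.group_sizes.values()) < 4:
            raise ParameterError("need at least 4 records in total")
        if self.fs * self.duration_s < 40 * self.fs:
            raise ParameterError("duration too short for an analyzable record")


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit SD."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1]  # avoid the DC singularity
    spec /= f ** (exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    return x / np.std(x)


def _narrowband_noise(
    n: int,
    fs: float,
    f_center: float,
    bandwidth: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-SD narrowband Gaussian noise centred on ``f_center``.

    White noise shaped by a Gaussian spectral window of the given full width
    at half maximum; a stochastic, non-periodic stand-in for physiological
    narrowband activity (spectral peak without tone-like regularity)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    sigma = bandwidth / 2.355  # FWHM -> gaussian sigma
    spec *= np.exp(-0.5 * ((f - f_center) / sigma) ** 2)
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _jittered_tone(
    n: int,
    fs: float,
    f0: float,
    freq_sd: float,
    rng: np.random.Generator,
    tau_s: float = 30.0,
) -> np.ndarray:
    """Unit-amplitude tone with mean-reverting (OU) frequency jitter.

    The instantaneous frequency fluctuates around ``f0`` with stationary
    standard deviation ``freq_sd`` and correlation time ``tau_s``, so the
    spectral line width does not grow with record duration."""
    alpha = 1.0 / (tau_s * fs)
    step_sd = freq_sd * np.sqrt(2.0 * alpha - alpha * alpha)
    from scipy.signal import lfilter

    eps = rng.standard_normal(n) * step_sd
    dev = lfilter([1.0], [1.0, -(1.0 - alpha)], eps)
    freq = np.clip(f0 + dev, 0.3 * f0, 1.7 * f0)
    phase = 2.0 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    return np.sin(phase)


def generate_record(
    premature: bool,
    effects: ClassEffectParams,
    fs: float = 20.0,
    duration_s: float = 1800.0,
    seed: int = 0,
    record_id: str = "synth",
    meta: RecordMetadata | None = None,
) -> EHGRecord:
    """Generate one 3-channel record of the requested class."""
    n = int(round(fs * duration_s))
    rng = np.random.default_rng(seed)

    # One shared gain models overall conductivity/electrode coupling; the
    # LF and FWL components also get small independent jitters.  The
    # premature class multiplies the FWL *power* peak by fwl_peak_gain
    # (amplitude x sqrt(gain)), which elevates the normalized peak
    # amplitude by ~gain while keeping it below the B0 reference peak.
    shared_scale = rng.lognormal(0.0, effects.amp_jitter_sd)
    lf_amp = effects.lf_amp * shared_scale * rng.lognormal(0.0, effects.component_jitter_sd)
    lf = lf_amp * _jittered_tone(n, fs, effects.lf_center_hz, 0.010, rng, tau_s=2.0)

    # Premature records concentrate the FWL line into a narrower band at
    # unchanged power: the spectral *peak* rises by ~fwl_peak_gain while
    # the total band power -- and with it the band medians and the
    # regularity seen by the entropy features -- stays class-independent.
    fwl_amp = effects.fwl_amp * shared_scale * rng.lognormal(0.0, effects.component_jitter_sd)
    fwl_sd = effects.fwl_freq_sd
    if premature:
        fwl_sd /= effects.fwl_peak_gain
    fwl_center = effects.fwl_center_hz + rng.uniform(
        -effects.fwl_center_jitter, effects.fwl_center_jitter
    )
    fwl = fwl_amp * _jittered_tone(n, fs, fwl_center, fwl_sd, rng, tau_s=2.0)

    mhr = effects.mhr_base - (effects.mhr_shift if premature else 0.0)
    mhr += rng.normal(0.0, effects.mhr_record_sd)
    heart = np.zeros(n)
    for h, amp in enumerate(effects.harmonic_amps, start=1):
        amp_rec = amp * rng.lognormal(0.0, effects.amp_jitter_sd)
        # line width and sideband split are fixed per harmonic (not tied
        # to the class-shifted rate), so hump shape carries no class
        # information; the 3rd harmonic splits into heart-rate-variability
        # sidebands, which blurs the exact peak location while leaving the
        # in-band median anchored to the heart rate
        width = effects.mhr_line_width * h * effects.mhr_base
        if h == 3 and effects.mhr_sideband_hz > 0.0:
            for sb in (-effects.mhr_sideband_hz, effects.mhr_sideband_hz):
                heart += (amp_rec / np.sqrt(2.0)) * _jittered_tone(
                    n, fs, h * mhr + sb, width / 2.0, rng, tau_s=10.0
                )
        else:
            heart += amp_rec * _jittered_tone(n, fs, h * mhr, width, rng, tau_s=5.0)

    fwh_center = rng.uniform(effects.fwh_lo, effects.fwh_hi)
    fwh_amp = effects.fwh_amp * rng.lognormal(0.0, effects.fwh_amp_jitter_sd)
    fwh = fwh_amp * _narrowband_noise(n, fs, fwh_center, effects.fwh_bandwidth, rng)

    signals = {}
    for c, name in enumerate(("S1", "S2", "S3")):
        gain = rng.uniform(0.9, 1.1)
        shared = (
            lf
            + effects.fwl_channel_gains[c] * fwl
            + effects.heart_channel_gains[c] * heart
            + fwh
        )
        noise = effects.noise_scale * _pink_noise(n, effects.noise_exponent, rng)
        signals[name] = gain * shared + noise

    if meta is None:
        rec_week = rng.uniform(29.0, 32.0)
        if premature:
            deliv = rng.uniform(max(rec_week + 0.5, 30.0), 36.5)
        else:
            deliv = rng.uniform(37.5, 41.5)
        meta = RecordMetadata(
            gestation_at_recording=rec_week,
            gestation_at_delivery=deliv,
            delivery_mode=DeliveryMode.SPONTANEOUS,
            dataset=Dataset.SYNTHETIC,
            epoch="later",
        )
    return EHGRecord(record_id=record_id, signals=signals, fs=fs, meta=meta)


def generate_dataset(config: SyntheticConfig) -> RecordCollection:
    """Generate a labeled collection with the configured group layout.

    Premature (PL) records use the premature class effects; all term groups
    share the term effects and differ only in delivery-mode label, mirroring
    the finding that term delivery modes behave alike in feature space.
    """
    records = []
    rng = np.random.default_rng(child_seed(config.seed, 0))
    idx = 0
    for group in (GroupLabel.PL, GroupLabel.TL, GroupLabel.IL, GroupLabel.CL, GroupLabel.ICL):
        n_group = config.group_sizes.get(group, 0)
        premature = group is GroupLabel.PL
        mode = _MODE_BY_GROUP[group]
        for j in range(n_group):
            rec_week = rng.uniform(29.0, 32.0)
            if premature:
                deliv = rng.uniform(max(rec_week + 0.5, 30.0), 36.5)
            else:
                deliv = rng.uniform(37.5, 41.5)
            meta = RecordMetadata(
                gestation_at_recording=rec_week,
                gestation_at_delivery=deliv,
                delivery_mode=mode,
                dataset=Dataset.SYNTHETIC,
                epoch="later",
            )
            records.append(
                generate_record(
                    premature=premature,
                    effects=config.effects,
                    fs=config.fs,
                    duration_s=config.duration_s,
                    seed=child_seed(config.seed, 1, idx),
                    record_id=f"{group.value}_{j:03d}",
                    meta=meta,
                )
            )
            idx += 1
    return RecordCollection(records=records)


def null_effects() -> ClassEffectParams:
    """Effects with no class contrast (gain 1, no heart-rate shift)."""
    return replace(ClassEffectParams(), fwl_peak_gain=1.0, mhr_shift=0.0)


def write_fixture(collection: RecordCollection, directory) -> None:
    """Write a collection as WFDB-compatible header/signal pairs."""
    import warnings as _warnings

    if len(collection) == 0:
        _warnings.warn("empty collection: nothing written", stacklevel=2)
        return
    for rec in collection:
        write_ehg_record(rec, directory)
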
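"""The ten analysis frequency bands of the uterine EMG (EHG).

The bands tile and overlap the 0.08-5.0 Hz range of the 20 Hz EHG:

* ``B0`` (0.08-1.0 Hz) is the reference band for the normalized peak
  amplitude and is mainly reflective of uterine electrical activity;
* ``B1``/``B2``/``B3`` (1.0-2.2 / 2.2-3.5 / 3.5-5.0 Hz) capture the maternal
  heart rate and its 2nd and 3rd harmonics as seen on the abdominal wall;
* ``Bb`` (0.3-4.0 Hz) and ``B0b`` (0.08-4.0 Hz) are broad catch-all bands;
* ``B0L`` (0.08-0.3 Hz), ``B0Lp`` (0.125-0.575 Hz) and ``B0Lpp``
  (0.225-0.475 Hz) target the Fast Wave Low (FWL) components, while
  ``B0Hp`` (0.575-1.0 Hz) targets the Fast Wave High below 1.0 Hz.

Band-name suffix ``p`` stands for the prime in the printed band names
(``B0Lp`` == B0L', ``B0Lpp`` == B0L'', ``B0Hp`` == B0H').
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError


@dataclass(frozen=True)
class Band:
    """A frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ParameterError(
                f"band {self.name}: need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})"
            )

    def validate_against(self, fs: float) -> None:
        if self.f_hi > fs / 2.0:
            raise ParameterError(
                f"band {self.name} upper edge {self.f_hi} Hz exceeds Nyquist {fs / 2.0} Hz"
            )


#: Canonical band table, in the order used for feature-spec enumeration.
BANDS: dict[str, Band] = {
    b.name: b
    for b in (
        Band("B0", 0.08, 1.0),
        Band("B1", 1.0, 2.2),
        Band("B2", 2.2, 3.5),
        Band("B3", 3.5, 5.0),
        Band("Bb", 0.3, 4.0),
        Band("B0b", 0.08, 4.0),
        Band("B0L", 0.08, 0.3),
        Band("B0Lp", 0.125, 0.575),
        Band("B0Lpp", 0.225, 0.475),
        Band("B0Hp", 0.575, 1.0),
    )
}

#: The reference band for the normalized peak amplitude (PA).
REFERENCE_BAND = BANDS["B0"]


def get_band(name: str) -> Band:
    try:
        return BANDS[name]
    except KeyError:
        raise ParameterError(f"unknown band {name!r}; known: {sorted(BANDS)}") from None
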
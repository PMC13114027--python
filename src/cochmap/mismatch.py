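"""Frequency-to-place mismatch in semitones and its per-ear summary at C6.

With default clinical maps, a shallowly inserted array leaves each contact
basal to the cochlear place its filter band was designed for: the
Greenwood place frequency at the contact exceeds the assigned centre
frequency.  The mismatch at contact k is the absolute semitone interval
``|12 log2(f_place / f_center)|``.

Following common practice, a fourth-order polynomial is fitted to the
per-contact deviations as a function of insertion angle and evaluated at
the mid-array contact C6, whose place sits in the 1-2 kHz region that
carries most speech information; the resulting scalar is the ear's
mismatch statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial

from .electrode_map import ElectrodeState, FrequencyMap

__all__ = ["MismatchProfile", "semitone_deviation", "fit_mismatch_profile", "mismatch_at_c6"]

_C6_INDEX = 5  # apex-first: C1 -> 0, C6 -> 5
_POLY_DEGREE = 4


def semitone_deviation(f_center, f_place):
    """Absolute semitone interval between two frequencies.

    ``|12 log2(f_place / f_center)|`` — symmetric in its arguments; 12
    semitones per octave.
    """
    fc = np.asarray(f_center, float)
    fp = np.asarray(f_place, float)
    if np.any(fc <= 0) or np.any(fp <= 0):
        raise ValueError("frequencies must be positive")
    s = np.abs(12.0 * np.log2(fp / fc))
    return float(s) if (np.isscalar(f_center) and np.isscalar(f_place)) else s


@dataclass(frozen=True)
class MismatchProfile:
    """Fitted per-ear mismatch profile and its C6 summary.

    ``coeffs`` are the degree-4 least-squares polynomial coefficients in
    the plain degree basis (ascending, angle in degrees).  ``fallback``
    marks ears with fewer than 5 intracochlear contacts, where the raw C6
    deviation replaces the fit; ``clamped`` marks ears where the smoother
    dipped below zero at C6 and was clamped.
    """

    angles_deg: np.ndarray
    deviations_st: np.ndarray
    coeffs: np.ndarray
    mismatch_c6: float
    c6_place_hz: float
    c6_center_hz: float
    target_band: tuple[float, float] = (1000.0, 2000.0)
    fallback: bool = False
    clamped: bool = False

    def evaluate(self, theta_deg):
        """Evaluate the fitted polynomial at angle(s) in degrees."""
        return Polynomial(self.coeffs)(np.asarray(theta_deg, float))

    @property
    def c6_in_target_band(self) -> bool:
        lo, hi = self.target_band
        return lo <= self.c6_place_hz <= hi


def fit_mismatch_profile(
    state: ElectrodeState,
    freq_map: FrequencyMap | None = None,
    signed_fit: bool = False,
) -> MismatchProfile:
    """Fit the degree-4 mismatch-versus-angle polynomial for one ear.

    Deviations are taken in absolute value before fitting (set
    ``signed_fit=True`` to fit the signed deviation and take the absolute
    value of the smoother instead).  Ears with fewer than 5 intracochlear
    contacts cannot support a quartic: the raw C6 deviation is used and
    the profile is flagged ``fallback``.
    """
    centers = state.center_hz if freq_map is None else np.asarray(freq_map.centers, float)
    inside = state.intracochlear
    theta = state.angles_deg[inside]
    signed = 12.0 * np.log2(state.place_hz[inside] / centers[inside])
    dev = signed if signed_fit else np.abs(signed)

    c6_place = float(state.place_hz[_C6_INDEX])
    c6_center = float(centers[_C6_INDEX])
    theta6 = float(state.angles_deg[_C6_INDEX])
    if np.isnan(theta6):
        raise ValueError("C6 is extracochlear; no mismatch statistic is defined")

    if inside.sum() < _POLY_DEGREE + 1:
        raw = semitone_deviation(c6_center, c6_place)
        return MismatchProfile(
            angles_deg=theta,
            deviations_st=np.abs(dev),
            coeffs=np.array([raw]),
            mismatch_c6=raw,
            c6_place_hz=c6_place,
            c6_center_hz=c6_center,
            fallback=True,
        )

    # Fit in a rescaled domain for conditioning; report plain coefficients.
    fit = Polynomial.fit(theta, dev, _POLY_DEGREE)
    coeffs = fit.convert().coef
    value = float(fit(theta6))
    if signed_fit:
        value = abs(value)
    clamped = value < 0.0
    return MismatchProfile(
        angles_deg=theta,
        deviations_st=np.abs(dev),
        coeffs=coeffs,
        mismatch_c6=max(value, 0.0),
        c6_place_hz=c6_place,
        c6_center_hz=c6_center,
        clamped=clamped,
    )


def mismatch_at_c6(profile: MismatchProfile, state: ElectrodeState) -> float:
    """The ear's scalar mismatch: the fitted profile at C6's own angle.

    Equals ``profile.mismatch_c6``; re-evaluates the polynomial at the
    state's C6 angle so a profile can be paired with an updated state.
    """
    if profile.fallback:
        return profile.mismatch_c6
    theta6 = float(state.angles_deg[_C6_INDEX])
    if np.isnan(theta6):
        raise ValueError("C6 is extracochlear; no mismatch statistic is defined")
    return max(float(profile.evaluate(theta6)), 0.0)
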
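"""Lateral-wall electrode array model and default frequency allocation.

Models a straight 12-contact array (28 mm overall, 23.1 mm between the
most apical and most basal contacts) inserted along the lateral wall, and
the clinical default filter bank: 12 logarithmically spaced channels over
70-8500 Hz, apex-aligned so the most apical contact (C1) carries the
lowest band.  Contacts are numbered apex-first, C1 (apical) to C12
(basal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    GeometryConfig,
    electrode_coverage,
    lateral_wall_model,
    length_to_angle,
)
from .tonotopy import GreenwoodParams, place_frequency_at_angle

__all__ = [
    "ElectrodeArray",
    "FrequencyMap",
    "ElectrodeState",
    "default_frequency_map",
    "locate_contacts",
]


@dataclass(frozen=True)
class ElectrodeArray:
    """Physical array: equally spaced contacts along ``contact_span`` mm."""

    n_contacts: int = 12
    contact_span: float = 23.1  # mm, C1 to C12
    array_length: float = 28.0  # mm overall

    def __post_init__(self) -> None:
        if self.n_contacts < 2:
            raise ValueError("need at least 2 contacts")
        if not 0 < self.contact_span <= self.array_length:
            raise ValueError("require 0 < contact_span <= array_length")

    @property
    def pitch(self) -> float:
        """Centre-to-centre contact spacing, mm."""
        return self.contact_span / (self.n_contacts - 1)


@dataclass(frozen=True)
class FrequencyMap:
    """Filter-bank band edges and channel centre frequencies (Hz).

    ``band_edges`` holds ``n + 1`` strictly ascending values with an exact
    constant ratio between consecutive edges; ``centers`` are the geometric
    means of adjacent edges, apex-aligned (index 0 belongs to C1).
    """

    band_edges: np.ndarray
    centers: np.ndarray
    f_low: float = 70.0
    f_high: float = 8500.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.band_edges, float)
        centers = np.asarray(self.centers, float)
        if edges.ndim != 1 or len(edges) != len(centers) + 1:
            raise ValueError("need n+1 band edges for n centers")
        if np.any(np.diff(edges) <= 0) or np.any(np.diff(centers) <= 0):
            raise ValueError("band edges and centers must be strictly ascending")
        object.__setattr__(self, "band_edges", edges)
        object.__setattr__(self, "centers", centers)

    @property
    def n_channels(self) -> int:
        return len(self.centers)


def default_frequency_map(
    f_low: float = 70.0, f_high: float = 8500.0, n_channels: int = 12
) -> FrequencyMap:
    """Logarithmic filter bank: geometric band edges, geometric-mean centres."""
    if not 0 < f_low < f_high:
        raise ValueError(f"require 0 < f_low < f_high, got {f_low}, {f_high}")
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    edges = f_low * (f_high / f_low) ** (np.arange(n_channels + 1) / n_channels)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return FrequencyMap(edges, centers, f_low=f_low, f_high=f_high)


@dataclass(frozen=True)
class ElectrodeState:
    """Per-contact geometry and frequency assignment for one ear.

    Arrays are apex-first (index 0 = C1).  Extracochlear contacts — basal
    contacts left outside the cochlea by a partial insertion — carry NaN
    angles and place frequencies and are counted in ``n_extracochlear``.
    """

    angles_deg: np.ndarray
    place_hz: np.ndarray
    center_hz: np.ndarray
    aid_deg: float
    coverage_pct: float
    insertion_complete: bool
    n_extracochlear: int = 0
    cdl: float = field(default=float("nan"))
    inserted_mm: float = field(default=float("nan"))

    @property
    def n_contacts(self) -> int:
        return len(self.angles_deg)

    @property
    def intracochlear(self) -> np.ndarray:
        """Boolean mask of contacts inside the cochlea (apex-first)."""
        return ~np.isnan(self.angles_deg)

    def to_frame(self):
        """Per-contact table: contact, angle_deg, place_hz, center_hz."""
        import pandas as pd

        return pd.DataFrame(
            {
                "contact": [f"C{i + 1}" for i in range(self.n_contacts)],
                "angle_deg": self.angles_deg,
                "place_hz": self.place_hz,
                "center_hz": self.center_hz,
            }
        )


def locate_contacts(
    inserted_mm: float,
    cdl: float,
    array: ElectrodeArray = ElectrodeArray(),
    cfg: GeometryConfig = GeometryConfig(),
    freq_map: FrequencyMap | None = None,
    greenwood: GreenwoodParams = GreenwoodParams(),
) -> ElectrodeState:
    """Place every contact angularly and assign place and centre frequencies.

    The apical contact C1 sits at arc position ``inserted_mm`` from the
    round window; contact k sits one pitch more basal than k-1.  Contacts
    whose arc position falls below zero are extracochlear: the state is
    flagged ``insertion_complete=False`` and those contacts carry NaN.
    """
    if freq_map is None:
        freq_map = default_frequency_map(n_channels=array.n_contacts)
    if freq_map.n_channels != array.n_contacts:
        raise ValueError(
            f"frequency map has {freq_map.n_channels} channels for "
            f"{array.n_contacts} contacts"
        )
    coverage = electrode_coverage(inserted_mm, cdl)  # validates 0 < L <= cdl

    positions = inserted_mm - np.arange(array.n_contacts) * array.pitch
    inside = positions >= 0
    n_out = int(np.count_nonzero(~inside))

    lateral = lateral_wall_model(cdl, cfg)
    angles = np.full(array.n_contacts, np.nan)
    angles[inside] = length_to_angle(positions[inside], lateral)

    place = np.full(array.n_contacts, np.nan)
    place[inside] = place_frequency_at_angle(angles[inside], cdl, cfg, greenwood)

    return ElectrodeState(
        angles_deg=angles,
        place_hz=place,
        center_hz=np.asarray(freq_map.centers, float).copy(),
        aid_deg=float(angles[0]),
        coverage_pct=coverage,
        insertion_complete=(n_out == 0),
        n_extracochlear=n_out,
        cdl=cdl,
        inserted_mm=inserted_mm,
    )
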
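"""Loose and tapped bulk-density arithmetic.

A tap test fills a box of known mass ``m_c`` (g) and volume ``v_c`` (cm3)
with powder, weighs it loose (``m_l``) and after a standardized tapping
run (``m_t``, here 1250 taps as metadata), and reports

    loose density  D_L = (m_l - m_c) / v_c
    tapped density D_T = (m_t - m_c) / v_c

converted from g/cm3 to kg/m3 (x1000).  Milk-powder bulk densities fall
roughly in 300-700 kg/m3; values outside that band are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

#: plausibility band for instant whole milk powder bulk density, kg/m3
PLAUSIBLE_RANGE = (300.0, 700.0)
TAP_COUNT = 1250  # metadata only


def _density(m_total: float, m_c: float, v_c: float) -> float:
    if v_c <= 0:
        raise ValueError("container volume must be positive")
    if m_total < m_c:
        raise ValueError("total mass below container mass")
    return (m_total - m_c) / v_c * 1000.0


def loose_density(m_l: float, m_c: float, v_c: float) -> float:
    """Loose bulk density in kg/m3 from masses in g and volume in cm3."""
    return _density(m_l, m_c, v_c)


def tapped_density(m_t: float, m_c: float, v_c: float) -> float:
    """Tapped bulk density in kg/m3 from masses in g and volume in cm3."""
    return _density(m_t, m_c, v_c)


def is_plausible(density: float, band: tuple[float, float] = PLAUSIBLE_RANGE) -> bool:
    """True if a bulk density lies in the expected milk-powder band."""
    return band[0] <= density <= band[1]


@dataclass
class DensityMeasurement:
    """One tap-test record: masses (g), volume (cm3), derived densities (kg/m3)."""

    m_c: float
    m_l: float
    m_t: float
    v_c: float
    d_l: float = None  # type: ignore[assignment]
    d_t: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.m_t < self.m_l:
            raise ValueError("tapped mass below loose mass")
        self.d_l = loose_density(self.m_l, self.m_c, self.v_c)
        self.d_t = tapped_density(self.m_t, self.m_c, self.v_c)
        for label, d in (("loose", self.d_l), ("tapped", self.d_t)):
            if d > 0 and not is_plausible(d):
                warnings.warn(
                    f"{label} density {d:.1f} kg/m3 outside plausible band "
                    f"{PLAUSIBLE_RANGE}",
                    stacklevel=2,
                )
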
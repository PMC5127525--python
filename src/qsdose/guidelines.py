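"""Frequency-dependent basic restrictions (general-public tier).

Implements the ICNIRP 1998 induced-current-density limit, the ICNIRP 2010
internal-electric-field (E99) limit, the IEEE C95.1 line-averaged internal
field (E5mm) limits per tissue group, and the SAR limits shared by both
guideline families in the intermediate band. Only the general-public
(unrestricted environment) tier is provided; frequencies outside each
guideline's stated validity band are refused rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

GUIDELINES = ("ICNIRP1998", "ICNIRP2010", "IEEE")

#: Validity bands (Hz) of the implemented limits.
_BANDS = {
    "ICNIRP1998": (100e3, 10e6),
    "ICNIRP2010": (100e3, 10e6),
    "IEEE": (100e3, 5e6),
}

_SAR_LIMITS = {  # constant across the band, shared ICNIRP/IEEE values
    ("SAR_10g", "head_trunk"): 2.0,
    ("SAR_10g", "limbs"): 4.0,
    ("SAR_wm", None): 0.08,
}

#: IEEE E5mm scaling: limit = coefficient · f / f_e (V/m rms basis as printed).
_IEEE_E5MM = {
    "brain": (5.89e-3, 20.0),
    "heart": (0.943, 167.0),
    "limbs": (2.1, 3350.0),
    "other": (0.701, 3350.0),
}


@dataclass(frozen=True)
class GuidelineLimit:
    guideline: str
    metric: str
    frequency: float
    value: float
    units: str
    group: str | None = None
    band: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("limit value must be > 0")


def _check_band(guideline: str, frequency: float):
    lo, hi = _BANDS[guideline]
    if not (lo <= frequency <= hi):
        raise ValueError(
            f"{guideline} limits implemented for {lo:g}–{hi:g} Hz; "
            f"got {frequency:g} Hz"
        )


def limit(
    guideline: str,
    metric: str,
    frequency: float,
    group: str | None = None,
) -> GuidelineLimit:
    """Basic-restriction value for (guideline, metric) at ``frequency`` Hz.

    Metrics: ``J`` (ICNIRP1998, A/m²), ``E99`` (ICNIRP2010, V/m), ``E5mm``
    (IEEE, V/m, needs a tissue ``group``), ``SAR_10g`` (needs group
    ``head_trunk`` or ``limbs``) and ``SAR_wm`` (any guideline).
    """
    if guideline not in GUIDELINES:
        raise ValueError(f"guideline must be one of {GUIDELINES}, got {guideline!r}")
    _check_band(guideline, frequency)
    band = _BANDS[guideline]

    if metric == "J":
        if guideline != "ICNIRP1998":
            raise ValueError("the J basic restriction belongs to ICNIRP1998")
        # general public: f/500 mA/m² with f in Hz
        return GuidelineLimit(
            guideline, metric, frequency, frequency / 500.0e3, "A/m²", None, band
        )
    if metric == "E99":
        if guideline != "ICNIRP2010":
            raise ValueError("the E99 basic restriction belongs to ICNIRP2010")
        return GuidelineLimit(
            guideline, metric, frequency, 1.35e-4 * frequency, "V/m", None, band
        )
    if metric == "E5mm":
        if guideline != "IEEE":
            raise ValueError("the E5mm basic restriction belongs to IEEE")
        if group not in _IEEE_E5MM:
            raise ValueError(
                f"E5mm needs a tissue group in {tuple(_IEEE_E5MM)}, got {group!r}"
            )
        coeff, fe = _IEEE_E5MM[group]
        return GuidelineLimit(
            guideline, metric, frequency, coeff * frequency / fe, "V/m", group, band
        )
    if metric in ("SAR_10g", "SAR_wm"):
        key = (metric, group if metric == "SAR_10g" else None)
        if key not in _SAR_LIMITS:
            raise ValueError(
                "SAR_10g needs group 'head_trunk' or 'limbs'; SAR_wm takes none"
            )
        return GuidelineLimit(
            guideline, metric, frequency, _SAR_LIMITS[key], "W/kg",
            key[1], band,
        )
    raise ValueError(f"unknown metric {metric!r}")


def compliance_table(report, frequency: float | None = None) -> pd.DataFrame:
    """Compare a :class:`~qsdose.metrics.DoseReport` against every limit.

    One row per applicable (guideline, metric, group): computed value, limit,
    pass/fail, margin (limit/value) and the maximum allowable power derived
    from the report's stated input power (quadratic scaling for field
    metrics, linear for SAR).
    """
    from .metrics import maximum_allowable_power

    f = report.frequency if frequency is None else frequency
    p_ref = report.input_power
    rows = []

    def add(guideline, metric, group, value, scaling):
        if value is None:
            return
        lim = limit(guideline, metric, f, group)
        ok = value <= lim.value
        map_w = (
            maximum_allowable_power(value, lim.value, p_ref, scaling)
            if value > 0
            else float("inf")
        )
        rows.append(
            {
                "guideline": guideline,
                "metric": metric,
                "group": group or "",
                "value": value,
                "limit": lim.value,
                "units": lim.units,
                "pass": bool(ok),
                "margin": lim.value / value if value > 0 else float("inf"),
                "MAP_W": map_w,
            }
        )

    add("ICNIRP1998", "J", None, report.j_max, "field")
    add("ICNIRP2010", "E99", None, report.e99, "field")
    for group, value in sorted(report.e5mm_groups.items()):
        add("IEEE", "E5mm", group, value, "field")
    add("IEEE", "SAR_10g", "head_trunk", report.sar_10g_head_trunk, "power")
    if report.sar_10g_limbs is not None:
        add("IEEE", "SAR_10g", "limbs", report.sar_10g_limbs, "power")
    add("IEEE", "SAR_wm", None, report.sar_wm, "power")
    return pd.DataFrame(rows)
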
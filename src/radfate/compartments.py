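"""Fast/slow NHEJ compartment model and pathway assignment.

Two factors decide whether a DSB is repaired by the fast
(resection-independent) or slow (resection-dependent) NHEJ compartment:
the chromatin environment and the complexity of the break.  DSBs in
heterochromatin, and complex DSBs in euchromatin, go to the slow
compartment; simple euchromatic DSBs go to the fast one.  The overall
slow fraction is therefore

    F_slow = HC + (1 - HC) * DSB_complex,EC

where HC is the heterochromatin fraction and DSB_complex,EC the complex
fraction among euchromatic DSBs.  To compare radiation qualities across
cell lines with different HC, the *extra* slow fraction relative to an
X-ray baseline is used:

    ExF_slow = (F_slow(rad) - F_slow(X-ray)) / (1 - F_slow(X-ray))

in which HC cancels algebraically.  ExF_slow is empirically linear in
the complex-DSB fraction; the fitted line (slope 0.8268, intercept
0.0705) maps a simulated complexity spectrum onto repair kinetics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .damage import Chromatin, Complexity, DamageSet, Pathway

__all__ = [
    "CompartmentParams",
    "RepairFractionDatum",
    "fraction_slow",
    "exf_slow",
    "predict_exf_from_complexity",
    "fit_exf_line",
    "assign_pathways",
    "read_fit_data_tsv",
    "fit_report_json",
]

#: Fitted ExF_slow ~ DSB_c line: slope and intercept.
DEFAULT_SLOPE = 0.8268
DEFAULT_INTERCEPT = 0.0705


def _check_unit_interval(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass(frozen=True)
class CompartmentParams:
    """Parameters of the complexity -> slow-fraction mapping."""

    slope: float = DEFAULT_SLOPE
    intercept: float = DEFAULT_INTERCEPT
    hc_fraction: float = 0.2

    def __post_init__(self) -> None:
        _check_unit_interval("hc_fraction", self.hc_fraction)


@dataclass(frozen=True)
class RepairFractionDatum:
    """One experiment: complex-DSB fraction and fitted slow fractions."""

    label: str
    dsb_c_fraction: float
    f_slow: float
    f_slow_xray_reference: float

    def __post_init__(self) -> None:
        _check_unit_interval("dsb_c_fraction", self.dsb_c_fraction)
        _check_unit_interval("f_slow", self.f_slow)
        _check_unit_interval("f_slow_xray_reference", self.f_slow_xray_reference)


def fraction_slow(hc: float, dsb_complex_ec: float) -> float:
    """Overall slow-compartment fraction: HC + (1 - HC) * DSB_complex,EC."""
    _check_unit_interval("hc", hc)
    _check_unit_interval("dsb_complex_ec", dsb_complex_ec)
    return hc + (1.0 - hc) * dsb_complex_ec


def exf_slow(f_slow_radiation: float, f_slow_xray: float) -> float:
    """Extra slow fraction of a radiation quality relative to X-rays."""
    _check_unit_interval("f_slow_radiation", f_slow_radiation)
    _check_unit_interval("f_slow_xray", f_slow_xray)
    if f_slow_xray >= 1.0:
        raise ZeroDivisionError("f_slow_xray = 1 leaves no fast compartment to compare")
    return (f_slow_radiation - f_slow_xray) / (1.0 - f_slow_xray)


def predict_exf_from_complexity(
    dsb_c_fraction: float, params: CompartmentParams | None = None
) -> float:
    """Predicted ExF_slow from the complex-DSB fraction (linear map, clipped)."""
    _check_unit_interval("dsb_c_fraction", dsb_c_fraction)
    params = params or CompartmentParams()
    return float(np.clip(params.slope * dsb_c_fraction + params.intercept, 0.0, 1.0))


def fit_exf_line(
    data: list[RepairFractionDatum],
) -> tuple[float, float, float, float]:
    """Ordinary least squares of ExF_slow on DSB_c.

    Returns ``(slope, intercept, pearson_r, r_squared)``.  Requires at
    least three points with non-degenerate spread in both coordinates.
    """
    if len(data) < 3:
        raise ValueError(f"need >= 3 data points, got {len(data)}")
    x = np.array([d.dsb_c_fraction for d in data])
    y = np.array([exf_slow(d.f_slow, d.f_slow_xray_reference) for d in data])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in dsb_c_fraction; cannot fit a line")
    if np.ptp(y) == 0:
        raise ValueError("zero variance in ExF_slow; Pearson r undefined")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), float(res.rvalue**2)


def assign_pathways(
    damage: DamageSet,
    params: CompartmentParams | None = None,
    seed: int = 0,
    forced_f_slow: float | None = None,
) -> DamageSet:
    """Assign each DSB to the fast or slow NHEJ compartment.

    Default (mechanistic) mode: heterochromatic DSBs and complex
    euchromatic DSBs go slow, simple euchromatic DSBs go fast.

    Sweep mode (``forced_f_slow`` given): the compartment is an
    independent Bernoulli(F_slow) draw per DSB, overriding the labels —
    used to impose population slow fractions such as 20-80%.

    Returns a new :class:`DamageSet`; the input is not modified.
    """
    params = params or CompartmentParams()
    out = damage.copy()
    if forced_f_slow is not None:
        _check_unit_interval("forced_f_slow", forced_f_slow)
        rng = np.random.default_rng(seed)
        draws = rng.random(len(out.dsbs)) < forced_f_slow
        for rec, slow in zip(out.dsbs, draws):
            rec.pathway = Pathway.SLOW if slow else Pathway.FAST
        return out

    for rec in out.dsbs:
        if rec.complexity is None:  # pragma: no cover - dataclass enforces this
            raise ValueError(f"DSB {rec.id} has no complexity label")
        if rec.chromatin == Chromatin.HC or rec.complexity == Complexity.COMPLEX:
            rec.pathway = Pathway.SLOW
        else:
            rec.pathway = Pathway.FAST
    return out


# ---------------------------------------------------------------------------
# I/O helpers

def read_fit_data_tsv(path) -> list[RepairFractionDatum]:
    """Read fit input: columns label, dsb_c_fraction, f_slow, f_slow_xray."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "dsb_c_fraction", "f_slow", "f_slow_xray"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fit data missing columns: {sorted(missing)}")
    return [
        RepairFractionDatum(
            label=str(row.label),
            dsb_c_fraction=float(row.dsb_c_fraction),
            f_slow=float(row.f_slow),
            f_slow_xray_reference=float(row.f_slow_xray),
        )
        for row in df.itertuples()
    ]


def fit_report_json(data: list[RepairFractionDatum]) -> str:
    slope, intercept, r, r2 = fit_exf_line(data)
    return json.dumps(
        {
            "n_points": len(data),
            "slope": slope,
            "intercept": intercept,
            "pearson_r": r,
            "r_squared": r2,
        },
        indent=2,
    )
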
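"""qPCR standard curves and Ct-to-copies conversion.

A qPCR standard curve is an ordinary least-squares fit of cycle threshold
(Ct) on log10 of the initial template copy number:

    Ct = intercept + slope * log10(copies)

A valid curve has a negative slope; the per-cycle amplification
efficiency is ``10^(-1/slope) - 1`` (1.0 means perfect doubling, slope
about -3.32).  Inverting the curve converts sample Ct values to absolute
copy numbers, which :func:`per_gram_from_reaction` places on the same
copies-per-gram scale as the spike-in estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EFFICIENCY_LOW = 0.9
EFFICIENCY_HIGH = 1.1


@dataclass(frozen=True)
class StandardCurve:
    slope: float  # Ct per log10(copies)
    intercept: float  # Ct at 1 copy
    r_squared: float
    efficiency: float  # 10^(-1/slope) - 1
    valid: bool  # slope < 0
    warnings: tuple[str, ...] = ()


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit Ct on log10(copies) by ordinary least squares.

    ``points`` are ``(copies, ct)`` pairs; at least three are required and
    copies must be positive.  A non-negative slope yields a curve flagged
    invalid; an efficiency outside [0.9, 1.1] or a standard series
    spanning fewer than two decades yields a warning flag.
    """
    pts = [(float(c), float(ct)) for c, ct in points]
    if len(pts) < 3:
        raise ValueError("standard curve needs >= 3 points")
    copies = np.array([c for c, _ in pts])
    ct = np.array([t for _, t in pts])
    if np.any(copies <= 0):
        raise ValueError("standard copies must be > 0")
    logc = np.log10(copies)
    res = sps.linregress(logc, ct)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2)
    warnings: list[str] = []
    if np.ptp(logc) < 2:
        warnings.append("standards span fewer than 2 decades")
    valid = slope < 0
    if valid:
        efficiency = float(10 ** (-1.0 / slope) - 1.0)
        if not (EFFICIENCY_LOW <= efficiency <= EFFICIENCY_HIGH):
            warnings.append(f"efficiency {efficiency:.3f} outside [0.9, 1.1]")
    else:
        efficiency = float("nan")
        warnings.append("non-negative slope: curve invalid")
    return StandardCurve(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        efficiency=efficiency,
        valid=valid,
        warnings=tuple(warnings),
    )


def curve_predict(copies: float, curve: StandardCurve) -> float:
    """Predicted Ct for a template of ``copies`` molecules."""
    if copies <= 0:
        raise ValueError("copies must be > 0")
    return curve.intercept + curve.slope * np.log10(copies)


def ct_to_copies(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: ``copies = 10^((ct - intercept)/slope)``.

    Values below one copy are returned as-is (the caller flags them as
    below the quantification range).
    """
    if not curve.valid:
        raise ValueError("cannot convert Ct with an invalid standard curve")
    return float(10 ** ((ct - curve.intercept) / curve.slope))


def per_gram_from_reaction(
    copies_per_reaction: float,
    template_volume_ul: float,
    elution_volume_ul: float,
    feces_mass_g: float,
) -> float:
    """Scale a per-reaction copy number to copies per gram of sample.

    Copies measured in the reaction template are scaled to the whole
    eluate (``elution / template``) and divided by the sample wet mass.
    """
    for name, v in (
        ("copies_per_reaction", copies_per_reaction),
        ("template_volume_ul", template_volume_ul),
        ("elution_volume_ul", elution_volume_ul),
        ("feces_mass_g", feces_mass_g),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v!r}")
    return copies_per_reaction * (elution_volume_ul / template_volume_ul) / feces_mass_g


def average_replicates(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Average replicate Ct columns (``ct_rep1``, ``ct_rep2``, ...).

    Returns one row per input row with ``ct_mean`` and ``ct_sd`` columns;
    replicate means are taken before curve conversion.
    """
    rep_cols = [c for c in ct_table.columns if c.startswith("ct_rep")]
    if not rep_cols:
        raise ValueError("no ct_rep* columns found")
    out = ct_table.drop(columns=rep_cols).copy()
    out["ct_mean"] = ct_table[rep_cols].mean(axis=1)
    out["ct_sd"] = ct_table[rep_cols].std(axis=1, ddof=1)
    return out


def quantify_qpcr(
    ct_table: pd.DataFrame,
    curve: StandardCurve,
    template_volume_ul: float,
    meta: dict[str, tuple[float, float]],
) -> pd.DataFrame:
    """Convert a per-sample Ct table into copies per gram.

    ``ct_table`` needs ``sample_id`` plus either ``ct_mean`` or replicate
    ``ct_rep*`` columns.  ``meta`` maps sample id to ``(elution_volume_ul,
    feces_mass_g)``.  Rows converting to fewer than one copy per reaction
    are marked ``below_quantification``.
    """
    if "ct_mean" not in ct_table.columns:
        ct_table = average_replicates(ct_table)
    rows = []
    for _, row in ct_table.iterrows():
        sid = row["sample_id"]
        if sid not in meta:
            raise ValueError(f"no elution/mass metadata for sample {sid!r}")
        elution, mass = meta[sid]
        copies = ct_to_copies(float(row["ct_mean"]), curve)
        rows.append(
            {
                "sample_id": sid,
                "ct_mean": float(row["ct_mean"]),
                "copies_per_reaction": copies,
                "copies_per_g": per_gram_from_reaction(
                    copies, template_volume_ul, elution, mass
                ),
                "below_quantification": copies < 1,
            }
        )
    return pd.DataFrame(rows)
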
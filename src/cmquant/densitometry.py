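"""Gel-band densitometry normalization and dose-response quantification.

Two-step band normalization for cross-gel comparison:

* Norm1 — target band density divided by the loading molecular-weight
  marker band density of the same lane;
* Norm2 — Norm1 divided by the control-group mean of Norm1, per gel, so the
  control group averages exactly 1 and fold changes are comparable across
  gels.

Co-sedimentation dose-response series are summarized by normalized bound
intensity and the Spearman rank correlation of bound amount vs competitor
dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

REQUIRED_COLUMNS = ("sample_id", "group", "band_density", "marker_density")


@dataclass(frozen=True)
class DoseResponse:
    doses: np.ndarray
    bound_intensity: np.ndarray
    normalized_bound: np.ndarray
    trend_stat: float


def normalize_bands(table: pd.DataFrame,
                    control_label: str = "control") -> pd.DataFrame:
    """Append norm1 and norm2 columns (applied per gel_id).

    Requires every row's marker density to be positive and every gel to
    contain at least one control row.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = table.copy()
    if "gel_id" not in out.columns:
        out["gel_id"] = 0
    bad = out.index[out["marker_density"] <= 0]
    if len(bad):
        raise ValueError(f"non-positive marker density in row {bad[0]} "
                         f"(sample {out.loc[bad[0], 'sample_id']!r})")
    out["norm1"] = out["band_density"] / out["marker_density"]
    out["norm2"] = np.nan
    for gel, sub in out.groupby("gel_id"):
        ctrl = sub["norm1"][sub["group"] == control_label]
        if ctrl.empty:
            raise ValueError(f"gel {gel!r} has no {control_label!r} rows")
        out.loc[sub.index, "norm2"] = sub["norm1"] / ctrl.mean()
    return out


def band_ratio(numerator, denominator):
    """Element-wise band ratio (e.g. dTyr-tubulin over total alpha-tubulin)."""
    num = np.asarray(numerator, dtype=float)
    den = np.asarray(denominator, dtype=float)
    if np.any(den == 0.0):
        raise ValueError("zero denominator band density")
    out = num / den
    return float(out) if out.ndim == 0 else out


def binding_series(doses, bound_intensities) -> DoseResponse:
    """Dose-response summary of bound protein vs competitor dose.

    ``normalized_bound`` is relative to the first (lowest) dose;
    ``trend_stat`` is the Spearman rank correlation (constant series map to
    0 — fully tied ranks carry no trend).
    """
    doses = np.asarray(doses, dtype=float)
    bound = np.asarray(bound_intensities, dtype=float)
    if doses.size != bound.size:
        raise ValueError("doses and intensities must be equal length")
    if doses.size < 3:
        raise ValueError("need at least 3 dose points")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    if bound[0] == 0:
        norm = np.full_like(bound, np.nan)
        norm[0] = 1.0
    else:
        norm = bound / bound[0]
    if np.all(bound == bound[0]):
        rho = 0.0
    else:
        rho = float(sps.spearmanr(doses, bound).statistic)
    return DoseResponse(doses=doses, bound_intensity=bound,
                        normalized_bound=norm, trend_stat=rho)
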
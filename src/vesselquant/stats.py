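"""Per-branch summary statistics and report tables.

Each branch contributes one row: total length, mean and variance of
curvature, torsion, envelope radius and included angle over the profile's
samples, and the fitting-error triple (sum / mean / variance of the minimum
distances from raw skeleton samples to the fitted curve). Undefined samples
(NaN torsion at locally straight points, NaN angle at endpoints, degenerate
envelope radii) are excluded from the statistics of that quantity; if no
sample of a quantity is defined the cell is reported missing (NaN).

Variances are population variances (divide by the number of defined
samples); pass ``ddof=1`` for sample variance. Values are rounded to two
decimals only at serialization, never internally.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import BranchStatistics, GeometryProfile

#: column order of the report table
REPORT_COLUMNS = [
    "Branch", "Length", "CurvMean", "CurvVar", "TorsMean", "TorsVar",
    "RadMean", "RadVar", "AngMean", "AngVar", "ErrSum", "ErrMean", "ErrVar",
]


def _mean_var(values: Optional[np.ndarray],
              ddof: int = 0) -> Tuple[float, float]:
    if values is None:
        return float("nan"), float("nan")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0 or len(v) <= ddof:
        return float("nan"), float("nan")
    return float(v.mean()), float(v.var(ddof=ddof))


def branch_summary(profile: GeometryProfile,
                   fitting_error: Tuple[float, float, float] = (
                       float("nan"), float("nan"), float("nan")),
                   ddof: int = 0) -> BranchStatistics:
    """Summarise one branch profile into a statistics row.

    ``fitting_error`` is the (sum, mean, variance) triple from
    :func:`vesselquant.bspline.fitting_error`.
    """
    cm, cv = _mean_var(profile.curvature, ddof)
    tm, tv = _mean_var(profile.torsion, ddof)
    rm, rv = _mean_var(profile.radius, ddof)
    am, av = _mean_var(profile.angle, ddof)
    n_undef = int(np.sum(~np.isfinite(profile.torsion)))
    return BranchStatistics(
        branch_label=profile.branch_label or "branch",
        length=float(profile.total_length),
        curvature_mean=cm, curvature_var=cv,
        torsion_mean=tm, torsion_var=tv,
        radius_mean=rm, radius_var=rv,
        angle_mean=am, angle_var=av,
        error_sum=float(fitting_error[0]),
        error_mean=float(fitting_error[1]),
        error_var=float(fitting_error[2]),
        torsion_undefined=n_undef,
    )


def statistics_table(rows: Sequence[BranchStatistics]) -> pd.DataFrame:
    """One row per branch with the standard 13 report columns (branch name
    plus 12 numeric columns), full precision."""
    records = []
    for r in rows:
        records.append({
            "Branch": r.branch_label,
            "Length": r.length,
            "CurvMean": r.curvature_mean, "CurvVar": r.curvature_var,
            "TorsMean": r.torsion_mean, "TorsVar": r.torsion_var,
            "RadMean": r.radius_mean, "RadVar": r.radius_var,
            "AngMean": r.angle_mean, "AngVar": r.angle_var,
            "ErrSum": r.error_sum, "ErrMean": r.error_mean,
            "ErrVar": r.error_var,
        })
    return pd.DataFrame.from_records(records, columns=REPORT_COLUMNS)


def write_csv(rows: Sequence[BranchStatistics], path,
              full_precision: bool = False) -> None:
    """Write the branch table as RFC-4180 CSV, two decimal places by
    default (matching how such tables are conventionally reported)."""
    df = statistics_table(rows)
    if full_precision:
        df.to_csv(path, index=False, lineterminator="\r\n")
    else:
        df.to_csv(path, index=False, float_format="%.2f",
                  lineterminator="\r\n")


def write_json(rows: Sequence[BranchStatistics], path) -> None:
    """JSON mirror of the report table, full precision."""
    payload = [r.to_dict() for r in rows]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)
        fh.write("\n")


def symmetric_compare(profile_left: GeometryProfile,
                      profile_right: GeometryProfile) -> dict:
    """Compare a left/right symmetric branch pair sample by sample.

    The left profile is traversed in reverse when its endpoints indicate
    mirrored orientation (its last arc position pairs with the right
    profile's first). Returns per-sample absolute differences and a mean
    absolute difference per quantity (curvature, torsion, radius, angle),
    skipping samples undefined on either side.
    """
    if profile_left.n_samples != profile_right.n_samples:
        raise ValueError("profiles not comparable: sample counts differ")
    flip = False
    # mirrored orientation heuristic: if reversing the left profile makes
    # endpoint quantities (radius if present, else curvature) line up better
    ql = profile_left.radius if profile_left.radius is not None \
        else profile_left.curvature
    qr = profile_right.radius if profile_right.radius is not None \
        else profile_right.curvature
    if ql is not None and qr is not None and len(ql) == len(qr):
        direct = np.nansum(np.abs(ql - qr))
        reverse = np.nansum(np.abs(ql[::-1] - qr))
        flip = reverse < direct
    out = {"flipped_left": bool(flip), "per_sample": {}, "mean_abs": {}}
    for name in ("curvature", "torsion", "radius", "angle"):
        left = getattr(profile_left, name)
        right = getattr(profile_right, name)
        if left is None or right is None:
            continue
        lv = np.asarray(left, dtype=float)
        if flip:
            lv = lv[::-1]
        delta = np.abs(lv - np.asarray(right, dtype=float))
        out["per_sample"][name] = delta
        finite = delta[np.isfinite(delta)]
        out["mean_abs"][name] = float(finite.mean()) if len(finite) else \
            float("nan")
    return out
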
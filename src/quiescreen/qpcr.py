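"""Relative quantitation of qPCR expression by the comparative Ct method.

Replicate Cts are averaged per (sample, target); dCt subtracts the
housekeeping Ct; ddCt subtracts the calibrator's dCt; RQ = 2^-ddCt.
Undetermined target Cts (missing values) are reported as detectable=False
with RQ 0, never imputed.  Amplification efficiency is fixed at 2.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class RqResult:
    sample_id: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    detectable: bool


def relative_quantitation(
    wells: pd.DataFrame,
    calibrator: str,
    target: str,
    housekeeping: str = "GAPDH",
) -> pd.DataFrame:
    """Compute RQ per sample from a wells table.

    ``wells`` columns: sample, target, ct, replicate.  A missing/NaN ct marks
    an undetermined well.  Every sample must have a detectable housekeeping
    Ct; the calibrator must additionally have a detectable target Ct.
    """
    required = {"sample", "target", "ct"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing column(s): {sorted(missing)}")
    sub = wells[wells["target"].isin([target, housekeeping])]
    mean_ct = (
        sub.groupby(["sample", "target"])["ct"]
        .apply(lambda s: float(s.mean()) if s.notna().any() else np.nan)
        .unstack()
    )
    samples = list(mean_ct.index)
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} absent from wells table")
    for s in samples:
        if housekeeping not in mean_ct.columns or pd.isna(mean_ct.loc[s, housekeeping]):
            raise ValueError(f"sample {s!r}: missing housekeeping ({housekeeping}) Ct")
    if target not in mean_ct.columns or pd.isna(mean_ct.loc[calibrator, target]):
        raise ValueError(f"calibrator {calibrator!r} has undetectable target Ct")

    dct_cal = float(mean_ct.loc[calibrator, target] - mean_ct.loc[calibrator, housekeeping])
    rows = []
    for s in samples:
        tgt = mean_ct.loc[s, target] if target in mean_ct.columns else np.nan
        if pd.isna(tgt):
            rows.append({"sample": s, "delta_ct": np.nan, "delta_delta_ct": np.nan, "rq": 0.0, "detectable": False})
            continue
        dct = float(tgt - mean_ct.loc[s, housekeeping])
        ddct = dct - dct_cal
        rows.append({"sample": s, "delta_ct": dct, "delta_delta_ct": ddct, "rq": float(2.0 ** (-ddct)), "detectable": True})
    return pd.DataFrame(rows, columns=["sample", "delta_ct", "delta_delta_ct", "rq", "detectable"])
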
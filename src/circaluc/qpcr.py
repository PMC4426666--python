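"""Efficiency-corrected relative quantification of qPCR time courses.

Relative expression follows the efficiency-corrected ratio

    R = E_target^(Cq_cal,target - Cq_sample,target)
        / E_ref^(Cq_cal,ref - Cq_sample,ref)

with per-primer amplification efficiencies E in (1, 2] (E = 2 recovers the
classic delta-delta-Ct).  Technical replicates are collapsed by mean Cq
before ratios.  Two normalisation conventions are provided: circadian
profiles are divided by the grand mean over all timepoints, induction time
courses by the mean of the untreated (0-min) group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["relative_expression", "normalize_profile", "validate_records"]

REQUIRED_COLUMNS = ("sample_id", "gene", "cq")


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check a Cq table: required columns, Cq in (0, 45), E in (1, 2]."""
    df = records.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Cq table missing columns {missing}")
    if "efficiency" not in df.columns:
        df["efficiency"] = 2.0
    df["efficiency"] = df["efficiency"].fillna(2.0)
    if not df["cq"].between(0, 45, inclusive="neither").all():
        raise ValueError("Cq values must lie in (0, 45)")
    if not ((df["efficiency"] > 1.0) & (df["efficiency"] <= 2.0)).all():
        raise ValueError("primer efficiencies must lie in (1, 2]")
    return df


def _mean_cq(df: pd.DataFrame, gene: str) -> pd.Series:
    """Per-sample mean Cq for one gene (collapses technical replicates)."""
    sub = df[df["gene"] == gene]
    if sub.empty:
        raise ValueError(f"no records for gene {gene!r}")
    return sub.groupby("sample_id")["cq"].mean()


def relative_expression(
    records: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator: str | list[str],
    efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Efficiency-corrected relative quantity of ``target_gene`` per sample.

    ``calibrator`` is a sample id (or list of ids averaged on the Cq scale)
    that maps to a relative quantity of 1.  Per-gene efficiencies come from
    the table's ``efficiency`` column unless overridden via ``efficiencies``.
    Returns a DataFrame with columns sample_id, relative_expression plus any
    per-sample annotation columns present in the input.
    """
    df = validate_records(records)
    if efficiencies:
        for g, e in efficiencies.items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency for {g} must be in (1, 2]")
            df.loc[df["gene"] == g, "efficiency"] = e

    cq_t = _mean_cq(df, target_gene)
    cq_r = _mean_cq(df, reference_gene)
    samples = cq_t.index.intersection(cq_r.index)
    if len(samples) == 0:
        raise ValueError("no sample has both target and reference Cq")

    cal_ids = [calibrator] if isinstance(calibrator, str) else list(calibrator)
    missing = [c for c in cal_ids if c not in samples]
    if missing:
        raise ValueError(f"calibrator sample(s) {missing} lack target or reference Cq")
    cal_t = float(cq_t.loc[cal_ids].mean())
    cal_r = float(cq_r.loc[cal_ids].mean())

    e_t = float(df.loc[df["gene"] == target_gene, "efficiency"].mean())
    e_r = float(df.loc[df["gene"] == reference_gene, "efficiency"].mean())

    ratio = e_t ** (cal_t - cq_t.loc[samples]) / e_r ** (cal_r - cq_r.loc[samples])
    out = pd.DataFrame({"sample_id": samples, "relative_expression": ratio.to_numpy()})

    # carry over per-sample annotation columns (constant within a sample)
    anno_cols = [
        c
        for c in records.columns
        if c not in ("sample_id", "gene", "cq", "efficiency", "replicate")
        and records.groupby("sample_id")[c].nunique().le(1).all()
    ]
    if anno_cols:
        anno = records.groupby("sample_id")[anno_cols].first()
        out = out.merge(anno, left_on="sample_id", right_index=True, how="left")
    return out.reset_index(drop=True)


def normalize_profile(
    values,
    mode: str = "circadian_mean",
    timepoints=None,
) -> np.ndarray:
    """Normalise a profile of relative quantities.

    ``circadian_mean`` divides by the grand mean across all values (the
    normalised profile averages to 1); ``untreated_zero`` divides by the mean
    of the observations whose ``timepoints`` entry equals 0.
    """
    v = np.asarray(values, dtype=float)
    if mode == "circadian_mean":
        if len(v) < 2:
            raise ValueError("circadian_mean needs at least 2 timepoints")
        m = v.mean()
    elif mode == "untreated_zero":
        if timepoints is None:
            raise ValueError("untreated_zero requires the timepoints argument")
        tp = np.asarray(timepoints, dtype=float)
        zero = v[tp == 0]
        if len(zero) == 0:
            raise ValueError("no 0-min (untreated) observations present")
        m = zero.mean()
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    if m == 0:
        raise ValueError("normalisation denominator is zero")
    return v / m
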
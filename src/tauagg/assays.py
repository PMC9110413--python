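"""Closed-form assay readouts: vesicle calcium influx, LDH cytotoxicity, and
RT-qPCR relative expression.

All three are ratio formulas constructed so that uniform gain (and, where the
numerator and denominator are both differences, uniform offset) cancels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class VesicleMeasurement:
    """Mean fluorescence of one vesicle in the three acquisition phases."""

    vesicle_id: int
    f_background: float
    f_sample: float
    f_ionomycin: float


@dataclass
class LdhMeasurement:
    """490/680 nm absorbance pairs for sample and the two controls."""

    a490_sample: float
    a680_sample: float
    a490_spontaneous: float
    a680_spontaneous: float
    a490_maximum: float
    a680_maximum: float


def calcium_influx(v: VesicleMeasurement) -> tuple[float, bool]:
    """Percent calcium influx of one vesicle, normalized to ionomycin.

    ``100 * (F_sample - F_background) / (F_ionomycin - F_background)``.
    Returns ``(percent, out_of_range)``; noise-induced values outside
    [0, 100] are reported raw with the flag set, never silently clipped.
    """
    denom = v.f_ionomycin - v.f_background
    if denom <= 0:
        raise ValueError(
            f"vesicle {v.vesicle_id} excluded: F_ionomycin <= F_background")
    pct = 100.0 * (v.f_sample - v.f_background) / denom
    return pct, not (0.0 <= pct <= 100.0)


def field_average_influx(vesicles: list[VesicleMeasurement]) -> float:
    """Arithmetic mean influx over the usable vesicles of one field of view.

    Vesicles with a non-positive ionomycin response are excluded (with the
    count logged by the caller); an empty usable set is an error.
    """
    values = []
    for v in vesicles:
        try:
            pct, _ = calcium_influx(v)
        except ValueError:
            continue
        values.append(pct)
    if not values:
        raise ValueError("no usable vesicles in field")
    return float(np.mean(values))


def influx_from_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized influx over a per-vesicle table
    (columns f_background, f_sample, f_ionomycin)."""
    vs = [VesicleMeasurement(int(row.get("vesicle", i)), row["f_background"],
                             row["f_sample"], row["f_ionomycin"])
          for i, row in frame.iterrows()]
    rows = []
    for v in vs:
        try:
            pct, flag = calcium_influx(v)
            rows.append({"vesicle": v.vesicle_id, "influx_pct": pct,
                         "out_of_range": flag, "excluded": False})
        except ValueError:
            rows.append({"vesicle": v.vesicle_id, "influx_pct": np.nan,
                         "out_of_range": False, "excluded": True})
    return pd.DataFrame(rows)


def ldh_cytotoxicity(m: LdhMeasurement) -> float:
    """Percent cytotoxicity from background-corrected LDH absorbances.

    Each well's LDH signal is A490 - A680; the result is
    ``100 * (sample - spontaneous) / (maximum - spontaneous)``.
    """
    sample = m.a490_sample - m.a680_sample
    spont = m.a490_spontaneous - m.a680_spontaneous
    maximum = m.a490_maximum - m.a680_maximum
    denom = maximum - spont
    if denom <= 0:
        raise ValueError("corrected maximum must exceed corrected spontaneous")
    return 100.0 * (sample - spont) / denom


def relative_expression(ct: pd.DataFrame, housekeeping: tuple[str, ...] =
                        ("GAPDH", "18S"), reference_group: str = "PBS"
                        ) -> pd.DataFrame:
    """Fold change per sample x gene by the delta-delta-Ct method.

    ``ct`` columns: sample, group, gene, ct.  Per sample,
    dCt = Ct(gene) - mean Ct(housekeeping genes); per gene,
    ddCt = dCt - mean dCt of the reference group; fold change = 2^(-ddCt)
    (amplification efficiency 2 assumed, recorded in the output metadata).
    """
    required = {"sample", "group", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    hk = ct[ct["gene"].isin(housekeeping)]
    counts = hk.groupby("sample")["gene"].nunique()
    missing = sorted(s for s in set(ct["sample"])
                     if counts.get(s, 0) < len(housekeeping))
    if missing:
        raise ValueError(f"samples missing housekeeping measurements: {missing}")
    hk_mean = hk.groupby("sample")["ct"].mean()
    genes = ct[~ct["gene"].isin(housekeeping)].copy()
    genes["dct"] = genes["ct"] - genes["sample"].map(hk_mean)
    ref = genes[genes["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"empty reference group {reference_group!r}")
    ref_mean = ref.groupby("gene")["dct"].mean()
    missing_ref = set(genes["gene"]) - set(ref_mean.index)
    if missing_ref:
        raise ValueError(
            f"reference group missing for genes: {sorted(missing_ref)}")
    genes["ddct"] = genes["dct"] - genes["gene"].map(ref_mean)
    genes["fold_change"] = 2.0 ** (-genes["ddct"])
    genes.attrs["method"] = "ddCt, efficiency 2"
    return genes[["sample", "group", "gene", "dct", "ddct", "fold_change"]]
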
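"""qPCR-based quantification of DSB end resection.

Resection past a StyI restriction site converts the site to single-stranded
DNA, protecting it from digestion; the protected (resected) fraction is read
out from the cycle-threshold shift between a StyI-digested and a
mock-digested aliquot of the same genomic DNA:

    raw resection = 2 / (1 + 2**dCt),   dCt = Ct_StyI - Ct_mock.

Relative resection divides raw resection by the fraction of molecules
actually cut at the matching timepoint, and the two-sided ratio compares
resection speed on the repeat-proximal vs repeat-distal side of the break,
normalized to a non-repeated (NR) control construct whose ratio is 1 by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ResectionResult:
    raw_resection: float
    relative_resection: float | None = None
    ratio_vs_nr: float | None = None


def raw_resection(delta_ct: float) -> float:
    """2 / (1 + 2**delta_ct); strictly decreasing in delta_ct.

    Values above 1 (negative dCt) are biologically impossible — more
    protected molecules than total — and signal assay noise; they are
    returned as computed but with a warning.
    """
    if not np.isfinite(delta_ct):
        raise ValueError("delta_ct must be finite")
    r = 2.0 / (1.0 + 2.0 ** float(delta_ct))
    if r > 1.0:
        warnings.warn(
            f"raw resection {r:.3f} > 1 (delta_ct={delta_ct:.3f} < 0): assay noise"
        )
    return r


def relative_resection(raw: float, dsb_fraction: float) -> float:
    """Raw resection divided by the cut fraction at the matching timepoint.

    ``dsb_fraction`` is a fraction in (0, 1]; tables carrying percent must
    divide by 100 at the interface (the unit is declared in the input
    header) to avoid a silent 100-fold error.
    """
    if not 0.0 < dsb_fraction <= 1.0:
        raise ValueError("dsb_fraction must be in (0, 1] (fraction, not percent)")
    return raw / dsb_fraction


def resection_ratio(
    repeat_end_rel: float,
    distal_end_rel: float,
    nr_repeat_rel: float,
    nr_distal_rel: float,
) -> float:
    """(repeat/distal) ratio normalized to the NR control's (repeat/distal)."""
    vals = (repeat_end_rel, distal_end_rel, nr_repeat_rel, nr_distal_rel)
    if any(v <= 0 for v in vals):
        raise ValueError("all relative resection values must be > 0")
    return (repeat_end_rel / distal_end_rel) / (nr_repeat_rel / nr_distal_rel)


def mean_ct(replicates: Sequence[float]) -> float:
    """Mean of triplicate (or any number of) Ct measurements, taken before
    forming the dCt difference."""
    if len(replicates) == 0:
        raise ValueError("need at least one Ct replicate")
    return float(np.mean(replicates))


def analyze_resection_table(df: pd.DataFrame, control: str = "NR") -> pd.DataFrame:
    """Process a long-format resection table into per-sample ratios.

    Expected columns: ``sample``, ``end`` (repeat_proximal / repeat_distal),
    ``ct_styI``, ``ct_mock`` (scalar or semicolon-separated replicates) and
    ``dsb_percent``.  Returns one row per sample with raw and relative
    resection per end and the ratio normalized to ``control``.
    """
    rows = []
    for (sample, end), grp in df.groupby(["sample", "end"], sort=False):
        cts = _parse_ct(grp["ct_styI"])
        ctm = _parse_ct(grp["ct_mock"])
        dct = mean_ct(cts) - mean_ct(ctm)
        raw = raw_resection(dct)
        dsb = float(grp["dsb_percent"].iloc[0]) / 100.0
        rows.append(
            {"sample": sample, "end": end, "delta_ct": dct,
             "raw_resection": raw, "relative_resection": relative_resection(raw, dsb)}
        )
    per_end = pd.DataFrame(rows)
    wide = per_end.pivot(index="sample", columns="end", values="relative_resection")
    if control not in wide.index:
        raise ValueError(f"control sample {control!r} absent from table")
    nr_prox = wide.loc[control, "repeat_proximal"]
    nr_dist = wide.loc[control, "repeat_distal"]
    wide["ratio_vs_nr"] = [
        resection_ratio(wide.loc[s, "repeat_proximal"], wide.loc[s, "repeat_distal"],
                        nr_prox, nr_dist)
        for s in wide.index
    ]
    return wide.reset_index()


def _parse_ct(col: pd.Series) -> list[float]:
    vals: list[float] = []
    for v in col:
        if isinstance(v, str) and ";" in v:
            vals.extend(float(x) for x in v.split(";"))
        else:
            vals.append(float(v))
    return vals
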
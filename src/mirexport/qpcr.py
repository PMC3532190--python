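"""Relative RT-qPCR quantification of miRNAs (2^-dCt) and EV:cell ratios.

Expression of a miRNA relative to an endogenous reference miRNA in the
same sample is 2^-dCt with dCt = Ct(miRNA) - Ct(reference), assuming a
per-cycle amplification efficiency of 2. Replicate wells are averaged on
the Ct scale before the difference is taken. The EV:cell ratio of a miRNA
is the ratio of its relative expressions in the EV and cell samples, i.e.
2^(dCt_cell - dCt_EV) — adding any constant to all Cts of a sample (e.g.
input amount differences) cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CtTable", "relative_expression", "delta_ct", "qpcr_ev_cell_ratio"]


class MissingReferenceError(KeyError):
    """The normalization reference miRNA was not measured in a sample."""


@dataclass
class CtTable:
    """Threshold-cycle measurements with a designated reference miRNA.

    ``data`` has columns sample, mirna, replicate, ct. Undetermined wells
    (no amplification) are simply absent — they are not encoded as Ct 40.
    """

    data: pd.DataFrame
    reference_mirna: str

    def __post_init__(self) -> None:
        required = {"sample", "mirna", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"CtTable missing columns: {sorted(missing)}")
        if not np.isfinite(self.data["ct"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite Ct values; drop undetermined wells instead")

    @classmethod
    def from_csv(cls, path: str | Path, reference_mirna: str) -> "CtTable":
        return cls(pd.read_csv(path), reference_mirna)

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample"].unique())

    def mean_ct(self, sample: str, mirna: str) -> float:
        """Replicate-averaged Ct, NaN when the miRNA was not measured."""
        sel = self.data[(self.data["sample"] == sample) & (self.data["mirna"] == mirna)]
        if sel.empty:
            return float("nan")
        return float(sel["ct"].mean())

    def ct_sd(self, sample: str, mirna: str) -> float:
        sel = self.data[(self.data["sample"] == sample) & (self.data["mirna"] == mirna)]
        if len(sel) < 2:
            return float("nan")
        return float(sel["ct"].std(ddof=1))


def delta_ct(ct: CtTable, sample: str, mirna: str) -> float:
    """dCt = mean Ct(miRNA) - mean Ct(reference) within one sample."""
    ref = ct.mean_ct(sample, ct.reference_mirna)
    if math.isnan(ref):
        raise MissingReferenceError(
            f"reference {ct.reference_mirna!r} not measured in sample {sample!r}"
        )
    return ct.mean_ct(sample, mirna) - ref


def relative_expression(
    ct: CtTable, sample: str, mirna: str, efficiency: float = 2.0
) -> float:
    """Expression relative to the reference miRNA: efficiency^-dCt.

    The default efficiency of 2 (perfect doubling) gives the standard
    2^-dCt; pass a measured efficiency for the corrected variant. Returns
    NaN (undetected) when the miRNA was not measured in the sample.
    """
    d = delta_ct(ct, sample, mirna)
    if math.isnan(d):
        return float("nan")
    return float(efficiency ** (-d))


def qpcr_ev_cell_ratio(
    ct: CtTable,
    mirna: str,
    cell_sample: str,
    ev_sample: str,
    efficiency: float = 2.0,
) -> float:
    """EV:cell expression ratio of a miRNA from its two samples' dCt.

    Equals relative_expression(EV) / relative_expression(cell) =
    efficiency^(dCt_cell - dCt_EV); its log2 equals dCt_cell - dCt_EV
    exactly when efficiency is 2.
    """
    d_cell = delta_ct(ct, cell_sample, mirna)
    d_ev = delta_ct(ct, ev_sample, mirna)
    if math.isnan(d_cell) or math.isnan(d_ev):
        return float("nan")
    return float(efficiency ** (d_cell - d_ev))


def relative_expression_table(ct: CtTable, efficiency: float = 2.0) -> pd.DataFrame:
    """Relative expression (and dCt spread) for every (sample, miRNA).

    Columns: sample, mirna, mean_ct, delta_ct, rel_expr, ct_sd — the
    per-replicate Ct standard deviation is reported alongside so error
    bars can be drawn on either the dCt or the ratio scale.
    """
    rows = []
    for (sample, mirna), sel in ct.data.groupby(["sample", "mirna"], sort=True):
        d = delta_ct(ct, sample, mirna)
        rows.append(
            {
                "sample": sample,
                "mirna": mirna,
                "mean_ct": float(sel["ct"].mean()),
                "delta_ct": d,
                "rel_expr": float(efficiency ** (-d)),
                "ct_sd": float(sel["ct"].std(ddof=1)) if len(sel) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
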
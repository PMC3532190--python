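"""Export statistics: log2(EV/cell) ratios, classification, and the
:class:`ExportAnalysis` model.

For each miRNA the export statistic is the base-2 log of the ratio of its
normalized abundance (RPMM) in extracellular vesicles over that in the
producing cells: positive values mean preferential export, negative values
retention. MiRNAs whose ratio lies inside a one-log2-unit band around zero
are "similar" — represented proportionally in cells and vesicles, as
expected under passive, non-selective packaging.

The modelling interface follows the statsmodels convention: an
:class:`ExportAnalysis` instance is built from a count table plus a
cell/EV library pairing; :meth:`ExportAnalysis.fit` runs the normalization
pipeline (pseudocount rule, RPMM, optional exclusion–renormalization of an
overexpressed miRNA) and returns an :class:`ExportResults` object holding
per-miRNA estimates with Poisson delta-method standard errors, ranked
released/retained lists, distribution diagnostics and a text summary.
The individual statistics are also exposed as plain functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import CountTable
from .normalize import (
    ExpressionMatrix,
    Pairing,
    apply_pseudocount_rule,
    exclude_and_renormalize,
    rpmm,
)

__all__ = [
    "log2_ev_cell",
    "build_export_table",
    "distribution_summary",
    "correlation_report",
    "ExportTable",
    "DistributionSummary",
    "CorrelationReport",
    "ExportAnalysis",
    "ExportResults",
]

LN2 = math.log(2.0)

Interval = Literal["open", "closed"]

EXPORT_COLUMNS = [
    "cell_rpmm",
    "ev_rpmm",
    "log2_ratio",
    "se_log2",
    "cell_reads",
    "ev_reads",
    "expressed",
    "class",
]


def log2_ev_cell(cell_rpmm, ev_rpmm):
    """log2 of the EV:cell expression ratio.

    Accepts scalars or arrays. A non-positive value on either side makes
    the ratio undefined and yields NaN (never a silent zero); zeros are
    expected to have been handled upstream by the pseudocount rule.
    """
    cell = np.asarray(cell_rpmm, dtype=float)
    ev = np.asarray(ev_rpmm, dtype=float)
    out = np.full(np.broadcast(cell, ev).shape, np.nan)
    valid = (cell > 0) & (ev > 0)
    out = np.where(valid, np.log2(np.where(valid, ev, 1.0) / np.where(valid, cell, 1.0)), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class ExportTable:
    """Per-condition export statistics (the released/retained table object).

    ``frames`` maps each condition label to a DataFrame indexed by
    mature_id with columns cell_rpmm, ev_rpmm, log2_ratio, se_log2,
    cell_reads, ev_reads, expressed, class.
    """

    frames: dict[str, pd.DataFrame]
    read_threshold: int = 1000
    excluded: list[str] = field(default_factory=list)

    @property
    def conditions(self) -> list[str]:
        return list(self.frames)

    def frame(self, condition: str) -> pd.DataFrame:
        return self.frames[condition]

    def released(self, condition: str) -> pd.DataFrame:
        """Expressed miRNAs with log2 ratio > +1, most exported first."""
        f = self.frames[condition]
        sel = f[f["class"] == "released"]
        # stable sort after an index sort -> lexicographic tie-break
        return sel.sort_index(kind="mergesort").sort_values(
            "log2_ratio", ascending=False, kind="mergesort"
        )

    def retained(self, condition: str) -> pd.DataFrame:
        """Expressed miRNAs with log2 ratio < -1, most retained first."""
        f = self.frames[condition]
        sel = f[f["class"] == "retained"]
        return sel.sort_index(kind="mergesort").sort_values(
            "log2_ratio", ascending=True, kind="mergesort"
        )

    def to_tsv(self, path: str | Path, decimals: int = 2) -> None:
        """Write a report table mirroring the published layout:
        miRNA, then (RPMM cells, RPMM EV, log2(EV/Cells)) per condition."""
        pieces = []
        for cond, f in self.frames.items():
            sub = f[["cell_rpmm", "ev_rpmm", "log2_ratio"]].copy()
            sub["log2_ratio"] = sub["log2_ratio"].round(decimals)
            sub.columns = pd.MultiIndex.from_product(
                [[cond], ["RPMM cells", "RPMM EV", "log2(EV/Cells)"]]
            )
            pieces.append(sub)
        pd.concat(pieces, axis=1).to_csv(path, sep="\t", index_label="miRNA")


def _classify(
    log2_ratio: float, expressed: bool, band: Interval = "closed"
) -> str:
    if not np.isfinite(log2_ratio) or not expressed:
        return "undetected"
    if band == "closed":
        inside = -1.0 <= log2_ratio <= 1.0
    else:
        inside = -1.0 < log2_ratio < 1.0
    if inside:
        return "similar"
    return "released" if log2_ratio > 1.0 else "retained"


def build_export_table(
    expr: ExpressionMatrix,
    counts: CountTable,
    pairing: Pairing,
    read_threshold: int = 1000,
    band: Interval = "closed",
) -> ExportTable:
    """Assemble per-condition export statistics from RPMM values and counts.

    The expressed flag uses raw read counts — a miRNA qualifies when its
    cell or EV library holds strictly more than ``read_threshold`` reads —
    while the log2 ratio is computed on the normalized (RPMM) scale.
    The delta-method standard error of the log ratio under Poisson counts
    is sqrt(1/cell_reads + 1/ev_reads)/ln 2.
    """
    frames: dict[str, pd.DataFrame] = {}
    for cond, (cell_lib, ev_lib) in pairing.items():
        for lib in (cell_lib, ev_lib):
            if lib not in expr.values.columns:
                raise KeyError(f"pairing references unknown library {lib!r}")
        cell = expr.values[cell_lib]
        ev = expr.values[ev_lib]
        cell_reads = counts.counts[cell_lib].reindex(cell.index).fillna(0.0)
        ev_reads = counts.counts[ev_lib].reindex(cell.index).fillna(0.0)
        ratio = pd.Series(log2_ev_cell(cell.values, ev.values), index=cell.index)
        with np.errstate(divide="ignore"):
            se = np.sqrt(
                np.where(cell_reads > 0, 1.0 / cell_reads, np.nan)
                + np.where(ev_reads > 0, 1.0 / ev_reads, np.nan)
            ) / LN2
        expressed = np.maximum(cell_reads, ev_reads) > read_threshold
        frame = pd.DataFrame(
            {
                "cell_rpmm": cell,
                "ev_rpmm": ev,
                "log2_ratio": ratio,
                "se_log2": se,
                "cell_reads": cell_reads,
                "ev_reads": ev_reads,
                "expressed": expressed,
            }
        )
        frame["class"] = [
            _classify(r, e, band) for r, e in zip(frame["log2_ratio"], frame["expressed"])
        ]
        frames[cond] = frame
    return ExportTable(frames=frames, read_threshold=read_threshold, excluded=list(expr.excluded))


@dataclass
class DistributionSummary:
    """Histogram and shape diagnostics of the log2(EV/cell) distribution."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    fitted_mean: float
    fitted_sd: float
    skewness: float
    fraction_similar: float
    n: int
    interval: Interval = "open"


def distribution_summary(
    table: ExportTable | pd.DataFrame,
    condition: str | None = None,
    bin_width: float = 0.5,
    interval: Interval = "open",
) -> DistributionSummary:
    """Histogram the co-detected log2 ratios and fit a normal by moments.

    ``fraction_similar`` is the share of co-detected miRNAs whose ratio
    falls in the one-log2-unit band around zero; the default open interval
    (-1, +1) matches how that share is conventionally quoted. A positive
    skewness indicates the right shift produced by a minority of strongly
    exported miRNAs.
    """
    if isinstance(table, ExportTable):
        if condition is None:
            condition = table.conditions[0]
        frame = table.frames[condition]
    else:
        frame = table
    ratios = frame["log2_ratio"].to_numpy(dtype=float)
    ratios = ratios[np.isfinite(ratios)]
    if ratios.size < 3:
        raise ValueError(f"need >= 3 co-detected miRNAs, have {ratios.size}")
    lo = math.floor(ratios.min() / bin_width) * bin_width
    hi = math.ceil(ratios.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    freq, edges = np.histogram(ratios, bins=nbins, range=(lo, hi))
    if interval == "open":
        similar = np.mean((ratios > -1.0) & (ratios < 1.0))
    else:
        similar = np.mean((ratios >= -1.0) & (ratios <= 1.0))
    return DistributionSummary(
        bin_edges=edges,
        frequencies=freq,
        fitted_mean=float(ratios.mean()),
        fitted_sd=float(ratios.std(ddof=1)),
        skewness=float(stats.skew(ratios, bias=False)),
        fraction_similar=float(similar),
        n=int(ratios.size),
        interval=interval,
    )


@dataclass
class CorrelationReport:
    """Pairwise coefficients of determination between expression vectors."""

    pairs: list[dict]

    def r_squared(self, a: str, b: str) -> float:
        for p in self.pairs:
            if {p["a"], p["b"]} == {a, b}:
                return p["r_squared"]
        raise KeyError((a, b))


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def correlation_report(
    expr_a: ExpressionMatrix | pd.DataFrame,
    expr_b: ExpressionMatrix | pd.DataFrame | None = None,
    scale: Literal["log", "raw"] = "log",
    read_threshold: int = 0,
    counts_a: CountTable | None = None,
    counts_b: CountTable | None = None,
) -> CorrelationReport:
    """Pearson R^2 between library expression profiles.

    With one matrix, every unordered pair of its libraries is compared;
    with two, every cross pair. ``scale="log"`` (default) correlates
    log2(RPMM + 1); the untransformed option is provided because either
    convention appears in practice. An optional read threshold keeps only
    miRNAs exceeding it (raw reads) in at least one member of the pair.
    Fewer than 3 shared miRNAs is an error.
    """
    va = expr_a.values if isinstance(expr_a, ExpressionMatrix) else expr_a
    if expr_b is None:
        vb = va
        cols = list(va.columns)
        pair_list = [
            (cols[i], cols[j]) for i in range(len(cols)) for j in range(i + 1, len(cols))
        ]
        counts_b = counts_a
    else:
        vb = expr_b.values if isinstance(expr_b, ExpressionMatrix) else expr_b
        pair_list = [(a, b) for a in va.columns for b in vb.columns]

    shared = va.index.intersection(vb.index)
    out = []
    for a, b in pair_list:
        x = va.loc[shared, a]
        y = vb.loc[shared, b]
        keep = np.isfinite(x.values) & np.isfinite(y.values)
        if read_threshold > 0:
            ca = counts_a.counts[a].reindex(shared).fillna(0.0) if counts_a is not None else x
            cb = (counts_b.counts[b].reindex(shared).fillna(0.0) if counts_b is not None else y)
            keep &= (np.maximum(ca.values, cb.values) > read_threshold)
        xs, ys = x.values[keep], y.values[keep]
        if xs.size < 3:
            raise ValueError(
                f"fewer than 3 shared miRNAs for pair ({a}, {b}) after filtering"
            )
        if scale == "log":
            xs, ys = np.log2(xs + 1.0), np.log2(ys + 1.0)
        out.append(
            {
                "a": a,
                "b": b,
                "r_squared": _r_squared(xs, ys),
                "scale": scale,
                "read_threshold": read_threshold,
                "n": int(xs.size),
            }
        )
    return CorrelationReport(pairs=out)


class ExportAnalysis:
    """Model of selective miRNA export from paired cell/EV count data.

    Parameters
    ----------
    counts
        Mature-miRNA read counts per library (cells and EVs, one pair per
        condition).
    pairing
        Mapping condition -> (cell library label, EV library label).
    read_threshold
        Raw-read floor (strict) for a miRNA to enter the released/retained
        lists; 1000 by default.
    exclude
        MiRNAs (e.g. a transfection spike) whose reads are removed before
        normalization, with the affected libraries renormalized so the
        remaining miRNAs are comparable across conditions.
    exclude_libraries
        Libraries the exclusion applies to (default: all libraries).
    pseudocount
        Apply the lone-zero cell-library pseudocount rule before
        normalization (default True).
    ev_side_pseudocount
        Also apply the symmetric EV-side rule (default False).
    band
        Whether the "similar" classification band [-1, +1] includes its
        endpoints ("closed", default) or not ("open").
    """

    def __init__(
        self,
        counts: CountTable,
        pairing: Pairing,
        read_threshold: int = 1000,
        exclude: Sequence[str] = (),
        exclude_libraries: Sequence[str] | None = None,
        pseudocount: bool = True,
        ev_side_pseudocount: bool = False,
        band: Interval = "closed",
    ) -> None:
        self.counts = counts
        self.pairing = dict(pairing)
        self.read_threshold = read_threshold
        self.exclude = list(exclude)
        self.exclude_libraries = (
            list(exclude_libraries) if exclude_libraries is not None else None
        )
        self.pseudocount = pseudocount
        self.ev_side_pseudocount = ev_side_pseudocount
        self.band: Interval = band

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, pairing: Pairing, **kwargs
    ) -> "ExportAnalysis":
        """Build from a plain mature_id x library count DataFrame."""
        return cls(CountTable.from_counts(counts), pairing, **kwargs)

    def _effective_counts(self) -> tuple[CountTable, list[str]]:
        table = self.counts
        excluded: list[str] = []
        if self.exclude:
            df = table.counts.copy()
            libs = self.exclude_libraries or list(df.columns)
            missing = [m for m in self.exclude if m not in df.index]
            if missing:
                raise KeyError(f"cannot exclude unknown miRNAs: {missing}")
            # removing the excluded reads from the chosen libraries shrinks
            # those libraries' denominators — de novo RPMM on spike-free counts
            df.loc[self.exclude, libs] = 0.0
            table = CountTable.from_counts(df)
            excluded = list(self.exclude)
        if self.pseudocount:
            table = apply_pseudocount_rule(
                table, self.pairing, ev_side=self.ev_side_pseudocount
            )
        return table, excluded

    def fit(self) -> "ExportResults":
        """Run normalization and compute the per-miRNA export statistics."""
        counts, excluded = self._effective_counts()
        expr = rpmm(counts)
        expr.excluded = excluded
        table = build_export_table(
            expr, counts, self.pairing, self.read_threshold, self.band
        )
        return ExportResults(self, expr, counts, table)


class ExportResults:
    """Fitted export statistics with diagnostics and reporting helpers."""

    def __init__(
        self,
        model: ExportAnalysis,
        expr: ExpressionMatrix,
        effective_counts: CountTable,
        table: ExportTable,
    ) -> None:
        self.model = model
        self.expr = expr
        self.effective_counts = effective_counts
        self.table = table

    @property
    def conditions(self) -> list[str]:
        return self.table.conditions

    def frame(self, condition: str | None = None) -> pd.DataFrame:
        return self.table.frame(condition or self.conditions[0])

    def log2_ratios(self, condition: str | None = None) -> pd.Series:
        return self.frame(condition)["log2_ratio"]

    def released(self, condition: str | None = None) -> pd.DataFrame:
        return self.table.released(condition or self.conditions[0])

    def retained(self, condition: str | None = None) -> pd.DataFrame:
        return self.table.retained(condition or self.conditions[0])

    def distribution(
        self,
        condition: str | None = None,
        bin_width: float = 0.5,
        interval: Interval = "open",
    ) -> DistributionSummary:
        return distribution_summary(
            self.table, condition or self.conditions[0], bin_width, interval
        )

    def correlations(
        self, scale: Literal["log", "raw"] = "log", read_threshold: int = 0
    ) -> CorrelationReport:
        return correlation_report(
            self.expr,
            scale=scale,
            read_threshold=read_threshold,
            counts_a=self.effective_counts,
        )

    def summary(self, top: int = 10) -> str:
        """Text report: library totals, class counts and the most released
        and retained miRNAs per condition."""
        lines = ["miRNA export analysis", "=" * 52]
        lines.append(f"read threshold (strict): {self.model.read_threshold}")
        if self.table.excluded:
            lines.append(f"excluded before normalization: {', '.join(self.table.excluded)}")
        for cond in self.conditions:
            f = self.frame(cond)
            cell_lib, ev_lib = self.model.pairing[cond]
            lines.append("")
            lines.append(f"condition {cond!r}: cells={cell_lib}  EVs={ev_lib}")
            counts = f["class"].value_counts()
            lines.append(
                "  classes: "
                + ", ".join(
                    f"{k}={int(counts.get(k, 0))}"
                    for k in ("released", "retained", "similar", "undetected")
                )
            )
            rel = self.released(cond).head(top)
            ret = self.retained(cond).head(top)
            for title, sub in (("most released", rel), ("most retained", ret)):
                lines.append(f"  {title}:")
                for mid, row in sub.iterrows():
                    lines.append(
                        f"    {mid:<16} cell={row.cell_rpmm:>12.1f}  "
                        f"EV={row.ev_rpmm:>12.1f}  log2={row.log2_ratio:>6.2f}"
                        f" (se {row.se_log2:.2f})"
                    )
        return "\n".join(lines)

    def plot_distribution(
        self, condition: str | None = None, bin_width: float = 0.5, ax=None
    ):
        """Histogram of log2 ratios with the moment-fitted normal overlay."""
        import matplotlib.pyplot as plt

        summ = self.distribution(condition, bin_width)
        if ax is None:
            _, ax = plt.subplots()
        centers = 0.5 * (summ.bin_edges[:-1] + summ.bin_edges[1:])
        ax.bar(centers, summ.frequencies, width=bin_width * 0.9, label="miRNAs")
        grid = np.linspace(summ.bin_edges[0], summ.bin_edges[-1], 200)
        pdf = stats.norm.pdf(grid, summ.fitted_mean, summ.fitted_sd)
        ax.plot(grid, pdf * summ.n * bin_width, color="0.4", label="normal fit")
        ax.set_xlabel("log2(EV/cell)")
        ax.set_ylabel("miRNAs")
        ax.legend()
        return ax
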
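"""Library-size normalization to reads per million mapped (RPMM).

RPMM rescales each library's mature-miRNA counts by 10^6 over the
library's total mapped reads, making expression levels comparable across
libraries of different depth. Two refinements needed for cell/EV export
analysis live here as well:

* exclusion–renormalization — removing an overexpressed (transfected)
  miRNA's reads and rescaling the remaining miRNAs back to per-million
  units, so transfected libraries can be compared with untransfected ones;
* the pseudocount rule — a miRNA detected in every EV library but in all
  but one cell library gets a single read in the zero cell library, purely
  so that an EV:cell ratio can be formed (zeros otherwise make the log
  ratio undefined).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import CountTable

__all__ = ["ExpressionMatrix", "rpmm", "exclude_and_renormalize", "apply_pseudocount_rule"]

MILLION = 1_000_000.0

# condition -> (cell library label, EV library label)
Pairing = Mapping[str, tuple[str, str]]


@dataclass
class ExpressionMatrix:
    """RPMM values per mature miRNA per library.

    ``denominators`` are the per-library total mapped read counts the
    values were scaled by; ``excluded`` records miRNAs removed by
    exclusion–renormalization (so report tables can annotate them).
    Included values sum to 10^6 per library.
    """

    values: pd.DataFrame
    denominators: pd.Series
    excluded: list[str] = field(default_factory=list)

    @property
    def libraries(self) -> list[str]:
        return list(self.values.columns)

    def validate(self, rtol: float = 1e-6) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative RPMM values")
        sums = self.values.sum(axis=0).values
        if not np.allclose(sums, MILLION, rtol=rtol):
            raise ValueError(f"library sums deviate from 1e6: {sums}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            denoms = "\t".join(f"{lib}={d:g}" for lib, d in self.denominators.items())
            fh.write(f"# denominators\t{denoms}\n")
            fh.write(f"# excluded\t{','.join(self.excluded) if self.excluded else '-'}\n")
            self.values.to_csv(fh, sep="\t", index_label="mature_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        denominators: dict[str, float] = {}
        excluded: list[str] = []
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if not line.startswith("#"):
                body_start = i
                break
            tag, _, payload = line[1:].strip().partition("\t")
            if tag == "denominators":
                for item in payload.split("\t"):
                    lib, _, val = item.partition("=")
                    denominators[lib] = float(val)
            elif tag == "excluded" and payload != "-":
                excluded = payload.split(",")
        from io import StringIO

        values = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col="mature_id")
        values.index.name = None
        return cls(values=values, denominators=pd.Series(denominators), excluded=excluded)


def rpmm(counts: CountTable) -> ExpressionMatrix:
    """Normalize a count table to reads per million mapped.

    value[i, lib] = counts[i, lib] / total_mapped[lib] * 10^6. Raises on a
    library with zero mapped reads (its RPMM is undefined).
    """
    zero = counts.total_mapped[counts.total_mapped <= 0]
    if len(zero):
        raise ValueError(f"zero total mapped reads in libraries: {list(zero.index)}")
    values = counts.counts.div(counts.total_mapped, axis=1) * MILLION
    return ExpressionMatrix(values=values, denominators=counts.total_mapped.copy())


def exclude_and_renormalize(
    expr: ExpressionMatrix, exclude: Sequence[str]
) -> ExpressionMatrix:
    """Drop the given miRNAs and rescale each library back to 10^6.

    Within each library all remaining pairwise ratios are unchanged; the
    result is identical to RPMM computed de novo on counts with the
    excluded rows removed. Denominators are reduced by the excluded reads.
    """
    missing = [m for m in exclude if m not in expr.values.index]
    if missing:
        raise KeyError(f"cannot exclude unknown miRNAs: {missing}")
    remaining = expr.values.drop(index=list(exclude))
    sums = remaining.sum(axis=0)
    dead = sums[sums <= 0]
    if len(dead):
        raise ValueError(
            f"exclusion removes all expressed miRNAs of libraries: {list(dead.index)}"
        )
    factor = MILLION / sums
    values = remaining.mul(factor, axis=1)
    new_denoms = expr.denominators * (sums / MILLION)
    return ExpressionMatrix(
        values=values,
        denominators=new_denoms,
        excluded=list(expr.excluded) + list(exclude),
    )


def apply_pseudocount_rule(
    counts: CountTable,
    pairing: Pairing,
    ev_side: bool = False,
) -> CountTable:
    """Assign one read to a lone zero cell library of an EV-detected miRNA.

    For each miRNA with nonzero counts in *all* EV libraries of the pairing
    but a zero count in *exactly one* cell library, that cell entry is set
    to 1 read (pre-normalization, so it flows through the library's own
    denominator). All other zeros are untouched; the rule is idempotent.
    ``ev_side=True`` additionally applies the symmetric rule to a lone EV
    zero (off by default).
    """
    cell_libs = [pair[0] for pair in pairing.values()]
    ev_libs = [pair[1] for pair in pairing.values()]
    for lib in cell_libs + ev_libs:
        if lib not in counts.counts.columns:
            raise KeyError(f"pairing references unknown library {lib!r}")

    new = counts.counts.copy()

    def _fill(detect_libs: list[str], zero_libs: list[str]) -> None:
        detected_all = (new[detect_libs] > 0).all(axis=1)
        zeros = new[zero_libs] == 0
        lone_zero = detected_all & (zeros.sum(axis=1) == 1)
        for lib in zero_libs:
            mask = lone_zero & zeros[lib]
            new.loc[mask, lib] = 1.0

    _fill(ev_libs, cell_libs)
    if ev_side:
        _fill(cell_libs, ev_libs)
    return CountTable.from_counts(new)
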
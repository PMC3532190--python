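"""Cross-dataset rank concordance of miRNA export.

Different studies measure cell and EV miRNA levels on different platforms
(small-RNA sequencing, microarrays, RT-qPCR arrays) whose values are not
directly comparable. What can be compared are ranks: within each dataset
miRNAs are ordered by how preferentially they are exported — by the EV:cell
expression ratio for sequencing/microarray data, or by dCt = Ct(cells) −
Ct(EVs) for qPCR arrays (lower Ct in EVs means more abundant there, so a
larger dCt means more exported; both orderings coincide because
log2(EV/cell) = dCt under perfect doubling efficiency).

A rank matrix aligns every dataset on a reference dataset's miRNA ordering
while keeping each dataset's *native* ranks (computed over its full
detected set before row restriction), mirroring how multi-study rank
heatmaps are built. Concordance between dataset pairs is summarized by
Spearman correlation over co-detected miRNAs and by top-k overlap counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DatasetMeasure",
    "RankMatrix",
    "rank_dataset",
    "build_rank_matrix",
    "concordance",
    "read_dataset_measure",
]

Platform = Literal["sequencing", "microarray", "qpcr_array"]


@dataclass
class DatasetMeasure:
    """Per-miRNA export score of one dataset.

    ``scores`` is indexed by mature_id; NaN marks miRNAs not detected (or
    not assayed) on the platform. For ratio platforms the score is the
    EV:cell expression ratio; for qPCR arrays it is dCt = Ct(cells) −
    Ct(EVs). Larger always means more exported. ``ranks`` is filled by
    :func:`rank_dataset` (1 = most exported, average ranks on ties).
    """

    dataset_id: str
    platform: Platform
    scores: pd.Series
    ranks: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.platform not in ("sequencing", "microarray", "qpcr_array"):
            raise ValueError(f"unknown platform {self.platform!r}")
        self.scores = self.scores.astype(float)

    @property
    def detected(self) -> pd.Series:
        return self.scores.notna()

    @property
    def n_detected(self) -> int:
        return int(self.detected.sum())


def rank_dataset(measure: DatasetMeasure) -> DatasetMeasure:
    """Rank the dataset's detected miRNAs by export score, 1 = most exported.

    Any strictly monotone transform of the scores yields identical ranks;
    ties receive average (fractional) ranks.
    """
    det = measure.scores.dropna()
    if len(det) < 2:
        raise ValueError(
            f"dataset {measure.dataset_id!r}: need >= 2 detected miRNAs to rank"
        )
    # rankdata ranks ascending; negate so the largest score gets rank 1
    ranks = pd.Series(
        stats.rankdata(-det.values, method="average"), index=det.index
    ).reindex(measure.scores.index)
    return DatasetMeasure(measure.dataset_id, measure.platform, measure.scores, ranks)


@dataclass
class RankMatrix:
    """Native ranks of the reference dataset's miRNAs across datasets.

    Rows are the reference's detected miRNAs sorted by reference rank;
    each column holds a dataset's native ranks (NaN = blank: not detected
    or not assayed). ``bands`` maps every non-blank cell to the decile
    (1–10, 1 = top) of its native rank within its own dataset.
    """

    reference_dataset: str
    ranks: pd.DataFrame
    bands: pd.DataFrame
    n_detected: pd.Series

    @property
    def datasets(self) -> list[str]:
        return list(self.ranks.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.ranks.copy()
        out.to_csv(path, sep="\t", index_label="mature_id")


def build_rank_matrix(
    reference: DatasetMeasure, others: Sequence[DatasetMeasure]
) -> RankMatrix:
    """Align every dataset's native ranks on the reference miRNA ordering.

    Native ranks are computed per dataset over its full detected set
    *before* restriction to the reference miRNAs, so a miRNA keeps the
    rank it holds in its own study.
    """
    ref = reference if reference.ranks is not None else rank_dataset(reference)
    ranked = [ref] + [
        m if m.ranks is not None else rank_dataset(m) for m in others
    ]
    order = ref.ranks.dropna().sort_values().index
    cols = {}
    n_det = {}
    for m in ranked:
        if m.dataset_id in cols:
            raise ValueError(f"duplicate dataset id {m.dataset_id!r}")
        cols[m.dataset_id] = m.ranks.reindex(order)
        n_det[m.dataset_id] = m.ranks.notna().sum()
    ranks = pd.DataFrame(cols)
    n_detected = pd.Series(n_det)
    bands = np.ceil(ranks.div(n_detected, axis=1) * 10).clip(1, 10)
    return RankMatrix(
        reference_dataset=ref.dataset_id,
        ranks=ranks,
        bands=bands,
        n_detected=n_detected,
    )


@dataclass
class ConcordanceTable:
    """Pairwise Spearman correlations and top-k overlaps between datasets."""

    pairs: pd.DataFrame  # columns: a, b, spearman, n_shared, topk_overlap, computable
    top_k: int

    def spearman(self, a: str, b: str) -> float:
        sel = self.pairs[
            ((self.pairs["a"] == a) & (self.pairs["b"] == b))
            | ((self.pairs["a"] == b) & (self.pairs["b"] == a))
        ]
        if sel.empty:
            raise KeyError((a, b))
        return float(sel.iloc[0]["spearman"])


def concordance(matrix: RankMatrix, top_k: int = 6) -> ConcordanceTable:
    """Pairwise rank agreement over the matrix rows.

    For each dataset pair: Spearman correlation of native ranks over
    co-detected miRNAs (marked non-computable below 3 shared), and the
    number of miRNAs inside both datasets' native top-``top_k``.
    """
    cols = matrix.datasets
    if len(cols) < 2:
        raise ValueError("need >= 2 datasets")
    rows = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a, b = cols[i], cols[j]
            x = matrix.ranks[a]
            y = matrix.ranks[b]
            keep = x.notna() & y.notna()
            n = int(keep.sum())
            if n < 3:
                rows.append(
                    dict(a=a, b=b, spearman=np.nan, n_shared=n,
                         topk_overlap=np.nan, computable=False)
                )
                continue
            rho, _ = stats.spearmanr(x[keep], y[keep])
            overlap = int(((x <= top_k) & (y <= top_k)).sum())
            rows.append(
                dict(a=a, b=b, spearman=float(rho), n_shared=n,
                     topk_overlap=overlap, computable=True)
            )
    return ConcordanceTable(pairs=pd.DataFrame(rows), top_k=top_k)


def read_dataset_measure(path: str | Path) -> DatasetMeasure:
    """Read a per-dataset TSV: header comments ``# dataset=ID`` and
    ``# platform=...``, then columns mature_id, cell_value, ev_value.

    For ratio platforms the export score is ev_value / cell_value; for
    qPCR arrays the columns are Ct values and the score is cell − ev.
    Missing values leave the miRNA undetected.
    """
    dataset_id = Path(path).stem
    platform: Platform = "sequencing"
    with open(path) as fh:
        header_lines = 0
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            tag, _, val = line[1:].strip().partition("=")
            if tag.strip() == "dataset":
                dataset_id = val.strip()
            elif tag.strip() == "platform":
                platform = val.strip()  # type: ignore[assignment]
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index("mature_id")
    cell = df["cell_value"].astype(float)
    ev = df["ev_value"].astype(float)
    if platform == "qpcr_array":
        scores = cell - ev
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = ev / cell
        scores[(cell <= 0) | ~np.isfinite(scores)] = np.nan
    return DatasetMeasure(dataset_id, platform, scores)
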
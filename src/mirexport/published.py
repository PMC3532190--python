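"""Published HEK293T cell/EV RPMM reference values.

The packaged table lists the most preferentially released and retained
miRNAs of the HEK293T deep-sequencing study this pipeline reproduces, with
RPMM values for cells and EVs in the non-transfected (nt) and
miR-146a-transfected (tf) conditions and the log2(EV/Cells) values as
printed. In the transfected condition the overexpressed miR-146a reached
317,863 RPMM in cells (32% of the library) and 440,496 RPMM in EVs (44%).

Note: the printed transfected-condition log2 values for mir-143 and
mir-720 do not follow from their printed RPMM pairs (both ratios are < 1
yet the printed logs are positive); the rows are reproduced verbatim and
simply not used for numeric checks.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = ["load_hek293t_tables", "hek293t_measure"]

SPIKE_CELL_RPMM = 317_863.3
SPIKE_EV_RPMM = 440_496.3


def load_hek293t_tables() -> pd.DataFrame:
    """The released/retained tables as a DataFrame indexed by miRNA.

    Columns: list ("released"/"retained"), {nt,tf}_cell_rpmm,
    {nt,tf}_ev_rpmm and the printed {nt,tf}_log2_printed values.
    """
    ref = importlib.resources.files("mirexport") / "data" / "hek293t_export_tables.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("mirna")


def hek293t_measure(condition: str = "nt"):
    """The published values as a rankable sequencing DatasetMeasure."""
    from .cross_dataset import DatasetMeasure

    df = load_hek293t_tables()
    cell = df[f"{condition}_cell_rpmm"]
    ev = df[f"{condition}_ev_rpmm"]
    return DatasetMeasure(
        dataset_id=f"hek293t_{condition}",
        platform="sequencing",
        scores=(ev / cell),
    )
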
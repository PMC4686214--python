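"""Bundled reference data.

``reference_peptides.tsv`` lists the 32 peptides commonly detected across a
published mouse striatal-cell peptidomics benchmark, with their reported mean
relative levels (± SD) in two polyQ-expanded genotypes and after two
proteasome-inhibitor treatments, all relative to untreated wild-type cells.
Means printed at the 0.20 lower cap are stored as 0.20 and listed in the
``capped_low`` column.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_peptides", "CONDITION_COLUMNS"]

CONDITION_COLUMNS = ("q7q111", "q111q111", "epoxomicin", "bortezomib")


def load_reference_peptides() -> pd.DataFrame:
    """The benchmark table of 32 commonly detected peptides and their levels."""
    with resources.files("tmabquant.data").joinpath("reference_peptides.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["capped_low"] = df["capped_low"].fillna("")
    df["n_term_acetylated"] = df["n_term_acetylated"].astype(bool)
    return df
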
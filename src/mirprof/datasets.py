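"""Bundled example datasets."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def published_ne_profile() -> pd.DataFrame:
    """Published two-library normalized-expression profile (145 miRNAs).

    Columns: miRNA, NE_R, NE_P (reads-per-million). The last two rows
    were detected in a single library only (the other NE is 0); the
    first 143 rows were reported as differentially expressed. Used in
    tests and the acceptance report for fold-change classification.
    """
    with resources.files("mirprof.data").joinpath("published_ne_profile.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
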
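"""Small bundled example tables from a published colorectal-cancer lncRNA
m6A profiling study: the top differentially methylated lncRNAs and the
disease-associated candidates screened for network analysis."""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

__all__ = ["load_top_diff_methylated", "load_cerna_screen_table"]


def _data_path(name: str):
    return resources.files("lncm6a.data").joinpath(name)


def load_top_diff_methylated() -> pd.DataFrame:
    """Top ten hyper- and hypomethylated lncRNAs (diffReps-style table).

    Columns: chrom, txStart, txEnd (1-based closed), name, foldchange,
    regulation.
    """
    with resources.as_file(_data_path("crc_top_diff_methylated.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_cerna_screen_table() -> pd.DataFrame:
    """Disease-associated lncRNAs screened for ceRNA analysis.

    Eight methylation-screened rows (fold change > 7) and eight
    expression-screened rows (fold change > 2.5); ``Inf`` tokens are parsed
    to +infinity magnitude.
    """
    with resources.as_file(_data_path("crc_cerna_screen.tsv")) as path:
        frame = pd.read_csv(path, sep="\t")
    frame["fold_change"] = [
        math.inf if str(v).lstrip("-").lower() in ("inf", "infinity") else abs(float(v))
        for v in frame["fold_change"]
    ]
    return frame
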
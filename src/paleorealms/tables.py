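"""Published worked-example tables shipped as small text fixtures.

These are published summary tables of a global marine-biogeography
analysis (per-realm standardized event
rates, global process totals, and per-group realm-interchange matrices),
transcribed verbatim as TSV package data.  They serve as inputs to the
accounting layer's arithmetic — shares, percentages, interchange totals —
in worked examples and tests; nothing in the package derives them.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .accounting import InterchangeMatrix
from .core import MARINE_REALMS

__all__ = ["load_event_rates", "load_process_totals", "load_interchange", "INTERCHANGE_GROUPS"]

INTERCHANGE_GROUPS = ("corals", "cetaceans", "seagrass", "fish")


def _read(name: str) -> pd.DataFrame:
    with resources.files("paleorealms.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_event_rates() -> pd.DataFrame:
    """Richness-standardized per-realm event rates by group (realm-coded)."""
    return _read("table1.tsv")


def load_process_totals() -> pd.Series:
    """Global mean counts of the six biogeographic process types."""
    df = _read("table2.tsv")
    return df.set_index("process_type")["total_average_number_of_processes"]


def load_interchange(group: str) -> InterchangeMatrix:
    """One group's printed realm-interchange matrix (source rows, sink columns).

    The printed diagonal packs ``in_situ/extinction``; it is split out into
    the InterchangeMatrix's series and the matrix diagonal zeroed.
    """
    if group not in INTERCHANGE_GROUPS:
        raise ValueError(f"group must be one of {INTERCHANGE_GROUPS}")
    df = _read("table3.tsv")
    df = df[df["group"] == group].set_index("source")
    labels = list(MARINE_REALMS)
    matrix = np.zeros((len(labels), len(labels)))
    in_situ = np.zeros(len(labels))
    extinction = np.zeros(len(labels))
    for i, src in enumerate(labels):
        for k, dst in enumerate(labels):
            cell = str(df.loc[src, dst])
            if "/" in cell:
                a, b = cell.split("/")
                in_situ[i] = float(a)
                extinction[i] = float(b)
            else:
                matrix[i, k] = float(cell)
    return InterchangeMatrix(
        matrix=pd.DataFrame(matrix, index=labels, columns=labels),
        in_situ=pd.Series(in_situ, index=labels),
        extinction=pd.Series(extinction, index=labels),
    )
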
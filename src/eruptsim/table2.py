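"""Packaged fixture of the published per-tooth compression percentages.

The original study's jaw mesh was CT-specific and is not reproducible;
its printed per-tooth relative compression percentages (volume basis and
BRU basis, per side, bite mode and cap) are packaged so the exception
classification can be run against them without any solve.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_printed_table"]


def load_printed_table() -> pd.DataFrame:
    """The printed 64-value compression-percentage table.

    Returns a DataFrame with columns
    ``side, load, tooth, cap, basis, compression_pct`` covering
    {left, right} x {incisive, right_molar} x
    {canine, first_premolar, second_premolar, second_molar} x
    {coronal, apical} x {volume, bru}.
    """
    with resources.files("eruptsim.data").joinpath("table2.csv").open() as fh:
        table = pd.read_csv(fh)
    assert len(table) == 64
    return table
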
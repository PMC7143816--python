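"""Bundled reference tables.

Currently one table: the coordinates of the nine candidate
diversifying-selection regions reported for the Sokólski vs Sztumski
cold-blooded horse comparison, used to validate the package's region
arithmetic (1-based coordinates; size = end - start).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_regions"]


def load_reference_regions() -> pd.DataFrame:
    """Candidate-region coordinates for the two horse types.

    Columns: ``chromosome``, ``start_bp``, ``end_bp``, ``size_bp``.
    """
    with resources.files("divscan.data").joinpath("sok_sztum_regions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chromosome": str})
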
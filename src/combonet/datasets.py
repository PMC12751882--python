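"""Bundled reference data.

``reference_pairs.tsv`` holds eleven externally validated drug pairs as
pre-computed set distances (d_pp, d_mm, d_pm, d_mp), the reference relative
distances (d_plus_ref, d_minus_ref, both rounded to 2 decimals at the
source) and the observed interaction label. It exercises the relative-
distance and classification stages without any network computation.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

_REFERENCE_NAME = "reference_pairs.tsv"


def reference_pairs_path() -> Path:
    """Filesystem path of the bundled reference distance table."""
    return Path(resources.files("combonet") / "data" / _REFERENCE_NAME)


def load_reference_pairs() -> pd.DataFrame:
    """Load the bundled reference table as a DataFrame.

    Columns: pair (str), d_pp, d_mm, d_pm, d_mp, d_plus_ref, d_minus_ref
    (floats), label (synergism/antagonism).
    """
    df = pd.read_csv(reference_pairs_path(), sep="\t", dtype={"pair": str})
    for col in ("d_pp", "d_mm", "d_pm", "d_mp", "d_plus_ref", "d_minus_ref"):
        df[col] = df[col].astype(float)
    return df


def load_distance_table(path) -> pd.DataFrame:
    """Load a user-supplied distance table with the reference schema.

    Requires columns d_pp, d_mm, d_pm, d_mp and label; reference columns
    are optional.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"d_pp", "d_mm", "d_pm", "d_mp", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"distance table missing columns: {sorted(missing)}")
    return df
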
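"""Bundled reference data."""

from importlib import resources

import pandas as pd


def load_published_benchmark() -> pd.DataFrame:
    """Published per-1000 lifetime outcomes of the 15 Japanese endoscopic
    screening strategies (costs in $1000s discounted at 3%, QALYs gained vs
    no screening).  Used as a desk-scale fixture for the CEA machinery."""
    ref = resources.files("gcscreen.data") / "japan_screening_benchmark.csv"
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#")
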
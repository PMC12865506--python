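"""Small packaged reference tables."""

from importlib.resources import files

import pandas as pd


def load_case_study_retention() -> pd.DataFrame:
    """Retention accounting for the 29-species Olympic National Park case study.

    Columns: species code, the solved 95%-precision confidence-score
    threshold, total and above-threshold label counts, the published retained
    fraction (2 dp), and per-stratum attempted / model-fit / phenoperiod-
    detected indicators.  Used as an arithmetic reference for the retention
    reporting surface; the counts are inputs, not recomputed quantities.
    """
    path = files("vocalphen.data").joinpath("olympic_retention.csv")
    with path.open() as fh:
        return pd.read_csv(fh)
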
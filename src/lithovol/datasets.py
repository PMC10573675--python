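"""Bundled datasets.

``load_interobserver_medians`` returns a published inter-observer
volumetry reliability dataset: 50 renal-stone cases measured by three
observers of different endourology experience (junior, senior, expert),
five blinded repeat segmentations each, summarized as per-case median
volumes with quartiles (mm^3).  The raw replicate measurements were not
published, so the per-case medians are the finest grain available.

The transcription is verbatim, anomalies included, with the original
cell text preserved in the ``raw`` column:

* case 5, senior: a decimal comma in the printed Q3 ("320,5" -> 320.5);
* case 22, expert: the printed quartile interval does not bracket the
  median;
* case 28, junior: the printed median lies below the printed Q1;
* case 47, senior: the printed quartile interval (1019-1076) does not
  bracket the median 2033 (it repeats the neighbouring case's interval).

Quartile-dependent analyses should therefore exclude the affected cells;
the medians themselves are used as printed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .agreement import MeasurementTable

__all__ = ["load_interobserver_medians", "interobserver_median_table"]

OBSERVER_ORDER = ("junior", "senior", "expert")


def load_interobserver_medians() -> pd.DataFrame:
    """The bundled 50-case x 3-observer median-volume dataset, long format."""
    with resources.files("lithovol.data").joinpath("table2b.csv").open() as fh:
        df = pd.read_csv(fh)
    df["observer_id"] = pd.Categorical(
        df["observer_id"], categories=OBSERVER_ORDER, ordered=True
    )
    return df


def interobserver_median_table() -> MeasurementTable:
    """The bundled dataset as a MeasurementTable (one 'replicate' per cell).

    Each cell is a per-case median of five blinded measurements, so
    replicate-level statistics (CV, intra-observer concordance) are not
    computable from it; pairwise and overall concordance are.
    """
    df = load_interobserver_medians()[["case_id", "observer_id", "median_mm3"]].copy()
    df["observer_id"] = df["observer_id"].astype(str)
    df = df.rename(columns={"median_mm3": "volume_mm3"})
    df["replicate"] = 1
    return MeasurementTable(df)
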
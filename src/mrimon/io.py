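"""Flat-file I/O for relaxation series, fit results and cohort tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from mrimon.series import RelaxationSeries

SERIES_COLUMNS = ["kind", "time_ms", "signal", "excluded", "roi", "animal", "timepoint"]


def read_series_table(path: str | Path) -> list[RelaxationSeries]:
    """Read a long-format CSV/TSV of relaxation samples into series objects.

    Expected columns: kind, time_ms, signal, excluded (0/1), roi, animal,
    timepoint.  One series per (kind, roi, animal, timepoint) group, sorted
    by time.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"series table missing columns: {sorted(missing)}")
    out = []
    for (kind, roi, animal, tp), grp in df.groupby(
        ["kind", "roi", "animal", "timepoint"], sort=True
    ):
        grp = grp.sort_values("time_ms")
        out.append(
            RelaxationSeries(
                kind=kind,
                times=grp["time_ms"].to_numpy(float),
                signals=grp["signal"].to_numpy(float),
                excluded=grp["excluded"].to_numpy(bool),
                roi_label=str(roi),
                meta={"animal": animal, "timepoint": float(tp)},
            )
        )
    return out


def write_series_table(series_list: list[RelaxationSeries], path: str | Path) -> None:
    rows = []
    for s in series_list:
        for t, sig, ex in zip(s.times, s.signals, s.excluded):
            rows.append(
                {
                    "kind": s.kind,
                    "time_ms": t,
                    "signal": sig,
                    "excluded": int(ex),
                    "roi": s.roi_label,
                    "animal": s.meta.get("animal", ""),
                    "timepoint": s.meta.get("timepoint", np.nan),
                }
            )
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def write_fit_table(rows: list[dict], path: str | Path) -> pd.DataFrame:
    """Write a flat CSV of per-fit records (animal, timepoint, tissue, value,
    diagnostics); returns the DataFrame for further use."""
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
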
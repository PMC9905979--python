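"""Stand-in false-positive filter for coded-tag detections.

The published filtering routine for this kind of data lives in an external
reference; this module implements a documented stand-in built on the same
physical signal: genuine detections arrive in runs at one receiver whose
inter-detection gaps are integer multiples of the tag's fixed burst
interval.  A detection is kept only if it belongs to a run of at least
``min_run`` detections at the same receiver, with successive gaps no
longer than ``max_gap_s`` and within ``tol`` (fractional) of an integer
multiple of the burst interval.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def filter_false_positives(
    detections: pd.DataFrame,
    burst_intervals: dict,
    min_run: int = 3,
    max_gap_s: float = 600.0,
    tol: float = 0.2,
    return_report: bool = False,
):
    """Drop presumed false positives from a raw detection table.

    ``burst_intervals`` maps tag_id -> burst interval in seconds; tags not
    present are dropped entirely (flagged with a logged count).
    """
    df = detections.reset_index(drop=True)
    known = df["tag_id"].isin(burst_intervals.keys())
    n_unknown = int((~known).sum())
    if n_unknown:
        log.warning("dropping %d detections with unknown tag ids", n_unknown)
    df = df.loc[known]

    keep_idx = []
    for (tag, _rec), grp in df.groupby(["tag_id", "receiver_id"], sort=False):
        bi = burst_intervals[tag]
        grp = grp.sort_values("timestamp", kind="mergesort")
        ts = grp["timestamp"].astype("int64").to_numpy() / 1e9
        gaps = np.diff(ts)
        mult = np.round(gaps / bi)
        ok = (
            (gaps <= max_gap_s)
            & (mult >= 1)
            & (np.abs(gaps - mult * bi) <= tol * bi)
        )
        # run-length encode: detection i joins the run of i-1 when ok[i-1]
        run_start = 0
        n = len(grp)
        idx = grp.index.to_numpy()
        for i in range(1, n + 1):
            if i == n or not ok[i - 1]:
                if i - run_start >= min_run:
                    keep_idx.extend(idx[run_start:i])
                run_start = i
    base = detections.reset_index(drop=True)
    out = base.loc[sorted(keep_idx)] if keep_idx else base.iloc[0:0]
    out = out.sort_values(["timestamp", "tag_id", "receiver_id"],
                          kind="mergesort").reset_index(drop=True)
    if return_report:
        report = {
            "n_input": len(detections),
            "n_unknown_tag": n_unknown,
            "n_removed": len(detections) - n_unknown - len(out),
            "n_kept": len(out),
        }
        return out, report
    return out
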
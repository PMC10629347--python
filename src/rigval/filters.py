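"""Temporal 2D filters applied to detection sets before triangulation.

Only a median filter is provided, as a plumbing slot for comparing filtered
against unfiltered reconstructions; more elaborate trajectory smoothers are
out of scope.
"""

from __future__ import annotations

from .detections import DetectionSet

__all__ = ["median_filter_detections"]


def median_filter_detections(detections: DetectionSet, window: int = 3) -> DetectionSet:
    """Centered rolling-median filter on pixel coordinates.

    Applied per (camera, keypoint) over frames; missing detections do not
    contribute to neighbouring medians and stay missing themselves. ``window``
    must be odd.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window == 1:
        return DetectionSet(detections.table.copy())
    tab = detections.table.copy()
    tab = tab.sort_values(["camera_id", "keypoint", "frame"]).reset_index(drop=True)
    grp = tab.groupby(["camera_id", "keypoint"], sort=False)
    for col in ("u", "v"):
        tab[col] = grp[col].transform(
            lambda s: s.rolling(window, center=True, min_periods=1).median()
        )
    # a missing record keeps NaN pixels regardless of neighbours
    tab.loc[tab["missing"], ["u", "v"]] = float("nan")
    return DetectionSet(tab)
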
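"""The 12 per-call acoustic parameters, plus the per-animal call count.

Definitions (f_i is the contour frequency at frame i, n frames total):

- duration_ms        : (offset - onset) * 1000
- freq_dynamic_hz    : max(f) - min(f)
- delta_freq_hz      : f_end - f_start (end minus start frequency)
- mean_freq_hz       : mean(f)
- freq_tv_hz         : total variation, sum |f_{i+1} - f_i|
- mean_freq_tv_hz    : freq_tv / (n - 1), the mean per-step change
- linearity_index    : freq_tv / freq_dynamic (1 for a monotone sweep; defined
                       as 1 for a constant contour)
- nb_modulation      : local extrema of the smoothed contour with prominence
                       at or above the modulation depth
- nb_jumps           : inter-frame steps |f_{i+1} - f_i| above the jump
                       threshold
- min_freq_hz / max_freq_hz
- peak_freq_hz       : frequency at the frame of maximal amplitude (earliest
                       frame on ties)

The path-length interpretations of linearity index and mean frequency TV are
this package's declared conventions (configurable via
:class:`~usvkit.config.FeatureParams`); they match the expected orders of
magnitude of the reported group statistics but other conventions exist.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .config import FeatureParams
from .contour import Contour
from .io_formats import FEATURE_COLUMNS, CallRecord


def compute_features(c: Contour, params: FeatureParams | None = None) -> dict[str, float]:
    """The 12 acoustic parameters of one call, keyed by canonical column name."""
    params = params or FeatureParams()
    f = c.freqs
    n = f.size
    if n < 2:
        raise ValueError("contour must have at least 2 frames")
    steps = np.abs(np.diff(f))
    freq_tv = float(steps.sum())
    fmin, fmax = float(f.min()), float(f.max())
    dynamic = fmax - fmin
    linearity = freq_tv / dynamic if dynamic > 0 else 1.0
    width = min(params.smoothing_frames, n)
    if width > 1:
        from scipy.ndimage import uniform_filter1d
        smoothed = uniform_filter1d(f, size=width, mode="nearest")
    else:
        smoothed = f
    peaks_up, _ = find_peaks(smoothed, prominence=params.modulation_depth_hz)
    peaks_dn, _ = find_peaks(-smoothed, prominence=params.modulation_depth_hz)
    peak_frame = int(np.argmax(c.amps))  # argmax takes the earliest tie
    return {
        "duration_ms": (c.offset_s - c.onset_s) * 1000.0,
        "freq_dynamic_hz": dynamic,
        "delta_freq_hz": float(f[-1] - f[0]),
        "mean_freq_hz": float(f.mean()),
        "freq_tv_hz": freq_tv,
        "mean_freq_tv_hz": freq_tv / (n - 1),
        "linearity_index": linearity,
        "nb_modulation": float(peaks_up.size + peaks_dn.size),
        "nb_jumps": float(np.count_nonzero(steps > params.jump_threshold_hz)),
        "min_freq_hz": fmin,
        "max_freq_hz": fmax,
        "peak_freq_hz": float(f[peak_frame]),
    }


def features_frame(contours: list[Contour], params: FeatureParams | None = None,
                   ) -> pd.DataFrame:
    """Feature rows (canonical column order) for a list of contours."""
    rows = [compute_features(c, params) for c in contours]
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def featurize_table(calls: list[CallRecord], contours: list[Contour],
                    params: FeatureParams | None = None,
                    ) -> tuple[list[CallRecord], pd.DataFrame]:
    """Attach a feature vector to each call; summarize per-animal call counts.

    Returns the updated records and an animal summary with columns
    ``animal_id, group, voc_number``.  Records and contours are matched by
    position.
    """
    if len(calls) != len(contours):
        raise ValueError(f"{len(calls)} calls but {len(contours)} contours")
    out = []
    for rec, c in zip(calls, contours):
        feats = compute_features(c, params)
        out.append(CallRecord(call_id=rec.call_id, animal_id=rec.animal_id,
                              group=rec.group, onset_s=rec.onset_s,
                              offset_s=rec.offset_s, features=feats,
                              call_type=rec.call_type, is_truth=rec.is_truth))
    if out:
        summary = (pd.DataFrame([{"animal_id": r.animal_id, "group": r.group}
                                 for r in out])
                   .groupby(["animal_id", "group"], as_index=False)
                   .size().rename(columns={"size": "voc_number"})
                   .sort_values("animal_id").reset_index(drop=True))
    else:
        summary = pd.DataFrame(columns=["animal_id", "group", "voc_number"])
    return out, summary


def attach_voc_number(features: pd.DataFrame, animal_ids: pd.Series | np.ndarray,
                      ) -> pd.DataFrame:
    """Append each animal's call count (voc_number) to its feature rows.

    The 13th variable used for variable clustering: the number of calls an
    animal produced in the session, repeated on every call row of that animal.
    """
    ids = pd.Series(np.asarray(animal_ids), index=features.index, name="animal_id")
    counts = ids.map(ids.value_counts())
    out = features.copy()
    out["voc_number"] = counts.astype(float)
    return out
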
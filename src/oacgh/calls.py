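"""Gain/loss calling on segmented profiles, under two rules.

Threshold rule: a segment is a gain when its mean is at or above the gain
threshold (default +0.2) with at least ``min_probes`` probes (default 3),
a loss at or below the loss threshold (default -0.2); otherwise neutral.

MAD dichotomization: gains and losses are segments whose mean lies more
than 3 mean-absolute-deviations from the median of the sample's response
across all chromosomes; the median and MAD come from probe-level values
by default (config switch for segment means).

Both rules produce a three-state track {-1, 0, +1} per segment, tagged
with the rule and its parameters in ``DataFrame.attrs``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .normalize import NormalizedProfile, mean_abs_deviation

GAIN_THR = 0.2
LOSS_THR = -0.2
MIN_PROBES = 3
N_MAD = 3.0


def call_threshold(
    segments: pd.DataFrame,
    gain_thr: float = GAIN_THR,
    loss_thr: float = LOSS_THR,
    min_probes: int = MIN_PROBES,
) -> pd.DataFrame:
    """Three-state calls from segment means and probe counts."""
    if not loss_thr < 0 < gain_thr:
        raise ValueError("thresholds must satisfy loss_thr < 0 < gain_thr")
    mean = segments["seg_mean"].to_numpy(dtype=float)
    n = segments["n_probes"].to_numpy()
    state = np.zeros(len(segments), dtype=int)
    state[(mean >= gain_thr) & (n >= min_probes)] = 1
    state[(mean <= loss_thr) & (n >= min_probes)] = -1
    out = segments.copy()
    out["state"] = state
    out.attrs["rule"] = "threshold"
    out.attrs["params"] = {
        "gain_thr": gain_thr, "loss_thr": loss_thr, "min_probes": min_probes,
    }
    return out


def dichotomize_mad(
    segments: pd.DataFrame,
    profile: NormalizedProfile | np.ndarray,
    n_mad: float = N_MAD,
    basis: str = "probe",
) -> pd.DataFrame:
    """Three-state calls at median +/- ``n_mad`` * MAD of the sample response.

    ``profile`` supplies the probe-level ProcessedRatio values across all
    chromosomes (or pass ``basis="segment"`` to compute the center and
    spread from segment means instead).
    """
    if basis == "probe":
        if isinstance(profile, NormalizedProfile):
            values = profile.probes["processed_ratio"].to_numpy(dtype=float)
        else:
            values = np.asarray(profile, dtype=float)
    elif basis == "segment":
        values = segments["seg_mean"].to_numpy(dtype=float)
    else:
        raise ValueError(f"basis must be 'probe' or 'segment', got {basis!r}")
    if len(np.unique(values)) < 2:
        raise ValueError("sample response is constant; MAD dichotomization undefined")
    center = float(np.median(values))
    spread = mean_abs_deviation(values)
    if spread == 0:
        raise ValueError("zero MAD; cannot dichotomize")
    mean = segments["seg_mean"].to_numpy(dtype=float)
    state = np.zeros(len(segments), dtype=int)
    state[mean > center + n_mad * spread] = 1
    state[mean < center - n_mad * spread] = -1
    out = segments.copy()
    out["state"] = state
    out.attrs["rule"] = "mad"
    out.attrs["params"] = {
        "n_mad": n_mad, "basis": basis, "median": center, "mad": spread,
    }
    return out
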
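"""Reporter-ion extraction from MS3 peak lists and PSM-level quantification QC.

Extraction takes, per channel, the most intense peak within a narrow window
(default 0.003 Da) around the theoretical reporter m/z; the per-channel
signal-to-noise is the selected peak's intensity over its instrument noise
estimate.  PSMs with poor-quality MS3 spectra are excluded from
quantification: below 100 summed signal-to-noise across the 10 channels, or
below 0.7 precursor isolation specificity.  Both thresholds are strict
(values exactly at the boundary are kept).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .masses import TMT10_CHANNELS, TMT10_REPORTER_MZ

DEFAULT_WINDOW_DA = 0.003
MIN_SUMMED_SN = 100.0
MIN_ISOLATION_SPECIFICITY = 0.7

REASON_LOW_SN = "low_summed_sn"
REASON_LOW_SPECIFICITY = "low_isolation_specificity"


@dataclass
class ReporterVector:
    channel_ids: tuple
    intensities: np.ndarray
    signal_to_noise: np.ndarray

    @property
    def summed_sn(self) -> float:
        return float(np.sum(self.signal_to_noise))


def extract_reporters(
    reporter_peaks: Sequence[tuple],
    theoretical_mz: Sequence[float] = TMT10_REPORTER_MZ,
    window: float = DEFAULT_WINDOW_DA,
    channel_ids: Sequence[str] = TMT10_CHANNELS,
) -> ReporterVector:
    """Pick, per channel, the most intense peak within ``window`` Da of the
    theoretical reporter m/z.  A channel with no candidate peak gets
    intensity 0 and S/N 0."""
    if window <= 0:
        raise ValueError("window must be positive")
    theo = np.asarray(theoretical_mz, dtype=float)
    if np.any(np.diff(theo) <= 0):
        raise ValueError("theoretical_mz must be strictly increasing")
    peaks = list(reporter_peaks)
    mz = np.array([p[0] for p in peaks], dtype=float)
    if mz.size and np.any(np.diff(mz) < 0):
        raise ValueError("reporter peak list must be sorted by m/z")
    inten = np.array([p[1] for p in peaks], dtype=float)
    noise = np.array([p[2] for p in peaks], dtype=float)

    out_i = np.zeros(len(theo))
    out_sn = np.zeros(len(theo))
    for c, t in enumerate(theo):
        if not mz.size:
            continue
        cand = np.abs(mz - t) <= window
        if not cand.any():
            continue
        best = np.flatnonzero(cand)[np.argmax(inten[cand])]
        out_i[c] = inten[best]
        out_sn[c] = inten[best] / noise[best] if noise[best] > 0 else 0.0
    return ReporterVector(tuple(channel_ids[: len(theo)]), out_i, out_sn)


def qc_filter_psm(
    vector: ReporterVector,
    isolation_specificity: float,
    min_summed_sn: float = MIN_SUMMED_SN,
    min_specificity: float = MIN_ISOLATION_SPECIFICITY,
) -> tuple[bool, str | None]:
    """Keep/drop decision with a reason code naming the rule(s) that fired.

    Drop iff summed S/N < ``min_summed_sn`` (strict) or isolation
    specificity < ``min_specificity`` (strict).
    """
    if not 0.0 <= isolation_specificity <= 1.0:
        raise ValueError("isolation_specificity must be in [0, 1]")
    reasons = []
    if vector.summed_sn < min_summed_sn:
        reasons.append(REASON_LOW_SN)
    if isolation_specificity < min_specificity:
        reasons.append(REASON_LOW_SPECIFICITY)
    return (not reasons, ",".join(reasons) or None)


def quantify_psms(
    psm_frame: pd.DataFrame,
    window: float = DEFAULT_WINDOW_DA,
    min_summed_sn: float = MIN_SUMMED_SN,
    min_specificity: float = MIN_ISOLATION_SPECIFICITY,
) -> pd.DataFrame:
    """Extract reporter intensities and apply QC for a whole PSM table.

    Expects the frame produced by :func:`plexquant.io.psms_to_frame` (one
    ``reporter_peaks`` object column).  Returns the frame with ten intensity
    columns (one per channel), ``summed_sn``, ``qc_keep`` and ``qc_reason``.
    """
    n_ch = len(TMT10_CHANNELS)
    inten = np.zeros((len(psm_frame), n_ch))
    sn = np.zeros(len(psm_frame))
    for i, peaks in enumerate(psm_frame["reporter_peaks"]):
        vec = extract_reporters(peaks, window=window)
        inten[i] = vec.intensities
        sn[i] = vec.summed_sn
    out = psm_frame.copy()
    for c, label in enumerate(TMT10_CHANNELS):
        out[f"intensity_{label}"] = inten[:, c]
    out["summed_sn"] = sn
    spec = out["isolation_specificity"].to_numpy(dtype=float)
    low_sn = sn < min_summed_sn
    low_spec = spec < min_specificity
    out["qc_keep"] = ~(low_sn | low_spec)
    reasons = np.where(
        low_sn & low_spec,
        f"{REASON_LOW_SN},{REASON_LOW_SPECIFICITY}",
        np.where(low_sn, REASON_LOW_SN, np.where(low_spec, REASON_LOW_SPECIFICITY, "")),
    )
    out["qc_reason"] = reasons
    return out
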
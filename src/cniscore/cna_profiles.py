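"""Cohort-level gain/loss frequency tracks and profile concordance.

Plasma profiles are thresholded on Z-scores (|Z| > 2.84), tumor-tissue
profiles on log2 ratios (+/-0.3), and each window's alteration frequency
is the fraction of informative (unmasked) samples altered there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import Z_CRIT

TISSUE_LOG2_THRESHOLD = 0.3


@dataclass
class AlterationFrequencyTrack:
    """Per-window gain/loss frequencies over informative samples."""

    gain: pd.Series
    loss: pd.Series
    n_informative: pd.Series

    def __post_init__(self) -> None:
        if not (self.gain.index.equals(self.loss.index) and self.gain.index.equals(self.n_informative.index)):
            raise ValueError("track component indices differ")

    @property
    def signed(self) -> pd.Series:
        return self.gain - self.loss

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gain_freq": self.gain, "loss_freq": self.loss, "n": self.n_informative}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA")


def _threshold_track(matrix: pd.DataFrame, upper: float, lower: float) -> AlterationFrequencyTrack:
    if matrix.shape[0] == 0:
        raise ValueError("matrix has zero samples")
    vals = matrix.to_numpy(dtype=float)
    informative = np.isfinite(vals)
    n_inf = informative.sum(axis=0)
    with np.errstate(invalid="ignore"):
        gains = np.where(informative, vals > upper, False).sum(axis=0)
        losses = np.where(informative, vals < lower, False).sum(axis=0)
    denom = np.where(n_inf > 0, n_inf, 1)
    gain = np.where(n_inf > 0, gains / denom, np.nan)
    loss = np.where(n_inf > 0, losses / denom, np.nan)
    idx = matrix.columns
    return AlterationFrequencyTrack(
        gain=pd.Series(gain, index=idx),
        loss=pd.Series(loss, index=idx),
        n_informative=pd.Series(n_inf, index=idx),
    )


def plasma_frequencies(
    z_matrix: pd.DataFrame, z_crit: float = Z_CRIT
) -> AlterationFrequencyTrack:
    """Gain/loss frequencies from a samples x windows Z matrix.

    Gain where z > z_crit, loss where z < -z_crit, both strict.
    """
    return _threshold_track(z_matrix, upper=z_crit, lower=-z_crit)


def tissue_frequencies(
    log2_matrix: pd.DataFrame, threshold: float = TISSUE_LOG2_THRESHOLD
) -> AlterationFrequencyTrack:
    """Gain/loss frequencies from a tissue log2-ratio matrix at +/-threshold."""
    return _threshold_track(log2_matrix, upper=threshold, lower=-threshold)


@dataclass
class ConcordanceSummary:
    """Correlations between two frequency tracks on the same window grid."""

    gain_correlation: float
    loss_correlation: float
    signed_correlation: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _corr(a: pd.Series, b: pd.Series) -> float:
    x = a.to_numpy(dtype=float)
    y = b.to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def profile_concordance(
    track_a: AlterationFrequencyTrack, track_b: AlterationFrequencyTrack
) -> ConcordanceSummary:
    """Pearson correlation of gain, loss, and signed (gain - loss) tracks."""
    if not track_a.gain.index.equals(track_b.gain.index):
        raise ValueError("tracks are on different window sets")
    return ConcordanceSummary(
        gain_correlation=_corr(track_a.gain, track_b.gain),
        loss_correlation=_corr(track_a.loss, track_b.loss),
        signed_correlation=_corr(track_a.signed, track_b.signed),
    )


def truth_signed_track(
    segments_by_sample: dict[str, tuple], n_condensed: int, window_ids: pd.Index
) -> AlterationFrequencyTrack:
    """Gain/loss frequency track implied by simulator truth segments.

    Useful for round-trip checks of plasma tracks against the generating
    copy-number profiles.
    """
    gains = np.zeros(n_condensed)
    losses = np.zeros(n_condensed)
    n = len(segments_by_sample)
    if n == 0:
        raise ValueError("no samples")
    for segs in segments_by_sample.values():
        for seg in segs:
            sl = slice(seg.start_window_index, seg.end_window_index)
            if seg.total_copy_number > 2:
                gains[sl] += 1
            elif seg.total_copy_number < 2:
                losses[sl] += 1
    return AlterationFrequencyTrack(
        gain=pd.Series(gains / n, index=window_ids),
        loss=pd.Series(losses / n, index=window_ids),
        n_informative=pd.Series(np.full(n_condensed, n), index=window_ids),
    )
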
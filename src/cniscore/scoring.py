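"""Panel of normals, per-window Z-scores, and the CNI-Score.

The Copy Number Instability score condenses a genome-wide copy-number
profile into a single number: each final window's log2 ratio is
standardized against the mean and standard deviation of a reference panel
of healthy donors, windows whose |Z| exceeds the critical difference
(2.84 by default) are called significantly deviant from diploid, and the
absolute Z-scores of those windows are summed.

Under the null (no tumor DNA, well-calibrated Z), the expected score for
m windows is m * 2 * phi(z_crit) where phi is the standard normal density
— about 9.9 for 701 windows at z_crit 2.84 — with a median near 9.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import Log2Matrix, condense, correct_biases, to_log2
from .windows import WindowSet

Z_CRIT = 2.84
SCORE_CUTOFF = 24.0
SD_FLOOR = 1e-6


@dataclass
class NormalPanel:
    """Per-window mean and sample SD of panel log2 ratios at condensed resolution."""

    mean: pd.Series
    sd: pd.Series
    n: int

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("panel mean/sd indices differ")
        if self.n < 2:
            raise ValueError("panel needs at least 2 samples")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"mean": self.mean, "sd": self.sd, "n": self.n}).to_csv(
            path, sep="\t", na_rep="NA"
        )

    @classmethod
    def from_tsv(cls, path) -> "NormalPanel":
        t = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        return cls(mean=t["mean"], sd=t["sd"], n=int(t["n"].iloc[0]))


@dataclass
class ZProfile:
    """Per-window Z-scores of one sample against the normal panel (NaN = masked)."""

    z: pd.Series

    @property
    def n_masked(self) -> int:
        return int(self.z.isna().sum())


@dataclass
class CNIResult:
    """CNI-Score of one sample, with the windows that drove it."""

    cni_score: float
    n_significant_windows: int
    z_crit: float
    call: bool
    cutoff_used: float

    def to_dict(self) -> dict:
        return {
            "cni_score": self.cni_score,
            "n_significant_windows": self.n_significant_windows,
            "z_crit": self.z_crit,
            "call": "positive" if self.call else "negative",
            "cutoff": self.cutoff_used,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_panel(
    panel_log2: Log2Matrix, sd_floor: float = SD_FLOOR, calibrate_prediction: bool = True
) -> NormalPanel:
    """Per-window mean and n-1 SD over the unmasked panel values.

    With ``calibrate_prediction`` (default), the sample SD is inflated by
    sqrt((1 + 1/n) * (n-1) / (n-3)): the Z-score of a *fresh* normal
    sample against an estimated mean and SD is t-distributed with n-1
    degrees of freedom and variance above 1, and this factor restores unit
    variance so the |Z| > z_crit tail calls stay calibrated.  For n = 137
    the factor is ~1.1%; disable it to reproduce the raw panel SD.

    Windows whose SD falls below ``sd_floor`` are floored (with a warning)
    so a degenerate zero-variance window can never yield infinite Z.
    """
    vals = panel_log2.values
    if vals.shape[0] < 2:
        raise ValueError(f"panel has {vals.shape[0]} samples; need >= 2")
    mean = vals.mean(axis=0, skipna=True)
    sd = vals.std(axis=0, ddof=1, skipna=True)
    n = vals.shape[0]
    if calibrate_prediction and n > 3:
        sd = sd * np.sqrt((1.0 + 1.0 / n) * (n - 1.0) / (n - 3.0))
    floored = int((sd < sd_floor).sum())
    if floored:
        warnings.warn(f"{floored} panel windows had SD < {sd_floor}; floored")
        sd = sd.clip(lower=sd_floor)
    return NormalPanel(mean=mean, sd=sd, n=vals.shape[0])


def z_scores(sample_log2: pd.Series | Log2Matrix, panel: NormalPanel) -> ZProfile:
    """Standardize one sample's condensed log2 profile against the panel."""
    if isinstance(sample_log2, Log2Matrix):
        if sample_log2.values.shape[0] != 1:
            raise ValueError("z_scores expects a single sample")
        sample_log2 = sample_log2.values.iloc[0]
    if not sample_log2.index.equals(panel.mean.index):
        raise ValueError("sample windows do not match panel windows")
    return ZProfile(z=(sample_log2 - panel.mean) / panel.sd)


def z_score_matrix(log2: Log2Matrix, panel: NormalPanel) -> pd.DataFrame:
    """Z-scores for every row of a condensed log2 matrix."""
    if not log2.values.columns.equals(panel.mean.index):
        raise ValueError("log2 windows do not match panel windows")
    return (log2.values - panel.mean) / panel.sd


def cni_score(
    z: ZProfile | pd.Series,
    z_crit: float = Z_CRIT,
    cutoff: float = SCORE_CUTOFF,
) -> CNIResult:
    """Sum |Z| over windows with |Z| strictly above ``z_crit``."""
    zv = z.z if isinstance(z, ZProfile) else z
    absz = np.abs(np.asarray(zv, dtype=float))
    sig = absz > z_crit  # NaN compares False: masked windows never significant
    score = float(absz[sig].sum())
    return CNIResult(
        cni_score=score,
        n_significant_windows=int(sig.sum()),
        z_crit=z_crit,
        call=classify(score, cutoff),
        cutoff_used=cutoff,
    )


def cni_scores_from_z(z_matrix: np.ndarray | pd.DataFrame, z_crit: float = Z_CRIT) -> np.ndarray:
    """Vectorized CNI-Scores for a samples x windows Z matrix."""
    absz = np.abs(np.asarray(z_matrix, dtype=float))
    return np.where(absz > z_crit, absz, 0.0).sum(axis=1)


def classify(score: float, cutoff: float = SCORE_CUTOFF) -> bool:
    """Positive call iff score strictly exceeds the cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return score > cutoff


@dataclass
class PipelineResult:
    """End-to-end scoring output with exportable intermediates."""

    result: CNIResult
    corrected: pd.DataFrame
    log2_small: Log2Matrix
    log2_condensed: Log2Matrix
    z: ZProfile


def run_pipeline(
    counts: pd.Series | pd.DataFrame,
    windows: WindowSet,
    panel: NormalPanel,
    z_crit: float = Z_CRIT,
    cutoff: float = SCORE_CUTOFF,
    loess_span: float = 0.3,
    min_mappability: float = 0.0,
) -> PipelineResult:
    """Score one sample: count -> correct -> log2 -> condense -> Z -> CNI."""
    if isinstance(counts, pd.Series):
        counts = counts.to_frame().T
        counts.index = ["sample"]
    if counts.shape[0] != 1:
        raise ValueError("run_pipeline scores a single sample")
    corrected = correct_biases(
        counts, windows, loess_span=loess_span, min_mappability=min_mappability
    )
    log2_small = to_log2(corrected)
    log2_cond = condense(log2_small, windows)
    z = z_scores(log2_cond.values.iloc[0], panel)
    return PipelineResult(
        result=cni_score(z, z_crit=z_crit, cutoff=cutoff),
        corrected=corrected,
        log2_small=log2_small,
        log2_condensed=log2_cond,
        z=z,
    )


def build_panel_from_counts(
    panel_counts: pd.DataFrame,
    windows: WindowSet,
    sd_floor: float = SD_FLOOR,
    loess_span: float = 0.3,
    min_mappability: float = 0.0,
) -> NormalPanel:
    """Convenience: normalize a panel count matrix and build the NormalPanel."""
    corrected = correct_biases(
        panel_counts, windows, loess_span=loess_span, min_mappability=min_mappability
    )
    log2_cond = condense(to_log2(corrected), windows)
    return build_panel(log2_cond, sd_floor=sd_floor)
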
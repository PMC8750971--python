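"""GC/mappability bias correction, log2 transform, and window condensation.

Shallow-WGS bin counts carry strong technical biases: coverage depends
smoothly on window GC content and on alignability.  Each sample is
corrected independently with two sequential locally weighted (lowess)
regressions — count on GC, then the residual ratio on mappability — and
rescaled so the sample median equals 1.  The correction never looks at
other samples, so panel and test samples are treated identically.

Masked windows are carried as NaN throughout (never dropped), keeping
window indices aligned between samples and the panel of normals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .windows import WindowSet

DEFAULT_LOESS_SPAN = 0.3
MIN_USABLE_WINDOWS = 50


@dataclass
class Log2Matrix:
    """Samples x windows log2 ratios with provenance flags.

    NaN encodes masked entries.  ``resolution`` is "small" or "condensed";
    ``corrected`` / ``condensed`` record which pipeline stages produced it.
    """

    values: pd.DataFrame
    resolution: str = "small"
    corrected: bool = True
    condensed: bool = False

    @property
    def n_masked(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA")

    @classmethod
    def from_tsv(cls, path, **kwargs) -> "Log2Matrix":
        values = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
        return cls(values, **kwargs)


def _smooth_fit(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Lowess fit of y on x evaluated at x, with delta acceleration."""
    delta = 0.01 * (x.max() - x.min())
    return lowess(y, x, frac=span, delta=delta, return_sorted=False)


def correct_biases(
    counts: pd.DataFrame,
    windows: WindowSet,
    loess_span: float = DEFAULT_LOESS_SPAN,
    min_mappability: float = 0.0,
) -> pd.DataFrame:
    """Remove GC and mappability bias per sample; median-rescale to 1.

    ``counts`` is samples x windows (matching ``windows`` order).  For each
    sample the smooth fits are estimated on windows with mappability >=
    ``min_mappability``; windows with non-positive fitted values are masked
    (NaN).  Returns a real-valued matrix whose per-sample median over
    unmasked windows is 1.
    """
    if counts.shape[1] != len(windows):
        raise ValueError(
            f"count matrix has {counts.shape[1]} windows, window set has {len(windows)}"
        )
    gc = windows.table["gc"].to_numpy(dtype=float)
    mp = windows.table["mappability"].to_numpy(dtype=float)
    usable = mp >= min_mappability
    if int(usable.sum()) < MIN_USABLE_WINDOWS:
        raise ValueError(
            f"only {int(usable.sum())} usable windows (< {MIN_USABLE_WINDOWS})"
        )
    out = np.full(counts.shape, np.nan)
    raw = counts.to_numpy(dtype=float)
    for i, sample in enumerate(counts.index):
        y = raw[i]
        if not np.any(y[usable] > 0):
            raise ValueError(f"sample {sample!r} has all-zero counts")
        ratio = np.full_like(y, np.nan)
        ok = usable
        ratio[ok] = y[ok]
        # backfit the two smooth corrections: a single GC -> mappability
        # pass leaves residual structure when the two annotation tracks are
        # correlated along the genome, so iterate the pair twice
        for _ in range(2):
            if np.any(ok) and np.ptp(gc[ok]) > 0:
                fit_gc = np.full_like(y, np.nan)
                fit_gc[ok] = _smooth_fit(gc[ok], ratio[ok], loess_span)
                ok = ok & (fit_gc > 0)
                ratio[~ok] = np.nan
                ratio[ok] = ratio[ok] / fit_gc[ok]
            if np.any(ok) and np.ptp(mp[ok]) > 0:
                fit_mp = np.full_like(y, np.nan)
                fit_mp[ok] = _smooth_fit(mp[ok], ratio[ok], loess_span)
                ok = ok & (fit_mp > 0)
                ratio[~ok] = np.nan
                ratio[ok] = ratio[ok] / fit_mp[ok]
        med = np.nanmedian(ratio)
        if not np.isfinite(med) or med <= 0:
            raise ValueError(f"sample {sample!r}: degenerate correction (median {med})")
        out[i] = ratio / med
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def to_log2(corrected: pd.DataFrame) -> Log2Matrix:
    """log2-transform corrected ratios; zeros become masked entries."""
    vals = corrected.to_numpy(dtype=float)
    if np.any(vals[np.isfinite(vals)] < 0):
        raise ValueError("corrected values must be non-negative")
    with np.errstate(divide="ignore"):
        log2 = np.where(vals > 0, np.log2(np.where(vals > 0, vals, 1.0)), np.nan)
    return Log2Matrix(
        pd.DataFrame(log2, index=corrected.index, columns=corrected.columns),
        resolution="small",
        corrected=True,
        condensed=False,
    )


def condense(
    log2: Log2Matrix, windows: WindowSet, max_masked_fraction: float = 0.5
) -> Log2Matrix:
    """Average groups of small-window log2 values into condensed windows.

    Each condensed window is the mean of its unmasked members; it is masked
    when more than ``max_masked_fraction`` of its members are masked.
    Trailing small windows with group -1 are ignored.
    """
    if log2.resolution != "small":
        raise ValueError("condense expects small-resolution input")
    groups = windows.table["group"].to_numpy()
    if (groups >= 0).sum() == 0:
        raise ValueError("window set records no condensation grouping")
    if log2.values.shape[1] != len(windows):
        raise ValueError("log2 matrix does not align with window set")
    keep = groups >= 0
    vals = log2.values.to_numpy(dtype=float)[:, keep]
    g = groups[keep]
    order = np.argsort(g, kind="stable")
    vals = vals[:, order]
    g = g[order]
    uniq, starts = np.unique(g, return_index=True)
    n_samples = vals.shape[0]
    out = np.full((n_samples, len(uniq)), np.nan)
    bounds = np.append(starts, len(g))
    for j in range(len(uniq)):
        block = vals[:, bounds[j] : bounds[j + 1]]
        n_members = block.shape[1]
        n_ok = np.sum(np.isfinite(block), axis=1)
        mean = np.where(n_ok > 0, np.nansum(block, axis=1) / np.maximum(n_ok, 1), np.nan)
        masked = (n_members - n_ok) > max_masked_fraction * n_members
        out[:, j] = np.where(masked, np.nan, mean)
    return Log2Matrix(
        pd.DataFrame(out, index=log2.values.index, columns=windows.condensed_ids()),
        resolution="condensed",
        corrected=log2.corrected,
        condensed=True,
    )
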
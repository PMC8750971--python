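"""Synthetic cfDNA shallow-WGS data with known truth.

Generates the three ingredients the CNI pipeline consumes — a window grid
with smooth GC/mappability annotations, per-window fragment counts for
normal-panel and tumor samples, and fragment-length draws — from an
explicit generative model:

* counts are negative-binomial around ``mean_count * bias(gc) *
  mappability * copy_ratio`` with variance mu + mu^2 * d;
* a tumor with fraction f and a segment at total copy number c shifts the
  expected relative copy ratio to (2(1-f) + c*f)/2, i.e. an expected log2
  ratio of log2(1 + f(c-2)/2);
* fragment lengths are a two-component Gaussian mixture: a mononucleosomal
  background (mean 167 bp) and a shorter tumor-derived mode (mean 145 bp),
  truncated to [50, 400] bp.

The GC bias curve is known to the simulator only; the pipeline must
recover and remove it blind.  All randomness flows from one master seed
through numpy SeedSequence spawning, so cohorts are reproducible
sample-by-sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .windows import WindowSet, build_windows

N_PSEUDO_AUTOSOMES = 22


@dataclass(frozen=True)
class CNASegment:
    """A segmental copy-number alteration on the condensed window grid.

    ``start_window_index``/``end_window_index`` are 0-based half-open
    indices into condensed windows; ``total_copy_number`` is the tumor's
    total copy number there (diploid = 2).
    """

    start_window_index: int
    end_window_index: int
    total_copy_number: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_window_index < self.end_window_index:
            raise ValueError("need 0 <= start < end for segment window indices")
        if self.total_copy_number < 0:
            raise ValueError("total copy number must be >= 0")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cfDNA study.

    Defaults mirror the assay geometry: 7010 small windows of 0.55 Mbp
    condensing 10:1 into 701 final windows, ~1800 fragments per small
    window (~18,000 per condensed bin), and a 137-sample normal panel.
    """

    n_small_windows: int = 7010
    condense_factor: int = 10
    small_window_bp: int = 550_000
    mean_count_per_small_window: float = 1800.0
    nb_dispersion: float = 0.002
    gc_bias_amplitude: float = 0.3
    n_panel: int = 137
    tumor_fraction: float = 0.0
    segments: tuple[CNASegment, ...] = ()
    fragment_length_normal: tuple[float, float] = (167.0, 10.0)
    fragment_length_tumor: tuple[float, float] = (145.0, 12.0)
    fragment_length_range: tuple[int, int] = (50, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_small_windows <= 0 or self.n_small_windows % self.condense_factor:
            raise ValueError(
                "n_small_windows must be a positive multiple of condense_factor"
            )
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.mean_count_per_small_window <= 0 or self.small_window_bp <= 0:
            raise ValueError("means and window size must be positive")
        if self.n_panel < 2:
            raise ValueError("n_panel must be >= 2")
        self.segments = tuple(self.segments)
        n_cond = self.n_small_windows // self.condense_factor
        for seg in self.segments:
            if seg.end_window_index > n_cond:
                raise ValueError(
                    f"segment [{seg.start_window_index}, {seg.end_window_index}) "
                    f"exceeds {n_cond} condensed windows"
                )

    @property
    def n_condensed_windows(self) -> int:
        return self.n_small_windows // self.condense_factor

    def to_yaml(self, path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) and not isinstance(v[0], CNASegment) else v)
            for k, v in self.__dict__.items()
            if k != "segments"
        }
        d["segments"] = [
            [s.start_window_index, s.end_window_index, s.total_copy_number]
            for s in self.segments
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["segments"] = tuple(CNASegment(*s) for s in d.get("segments", []))
        for k in ("fragment_length_normal", "fragment_length_tumor", "fragment_length_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def gc_bias_curve(gc: np.ndarray, amplitude: float = 0.3) -> np.ndarray:
    """The simulator's multiplicative GC bias: a smooth unimodal bump.

    bias(gc) = 1 + amplitude * exp(-(gc - 0.45)^2 / (2 * 0.08^2)).  Peaked
    at mid-GC, as library preparation favors mid-GC fragments.  Exposed so
    tests can compare the pipeline's blind correction against the truth.
    """
    return 1.0 + amplitude * np.exp(-((np.asarray(gc) - 0.45) ** 2) / (2 * 0.08**2))


def _smooth_series(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """A smooth spatial process in [lo, hi]: Gaussian-kernel-smoothed noise."""
    raw = rng.standard_normal(n + 200)
    width = max(5, n // 60)
    kernel = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="same")[100 : 100 + n]
    span = smooth.max() - smooth.min()
    if span == 0:
        return np.full(n, (lo + hi) / 2)
    return lo + (hi - lo) * (smooth - smooth.min()) / span


def simulate_genome(config: SimulationConfig) -> WindowSet:
    """Build the synthetic window grid: equal pseudo-autosomes, smooth GC.

    Condensed groups are distributed near-evenly over up to 22
    pseudo-chromosomes so that every chromosome holds whole groups and the
    condensed window count is exactly n_small_windows / condense_factor.
    GC fractions follow a smooth spatial process in [0.3, 0.6];
    mappability in [0.8, 1.0].  Deterministic given the config seed.
    """
    n_groups = config.n_condensed_windows
    n_chrom = min(N_PSEUDO_AUTOSOMES, n_groups)
    base, extra = divmod(n_groups, n_chrom)
    chrom_sizes = {}
    for i in range(n_chrom):
        groups_here = base + (1 if i < extra else 0)
        chrom_sizes[f"chr{i + 1}"] = groups_here * config.condense_factor * config.small_window_bp
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11]))
    gc = _smooth_series(rng, config.n_small_windows, 0.3, 0.6)
    mappability = _smooth_series(rng, config.n_small_windows, 0.8, 1.0)
    return build_windows(
        chrom_sizes,
        small_window_bp=config.small_window_bp,
        condense_factor=config.condense_factor,
        gc=gc,
        mappability=mappability,
    )


def _copy_ratio_small(
    windows: WindowSet, config: SimulationConfig, tumor_fraction: float,
    segments: Sequence[CNASegment],
) -> np.ndarray:
    """Relative copy ratio per small window: (2(1-f) + c*f) / 2."""
    c = np.full(len(windows), 2.0)
    groups = windows.table["group"].to_numpy()
    for seg in segments:
        if seg.end_window_index > config.n_condensed_windows:
            raise ValueError("segment index out of range for this window set")
        in_seg = (groups >= seg.start_window_index) & (groups < seg.end_window_index)
        c[in_seg] = seg.total_copy_number
    return (2.0 * (1.0 - tumor_fraction) + c * tumor_fraction) / 2.0


def expected_counts(
    windows: WindowSet,
    config: SimulationConfig,
    tumor_fraction: float = 0.0,
    segments: Sequence[CNASegment] = (),
) -> np.ndarray:
    """Analytic expectation of simulate_counts, for oracle checks."""
    gc = windows.table["gc"].to_numpy()
    mp = windows.table["mappability"].to_numpy()
    ratio = _copy_ratio_small(windows, config, tumor_fraction, segments)
    return (
        config.mean_count_per_small_window
        * gc_bias_curve(gc, config.gc_bias_amplitude)
        * mp
        * ratio
    )


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mu + mu^2 * d (gamma-Poisson mixture)."""
    if dispersion == 0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    windows: WindowSet,
    config: SimulationConfig,
    tumor_fraction: float | None = None,
    segments: Sequence[CNASegment] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """One sample's small-window counts under the admixture model."""
    f = config.tumor_fraction if tumor_fraction is None else tumor_fraction
    if not 0.0 <= f <= 1.0:
        raise ValueError("tumor_fraction must lie in [0, 1]")
    segs = config.segments if segments is None else segments
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    mu = expected_counts(windows, config, f, segs)
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    return pd.Series(counts, index=windows.ids)


def simulate_panel(
    windows: WindowSet, config: SimulationConfig, n_panel: int | None = None
) -> pd.DataFrame:
    """Normal panel: n_panel independent tumor-free samples (f = 0)."""
    n = config.n_panel if n_panel is None else n_panel
    ss = np.random.SeedSequence([config.seed, 0x9A])
    children = ss.spawn(n)
    rows = {}
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        rows[f"panel_{i:03d}"] = simulate_counts(
            windows, config, tumor_fraction=0.0, segments=(), rng=rng
        )
    mat = pd.DataFrame(rows).T
    mat.index.name = "sample"
    return mat


def simulate_fragment_lengths(
    n: int,
    tumor_fraction: float,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Integer fragment lengths from the two-mode truncated Gaussian mixture."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must lie in [0, 1]")
    cfg = config or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lo, hi = cfg.fragment_length_range
    mu_n, sd_n = cfg.fragment_length_normal
    mu_t, sd_t = cfg.fragment_length_tumor
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        m = n - filled
        is_tumor = rng.random(m) < tumor_fraction
        draws = np.where(
            is_tumor,
            rng.normal(mu_t, sd_t, m),
            rng.normal(mu_n, sd_n, m),
        )
        keep = draws[(draws >= lo) & (draws <= hi)]
        out[filled : filled + len(keep)] = np.rint(keep).astype(np.int64)
        filled += len(keep)
    return out


@dataclass
class GroupSpec:
    """One cohort group: label, size, and how tumor fraction/segments arise.

    ``tumor_fraction`` is either a constant or a callable(rng) -> float;
    ``segments`` either a fixed sequence or a callable(rng) -> sequence.
    """

    label: str
    n_samples: int
    tumor_fraction: float | Callable[[np.random.Generator], float] = 0.0
    segments: Sequence[CNASegment] | Callable[[np.random.Generator], Sequence[CNASegment]] = ()


@dataclass
class Cohort:
    """Simulated cohort: counts, fragment lengths, and the generating truth."""

    counts: pd.DataFrame  # samples x small windows
    fragment_lengths: dict[str, np.ndarray]
    truth: pd.DataFrame  # sample, group, tumor_fraction, segments (repr string)


def random_segments(
    rng: np.random.Generator,
    n_condensed: int,
    n_segments: tuple[int, int] = (2, 6),
    length_windows: tuple[int, int] = (10, 60),
    copy_numbers: Sequence[float] = (0.0, 1.0, 3.0, 4.0),
) -> tuple[CNASegment, ...]:
    """Draw a random non-overlapping tumor segment profile."""
    k = int(rng.integers(n_segments[0], n_segments[1] + 1))
    segs: list[CNASegment] = []
    taken = np.zeros(n_condensed, dtype=bool)
    for _ in range(k * 10):
        if len(segs) >= k:
            break
        length = int(rng.integers(length_windows[0], min(length_windows[1], n_condensed) + 1))
        start = int(rng.integers(0, max(1, n_condensed - length)))
        if taken[start : start + length].any():
            continue
        taken[start : start + length] = True
        c = float(rng.choice(np.asarray(copy_numbers)))
        segs.append(CNASegment(start, start + length, c))
    return tuple(sorted(segs, key=lambda s: s.start_window_index))


def simulate_cohort(
    config: SimulationConfig,
    group_spec: Sequence[GroupSpec],
    windows: WindowSet | None = None,
    n_fragment_lengths: int = 2000,
) -> Cohort:
    """Simulate labelled groups of samples with per-sample persisted truth."""
    if not group_spec:
        raise ValueError("group_spec is empty")
    labels = [g.label for g in group_spec]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    for g in group_spec:
        if g.n_samples <= 0:
            raise ValueError(f"group {g.label!r} has non-positive sample count")
    if windows is None:
        windows = simulate_genome(config)
    ss = np.random.SeedSequence([config.seed, 0xC0407])
    total = sum(g.n_samples for g in group_spec)
    children = iter(ss.spawn(total))
    rows = {}
    lengths: dict[str, np.ndarray] = {}
    truth_rows = []
    for g in group_spec:
        for i in range(g.n_samples):
            rng = np.random.default_rng(next(children))
            f = g.tumor_fraction(rng) if callable(g.tumor_fraction) else g.tumor_fraction
            segs = g.segments(rng) if callable(g.segments) else g.segments
            name = f"{g.label}_{i:03d}"
            rows[name] = simulate_counts(windows, config, f, segs, rng=rng)
            lengths[name] = simulate_fragment_lengths(
                n_fragment_lengths, f, config=config, rng=rng
            )
            truth_rows.append(
                {
                    "sample": name,
                    "group": g.label,
                    "tumor_fraction": f,
                    "segments": ";".join(
                        f"{s.start_window_index}-{s.end_window_index}:{s.total_copy_number}"
                        for s in segs
                    ),
                }
            )
    counts = pd.DataFrame(rows).T
    counts.index.name = "sample"
    return Cohort(
        counts=counts,
        fragment_lengths=lengths,
        truth=pd.DataFrame(truth_rows).set_index("sample"),
    )
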
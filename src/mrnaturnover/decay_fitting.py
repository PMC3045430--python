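"""Half-life estimation from promoter-shutoff decay series.

After transcriptional shutoff an mRNA following first-order kinetics
decays as RA(t) = RA(0)*exp(-k_D*t), so ln(RA) is linear in time with
slope -k_D and half-life t1/2 = ln2/k_D.  Band intensities from the
blot are background-subtracted, normalized to the loading-control lane,
and referred to the time-0 sample; the regression uses only the initial
points over which log-linearity holds (late points flatten once the
signal approaches the detection floor or a stable sub-population).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class NorthernSeries:
    """One decay time course: band, local background, and loading lanes."""

    gene_id: str
    condition_label: str
    sample_times: np.ndarray  # minutes after repression, increasing, first = 0
    band_signal: np.ndarray
    background_signal: np.ndarray
    loading_signal: np.ndarray
    replicate_id: int | None = None

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.band_signal = np.asarray(self.band_signal, dtype=float)
        self.background_signal = np.asarray(self.background_signal, dtype=float)
        self.loading_signal = np.asarray(self.loading_signal, dtype=float)
        n = self.sample_times.size
        for name, v in (
            ("band_signal", self.band_signal),
            ("background_signal", self.background_signal),
            ("loading_signal", self.loading_signal),
        ):
            if v.size != n:
                raise ValueError(f"{name} length {v.size} != {n} sample times")
        if self.sample_times[0] != 0 or not np.all(np.diff(self.sample_times) > 0):
            raise ValueError("sample_times must increase from 0")
        if np.any(self.loading_signal <= 0):
            raise ValueError("loading_signal must be positive")
        if np.any(self.band_signal < 0):
            raise ValueError("band_signal must be non-negative")


@dataclass(frozen=True)
class HalfLifeEstimate:
    t_half: float  # minutes; NaN when the fit failed
    kd: float  # 1/min, ln2 / t_half
    fit_window: int  # number of initial points used
    r_squared: float
    n_replicates: int = 1
    flags: tuple[str, ...] = ()


def correct_signal(
    s: NorthernSeries, floor_epsilon: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtract, loading-normalize, and refer to time 0.

    Returns (relative_abundance, floored_mask).  Corrected values that go
    non-positive (background exceeding the band at late, faint lanes) are
    floored at ``floor_epsilon`` times the time-0 value and flagged;
    flagged points are excluded from fit-window selection.
    """
    corrected = (s.band_signal - s.background_signal) / s.loading_signal
    if corrected[0] <= 0:
        raise ValueError(
            f"{s.gene_id}: corrected signal at time 0 is non-positive"
        )
    rel = corrected / corrected[0]
    floored = rel <= floor_epsilon
    rel = np.where(floored, floor_epsilon, rel)
    return rel, floored


def fit_first_order(
    values: np.ndarray,
    times: np.ndarray,
    r2_threshold: float = 0.95,
    usable: np.ndarray | None = None,
) -> HalfLifeEstimate:
    """Log-linear fit of the initial decay, longest-linear-prefix window.

    Among prefixes of length >= 3 (skipping points masked out by
    ``usable``), the longest one with r^2 >= ``r2_threshold`` is fitted by
    ordinary least squares of ln(value) on time; if none qualifies the
    3-point prefix is used and flagged ``low_r2``.  A non-negative slope
    means no measurable decay and is flagged ``fit_failed``.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if usable is None:
        usable = np.ones(values.shape, dtype=bool)
    keep = usable & (values > 0)
    v, t = values[keep], times[keep]
    if v.size < 3:
        raise ValueError(f"need >= 3 usable points, have {v.size}")
    logv = np.log(v)

    best_n, best_fit = None, None
    for n in range(3, v.size + 1):
        slope, intercept, r, _, _ = stats.linregress(t[:n], logv[:n])
        if r * r >= r2_threshold:
            best_n, best_fit = n, (slope, r * r)
    flags: list[str] = []
    if best_n is None:
        slope, _, r, _, _ = stats.linregress(t[:3], logv[:3])
        best_n, best_fit = 3, (slope, r * r)
        flags.append("low_r2")
    slope, r2 = best_fit
    if slope >= 0:
        return HalfLifeEstimate(
            math.nan, math.nan, best_n, r2, flags=tuple(flags + ["fit_failed"])
        )
    kd = -slope
    return HalfLifeEstimate(math.log(2) / kd, kd, best_n, r2, flags=tuple(flags))


def estimate_half_life(
    series: list[NorthernSeries],
    r2_threshold: float = 0.95,
    floor_epsilon: float = 1e-6,
) -> tuple[HalfLifeEstimate, float, list[HalfLifeEstimate]]:
    """Fit each replicate separately; report mean t1/2 and SD across them.

    Returns (pooled estimate carrying the mean t1/2, SD of t1/2, per-replicate
    estimates).  Replicates whose fit failed are excluded from the mean.
    """
    fits = []
    for s in series:
        rel, floored = correct_signal(s, floor_epsilon)
        fits.append(
            fit_first_order(rel, s.sample_times, r2_threshold, usable=~floored)
        )
    good = [f for f in fits if math.isfinite(f.t_half)]
    if not good:
        raise ValueError("all replicate fits failed")
    t_halves = np.array([f.t_half for f in good])
    mean_th = float(np.mean(t_halves))
    sd = float(np.std(t_halves, ddof=1)) if len(good) > 1 else math.nan
    pooled = HalfLifeEstimate(
        mean_th,
        math.log(2) / mean_th,
        int(round(np.mean([f.fit_window for f in good]))),
        float(np.mean([f.r_squared for f in good])),
        n_replicates=len(good),
    )
    return pooled, sd, fits


def _kruskal_h(groups: list[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H statistic."""
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if tie_term == 0:  # all values identical
        return 0.0
    return h / tie_term


def compare_halflives(
    groups: list[list[float]], exact_max_n: int = 12
) -> tuple[float, float]:
    """Kruskal-Wallis comparison of half-life groups across conditions.

    Small samples (total n <= ``exact_max_n``) get an exact permutation
    p-value by full enumeration of group assignments; larger samples use
    the chi-square approximation.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    h_obs = _kruskal_h(arrs)
    n_total = sum(a.size for a in arrs)
    if np.ptp(np.concatenate(arrs)) == 0:
        return 0.0, 1.0
    if n_total <= exact_max_n:
        sizes = [a.size for a in arrs]
        pooled = np.concatenate(arrs)
        idx = range(n_total)
        count = total = 0
        # enumerate distinct assignments of observations to the groups
        for combo in _group_assignments(idx, sizes):
            perm_groups = [pooled[list(ix)] for ix in combo]
            if _kruskal_h(perm_groups) >= h_obs - 1e-12:
                count += 1
            total += 1
        return h_obs, count / total
    p = stats.chi2.sf(h_obs, df=len(arrs) - 1)
    return h_obs, float(p)


def _group_assignments(idx, sizes):
    """Yield all distinct splits of ``idx`` into groups of the given sizes."""
    idx = tuple(idx)
    if len(sizes) == 1:
        yield (idx,)
        return
    for first in itertools.combinations(idx, sizes[0]):
        rest = tuple(i for i in idx if i not in first)
        for sub in _group_assignments(rest, sizes[1:]):
            yield (first,) + sub
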
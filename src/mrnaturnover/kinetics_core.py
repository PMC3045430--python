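"""Non-steady-state first-order mRNA turnover kinetics.

The central model is the mass balance of a single mRNA species,

    dRA/dt = TR(t) - k_D * RA(t),

with the transcription rate TR(t) varying linearly between consecutive
measurement times and the decay constant k_D held constant within each
interval.  Under those assumptions the balance has a closed-form solution
(:func:`forward_ra`), which can be inverted for the interval-mean k_D by
bisection (:func:`solve_kd_interval`): for fixed endpoints the predicted
RA at the end of the interval is strictly decreasing in k_D, so the root
is unique whenever it exists.

Derivation of the closed form.  Write TR(s) = TR1 + m*s with
m = (TR2 - TR1)/dt for s in [0, dt].  The integrating-factor solution is

    RA(dt) = RA1*exp(-k*dt)
           + TR1 * (1 - exp(-k*dt)) / k
           + m   * (k*dt - 1 + exp(-k*dt)) / k**2.

Both non-homogeneous terms are smooth at k -> 0 (their limits give the
trapezoidal integral of TR); a short series branch is used for tiny k*dt
to avoid cancellation.

The steady-state decay constant at time 0 is the ratio TR0/RA0, because a
constant RA forces TR = k_D * RA.  The "theoretical" RA trajectory keeps
this time-0 k_D frozen and propagates the measured TR forward; deviation
of the measured RA from it isolates the contribution of regulated mRNA
stability from that of transcription.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

GAS_CONSTANT_KCAL = 1.987e-3
"""Gas constant in kcal/(mol*K)."""

#: k*dt below which the series branch of the forward solution is used;
#: the exact expressions lose ~eps/x^2 relative accuracy to cancellation
#: there, while the truncated series is accurate to ~x^5.
_SMALL_KDT = 1e-2


class KineticsError(ValueError):
    """Raised on physically invalid kinetics inputs."""


@dataclass(frozen=True)
class TimeGrid:
    """Sampling times in minutes; the first point is the pre-shift steady state."""

    times: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 3:
            raise KineticsError("time grid needs at least 3 points")
        if t[0] != 0.0:
            raise KineticsError("time grid must start at 0 (steady-state sample)")
        if not np.all(np.diff(t) > 0):
            raise KineticsError("time grid must be strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dts(self) -> np.ndarray:
        """Interval widths, minutes."""
        return np.diff(np.asarray(self.times))

    @property
    def midpoints(self) -> np.ndarray:
        """Midpoints of consecutive intervals; interval k_D estimates live here."""
        t = np.asarray(self.times)
        return (t[:-1] + t[1:]) / 2.0


#: Default sampling design of the heat-shock time course (minutes).
DEFAULT_GRID = TimeGrid((0.0, 4.0, 11.0, 16.0, 26.0, 40.0))


@dataclass
class GeneKinetics:
    """Per-gene TR (units/min) and RA (units) vectors on a shared grid."""

    gene_id: str
    grid: TimeGrid
    tr: np.ndarray
    ra: np.ndarray

    def __post_init__(self) -> None:
        self.tr = np.asarray(self.tr, dtype=float)
        self.ra = np.asarray(self.ra, dtype=float)
        n = len(self.grid)
        if self.tr.shape != (n,) or self.ra.shape != (n,):
            raise KineticsError(
                f"gene {self.gene_id}: TR/RA length must match grid length {n}"
            )
        if not (np.all(np.isfinite(self.tr)) and np.all(np.isfinite(self.ra))):
            raise KineticsError(f"gene {self.gene_id}: non-finite TR/RA values")
        if np.any(self.tr < 0) or np.any(self.ra < 0):
            raise KineticsError(f"gene {self.gene_id}: negative TR/RA values")


@dataclass(frozen=True)
class IntervalSolveResult:
    """Interval-mean decay constant assigned to the interval midpoint."""

    t_mid: float
    kd: float
    kd_relative: float  # kd / kd0; NaN when kd0 == 0
    flag: str  # ok | at_zero_bound | no_positive_root | bracket_expanded


@dataclass
class DecayProfile:
    gene_id: str
    kd0: float
    intervals: list[IntervalSolveResult]


@dataclass(frozen=True)
class TemperatureCorrection:
    """Arrhenius fold-change of a catalytic constant between two temperatures."""

    ea_kcal_mol: float
    t1_kelvin: float
    t2_kelvin: float
    factor: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "factor",
            temperature_factor(self.ea_kcal_mol, self.t1_kelvin, self.t2_kelvin),
        )


@dataclass(frozen=True)
class StabilityCall:
    """Stability classification from measured vs. frozen-k_D theoretical RA."""

    gene_id: str
    pearson_r: float
    mean_log_ratio: float  # mean log2(RA / RA_theo) over post-shift points
    label: str  # stabilized | destabilized | unchanged | undefined


def steady_state_kd(tr0: float, ra0: float) -> float:
    """Steady-state decay constant k_D0 = TR0/RA0 at the pre-shift sample."""
    if not (math.isfinite(tr0) and math.isfinite(ra0)):
        raise KineticsError("non-finite TR0/RA0")
    if ra0 <= 0:
        raise KineticsError(f"RA0 must be positive, got {ra0}")
    if tr0 < 0:
        raise KineticsError(f"TR0 must be non-negative, got {tr0}")
    if tr0 == 0:
        warnings.warn("TR0 = 0 gives kd0 = 0; gene cannot be inverted downstream")
        return 0.0
    return tr0 / ra0


def forward_ra(ra1: float, tr1: float, tr2: float, kd: float, dt: float) -> float:
    """Exact RA at t1+dt for dRA/dt = TR(t) - kd*RA with TR linear TR1 -> TR2.

    Continuous at kd -> 0, where it reduces to RA1 plus the trapezoidal
    integral of TR.
    """
    if dt <= 0:
        raise KineticsError(f"dt must be positive, got {dt}")
    if kd < 0:
        raise KineticsError(f"kd must be non-negative, got {kd}")
    for v in (ra1, tr1, tr2, kd, dt):
        if not math.isfinite(v):
            raise KineticsError("non-finite input to forward_ra")
    m = (tr2 - tr1) / dt
    x = kd * dt
    if x < _SMALL_KDT:
        # series of (1-e^-x)/x and (x-1+e^-x)/x^2, truncation error ~x^5
        x2, x3, x4 = x * x, x * x * x, x * x * x * x
        g1 = 1.0 - x / 2.0 + x2 / 6.0 - x3 / 24.0 + x4 / 120.0
        g2 = 0.5 - x / 6.0 + x2 / 24.0 - x3 / 120.0 + x4 / 720.0
        return ra1 * math.exp(-x) + tr1 * dt * g1 + m * dt * dt * g2
    e = math.exp(-x)
    return ra1 * e + tr1 * (1.0 - e) / kd + m * (x - 1.0 + e) / (kd * kd)


def _zero_decay_bound(ra1: float, tr1: float, tr2: float, dt: float) -> float:
    """Largest reachable RA2: no decay at all, RA1 plus trapezoid of TR."""
    return ra1 + (tr1 + tr2) * dt / 2.0


def solve_kd_interval(
    ra1: float,
    ra2: float,
    tr1: float,
    tr2: float,
    dt: float,
    t_mid: float = math.nan,
    kd0: float = math.nan,
    kd_max: float = 10.0,
    kd_tol: float = 1e-12,
    resid_rtol: float = 1e-8,
) -> IntervalSolveResult:
    """Invert the forward solution for the interval-mean k_D by bisection.

    The predicted RA2 is strictly decreasing in k_D, so ``[0, kd_max]`` is a
    valid bracket whenever the observed RA2 lies below the zero-decay bound
    and above the prediction at ``kd_max``; the bracket auto-expands tenfold
    (flagged) if the upper prediction still exceeds RA2.  An observed RA2 at
    or above the zero-decay bound is unreachable for any k_D >= 0 and is
    reported as k_D = 0 with flag ``no_positive_root`` (``at_zero_bound``
    when within the residual tolerance of the bound).
    """
    for v in (ra1, ra2, tr1, tr2, dt):
        if not math.isfinite(v):
            raise KineticsError("non-finite input to solve_kd_interval")
    if ra1 <= 0:
        raise KineticsError(f"RA1 must be positive, got {ra1}")
    if dt <= 0:
        raise KineticsError(f"dt must be positive, got {dt}")
    if tr1 < 0 or tr2 < 0:
        raise KineticsError("TR values must be non-negative")

    def rel(kd: float) -> float:
        return kd / kd0 if kd0 and kd0 > 0 else math.nan

    bound = _zero_decay_bound(ra1, tr1, tr2, dt)
    if ra2 >= bound:
        flag = "at_zero_bound" if abs(ra2 - bound) <= resid_rtol * max(ra2, 1e-300) \
            else "no_positive_root"
        return IntervalSolveResult(t_mid, 0.0, rel(0.0), flag)

    flag = "ok"
    hi = kd_max
    while forward_ra(ra1, tr1, tr2, hi, dt) > ra2:
        hi *= 10.0
        flag = "bracket_expanded"
        if hi > 1e3:
            # RA2 below even the fastest plausible decay: pin at the cap
            return IntervalSolveResult(t_mid, 1e3, rel(1e3), "bracket_expanded")
    lo = 0.0
    # bisect to a tight absolute tolerance on kd; the residual tolerance is
    # only used to classify boundary cases, since an early residual exit
    # would limit relative accuracy for slowly decaying transcripts
    while hi - lo > kd_tol:
        mid = (lo + hi) / 2.0
        if forward_ra(ra1, tr1, tr2, mid, dt) > ra2:
            lo = mid
        else:
            hi = mid
    kd = (lo + hi) / 2.0
    return IntervalSolveResult(t_mid, kd, rel(kd), flag)


def decay_profile(g: GeneKinetics, kd_max: float = 10.0) -> DecayProfile:
    """Per-interval k_D estimates for one gene, midpoint-assigned.

    kd0 comes from the steady-state ratio at time 0; each consecutive grid
    pair is inverted independently and the interval-mean k_D assigned to
    the midpoint, relative values as kd/kd0.
    """
    if np.any(g.ra <= 0):
        raise KineticsError(f"gene {g.gene_id}: RA must be strictly positive")
    kd0 = steady_state_kd(g.tr[0], g.ra[0])
    t = np.asarray(g.grid.times)
    mids = g.grid.midpoints
    intervals = [
        solve_kd_interval(
            g.ra[i], g.ra[i + 1], g.tr[i], g.tr[i + 1],
            t[i + 1] - t[i], t_mid=mids[i], kd0=kd0, kd_max=kd_max,
        )
        for i in range(len(t) - 1)
    ]
    return DecayProfile(g.gene_id, kd0, intervals)


def theoretical_ra(g: GeneKinetics, kd0: float | None = None) -> np.ndarray:
    """RA trajectory predicted from measured TR with the time-0 k_D frozen.

    Starts from the measured RA at time 0 and propagates interval by
    interval with :func:`forward_ra`; any departure of the measured RA from
    this curve indicates a change in mRNA stability after the shift.
    """
    if kd0 is None:
        if g.ra[0] <= 0:
            raise KineticsError(f"gene {g.gene_id}: RA(t0) must be positive")
        kd0 = steady_state_kd(g.tr[0], g.ra[0])
    t = np.asarray(g.grid.times)
    out = np.empty(len(t))
    out[0] = g.ra[0]
    for i in range(len(t) - 1):
        out[i + 1] = forward_ra(out[i], g.tr[i], g.tr[i + 1], kd0, t[i + 1] - t[i])
    return out


def temperature_factor(ea_kcal_mol: float, t1_kelvin: float, t2_kelvin: float) -> float:
    """Arrhenius fold-change exp[(Ea/R)(1/T1 - 1/T2)] of a rate constant."""
    if t1_kelvin <= 0 or t2_kelvin <= 0:
        raise KineticsError("temperatures must be positive kelvin")
    return math.exp(
        (ea_kcal_mol / GAS_CONSTANT_KCAL) * (1.0 / t1_kelvin - 1.0 / t2_kelvin)
    )


@dataclass
class CorrectedKinetics(GeneKinetics):
    """GeneKinetics whose post-shift TR has already been scaled; guards re-application."""

    tr_correction_applied: float = 1.0


def apply_tr_correction(g: GeneKinetics, factor: float) -> CorrectedKinetics:
    """Scale post-t0 TR by a temperature factor (time-0 TR untouched).

    Run-on incorporation measures polymerase density; after a temperature
    upshift the elongation speed rises, so the post-shift synthesis rates
    must be multiplied by the Arrhenius fold.  Applying the correction
    twice is an error (provenance is recorded on the returned object).
    """
    if factor <= 0:
        raise KineticsError(f"correction factor must be positive, got {factor}")
    if getattr(g, "tr_correction_applied", 1.0) != 1.0:
        raise KineticsError(
            f"gene {g.gene_id}: TR correction already applied "
            f"(factor {g.tr_correction_applied})"
        )
    tr = g.tr.copy()
    tr[1:] *= factor
    return CorrectedKinetics(
        g.gene_id, g.grid, tr, g.ra.copy(), tr_correction_applied=factor
    )


def classify_stability(
    g: GeneKinetics, ra_theo: np.ndarray, threshold: float = 0.3
) -> StabilityCall:
    """Call a gene stabilized/destabilized from measured vs. theoretical RA.

    Uses post-shift points only.  mean_log_ratio is the mean log2 of
    measured over theoretical RA: positive means the mRNA outlived the
    frozen-k_D prediction (stabilized).  The Pearson correlation between
    the two curves is reported as a goodness-of-prediction statistic.
    """
    ra_theo = np.asarray(ra_theo, dtype=float)
    ra = g.ra[1:]
    theo = ra_theo[1:]
    if np.any(theo <= 0) or np.any(ra <= 0):
        return StabilityCall(g.gene_id, math.nan, math.nan, "undefined")
    mlr = float(np.mean(np.log2(ra / theo)))
    if np.std(ra) == 0 or np.std(theo) == 0:
        # flat curves: perfectly predicted when equal, uninformative otherwise
        r = 1.0 if np.allclose(ra, theo) else math.nan
    else:
        r = float(np.corrcoef(ra, theo)[0, 1])
    if mlr > threshold:
        label = "stabilized"
    elif mlr < -threshold:
        label = "destabilized"
    else:
        label = "unchanged"
    return StabilityCall(g.gene_id, r, mlr, label)


def global_summaries(genes: list[GeneKinetics]) -> dict[str, np.ndarray]:
    """Whole-transcriptome TR and RA curves relative to time 0.

    Sums TR and RA over genes at each time and divides by the time-0 sum,
    the total-transcription / total-mRNA view of the response.
    """
    if not genes:
        raise KineticsError("no genes to summarize")
    tr = np.sum([g.tr for g in genes], axis=0)
    ra = np.sum([g.ra for g in genes], axis=0)
    if tr[0] == 0 or ra[0] == 0:
        raise KineticsError("time-0 total is zero; relative curves undefined")
    return {
        "times": np.asarray(genes[0].grid.times),
        "total_tr_relative": tr / tr[0],
        "total_ra_relative": ra / ra[0],
    }
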
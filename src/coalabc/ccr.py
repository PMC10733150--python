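"""Relative cross-coalescence rate (rCCR) curves from true genealogies.

The rCCR between populations A and B is 2·λ_cross / (λ_within_A +
λ_within_B), where λ are per-time-bin coalescence hazards of haplotype
pairs.  A value of 1 indicates a single ancestral population, 0 complete
isolation; the time at which the curve crosses 0.5 is a common split-time
heuristic and 0.9 a proxy for the onset of structure.  Hazards here are
estimated directly from simulated genealogies — pair coalescence times are
exact — so the curves exercise the crossing heuristics themselves, free of
sequence-based inference error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .coalsim import SampleConfig, pair_coalescence_times, simulate_genealogies
from .demography import DemographicModel
from .errors import InputError

DEFAULT_BINS = np.logspace(1, 5, 33)  # 32 log-spaced bins, 10..1e5 generations
MIN_PAIRS_PER_BIN = 20


@dataclass
class RccrCurve:
    bins: np.ndarray          # edges, length n_bins + 1, ascending
    lam_a: np.ndarray         # within-A hazard per bin
    lam_b: np.ndarray         # within-B hazard per bin
    lam_cross: np.ndarray     # cross hazard per bin
    rccr: np.ndarray          # 2*cross / (a + b); NaN where undefined
    n_pairs: np.ndarray       # pairs still exposed at each bin start (cross)

    @property
    def midpoints(self) -> np.ndarray:
        return np.sqrt(self.bins[:-1] * self.bins[1:])  # geometric mid (log bins)

    def smoothed(self) -> np.ndarray:
        """rCCR monotonized to be non-decreasing toward the past."""
        ok = np.isfinite(self.rccr)
        if ok.sum() < 2:
            return self.rccr.copy()
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        out = np.full_like(self.rccr, np.nan)
        out[ok] = iso.fit_transform(self.midpoints[ok], self.rccr[ok])
        return out


def _bin_hazard(times: np.ndarray, bins: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin hazard: coalescences in bin / total pair exposure time in bin."""
    lo, hi = bins[:-1], bins[1:]
    events = np.histogram(times, bins=bins)[0].astype(float)
    # exposure of a pair with coalescence time t in bin [lo, hi): min(t, hi) - lo, if t > lo
    exposure = np.empty(len(lo))
    alive = np.empty(len(lo))
    for k in range(len(lo)):
        contrib = np.clip(np.minimum(times, hi[k]) - lo[k], 0.0, None)
        exposure[k] = contrib.sum()
        alive[k] = np.count_nonzero(times > lo[k])
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(exposure > 0, events / np.maximum(exposure, 1e-300), np.nan)
    return lam, exposure, alive


def hazard_curves(within_a: np.ndarray, within_b: np.ndarray, cross: np.ndarray,
                  bins: np.ndarray | None = None,
                  min_pairs: int = MIN_PAIRS_PER_BIN) -> RccrCurve:
    """Assemble an :class:`RccrCurve` from pair coalescence times."""
    for arr in (within_a, within_b, cross):
        if len(arr) == 0:
            raise InputError("each pair-time list must be non-empty")
    bins = np.asarray(DEFAULT_BINS if bins is None else bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise InputError("bins must be strictly ascending")
    la, _, na = _bin_hazard(np.asarray(within_a, float), bins)
    lb, _, nb = _bin_hazard(np.asarray(within_b, float), bins)
    lc, _, nc = _bin_hazard(np.asarray(cross, float), bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = la + lb
        rccr = 2.0 * lc / denom
    ok = np.isfinite(rccr) & (na >= min_pairs) & (nb >= min_pairs) & (nc >= min_pairs) \
        & (denom > 0)
    rccr = np.where(ok, rccr, np.nan)
    return RccrCurve(bins=bins, lam_a=la, lam_b=lb, lam_cross=lc,
                     rccr=rccr, n_pairs=nc)


def rccr_between(model: DemographicModel, popA: str, popB: str,
                 n_pairs: int = 200, n_loci: int = 100,
                 bins: np.ndarray | None = None, seed: int = 1,
                 diploids_per_pop: int = 10) -> RccrCurve:
    """Simulate genealogies under ``model`` and build the rCCR curve for a
    population pair (``n_pairs`` subsampled pairs per class per locus)."""
    pops = {popA: diploids_per_pop} if popA == popB else \
        {popA: diploids_per_pop, popB: diploids_per_pop}
    samples = SampleConfig(diploids=pops)
    trees = simulate_genealogies(model, samples, n_loci=n_loci, seed=seed)
    if popA == popB:
        t = pair_coalescence_times(trees, popA, popA,
                                   max_pairs_per_locus=n_pairs, seed=seed + 1)
        return hazard_curves(t, t, t, bins=bins)
    wa = pair_coalescence_times(trees, popA, popA,
                                max_pairs_per_locus=n_pairs, seed=seed + 1)
    wb = pair_coalescence_times(trees, popB, popB,
                                max_pairs_per_locus=n_pairs, seed=seed + 2)
    cr = pair_coalescence_times(trees, popA, popB,
                                max_pairs_per_locus=n_pairs, seed=seed + 3)
    return hazard_curves(wa, wb, cr, bins=bins)


def crossing_time(curve: RccrCurve, level: float = 0.5,
                  smooth: bool = True) -> float:
    """Time (generations) at which the curve crosses ``level``.

    The (optionally isotonic-smoothed) curve is scanned from the oldest
    populated bin toward the present; the crossing is linearly interpolated
    between the first adjacent populated bin pair straddling the level.
    Returns NaN when the level is never crossed.
    """
    y = curve.smoothed() if smooth else curve.rccr
    x = curve.midpoints
    ok = np.isfinite(y)
    if ok.sum() < 2:
        raise InputError("need at least 2 populated bins")
    xs, ys = x[ok], y[ok]
    for k in range(len(xs) - 1, 0, -1):   # oldest -> youngest
        y_old, y_young = ys[k], ys[k - 1]
        if (y_young - level) * (y_old - level) <= 0 and y_old != y_young:
            frac = (level - y_young) / (y_old - y_young)
            return float(xs[k - 1] + frac * (xs[k] - xs[k - 1]))
        if y_young == level == y_old:
            return float(xs[k - 1])
    return float("nan")
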
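"""Safe-range ("KE-LS") prediction of trajectory deviations.

Given a modelled kinetic-energy landscape per submovement and the subject's
effective (central 98%) range of produced hand deviations, the KE-LS
predictor finds the longest stretch of deviations over which the landscape's
absolute slope stays below a per-submovement threshold — the SD of the
modelled KE within the effective range — and predicts the median of that
stretch.  Two competitors are provided: the deviation of minimum modelled KE
and the zero-deviation (straight hand path) prediction.  A resampled-RMSE
procedure compares the three against observed late-session deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trajectory_synthesis import KELandscape

__all__ = [
    "EffectiveRange",
    "PredictionSet",
    "NoQualifyingLevelError",
    "effective_deviation_range",
    "kels_threshold",
    "kels_predict",
    "minke_predict",
    "build_prediction_set",
    "compare_predictions",
    "predicted_vs_observed_change",
]


class NoQualifyingLevelError(ValueError):
    """Every landscape derivative is at or above the threshold."""


@dataclass(frozen=True)
class EffectiveRange:
    """Central-coverage quantile range of a subject's pooled hand deviations."""

    lo: float
    hi: float
    coverage: float = 0.98

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("lo must not exceed hi")


@dataclass(frozen=True)
class PredictionSet:
    """Per-submovement predictions of the three approaches."""

    submovement_id: str
    kels_pred: float
    safe_range: tuple[float, float]
    minke_pred: float
    zero_pred: float
    threshold_used: float

    def __post_init__(self) -> None:
        lo, hi = self.safe_range
        if not (lo - 1e-12 <= self.kels_pred <= hi + 1e-12):
            raise ValueError("kels_pred must lie inside safe_range")
        if self.zero_pred != 0.0:
            raise ValueError("zero_pred is the straight hand path: always 0")


def effective_deviation_range(values, coverage: float = 0.98) -> EffectiveRange:
    """Empirical central-``coverage`` quantile range of pooled deviations."""
    values = np.asarray(values, dtype=float)
    if values.size < 100:
        raise ValueError(f"need >= 100 deviations, got {values.size}")
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    tail = (1.0 - coverage) / 2.0
    lo, hi = np.quantile(values, [tail, 1.0 - tail])
    if lo == hi:
        warnings.warn("degenerate zero-width effective range", RuntimeWarning)
    return EffectiveRange(lo=float(lo), hi=float(hi), coverage=coverage)


def _in_range_mask(landscape: KELandscape, erange: EffectiveRange) -> np.ndarray:
    return (landscape.levels >= erange.lo) & (landscape.levels <= erange.hi)


def kels_threshold(
    landscape: KELandscape, erange: EffectiveRange, ddof: int = 0
) -> float:
    """Slope threshold: SD of modelled KE inside the effective range.

    Population SD by default (``ddof=0``); the sample form is available via
    ``ddof=1``.  Used directly as the bound on |dKE/d(deviation)|.
    """
    mask = _in_range_mask(landscape, erange)
    if mask.sum() < 2:
        raise ValueError("effective range overlaps fewer than 2 grid levels")
    return float(np.std(landscape.mean_ke[mask], ddof=ddof))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of consecutive True runs."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def kels_predict(
    landscape: KELandscape, threshold: float, erange: EffectiveRange
) -> tuple[tuple[float, float], float]:
    """Safe range and KE-LS prediction for one landscape.

    The unsigned slope |dKE/d(deviation)| is estimated by central differences
    on the grid (one-sided at the edges), restricted to the effective range.
    The safe range is the longest contiguous run of grid levels whose slope is
    strictly below ``threshold``; ties go first to the run with the lower mean
    KE, then to the run whose median level is nearer 0.  The prediction is the
    run's median grid level (lower-middle for even-length runs, so it stays on
    the grid).

    Returns ``((lo, hi), kels_pred)``.
    """
    deriv = np.abs(np.gradient(landscape.mean_ke, landscape.levels))
    mask = _in_range_mask(landscape, erange)
    if not mask.any():
        raise ValueError("effective range does not overlap the landscape grid")
    below = mask & (deriv < threshold)
    runs = _runs(below)
    if not runs:
        raise NoQualifyingLevelError(
            "every in-range derivative is at or above the threshold"
        )

    def median_level(run: tuple[int, int]) -> float:
        i0, i1 = run
        return float(landscape.levels[i0 + (i1 - i0) // 2])

    def key(run: tuple[int, int]):
        i0, i1 = run
        length = i1 - i0 + 1
        mean_ke = float(np.mean(landscape.mean_ke[i0 : i1 + 1]))
        return (-length, mean_ke, abs(median_level(run)))

    best = min(runs, key=key)
    lo = float(landscape.levels[best[0]])
    hi = float(landscape.levels[best[1]])
    return (lo, hi), median_level(best)


def minke_predict(landscape: KELandscape) -> float:
    """Deviation of minimum modelled KE; ties prefer small |deviation|, then
    the negative side."""
    mean_ke = landscape.mean_ke
    candidates = np.flatnonzero(mean_ke == mean_ke.min())
    levels = landscape.levels[candidates]
    order = np.lexsort((levels, np.abs(levels)))  # |level| first, negative wins ties
    return float(levels[order[0]])


def build_prediction_set(
    landscape: KELandscape, erange: EffectiveRange, ddof: int = 0
) -> PredictionSet:
    """All three predictions for one submovement's landscape."""
    threshold = kels_threshold(landscape, erange, ddof=ddof)
    safe_range, kels = kels_predict(landscape, threshold, erange)
    return PredictionSet(
        submovement_id=landscape.submovement_id,
        kels_pred=kels,
        safe_range=safe_range,
        minke_pred=minke_predict(landscape),
        zero_pred=0.0,
        threshold_used=threshold,
    )


def compare_predictions(
    predictions: dict[str, np.ndarray],
    observed: np.ndarray,
    n_folds: int = 5,
    n_repeats: int = 20,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Resampled RMSE of each prediction method against observed deviations.

    Each repeat randomly partitions the submovements into ``n_folds``
    near-equal folds (the same partition for every method) and computes the
    RMSE within each fold, yielding ``n_folds * n_repeats`` values per method.
    """
    observed = np.asarray(observed, dtype=float)
    n = observed.size
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} submovements, got {n}")
    preds = {m: np.asarray(p, dtype=float) for m, p in predictions.items()}
    for m, p in preds.items():
        if p.size != n:
            raise ValueError(f"method {m!r} has {p.size} predictions for {n} observations")
    rng = rng if rng is not None else np.random.default_rng(0)
    out = {m: [] for m in preds}
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        for fold in np.array_split(perm, n_folds):
            for m, p in preds.items():
                out[m].append(float(np.sqrt(np.mean((p[fold] - observed[fold]) ** 2))))
    return {m: np.asarray(v) for m, v in out.items()}


def predicted_vs_observed_change(
    early_medians: np.ndarray,
    kels_preds: np.ndarray,
    observed_changes: np.ndarray,
) -> tuple[float, float]:
    """Correlation of predicted against observed deviation changes.

    The predicted change for a submovement is ``kels_pred - early_median``
    (how far the prediction sits from where behaviour started); observed
    changes are late-minus-early summaries from the data.  Returns
    ``(pearson_r, slope)`` with the slope from the OLS fit of observed on
    predicted.
    """
    pred = np.asarray(kels_preds, dtype=float) - np.asarray(early_medians, dtype=float)
    obs = np.asarray(observed_changes, dtype=float)
    if pred.size != obs.size or pred.size < 3:
        raise ValueError("need >= 3 aligned submovements")
    if np.ptp(pred) == 0.0 or np.ptp(obs) == 0.0:
        raise ValueError("degenerate variance: changes are constant")
    res = stats.linregress(pred, obs)
    return float(res.rvalue), float(res.slope)
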
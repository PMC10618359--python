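"""Gray-level thresholding: Otsu's criterion and its osprey-optimized variant.

Dried-mushroom photographs show a dark object on a near-white background, so a
single global threshold on the 256-bin gray histogram separates foreground from
background.  Three routes to that threshold are provided:

* a fixed user-supplied threshold (``apply_threshold`` alone),
* exhaustive Otsu — maximize the between-class variance over all 256 levels,
* OOA-Otsu — the osprey optimization algorithm (OOA), a two-phase population
  metaheuristic, searching the same objective with far fewer than 256 distinct
  objective evaluations.

All objectives are defined on :class:`Histogram256`; the OOA works on a
continuous position in [0, 255] whose fitness is the *negated* between-class
variance of the rounded integer level (the criterion is inverted so the
optimizer minimizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Histogram256",
    "ThresholdResult",
    "OOAConfig",
    "OOAResult",
    "gray_histogram",
    "between_class_variance",
    "otsu_exhaustive",
    "ooa_optimize",
    "ooa_otsu_threshold",
    "apply_threshold",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Histogram256:
    """256-bin gray-level histogram, the domain of every threshold objective.

    Attributes
    ----------
    counts : numpy.ndarray
        Integer pixel count per gray level, length exactly 256.
    total : int
        Sum of counts = number of pixels of the source image.
    """

    counts: np.ndarray
    total: int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,):
            raise ValueError(f"histogram must have 256 bins, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("histogram counts must be non-negative")
        if int(counts.sum()) != self.total:
            raise ValueError("total does not equal sum of counts")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a threshold search.

    ``objective_value`` is the between-class variance at ``threshold`` in
    squared gray-level units; ``objective_evaluations`` counts *distinct*
    objective evaluations performed by the search.  ``degenerate`` flags the
    single-gray-level image, for which every threshold has zero variance.
    """

    threshold: int
    objective_value: float
    objective_evaluations: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= 255:
            raise ValueError("threshold outside [0, 255]")
        if self.objective_value < 0:
            raise ValueError("objective_value must be >= 0")
        if self.objective_evaluations > 256:
            raise ValueError("more than 256 distinct objective evaluations")


@dataclass(frozen=True)
class OOAConfig:
    """Hyperparameters of the osprey optimizer.

    ``population_size`` (N) ospreys run for ``max_iterations`` (T) iterations
    over the interval [``lower_bound``, ``upper_bound``]; ``seed`` fixes the
    random stream (one generator per call, no global state).
    """

    population_size: int = 8
    max_iterations: int = 8
    lower_bound: float = 0.0
    upper_bound: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")


@dataclass
class OOAResult:
    """Best point found by :func:`ooa_optimize` plus an evaluation trace."""

    best_position: float
    best_fitness: float
    evaluations: int
    evaluated_positions: list[float] = field(default_factory=list, repr=False)
    incumbent_history: list[float] = field(default_factory=list, repr=False)


# ---------------------------------------------------------------------------
# histogram and objective
# ---------------------------------------------------------------------------

def gray_histogram(image: np.ndarray) -> Histogram256:
    """Tally a 2-D integer gray image (values 0..255) into a Histogram256."""
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("image must be integer-valued")
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("gray values outside [0, 255]")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=256)
    return Histogram256(counts=counts, total=int(arr.size))


def _class_stats(hist: Histogram256) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative weight ω0(t) and first moment of class 0 for all t."""
    counts = hist.counts.astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(counts) / hist.total
    m0 = np.cumsum(counts * levels) / hist.total
    return w0, m0


def _variance_curve(hist: Histogram256) -> np.ndarray:
    """σ_b²(t) for every t in 0..255 (0 where a class is empty)."""
    w0, m0 = _class_stats(hist)
    mu_total = m0[-1]
    w1 = 1.0 - w0
    var = np.zeros(256)
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(m0, w0, out=np.zeros_like(m0), where=w0 > 0)
    mu1 = np.divide(mu_total - m0, w1, out=np.zeros_like(m0), where=w1 > 0)
    var[valid] = (w0 * w1 * (mu0 - mu1) ** 2)[valid]
    return var


def between_class_variance(hist: Histogram256, t: int) -> float:
    """Otsu's criterion σ_b²(t) = ω0·ω1·(μ0 − μ1)².

    Class 0 holds levels ≤ t, class 1 levels > t.  Returns 0 when either
    class is empty.
    """
    if not 0 <= t <= 255:
        raise ValueError(f"threshold {t} outside [0, 255]")
    if hist.total <= 0:
        raise ValueError("histogram is empty")
    return float(_variance_curve(hist)[int(t)])


def otsu_exhaustive(hist: Histogram256) -> ThresholdResult:
    """Maximize σ_b² by traversing all 256 gray levels.

    Ties are broken toward the smallest maximizing level.  A single-level
    histogram yields that level with zero objective, flagged degenerate.
    """
    if hist.total <= 0:
        raise ValueError("histogram is empty")
    var = _variance_curve(hist)
    best = float(var.max())
    if best == 0.0:
        # all pixels share one gray level
        level = int(np.flatnonzero(hist.counts)[0])
        return ThresholdResult(level, 0.0, 256, degenerate=True)
    t = int(np.argmax(var))  # argmax returns the first (smallest) maximizer
    return ThresholdResult(t, best, 256)


# ---------------------------------------------------------------------------
# osprey optimization
# ---------------------------------------------------------------------------

def ooa_optimize(objective, config: OOAConfig) -> OOAResult:
    """Minimize a scalar objective on [lb, ub] with the osprey algorithm.

    Each iteration runs two phases per population member Xi:

    * *fish hunting* (exploration): a "fish set" FPi gathers the members with
      strictly better fitness plus the incumbent best; one fish SFi is drawn
      and the candidate is Xi + r·(SFi − I·Xi) with r ~ U(0,1) and I random
      in {1, 2};
    * *carrying the fish* (exploitation): the candidate is
      Xi + (lb + r·(ub − lb)) / t, a perturbation shrinking with the
      iteration counter t.

    Candidates are clamped to the bounds and accepted greedily, so the
    incumbent best never worsens.  Total evaluations ≤ N·(2T + 1).
    """
    rng = np.random.default_rng(config.seed)
    n, t_max = config.population_size, config.max_iterations
    lb, ub = config.lower_bound, config.upper_bound

    def _eval(x: float) -> float:
        f = float(objective(x))
        if not np.isfinite(f):
            raise ValueError(f"objective returned non-finite value at position {x!r}")
        trace.append(x)
        return f

    trace: list[float] = []
    pos = rng.uniform(lb, ub, size=n)
    fit = np.array([_eval(x) for x in pos])
    best_i = int(np.argmin(fit))
    best_x, best_f = float(pos[best_i]), float(fit[best_i])
    history = [best_f]

    for t in range(1, t_max + 1):
        for i in range(n):
            # phase 1: move toward a randomly selected better "fish"
            better = np.flatnonzero(fit < fit[i])
            fish = list(pos[better]) + [best_x]
            sf = fish[rng.integers(len(fish))]
            r = rng.random()
            intensity = rng.integers(1, 3)  # I in {1, 2}
            cand = np.clip(pos[i] + r * (sf - intensity * pos[i]), lb, ub)
            f_cand = _eval(cand)
            if f_cand < fit[i]:
                pos[i], fit[i] = cand, f_cand

            # phase 2: shrinking perturbation around the current position
            r = rng.random()
            cand = np.clip(pos[i] + (lb + r * (ub - lb)) / t, lb, ub)
            f_cand = _eval(cand)
            if f_cand < fit[i]:
                pos[i], fit[i] = cand, f_cand

            if fit[i] < best_f:
                best_x, best_f = float(pos[i]), float(fit[i])
        history.append(best_f)

    return OOAResult(best_x, best_f, len(trace), trace, history)


def ooa_otsu_threshold(image: np.ndarray, config: OOAConfig | None = None) -> ThresholdResult:
    """Otsu's threshold found by the osprey optimizer instead of traversal.

    Positions are continuous; the objective memoizes on the rounded integer
    level, so ``objective_evaluations`` counts distinct gray levels only and
    is bounded by min(256, N·(2T+1)).
    """
    config = config or OOAConfig()
    hist = gray_histogram(image)
    var = _variance_curve(hist)
    cache: dict[int, float] = {}

    def fitness(x: float) -> float:
        level = int(np.clip(round(x), 0, 255))
        if level not in cache:
            cache[level] = -float(var[level])
        return cache[level]

    res = ooa_optimize(fitness, config)
    t = int(np.clip(round(res.best_position), 0, 255))
    value = float(var[t])
    if value == 0.0 and var.max() == 0.0:
        level = int(np.flatnonzero(hist.counts)[0])
        return ThresholdResult(level, 0.0, len(cache), degenerate=True)
    return ThresholdResult(t, value, len(cache))


def apply_threshold(image: np.ndarray, t: int, polarity: str = "dark-foreground") -> np.ndarray:
    """Binarize a gray image at level ``t``.

    With the default ``"dark-foreground"`` polarity (object darker than the
    white background) the mask is 1 where pixel < t; ``"bright-foreground"``
    marks pixels > t.
    """
    if not 0 <= t <= 255:
        raise ValueError(f"threshold {t} outside [0, 255]")
    arr = np.asarray(image)
    if polarity == "dark-foreground":
        return (arr < t).astype(np.uint8)
    if polarity == "bright-foreground":
        return (arr > t).astype(np.uint8)
    raise ValueError(f"unknown polarity {polarity!r}")
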
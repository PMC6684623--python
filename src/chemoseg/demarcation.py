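"""Objective chemotype categorisation by kernel density estimation.

A fraction variable (e.g. F_C3, in percent) observed on an F2 population
is smoothed with a Gaussian KDE whose bandwidth is chosen by the
Sheather–Jones solve-the-equation plug-in. Local maxima of the density
are taken as chemotype modes; the local minima (antimodes) between them
become category boundaries, and every observation is assigned to the
ordered categories I, II, … by baseline peak integration. Peaks
supported by fewer than ``min_support`` observations are merged into a
neighbouring category, so singleton kernels never form a category of
their own.

:class:`ChemotypeDemarcator` wraps the procedure as a scikit-learn
style estimator (``fit`` learns boundaries, ``predict`` assigns
categories); :func:`demarcate` and :func:`assign_categories` are thin
functional wrappers over it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from sklearn.base import BaseEstimator

__all__ = [
    "KernelDensityEstimate",
    "ModeSet",
    "ChemotypeCategories",
    "ChemotypeDemarcator",
    "sj_bandwidth",
    "normal_reference_bandwidth",
    "estimate_density",
    "find_modes",
    "demarcate",
    "assign_categories",
]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


# ---------------------------------------------------------------------------
# bandwidth selection


def normal_reference_bandwidth(values: np.ndarray) -> float:
    """Normal-reference (Silverman) bandwidth 1.059 · σ̂ · n^(−1/5)."""
    x = np.asarray(values, dtype=float)
    return 1.059 * float(np.std(x, ddof=1)) * len(x) ** (-0.2)


def _phi4_sum(d2: np.ndarray, n: int, h: float) -> float:
    # ψ4 functional estimate: Σ_{i,j} φ⁽⁴⁾((xi−xj)/h) / (n(n−1) h⁵),
    # φ⁽⁴⁾(u) = (u⁴ − 6u² + 3) φ(u); the i=j diagonal contributes n·3.
    u2 = d2 / (h * h)
    term = np.exp(-u2 / 2.0) * (u2 * u2 - 6.0 * u2 + 3.0)
    s = 2.0 * float(term.sum()) + n * 3.0
    return s / (n * (n - 1) * h**5 * _SQRT_2PI)


def _phi6_sum(d2: np.ndarray, n: int, h: float) -> float:
    u2 = d2 / (h * h)
    term = np.exp(-u2 / 2.0) * (u2**3 - 15.0 * u2 * u2 + 45.0 * u2 - 15.0)
    s = 2.0 * float(term.sum()) + n * (-15.0)
    return s / (n * (n - 1) * h**7 * _SQRT_2PI)


def sj_bandwidth(values: np.ndarray) -> float:
    """Sheather–Jones solve-the-equation plug-in bandwidth (Gaussian kernel).

    Two-stage normal-scale pilot bandwidths estimate the density-derivative
    functionals; the plug-in equation is then solved for h by a bracketing
    root-finder on a geometric bracket expanded from the normal-reference
    bandwidth. If no root can be bracketed within
    [h_ref/100, 100·h_ref] the normal-reference rule is returned with a
    warning.

    Raises ``ValueError`` for n < 4 or (numerically) zero variance; such
    samples should be treated as a single chemotype category.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = len(x)
    if n < 4:
        raise ValueError(f"Sheather-Jones bandwidth needs n >= 4, got {n}; treat as one category")
    sd = float(np.std(x, ddof=1))
    if sd <= 1e-9 * max(1.0, abs(float(np.mean(x)))):
        raise ValueError("zero variance sample; treat as a single category")

    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd

    # pairwise squared distances, upper triangle (diagonal handled analytically)
    iu = np.triu_indices(n, k=1)
    d2 = (x[:, None] - x[None, :])[iu] ** 2

    a = 1.24 * scale * n ** (-1.0 / 7.0)
    b = 1.23 * scale * n ** (-1.0 / 9.0)
    h_ref = normal_reference_bandwidth(x)

    TD = -_phi6_sum(d2, n, b)
    SD_a = _phi4_sum(d2, n, a)
    if not np.isfinite(TD) or TD <= 0 or SD_a <= 0:
        warnings.warn("Sheather-Jones pilot functionals degenerate; using normal-reference rule")
        return h_ref

    c1 = 1.0 / (2.0 * np.sqrt(np.pi) * n)
    alpha_factor = 1.357 * (SD_a / TD) ** (1.0 / 7.0)

    def equation(h: float) -> float:
        sd_h = _phi4_sum(d2, n, alpha_factor * h ** (5.0 / 7.0))
        if sd_h <= 0:
            return -h  # push the root-finder towards smaller h
        return (c1 / sd_h) ** 0.2 - h

    lo = hi = h_ref
    f_lo = equation(lo)
    f_hi = f_lo
    # expand a geometric bracket around the reference bandwidth
    for _ in range(40):
        if f_lo > 0 and f_hi < 0:
            break
        if f_lo <= 0 and lo > h_ref / 100.0:
            lo /= 1.4
            f_lo = equation(lo)
        elif f_hi >= 0 and hi < h_ref * 100.0:
            hi *= 1.4
            f_hi = equation(hi)
        else:
            break
    if not (f_lo > 0 and f_hi < 0):
        warnings.warn(
            "Sheather-Jones equation has no bracketed root in [h_ref/100, 100*h_ref]; "
            "falling back to the normal-reference bandwidth"
        )
        return h_ref
    return float(brentq(equation, lo, hi, xtol=1e-6 * h_ref))


# ---------------------------------------------------------------------------
# density estimation and mode finding


@dataclass
class KernelDensityEstimate:
    """Gaussian KDE of fraction values on a uniform grid over [0, 100]."""

    values: np.ndarray
    n: int
    h: float
    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError("bandwidth must be positive")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")
        dg = np.diff(self.grid)
        if np.any(dg <= 0) or not np.allclose(dg, dg[0], rtol=1e-8):
            raise ValueError("grid must be strictly increasing and uniform")
        integral = float(np.trapezoid(self.density, self.grid))
        if not (0.98 <= integral <= 1.02):
            # kernel mass can leak outside [0, 100] when observations pile
            # up against a boundary (e.g. F_C3 near 0); flag, don't fail
            warnings.warn(
                f"KDE integral over the grid is {integral:.3f}, outside [0.98, 1.02]; "
                "mass may extend beyond the [0, 100] clip"
            )


def estimate_density(
    values: np.ndarray,
    h: float,
    grid_points: int = 512,
    padding: float = 3.0,
) -> KernelDensityEstimate:
    """Evaluate the Gaussian KDE on a uniform grid.

    The grid spans [max(0, min−padding·h), min(100, max+padding·h)] with
    ``grid_points`` points (≥ 64).
    """
    x = np.asarray(values, dtype=float).ravel()
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_points < 64:
        raise ValueError("grid_points must be at least 64")
    lo = max(0.0, float(x.min()) - padding * h)
    hi = min(100.0, float(x.max()) + padding * h)
    if hi <= lo:  # all mass at a single clipped point
        lo, hi = max(0.0, lo - 1.0), min(100.0, hi + 1.0)
    grid = np.linspace(lo, hi, grid_points)
    u = (grid[:, None] - x[None, :]) / h
    density = np.exp(-0.5 * u * u).sum(axis=1) / (len(x) * h * _SQRT_2PI)
    return KernelDensityEstimate(values=x, n=len(x), h=h, grid=grid, density=density)


@dataclass
class ModeSet:
    """Indices of density peaks and the valleys (antimodes) separating them."""

    peaks: list[int]
    valleys: list[int]
    support_counts: list[int] = field(default_factory=list)


def find_modes(kde: KernelDensityEstimate) -> ModeSet:
    """Locate local maxima/minima of the density by first-difference sign changes.

    Plateaus are collapsed to their midpoint; the first and last grid
    points count as maxima when the density falls away from them.
    """
    d = np.diff(kde.density)
    signs = np.sign(d)
    # collapse plateaus: propagate the preceding trend through zero runs
    peaks: list[int] = []
    valleys: list[int] = []
    prev_sign = 0.0
    run_start = 0  # start of the current plateau (for midpoint collapse)
    for i, s in enumerate(signs):
        if s == 0:
            continue
        if prev_sign == 0:
            # leading run: a boundary maximum if density decreases from the start
            if s < 0:
                peaks.append(run_start // 2)
            prev_sign = s
            run_start = i + 1
            continue
        if s != prev_sign:
            turn = (run_start + i) // 2 if run_start < i else i
            if prev_sign > 0 and s < 0:
                peaks.append(turn)
            elif prev_sign < 0 and s > 0:
                valleys.append(turn)
            prev_sign = s
        run_start = i + 1
    if prev_sign > 0:  # trailing boundary maximum
        peaks.append(len(kde.density) - 1)
    if prev_sign == 0 and not peaks:  # perfectly flat density
        peaks.append(len(kde.density) // 2)
    # keep only valleys strictly between adjacent peaks
    valleys = [
        v for p0, p1 in zip(peaks[:-1], peaks[1:]) for v in valleys if p0 < v < p1
    ]
    ms = ModeSet(peaks=peaks, valleys=valleys)
    ms.support_counts = _support_counts(kde, ms)
    return ms


def _support_counts(kde: KernelDensityEstimate, modes: ModeSet) -> list[int]:
    bounds = [kde.grid[v] for v in modes.valleys]
    edges = np.concatenate(([-np.inf], bounds, [np.inf]))
    counts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        counts.append(int(np.sum((kde.values > lo) & (kde.values <= hi))))
    # the lowest interval is closed at both ends; -inf edge already covers it
    return counts


# ---------------------------------------------------------------------------
# demarcation


def _roman(k: int) -> str:
    numerals = [(10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I")]
    out = []
    while k > 0:
        for v, s in numerals:
            if k >= v:
                out.append(s)
                k -= v
                break
    return "".join(out)


@dataclass
class ChemotypeCategories:
    """Ordered chemotype categories with their boundaries and counts.

    ``boundaries`` are the antimode cut points (percent); category ``labels``
    are I, II, … in order of increasing fraction value. Intervals are
    left-open/right-closed except the first, which is closed at both ends.
    """

    boundaries: list[float]
    labels: list[str]
    counts: dict[str, int]
    bandwidth: float | None = None
    assignment: dict[str, str] | None = None
    unresolved_valleys: list[float] = field(default_factory=list)

    @property
    def n_categories(self) -> int:
        return len(self.labels)

    def ordered_counts(self) -> list[int]:
        return [self.counts[lab] for lab in self.labels]


def demarcate(
    kde: KernelDensityEstimate,
    min_support: int = 2,
    valley_depth_frac: float = 0.5,
) -> ChemotypeCategories:
    """Partition observations into chemotype categories by baseline peak integration.

    Peak intervals are delimited by the flanking antimodes (or the data
    range ends). Demarcation is *baseline* peak integration: an antimode
    cuts only when the density drops at least ``valley_depth_frac`` of the
    lower flanking peak's height toward baseline there; shallower valleys
    are reported as unresolvable and do not cut. An interval holding
    fewer than ``min_support`` observations is merged into the adjacent
    interval whose shared valley has the higher density (ties merge
    toward the larger-support neighbour).
    """
    if kde.n < 2:
        warnings.warn("fewer than 2 observations; returning a single category")
        return ChemotypeCategories([], ["I"], {"I": kde.n}, bandwidth=kde.h)
    modes = find_modes(kde)
    peaks = list(modes.peaks)
    valleys = list(modes.valleys)
    unresolved: list[float] = []

    # 1. drop unresolvable (too shallow) valleys, shallowest first
    def rel_depth(j: int) -> float:
        flank = min(kde.density[peaks[j]], kde.density[peaks[j + 1]])
        return (flank - kde.density[valleys[j]]) / flank if flank > 0 else 0.0

    while valleys:
        j = min(range(len(valleys)), key=rel_depth)
        if rel_depth(j) >= valley_depth_frac:
            break
        unresolved.append(float(kde.grid[valleys[j]]))
        # merge the two flanking peaks, keeping the taller one
        keep = peaks[j] if kde.density[peaks[j]] >= kde.density[peaks[j + 1]] else peaks[j + 1]
        peaks[j : j + 2] = [keep]
        del valleys[j]

    counts = _support_counts(kde, ModeSet(peaks=peaks, valleys=valleys))

    # 2. merge under-supported intervals (singleton kernels are not categories)
    while len(counts) > 1 and min(counts) < min_support:
        i = int(np.argmin(counts))
        if i == 0:
            j = 0  # only the right valley exists
        elif i == len(counts) - 1:
            j = i - 1
        else:
            d_left, d_right = kde.density[valleys[i - 1]], kde.density[valleys[i]]
            if d_left > d_right:
                j = i - 1
            elif d_right > d_left:
                j = i
            else:  # tie: merge toward the larger-support neighbour
                j = i - 1 if counts[i - 1] >= counts[i + 1] else i
        # removing valley j fuses intervals j and j+1
        del valleys[j]
        counts[j : j + 2] = [counts[j] + counts[j + 1]]
        keep = peaks[j] if kde.density[peaks[j]] >= kde.density[peaks[j + 1]] else peaks[j + 1]
        peaks[j : j + 2] = [keep]

    boundaries = [float(kde.grid[v]) for v in valleys]
    labels = [_roman(i + 1) for i in range(len(counts))]
    return ChemotypeCategories(
        boundaries=boundaries,
        labels=labels,
        counts=dict(zip(labels, counts)),
        bandwidth=kde.h,
        unresolved_valleys=unresolved,
    )


def assign_categories(values: np.ndarray, categories: ChemotypeCategories) -> np.ndarray:
    """Assign each value to its chemotype category label.

    Intervals are left-open/right-closed; the lowest interval is closed at
    both ends, so a value exactly on a boundary belongs to the
    lower-fraction category.
    """
    x = np.asarray(values, dtype=float).ravel()
    if np.any((x < 0) | (x > 100)):
        raise ValueError("fraction values must lie in [0, 100]")
    if not categories.boundaries:
        return np.array([categories.labels[0]] * len(x), dtype=object)
    idx = np.searchsorted(np.asarray(categories.boundaries), x, side="left")
    return np.array([categories.labels[i] for i in idx], dtype=object)


# ---------------------------------------------------------------------------
# estimator


class ChemotypeDemarcator(BaseEstimator):
    """KDE-based chemotype categoriser with a scikit-learn interface.

    Fit on a 1-D array of fraction values (percent, in [0, 100]); the
    fitted estimator exposes the category boundaries and counts and
    assigns categories to new values with :meth:`predict`.

    Parameters
    ----------
    bandwidth : float or None
        Kernel bandwidth in percent units; ``None`` (default) selects it
        by the Sheather–Jones solve-the-equation plug-in.
    min_support : int
        Minimum observations per category; smaller peaks are merged.
    grid_points : int
        Density evaluation grid resolution.
    padding : float
        Grid padding beyond the data range, in multiples of the bandwidth.
    valley_depth_frac : float
        Minimum relative valley depth for an antimode to cut.

    Attributes
    ----------
    bandwidth_ : float
    kde_ : KernelDensityEstimate
    categories_ : ChemotypeCategories
    boundaries_ : list of float
    category_names_ : list of str
    labels_ : ndarray of int — category index of each training value
    counts_ : list of int — per-category training counts
    n_categories_ : int
    """

    def __init__(
        self,
        bandwidth: float | None = None,
        min_support: int = 2,
        grid_points: int = 512,
        padding: float = 3.0,
        valley_depth_frac: float = 0.5,
    ) -> None:
        self.bandwidth = bandwidth
        self.min_support = min_support
        self.grid_points = grid_points
        self.padding = padding
        self.valley_depth_frac = valley_depth_frac

    def _as_values(self, X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("expected a 1-D array of fraction values")
        if not np.all(np.isfinite(x)):
            raise ValueError("fraction values must be finite")
        if np.any((x < -1e-9) | (x > 100 + 1e-9)):
            raise ValueError("fraction values must lie in [0, 100]")
        return np.clip(x, 0.0, 100.0)

    def fit(self, X, y=None) -> "ChemotypeDemarcator":
        x = self._as_values(X)
        if self.bandwidth is not None:
            h = float(self.bandwidth)
        else:
            try:
                h = sj_bandwidth(x)
            except ValueError as err:
                warnings.warn(f"{err}; treating the sample as a single category")
                self.bandwidth_ = None
                self.kde_ = None
                self.categories_ = ChemotypeCategories([], ["I"], {"I": len(x)})
                self._finalise(x)
                return self
        self.bandwidth_ = h
        self.kde_ = estimate_density(x, h, self.grid_points, self.padding)
        self.categories_ = demarcate(self.kde_, self.min_support, self.valley_depth_frac)
        self._finalise(x)
        return self

    def _finalise(self, x: np.ndarray) -> None:
        cats = self.categories_
        self.boundaries_ = list(cats.boundaries)
        self.category_names_ = list(cats.labels)
        self.n_categories_ = cats.n_categories
        assigned = assign_categories(x, cats)
        name_to_idx = {lab: i for i, lab in enumerate(cats.labels)}
        self.labels_ = np.array([name_to_idx[a] for a in assigned])
        self.counts_ = [int(np.sum(self.labels_ == i)) for i in range(cats.n_categories)]

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "categories_"):
            raise AttributeError("ChemotypeDemarcator is not fitted yet")
        x = self._as_values(X)
        assigned = assign_categories(x, self.categories_)
        name_to_idx = {lab: i for i, lab in enumerate(self.categories_.labels)}
        return np.array([name_to_idx[a] for a in assigned])

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
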
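"""Topological features of 1-D signals.

A 3-s signal window is treated as a function on the line; sweeping a
threshold upward through its values and tracking connected components of
the sublevel sets yields the 0-dimensional persistence diagram: each
component is born at a local minimum and dies when it merges with an older
component (elder rule).  The essential component is closed at the global
maximum.  From the diagram we compute per-pair *lifespans* ``d - b`` and
*midlives* ``(b + d) / 2``; their summary statistics (ten numbers) plus the
L2 norm of the Gaussian persistence curve give the 11 topological features
used per channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "PersistenceDiagram",
    "persistence_diagram",
    "persistence_statistics",
    "gaussian_persistence_curve_norm",
    "tda_features",
    "TDA_FEATURE_NAMES",
]


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of (birth, death) pairs; includes the essential pair."""

    pairs: np.ndarray  # (k, 2), death >= birth

    def __post_init__(self):
        object.__setattr__(self, "pairs",
                           np.asarray(self.pairs, dtype=float).reshape(-1, 2))
        if len(self.pairs) and np.any(self.pairs[:, 1] < self.pairs[:, 0]):
            raise ValueError("death < birth in persistence pair")

    @property
    def lifespans(self) -> np.ndarray:
        return self.pairs[:, 1] - self.pairs[:, 0]

    @property
    def midlives(self) -> np.ndarray:
        return self.pairs.mean(axis=1)

    def __len__(self) -> int:
        return len(self.pairs)


def persistence_diagram(series) -> PersistenceDiagram:
    """0-dim sublevel-set persistence of a 1-D series.

    Components are born at local minima; at a merge the younger component
    (larger birth) dies (elder rule, ties broken toward the earlier index).
    Plateau-induced zero-persistence pairs are merged away.  The essential
    class is closed at the global maximum, so a diagram always contains the
    pair ``(min, max)``.

    Length-0/1 input yields a single degenerate pair.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        return PersistenceDiagram(np.empty((0, 2)))
    if x.size == 1:
        return PersistenceDiagram([[x[0], x[0]]])
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")

    n = x.size
    parent = np.full(n, -1, dtype=np.int64)  # -1: not yet added
    birth = np.empty(n, dtype=float)  # birth value of component rooted here

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:  # path compression
            parent[i], i = root, parent[i]
        return root

    order = np.argsort(x, kind="stable")
    pairs: list[tuple[float, float]] = []
    for i in order:
        parent[i] = i
        birth[i] = x[i]
        for j in (i - 1, i + 1):
            if 0 <= j < n and parent[j] != -1:
                ri, rj = find(i), find(j)
                if ri == rj:
                    continue
                # elder rule: component with larger birth dies now
                if (birth[ri], ri) <= (birth[rj], rj):
                    elder, younger = ri, rj
                else:
                    elder, younger = rj, ri
                if birth[younger] < x[i]:  # skip zero-persistence plateaus
                    pairs.append((birth[younger], x[i]))
                parent[younger] = elder
    pairs.append((float(x.min()), float(x.max())))  # essential class
    return PersistenceDiagram(np.array(pairs))


def _five_stats(values: np.ndarray) -> list[float]:
    """mean, SD, skewness, kurtosis, Shannon entropy of the normalized vector.

    Sets with fewer than two elements (or zero spread) get SD/skew/kurt 0;
    a non-positive total mass gets entropy 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return [0.0] * 5
    mean = float(v.mean())
    if v.size < 2 or np.ptp(v) == 0:
        sd = skew = kurt = 0.0
    else:
        sd = float(v.std(ddof=1))
        skew = float(sstats.skew(v))
        kurt = float(sstats.kurtosis(v))
    total = v.sum()
    if total > 0 and np.all(v >= 0):
        p = v[v > 0] / total
        entropy = float(-(p * np.log(p)).sum())
    else:
        entropy = 0.0
    return [mean, sd, skew, kurt, entropy]


def persistence_statistics(diagram: PersistenceDiagram) -> np.ndarray:
    """Ten persistence statistics: five stats of lifespans, five of midlives.

    Midlives are shifted by their minimum before the entropy term so the
    normalized vector is a proper distribution.  An empty diagram yields ten
    zeros.
    """
    if len(diagram) == 0:
        return np.zeros(10)
    life = diagram.lifespans
    mid = diagram.midlives
    out = _five_stats(life)
    mid_stats = _five_stats(mid - mid.min())
    # mean of midlives is reported unshifted; spread/shape terms are
    # shift-invariant, entropy uses the shifted vector
    mid_stats[0] = float(mid.mean())
    return np.array(out + mid_stats)


def gaussian_persistence_curve_norm(
    diagram: PersistenceDiagram,
    sigma_scale: float = 0.5,
    grid: np.ndarray | None = None,
    value_range: tuple[float, float] | None = None,
    n_grid: int = 256,
) -> float:
    """L2 norm of the Gaussian persistence curve.

    ``G(t) = sum_i l_i * N(t; mu=m_i, sigma=sigma_scale*l_i)`` over pairs
    with positive lifespan ``l_i`` and midlife ``m_i``.  The norm is
    ``sqrt(integral G^2)`` on a fixed grid spanning ``value_range`` (by
    default the diagram's own value span, padded by one bandwidth).
    """
    if len(diagram) == 0:
        return 0.0
    life = diagram.lifespans
    mid = diagram.midlives
    keep = life > 0
    if not np.any(keep):
        return 0.0
    life, mid = life[keep], mid[keep]
    sigma = sigma_scale * life
    if grid is None:
        if value_range is None:
            pad = float(sigma.max()) * 4.0
            value_range = (float(diagram.pairs.min()) - pad,
                           float(diagram.pairs.max()) + pad)
        grid = np.linspace(value_range[0], value_range[1], n_grid)
    grid = np.asarray(grid, dtype=float)
    z = (grid[None, :] - mid[:, None]) / sigma[:, None]
    curve = (life[:, None] / (sigma[:, None] * np.sqrt(2 * np.pi))
             * np.exp(-0.5 * z**2)).sum(axis=0)
    return float(np.sqrt(np.trapezoid(curve**2, grid)))


TDA_FEATURE_NAMES = (
    "life_mean", "life_sd", "life_skew", "life_kurt", "life_entropy",
    "mid_mean", "mid_sd", "mid_skew", "mid_kurt", "mid_entropy",
    "gpc_norm",
)


def tda_features(series) -> np.ndarray:
    """The 11 topological features of a 1-D window (stats + curve norm)."""
    x = np.asarray(series, dtype=float).ravel()
    dgm = persistence_diagram(x)
    span = (float(x.min()), float(x.max())) if x.size else (0.0, 1.0)
    if span[0] == span[1]:
        span = (span[0] - 0.5, span[1] + 0.5)
    norm = gaussian_persistence_curve_norm(dgm, value_range=span)
    return np.concatenate([persistence_statistics(dgm), [norm]])
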
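"""Intratumoral-heterogeneity texture indicators on the coarse hexagon grid.

Per-hexagon biomarker percentages are ranked into 10 fixed intervals
(0-10%, >10-20%, ..., >90-100%).  A symmetric co-occurrence matrix over
adjacent retained hexagons is built from the ranks and summarized by five
Haralick indicators (contrast, dissimilarity, entropy, energy, homogeneity).
Bimodality of the per-hexagon percentage distribution is quantified by
Ashman's D from a two-component Gaussian mixture:

    D = sqrt(2) * |mu1 - mu2| / sqrt(sigma1^2 + sigma2^2)

with D > 2 the conventional bimodality threshold.

Conventions (config-exposed where stated): entropy uses the natural log;
energy is the angular second moment; rank indices enter the Haralick sums as
integers 1..10.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from hexgradient.errors import UndefinedIndicatorError, ValidationError
from hexgradient.hexgrid import HexStatTable, tile_marker_percentages

N_RANKS = 10

#: minimum marker-denominator cells for a tile to be ranked
MIN_MARKER_CELLS = 10


@dataclass
class RankMap:
    """Per-tile interval rank for one marker.

    ``ranks`` aligns with the tile rows of the HexStatTable; 0 marks tiles
    without a rank (not retained, undefined percentage, or denominator below
    the minimum).  Ranked tiles carry an integer in 1..10: rank 1 covers
    [0, 10], rank k >= 2 covers (10(k-1), 10k].
    """

    marker: str
    ranks: np.ndarray

    @property
    def n_ranked(self) -> int:
        return int((self.ranks > 0).sum())


@dataclass
class CoocMatrix:
    """Normalized symmetric rank co-occurrence matrix.

    ``P`` is 10x10 with sum 1; ``pair_count`` is the number of ordered
    adjacent pairs tallied (twice the unordered pairs).
    """

    P: np.ndarray
    pair_count: int


@dataclass
class TextureIndicators:
    contrast: float
    dissimilarity: float
    entropy: float
    energy: float
    homogeneity: float

    def as_dict(self) -> dict[str, float]:
        return {
            "contrast": self.contrast,
            "dissimilarity": self.dissimilarity,
            "entropy": self.entropy,
            "energy": self.energy,
            "homogeneity": self.homogeneity,
        }


@dataclass
class BimodalityResult:
    """Two-component Gaussian-mixture fit and Ashman's D."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    weight1: float
    ashman_d: float
    converged: bool
    reliable: bool = True
    degenerate: bool = False


def percentage_rank(values: np.ndarray) -> np.ndarray:
    """Rank percentages in [0, 100] into the 10 fixed intervals.

    0 and 10 both fall in rank 1; 10.1 in rank 2; 100 in rank 10.
    NaN maps to rank 0 (unranked).
    """
    v = np.asarray(values, dtype=float)
    with np.errstate(invalid="ignore"):
        ranks = np.where(v <= 10.0, 1, np.ceil(v / 10.0)).astype(np.int64)
    ranks = np.clip(ranks, 1, N_RANKS)
    ranks[~np.isfinite(v)] = 0
    return ranks


def rank_tiles(
    stats: HexStatTable,
    marker: str,
    min_marker_cells: int = MIN_MARKER_CELLS,
    denominator: str = "tumor",
) -> RankMap:
    """Rank the retained tiles' marker percentages into the 10 intervals.

    Tiles are eligible when retained by the sampling filter, their percentage
    is defined, and the marker denominator holds at least ``min_marker_cells``
    cells (percentages over near-empty denominators are unstable).
    """
    vals, dens = tile_marker_percentages(stats, marker, denominator=denominator)
    eligible = (
        stats.tiles["retained"].to_numpy()
        & np.isfinite(vals)
        & (dens >= min_marker_cells)
    )
    ranks = percentage_rank(vals)
    ranks[~eligible] = 0
    if not (ranks > 0).any():
        raise UndefinedIndicatorError(f"no tiles eligible for ranking marker {marker}")
    return RankMap(marker=marker, ranks=ranks)


def cooccurrence(ranks: RankMap, stats: HexStatTable) -> CoocMatrix:
    """Build the normalized symmetric co-occurrence matrix of adjacent ranks.

    Adjacency is the 6-neighborhood of the tessellation.  Pairs in which
    either tile is unranked are dropped.  Each unordered pair (a, b)
    contributes one count to P[a, b] and one to P[b, a] before normalization.
    """
    pairs = stats.neighbor_pairs()
    r = ranks.ranks
    if len(pairs):
        ok = (r[pairs[:, 0]] > 0) & (r[pairs[:, 1]] > 0)
        pairs = pairs[ok]
    if len(pairs) < 1:
        raise UndefinedIndicatorError(
            f"no adjacent ranked tile pairs for marker {ranks.marker}; texture undefined"
        )
    a = r[pairs[:, 0]] - 1
    b = r[pairs[:, 1]] - 1
    counts = np.zeros((N_RANKS, N_RANKS), dtype=float)
    np.add.at(counts, (a, b), 1.0)
    np.add.at(counts, (b, a), 1.0)
    return CoocMatrix(P=counts / counts.sum(), pair_count=2 * len(pairs))


def haralick(cooc: CoocMatrix | np.ndarray) -> TextureIndicators:
    """Compute the five Haralick indicators from a normalized co-occurrence
    matrix.

    contrast      = sum P[i,j] (i-j)^2
    dissimilarity = sum P[i,j] |i-j|
    entropy       = -sum P[i,j] ln P[i,j]        (0 ln 0 := 0)
    energy        = sum P[i,j]^2                 (angular second moment)
    homogeneity   = sum P[i,j] / (1 + (i-j)^2)

    with rank indices i, j in 1..10.
    """
    P = cooc.P if isinstance(cooc, CoocMatrix) else np.asarray(cooc, dtype=float)
    if P.shape != (N_RANKS, N_RANKS):
        raise ValidationError(f"co-occurrence matrix must be {N_RANKS}x{N_RANKS}")
    total = P.sum()
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValidationError(f"co-occurrence matrix not normalized (sum {total})")
    i = np.arange(1, N_RANKS + 1)
    diff = i[:, None] - i[None, :]
    nz = P > 0
    entropy = float(-(P[nz] * np.log(P[nz])).sum())
    return TextureIndicators(
        contrast=float((P * diff**2).sum()),
        dissimilarity=float((P * np.abs(diff)).sum()),
        entropy=entropy,
        energy=float((P**2).sum()),
        homogeneity=float((P / (1.0 + diff**2)).sum()),
    )


#: SD floor (percentage points) preventing mixture-component collapse
SIGMA_FLOOR = 1e-3


def ashman_d(
    values: np.ndarray,
    seed: int = 0,
    n_init: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BimodalityResult:
    """Fit a two-component Gaussian mixture by EM and return Ashman's D.

    D = sqrt(2)|mu1 - mu2| / sqrt(sigma1^2 + sigma2^2).  The fit uses
    ``n_init`` k-means++-style restarts.  Fewer than 20 values yields a
    result flagged unreliable; identical values yield D = 0 with a
    degenerate-fit flag.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise UndefinedIndicatorError("no values for bimodality assessment")
    reliable = len(v) >= 20
    if np.ptp(v) == 0.0:
        m = float(v[0])
        return BimodalityResult(
            mu1=m, mu2=m, sigma1=SIGMA_FLOOR, sigma2=SIGMA_FLOOR, weight1=1.0,
            ashman_d=0.0, converged=True, reliable=reliable, degenerate=True,
        )
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_init,
        tol=tol,
        max_iter=max_iter,
        reg_covar=SIGMA_FLOOR**2,
        init_params="k-means++",
        random_state=seed,
    ).fit(v.reshape(-1, 1))
    mu = gm.means_.ravel()
    sigma = np.maximum(np.sqrt(gm.covariances_.ravel()), SIGMA_FLOOR)
    order = np.argsort(mu)
    mu, sigma = mu[order], sigma[order]
    w1 = float(gm.weights_.ravel()[order][0])
    d = float(np.sqrt(2.0) * abs(mu[0] - mu[1]) / np.sqrt(sigma[0] ** 2 + sigma[1] ** 2))
    return BimodalityResult(
        mu1=float(mu[0]), mu2=float(mu[1]),
        sigma1=float(sigma[0]), sigma2=float(sigma[1]),
        weight1=w1, ashman_d=d, converged=bool(gm.converged_), reliable=reliable,
    )


def texture_profile(
    stats: HexStatTable,
    marker: str,
    min_marker_cells: int = MIN_MARKER_CELLS,
    seed: int = 0,
) -> dict[str, float]:
    """Full per-marker texture record for one slide: the five Haralick
    indicators, Ashman's D, and the tile/pair counts they were computed from.

    Raises UndefinedIndicatorError when no tile (or no adjacent pair) is
    eligible; callers that tolerate partial slides should catch it.
    """
    ranks = rank_tiles(stats, marker, min_marker_cells=min_marker_cells)
    cooc = cooccurrence(ranks, stats)
    tex = haralick(cooc)
    vals, dens = tile_marker_percentages(stats, marker)
    eligible = (
        stats.tiles["retained"].to_numpy()
        & np.isfinite(vals)
        & (dens >= min_marker_cells)
    )
    bim = ashman_d(vals[eligible], seed=seed)
    out = tex.as_dict()
    out["ashman_d"] = bim.ashman_d
    out["n_tiles"] = ranks.n_ranked
    out["n_pairs"] = cooc.pair_count
    return out
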
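"""Binary cell-area masks via graph-cut MRF segmentation.

The mask M marks the total cell-covered area of the field; during training it
penalizes any per-cell segmentation that spills onto background. Two paths
produce it:

* fluorescence: graph cut directly on normalized intensity, with unary costs
  −log(α·xᵢ) for foreground and −log((1−α)(1−xᵢ)) for background, a Potts
  boundary penalty κ on 4-connected neighbor pairs, and α the prior foreground
  fraction (estimated from expected cell coverage);
* bright-field: gray values carry no foreground contrast, so a two-class
  random-forest pixel classifier (Gaussian, local-variance and Laplacian
  features at several scales, trained on a few user scribbles) produces a
  foreground probability map, and the graph cut runs on that map instead.

The cut is solved exactly as an s–t min-cut/max-flow problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from sklearn.ensemble import RandomForestClassifier

EPS = 1e-6
_FLOW_SCALE = 2**20  # float costs → integer capacities for the max-flow solver


@dataclass
class GraphCutProblem:
    x: np.ndarray  # normalized intensity per pixel, strictly inside (0, 1)
    alpha: float  # prior foreground probability
    kappa: float = 1.0  # Potts cut penalty per disagreeing neighbor pair
    connectivity: int = 4

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if np.any(self.x <= 0.0) or np.any(self.x >= 1.0) or not np.all(np.isfinite(self.x)):
            raise ValueError("x must be strictly inside (0, 1); clip it first")


@dataclass
class BinaryMask:
    m: np.ndarray  # {0,1} per pixel, full field size

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m)
        if not np.isin(self.m, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")


@dataclass
class ScribbleSet:
    labels: np.ndarray  # 0 = unlabeled, 1 = foreground, 2 = background

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not ((self.labels == 1).any() and (self.labels == 2).any()):
            raise ValueError("scribbles must contain both a foreground and a background stroke")


def normalize_intensity(
    image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0, eps: float = EPS
) -> np.ndarray:
    """Percentile-affine rescale into (eps, 1−eps); a constant image maps to 0.5."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    lo, hi = np.percentile(image, [low_pct, high_pct])
    if hi <= lo:
        return np.full(image.shape, 0.5)
    return np.clip((image - lo) / (hi - lo), eps, 1.0 - eps)


def estimate_alpha(coverage_hint: float, image: np.ndarray | None = None) -> float:
    """Prior foreground probability from expected cell coverage, clamped to [0.05, 0.95]."""
    if not (0.0 < coverage_hint < 1.0):
        raise ValueError("coverage_hint must lie in (0, 1)")
    return float(np.clip(coverage_hint, 0.05, 0.95))


def unary_costs(x: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """(foreground, background) unary energies per pixel."""
    cost_fg = -np.log(alpha * x)
    cost_bg = -np.log((1.0 - alpha) * (1.0 - x))
    if not (np.all(np.isfinite(cost_fg)) and np.all(np.isfinite(cost_bg))):
        raise ValueError("non-finite unary cost; x must be clipped away from 0 and 1")
    return cost_fg, cost_bg


def _neighbor_pairs(shape: tuple[int, int], connectivity: int) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    pairs = [
        (idx[:-1, :].ravel(), idx[1:, :].ravel()),
        (idx[:, :-1].ravel(), idx[:, 1:].ravel()),
    ]
    if connectivity == 8:
        pairs.append((idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()))
        pairs.append((idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()))
    a = np.concatenate([p[0] for p in pairs])
    b = np.concatenate([p[1] for p in pairs])
    return a, b


def graphcut_energy(problem: GraphCutProblem, y: np.ndarray) -> float:
    """The MRF energy E(y) = Σ unary + κ·#{neighbor pairs with unequal labels}."""
    y = np.asarray(y).astype(bool)
    cost_fg, cost_bg = unary_costs(problem.x, problem.alpha)
    e = float(np.where(y, cost_fg, cost_bg).sum())
    a, b = _neighbor_pairs(problem.x.shape, problem.connectivity)
    yf = y.ravel()
    e += problem.kappa * int(np.count_nonzero(yf[a] != yf[b]))
    return e


def graphcut_mask(problem: GraphCutProblem) -> BinaryMask:
    """Exact global minimizer of the MRF energy via s–t min-cut.

    Graph: source = foreground terminal, sink = background terminal;
    cap(s→i) = background unary (paid when i is labeled 0), cap(i→t) =
    foreground unary, κ both ways between neighbors. Costs are scaled to
    integers for the solver; after max-flow the source side of the residual
    graph is the foreground.
    """
    x = problem.x
    h, w = x.shape
    n = h * w
    s, t = n, n + 1
    cost_fg, cost_bg = unary_costs(x, problem.alpha)

    rows = [np.full(n, s), np.arange(n)]
    cols = [np.arange(n), np.full(n, t)]
    caps = [cost_bg.ravel(), cost_fg.ravel()]
    if problem.kappa > 0:
        a, b = _neighbor_pairs((h, w), problem.connectivity)
        k = np.full(len(a), problem.kappa)
        rows += [a, b]
        cols += [b, a]
        caps += [k, k]
    cap_int = np.rint(np.concatenate(caps) * _FLOW_SCALE).astype(np.int64)
    graph = coo_matrix(
        (cap_int, (np.concatenate(rows), np.concatenate(cols))), shape=(n + 2, n + 2)
    ).tocsr()

    result = maximum_flow(graph, s, t)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reachable = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    mask = np.zeros(n, dtype=np.uint8)
    mask[reachable[reachable < n]] = 1
    return BinaryMask(m=mask.reshape(h, w))


def _features(image: np.ndarray, sigmas: tuple[float, ...]) -> np.ndarray:
    """Per-pixel feature stack: Gaussian blur, local variance, Laplacian at each scale."""
    feats = []
    for s in sigmas:
        g = ndimage.gaussian_filter(image, s)
        var = ndimage.gaussian_filter(image**2, s) - g**2
        lap = ndimage.gaussian_laplace(image, s)
        feats += [g, var, lap]
    return np.stack(feats, axis=-1)


def pixel_classifier_probability(
    image: np.ndarray,
    scribbles: ScribbleSet,
    sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
    n_estimators: int = 50,
    random_state: int = 0,
) -> np.ndarray:
    """Foreground probability per pixel from a scribble-trained random forest."""
    image = np.asarray(image, dtype=np.float64)
    feats = _features(image, sigmas)
    lab = scribbles.labels
    train_mask = lab > 0
    X = feats[train_mask]
    y = (lab[train_mask] == 1).astype(np.int64)
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=random_state)
    clf.fit(X, y)
    proba = clf.predict_proba(feats.reshape(-1, feats.shape[-1]))
    fg_col = list(clf.classes_).index(1)
    return proba[:, fg_col].reshape(image.shape)


def mask_from_brightfield(
    image: np.ndarray,
    scribbles: ScribbleSet,
    alpha: float,
    kappa: float = 1.0,
    sigmas: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0),
    connectivity: int = 4,
    random_state: int = 0,
) -> BinaryMask:
    """Scribble-trained classifier probability, then graph cut on that probability."""
    prob = pixel_classifier_probability(image, scribbles, sigmas, random_state=random_state)
    prob = np.clip(prob, EPS, 1.0 - EPS)
    return graphcut_mask(GraphCutProblem(x=prob, alpha=alpha, kappa=kappa, connectivity=connectivity))


def mask_from_fluorescence(
    image: np.ndarray,
    alpha: float,
    kappa: float = 1.0,
    low_pct: float = 1.0,
    high_pct: float | None = None,
    connectivity: int = 4,
) -> BinaryMask:
    """Normalize intensity, then graph cut — the fluorescence masking path.

    The unary model reads normalized intensity as a foreground likelihood, so
    the dimmest genuine cell should land near the top of the (0,1) range. By
    default the high normalization percentile is therefore tied to the
    coverage prior — roughly the background fraction plus a margin — instead
    of a fixed 99th percentile that would leave dim cells mid-range and push
    them into the background.
    """
    if high_pct is None:
        high_pct = float(np.clip(100.0 * (1.0 - 0.9 * alpha), 50.0, 99.0))
    x = normalize_intensity(image, low_pct, high_pct)
    return graphcut_mask(GraphCutProblem(x=x, alpha=alpha, kappa=kappa, connectivity=connectivity))
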
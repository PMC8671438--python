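"""Independent brute-force oracles the implementation is checked against.

These deliberately mirror the literal definitions — zero-padded full-field
grids and exhaustive enumeration — and stay independent of the package's
optimized code paths.
"""

from __future__ import annotations

import itertools

import numpy as np

from patchseg.masking import GraphCutProblem, graphcut_energy
from patchseg.patching import PatchPrediction
from patchseg.selfsup_loss import LossWeights


def brute_force_loss(preds: list[PatchPrediction], mask: np.ndarray, w: LossWeights):
    """Naive evaluation on materialized zero-padded full-field grids.

    Sums run over every field pixel and every ordered patch pair, exactly as
    the definition reads; the zero-padded regions contribute nothing because
    the padded probability is zero there by construction.
    """
    h, wd = mask.shape
    fields = []
    for p in preds:
        full = np.zeros((h, wd))
        r0, c0 = p.origin
        kr, kc = p.y.shape
        full[r0 : r0 + kr, c0 : c0 + kc] = np.clip(p.y, w.eps, 1.0 - w.eps)
        fields.append(full)

    area = 0.0
    for y in fields:
        for d0 in range(h):
            for d1 in range(wd):
                area -= y[d0, d1]

    consistency = 0.0
    for i, yi in enumerate(fields):
        for j, yj in enumerate(fields):
            if i == j:
                continue
            # the summand is yi * log10(1 - yj); it vanishes wherever either
            # window is absent (yi = 0 there, and yj = 0 makes the log zero)
            consistency += float((yi * np.log10(1.0 - yj)).sum())
    consistency *= -w.lam

    mask_pen = 0.0
    for y in fields:
        mask_pen += float((y * (1.0 - mask)).sum())
    mask_pen *= w.beta

    return area, consistency, mask_pen, area + consistency + mask_pen


def exhaustive_graphcut(problem: GraphCutProblem) -> tuple[np.ndarray, float]:
    """Global minimizer of the MRF energy by enumerating every labeling."""
    h, w = problem.x.shape
    n = h * w
    if n > 16:
        raise ValueError("exhaustive enumeration limited to 16 pixels")
    best_y, best_e = None, np.inf
    for bits in itertools.product((0, 1), repeat=n):
        y = np.asarray(bits).reshape(h, w)
        e = graphcut_energy(problem, y)
        if e < best_e:
            best_e, best_y = e, y
    return best_y, best_e
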
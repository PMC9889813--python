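"""Spatially structured empirical Bayes smoothing of small-area rates.

The estimator is the local (neighborhood) moment estimator of Marshall:
each municipality's age-standardized rate is shrunk toward the mean of
its spatial neighborhood, with shrinkage weight driven by how much of the
local variability looks like true between-area heterogeneity rather than
Poisson noise.  Writing D_i = N(i) ∪ {i} for the neighborhood including
the focal unit, with pseudo-counts O*_j = asr_j · n_j:

    m_i   = Σ_{j∈D_i} O*_j / Σ_{j∈D_i} n_j          (neighborhood mean)
    s²_i  = Σ_{j∈D_i} n_j (asr_j − m_i)² / Σ_{j∈D_i} n_j
    A_i   = max(0, s²_i − m_i / n̄_i)                 (between-area variance)
    w_i   = A_i / (A_i + m_i / n_i)                  (0 when both terms 0)
    ebsir = m_i + w_i (asr_i − m_i)

Small municipalities (m_i/n_i large) are pulled strongly toward the
neighborhood mean; large ones keep their raw rate.  A "global" variant
(single neighborhood containing every unit, the Clayton–Kaldor moment
estimator with rate-consistent pseudo-counts) is available for
comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geo import AdjacencyStructure

log = logging.getLogger(__name__)


def local_eb(
    surface: pd.DataFrame,
    adjacency: AdjacencyStructure | None,
    rate_col: str = "asr",
    neighborhood: str = "local",
) -> pd.DataFrame:
    """Empirical Bayes smoothing of per-municipality rates.

    ``surface`` needs columns municipality_id, ``rate_col`` and n_births.
    ``neighborhood`` is "local" (spatial, requires ``adjacency``) or
    "global" (every unit in one pool).  Isolated units (empty neighbor
    set) keep their raw rate and are logged.

    Returns a frame with raw rate, neighborhood mean m_i, shrinkage
    weight w_i ∈ [0, 1] and the smoothed value, which always lies
    between the raw rate and m_i.
    """
    df = surface.set_index("municipality_id")
    ids = df.index.to_list()
    rate = df[rate_col].to_numpy(dtype=float)
    n = df["n_births"].to_numpy(dtype=float)
    if np.any(n < 0):
        raise ValueError("negative denominators")
    pseudo = rate * n  # rate-consistent pseudo-counts

    if neighborhood == "global":
        members = [list(range(len(ids)))] * len(ids)
    elif neighborhood == "local":
        if adjacency is None:
            raise ValueError("local smoothing requires an adjacency structure")
        pos = {mid: k for k, mid in enumerate(ids)}
        missing = [mid for mid in ids if mid not in adjacency.neighbor_sets]
        if missing:
            raise ValueError(f"adjacency lacks municipalities: {missing[:10]}")
        members = []
        isolated = []
        for mid in ids:
            nbrs = adjacency.neighbor_sets[mid]
            if not nbrs:
                isolated.append(mid)
            members.append([pos[mid]] + [pos[j] for j in nbrs if j in pos])
        if isolated:
            log.warning("isolated units smoothed to their raw rate: %s", isolated[:10])
    else:
        raise ValueError(f"unknown neighborhood kind: {neighborhood!r}")

    m = np.empty(len(ids))
    w = np.empty(len(ids))
    for k, idx in enumerate(members):
        idx = np.asarray(idx)
        n_d = n[idx]
        n_sum = n_d.sum()
        if n_sum == 0:
            m[k], w[k] = 0.0, 0.0
            continue
        m_k = pseudo[idx].sum() / n_sum
        s2 = float(np.sum(n_d * (rate[idx] - m_k) ** 2) / n_sum)
        nbar = float(n_d.mean())
        a_k = max(0.0, s2 - (m_k / nbar if nbar > 0 else 0.0))
        noise = m_k / n[k] if n[k] > 0 else 0.0
        denom = a_k + noise
        m[k] = m_k
        w[k] = a_k / denom if denom > 0 else 0.0

    ebsir = m + w * (rate - m)
    # isolated units: neighborhood is {i}, s²=0 ⇒ full shrinkage to m=rate
    out = pd.DataFrame(
        {
            "municipality_id": ids,
            rate_col: rate,
            "neighborhood_mean": m,
            "shrinkage_weight": w,
            "ebsir": ebsir,
        }
    )
    return out


def quantile_classes(values, n_classes: int = 5) -> np.ndarray:
    """Quantile map classes 1..Q; ties at a boundary fall to the lower class."""
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    v = np.asarray(values, dtype=float)
    probs = np.arange(1, n_classes) / n_classes
    bounds = np.quantile(v, probs)
    # count of boundaries strictly below v  →  class index
    return np.searchsorted(bounds, v, side="left") + 1
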
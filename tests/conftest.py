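import math

import numpy as np
import pandas as pd
import pytest

from geonatal.synthetic import PlantedCluster, SyntheticConfig, simulate_birth_records


@pytest.fixture(scope="session")
def small_registry():
    """A small synthetic registry (5x5 grid) with one planted LBW cluster."""
    cfg = SyntheticConfig(
        grid_shape=(5, 5),
        median_births=200.0,
        dispersion=0.8,
        planted_clusters=[PlantedCluster(center_index=12, radius_km=10.5,
                                         relative_risk=2.0, outcome="lbw")],
        seed=7,
    )
    records, counts, truth = simulate_birth_records(cfg)
    return cfg, records, counts, truth


def brute_force_scan(xy, observed, expected, max_fraction=1.0):
    """Independent exhaustive circular-scan oracle: every center × radius.

    Pure-python evaluation of the one-sided Poisson LLR over all distinct
    distance-ordered prefixes, returning (best_llr, best_member_frozenset).
    The size cap is measured in expected counts.
    """
    n = len(observed)
    o_tot = float(sum(observed))
    cap = max_fraction * float(sum(expected))
    best = (0.0, frozenset())
    for c in range(n):
        dists = [math.hypot(xy[j][0] - xy[c][0], xy[j][1] - xy[c][1]) for j in range(n)]
        order = sorted(range(n), key=lambda j: (dists[j], j))
        o_z = e_z = 0.0
        for rank, j in enumerate(order):
            o_z += observed[j]
            e_z += expected[j]
            if rank > 0 and e_z > cap + 1e-9:
                break
            if e_z <= 0:
                continue
            e_out = o_tot - e_z
            o_out = o_tot - o_z
            if e_out <= 0:
                continue
            if o_z / e_z <= o_out / e_out:
                continue
            llr = 0.0
            if o_z > 0:
                llr += o_z * math.log(o_z / e_z)
            if o_out > 0:
                llr += o_out * math.log(o_out / e_out)
            members = frozenset(order[: rank + 1])
            if llr > best[0] + 1e-12:
                best = (llr, members)
    return best
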
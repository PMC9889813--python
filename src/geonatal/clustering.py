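"""Global clustering test and circular Poisson spatial scan.

Two complementary inferential tools over municipality-level observed
counts O_i and (calibrated) expected counts E_i:

* **Tango's general clustering index** C — a quadratic form contrasting
  observed and expected case shares under a distance-decay kernel
  a_ij = exp(−d_ij/λ):

      C = Σ_i Σ_j a_ij (O_i/O₊ − E_i/E₊)(O_j/O₊ − E_j/E₊)

  It answers "is there *any* spatial clustering", without locating it.
  Significance is Monte Carlo: replicate counts are drawn multinomially
  with size O₊ and cell probabilities E_i/E₊ (the constant-risk null),
  and p = (1 + #{C_sim ≥ C_obs}) / (nsim + 1).

* **Circular spatial scan** (Kulldorff–Nagarwalla) — for every candidate
  circular window Z (each municipality as a center, absorbing the others
  in order of distance while the window holds at most ``max_fraction`` of
  all births), the one-sided Poisson log-likelihood ratio

      LLR(Z) = O_Z ln(O_Z/E_Z) + (O₊−O_Z) ln((O₊−O_Z)/(E₊−E_Z))

  when the inside rate exceeds the outside rate, else 0.  The most /
  second / third likely clusters (MLC/SLC/TLC) are the top-ranked
  pairwise-disjoint windows; each window's Monte Carlo p-value compares
  its LLR against the max-LLR distribution of multinomial null
  replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Tango's general clustering statistic
# ---------------------------------------------------------------------------


@dataclass
class TangoResult:
    statistic: float
    lam: float  # kernel scale, km
    p_value: float | None
    nsim: int


def tango_statistic(
    observed: np.ndarray, expected: np.ndarray, dist: np.ndarray, lam: float
) -> float:
    """Tango's C for counts O, E on distance matrix ``dist`` (km)."""
    if lam <= 0:
        raise ValueError("kernel scale lambda must be positive")
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    o_tot, e_tot = o.sum(), e.sum()
    if o_tot <= 0 or e_tot <= 0:
        raise ValueError("totals must be positive")
    r = o / o_tot - e / e_tot
    a = np.exp(-np.asarray(dist, dtype=float) / lam)
    return float(r @ a @ r)


def median_nn_distance(dist: np.ndarray) -> float:
    """Median nearest-neighbor distance — the default kernel scale λ."""
    d = np.asarray(dist, dtype=float).copy()
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def tango_mc_test(
    observed: np.ndarray,
    expected: np.ndarray,
    dist: np.ndarray,
    lam: float | None = None,
    nsim: int = 999,
    seed: int | np.random.Generator | None = None,
) -> TangoResult:
    """Monte Carlo calibration of Tango's C under the constant-risk null."""
    if nsim < 19:
        raise ValueError("nsim < 19 cannot resolve significance at 0.05")
    if lam is None:
        lam = median_nn_distance(dist)
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    o_tot = int(round(o.sum()))
    p = e / e.sum()
    a = np.exp(-np.asarray(dist, dtype=float) / lam)
    c_obs = tango_statistic(o, e, dist, lam)

    rng = np.random.default_rng(seed)
    sims = rng.multinomial(o_tot, p, size=nsim).astype(float)
    r = sims / o_tot - p  # centered shares, one row per replicate
    c_sim = np.einsum("ri,ij,rj->r", r, a, r)
    p_value = (1 + int(np.sum(c_sim >= c_obs - 1e-12))) / (nsim + 1)
    return TangoResult(statistic=c_obs, lam=float(lam), p_value=p_value, nsim=nsim)


# ---------------------------------------------------------------------------
# Circular scan: window family
# ---------------------------------------------------------------------------


@dataclass
class Zone:
    """A circular window: center plus the members absorbed in distance order."""

    center_id: str
    member_ids: tuple[str, ...]
    observed: float
    expected: float
    llr: float


@dataclass
class ClusterReport:
    rank: str  # "MLC", "SLC", "TLC", "4", ...
    member_ids: tuple[str, ...]
    n_municipalities: int
    expected: float
    observed: float
    relative_risk: float  # O/E, the reported form
    kulldorff_rr: float
    llr: float
    p_value: float | None


@dataclass
class ScanConfig:
    max_fraction: float = 0.5
    nsim: int = 1000
    seed: int | None = None
    n_report: int = 3
    direction: str = "high"  # "high" (elevated risk) or "low"

    def __post_init__(self):
        if not 0 < self.max_fraction <= 1:
            raise ValueError("max_fraction must be in (0, 1]")
        if self.direction not in ("high", "low"):
            raise ValueError("direction must be 'high' or 'low'")


def zone_membership(
    dist: np.ndarray, n_births: np.ndarray, max_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-ordered membership and window-size caps for every center.

    Returns ``order`` (n×n; row c lists unit indices by increasing distance
    from center c, ties broken by index, i.e. ascending id for id-sorted
    input) and ``max_len`` (per center, the largest prefix of that row whose
    cumulative births stay within ``max_fraction`` of the total; at least 1
    so every center forms a singleton window).
    """
    d = np.asarray(dist, dtype=float)
    n = np.asarray(n_births, dtype=float)
    order = np.argsort(d, axis=1, kind="stable")
    cap = max_fraction * n.sum()
    cum = np.cumsum(n[order], axis=1)
    max_len = np.maximum((cum <= cap).sum(axis=1), 1)
    return order, max_len


def enumerate_zones(
    ids: list[str],
    dist: np.ndarray,
    n_births: np.ndarray,
    observed: np.ndarray,
    expected: np.ndarray,
    max_fraction: float = 0.5,
    direction: str = "high",
) -> list[Zone]:
    """Materialize the deduplicated circular window family with LLRs."""
    order, max_len = zone_membership(dist, n_births, max_fraction)
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    o_tot = o.sum()
    seen: set[frozenset] = set()
    zones: list[Zone] = []
    for c in range(len(ids)):
        for length in range(1, int(max_len[c]) + 1):
            members = order[c, :length]
            key = frozenset(members.tolist())
            if key in seen:
                continue
            seen.add(key)
            o_z = float(o[members].sum())
            e_z = float(e[members].sum())
            zones.append(
                Zone(
                    center_id=ids[c],
                    member_ids=tuple(ids[m] for m in members),
                    observed=o_z,
                    expected=e_z,
                    llr=poisson_llr(o_z, e_z, o_tot, direction=direction),
                )
            )
    return zones


# ---------------------------------------------------------------------------
# Poisson log-likelihood ratio
# ---------------------------------------------------------------------------


def _xlogy(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(x > 0, x * np.log(np.where(y > 0, y, 1.0)), 0.0)


def poisson_llr(
    o_z: float, e_z: float, o_total: float, direction: str = "high"
) -> float:
    """One-sided Poisson scan LLR for a single window (E₊ = O₊, calibrated)."""
    if e_z <= 0:
        raise ValueError("window expected count must be positive")
    if not 0 <= o_z <= o_total:
        raise ValueError("window observed count outside [0, total]")
    return float(
        poisson_llr_vec(
            np.array([o_z]), np.array([e_z]), o_total, direction=direction
        )[0]
    )


def poisson_llr_vec(
    o_z: np.ndarray, e_z: np.ndarray, o_total: float, direction: str = "high"
) -> np.ndarray:
    """Vectorized scan LLR over windows; zero outside the tested direction."""
    o_z = np.asarray(o_z, dtype=float)
    e_z = np.asarray(e_z, dtype=float)
    e_out = o_total - e_z  # E₊ = O₊ after calibration
    o_out = o_total - o_z
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = np.where(e_z > 0, o_z / np.where(e_z > 0, e_z, 1.0), 0.0)
        outside = np.where(e_out > 0, o_out / np.where(e_out > 0, e_out, 1.0), np.inf)
    llr = _xlogy(o_z, np.where(inside > 0, inside, 1.0)) + _xlogy(
        o_out, np.where(outside > 0, np.where(np.isfinite(outside), outside, 1.0), 1.0)
    )
    active = inside > outside if direction == "high" else inside < outside
    return np.where(active, np.maximum(llr, 0.0), 0.0)


# ---------------------------------------------------------------------------
# Scan test with Monte Carlo inference
# ---------------------------------------------------------------------------


def _all_window_stats(
    counts: np.ndarray, order: np.ndarray, max_len: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative (O, mask) over distance-ordered prefixes for every center."""
    cum = np.cumsum(counts[order], axis=1)
    mask = np.arange(order.shape[1])[None, :] < max_len[:, None]
    return cum, mask


def scan_test(
    ids: list[str],
    observed: np.ndarray,
    expected: np.ndarray,
    dist: np.ndarray,
    config: ScanConfig | None = None,
    n_births: np.ndarray | None = None,
) -> tuple[list[ClusterReport], np.ndarray]:
    """Circular Poisson scan: ranked disjoint clusters with Monte Carlo p.

    ``expected`` must be calibrated (Σ E = Σ O).  The window-size cap is
    measured in births when ``n_births`` is given, otherwise in expected
    cases (proportional to the at-risk population under the null).
    Returns the reports and the null max-LLR distribution (empty when
    ``config.nsim == 0``, in which case p-values are None).
    """
    config = config or ScanConfig()
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    n_units = len(ids)
    o_tot = o.sum()
    if o_tot <= 0:
        raise ValueError("no observed cases")
    if abs(e.sum() - o_tot) > 1e-6 * max(1.0, o_tot):
        raise ValueError("expected counts must be calibrated to the observed total")

    size_measure = e if n_births is None else np.asarray(n_births, dtype=float)
    order, max_len = zone_membership(dist, size_measure, config.max_fraction)
    e_cum, mask = _all_window_stats(e, order, max_len)
    o_cum, _ = _all_window_stats(o, order, max_len)
    llr = poisson_llr_vec(o_cum, e_cum, o_tot, direction=config.direction)
    llr[~mask] = 0.0

    reports = _select_disjoint(
        ids, o, e, o_tot, order, llr, config.n_report, config.direction
    )

    null_max = np.empty(0)
    if config.nsim > 0:
        rng = np.random.default_rng(config.seed)
        p_null = e / e.sum()
        null_max = np.empty(config.nsim)
        for r in range(config.nsim):
            sim = rng.multinomial(int(round(o_tot)), p_null).astype(float)
            s_cum = np.cumsum(sim[order], axis=1)
            s_llr = poisson_llr_vec(s_cum, e_cum, o_tot, direction=config.direction)
            s_llr[~mask] = 0.0
            null_max[r] = s_llr.max()
        for rep in reports:
            rep.p_value = (1 + int(np.sum(null_max >= rep.llr - 1e-12))) / (
                config.nsim + 1
            )
    return reports, null_max


RANK_LABELS = {1: "MLC", 2: "SLC", 3: "TLC"}


def _select_disjoint(
    ids, o, e, o_tot, order, llr, n_report, direction
) -> list[ClusterReport]:
    """Greedy top-LLR selection of pairwise-disjoint windows."""
    flat = np.argsort(llr, axis=None)[::-1]
    taken: set[int] = set()
    reports: list[ClusterReport] = []
    n = order.shape[1]
    for f in flat:
        if len(reports) >= n_report:
            break
        c, length = divmod(int(f), n)
        val = float(llr[c, length])
        if val <= 0:
            break
        members = order[c, : length + 1]
        if taken.intersection(members.tolist()):
            continue
        taken.update(members.tolist())
        o_z = float(o[members].sum())
        e_z = float(e[members].sum())
        reports.append(
            ClusterReport(
                rank=RANK_LABELS.get(len(reports) + 1, str(len(reports) + 1)),
                member_ids=tuple(ids[m] for m in members),
                n_municipalities=len(members),
                expected=e_z,
                observed=o_z,
                relative_risk=reported_rr(o_z, e_z),
                kulldorff_rr=kulldorff_rr(o_z, e_z, o_tot),
                llr=val,
                p_value=None,
            )
        )
    return reports


def reported_rr(o_z: float, e_z: float) -> float:
    """Relative risk as reported in cluster tables: observed/expected."""
    if e_z <= 0:
        raise ValueError("expected must be positive")
    return o_z / e_z


def kulldorff_rr(o_z: float, e_z: float, o_tot: float) -> float:
    """Inside/outside risk ratio (O_Z/E_Z) / ((O₊−O_Z)/(E₊−E_Z))."""
    e_out = o_tot - e_z
    o_out = o_tot - o_z
    inside = o_z / e_z
    if e_out <= 0 or o_out <= 0:
        return float("inf") if inside > 0 else float("nan")
    return inside / (o_out / e_out)


def reports_to_frame(reports: list[ClusterReport]) -> pd.DataFrame:
    """Cluster reports as a flat table (member ids semicolon-joined)."""
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "n_municipalities": r.n_municipalities,
                "expected": r.expected,
                "observed": r.observed,
                "relative_risk": r.relative_risk,
                "kulldorff_rr": r.kulldorff_rr,
                "llr": r.llr,
                "p_value": r.p_value,
                "member_ids": ";".join(r.member_ids),
            }
            for r in reports
        ],
        columns=[
            "rank", "n_municipalities", "expected", "observed",
            "relative_risk", "kulldorff_rr", "llr", "p_value", "member_ids",
        ],
    )
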
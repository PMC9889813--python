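import numpy as np
import pytest

from conftest import brute_force_scan
from geonatal.clustering import (
    ScanConfig,
    enumerate_zones,
    kulldorff_rr,
    median_nn_distance,
    poisson_llr,
    reported_rr,
    scan_test,
    tango_mc_test,
    tango_statistic,
)
from geonatal.rates import round_half_up


def _random_instance(rng, n_units, scale=30.0):
    """Random planar instance with multinomial counts under mild heterogeneity."""
    xy = rng.uniform(0, scale, size=(n_units, 2))
    dist = np.hypot(
        xy[:, 0][:, None] - xy[:, 0][None, :], xy[:, 1][:, None] - xy[:, 1][None, :]
    )
    e = rng.uniform(1.0, 20.0, n_units)
    total = int(rng.integers(50, 200))
    p = rng.dirichlet(e)  # heterogeneous risk so clusters exist
    o = rng.multinomial(total, p).astype(float)
    e = e * o.sum() / e.sum()  # calibrate
    return xy, dist, o, e


# --------------------------------------------------------------------- Tango


def test_tango_zero_when_shares_match():
    d = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert tango_statistic([10, 30], [1.0, 3.0], d, lam=5.0) == pytest.approx(0.0, abs=1e-15)


def test_tango_small_lambda_limit_is_sum_of_squares():
    rng = np.random.default_rng(20)
    xy = rng.uniform(0, 10, (5, 2))
    d = np.hypot(xy[:, 0][:, None] - xy[:, 0], xy[:, 1][:, None] - xy[:, 1])
    o = rng.integers(1, 20, 5).astype(float)
    e = rng.uniform(1, 10, 5)
    r = o / o.sum() - e / e.sum()
    assert tango_statistic(o, e, d, lam=1e-3) == pytest.approx(np.sum(r**2), abs=1e-12)


def test_tango_matches_double_loop_oracle():
    rng = np.random.default_rng(21)
    for _ in range(5):
        xy = rng.uniform(0, 50, (6, 2))
        d = np.hypot(xy[:, 0][:, None] - xy[:, 0], xy[:, 1][:, None] - xy[:, 1])
        o = rng.integers(0, 30, 6).astype(float)
        o[0] += 1  # ensure positive total
        e = rng.uniform(0.5, 10, 6)
        lam = rng.uniform(1, 20)
        # independent O(n^2) summation
        ro = o / o.sum()
        re = e / e.sum()
        expected = sum(
            np.exp(-d[i, j] / lam) * (ro[i] - re[i]) * (ro[j] - re[j])
            for i in range(6)
            for j in range(6)
        )
        assert tango_statistic(o, e, d, lam) == pytest.approx(expected, abs=1e-12)
        assert tango_statistic(o, e, d, lam) >= -1e-12  # PSD kernel


def test_tango_rejects_bad_lambda():
    d = np.zeros((2, 2))
    with pytest.raises(ValueError):
        tango_statistic([1, 1], [1, 1], d, lam=0.0)


def test_tango_mc_p_floor_and_determinism():
    rng = np.random.default_rng(22)
    xy = rng.uniform(0, 20, (8, 2))
    d = np.hypot(xy[:, 0][:, None] - xy[:, 0], xy[:, 1][:, None] - xy[:, 1])
    e = np.full(8, 10.0)
    o = np.array([70, 2, 1, 1, 2, 1, 2, 1], dtype=float)  # extreme clustering
    res = tango_mc_test(o, e * o.sum() / e.sum(), d, nsim=999, seed=4)
    assert res.p_value == pytest.approx(1 / 1000)
    res2 = tango_mc_test(o, e * o.sum() / e.sum(), d, nsim=999, seed=4)
    assert res2.p_value == res.p_value and res2.statistic == res.statistic


def test_tango_mc_rejects_tiny_nsim():
    d = np.zeros((2, 2))
    with pytest.raises(ValueError):
        tango_mc_test([1, 1], [1, 1], d, nsim=9)


def test_tango_null_calibration():
    """Null rejection rate at alpha=0.05 sits inside the binomial band."""
    rng = np.random.default_rng(23)
    n_units = 20
    xy = rng.uniform(0, 40, (n_units, 2))
    d = np.hypot(xy[:, 0][:, None] - xy[:, 0], xy[:, 1][:, None] - xy[:, 1])
    e = rng.uniform(2, 20, n_units)
    p = e / e.sum()
    rejections = 0
    n_rep = 200
    for r in range(n_rep):
        o = rng.multinomial(400, p).astype(float)
        res = tango_mc_test(o, e * 400 / e.sum(), d, nsim=99, seed=1000 + r)
        rejections += res.p_value <= 0.05
    assert 0.01 <= rejections / n_rep <= 0.10


def test_median_nn_distance():
    d = np.array([[0, 1, 5], [1, 0, 2], [5, 2, 0]], dtype=float)
    assert median_nn_distance(d) == 1.0  # NN distances 1, 1, 2


# ----------------------------------------------------------------- LLR & RR


def test_poisson_llr_inactive_branches():
    assert poisson_llr(10, 10.0, 100) == 0.0
    assert poisson_llr(5, 10.0, 100) == 0.0  # one-sided, low side
    assert poisson_llr(5, 10.0, 100, direction="low") > 0.0


def test_poisson_llr_closed_form():
    # frozen independent evaluation: 20 ln 2 + 80 ln(80/90)
    assert poisson_llr(20, 10.0, 100) == pytest.approx(4.440300758688226, abs=1e-12)


def test_poisson_llr_monotone_in_observed():
    prev = 0.0
    for o_z in range(11, 60):
        llr = poisson_llr(o_z, 10.0, 100)
        assert llr >= prev - 1e-12
        prev = llr


def test_poisson_llr_errors():
    with pytest.raises(ValueError):
        poisson_llr(5, 0.0, 100)
    with pytest.raises(ValueError):
        poisson_llr(101, 10.0, 100)


@pytest.mark.parametrize(
    "observed,expected,printed",
    [
        (15174, 12672.10, 1.20),
        (12890, 11743.66, 1.10),
        (106, 68.49, 1.55),
        (206, 123.41, 1.67),
        (28, 13.05, 2.15),
    ],
)
def test_reported_rr_matches_printed_cluster_rows(observed, expected, printed):
    assert round_half_up(reported_rr(observed, expected), 2) == printed


def test_kulldorff_rr_exceeds_reported_for_hot_cluster():
    # removing the cluster from the reference makes the ratio strictly larger
    assert kulldorff_rr(20, 10.0, 100) > reported_rr(20, 10.0)


# -------------------------------------------------------------------- zones


def test_enumerate_zones_single_unit():
    zones = enumerate_zones(["A"], np.zeros((1, 1)), np.array([5.0]),
                            np.array([2.0]), np.array([2.0]), max_fraction=1.0)
    assert len(zones) == 1 and zones[0].member_ids == ("A",)


def test_enumerate_zones_three_on_line_dedup():
    # hand enumeration: {0},{1},{2},{01},{12},{012} -> 6 distinct windows
    dist = np.abs(np.arange(3)[:, None] - np.arange(3)[None, :]).astype(float)
    n = np.full(3, 10.0)
    o = np.array([1.0, 2.0, 3.0])
    e = o.copy()
    zones = enumerate_zones(["A", "B", "C"], dist, n, o, e, max_fraction=1.0)
    assert len(zones) == 6
    member_sets = {frozenset(z.member_ids) for z in zones}
    assert frozenset({"A", "B", "C"}) in member_sets


def test_enumerate_zones_respects_cap():
    dist = np.abs(np.arange(4)[:, None] - np.arange(4)[None, :]).astype(float)
    n = np.full(4, 10.0)
    zones = enumerate_zones(list("ABCD"), dist, n, n, n, max_fraction=0.5)
    assert max(len(z.member_ids) for z in zones) == 2


# --------------------------------------------------------------------- scan


def test_scan_mlc_matches_exhaustive_oracle_many_instances():
    rng = np.random.default_rng(30)
    for _ in range(20):
        n_units = int(rng.integers(4, 11))
        xy, dist, o, e = _random_instance(rng, n_units)
        reports, _ = scan_test(
            [f"M{i}" for i in range(n_units)], o, e, dist,
            ScanConfig(max_fraction=1.0, nsim=0, n_report=1),
        )
        best_llr, best_members = brute_force_scan(xy, o, e, max_fraction=1.0)
        if best_llr == 0.0:
            assert reports == []
            continue
        assert reports[0].llr == pytest.approx(best_llr, abs=1e-9)
        got = frozenset(int(m[1:]) for m in reports[0].member_ids)
        assert got == best_members


def test_scan_relabeling_leaves_llr_unchanged():
    rng = np.random.default_rng(31)
    xy, dist, o, e = _random_instance(rng, 9)
    ids = [f"M{i}" for i in range(9)]
    r1, _ = scan_test(ids, o, e, dist, ScanConfig(nsim=0, max_fraction=1.0))
    perm = rng.permutation(9)
    r2, _ = scan_test(
        [ids[p] for p in perm], o[perm], e[perm], dist[np.ix_(perm, perm)],
        ScanConfig(nsim=0, max_fraction=1.0),
    )
    assert [x.llr for x in r1] == pytest.approx([x.llr for x in r2], abs=1e-9)
    assert [frozenset(x.member_ids) for x in r1] == [frozenset(x.member_ids) for x in r2]


def test_scan_reports_disjoint_and_ranked():
    rng = np.random.default_rng(32)
    xy, dist, o, e = _random_instance(rng, 30, scale=100.0)
    reports, _ = scan_test(
        [f"M{i}" for i in range(30)], o, e, dist,
        ScanConfig(max_fraction=0.5, nsim=99, seed=5),
    )
    members = [set(r.member_ids) for r in reports]
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            assert not members[i] & members[j]
    llrs = [r.llr for r in reports]
    assert llrs == sorted(llrs, reverse=True)
    for r in reports:
        assert 1 / 100 <= r.p_value <= 1.0


def test_scan_same_seed_identical_reports():
    rng = np.random.default_rng(33)
    xy, dist, o, e = _random_instance(rng, 15)
    ids = [f"M{i}" for i in range(15)]
    cfg = ScanConfig(nsim=199, seed=9)
    r1, null1 = scan_test(ids, o, e, dist, cfg)
    r2, null2 = scan_test(ids, o, e, dist, cfg)
    assert (null1 == null2).all()
    assert [(x.llr, x.p_value, x.member_ids) for x in r1] == [
        (x.llr, x.p_value, x.member_ids) for x in r2
    ]


def test_scan_planted_cluster_recovered():
    """A strong planted cluster (RR=3, large counts) is the MLC."""
    rng = np.random.default_rng(34)
    side = 7
    xy = np.array([(x, y) for x in range(side) for y in range(side)], dtype=float)
    n_units = side * side
    dist = np.hypot(xy[:, 0][:, None] - xy[:, 0], xy[:, 1][:, None] - xy[:, 1])
    center = 24  # middle of the grid
    in_cluster = dist[center] <= 1.0  # plus-shaped 5-unit zone
    base = np.full(n_units, 50.0)
    lam = base * np.where(in_cluster, 3.0, 1.0)
    o = rng.poisson(lam).astype(float)
    e = base * o.sum() / base.sum()
    reports, _ = scan_test([f"M{i}" for i in range(n_units)], o, e, dist,
                           ScanConfig(nsim=99, seed=6))
    got = {int(m[1:]) for m in reports[0].member_ids}
    truth = set(np.where(in_cluster)[0])
    jacc = len(got & truth) / len(got | truth)
    assert jacc >= 0.6
    assert reports[0].p_value == pytest.approx(1 / 100)


def test_scan_null_no_positive_llr():
    # two units with identical shares: no window elevates the rate
    dist = np.array([[0.0, 1.0], [1.0, 0.0]])
    o = np.array([10.0, 10.0])
    e = np.array([10.0, 10.0])
    reports, null_max = scan_test(["A", "B"], o, e, dist,
                                  ScanConfig(nsim=49, seed=1, max_fraction=1.0))
    assert reports == []
    assert len(null_max) == 49


def test_scan_requires_calibrated_expected():
    dist = np.zeros((2, 2))
    with pytest.raises(ValueError):
        scan_test(["A", "B"], np.array([5.0, 5.0]), np.array([2.0, 2.0]), dist,
                  ScanConfig(nsim=0))
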
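"""Synthetic municipality birth data with planted spatial clusters.

Real vital-registration microdata on births is access-restricted, so
every stage of the pipeline is exercised on simulated municipality
systems built to echo the national registry's gross features:

* a planar grid (or random scatter) of centroids in km, optionally with
  square polygons so queen contiguity is testable;
* heavy-tailed birth denominators — municipality totals are log-normal,
  spanning small islands to metropolitan wards;
* a 9-class maternal-age profile whose coarse shares reproduce the
  national reporting strata (≈2.2% ≤20, ≈76.6% (20,35], ≈21.1% >35);
* age-specific baseline outcome rates with the familiar U-shape in
  maternal age, scaled so the pooled national proportions sit near
  LBW 8.2%, PTB 4.7%, LBW-at-term 5.2%, LBW-preterm 3.0%;
* circular planted clusters multiplying the baseline risk of a chosen
  outcome (relative risks in the 1.1–2.2 range typical of published
  municipal cluster analyses).

Everything is driven by one integer seed; the same config and seed
reproduce every table bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import N_AGE_CLASSES
from .geo import MunicipalityGeo

try:  # square polygons only needed for queen-contiguity runs
    from shapely.geometry import box
except ImportError:  # pragma: no cover
    box = None

#: fine age-class shares; coarse sums: 1+2 → 2.2%, 3–5 → 76.5%, 6–9 → 21.3%
DEFAULT_AGE_PROFILE = (
    0.002, 0.020, 0.105, 0.280, 0.380, 0.170, 0.040, 0.0028, 0.0002,
)

#: relative risk of each age class against the population mean (U-shaped)
AGE_RISK_SHAPE = (1.45, 1.25, 1.05, 0.95, 0.95, 1.05, 1.25, 1.40, 1.50)

#: pooled target proportions for the three non-reference outcome groups
DEFAULT_GROUP_TARGETS = {"lbwterm": 0.0523, "lbwpre": 0.0300, "nbwpre": 0.0174}


@dataclass
class PlantedCluster:
    center_index: int
    radius_km: float
    relative_risk: float
    outcome: str = "lbw"  # lbw | ptb | lbwterm | lbwpre


@dataclass
class SyntheticConfig:
    """Full recipe for one reproducible simulated registry."""

    grid_shape: tuple[int, int] = (15, 15)
    spacing_km: float = 10.0
    layout: str = "grid"  # "grid" | "random"
    n_random: int = 225  # used when layout == "random"
    median_births: float = 400.0  # log-normal median of municipality totals
    dispersion: float = 1.2  # log-normal sigma (4+ orders of magnitude tails)
    age_profile: tuple[float, ...] = DEFAULT_AGE_PROFILE
    group_targets: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_TARGETS))
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    seed: int = 0
    with_polygons: bool = False

    def __post_init__(self):
        prof = np.asarray(self.age_profile, dtype=float)
        if len(prof) != N_AGE_CLASSES or abs(prof.sum() - 1.0) > 1e-9:
            raise ValueError("age_profile must be 9 shares summing to 1")
        for pc in self.planted_clusters:
            if pc.relative_risk <= 0:
                raise ValueError("planted relative risk must be positive")


def baseline_group_rates(config: SyntheticConfig) -> pd.DataFrame:
    """Age-specific rates per outcome group, scaled to the pooled targets.

    Each group's class-a rate is target · shape_a / Σ_b profile_b shape_b,
    so that Σ_a profile_a · rate_a equals the configured pooled proportion.
    """
    prof = np.asarray(config.age_profile)
    shape = np.asarray(AGE_RISK_SHAPE)
    norm = float(prof @ shape)
    rows = {
        group: target * shape / norm
        for group, target in config.group_targets.items()
    }
    return pd.DataFrame(rows, index=pd.RangeIndex(1, N_AGE_CLASSES + 1, name="age_class"))


def generate_municipalities(config: SyntheticConfig) -> list[MunicipalityGeo]:
    """Planar centroids in km (``lat``/``lon`` hold y/x) with optional squares."""
    rng = np.random.default_rng(config.seed)
    if config.layout == "grid":
        rows, cols = config.grid_shape
        ys, xs = np.mgrid[0:rows, 0:cols]
        xy = np.column_stack([xs.ravel(), ys.ravel()]) * config.spacing_km
    elif config.layout == "random":
        side = config.spacing_km * np.sqrt(config.n_random)
        xy = rng.uniform(0, side, size=(config.n_random, 2))
    else:
        raise ValueError(f"unknown layout: {config.layout!r}")
    width = len(str(len(xy) - 1))
    geos = []
    for i, (x, y) in enumerate(xy):
        poly = None
        if config.with_polygons and config.layout == "grid":
            h = config.spacing_km / 2
            poly = box(x - h, y - h, x + h, y + h)
        geos.append(
            MunicipalityGeo(
                municipality_id=f"M{i:0{width}d}", lat=float(y), lon=float(x),
                polygon=poly,
            )
        )
    return geos


def generate_denominators(config: SyntheticConfig) -> pd.DataFrame:
    """Municipality × age-class birth denominators (log-normal totals)."""
    geos = generate_municipalities(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_units = len(geos)
    totals = np.maximum(
        1,
        np.rint(
            np.exp(rng.normal(np.log(config.median_births), config.dispersion, n_units))
        ).astype(int),
    )
    prof = np.asarray(config.age_profile)
    rows = []
    for g, tot in zip(geos, totals):
        split = rng.multinomial(tot, prof)
        for a in range(N_AGE_CLASSES):
            rows.append((g.municipality_id, a + 1, int(split[a])))
    return pd.DataFrame(rows, columns=["municipality_id", "age_class", "n_births"])


def plant_risk_surface(
    geos: list[MunicipalityGeo], config: SyntheticConfig
) -> pd.DataFrame:
    """Per-unit relative-risk multipliers per outcome (product over clusters)."""
    ids = [g.municipality_id for g in geos]
    xy = np.array([[g.lon, g.lat] for g in geos])
    rr = pd.DataFrame(
        1.0, index=pd.Index(ids, name="municipality_id"),
        columns=["lbw", "ptb", "lbwterm", "lbwpre"],
    )
    for pc in config.planted_clusters:
        center = xy[pc.center_index]
        covered = np.hypot(*(xy - center).T) <= pc.radius_km + 1e-9
        rr.loc[covered, pc.outcome] *= pc.relative_risk
    return rr


def _group_multipliers(rr_row: pd.Series) -> np.ndarray:
    """Map outcome-level multipliers onto the three case groups.

    LBW-family multipliers act on both LBW subgroups; the PTB multiplier
    additionally acts on the preterm groups.  Order: lbwterm, lbwpre, nbwpre.
    """
    return np.array(
        [
            rr_row["lbw"] * rr_row["lbwterm"],
            rr_row["lbw"] * rr_row["ptb"] * rr_row["lbwpre"],
            rr_row["ptb"],
        ]
    )


def simulate_cases(
    denominators: pd.DataFrame,
    rates: pd.Series | np.ndarray,
    risk_multipliers: pd.Series | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Poisson case counts for one outcome: O_ia ~ Poi(n_ia ρ_a RR_i), O ≤ n.

    ``rates`` gives the baseline per-class rates ρ_a (index 1..9);
    ``risk_multipliers`` the per-municipality RR_i (default 1).  Raises if
    any ρ_a·RR_i exceeds 1.
    """
    rho = pd.Series(np.asarray(rates, dtype=float),
                    index=pd.RangeIndex(1, N_AGE_CLASSES + 1))
    df = denominators.copy()
    rr = (
        pd.Series(1.0, index=df["municipality_id"].unique())
        if risk_multipliers is None
        else risk_multipliers
    )
    lam_rate = df["age_class"].map(rho).to_numpy() * df["municipality_id"].map(rr).to_numpy()
    if np.any(lam_rate > 1.0 + 1e-12):
        raise ValueError("rate × RR exceeds 1 in some stratum")
    rng = np.random.default_rng(seed)
    draws = rng.poisson(lam_rate * df["n_births"].to_numpy())
    df["n_cases"] = np.minimum(draws, df["n_births"].to_numpy())
    return df


# age-class bounds used to draw integer maternal ages for record mode
_AGE_BOUNDS = [(13, 15), (16, 20), (21, 25), (26, 30), (31, 35),
               (36, 40), (41, 45), (46, 50), (51, 54)]

# per-group (weight range, gestation range) for plausible record values
_GROUP_VALUE_RANGES = {
    "NBW_term": ((2500, 4200), (37, 42)),
    "LBW_term": ((1500, 2499), (37, 42)),
    "LBW_pre": ((500, 2499), (22, 36)),
    "NBW_pre": ((2500, 3400), (32, 36)),
}


def simulate_birth_records(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full registry simulation: birth records + exact bookkeeping counts.

    Per stratum (municipality × age class) the four outcome groups are
    drawn from one multinomial over (NBW_term, LBW_term, LBW_pre,
    NBW_pre) probabilities, so the partition identities hold exactly and
    aggregating the emitted records reproduces the returned count table
    bit-for-bit.  Returns (records, counts, truth) where counts has the
    aggregated-count-table schema and truth the per-unit planted RRs.
    """
    geos = generate_municipalities(config)
    denom = generate_denominators(config)
    rr = plant_risk_surface(geos, config)
    group_rates = baseline_group_rates(config)  # columns lbwterm, lbwpre, nbwpre

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    rec_rows = []
    count_rows = []
    years = np.arange(2012, 2017)
    for row in denom.itertuples():
        mid, a, n = row.municipality_id, row.age_class, row.n_births
        mult = _group_multipliers(rr.loc[mid])
        p = group_rates.loc[a, ["lbwterm", "lbwpre", "nbwpre"]].to_numpy() * mult
        if p.sum() > 1:
            raise ValueError(f"group rates × RR exceed 1 in stratum ({mid}, {a})")
        k_term, k_pre, k_nbwpre = rng.multinomial(n, np.append(p, 1 - p.sum()))[:3]
        count_rows.append(
            (mid, a, n, k_term + k_pre, k_pre + k_nbwpre, k_term, k_pre)
        )
        if n == 0:
            continue
        groups = (["LBW_term"] * k_term + ["LBW_pre"] * k_pre
                  + ["NBW_pre"] * k_nbwpre
                  + ["NBW_term"] * (n - k_term - k_pre - k_nbwpre))
        lo_a, hi_a = _AGE_BOUNDS[a - 1]
        ages = rng.integers(lo_a, hi_a + 1, size=n)
        for grp, age in zip(groups, ages):
            (w_lo, w_hi), (g_lo, g_hi) = _GROUP_VALUE_RANGES[grp]
            rec_rows.append(
                (
                    mid,
                    int(rng.choice(years)),
                    int(rng.integers(w_lo, w_hi + 1)),
                    int(rng.integers(g_lo, g_hi + 1)),
                    int(age),
                    1,
                    "male" if rng.random() < 0.513 else "female",
                )
            )
    records = pd.DataFrame(
        rec_rows,
        columns=["municipality_id", "year", "birthweight_g",
                 "gestational_weeks", "maternal_age", "plurality", "sex"],
    )
    counts = pd.DataFrame(
        count_rows,
        columns=["municipality_id", "age_class", "n_births", "n_cases_lbw",
                 "n_cases_ptb", "n_cases_lbwterm", "n_cases_lbwpre"],
    )
    truth = rr.reset_index()
    return records, counts, truth


def planted_member_ids(config: SyntheticConfig) -> dict[int, list[str]]:
    """Ids covered by each planted cluster (for scoring recovery)."""
    geos = generate_municipalities(config)
    xy = np.array([[g.lon, g.lat] for g in geos])
    ids = np.array([g.municipality_id for g in geos])
    out = {}
    for k, pc in enumerate(config.planted_clusters):
        covered = np.hypot(*(xy - xy[pc.center_index]).T) <= pc.radius_km + 1e-9
        out[k] = ids[covered].tolist()
    return out
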
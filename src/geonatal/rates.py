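"""Crude, directly age-standardized and indirectly standardized incidence.

Direct standardization weights each municipality's stratum-specific rates
r_ia = O_ia / n_ia by a reference age structure W_a (ASR = Σ_a W_a r_ia).
Empty strata are handled by imputing a very small denominator (1e-4) with
a zero numerator, so they contribute zero rate mass instead of a division
failure.

Indirect standardization multiplies each municipality's stratum
denominators by pooled national stratum rates ρ_a, giving expected counts
E_i = Σ_a n_ia ρ_a; after multiplicative calibration Σ E_i = Σ O_i
exactly, so O_i/E_i is a standardized incidence ratio.  Expected counts
feed the clustering statistics; direct ASRs feed the smoothed maps.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .cohort import N_AGE_CLASSES, REPORTING_STRATA, classify_records

#: denominator imputed into empty age strata for direct standardization
EMPTY_STRATUM_EPSILON = 1e-4


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used in printed report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def crude_rate(observed: float, n: float) -> float:
    """Cases per birth; NaN (never 0) when the denominator is empty."""
    if observed > n:
        raise ValueError(f"observed {observed} exceeds denominator {n}")
    if n == 0:
        return float("nan")
    return observed / n


def outcome_proportion(count: int, total: int) -> float:
    """Percentage 100·count/total, display-rounded half-up to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count > total:
        raise ValueError(f"count {count} exceeds total {total}")
    return round_half_up(100.0 * count / total, 2)


def reference_weights_from_counts(counts: pd.DataFrame) -> pd.Series:
    """Reference age structure W_a = pooled births share per age class."""
    pooled = counts.groupby("age_class")["n_births"].sum()
    pooled = pooled.reindex(range(1, N_AGE_CLASSES + 1), fill_value=0)
    total = pooled.sum()
    if total == 0:
        raise ValueError("no births in pooled counts")
    return pooled / total


def read_reference_weights(path) -> pd.Series:
    """Read reference weights CSV ``age_class,weight``; must sum to 1."""
    df = pd.read_csv(path)
    w = df.set_index("age_class")["weight"].reindex(
        range(1, N_AGE_CLASSES + 1), fill_value=0.0
    )
    if abs(w.sum() - 1.0) > 1e-12:
        raise ValueError(f"reference weights sum to {w.sum()}, expected 1")
    return w


def direct_asr(
    municipality_counts: pd.DataFrame,
    ref_weights: pd.Series,
    case_col: str,
    epsilon: float = EMPTY_STRATUM_EPSILON,
) -> float:
    """Direct age-standardized rate for one municipality's 9-class table."""
    tab = municipality_counts.set_index("age_class").reindex(
        range(1, N_AGE_CLASSES + 1), fill_value=0
    )
    n = tab["n_births"].to_numpy(dtype=float)
    o = tab[case_col].to_numpy(dtype=float)
    if np.any(n < 0) or np.any(o < 0):
        raise ValueError("negative counts")
    n = np.where(n == 0, epsilon, n)  # empty stratum: rate becomes 0/eps = 0
    r = o / n
    w = ref_weights.reindex(range(1, N_AGE_CLASSES + 1), fill_value=0.0).to_numpy()
    return float(np.dot(w, r))


def national_age_rates(counts: pd.DataFrame, case_col: str) -> pd.Series:
    """Pooled per-class rates ρ_a = Σ_i O_ia / Σ_i n_ia (0 for empty classes)."""
    g = counts.groupby("age_class").agg(o=(case_col, "sum"), n=("n_births", "sum"))
    g = g.reindex(range(1, N_AGE_CLASSES + 1), fill_value=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(g["n"] > 0, g["o"] / g["n"], 0.0)
    return pd.Series(rho, index=g.index, name="rho")


def indirect_expected(
    counts: pd.DataFrame, rho: pd.Series, case_col: str
) -> pd.DataFrame:
    """Age-adjusted expected counts per municipality, calibrated to Σ E = Σ O.

    Raw E_i = Σ_a n_ia ρ_a; a multiplicative factor Σ O / Σ E then makes
    totals match exactly (a no-op when ρ was derived from the same pooled
    data).  Returns a frame indexed by municipality with O_i, E_i, n_i.
    """
    df = counts.copy()
    df["e_stratum"] = df["n_births"] * df["age_class"].map(rho)
    per_unit = df.groupby("municipality_id").agg(
        observed=(case_col, "sum"),
        expected=("e_stratum", "sum"),
        n_births=("n_births", "sum"),
    )
    total_o = per_unit["observed"].sum()
    total_e = per_unit["expected"].sum()
    if total_e == 0:
        if total_o > 0:
            raise ValueError("expected counts are all zero but cases observed")
        return per_unit
    per_unit["expected"] *= total_o / total_e
    return per_unit


def rate_surface(
    counts: pd.DataFrame,
    case_col: str,
    ref_weights: pd.Series | None = None,
    epsilon: float = EMPTY_STRATUM_EPSILON,
) -> pd.DataFrame:
    """Per-municipality crude rate, direct ASR, observed and expected counts."""
    if ref_weights is None:
        ref_weights = reference_weights_from_counts(counts)
    rho = national_age_rates(counts, case_col)
    surface = indirect_expected(counts, rho, case_col)
    with np.errstate(invalid="ignore", divide="ignore"):
        surface["crude_rate"] = np.where(
            surface["n_births"] > 0,
            surface["observed"] / surface["n_births"],
            np.nan,
        )
    asr = counts.groupby("municipality_id", sort=True).apply(
        lambda g: direct_asr(g, ref_weights, case_col, epsilon),
        include_groups=False,
    )
    surface["asr"] = asr
    return surface.reset_index()


def summary_table(records: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics by outcome group, in the style of a Table-1.

    Rows: totals, survey-year counts/percentages, sex, coarse maternal-age
    strata, and mean plus interquartile range of birthweight and
    gestational age; columns: Total, LBW, Preterm, LBWterm, LBWpre.
    """
    df = records if "group" in records.columns else classify_records(records)
    cols = {
        "Total": pd.Series(True, index=df.index),
        "LBW": df["is_lbw"],
        "Preterm": df["is_preterm"],
        "LBWterm": df["group"] == "LBW_term",
        "LBWpre": df["group"] == "LBW_pre",
    }
    rows: list[dict] = []

    def add(section: str, level: str, fn) -> None:
        row: dict = {"section": section, "level": level}
        for name, mask in cols.items():
            row[name] = fn(df.loc[mask])
        rows.append(row)

    add("N", "", len)
    for year in sorted(df["year"].dropna().unique()):
        add("Survey year", str(int(year)),
            lambda d, y=year: int((d["year"] == y).sum()))
    for sex in ("male", "female"):
        add("Sex", sex, lambda d, s=sex: int((d["sex"] == s).sum()))
    for stratum in REPORTING_STRATA:
        add("Maternal age", stratum,
            lambda d, s=stratum: int((d["reporting_stratum"] == s).sum()))
    add("Birthweight mean", "g", lambda d: round_half_up(d["birthweight_g"].mean(), 1))
    add("Birthweight IQR", "g",
        lambda d: tuple(d["birthweight_g"].quantile([0.25, 0.75])))
    add("Gestational age mean", "wk",
        lambda d: round_half_up(d["gestational_weeks"].mean(), 1))
    add("Gestational age IQR", "wk",
        lambda d: tuple(d["gestational_weeks"].quantile([0.25, 0.75])))
    out = pd.DataFrame(rows)

    # percentage companions for the count sections
    totals = {name: int(cols[name].sum()) for name in cols}
    for name in cols:
        out[f"{name}_pct"] = [
            round_half_up(100.0 * v / totals[name], 1)
            if isinstance(v, (int, np.integer)) and r_sec not in ("N",) and totals[name]
            else np.nan
            for v, r_sec in zip(out[name], out["section"])
        ]
    return out
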
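"""End-to-end orchestration: cohort → rates → smoothing → Tango → scan.

One run covers every requested outcome × maternal-age stratum cell
(default: LBW, PTB, LBW_term, LBW_pre × {all, ≤20, (20,35], >35}) and
writes, per cell, the rate surface, the smoothed (EBSIR) surface, the
Tango global-clustering result and the ranked cluster report, plus a
Table-1-style cohort summary and a JSON manifest (config hash, seed,
package versions) sufficient to reproduce the bundle byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort, geo, rates, smoothing
from .clustering import (
    ScanConfig,
    reports_to_frame,
    scan_test,
    tango_mc_test,
)
from .rates import round_half_up

log = logging.getLogger(__name__)

STRATA = ("all",) + cohort.REPORTING_STRATA
#: fine age classes belonging to each coarse reporting stratum
STRATUM_CLASSES = {
    "all": tuple(range(1, 10)),
    "<=20": (1, 2),
    "(20,35]": (3, 4, 5),
    ">35": (6, 7, 8, 9),
}


@dataclass
class PipelineConfig:
    records_path: str | None = None
    geometry_path: str | None = None  # CSV centroids or GeoJSON polygons
    reference_weights_path: str | None = None
    out_dir: str = "out"
    outcomes: tuple[str, ...] = cohort.OUTCOMES
    strata: tuple[str, ...] = STRATA
    adjacency: str = "knn"  # "queen" | "knn"
    knn_k: int = 8
    metric: str = "haversine"  # "haversine" | "planar"
    scan: ScanConfig = field(default_factory=ScanConfig)
    tango_lambda: float | None = None  # km; None → median NN distance
    tango_nsim: int = 999
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        scan_raw = raw.pop("scan", {})
        cfg = cls(**raw)
        cfg.scan = ScanConfig(**scan_raw)
        return cfg

    def to_dict(self) -> dict:
        # analysis-relevant parameters only: the output location does not
        # affect results and must not perturb the config hash
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_adjacency(geos, config: PipelineConfig):
    if config.adjacency == "queen":
        return geo.queen_adjacency(geos)
    if config.adjacency == "knn":
        return geo.knn_adjacency(geos, k=config.knn_k, metric=config.metric)
    raise ValueError(f"unknown adjacency kind: {config.adjacency!r}")


def analyze_counts(
    counts: pd.DataFrame,
    geos: list[geo.MunicipalityGeo],
    config: PipelineConfig,
    outcome: str,
    stratum: str = "all",
    adjacency=None,
    seed: int | None = None,
) -> dict:
    """One analysis cell: rate surface, EBSIR, Tango test and scan report.

    ``stratum`` restricts the count table to the fine age classes in that
    coarse reporting stratum; expected counts are recomputed on the
    restricted table, so each cell is standardized within stratum.
    """
    case_col = f"n_cases_{outcome}"
    sub = counts[counts["age_class"].isin(STRATUM_CLASSES[stratum])]
    surface = rates.rate_surface(sub, case_col)
    id_order = [g.municipality_id for g in geos]
    surface = (
        surface.set_index("municipality_id").reindex(id_order).fillna(
            {"observed": 0, "expected": 0, "n_births": 0}
        ).reset_index()
    )

    if adjacency is None:
        adjacency = build_adjacency(geos, config)
    eb = smoothing.local_eb(surface, adjacency)
    eb["quantile_class"] = smoothing.quantile_classes(eb["ebsir"].to_numpy())

    lat = [g.lat for g in geos]
    lon = [g.lon for g in geos]
    dist = geo.distance_matrix(lat, lon, metric=config.metric)
    observed = surface["observed"].to_numpy(dtype=float)
    expected = surface["expected"].to_numpy(dtype=float)

    cell_seed = seed if seed is not None else config.seed
    tango = tango_mc_test(
        observed, expected, dist, lam=config.tango_lambda,
        nsim=config.tango_nsim, seed=cell_seed,
    )
    scan_cfg = dataclasses.replace(config.scan, seed=cell_seed)
    reports, null_max = scan_test(
        id_order, observed, expected, dist, scan_cfg,
        n_births=surface["n_births"].to_numpy(dtype=float),
    )
    return {
        "outcome": outcome,
        "stratum": stratum,
        "surface": surface,
        "ebsir": eb,
        "tango": tango,
        "clusters": reports,
        "null_max_llr": null_max,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the output bundle to out_dir."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geometry_path = str(config.geometry_path)
    if geometry_path.endswith((".geojson", ".json")):
        geos = geo.read_geojson(config.geometry_path)
    else:
        geos = geo.read_centroids_csv(config.geometry_path)
    id_order = [g.municipality_id for g in geos]

    raw = cohort.read_birth_records(config.records_path)
    kept, excl = cohort.apply_exclusions(raw)
    log.info("cohort: %d raw, %d kept (%d multiple, %d missing)",
             len(raw), len(kept), excl.multiple, excl.missing)
    classified = cohort.classify_records(kept)
    counts = cohort.aggregate_counts(classified, municipality_ids=id_order)

    summary = rates.summary_table(classified)
    summary.to_csv(out / "summary_table.csv", index=False)
    counts.to_csv(out / "aggregated_counts.csv", index=False)

    adjacency = build_adjacency(geos, config)
    adjacency.to_edge_list().to_csv(out / "adjacency_edges.csv", index=False)

    # stable per-cell seeds derived from the run seed
    tango_rows = []
    results = {}
    for ci, outcome in enumerate(config.outcomes):
        for si, stratum in enumerate(config.strata):
            cell_seed = int(
                np.random.SeedSequence(
                    [config.seed, ci, si]
                ).generate_state(1)[0] % (2**31)
            )
            res = analyze_counts(
                counts, geos, config, outcome, stratum,
                adjacency=adjacency, seed=cell_seed,
            )
            tag = f"{outcome}_{_slug(stratum)}"
            res["surface"].to_csv(out / f"rates_{tag}.csv", index=False)
            res["ebsir"].to_csv(out / f"ebsir_{tag}.csv", index=False)
            render_cluster_table(res["clusters"]).to_csv(
                out / f"clusters_{tag}.csv", index=False
            )
            tango_rows.append(
                {
                    "outcome": outcome,
                    "stratum": stratum,
                    "statistic": res["tango"].statistic,
                    "lambda_km": res["tango"].lam,
                    "p_value": res["tango"].p_value,
                    "nsim": res["tango"].nsim,
                }
            )
            results[(outcome, stratum)] = res
            log.info("cell %s/%s: tango p=%.4g, %d clusters",
                     outcome, stratum, res["tango"].p_value, len(res["clusters"]))
    pd.DataFrame(tango_rows).to_csv(out / "tango_results.csv", index=False)

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "config": config.to_dict(),
        "n_records_raw": int(len(raw)),
        "n_records_kept": int(len(kept)),
        "exclusions": {"multiple": excl.multiple, "missing": excl.missing},
        "versions": _versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return results


def _slug(stratum: str) -> str:
    return {"all": "all", "<=20": "le20", "(20,35]": "20to35", ">35": "gt35"}[stratum]


def _versions() -> dict:
    import scipy
    import shapely

    from . import __version__

    return {
        "geonatal": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "shapely": shapely.__version__,
    }


def render_cluster_table(reports) -> pd.DataFrame:
    """Publication-style cluster table: 2-dp rounding, '< 0.001' p floor."""
    rows = []
    for r in reports:
        if r.p_value is None:
            p_str = ""
        elif r.p_value < 0.001 + 1e-12:
            p_str = "< 0.001"
        else:
            p_str = f"{r.p_value:.3f}"
        rows.append(
            {
                "cluster": r.rank,
                "n_municipalities": r.n_municipalities,
                "expected_cases": round_half_up(r.expected, 2),
                "observed_cases": int(r.observed),
                "relative_risk": round_half_up(r.relative_risk, 2),
                "p_value": p_str,
                "llr": r.llr,
                "member_ids": ";".join(r.member_ids),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster", "n_municipalities", "expected_cases",
                 "observed_cases", "relative_risk", "p_value", "llr",
                 "member_ids"],
    )
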
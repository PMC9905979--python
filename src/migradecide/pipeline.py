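"""Pipeline orchestration: simulate -> process -> annotate -> fit -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .decision_models import fit_departure_model, fit_logistic_glmm
from .decision_models.inference import FitConfig
from .synthetic_world import SimConfig, simulate_world
from .synthetic_world.io import deployments_frame, read_world
from .track_processing import process_tracks
from .weather_annotation import build_departure_table, build_flight_covariates

log = logging.getLogger(__name__)


@dataclass
class CohortSummary:
    """Per-species flight counts by year, route and landing, plus totals."""

    table: pd.DataFrame
    n_flights: int
    n_onshore: int
    n_offshore: int
    offshore_pct: float
    n_landings: int
    n_tagged: int | None = None
    n_no_flight: int | None = None


def summarize_cohort(flights: pd.DataFrame, deployments: pd.DataFrame | None = None,
                     species_order=None) -> CohortSummary:
    """Count first flights per species and year with routing/landing splits.

    ``flights`` needs columns species, year, route, landed (one row per
    first flight).  With ``deployments`` the tagged-bird total and the
    number of birds without a recorded flight are filled in; flight species
    labels outside the deployment set raise an error.
    """
    flights = flights.copy()
    if deployments is not None:
        allowed = set(deployments["species"])
        bad = set(flights["species"]) - allowed
        if bad:
            raise ValueError(f"species outside the configured set: {sorted(bad)}")
    species = list(species_order) if species_order else sorted(
        set(flights["species"])
        | (set(deployments["species"]) if deployments is not None else set())
    )
    years = sorted(flights["year"].unique())
    rows = []
    for sp in species:
        sub = flights.loc[flights["species"] == sp]
        row = {"species": sp}
        for yr in years:
            row[str(yr)] = int((sub["year"] == yr).sum())
        row["onshore"] = int((sub["route"] == "onshore").sum())
        row["offshore"] = int((sub["route"] == "offshore").sum())
        row["landings"] = int(sub["landed"].sum())
        rows.append(row)
    columns = ["species"] + [str(y) for y in years] + ["onshore", "offshore",
                                                       "landings"]
    table = pd.DataFrame(rows, columns=columns).set_index("species")
    n_flights = int(len(flights))
    n_off = int(table["offshore"].sum())
    summary = CohortSummary(
        table=table,
        n_flights=n_flights,
        n_onshore=int(table["onshore"].sum()),
        n_offshore=n_off,
        offshore_pct=round(100.0 * n_off / n_flights, 1) if n_flights else 0.0,
        n_landings=int(table["landings"].sum()),
    )
    if deployments is not None:
        summary.n_tagged = int(len(deployments))
        summary.n_no_flight = summary.n_tagged - n_flights
    return summary


def flights_from_counts(records) -> pd.DataFrame:
    """Expand aggregated per-species counts into one row per first flight.

    Each record needs ``species``, ``years`` (year -> flight count),
    ``offshore`` and ``landings``; route and landing flags are assigned
    deterministically to match the aggregate counts, so
    :func:`summarize_cohort` on the result reproduces them exactly.
    """
    rows = []
    for rec in records:
        total = sum(rec["years"].values())
        if rec["offshore"] > total or rec["landings"] > total:
            raise ValueError(f"inconsistent counts for {rec['species']!r}")
        i = 0
        for year in sorted(rec["years"]):
            for _ in range(rec["years"][year]):
                rows.append({
                    "tag_id": f"{rec['species']}_{i}",
                    "species": rec["species"],
                    "year": int(year),
                    "route": "offshore" if i < rec["offshore"] else "onshore",
                    "landed": int(i < rec["landings"]),
                })
                i += 1
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def fit_all_models(departure_table: pd.DataFrame, flight_covariates: pd.DataFrame,
                   config: FitConfig | None = None,
                   forced_onshore_species=("sedge_warbler",),
                   random_intercepts: bool = True) -> dict:
    """Fit the three final decision models and return their fits.

    Routing excludes species never observed offshore; the landing model
    uses the flight-level northward-wind change and end-of-flight cloud.
    ``random_intercepts=False`` drops the year-species and day-of-year
    groupings from all three models (useful for recovery experiments on
    synthetic data whose truth contains no group effects).
    """
    config = config or FitConfig()
    fits = {}
    fits["departure"] = fit_departure_model(
        departure_table, config=config,
        random_intercepts=("year_species", "doy") if random_intercepts else (),
    )
    routing_rows = flight_covariates.loc[
        ~flight_covariates["species"].isin(forced_onshore_species)
    ]

    def usable(df, names):
        if not random_intercepts:
            return []
        return [g for g in names if df[g].nunique() > 1]

    fits["routing"] = fit_logistic_glmm(
        routing_rows, "offshore", ["u"],
        groups=usable(routing_rows, ("year_species", "doy_dep")),
        config=config,
    )
    fits["landing"] = fit_logistic_glmm(
        flight_covariates, "landed", ["dv_flight", "cloud"],
        groups=usable(flight_covariates, ("year_species", "doy_end")),
        config=config,
    )
    return fits


def run_all(config: SimConfig, out_dir, skip_fit: bool = False,
            fit_config: FitConfig | None = None) -> dict:
    """Execute every stage, writing outputs and a reproducibility manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings, outputs = {}, []

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception:
            log.error("stage %r failed", name)
            raise
        timings[name] = round(time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", name, timings[name])
        return result

    sim = stage("simulate", lambda: simulate_world(config, out_dir=out))
    deployments = deployments_frame(sim["deployments"])
    deployments["capture_ts"] = pd.to_datetime(deployments["capture_ts"])

    processed = stage("process", lambda: process_tracks(
        sim["detections"], sim["receivers"], deployments))
    processed["flights"].to_csv(out / "flights.csv", index=False)
    processed["landings"].to_csv(out / "landings.csv", index=False)
    processed["stopovers"].to_csv(out / "stopovers.csv", index=False)

    dep_table = stage("annotate", lambda: build_departure_table(
        processed["stopovers"], processed["flights"], sim["world"]))
    flight_cov = build_flight_covariates(
        processed["flights"], processed["stopovers"], sim["world"])
    dep_table.to_csv(out / "departure_table.csv", index=False)
    flight_cov.to_csv(out / "flight_covariates.csv", index=False)

    summary = summarize_cohort(processed["flights"], deployments)
    summary.table.to_csv(out / "cohort_summary.csv")

    fits = None
    if not skip_fit:
        fc = fit_config or FitConfig(seed=config.seed)
        fits = stage("fit", lambda: fit_all_models(
            dep_table, flight_cov,
            config=fc, forced_onshore_species=config.forced_onshore_species))
        for name, table_name in (("departure", "table2"), ("routing", "table3"),
                                 ("landing", "table4")):
            fits[name].table.to_csv(out / f"{table_name}.csv")
            fits[name].summary.draws.to_csv(out / f"draws_{name}.csv", index=False)

    outputs = sorted(p.name for p in out.iterdir() if p.is_file())
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
            .encode()
        ).hexdigest(),
        "stage_timings_s": timings,
        "outputs": {name: _sha256(out / name) for name in outputs
                    if name != "manifest.json"},
        "processing_report": processed["report"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "manifest": manifest,
        "summary": summary,
        "fits": fits,
        "processed": processed,
        "departure_table": dep_table,
        "flight_covariates": flight_cov,
    }


__all__ = ["CohortSummary", "summarize_cohort", "fit_all_models", "run_all",
           "read_world"]
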
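"""Configuration, I/O and end-to-end orchestration of the study.

``run_study`` reproduces the full analysis on any data laid out in the
pipeline's CSV schemas — the synthetic generator writes the same schemas,
so generated panels are drop-in replacements for deposited data.  Per
country it detects mobility changepoints and severity, fits the
difference-in-discontinuities model (all three forms) to every food
category, the four access-mode groups and total food, derives short-term
effects, reversion times and long-term effects (plus the share-of-total
outcome variant), computes surplus reports and mobility–interest
correlations, reruns the model at the second-wave cutoff where one is
detected, and closes with the cross-country dose-response.  Individual
series failures (e.g. zero volumes) are recorded and skipped rather than
aborting the run.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, metrics, mobility, rdd, taxonomy
from .series import (
    BASELINE_YEAR,
    TREATMENT_YEAR,
    WEEKS_PER_YEAR,
    InterestSeries,
    MobilitySeries,
)
from .synthetic import SyntheticPanel

logger = logging.getLogger(__name__)

TOTAL_FOOD = "total_food"
ACCESS_GROUP_LABELS = {
    ("home", "household"): "household_home",
    ("home", "third_party"): "third_party_home",
    ("outside", "household"): "household_outside",
    ("outside", "third_party"): "third_party_outside",
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one study run."""

    countries: list[str]
    interest_path: str
    catalog_path: str
    mobility_path: str
    out_dir: str
    forms: tuple[str, ...] = rdd.FORMS
    t_min: int = 10
    t_max: int = 30
    threshold: float = mobility.DEFAULT_THRESHOLD
    correlation_window: tuple[int, int] = association.DEFAULT_WINDOW
    dose_exclude: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.countries:
            raise ValueError("countries must be non-empty")
        self.forms = tuple(self.forms)
        self.dose_exclude = tuple(self.dose_exclude)
        self.correlation_window = tuple(self.correlation_window)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON config file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# interest panel I/O (CSV schema: country, entity_id, year, week, volume)

def read_interest_panel(path: str | Path) -> list[InterestSeries]:
    """Read a calibrated interest panel, one series per (country, entity).

    Week-53 rows (leap-week artifacts of the ISO calendar) are dropped
    with a logged count; negative volumes are a hard error.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"cannot parse interest panel {path}: {exc}") from exc
    required = {"country", "entity_id", "year", "week", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interest panel {path}: missing columns {sorted(missing)}")
    over = df["week"] > WEEKS_PER_YEAR
    if over.any():
        logger.info("dropping %d week-53 row(s) from %s", int(over.sum()), path)
        df = df[~over]
    if (df["volume"] < 0).any():
        bad = df[df["volume"] < 0].iloc[0]
        raise ValueError(
            f"negative volume for {bad['entity_id']} ({bad['country']}), "
            f"year {int(bad['year'])} week {int(bad['week'])}"
        )
    out = []
    for (country, entity), sub in df.groupby(["country", "entity_id"], sort=True):
        out.append(
            InterestSeries(str(country), str(entity), sub[["year", "week", "volume"]])
        )
    return out


def write_interest_panel(series: list[InterestSeries], path: str | Path) -> None:
    frames = []
    for s in series:
        f = s.data.copy()
        f.insert(0, "entity_id", s.label)
        f.insert(0, "country", s.country)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_panel(panel: SyntheticPanel, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic panel in the pipeline's input schemas.

    Produces ``interest.csv`` (one entity per generated series, entity id
    ``/syn/<label>``), ``catalog.csv`` and ``mobility.csv``, and returns
    their paths.  The catalog marks the four access-mode labels as
    access-mode entities and every other label as a single-member food
    category, so the taxonomy stage reconstructs exactly the generated
    groups.
    """
    from .synthetic import CATEGORY_EFFECT_MULTIPLIERS, GROUP_EFFECT_MULTIPLIERS

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series: list[InterestSeries] = []
    for country in panel.countries:
        for label, s in panel.interest[country].items():
            if label == TOTAL_FOOD:
                continue  # reconstructed by aggregation downstream
            series.append(InterestSeries(country, f"/syn/{label}", s.data))
    entries = []
    for label in GROUP_EFFECT_MULTIPLIERS:
        home, preparer = next(
            k for k, v in ACCESS_GROUP_LABELS.items() if v == label
        )
        entries.append(
            taxonomy.CatalogEntry(
                entity_id=f"/syn/{label}",
                display_name=label,
                kind=taxonomy.KIND_ACCESS,
                access_home=home,
                access_preparer=preparer,
            )
        )
    for label in CATEGORY_EFFECT_MULTIPLIERS:
        entries.append(
            taxonomy.CatalogEntry(
                entity_id=f"/syn/{label}",
                display_name=label,
                kind=taxonomy.KIND_FOOD,
                category=label,
            )
        )
    paths = {
        "interest": out / "interest.csv",
        "catalog": out / "catalog.csv",
        "mobility": out / "mobility.csv",
    }
    write_interest_panel(series, paths["interest"])
    taxonomy.write_catalog(taxonomy.EntityCatalog(tuple(entries)), paths["catalog"])
    mobility.write_mobility_reports(panel.mobility, paths["mobility"])
    return paths


# ---------------------------------------------------------------------------
# study orchestration

@dataclass
class StudyReport:
    """All tables produced by one study run."""

    changepoints: pd.DataFrame
    effects: pd.DataFrame
    correlations: pd.DataFrame
    surplus: pd.DataFrame
    dose_response: pd.DataFrame
    manifest: dict


def _effect_row(est: rdd.EffectEstimate, prefix: str) -> dict:
    return {
        f"{prefix}_effect": est.point,
        f"{prefix}_ci_low": est.ci_low,
        f"{prefix}_ci_high": est.ci_high,
        f"{prefix}_p": est.p_value,
        f"{prefix}_significant": est.significant,
        f"{prefix}_log": est.log_effect,
        f"{prefix}_log_se": est.log_se,
    }


def _fit_one(
    s: InterestSeries,
    spec: rdd.ModelSpec,
    wave: int,
) -> dict:
    design = rdd.build_design(s, spec)
    fit = rdd.fit_rdd(design, spec)
    short = rdd.short_term_effect(fit)
    rev = rdd.reversion_time(fit)
    row = {
        "country": s.country,
        "label": s.label,
        "wave": wave,
        "form": spec.form,
        "outcome": spec.outcome,
        "cutoff_week": spec.cutoff,
        "t_min": spec.t_min,
        "t_max": spec.t_max,
        "n_obs": fit.n_obs,
        "reversion_status": rev.status,
        "reversion_weeks": rev.weeks,
    }
    row.update(_effect_row(short, "short"))
    row.update(_effect_row(rdd.long_term_effect(fit), "long"))
    return row


def _group_series(
    catalog: taxonomy.EntityCatalog,
    per_entity: list[InterestSeries],
) -> dict[str, InterestSeries]:
    """Aggregate per-entity series into categories, access modes, total food."""
    groups: dict[str, InterestSeries] = {}
    for cat in catalog.categories:
        groups[cat] = taxonomy.aggregate_series(
            per_entity, catalog.category_members(cat), label=cat
        )
    for cell, members in catalog.access_mode_groups().items():
        groups[ACCESS_GROUP_LABELS[cell]] = taxonomy.aggregate_series(
            per_entity, members, label=ACCESS_GROUP_LABELS[cell]
        )
    groups[TOTAL_FOOD] = taxonomy.aggregate_series(
        per_entity, catalog.food_ids(), label=TOTAL_FOOD
    )
    return groups


def run_study(config: RunConfig) -> StudyReport:
    """Run the full analysis and write all result tables to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    catalog = taxonomy.load_catalog(config.catalog_path)
    panel = read_interest_panel(config.interest_path)
    mob = mobility.read_mobility_reports(config.mobility_path, config.countries)

    cp_rows, effect_rows, corr_rows, surplus_rows = [], [], [], []
    failures: list[dict] = []
    planned = 0
    severity_by_country: dict[str, float] = {}

    for country in config.countries:
        if country not in mob:
            failures.append({"country": country, "stage": "mobility",
                             "error": "no mobility series"})
            continue
        cp = mobility.detect_changepoints(mob[country], config.threshold)
        cp_rows.append(
            {
                "country": country,
                "first_decrease": cp.first_decrease,
                "mobility_increase": cp.mobility_increase,
                "second_decrease": cp.second_decrease,
                "peak_severity": cp.peak_severity,
                "threshold": cp.threshold,
            }
        )
        if cp.first_decrease is None:
            failures.append({"country": country, "stage": "changepoints",
                             "error": "mobility never crossed threshold"})
            continue
        severity_by_country[country] = float(cp.peak_severity)

        per_entity = [s for s in panel if s.country == country]
        try:
            groups = _group_series(catalog, per_entity)
        except ValueError as exc:
            failures.append({"country": country, "stage": "aggregation",
                             "error": str(exc)})
            continue
        total = groups[TOTAL_FOOD]

        cutoff = cp.cutoff_week
        t_min = min(config.t_min, cutoff - 1)
        t_max = min(config.t_max, WEEKS_PER_YEAR - cutoff)
        if (t_min, t_max) != (config.t_min, config.t_max):
            logger.info(
                "%s: bandwidth truncated to (t_min=%d, t_max=%d) around cutoff "
                "week %d", country, t_min, t_max, cutoff,
            )

        for label, s in groups.items():
            # primary fits: every form on log volume
            for form in config.forms:
                planned += 1
                try:
                    spec = rdd.ModelSpec(form, t_min, t_max, cutoff)
                    effect_rows.append(_fit_one(s, spec, wave=1))
                except ValueError as exc:
                    failures.append({"country": country, "stage": f"fit:{form}",
                                     "label": label, "error": str(exc)})
            # share-of-total variant (quadratic form)
            if label != TOTAL_FOOD:
                planned += 1
                try:
                    share = rdd.share_outcome(s, total)
                    spec = rdd.ModelSpec(
                        "quadratic", t_min, t_max, cutoff, outcome="log_share"
                    )
                    effect_rows.append(_fit_one(share, spec, wave=1))
                except ValueError as exc:
                    failures.append({"country": country, "stage": "fit:share",
                                     "label": label, "error": str(exc)})
            # mobility-interest correlation
            try:
                sp = association.mobility_interest_correlation(
                    s, mob[country], config.correlation_window
                )
                corr_rows.append(
                    {"country": country, "label": label, "rho": sp.rho,
                     "p": sp.p_value, "n": sp.n,
                     "window": f"{config.correlation_window[0]}-"
                               f"{config.correlation_window[1]}"}
                )
            except ValueError as exc:
                failures.append({"country": country, "stage": "correlation",
                                 "label": label, "error": str(exc)})
            # second-wave rerun (quadratic)
            if cp.second_decrease is not None:
                cutoff2 = cp.second_cutoff_week
                t_max2 = WEEKS_PER_YEAR - cutoff2
                t_min2 = min(config.t_min, cutoff2 - 1)
                if t_max2 >= 3:
                    planned += 1
                    try:
                        spec2 = rdd.ModelSpec("quadratic", t_min2, t_max2, cutoff2)
                        effect_rows.append(_fit_one(s, spec2, wave=2))
                    except ValueError as exc:
                        failures.append(
                            {"country": country, "stage": "fit:second_wave",
                             "label": label, "error": str(exc)}
                        )

        # surplus report on total food
        try:
            rep = metrics.surplus_report(metrics.zscore_series(total))
            surplus_rows.append(
                {"country": country, "peak_week": rep.peak_week,
                 "peak_ratio": rep.peak_ratio, "window_ratio": rep.window_ratio,
                 "window": f"{rep.window[0]}-{rep.window[1]}",
                 "ref_year": rep.ref_week[0], "ref_week": rep.ref_week[1]}
            )
        except ValueError as exc:
            failures.append({"country": country, "stage": "surplus",
                             "error": str(exc)})

    effects = pd.DataFrame(effect_rows)

    # dose-response across countries per access-mode group (wave 1, quadratic)
    dose_rows = []
    if len(effects):
        first_wave = effects[
            (effects["wave"] == 1)
            & (effects["form"] == "quadratic")
            & (effects["outcome"] == "log_volume")
        ]
        for label in sorted(ACCESS_GROUP_LABELS.values()):
            sub = first_wave[first_wave["label"] == label]
            ests = {
                row["country"]: rdd.EffectEstimate(
                    point=row["short_effect"], ci_low=row["short_ci_low"],
                    ci_high=row["short_ci_high"], p_value=row["short_p"],
                    significant=row["short_significant"],
                    log_effect=row["short_log"], log_se=row["short_log_se"],
                )
                for _, row in sub.iterrows()
            }
            if len(ests) < 3:
                continue
            dr = association.dose_response(
                severity_by_country, ests, exclude=config.dose_exclude
            )
            dose_rows.append(
                {"label": label, "pearson_r": dr.pearson_r, "p": dr.p_value,
                 "slope": dr.slope, "intercept": dr.intercept, "n": dr.n,
                 "excluded": ",".join(dr.excluded)}
            )

    report = StudyReport(
        changepoints=pd.DataFrame(cp_rows),
        effects=effects,
        correlations=pd.DataFrame(corr_rows),
        surplus=pd.DataFrame(surplus_rows),
        dose_response=pd.DataFrame(dose_rows),
        manifest={
            "config": config.to_dict(),
            "planned_fits": planned,
            "completed_fits": int(len(effects)),
            "failures": failures,
            "n_countries": len(config.countries),
            "n_tests_uncorrected": int(len(effects) + len(corr_rows) + len(dose_rows)),
        },
    )
    if planned and len(effects) == 0:
        raise ValueError("empty result set: every planned fit failed")

    report.changepoints.to_csv(out / "changepoints.csv", index=False)
    report.effects.to_csv(out / "effects.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv", index=False)
    report.surplus.to_csv(out / "surplus.csv", index=False)
    report.dose_response.to_csv(out / "dose_response.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(report.manifest, default=str, indent=2))
    return report
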
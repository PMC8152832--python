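"""End-to-end orchestration: simulate -> behavior -> MRS -> statistics.

A run is driven by a :class:`RunConfig` (YAML-loadable, shipped defaults
reproduce the study's procedural choices) and produces delimited-text
output tables — a performance group summary with t-tests, QC-gated
corrected metabolite concentrations, metabolite group tests under FDR
control, the correlation screen, and candidate regressions — plus a
manifest recording seeds, versions, row counts and every exclusion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import behavior as _behavior
from . import mrs as _mrs
from . import stats as _stats
from . import synthetic as _synthetic

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "StatsConfig",
    "RunConfig",
    "RunManifest",
    "load_config",
    "validate_inputs",
    "run_pipeline",
]


@dataclass(frozen=True)
class QCConfig:
    min_snr: float = _mrs.QC_MIN_SNR
    max_linewidth_hz: float = _mrs.QC_MAX_LINEWIDTH_HZ

    def __post_init__(self) -> None:
        if self.min_snr < 0 or self.max_linewidth_hz <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass(frozen=True)
class StatsConfig:
    fdr_q: float = 0.05
    screen_alpha: float = 0.05
    equal_var: bool = True  # pooled t (df = n1 + n2 - 2); False = Welch
    min_r2_change: float = 0.01
    slowing: str = "difference-of-averages"

    def __post_init__(self) -> None:
        for name in ("fdr_q", "screen_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.min_r2_change < 0:
            raise ValueError("min_r2_change must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    cohort: _synthetic.CohortSpec = field(default_factory=_synthetic.CohortSpec)
    constants: _mrs.RelaxationConstants = field(
        default_factory=_mrs.RelaxationConstants
    )
    qc: QCConfig = field(default_factory=QCConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    trials_path: str | None = None  # analyze user-supplied tables instead of simulating
    panel_path: str | None = None

    def __post_init__(self) -> None:
        if (self.trials_path is None) != (self.panel_path is None):
            raise ValueError("trials_path and panel_path must be given together")
        for p in (self.trials_path, self.panel_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input table not found: {p}")


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    seed: int
    versions: dict
    counts: dict
    exclusions: dict
    started_at: str
    finished_at: str

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in {context}; expected a subset "
            f"of {sorted(known)}"
        )
    return cls(**data)


def _cohort_from_dict(data: dict) -> _synthetic.CohortSpec:
    data = dict(data)
    for group_key, default in (("young", _synthetic._default_young),
                               ("older", _synthetic._default_older)):
        if group_key in data:
            gdata = dict(data[group_key])
            base = default()
            pfields = {f.name for f in dataclasses.fields(_synthetic.RaceModelParams)}
            pdata = {k: v for k, v in gdata.items() if k in pfields}
            gdata = {k: v for k, v in gdata.items() if k not in pfields}
            params = dataclasses.replace(base.params, **pdata)
            data[group_key] = _build(
                _synthetic.GroupSpec,
                {"params": params, **gdata},
                f"cohort.{group_key}",
            )
    if "effects" in data:
        data["effects"] = tuple(
            _build(_synthetic.PlantedEffect, dict(e), "cohort.effects[]")
            for e in data["effects"]
        )
    if "design" in data:
        data["design"] = _build(
            _synthetic.SessionDesign, dict(data["design"]), "cohort.design"
        )
    return _build(_synthetic.CohortSpec, data, "cohort")


def load_config(path=None, *, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file and/or an override mapping.

    Unknown keys raise with the expected key set named, so typos surface
    immediately.  With no file the shipped defaults apply.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    if "cohort" in data:
        data["cohort"] = _cohort_from_dict(dict(data["cohort"]))
    if "constants" in data:
        data["constants"] = _build(
            _mrs.RelaxationConstants, dict(data["constants"]), "constants"
        )
    if "qc" in data:
        data["qc"] = _build(QCConfig, dict(data["qc"]), "qc")
    if "stats" in data:
        data["stats"] = _build(StatsConfig, dict(data["stats"]), "stats")
    config = _build(RunConfig, data, "run config")
    # the master seed flows into the cohort spec unless the cohort pins its own
    if config.cohort.seed == 0 and config.seed != 0:
        config = dataclasses.replace(
            config, cohort=dataclasses.replace(config.cohort, seed=config.seed)
        )
    return config


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(
    trials: pd.DataFrame, panel: pd.DataFrame
) -> pd.DataFrame:
    """Schema/range/invariant checks on the input tables (non-mutating).

    Returns a violation table (table, row, rule, detail); empty when clean.
    """
    violations: list[dict] = []

    def flag(table: str, row, rule: str, detail: str) -> None:
        violations.append({"table": table, "row": row, "rule": rule, "detail": detail})

    missing = set(_synthetic.TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        flag("trials", -1, "schema", f"missing columns {sorted(missing)}")
        return pd.DataFrame(violations)
    missing = set(_synthetic.PANEL_COLUMNS) - set(panel.columns)
    if missing:
        flag("panel", -1, "schema", f"missing columns {sorted(missing)}")
        return pd.DataFrame(violations)

    for i, row in enumerate(trials.itertuples()):
        if row.trial_type not in ("go", "stop"):
            flag("trials", i, "trial-type", f"unknown trial type {row.trial_type!r}")
            continue
        if row.ssp not in (0, 20, 40):
            flag("trials", i, "ssp", f"unknown SSP condition {row.ssp!r}")
        if row.trial_type == "go":
            if pd.notna(row.ssd_ms):
                flag("trials", i, "go-has-ssd", "go trial carries an SSD")
            if pd.notna(row.stop_success):
                flag("trials", i, "go-has-outcome", "go trial carries a stop outcome")
        else:
            if row.ssp == 0:
                flag("trials", i, "stop-in-0pct", "stop trial inside the 0% SSP block")
            if pd.isna(row.ssd_ms) or row.ssd_ms < 0:
                flag("trials", i, "ssd-range", f"invalid SSD {row.ssd_ms}")
            if pd.isna(row.stop_success):
                flag("trials", i, "stop-outcome", "stop trial without an outcome")
            elif bool(row.stop_success) and pd.notna(row.rt_ms):
                flag("trials", i, "success-has-rt", "successful stop carries an RT")
        if pd.notna(row.rt_ms) and row.rt_ms < 0:
            flag("trials", i, "rt-range", f"negative RT {row.rt_ms}")

    for i, row in enumerate(panel.itertuples()):
        fracs = (row.f_gm, row.f_wm, row.f_csf)
        if any(pd.isna(f) or f < 0 or f > 1 for f in fracs):
            flag("panel", i, "fraction-range", f"fractions outside [0, 1]: {fracs}")
        elif abs(sum(fracs) - 1.0) > 1e-3:
            flag("panel", i, "fraction-sum", f"fractions sum to {sum(fracs):.4f}")
        if pd.notna(row.snr) and row.snr < 0:
            flag("panel", i, "snr-range", f"negative SNR {row.snr}")
        if pd.notna(row.linewidth_hz) and row.linewidth_hz < 0:
            flag("panel", i, "linewidth-range", f"negative linewidth {row.linewidth_hz}")
        if row.region not in _mrs.REGIONS:
            flag("panel", i, "region", f"unknown region {row.region!r}")
        if row.metabolite not in _mrs.METABOLITES:
            flag("panel", i, "metabolite", f"unknown metabolite {row.metabolite!r}")
    return pd.DataFrame(
        violations, columns=["table", "row", "rule", "detail"]
    )


# ---------------------------------------------------------------------------
# stages


def _metabolite_group_tests(
    features: pd.DataFrame, stats_cfg: StatsConfig
) -> pd.DataFrame:
    """Per-feature young-vs-older t-tests with BH-FDR over the whole family."""
    rows = []
    feat_cols = [c for c in features.columns if c != "group"]
    young = features[features["group"] == "young"]
    older = features[features["group"] == "older"]
    for col in feat_cols:
        x = young[col].dropna()
        y = older[col].dropna()
        if len(x) < 2 or len(y) < 2:
            continue
        res = _stats.pooled_t_from_raw(x, y, equal_var=stats_cfg.equal_var)
        region, metabolite = col.split(" ", 1)
        rows.append(
            {
                "region": region,
                "metabolite": metabolite,
                "mean_young": res.mean1,
                "sd_young": res.sd1,
                "n_young": res.n1,
                "mean_older": res.mean2,
                "sd_older": res.sd2,
                "n_older": res.n2,
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        critical, reject = _stats.bh_fdr(table["p"].to_numpy(), q=stats_cfg.fdr_q)
        table["fdr_reject"] = reject
        table["fdr_critical_p"] = critical if critical is not None else np.nan
    return table


def _performance_group_table(
    performance: pd.DataFrame, stats_cfg: StatsConfig
) -> pd.DataFrame:
    """Group mean (SD) and young-vs-older t per performance measure."""
    summary = _behavior.summarize_group(performance)
    rows = []
    for measure in summary.index:
        row = {"measure": measure}
        for grp in ("young", "older"):
            if (grp, "mean") in summary.columns:
                row[f"mean_{grp}"] = summary.loc[measure, (grp, "mean")]
                row[f"sd_{grp}"] = summary.loc[measure, (grp, "std")]
        if {"mean_young", "mean_older"} <= set(row):
            x = performance.loc[performance["group"] == "young", measure].dropna()
            y = performance.loc[performance["group"] == "older", measure].dropna()
            res = _stats.pooled_t_from_raw(x, y, equal_var=stats_cfg.equal_var)
            row.update(t=res.t, df=res.df, p=res.p)
        rows.append(row)
    return pd.DataFrame(rows)


def _candidate_regressions(
    screen: pd.DataFrame,
    features: pd.DataFrame,
    performance: pd.DataFrame,
    stats_cfg: StatsConfig,
) -> tuple[pd.DataFrame, dict]:
    """Per group x measure: OLS on the screened candidates, with two-step refit."""
    rows = []
    listwise: dict[str, int] = {}
    perf = performance.set_index("subject_id")
    for (group, measure), sub in screen.groupby(["group", "measure"], sort=True):
        candidates = sub.loc[sub["candidate"], "feature"].tolist()
        if not candidates:
            continue
        sids = perf.index[perf["group"] == group]
        X = features.loc[features.index.intersection(sids), candidates]
        y = perf.loc[X.index, measure]
        n_complete = int(pd.concat([y, X], axis=1).dropna().shape[0])
        if n_complete <= len(candidates) + 1:
            logger.warning(
                "%s/%s: %d complete rows for %d candidates; regression skipped",
                group, measure, n_complete, len(candidates),
            )
            continue
        listwise[f"{group}/{measure}"] = len(X) - n_complete
        full, reduced, dropped = _stats.refit_dropping_negligible(
            y, X, min_r2_change=stats_cfg.min_r2_change
        )
        for label, model in (("full", full), ("reduced", reduced)):
            if label == "reduced" and not dropped:
                continue
            frame = model.as_frame()
            frame.insert(0, "group", group)
            frame.insert(1, "measure", measure)
            frame.insert(2, "model", label)
            frame.insert(3, "r2", model.r2)
            frame.insert(4, "r2_adjusted", model.r2_adjusted)
            frame.insert(5, "F", model.f)
            frame.insert(6, "n", model.n)
            rows.append(frame)
    table = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(
            columns=[
                "group", "measure", "model", "r2", "r2_adjusted", "F", "n",
                "predictor", "r2_change", "beta", "beta_se", "B", "B_se", "p",
            ]
        )
    )
    return table, listwise


def run_pipeline(config: RunConfig, out_dir) -> RunManifest:
    """Execute all stages and write output tables plus ``manifest.json``.

    Identical config + seed reproduce byte-identical tables; input files are
    never mutated.  A validation failure on user-supplied tables aborts with
    the offending rows listed.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: obtain tables -------------------------------------------------
    if config.trials_path is not None:
        logger.info("loading user tables")
        trials = _synthetic.read_trials(config.trials_path)
        panel = _synthetic.read_panel(config.panel_path)
    else:
        logger.info("simulating cohort (seed=%d)", config.cohort.seed)
        trials, panel = _synthetic.simulate_cohort(config.cohort, config.constants)
    _synthetic.write_trials(trials, out / "trials.csv")
    _synthetic.write_panel(panel, out / "panel.csv")

    # --- stage: validate ------------------------------------------------------
    violations = validate_inputs(trials, panel)
    violations.to_csv(out / "validation.csv", index=False)
    if len(violations):
        raise RuntimeError(
            f"validation failed with {len(violations)} violation(s); first rows: "
            f"{violations.head(5).to_dict('records')}"
        )

    # --- stage: behavior ------------------------------------------------------
    performance = _behavior.performance_table(trials, slowing=config.stats.slowing)
    performance.to_csv(out / "performance.csv", index=False)
    n_go = int((trials["trial_type"] == "go").sum())
    n_valid_go = int(performance["n_valid_go"].sum())
    groups_present = performance["group"].nunique()
    if groups_present == 2:
        _performance_group_table(performance, config.stats).to_csv(
            out / "table1_performance.csv", index=False
        )

    # --- stage: MRS correction ------------------------------------------------
    corrected = _mrs.correct_panel(
        panel,
        config.constants,
        min_snr=config.qc.min_snr,
        max_linewidth_hz=config.qc.max_linewidth_hz,
    )
    corrected.to_csv(out / "corrected_panel.csv", index=False)
    n_qc_failed = int((~corrected["qc_pass"]).sum())
    logger.info("QC excluded %d of %d spectra", n_qc_failed, len(corrected))

    # --- stage: statistics ----------------------------------------------------
    features = _stats.build_feature_matrix(corrected)
    if groups_present == 2:
        _metabolite_group_tests(features, config.stats).to_csv(
            out / "metabolite_group_tests.csv", index=False
        )
    screen = _stats.pearson_screen(
        features, performance, alpha=config.stats.screen_alpha
    )
    screen.to_csv(out / "table2_screen.csv", index=False)
    regressions, listwise = _candidate_regressions(
        screen, features, performance, config.stats
    )
    regressions.to_csv(out / "table3_regressions.csv", index=False)

    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=config.seed,
        versions={
            "ssmrs": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        counts={
            "n_subjects": int(performance.shape[0]),
            "n_trials": int(len(trials)),
            "n_go_trials": n_go,
            "n_valid_go_trials": n_valid_go,
            "n_stop_trials": int((trials["trial_type"] == "stop").sum()),
            "n_spectra": int(len(panel)),
            "n_screen_tests": int(len(screen)),
            "n_candidates": int(screen["candidate"].sum()),
        },
        exclusions={
            "go_trials_filtered": n_go - n_valid_go,
            "spectra_qc_failed": n_qc_failed,
            "regression_listwise_dropped": listwise,
        },
        started_at=started,
        finished_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.as_dict(), fh, indent=2)
    return manifest
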
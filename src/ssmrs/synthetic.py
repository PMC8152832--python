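"""Synthetic stop-signal experiments and metabolite cohorts.

Provides a fully simulated stand-in for the study data so that every
downstream stage (behavioral measures, MRS correction, statistics) can be
exercised and validated end to end.

**Race model.**  Each trial draws a planned lift time
``T ~ Normal(planned_rt_mean + context_delta, planned_rt_sd)`` (ms from
trial onset; the indicator crosses the target line at 800 ms).  On a stop
trial with stop-signal delay SSD the stop process finishes at
``SSD + ssrt_true``; under the independent-race assumption the stop wins —
and the lift is cancelled — iff ``T >= SSD + ssrt_true``.  A failed stop
responds at ``T`` (the RT on failed stops, which is therefore
stochastically faster than the go RT from the same parameters).  Proactive
slowing is an additive mean shift per stop-signal-probability (SSP)
context.

**Staircase.**  SSD follows a one-up/one-down tracking rule: +33 ms after
a successful stop, -33 ms after a failed one, clamped to [33, 767] ms so
the indicator always halts before the 800 ms crossing.  The rule converges
on the SSD where stopping succeeds half the time.

**Session layout** (defaults): a 25-trial 0%-SSP go block followed by a
150-trial block randomly interleaving the 20% SSP condition (80 go + 20
stop) and the 40% SSP condition (30 go + 20 stop); two sessions per
subject give 350 trials.

**Cohorts.**  Subjects draw individual timing means and stop latencies
around group-level values; per region x metabolite, water-referenced
signal levels are generated so that the corrected concentrations carry a
configurable sample correlation with a behavioral measure (see
:class:`PlantedEffect` and docs/methods.md for the coupling conventions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior as _behavior
from . import mrs as _mrs

__all__ = [
    "TARGET_CROSSING_MS",
    "TRIAL_DEADLINE_MS",
    "RaceModelParams",
    "StaircaseState",
    "SessionDesign",
    "GroupSpec",
    "PlantedEffect",
    "CohortSpec",
    "simulate_stop_trial",
    "staircase_update",
    "simulate_session",
    "simulate_subject",
    "simulate_cohort",
    "write_trials",
    "read_trials",
    "write_panel",
    "read_panel",
]

#: The moving indicator crosses the horizontal target line 800 ms after onset.
TARGET_CROSSING_MS = 800.0
#: The indicator empties at 1280 ms; no lift by then is an omission.
TRIAL_DEADLINE_MS = 1280.0

TRIAL_COLUMNS = [
    "subject_id",
    "group",
    "session",
    "ssp",
    "trial_type",
    "ssd_ms",
    "rt_ms",
    "stop_success",
]
PANEL_COLUMNS = [
    "subject_id",
    "group",
    "region",
    "metabolite",
    "level",
    "snr",
    "linewidth_hz",
    "f_gm",
    "f_wm",
    "f_csf",
]


@dataclass(frozen=True)
class RaceModelParams:
    """Subject-level parameters of the independent race model (all times ms)."""

    planned_rt_mean: float = 800.0
    planned_rt_sd: float = 50.0
    ssrt_true: float = 200.0
    proactive_delta_20: float = 0.0
    proactive_delta_40: float = 0.0
    early_resp_rate: float = 0.0
    omission_rate: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.planned_rt_sd <= 0:
            raise ValueError("planned_rt_sd must be positive")
        if self.ssrt_true <= 0:
            raise ValueError("ssrt_true must be positive")
        for name in ("early_resp_rate", "omission_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def context_delta(self, ssp: int) -> float:
        return {0: 0.0, 20: self.proactive_delta_20, 40: self.proactive_delta_40}[ssp]


@dataclass(frozen=True)
class StaircaseState:
    """State of the one-up/one-down SSD tracking staircase (ms)."""

    current_ssd: float = 550.0
    step: float = 33.0
    lower_bound: float = 33.0
    upper_bound: float = 767.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("staircase step must be positive")
        if not self.lower_bound <= self.current_ssd <= self.upper_bound:
            raise ValueError(
                f"SSD {self.current_ssd} outside bounds "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )


def staircase_update(state: StaircaseState, stop_success: bool) -> StaircaseState:
    """Advance the staircase: harder (longer SSD) after success, easier after failure."""
    delta = state.step if stop_success else -state.step
    new_ssd = min(max(state.current_ssd + delta, state.lower_bound), state.upper_bound)
    return replace(state, current_ssd=new_ssd)


def simulate_stop_trial(
    params: RaceModelParams,
    ssd: float,
    context: int,
    rng: np.random.Generator,
) -> tuple[bool, float | None]:
    """Race one stop trial; returns (stop_success, rt on failed stops else None)."""
    if not math.isfinite(ssd) or ssd < 0:
        raise ValueError(f"ssd must be a non-negative finite delay, got {ssd}")
    if context not in (20, 40):
        raise ValueError(f"stop trials occur only in the 20/40% SSP contexts: {context}")
    planned = rng.normal(
        params.planned_rt_mean + params.context_delta(context), params.planned_rt_sd
    )
    if planned >= ssd + params.ssrt_true:
        return True, None
    return False, float(planned)


@dataclass(frozen=True)
class SessionDesign:
    """Per-session trial counts: a 0%-SSP go block, then an interleaved block."""

    n_go_0: int = 25
    n_go_20: int = 80
    n_stop_20: int = 20
    n_go_40: int = 30
    n_stop_40: int = 20
    n_stop_0: int = 0  # must stay 0; the 0% block promises no stop signals

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0 or (name != "n_stop_0" and name.startswith("n_go") and v == 0):
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_stop_0 != 0:
            raise ValueError("the 0% SSP block cannot contain stop trials")

    @property
    def n_trials(self) -> int:
        return (
            self.n_go_0 + self.n_go_20 + self.n_stop_20 + self.n_go_40 + self.n_stop_40
        )


def _go_rts(
    params: RaceModelParams, ssp: int, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Planned lift times for n go trials, with early responses and omissions injected."""
    rts = rng.normal(
        params.planned_rt_mean + params.context_delta(ssp), params.planned_rt_sd, size=n
    )
    u = rng.random(n)
    early = u < params.early_resp_rate
    omitted = (u >= params.early_resp_rate) & (
        u < params.early_resp_rate + params.omission_rate
    )
    rts[early] = rng.uniform(150.0, _behavior.GO_RT_MIN_MS - 1.0, size=int(early.sum()))
    rts[omitted] = np.nan
    return rts


def simulate_session(
    params: RaceModelParams,
    design: SessionDesign | None = None,
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    staircase: StaircaseState | None = None,
    subject_id: str = "S000",
    group: str = "young",
    session: int = 1,
) -> tuple[pd.DataFrame, StaircaseState]:
    """Simulate one session; returns the trial table and the final staircase state.

    The 20%/40% trials of the second block are randomly interleaved; the
    staircase is shared across both SSP conditions and carried across the
    block's stop trials in presentation order.
    """
    if design is None:
        design = SessionDesign()
    if rng is None:
        rng = np.random.default_rng(seed)
    if staircase is None:
        staircase = StaircaseState()

    rows: list[tuple] = []

    def add(ssp, trial_type, ssd, rt, success):
        rows.append(
            (subject_id, group, session, ssp, trial_type, ssd, rt, success)
        )

    for rt in _go_rts(params, 0, design.n_go_0, rng):
        add(0, "go", np.nan, rt, pd.NA)

    block2 = (
        [(20, "go")] * design.n_go_20
        + [(20, "stop")] * design.n_stop_20
        + [(40, "go")] * design.n_go_40
        + [(40, "stop")] * design.n_stop_40
    )
    order = rng.permutation(len(block2))
    # go RTs are drawn in condition batches (the draws are i.i.d. given the
    # context, so batching does not change the law); stop trials stay
    # sequential because each outcome moves the staircase.
    go_pools = {
        20: iter(_go_rts(params, 20, design.n_go_20, rng)),
        40: iter(_go_rts(params, 40, design.n_go_40, rng)),
    }
    for idx in order:
        ssp, trial_type = block2[idx]
        if trial_type == "go":
            add(ssp, "go", np.nan, next(go_pools[ssp]), pd.NA)
        else:
            ssd = staircase.current_ssd
            success, rt = simulate_stop_trial(params, ssd, ssp, rng)
            add(ssp, "stop", ssd, np.nan if rt is None else rt, success)
            staircase = staircase_update(staircase, success)

    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    trials["stop_success"] = trials["stop_success"].astype("boolean")
    return trials, staircase


@dataclass(frozen=True)
class GroupSpec:
    """Population-level behavior parameters for one age group.

    ``params`` holds the group-mean race-model parameters; subjects draw
    individual timing means and stop latencies around them with the given
    between-subject SDs (ms).
    """

    params: RaceModelParams = field(default_factory=RaceModelParams)
    between_rt_sd: float = 9.5
    between_ssrt_sd: float = 12.5

    def __post_init__(self) -> None:
        if self.between_rt_sd < 0 or self.between_ssrt_sd < 0:
            raise ValueError("between-subject SDs must be non-negative")


def _default_young() -> GroupSpec:
    return GroupSpec(
        params=RaceModelParams(
            planned_rt_mean=815.5,
            planned_rt_sd=50.0,
            ssrt_true=193.0,
            proactive_delta_20=0.0,
            proactive_delta_40=10.3,
            early_resp_rate=0.02,
            omission_rate=0.02,
        ),
        between_rt_sd=9.5,
        between_ssrt_sd=12.5,
    )


def _default_older() -> GroupSpec:
    return GroupSpec(
        params=RaceModelParams(
            planned_rt_mean=821.6,
            planned_rt_sd=50.0,
            ssrt_true=206.0,
            proactive_delta_20=0.0,
            proactive_delta_40=13.0,
            early_resp_rate=0.02,
            omission_rate=0.02,
        ),
        between_rt_sd=20.6,
        between_ssrt_sd=18.0,
    )


@dataclass(frozen=True)
class PlantedEffect:
    """A target correlation between one region x metabolite and one behavioral measure.

    ``metabolite`` may be a single metabolite or the ``"NAA/mIns"`` ratio;
    ``measure`` is one of ``go_rt``, ``proactive_slowing``, ``ssrt``.
    """

    group: str
    region: str
    metabolite: str
    measure: str
    r: float

    def __post_init__(self) -> None:
        if not abs(self.r) < 1.0:
            raise ValueError(f"target correlation must satisfy |r| < 1, got {self.r}")
        if self.measure not in ("go_rt", "proactive_slowing", "ssrt"):
            raise ValueError(f"unknown behavioral measure {self.measure!r}")
        if self.region not in _mrs.REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.metabolite not in _mrs.METABOLITES + ("NAA/mIns",):
            raise ValueError(f"unknown metabolite {self.metabolite!r}")


DEFAULT_METABOLITE_MEANS = {
    "NAA": 12.0,
    "Glx": 10.0,
    "Cr": 8.0,
    "Cho": 2.0,
    "mIns": 6.0,
    "NAA/mIns": 2.0,
}
DEFAULT_METABOLITE_SDS = {
    "NAA": 1.2,
    "Glx": 1.0,
    "Cr": 0.8,
    "Cho": 0.25,
    "mIns": 0.9,
    "NAA/mIns": 0.3,
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a two-group synthetic cohort.

    ``anchor`` selects the behavioral quantity the planted correlation is
    measured against: ``"measured"`` (default; the session-averaged measure
    the analysis pipeline itself computes) or ``"true"`` (the subject's
    latent generating parameter).  ``coupling`` selects whether the sample
    correlation is planted exactly (``"exact"``, Gram-Schmidt residual
    construction) or only in expectation (``"population"``).  A group may be
    omitted by setting its n to 0; present groups need n >= 4.
    """

    n_young: int = 25
    n_older: int = 26
    young: GroupSpec = field(default_factory=_default_young)
    older: GroupSpec = field(default_factory=_default_older)
    effects: tuple[PlantedEffect, ...] = ()
    metabolite_means: dict = field(default_factory=lambda: dict(DEFAULT_METABOLITE_MEANS))
    metabolite_sds: dict = field(default_factory=lambda: dict(DEFAULT_METABOLITE_SDS))
    qc_fail_rate: float = 0.04
    anchor: str = "measured"
    coupling: str = "exact"
    design: SessionDesign = field(default_factory=SessionDesign)
    n_sessions: int = 2
    reset_staircase_between_sessions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in (("n_young", self.n_young), ("n_older", self.n_older)):
            if n != 0 and n < 4:
                raise ValueError(f"{name} must be 0 (absent) or >= 4, got {n}")
        if self.n_young == 0 and self.n_older == 0:
            raise ValueError("cohort needs at least one group")
        if self.anchor not in ("measured", "true"):
            raise ValueError(f"anchor must be 'measured' or 'true', got {self.anchor!r}")
        if self.coupling not in ("exact", "population"):
            raise ValueError(
                f"coupling must be 'exact' or 'population', got {self.coupling!r}"
            )
        if not 0.0 <= self.qc_fail_rate <= 1.0:
            raise ValueError("qc_fail_rate must lie in [0, 1]")
        seen = set()
        for e in self.effects:
            key = (e.group, e.region, e.metabolite)
            if key in seen:
                raise ValueError(
                    f"conflicting planted effects for {key}: one target per "
                    "region x metabolite per group"
                )
            seen.add(key)
            if e.metabolite in ("NAA", "mIns") and (
                (e.group, e.region, "NAA/mIns") in seen
            ):
                raise ValueError(
                    f"effect on {e.metabolite} conflicts with a ratio effect in "
                    f"{e.region}"
                )
        for e in self.effects:
            if e.metabolite == "NAA/mIns":
                for m in ("NAA", "mIns"):
                    if (e.group, e.region, m) in seen:
                        raise ValueError(
                            f"ratio effect in {e.region} conflicts with an effect "
                            f"on {m}"
                        )


def simulate_subject(
    params: RaceModelParams,
    *,
    design: SessionDesign | None = None,
    n_sessions: int = 2,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    subject_id: str = "S000",
    group: str = "young",
    reset_staircase_between_sessions: bool = False,
) -> pd.DataFrame:
    """Simulate all sessions for one subject (staircase carried over by default)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    staircase: StaircaseState | None = StaircaseState()
    frames = []
    for s in range(1, n_sessions + 1):
        if reset_staircase_between_sessions:
            staircase = StaircaseState()
        trials, staircase = simulate_session(
            params,
            design,
            rng=rng,
            staircase=staircase,
            subject_id=subject_id,
            group=group,
            session=s,
        )
        frames.append(trials)
    return pd.concat(frames, ignore_index=True)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("anchor variable has zero variance; cannot plant correlation")
    return (x - x.mean()) / sd


def _coupled_scores(
    anchor: np.ndarray, r: float, rng: np.random.Generator, coupling: str
) -> np.ndarray:
    """Unit-scale scores with correlation r against ``anchor``.

    ``exact``: the sample correlation equals r exactly (noise residualized
    against the anchor, Gram-Schmidt); ``population``: r holds in
    expectation only.
    """
    a = _standardize(anchor)
    e = rng.standard_normal(a.size)
    if coupling == "population":
        return r * a + math.sqrt(1.0 - r * r) * e
    e_perp = e - (e @ a) / (a @ a) * a
    sd = e_perp.std(ddof=0)
    if sd == 0.0:
        raise ValueError("degenerate noise draw while planting correlation")
    return r * a + math.sqrt(1.0 - r * r) * (e_perp - e_perp.mean()) / sd


def _subject_anchors(
    spec: CohortSpec,
    group: str,
    subject_params: list[RaceModelParams],
    trials: pd.DataFrame,
) -> pd.DataFrame:
    """Behavioral anchor values per subject for correlation planting."""
    if spec.anchor == "true":
        return pd.DataFrame(
            {
                "go_rt": [p.planned_rt_mean for p in subject_params],
                "proactive_slowing": [
                    p.proactive_delta_40 - p.proactive_delta_20 for p in subject_params
                ],
                "ssrt": [p.ssrt_true for p in subject_params],
            },
            index=trials["subject_id"].unique(),
        )
    perf = _behavior.performance_table(trials)
    return perf.set_index("subject_id")[["go_rt", "proactive_slowing", "ssrt"]]


def _group_panel(
    spec: CohortSpec,
    group: str,
    subject_ids: list[str],
    anchors: pd.DataFrame,
    rng: np.random.Generator,
    constants: _mrs.RelaxationConstants,
) -> pd.DataFrame:
    n = len(subject_ids)
    effects = {
        (e.region, e.metabolite): e for e in spec.effects if e.group == group
    }

    # per subject x region tissue fractions around a typical cortical mix
    frac_rows = {}
    for region in _mrs.REGIONS:
        base = np.array([0.55, 0.35, 0.10])
        noise = rng.normal(0.0, 0.03, size=(n, 3))
        raw = np.clip(base + noise, 0.01, None)
        raw /= raw.sum(axis=1, keepdims=True)
        frac_rows[region] = raw

    def draw_levels(region: str, metabolite: str) -> np.ndarray:
        """Concentration-scale values, with any planted correlation applied."""
        mean = spec.metabolite_means[metabolite]
        sd = spec.metabolite_sds[metabolite]
        eff = effects.get((region, metabolite))
        if eff is not None:
            scores = _coupled_scores(
                anchors.loc[subject_ids, eff.measure].to_numpy(),
                eff.r,
                rng,
                spec.coupling,
            )
        else:
            scores = rng.standard_normal(n)
        return mean + sd * scores

    rows = []
    for region in _mrs.REGIONS:
        ratio_eff = effects.get((region, "NAA/mIns"))
        concentrations = {}
        if ratio_eff is not None:
            # plant the effect on the ratio itself: draw mIns freely and set
            # NAA = ratio * mIns so corrected NAA/mIns carries the target r
            ratio = draw_levels(region, "NAA/mIns")
            mins = draw_levels(region, "mIns")
            concentrations["mIns"] = mins
            concentrations["NAA"] = ratio * mins
            remaining = [m for m in _mrs.METABOLITES if m not in ("NAA", "mIns")]
        else:
            remaining = list(_mrs.METABOLITES)
        for metabolite in remaining:
            concentrations[metabolite] = draw_levels(region, metabolite)

        for metabolite in _mrs.METABOLITES:
            conc = concentrations[metabolite]
            fracs = frac_rows[region]
            fail = rng.random(n) < spec.qc_fail_rate
            snr = np.maximum(rng.normal(15.0, 4.0, size=n), 5.5)
            linewidth = np.clip(rng.normal(6.5, 1.2, size=n), 2.0, 9.5)
            fail_mode = rng.random(n) < 0.5
            snr[fail & fail_mode] = rng.uniform(1.0, 5.0, size=int((fail & fail_mode).sum()))
            linewidth[fail & ~fail_mode] = rng.uniform(
                10.0, 14.0, size=int((fail & ~fail_mode).sum())
            )
            for i, sid in enumerate(subject_ids):
                fr = _mrs.TissueFractions(*fracs[i])
                level = _mrs.signal_from_concentration(conc[i], fr, constants)
                rows.append(
                    (
                        sid,
                        group,
                        region,
                        metabolite,
                        level,
                        snr[i],
                        linewidth[i],
                        fr.f_gm,
                        fr.f_wm,
                        fr.f_csf,
                    )
                )
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def simulate_cohort(
    spec: CohortSpec,
    constants: _mrs.RelaxationConstants | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-group cohort: trial table and metabolite panel.

    All randomness derives from ``spec.seed`` through named per-group
    substreams, so identical specs reproduce bit-identical tables.
    """
    if constants is None:
        constants = _mrs.RelaxationConstants()
    root = np.random.SeedSequence(spec.seed)
    streams = root.spawn(4)
    trial_frames, panel_frames = [], []
    group_defs = [
        ("young", spec.n_young, spec.young, streams[0], streams[1]),
        ("older", spec.n_older, spec.older, streams[2], streams[3]),
    ]
    for group, n, gspec, behav_ss, panel_ss in group_defs:
        if n == 0:
            continue
        behav_rng = np.random.default_rng(behav_ss)
        panel_rng = np.random.default_rng(panel_ss)
        prefix = "Y" if group == "young" else "O"
        subject_ids = [f"{prefix}{i + 1:03d}" for i in range(n)]
        subject_params = []
        frames = []
        for sid in subject_ids:
            p = replace(
                gspec.params,
                planned_rt_mean=behav_rng.normal(
                    gspec.params.planned_rt_mean, gspec.between_rt_sd
                ),
                ssrt_true=max(
                    behav_rng.normal(gspec.params.ssrt_true, gspec.between_ssrt_sd),
                    50.0,
                ),
            )
            subject_params.append(p)
            frames.append(
                simulate_subject(
                    p,
                    design=spec.design,
                    n_sessions=spec.n_sessions,
                    rng=behav_rng,
                    subject_id=sid,
                    group=group,
                    reset_staircase_between_sessions=spec.reset_staircase_between_sessions,
                )
            )
        group_trials = pd.concat(frames, ignore_index=True)
        anchors = _subject_anchors(spec, group, subject_params, group_trials)
        panel_frames.append(
            _group_panel(spec, group, subject_ids, anchors, panel_rng, constants)
        )
        trial_frames.append(group_trials)
    return (
        pd.concat(trial_frames, ignore_index=True),
        pd.concat(panel_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# delimited-text round trips


def write_trials(trials: pd.DataFrame, path) -> None:
    out = trials.copy()
    out["stop_success"] = out["stop_success"].map(
        lambda v: "" if pd.isna(v) else ("true" if v else "false")
    )
    out.to_csv(path, index=False, float_format="%.6f")


def read_trials(path) -> pd.DataFrame:
    trials = pd.read_csv(
        path, dtype={"subject_id": str, "group": str, "stop_success": str}
    )
    trials["stop_success"] = (
        trials["stop_success"]
        .str.lower()
        .map({"true": True, "false": False})
        .astype("boolean")
    )
    return trials[TRIAL_COLUMNS]


def write_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)


def read_panel(path) -> pd.DataFrame:
    panel = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    return panel
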
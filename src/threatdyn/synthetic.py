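"""Synthetic study generator.

Produces complete, seeded studies — counterbalanced 2x3 designs, survey
responses, per-trial covariates, Bernoulli outcomes from the hierarchical
logistic structure, and pixel-level mouse trajectories whose measured AUC,
sample entropy, and RT approximate per-trial targets — so every pipeline
stage is testable without external data.

Covariates are generated first from target marginal distributions (on the
transformed scales the models use) and outcomes second, conditioning on
them, which mirrors the fitted model's direction and enables parameter-
recovery tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import dataio
from .bayes_glm import MODEL_SPECS, ModelSpec, build_design_matrix
from .dataio import AUTH_LEVELS, RawTrajectory
from .entropy import EntropyConfig, multiscale_sample_entropy
from .errors import ConfigError, ValidationError
from .kinematics import distance_to_endpoint_series, normalize_trajectory, response_angle

#: Credible coefficient point estimates used as simulation truth defaults
#: (standardized predictor scale).
TWO_FACTOR_TRUTH = {
    "intercept": 1.63,
    "spoof": -1.69,
    "spoof:auth": -0.56,
}

REAL_TIME_TRUTH = {
    "intercept": 2.18,
    "spoof": -2.43,
    "auth": 0.74,
    "knowledge": 2.12,
    "familiarity": 1.10,
    "auc": 1.57,
    "se": -1.47,
    "spoof:auth": -1.40,
    "spoof:auc": -3.90,
    "spoof:se": 2.01,
    "spoof:rt": 1.66,
    "auth:auc": 1.73,
    "knowledge:se": 2.35,
    "auc:se": 1.60,
    "se:rt": -2.69,
    "spoof:auth:auc": -2.26,
    "spoof:auc:se": -3.25,
    "auth:knowledge:auc": 1.82,
    "auth:knowledge:se": -1.54,
    "auc:se:rt": 1.98,
}

TRUTH_BY_MODEL = {"two_factor": TWO_FACTOR_TRUTH, "real_time": REAL_TIME_TRUTH}

#: Marginal targets on the transformed scales (mean, sd).
COVARIATE_TARGETS = {
    "auc": (1.31, 1.29),  # signed-log scale
    "se": (-2.34, 0.65),  # log scale
    "rt": (8.96, 0.51),  # ln milliseconds
}

#: Discrete familiarity distribution over 1..5 (mean 3.16, SD 1.62).
FAMILIARITY_PROBS = (0.26, 0.13, 0.13, 0.15, 0.33)

#: Beta parameters giving knowledge mean 0.52, SD 0.25 before 0.1-gridding.
KNOWLEDGE_BETA = (1.555, 1.435)

START_PX = (960, 540)
BACK_BUTTON_PX = (60, 40)
SCREEN = (1920, 1080)

#: Time penalties for incorrect responses (recorded as run metadata).
PENALTY_S = {"login_to_spoof": 10.0, "back_from_legit": 20.0}

SITE_VERSIONS = ("a", "b")


@dataclass
class SynthConfig:
    """All knobs of the generator; the seed fully determines the output."""

    n_participants: int = 123
    trials_per_participant: int = 6
    seed: int = 0
    truth_model: str = "real_time"
    beta_true: dict = field(default_factory=dict)  # empty -> model default
    sigma_u: float = 0.85
    knowledge_beta: tuple[float, float] = KNOWLEDGE_BETA
    familiarity_probs: tuple[float, ...] = FAMILIARITY_PROBS
    covariate_targets: dict = field(default_factory=lambda: dict(COVARIATE_TARGETS))
    condition_shifts: dict = field(
        default_factory=lambda: {"auc": 0.2, "rt": 0.05, "se": 0.0}
    )  # additive spoof-trial shift on the transformed scale
    sample_rate_hz: float = 60.0
    n_unusable: int = 2
    penalties_s: dict = field(default_factory=lambda: dict(PENALTY_S))

    def __post_init__(self) -> None:
        if self.truth_model not in TRUTH_BY_MODEL:
            raise ConfigError(f"unknown truth model {self.truth_model!r}")
        if self.trials_per_participant % 6 != 0:
            raise ConfigError("trials_per_participant must be a multiple of 6")

    @property
    def truth(self) -> dict:
        return self.beta_true or TRUTH_BY_MODEL[self.truth_model]

    @property
    def truth_spec(self) -> ModelSpec:
        return MODEL_SPECS[self.truth_model]

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, tuple):
                return [plain(x) for x in v]
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            return v

        return {k: plain(v) for k, v in asdict(self).items()}


def _site_label(auth_level: str, version: str) -> str:
    return f"{auth_level.lower()}_{version}"


def gen_design(config: SynthConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Trial conditions: each participant gets every site_type x auth cell.

    Counterbalancing alternates which website version is the spoofed one
    between the two participant halves.  Trial order is randomized per
    participant.
    """
    rng = rng or np.random.default_rng(config.seed)
    reps = config.trials_per_participant // 6
    rows = []
    for i in range(config.n_participants):
        pid = f"p{i:04d}"
        group = i % 2
        cells = [
            (st, auth)
            for st in ("non_spoof", "spoof")
            for auth in AUTH_LEVELS
            for _ in range(reps)
        ]
        order = rng.permutation(len(cells))
        for k, idx in enumerate(order):
            st, auth = cells[idx]
            spoof_version = SITE_VERSIONS[group]
            version = (
                spoof_version
                if st == "spoof"
                else SITE_VERSIONS[1 - SITE_VERSIONS.index(spoof_version)]
            )
            rows.append(
                {
                    "participant_id": pid,
                    "trial_id": f"t{k}",
                    "site": _site_label(auth, version),
                    "site_type": st,
                    "auth_level": auth,
                    "counterbalance_group": group,
                }
            )
    return pd.DataFrame(rows)


def gen_survey(
    config: SynthConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Participant-level survey records (knowledge, indicators, familiarity)."""
    n = config.n_participants
    a, b = config.knowledge_beta
    knowledge_correct = np.clip(
        np.round(10 * rng.beta(a, b, size=n)), 0, 10
    ).astype(int)
    fam_levels = np.arange(1, 6)
    probs = np.asarray(config.familiarity_probs, dtype=float)
    probs = probs / probs.sum()
    sites = [_site_label(auth, v) for auth in AUTH_LEVELS for v in SITE_VERSIONS]
    rows = []
    for i in range(n):
        row = {
            "participant_id": f"p{i:04d}",
            "knowledge_correct": int(knowledge_correct[i]),
            "indicators_correct": int(rng.integers(0, 4)),
            "indicators_incorrect": int(rng.integers(0, 5)),
            "age": int(np.clip(18 + rng.gamma(2.0, 6.5), 18, 75)),
            "gender": str(rng.choice(["female", "male"], p=[0.41, 0.59])),
        }
        for site in sites:
            row[f"familiarity_{site}"] = int(rng.choice(fam_levels, p=probs))
        rows.append(row)
    return pd.DataFrame(rows)


def gen_covariates(
    design: pd.DataFrame, survey: pd.DataFrame, config: SynthConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-trial covariates on both raw and transformed scales."""
    table = design.merge(
        survey[["participant_id", "knowledge_correct"]], on="participant_id"
    )
    table["knowledge"] = table["knowledge_correct"] / 10.0
    fam_lookup = survey.set_index("participant_id")
    table["familiarity"] = [
        int(fam_lookup.loc[pid, f"familiarity_{site}"])
        for pid, site in zip(table["participant_id"], table["site"])
    ]
    n = len(table)
    spoof = (table["site_type"] == "spoof").to_numpy(dtype=float)
    t_vals = {}
    for name in ("auc", "se", "rt"):
        mean, sd = config.covariate_targets[name]
        shift = config.condition_shifts.get(name, 0.0)
        t_vals[name] = rng.normal(mean, sd, size=n) + shift * spoof
    table["auc"] = np.sign(t_vals["auc"]) * np.expm1(np.abs(t_vals["auc"]))
    table["se_raw"] = np.exp(t_vals["se"])
    table["se_log"] = t_vals["se"]
    table["rt_s"] = np.exp(t_vals["rt"]) / 1000.0
    return table.drop(columns=["knowledge_correct"])


def gen_outcomes(
    table: pd.DataFrame,
    config: SynthConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Accuracy and response per trial from the logistic truth.

    Participant intercepts are Normal(0, sigma_u); the linear predictor is
    the truth-model design matrix (standardized within this sample) times
    the true coefficient vector.  Response follows from accuracy and site
    type (correct on non-spoof = login, correct on spoof = back).
    """
    spec = config.truth_spec
    design = build_design_matrix(table, spec)
    beta = np.array([config.truth.get(label, 0.0) for label in design.labels])
    pids = sorted(table["participant_id"].unique())
    u = rng.normal(0.0, config.sigma_u, size=len(pids))
    u_map = dict(zip(pids, u))
    eta = design.X @ beta + np.array(
        [u_map[pid] for pid in table["participant_id"]]
    )
    prob = 1.0 / (1.0 + np.exp(-eta))
    accuracy = (rng.random(len(table)) < prob).astype(int)
    table = table.copy()
    table["accuracy"] = accuracy
    is_spoof = table["site_type"] == "spoof"
    table["response"] = np.where(
        accuracy == 1,
        np.where(is_spoof, "back", "login"),
        np.where(is_spoof, "login", "back"),
    )
    truth = {
        "model": config.truth_model,
        "beta": {k: float(v) for k, v in zip(design.labels, beta)},
        "sigma_u": config.sigma_u,
        "u": {pid: float(val) for pid, val in u_map.items()},
        "transform": design.meta.to_dict(),
    }
    return table, truth


# ---------------------------------------------------------------------------
# trajectory synthesis

_SE_CAL_BUCKETS = (120, 240, 480, 960, 1920)
_SE_CAL_AMPS = (0.0005, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05, 0.1, 0.2)
_se_calibration_cache: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}

DWELL_FRAC = 0.6  # fraction of samples spent hovering before the approach


def _distance_profile(
    n: int, amp: float, rng: np.random.Generator, dwell_frac: float = DWELL_FRAC
) -> np.ndarray:
    """Distance-to-endpoint series: dwell, minimum-jerk descent, AR jitter.

    The series starts at exactly 1 (the unit chord) and ends at exactly 0;
    ``amp`` scales autoregressive jitter that carries the entropy target.
    """
    n_dwell = int(dwell_frac * n)
    n_move = max(n - n_dwell, 4)
    n_dwell = n - n_move
    tau = np.linspace(0.0, 1.0, n_move)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5  # minimum-jerk progress
    d = np.concatenate([np.ones(n_dwell), 1.0 - s])
    if amp > 0:
        phi = 0.9
        innov = rng.standard_normal(n) * np.sqrt(1 - phi**2)
        e = np.empty(n)
        e[0] = innov[0]
        for i in range(1, n):
            e[i] = phi * e[i - 1] + innov[i]
        d = d + amp * e
        d[0], d[-1] = 1.0, 0.0
        d = np.maximum(d, 0.0)
    return d


def _se_calibration(
    n: int, dwell_frac: float = DWELL_FRAC
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical jitter-amplitude -> mean se_raw map for a sample-count bucket."""
    bucket = min(_SE_CAL_BUCKETS, key=lambda b: abs(b - n))
    key = (bucket, round(dwell_frac, 3))
    if key not in _se_calibration_cache:
        rng = np.random.default_rng(123456 + bucket)
        amps = np.asarray(_SE_CAL_AMPS)
        means = []
        for amp in amps:
            vals = [
                multiscale_sample_entropy(
                    _distance_profile(bucket, amp, rng, dwell_frac)
                ).se_raw
                for _ in range(2)
            ]
            means.append(np.mean(vals))
        means = np.maximum.accumulate(np.asarray(means))
        means += 1e-9 * np.arange(means.size)  # keep interp abscissae increasing
        _se_calibration_cache[key] = (amps, means)
    return _se_calibration_cache[key]


def _solve_sweep(d: np.ndarray, target_area: float) -> float:
    """Total angular sweep giving the target signed polygon area.

    The path is radial around the endpoint with uniform angular increments,
    so the closed-curve shoelace area is 0.5 * sin(c/(n-1)) * sum(d_i d_{i+1})
    — solved for c in closed form.  Unreachable targets are clamped to the
    maximum with a warning.
    """
    S = float(np.dot(d[:-1], d[1:]))
    if S == 0.0:
        return 0.0
    x = 2.0 * target_area / S
    if abs(x) > 1.0:
        warnings.warn(
            f"area target {target_area:.3g} infeasible (max {S / 2:.3g}); clamping",
            stacklevel=3,
        )
        x = float(np.clip(x, -1.0, 1.0))
    return float(np.arcsin(x) * (d.size - 1))


def gen_trajectory(
    response: str,
    target_auc: float,
    target_se_raw: float,
    rt_s: float,
    rate: float = 60.0,
    rng: np.random.Generator | None = None,
    participant_id: str = "p0000",
    trial_id: str = "t0",
    start_px: tuple[int, int] = START_PX,
    button_px: tuple[int, int] | None = None,
    screen: tuple[int, int] = SCREEN,
    dwell_frac: float = DWELL_FRAC,
) -> RawTrajectory:
    """Pixel trajectory whose normalized AUC and entropy approximate targets.

    The distance-to-endpoint profile (dwell, then a minimum-jerk approach,
    plus autoregressive jitter calibrated against an empirical amplitude ->
    entropy map) carries the entropy target; an angular sweep around the
    endpoint, solved in closed form, carries the signed-area target.
    Sample count is ``rt_s * rate``; timestamps span the response time.
    """
    if rt_s <= 0 or rate <= 0:
        raise ValidationError("rt_s and rate must be positive")
    rng = rng or np.random.default_rng(0)
    if button_px is None:
        if response == "back":
            button_px = BACK_BUTTON_PX
        else:
            button_px = (int(rng.integers(900, 1700)), int(rng.integers(500, 1000)))
    n = max(20, int(round(rt_s * rate)))

    if target_se_raw <= 0:
        amp = 0.0
    else:
        amps, se_means = _se_calibration(n, dwell_frac)
        amp = float(
            np.exp(np.interp(np.log(target_se_raw), np.log(se_means), np.log(amps)))
        )
    d = _distance_profile(n, amp, rng, dwell_frac)

    # normalized frame: endpoint on the response ray, radial path around it
    theta = response_angle(response)
    shoelace_target = target_auc if response == "back" else -target_auc
    sweep = _solve_sweep(d, shoelace_target)
    psi = theta + sweep * np.linspace(0.0, 1.0, n)
    ex, ey = np.cos(theta), np.sin(theta)
    nx = ex - d * np.cos(psi)
    ny = ey - d * np.sin(psi)

    # embed into screen pixels: start -> start_px, end -> button_px
    dx = button_px[0] - start_px[0]
    dy = button_px[1] - start_px[1]
    mx, my = float(dx), float(-dy)  # math-coordinate chord (y up)
    L = float(np.hypot(mx, my))
    if L == 0:
        raise ValidationError("start and button positions coincide")
    phi = np.arctan2(my, mx) - theta
    cp, sp = np.cos(phi), np.sin(phi)
    qx = L * (cp * nx - sp * ny)
    qy = L * (sp * nx + cp * ny)
    x = np.round(start_px[0] + qx).astype(np.int64)
    y = np.round(start_px[1] - qy).astype(np.int64)
    x[0], y[0] = start_px
    x[-1], y[-1] = button_px

    rt_ms = int(round(rt_s * 1000))
    t = np.round(np.linspace(0.0, rt_ms, n)).astype(np.int64)
    return RawTrajectory(
        participant_id=participant_id,
        trial_id=trial_id,
        t=t,
        x=x,
        y=y,
        page_load_t=0,
        final_click=(rt_ms, int(button_px[0]), int(button_px[1])),
        response=response,
        screen=screen,
    )


@dataclass
class SyntheticDataset:
    trials: pd.DataFrame
    survey: pd.DataFrame
    trajectories: dict[tuple[str, str], RawTrajectory]
    covariate_table: pd.DataFrame  # per-trial true covariates and outcomes
    truth: dict
    config: SynthConfig


def gen_dataset(
    config: SynthConfig, out_dir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a full study; optionally write the three schema files.

    When ``out_dir`` is given, writes ``trajectories.csv``, ``trials.csv``,
    ``survey.csv``, and a ``metadata.json`` sidecar (seed, penalties,
    truth parameters).  Identical seeds produce identical files.
    """
    rng = np.random.default_rng(config.seed)
    design = gen_design(config, rng)
    survey = gen_survey(config, rng)
    table = gen_covariates(design, survey, config, rng)
    table, truth = gen_outcomes(table, config, rng)

    trajectories: dict[tuple[str, str], RawTrajectory] = {}
    for rec in table.to_dict(orient="records"):
        key = (rec["participant_id"], rec["trial_id"])
        trajectories[key] = gen_trajectory(
            rec["response"],
            rec["auc"],
            rec["se_raw"],
            rec["rt_s"],
            rate=config.sample_rate_hz,
            rng=rng,
            participant_id=rec["participant_id"],
            trial_id=rec["trial_id"],
        )

    trials = table[
        ["participant_id", "trial_id", "site_type", "auth_level", "response", "site"]
    ].copy()
    trials["usable"] = 1
    if config.n_unusable > 0:
        drop_idx = rng.choice(len(trials), size=config.n_unusable, replace=False)
        trials.iloc[drop_idx, trials.columns.get_loc("usable")] = 0

    dataset = SyntheticDataset(
        trials=trials,
        survey=survey,
        trajectories=trajectories,
        covariate_table=table,
        truth=truth,
        config=config,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        dataio.write_trajectories(trajectories, out_dir / "trajectories.csv")
        dataio.write_trials(trials, out_dir / "trials.csv")
        dataio.write_surveys(survey, out_dir / "survey.csv")
        meta = {
            "seed": config.seed,
            "penalties_s": config.penalties_s,
            "truth": truth,
            "config": {
                k: v
                for k, v in config.to_dict().items()
                if not isinstance(v, (np.ndarray,))
            },
        }
        (out_dir / "metadata.json").write_text(json.dumps(meta, indent=2))
    return dataset
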
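"""Hierarchical Bayesian logistic models of trial accuracy.

Three nested model specifications share one machinery:

* ``two_factor`` — spoof and authentication level, interactions to order 2.
* ``survey_based`` — adds knowledge and familiarity, interactions to order 3.
* ``real_time`` — adds AUC, sample entropy, and RT, interactions to order 3.

Coding: spoof is 0/1 (non-spoof baseline), authentication is the centered
linear ordinal contrast (PE=-1, SV=0, EV=+1), and continuous predictors
are transformed (ln ms for RT, ln for raw sample entropy, signed log for
AUC) then centered and scaled to unit SD, so the intercept is the logit of
accuracy in the non-spoof, standard-validation cell at average covariates.

Priors are Student-t with 3 degrees of freedom: scale 5 on coefficients,
scale 10 on the intercept, and half-Student-t(3, 0, 10) on the group SD of
the partially pooled participant intercepts.  The posterior is explored by
the package's own NUTS sampler on a non-centered parameterization.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import AUTH_CODE
from .errors import ConvergenceError, ValidationError
from .sampling import SamplerConfig, sample_nuts

PRIOR_DF = 3.0
COEF_SCALE = 5.0
INTERCEPT_SCALE = 10.0
GROUP_SD_SCALE = 10.0

CATEGORICAL_PREDICTORS = ("spoof", "auth")
CONTINUOUS_PREDICTORS = ("knowledge", "familiarity", "auc", "se", "rt")

#: Transform applied to each continuous predictor before standardization.
TRANSFORMS = {
    "knowledge": "identity",
    "familiarity": "identity",
    "auc": "signed_log",
    "se": "log",
    "rt": "log_ms",
}

#: Continuous predictors are centered and divided by ``SD_SCALE_FACTOR``
#: standard deviations.  Two SDs puts them on the same footing as the 0/1
#: site-type factor and matches figure axes running -1..+1 at +/-2 SD;
#: unit-SD coding makes the reported coefficient magnitudes imply
#: quasi-separated outcomes.
SD_SCALE_FACTOR = 2.0


@dataclass(frozen=True)
class ModelSpec:
    """Declarative definition of one accuracy model."""

    name: str
    predictors: tuple[str, ...]
    max_interaction_order: int

    def __post_init__(self) -> None:
        known = CATEGORICAL_PREDICTORS + CONTINUOUS_PREDICTORS
        unknown = [p for p in self.predictors if p not in known]
        if unknown:
            raise ValidationError(f"unknown predictors {unknown}")

    @property
    def n_columns(self) -> int:
        p = len(self.predictors)
        return sum(
            len(list(itertools.combinations(range(p), k)))
            for k in range(self.max_interaction_order + 1)
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "predictors": list(self.predictors),
            "max_interaction_order": self.max_interaction_order,
        }


MODEL_SPECS: dict[str, ModelSpec] = {
    "two_factor": ModelSpec("two_factor", ("spoof", "auth"), 2),
    "survey_based": ModelSpec(
        "survey_based", ("spoof", "auth", "knowledge", "familiarity"), 3
    ),
    "real_time": ModelSpec(
        "real_time",
        ("spoof", "auth", "knowledge", "familiarity", "auc", "se", "rt"),
        3,
    ),
}


@dataclass
class TransformMeta:
    """Centering/scaling constants so held-out data project identically."""

    centers: dict[str, float]
    scales: dict[str, float]

    def to_dict(self) -> dict:
        return {"centers": dict(self.centers), "scales": dict(self.scales)}


@dataclass
class DesignMatrix:
    X: np.ndarray
    labels: list[str]
    meta: TransformMeta
    row_index: np.ndarray  # indices of table rows kept


def _raw_predictor(table: pd.DataFrame, name: str) -> np.ndarray:
    if name == "spoof":
        return (table["site_type"] == "spoof").to_numpy(dtype=float)
    if name == "auth":
        return table["auth_level"].map(AUTH_CODE).to_numpy(dtype=float)
    if name == "knowledge":
        return table["knowledge"].to_numpy(dtype=float)
    if name == "familiarity":
        return table["familiarity"].to_numpy(dtype=float)
    if name == "auc":
        a = table["auc"].to_numpy(dtype=float)
        return np.sign(a) * np.log1p(np.abs(a))
    if name == "se":
        if "se_log" in table.columns and table["se_log"].notna().all():
            return table["se_log"].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            return np.log(table["se_raw"].to_numpy(dtype=float))
    if name == "rt":
        return np.log(table["rt_s"].to_numpy(dtype=float) * 1000.0)
    raise ValidationError(f"unknown predictor {name!r}")


def build_design_matrix(
    table: pd.DataFrame,
    spec: ModelSpec,
    meta: TransformMeta | None = None,
    na_action: str = "error",
) -> DesignMatrix:
    """Design matrix with all main effects and interactions up to the
    spec's order.

    When ``meta`` is supplied (projection of held-out data) its centering
    and scaling constants are reused; otherwise they are estimated from
    ``table`` and recorded.  Non-finite transformed values raise by
    default; ``na_action='drop'`` flags and drops the offending rows.
    """
    fitting = meta is None
    centers: dict[str, float] = {} if fitting else meta.centers
    scales: dict[str, float] = {} if fitting else meta.scales

    raw = {name: _raw_predictor(table, name) for name in spec.predictors}
    finite = np.ones(len(table), dtype=bool)
    for name, vals in raw.items():
        finite &= np.isfinite(vals)
    if not finite.all():
        if na_action == "drop":
            raw = {k: v[finite] for k, v in raw.items()}
        else:
            bad = np.flatnonzero(~finite)
            raise ValidationError(
                f"non-finite transformed predictor values at rows {bad[:5].tolist()}"
            )
    row_index = np.flatnonzero(finite)

    coded = {}
    for name in spec.predictors:
        vals = raw[name]
        if name in CONTINUOUS_PREDICTORS:
            if fitting:
                centers[name] = float(np.mean(vals))
                sd = float(np.std(vals, ddof=0))
                scales[name] = SD_SCALE_FACTOR * sd if sd > 0 else 1.0
            vals = (vals - centers[name]) / scales[name]
        coded[name] = vals

    n = len(row_index)
    columns = [np.ones(n)]
    labels = ["intercept"]
    for order in range(1, spec.max_interaction_order + 1):
        for combo in itertools.combinations(spec.predictors, order):
            col = np.ones(n)
            for name in combo:
                col = col * coded[name]
            columns.append(col)
            labels.append(":".join(combo))
    X = np.column_stack(columns)
    return DesignMatrix(
        X=X,
        labels=labels,
        meta=TransformMeta(centers=centers, scales=scales),
        row_index=row_index,
    )


# ---------------------------------------------------------------------------
# posterior

def _student_t_logp_grad(theta: np.ndarray, scale: np.ndarray):
    """Unnormalized Student-t(df=3) log density and gradient."""
    s2 = PRIOR_DF * scale**2
    logp = -0.5 * (PRIOR_DF + 1.0) * np.log1p(theta**2 / s2)
    grad = -(PRIOR_DF + 1.0) * theta / (s2 + theta**2)
    return float(np.sum(logp)), grad


def make_logp_grad(
    X: np.ndarray,
    y: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    coef_scales: np.ndarray,
):
    """Joint log density and gradient of (beta, z, log sigma_u).

    Non-centered parameterization: participant intercepts are
    ``u_j = sigma_u * z_j`` with standard-normal ``z``.
    """
    p = X.shape[1]
    Xt = X.T
    n = X.shape[0]

    def logp_grad(theta: np.ndarray):
        beta = theta[:p]
        z = theta[p : p + n_groups]
        ls = theta[-1]
        sigma = np.exp(ls)

        logp, gbeta = _student_t_logp_grad(beta, coef_scales)
        logp += -0.5 * float(np.dot(z, z))
        gz = -z
        # half-Student-t(3, 0, GROUP_SD_SCALE) on sigma, plus log Jacobian
        s2 = PRIOR_DF * GROUP_SD_SCALE**2
        logp += -0.5 * (PRIOR_DF + 1.0) * np.log1p(sigma**2 / s2) + ls
        gls = -(PRIOR_DF + 1.0) * sigma**2 / (s2 + sigma**2) + 1.0

        if n:
            eta = X @ beta + sigma * z[group_idx]
            logp += float(np.dot(y, eta) - np.sum(np.logaddexp(0.0, eta)))
            resid = y - 1.0 / (1.0 + np.exp(-eta))
            gbeta = gbeta + Xt @ resid
            gz = gz + sigma * np.bincount(group_idx, weights=resid, minlength=n_groups)
            gls += sigma * float(np.dot(z[group_idx], resid))
        return logp, np.concatenate([gbeta, gz, [gls]])

    return logp_grad


@dataclass
class PosteriorFit:
    """Posterior draws and diagnostics for one fitted model."""

    spec: ModelSpec
    labels: list[str]
    meta: TransformMeta
    beta: np.ndarray  # (chains, draws, p)
    u: np.ndarray  # (chains, draws, J) on the natural (logit) scale
    sigma_u: np.ndarray  # (chains, draws)
    participant_index: dict[str, int]
    diagnostics: dict
    sampler_config: SamplerConfig

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    @property
    def beta_flat(self) -> np.ndarray:
        return self.beta.reshape(-1, self.beta.shape[-1])

    @property
    def u_flat(self) -> np.ndarray:
        return self.u.reshape(-1, self.u.shape[-1])

    @property
    def sigma_flat(self) -> np.ndarray:
        return self.sigma_u.reshape(-1)

    def coefficient_summary(self) -> pd.DataFrame:
        flat = self.beta_flat
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        return pd.DataFrame(
            {
                "coefficient": self.labels,
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "q2.5": lo,
                "q97.5": hi,
            }
        )


def _compute_diagnostics(beta, u, sigma_u, labels):
    import arviz as az

    data = {"beta": beta, "sigma_u": sigma_u[..., None]}
    if u.shape[-1]:
        data["u"] = u
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=data)
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    out = {"rhat": {}, "ess": {}}
    for var, names in (("beta", labels), ("u", None), ("sigma_u", None)):
        if var not in rhat:
            continue
        r = np.atleast_1d(rhat[var].values)
        e = np.atleast_1d(ess[var].values)
        for i, (rv, ev) in enumerate(zip(r, e)):
            name = names[i] if names is not None else f"{var}[{i}]"
            if var == "sigma_u":
                name = "sigma_u"
            out["rhat"][name] = float(rv)
            out["ess"][name] = float(ev)
    return out


def fit_model(
    design: DesignMatrix | np.ndarray,
    y: np.ndarray,
    participant_ids,
    spec: ModelSpec,
    sampler_config: SamplerConfig | None = None,
) -> PosteriorFit:
    """Sample the posterior of the hierarchical logistic model.

    Raises :class:`~threatdyn.errors.ConvergenceError` naming the offending
    parameters when any split-R-hat exceeds ``sampler_config.rhat_tol``.
    """
    sampler_config = sampler_config or SamplerConfig()
    if isinstance(design, DesignMatrix):
        X, labels, meta = design.X, design.labels, design.meta
    else:
        X = np.asarray(design, dtype=float)
        labels = [f"b{i}" for i in range(X.shape[1])]
        meta = TransformMeta(centers={}, scales={})
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n and not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("outcomes must be binary")

    pids = [str(pid) for pid in participant_ids]
    unique = sorted(set(pids))
    if n and len(unique) < 2:
        raise ValidationError("need at least 2 participants")
    participant_index = {pid: j for j, pid in enumerate(unique)}
    group_idx = np.array([participant_index[pid] for pid in pids], dtype=np.int64)
    J = len(unique)

    coef_scales = np.full(p, COEF_SCALE)
    if "intercept" in labels:
        coef_scales[labels.index("intercept")] = INTERCEPT_SCALE

    logp_grad = make_logp_grad(X, y, group_idx, J, coef_scales)
    dim = p + J + 1
    init = np.zeros(dim)
    init[-1] = np.log(0.5)
    draws = sample_nuts(logp_grad, dim, sampler_config, init=init)

    beta = draws[:, :, :p]
    z = draws[:, :, p : p + J]
    sigma_u = np.exp(draws[:, :, -1])
    u = z * sigma_u[:, :, None]

    if sampler_config.chains >= 2:
        diagnostics = _compute_diagnostics(beta, u, sigma_u, labels)
    else:
        diagnostics = {"rhat": {}, "ess": {}}
    if sampler_config.rhat_tol is not None and diagnostics["rhat"]:
        bad = [
            name
            for name, val in diagnostics["rhat"].items()
            if np.isfinite(val) and val > sampler_config.rhat_tol
        ]
        if bad:
            raise ConvergenceError(
                f"split-R-hat above {sampler_config.rhat_tol} for {bad}",
                parameters=bad,
            )
    return PosteriorFit(
        spec=spec,
        labels=list(labels),
        meta=meta,
        beta=beta,
        u=u,
        sigma_u=sigma_u,
        participant_index=participant_index,
        diagnostics=diagnostics,
        sampler_config=sampler_config,
    )


def posterior_predict(
    fit: PosteriorFit,
    X: np.ndarray,
    participant_ids=None,
    rng: np.random.Generator | None = None,
    u_mode: str = "auto",
) -> np.ndarray:
    """Per-draw success probabilities for the given design rows.

    Rows must already be projected with the fit's transform metadata.
    Participants unseen at fit time (or ``participant_ids=None``) get a
    fresh intercept drawn from Normal(0, sigma_u) per draw.
    ``u_mode='zero'`` suppresses the participant term entirely
    (population-level prediction at u = 0).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = fit.beta.shape[-1]
    if X.shape[1] != p:
        raise ValidationError(f"design has {X.shape[1]} columns, expected {p}")
    rng = rng or np.random.default_rng(fit.sampler_config.seed + 1)
    S = fit.n_draws
    eta = fit.beta_flat @ X.T  # (S, n)
    if u_mode == "zero":
        pass
    elif participant_ids is None:
        eta = eta + rng.standard_normal((S, X.shape[0])) * fit.sigma_flat[:, None]
    else:
        pids = [str(pid) for pid in participant_ids]
        known = np.array([pid in fit.participant_index for pid in pids])
        if known.any():
            idx = np.array(
                [fit.participant_index[pid] for pid, k in zip(pids, known) if k]
            )
            eta[:, known] += fit.u_flat[:, idx]
        if (~known).any():
            fresh_ids = sorted({pid for pid, k in zip(pids, known) if not k})
            fresh_u = {
                pid: rng.standard_normal(S) * fit.sigma_flat for pid in fresh_ids
            }
            for col, (pid, k) in enumerate(zip(pids, known)):
                if not k:
                    eta[:, col] += fresh_u[pid]
    return 1.0 / (1.0 + np.exp(-eta))


def condition_means(
    fit: PosteriorFit,
    table: pd.DataFrame,
    site_type: str,
    auth_level: str,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Posterior distribution of mean accuracy in one design cell.

    Averages posterior-predicted probabilities over the cell's rows,
    marginalizing participant effects (fresh intercept draws).
    """
    mask = (table["site_type"] == site_type) & (table["auth_level"] == auth_level)
    cell = table[mask]
    if cell.empty:
        raise ValidationError(f"no rows in condition {site_type}/{auth_level}")
    design = build_design_matrix(cell, fit.spec, meta=fit.meta)
    probs = posterior_predict(fit, design.X, participant_ids=None, rng=rng)
    return probs.mean(axis=1)
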
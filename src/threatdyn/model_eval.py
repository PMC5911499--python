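"""Model evaluation: ELPD, k-fold cross-validation, posterior-predictive
accuracy, pairwise comparison distributions, and the small auxiliary
Bayesian comparisons (two-group mean difference, simple regression slope).

ELPD here is the sum over observations of the Bernoulli log probability of
the observed outcome, evaluated per posterior draw, so every comparison is
a distribution over draws.  Cross-validation folds are trial-level and
stratified by condition cell so each participant keeps training trials in
every fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayes_glm import (
    ModelSpec,
    PosteriorFit,
    build_design_matrix,
    fit_model,
    posterior_predict,
)
from .errors import ValidationError
from .sampling import SamplerConfig

logger = logging.getLogger(__name__)

P_CLAMP = 1e-12


@dataclass
class ElpdResult:
    """Per-observation Bernoulli log densities, draws x observations."""

    log_density: np.ndarray  # (S, n)
    fold_ids: np.ndarray  # (n,)
    scope: str  # "in_sample" | "out_of_sample"

    def __post_init__(self) -> None:
        if np.any(self.log_density > 1e-9):
            raise ValidationError("Bernoulli log densities must be <= 0")

    @property
    def per_draw_totals(self) -> np.ndarray:
        return self.log_density.sum(axis=1)

    @property
    def n_obs(self) -> int:
        return self.log_density.shape[1]

    def summary(self) -> dict:
        totals = self.per_draw_totals
        lo, hi = np.percentile(totals, [2.5, 97.5])
        return {
            "scope": self.scope,
            "mean": float(totals.mean()),
            "q2.5": float(lo),
            "q97.5": float(hi),
            "n_obs": self.n_obs,
        }


@dataclass
class AccuracyResult:
    """Posterior-predictive accuracy distribution, overall and by site type."""

    overall: np.ndarray  # (S,)
    by_site_type: dict[str, np.ndarray]
    rule: str

    def summary(self) -> dict:
        def s(draws):
            lo, hi = np.percentile(draws, [2.5, 97.5])
            return {"mean": float(draws.mean()), "q2.5": float(lo), "q97.5": float(hi)}

        out = {"rule": self.rule, "overall": s(self.overall)}
        for k, v in self.by_site_type.items():
            out[k] = s(v)
        return out


@dataclass
class ComparisonResult:
    """Paired per-draw difference of two ELPD (or accuracy) distributions."""

    diff: np.ndarray
    mean: float
    q2_5: float
    q97_5: float
    note: str = (
        "an ELPD difference of d corresponds to a likelihood ratio of exp(d)"
    )

    def summary(self) -> dict:
        return {
            "mean": self.mean,
            "q2.5": self.q2_5,
            "q97.5": self.q97_5,
            "credible": bool(self.q2_5 > 0 or self.q97_5 < 0),
        }


def pointwise_log_density(probs: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Bernoulli log density per draw and observation.

    ``probs`` is (S, n); probabilities at exactly 0 or 1 are clamped to
    [P_CLAMP, 1 - P_CLAMP] with a warning.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.asarray(y, dtype=float)
    if np.any((probs <= 0) | (probs >= 1)):
        logger.warning("clamping degenerate predicted probabilities")
        probs = np.clip(probs, P_CLAMP, 1.0 - P_CLAMP)
    return y * np.log(probs) + (1.0 - y) * np.log1p(-probs)


def elpd_from_fit(
    fit: PosteriorFit,
    X: np.ndarray,
    y: np.ndarray,
    participant_ids,
    scope: str = "in_sample",
    fold_ids: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ElpdResult:
    probs = posterior_predict(fit, X, participant_ids=participant_ids, rng=rng)
    ld = pointwise_log_density(probs, y)
    if fold_ids is None:
        fold_ids = np.zeros(ld.shape[1], dtype=int)
    return ElpdResult(log_density=ld, fold_ids=np.asarray(fold_ids), scope=scope)


def model_accuracy(
    probs: np.ndarray,
    y: np.ndarray,
    site_type: np.ndarray | None = None,
    rule: str = "bernoulli",
    rng: np.random.Generator | None = None,
) -> AccuracyResult:
    """Accuracy distribution over posterior draws.

    ``bernoulli`` (default): sample predicted labels from the predictive
    probabilities per draw; ``threshold``: predict 1 when p >= 0.5.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    y = np.asarray(y, dtype=float)
    if rule == "bernoulli":
        rng = rng or np.random.default_rng(0)
        yhat = rng.random(probs.shape) < probs
    elif rule == "threshold":
        yhat = probs >= 0.5
    else:
        raise ValidationError(f"unknown accuracy rule {rule!r}")
    correct = yhat == (y > 0.5)
    overall = correct.mean(axis=1)
    by_site: dict[str, np.ndarray] = {}
    if site_type is not None:
        site_type = np.asarray(site_type)
        for st in np.unique(site_type):
            by_site[str(st)] = correct[:, site_type == st].mean(axis=1)
    return AccuracyResult(overall=overall, by_site_type=by_site, rule=rule)


def compare_models(a, b) -> ComparisonResult:
    """Paired per-draw difference (a minus b) of ELPD totals or accuracies."""
    da = a.per_draw_totals if isinstance(a, ElpdResult) else np.asarray(a)
    db = b.per_draw_totals if isinstance(b, ElpdResult) else np.asarray(b)
    if isinstance(a, ElpdResult) != isinstance(b, ElpdResult):
        raise ValidationError("cannot compare ELPD with accuracy distributions")
    if da.shape != db.shape:
        raise ValidationError(f"draw shape mismatch: {da.shape} vs {db.shape}")
    if isinstance(a, ElpdResult) and a.n_obs != b.n_obs:
        raise ValidationError("ELPD results cover different observation sets")
    diff = da - db
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return ComparisonResult(
        diff=diff, mean=float(diff.mean()), q2_5=float(lo), q97_5=float(hi)
    )


# ---------------------------------------------------------------------------
# k-fold cross-validation

def make_folds(
    table: pd.DataFrame, k: int, rng: np.random.Generator, max_retries: int = 20
) -> np.ndarray:
    """Trial-level folds stratified by site_type x auth_level.

    Reshuffles (with a logged retry) if any fold would leave a participant
    with no training trial.
    """
    n = len(table)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} available trials")
    cells = table.groupby(["site_type", "auth_level"]).indices
    for attempt in range(max_retries):
        folds = np.empty(n, dtype=int)
        for idx in cells.values():
            idx = np.asarray(idx)
            perm = rng.permutation(idx)
            folds[perm] = np.arange(perm.size) % k
        ok = True
        pids = table["participant_id"].to_numpy()
        for f in range(k):
            train_pids = set(pids[folds != f])
            if not set(pids) <= train_pids:
                ok = False
                break
        if ok:
            return folds
        logger.warning("fold %d left a participant untrained; reshuffling", attempt)
    raise ValidationError("could not build folds satisfying participant constraint")


@dataclass
class KfoldResult:
    spec: ModelSpec
    elpd_in: ElpdResult
    elpd_out: ElpdResult
    accuracy_in: AccuracyResult
    accuracy_out: AccuracyResult
    folds: np.ndarray
    fits: list = field(default_factory=list, repr=False)


def kfold_evaluate(
    spec: ModelSpec,
    table: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    sampler_config: SamplerConfig | None = None,
    accuracy_rule: str = "bernoulli",
    keep_fits: bool = False,
) -> KfoldResult:
    """Fit on k-1 folds and score the held-out fold, for every fold.

    Out-of-sample pointwise log densities are pooled across folds into one
    draws x observations matrix (per-draw totals are therefore totals over
    the full data).  In-sample densities for each observation are averaged
    over the k-1 fits that trained on it.
    """
    if sampler_config is None:
        sampler_config = SamplerConfig(chains=2, draws=500, warmup=500, rhat_tol=None)
    rng = np.random.default_rng(seed)
    table = table.reset_index(drop=True)
    folds = make_folds(table, k, rng)
    n = len(table)
    y = table["accuracy"].to_numpy(dtype=float)
    pids = table["participant_id"].to_numpy()
    S = sampler_config.chains * sampler_config.draws

    out_ld = np.zeros((S, n))
    in_ld_sum = np.zeros((S, n))
    in_counts = np.zeros(n)
    fits = []
    for f in range(k):
        test_mask = folds == f
        train = table[~test_mask]
        design = build_design_matrix(train, spec)
        cfg = SamplerConfig(**{**sampler_config.to_dict(), "seed": sampler_config.seed + f})
        fit = fit_model(
            design,
            train["accuracy"].to_numpy(dtype=float),
            train["participant_id"].to_numpy(),
            spec,
            cfg,
        )
        if keep_fits:
            fits.append(fit)
        # in-sample
        probs_in = posterior_predict(
            fit, design.X, participant_ids=train["participant_id"], rng=rng
        )
        in_ld_sum[:, ~test_mask] += pointwise_log_density(
            probs_in, train["accuracy"].to_numpy(dtype=float)
        )
        in_counts[~test_mask] += 1
        # out-of-sample
        test = table[test_mask]
        test_design = build_design_matrix(test, spec, meta=design.meta)
        probs_out = posterior_predict(
            fit, test_design.X, participant_ids=test["participant_id"], rng=rng
        )
        out_ld[:, test_mask] = pointwise_log_density(probs_out, y[test_mask])

    elpd_out = ElpdResult(log_density=out_ld, fold_ids=folds, scope="out_of_sample")
    elpd_in = ElpdResult(
        log_density=in_ld_sum / in_counts, fold_ids=folds, scope="in_sample"
    )
    site = table["site_type"].to_numpy()
    acc_rng = np.random.default_rng(seed + 1)
    # recover p from log density: p = exp(ld) if y==1 else 1-exp(ld)
    p_out = np.where(y > 0.5, np.exp(out_ld), 1.0 - np.exp(out_ld))
    accuracy_out = model_accuracy(p_out, y, site_type=site, rule=accuracy_rule, rng=acc_rng)
    p_in = np.where(y > 0.5, np.exp(in_ld_sum / in_counts), 1.0 - np.exp(in_ld_sum / in_counts))
    accuracy_in = model_accuracy(p_in, y, site_type=site, rule=accuracy_rule, rng=acc_rng)
    return KfoldResult(
        spec=spec,
        elpd_in=elpd_in,
        elpd_out=elpd_out,
        accuracy_in=accuracy_in,
        accuracy_out=accuracy_out,
        folds=folds,
        fits=fits,
    )


# ---------------------------------------------------------------------------
# auxiliary Bayesian comparisons

def bayesian_mean_difference(
    x, y, n_draws: int = 20000, seed: int = 0
) -> dict:
    """Posterior of the difference in group means under a normal model.

    Weakly informative (Jeffreys) treatment of each group's mean and
    variance gives a scaled-t posterior for each mean; the difference is
    summarized with mean, 95% UI, and the UI-excludes-zero credibility
    flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("need at least 2 observations per group")
    rng = np.random.default_rng(seed)

    def posterior_mean_draws(g):
        n = g.size
        sd = g.std(ddof=1)
        if sd == 0:
            sd = 1e-12
        return g.mean() + sd / np.sqrt(n) * rng.standard_t(n - 1, size=n_draws)

    diff = posterior_mean_draws(x) - posterior_mean_draws(y)
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return {
        "mean": float(diff.mean()),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "credible": bool(lo > 0 or hi < 0),
        "draws": diff,
    }


def bayesian_slope(x, y, n_draws: int = 20000, seed: int = 0) -> dict:
    """Posterior of the simple-regression slope under weak priors.

    With the standard noninformative prior the slope posterior is a scaled
    t around the least-squares estimate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.std(x) == 0:
        raise ValidationError("x has zero variance")
    n = x.size
    res = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    draws = res.slope + res.stderr * rng.standard_t(n - 2, size=n_draws)
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "mean": float(draws.mean()),
        "slope_ls": float(res.slope),
        "q2.5": float(lo),
        "q97.5": float(hi),
        "credible": bool(lo > 0 or hi < 0),
        "draws": draws,
    }
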
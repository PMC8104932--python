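"""Bayesian model of allelic imbalance in one or two conditions.

Model
-----
For a feature in condition ``c`` let ``x_c`` and ``y_c`` be the informative
read counts to parental genome 1 and genome 2, ``q1_c`` and ``q2_c`` the
mapping-bias priors (probability that a read of a given origin maps better
to its own genome), and ``theta_c`` the proportion of expression from
allele 1 (0.5 = allelic balance).  An informative read is genome-1
informative with probability

    pi_c = theta_c * q1_c / (theta_c * q1_c + (1 - theta_c) * q2_c)

and the likelihood is ``x_c | x_c + y_c ~ Binomial(x_c + y_c, pi_c)``,
conditional on the informative total; ambiguous reads carry no allelic
information under this likelihood and are excluded.  The prior is
``pi_c ~ Beta(a, b)`` (default a = b = 1, symmetric at the null), so the
exact posterior of ``pi_c`` is ``Beta(a + x_c, b + y_c)`` and ``theta_c``
is its deterministic transform.  Conditions are independent a priori;
``delta = theta_1 - theta_2`` tests whether imbalance differs between them.

The production path samples the posterior by MCMC (vectorised random-walk
Metropolis on logit pi with step-size adaptation during warmup); the
conjugate Beta posterior is retained as an analytic oracle so the sampler
can be checked against a closed form.

Evidence statistic
------------------
``ev`` is the smallest value such that the ``1 - ev`` equal-tailed central
credible interval excludes the null; equivalently
``ev = 2 * min(F(null), 1 - F(null))`` under the empirical posterior CDF
``F``.  Small ``ev`` is evidence against the null.  H1/H2 test allelic
balance (null theta_c = 0.5) in conditions 1/2; H3 tests equal imbalance
(null delta = 0).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy import special, stats

RHAT_LIMIT = 1.05

FIT_COLUMNS = [
    "FEATURE_ID",
    "COMPARISON",
    "THETA1_MEAN",
    "THETA1_Q025",
    "THETA1_Q975",
    "THETA2_MEAN",
    "THETA2_Q025",
    "THETA2_Q975",
    "DELTA_MEAN",
    "DELTA_Q025",
    "DELTA_Q975",
    "EV_H1",
    "EV_H2",
    "EV_H3",
    "CONVERGED",
]


# ---------------------------------------------------------------------------
# deterministic transforms


def pi_from_theta(theta, q1, q2):
    """Probability that an informative read is genome-1 informative.

    pi = theta*q1 / (theta*q1 + (1-theta)*q2).  Equal biases give pi = theta.
    """
    theta = np.asarray(theta, dtype=float)
    num = theta * q1
    return num / (num + (1.0 - theta) * q2)


def theta_from_pi(pi, q1, q2):
    """Inverse of :func:`pi_from_theta`: theta = pi*q2 / (pi*q2 + (1-pi)*q1)."""
    pi = np.asarray(pi, dtype=float)
    num = pi * q2
    return num / (num + (1.0 - pi) * q1)


def fold_ratio(theta):
    """Allele-1 : allele-2 expression ratio theta / (1 - theta)."""
    theta = np.asarray(theta, dtype=float)
    return theta / (1.0 - theta)


# ---------------------------------------------------------------------------
# conjugate analytic posterior (oracle)


@dataclass(frozen=True)
class ConjugatePosterior:
    """Exact posterior: pi ~ Beta(alpha, beta); theta its monotone transform."""

    alpha: float
    beta: float
    q1: float
    q2: float

    def pi_quantile(self, p):
        return stats.beta.ppf(p, self.alpha, self.beta)

    def theta_quantile(self, p):
        # theta_from_pi is strictly increasing in pi, so quantiles push through
        return theta_from_pi(self.pi_quantile(p), self.q1, self.q2)

    def theta_mean(self, n_grid: int = 4001) -> float:
        """E[theta] by quadrature over the Beta density of pi."""
        # integrate on the quantile scale: E[theta] = int_0^1 theta(Q(u)) du,
        # which is smooth and bounded even for sharp posteriors
        u = (np.arange(n_grid) + 0.5) / n_grid
        return float(np.mean(self.theta_quantile(u)))

    def theta_cdf(self, theta):
        pi = pi_from_theta(np.asarray(theta, dtype=float), self.q1, self.q2)
        return stats.beta.cdf(pi, self.alpha, self.beta)

    def ev(self, null_value: float = 0.5) -> float:
        f = float(self.theta_cdf(null_value))
        return min(1.0, 2.0 * min(f, 1.0 - f))


def conjugate_posterior(
    x: int, y: int, q1: float, q2: float, a: float = 1.0, b: float = 1.0
) -> ConjugatePosterior:
    """Closed-form posterior over theta given informative counts (x, y)."""
    if x < 0 or y < 0:
        raise ValueError("counts must be nonnegative")
    return ConjugatePosterior(alpha=a + x, beta=b + y, q1=q1, q2=q2)


# ---------------------------------------------------------------------------
# evidence statistic


def compute_ev(draws: Sequence[float] | np.ndarray, null_value: float) -> float:
    """Smallest ev whose 1 - ev equal-tailed interval excludes the null.

    Computed as 2 * min(F(null), 1 - F(null)) with F(v) = #(draws <= v)/n,
    clamped to [0, 1].
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("ev requires a nonempty posterior sample")
    f = np.count_nonzero(draws <= null_value) / draws.size
    return min(1.0, 2.0 * min(f, 1.0 - f))


def compute_ev_batch(draws: np.ndarray, null_value: float) -> np.ndarray:
    """Vectorised :func:`compute_ev` over the leading axis of ``draws``."""
    flat = draws.reshape(draws.shape[0], -1)
    f = np.count_nonzero(flat <= null_value, axis=1) / flat.shape[1]
    return np.minimum(1.0, 2.0 * np.minimum(f, 1.0 - f))


# ---------------------------------------------------------------------------
# sampler


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    seed: int = 0
    proposal_df: float = 5.0  # Student-t proposal degrees of freedom
    proposal_scale: float = 1.2  # widening over the Laplace scale

    def __post_init__(self) -> None:
        if not (self.iterations > self.warmup >= 0):
            raise ValueError("need iterations > warmup >= 0")
        if self.chains < 1:
            raise ValueError("need at least one chain")


def sample_pi_posterior(
    x: np.ndarray,
    y: np.ndarray,
    a: float,
    b: float,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independence Metropolis-Hastings draws of pi for a batch of features.

    ``x`` and ``y`` are integer arrays of shape (F,); the return value has
    shape (F, chains, iterations - warmup).  The chain state is
    eta = logit(pi); with the Jacobian of the transform the target is
    log p(eta) = (a + x) log pi + (b + y) log(1 - pi) + const.  Proposals
    are Student-t, centred at the mode of the target with a scale widened
    over the Laplace (inverse-curvature) scale so the proposal tails
    dominate the target's; acceptance is typically above 0.9, giving
    near-independent draws.  Warmup draws are discarded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n_feat = x.shape[0]
    c = config.chains
    kept = config.iterations - config.warmup

    ax = (a + x)[:, None]  # (F, 1)
    by = (b + y)[:, None]

    def logp(eta: np.ndarray) -> np.ndarray:
        # ax*log(pi) + by*log(1-pi) = -ax*log1p(e^-eta) - by*log1p(e^eta)
        return -ax * np.logaddexp(0.0, -eta) - by * np.logaddexp(0.0, eta)

    # mode and curvature of logp: dlogp/deta = ax - (ax+by)*sigmoid(eta)
    # vanishes at sigmoid(eta) = ax/(ax+by); -d2logp = (ax+by)*s*(1-s)
    mode = np.log(ax / by)
    scale = config.proposal_scale * np.sqrt((ax + by) / (ax * by))
    df = config.proposal_df

    def logq(eta: np.ndarray) -> np.ndarray:
        z = (eta - mode) / scale
        return -0.5 * (df + 1.0) * np.log1p(z * z / df)

    eta = mode + scale * rng.standard_t(df, size=(n_feat, c))
    ratio = logp(eta) - logq(eta)
    out = np.empty((n_feat, c, kept))
    for t in range(config.iterations):
        prop = mode + scale * rng.standard_t(df, size=(n_feat, c))
        ratio_prop = logp(prop) - logq(prop)
        accept = np.log(rng.random((n_feat, c))) < (ratio_prop - ratio)
        eta = np.where(accept, prop, eta)
        ratio = np.where(accept, ratio_prop, ratio)
        if t >= config.warmup:
            out[:, :, t - config.warmup] = special.expit(eta)
    return out


def summarize_draws(draws: np.ndarray) -> dict[str, np.ndarray]:
    """Posterior mean, central 95% interval, split-Rhat, bulk ESS and MCSEs.

    ``draws`` has shape (F, chains, kept); every returned array has shape
    (F,).  Diagnostics come from arviz on the (chain, draw, feature) layout.
    """
    mean = draws.mean(axis=(1, 2))
    q025 = np.quantile(draws, 0.025, axis=(1, 2))
    q975 = np.quantile(draws, 0.975, axis=(1, 2))
    arr = np.moveaxis(draws, 0, -1)  # (chain, draw, F)
    ds = az.convert_to_dataset(arr[None] if arr.ndim == 2 else arr)
    rhat = az.rhat(ds)["x"].values.reshape(-1)
    ess = az.ess(ds)["x"].values.reshape(-1)
    sd = draws.std(axis=(1, 2), ddof=1)
    mcse_mean = sd / np.sqrt(np.maximum(ess, 1.0))
    mcse_q = {
        p: az.mcse(ds, method="quantile", prob=p)["x"].values.reshape(-1)
        for p in (0.025, 0.975)
    }
    return {
        "mean": mean,
        "q025": q025,
        "q975": q975,
        "rhat": rhat,
        "ess": ess,
        "mcse_mean": mcse_mean,
        "mcse_q025": mcse_q[0.025],
        "mcse_q975": mcse_q[0.975],
    }


# ---------------------------------------------------------------------------
# model input / output containers


@dataclass(frozen=True)
class ConditionData:
    x: int
    y: int
    q1: float
    q2: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be nonnegative")
        if not (0 < self.q1 < 1 and 0 < self.q2 < 1):
            raise ValueError("q1 and q2 must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class ModelInput:
    feature_id: str
    comparison_id: str
    cond1: ConditionData
    cond2: ConditionData | None = None
    a: float = 1.0
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta hyperparameters must be positive")
        totals = [self.cond1.x + self.cond1.y]
        if self.cond2 is not None:
            totals.append(self.cond2.x + self.cond2.y)
        if max(totals) == 0:
            raise ValueError("at least one condition needs informative reads")


@dataclass
class PosteriorSummary:
    feature_id: str
    comparison_id: str
    theta1_mean: float
    theta1_ci_low: float
    theta1_ci_high: float
    ev_h1: float
    theta2_mean: float | None = None
    theta2_ci_low: float | None = None
    theta2_ci_high: float | None = None
    delta_mean: float | None = None
    delta_ci_low: float | None = None
    delta_ci_high: float | None = None
    ev_h2: float | None = None
    ev_h3: float | None = None
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fitting


def fit_batch(
    x1: np.ndarray,
    y1: np.ndarray,
    q1_1: np.ndarray,
    q2_1: np.ndarray,
    x2: np.ndarray | None = None,
    y2: np.ndarray | None = None,
    q1_2: np.ndarray | None = None,
    q2_2: np.ndarray | None = None,
    a: float = 1.0,
    b: float = 1.0,
    config: SamplerConfig | None = None,
) -> dict[str, np.ndarray]:
    """Fit many independent features at once; the workhorse behind fit_comparison.

    Returns a dict of arrays of shape (F,): theta1/theta2/delta means and
    95% interval bounds, ev_h1/ev_h2/ev_h3, rhat_max, converged.  Condition-2
    arrays may be omitted for single-condition fits.
    """
    config = config or SamplerConfig()
    rng = np.random.default_rng(config.seed)
    rng1, rng2 = rng.spawn(2)
    x1 = np.atleast_1d(np.asarray(x1))
    y1 = np.atleast_1d(np.asarray(y1))
    pi1 = sample_pi_posterior(x1, y1, a, b, config, rng1)
    theta1 = theta_from_pi(pi1, np.asarray(q1_1).reshape(-1, 1, 1), np.asarray(q2_1).reshape(-1, 1, 1))
    s1 = summarize_draws(theta1)
    out: dict[str, np.ndarray] = {
        "theta1_mean": s1["mean"],
        "theta1_q025": s1["q025"],
        "theta1_q975": s1["q975"],
        "ev_h1": compute_ev_batch(theta1, 0.5),
        "theta1_mcse_mean": s1["mcse_mean"],
        "theta1_mcse_q025": s1["mcse_q025"],
        "theta1_mcse_q975": s1["mcse_q975"],
        "ess1": s1["ess"],
    }
    rhat_max = s1["rhat"].copy()
    if x2 is not None:
        x2 = np.atleast_1d(np.asarray(x2))
        y2 = np.atleast_1d(np.asarray(y2))
        pi2 = sample_pi_posterior(x2, y2, a, b, config, rng2)
        theta2 = theta_from_pi(pi2, np.asarray(q1_2).reshape(-1, 1, 1), np.asarray(q2_2).reshape(-1, 1, 1))
        s2 = summarize_draws(theta2)
        delta = theta1 - theta2
        sd = summarize_draws(delta)
        out.update(
            theta2_mean=s2["mean"],
            theta2_q025=s2["q025"],
            theta2_q975=s2["q975"],
            ev_h2=compute_ev_batch(theta2, 0.5),
            delta_mean=sd["mean"],
            delta_q025=sd["q025"],
            delta_q975=sd["q975"],
            ev_h3=compute_ev_batch(delta, 0.0),
            ess2=s2["ess"],
        )
        rhat_max = np.maximum.reduce([rhat_max, s2["rhat"], sd["rhat"]])
    out["rhat_max"] = rhat_max
    out["converged"] = rhat_max <= RHAT_LIMIT
    return out


def fit_comparison(model_input: ModelInput, config: SamplerConfig | None = None) -> PosteriorSummary:
    """Posterior for one feature in one or two conditions.

    Returns allelic-imbalance estimates theta (and delta = theta1 - theta2
    for two conditions) with 95% central credible intervals, the ev evidence
    values for H1/H2/H3, and convergence diagnostics.  Identical input and
    seed reproduce identical output.
    """
    config = config or SamplerConfig()
    c1, c2 = model_input.cond1, model_input.cond2
    if c2 is None:
        res = fit_batch(
            [c1.x], [c1.y], [c1.q1], [c1.q2], a=model_input.a, b=model_input.b, config=config
        )
        return PosteriorSummary(
            feature_id=model_input.feature_id,
            comparison_id=model_input.comparison_id,
            theta1_mean=float(res["theta1_mean"][0]),
            theta1_ci_low=float(res["theta1_q025"][0]),
            theta1_ci_high=float(res["theta1_q975"][0]),
            ev_h1=float(res["ev_h1"][0]),
            converged=bool(res["converged"][0]),
            diagnostics={"rhat_max": float(res["rhat_max"][0]), "ess1": float(res["ess1"][0])},
        )
    res = fit_batch(
        [c1.x], [c1.y], [c1.q1], [c1.q2],
        [c2.x], [c2.y], [c2.q1], [c2.q2],
        a=model_input.a, b=model_input.b, config=config,
    )
    return PosteriorSummary(
        feature_id=model_input.feature_id,
        comparison_id=model_input.comparison_id,
        theta1_mean=float(res["theta1_mean"][0]),
        theta1_ci_low=float(res["theta1_q025"][0]),
        theta1_ci_high=float(res["theta1_q975"][0]),
        ev_h1=float(res["ev_h1"][0]),
        theta2_mean=float(res["theta2_mean"][0]),
        theta2_ci_low=float(res["theta2_q025"][0]),
        theta2_ci_high=float(res["theta2_q975"][0]),
        delta_mean=float(res["delta_mean"][0]),
        delta_ci_low=float(res["delta_q025"][0]),
        delta_ci_high=float(res["delta_q975"][0]),
        ev_h2=float(res["ev_h2"][0]),
        ev_h3=float(res["ev_h3"][0]),
        converged=bool(res["converged"][0]),
        diagnostics={
            "rhat_max": float(res["rhat_max"][0]),
            "ess1": float(res["ess1"][0]),
            "ess2": float(res["ess2"][0]),
        },
    )


# ---------------------------------------------------------------------------
# table-level driver (TSV contract)

COMPARISON_COLUMNS = [
    "COMPARISON_ID",
    "COND1_CROSS",
    "COND1_CONDITION",
    "COND2_CROSS",
    "COND2_CONDITION",
]


def _prior_lookup(priors: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for r in priors.itertuples(index=False):
        table[(str(r.FEATURE_ID), str(r.CONDITION))] = (float(r.Q1), float(r.Q2))
    return table


def _get_prior(
    table: dict[tuple[str, str], tuple[float, float]],
    feature: str,
    cross: str,
    condition: str,
) -> tuple[float, float]:
    # most specific key first: cross:condition, then condition, then blank
    for key in (f"{cross}:{condition}", condition, ""):
        hit = table.get((feature, key))
        if hit is not None:
            return hit
    return (0.5, 0.5)


def fit_table(
    counts: pd.DataFrame,
    comparisons: pd.DataFrame,
    priors: pd.DataFrame | None = None,
    a: float = 1.0,
    b: float = 1.0,
    config: SamplerConfig | None = None,
) -> pd.DataFrame:
    """Fit every (feature, comparison) pair from TSV-shaped tables.

    ``counts`` follows the count-table contract (FEATURE_ID, CROSS,
    CONDITION, REP, COUNT_G1, COUNT_G2, COUNT_AMBIG, FLAG_LOW_COVERAGE);
    replicate rows of one (feature, cross, condition) are summed before
    fitting.  Identifier mismatches between the design and the counts are
    fatal and name the orphans.
    """
    config = config or SamplerConfig()
    grouped = (
        counts.groupby(["FEATURE_ID", "CROSS", "CONDITION"], as_index=False)
        .agg(COUNT_G1=("COUNT_G1", "sum"), COUNT_G2=("COUNT_G2", "sum"))
    )
    indexed = grouped.set_index(["FEATURE_ID", "CROSS", "CONDITION"])
    available = set(zip(grouped["CROSS"].astype(str), grouped["CONDITION"].astype(str)))
    orphans = []
    for r in comparisons.itertuples(index=False):
        for cross, cond in (
            (str(r.COND1_CROSS), str(r.COND1_CONDITION)),
            (str(r.COND2_CROSS), str(r.COND2_CONDITION)),
        ):
            if (cross, cond) not in available:
                orphans.append(f"{r.COMPARISON_ID}: no counts for cross={cross} condition={cond}")
    if orphans:
        raise ValueError("design/count identifier mismatch:\n" + "\n".join(orphans))

    prior_table = _prior_lookup(priors) if priors is not None else {}
    rows = []
    for r in comparisons.itertuples(index=False):
        comp = str(r.COMPARISON_ID)
        c1 = (str(r.COND1_CROSS), str(r.COND1_CONDITION))
        c2 = (str(r.COND2_CROSS), str(r.COND2_CONDITION))
        f1 = indexed.xs((c1[0], c1[1]), level=("CROSS", "CONDITION"))
        f2 = indexed.xs((c2[0], c2[1]), level=("CROSS", "CONDITION"))
        feats = sorted(set(f1.index) & set(f2.index))
        if not feats:
            raise ValueError(f"comparison {comp}: no shared features between conditions")
        x1 = f1.loc[feats, "COUNT_G1"].to_numpy()
        y1 = f1.loc[feats, "COUNT_G2"].to_numpy()
        x2 = f2.loc[feats, "COUNT_G1"].to_numpy()
        y2 = f2.loc[feats, "COUNT_G2"].to_numpy()
        keep = (x1 + y1 > 0) | (x2 + y2 > 0)
        feats = [f for f, k in zip(feats, keep) if k]
        x1, y1, x2, y2 = x1[keep], y1[keep], x2[keep], y2[keep]
        p1 = np.array([_get_prior(prior_table, f, *c1) for f in feats])
        p2 = np.array([_get_prior(prior_table, f, *c2) for f in feats])
        res = fit_batch(
            x1, y1, p1[:, 0], p1[:, 1], x2, y2, p2[:, 0], p2[:, 1], a=a, b=b, config=config
        )
        for i, feat in enumerate(feats):
            rows.append(
                (
                    feat,
                    comp,
                    res["theta1_mean"][i],
                    res["theta1_q025"][i],
                    res["theta1_q975"][i],
                    res["theta2_mean"][i],
                    res["theta2_q025"][i],
                    res["theta2_q975"][i],
                    res["delta_mean"][i],
                    res["delta_q025"][i],
                    res["delta_q975"][i],
                    res["ev_h1"][i],
                    res["ev_h2"][i],
                    res["ev_h3"][i],
                    int(res["converged"][i]),
                )
            )
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def write_fits(fits: pd.DataFrame, path: str | os.PathLike) -> None:
    fits.to_csv(path, sep="\t", index=False)


def read_fits(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
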
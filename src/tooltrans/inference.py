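"""Bayesian binomial-logit model of tool-user status.

Each individual's tool-user status (0/1) is modelled with a Bernoulli
likelihood and a logit link. Age class (developmental vs adult) and phenotype
(common-like vs hybrid-like) define four groups, each with its own intercept
and its own slopes on the two network predictors:

    logit(p_i) = a[g_i] + b_c[g_i] * C_i + b_s[g_i] * S_i

where C is max-rescaled EV-centrality and S is max-rescaled strength to tool
users. Priors are weakly informative: Normal(0, 1) on the intercepts and
LogNormal(0, 1) on the slopes, encoding the expectation that better network
position can only increase the odds of being a tool user. Slopes are sampled
on the log scale (a Normal(0, 1) prior on log b is exactly a LogNormal(0, 1)
prior on b), which leaves the posterior unconstrained for the ensemble
sampler. Summaries report means, sds, the central 89 % interval (5.5 % and
94.5 % quantiles), effective sample sizes and Rhat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd

from .simcore import COMMON_LIKE, HYBRID_LIKE

DEVELOPMENTAL = "developmental"
ADULT = "adult"

# group order: (DA, common), (DA, hybrid), (adult, common), (adult, hybrid)
GROUPS = (
    (DEVELOPMENTAL, COMMON_LIKE),
    (DEVELOPMENTAL, HYBRID_LIKE),
    (ADULT, COMMON_LIKE),
    (ADULT, HYBRID_LIKE),
)
_GROUP_LABELS = ("DA, common like", "DA, hybrid", "adult, common", "adult, hybrid")

PARAM_NAMES = tuple(
    f"{kind} ({label})"
    for kind in ("intercept", "centrality", "strength")
    for label in _GROUP_LABELS
)


@dataclass
class ModelData:
    """Design table for the logit model.

    One row per individual: outcome ``tool_user`` in {0, 1}, group index
    ``group`` in 0..3 (age class x phenotype), and the two predictors
    rescaled to [0, 1].
    """

    tool_user: np.ndarray
    group: np.ndarray
    centrality: np.ndarray
    strength: np.ndarray

    def __post_init__(self) -> None:
        self.tool_user = np.asarray(self.tool_user, dtype=float)
        self.group = np.asarray(self.group, dtype=int)
        self.centrality = np.asarray(self.centrality, dtype=float)
        self.strength = np.asarray(self.strength, dtype=float)
        n = len(self.tool_user)
        if not (len(self.group) == len(self.centrality) == len(self.strength) == n):
            raise ValueError("field lengths differ")
        if n == 0:
            raise ValueError("empty model data")
        for name in ("tool_user", "centrality", "strength", "group"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name}")

    def to_frame(self) -> pd.DataFrame:
        age_class = [GROUPS[g][0] for g in self.group]
        phenotype = [GROUPS[g][1] for g in self.group]
        return pd.DataFrame(
            {
                "tool_user": self.tool_user.astype(int),
                "age_class": age_class,
                "phenotype": phenotype,
                "centrality": self.centrality,
                "strength": self.strength,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ModelData":
        group = np.array(
            [
                GROUPS.index((ac, ph))
                for ac, ph in zip(df["age_class"], df["phenotype"])
            ]
        )
        return cls(
            tool_user=df["tool_user"].to_numpy(),
            group=group,
            centrality=df["centrality"].to_numpy(),
            strength=df["strength"].to_numpy(),
        )


@dataclass
class ModelSpec:
    """Priors and sampler defaults for the binomial-logit model."""

    intercept_sd: float = 1.0
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    n_groups: int = 4

    @property
    def n_params(self) -> int:
        return 3 * self.n_groups


def build_design(
    attributes: pd.DataFrame,
    metrics: pd.DataFrame,
    age_threshold: Optional[int] = 25,
    mature_col: Optional[str] = None,
) -> ModelData:
    """Join attributes with network metrics and rescale predictors.

    Age class is ``developmental`` when ``age <= age_threshold`` (simulator
    input) or when the boolean ``mature_col`` is False (observational input);
    ``adult`` otherwise. Centrality and strength are rescaled to [0, 1] by
    dividing by their observed maxima; a zero-variance predictor is left
    unrescaled with a warning.
    """
    df = attributes.merge(metrics, on="id", how="inner", validate="one_to_one")
    if len(df) != len(attributes):
        raise ValueError("every individual needs both attributes and metrics")
    if mature_col is not None:
        adult = df[mature_col].astype(bool).to_numpy()
    else:
        if age_threshold is None:
            raise ValueError("need age_threshold or mature_col")
        adult = df["age"].to_numpy() > age_threshold
    age_class = np.where(adult, ADULT, DEVELOPMENTAL)
    group = np.array(
        [GROUPS.index((ac, ph)) for ac, ph in zip(age_class, df["phenotype"])]
    )

    def rescale(x: np.ndarray, name: str) -> np.ndarray:
        m = np.max(x)
        if m <= 0:
            warnings.warn(f"{name} has no variation; rescaling by 1")
            return x.astype(float)
        return x / m

    return ModelData(
        tool_user=df["tool_user"].astype(bool).astype(int).to_numpy(),
        group=group,
        centrality=rescale(df["ev_centrality"].to_numpy(float), "centrality"),
        strength=rescale(df["strength_to_tool_users"].to_numpy(float), "strength"),
    )


@dataclass
class PosteriorDraws:
    """MCMC output: arrays of shape (chains, draws) per parameter.

    ``a`` are the group intercepts, ``b_c`` / ``b_s`` the (positive)
    centrality / strength slopes on the natural scale.
    """

    a: np.ndarray  # (chains, draws, n_groups)
    b_c: np.ndarray
    b_s: np.ndarray
    metadata: dict = field(default_factory=dict)

    def stacked(self) -> np.ndarray:
        """All parameters as (chains, draws, 12) in canonical order."""
        return np.concatenate([self.a, self.b_c, self.b_s], axis=2)

    def flat(self) -> np.ndarray:
        """(n_total_draws, 12) with chains pooled."""
        s = self.stacked()
        return s.reshape(-1, s.shape[2])

    def to_inference_data(self) -> az.InferenceData:
        return az.from_dict(
            posterior={
                "a": self.a,
                "b_c": self.b_c,
                "b_s": self.b_s,
            }
        )

    def write(self, path) -> None:
        """Columnar export: one column per parameter plus chain/draw ids."""
        s = self.stacked()
        chains, draws, k = s.shape
        cols = {"chain": np.repeat(np.arange(chains), draws),
                "draw": np.tile(np.arange(draws), chains)}
        for j, name in enumerate(PARAM_NAMES):
            cols[name] = s[:, :, j].reshape(-1)
        pd.DataFrame(cols).to_csv(path, index=False)


def _log_prob(theta: np.ndarray, data: ModelData, spec: ModelSpec) -> np.ndarray:
    """Vectorized log posterior; theta has shape (walkers, 12).

    Layout: 4 intercepts, 4 log centrality slopes, 4 log strength slopes.
    """
    ng = spec.n_groups
    a = theta[:, :ng]
    log_bc = theta[:, ng : 2 * ng]
    log_bs = theta[:, 2 * ng :]
    # priors: a ~ N(0, sd); log b ~ N(mu_L, sigma_L)  (<=> b ~ LogNormal)
    lp = (
        -0.5 * np.sum((a / spec.intercept_sd) ** 2, axis=1)
        - 0.5 * np.sum(((log_bc - spec.lognormal_mu) / spec.lognormal_sigma) ** 2, axis=1)
        - 0.5 * np.sum(((log_bs - spec.lognormal_mu) / spec.lognormal_sigma) ** 2, axis=1)
    )
    g = data.group
    eta = (
        a[:, g]
        + np.exp(log_bc)[:, g] * data.centrality
        + np.exp(log_bs)[:, g] * data.strength
    )
    y = data.tool_user
    # Bernoulli log-likelihood via numerically stable log(1+exp(.))
    ll = np.sum(y * eta - np.logaddexp(0.0, eta), axis=1)
    return lp + ll


def fit_model(
    data: ModelData,
    spec: Optional[ModelSpec] = None,
    chains: int = 4,
    draws: int = 1000,
    seed: int = 0,
    warmup: int = 2000,
    thin: int = 4,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Sample the posterior with differential-evolution ensemble MCMC.

    ``chains`` fully independent ensembles (24 walkers each) are run from
    distinct seeds; because walkers within an ensemble interact, convergence
    (Rhat) is judged *across* ensembles, while effective sample size pools
    every walker's thinned chain. Each ensemble keeps ``draws`` post-warmup
    states per walker after thinning by ``thin``. A diagnostics failure
    (Rhat > 1.01 or ESS < 400) is flagged in metadata and warned about, not
    raised.

    ``prior_only`` drops the likelihood term (prior predictive sampling).
    """
    spec = spec or ModelSpec()
    if not prior_only:
        y = data.tool_user
        if y.min() == y.max():
            raise ValueError("both outcome classes must be present")
    ndim = spec.n_params
    nwalkers = 2 * ndim
    ng = spec.n_groups

    if prior_only:
        def log_prob(theta):
            a = theta[:, :ng]
            logb = theta[:, ng:]
            return (
                -0.5 * np.sum((a / spec.intercept_sd) ** 2, axis=1)
                - 0.5 * np.sum(((logb - spec.lognormal_mu) / spec.lognormal_sigma) ** 2, axis=1)
            )
    else:
        def log_prob(theta):
            return _log_prob(theta, data, spec)

    ensembles = []
    accepts = []
    for c in range(chains):
        rng = np.random.default_rng((seed, c))
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim, log_prob, vectorize=True,
            moves=[(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)],
        )
        sampler.random_state = np.random.RandomState(
            rng.integers(2**32)
        ).get_state()
        p0 = 0.5 * rng.standard_normal((nwalkers, ndim))
        sampler.run_mcmc(
            p0, warmup + draws * thin, progress=False, skip_initial_state_check=True
        )
        chain = sampler.get_chain(discard=warmup, thin=thin)  # (draws, walkers, ndim)
        ensembles.append(np.moveaxis(chain, 0, 1))  # (walkers, draws, ndim)
        accepts.append(float(np.mean(sampler.acceptance_fraction)))

    # walker-level chains for ESS (autocorrelation along each walker's path)
    theta = np.concatenate(ensembles, axis=0)  # (chains*walkers, draws, ndim)
    out = PosteriorDraws(
        a=theta[:, :, :ng],
        b_c=np.exp(theta[:, :, ng : 2 * ng]),
        b_s=np.exp(theta[:, :, 2 * ng :]),
    )
    ess = az.ess(out.to_inference_data())
    # ensemble-level chains for Rhat (only independent ensembles are
    # exchangeable; walkers within one ensemble are coupled)
    pooled = np.stack([e.reshape(-1, ndim) for e in ensembles])  # (chains, w*d, ndim)
    rhat = az.rhat(
        az.from_dict(
            posterior={
                "a": pooled[:, :, :ng],
                "b_c": np.exp(pooled[:, :, ng : 2 * ng]),
                "b_s": np.exp(pooled[:, :, 2 * ng :]),
            }
        )
    )
    min_ess = float(min(ess[v].min() for v in ("a", "b_c", "b_s")))
    max_rhat = float(max(rhat[v].max() for v in ("a", "b_c", "b_s")))
    accept = float(np.mean(accepts))
    out.metadata = {
        "sampler": "emcee.EnsembleSampler (DE + snooker moves)",
        "n_ensembles": chains,
        "nwalkers": nwalkers,
        "warmup": warmup,
        "draws_per_walker": draws,
        "seed": seed,
        "min_ess": min_ess,
        "max_rhat": max_rhat,
        "mean_acceptance_fraction": accept,
        "diagnostics_ok": bool(min_ess >= 400 and max_rhat <= 1.01),
        "predictor_rescaling": "divide-by-max to [0, 1]",
        "centrality_adjacency": "symmetrized",
    }
    if not out.metadata["diagnostics_ok"]:
        warnings.warn(
            f"sampler diagnostics failed: min ESS {min_ess:.0f}, max Rhat {max_rhat:.3f}"
        )
    return out


def summarize_posterior(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary table: 12 rows (4 intercepts, 4 centrality slopes,
    4 strength slopes) with mean, sd, 5.5 % / 94.5 % quantiles, ESS and Rhat."""
    s = draws.stacked()  # (chains, draws, 12)
    flat = s.reshape(-1, s.shape[2])
    ess = az.ess(draws.to_inference_data())
    # Rhat over independent ensembles when the sampler recorded them;
    # walkers within an ensemble are coupled and are pooled per ensemble
    n_ens = draws.metadata.get("n_ensembles")
    if n_ens and s.shape[0] % n_ens == 0:
        r = s.reshape(n_ens, -1, s.shape[2])
    else:
        r = s
    rhat = az.rhat(az.from_dict(posterior={"theta": r}))["theta"].values
    ess_all = np.concatenate([ess[v].values for v in ("a", "b_c", "b_s")])
    rhat_all = rhat
    q = np.quantile(flat, [0.055, 0.945], axis=0)
    return pd.DataFrame(
        {
            "parameter": PARAM_NAMES,
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(flat.shape[1]),
            "q5.5": q[0],
            "q94.5": q[1],
            "n_eff": ess_all,
            "rhat": rhat_all,
        }
    )


def posterior_predict(
    draws: PosteriorDraws,
    group: int,
    grid: Sequence[float],
    predictor: str = "strength",
    other_value: float | None = None,
    data: Optional[ModelData] = None,
) -> pd.DataFrame:
    """Posterior predictive curve of P(tool user) along one predictor.

    The varied predictor runs over ``grid`` (within [0, 1]); the other
    predictor is held at ``other_value``, defaulting to its group mean in
    ``data`` (or 0.5 with neither given). Returns columns
    ``group, predictor, value, p_mean, p_q5.5, p_q94.5``.
    """
    if predictor not in ("centrality", "strength"):
        raise ValueError("predictor must be 'centrality' or 'strength'")
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("grid must lie within [0, 1]")
    if other_value is None:
        if data is not None:
            mask = data.group == group
            other = data.strength if predictor == "centrality" else data.centrality
            other_value = float(other[mask].mean()) if mask.any() else 0.5
        else:
            other_value = 0.5
    a = draws.a.reshape(-1, draws.a.shape[2])[:, group]
    bc = draws.b_c.reshape(-1, draws.b_c.shape[2])[:, group]
    bs = draws.b_s.reshape(-1, draws.b_s.shape[2])[:, group]
    if predictor == "centrality":
        eta = a[:, None] + bc[:, None] * grid[None, :] + bs[:, None] * other_value
    else:
        eta = a[:, None] + bs[:, None] * grid[None, :] + bc[:, None] * other_value
    p = 1.0 / (1.0 + np.exp(-eta))
    q = np.quantile(p, [0.055, 0.945], axis=0)
    return pd.DataFrame(
        {
            "group": _GROUP_LABELS[group],
            "predictor": predictor,
            "value": grid,
            "p_mean": p.mean(axis=0),
            "p_q5.5": q[0],
            "p_q94.5": q[1],
        }
    )
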
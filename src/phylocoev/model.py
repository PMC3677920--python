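"""Bayesian fitting of constrained CTMC trait models over a tree sample.

The sampler is Metropolis-Hastings over the rate vector with uniform
rate priors: each iteration perturbs one rate by a sliding-window
proposal (reflected at the prior bounds) and independently resamples
the tree uniformly from the sample, so the chain targets the posterior
averaged over the fixed tree sample.

Public surface follows the Model/Results convention:

>>> model = DiscreteTraitModel(trees, data, DEP_8RATE)
>>> res = model.fit(McmcConfig(iterations=20_000, seed=1))
>>> res.summary()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .characters import CharacterData
from .likelihood import TreeIndex, log_likelihood, simulate_character
from .ratemodels import RateModelSpec, RootPolicy, build_generator
from .trees import RootedTree, TreeSample

__all__ = [
    "McmcConfig", "McmcTrace", "DiscreteTraitModel", "DiscreteTraitResults",
    "run_mcmc", "tune_rate_deviation",
]

_STALL_LIMIT = 100_000  # consecutive rejections before aborting


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    rate_deviation is the sliding-window half-width (bounded to
    [0.001, 2.0] as in the replication protocol); the prior is uniform
    on (prior_lower, prior_upper] per rate.
    """

    iterations: int = 500_000
    burn_in_fraction: float = 0.30
    rate_deviation: float = 0.5
    target_acceptance: tuple[float, float] = (0.20, 0.40)
    prior_lower: float = 0.0
    prior_upper: float = 100.0
    thin: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.burn_in_fraction < 1):
            raise ValueError("burn_in_fraction must be in (0, 1)")
        if not (0.001 <= self.rate_deviation <= 2.0):
            raise ValueError("rate_deviation must lie in [0.001, 2.0]")
        if not (self.prior_upper > self.prior_lower >= 0):
            raise ValueError("prior bounds must satisfy upper > lower >= 0")
        if self.iterations < 1 or self.thin < 1:
            raise ValueError("iterations and thin must be positive")


@dataclass
class McmcTrace:
    """Post-burn-in, thinned chain records."""

    iteration: np.ndarray      # original iteration numbers
    log_likelihood: np.ndarray
    rates: np.ndarray          # (n_records, n_params)
    tree_index: np.ndarray
    accepted: np.ndarray       # bool per recorded iteration
    acceptance_rate: float     # realized fraction over all iterations
    config: McmcConfig
    model_name: str = ""

    def __len__(self) -> int:
        return len(self.log_likelihood)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"iteration": self.iteration,
                           "lnL": self.log_likelihood})
        for j in range(self.rates.shape[1]):
            df[f"q{j}"] = self.rates[:, j]
        df["tree_index"] = self.tree_index
        df["accepted"] = self.accepted.astype(int)
        return df

    def to_tsv(self) -> str:
        return self.to_dataframe().to_csv(sep="\t", index=False)

    @classmethod
    def from_tsv(cls, text: str, config: McmcConfig | None = None,
                 model_name: str = "") -> "McmcTrace":
        df = pd.read_csv(_as_buffer(text), sep="\t")
        rate_cols = [c for c in df.columns if c.startswith("q")]
        acc = df["accepted"].to_numpy(bool)
        return cls(df["iteration"].to_numpy(), df["lnL"].to_numpy(),
                   df[rate_cols].to_numpy(), df["tree_index"].to_numpy(int),
                   acc, float(acc.mean()), config or McmcConfig(), model_name)


def _as_buffer(text: str):
    import io
    return io.StringIO(text)


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a proposal into (lo, hi]."""
    width = hi - lo
    y = (x - lo) % (2 * width)
    if y < 0:
        y += 2 * width
    y = width - abs(y - width)
    return lo + y


def run_mcmc(trees: TreeSample, data: CharacterData, spec: RateModelSpec,
             config: McmcConfig,
             root_policy: RootPolicy | None = None) -> McmcTrace:
    """Sample rate vectors (and tree indices) from the posterior.

    Deterministic given the config seed.
    """
    if set(data.state_space) != set(spec.state_space) and data.k != spec.k:
        raise ValueError(
            f"character has {data.k} states but model {spec.name} expects {spec.k}")
    missing = trees.taxa - data.taxa
    if missing:
        raise ValueError(f"taxa in trees but not in data: {sorted(missing)}")
    rng = np.random.default_rng(config.seed)
    policy = root_policy or spec.root_policy
    indices = [TreeIndex(t) for t in trees]
    npar = spec.n_params
    lo, hi = config.prior_lower, config.prior_upper

    def ll(rates: np.ndarray, ti: int) -> float:
        Q = build_generator(spec, rates)
        return log_likelihood(trees[ti], data, Q, policy, indices[ti])

    # deterministic initial point inside the prior
    rates = rng.uniform(max(lo, 1e-3), min(hi, 5.0), size=npar)
    tree_i = int(rng.integers(len(trees)))
    cur_ll = ll(rates, tree_i)
    tries = 0
    while not np.isfinite(cur_ll) and tries < 100:
        rates = rng.uniform(max(lo, 1e-3), min(hi, 5.0), size=npar)
        cur_ll = ll(rates, tree_i)
        tries += 1
    if not np.isfinite(cur_ll):
        raise RuntimeError("could not find a starting point with finite likelihood")

    burn = int(config.iterations * config.burn_in_fraction)
    rec_it, rec_ll, rec_rates, rec_tree, rec_acc = [], [], [], [], []
    n_accept = 0
    stall = 0
    for it in range(config.iterations):
        j = int(rng.integers(npar))
        prop = rates.copy()
        prop[j] = _reflect(prop[j] + rng.uniform(-config.rate_deviation,
                                                 config.rate_deviation), lo, hi)
        if prop[j] <= 0:
            prop[j] = min(hi, 1e-9)
        prop_tree = int(rng.integers(len(trees)))
        prop_ll = ll(prop, prop_tree)
        accept = np.log(rng.uniform()) < (prop_ll - cur_ll)
        if accept:
            rates, tree_i, cur_ll = prop, prop_tree, prop_ll
            n_accept += 1
            stall = 0
        else:
            stall += 1
            if stall > _STALL_LIMIT:
                raise RuntimeError(
                    f"sampler stalled: {stall} consecutive rejections "
                    f"(rate_deviation={config.rate_deviation})")
        if it >= burn and (it - burn) % config.thin == 0:
            rec_it.append(it)
            rec_ll.append(cur_ll)
            rec_rates.append(rates.copy())
            rec_tree.append(tree_i)
            rec_acc.append(bool(accept))
    return McmcTrace(np.array(rec_it), np.array(rec_ll), np.array(rec_rates),
                     np.array(rec_tree), np.array(rec_acc),
                     n_accept / config.iterations, config, spec.name)


def tune_rate_deviation(pilot: McmcTrace, config: McmcConfig) -> float:
    """Factor-2 adjustment of the proposal half-width toward the target
    acceptance window, clamped to [0.001, 2.0]."""
    lo, hi = config.target_acceptance
    dev = config.rate_deviation
    acc = pilot.acceptance_rate
    if acc > hi:
        dev = min(2.0, dev * 2.0)
    elif acc < lo:
        dev = max(0.001, dev / 2.0)
    return dev


def fit_with_tuning(trees: TreeSample, data: CharacterData, spec: RateModelSpec,
                    config: McmcConfig, root_policy: RootPolicy | None = None,
                    pilot_iterations: int = 2000, max_rounds: int = 10,
                    ) -> tuple[McmcTrace, McmcConfig]:
    """Run short pilots, tuning rate_deviation until acceptance is in the
    target window (or rounds are exhausted), then run the full chain."""
    cfg = config
    for r in range(max_rounds):
        pilot_cfg = replace(cfg, iterations=pilot_iterations, thin=1,
                            seed=cfg.seed + 7919 * (r + 1))
        pilot = run_mcmc(trees, data, spec, pilot_cfg, root_policy)
        lo, hi = cfg.target_acceptance
        if lo <= pilot.acceptance_rate <= hi:
            break
        new_dev = tune_rate_deviation(pilot, replace(cfg, rate_deviation=pilot_cfg.rate_deviation))
        if new_dev == cfg.rate_deviation:
            break
        cfg = replace(cfg, rate_deviation=new_dev)
    return run_mcmc(trees, data, spec, cfg, root_policy), cfg


class DiscreteTraitModel:
    """Constrained CTMC model of a categorical character on a tree sample.

    Parameters
    ----------
    trees : TreeSample or RootedTree
    data : CharacterData covering the trees' taxa (missing allowed).
    spec : RateModelSpec (one of the named constants or user-defined).
    root_policy : optional override of the spec's root policy.
    """

    def __init__(self, trees: TreeSample | RootedTree, data: CharacterData,
                 spec: RateModelSpec, root_policy: RootPolicy | None = None):
        if isinstance(trees, RootedTree):
            trees = TreeSample([trees])
        self.trees = trees
        self.data = data
        self.spec = spec
        self.root_policy = root_policy or spec.root_policy
        self._indices = [TreeIndex(t) for t in trees]

    def loglike(self, rates, tree_index: int = 0) -> float:
        Q = build_generator(self.spec, rates)
        return log_likelihood(self.trees[tree_index], self.data, Q,
                              self.root_policy, self._indices[tree_index])

    def fit(self, config: McmcConfig | None = None, tune: bool = False,
            ) -> "DiscreteTraitResults":
        config = config or McmcConfig()
        if tune:
            trace, config = fit_with_tuning(self.trees, self.data, self.spec,
                                            config, self.root_policy)
        else:
            trace = run_mcmc(self.trees, self.data, self.spec, config,
                             self.root_policy)
        return DiscreteTraitResults(self, trace)

    def fit_runs(self, n_runs: int = 4, config: McmcConfig | None = None,
                 tune: bool = False) -> list["DiscreteTraitResults"]:
        """Independent analyses differing only by seed."""
        config = config or McmcConfig()
        out = []
        for r in range(n_runs):
            cfg = replace(config, seed=config.seed + 1000003 * r)
            out.append(self.fit(cfg, tune=tune))
        return out

    def simulate(self, rates, seed=0, tree_index: int = 0):
        Q = build_generator(self.spec, rates)
        return simulate_character(
            self.trees[tree_index], Q, self.root_policy, seed,
            tip_frequencies=self.data.frequencies(),
            state_space=list(self.spec.state_space))


class DiscreteTraitResults:
    """Posterior sample and summaries for a fitted DiscreteTraitModel."""

    def __init__(self, model: DiscreteTraitModel, trace: McmcTrace):
        self.model = model
        self.trace = trace

    @property
    def rate_means(self) -> np.ndarray:
        return self.trace.rates.mean(axis=0)

    @property
    def acceptance_rate(self) -> float:
        return self.trace.acceptance_rate

    def rate_interval(self, level: float = 0.95) -> np.ndarray:
        """Equal-tailed posterior credible intervals, shape (n_params, 2)."""
        a = (1 - level) / 2
        return np.quantile(self.trace.rates, [a, 1 - a], axis=0).T

    def ess(self, parameter: int | str = "lnL") -> float:
        from .inference import effective_sample_size
        return effective_sample_size(self.trace, parameter)

    def marginal_likelihood(self, n_bootstrap: int = 1000, seed: int = 0):
        from .inference import marginal_likelihood
        return marginal_likelihood(self.trace, n_bootstrap=n_bootstrap, seed=seed)

    def summary(self) -> pd.DataFrame:
        ci = self.rate_interval()
        rows = []
        for j in range(self.trace.rates.shape[1]):
            rows.append({
                "parameter": f"q{j}",
                "mean": self.rate_means[j],
                "sd": self.trace.rates[:, j].std(ddof=1) if len(self.trace) > 1 else 0.0,
                "ci2.5%": ci[j, 0],
                "ci97.5%": ci[j, 1],
            })
        df = pd.DataFrame(rows)
        df.attrs["model"] = self.model.spec.name
        df.attrs["acceptance_rate"] = self.acceptance_rate
        df.attrs["records"] = len(self.trace)
        return df

    def __repr__(self) -> str:
        return (f"<DiscreteTraitResults {self.model.spec.name}: "
                f"{len(self.trace)} records, "
                f"acceptance {self.acceptance_rate:.2f}>")
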
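"""Model / Results interface for the multilevel graded-response model.

``MLIRTModel`` is constructed from the survey data objects (responses,
dwelling nesting, covariate designs) and ``fit()`` runs the Gibbs sampler,
returning an ``MLIRTResults`` carrying posterior means, posterior SDs,
95% HPD intervals, latent health scores, DIC and convergence diagnostics —
in the spirit of a statsmodels model/results pair.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import sampler as smp
from .data import CovariateSet, DwellingIndex, ResponseMatrix

__all__ = ["MLIRTModel", "MLIRTResults"]


class MLIRTModel:
    """Multilevel IRT model: GRM measurement + two-level latent regression.

    Parameters
    ----------
    responses : ResponseMatrix
        Ordinal item responses (higher code = worse health).
    dwellings : DwellingIndex
        person -> dwelling nesting; dwelling random effects are always
        included.
    person_covariates, dwelling_covariates : DataFrame, optional
        Reference-coded designs indexed by person_id / dwelling_id.  Omit
        both for the covariate-free ("empty") model: intercept + dwelling
        random effect only.
    fixed_covariates : sequence of str
        Columns treated as error-free known predictors (e.g. a previously
        estimated health score entered with its error fixed to zero).
    link : 'probit' or 'logit'
        Response function of the GRM; probit enables fully conjugate
        data augmentation.
    """

    def __init__(self, responses: ResponseMatrix, dwellings: DwellingIndex,
                 person_covariates: pd.DataFrame | None = None,
                 dwelling_covariates: pd.DataFrame | None = None,
                 fixed_covariates=(), link: str = "probit"):
        self.responses = responses
        self.dwellings = dwellings
        self.link = link
        self.fixed_covariates = tuple(fixed_covariates)
        n = responses.n_persons
        ids = responses.person_ids
        self.dwelling_codes, self.dwelling_ids = dwellings.codes_for(ids)

        blocks = [np.ones((n, 1))]
        names = ["intercept"]
        if person_covariates is not None and person_covariates.shape[1]:
            Xp = person_covariates.loc[ids]
            blocks.append(Xp.to_numpy(float))
            names += list(Xp.columns)
        if dwelling_covariates is not None and dwelling_covariates.shape[1]:
            dw = [dwellings.dwelling_of(p) for p in ids]
            Wd = dwelling_covariates.loc[dw]
            blocks.append(Wd.to_numpy(float))
            names += list(Wd.columns)
        self.exog = np.hstack(blocks)
        self.exog_names = names
        missing = set(self.fixed_covariates) - set(names)
        if missing:
            raise ValueError(f"fixed covariates not in design: {sorted(missing)}")

    @classmethod
    def from_covariate_set(cls, responses: ResponseMatrix,
                           dwellings: DwellingIndex, covariates: CovariateSet,
                           **kwargs) -> "MLIRTModel":
        return cls(responses, dwellings,
                   person_covariates=covariates.person_design,
                   dwelling_covariates=covariates.dwelling_design, **kwargs)

    def fit(self, n_iterations: int = 5000, burn_in: int = 1000,
            thin: int = 1, seed: int = 0, store_theta_trace: bool = False,
            progress=None, **prior_kwargs) -> "MLIRTResults":
        config = smp.MCMCConfig(n_iterations=n_iterations, burn_in=burn_in,
                                thin=thin, seed=seed, link=self.link,
                                fixed_covariates=self.fixed_covariates,
                                store_theta_trace=store_theta_trace,
                                **prior_kwargs)
        chains = smp.run_mcmc(self.responses.values, self.responses.mask,
                              self.exog, self.dwelling_codes, config,
                              beta_names=self.exog_names,
                              item_ids=self.responses.item_bank.item_ids,
                              progress=progress)
        return MLIRTResults(self, chains)


class MLIRTResults:
    """Posterior summaries of a fitted MLIRT model."""

    def __init__(self, model: MLIRTModel, chains: smp.ChainStore):
        self.model = model
        self.chains = chains

    # -- point estimates ---------------------------------------------------
    @property
    def params(self) -> pd.Series:
        """Posterior means of the structural fixed effects."""
        return pd.Series(self.chains.beta.mean(axis=0),
                         index=self.chains.beta_names, name="mean")

    @property
    def bse(self) -> pd.Series:
        """Posterior standard deviations of the fixed effects."""
        return pd.Series(self.chains.beta.std(axis=0, ddof=1),
                         index=self.chains.beta_names, name="sd")

    @property
    def sigma2(self) -> float:
        return float(self.chains.sigma2.mean())

    @property
    def tau2(self) -> float:
        return float(self.chains.tau2.mean())

    @property
    def icc(self) -> float:
        """Posterior-mean intraclass correlation tau2 / (tau2 + sigma2)."""
        draws = self.chains.tau2 / (self.chains.tau2 + self.chains.sigma2)
        return float(draws.mean())

    @property
    def discrimination(self) -> pd.Series:
        return pd.Series(self.chains.a.mean(axis=0),
                         index=self.chains.item_ids, name="discrimination")

    @property
    def thresholds(self) -> pd.DataFrame:
        k = self.chains.kappa.mean(axis=0)
        return pd.DataFrame(k, index=self.chains.item_ids,
                            columns=[f"thr{c + 1}" for c in range(k.shape[1])])

    @property
    def scores(self) -> pd.Series:
        """Posterior-mean latent health score per person (higher = worse)."""
        return pd.Series(self.chains.theta_mean,
                         index=self.model.responses.person_ids, name="score")

    def hpd(self, prob: float = 0.95) -> pd.DataFrame:
        rows = [smp.hpd_interval(col, prob) for col in self.chains.beta.T]
        return pd.DataFrame(rows, index=self.chains.beta_names,
                            columns=["hpd_lower", "hpd_upper"])

    # -- model fit / convergence -------------------------------------------
    def dic(self) -> tuple[float, float, float]:
        """(DIC, pD, mean deviance) of the measurement model."""
        return smp.compute_dic(self.chains, self.model.responses.values,
                               self.model.responses.mask)

    def geweke(self) -> pd.DataFrame:
        draws = np.column_stack([self.chains.beta, self.chains.sigma2,
                                 self.chains.tau2])
        out = smp.geweke_diagnostic(draws)
        out.index = self.chains.beta_names + ["sigma2", "tau2"]
        return out

    def summary(self, prob: float = 0.95,
                include_items: bool = True) -> pd.DataFrame:
        """Posterior mean / SD / HPD table (fixed effects, variances, items)."""
        return smp.summarize(self.chains, prob=prob,
                             include_items=include_items)

    def __repr__(self):
        return (f"<MLIRTResults: {self.model.responses.n_persons} persons, "
                f"{self.model.responses.n_items} items, "
                f"{self.chains.n_draws} stored draws>")
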
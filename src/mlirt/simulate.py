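"""Synthetic nested ordinal survey generator with known ground truth.

Emulates the statistical structure of a disability survey of community
dwellings: ~1.13 adults per dwelling (singletons dominating), two banks of
3-category ordinal functioning items ("biological" health = difficulty
without aids; "lived" health = difficulty with any aids in use), person- and
dwelling-level covariates of the kinds used in the structural model, MCAR
item missingness, and an assistive-aid-use table that decides which lived
answers are actually observed.

Latent structure
----------------
biological:  theta_B = u^B_j + e^B_i, standardized to mean 0 / SD 1
lived:       theta_L = b0 + x'beta + w'gamma + u_j + e_i, standardized

with u_j ~ N(0, tau2), e_i ~ N(0, sigma2) and tau2/(tau2+sigma2) the
configured residual intraclass correlation.  Responses are drawn from the
graded response model at the standardized scores, so the stored truth lives
on the same identified scale the sampler reports.  Default structural
coefficients are the survey study's published point estimates (biological
health 0.902, male -0.172, older than 65 0.101, feeling discriminated
-0.103, occupation change 0.269, work-relation change 0.148); the
dwelling-level adaptation effect defaults to zero, matching its published
null interval.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (AidUseTable, DwellingIndex, Item, ItemBank, ResponseMatrix,
                   write_responses)
from .grm import category_probs

__all__ = [
    "GeneratorConfig", "SyntheticTruth", "SyntheticDataset",
    "generate_nesting", "generate_truth", "generate_responses",
    "inject_missingness", "generate_aid_use", "generate_dataset",
    "write_bundle", "DOMAINS",
]

DOMAINS = ("communication", "learning", "mobility", "self_care", "home_life")

#: scale of the Spanish disability survey: 17,303 adults in 15,263 dwellings
SURVEY_MEAN_CLUSTER = 17303 / 15263


def _default_person_coefs() -> dict[str, float]:
    return {
        "bio_health": 0.902,
        "gender_male": -0.172,
        "age_older": 0.101,
        "discriminated": -0.103,
        "work_change_occupation": 0.269,
        "work_change_relation": 0.148,
    }


def _default_dwelling_coefs() -> dict[str, float]:
    return {"no_adaptation": 0.0}


@dataclass
class GeneratorConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    n_dwellings: int = 2000
    mean_persons_per_dwelling: float = SURVEY_MEAN_CLUSTER
    n_items: int = 15            # per role
    n_categories: int = 3
    discrimination_range: tuple[float, float] = (0.9, 3.2)
    threshold_start_range: tuple[float, float] = (-1.0, 0.5)
    threshold_gap_range: tuple[float, float] = (0.5, 1.5)
    intercept: float = -0.072
    person_coefs: dict[str, float] = field(default_factory=_default_person_coefs)
    dwelling_coefs: dict[str, float] = field(default_factory=_default_dwelling_coefs)
    icc: float = 0.15            # residual tau2 / (tau2 + sigma2)
    residual_variance: float = 0.25   # tau2 + sigma2
    bio_icc: float = 0.15        # clustering of the biological score
    bio_dwelling_share: float = 0.5   # within-dwelling correlation of bio covariate
    missing_rate: float = 0.05
    aid_intercept: float = 0.0   # logistic model for aid use: expit(a0 + a1*theta_L)
    aid_slope: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_dwellings < 1:
            raise ValueError("n_dwellings must be >= 1")
        if self.mean_persons_per_dwelling < 1:
            raise ValueError("mean cluster size must be >= 1")
        if not 0 <= self.icc < 1 or not 0 <= self.bio_icc < 1:
            raise ValueError("icc must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        for lo, hi in (self.discrimination_range, self.threshold_start_range,
                       self.threshold_gap_range):
            if lo > hi:
                raise ValueError("invalid range")
        if self.discrimination_range[0] <= 0:
            raise ValueError("discriminations must be positive")
        if self.threshold_gap_range[0] <= 0:
            raise ValueError("threshold gaps must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def tau2(self) -> float:
        return self.icc * self.residual_variance

    @property
    def sigma2(self) -> float:
        return (1 - self.icc) * self.residual_variance


@dataclass
class SyntheticTruth:
    """Generating parameters + latent draws, on the identified scale."""

    config: GeneratorConfig
    item_params: dict[str, dict[str, np.ndarray]]  # role -> {"a", "kappa"}
    person_ids: list[str]
    dwellings: DwellingIndex
    person_design: pd.DataFrame
    dwelling_design: pd.DataFrame
    theta_bio: np.ndarray        # standardized biological score
    theta_lived: np.ndarray      # standardized lived score
    # structural parameters on the identified (post-standardization) scale
    intercept: float
    person_coefs: dict[str, float]
    dwelling_coefs: dict[str, float]
    u: np.ndarray                # identified dwelling effects (lived model)
    tau2: float
    sigma2: float

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        payload = {
            "config": dataclasses.asdict(self.config),
            "item_params": {r: {k: v.tolist() for k, v in p.items()}
                            for r, p in self.item_params.items()},
            "intercept": self.intercept,
            "person_coefs": self.person_coefs,
            "dwelling_coefs": self.dwelling_coefs,
            "tau2": self.tau2,
            "sigma2": self.sigma2,
            "theta_bio": self.theta_bio.tolist(),
            "theta_lived": self.theta_lived.tolist(),
            "person_ids": self.person_ids,
        }
        return json.dumps(payload, default=enc, indent=1)


def generate_nesting(config: GeneratorConfig,
                     rng: np.random.Generator | None = None) -> DwellingIndex:
    """Assign persons to dwellings; cluster sizes are 1 + Poisson(mean - 1)."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    sizes = 1 + rng.poisson(config.mean_persons_per_dwelling - 1.0,
                            size=config.n_dwellings)
    mapping: dict[str, str] = {}
    p = 0
    for j, s in enumerate(sizes):
        for _ in range(int(s)):
            mapping[f"p{p:06d}"] = f"d{j:06d}"
            p += 1
    return DwellingIndex(mapping)


def _draw_item_params(config: GeneratorConfig, rng: np.random.Generator):
    K, C = config.n_items, config.n_categories
    a = rng.uniform(*config.discrimination_range, size=K)
    start = rng.uniform(*config.threshold_start_range, size=K)
    gaps = rng.uniform(*config.threshold_gap_range, size=(K, C - 2))
    kappa = np.concatenate([start[:, None], gaps], axis=1).cumsum(axis=1)
    if np.any(np.diff(kappa, axis=1) <= 0):
        raise ValueError("infeasible threshold range")
    return {"a": a, "kappa": kappa}


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    m, s = float(np.mean(x)), float(np.std(x))
    if s == 0:
        raise ValueError("degenerate latent scores")
    return (x - m) / s, m, s


def generate_truth(config: GeneratorConfig,
                   rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Draw item parameters, covariates and latent scores for both roles."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    nesting = generate_nesting(config, rng)
    person_ids = list(nesting.mapping)
    codes, dwelling_ids = nesting.codes_for(person_ids)
    n, J = len(person_ids), len(dwelling_ids)

    item_params = {"biological": _draw_item_params(config, rng),
                   "lived": _draw_item_params(config, rng)}

    # biological score: dwelling effect + person effect, then standardized
    ub = rng.normal(0, np.sqrt(config.bio_icc), size=J)
    eb = rng.normal(0, np.sqrt(1 - config.bio_icc), size=n)
    theta_bio, _, _ = _standardize(ub[codes] + eb)

    # person-level covariates; the continuous biological-health stand-in has a
    # dwelling-level variance share so covariates explain both levels
    share = config.bio_dwelling_share
    X = pd.DataFrame(index=pd.Index(person_ids, name="person_id"))
    for name in config.person_coefs:
        if name == "bio_health":
            X[name] = theta_bio
        elif name == "gender_male":
            X[name] = rng.binomial(1, 0.376, size=n)
        elif name == "age_older":
            X[name] = rng.binomial(1, 0.596, size=n)
        elif name == "discriminated":
            X[name] = rng.binomial(1, 0.25, size=n)
        elif name == "work_change_occupation":
            work = rng.choice(3, size=n, p=[0.60, 0.15, 0.25])
            X[name] = (work == 1).astype(int)
            if "work_change_relation" in config.person_coefs:
                X["work_change_relation"] = (work == 2).astype(int)
        elif name == "work_change_relation":
            if name not in X.columns:
                X[name] = rng.binomial(1, 0.25, size=n)
        else:  # unnamed extras: clustered standard normal
            v = rng.normal(size=J)
            X[name] = (np.sqrt(share) * v[codes]
                       + np.sqrt(1 - share) * rng.normal(size=n))
    X = X[list(config.person_coefs)]

    W = pd.DataFrame(index=pd.Index(dwelling_ids, name="dwelling_id"))
    for name in config.dwelling_coefs:
        W[name] = rng.binomial(1, 0.5, size=J)

    beta = np.array([config.person_coefs[c] for c in X.columns])
    gamma = np.array([config.dwelling_coefs[c] for c in W.columns])
    u = rng.normal(0, np.sqrt(config.tau2), size=J)
    e = rng.normal(0, np.sqrt(config.sigma2), size=n)
    raw = (config.intercept + X.to_numpy(float) @ beta
           + W.to_numpy(float)[codes] @ gamma + u[codes] + e)
    theta_lived, m, s = _standardize(raw)

    return SyntheticTruth(
        config=config, item_params=item_params, person_ids=person_ids,
        dwellings=nesting, person_design=X, dwelling_design=W,
        theta_bio=theta_bio, theta_lived=theta_lived,
        intercept=(config.intercept - m) / s,
        person_coefs={c: config.person_coefs[c] / s for c in X.columns},
        dwelling_coefs={c: config.dwelling_coefs[c] / s for c in W.columns},
        u=u / s, tau2=config.tau2 / s**2, sigma2=config.sigma2 / s**2)


def _item_bank(config: GeneratorConfig, role: str) -> ItemBank:
    prefix = "bio" if role == "biological" else "lived"
    items = tuple(
        Item(item_id=f"{prefix}_{k:02d}", domain=DOMAINS[k % len(DOMAINS)],
             role=role, n_categories=config.n_categories)
        for k in range(config.n_items))
    return ItemBank(items)


def generate_responses(truth: SyntheticTruth, role: str = "lived",
                       link: str = "probit",
                       rng: np.random.Generator | None = None) -> ResponseMatrix:
    """Sample every cell from the GRM at the person's latent score."""
    rng = (np.random.default_rng(truth.config.seed + 1)
           if rng is None else rng)
    theta = truth.theta_bio if role == "biological" else truth.theta_lived
    params = truth.item_params[role]
    bank = _item_bank(truth.config, role)
    n, K = len(theta), truth.config.n_items
    values = np.empty((n, K), dtype=int)
    unif = rng.random((n, K))
    for k in range(K):
        p = category_probs(params["a"][k], params["kappa"][k], theta, link)
        cum = np.cumsum(p, axis=-1)
        values[:, k] = (unif[:, k, None] > cum[:, :-1]).sum(axis=1)
    mask = np.zeros((n, K), dtype=bool)
    return ResponseMatrix(truth.person_ids, bank, values, mask)


def inject_missingness(rm: ResponseMatrix, rate: float,
                       seed: int | np.random.Generator) -> ResponseMatrix:
    """Mask cells i.i.d. Bernoulli(rate), independent of their values (MCAR)."""
    if not 0 <= rate < 1:
        raise ValueError("missing rate must be in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    extra = rng.random(rm.values.shape) < rate
    mask = rm.mask | extra
    values = np.where(mask, -1, rm.values)
    return ResponseMatrix(rm.person_ids, rm.item_bank, values, mask)


def generate_aid_use(truth: SyntheticTruth,
                     rng: np.random.Generator | None = None) -> AidUseTable:
    """Bernoulli aid use per person x domain, logistic in the lived score."""
    rng = (np.random.default_rng(truth.config.seed + 2)
           if rng is None else rng)
    cfg = truth.config
    from scipy.special import expit
    p = expit(cfg.aid_intercept + cfg.aid_slope * truth.theta_lived)
    tab = pd.DataFrame(
        {dom: rng.random(len(p)) < p for dom in DOMAINS},
        index=pd.Index(truth.person_ids, name="person_id"))
    return AidUseTable(tab)


@dataclass
class SyntheticDataset:
    """Everything the two-step pipeline consumes, plus the generating truth."""

    truth: SyntheticTruth
    rm_bio: ResponseMatrix            # biological responses, MCAR missing
    rm_lived_full: ResponseMatrix     # lived responses, everyone (for recovery)
    rm_lived_observed: ResponseMatrix  # lived responses, aid users only
    aid_use: AidUseTable
    weights: pd.Series


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """One call producing the full survey bundle, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    truth = generate_truth(config, rng)
    rm_bio = generate_responses(truth, "biological", rng=rng)
    rm_lived_full = generate_responses(truth, "lived", rng=rng)
    aid = generate_aid_use(truth, rng=rng)
    # lived answers exist only for aid users in the item's domain
    aid_tab = aid.table.loc[rm_lived_full.person_ids]
    obs_mask = rm_lived_full.mask.copy()
    for k, item in enumerate(rm_lived_full.item_bank):
        obs_mask[:, k] |= ~aid_tab[item.domain].to_numpy(bool)
    rm_lived_observed = ResponseMatrix(
        rm_lived_full.person_ids, rm_lived_full.item_bank,
        np.where(obs_mask, -1, rm_lived_full.values), obs_mask)
    if config.missing_rate > 0:
        rm_bio = inject_missingness(rm_bio, config.missing_rate, rng)
        rm_lived_observed = inject_missingness(rm_lived_observed,
                                               config.missing_rate, rng)
    weights = pd.Series(rng.uniform(0.5, 2.0, size=len(truth.person_ids)),
                        index=pd.Index(truth.person_ids, name="person_id"),
                        name="weight")
    return SyntheticDataset(truth, rm_bio, rm_lived_full, rm_lived_observed,
                            aid, weights)


def write_bundle(ds: SyntheticDataset, outdir) -> None:
    """Write the CSV bundle + truth.json the pipeline and CLI consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_responses(ds.rm_bio, outdir / "responses_biological.csv")
    write_responses(ds.rm_lived_observed, outdir / "responses_lived.csv")
    pd.DataFrame({"person_id": list(ds.truth.dwellings.mapping),
                  "dwelling_id": list(ds.truth.dwellings.mapping.values())}
                 ).to_csv(outdir / "dwellings.csv", index=False)
    # the observable covariates exclude the latent bio stand-in: the pipeline
    # estimates the biological score itself in step 1
    X = ds.truth.person_design.drop(columns=["bio_health"], errors="ignore")
    X.to_csv(outdir / "covariates_person.csv")
    ds.truth.dwelling_design.to_csv(outdir / "covariates_dwelling.csv")
    ds.aid_use.table.astype(int).to_csv(outdir / "aid_use.csv")
    ds.weights.to_frame().to_csv(outdir / "weights.csv")
    (outdir / "truth.json").write_text(ds.truth.to_json())
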
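"""IRT assumption diagnostics: unidimensionality, local independence,
monotonicity — plus item-retention and robustness logic.

Before fitting the latent-trait model, three assumptions are screened:

* **unidimensionality** — a bifactor analysis of the polychoric matrix; the
  assumption is supported when items load more highly on the general factor
  than on their domain's group factor;
* **local independence** — residual correlations after a single-factor model;
  pairs with |residual| above a threshold (default 0.25) are flagged, and
  flagged pairs are merged into subsets of mutually dependent items;
* **monotonicity** — the mean item score must be non-decreasing in the
  rest-score (mean of the remaining items), checked on binned rest-scores.

Items failing monotonicity are excluded; within each local-dependence subset
a single item is retained (the most discriminating one from a provisional
fit); domain-level unidimensionality flags produce warnings and an optional
sensitivity re-fit rather than automatic removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import factor
from .data import ResponseMatrix

__all__ = ["DiagnosticsReport", "RobustnessResult", "polychoric_matrix",
           "bifactor_check", "local_dependence", "monotonicity_check",
           "select_items", "robustness_check", "run_diagnostics"]

logger = logging.getLogger(__name__)


@dataclass
class MonotonicityVerdict:
    item_id: str
    passed: bool | None          # None = indeterminate
    rest_score_bins: np.ndarray  # bin mean rest-scores
    item_means: np.ndarray       # bin mean item scores
    max_decrease: float

    @property
    def verdict(self) -> str:
        if self.passed is None:
            return "indeterminate"
        return "pass" if self.passed else "fail"


@dataclass
class RobustnessResult:
    correlation: float
    mean_abs_diff: float
    max_abs_diff: float
    robust: bool


@dataclass
class DiagnosticsReport:
    item_ids: list[str]
    polychoric: pd.DataFrame
    loadings: pd.DataFrame | None = None
    domain_flags: dict[str, bool] = field(default_factory=dict)
    residuals: pd.DataFrame | None = None
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)
    ld_subsets: list[list[str]] = field(default_factory=list)
    monotonicity: dict[str, MonotonicityVerdict] = field(default_factory=dict)
    retained: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "items": self.item_ids,
            "domain_flags": self.domain_flags,
            "flagged_pairs": [list(p) for p in self.flagged_pairs],
            "local_dependence_subsets": [list(s) for s in self.ld_subsets],
            "monotonicity": {k: v.verdict for k, v in self.monotonicity.items()},
            "retained": self.retained,
        }


# ---------------------------------------------------------------------------


def polychoric_matrix(rm: ResponseMatrix) -> pd.DataFrame:
    """Pairwise polychoric correlations of the items of a response matrix."""
    R, kept = factor.polychoric_matrix(rm.values, rm.mask)
    ids = [rm.item_bank.item_ids[k] for k in kept]
    return pd.DataFrame(R, index=ids, columns=ids)


def bifactor_check(R: pd.DataFrame, group_structure: dict[str, str],
                   n_group_factors: int | None = None):
    """Bifactor analysis of a correlation matrix.

    ``group_structure`` maps item_id -> domain.  Extracts 1 + G factors by
    minres, rotates them with an orthogonal bi-quartimin gradient-projection
    rotation, labels each group factor with the domain whose items dominate
    it, and flags every domain whose items load higher (on average) on their
    group factor than on the general factor.

    Returns ``(loadings DataFrame, domain_flags dict)``.
    """
    ids = list(R.index)
    domains = [group_structure[i] for i in ids]
    uniq = list(dict.fromkeys(domains))
    G = len(uniq) if n_group_factors is None else n_group_factors
    A = factor.minres_factor(R.to_numpy(float), n_factors=1 + G)
    L = factor.rotate_bifactor(A)
    cols = ["general"] + [f"group{g + 1}" for g in range(G)]
    load = pd.DataFrame(L, index=ids, columns=cols)
    # label each group factor by the domain with the largest mean |loading|
    labels = {}
    for col in cols[1:]:
        by_dom = load[col].abs().groupby(pd.Series(domains, index=ids)).mean()
        labels[col] = by_dom.idxmax()
    flags = {}
    for dom in uniq:
        members = [i for i, d in zip(ids, domains) if d == dom]
        gen = load.loc[members, "general"].abs()
        flags[dom] = False
        # a genuine domain factor is one group factor shared by the domain's
        # items; singleton factors absorbing a single item's uniqueness (an
        # over-extraction artifact) must not trigger the flag
        for c in (c for c, lab in labels.items() if lab == dom):
            grp = load.loc[members, c].abs()
            if (grp > gen).mean() > 0.5:
                flags[dom] = True
    return load, flags


def local_dependence(R: pd.DataFrame, threshold: float = 0.25):
    """Flag item pairs with |residual correlation| > threshold after a
    single-factor model.

    Returns ``(residual DataFrame, flagged pairs, subsets)`` where subsets
    are the connected components of the flagged-pair graph — groups of
    mutually dependent questions, of which one representative is retained.
    """
    ids = list(R.index)
    if len(ids) < 3:
        raise ValueError("need at least 3 items")
    lam = factor.minres_factor(R.to_numpy(float), n_factors=1)[:, 0]
    resid = R.to_numpy(float) - np.outer(lam, lam)
    np.fill_diagonal(resid, 0.0)
    residuals = pd.DataFrame(resid, index=ids, columns=ids)
    flagged = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(resid[i, j]) > threshold:
                flagged.append((ids[i], ids[j]))
    subsets = _connected_components(ids, flagged)
    return residuals, flagged, subsets


def _connected_components(ids, pairs):
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    return [sorted(c) for c in comps.values() if len(c) > 1]


def monotonicity_check(rm: ResponseMatrix, min_bin_size: int = 50,
                       tol: float = 0.03) -> dict[str, MonotonicityVerdict]:
    """Rest-score monotonicity check for every item.

    The rest-score is the person's mean score over the *other* non-missing
    items.  Persons are binned by rest-score deciles (adjacent bins merged
    until each holds at least ``min_bin_size`` persons); an item fails when
    its binned mean score shows a decrease that exceeds both ``tol`` and
    twice its sampling standard error — the automated analogue of judging a
    rest-score graph by eye, where a dip within noise is not a violation.
    """
    if rm.n_items < 2:
        raise ValueError("need at least 2 items for rest-scores")
    vals = np.where(rm.mask, np.nan, rm.values.astype(float))
    out: dict[str, MonotonicityVerdict] = {}
    for k, item_id in enumerate(rm.item_bank.item_ids):
        others = np.delete(vals, k, axis=1)
        with np.errstate(invalid="ignore"):
            rest = np.nanmean(others, axis=1)
        ok = np.isfinite(rest) & np.isfinite(vals[:, k])
        rest_k, score_k = rest[ok], vals[ok, k]
        if ok.sum() < 2 * min_bin_size:
            out[item_id] = MonotonicityVerdict(item_id, None, np.array([]),
                                               np.array([]), np.nan)
            continue
        edges = np.quantile(rest_k, np.linspace(0, 1, 11)[1:-1])
        bins = np.searchsorted(edges, rest_k, side="right")
        counts = np.bincount(bins, minlength=10)
        merged = _merge_bins(bins, counts, min_bin_size)
        labels = sorted(set(merged))
        if len(labels) < 2:
            out[item_id] = MonotonicityVerdict(item_id, None, np.array([]),
                                               np.array([]), np.nan)
            continue
        rest_means = np.array([rest_k[merged == b].mean() for b in labels])
        item_means = np.array([score_k[merged == b].mean() for b in labels])
        sems = np.array([score_k[merged == b].std(ddof=1)
                         / np.sqrt((merged == b).sum()) for b in labels])
        order = np.argsort(rest_means)
        rest_means = rest_means[order]
        item_means = item_means[order]
        sems = sems[order]
        decreases = np.maximum(0.0, -np.diff(item_means))
        max_dec = float(decreases.max()) if decreases.size else 0.0
        se_pair = np.sqrt(sems[1:] ** 2 + sems[:-1] ** 2)
        violated = bool(np.any(decreases > np.maximum(tol, 2.0 * se_pair)))
        out[item_id] = MonotonicityVerdict(item_id, not violated,
                                           rest_means, item_means, max_dec)
    return out


def _merge_bins(bins, counts, min_bin_size):
    """Merge adjacent decile bins left-to-right until all hold enough persons."""
    mapping = {}
    group, acc = 0, 0
    for b in range(len(counts)):
        mapping[b] = group
        acc += counts[b]
        if acc >= min_bin_size:
            group += 1
            acc = 0
    if acc > 0 and group > 0:   # leftover tail joins the previous group
        for b in range(len(counts)):
            if mapping[b] == group:
                mapping[b] = group - 1
    merged = np.array([mapping[b] for b in bins])
    return merged


def select_items(report: DiagnosticsReport,
                 provisional_discriminations: pd.Series | dict) -> list[str]:
    """Apply the retention rules and record them on the report.

    Monotonicity failures are dropped outright; within each local-dependence
    subset only the item with the highest provisional discrimination stays;
    domain-level bifactor flags warn but do not remove items.
    """
    disc = pd.Series(provisional_discriminations)
    failed = {i for i, v in report.monotonicity.items() if v.passed is False}
    retained = [i for i in report.item_ids if i not in failed]
    for subset in report.ld_subsets:
        candidates = [i for i in subset if i not in failed]
        if not candidates:
            continue
        keep = disc.loc[candidates].idxmax()
        for i in candidates:
            if i != keep and i in retained:
                retained.remove(i)
    for dom, flagged in report.domain_flags.items():
        if flagged:
            logger.warning("domain %r loads higher on its group factor than "
                           "on the general factor; items kept (consider a "
                           "sensitivity re-fit)", dom)
    report.retained = retained
    return retained


def robustness_check(scores_with: pd.Series, scores_without: pd.Series,
                     min_correlation: float = 0.95,
                     max_mad: float = 0.1) -> RobustnessResult:
    """Compare person scores from fits with and without flagged items."""
    if not scores_with.index.equals(scores_without.index):
        raise ValueError("score vectors cover different persons")
    x = scores_with.to_numpy(float)
    y = scores_without.to_numpy(float)
    r = float(np.corrcoef(x, y)[0, 1])
    mad = float(np.mean(np.abs(x - y)))
    mx = float(np.max(np.abs(x - y)))
    return RobustnessResult(r, mad, mx,
                            robust=(r >= min_correlation and mad <= max_mad))


def run_diagnostics(rm: ResponseMatrix, ld_threshold: float = 0.25,
                    min_bin_size: int = 50, mono_tol: float = 0.03,
                    check_unidimensionality: bool = True) -> DiagnosticsReport:
    """Full assumption screen of one response matrix."""
    R = polychoric_matrix(rm)
    report = DiagnosticsReport(item_ids=list(R.index), polychoric=R)
    if check_unidimensionality:
        groups = {it.item_id: it.domain for it in rm.item_bank}
        try:
            report.loadings, report.domain_flags = bifactor_check(R, groups)
        except RuntimeError as err:
            logger.warning("bifactor rotation failed: %s", err)
    resid, flagged, subsets = local_dependence(R, threshold=ld_threshold)
    report.residuals = resid
    report.flagged_pairs = flagged
    report.ld_subsets = subsets
    report.monotonicity = monotonicity_check(rm, min_bin_size=min_bin_size,
                                             tol=mono_tol)
    return report
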
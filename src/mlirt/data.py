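"""Data model and I/O for nested ordinal survey data.

Holds the observed side of the analysis: ordinal item responses
(persons x items, missing allowed), the person -> dwelling nesting, the
reference-coded covariate designs on both levels, the table of assistive-aid
use that governs which lived-health answers were actually observed, and the
pre-analysis transformations applied before model fitting: collapsing sparse
response categories, restricting to respondents reporting any difficulty,
and equating lived with biological health for people who use no aids.

Files are CSV with a header; missing responses are empty cells.  Survey
files use the instrument's 1-based ordinal scale ("1 = without difficulty or
with little difficulty" ... "4 = cannot carry out"); internal codes are
0-based so that threshold ``kappa_c`` separates categories ``c-1`` and ``c``
without off-by-one bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ItemBank", "Item", "ResponseMatrix", "DwellingIndex", "CovariateSet",
    "AidUseTable", "MISSING",
    "load_responses", "write_responses", "collapse_categories",
    "filter_respondents", "equate_lived_with_biological",
    "weighted_descriptives", "load_dwellings", "load_aid_use", "load_weights",
]

logger = logging.getLogger(__name__)

#: sentinel stored in masked cells of a ResponseMatrix
MISSING = -1

ROLES = ("biological", "lived")


@dataclass(frozen=True)
class Item:
    item_id: str
    domain: str
    role: str  # "biological" | "lived"
    n_categories: int = 3

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of survey items with unique ids."""

    items: tuple[Item, ...]

    def __post_init__(self):
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")

    def __len__(self):
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def domains(self) -> list[str]:
        return [it.domain for it in self.items]

    @property
    def n_categories(self) -> int:
        cats = {it.n_categories for it in self.items}
        if len(cats) != 1:
            raise ValueError("items have heterogeneous category counts")
        return cats.pop()

    def subset(self, item_ids) -> "ItemBank":
        keep = set(item_ids)
        return ItemBank(tuple(it for it in self.items if it.item_id in keep))


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with a missingness mask.

    ``values`` holds 0-based category codes (higher code = more difficulty =
    worse health); masked cells hold :data:`MISSING`.
    """

    person_ids: list[str]
    item_bank: ItemBank
    values: np.ndarray  # (n, K) int
    mask: np.ndarray    # (n, K) bool, True = missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, K = self.values.shape
        if len(self.person_ids) != n or len(self.item_bank) != K:
            raise ValueError("shape mismatch between ids, items and values")
        if self.mask.shape != (n, K):
            raise ValueError("mask shape mismatch")
        self.values = np.where(self.mask, MISSING, self.values)
        for k, item in enumerate(self.item_bank):
            col = self.values[:, k]
            obs = ~self.mask[:, k]
            if obs.any() and (col[obs].min() < 0 or col[obs].max() >= item.n_categories):
                raise ValueError(
                    f"item {item.item_id!r}: code outside 0..{item.n_categories - 1}")

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def take_persons(self, person_ids) -> "ResponseMatrix":
        pos = {p: i for i, p in enumerate(self.person_ids)}
        idx = np.array([pos[p] for p in person_ids], dtype=int)
        return ResponseMatrix(list(person_ids), self.item_bank,
                              self.values[idx], self.mask[idx])

    def take_items(self, item_ids) -> "ResponseMatrix":
        pos = {it: k for k, it in enumerate(self.item_bank.item_ids)}
        idx = np.array([pos[i] for i in item_ids], dtype=int)
        return ResponseMatrix(self.person_ids, self.item_bank.subset(item_ids),
                              self.values[:, idx], self.mask[:, idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values.astype(float),
                          columns=self.item_bank.item_ids)
        df[self.mask] = np.nan
        df.insert(0, "person_id", self.person_ids)
        return df


@dataclass(frozen=True)
class DwellingIndex:
    """person_id -> dwelling_id map; every person lives in exactly one dwelling."""

    mapping: dict[str, str]

    def dwelling_of(self, person_id: str) -> str:
        return self.mapping[person_id]

    @property
    def dwelling_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for d in self.mapping.values():
            seen.setdefault(d)
        return list(seen)

    def codes_for(self, person_ids) -> tuple[np.ndarray, list[str]]:
        """Integer dwelling codes aligned to ``person_ids`` plus the id list."""
        dw: dict[str, int] = {}
        codes = np.empty(len(person_ids), dtype=int)
        for i, p in enumerate(person_ids):
            d = self.mapping[p]
            codes[i] = dw.setdefault(d, len(dw))
        return codes, list(dw)

    def mean_cluster_size(self) -> float:
        return len(self.mapping) / len(self.dwelling_ids)


@dataclass
class CovariateSet:
    """Reference-coded design matrices at the person and dwelling level.

    Both designs are pandas DataFrames indexed by person_id / dwelling_id;
    categorical covariates arrive already expanded to dummy columns (the
    reference category is the omitted one, recorded in ``reference``).
    """

    person_design: pd.DataFrame
    dwelling_design: pd.DataFrame
    reference: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for df, what in ((self.person_design, "person"), (self.dwelling_design, "dwelling")):
            if df.isna().any().any():
                raise ValueError(f"missing cells in {what}-level design "
                                 "(complete-case input required)")

    def aligned(self, person_ids, dwellings: DwellingIndex):
        """(X_person, W_dwelling-expanded-to-persons) numpy arrays + names."""
        X = self.person_design.loc[list(person_ids)]
        dw = [dwellings.dwelling_of(p) for p in person_ids]
        W = self.dwelling_design.loc[dw]
        return (X.to_numpy(float), W.to_numpy(float),
                list(X.columns), list(W.columns))


@dataclass
class AidUseTable:
    """person x domain booleans: uses a technical aid and/or personal assistance."""

    table: pd.DataFrame  # index person_id, columns domain, bool

    def uses_aid(self, person_id: str, domain: str) -> bool:
        return bool(self.table.loc[person_id, domain])


# ---------------------------------------------------------------------------
# I/O


def load_responses(path, item_bank: ItemBank,
                   drop_all_missing: bool = True) -> ResponseMatrix:
    """Read a responses CSV (person_id + one column per item, 1-based codes).

    Blank cells become missing; codes are shifted to the 0-based internal
    scale.  Unknown item columns or out-of-range codes raise ``ValueError``.
    Persons with every response missing are dropped with a warning unless
    ``drop_all_missing=False`` (useful before an equating step fills them).
    """
    df = pd.read_csv(path, dtype={"person_id": str})
    cols = [c for c in df.columns if c != "person_id"]
    known = set(item_bank.item_ids)
    unknown = [c for c in cols if c not in known]
    if unknown:
        raise ValueError(f"unknown item columns in {path}: {unknown}")
    absent = [i for i in item_bank.item_ids if i not in cols]
    if absent:
        raise ValueError(f"item columns missing from {path}: {absent}")
    raw = df[item_bank.item_ids].to_numpy(dtype=float)
    mask = np.isnan(raw)
    values = np.where(mask, 0, raw).astype(int) - 1  # 1-based file -> 0-based
    values = np.where(mask, MISSING, values)
    for k, item in enumerate(item_bank):
        obs = ~mask[:, k]
        bad = obs & ((values[:, k] < 0) | (values[:, k] >= item.n_categories))
        if bad.any():
            row = int(np.argmax(bad))
            raise ValueError(
                f"{path}: code {values[row, k] + 1} out of range for item "
                f"{item.item_id!r} at row {row} (person "
                f"{df['person_id'].iloc[row]!r})")
    rm = ResponseMatrix(df["person_id"].tolist(), item_bank, values, mask)
    return _drop_all_missing(rm) if drop_all_missing else rm


def _drop_all_missing(rm: ResponseMatrix) -> ResponseMatrix:
    all_missing = rm.mask.all(axis=1)
    if all_missing.any():
        dropped = [p for p, m in zip(rm.person_ids, all_missing) if m]
        logger.warning("dropping %d person(s) with all responses missing: %s",
                       len(dropped), dropped[:5])
        keep = [p for p, m in zip(rm.person_ids, all_missing) if not m]
        rm = rm.take_persons(keep)
    return rm


def write_responses(rm: ResponseMatrix, path) -> None:
    """Write a ResponseMatrix back to the 1-based CSV convention."""
    df = rm.to_frame()
    for c in rm.item_bank.item_ids:
        df[c] = df[c] + 1
    df.to_csv(path, index=False, float_format="%.0f")


def load_dwellings(path) -> DwellingIndex:
    df = pd.read_csv(path, dtype=str)
    if df["person_id"].duplicated().any():
        raise ValueError("a person maps to more than one dwelling")
    return DwellingIndex(dict(zip(df["person_id"], df["dwelling_id"])))


def load_aid_use(path) -> AidUseTable:
    df = pd.read_csv(path, dtype={"person_id": str}).set_index("person_id")
    return AidUseTable(df.astype(bool))


def load_weights(path) -> pd.Series:
    df = pd.read_csv(path, dtype={"person_id": str})
    w = pd.Series(df["weight"].to_numpy(float), index=df["person_id"])
    if (w < 0).any():
        raise ValueError("negative sampling weight")
    return w


# ---------------------------------------------------------------------------
# Pre-analysis transformations


def collapse_categories(rm: ResponseMatrix, mapping: dict[int, int]) -> ResponseMatrix:
    """Merge ordinal categories via an order-preserving surjection.

    The survey's "with moderate difficulty" and "with severe difficulty"
    options were sparse and are merged into a single middle category, taking
    the instrument's 4 response options to 3: ``{0: 0, 1: 1, 2: 1, 3: 2}``.
    """
    old_c = rm.item_bank.n_categories
    if set(mapping) != set(range(old_c)):
        raise ValueError("mapping must cover every old code exactly once")
    new_codes = [mapping[c] for c in range(old_c)]
    if any(b - a not in (0, 1) for a, b in zip(new_codes, new_codes[1:])) \
            or new_codes[0] != 0:
        raise ValueError("mapping must be a monotone surjection onto 0..C'-1")
    new_c = max(new_codes) + 1
    lut = np.array(new_codes)
    values = np.where(rm.mask, MISSING, lut[np.where(rm.mask, 0, rm.values)])
    bank = ItemBank(tuple(replace(it, n_categories=new_c) for it in rm.item_bank))
    return ResponseMatrix(rm.person_ids, bank, values, rm.mask)


def filter_respondents(rm_biological: ResponseMatrix):
    """Keep only persons reporting difficulty on >= 1 biological item.

    Returns ``(kept_person_ids, n_kept)``.  A person whose non-missing codes
    are all in the lowest category reported no difficulty and is dropped.
    """
    observed_positive = (~rm_biological.mask) & (rm_biological.values > 0)
    keep = observed_positive.any(axis=1)
    if not keep.any():
        raise ValueError("no respondent reports any difficulty; nothing to analyse")
    kept = [p for p, k in zip(rm_biological.person_ids, keep) if k]
    return kept, len(kept)


def equate_lived_with_biological(rm_bio: ResponseMatrix, rm_lived: ResponseMatrix,
                                 aid_use: AidUseTable) -> ResponseMatrix:
    """Fill lived-health answers for people who use no aids in a domain.

    Lived-health questions were only put to people using technical aids or
    personal assistance in that domain; for everyone else lived health is by
    definition the same as biological health, so the biological response is
    copied over.  Aid users keep their observed lived responses.
    """
    if rm_bio.person_ids != rm_lived.person_ids:
        raise ValueError("person ids of the two matrices must align")
    bio_by_domain: dict[str, int] = {}
    for k, it in enumerate(rm_bio.item_bank):
        bio_by_domain.setdefault(it.domain, k)
    values = rm_lived.values.copy()
    mask = rm_lived.mask.copy()
    aid = aid_use.table.loc[rm_lived.person_ids]
    for k, item in enumerate(rm_lived.item_bank):
        if item.domain not in bio_by_domain:
            raise ValueError(f"lived item {item.item_id!r} (domain "
                             f"{item.domain!r}) has no biological counterpart")
        bk = _match_bio_item(rm_bio.item_bank, item, bio_by_domain)
        copy = ~aid[item.domain].to_numpy(bool)
        values[copy, k] = rm_bio.values[copy, bk]
        mask[copy, k] = rm_bio.mask[copy, bk]
    values = np.where(mask, MISSING, values)
    return ResponseMatrix(rm_lived.person_ids, rm_lived.item_bank, values, mask)


def _match_bio_item(bio_bank: ItemBank, lived_item: Item,
                    fallback: dict[str, int]) -> int:
    # prefer an explicit id correspondence (bio_<x> <-> lived_<x>), fall back
    # to the first biological item of the same domain
    want = lived_item.item_id.replace("lived", "bio")
    for k, it in enumerate(bio_bank):
        if it.item_id == want:
            return k
    return fallback[lived_item.domain]


def weighted_descriptives(covariates: pd.DataFrame, weights) -> pd.DataFrame:
    """Population-weighted frequency table of categorical covariates.

    One row per (variable, category) with weighted N and percentage;
    percentages sum to 100 within each variable.
    """
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("negative sampling weight")
    if len(w) != len(covariates):
        raise ValueError("weights not aligned to persons")
    rows = []
    for var in covariates.columns:
        grp = pd.Series(w).groupby(covariates[var].to_numpy()).sum()
        total = grp.sum()
        for cat, n in grp.items():
            rows.append({"variable": var, "category": cat,
                         "weighted_n": float(n),
                         "percent": 100.0 * float(n) / total})
    return pd.DataFrame(rows)
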
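"""Small/large-effect classification of mutations.

Mutations split by experimental effect size at |ddG| = 1 kcal/mol: small
effect below, large effect at or above.  Four "flags" carry probabilistic
information about the effect size: the WT residue type (X -> any), the MT
residue type (any -> X), and the location class of the mutation site in the
WT and in the MT complex.  Each flag row holds the empirical probability of
a large effect,

    P(flag row) = (# cases with |ddG| >= 1) / (# cases in row).

Cases whose four flags disagree are reconciled by reweighting: for flag
dimension i, every case's |ddG| is altered using the other three flags'
probabilities,

    |ddG|_altered = 2/3 * sum_{j != i} p_j       * |ddG|   if |ddG| < 1
    |ddG|_altered = 2/3 * sum_{j != i} (1 - p_j) * |ddG|   if |ddG| >= 1,

and dimension i's table is rebuilt from its own altered values (one pass).
When every probability is 0.5 the alteration is the identity.

Prediction routes on the consensus probability P = mean of the four
p_large values: P >= 0.5 selects the large-effect weight set.

The bundled default tables were derived from a curated experimental
mutation database (~2000 single point mutations) after one alteration pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .constants import LARGE_EFFECT_THRESHOLD
from .surface import LocationClass

_FLAG_NAMES = ("wt_residue", "mt_residue", "wt_location", "mt_location")


class UndefinedFlagError(KeyError):
    """A probability-table row needed for a flag has no data."""


@dataclass(frozen=True)
class MutationAnnotation:
    """The four flags of one mutation."""

    wt_aa: str
    mt_aa: str
    loc_wt: LocationClass
    loc_mt: LocationClass

    def flag_keys(self) -> tuple:
        return (self.wt_aa, self.mt_aa, self.loc_wt, self.loc_mt)


@dataclass
class ProbabilityTables:
    """Four per-flag tables of (p_small, p_large, n_cases).

    Each table maps a flag value (one-letter residue code, or a
    :class:`LocationClass`) to a (p_small, p_large, n) triple.  Rows with no
    data are simply absent; looking them up raises
    :class:`UndefinedFlagError` rather than defaulting.
    """

    wt_residue: dict = field(default_factory=dict)
    mt_residue: dict = field(default_factory=dict)
    wt_location: dict = field(default_factory=dict)
    mt_location: dict = field(default_factory=dict)

    def _table(self, name: str) -> dict:
        return getattr(self, name)

    def p_large(self, flag: str, key) -> float:
        table = self._table(flag)
        if key not in table:
            raise UndefinedFlagError(
                f"no data for flag {flag!r} value {key!s}")
        return table[key][1]

    def flag_probabilities(self, annotation: MutationAnnotation
                           ) -> tuple[float, float, float, float]:
        return tuple(self.p_large(flag, key)
                     for flag, key in zip(_FLAG_NAMES, annotation.flag_keys()))

    def validate(self, tol: float = 1e-9) -> None:
        for name in _FLAG_NAMES:
            for key, (p_small, p_large, n) in self._table(name).items():
                if not (0 <= p_small <= 1 and 0 <= p_large <= 1):
                    raise ValueError(f"{name}[{key}]: probability out of [0,1]")
                if abs(p_small + p_large - 1.0) > tol:
                    raise ValueError(f"{name}[{key}]: p_small+p_large != 1")
                if n < 0:
                    raise ValueError(f"{name}[{key}]: negative count")


def load_default_tables() -> ProbabilityTables:
    """The bundled (altered) residue-type and location probability tables."""
    pkg = resources.files("ddgbind") / "data"
    res = pd.read_csv(pkg / "residue_effect_probabilities.tsv", sep="\t")
    loc = pd.read_csv(pkg / "location_effect_probabilities.tsv", sep="\t")
    tables = ProbabilityTables()
    for _, row in res.iterrows():
        tables.wt_residue[row["aa"]] = (row["wt_p_small"], row["wt_p_large"],
                                        int(row["wt_n"]))
        tables.mt_residue[row["aa"]] = (row["mt_p_small"], row["mt_p_large"],
                                        int(row["mt_n"]))
    for _, row in loc.iterrows():
        key = LocationClass(row["location"])
        tables.wt_location[key] = (row["wt_p_small"], row["wt_p_large"],
                                   int(row["wt_n"]))
        tables.mt_location[key] = (row["mt_p_small"], row["mt_p_large"],
                                   int(row["mt_n"]))
    # printed tables are rounded to 2 decimals, so allow that much slack
    tables.validate(tol=0.011)
    return tables


def _coerce_records(records) -> pd.DataFrame:
    """Accept a DataFrame or (annotation, ddg) pairs; return a flat frame."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
        if "abs_ddg" not in df.columns:
            df["abs_ddg"] = df["ddg_exp"].abs()
        df["loc_wt"] = [LocationClass(x) if not isinstance(x, LocationClass)
                        else x for x in df["loc_wt"]]
        df["loc_mt"] = [LocationClass(x) if not isinstance(x, LocationClass)
                        else x for x in df["loc_mt"]]
        return df
    rows = [{"wt_aa": ann.wt_aa, "mt_aa": ann.mt_aa,
             "loc_wt": ann.loc_wt, "loc_mt": ann.loc_mt,
             "abs_ddg": abs(float(ddg))} for ann, ddg in records]
    return pd.DataFrame(rows)


def build_probability_tables(records) -> ProbabilityTables:
    """Empirical per-flag large-effect probabilities from annotated data.

    ``records`` is a DataFrame with columns wt_aa, mt_aa, loc_wt, loc_mt and
    abs_ddg (or ddg_exp), or an iterable of (MutationAnnotation, ddg) pairs.
    |ddG| >= 1 kcal/mol counts as a large effect; rows with no cases stay
    undefined.
    """
    df = _coerce_records(records)
    if df.empty:
        raise ValueError("empty dataset: cannot build probability tables")
    tables = ProbabilityTables()
    large = df["abs_ddg"] >= LARGE_EFFECT_THRESHOLD
    for flag, column in zip(_FLAG_NAMES, ("wt_aa", "mt_aa", "loc_wt", "loc_mt")):
        table = tables._table(flag)
        for key, group in df.groupby(column, sort=False):
            n = len(group)
            p_lg = float(large[group.index].sum()) / n
            table[key] = (1.0 - p_lg, p_lg, n)
    return tables


def alter_ddg(abs_ddg: float, flag_index: int,
              p: tuple[float, float, float, float]) -> float:
    """Altered |ddG| for one flag dimension (1-based ``flag_index``).

    Leaves out the probability of the examined flag and weighs |ddG| by the
    other three flags' consensus: small-effect cases by their probability of
    a large effect, large-effect cases by the complementary probability.
    """
    if flag_index not in (1, 2, 3, 4):
        raise ValueError("flag_index must be in 1..4")
    if abs_ddg < 0:
        raise ValueError("abs_ddg must be non-negative")
    others = [p[j] for j in range(4) if j != flag_index - 1]
    if abs_ddg < LARGE_EFFECT_THRESHOLD:
        factor = sum(others)
    else:
        factor = sum(1.0 - pj for pj in others)
    return (2.0 / 3.0) * factor * abs_ddg


def reweight_tables(records, initial: ProbabilityTables) -> ProbabilityTables:
    """One alteration pass: rebuild each flag table from its own altered set.

    Records whose flags have no row in ``initial`` are excluded with a
    warning.  A dataset whose initial tables are uniformly (0.5, 0.5) is a
    fixed point: the altered tables equal the initial ones.
    """
    df = _coerce_records(records)
    probs = []
    keep = []
    for idx, row in df.iterrows():
        ann = MutationAnnotation(row["wt_aa"], row["mt_aa"],
                                 row["loc_wt"], row["loc_mt"])
        try:
            probs.append(initial.flag_probabilities(ann))
            keep.append(idx)
        except UndefinedFlagError as exc:
            warnings.warn(f"record {idx} excluded from reweighting: {exc}",
                          stacklevel=2)
    df = df.loc[keep]
    probs = np.asarray(probs)

    out = ProbabilityTables()
    for i, (flag, column) in enumerate(
            zip(_FLAG_NAMES, ("wt_aa", "mt_aa", "loc_wt", "loc_mt")), start=1):
        altered = np.array([
            alter_ddg(row_abs, i, tuple(p_row))
            for row_abs, p_row in zip(df["abs_ddg"].to_numpy(), probs)
        ])
        table = out._table(flag)
        large = altered >= LARGE_EFFECT_THRESHOLD
        values = df[column].to_numpy()
        for key in pd.unique(values):
            mask = values == key
            n = int(mask.sum())
            p_lg = float(large[mask].sum()) / n
            table[key] = (1.0 - p_lg, p_lg, n)
    return out


def consensus_probability(annotation: MutationAnnotation,
                          tables: ProbabilityTables
                          ) -> tuple[float, str]:
    """Mean of the four flag probabilities and the resulting subset tag.

    Returns ``(P, tag)`` with tag "large" when P >= 0.5, else "small".
    """
    probs = tables.flag_probabilities(annotation)
    p = float(np.mean(probs))
    return p, ("large" if p >= 0.5 else "small")
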
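"""Loading and curation of experimental mutation datasets.

The expected tabular format is SKEMPI-like: one row per measured mutation
with the complex's PDB id, the two partner chain groups, a compact mutation
string (WT residue, chain, author site number, MT residue — e.g. "QA123P")
and the experimental ddG in kcal/mol.

Curation mirrors standard practice for such compilations:

* exact duplicates (same mutation, same value) collapse to one entry;
* repeated measurements of one mutation are fused to their mean when their
  spread (max - min) is below 1.5 kcal/mol, and the mutation is dropped
  entirely when the spread reaches 1.5 kcal/mol or more (irreconcilable
  measurements);
* rows flagged as sitting in structurally disordered segments are removed.

Every action is recorded in an audit log.  Curation is idempotent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .structures import MutationDescriptor

#: measurement-spread threshold (kcal/mol): >= this, the group is deleted
FUSION_SPREAD_THRESHOLD = 1.5

_MUTATION_RE = re.compile(
    r"^(?P<wt>[A-Z])(?P<chain>[A-Za-z0-9])(?P<site>\d+)(?P<icode>[A-Z]?)"
    r"(?P<mt>[A-Z])$")


@dataclass(frozen=True)
class MutationRecord:
    """One experimental measurement of a point mutation's effect on binding."""

    pdb_id: str
    partner_a_chains: tuple
    partner_b_chains: tuple
    mutation: MutationDescriptor
    ddg_exp: float
    source: str = ""


def parse_mutation_string(text: str) -> MutationDescriptor:
    """Parse a compact SKEMPI-style mutation string like ``QA123P``."""
    m = _MUTATION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse mutation string {text!r}")
    return MutationDescriptor(chain_id=m.group("chain"),
                              site=int(m.group("site")),
                              wt_aa=m.group("wt"), mt_aa=m.group("mt"),
                              icode=m.group("icode"))


def load_mutation_csv(path: str | Path) -> pd.DataFrame:
    """Read a mutation dataset CSV into a normalized DataFrame.

    Expected columns: pdb, chain_a, chain_b, mutation, ddg; optional:
    disordered (truthy marks mutations in disordered segments), source.
    Adds parsed columns wt_aa, chain, site, icode, mt_aa.
    """
    df = pd.read_csv(path, dtype={"pdb": str, "chain_a": str, "chain_b": str,
                                  "mutation": str})
    required = {"pdb", "chain_a", "chain_b", "mutation", "ddg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation CSV lacks columns {sorted(missing)}")
    parsed = [parse_mutation_string(s) for s in df["mutation"]]
    df = df.assign(
        wt_aa=[m.wt_aa for m in parsed], chain=[m.chain_id for m in parsed],
        site=[m.site for m in parsed], icode=[m.icode for m in parsed],
        mt_aa=[m.mt_aa for m in parsed],
    )
    df["ddg"] = df["ddg"].astype(float)
    if not df["ddg"].map(pd.notna).all() or not df["ddg"].map(
            lambda v: abs(v) < float("inf")).all():
        raise ValueError("non-finite ddg values in mutation CSV")
    return df


_GROUP_KEY = ["pdb", "chain", "site", "icode", "wt_aa", "mt_aa"]


def curate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the curation rules; returns (curated frame, audit log).

    Groups rows by (pdb, chain, site, insertion code, WT, MT).  Within each
    group: exact duplicates collapse first; then a spread below 1.5
    kcal/mol fuses the group to its mean ddg, while a spread of 1.5 or more
    deletes the group.  Rows with a truthy ``disordered`` column are
    removed up front.  The audit log records one entry per action.
    """
    audit: list[dict] = []
    df = df.copy()
    if "disordered" in df.columns:
        bad = df["disordered"].map(lambda v: bool(v) and not pd.isna(v))
        for _, row in df[bad].iterrows():
            audit.append({"action": "removed_disordered",
                          "mutation": row["mutation"], "pdb": row["pdb"]})
        df = df[~bad]

    kept_rows = []
    for key, group in df.groupby(_GROUP_KEY, sort=False):
        values = group["ddg"]
        n_before = len(values)
        deduped = values.drop_duplicates()
        if len(deduped) < n_before:
            audit.append({"action": "collapsed_duplicates", "key": key,
                          "n_removed": n_before - len(deduped)})
        if len(deduped) == 1:
            row = group.iloc[[0]].copy()
            row["ddg"] = deduped.iloc[0]
            kept_rows.append(row)
            continue
        spread = float(deduped.max() - deduped.min())
        if spread < FUSION_SPREAD_THRESHOLD:
            row = group.iloc[[0]].copy()
            row["ddg"] = float(deduped.mean())
            kept_rows.append(row)
            audit.append({"action": "fused", "key": key,
                          "n_fused": len(deduped), "spread": spread,
                          "mean_ddg": float(deduped.mean())})
        else:
            audit.append({"action": "deleted_inconsistent", "key": key,
                          "n_deleted": len(deduped), "spread": spread})
    if kept_rows:
        curated = pd.concat(kept_rows, ignore_index=True)
    else:
        curated = df.iloc[0:0].copy()
    return curated, audit
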
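"""Reproducible table pipelines over a graph collection.

Thin orchestration: compute descriptor (or superindex) value tables and
emit uniqueness summaries shaped like the published tables — one row per
descriptor with (ndv, sensitivity) for the single-index table, and a
pairs-by-combinators ndv matrix for the superindex tables.  Every run can
write a machine-readable JSON log (config, seed, version, wall time) so a
stored configuration re-executes to identical outputs.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .descriptors import DescriptorUnavailable, compute_tables
from .enumeration import GraphCollection
from .superindices import EQ_IDS, SuperIndexSpec, combine
from .uniqueness import (
    DEFAULT_POLICY,
    EqualityPolicy,
    ndv,
    sensitivity,
    uniqueness_scan,
)

__all__ = ["run_table4", "run_supertables", "write_run_log"]


def run_table4(
    collection: GraphCollection,
    names: Sequence[str],
    policy: EqualityPolicy = DEFAULT_POLICY,
) -> pd.DataFrame:
    """Single-descriptor uniqueness table: (descriptor, ndv, sensitivity).

    Unimplemented descriptors yield a row marked unavailable instead of
    aborting the run.  Sensitivity is reported at full precision and
    rounded to 5 decimals for comparability with the published layout.
    """
    reports = uniqueness_scan(collection, list(names), policy)
    return pd.DataFrame(
        {
            "descriptor": [r.index_name for r in reports],
            "ndv": [r.ndv if r.available else pd.NA for r in reports],
            "sensitivity": [r.sensitivity for r in reports],
            "sensitivity_5dp": [r.sensitivity_5dp for r in reports],
            "available": [r.available for r in reports],
            "policy": [r.policy for r in reports],
        }
    )


def run_supertables(
    collection: GraphCollection,
    pairs: Sequence[tuple[str, str]],
    eq_ids: Sequence[str] = EQ_IDS,
    policy: EqualityPolicy = DEFAULT_POLICY,
) -> pd.DataFrame:
    """Superindex ndv matrix: pairs as rows, combinators as columns."""
    for eq in eq_ids:
        SuperIndexSpec(eq, "_a", "_b")  # validates eq_id
    names = sorted({x for pair in pairs for x in pair})
    tables = {}
    missing = set()
    for name in names:
        try:
            tables.update(compute_tables(collection, [name]))
        except DescriptorUnavailable:
            missing.add(name)
    rows = {}
    for a, b in pairs:
        label = f"{a}_{b}"
        if a in missing or b in missing:
            rows[label] = {eq: pd.NA for eq in eq_ids}
            continue
        rows[label] = {
            eq: ndv(combine(tables[a], tables[b], eq), policy)
            for eq in eq_ids
        }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(eq_ids))
    df.index.name = "pair"
    return df


def write_run_log(
    path: str | Path, config: dict, started: float, seed: int | None = None
) -> None:
    """JSON run log: config, seed, tool version, wall time."""
    log = {
        "tool": "topodisc",
        "version": __version__,
        "seed": seed,
        "config": config,
        "wall_seconds": round(time.time() - started, 3),
    }
    Path(path).write_text(json.dumps(log, indent=2, default=str) + "\n")
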
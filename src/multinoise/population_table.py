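"""Genome-wide protein-statistics summaries by essentiality and multimer order.

Real genome-wide inputs (per-gene mean copy number, squared CV,
essentiality, homogeneous-subunit count) arrive as a plain CSV with columns
``gene, essential, subunits, mean, cv2``; :func:`summarize` reduces such a
table to the per-(essentiality, subunit-count) percentages and medians.
:func:`generate_fixture` draws a synthetic table with the same qualitative
structure reported for E. coli — essential genes are fewer, more highly
expressed, more often multimeric, and their noise sits on a floor — for
testing the summarizer without the external databases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProteinRecord",
    "MultimerSummary",
    "summarize",
    "generate_fixture",
    "read_records",
    "write_records",
]


@dataclass(frozen=True)
class ProteinRecord:
    """One gene's population statistics.

    mean   mean protein copies per cell (> 0)
    noise  squared coefficient of variation of the copy number (>= 0)
    """

    gene: str
    essential: bool
    subunits: int
    mean: float
    noise: float

    def __post_init__(self):
        if int(self.subunits) != self.subunits or self.subunits < 1:
            raise ValueError("subunits must be an integer >= 1")
        object.__setattr__(self, "subunits", int(self.subunits))
        if not (self.mean > 0 and math.isfinite(self.mean)):
            raise ValueError("mean must be positive")
        if not (self.noise >= 0 and math.isfinite(self.noise)):
            raise ValueError("noise must be nonnegative")


@dataclass(frozen=True)
class MultimerSummary:
    """Per (essentiality, subunit count) percentages and medians.

    ``table`` has one row per group with columns ``essential, subunits,
    n_genes, percent, med_mu, med_eta``; groups absent from the input are
    not listed (an unavailable cell in the wide view is NaN).  Within each
    essentiality class the percentages sum to 100.
    """

    table: pd.DataFrame

    def wide(self) -> pd.DataFrame:
        """Table-style wide view: rows (class, statistic) x subunit count."""
        out = {}
        for stat in ("percent", "med_mu", "med_eta"):
            p = self.table.pivot(index="essential", columns="subunits", values=stat)
            for ess in p.index:
                out[("essential" if ess else "non_essential", stat)] = p.loc[ess]
        return pd.DataFrame(out).T


def summarize(records: Sequence[ProteinRecord]) -> MultimerSummary:
    """Group by (essentiality, subunit count): percent of class, med mu/eta."""
    if not records:
        raise ValueError("no records to summarize")
    df = pd.DataFrame(
        {
            "essential": [r.essential for r in records],
            "subunits": [r.subunits for r in records],
            "mean": [r.mean for r in records],
            "noise": [r.noise for r in records],
        }
    )
    class_sizes = df.groupby("essential").size()
    g = df.groupby(["essential", "subunits"])
    table = g.agg(n_genes=("mean", "size"), med_mu=("mean", "median"),
                  med_eta=("noise", "median")).reset_index()
    table["percent"] = [
        100.0 * n / class_sizes[ess] for ess, n in zip(table["essential"], table["n_genes"])
    ]
    table = table[["essential", "subunits", "n_genes", "percent", "med_mu", "med_eta"]]
    table = table.sort_values(["essential", "subunits"]).reset_index(drop=True)
    return MultimerSummary(table=table)


# Default subunit-count distributions, patterned on the reported class
# compositions for essential and non-essential bacterial genes (index i is
# the probability of i+1 homogeneous subunits).
_ESSENTIAL_SUBUNIT_P = (0.5455, 0.2975, 0.0413, 0.0496, 0.0, 0.0496, 0.0083, 0.0, 0.0, 0.0083)
_NONESSENTIAL_SUBUNIT_P = (0.7280, 0.1806, 0.0123, 0.0457, 0.0022, 0.0178, 0.0, 0.0, 0.0, 0.0134)


def generate_fixture(
    n_genes: int = 1000,
    essential_fraction: float = 0.12,
    subunit_distribution: Mapping[bool, Sequence[float]] | None = None,
    mu_median: Mapping[bool, float] | None = None,
    mu_sigma: float = 1.2,
    mu_subunit_exponent: float = 0.5,
    noise_floor: float = 0.12,
    noise_scale: float = 2.0,
    noise_sigma: float = 0.4,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Draw a synthetic genome-wide protein-statistics table.

    The generative model mirrors the qualitative genome-wide picture:
    essential genes (a fraction ``essential_fraction``) have higher median
    expression, a subunit-count distribution skewed toward multimers, and
    mean levels that grow with subunit count (``mu ~ lognormal`` with
    median ``mu_median * subunits**mu_subunit_exponent``); noise decreases
    with the mean down to an extrinsic floor,
    ``eta = (noise_floor + noise_scale / mu) * lognormal(0, noise_sigma)``.
    """
    if not 0 < essential_fraction < 1:
        raise ValueError("essential_fraction must be in (0, 1)")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    sub_p = {True: _ESSENTIAL_SUBUNIT_P, False: _NONESSENTIAL_SUBUNIT_P}
    if subunit_distribution is not None:
        sub_p.update(subunit_distribution)
    med = {True: 34.0, False: 9.0}
    if mu_median is not None:
        med.update(mu_median)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_genes):
        essential = bool(rng.random() < essential_fraction)
        p = np.asarray(sub_p[essential], dtype=float)
        if np.any(p < 0) or p.sum() <= 0:
            raise ValueError("subunit distribution must be nonnegative and sum > 0")
        subunits = int(rng.choice(np.arange(1, len(p) + 1), p=p / p.sum()))
        mu = float(
            np.exp(
                math.log(med[essential] * subunits**mu_subunit_exponent)
                + mu_sigma * rng.standard_normal()
            )
        )
        noise = float((noise_floor + noise_scale / mu) * np.exp(noise_sigma * rng.standard_normal()))
        records.append(
            ProteinRecord(gene=f"g{i:04d}", essential=essential, subunits=subunits,
                          mean=mu, noise=noise)
        )
    return records


_COLUMNS = ["gene", "essential", "subunits", "mean", "cv2"]


def write_records(records: Sequence[ProteinRecord], path) -> None:
    pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "essential": [r.essential for r in records],
            "subunits": [r.subunits for r in records],
            "mean": [r.mean for r in records],
            "cv2": [r.noise for r in records],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_records(path) -> list[ProteinRecord]:
    """Read the documented CSV schema (gene, essential, subunits, mean, cv2)."""
    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [
        ProteinRecord(
            gene=str(r.gene), essential=bool(r.essential), subunits=int(r.subunits),
            mean=float(r.mean), noise=float(r.cv2),
        )
        for r in df.itertuples()
    ]
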
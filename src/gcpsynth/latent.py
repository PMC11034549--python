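"""Latent patient tables.

A :class:`LatentTable` holds one row per patient over named real-valued
latent columns: the GCP patient factors, optionally the mask-tensor patient
factors, a visit-count column, and baseline attributes.  All samplers
consume and produce this object.  :class:`AugmentedLatent` additionally tags
contiguous column blocks so that the sampled table can be split back into
its parts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LatentTable", "AugmentedLatent", "augment_latent"]

COLUMN_KINDS = ("continuous", "count", "categorical-coded")


@dataclass
class LatentTable:
    """Per-patient rows over named latent columns; no missing cells allowed.

    ``kinds`` maps column name -> one of {"continuous", "count",
    "categorical-coded"}; unlisted columns default to "continuous".
    ``provenance_loss`` records which GCP loss produced the factor columns
    (the HMC sampler refuses non-Gaussian provenance by default).
    """

    df: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)
    provenance_loss: str | None = None

    def __post_init__(self) -> None:
        self.df = pd.DataFrame(self.df).reset_index(drop=True)
        if self.df.columns.duplicated().any():
            raise ValueError("latent column names must be unique")
        if self.df.isna().any().any():
            raise ValueError("latent tables must not contain missing cells")
        for col, kind in self.kinds.items():
            if kind not in COLUMN_KINDS:
                raise ValueError(f"unknown column kind {kind!r} for {col!r}")

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def kind_of(self, col: str) -> str:
        return self.kinds.get(col, "continuous")

    def like(self, values: np.ndarray) -> "LatentTable":
        """New table with the same columns/kinds/provenance but new rows."""
        return LatentTable(
            pd.DataFrame(np.asarray(values, dtype=float), columns=self.columns),
            dict(self.kinds),
            self.provenance_loss,
        )


@dataclass
class AugmentedLatent:
    """A LatentTable whose columns are partitioned into tagged blocks.

    ``blocks`` maps block tag ("gcp_factors", "mask_factors", "visit_count",
    "baseline") to the list of column names in that block, in table order.
    """

    table: LatentTable
    blocks: dict[str, list[str]]

    def __post_init__(self) -> None:
        tagged = [c for cols in self.blocks.values() for c in cols]
        if sorted(tagged) != sorted(self.table.columns):
            raise ValueError("block tags must partition the latent columns")
        if len(tagged) != len(set(tagged)):
            raise ValueError("a column may belong to exactly one block")

    def split(self) -> dict[str, LatentTable]:
        """Per-block sub-tables; concatenating them restores the table."""
        out = {}
        for tag, cols in self.blocks.items():
            out[tag] = LatentTable(
                self.table.df[cols].copy(),
                {c: self.table.kind_of(c) for c in cols},
                self.table.provenance_loss,
            )
        return out

    def with_table(self, table: LatentTable) -> "AugmentedLatent":
        """Same block structure over new rows (e.g. sampler output)."""
        return AugmentedLatent(table, {k: list(v) for k, v in self.blocks.items()})


def augment_latent(
    gcp_factors: LatentTable,
    mask_factors: LatentTable | None = None,
    visit_counts: np.ndarray | None = None,
    baselines: LatentTable | None = None,
) -> AugmentedLatent:
    """Column-wise concatenation of latent blocks with tags.

    All blocks must share patient order and row count.  The inverse
    operation is :meth:`AugmentedLatent.split`.
    """
    parts = [gcp_factors.df]
    kinds = dict(gcp_factors.kinds)
    blocks: dict[str, list[str]] = {"gcp_factors": gcp_factors.columns}
    n = gcp_factors.n_rows

    if mask_factors is not None:
        if mask_factors.n_rows != n:
            raise ValueError(
                f"mask_factors rows ({mask_factors.n_rows}) != gcp rows ({n})"
            )
        parts.append(mask_factors.df)
        kinds.update(mask_factors.kinds)
        blocks["mask_factors"] = mask_factors.columns
    if visit_counts is not None:
        vc = np.asarray(visit_counts, dtype=float)
        if vc.shape != (n,):
            raise ValueError(f"visit_counts shape {vc.shape} != ({n},)")
        parts.append(pd.DataFrame({"visit_count": vc}))
        kinds["visit_count"] = "count"
        blocks["visit_count"] = ["visit_count"]
    if baselines is not None:
        if baselines.n_rows != n:
            raise ValueError(f"baseline rows ({baselines.n_rows}) != gcp rows ({n})")
        parts.append(baselines.df)
        kinds.update(baselines.kinds)
        blocks["baseline"] = baselines.columns

    df = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    table = LatentTable(df, kinds, gcp_factors.provenance_loss)
    return AugmentedLatent(table, blocks)
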
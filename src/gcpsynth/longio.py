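"""Long-format records and artifact IO.

The interchange format is a tidy UTF-8 CSV with header exactly
``patient_id,variable,visit,value``; an empty value field denotes a missing
cell (mask = 0).  A :class:`LongTable` is the in-memory form; conversion to
and from :class:`~gcpsynth.tensor.Tensor3` lives here as well.

Kruskal models serialize to a directory of delimited text matrices (A.tsv,
B.tsv, C.tsv) plus a JSON metadata file (rank, loss, weights, axis labels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DuplicateCellError, FormatError
from .tensor import KruskalModel, Tensor3

__all__ = [
    "LongTable",
    "read_long_csv",
    "write_long_csv",
    "tensor_to_long",
    "long_to_tensor",
    "save_model",
    "load_model",
]

HEADER = ["patient_id", "variable", "visit", "value"]


@dataclass
class LongTable:
    """Tidy (patient, variable, visit, value) records; NaN value = missing."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=HEADER))

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.df)
        if list(df.columns) != HEADER:
            raise FormatError(f"columns must be exactly {HEADER}, got {list(df.columns)}")
        df = df.astype({"patient_id": str, "variable": str})
        try:
            df["visit"] = df["visit"].astype(int)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"visit indices must be integers: {exc}") from exc
        if (df["visit"] < 1).any():
            raise FormatError("visit indices must be >= 1")
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        dupes = df.duplicated(subset=["patient_id", "variable", "visit"], keep=False)
        if dupes.any():
            offenders = df.loc[dupes, ["patient_id", "variable", "visit"]].head(5)
            raise DuplicateCellError(
                f"duplicate (patient, variable, visit) cells:\n{offenders}"
            )
        self.df = df.sort_values(["patient_id", "variable", "visit"]).reset_index(
            drop=True
        )

    @property
    def n_patients(self) -> int:
        return self.df["patient_id"].nunique()

    @property
    def variables(self) -> list[str]:
        return sorted(self.df["variable"].unique())

    def missing_count(self) -> int:
        return int(self.df["value"].isna().sum())

    def missing_fraction(self) -> float:
        return float(self.df["value"].isna().mean()) if len(self.df) else 0.0

    def observed_values(self, variable: str) -> np.ndarray:
        sel = self.df[self.df["variable"] == variable]["value"]
        return sel.dropna().to_numpy(dtype=float)


def read_long_csv(path: str | Path) -> LongTable:
    """Read a long-format CSV; empty value fields become missing cells."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().strip()
    if header.split(",") != HEADER:
        raise FormatError(
            f"{path}: line 1: header must be {','.join(HEADER)!r}, got {header!r}"
        )
    try:
        df = pd.read_csv(
            path,
            dtype={"patient_id": str, "variable": str},
            float_precision="round_trip",
        )
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    return LongTable(df)


def write_long_csv(table: LongTable, path: str | Path, precision: int = 17) -> None:
    """Write the table; missing cells round-trip as empty fields."""
    table.df.to_csv(path, index=False, float_format=f"%.{precision}g")


def long_to_tensor(table: LongTable) -> Tensor3:
    """Pivot the long table into a dense tensor with a binary mask.

    Axis labels come from sorted unique patients/variables and visits
    1..max(visit).  Cells absent from the table (or present with an empty
    value) get mask 0.
    """
    if table.df.empty:
        raise FormatError("cannot tensorize an empty table")
    patients = sorted(table.df["patient_id"].unique())
    variables = sorted(table.df["variable"].unique())
    K = int(table.df["visit"].max())
    I, J = len(patients), len(variables)
    values = np.full((I, J, K), np.nan)
    mask = np.zeros((I, J, K))
    pi = {p: i for i, p in enumerate(patients)}
    vj = {v: j for j, v in enumerate(variables)}
    rows = table.df
    ii = rows["patient_id"].map(pi).to_numpy()
    jj = rows["variable"].map(vj).to_numpy()
    kk = rows["visit"].to_numpy() - 1
    vals = rows["value"].to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    values[ii[obs], jj[obs], kk[obs]] = vals[obs]
    mask[ii[obs], jj[obs], kk[obs]] = 1.0
    return Tensor3(values, mask, patients, variables, list(range(1, K + 1)))


def tensor_to_long(t: Tensor3, include_missing: bool = False) -> LongTable:
    """Flatten a tensor back into tidy records.

    With ``include_missing`` masked cells are emitted with empty values
    (useful to preserve a missingness pattern in the CSV); otherwise they
    are dropped.
    """
    I, J, K = t.shape
    ii, jj, kk = np.meshgrid(range(I), range(J), range(K), indexing="ij")
    obs = t.observed.ravel()
    keep = np.ones(I * J * K, dtype=bool) if include_missing else obs
    vals = np.where(t.observed, t.values, np.nan).ravel()
    df = pd.DataFrame(
        {
            "patient_id": np.asarray(t.patient_ids)[ii.ravel()[keep]],
            "variable": np.asarray(t.variable_names)[jj.ravel()[keep]],
            "visit": np.asarray(t.visit_indices)[kk.ravel()[keep]],
            "value": vals[keep],
        }
    )
    return LongTable(df)


def save_model(model: KruskalModel, directory: str | Path, labels: dict | None = None) -> None:
    """Persist a Kruskal model as delimited text matrices + JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, f in zip(("A", "B", "C"), model.factors):
        np.savetxt(directory / f"{name}.tsv", f, delimiter="\t", fmt="%.17g")
    meta = {
        "rank": model.rank,
        "loss": model.loss_name,
        "nonnegative": model.nonnegative,
        "weights": [float(w) for w in model.weights],
        "labels": labels or {},
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> tuple[KruskalModel, dict]:
    """Inverse of :func:`save_model`; returns (model, labels)."""
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    factors = tuple(
        np.loadtxt(directory / f"{name}.tsv", delimiter="\t", ndmin=2)
        for name in ("A", "B", "C")
    )
    model = KruskalModel(
        factors=factors,  # type: ignore[arg-type]
        weights=np.asarray(meta["weights"], dtype=float),
        loss_name=meta["loss"],
        nonnegative=meta["nonnegative"],
    )
    return model, meta.get("labels", {})
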
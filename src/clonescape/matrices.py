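"""Labelled square matrices shared across the pipeline.

Pairwise F_ST, over-water distances, dispersal probability and flow are all
square matrices whose rows/columns are site or patch names; this container
keeps labels and values aligned and handles the CSV round trip (header row +
label column, optional ``#``-prefixed provenance comment lines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LabelledMatrix"]


@dataclass
class LabelledMatrix:
    labels: tuple
    values: np.ndarray
    kind: str = "symmetric"  # or "asymmetric"
    units: str = ""

    def __post_init__(self):
        self.labels = tuple(str(x) for x in self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"values shape {self.values.shape} does not match {n} labels"
            )
        if self.kind not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.kind == "symmetric" and not np.allclose(
            self.values, self.values.T, equal_nan=True
        ):
            raise ValueError("matrix declared symmetric but is not")

    @property
    def n(self) -> int:
        return len(self.labels)

    def loc(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def offdiag_upper(self) -> np.ndarray:
        """Vectorized strict upper triangle (the 120 pairs for 16 sites)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, labels) -> "LabelledMatrix":
        idx = [self.labels.index(l) for l in labels]
        return LabelledMatrix(
            labels=tuple(labels),
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
            units=self.units,
        )

    def map(self, fn, kind: str | None = None) -> "LabelledMatrix":
        return LabelledMatrix(
            labels=self.labels,
            values=fn(self.values.copy()),
            kind=kind or self.kind,
            units=self.units,
        )

    def to_csv(self, path, meta: dict | None = None) -> None:
        with open(path, "w") as fh:
            if meta:
                for k, v in meta.items():
                    fh.write(f"# {k}={v}\n")
            self.to_frame().to_csv(fh, index_label="site")

    @classmethod
    def from_csv(cls, path, kind: str = "symmetric", units: str = "") -> "LabelledMatrix":
        df = pd.read_csv(path, comment="#", index_col=0)
        df.columns = [str(c) for c in df.columns]
        if list(df.index.astype(str)) != list(df.columns):
            raise ValueError("row labels do not match column labels")
        return cls(labels=tuple(df.columns), values=df.to_numpy(float), kind=kind, units=units)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str = "symmetric", units: str = "") -> "LabelledMatrix":
        return cls(labels=tuple(str(c) for c in df.columns), values=df.to_numpy(float), kind=kind, units=units)
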
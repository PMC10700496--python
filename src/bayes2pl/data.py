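"""Dichotomous response matrices and their delimited-text representation.

Persons are rows, items are columns, entries are 0/1 with an optional
missing marker (default ``NA``).  Files carry a header row of item ids and
a first column of person ids; both delimiter and missing marker are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ResponseMatrix", "read_response_matrix", "write_response_matrix"]


@dataclass
class ResponseMatrix:
    """N x I matrix of dichotomous responses with a missing-entry mask.

    ``y`` stores 0/1 (missing cells hold 0 and are excluded via ``mask``);
    ``mask`` is True where the response was observed.
    """

    y: np.ndarray
    mask: np.ndarray | None = None
    person_ids: list = field(default=None)
    item_ids: list = field(default=None)

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if self.y.ndim != 2:
            raise ValueError("response matrix must be two-dimensional")
        if self.mask is None:
            # NaN marks missing in a float input
            if np.issubdtype(self.y.dtype, np.floating):
                self.mask = ~np.isnan(self.y)
            else:
                self.mask = np.ones(self.y.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.y.shape:
            raise ValueError("mask shape must match response matrix shape")
        y = np.where(self.mask, self.y, 0)
        vals = np.unique(y[self.mask]) if self.mask.any() else np.array([])
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("observed responses must be 0 or 1")
        self.y = y.astype(np.int8)
        if not self.mask.any(axis=1).all():
            raise ValueError("every person needs at least one observed response")
        if not self.mask.any(axis=0).all():
            raise ValueError("every item needs at least one observed response")
        if self.person_ids is None:
            self.person_ids = [f"p{j+1}" for j in range(self.y.shape[0])]
        if self.item_ids is None:
            self.item_ids = [f"i{i+1}" for i in range(self.y.shape[1])]

    @property
    def n_persons(self) -> int:
        return self.y.shape[0]

    @property
    def n_items(self) -> int:
        return self.y.shape[1]

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def to_frame(self, missing="NA") -> pd.DataFrame:
        obj = self.y.astype(object)
        obj[~self.mask] = missing
        return pd.DataFrame(obj, index=self.person_ids, columns=self.item_ids)


def read_response_matrix(path, delimiter=",", missing="NA") -> ResponseMatrix:
    """Read a delimited 0/1 response matrix with header and person-id column.

    Raises a ``ValueError`` naming the offending cell for any entry that is
    not 0, 1 or the missing marker, and for ragged rows.
    """
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    y = np.zeros(df.shape, dtype=np.int8)
    mask = np.ones(df.shape, dtype=bool)
    for j in range(df.shape[0]):
        for i in range(df.shape[1]):
            cell = str(df.iat[j, i]).strip()
            if cell == missing:
                mask[j, i] = False
            elif cell in ("0", "1"):
                y[j, i] = int(cell)
            else:
                raise ValueError(
                    f"invalid response {cell!r} at row {df.index[j]!r}, "
                    f"column {df.columns[i]!r}: expected 0, 1 or {missing!r}"
                )
    return ResponseMatrix(
        y=y, mask=mask, person_ids=list(df.index), item_ids=list(df.columns)
    )


def write_response_matrix(rm: ResponseMatrix, path, delimiter=",", missing="NA") -> None:
    """Write a response matrix as delimited text (round-trip stable)."""
    rm.to_frame(missing=missing).to_csv(path, sep=delimiter)
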
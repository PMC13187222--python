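"""Shared data container: the participants x items response matrix."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Group label for the higher-scoring (clinical-analog) group.
CASE = "case"
#: Group label for the comparison group.
COMPARISON = "comparison"


@dataclass
class ResponseMatrix:
    """Integer Likert ratings (1-7) for participants x items, with group labels.

    Attributes
    ----------
    values : ndarray of shape (n_participants, n_items)
        Integer ratings in 1..7.
    group : ndarray of str, shape (n_participants,)
        Per-participant label, ``"case"`` or ``"comparison"``.
    item_ids : list of str
        Ordered unique item identifiers, e.g. ``"IP38"``.
    participant_ids : list of str
        Ordered participant identifiers.
    """

    values: np.ndarray
    group: np.ndarray
    item_ids: list[str] = field(default_factory=list)
    participant_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.group = np.asarray(self.group, dtype=object)
        n, p = self.values.shape
        if not self.item_ids:
            self.item_ids = [f"IP{i + 1}" for i in range(p)]
        if not self.participant_ids:
            self.participant_ids = [f"P{i + 1}" for i in range(n)]
        if len(self.item_ids) != p:
            raise ValueError("item_ids length does not match number of columns")
        if len(set(self.item_ids)) != p:
            raise ValueError("item_ids must be unique")
        if len(self.group) != n:
            raise ValueError("group length does not match number of rows")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def column(self, item_id: str) -> np.ndarray:
        try:
            j = self.item_ids.index(item_id)
        except ValueError:
            raise KeyError(f"unknown item id: {item_id!r}") from None
        return self.values[:, j]

    def subset(self, item_ids: list[str]) -> "ResponseMatrix":
        """Return a new matrix restricted to ``item_ids`` (given order kept)."""
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(
            values=self.values[:, idx],
            group=self.group.copy(),
            item_ids=list(item_ids),
            participant_ids=list(self.participant_ids),
        )

    def group_mask(self, label: str = CASE) -> np.ndarray:
        return self.group == label

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.item_ids)
        df.insert(0, "group", self.group)
        df.insert(0, "participant_id", self.participant_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ResponseMatrix":
        df = pd.read_csv(path)
        required = {"participant_id", "group"}
        if not required <= set(df.columns):
            raise ValueError("response CSV needs participant_id and group columns")
        items = [c for c in df.columns if c not in required]
        return cls(
            values=df[items].to_numpy(dtype=int),
            group=df["group"].to_numpy(dtype=object),
            item_ids=items,
            participant_ids=df["participant_id"].astype(str).tolist(),
        )
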
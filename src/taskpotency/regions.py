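"""Atlas handling and region-level aggregation of edge scores."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class Atlas:
    """Ordered region records (index, name, network id) for an R-region parcellation."""

    names: list
    networks: list

    def __post_init__(self):
        if len(self.names) != len(self.networks):
            raise ValueError("names and networks differ in length")

    @property
    def n_regions(self) -> int:
        return len(self.names)

    @property
    def n_networks(self) -> int:
        return len(set(self.networks))

    @classmethod
    def synthetic(cls, n_regions: int, n_networks: int) -> "Atlas":
        """Even block assignment of regions to networks (remainder in the last)."""
        block = max(n_regions // n_networks, 1)
        nets = [min(i // block, n_networks - 1) + 1 for i in range(n_regions)]
        return cls([f"region{i}" for i in range(n_regions)], nets)

    @classmethod
    def from_tsv(cls, path) -> "Atlas":
        df = pd.read_csv(path, sep="\t")
        df = df.sort_values("index").reset_index(drop=True)
        if list(df["index"]) != list(range(len(df))):
            raise ValueError("atlas indices must be contiguous 0..R-1")
        return cls(list(df["name"]), list(df["network"]))

    def to_tsv(self, path) -> None:
        pd.DataFrame({"index": range(self.n_regions), "name": self.names,
                      "network": self.networks}).to_csv(path, sep="\t", index=False)


def region_scores(edge_values: np.ndarray, atlas) -> np.ndarray:
    """Per-region score: mean |value| over the R-1 edges incident to each region."""
    e = np.asarray(edge_values, dtype=float).ravel()
    r = atlas.n_regions if isinstance(atlas, Atlas) else int(atlas)
    expected = r * (r - 1) // 2
    if e.size != expected:
        raise ValueError(f"expected {expected} edges for R={r}, got {e.size}")
    iu, ju = np.triu_indices(r, k=1)
    acc = np.zeros(r)
    np.add.at(acc, iu, np.abs(e))
    np.add.at(acc, ju, np.abs(e))
    return acc / (r - 1)


def top_regions(scores: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Indices of the ceil(fraction*R) highest-scoring regions, descending.

    Ties are broken by ascending region index.
    """
    s = np.asarray(scores, dtype=float)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * s.size)
    # sort by (-score, index): stable mergesort on index order
    order = np.argsort(-s, kind="stable")
    return order[:k]
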
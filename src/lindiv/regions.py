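"""Region sets and per-node state-probability containers.

A :class:`RegionSet` fixes the ordered axis shared by every probability,
richness and diversity vector in the package.  The default coding follows
the biogeographic convention for the East Asian freshwater fauna:
Palearctic = I, Oriental = II, Nearctic = III, Japanese Archipelago = IV.

A :class:`StatePosterior` maps node ids to marginal probability vectors
over a :class:`RegionSet` (each vector sums to one).  It is the common
currency between ancestral state reconstruction and the lineage-diversity
stage, and round-trips through a sidecar TSV (one row per node, one column
per region).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = ["RegionSet", "StatePosterior", "DEFAULT_REGIONS"]


@dataclass(frozen=True)
class RegionSet:
    """Ordered, unique region labels with optional display names."""

    labels: tuple[str, ...]
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("a RegionSet needs at least two regions")
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate region labels: {labels}")
        if self.names is not None:
            names = tuple(str(x) for x in self.names)
            if len(names) != len(labels):
                raise ValueError("names must match labels in length")
            object.__setattr__(self, "names", names)

    @property
    def k(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"unknown region {label!r}; known regions: {self.labels}"
            ) from None

    def one_hot(self, label: str) -> np.ndarray:
        v = np.zeros(self.k)
        v[self.index(label)] = 1.0
        return v

    def display_name(self, label: str) -> str:
        if self.names is None:
            return label
        return self.names[self.index(label)]

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __len__(self) -> int:
        return self.k


#: Default coding: Palearctic=I, Oriental=II, Nearctic=III, Japanese Archipelago=IV.
DEFAULT_REGIONS = RegionSet(
    ("I", "II", "III", "IV"),
    ("Palearctic", "Oriental", "Nearctic", "Japanese Archipelago"),
)


class StatePosterior:
    """Per-node marginal probability vectors over a :class:`RegionSet`.

    Parameters
    ----------
    regions
        The region axis of every vector.
    probs
        Mapping from node id to a length-K array-like of probabilities.
    atol
        Tolerance on ``|sum - 1|``.  Vectors off by more than `atol` but no
        more than `hard_tol` are renormalized when ``renormalize=True``;
        beyond `hard_tol` construction always fails.
    """

    def __init__(
        self,
        regions: RegionSet,
        probs: Mapping[int, Iterable[float]],
        *,
        atol: float = 1e-9,
        renormalize: bool = False,
        hard_tol: float = 0.05,
    ) -> None:
        self.regions = regions
        clean: dict[int, np.ndarray] = {}
        for node, raw in probs.items():
            v = np.asarray(list(raw), dtype=float)
            if v.shape != (regions.k,):
                raise ValueError(
                    f"node {node}: expected {regions.k} probabilities, got shape {v.shape}"
                )
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise ValueError(f"node {node}: probabilities must be finite and >= 0")
            s = v.sum()
            if abs(s - 1.0) > hard_tol:
                raise ValueError(
                    f"node {node}: probability vector sums to {s:.6g}, "
                    f"off by more than {hard_tol} from 1"
                )
            if abs(s - 1.0) > atol:
                if not renormalize:
                    raise ValueError(
                        f"node {node}: probability vector sums to {s:.6g} "
                        f"(tolerance {atol}); pass renormalize=True to repair"
                    )
                v = v / s
            clean[int(node)] = v
        self._probs = clean

    # -- mapping-ish surface -------------------------------------------------
    def __getitem__(self, node: int) -> np.ndarray:
        return self._probs[node]

    def __contains__(self, node: int) -> bool:
        return node in self._probs

    def __len__(self) -> int:
        return len(self._probs)

    @property
    def nodes(self) -> list[int]:
        return sorted(self._probs)

    def items(self):
        return self._probs.items()

    def max_probability(self, node: int) -> float:
        return float(self._probs[node].max())

    def modal_region(self, node: int) -> str:
        return self.regions.labels[int(np.argmax(self._probs[node]))]

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"node": node, **dict(zip(self.regions.labels, v))}
            for node, v in sorted(self._probs.items())
        ]
        return pd.DataFrame(rows, columns=["node", *self.regions.labels])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        regions: RegionSet,
        *,
        renormalize: bool = True,
        atol: float = 1e-3,
        hard_tol: float = 0.05,
    ) -> "StatePosterior":
        missing = [r for r in regions.labels if r not in frame.columns]
        if missing:
            raise ValueError(f"node table lacks region columns {missing}")
        probs = {
            int(row["node"]): np.asarray([row[r] for r in regions.labels], dtype=float)
            for _, row in frame.iterrows()
        }
        return cls(regions, probs, atol=atol, renormalize=renormalize, hard_tol=hard_tol)

    @classmethod
    def from_tsv(cls, path, regions: RegionSet, **kwargs) -> "StatePosterior":
        return cls.from_frame(pd.read_csv(path, sep="\t"), regions, **kwargs)
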
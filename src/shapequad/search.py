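"""Filtered 3-D neighbour search: the end-to-end use of the filter cascade.

For every query x search conformer pair the stages run cheapest first:

1. volume-only ST upper bound from the self-overlap volumes,
2. the Qx -> Qy -> Qz quadrupole filter cascade (if filters are supplied),
3. full superposition optimisation for the survivors.

Per-stage removal counts are reported so the cost structure of a run is
visible; with sound filters the neighbour list is identical to an unfiltered
run while far fewer superpositions are optimised.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .filters import FilterSet
from .screen import apply_cascade
from .shape import Conformer, DescriptorConfig, build_gaussians, descriptors
from .superpose import optimize_superposition, st_volume_bound

__all__ = ["SearchStats", "neighbor_search"]


@dataclass(frozen=True)
class SearchStats:
    """Per-stage accounting of one neighbour-search run."""

    n_pairs: int
    removed_volume_bound: int
    removed_x: int
    removed_y: int
    removed_z: int
    n_superpositions: int
    n_neighbors: int

    @property
    def removed_total(self) -> int:
        return (
            self.removed_volume_bound
            + self.removed_x
            + self.removed_y
            + self.removed_z
        )

    def to_text(self) -> str:
        n = max(self.n_pairs, 1)
        rows = [
            ("Total conformer pairs", self.n_pairs, ""),
            ("ST volume bound", self.removed_volume_bound, f"{100 * self.removed_volume_bound / n:.1f}%"),
            ("Qx filter", self.removed_x, f"{100 * self.removed_x / n:.1f}%"),
            ("Qy filter", self.removed_y, f"{100 * self.removed_y / n:.1f}%"),
            ("Qz filter", self.removed_z, f"{100 * self.removed_z / n:.1f}%"),
            ("Superposition optimizations", self.n_superpositions, f"{100 * self.n_superpositions / n:.1f}%"),
            ("Neighbors found", self.n_neighbors, ""),
        ]
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {count:>10}  {pct:>7}" for name, count, pct in rows)


def neighbor_search(
    queries: list[Conformer],
    searches: list[Conformer],
    st_threshold: float = 0.80,
    filters: FilterSet | None = None,
    use_volume_bound: bool = True,
    config: DescriptorConfig | None = None,
    unknown_key_policy: str = "pass",
) -> tuple[pd.DataFrame, SearchStats]:
    """All-by-all neighbour search of queries against a search set.

    Returns (neighbors, stats): neighbours as a frame with columns
    id1 (query), id2 (search), st, v_ab for every pair with optimised
    ST >= ``st_threshold``, plus the stage accounting.
    """
    if config is None:
        config = DescriptorConfig()
    if filters is not None and filters.st_threshold > st_threshold:
        raise ValueError(
            "filters were built at a stricter ST threshold than the search; "
            "they would not be sound for this run"
        )

    def prep(conformers: list[Conformer]):
        out = []
        for c in conformers:
            g = build_gaussians(c, config.radii, config.amplitude, config.include_hydrogens)
            out.append((c.id, g, descriptors(c, config)))
        return out

    qs, ss = prep(queries), prep(searches)
    removed = {"volume_bound": 0, "x": 0, "y": 0, "z": 0}
    n_super = 0
    records = []
    for qid, gq, dq in qs:
        for sid, gs, ds in ss:
            if use_volume_bound and st_volume_bound(dq.v_so, ds.v_so) < st_threshold:
                removed["volume_bound"] += 1
                continue
            if filters is not None:
                verdict = apply_cascade(
                    filters, dq, ds, use_volume_bound=False,
                    unknown_key_policy=unknown_key_policy,
                )
                if not verdict.passed:
                    removed[verdict.rejected_by] += 1
                    continue
            n_super += 1
            res = optimize_superposition(gq, gs)
            if res.st >= st_threshold:
                records.append(
                    {"id1": qid, "id2": sid, "st": res.st, "v_ab": res.v_ab}
                )
    neighbors = pd.DataFrame(records, columns=["id1", "id2", "st", "v_ab"])
    stats = SearchStats(
        n_pairs=len(qs) * len(ss),
        removed_volume_bound=removed["volume_bound"],
        removed_x=removed["x"],
        removed_y=removed["y"],
        removed_z=removed["z"],
        n_superpositions=n_super,
        n_neighbors=len(neighbors),
    )
    return neighbors, stats
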
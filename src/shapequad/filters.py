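"""Construction of quadrupole shape-compatibility filters.

A quadrupole filter is a lookup table built from a corpus of known 3-D
neighbour pairs (conformer pairs with shape Tanimoto at or above a
threshold).  Volumes and quadrupole components are discretised into integer
bins; for every ordered pair of volume bins the filter stores the inclusive
range of binned quadrupole differences ever observed among neighbours.  A
candidate pair whose difference falls outside the stored range cannot — on
the evidence of the corpus — reach the ST threshold, and is rejected without
any superposition work.

Because the corpus is a finite sample, the raw observed map is additionally
"fringe filled": at each difference level, processed from the largest
magnitude downward and separately for the positive and negative branches,
gaps between the minimum and maximum populated volume bins of each row and
column are closed.  This protects sparsely sampled boundary regions of the
map from producing false rejections on unseen but plausible pairs.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

from .shape import ShapeDescriptors

__all__ = [
    "BinConfig",
    "BinnedDescriptors",
    "FilterSet",
    "QuadrupoleFilter",
    "RawDeltaMap",
    "accumulate",
    "bin_descriptors",
    "build_filter_set",
    "fill_map",
    "order_pair",
    "to_bin",
]

COMPONENTS = ("x", "y", "z")
VOLUME_TYPES = ("an", "mp", "so")

#: Default bin widths: 5.0 A^3 for every volume type; 2.5 / 0.5 / 0.1 for the
#: Qx / Qy / Qz components (matched to their dynamic ranges).
DEFAULT_Q_BINSIZES: Mapping[str, float] = {"x": 2.5, "y": 0.5, "z": 0.1}


@dataclass(frozen=True)
class BinConfig:
    """Discretisation and threshold settings shared by a filter set."""

    vol_binsize: float = 5.0
    q_binsizes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_Q_BINSIZES)
    )
    volume_type: str = "mp"
    st_threshold: float = 0.80

    def __post_init__(self) -> None:
        if self.vol_binsize <= 0:
            raise ValueError("volume bin size must be positive")
        if set(self.q_binsizes) != set(COMPONENTS):
            raise ValueError("q_binsizes must cover components x, y, z")
        if any(b <= 0 for b in self.q_binsizes.values()):
            raise ValueError("quadrupole bin sizes must be positive")
        if self.volume_type not in VOLUME_TYPES:
            raise ValueError(f"unknown volume type {self.volume_type!r}")
        if not (0.0 < self.st_threshold <= 1.0):
            raise ValueError("st_threshold must lie in (0, 1]")


@dataclass(frozen=True, order=False)
class BinnedDescriptors:
    """Integer-binned volume and quadrupole components of one conformer."""

    v_bin: int
    qx_bin: int
    qy_bin: int
    qz_bin: int

    def q_bin(self, component: str) -> int:
        return {"x": self.qx_bin, "y": self.qy_bin, "z": self.qz_bin}[component]

    @property
    def sort_key(self) -> tuple[int, int, int, int]:
        return (self.v_bin, self.qx_bin, self.qy_bin, self.qz_bin)


def to_bin(value: float, binsize: float) -> int:
    """Discretise a non-negative descriptor value: floor(value / binsize)."""
    if binsize <= 0:
        raise ValueError("binsize must be positive")
    if value < 0:
        raise ValueError(f"cannot bin negative descriptor value {value}")
    return int(math.floor(value / binsize))


def bin_descriptors(desc: ShapeDescriptors, cfg: BinConfig) -> BinnedDescriptors:
    return BinnedDescriptors(
        v_bin=to_bin(desc.volume(cfg.volume_type), cfg.vol_binsize),
        qx_bin=to_bin(desc.qx, cfg.q_binsizes["x"]),
        qy_bin=to_bin(desc.qy, cfg.q_binsizes["y"]),
        qz_bin=to_bin(desc.qz, cfg.q_binsizes["z"]),
    )


def order_pair(
    a: BinnedDescriptors, b: BinnedDescriptors
) -> tuple[BinnedDescriptors, BinnedDescriptors]:
    """Canonical pair ordering: molecule 1 has the smaller volume bin.

    Ties cascade through Qx, Qy and Qz bins (smaller value first); fully
    identical bins preserve the input order, so the ordering is stable.
    """
    if b.sort_key < a.sort_key:
        return b, a
    return a, b


@dataclass
class RawDeltaMap:
    """Observed binned quadrupole differences of a neighbour-pair corpus.

    Keys are canonically ordered volume-bin pairs (v1 <= v2); values count the
    occurrences of each signed difference Q_bin(mol2) - Q_bin(mol1).
    """

    component: str
    cfg: BinConfig
    counts: dict[tuple[int, int], Counter] = field(default_factory=dict)

    def add(self, v1_bin: int, v2_bin: int, dq_bin: int, n: int = 1) -> None:
        if v1_bin > v2_bin:
            raise ValueError(
                f"volume-bin key ({v1_bin}, {v2_bin}) violates canonical ordering"
            )
        self.counts.setdefault((v1_bin, v2_bin), Counter())[dq_bin] += n

    @property
    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())


def accumulate(
    pairs: Iterable[tuple[BinnedDescriptors, BinnedDescriptors]],
    component: str,
    cfg: BinConfig,
) -> RawDeltaMap:
    """Tally one quadrupole component's binned differences over neighbour pairs."""
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    raw = RawDeltaMap(component=component, cfg=cfg)
    for a, b in pairs:
        m1, m2 = order_pair(a, b)
        raw.add(m1.v_bin, m2.v_bin, m2.q_bin(component) - m1.q_bin(component))
    return raw


@dataclass(frozen=True)
class QuadrupoleFilter:
    """Allowed range of binned quadrupole differences per volume-bin pair."""

    component: str
    volume_type: str
    st_threshold: float
    cfg: BinConfig
    entries: dict[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        for key, (lo, hi) in self.entries.items():
            if key[0] > key[1]:
                raise ValueError(f"filter key {key} violates canonical ordering")
            if lo > hi:
                raise ValueError(f"empty range ({lo}, {hi}) at key {key}")

    def lookup(self, v1_bin: int, v2_bin: int) -> tuple[int, int] | None:
        return self.entries.get((v1_bin, v2_bin))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (k[0], k[1], lo, hi) for k, (lo, hi) in self.entries.items()
        )
        return pd.DataFrame(rows, columns=["v1bin", "v2bin", "dqmin", "dqmax"])


def _close_region(region: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Row/column gap closure to a fixed point.

    For every v1 all v2 between the populated extremes are added, and
    symmetrically for every v2; repeated until stable so the closure is
    idempotent.
    """
    region = set(region)
    while True:
        rows: dict[int, list[int]] = defaultdict(list)
        cols: dict[int, list[int]] = defaultdict(list)
        for v1, v2 in region:
            rows[v1].append(v2)
            cols[v2].append(v1)
        added = set()
        for v1, v2s in rows.items():
            for v2 in range(min(v2s), max(v2s) + 1):
                if (v1, v2) not in region:
                    added.add((v1, v2))
        for v2, v1s in cols.items():
            for v1 in range(min(v1s), max(v1s) + 1):
                if (v1, v2) not in region:
                    added.add((v1, v2))
        if not added:
            return region
        region |= added


def _fill_once(
    observed_values: Mapping[tuple[int, int], Iterable[int]]
) -> dict[tuple[int, int], tuple[int, int]]:
    """One level sweep of the fringe fill; returns per-key (min, max)."""
    lo: dict[tuple[int, int], int] = {}
    hi: dict[tuple[int, int], int] = {}
    for sign in (1, -1):
        observed: dict[int, set[tuple[int, int]]] = defaultdict(set)
        for key, dqs in observed_values.items():
            for dq in dqs:
                if (sign > 0 and dq >= 0) or (sign < 0 and dq <= 0):
                    observed[abs(dq)].add(key)
        if not observed:
            continue
        region: set[tuple[int, int]] = set()
        for level in sorted(observed, reverse=True):
            region |= observed[level]
            region = _close_region(region)
            dq = sign * level
            for key in region:
                if key not in lo or dq < lo[key]:
                    lo[key] = dq
                if key not in hi or dq > hi[key]:
                    hi[key] = dq
    return {key: (lo[key], hi[key]) for key in lo}


def fill_map(raw: RawDeltaMap) -> QuadrupoleFilter:
    """Turn an observed difference map into a fringe-filled filter.

    Unique difference magnitudes are processed from the maximum downward,
    separately for the non-negative and non-positive branches.  At each
    level the cumulative populated region (this level and all greater ones of
    the branch, including previously filled-in bins) is gap-closed row- and
    column-wise, and every bin of the closed region becomes allowed at that
    difference value.  The allowed set per key is collapsed to its inclusive
    (min, max) range, and the sweep is repeated on the collapsed ranges until
    nothing changes, so filling a filled map is a no-op.
    """
    if not raw.counts:
        raise ValueError("cannot fill an empty difference map")
    entries = _fill_once(raw.counts)
    while True:
        refined = _fill_once(
            {key: range(lo, hi + 1) for key, (lo, hi) in entries.items()}
        )
        if refined == entries:
            break
        entries = refined
    return QuadrupoleFilter(
        component=raw.component,
        volume_type=raw.cfg.volume_type,
        st_threshold=raw.cfg.st_threshold,
        cfg=raw.cfg,
        entries=entries,
    )


@dataclass(frozen=True)
class FilterSet:
    """The x, y, z quadrupole filters sharing a volume type and threshold."""

    fx: QuadrupoleFilter
    fy: QuadrupoleFilter
    fz: QuadrupoleFilter

    def __post_init__(self) -> None:
        members = (self.fx, self.fy, self.fz)
        if tuple(f.component for f in members) != COMPONENTS:
            raise ValueError("filter set members must be the x, y, z filters")
        if len({f.volume_type for f in members}) != 1:
            raise ValueError("filter set members disagree on volume type")
        if len({f.st_threshold for f in members}) != 1:
            raise ValueError("filter set members disagree on ST threshold")

    @property
    def cfg(self) -> BinConfig:
        return self.fx.cfg

    @property
    def volume_type(self) -> str:
        return self.fx.volume_type

    @property
    def st_threshold(self) -> float:
        return self.fx.st_threshold

    def member(self, component: str) -> QuadrupoleFilter:
        return {"x": self.fx, "y": self.fy, "z": self.fz}[component]


def build_filter_set(
    pairs: pd.DataFrame,
    desc_map: Mapping[str, ShapeDescriptors],
    cfg: BinConfig,
) -> FilterSet:
    """Build the three quadrupole filters from a labelled pair corpus.

    ``pairs`` needs columns id1, id2, st.  Only pairs with st >= the config
    threshold (the 3-D neighbours) contribute.
    """
    for col in ("id1", "id2", "st"):
        if col not in pairs.columns:
            raise ValueError(f"pair table lacks required column {col!r}")
    missing = sorted(
        {i for i in pd.concat([pairs["id1"], pairs["id2"]]) if i not in desc_map}
    )
    if missing:
        shown = ", ".join(map(str, missing[:10]))
        raise KeyError(f"descriptor table lacks {len(missing)} id(s): {shown}")
    neighbors = pairs[pairs["st"] >= cfg.st_threshold]
    if neighbors.empty:
        raise ValueError(
            f"no pairs at or above ST threshold {cfg.st_threshold}; cannot build filters"
        )
    binned = {
        i: bin_descriptors(desc_map[i], cfg)
        for i in pd.concat([neighbors["id1"], neighbors["id2"]]).unique()
    }
    pair_bins = [
        (binned[i1], binned[i2])
        for i1, i2 in zip(neighbors["id1"], neighbors["id2"])
    ]
    built = {
        comp: fill_map(accumulate(pair_bins, comp, cfg)) for comp in COMPONENTS
    }
    return FilterSet(fx=built["x"], fy=built["y"], fz=built["z"])
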
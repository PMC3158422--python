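"""Application of quadrupole filters and confusion-matrix evaluation.

Filters are applied singly or as the x -> y -> z cascade (optionally preceded
by the volume-only ST upper bound), short-circuiting at the first rejection.
Against a corpus of pairs labelled with their optimised shape Tanimoto, the
verdicts are tallied into a confusion matrix:

* TP — passed the filter and is a true neighbour (ST >= threshold),
* FP — passed but is not a neighbour (the pairs that still need superposing),
* FN — rejected despite being a neighbour (the loss the method must keep
  negligible; zero by construction on the training corpus),
* TN — rejected and not a neighbour (the filtering efficiency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .filters import (
    BinConfig,
    COMPONENTS,
    FilterSet,
    QuadrupoleFilter,
    bin_descriptors,
    build_filter_set,
    order_pair,
)
from .shape import ShapeDescriptors
from .superpose import st_volume_bound

__all__ = [
    "ConfusionMatrix",
    "FilterVerdict",
    "apply_cascade",
    "apply_single",
    "evaluate",
    "threshold_sweep",
]

UNKNOWN_KEY_POLICIES = ("pass", "reject")


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of screening one candidate pair."""

    passed: bool
    rejected_by: str | None  # None | "x" | "y" | "z" | "volume_bound"
    key_found: bool

    def __post_init__(self) -> None:
        if self.passed != (self.rejected_by is None):
            raise ValueError("passed must hold exactly when nothing rejected")


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN tally of filter verdicts against ST ground truth."""

    tp: int
    fp: int
    fn: int
    tn: int
    st_threshold: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def fraction(self, which: str) -> float:
        n = self.total
        return getattr(self, which) / n if n else 0.0

    def percentages(self) -> dict[str, float]:
        return {k: 100.0 * self.fraction(k) for k in ("tp", "fp", "fn", "tn")}

    @property
    def rejected_fraction(self) -> float:
        n = self.total
        return (self.tn + self.fn) / n if n else 0.0

    def to_text(self) -> str:
        pct = self.percentages()
        lines = [f"{'':10s}{'TP':>12s}{'FP':>12s}{'FN':>12s}{'TN':>12s}"]
        lines.append(
            f"{'count':10s}{self.tp:>12d}{self.fp:>12d}{self.fn:>12d}{self.tn:>12d}"
        )
        lines.append(
            f"{'percent':10s}"
            + "".join(f"{pct[k]:>11.1f}%" for k in ("tp", "fp", "fn", "tn"))
        )
        return "\n".join(lines)


def _check_policy(policy: str) -> None:
    if policy not in UNKNOWN_KEY_POLICIES:
        raise ValueError(f"unknown-key policy must be one of {UNKNOWN_KEY_POLICIES}")


def apply_single(
    f: QuadrupoleFilter,
    a: ShapeDescriptors,
    b: ShapeDescriptors,
    unknown_key_policy: str = "pass",
) -> FilterVerdict:
    """Screen one pair through a single quadrupole filter.

    Volume-bin keys the filter was never trained on follow the unknown-key
    policy; the default ("pass") only ever rejects pairs the corpus holds
    evidence against.
    """
    _check_policy(unknown_key_policy)
    ba = bin_descriptors(a, f.cfg)
    bb = bin_descriptors(b, f.cfg)
    m1, m2 = order_pair(ba, bb)
    rng = f.lookup(m1.v_bin, m2.v_bin)
    if rng is None:
        passed = unknown_key_policy == "pass"
        return FilterVerdict(
            passed=passed,
            rejected_by=None if passed else f.component,
            key_found=False,
        )
    dq = m2.q_bin(f.component) - m1.q_bin(f.component)
    ok = rng[0] <= dq <= rng[1]
    return FilterVerdict(
        passed=ok, rejected_by=None if ok else f.component, key_found=True
    )


def apply_cascade(
    fs: FilterSet,
    a: ShapeDescriptors,
    b: ShapeDescriptors,
    use_volume_bound: bool = False,
    unknown_key_policy: str = "pass",
) -> FilterVerdict:
    """Screen one pair through the filter cascade, short-circuiting.

    Order: optional self-overlap volume bound, then the x, y, z filters (the
    x filter is consistently the most efficient, so it runs first).
    """
    _check_policy(unknown_key_policy)
    if use_volume_bound:
        if st_volume_bound(a.v_so, b.v_so) < fs.st_threshold:
            return FilterVerdict(
                passed=False, rejected_by="volume_bound", key_found=True
            )
    key_found = True
    for comp in COMPONENTS:
        verdict = apply_single(fs.member(comp), a, b, unknown_key_policy)
        key_found = key_found and verdict.key_found
        if not verdict.passed:
            return FilterVerdict(
                passed=False, rejected_by=verdict.rejected_by, key_found=key_found
            )
    return FilterVerdict(passed=True, rejected_by=None, key_found=key_found)


def _tally(
    outcomes: list[tuple[bool, bool]], st_threshold: float
) -> ConfusionMatrix:
    tp = sum(1 for passed, pos in outcomes if passed and pos)
    fp = sum(1 for passed, pos in outcomes if passed and not pos)
    fn = sum(1 for passed, pos in outcomes if not passed and pos)
    tn = sum(1 for passed, pos in outcomes if not passed and not pos)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn, st_threshold=st_threshold)


def evaluate(
    fs: FilterSet,
    pairs: pd.DataFrame,
    desc_map: Mapping[str, ShapeDescriptors],
    st_threshold: float | None = None,
    use_volume_bound: bool = False,
    unknown_key_policy: str = "pass",
) -> dict[str, ConfusionMatrix]:
    """Confusion matrices of each single filter and of the cascade.

    ``pairs`` needs columns id1, id2, st; the ST labels are the ground truth.
    Returns matrices keyed "x", "y", "z" and "cascade".
    """
    if st_threshold is None:
        st_threshold = fs.st_threshold
    for col in ("id1", "id2", "st"):
        if col not in pairs.columns:
            raise ValueError(f"pair table lacks required column {col!r}")
    if pairs["st"].isna().any():
        raise ValueError("pair table contains missing ST labels")

    single: dict[str, list[tuple[bool, bool]]] = {c: [] for c in COMPONENTS}
    cascade: list[tuple[bool, bool]] = []
    for i1, i2, st in zip(pairs["id1"], pairs["id2"], pairs["st"]):
        a, b = desc_map[i1], desc_map[i2]
        positive = st >= st_threshold
        for comp in COMPONENTS:
            v = apply_single(fs.member(comp), a, b, unknown_key_policy)
            single[comp].append((v.passed, positive))
        v = apply_cascade(fs, a, b, use_volume_bound, unknown_key_policy)
        cascade.append((v.passed, positive))

    result = {c: _tally(single[c], st_threshold) for c in COMPONENTS}
    result["cascade"] = _tally(cascade, st_threshold)
    return result


def threshold_sweep(
    train_pairs: pd.DataFrame,
    test_pairs: pd.DataFrame,
    desc_map: Mapping[str, ShapeDescriptors],
    thresholds: list[float],
    cfg: BinConfig,
    unknown_key_policy: str = "pass",
) -> pd.DataFrame:
    """Filter efficiency as a function of the neighbouring ST threshold.

    For each threshold a filter set is rebuilt from the training pairs at or
    above it and evaluated on the test pairs at the same threshold.  Returns
    one row per (threshold, filter) with the rejected fraction and FN count;
    thresholds whose training restriction is empty are flagged, not fatal.
    """
    if any(not (0.0 < t <= 1.0) for t in thresholds):
        raise ValueError("thresholds must lie in (0, 1]")
    if sorted(thresholds) != list(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        t_cfg = BinConfig(
            vol_binsize=cfg.vol_binsize,
            q_binsizes=dict(cfg.q_binsizes),
            volume_type=cfg.volume_type,
            st_threshold=t,
        )
        try:
            fs = build_filter_set(train_pairs, desc_map, t_cfg)
        except ValueError:
            for name in (*COMPONENTS, "cascade"):
                rows.append(
                    {
                        "st_threshold": t,
                        "filter": name,
                        "rejected_fraction": float("nan"),
                        "fn": -1,
                        "n_pairs": len(test_pairs),
                        "empty_training": True,
                    }
                )
            continue
        matrices = evaluate(
            fs, test_pairs, desc_map, st_threshold=t,
            unknown_key_policy=unknown_key_policy,
        )
        for name, cm in matrices.items():
            rows.append(
                {
                    "st_threshold": t,
                    "filter": name,
                    "rejected_fraction": cm.rejected_fraction,
                    "fn": cm.fn,
                    "n_pairs": cm.total,
                    "empty_training": False,
                }
            )
    return pd.DataFrame(rows)
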
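"""Sliding-window shape prediction and methylation Δshape.

Given a query table, the shape profile of a sequence of length N assigns

* MGW/ProT at base pair ``i`` (0-based ``2 .. N-3``) from the pentamer
  centered at ``i`` — N − 4 defined values;
* Roll/HelT at step ``(i, i+1)`` from up to two pentamer windows: the
  step-3–4 slot of the pentamer centered at ``i`` and the step-2–3 slot of
  the pentamer centered at ``i+1``.  Interior steps average the two
  contributions (a documented policy; the two slots estimate the same
  physical step from shifted windows), the two boundary steps use the single
  available one — N − 3 defined step values.

All other entries are undefined (NaN), so profile axes align with input
coordinates.

Δshape is the elementwise difference between the profile of the methylated
sequence (queried against the methylation-aware table, mPQT) and of the
unmethylated sequence (queried against the standard table, PQT).  A sequence
with no methylation mark has Δshape ≡ 0 by definition.

For positions whose pentamer window covers only one base of a CpG
dinucleotide, the plain PQT term is confounded by a weak dependency of shape
on the base just outside the window (the mPQT key implies a following ``g``;
the PQT key averages over all four bases).  ``delta_mgw_context_matched``
removes the confound by taking the unmethylated term from a CpG-context
table (hexamers ending in CG / heptamers with CG flanks) so both terms share
the implied context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .alphabet import (
    AlphabetError,
    is_valid,
    methylate,
    reverse_complement,
    validate,
)
from .records import ShapeRecord
from .tableset import ContextTable, QueryTable, build_table

__all__ = [
    "ShapeProfile",
    "DeltaProfile",
    "shape_profile",
    "delta_shape",
    "delta_mgw_context_matched",
    "PentamerShapeModel",
    "ATRACT_3BP_SERIES",
    "ATRACT_4BP_SERIES",
    "collect_paired_mgw",
    "atract_analysis",
]

#: 3-bp A-tract pentamer series (A/T exchanged one at a time from the 3' end),
#: followed by a CpG step; MGW is read at the central base (offset 2).
ATRACT_3BP_SERIES = ("AAACG", "AATCG", "ATTCG", "TTTCG")
#: 4-bp A-tract hexamer series with the CpG step at positions 5-6; MGW is
#: read at position 3 of the hexamer (offset 2).
ATRACT_4BP_SERIES = ("AAAACG", "AAATCG", "AATTCG", "ATTTCG", "TTTTCG")


@dataclass
class ShapeProfile:
    """Per-position shape feature vectors; NaN marks undefined entries."""

    seq: str
    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray

    def feature(self, name: str) -> np.ndarray:
        return getattr(self, name.lower())

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with 1-based coordinates (step k = bp k,k+1)."""
        rows = []
        for name in ("MGW", "ProT"):
            arr = self.feature(name)
            rows += [(name, i + 1, v) for i, v in enumerate(arr)]
        for name in ("Roll", "HelT"):
            arr = self.feature(name)
            rows += [(name, i + 1, v) for i, v in enumerate(arr)]
        return pd.DataFrame(rows, columns=["feature", "position", "value"])


class DeltaProfile(ShapeProfile):
    """Δshape = methylated − unmethylated profile on the same axes."""


def _step_value(left: float, right: float, policy: str) -> float:
    have_l, have_r = np.isfinite(left), np.isfinite(right)
    if have_l and have_r:
        if policy == "mean":
            return 0.5 * (left + right)
        if policy == "left":
            return left
        if policy == "right":
            return right
        raise ValueError(f"unknown step policy {policy!r}")
    if have_l:
        return left
    if have_r:
        return right
    return float("nan")


def shape_profile(
    seq: str,
    table: QueryTable,
    step_policy: str = "mean",
    missing: str = "error",
) -> ShapeProfile:
    """Predict the four shape features of a fragment-valid sequence.

    ``step_policy`` selects how interior steps combine their two pentamer
    contributions: ``"mean"`` (default), ``"left"`` (step-3–4 slot of the
    left-centered window) or ``"right"``.
    """
    n = len(seq)
    if n < 5:
        raise AlphabetError(f"sequence shorter than 5 bp: {seq!r}")
    bad = validate(seq, "fragment")
    if bad:
        raise AlphabetError(
            f"invalid sequence {seq!r}: "
            + "; ".join(f"pos {v.position}: {v.message}" for v in bad)
        )
    mgw = np.full(n, np.nan)
    prot = np.full(n, np.nan)
    # per-window step slots, indexed by absolute step
    left = {"roll": np.full(n - 1, np.nan), "helt": np.full(n - 1, np.nan)}
    right = {"roll": np.full(n - 1, np.nan), "helt": np.full(n - 1, np.nan)}
    for c in range(2, n - 2):
        ft = table.query(seq[c - 2 : c + 3], missing=missing)
        mgw[c] = ft.mgw
        prot[c] = ft.prot
        right["roll"][c - 1] = ft.roll23
        right["helt"][c - 1] = ft.helt23
        left["roll"][c] = ft.roll34
        left["helt"][c] = ft.helt34
    roll = np.array(
        [_step_value(left["roll"][s], right["roll"][s], step_policy) for s in range(n - 1)]
    )
    helt = np.array(
        [_step_value(left["helt"][s], right["helt"][s], step_policy) for s in range(n - 1)]
    )
    return ShapeProfile(seq=seq, mgw=mgw, prot=prot, roll=roll, helt=helt)


def _zero_delta(n: int) -> DeltaProfile:
    mgw = np.full(n, np.nan)
    mgw[2 : n - 2] = 0.0
    roll = np.full(n - 1, np.nan)
    roll[1 : n - 2] = 0.0
    return DeltaProfile(seq="", mgw=mgw, prot=mgw.copy(), roll=roll, helt=roll.copy())


def delta_shape(
    seq: str,
    methylation: Union[str, Iterable[int]],
    pqt: QueryTable,
    mpqt: QueryTable,
    step_policy: str = "mean",
    missing: str = "error",
) -> DeltaProfile:
    """Effect of CpG methylation on the shape profile of ``seq``.

    ``seq`` is standard DNA; ``methylation`` is ``"all_cpg"`` or an iterable
    of 0-based CpG start positions.  Entries are defined where both parent
    profiles are defined; with no methylation mark the result is exactly
    zero.
    """
    mseq = methylate(seq, methylation)
    if mseq == seq:
        out = _zero_delta(len(seq))
        out.seq = seq
        return out
    pm = shape_profile(mseq, mpqt, step_policy=step_policy, missing=missing)
    pu = shape_profile(seq, pqt, step_policy=step_policy, missing=missing)
    return DeltaProfile(
        seq=mseq,
        mgw=pm.mgw - pu.mgw,
        prot=pm.prot - pu.prot,
        roll=pm.roll - pu.roll,
        helt=pm.helt - pu.helt,
    )


def delta_mgw_context_matched(
    seq: str,
    position: int,
    methyl_positions: Sequence[int],
    pqt: QueryTable,
    mpqt: QueryTable,
    hexamer_table: Optional[ContextTable] = None,
    heptamer_table: Optional[ContextTable] = None,
) -> float:
    """Context-matched ΔMGW at 0-based ``position`` of a standard sequence.

    When every methylated CpG overlapping the pentamer window lies fully
    inside it, this equals plain ``delta_shape`` MGW.  When a CpG
    contributes only one base to the window (its C at the last window
    position, or its G at the first), the unmethylated term is read from the
    matching CpG-context table — the hexamer-ending-in-CG table for a single
    partial CpG, the CG-flank heptamer table when both window ends touch a
    CpG — so the methylated (mPQT) and unmethylated terms share the implied
    out-of-window context.
    """
    n = len(seq)
    if not 2 <= position <= n - 3:
        raise ValueError(f"position {position} has no pentamer window in length {n}")
    mseq = methylate(seq, methyl_positions)
    mpent = mseq[position - 2 : position + 3]
    meth_val = mpqt.query(mpent).mgw

    lo, hi = position - 2, position + 2
    trailing = any(c == hi for c in methyl_positions)  # C at window pos 5
    leading = any(c + 1 == lo for c in methyl_positions)  # g at window pos 1

    if not trailing and not leading:
        return meth_val - pqt.query(seq[lo : hi + 1]).mgw
    if trailing and leading:
        if heptamer_table is None:
            raise ValueError("heptamer context table required for CG flanks on both sides")
        if lo - 1 < 0 or hi + 2 > n:
            raise ValueError("CpG context extends outside the sequence")
        return meth_val - heptamer_table.mgw_at(seq[lo - 1 : hi + 2], 3)
    if hexamer_table is None:
        raise ValueError("hexamer context table required for a partial CpG")
    if trailing:
        if hi + 2 > n:
            raise ValueError("CpG context extends outside the sequence")
        return meth_val - hexamer_table.mgw_at(seq[lo : hi + 2], 2)
    if lo - 1 < 0:
        raise ValueError("CpG context extends outside the sequence")
    return meth_val - hexamer_table.mgw_at(seq[lo - 1 : hi + 1], 3)


class PentamerShapeModel(TransformerMixin, BaseEstimator):
    """Sliding-window shape predictor learned from a shape-record pool.

    ``fit`` mines and averages a pool of :class:`~methylshape.records.ShapeRecord`
    into a query table (``table_``); ``transform`` maps sequences to
    :class:`ShapeProfile` objects.  Follows the scikit-learn estimator
    protocol (``get_params``/``set_params``; fitted state in trailing-
    underscore attributes), composing with sklearn pipelines whose X is a
    list of records / sequences.
    """

    def __init__(
        self,
        universe: Optional[Union[str, Sequence[str]]] = None,
        margin: int = 1,
        min_occurrences: int = 1,
        on_missing: str = "error",
        step_policy: str = "mean",
        missing_query: str = "error",
    ) -> None:
        self.universe = universe
        self.margin = margin
        self.min_occurrences = min_occurrences
        self.on_missing = on_missing
        self.step_policy = step_policy
        self.missing_query = missing_query

    def fit(self, X: Iterable[ShapeRecord], y=None) -> "PentamerShapeModel":
        self.table_ = build_table(
            X,
            universe=self.universe,
            margin=self.margin,
            min_occurrences=self.min_occurrences,
            on_missing=self.on_missing,
        )
        self.n_keys_ = len(self.table_)
        return self

    def transform(self, X: Iterable[str]) -> List[ShapeProfile]:
        if not hasattr(self, "table_"):
            raise RuntimeError("PentamerShapeModel is not fitted")
        return [
            shape_profile(
                seq,
                self.table_,
                step_policy=self.step_policy,
                missing=self.missing_query,
            )
            for seq in X
        ]


# ---------------------------------------------------------------------------
# A-tract MGW analysis
# ---------------------------------------------------------------------------


def collect_paired_mgw(
    unmeth_pool: Iterable[ShapeRecord],
    meth_pool: Iterable[ShapeRecord],
    context: str,
    center_offset: int = 2,
) -> Tuple[np.ndarray, np.ndarray]:
    """Paired per-occurrence MGW samples for one unmethylated k-mer context.

    Finds every occurrence of ``context`` (either strand) in the
    unmethylated pool, reads MGW at ``center_offset`` within the k-mer, and
    pairs it with the value at the same absolute position of the record with
    the same ``fragment_id`` in the methylated pool.  Returns
    ``(unmethylated, methylated)`` arrays.
    """
    k = len(context)
    rc_context = reverse_complement(context)
    meth_by_id: Dict[str, ShapeRecord] = {r.fragment_id: r for r in meth_pool}
    xs: List[float] = []
    ys: List[float] = []
    for rec in unmeth_pool:
        mate = meth_by_id.get(rec.fragment_id)
        if mate is None:
            continue
        for s in range(rec.length - k + 1):
            w = rec.seq[s : s + k]
            if w == context:
                p = s + center_offset
            elif w == rc_context:
                p = s + (k - 1 - center_offset)
            else:
                continue
            u, m = rec.mgw[p], mate.mgw[p]
            if np.isfinite(u) and np.isfinite(m):
                xs.append(u)
                ys.append(m)
    return np.array(xs), np.array(ys)


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def atract_analysis(
    paired: Dict[str, Tuple[np.ndarray, np.ndarray]],
    test: str = "wilcoxon",
) -> pd.DataFrame:
    """One-sided tests for methylation narrowing the minor groove.

    ``paired`` maps a context (e.g. ``"AAACG"``) to paired
    ``(unmethylated, methylated)`` MGW sample arrays.  The alternative
    hypothesis is narrowing (methylated < unmethylated), tested with the
    Wilcoxon signed-rank test (``test="wilcoxon"``, default for the 3-bp
    series) or the paired t test (``test="ttest"``, default for the 4-bp
    series).  Stars: * for 0.01 < P ≤ 0.05, ** for 0.001 < P ≤ 0.01,
    *** for P ≤ 0.001.
    """
    if test not in ("wilcoxon", "ttest"):
        raise ValueError(f"unknown test {test!r}")
    rows = []
    for context, (unmeth, meth) in paired.items():
        unmeth = np.asarray(unmeth, dtype=float)
        meth = np.asarray(meth, dtype=float)
        if unmeth.shape != meth.shape or unmeth.size < 2:
            raise ValueError(f"context {context!r}: need >= 2 paired samples")
        diff = meth - unmeth
        if np.allclose(diff, 0.0):
            p = 1.0
        elif test == "wilcoxon":
            p = float(
                stats.wilcoxon(meth, unmeth, alternative="less", zero_method="zsplit").pvalue
            )
        else:
            p = float(stats.ttest_rel(meth, unmeth, alternative="less").pvalue)
        rows.append(
            {
                "context": context,
                "n_pairs": unmeth.size,
                "mean_unmethylated": float(unmeth.mean()),
                "mean_methylated": float(meth.mean()),
                "delta_mgw": float(diff.mean()),
                "p_value": p,
                "stars": _stars(p),
            }
        )
    return pd.DataFrame(rows)
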
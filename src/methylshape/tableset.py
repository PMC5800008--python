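"""Pentamer Query Tables (PQT / mPQT) and CpG-context k-mer tables.

A query table maps each canonical pentamer to six shape values mined from a
pool of shape records with a sliding pentamer window:

* **MGW** and **ProT** assigned to the central base pair of the pentamer;
* **Roll** and **HelT** recorded twice, at window steps 2–3 and 3–4
  (1-based within the 5-bp window).

Tables are strand independent: every window is recorded once under its
canonical key, and when the canonical form is the reverse complement of the
observed window the two step slots are swapped (step 2–3 of a pentamer is
step 3–4 of its reverse complement).  MGW and ProT at the central base pair
read the same from either strand.

The assigned value for each slot is the arithmetic mean over *all* window
occurrences in the pool (occurrences are pooled, not averaged per fragment
first).

Context tables extend the pentamer logic for positions whose pentamer window
contains only one base of a CpG dinucleotide: a table keyed on hexamers
ending in CG (pattern ``NNNNCG``) and one keyed on heptamers with CG on both
flanks (``CGNNNCG``) store per-position MGW/ProT means restricted to
occurrences whose flanking context matches — capturing the dependency on the
position just outside the pentamer window that a pentamer table averages
away.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np

from .alphabet import (
    AlphabetError,
    canonical,
    canonical_key,
    enumerate_pentamers,
    is_valid,
    reverse_complement,
)
from .records import ShapeRecord

__all__ = [
    "FeatureTuple",
    "QueryTable",
    "ContextTable",
    "MissingKeyError",
    "mine_occurrences",
    "build_table",
    "build_context_table",
    "write_table",
    "read_table",
    "write_context_table",
    "read_context_table",
    "HEXAMER_CG",
    "HEPTAMER_CG_FLANKS",
]

#: slot order used everywhere a six-vector of pentamer features appears
SLOTS = ("MGW", "ProT", "Roll23", "Roll34", "HelT23", "HelT34")
_SWAP = np.array([0, 1, 3, 2, 5, 4])  # step-slot swap under reverse complement

HEXAMER_CG = "NNNNCG"
HEPTAMER_CG_FLANKS = "CGNNNCG"


class MissingKeyError(KeyError):
    """Query for a pentamer/k-mer absent from the table."""


class FeatureTuple(NamedTuple):
    """Six pentamer shape values plus the occurrence count behind them."""

    mgw: float
    prot: float
    roll23: float
    roll34: float
    helt23: float
    helt34: float
    n_occurrences: int

    @property
    def values(self) -> np.ndarray:
        return np.array(self[:6], dtype=float)


def mine_occurrences(
    records: Iterable[ShapeRecord], margin: int = 1
) -> Iterator[Tuple[str, np.ndarray]]:
    """Slide a pentamer window over each record and emit canonical samples.

    For a record of length N the window center runs over base pairs whose
    distance from either fragment end is at least ``2 + margin`` (0-based
    centers ``2 + margin .. N - 3 - margin``); the extra margin keeps
    fray-affected terminal values out of the averages.  Each emitted sample
    is ``(canonical key, [MGW, ProT, Roll23, Roll34, HelT23, HelT34])`` with
    the step slots swapped when the canonical form is the reverse complement
    of the observed window.  Windows with any non-finite slot are skipped.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    for rec in records:
        n = rec.length
        for c in range(2 + margin, n - 2 - margin):
            p = rec.seq[c - 2 : c + 3]
            vals = np.array(
                [
                    rec.mgw[c],
                    rec.prot[c],
                    rec.roll[c - 1],
                    rec.roll[c],
                    rec.helt[c - 1],
                    rec.helt[c],
                ]
            )
            if not np.all(np.isfinite(vals)):
                continue
            key, flipped = canonical(p)
            if flipped:
                vals = vals[_SWAP]
            yield key, vals


@dataclass
class QueryTable:
    """Canonical pentamer → mean shape features, with occurrence counts."""

    entries: Dict[str, np.ndarray] = field(default_factory=dict)
    counts: Dict[str, int] = field(default_factory=dict)
    meta: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._wildcard_cache: Dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pentamer: str) -> bool:
        return canonical(pentamer)[0] in self.entries

    def keys(self) -> List[str]:
        return sorted(self.entries)

    def query(self, pentamer: str, missing: str = "error") -> FeatureTuple:
        """Strand-independent lookup of a window-valid pentamer.

        When the canonical form is the reverse complement of the query, the
        (Roll23, Roll34) and (HelT23, HelT34) pairs are swapped before
        return; MGW and ProT are unchanged.  ``missing`` is ``"error"``
        (raise :class:`MissingKeyError`) or ``"na"`` (all-NaN tuple).
        """
        key, flipped = canonical_key(pentamer)
        vals = self.entries.get(key)
        if vals is None:
            if missing == "na":
                return FeatureTuple(*([float("nan")] * 6), 0)
            raise MissingKeyError(pentamer)
        if flipped:
            vals = vals[_SWAP]
        return FeatureTuple(*vals, self.counts.get(key, 0))

    def query_wildcard(self, pattern: str, missing: str = "error") -> FeatureTuple:
        """Unweighted mean of :meth:`query` over all expansions of ``N``.

        ``pattern`` is a length-5 string over {A,C,G,T,m,g,N}; each ``N``
        expands over the four standard bases.  Used to pad k-mer contexts
        whose flanks are unknown.
        """
        cached = self._wildcard_cache.get(pattern)
        if cached is not None:
            return FeatureTuple(*cached[:6], int(cached[6]))
        expansions = [""]
        for ch in pattern:
            opts = "ACGT" if ch == "N" else ch
            expansions = [e + o for e in expansions for o in opts]
        vals = np.zeros(6)
        n = 0
        for p in expansions:
            ft = self.query(p, missing=missing)
            vals += ft.values
            n += ft.n_occurrences
        vals /= len(expansions)
        self._wildcard_cache[pattern] = np.append(vals, n)
        return FeatureTuple(*vals, n)


def build_table(
    pool: Iterable[ShapeRecord],
    universe: Optional[Sequence[str]] = None,
    margin: int = 1,
    min_occurrences: int = 1,
    on_missing: str = "error",
) -> QueryTable:
    """Average mined occurrences into a query table.

    ``universe`` is an explicit canonical-key universe or one of the kinds
    accepted by :func:`~methylshape.alphabet.enumerate_pentamers`; keys of
    the universe with fewer than ``min_occurrences`` mined occurrences are a
    hard error by default (``on_missing="error"``) or recorded in
    ``table.meta["missing"]`` and left out (``on_missing="na"``).
    """
    pool = list(pool)
    if not pool:
        raise ValueError("empty record pool")
    sums: Dict[str, np.ndarray] = {}
    counts: Dict[str, int] = {}
    for key, vals in mine_occurrences(pool, margin=margin):
        acc = sums.get(key)
        if acc is None:
            sums[key] = vals.copy()
            counts[key] = 1
        else:
            acc += vals
            counts[key] += 1
    if not sums:
        raise ValueError("pool contributed zero occurrences")
    if isinstance(universe, str):
        universe = enumerate_pentamers(universe)
    table = QueryTable(meta={"margin": str(margin)})
    keys = universe if universe is not None else sorted(sums)
    if universe is not None and len(keys) == 0:
        raise ValueError("empty universe")
    missing = []
    for key in keys:
        n = counts.get(key, 0)
        if n < min_occurrences:
            missing.append(key)
            continue
        table.entries[key] = sums[key] / n
        table.counts[key] = n
    if missing:
        if on_missing == "error":
            raise MissingKeyError(
                f"{len(missing)} universe keys below {min_occurrences} occurrences "
                f"(first: {missing[:5]})"
            )
        table.meta["missing"] = ",".join(missing)
    return table


# ---------------------------------------------------------------------------
# context tables
# ---------------------------------------------------------------------------


def _matches(kmer: str, pattern: str) -> bool:
    return len(kmer) == len(pattern) and all(
        p == "N" or p == c for p, c in zip(pattern, kmer)
    )


@dataclass
class ContextTable:
    """k-mer context table of per-position MGW/ProT means.

    Keys are stored in *pattern orientation* (e.g. every hexamer key ends in
    ``CG``); a window whose reverse complement matches the pattern
    contributes with its positions mirrored.  ``mgw[key][j]`` is the mean
    MGW at k-mer position ``j`` (0-based), NaN where never mined.
    """

    pattern: str
    mgw: Dict[str, np.ndarray] = field(default_factory=dict)
    prot: Dict[str, np.ndarray] = field(default_factory=dict)
    counts: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.pattern)

    def __len__(self) -> int:
        return len(self.mgw)

    def _orient(self, kmer: str) -> Tuple[str, bool]:
        if _matches(kmer, self.pattern):
            return kmer, False
        rc = reverse_complement(kmer)
        if _matches(rc, self.pattern):
            return rc, True
        raise AlphabetError(
            f"{kmer!r} matches neither {self.pattern!r} nor its reverse complement"
        )

    def mgw_at(self, kmer: str, position: int) -> float:
        """Mean MGW at 0-based ``position`` of ``kmer`` (either strand)."""
        key, flipped = self._orient(kmer)
        if key not in self.mgw:
            raise MissingKeyError(kmer)
        j = self.k - 1 - position if flipped else position
        return float(self.mgw[key][j])

    def prot_at(self, kmer: str, position: int) -> float:
        key, flipped = self._orient(kmer)
        if key not in self.prot:
            raise MissingKeyError(kmer)
        j = self.k - 1 - position if flipped else position
        return float(self.prot[key][j])


def build_context_table(
    pool: Iterable[ShapeRecord],
    pattern: str = HEXAMER_CG,
    margin: int = 1,
) -> ContextTable:
    """Mine per-position MGW/ProT means for k-mers matching ``pattern``.

    The pool must be unmethylated (the table supplies the unmethylated side
    of context-matched ΔMGW estimates).  Both strands of every window are
    checked against the pattern; base-pair positions are mined under the
    same terminal margin rule as :func:`mine_occurrences`.
    """
    k = len(pattern)
    sums: Dict[str, np.ndarray] = {}
    sums_p: Dict[str, np.ndarray] = {}
    counts: Dict[str, np.ndarray] = {}
    for rec in pool:
        if any(c in "mg" for c in rec.seq):
            raise AlphabetError(
                f"record {rec.fragment_id!r}: context tables are mined from "
                "unmethylated pools"
            )
        n = rec.length
        lo, hi = 2 + margin, n - 3 - margin  # minable base-pair positions
        for s in range(0, n - k + 1):
            w = rec.seq[s : s + k]
            readings = []
            if _matches(w, pattern):
                readings.append((w, False))
            rc = reverse_complement(w)
            if rc != w and _matches(rc, pattern):
                readings.append((rc, True))
            for key, flipped in readings:
                if key not in sums:
                    sums[key] = np.zeros(k)
                    sums_p[key] = np.zeros(k)
                    counts[key] = np.zeros(k, dtype=int)
                for j in range(k):
                    p = s + j
                    if p < lo or p > hi or not np.isfinite(rec.mgw[p]):
                        continue
                    jj = k - 1 - j if flipped else j
                    sums[key][jj] += rec.mgw[p]
                    sums_p[key][jj] += rec.prot[p]
                    counts[key][jj] += 1
    table = ContextTable(pattern=pattern)
    for key, cnt in counts.items():
        with np.errstate(invalid="ignore"):
            table.mgw[key] = np.where(cnt > 0, sums[key] / np.maximum(cnt, 1), np.nan)
            table.prot[key] = np.where(cnt > 0, sums_p[key] / np.maximum(cnt, 1), np.nan)
        table.counts[key] = cnt
    return table


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_table(table: QueryTable, path, precision: int = 2) -> None:
    """Serialize a query table as tab-separated text.

    One row per canonical key: key, MGW, ProT, Roll23, Roll34, HelT23,
    HelT34, n; missing values as ``NA``; fixed decimal precision (default 2,
    the style of published pentamer shape tables).
    """
    with open(path, "w") as fh:
        fh.write("pentamer\t" + "\t".join(SLOTS) + "\tn\n")
        for key in table.keys():
            vals = table.entries[key]
            cells = [
                "NA" if not np.isfinite(v) else f"{v:.{precision}f}" for v in vals
            ]
            fh.write(key + "\t" + "\t".join(cells) + f"\t{table.counts.get(key, 0)}\n")


def write_context_table(table: ContextTable, path, precision: int = 2) -> None:
    """Serialize a context table: pattern header, then per-key rows with
    semicolon-joined per-position MGW, ProT and count lists."""
    with open(path, "w") as fh:
        fh.write(f"#pattern\t{table.pattern}\n")
        fh.write("kmer\tMGW\tProT\tn\n")
        for key in sorted(table.mgw):
            mgw = ";".join(
                "NA" if not np.isfinite(v) else f"{v:.{precision}f}"
                for v in table.mgw[key]
            )
            prot = ";".join(
                "NA" if not np.isfinite(v) else f"{v:.{precision}f}"
                for v in table.prot[key]
            )
            n = ";".join(str(int(c)) for c in table.counts[key])
            fh.write(f"{key}\t{mgw}\t{prot}\t{n}\n")


def read_context_table(path) -> ContextTable:
    """Read a context table written by :func:`write_context_table`."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#pattern\t"):
            raise ValueError(f"{path}:1: missing pattern header")
        table = ContextTable(pattern=first.split("\t", 1)[1])
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["kmer", "MGW", "ProT", "n"]:
            raise ValueError(f"{path}:2: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            key = parts[0]
            if not _matches(key, table.pattern):
                raise ValueError(f"{path}:{lineno}: key {key!r} off-pattern")
            parse = lambda t: np.array(
                [np.nan if x == "NA" else float(x) for x in t.split(";")]
            )
            table.mgw[key] = parse(parts[1])
            table.prot[key] = parse(parts[2])
            table.counts[key] = np.array([int(x) for x in parts[3].split(";")])
    return table


def read_table(path) -> QueryTable:
    """Read a table written by :func:`write_table`; rejects non-canonical keys."""
    table = QueryTable()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["pentamer", *SLOTS, "n"]:
            raise ValueError(f"{path}:1: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns, got {len(parts)}")
            key = parts[0]
            try:
                canon, flipped = canonical_key(key)
            except AlphabetError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if flipped or canon != key:
                raise ValueError(f"{path}:{lineno}: non-canonical key {key!r}")
            try:
                vals = np.array(
                    [np.nan if t == "NA" else float(t) for t in parts[1:7]]
                )
                n = int(parts[7])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            table.entries[key] = vals
            table.counts[key] = n
    return table
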
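"""Shape-record pools: per-fragment, per-position feature values.

A :class:`ShapeRecord` carries, for one double-stranded DNA fragment, the
trajectory-averaged structural features of that fragment: minor groove width
(MGW, Å) and propeller twist (ProT, °) per base pair, and Roll / helix twist
(HelT, °) per base-pair step (step ``k`` sits between base pairs ``k`` and
``k+1``).  Terminal entries may be undefined (NaN) — fraying near fragment
ends makes them unreliable.

The on-disk pool format is a tab-separated text file with a header and one
row per fragment::

    fragment_id  sequence  mgw  prot  roll  helt

where the four feature columns are semicolon-joined decimal lists (``NA`` for
undefined).  ``.gz`` paths are read and written transparently.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from typing import IO, Iterable, List, Sequence, Union

import numpy as np

from .alphabet import AlphabetError, validate

__all__ = ["ShapeRecord", "read_pool", "write_pool"]

_COLUMNS = ("fragment_id", "sequence", "mgw", "prot", "roll", "helt")


@dataclass
class ShapeRecord:
    """Per-fragment shape feature arrays.

    ``mgw``/``prot`` have one entry per base pair (length N), ``roll``/``helt``
    one per step (length N−1).  NaN marks undefined terminal entries.
    """

    fragment_id: str
    seq: str
    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray

    def __post_init__(self) -> None:
        self.mgw = np.asarray(self.mgw, dtype=float)
        self.prot = np.asarray(self.prot, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        self.helt = np.asarray(self.helt, dtype=float)
        n = len(self.seq)
        bad = validate(self.seq, "fragment")
        if bad:
            raise AlphabetError(
                f"record {self.fragment_id!r}: invalid fragment sequence "
                + "; ".join(f"pos {v.position}: {v.message}" for v in bad)
            )
        for name, arr, want in (
            ("mgw", self.mgw, n),
            ("prot", self.prot, n),
            ("roll", self.roll, n - 1),
            ("helt", self.helt, n - 1),
        ):
            if arr.shape != (want,):
                raise ValueError(
                    f"record {self.fragment_id!r}: {name} has length "
                    f"{arr.shape[0] if arr.ndim == 1 else arr.shape}, expected {want}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)


def _open(path, mode: str) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, mode + "b"))  # type: ignore[arg-type]
    return open(path, mode)


def _fmt_list(values: np.ndarray, precision: int) -> str:
    return ";".join(
        "NA" if not np.isfinite(v) else f"{v:.{precision}f}" for v in values
    )


def _parse_list(text: str) -> np.ndarray:
    return np.array(
        [np.nan if tok == "NA" else float(tok) for tok in text.split(";")],
        dtype=float,
    )


def write_pool(records: Iterable[ShapeRecord], path, precision: int = 3) -> None:
    """Write a record pool as tab-separated text (gzip if path ends in .gz)."""
    with _open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    (
                        r.fragment_id,
                        r.seq,
                        _fmt_list(r.mgw, precision),
                        _fmt_list(r.prot, precision),
                        _fmt_list(r.roll, precision),
                        _fmt_list(r.helt, precision),
                    )
                )
                + "\n"
            )


def read_pool(path) -> List[ShapeRecord]:
    """Read a record pool written by :func:`write_pool`."""
    out: List[ShapeRecord] = []
    with _open(path, "r") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COLUMNS:
            raise ValueError(f"unexpected pool header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, got {len(parts)}")
            try:
                out.append(
                    ShapeRecord(
                        fragment_id=parts[0],
                        seq=parts[1],
                        mgw=_parse_list(parts[2]),
                        prot=_parse_list(parts[3]),
                        roll=_parse_list(parts[4]),
                        helt=_parse_list(parts[5]),
                    )
                )
            except (ValueError, AlphabetError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out
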
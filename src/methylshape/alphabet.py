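"""Expanded six-letter alphabet for CpG-methylated DNA.

DNA carrying symmetric CpG methylation is written over ``{A, C, G, T, m, g}``:
``m`` is 5-methylcytosine and ``g`` is the guanine base-paired with a 5mC on
the opposite strand.  Because mammalian CpG methylation is symmetric (both
cytosines of the CG/CG duplex step are methylated — partial methylation is not
modelled), ``m`` and ``g`` are not independent letters: they occur only as the
dinucleotide unit ``mg``.

Two validity modes exist:

* **fragment** — a complete double-stranded fragment: every ``m`` must be
  immediately followed by ``g`` and every ``g`` immediately preceded by ``m``.
* **window** — a k-mer cut out of a larger fragment: additionally permits a
  trailing ``m`` (the pairing ``g`` lies beyond the window) and a leading
  ``g`` (the pairing ``m`` lies before it).

Canonicalization picks, for each k-mer, the lexicographic minimum of the
k-mer and its reverse complement under the fixed letter order
``A < C < G < T < g < m``.  The order is arbitrary but must stay fixed:
serialized query tables key on canonical form.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, List, NamedTuple, Sequence, Tuple, Union
from itertools import product

__all__ = [
    "AlphabetError",
    "MethylationError",
    "Violation",
    "complement",
    "reverse_complement",
    "validate",
    "is_valid",
    "methylate",
    "demethylate",
    "cpg_positions",
    "canonical",
    "canonical_key",
    "count_cpg_steps",
    "enumerate_pentamers",
    "pentamer_windows",
]

LETTERS = "ACGTgm"
#: rank used for canonical ordering; fixed — table files depend on it
_RANK = {c: i for i, c in enumerate(LETTERS)}
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "m": "g", "g": "m"}


class AlphabetError(ValueError):
    """A symbol outside {A, C, G, T, m, g} or an invalid sequence."""


class MethylationError(ValueError):
    """A methylation request at a position that does not hold a CpG."""


class Violation(NamedTuple):
    """One grammar violation, at 0-based ``position``."""

    position: int
    message: str


def complement(base: str) -> str:
    """Watson–Crick complement over the expanded alphabet (A↔T, C↔G, m↔g)."""
    try:
        return _COMP[base]
    except KeyError:
        raise AlphabetError(f"unknown symbol {base!r}") from None


def reverse_complement(seq: str) -> str:
    """Reverse complement; maps a trailing ``m`` to a leading ``g`` and back."""
    try:
        return "".join(_COMP[c] for c in reversed(seq))
    except KeyError as exc:
        raise AlphabetError(f"unknown symbol {exc.args[0]!r} in {seq!r}") from None


def validate(seq: str, mode: str = "fragment") -> List[Violation]:
    """Check the CpG grammar; returns a list of violations (empty = valid).

    Parameters
    ----------
    seq : str
        Sequence over the expanded alphabet.
    mode : {"fragment", "window"}
        ``fragment`` requires full ``mg`` units; ``window`` additionally
        allows ``m`` at the last position and ``g`` at the first.
    """
    if mode not in ("fragment", "window"):
        raise ValueError(f"mode must be 'fragment' or 'window', got {mode!r}")
    out: List[Violation] = []
    n = len(seq)
    for i, ch in enumerate(seq):
        if ch not in _RANK:
            out.append(Violation(i, f"unknown symbol {ch!r}"))
            continue
        if ch == "m":
            if i == n - 1:
                if mode == "fragment":
                    out.append(Violation(i, "trailing 'm' without pairing 'g'"))
            elif seq[i + 1] != "g":
                out.append(Violation(i, "'m' not followed by 'g'"))
        elif ch == "g":
            if i == 0:
                if mode == "fragment":
                    out.append(Violation(i, "leading 'g' without pairing 'm'"))
            elif seq[i - 1] != "m":
                out.append(Violation(i, "'g' not preceded by 'm'"))
    return out


def is_valid(seq: str, mode: str = "fragment") -> bool:
    """True when :func:`validate` reports no violations."""
    return not validate(seq, mode)


def _require_valid(seq: str, mode: str) -> None:
    bad = validate(seq, mode)
    if bad:
        raise AlphabetError(
            f"invalid {mode}-mode sequence {seq!r}: "
            + "; ".join(f"pos {v.position}: {v.message}" for v in bad)
        )


def cpg_positions(seq: str) -> List[int]:
    """0-based start positions of every CG or mg dinucleotide."""
    return [
        i
        for i in range(len(seq) - 1)
        if seq[i : i + 2] in ("CG", "mg")
    ]


def methylate(seq: str, positions: Union[str, Iterable[int]] = "all_cpg") -> str:
    """Replace CpG dinucleotides by ``mg``.

    ``positions`` is ``"all_cpg"`` (every CG step) or an iterable of 0-based
    start positions each of which must hold ``CG``.  Positions already
    methylated (``mg``) are accepted and left as-is.
    """
    if positions == "all_cpg":
        pos = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
    else:
        pos = sorted(set(int(p) for p in positions))
    letters = list(seq)
    for i in pos:
        if i < 0 or i + 1 >= len(seq):
            raise MethylationError(f"position {i} out of range for length {len(seq)}")
        di = seq[i : i + 2]
        if di == "mg":
            continue
        if di != "CG":
            raise MethylationError(f"position {i} holds {di!r}, not a CpG")
        letters[i], letters[i + 1] = "m", "g"
    return "".join(letters)


def demethylate(seq: str) -> str:
    """Strip methylation marks: m → C, g → G."""
    return seq.replace("m", "C").replace("g", "G")


@lru_cache(maxsize=1 << 18)
def canonical(kmer: str) -> Tuple[str, bool]:
    """Canonical form of a k-mer and whether the reverse complement was chosen.

    The canonical form is the minimum of ``{kmer, revcomp(kmer)}`` under the
    fixed letter order A < C < G < T < g < m.  Ties (a k-mer equal to its own
    reverse complement, possible only at even length) return ``flipped=False``.
    """
    rc = reverse_complement(kmer)
    fwd = tuple(_RANK[c] for c in kmer)
    rev = tuple(_RANK[c] for c in rc)
    if rev < fwd:
        return rc, True
    return kmer, False


def canonical_key(pentamer: str) -> Tuple[str, bool]:
    """Canonical table key for a window-valid pentamer, with the flip flag."""
    if len(pentamer) != 5:
        raise AlphabetError(f"pentamer must have length 5, got {pentamer!r}")
    _require_valid(pentamer, "window")
    return canonical(pentamer)


def count_cpg_steps(pentamer: str) -> int:
    """Number of CG or mg steps in a window-valid pentamer."""
    _require_valid(pentamer, "window")
    return sum(
        1 for i in range(len(pentamer) - 1) if pentamer[i : i + 2] in ("CG", "mg")
    )


def _window_valid_strings(length: int, methylated: bool) -> List[str]:
    alphabet = LETTERS if methylated else "ACGT"
    out = []
    for tup in product(alphabet, repeat=length):
        s = "".join(tup)
        if methylated and not any(c in "mg" for c in s):
            continue
        if is_valid(s, "window"):
            out.append(s)
    return out


def enumerate_pentamers(kind: str = "all") -> List[str]:
    """Exhaustive, duplicate-free canonical pentamer universe, sorted.

    kind : {"unmethylated", "methylated_new", "all"}
        ``unmethylated`` — the 512 canonical ACGT pentamers;
        ``methylated_new`` — the 475 additional canonical window-valid
        pentamers carrying at least one m/g; ``all`` — their union (987).
    """
    if kind not in ("unmethylated", "methylated_new", "all"):
        raise ValueError(f"unknown kind {kind!r}")
    keys = set()
    if kind in ("unmethylated", "all"):
        for s in _window_valid_strings(5, methylated=False):
            keys.add(canonical(s)[0])
    if kind in ("methylated_new", "all"):
        for s in _window_valid_strings(5, methylated=True):
            keys.add(canonical(s)[0])
    return sorted(keys, key=lambda s: tuple(_RANK[c] for c in s))


def pentamer_windows(seq: str) -> List[Tuple[int, str]]:
    """All (0-based center, pentamer) windows of a sequence of length ≥ 5."""
    return [(c, seq[c - 2 : c + 3]) for c in range(2, len(seq) - 2)]
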
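"""Synthetic data with planted ground truth.

Real pentamer query tables are mined from all-atom Monte Carlo trajectories
of thousands of designed DNA fragments.  This module replaces that pipeline
with a statistical stand-in: a seeded :class:`TruthModel` plants a ground
truth for every canonical sequence context, fragment pools are designed to
cover the complete pentamer space, and per-record feature arrays are the
planted values plus i.i.d. Gaussian occurrence noise.  Every downstream
module can then be tested against the stored truth.

The truth is planted at the physically consistent level:

* per-base-pair features (MGW, ProT) are a function of the canonical
  **pentamer** centered on the base pair;
* step features (Roll, HelT) are a function of the canonical **tetramer**
  around the step — the context shared by the two pentamer windows that
  both report that step, so overlapping windows agree and a noise-free pool
  reproduces the planted table exactly.

Methylation effects default to the magnitudes reported for CpG methylation:
Roll +6° at the methylated (mg) step, ProT −5° at a base pair whose central
base carries the mark on either strand, HelT −2° at steps adjacent to an mg
step, and a small MGW shift in methylated windows.  An optional position-6
MGW interaction term (off by default) makes the unmethylated value at a
window depend weakly on the base just outside it, reproducing the confound
that CpG-context tables correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .alphabet import (
    canonical,
    demethylate,
    enumerate_pentamers,
    is_valid,
    methylate,
    reverse_complement,
)
from .records import ShapeRecord
from .tableset import QueryTable
from .affinity import featurize_kmers

__all__ = [
    "TruthModel",
    "FragmentDesign",
    "DEFAULT_FLANKS",
    "design_pool",
    "fragments_for_core",
    "simulate_records",
    "simulate_paired_records",
    "simulate_cleavage",
    "simulate_binding",
]

#: flank tetramers used in fragment design: CpG-free, A-terminated so no CG
#: step forms at the flank/core junctions
DEFAULT_FLANKS = ("ACCA", "AGGA", "ATTA", "AAGA")


def _window_valid_kmers(length: int) -> List[str]:
    out = []
    for tup in product("ACGTgm", repeat=length):
        s = "".join(tup)
        if is_valid(s, "window"):
            out.append(s)
    return out


@dataclass
class TruthModel:
    """Planted per-context shape truth plus methylation-effect parameters.

    Base values are drawn once, from ``seed``, on realistic scales
    (MGW ≈ 5.1 ± 0.35 Å, ProT ≈ −7 ± 2.5°, Roll ≈ −1 ± 3°,
    HelT ≈ 34.5 ± 1.5°); methylated contexts are the demethylated base value
    plus the configured effect.  Methylation effects are context dependent:
    each methylated context adds a seeded Gaussian jitter of sd
    ``effect_sd`` (scaled down ×0.2 for MGW) around the nominal shift, so
    e.g. Roll shifts spread around +6° rather than being one constant.
    ``sigma`` is the per-occurrence Gaussian noise used by
    :func:`simulate_records`.
    """

    seed: int = 0
    roll_shift: float = 6.0
    prot_shift: float = -5.0
    helt_shift: float = -2.0
    mgw_shift: float = -0.3
    effect_sd: float = 0.5
    pos6_mgw: float = 0.0
    sigma: float = 0.5
    pentamer_mgw: Dict[str, float] = field(default_factory=dict, repr=False)
    pentamer_prot: Dict[str, float] = field(default_factory=dict, repr=False)
    tet_roll: Dict[str, float] = field(default_factory=dict, repr=False)
    tet_helt: Dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.pentamer_mgw:
            return
        rng = np.random.default_rng(self.seed)
        unmeth_pent = enumerate_pentamers("unmethylated")
        for p in unmeth_pent:
            self.pentamer_mgw[p] = float(rng.normal(5.1, 0.35))
            self.pentamer_prot[p] = float(rng.normal(-7.0, 2.5))
        for p in enumerate_pentamers("methylated_new"):
            base = canonical(demethylate(p))[0]
            mgw = self.pentamer_mgw[base]
            prot = self.pentamer_prot[base]
            if any(c in "mg" for c in p):
                mgw += self.mgw_shift + 0.2 * self.effect_sd * rng.standard_normal()
            if p[2] in "mg":
                prot += self.prot_shift + self.effect_sd * rng.standard_normal()
            self.pentamer_mgw[p] = mgw
            self.pentamer_prot[p] = prot
        unmeth_tet = sorted(
            {canonical(t)[0] for t in _window_valid_kmers(4) if "m" not in t and "g" not in t}
        )
        for t in unmeth_tet:
            self.tet_roll[t] = float(rng.normal(-1.0, 3.0))
            self.tet_helt[t] = float(rng.normal(34.5, 1.5))
        meth_tet = sorted(
            {canonical(t)[0] for t in _window_valid_kmers(4)} - set(unmeth_tet)
        )
        for t in meth_tet:
            base = canonical(demethylate(t))[0]
            roll = self.tet_roll[base]
            helt = self.tet_helt[base]
            if t[1:3] == "mg":
                roll += self.roll_shift + self.effect_sd * rng.standard_normal()
            if t[0:2] == "mg" or t[2:4] == "mg":
                helt += self.helt_shift + self.effect_sd * rng.standard_normal()
            self.tet_roll[t] = roll
            self.tet_helt[t] = helt

    # -- lookups (orientation-free: all four features are strand symmetric) --

    def bp_truth(self, pentamer: str) -> Tuple[float, float]:
        key = canonical(pentamer)[0]
        return self.pentamer_mgw[key], self.pentamer_prot[key]

    def step_truth(self, tetramer: str) -> Tuple[float, float]:
        key = canonical(tetramer)[0]
        return self.tet_roll[key], self.tet_helt[key]

    def feature_tuple(self, pentamer: str) -> np.ndarray:
        """[MGW, ProT, Roll23, Roll34, HelT23, HelT34] in the orientation of
        ``pentamer``."""
        mgw, prot = self.bp_truth(pentamer)
        r23, h23 = self.step_truth(pentamer[0:4])
        r34, h34 = self.step_truth(pentamer[1:5])
        return np.array([mgw, prot, r23, r34, h23, h34])

    def as_query_table(self, kind: str = "all") -> QueryTable:
        """Noise-free query table holding the planted truth (synthetic)."""
        table = QueryTable(meta={"source": "synthetic-truth", "seed": str(self.seed)})
        for key in enumerate_pentamers(kind):
            table.entries[key] = self.feature_tuple(key)
            table.counts[key] = 1
        return table


@dataclass(frozen=True)
class FragmentDesign:
    """One designed fragment: 4-bp left flank + core + reverse-complement
    right flank (13–24 bp total)."""

    design_id: str
    core: str
    left_flank: str

    @property
    def fragment(self) -> str:
        return self.left_flank + self.core + reverse_complement(self.left_flank)


def _core_for_key(key: str) -> str:
    core = key
    if core[0] == "g":
        core = "m" + core
    if core[-1] == "m":
        core = core + "g"
    return core


def _minable_keys(seq: str, margin: int) -> List[str]:
    return [
        canonical(seq[c - 2 : c + 3])[0]
        for c in range(2 + margin, len(seq) - 2 - margin)
    ]


def design_pool(
    universe: Union[str, Sequence[str]] = "all",
    coverage: int = 1,
    flank_set: Sequence[str] = DEFAULT_FLANKS,
    margin: int = 1,
) -> List[FragmentDesign]:
    """Greedy fragment design covering every canonical pentamer ≥ ``coverage``
    times (counting minable windows under ``margin``).

    Keys are visited in canonical order; a key still short of coverage gets
    a fragment whose core embeds it (extended to a full ``mg`` unit when the
    key has a boundary mark), cycling through ``flank_set``.  Fragments
    added for one key also count toward every other pentamer they contain,
    so the pool is smaller than ``coverage × |universe|``.  Deterministic.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not flank_set:
        raise ValueError("flank_set must be nonempty")
    if isinstance(universe, str):
        keys = enumerate_pentamers(universe)
    else:
        keys = sorted({canonical(k)[0] for k in universe})
    if not keys:
        raise ValueError("empty universe")
    counts: Dict[str, int] = {k: 0 for k in keys}
    designs: List[FragmentDesign] = []
    for key in keys:
        added = 0
        while counts[key] < coverage:
            flank = flank_set[added % len(flank_set)]
            core = _core_for_key(key)
            design = FragmentDesign(
                design_id=f"d{len(designs):05d}_{key}", core=core, left_flank=flank
            )
            frag = design.fragment
            if not is_valid(frag, "fragment"):
                raise ValueError(f"designed fragment {frag!r} violates the CpG grammar")
            gained = _minable_keys(frag, margin)
            if key not in gained:
                raise ValueError(
                    f"fragment for {key!r} does not expose it to mining "
                    f"(margin {margin} too large?)"
                )
            for k in gained:
                if k in counts:
                    counts[k] += 1
            designs.append(design)
            added += 1
    return designs


def fragments_for_core(core: str, flank_set: Sequence[str] = DEFAULT_FLANKS):
    """One fragment per flank for a shared core (the classic design: four
    flank combinations around every designed core)."""
    return [
        FragmentDesign(design_id=f"{core}_{i}", core=core, left_flank=flank)
        for i, flank in enumerate(flank_set)
    ]


def _truth_arrays(truth: TruthModel, seq: str) -> Tuple[np.ndarray, ...]:
    n = len(seq)
    mgw = np.full(n, np.nan)
    prot = np.full(n, np.nan)
    roll = np.full(n - 1, np.nan)
    helt = np.full(n - 1, np.nan)
    for p in range(2, n - 2):
        m, pr = truth.bp_truth(seq[p - 2 : p + 3])
        if truth.pos6_mgw != 0.0:
            # weak dependency on the base just outside the window, stated
            # symmetrically so both strand readings agree
            if p + 3 < n and seq[p + 3] in "Gg":
                m += truth.pos6_mgw
            if p - 3 >= 0 and seq[p - 3] in "Cm":
                m += truth.pos6_mgw
        mgw[p] = m
        prot[p] = pr
    for s in range(1, n - 2):
        roll[s], helt[s] = truth.step_truth(seq[s - 1 : s + 3])
    return mgw, prot, roll, helt


def simulate_records(
    truth: TruthModel,
    designs: Sequence[FragmentDesign],
    n_occ: int = 1,
    sigma: Optional[float] = None,
    seed: int = 0,
    demethylated: bool = False,
) -> List[ShapeRecord]:
    """Emulate mined-trajectory records: planted truth + Gaussian noise.

    Each design yields ``n_occ`` replicate records (ids ``<design_id>:<r>``)
    with independent noise of standard deviation ``sigma`` (default: the
    truth model's).  ``demethylated=True`` strips the methylation marks from
    every fragment first (for paired methylated/unmethylated pools).
    """
    if sigma is None:
        sigma = truth.sigma
    rng = np.random.default_rng(seed)
    out: List[ShapeRecord] = []
    for design in designs:
        seq = demethylate(design.fragment) if demethylated else design.fragment
        mgw, prot, roll, helt = _truth_arrays(truth, seq)
        n = len(seq)
        for r in range(n_occ):
            if sigma > 0:
                noise_bp = rng.normal(0.0, sigma, size=(2, n))
                noise_st = rng.normal(0.0, sigma, size=(2, n - 1))
            else:
                noise_bp = np.zeros((2, n))
                noise_st = np.zeros((2, n - 1))
            out.append(
                ShapeRecord(
                    fragment_id=f"{design.design_id}:{r}",
                    seq=seq,
                    mgw=mgw + noise_bp[0],
                    prot=prot + noise_bp[1],
                    roll=roll + noise_st[0],
                    helt=helt + noise_st[1],
                )
            )
    return out


def simulate_paired_records(
    truth: TruthModel,
    designs: Sequence[FragmentDesign],
    n_occ: int = 1,
    sigma: Optional[float] = None,
    seed: int = 0,
) -> Tuple[List[ShapeRecord], List[ShapeRecord]]:
    """Matched (unmethylated, methylated) pools with shared fragment ids and
    independent noise streams."""
    unmeth = simulate_records(
        truth, designs, n_occ=n_occ, sigma=sigma, seed=seed, demethylated=True
    )
    meth = simulate_records(
        truth, designs, n_occ=n_occ, sigma=sigma, seed=seed + 1, demethylated=False
    )
    return unmeth, meth


def simulate_cleavage(
    weights: np.ndarray,
    hexamers: Sequence[str],
    pqt: QueryTable,
    mpqt: QueryTable,
    depth: int = 1_000_000,
    seed: int = 0,
    cpg_start: int = 3,
) -> pd.DataFrame:
    """Multinomial cleavage counts from a planted weight vector.

    Unmethylated counts are drawn with probabilities ∝ exp(−W·x(h)) over the
    hexamer set; methylated variants exist for hexamers carrying a CpG at
    0-based ``cpg_start`` and use methylation-shifted features from the
    mPQT.  Returns a frame with columns hexamer, variant, cpg_start, count.
    """
    weights = np.asarray(weights, dtype=float)
    rng = np.random.default_rng(seed)
    X_u = featurize_kmers(hexamers, pqt)
    E_u = X_u @ weights
    if not np.all(np.isfinite(E_u)):
        raise ValueError("non-finite planted energies")
    p_u = np.exp(-(E_u - E_u.max()))
    counts_u = rng.multinomial(depth, p_u / p_u.sum())
    rows = [
        {"hexamer": h, "variant": "unmethylated", "cpg_start": pd.NA, "count": c}
        for h, c in zip(hexamers, counts_u)
    ]
    meth_hex = [h for h in hexamers if h[cpg_start : cpg_start + 2] == "CG"]
    if meth_hex:
        X_m = featurize_kmers(
            [methylate(h, [cpg_start]) for h in meth_hex], mpqt
        )
        E_m = X_m @ weights
        if not np.all(np.isfinite(E_m)):
            raise ValueError("non-finite planted energies")
        p_m = np.exp(-(E_m - E_m.max()))
        counts_m = rng.multinomial(depth, p_m / p_m.sum())
        rows += [
            {"hexamer": h, "variant": "methylated", "cpg_start": cpg_start, "count": c}
            for h, c in zip(meth_hex, counts_m)
        ]
    return pd.DataFrame(rows, columns=["hexamer", "variant", "cpg_start", "count"])


def simulate_binding(
    effects: Dict[int, float],
    n_per_offset: int = 30,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_unaffected: int = 0,
) -> pd.DataFrame:
    """EpiSELEX-style relative-affinity records for 12-bp Pbx-Hox sites.

    ``effects`` maps a 1-based CpG offset (e.g. 6, 9, 10) to the planted
    ΔΔΔG/RT of methylation at that offset (positive = suppressed binding).
    Each simulated site contributes an unmethylated record and one
    methylated record per planted CpG; ``noise_sd`` is lognormal affinity
    noise.  Returns columns site, cpg_start, affinity.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pattern = "NTGAYNNAYNNN"
    iupac = {"N": "ACGT", "Y": "CT"}

    def draw_site(offset: Optional[int]) -> str:
        while True:
            site = "".join(
                rng.choice(list(iupac.get(p, p))) for p in pattern
            )
            if offset is not None:
                site = site[: offset - 1] + "CG" + site[offset + 1 :]
            if all(c in iupac.get(p, p) for c, p in zip(site, pattern)):
                return site

    for offset, dddg in sorted(effects.items()):
        for _ in range(n_per_offset):
            site = draw_site(offset)
            a_u = float(np.exp(rng.normal(0.0, noise_sd)))
            a_m = float(a_u * np.exp(-dddg + rng.normal(0.0, noise_sd)))
            rows.append({"site": site, "cpg_start": pd.NA, "affinity": a_u})
            rows.append({"site": site, "cpg_start": offset, "affinity": a_m})
    for _ in range(n_unaffected):
        site = draw_site(None)
        rows.append(
            {"site": site, "cpg_start": pd.NA, "affinity": float(np.exp(rng.normal(0, noise_sd)))}
        )
    df = pd.DataFrame(rows, columns=["site", "cpg_start", "affinity"])
    # distinct sites may repeat across draws; keep the first unmethylated
    # record per site so pairing stays unambiguous
    um = df["cpg_start"].isna()
    df = pd.concat(
        [df[um].drop_duplicates(subset="site", keep="first"), df[~um]],
        ignore_index=True,
    )
    return df
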
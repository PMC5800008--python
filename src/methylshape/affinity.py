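"""Shape-to-affinity modeling of DNase I cleavage and Pbx-Hox binding.

The DNase I side works on hexamer cleavage-count tables (3 bp on each side
of the phosphate cleavage site).  Counts are filtered (absolute cleavage
count ≥ 25 by default), converted to free energies ΔΔG/RT = −ln(c / c̄)
relative to a class reference c̄, and regressed on shape features of the
hexamer with an L1/L2-regularized linear model:

    minimize ‖y − Xw − b‖² + λ1‖w‖₁ + λ2‖w‖²

Because the model is affine, the predicted methylation-induced energy shift
is ΔΔΔĜ/RT = W·Δshape with no intercept — the Δshape vector produced by the
pentamer tables feeds the model directly.

The Pbx-Hox side compares relative binding affinities of methylated and
unmethylated 12-bp sites matching ``NTGAYNNAYNNN`` (Y = C/T):
ΔΔΔG/RT = −ln(affinity_methylated / affinity_unmethylated), grouped by the
offset of the methylated CpG within the site (6/7, 9/10, 10/11, other).
"""

from __future__ import annotations

import re
import warnings
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import KFold

from .alphabet import is_valid, methylate
from .tableset import QueryTable

__all__ = [
    "PBX_HOX_PATTERN",
    "filter_hexamers",
    "counts_to_energy",
    "feature_layout",
    "featurize_kmer",
    "featurize_kmers",
    "delta_features",
    "ShapeAffinityRegressor",
    "fit_affinity_model",
    "predict_dddG",
    "cross_validate_penalties",
    "classify_cpg_offset",
    "methylation_effect",
]

PBX_HOX_PATTERN = "NTGAYNNAYNNN"
_IUPAC = {"N": "ACGT", "Y": "CT", "A": "A", "C": "C", "G": "G", "T": "T"}

CLEAVAGE_COLUMNS = ("hexamer", "variant", "cpg_start", "count")


def filter_hexamers(table: pd.DataFrame, min_count: int = 25) -> pd.DataFrame:
    """Drop rows with cleavage count below ``min_count`` (per row, so the
    filter applies independently to methylated and unmethylated variants)."""
    if (table["count"] < 0).any():
        raise ValueError("cleavage counts must be non-negative")
    out = table[table["count"] >= min_count].reset_index(drop=True)
    if out.empty:
        warnings.warn("all rows fell below the count threshold", stacklevel=2)
    return out


def counts_to_energy(
    table: pd.DataFrame, reference: Union[str, None] = "mean"
) -> pd.DataFrame:
    """Infer ΔΔG/RT = −ln(count / c̄) per variant class.

    ``reference`` selects c̄ within each variant class: ``"mean"`` (default),
    ``"median"``, or a hexamer whose count serves as the reference.  Scale
    invariant: rescaling every count in a class leaves the energies
    unchanged up to the reference definition (exactly, for mean/median).
    """
    if (table["count"] <= 0).any():
        raise ValueError("counts must be positive after filtering")
    out = table.copy()
    energies = np.empty(len(out))
    for variant, idx in out.groupby("variant").groups.items():
        counts = out.loc[idx, "count"].to_numpy(dtype=float)
        if reference == "mean":
            ref = counts.mean()
        elif reference == "median":
            ref = float(np.median(counts))
        else:
            hit = out.loc[idx][out.loc[idx, "hexamer"] == reference]
            if hit.empty:
                raise ValueError(
                    f"reference hexamer {reference!r} absent from variant {variant!r}"
                )
            ref = float(hit["count"].iloc[0])
        energies[out.index.get_indexer(idx)] = -np.log(counts / ref)
    out["ddG"] = energies
    return out


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------


def feature_layout(k: int) -> List[Tuple[str, int]]:
    """Fixed (feature, offset) layout for a k-mer: k MGW, k ProT, k−1 Roll,
    k−1 HelT entries (22 for a hexamer)."""
    layout = [("MGW", i) for i in range(k)] + [("ProT", i) for i in range(k)]
    layout += [("Roll", i) for i in range(k - 1)] + [("HelT", i) for i in range(k - 1)]
    return layout


def featurize_kmer(kmer: str, table: QueryTable) -> np.ndarray:
    """Shape feature vector of a fragment-valid k-mer, wildcard-padded.

    Flanking context outside the k-mer is unknown, so pentamer windows
    reaching past the ends are queried as wildcard patterns averaging over
    all concrete flanks; every internal position and step therefore gets a
    value.  Interior steps average their two window contributions.
    """
    k = len(kmer)
    if k < 2:
        raise ValueError("k-mer too short to featurize")
    if not is_valid(kmer, "fragment"):
        raise ValueError(f"{kmer!r} is not fragment-valid")

    def window(center: int) -> Tuple[float, float, float, float, float, float]:
        lo, hi = center - 2, center + 3
        pattern = (
            "N" * max(0, -lo) + kmer[max(0, lo) : min(k, hi)] + "N" * max(0, hi - k)
        )
        return table.query_wildcard(pattern)

    per_bp = [window(i) for i in range(k)]
    mgw = [ft.mgw for ft in per_bp]
    prot = [ft.prot for ft in per_bp]
    roll = [0.5 * (per_bp[s].roll34 + per_bp[s + 1].roll23) for s in range(k - 1)]
    helt = [0.5 * (per_bp[s].helt34 + per_bp[s + 1].helt23) for s in range(k - 1)]
    return np.array(mgw + prot + roll + helt)


def featurize_kmers(kmers: Sequence[str], table: QueryTable) -> np.ndarray:
    """Feature matrix (one row per k-mer, fixed layout)."""
    return np.vstack([featurize_kmer(km, table) for km in kmers])


def delta_features(
    kmer: str,
    methyl_positions: Union[str, Iterable[int]],
    pqt: QueryTable,
    mpqt: QueryTable,
) -> np.ndarray:
    """Δshape feature vector: methylated (mPQT) − unmethylated (PQT)."""
    mk = methylate(kmer, methyl_positions)
    return featurize_kmer(mk, mpqt) - featurize_kmer(kmer, pqt)


def _select_features(model, names: Optional[Sequence[str]], layout_k: int):
    if names is None:
        return None
    layout = feature_layout(layout_k)
    return np.array([i for i, (f, _) in enumerate(layout) if f in names])


# ---------------------------------------------------------------------------
# elastic-net shape-to-affinity model
# ---------------------------------------------------------------------------


class ShapeAffinityRegressor(RegressorMixin, BaseEstimator):
    """L1/L2-regularized linear shape-to-affinity model.

    Minimizes ``‖y − Xw − b‖² + l1·‖w‖₁ + l2·‖w‖²``.  Features are
    standardized internally (penalties act on the standardized scale) and
    ``coef_`` is reported on the original scale; zero-variance columns are
    dropped with a warning and receive a zero coefficient.  With
    ``l1 == l2 == 0`` the fit is the exact least-squares solution; with
    ``l1 == 0`` the exact ridge solution; otherwise scikit-learn's cyclic
    coordinate descent.  Deterministic for fixed inputs.

    ``feature_names`` (optional) restricts the model to one feature class
    (e.g. a Roll-only submodel) given the k-mer layout of
    :func:`feature_layout`; excluded columns keep zero coefficients so the
    layout of ``coef_`` never changes.
    """

    def __init__(
        self,
        l1: float = 0.01,
        l2: float = 0.01,
        feature_names: Optional[Sequence[str]] = None,
        kmer_length: int = 6,
        max_iter: int = 100000,
        tol: float = 1e-8,
    ) -> None:
        self.l1 = l1
        self.l2 = l2
        self.feature_names = feature_names
        self.kmer_length = kmer_length
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y) -> "ShapeAffinityRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per response value")
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 observations")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("penalties must be non-negative")

        active = np.arange(p)
        sel = _select_features(self, self.feature_names, self.kmer_length)
        if sel is not None:
            active = sel
        sd_all = X.std(axis=0)
        dead = sd_all[active] == 0
        if dead.any():
            warnings.warn(
                f"dropping {int(dead.sum())} zero-variance feature(s)", stacklevel=2
            )
            active = active[~dead]
        if active.size == 0:
            raise ValueError("no usable features")

        mu = X[:, active].mean(axis=0)
        sd = X[:, active].std(axis=0)
        Xs = (X[:, active] - mu) / sd

        if self.l1 == 0:
            ybar = y.mean()
            yc = y - ybar
            if self.l2 == 0:
                w, *_ = np.linalg.lstsq(Xs, yc, rcond=None)
            else:
                A = Xs.T @ Xs + self.l2 * np.eye(active.size)
                w = linalg.solve(A, Xs.T @ yc, assume_a="pos")
            b = ybar
        else:
            # rescale to sklearn's objective (1/2n)‖r‖² + αρ‖w‖₁ + α(1−ρ)/2 ‖w‖²
            alpha = self.l1 / (2 * n) + self.l2 / n
            l1_ratio = (self.l1 / (2 * n)) / alpha
            en = ElasticNet(
                alpha=alpha,
                l1_ratio=l1_ratio,
                fit_intercept=True,
                max_iter=self.max_iter,
                tol=self.tol,
                selection="cyclic",
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                en.fit(Xs, y)
            w = en.coef_
            b = float(en.intercept_)

        coef = np.zeros(p)
        coef[active] = w / sd
        self.coef_ = coef
        self.intercept_ = float(b - np.sum(w * mu / sd))
        self.n_features_in_ = p
        self.active_features_ = active
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    def predict_delta(self, dX) -> np.ndarray:
        """Energy shift W·Δfeatures — no intercept (linearity of the model)."""
        dX = np.asarray(dX, dtype=float)
        if dX.shape[-1] != self.coef_.shape[0]:
            raise ValueError(
                f"layout mismatch: {dX.shape[-1]} features, model has "
                f"{self.coef_.shape[0]}"
            )
        return dX @ self.coef_

    def to_text(self) -> str:
        """Plain-text key=value serialization (layout versioned by k)."""
        lines = [f"kmer_length={self.kmer_length}", f"l1={self.l1}", f"l2={self.l2}"]
        lines.append(f"intercept={float(self.intercept_)!r}")
        for (feat, off), c in zip(feature_layout(self.kmer_length), self.coef_):
            lines.append(f"{feat}@{off}={float(c)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ShapeAffinityRegressor":
        fields = dict(
            line.split("=", 1) for line in text.strip().splitlines() if line.strip()
        )
        k = int(fields.pop("kmer_length"))
        model = cls(l1=float(fields.pop("l1")), l2=float(fields.pop("l2")), kmer_length=k)
        model.intercept_ = float(fields.pop("intercept"))
        layout = feature_layout(k)
        coef = np.zeros(len(layout))
        for i, (feat, off) in enumerate(layout):
            coef[i] = float(fields[f"{feat}@{off}"])
        model.coef_ = coef
        model.n_features_in_ = len(layout)
        return model


def fit_affinity_model(
    X, y, l1: float = 0.01, l2: float = 0.01, **kwargs
) -> ShapeAffinityRegressor:
    """Thin wrapper: fit a :class:`ShapeAffinityRegressor`."""
    return ShapeAffinityRegressor(l1=l1, l2=l2, **kwargs).fit(X, y)


def predict_dddG(model: ShapeAffinityRegressor, delta: np.ndarray) -> np.ndarray:
    """Predicted methylation-induced energy shift ΔΔΔĜ/RT = W·Δshape."""
    return model.predict_delta(delta)


def cross_validate_penalties(
    X,
    y,
    l1_grid: Sequence[float],
    l2_grid: Sequence[float],
    k: int = 5,
    seed: int = 0,
) -> Tuple[float, float]:
    """Seeded k-fold CV over a penalty grid; returns the (l1, l2) pair with
    the lowest mean held-out squared error."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(X))
    best = (float("inf"), l1_grid[0], l2_grid[0])
    for l1 in l1_grid:
        for l2 in l2_grid:
            errs = []
            for tr, te in folds:
                m = ShapeAffinityRegressor(l1=l1, l2=l2).fit(X[tr], y[tr])
                errs.append(np.mean((m.predict(X[te]) - y[te]) ** 2))
            score = float(np.mean(errs))
            if score < best[0]:
                best = (score, l1, l2)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Pbx-Hox comparator
# ---------------------------------------------------------------------------


def _site_matches(site: str, pattern: str = PBX_HOX_PATTERN) -> bool:
    return len(site) == len(pattern) and all(
        c in _IUPAC[p] for c, p in zip(site, pattern)
    )


def classify_cpg_offset(site: str, cpg_start: Optional[int] = None) -> str:
    """Offset class of a methylated CpG in a 12-bp Pbx-Hox site.

    ``site`` must match ``NTGAYNNAYNNN``; ``cpg_start`` is the 1-based
    position of the methylated C (the field's offset nomenclature: offset
    6/7 means C at 6, G at 7).  Returns ``"6/7"``, ``"9/10"``, ``"10/11"``,
    ``"other"``, or ``"none"`` when unmethylated.
    """
    if not _site_matches(site):
        raise ValueError(f"site {site!r} does not match {PBX_HOX_PATTERN}")
    if cpg_start is None or (isinstance(cpg_start, float) and np.isnan(cpg_start)):
        return "none"
    p = int(cpg_start)
    if not 1 <= p < len(site):
        raise ValueError(f"CpG start {p} out of range")
    if site[p - 1 : p + 1] != "CG":
        raise ValueError(f"positions {p}/{p + 1} of {site!r} hold "
                         f"{site[p - 1 : p + 1]!r}, not CpG")
    return f"{p}/{p + 1}" if p in (6, 9, 10) else "other"


def methylation_effect(records: pd.DataFrame) -> pd.DataFrame:
    """Per-pair methylation effect on binding free energy.

    ``records`` has columns ``site`` (12-mer), ``cpg_start`` (1-based
    methylated-C position, NA for the unmethylated measurement) and
    ``affinity`` (relative affinity, > 0).  Each methylated record is paired
    with the unmethylated record of the same site;
    ΔΔΔG/RT = −ln(affinity_methylated / affinity_unmethylated) — positive
    means methylation suppresses binding.  Returns one row per pair with the
    offset class attached.
    """
    if (records["affinity"] <= 0).any():
        raise ValueError("relative affinities must be positive")
    unmeth = records[records["cpg_start"].isna()]
    ref = unmeth.set_index("site")["affinity"]
    if ref.index.has_duplicates:
        raise ValueError("multiple unmethylated records for one site")
    rows = []
    for _, rec in records[records["cpg_start"].notna()].iterrows():
        site = rec["site"]
        if site not in ref.index:
            raise ValueError(f"no unmethylated partner for site {site!r}")
        dddg = -np.log(rec["affinity"] / ref.loc[site])
        rows.append(
            {
                "site": site,
                "cpg_start": int(rec["cpg_start"]),
                "offset_class": classify_cpg_offset(site, int(rec["cpg_start"])),
                "dddG": float(dddg),
            }
        )
    return pd.DataFrame(rows)
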
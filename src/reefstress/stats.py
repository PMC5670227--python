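"""Permutation-based community statistics.

From-scratch implementations of the multivariate and categorical tests
used to compare benthic community health between sites and times:
square-root transform, Bray-Curtis dissimilarity, one- and two-way
PERMANOVA with permutation p-values, Holm (sequential Bonferroni)
pairwise comparisons, covariance-matrix PCA, and Pearson chi-square.

Conventions
-----------
* Bray-Curtis is implemented as a dissimilarity in [0, 1]; a PERMANOVA on
  1 - similarity is identical either way.
* Two-way sums of squares use a sequential (Type-I) partition via the
  Gower-centered inner-product matrix and projection onto the nested
  design subspaces (factor A, then B given A, then the interaction).
* Significance uses unrestricted permutation of raw observations, all
  terms recomputed each permutation; p = (b + 1) / (m + 1) with ties in
  the F comparison counted as exceedances (conservative, p > 0 always).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AbundanceMatrix",
    "Chi2Result",
    "ContingencyTable",
    "DistanceMatrix",
    "PcaResult",
    "PermanovaResult",
    "TermResult",
    "bray_curtis",
    "chi_square",
    "holm_adjust",
    "pairwise_posthoc",
    "pca",
    "permanova_oneway",
    "permanova_twoway",
    "sqrt_transform",
]


class InputError(ValueError):
    pass


class StateError(RuntimeError):
    pass


@dataclass
class AbundanceMatrix:
    """Transect-by-class percent-abundance matrix with row metadata.

    ``data`` holds non-negative abundances (columns are genus-x-health or
    health classes); ``meta`` aligns row-wise with labels such as site,
    habitat and time; ``transform_state`` is ``"raw"`` or ``"sqrt"``.
    """

    data: pd.DataFrame
    meta: pd.DataFrame
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        if self.transform_state not in ("raw", "sqrt"):
            raise InputError(f"bad transform_state {self.transform_state!r}")
        if len(self.data) != len(self.meta):
            raise InputError("data and meta row counts differ")
        vals = self.data.to_numpy(dtype=float)
        if np.isnan(vals).all(axis=1).any():
            raise InputError("all-missing row in abundance matrix")
        if (vals < 0).any():
            raise InputError("abundance values must be non-negative")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @classmethod
    def from_wide_csv(
        cls, path, meta_cols=("site", "habitat", "time", "transect_id")
    ) -> "AbundanceMatrix":
        df = pd.read_csv(path)
        meta = [c for c in meta_cols if c in df.columns]
        return cls(data=df.drop(columns=meta), meta=df[meta].copy())


def sqrt_transform(m: AbundanceMatrix) -> AbundanceMatrix:
    """Element-wise square root; guards against double application."""
    if m.transform_state != "raw":
        raise StateError("matrix already square-root transformed")
    return AbundanceMatrix(
        data=np.sqrt(m.data), meta=m.meta.copy(), transform_state="sqrt"
    )


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    values: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InputError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InputError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise InputError("distance matrix diagonal must be zero")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, idx) -> "DistanceMatrix":
        idx = np.asarray(idx)
        return DistanceMatrix(
            values=self.values[np.ix_(idx, idx)],
            labels=[self.labels[i] for i in idx],
        )


def bray_curtis(m: AbundanceMatrix) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities between rows.

    ``d(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk)``; a pair of
    all-zero rows is defined to have distance 0 (with a warning).
    """
    if m.n_rows < 2:
        raise InputError("need at least two rows for a distance matrix")
    if m.transform_state == "raw":
        warnings.warn(
            "computing Bray-Curtis on untransformed abundances", stacklevel=2
        )
    x = m.data.to_numpy(dtype=float)
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    zero_pairs = den == 0
    if (zero_pairs & ~np.eye(len(x), dtype=bool)).any():
        warnings.warn(
            "pair(s) of all-zero rows: Bray-Curtis defined as 0", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(zero_pairs, 0.0, num / np.where(zero_pairs, 1.0, den))
    np.fill_diagonal(d, 0.0)
    labels = list(m.meta.index) if m.meta.index.is_unique else list(range(len(x)))
    return DistanceMatrix(values=d, labels=labels)


@dataclass
class TermResult:
    name: str
    df: int
    ss: float
    f: float | None
    p: float | None


@dataclass
class PermanovaResult:
    terms: list[TermResult]
    residual_df: int
    residual_ss: float
    total_df: int
    total_ss: float
    n_permutations: int
    seed: int | None
    permutation_scheme: str = "unrestricted_raw"

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t.name, t.df, t.ss, t.f, t.p) for t in self.terms
        ]
        rows.append(("Residual", self.residual_df, self.residual_ss, None, None))
        rows.append(("Total", self.total_df, self.total_ss, None, None))
        return pd.DataFrame(rows, columns=["term", "df", "ss", "F", "p"])


def _group_indices(groups) -> dict:
    groups = np.asarray(groups)
    return {g: np.flatnonzero(groups == g) for g in pd.unique(groups)}


def _oneway_ss(d2: np.ndarray, idx_by_group: dict) -> tuple[float, float]:
    n = d2.shape[0]
    ss_t = d2.sum() / (2.0 * n)
    ss_w = 0.0
    for idx in idx_by_group.values():
        ss_w += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss_t, ss_w


def permanova_oneway(
    d: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed=None,
    factor_name: str = "Group",
) -> PermanovaResult:
    """One-way PERMANOVA with permutation p-value.

    ``n_perm`` may be the string ``"exact"`` to enumerate every row
    permutation (only sensible for very small n); the exact p-value is
    then the fraction of all n! permutations with F >= F_observed.
    """
    groups = np.asarray(groups)
    n = d.n
    if len(groups) != n:
        raise InputError("group labels do not conform to the distance matrix")
    idx_by_group = _group_indices(groups)
    a = len(idx_by_group)
    if a < 2:
        raise InputError("need at least two groups")
    for g, idx in idx_by_group.items():
        if len(idx) < 2:
            raise InputError(f"group {g!r} has fewer than 2 members")
    d2 = d.values**2
    ss_t, ss_w = _oneway_ss(d2, idx_by_group)
    ss_a = ss_t - ss_w
    df_a, df_w = a - 1, n - a
    f_obs = (ss_a / df_a) / (ss_w / df_w)

    sizes = {g: len(idx) for g, idx in idx_by_group.items()}

    def f_of(perm: np.ndarray) -> float:
        start = 0
        ssw = 0.0
        for g in idx_by_group:  # contiguous blocks of the permuted order
            ng = sizes[g]
            idx = perm[start : start + ng]
            ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * ng)
            start += ng
        ssa = ss_t - ssw
        return (ssa / df_a) / (ssw / df_w)

    if n_perm == "exact":
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            if f_of(np.asarray(perm)) >= f_obs - 1e-12:
                count += 1
            total += 1
        p = count / total
        n_used = total
    else:
        if n_perm < 1:
            raise InputError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        order = np.concatenate([idx_by_group[g] for g in idx_by_group])
        count = 0
        for _ in range(n_perm):
            if f_of(rng.permutation(order)) >= f_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm

    return PermanovaResult(
        terms=[TermResult(factor_name, df_a, ss_a, f_obs, p)],
        residual_df=df_w,
        residual_ss=ss_w,
        total_df=n - 1,
        total_ss=ss_t,
        n_permutations=n_used,
        seed=seed if isinstance(seed, int) else None,
    )


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # projection onto the column space; pinv handles rank deficiency
    return x @ np.linalg.pinv(x)


def _dummies(labels) -> np.ndarray:
    labels = pd.Series(np.asarray(labels))
    return pd.get_dummies(labels, drop_first=True, dtype=float).to_numpy()


def permanova_twoway(
    d: DistanceMatrix,
    factor_a,
    factor_b,
    n_perm: int = 9999,
    seed=None,
    names: tuple[str, str] = ("A", "B"),
) -> PermanovaResult:
    """Two-way crossed PERMANOVA with sequential (Type-I) partition.

    Sums of squares come from the Gower-centered matrix ``G`` built from
    the squared dissimilarities, with each term's SS the trace of ``G``
    projected onto the increment of the nested design subspaces
    (A, then B|A, then AxB|A,B). Pseudo-F uses the residual mean square.
    p-values come from unrestricted permutation of the raw observations,
    recomputing every term per permutation.
    """
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    n = d.n
    if len(fa) != n or len(fb) != n:
        raise InputError("factor labels do not conform to the distance matrix")
    levels_a = pd.unique(fa)
    levels_b = pd.unique(fb)
    a, b = len(levels_a), len(levels_b)
    if a >= 2 and b >= 2:
        cells = pd.crosstab(pd.Series(fa), pd.Series(fb))
        if (cells.to_numpy() == 0).any():
            empty = [
                (ra, cb)
                for ra in cells.index
                for cb in cells.columns
                if cells.loc[ra, cb] == 0
            ]
            raise InputError(f"empty design cell(s): {empty}")

    xa = _dummies(fa)
    xb = _dummies(fb)
    inter = pd.Series(fa).astype(str) + "::" + pd.Series(fb).astype(str)
    ones = np.ones((n, 1))
    x1 = ones
    x2 = np.hstack([ones, xa])
    x3 = np.hstack([ones, xa, xb])
    # full model spans cell means; equivalent to adding A:B dummies
    x4 = np.hstack([ones, _dummies(inter)])

    df_a = a - 1
    df_b = b - 1
    n_cells = inter.nunique()
    df_ab = n_cells - 1 - df_a - df_b
    df_res = n - n_cells
    if df_res < 1:
        raise InputError("no residual degrees of freedom (cells need >= 2 members)")
    if df_ab < 0:
        raise InputError("aliased factors: interaction df negative")

    h1, h2, h3, h4 = _hat(x1), _hat(x2), _hat(x3), _hat(x4)
    pa = h2 - h1
    pb = h3 - h2
    pab = h4 - h3
    pres = np.eye(n) - h4
    ptot = np.eye(n) - h1

    g = _gower_center(d.values)

    def partition(gmat: np.ndarray):
        ss_a = float(np.sum(pa * gmat))  # tr(P G) for symmetric P, G
        ss_b = float(np.sum(pb * gmat))
        ss_ab = float(np.sum(pab * gmat))
        ss_res = float(np.sum(pres * gmat))
        return ss_a, ss_b, ss_ab, ss_res

    ss_a, ss_b, ss_ab, ss_res = partition(g)
    ss_tot = float(np.sum(ptot * g))
    ms_res = ss_res / df_res

    def f_stats(sss):
        sa, sb, sab, sr = sss
        mr = sr / df_res
        f_a = (sa / df_a) / mr if df_a > 0 else None
        f_b = (sb / df_b) / mr if df_b > 0 else None
        f_ab = (sab / df_ab) / mr if df_ab > 0 else None
        return f_a, f_b, f_ab

    f_a, f_b, f_ab = f_stats((ss_a, ss_b, ss_ab, ss_res))

    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    counts = [0, 0, 0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        fp = f_stats(partition(gp))
        for k, (fo, fpk) in enumerate(zip((f_a, f_b, f_ab), fp)):
            if fo is not None and fpk is not None and fpk >= fo - 1e-12:
                counts[k] += 1
    pvals = [
        (c + 1) / (n_perm + 1) if fo is not None else None
        for c, fo in zip(counts, (f_a, f_b, f_ab))
    ]

    terms = [
        TermResult(names[0], df_a, ss_a, f_a, pvals[0]),
        TermResult(names[1], df_b, ss_b, f_b, pvals[1]),
        TermResult(f"{names[0]}x{names[1]}", df_ab, ss_ab, f_ab, pvals[2]),
    ]
    return PermanovaResult(
        terms=terms,
        residual_df=df_res,
        residual_ss=ss_res,
        total_df=n - 1,
        total_ss=ss_tot,
        n_permutations=n_perm,
        seed=seed if isinstance(seed, int) else None,
    )


def holm_adjust(pvals) -> np.ndarray:
    """Holm sequential-Bonferroni adjustment (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[i]))
        adj[i] = running
    return adj


def pairwise_posthoc(
    d: DistanceMatrix,
    groups,
    n_perm: int = 9999,
    seed=None,
) -> pd.DataFrame:
    """One-way PERMANOVA per group pair with Holm-adjusted p-values."""
    groups = np.asarray(groups)
    idx_by_group = _group_indices(groups)
    if len(idx_by_group) < 2:
        raise InputError("need at least two groups")
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    pairs = list(itertools.combinations(idx_by_group, 2))
    child_seeds = ss.spawn(len(pairs))
    rows = []
    for (g1, g2), child in zip(pairs, child_seeds):
        idx = np.concatenate([idx_by_group[g1], idx_by_group[g2]])
        sub = d.submatrix(idx)
        res = permanova_oneway(
            sub, groups[idx], n_perm=n_perm, seed=np.random.default_rng(child)
        )
        t = res.terms[0]
        rows.append((g1, g2, t.df, t.f, t.p))
    out = pd.DataFrame(
        rows, columns=["group1", "group2", "df", "F", "p_raw"]
    )
    out["p_adjusted"] = holm_adjust(out["p_raw"].to_numpy())
    out.attrs["n_permutations"] = n_perm
    out.attrs["seed"] = seed
    return out


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_ratio: np.ndarray


def pca(m: AbundanceMatrix) -> PcaResult:
    """PCA on the column variance-covariance matrix.

    Scores are the centered data projected on the eigenvectors; the sign
    of each component is fixed so its largest-|loading| entry is positive.
    """
    if m.transform_state != "sqrt":
        warnings.warn("PCA on untransformed abundances", stacklevel=2)
    x = m.data.to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise InputError("need at least 3 rows for PCA")
    xc = x - x.mean(axis=0)
    cov = (xc.T @ xc) / (x.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval.max(initial=0.0) <= 1e-12:
        raise InputError("rank-0 data: all rows identical")
    eigval = np.clip(eigval, 0.0, None)
    # sign convention: dominant loading positive per component
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = xc @ eigvec
    comps = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    return PcaResult(
        eigenvalues=eigval,
        scores=pd.DataFrame(scores, index=m.data.index, columns=comps),
        loadings=pd.DataFrame(eigvec, index=m.data.columns, columns=comps),
        variance_ratio=eigval / eigval.sum(),
    )


@dataclass
class ContingencyTable:
    """Non-negative integer counts with row/column labels."""

    counts: np.ndarray
    row_labels: list
    col_labels: list

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise InputError("contingency table needs >= 2 rows and columns")
        if (c < 0).any():
            raise InputError("counts must be non-negative")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.allclose(c, np.round(c)):
                raise InputError("counts must be integers")
            c = np.round(c).astype(int)
        if c.sum() == 0:
            raise InputError("grand total must be positive")
        self.counts = c

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContingencyTable":
        return cls(
            counts=df.to_numpy(),
            row_labels=list(df.index),
            col_labels=list(df.columns),
        )


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p: float
    expected: np.ndarray
    correction: str = "none"


def chi_square(t: ContingencyTable, correction: str = "none") -> Chi2Result:
    """Pearson chi-square test of independence.

    ``correction='yates'`` applies the continuity correction
    (|O - E| reduced by 0.5, floored at zero). Zero row/column margins
    are rejected with a message naming the margin.
    """
    if correction not in ("none", "yates"):
        raise InputError(f"unknown correction {correction!r}")
    obs = t.counts.astype(float)
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    for i, rt in enumerate(row_tot):
        if rt == 0:
            raise InputError(f"zero margin: row {t.row_labels[i]!r}")
    for j, ct in enumerate(col_tot):
        if ct == 0:
            raise InputError(f"zero margin: column {t.col_labels[j]!r}")
    grand = obs.sum()
    expected = np.outer(row_tot, col_tot) / grand
    dev = np.abs(obs - expected)
    if correction == "yates":
        dev = np.clip(dev - 0.5, 0.0, None)
    stat = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return Chi2Result(
        statistic=stat, df=df, p=p, expected=expected, correction=correction
    )
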
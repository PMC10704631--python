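"""Shared statistical machinery.

Paired Wilcoxon signed-rank tests, Storey q-values (with Benjamini-Hochberg
fallback for small families), Fisher's exact test, Bray-Curtis dissimilarity,
classical principal coordinate analysis and marginal-term PERMANOVA with
omega-squared effect sizes.

Distance matrices are carried around as :class:`DistanceMatrix`, a thin
labelled wrapper over a dense symmetric numpy array with TSV round-trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import UnivariateSpline

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "wilcoxon_signed_rank_paired",
    "qvalues",
    "fisher_exact_2x2",
    "bray_curtis",
    "pcoa",
    "PcoaResult",
    "permanova_marginal",
]

_SYMMETRY_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Labelled dense symmetric distance matrix with zero diagonal."""

    labels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if self.data.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.data.shape} does not match {n} labels"
            )
        if not np.allclose(self.data, self.data.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.data)) > _SYMMETRY_TOL):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.data < -_SYMMETRY_TOL):
            raise ValueError("distances must be non-negative")
        # enforce exact symmetry / zero diagonal after validation
        self.data = (self.data + self.data.T) / 2.0
        np.fill_diagonal(self.data, 0.0)

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.data[i, j])

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.data[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def _wilcoxon_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided signed-rank p over all 2^n sign patterns.

    Works with midranks (ties) by doubling ranks to integers and convolving
    the sign-flip distribution; p = P(|W - E[W]| >= |w_obs - E[W]|).
    """
    ranks2 = np.rint(2 * ranks).astype(int)
    total2 = int(ranks2.sum())
    dist = np.zeros(total2 + 1)
    dist[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total2 + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    center = total2 / 2.0  # E[W] on the doubled scale
    dev2 = abs(2 * w_obs - center)
    w2_grid = np.arange(total2 + 1)
    return float(dist[np.abs(w2_grid - center) >= dev2 - 1e-9].sum())


def wilcoxon_signed_rank_paired(
    x: Iterable[float], y: Iterable[float], exact_max_n: int = 25
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped. When the number of non-zero differences is
    at most ``exact_max_n`` the exact null distribution over all 2^n sign
    patterns is used (midranks make this exact under ties as well); for
    larger n a normal approximation with continuity and tie correction.

    Returns ``(W, p_two_sided)`` where ``W`` is the positive-rank sum. With no
    non-zero differences the test is degenerate and ``p = 1``.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size == 0:
        raise ValueError("empty samples")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_pos, min(1.0, _wilcoxon_exact_p(ranks, w_pos))
    res = sps.wilcoxon(
        d, zero_method="wilcox", correction=True, method="approx"
    )
    return w_pos, float(res.pvalue)


def _storey_pi0(p: np.ndarray) -> float:
    lambdas = np.arange(0.05, 0.951, 0.05)
    m = p.size
    pi0_hat = np.array(
        [np.mean(p > lam) / (1.0 - lam) for lam in lambdas]
    )
    # cubic smoothing spline over the lambda grid, evaluated at the largest
    # lambda (same scheme as the reference pFDR implementation)
    spline = UnivariateSpline(lambdas, pi0_hat, k=3)
    pi0 = float(spline(lambdas[-1]))
    pi0 = min(pi0, 1.0)
    if pi0 <= 0:
        warnings.warn(
            "estimated pi0 <= 0; falling back to pi0 = 1 (BH)", stacklevel=2
        )
        pi0 = 1.0
    return pi0


def qvalues(pvals: Iterable[float], min_storey_m: int = 100) -> np.ndarray:
    """q-values for a family of p-values.

    Storey's procedure with spline-smoothed pi0 when the family has at least
    ``min_storey_m`` tests; for smaller families pi0 is fixed at 1, which is
    exactly Benjamini-Hochberg. Output is monotone non-decreasing in p and
    bounded by 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.array([], dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    pi0 = _storey_pi0(p) if m >= min_storey_m else 1.0
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns ``(odds_ratio, p)``. The two-sided p sums hypergeometric
    probabilities not exceeding that of the observed table. A zero margin
    gives p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_int = t.astype(int)
        if np.any(t_int != t) or np.any(t_int < 0):
            raise ValueError("table cells must be non-negative integers")
        t = t_int
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def bray_curtis(abundance: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between rows of a samples x features table.

    d(x, y) = 1 - 2 * sum(min(x, y)) / (sum(x) + sum(y)). A pair of all-zero
    rows has undefined dissimilarity; it is set to 0 with a warning.
    """
    x = abundance.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    n = x.shape[0]
    d = np.zeros((n, n), dtype=float)
    row_sums = x.sum(axis=1)
    for i in range(n):
        for j in range(i + 1, n):
            denom = row_sums[i] + row_sums[j]
            if denom == 0:
                warnings.warn(
                    "two all-zero rows: Bray-Curtis undefined, set to 0",
                    stacklevel=2,
                )
                d[i, j] = d[j, i] = 0.0
            else:
                shared = np.minimum(x[i], x[j]).sum()
                d[i, j] = d[j, i] = 1.0 - 2.0 * shared / denom
    return DistanceMatrix([str(l) for l in abundance.index], d)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # for retained (positive) axes


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> PcoaResult:
    """Classical principal coordinate analysis (Gower's method).

    The doubly-centered matrix of -0.5 * D^2 is eigendecomposed; axes are
    ordered by eigenvalue, negative-eigenvalue axes are dropped (but the
    eigenvalues are reported), and coordinates are scaled by sqrt(eigenvalue).
    """
    D = dm.data
    n = D.shape[0]
    B = -0.5 * D**2
    centering = np.eye(n) - np.ones((n, n)) / n
    B = centering @ B @ centering
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = np.abs(eigvals).max() if n else 1.0
    keep = eigvals > eps * max(scale, 1.0)
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    pos_sum = eigvals[keep].sum()
    prop = eigvals[keep] / pos_sum if pos_sum > 0 else np.zeros(keep.sum())
    cols = [f"PC{i + 1}" for i in range(int(keep.sum()))]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dm.labels, columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


@dataclass
class PermanovaResult:
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])


def _design_matrix(metadata: pd.DataFrame, terms: Sequence[str]):
    """Intercept + treatment-coded dummies for each factor term."""
    blocks = {"Intercept": np.ones((len(metadata), 1))}
    for term in terms:
        dummies = pd.get_dummies(
            metadata[term].astype("category"), drop_first=True
        ).to_numpy(dtype=float)
        blocks[term] = dummies
    return blocks


def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X)


def permanova_marginal(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    terms: Sequence[str] = ("Host", "Location"),
    n_perm: int = 999,
    rng: np.random.Generator | None = None,
) -> PermanovaResult:
    """Permutational MANOVA with marginal (type-III-style) term tests.

    Distances enter through the Gower-centered inner-product matrix G;
    each term's sum of squares is tr(H_full G) - tr(H_reduced G) where H are
    hat matrices of the full and term-deleted designs. p-values come from
    freely permuting sample labels; omega-squared is the bias-adjusted R2
    (SS_term - df_term * MS_resid) / (SS_total + MS_resid).
    """
    if rng is None:
        rng = np.random.default_rng()
    n = len(dm)
    if n < 4:
        raise ValueError("need at least 4 samples")
    meta = metadata.set_index(metadata["sample_id"].astype(str)).loc[dm.labels] \
        if "sample_id" in metadata.columns else metadata.loc[dm.labels]
    for term in terms:
        if term not in meta.columns:
            raise ValueError(f"metadata lacks term column {term!r}")
        if meta[term].isna().any():
            raise ValueError(f"term {term!r} has missing values")

    blocks = _design_matrix(meta, terms)
    X_full = np.hstack(list(blocks.values()))
    rank_full = np.linalg.matrix_rank(X_full)
    expected = sum(b.shape[1] for b in blocks.values())
    if rank_full < expected:
        raise ValueError(
            f"aliased (confounded) design over terms {list(terms)}: "
            f"rank {rank_full} < {expected} columns"
        )
    H_full = _hat(X_full)
    R_full = np.eye(n) - H_full
    df_resid = n - rank_full

    # Gower-centered inner-product matrix
    A = -0.5 * dm.data**2
    C = np.eye(n) - np.ones((n, n)) / n
    G = C @ A @ C

    ss_total = float(np.trace(G))
    ss_resid = float(np.sum(R_full * G))

    term_info = {}
    for term in terms:
        X_red = np.hstack([b for t, b in blocks.items() if t != term])
        H_red = _hat(X_red)
        A_term = H_full - H_red  # symmetric difference of projectors
        df_term = rank_full - np.linalg.matrix_rank(X_red)
        term_info[term] = (A_term, df_term)

    def f_stats(Gmat: np.ndarray) -> dict[str, float]:
        ss_res = float(np.sum(R_full * Gmat))
        ms_res = ss_res / df_resid
        out = {}
        for term, (A_term, df_term) in term_info.items():
            ss_t = float(np.sum(A_term * Gmat))
            out[term] = (ss_t / df_term) / ms_res if ms_res > 0 else np.inf
        return out

    f_obs = f_stats(G)
    exceed = {term: 1 for term in terms}  # +1: observed counts as a perm
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        f_perm = f_stats(Gp)
        for term in terms:
            if f_perm[term] >= f_obs[term]:
                exceed[term] += 1

    ms_resid = ss_resid / df_resid
    rows = []
    for term, (A_term, df_term) in term_info.items():
        ss_t = float(np.sum(A_term * G))
        omega2 = (ss_t - df_term * ms_resid) / (ss_total + ms_resid)
        rows.append(
            {
                "term": term,
                "df": df_term,
                "SS": ss_t,
                "F": f_obs[term],
                "R2": ss_t / ss_total,
                "omega2": omega2,
                "p": exceed[term] / (n_perm + 1),
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "SS": ss_resid,
            "F": np.nan,
            "R2": ss_resid / ss_total,
            "omega2": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "SS": ss_total,
            "F": np.nan,
            "R2": 1.0,
            "omega2": np.nan,
            "p": np.nan,
        }
    )
    table = pd.DataFrame(rows).set_index("term")
    return PermanovaResult(table=table)
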
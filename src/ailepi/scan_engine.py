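"""Two-locus epistatic model fits and marker scans.

Implements the two-locus linear model with marginal (additive, dominance)
and all four product interaction terms, 2D scans used to pick one marker
per chromosomal segment, one-dimensional additive scans, bootstrap-averaged
profiles, and max-statistic permutation thresholds at study-wide confidence.

Predictors are built from discretized calls by default (additive code
HH=+1, HL=0, LL=-1; dominance code HL=1, else 0); fixed effects are handled
upstream by residualization.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_strata import DEFAULT_MIN_STRATUM

TWO_LOCUS_TERMS = ("intercept", "a1", "d1", "a2", "d2", "aa", "ad", "da", "dd")

_ACODE = {"HH": 1.0, "HL": 0.0, "LL": -1.0, "NA": np.nan}
_DCODE = {"HH": 0.0, "HL": 1.0, "LL": 0.0, "NA": np.nan}

_EPS = 1e-12


@dataclass(frozen=True)
class TwoLocusFit:
    locus_a: str
    locus_b: str
    coefficients: dict[str, float]
    F_full_vs_marginal: float
    F_full_vs_null: float
    df_resid: int
    n: int
    aliased: tuple[str, ...] = ()


@dataclass
class ScanProfile:
    """Per-marker statistic profile, in the order markers were requested."""

    markers: list[str]
    statistic: np.ndarray
    flags: dict[str, str] = field(default_factory=dict)
    threshold: float | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker_id": self.markers, "statistic": self.statistic,
                             "flag": [self.flags.get(m, "") for m in self.markers]})

    def peak(self) -> str:
        return self.markers[int(np.argmax(self.statistic))]


@dataclass(frozen=True)
class PermutationThreshold:
    threshold: float
    maxima: np.ndarray
    alpha: float
    n_perm: int


def additive_code(calls) -> np.ndarray:
    return np.vectorize(_ACODE.get, otypes=[float])(np.asarray(calls))


def dominance_code(calls) -> np.ndarray:
    return np.vectorize(_DCODE.get, otypes=[float])(np.asarray(calls))


def _safe_f(num_ss: float, num_df: int, den_ss: float, den_df: int) -> float:
    """F ratio with 0/0 -> 0 and x/0 -> inf conventions."""
    if num_df <= 0 or den_df <= 0:
        return 0.0
    num = max(num_ss, 0.0) / num_df
    den = max(den_ss, 0.0) / den_df
    if num <= _EPS:
        return 0.0
    if den <= _EPS:
        return np.inf
    return num / den


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), int(rank)


def fit_two_locus(y: pd.Series, locus_a: str, locus_b: str, calls: pd.DataFrame,
                  min_n: int = DEFAULT_MIN_STRATUM) -> TwoLocusFit:
    """Fit the full two-locus epistatic model and nested F-tests.

    The full model regresses the residual phenotype on a1, d1, a2, d2 and
    the four products aa, ad, da, dd.  ``F_full_vs_marginal`` tests the four
    interaction terms jointly; ``F_full_vs_null`` tests all genetic terms
    against an intercept-only model.  Rank-deficient designs (e.g. an
    unobserved genotype class) are fitted with the pseudo-inverse and the
    aliased columns are flagged.
    """
    sub = pd.DataFrame({"y": y, "ga": calls[locus_a], "gb": calls[locus_b]}).dropna()
    sub = sub[(sub["ga"] != "NA") & (sub["gb"] != "NA")]
    n = len(sub)
    if n < min_n:
        raise ValueError(f"only {n} complete observations at {locus_a} x {locus_b} "
                         f"(minimum {min_n})")
    a1, d1 = additive_code(sub["ga"]), dominance_code(sub["ga"])
    a2, d2 = additive_code(sub["gb"]), dominance_code(sub["gb"])
    X = np.column_stack([np.ones(n), a1, d1, a2, d2,
                         a1 * a2, a1 * d2, d1 * a2, d1 * d2])
    yv = sub["y"].to_numpy(dtype=float)

    beta, _, rank_f, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    rss_f = float(resid @ resid)

    aliased: tuple[str, ...] = ()
    if rank_f < X.shape[1]:
        # columns whose QR diagonal collapses are aliased with earlier ones
        r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        tol = max(X.shape) * np.finfo(float).eps * (r_diag.max() if r_diag.size else 1.0)
        aliased = tuple(t for t, d in zip(TWO_LOCUS_TERMS, r_diag) if d < tol)

    rss_m, rank_m = _rss(X[:, :5], yv)
    rss_0 = float(np.sum((yv - yv.mean()) ** 2))

    f_fvm = _safe_f(rss_m - rss_f, rank_f - rank_m, rss_f, n - rank_f)
    f_fv0 = _safe_f(rss_0 - rss_f, rank_f - 1, rss_f, n - rank_f)
    coefs = dict(zip(TWO_LOCUS_TERMS, (float(b) for b in beta)))
    return TwoLocusFit(locus_a=locus_a, locus_b=locus_b, coefficients=coefs,
                       F_full_vs_marginal=f_fvm, F_full_vs_null=f_fv0,
                       df_resid=n - rank_f, n=n, aliased=aliased)


def scan_2d(y: pd.Series, calls: pd.DataFrame, marker_map: pd.DataFrame,
            min_n: int = DEFAULT_MIN_STRATUM) -> pd.DataFrame:
    """Select, per segment, the marker with the strongest interaction support.

    Fits the two-locus model for every between-segment marker pair; each
    marker's score is its largest ``F_full_vs_marginal`` over all pairings
    and each segment contributes the marker with the highest score.  Ties
    break toward the lower marker index.  Returns a DataFrame with columns
    ``segment, marker_id, score``.
    """
    mm = marker_map.sort_values(["segment", "marker"], kind="stable")
    segments = list(dict.fromkeys(marker_map["segment"]))
    if len(segments) < 2:
        raise ValueError("scan_2d needs at least 2 segments")
    seg_markers = {s: mm.loc[mm["segment"] == s, "marker_id"].tolist() for s in segments}

    score: dict[str, float] = {m: -np.inf for m in mm["marker_id"]}
    for sa, sb in itertools.combinations(segments, 2):
        for ma in seg_markers[sa]:
            for mb in seg_markers[sb]:
                f = fit_two_locus(y, ma, mb, calls, min_n=min_n).F_full_vs_marginal
                if f > score[ma]:
                    score[ma] = f
                if f > score[mb]:
                    score[mb] = f

    rows = []
    for seg in segments:
        best, best_score = None, -np.inf
        for m in seg_markers[seg]:  # map order => lowest index wins ties
            if score[m] > best_score:
                best, best_score = m, score[m]
        rows.append({"segment": seg, "marker_id": best, "score": best_score})
    return pd.DataFrame(rows)


def _additive_f_matrix(yv: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-column additive F statistics (simple regression).

    Returns (F, monomorphic_mask).  F = (n-2) r^2 / (1-r^2); monomorphic
    columns get F = 0.
    """
    n = len(yv)
    yc = yv - yv.mean()
    syy = float(yc @ yc)
    Ac = A - A.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Ac, Ac)
    mono = sxx <= _EPS
    sxy = Ac.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(mono | (syy <= _EPS), 0.0, sxy ** 2 / np.maximum(sxx * syy, _EPS))
        r2 = np.clip(r2, 0.0, 1.0)
        F = np.where(r2 >= 1.0, np.inf, (n - 2) * r2 / (1.0 - r2))
    return F, mono


def scan_1d(y: pd.Series, markers, calls: pd.DataFrame) -> ScanProfile:
    """One-dimensional additive scan: per-marker F of the additive term.

    Fixed effects are assumed already removed from ``y`` by
    residualization.  Monomorphic markers score 0 and are flagged.
    Markers with missing calls are handled per-marker on complete cases.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("scan_1d needs at least one marker")
    sub = calls.loc[calls.index.intersection(y.index), markers]
    yv = y.loc[sub.index].to_numpy(dtype=float)
    A = additive_code(sub.to_numpy())
    flags: dict[str, str] = {}
    if not np.isnan(A).any():
        F, mono = _additive_f_matrix(yv, A)
    else:
        F = np.zeros(len(markers))
        mono = np.zeros(len(markers), dtype=bool)
        for j in range(len(markers)):
            ok = ~np.isnan(A[:, j])
            Fj, monoj = _additive_f_matrix(yv[ok], A[ok, j:j + 1])
            F[j], mono[j] = Fj[0], monoj[0]
    for j, m in enumerate(markers):
        if mono[j]:
            flags[m] = "monomorphic"
    return ScanProfile(markers=markers, statistic=F, flags=flags)


def bootstrap_scan(y: pd.Series, markers, calls: pd.DataFrame, B: int = 200,
                   seed: int | np.random.Generator = 0,
                   min_n: int = DEFAULT_MIN_STRATUM) -> ScanProfile:
    """Bootstrap-averaged 1D scan.

    Individuals are resampled with replacement to the original sample size
    B times; the per-marker statistics are averaged over replicates.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    n = len(y)
    if n < min_n:
        raise ValueError(f"sample of {n} below minimum size {min_n}")
    rng = seed if hasattr(seed, "integers") else np.random.default_rng(seed)
    markers = list(markers)
    sub = calls.loc[y.index, markers]
    yv = y.to_numpy(dtype=float)
    A = additive_code(sub.to_numpy())
    has_na = bool(np.isnan(A).any())
    acc = np.zeros(len(markers))
    for _ in range(B):
        idx = np.asarray(rng.integers(0, n, size=n))
        Ab, yb = A[idx], yv[idx]
        if not has_na:
            F, _ = _additive_f_matrix(yb, Ab)
        else:
            F = np.zeros(len(markers))
            for j in range(len(markers)):
                ok = ~np.isnan(Ab[:, j])
                F[j] = _additive_f_matrix(yb[ok], Ab[ok, j:j + 1])[0][0]
        acc += F
    return ScanProfile(markers=markers, statistic=acc / B)


def permutation_threshold(y: pd.Series, markers, calls: pd.DataFrame,
                          N: int = 1000, alpha: float = 0.05,
                          seed: int = 0) -> PermutationThreshold:
    """Study-wide significance threshold for the 1D additive scan.

    Genotype rows are permuted against the (phenotype, fixed-effect)
    tuples — with residualized phenotypes this is a permutation of the
    residuals against the genotype matrix.  The threshold is the empirical
    (1-alpha) quantile (linear interpolation) of the per-permutation
    maximum statistics.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if N < 100:
        raise ValueError("at least 100 permutations are required")
    rng = np.random.default_rng(seed)
    markers = sorted(markers)  # invariant to caller's marker ordering
    sub = calls.loc[calls.index.intersection(y.index), markers]
    yv = y.loc[sub.index].to_numpy(dtype=float)
    A = additive_code(sub.to_numpy())
    n = len(yv)

    if not np.isnan(A).any():
        # standardized cross-products: one matmul for all permutations
        Ac = A - A.mean(axis=0)
        norms = np.sqrt(np.einsum("ij,ij->j", Ac, Ac))
        mono = norms <= _EPS
        norms[mono] = 1.0
        As = Ac / norms
        perms = np.empty((N, n), dtype=np.int64)
        for i in range(N):
            perms[i] = rng.permutation(n)
        yc = yv - yv.mean()
        ynorm = np.sqrt(yc @ yc)
        Ys = (yc / (ynorm if ynorm > _EPS else 1.0))[perms].T  # n x N
        R = As.T @ Ys
        r2 = np.clip(R ** 2, 0.0, 1.0)
        r2[mono, :] = 0.0
        with np.errstate(divide="ignore"):
            F = np.where(r2 >= 1.0, np.inf, (n - 2) * r2 / (1.0 - r2))
        maxima = F.max(axis=0)
    else:
        maxima = np.empty(N)
        for i in range(N):
            perm = rng.permutation(n)
            prof = scan_1d(pd.Series(yv[perm], index=sub.index), markers, sub)
            maxima[i] = prof.statistic.max()

    thr = float(np.quantile(maxima, 1.0 - alpha))
    return PermutationThreshold(threshold=thr, maxima=maxima, alpha=alpha, n_perm=N)


def pairwise_interaction_threshold(y: pd.Series, calls: pd.DataFrame, markers,
                                   N: int = 1000, alpha: float = 0.05,
                                   seed: int = 0) -> PermutationThreshold:
    """Permutation threshold for the max pairwise ``F_full_vs_marginal``.

    Used to declare a marker pair "interacting": the pair's observed
    interaction F must exceed the (1-alpha) quantile of the maximum over
    all pairs under permutation of phenotypes against genotype rows.
    Restricted to individuals with complete calls at all ``markers``.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    rng = np.random.default_rng(seed)
    markers = sorted(markers)
    sub = calls.loc[calls.index.intersection(y.index), markers]
    sub = sub[(sub != "NA").all(axis=1)]
    yv = y.loc[sub.index].to_numpy(dtype=float)
    n = len(yv)

    A = additive_code(sub.to_numpy())
    D = dominance_code(sub.to_numpy())
    pairs = list(itertools.combinations(range(len(markers)), 2))
    # per pair: orthonormal bases of the marginal and full column spaces
    Qm, Qf, dfm, dff = [], [], [], []
    for i, j in pairs:
        Xm = np.column_stack([np.ones(n), A[:, i], D[:, i], A[:, j], D[:, j]])
        Xf = np.column_stack([Xm, A[:, i] * A[:, j], A[:, i] * D[:, j],
                              D[:, i] * A[:, j], D[:, i] * D[:, j]])
        qm = np.linalg.qr(Xm)[0][:, :np.linalg.matrix_rank(Xm)]
        qf = np.linalg.qr(Xf)[0][:, :np.linalg.matrix_rank(Xf)]
        Qm.append(qm)
        Qf.append(qf)
        dfm.append(qm.shape[1])
        dff.append(qf.shape[1])

    def max_f(Y: np.ndarray) -> np.ndarray:
        """Y: n x K matrix of phenotype vectors; returns per-column max F."""
        tot = np.einsum("ik,ik->k", Y, Y)
        best = np.zeros(Y.shape[1])
        for qm, qf, rm, rf in zip(Qm, Qf, dfm, dff):
            pm = np.einsum("ik,ik->k", qm.T @ Y, qm.T @ Y)
            pf = np.einsum("ik,ik->k", qf.T @ Y, qf.T @ Y)
            num_df, den_df = rf - rm, n - rf
            if num_df <= 0 or den_df <= 0:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                f = ((pf - pm) / num_df) / np.maximum((tot - pf) / den_df, _EPS)
            best = np.maximum(best, np.nan_to_num(f, nan=0.0))
        return best

    maxima = np.empty(N)
    chunk = 200
    for lo in range(0, N, chunk):
        k = min(chunk, N - lo)
        Y = np.empty((n, k))
        for c in range(k):
            Y[:, c] = yv[rng.permutation(n)]
        maxima[lo:lo + k] = max_f(Y)
    thr = float(np.quantile(maxima, 1.0 - alpha))
    return PermutationThreshold(threshold=thr, maxima=maxima, alpha=alpha, n_perm=N)
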
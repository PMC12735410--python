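"""Driver-inference statistics for carbon use efficiency.

The screening procedure asks which of several groups of candidate drivers
(A-strategy gene scores, S-strategy gene scores, carbon substrate
fractions, soil enzyme activities) carry independent signal for CUE:

1. within each factor group, variables are standardized and reduced to
   their first principal component (PC1) to tame collinearity;
2. CUE is correlated with each group's PC1 both zero-order and partially,
   holding each *other* group's PC1 fixed one at a time;
3. a Mantel permutation test relates multivariate dissimilarity structures
   (e.g. A-strategy gene composition vs enzyme activity);
4. a bagged regression-tree ensemble ranks individual genes by permutation
   importance (percent increase in out-of-bag MSE);
5. simple Pearson/OLS summaries and one-way ANOVA with LSD letter groups
   describe stage contrasts.

No multiple-testing correction is applied across the screen; α = 0.05
throughout.  All stochastic routines are reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "FactorGroups",
    "PartialCorResult",
    "group_pc1",
    "partial_correlation",
    "cue_driver_screen",
    "mantel_test",
    "importance_screen",
    "linear_fit_r2",
    "group_compare",
]


# ---------------------------------------------------------------------------
# PCA control factors


def group_pc1(matrix: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, float]:
    """First-principal-component scores of a samples × variables matrix.

    Variables are standardized (zero mean, unit sample variance) before the
    decomposition, i.e. PCA on the correlation matrix, because groups mix
    units (enzyme activities vs gene abundances).  Zero-variance variables
    are dropped with a warning.  The sign of PC1 is fixed so that it
    correlates positively with the variable carrying the largest loading
    magnitude.

    Returns ``(scores, variance_explained_percent)``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n < 3:
        raise ValueError(f"need >= 3 samples, got {n}")
    if p < 1:
        raise ValueError("need >= 1 variable")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all variables have zero variance")
    if not keep.all():
        import warnings

        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance variable(s) before PCA",
            stacklevel=2,
        )
        X, sd = X[:, keep], sd[keep]
    Z = (X - X.mean(axis=0)) / sd
    if Z.shape[1] == 1:
        return Z[:, 0].copy(), 100.0
    pca = PCA(n_components=1)
    scores = pca.fit_transform(Z)[:, 0]
    loadings = pca.components_[0]
    anchor = int(np.argmax(np.abs(loadings)))
    if loadings[anchor] < 0:
        scores = -scores
    variance_explained = 100.0 * float(pca.explained_variance_ratio_[0])
    return scores, variance_explained


@dataclass
class FactorGroups:
    """Named groups of per-sample covariates sharing one sample ordering.

    ``groups`` maps a group name (e.g. ``"ASG"``, ``"SSG"``, ``"CS"``,
    ``"SE"``) to a samples × variables DataFrame.  Groups with a single
    variable are allowed and flagged.
    """

    groups: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("no factor groups given")
        indices = [tuple(df.index) for df in self.groups.values()]
        if len(set(indices)) != 1:
            raise ValueError("all factor groups must share the same sample ordering")
        self.singletons = {
            name for name, df in self.groups.items() if df.shape[1] < 2
        }

    @property
    def sample_ids(self) -> list:
        return list(next(iter(self.groups.values())).index)

    def pc1_scores(self) -> dict[str, tuple[np.ndarray, float]]:
        return {name: group_pc1(df) for name, df in self.groups.items()}


# ---------------------------------------------------------------------------
# Partial correlation


@dataclass(frozen=True)
class PartialCorResult:
    target: str
    factor_group: str
    control_group: str  # "zero-order" when uncontrolled
    r: float
    p: float
    n: int


def _pearson_with_df(x: np.ndarray, y: np.ndarray, df: int) -> tuple[float, float]:
    """Pearson r with a t-test on the stated residual degrees of freedom."""
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if df <= 0:
        return r, float("nan")
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return r, p


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    controls: Sequence[Sequence[float]] | np.ndarray | None = None,
    *,
    target: str = "x",
    factor_group: str = "y",
    control_group: str | None = None,
) -> PartialCorResult:
    """Correlation of x and y after removing linear effects of controls.

    Both variables are regressed (with intercept) on the control matrix and
    the Pearson correlation of the residuals is returned, with a two-sided
    p-value from the t-distribution on ``n - 2 - k`` degrees of freedom for
    ``k`` controls.  With no controls this is the ordinary Pearson
    correlation.  The single-control case agrees with the textbook closed
    form ``(r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(controls, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        elif Z.shape[0] != n and Z.shape[1] == n:
            Z = Z.T  # accept list-of-control-vectors layout
    k = Z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), Z])
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.var(rx) < 1e-12 * max(1.0, np.var(x)) or np.var(ry) < 1e-12 * max(
        1.0, np.var(y)
    ):
        raise ValueError("controls are (nearly) collinear with x or y")
    r, p = _pearson_with_df(rx, ry, n - 2 - k)
    return PartialCorResult(
        target=target,
        factor_group=factor_group,
        control_group=control_group or ("zero-order" if k == 0 else "controls"),
        r=r,
        p=p,
        n=n,
    )


def cue_driver_screen(
    cue: Sequence[float],
    groups: FactorGroups,
    *,
    all_controls: bool = False,
) -> list[PartialCorResult]:
    """Zero-order and controlled correlations of CUE with each group's PC1.

    For each focal group the screen reports the Pearson correlation of CUE
    with the group's PC1, then the partial correlation holding each other
    group's PC1 fixed, one control at a time (the fan layout of the
    correlation wheel, as a table).  With ``all_controls`` an extra row per
    focal group conditions on all other groups' PC1s simultaneously.
    """
    cue = np.asarray(cue, dtype=float)
    if cue.size != len(groups.sample_ids):
        raise ValueError("cue length does not match group sample count")
    if cue.size < 4:
        raise ValueError("need >= 4 complete samples")
    pc1 = groups.pc1_scores()
    results: list[PartialCorResult] = []
    for focal, (scores, _ve) in pc1.items():
        results.append(
            partial_correlation(
                cue, scores, None, target="CUE", factor_group=focal,
                control_group="zero-order",
            )
        )
        others = [g for g in pc1 if g != focal]
        for ctrl in others:
            results.append(
                partial_correlation(
                    cue, scores, pc1[ctrl][0][:, None],
                    target="CUE", factor_group=focal, control_group=ctrl,
                )
            )
        if all_controls and others:
            Z = np.column_stack([pc1[g][0] for g in others])
            results.append(
                partial_correlation(
                    cue, scores, Z, target="CUE", factor_group=focal,
                    control_group="+".join(others),
                )
            )
    return results


def screen_frame(results: Iterable[PartialCorResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.target, r.factor_group, r.control_group, r.r, r.p, r.n)
            for r in results
        ],
        columns=["target", "factor_group", "control_group", "r", "p", "n"],
    )


# ---------------------------------------------------------------------------
# Mantel test


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} is not square")
    if np.isnan(d).any():
        raise ValueError(f"{name} contains NaN")
    if not np.allclose(d, d.T, rtol=0, atol=1e-12):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-12):
        raise ValueError(f"{name} has a non-zero diagonal")
    return d


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-sided (greater) Mantel permutation test between distance matrices.

    The statistic is the Pearson correlation over the strictly lower
    triangles.  The null distribution is built by jointly permuting the row
    and column labels of ``d2``; the p-value is
    ``(1 + #{r_perm >= r_obs}) / (permutations + 1)``.
    """
    d1 = _check_distance_matrix(d1, "d1")
    d2 = _check_distance_matrix(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices differ in dimension")
    m = d1.shape[0]
    if m < 4:
        raise ValueError("need matrices of dimension >= 4")
    if permutations < 99:
        raise ValueError("need >= 99 permutations")
    rows, cols = np.tril_indices(m, k=-1)
    v1 = d1[rows, cols]
    v1c = v1 - v1.mean()
    norm1 = np.linalg.norm(v1c)
    if norm1 == 0:
        raise ValueError("d1 lower triangle is constant")

    def corr_with(dmat: np.ndarray) -> float:
        v2 = dmat[rows, cols]
        v2c = v2 - v2.mean()
        norm2 = np.linalg.norm(v2c)
        if norm2 == 0:
            raise ValueError("d2 lower triangle is constant")
        return float(v1c @ v2c / (norm1 * norm2))

    r_obs = corr_with(d2)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(m)
        if corr_with(d2[np.ix_(perm, perm)]) >= r_obs - 1e-15:
            count += 1
    p = (1 + count) / (permutations + 1)
    return r_obs, p


def distance_matrix(X: pd.DataFrame | np.ndarray, standardize: bool = True) -> np.ndarray:
    """Euclidean distances between samples, optionally on standardized variables."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(X, metric="euclidean"))


# ---------------------------------------------------------------------------
# Random-forest importance screen


def importance_screen(
    features: pd.DataFrame | np.ndarray,
    response: Sequence[float],
    trees: int = 5000,
    seed: int | None = None,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Rank features by out-of-bag permutation importance (%IncMSE).

    Fits a bagged regression-tree ensemble (random forest, mtry = p/3 as is
    conventional for regression forests).  For each tree, the MSE on its
    out-of-bag samples is compared with the MSE after permuting one feature
    within the out-of-bag set; the importance of a feature is the mean MSE
    increase across trees, expressed as a percentage of the mean out-of-bag
    MSE.  Returns a DataFrame (feature, pct_mse_increase) sorted descending.
    """
    X = pd.DataFrame(features)
    y = np.asarray(response, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError(f"need n >= 10 samples, got {n}")
    if p < 2:
        raise ValueError("need >= 2 features")
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    names = [str(c) for c in X.columns]
    Xv = X.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    forest = RandomForestRegressor(
        n_estimators=trees,
        max_features=max(1, p // 3),
        bootstrap=True,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(Xv, y)

    base_errs = np.full(trees, np.nan)
    delta = np.zeros((trees, p))
    for t_idx, (tree, sampled) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.setdiff1d(np.arange(n), sampled)
        if oob.size == 0:
            continue
        X_oob = Xv[oob]
        y_oob = y[oob]
        err = float(np.mean((tree.predict(X_oob) - y_oob) ** 2))
        base_errs[t_idx] = err
        for j in range(p):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_perm[rng.permutation(oob.size), j]
            err_perm = float(np.mean((tree.predict(X_perm) - y_oob) ** 2))
            delta[t_idx, j] = err_perm - err
    valid = ~np.isnan(base_errs)
    if not valid.any():
        raise RuntimeError("no tree had out-of-bag samples")
    mean_err = float(base_errs[valid].mean())
    pct = 100.0 * delta[valid].mean(axis=0) / mean_err if mean_err > 0 else (
        np.zeros(p)
    )
    out = (
        pd.DataFrame({"feature": names, "pct_mse_increase": pct})
        .sort_values("pct_mse_increase", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return out.head(top_k) if top_k else out


# ---------------------------------------------------------------------------
# Simple summaries


def linear_fit_r2(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float]:
    """OLS fit with intercept: returns (slope, intercept, r², slope p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2), float(res.pvalue)


def group_compare(
    values: Sequence[float],
    labels: Sequence[str],
    alpha: float = 0.05,
) -> tuple[float, float, dict[str, str]]:
    """One-way ANOVA with Fisher's LSD letter groups.

    Pairwise comparisons use the pooled within-group MSE (the least
    significant difference test); the compact-letter display assigns
    letters so that groups sharing a letter do not differ at ``alpha``.
    Returns ``(F, p, letters)`` with letters keyed by group label in first-
    appearance order.
    """
    values = np.asarray(values, dtype=float)
    labels = [str(l) for l in labels]
    if values.size != len(labels):
        raise ValueError("values and labels differ in length")
    order = list(dict.fromkeys(labels))
    groups = {g: values[[i for i, l in enumerate(labels) if l == g]] for g in order}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has < 2 observations")
    F, p = sps.f_oneway(*groups.values())
    if not np.isfinite(F):  # identical values in every group
        F, p = 0.0, 1.0

    # Fisher's LSD: pooled MSE t-tests on N - k residual df.
    N = values.size
    k = len(groups)
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / (N - k)
    means = {g: float(v.mean()) for g, v in groups.items()}
    ns = {g: v.size for g, v in groups.items()}

    def differ(g1: str, g2: str) -> bool:
        if mse == 0:
            return means[g1] != means[g2]
        se = np.sqrt(mse * (1 / ns[g1] + 1 / ns[g2]))
        t = abs(means[g1] - means[g2]) / se
        return 2 * sps.t.sf(t, N - k) < alpha

    # Compact letter display: walk groups by descending mean, join each to
    # every letter class whose members it does not differ from.
    by_mean = sorted(order, key=lambda g: -means[g])
    classes: list[list[str]] = []
    for g in by_mean:
        placed = False
        for cls in classes:
            if all(not differ(g, member) for member in cls):
                cls.append(g)
                placed = True
        if not placed:
            classes.append([g])
    # Absorb classes fully contained in another (keeps the display compact).
    classes = [
        cls
        for i, cls in enumerate(classes)
        if not any(set(cls) < set(other) for j, other in enumerate(classes) if j != i)
    ]
    letters = {g: "" for g in order}
    for letter, cls in zip("abcdefghijklmnopqrstuvwxyz", classes):
        for g in cls:
            letters[g] += letter
    letters = {g: "".join(sorted(l)) for g, l in letters.items()}
    return float(F), float(p), letters
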
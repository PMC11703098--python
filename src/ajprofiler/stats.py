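"""Statistics on morphological profiles.

Profiles (cluster-occupancy frequency vectors) are compared across
conditions by cosine similarity, by Hotelling's T-squared on an LDA-reduced
representation (the observational unit is the per-well technical-replicate
profile), by one-way ANOVA and pairwise t-tests on 1D LDA reductions, and by
PCA of the profile matrix.  Profiles enter LDA/PCA as raw frequencies; a
centered-log-ratio transform is available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

RIDGE_REL = 1e-8  # ridge added to singular scatter matrices: RIDGE_REL*trace/p


@dataclass
class StatResult:
    statistic: float
    df: tuple[float, float]
    p_value: float
    method: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")


@dataclass
class LDAModel:
    """Frozen Fisher-discriminant reduction fitted on one dataset."""

    sk_model: LinearDiscriminantAnalysis
    n_components: int
    explained_variance_ratio: np.ndarray = field(default=None)
    class_means: np.ndarray = field(default=None)

    def transform(self, points: np.ndarray) -> np.ndarray:
        return self.sk_model.transform(np.asarray(points, dtype=np.float64))


def _as_profile_array(p) -> np.ndarray:
    freq = getattr(p, "frequencies", p)
    return np.asarray(freq, dtype=np.float64)


def clr_transform(profiles: np.ndarray, pseudo: float = 1e-6) -> np.ndarray:
    """Centered log-ratio transform of compositional profiles (optional)."""
    x = np.log(np.asarray(profiles, dtype=np.float64) + pseudo)
    return x - x.mean(axis=1, keepdims=True)


def cosine_similarity(p, q) -> float:
    """dot(p, q) / (||p|| ||q||); in [0, 1] for frequency vectors."""
    a, b = _as_profile_array(p), _as_profile_array(q)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.dot(a, b) / (na * nb))


def similarity_matrix(profiles: list) -> np.ndarray:
    """Symmetric cosine-similarity matrix with unit diagonal."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    arrs = [_as_profile_array(p) for p in profiles]
    n = len(arrs)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = cosine_similarity(arrs[i], arrs[j])
    return out


def fit_lda(points: np.ndarray, groups, n_components: int = 2) -> tuple[LDAModel, np.ndarray]:
    """Fisher discriminant directions; frozen transform for later data.

    Returns the model and the transformed coordinates of the fit data.
    Singular within-class scatter is handled by a small ridge (automatic
    shrinkage retry).  A pre-fitted model transforms new replicates without
    refitting.
    """
    X = np.asarray(points, dtype=np.float64)
    y = np.asarray(groups)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("LDA needs at least two groups")
    if any((y == c).sum() < 2 for c in classes):
        raise ValueError("each group needs at least two points")
    max_comp = min(len(classes) - 1, X.shape[1])
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    try:
        sk = LinearDiscriminantAnalysis(solver="eigen", n_components=n_components)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Z = sk.fit_transform(X, y)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; refitting with shrinkage ridge", stacklevel=2)
        sk = LinearDiscriminantAnalysis(solver="eigen", shrinkage=1e-6, n_components=n_components)
        Z = sk.fit_transform(X, y)
    model = LDAModel(
        sk_model=sk,
        n_components=n_components,
        explained_variance_ratio=np.asarray(sk.explained_variance_ratio_[:n_components]),
        class_means=np.asarray(sk.means_),
    )
    return model, Z


def hotelling_t2(sample_a: np.ndarray, sample_b: np.ndarray) -> StatResult:
    """Two-sample Hotelling's T-squared with pooled covariance.

    T2 = (na*nb/(na+nb)) * d' S_pooled^-1 d with d the mean difference;
    the p-value comes from the exact F transformation
    F = T2 * (na+nb-p-1) / (p*(na+nb-2)) on (p, na+nb-p-1) df.
    """
    A = np.atleast_2d(np.asarray(sample_a, dtype=np.float64))
    B = np.atleast_2d(np.asarray(sample_b, dtype=np.float64))
    if A.shape[1] != B.shape[1]:
        raise ValueError("samples must share dimensionality")
    na, nb, p = len(A), len(B), A.shape[1]
    if na < p + 1 or nb < p + 1:
        raise ValueError(f"need at least p+1={p + 1} observations per sample")
    d = A.mean(axis=0) - B.mean(axis=0)
    S = ((na - 1) * np.cov(A, rowvar=False) + (nb - 1) * np.cov(B, rowvar=False)) / (na + nb - 2)
    S = np.atleast_2d(S)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; adding ridge", stacklevel=2)
        S = S + np.eye(p) * RIDGE_REL * np.trace(S) / p
        Sinv = np.linalg.inv(S)
    t2 = float(na * nb / (na + nb) * d @ Sinv @ d)
    df1, df2 = p, na + nb - p - 1
    f_stat = t2 * df2 / (p * (na + nb - 2))
    p_value = float(sps.f.sf(f_stat, df1, df2))
    return StatResult(statistic=t2, df=(df1, df2), p_value=p_value, method="hotelling_t2")


def group_compare_1d(values_by_group: dict) -> tuple[StatResult, list[dict]]:
    """One-way ANOVA across all groups plus Holm-adjusted pairwise t-tests.

    ``values_by_group`` maps group name -> 1D values (each group >= 2).
    Returns (anova result, list of pairwise dicts with keys group_a, group_b,
    t, p_raw, p_holm).
    """
    names = list(values_by_group)
    groups = [np.asarray(values_by_group[k], dtype=np.float64).ravel() for k in names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(g.var() == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        warnings.warn("all values identical; ANOVA degenerate, p = 1", stacklevel=2)
        anova = StatResult(0.0, (len(groups) - 1, sum(map(len, groups)) - len(groups)), 1.0, "anova")
    else:
        f, p = sps.f_oneway(*groups)
        if np.isnan(f):  # zero variance within and between
            f, p = 0.0, 1.0
        anova = StatResult(
            float(f), (len(groups) - 1, sum(map(len, groups)) - len(groups)), float(p), "anova"
        )
    pairs = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            t, p = sps.ttest_ind(groups[i], groups[j])
            if np.isnan(t):
                t, p = 0.0, 1.0
            pairs.append({"group_a": names[i], "group_b": names[j], "t": float(t), "p_raw": float(p)})
    # Holm step-down adjustment
    order = np.argsort([pr["p_raw"] for pr in pairs])
    m = len(pairs)
    running = 0.0
    for rank, k in enumerate(order):
        adj = min((m - rank) * pairs[k]["p_raw"], 1.0)
        running = max(running, adj)
        pairs[k]["p_holm"] = running
    return anova, pairs


def pca_profiles(profiles: np.ndarray, n_components: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Centered PCA of a profile matrix: (scores, explained-variance ratios).

    Which components to plot (e.g. the first and third) is the caller's
    choice.  Requires at least 2 profiles.
    """
    X = np.asarray(profiles, dtype=np.float64)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need a 2D matrix with >= 2 profiles")
    max_comp = min(len(X) - 1, X.shape[1])
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
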
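"""Differential abundance statistics on the normalized protein matrix.

Per-protein log2 ratios of group means with delta-method standard errors,
two-sample Student's t tests (equal-variance, as in the source protocol;
Welch behind a flag), volcano tables at p < 0.05, agglomerative clustering
with Euclidean distance on z-scored rows, and PCA of the samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .quantify import QuantMatrix

DEFAULT_ALPHA = 0.05


def pseudo_floor(values: pd.DataFrame | np.ndarray) -> float:
    """Half the smallest positive value of the matrix (zero replacement)."""
    arr = np.asarray(values, dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("matrix has no positive values; ratios undefined")
    return float(positive.min()) / 2.0


def log2_fold_change(values_a, values_b, floor: float = 0.0) -> tuple[float, float]:
    """log2(mean_A / mean_B) and its delta-method standard error.

    ``floor`` replaces zeros before the ratio (callers pass the matrix-wide
    pseudo-floor).  se = (1/ln 2) * sqrt(sd_A^2/(n_A mean_A^2) +
    sd_B^2/(n_B mean_B^2)).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one value")
    if floor > 0:
        a = np.where(a == 0, floor, a)
        b = np.where(b == 0, floor, b)
    ma, mb = a.mean(), b.mean()
    if ma == 0 and mb == 0:
        raise ZeroDivisionError("both group means are zero after flooring")
    lfc = math.log2(ma / mb)
    va = a.var(ddof=1) if a.size > 1 else 0.0
    vb = b.var(ddof=1) if b.size > 1 else 0.0
    se = math.sqrt(va / (a.size * ma**2) + vb / (b.size * mb**2)) / math.log(2)
    return lfc, se


def student_t_test(values_a, values_b, welch: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t test (pooled variance by default).

    Degenerate data (pooled sd = 0): p = 1 when the means agree, p = 0
    when they differ (a zero-variance separation is unambiguous).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        if ma == mb:
            return 0.0, 1.0
        return (math.inf if ma > mb else -math.inf), 0.0
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


@dataclass
class DiffResult:
    protein: str
    log2_ratio: float
    p_value: float
    se_log2: float
    mean_a: float
    mean_b: float
    significant: bool


def volcano_table(
    matrix: QuantMatrix,
    contrast: tuple[str, str],
    tissue: str | None = None,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> pd.DataFrame:
    """One row per quantified protein for the (mutant, control) contrast.

    ``contrast = (genotype_A, genotype_B)``; the ratio is mean_A over
    mean_B.  Output is sorted by p-value then |log2 ratio| descending.
    """
    geno_a, geno_b = contrast
    ch_a = matrix.channels_for(geno_a, tissue)
    ch_b = matrix.channels_for(geno_b, tissue)
    if not ch_a or not ch_b:
        raise ValueError(f"contrast {contrast!r} not present in the design")
    floor = pseudo_floor(matrix.values)
    A = matrix.values[ch_a].to_numpy(dtype=float)
    B = matrix.values[ch_b].to_numpy(dtype=float)
    rows = []
    for i, protein in enumerate(matrix.values.index):
        lfc, se = log2_fold_change(A[i], B[i], floor=floor)
        _, p = student_t_test(A[i], B[i], welch=welch)
        rows.append(
            DiffResult(
                protein, lfc, p, se,
                float(np.where(A[i] == 0, floor, A[i]).mean()),
                float(np.where(B[i] == 0, floor, B[i]).mean()),
                p < alpha,
            )
        )
    out = pd.DataFrame([vars(r) for r in rows])
    out = out.sort_values(
        ["p_value", "log2_ratio"],
        key=lambda s: s if s.name == "p_value" else -s.abs(),
    ).reset_index(drop=True)
    return out


def zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Per-row z-scoring; constant rows are dropped (returned separately)."""
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1, ddof=0)
    const = sd == 0
    kept = values.loc[~const]
    z = (kept.to_numpy(dtype=float) - kept.to_numpy(dtype=float).mean(axis=1, keepdims=True))
    z = z / kept.to_numpy(dtype=float).std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame(z, index=kept.index, columns=kept.columns), list(values.index[const])


def hierarchical_cluster(
    matrix: QuantMatrix,
    axis: str = "samples",
    method: str = "average",
    zscore: bool = True,
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering (Euclidean distance, average linkage).

    Rows (proteins) are z-scored first so clustering reflects relative
    profiles, not absolute abundance.  Returns the SciPy linkage matrix and
    the ordered item labels.
    """
    if axis not in ("samples", "proteins"):
        raise ValueError("axis must be 'samples' or 'proteins'")
    values = matrix.values
    if zscore:
        values, dropped = zscore_rows(values)
        if dropped:
            matrix.log("hierarchical_cluster_dropped_constant_rows", rows=dropped)
    data = values.T if axis == "samples" else values
    if len(data) < 2:
        raise ValueError("need at least 2 items to cluster")
    dist = pdist(data.to_numpy(dtype=float), metric="euclidean")
    Z = hierarchy.linkage(dist, method=method)
    return Z, list(data.index)


def pca_scores(matrix: QuantMatrix, n_components: int | None = None) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the principal components plus variance fractions.

    Proteins are centered; the sign of each component is fixed so its
    largest-|loading| protein entry is positive, which makes scores
    reproducible across runs.
    """
    X = matrix.values.to_numpy(dtype=float)  # proteins x samples
    n_samples = X.shape[1]
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    # SVD of samples-by-proteins
    U, S, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    k = n_components or min(n_samples - 1, len(S))
    k = min(k, len(S))
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = U[:, :k] * S[:k]
    loadings = Vt[:k].T  # proteins x k
    for j in range(k):
        top = np.argmax(np.abs(loadings[:, j]))
        if loadings[top, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    cols = [f"PC{j + 1}" for j in range(k)]
    return (
        pd.DataFrame(scores, index=matrix.values.columns, columns=cols),
        frac[:k],
    )
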
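"""PSM confidence: linear discriminant scoring and target-decoy FDR control.

Peptide-spectrum matches are scored with a Fisher linear discriminant over
the search features (XCorr, deltaCn, absolute mass error, missed cleavages,
peptide length, charge), then filtered to a nominal false discovery rate
(default 1%) by target-decoy competition.  Confident PSMs are further
collapsed to proteins (protein score = best peptide score) and the same
estimator is applied at the protein level, mirroring the two-level 1% FDR
filtering used in TMT pipelines.

FDR at threshold t is estimated as ``#decoys(score >= t) / max(1,
#targets(score >= t))`` (an optional +1 correction on the decoy count is
available); q-values are the monotonized minima of this estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_FEATURES = (
    "xcorr",
    "delta_cn",
    "abs_mass_error_ppm",
    "missed_cleavages",
    "peptide_length",
    "charge",
)

DEFAULT_FDR_LEVEL = 0.01


@dataclass
class DiscriminantModel:
    feature_names: tuple
    weights: np.ndarray
    offset: float
    means: np.ndarray  # per-feature standardization mean
    sds: np.ndarray  # per-feature standardization sd (> 0)

    def score_frame(self, frame: pd.DataFrame) -> np.ndarray:
        X = _feature_matrix(frame, self.feature_names)
        Z = (X - self.means) / self.sds
        return Z @ self.weights + self.offset


def _feature_matrix(frame: pd.DataFrame, features) -> np.ndarray:
    cols = []
    for name in features:
        if name == "abs_mass_error_ppm" and name not in frame:
            cols.append(np.abs(frame["mass_error_ppm"].to_numpy(dtype=float)))
        else:
            cols.append(frame[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_lda(
    psm_frame: pd.DataFrame,
    features=DEFAULT_FEATURES,
    ridge: float = 1e-6,
) -> DiscriminantModel:
    """Fit a Fisher discriminant separating target from decoy PSMs.

    Features are standardized; weights solve
    ``(pooled within-class covariance + ridge*I) w = mean_target - mean_decoy``.
    The sign convention is enforced so that higher scores are more
    target-like.
    """
    is_decoy = psm_frame["is_decoy"].to_numpy(dtype=bool)
    if (~is_decoy).sum() < 2 or is_decoy.sum() < 2:
        raise ValueError("need at least 2 targets and 2 decoys to fit the LDA")
    X = _feature_matrix(psm_frame, features)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    sds = np.where(sds > 1e-12, sds, 1.0)  # constant features carry no signal
    Z = (X - means) / sds

    Zt, Zd = Z[~is_decoy], Z[is_decoy]
    mu_t, mu_d = Zt.mean(axis=0), Zd.mean(axis=0)
    n = len(Z)
    S = (
        (Zt - mu_t).T @ (Zt - mu_t) + (Zd - mu_d).T @ (Zd - mu_d)
    ) / (n - 2)
    S_reg = S + ridge * np.eye(S.shape[0])
    try:
        w = np.linalg.solve(S_reg, mu_t - mu_d)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"within-class covariance singular even after ridge {ridge}: {exc}"
        ) from exc
    offset = -0.5 * float(w @ (mu_t + mu_d))
    model = DiscriminantModel(tuple(features), w, offset, means, sds)
    scores = model.score_frame(psm_frame)
    if scores[~is_decoy].mean() < scores[is_decoy].mean():
        model.weights = -model.weights
        model.offset = -model.offset
    return model


@dataclass
class FdrResult:
    threshold: float  # nan if no threshold achieves the level
    kept: np.ndarray  # boolean mask over the input (targets only)
    q_values: np.ndarray  # per-input q-value


def estimate_fdr_threshold(
    scores,
    is_decoy,
    level: float = DEFAULT_FDR_LEVEL,
    plus_one: bool = False,
) -> FdrResult:
    """Target-decoy FDR: threshold, kept-target mask and q-values.

    The threshold is the smallest score t whose q-value is <= ``level``;
    decoys never enter the kept set.  If no threshold achieves the level the
    kept set is empty (with a warning), not an error.
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_cum = np.cumsum(is_decoy[order])
    t_cum = np.cumsum(~is_decoy[order])
    # collapse ties: every member of a tied block sees the block-inclusive counts
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    ends = np.flatnonzero(last)
    idx_last = ends[np.searchsorted(ends, np.arange(len(s_sorted)))]
    d_at = d_cum[idx_last].astype(float)
    t_at = t_cum[idx_last].astype(float)
    num = d_at + 1.0 if plus_one else d_at
    fdr = num / np.maximum(1.0, t_at)
    # q-values: running minimum from the least stringent threshold upward
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    ok = q_sorted <= level
    if not ok.any():
        warnings.warn(
            f"no score threshold achieves FDR <= {level}; kept set is empty",
            stacklevel=2,
        )
        return FdrResult(float("nan"), np.zeros(len(scores), dtype=bool), q)
    threshold = float(s_sorted[np.flatnonzero(ok)[-1]])
    kept = (scores >= threshold) & ~is_decoy
    return FdrResult(threshold, kept, q)


def score_and_filter_psms(
    psm_frame: pd.DataFrame,
    level: float = DEFAULT_FDR_LEVEL,
    features=DEFAULT_FEATURES,
    ridge: float = 1e-6,
    plus_one: bool = False,
) -> tuple[pd.DataFrame, DiscriminantModel]:
    """Fit the discriminant, attach score/q_value/kept columns, return frame."""
    model = fit_lda(psm_frame, features=features, ridge=ridge)
    out = psm_frame.copy()
    out["score"] = model.score_frame(psm_frame)
    res = estimate_fdr_threshold(
        out["score"], out["is_decoy"], level=level, plus_one=plus_one
    )
    out["q_value"] = res.q_values
    out["kept"] = res.kept
    return out, model


def protein_level_fdr(
    scored_psms: pd.DataFrame,
    level: float = DEFAULT_FDR_LEVEL,
    plus_one: bool = False,
) -> tuple[set, pd.DataFrame]:
    """Collapse kept PSMs to proteins and filter at the protein level.

    Protein score = maximum discriminant score over the protein's PSMs;
    decoy proteins (from decoy PSMs surviving nothing at the PSM stage are
    still competed here) share the estimator.  Returns the confident target
    protein set and the per-protein score table.
    """
    psms = scored_psms[scored_psms["kept"] | scored_psms["is_decoy"]]
    rows = []
    for _, r in psms.iterrows():
        accs = r["protein_accessions"]
        if isinstance(accs, str):
            accs = accs.split(";")
        for acc in accs:
            rows.append((acc, r["score"], bool(r["is_decoy"])))
    if not rows:
        return set(), pd.DataFrame(columns=["protein", "score", "is_decoy", "q_value", "kept"])
    table = (
        pd.DataFrame(rows, columns=["protein", "score", "is_decoy"])
        .groupby("protein", as_index=False)
        .agg(score=("score", "max"), is_decoy=("is_decoy", "any"))
    )
    res = estimate_fdr_threshold(
        table["score"], table["is_decoy"], level=level, plus_one=plus_one
    )
    table["q_value"] = res.q_values
    table["kept"] = res.kept
    return set(table.loc[table["kept"], "protein"]), table
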
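"""Discriminant scoring and target-decoy FDR estimation."""

import numpy as np
import pandas as pd
import pytest

from plexquant.confidence import (
    estimate_fdr_threshold,
    fit_lda,
    protein_level_fdr,
    score_and_filter_psms,
)


def _frame(n, rng, informative=True):
    is_decoy = np.zeros(n, dtype=bool)
    is_decoy[n // 2 :] = True
    x = rng.normal(0.0, 1.0, n)
    if informative:
        x[~is_decoy] += 5.0
    return pd.DataFrame(
        {
            "signal": x,
            "noise1": rng.normal(size=n),
            "noise2": rng.normal(size=n),
            "is_decoy": is_decoy,
        }
    )


def auroc(scores, labels):
    order = np.argsort(scores)
    ranks = np.empty(len(scores))
    ranks[order] = np.arange(1, len(scores) + 1)
    pos = labels.astype(bool)
    n1, n0 = pos.sum(), (~pos).sum()
    return (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def test_informative_feature_dominates_weights():
    rng = np.random.default_rng(17)
    frame = _frame(10000, rng)
    model = fit_lda(frame, features=("signal", "noise1", "noise2"))
    w = np.abs(model.weights)
    assert w[0] == max(w) and w[0] > 5 * max(w[1:])


def test_uninformative_features_give_null_auroc():
    rng = np.random.default_rng(17)
    frame = _frame(10000, rng, informative=False)
    model = fit_lda(frame, features=("signal", "noise1", "noise2"))
    scores = model.score_frame(frame)
    assert auroc(scores, ~frame["is_decoy"].to_numpy()) == pytest.approx(0.5, abs=0.02)


def test_duplicate_feature_columns_survive_ridge():
    rng = np.random.default_rng(3)
    frame = _frame(200, rng)
    frame["signal_copy"] = frame["signal"]
    model = fit_lda(frame, features=("signal", "signal_copy"), ridge=1e-6)
    scores = model.score_frame(frame)
    assert scores[~frame["is_decoy"]].mean() > scores[frame["is_decoy"]].mean()


def test_lda_needs_both_classes():
    frame = pd.DataFrame({"signal": [1.0, 2.0, 3.0], "is_decoy": [False, False, False]})
    with pytest.raises(ValueError):
        fit_lda(frame, features=("signal",))


# ---------------------------------------------------------------------------
# FDR estimation


def brute_force_fdr(scores, is_decoy, level):
    """Oracle: exhaustive enumeration over all candidate thresholds."""
    scores = np.asarray(scores, float)
    is_decoy = np.asarray(is_decoy, bool)
    cand = np.unique(scores)

    def fdr_at(t):
        above = scores >= t
        return (above & is_decoy).sum() / max(1, (above & ~is_decoy).sum())

    def q_at(t):
        return min(fdr_at(u) for u in cand if u <= t)

    ok = [t for t in cand if q_at(t) <= level]
    if not ok:
        return set()
    thr = min(ok)
    return set(np.flatnonzero((scores >= thr) & ~is_decoy))


def test_fdr_worked_example():
    scores = [5, 4, 3, 2, 2.5, 1]
    decoy = [False, False, False, False, True, True]
    res = estimate_fdr_threshold(scores, decoy, level=0.01)
    assert res.threshold == 3
    assert res.kept.sum() == 3
    assert set(np.flatnonzero(res.kept)) == {0, 1, 2}


def test_all_decoys_below_targets():
    res = estimate_fdr_threshold([5, 4, 3, 1, 0.5], [0, 0, 0, 1, 1], level=0.01)
    assert res.kept.sum() == 3
    assert np.all(res.q_values[:3] == 0)


def test_vacuous_level_keeps_all_targets():
    res = estimate_fdr_threshold([3, 2, 1], [False, True, False], level=1.0)
    assert res.kept.sum() == 2


def test_unachievable_level_warns_and_keeps_nothing():
    with pytest.warns(UserWarning):
        res = estimate_fdr_threshold([1.0, 2.0], [False, True], level=0.01)
    assert res.kept.sum() == 0


def test_kept_set_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(17)
    for _ in range(50):
        n = int(rng.integers(5, 40))
        scores = np.round(rng.normal(size=n), 1)  # coarse grid to force ties
        decoy = rng.random(n) < 0.4
        if decoy.all() or not decoy.any():
            continue
        for level in (0.05, 0.25, 0.5):
            res = estimate_fdr_threshold(scores, decoy, level=level)
            assert set(np.flatnonzero(res.kept)) == brute_force_fdr(scores, decoy, level)


def test_lowering_level_never_enlarges_kept_set():
    rng = np.random.default_rng(5)
    scores = rng.normal(size=500)
    decoy = rng.random(500) < 0.5
    scores[~decoy] += 1.5
    kept_sizes = [
        estimate_fdr_threshold(scores, decoy, level=lv).kept.sum()
        for lv in (0.5, 0.2, 0.1, 0.05, 0.01)
    ]
    assert kept_sizes == sorted(kept_sizes, reverse=True)


def test_q_values_nonincreasing_in_score():
    rng = np.random.default_rng(7)
    scores = rng.normal(size=300)
    decoy = rng.random(300) < 0.5
    res = estimate_fdr_threshold(scores, decoy, level=0.1)
    order = np.argsort(scores)
    q_sorted = res.q_values[order]
    assert np.all(np.diff(q_sorted) <= 1e-12)


# ---------------------------------------------------------------------------
# protein-level competition


def _scored_frame(scores, decoy, proteins):
    return pd.DataFrame(
        {
            "score": scores,
            "is_decoy": decoy,
            "kept": [not d for d in decoy],
            "protein_accessions": [[p] for p in proteins],
        }
    )


def test_protein_with_top_score_retained():
    frame = _scored_frame(
        [9.0, 1.0, 0.5], [False, True, True], ["A", "rev_B", "rev_C"]
    )
    kept, table = protein_level_fdr(frame, level=0.5)
    assert "A" in kept


def test_no_decoy_proteins_keeps_all_targets():
    frame = _scored_frame([3.0, 2.0], [False, False], ["A", "B"])
    kept, table = protein_level_fdr(frame, level=0.01)
    assert kept == {"A", "B"}
    assert np.all(table["q_value"] == 0)


def test_protein_fdr_matches_threshold_enumeration():
    rng = np.random.default_rng(11)
    n = 100
    proteins = [f"P{i}" for i in range(50)] + [f"rev_P{i}" for i in range(50)]
    decoy = [False] * 50 + [True] * 50
    scores = np.empty(n)
    scores[:50] = rng.normal(1.0, 1.0, 50)
    scores[50:] = rng.normal(0.0, 1.0, 50)
    frame = _scored_frame(scores, decoy, proteins)
    frame["kept"] = ~frame["is_decoy"]
    kept, table = protein_level_fdr(frame, level=0.1)
    # max-per-protein collapse is identity here (one PSM per protein)
    oracle_idx = brute_force_fdr(
        table["score"].to_numpy(), table["is_decoy"].to_numpy(), 0.1
    )
    assert kept == set(table.loc[sorted(oracle_idx), "protein"])


def test_score_and_filter_pipeline_outputs_columns():
    rng = np.random.default_rng(2)
    frame = _frame(400, rng)
    frame = frame.rename(columns={"signal": "xcorr"})
    frame["delta_cn"] = rng.random(400)
    frame["mass_error_ppm"] = rng.normal(size=400)
    frame["missed_cleavages"] = 0
    frame["peptide_length"] = 10
    frame["charge"] = 2
    scored, model = score_and_filter_psms(frame, level=0.05)
    assert {"score", "q_value", "kept"} <= set(scored.columns)
    assert not scored.loc[scored["kept"], "is_decoy"].any()
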
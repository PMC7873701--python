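"""Cross-tissue / cross-model integration of differential-abundance results.

The integration is set logic, not statistical pooling: a protein is flagged
"altered" in a tissue when it is up- or downregulated at least 20% allowing
for standard error (|log2 ratio| minus a configurable multiple of the SE
clears log2(1.20)); proteins altered in multiple tissues are tabulated with
per-model direction summaries; young/old cohorts are intersected at the
>25%-and-p<0.05 rule; and proximity-labeling (APEX2-style) hits are selected
at >= 1.5-fold with BH-adjusted p < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .enrichment import bh_adjust

DEFAULT_ALTERED_FRACTION = 0.20
DEFAULT_AGE_FC_FRACTION = 0.25
DEFAULT_APEX_FOLD = 1.5
DEFAULT_ALPHA = 0.05


@dataclass
class TissueResultSet:
    tissue: str
    model: str  # genetic background (KO, KI, Tg-WT, Tg-mut, ...)
    results: pd.DataFrame  # volcano table: protein, log2_ratio, se_log2, p_value

    @property
    def label(self) -> tuple:
        return (self.tissue, self.model)


def flag_altered_with_se(
    log2_ratio: float,
    se_log2: float,
    threshold_fraction: float = DEFAULT_ALTERED_FRACTION,
    se_multiplier: float = 1.0,
) -> bool:
    """Altered iff (|log2 ratio| - se_multiplier*SE) >= log2(1 + threshold)."""
    return (abs(log2_ratio) - se_multiplier * se_log2) >= math.log2(
        1.0 + threshold_fraction
    )


def shared_across_tissues(
    sets: list[TissueResultSet],
    min_tissues: int = 2,
    threshold_fraction: float = DEFAULT_ALTERED_FRACTION,
    se_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Proteins altered (>= threshold allowing for SE) in >= ``min_tissues``.

    One row per qualifying protein: the number of tissues in which it is
    altered, the per-model direction summary, and a discordance flag when a
    protein moves up in one tissue and down in another.  Sorted by count
    descending, then accession.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 result sets")
    tallies: dict = {}
    for ts in sets:
        for r in ts.results.itertuples():
            if flag_altered_with_se(
                r.log2_ratio, r.se_log2, threshold_fraction, se_multiplier
            ):
                tallies.setdefault(r.protein, []).append(
                    (ts.tissue, ts.model, "up" if r.log2_ratio > 0 else "down")
                )
    rows = []
    for protein, hits in tallies.items():
        n_tissues = len({t for t, _, _ in hits})
        if n_tissues < min_tissues:
            continue
        directions = {d for _, _, d in hits}
        rows.append(
            {
                "protein": protein,
                "n_tissues_altered": n_tissues,
                "models": ";".join(sorted({m for _, m, _ in hits})),
                "summary": ";".join(f"{t}/{m}:{d}" for t, m, d in sorted(hits)),
                "discordant": len(directions) > 1,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["protein", "n_tissues_altered", "models", "summary", "discordant"],
    )
    return out.sort_values(
        ["n_tissues_altered", "protein"], ascending=[False, True]
    ).reset_index(drop=True)


def _hit_sets(results: pd.DataFrame, fc_threshold: float, alpha: float):
    lo = math.log2(1.0 + fc_threshold)
    sig = results["p_value"] < alpha
    up = set(results.loc[sig & (results["log2_ratio"] > lo), "protein"])
    down = set(results.loc[sig & (results["log2_ratio"] < -lo), "protein"])
    return up, down


def overlap_by_age(
    old: TissueResultSet,
    young: TissueResultSet,
    fc_threshold: float = DEFAULT_AGE_FC_FRACTION,
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Venn-style intersection of aged vs young hit sets (>25%, p < 0.05).

    Fold-change bounds are strict (>25%); returns shared_up, shared_down,
    old_only and young_only protein sets (old_only/young_only pool both
    directions).
    """
    up_o, down_o = _hit_sets(old.results, fc_threshold, alpha)
    up_y, down_y = _hit_sets(young.results, fc_threshold, alpha)
    hits_o, hits_y = up_o | down_o, up_y | down_y
    return {
        "shared_up": up_o & up_y,
        "shared_down": down_o & down_y,
        "old_only": hits_o - hits_y,
        "young_only": hits_y - hits_o,
    }


def select_apex_enriched(
    results: pd.DataFrame,
    fold_threshold: float = DEFAULT_APEX_FOLD,
    alpha: float = DEFAULT_ALPHA,
    adj_col: str = "adj_p",
) -> set:
    """Proximity-labeling selection: fold >= threshold (inclusive) and
    BH-adjusted p < alpha (strict).

    If the frame has no adjusted-p column it is computed over all tested
    proteins first.
    """
    df = results.copy()
    if adj_col not in df:
        df[adj_col] = bh_adjust(df["p_value"])
    lo = math.log2(fold_threshold)
    sel = (df["log2_ratio"] >= lo) & (df[adj_col] < alpha)
    return set(df.loc[sel, "protein"])
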
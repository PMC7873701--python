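"""Peptide-to-protein rollup, the CV reproducibility filter, and the two
normalizations (label-check mixing factors; equal peptide loading).

Peptides must reproduce within each replicate group (coefficient of
variation < 20%, strict) to contribute to protein quantification; protein
channel values are the sum of their kept peptides' reporter intensities; and
the final matrix is column-scaled so every channel carries the same total
signal ("equal peptide loading").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_CV_THRESHOLD = 0.20


class DegenerateChannelError(ValueError):
    """A channel with zero total signal cannot be normalized."""


@dataclass
class QuantMatrix:
    """Protein x channel abundance table with design metadata.

    ``values``: DataFrame indexed by protein accession, one column per
    channel.  ``design``: DataFrame indexed by channel with columns
    tissue/genotype/replicate.  ``provenance``: ordered log of the
    transformations applied.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    provenance: list = field(default_factory=list)

    def log(self, step: str, **info):
        self.provenance.append({"step": step, **info})

    def channels_for(self, genotype: str, tissue: str | None = None) -> list:
        d = self.design
        mask = d["genotype"] == genotype
        if tissue is not None:
            mask &= d["tissue"] == tissue
        return list(d.index[mask])

    def copy(self) -> "QuantMatrix":
        return QuantMatrix(self.values.copy(), self.design.copy(), list(self.provenance))


def label_check_factors(pooled_totals) -> np.ndarray:
    """Mixing factors from a pooled 'label check' run: mean(total)/total.

    Applying the factors equalizes the channel totals exactly; the factors
    are the per-channel volumes used to mix the remaining sample.
    """
    totals = np.asarray(pooled_totals, dtype=float)
    if np.any(totals <= 0):
        raise DegenerateChannelError(
            f"non-positive channel total at index {int(np.argmin(totals))}"
        )
    return totals.mean() / totals


def cv_filter(
    peptide_values: pd.DataFrame,
    replicate_groups: dict,
    threshold: float = DEFAULT_CV_THRESHOLD,
) -> tuple[pd.Series, pd.Series]:
    """Keep peptides whose CV is below ``threshold`` in every evaluable group.

    ``replicate_groups`` maps group name -> list of channel columns; groups
    with fewer than 2 channels are skipped.  CV uses the sample standard
    deviation (n-1).  A peptide with zero mean in any evaluable group is
    dropped with reason ``zero-signal``.
    """
    keep = pd.Series(True, index=peptide_values.index)
    reason = pd.Series("", index=peptide_values.index)
    for name, channels in replicate_groups.items():
        if len(channels) < 2:
            continue
        block = peptide_values[list(channels)].to_numpy(dtype=float)
        mean = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        zero = mean == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(zero, np.inf, sd / np.where(zero, 1.0, mean))
        fail = ~(cv < threshold)
        newly_zero = zero & keep.to_numpy()
        newly_cv = fail & ~zero & keep.to_numpy()
        reason[newly_zero] = "zero-signal"
        reason[newly_cv] = f"cv>={threshold:g}:{name}"
        keep &= ~fail
    return keep, reason


def rollup_protein(
    peptide_values: pd.DataFrame,
    peptide_to_protein: pd.Series,
    design: pd.DataFrame,
) -> QuantMatrix:
    """Sum kept peptide reporter intensities into protein channel values.

    ``peptide_to_protein`` assigns each peptide row to exactly one protein
    (group representative).  Proteins without kept peptides simply do not
    appear; the provenance records the counts.
    """
    aligned = peptide_to_protein.reindex(peptide_values.index)
    if aligned.isna().any():
        raise ValueError("every peptide must be assigned to a protein group")
    values = peptide_values.groupby(aligned).sum()
    values.index.name = "protein"
    qm = QuantMatrix(values, design)
    qm.log(
        "rollup_protein",
        n_peptides=int(len(peptide_values)),
        n_proteins=int(len(values)),
    )
    return qm


def normalize_equal_loading(matrix: QuantMatrix) -> QuantMatrix:
    """Scale each channel by mean(channel totals)/total: equal peptide loading.

    Conserves the grand total and is idempotent.  A zero-total channel is an
    error naming the channel.
    """
    totals = matrix.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateChannelError(
            f"channel(s) with zero total signal: {', '.join(map(str, zero.index))}"
        )
    factors = totals.mean() / totals
    out = matrix.copy()
    out.values = matrix.values * factors
    out.log("normalize_equal_loading", factors={str(k): float(v) for k, v in factors.items()})
    return out
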
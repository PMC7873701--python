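"""Parsimony protein inference: smallest protein set explaining all peptides.

Minimum set cover is NP-hard, so the default solver is the classical greedy:
repeatedly select the protein explaining the most still-unexplained peptides
(ties broken by total peptide count, then lexicographic accession), then
prune until the cover is irredundant.  Proteins with identical peptide sets
are reported as one group.  An exact brute-force solver is available for
small maps (<= 15 proteins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import pandas as pd


@dataclass
class ProteinGroup:
    representative: str
    members: tuple  # proteins with identical peptide sets, representative first
    peptides: frozenset
    unique_peptides: frozenset = frozenset()  # filled by assign_peptides
    shared_peptides: frozenset = frozenset()


def _invert(peptide_map: Mapping[str, set]) -> dict:
    prot_to_peps: dict = {}
    for pep, prots in peptide_map.items():
        if not prots:
            raise ValueError(f"peptide {pep!r} maps to no protein")
        for p in prots:
            prot_to_peps.setdefault(p, set()).add(pep)
    return prot_to_peps


def assemble_parsimony(peptide_map: Mapping[str, set]) -> list[ProteinGroup]:
    """Greedy set cover over the peptide->proteins map.

    Returns protein groups in selection order.  The cover is valid (every
    peptide explained) and irredundant (every selected group retains at
    least one peptide explained by no other selected group).
    """
    if not peptide_map:
        raise ValueError("peptide map is empty")
    prot_to_peps = _invert(peptide_map)

    # group proteins sharing an identical peptide set
    by_pepset: dict = {}
    for prot, peps in prot_to_peps.items():
        by_pepset.setdefault(frozenset(peps), []).append(prot)
    groups = [
        ProteinGroup(min(prots), tuple(sorted(prots, key=lambda a: (a != min(prots), a))), peps)
        for peps, prots in by_pepset.items()
    ]

    # Greedy selection with a lazily invalidated heap: equivalent to picking
    # argmax (uncovered gain, total peptides, lexicographic accession) each
    # round, but near-linear when most peptides are unique.
    import heapq

    pep_to_groups: dict = {}
    for gi, g in enumerate(groups):
        for pep in g.peptides:
            pep_to_groups.setdefault(pep, []).append(gi)
    gain = {gi: len(g.peptides) for gi, g in enumerate(groups)}
    heap = [
        (-gain[gi], -len(g.peptides), g.representative, gi, gain[gi])
        for gi, g in enumerate(groups)
    ]
    heapq.heapify(heap)
    uncovered = set(peptide_map)
    selected: list[ProteinGroup] = []
    chosen: set = set()
    while uncovered and heap:
        _, _, _, gi, snap = heapq.heappop(heap)
        if gi in chosen or snap != gain[gi]:
            continue  # stale entry
        g = groups[gi]
        newly = g.peptides & uncovered
        if not newly:
            continue
        selected.append(g)
        chosen.add(gi)
        uncovered -= newly
        touched = set()
        for pep in newly:
            for gj in pep_to_groups[pep]:
                if gj not in chosen:
                    gain[gj] -= 1
                    touched.add(gj)
        for gj in touched:
            h = groups[gj]
            heapq.heappush(
                heap, (-gain[gj], -len(h.peptides), h.representative, gj, gain[gj])
            )

    # prune to irredundancy (later picks can obsolete earlier ones)
    changed = True
    while changed:
        changed = False
        for g in list(selected):
            others = set().union(
                *(h.peptides for h in selected if h is not g)
            ) if len(selected) > 1 else set()
            if g.peptides <= others:
                selected.remove(g)
                changed = True
                break
    return assign_peptides(selected)


def assign_peptides(selected: list[ProteinGroup]) -> list[ProteinGroup]:
    """Mark each covered peptide unique/shared among the selected groups and
    assign shared peptides to the selected group with the most peptides."""
    count: dict = {}
    for g in selected:
        for pep in g.peptides:
            count[pep] = count.get(pep, 0) + 1
    owner: dict = {}
    for pep in count:
        owners = [g for g in selected if pep in g.peptides]
        owner[pep] = min(owners, key=lambda g: (-len(g.peptides), g.representative))
    out = []
    for g in selected:
        uniq = frozenset(p for p in g.peptides if count[p] == 1)
        shared = frozenset(
            p for p in g.peptides if count[p] > 1 and owner[p] is g
        )
        out.append(ProteinGroup(g.representative, g.members, g.peptides, uniq, shared))
    return out


def exact_minimum_cover(peptide_map: Mapping[str, set], max_proteins: int = 15) -> set:
    """Brute-force minimum protein cover (exponential; small maps only)."""
    prot_to_peps = _invert(peptide_map)
    prots = sorted(prot_to_peps)
    if len(prots) > max_proteins:
        raise ValueError(f"exact solver limited to {max_proteins} proteins")
    all_peps = set(peptide_map)
    for k in range(1, len(prots) + 1):
        for combo in combinations(prots, k):
            covered = set().union(*(prot_to_peps[p] for p in combo))
            if covered == all_peps:
                return set(combo)
    raise ValueError("no cover exists (inconsistent map)")


def unique_peptides(accession: str, peptide_map: Mapping[str, set]) -> set:
    """Peptides mapping only to ``accession`` (paralog-specific peptides).

    This is the rule used to quantify closely related paralogs (such as the
    ubiquilin family) without cross-contamination from shared peptides.
    """
    known = set().union(*peptide_map.values()) if peptide_map else set()
    if accession not in known:
        raise KeyError(f"accession {accession!r} not present in the map")
    return {pep for pep, prots in peptide_map.items() if prots == {accession}}


def groups_frame(groups: list[ProteinGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "representative": [g.representative for g in groups],
            "members": [";".join(g.members) for g in groups],
            "n_peptides": [len(g.peptides) for g in groups],
            "n_unique_peptides": [len(g.unique_peptides) for g in groups],
            "n_shared_peptides": [len(g.shared_peptides) for g in groups],
        }
    )
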
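"""Generators: determinism, digestion correctness, planted-truth bookkeeping,
and the noiseless conservation limit."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plexquant.simulate import (
    Arm,
    DecayParams,
    DesignError,
    FoldChangeSpec,
    digest_tryptic,
    generate_proteome,
    plant_design,
    simulate_decay_course,
    simulate_psm_table,
    simulate_search_features,
)


# ---------------------------------------------------------------------------
# proteome


def test_proteome_counts_and_decoy_reversal():
    records = generate_proteome(100, seed=3)
    assert len(records) == 200
    assert sum(r.is_decoy for r in records) == 100
    targets = {r.accession: r for r in records if not r.is_decoy}
    for r in records:
        if r.is_decoy:
            partner = targets[r.accession.removeprefix("rev_")]
            assert r.sequence == partner.sequence[::-1]


def test_proteome_deterministic():
    a = generate_proteome(5, seed=17)
    b = generate_proteome(5, seed=17)
    assert a == b
    assert a != generate_proteome(5, seed=18)


def test_proteome_rejects_nonpositive():
    with pytest.raises(ValueError):
        generate_proteome(0)


# ---------------------------------------------------------------------------
# digestion


def brute_force_digest(sequence, max_missed):
    """Independent oracle: every substring whose boundaries are valid
    cleavage boundaries with <= max_missed internal sites."""
    sites = {
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    }
    bounds = sorted({0, len(sequence)} | sites)
    out = set()
    for a in bounds:
        for b in bounds:
            if b <= a:
                continue
            internal = sum(1 for s in sites if a < s < b)
            if internal <= max_missed:
                out.add((sequence[a:b], internal))
    return out


@pytest.mark.parametrize(
    "sequence,max_missed,expected",
    [
        ("MKTAYIAKR", 2, {"MK", "TAYIAK", "R", "MKTAYIAK", "TAYIAKR", "MKTAYIAKR"}),
        ("AAAA", 2, {"AAAA"}),
        ("AKPR", 0, {"AKPR"}),
    ],
)
def test_digest_examples(sequence, max_missed, expected):
    peptides = {p.sequence for p in digest_tryptic(sequence, max_missed)}
    assert peptides == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
    max_missed=st.integers(0, 3),
)
def test_digest_matches_brute_force_enumeration(seq, max_missed):
    got = {(p.sequence, p.missed_cleavages) for p in digest_tryptic(seq, max_missed)}
    assert got == brute_force_digest(seq, max_missed)


def test_digest_flags_short_products():
    peps = {p.sequence: p for p in digest_tryptic("MKTAYIAKR", 2)}
    assert peps["R"].is_short
    assert not peps["TAYIAK"].is_short


def test_digest_empty_sequence_rejected():
    with pytest.raises(ValueError):
        digest_tryptic("", 2)


# ---------------------------------------------------------------------------
# design / ground truth


PROTEINS = [f"PROT{i:04d}" for i in range(2000)]


def test_plant_design_rounding_rule():
    truth = plant_design(
        [Arm("brain", "WT", 3), Arm("brain", "KO", 3)], PROTEINS, 0.05, seed=1
    )
    assert len(truth.changed_set) == 100
    # reference condition always has fold change 1
    for acc in truth.changed_set:
        assert truth.fold_change.get((acc, ("brain", "WT")), 1.0) == 1.0


def test_plant_design_zero_fraction_and_determinism():
    args = ([Arm("brain", "WT", 2), Arm("brain", "KO", 2)], PROTEINS)
    empty = plant_design(*args, 0.0, seed=5)
    assert empty.changed_set == set() and empty.fold_change == {}
    a = plant_design(*args, 0.1, seed=5)
    b = plant_design(*args, 0.1, seed=5)
    assert a.changed_set == b.changed_set and a.fold_change == b.fold_change


def test_plant_design_validates_layout():
    with pytest.raises(DesignError):
        plant_design([Arm("brain", "KO", 3)], PROTEINS, 0.0)  # no reference arm
    with pytest.raises(DesignError):
        plant_design(
            [Arm("brain", "WT", 6), Arm("brain", "KO", 6)], PROTEINS, 0.0
        )  # 12 samples on a 10-plex


# ---------------------------------------------------------------------------
# PSM simulation


def _noiseless_truth_and_proteome(n=40, seed=11):
    proteome = generate_proteome(n, seed=seed)
    accs = [p.accession for p in proteome if not p.is_decoy]
    truth = plant_design(
        [Arm("brain", "WT", 3), Arm("brain", "KO", 3)],
        accs,
        0.25,
        FoldChangeSpec(1.0, 0.0, "up"),
        noise_cv=0.0,
        seed=seed,
    )
    return truth, proteome


def test_noiseless_limit_reporter_ratios_equal_planted_fold_change():
    truth, proteome = _noiseless_truth_and_proteome()
    psms = simulate_psm_table(
        truth, proteome, psms_per_protein=4, interference_level=0.0,
        decoy_fraction=0.0, entrapment_fraction=0.0, loading_cv=0.0, seed=2,
    )
    channels = list(truth.design)
    for psm in psms:
        acc = psm.protein_accessions[0]
        intensities = np.array([p[1] for p in sorted(psm.reporter_peaks)])
        fcs = np.array([truth.fc(acc, c) for c in channels])
        ref = intensities[0] / fcs[0]
        assert np.allclose(intensities, ref * fcs, rtol=1e-12)


def test_psm_table_deterministic():
    truth, proteome = _noiseless_truth_and_proteome()
    a = simulate_psm_table(truth, proteome, psms_per_protein=3, seed=7)
    b = simulate_psm_table(truth, proteome, psms_per_protein=3, seed=7)
    assert a == b


def test_target_decoy_xcorr_separation_matches_configured_shift():
    frame = simulate_search_features(10000, 10000, xcorr_shift=1.5, seed=17)
    shift = (
        frame.loc[~frame["is_decoy"], "xcorr"].mean()
        - frame.loc[frame["is_decoy"], "xcorr"].mean()
    )
    assert shift == pytest.approx(1.5, abs=0.05)


def test_entrapment_fraction_respected():
    frame = simulate_search_features(1000, 1000, entrapment_fraction=0.1, seed=1)
    assert frame["is_entrapment"].sum() == 100
    assert not (frame["is_entrapment"] & frame["is_decoy"]).any()


# ---------------------------------------------------------------------------
# decay course


def test_decay_course_closed_form_values():
    params = DecayParams(0.6, 0.5, 0.4, 0.05, 0.0)
    df = simulate_decay_course(params, [0.0, 24.0], 10, event_cv=0.0, seed=3)
    r0 = (df.loc[df["time_h"] == 0.0, "rfp"] / df.loc[df["time_h"] == 0.0, "cfp"]).unique()
    assert r0 == pytest.approx(1.0)  # span_fast + span_slow + plateau at t=0
    r24 = (df.loc[df["time_h"] == 24.0, "rfp"] / df.loc[df["time_h"] == 24.0, "cfp"]).iloc[0]
    expected = 0.6 * math.exp(-12.0) + 0.4 * math.exp(-1.2)
    assert r24 == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.1205, abs=5e-4)


def test_decay_course_degenerate_constant():
    df = simulate_decay_course(
        DecayParams(0.0, 1.0, 0.7, 0.0, 0.0), [0, 4, 8], 5, 0.0, seed=1
    )
    ratios = df["rfp"] / df["cfp"]
    assert np.allclose(ratios, 0.7, rtol=1e-12)


def test_decay_course_rejects_bad_rates():
    with pytest.raises(ValueError):
        simulate_decay_course(DecayParams(0.5, 0.1, 0.5, 0.2, 0.0), [0, 1], 5, 0.0)
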
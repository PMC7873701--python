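"""Synthetic multiplexed-proteomics data with known ground truth.

This module generates everything the downstream pipeline consumes: a
target-decoy protein database, tryptic peptides, 10-plex PSM tables with
planted protein fold changes, search-feature draws for target/decoy/entrapment
populations, GO-style annotation tables, and photoconversion pulse-chase decay
time courses.  Each generator is deterministic for a fixed seed.

The generators emulate the structure of a multi-tissue TMT-SPS-MS3 experiment
comparing wild-type with knockout/knock-in/transgenic arms (2-6 biological
replicates per arm, up to 10 channels per plex).  They do not simulate
fragment spectra, chromatography, or fractionation; search scores (XCorr,
deltaCn, ...) are drawn from parametric distributions with a configurable
target/decoy separation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .masses import TMT10_CHANNELS, TMT10_REPORTER_MZ

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Prefix that marks reversed-sequence decoy entries.
DECOY_PREFIX = "rev_"

DEFAULT_SEED = 17


class DesignError(ValueError):
    """Raised when a sample design cannot be laid out on a 10-plex."""


# ---------------------------------------------------------------------------
# protein database


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self):
        if len(self.sequence) < 6:
            raise ValueError(f"{self.accession}: sequence shorter than 6 residues")


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (60, 400),
    seed: int = DEFAULT_SEED,
) -> list[ProteinRecord]:
    """Random target proteins plus one reversed-sequence decoy per target.

    Returns ``2 * n_proteins`` records: targets first, then their decoys.
    Decoy accessions carry the ``rev_`` prefix and the reversed sequence of
    the corresponding target, mirroring the reversed-database construction
    used for target-decoy searching.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 6 or hi < lo:
        raise ValueError("length_range must satisfy 6 <= lo <= hi")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")
    targets = []
    width = max(4, len(str(n_proteins)))
    for i in range(n_proteins):
        n = int(rng.integers(lo, hi + 1))
        seq = b"".join(rng.choice(aa, size=n)).decode()
        targets.append(ProteinRecord(f"PROT{i + 1:0{width}d}", seq, False))
    decoys = [
        ProteinRecord(DECOY_PREFIX + t.accession, t.sequence[::-1], True)
        for t in targets
    ]
    return targets + decoys


# ---------------------------------------------------------------------------
# tryptic digestion


@dataclass(frozen=True)
class Peptide:
    sequence: str
    missed_cleavages: int
    is_short: bool  # length < 2; retained but flagged


def digest_tryptic(sequence: str, max_missed: int = 2) -> list[Peptide]:
    """In-silico tryptic digest: cleave C-terminal to K/R except before P.

    Returns every peptide with 0..``max_missed`` internal missed cleavage
    sites.  Sub-2-residue products are kept but flagged ``is_short``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    # indices AFTER which we cut (exclusive end of a fragment)
    cuts = [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]
    bounds = [0] + cuts + [len(sequence)]
    fragments = [sequence[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    peptides = []
    for start in range(len(fragments)):
        for miss in range(min(max_missed, len(fragments) - start - 1) + 1):
            pep = "".join(fragments[start : start + miss + 1])
            peptides.append(Peptide(pep, miss, len(pep) < 2))
    return peptides


# ---------------------------------------------------------------------------
# sample design / ground truth


@dataclass(frozen=True)
class Arm:
    tissue: str
    genotype: str
    n_replicates: int


@dataclass(frozen=True)
class FoldChangeSpec:
    """Distribution of planted log2 fold changes.

    ``log2fc`` is the central magnitude, ``log2_sd`` the spread, and
    ``direction`` one of ``"up"``, ``"down"`` or ``"both"`` (random sign).
    """

    log2fc: float = 1.0
    log2_sd: float = 0.0
    direction: str = "up"


@dataclass
class GroundTruth:
    """Planted truth for one simulated plex (or multi-tissue set of plexes)."""

    design: dict  # channel label -> (tissue, genotype, replicate index)
    base_abundance: dict  # accession -> positive real
    fold_change: dict  # (accession, (tissue, genotype)) -> positive real
    changed_set: set
    noise_cv: float
    seed: int

    def condition_of(self, channel: str) -> tuple[str, str]:
        tissue, genotype, _ = self.design[channel]
        return (tissue, genotype)

    def fc(self, accession: str, channel: str) -> float:
        return self.fold_change.get((accession, self.condition_of(channel)), 1.0)

    def design_frame(self) -> pd.DataFrame:
        rows = [
            {"channel": c, "tissue": t, "genotype": g, "replicate": r}
            for c, (t, g, r) in self.design.items()
        ]
        return pd.DataFrame(rows).set_index("channel")


def plant_design(
    design_spec: Sequence[Arm],
    proteins: Sequence[str],
    frac_changed: float,
    fc_spec: FoldChangeSpec = FoldChangeSpec(),
    reference_genotype: str = "WT",
    noise_cv: float = 0.10,
    seed: int = DEFAULT_SEED,
) -> GroundTruth:
    """Lay arms out on 10-plex channels and plant per-protein fold changes.

    Exactly one arm per tissue must carry the reference genotype; the
    reference condition has fold change 1 for every protein.  A fraction
    ``frac_changed`` of the proteins (rounded) receives a planted fold
    change, applied consistently to every non-reference condition.
    """
    if not 0 <= frac_changed <= 1:
        raise ValueError("frac_changed must be in [0, 1]")
    tissues = {}
    for arm in design_spec:
        tissues.setdefault(arm.tissue, []).append(arm)
    for tissue, arms in tissues.items():
        n_ref = sum(1 for a in arms if a.genotype == reference_genotype)
        if n_ref != 1:
            raise DesignError(
                f"tissue {tissue!r} has {n_ref} reference arms (need exactly 1)"
            )
    total = sum(a.n_replicates for a in design_spec)
    if total > len(TMT10_CHANNELS):
        raise DesignError(
            f"{total} samples exceed the {len(TMT10_CHANNELS)} channels of one plex"
        )
    design = {}
    i = 0
    for arm in design_spec:
        for rep in range(1, arm.n_replicates + 1):
            design[TMT10_CHANNELS[i]] = (arm.tissue, arm.genotype, rep)
            i += 1

    rng = np.random.default_rng(seed)
    accessions = list(proteins)
    n_changed = int(round(frac_changed * len(accessions)))
    changed = set(rng.choice(accessions, size=n_changed, replace=False)) if n_changed else set()

    # base abundance: broad lognormal, median ~5e3 per channel
    base = dict(
        zip(accessions, np.exp(rng.normal(math.log(5e3), 0.8, size=len(accessions))))
    )

    conditions = {(a.tissue, a.genotype) for a in design_spec}
    non_ref = {c for c in conditions if c[1] != reference_genotype}
    fold_change = {}
    for acc in sorted(changed):
        if fc_spec.direction == "up":
            sign = 1.0
        elif fc_spec.direction == "down":
            sign = -1.0
        elif fc_spec.direction == "both":
            sign = 1.0 if rng.random() < 0.5 else -1.0
        else:
            raise ValueError(f"unknown direction {fc_spec.direction!r}")
        lfc = sign * (fc_spec.log2fc + fc_spec.log2_sd * rng.standard_normal())
        for cond in non_ref:
            fold_change[(acc, cond)] = 2.0 ** lfc
    return GroundTruth(design, base, fold_change, changed, noise_cv, seed)


# ---------------------------------------------------------------------------
# PSM simulation


@dataclass
class PSMRecord:
    spectrum_id: str
    peptide_sequence: str
    protein_accessions: list
    charge: int
    xcorr: float
    delta_cn: float
    mass_error_ppm: float
    missed_cleavages: int
    peptide_length: int
    is_decoy: bool
    isolation_specificity: float
    reporter_peaks: list  # [(mz, intensity, noise), ...] sorted by mz
    is_entrapment: bool = False  # ground-truth flag: mismatched target PSM


def simulate_search_features(
    n_targets: int,
    n_decoys: int,
    entrapment_fraction: float = 0.0,
    xcorr_shift: float = 1.5,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Draw SEQUEST-style search features for target/decoy/entrapment PSMs.

    Correct target PSMs draw XCorr from N(3.5, 0.9) and small mass errors;
    decoys draw from a distribution shifted down by ``xcorr_shift`` with
    diffuse mass errors.  A fraction of the target-labelled PSMs are
    "entrapment" false targets and draw from the decoy-like distributions
    while keeping ``is_decoy=False`` — these are the known false positives
    used to measure realized FDR downstream.
    """
    rng = np.random.default_rng(seed)
    n_entrap = int(round(entrapment_fraction * n_targets))
    n_true = n_targets - n_entrap
    n = n_targets + n_decoys
    is_decoy = np.zeros(n, dtype=bool)
    is_decoy[n_targets:] = True
    is_entrap = np.zeros(n, dtype=bool)
    entrap_idx = rng.choice(n_targets, size=n_entrap, replace=False)
    is_entrap[entrap_idx] = True

    false_like = is_decoy | is_entrap  # decoy-distribution draws
    xcorr = np.where(
        false_like,
        rng.normal(3.5 - xcorr_shift, 0.9, n),
        rng.normal(3.5, 0.9, n),
    ).clip(0.1)
    delta_cn = np.where(
        false_like,
        rng.normal(0.08, 0.05, n),
        rng.normal(0.28, 0.08, n),
    ).clip(0.0, 1.0)
    mass_error = np.where(
        false_like,
        rng.uniform(-20.0, 20.0, n),
        rng.normal(0.0, 2.5, n).clip(-20.0, 20.0),
    )
    return pd.DataFrame(
        {
            "xcorr": xcorr,
            "delta_cn": delta_cn,
            "mass_error_ppm": mass_error,
            "missed_cleavages": rng.choice([0, 1, 2], size=n, p=[0.7, 0.25, 0.05]),
            "peptide_length": rng.integers(7, 36, size=n),
            "charge": rng.choice([2, 3, 4], size=n, p=[0.6, 0.3, 0.1]),
            "is_decoy": is_decoy,
            "is_entrapment": is_entrap,
        }
    )


def simulate_psm_table(
    truth: GroundTruth,
    proteome: Sequence[ProteinRecord],
    psms_per_protein: int = 15,
    interference_level: float = 0.1,
    decoy_fraction: float = 0.25,
    entrapment_fraction: float = 0.05,
    loading_cv: float = 0.05,
    xcorr_shift: float = 1.5,
    seed: int = DEFAULT_SEED,
) -> list[PSMRecord]:
    """Simulate an SPS-MS3 PSM table for one 10-plex.

    For a correctly matched target PSM of protein *p*, the true reporter
    signal in channel *c* is::

        base_abundance[p] * fold_change(p, condition(c))
            * peptide ionization factor * channel loading factor
            * Lognormal(mean 1, CV noise_cv)

    and the measured signal blends in a channel-uniform co-isolation term
    with weight ``(1 - isolation_specificity)``::

        measured_c = s * true_c + (1 - s) * interference_level * mean(true)

    where ``interference_level`` is the residual fraction of co-isolated
    signal surviving the SPS-MS3 stage.  Entrapment PSMs (mismatched target
    identifications) carry a channel-uniform, interference-like pattern and
    decoy-like search scores.  Decoy PSMs draw peptides from the reversed
    decoy entries.
    """
    rng = np.random.default_rng(seed)
    targets = [p for p in proteome if not p.is_decoy]
    decoys = [p for p in proteome if p.is_decoy]
    channels = list(truth.design)
    n_ch = len(channels)
    theo = np.array(TMT10_REPORTER_MZ[:n_ch])

    loading = np.exp(rng.normal(0.0, loading_cv, n_ch)) if loading_cv > 0 else np.ones(n_ch)
    sigma = math.sqrt(math.log(1.0 + truth.noise_cv**2)) if truth.noise_cv > 0 else 0.0

    def peptide_pool(protein):
        peps = [
            p
            for p in digest_tryptic(protein.sequence, 2)
            if not p.is_short and 7 <= len(p.sequence) <= 35
        ]
        return peps or [p for p in digest_tryptic(protein.sequence, 2) if not p.is_short]

    n_target_psms = psms_per_protein * len(targets)
    n_entrap = int(round(entrapment_fraction * n_target_psms))
    n_decoy_psms = int(round(decoy_fraction * n_target_psms))
    features = simulate_search_features(
        n_target_psms,
        n_decoy_psms,
        entrapment_fraction=0.0,
        xcorr_shift=xcorr_shift,
        seed=int(rng.integers(2**31)),
    )
    # decoy-like feature rows for entrapment PSMs
    entrap_rows = rng.choice(n_target_psms, size=n_entrap, replace=False)
    decoy_like = simulate_search_features(
        0, n_entrap, xcorr_shift=xcorr_shift, seed=int(rng.integers(2**31))
    )
    feat_cols = ["xcorr", "delta_cn", "mass_error_ppm"]
    features.loc[entrap_rows, feat_cols] = decoy_like[feat_cols].to_numpy()

    records: list[PSMRecord] = []
    spec_no = 0

    def make_peaks(intensities):
        jitter = rng.normal(0.0, 0.0004, n_ch)
        noise = np.exp(rng.normal(math.log(30.0), 0.2, n_ch))
        peaks = sorted(
            zip((theo + jitter).tolist(), intensities.tolist(), noise.tolist())
        )
        return [(float(m), float(i), float(nz)) for m, i, nz in peaks]

    # target (and entrapment) PSMs
    entrap_set = set(entrap_rows.tolist())
    row = 0
    for prot in targets:
        peps = peptide_pool(prot)
        fcs = np.array([truth.fc(prot.accession, c) for c in channels])
        base = truth.base_abundance[prot.accession]
        for _ in range(psms_per_protein):
            pep = peps[int(rng.integers(len(peps)))]
            f = features.iloc[row]
            is_entrap = row in entrap_set
            ion = math.exp(rng.normal(0.0, 1.2))
            spec = float(1.0 - 0.5 * rng.beta(1.2, 4.0))
            if is_entrap:
                # wrong match: flat, interference-like pattern
                true_sig = np.full(n_ch, base * ion)
            else:
                true_sig = base * fcs * ion * loading
            if sigma > 0:
                true_sig = true_sig * np.exp(
                    rng.normal(-0.5 * sigma**2, sigma, n_ch)
                )
            measured = spec * true_sig + (1.0 - spec) * interference_level * true_sig.mean()
            spec_no += 1
            records.append(
                PSMRecord(
                    spectrum_id=f"scan{spec_no:06d}",
                    peptide_sequence=pep.sequence,
                    protein_accessions=[prot.accession],
                    charge=int(f["charge"]),
                    xcorr=float(f["xcorr"]),
                    delta_cn=float(f["delta_cn"]),
                    mass_error_ppm=float(f["mass_error_ppm"]),
                    missed_cleavages=int(pep.missed_cleavages),
                    peptide_length=len(pep.sequence),
                    is_decoy=False,
                    isolation_specificity=spec,
                    reporter_peaks=make_peaks(measured),
                    is_entrapment=is_entrap,
                )
            )
            row += 1

    # decoy PSMs
    for r in range(n_decoy_psms):
        prot = decoys[int(rng.integers(len(decoys)))]
        peps = peptide_pool(prot)
        pep = peps[int(rng.integers(len(peps)))]
        f = features.iloc[n_target_psms + r]
        ion = math.exp(rng.normal(0.0, 1.2))
        spec = float(1.0 - 0.5 * rng.beta(1.2, 4.0))
        flat = np.full(n_ch, 2e3 * ion)
        if sigma > 0:
            flat = flat * np.exp(rng.normal(-0.5 * sigma**2, sigma, n_ch))
        spec_no += 1
        records.append(
            PSMRecord(
                spectrum_id=f"scan{spec_no:06d}",
                peptide_sequence=pep.sequence,
                protein_accessions=[prot.accession],
                charge=int(f["charge"]),
                xcorr=float(f["xcorr"]),
                delta_cn=float(f["delta_cn"]),
                mass_error_ppm=float(f["mass_error_ppm"]),
                missed_cleavages=int(pep.missed_cleavages),
                peptide_length=len(pep.sequence),
                is_decoy=True,
                isolation_specificity=spec,
                reporter_peaks=make_peaks(flat),
            )
        )
    return records


# ---------------------------------------------------------------------------
# annotations (GO-style)


def simulate_annotations(
    proteins: Sequence[str],
    n_terms: int = 60,
    size_range: tuple[int, int] = (10, 200),
    namespaces: Sequence[str] = ("BP", "MF", "CC"),
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Random protein->term annotation table (protein_id, term_id, term_name,
    namespace) for exercising over-representation analysis."""
    rng = np.random.default_rng(seed)
    proteins = list(proteins)
    rows = []
    for i in range(n_terms):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        size = min(size, len(proteins))
        members = rng.choice(proteins, size=size, replace=False)
        ns = namespaces[i % len(namespaces)]
        tid = f"GO:{i + 1:07d}"
        for p in members:
            rows.append((p, tid, f"synthetic term {i + 1}", ns))
    return pd.DataFrame(
        rows, columns=["protein_id", "term_id", "term_name", "namespace"]
    )


# ---------------------------------------------------------------------------
# photoconversion pulse-chase decay


@dataclass(frozen=True)
class DecayParams:
    span_fast: float
    k_fast: float
    span_slow: float
    k_slow: float
    plateau: float = 0.0

    def curve(self, t):
        t = np.asarray(t, dtype=float)
        return (
            self.span_fast * np.exp(-self.k_fast * t)
            + self.span_slow * np.exp(-self.k_slow * t)
            + self.plateau
        )


def simulate_decay_course(
    params: DecayParams | tuple,
    timepoints: Sequence[float],
    events_per_timepoint: int = 1000,
    event_cv: float = 0.05,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Per-event (time, rfp, cfp) table following a two-phase decay.

    The expected RFP/CFP ratio at time t is
    ``span_fast*exp(-k_fast*t) + span_slow*exp(-k_slow*t) + plateau``;
    per-event multiplicative noise is lognormal with mean 1 and the given CV.
    """
    if not isinstance(params, DecayParams):
        params = DecayParams(*params)
    if params.k_fast <= params.k_slow:
        raise ValueError("require k_fast > k_slow")
    if params.k_slow < 0 or params.span_fast < 0 or params.span_slow < 0:
        raise ValueError("rates and spans must be nonnegative")
    if events_per_timepoint < 1:
        raise ValueError("events_per_timepoint must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + event_cv**2)) if event_cv > 0 else 0.0
    rows = []
    for t in timepoints:
        mean_ratio = float(params.curve(t))
        cfp = np.exp(rng.normal(math.log(1000.0), 0.3, events_per_timepoint))
        if sigma > 0:
            ratio = mean_ratio * np.exp(
                rng.normal(-0.5 * sigma**2, sigma, events_per_timepoint)
            )
        else:
            ratio = np.full(events_per_timepoint, mean_ratio)
        for c, r in zip(cfp, ratio):
            rows.append((float(t), float(r * c), float(c)))
    return pd.DataFrame(rows, columns=["time_h", "rfp", "cfp"])


# ---------------------------------------------------------------------------
# default desk-scale design


def default_design() -> list[Arm]:
    """The default single-tissue 3 vs 3 comparison used throughout the tests."""
    return [Arm("brain", "WT", 3), Arm("brain", "KO", 3)]
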
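"""End-to-end orchestration: generate -> extract -> QC -> FDR -> inference ->
quantify -> normalize -> differential -> enrichment (+ decay), with a
provenance manifest recording the configuration hash, seeds, and row counts
in and out of every filtering stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .confidence import protein_level_fdr, score_and_filter_psms
from .decay import fit_decay_table
from .diffstats import volcano_table
from .enrichment import go_ora
from .inference import assemble_parsimony, groups_frame
from .masses import TMT10_CHANNELS
from .meta import DEFAULT_ALTERED_FRACTION
from .quantify import (
    QuantMatrix,
    cv_filter,
    label_check_factors,
    normalize_equal_loading,
    rollup_protein,
)
from .reporter import quantify_psms
from .simulate import (
    Arm,
    FoldChangeSpec,
    default_design,
    generate_proteome,
    plant_design,
    simulate_annotations,
    simulate_decay_course,
    simulate_psm_table,
)


@dataclass
class RunConfig:
    """All thresholds and study-condition knobs of one pipeline run."""

    # synthetic study conditions
    n_proteins: int = 2000
    psms_per_protein: int = 15
    frac_changed: float = 0.05
    planted_log2fc: float = 1.0
    fc_direction: str = "up"
    noise_cv: float = 0.10
    interference_level: float = 0.1
    decoy_fraction: float = 0.25
    entrapment_fraction: float = 0.05
    loading_cv: float = 0.05
    arms: list = field(default_factory=lambda: [["brain", "WT", 3], ["brain", "KO", 3]])
    contrast: list = field(default_factory=lambda: ["KO", "WT"])
    seed: int = 17
    # stage toggles
    qc_enabled: bool = True
    fdr_enabled: bool = True
    cv_filter_enabled: bool = True
    enrichment_enabled: bool = True
    decay_enabled: bool = False
    # thresholds (the printed filter values)
    reporter_window_da: float = 0.003
    min_summed_sn: float = 100.0
    min_isolation_specificity: float = 0.7
    psm_fdr: float = 0.01
    protein_fdr: float = 0.01
    cv_threshold: float = 0.20
    alpha: float = 0.05
    meta_threshold: float = DEFAULT_ALTERED_FRACTION
    age_fc_threshold: float = 0.25
    apex_fold: float = 1.5
    # decay stage conditions
    decay_params: list = field(default_factory=lambda: [0.6, 0.5, 0.4, 0.05, 0.0])
    decay_timepoints: list = field(default_factory=lambda: [0, 1, 2, 4, 8, 16, 24])
    decay_events_per_timepoint: int = 500
    decay_event_cv: float = 0.05

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_end_to_end(config: RunConfig, outdir) -> dict:
    """Execute every configured stage, writing all outputs under ``outdir``.

    Returns the provenance manifest (also written as ``manifest.json``).
    Any stage failure raises :class:`StageError` naming the stage; outputs
    of completed stages are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage, **counts):
        manifest["stages"][stage] = counts

    def _write_manifest():
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    stage = "simulate"
    try:
        proteome = generate_proteome(config.n_proteins, seed=config.seed)
        arms = [Arm(*a) for a in config.arms]
        truth = plant_design(
            arms,
            [p.accession for p in proteome if not p.is_decoy],
            config.frac_changed,
            FoldChangeSpec(config.planted_log2fc, 0.0, config.fc_direction),
            noise_cv=config.noise_cv,
            seed=config.seed,
        )
        psms = simulate_psm_table(
            truth,
            proteome,
            psms_per_protein=config.psms_per_protein,
            interference_level=config.interference_level,
            decoy_fraction=config.decoy_fraction,
            entrapment_fraction=config.entrapment_fraction,
            loading_cv=config.loading_cv,
            seed=config.seed,
        )
        pio.write_fasta(proteome, outdir / "proteome.fasta")
        design = truth.design_frame()
        pio.write_design_tsv(design, outdir / "design.tsv")
        frame = pio.psms_to_frame(psms)
        pio.write_psm_tsv(frame, outdir / "psms.tsv")
        record(stage, n_proteins=len(proteome) // 2, n_psms=len(frame),
               n_changed=len(truth.changed_set))
    except Exception as exc:
        _write_manifest()
        raise StageError(stage, exc) from exc

    stage = "reporter_qc"
    try:
        quant = quantify_psms(
            frame,
            window=config.reporter_window_da,
            min_summed_sn=config.min_summed_sn,
            min_specificity=config.min_isolation_specificity,
        )
        if not config.qc_enabled:
            quant["qc_keep"] = True
            quant["qc_reason"] = ""
        reasons = quant.loc[~quant["qc_keep"], "qc_reason"].value_counts().to_dict()
        pio.write_psm_tsv(quant.drop(columns=["reporter_peaks"]), outdir / "psm_quant.tsv")
        record(stage, n_in=len(quant), n_kept=int(quant["qc_keep"].sum()),
               n_dropped=int((~quant["qc_keep"]).sum()), drop_reasons=reasons)
    except Exception as exc:
        _write_manifest()
        raise StageError(stage, exc) from exc

    stage = "psm_confidence"
    try:
        scored, model = score_and_filter_psms(quant, level=config.psm_fdr)
        if not config.fdr_enabled:
            scored["kept"] = ~scored["is_decoy"]
        confident_proteins, protein_table = protein_level_fdr(
            scored, level=config.protein_fdr
        )
        pio.write_psm_tsv(
            scored.drop(columns=["reporter_peaks"]), outdir / "psm_scores.tsv"
        )
        protein_table.to_csv(outdir / "protein_fdr.tsv", sep="\t", index=False)
        record(
            stage,
            n_in=len(scored),
            n_kept_psms=int(scored["kept"].sum()),
            n_dropped_psms=int(len(scored) - scored["kept"].sum()),
            n_confident_proteins=len(confident_proteins),
        )
    except Exception as exc:
        _write_manifest()
        raise StageError(stage, exc) from exc

    stage = "protein_inference"
    try:
        usable = scored[scored["kept"] & scored["qc_keep"]]
        pep_map: dict = {}
        for pep, accs in zip(usable["peptide_sequence"], usable["protein_accessions"]):
            accs = [a for a in accs if a in confident_proteins]
            if accs:
                pep_map.setdefault(pep, set()).update(accs)
        groups = assemble_parsimony(pep_map)
        groups_frame(groups).to_csv(outdir / "protein_groups.tsv", sep="\t", index=False)
        rep_of = {}
        for g in groups:
            for pep in g.unique_peptides | g.shared_peptides:
                rep_of[pep] = g.representative
        record(stage, n_peptides=len(pep_map), n_groups=len(groups))
    except Exception as exc:
        _write_manifest()
        raise StageError(stage, exc) from exc

    stage = "quantify"
    try:
        chan_cols = [f"intensity_{c}" for c in TMT10_CHANNELS if c in design.index]
        usable_q = usable[usable["peptide_sequence"].isin(rep_of)]
        pep_values = (
            usable_q.groupby("peptide_sequence")[chan_cols].sum()
        )
        pep_values.columns = [c.removeprefix("intensity_") for c in pep_values.columns]
        factors = label_check_factors(pep_values.sum(axis=0).to_numpy())
        rep_groups = {
            f"{t}/{g}": list(design.index[(design["tissue"] == t) & (design["genotype"] == g)])
            for t, g in design[["tissue", "genotype"]].drop_duplicates().itertuples(index=False)
        }
        if config.cv_filter_enabled:
            keep, reason = cv_filter(pep_values, rep_groups, threshold=config.cv_threshold)
        else:
            keep = pd.Series(True, index=pep_values.index)
            reason = pd.Series("", index=pep_values.index)
        kept_values = pep_values[keep]
        assign = pd.Series({p: rep_of[p] for p in kept_values.index})
        qm = rollup_protein(kept_values, assign, design)
        qm.log("label_check_factors", factors=[float(f) for f in factors])
        qm_norm = normalize_equal_loading(qm)
        pio.write_quant_tsv(qm, outdir / "quant_raw.tsv")
        pio.write_quant_tsv(qm_norm, outdir / "quant_normalized.tsv")
        record(
            stage,
            n_peptides_in=len(pep_values),
            n_peptides_kept=int(keep.sum()),
            n_peptides_dropped=int((~keep).sum()),
            n_proteins=len(qm.values),
        )
    except Exception as exc:
        _write_manifest()
        raise StageError(stage, exc) from exc

    stage = "differential"
    try:
        volcano = volcano_table(qm_norm, tuple(config.contrast), alpha=config.alpha)
        volcano.to_csv(outdir / "volcano.tsv", sep="\t", index=False)
        record(
            stage,
            n_proteins=len(volcano),
            n_significant=int(volcano["significant"].sum()),
        )
    except Exception as exc:
        _write_manifest()
        raise StageError(stage, exc) from exc

    if config.enrichment_enabled:
        stage = "enrichment"
        try:
            background = set(volcano["protein"])
            annotations = simulate_annotations(sorted(background), seed=config.seed)
            annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)
            sig = volcano[volcano["significant"]]
            up = set(sig.loc[sig["log2_ratio"] > 0, "protein"])
            down = set(sig.loc[sig["log2_ratio"] < 0, "protein"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ora_up = go_ora(up, background, annotations, direction="up")
                ora_down = go_ora(down, background, annotations, direction="down")
            ora = pd.concat([ora_up, ora_down], ignore_index=True)
            ora.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            record(stage, n_terms=len(ora), n_query_up=len(up), n_query_down=len(down))
        except Exception as exc:
            _write_manifest()
            raise StageError(stage, exc) from exc

    if config.decay_enabled:
        stage = "decay"
        try:
            events = simulate_decay_course(
                tuple(config.decay_params),
                config.decay_timepoints,
                config.decay_events_per_timepoint,
                config.decay_event_cv,
                seed=config.seed,
            )
            events["construct"] = "synthetic"
            events["genotype"] = "WT"
            fits = fit_decay_table(events)
            events.to_csv(outdir / "decay_events.tsv", sep="\t", index=False)
            fits.to_csv(outdir / "decay_fits.tsv", sep="\t", index=False)
            record(stage, n_events=len(events), n_fits=len(fits))
        except Exception as exc:
            _write_manifest()
            raise StageError(stage, exc) from exc

    config.to_yaml(outdir / "config.yaml")
    _write_manifest()
    return manifest
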
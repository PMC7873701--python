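"""File formats: FASTA databases, PSM/design/annotation TSVs, quant matrices.

The PSM TSV carries the MS3 reporter-region peak list in one column encoded
``mz:intensity:noise;mz:intensity:noise;...`` so tables stay plain text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import fasta as _fasta

from .quantify import QuantMatrix
from .simulate import PSMRecord, ProteinRecord


def write_fasta(proteome: Sequence[ProteinRecord], path) -> None:
    entries = [(p.accession, p.sequence) for p in proteome]
    _fasta.write(entries, str(path), file_mode="w")


def read_fasta(path, decoy_prefix: str = "rev_") -> list[ProteinRecord]:
    records = []
    with _fasta.read(str(path)) as reader:
        for header, seq in reader:
            acc = header.split()[0]
            records.append(ProteinRecord(acc, seq, acc.startswith(decoy_prefix)))
    return records


def encode_peaks(peaks) -> str:
    return ";".join(f"{m:.6f}:{i:.4f}:{n:.4f}" for m, i, n in peaks)


def decode_peaks(text: str) -> list:
    if not text:
        return []
    out = []
    for chunk in text.split(";"):
        m, i, n = chunk.split(":")
        out.append((float(m), float(i), float(n)))
    return out


def psms_to_frame(records: Iterable[PSMRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = vars(r).copy()
        d["protein_accessions"] = list(r.protein_accessions)
        rows.append(d)
    return pd.DataFrame(rows)


def write_psm_tsv(frame_or_records, path) -> None:
    frame = (
        frame_or_records
        if isinstance(frame_or_records, pd.DataFrame)
        else psms_to_frame(frame_or_records)
    )
    out = frame.copy()
    if "reporter_peaks" in out and len(out) and not isinstance(out["reporter_peaks"].iloc[0], str):
        out["reporter_peaks"] = out["reporter_peaks"].map(encode_peaks)
    if "protein_accessions" in out and len(out) and not isinstance(out["protein_accessions"].iloc[0], str):
        out["protein_accessions"] = out["protein_accessions"].map(";".join)
    out.to_csv(path, sep="\t", index=False)


def read_psm_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "reporter_peaks" in frame:
        frame["reporter_peaks"] = frame["reporter_peaks"].fillna("").map(decode_peaks)
    if "protein_accessions" in frame:
        frame["protein_accessions"] = frame["protein_accessions"].map(
            lambda s: s.split(";") if isinstance(s, str) else []
        )
    return frame


def write_design_tsv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=True, index_label="channel")


def read_design_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("channel")


def write_quant_tsv(matrix: QuantMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index=True, index_label="protein")


def read_quant_tsv(path, design: pd.DataFrame) -> QuantMatrix:
    values = pd.read_csv(path, sep="\t").set_index("protein")
    return QuantMatrix(values, design)
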
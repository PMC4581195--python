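"""File-based plumbing: training manifests, corpus loading, prediction files.

The training manifest is a plain TSV with one row per sequence:
``id  fasta  labels  pssm  hhm  ss8  acc3  fold`` — optional columns may hold
``-`` when a feature class is absent (e.g. sequence-only training).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .features import (AminoAcidTables, FEATURE_MODES, assemble_features,
                       read_fasta, read_profile, read_structure)
from .labels import label_from_annotation, read_label_file
from .training import TrainingCorpus
from .types import FeatureMatrix

MANIFEST_COLUMNS = ("id", "fasta", "labels", "pssm", "hhm", "ss8", "acc3", "fold")


@dataclass
class ManifestRow:
    id: str
    fasta: str
    labels: str
    pssm: str = "-"
    hhm: str = "-"
    ss8: str = "-"
    acc3: str = "-"
    fold: int = 0


def read_manifest(path) -> list:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(MANIFEST_COLUMNS[:3]) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: manifest is missing required columns {sorted(missing)}")
        for rec in reader:
            rows.append(ManifestRow(
                id=rec["id"], fasta=rec["fasta"], labels=rec["labels"],
                pssm=rec.get("pssm", "-") or "-", hhm=rec.get("hhm", "-") or "-",
                ss8=rec.get("ss8", "-") or "-", acc3=rec.get("acc3", "-") or "-",
                fold=int(rec.get("fold", 0) or 0)))
    if not rows:
        raise ValueError(f"{path}: manifest has no data rows")
    return rows


def _features_for_row(row: ManifestRow, sequence: str, tables: AminoAcidTables,
                      mode: str) -> FeatureMatrix:
    need = FEATURE_MODES[mode]
    profile = structure = None
    if "evo" in need:
        if row.pssm == "-" or row.hhm == "-":
            raise ValueError(
                f"sequence {row.id}: feature mode {mode!r} needs pssm and hhm files"
            )
        profile = read_profile(row.pssm, row.hhm, sequence)
    if "struct" in need:
        if row.ss8 == "-" or row.acc3 == "-":
            raise ValueError(
                f"sequence {row.id}: feature mode {mode!r} needs ss8 and acc3 files"
            )
        structure = read_structure(row.ss8, row.acc3)
    return assemble_features(sequence, tables=tables, profile=profile,
                             structure=structure, mode=mode, sequence_id=row.id)


def load_corpus(manifest_path, mode: str = "full",
                tables: AminoAcidTables = None) -> TrainingCorpus:
    """Build a training corpus from a manifest, masking removed residues.

    Residues masked by the label rules (the ``N`` annotation) are dropped from
    both labels and feature rows so every corpus item is fully observed.
    """
    rows = read_manifest(manifest_path)
    if tables is None:
        tables = AminoAcidTables.default()
    fasta_cache: dict = {}
    label_cache: dict = {}
    items, ids, folds = [], [], []
    for row in rows:
        if row.fasta not in fasta_cache:
            fasta_cache[row.fasta] = read_fasta(row.fasta)
        if row.labels not in label_cache:
            label_cache[row.labels] = read_label_file(row.labels)
        seqs = fasta_cache[row.fasta]
        if row.id not in seqs:
            raise ValueError(f"sequence {row.id} not found in {row.fasta}")
        anns = label_cache[row.labels]
        if row.id not in anns:
            raise ValueError(f"sequence {row.id} not found in {row.labels}")
        sequence = seqs[row.id]
        labels = label_from_annotation(anns[row.id])
        if len(labels) != len(sequence):
            raise ValueError(
                f"sequence {row.id}: {len(sequence)} residues but {len(labels)} labels"
            )
        x = _features_for_row(row, sequence, tables, mode)
        dense, kept = labels.compressed()
        x = FeatureMatrix(x.values[kept], x.sequence_id, x.manifest)
        items.append((x, dense))
        ids.append(row.id)
        folds.append(row.fold)
    return TrainingCorpus(items=items, ids=ids, fold_assignment=np.asarray(folds))


def write_predictions(path, records, threshold: float, header_lines=()) -> None:
    """Write the tabular prediction file: id, pos, residue, probability, call.

    ``records`` yields (id, sequence, probabilities, mask); masked residues are
    reported with an empty probability and the sentinel call ``-``.
    """
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("id\tpos\tresidue\tprob_disorder\tcall\n")
        for name, sequence, probs, mask in records:
            j = 0
            for i, aa in enumerate(sequence):
                if mask is not None and not mask[i]:
                    fh.write(f"{name}\t{i + 1}\t{aa}\t\t-\n")
                    continue
                p = probs[j]
                j += 1
                call = 1 if p >= threshold else 0
                fh.write(f"{name}\t{i + 1}\t{aa}\t{p:.6f}\t{call}\n")


def read_predictions(path) -> dict:
    """Read a prediction file back: id -> (positions, probabilities, calls)."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", comment="#")
    out = {}
    for name, grp in df.groupby("id", sort=False):
        obs = grp[grp["call"] != "-"] if grp["call"].dtype == object else grp
        out[name] = (obs["pos"].to_numpy(int), obs["prob_disorder"].to_numpy(float),
                     obs["call"].to_numpy(int))
    return out
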
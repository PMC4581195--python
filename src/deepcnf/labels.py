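"""Order/disorder labels from missing-coordinate annotations (CASP convention).

Annotation alphabet, one character per residue:

* ``O`` — observed in the crystal structure,
* ``D`` — atomic coordinates missing,
* ``N`` — residue not available (removed from the chain and masked out),
* ``X`` — explicit coordinates-missing mark, always labeled disordered.

A maximal run of coordinate-lacking residues (``D`` or ``X``) longer than
three residues is labeled disordered; shorter runs are labeled ordered, except
that ``X`` positions are forced to disorder regardless of run length. ``N``
residues are removed before run lengths are measured (so a run interrupted
only by ``N`` counts as one run) and reported as masked positions.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import DISORDER, ORDER, LabelSequence

ANNOTATION_ALPHABET = set("ODNX")
MIN_DISORDER_RUN = 4  # "longer than three residues"

SEGMENT_BINS = ((1, 5), (6, 15), (16, 25), (26, None))
SEGMENT_BIN_NAMES = ("1-5", "6-15", "16-25", ">25")


def label_from_annotation(annotation: str) -> LabelSequence:
    """Convert a per-residue coordinate annotation into order/disorder labels."""
    ann = annotation.strip().upper()
    if not ann:
        raise ValueError("empty annotation")
    bad = set(ann) - ANNOTATION_ALPHABET
    if bad:
        raise ValueError(f"annotation contains characters outside {{O,D,N,X}}: {sorted(bad)}")
    chars = np.array(list(ann))
    mask = chars != "N"
    kept = chars[mask]

    missing = (kept == "D") | (kept == "X")
    states_kept = np.full(kept.shape, ORDER, dtype=np.int8)
    # maximal runs of coordinate-lacking residues on the N-removed chain
    i = 0
    n = len(kept)
    while i < n:
        if missing[i]:
            j = i
            while j < n and missing[j]:
                j += 1
            if j - i >= MIN_DISORDER_RUN:
                states_kept[i:j] = DISORDER
            i = j
        else:
            i += 1
    states_kept[kept == "X"] = DISORDER  # the X rule overrides the run-length rule

    states = np.full(chars.shape, -1, dtype=np.int8)
    states[mask] = states_kept
    return LabelSequence(states, mask)


def _segments(labels: LabelSequence):
    """(start, length, terminal) of each disorder segment on the unmasked chain."""
    dense, _ = labels.compressed()
    y = dense.states
    n = len(y)
    out = []
    i = 0
    while i < n:
        if y[i] == DISORDER:
            j = i
            while j < n and y[j] == DISORDER:
                j += 1
            out.append((i, j - i, i == 0 or j == n))
            i = j
        else:
            i += 1
    return out


def disorder_segment_stats(labels) -> pd.DataFrame:
    """Count non-terminal disorder segments per length bin (1-5, 6-15, 16-25, >25).

    Terminal segments (touching either chain end) are excluded. Returns a
    table with residue totals and fragment counts per bin.
    """
    residues = np.zeros(len(SEGMENT_BINS), dtype=int)
    fragments = np.zeros(len(SEGMENT_BINS), dtype=int)
    for seq in labels:
        for _, length, terminal in _segments(seq):
            if terminal:
                continue
            for b, (lo, hi) in enumerate(SEGMENT_BINS):
                if length >= lo and (hi is None or length <= hi):
                    residues[b] += length
                    fragments[b] += 1
                    break
    return pd.DataFrame(
        {"residues": residues, "fragments": fragments},
        index=pd.Index(SEGMENT_BIN_NAMES, name="segment_length"),
    )


def labels_to_annotation(labels: LabelSequence) -> str:
    """Inverse mapping: masked -> N, order -> O, disorder -> D or X.

    Disorder runs longer than three residues survive the run-length rule as
    plain ``D``; shorter disorder segments are only representable through the
    ``X`` mark, so they are written as ``X`` and the annotation round-trips
    exactly through :func:`label_from_annotation`.
    """
    n = len(labels)
    out = np.array(["O"] * n)
    out[~labels.mask] = "N"
    dense, kept = labels.compressed()
    for start, length, _ in _segments(labels):
        mark = "D" if length >= MIN_DISORDER_RUN else "X"
        out[kept[start:start + length]] = mark
    return "".join(out)


def read_label_file(path) -> dict:
    """Two-column TSV (id, annotation string over {O,D,N,X}) -> id -> annotation."""
    out = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'id<TAB>annotation'")
            out[parts[0]] = parts[1]
    if not out:
        raise ValueError(f"{path}: no label rows found")
    return out


def write_label_file(path, annotations: dict) -> None:
    with open(path, "w") as fh:
        fh.write("# per-residue coordinate annotation: O observed, D missing, "
                 "N not-available, X CASP disorder mark\n")
        for name, ann in annotations.items():
            fh.write(f"{name}\t{ann}\n")
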
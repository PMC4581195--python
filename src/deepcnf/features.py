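"""Per-residue feature construction for order/disorder prediction.

The full feature vector has 129 columns per residue, in three classes:

* amino-acid related (78 = 20 indicator + 7 physico-chemical + 11
  secondary-structure endpoint propensities + 40 correlated contact
  potentials),
* evolution related (40 = 20 PSI-BLAST PSSM columns + 20 profile-HMM match
  emission probabilities),
* structure related (11 = 8-state secondary-structure + 3-state solvent
  accessibility probabilities from an upstream predictor).

Raw PSSM log-odds scores are squashed elementwise through a sigmoid so all
inputs to the convolution stack are bounded; HHM emissions are already
probabilities and enter unchanged. The squashing is configurable.

Ablation modes drop whole feature classes (e.g. ``ami_only`` for the
sequence-only predictor); a missing class is never silently zero-filled.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit

from .types import FeatureMatrix

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"  # canonical column/row order used throughout
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
# non-standard one-letter codes folded into the unknown residue X
AMBIGUOUS_TO_X = {"B", "Z", "U", "O", "J"}

SS8_STATES = ("H", "G", "I", "E", "B", "T", "S", "C")
ACC3_STATES = ("B", "M", "E")  # buried / medium / exposed

AA_BLOCK_WIDTH = 78
EVO_BLOCK_WIDTH = 40
STRUCT_BLOCK_WIDTH = 11

#: feature classes included by each assembly mode, in fixed order
FEATURE_MODES = {
    "full": ("ami", "evo", "struct"),
    "ami_only": ("ami",),
    "evo_only": ("evo",),
    "struct_only": ("struct",),
    "ami_evo": ("ami", "evo"),
    "ami_struct": ("ami", "struct"),
    "evo_struct": ("evo", "struct"),
}
BLOCK_WIDTHS = {"ami": AA_BLOCK_WIDTH, "evo": EVO_BLOCK_WIDTH, "struct": STRUCT_BLOCK_WIDTH}

MANIFEST_VERSION = 1


class ParseError(ValueError):
    """Malformed external file; message carries the file and line/position."""


# ---------------------------------------------------------------------------
# amino-acid property tables
# ---------------------------------------------------------------------------


def _read_table(handle_or_path, expect_cols: int) -> np.ndarray:
    df = pd.read_csv(handle_or_path, sep="\t", comment="#", index_col=0)
    if list(df.index) != list(AA_ALPHABET) or df.shape[1] != expect_cols:
        raise ParseError(
            f"amino-acid table must have the 20 standard residues in order "
            f"{AA_ALPHABET} and {expect_cols} value columns; got shape {df.shape}"
        )
    return df.to_numpy(dtype=float)


@dataclass(frozen=True)
class AminoAcidTables:
    """Fixed per-residue property tables used by the amino-acid feature block.

    The packaged physico-chemical table carries literature values; the 11-column
    SS-endpoint and 40-column contact-potential tables shipped with the package
    are synthetic stand-ins (see their file headers) and can be replaced with
    literature tables via :meth:`from_files`.
    """

    physico_chemical: np.ndarray  # 20 x 7
    ss_endpoint: np.ndarray       # 20 x 11
    contact_potential: np.ndarray  # 20 x 40

    def __post_init__(self):
        for name, arr, w in (("physico_chemical", self.physico_chemical, 7),
                             ("ss_endpoint", self.ss_endpoint, 11),
                             ("contact_potential", self.contact_potential, 40)):
            if arr.shape != (20, w):
                raise ValueError(f"{name} table must be 20x{w}, got {arr.shape}")

    @classmethod
    def default(cls) -> "AminoAcidTables":
        pkg = resources.files("deepcnf") / "tables"
        return cls(
            physico_chemical=_read_table((pkg / "physico_chemical.tsv").open(), 7),
            ss_endpoint=_read_table((pkg / "ss_endpoint_propensity.synthetic.tsv").open(), 11),
            contact_potential=_read_table((pkg / "contact_potential.synthetic.tsv").open(), 40),
        )

    @classmethod
    def from_files(cls, physico_chemical, ss_endpoint, contact_potential) -> "AminoAcidTables":
        return cls(
            physico_chemical=_read_table(physico_chemical, 7),
            ss_endpoint=_read_table(ss_endpoint, 11),
            contact_potential=_read_table(contact_potential, 40),
        )


def normalize_residue(letter: str, position: int) -> str:
    """Uppercase a residue letter, folding ambiguity codes into X."""
    r = letter.upper()
    if r in AMBIGUOUS_TO_X:
        return "X"
    if r != "X" and r not in AA_INDEX:
        raise ValueError(f"unknown residue letter {letter!r} at position {position + 1}")
    return r


def aa_features(sequence: str, tables: AminoAcidTables) -> np.ndarray:
    """L x 78 amino-acid block: indicator(20) | physico-chemical(7) | endpoint(11) | contact(40).

    Unknown residues (X) get an all-zero indicator and the column mean of each
    property table.
    """
    length = len(sequence)
    out = np.empty((length, AA_BLOCK_WIDTH))
    tabs = (tables.physico_chemical, tables.ss_endpoint, tables.contact_potential)
    means = [t.mean(axis=0) for t in tabs]
    for i, letter in enumerate(sequence):
        r = normalize_residue(letter, i)
        ind = np.zeros(20)
        if r == "X":
            rows = means
        else:
            j = AA_INDEX[r]
            ind[j] = 1.0
            rows = [t[j] for t in tabs]
        out[i] = np.concatenate([ind] + list(rows))
    return out


# ---------------------------------------------------------------------------
# evolutionary profiles
# ---------------------------------------------------------------------------


@dataclass
class SequenceProfile:
    """Evolutionary profile: raw PSSM log-odds scores and HHM match-emission probabilities."""

    pssm: np.ndarray  # L x 20, canonical residue order
    hhm: np.ndarray   # L x 20, probabilities

    def __post_init__(self):
        self.pssm = np.asarray(self.pssm, dtype=float)
        self.hhm = np.asarray(self.hhm, dtype=float)
        if self.pssm.shape != self.hhm.shape or self.pssm.ndim != 2 or self.pssm.shape[1] != 20:
            raise ValueError(
                f"pssm and hhm must both be L x 20, got {self.pssm.shape} and {self.hhm.shape}"
            )
        if not (np.all(np.isfinite(self.pssm)) and np.all(np.isfinite(self.hhm))):
            raise ValueError("profile contains non-finite values")

    def __len__(self) -> int:
        return self.pssm.shape[0]


def evo_features(profile: SequenceProfile, pssm_transform: str = "sigmoid") -> np.ndarray:
    """L x 40 evolution block: squashed PSSM(20) | HHM probabilities(20)."""
    if pssm_transform == "sigmoid":
        p = expit(profile.pssm)
    elif pssm_transform == "identity":
        p = profile.pssm
    else:
        raise ValueError(f"unknown pssm_transform {pssm_transform!r}")
    return np.concatenate([p, profile.hhm], axis=1)


# ---------------------------------------------------------------------------
# predicted local structure
# ---------------------------------------------------------------------------


@dataclass
class StructurePrediction:
    """Predicted SS8 and ACC3 probability rows; each row must sum to 1 (tolerance 1e-3)."""

    ss8: np.ndarray  # L x 8
    acc3: np.ndarray  # L x 3

    def __post_init__(self):
        self.ss8 = np.asarray(self.ss8, dtype=float)
        self.acc3 = np.asarray(self.acc3, dtype=float)
        if self.ss8.ndim != 2 or self.ss8.shape[1] != 8:
            raise ValueError(f"ss8 must be L x 8, got {self.ss8.shape}")
        if self.acc3.shape != (self.ss8.shape[0], 3):
            raise ValueError(
                f"acc3 must be L x 3 with the same L as ss8, got {self.acc3.shape}"
            )
        for name, arr in (("ss8", self.ss8), ("acc3", self.acc3)):
            if np.any(arr < 0):
                bad = int(np.argwhere(arr < 0)[0, 0])
                raise ValueError(f"{name} row {bad + 1} has a negative probability")
            sums = arr.sum(axis=1)
            off = np.abs(sums - 1.0) > 1e-3
            if off.any():
                bad = int(np.flatnonzero(off)[0])
                raise ValueError(
                    f"{name} row {bad + 1} sums to {sums[bad]:.4f}, expected 1 within 1e-3"
                )

    def __len__(self) -> int:
        return self.ss8.shape[0]


def struct_features(sp: StructurePrediction) -> np.ndarray:
    """L x 11 structure block: SS8 | ACC3, passed through unchanged."""
    return np.concatenate([sp.ss8, sp.acc3], axis=1)


# ---------------------------------------------------------------------------
# assembly and the column manifest
# ---------------------------------------------------------------------------


def feature_manifest(mode: str, pssm_transform: str = "sigmoid") -> str:
    """Frozen description of the feature columns an assembly produces."""
    blocks = FEATURE_MODES[mode]
    spec = ",".join(f"{b}:{BLOCK_WIDTHS[b]}" for b in blocks)
    return (f"v{MANIFEST_VERSION};mode={mode};blocks={spec};"
            f"pssm_transform={pssm_transform}")


def assemble_features(sequence: str, tables: AminoAcidTables = None,
                      profile: SequenceProfile = None,
                      structure: StructurePrediction = None,
                      mode: str = "full", pssm_transform: str = "sigmoid",
                      sequence_id: str = "") -> FeatureMatrix:
    """Build the per-residue feature matrix for one chain.

    ``mode`` selects which feature classes enter (see ``FEATURE_MODES``);
    every class the mode requires must be supplied — absent classes are an
    error, never zero-filled.
    """
    if mode not in FEATURE_MODES:
        raise ValueError(f"unknown feature mode {mode!r}; choose from {sorted(FEATURE_MODES)}")
    blocks = []
    for block in FEATURE_MODES[mode]:
        if block == "ami":
            if tables is None:
                tables = AminoAcidTables.default()
            blocks.append(aa_features(sequence, tables))
        elif block == "evo":
            if profile is None:
                raise ValueError(f"mode {mode!r} needs an evolutionary profile, none given")
            if len(profile) != len(sequence):
                raise ValueError(
                    f"profile length {len(profile)} != sequence length {len(sequence)}"
                )
            blocks.append(evo_features(profile, pssm_transform))
        else:
            if structure is None:
                raise ValueError(f"mode {mode!r} needs structure predictions, none given")
            if len(structure) != len(sequence):
                raise ValueError(
                    f"structure length {len(structure)} != sequence length {len(sequence)}"
                )
            blocks.append(struct_features(structure))
    return FeatureMatrix(np.concatenate(blocks, axis=1), sequence_id=sequence_id,
                         manifest=feature_manifest(mode, pssm_transform))


def check_manifest(expected: str, actual: str) -> None:
    if expected and actual and expected != actual:
        raise ValueError(
            f"feature manifest mismatch: model expects {expected!r}, inputs give {actual!r}"
        )


# ---------------------------------------------------------------------------
# external-file parsers
# ---------------------------------------------------------------------------


def read_fasta(path) -> dict:
    """Minimal FASTA reader returning an ordered id -> sequence mapping."""
    seqs: dict = {}
    name = None
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ParseError(f"{path}: sequence data before first FASTA header")
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    return seqs


def parse_pssm(path, sequence: str = None) -> np.ndarray:
    """Read the first score block of a PSI-BLAST ASCII PSSM.

    The file layout is: header lines, a column-letter line naming (at least)
    20 residues, then one row per residue with a 1-based index, the residue
    letter and 20 integer log-odds scores. Columns are re-ordered to the
    package's canonical residue order. If ``sequence`` is given, row letters
    are cross-checked against it.
    """
    col_order = None
    rows = []
    letters = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tok = raw.split()
            if col_order is None:
                if len(tok) >= 20 and all(t in AA_INDEX for t in tok[:20]):
                    col_order = tok[:20]
                continue
            if not tok:
                if rows:
                    break  # blank line after the matrix ends the block
                continue
            if not tok[0].isdigit():
                break  # footer (statistics) lines
            if len(tok) < 22:
                raise ParseError(
                    f"{path}:{lineno}: PSSM row has {len(tok)} fields, need index, "
                    f"letter and 20 scores"
                )
            try:
                scores = [int(v) for v in tok[2:22]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer PSSM score ({exc})") from exc
            letters.append(tok[1])
            rows.append(scores)
    if col_order is None:
        raise ParseError(f"{path}: no PSSM column header line found")
    if not rows:
        raise ParseError(f"{path}: PSSM contains no residue rows")
    mat = np.asarray(rows, dtype=float)
    # re-order columns to canonical order
    perm = [col_order.index(a) for a in AA_ALPHABET]
    mat = mat[:, perm]
    if sequence is not None:
        if len(sequence) != mat.shape[0]:
            raise ParseError(
                f"{path}: PSSM has {mat.shape[0]} rows but sequence has {len(sequence)} residues"
            )
        for i, (got, want) in enumerate(zip(letters, sequence)):
            if want.upper() in AA_INDEX and got.upper() != want.upper():
                raise ParseError(
                    f"{path}: residue mismatch at position {i + 1}: PSSM has {got}, "
                    f"sequence has {want}"
                )
    return mat


def _hhm_field_to_prob(field: str, path: str, lineno: int) -> float:
    if field == "*":
        return 0.0
    try:
        return float(2.0 ** (-int(field) / 1000.0))
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-numeric HHM field {field!r}") from exc


def parse_hhm(path) -> np.ndarray:
    """Read match-emission probabilities from an HH-suite HHM file.

    Emissions are stored as -1000*log2(p) with ``*`` meaning probability 0;
    rows live between the ``HMM`` header and the ``//`` terminator. Columns
    are re-ordered to the canonical residue order.
    """
    rows = []
    col_order = None
    in_block = False
    terminated = False
    residue_re = re.compile(r"^[A-Z]$")
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        tok = raw.split()
        if not in_block:
            if tok and tok[0] == "HMM":
                if len(tok) >= 21 and all(t in AA_INDEX for t in tok[1:21]):
                    col_order = tok[1:21]
                in_block = True
            continue
        if not tok:
            continue
        if tok[0] == "//":
            terminated = True
            break
        if residue_re.match(tok[0]) and len(tok) >= 22:
            vals = [_hhm_field_to_prob(f, str(path), lineno) for f in tok[2:22]]
            rows.append((tok[0], vals))
        # transition lines and the begin-state line are skipped
    if not in_block:
        raise ParseError(f"{path}: no HMM block found")
    if not terminated:
        raise ParseError(f"{path}: HMM block missing '//' terminator")
    if not rows:
        raise ParseError(f"{path}: HMM block contains no match states")
    mat = np.asarray([v for _, v in rows], dtype=float)
    if col_order is not None:
        perm = [col_order.index(a) for a in AA_ALPHABET]
        mat = mat[:, perm]
    return mat


def _parse_prob_tsv(path, states) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [s for s in states if s not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing probability columns {missing}")
    return df[list(states)].to_numpy(dtype=float)


def parse_ss8(path) -> np.ndarray:
    """Read an 8-state secondary-structure probability TSV (columns H G I E B T S C)."""
    return _parse_prob_tsv(path, SS8_STATES)


def parse_acc3(path) -> np.ndarray:
    """Read a 3-state solvent-accessibility probability TSV (columns B M E)."""
    return _parse_prob_tsv(path, ACC3_STATES)


def read_profile(pssm_path, hhm_path, sequence: str = None) -> SequenceProfile:
    return SequenceProfile(pssm=parse_pssm(pssm_path, sequence), hhm=parse_hhm(hhm_path))


def read_structure(ss8_path, acc3_path) -> StructurePrediction:
    return StructurePrediction(ss8=parse_ss8(ss8_path), acc3=parse_acc3(acc3_path))
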
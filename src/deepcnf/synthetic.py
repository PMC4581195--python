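"""Seeded generator of desk-scale synthetic disorder corpora.

Emulates the statistical structure of real training data — ~7% disordered
residues arranged in segments whose length mixture follows the observed
fragment distribution of curated disorder datasets — together with
format-valid companion files (FASTA, PSI-BLAST PSSM, HH-suite HHM, SS8/ACC3
probability TSVs) that carry a tunable amount of label signal:

* disorder-promoting residues (P, E, S, Q, K) are enriched inside disordered
  segments and order-promoting residues (C, W, I, Y, F, L, M, H) inside
  ordered regions,
* profile scores tilt the same way,
* predicted secondary structure leans to coil and solvent accessibility to
  exposed inside disordered segments.

``signal_strength`` scales every enrichment; at 0 the features are
independent of the labels. The generator makes no attempt at biophysically
realistic evolution — it exists so that the whole pipeline can be exercised
and validated without external datasets or predictors.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import (AA_ALPHABET, AA_INDEX, ACC3_STATES, SS8_STATES,
                       AminoAcidTables, SequenceProfile, StructurePrediction,
                       assemble_features)
from .labels import labels_to_annotation, write_label_file
from .training import TrainingCorpus
from .types import DISORDER, ORDER, LabelSequence

DISORDER_PROMOTING = set("PESQK")
ORDER_PROMOTING = set("CWIYFLMH")

# +1 disorder-promoting, -1 order-promoting, 0 neutral, per canonical residue
PROPENSITY = np.array(
    [(1.0 if a in DISORDER_PROMOTING else (-1.0 if a in ORDER_PROMOTING else 0.0))
     for a in AA_ALPHABET]
)

# background residue frequencies (approximate UniProt composition)
BACKGROUND = np.array([
    0.0826, 0.0553, 0.0406, 0.0546, 0.0137, 0.0393, 0.0674, 0.0708, 0.0227,
    0.0593, 0.0966, 0.0582, 0.0241, 0.0386, 0.0472, 0.0660, 0.0535, 0.0110,
    0.0292, 0.0687,
])
BACKGROUND = BACKGROUND / BACKGROUND.sum()

#: segment-length bins shared with the label statistics: 1-5, 6-15, 16-25, >25
SEGMENT_BINS = ((1, 5), (6, 15), (16, 25), (26, 40))
#: default mixture over the bins, following the fragment-count distribution of
#: the Disorder723-style training data (heavy on short segments)
DEFAULT_BIN_MIXTURE = (0.629, 0.289, 0.058, 0.024)


class GeneratorError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n_sequences: int = 50
    length_range: tuple = (100, 250)
    disorder_fraction: float = 0.07
    bin_mixture: tuple = DEFAULT_BIN_MIXTURE
    signal_strength: float = 2.0
    terminal_policy: str = "allow"  # allow | forbid | force
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.disorder_fraction < 1.0):
            raise GeneratorError("disorder_fraction must lie in [0, 1)")
        if self.disorder_fraction > 0.5:
            raise GeneratorError(
                "disorder_fraction above 0.5 cannot be realized with non-adjacent segments"
            )
        if abs(sum(self.bin_mixture) - 1.0) > 1e-6 or min(self.bin_mixture) < 0:
            raise GeneratorError("bin_mixture must be a distribution over the 4 bins")
        if self.signal_strength < 0:
            raise GeneratorError("signal_strength must be >= 0")
        if self.terminal_policy not in ("allow", "forbid", "force"):
            raise GeneratorError(f"unknown terminal_policy {self.terminal_policy!r}")
        if self.length_range[0] < 10 or self.length_range[0] > self.length_range[1]:
            raise GeneratorError("length_range must satisfy 10 <= lo <= hi")


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------


def _place_segments(length, target, cfg: GeneratorConfig, rng) -> np.ndarray:
    states = np.zeros(length, dtype=np.int8)
    placed = 0
    attempts = 0
    force_terminal_pending = cfg.terminal_policy == "force"
    while placed < target and attempts < 200:
        attempts += 1
        b = rng.choice(len(SEGMENT_BINS), p=np.asarray(cfg.bin_mixture))
        lo, hi = SEGMENT_BINS[b]
        seg = int(rng.integers(lo, hi + 1))
        seg = min(seg, target - placed) or 1
        if force_terminal_pending:
            start = 0 if rng.random() < 0.5 else length - seg
            force_terminal_pending = False
        elif cfg.terminal_policy == "forbid":
            if seg > length - 4:
                continue
            start = int(rng.integers(1, length - seg - 1))
        else:
            start = int(rng.integers(0, length - seg + 1))
        # keep one ordered residue between segments so each stays a distinct run
        lo_chk = max(0, start - 1)
        hi_chk = min(length, start + seg + 1)
        if states[lo_chk:hi_chk].any():
            continue
        states[start:start + seg] = DISORDER
        placed += seg
    if target and placed < 0.5 * target:
        raise GeneratorError(
            f"could not place disorder segments: target {target} residues of {length}"
        )
    return states


def generate_labels(config: GeneratorConfig, rng=None) -> list:
    """Draw per-sequence label chains matching the configured imbalance."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = []
    for _ in range(config.n_sequences):
        length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        target = round(config.disorder_fraction * length)
        if config.disorder_fraction > 0 and target == 0:
            target = 1
        states = (np.zeros(length, dtype=np.int8) if target == 0
                  else _place_segments(length, target, config, rng))
        out.append(LabelSequence(states))
    return out


# ---------------------------------------------------------------------------
# sequences, profiles, structure predictions
# ---------------------------------------------------------------------------


def _label_tilt(states: np.ndarray, strength: float) -> np.ndarray:
    """Per-position additive logit tilt over the 20 residues."""
    direction = np.where(states == DISORDER, 1.0, -1.0)
    return 0.5 * strength * direction[:, None] * PROPENSITY[None, :]


def generate_sequences(labels, config: GeneratorConfig, rng) -> list:
    seqs = []
    log_bg = np.log(BACKGROUND)
    for y in labels:
        logits = log_bg[None, :] + _label_tilt(y.states, config.signal_strength)
        p = np.exp(logits - logits.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        idx = np.array([rng.choice(20, p=row) for row in p])
        seqs.append("".join(AA_ALPHABET[i] for i in idx))
    return seqs


def generate_profile(sequence: str, states: np.ndarray, config: GeneratorConfig,
                     rng) -> SequenceProfile:
    length = len(sequence)
    tilt = _label_tilt(states, config.signal_strength)
    aa_idx = np.array([AA_INDEX[a] for a in sequence])
    # integer PSSM: noise + label tilt + a match bonus on the observed residue
    pssm = rng.integers(-2, 3, size=(length, 20)).astype(float)
    pssm += np.rint(2.0 * tilt)
    pssm[np.arange(length), aa_idx] += 3
    pssm = np.clip(pssm, -9, 11)
    # HHM emissions: softmax of observed-residue bonus + tilt + noise
    logits = np.log(BACKGROUND)[None, :] + tilt + 0.3 * rng.normal(size=(length, 20))
    logits[np.arange(length), aa_idx] += 2.0
    hhm = np.exp(logits - logits.max(axis=1, keepdims=True))
    hhm /= hhm.sum(axis=1, keepdims=True)
    return SequenceProfile(pssm=pssm, hhm=hhm)


# Dirichlet concentrations: neutral, order-like (helix/sheet-heavy, buried)
# and disorder-like (coil-heavy, exposed)
_SS8_NEUTRAL = np.full(8, 3.0)
_SS8_ORDER = np.array([8.0, 2.0, 1.0, 6.0, 2.0, 2.0, 2.0, 3.0])
_SS8_DISORDER = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 2.0, 2.0, 14.0])
_ACC_NEUTRAL = np.full(3, 3.0)
_ACC_ORDER = np.array([6.0, 3.0, 1.0])
_ACC_DISORDER = np.array([1.0, 3.0, 6.0])


def generate_structure(states: np.ndarray, config: GeneratorConfig,
                       rng) -> StructurePrediction:
    mix = min(1.0, config.signal_strength / 3.0)
    ss8 = np.empty((len(states), 8))
    acc3 = np.empty((len(states), 3))
    for i, s in enumerate(states):
        a_ss = (1 - mix) * _SS8_NEUTRAL + mix * (_SS8_DISORDER if s else _SS8_ORDER)
        a_ac = (1 - mix) * _ACC_NEUTRAL + mix * (_ACC_DISORDER if s else _ACC_ORDER)
        ss8[i] = rng.dirichlet(a_ss)
        acc3[i] = rng.dirichlet(a_ac)
    return StructurePrediction(ss8=ss8, acc3=acc3)


# ---------------------------------------------------------------------------
# corpus assembly (in memory) and file emission
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCorpus:
    ids: list
    sequences: list
    labels: list
    profiles: list
    structures: list

    def training_corpus(self, tables: AminoAcidTables = None,
                        mode: str = "full") -> TrainingCorpus:
        if tables is None:
            tables = AminoAcidTables.default()
        items = []
        for name, seq, y, prof, sp in zip(self.ids, self.sequences, self.labels,
                                          self.profiles, self.structures):
            x = assemble_features(seq, tables=tables, profile=prof, structure=sp,
                                  mode=mode, sequence_id=name)
            items.append((x, y))
        return TrainingCorpus(items=items, ids=list(self.ids))


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Draw a complete in-memory corpus (labels, sequences, profiles, structure)."""
    rng = np.random.default_rng(config.seed)
    labels = generate_labels(config, rng)
    sequences = generate_sequences(labels, config, rng)
    profiles = [generate_profile(s, y.states, config, rng)
                for s, y in zip(sequences, labels)]
    structures = [generate_structure(y.states, config, rng) for y in labels]
    ids = [f"syn{i:04d}" for i in range(config.n_sequences)]
    return SyntheticCorpus(ids=ids, sequences=sequences, labels=labels,
                           profiles=profiles, structures=structures)


def _write_pssm(path, sequence, pssm):
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(AA_ALPHABET) + "\n")
        for i, (aa, row) in enumerate(zip(sequence, pssm), start=1):
            scores = " ".join(f"{int(v):4d}" for v in row)
            fh.write(f"{i:5d} {aa}  {scores}\n")
        fh.write("\n")


def _write_hhm(path, name, sequence, hhm):
    with open(path, "w") as fh:
        fh.write("HHsearch 1.5\n")
        fh.write(f"NAME  {name}\n")
        fh.write(f"LENG  {len(sequence)}\n")
        fh.write("HMM    " + "\t".join(AA_ALPHABET) + "\n")
        fh.write("       M->M\tM->I\tM->D\tI->M\tI->I\tD->M\tD->D\tNeff\n")
        fh.write("       0\t*\t*\t0\t*\t0\t*\t0\n")
        for i, (aa, row) in enumerate(zip(sequence, hhm), start=1):
            fields = []
            for p in row:
                fields.append("*" if p <= 0 else str(int(round(-1000.0 * math.log2(p)))))
            fh.write(f"{aa} {i}\t" + "\t".join(fields) + f"\t{i}\n")
            fh.write("       0\t*\t*\t0\t*\t0\t*\t1000\n")
        fh.write("//\n")


def _write_prob_tsv(path, states, mat, comment):
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        fh.write("pos\t" + "\t".join(states) + "\n")
        for i, row in enumerate(mat, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def write_corpus(corpus: SyntheticCorpus, outdir, folds: int = 0, seed: int = 0) -> Path:
    """Write FASTA, labels, profile/structure files and a training manifest.

    Returns the manifest path. The emitted files use exactly the dialects the
    feature parsers consume, so a written corpus round-trips through the
    file-based pipeline.
    """
    outdir = Path(outdir)
    for sub in ("pssm", "hhm", "ss8", "acc3"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    fasta = outdir / "sequences.fasta"
    with open(fasta, "w") as fh:
        for name, seq in zip(corpus.ids, corpus.sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    label_path = outdir / "labels.tsv"
    write_label_file(label_path,
                     {n: labels_to_annotation(y) for n, y in zip(corpus.ids, corpus.labels)})
    if folds:
        from .training import kfold_split
        assignment = kfold_split(len(corpus.ids), folds, seed)
    else:
        assignment = np.zeros(len(corpus.ids), dtype=int)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("id\tfasta\tlabels\tpssm\thhm\tss8\tacc3\tfold\n")
        for i, name in enumerate(corpus.ids):
            pssm = outdir / "pssm" / f"{name}.pssm"
            hhm = outdir / "hhm" / f"{name}.hhm"
            ss8 = outdir / "ss8" / f"{name}.ss8.tsv"
            acc3 = outdir / "acc3" / f"{name}.acc3.tsv"
            _write_pssm(pssm, corpus.sequences[i], corpus.profiles[i].pssm)
            _write_hhm(hhm, name, corpus.sequences[i], corpus.profiles[i].hhm)
            _write_prob_tsv(ss8, SS8_STATES, corpus.structures[i].ss8,
                            f"synthetic SS8 probabilities for {name}")
            _write_prob_tsv(acc3, ACC3_STATES, corpus.structures[i].acc3,
                            f"synthetic ACC3 probabilities for {name}")
            fh.write("\t".join([name, str(fasta), str(label_path), str(pssm),
                                str(hhm), str(ss8), str(acc3), str(assignment[i])]) + "\n")
    return manifest


def label_feature_mutual_information(sequences, labels) -> float:
    """Empirical mutual information (nats) between residue identity and label."""
    joint = np.zeros((20, 2))
    for seq, y in zip(sequences, labels):
        for aa, s in zip(seq, y.states):
            joint[AA_INDEX[aa], int(s)] += 1
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (pa @ pb))
    return float(np.nansum(terms))
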
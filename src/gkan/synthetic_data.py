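"""Flipon-style synthetic DNA benchmarks.

Generates labeled binary datasets in which the positive class carries a
planted non-B-DNA signature and the negative class is background:

* ``zdna`` — alternating purine/pyrimidine dinucleotide steps (the Z-DNA
  signature), GC-biased;
* ``g4`` — four runs of >= 3 guanines separated by 1-7 nt loops (the
  G-quadruplex consensus G{3,}N{1,7}G{3,}N{1,7}G{3,}N{1,7}G{3,});
* ``hdna`` — a homopurine mirror repeat around a short spacer
  (triplex-forming H-DNA);
* ``diffuse`` — weak degenerate 4-mers scattered over the whole sequence,
  a stand-in for functional elements without a crisp motif;
* ``none`` — labels carry no signal at all (negative control).

Each planted position follows its class rule independently with probability
``motif_strength``, so the signal is tunable from absent (0) to exact (1).
Datasets are exactly balanced, exact-duplicate-free across splits, and carry
stratified fold assignments; everything is reproducible from the spec's seed.

On-disk formats: two-column ``sequence,label`` CSV (Genomic-Benchmarks
dialect), FASTA with the label in the description, BED with planted motif
coordinates (0-based half-open), and a JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SyntheticDatasetSpec", "LabeledSequenceSet", "sample_background",
    "plant_motif", "make_dataset", "one_hot_encode", "one_hot_decode",
    "write_csv", "read_csv", "write_fasta", "read_fasta", "write_bed",
]

GENERATOR_VERSION = "1.0"
ALPHABET = "ACGT"
PURINES = "AG"
PYRIMIDINES = "CT"
MOTIF_CLASSES = ("zdna", "g4", "hdna", "diffuse", "none")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    """Everything a dataset IS: class, sizes, signal strength, seed."""

    motif_class: str = "zdna"
    n_sequences: int = 2000
    seq_length: int = 200
    positive_fraction: float = 0.5
    motif_length: int = 24
    motif_strength: float = 0.9
    background: str = "iid"
    gc_content: float = 0.41  # human genome-wide GC
    n_folds: int = 5
    seed: int = 0

    def validate(self):
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be strictly inside (0, 1)")
        if not 0.0 <= self.motif_strength <= 1.0:
            raise ValueError("motif_strength must be in [0, 1]")
        if self.background not in ("iid", "markov1"):
            raise ValueError(f"unknown background model {self.background!r}")
        if self.n_sequences < 1 or self.seq_length < 1:
            raise ValueError("sizes must be positive")
        if self.motif_length > self.seq_length:
            raise ValueError("motif longer than sequence")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class LabeledSequenceSet:
    sequences: list[str]
    labels: np.ndarray
    fold_ids: np.ndarray
    motif_spans: list[tuple[int, int] | None]
    spec: SyntheticDatasetSpec | None = None
    generator_version: str = GENERATOR_VERSION

    def __len__(self):
        return len(self.sequences)

    def fold_split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Indices of (train, test) rows with ``fold`` held out."""
        test = np.flatnonzero(self.fold_ids == fold)
        train = np.flatnonzero(self.fold_ids != fold)
        if len(test) == 0:
            raise ValueError(f"fold {fold} is empty")
        return train, test


def _base_probs(gc_content: float) -> np.ndarray:
    g = gc_content / 2.0
    a = (1.0 - gc_content) / 2.0
    return np.array([a, g, g, a])  # A, C, G, T


def sample_background(n: int, length: int, background: str = "iid",
                      gc_content: float = 0.41, seed: int = 0) -> list[str]:
    """Draw background DNA; iid per-base or a persistent first-order chain.

    iid: P(G) = P(C) = gc/2, P(A) = P(T) = (1-gc)/2.  markov1 mixes the same
    stationary distribution with a 0.3 probability of repeating the previous
    base, a crude model of the short-range autocorrelation of real genomes.
    """
    if n < 1 or length < 1:
        raise ValueError("n and length must be positive")
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    probs = _base_probs(gc_content)
    letters = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    if background == "iid":
        idx = rng.choice(4, size=(n, length), p=probs)
    elif background == "markov1":
        persist = 0.3
        idx = np.empty((n, length), dtype=np.int64)
        idx[:, 0] = rng.choice(4, size=n, p=probs)
        for j in range(1, length):
            fresh = rng.choice(4, size=n, p=probs)
            stay = rng.uniform(size=n) < persist
            idx[:, j] = np.where(stay, idx[:, j - 1], fresh)
    else:
        raise ValueError(f"unknown background model {background!r}")
    return [letters[row].tobytes().decode() for row in idx]


def _plant_zdna(seq: list[str], start: int, length: int, strength: float,
                rng: np.random.Generator):
    # alternating R/Y steps; GC steps favoured (Z-DNA forms most readily on
    # (GC)n tracts), so purine ~ G, pyrimidine ~ C with weight 0.75
    for off in range(length):
        if rng.uniform() >= strength:
            continue
        if off % 2 == 0:
            seq[start + off] = "G" if rng.uniform() < 0.75 else "A"
        else:
            seq[start + off] = "C" if rng.uniform() < 0.75 else "T"


def _g4_layout(length: int, rng: np.random.Generator) -> list[tuple[int, int, bool]]:
    """Partition ``length`` into 4 G-runs (>=3) and 3 loops (1-7)."""
    runs = [3, 3, 3, 3]
    loops = [int(rng.integers(1, 8)) for _ in range(3)]
    total = sum(runs) + sum(loops)
    # grow runs, then shrink loops, until the layout fits the window
    i = 0
    while total < length:
        runs[i % 4] += 1
        total += 1
        i += 1
    while total > length:
        j = int(np.argmax(loops))
        if loops[j] > 1:
            loops[j] -= 1
            total -= 1
        else:
            k = int(np.argmax(runs))
            if runs[k] <= 3:
                raise ValueError("motif window too small for a G-quadruplex")
            runs[k] -= 1
            total -= 1
    segments = []
    for r, l in zip(runs, loops + [0]):
        segments.append((r, True))
        if l:
            segments.append((l, False))
    out, pos = [], 0
    for seg_len, is_run in segments:
        out.append((pos, pos + seg_len, is_run))
        pos += seg_len
    return out


def _plant_g4(seq: list[str], start: int, length: int, strength: float,
              rng: np.random.Generator):
    for lo, hi, is_run in _g4_layout(length, rng):
        if not is_run:
            continue
        for off in range(lo, hi):
            if rng.uniform() < strength:
                seq[start + off] = "G"


def _plant_hdna(seq: list[str], start: int, length: int, strength: float,
                rng: np.random.Generator):
    spacer = min(4, max(0, length - 2 * 6))
    arm = (length - spacer) // 2
    spacer = length - 2 * arm
    arm_bases = ["G" if rng.uniform() < 0.5 else "A" for _ in range(arm)]
    for off in range(arm):
        if rng.uniform() < strength:
            seq[start + off] = arm_bases[off]
        # mirror repeat: the second arm reads the first one backwards
        if rng.uniform() < strength:
            seq[start + length - 1 - off] = arm_bases[off]


_DIFFUSE_4MER = "GGTA"  # weak consensus; R/Y degenerate at the two outer spots
_IUPAC = {"R": "AG", "Y": "CT", "S": "CG", "W": "AT"}


def _plant_diffuse(seq: list[str], length: int, motif_length: int,
                   strength: float, rng: np.random.Generator):
    n_copies = max(1, motif_length // 4)
    starts = rng.choice(max(1, length - 4), size=n_copies, replace=False) \
        if length - 4 >= n_copies else [0] * n_copies
    for s in np.atleast_1d(starts):
        for off, base in enumerate(_DIFFUSE_4MER):
            if int(s) + off < length and rng.uniform() < strength:
                seq[int(s) + off] = base


def plant_motif(sequence: str, motif_class: str, motif_length: int,
                motif_strength: float, seed: int = 0,
                rng: np.random.Generator | None = None) -> tuple[str, int, int]:
    """Plant one motif instance; returns (sequence, start, end) half-open.

    Each planted position follows its class rule independently with
    probability ``motif_strength`` and otherwise keeps the background base.
    For the diffuse class the reported span is the whole sequence.
    """
    if motif_class not in MOTIF_CLASSES:
        raise ValueError(f"unknown motif class {motif_class!r}")
    length = len(sequence)
    if motif_length > length:
        raise ValueError(
            f"motif length {motif_length} exceeds sequence length {length}")
    if rng is None:
        rng = np.random.default_rng(seed)
    seq = list(sequence)
    if motif_class == "none":
        return sequence, 0, 0
    if motif_class == "diffuse":
        _plant_diffuse(seq, length, motif_length, motif_strength, rng)
        return "".join(seq), 0, length
    start = int(rng.integers(0, length - motif_length + 1))
    if motif_class == "zdna":
        _plant_zdna(seq, start, motif_length, motif_strength, rng)
    elif motif_class == "g4":
        _plant_g4(seq, start, motif_length, motif_strength, rng)
    elif motif_class == "hdna":
        _plant_hdna(seq, start, motif_length, motif_strength, rng)
    return "".join(seq), start, start + motif_length


def make_dataset(spec: SyntheticDatasetSpec) -> LabeledSequenceSet:
    """Balanced, deduplicated, fold-annotated dataset from a spec.

    Exact-duplicate strings are regenerated before splitting so no sequence
    can appear on both sides of any train/test split; fold assignment is
    stratified by label with fold sizes differing by at most one.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_sequences * spec.positive_fraction))
    n_neg = spec.n_sequences - n_pos
    seen: set[str] = set()
    sequences: list[str] = []
    labels: list[int] = []
    spans: list[tuple[int, int] | None] = []

    def draw(positive: bool):
        for _ in range(200):  # regenerate on duplicate collision
            bg = sample_background(1, spec.seq_length, spec.background,
                                   spec.gc_content,
                                   seed=int(rng.integers(2**31)))[0]
            span = None
            if positive and spec.motif_class != "none":
                bg, s, e = plant_motif(bg, spec.motif_class, spec.motif_length,
                                       spec.motif_strength, rng=rng)
                span = (s, e)
            if bg not in seen:
                seen.add(bg)
                sequences.append(bg)
                labels.append(int(positive))
                spans.append(span)
                return
        raise ValueError(
            "could not generate enough unique sequences; the alphabet is "
            "exhausted at this length — increase seq_length or reduce n")

    for _ in range(n_pos):
        draw(True)
    for _ in range(n_neg):
        draw(False)

    labels_arr = np.array(labels)
    order = rng.permutation(spec.n_sequences)
    sequences = [sequences[i] for i in order]
    labels_arr = labels_arr[order]
    spans = [spans[i] for i in order]
    # stratified fold ids: cycle folds within each label group
    fold_ids = np.empty(spec.n_sequences, dtype=np.int64)
    for lab in (0, 1):
        idx = np.flatnonzero(labels_arr == lab)
        fold_ids[idx] = np.arange(len(idx)) % spec.n_folds
    return LabeledSequenceSet(sequences=sequences, labels=labels_arr,
                              fold_ids=fold_ids, motif_spans=spans, spec=spec)


# -- encoding ---------------------------------------------------------------

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def one_hot_encode(sequences: list[str], n_policy: str = "reject") -> np.ndarray:
    """Encode equal-length sequences as (n, 4, L); channel order A, C, G, T.

    ``n_policy`` controls ambiguous bases: 'reject' raises (with the
    offending position), 'uniform' encodes N as 0.25 in every channel.
    """
    if not sequences:
        raise ValueError("empty sequence list")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must be equal length (pad or trim first)")
    raw = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    raw = raw.reshape(len(sequences), L)
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    idx = lut[raw]
    bad = idx < 0
    is_n = raw == ord("N")
    hard_bad = bad & ~is_n if n_policy == "uniform" else bad
    if hard_bad.any():
        i, j = map(int, np.argwhere(hard_bad)[0])
        raise ValueError(
            f"non-ACGT character {sequences[i][j]!r} at sequence {i}, position {j}")
    out = np.zeros((len(sequences), 4, L))
    rows, cols = np.nonzero(~bad)
    out[rows, idx[rows, cols], cols] = 1.0
    if n_policy == "uniform":
        rows, cols = np.nonzero(is_n)
        out[rows, :, cols] = 0.25
    return out


def one_hot_decode(x: np.ndarray) -> list[str]:
    letters = np.array(list(ALPHABET))
    return ["".join(letters[row.argmax(axis=0)]) for row in x]


# -- I/O --------------------------------------------------------------------

def write_csv(data: LabeledSequenceSet, path: str, include_folds: bool = True):
    cols = {"sequence": data.sequences, "label": data.labels}
    if include_folds:
        cols["fold"] = data.fold_ids
    pd.DataFrame(cols).to_csv(path, index=False)


def read_csv(path: str) -> LabeledSequenceSet:
    """Read the two-column Genomic-Benchmarks dialect (plus optional fold)."""
    df = pd.read_csv(path)
    if "sequence" not in df or "label" not in df:
        raise ValueError("CSV must have 'sequence' and 'label' columns")
    folds = df["fold"].to_numpy() if "fold" in df else np.zeros(len(df), dtype=int)
    return LabeledSequenceSet(sequences=df["sequence"].astype(str).tolist(),
                              labels=df["label"].to_numpy().astype(int),
                              fold_ids=folds.astype(int),
                              motif_spans=[None] * len(df))


def write_fasta(data: LabeledSequenceSet, path: str):
    records = [
        SeqRecord(Seq(s), id=f"seq{i}", description=f"label={l} fold={f}")
        for i, (s, l, f) in enumerate(zip(data.sequences, data.labels,
                                          data.fold_ids))
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")]


def write_bed(data: LabeledSequenceSet, path: str):
    """Planted-motif coordinates, 0-based half-open, one row per positive."""
    with open(path, "w") as fh:
        for i, span in enumerate(data.motif_spans):
            if span is not None:
                fh.write(f"seq{i}\t{span[0]}\t{span[1]}\t{data.spec.motif_class}\n")


def write_manifest(data: LabeledSequenceSet, path: str):
    import hashlib
    digest = hashlib.sha256("".join(data.sequences).encode()).hexdigest()
    manifest = {
        "spec": data.spec.to_dict() if data.spec else None,
        "generator_version": data.generator_version,
        "n_sequences": len(data),
        "checksum_sha256": digest,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
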
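"""Quality metrics for generated DNA sequence sets.

Diversity and memorization are measured with nearest-neighbor Levenshtein
distances: D_self is the mean distance from each sequence (in a sample of
``n_eval``, 1000 by default) to its nearest neighbor within the same set —
low values mean mode collapse — and D_train is the mean distance from each
generated sequence to its nearest training sequence — zero means verbatim
memorization.  A useful reference point is D_self of the real training/test
sets themselves: a good generator's D_self should sit near it.

Distributional agreement between real and generated sets is summarized two
ways, both documented interpretations rather than canon: KL divergence
between k-mer frequency distributions (k = 3 by default, pseudocounted),
and the 1-D Wasserstein distance between per-sequence scalar summaries
(GC content by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import edlib
import numpy as np

__all__ = [
    "GenEvalReport", "edit_distance", "d_self", "d_train",
    "kmer_distribution", "kl_divergence", "wasserstein_1d", "gc_content",
    "evaluate_generation",
]


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (insertions, deletions, substitutions)."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


def _subsample(seqs: list[str], n_eval: int, seed: int) -> list[str]:
    if n_eval >= len(seqs):
        return list(seqs)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(seqs), size=n_eval, replace=False)
    return [seqs[i] for i in idx]


def d_self(sequences: list[str], n_eval: int = 1000, seed: int = 0) -> float:
    """Mean nearest-neighbor edit distance within a set (self excluded)."""
    if len(sequences) < 2:
        raise ValueError("d_self needs at least two sequences")
    sample = _subsample(list(sequences), n_eval, seed)
    total = 0.0
    for i, s in enumerate(sample):
        best = None
        for j, t in enumerate(sample):
            if i == j:
                continue
            d = edit_distance(s, t)
            if best is None or d < best:
                best = d
                if best == 0:
                    break
        total += best
    return total / len(sample)


def d_train(generated: list[str], train: list[str], n_eval: int = 1000,
            seed: int = 0) -> float:
    """Mean distance from generated sequences to their nearest training one.

    Zero iff every evaluated generated sequence occurs verbatim in the
    training set — the memorization alarm.
    """
    if not generated or not train:
        raise ValueError("both sequence sets must be nonempty")
    sample = _subsample(list(generated), n_eval, seed)
    train_set = set(train)
    total = 0.0
    for s in sample:
        if s in train_set:
            continue  # exact hit, distance 0
        best = min(edit_distance(s, t) for t in train)
        total += best
    return total / len(sample)


def kmer_distribution(sequences: list[str], k: int = 3,
                      pseudocount: float = 0.5) -> np.ndarray:
    """Sliding-window k-mer frequencies over 4^k cells, pseudocounted."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not sequences:
        raise ValueError("empty sequence set")
    if min(len(s) for s in sequences) < k:
        raise ValueError(f"all sequences must be at least {k} long")
    index = {"".join(p): i for i, p in enumerate(product("ACGT", repeat=k))}
    counts = np.zeros(4 ** k)
    for s in sequences:
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            if kmer in index:
                counts[index[kmer]] += 1
    counts += pseudocount
    total = counts.sum()
    if total == 0:
        raise ValueError("no countable k-mers and zero pseudocount")
    return counts / total


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence sum p log(p/q), natural log."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal dimension")
    if np.any((q <= 0) & (p > 0)):
        raise ValueError("q has zero mass where p > 0; add a pseudocount")
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def wasserstein_1d(p_samples, q_samples) -> float:
    """First-order Wasserstein distance between empirical 1-D distributions.

    Computed by the quantile-coupling formula: integrate |F_p - F_q| over
    the merged sample support.
    """
    p = np.sort(np.asarray(p_samples, dtype=float))
    q = np.sort(np.asarray(q_samples, dtype=float))
    if p.size == 0 or q.size == 0:
        raise ValueError("empty sample set")
    all_x = np.concatenate([p, q])
    all_x.sort(kind="mergesort")
    deltas = np.diff(all_x)
    cdf_p = np.searchsorted(p, all_x[:-1], side="right") / p.size
    cdf_q = np.searchsorted(q, all_x[:-1], side="right") / q.size
    return float(np.sum(np.abs(cdf_p - cdf_q) * deltas))


def gc_content(sequence: str) -> float:
    if not sequence:
        return 0.0
    return (sequence.count("G") + sequence.count("C")) / len(sequence)


@dataclass
class GenEvalReport:
    d_self: float
    d_train: float
    d_self_train_reference: float
    kl_divergence: float
    wasserstein: float
    k: int
    n_eval: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate_generation(generated: list[str], train: list[str],
                        n_eval: int = 1000, k: int = 3,
                        pseudocount: float = 0.5, seed: int = 0) -> GenEvalReport:
    """Full generation-quality panel for one generated set.

    Always carries D_self of the real training data as the diversity
    reference the generated value should be compared against.
    """
    return GenEvalReport(
        d_self=d_self(generated, n_eval=n_eval, seed=seed),
        d_train=d_train(generated, train, n_eval=n_eval, seed=seed),
        d_self_train_reference=d_self(train, n_eval=n_eval, seed=seed),
        kl_divergence=kl_divergence(
            kmer_distribution(generated, k=k, pseudocount=pseudocount),
            kmer_distribution(train, k=k, pseudocount=pseudocount)),
        wasserstein=wasserstein_1d([gc_content(s) for s in generated],
                                   [gc_content(s) for s in train]),
        k=k, n_eval=n_eval)
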
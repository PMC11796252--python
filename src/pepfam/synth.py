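"""Synthetic datasets with planted small-protein families, plus recovery metrics.

Each planted family descends from a random root peptide: every member is the
root with i.i.d. substitutions (replacement drawn from the background,
excluding the original residue, so each event changes the sequence) and
single-residue indels.  Decoys and singletons are unrelated background
peptides — decoys model noise that the pipeline must leave unclustered,
singletons model genuine proteins without homologs.  Product labels carry a
configurable fraction of "hypothetical protein" noise, mimicking incomplete
annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .io import ProteinRecord
from .mcl import Clustering
from .families import default_background
from .scoring import ALPHABET

_RESIDUES = ALPHABET[:20]

DEFAULT_PRODUCT_VOCAB = tuple(
    f"DUF{1000 + 7 * i} family protein" for i in range(64)
)


@dataclass(frozen=True)
class SynthConfig:
    n_families: int = 10
    family_size_range: tuple[int, int] = (5, 20)
    root_length_range: tuple[int, int] = (20, 50)
    substitution_rate: float = 0.15
    indel_rate: float = 0.02
    n_decoys: int = 20
    n_singletons: int = 10
    product_vocab: tuple[str, ...] = DEFAULT_PRODUCT_VOCAB
    label_noise: float = 0.2
    seed: int = 0
    min_length: int = 5
    max_length: int = 50

    def __post_init__(self):
        for name in ("substitution_rate", "indel_rate", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.root_length_range
        if not (self.min_length <= lo <= hi <= self.max_length):
            raise ValueError("root lengths must lie within [min_length, max_length]")
        if self.family_size_range[0] > self.family_size_range[1]:
            raise ValueError("family_size_range must be (min, max) with min <= max")
        if self.n_families < 0 or self.n_decoys < 0 or self.n_singletons < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class TruthTable:
    """Ground-truth class per generated protein id.

    Family members map to their family label; decoys and singletons map to
    "decoy"/"singleton" markers and are treated as their own one-member truth
    classes during evaluation.
    """

    labels: dict[str, str] = field(default_factory=dict)

    def truth_classes(self) -> dict[str, str]:
        """Per-id truth class; each decoy/singleton becomes its own class."""
        out = {}
        for pid, label in self.labels.items():
            out[pid] = pid if label in ("decoy", "singleton") else label
        return out

    def family_members(self) -> dict[str, list[str]]:
        fams: dict[str, list[str]] = {}
        for pid, label in self.labels.items():
            if label not in ("decoy", "singleton"):
                fams.setdefault(label, []).append(pid)
        return {k: sorted(v) for k, v in fams.items()}


def _random_peptide(rng: np.random.Generator, length: int, bg: np.ndarray) -> str:
    return "".join(np.array(list(_RESIDUES))[rng.choice(20, size=length, p=bg)])


def _mutate(rng: np.random.Generator, root: str, cfg: SynthConfig, bg: np.ndarray) -> str:
    seq = []
    for ch in root:
        # substitution: replacement drawn from background excluding the original
        if rng.random() < cfg.substitution_rate:
            i = _RESIDUES.index(ch)
            p = bg.copy()
            p[i] = 0.0
            p /= p.sum()
            ch = _RESIDUES[rng.choice(20, p=p)]
        # single-residue indel, insert or delete with equal probability
        if rng.random() < cfg.indel_rate:
            if rng.random() < 0.5:
                seq.append(ch)
                seq.append(_RESIDUES[rng.choice(20, p=bg)])
            # else: deletion, drop the residue
        else:
            seq.append(ch)
    out = "".join(seq)
    if len(out) < cfg.min_length:  # pad back from the root to stay in range
        out = (out + root)[: cfg.min_length]
    return out[: cfg.max_length]


def generate_dataset(config: SynthConfig) -> tuple[list[ProteinRecord], TruthTable]:
    """Generate planted families, decoys and singletons; reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    bg = default_background()
    records: list[ProteinRecord] = []
    truth = TruthTable()
    for f in range(config.n_families):
        label = f"fam{f:03d}"
        product = config.product_vocab[f % len(config.product_vocab)]
        root_len = int(rng.integers(config.root_length_range[0], config.root_length_range[1] + 1))
        root = _random_peptide(rng, root_len, bg)
        size = int(rng.integers(config.family_size_range[0], config.family_size_range[1] + 1))
        for m in range(size):
            pid = f"{label}_m{m:02d}"
            seq = _mutate(rng, root, config, bg)
            labeled = rng.random() >= config.label_noise
            records.append(
                ProteinRecord(
                    id=pid,
                    sequence=seq,
                    product=product if labeled else "hypothetical protein",
                )
            )
            truth.labels[pid] = label
    for d in range(config.n_decoys):
        pid = f"decoy{d:03d}"
        length = int(rng.integers(config.root_length_range[0], config.root_length_range[1] + 1))
        records.append(ProteinRecord(id=pid, sequence=_random_peptide(rng, length, bg)))
        truth.labels[pid] = "decoy"
    for s in range(config.n_singletons):
        pid = f"single{s:03d}"
        length = int(rng.integers(config.root_length_range[0], config.root_length_range[1] + 1))
        records.append(ProteinRecord(id=pid, sequence=_random_peptide(rng, length, bg)))
        truth.labels[pid] = "singleton"
    return records, truth


# --- recovery metrics ------------------------------------------------------

def _comb2(x: np.ndarray | int) -> np.ndarray | float:
    return x * (x - 1) / 2.0


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """ARI by the standard pair-counting formula on two equal-length labelings."""
    if len(labels_a) != len(labels_b):
        raise ValueError("labelings must cover the same items")
    a_codes = {lab: i for i, lab in enumerate(dict.fromkeys(labels_a))}
    b_codes = {lab: i for i, lab in enumerate(dict.fromkeys(labels_b))}
    table = np.zeros((len(a_codes), len(b_codes)))
    for la, lb in zip(labels_a, labels_b):
        table[a_codes[la], b_codes[lb]] += 1
    n = len(labels_a)
    sum_ij = _comb2(table).sum()
    sum_a = _comb2(table.sum(axis=1)).sum()
    sum_b = _comb2(table.sum(axis=0)).sum()
    total = _comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0  # both partitions trivial (all-singleton or all-one)
    return float((sum_ij - expected) / (max_index - expected))


@dataclass
class RecoveryMetrics:
    ari: float
    family_precision: float
    family_recall: float


def evaluate_recovery(truth: TruthTable, clustering: Clustering) -> RecoveryMetrics:
    """Compare a clustering against the generator's ground truth.

    The clustering must cover exactly the generated ids (unclustered proteins
    should be passed as singleton clusters).  Precision and recall are
    pairwise: over all co-clustered pairs, the fraction that are true
    co-family pairs, and vice versa.
    """
    truth_classes = truth.truth_classes()
    missing = set(truth_classes) ^ set(clustering.assignment)
    if missing:
        raise ValueError(f"id mismatch between truth and clustering: {sorted(missing)}")
    ids = sorted(truth_classes)
    t_labels = [truth_classes[i] for i in ids]
    c_labels = [clustering.assignment[i] for i in ids]
    ari = adjusted_rand_index(t_labels, c_labels)

    tp = fp = fn = 0
    for i, j in combinations(range(len(ids)), 2):
        same_t = t_labels[i] == t_labels[j]
        same_c = c_labels[i] == c_labels[j]
        if same_t and same_c:
            tp += 1
        elif same_c:
            fp += 1
        elif same_t:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return RecoveryMetrics(ari=ari, family_precision=precision, family_recall=recall)


def count_recovered_families(
    truth: TruthTable, called_families: Sequence[Sequence[str]], min_jaccard: float = 0.5
) -> int:
    """Planted families matched by a called family at Jaccard >= ``min_jaccard``."""
    recovered = 0
    for members in truth.family_members().values():
        tset = set(members)
        for called in called_families:
            cset = set(called)
            jac = len(tset & cset) / len(tset | cset)
            if jac >= min_jaccard:
                recovered += 1
                break
    return recovered
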
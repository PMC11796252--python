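"""From clusters to families: alignment, profile model, cutoff, annotation.

A cluster with at least five members is called a family.  Its members are
multiple-aligned by a deterministic center-star procedure, a lightweight
profile model (match/insert/delete states with pooled transitions and
per-column log-odds emissions in bits) is built from the alignment, and the
gathering cutoff is set to the lowest member score so that every member is
recovered when the profile is scanned at its own cutoff.  A product label is
assigned by plurality vote over informative member annotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import Msa, ProteinRecord
from .mcl import Clustering
from .scoring import (
    ALPHABET,
    BLOSUM62_BACKGROUND,
    ScoringScheme,
    local_align,
    needleman_wunsch,
)

DEFAULT_MIN_FAMILY_SIZE = 5

#: Labels that carry no functional information and are excluded from voting.
UNINFORMATIVE_PRODUCTS = frozenset({"hypothetical protein", "uncharacterized protein", ""})

_RESIDUES = ALPHABET[:20]
_RES_INDEX = {aa: i for i, aa in enumerate(_RESIDUES)}


def default_background() -> np.ndarray:
    bg = np.array([BLOSUM62_BACKGROUND[aa] for aa in _RESIDUES])
    return bg / bg.sum()


# --- family calling --------------------------------------------------------

@dataclass
class FamilyCallReport:
    families: list[list[str]]  # member-id lists, size >= min_size
    small_clusters: list[list[str]]  # 2 <= size < min_size
    singletons: list[str]


def call_families(clustering: Clustering, min_size: int = DEFAULT_MIN_FAMILY_SIZE) -> FamilyCallReport:
    """Split clusters into families (>= min_size), small clusters, singletons."""
    families, small, singles = [], [], []
    for members in clustering.clusters():
        if len(members) >= min_size:
            families.append(members)
        elif len(members) > 1:
            small.append(members)
        else:
            singles.extend(members)
    key = lambda ms: (-len(ms), ms[0])
    return FamilyCallReport(
        families=sorted(families, key=key),
        small_clusters=sorted(small, key=key),
        singletons=sorted(singles),
    )


# --- center-star multiple alignment ---------------------------------------

def _merge_into_master(master_rows: list[list[str]], aligned_center: str, aligned_new: str) -> list[str]:
    """Merge one pairwise (center, member) alignment into the growing MSA.

    ``master_rows[0]`` is the gapped center; both it and ``aligned_center``
    spell the center when ungapped, so columns are reconciled by the
    "once a gap, always a gap" rule.
    """
    old = master_rows
    new_rows: list[list[str]] = [[] for _ in range(len(old) + 1)]
    i = j = 0
    master_center = old[0]
    len_m, len_a = len(master_center), len(aligned_center)
    while i < len_m or j < len_a:
        cm = master_center[i] if i < len_m else None
        ca = aligned_center[j] if j < len_a else None
        if cm is not None and ca is not None and (cm == ca or (cm != "-" and ca != "-")):
            for r, row in enumerate(old):
                new_rows[r].append(row[i])
            new_rows[-1].append(aligned_new[j])
            i += 1
            j += 1
        elif cm == "-" or ca is None:  # gap column from an earlier member
            for r, row in enumerate(old):
                new_rows[r].append(row[i])
            new_rows[-1].append("-")
            i += 1
        else:  # ca == "-" or cm is None: new member inserts a column
            for r in range(len(old)):
                new_rows[r].append("-")
            new_rows[-1].append(aligned_new[j])
            j += 1
    return ["".join(r) for r in new_rows]


def align_family(members: Sequence[ProteinRecord], scheme: ScoringScheme) -> Msa:
    """Deterministic center-star MSA.

    The center is the member with the largest summed pairwise alignment bit
    score (ties to the smallest id); every other member is globally aligned
    to the center and merged, propagating gaps.  Removing the gaps from any
    row recovers that member's sequence exactly.
    """
    if len(members) < 2:
        raise ValueError("align_family needs at least two sequences")
    members = sorted(members, key=lambda r: r.id)
    sums = {m.id: 0.0 for m in members}
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            bits = local_align(a, b, scheme).bit_score
            sums[a.id] += bits
            sums[b.id] += bits
    center = max(members, key=lambda m: sums[m.id])  # ties: first in id order
    rest = [m for m in members if m.id != center.id]
    rows = [list(center.sequence)]
    ids = [center.id]
    str_rows = ["".join(rows[0])]
    for m in rest:
        ac, am = needleman_wunsch(center.sequence, m.sequence, scheme)
        str_rows = _merge_into_master([list(r) for r in str_rows], ac, am)
        ids.append(m.id)
    return Msa(ids=tuple(ids), rows=tuple(str_rows))


# --- profile model ---------------------------------------------------------

_TRANSITIONS = ("MM", "MI", "MD", "IM", "II", "DM", "DD")


@dataclass(frozen=True)
class ProfileModel:
    """Lightweight profile with match emissions and pooled transitions.

    ``match_logodds[k, a]`` is the bit-score contribution of residue ``a`` at
    match state ``k+1``; insert emissions score 0 (background); transitions
    are position-independent log2 probabilities.
    """

    match_columns: tuple[int, ...]
    match_probs: np.ndarray  # (K, 20) emission probabilities
    match_logodds: np.ndarray  # (K, 20) bits
    transitions: dict[str, float]  # probability per transition label
    background: np.ndarray  # (20,)

    @property
    def n_match_states(self) -> int:
        return len(self.match_columns)

    def transition_bits(self, label: str) -> float:
        return math.log2(self.transitions[label])


def build_profile(
    msa: Msa,
    background: np.ndarray | None = None,
    pseudocount_weight: float = 1.0,
    max_gap_fraction: float = 0.5,
) -> ProfileModel:
    """Build a profile from an alignment.

    Columns with a gap fraction below ``max_gap_fraction`` become match
    states; emissions mix observed counts with background pseudocounts;
    transition probabilities come from the observed match/insert/delete
    structure with add-one smoothing.
    """
    if len(msa.rows) < 2:
        raise ValueError("profile needs an alignment of at least two rows")
    bg = default_background() if background is None else np.asarray(background, dtype=float)
    n_rows = len(msa.rows)
    n_cols = len(msa.rows[0])
    gap_frac = [
        sum(1 for row in msa.rows if row[c] in "-.") / n_rows for c in range(n_cols)
    ]
    match_cols = tuple(c for c in range(n_cols) if gap_frac[c] < max_gap_fraction)
    if not match_cols:
        raise ValueError("alignment yields no match columns")
    counts = np.zeros((len(match_cols), 20))
    for k, c in enumerate(match_cols):
        for row in msa.rows:
            ch = row[c]
            if ch in _RES_INDEX:  # gaps and X carry no emission evidence
                counts[k, _RES_INDEX[ch]] += 1
    probs = (counts + pseudocount_weight * bg) / (
        counts.sum(axis=1, keepdims=True) + pseudocount_weight
    )
    logodds = np.log2(probs / bg)

    match_set = set(match_cols)
    t_counts = {t: 0 for t in _TRANSITIONS}
    for row in msa.rows:
        states = []
        for c in range(n_cols):
            if c in match_set:
                states.append("M" if row[c] not in "-." else "D")
            elif row[c] not in "-.":
                states.append("I")
        for a, b in zip(states, states[1:]):
            if a + b in t_counts:
                t_counts[a + b] += 1
    trans: dict[str, float] = {}
    for src, outs in (("M", ("MM", "MI", "MD")), ("I", ("IM", "II")), ("D", ("DM", "DD"))):
        total = sum(t_counts[o] + 1 for o in outs)
        for o in outs:
            trans[o] = (t_counts[o] + 1) / total
    return ProfileModel(
        match_columns=match_cols,
        match_probs=probs,
        match_logodds=logodds,
        transitions=trans,
        background=bg,
    )


def score_profile(profile: ProfileModel, query: ProteinRecord | str) -> float:
    """Best Viterbi log-odds score in bits: global in the profile, local in
    the query (flanking query residues are free).

    States M_k emit with the column log-odds, I_k emit at background (0),
    D_k emit nothing; a path enters at M_1 or D_1 and leaves from M_K or D_K.
    """
    seq = query.sequence if isinstance(query, ProteinRecord) else query
    K = profile.n_match_states
    L = len(seq)
    res = [_RES_INDEX.get(c, None) for c in seq]  # None (e.g. X) scores 0

    def emit(k: int, i: int) -> float:
        r = res[i - 1]
        return 0.0 if r is None else float(profile.match_logodds[k - 1, r])

    t = {label: profile.transition_bits(label) for label in _TRANSITIONS}
    neg = -math.inf
    VM = np.full((K + 1, L + 1), neg)
    VI = np.full((K + 1, L + 1), neg)
    VD = np.full((K + 1, L + 1), neg)
    for i in range(1, L + 1):
        VM[1, i] = emit(1, i)
    VD[1, :] = 0.0
    for k in range(1, K + 1):
        if k > 1:
            for i in range(0, L + 1):
                VD[k, i] = max(VM[k - 1, i] + t["MD"], VD[k - 1, i] + t["DD"])
                if i >= 1:
                    VM[k, i] = emit(k, i) + max(
                        VM[k - 1, i - 1] + t["MM"],
                        VI[k - 1, i - 1] + t["IM"],
                        VD[k - 1, i - 1] + t["DM"],
                    )
        if k < K:  # inserts live between match states k and k+1
            for i in range(1, L + 1):
                VI[k, i] = max(VM[k, i - 1] + t["MI"], VI[k, i - 1] + t["II"])
    best = max(float(VM[K, 1:].max(initial=neg)), float(VD[K, :].max(initial=neg)))
    return best


def gathering_cutoff(profile: ProfileModel, members: Iterable[ProteinRecord | str]) -> float:
    """Lowest member score: the weakest threshold that still keeps every member."""
    scores = [score_profile(profile, m) for m in members]
    if not scores:
        raise ValueError("gathering cutoff needs at least one member")
    return min(scores)


# --- product voting --------------------------------------------------------

def _normalize_label(label: str) -> str:
    return " ".join(label.split()).lower()


def assign_product(
    member_products: Iterable[str | None],
    uninformative: frozenset[str] = UNINFORMATIVE_PRODUCTS,
) -> str | None:
    """Plurality vote over informative product labels.

    Labels are compared after trimming, whitespace collapsing and
    lowercasing; the winner is reported in its first-seen original casing.
    An exact tie, or no informative label, yields no assignment.
    """
    counts: dict[str, int] = {}
    first_seen: dict[str, str] = {}
    for label in member_products:
        if label is None:
            continue
        norm = _normalize_label(label)
        if norm in uninformative:
            continue
        counts[norm] = counts.get(norm, 0) + 1
        first_seen.setdefault(norm, " ".join(label.split()))
    if not counts:
        return None
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return first_seen[ranked[0][0]]


# --- family assembly -------------------------------------------------------

@dataclass(frozen=True)
class Family:
    """A called family with its alignment, profile and gathering cutoff."""

    family_id: str
    member_ids: frozenset[str]
    msa: Msa
    profile: ProfileModel
    gathering_cutoff: float
    product: str | None
    member_lengths: Mapping[str, int]

    def __post_init__(self):
        if len(self.member_ids) < 2:
            raise ValueError("a family needs multiple members")


def build_family(
    family_id: str,
    member_records: Sequence[ProteinRecord],
    scheme: ScoringScheme,
    background: np.ndarray | None = None,
) -> Family:
    msa = align_family(member_records, scheme)
    profile = build_profile(msa, background=background)
    ga = gathering_cutoff(profile, member_records)
    product = assign_product([m.product for m in member_records])
    return Family(
        family_id=family_id,
        member_ids=frozenset(m.id for m in member_records),
        msa=msa,
        profile=profile,
        gathering_cutoff=ga,
        product=product,
        member_lengths={m.id: len(m.sequence) for m in member_records},
    )


def build_families(
    member_sets: Sequence[Sequence[str]],
    records_by_id: Mapping[str, ProteinRecord],
    scheme: ScoringScheme,
    background: np.ndarray | None = None,
) -> list[Family]:
    """Assemble Family objects; ids F00001... by descending size then members."""
    ordered = sorted(member_sets, key=lambda ms: (-len(ms), sorted(ms)[0]))
    families = []
    for n, members in enumerate(ordered, start=1):
        records = [records_by_id[mid] for mid in sorted(members)]
        families.append(build_family(f"F{n:05d}", records, scheme, background=background))
    return families
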
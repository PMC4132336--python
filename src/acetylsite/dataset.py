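"""Dataset construction: negative balancing, homology reduction, folds.

Training data for acetylation-site models is heavily imbalanced (far more
nonacetylated than acetylated lysines), so negatives are reduced to a
representative subset of exactly the positive-set size by clustering on
sequence identity and keeping one medoid per cluster.  Homology between a
training set and a test set is removed with a two-stage filter: proteins
sharing more than 30% global identity are homologs, and a test site is
discarded only when its window is additionally identical to a window of
the homologous training protein.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.model_selection import StratifiedKFold

from .seqio import Fragment, ProteinRecord

#: Protein pairs above this global identity are treated as homologous.
HOMOLOGY_IDENTITY = 0.30

_aligner: Align.PairwiseAligner | None = None


def _get_aligner() -> Align.PairwiseAligner:
    # BL2SEQ-style defaults: BLOSUM62, gap open 11, gap extend 1.
    global _aligner
    if _aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        _aligner = aligner
    return _aligner


def _sanitize(seq: str) -> str:
    # U and the pad character are outside the BLOSUM62 alphabet; score them
    # as X.  Identity is still counted on the original symbols.
    return seq.replace("U", "X").replace("-", "X")


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns in the optimal global alignment.

    Identity = identical aligned residue pairs / alignment length
    (gap columns included in the denominator).
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    if seq_a == seq_b:
        return 1.0
    alignment = _get_aligner().align(_sanitize(seq_a), _sanitize(seq_b))[0]
    matches = 0
    for (a_start, a_end), (b_start, b_end) in zip(*alignment.aligned):
        for i, j in zip(range(a_start, a_end), range(b_start, b_end)):
            if seq_a[i] == seq_b[j]:
                matches += 1
    return matches / alignment.length


def _distance_matrix(windows: Sequence[str]) -> np.ndarray:
    n = len(windows)
    dist = np.zeros((n, n))
    cache: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            key = (windows[i], windows[j]) if windows[i] <= windows[j] else (windows[j], windows[i])
            d = cache.get(key)
            if d is None:
                d = 1.0 - pairwise_identity(windows[i], windows[j])
                cache[key] = d
            dist[i, j] = dist[j, i] = d
    return dist


def balance_negatives(
    positives: Sequence[Fragment],
    negatives: Sequence[Fragment],
    seed: int = 1,
    method: str = "kmedoids",
    max_iter: int = 50,
) -> list[Fragment]:
    """Select exactly ``len(positives)`` representative negative fragments.

    The default clusters the negative windows into K = |positives| groups
    by k-medoids on the distance ``1 − pairwise_identity`` and returns one
    medoid per cluster.  ``method="sample"`` is a fast alternative
    (seeded random subsample without replacement) for very large negative
    sets, since all-pairs identity is quadratic.
    """
    k = len(positives)
    if k < 1:
        raise ValueError("need at least one positive fragment")
    if len(negatives) < k:
        raise ValueError(
            f"only {len(negatives)} negatives for {k} positives; "
            "balancing cannot downsample — use all negatives instead"
        )
    if len(negatives) == k:
        return list(negatives)

    rng = np.random.default_rng(seed)
    if method == "sample":
        idx = rng.choice(len(negatives), size=k, replace=False)
        return [negatives[i] for i in sorted(idx)]
    if method != "kmedoids":
        raise ValueError(f"unknown balancing method {method!r}")

    windows = [f.window for f in negatives]
    dist = _distance_matrix(windows)
    medoids = np.sort(rng.choice(len(negatives), size=k, replace=False))
    for _ in range(max_iter):
        assignment = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assignment == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[np.argmin(within)]
        new_medoids = np.sort(new_medoids)
        if np.array_equal(new_medoids, medoids):
            break
        medoids = new_medoids
    return [negatives[i] for i in medoids]


def remove_test_homologs(
    train_proteins: Sequence[ProteinRecord],
    train_fragments: Sequence[Fragment],
    test_proteins: Sequence[ProteinRecord],
    test_fragments: Sequence[Fragment],
    identity_threshold: float = HOMOLOGY_IDENTITY,
) -> list[Fragment]:
    """Drop test fragments that duplicate training material.

    A test fragment is removed iff its source protein shares more than
    *identity_threshold* global identity with some training protein AND
    its window is identical (100%) to one of that training protein's
    fragment windows.
    """
    test_by_id = {p.id: p for p in test_proteins}
    train_windows: Mapping[str, set[str]] = defaultdict(set)
    for frag in train_fragments:
        train_windows[frag.protein_id].add(frag.window)

    identity_cache: dict[tuple[str, str], float] = {}
    kept = []
    for frag in test_fragments:
        test_protein = test_by_id[frag.protein_id]
        homolog_hit = False
        for train_protein in train_proteins:
            if frag.window not in train_windows[train_protein.id]:
                continue
            key = (test_protein.id, train_protein.id)
            if key not in identity_cache:
                identity_cache[key] = pairwise_identity(
                    test_protein.sequence, train_protein.sequence
                )
            if identity_cache[key] > identity_threshold:
                homolog_hit = True
                break
        if not homolog_hit:
            kept.append(frag)
    return kept


def deduplicate(fragments: Sequence[Fragment]) -> list[Fragment]:
    """Keep the first fragment per (protein_id, center).

    Conflicting labels for the same site are an error rather than a
    silent choice.
    """
    seen: dict[tuple[str, int], Fragment] = {}
    out = []
    for frag in fragments:
        key = (frag.protein_id, frag.center)
        prior = seen.get(key)
        if prior is None:
            seen[key] = frag
            out.append(frag)
        elif prior.label != frag.label:
            raise ValueError(
                f"conflicting labels for site {key}: {prior.label!r} vs {frag.label!r}"
            )
    return out


def assign_folds(
    fragments: Sequence[Fragment], k: int = 5, seed: int = 1
) -> dict[Fragment, int]:
    """Stratified k-fold assignment; per-class fold sizes differ by at most 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = [f.label for f in fragments]
    for cls in set(labels):
        if labels.count(cls) < k:
            raise ValueError(
                f"class {cls!r} has {labels.count(cls)} fragments, fewer than k={k}"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment: dict[Fragment, int] = {}
    y = np.array(labels)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        for i in test_idx:
            assignment[fragments[i]] = fold
    return assignment
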
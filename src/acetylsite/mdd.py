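"""Maximal dependence decomposition (MDD) of aligned peptide windows.

MDD recursively partitions a set of acetylated-lysine windows into motif
subgroups.  At each node it looks for the flank position whose residue
content depends most strongly on the other positions, measured by a
chi-square statistic on a 5×5 contingency table of amino-acid *property
groups* (polar / acidic / basic / hydrophobic / aromatic).  When some
position pair exceeds the significance threshold, the node is split into
the fragments that carry the winning property group at the winning
position ("with" branch) and the rest ("without" branch).  Recursion
stops when a node is smaller than ``max_cluster_size`` or no dependence
is significant, yielding leaf subgroups with conserved motifs.

The default threshold is the published constant 34.3 for the 5×5 table
(16 degrees of freedom).  Note that the upper-0.01 chi-square critical
value at df=16 is ≈32.0 and 34.3 is closer to the upper-0.005 point; the
constant is used verbatim (see docs/methods.md).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .seqio import STANDARD_AA, Fragment

#: Five-way chemical classification of the 20 standard amino acids.
PROPERTY_GROUPS: dict[str, str] = {
    "polar": "GSTCQN",
    "acidic": "DE",
    "basic": "KRH",
    "hydrophobic": "AVLIPM",
    "aromatic": "FYW",
}
GROUP_ORDER = ("polar", "acidic", "basic", "hydrophobic", "aromatic")

#: Published chi-square cutoff for the 5×5 property-group table.
DEFAULT_CHI2_THRESHOLD = 34.3
#: Degrees of freedom of the 5×5 contingency table: (5−1)(5−1).
CHI2_DF = 16

_AA_GROUP: dict[str, int] = {}
for _g, _letters in PROPERTY_GROUPS.items():
    for _aa in _letters:
        _AA_GROUP[_aa] = GROUP_ORDER.index(_g)
assert set(_AA_GROUP) == set(STANDARD_AA)


def residue_group(ch: str) -> int | None:
    """Group index of a residue, or None for pads/ambiguity codes."""
    return _AA_GROUP.get(ch)


@dataclass(frozen=True)
class ContingencyTable:
    """5×5 property-group co-occurrence counts between two flank positions."""

    counts: np.ndarray  # shape (5, 5)
    position_i: int  # offsets relative to the central lysine
    position_j: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def degrees_of_freedom(self) -> int:
        return CHI2_DF


def _window_index(offset: int, n: int) -> int:
    if offset == 0 or abs(offset) > n:
        raise ValueError(f"offset must be within ±{n} and nonzero, got {offset}")
    return n + offset


def contingency_table(
    fragments: Sequence[Fragment], i: int, j: int
) -> ContingencyTable:
    """Count group co-occurrences between flank offsets *i* and *j*.

    Offsets are relative to the central lysine (negative = N-terminal).
    Fragments with a pad or ambiguity code at either position are
    excluded from the table.
    """
    if i == j:
        raise ValueError("positions must differ")
    if not fragments:
        raise ValueError("contingency_table requires at least one fragment")
    n = fragments[0].n
    pi, pj = _window_index(i, n), _window_index(j, n)
    counts = np.zeros((5, 5))
    for frag in fragments:
        gi = residue_group(frag.window[pi])
        gj = residue_group(frag.window[pj])
        if gi is not None and gj is not None:
            counts[gi, gj] += 1
    return ContingencyTable(counts, i, j)


def chi_square(table: ContingencyTable) -> float:
    """Pearson chi-square of independence on the 5×5 group table.

    ``χ² = Σ_m Σ_n (X_mn − E_mn)² / E_mn`` with ``E_mn = X_mR·X_Cn / X``;
    cells whose expected count is zero contribute nothing.
    """
    counts = table.counts
    total = counts.sum()
    if total < 1:
        raise ValueError("empty contingency table")
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    mask = expected > 0
    return float(((counts[mask] - expected[mask]) ** 2 / expected[mask]).sum())


def _pairwise_chi2(
    fragments: Sequence[Fragment], offsets: Sequence[int]
) -> dict[tuple[int, int], float]:
    """χ² for every unordered offset pair (the statistic is symmetric)."""
    chi2: dict[tuple[int, int], float] = {}
    for a in range(len(offsets)):
        for b in range(a + 1, len(offsets)):
            i, j = offsets[a], offsets[b]
            table = contingency_table(fragments, i, j)
            value = chi_square(table) if table.total >= 1 else 0.0
            chi2[(i, j)] = chi2[(j, i)] = value
    return chi2


def best_split(
    fragments: Sequence[Fragment],
    chi2_threshold: float = DEFAULT_CHI2_THRESHOLD,
) -> tuple[int, str, float] | None:
    """Choose the most dependent (position, property group) to split on.

    For every flank offset ``i`` the dependence score is
    ``S_i = Σ_{j≠i} χ²(A_i, A_j)``.  Only offsets with at least one
    pairwise χ² above *chi2_threshold* are eligible; among those the
    offset with maximal ``S_i`` wins (ties broken toward the center, then
    toward the N-terminal side).  At the winning offset the property
    group with the largest summed positive observed−expected contribution
    across its pairwise tables is chosen.  Returns ``None`` when no pair
    is significant.
    """
    if len(fragments) < 2:
        return None
    n = fragments[0].n
    offsets = [o for o in range(-n, n + 1) if o != 0]
    chi2 = _pairwise_chi2(fragments, offsets)

    best_offset = None
    best_s = -1.0
    for i in offsets:
        pair_values = [chi2[(i, j)] for j in offsets if j != i]
        if max(pair_values) <= chi2_threshold:
            continue
        s_i = sum(pair_values)
        if best_offset is None or (
            (s_i, -abs(i), -i) > (best_s, -abs(best_offset), -best_offset)
        ):
            best_offset, best_s = i, s_i
    if best_offset is None:
        return None

    # Group choice: largest summed positive (observed − expected) mass for
    # the winning offset's rows across all its pairwise tables.
    contribution = np.zeros(5)
    for j in offsets:
        if j == best_offset:
            continue
        table = contingency_table(fragments, best_offset, j)
        total = table.counts.sum()
        if total < 1:
            continue
        expected = (
            np.outer(table.counts.sum(axis=1), table.counts.sum(axis=0)) / total
        )
        contribution += np.clip(table.counts - expected, 0.0, None).sum(axis=1)
    group = GROUP_ORDER[int(np.argmax(contribution))]
    max_pair = max(chi2[(best_offset, j)] for j in offsets if j != best_offset)
    return best_offset, group, max_pair


@dataclass
class MddLeaf:
    """A terminal subgroup: id (depth-first order) and member fragments."""

    id: int
    members: list[Fragment]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class MddNode:
    """An internal split: property *group* present at *position* or not."""

    position: int
    group: str
    chi2: float
    with_branch: "MddNode | MddLeaf"
    without_branch: "MddNode | MddLeaf"


@dataclass
class MddTree:
    """Binary decision tree over (position, property-group) tests."""

    root: MddNode | MddLeaf
    n: int
    max_cluster_size: int
    chi2_threshold: float

    def leaves(self) -> list[MddLeaf]:
        out: list[MddLeaf] = []

        def walk(node: MddNode | MddLeaf) -> None:
            if isinstance(node, MddLeaf):
                out.append(node)
            else:
                walk(node.with_branch)
                walk(node.without_branch)

        walk(self.root)
        return out

    def __iter__(self) -> Iterator[MddLeaf]:
        return iter(self.leaves())

    def to_dict(self) -> dict:
        def serialize(node: MddNode | MddLeaf) -> dict:
            if isinstance(node, MddLeaf):
                return {"leaf": node.id, "size": node.size}
            return {
                "position": node.position,
                "group": node.group,
                "chi2": node.chi2,
                "with": serialize(node.with_branch),
                "without": serialize(node.without_branch),
            }

        return {
            "n": self.n,
            "max_cluster_size": self.max_cluster_size,
            "chi2_threshold": self.chi2_threshold,
            "tree": serialize(self.root),
        }

    def save_json(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(self.to_dict(), handle, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "MddTree":
        """Rebuild the routing structure from :meth:`to_dict` output.

        Leaf member lists are not serialized, so the reconstructed tree
        routes fragments but carries empty leaves.
        """

        def parse(node: dict) -> MddNode | MddLeaf:
            if "leaf" in node:
                return MddLeaf(node["leaf"], [])
            return MddNode(
                node["position"],
                node["group"],
                node["chi2"],
                parse(node["with"]),
                parse(node["without"]),
            )

        return cls(
            parse(payload["tree"]),
            payload["n"],
            payload["max_cluster_size"],
            payload["chi2_threshold"],
        )


def _has_group(fragment: Fragment, position: int, group: str) -> bool:
    idx = _window_index(position, fragment.n)
    g = residue_group(fragment.window[idx])
    return g is not None and GROUP_ORDER[g] == group


def mdd_cluster(
    fragments: Sequence[Fragment],
    max_cluster_size: int | None = None,
    chi2_threshold: float = DEFAULT_CHI2_THRESHOLD,
) -> MddTree:
    """Recursively partition fragments into motif subgroups.

    A node is split only while its size is at least *max_cluster_size*
    and :func:`best_split` finds a significant dependence; splitting is
    deterministic, so repeated runs on the same input are identical.
    The default *max_cluster_size* is ``ceil(len(fragments) / 5)``.
    """
    fragments = list(fragments)
    if not fragments:
        raise ValueError("mdd_cluster requires at least one fragment")
    if max_cluster_size is None:
        max_cluster_size = math.ceil(len(fragments) / 5)
    if max_cluster_size < 2:
        raise ValueError("max_cluster_size must be >= 2")
    n = fragments[0].n
    if any(f.n != n for f in fragments):
        raise ValueError("all fragments must share the same window length")

    counter = iter(range(len(fragments) + 1))

    def build(members: list[Fragment]) -> MddNode | MddLeaf:
        if len(members) < max_cluster_size:
            return MddLeaf(next(counter), members)
        split = best_split(members, chi2_threshold)
        if split is None:
            return MddLeaf(next(counter), members)
        position, group, chi2_value = split
        with_members = [f for f in members if _has_group(f, position, group)]
        without_members = [f for f in members if not _has_group(f, position, group)]
        if not with_members or not without_members:
            return MddLeaf(next(counter), members)
        return MddNode(
            position,
            group,
            chi2_value,
            build(with_members),
            build(without_members),
        )

    return MddTree(build(fragments), n, max_cluster_size, chi2_threshold)


def assign_subgroup(tree: MddTree, fragment: Fragment) -> int:
    """Route a fragment down the tree; returns the reached leaf id.

    A pad or ambiguity code at a tested position fails the group test and
    follows the "without" branch.
    """
    if fragment.n != tree.n:
        raise ValueError(
            f"fragment half-window {fragment.n} does not match tree n={tree.n}"
        )
    node = tree.root
    while isinstance(node, MddNode):
        node = (
            node.with_branch
            if _has_group(fragment, node.position, node.group)
            else node.without_branch
        )
    return node.id


def subgroup_pfm(members: Sequence[Fragment]) -> np.ndarray:
    """Position frequency matrix of a leaf: (21 symbols, L), columns sum to 1."""
    if not members:
        raise ValueError("subgroup_pfm requires at least one member")
    L = len(members[0].window)
    counts = np.zeros((21, L))
    for frag in members:
        for p, ch in enumerate(frag.window):
            row = STANDARD_AA.index(ch) if ch in STANDARD_AA else 20
            counts[row, p] += 1
    return counts / len(members)


def write_pfm(pfm: np.ndarray, path: str | Path) -> None:
    """Export a PFM as TSV (rows: 20 AAs + 'other'; columns: positions)."""
    symbols = list(STANDARD_AA) + ["other"]
    with open(path, "w") as handle:
        L = pfm.shape[1]
        handle.write("symbol\t" + "\t".join(str(p) for p in range(L)) + "\n")
        for sym, row in zip(symbols, pfm):
            handle.write(sym + "\t" + "\t".join(format(v, ".6g") for v in row) + "\n")
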
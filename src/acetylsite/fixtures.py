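"""Seeded synthetic benchmark generator with planted property-group motifs.

Every module in the package is exercised offline on data from this
generator: background proteins drawn i.i.d. from a residue composition,
acetylation sites planted on interior lysines by resampling their flanks
under a :class:`MotifSpec`, and untouched lysines serving as negatives.
The ground-truth motif assignment of each planted site is returned so
clustering recovery can be scored.

A :class:`MotifSpec` entry ``(offset, group, probability)`` makes the
residue at that flank offset come from the named property group with
exactly the stated probability (the complement is drawn from the
background renormalized over non-group residues).  Probability 0.0
therefore *excludes* the group at that offset — the "without" structure
an MDD tree carves out.  The default benchmark plants two mutually
exclusive multi-position motifs inspired by the biology of acetylation
flanks: a K/R/H-rich stretch downstream of the site (histone-like) and a
D/E-rich stretch upstream (nonhistone-like).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .mdd import PROPERTY_GROUPS
from .seqio import (
    PAD,
    STANDARD_AA,
    Fragment,
    ProteinRecord,
    SiteAnnotation,
    extract_fragment,
    write_fasta,
)

#: Uniform background over the 20 standard amino acids — the simplest
#: null for chi-square calibration.
UNIFORM_BACKGROUND: dict[str, float] = {aa: 0.05 for aa in STANDARD_AA}

#: Approximate SwissProt residue composition, for optionally less
#: idealized backgrounds.
SWISSPROT_BACKGROUND: dict[str, float] = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0581, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0474, "Q": 0.0394, "R": 0.0553,
    "S": 0.0663, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass(frozen=True)
class MotifSpec:
    """A planted motif: per-offset property-group enrichment.

    ``positions`` holds ``(offset, group, probability)`` triples with
    offsets in ±n excluding 0; ``count`` is the number of sites planted
    with this motif.
    """

    name: str
    positions: tuple[tuple[int, str, float], ...]
    count: int

    def __post_init__(self) -> None:
        for offset, group, prob in self.positions:
            if offset == 0:
                raise ValueError("motif offsets must not be the center")
            if group not in PROPERTY_GROUPS:
                raise ValueError(f"unknown property group {group!r}")
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"probability {prob} outside [0, 1]")
        if self.count < 1:
            raise ValueError("motif count must be >= 1")


#: Default benchmark motifs: mutually exclusive basic-downstream vs
#: acidic-upstream flanks (see module docstring).
DEFAULT_MOTIFS: tuple[MotifSpec, ...] = (
    MotifSpec(
        "basic_downstream",
        ((1, "basic", 0.95), (2, "basic", 0.95), (3, "basic", 0.95),
         (-1, "acidic", 0.0), (-2, "acidic", 0.0), (-3, "acidic", 0.0)),
        count=150,
    ),
    MotifSpec(
        "acidic_upstream",
        ((-1, "acidic", 0.95), (-2, "acidic", 0.95), (-3, "acidic", 0.95),
         (1, "basic", 0.0), (2, "basic", 0.0), (3, "basic", 0.0)),
        count=150,
    ),
)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Shape of the default synthetic study: two motif classes of 150
    sites each plus 300 background negatives on 15-mer windows."""

    n: int = 7
    motif_specs: tuple[MotifSpec, ...] = DEFAULT_MOTIFS
    n_negatives: int = 300
    n_proteins: int = 80
    protein_length: int = 300
    background: Mapping[str, float] | None = None  # None = uniform


def _background_arrays(background: Mapping[str, float] | None):
    bg = dict(UNIFORM_BACKGROUND if background is None else background)
    letters = list(STANDARD_AA)
    probs = np.array([bg[aa] for aa in letters], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("background composition must sum to 1")
    return letters, probs


def generate_proteins(
    count: int,
    length: int,
    background: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[ProteinRecord]:
    """I.i.d. background proteins, each guaranteed at least one lysine."""
    letters, probs = _background_arrays(background)
    rng = np.random.default_rng(seed)
    proteins = []
    for i in range(count):
        seq = rng.choice(letters, size=length, p=probs)
        if "K" not in seq:
            seq[rng.integers(length)] = "K"
        proteins.append(ProteinRecord(f"SYN{i:04d}", "".join(seq)))
    return proteins


def _draw_flank(
    rng: np.random.Generator,
    entry: tuple[str, float] | None,
    letters: list[str],
    probs: np.ndarray,
) -> str:
    if entry is None:
        return str(rng.choice(letters, p=probs))
    group, prob = entry
    members = list(PROPERTY_GROUPS[group])
    if rng.random() < prob:
        return str(rng.choice(members))
    keep = [i for i, aa in enumerate(letters) if aa not in members]
    rest = probs[keep] / probs[keep].sum()
    return str(rng.choice([letters[i] for i in keep], p=rest))


def plant_sites(
    proteins: Sequence[ProteinRecord],
    motif_specs: Sequence[MotifSpec],
    n: int = 7,
    seed: int = 0,
    n_negatives: int | None = None,
    background: Mapping[str, float] | None = None,
) -> tuple[list[ProteinRecord], list[SiteAnnotation], dict[tuple[str, int], str]]:
    """Plant motif sites on interior lysines; untouched lysines become negatives.

    Returns the mutated proteins, site annotations (planted positives
    plus negatives), and the ground-truth map ``(protein_id, position) →
    motif name`` for the positives.  Candidate positives are interior
    lysines whose full window fits in the sequence, chosen so planted
    windows never overlap; the flanks of each chosen site are resampled
    per its motif spec.
    """
    letters, probs = _background_arrays(background)
    rng = np.random.default_rng(seed)
    total_needed = sum(spec.count for spec in motif_specs)

    # Non-overlapping interior lysine windows, greedily per protein.
    candidates: list[tuple[int, int]] = []  # (protein index, 1-based position)
    for pi, protein in enumerate(proteins):
        last_end = -1
        for idx, ch in enumerate(protein.sequence):
            pos = idx + 1
            if ch != "K" or pos - n < 1 or pos + n > len(protein):
                continue
            if pos - n <= last_end:
                continue
            candidates.append((pi, pos))
            last_end = pos + n
    if len(candidates) < total_needed:
        raise ValueError(
            f"only {len(candidates)} plantable lysines for {total_needed} sites; "
            "use more or longer proteins"
        )
    order = rng.permutation(len(candidates))
    chosen = [candidates[i] for i in order[:total_needed]]

    sequences = [list(p.sequence) for p in proteins]
    truth: dict[tuple[str, int], str] = {}
    annotations: list[SiteAnnotation] = []
    cursor = 0
    planted_windows: dict[int, list[tuple[int, int]]] = {}
    for spec in motif_specs:
        by_offset = {offset: (group, prob) for offset, group, prob in spec.positions}
        for pi, pos in chosen[cursor : cursor + spec.count]:
            for offset in range(-n, n + 1):
                if offset == 0:
                    continue
                sequences[pi][pos - 1 + offset] = _draw_flank(
                    rng, by_offset.get(offset), letters, probs
                )
            pid = proteins[pi].id
            annotations.append(SiteAnnotation(pid, pos, "positive"))
            truth[(pid, pos)] = spec.name
            planted_windows.setdefault(pi, []).append((pos - n, pos + n))
        cursor += spec.count

    mutated = [
        ProteinRecord(p.id, "".join(seq)) for p, seq in zip(proteins, sequences)
    ]

    # Negatives: lysines outside every planted window, in the final sequences.
    negatives: list[tuple[int, int]] = []
    for pi, protein in enumerate(mutated):
        windows = planted_windows.get(pi, [])
        for idx, ch in enumerate(protein.sequence):
            pos = idx + 1
            if ch != "K":
                continue
            if any(start <= pos <= end for start, end in windows):
                continue
            negatives.append((pi, pos))
    if n_negatives is not None:
        if len(negatives) < n_negatives:
            raise ValueError(
                f"only {len(negatives)} negative lysines available, "
                f"{n_negatives} requested"
            )
        keep = rng.choice(len(negatives), size=n_negatives, replace=False)
        negatives = [negatives[i] for i in sorted(keep)]
    for pi, pos in negatives:
        annotations.append(SiteAnnotation(mutated[pi].id, pos, "negative"))

    return mutated, annotations, truth


def benchmark_fragments(
    proteins: Sequence[ProteinRecord],
    annotations: Sequence[SiteAnnotation],
    n: int = 7,
) -> tuple[list[Fragment], list[Fragment]]:
    """Extract (positives, negatives) fragment lists from annotations."""
    by_id = {p.id: p for p in proteins}
    pos, neg = [], []
    for ann in annotations:
        frag = extract_fragment(by_id[ann.protein_id], ann.position, n, ann.label)
        (pos if ann.label == "positive" else neg).append(frag)
    return pos, neg


def generate_benchmark(
    config: BenchmarkConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
):
    """Produce the full synthetic dataset, optionally written to disk.

    Returns ``(proteins, annotations, truth)``.  With *out_dir* the same
    data is written as ``proteins.fasta``, ``sites.tsv`` (the annotation
    TSV consumed by :mod:`acetylsite.seqio`) and ``truth.json`` mapping
    ``"protein_id:position"`` to the planted motif name.
    """
    config = config or BenchmarkConfig()
    proteins = generate_proteins(
        config.n_proteins, config.protein_length, config.background, seed
    )
    mutated, annotations, truth = plant_sites(
        proteins,
        config.motif_specs,
        n=config.n,
        seed=seed + 1,
        n_negatives=config.n_negatives,
        background=config.background,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(mutated, out_dir / "proteins.fasta")
        with open(out_dir / "sites.tsv", "w") as handle:
            handle.write("protein_id\tposition\tlabel\n")
            for ann in annotations:
                handle.write(f"{ann.protein_id}\t{ann.position}\t{ann.label}\n")
        with open(out_dir / "truth.json", "w") as handle:
            json.dump(
                {f"{pid}:{pos}": motif for (pid, pos), motif in truth.items()},
                handle,
                indent=2,
            )
    return mutated, annotations, truth
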
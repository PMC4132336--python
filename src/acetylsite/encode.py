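"""Feature encoders: fragment windows → numeric vectors.

Seven schemes are supported, each deterministic in the window (plus a
sidecar where noted) and independent of the label:

========  ==========  =======================================================
scheme    dimension   meaning
========  ==========  =======================================================
``AA``    ``21·L``    one-hot per position over 20 AAs + one "other" slot
``B62``   ``20·L``    BLOSUM62 substitution row of each residue
``AAC``   ``20``      amino-acid composition of the window
``AAPC``  ``400``     ordered adjacent amino-acid pair composition (20×20)
``PWM``   ``L``       positive-set position-weight-matrix frequency lookup
``ASA``   ``L``       accessible surface area per residue (sidecar)
``PSSM``  ``20·L``    PSI-BLAST profile rows, logistic-rescaled (sidecar)
========  ==========  =======================================================

``L = 2n + 1`` is the window length.  Schemes combine by concatenation
with ``'+'``-joined names, e.g. ``"B62+AAPC"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import PAD, STANDARD_AA, Fragment

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}
#: 21-symbol alphabet used by the one-hot and PWM encoders: the 20
#: standard amino acids plus a shared slot for pads and ambiguity codes.
OTHER_SLOT = 20

SCHEMES = ("AA", "B62", "AAC", "AAPC", "PWM", "ASA", "PSSM")

_B62 = substitution_matrices.load("BLOSUM62")
#: Per-residue BLOSUM62 rows restricted to the 20 standard columns.
B62_ROWS: dict[str, np.ndarray] = {
    aa: np.array([float(_B62[aa, bb]) for bb in STANDARD_AA]) for aa in STANDARD_AA
}
_B62_ZERO = np.zeros(20)


def _symbol_index(ch: str) -> int:
    return AA_INDEX.get(ch, OTHER_SLOT)


@dataclass(frozen=True)
class FeatureVector:
    """A named numeric encoding of a single fragment."""

    scheme: str
    values: np.ndarray

    @property
    def dimension(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix over 21 symbols × L positions.

    Columns are add-one-smoothed relative frequencies and each sums to 1.
    """

    matrix: np.ndarray  # shape (21, L)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass
class EncodingContext:
    """Side inputs needed by the PWM/ASA/PSSM schemes.

    ``asa`` maps protein id → {1-based position: ASA value}; ``pssm`` maps
    protein id → (length, 20) score matrix in :data:`STANDARD_AA` column
    order.
    """

    pwm: Pwm | None = None
    asa: Mapping[str, Mapping[int, float]] | None = None
    pssm: Mapping[str, np.ndarray] | None = None


def encode_binary(fragment: Fragment) -> FeatureVector:
    """Orthogonal one-hot encoding, 21 slots per window position."""
    L = len(fragment.window)
    values = np.zeros(21 * L)
    for p, ch in enumerate(fragment.window):
        values[21 * p + _symbol_index(ch)] = 1.0
    return FeatureVector("AA", values)


def encode_blosum62(fragment: Fragment) -> FeatureVector:
    """Per-position BLOSUM62 substitution rows; pads/ambiguous → zero row."""
    rows = [B62_ROWS.get(ch, _B62_ZERO) for ch in fragment.window]
    return FeatureVector("B62", np.concatenate(rows))


def encode_aac(fragment: Fragment) -> FeatureVector:
    """Relative frequencies of the 20 standard AAs in the window."""
    values = np.zeros(20)
    total = 0
    for ch in fragment.window:
        idx = AA_INDEX.get(ch)
        if idx is not None:
            values[idx] += 1
            total += 1
    if total:
        values /= total
    return FeatureVector("AAC", values)


def encode_aapc(fragment: Fragment) -> FeatureVector:
    """Ordered adjacent-pair composition, 400 = 20×20 dimensions.

    Pairs touching a pad or ambiguity code are skipped.
    """
    values = np.zeros(400)
    total = 0
    window = fragment.window
    for a, b in zip(window, window[1:]):
        ia, ib = AA_INDEX.get(a), AA_INDEX.get(b)
        if ia is not None and ib is not None:
            values[20 * ia + ib] += 1
            total += 1
    if total:
        values /= total
    return FeatureVector("AAPC", values)


def build_pwm(positive_fragments: Sequence[Fragment]) -> Pwm:
    """Symbol frequencies per position over the positive training set.

    Add-one smoothing keeps every column strictly positive; ambiguity
    codes are pooled with the pad into the 21st slot.
    """
    if not positive_fragments:
        raise ValueError("build_pwm requires at least one fragment")
    L = len(positive_fragments[0].window)
    if any(len(f.window) != L for f in positive_fragments):
        raise ValueError("all fragments must share the same window length")
    counts = np.zeros((21, L))
    for frag in positive_fragments:
        for p, ch in enumerate(frag.window):
            counts[_symbol_index(ch), p] += 1
    return Pwm((counts + 1.0) / (len(positive_fragments) + 21.0))


def encode_pwm(fragment: Fragment, pwm: Pwm) -> FeatureVector:
    """The PWM frequency of the fragment's own symbol at each position."""
    if len(fragment.window) != pwm.length:
        raise ValueError(
            f"fragment window length {len(fragment.window)} != PWM length {pwm.length}"
        )
    values = np.array(
        [pwm.matrix[_symbol_index(ch), p] for p, ch in enumerate(fragment.window)]
    )
    return FeatureVector("PWM", values)


def read_asa_sidecar(path: str | Path) -> dict[str, dict[int, float]]:
    """Read a per-residue ASA table (``protein_id<TAB>position<TAB>asa``)."""
    asa: dict[str, dict[int, float]] = {}
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    start = 1 if lines and lines[0].lower().startswith("protein_id") else 0
    for rowno, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"ASA row {rowno}: expected 3 tab-separated columns")
        pid, pos, value = fields[0], int(fields[1]), float(fields[2])
        if pos < 1:
            raise ValueError(f"ASA row {rowno}: position must be >= 1")
        asa.setdefault(pid, {})[pos] = value
    return asa


def validate_asa(asa: Mapping[str, Mapping[int, float]], proteins) -> None:
    """Check that each sidecar covers its protein exactly once per residue."""
    for protein in proteins:
        values = asa.get(protein.id)
        if values is None:
            continue
        expected = set(range(1, len(protein) + 1))
        if set(values) != expected:
            raise ValueError(
                f"ASA sidecar for {protein.id!r} covers {len(values)} positions, "
                f"protein has {len(protein)} residues"
            )


def encode_asa(fragment: Fragment, asa: Mapping[int, float]) -> FeatureVector:
    """ASA of each window residue; pad positions get 0."""
    n = fragment.n
    values = np.zeros(2 * n + 1)
    for p, ch in enumerate(fragment.window):
        if ch == PAD:
            continue
        pos = fragment.center - n + p
        if pos not in asa:
            raise ValueError(
                f"ASA sidecar for {fragment.protein_id!r} missing position {pos}"
            )
        values[p] = asa[pos]
    return FeatureVector("ASA", values)


def read_pssm(path: str | Path) -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm``).

    Returns a (protein length, 20) array of log-odds scores with columns
    reordered to :data:`STANDARD_AA`.
    """
    rows: list[np.ndarray] = []
    column_order: list[str] | None = None
    expected_index = 1
    with open(path) as handle:
        for line in handle:
            fields = line.split()
            if column_order is None:
                # Header: 40 residue letters; the first 20 label the scores.
                if len(fields) >= 20 and all(f in STANDARD_AA for f in fields[:20]):
                    column_order = fields[:20]
                continue
            if not fields or not fields[0].isdigit():
                continue
            if len(fields) < 22:
                raise ValueError(f"malformed PSSM row: {line.rstrip()!r}")
            if int(fields[0]) != expected_index:
                raise ValueError(
                    f"PSSM rows out of order: expected {expected_index}, got {fields[0]}"
                )
            expected_index += 1
            scores = np.array([float(x) for x in fields[2:22]])
            reorder = [column_order.index(aa) for aa in STANDARD_AA]
            rows.append(scores[reorder])
    if column_order is None or not rows:
        raise ValueError(f"{path}: not a PSI-BLAST ASCII PSSM")
    return np.vstack(rows)


def encode_pssm(fragment: Fragment, pssm: np.ndarray) -> FeatureVector:
    """Logistic-rescaled profile rows per window position; pads → zeros.

    Raw log-odds scores are mapped through ``1 / (1 + exp(-x))`` so every
    feature lies in (0, 1); pad positions are exact zeros by convention.
    """
    n = fragment.n
    L = 2 * n + 1
    values = np.zeros(20 * L)
    for p, ch in enumerate(fragment.window):
        if ch == PAD:
            continue
        pos = fragment.center - n + p  # 1-based residue index
        if not 1 <= pos <= pssm.shape[0]:
            raise ValueError(
                f"PSSM for {fragment.protein_id!r} has {pssm.shape[0]} rows, "
                f"window needs position {pos}"
            )
        values[20 * p : 20 * (p + 1)] = 1.0 / (1.0 + np.exp(-pssm[pos - 1]))
    return FeatureVector("PSSM", values)


def concat_features(vectors: Sequence[FeatureVector]) -> FeatureVector:
    """Ordered concatenation; the scheme name records the order."""
    if not vectors:
        raise ValueError("concat_features requires at least one vector")
    if len(vectors) == 1:
        return vectors[0]
    return FeatureVector(
        "+".join(v.scheme for v in vectors),
        np.concatenate([v.values for v in vectors]),
    )


_SINGLE = {
    "AA": encode_binary,
    "B62": encode_blosum62,
    "AAC": encode_aac,
    "AAPC": encode_aapc,
}


def encode_fragment(
    fragment: Fragment, scheme: str, context: EncodingContext | None = None
) -> FeatureVector:
    """Encode one fragment under a (possibly ``'+'``-combined) scheme."""
    parts = []
    for name in scheme.split("+"):
        if name in _SINGLE:
            parts.append(_SINGLE[name](fragment))
        elif name == "PWM":
            if context is None or context.pwm is None:
                raise ValueError("scheme PWM requires an EncodingContext with a pwm")
            parts.append(encode_pwm(fragment, context.pwm))
        elif name == "ASA":
            if context is None or context.asa is None:
                raise ValueError("scheme ASA requires an EncodingContext with asa values")
            if fragment.protein_id not in context.asa:
                raise ValueError(f"no ASA sidecar for protein {fragment.protein_id!r}")
            parts.append(encode_asa(fragment, context.asa[fragment.protein_id]))
        elif name == "PSSM":
            if context is None or context.pssm is None:
                raise ValueError("scheme PSSM requires an EncodingContext with pssm matrices")
            if fragment.protein_id not in context.pssm:
                raise ValueError(f"no PSSM for protein {fragment.protein_id!r}")
            parts.append(encode_pssm(fragment, context.pssm[fragment.protein_id]))
        else:
            raise ValueError(f"unknown feature scheme {name!r}")
    return concat_features(parts)


def encode_fragments(
    fragments: Sequence[Fragment], scheme: str, context: EncodingContext | None = None
) -> np.ndarray:
    """Encode a fragment list into a dense (n_fragments, dim) matrix."""
    return np.vstack([encode_fragment(f, scheme, context).values for f in fragments])


def write_feature_matrix(
    fragments: Sequence[Fragment],
    scheme: str,
    path: str | Path,
    context: EncodingContext | None = None,
) -> None:
    """Export an encoded fragment set as a dense TSV with named columns."""
    matrix = encode_fragments(fragments, scheme, context)
    header = ["protein_id", "center", "label"] + [
        f"{scheme}_{i}" for i in range(matrix.shape[1])
    ]
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for frag, row in zip(fragments, matrix):
            cells = [frag.protein_id, str(frag.center), frag.label]
            cells += [format(v, ".6g") for v in row]
            handle.write("\t".join(cells) + "\n")
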
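"""Sequence and site-annotation I/O, and lysine-centered window extraction.

The unit of prediction throughout the package is a *fragment*: a peptide
window of length ``2n + 1`` centered on a candidate lysine.  Windows that
run off a protein terminus are padded with ``'-'``, which downstream
encoders treat as a 21st symbol.  Coordinates in all on-disk formats are
1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

PAD = "-"
#: The 20 standard amino acids, in the fixed alphabetical order used by
#: every positional encoder in :mod:`acetylsite.encode`.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Nonstandard letters accepted in input sequences (ambiguity codes and
#: selenocysteine); encoders map these to a shared "other" slot.
AMBIGUOUS_AA = "BZXU"
_ALLOWED = set(STANDARD_AA) | set(AMBIGUOUS_AA)

VALID_LABELS = ("positive", "negative")


class FastaParseError(ValueError):
    """Malformed FASTA input (message names the offending line)."""


class AnnotationError(ValueError):
    """Invalid site-annotation row (message identifies the row)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid sequence characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A labelled candidate site: 1-based lysine position in a protein."""

    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")


@dataclass(frozen=True)
class Fragment:
    """A ``2n+1``-residue window centered on a lysine.

    ``window[n]`` is always ``'K'``; flank positions that fall outside the
    source protein hold the pad character ``'-'``.
    """

    protein_id: str
    center: int
    window: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if len(self.window) % 2 != 1:
            raise ValueError(f"window length must be odd, got {len(self.window)}")
        n = len(self.window) // 2
        if self.window[n] != "K":
            raise ValueError(
                f"window center must be 'K', got {self.window[n]!r} in {self.window!r}"
            )
        if self.label not in VALID_LABELS + ("unknown",):
            raise ValueError(f"invalid fragment label {self.label!r}")

    @property
    def n(self) -> int:
        """Half-window width (window length is ``2n + 1``)."""
        return len(self.window) // 2


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a multi-record FASTA file.

    Sequences are uppercased and a single terminal ``'*'`` stop is
    stripped.  Duplicate record ids, empty sequences and sequence data
    before the first header raise :class:`FastaParseError` naming the line.
    """
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    parts: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(parts).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FastaParseError(
                f"line {header_line}: record {header!r} has an empty sequence"
            )
        try:
            records.append(ProteinRecord(header, seq))
        except ValueError as exc:
            raise FastaParseError(f"record starting at line {header_line}: {exc}") from exc

    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"line {lineno}: empty FASTA header")
                header_line = lineno
                parts = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before first '>' header"
                    )
                parts.append(line)
    flush()

    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.id] = seen.get(rec.id, 0) + 1
    dupes = sorted(i for i, c in seen.items() if c > 1)
    if dupes:
        raise FastaParseError(f"duplicate record ids: {dupes}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def read_site_annotations(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[SiteAnnotation]:
    """Read the tab-delimited site table and validate against *proteins*.

    Expected columns: ``protein_id<TAB>position<TAB>label`` with a header
    row.  Each row must reference a known protein, a position inside it,
    and a lysine residue at that position.
    """
    by_id = {p.id: p for p in proteins}
    annotations: list[SiteAnnotation] = []
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    if not lines:
        raise AnnotationError(f"{path}: empty annotation file")
    start = 1 if lines[0].lower().startswith("protein_id") else 0
    for rowno, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise AnnotationError(f"row {rowno}: expected 3 tab-separated columns")
        pid, pos_str, label = fields[0], fields[1], fields[2]
        try:
            position = int(pos_str)
        except ValueError:
            raise AnnotationError(f"row {rowno}: position {pos_str!r} is not an integer")
        protein = by_id.get(pid)
        if protein is None:
            raise AnnotationError(f"row {rowno}: unknown protein id {pid!r}")
        if not 1 <= position <= len(protein):
            raise AnnotationError(
                f"row {rowno}: position {position} out of range for {pid!r} "
                f"(length {len(protein)})"
            )
        residue = protein.sequence[position - 1]
        if residue != "K":
            raise AnnotationError(
                f"row {rowno}: residue at {pid!r}:{position} is {residue!r}, not 'K'"
            )
        try:
            annotations.append(SiteAnnotation(pid, position, label))
        except ValueError as exc:
            raise AnnotationError(f"row {rowno}: {exc}") from exc
    return annotations


def extract_fragment(
    protein: ProteinRecord, position: int, n: int = 7, label: str = "unknown"
) -> Fragment:
    """Cut the ``2n+1`` window centered on the lysine at *position* (1-based).

    Flank positions before residue 1 or past the terminus are filled with
    the pad character.
    """
    if not 1 <= position <= len(protein):
        raise ValueError(
            f"position {position} out of range for {protein.id!r} (length {len(protein)})"
        )
    if protein.sequence[position - 1] != "K":
        raise ValueError(
            f"residue at {protein.id!r}:{position} is "
            f"{protein.sequence[position - 1]!r}, not 'K'"
        )
    idx = position - 1
    left = protein.sequence[max(0, idx - n) : idx]
    right = protein.sequence[idx + 1 : idx + 1 + n]
    window = PAD * (n - len(left)) + left + "K" + right + PAD * (n - len(right))
    return Fragment(protein.id, position, window, label)


def enumerate_lysine_fragments(protein: ProteinRecord, n: int = 7) -> list[Fragment]:
    """One unlabelled fragment per lysine, in ascending position order."""
    return [
        extract_fragment(protein, i + 1, n)
        for i, ch in enumerate(protein.sequence)
        if ch == "K"
    ]


def write_fragments(fragments: Iterable[Fragment], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("protein_id\tcenter\twindow\tlabel\n")
        for frag in fragments:
            handle.write(f"{frag.protein_id}\t{frag.center}\t{frag.window}\t{frag.label}\n")


def read_fragments(path: str | Path) -> list[Fragment]:
    fragments = []
    with open(path) as handle:
        lines = [ln.rstrip("\n") for ln in handle if ln.strip()]
    for line in lines[1:]:
        pid, center, window, label = line.split("\t")
        fragments.append(Fragment(pid, int(center), window, label))
    return fragments
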
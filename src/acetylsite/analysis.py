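"""Positional composition-bias statistics between fragment sets.

This is the computation behind two-sample sequence-logo displays: for
every flank position and residue, the frequency among acetylated windows
is compared with the frequency among nonacetylated windows by a
two-proportion z-test with continuity correction, and the residue is
flagged as enriched or depleted at the chosen significance level.  No
multiple-testing correction is applied, matching common practice for
these displays; the resulting inflation of the per-table false-positive
rate is bounded and documented in docs/methods.md.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy.stats import norm

from .seqio import STANDARD_AA, Fragment


def _two_proportion_p(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided two-proportion z-test with continuity correction."""
    p1, p2 = x1 / n1, x2 / n2
    if p1 == p2:
        return 1.0
    pooled = (x1 + x2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        return 1.0
    cc = 0.5 * (1.0 / n1 + 1.0 / n2)
    z = max(0.0, abs(p1 - p2) - cc) / se
    return float(2.0 * norm.sf(z))


def composition_bias(
    pos: Sequence[Fragment],
    neg: Sequence[Fragment],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per (position, residue) enrichment/depletion table.

    Positions are offsets relative to the central lysine (center
    excluded).  Frequencies are fractions of fragments carrying the
    residue at that position (pads count toward the denominator).
    Direction is ``enriched``/``depleted`` by the sign of the positive
    minus negative frequency when ``p <= alpha``, else ``none``; exactly
    equal frequencies are always ``none``.
    """
    if not pos or not neg:
        raise ValueError("both fragment sets must be nonempty")
    L = len(pos[0].window)
    if any(len(f.window) != L for f in list(pos) + list(neg)):
        raise ValueError("all fragments must share the same window length")
    n = L // 2
    n1, n2 = len(pos), len(neg)
    rows = []
    for offset in range(-n, n + 1):
        if offset == 0:
            continue
        p_idx = n + offset
        pos_column = [f.window[p_idx] for f in pos]
        neg_column = [f.window[p_idx] for f in neg]
        for residue in STANDARD_AA:
            x1 = pos_column.count(residue)
            x2 = neg_column.count(residue)
            p_value = _two_proportion_p(x1, n1, x2, n2)
            f1, f2 = x1 / n1, x2 / n2
            if f1 == f2 or p_value > alpha:
                direction = "none"
            else:
                direction = "enriched" if f1 > f2 else "depleted"
            rows.append(
                {
                    "position": offset,
                    "residue": residue,
                    "pos_freq": f1,
                    "neg_freq": f2,
                    "p_value": p_value,
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


def write_bias_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def render_bias(table: pd.DataFrame) -> str:
    """Plain-text summary: significant residues per position."""
    lines = []
    for offset, group in table.groupby("position"):
        enriched = "".join(group.loc[group.direction == "enriched", "residue"])
        depleted = "".join(group.loc[group.direction == "depleted", "residue"])
        if enriched or depleted:
            lines.append(
                f"{offset:+d}: enriched [{enriched or '-'}] depleted [{depleted or '-'}]"
            )
    return "\n".join(lines) if lines else "(no significant positional bias)"
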
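"""Tajima's D neutrality test on ORF alignments.

D contrasts two estimators of the population mutation parameter theta:
mean pairwise difference count (pi) and the segregating-site count S
scaled by a1 = sum 1/i. Under neutrality in a constant-size population
their expectations agree; an excess of rare variants (recent expansion or
selective sweep) drives D negative, balancing selection drives it
positive. Computed with complete deletion of gap/ambiguous columns, on
difference counts per alignment (not per site), matching the common
implementation for this test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .distances import complete_deletion_columns
from .seqio import Alignment


@dataclass
class TajimaResult:
    n: int
    S: int
    pi: float  # mean pairwise differences per alignment
    D: Optional[float]
    sites: int  # columns retained after complete deletion
    pi_per_site: float = 0.0
    warnings: list[str] = field(default_factory=list)


def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) from the standard a1, a2, b1, b2, c1, c2 cascade."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_d(aln: Alignment) -> TajimaResult:
    """Tajima's neutrality statistic for one alignment.

    Columns with any gap or N are excluded (complete deletion). With S = 0
    the statistic is undefined but S and pi are still reported; n < 4
    triggers a warning (small per-genotype ORF sets are legitimate but the
    variance approximation is poor).
    """
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    warns: list[str] = []
    if n < 4:
        msg = f"n={n} < 4: Tajima's D variance approximation is unreliable"
        warnings.warn(msg)
        warns.append(msg)
    keep = complete_deletion_columns(aln)
    mat = np.array(
        [[r.residues[i] for i in keep] for r in aln.records], dtype="U1"
    )
    L = mat.shape[1]
    seg = 0
    for j in range(L):
        if len(set(mat[:, j])) > 1:
            seg += 1
    diffs = 0
    pairs = n * (n - 1) // 2
    for i in range(n):
        for j in range(i + 1, n):
            diffs += int((mat[i] != mat[j]).sum())
    pi = diffs / pairs
    pps = pi / L if L else 0.0
    if seg == 0:
        return TajimaResult(n, 0, pi, None, L, pps, warns)
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    var = e1 * seg + e2 * seg * (seg - 1)
    if var <= 0:  # n <= 3 collapses the variance approximation to zero
        warns.append(f"variance estimate non-positive at n={n}: D undefined")
        return TajimaResult(n, seg, pi, None, L, pps, warns)
    d = (pi - seg / a1) / np.sqrt(var)
    return TajimaResult(n, seg, pi, float(d), L, pps, warns)
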
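"""Pairwise nucleotide distances and composition statistics.

Implements the Kimura two-parameter (K2P) distance with optional gamma rate
correction, under either pairwise or complete deletion of gap/ambiguous
positions, plus transition/transversion accounting, base composition, and
nearest-exemplar genotype assignment.

K2P separates the transition proportion P (A<->G, C<->T) from the
transversion proportion Q:

    K = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and with gamma-distributed rate variation of shape ``a``:

    K = a/2 [(1 - 2P - Q)^(-1/a) - 1] + a/4 [(1 - 2Q)^(-1/a) - 1]
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .errors import SaturationError, UndefinedDistanceError
from .seqio import MISSING, Alignment, SequenceRecord, consensus

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
BASES = "ACGT"


class GapPolicy(Enum):
    """How gap/N positions are removed before counting differences.

    ``pairwise_deletion`` drops positions missing in either member of the
    pair only; ``complete_deletion`` drops every column missing in any
    record of the whole set before pairing.
    """

    pairwise = "pairwise_deletion"
    complete = "complete_deletion"


@dataclass
class PairDistance:
    """K2P distance between one pair of aligned sequences."""

    P: float
    Q: float
    sites: int
    K: float
    transitions: int
    transversions: int
    gamma_shape: Optional[float] = None

    @property
    def p_distance(self) -> float:
        return self.P + self.Q


def count_differences(a: str, b: str) -> tuple[int, int, int]:
    """Count transitions, transversions and comparable sites for a pair.

    Positions where either sequence holds a gap or N are excluded
    (pairwise deletion); complete deletion is obtained by pre-masking the
    alignment with :func:`complete_deletion_columns`.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    ts = tv = sites = 0
    for x, y in zip(a, b):
        if x in MISSING or y in MISSING:
            continue
        sites += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if sites == 0:
        raise UndefinedDistanceError("no comparable sites between pair")
    return ts, tv, sites


def complete_deletion_columns(aln: Alignment) -> list[int]:
    """Indices of columns free of gaps and N across every record."""
    return [
        i
        for i in range(aln.length)
        if all(r.residues[i] not in MISSING for r in aln.records)
    ]


def _k2p_from_pq(p: float, q: float, gamma_shape: Optional[float]) -> float:
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(p, q)
    if gamma_shape is None:
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    a = gamma_shape
    return (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + (a / 4.0) * (
        w2 ** (-1.0 / a) - 1.0
    )


def k2p(
    a: str | SequenceRecord,
    b: str | SequenceRecord,
    gamma_shape: Optional[float] = None,
) -> PairDistance:
    """Kimura two-parameter distance between two aligned sequences.

    Raises :class:`SaturationError` when the observed proportions fall
    outside the domain of the log/power correction.
    """
    sa = a.residues if isinstance(a, SequenceRecord) else a
    sb = b.residues if isinstance(b, SequenceRecord) else b
    ts, tv, sites = count_differences(sa, sb)
    p, q = ts / sites, tv / sites
    k = _k2p_from_pq(p, q, gamma_shape)
    return PairDistance(
        P=p, Q=q, sites=sites, K=k, transitions=ts, transversions=tv,
        gamma_shape=gamma_shape,
    )


def cpg_columns(reference: str) -> list[int]:
    """Columns belonging to a CpG dinucleotide in the reference.

    Adjacency is taken on the reference after skipping its gap columns, so
    a C...G pair separated only by reference gaps still counts; both member
    columns are returned.
    """
    idx = [i for i, c in enumerate(reference) if c != "-"]
    out: set[int] = set()
    for a, b in zip(idx, idx[1:]):
        if reference[a] == "C" and reference[b] == "G":
            out.update((a, b))
    return sorted(out)


def distance_matrix(
    aln: Alignment,
    policy: GapPolicy = GapPolicy.pairwise,
    gamma_shape: Optional[float] = None,
    exclude_cpg: bool = False,
    reference: Optional[SequenceRecord] = None,
) -> pd.DataFrame:
    """Symmetric K2P distance matrix over all records.

    With ``exclude_cpg``, columns that are part of a CpG dinucleotide in
    the designated reference (the consensus when none is given) are removed
    first. Pairs whose distance is undefined or saturated appear as NaN.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 records")
    work = aln
    if exclude_cpg:
        ref = reference if reference is not None else consensus(aln)
        drop = set(cpg_columns(ref.residues))
        keep = [i for i in range(aln.length) if i not in drop]
        work = aln.take_columns(keep)
    if policy is GapPolicy.complete:
        work = work.take_columns(complete_deletion_columns(work))
    ids = work.ids()
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        try:
            d = k2p(work.records[i], work.records[j], gamma_shape).K
        except (SaturationError, UndefinedDistanceError):
            d = np.nan
        mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class TsTvResult:
    transitions: int
    transversions: int

    @property
    def infinite(self) -> bool:
        return self.transversions == 0 and self.transitions > 0

    @property
    def ratio(self) -> Optional[float]:
        """Observed R; None when no transversion (or no mismatch) was seen."""
        if self.transversions == 0:
            return None
        return self.transitions / self.transversions


def tstv_ratio(
    aln: Alignment, policy: GapPolicy = GapPolicy.pairwise
) -> TsTvResult:
    """Count-based transition/transversion ratio pooled over all pairs.

    This is the observed-count approximation, not a maximum-likelihood
    estimate; it is validated by recovery of simulated ts:tv biases.
    """
    work = aln
    if policy is GapPolicy.complete:
        work = work.take_columns(complete_deletion_columns(work))
    ts_total = tv_total = 0
    for ra, rb in combinations(work.records, 2):
        try:
            ts, tv, _ = count_differences(ra.residues, rb.residues)
        except UndefinedDistanceError:
            continue
        ts_total += ts
        tv_total += tv
    return TsTvResult(ts_total, tv_total)


def composition(
    seq: str | SequenceRecord,
    region: Optional[tuple[int, int]] = None,
) -> dict[str, float]:
    """Base fractions over A/C/G/T, excluding gaps and N.

    ``region`` is a 0-based half-open interval applied before counting.
    """
    s = seq.residues if isinstance(seq, SequenceRecord) else seq
    if region is not None:
        s = s[region[0]: region[1]]
    counts = {b: 0 for b in BASES}
    for c in s:
        if c in counts:
            counts[c] += 1
    total = sum(counts.values())
    if total == 0:
        raise UndefinedDistanceError("no unambiguous bases in region")
    return {b: counts[b] / total for b in BASES}


Genotype = Literal["SERV1", "SERV2", "unassigned"]


def classify_genotype(
    seq: str | SequenceRecord,
    ref1: str | SequenceRecord,
    ref2: str | SequenceRecord,
    gamma_shape: Optional[float] = None,
    margin: float = 0.01,
) -> tuple[Genotype, float, float]:
    """Assign a sequence to the nearer of two genotype exemplars by K2P.

    Assignment is by distance, not by PBS, because PBS switching between
    genotypes is documented; distances within ``margin`` of each other are
    left unassigned rather than broken arbitrarily.
    """
    k1 = k2p(seq, ref1, gamma_shape).K
    k2_ = k2p(seq, ref2, gamma_shape).K
    if abs(k1 - k2_) < margin:
        return "unassigned", k1, k2_
    return ("SERV1" if k1 < k2_ else "SERV2"), k1, k2_
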
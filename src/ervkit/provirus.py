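"""Provirus structural features.

Locates the terminal LTR pair of a candidate provirus, detects the 6 nt
target-site duplication (TSD) left by integrase, extracts and classifies
the tRNA primer-binding site (PBS) immediately downstream of the 5' LTR,
scans reading-frame status of the viral genes, and flags records whose LTR
pair is too divergent to be a genuine single integration (assembly-error
screen).

A provirus is structured LTR-gag-pro/pol-env-LTR; at integration the two
LTRs are identical and the host target 6-mer is duplicated on both flanks.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from statistics import median
from typing import Literal, Optional

import edlib
import numpy as np

from .distances import k2p
from .errors import FlankError, NotAProvirusError, SaturationError
from .seqio import SequenceRecord

Span = tuple[int, int]  # 0-based half-open

#: 18-mer PBS complementary to tRNA-lys3 (genotype-1 consensus).
PBS_LYS3 = "TGGCGCCCGAACAGGGAC"
#: 18-mer PBS complementary to tRNA-lys1,2 (genotype-2 consensus).
PBS_LYS12 = "TGGCGCCCAACGTGGGGC"

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class ProvirusRecord:
    """One provirus locus (viral genome plus host flanks) with annotations."""

    id: str
    locus: SequenceRecord
    strand: Literal["+", "-"] = "+"
    ltr5_span: Optional[Span] = None
    ltr3_span: Optional[Span] = None
    tsd: Optional[str] = None
    pbs: Optional[str] = None
    genotype: str = "unassigned"
    orfs: dict[str, Span] = field(default_factory=dict)

    @property
    def provirus_span(self) -> Span:
        if self.ltr5_span is None or self.ltr3_span is None:
            raise ValueError(f"{self.id}: LTR spans not set")
        return (self.ltr5_span[0], self.ltr3_span[1])

    @property
    def ltr5_seq(self) -> str:
        s, e = self.ltr5_span
        return self.locus.residues[s:e]

    @property
    def ltr3_seq(self) -> str:
        s, e = self.ltr3_span
        return self.locus.residues[s:e]

    def flank5(self, window: int) -> str:
        start = self.provirus_span[0]
        if start < window:
            raise FlankError(f"{self.id}: 5' flank shorter than {window} nt")
        return self.locus.residues[start - window: start]

    def flank3(self, window: int) -> str:
        end = self.provirus_span[1]
        if len(self.locus) - end < window:
            raise FlankError(f"{self.id}: 3' flank shorter than {window} nt")
        return self.locus.residues[end: end + window]


# ---------------------------------------------------------------------------
# LTR detection
# ---------------------------------------------------------------------------

def _spans_for_offset(
    arr: np.ndarray, d: int, mismatch: float = 2.0
) -> Optional[tuple[int, int, float]]:
    """Best repeat extent on diagonal ``d`` of the self-comparison.

    Scores match +1 / mismatch -``mismatch`` and takes the maximum-sum
    window (Kadane), so a repeat pair at >= ~70% identity stands out
    against the ~25% background of unrelated sequence. The window is
    trimmed to matched boundary positions. Returns (start, end, identity).
    """
    n = len(arr)
    overlap = n - d
    if overlap <= 0:
        return None
    m = arr[:overlap] == arr[d: d + overlap]
    score = np.where(m, 1.0, -mismatch)
    best = run = 0.0
    best_span = (0, 0)
    start = 0
    for i, sc in enumerate(score):
        if run <= 0:
            run = sc
            start = i
        else:
            run += sc
        if run > best:
            best = run
            best_span = (start, i + 1)
    if best <= 0:
        return None
    first, last = best_span[0], best_span[1] - 1
    # anchor each boundary on a short run of consecutive matches: isolated
    # chance matches in the flanking sequence (p=0.25 each) would otherwise
    # stretch the span by a few nt
    run_anchor = 4
    while first < last and not m[first: first + run_anchor].all():
        first += 1
    while last > first and not m[max(0, last - run_anchor + 1): last + 1].all():
        last -= 1
    identity = float(m[first: last + 1].mean())
    return first, last + 1, identity


def extract_ltrs(
    provirus: SequenceRecord | str,
    min_len: int = 400,
    min_identity: float = 0.85,
    anchor_frac: float = 0.10,
    k: int = 20,
) -> tuple[Span, Span, float]:
    """Find the highest-scoring pair of terminal direct repeats.

    Candidate diagonals are seeded by exact ``k``-mer matches between the
    head and tail of the sequence (so the method assumes substitution-only
    divergence between the two LTR copies, which holds for LTRs young
    enough to date). The 5' repeat must start within the first
    ``anchor_frac`` of the sequence and the 3' repeat must end within the
    last ``anchor_frac``; length and identity must meet the thresholds.

    Returns ``(ltr5_span, ltr3_span, identity)`` or raises
    :class:`NotAProvirusError`.
    """
    s = provirus.residues if isinstance(provirus, SequenceRecord) else provirus
    n = len(s)
    if n < 2 * min_len:
        raise NotAProvirusError(f"sequence ({n} nt) shorter than 2*min_len")
    head_limit = int(n * anchor_frac) + min_len
    tail_start = max(0, n - int(n * anchor_frac) - min_len - k)
    tail_kmers: dict[str, list[int]] = {}
    for j in range(tail_start, n - k + 1):
        tail_kmers.setdefault(s[j: j + k], []).append(j)
    votes: dict[int, int] = {}
    for i in range(0, min(head_limit, n - k + 1)):
        for j in tail_kmers.get(s[i: i + k], ()):
            d = j - i
            if d >= n // 2:
                votes[d] = votes.get(d, 0) + 1
    if not votes:
        raise NotAProvirusError("no terminal repeat seed found")
    arr = np.frombuffer(s.encode(), dtype="S1")
    best = None
    for d, _ in sorted(votes.items(), key=lambda kv: -kv[1])[:5]:
        res = _spans_for_offset(arr, d)
        if res is None:
            continue
        start, end, identity = res
        length = end - start
        if length < min_len or identity < min_identity:
            continue
        if start > n * anchor_frac:  # 5' repeat must be terminal-anchored
            continue
        if end + d < n - n * anchor_frac:  # 3' repeat end in the last 10%
            continue
        score = length * identity
        if best is None or score > best[0]:
            best = (score, (start, end), (start + d, end + d), identity)
    if best is None:
        raise NotAProvirusError(
            f"no terminal repeat pair >= {min_len} nt at identity >= {min_identity}"
        )
    return best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# TSD and flanks
# ---------------------------------------------------------------------------

def detect_tsd(
    locus: SequenceRecord | str, provirus_span: Span, tsd_len: int = 6
) -> Optional[str]:
    """Return the target-site duplication, or None if absent.

    The ``tsd_len``-mer immediately 5' of the provirus must exactly equal
    the one immediately 3' of it: the duplication is binary evidence of
    integrase-driven insertion, so no fuzzy matching is attempted.
    """
    s = locus.residues if isinstance(locus, SequenceRecord) else locus
    start, end = provirus_span
    if start < tsd_len or len(s) - end < tsd_len:
        raise FlankError(
            f"need >= {tsd_len} nt of host flank on both sides of the provirus"
        )
    left = s[start - tsd_len: start]
    right = s[end: end + tsd_len]
    return left if left == right else None


def flanks_match(
    a: ProvirusRecord,
    b: ProvirusRecord,
    window: int = 50,
    min_identity: float = 0.9,
) -> bool:
    """Whether two loci occupy the same host integration site.

    True iff both 5' and both 3' host flanks agree at >= ``min_identity``
    over ``window`` nt (position-wise identity, no gaps assumed).
    """
    def ident(x: str, y: str) -> float:
        return sum(1 for p, q in zip(x, y) if p == q) / window

    return (
        ident(a.flank5(window), b.flank5(window)) >= min_identity
        and ident(a.flank3(window), b.flank3(window)) >= min_identity
    )


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------

@dataclass
class PBSCall:
    """Classification of a PBS against the two tRNA-lys references."""

    label: Literal["lys3", "lys12", "ambiguous"]
    edit_distance_lys3: int
    edit_distance_lys12: int
    variants: list[tuple[int, str]] = field(default_factory=list)


def _edit_distance(query: str, ref: str) -> int:
    return edlib.align(query, ref, mode="NW", task="distance")["editDistance"]


def _variants(query: str, ref: str) -> list[tuple[int, str]]:
    """Variant list (1-based reference position, description) from an
    edlib global alignment of ``query`` against ``ref``."""
    res = edlib.align(query, ref, mode="NW", task="path")
    out: list[tuple[int, str]] = []
    qi = ri = 0
    for num, op in re.findall(r"(\d+)([=XIDM])", res["cigar"]):
        num = int(num)
        if op == "=":
            qi += num
            ri += num
        elif op == "X":
            for _ in range(num):
                out.append((ri + 1, f"{ref[ri]}>{query[qi]}"))
                qi += 1
                ri += 1
        elif op == "I":  # extra base in the query
            for _ in range(num):
                out.append((ri, f"ins{query[qi]}"))
                qi += 1
        elif op == "D":  # reference base missing from the query
            for _ in range(num):
                out.append((ri + 1, f"del{ref[ri]}"))
                ri += 1
    return out


def classify_pbs(pbs: str) -> PBSCall:
    """Label a PBS as lys3, lys12 or ambiguous by Levenshtein distance.

    Levenshtein (not Hamming) so single-nucleotide PBS insertions classify
    correctly; equal distances yield ``ambiguous``. Variants are reported
    against the winning reference (lys3 on a tie).
    """
    if not 17 <= len(pbs) <= 19:
        raise ValueError(f"PBS length {len(pbs)} outside 17-19 nt")
    d3 = _edit_distance(pbs, PBS_LYS3)
    d12 = _edit_distance(pbs, PBS_LYS12)
    if d3 == d12:
        return PBSCall("ambiguous", d3, d12, _variants(pbs, PBS_LYS3))
    if d3 < d12:
        return PBSCall("lys3", d3, d12, _variants(pbs, PBS_LYS3))
    return PBSCall("lys12", d3, d12, _variants(pbs, PBS_LYS12))


def extract_pbs(
    provirus: SequenceRecord | str, ltr5_span: Span
) -> str:
    """The PBS window immediately 3' of the 5' LTR.

    Normally the 18 nt after the LTR; when extending to 19 nt fits both
    references strictly better (a single PBS insertion, as seen in variant
    PBS sequences), the 19 nt window is returned instead.
    """
    s = provirus.residues if isinstance(provirus, SequenceRecord) else provirus
    start = ltr5_span[1]
    if len(s) < start + 18:
        raise FlankError("sequence ends before an 18 nt PBS after the 5' LTR")
    w18 = s[start: start + 18]
    d18 = min(_edit_distance(w18, PBS_LYS3), _edit_distance(w18, PBS_LYS12))
    if len(s) >= start + 19:
        w19 = s[start: start + 19]
        d19 = min(_edit_distance(w19, PBS_LYS3), _edit_distance(w19, PBS_LYS12))
        if d19 < d18:
            return w19
    return w18


# ---------------------------------------------------------------------------
# ORF status
# ---------------------------------------------------------------------------

@dataclass
class OrfStatus:
    gene: Optional[str]
    state: Literal["open", "premature_stop", "frameshift_indel"]
    detail: Optional[int] = None  # 1-based nt position of first defect


def orf_status(
    gene_seq: str, reference_len: int, gene: Optional[str] = None
) -> OrfStatus:
    """Reading-frame status of a gapless gene sequence.

    A length differing from the reference by a non-multiple of 3 is a
    frameshift indel; otherwise the first in-frame stop before the
    terminal codon is a premature stop; otherwise the gene is open.
    """
    if (len(gene_seq) - reference_len) % 3 != 0:
        return OrfStatus(gene, "frameshift_indel")
    n_codons = len(gene_seq) // 3
    for ci in range(n_codons - 1):
        if gene_seq[3 * ci: 3 * ci + 3] in STOP_CODONS:
            return OrfStatus(gene, "premature_stop", detail=3 * ci + 1)
    return OrfStatus(gene, "open")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_provirus(
    rec: ProvirusRecord,
    cohort_ltr_distances: list[float],
    multiple: float = 3.0,
    cap: float = 0.15,
) -> Literal["valid", "suspect_assembly"]:
    """Flag records whose LTR pair cannot be one integration event.

    A record is ``suspect_assembly`` when its 5'-3' LTR K2P distance
    exceeds ``multiple`` times the cohort median within-provirus LTR
    distance, exceeds the absolute ``cap``, or is saturated outright (a
    shuffled/foreign LTR sits near the random expectation, where the K2P
    correction has no value).
    """
    try:
        d = k2p(rec.ltr5_seq, rec.ltr3_seq).K
    except SaturationError:
        return "suspect_assembly"
    if cohort_ltr_distances:
        med = median(cohort_ltr_distances)
        if med > 0 and d > multiple * med:
            return "suspect_assembly"
    if d > cap:
        return "suspect_assembly"
    return "valid"
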
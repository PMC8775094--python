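"""Context-dependent mutation signatures.

Two host repression mechanisms leave distinct footprints in an endogenous
provirus:

* APOBEC3 cytidine deaminases edit minus-strand DNA during reverse
  transcription (before integration), producing plus-strand G->A changes
  in enzyme-specific dinucleotide contexts (GG for APOBEC3G, GA for the
  non-3G members).
* Methylation of CpG dinucleotides after integration leads, via
  deamination of 5-methylcytosine, to CpG->TpG (plus strand) or CpG->CpA
  (minus strand) transitions at a strongly elevated rate.

The hypermutation scan counts mutated vs. potential sites in a primary
context against a disjoint control context and tests enrichment with a
one-sided Fisher's exact test; the CpG census enumerates reference CpG
sites directly. Default patterns reproduce the HYPERMUT-style settings
K-(G>A)-D (control K-(G>A)-N) for APOBEC3G and D-(G>A)-AD (control
D-(G>A)-N) for non-3G, with the context enforced on both reference and
query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy import stats

from .seqio import SequenceRecord

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "K": frozenset("GT"),
    "M": frozenset("AC"), "S": frozenset("CG"), "W": frozenset("AT"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


@dataclass
class MutationPattern:
    """A context-dependent substitution pattern with a control context.

    ``upstream``/``downstream`` are IUPAC strings of arbitrary length
    (empty = unconstrained). Control sites are sites matching the control
    context but *not* the primary context, so the two arms are disjoint.
    """

    from_base: str
    to_base: str
    upstream: str = ""
    downstream: str = ""
    control_upstream: str = ""
    control_downstream: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        for s in (self.upstream, self.downstream,
                  self.control_upstream, self.control_downstream):
            bad = set(s) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC letters {sorted(bad)} in context")
        if self.from_base not in "ACGT" or self.to_base not in "ACGT":
            raise ValueError("from/to must be single unambiguous bases")


_PATTERN_RE = re.compile(r"^([A-Z]*)-\(([A-Z])[>→]([A-Z])\)-([A-Z]*)$")


def parse_pattern(primary: str, control: str = "", name: str = "") -> MutationPattern:
    """Parse HYPERMUT-style text patterns, e.g. ``"K-(G>A)-D"``.

    ``control`` gives the control-arm context (same from/to); arbitrary
    context lengths are allowed on either side, e.g. ``"D-(G>A)-AD"``.
    """
    m = _PATTERN_RE.match(primary.strip())
    if not m:
        raise ValueError(f"cannot parse pattern {primary!r}")
    up, frm, to, down = m.groups()
    cu = cd = ""
    if control:
        mc = _PATTERN_RE.match(control.strip())
        if not mc:
            raise ValueError(f"cannot parse control pattern {control!r}")
        cu, cfrm, cto, cd = mc.groups()
        if (cfrm, cto) != (frm, to):
            raise ValueError("control pattern must share from/to bases")
    return MutationPattern(
        from_base=frm, to_base=to, upstream=up, downstream=down,
        control_upstream=cu, control_downstream=cd, name=name,
    )


APOBEC3G = parse_pattern("K-(G>A)-D", "K-(G>A)-N", name="APOBEC3G")
APOBEC_NON3G = parse_pattern("D-(G>A)-AD", "D-(G>A)-N", name="APOBEC-non-3G")

DEFAULT_PATTERNS = (APOBEC3G, APOBEC_NON3G)


@dataclass
class HypermutReport:
    """Counts and enrichment test for one pattern on one sequence pair."""

    matched_mutations: int
    matched_potentials: int
    control_mutations: int
    control_potentials: int
    p_value: Optional[float]
    pattern: str = ""
    undefined: bool = False

    @property
    def rate_ratio(self) -> Optional[float]:
        """(matched rate) / (control rate); None when a denominator is 0."""
        if (
            self.matched_potentials == 0
            or self.control_potentials == 0
            or self.control_mutations == 0
        ):
            return None
        return (self.matched_mutations / self.matched_potentials) / (
            self.control_mutations / self.control_potentials
        )


def fisher_exact(
    table: list[list[int]] | tuple[tuple[int, int], tuple[int, int]],
    sided: Literal["one_greater", "two"] = "one_greater",
) -> float:
    """Fisher's exact test on a 2x2 count table.

    ``one_greater`` is the exact hypergeometric upper tail (enrichment in
    row 1); ``two`` sums all outcomes at fixed margins with probability
    <= the observed table's.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if sided == "one_greater":
        return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def _context_ok(
    base_in: np.ndarray, seq_codes: np.ndarray, pos: np.ndarray,
    context: str, offset_sign: int,
) -> np.ndarray:
    """Vector mask: does ``context`` match ``seq_codes`` adjacent to each
    position in ``pos``? ``offset_sign=-1`` reads upstream (context string
    ends just before the site), ``+1`` downstream (starts just after)."""
    n = len(seq_codes)
    ok = np.ones(len(pos), dtype=bool)
    L = len(context)
    for k, letter in enumerate(context):
        if offset_sign < 0:
            off = -(L - k)
        else:
            off = k + 1
        p = pos + off
        inside = (p >= 0) & (p < n)
        ok &= inside
        allowed = base_in[letter]
        vals = np.where(inside, seq_codes[np.clip(p, 0, n - 1)], 255)
        ok &= np.where(inside, allowed[np.clip(vals, 0, 4)], False)
    return ok


_CODE = {b: i for i, b in enumerate("ACGT")}


def _encode(s: str) -> np.ndarray:
    """Map ACGT to 0..3 and anything else (N) to 4."""
    arr = np.full(len(s), 4, dtype=np.uint8)
    for b, i in _CODE.items():
        arr[np.frombuffer(s.encode(), dtype="S1") == b.encode()] = i
    return arr


def _iupac_lookup() -> dict[str, np.ndarray]:
    out = {}
    for letter, bases in IUPAC.items():
        v = np.zeros(5, dtype=bool)
        for b in bases:
            v[_CODE[b]] = True
        out[letter] = v
    return out


_BASE_IN = _iupac_lookup()


def hypermut_scan(
    reference: str | SequenceRecord,
    query: str | SequenceRecord,
    pattern: MutationPattern,
) -> HypermutReport:
    """Scan a query against its reference for context-dependent mutations.

    Columns gapped in either sequence are removed first (a context
    interrupted by a gap does not match). A potential site is a reference
    position holding ``from_base`` whose context matches in *both* the
    reference and the query (so a neighbouring query mutation can
    disqualify a site); a matched mutation is a potential site where the
    query holds ``to_base``. Control sites match the control context but
    not the primary one. Enrichment is tested one-sided on
    ``[[mm, mp-mm], [cm, cp-cm]]``.
    """
    r = reference.residues if isinstance(reference, SequenceRecord) else reference
    q = query.residues if isinstance(query, SequenceRecord) else query
    if len(r) != len(q):
        raise ValueError("reference and query must be aligned (equal length)")
    ra = np.frombuffer(r.encode(), dtype="S1")
    qa = np.frombuffer(q.encode(), dtype="S1")
    keep = (ra != b"-") & (qa != b"-")
    rc = _encode(r)[keep]
    qc = _encode(q)[keep]

    pos = np.nonzero(rc == _CODE[pattern.from_base])[0]
    primary = _context_ok(_BASE_IN, rc, pos, pattern.upstream, -1)
    primary &= _context_ok(_BASE_IN, rc, pos, pattern.downstream, +1)
    primary &= _context_ok(_BASE_IN, qc, pos, pattern.upstream, -1)
    primary &= _context_ok(_BASE_IN, qc, pos, pattern.downstream, +1)

    control = _context_ok(_BASE_IN, rc, pos, pattern.control_upstream, -1)
    control &= _context_ok(_BASE_IN, rc, pos, pattern.control_downstream, +1)
    control &= _context_ok(_BASE_IN, qc, pos, pattern.control_upstream, -1)
    control &= _context_ok(_BASE_IN, qc, pos, pattern.control_downstream, +1)
    control &= ~primary  # disjoint arms

    mutated = qc[pos] == _CODE[pattern.to_base]
    mp = int(primary.sum())
    mm = int((primary & mutated).sum())
    cp = int(control.sum())
    cm = int((control & mutated).sum())
    if mp == 0 and cp == 0:
        return HypermutReport(0, 0, 0, 0, None, pattern.name, undefined=True)
    p = fisher_exact([[mm, mp - mm], [cm, cp - cm]], "one_greater")
    return HypermutReport(mm, mp, cm, cp, p, pattern.name)


@dataclass
class CpGCensus:
    """Per-sequence census of mutated reference CpG sites."""

    n_cpg_sites: int
    n_tpg: int
    n_cpa: int
    n_other: int = 0

    @property
    def fraction_mutated(self) -> float:
        if self.n_cpg_sites == 0:
            return 0.0
        return (self.n_tpg + self.n_cpa) / self.n_cpg_sites


def cpg_census(
    reference: str | SequenceRecord, query: str | SequenceRecord
) -> CpGCensus:
    """Count CpG-deamination mutations in a query against its reference.

    CpG sites are enumerated on the reference (C immediately followed by
    G, with reference gap columns skipped). At each site the query state
    is read: CG->TG counts as TpG, CG->CA as CpA, and any other mutated
    state (TA, or both bases changed) as "other". Sites where the query is
    gapped or ambiguous at either position are not comparable and are
    excluded from the site count.
    """
    r = reference.residues if isinstance(reference, SequenceRecord) else reference
    q = query.residues if isinstance(query, SequenceRecord) else query
    if len(r) != len(q):
        raise ValueError("reference and query must be aligned (equal length)")
    idx = [i for i, c in enumerate(r) if c != "-"]
    sites = tpg = cpa = other = 0
    for a, b in zip(idx, idx[1:]):
        if not (r[a] == "C" and r[b] == "G"):
            continue
        pair = q[a] + q[b]
        if any(c in "-N" for c in pair):
            continue
        sites += 1
        if pair == "CG":
            continue
        if pair == "TG":
            tpg += 1
        elif pair == "CA":
            cpa += 1
        else:
            other += 1
    return CpGCensus(n_cpg_sites=sites, n_tpg=tpg, n_cpa=cpa, n_other=other)


@dataclass
class StrandSplit:
    total_tpg: int
    total_cpa: int
    ratio: Optional[float]
    undefined: bool = False


def cpg_strand_split(censuses: list[CpGCensus]) -> StrandSplit:
    """Pooled TpG:CpA ratio over a set of censuses.

    A ratio near 1 means CpG methylation-driven deamination hit both
    strands equally. Zero counts in either class flag the ratio undefined.
    """
    if not censuses:
        raise ValueError("empty census list")
    tpg = sum(c.n_tpg for c in censuses)
    cpa = sum(c.n_cpa for c in censuses)
    if tpg == 0 or cpa == 0:
        return StrandSplit(tpg, cpa, None, undefined=True)
    return StrandSplit(tpg, cpa, tpg / cpa)
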
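"""Molecular dating of provirus integrations from LTR divergence.

At integration a provirus's two LTRs are identical copies; they then
diverge independently at the host substitution rate, so the pairwise
distance K between the 5' and 3' LTR measures twice the elapsed time:

    T = K / (2 r)

with r the per-site substitution rate. Primate-ERV calibrations bracket r
between 2.3e-9 ("slow") and 5e-9 ("fast") substitutions/site/year, so
every age is reported under both rates. Between-LTR distances across
species date lineage splits (TMRCA) instead of integrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .distances import GapPolicy, complete_deletion_columns, k2p
from .errors import SaturationError
from .seqio import Alignment, SequenceRecord

#: Age (Myr) below the resolution of one substitution in a ~485 nt LTR at
#: the fast rate: 1/485/(2 * 5e-9) ~ 0.21 Myr, reported as "<0.3".
AGE_FLOOR_MYR = 0.3


@dataclass
class RateSet:
    """Fast/slow bracket of the per-site substitution rate (s/s/y)."""

    fast: float = 5e-9
    slow: float = 2.3e-9

    def __post_init__(self) -> None:
        if self.fast <= 0 or self.slow <= 0:
            raise ValueError("rates must be positive")
        if self.fast < self.slow:
            raise ValueError("fast rate must be >= slow rate")


@dataclass
class AgeEstimate:
    """A single T = K/2r conversion."""

    K: float
    r: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("K must be non-negative")
        if self.r <= 0:
            raise ValueError("r must be positive")

    @property
    def T(self) -> float:
        """Age in years."""
        return self.K / (2.0 * self.r)

    @property
    def T_myr(self) -> float:
        return self.T / 1e6

    def formatted(self) -> str:
        """Report form: 1-decimal Myr, with a floor band at K = 0."""
        if self.K == 0:
            return f"<{AGE_FLOOR_MYR}"
        return f"{self.T_myr:.1f}"


def date_integration(K: float, r: float, label: str = "") -> AgeEstimate:
    """Convert an LTR divergence K to an integration age."""
    return AgeEstimate(K=K, r=r, label=label)


def provirus_age(
    rec,
    rates: RateSet = RateSet(),
    gamma_shape: Optional[float] = None,
) -> tuple[AgeEstimate, AgeEstimate]:
    """(fast, slow) age estimates from a record's own 5'/3' LTR pair.

    K is the K2P distance with CpG sites included (removing them would
    discard most of the divergence signal in heavily methylated
    proviruses). Saturation propagates: an unclockable LTR pair has no age.
    """
    d = k2p(rec.ltr5_seq, rec.ltr3_seq, gamma_shape)
    return (
        AgeEstimate(d.K, rates.fast, label=f"{rec.id}:fast"),
        AgeEstimate(d.K, rates.slow, label=f"{rec.id}:slow"),
    )


@dataclass
class AgeSummary:
    n: int
    mean_myr: float
    sd_myr: Optional[float]
    min_myr: float
    max_myr: float

    def formatted(self) -> str:
        lo = f"<{AGE_FLOOR_MYR}" if self.min_myr == 0 else f"{self.min_myr:.1f}"
        sd = f" ± {self.sd_myr:.1f}" if self.sd_myr is not None else ""
        return f"{self.mean_myr:.1f}{sd} Myr (range {lo}-{self.max_myr:.1f})"


def cohort_age_summary(ages: list[AgeEstimate]) -> AgeSummary:
    """Mean, sample sd and range of a cohort of age estimates (Myr)."""
    if not ages:
        raise ValueError("empty age list")
    t = [a.T_myr for a in ages]
    n = len(t)
    mean = sum(t) / n
    sd = None
    if n > 1:
        sd = math.sqrt(sum((x - mean) ** 2 for x in t) / (n - 1))
    return AgeSummary(n=n, mean_myr=mean, sd_myr=sd, min_myr=min(t), max_myr=max(t))


@dataclass
class EventAge:
    """An evolutionary event dated as the mean of component pair ages.

    Component ages enter the mean unrounded; only the report rounds.
    """

    name: str
    component_ages: list[AgeEstimate]

    @property
    def mean_T(self) -> float:
        return sum(a.T for a in self.component_ages) / len(self.component_ages)

    @property
    def mean_T_myr(self) -> float:
        return self.mean_T / 1e6

    @property
    def min_T(self) -> float:
        return min(a.T for a in self.component_ages)

    @property
    def max_T(self) -> float:
        return max(a.T for a in self.component_ages)


@dataclass
class PairAge:
    """One row of the shared-integration dating table."""

    kind: str  # within | between_5 | between_3
    a: str
    b: str
    K: float
    sites: int
    fast: AgeEstimate
    slow: AgeEstimate


def shared_provirus_ages(
    ltr5_set: dict[str, str],
    ltr3_set: dict[str, str],
    rates: RateSet = RateSet(),
    events: Optional[dict[str, list[tuple[str, str]]]] = None,
) -> tuple[list[PairAge], list[EventAge]]:
    """Date a provirus integration shared across species.

    ``ltr5_set``/``ltr3_set`` map species to aligned LTR sequences (one
    shared coordinate frame). Within-species 5'-vs-3' distances date the
    integration itself; between-species 5'-vs-5' and 3'-vs-3' distances
    date lineage splits. Distances use complete deletion with CpG sites
    included. The integration event averages all within-species pair ages;
    TMRCA events average the between-species pairs named in ``events``
    (``{name: [(species_a, species_b), ...]}``), or all of them when no
    grouping is given.
    """
    seqs = list(ltr5_set.values()) + list(ltr3_set.values())
    if not seqs:
        raise ValueError("no LTR sequences supplied")
    aln = Alignment(
        [SequenceRecord(f"s{i}", s) for i, s in enumerate(seqs)]
    )
    keep = complete_deletion_columns(aln)

    def seq(s: str) -> str:
        return "".join(s[i] for i in keep)

    rows: list[PairAge] = []

    def add(kind: str, a: str, b: str, sa: str, sb: str) -> None:
        try:
            d = k2p(seq(sa), seq(sb))
        except SaturationError:
            return
        rows.append(
            PairAge(
                kind, a, b, d.K, d.sites,
                AgeEstimate(d.K, rates.fast, label=f"{a}/{b}:fast"),
                AgeEstimate(d.K, rates.slow, label=f"{a}/{b}:slow"),
            )
        )

    for sp in sorted(set(ltr5_set) & set(ltr3_set)):
        add("within", sp, sp, ltr5_set[sp], ltr3_set[sp])
    for a, b in combinations(sorted(ltr5_set), 2):
        add("between_5", a, b, ltr5_set[a], ltr5_set[b])
    for a, b in combinations(sorted(ltr3_set), 2):
        add("between_3", a, b, ltr3_set[a], ltr3_set[b])

    groups: list[EventAge] = []
    within_fast = [r.fast for r in rows if r.kind == "within"]
    if within_fast:
        groups.append(EventAge("integration", within_fast))
    between = [r for r in rows if r.kind != "within"]
    if events is not None:
        for name, pairs in events.items():
            wanted = {frozenset(p) for p in pairs}
            comp = [r.fast for r in between if frozenset((r.a, r.b)) in wanted]
            if comp:
                groups.append(EventAge(name, comp))
    elif between:
        groups.append(EventAge("tmrca_all", [r.fast for r in between]))
    return rows, groups
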
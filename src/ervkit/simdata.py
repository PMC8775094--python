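"""Synthetic endogenization simulator.

Generates truth-tagged provirus cohorts with the statistical structure the
analysis modules assume: an ~8.4 kb provirus with two initially identical
~485 nt terminal LTRs, an 18 nt tRNA-lys PBS immediately 3' of the 5' LTR,
open gag/pro/pol/env reading frames, region-specific base composition
(A-rich coding regions, a GC-richer LTR), and a controlled genome-wide CpG
count. Integration duplicates the host target 6-mer on both flanks;
neutral divergence then accumulates per site at the host rate with a
configurable transition bias, CpG dinucleotides additionally receive
deamination transitions (C->T / G->A, strand-symmetric) at a strongly
elevated rate, and an optional APOBEC editing episode introduces G->A
changes in a defined context once, before integration.

Every mutation is logged (position, from, to, cause) so emitted sequences
can be replayed exactly, and every draw flows from one master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .errors import SimulationError
from .provirus import PBS_LYS12, PBS_LYS3, ProvirusRecord, Span
from .seqio import SequenceRecord, write_fasta
from .signatures import _BASE_IN, _CODE, MutationPattern, _context_ok, parse_pattern

BASES = np.frombuffer(b"ACGT", dtype="S1")
_PARTNER = np.array([2, 3, 0, 1])  # transition partner of A,C,G,T

#: APOBEC3G edits the first G of a plus-strand GG dinucleotide.
DEFAULT_APOBEC = parse_pattern("-(G>A)-G", name="APOBEC3G-sim")

#: Canonical gene lengths (nt) used to lay out the coding region.
GENE_LENGTHS = {"gag": 1977, "pro": 540, "pol": 2613, "env": 1713}

# Base compositions (A, C, G, T) per region. Coding regions are A-rich and
# G-poor as in type D retroviruses; the LTR is GC-richer, promoter-like.
COMPOSITION = {
    "ltr": (0.226, 0.270, 0.264, 0.240),
    "gagpol": (0.333, 0.210, 0.187, 0.270),
    "env": (0.297, 0.240, 0.213, 0.250),
    "noncoding": (0.310, 0.220, 0.210, 0.260),
}

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class SimParams:
    """Study conditions for one simulated cohort cell."""

    provirus_length: int = 8393
    ltr_length: int = 485
    pbs_choice: Literal["lys3", "lys12"] = "lys3"
    cpg_target_count: int = 198
    base_rate: float = 5e-9           # s/s/y
    cpg_transition_rate: float = 1.6e-7  # s/s/y, per CpG base
    tsd_length: int = 6
    years: float = 3e6
    ts_tv_weight: float = 4.0
    apobec_pattern: Optional[MutationPattern] = None
    apobec_efficiency: float = 0.0
    genotype_label: str = "SERV1"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.provirus_length, self.ltr_length) <= 0:
            raise ValueError("lengths must be positive")
        if min(self.base_rate, self.cpg_transition_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not 0 <= self.apobec_efficiency <= 1:
            raise ValueError("apobec efficiency must be in [0, 1]")

    @classmethod
    def genotype2(cls, **kw) -> "SimParams":
        """Genotype-2 profile: lys1,2 PBS and the lower CpG census."""
        base = dict(pbs_choice="lys12", cpg_target_count=144,
                    genotype_label="SERV2")
        base.update(kw)
        return cls(**base)


@dataclass
class Mutation:
    position: int
    from_base: str
    to_base: str
    cause: Literal["neutral", "cpg", "apobec"]


# ---------------------------------------------------------------------------
# Ancestor construction
# ---------------------------------------------------------------------------

def _random_region(n: int, comp: tuple, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(4, size=n, p=comp).astype(np.uint8)


def _repair_stops(codes: np.ndarray) -> None:
    """Replace the leading T of every stop codon with C, in place."""
    s = codes_to_str(codes)
    for ci in range(len(codes) // 3):
        if s[3 * ci: 3 * ci + 3] in _STOPS:
            codes[3 * ci] = 1  # C
            s = s[: 3 * ci] + "C" + s[3 * ci + 1:]


def codes_to_str(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def str_to_codes(s: str) -> np.ndarray:
    out = np.empty(len(s), dtype=np.uint8)
    raw = np.frombuffer(s.encode(), dtype="S1")
    for b, i in _CODE.items():
        out[raw == b.encode()] = i
    return out


def _count_cpg(codes: np.ndarray) -> int:
    return int(np.sum((codes[:-1] == 1) & (codes[1:] == 2)))


def _adjust_cpg(
    codes: np.ndarray, lo: int, hi: int, target: int,
    rng: np.random.Generator, tol: float = 0.05, max_rounds: int = 60,
) -> None:
    """Tune the genome-wide CpG count to ``target`` (+-tol) by editing only
    positions in [lo, hi). Removal mutates the G of a CpG to A; planting
    writes a CG pair. Neither edit can create a stop codon (stops contain
    no C, and the only G position in a stop is preceded by A or T)."""
    for _ in range(max_rounds):
        total = _count_cpg(codes)
        diff = total - target
        if abs(diff) <= tol * target:
            return
        if diff > 0:
            g_pos = np.nonzero((codes[:-1] == 1) & (codes[1:] == 2))[0] + 1
            g_pos = g_pos[(g_pos >= lo + 1) & (g_pos < hi)]
            if g_pos.size == 0:
                raise SimulationError("cannot deplete CpG count to target")
            take = rng.choice(g_pos, size=min(diff, g_pos.size), replace=False)
            codes[take] = 0  # G -> A
        else:
            cand = np.nonzero(
                ~((codes[lo: hi - 1] == 1) & (codes[lo + 1: hi] == 2))
            )[0] + lo
            if cand.size == 0:
                raise SimulationError("cannot plant enough CpG sites")
            take = rng.choice(cand, size=min(-diff, cand.size), replace=False)
            codes[take] = 1
            codes[take + 1] = 2
    raise SimulationError("CpG adjustment did not converge")


def make_ancestor(
    params: SimParams, rng: Optional[np.random.Generator] = None,
    id: str = "ancestor",
) -> ProvirusRecord:
    """Build an ancestral provirus with identical LTRs and open ORFs.

    Layout: 5'LTR | PBS | leader | gag | pro | pol | env | spacer | 3'LTR,
    with gene lengths scaled down proportionally (kept in frame) when the
    requested provirus is too short for the canonical lengths. The
    genome-wide CpG dinucleotide count is tuned to ``cpg_target_count``
    within 5%, editing only the internal region so the two LTR copies stay
    byte-identical.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    L, plen = params.ltr_length, params.provirus_length
    pbs = PBS_LYS3 if params.pbs_choice == "lys3" else PBS_LYS12
    leader = 100
    internal = plen - 2 * L - len(pbs)
    canonical = sum(GENE_LENGTHS.values())
    avail = internal - leader - 60  # keep a spacer before the 3' LTR
    if avail < 300:
        raise SimulationError("provirus too short for LTRs + coding region")
    scale = min(1.0, avail / canonical)
    genes = {g: 3 * int(n * scale / 3) for g, n in GENE_LENGTHS.items()}

    ltr = _random_region(L, COMPOSITION["ltr"], rng)
    parts: list[np.ndarray] = [ltr, str_to_codes(pbs)]
    orfs: dict[str, Span] = {}
    cursor = L + len(pbs)
    lead = _random_region(leader, COMPOSITION["noncoding"], rng)
    parts.append(lead)
    cursor += leader
    for g in ("gag", "pro", "pol", "env"):
        comp = COMPOSITION["env"] if g == "env" else COMPOSITION["gagpol"]
        seg = _random_region(genes[g], comp, rng)
        _repair_stops(seg)
        orfs[g] = (cursor, cursor + genes[g])
        parts.append(seg)
        cursor += genes[g]
    spacer_len = plen - L - cursor
    parts.append(_random_region(spacer_len, COMPOSITION["noncoding"], rng))
    parts.append(ltr.copy())
    codes = np.concatenate(parts)
    assert len(codes) == plen

    # CpG tuning may only touch the internal region (past the PBS, before
    # the 3' LTR) so LTR copies and the PBS are preserved; fixed CpGs in
    # those segments bound the reachable target from below.
    lo, hi = L + len(pbs), plen - L
    fixed = _count_cpg(codes) - _count_cpg(codes[lo:hi])
    if params.cpg_target_count < fixed * 0.9:
        raise SimulationError(
            f"CpG target {params.cpg_target_count} below the {fixed} sites "
            "fixed in LTRs/PBS"
        )
    _adjust_cpg(codes, lo, hi, params.cpg_target_count, rng)
    # tuning may have re-introduced stop codons only via G->A; it cannot
    # (see _adjust_cpg), so ORFs are still open
    seq = codes_to_str(codes)
    return ProvirusRecord(
        id=id,
        locus=SequenceRecord(id, seq),
        ltr5_span=(0, L),
        ltr3_span=(plen - L, plen),
        pbs=pbs,
        genotype=params.genotype_label,
        orfs=orfs,
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def random_host(n: int, rng: np.random.Generator) -> str:
    """An i.i.d. uniform host background sequence."""
    return codes_to_str(rng.integers(0, 4, size=n).astype(np.uint8))


def integrate(
    host: str | SequenceRecord,
    provirus_seq: str,
    position: int,
    tsd_length: int = 6,
) -> tuple[str, Span, Optional[str]]:
    """Insert a provirus with target-site-duplication semantics.

    The host ``tsd_length``-mer ending at ``position`` is duplicated on
    both flanks of the insertion. Returns (locus, provirus span, tsd).
    """
    h = host.residues if isinstance(host, SequenceRecord) else host
    if not tsd_length <= position <= len(h):
        raise ValueError(
            f"position {position} out of range for host of {len(h)} nt "
            f"with tsd_length {tsd_length}"
        )
    locus = h[:position] + provirus_seq + h[position - tsd_length:]
    span = (position, position + len(provirus_seq))
    tsd = h[position - tsd_length: position] if tsd_length else None
    return locus, span, tsd


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

def apobec_edit(
    seq: str,
    pattern: MutationPattern,
    efficiency: float,
    rng: np.random.Generator,
) -> tuple[str, list[Mutation]]:
    """One pre-integration APOBEC editing episode.

    Every plus-strand position matching the pattern's primary context on
    the *pre-edit* sequence receives from->to with independent probability
    ``efficiency``; evaluating context before any edit makes the outcome
    order-independent.
    """
    codes = str_to_codes(seq)
    pos = np.nonzero(codes == _CODE[pattern.from_base])[0]
    ok = _context_ok(_BASE_IN, codes, pos, pattern.upstream, -1)
    ok &= _context_ok(_BASE_IN, codes, pos, pattern.downstream, +1)
    sites = pos[ok]
    hit = sites[rng.random(sites.size) < efficiency]
    log = [
        Mutation(int(i), pattern.from_base, pattern.to_base, "apobec")
        for i in sorted(hit)
    ]
    codes[hit] = _CODE[pattern.to_base]
    return codes_to_str(codes), log


def evolve(
    seq: str,
    params: SimParams,
    rng: np.random.Generator,
    epochs: int = 10,
) -> tuple[str, list[Mutation]]:
    """Neutral + CpG-deamination evolution of one lineage.

    Per epoch, each site substitutes with probability base_rate*dt
    (Poisson approximation; valid because r*T <= 0.1 in all default
    regimes), transitions weighted ``ts_tv_weight`` : 1 over the two
    transversions combined. Sites that are currently the C or G of a CpG
    dinucleotide additionally receive their deamination transition (C->T
    or G->A, strand-symmetric) at cpg_transition_rate*dt; CpG status is
    re-evaluated each epoch so destroyed sites stop being hotspots.
    """
    if params.base_rate * params.years > 0.5 or (
        params.cpg_transition_rate * params.years > 0.5
    ):
        warnings.warn("expected per-site substitution probability > 0.5")
    codes = str_to_codes(seq)
    n = len(codes)
    log: list[Mutation] = []
    dt = params.years / epochs
    p_base = params.base_rate * dt
    p_cpg = params.cpg_transition_rate * dt
    w = params.ts_tv_weight
    p_ts = w / (w + 1.0)
    for _ in range(epochs):
        is_c = codes[:-1] == 1
        is_g = codes[1:] == 2
        cpg_c = np.nonzero(is_c & is_g)[0]
        cpg_g = cpg_c + 1
        # neutral substitutions
        hits = np.nonzero(rng.random(n) < p_base)[0]
        for i in hits:
            old = int(codes[i])
            if rng.random() < p_ts:
                new = int(_PARTNER[old])
            else:
                tv = [b for b in range(4) if b != old and b != _PARTNER[old]]
                new = tv[int(rng.integers(2))]
            codes[i] = new
            log.append(
                Mutation(int(i), chr(BASES[old][0]), chr(BASES[new][0]),
                         "neutral")
            )
        # CpG deamination on sites that were CpG at epoch start and still
        # hold the vulnerable base
        if p_cpg > 0 and cpg_c.size:
            dc = cpg_c[rng.random(cpg_c.size) < p_cpg]
            for i in dc:
                if codes[i] == 1:
                    codes[i] = 3  # C -> T
                    log.append(Mutation(int(i), "C", "T", "cpg"))
            dg = cpg_g[rng.random(cpg_g.size) < p_cpg]
            for i in dg:
                if codes[i] == 2:
                    codes[i] = 0  # G -> A
                    log.append(Mutation(int(i), "G", "A", "cpg"))
    return codes_to_str(codes), log


def deaminate_cpg_sites(
    seq: str, per_site_prob: float, rng: np.random.Generator
) -> str:
    """Mutate each CpG dinucleotide with the given probability, half to
    TpG and half to CpA. Direct generator for censusing a known per-site
    mutation fraction, bypassing the clock."""
    codes = str_to_codes(seq)
    cpos = np.nonzero((codes[:-1] == 1) & (codes[1:] == 2))[0]
    hit = cpos[rng.random(cpos.size) < per_site_prob]
    for i in hit:
        if rng.random() < 0.5:
            codes[i] = 3  # TpG
        else:
            codes[i + 1] = 0  # CpA
    return codes_to_str(codes)


def replay(initial: str, log: list[Mutation]) -> str:
    """Apply a mutation log to its initial sequence, verifying each step."""
    codes = str_to_codes(initial)
    for m in log:
        if codes_to_str(codes[m.position: m.position + 1]) != m.from_base:
            raise SimulationError(
                f"log replay mismatch at {m.position}: expected "
                f"{m.from_base}, found {codes_to_str(codes[m.position:m.position+1])}"
            )
        codes[m.position] = _CODE[m.to_base]
    return codes_to_str(codes)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth for one simulated locus."""

    id: str
    years: float
    genotype: str
    pbs_label: str
    tsd: Optional[str]
    apobec: bool
    provirus_span: Span
    ltr5_span: Span
    ltr3_span: Span
    initial_locus: str
    log: list[Mutation] = field(default_factory=list)


@dataclass
class Cohort:
    loci: list[ProvirusRecord]
    truth: list[SimTruth]
    seed: int

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            rows.append(
                dict(
                    id=t.id, years=t.years, genotype=t.genotype,
                    pbs_label=t.pbs_label, tsd=t.tsd or "",
                    apobec=int(t.apobec),
                    provirus_start=t.provirus_span[0] + 1,
                    provirus_end=t.provirus_span[1],
                    ltr5_start=t.ltr5_span[0] + 1, ltr5_end=t.ltr5_span[1],
                    ltr3_start=t.ltr3_span[0] + 1, ltr3_end=t.ltr3_span[1],
                    n_mutations=len(t.log),
                )
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        recs = [
            SequenceRecord(r.id, r.locus.residues, f"seed={self.seed}")
            for r in self.loci
        ]
        write_fasta(recs, outdir / "loci.fasta")
        path = outdir / "truth.tsv"
        with open(path, "w") as fh:
            fh.write(f"# master seed = {self.seed}\n")
            self.truth_frame().to_csv(fh, sep="\t", index=False)


def simulate_locus(
    params: SimParams,
    rng: np.random.Generator,
    ancestor: Optional[ProvirusRecord] = None,
    flank: int = 500,
    locus_id: str = "locus",
) -> tuple[ProvirusRecord, SimTruth]:
    """One endogenization: (optional APOBEC edit ->) integrate -> evolve."""
    if ancestor is None:
        ancestor = make_ancestor(params, rng)
    prov = ancestor.locus.residues
    apobec_log: list[Mutation] = []
    edited = prov
    if params.apobec_pattern is not None and params.apobec_efficiency > 0:
        edited, apobec_log = apobec_edit(
            prov, params.apobec_pattern, params.apobec_efficiency, rng
        )
    host = random_host(2 * flank, rng)
    position = flank
    locus0_unedited, span, tsd = integrate(
        host, prov, position, params.tsd_length
    )
    locus0, _, _ = integrate(host, edited, position, params.tsd_length)
    shifted = [
        Mutation(m.position + position, m.from_base, m.to_base, m.cause)
        for m in apobec_log
    ]
    final, evo_log = evolve(locus0, params, rng)
    L = params.ltr_length
    truth = SimTruth(
        id=locus_id,
        years=params.years,
        genotype=params.genotype_label,
        pbs_label=params.pbs_choice,
        tsd=tsd,
        apobec=bool(apobec_log) or params.apobec_efficiency > 0,
        provirus_span=span,
        ltr5_span=(span[0], span[0] + L),
        ltr3_span=(span[1] - L, span[1]),
        initial_locus=locus0_unedited,
        log=shifted + evo_log,
    )
    rec = ProvirusRecord(
        id=locus_id,
        locus=SequenceRecord(locus_id, final),
        ltr5_span=truth.ltr5_span,
        ltr3_span=truth.ltr3_span,
        genotype=params.genotype_label,
    )
    return rec, truth


def generate_cohort(
    cells: list[SimParams],
    n_per_cell: int,
    seed: int,
    flank: int = 500,
    share_ancestor: bool = True,
) -> Cohort:
    """A reproducible cohort spanning the given parameter cells.

    Each cell gets one ancestral virus (re-used across its integrations,
    as a real germ-line invader would be) unless ``share_ancestor`` is
    False. All randomness descends from ``seed`` via spawned generators.
    """
    ss = np.random.SeedSequence(seed)
    loci: list[ProvirusRecord] = []
    truths: list[SimTruth] = []
    for ci, params in enumerate(cells):
        cell_ss = ss.spawn(1)[0]
        streams = cell_ss.spawn(n_per_cell + 1)
        anc_rng = np.random.default_rng(streams[0])
        ancestor = make_ancestor(params, anc_rng) if share_ancestor else None
        for ri in range(n_per_cell):
            rng = np.random.default_rng(streams[ri + 1])
            lid = (
                f"{params.genotype_label}_T{params.years/1e6:g}My_"
                f"ap{int(params.apobec_efficiency > 0)}_c{ci}_r{ri}"
            )
            rec, truth = simulate_locus(
                params, rng, ancestor=ancestor, flank=flank, locus_id=lid
            )
            loci.append(rec)
            truths.append(truth)
    return Cohort(loci=loci, truth=truths, seed=seed)


def default_grid(
    ages_myr: tuple[float, ...] = (1.0, 3.0, 8.0),
    apobec: tuple[bool, ...] = (False, True),
    apobec_efficiency: float = 0.3,
) -> list[SimParams]:
    """The standard study grid: ages x APOBEC on/off, genotype-1 profile."""
    cells = []
    for t in ages_myr:
        for ap in apobec:
            cells.append(
                SimParams(
                    years=t * 1e6,
                    apobec_pattern=DEFAULT_APOBEC if ap else None,
                    apobec_efficiency=apobec_efficiency if ap else 0.0,
                )
            )
    return cells
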
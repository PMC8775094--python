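import numpy as np
import pytest

from ervkit.distances import composition, k2p
from ervkit.errors import SimulationError
from ervkit.provirus import PBS_LYS3, PBS_LYS12, detect_tsd, orf_status
from ervkit.simdata import (
    DEFAULT_APOBEC,
    Cohort,
    SimParams,
    apobec_edit,
    default_grid,
    evolve,
    generate_cohort,
    integrate,
    make_ancestor,
    random_host,
    replay,
    simulate_locus,
)


def count_cpg(s):
    return sum(1 for i in range(len(s) - 1) if s[i: i + 2] == "CG")


class TestMakeAncestor:
    def test_default_structure(self, ancestor):
        s = ancestor.locus.residues
        assert len(s) == 8393
        assert s[:485] == s[-485:]  # identical terminal LTRs
        assert s[485: 485 + 18] == PBS_LYS3

    def test_cpg_target_hit_within_band(self):
        anc = make_ancestor(SimParams.genotype2(seed=3))
        n = count_cpg(anc.locus.residues)
        assert 137 <= n <= 151  # 144 +- 5%
        assert anc.locus.residues[485: 485 + 18] == PBS_LYS12

    def test_orfs_are_open(self, ancestor):
        s = ancestor.locus.residues
        assert set(ancestor.orfs) == {"gag", "pro", "pol", "env"}
        for g, (a, b) in ancestor.orfs.items():
            assert orf_status(s[a:b], b - a, g).state == "open"

    def test_region_composition_profiles(self, ancestor):
        s = ancestor.locus.residues
        ltr_a = composition(s, ancestor.ltr5_span)["A"]
        gag = composition(s, ancestor.orfs["gag"])
        env = composition(s, ancestor.orfs["env"])
        assert ltr_a < gag["A"]  # LTR is the A-poorest region
        assert gag["A"] > gag["G"]  # A-rich, G-poor coding region
        assert env["A"] < gag["A"]

    def test_same_seed_reproduces(self):
        a = make_ancestor(SimParams(seed=42))
        b = make_ancestor(SimParams(seed=42))
        assert a.locus.residues == b.locus.residues

    def test_infeasible_cpg_target_errors(self):
        with pytest.raises(SimulationError):
            make_ancestor(SimParams(cpg_target_count=4000, seed=1))


class TestIntegrate:
    def test_tsd_duplicated_and_recovered(self, ancestor, rng):
        host = random_host(1000, rng)
        locus, span, tsd = integrate(host, ancestor.locus.residues, 500)
        assert len(tsd) == 6
        assert tsd == host[494:500]
        assert detect_tsd(locus, span) == tsd

    def test_zero_tsd_length_no_duplication(self, ancestor, rng):
        host = random_host(1000, rng)
        locus, span, tsd = integrate(host, ancestor.locus.residues, 500,
                                     tsd_length=0)
        assert tsd is None
        assert detect_tsd(locus, span) is None or len(locus) == len(host) + 8393

    def test_out_of_range_position(self, ancestor):
        with pytest.raises(ValueError):
            integrate("ACGT" * 10, ancestor.locus.residues, 500)


class TestEvolve:
    def test_zero_years_is_identity(self, ancestor, rng):
        s = ancestor.locus.residues
        out, log = evolve(s, SimParams(years=0), rng)
        assert out == s and log == []

    def test_log_replays_to_output(self, ancestor, rng):
        s = ancestor.locus.residues
        out, log = evolve(s, SimParams(years=3e6), rng)
        assert len(log) > 0
        assert replay(s, log) == out

    def test_expected_ltr_divergence_without_cpg(self, rng):
        """Two 485 nt copies evolved independently for T years diverge by
        ~2rT; at T=3 Myr, r=5e-9 the mean K must sit in [0.026, 0.034]."""
        params = SimParams(years=3e6, cpg_transition_rate=0.0)
        ltr = random_host(485, rng)
        ks = []
        for _ in range(200):
            a, _ = evolve(ltr, params, rng)
            b, _ = evolve(ltr, params, rng)
            ks.append(k2p(a, b).K)
        assert 0.026 <= np.mean(ks) <= 0.034

    def test_cpg_sites_mutate_faster(self, ancestor, rng):
        s = ancestor.locus.residues
        _, log = evolve(s, SimParams(years=2e6), rng)
        cpg_events = sum(1 for m in log if m.cause == "cpg")
        neutral_events = sum(1 for m in log if m.cause == "neutral")
        n_cpg_bases = 2 * count_cpg(s)
        cpg_rate = cpg_events / n_cpg_bases
        neutral_rate = neutral_events / len(s)
        assert cpg_rate > 5 * neutral_rate

    def test_transition_bias_recovered(self, rng):
        """The 4:1 ts:tv weighting must reappear in pooled cohort counts."""
        from ervkit.distances import tstv_ratio
        from ervkit.seqio import Alignment, SequenceRecord

        params = SimParams(years=8e6, cpg_transition_rate=0.0,
                           ts_tv_weight=10.0)
        base = random_host(4000, rng)
        ratios = []
        for _ in range(20):
            recs = []
            for i in range(4):
                s, _ = evolve(base, params, rng)
                recs.append(SequenceRecord(f"s{i}", s))
            r = tstv_ratio(Alignment(recs))
            ratios.append(r.ratio)
        assert 8 <= np.mean(ratios) <= 12

    def test_saturation_warns(self, rng):
        with pytest.warns(UserWarning, match="> 0.5"):
            evolve("ACGT" * 200, SimParams(years=2e8), rng)


class TestApobecEdit:
    def test_zero_efficiency_is_identity(self, ancestor, rng):
        s = ancestor.locus.residues
        out, log = apobec_edit(s, DEFAULT_APOBEC, 0.0, rng)
        assert out == s and log == []

    def test_full_efficiency_uses_pre_edit_context(self, rng):
        # in TGGT both Gs match -(G>A)-G? No: only the first G has a
        # downstream G on the pre-edit sequence, so TGGT -> TAGT
        out, log = apobec_edit("TGGT", DEFAULT_APOBEC, 1.0, rng)
        assert out == "TAGT"
        assert [(m.position, m.from_base, m.to_base) for m in log] == [
            (1, "G", "A")
        ]

    def test_pre_edit_convention_with_kgd_pattern(self, rng):
        # with K-(G>A)-D both Gs of TGGT qualify against the pre-edit
        # sequence, so both are edited even though editing the first
        # destroys the second's upstream context
        from ervkit.signatures import parse_pattern

        pat = parse_pattern("K-(G>A)-D")
        out, _ = apobec_edit("TGGT", pat, 1.0, rng)
        assert out == "TAAT"

    def test_edit_count_in_binomial_interval(self, ancestor, rng):
        from scipy import stats

        s = ancestor.locus.residues
        _, log0 = apobec_edit(s, DEFAULT_APOBEC, 1.0, rng)
        n_sites = len(log0)
        assert n_sites >= 50
        _, log = apobec_edit(s, DEFAULT_APOBEC, 0.3, rng)
        lo, hi = stats.binom.interval(0.99, n_sites, 0.3)
        assert lo <= len(log) <= hi


class TestCohort:
    def test_grid_cardinality(self):
        cells = default_grid(ages_myr=(1.0, 3.0), apobec=(False, True))
        cohort = generate_cohort(cells, 5, seed=9)
        assert len(cohort.loci) == 20
        assert len(cohort.truth) == 20

    def test_determinism_of_master_seed(self):
        cells = [SimParams(years=1e6)]
        a = generate_cohort(cells, 3, seed=77)
        b = generate_cohort(cells, 3, seed=77)
        assert [r.locus.residues for r in a.loci] == [
            r.locus.residues for r in b.loci
        ]

    def test_truth_logs_replay_to_emitted_sequences(self):
        cohort = generate_cohort(default_grid(ages_myr=(3.0,)), 3, seed=5)
        for rec, truth in zip(cohort.loci, cohort.truth):
            assert replay(truth.initial_locus, truth.log) == rec.locus.residues

    def test_write_outputs(self, tmp_path):
        cohort = generate_cohort([SimParams(years=1e6)], 2, seed=1)
        cohort.write(tmp_path / "cohort")
        fasta = (tmp_path / "cohort" / "loci.fasta").read_text()
        truth = (tmp_path / "cohort" / "truth.tsv").read_text()
        assert fasta.count(">") == 2
        assert "seed=1" in fasta
        assert truth.startswith("# master seed = 1")

    def test_round_trip_recovery_of_tsd_and_pbs(self):
        """Undamaged loci return the planted TSD and PBS label exactly."""
        from ervkit.provirus import classify_pbs, extract_pbs

        cohort = generate_cohort(default_grid(ages_myr=(1.0, 3.0)), 5, seed=21)
        n_checked = 0
        for rec, truth in zip(cohort.loci, cohort.truth):
            start, end = truth.provirus_span
            tsd_window = set(range(start - 6, start)) | set(range(end, end + 6))
            pbs_window = set(range(truth.ltr5_span[1], truth.ltr5_span[1] + 18))
            hit = {m.position for m in truth.log}
            if not (hit & tsd_window):
                assert detect_tsd(rec.locus, truth.provirus_span) == truth.tsd
                n_checked += 1
            if not (hit & pbs_window):
                pbs = extract_pbs(rec.locus, truth.ltr5_span)
                assert classify_pbs(pbs).label == truth.pbs_label
        assert n_checked > 0
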
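"""Rho statistics, star-likeness, the corrected clock and clock ML."""

import io
import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from lineagekit import chronos, synthgen
from lineagekit.chronos import (CladeSummary, ClockSpec, GenealogyBranch,
                                MlConfig, clock_convert, clock_convert_ci,
                                date_clade_rho, discrete_gamma_rates,
                                hky_eigen, hky_transition_matrices,
                                method_concordance, ml_root_distance,
                                rho_stat, saillard_sigma, star_index)


def star_clade(n, m_per_tip=1):
    return CladeSummary(n=n, branches=[GenealogyBranch(m_per_tip, 1)
                                       for _ in range(n)])


class TestRhoSigmaStar:
    def test_rho_is_mean_root_distance(self):
        clade = CladeSummary(n=3, branches=[
            GenealogyBranch(0, 1), GenealogyBranch(1, 1),
            GenealogyBranch(2, 1)], root_distances=[0, 1, 2])
        assert rho_stat(clade) == 1.0

    def test_star_of_four(self):
        clade = star_clade(4)
        assert rho_stat(clade) == 1.0
        assert saillard_sigma(clade) == pytest.approx(0.5)
        assert star_index(clade) == pytest.approx(1.0)

    def test_single_shared_haplotype(self):
        clade = CladeSummary(n=5, branches=[GenealogyBranch(3, 5)])
        assert saillard_sigma(clade) == pytest.approx(math.sqrt(3))
        assert star_index(clade) == pytest.approx(1 / 5)

    def test_mutation_free_clade(self):
        clade = CladeSummary(n=4, branches=[GenealogyBranch(0, 1)] * 4)
        assert saillard_sigma(clade) == 0.0
        assert star_index(clade) is None

    def test_rho_matches_path_enumeration_oracle(self):
        # explicit genealogy: ((t0,t1),t2); root->A has 2 mutations,
        # A->t0 1, A->t1 0, root->t2 3
        clade = CladeSummary(n=3, branches=[
            GenealogyBranch(2, 2), GenealogyBranch(1, 1),
            GenealogyBranch(0, 1), GenealogyBranch(3, 1)])
        root_paths = [2 + 1, 2 + 0, 3]
        assert rho_stat(clade) == pytest.approx(np.mean(root_paths))

    def test_star_index_bounds_over_random_genealogies(self):
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(500):
            n = int(rng.integers(2, 25))
            sim = synthgen.sim_clade(synthgen.CladeSimSpec(
                n_tips=n, tmrca_years=float(rng.uniform(500, 20000)),
                rate_per_year=1 / 1000.0,
                genealogy="kingman_coalescent",
                n_sites=300, seed=int(rng.integers(2**31))))
            s = star_index(sim.summary)
            if s is None:
                continue
            checked += 1
            assert 1 / n - 1e-9 <= s <= 1 + 1e-9
        assert checked > 400

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CladeSummary(n=2, branches=[GenealogyBranch(1, 1)],
                         root_distances=[3, 3])

    def test_summary_tsv_reader(self):
        buf = io.StringIO("branch\tm\tn_desc\nb0\t2\t2\nb1\t1\t1\n")
        clade = CladeSummary.from_tsv(buf, n=2)
        assert rho_stat(clade) == pytest.approx((2 * 2 + 1) / 2)


class TestCorrectedClock:
    def test_zero_maps_to_zero(self):
        assert clock_convert(0.0) == 0.0

    def test_strictly_increasing_and_inverse_round_trip(self):
        spec = ClockSpec()
        ds = np.linspace(0.01, 100, 80)
        ages = [clock_convert(d, spec) for d in ds]
        assert all(b > a for a, b in zip(ages, ages[1:]))
        for d, t in zip(ds, ages):
            assert spec.expected_distance(t) == pytest.approx(
                d, rel=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            clock_convert(-1.0)

    def test_ci_truncates_at_zero_and_collapses_for_zero_sd(self):
        lo, hi = clock_convert_ci(1.0, 10.0)
        assert lo == 0.0 and hi > 0
        lo, hi = clock_convert_ci(2.0, 0.0)
        assert lo == hi == pytest.approx(clock_convert(2.0))

    def test_synonymous_mode_is_linear(self):
        spec = ClockSpec(mode="synonymous")
        assert clock_convert(1.0, spec) == pytest.approx(7884.0)
        assert clock_convert(2.0, spec) == pytest.approx(15768.0)

    def test_young_clades_run_faster_than_old(self):
        # transient excess: years-per-mutation grows with age
        r1 = clock_convert(0.5) / 0.5
        r2 = clock_convert(5.0) / 5.0
        assert r1 < r2


class TestRhoDating:
    def test_star_clade_age_recovery_small(self):
        # simulated mutations are a constant-rate Poisson process, so the
        # matching converter is the linear long-term clock
        rate = 1 / 3624.0
        tm = 8000.0
        spec = ClockSpec(mode="linear")
        ages = []
        for seed in range(40):
            sim = synthgen.sim_clade(synthgen.CladeSimSpec(
                n_tips=20, tmrca_years=tm, rate_per_year=rate,
                n_sites=2000, seed=seed))
            res = date_clade_rho(sim.summary, spec, name="star")
            ages.append(res.age_years)
            assert res.ci_low_years <= res.age_years <= res.ci_high_years
        assert np.mean(ages) == pytest.approx(tm, rel=0.10)

    def test_report_columns(self):
        res = date_clade_rho(star_clade(4), name="toy")
        buf = io.StringIO()
        chronos.write_dating_report([res], buf)
        head = buf.getvalue().splitlines()[0].split("\t")
        assert head == ["haplogroup", "n", "mean_kya", "ci95_kya",
                        "distance", "sd", "method"]


class TestMethodConcordance:
    def test_identical_maps(self):
        ratios, mean, flags = method_concordance({"A": 1.0, "B": 2.0},
                                                 {"A": 1.0, "B": 2.0})
        assert mean == 1.0 and flags == []

    def test_flagging(self):
        ratios, mean, flags = method_concordance({"A": 8000.0},
                                                 {"A": 4000.0})
        assert ratios["A"] == 2.0 and flags == ["A"]

    def test_zero_ml_age_reported_infinite(self):
        ratios, mean, flags = method_concordance({"A": 100.0},
                                                 {"A": 0.0})
        assert math.isinf(ratios["A"]) and flags == ["A"]

    def test_rho_and_ml_agree_on_simulated_star_clades(self):
        # star clades, balanced analysis topology, linear clock matching
        # the constant-rate generative process
        clock = ClockSpec(mode="linear", long_term_years_per_sub=3000.0)
        rho_ages, ml_ages = {}, {}
        master = np.random.default_rng(77)
        for rep in range(10):
            sim = synthgen.sim_clade(synthgen.CladeSimSpec(
                n_tips=8, tmrca_years=8000, rate_per_year=1 / 3000.0,
                n_sites=1200, seed=int(master.integers(2**31))))
            name = f"clade{rep}"
            rho_ages[name] = date_clade_rho(sim.summary, clock).age_years
            seqs = {r.id: r.sequence for r in sim.sequences
                    if r.id != "root"}
            t = [f"tip{i}" for i in range(8)]
            topo = (((t[0], t[1]), (t[2], t[3])),
                    ((t[4], t[5]), (t[6], t[7])))
            cfg = MlConfig(fix_kappa=True, kappa=2.0, gamma_categories=1,
                           partitions=None)
            ml = ml_root_distance(seqs, topo, cfg)
            ml_ages[name] = chronos.clock_convert(ml.distance, clock)
        ratios, mean, flags = method_concordance(rho_ages, ml_ages)
        assert 0.9 <= mean <= 1.1
        assert flags == []


class TestHkyMachinery:
    @pytest.mark.parametrize("kappa,freqs", [
        (1.0, (0.25, 0.25, 0.25, 0.25)),
        (4.0, (0.3, 0.2, 0.15, 0.35)),
    ])
    def test_transition_matrix_matches_expm(self, kappa, freqs):
        eig = hky_eigen(kappa, np.asarray(freqs))
        # rebuild Q explicitly for the oracle
        pi = np.asarray(freqs)
        Q = np.empty((4, 4))
        trans = {(0, 2), (2, 0), (1, 3), (3, 1)}
        for i, j in itertools.product(range(4), range(4)):
            if i != j:
                Q[i, j] = (kappa if (i, j) in trans else 1.0) * pi[j]
        np.fill_diagonal(Q, 0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        Q /= -np.sum(pi * np.diag(Q))
        for t in (0.0, 0.05, 0.7):
            P = hky_transition_matrices([t], eig)[0]
            assert np.allclose(P, expm(Q * t), atol=1e-10)
            assert np.allclose(P.sum(axis=1), 1.0)

    def test_discrete_gamma_rates_have_unit_mean(self):
        for alpha in (0.2, 0.5, 1.0, 5.0):
            r = discrete_gamma_rates(alpha, 32)
            assert len(r) == 32
            assert np.mean(r) == pytest.approx(1.0)
            assert np.all(np.diff(r) > 0)

    def test_degenerate_frequencies_rejected(self):
        with pytest.raises(ValueError):
            hky_eigen(2.0, np.array([0.5, 0.5, 0.0, 0.0]))


def _transition(b):
    return {"A": "G", "G": "A", "C": "T", "T": "C"}[b]


class TestMlRootDistance:
    def test_identical_sequences_zero_distance(self):
        s = "ACGT" * 100
        cfg = MlConfig(gamma_categories=1, partitions=None)
        res = ml_root_distance({"a": s, "b": s}, ("a", "b"), cfg)
        assert res.per_site == pytest.approx(0.0, abs=2e-4)

    def test_matches_jc_closed_form_two_taxa(self):
        rng = np.random.default_rng(0)
        s1 = "".join(rng.choice(list("ACGT"), size=1000))
        s2 = list(s1)
        for i in rng.choice(1000, size=100, replace=False):
            s2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s2[i]]
        cfg = MlConfig(kappa=1.0, fix_kappa=True, gamma_categories=1,
                       base_freqs=(0.25,) * 4, partitions=None)
        res = ml_root_distance({"a": s1, "b": "".join(s2)}, ("a", "b"),
                               cfg)
        jc = -0.75 * math.log(1 - 4 / 3 * 0.1)
        assert res.per_site == pytest.approx(jc / 2, abs=1e-4)

    def test_unaligned_input_rejected(self):
        with pytest.raises(ValueError, match="unaligned"):
            ml_root_distance({"a": "ACGT", "b": "ACG"}, ("a", "b"),
                             MlConfig(partitions=None))

    def test_partition_rates_average_to_one(self):
        rng = np.random.default_rng(5)
        root = "".join(rng.choice(list("ACGT"), size=400))

        def mutate(s, k):
            s = list(s)
            for i in rng.choice(len(s), size=k, replace=False):
                s[i] = _transition(s[i])
            return "".join(s)

        seqs = {f"t{i}": mutate(root, 6) for i in range(3)}
        cfg = MlConfig(gamma_categories=1, fix_kappa=True,
                       partitions=(("left", ((1, 200),)),
                                   ("right", None)))
        res = ml_root_distance(seqs, (("t0", "t1"), "t2"), cfg)
        assert 0.5 * res.partition_rates["left"] + \
            0.5 * res.partition_rates["right"] == pytest.approx(1.0)

    def test_whole_molecule_scale(self):
        s = "ACGT" * 50
        q = _transition(s[0]) + s[1:]
        cfg = MlConfig(kappa=1.0, fix_kappa=True, gamma_categories=1,
                       base_freqs=(0.25,) * 4, partitions=None)
        res = ml_root_distance({"a": s, "b": q}, ("a", "b"), cfg)
        assert res.distance == pytest.approx(res.per_site * 200)
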
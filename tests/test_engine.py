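"""Wright-Fisher engine: rescaling, mutation, recombination, mating,
pruning, demography, and drift calibration."""

import numpy as np
import pandas as pd
import pytest

import introsim
from introsim import experiments as ex
from introsim.ancestry import DONOR, RECIPIENT
from introsim.engine import (
    POP_DONOR,
    POP_RECIPIENT,
    DemographicModel,
    Engine,
    Haplotype,
    Individual,
    rescale,
)
from introsim.selection import NONSYNONYMOUS, SYNONYMOUS, individual_fitness

from conftest import all_exon_structure, tiny_engine


class TestRescale:
    def test_identity_at_c_equal_one(self):
        cfg = ex.build_config(model=0, N_A=100, L=10_000, c=1.0, seed=0)
        assert rescale(cfg) is cfg

    def test_population_size_and_times(self):
        cfg = ex.build_config(model=0, N_A=10_000, L=10_000, c=5.0, seed=0)
        scaled = rescale(cfg)
        d = scaled.demography
        assert d.N_A == 2000
        assert d.burn_in == 20_000
        assert d.t_s == 4000
        assert d.post_admixture == 2000

    def test_selection_and_mutation_scaled_up(self):
        cfg = ex.build_config(model=0, N_A=10_000, L=10_000, c=5.0, seed=0)
        scaled = rescale(cfg)
        assert scaled.dfe.mean_s == pytest.approx(5 * cfg.dfe.mean_s)
        assert scaled.mu == pytest.approx(5 * cfg.mu)

    def test_recombination_haldane_transform(self):
        cfg = ex.build_config(model=0, N_A=10_000, L=10_000, c=5.0, r=1e-8, seed=0)
        scaled = rescale(cfg)
        r = scaled.structure.recomb_map.rates[0]
        assert r == pytest.approx(0.5 * (1 - (1 - 2e-8) ** 5), rel=1e-12)
        assert r == pytest.approx(4.9999995e-8, rel=1e-6)

    def test_sequence_length_unchanged(self):
        cfg = ex.build_config(model=0, N_A=10_000, L=123_456, c=5.0, seed=0)
        assert rescale(cfg).structure.length == 123_456

    def test_overscaled_population_rejected(self):
        cfg = ex.build_config(model=0, N_A=100, L=10_000, c=100.0, seed=0)
        with pytest.raises(ValueError, match="< 2"):
            rescale(cfg)


class TestMutateGamete:
    def test_zero_rate_returns_same_haplotype(self):
        eng = tiny_engine(mu=0.0)
        hap = Haplotype.empty(eng.L)
        assert eng.mutate_gamete(hap) is hap

    def test_poisson_mean_matches_mu_times_length(self):
        eng = tiny_engine(mu=2e-5)  # all-exon structure, 100 kb
        hap = Haplotype.empty(eng.L)
        counts = [len(eng.mutate_gamete(hap).ids) for _ in range(3000)]
        lam = eng.mu_total
        se = np.sqrt(lam / len(counts))
        assert abs(np.mean(counts) - lam) < 4 * se

    def test_exonic_class_ratio(self):
        eng = tiny_engine(mu=2e-4, seed=3)
        hap = Haplotype.empty(eng.L)
        for _ in range(40):
            hap = eng.mutate_gamete(hap)
        cls = eng.tbl.func_class[: eng.tbl.n]
        ns = (cls == NONSYNONYMOUS).sum()
        syn = (cls == SYNONYMOUS).sum()
        n = ns + syn
        p_hat = ns / n
        p = 2.31 / 3.31
        assert abs(p_hat - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_infinite_sites_within_haplotype(self):
        eng = tiny_engine(mu=1e-4, seed=4)
        hap = Haplotype.empty(eng.L)
        for _ in range(50):
            hap = eng.mutate_gamete(hap)
        assert len(np.unique(hap.pos)) == len(hap.pos)
        assert (np.diff(hap.pos) > 0).all()

    def test_origin_matches_covering_ancestry_segment(self):
        eng = tiny_engine(mu=5e-5, seed=5)
        hap = Haplotype(np.empty(0, np.int64), np.empty(0, np.int64), 1.0,
                        frozenset(),
                        np.array([eng.L // 2, eng.L], dtype=np.int64),
                        np.array([RECIPIENT, DONOR], dtype=np.int8))
        for _ in range(60):
            hap = eng.mutate_gamete(hap, pop_code=POP_RECIPIENT)
        pos = eng.tbl.position[: eng.tbl.n]
        origin = eng.tbl.origin_pop[: eng.tbl.n]
        assert (origin[pos < eng.L // 2] == POP_RECIPIENT).all()
        assert (origin[pos >= eng.L // 2] == POP_DONOR).all()


class TestRecombine:
    def _parents(self, eng, seed=0):
        rng = np.random.default_rng(seed)
        def hap(label, n_muts):
            p = np.sort(rng.choice(eng.L, size=n_muts, replace=False)).astype(np.int64)
            ids = eng.tbl.add_many(p, np.zeros(n_muts), np.full(n_muts, 0.5),
                                   np.full(n_muts, SYNONYMOUS), label, 0,
                                   eng.cfg.dominance)
            return Haplotype(p, ids, 1.0, frozenset(),
                             np.array([eng.L], dtype=np.int64),
                             np.array([label], dtype=np.int8))
        h1 = hap(RECIPIENT, 40)
        h2 = hap(DONOR, 40)
        return Individual(h1, h2, 1.0)

    def test_zero_map_copies_one_parent_haplotype(self):
        eng = tiny_engine(all_exon_structure(r=0.0))
        parent = self._parents(eng)
        for _ in range(5):
            g = eng.recombine(parent)
            assert g is parent.h1 or g is parent.h2

    def test_mean_crossovers_matches_map_length(self):
        structure = all_exon_structure(length=5_000_000, r=1e-8)
        eng = tiny_engine(structure, mu=0.0)
        assert eng.morgans == pytest.approx(0.05)
        rng = np.random.default_rng(0)
        draws = rng.poisson(eng.morgans, 10_000)
        assert abs(draws.mean() - 0.05) < 4 * np.sqrt(0.05 / 10_000)

    def test_gamete_mutations_consistent_with_ancestry(self):
        # mutations on the gamete must lie inside segments inherited from
        # the parental haplotype that carried them
        eng = tiny_engine(all_exon_structure(r=5e-7), seed=9)
        parent = self._parents(eng, seed=1)
        h1_ids = set(parent.h1.ids.tolist())
        for _ in range(60):
            g = eng.recombine(parent)
            for p, mid in zip(g.pos, g.ids):
                seg = int(np.searchsorted(g.anc_ends, p, side="right"))
                label = g.anc_orig[seg]
                expect = RECIPIENT if mid in h1_ids else DONOR
                assert label == expect

    def test_segments_tile_and_merge(self):
        eng = tiny_engine(all_exon_structure(r=5e-7), seed=10)
        parent = self._parents(eng, seed=2)
        for _ in range(60):
            g = eng.recombine(parent)
            assert g.anc_ends[-1] == eng.L
            assert (np.diff(g.anc_ends) > 0).all()
            assert (g.anc_orig[:-1] != g.anc_orig[1:]).all()


class TestMatingAndDemography:
    def test_full_selfing_uses_single_parent(self):
        eng = tiny_engine(all_exon_structure(r=0.0), mu=0.0)
        pop = []
        for label in range(6):
            h = Haplotype.empty(eng.L)
            h2 = Haplotype.empty(eng.L)
            pop.append(Individual(h, h2, 1.0))
        kids = eng._offspring_auto(20, pop, None, 0.0, 1.0, 1, POP_RECIPIENT)
        parent_haps = [{id(ind.h1), id(ind.h2)} for ind in pop]
        for kid in kids:
            got = {id(kid.h1), id(kid.h2)}
            assert any(got <= haps for haps in parent_haps)

    def test_model_presets_sizes(self):
        d = DemographicModel.preset(4, 1000)
        assert d.recipient_size(0) == 100
        assert d.recipient_size(d.t_s - 1) == 100
        assert d.recipient_size(d.t_s) == 1000
        assert d.donor_size(0) == 1000
        d2 = DemographicModel.preset(2, 1000)
        assert d2.donor_size(0) == 100
        assert d2.recipient_size(0) == 1000
        d1 = DemographicModel.preset(1, 1000)
        assert d1.recipient_size(d1.t_s - 1) == 100
        assert d1.recipient_size(d1.t_s - 101) == 1000

    def test_sizes_follow_schedule_every_generation(self):
        res = introsim.run(ex.build_config(
            model=4, N_A=40, L=20_000, c=1.0, seed=1, record_every=10,
            track_neutral=False))
        ts = res.timeseries
        d = res.scaled_config.demography
        for _, row in ts.iterrows():
            expect = (d.donor_size(row.gen_rel) if row["pop"] == "donor"
                      else d.recipient_size(row.gen_rel))
            assert row["size"] == expect

    def test_determinism_same_seed(self):
        kw = dict(model=2, dominance="recessive", N_A=40, L=50_000, c=1.0,
                  seed=77, record_every=20)
        a = introsim.run(ex.build_config(**kw))
        b = introsim.run(ex.build_config(**kw))
        pd.testing.assert_frame_equal(a.timeseries, b.timeseries)
        ids_a = sorted(tuple(h.ids) for i in a.populations["recipient"]
                       for h in i.haplotypes())
        ids_b = sorted(tuple(h.ids) for i in b.populations["recipient"]
                       for h in i.haplotypes())
        assert ids_a == ids_b

    def test_engine_fitness_matches_reference_computation(self):
        # dual route: cached engine fitness vs the per-locus reference
        res = introsim.run(ex.build_config(
            model=0, dominance="hs", N_A=30, L=100_000, c=2.0, seed=5,
            mu=1e-7, track_neutral=False))
        tbl = res.table
        for pop in res.populations.values():
            for ind in pop[:10]:
                c1 = {int(m) for m in ind.h1.ids if tbl.selected[m]}
                c2 = {int(m) for m in ind.h2.ids if tbl.selected[m]}
                geno = [(tbl.s[m], tbl.h[m], (m in c1) + (m in c2))
                        for m in c1 | c2]
                expect = individual_fitness(geno, res.scaled_config.dominance)
                assert ind.w == pytest.approx(expect, rel=1e-9)


class TestPruneFixed:
    def _engine_with_pops(self):
        eng = tiny_engine(all_exon_structure(r=0.0), mu=0.0,
                          dominance="recessive")
        tbl = eng.tbl
        dom = eng.cfg.dominance
        m_both = tbl.add(10, -0.1, 0.0, NONSYNONYMOUS, 0, 0, dom)
        m_donor = tbl.add(20, -0.2, 0.0, NONSYNONYMOUS, 0, 0, dom)
        m_seg = tbl.add(30, -0.3, 0.0, NONSYNONYMOUS, 0, 0, dom)

        def hap(mut_ids, label):
            ids = np.array(sorted(mut_ids), dtype=np.int64)
            pos = tbl.position[ids]
            h = Haplotype(pos, ids, float(tbl.het_factor[ids].prod()),
                          frozenset(ids.tolist()),
                          np.array([eng.L], dtype=np.int64),
                          np.array([label], dtype=np.int8))
            return h

        def ind(mids1, mids2, label):
            h1, h2 = hap(mids1, label), hap(mids2, label)
            return Individual(h1, h2, eng._fitness(h1, h2))

        donor = [ind({m_both, m_donor}, {m_both, m_donor}, DONOR)
                 for _ in range(3)]
        recip = [ind({m_both}, {m_both, m_seg}, RECIPIENT) for _ in range(3)]
        return eng, {"donor": donor, "recipient": recip}, (m_both, m_donor, m_seg)

    def test_only_globally_fixed_removed_and_logged(self):
        eng, pops, (m_both, m_donor, m_seg) = self._engine_with_pops()
        removed = eng.prune_fixed(pops, gen=42)
        assert removed == [m_both]
        assert eng.substitutions == [(m_both, 42)]
        remaining = {int(m) for ind in pops["donor"] for h in ind.haplotypes()
                     for m in h.ids}
        assert m_donor in remaining and m_both not in remaining

    def test_relative_fitness_invariant(self):
        eng, pops, _ = self._engine_with_pops()
        w_r = np.mean([i.w for i in pops["recipient"]])
        w_d = np.mean([i.w for i in pops["donor"]])
        ratio_before = w_r / w_d
        eng.prune_fixed(pops, gen=1)
        w_r2 = np.mean([i.w for i in pops["recipient"]])
        w_d2 = np.mean([i.w for i in pops["donor"]])
        assert w_r2 / w_d2 == pytest.approx(ratio_before, rel=1e-12)


_DRIFT_N = 50
_DRIFT_POST = 60


@pytest.fixture(scope="module")
def drift_final_p():
    struct = all_exon_structure(length=10_000, r=0.0)
    out = []
    for rep in range(80):
        cfg = ex.build_config(model=0, N_A=_DRIFT_N, L=struct.length,
                              structure=struct, c=1.0, neutral=True,
                              mu=0.0, burn_in=5, t_s=10,
                              post_admixture=_DRIFT_POST,
                              seed=ex.derive_seed(123, "drift", rep),
                              record_every=200, track_neutral=False)
        res = introsim.run(cfg)
        rec = res.timeseries
        out.append(float(rec[rec["pop"] == "recipient"].iloc[-1]["p_I"]))
    return np.asarray(out)


class TestNeutralDrift:
    """With s = 0 the chromosome-wide ancestry fraction is a single-locus
    Wright-Fisher martingale (map length 0 makes this exact)."""

    def test_mean_is_admixture_fraction(self, drift_final_p):
        se = drift_final_p.std(ddof=1) / np.sqrt(len(drift_final_p))
        assert abs(drift_final_p.mean() - 0.05) < 3 * se

    def test_variance_matches_binomial_oracle(self, drift_final_p):
        from scipy import stats
        T = _DRIFT_POST + 1  # pulse draw plus post-admixture generations
        var_theory = 0.05 * 0.95 * (1 - (1 - 1 / (2 * _DRIFT_N)) ** T)
        n = len(drift_final_p)
        stat = (n - 1) * drift_final_p.var(ddof=1) / var_theory
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1)
        assert lo < stat < hi


class TestXMode:
    def test_sex_ratio_and_ploidy(self):
        res = introsim.run(ex.build_config(
            model=0, N_A=40, L=20_000, c=1.0, seed=3, x_mode=True,
            track_neutral=False))
        for pop in res.populations.values():
            sexes = [i.sex for i in pop]
            assert abs(sexes.count("female") - sexes.count("male")) <= 1
            for i in pop:
                assert (i.h2 is None) == (i.sex == "male")

    def test_paternal_x_transmitted_without_recombination(self):
        eng = tiny_engine(all_exon_structure(r=1e-6), mu=0.0, x_mode=True,
                          N_A=20)
        pop = eng._init_pop(20)
        # give every male a distinctive haplotype object
        for ind in pop:
            if ind.sex == "male":
                ind.h1 = Haplotype.empty(eng.L)
        kids = eng._offspring_x(30, pop, None, 0.0, 1, POP_RECIPIENT)
        father_haps = {id(i.h1) for i in pop if i.sex == "male"}
        for kid in kids:
            if kid.sex == "female":
                assert id(kid.h2) in father_haps
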
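"""Event mechanics and the branch/tree simulation process."""

import numpy as np
import pytest

from rearrabc import (
    Genome,
    ModelParams,
    apply_fission,
    apply_fusion,
    apply_inversion,
    apply_translocation,
    canonical_chromosome,
    make_root_genome,
    simulate_branch,
    simulate_tree,
    zipf_block_pmf,
    random_tree,
)
from rearrabc.simulator import sample_block_size
from conftest import random_signed_genome


class TestZipf:
    def test_closed_form(self):
        # 1 + 1/4 + 1/9 = 49/36 -> pmf (36, 9, 4)/49
        np.testing.assert_allclose(
            zipf_block_pmf(2.0, 3), np.array([36, 9, 4]) / 49
        )
        np.testing.assert_allclose(zipf_block_pmf(1.7, 1), [1.0])

    def test_normalizes_and_decreases(self, rng):
        for _ in range(20):
            a = float(rng.uniform(0.2, 4.0))
            m = int(rng.integers(1, 80))
            p = zipf_block_pmf(a, m)
            assert p.sum() == pytest.approx(1.0)
            assert np.all(np.diff(p) <= 0)

    def test_sampler_matches_pmf(self, rng):
        a, m, n = 1.5, 50, 1_000_000
        draws = sample_block_size(a, m, rng, n)
        p = zipf_block_pmf(a, m)
        freq = np.bincount(draws, minlength=m + 1)[1:] / n
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(freq - p) <= 3 * se + 1e-9)


class TestRootGenome:
    def test_forced_layouts(self, rng):
        g = make_root_genome(3, 3, rng)
        assert g.chromosomes == ((1,), (2,), (3,))
        g = make_root_genome(500, 1, rng)
        assert g.chromosomes == (tuple(range(1, 501)),)

    def test_near_multinomial_sizes(self, rng):
        n, ch, reps = 100, 4, 3000
        sizes = np.array(
            [
                [len(c) for c in make_root_genome(n, ch, rng).chromosomes]
                for _ in range(reps)
            ],
            dtype=float,
        )
        assert sizes.min() >= 1
        # mean size 25 per chromosome; se of the grand mean over reps
        se = sizes.mean(axis=1).std() / np.sqrt(reps)
        assert abs(sizes.mean() - n / ch) <= 3 * se + 1e-9

    def test_too_many_chromosomes(self, rng):
        with pytest.raises(ValueError):
            make_root_genome(3, 4, rng)


class TestInversion:
    def test_definition(self):
        g = Genome(((1, 2, 3, 4, 5),))
        assert apply_inversion(g, 1, 2, 3).chromosomes == ((1, -4, -3, -2, 5),)
        assert apply_inversion(Genome(((1, 2, 3),)), 1, 2, 1).chromosomes == (
            (1, -2, 3),
        )

    def test_involution(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 30))
            g = random_signed_genome(rng, n)
            start = int(rng.integers(1, n + 1))
            size = int(rng.integers(1, n - start + 2))
            once = apply_inversion(g, 1, start, size)
            assert apply_inversion(once, 1, start, size) == g

    def test_bounds(self):
        with pytest.raises(ValueError):
            apply_inversion(Genome(((1, 2, 3),)), 1, 3, 2)


class TestTranslocation:
    def test_definition_and_inverted(self):
        g = Genome(((1, 2, 3, 4, 5),))
        assert apply_translocation(g, 1, 2, 2, 1, 4, False).chromosomes == (
            (1, 4, 2, 3, 5),
        )
        assert apply_translocation(g, 1, 2, 2, 1, 4, True).chromosomes == (
            (1, 4, -3, -2, 5),
        )

    def test_null_and_illdefined_rejected(self):
        g = Genome(((1, 2, 3, 4, 5),))
        with pytest.raises(ValueError, match="null"):
            apply_translocation(g, 1, 2, 2, 1, 1, False)
        with pytest.raises(ValueError, match="block area"):
            apply_translocation(g, 1, 2, 2, 1, 3, False)

    def test_every_accepted_destination_changes_genome(self):
        g = Genome(((1, 2, 3, 4, 5),))
        for start in range(1, 5):
            for size in range(1, 5 - start + 1):
                for dest in range(0, 6):
                    for inv in (False, True):
                        try:
                            out = apply_translocation(g, 1, start, size, 1, dest, inv)
                        except ValueError:
                            continue
                        assert out != g, (start, size, dest, inv)

    def test_content_conserved_across_chromosomes(self, rng):
        g = Genome(((1, 2, 3), (4, 5, 6, 7)))
        out = apply_translocation(g, 2, 2, 2, 1, 0, True)
        assert sorted(abs(x) for x in out.genes()) == list(range(1, 8))


class TestFissionFusion:
    def test_fission(self):
        g = Genome(((1, 2, 3, 4),))
        assert apply_fission(g, 1, 2).chromosomes == ((1, 2), (3, 4))
        for pos in (0, 4):
            with pytest.raises(ValueError):
                apply_fission(g, 1, pos)

    def test_fusion_end_semantics(self):
        g = Genome(((1, 2), (3, 4)))
        assert apply_fusion(g, 1, "tail", 2, "head").chromosomes == ((1, 2, 3, 4),)
        assert apply_fusion(g, 1, "tail", 2, "tail").chromosomes == ((1, 2, -4, -3),)
        with pytest.raises(ValueError):
            apply_fusion(g, 1, "tail", 1, "head")

    def test_fission_fusion_inverse(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 20))
            g = random_signed_genome(rng, n)
            pos = int(rng.integers(1, n))
            split = apply_fission(g, 1, pos)
            back = apply_fusion(split, 1, "tail", 2, "head")
            assert back.canonical() == g.canonical()


class TestBranchProcess:
    def test_zero_rates_identity(self, rng):
        g = random_signed_genome(rng, 50)
        out, ev = simulate_branch(g, 5.0, ModelParams(), rng)
        assert out == g and ev == []

    def test_negative_length(self, rng):
        with pytest.raises(ValueError):
            simulate_branch(Genome(((1, 2),)), -0.1, ModelParams(), rng)

    def test_poisson_event_count(self, rng):
        # rate per gene 0.1, n=100, t=0.5 -> Poisson mean 5
        g = Genome((tuple(range(1, 101)),))
        p = ModelParams(r_inv=0.1)
        reps = 10_000
        counts = np.array(
            [len(simulate_branch(g, 0.5, p, rng)[1]) for _ in range(reps)]
        )
        mean = 0.1 * 100 * 0.5
        se = np.sqrt(mean / reps)
        assert abs(counts.mean() - mean) <= 3 * se

    def test_m0_stays_single_chromosome_and_conserves_content(self, rng):
        g = Genome((tuple(range(1, 61)),))
        p = ModelParams(r_inv=0.5, r_trans=0.5, a=1.3)
        for _ in range(50):
            out, _ = simulate_branch(g, 0.3, p, rng)
            assert out.n_chromosomes == 1
            assert sorted(abs(x) for x in out.genes()) == list(range(1, 61))

    def test_chromosome_count_bookkeeping(self, rng):
        p = ModelParams(
            model="M1", r_inv=0.2, r_trans=0.2, ch_root=5, r_fus=0.5, r_fis=0.01
        )
        g = make_root_genome(80, 5, rng)
        for _ in range(50):
            out, ev = simulate_branch(g, 1.0, p, rng)
            delta = sum(1 for e in ev if e.kind == "fission") - sum(
                1 for e in ev if e.kind == "fusion"
            )
            assert out.n_chromosomes == 5 + delta
            assert sorted(abs(x) for x in out.genes()) == list(range(1, 81))

    def test_fusion_hazard_scales_with_chromosomes(self, rng):
        # only fusions possible: expected count ~ r_fus * C * t while C > 1
        p = ModelParams(model="M1", ch_root=10, r_fus=0.3)
        g = make_root_genome(40, 10, rng)
        reps = 4000
        counts = np.array(
            [len(simulate_branch(g, 0.1, p, rng)[1]) for _ in range(reps)]
        )
        mean = 0.3 * 10 * 0.1  # C ~ constant over the short branch
        assert abs(counts.mean() - mean) <= 4 * np.sqrt(mean / reps) + 0.01

    def test_no_null_events(self, rng):
        p = ModelParams(
            model="M1", r_inv=0.3, r_trans=0.3, ch_root=3, r_fus=0.3, r_fis=0.02
        )
        g = make_root_genome(40, 3, rng)
        # single-event branches must change the canonical genome
        for _ in range(200):
            out, ev = simulate_branch(g, 0.02, p, rng)
            if len(ev) == 1:
                assert out.canonical() != g.canonical()


class TestTreeSimulation:
    def test_zero_rates_all_leaves_equal_root(self, rng):
        tree = random_tree(6, 1.0, rng)
        gs, log = simulate_tree(tree, ModelParams(), 30, rng)
        root = Genome((tuple(range(1, 31)),))
        assert all(g == root for g in gs.genomes.values()) and log == []

    def test_determinism(self):
        tree = random_tree(5, 0.5, np.random.default_rng(3))
        p = ModelParams(r_inv=0.4, r_trans=0.2)
        a, _ = simulate_tree(tree, p, 50, np.random.default_rng(42))
        b, _ = simulate_tree(tree, p, 50, np.random.default_rng(42))
        assert a.genomes == b.genomes

    def test_rate_time_confounding(self, rng):
        # scaling rates by c and branch lengths by 1/c leaves the
        # leaf-genome distribution unchanged; compare UB-count moments
        from rearrabc import m0_summary

        tree = random_tree(4, 0.4, rng)
        half = tree.scale_branch_lengths(0.5)
        p1 = ModelParams(r_inv=0.4, r_trans=0.2)
        p2 = ModelParams(r_inv=0.8, r_trans=0.4)
        tot1, tot2 = [], []
        for _ in range(150):
            gs1, _ = simulate_tree(tree, p1, 100, rng)
            gs2, _ = simulate_tree(half, p2, 100, rng)
            tot1.append(m0_summary(gs1)[:11].sum())
            tot2.append(m0_summary(gs2)[:11].sum())
        m1, m2 = np.mean(tot1), np.mean(tot2)
        se = np.sqrt(np.var(tot1) / 150 + np.var(tot2) / 150)
        assert abs(m1 - m2) <= 4 * se + 1e-9
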
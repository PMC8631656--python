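"""K81 distances, distance profiles, shared blocks and the permutation test."""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transloscan.genome_io import AnnotatedGenome
from transloscan.haplotype_sharing import (
    focal_window_distances,
    gene_profile,
    k81_distance,
    mannwhitney,
    random_window_null,
    shared_block,
    window_significance,
)
from transloscan.synthetic_data import (
    evolve_k81,
    plant_shared_block,
    simulate_reference,
    SimulationConfig,
    build_ortholog_map,
)

BASES = "ACGT"
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
TV1 = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
TV2 = {("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")}


def k81_oracle(a: str, b: str) -> float:
    """Brute-force site classification + closed form, written independently
    of the vectorized implementation."""
    pairs = [(x, y) for x, y in zip(a, b) if x in BASES and y in BASES]
    n = len(pairs)
    P = sum((x, y) in TRANSITIONS for x, y in pairs) / n
    Q = sum((x, y) in TV1 for x, y in pairs) / n
    R = sum((x, y) in TV2 for x, y in pairs) / n
    return -0.25 * (
        math.log(1 - 2 * P - 2 * Q)
        + math.log(1 - 2 * P - 2 * R)
        + math.log(1 - 2 * Q - 2 * R)
    )


def mw_exact_oracle(x, y) -> float:
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = list(x) + list(y)
    n = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(sum(1 for a in grp for b in rest if a > b))
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(1.0, p)


class TestK81Distance:
    def test_identical_sequences_zero(self):
        assert k81_distance("ACGTACGT", "ACGTACGT").distance == 0.0

    def test_counting_example(self):
        """100 bp with exactly 2 transitions, 1 A<->T, 1 A<->C transversion."""
        a = list("ACGT" * 25)
        b = a.copy()
        b[0] = "G"   # A->G transition
        b[5] = "T"   # C->T transition
        b[8] = "T"   # A->T tv1
        b[12] = "C"  # A->C tv2
        res = k81_distance("".join(a), "".join(b))
        assert (res.p_transition, res.q_transversion, res.r_transversion) == (
            0.02, 0.01, 0.01
        )
        assert res.mismatches == 4
        assert res.distance == pytest.approx(k81_oracle("".join(a), "".join(b)), abs=1e-15)

    def test_equal_class_limit_equals_jc69(self):
        """With P=Q=R=p/3 the K81 distance collapses to the JC69 closed form
        −(3/4)ln(1−4p/3); checked at p = 0.06."""
        n = 1200
        per = int(n * 0.02)  # 2% per class
        a = list("ACGT" * (n // 4))
        b = a.copy()
        # disjoint site ranges per class, substituting the partner base
        for i in range(per):
            b[i] = {"A": "G", "C": "T", "G": "A", "T": "C"}[a[i]]
        for i in range(per, 2 * per):
            b[i] = {"A": "T", "C": "G", "G": "C", "T": "A"}[a[i]]
        for i in range(2 * per, 3 * per):
            b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[a[i]]
        res = k81_distance("".join(a), "".join(b))
        p = 0.06
        jc69 = -0.75 * math.log(1 - 4 * p / 3)
        assert res.distance == pytest.approx(jc69, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_pairs(self, rng):
        for _ in range(250):
            n = int(rng.integers(60, 400))
            a = "".join(np.array(list(BASES))[rng.integers(0, 4, n)])
            b = list(a)
            for i in np.flatnonzero(rng.random(n) < 0.08):
                b[i] = BASES[(BASES.index(b[i]) + int(rng.integers(1, 4))) % 4]
            b = "".join(b)
            res = k81_distance(a, b)
            if not res.saturated:
                assert res.distance == pytest.approx(k81_oracle(a, b), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        a = "".join(np.array(list(BASES))[rng.integers(0, 4, n)])
        b = "".join(np.array(list(BASES))[rng.integers(0, 4, n)])
        ra, rb = k81_distance(a, b), k81_distance(b, a)
        assert ra.saturated == rb.saturated
        if not ra.saturated:
            assert ra.distance == pytest.approx(rb.distance, abs=1e-15)

    def test_matches_ape_reference_implementation(self, tmp_path, rng):
        """Cross-check against the independent K81 implementation in the R
        ape package (dist.dna, model 'K81')."""
        a = "".join(np.array(list(BASES))[rng.integers(0, 4, 1500)])
        g = AnnotatedGenome("x", {"c": a}, [])
        b = evolve_k81(g, 0.07, fractions=(0.5, 0.3, 0.2), seed=77).chromosomes["c"]
        fa = tmp_path / "pair.fasta"
        fa.write_text(f">a\n{a}\n>b\n{b}\n")
        out = subprocess.run(
            ["Rscript", "-e",
             f'library(ape); d <- read.dna("{fa}", format="fasta"); '
             'cat(sprintf("%.12f", dist.dna(d, model="K81")))'],
            capture_output=True, text=True, check=True,
        )
        assert k81_distance(a, b).distance == pytest.approx(
            float(out.stdout.strip()), abs=1e-9
        )

    def test_n_sites_excluded(self):
        res = k81_distance("ANGT", "AAGT")
        assert res.n_sites == 3 and res.mismatches == 0

    def test_all_n_raises(self):
        with pytest.raises(ValueError):
            k81_distance("NNN", "NNN")

    def test_saturation_flagged(self):
        # complementary sequences: every site an A<->T or G<->C change
        assert k81_distance("ATAT" * 10, "TATA" * 10).saturated


@pytest.fixture(scope="module")
def diverged_pair():
    cfg = SimulationConfig(
        seed=42, n_chromosomes=1, genes_per_chromosome=60, gene_length=600,
        intergenic_length=600, focal_chromosome="chr1", focal_index=30,
    )
    ref, _ = simulate_reference(cfg)
    a = evolve_k81(ref, 0.025, seed=1, strain_id="A")
    b = evolve_k81(ref, 0.025, seed=2, strain_id="B")
    omap = build_ortholog_map([a, b])
    return a, b, omap, cfg.focal_ortholog


class TestGeneProfile:
    def test_identical_strains_all_zero(self, small_reference):
        genome, _, focal = small_reference
        a = genome.relabel_strain("A")
        b = genome.relabel_strain("B")
        omap = build_ortholog_map([a, b])
        profile = gene_profile(a, b, omap, focal, flank=5)
        assert len(profile.records) == 11
        assert all(r.distance == 0 and r.mismatches == 0 for r in profile.records)

    def test_planted_block_zero_others_positive(self, diverged_pair):
        a, b, omap, focal = diverged_pair
        b2, _ = plant_shared_block(a, b, focal, left=0, right=10)
        profile = gene_profile(a, b2, omap, focal, flank=15)
        for r in profile.records:
            if 0 <= r.rank <= 10:
                assert r.mismatches == 0
            elif r.rank < 0:
                assert r.mismatches > 0

    def test_profile_contains_focal_at_rank_zero(self, diverged_pair):
        a, b, omap, focal = diverged_pair
        rec = gene_profile(a, b, omap, focal, flank=3).record_at(0)
        assert rec is not None and rec.ortholog_id == focal


class TestSharedBlock:
    def test_planted_extents_recovered_exactly(self, diverged_pair):
        a, b, omap, focal = diverged_pair
        b2, _ = plant_shared_block(a, b, focal, left=12, right=7)
        blk = shared_block(gene_profile(a, b2, omap, focal, flank=20))
        assert (blk.left, blk.right) == (12, 7)
        assert blk.span_kb > 0

    def test_no_identical_neighbors(self, diverged_pair):
        a, b, omap, focal = diverged_pair
        b2, _ = plant_shared_block(a, b, focal, left=0, right=0)
        blk = shared_block(gene_profile(a, b2, omap, focal, flank=10))
        assert (blk.left, blk.right) == (0, 0)

    def test_focal_not_identical_gives_empty_block(self, diverged_pair):
        a, b, omap, focal = diverged_pair
        blk = shared_block(gene_profile(a, b, omap, focal, flank=5))
        assert (blk.left, blk.right) == (0, 0) and blk.span_kb == 0.0

    def test_missing_ortholog_terminates_walk(self, diverged_pair):
        a, b, omap, focal = diverged_pair
        b2, _ = plant_shared_block(a, b, focal, left=6, right=6)
        # drop the ortholog 3 genes right of focal from strain B
        focal_gene = a.find_ortholog(focal)
        on = a.genes_on(focal_gene.chromosome)
        gap_og = on[on.index(focal_gene) + 3].ortholog_id
        genes = [g for g in b2.genes if g.ortholog_id != gap_og]
        b3 = AnnotatedGenome("B", dict(b2.chromosomes), genes)
        blk = shared_block(gene_profile(a, b3, omap, focal, flank=10))
        assert (blk.left, blk.right) == (6, 2)


class TestRandomWindowNull:
    def test_contract_and_determinism(self, diverged_pair):
        a, b, omap, focal = diverged_pair
        s1 = random_window_null(a, b, omap, window_size=10, n_windows=50, seed=7)
        s2 = random_window_null(a, b, omap, window_size=10, n_windows=50, seed=7)
        assert s1.n_windows == 50 and s1.window_size == 10
        assert len(s1.window_means) == 50
        assert np.array_equal(s1.distances, s2.distances)

    def test_exclusion_respected(self, diverged_pair):
        a, b, omap, focal = diverged_pair
        b2, _ = plant_shared_block(a, b, focal, left=5, right=5)
        blk = shared_block(gene_profile(a, b2, omap, focal, flank=10))
        null = random_window_null(
            a, b2, omap, window_size=10, n_windows=300, seed=1,
            exclusion=(blk.chromosome, *blk.interval),
        )
        # planted-identical genes can never enter a window: no zero distances
        assert np.all(null.distances > 0)

    def test_no_valid_windows_raises(self, diverged_pair):
        a, b, omap, focal = diverged_pair
        with pytest.raises(ValueError):
            random_window_null(a, b, omap, window_size=1000, n_windows=5, seed=0)


class TestMannWhitney:
    @pytest.mark.parametrize("n,m", [(3, 3), (4, 6), (5, 5), (8, 7)])
    def test_matches_exact_enumeration(self, rng, n, m):
        for _ in range(12):
            x = rng.normal(size=n)
            y = rng.normal(size=m)
            u, p, method = mannwhitney(x, y)
            assert method == "exact"
            assert p == pytest.approx(mw_exact_oracle(x, y), abs=1e-12)

    def test_identical_constant_samples(self):
        _, p, _ = mannwhitney([1.0, 1.0], [1.0, 1.0, 1.0])
        assert p == 1.0

    def test_large_samples_use_asymptotic(self, rng):
        _, _, method = mannwhitney(rng.normal(size=30), rng.normal(size=40))
        assert method == "asymptotic"


class TestWindowSignificance:
    def test_identical_block_vs_diverged_null(self, diverged_pair):
        a, b, omap, focal = diverged_pair
        b2, _ = plant_shared_block(a, b, focal, left=5, right=4)
        blk = shared_block(gene_profile(a, b2, omap, focal, flank=10))
        null = random_window_null(
            a, b2, omap, window_size=10, n_windows=200, seed=5,
            exclusion=(blk.chromosome, *blk.interval),
        )
        focal_d = focal_window_distances(a, b2, omap, focal, window_size=10)
        res = window_significance(focal_d, null)
        assert res.p_value < 0.05
        assert res.empirical_p < 0.05
        assert res.focal_mean == 0.0

    def test_type_i_error_calibration(self, rng):
        """Focal and null drawn from the same distribution: rejection rate
        at alpha = 0.05 stays within 0.05 +/- 0.02 (checked at moderate n)."""
        reject = 0
        n_sim = 400
        for _ in range(n_sim):
            focal = rng.lognormal(mean=-3, sigma=0.4, size=20)
            null = rng.lognormal(mean=-3, sigma=0.4, size=1000)
            res = window_significance(focal, null)
            reject += res.p_value < 0.05
        assert 0.03 <= reject / n_sim <= 0.07

    def test_monotone_in_background_divergence(self):
        """A fixed identical focal block never becomes meaningfully less
        significant as background divergence grows from 0.01 to 0.10.

        With a fully identical focal window the U statistic sits at its
        floor for every divergence level, so the p-value can only wiggle
        through the tie-correction term (null windows resample the same
        genes); the comparison therefore allows a small multiplicative
        jitter band around strict monotonicity.
        """
        cfg = SimulationConfig(
            seed=9, n_chromosomes=1, genes_per_chromosome=60, gene_length=500,
            intergenic_length=400, motif_distance=300,
            focal_chromosome="chr1", focal_index=30,
        )
        ref, _ = simulate_reference(cfg)
        focal = cfg.focal_ortholog
        prev_p = None
        for d in (0.01, 0.03, 0.06, 0.10):
            a = evolve_k81(ref, d / 2, seed=11, strain_id="A")
            b = evolve_k81(ref, d / 2, seed=12, strain_id="B")
            omap = build_ortholog_map([a, b])
            b, _ = plant_shared_block(a, b, focal, left=5, right=4)
            blk = shared_block(gene_profile(a, b, omap, focal, flank=10))
            null = random_window_null(
                a, b, omap, 10, 200, seed=13,
                exclusion=(blk.chromosome, *blk.interval),
            )
            focal_d = focal_window_distances(a, b, omap, focal, window_size=10)
            p = window_significance(focal_d, null).p_value
            if prev_p is not None:
                assert p <= prev_p * 1.1  # tie-correction jitter only
            prev_p = p

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            window_significance([], np.array([1.0]))
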
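import numpy as np
import pytest

from ncoscan import pedio
from ncoscan.simulate import (
    SimParams,
    inject_genotype_errors,
    simulate_founders,
    simulate_markers,
    simulate_meiosis,
    simulate_pedigrees,
)


def _flat_params(**kw):
    base = dict(
        n_pedigrees=1,
        chrom_lengths={"chr01": 5_000_000},
        marker_spacing_bp=3000,
    )
    base.update(kw)
    return SimParams(**base)


class TestFounders:
    def test_heterozygosity_matches_frequency_law(self):
        rng = np.random.default_rng(1)
        params = _flat_params(maf_range=(0.5, 0.5),
                              chrom_lengths={"chr01": 30_000_000})
        markers = simulate_markers(params, rng)
        haps = simulate_founders(markers, 1, rng)[0]
        het = (haps[0] != haps[1]).mean()
        n = len(markers)
        se = np.sqrt(0.25 / n)
        assert abs(het - 0.5) < 3 * se

    def test_fixed_frequency_zero_gives_monomorphic(self):
        rng = np.random.default_rng(2)
        markers = simulate_markers(_flat_params(maf_range=(0.0, 0.0)), rng)
        haps = simulate_founders(markers, 3, rng)
        assert (haps == 0).all()

    def test_marker_class_mix(self):
        rng = np.random.default_rng(3)
        params = _flat_params(frac_at_gc=0.99,
                              chrom_lengths={"chr01": 30_000_000})
        markers = simulate_markers(params, rng)
        frac = (markers.snp_class == "AT_GC").mean()
        assert frac > 0.97
        assert (np.diff(markers.pos) > 0).all()


class TestMeiosis:
    def test_no_recombination_returns_parental_haplotype(self):
        rng = np.random.default_rng(4)
        params = _flat_params(rate_cm_per_mb=0.0, nco_rate=0.0)
        markers = simulate_markers(params, rng)
        haps = simulate_founders(markers, 1, rng)[0]
        gam, cos, tracts = simulate_meiosis(haps, markers, params, rng)
        assert not cos and not tracts
        assert (gam == haps[0]).all() or (gam == haps[1]).all()

    def test_crossover_count_is_poisson_with_map_mean(self):
        rng = np.random.default_rng(5)
        params = _flat_params(
            chrom_lengths={"chr01": 50_000_000}, rate_cm_per_mb=2.0,
            nco_rate=0.0,
        )
        markers = simulate_markers(params, rng)
        haps = simulate_founders(markers, 1, rng)[0]
        n = 800
        counts = [
            len(simulate_meiosis(haps, markers, params, rng)[1])
            for _ in range(n)
        ]
        expect = 2.0 * (50_000_000 - 1) / 1e6 / 100  # Morgans
        se = np.sqrt(expect / n)
        assert abs(np.mean(counts) - expect) < 3 * se

    def test_tract_initiation_intensity(self):
        # coverage R and mean length l imply R/l initiations per bp
        rng = np.random.default_rng(6)
        params = _flat_params(
            chrom_lengths={"chr01": 20_000_000}, nco_rate=5.9e-5,
            mean_tract_bp=75, rate_cm_per_mb=0.0,
        )
        markers = simulate_markers(params, rng)
        haps = simulate_founders(markers, 1, rng)[0]
        n = 300
        total = sum(
            len(simulate_meiosis(haps, markers, params, rng)[2])
            for _ in range(n)
        )
        expect = n * 20_000_000 * 5.9e-5 / 75
        se = np.sqrt(expect)
        assert abs(total - expect) < 3 * se

    def test_coverage_identity(self):
        # fraction of bp inside tracts approaches nco_rate
        rng = np.random.default_rng(7)
        L = 20_000_000
        params = _flat_params(chrom_lengths={"chr01": L}, nco_rate=1e-4,
                              mean_tract_bp=300, rate_cm_per_mb=0.0)
        markers = simulate_markers(params, rng)
        haps = simulate_founders(markers, 1, rng)[0]
        n = 200
        bp = 0
        n_tracts = 0
        for _ in range(n):
            _, _, tr = simulate_meiosis(haps, markers, params, rng)
            bp += sum(e - s + 1 for _, s, e, _, _, _ in tr)
            n_tracts += len(tr)
        cover = bp / (n * L)
        rel_se = 3 / np.sqrt(n_tracts)  # tract count dominates the variance
        assert abs(cover - 1e-4) < 3 * 1e-4 * rel_se

    def test_gc_identity_among_converted_sites(self):
        rng = np.random.default_rng(8)
        params = _flat_params(
            chrom_lengths={"chr01": 10_000_000}, nco_rate=5e-3,
            mean_tract_bp=300, gc_bias=0.68, rate_cm_per_mb=0.0,
            maf_range=(0.5, 0.5),
        )
        markers = simulate_markers(params, rng)
        at_gc = (markers.snp_class == "AT_GC").to_numpy()
        gc_is_a1 = markers.gc_is_a1.to_numpy()
        haps = simulate_founders(markers, 1, rng)[0]
        n_gc = n_tot = 0
        for _ in range(120):
            _, _, tracts = simulate_meiosis(haps, markers, params, rng)
            for _, _, _, conv, trans, _ in tracts:
                for m, a in zip(conv, trans):
                    if at_gc[m]:
                        n_tot += 1
                        n_gc += int((a == 1) == gc_is_a1[m])
        assert n_tot > 600
        se = np.sqrt(0.68 * 0.32 / n_tot)
        assert abs(n_gc / n_tot - 0.68) < 3 * se

    def test_converted_sites_lie_in_tract_and_differ_from_background(self):
        rng = np.random.default_rng(9)
        params = _flat_params(nco_rate=5e-4, mean_tract_bp=500,
                              rate_cm_per_mb=0.0)
        markers = simulate_markers(params, rng)
        pos = markers.pos.to_numpy()
        haps = simulate_founders(markers, 1, rng)[0]
        gam, cos, tracts = simulate_meiosis(haps, markers, params, rng)
        for chrom, s, e, conv, trans, _ in tracts:
            for m, a in zip(conv, trans):
                assert s <= pos[m] <= e
                assert haps[0, m] != haps[1, m]  # heterozygous by definition
                assert gam[m] == a

    def test_map_shorter_than_chromosome_fatal(self):
        rng = np.random.default_rng(10)
        params = _flat_params()
        markers = simulate_markers(params, rng)
        haps = simulate_founders(markers, 1, rng)[0]
        short = pedio.flat_map({"chr01": 1_000_000}, 1.0)
        with pytest.raises(ValueError, match="map shorter"):
            simulate_meiosis(haps, markers, params, rng, short)


class TestPedigrees:
    def test_mendelian_consistent_when_error_free(self, small_sim):
        _params, peds, gm, _truth = small_sim
        for ped in peds.pedigrees:
            df = gm.of(ped.father)
            dm = gm.of(ped.mother)
            lo = (df == 2).astype(int) + (dm == 2).astype(int)
            hi = 2 - ((df == 0).astype(int) + (dm == 0).astype(int))
            for c in ped.children:
                dc = gm.of(c)
                assert not ((dc < lo) | (dc > hi)).any()

    def test_determinism_under_fixed_seed(self, tmp_path):
        params = _flat_params(nco_rate=5e-5, error_rate=0.01,
                              missing_rate=0.01)
        out = []
        for _ in range(2):
            peds, gm, truth = simulate_pedigrees(params, 99)
            p = tmp_path / f"v{len(out)}.vcf"
            pedio.write_vcf(gm, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_no_grandchildren_means_no_analyzable_pedigree(self):
        params = _flat_params(grandchildren_per_analyzed_child=0)
        peds, gm, _ = simulate_pedigrees(params, 1)
        assert not peds.analyzable()


class TestErrors:
    def test_zero_rate_leaves_matrix_unchanged(self, small_sim):
        _params, _peds, gm, _ = small_sim
        out, log = inject_genotype_errors(gm, 0.0, np.random.default_rng(1))
        np.testing.assert_array_equal(out.dosage, gm.dosage)
        assert log.empty

    def test_rate_one_het_becomes_homozygous(self):
        markers = pedio.make_marker_table(
            ["c"] * 3, [10, 20, 30], list("abc"), ["A"] * 3, ["G"] * 3
        )
        gm = pedio.GenotypeMatrix(
            markers, np.ones((3, 1), dtype=np.int8), ["s"]
        )
        out, log = inject_genotype_errors(gm, 1.0, np.random.default_rng(2))
        assert set(np.unique(out.dosage)) <= {0, 2}
        assert len(log) == 3

    def test_error_count_binomial(self):
        rng = np.random.default_rng(3)
        markers = pedio.make_marker_table(
            ["c"] * 1000, np.arange(1, 1001) * 10, [f"m{i}" for i in range(1000)],
            ["A"] * 1000, ["G"] * 1000,
        )
        gm = pedio.GenotypeMatrix(
            markers, rng.integers(0, 3, (1000, 100)).astype(np.int8),
            [f"s{i}" for i in range(100)],
        )
        out, log = inject_genotype_errors(gm, 0.01, rng)
        expect = 1000.0
        assert abs(len(log) - expect) < 3 * np.sqrt(expect)
        # perturbations recorded faithfully
        for _, r in log.head(20).iterrows():
            assert out.dosage[r.marker, out.col(r["sample"])] == r.observed
            assert gm.dosage[r.marker, gm.col(r["sample"])] == r.original
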
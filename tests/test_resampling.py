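import numpy as np
import pandas as pd
import pytest

from mampscan import mixed_model as mm
from mampscan import phenotype_stats as ps
from mampscan import resampling as rs
from mampscan import synthetic_data as sd
from mampscan.datatypes import GeneAnnotation, PeakRegion
from mampscan.errors import ConfigError


def region(chrom, start, end, apex=None, trait="t", p=1e-6):
    apex = apex if apex is not None else (start + end) // 2
    return PeakRegion(
        trait=trait, chrom=chrom, start=start, end=end,
        apex_snp="x", apex_pos=apex, apex_p=p, members=["x"],
    )


class TestAprioriFrequency:
    def test_table_arithmetic(self):
        genes = {f"g{i}" for i in range(922)}
        apriori = {f"g{i}" for i in range(5)} | {"other1", "other2"}
        n_found, n_genes, freq = rs.apriori_frequency(genes, apriori)
        assert (n_found, n_genes) == (5, 922)
        assert round(freq, 4) == 0.0054

    def test_zero_overlap(self):
        assert rs.apriori_frequency({"a", "b"}, {"c"}) == (0, 2, 0.0)

    def test_empty_gene_set(self):
        assert rs.apriori_frequency(set(), {"c"}) == (0, 0, 0.0)


class TestCircularShift:
    LENGTHS = {"1": 100}

    def covered(self, intervals):
        out = set()
        for chrom, parts in intervals:
            for s, e in parts:
                out |= set(range(s, e + 1))
        return out

    def rotate(self, positions, d, L=100):
        return {(p - 1 + d) % L + 1 for p in positions}

    def test_zero_offset_identity(self):
        peaks = [region("1", 10, 30), region("1", 50, 70)]
        rng = np.random.default_rng(0)
        shifted = rs.circular_shift_peaks(peaks, self.LENGTHS, rng, offsets={"1": 0})
        assert shifted == [("1", [(10, 30)]), ("1", [(50, 70)])]

    def test_full_length_offset_identity(self):
        peaks = [region("1", 10, 30)]
        shifted = rs.circular_shift_peaks(
            peaks, self.LENGTHS, np.random.default_rng(0), offsets={"1": 100}
        )
        assert shifted == [("1", [(10, 30)])]

    def test_wrap_matches_positionwise_rotation(self):
        # exhaustive oracle on a 100 bp toy chromosome
        for start, end in [(90, 99), (80, 100), (1, 10), (40, 60)]:
            for d in range(0, 100, 7):
                peaks = [region("1", start, end)]
                shifted = rs.circular_shift_peaks(
                    peaks, self.LENGTHS, np.random.default_rng(0), offsets={"1": d}
                )
                expected = self.rotate(set(range(start, end + 1)), d)
                assert self.covered(shifted) == expected, (start, end, d)

    def test_count_and_covered_length_preserved(self):
        rng = np.random.default_rng(1)
        peaks = [region("1", s, min(s + 14, 100)) for s in (3, 30, 55, 81)]
        for _ in range(20):
            shifted = rs.circular_shift_peaks(peaks, self.LENGTHS, rng)
            assert len(shifted) == len(peaks)
            total = sum(e - s + 1 for _, parts in shifted for s, e in parts)
            assert total == sum(p.end - p.start + 1 for p in peaks)

    def test_pairwise_spacing_preserved_mod_length(self):
        rng = np.random.default_rng(2)
        peaks = [region("1", 10, 20, apex=15), region("1", 40, 50, apex=45),
                 region("1", 70, 80, apex=75)]
        starts0 = [10, 40, 70]
        gaps0 = sorted((b - a) % 100 for a in starts0 for b in starts0 if a != b)
        for _ in range(10):
            d = int(rng.integers(0, 100))
            shifted = rs.circular_shift_peaks(
                peaks, self.LENGTHS, rng, offsets={"1": d}
            )
            starts = [(10 - 1 + d) % 100 + 1, (40 - 1 + d) % 100 + 1, (70 - 1 + d) % 100 + 1]
            gaps = sorted((b - a) % 100 for a in starts for b in starts if a != b)
            assert gaps == gaps0
            assert len(shifted) == 3


@pytest.fixture(scope="module")
def tiled_annotation():
    ids = [f"g{i:03d}" for i in range(60)]
    starts = np.arange(60) * 15_000 + 1
    return GeneAnnotation.create(
        ids, ["1"] * 30 + ["2"] * 30,
        np.concatenate([starts[:30], starts[:30]]),
        np.concatenate([starts[:30] + 2999, starts[:30] + 2999]),
    )


class TestEnrichment:
    LENGTHS = {"1": 460_000, "2": 460_000}

    def test_zero_observed_frequency_p_one(self, tiled_annotation):
        peaks = [region("1", 100_000, 130_000)]
        apriori = {"no_such_gene"}
        res = rs.enrichment_test(
            peaks, tiled_annotation, apriori, n_perm=20,
            rng=np.random.default_rng(0), chrom_lengths=self.LENGTHS,
        )
        assert res.frequency == 0.0
        assert res.empirical_p == 1.0

    def test_apriori_everything_p_one(self, tiled_annotation):
        peaks = [region("1", 100_000, 130_000)]
        apriori = set(tiled_annotation.gene_id)
        res = rs.enrichment_test(
            peaks, tiled_annotation, apriori, n_perm=20,
            rng=np.random.default_rng(0), chrom_lengths=self.LENGTHS,
        )
        assert res.frequency == 1.0
        assert res.empirical_p == 1.0
        assert (res.permuted == 1.0).all()

    def test_gene_relabeling_invariance(self, tiled_annotation):
        peaks = [region("1", 50_000, 80_000), region("2", 200_000, 230_000)]
        apriori = {"g003", "g012", "g040"}
        res1 = rs.enrichment_test(
            peaks, tiled_annotation, apriori, n_perm=50,
            rng=np.random.default_rng(7), chrom_lengths=self.LENGTHS,
        )
        relabel = {g: f"x_{g}" for g in tiled_annotation.gene_id}
        ann2 = GeneAnnotation.create(
            [relabel[g] for g in tiled_annotation.gene_id],
            tiled_annotation.chrom, tiled_annotation.start,
            tiled_annotation.end, tiled_annotation.strand,
        )
        res2 = rs.enrichment_test(
            peaks, ann2, {relabel[g] for g in apriori}, n_perm=50,
            rng=np.random.default_rng(7), chrom_lengths=self.LENGTHS,
        )
        assert res1.frequency == res2.frequency
        assert res1.empirical_p == res2.empirical_p
        assert np.allclose(res1.permuted, res2.permuted)

    def test_add_one_variant(self, tiled_annotation):
        peaks = [region("1", 100_000, 130_000)]
        res = rs.enrichment_test(
            peaks, tiled_annotation, {"no_such_gene"}, n_perm=20,
            rng=np.random.default_rng(0), chrom_lengths=self.LENGTHS, add_one=True,
        )
        assert res.empirical_p == pytest.approx(21 / 21)

    def test_nperm_zero_rejected(self, tiled_annotation):
        with pytest.raises(ConfigError):
            rs.enrichment_test([], tiled_annotation, set(), n_perm=0)


class TestSharedPeaks:
    def test_identical_lists(self):
        peaks = [region("1", 1, 30_000, apex=15_000), region("1", 200_000, 230_000, apex=215_000)]
        assert rs.count_shared_peaks(peaks, peaks) == 2

    def test_disjoint_chromosomes(self):
        a = [region("1", 1, 30_000, apex=15_000)]
        b = [region("2", 1, 30_000, apex=15_000)]
        assert rs.count_shared_peaks(a, b) == 0

    def test_apex_distance_29kb_shared_31kb_not(self):
        a = [region("1", 0, 0, apex=100_000)]
        shared = [region("1", 0, 0, apex=129_000)]
        unshared = [region("1", 0, 0, apex=131_000)]
        assert rs.count_shared_peaks(a, shared) == 1
        assert rs.count_shared_peaks(a, unshared) == 0

    def test_count_bounded_by_smaller_list(self):
        a = [region("1", 0, 0, apex=x) for x in (100_000, 110_000, 120_000)]
        b = [region("1", 0, 0, apex=105_000)]
        assert rs.count_shared_peaks(a, b) == 1
        assert rs.count_shared_peaks(b, a) == 1

    def test_symmetry_on_random_peak_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = [
                region(str(rng.choice(["1", "2"])), 0, 0, apex=int(rng.integers(1, 500_000)))
                for _ in range(rng.integers(1, 12))
            ]
            b = [
                region(str(rng.choice(["1", "2"])), 0, 0, apex=int(rng.integers(1, 500_000)))
                for _ in range(rng.integers(1, 12))
            ]
            assert rs.count_shared_peaks(a, b) == rs.count_shared_peaks(b, a)


class TestOverlapNull:
    def test_output_contract_on_small_study(self, small_study):
        sgi = ps.genotype_mean_sgi(small_study.phenotypes)
        k = mm.compute_kinship(small_study.genotypes)
        res = rs.overlap_null_test(
            sgi, small_study.genotypes, k, ("elf18_DC", "elf18_Ps"),
            n_perm=5, rng=np.random.default_rng(1),
            chrom_lengths={c: int(v) for c, v in
                           small_study.config.chromosome_lengths.items()},
        )
        assert len(res.permuted) == 5
        assert 0.0 <= res.empirical_p <= 1.0
        assert res.bonferroni_alpha == pytest.approx(0.05 / 21)
        assert res.observed >= 0


class TestWilcoxonValidation:
    def frame(self, groups):
        rows = []
        for gene, mamp, arm, values in groups:
            rows += [{"gene_id": gene, "mamp_id": mamp, "arm": arm, "sgi": v} for v in values]
        return pd.DataFrame(rows)

    def test_identical_arms_not_confirmed(self):
        vals = [30.0, 35.0, 40.0, 45.0]
        res = rs.wilcoxon_validation(
            self.frame([("g1", "elf18_DC", "mutant", vals), ("g1", "elf18_DC", "wildtype", vals)])
        )
        assert res[0].p == 1.0
        assert not res[0].confirmed

    def test_all_tied_values_p_one(self):
        res = rs.wilcoxon_validation(
            self.frame([
                ("g1", "flg22_Pa", "mutant", [40.0] * 5),
                ("g1", "flg22_Pa", "wildtype", [40.0] * 5),
            ])
        )
        assert res[0].p == 1.0

    def test_large_shift_confirmed_with_direction(self):
        rng = np.random.default_rng(4)
        wt = rng.normal(40, 5, 12)
        mut = rng.normal(70, 5, 12)
        res = rs.wilcoxon_validation(
            self.frame([
                ("g1", "elf18_DC", "mutant", mut),
                ("g1", "elf18_DC", "wildtype", wt),
                ("g2", "elf18_DC", "mutant", rng.normal(40, 5, 12)),
                ("g2", "elf18_DC", "wildtype", rng.normal(40, 5, 12)),
            ])
        )
        by_gene = {r.gene: r for r in res}
        assert by_gene["g1"].confirmed and by_gene["g1"].direction == "+"
        assert by_gene["g1"].q <= 0.05

    def test_bh_q_monotone_in_sorted_p(self):
        rng = np.random.default_rng(5)
        groups = []
        for i in range(8):
            shift = 5.0 * i
            groups.append((f"g{i}", "elf18_DC", "mutant", rng.normal(40 + shift, 5, 10)))
            groups.append((f"g{i}", "elf18_DC", "wildtype", rng.normal(40, 5, 10)))
        res = rs.wilcoxon_validation(self.frame(groups))
        df = pd.DataFrame([(r.p, r.q) for r in res], columns=["p", "q"]).sort_values("p")
        assert (df["q"].diff().dropna() >= -1e-12).all()
        assert (df["q"] >= df["p"] - 1e-12).all()

    def test_small_arm_rejected(self):
        with pytest.raises(Exception, match="n >= 3"):
            rs.wilcoxon_validation(
                self.frame([
                    ("g1", "elf18_DC", "mutant", [1.0, 2.0]),
                    ("g1", "elf18_DC", "wildtype", [1.0, 2.0, 3.0]),
                ])
            )
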
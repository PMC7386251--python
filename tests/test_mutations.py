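"""Mutation-class rules and dependency-association statistics."""

import numpy as np
import pandas as pd
import pytest

from deepdep import mutations as mu


def var(sample="S1", gene="G1", cls="nonsense", zyg="heterozygous", vaf=0.3,
        pos=None, sub=None):
    return mu.VariantRecord(sample, gene, cls, zyg, vaf, position=pos, substitution=sub)


class TestClassifyLof:
    def test_het_low_vaf(self):
        assert mu.classify_lof(var(vaf=0.30)) == "hetLOF"

    def test_homozygous_high_vaf(self):
        assert mu.classify_lof(var(cls="frameshift_indel", zyg="homozygous", vaf=0.95)) == "homoLOF"

    def test_het_gap_unclassified(self):
        assert mu.classify_lof(var(vaf=0.45)) == "none"

    def test_het_above_half_is_homolof(self):
        assert mu.classify_lof(var(vaf=0.60)) == "homoLOF"

    def test_missense_rejected(self):
        with pytest.raises(ValueError, match="inactivating"):
            mu.classify_lof(var(cls="missense", pos=1, sub="p.A1V"))

    def test_exhaustive_vaf_grid_partitions(self):
        """hetLOF and homoLOF never overlap on any (VAF, zygosity) combination."""
        for zyg in ("heterozygous", "homozygous"):
            for vaf in np.round(np.arange(0, 1.001, 0.01), 2):
                got = mu.classify_lof(var(zyg=zyg, vaf=float(vaf)))
                if zyg == "homozygous":
                    assert got == "homoLOF"
                elif vaf < 0.40:
                    assert got == "hetLOF"
                elif vaf > 0.50:
                    assert got == "homoLOF"
                else:
                    assert got == "none"


class TestFindGof:
    def test_shared_substitution_two_samples(self):
        cohort = [
            var(sample="S1", cls="missense", pos=12, sub="p.G12D"),
            var(sample="S2", cls="missense", pos=12, sub="p.G12D"),
        ]
        assert mu.find_gof(cohort) == {"G1": {(12, "p.G12D")}}

    def test_same_position_different_substitution(self):
        cohort = [
            var(sample="S1", cls="missense", pos=12, sub="p.G12D"),
            var(sample="S2", cls="missense", pos=12, sub="p.G12V"),
        ]
        assert mu.find_gof(cohort) == {}

    def test_single_carrier_not_gof(self):
        cohort = [var(sample="S1", cls="missense", pos=12, sub="p.G12D")]
        assert mu.find_gof(cohort) == {}

    def test_duplicate_rows_one_sample_not_counted_twice(self):
        cohort = [var(sample="S1", cls="missense", pos=12, sub="p.G12D")] * 3
        assert mu.find_gof(cohort) == {}


class TestPutativeTsg:
    def test_five_samples_included(self):
        cohort = [var(sample=f"S{i}") for i in range(5)]
        assert mu.putative_tsg(cohort) == {"G1"}

    def test_four_samples_excluded(self):
        cohort = [var(sample=f"S{i}") for i in range(4)]
        assert mu.putative_tsg(cohort) == set()

    def test_counts_distinct_samples_not_variants(self):
        cohort = [var(sample="S1", vaf=v) for v in (0.1, 0.2, 0.3, 0.35, 0.05)]
        assert mu.putative_tsg(cohort) == set()

    def test_known_list_unioned(self):
        assert mu.putative_tsg([], known_tsgs=["TP53"]) == {"TP53"}


class TestSilentOnlyOncogenes:
    def test_silent_only_included(self):
        cohort = [var(cls="silent", vaf=0.2) for _ in range(3)]
        assert mu.silent_only_oncogenes(cohort, ["G1"]) == {"G1"}

    def test_any_missense_excluded(self):
        cohort = [var(cls="silent"), var(cls="missense", pos=1, sub="p.A1V")]
        assert mu.silent_only_oncogenes(cohort, ["G1"]) == set()

    def test_no_variants_excluded(self):
        assert mu.silent_only_oncogenes([], ["G1"]) == set()


class TestCopyNumber:
    @pytest.mark.parametrize(
        "code,expected",
        [
            (-2, "homozygous_deletion"),
            (-1, "heterozygous_deletion"),
            (0, "normal"),
            (1, "low_amplification"),
            (2, "high_amplification"),
        ],
    )
    def test_mapping(self, code, expected):
        assert mu.map_copy_number(code) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            mu.map_copy_number(3)


class TestClassifyCohort:
    def test_homolof_dominates(self):
        cohort = [
            var(vaf=0.3),  # hetLOF
            var(zyg="homozygous", vaf=0.9),  # homoLOF, same (sample, gene)
        ]
        classes = mu.classify_cohort(cohort)
        assert classes.loc[0, "mutation_class"] == "homoLOF"

    def test_gof_assigned(self):
        cohort = [
            var(sample="S1", gene="KRAS", cls="missense", pos=12, sub="p.G12D"),
            var(sample="S2", gene="KRAS", cls="missense", pos=12, sub="p.G12D"),
        ]
        classes = mu.classify_cohort(cohort)
        assert set(classes["mutation_class"]) == {"GOF"}


def ks_oracle(a, b):
    """Brute-force max distance between empirical CDFs."""
    points = np.concatenate([a, b])
    return max(
        abs((a <= x).mean() - (b <= x).mean()) for x in points
    )


class TestCompareMutantWildtype:
    def _frames(self, mutant_shift, n=50, seed=0):
        rng = np.random.default_rng(seed)
        rows, classes = [], []
        for i in range(n):
            rows.append((f"D{i}", "G1", rng.normal(mutant_shift, 0.1)))
            classes.append((f"D{i}", "G1", "hetLOF"))
        for i in range(n):
            rows.append((f"E{i}", "G1", rng.normal(0.0, 0.1)))
        diff = pd.DataFrame(rows, columns=["donor", "gene", "diff"])
        cls = pd.DataFrame(classes, columns=["sample", "gene", "mutation_class"])
        return diff, cls

    def test_identical_groups_zero_statistics(self):
        diff, cls = self._frames(mutant_shift=0.0)
        # force identical values
        diff["diff"] = 0.25
        out = mu.compare_mutant_wildtype(diff, cls, "hetLOF")
        assert out["ks_statistic"] == 0.0

    def test_planted_shift_detected(self):
        diff, cls = self._frames(mutant_shift=0.3)
        out = mu.compare_mutant_wildtype(diff, cls, "hetLOF")
        assert out["t_statistic"] > 0
        assert out["t_p"] < 1e-6 and out["ks_p"] < 1e-6
        assert out["n_mutant"] == 50 and out["n_wildtype"] == 50

    def test_ks_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            a, b = rng.normal(size=10), rng.normal(0.5, 1, 10)
            diff = pd.DataFrame(
                [(f"D{i}", "G", v) for i, v in enumerate(a)]
                + [(f"E{i}", "G", v) for i, v in enumerate(b)],
                columns=["donor", "gene", "diff"],
            )
            cls = pd.DataFrame(
                [(f"D{i}", "G", "GOF") for i in range(10)],
                columns=["sample", "gene", "mutation_class"],
            )
            out = mu.compare_mutant_wildtype(diff, cls, "GOF")
            assert out["ks_statistic"] == pytest.approx(ks_oracle(a, b))

    def test_empty_group_rejected(self):
        diff, cls = self._frames(0.1)
        with pytest.raises(ValueError, match="homoLOF"):
            mu.compare_mutant_wildtype(diff, cls, "homoLOF")


class TestMafConversion:
    def test_standard_columns(self):
        maf = pd.DataFrame(
            {
                "Tumor_Sample_Barcode": ["S1"],
                "Hugo_Symbol": ["KRAS"],
                "Variant_Classification": ["Missense_Mutation"],
                "Protein_position": [12],
                "HGVSp_Short": ["p.G12D"],
                "t_alt_count": [30],
                "t_depth": [100],
                "zygosity": ["heterozygous"],
            }
        )
        (rec,) = mu.from_maf(maf)
        assert rec.variant_class == "missense"
        assert rec.vaf == pytest.approx(0.3)
        assert rec.substitution == "p.G12D"

    def test_roundtrip_through_frame(self):
        cohort = [var(vaf=0.3), var(cls="missense", pos=5, sub="p.K5N", vaf=0.2)]
        frame = mu.variants_to_frame(cohort)
        back = mu.frame_to_variants(frame)
        assert back == cohort
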
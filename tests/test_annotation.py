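"""Curation pipeline: .out parsing, the four editing operations, structural
classification, BED12 and counting."""

import numpy as np
import pytest

from tyland import annotation as ann
from tyland import simulate as sim


def hit(name="Ty1_I", start=1000, end=2000, group=1, div=5.0, strand="+", chrom="chrI"):
    return ann.RepeatHit(
        score=1000, pct_divergence=div, query_id=chrom, query_start=start,
        query_end=end, strand=strand, repeat_name=name, repeat_class="LTR/Copia",
        hit_group_id=group,
    )


class TestParseRmOut:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.out"
        p.write_text("")
        assert ann.parse_rm_out(p) == []

    def test_c_strand_maps_to_minus_and_roundtrip(self, tmp_path):
        hits = [hit(strand="-"), hit(name="Ty1_LTR", start=100, end=434, group=2)]
        p = tmp_path / "h.out"
        ann.write_rm_out(hits, p)
        parsed = ann.parse_rm_out(p)
        assert parsed == hits
        assert parsed[0].strand == "-"

    def test_synthetic_roundtrip_preserves_coordinates(self, tmp_path):
        truth = sim.plant_genome(
            sim.GenomeConfig(elements=[sim.ElementSpec(), sim.ElementSpec(structural_class="solo_ltr")]),
            seed=3,
        )
        p = tmp_path / "s.out"
        ann.write_rm_out(truth.raw_hits, p)
        assert ann.parse_rm_out(p) == truth.raw_hits

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.out"
        p.write_text("1000 5.0 0.0 0.0 chrI notanint 2000 (0) + Ty1_I LTR/Copia 1 1000 (0) 1\n")
        with pytest.raises(ValueError, match="line 1"):
            ann.parse_rm_out(p)


class TestFilterFalsePositives:
    def test_boundary_is_strict_greater_than(self):
        kept = ann.filter_false_positives([hit(div=20.0), hit(div=25.0), hit(div=20.1)])
        assert [h.pct_divergence for h in kept] == [20.0]

    def test_counting(self):
        rng = np.random.default_rng(1)
        divs = rng.uniform(0, 40, 50)
        hits = [hit(div=round(float(d), 1)) for d in divs]
        kept = ann.filter_false_positives(hits)
        assert len(kept) == sum(1 for h in hits if h.pct_divergence <= 20)


class TestRelabelLtrFragments:
    def test_mislabelled_ltr_renamed_to_internal_family(self):
        group = [
            hit("Ty1_LTR", 100, 434, group=1),
            hit("Ty1_I", 435, 5684, group=1),
            hit("Ty2_LTR", 5685, 6018, group=1),
        ]
        out = ann.relabel_ltr_fragments(group)
        assert [h.repeat_name for h in out] == ["Ty1_LTR", "Ty1_I", "Ty1_LTR"]

    def test_solo_group_unchanged(self):
        solo = [hit("Ty1_LTR", 100, 434, group=7)]
        assert ann.relabel_ltr_fragments(solo) == solo

    def test_conflicting_internals_flagged_unchanged(self):
        group = [
            hit("Ty1_I", 100, 2000, group=1),
            hit("Ty2_I", 2100, 4000, group=1),
            hit("Ty2_LTR", 4100, 4400, group=1),
        ]
        with pytest.warns(UserWarning, match="internal fragments"):
            out = ann.relabel_ltr_fragments(group)
        assert out == group

    def test_synthetic_mislabels_all_repaired(self, library):
        config = sim.GenomeConfig(
            elements=[sim.ElementSpec() for _ in range(4)],
            errors=sim.ErrorModeConfig(p_mislabel_ltr=1.0),
        )
        truth = sim.plant_genome(config, seed=8)
        assert any(h.repeat_name == "Ty2_LTR" for h in truth.raw_hits)  # errors planted
        out = ann.relabel_ltr_fragments(truth.raw_hits)
        assert all(h.family == "Ty1" for h in out)


class TestSplitTandemArrays:
    @staticmethod
    def tandem_group(n_copies, group=1):
        hits = [hit("Ty1_LTR", 100, 434, group=group)]
        pos = 435
        for _ in range(n_copies):
            hits.append(hit("Ty1_I", pos, pos + 5249, group=group))
            pos += 5250
            hits.append(hit("Ty1_LTR", pos, pos + 333, group=group))
            pos += 334
        return hits

    def test_two_copy_array_splits_sharing_middle_ltr(self):
        groups = ann.split_tandem_arrays(ann.group_hits(self.tandem_group(2)))
        assert len(groups) == 2
        shared = groups[0][-1]
        assert shared == groups[1][0]
        assert all(len(g) == 3 for g in groups)

    def test_single_copy_unchanged(self):
        g = self.tandem_group(1)
        assert ann.split_tandem_arrays(ann.group_hits(g)) == [g]

    def test_three_copy_synthetic_truth(self, library):
        config = sim.GenomeConfig(
            elements=[sim.ElementSpec(tandem_copies=3)],
            errors=sim.ErrorModeConfig(p_merge_tandem=1.0),
        )
        truth = sim.plant_genome(config, seed=9)
        els = ann.curate(truth.raw_hits, library, "s")
        counts = ann.count_by_family(els)
        assert counts.get("Ty1", "full_length") == 3


class TestSplitFusedSolos:
    def test_distal_ltr_becomes_solo(self):
        group = [
            hit("Ty1_LTR", 100, 434, group=1),
            hit("Ty1_I", 435, 5684, group=1),
            hit("Ty1_LTR", 5685, 6018, group=1),
            hit("Ty1_LTR", 6520, 6853, group=1),  # 500 bp downstream
        ]
        out = ann.split_fused_solos([group])
        assert len(out) == 2
        assert len(out[0]) == 3 and len(out[1]) == 1
        assert out[1][0].query_start == 6520

    def test_clean_element_unchanged(self):
        group = [
            hit("Ty1_LTR", 100, 434, group=1),
            hit("Ty1_I", 435, 5684, group=1),
            hit("Ty1_LTR", 5685, 6018, group=1),
        ]
        assert ann.split_fused_solos([group]) == [group]

    def test_synthetic_fused_solos_recovered(self, library):
        config = sim.GenomeConfig(
            elements=[sim.ElementSpec(with_fused_solo=True) for _ in range(3)],
            errors=sim.ErrorModeConfig(p_fuse_solo=1.0),
        )
        truth = sim.plant_genome(config, seed=10)
        els = ann.curate(truth.raw_hits, library, "s")
        counts = ann.count_by_family(els)
        assert counts.get("Ty1", "solo_ltr") == 3
        assert counts.get("Ty1", "full_length") == 3


class TestClassifyStructure:
    def test_95_percent_rule(self, library):
        # canonical Ty1 total 5918: 5700/5918 = 0.963 -> full; 5000 -> truncated
        full_group = [hit("Ty1_LTR", 1, 334), hit("Ty1_I", 335, 5700)]
        cls, fam = ann.classify_structure(full_group, library)
        assert (cls, fam) == ("full_length", "Ty1")
        trunc_group = [hit("Ty1_LTR", 1, 334), hit("Ty1_I", 335, 5000)]
        assert ann.classify_structure(trunc_group, library)[0] == "truncated"

    def test_solo_is_ltr_only(self, library):
        assert ann.classify_structure([hit("Ty1_LTR", 1, 334)], library)[0] == "solo_ltr"

    def test_boundary_changes_exactly_once(self, library):
        """Class as a function of total length flips once, at 0.95 x canonical."""
        canonical = library["Ty1"].canonical_total_length
        threshold = 0.95 * canonical
        prev = None
        flips = 0
        for total in range(int(threshold) - 3, int(threshold) + 4):
            group = [hit("Ty1_LTR", 1, 334), hit("Ty1_I", 335, total)]
            cls, _ = ann.classify_structure(group, library)
            if prev is not None and cls != prev:
                flips += 1
                assert total > threshold  # strictly greater -> full
            prev = cls
        assert flips == 1

    def test_unknown_family_raises(self, library):
        with pytest.raises(KeyError):
            ann.classify_structure([hit("Ty9_LTR", 1, 300)], library)


class TestBed12:
    def test_block_arithmetic(self, tmp_path):
        el = ann.TyElement(
            element_id="s_f1", structural_class="full_length", family="Ty1",
            strand="+", chrom="chrI", blocks=[(100, 438), (5500, 5838)],
        )
        p = tmp_path / "e.bed"
        ann.write_bed12([el], p)
        fields = p.read_text().strip().split("\t")
        assert fields[9] == "2"
        assert fields[10] == "338,338"
        assert fields[11] == "0,5400"

    def test_roundtrip_identity(self, tmp_path):
        el = ann.TyElement(
            element_id="s_t2", structural_class="truncated", family="Ty1",
            strand="-", chrom="chrII", blocks=[(10, 400), (900, 1500)],
        )
        p = tmp_path / "e.bed"
        ann.write_bed12([el], p)
        back = ann.read_bed12(p)[0]
        assert (back.element_id, back.chrom, back.strand, back.blocks) == (
            "s_t2", "chrII", "-", [(10, 400), (900, 1500)]
        )
        assert back.structural_class == "truncated"

    def test_empty_element_list(self, tmp_path):
        p = tmp_path / "empty.bed"
        ann.write_bed12([], p)
        assert p.read_text() == ""
        assert ann.read_bed12(p) == []


class TestCounts:
    def test_pooled_solo_row(self):
        els = [
            ann.TyElement("s_f1", "full_length", "Ty1", "+", "c", [(0, 5918)]),
            ann.TyElement("s_s2", "solo_ltr", "Ty1", "+", "c", [(7000, 7334)]),
            ann.TyElement("s_s3", "solo_ltr", "Ty1", "+", "c", [(8000, 8334)]),
            ann.TyElement("s_s4", "solo_ltr", "Ty2", "+", "c", [(9000, 9332)]),
            ann.TyElement("s_s5", "solo_ltr", "Ty2", "+", "c", [(9500, 9832)]),
            ann.TyElement("s_s6", "solo_ltr", "Ty2", "+", "c", [(9900, 10232)]),
        ]
        counts = ann.count_by_family(els)
        assert counts.pooled_ty1_ty2_solo == 5

    def test_empty_is_all_zero(self):
        counts = ann.count_by_family([])
        assert counts.per_family == {} and counts.pooled_ty1_ty2_solo == 0


class TestEndToEnd:
    def test_all_error_modes_curated_to_truth(self, library):
        """Curated counts equal planted truth with every error mode enabled."""
        rng = np.random.default_rng(123)
        for _ in range(10):
            config = sim.random_genome_config(rng)
            truth = sim.plant_genome(config, seed=int(rng.integers(0, 2**31 - 1)))
            els = ann.curate(truth.raw_hits, library, "synth")
            assert ann.count_by_family(els).per_family == truth.truth_counts

    def test_adding_false_positive_never_changes_counts(self, library):
        rng = np.random.default_rng(55)
        config = sim.random_genome_config(rng, all_error_modes=False)
        truth = sim.plant_genome(config, seed=21)
        base = ann.count_by_family(ann.curate(truth.raw_hits, library, "s")).per_family
        for div in (20.1, 30.0, 99.9):
            extra = hit("Ty1_I", 50, 450, group=9999, div=div)
            got = ann.count_by_family(
                ann.curate(truth.raw_hits + [extra], library, "s")
            ).per_family
            assert got == base

    def test_element_ids_follow_class_prefix_and_order(self, library):
        truth = sim.plant_genome(
            sim.GenomeConfig(
                elements=[
                    sim.ElementSpec(structural_class="solo_ltr"),
                    sim.ElementSpec(),
                    sim.ElementSpec(structural_class="truncated"),
                ]
            ),
            seed=2,
        )
        els = ann.curate(truth.raw_hits, library, "str1")
        assert [e.element_id for e in els] == ["str1_s1", "str1_f2", "str1_t3"]
        assert [e.start for e in els] == sorted(e.start for e in els)
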
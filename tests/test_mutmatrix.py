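"""Presence calling, matrix assembly, display filter, substitution spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mlclonal import mutmatrix
from mlclonal.io_formats import MutationRecord
from mlclonal.mutmatrix import (
    ABSENT_COVERED,
    ABSENT_LOW_COVERAGE,
    PRESENT,
    build_matrix,
    call_presence,
    heatmap_filter,
    substitution_spectrum,
)
from conftest import make_manifest, make_matrix, make_records


class TestCallPresence:
    @pytest.mark.parametrize("ref,alt,expected", [
        (30, 0, ABSENT_COVERED),        # covered zero-alt site
        (27, 3, PRESENT),               # vaf 0.10 >= 0.05, alt 3 >= 3
        (5, 0, ABSENT_LOW_COVERAGE),    # depth 5 < 10
        (0, 0, ABSENT_LOW_COVERAGE),
        (98, 2, ABSENT_LOW_COVERAGE),   # 2 alt reads: neither present nor clean absence
        (100, 1, ABSENT_COVERED),
        (100, 3, ABSENT_LOW_COVERAGE),  # vaf 0.029 < 0.05
    ])
    def test_threshold_logic(self, ref, alt, expected):
        assert call_presence(ref, alt) == expected

    @settings(max_examples=200, derandomize=True)
    @given(ref=st.integers(0, 500), alt=st.integers(0, 500), extra=st.integers(1, 50))
    def test_more_alt_reads_never_lose_presence(self, ref, alt, extra):
        if call_presence(ref, alt) == PRESENT:
            assert call_presence(ref, alt + extra) == PRESENT


class TestBuildMatrix:
    def test_matrix_matches_per_cell_oracle(self):
        rng = np.random.default_rng(0)
        manifest = make_manifest({"T1": ["S1", "S2"], "T2": ["S3"]})
        records = []
        for i in range(30):
            depths = {s: (int(rng.integers(0, 60)), int(rng.integers(0, 12)))
                      for s in manifest.samples}
            records.append(MutationRecord(chrom="chr1", pos=i + 1, ref="C", alt="A",
                                          depths=depths))
        m = build_matrix(records, manifest)
        for rec in records:
            for s in manifest.samples:
                assert m.status.loc[rec.mutation_id, s] == \
                    call_presence(*rec.depths[s])

    def test_duplicate_rows_rejected(self):
        manifest = make_manifest({"T1": ["S1"]})
        rec = MutationRecord(chrom="chr1", pos=5, ref="C", alt="T",
                             depths={s: (10, 10) for s in manifest.samples})
        with pytest.raises(ValueError, match="duplicate"):
            build_matrix([rec, rec], manifest)

    def test_vaf_missing_at_zero_depth(self):
        manifest = make_manifest({"T1": ["S1"]})
        rec = MutationRecord(chrom="chr1", pos=5, ref="C", alt="T",
                             depths={"S1": (0, 0), "NORMAL": (50, 0)})
        m = build_matrix([rec], manifest)
        assert np.isnan(m.vaf.loc[rec.mutation_id, "S1"])

    def test_normal_presence_flags_suspect_germline(self):
        manifest = make_manifest({"T1": ["S1"]})
        rec = MutationRecord(chrom="chr1", pos=5, ref="C", alt="T",
                             depths={"S1": (30, 30), "NORMAL": (30, 30)})
        m = build_matrix([rec], manifest)
        assert m.suspect_germline == [rec.mutation_id]
        assert m.present_set("S1") == set()

    def test_fixture_normal_column_all_absent(self, fixture_matrix):
        assert not (fixture_matrix.status["NORMAL"] == PRESENT).any()
        assert fixture_matrix.suspect_germline == []


class TestHeatmapFilter:
    def _matrix(self):
        manifest = make_manifest({"T1": ["S1", "S2"]})
        records = [
            MutationRecord(chrom="chr1", pos=1, ref="C", alt="T", gene="g1",
                           func_class="nonsynonymous",
                           depths={"S1": (40, 20), "S2": (40, 0), "NORMAL": (40, 0)}),
            MutationRecord(chrom="chr1", pos=2, ref="C", alt="T", gene="g2",
                           func_class="nonsynonymous",
                           depths={"S1": (40, 20), "S2": (10, 0), "NORMAL": (40, 0)}),
            MutationRecord(chrom="chr1", pos=3, ref="C", alt="T", gene="g3",
                           func_class="synonymous",
                           depths={"S1": (40, 20), "S2": (40, 0), "NORMAL": (40, 0)}),
        ]
        return build_matrix(records, manifest)

    def test_boundary_depth_excluded_by_strict_inequality(self):
        m = self._matrix()
        kept = heatmap_filter(m).mutation_ids
        assert kept == ["chr1:1:C>T"]  # pos 2 has depth exactly 10 in S2

    def test_synonymous_rows_excluded(self):
        kept = heatmap_filter(self._matrix()).mutation_ids
        assert "chr1:3:C>T" not in kept

    def test_idempotent_and_subset(self):
        m = self._matrix()
        once = heatmap_filter(m)
        twice = heatmap_filter(once)
        assert twice.mutation_ids == once.mutation_ids
        assert set(once.mutation_ids) <= set(m.mutation_ids)

    def test_all_pass_matrix_is_identity(self):
        manifest = make_manifest({"T1": ["S1"]})
        m = make_matrix({"m1": {"S1"}, "m2": {"S1"}}, manifest)
        assert heatmap_filter(m).mutation_ids == m.mutation_ids


class TestSpectrum:
    def _matrix(self, ref_alts):
        manifest = make_manifest({"T1": ["S1"]})
        records = [
            MutationRecord(chrom="chr1", pos=i + 1, ref=r, alt=a,
                           depths={"S1": (70, 30), "NORMAL": (70, 0)})
            for i, (r, a) in enumerate(ref_alts)]
        return build_matrix(records, manifest)

    def test_pure_transition_spectrum(self):
        m = self._matrix([("A", "G")] * 4)
        assert substitution_spectrum(m, "S1")["ti_fraction"] == 1.0

    def test_three_transitions_one_transversion(self):
        m = self._matrix([("C", "T"), ("T", "C"), ("A", "G"), ("C", "A")])
        spec = substitution_spectrum(m, "S1")
        assert spec["ti_fraction"] == pytest.approx(0.75)
        assert sum(spec["fractions"].values()) == pytest.approx(1.0)

    def test_purine_reference_collapses_to_pyrimidine_classes(self):
        spec = substitution_spectrum(self._matrix([("G", "A")]), "S1")
        assert spec["fractions"]["C>T"] == 1.0

    def test_indels_excluded_and_empty_errors(self):
        manifest = make_manifest({"T1": ["S1"]})
        rec = MutationRecord(chrom="chr1", pos=1, ref="CA", alt="C",
                             func_class="indel",
                             depths={"S1": (70, 30), "NORMAL": (70, 0)})
        m = build_matrix([rec], manifest)
        with pytest.raises(ValueError):
            substitution_spectrum(m, "S1")

    def test_fixture_seeding_primary_transition_fraction(self, fixture_matrix):
        spec = substitution_spectrum(
            fixture_matrix, ["HCC-A1", "HCC-A2", "HCC-A3"])
        assert spec["ti_fraction"] == pytest.approx(0.52, abs=0.005)


def test_present_set_accepts_sample_groups(fixture_matrix):
    single = fixture_matrix.present_set("HCC-A1")
    union = fixture_matrix.present_set(["HCC-A1", "HCC-A2", "HCC-A3"])
    assert single <= union


def test_records_helper_respects_patterns():
    manifest = make_manifest({"T1": ["S1", "S2"]})
    recs = make_records({"m1": {"S1"}}, manifest)
    m = mutmatrix.build_matrix(recs, manifest)
    assert m.present_set("S1") and not m.present_set("S2")
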
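"""Scan-table parsing, recognition calling, motif derivation, titration."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from tcrisk.exchange_scan import (
    AssayFailedError,
    ExchangeScanTable,
    MotifAmbiguityError,
    Peptide,
    RecognitionCall,
    ScanTableError,
    TitrationCurve,
    VariantRow,
    call_recognition,
    derive_motif,
    parse_scan_table,
    parse_titration_table,
    titration_threshold,
    write_scan_table,
)

from conftest import ADRB3_PEPTIDE


def make_table(variant_means, original_mean=100, background_mean=5,
               sequence=ADRB3_PEPTIDE, reps=3):
    """Table with exact (noise-free) replicate counts at the given means."""
    variants = tuple(
        VariantRow(pos, "S" if sequence[pos - 1] == "A" else "A",
                   tuple([mean] * reps))
        for pos, mean in variant_means.items()
    )
    return ExchangeScanTable(
        original=Peptide("test", sequence),
        variants=variants,
        original_counts=tuple([original_mean] * reps),
        background_counts=tuple([background_mean] * reps),
    )


def calls_for(mapping, sequence=ADRB3_PEPTIDE, sub="A"):
    return [
        RecognitionCall(pos, sub if sequence[pos - 1] != sub else "S",
                        rel, call)
        for pos, (rel, call) in mapping.items()
    ]


class TestParseScanTable:
    def write(self, tmp_path, lines):
        path = tmp_path / "scan.tsv"
        path.write_text("\n".join(lines) + "\n")
        return path

    HEADER = "row_type\tposition\toriginal_residue\tsubstituted_residue\trep1\trep2\trep3"

    def full_table_lines(self):
        lines = [
            "# name: ADRB3_295",
            "# pulse_concentration_uM: 0.01",
            self.HEADER,
            f"original\t\t{ADRB3_PEPTIDE}\t\t98\t102\t100",
            "background\t\t\t\t4\t6\t5",
        ]
        for pos, orig in enumerate(ADRB3_PEPTIDE, start=1):
            sub = "S" if orig == "A" else "A"
            lines.append(f"variant\t{pos}\t{orig}\t{sub}\t90\t95\t92")
        return lines

    def test_well_formed_nine_variant_table(self, tmp_path):
        table = parse_scan_table(self.write(tmp_path, self.full_table_lines()))
        assert len(table.variants) == 9
        assert table.original.sequence == ADRB3_PEPTIDE
        assert table.original.name == "ADRB3_295"
        assert table.original_counts == (98, 102, 100)
        assert table.background_counts == (4, 6, 5)
        assert table.pulse_concentration_uM == pytest.approx(0.01)

    def test_missing_background_row_is_structural_error(self, tmp_path):
        lines = [l for l in self.full_table_lines() if not l.startswith("background")]
        with pytest.raises(ScanTableError, match="background"):
            parse_scan_table(self.write(tmp_path, lines))

    def test_missing_original_row_is_structural_error(self, tmp_path):
        lines = [l for l in self.full_table_lines() if not l.startswith("original")]
        with pytest.raises(ScanTableError, match="original"):
            parse_scan_table(self.write(tmp_path, lines))

    def test_position_out_of_range_names_the_problem(self, tmp_path):
        lines = self.full_table_lines() + ["variant\t10\t\tA\t1\t2\t3"]
        with pytest.raises(ScanTableError, match="position 10"):
            parse_scan_table(self.write(tmp_path, lines))

    @pytest.mark.parametrize("bad_row, match", [
        ("variant\t3\tI\tZ\t1\t2\t3", "substituted residue"),
        ("variant\t3\tI\tV\t-1\t2\t3", "negative"),
        ("variant\t3\tM\tV\t1\t2\t3", "disagrees"),
        ("mystery\t3\tI\tV\t1\t2\t3", "row_type"),
    ])
    def test_invalid_rows_are_validation_errors(self, tmp_path, bad_row, match):
        lines = self.full_table_lines() + [bad_row]
        with pytest.raises(ScanTableError, match=match):
            parse_scan_table(self.write(tmp_path, lines))

    def test_write_parse_round_trip(self, tmp_path):
        table = parse_scan_table(self.write(tmp_path, self.full_table_lines()))
        out = tmp_path / "rewritten.tsv"
        write_scan_table(table, out)
        assert parse_scan_table(out) == table


class TestCallRecognition:
    def test_background_subtracted_relative_activity(self):
        # original 100, background 5, variant 90 -> (90-5)/(100-5) ~ 0.895
        table = make_table({3: 90})
        [call] = call_recognition(table, low=0.25, high=0.75)
        assert call.relative_activity == pytest.approx(85 / 95)
        assert call.call == "unaffected"

    def test_variant_identical_to_original_is_unity(self):
        [call] = call_recognition(make_table({3: 100}))
        assert call.relative_activity == pytest.approx(1.0)
        assert call.call == "unaffected"

    def test_variant_at_background_is_abolished(self):
        [call] = call_recognition(make_table({3: 5}))
        assert call.relative_activity == 0.0
        assert call.call == "abolished"

    def test_variant_below_background_clamps_to_zero(self):
        [call] = call_recognition(make_table({3: 1}))
        assert call.relative_activity == 0.0

    def test_partial_band_between_thresholds(self):
        [call] = call_recognition(make_table({3: 52}))  # rel ~ 0.495
        assert call.call == "partial"

    def test_failed_assay_signalled(self):
        with pytest.raises(AssayFailedError, match="no specific recognition"):
            call_recognition(make_table({3: 50}, original_mean=5,
                                        background_mean=5))

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_recognition(make_table({3: 50}), low=0.8, high=0.2)

    def test_scale_invariance_of_relative_activity(self):
        base = make_table({2: 10, 5: 60, 8: 95})
        scaled = make_table({2: 30, 5: 180, 8: 285}, original_mean=300,
                            background_mean=15)
        for a, b in zip(call_recognition(base), call_recognition(scaled)):
            assert a.relative_activity == pytest.approx(b.relative_activity)
            assert a.call == b.call


class TestDeriveMotif:
    ADRB3_CALLS = {2: (0.1, "abolished"), 7: (0.05, "abolished"),
                   9: (0.5, "partial"),
                   **{p: (0.9, "unaffected") for p in (1, 3, 4, 5, 6, 8)}}

    def test_published_adrb3_motif_conservative(self, adrb3):
        d = derive_motif(adrb3, calls_for(self.ADRB3_CALLS))
        assert d.pattern.render() == "X-L-X-X-X-X-F-X-[LA]"
        assert d.untested_positions == ()

    def test_published_chm1_motif_conservative(self):
        chm1 = Peptide("CHM1_319", "QQQQQSWWV")
        calls = calls_for(
            {6: (0.5, "partial"), 7: (0.1, "abolished"), 8: (0.1, "abolished"),
             9: (0.5, "partial"),
             **{p: (0.9, "unaffected") for p in (1, 2, 3, 4, 5)}},
            sequence="QQQQQSWWV", sub="T",
        )
        assert derive_motif(chm1, calls).pattern.render() == "X-X-X-X-X-[ST]-W-W-[VT]"

    def test_strict_mode_wildcards_partial_positions(self, adrb3):
        d = derive_motif(adrb3, calls_for(self.ADRB3_CALLS), mode="strict")
        assert d.pattern.render() == "X-L-X-X-X-X-F-X-X"

    def test_fully_abolished_fixes_whole_sequence(self, adrb3):
        calls = calls_for({p: (0.0, "abolished") for p in range(1, 10)})
        assert derive_motif(adrb3, calls).pattern.render() == "G-L-I-M-G-T-F-T-L"

    def test_fully_unaffected_is_all_wildcards(self, adrb3):
        calls = calls_for({p: (0.9, "unaffected") for p in range(1, 10)})
        assert derive_motif(adrb3, calls).pattern.render() == (
            "X-X-X-X-X-X-X-X-X"
        )

    def test_untested_positions_fixed_and_flagged(self, adrb3):
        calls = calls_for({2: (0.05, "abolished"),
                           5: (0.9, "unaffected")})
        d = derive_motif(adrb3, calls)
        assert d.untested_positions == (1, 3, 4, 6, 7, 8, 9)
        assert d.pattern.render() == "G-L-I-M-X-T-F-T-L"

    def test_order_invariance(self, adrb3):
        calls = calls_for(self.ADRB3_CALLS)
        rendered = {
            derive_motif(adrb3, perm).pattern.render()
            for perm in itertools.islice(itertools.permutations(calls), 24)
        }
        assert rendered == {"X-L-X-X-X-X-F-X-[LA]"}

    def test_conflicting_calls_raise_ambiguity(self, adrb3):
        calls = [RecognitionCall(2, "A", 0.1, "abolished"),
                 RecognitionCall(2, "S", 0.9, "unaffected")]
        with pytest.raises(MotifAmbiguityError, match="position 2"):
            derive_motif(adrb3, calls)

    def test_duplicate_call_rows_raise_ambiguity(self, adrb3):
        calls = [RecognitionCall(2, "A", 0.1, "abolished"),
                 RecognitionCall(2, "A", 0.9, "unaffected")]
        with pytest.raises(MotifAmbiguityError):
            derive_motif(adrb3, calls)

    def test_agreeing_partial_calls_pool_residues(self, adrb3):
        calls = [RecognitionCall(9, "A", 0.5, "partial"),
                 RecognitionCall(9, "V", 0.6, "partial")]
        d = derive_motif(adrb3, calls)
        assert d.pattern.positions[8].residues == ("L", "A", "V")

    def test_derivation_metadata_serializes(self, adrb3):
        d = derive_motif(adrb3, calls_for(self.ADRB3_CALLS))
        payload = d.to_json_dict()
        assert payload["pattern"] == "X-L-X-X-X-X-F-X-[LA]"
        assert len(payload["calls"]) == 9


@given(st.dictionaries(
    st.integers(min_value=1, max_value=9),
    st.sampled_from(["abolished", "partial", "unaffected"]),
    min_size=0, max_size=9,
))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_bracket_classes_appear_exactly_at_partial_positions(truth):
    """Strict mode never brackets; conservative brackets iff the call is partial."""
    peptide = Peptide("t", ADRB3_PEPTIDE)
    calls = [
        RecognitionCall(pos, "S" if ADRB3_PEPTIDE[pos - 1] == "A" else "A",
                        {"abolished": 0.0, "partial": 0.5, "unaffected": 1.0}[c], c)
        for pos, c in truth.items()
    ]
    conservative = derive_motif(peptide, calls).pattern
    strict = derive_motif(peptide, calls, mode="strict").pattern
    for pos in range(1, 10):
        assert (conservative.positions[pos - 1].kind == "include") == (
            truth.get(pos) == "partial"
        )
        assert strict.positions[pos - 1].kind != "include"


class TestTitration:
    def make_curve(self, means, background=5, reps=3):
        return TitrationCurve(
            concentrations_uM=tuple(c for c, _ in means),
            spot_counts=tuple(tuple([m] * reps) for _, m in means),
            background_counts=tuple([background] * reps),
        )

    def test_threshold_at_point_zero_one_micromolar(self):
        # responses stay above the low fraction down to and including 0.01 uM
        curve = self.make_curve([(10, 105), (1, 100), (0.1, 80), (0.01, 40),
                                 (0.001, 8)])
        assert titration_threshold(curve, low=0.25) == pytest.approx(0.01)

    def test_all_background_returns_absent(self):
        curve = self.make_curve([(10, 5), (1, 5), (0.1, 5)])
        assert titration_threshold(curve, low=0.25) is None

    def test_recognition_at_every_dose_returns_lowest_tested(self):
        curve = self.make_curve([(10, 100), (1, 95), (0.1, 90), (0.01, 85),
                                 (0.001, 80)])
        assert titration_threshold(curve, low=0.25) == pytest.approx(0.001)

    def test_concentrations_must_strictly_decrease(self):
        with pytest.raises(ValueError, match="decreasing"):
            self.make_curve([(1, 100), (10, 90)])

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            TitrationCurve((), (), (5,))

    def test_parse_titration_tsv(self, tmp_path):
        path = tmp_path / "titration.tsv"
        path.write_text(
            "concentration_uM\trep1\trep2\trep3\n"
            "0.001\t7\t9\t8\n"
            "10\t100\t110\t105\n"
            "1\t95\t100\t98\n"
            "0.1\t70\t75\t72\n"
            "0.01\t30\t35\t32\n"
            "background\t4\t6\t5\n"
        )
        curve = parse_titration_table(path)
        assert curve.concentrations_uM == (10, 1, 0.1, 0.01, 0.001)
        assert titration_threshold(curve, low=0.25) == pytest.approx(0.01)
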
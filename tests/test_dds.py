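"""Duplex-stability encoding: table loading, the L−1 length law, the
no-zero position convention, and longitudinal profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promdds import dds
from promdds.sequences import PromoterRecord, reverse_complement

DNA = st.text(alphabet="ACGT", min_size=2, max_size=150)


class TestTable:
    def test_default_table_complete_and_negative(self, table):
        assert set(table.values) == set(dds.DINUCLEOTIDES)
        assert all(v < 0 for v in table.values.values())

    def test_reverse_complement_symmetry(self, table):
        # a stack and its reverse complement are the same duplex
        for dinuc in dds.DINUCLEOTIDES:
            assert table[dinuc] == table[reverse_complement(dinuc)]

    def test_missing_entry_rejected(self, tmp_path, table):
        lines = [f"{k}: {v}" for k, v in sorted(table.values.items())][:15]
        p = tmp_path / "short.txt"
        p.write_text("\n".join(lines))
        with pytest.raises(dds.TableFormatError, match="16"):
            dds.load_dds_table(p)

    def test_non_acgt_entry_names_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("AN: -1.0\n")
        with pytest.raises(dds.TableFormatError, match=":1"):
            dds.load_dds_table(p)

    def test_duplicate_entry_rejected(self, tmp_path, table):
        lines = [f"{k}: {v}" for k, v in sorted(table.values.items())]
        p = tmp_path / "dup.txt"
        p.write_text("\n".join(lines + ["AA: -2.0"]))
        with pytest.raises(dds.TableFormatError, match="duplicate"):
            dds.load_dds_table(p)

    def test_roundtrip_custom_table(self, tmp_path, table):
        p = tmp_path / "ok.txt"
        p.write_text("# comment\n" + "\n".join(f"{k}: {v}" for k, v in table.values.items()))
        loaded = dds.load_dds_table(p)
        assert loaded.values == table.values


class TestEncoding:
    def test_core_window_yields_99_features(self, table):
        fv = dds.encode_sequence("ACGT" * 25, table)
        assert len(fv) == 99
        assert fv.position_labels[0] == -80
        assert fv.position_labels[-1] == 19
        assert 0 not in fv.position_labels

    def test_aatt_values(self, table):
        fv = dds.encode_sequence("AATT", table, tss_offset=1)
        assert fv.values.tolist() == [table["AA"], table["AT"], table["TT"]]
        assert table["AA"] == table["TT"]

    def test_homopolymer_constant(self, table):
        fv = dds.encode_sequence("AAAA", table)
        assert np.unique(fv.values).size == 1

    def test_too_short_rejected(self, table):
        with pytest.raises(dds.EncodingError):
            dds.encode_sequence("A", table)

    def test_ambiguous_base_strict_names_position(self, table):
        with pytest.raises(dds.EncodingError, match="position 2"):
            dds.encode_sequence("AANA", table)

    def test_ambiguous_base_mean_policy(self, table):
        fv = dds.encode_sequence("AANA", table, ambiguous="mean")
        assert fv.values[1] == pytest.approx(table.mean())
        assert fv.values[2] == pytest.approx(table.mean())

    @settings(max_examples=50, deadline=None)
    @given(seq=DNA)
    def test_length_law_and_determinism(self, seq, table):
        fv1 = dds.encode_sequence(seq, table, tss_offset=1)
        fv2 = dds.encode_sequence(seq, table, tss_offset=1)
        assert len(fv1) == len(seq) - 1
        assert np.array_equal(fv1.values, fv2.values)

    def test_at_gc_stability_contrast(self, table):
        at = dds.encode_sequence("AT" * 30, table).values.mean()
        gc = dds.encode_sequence("GC" * 30, table).values.mean()
        assert at > gc  # GC stacks contribute more negatively


class TestBatch:
    def test_batch_matches_single(self, table):
        recs = [PromoterRecord(id="r0", sequence="ACGTACGTAC")]
        mat = dds.encode_batch(recs, table)
        fv = dds.encode_sequence("ACGTACGTAC", table)
        assert np.array_equal(mat.values[0], fv.values)
        assert mat.ids == ("r0",)

    def test_mixed_lengths_name_offenders(self, table):
        recs = [
            PromoterRecord(id="ok", sequence="ACGTACGT"),
            PromoterRecord(id="bad", sequence="ACG"),
        ]
        with pytest.raises(dds.DimensionError, match="bad"):
            dds.encode_batch(recs, table)

    def test_empty_batch(self, table):
        mat = dds.encode_batch([], table)
        assert mat.n_sequences == 0

    def test_tsv_export_header(self, table, tmp_path):
        recs = [PromoterRecord(id="r0", sequence="ACGT" * 25)]
        mat = dds.encode_batch(recs, table)
        out = tmp_path / "m.tsv"
        mat.to_tsv(out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header[0] == "id" and header[1] == "-80" and header[-1] == "19"


class TestProfiles:
    def test_single_row_profile_is_row(self, table):
        recs = [PromoterRecord(id="r", sequence="ACGTAC")]
        mat = dds.encode_batch(recs, table)
        prof = dds.mean_profile(mat)
        assert np.array_equal(prof.values, mat.values[0])
        assert prof.n_sequences == 1

    def test_two_row_mean(self, table):
        recs = [
            PromoterRecord(id="a", sequence="AAAA"),
            PromoterRecord(id="b", sequence="GGGG"),
        ]
        prof = dds.mean_profile(dds.encode_batch(recs, table))
        expected = (table["AA"] + table["GG"]) / 2
        assert np.allclose(prof.values, expected)

    def test_empty_profile_rejected(self, table):
        with pytest.raises(ValueError):
            dds.mean_profile(dds.encode_batch([], table))

    def test_planted_box_peaks_in_window(self, table, tata_spec):
        from promdds import generate_promoters

        recs = generate_promoters(tata_spec, 500, seed=5)
        prof = dds.mean_profile(dds.encode_batch(recs, table))
        assert -32 <= prof.peak_position() <= -25

    def test_correlation_identities(self):
        p = np.array([1.0, 2.0, 4.0, 3.0])
        assert dds.profile_correlation(p, p) == pytest.approx(1.0)
        assert dds.profile_correlation(p, -p) == pytest.approx(-1.0)

    def test_correlation_hand_value(self):
        # closed-form Pearson on p1=[1,2,3,4], p2=[2,4,6,9]
        p1, p2 = np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 9])
        n = 4
        num = n * (p1 * p2).sum() - p1.sum() * p2.sum()
        den = np.sqrt(n * (p1**2).sum() - p1.sum() ** 2) * np.sqrt(
            n * (p2**2).sum() - p2.sum() ** 2
        )
        assert dds.profile_correlation(p1, p2) == pytest.approx(num / den, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_correlation_matches_sum_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=20), rng.normal(size=20)
        cov = ((a - a.mean()) * (b - b.mean())).mean()
        r = cov / (a.std() * b.std())
        assert dds.profile_correlation(a, b) == pytest.approx(r, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            dds.profile_correlation(np.ones(5), np.arange(5.0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(dds.DimensionError):
            dds.profile_correlation(np.arange(4.0), np.arange(5.0))
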
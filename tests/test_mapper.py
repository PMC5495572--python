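"""Trim-and-split geometry, placement reconciliation, FASTQ mapping."""

import numpy as np
import pytest

from exactrna.errors import FastqFormatError, GeometryError
from exactrna.mapper import (
    Placement,
    ReadRecord,
    map_fastq,
    place_read,
    read_placements_tsv,
    reverse_complement,
    split_read,
    write_placements_tsv,
    write_sam,
)
from exactrna.refindex import ReferenceSet, build_index

from conftest import naive_find, random_refs


class TestSplitRead:
    def test_canonical_100nt_geometry(self):
        sp = split_read("A" * 2 + "C" * 32 + "G" * 32 + "T" * 32 + "A" * 2)
        assert sp.offsets_in_read == (2, 34, 66)
        assert sp.parts == ("C" * 32, "G" * 32, "T" * 32)

    def test_94nt_gives_three_30mers(self):
        sp = split_read("A" * 94)
        assert sp.part_length == 30

    @pytest.mark.parametrize("length", [10, 99, 101, 4])
    def test_geometry_errors_name_length(self, length):
        with pytest.raises(GeometryError, match=str(length)):
            split_read("A" * length)

    def test_parts_cover_trimmed_core(self, rng):
        read = "".join(rng.choice(list("ACGT"), size=100))
        sp = split_read(read)
        assert "".join(sp.parts) == read[2:-2]


def planted_read(seq: str, pos: int, L: int = 100) -> str:
    return seq[pos : pos + L]


class TestPlaceRead:
    def test_planted_read_unique_placement(self, toy_refs, toy_index):
        seq = toy_refs.records["chrA"]
        read = ReadRecord("r1", planted_read(seq, 100))
        pl = place_read(toy_index, read)
        # start records the trimmed-span start: source pos + 2
        assert (pl.status, pl.sequence_id, pl.start, pl.strand) == ("unique", "chrA", 102, "+")
        assert pl.span == 96

    def test_reverse_strand_read(self, toy_refs, toy_index):
        seq = toy_refs.records["chrB"]
        read = ReadRecord("r1", reverse_complement(planted_read(seq, 500)))
        pl = place_read(toy_index, read)
        assert (pl.status, pl.sequence_id, pl.strand) == ("unique", "chrB", "-")
        assert pl.start == 502

    def test_substitution_in_middle_part_unmaps(self, toy_refs, toy_index):
        seq = toy_refs.records["chrA"]
        read = list(planted_read(seq, 100))
        i = 50  # inside the middle part (offsets 34..66)
        read[i] = {"A": "C"}.get(read[i], "A")
        pl = place_read(toy_index, ReadRecord("r1", "".join(read)))
        assert pl.status == "unmapped"
        assert pl.sequence_id is None and pl.start is None

    def test_flank_substitution_tolerated(self, toy_refs, toy_index):
        seq = toy_refs.records["chrA"]
        read = list(planted_read(seq, 100))
        read[0] = {"A": "C"}.get(read[0], "A")
        read[-1] = {"A": "C"}.get(read[-1], "A")
        pl = place_read(toy_index, ReadRecord("r1", "".join(read)))
        assert pl.status == "unique" and pl.start == 102

    def test_duplicated_region_gives_multi(self):
        core = "".join(np.random.default_rng(7).choice(list("ACGT"), size=104))
        refs = ReferenceSet({"dup": core + "TTTTCCCCAAAAGGGG" + core})
        idx = build_index(refs)
        pl = place_read(idx, ReadRecord("r1", core[:100]))
        assert pl.status == "multi"

    def test_discordant_when_parts_hit_inconsistently(self, rng):
        # all three parts present but never collinear
        a = "".join(rng.choice(list("ACGT"), size=32))
        b = "".join(rng.choice(list("ACGT"), size=32))
        c = "".join(rng.choice(list("ACGT"), size=32))
        gap = "TTTTTTTTTT"
        refs = ReferenceSet({"s": a + gap + b + gap + c})
        idx = build_index(refs)
        read = "AA" + a + b + c + "AA"
        pl = place_read(idx, ReadRecord("r1", read))
        assert pl.status == "discordant"

    def test_oracle_equivalence_error_free_reads(self, rng):
        refs = random_refs(rng, {"chr": 8000})
        idx = build_index(refs)
        seq = refs.records["chr"]
        for _ in range(200):
            pos = int(rng.integers(0, len(seq) - 100))
            raw = planted_read(seq, pos)
            if rng.random() < 0.5:
                raw = reverse_complement(raw)
            pl = place_read(idx, ReadRecord("r", raw))
            # oracle: full trimmed-span exact search on both strands
            fwd = naive_find(refs, raw[2:-2])
            rev = naive_find(refs, reverse_complement(raw)[2:-2])
            n = len(fwd) + len(rev)
            if n == 1:
                assert pl.status == "unique"
                hit, strand = (fwd[0], "+") if fwd else (rev[0], "-")
                assert (pl.sequence_id, pl.start, pl.strand) == (hit[0], hit[1], strand)
            else:
                assert pl.status == "multi"

    def test_strand_symmetry_under_reference_mirroring(self, rng):
        # reverse-complementing the reference mirrors placements:
        # start' = L - (start + span), strand flipped
        refs = random_refs(rng, {"c": 2000})
        mirrored = ReferenceSet({"c": reverse_complement(refs.records["c"])})
        idx, midx = build_index(refs), build_index(mirrored)
        L = len(refs.records["c"])
        for _ in range(50):
            pos = int(rng.integers(0, L - 100))
            raw = planted_read(refs.records["c"], pos)
            if rng.random() < 0.5:
                raw = reverse_complement(raw)
            pl = place_read(idx, ReadRecord("r", raw))
            mpl = place_read(midx, ReadRecord("r", raw))
            assert pl.status == mpl.status == "unique"
            assert mpl.start == L - (pl.start + pl.span)
            assert {pl.strand, mpl.strand} == {"+", "-"}


def write_fastq_text(path, records):
    path.write_text("".join(f"@{r[0]}\n{r[1]}\n+\n{'I' * len(r[1])}\n" for r in records))


class TestMapFastq:
    def test_planted_reads_all_unique(self, tmp_path, toy_refs, toy_index, rng):
        seq = toy_refs.records["chrA"]
        recs = [(f"r{i}", planted_read(seq, int(rng.integers(0, 2900)))) for i in range(10)]
        fq = tmp_path / "reads.fq"
        write_fastq_text(fq, recs)
        placements, stats = map_fastq(toy_index, fq)
        assert stats.as_dict() == {
            "total": 10, "unique": 10, "multi": 0,
            "unmapped": 0, "discordant": 0, "geometry_skipped": 0,
        }
        assert len(placements) == 10

    def test_geometry_violators_skipped_not_unmapped(self, tmp_path, toy_index):
        fq = tmp_path / "reads.fq"
        write_fastq_text(fq, [("short", "ACGTACGTAC")])
        placements, stats = map_fastq(toy_index, fq)
        assert stats.geometry_skipped == 1 and stats.unmapped == 0
        assert placements == []

    def test_empty_fastq(self, tmp_path, toy_index):
        fq = tmp_path / "empty.fq"
        fq.write_text("")
        placements, stats = map_fastq(toy_index, fq)
        assert placements == [] and stats.total == 0

    def test_malformed_record_reports_index(self, tmp_path, toy_index):
        fq = tmp_path / "bad.fq"
        fq.write_text("@r0\nACGT\n+\nIIII\nr1-missing-at\nACGT\n+\nIIII\n")
        with pytest.raises(FastqFormatError) as err:
            map_fastq(toy_index, fq)
        assert err.value.record_index == 1

    def test_status_counts_partition_placements(self, tmp_path, toy_refs, toy_index, rng):
        seq = toy_refs.records["chrA"]
        recs = []
        for i in range(20):
            r = planted_read(seq, int(rng.integers(0, 2900)))
            if i % 4 == 0:  # corrupt middle part
                r = r[:50] + ("A" if r[50] != "A" else "C") + r[51:]
            recs.append((f"r{i}", r))
        recs.append(("short", "ACGT" * 5))
        fq = tmp_path / "mix.fq"
        write_fastq_text(fq, recs)
        placements, s = map_fastq(toy_index, fq)
        assert s.unique + s.multi + s.unmapped + s.discordant + s.geometry_skipped == s.total
        assert len(placements) == s.total - s.geometry_skipped


class TestOutputs:
    def test_placements_tsv_round_trip(self, tmp_path, toy_refs, toy_index):
        seq = toy_refs.records["chrA"]
        pls = [
            place_read(toy_index, ReadRecord("a", planted_read(seq, 11))),
            Placement("b", None, None, None, "unmapped", 96),
        ]
        path = tmp_path / "pl.tsv"
        write_placements_tsv(pls, path)
        assert read_placements_tsv(path) == pls

    def test_sam_output_valid(self, tmp_path, toy_refs, toy_index):
        import pysam

        seq = toy_refs.records["chrA"]
        pls = [place_read(toy_index, ReadRecord("a", planted_read(seq, 11)))]
        sam = tmp_path / "out.sam"
        write_sam(pls, toy_index, sam)
        with pysam.AlignmentFile(str(sam)) as fh:
            recs = list(fh)
        assert len(recs) == 1
        assert recs[0].reference_start == 13 and recs[0].cigarstring == "96M"
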
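"""Demultiplexing: FASTQ conversion, MID assignment, clipping, length filter."""
import string

import pytest
from hypothesis import given
from hypothesis import strategies as st

from icemeta import demux as dx

MID_2149 = dx.DEFAULT_MIDS["2149m"]


def decorated(insert: str, mid: str = MID_2149) -> str:
    return dx.ION_ADAPTER_A + mid + dx.ECORI_NOTI_LINKER + insert


# ---------------------------------------------------------------------------
# FASTQ -> FASTA
# ---------------------------------------------------------------------------

def test_fastq_to_fasta_preserves_ids_and_bases(tmp_path):
    reads = [
        dx.SequenceRead(f"r{i}", "ACGT" * (i + 13), (40,) * (4 * (i + 13)))
        for i in range(3)
    ]
    fq = tmp_path / "in.fastq"
    fa = tmp_path / "out.fasta"
    dx.write_fastq(reads, fq)
    assert dx.convert_fastq_to_fasta(fq, fa) == 3
    out = dx.read_fasta(fa)
    assert [r.read_id for r in out] == [r.read_id for r in reads]
    assert [r.bases for r in out] == [r.bases for r in reads]
    assert all(r.qualities is None for r in out)


def test_fastq_to_fasta_empty_file(tmp_path):
    fq = tmp_path / "in.fastq"
    fq.write_text("")
    assert dx.convert_fastq_to_fasta(fq, tmp_path / "out.fasta") == 0


def test_fastq_roundtrip_against_truth(exhaustive_run, tmp_path):
    reads = [r for s in sorted(exhaustive_run.reads) for r in exhaustive_run.reads[s]]
    fq = tmp_path / "run.fastq"
    dx.write_fastq(reads, fq)
    out = dx.read_fastq(fq)
    assert len(out) == len(reads)
    assert all(a.bases == b.bases for a, b in zip(out, reads))


def test_malformed_fastq_reports_location(tmp_path):
    fq = tmp_path / "bad.fastq"
    fq.write_text("@r1\nACGT\n+\nII\n")  # quality length mismatch
    with pytest.raises(dx.FastqParseError, match="record 1"):
        dx.read_fastq(fq)


# ---------------------------------------------------------------------------
# MID assignment
# ---------------------------------------------------------------------------

def test_decorated_read_assigned_to_its_sample():
    read = dx.SequenceRead("r1", decorated("ACGT" * 20))
    result = dx.assign_by_mid([read], dx.default_manifest(), max_mismatch=0)
    assert [r.read_id for r in result.bins["2149m"]] == ["r1"]
    assert not result.unassigned


def test_featureless_read_unassigned():
    read = dx.SequenceRead("r1", "A" * 120)
    result = dx.assign_by_mid([read], dx.default_manifest())
    assert result.unassigned == [read]
    assert all(not v for v in result.bins.values())


def test_two_mids_in_window_is_ambiguous():
    other = dx.DEFAULT_MIDS["3585m"]
    read = dx.SequenceRead("r1", dx.ION_ADAPTER_A[:10] + MID_2149 + other + "ACGT" * 30)
    result = dx.assign_by_mid([read], dx.default_manifest(), max_mismatch=0)
    assert result.unassigned == [read]


def test_one_mismatch_tolerated_when_allowed():
    mutated = "T" + MID_2149[1:]
    read = dx.SequenceRead("r1", dx.ION_ADAPTER_A + mutated + dx.ECORI_NOTI_LINKER + "ACGT" * 20)
    strict = dx.assign_by_mid([read], dx.default_manifest(), max_mismatch=0)
    assert strict.unassigned == [read]
    lax = dx.assign_by_mid([read], dx.default_manifest(), max_mismatch=1)
    assert [r.read_id for r in lax.bins["2149m"]] == ["r1"]


def test_zero_error_run_fully_recovers_truth(exhaustive_run):
    run = exhaustive_run
    reads = [r for s in sorted(run.reads) for r in run.reads[s]]
    result = dx.demux_reads(reads, run.manifest)
    truth = run.truth.set_index("read_id")
    assert not result.unassigned and not result.short and not result.fully_clipped
    for label, bin_reads in result.bins.items():
        for r in bin_reads:
            assert truth.loc[r.read_id, "sample"] == label
            assert truth.loc[r.read_id, "insert"] == r.bases


# ---------------------------------------------------------------------------
# Clipping
# ---------------------------------------------------------------------------

def test_clip_recovers_exact_insert():
    insert = "ACGTTGCA" * 8  # 64 nt
    read = dx.SequenceRead("r1", decorated(insert))
    entry = dx.default_manifest()["2149m"]
    clipped = dx.clip_decoration(read, entry)
    assert clipped.bases == insert


def test_clip_removes_linker_from_output():
    insert = "TTGACCTG" * 10
    read = dx.SequenceRead("r1", decorated(insert))
    clipped = dx.clip_decoration(read, dx.default_manifest()["2149m"])
    assert dx.ECORI_NOTI_LINKER not in clipped.bases


def test_clip_truncates_at_three_prime_adapter():
    insert = "ACGTTGCA" * 8
    tail = dx._revcomp(dx.ION_ADAPTER_P1) + "GGGG"
    read = dx.SequenceRead("r1", decorated(insert + tail))
    clipped = dx.clip_decoration(read, dx.default_manifest()["2149m"])
    assert clipped.bases == insert


def test_clip_without_three_prime_adapter_removes_only_decoration():
    insert = "ACGTACTG" * 12
    read = dx.SequenceRead("r1", decorated(insert))
    clipped = dx.clip_decoration(read, dx.default_manifest()["2149m"])
    assert clipped.bases == insert
    assert clipped.bases in read.bases  # contiguous substring


def test_fully_clipped_read_routed_to_discard():
    read = dx.SequenceRead("r1", decorated(""))
    result = dx.demux_reads([read], dx.default_manifest())
    assert [r.read_id for r in result.fully_clipped] == ["r1"]
    assert result.n_input == 1


# ---------------------------------------------------------------------------
# Length filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("length,kept", [(50, True), (49, False), (51, True), (1, False)])
def test_min_length_boundary(length, kept):
    reads = [dx.SequenceRead("r1", "A" * length)]
    retained, discarded = dx.filter_min_length(reads, min_len=50)
    assert (len(retained) == 1) is kept
    assert discarded == (0 if kept else 1)


def test_min_length_matches_brute_force_on_clipped_run(exhaustive_run):
    run = exhaustive_run
    reads = [r for s in sorted(run.reads) for r in run.reads[s]]
    result = dx.demux_reads(reads, run.manifest, min_len=50)
    expected = int((run.truth["insert_length"] >= 50).sum())
    assert sum(len(v) for v in result.bins.values()) == expected


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


@given(st.lists(dna, max_size=40))
def test_partition_property(seqs):
    reads = [dx.SequenceRead(f"r{i}", s) for i, s in enumerate(seqs)]
    result = dx.demux_reads(reads, dx.default_manifest())
    assert result.n_input == len(reads)


@given(dna)
def test_clipping_substring_property(insert):
    read = dx.SequenceRead("r1", decorated(insert))
    clipped = dx.clip_decoration(read, dx.default_manifest()["2149m"])
    if clipped is not None:
        assert clipped.bases in read.bases


def test_duplicate_mid_manifest_rejected():
    entries = (
        dx.MIDEntry("a", "ACGCTCGACA"),
        dx.MIDEntry("b", "ACGCTCGACA"),
    )
    with pytest.raises(dx.DemuxError, match="duplicate MID"):
        dx.MIDManifest(entries)
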
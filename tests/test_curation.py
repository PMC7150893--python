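"""Hit-table parsing, thresholds, decontamination, dedup, enumeration."""
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from icemeta import curation as cur


def hit(qseqid="r1", sacc="AB1", sgi=111, length=150, pident=98.0, evalue=1e-40,
        staxid=562, ssciname="Escherichia coli", sskingdom="Bacteria",
        sstart=1, send=150):
    return cur.HitRecord(
        qseqid=qseqid, sacc=sacc, sgi=sgi, length=length, sstart=sstart,
        send=send, pident=pident, evalue=evalue, staxid=staxid,
        sskingdom=sskingdom, ssciname=ssciname,
    )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def test_parse_single_row_field_mapping(tmp_path):
    p = tmp_path / "hits.csv"
    p.write_text("r1,AB1,111,150,1,150,98.7,1e-40,562,Bacteria,Escherichia coli\n")
    (rec,) = cur.parse_hit_table(p)
    assert rec.qseqid == "r1" and rec.sacc == "AB1" and rec.sgi == 111
    assert rec.pident == 98.7 and rec.evalue == 1e-40
    assert rec.staxid == 562 and rec.ssciname == "Escherichia coli"


def test_parse_empty_file(tmp_path):
    p = tmp_path / "hits.csv"
    p.write_text("")
    assert cur.parse_hit_table(p) == []


def test_parse_wrong_field_count_names_row(tmp_path):
    p = tmp_path / "hits.csv"
    p.write_text("r1,AB1,111,150,1,150,98.7,1e-40,562,Bacteria,E coli\nr2,AB1,111\n")
    with pytest.raises(cur.HitTableParseError, match="row 2"):
        cur.parse_hit_table(p)


def test_parse_bad_numeric_names_field(tmp_path):
    p = tmp_path / "hits.csv"
    p.write_text("r1,AB1,xxx,150,1,150,98.7,1e-40,562,Bacteria,E coli\n")
    with pytest.raises(cur.HitTableParseError, match="sgi"):
        cur.parse_hit_table(p)


def test_simulated_tables_roundtrip_losslessly(small_run, tmp_path):
    for sample, rows in small_run.hits.tables.items():
        p = tmp_path / f"{sample}.csv"
        cur.write_hit_table(rows, p)
        back = cur.parse_hit_table(p)
        assert back == rows


# ---------------------------------------------------------------------------
# Thresholds (identity inclusive, e-value strict)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pident,evalue,kept",
    [
        (97.0, 1e-7, True),    # identity floor is inclusive
        (96.9, 1e-30, False),  # below the identity floor
        (99.0, 1e-6, False),   # e-value ceiling is strict
        (99.0, 9.9e-7, True),  # just under the ceiling
    ],
)
def test_threshold_boundaries(pident, evalue, kept):
    out = cur.apply_thresholds([hit(pident=pident, evalue=evalue)])
    assert (len(out) == 1) is kept


# ---------------------------------------------------------------------------
# Control subtraction
# ---------------------------------------------------------------------------

def test_empty_control_is_identity():
    hits = [hit(sgi=1), hit(sgi=2)]
    kept, removed = cur.subtract_control(hits, [])
    assert kept == hits and removed == {}


def test_control_gi_removes_all_sample_rows():
    sample = [hit(qseqid="r1", sgi=111), hit(qseqid="r2", sgi=111), hit(sgi=5)]
    control = [hit(qseqid="c1", sgi=111, pident=99.0)]
    kept, removed = cur.subtract_control(sample, control)
    assert [h.sgi for h in kept] == [5]
    assert removed == {111: 2}


def test_low_identity_control_hit_does_not_implicate():
    sample = [hit(sgi=111)]
    control = [hit(qseqid="c1", sgi=111, pident=90.0)]
    kept, removed = cur.subtract_control(sample, control)
    assert kept == sample and removed == {}


def test_planted_contaminants_removed_exactly(exhaustive_run):
    run = exhaustive_run
    planted = set(run.spec.contaminant_gis)
    for sample, rows in run.hits.tables.items():
        profile, prov = cur.curate(
            rows, run.hits.control, sample_label=sample,
            molecule_metadata=run.metadata,
        )
        assert {int(g) for g in prov["removed_gis"]} == planted
        assert not planted & set(profile.records)


# ---------------------------------------------------------------------------
# Enumeration and dedup
# ---------------------------------------------------------------------------

def test_multiple_hsps_of_one_read_count_once():
    rows = [hit(qseqid="r1"), hit(qseqid="r1", length=80), hit(qseqid="r1", length=60)]
    assert cur.enumerate_reads(rows) == {"AB1": 1}


def test_five_reads_one_accession():
    rows = [hit(qseqid=f"r{i}") for i in range(5)]
    assert cur.enumerate_reads(rows) == {"AB1": 5}


def test_dedup_keeps_lowest_evalue():
    rows = [hit(evalue=1e-12), hit(evalue=1e-30), hit(evalue=1e-8)]
    (kept,) = cur.dedupe_best_hit(rows)
    assert kept.evalue == 1e-30


def test_dedup_breaks_evalue_tie_by_identity():
    rows = [hit(evalue=1e-20, pident=98.0), hit(evalue=1e-20, pident=99.1)]
    (kept,) = cur.dedupe_best_hit(rows)
    assert kept.pident == 99.1


def test_dedup_idempotent_and_stable():
    rows = [hit(sgi=2, evalue=1e-5), hit(sgi=1, evalue=1e-9), hit(sgi=2, evalue=1e-9)]
    once = cur.dedupe_best_hit(rows)
    assert cur.dedupe_best_hit(once) == once
    assert [h.sgi for h in once] == [2, 1]  # first-seen GI order


# ---------------------------------------------------------------------------
# Classification and the full curate chain
# ---------------------------------------------------------------------------

def test_unknown_accession_classified_other_with_warning(caplog):
    rec = hit(sacc="NOPE")
    with caplog.at_level("WARNING"):
        assert cur.classify_molecule(rec, {}) == "other"
    assert "NOPE" in caplog.text


def test_curate_profile_invariants_and_no_hit_fraction(small_run):
    run = small_run
    for sample, rows in run.hits.tables.items():
        n_sample_reads = int((run.truth["sample"] == sample).sum())
        profile, prov = cur.curate(
            rows, run.hits.control, sample_label=sample,
            reads_searched=n_sample_reads, molecule_metadata=run.metadata,
        )
        profile.validate()
        expected_no_hit = run.hits.no_hit_fraction(sample, n_sample_reads)
        assert prov["no_hit_fraction"] == pytest.approx(expected_no_hit)


def test_read_counts_match_truth_multinomial(exhaustive_run):
    run = exhaustive_run
    sample = "3501_3520m"
    profile, _ = cur.curate(
        run.hits.tables[sample], run.hits.control, sample_label=sample,
        molecule_metadata=run.metadata,
    )
    truth = run.truth[run.truth["sample"] == sample]
    planted = set(run.spec.contaminant_gis)
    expected = truth[~truth["gi"].isin(planted)].groupby("gi").size().to_dict()
    observed = {gi: rec.read_count for gi, rec in profile.records.items()}
    assert observed == expected


def test_molecule_class_proportions_follow_mix(exhaustive_run):
    run = exhaustive_run
    truth = run.truth
    gi_to_mix = {t.gi: dict(zip(("rRNA", "mRNA", "other"), t.molecule_class_mix))
                 for t in run.spec.taxa}
    grouped = truth.groupby(["gi", "molecule_class"]).size()
    for (gi, cls), n in grouped.items():
        total = int((truth["gi"] == gi).sum())
        p = gi_to_mix[gi][cls]
        se = math.sqrt(max(total * p * (1 - p), 1.0))
        assert abs(n - total * p) <= 4 * se


# ---------------------------------------------------------------------------
# Property: curate output always satisfies the profile contract
# ---------------------------------------------------------------------------

@st.composite
def random_hits(draw):
    n = draw(st.integers(0, 30))
    rows = []
    for i in range(n):
        rows.append(
            hit(
                qseqid=f"r{draw(st.integers(0, 9))}",
                sgi=draw(st.integers(1, 8)),
                sacc=f"A{draw(st.integers(1, 8))}",
                pident=draw(st.floats(50.0, 100.0)),
                evalue=float(10.0 ** draw(st.integers(-40, 0))),
                length=draw(st.integers(1, 500)),
            )
        )
    return rows


@given(random_hits(), random_hits())
def test_curate_invariants_on_random_tables(sample_rows, control_rows):
    profile, prov = cur.curate(sample_rows, control_rows)
    profile.validate()
    removed = {int(g) for g in prov["removed_gis"]}
    assert not removed & set(profile.records)
    assert prov["hits_after_thresholds"] >= prov["hits_after_control_subtraction"]
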
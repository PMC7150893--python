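"""Trait annotation, category tallies, and the metabolic-capability matrix."""
import pytest

from icemeta import annotation as ann
from icemeta import curation as cur
from icemeta import synthetic as syn


def profile_from(run, sample):
    profile, _ = cur.curate(
        run.hits.tables[sample], run.hits.control, sample_label=sample,
        molecule_metadata=run.metadata,
    )
    return profile


# ---------------------------------------------------------------------------
# Trait table I/O
# ---------------------------------------------------------------------------

def test_trait_table_roundtrip(tmp_path, small_run):
    path = tmp_path / "traits.tsv"
    ann.write_trait_table(small_run.traits, path)
    back = ann.read_trait_table(path)
    assert back == ann.trait_index(small_run.traits)


def test_duplicate_ssciname_rejected(tmp_path):
    entries = [ann.TraitEntry(ssciname="X"), ann.TraitEntry(ssciname="X")]
    with pytest.raises(ann.AnnotationError, match="duplicate"):
        ann.trait_index(entries)


def test_ambiguous_entry_cannot_carry_labels():
    with pytest.raises(ann.AnnotationError, match="ambiguous"):
        ann.TraitEntry(ssciname="X", sources=frozenset({"marine"}), ambiguous=True)


def test_unknown_vocabulary_rejected():
    with pytest.raises(ann.AnnotationError, match="vocabulary"):
        ann.TraitEntry(ssciname="X", processes=frozenset({"levitation"}))


# ---------------------------------------------------------------------------
# Annotation join
# ---------------------------------------------------------------------------

def test_empty_traits_keeps_all_taxa_with_no_labels(exhaustive_run):
    profile = profile_from(exhaustive_run, "3585m")
    annotated = ann.annotate(profile, {})
    assert len(annotated) == len(profile)
    assert all(t.entry is None for t in annotated.taxa)
    summary = ann.summarize_categories(annotated)
    assert summary.n_labeled == 0
    assert sum(summary.source_counts.values()) == 0


def test_ambiguous_taxon_excluded_from_tallies(exhaustive_run):
    run = exhaustive_run
    profile = profile_from(run, "3501_3520m")
    annotated = ann.annotate(profile, ann.trait_index(run.traits))
    amb = [t for t in annotated.taxa if t.ssciname.startswith("uncultured")]
    assert amb and not amb[0].labeled
    # still counted toward domain/phylum
    summary = ann.summarize_categories(annotated)
    assert sum(summary.domain_counts.values()) == len(profile)


def test_category_tallies_equal_brute_force(exhaustive_run):
    run = exhaustive_run
    traits = ann.trait_index(run.traits)
    profile = profile_from(run, "3540_3569m")
    annotated = ann.annotate(profile, traits)
    summary = ann.summarize_categories(annotated)
    detected = {rec.best.ssciname for rec in profile.records.values()}
    for cat in ann.SOURCE_CATEGORIES:
        expected = sum(
            1
            for name in detected
            if name in traits
            and not traits[name].ambiguous
            and cat in traits[name].sources
        )
        assert summary.source_counts[cat] == expected
    for cat in ann.PHYSIOLOGY_CATEGORIES:
        expected = sum(
            1
            for name in detected
            if name in traits
            and not traits[name].ambiguous
            and cat in traits[name].physiologies
        )
        assert summary.physiology_counts[cat] == expected


def test_multi_source_taxon_counts_in_each_category():
    entry = ann.TraitEntry(
        ssciname="X", domain="Bacteria", phylum="Bacteroidetes",
        sources=frozenset({"marine", "aquatic_freshwater"}),
    )
    taxon = ann.AnnotatedTaxon(
        gi=1, sacc="A1", ssciname="X", read_count=1, molecule_class="other",
        domain="Bacteria", phylum="Bacteroidetes", entry=entry,
    )
    summary = ann.summarize_categories(ann.AnnotatedProfile("s", [taxon]))
    assert summary.source_counts["marine"] == 1
    assert summary.source_counts["aquatic_freshwater"] == 1


def test_empty_profile_summary_is_all_zero():
    summary = ann.summarize_categories(ann.AnnotatedProfile("s", []))
    assert summary.n_taxa == 0
    assert all(v == 0 for v in summary.source_counts.values())
    assert all(v == 0 for v in summary.physiology_counts.values())


# ---------------------------------------------------------------------------
# Metabolic matrix
# ---------------------------------------------------------------------------

def _single_taxon_profile(sample, name, phylum, process):
    entry = ann.TraitEntry(
        ssciname=name, domain="Bacteria", phylum=phylum,
        processes=frozenset({process}),
    )
    taxon = ann.AnnotatedTaxon(
        gi=hash(name) % 10_000 + 1, sacc="A", ssciname=name, read_count=1,
        molecule_class="other", domain="Bacteria", phylum=phylum, entry=entry,
    )
    return ann.AnnotatedProfile(sample, [taxon])


def test_iron_oxidizer_appears_in_both_groups():
    iron = "Iron oxidation"
    profiles = [
        _single_taxon_profile("s1", "Ferriphilus basalis", "Betaproteobacteria", iron),
        _single_taxon_profile("s2", "Ferriphilus lacustris", "Betaproteobacteria", iron),
    ]
    matrix = ann.build_metabolic_matrix(profiles, {"s1": "basal", "s2": "accretion"})
    assert matrix.loc[iron, "basal"] == "βP"
    assert matrix.loc[iron, "accretion"] == "βP"


def test_absent_process_renders_nd():
    profiles = [
        _single_taxon_profile("s1", "X y", "Betaproteobacteria", "Iron oxidation")
    ]
    matrix = ann.build_metabolic_matrix(profiles, {"s1": "basal"})
    assert matrix.loc["Manganese oxidation", "basal"] == ann.EMPTY_CELL


def test_reference_matrix_rebuilt_cell_for_cell():
    ref = ann.load_reference_metabolic_matrix()
    profiles, grouping = syn.metabolic_reference_community()
    rebuilt = ann.build_metabolic_matrix(profiles, grouping, processes=list(ref.index))
    for process in ref.index:
        for group in ref.columns:
            assert ann.matrix_cell_set(rebuilt.loc[process, group]) == \
                ann.matrix_cell_set(ref.loc[process, group]), (process, group)


def test_reference_matrix_spot_values():
    ref = ann.load_reference_metabolic_matrix()
    assert ann.matrix_cell_set(ref.loc["Iron oxidation", "basal"]) == {"βP"}
    assert ann.matrix_cell_set(ref.loc["Manganese oxidation", "basal"]) == set()
    assert ann.matrix_cell_set(ref.loc["Manganese oxidation", "accretion"]) == {"δP"}


def test_annotation_is_order_invariant(exhaustive_run):
    run = exhaustive_run
    traits = ann.trait_index(run.traits)
    profile = profile_from(run, "3585m")
    annotated = ann.annotate(profile, traits)
    reversed_profile = cur.CuratedProfile(
        sample_label=profile.sample_label,
        records=dict(reversed(list(profile.records.items()))),
    )
    annotated_rev = ann.annotate(reversed_profile, traits)
    a = ann.summarize_categories(annotated)
    b = ann.summarize_categories(annotated_rev)
    assert a.source_counts == b.source_counts
    assert a.physiology_counts == b.physiology_counts
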
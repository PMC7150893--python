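"""Trait annotation of curated community profiles.

Each curated taxon is joined — by exact scientific name, at the
species/strain level — to a declarative trait table that records where
the organism has been reported from (soil/sediment, freshwater, marine,
permafrost/ice, animal, plant), its physiology (psychrophilic,
thermophilic, halophilic, alkaliphilic, acidophilic,
desiccation-resistant, mesophilic), its trophic mode, and the metabolic
processes it can carry out (nitrogen cycling, carbon fixation, metal and
sulfur redox chemistry).  Entries flagged ambiguous carry no category
labels: a determination is only made when the literature evidence is
unambiguous.  Category tallies count unique taxa and use set semantics —
one organism may contribute to several source or physiology categories.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .curation import CuratedProfile

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Invalid trait table or annotation request."""


SOURCE_CATEGORIES: tuple[str, ...] = (
    "soil_sediment",
    "aquatic_freshwater",
    "marine",
    "permafrost_ice",
    "animal",
    "plant",
)

# One-letter figure codes for the source categories.
SOURCE_CODES: dict[str, str] = {
    "soil_sediment": "S",
    "aquatic_freshwater": "W",
    "marine": "M",
    "permafrost_ice": "I",
    "animal": "A",
    "plant": "P",
}

PHYSIOLOGY_CATEGORIES: tuple[str, ...] = (
    "psychrophilic_psychrotolerant",
    "thermophilic_thermotolerant",
    "halophilic_halotolerant",
    "alkaliphilic_alkalitolerant",
    "acidophilic_acidotolerant",
    "desiccation_resistant",
    "mesophilic",
)

PHYSIOLOGY_CODES: dict[str, str] = {
    "psychrophilic_psychrotolerant": "P",
    "thermophilic_thermotolerant": "T",
    "halophilic_halotolerant": "H",
    "alkaliphilic_alkalitolerant": "K",
    "acidophilic_acidotolerant": "C",
    "desiccation_resistant": "D",
    "mesophilic": "Me",
}

TROPHIC_MODES: tuple[str, ...] = ("heterotroph", "chemolithoautotroph", "photoautotroph")

DOMAINS: tuple[str, ...] = ("Archaea", "Bacteria", "Eukarya")

# Metabolic-process vocabulary (nitrogen cycle, carbon fixation, redox).
PROCESSES: tuple[str, ...] = (
    "Nitrogen fixation (N2 -> NH4+)",
    "Nitrification (NH4+ -> NO2-)",
    "Nitrification (NO2- -> NO3-)",
    "Denitrification (NO2- -> NH4+)",
    "Denitrification (NO3- -> NO2-)",
    "Denitrification (NO3- -> N2)",
    "Nitrate reduction (NO3- -> NH4+)",
    "Assimilation (NH4+ -> organic)",
    "Decomposition (organic -> NH4+)",
    "Anammox (NH4+ + NO2- -> N2)",
    "Carbon fixation: reductive pentose phosphate",
    "Carbon fixation: reductive TCA",
    "Carbon fixation: reductive acetyl-CoA",
    "Carbon fixation: 3-hydroxypropionate bicycle",
    "C-1 metabolism",
    "Arsenic oxidation",
    "Arsenate reduction",
    "Chromium reduction",
    "Iron oxidation",
    "Iron reduction",
    "Manganese oxidation",
    "Methylotrophy",
    "Sulfur oxidation",
    "Sulfate reduction",
    "Uranium oxidation",
    "Uranium reduction",
)

# Short phylum codes used in the metabolic-capability matrix.
PHYLUM_CODES: dict[str, str] = {
    "Actinobacteria": "Ac",
    "Acidobacteria": "Ad",
    "Alphaproteobacteria": "αP",
    "Archaea": "Ar",
    "Euryarchaeota": "Ar",
    "Ascomycota": "As",
    "Bacteroidetes": "Ba",
    "Basidiomycota": "Bd",
    "Betaproteobacteria": "βP",
    "Chlorobi": "Cb",
    "Chlorophyta": "Ch",
    "Cyanobacteria": "Cy",
    "Deinococcus-Thermus": "DT",
    "Deltaproteobacteria": "δP",
    "Epsilonproteobacteria": "εP",
    "Firmicutes": "Fi",
    "Gammaproteobacteria": "γP",
    "Planctomycetes": "Pl",
}

EMPTY_CELL = "nd"  # rendered value for a metabolic-matrix cell with no taxa


def phylum_code(phylum: str) -> str:
    """Short code for a phylum; unknown phyla pass through verbatim."""
    return PHYLUM_CODES.get(phylum, phylum)


@dataclass(frozen=True)
class TraitEntry:
    """Declarative habitat/physiology/metabolism labels for one species."""

    ssciname: str
    domain: str = ""
    phylum: str = ""
    sources: frozenset[str] = frozenset()
    physiologies: frozenset[str] = frozenset()
    trophic: Optional[str] = None
    processes: frozenset[str] = frozenset()
    evidence: str = ""
    ambiguous: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sources) - set(SOURCE_CATEGORIES)
        if bad:
            raise AnnotationError(
                f"{self.ssciname!r}: unknown source(s) {sorted(bad)}; "
                f"vocabulary: {list(SOURCE_CATEGORIES)}"
            )
        bad = set(self.physiologies) - set(PHYSIOLOGY_CATEGORIES)
        if bad:
            raise AnnotationError(
                f"{self.ssciname!r}: unknown physiology(ies) {sorted(bad)}; "
                f"vocabulary: {list(PHYSIOLOGY_CATEGORIES)}"
            )
        if self.trophic is not None and self.trophic not in TROPHIC_MODES:
            raise AnnotationError(
                f"{self.ssciname!r}: unknown trophic mode {self.trophic!r}"
            )
        bad = set(self.processes) - set(PROCESSES)
        if bad:
            raise AnnotationError(
                f"{self.ssciname!r}: unknown process(es) {sorted(bad)}; "
                f"vocabulary: {list(PROCESSES)}"
            )
        if self.ambiguous and (self.sources or self.physiologies):
            raise AnnotationError(
                f"{self.ssciname!r}: ambiguous entries must carry no "
                "source/physiology labels"
            )


_TRAIT_COLUMNS = (
    "ssciname",
    "domain",
    "phylum",
    "sources",
    "physiologies",
    "trophic",
    "processes",
    "evidence",
    "ambiguous",
)


def write_trait_table(entries: Iterable[TraitEntry], path: str | Path) -> None:
    """Write a trait table as TSV with a header; multi-valued fields use ';'."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_TRAIT_COLUMNS)
        for e in entries:
            w.writerow(
                [
                    e.ssciname,
                    e.domain,
                    e.phylum,
                    ";".join(sorted(e.sources)),
                    ";".join(sorted(e.physiologies)),
                    e.trophic or "",
                    ";".join(sorted(e.processes)),
                    e.evidence,
                    "true" if e.ambiguous else "false",
                ]
            )


def read_trait_table(path: str | Path) -> dict[str, TraitEntry]:
    """Parse a TSV trait table; duplicate species names are an error."""
    entries: dict[str, TraitEntry] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            name = row["ssciname"]
            if name in entries:
                raise AnnotationError(f"duplicate ssciname {name!r} (row {i})")
            split = lambda s: frozenset(x for x in (s or "").split(";") if x)
            entries[name] = TraitEntry(
                ssciname=name,
                domain=row.get("domain", "") or "",
                phylum=row.get("phylum", "") or "",
                sources=split(row.get("sources")),
                physiologies=split(row.get("physiologies")),
                trophic=(row.get("trophic") or None),
                processes=split(row.get("processes")),
                evidence=row.get("evidence", "") or "",
                ambiguous=(row.get("ambiguous", "false").strip().lower() == "true"),
            )
    return entries


def trait_index(entries: Iterable[TraitEntry]) -> dict[str, TraitEntry]:
    out: dict[str, TraitEntry] = {}
    for e in entries:
        if e.ssciname in out:
            raise AnnotationError(f"duplicate ssciname {e.ssciname!r} in trait table")
        out[e.ssciname] = e
    return out


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotatedTaxon:
    """One curated taxon joined (or not) to its trait entry."""

    gi: int
    sacc: str
    ssciname: str
    read_count: int
    molecule_class: str
    domain: str
    phylum: str
    entry: Optional[TraitEntry] = None

    @property
    def labeled(self) -> bool:
        """True when the taxon contributes to source/physiology tallies."""
        return self.entry is not None and not self.entry.ambiguous


@dataclass
class AnnotatedProfile:
    sample_label: str
    taxa: list[AnnotatedTaxon]

    def __len__(self) -> int:
        return len(self.taxa)


def annotate(
    profile: CuratedProfile, traits: Mapping[str, TraitEntry] | Iterable[TraitEntry]
) -> AnnotatedProfile:
    """Join curated taxa to trait entries by exact scientific name.

    The join is total: taxa with no trait entry, or with an ambiguous
    one, stay in the profile but carry no category labels.  Domain falls
    back to the hit's super-kingdom when the trait table is silent.
    """
    if not isinstance(traits, Mapping):
        traits = trait_index(traits)
    taxa: list[AnnotatedTaxon] = []
    for gi in sorted(profile.records):
        rec = profile.records[gi]
        entry = traits.get(rec.best.ssciname)
        domain = entry.domain if entry is not None and entry.domain else rec.best.sskingdom
        phylum = entry.phylum if entry is not None else ""
        taxa.append(
            AnnotatedTaxon(
                gi=gi,
                sacc=rec.best.sacc,
                ssciname=rec.best.ssciname,
                read_count=rec.read_count,
                molecule_class=rec.molecule_class,
                domain=domain,
                phylum=phylum,
                entry=entry,
            )
        )
    return AnnotatedProfile(sample_label=profile.sample_label, taxa=taxa)


@dataclass
class CategorySummary:
    """Per-sample unique-taxon tallies by source, physiology and taxonomy."""

    sample_label: str
    source_counts: dict[str, int]
    physiology_counts: dict[str, int]
    domain_counts: dict[str, int]
    phylum_counts: dict[str, int]
    trophic_counts: dict[str, int]
    n_taxa: int
    n_labeled: int
    # process -> set of phylum codes of contributing taxa
    process_phyla: dict[str, set[str]] = field(default_factory=dict)


def summarize_categories(profile: AnnotatedProfile) -> CategorySummary:
    """Tally unique taxa per category (set semantics: one taxon may count
    toward several sources or physiologies)."""
    src = {c: 0 for c in SOURCE_CATEGORIES}
    phys = {c: 0 for c in PHYSIOLOGY_CATEGORIES}
    dom: dict[str, int] = {}
    phyl: dict[str, int] = {}
    troph: dict[str, int] = {}
    proc: dict[str, set[str]] = {}
    n_labeled = 0
    for t in profile.taxa:
        dom[t.domain or "unknown"] = dom.get(t.domain or "unknown", 0) + 1
        key = t.phylum if t.phylum else "+"
        phyl[key] = phyl.get(key, 0) + 1
        if not t.labeled:
            continue
        n_labeled += 1
        for s in t.entry.sources:
            src[s] += 1
        for p in t.entry.physiologies:
            phys[p] += 1
        if t.entry.trophic:
            troph[t.entry.trophic] = troph.get(t.entry.trophic, 0) + 1
        for pr in t.entry.processes:
            proc.setdefault(pr, set()).add(phylum_code(t.phylum))
    return CategorySummary(
        sample_label=profile.sample_label,
        source_counts=src,
        physiology_counts=phys,
        domain_counts=dom,
        phylum_counts=phyl,
        trophic_counts=troph,
        n_taxa=len(profile.taxa),
        n_labeled=n_labeled,
        process_phyla=proc,
    )


def summary_frame(summaries: Sequence[CategorySummary]) -> pd.DataFrame:
    """Long-format DataFrame of all category tallies, one row per count."""
    rows = []
    for s in summaries:
        for kind, counts in (
            ("source", s.source_counts),
            ("physiology", s.physiology_counts),
            ("domain", s.domain_counts),
            ("phylum", s.phylum_counts),
            ("trophic", s.trophic_counts),
        ):
            for cat, n in counts.items():
                rows.append(
                    {"sample": s.sample_label, "kind": kind, "category": cat, "count": n}
                )
    return pd.DataFrame(rows, columns=["sample", "kind", "category", "count"])


# ---------------------------------------------------------------------------
# Metabolic-capability matrix
# ---------------------------------------------------------------------------

def build_metabolic_matrix(
    profiles: Iterable[AnnotatedProfile],
    grouping: Mapping[str, str],
    processes: Sequence[str] = PROCESSES,
) -> pd.DataFrame:
    """Process x group matrix of phylum-code sets.

    Cell (process, group) is the union of the phylum codes of the taxa —
    pooled over the samples mapped to that group — whose trait entry
    carries that process.  Empty cells render as ``"nd"``.
    """
    groups = sorted(set(grouping.values()))
    cells: dict[tuple[str, str], set[str]] = {}
    for profile in profiles:
        group = grouping.get(profile.sample_label)
        if group is None:
            continue
        for t in profile.taxa:
            if not t.labeled:
                continue
            for pr in t.entry.processes:
                if pr not in PROCESSES:
                    raise AnnotationError(
                        f"unknown process {pr!r}; vocabulary: {list(PROCESSES)}"
                    )
                cells.setdefault((pr, group), set()).add(phylum_code(t.phylum))
    data = {
        g: [
            ", ".join(sorted(cells.get((pr, g), set()))) or EMPTY_CELL
            for pr in processes
        ]
        for g in groups
    }
    return pd.DataFrame(data, index=list(processes))


def load_reference_metabolic_matrix() -> pd.DataFrame:
    """Packaged reference matrix of metabolic capabilities by ice type.

    Columns ``basal`` and ``accretion`` hold comma-separated phylum
    codes (or ``nd``); used as a regression fixture for
    :func:`build_metabolic_matrix`.
    """
    with resources.files("icemeta.data").joinpath("metabolic_capabilities.tsv").open(
        encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh, sep="\t", index_col="process", dtype=str).fillna(EMPTY_CELL)
    return df


def matrix_cell_set(cell: str) -> frozenset[str]:
    """Parse a matrix cell into its set of codes (empty for ``nd``)."""
    if not cell or cell == EMPTY_CELL:
        return frozenset()
    return frozenset(x.strip() for x in cell.split(",") if x.strip())
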
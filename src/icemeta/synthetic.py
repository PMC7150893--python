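"""Synthetic multiplexed ice-core sequencing data with known ground truth.

Emulates the study design end to end: a small multi-domain community
with trait labels is sampled into decorated reads

    <platform adapter A> + <10-nt MID> + <EcoRI/NotI linker> + insert

for four ice-core depth pools plus a sterile-water control; tabular
homology hits in the 11-field layout are then fabricated for each read,
with planted sub-threshold noise, duplicate-GI rows at worse e-values,
a configurable no-hit fraction (one third of reads by default), and
contaminant taxa that also surface in the control hit table.  Every
stochastic draw is seeded, so identical specs give bit-identical FASTQ,
hit tables and truth maps.

Nothing here claims real database identity: GI numbers, accessions and
taxon ids are synthetic integers/strings.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from .annotation import TraitEntry
from .curation import HitRecord, write_hit_table
from .demux import (
    ECORI_NOTI_LINKER,
    ION_ADAPTER_A,
    MIDManifest,
    SequenceRead,
    default_manifest,
    write_fastq,
)

_BASES = np.array(list("ACGT"))
ABUNDANCE_TOL = 1e-9
DEFAULT_NO_HIT_RATE = 0.33  # fraction of reads that return no hit at all
CONTROL_LABEL = "control"


class SyntheticValidationError(ValueError):
    """Community spec violates an invariant."""


@dataclass(frozen=True)
class TaxonSpec:
    """One community member with its surrogate database identity."""

    sciname: str
    gi: int
    taxid: int
    domain: str
    phylum: str
    abundance: float
    traits: TraitEntry
    molecule_class_mix: tuple[float, float, float] = (0.7, 0.2, 0.1)  # rRNA, mRNA, other
    reference_length: int = 3000

    def __post_init__(self) -> None:
        if self.gi <= 0 or self.taxid <= 0:
            raise SyntheticValidationError(
                f"{self.sciname!r}: gi and taxid must be positive integers"
            )
        s = sum(self.molecule_class_mix)
        if abs(s - 1.0) > ABUNDANCE_TOL:
            raise SyntheticValidationError(
                f"{self.sciname!r}: molecule_class_mix sums to {s!r}, expected 1"
            )
        if not (0.0 <= self.abundance <= 1.0):
            raise SyntheticValidationError(
                f"{self.sciname!r}: abundance {self.abundance} outside [0, 1]"
            )


@dataclass(frozen=True)
class CommunitySpec:
    """Ground-truth community: taxa, abundances, planted contaminants."""

    taxa: tuple[TaxonSpec, ...]
    n_reads_per_sample: int = 2000
    insert_length_range: tuple[int, int] = (50, 1000)
    per_base_error_rate: float = 0.0
    contaminant_gis: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.taxa:
            raise SyntheticValidationError("community has no taxa")
        gis = [t.gi for t in self.taxa]
        if len(set(gis)) != len(gis):
            raise SyntheticValidationError("duplicate GI numbers in community")
        total = sum(t.abundance for t in self.taxa)
        if abs(total - 1.0) > ABUNDANCE_TOL:
            raise SyntheticValidationError(
                f"relative abundances sum to {total!r}, expected 1 within {ABUNDANCE_TOL}"
            )
        lo, hi = self.insert_length_range
        if lo < 1 or hi < lo:
            raise SyntheticValidationError(
                f"invalid insert_length_range {self.insert_length_range}"
            )
        if not (0.0 <= self.per_base_error_rate <= 1.0):
            raise SyntheticValidationError("per_base_error_rate outside [0, 1]")
        if not self.contaminant_gis <= set(gis):
            raise SyntheticValidationError(
                "contaminant_gis must be a subset of the community's GIs"
            )
        if self.n_reads_per_sample <= 0:
            raise SyntheticValidationError("n_reads_per_sample must be positive")

    @property
    def contaminants(self) -> tuple[TaxonSpec, ...]:
        return tuple(t for t in self.taxa if t.gi in self.contaminant_gis)

    def taxon(self, gi: int) -> TaxonSpec:
        for t in self.taxa:
            if t.gi == gi:
                return t
        raise KeyError(gi)


def simulate_community(
    spec: CommunitySpec, samples: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Normalized expected read share per taxon and sample.

    Deterministic for a fixed spec; every sample draws from the same
    community, so the columns are identical normalized shares.
    """
    if samples is None:
        samples = [
            e.sample_label for e in default_manifest() if e.sample_label != CONTROL_LABEL
        ]
    shares = np.array([t.abundance for t in spec.taxa], dtype=float)
    shares = shares / shares.sum()
    return pd.DataFrame(
        {s: shares for s in samples}, index=[t.sciname for t in spec.taxa]
    )


def reference_sequence(spec: CommunitySpec, taxon: TaxonSpec) -> str:
    """Deterministic surrogate reference sequence for one taxon."""
    rng = np.random.default_rng([spec.seed, taxon.gi, 7])
    return "".join(rng.choice(_BASES, size=taxon.reference_length))


_CLASS_SUFFIX = {"rRNA": "r", "mRNA": "m", "other": "o"}


def accession_for(taxon: TaxonSpec, molecule_class: str) -> str:
    """Synthetic accession; one per (taxon, molecule class)."""
    return f"SYN{taxon.gi}.{_CLASS_SUFFIX[molecule_class]}"


def molecule_metadata(spec: CommunitySpec) -> dict[str, str]:
    """Accession -> molecule class map for the whole community."""
    return {
        accession_for(t, cls): cls for t in spec.taxa for cls in _CLASS_SUFFIX
    }


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _mutate(bases: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return bases
    arr = np.frombuffer(bases.encode(), dtype="S1").astype("U1")
    hit = rng.random(len(arr)) < rate
    if not hit.any():
        return bases
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_reads(
    spec: CommunitySpec,
    manifest: Optional[MIDManifest] = None,
    control_label: str = CONTROL_LABEL,
    n_control_reads: Optional[int] = None,
) -> tuple[dict[str, list[SequenceRead]], pd.DataFrame]:
    """Decorated FASTQ-style reads per sample plus the truth map.

    Community samples draw taxa multinomially by abundance; the control
    sample draws only from the planted contaminants (renormalized), with
    a tenth of the per-sample depth by default.  The truth map records
    (read_id, sample, gi, sciname, insert, insert length, molecule
    class) for every read.
    """
    if manifest is None:
        manifest = default_manifest()
    if n_control_reads is None:
        n_control_reads = max(spec.n_reads_per_sample // 10, 1)
    refs = {t.gi: reference_sequence(spec, t) for t in spec.taxa}
    abunds = np.array([t.abundance for t in spec.taxa], dtype=float)
    abunds = abunds / abunds.sum()
    mixes = np.array([t.molecule_class_mix for t in spec.taxa], dtype=float)
    lo, hi = spec.insert_length_range

    reads: dict[str, list[SequenceRead]] = {}
    truth_rows: list[dict] = []
    for sample_idx, entry in enumerate(manifest):
        sample = entry.sample_label
        rng = np.random.default_rng([spec.seed, 101, sample_idx])
        if sample == control_label:
            contams = spec.contaminants
            if not contams:
                reads[sample] = []
                continue
            p = np.array([t.abundance for t in contams], dtype=float)
            pool = list(contams)
            p = p / p.sum()
            n = n_control_reads
        else:
            pool = list(spec.taxa)
            p = abunds
            n = spec.n_reads_per_sample
        chosen = rng.choice(len(pool), size=n, p=p)
        sample_reads: list[SequenceRead] = []
        for i, ti in enumerate(chosen):
            taxon = pool[ti]
            ref = refs[taxon.gi]
            max_len = min(hi, taxon.reference_length)
            length = int(rng.integers(lo, max_len + 1))
            start = int(rng.integers(0, taxon.reference_length - length + 1))
            insert = ref[start : start + length]
            full_mix = mixes[[t.gi for t in spec.taxa].index(taxon.gi)]
            cls = ("rRNA", "mRNA", "other")[int(rng.choice(3, p=full_mix))]
            read_id = f"{sample}:r{i:05d}"
            decorated = ION_ADAPTER_A + entry.mid + entry.linker + insert
            decorated = _mutate(decorated, spec.per_base_error_rate, rng)
            sample_reads.append(
                SequenceRead(
                    read_id=read_id,
                    bases=decorated,
                    qualities=(40,) * len(decorated),
                )
            )
            truth_rows.append(
                {
                    "read_id": read_id,
                    "sample": sample,
                    "gi": taxon.gi,
                    "sciname": taxon.sciname,
                    "insert": insert,
                    "insert_length": length,
                    "molecule_class": cls,
                }
            )
        reads[sample] = sample_reads
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "sample",
            "gi",
            "sciname",
            "insert",
            "insert_length",
            "molecule_class",
        ],
    )
    return reads, truth


# ---------------------------------------------------------------------------
# Hit-table simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedHits:
    """Fabricated hit tables plus the bookkeeping needed by oracles."""

    tables: dict[str, list[HitRecord]]
    control: list[HitRecord]
    no_hit_reads: dict[str, set]  # sample -> read ids given no hit at all

    def no_hit_fraction(self, sample: str, n_reads: int) -> float:
        return len(self.no_hit_reads.get(sample, set())) / n_reads if n_reads else 0.0


def _true_row(
    read: pd.Series,
    taxon: TaxonSpec,
    rng: np.random.Generator,
    min_true_pident: float,
    max_true_evalue: float,
) -> HitRecord:
    pident = float(rng.uniform(min_true_pident, 100.0))
    evalue = float(10.0 ** rng.uniform(-40.0, math.log10(max_true_evalue)))
    return HitRecord(
        qseqid=read["read_id"],
        sacc=accession_for(taxon, read["molecule_class"]),
        sgi=taxon.gi,
        length=int(read["insert_length"]),
        sstart=1,
        send=int(read["insert_length"]),
        pident=round(pident, 3),
        evalue=evalue,
        staxid=taxon.taxid,
        sskingdom=taxon.domain,
        ssciname=taxon.sciname,
    )


def simulate_hit_table(
    truth: pd.DataFrame,
    spec: CommunitySpec,
    min_true_pident: float = 97.0,
    max_true_evalue: float = 1e-7,
    no_hit_rate: float = DEFAULT_NO_HIT_RATE,
    dup_rate: float = 0.3,
    decoy_rate: float = 0.5,
    control_label: str = CONTROL_LABEL,
) -> SimulatedHits:
    """Fabricate per-sample hit tables (and the control table) from truth.

    Per read with a hit: one true-taxon row with pident >= the floor and
    e-value <= the ceiling; optionally 1–3 duplicate rows for the same
    GI at strictly worse e-values; optionally 1–3 sub-threshold decoy
    rows (identity < 97 or e-value >= 1e-6) against decoy GIs.  At most
    20 rows per read, mirroring a 20-target search cap.  Every planted
    contaminant GI is guaranteed to appear in the control table at
    >= 97% identity.
    """
    if truth.empty:
        raise SyntheticValidationError("truth map is empty")
    tables: dict[str, list[HitRecord]] = {}
    no_hit: dict[str, set] = {}
    rng = np.random.default_rng([spec.seed, 202])
    decoy_gi_base = 9_000_000
    for sample, sub in truth.groupby("sample", sort=True):
        rows: list[HitRecord] = []
        skipped: set = set()
        for _, read in sub.iterrows():
            if rng.random() < no_hit_rate:
                skipped.add(read["read_id"])
                continue
            taxon = spec.taxon(int(read["gi"]))
            true = _true_row(read, taxon, rng, min_true_pident, max_true_evalue)
            rows.append(true)
            if rng.random() < dup_rate:
                for _ in range(int(rng.integers(1, 4))):
                    # strictly worse than the true row, still under threshold
                    worse_e = min(true.evalue * 10.0 ** rng.uniform(1.0, 8.0), 9e-7)
                    rows.append(
                        replace(
                            true,
                            evalue=float(worse_e),
                            pident=round(float(rng.uniform(97.0, true.pident)), 3),
                            length=max(int(true.length * rng.uniform(0.5, 0.95)), 1),
                        )
                    )
            if rng.random() < decoy_rate:
                for _ in range(int(rng.integers(1, 4))):
                    gi = decoy_gi_base + int(rng.integers(0, 5000))
                    if rng.random() < 0.5:  # identity violation
                        pid = round(float(rng.uniform(70.0, 96.9)), 3)
                        ev = float(10.0 ** rng.uniform(-20.0, -7.0))
                    else:  # e-value violation
                        pid = round(float(rng.uniform(97.0, 100.0)), 3)
                        ev = float(10.0 ** rng.uniform(-5.9, 1.0))
                    rows.append(
                        HitRecord(
                            qseqid=read["read_id"],
                            sacc=f"DEC{gi}",
                            sgi=gi,
                            length=int(read["insert_length"]),
                            sstart=1,
                            send=int(read["insert_length"]),
                            pident=pid,
                            evalue=ev,
                            staxid=gi,
                            sskingdom="Bacteria",
                            ssciname=f"decoy organism {gi}",
                        )
                    )
        tables[sample] = rows
        no_hit[sample] = skipped

    control = tables.pop(control_label, [])
    # Invariant: every planted contaminant appears in the control table
    # at >= 97% identity, even if no control read drew it.
    present = {h.sgi for h in control if h.pident >= 97.0}
    for i, taxon in enumerate(spec.contaminants):
        if taxon.gi not in present:
            control.append(
                HitRecord(
                    qseqid=f"{control_label}:forced{i:03d}",
                    sacc=accession_for(taxon, "other"),
                    sgi=taxon.gi,
                    length=100,
                    sstart=1,
                    send=100,
                    pident=99.0,
                    evalue=1e-30,
                    staxid=taxon.taxid,
                    sskingdom=taxon.domain,
                    ssciname=taxon.sciname,
                )
            )
    return SimulatedHits(tables=tables, control=control, no_hit_reads=no_hit)


# ---------------------------------------------------------------------------
# Association dataset
# ---------------------------------------------------------------------------

COVARIATES: tuple[str, ...] = ("Na", "K", "Ca", "Mg", "Cl", "SO4", "NPOC", "AA")

# Draw ranges spanning the measured profiles: ions in µmol/L, NPOC and
# total amino acids in mol/L.
COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "Na": (4.0, 40.0),
    "K": (0.5, 1.5),
    "Ca": (1.0, 32.0),
    "Mg": (3.0, 30.0),
    "Cl": (2.0, 30.0),
    "SO4": (1.0, 32.0),
    "NPOC": (9e-7, 2e-6),
    "AA": (1e-8, 3e-7),
}

HABITATS: tuple[str, ...] = (
    "soil",
    "freshwater",
    "marine",
    "ice",
    "animal_associated",
    "plant_associated",
)


def standardized(values: np.ndarray, name: str) -> np.ndarray:
    """Z-score a covariate using the theoretical moments of its uniform
    draw range (mean (a+b)/2, sd (b-a)/sqrt(12))."""
    a, b = COVARIATE_RANGES[name]
    return (values - (a + b) / 2.0) / ((b - a) / math.sqrt(12.0))


def simulate_association_dataset(
    betas: Optional[Mapping[str, float]] = None,
    dispersion: float = 2.0,
    n_habitats: int = 6,
    n_obs: int = 600,
    seed: int = 0,
    sigma_u: float = 0.5,
    intercept: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Habitat-structured overdispersed count data with known parameters.

    log(mu) = intercept + sum(beta_c * z_c) + u_habitat with z_c the
    standardized covariate and u ~ Normal(0, sigma_u^2); counts are
    negative-binomial (NB2) with the given dispersion.  Betas are
    effects per 1 SD of the covariate.  Returns (data, ground truth).
    """
    if dispersion <= 0:
        raise SyntheticValidationError(f"dispersion must be > 0, got {dispersion}")
    if not (n_obs >= n_habitats >= 2):
        raise SyntheticValidationError(
            f"need n_obs >= n_habitats >= 2, got {n_obs}, {n_habitats}"
        )
    betas = dict(betas or {})
    unknown = set(betas) - set(COVARIATES)
    if unknown:
        raise SyntheticValidationError(f"unknown covariate(s) {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    habitats = [HABITATS[i % n_habitats] for i in range(n_obs)]
    u = rng.normal(0.0, sigma_u, size=n_habitats)
    u_obs = np.array([u[i % n_habitats] for i in range(n_obs)])
    data: dict[str, np.ndarray] = {}
    eta = np.full(n_obs, float(intercept))
    for name in COVARIATES:
        a, b = COVARIATE_RANGES[name]
        x = rng.uniform(a, b, size=n_obs)
        data[name] = x
        eta += betas.get(name, 0.0) * standardized(x, name)
    eta += u_obs
    mu = np.exp(np.clip(eta, -30, 30))
    counts = rng.negative_binomial(dispersion, dispersion / (dispersion + mu))
    df = pd.DataFrame(
        {
            "habitat": habitats,
            "depth_label": [f"depth_{i // n_habitats:03d}" for i in range(n_obs)],
            "species_count": counts.astype(int),
            **data,
        }
    )
    truth = {
        "betas": {c: betas.get(c, 0.0) for c in COVARIATES},
        "dispersion": dispersion,
        "sigma_u": sigma_u,
        "intercept": intercept,
        "random_intercepts": {HABITATS[i]: float(u[i]) for i in range(n_habitats)},
    }
    return df, truth


def simulate_geochemistry(
    depth_labels: Sequence[str], seed: int = 0
) -> pd.DataFrame:
    """Depth-indexed covariate table drawn from the measured ranges."""
    rng = np.random.default_rng([seed, 303])
    data = {"depth_label": list(depth_labels)}
    for name in COVARIATES:
        a, b = COVARIATE_RANGES[name]
        data[name] = rng.uniform(a, b, size=len(depth_labels))
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Default community
# ---------------------------------------------------------------------------

def _taxon(
    i: int,
    sciname: str,
    domain: str,
    phylum: str,
    sources: Iterable[str] = (),
    physiologies: Iterable[str] = (),
    trophic: Optional[str] = None,
    processes: Iterable[str] = (),
    ambiguous: bool = False,
) -> dict:
    return {
        "sciname": sciname,
        "gi": 100001 + i,
        "taxid": 500001 + i,
        "domain": domain,
        "phylum": phylum,
        "traits": TraitEntry(
            ssciname=sciname,
            domain=domain,
            phylum=phylum,
            sources=frozenset(sources),
            physiologies=frozenset(physiologies),
            trophic=trophic,
            processes=frozenset(processes),
            evidence="synthetic community ground truth",
            ambiguous=ambiguous,
        ),
    }


_P = ann.PROCESSES  # canonical process names


def _default_taxa() -> list[dict]:
    psychro = "psychrophilic_psychrotolerant"
    thermo = "thermophilic_thermotolerant"
    halo = "halophilic_halotolerant"
    alkali = "alkaliphilic_alkalitolerant"
    acido = "acidophilic_acidotolerant"
    desic = "desiccation_resistant"
    meso = "mesophilic"
    return [
        _taxon(0, "Polaromonas glacialis", "Bacteria", "Betaproteobacteria",
               ["permafrost_ice", "aquatic_freshwater"], [psychro], "heterotroph",
               [_P[18]]),  # iron oxidation
        _taxon(1, "Flavobacterium psychrophilum", "Bacteria", "Bacteroidetes",
               ["aquatic_freshwater", "animal"], [psychro], "heterotroph", [_P[8]]),
        _taxon(2, "Cryobacterium arcticum", "Bacteria", "Actinobacteria",
               ["permafrost_ice", "soil_sediment"], [psychro], "heterotroph", [_P[2]]),
        _taxon(3, "Arthrobacter agilis", "Bacteria", "Actinobacteria",
               ["soil_sediment"], [psychro, desic], "heterotroph", [_P[4]]),
        _taxon(4, "Bacillus subtilis", "Bacteria", "Firmicutes",
               ["soil_sediment", "plant"], [meso, desic], "heterotroph",
               [_P[5], _P[24]]),
        _taxon(5, "Thermus aquaticus", "Bacteria", "Deinococcus-Thermus",
               ["aquatic_freshwater"], [thermo], "heterotroph", [_P[3], _P[5]]),
        _taxon(6, "Halorubrum trapanicum", "Archaea", "Euryarchaeota",
               ["marine", "aquatic_freshwater"], [halo], "heterotroph", [_P[12]]),
        _taxon(7, "Halobacterium salinarum", "Archaea", "Euryarchaeota",
               ["marine"], [halo, alkali], "heterotroph", [_P[12]]),
        _taxon(8, "Nitrosomonas europaea", "Bacteria", "Betaproteobacteria",
               ["soil_sediment", "aquatic_freshwater"], [meso],
               "chemolithoautotroph", [_P[1]]),
        _taxon(9, "Sideroxydans lithotrophicus", "Bacteria", "Betaproteobacteria",
               ["aquatic_freshwater"], [meso], "chemolithoautotroph",
               [_P[18], _P[10]]),
        _taxon(10, "Azospirillum brasilense", "Bacteria", "Alphaproteobacteria",
               ["soil_sediment", "plant"], [meso], "heterotroph", [_P[0]]),
        _taxon(11, "Pseudomonas fluorescens", "Bacteria", "Gammaproteobacteria",
               ["soil_sediment", "aquatic_freshwater"], [psychro], "heterotroph",
               [_P[5], _P[6]]),
        _taxon(12, "Desulfovibrio vulgaris", "Bacteria", "Deltaproteobacteria",
               ["aquatic_freshwater", "soil_sediment"], [meso], "heterotroph",
               [_P[23], _P[19]]),
        _taxon(13, "Sulfurimonas denitrificans", "Bacteria", "Epsilonproteobacteria",
               ["marine"], [meso], "chemolithoautotroph", [_P[11], _P[22], _P[5]]),
        _taxon(14, "Nostoc commune", "Bacteria", "Cyanobacteria",
               ["soil_sediment", "aquatic_freshwater"], [desic], "photoautotroph",
               [_P[0], _P[10]]),
        _taxon(15, "Chlorobium limicola", "Bacteria", "Chlorobi",
               ["aquatic_freshwater"], [meso], "photoautotroph", [_P[11], _P[13]]),
        _taxon(16, "Candidatus Brocadia anammoxidans", "Bacteria", "Planctomycetes",
               ["aquatic_freshwater"], [meso], "chemolithoautotroph", [_P[9]]),
        _taxon(17, "Methylobacterium extorquens", "Bacteria", "Alphaproteobacteria",
               ["soil_sediment", "plant"], [meso], "heterotroph", [_P[21], _P[14]]),
        _taxon(18, "Acidithiobacillus ferrooxidans", "Bacteria", "Gammaproteobacteria",
               ["soil_sediment"], [acido], "chemolithoautotroph",
               [_P[18], _P[22], _P[10]]),
        _taxon(19, "Antarctomyces psychrotrophicus", "Eukarya", "Ascomycota",
               ["permafrost_ice", "soil_sediment"], [psychro], "heterotroph",
               [_P[8]]),
        _taxon(20, "Mrakia frigida", "Eukarya", "Basidiomycota",
               ["permafrost_ice"], [psychro], "heterotroph", [_P[8]]),
        _taxon(21, "Chlamydomonas nivalis", "Eukarya", "Chlorophyta",
               ["permafrost_ice"], [psychro], "photoautotroph", [_P[10]]),
        _taxon(22, "Phaeocystis antarctica", "Eukarya", "Haptophyta",
               ["marine"], [psychro], "photoautotroph", [_P[10]]),
        _taxon(23, "Notothenia coriiceps", "Eukarya", "Chordata",
               ["marine", "animal"], [psychro], "heterotroph", []),
        # Planted contaminants: shared between samples and the water control.
        _taxon(24, "Cutibacterium acnes", "Bacteria", "Actinobacteria",
               ["animal"], [meso], "heterotroph", []),
        _taxon(25, "Ralstonia pickettii", "Bacteria", "Betaproteobacteria",
               ["aquatic_freshwater"], [meso], "heterotroph", []),
        _taxon(26, "Bradyrhizobium japonicum", "Bacteria", "Alphaproteobacteria",
               ["soil_sediment", "plant"], [meso], "heterotroph", [_P[0]]),
        # Ambiguous entry: stays in profiles, never in category tallies.
        _taxon(27, "uncultured cyanobacterium clone V1", "Bacteria", "Cyanobacteria",
               ambiguous=True),
    ]


CONTAMINANT_GIS = frozenset({100025, 100026, 100027})  # the three planted taxa


def default_community(
    seed: int = 0,
    n_reads_per_sample: int = 2000,
    per_base_error_rate: float = 0.0,
) -> CommunitySpec:
    """The default 28-taxon study community (lognormal abundances, three
    planted water-control contaminants, one ambiguous-trait taxon)."""
    specs = _default_taxa()
    rng = np.random.default_rng([seed, 404])
    raw = rng.lognormal(mean=0.0, sigma=1.0, size=len(specs))
    shares = raw / raw.sum()
    mixes = [(0.7, 0.2, 0.1), (0.5, 0.4, 0.1), (0.6, 0.2, 0.2)]
    taxa = tuple(
        TaxonSpec(
            abundance=float(shares[i]),
            molecule_class_mix=mixes[i % len(mixes)],
            reference_length=int(rng.integers(2000, 4001)),
            **sp,
        )
        for i, sp in enumerate(specs)
    )
    return CommunitySpec(
        taxa=taxa,
        n_reads_per_sample=n_reads_per_sample,
        per_base_error_rate=per_base_error_rate,
        contaminant_gis=CONTAMINANT_GIS,
        seed=seed,
    )


def trait_table(spec: CommunitySpec) -> list[TraitEntry]:
    return [t.traits for t in spec.taxa]


# ---------------------------------------------------------------------------
# Metabolic-matrix reconstruction fixture
# ---------------------------------------------------------------------------

def metabolic_reference_community() -> tuple[list[ann.AnnotatedProfile], dict[str, str]]:
    """Synthetic stand-in community rebuilt from the packaged reference
    metabolic matrix: one representative taxon per (process, group,
    code) cell token, so the matrix builder must reproduce the packaged
    cells exactly.  Purely synthetic; no claim of real organisms."""
    ref = ann.load_reference_metabolic_matrix()
    profiles: list[ann.AnnotatedProfile] = []
    grouping: dict[str, str] = {}
    gi = 1
    for group in ref.columns:
        sample = f"{group}_sample"
        grouping[sample] = group
        taxa: list[ann.AnnotatedTaxon] = []
        for process in ref.index:
            for code in sorted(ann.matrix_cell_set(ref.loc[process, group])):
                name = f"synthetic {code} representative ({process}; {group})"
                entry = TraitEntry(
                    ssciname=name,
                    domain="Bacteria",
                    phylum=code,  # codes pass through phylum_code verbatim
                    processes=frozenset({process}),
                    evidence="synthetic matrix reconstruction fixture",
                )
                taxa.append(
                    ann.AnnotatedTaxon(
                        gi=gi,
                        sacc=f"SYNM{gi}",
                        ssciname=name,
                        read_count=1,
                        molecule_class="other",
                        domain="Bacteria",
                        phylum=code,
                        entry=entry,
                    )
                )
                gi += 1
        profiles.append(ann.AnnotatedProfile(sample_label=sample, taxa=taxa))
    return profiles, grouping


# ---------------------------------------------------------------------------
# Whole-run convenience
# ---------------------------------------------------------------------------

@dataclass
class SimulatedRun:
    spec: CommunitySpec
    manifest: MIDManifest
    reads: dict[str, list[SequenceRead]]
    truth: pd.DataFrame
    hits: SimulatedHits
    traits: list[TraitEntry]
    metadata: dict[str, str]


def simulate_run(
    spec: Optional[CommunitySpec] = None,
    manifest: Optional[MIDManifest] = None,
    no_hit_rate: float = DEFAULT_NO_HIT_RATE,
    seed: Optional[int] = None,
) -> SimulatedRun:
    """Generate a full synthetic run: reads, truth, hit tables, traits."""
    if spec is None:
        spec = default_community(seed=seed if seed is not None else 0)
    elif seed is not None and seed != spec.seed:
        spec = replace(spec, seed=seed)
    if manifest is None:
        manifest = default_manifest()
    reads, truth = simulate_reads(spec, manifest)
    hits = simulate_hit_table(truth, spec, no_hit_rate=no_hit_rate)
    return SimulatedRun(
        spec=spec,
        manifest=manifest,
        reads=reads,
        truth=truth,
        hits=hits,
        traits=trait_table(spec),
        metadata=molecule_metadata(spec),
    )


def write_run(run: SimulatedRun, outdir: str | Path) -> dict[str, Path]:
    """Write a simulated run to disk: one FASTQ of all reads, per-sample
    hit CSVs, a control hit CSV, the trait TSV, the truth TSV and the
    molecule-class metadata TSV.  Returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    all_reads = [r for sample in sorted(run.reads) for r in run.reads[sample]]
    paths["reads_fastq"] = outdir / "reads.fastq"
    write_fastq(all_reads, paths["reads_fastq"])
    for sample, rows in sorted(run.hits.tables.items()):
        p = outdir / f"hits_{sample}.csv"
        write_hit_table(rows, p)
        paths[f"hits_{sample}"] = p
    paths["control_hits"] = outdir / "hits_control.csv"
    write_hit_table(run.hits.control, paths["control_hits"])
    paths["traits"] = outdir / "traits.tsv"
    ann.write_trait_table(run.traits, paths["traits"])
    paths["truth"] = outdir / "truth.tsv"
    run.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["molecule_metadata"] = outdir / "molecule_classes.tsv"
    with open(paths["molecule_metadata"], "w") as fh:
        fh.write("sacc\tmolecule_class\n")
        for acc in sorted(run.metadata):
            fh.write(f"{acc}\t{run.metadata[acc]}\n")
    return paths
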
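# Methods

This note documents the models and procedures implemented in `icemeta`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Read model and demultiplexing

Reads are single-end and decorated 5′→3′ as
`platform adapter A (30 nt) + MID (10 nt) + EcoRI/NotI linker (19 nt) +
insert`. The packaged manifest carries five MIDs — four ice-core depth pools
(2149 m glacial; 3501+3520 m basal; 3540+3569 m western-embayment accretion;
3585 m eastern-embayment accretion) and a sterile-water control.

**MID search.** The MID must occur entirely within the first 45 bases
(leaving room for the platform adapter), with at most `max_mismatch`
substitutions (default 0). If two or more MIDs match equally well the read
goes to *unassigned*: guessing would silently bleed reads across samples,
which matters in a study built around a negative control. Forward strand
only by default.

**Clipping.** Everything through the end of the matched MID is removed; a
linker immediately following (within the mismatch tolerance) is removed too.
Any 3′ occurrence of the linker or either platform adapter — forward or
reverse complement — truncates the read. Clipped output is always a
contiguous substring of the input; a read clipped to nothing goes to a
*fully-clipped* discard list rather than raising. Reads shorter than 50 bp
after clipping are discarded (the boundary is inclusive: a 50-bp insert is
kept).

**Quality.** The pipeline treats incoming reads as already quality-screened.
An optional mean-Phred ≥ Q20 pre-filter is provided (`mean_quality_filter`)
but off by default, because no principled default exists for data whose
upstream screening is unknown.

## Hit curation

Hits arrive in an 11-field comma-separated layout (one HSP per row,
headerless; scientific names must not contain embedded commas in this
dialect). The curation chain runs in a fixed order:

1. **Thresholds**: keep `pident ≥ 97.0` AND `evalue < 1e-6`. The identity
   cutoff is inclusive and the e-value cutoff strict — deliberately
   asymmetric, matching the convention the thresholds come from.
2. **Control subtraction**: a control hit at ≥ 97% identity implicates its
   GI; every sample row with that GI is removed. The sample-side identity is
   not re-checked beyond step 1 — contamination is a property of the subject
   sequence, not of any one alignment.
3. **Read enumeration**: per accession (or GI), the number of *distinct*
   query reads. Multiple HSPs of one read against one subject count once;
   one read hitting several subjects counts once per subject.
4. **Best-hit dedup**: one record per GI by minimal e-value, then maximal
   identity, then maximal alignment length, then first-seen. The last two
   tie-breaks are ours, chosen purely for determinism; the operation is
   idempotent.
5. **Molecule classification** into rRNA/mRNA/other via an accession →
   class map; unknown accessions fall back to *other* with a warning.

The provenance block records thresholds, removed GIs with row counts, and
the **no-hit fraction** `1 − (reads with any hit)/(reads searched)`, which
in this kind of survey is substantial (the generator plants 33% by default).
The 20-target cap of the upstream search is recorded as provenance, not
re-enforced at parse time.

## Trait annotation

Trait lookup is a declarative TSV (one row per species: domain, phylum,
source categories, physiology categories, trophic mode, metabolic processes,
evidence, ambiguous flag) rather than a live literature search — that is the
only way the step can be reproducible and testable offline. The join is by
exact scientific name at species/strain level; no genus-level fallback, and
ambiguous entries (which must carry no labels) are excluded from category
tallies while still counting toward domain/phylum totals. Category tallies
use set semantics: one organism may count toward several sources or
physiologies. Whether multi-category membership is the right convention is
genuinely open; sets were chosen because forcing a single label would
require an ordering the trait table does not contain.

The metabolic-capability matrix maps each process (26-term vocabulary:
nitrogen cycle steps, four carbon-fixation pathways, C-1 metabolism, metal
and sulfur redox reactions) and sample group to the union of phylum codes
(Ac, Ad, αP, Ar, As, Ba, Bd, βP, Cb, Ch, Cy, DT, δP, εP, Fi, γP, Pl) of the
taxa carrying it; empty cells render as `nd`. A reference matrix for basal
vs accretion ice ships as package data and is reproduced cell-for-cell from
synthetic representative taxa in the tests.

## Diversity and overlap

`H = −Σ p_i log p_i` over read counts, with evenness `H / log S`. The log
base defaults to natural log and is configurable (2, e, 10); evenness is
base-invariant, so the choice affects only the printed `H`. A single-taxon
sample has `H = 0` and *undefined* evenness (`None`, never 0). `H` is
permutation- and scale-invariant, bounded by `log S`, and coarsening
(merging taxa) never increases it — all property-tested.

Overlap operates on unique taxon keys after dedup (accession by default,
scientific name as an alternative), not on reads. Each element of the union
is classified by its exact membership pattern, so the disjoint region counts
are exact for any number of samples.

## Count–geochemistry association

The model is an NB2 mixed-effects regression:
`y_ij ~ NB(μ_ij, θ)` with `Var = μ + μ²/θ`,
`log μ_ij = β₀ + x_ij′β + u_j`, `u_j ~ N(0, σ_u²)` over habitats (soil,
freshwater, marine, ice, animal-associated, plant-associated). NB2 was
chosen as the standard parameterization for overdispersed ecological counts.

**Estimation.** The marginal likelihood integrates `u_j` out per habitat
with Gauss–Hermite quadrature (15 nodes by default; 9 in the replicated
calibration studies) and is maximized by L-BFGS-B over
`(β, log θ, log σ_u)`, initialized from a plain NB fit. Wald 2-tailed
p-values at α = 0.05 come from the inverse observed Hessian
(central differences). When `σ̂_u < 1e-3` the model has collapsed to a plain
NB regression; standard errors are then computed on that reduced surface,
because the boundary direction is flat and would make the full Hessian
singular. Non-convergence (including a non-invertible Hessian) is reported
in the result object, never silently.

**Scaling.** Covariates are z-scored internally — ion concentrations are in
µmol/L while NPOC and amino acids are in mol/L, nine orders of magnitude
apart — and coefficients are reported both per SD and back-transformed to
natural units (p-values are scale-invariant). The synthetic generator plants
effects on the same per-SD scale for the same reason.

**Unit of analysis.** `prepare_association_table` builds one row per
(habitat × depth), with the per-habitat unique-species count taken from the
source-category tallies. This join convention is a package choice, exposed
as configuration; at the packaged fixture scale (4 depths × 6 habitats = 24
rows) the fit is structural only and honestly reports its convergence
status. Calibration claims are made at n = 600: with all β = 0 and
σ_u = 0 the per-covariate type-I error over 200 replicates sits in
[0.01, 0.10] at nominal 0.05, and a planted per-SD NPOC effect of 0.5 is
recovered in sign and significance in ≥ 90% of 200 replicates (both
recomputed by the test suite and `scripts/acceptance.py`). The independent
oracle for the fit itself is `glmmTMB` (R), which maximizes the same
marginal likelihood; agreement on fixed effects is to ~1e-3.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study design: a 28-taxon community spanning
Bacteria (Proteobacteria classes, Bacteroidetes, Actinobacteria, Firmicutes,
Cyanobacteria, Chlorobi, Planctomycetes, Deinococcus-Thermus), two
halophilic archaea, six eukaryotes (fungi, green alga, haptophyte, a fish),
three planted water-control contaminants and one ambiguous-trait taxon;
lognormal(0, 1) abundances normalized to 1; inserts uniform on [50, 1000] bp
from deterministic per-taxon reference sequences (the lower end deliberately
sits on the length-filter boundary); substitution-only errors at a
configurable per-base rate (no indels — sufficient to exercise identity
thresholds without alignment machinery); per-read hit rows with the true
taxon passing both thresholds, duplicate-GI rows at strictly worse e-values,
sub-threshold decoys, and a 33% no-hit fraction; a control hit table
guaranteed to contain every planted contaminant at ≥ 97% identity. The
control sample draws reads from the contaminant taxa at one tenth of the
per-sample depth. Geochemistry covariates are drawn uniformly from the
measured ranges (e.g. Na⁺ 4–40 µmol/L, NPOC 0.9–2 × 10⁻⁶ mol/L).

Not emulated: realistic quality-score or error profiles, indels, chimeras,
strand flips of the MID, real database identifiers or taxonomy, correlated
covariate profiles along depth, and alignment-level structure beyond the
fields the curation rules read. Passing tests therefore demonstrate that the
*rules* are implemented exactly and calibrated — not that they are robust to
artifacts the generator does not produce.

## Numerical choices and degenerate inputs

- Abundance and molecule-mix sums are validated to 1 within 1e-9.
- The linear predictor is clipped to ±30 before exponentiation.
- `log θ` is bounded in [−4, 6] and `log σ_u` in [−10, 3] during
  optimization; θ at its upper bound signals effectively Poisson data.
- Dedup and overlap are stable under input order; all TSV/JSON outputs are
  written with sorted keys and fixed float formats so identical seeds give
  byte-identical files.
- Single-habitat data fall back to a fixed-effects NB fit with a warning;
  empty geochemistry tables, duplicate MIDs/species names, unknown process
  names and malformed hit rows all raise typed validation errors naming the
  offender.

## Problem sizes

Defaults were sized for a desk-scale, fully-checkable study: 1000–2000 reads
per sample in the drivers and acceptance script, 200-replicate calibration
studies at n = 600, 100 randomized communities for the decontamination
exactness check. These are the package's own study conditions, chosen so
every claim above is recomputed on every run.

## Known limitations

- The MID search is forward-strand with exact matching by default; highly
  error-prone tags would need `max_mismatch > 0` and possibly
  reverse-complement search.
- Control subtraction keys on GI alone once the control hit passes 97%; a
  GI legitimately present in both control and sample is removed regardless.
- Read enumeration counts a read once per accession; a read whose HSPs span
  several accessions of one organism inflates that organism's total.
- The association join aggregates species counts by habitat category, so a
  species reported from two habitats contributes to two rows.
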
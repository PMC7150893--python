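# icemeta

Curation and community analysis of multiplexed ice-core metagenome and
metatranscriptome sequencing runs — the kind of survey used to profile
microbial life in glacial, basal and subglacial-lake accretion ice, where a
handful of depth-pooled samples are tagged with multiplex identifiers (MIDs),
sequenced together, searched against a nucleotide database, and turned into
per-sample community profiles, trait/ecology summaries, diversity indices and
count–geochemistry associations.

It is written for microbial ecologists who have (a) multiplexed reads, (b)
tabular homology-search output, (c) a species trait table, and (d) a
depth-indexed geochemistry table — and who want every curation rule applied
reproducibly, with a seeded synthetic-data generator so the whole pipeline is
testable without any external download.

## What the pipeline does

1. **Demultiplex** (`icemeta.demux`). Reads are decorated as
   `adapter + MID(10 nt) + EcoRI/NotI linker + insert`. FASTQ is converted to
   FASTA, reads are binned by the best MID occurrence in a 45-nt 5′ window
   (exact match by default; ties go to *unassigned*), the decoration is
   clipped (3′ adapter/linker remnants removed, reverse-complement aware), and
   reads shorter than 50 bp are dropped.
2. **Curate hits** (`icemeta.curation`). The 11-field comma-separated layout
   `qseqid,sacc,sgi,length,sstart,send,pident,evalue,staxid,sskingdom,ssciname`
   is filtered with **pident ≥ 97 (inclusive)** and **e-value < 10⁻⁶
   (strict)**; any subject GI found in the sterile-water control at ≥ 97%
   identity is subtracted from every sample; read frequencies are counted as
   *distinct* query reads per accession; duplicate GIs are collapsed to the
   lowest e-value, then highest identity; records are classed rRNA/mRNA/other.
   The provenance block records removed GIs and the no-hit fraction.
3. **Annotate** (`icemeta.annotation`). Curated taxa join a declarative trait
   table by exact species name (ambiguity ⇒ no labels), giving unique-taxon
   tallies per source (soil/sediment, freshwater, marine, permafrost/ice,
   animal, plant) and physiology (psychrophilic, thermophilic, halophilic,
   alkaliphilic, acidophilic, desiccation-resistant) category, and a
   process × ice-type metabolic-capability matrix of phylum codes.
4. **Diversity and overlap** (`icemeta.diversity`). With `p_i` the relative
   read abundance of taxon `i`:

   `H = −Σ p_i ln p_i`,  `evenness = H / ln S`  (S = richness).

   Overlap accounting reports exclusive and shared taxa (exact membership
   regions) across samples, keyed by accession.
5. **Associate** (`icemeta.association`). A multi-level mixed-effects
   negative-binomial regression of species counts on Na⁺, K⁺, Ca²⁺, Mg²⁺,
   Cl⁻, SO₄²⁻, NPOC and total amino acids:

   `y ~ NB(μ, θ)`,  `log μ = β₀ + x′β + u_habitat`,  `u ~ N(0, σ_u²)`,

   fitted by Gauss–Hermite marginal likelihood with 2-tailed Wald tests at
   α = 0.05. Covariates are standardized internally (units span µmol/L to
   mol/L); coefficients are reported per-SD and in natural units.

The synthetic generator (`icemeta.synthetic`) plants everything the curation
rules must catch: sub-threshold noise hits, duplicate-GI rows at worse
e-values, shared sample/control contaminant GIs, and a one-third no-hit
fraction.

## Worked example

```sh
python analysis/01_simulate_community.py   # synthetic run -> results/data/
python analysis/02_demux_reads.py
python analysis/03_curate_hits.py
python analysis/04_annotate_traits.py
python analysis/05_diversity_overlap.py
python analysis/06_fit_geochemistry_model.py
```

Step 03 prints, per sample (seed 42, 1000 reads/sample):

```
3501_3520m    1809 hit rows ->  25 unique GIs,   603 reads, 3 contaminant GIs removed, no-hit fraction 0.331
```

meaning: of 1809 parsed hit rows, thresholding, control subtraction and
best-hit deduplication leave 25 unique subject GIs backed by 603 distinct
read-to-accession assignments; the three GIs planted in the water control
were all removed; 33.1% of the sample's reads returned no hit. Step 05 then
prints the diversity of each profile, e.g.

```
3501_3520m   S= 25 reads=  603 H=2.761 nats  evenness=0.858
```

and step 06 fits the count–geochemistry model, reporting at the calibrated
study size (n = 600, true per-SD NPOC effect 0.5, habitat spread 0.5):

```
beta_NPOC = 0.447 (p = 5.73e-48), sigma_u = 0.414, theta = 2.14
```

The same operations are available as subcommands of the `icemeta` console
script (`icemeta simulate`, `icemeta demux`, `icemeta curate`,
`icemeta diversity`, `icemeta overlap`, `icemeta associate`,
`icemeta pipeline`).

## Layout

```
src/icemeta/      library (demux, curation, annotation, diversity,
                  association, synthetic, pipeline, cli)
analysis/         numbered narrative drivers over the library
tests/            pytest suite (unit, property and acceptance tests)
scripts/          acceptance script
docs/methods.md   methods note: models, defaults, design choices, limits
```
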
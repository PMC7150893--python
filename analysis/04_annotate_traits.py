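#!/usr/bin/env python
"""Annotate curated taxa with habitat, physiology and metabolism labels.

Joins each profile to the trait table by exact species name (ambiguous
entries carry no labels), tallies unique taxa per source and physiology
category, and builds the process x ice-type metabolic-capability matrix
(glacial/basal depths vs accretion-ice depths).  Outputs go to
results/annotation/.
"""
from pathlib import Path

from icemeta import annotation as ann
from icemeta import curation as cur

RESULTS = Path(__file__).resolve().parents[1] / "results"

# depth pools by ice type: glacial+basal vs lake-water accretion ice
GROUPING = {
    "2149m": "basal",
    "3501_3520m": "basal",
    "3540_3569m": "accretion",
    "3585m": "accretion",
}


def main() -> None:
    traits = ann.read_trait_table(RESULTS / "data" / "traits.tsv")
    outdir = RESULTS / "annotation"
    outdir.mkdir(parents=True, exist_ok=True)
    annotated = {}
    summaries = []
    for path in sorted((RESULTS / "curation").glob("profile_*.tsv")):
        profile = cur.read_profile(path)
        annotated[profile.sample_label] = ann.annotate(profile, traits)
        summary = ann.summarize_categories(annotated[profile.sample_label])
        summaries.append(summary)
        phys = {ann.PHYSIOLOGY_CODES[k]: v for k, v in summary.physiology_counts.items() if v}
        print(f"{summary.sample_label:12s} {summary.n_taxa:3d} taxa "
              f"({summary.n_labeled} labeled)  physiology: {phys}")
    ann.summary_frame(summaries).to_csv(
        outdir / "category_summaries.tsv", sep="\t", index=False
    )
    matrix = ann.build_metabolic_matrix(annotated.values(), GROUPING)
    matrix.to_csv(outdir / "metabolic_matrix.tsv", sep="\t", index_label="process")
    populated = (matrix != ann.EMPTY_CELL).sum().to_dict()
    print(f"metabolic matrix: {len(matrix)} processes; populated cells per group: {populated}")


if __name__ == "__main__":
    main()
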
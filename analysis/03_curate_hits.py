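#!/usr/bin/env python
"""Curate the per-sample hit tables.

Applies the curation chain — identity >= 97% (inclusive) and e-value <
1e-6 (strict), negative-control GI subtraction, distinct-read
enumeration, best-hit deduplication, rRNA/mRNA/other classification —
and writes per-sample profiles plus a provenance block (thresholds,
removed GIs, no-hit fraction) under results/curation/.
"""
import csv
from pathlib import Path

from icemeta import curation as cur

RESULTS = Path(__file__).resolve().parents[1] / "results"


def demux_counts() -> dict[str, int]:
    counts = {}
    with open(RESULTS / "demux" / "demux_report.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["category"] == "assigned":
                counts[row["sample"]] = int(row["count"])
    return counts


def molecule_metadata() -> dict[str, str]:
    with open(RESULTS / "data" / "molecule_classes.tsv") as fh:
        return {r["sacc"]: r["molecule_class"] for r in csv.DictReader(fh, delimiter="\t")}


def main() -> None:
    control = cur.parse_hit_table(RESULTS / "data" / "hits_control.csv")
    searched = demux_counts()
    metadata = molecule_metadata()
    outdir = RESULTS / "curation"
    outdir.mkdir(parents=True, exist_ok=True)
    provenances = {}
    for path in sorted((RESULTS / "data").glob("hits_*.csv")):
        sample = path.stem.removeprefix("hits_")
        if sample == "control":
            continue
        profile, prov = cur.curate(
            cur.parse_hit_table(path), control, sample_label=sample,
            reads_searched=searched.get(sample), molecule_metadata=metadata,
        )
        cur.write_profile(profile, outdir / f"profile_{sample}.tsv")
        provenances[sample] = prov
        print(
            f"{sample:12s} {prov['hits_parsed']:5d} hit rows -> "
            f"{len(profile):3d} unique GIs, {profile.total_reads:5d} reads, "
            f"{len(prov['removed_gis'])} contaminant GIs removed, "
            f"no-hit fraction {prov['no_hit_fraction']:.3f}"
        )
    cur.write_provenance(provenances, outdir / "curation_provenance.json")


if __name__ == "__main__":
    main()
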
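#!/usr/bin/env python
"""Diversity and cross-sample overlap.

Computes Shannon–Weaver H (nats) and evenness per sample from the
curated read counts, and the unique/shared accession accounting across
samples (exact membership regions).  Outputs go to results/diversity/.
"""
import json
from pathlib import Path

from icemeta import curation as cur
from icemeta import diversity as dv

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    outdir = RESULTS / "diversity"
    outdir.mkdir(parents=True, exist_ok=True)
    results = []
    keysets = {}
    for path in sorted((RESULTS / "curation").glob("profile_*.tsv")):
        profile = cur.read_profile(path)
        counts = {gi: rec.read_count for gi, rec in profile.records.items()}
        res = dv.shannon_weaver(counts, sample_label=profile.sample_label)
        results.append(res)
        keysets[profile.sample_label] = {
            rec.best.sacc for rec in profile.records.values()
        }
        ev = f"{res.evenness:.3f}" if res.evenness is not None else "undefined"
        print(f"{res.sample_label:12s} S={res.richness:3d} reads={res.n_reads:5d} "
              f"H={res.shannon:.3f} nats  evenness={ev}")
    dv.diversity_frame(results).to_csv(
        outdir / "diversity.tsv", sep="\t", index=False, float_format="%.6f"
    )
    report = dv.overlap(keysets)
    with open(outdir / "overlap.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"union of accessions: {report.union_size}; "
          f"exclusive per sample: {report.unique}")


if __name__ == "__main__":
    main()
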
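"""End-to-end pipeline orchestration with provenance capture.

Stages run in a fixed order — simulate (or load inputs) -> demux ->
curate -> annotate -> diversity/overlap -> associate — and every run
writes a machine-readable manifest: package version, parameters, input
digests and per-stage record counts.  Identical config + inputs give
byte-identical outputs (no timestamps are recorded).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import annotation as ann
from . import association as assoc
from . import curation as cur
from . import demux as dx
from . import diversity as dv
from . import synthetic as syn


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


ALL_STAGES = ("simulate", "demux", "curate", "annotate", "diversity", "associate")


@dataclass
class PipelineConfig:
    """Paths, parameters and stage toggles for one pipeline run."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic-input parameters (used when the simulate stage is on)
    n_reads_per_sample: int = 500
    per_base_error_rate: float = 0.0
    no_hit_rate: float = syn.DEFAULT_NO_HIT_RATE
    # external inputs (used when the simulate stage is off)
    reads_fastq: Optional[Path] = None
    hits_dir: Optional[Path] = None
    control_hits: Optional[Path] = None
    traits: Optional[Path] = None
    geochemistry: Optional[Path] = None
    # curation / demux / analysis parameters
    min_len: int = 50
    min_pident: float = 97.0
    max_evalue: float = 1e-6
    max_mismatch: int = 0
    log_base: float = math.e
    alpha: float = 0.05
    control_label: str = syn.CONTROL_LABEL

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s): {sorted(unknown)}")
        if not (0.0 <= self.min_pident <= 100.0):
            raise PipelineError(f"min_pident {self.min_pident} outside [0, 100]")
        if self.max_evalue <= 0:
            raise PipelineError("max_evalue must be positive")
        if self.min_len < 0 or self.max_mismatch < 0:
            raise PipelineError("min_len and max_mismatch must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns (and writes) the manifest.

    Any stage failure aborts with the stage name; outputs written by
    earlier stages are preserved.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "n_reads_per_sample": config.n_reads_per_sample,
            "per_base_error_rate": config.per_base_error_rate,
            "no_hit_rate": config.no_hit_rate,
            "min_len": config.min_len,
            "min_pident": config.min_pident,
            "max_evalue": config.max_evalue,
            "max_mismatch": config.max_mismatch,
            "log_base": config.log_base,
            "alpha": config.alpha,
        },
        "inputs": {},
        "counts": {},
    }
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _STAGE_FUNCS[stage](config, state, manifest)
        except Exception as exc:
            _write_manifest(manifest, outdir)
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: PipelineConfig, state: dict, manifest: dict) -> None:
    run = syn.simulate_run(
        spec=syn.default_community(
            seed=config.seed,
            n_reads_per_sample=config.n_reads_per_sample,
            per_base_error_rate=config.per_base_error_rate,
        ),
        no_hit_rate=config.no_hit_rate,
    )
    indir = config.outdir / "inputs"
    paths = syn.write_run(run, indir)
    state["run"] = run
    state["manifest_obj"] = run.manifest
    state["paths"] = paths
    manifest["inputs"] = {k: _sha256(p) for k, p in sorted(paths.items())}
    manifest["counts"]["simulate"] = {
        "taxa": len(run.spec.taxa),
        "reads": int(sum(len(v) for v in run.reads.values())),
        "truth_rows": int(len(run.truth)),
        "control_hit_rows": len(run.hits.control),
    }


def _stage_demux(config: PipelineConfig, state: dict, manifest: dict) -> None:
    mid_manifest = state.get("manifest_obj") or dx.default_manifest()
    if "run" in state:
        reads = [r for s in sorted(state["run"].reads) for r in state["run"].reads[s]]
    else:
        if config.reads_fastq is None:
            raise PipelineError("demux stage needs reads_fastq when simulate is off")
        reads = dx.read_fastq(config.reads_fastq)
        manifest["inputs"]["reads_fastq"] = _sha256(Path(config.reads_fastq))
    result = dx.demux_reads(
        reads,
        mid_manifest,
        max_mismatch=config.max_mismatch,
        min_len=config.min_len,
    )
    for label in sorted(result.bins):
        dx.write_fasta(result.bins[label], config.outdir / f"demux_{label}.fasta")
    dx.write_demux_report(result, config.outdir / "demux_report.tsv")
    state["demux"] = result
    manifest["counts"]["demux"] = {
        "input": result.n_input,
        "assigned": {k: len(v) for k, v in sorted(result.bins.items())},
        "unassigned": len(result.unassigned),
        "short": len(result.short),
        "fully_clipped": len(result.fully_clipped),
    }


def _stage_curate(config: PipelineConfig, state: dict, manifest: dict) -> None:
    if "run" in state:
        run = state["run"]
        tables = run.hits.tables
        control = run.hits.control
        metadata = run.metadata
        reads_searched = {
            s: len(state["demux"].bins[s]) if "demux" in state else None
            for s in tables
        }
    else:
        if config.hits_dir is None:
            raise PipelineError("curate stage needs hits_dir when simulate is off")
        tables = {}
        for p in sorted(Path(config.hits_dir).glob("*.csv")):
            label = p.stem.removeprefix("hits_")
            if label == config.control_label:
                continue
            tables[label] = cur.parse_hit_table(p)
            manifest["inputs"][f"hits_{label}"] = _sha256(p)
        control = (
            cur.parse_hit_table(config.control_hits) if config.control_hits else []
        )
        metadata = {}
        reads_searched = {s: None for s in tables}
    profiles: dict[str, cur.CuratedProfile] = {}
    provenances: dict[str, dict] = {}
    for label in sorted(tables):
        profile, prov = cur.curate(
            tables[label],
            control,
            sample_label=label,
            min_pident=config.min_pident,
            max_evalue=config.max_evalue,
            reads_searched=reads_searched.get(label),
            molecule_metadata=metadata,
        )
        profiles[label] = profile
        provenances[label] = prov
        cur.write_profile(profile, config.outdir / f"profile_{label}.tsv")
    cur.write_provenance(provenances, config.outdir / "curation_provenance.json")
    state["profiles"] = profiles
    manifest["counts"]["curate"] = {
        label: {
            "unique_gis": len(profiles[label]),
            "reads": profiles[label].total_reads,
            "removed_gis": len(provenances[label]["removed_gis"]),
        }
        for label in sorted(profiles)
    }


def _stage_annotate(config: PipelineConfig, state: dict, manifest: dict) -> None:
    if "profiles" not in state:
        raise PipelineError("annotate stage needs the curate stage")
    if "run" in state:
        traits = ann.trait_index(state["run"].traits)
    else:
        if config.traits is None:
            raise PipelineError("annotate stage needs a traits table")
        traits = ann.read_trait_table(config.traits)
        manifest["inputs"]["traits"] = _sha256(Path(config.traits))
    annotated = {
        label: ann.annotate(profile, traits)
        for label, profile in sorted(state["profiles"].items())
    }
    summaries = [ann.summarize_categories(annotated[l]) for l in sorted(annotated)]
    ann.summary_frame(summaries).to_csv(
        config.outdir / "category_summaries.tsv", sep="\t", index=False
    )
    state["annotated"] = annotated
    state["summaries"] = summaries
    manifest["counts"]["annotate"] = {
        s.sample_label: {"taxa": s.n_taxa, "labeled": s.n_labeled} for s in summaries
    }


def _stage_diversity(config: PipelineConfig, state: dict, manifest: dict) -> None:
    if "profiles" not in state:
        raise PipelineError("diversity stage needs the curate stage")
    results = []
    for label in sorted(state["profiles"]):
        profile = state["profiles"][label]
        if len(profile) == 0:
            continue
        counts = {gi: rec.read_count for gi, rec in profile.records.items()}
        results.append(
            dv.shannon_weaver(counts, log_base=config.log_base, sample_label=label)
        )
    dv.diversity_frame(results).to_csv(
        config.outdir / "diversity.tsv", sep="\t", index=False, float_format="%.6f"
    )
    keysets = {
        label: {rec.best.sacc for rec in state["profiles"][label].records.values()}
        for label in sorted(state["profiles"])
        if len(state["profiles"][label])
    }
    overlap_report = dv.overlap(keysets) if len(keysets) >= 2 else None
    if overlap_report is not None:
        with open(config.outdir / "overlap.json", "w") as fh:
            json.dump(overlap_report.to_json_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    manifest["counts"]["diversity"] = {
        r.sample_label: {"richness": r.richness, "reads": r.n_reads} for r in results
    }


def _stage_associate(config: PipelineConfig, state: dict, manifest: dict) -> None:
    if "summaries" not in state:
        raise PipelineError("associate stage needs the annotate stage")
    if config.geochemistry is not None:
        geo = pd.read_csv(config.geochemistry, sep="\t")
        manifest["inputs"]["geochemistry"] = _sha256(Path(config.geochemistry))
    else:
        depths = [s.sample_label for s in state["summaries"]]
        geo = syn.simulate_geochemistry(depths, seed=config.seed)
    table = assoc.prepare_association_table(state["summaries"], geo)
    table.to_csv(config.outdir / "association_table.tsv", sep="\t", index=False)
    fit = assoc.fit_count_association(table, alpha=config.alpha)
    with open(config.outdir / "association_fit.json", "w") as fh:
        json.dump(fit.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(config.outdir / "association_fit.txt", "w") as fh:
        fh.write(fit.summary() + "\n")
    state["fit"] = fit
    manifest["counts"]["associate"] = {
        "rows": int(len(table)),
        "converged": fit.converged,
        "significant": int(fit.params["significant"].iloc[1:].sum()),
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "demux": _stage_demux,
    "curate": _stage_curate,
    "annotate": _stage_annotate,
    "diversity": _stage_diversity,
    "associate": _stage_associate,
}
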
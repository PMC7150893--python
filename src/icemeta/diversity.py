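"""Shannon–Weaver diversity, evenness and cross-sample overlap accounting.

Diversity is computed from read counts per taxon: with p_i the relative
read abundance of taxon i, H = -sum(p_i log p_i) and evenness = H / log S
(S = richness).  Evenness is base-invariant; H defaults to nats with a
selectable log base.  Overlap accounting operates on unique taxon keys
(post-deduplication accessions by default), not reads: it reports the
taxa exclusive to each sample, pairwise intersections, and the exact
count in every membership region of up to a handful of samples.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotatedProfile


class DiversityError(ValueError):
    """Invalid abundance vector or overlap request."""


@dataclass(frozen=True)
class DiversityResult:
    sample_label: str
    richness: int
    n_reads: int
    shannon: float
    evenness: Optional[float]  # None (undefined) when richness == 1
    log_base: float

    @property
    def evenness_defined(self) -> bool:
        return self.evenness is not None


def shannon_weaver(
    counts: Mapping[Hashable, int] | Sequence[int],
    log_base: float = math.e,
    sample_label: str = "",
) -> DiversityResult:
    """Shannon–Weaver H and evenness from positive integer read counts.

    H is in units of ``log_base`` (nats by default); evenness = H /
    log(S).  A single-taxon vector has H = 0 and *undefined* evenness
    (reported as ``None``, not 0).
    """
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    if not values:
        raise DiversityError("abundance vector has no taxa")
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 1):
        raise DiversityError("all counts must be >= 1")
    total = arr.sum()
    p = arr / total
    h = float(-(p * (np.log(p) / math.log(log_base))).sum())
    h = max(h, 0.0)  # clip the -0.0 of single-taxon vectors
    s = len(values)
    evenness = h / (math.log(s) / math.log(log_base)) if s > 1 else None
    return DiversityResult(
        sample_label=sample_label,
        richness=s,
        n_reads=int(total),
        shannon=h,
        evenness=evenness,
        log_base=log_base,
    )


def diversity_frame(results: Sequence[DiversityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": r.sample_label,
                "richness": r.richness,
                "reads": r.n_reads,
                "shannon": r.shannon,
                "evenness": r.evenness if r.evenness is not None else float("nan"),
                "log_base": r.log_base,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Overlap accounting
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    """Unique / shared taxon accounting across samples.

    ``unique``: taxa found in exactly that sample and no other.
    ``shared_pairs``: |intersection| for each unordered sample pair.
    ``regions``: exact count for every non-empty membership pattern
    (keyed by the sorted tuple of member samples); region counts are
    disjoint and sum to the union size.
    """

    labels: tuple[str, ...]
    sizes: dict[str, int]
    unique: dict[str, int]
    shared_pairs: dict[frozenset, int]
    regions: dict[tuple[str, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.regions.values())

    def to_json_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "sizes": dict(sorted(self.sizes.items())),
            "unique": dict(sorted(self.unique.items())),
            "shared_pairs": {
                " & ".join(sorted(k)): v for k, v in sorted(
                    self.shared_pairs.items(), key=lambda kv: sorted(kv[0])
                )
            },
            "regions": {
                " & ".join(k): v for k, v in sorted(self.regions.items())
            },
            "union_size": self.union_size,
        }


def overlap(profiles: Mapping[str, Iterable[Hashable]]) -> OverlapReport:
    """Region-exact overlap of >= 2 labelled taxon-key sets.

    Each element of the union is assigned to its membership pattern, so
    the disjoint region counts are exact for any number of samples (the
    per-pair ``shared_pairs`` are plain intersection sizes).
    """
    if len(profiles) < 2:
        raise DiversityError("overlap needs at least two profiles")
    sets = {label: set(keys) for label, keys in profiles.items()}
    if len(sets) != len(profiles):
        raise DiversityError("duplicate sample labels")
    labels = tuple(sets)
    union = set().union(*sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for element in union:
        members = tuple(sorted(l for l in labels if element in sets[l]))
        regions[members] = regions.get(members, 0) + 1
    unique = {l: regions.get((l,), 0) for l in labels}
    shared_pairs = {
        frozenset((a, b)): len(sets[a] & sets[b]) for a, b in combinations(labels, 2)
    }
    return OverlapReport(
        labels=labels,
        sizes={l: len(sets[l]) for l in labels},
        unique=unique,
        shared_pairs=shared_pairs,
        regions=regions,
    )


# ---------------------------------------------------------------------------
# Taxonomic breakdown
# ---------------------------------------------------------------------------

def domain_phylum_breakdown(profile: AnnotatedProfile) -> pd.DataFrame:
    """Unique-taxon counts and fractions per domain and per phylum.

    Taxa with no phylum label are pooled under the ``"+"`` bucket.
    Fractions within each level sum to 1 for nonempty profiles.
    """
    rows = []
    domains: dict[str, int] = {}
    phyla: dict[str, int] = {}
    for t in profile.taxa:
        domains[t.domain or "unknown"] = domains.get(t.domain or "unknown", 0) + 1
        key = t.phylum if t.phylum else "+"
        phyla[key] = phyla.get(key, 0) + 1
    n = len(profile.taxa)
    for level, counts in (("domain", domains), ("phylum", phyla)):
        for name in sorted(counts):
            rows.append(
                {
                    "sample": profile.sample_label,
                    "level": level,
                    "taxon": name,
                    "count": counts[name],
                    "fraction": counts[name] / n if n else float("nan"),
                }
            )
    return pd.DataFrame(rows, columns=["sample", "level", "taxon", "count", "fraction"])
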
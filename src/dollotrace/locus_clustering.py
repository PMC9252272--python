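"""Turn per-sample TE calls into cross-sample loci and a presence matrix.

Pipeline order mirrors how TE detector output is conventionally curated:

1. :func:`mask_calls` — keep calls lying entirely inside normal-recombination
   regions and drop excluded families (INE-1 by default).
2. :func:`cluster_calls` — single-linkage clustering of calls on the same
   chromosome and strand; two calls join directly if their intervals share at
   least one base pair, and clusters are the transitive closure.
3. :func:`filter_clusters` — retain loci with a single TE family and at most
   one prediction per sample; any violation invalidates the whole cluster.
4. :func:`build_matrix` — binary presence/absence matrix, samples x loci.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    GenomeConfig,
    PresenceMatrix,
    TEInsertionCall,
    TELocus,
    ValidationError,
)

__all__ = [
    "mask_calls",
    "cluster_calls",
    "filter_clusters",
    "build_matrix",
    "cluster_pipeline",
    "TELocus",
    "PresenceMatrix",
]


def mask_calls(
    calls: Sequence[TEInsertionCall], config: GenomeConfig
) -> list[TEInsertionCall]:
    """Keep calls fully contained in a normal-recombination interval whose
    family is not excluded.  Order is preserved.

    A call on a chromosome absent from the config signals a genome/config
    mismatch and raises :class:`ValidationError`.
    """
    if not config.normal_recomb_regions:
        raise ValidationError("genome config declares no normal-recombination regions")
    kept = []
    for call in calls:
        if call.chrom not in config.chrom_lengths:
            raise ValidationError(
                f"call on chromosome {call.chrom!r} absent from genome config"
            )
        if call.family in config.excluded_families:
            continue
        if config.contains_interval(call.chrom, call.start, call.end):
            kept.append(call)
    return kept


def cluster_calls(calls: Iterable[TEInsertionCall]) -> list[TELocus]:
    """Single-linkage interval clustering within each (chrom, strand) group.

    Because direct overlap requires a shared base pair, a coordinate sweep
    over start-sorted calls yields exactly the connected components of the
    pairwise-overlap graph.  Every input call lands in exactly one cluster.
    """
    groups: dict[tuple[str, str], list[TEInsertionCall]] = {}
    for call in calls:
        groups.setdefault((call.chrom, call.strand), []).append(call)

    loci: list[TELocus] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda c: (c.start, c.end, c.sample_id))
        current: list[TEInsertionCall] = []
        max_end = -1
        for call in members:
            if current and call.start >= max_end:
                loci.append(TELocus(current))
                current = []
                max_end = -1
            current.append(call)
            max_end = max(max_end, call.end)
        if current:
            loci.append(TELocus(current))
    return loci


def filter_clusters(clusters: Iterable[TELocus]) -> list[TELocus]:
    """Drop low-quality loci: more than one TE family, or any sample
    contributing more than one call, invalidates the whole cluster."""
    kept = []
    for locus in clusters:
        if len(locus.families) != 1:
            continue
        if any(len(calls) > 1 for calls in locus.members.values()):
            continue
        kept.append(locus)
    return kept


def build_matrix(
    loci: Sequence[TELocus], samples: Sequence[str]
) -> PresenceMatrix:
    """Binary matrix over the given sample order; columns sorted by
    (chrom, start, end, strand, family)."""
    sample_set = set(samples)
    if len(sample_set) != len(samples):
        raise ValidationError("duplicate sample labels")
    for locus in loci:
        unknown = locus.samples - sample_set
        if unknown:
            raise ValidationError(
                f"locus {locus.locus_id} references unknown samples {sorted(unknown)}"
            )
    if not loci:
        raise ValidationError("cannot build a presence matrix from zero loci")
    ordered = sorted(
        loci, key=lambda l: (l.chrom, l.start, l.end, l.strand, l.family)
    )
    values = np.zeros((len(samples), len(ordered)), dtype=np.uint8)
    index = {s: i for i, s in enumerate(samples)}
    for j, locus in enumerate(ordered):
        for sample in locus.samples:
            values[index[sample], j] = 1
    return PresenceMatrix(
        pd.DataFrame(values, index=list(samples), columns=[l.locus_id for l in ordered])
    )


def cluster_pipeline(
    calls_by_sample: dict[str, list[TEInsertionCall]],
    config: GenomeConfig,
) -> tuple[PresenceMatrix, list[TELocus], dict[str, int]]:
    """Run mask -> cluster -> filter -> matrix and report per-stage counts."""
    samples = list(calls_by_sample)
    all_calls = [c for s in samples for c in calls_by_sample[s]]
    masked = mask_calls(all_calls, config)
    clusters = cluster_calls(masked)
    loci = filter_clusters(clusters)
    stats = {
        "calls_in": len(all_calls),
        "calls_after_masking": len(masked),
        "clusters": len(clusters),
        "loci_retained": len(loci),
    }
    matrix = build_matrix(loci, samples)
    stats["matrix_samples"] = matrix.n_samples
    stats["matrix_loci"] = matrix.n_loci
    return matrix, loci, stats
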
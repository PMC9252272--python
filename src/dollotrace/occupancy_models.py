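"""Occupancy-spectrum analysis and transposition-model discrimination.

The occupancy of a locus is the number of samples carrying it (the column
sum of the presence matrix).  In a genomic region free of shared
copy-number-loss events, the shape of the occupancy spectrum separates two
models of TE proliferation in cell culture:

* **burst** ("early transposition and subsequent deletion") — insertions
  arose once, before the sublines diverged, so absent deletions every locus
  is carried by every sample and the spectrum piles up at k = N;
* **ongoing** ("ongoing transposition in cell culture") — insertions keep
  accumulating along the tree, so most loci are private or shared by small
  clades and the spectrum leans toward low k.

The classifier simulates spectra under both models (sharing the tree, the
sample count and the expected locus total) and assigns the observed
spectrum to the model with the smaller total-variation distance to the
model's mean normalized spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    PresenceMatrix,
    ValidationError,
    parse_locus_id,
)
from .dollo_phylo import heuristic_search, rf_distance
from .synthetic_data import SimConfig
from .tree import Tree

__all__ = [
    "OccupancySpectrum",
    "restrict_matrix",
    "occupancy_spectrum",
    "burst_fraction_statistic",
    "simulate_occupancy_spectrum",
    "classify_model",
    "region_tree_concordance",
]


@dataclass
class OccupancySpectrum:
    """Histogram of locus occupancies over N samples."""

    n_samples: int
    counts: dict[int, int]
    region: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        for k, count in self.counts.items():
            if not (1 <= k <= self.n_samples):
                raise ValidationError(f"occupancy {k} outside 1..{self.n_samples}")
            if count < 0:
                raise ValidationError("occupancy counts must be >= 0")

    @property
    def n_loci(self) -> int:
        return sum(self.counts.values())

    def normalized(self) -> np.ndarray:
        """Probability vector over k = 1..N."""
        vec = np.zeros(self.n_samples, dtype=float)
        for k, count in self.counts.items():
            vec[k - 1] = count
        total = vec.sum()
        if total == 0:
            raise ValidationError("empty occupancy spectrum")
        return vec / total

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "occupancy": list(range(1, self.n_samples + 1)),
                "n_loci": [self.counts.get(k, 0) for k in range(1, self.n_samples + 1)],
            }
        )


def restrict_matrix(
    matrix: PresenceMatrix,
    region: Optional[tuple[str, int, int]] = None,
    sample_subset: Optional[set[str]] = None,
) -> PresenceMatrix:
    """Keep loci fully inside the region (0-based half-open) and rows in the
    sample subset; columns that become all-absent are dropped."""
    df = matrix.df
    if sample_subset is not None:
        unknown = set(sample_subset) - set(matrix.samples)
        if unknown:
            raise ValidationError(f"unknown samples in subset: {sorted(unknown)}")
        df = df.loc[[s for s in matrix.samples if s in sample_subset]]
    if region is not None:
        chrom, rstart, rend = region
        keep = []
        for lid in df.columns:
            c, start, end, _, _ = parse_locus_id(lid)
            if c == chrom and rstart <= start and end <= rend:
                keep.append(lid)
        df = df[keep]
    df = df.loc[:, df.sum(axis=0) > 0]
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(
            f"restriction to region={region} subset={sample_subset} left an "
            f"empty matrix ({df.shape[0]} samples x {df.shape[1]} loci)"
        )
    return PresenceMatrix(df)


def occupancy_spectrum(
    matrix: PresenceMatrix, region: Optional[tuple[str, int, int]] = None
) -> OccupancySpectrum:
    """Occupancy histogram of a (typically region-restricted) matrix."""
    sums = matrix.column_sums()
    counts: dict[int, int] = {}
    for k in sums:
        counts[int(k)] = counts.get(int(k), 0) + 1
    return OccupancySpectrum(n_samples=matrix.n_samples, counts=counts, region=region)


def burst_fraction_statistic(spectrum: OccupancySpectrum) -> float:
    """Fraction of loci carried by every sample.

    Values near 1 are what a pre-divergence transposition burst leaves
    behind (absent deletions); values near 0 indicate insertions arising
    along the tree.
    """
    total = spectrum.n_loci
    if total == 0:
        raise ValidationError("empty occupancy spectrum")
    return spectrum.counts.get(spectrum.n_samples, 0) / total


def simulate_occupancy_spectrum(
    config: SimConfig, rng: np.random.Generator
) -> OccupancySpectrum:
    """Draw one occupancy spectrum under a simulation config.

    Coordinate-free fast path: per branch, the number of insertions is
    Poisson with the branch's total rate; each insertion is carried by the
    samples under the branch, thinned by false-negative dropout; spurious
    calls add private (occupancy-1) loci.  Matches the occupancy
    distribution of the full simulator when deletions are disabled — it
    refuses configs with deletion events, mirroring the restriction of the
    occupancy analysis to regions without shared copy-number loss.
    """
    if config.deletions:
        raise ValidationError(
            "occupancy simulation assumes a deletion-free region; "
            "got a config with deletion events"
        )
    tree = config.tree
    clades = tree.branch_clades()
    n_samples = len(tree.leaf_names())
    branch_rate: dict[str, float] = {}
    for per_branch in config.rates.values():
        for branch, lam in per_branch.items():
            branch_rate[branch] = branch_rate.get(branch, 0.0) + lam

    counts: dict[int, int] = {}
    for branch in sorted(branch_rate):
        lam = branch_rate[branch]
        if lam <= 0:
            continue
        carriers = len(clades[branch])
        n_new = int(rng.poisson(lam))
        if n_new == 0:
            continue
        if config.fn_rate > 0:
            detected = rng.binomial(carriers, 1.0 - config.fn_rate, size=n_new)
        else:
            detected = np.full(n_new, carriers)
        for k in detected:
            if k > 0:
                counts[int(k)] = counts.get(int(k), 0) + 1
    if config.fp_rate > 0:
        n_fp = int(rng.poisson(config.fp_rate * n_samples))
        if n_fp:
            counts[1] = counts.get(1, 0) + n_fp
    return OccupancySpectrum(n_samples=n_samples, counts=counts)


def _mean_normalized_spectrum(
    config: SimConfig, replicates: int, rng: np.random.Generator
) -> np.ndarray:
    acc = np.zeros(len(config.tree.leaf_names()), dtype=float)
    for _ in range(replicates):
        acc += simulate_occupancy_spectrum(config, rng).normalized()
    return acc / replicates


def total_variation_distance(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def classify_model(
    observed: OccupancySpectrum,
    burst_config: SimConfig,
    ongoing_config: SimConfig,
    replicates: int = 50,
    seed: int = 0,
    indeterminate_tol: float = 0.02,
) -> tuple[str, dict[str, float]]:
    """Assign an observed occupancy spectrum to the closer transposition
    model.

    Both configs must share the tree (and hence N); simulated spectra
    include the configs' detection noise so the decision is not trivially
    keyed to occupancy N vs N-1.  Returns the label ('burst', 'ongoing', or
    'indeterminate' when the distances differ by less than
    ``indeterminate_tol``) plus both total-variation distances.
    """
    if burst_config.tree.clades(include_trivial=True) != ongoing_config.tree.clades(
        include_trivial=True
    ):
        raise ValidationError("model configs must share the same tree")
    if observed.n_samples != len(burst_config.tree.leaf_names()):
        raise ValidationError("observed spectrum sample count differs from configs")
    rng = np.random.default_rng(seed)
    p_obs = observed.normalized()
    distances = {
        "burst": total_variation_distance(
            p_obs, _mean_normalized_spectrum(burst_config, replicates, rng)
        ),
        "ongoing": total_variation_distance(
            p_obs, _mean_normalized_spectrum(ongoing_config, replicates, rng)
        ),
    }
    if abs(distances["burst"] - distances["ongoing"]) < indeterminate_tol:
        label = "indeterminate"
    else:
        label = min(distances, key=distances.get)
    return label, distances


def region_tree_concordance(
    matrix: PresenceMatrix,
    region: Optional[tuple[str, int, int]],
    genome_tree: Tree,
    replicates: int = 50,
    seed: int = 0,
) -> tuple[Tree, int, list[frozenset[str]]]:
    """Infer a tree from the region-restricted matrix and compare it with the
    genome-wide tree: returns (region tree, rooted RF distance, the genome
    tree's nontrivial clades recovered in the region tree)."""
    restricted = restrict_matrix(matrix, region=region)
    if set(restricted.samples) != set(matrix.samples):
        raise ValidationError(
            "region restriction dropped samples; concordance needs all taxa"
        )
    region_tree, _ = heuristic_search(restricted, replicates=replicates, seed=seed)
    distance = rf_distance(region_tree, genome_tree)
    all_leaves = frozenset(genome_tree.leaf_names())
    shared = sorted(
        (c for c in genome_tree.clades() & region_tree.clades() if c != all_leaves),
        key=lambda c: (len(c), sorted(c)),
    )
    return region_tree, distance, shared
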
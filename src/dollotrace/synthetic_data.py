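"""Forward simulation of clonal subline evolution.

The generator produces exactly the inputs the analysis consumes — per-sample
TE insertion calls, per-window depth tables — together with full ground
truth, so every pipeline stage is testable without sequencing data.

Model
-----
A known subline tree is evolved forward.  On each branch ``b`` and for each
TE family ``f``, the number of new insertions is Poisson with mean
``lambda_{f,b}``; each insertion gets a uniform position inside the
normal-recombination regions, a uniform strand, and a uniform haplotype in
``1..ploidy``.  Insertions are clonally inherited by all descendant samples.
Segmental deletion events on a branch remove, from all its descendants, the
loci lying in the deleted interval on the affected haplotype(s) — because
the cells are polyploid, a one-haplotype deletion only removes the subset of
insertions that happen to sit on that haplotype.

Detector noise is layered on at emission time: per-(sample, locus) i.i.d.
false-negative dropout, Poisson-distributed private false-positive calls,
and breakpoint jitter of up to J bp on each side of the insertion point (so
cross-sample calls still share the insertion point and overlap directly,
but are not byte-identical).

Everything is deterministic given the config's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    GenomeConfig,
    PresenceMatrix,
    TEInsertionCall,
    ValidationError,
    make_locus_id,
    parse_locus_id,
)
from .formats_io import write_te_bed, write_window_table, write_newick
from .tree import Tree

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimLocus",
    "DeletionEvent",
    "simulate_evolution",
    "generate_sample_calls",
    "emit_sample_beds",
    "simulate_depth",
    "align_to_truth",
    "default_genome",
    "random_tree",
    "uniform_rates",
    "burst_config",
    "ongoing_config",
    "recovery_config",
    "DEFAULT_FAMILIES",
]

# the most transpositionally active families in Drosophila cell culture;
# used as default family labels for simulated insertions
DEFAULT_FAMILIES = (
    "blood",
    "copia",
    "297",
    "3S18",
    "1731",
    "diver",
    "mdg1",
    "17.6",
    "jockey",
    "Juan",
)

# dm6 major-arm lengths with the euchromatic normal-recombination regions
# used for masking (region boundaries quoted 1-based inclusive, stored
# 0-based half-open)
_DM6_ARMS = {
    "chrX": 23542271,
    "chr2L": 23513712,
    "chr2R": 25286936,
    "chr3L": 28110227,
    "chr3R": 32079331,
}
_DM6_NORMAL_RECOMB = [
    ("chrX", 405967, 20928973),
    ("chr2L", 200000, 20100000),
    ("chr2R", 6412495, 25112477),
    ("chr3L", 100000, 21906900),
    ("chr3R", 4774278, 31974278),
]


def default_genome(
    ploidy_by_sample: Optional[dict[str, int]] = None, default_ploidy: int = 4
) -> GenomeConfig:
    """Fly-arm genome with euchromatic normal-recombination regions, INE-1
    excluded, tetraploid baseline (cultured fly cells are typically
    tetraploid)."""
    return GenomeConfig(
        chrom_lengths=dict(_DM6_ARMS),
        normal_recomb_regions=[(c, s - 1, e) for c, s, e in _DM6_NORMAL_RECOMB],
        ploidy_by_sample=dict(ploidy_by_sample or {}),
        default_ploidy=default_ploidy,
    )


@dataclass(frozen=True)
class DeletionEvent:
    """Segmental deletion on a branch, removing ``haplotypes`` copies of the
    interval from all samples descending from the branch."""

    branch: str
    chrom: str
    start: int
    end: int
    haplotypes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("deletion interval must have start < end")
        if not self.haplotypes:
            raise ValidationError("deletion must affect >= 1 haplotype")


@dataclass
class SimConfig:
    """Study conditions for one simulated clonal-evolution experiment.

    ``rates`` maps family -> branch id -> expected number of new insertions
    on that branch (branch ids per :meth:`Tree.assign_branch_ids`, including
    the pre-root branch ``"root"``).
    """

    tree: Tree
    rates: dict[str, dict[str, float]]
    genome: GenomeConfig = field(default_factory=default_genome)
    ploidy: int = 4
    deletions: list[DeletionEvent] = field(default_factory=list)
    fn_rate: float = 0.0
    fp_rate: float = 0.0
    jitter: int = 3
    min_locus_spacing: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ploidy < 1:
            raise ValidationError("ploidy must be >= 1")
        if not (0.0 <= self.fn_rate <= 1.0):
            raise ValidationError("fn_rate must lie in [0, 1]")
        if self.fp_rate < 0:
            raise ValidationError("fp_rate must be >= 0")
        if self.jitter < 0:
            raise ValidationError("jitter must be >= 0")
        branch_ids = set(self.tree.branch_ids())
        for family, per_branch in self.rates.items():
            for branch, lam in per_branch.items():
                if branch not in branch_ids:
                    raise ValidationError(
                        f"rate for unknown branch {branch!r} (family {family})"
                    )
                if lam < 0:
                    raise ValidationError("insertion rates must be >= 0")
        for deletion in self.deletions:
            if deletion.branch not in branch_ids:
                raise ValidationError(
                    f"deletion references unknown branch {deletion.branch!r}"
                )
            if deletion.chrom not in self.genome.chrom_lengths:
                raise ValidationError(
                    f"deletion on unknown chromosome {deletion.chrom!r}"
                )
            if deletion.end > self.genome.chrom_lengths[deletion.chrom]:
                raise ValidationError("deletion interval outside chromosome")
            if any(h < 1 or h > self.ploidy for h in deletion.haplotypes):
                raise ValidationError("deletion haplotypes outside ploidy bounds")

    @property
    def samples(self) -> list[str]:
        return self.tree.leaf_names()


@dataclass(frozen=True)
class SimLocus:
    """One true insertion: a 1-bp breakpoint on one haplotype."""

    chrom: str
    pos: int
    strand: str
    family: str
    haplotype: int
    branch: str

    @property
    def locus_id(self) -> str:
        return make_locus_id(self.chrom, self.pos, self.pos + 1, self.strand, self.family)


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    tree: Tree
    loci: list[SimLocus]
    sample_loci: dict[str, set[int]]  # sample -> indices into loci
    gains: pd.DataFrame  # branch x family insertion counts (pre-deletion)
    deletion_ledger: list[dict]

    def surviving_indices(self) -> list[int]:
        """Loci still present in at least one sample."""
        seen: set[int] = set()
        for idx_set in self.sample_loci.values():
            seen |= idx_set
        return sorted(seen)

    def truth_matrix(self) -> PresenceMatrix:
        """Binary matrix of surviving loci (canonical point-locus ids),
        columns sorted like the clustering output."""
        surviving = self.surviving_indices()
        if not surviving:
            raise ValidationError("no surviving loci; truth matrix would be empty")
        order = sorted(
            surviving,
            key=lambda i: (
                self.loci[i].chrom,
                self.loci[i].pos,
                self.loci[i].strand,
                self.loci[i].family,
            ),
        )
        samples = self.tree.leaf_names()
        values = np.zeros((len(samples), len(order)), dtype=np.uint8)
        col = {idx: j for j, idx in enumerate(order)}
        for i, sample in enumerate(samples):
            for idx in self.sample_loci[sample]:
                values[i, col[idx]] = 1
        return PresenceMatrix.from_arrays(
            samples, [self.loci[i].locus_id for i in order], values
        )

    def gains_by_branch(self) -> pd.Series:
        return self.gains.sum(axis=1)


def _region_arrays(genome: GenomeConfig) -> tuple[list[tuple[str, int, int]], np.ndarray]:
    regions = list(genome.normal_recomb_regions)
    if not regions:
        raise ValidationError("genome config has no normal-recombination regions")
    lengths = np.array([e - s for _, s, e in regions], dtype=float)
    return regions, lengths / lengths.sum()


def _draw_position(
    regions, probs, rng: np.random.Generator
) -> tuple[str, int]:
    idx = rng.choice(len(regions), p=probs)
    chrom, start, end = regions[idx]
    return chrom, int(rng.integers(start, end))


def simulate_evolution(config: SimConfig) -> SimTruth:
    """Run the forward simulation and return full ground truth.

    Branches are visited in preorder and families alphabetically, so output
    is deterministic for a fixed seed.  Same-(chrom, strand) insertions are
    kept at least ``min_locus_spacing`` bp apart (positions are redrawn on
    collision), which makes homoplasy impossible by construction and keeps
    distinct loci from merging under breakpoint jitter.
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree
    branch_nodes = tree.assign_branch_ids()
    branch_order = tree.branch_ids()
    clades = tree.branch_clades()
    regions, probs = _region_arrays(config.genome)

    families = sorted(config.rates)
    gains = pd.DataFrame(
        np.zeros((len(branch_order), len(families)), dtype=np.int64),
        index=branch_order,
        columns=families,
    )
    loci: list[SimLocus] = []
    occupied: dict[tuple[str, str], list[int]] = {}

    def place(chrom: str, strand: str, pos: int) -> bool:
        taken = occupied.setdefault((chrom, strand), [])
        if any(abs(pos - p) < config.min_locus_spacing for p in taken):
            return False
        taken.append(pos)
        return True

    for branch in branch_order:
        for family in families:
            lam = config.rates[family].get(branch, 0.0)
            if lam <= 0:
                continue
            n_new = int(rng.poisson(lam))
            gains.loc[branch, family] += n_new
            for _ in range(n_new):
                for _attempt in range(1000):
                    chrom, pos = _draw_position(regions, probs, rng)
                    strand = "+" if rng.random() < 0.5 else "-"
                    if place(chrom, strand, pos):
                        break
                else:  # pragma: no cover - genome saturated
                    raise ValidationError(
                        "could not place insertion; genome too crowded"
                    )
                haplotype = int(rng.integers(1, config.ploidy + 1))
                loci.append(
                    SimLocus(chrom, pos, strand, family, haplotype, branch)
                )

    # clonal inheritance: a locus is carried by every sample descending from
    # its gain branch
    sample_loci: dict[str, set[int]] = {s: set() for s in tree.leaf_names()}
    for idx, locus in enumerate(loci):
        for sample in clades[locus.branch]:
            sample_loci[sample].add(idx)

    # deletions: on branch b, loci gained on b or an ancestor of b that sit
    # on an affected haplotype inside the interval vanish from b's
    # descendants (a deletion cannot remove insertions that arrive later)
    ledger: list[dict] = []
    ancestors: dict[str, set[str]] = {}
    for branch, node in branch_nodes.items():
        anc = set()
        cur = node
        while cur is not None:
            anc.add(cur.branch_id)
            cur = cur.parent
        ancestors[branch] = anc
    for deletion in config.deletions:
        affected_samples = clades[deletion.branch]
        removed: list[int] = []
        for idx, locus in enumerate(loci):
            if (
                locus.chrom == deletion.chrom
                and deletion.start <= locus.pos < deletion.end
                and locus.haplotype in deletion.haplotypes
                and locus.branch in ancestors[deletion.branch]
            ):
                removed.append(idx)
                for sample in affected_samples:
                    sample_loci[sample].discard(idx)
        ledger.append(
            {
                "branch": deletion.branch,
                "chrom": deletion.chrom,
                "start": deletion.start,
                "end": deletion.end,
                "haplotypes": deletion.haplotypes,
                "n_loci_removed": len(removed),
                "removed_indices": removed,
            }
        )

    return SimTruth(
        tree=tree,
        loci=loci,
        sample_loci=sample_loci,
        gains=gains,
        deletion_ledger=ledger,
    )


def generate_sample_calls(
    truth: SimTruth, config: SimConfig
) -> dict[str, list[TEInsertionCall]]:
    """Emulate detector output: per-sample calls with breakpoint jitter,
    false-negative dropout and spurious private calls.

    Each emitted call spans the true insertion point, with its start moved
    left and its end moved right by independent uniform offsets in
    ``[0, jitter]`` — so calls for the same locus always overlap directly
    but rarely coincide.  Deterministic given the config seed (a fixed
    offset separates this RNG stream from the evolution stream).
    """
    rng = np.random.default_rng(config.seed + 1)
    regions, probs = _region_arrays(config.genome)
    families = sorted(config.rates) or list(DEFAULT_FAMILIES)
    calls: dict[str, list[TEInsertionCall]] = {}
    for sample in sorted(truth.sample_loci):
        sample_calls: list[TEInsertionCall] = []
        for idx in sorted(truth.sample_loci[sample]):
            locus = truth.loci[idx]
            if config.fn_rate > 0 and rng.random() < config.fn_rate:
                continue
            left = int(rng.integers(0, config.jitter + 1)) if config.jitter else 0
            right = int(rng.integers(0, config.jitter + 1)) if config.jitter else 0
            sample_calls.append(
                TEInsertionCall(
                    sample_id=sample,
                    chrom=locus.chrom,
                    start=locus.pos - left,
                    end=locus.pos + 1 + right,
                    family=locus.family,
                    strand=locus.strand,
                    support="sim",
                )
            )
        n_fp = int(rng.poisson(config.fp_rate)) if config.fp_rate > 0 else 0
        for _ in range(n_fp):
            chrom, pos = _draw_position(regions, probs, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            family = families[int(rng.integers(0, len(families)))]
            sample_calls.append(
                TEInsertionCall(
                    sample_id=sample,
                    chrom=chrom,
                    start=pos,
                    end=pos + 1,
                    family=family,
                    strand=strand,
                    support="fp",
                )
            )
        sample_calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
        calls[sample] = sample_calls
    return calls


def emit_sample_beds(
    truth: SimTruth, config: SimConfig, outdir
) -> dict[str, Path]:
    """Write one BED6 file per sample into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    calls = generate_sample_calls(truth, config)
    paths: dict[str, Path] = {}
    for sample, sample_calls in calls.items():
        path = outdir / f"{sample}.bed"
        write_te_bed(sample_calls, path)
        paths[sample] = path
    return paths


def align_to_truth(matrix: PresenceMatrix, truth: SimTruth) -> PresenceMatrix:
    """Rename clustered locus columns to the truth locus ids they cover.

    A clustered locus matches the unique truth locus with the same
    chromosome, strand and family whose insertion point falls inside the
    cluster interval.  Raises if any column is unmatched or ambiguous —
    under detector noise that is expected, and this helper is then the
    wrong tool.  Rows and columns are reordered to the truth-matrix layout
    (tree leaf order; loci sorted by chrom, position, strand, family), so
    the result is directly comparable with :meth:`SimTruth.truth_matrix`.
    """
    by_key: dict[tuple[str, str, str], list[SimLocus]] = {}
    for idx in truth.surviving_indices():
        locus = truth.loci[idx]
        by_key.setdefault((locus.chrom, locus.strand, locus.family), []).append(locus)
    renames: dict[str, str] = {}
    for lid in matrix.locus_ids:
        chrom, start, end, strand, family = parse_locus_id(lid)
        hits = [
            l
            for l in by_key.get((chrom, strand, family), [])
            if start <= l.pos < end
        ]
        if len(hits) != 1:
            raise ValidationError(
                f"clustered locus {lid} matches {len(hits)} truth loci"
            )
        renames[lid] = hits[0].locus_id
    renamed = matrix.df.rename(columns=renames)
    ordered_cols = sorted(
        renamed.columns,
        key=lambda lid: tuple(parse_locus_id(lid)[i] for i in (0, 1, 3, 4)),
    )
    samples = truth.tree.leaf_names()
    if set(samples) != set(renamed.index):
        raise ValidationError("matrix samples do not match the truth tree leaves")
    return PresenceMatrix(renamed.loc[samples, ordered_cols])


# ----------------------------------------------------------------- depth sim
def simulate_depth(
    config: SimConfig,
    cn_segments: Optional[Mapping[str, Sequence[tuple[str, int, int, int]]]] = None,
    mean_count: float = 100.0,
    gc_bias: Optional[Sequence[float]] = None,
    window_size: int = 10_000,
    low_mappability_fraction: float = 0.02,
    samples: Optional[Sequence[str]] = None,
) -> dict[str, pd.DataFrame]:
    """Per-sample window tables with Poisson depth over copy-number segments.

    ``cn_segments[sample]`` lists (chrom, start, end, copy_number); windows
    outside any segment sit at the sample's baseline ploidy.  Window counts
    are Poisson(mean_count * cn / ploidy * bias(gc)), where ``gc_bias`` are
    polynomial coefficients (numpy convention, highest power first)
    evaluated at the window GC and normalized to mean 1 over the drawn GC
    values; GC is Normal(0.40, 0.025) clipped to [0.30, 0.48] — fly-like
    euchromatic windows, with the bulk inside the GC-correction's expected
    range.  A ``low_mappability_fraction`` of windows gets
    mappability below the exclusion threshold; the rest are fully mappable.
    Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed + 2)
    cn_segments = cn_segments or {}
    if samples is None:
        samples = config.samples
    tables: dict[str, pd.DataFrame] = {}
    for sample in samples:
        segs = list(cn_segments.get(sample, []))
        for i, (chrom_a, s_a, e_a, _) in enumerate(segs):
            for chrom_b, s_b, e_b, _ in segs[i + 1 :]:
                if chrom_a == chrom_b and s_a < e_b and s_b < e_a:
                    raise ValidationError(
                        f"overlapping copy-number segments for {sample}"
                    )
        ploidy = config.genome.ploidy_by_sample.get(sample, config.ploidy)
        rows = []
        for chrom in sorted(config.genome.chrom_lengths):
            length = config.genome.chrom_lengths[chrom]
            for start in range(0, length - window_size + 1, window_size):
                end = start + window_size
                cn = ploidy
                mid = start + window_size // 2
                for seg_chrom, seg_start, seg_end, seg_cn in segs:
                    if seg_chrom == chrom and seg_start <= mid < seg_end:
                        cn = seg_cn
                        break
                rows.append((chrom, start, end, cn))
        frame = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn_true"])
        n = len(frame)
        gc = np.clip(rng.normal(0.40, 0.025, size=n), 0.30, 0.48)
        mappability = np.ones(n)
        n_low = int(round(low_mappability_fraction * n))
        if n_low:
            low_idx = rng.choice(n, size=n_low, replace=False)
            mappability[low_idx] = rng.uniform(0.0, 0.84, size=n_low)
        bias = np.ones(n)
        if gc_bias is not None:
            bias = np.polyval(np.asarray(gc_bias, dtype=float), gc)
            if np.any(bias <= 0):
                raise ValidationError("gc_bias yields non-positive factors")
            bias = bias / bias.mean()
        lam = mean_count * frame["cn_true"].to_numpy() / ploidy * bias
        counts = rng.poisson(lam)
        tables[sample] = pd.DataFrame(
            {
                "chrom": frame["chrom"],
                "start": frame["start"],
                "end": frame["end"],
                "count": counts,
                "gc": gc,
                "mappability": mappability,
            }
        )
    return tables


# ------------------------------------------------------------------- presets
def random_tree(
    n_taxa: int, seed: int = 0, names: Optional[Sequence[str]] = None
) -> Tree:
    """Random rooted binary tree by sequential random leaf addition."""
    if n_taxa < 2:
        raise ValidationError("a tree needs at least 2 taxa")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"S{i + 1}" for i in range(n_taxa)]
    topo = 0
    for leaf in range(1, n_taxa):
        positions = _collect_positions(topo, leaf)
        topo = positions[int(rng.integers(0, len(positions)))]
    return Tree.from_topology(topo, names)


def _collect_positions(topo, leaf) -> list:
    out = [(topo, leaf)]
    if isinstance(topo, tuple):
        left, right = topo
        out.extend((nl, right) for nl in _collect_positions(left, leaf))
        out.extend((left, nr) for nr in _collect_positions(right, leaf))
    return out


def uniform_rates(
    tree: Tree,
    families: Sequence[str],
    gains_per_branch: float,
    branches: Optional[Sequence[str]] = None,
) -> dict[str, dict[str, float]]:
    """Split ``gains_per_branch`` expected insertions per branch evenly
    across families, on the given branches (all branches by default)."""
    if branches is None:
        branches = tree.branch_ids()
    per_family = gains_per_branch / len(families)
    return {f: {b: per_family for b in branches} for f in families}


def burst_config(
    tree: Tree,
    n_loci: float = 500.0,
    families: Sequence[str] = DEFAULT_FAMILIES[:5],
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SimConfig:
    """"Early transposition and subsequent deletion" conditions: the entire
    insertion mass sits on the pre-root branch (the burst during cell line
    establishment), so every locus starts out present in every sample."""
    tree.assign_branch_ids()
    rates = {f: {"root": n_loci / len(families)} for f in families}
    return SimConfig(
        tree=tree, rates=rates, fn_rate=fn_rate, fp_rate=fp_rate, seed=seed, **kwargs
    )


def ongoing_config(
    tree: Tree,
    n_loci: float = 500.0,
    families: Sequence[str] = DEFAULT_FAMILIES[:5],
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
    terminal_only: bool = False,
    **kwargs,
) -> SimConfig:
    """"Ongoing transposition in cell culture" conditions: the same expected
    number of insertions spread evenly over the ingroup branches (every
    branch except the pre-root one); ``terminal_only`` restricts gains to
    terminal branches, making every locus private."""
    tree.assign_branch_ids()
    if terminal_only:
        branches = [b for b in tree.branch_ids() if b in set(tree.leaf_names())]
    else:
        branches = [b for b in tree.branch_ids() if b != "root"]
    rates = uniform_rates(tree, families, n_loci / len(branches), branches)
    return SimConfig(
        tree=tree, rates=rates, fn_rate=fn_rate, fp_rate=fp_rate, seed=seed, **kwargs
    )


def recovery_config(
    n_taxa: int = 12,
    gains_per_branch: float = 30.0,
    families: Sequence[str] = DEFAULT_FAMILIES[:5],
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    seed: int = 0,
    tree_seed: Optional[int] = None,
    **kwargs,
) -> SimConfig:
    """Topology-recovery conditions: a random tree with the same expected
    insertion count on every branch (pre-root included)."""
    tree = random_tree(n_taxa, seed=seed if tree_seed is None else tree_seed)
    rates = uniform_rates(tree, families, gains_per_branch)
    return SimConfig(
        tree=tree, rates=rates, fn_rate=fn_rate, fp_rate=fp_rate, seed=seed, **kwargs
    )
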
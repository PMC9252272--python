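"""Core record types shared across the pipeline.

Coordinate convention
---------------------
All in-memory intervals are 0-based half-open, BED style.  Configuration
files and region strings (``chrX:405967-20928973``) follow the 1-based
inclusive genome-browser convention and are converted exactly once, on
load (``start - 1``, ``end`` unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


class DolloTraceError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(DolloTraceError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(DolloTraceError):
    """An in-memory object violates one of its invariants."""


# default exclusion: INE-1 has been transpositionally dead in Drosophila
# for millions of years, so any call on it is a mapping artifact
DEFAULT_EXCLUDED_FAMILIES = frozenset({"INE-1"})


@dataclass(frozen=True)
class TEInsertionCall:
    """One detector prediction of a nonreference TE insertion in one sample.

    ``support`` is an opaque score carried through from the detector and is
    never interpreted by the pipeline.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    family: str
    strand: str
    support: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"call {self.chrom}:{self.start}-{self.end}: start must be < end"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"call {self.chrom}:{self.start}-{self.end}: "
                f"strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.family:
            raise ValidationError(
                f"call {self.chrom}:{self.start}-{self.end}: empty TE family"
            )

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def make_locus_id(chrom: str, start: int, end: int, strand: str, family: str) -> str:
    """Canonical locus identifier ``chrom:start-end:strand:family``.

    Coordinates are the internal 0-based half-open ones, so identifiers are
    stable and diff-able across runs.
    """
    return f"{chrom}:{start}-{end}:{strand}:{family}"


def parse_locus_id(locus_id: str) -> tuple[str, int, int, str, str]:
    parts = locus_id.split(":")
    if len(parts) < 4:
        raise FormatError(f"malformed locus identifier: {locus_id!r}")
    chrom = parts[0]
    try:
        start_s, end_s = parts[1].split("-", 1)
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"malformed locus identifier: {locus_id!r}") from exc
    strand = parts[2]
    family = ":".join(parts[3:])
    if strand not in ("+", "-") or not family:
        raise FormatError(f"malformed locus identifier: {locus_id!r}")
    return chrom, start, end, strand, family


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive region string into 0-based half-open coords.

    >>> parse_region("chrX:405967-20928973")
    ('chrX', 405966, 20928973)
    """
    try:
        chrom, span = region.rsplit(":", 1)
        start_s, end_s = span.replace(",", "").split("-", 1)
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise FormatError(f"malformed region string: {region!r}") from exc
    if start < 1 or end < start:
        raise FormatError(f"invalid region bounds: {region!r}")
    return chrom, start - 1, end


@dataclass
class GenomeConfig:
    """Genome/region configuration for masking, simulation and CNV calling.

    ``normal_recomb_regions`` are stored 0-based half-open; YAML files hold
    them 1-based inclusive (the convention the region boundaries are usually
    quoted in) and are converted on load.
    """

    chrom_lengths: dict[str, int]
    normal_recomb_regions: list[tuple[str, int, int]]
    excluded_families: set[str] = field(
        default_factory=lambda: set(DEFAULT_EXCLUDED_FAMILIES)
    )
    ploidy_by_sample: dict[str, int] = field(default_factory=dict)
    default_ploidy: int = 4

    def __post_init__(self) -> None:
        for chrom, start, end in self.normal_recomb_regions:
            if chrom not in self.chrom_lengths:
                raise ValidationError(f"region on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValidationError(
                    f"region {chrom}:{start}-{end} outside chromosome bounds"
                )
        for sample, ploidy in self.ploidy_by_sample.items():
            if ploidy < 1:
                raise ValidationError(f"ploidy for {sample!r} must be >= 1")
        if self.default_ploidy < 1:
            raise ValidationError("default ploidy must be >= 1")

    def ploidy(self, sample: str) -> int:
        return self.ploidy_by_sample.get(sample, self.default_ploidy)

    def regions_for(self, chrom: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.normal_recomb_regions if c == chrom]

    def contains_interval(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) lies entirely within one retained region."""
        return any(s <= start and end <= e for s, e in self.regions_for(chrom))

    @classmethod
    def from_yaml(cls, path) -> "GenomeConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: genome config must be a YAML mapping")
        try:
            chrom_lengths = {str(k): int(v) for k, v in raw["chrom_lengths"].items()}
            regions = [
                (str(c), int(s) - 1, int(e))
                for c, s, e in raw.get("normal_recomb_regions", [])
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed genome config: {exc}") from exc
        excluded = set(raw.get("excluded_families", sorted(DEFAULT_EXCLUDED_FAMILIES)))
        ploidy_by_sample = {
            str(k): int(v) for k, v in raw.get("ploidy_by_sample", {}).items()
        }
        return cls(
            chrom_lengths=chrom_lengths,
            normal_recomb_regions=regions,
            excluded_families=excluded,
            ploidy_by_sample=ploidy_by_sample,
            default_ploidy=int(raw.get("default_ploidy", 4)),
        )

    def to_yaml(self, path) -> None:
        raw = {
            "chrom_lengths": dict(self.chrom_lengths),
            # written back in 1-based inclusive coordinates
            "normal_recomb_regions": [
                [c, s + 1, e] for c, s, e in self.normal_recomb_regions
            ],
            "excluded_families": sorted(self.excluded_families),
            "ploidy_by_sample": dict(self.ploidy_by_sample),
            "default_ploidy": self.default_ploidy,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


class TELocus:
    """A cross-sample cluster of overlapping same-strand TE calls.

    Before quality filtering a locus may hold several families or several
    calls from one sample; after :func:`filter_clusters` exactly one family
    remains and each member sample contributes exactly one call.
    """

    __slots__ = ("chrom", "strand", "start", "end", "members")

    def __init__(self, calls: Iterable[TEInsertionCall]):
        calls = list(calls)
        if not calls:
            raise ValidationError("a locus requires at least one call")
        self.chrom = calls[0].chrom
        self.strand = calls[0].strand
        for call in calls:
            if call.chrom != self.chrom or call.strand != self.strand:
                raise ValidationError(
                    "all member calls of a locus must share chrom and strand"
                )
        self.start = min(c.start for c in calls)
        self.end = max(c.end for c in calls)
        self.members: dict[str, list[TEInsertionCall]] = {}
        for call in calls:
            self.members.setdefault(call.sample_id, []).append(call)

    @property
    def calls(self) -> list[TEInsertionCall]:
        return [c for calls in self.members.values() for c in calls]

    @property
    def n_calls(self) -> int:
        return sum(len(v) for v in self.members.values())

    @property
    def families(self) -> set[str]:
        return {c.family for c in self.calls}

    @property
    def family(self) -> str:
        fams = self.families
        if len(fams) != 1:
            raise ValidationError(
                f"locus {self.chrom}:{self.start}-{self.end} has {len(fams)} families"
            )
        return next(iter(fams))

    @property
    def samples(self) -> set[str]:
        return set(self.members)

    @property
    def locus_id(self) -> str:
        return make_locus_id(self.chrom, self.start, self.end, self.strand, self.family)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"TELocus({self.chrom}:{self.start}-{self.end}:{self.strand}, "
            f"{len(self.members)} samples, {self.n_calls} calls)"
        )


class PresenceMatrix:
    """Binary taxa x loci character matrix (1 = insertion present).

    Wraps a pandas DataFrame with sample labels as the index and canonical
    locus identifiers as columns.  Invariants: cells are 0/1, labels are
    unique, and no column is all-absent (such a locus cannot arise from
    clustering observed calls).
    """

    def __init__(self, df: pd.DataFrame):
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError("presence matrix must have >=1 sample and >=1 locus")
        if df.index.duplicated().any():
            raise ValidationError("duplicate sample labels in presence matrix")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate locus identifiers: {dups[:3]}")
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("presence matrix cells must be 0 or 1")
        values = values.astype(np.uint8)
        if (values.sum(axis=0) == 0).any():
            raise ValidationError("presence matrix contains an all-absent locus")
        self.df = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns)

    @classmethod
    def from_arrays(
        cls,
        samples: Sequence[str],
        locus_ids: Sequence[str],
        values: np.ndarray,
    ) -> "PresenceMatrix":
        return cls(pd.DataFrame(np.asarray(values), index=list(samples), columns=list(locus_ids)))

    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_samples(self) -> int:
        return self.df.shape[0]

    @property
    def n_loci(self) -> int:
        return self.df.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def column_sums(self) -> np.ndarray:
        """Occupancy of each locus: number of samples carrying it."""
        return self.values.sum(axis=0)

    def presence_sets(self) -> list[frozenset[str]]:
        """Per locus, the set of samples carrying the insertion."""
        samples = np.array(self.samples, dtype=object)
        vals = self.values
        return [frozenset(samples[vals[:, j] == 1]) for j in range(self.n_loci)]

    def families(self) -> list[str]:
        return [parse_locus_id(lid)[4] for lid in self.locus_ids]

    def locus_records(self) -> list[tuple[str, int, int, str, str]]:
        return [parse_locus_id(lid) for lid in self.locus_ids]

    def family_map(self) -> dict[str, str]:
        return {lid: parse_locus_id(lid)[4] for lid in self.locus_ids}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"PresenceMatrix({self.n_samples} samples x {self.n_loci} loci)"


def character_masks(matrix: PresenceMatrix) -> np.ndarray:
    """Encode each matrix column as a leaf bitmask (bit i = sample i present).

    Sample order follows the matrix row order.  Limited to 63 samples, far
    above anything this pipeline encounters.
    """
    if matrix.n_samples > 63:
        raise ValidationError("bitmask encoding supports at most 63 samples")
    bits = matrix.values != 0
    masks = np.zeros(matrix.n_loci, dtype=np.uint64)
    for i in range(matrix.n_samples):
        masks |= bits[i].astype(np.uint64) << np.uint64(i)
    return masks
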
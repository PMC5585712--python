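"""Genome and annotation model for mariner (Himar1) Tn-Seq.

The mariner transposon inserts exclusively at TA dinucleotides, so the set of
possible insertion sites is enumerable from the genome sequence alone.  This
module loads the reference genome (FASTA) and its annotation (GFF3), builds
the index of TA sites, and applies the feature-relative site-availability
rules used by every downstream stage — most importantly the "first 5%" rule:
insertions in the initial 5% of a coding feature are discounted because they
frequently fail to disrupt function.

Coordinate conventions
----------------------
GFF3 I/O is 1-based inclusive; everything internal is 0-based half-open.
A TA site is identified by the 0-based offset of its 'T' on the forward
strand of its replicon — TA is its own reverse complement, so one canonical
key covers both junction orientations.  Site keys are ``(replicon_id,
position)`` tuples so multi-replicon genomes (chromosome + plasmids) work
throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from gffutils.feature import feature_from_line

SiteKey = tuple[str, int]

_VALID = frozenset("ACGT")
_T = ord("T")
_A = ord("A")


@dataclass(frozen=True)
class GenomeSequence:
    """A single replicon: an id and an uppercase A/C/G/T(/N) residue string."""

    id: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


class Genome:
    """Ordered collection of replicons keyed by record id.

    Multi-record FASTA files are treated as separate replicons; all site and
    alignment coordinates carry the replicon id.
    """

    def __init__(self, replicons: Iterable[GenomeSequence]):
        self._replicons: dict[str, GenomeSequence] = {}
        for rep in replicons:
            if rep.id in self._replicons:
                raise ValueError(f"duplicate replicon id {rep.id!r}")
            self._replicons[rep.id] = rep
        if not self._replicons:
            raise ValueError("genome contains no sequences")

    def __iter__(self) -> Iterator[GenomeSequence]:
        return iter(self._replicons.values())

    def __len__(self) -> int:
        return len(self._replicons)

    def __contains__(self, rep_id: str) -> bool:
        return rep_id in self._replicons

    def __getitem__(self, rep_id: str) -> GenomeSequence:
        return self._replicons[rep_id]

    @property
    def ids(self) -> list[str]:
        return list(self._replicons)

    @property
    def primary(self) -> GenomeSequence:
        """First replicon (the chromosome, by convention)."""
        return next(iter(self._replicons.values()))

    @property
    def total_length(self) -> int:
        return sum(rep.length for rep in self)

    @classmethod
    def from_string(cls, residues: str, rep_id: str = "chr") -> "Genome":
        return cls([GenomeSequence(rep_id, residues.upper())])


def load_genome(path: str | Path, ambiguous: str = "error") -> Genome:
    """Read a FASTA genome, uppercasing residues.

    Parameters
    ----------
    ambiguous:
        ``"error"`` (default) — any non-A/C/G/T residue is a hard error
        naming the offending record; zero-mismatch mapping is undefined over
        ambiguity codes.  ``"mask"`` — non-ACGT residues are replaced by
        ``N``; masked bases can never form a TA site nor match a read.
    """
    if ambiguous not in ("error", "mask"):
        raise ValueError(f"ambiguous policy must be 'error' or 'mask', got {ambiguous!r}")
    path = Path(path)
    replicons = []
    for record in SeqIO.parse(str(path), "fasta"):
        residues = str(record.seq).upper()
        bad = set(residues) - _VALID
        if bad:
            if ambiguous == "error":
                raise ValueError(
                    f"record {record.id!r} in {path.name} contains non-ACGT "
                    f"residues {sorted(bad)}; load with ambiguous='mask' to mask them"
                )
            table = str.maketrans({c: "N" for c in bad})
            residues = residues.translate(table)
        replicons.append(GenomeSequence(record.id, residues))
    if not replicons:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(replicons)


@dataclass
class TAIndex:
    """Sorted TA-site positions per replicon (0-based offset of the 'T')."""

    positions: dict[str, np.ndarray]
    _sets: dict[str, set[int]] = field(default_factory=dict, repr=False)

    def count(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def sites(self) -> Iterator[SiteKey]:
        for rep_id, pos in self.positions.items():
            for p in pos:
                yield (rep_id, int(p))

    def contains(self, rep_id: str, position: int) -> bool:
        if rep_id not in self._sets:
            self._sets[rep_id] = set(map(int, self.positions.get(rep_id, ())))
        return position in self._sets[rep_id]

    def in_replicon(self, rep_id: str) -> np.ndarray:
        return self.positions.get(rep_id, np.empty(0, dtype=np.int64))


def enumerate_ta_sites(genome: Genome) -> TAIndex:
    """All and only TA dinucleotide start offsets; overlaps allowed
    (``TATA`` yields two sites)."""
    positions = {}
    for rep in genome:
        arr = np.frombuffer(rep.residues.encode("ascii"), dtype=np.uint8)
        if len(arr) < 2:
            positions[rep.id] = np.empty(0, dtype=np.int64)
            continue
        mask = (arr[:-1] == _T) & (arr[1:] == _A)
        positions[rep.id] = np.flatnonzero(mask).astype(np.int64)
    return TAIndex(positions)


@dataclass(frozen=True)
class FeatureAnnotation:
    """One annotated feature with 1-based inclusive GFF3 coordinates."""

    feature_id: str
    replicon: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id!r}: strand must be '+' or '-'")
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"feature {self.feature_id!r}: invalid coordinates {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def load_annotation(
    path: str | Path,
    genome: Genome,
    feature_types: Sequence[str] = ("gene",),
) -> list[FeatureAnnotation]:
    """Parse GFF3, keeping rows of the selected types (default ``gene``).

    Duplicate feature ids and coordinates outside the genome are hard errors
    reported with the offending line number.
    """
    path = Path(path)
    wanted = set(feature_types)
    features: list[FeatureAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                row = feature_from_line(line)
            except Exception as exc:  # malformed row
                raise ValueError(f"{path.name}:{lineno}: cannot parse GFF3 row: {exc}") from exc
            if row.featuretype not in wanted:
                continue
            attrs = row.attributes
            fid = (attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name") or [None])[0]
            if fid is None:
                raise ValueError(f"{path.name}:{lineno}: feature has no ID/locus_tag/Name")
            if fid in seen:
                raise ValueError(f"{path.name}:{lineno}: duplicate feature id {fid!r}")
            if row.seqid not in genome:
                raise ValueError(f"{path.name}:{lineno}: unknown replicon {row.seqid!r}")
            if row.end < row.start:
                raise ValueError(f"{path.name}:{lineno}: end < start for {fid!r}")
            if row.start < 1 or row.end > genome[row.seqid].length:
                raise ValueError(
                    f"{path.name}:{lineno}: {fid!r} coordinates {row.start}..{row.end} "
                    f"outside replicon {row.seqid!r} (length {genome[row.seqid].length})"
                )
            product = (attrs.get("product") or [""])[0]
            strand = row.strand if row.strand in ("+", "-") else "+"
            features.append(
                FeatureAnnotation(fid, row.seqid, row.start, row.end, strand, product)
            )
            seen.add(fid)
    return features


@dataclass
class AvailableSiteSet:
    """TA sites assigned to a feature, split by the 5′-end exclusion rule."""

    feature_id: str
    sites: np.ndarray      # available (beyond the exclusion window)
    excluded: np.ndarray   # within the first exclusion_fraction of the feature

    @property
    def n_available(self) -> int:
        return len(self.sites)

    @property
    def n_member(self) -> int:
        return len(self.sites) + len(self.excluded)


def _member_offsets(feature: FeatureAnnotation, positions: np.ndarray):
    """TA sites assigned to the feature and their strand-aware 5′ offsets.

    Membership and offset are resolved by the site's first base *on the read
    strand*: the forward 'T' at p for + features, the base at p+1 (the 'T' of
    the minus-strand TA) for − features.  This makes site assignment exactly
    symmetric under reverse-complementing the genome and flipping strands.
    """
    s = feature.start - 1
    e = feature.end
    if feature.strand == "+":
        lo, hi = s, e - 1                    # p in [s, e-1]
        member = positions[(positions >= lo) & (positions <= hi)]
        offsets = member - s
    else:
        lo, hi = s - 1, e - 2                # p+1 in [s, e-1]
        member = positions[(positions >= lo) & (positions <= hi)]
        offsets = e - member - 2
    return member, offsets


def available_sites(
    feature: FeatureAnnotation,
    ta: TAIndex,
    exclusion_fraction: float = 0.05,
) -> AvailableSiteSet:
    """Assign a feature its TA sites, discounting the first-5% window.

    The exclusion window spans ``floor(exclusion_fraction * length)`` bases
    from the feature's 5′ end (the high-coordinate end for − strand
    features).  ``exclusion_fraction=0`` returns every assigned site.
    """
    if not 0 <= exclusion_fraction < 1:
        raise ValueError("exclusion_fraction must be in [0, 1)")
    positions = ta.in_replicon(feature.replicon)
    member, offsets = _member_offsets(feature, positions)
    window = math.floor(exclusion_fraction * feature.length)
    keep = offsets >= window
    return AvailableSiteSet(feature.feature_id, member[keep], member[~keep])


def feature_site_map(
    annotations: Sequence[FeatureAnnotation],
    ta: TAIndex,
    exclusion_fraction: float = 0.05,
) -> dict[str, AvailableSiteSet]:
    return {
        f.feature_id: available_sites(f, ta, exclusion_fraction) for f in annotations
    }


def site_host_lookup(
    annotations: Sequence[FeatureAnnotation],
    ta: TAIndex,
    exclusion_fraction: float = 0.05,
) -> dict[SiteKey, tuple[str, bool]]:
    """Map each genic TA site to ``(host feature id, disrupts)``.

    ``disrupts`` is True for sites beyond the 5′ exclusion window (an
    insertion there is expected to knock the feature out).  Sites absent from
    the map are intergenic.  For overlapping annotations the first feature
    in order wins.
    """
    lookup: dict[SiteKey, tuple[str, bool]] = {}
    for f in annotations:
        aset = available_sites(f, ta, exclusion_fraction)
        for p in aset.sites:
            lookup.setdefault((f.replicon, int(p)), (f.feature_id, True))
        for p in aset.excluded:
            lookup.setdefault((f.replicon, int(p)), (f.feature_id, False))
    return lookup
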
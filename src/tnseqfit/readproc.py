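"""Barcoded junction-read processing: demultiplex, trim, map, tabulate.

Implements the read-handling rules of an MmeI-based Tn-Seq protocol: exact
barcode demultiplexing, transposon-tag trimming, retention of genomic
junctions of at least 16 bp, exact-match (zero-mismatch) alignment against
both strands of every replicon, and discarding of reads that match more
than one locus.  Uniquely mapped reads are assigned back to their canonical
TA site; ambiguous reads are excluded from site counts but retained in the
totals used later for depth normalization.

The exact-match mapper is a seed-and-verify full-text index: every 16-mer
of the forward strand is indexed, a query is checked on both strands, and
each seed hit is verified over the read's full length, which guarantees
zero-mismatch full-length semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.Seq import reverse_complement
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome import Genome, SiteKey, TAIndex, enumerate_ta_sites

#: bookkeeping categories; every input read lands in exactly one
CATEGORIES = (
    "unique_mapped",
    "ambiguous",
    "unmapped",
    "too_short",
    "undemultiplexed",
    "no_tag",
    "off_ta",
)


def validate_barcode_table(barcode_table: dict[str, str]) -> int:
    """Check barcodes are distinct, non-empty and equal length; returns the
    barcode length."""
    if not barcode_table:
        raise ValueError("barcode table is empty")
    lens = {len(b) for b in barcode_table.values()}
    if len(lens) != 1 or 0 in lens:
        raise ValueError("barcodes must be non-empty and of equal length")
    if len(set(barcode_table.values())) != len(barcode_table):
        raise ValueError("barcode collision: two samples share a barcode")
    return lens.pop()


@dataclass(frozen=True)
class JunctionRead:
    sample_id: str
    genomic_seq: str
    read_id: str


@dataclass
class MappingOutcome:
    """Result of exact-match alignment: status plus candidate loci.

    Each locus is ``(replicon, start, strand)`` where ``start`` is the
    0-based forward-strand offset of the (possibly reverse-complemented)
    full-length match.
    """

    status: str                       # unique | ambiguous | unmapped
    loci: tuple[tuple[str, int, str], ...]

    @property
    def locus(self) -> tuple[str, int, str]:
        if self.status != "unique":
            raise ValueError("locus is defined only for unique outcomes")
        return self.loci[0]

    @property
    def n_candidates(self) -> int:
        return len(self.loci)


class MappingIndex:
    """Exact-match lookup over both strands of all replicons.

    Only forward-strand k-mers are stored; reverse-strand hits are found by
    querying the reverse complement of the read, so every substring of the
    genome (either strand) is guaranteed to return its true origin.
    """

    def __init__(self, genome: Genome, seed_len: int = 16):
        if seed_len < 1:
            raise ValueError("seed_len must be positive")
        self.genome = genome
        self.seed_len = seed_len
        index: dict[str, list[tuple[str, int]]] = {}
        for rep in genome:
            res = rep.residues
            for q in range(len(res) - seed_len + 1):
                index.setdefault(res[q : q + seed_len], []).append((rep.id, q))
        self._index = index

    def candidates(self, seed: str) -> Sequence[tuple[str, int]]:
        return self._index.get(seed, ())


def build_index(genome: Genome, seed_len: int = 16) -> MappingIndex:
    return MappingIndex(genome, seed_len)


def map_read(seq: str, index: MappingIndex) -> MappingOutcome:
    """Full-length exact match on either strand.

    Exactly one locus → unique; two or more → ambiguous; none → unmapped.
    Reads shorter than the seed length cannot be mapped.
    """
    k = index.seed_len
    if len(seq) < k:
        return MappingOutcome("unmapped", ())
    hits: list[tuple[str, int, str]] = []
    for rep_id, q in index.candidates(seq[:k]):
        res = index.genome[rep_id].residues
        if res[q : q + len(seq)] == seq:
            hits.append((rep_id, q, "+"))
    rc = reverse_complement(seq)
    for rep_id, q in index.candidates(rc[:k]):
        res = index.genome[rep_id].residues
        if res[q : q + len(rc)] == rc:
            hits.append((rep_id, q, "-"))
    if not hits:
        return MappingOutcome("unmapped", ())
    if len(hits) == 1:
        return MappingOutcome("unique", tuple(hits))
    return MappingOutcome("ambiguous", tuple(hits))


def locus_to_site(
    locus: tuple[str, int, str], read_len: int, ta: TAIndex
) -> SiteKey | None:
    """Invert the junction geometry: a + alignment starts at the TA's 'T';
    a − alignment ends at the TA's 'A'.  Returns None when the implied
    position is not a TA site (an "off-TA" alignment)."""
    rep_id, q, strand = locus
    p = q if strand == "+" else q + read_len - 2
    return (rep_id, p) if ta.contains(rep_id, p) else None


def assign_to_site(
    outcome: MappingOutcome, read_len: int, ta: TAIndex
) -> tuple[SiteKey | None, str]:
    """Map a unique outcome to ``(site key, orientation)``; site is None for
    off-TA alignments."""
    rep_id, q, strand = outcome.locus
    return locus_to_site(outcome.locus, read_len, ta), strand


@dataclass
class SiteCountTable:
    """Per-sample read counts keyed by TA site, plus full accounting totals."""

    sample_id: str
    counts: dict[SiteKey, list[int]] = field(default_factory=dict)
    unique_mapped: int = 0
    ambiguous: int = 0
    unmapped: int = 0
    too_short: int = 0
    undemultiplexed: int = 0
    no_tag: int = 0
    off_ta: int = 0
    ambiguous_sites: set[SiteKey] = field(default_factory=set)

    def add(self, site: SiteKey, orientation: str, n: int = 1) -> None:
        pair = self.counts.setdefault(site, [0, 0])
        pair[0 if orientation == "+" else 1] += n
        self.unique_mapped += n

    @property
    def assigned_reads(self) -> int:
        return sum(p + m for p, m in self.counts.values())

    @property
    def total_accounted(self) -> int:
        return (
            self.unique_mapped + self.ambiguous + self.unmapped
            + self.too_short + self.undemultiplexed + self.no_tag + self.off_ta
        )

    @property
    def normalization_denominator(self) -> int:
        """Unique + ambiguous reads: ambiguous mappings are excluded from
        site assignment but included for between-library normalization."""
        return self.unique_mapped + self.ambiguous

    def plain_counts(self) -> dict[SiteKey, tuple[int, int]]:
        return {k: (v[0], v[1]) for k, v in self.counts.items()}


@dataclass
class ProcessingResult:
    tables: dict[str, SiteCountTable]
    undemultiplexed: int = 0
    n_records: int = 0

    @property
    def total_accounted(self) -> int:
        return self.undemultiplexed + sum(
            t.total_accounted for t in self.tables.values()
        )


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (title, sequence) from FASTQ, with record-numbered errors."""
    with open(path) as fh:
        try:
            for title, seq, _qual in FastqGeneralIterator(fh):
                yield title, seq
        except ValueError as exc:
            raise ValueError(f"corrupt FASTQ record in {Path(path).name}: {exc}") from exc


def _barcode_from_title(title: str) -> str | None:
    for token in title.split()[1:]:
        if token.startswith("bc:"):
            return token[3:]
    return None


def demultiplex_and_trim(
    records: Iterable[tuple[str, str]],
    barcode_table: dict[str, str],
    transposon_tag: str,
    min_len: int = 16,
    max_len: int = 21,
    layout: str = "header",
) -> Iterator[tuple[str, str | None, str | None, str]]:
    """Demultiplex and trim an iterable of ``(title, seq)`` records.

    Yields ``(category, sample_id, genomic_seq, read_id)``; category is
    ``"ok"`` for accepted reads, else one of undemultiplexed / no_tag /
    too_short.  Layout "header" expects tag+junction with the barcode in the
    title (``bc:<seq>``); layout "inline" expects barcode+tag+junction.
    Remainders longer than ``max_len`` are truncated from the junction end
    (adaptor read-through).
    """
    if layout not in ("header", "inline"):
        raise ValueError("layout must be 'header' or 'inline'")
    if not transposon_tag:
        raise ValueError("transposon_tag must be non-empty")
    bc_len = validate_barcode_table(barcode_table)
    by_barcode = {v: k for k, v in barcode_table.items()}
    tag_len = len(transposon_tag)

    for title, seq in records:
        read_id = title.split()[0]
        if layout == "inline":
            barcode = seq[:bc_len]
            rest = seq[bc_len:]
        else:
            barcode = _barcode_from_title(title)
            rest = seq
        sample = by_barcode.get(barcode)
        if sample is None:
            yield "undemultiplexed", None, None, read_id
            continue
        if not rest.startswith(transposon_tag):
            yield "no_tag", sample, None, read_id
            continue
        genomic = rest[tag_len:]
        if len(genomic) < min_len:
            yield "too_short", sample, None, read_id
            continue
        if len(genomic) > max_len:
            genomic = genomic[:max_len]
        yield "ok", sample, genomic, read_id


def tabulate(
    outcomes: Iterable[tuple[str, SiteKey | None, str | None]],
    sample_id: str,
) -> SiteCountTable:
    """Fold ``(status, site, orientation)`` outcomes into a SiteCountTable.

    Ambiguous reads increment the totals but are never assigned to a site.
    """
    table = SiteCountTable(sample_id)
    for status, site, orientation in outcomes:
        if status == "unique":
            if site is None:
                table.off_ta += 1
            else:
                table.add(site, orientation)
        elif status == "ambiguous":
            table.ambiguous += 1
        elif status == "unmapped":
            table.unmapped += 1
        else:
            raise ValueError(f"unknown mapping status {status!r}")
    return table


def process_fastq(
    fastq_paths: str | Path | Sequence[str | Path],
    genome: Genome,
    barcode_table: dict[str, str],
    transposon_tag: str,
    ta: TAIndex | None = None,
    index: MappingIndex | None = None,
    min_len: int = 16,
    max_len: int = 21,
    layout: str = "header",
    seed_len: int = 16,
) -> ProcessingResult:
    """Full streaming pipeline: FASTQ → per-sample site-count tables.

    Mapping outcomes are memoized per genomic sequence (junction reads are
    massively repeated), so throughput is dominated by FASTQ parsing.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    ta = enumerate_ta_sites(genome) if ta is None else ta
    index = build_index(genome, seed_len) if index is None else index

    tables = {s: SiteCountTable(s) for s in barcode_table}
    result = ProcessingResult(tables)
    cache: dict[str, tuple[str, SiteKey | None, str | None, tuple]] = {}

    for path in fastq_paths:
        records = iter_fastq(path)
        for category, sample, genomic, _rid in demultiplex_and_trim(
            records, barcode_table, transposon_tag, min_len, max_len, layout
        ):
            result.n_records += 1
            if category == "undemultiplexed":
                result.undemultiplexed += 1
                continue
            table = tables[sample]
            if category != "ok":
                setattr(table, category, getattr(table, category) + 1)
                continue
            hit = cache.get(genomic)
            if hit is None:
                outcome = map_read(genomic, index)
                if outcome.status == "unique":
                    site, orientation = assign_to_site(outcome, len(genomic), ta)
                    hit = ("unique", site, orientation, ())
                elif outcome.status == "ambiguous":
                    amb = tuple(
                        s
                        for s in (
                            locus_to_site(loc, len(genomic), ta) for loc in outcome.loci
                        )
                        if s is not None
                    )
                    hit = ("ambiguous", None, None, amb)
                else:
                    hit = ("unmapped", None, None, ())
                cache[genomic] = hit
            status, site, orientation, amb_sites = hit
            if status == "unique":
                if site is None:
                    table.off_ta += 1
                else:
                    table.add(site, orientation)
            elif status == "ambiguous":
                table.ambiguous += 1
                table.ambiguous_sites.update(amb_sites)
            else:
                table.unmapped += 1
    return result
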
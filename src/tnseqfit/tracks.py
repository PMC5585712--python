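"""Plain-text exports: TSV count tables, BED / wiggle browser tracks,
FASTA/GFF3 for simulated genomes, and readers to re-enter the pipeline at
the analysis stage."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import FeatureAnnotation, Genome, SiteKey, TAIndex
from .readproc import SiteCountTable


def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [SeqRecord(Seq(rep.residues), id=rep.id, description="") for rep in genome]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(features: Sequence[FeatureAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.feature_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.replicon}\ttnseqfit\tgene\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def write_ta_index_tsv(genome: Genome, ta: TAIndex, path: str | Path) -> None:
    """Debug dump of the TA index: replicon, position0, context trinucleotide
    (the TA plus its following base)."""
    with open(path, "w") as fh:
        fh.write("replicon\tposition0\tcontext\n")
        for rep in genome:
            res = rep.residues
            for p in ta.in_replicon(rep.id):
                p = int(p)
                fh.write(f"{rep.id}\t{p}\t{res[p:p + 3]}\n")


def write_site_counts_tsv(table: SiteCountTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("replicon\tposition0\treads_plus\treads_minus\n")
        for (rep, pos), (p, m) in sorted(table.counts.items()):
            fh.write(f"{rep}\t{pos}\t{p}\t{m}\n")


def read_site_counts_tsv(path: str | Path, sample_id: str) -> SiteCountTable:
    table = SiteCountTable(sample_id)
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        table.counts[(str(row.replicon), int(row.position0))] = [
            int(row.reads_plus), int(row.reads_minus)
        ]
    table.unique_mapped = int(df["reads_plus"].sum() + df["reads_minus"].sum())
    return table


def write_mapping_stats_tsv(
    tables: Mapping[str, SiteCountTable], path: str | Path, undemultiplexed: int = 0
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "sample_id\tunique_mapped\tambiguous\tunmapped\ttoo_short\t"
            "no_tag\toff_ta\tundemultiplexed_shared\n"
        )
        for sid, t in tables.items():
            fh.write(
                f"{sid}\t{t.unique_mapped}\t{t.ambiguous}\t{t.unmapped}\t"
                f"{t.too_short}\t{t.no_tag}\t{t.off_ta}\t{undemultiplexed}\n"
            )


def read_mapping_stats_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("sample_id")


def write_bed(table: SiteCountTable, path: str | Path) -> None:
    """0-based half-open BED of insertion sites; score = total reads."""
    with open(path, "w") as fh:
        for (rep, pos), (p, m) in sorted(table.counts.items()):
            fh.write(f"{rep}\t{pos}\t{pos + 2}\tta_{pos}\t{p + m}\t+\n")


def write_wiggle(
    table: SiteCountTable, genome: Genome, path: str | Path
) -> None:
    """Fixed-step (step 1) wiggle of total reads per position, spanning each
    replicon so browsers render gaps as zeros."""
    per_pos: dict[str, dict[int, int]] = {}
    for (rep, pos), (p, m) in table.counts.items():
        per_pos.setdefault(rep, {})[pos] = p + m
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{table.sample_id}"\n')
        for rep in genome:
            fh.write(f"fixedStep chrom={rep.id} start=1 step=1\n")
            counts = per_pos.get(rep.id, {})
            fh.write("\n".join(str(counts.get(i, 0)) for i in range(rep.length)))
            fh.write("\n")


def write_feature_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def write_truth_counts_tsv(
    truth: Mapping[SiteKey, Sequence[int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("replicon\tposition0\treads_plus\treads_minus\n")
        for (rep, pos), (p, m) in sorted(truth.items()):
            fh.write(f"{rep}\t{pos}\t{p}\t{m}\n")


def read_truth_counts_tsv(path: str | Path) -> dict[SiteKey, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.replicon), int(r.position0)): (int(r.reads_plus), int(r.reads_minus))
        for r in df.itertuples(index=False)
    }
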
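"""Synthetic mariner Tn-Seq experiment generator.

Emulates the two-arm competition design used for conditional-fitness
Tn-Seq: a pooled mariner (Himar1) insertion library is plated on a
permissive acceptor (fumarate) — which removes clones disrupting
fumarate-lethal genes at the colony-selection step — then split into a test
arm grown on a poised electrode and a parallel fumarate control arm, each
for a stated number of parent-clock generations, followed by an identical
fumarate outgrowth of both arms.  Sequencing draws MmeI-style 20-bp
junction reads multinomially from clone abundances.

Every stage is seeded and deterministic: the same config always yields
byte-identical FASTQ output, and a truth table of exact per-site emitted
counts accompanies every sample so the downstream mapper can be checked
read-for-read.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .genome import (
    FeatureAnnotation,
    Genome,
    GenomeSequence,
    SiteKey,
    TAIndex,
    enumerate_ta_sites,
    site_host_lookup,
    _member_offsets,
)

CONDITIONS = ("parent", "fumarate", "electrode")

_DEFAULT_BARCODES = {
    # TruSeq-style 6-mers, one per sample/arm
    "parent": "ATCACG",
    "fumarate": "CGATGT",
    "electrode": "TTAGGC",
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment.

    Defaults are the study conditions this generator emulates: a mariner
    library in a GC-rich (0.60) half-megabase genome with 400 features, 5,000
    unique insertions, 2M reads per sample, 6 parent generations at a 10-h
    parent doubling time, 10% of features lethal on fumarate and 5% growing
    at a 15-h doubling time on the electrode (a log2 ratio of −2 after 6
    generations).
    """

    seed: int = 0
    genome_length: int = 500_000
    gc_content: float = 0.60
    n_features: int = 400
    target_unique_insertions: int = 5_000
    sequencing_depth: int = 2_000_000
    read_length: int = 20
    parent_doubling_time: float = 10.0
    parent_generations: float = 6.0
    outgrowth_generations: float = 6.0
    fraction_lethal_fumarate: float = 0.10
    fraction_electrode_defective: float = 0.05
    electrode_defective_doubling_time: float = 15.0
    barcode_table: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_BARCODES))
    transposon_tag: str = "ACAGGTTG"
    substitution_error_rate: float = 0.0
    read_layout: str = "header"          # "header" or "inline"
    read_length_jitter: bool = False     # 19-21 nt uniform when on
    feature_coverage: float = 0.85
    exclusion_fraction: float = 0.05
    transposon: str = "himar1"

    def __post_init__(self):
        for name in (
            "gc_content",
            "fraction_lethal_fumarate",
            "fraction_electrode_defective",
            "substitution_error_rate",
            "feature_coverage",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.transposon != "himar1":
            raise ValueError(
                f"unsupported transposon {self.transposon!r}: only the TA-targeting "
                "mariner/Himar1 site model is implemented"
            )
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be at least 10 kb")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be strictly between 0 and 1")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.n_features < 1:
            raise ValueError("n_features must be at least 1")
        if not 16 <= self.read_length <= 50:
            raise ValueError("read_length must be in [16, 50]")
        if self.parent_doubling_time <= 0:
            raise ValueError("parent_doubling_time must be positive")
        if self.electrode_defective_doubling_time <= 0:
            raise ValueError("electrode_defective_doubling_time must be positive")
        if self.read_layout not in ("header", "inline"):
            raise ValueError("read_layout must be 'header' or 'inline'")
        if not self.transposon_tag or set(self.transposon_tag) - set("ACGT"):
            raise ValueError("transposon_tag must be a non-empty ACGT string")
        lens = {len(b) for b in self.barcode_table.values()}
        if len(self.barcode_table) == 0 or lens == {0}:
            raise ValueError("barcode_table must contain at least one barcode")
        if len(lens) != 1:
            raise ValueError("barcodes must all have the same length")
        if len(set(self.barcode_table.values())) != len(self.barcode_table):
            raise ValueError("barcode collision: barcodes must be distinct")
        for bc in self.barcode_table.values():
            if set(bc) - set("ACGT"):
                raise ValueError(f"barcode {bc!r} contains non-ACGT characters")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def rng(self, *stream: int) -> np.random.Generator:
        """Named child generator; streams are stable across runs."""
        return np.random.default_rng([self.seed, *stream])


@dataclass
class FitnessTruth:
    """Ground-truth per-feature fitness driving the simulator.

    Only deviations from the parent doubling time are stored; unlisted
    features grow neutrally in every condition.  ``td_electrode`` may be
    ``inf`` (static: no net growth on the electrode).
    """

    parent_doubling_time: float
    lethal_fumarate: frozenset[str]
    td_electrode: dict[str, float] = field(default_factory=dict)
    td_fumarate: dict[str, float] = field(default_factory=dict)

    def doubling_time(self, feature_id: str | None, condition: str) -> float:
        if feature_id is None:
            return self.parent_doubling_time
        if condition in ("fumarate", "parent"):
            return self.td_fumarate.get(feature_id, self.parent_doubling_time)
        if condition == "electrode":
            return self.td_electrode.get(feature_id, self.parent_doubling_time)
        raise ValueError(f"unknown condition {condition!r}")

    def is_lethal(self, feature_id: str | None) -> bool:
        return feature_id is not None and feature_id in self.lethal_fumarate


@dataclass
class InsertionClone:
    replicon: str
    position: int              # TA site key: offset of the forward 'T'
    host_feature: str | None   # None = intergenic
    disrupts: bool             # site beyond the host's 5% window
    abundance: float

    @property
    def site(self) -> SiteKey:
        return (self.replicon, self.position)


@dataclass
class ClonePopulation:
    clones: list[InsertionClone]
    condition: str
    generations: float = 0.0

    def __len__(self) -> int:
        return len(self.clones)

    @property
    def total_abundance(self) -> float:
        return float(sum(c.abundance for c in self.clones))

    def abundances(self) -> np.ndarray:
        return np.array([c.abundance for c in self.clones], dtype=float)


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(bases, size=length, p=p)


def _count_available_ta(seq: np.ndarray, feature: FeatureAnnotation, excl: float) -> int:
    # local TA scan of the feature neighbourhood (avoids re-indexing the genome)
    s, e = feature.start - 1, feature.end
    lo = max(s - 1, 0)
    hi = min(e + 1, len(seq))
    sub = seq[lo:hi]
    if len(sub) < 2:
        return 0
    mask = (sub[:-1] == _T_BYTE) & (sub[1:] == _A_BYTE)
    positions = np.flatnonzero(mask).astype(np.int64) + lo
    member, offsets = _member_offsets(feature, positions)
    window = math.floor(excl * feature.length)
    return int(np.count_nonzero(offsets >= window))


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Genome, list[FeatureAnnotation]]:
    """Random genome at the configured GC with tiled non-overlapping features.

    Features cover ~``feature_coverage`` of the genome, separated by random
    intergenic gaps.  Each feature is guaranteed at least two TA sites beyond
    its 5′ exclusion window (TA dinucleotides are planted locally if the
    random sequence falls short) so that every feature is observable.
    """
    rng = config.rng(0) if rng is None else rng
    L, n = config.genome_length, config.n_features
    mean_len = config.feature_coverage * L / n
    if mean_len < 120:
        raise ValueError(
            f"infeasible layout: {n} features in {L} bp leaves a mean feature "
            f"length of {mean_len:.0f} bp (< 120 bp)"
        )
    lengths = np.maximum(60, (rng.uniform(0.5, 1.5, size=n) * mean_len)).astype(int)
    if lengths.sum() >= L:
        raise ValueError("infeasible layout: features exceed genome length")
    gap_total = L - int(lengths.sum())
    gaps = (rng.dirichlet(np.ones(n + 1)) * gap_total).astype(int)
    gaps[-1] = gap_total - int(gaps[:-1].sum())

    seq = _random_sequence(L, config.gc_content, rng)
    features: list[FeatureAnnotation] = []
    cursor = 0
    for i in range(n):
        cursor += int(gaps[i])
        start0 = cursor
        end0 = cursor + int(lengths[i])
        strand = "+" if rng.random() < 0.5 else "-"
        feat = FeatureAnnotation(
            feature_id=f"gene{i + 1:04d}",
            replicon="chr1",
            start=start0 + 1,
            end=end0,
            strand=strand,
            product="hypothetical protein",
        )
        features.append(feat)
        cursor = end0

    excl = config.exclusion_fraction
    for feat in features:
        for _ in range(50):
            have = _count_available_ta(seq, feat, excl)
            if have >= 2:
                break
            # plant a TA at a random position beyond the 5' window
            s, e = feat.start - 1, feat.end
            window = math.floor(excl * feat.length)
            if feat.strand == "+":
                lo, hi = s + window, min(e - 1, L - 2)
            else:
                lo, hi = max(s - 1, 0), e - 2 - window
            if hi <= lo:
                raise ValueError(
                    f"feature {feat.feature_id} too small to host TA sites"
                )
            p = int(rng.integers(lo, hi + 1))
            seq[p] = _T_BYTE
            seq[p + 1] = _A_BYTE
        else:
            raise RuntimeError(f"could not seed TA sites into {feat.feature_id}")

    genome = Genome([GenomeSequence("chr1", seq.tobytes().decode("ascii"))])
    return genome, features


_T_BYTE = ord("T")
_A_BYTE = ord("A")


def simulate_truth(
    annotations: Sequence[FeatureAnnotation],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> FitnessTruth:
    """Assign lethal-on-fumarate flags and electrode doubling times.

    ``floor(fraction * n)`` features are drawn for each class, disjointly, so
    expected class sizes are exact and reproducible.
    """
    rng = config.rng(1) if rng is None else rng
    ids = [f.feature_id for f in annotations]
    n_lethal = int(config.fraction_lethal_fumarate * len(ids))
    n_defect = int(config.fraction_electrode_defective * len(ids))
    if n_lethal + n_defect > len(ids):
        raise ValueError("lethal and defective fractions exceed the feature count")
    chosen = rng.choice(len(ids), size=n_lethal + n_defect, replace=False)
    lethal = frozenset(ids[i] for i in chosen[:n_lethal])
    defective = [ids[i] for i in chosen[n_lethal:]]
    return FitnessTruth(
        parent_doubling_time=config.parent_doubling_time,
        lethal_fumarate=lethal,
        td_electrode={
            fid: config.electrode_defective_doubling_time for fid in defective
        },
    )


def _max_read_length(config: SimulationConfig) -> int:
    return config.read_length + (1 if config.read_length_jitter else 0)


def eligible_sites(genome: Genome, ta: TAIndex, config: SimulationConfig) -> list[SiteKey]:
    """TA sites far enough from replicon ends to supply full-length junction
    reads on both sides."""
    rl = _max_read_length(config)
    out: list[SiteKey] = []
    for rep in genome:
        pos = ta.in_replicon(rep.id)
        ok = (pos >= rl - 2) & (pos + rl <= rep.length)
        out.extend((rep.id, int(p)) for p in pos[ok])
    return out


def construct_library(
    genome: Genome,
    annotations: Sequence[FeatureAnnotation],
    truth: FitnessTruth,
    config: SimulationConfig,
    ta: TAIndex | None = None,
    rng: np.random.Generator | None = None,
) -> ClonePopulation:
    """Sample K insertion sites uniformly without replacement, then apply the
    colony-selection bottleneck: clones disrupting a fumarate-lethal feature
    never form colonies and are removed.  Survivors start at equal abundance.
    """
    rng = config.rng(2) if rng is None else rng
    ta = enumerate_ta_sites(genome) if ta is None else ta
    candidates = eligible_sites(genome, ta, config)
    K = config.target_unique_insertions
    if K > len(candidates):
        raise ValueError(
            f"target_unique_insertions={K} exceeds the {len(candidates)} usable TA sites"
        )
    picked = rng.choice(len(candidates), size=K, replace=False)
    hosts = site_host_lookup(annotations, ta, config.exclusion_fraction)
    clones = []
    for i in sorted(picked):
        site = candidates[i]
        host, disrupts = hosts.get(site, (None, False))
        if disrupts and truth.is_lethal(host):
            continue  # plating selection: no colony
        clones.append(InsertionClone(site[0], site[1], host, disrupts, 1.0))
    return ClonePopulation(clones, condition="parent", generations=0.0)


def propagate(
    pop: ClonePopulation,
    condition: str,
    generations: float,
    truth: FitnessTruth,
    config: SimulationConfig,
) -> ClonePopulation:
    """Exponential outgrowth for ``generations`` parent-clock generations.

    Elapsed wall-clock time is T = generations × td_p; each clone grows by
    2^(T / td_i) where td_i is its host feature's doubling time under
    ``condition`` (td_p for intergenic, non-disrupting, or unaffected
    clones; a factor of 1 in the td → ∞ limit).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if generations < 0:
        raise ValueError("generations must be non-negative")
    T = generations * config.parent_doubling_time
    out = []
    for c in pop.clones:
        td = truth.doubling_time(c.host_feature if c.disrupts else None, condition)
        factor = 2.0 ** (T / td) if math.isfinite(td) else 1.0
        out.append(
            InsertionClone(c.replicon, c.position, c.host_feature, c.disrupts,
                           c.abundance * factor)
        )
    return ClonePopulation(out, condition=condition,
                           generations=pop.generations + generations)


@dataclass
class ExperimentResult:
    config: SimulationConfig
    genome: Genome
    annotations: list[FeatureAnnotation]
    ta: TAIndex
    truth: FitnessTruth
    populations: dict[str, ClonePopulation]  # parent / fumarate / electrode


def run_experiment(config: SimulationConfig) -> ExperimentResult:
    """The full two-arm design.

    parent → [electrode, G_p generations → fumarate outgrowth]   (test arm)
    parent → [fumarate, G_p generations → fumarate outgrowth]    (control arm)

    Both arms receive the same fumarate outgrowth, so it cancels in the
    electrode/control read ratio.
    """
    genome, annotations = simulate_genome(config)
    ta = enumerate_ta_sites(genome)
    truth = simulate_truth(annotations, config)
    parent = construct_library(genome, annotations, truth, config, ta=ta)

    gp, og = config.parent_generations, config.outgrowth_generations
    electrode = propagate(parent, "electrode", gp, truth, config)
    electrode = propagate(electrode, "fumarate", og, truth, config)
    electrode.condition = "electrode"  # arm label survives the outgrowth
    control = propagate(parent, "fumarate", gp, truth, config)
    control = propagate(control, "fumarate", og, truth, config)

    return ExperimentResult(
        config=config,
        genome=genome,
        annotations=annotations,
        ta=ta,
        truth=truth,
        populations={"parent": parent, "fumarate": control, "electrode": electrode},
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    if len(hit) == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def sequence_reads(
    pop: ClonePopulation,
    genome: Genome,
    config: SimulationConfig,
    sample_id: str,
    out_path: str | Path,
    rng: np.random.Generator | None = None,
) -> dict[SiteKey, list[int]]:
    """Draw D junction reads multinomially from clone abundances and write
    FASTQ (constant Phred-33 quality 'I').

    Junction geometry: a + read is the ``read_length`` bases starting at the
    TA site's 'T' going rightward on the forward strand; a − read is the
    ``read_length`` bases ending at the 'A' going leftward, reverse-
    complemented.  Orientation is a fair coin per read.  Layout "header"
    emits tag+junction with the barcode in the read description
    (``bc:<seq>``); layout "inline" emits barcode+tag+junction.

    Returns the truth table of exact per-site emitted counts
    ``{site: [plus, minus]}`` (errors are applied after counting, so the
    truth reflects what was drawn, not what remains mappable).
    """
    if len(pop) == 0:
        raise ValueError("cannot sequence an empty population")
    if sample_id not in config.barcode_table:
        raise ValueError(f"sample {sample_id!r} has no barcode in the table")
    rng = config.rng(3, sorted(config.barcode_table).index(sample_id)) if rng is None else rng

    barcode = config.barcode_table[sample_id]
    tag = config.transposon_tag
    D = config.sequencing_depth
    ab = pop.abundances()
    if ab.sum() <= 0:
        raise ValueError("population has zero total abundance")
    counts = rng.multinomial(D, ab / ab.sum())
    plus = rng.binomial(counts, 0.5)
    minus = counts - plus

    err = config.substitution_error_rate
    truth: dict[SiteKey, list[int]] = {}
    serial = 0
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        buf: list[str] = []
        for c, n_plus, n_minus in zip(pop.clones, plus, minus):
            if n_plus == 0 and n_minus == 0:
                continue
            truth[c.site] = [int(n_plus), int(n_minus)]
            res = genome[c.replicon].residues
            p = c.position
            for orient, n in (("+", int(n_plus)), ("-", int(n_minus))):
                for _ in range(n):
                    rl = (
                        int(rng.integers(config.read_length - 1, config.read_length + 2))
                        if config.read_length_jitter
                        else config.read_length
                    )
                    if orient == "+":
                        genomic = res[p : p + rl]
                    else:
                        genomic = reverse_complement(res[p + 2 - rl : p + 2])
                    if config.read_layout == "inline":
                        seq = barcode + tag + genomic
                        header = f"@{sample_id}:{serial}"
                    else:
                        seq = tag + genomic
                        header = f"@{sample_id}:{serial} bc:{barcode}"
                    if err > 0:
                        seq = _mutate(seq, err, rng)
                    buf.append(f"{header}\n{seq}\n+\n{'I' * len(seq)}\n")
                    serial += 1
                    if len(buf) >= 100_000:
                        fh.write("".join(buf))
                        buf.clear()
        fh.write("".join(buf))
    return truth


def simulate_to_dir(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run the whole experiment and write a complete dataset.

    Writes genome.fasta, annotation.gff3, one FASTQ + truth count TSV per
    sample, the per-feature truth fitness TSV, a sample sheet, and the TA
    index dump.  Returns a manifest-friendly dict of paths, per-sample read
    counts, and the in-memory ExperimentResult under ``"result"``.
    """
    from . import tracks  # deferred: avoid a cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = run_experiment(config)

    paths = {
        "genome": outdir / "genome.fasta",
        "annotation": outdir / "annotation.gff3",
        "ta_sites": outdir / "ta_sites.tsv",
        "truth_fitness": outdir / "truth_fitness.tsv",
        "sample_sheet": outdir / "sample_sheet.tsv",
    }
    tracks.write_fasta(result.genome, paths["genome"])
    tracks.write_gff3(result.annotations, paths["annotation"])
    tracks.write_ta_index_tsv(result.genome, result.ta, paths["ta_sites"])

    with open(paths["truth_fitness"], "w") as fh:
        fh.write("feature_id\tlethal_fumarate\ttd_fumarate_h\ttd_electrode_h\n")
        for f in result.annotations:
            fid = f.feature_id
            fh.write(
                f"{fid}\t{int(result.truth.is_lethal(fid))}\t"
                f"{result.truth.doubling_time(fid, 'fumarate')}\t"
                f"{result.truth.doubling_time(fid, 'electrode')}\n"
            )

    with open(paths["sample_sheet"], "w") as fh:
        fh.write("sample_id\tbarcode\tcondition\treplicate\n")
        for sample, bc in config.barcode_table.items():
            condition = sample if sample in CONDITIONS else "fumarate"
            fh.write(f"{sample}\t{bc}\t{condition}\t1\n")

    truths: dict[str, dict[SiteKey, list[int]]] = {}
    read_counts: dict[str, int] = {}
    for sample in config.barcode_table:
        pop = result.populations.get(sample)
        if pop is None:
            raise ValueError(
                f"sample {sample!r} in barcode_table has no simulated population"
            )
        fq = outdir / f"reads_{sample}.fastq"
        truth = sequence_reads(pop, result.genome, config, sample, fq)
        tracks.write_truth_counts_tsv(truth, outdir / f"truth_counts_{sample}.tsv")
        paths[f"reads_{sample}"] = fq
        paths[f"truth_counts_{sample}"] = outdir / f"truth_counts_{sample}.tsv"
        truths[sample] = truth
        read_counts[sample] = config.sequencing_depth

    return {
        "paths": {k: str(v) for k, v in paths.items()},
        "read_counts": read_counts,
        "truth_counts": truths,
        "result": result,
    }


def expected_unmappable_fraction(config: SimulationConfig) -> float:
    """Fraction of reads expected to fail zero-mismatch mapping because a
    substitution error hit the genomic junction portion."""
    return 1.0 - (1.0 - config.substitution_error_rate) ** config.read_length
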
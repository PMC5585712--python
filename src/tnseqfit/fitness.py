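"""Conditional-fitness statistics for Tn-Seq count tables.

The analysis chain is: depth normalization between barcoded libraries
(ambiguous mappings count toward the denominator but never toward a site),
per-feature aggregation under the first-5% rule, dual-criterion
essentiality classification (< 300 reads per feature *and* < 4 insertion
sites per kb at a 40M-read reference depth), per-feature log2 fitness
ratios against the parent/control library, and the exponential-growth
conversion from a log2 ratio to an apparent doubling time.

Model
-----
Over an experiment of G_p parent generations at parent doubling time td_p
(elapsed time T = G_p × td_p), a mutant with doubling time x accumulates
reads in proportion 2^(T/x), so its log2 ratio against the neutral
population is L = T/x − G_p and conversely

    x = T / (G_p + L),        defined for G_p + L > 0.

L = −2 after 6 generations at td_p = 10 h gives x = 60/4 = 15 h, i.e. a 50%
increase in apparent doubling time; populations with G_p + L ≤ 0 show a net
decline over the experiment and are flagged rather than assigned a time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genome import FeatureAnnotation, SiteKey, TAIndex, feature_site_map
from .readproc import SiteCountTable

#: reference sequencing depth at which the 300-read threshold is defined
REFERENCE_TOTAL = 40_000_000.0


@dataclass
class NormalizedCounts:
    """Per-site reads rescaled to a common reference depth."""

    sample_id: str
    counts: dict[SiteKey, float]
    factor: float
    reference_total: float
    raw: SiteCountTable


def normalize(
    table: SiteCountTable, reference_total: float = REFERENCE_TOTAL
) -> NormalizedCounts:
    """Scale every site count by reference_total / (unique + ambiguous).

    Ambiguous mappings are excluded from the essentiality analysis but are
    included in the total used for normalization between barcoded libraries.
    """
    denom = table.normalization_denominator
    if denom <= 0:
        raise ValueError(
            f"sample {table.sample_id!r}: normalization denominator is zero"
        )
    factor = reference_total / denom
    counts = {site: (p + m) * factor for site, (p, m) in table.counts.items()}
    return NormalizedCounts(table.sample_id, counts, factor, reference_total, table)


def aggregate(
    norm: NormalizedCounts,
    annotations: Sequence[FeatureAnnotation],
    ta: TAIndex,
    exclusion_fraction: float = 0.05,
    few_sites_threshold: int = 3,
) -> pd.DataFrame:
    """Per-feature statistics over *available* sites only (first-5% rule).

    Returns a DataFrame indexed by feature_id with raw and normalized read
    sums, unique sites hit, insertion density per kb of full feature length,
    and low-confidence guards: ``few_available_sites`` (fewer than
    ``few_sites_threshold`` available TA sites) and
    ``contains_ambiguous_sites`` (an available site was implicated in
    ambiguous-read exclusion, which can depress the density of a duplicated
    gene and wrongly code it essential).
    """
    site_map = feature_site_map(annotations, ta, exclusion_fraction)
    raw_counts = norm.raw.counts
    amb = norm.raw.ambiguous_sites
    rows = []
    for feat in annotations:
        aset = site_map[feat.feature_id]
        raw = 0
        normed = 0.0
        hit = 0
        has_amb = False
        for p in aset.sites:
            site = (feat.replicon, int(p))
            pair = raw_counts.get(site)
            if pair is not None:
                r = pair[0] + pair[1]
                if r > 0:
                    raw += r
                    normed += norm.counts[site]
                    hit += 1
            if site in amb:
                has_amb = True
        rows.append(
            {
                "feature_id": feat.feature_id,
                "length_bp": feat.length,
                "n_available_sites": aset.n_available,
                "raw_reads": raw,
                "normalized_reads": normed,
                "unique_sites_hit": hit,
                "sites_per_kb": hit / (feat.length / 1000.0),
                "contains_ambiguous_sites": has_amb,
                "few_available_sites": aset.n_available < few_sites_threshold,
            }
        )
    df = pd.DataFrame(rows).set_index("feature_id")
    df.attrs["sample_id"] = norm.sample_id
    df.attrs["reference_total"] = norm.reference_total
    return df


def classify_essential(
    stats: pd.DataFrame,
    reads_threshold: float = 300.0,
    density_threshold: float = 4.0,
    mode: str = "both",
) -> pd.DataFrame:
    """Dual-criterion essentiality call.

    A feature meets the reads criterion when its normalized reads fall below
    ``reads_threshold`` (defined at the 40M-read reference depth and scaled
    linearly if the stats were normalized to a different reference), and the
    density criterion when it has fewer than ``density_threshold`` insertion
    sites per kb.  Mode "both" (default) requires both criteria for an
    essential call — correcting both for small genes with few TA sites and
    for large genes that tolerate insertions between domains; mode "either"
    calls essential on either criterion.  Features with too few available
    sites or ambiguity flags are demoted to "low-confidence".
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    ref = stats.attrs.get("reference_total", REFERENCE_TOTAL)
    eff_reads_threshold = reads_threshold * (ref / REFERENCE_TOTAL)

    out = stats.copy()
    out["reads_criterion_met"] = out["normalized_reads"] < eff_reads_threshold
    out["density_criterion_met"] = out["sites_per_kb"] < density_threshold
    if mode == "both":
        essential = out["reads_criterion_met"] & out["density_criterion_met"]
    else:
        essential = out["reads_criterion_met"] | out["density_criterion_met"]
    # guard flags demote any call that rests on a suspect criterion: a gene
    # with almost no available sites, or one whose sites were eaten by
    # ambiguous-read exclusion, can look essential for the wrong reason
    low_conf = (out["few_available_sites"] | out["contains_ambiguous_sites"]) & (
        out["reads_criterion_met"] | out["density_criterion_met"]
    )
    call = np.where(essential, "essential", "nonessential")
    call = np.where(low_conf, "low-confidence", call)
    out["call"] = call
    out.attrs.update(stats.attrs)
    return out


def log2_ratio(
    condition_reads: float | np.ndarray,
    parent_reads: float | np.ndarray,
    pseudocount: float = 1.0,
) -> float | np.ndarray:
    """log2((condition + pseudocount) / (parent + pseudocount)).

    The pseudocount (default 1 normalized read) keeps features with zero
    reads under the test condition finite with minimal shrinkage.
    """
    return np.log2(
        (np.asarray(condition_reads, dtype=float) + pseudocount)
        / (np.asarray(parent_reads, dtype=float) + pseudocount)
    )[()]


@dataclass(frozen=True)
class DoublingTime:
    td_m: float               # hours; NaN when declining
    percent_td_change: float  # 100 × (td_m − td_p)/td_p; NaN when declining
    declining: bool


def apparent_doubling_time(
    L: float, td_p: float = 10.0, G_p: float = 6.0
) -> DoublingTime:
    """Convert a log2 ratio to the apparent doubling time x = T/(G_p + L)
    with T = G_p × td_p.

    When G_p + L ≤ 0 the mutant shows a net loss over the experiment and no
    finite doubling time reproduces its ratio; such features are flagged
    ``declining`` (the paper still reports their L, e.g. fumarate hydratase
    at −8 over 6 generations).
    """
    if td_p <= 0 or G_p <= 0:
        raise ValueError("td_p and G_p must be positive")
    T = G_p * td_p
    denom = G_p + L
    if denom <= 0:
        return DoublingTime(math.nan, math.nan, True)
    td_m = T / denom
    return DoublingTime(td_m, 100.0 * (td_m - td_p) / td_p, False)


def classify_defect(
    L: float, defect_cutoff: float = -2.0, enrich_cutoff: float = 1.0
) -> str:
    """Growth classification from a finite log2 ratio: defective at or below
    the −2 cutoff (≥50% increase in apparent doubling time), enriched at or
    above +1, otherwise below-threshold."""
    if not math.isfinite(L):
        raise ValueError("L must be finite")
    if L <= defect_cutoff:
        return "defective"
    if L >= enrich_cutoff:
        return "enriched"
    return "below-threshold"


def fitness_table(
    condition_stats: pd.DataFrame,
    parent_stats: pd.DataFrame,
    pseudocount: float = 1.0,
    td_p: float = 10.0,
    G_p: float = 6.0,
    defect_cutoff: float = -2.0,
    enrich_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Per-feature fitness: L, apparent doubling time, growth class.

    Both inputs are ``aggregate`` outputs over the same annotation.
    Features with zero normalized reads in both samples are classed
    "no-data"; features whose ratio implies a net decline keep their
    L-based growth class but carry the ``declining`` flag and no finite
    doubling time.
    """
    if not condition_stats.index.equals(parent_stats.index):
        raise ValueError("condition and parent stats cover different features")
    cond = condition_stats["normalized_reads"].to_numpy()
    par = parent_stats["normalized_reads"].to_numpy()
    L = log2_ratio(cond, par, pseudocount)
    rows = []
    for li, c, p in zip(np.atleast_1d(L), cond, par):
        if c == 0 and p == 0:
            rows.append((math.nan, math.nan, math.nan, False, "no-data"))
            continue
        dt = apparent_doubling_time(li, td_p, G_p)
        rows.append(
            (li, dt.td_m, dt.percent_td_change, dt.declining,
             classify_defect(li, defect_cutoff, enrich_cutoff))
        )
    out = pd.DataFrame(
        rows,
        index=condition_stats.index,
        columns=["log2_ratio", "apparent_doubling_time_h", "percent_td_change",
                 "declining", "growth_class"],
    )
    out.attrs["condition"] = condition_stats.attrs.get("sample_id")
    out.attrs["parent"] = parent_stats.attrs.get("sample_id")
    return out


def consistent_defects(
    fitness_tables: Sequence[pd.DataFrame], defect_cutoff: float = -2.0
) -> pd.Series:
    """Replicate-consistency filter: a defect is called only if L ≤ cutoff
    in every replicate (mirrors the use of two reactor replicates)."""
    if not fitness_tables:
        raise ValueError("need at least one fitness table")
    flags = [t["log2_ratio"] <= defect_cutoff for t in fitness_tables]
    out = flags[0]
    for f in flags[1:]:
        out = out & f
    return out


def summarize_library(
    unique_insertions: int,
    viable_ta_sites: float,
    total_reads: float,
    genome_length_bp: float | None = None,
    insertions_in_features: int | None = None,
    exclusion_fraction: float = 0.05,
) -> dict:
    """Library summary arithmetic on explicit inputs.

    TA recovery is the percentage of available sites recovered, where the
    available pool discounts the first-5% windows:
    100 × unique / (viable × (1 − exclusion_fraction)), rounded to the
    nearest integer.  Mean reads per insertion is also reported rounded to
    the nearest hundred for display.
    """
    out: dict = {"unique_insertions": int(unique_insertions)}
    if unique_insertions > 0:
        rpi = total_reads / unique_insertions
        out["mean_reads_per_insertion"] = rpi
        out["mean_reads_per_insertion_display"] = int(round(rpi / 100.0) * 100)
    else:
        out["mean_reads_per_insertion"] = 0.0
        out["mean_reads_per_insertion_display"] = 0
    if viable_ta_sites > 0:
        available = viable_ta_sites * (1.0 - exclusion_fraction)
        out["ta_recovery_percent"] = int(round(100.0 * unique_insertions / available))
    else:
        out["ta_recovery_percent"] = 0
    if genome_length_bp:
        out["insertions_per_kb"] = unique_insertions / (genome_length_bp / 1000.0)
    if insertions_in_features is not None and unique_insertions > 0:
        out["fraction_in_features"] = insertions_in_features / unique_insertions
    return out


def viable_ta_sites(
    ta: TAIndex,
    annotations: Sequence[FeatureAnnotation],
    lethal_features: Sequence[str] = (),
    convention: str = "whole",
    exclusion_fraction: float = 0.05,
) -> int:
    """TA sites able to yield viable mutants, netting out lethal genes.

    Convention "whole" subtracts every TA site assigned to a lethal feature;
    "beyond5" subtracts only sites beyond the 5′ exclusion window (an
    insertion inside the window does not kill the clone).  Both conventions
    are exposed because the per-gene accounting is a modeling choice.
    """
    if convention not in ("whole", "beyond5"):
        raise ValueError("convention must be 'whole' or 'beyond5'")
    lethal = set(lethal_features)
    site_map = feature_site_map(
        [f for f in annotations if f.feature_id in lethal], ta, exclusion_fraction
    )
    removed: set[SiteKey] = set()
    by_feature = {f.feature_id: f for f in annotations}
    for fid, aset in site_map.items():
        rep = by_feature[fid].replicon
        removed.update((rep, int(p)) for p in aset.sites)
        if convention == "whole":
            removed.update((rep, int(p)) for p in aset.excluded)
    return ta.count() - len(removed)


def library_summary(
    table: SiteCountTable,
    ta: TAIndex,
    annotations: Sequence[FeatureAnnotation],
    genome_length_bp: float,
    lethal_features: Sequence[str] = (),
    exclusion_fraction: float = 0.05,
) -> dict:
    """Summary of a sequenced library: unique insertions observed, genic
    fraction, density, reads per insertion and TA recovery under both
    viable-site conventions."""
    observed = [s for s, (p, m) in table.counts.items() if p + m > 0]
    genic = 0
    member_sites: set[SiteKey] = set()
    for f in annotations:
        aset = feature_site_map([f], ta, 0.0)[f.feature_id]
        member_sites.update((f.replicon, int(p)) for p in aset.sites)
    genic = sum(1 for s in observed if s in member_sites)

    summary = summarize_library(
        unique_insertions=len(observed),
        viable_ta_sites=viable_ta_sites(
            ta, annotations, lethal_features, "whole", exclusion_fraction
        ),
        total_reads=table.unique_mapped,
        genome_length_bp=genome_length_bp,
        insertions_in_features=genic,
        exclusion_fraction=exclusion_fraction,
    )
    summary["viable_ta_sites_whole"] = viable_ta_sites(
        ta, annotations, lethal_features, "whole", exclusion_fraction
    )
    summary["viable_ta_sites_beyond5"] = viable_ta_sites(
        ta, annotations, lethal_features, "beyond5", exclusion_fraction
    )
    avail5 = summary["viable_ta_sites_beyond5"] * (1.0 - exclusion_fraction)
    summary["ta_recovery_percent_beyond5"] = (
        int(round(100.0 * len(observed) / avail5)) if avail5 > 0 else 0
    )
    summary["total_ta_sites"] = ta.count()
    return summary


def replicate_correlation(
    stats_a: pd.DataFrame, stats_b: pd.DataFrame
) -> float:
    """Pearson r of per-feature normalized reads between two replicates.

    Features with zero reads in both replicates are included; fewer than
    three shared features is an error.
    """
    if not stats_a.index.equals(stats_b.index):
        raise ValueError("replicates cover different feature sets")
    if len(stats_a) < 3:
        raise ValueError("need at least 3 features for a correlation")
    r, _p = sps.pearsonr(
        stats_a["normalized_reads"].to_numpy(),
        stats_b["normalized_reads"].to_numpy(),
    )
    return float(r)
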
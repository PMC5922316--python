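"""Regional mutation load and intermutation distances.

Observed mutation counts in genomic regions are compared against the
expectation under a uniform rate over the *surveyed* bases of each sample
(positions with enough coverage to call a mutation, e.g. CallableLoci
output). Ignoring the surveyed set would turn low coverage into spurious
"depletion", so a surveyed interval set per sample is mandatory:

    expected = n_total * |region & surveyed| / |surveyed|

where n_total counts only mutations inside the surveyed set. Enrichment
or depletion is tested one-sided against Binomial(n_total, pi) with
pi = |region & surveyed| / |surveyed|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import binom, false_discovery_control

from .channels import classify_substitution
from .core import IntervalSet, MutationCatalogue

SIGNIFICANCE_LEVEL = 0.05


def genomic_distribution(
    catalogues,
    surveyed_per_sample: dict[str, IntervalSet],
    region_sets: dict[str, IntervalSet],
) -> pd.DataFrame:
    """Observed and expected mutation counts per sample and region set.

    ``observed`` counts SNVs inside region & surveyed; double-covered
    bases count once (regions and surveyed sets are merged before
    intersection). SNVs outside the surveyed set do not contribute to
    n_total. A sample without a surveyed set is an error.
    """
    rows = []
    for cat in catalogues:
        if cat.sample_id not in surveyed_per_sample:
            raise ValueError(
                f"no surveyed interval set for sample {cat.sample_id}; regional "
                "rates without a callable-loci correction are not meaningful"
            )
        surveyed = surveyed_per_sample[cat.sample_id].merged()
        surveyed_lookup = surveyed.point_lookup()
        surveyed_total = surveyed.total_length()
        in_surveyed = [snv for snv in cat if surveyed_lookup.covers(snv.chrom, snv.pos)]
        n_total = len(in_surveyed)
        for region_label, region in region_sets.items():
            region_surveyed = region.intersect(surveyed)
            region_lookup = region_surveyed.point_lookup()
            region_bases = region_surveyed.total_length()
            observed = sum(1 for snv in in_surveyed if region_lookup.covers(snv.chrom, snv.pos))
            expected = n_total * region_bases / surveyed_total if surveyed_total else 0.0
            rows.append(
                {
                    "sample": cat.sample_id,
                    "region": region_label,
                    "n_total": n_total,
                    "observed": observed,
                    "surveyed_region_bases": region_bases,
                    "surveyed_total_bases": surveyed_total,
                    "expected": expected,
                    "log2_ratio": (
                        float(np.log2(observed / expected)) if observed > 0 and expected > 0 else float("nan")
                    ),
                }
            )
    return pd.DataFrame(rows)


def enrichment_depletion_test(loads: pd.DataFrame, by: dict[str, str] | None = None) -> pd.DataFrame:
    """One-sided binomial enrichment/depletion test per (group, region).

    Counts and base totals are pooled within each group. With
    n = n_total, pi = surveyed_region / surveyed_total and
    X ~ Binomial(n, pi): observed >= expected tests enrichment with
    p = P[X >= observed], otherwise depletion with p = P[X <= observed]
    (equality is assigned to the enrichment branch, whose tail then
    includes the observation and cannot be significant). n = 0 yields
    direction "none" and p = 1.
    """
    if by is None:
        by = {s: s for s in loads["sample"].unique()}
    missing = set(loads["sample"].unique()) - set(by)
    if missing:
        raise ValueError(f"samples missing from group map: {sorted(missing)}")
    work = loads.copy()
    work["group"] = work["sample"].map(by)
    rows = []
    for (group, region), sub in work.groupby(["group", "region"], sort=False):
        n = int(sub["n_total"].sum())
        observed = int(sub["observed"].sum())
        region_bases = int(sub["surveyed_region_bases"].sum())
        total_bases = int(sub["surveyed_total_bases"].sum())
        pi = region_bases / total_bases if total_bases else 0.0
        expected = n * pi
        if n == 0:
            direction, p = "none", 1.0
        elif observed >= expected:
            direction = "enrichment"
            p = float(binom.sf(observed - 1, n, pi))
        else:
            direction = "depletion"
            p = float(binom.cdf(observed, n, pi))
        rows.append(
            {
                "group": group,
                "region": region,
                "n_total": n,
                "observed": observed,
                "expected": expected,
                "log2_ratio": (
                    float(np.log2(observed / expected)) if observed > 0 and expected > 0 else float("nan")
                ),
                "direction": direction,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjust"] = false_discovery_control(out["p_value"].to_numpy(), method="bh")
    out["significant"] = (out["p_value"] < SIGNIFICANCE_LEVEL) & (out["direction"] != "none")
    return out


def intermutation_distances(catalogue: MutationCatalogue) -> pd.DataFrame:
    """Rainfall series: distance of each SNV to the previous one on its chromosome.

    One row per SNV in (chrom, pos) order, with the distance NaN for the
    first SNV of each chromosome and the 6-category substitution type for
    colouring. Two SNVs at the same position (different alt) give a
    distance of 0.
    """
    rows = []
    prev: dict[str, int] = {}
    for snv in catalogue:
        dist = float(snv.pos - prev[snv.chrom]) if snv.chrom in prev else float("nan")
        prev[snv.chrom] = snv.pos
        rows.append(
            {
                "chrom": snv.chrom,
                "pos": snv.pos,
                "distance": dist,
                "type": classify_substitution(snv.ref, snv.alt),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "distance", "type"])
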
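"""Percent donor chimerism from allele counts.

The estimator converts the read fraction of a discriminating nucleotide
into percent donor chimerism with a zygosity correction: when the
informative allele sits on only one of a heterozygote's two chromosomes,
a pure sample of that animal shows it in 50% of reads, so the observed
fraction must be doubled. The three configurations give, with d and r
the percentages of effective reads carrying the donor-specific and
recipient-specific nucleotide:

* het donor / hom recipient:   percent = 2 * d
* hom donor / het recipient:   percent = 100 - 2 * r
* hom/hom different alleles:   percent = d

Raw values can leave [0, 100] under sampling noise; they are clamped
with a flag. A 95% Wilson score interval on the counted fraction is
pushed through the same affine map, giving per-SNP uncertainty; across
SNPs the aggregate is an unweighted mean with the SEM reported when two
or more SNPs were measured.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .amplicon_reads import AlleleCount
from .snp_panel import InformativeSnp, PairConfiguration

logger = logging.getLogger(__name__)


@dataclass
class ChimerismEstimate:
    """Percent donor chimerism at one SNP for one sample."""

    sample_id: str
    locus_id: str
    configuration: PairConfiguration
    raw_percent: float
    percent: float
    clamped: bool
    ci_low: float
    ci_high: float
    effective_reads: int
    no_coverage: bool = False
    contamination_warning: bool = False


@dataclass
class AggregateChimerism:
    """Cross-SNP mean +/- SEM donor chimerism for one sample.

    ``sem_percent`` is None in single-SNP mode (the assay's later
    standard practice): a standard error needs replication.
    """

    sample_id: str
    mean_percent: float
    sem_percent: Optional[float]
    n_snps: int
    per_snp: list


def _clamp(x: float) -> float:
    return min(100.0, max(0.0, x))


def estimate_chimerism(
    count: AlleleCount,
    snp: InformativeSnp,
    min_coverage: int = 100,
    contamination_warn_fraction: float = 0.02,
    alpha: float = 0.05,
) -> ChimerismEstimate:
    """Estimate percent donor chimerism at one SNP from allele counts.

    Counts below ``min_coverage`` effective reads yield a result flagged
    ``no_coverage`` that aggregation excludes. Reads carrying a
    nucleotide neither animal's genotype explains raise a contamination
    warning (flag + log) above ``contamination_warn_fraction``.
    """
    if count.locus_id != snp.locus.locus_id:
        raise ValueError(f"count is for {count.locus_id}, SNP for {snp.locus.locus_id}")
    eff = count.effective_reads
    cfg = snp.configuration

    if eff < min_coverage:
        logger.warning(
            "sample %s locus %s: %d effective reads < min_coverage %d",
            count.sample_id, count.locus_id, eff, min_coverage,
        )
        return ChimerismEstimate(
            sample_id=count.sample_id, locus_id=count.locus_id, configuration=cfg,
            raw_percent=math.nan, percent=math.nan, clamped=False,
            ci_low=math.nan, ci_high=math.nan, effective_reads=eff, no_coverage=True,
        )

    expected = {snp.donor_specific_nt, snp.recipient_specific_nt} - {None}
    expected |= set(snp.locus.observed_alleles)
    stray = sum(count.counts[nt] for nt in "ACGT" if nt not in expected)
    contamination = stray / eff > contamination_warn_fraction
    if contamination:
        logger.warning(
            "sample %s locus %s: %.1f%% of reads carry a nucleotide neither animal "
            "carries (possible contamination or wrong genotype)",
            count.sample_id, count.locus_id, 100 * stray / eff,
        )

    if cfg is PairConfiguration.HET_DONOR_HOM_RECIPIENT:
        k = count.counts[snp.donor_specific_nt]
        scale, shift = 200.0, 0.0
    elif cfg is PairConfiguration.HOM_DONOR_HET_RECIPIENT:
        k = count.counts[snp.recipient_specific_nt]
        scale, shift = -200.0, 100.0
    elif cfg is PairConfiguration.HOM_HOM_DIFFERENT:
        k = count.counts[snp.donor_specific_nt]
        scale, shift = 100.0, 0.0
    else:
        raise ValueError("cannot estimate chimerism at an UNINFORMATIVE locus")

    p_lo, p_hi = proportion_confint(k, eff, alpha=alpha, method="wilson")
    raw = shift + scale * (k / eff)
    bounds = sorted((shift + scale * p_lo, shift + scale * p_hi))
    return ChimerismEstimate(
        sample_id=count.sample_id,
        locus_id=count.locus_id,
        configuration=cfg,
        raw_percent=raw,
        percent=_clamp(raw),
        clamped=not 0.0 <= raw <= 100.0,
        ci_low=_clamp(bounds[0]),
        ci_high=_clamp(bounds[1]),
        effective_reads=eff,
        contamination_warning=contamination,
    )


def aggregate(estimates: Sequence[ChimerismEstimate], sample_id: str | None = None):
    """Aggregate per-SNP estimates for one sample into mean +/- SEM.

    No-coverage estimates are excluded; with zero usable estimates the
    sample gets no estimate (returns None, logged).
    """
    usable = [e for e in estimates if not e.no_coverage]
    if sample_id is None and estimates:
        sample_id = estimates[0].sample_id
    if any(e.sample_id != sample_id for e in estimates):
        raise ValueError("aggregate() expects estimates from a single sample")
    if not usable:
        logger.warning("sample %s: no usable per-SNP estimates", sample_id)
        return None
    values = np.array([e.percent for e in usable], dtype=float)
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) >= 2 else None
    return AggregateChimerism(
        sample_id=sample_id, mean_percent=mean, sem_percent=sem,
        n_snps=len(values), per_snp=list(usable),
    )


def longitudinal_table(
    aggregates: Iterable[AggregateChimerism], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Build the tidy animal x day x cell-subset chimerism table.

    ``metadata`` maps sample_id to animal_id, days_post_hsct and subset
    (e.g. whole blood, granulocyte, T cell). The output is long-format,
    sorted by animal, subset, day, with no interpolation. Duplicate
    (animal, day, subset) keys are rejected.
    """
    required = {"sample_id", "animal_id", "days_post_hsct", "subset"}
    if not required <= set(metadata.columns):
        raise ValueError(f"metadata missing columns {sorted(required - set(metadata.columns))}")
    meta = metadata.set_index("sample_id")
    rows = []
    for agg in aggregates:
        if agg is None:
            continue
        if agg.sample_id not in meta.index:
            raise ValueError(f"no metadata for sample {agg.sample_id}")
        m = meta.loc[agg.sample_id]
        rows.append(
            {
                "animal_id": m["animal_id"],
                "days_post_hsct": int(m["days_post_hsct"]),
                "subset": m["subset"],
                "sample_id": agg.sample_id,
                "mean_percent": agg.mean_percent,
                "sem_percent": agg.sem_percent,
                "n_snps": agg.n_snps,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["animal_id", "days_post_hsct", "subset", "sample_id",
                 "mean_percent", "sem_percent", "n_snps"],
    )
    if len(df):
        dup = df.duplicated(subset=["animal_id", "days_post_hsct", "subset"])
        if dup.any():
            keys = df.loc[dup, ["animal_id", "days_post_hsct", "subset"]].to_records(index=False)
            raise ValueError(f"duplicate (animal, day, subset) keys: {list(keys)}")
        df = df.sort_values(["animal_id", "subset", "days_post_hsct"], kind="stable")
        df = df.reset_index(drop=True)
    return df


def write_estimates_tsv(estimates, metadata: pd.DataFrame, path):
    """Per-SNP chimerism TSV joined with sample metadata."""
    meta = metadata.set_index("sample_id")
    rows = []
    for e in estimates:
        m = meta.loc[e.sample_id]
        rows.append(
            (e.sample_id, m["animal_id"], int(m["days_post_hsct"]), m["subset"],
             e.locus_id, e.configuration.value,
             f"{e.percent:.4f}" if not e.no_coverage else "NA",
             f"{e.ci_low:.4f}" if not e.no_coverage else "NA",
             f"{e.ci_high:.4f}" if not e.no_coverage else "NA",
             str(e.clamped), e.effective_reads)
        )
    pd.DataFrame(
        rows,
        columns=["sample_id", "animal_id", "days_post_hsct", "subset", "locus_id",
                 "configuration", "percent", "ci_low", "ci_high", "clamped",
                 "effective_reads"],
    ).to_csv(path, sep="\t", index=False)
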
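"""End-to-end chimerism pipeline: select-snps -> count -> estimate -> report.

Thin orchestration over the library modules, with a machine-readable run
manifest (inputs, thresholds, seed, package version) written alongside
the outputs so a run can be audited and reproduced. Reruns with
identical inputs produce byte-identical tables (the manifest differs
only in its timestamp).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .amplicon_reads import count_bases, read_fastq, read_fastq_pairs, write_counts_tsv
from .chimerism import aggregate, estimate_chimerism, longitudinal_table, write_estimates_tsv
from .snp_panel import load_genotype_table, load_panel, select_informative_snps

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, animal ids and thresholds for one pipeline run.

    The sample sheet is a TSV with columns sample_id, animal_id,
    days_post_hsct, subset, fastq1 and optionally fastq2 (paired input);
    FASTQ paths are resolved relative to the sample sheet's directory.
    """

    panel_fasta: str
    panel_offsets: str
    genotypes: str
    donor_id: str
    recipient_id: str
    sample_sheet: str
    output_dir: str
    min_base_quality: int = 20
    min_coverage: int = 100
    anchor_length: int = 12
    contamination_warn_fraction: float = 0.02
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self):
        for name in ("panel_fasta", "panel_offsets", "genotypes", "sample_sheet"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if not 0 <= self.min_base_quality <= 60:
            raise ValueError("min_base_quality out of range [0, 60]")
        if self.min_coverage < 1 or self.anchor_length < 8:
            raise ValueError("min_coverage must be >= 1 and anchor_length >= 8")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full chimerism pipeline and write tidy outputs.

    Writes allele_counts.tsv, chimerism_per_snp.tsv,
    chimerism_aggregate.tsv, chimerism_longitudinal.tsv and
    run_manifest.json into ``config.output_dir``; returns a summary dict.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    panel = load_panel(config.panel_fasta, config.panel_offsets)
    donor_gt = load_genotype_table(config.genotypes, config.donor_id)
    recipient_gt = load_genotype_table(config.genotypes, config.recipient_id)
    informative = select_informative_snps(panel, donor_gt, recipient_gt)
    if not informative:
        raise ValueError(
            f"no informative SNPs between donor {config.donor_id} "
            f"and recipient {config.recipient_id}"
        )
    by_locus = {s.locus.locus_id: s for s in informative}
    logger.info("%d informative SNPs: %s", len(informative), sorted(by_locus))

    sheet = pd.read_csv(config.sample_sheet, sep="\t", dtype=str)
    required = {"sample_id", "animal_id", "days_post_hsct", "subset", "fastq1"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet missing columns {sorted(required - set(sheet.columns))}")
    root = Path(config.sample_sheet).parent

    sub_panel = [s.locus for s in informative]
    all_counts, all_estimates, aggregates = [], [], []
    for row in sheet.itertuples(index=False):
        fq1 = root / row.fastq1
        fq2 = getattr(row, "fastq2", None)
        if isinstance(fq2, str) and fq2:
            reads = read_fastq_pairs(fq1, root / fq2)
        else:
            reads = read_fastq(fq1)
        counts = count_bases(
            reads, sub_panel,
            min_base_quality=config.min_base_quality,
            sample_id=row.sample_id,
            anchor_length=config.anchor_length,
        )
        all_counts.extend(counts)
        estimates = [
            estimate_chimerism(
                c, by_locus[c.locus_id],
                min_coverage=config.min_coverage,
                contamination_warn_fraction=config.contamination_warn_fraction,
            )
            for c in counts
        ]
        all_estimates.extend(estimates)
        agg = aggregate(estimates, sample_id=row.sample_id)
        if agg is not None:
            aggregates.append(agg)
            logger.info(
                "sample %s: %.2f%% donor chimerism (%d SNPs)",
                row.sample_id, agg.mean_percent, agg.n_snps,
            )
        else:
            logger.warning("sample %s: no estimate (insufficient coverage)", row.sample_id)

    write_counts_tsv(all_counts, outdir / "allele_counts.tsv")
    write_estimates_tsv(all_estimates, sheet, outdir / "chimerism_per_snp.tsv")
    agg_rows = [
        (a.sample_id, f"{a.mean_percent:.4f}",
         f"{a.sem_percent:.4f}" if a.sem_percent is not None else "NA", a.n_snps)
        for a in aggregates
    ]
    pd.DataFrame(
        agg_rows, columns=["sample_id", "mean_percent", "sem_percent", "n_snps"]
    ).to_csv(outdir / "chimerism_aggregate.tsv", sep="\t", index=False)
    table = longitudinal_table(aggregates, sheet)
    table.to_csv(outdir / "chimerism_longitudinal.tsv", sep="\t", index=False, float_format="%.4f")

    manifest = {
        "tool": "chimerseq",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": dataclasses.asdict(config),
        "informative_snps": {
            lid: by_locus[lid].configuration.value for lid in sorted(by_locus)
        },
        "n_samples": int(len(sheet)),
        "n_samples_estimated": len(aggregates),
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
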
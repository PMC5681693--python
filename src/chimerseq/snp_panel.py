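"""Donor/recipient SNP panels and informative-locus selection.

After an allogeneic hematopoietic stem cell transplant, the fraction of
blood cells derived from the donor ("donor chimerism") can be read out by
deep-sequencing short PCR amplicons that span single-nucleotide
polymorphisms (SNPs) at which the donor and recipient genomes differ.
A locus is *informative* when the two genotypes differ in a way that lets
read fractions discriminate cell origin:

* donor heterozygous / recipient homozygous — the donor carries a private
  allele the recipient lacks;
* donor homozygous / recipient heterozygous — the mirror case;
* both homozygous for different alleles — every read is origin-labelled.

All other genotype pairs (identical genotypes, or both animals
heterozygous for the same two alleles) yield identical expected allele
fractions in a pure-donor and a pure-recipient sample and are therefore
uninformative.

This module holds the domain types for loci and genotypes, the
pair-classification rule, and panel/genotype table IO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

NUCLEOTIDES = frozenset("ACGT")


class PairConfiguration(Enum):
    """Informativeness class of a donor/recipient genotype pair at one locus."""

    HET_DONOR_HOM_RECIPIENT = "het_donor_hom_recipient"
    HOM_DONOR_HET_RECIPIENT = "hom_donor_het_recipient"
    HOM_HOM_DIFFERENT = "hom_hom_different"
    UNINFORMATIVE = "uninformative"

    @property
    def informative(self) -> bool:
        return self is not PairConfiguration.UNINFORMATIVE


@dataclass(frozen=True)
class SnpLocus:
    """An amplicon reference sequence with a single interrogated SNP.

    Parameters
    ----------
    locus_id
        Unique locus name.
    amplicon_seq
        Uppercase A/C/G/T reference sequence of the amplicon (~220 bp in
        the assay this models).
    snp_offset
        0-based index of the SNP within ``amplicon_seq``.
    observed_alleles
        The nucleotides segregating at this locus (1 or 2; a biallelic
        panel never yields more).
    """

    locus_id: str
    amplicon_seq: str
    snp_offset: int
    observed_alleles: frozenset

    def __post_init__(self):
        seq = self.amplicon_seq
        if not seq or set(seq) - NUCLEOTIDES:
            raise ValueError(f"{self.locus_id}: amplicon must be non-empty uppercase A/C/G/T")
        if not 0 <= self.snp_offset < len(seq):
            raise ValueError(f"{self.locus_id}: snp_offset {self.snp_offset} outside amplicon")
        alleles = frozenset(self.observed_alleles)
        if not alleles <= NUCLEOTIDES or not 1 <= len(alleles) <= 2:
            raise ValueError(
                f"{self.locus_id}: observed_alleles must be 1-2 nucleotides, got {sorted(alleles)}"
            )
        if seq[self.snp_offset] not in alleles:
            raise ValueError(
                f"{self.locus_id}: reference base {seq[self.snp_offset]} at the SNP "
                f"is not among observed alleles {sorted(alleles)}"
            )
        object.__setattr__(self, "observed_alleles", alleles)


@dataclass(frozen=True)
class Genotype:
    """An unordered, unphased pair of alleles at one locus for one animal."""

    locus_id: str
    alleles: tuple

    def __post_init__(self):
        if len(self.alleles) != 2 or set(self.alleles) - NUCLEOTIDES:
            raise ValueError(
                f"{self.locus_id}: genotype needs two A/C/G/T alleles, got {self.alleles!r}"
            )
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    @property
    def allele_set(self) -> frozenset:
        return frozenset(self.alleles)


@dataclass(frozen=True)
class InformativeSnp:
    """A selected locus carrying the nucleotides the chimerism formulas count.

    ``donor_specific_nt`` is the allele present in the donor but absent from
    the recipient (set for het-donor/hom-recipient and hom-hom-different);
    ``recipient_specific_nt`` is the mirror (set for hom-donor/het-recipient
    and hom-hom-different).
    """

    locus: SnpLocus
    configuration: PairConfiguration
    donor_specific_nt: str | None
    recipient_specific_nt: str | None

    def __post_init__(self):
        cfg = self.configuration
        if cfg is PairConfiguration.UNINFORMATIVE:
            raise ValueError("an InformativeSnp cannot be UNINFORMATIVE")
        if cfg is PairConfiguration.HET_DONOR_HOM_RECIPIENT and self.donor_specific_nt is None:
            raise ValueError("het-donor/hom-recipient requires donor_specific_nt")
        if cfg is PairConfiguration.HOM_DONOR_HET_RECIPIENT and self.recipient_specific_nt is None:
            raise ValueError("hom-donor/het-recipient requires recipient_specific_nt")
        if cfg is PairConfiguration.HOM_HOM_DIFFERENT:
            if self.donor_specific_nt is None or self.recipient_specific_nt is None:
                raise ValueError("hom-hom-different requires both discriminating nucleotides")
            if self.donor_specific_nt == self.recipient_specific_nt:
                raise ValueError("hom-hom-different nucleotides must differ")


def classify_pair(donor: Genotype, recipient: Genotype) -> PairConfiguration:
    """Classify a donor/recipient genotype pair at one locus.

    Returns the configuration that determines which (if any) chimerism
    formula applies. A pair is UNINFORMATIVE when no nucleotide has a
    different expected read fraction between a pure-donor and a
    pure-recipient sample.
    """
    if donor.locus_id != recipient.locus_id:
        raise ValueError(f"locus mismatch: {donor.locus_id} vs {recipient.locus_id}")
    d, r = donor.allele_set, recipient.allele_set
    if d == r:
        return PairConfiguration.UNINFORMATIVE
    if not donor.is_homozygous and recipient.is_homozygous:
        # donor always carries an allele the recipient lacks here (sets differ)
        return PairConfiguration.HET_DONOR_HOM_RECIPIENT
    if donor.is_homozygous and not recipient.is_homozygous:
        return PairConfiguration.HOM_DONOR_HET_RECIPIENT
    if donor.is_homozygous and recipient.is_homozygous:
        return PairConfiguration.HOM_HOM_DIFFERENT
    # both heterozygous with differing allele sets: e.g. A/G vs A/T.  Read
    # fractions do differ in principle, but no single-formula case of the
    # assay covers it and the panel never uses such loci.
    return PairConfiguration.UNINFORMATIVE


def discriminating_nucleotides(
    donor: Genotype, recipient: Genotype, config: PairConfiguration
) -> tuple:
    """Return ``(donor_specific_nt, recipient_specific_nt)`` for a configuration.

    These are the nucleotides whose read fractions the percent-chimerism
    formulas count: the donor allele absent from the recipient and/or the
    recipient allele absent from the donor.
    """
    d, r = donor.allele_set, recipient.allele_set
    # A heterozygote sharing no allele with the homozygote has two private
    # alleles; each sits on one chromosome, so either serves the formula.
    # Take the lexicographically smallest for determinism.
    if config is PairConfiguration.HET_DONOR_HOM_RECIPIENT:
        return min(d - r), None
    if config is PairConfiguration.HOM_DONOR_HET_RECIPIENT:
        return None, min(r - d)
    if config is PairConfiguration.HOM_HOM_DIFFERENT:
        return donor.alleles[0], recipient.alleles[0]
    raise ValueError("no discriminating nucleotides for an UNINFORMATIVE pair")


def select_informative_snps(
    panel: Sequence[SnpLocus],
    donor_genotypes: Mapping[str, Genotype],
    recipient_genotypes: Mapping[str, Genotype],
) -> list:
    """Select the loci usable for chimerism estimation for one donor/recipient pair.

    Loci with a missing genotype in either animal are skipped with a
    warning; an empty result is legal (autologous pair) but leaves the
    downstream estimator with nothing to do.
    """
    out = []
    for locus in sorted(panel, key=lambda l: l.locus_id):
        dg = donor_genotypes.get(locus.locus_id)
        rg = recipient_genotypes.get(locus.locus_id)
        if dg is None or rg is None:
            logger.warning("locus %s skipped: genotype missing for one animal", locus.locus_id)
            continue
        observed = dg.allele_set | rg.allele_set
        if len(observed | {locus.amplicon_seq[locus.snp_offset]}) > 2:
            raise ValueError(
                f"locus {locus.locus_id}: more than two alleles observed "
                f"({sorted(observed)}); the panel is biallelic by design"
            )
        config = classify_pair(dg, rg)
        if not config.informative:
            continue
        donor_nt, recip_nt = discriminating_nucleotides(dg, rg, config)
        out.append(
            InformativeSnp(
                locus=locus,
                configuration=config,
                donor_specific_nt=donor_nt,
                recipient_specific_nt=recip_nt,
            )
        )
    if panel and not out:
        logger.warning("no informative loci for this donor-recipient pair")
    return out


# ---------------------------------------------------------------------------
# tabular / FASTA IO

def load_genotype_table(path, animal_id: str) -> dict:
    """Load one animal's genotypes from a TSV with columns
    locus_id, animal_id, allele1, allele2."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_id", "animal_id", "allele1", "allele2"}
    if not required <= set(df.columns):
        raise ValueError(f"genotype table missing columns {sorted(required - set(df.columns))}")
    sub = df[df["animal_id"] == animal_id]
    genotypes = {}
    for row in sub.itertuples(index=False):
        if row.locus_id in genotypes:
            raise ValueError(f"duplicate genotype for {animal_id} at {row.locus_id}")
        genotypes[row.locus_id] = Genotype(row.locus_id, (row.allele1, row.allele2))
    return genotypes


def load_panel(fasta_path, offsets_path) -> list:
    """Load SNP locus definitions: a FASTA of amplicon references keyed by
    locus_id plus a TSV with columns locus_id, snp_offset (0-based) and
    optionally ref_allele/alt_allele."""
    offsets = pd.read_csv(offsets_path, sep="\t", dtype={"locus_id": str, "snp_offset": int})
    if not {"locus_id", "snp_offset"} <= set(offsets.columns):
        raise ValueError("locus definition TSV needs columns locus_id, snp_offset")
    meta = offsets.set_index("locus_id")
    panel = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta.index:
            raise ValueError(f"amplicon {rec.id} has no snp_offset entry")
        row = meta.loc[rec.id]
        seq = str(rec.seq).upper()
        offset = int(row["snp_offset"])
        alleles = {seq[offset]}
        for col in ("ref_allele", "alt_allele"):
            if col in meta.columns and isinstance(row.get(col), str):
                alleles.add(row[col])
        panel.append(SnpLocus(rec.id, seq, offset, frozenset(alleles)))
    missing = set(meta.index) - {l.locus_id for l in panel}
    if missing:
        raise ValueError(f"loci {sorted(missing)} defined in TSV but absent from FASTA")
    return panel


def write_genotype_table(path, genotypes_by_animal: Mapping[str, Mapping[str, Genotype]]):
    rows = []
    for animal, table in genotypes_by_animal.items():
        for locus_id in sorted(table):
            g = table[locus_id]
            rows.append((locus_id, animal, g.alleles[0], g.alleles[1]))
    pd.DataFrame(rows, columns=["locus_id", "animal_id", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def write_panel(fasta_path, offsets_path, panel: Iterable[SnpLocus]):
    panel = sorted(panel, key=lambda l: l.locus_id)
    with open(fasta_path, "w") as fh:
        for locus in panel:
            fh.write(f">{locus.locus_id}\n{locus.amplicon_seq}\n")
    rows = []
    for locus in panel:
        ref = locus.amplicon_seq[locus.snp_offset]
        alts = sorted(locus.observed_alleles - {ref})
        rows.append((locus.locus_id, locus.snp_offset, ref, alts[0] if alts else ref))
    pd.DataFrame(rows, columns=["locus_id", "snp_offset", "ref_allele", "alt_allele"]).to_csv(
        offsets_path, sep="\t", index=False
    )
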
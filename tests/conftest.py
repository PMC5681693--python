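import numpy as np
import pytest

from chimerseq import Genotype, SnpLocus
from chimerseq.mhc_typing import load_bundled_reference


def make_locus(locus_id: str, seed: int, ref: str = "A", alt: str = "G",
               length: int = 220, offset: int = 110) -> SnpLocus:
    """Random amplicon with a fixed ref base at the SNP offset."""
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    seq = "".join(bases[i] for i in rng.integers(0, 4, size=length))
    seq = seq[:offset] + ref + seq[offset + 1:]
    return SnpLocus(locus_id, seq, offset, frozenset({ref, alt}))


@pytest.fixture(scope="session")
def locus_ag() -> SnpLocus:
    return make_locus("locAG", seed=11)


@pytest.fixture(scope="session")
def configured_pairs(locus_ag):
    """One (donor_gt, recipient_gt) per informative configuration at locus_ag."""
    lid = locus_ag.locus_id
    return {
        "HET_DONOR_HOM_RECIPIENT": (Genotype(lid, ("A", "G")), Genotype(lid, ("A", "A"))),
        "HOM_DONOR_HET_RECIPIENT": (Genotype(lid, ("A", "A")), Genotype(lid, ("A", "G"))),
        "HOM_HOM_DIFFERENT": (Genotype(lid, ("G", "G")), Genotype(lid, ("A", "A"))),
    }


@pytest.fixture(scope="session")
def mcm_reference():
    return load_bundled_reference()


def pure_sample_fraction(genotype: Genotype, nt: str) -> float:
    """Expected read fraction of nucleotide nt in a pure sample of this
    animal: the share of its two chromosomes carrying nt."""
    return sum(a == nt for a in genotype.alleles) / 2


def fractions_differ(donor: Genotype, recipient: Genotype) -> bool:
    """Does some nucleotide's expected read fraction differ between a
    pure-donor and a pure-recipient sample?"""
    return any(
        pure_sample_fraction(donor, nt) != pure_sample_fraction(recipient, nt)
        for nt in "ACGT"
    )


def informative_oracle(donor: Genotype, recipient: Genotype) -> bool:
    """Brute force: a pair is informative iff some nucleotide's expected
    read fraction differs between pure donor and pure recipient, AND at
    least one animal is homozygous — the assay's selection rule admits
    only het/hom, hom/het and hom/hom-different loci; both-heterozygous
    loci are never used even when a private allele exists."""
    return fractions_differ(donor, recipient) and (
        donor.is_homozygous or recipient.is_homozygous
    )
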
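"""Synthetic inputs for every pipeline stage.

Generates (a) donor/recipient genotype panels under Hardy-Weinberg
equilibrium, (b) mixed-origin amplicon reads at a known true chimerism
fraction with uniform substitution sequencing error, and (c) MHC exon-2
reads drawn from a known haplotype pair — each with a truth side-channel
so estimators can be checked against labelled ground truth.

The defaults emulate the assay being modelled: ~220 bp SNP amplicons
read full-length on 2x250 paired-end chemistry (a read spans the whole
amplicon, so fragments are not simulated), substitution-dominated MiSeq
error around 0.2%, constant Phred 35 qualities with an optional
low-quality 3' tail profile to exercise trimming and the N-gate.
Identical seed and configuration give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .amplicon_reads import ReadRecord
from .mhc_typing import HaplotypeDefinition, MhcAllele
from .snp_panel import Genotype, SnpLocus

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # ord("ACGT") -> 0..3


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq.encode("ascii")], dtype=np.uint8)


def _decode_rows(matrix: np.ndarray) -> list:
    buf = _BASES[matrix]
    width = matrix.shape[1]
    raw = buf.tobytes()
    return [raw[i * width : (i + 1) * width].decode("ascii") for i in range(matrix.shape[0])]


def _substitute(matrix: np.ndarray, error_rate: float, rng: np.random.Generator):
    """Apply iid per-base substitutions in place (uniform over the 3 other
    bases), via the exact equivalence Binomial(total, e) errors at
    uniformly chosen distinct positions."""
    if error_rate <= 0:
        return
    total = matrix.size
    n_err = rng.binomial(total, error_rate)
    if n_err == 0:
        return
    flat = rng.choice(total, size=n_err, replace=False)
    shift = rng.integers(1, 4, size=n_err, dtype=np.uint8)
    view = matrix.reshape(-1)
    view[flat] = (view[flat] + shift) % 4


@dataclass(frozen=True)
class MixtureSimConfig:
    """Conditions for one simulated chimerism sequencing run."""

    true_chimerism_percent: float
    depth_per_locus: int
    error_rate: float = 0.002
    read_length: int = 250
    seed: int = 0
    quality_model: int = 35          # constant Phred value
    low_quality_tail: int = 0        # final N bases at Phred 2, exercises trimming/N-gate

    def __post_init__(self):
        if not 0.0 <= self.true_chimerism_percent <= 100.0:
            raise ValueError("true_chimerism_percent must be in [0, 100]")
        if self.depth_per_locus <= 0:
            raise ValueError("depth_per_locus must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class SimTruth:
    """Ground-truth side channel for simulated reads."""

    origin_labels: dict = field(default_factory=dict)   # read_id -> "donor" | "recipient"
    donor_reads_per_locus: dict = field(default_factory=dict)
    depth_per_locus: dict = field(default_factory=dict)
    haplotype_pair: Optional[tuple] = None
    allele_of_read: dict = field(default_factory=dict)  # MHC mode: read_id -> allele name

    def donor_fraction(self, locus_id: str) -> float:
        return self.donor_reads_per_locus[locus_id] / self.depth_per_locus[locus_id]


# ---------------------------------------------------------------------------
# genotype panels

def simulate_genotype_pair(
    n_loci: int,
    maf: float = 0.5,
    seed: int = 0,
    amplicon_length: int = 220,
    snp_offset: int = 110,
) -> tuple:
    """Simulate a donor/recipient genotype pair over a biallelic SNP panel.

    Each animal draws two alleles independently at alternate-allele
    frequency ``maf`` (Hardy-Weinberg equilibrium); amplicon reference
    sequences are random with the SNP at ``snp_offset``. Returns
    ``(donor_genotypes, recipient_genotypes, panel)`` with genotypes as
    ``{locus_id: Genotype}``.
    """
    if n_loci <= 0:
        raise ValueError("n_loci must be positive")
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed)
    donor, recipient, panel = {}, {}, []
    width = len(str(n_loci))
    for i in range(n_loci):
        locus_id = f"snp{i:0{width}d}"
        codes = rng.integers(0, 4, size=amplicon_length, dtype=np.uint8)
        ref = int(codes[snp_offset])
        alt = int((ref + rng.integers(1, 4)) % 4)
        seq = _decode_rows(codes[None, :])[0]
        bases = "ACGT"
        alleles = frozenset((bases[ref], bases[alt]))
        panel.append(SnpLocus(locus_id, seq, snp_offset, alleles))
        for table in (donor, recipient):
            pair = tuple(bases[alt] if rng.random() < maf else bases[ref] for _ in range(2))
            table[locus_id] = Genotype(locus_id, pair)
    return donor, recipient, panel


def expected_informative_fraction(maf: float) -> float:
    """Closed-form probability that an independent donor/recipient pair is
    informative at a Hardy-Weinberg locus with alternate-allele frequency
    ``maf`` (het x hom, hom x het, or opposite homozygotes)."""
    q = maf
    p_het = 2 * q * (1 - q)
    p_hom_ref = (1 - q) ** 2
    p_hom_alt = q**2
    p_hom = p_hom_ref + p_hom_alt
    return 2 * p_het * p_hom + 2 * p_hom_ref * p_hom_alt


# ---------------------------------------------------------------------------
# mixed-origin SNP amplicon reads

def _quality_bytes(config: MixtureSimConfig, length: int) -> bytes:
    q = bytearray([config.quality_model]) * length
    if config.low_quality_tail:
        tail = min(config.low_quality_tail, length)
        q[length - tail :] = bytes([2]) * tail
    return bytes(q)


def simulate_mixture_reads(
    config: MixtureSimConfig,
    panel: Sequence[SnpLocus],
    donor_genotypes,
    recipient_genotypes,
) -> tuple:
    """Simulate amplicon reads from a donor/recipient cell mixture.

    Per locus, each read's origin is donor with probability
    ``true_chimerism_percent/100``; its SNP base is drawn uniformly from
    the origin animal's two alleles; every base is independently
    substituted with probability ``error_rate``; half the reads are
    emitted as the reverse complement. Requires at least one informative
    locus in the panel (checked against the genotypes).

    Returns ``(reads, truth)`` with reads as a list of
    :class:`ReadRecord` and truth labelling every read's origin.
    """
    from .snp_panel import classify_pair

    informative = [
        locus
        for locus in panel
        if locus.locus_id in donor_genotypes
        and locus.locus_id in recipient_genotypes
        and classify_pair(
            donor_genotypes[locus.locus_id], recipient_genotypes[locus.locus_id]
        ).informative
    ]
    if not informative:
        raise ValueError("no informative locus in the panel for this genotype pair")

    rng = np.random.default_rng(config.seed)
    c = config.true_chimerism_percent / 100.0
    reads: list = []
    truth = SimTruth()
    for locus in sorted(panel, key=lambda l: l.locus_id):
        depth = config.depth_per_locus
        amp = _encode(locus.amplicon_seq)
        matrix = np.tile(amp, (depth, 1))

        origin_donor = rng.random(depth) < c
        pick = rng.integers(0, 2, size=depth)
        d_alleles = np.array(
            [_CODE[ord(a)] for a in donor_genotypes[locus.locus_id].alleles], dtype=np.uint8
        )
        r_alleles = np.array(
            [_CODE[ord(a)] for a in recipient_genotypes[locus.locus_id].alleles], dtype=np.uint8
        )
        snp_base = np.where(origin_donor, d_alleles[pick], r_alleles[pick])
        matrix[:, locus.snp_offset] = snp_base

        _substitute(matrix, config.error_rate, rng)

        flip = rng.random(depth) < 0.5
        fwd = _decode_rows(matrix)
        rc_matrix = (3 - matrix[flip])[:, ::-1]
        rc_seqs = iter(_decode_rows(rc_matrix)) if flip.any() else iter(())

        qual = _quality_bytes(config, matrix.shape[1])
        for i in range(depth):
            seq = next(rc_seqs) if flip[i] else fwd[i]
            read_id = f"{locus.locus_id}:{i}"
            reads.append(ReadRecord(read_id, seq, qual, mate=1))
            truth.origin_labels[read_id] = "donor" if origin_donor[i] else "recipient"
        truth.donor_reads_per_locus[locus.locus_id] = int(origin_donor.sum())
        truth.depth_per_locus[locus.locus_id] = depth
    return reads, truth


# ---------------------------------------------------------------------------
# MHC reads from a known haplotype pair

def simulate_mhc_reads(
    haplotype_pair: tuple,
    definitions: Sequence[HaplotypeDefinition],
    library: Sequence[MhcAllele],
    depth_per_allele: int = 500,
    error_rate: float = 0.001,
    seed: int = 0,
    quality: int = 35,
) -> tuple:
    """Simulate exon-2 amplicon reads from an animal with a known
    haplotype pair: ``depth_per_allele`` full-length reads per allele in
    the pair's union allele set, with substitution errors and random
    strand."""
    defs = {d.haplotype_name: d.allele_names for d in definitions}
    for name in haplotype_pair:
        if name not in defs:
            raise ValueError(f"unknown haplotype {name!r}")
    union = sorted(defs[haplotype_pair[0]] | defs[haplotype_pair[1]])
    seqs = {a.allele_name: a.exon2_seq for a in library}
    missing = [a for a in union if a not in seqs]
    if missing:
        raise ValueError(f"alleles {missing} absent from the library")

    rng = np.random.default_rng(seed)
    reads: list = []
    truth = SimTruth(haplotype_pair=tuple(sorted(haplotype_pair)))
    for allele in union:
        amp = _encode(seqs[allele])
        matrix = np.tile(amp, (depth_per_allele, 1))
        _substitute(matrix, error_rate, rng)
        flip = rng.random(depth_per_allele) < 0.5
        fwd = _decode_rows(matrix)
        rc_matrix = (3 - matrix[flip])[:, ::-1]
        rc_seqs = iter(_decode_rows(rc_matrix)) if flip.any() else iter(())
        qual = bytes([quality]) * matrix.shape[1]
        for i in range(depth_per_allele):
            seq = next(rc_seqs) if flip[i] else fwd[i]
            read_id = f"{allele}:{i}"
            reads.append(ReadRecord(read_id, seq, qual, mate=1))
            truth.allele_of_read[read_id] = allele
    return reads, truth


# ---------------------------------------------------------------------------
# synthetic MCM reference (library + haplotype definitions)

def synthetic_mcm_reference(seed: int = 20240917) -> tuple:
    """Build a SYNTHETIC stand-in for the MCM MHC reference.

    The real M1-M7 haplotype allele compositions are published reference
    data not bundled here; this deterministic synthetic library preserves
    the structural features that matter to the algorithms: seven
    haplotypes, each carrying class I (191 bp exon-2 amplicon) and class
    II (169 bp) alleles, with one class I allele shared between adjacent
    haplotypes (so reads can legitimately support several haplotypes)
    and at least one private allele per haplotype (so all 28 unordered
    pairs have distinct union sets and are recoverable).

    Returns ``(library, definitions)``.
    """
    rng = np.random.default_rng(seed)
    base_I = rng.integers(0, 4, size=191, dtype=np.uint8)
    base_II = rng.integers(0, 4, size=169, dtype=np.uint8)

    def variant(base: np.ndarray, n_subs: int) -> str:
        codes = base.copy()
        pos = rng.choice(base.size, size=n_subs, replace=False)
        codes[pos] = (codes[pos] + rng.integers(1, 4, size=n_subs)) % 4
        return _decode_rows(codes[None, :])[0]

    library: list = []
    definitions: list = []
    seen = set()

    def make(base, n_subs):
        while True:
            seq = variant(base, n_subs)
            if seq not in seen:
                seen.add(seq)
                return seq

    shared = {i: make(base_I, 6) for i in range(1, 8)}  # shared[i]: between Mi and M(i%7+1)
    for i in range(1, 8):
        name = f"M{i}"
        alleles = set()
        for k in range(3):  # private class I alleles
            allele = f"I-{name}-{chr(ord('a') + k)}"
            library.append(MhcAllele(allele, "I", make(base_I, 8)))
            alleles.add(allele)
        shared_name = f"I-s{i}{i % 7 + 1}"
        if not any(a.allele_name == shared_name for a in library):
            library.append(MhcAllele(shared_name, "I", shared[i]))
        alleles.add(shared_name)
        prev = f"I-s{(i - 2) % 7 + 1}{i}"
        alleles.add(prev)
        for k in range(2):  # private class II alleles
            allele = f"II-{name}-{chr(ord('a') + k)}"
            library.append(MhcAllele(allele, "II", make(base_II, 8)))
            alleles.add(allele)
        definitions.append(HaplotypeDefinition(name, frozenset(alleles)))
    return library, definitions
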
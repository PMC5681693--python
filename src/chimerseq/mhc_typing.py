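"""MHC exon-2 amplicon genotyping and MCM haplotype-pair inference.

Mauritian-origin cynomolgus macaques (MCM) descend from a small founder
population and carry only seven fully characterized MHC haplotypes
(M1-M7), each a fixed block of linked class I and class II alleles.
Genotyping short exon-2 amplicons (~191 bp class I, ~169 bp class II)
against a reference allele library therefore resolves an animal to an
unordered haplotype pair, from which donor-recipient MHC match level
(full match / haploidentical / mismatch) follows directly.

Scoring is strict: a trimmed read supports an allele only by exact
substring containment (either direction, minimum overlap), mirroring a
perfect-match policy — sequencing errors cost reads, never create false
allele evidence. Alleles with identical exon-2 sequences are
indistinguishable by this amplicon and are reported jointly as a group.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .amplicon_reads import ReadRecord, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MhcAllele:
    """One reference allele: name, class (I or II), exon-2 amplicon sequence."""

    allele_name: str
    mhc_class: str
    exon2_seq: str

    def __post_init__(self):
        if self.mhc_class not in ("I", "II"):
            raise ValueError(f"{self.allele_name}: mhc_class must be 'I' or 'II'")
        if not self.exon2_seq or set(self.exon2_seq) - set("ACGT"):
            raise ValueError(f"{self.allele_name}: exon2_seq must be uppercase A/C/G/T")


@dataclass(frozen=True)
class HaplotypeDefinition:
    """A named MCM haplotype and the allele names it carries."""

    haplotype_name: str
    allele_names: frozenset

    def __post_init__(self):
        if not self.allele_names:
            raise ValueError(f"{self.haplotype_name}: empty allele set")
        object.__setattr__(self, "allele_names", frozenset(self.allele_names))


@dataclass
class HaplotypeCall:
    """Best-scoring unordered haplotype pair for one animal."""

    animal_id: str
    haplotype_pair: tuple
    score: float
    alleles_detected: dict
    unexplained_alleles: frozenset
    tied: bool = False


class MatchGrade(Enum):
    FULL_MATCH = "full_match"          # identical unordered haplotype pairs
    HAPLOIDENTICAL = "haploidentical"  # share >= 1 haplotype, not identical
    MISMATCH = "mismatch"
    INDETERMINATE = "indeterminate"    # at least one animal had no call


# ---------------------------------------------------------------------------
# read trimming

def trim_read(
    read: ReadRecord, quality_threshold: int = 20, min_length: int = 100, window: int = 4
) -> Optional[ReadRecord]:
    """Sliding-window quality trim of one read; None when it falls below
    ``min_length``.

    Scanning 5'->3', the read is truncated at the first window whose mean
    quality drops below the threshold (the final, shorter windows are
    checked too), which in practice removes low-quality 3' tails.
    """
    q = read.qualities
    cut = len(q)
    for i in range(len(q)):
        w = q[i : i + window]
        if sum(w) / len(w) < quality_threshold:
            cut = i
            # the failing window may start with good bases: keep them
            while cut < len(q) and q[cut] >= quality_threshold:
                cut += 1
            break
    if cut < min_length:
        return None
    if cut == len(q):
        return read
    return ReadRecord(read.read_id, read.sequence[:cut], q[:cut], read.mate)


def trim_reads(
    reads: Iterable[ReadRecord],
    quality_threshold: int = 20,
    min_length: int = 100,
    window: int = 4,
    stats: Optional[dict] = None,
) -> Iterator[ReadRecord]:
    """Stream-trim reads; drops (reads trimmed below ``min_length``) are
    counted into ``stats['dropped']`` when a stats dict is supplied."""
    dropped = 0
    for read in reads:
        trimmed = trim_read(read, quality_threshold, min_length, window)
        if trimmed is None:
            dropped += 1
        else:
            yield trimmed
    if stats is not None:
        stats["dropped"] = dropped


# ---------------------------------------------------------------------------
# perfect-match scoring

@dataclass
class AlleleGroup:
    """Alleles sharing an identical exon-2 sequence (indistinguishable)."""

    members: tuple
    exon2_seq: str

    @property
    def name(self) -> str:
        return "|".join(self.members)


@dataclass
class AlleleScoring:
    """Perfect-match read counts per allele group for one animal."""

    counts: dict              # group name -> read count
    groups: dict              # group name -> AlleleGroup
    total_assigned: int       # reads matching >= 1 allele
    n_reads: int

    def count_for(self, allele_name: str) -> int:
        for g in self.groups.values():
            if allele_name in g.members:
                return self.counts[g.name]
        return 0


def group_alleles(library: Sequence[MhcAllele]) -> dict:
    """Collapse identical exon-2 sequences into jointly-reported groups."""
    names = Counter(a.allele_name for a in library)
    dup = [n for n, c in names.items() if c > 1]
    if dup:
        raise ValueError(f"duplicate allele names in library: {dup}")
    by_seq: dict = {}
    for a in library:
        by_seq.setdefault(a.exon2_seq, []).append(a.allele_name)
    groups = {}
    for seq, members in by_seq.items():
        g = AlleleGroup(members=tuple(sorted(members)), exon2_seq=seq)
        groups[g.name] = g
        if len(members) > 1:
            logger.info("alleles %s share an exon-2 sequence; reported jointly", g.name)
    return groups


def score_alleles(
    reads: Iterable[ReadRecord], library: Sequence[MhcAllele], min_overlap: int = 100
) -> AlleleScoring:
    """Count perfect-match reads per allele (group).

    A read supports an allele iff the read (or its reverse complement)
    contains the allele's exon-2 sequence as an exact substring, or is
    itself contained in it with length >= ``min_overlap``. A read may
    support several alleles — shared exon-2 motifs are real. Counts are
    order- and strand-invariant.
    """
    if not library:
        raise ValueError("empty allele library")
    groups = group_alleles(library)
    counts = Counter()
    total_assigned = 0
    n_reads = 0
    # identical read sequences score identically: dedupe before matching
    seq_tally = Counter()
    for read in reads:
        n_reads += 1
        seq_tally[read.sequence] += 1
    for seq, mult in seq_tally.items():
        rc = revcomp(seq)
        matched = False
        for name, g in groups.items():
            ref = g.exon2_seq
            if (
                ref in seq
                or ref in rc
                or (len(seq) >= min_overlap and (seq in ref or rc in ref))
            ):
                counts[name] += mult
                matched = True
        if matched:
            total_assigned += mult
    return AlleleScoring(
        counts=dict(counts), groups=groups, total_assigned=total_assigned, n_reads=n_reads
    )


def call_alleles(
    scoring: AlleleScoring, min_fraction: float = 0.005, min_count: int = 10
) -> frozenset:
    """Present alleles: count >= min_count and fraction of assigned reads
    >= min_fraction (both boundaries inclusive). Group membership expands
    to every member name. Empty when nothing was assigned (no-call)."""
    if scoring.total_assigned == 0:
        logger.warning("no reads matched any reference allele: no-call")
        return frozenset()
    present = set()
    for name, count in scoring.counts.items():
        if count >= min_count and count / scoring.total_assigned >= min_fraction:
            present.update(scoring.groups[name].members)
    return frozenset(present)


# ---------------------------------------------------------------------------
# haplotype inference and match grading

def infer_haplotypes(
    present_alleles: frozenset,
    definitions: Sequence[HaplotypeDefinition],
    animal_id: str = "",
    alleles_detected: Optional[Mapping[str, int]] = None,
    explained_weight: float = 1.0,
    missing_penalty: float = 1.0,
    unexplained_penalty: float = 1.0,
) -> Optional[HaplotypeCall]:
    """Exhaustively score all unordered haplotype pairs against the
    detected allele set and return the best.

    For candidate pair (Hi, Hj) with union allele set U:

        score = w*|present & U| - lam*|U - present| - mu*|present - U|

    with w = lam = mu = 1 by default. Ties break toward fewer
    unexplained alleles, then the lexicographically first pair name; a
    surviving tie is flagged on the call. Empty ``present_alleles`` is a
    no-call (None).
    """
    if not definitions:
        raise ValueError("no haplotype definitions supplied")
    present = frozenset(present_alleles)
    if not present:
        logger.warning("animal %s: no alleles detected, haplotype no-call", animal_id)
        return None
    defs = {d.haplotype_name: d.allele_names for d in definitions}
    best = None
    for h1, h2 in itertools.combinations_with_replacement(sorted(defs), 2):
        union = defs[h1] | defs[h2]
        explained = len(present & union)
        missing = len(union - present)
        unexplained = len(present - union)
        score = (
            explained_weight * explained
            - missing_penalty * missing
            - unexplained_penalty * unexplained
        )
        key = (-score, unexplained, (h1, h2))
        if best is None or key < best[0]:
            best = (key, (h1, h2), score, unexplained, False)
        elif key[:2] == best[0][:2]:
            best = (best[0], best[1], best[2], best[3], True)
    _, pair, score, _, tied = best
    if tied:
        logger.warning("animal %s: tied haplotype-pair scores; reporting %s/%s", animal_id, *pair)
    union = defs[pair[0]] | defs[pair[1]]
    return HaplotypeCall(
        animal_id=animal_id,
        haplotype_pair=pair,
        score=float(score),
        alleles_detected=dict(alleles_detected or {}),
        unexplained_alleles=frozenset(present - union),
        tied=tied,
    )


def grade_match(donor: Optional[HaplotypeCall], recipient: Optional[HaplotypeCall]) -> MatchGrade:
    """Grade donor-recipient MHC match from their haplotype pairs.

    Symmetric; either no-call yields INDETERMINATE.
    """
    if donor is None or recipient is None:
        return MatchGrade.INDETERMINATE
    d = tuple(sorted(donor.haplotype_pair))
    r = tuple(sorted(recipient.haplotype_pair))
    if d == r:
        return MatchGrade.FULL_MATCH
    if set(d) & set(r):
        return MatchGrade.HAPLOIDENTICAL
    return MatchGrade.MISMATCH


def type_animal(
    reads: Iterable[ReadRecord],
    library: Sequence[MhcAllele],
    definitions: Sequence[HaplotypeDefinition],
    animal_id: str = "",
    quality_threshold: int = 20,
    min_length: int = 100,
    min_overlap: int = 100,
    min_fraction: float = 0.005,
    min_count: int = 10,
) -> tuple:
    """Full typing workflow: trim -> perfect-match score -> call -> infer.

    Returns ``(HaplotypeCall or None, AlleleScoring)``.
    """
    trimmed = trim_reads(reads, quality_threshold, min_length)
    scoring = score_alleles(trimmed, library, min_overlap)
    present = call_alleles(scoring, min_fraction, min_count)
    call = infer_haplotypes(
        present, definitions, animal_id=animal_id, alleles_detected=scoring.counts
    )
    return call, scoring


# ---------------------------------------------------------------------------
# reference IO

def load_allele_library(path) -> list:
    """FASTA with headers ``>allele_name class=I|II``."""
    library = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        if "class" not in fields:
            raise ValueError(f"allele {rec.id}: header lacks class=I|II")
        library.append(MhcAllele(rec.id, fields["class"], str(rec.seq).upper()))
    return library


def write_allele_library(library: Iterable[MhcAllele], path):
    with open(path, "w") as fh:
        for a in sorted(library, key=lambda x: x.allele_name):
            fh.write(f">{a.allele_name} class={a.mhc_class}\n{a.exon2_seq}\n")


def load_haplotype_definitions(path) -> list:
    """TSV with columns haplotype_name, allele_name (one row per allele)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"haplotype_name", "allele_name"} <= set(df.columns):
        raise ValueError("haplotype definitions need columns haplotype_name, allele_name")
    defs = [
        HaplotypeDefinition(name, frozenset(sub["allele_name"]))
        for name, sub in df.groupby("haplotype_name", sort=True)
    ]
    sets = [d.allele_names for d in defs]
    if len(set(sets)) != len(sets):
        raise ValueError("haplotype definitions contain duplicate allele sets")
    return defs


def load_bundled_reference() -> tuple:
    """Load the bundled SYNTHETIC MCM reference (library, definitions).

    A deterministic stand-in for the published M1-M7 allele compositions;
    see :func:`chimerseq.synthetic.synthetic_mcm_reference`, which
    generated these files.
    """
    from importlib.resources import files

    data = files("chimerseq") / "data"
    return (
        load_allele_library(str(data / "synthetic_mhc_library.fasta")),
        load_haplotype_definitions(str(data / "synthetic_mcm_haplotypes.tsv")),
    )


def write_haplotype_definitions(definitions: Iterable[HaplotypeDefinition], path):
    rows = [
        (d.haplotype_name, allele)
        for d in sorted(definitions, key=lambda x: x.haplotype_name)
        for allele in sorted(d.allele_names)
    ]
    pd.DataFrame(rows, columns=["haplotype_name", "allele_name"]).to_csv(
        path, sep="\t", index=False
    )
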
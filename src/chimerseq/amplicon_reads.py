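"""Amplicon FASTQ handling: locus assignment by flanking anchors and
per-SNP nucleotide tallies.

Reads come from short (~220 bp) PCR amplicons sequenced on 2x250
chemistry, so a read normally spans the whole amplicon. Instead of
coordinate mapping, a read is assigned to a locus by exact matches to the
``anchor_length`` bases immediately 5' and 3' of the SNP; the single base
between the anchors is the interrogated SNP base. Exactness keeps
assignment unambiguous: a sequencing error inside an anchor drops the
read (an origin-independent loss), never mis-assigns it.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# FASTQ quality char -> phred value, clamped at 0
_PHRED33 = bytes(max(0, b - 33) for b in range(256))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: id, bases, Phred qualities, mate number.

    ``qualities`` is any integer sequence (a ``bytes`` of raw Phred values
    is the compact choice); it must be as long as ``sequence``.
    """

    read_id: str
    sequence: str
    qualities: Sequence[int]
    mate: int = 1

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class AlleleCount:
    """Read tallies at one SNP position for one sample.

    ``counts['N']`` aggregates SNP bases failing the quality gate (and
    mate-disagreements); fractions derived from counts exclude N from the
    denominator (``effective_reads``).
    """

    locus_id: str
    sample_id: str
    counts: dict = field(default_factory=lambda: {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0})
    n_unassigned_reads: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def effective_reads(self) -> int:
        return self.total - self.counts["N"]

    def fraction(self, nt: str) -> float:
        eff = self.effective_reads
        return self.counts[nt] / eff if eff else float("nan")


class AnchorIndex:
    """Exact-anchor lookup for a panel of SNP loci.

    Each locus exposes the ``anchor_length`` bases flanking its SNP; a
    read (or its reverse complement) matches when it contains the 5'
    anchor, then exactly one base, then the 3' anchor. Panels in which
    two loci share an identical anchor pair are ambiguous by construction
    and rejected at load.
    """

    def __init__(self, panel, anchor_length: int = 12):
        if anchor_length < 8:
            raise ValueError("anchor_length must be >= 8")
        self.anchor_length = anchor_length
        self._fwd = []  # (anchor5, anchor3, locus_id)
        seen = {}
        for locus in panel:
            off, L = locus.snp_offset, anchor_length
            if off < L or len(locus.amplicon_seq) - off - 1 < L:
                raise ValueError(
                    f"locus {locus.locus_id}: amplicon too short to expose "
                    f"{L}-base anchors around offset {off}"
                )
            a5 = locus.amplicon_seq[off - L : off]
            a3 = locus.amplicon_seq[off + 1 : off + 1 + L]
            if (a5, a3) in seen:
                raise ValueError(
                    f"loci {seen[(a5, a3)]} and {locus.locus_id} share identical anchors"
                )
            seen[(a5, a3)] = locus.locus_id
            self._fwd.append((a5, a3, locus.locus_id))

    def assign(self, sequence: str) -> Optional[tuple]:
        """Assign a read sequence to a locus.

        Returns ``(locus_id, snp_position_in_read, is_reverse)`` for a
        unique match, ``None`` for zero or multiple matches.
        """
        hit = None
        L = self.anchor_length
        for orientation, seq in ((False, sequence), (True, revcomp(sequence))):
            for a5, a3, locus_id in self._fwd:
                i = seq.find(a5)
                while i != -1:
                    pos = i + L
                    if seq[pos + 1 : pos + 1 + L] == a3:
                        if hit is not None:
                            return None  # >= 2 matches: ambiguous
                        hit = (locus_id, pos, orientation)
                        break
                    i = seq.find(a5, i + 1)
        return hit

    def assign_read(self, read: ReadRecord) -> Optional[tuple]:
        """Return ``(locus_id, snp_base, snp_quality)`` or ``None``.

        The SNP base is reported on the amplicon's forward strand
        regardless of read orientation.
        """
        hit = self.assign(read.sequence)
        if hit is None:
            return None
        locus_id, pos, is_reverse = hit
        if is_reverse:
            base = read.sequence.translate(_COMPLEMENT)[len(read.sequence) - 1 - pos]
            qual = read.qualities[len(read.sequence) - 1 - pos]
        else:
            base = read.sequence[pos]
            qual = read.qualities[pos]
        return locus_id, base, qual


def assign_read(read: ReadRecord, panel, anchor_length: int = 12) -> Optional[tuple]:
    """Convenience wrapper building a throwaway :class:`AnchorIndex`."""
    return AnchorIndex(panel, anchor_length).assign_read(read)


def count_bases(
    reads: Iterable,
    panel,
    min_base_quality: int = 20,
    sample_id: str = "",
    anchor_length: int = 12,
) -> list:
    """Tally SNP-position nucleotides per locus for one sample.

    ``reads`` yields :class:`ReadRecord` items or ``(mate1, mate2)``
    tuples for synchronized paired input. A fragment whose two mates are
    both assigned to the same locus is counted once: mate 1's base when
    the mates agree, N when they disagree. Bases below
    ``min_base_quality`` count as N. Tallies are order- and
    strand-invariant.
    """
    index = AnchorIndex(panel, anchor_length)
    tallies = {a5a3[2]: {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0} for a5a3 in index._fwd}
    n_unassigned = 0

    def record(locus_id, base, qual):
        if qual < min_base_quality or base not in "ACGT":
            tallies[locus_id]["N"] += 1
        else:
            tallies[locus_id][base] += 1

    for item in reads:
        if isinstance(item, tuple):
            h1 = index.assign_read(item[0]) if item[0] is not None else None
            h2 = index.assign_read(item[1]) if item[1] is not None else None
            if h1 is None and h2 is None:
                n_unassigned += 1
            elif h1 is not None and h2 is not None and h1[0] == h2[0]:
                # overlapping mates: one fragment, one vote
                if h1[1] == h2[1]:
                    record(h1[0], h1[1], h1[2])
                else:
                    tallies[h1[0]]["N"] += 1
            else:
                for h in (h1, h2):
                    if h is not None:
                        record(*h)
        else:
            h = index.assign_read(item)
            if h is None:
                n_unassigned += 1
            else:
                record(*h)

    out = []
    for locus in sorted(panel, key=lambda l: l.locus_id):
        out.append(
            AlleleCount(
                locus_id=locus.locus_id,
                sample_id=sample_id,
                counts=tallies[locus.locus_id],
                n_unassigned_reads=n_unassigned,
            )
        )
    return out


# ---------------------------------------------------------------------------
# FASTQ IO

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path, mate: int = 1) -> Iterator[ReadRecord]:
    """Stream a (optionally gzipped) Phred+33 FASTQ file.

    Malformed records raise ``ValueError`` naming the offending read.
    """
    with _open_text(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            header = header.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise ValueError(f"malformed FASTQ record at {header!r} in {path}")
            if len(seq) != len(qual):
                raise ValueError(f"length mismatch in FASTQ record {header!r} in {path}")
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            yield ReadRecord(
                read_id=read_id,
                sequence=seq.upper(),
                qualities=qual.encode("ascii").translate(_PHRED33),
                mate=mate,
            )


def read_fastq_pairs(path1, path2) -> Iterator[tuple]:
    """Yield synchronized ``(mate1, mate2)`` tuples from a pair of FASTQs."""
    for r1, r2 in zip(read_fastq(path1, mate=1), read_fastq(path2, mate=2), strict=True):
        yield r1, r2


def write_fastq(reads: Iterable[ReadRecord], path):
    """Write Phred+33 FASTQ (gzipped when the path ends in .gz)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qualities)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def write_counts_tsv(counts: Iterable[AlleleCount], path):
    rows = [
        (c.sample_id, c.locus_id, c.counts["A"], c.counts["C"], c.counts["G"],
         c.counts["T"], c.counts["N"], c.total)
        for c in counts
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "locus_id", "A", "C", "G", "T", "N", "total"]
    ).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "locus_id": str})
    out = []
    for row in df.itertuples(index=False):
        counts = {nt: int(getattr(row, nt)) for nt in "ACGTN"}
        out.append(AlleleCount(locus_id=row.locus_id, sample_id=row.sample_id, counts=counts))
    return out
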
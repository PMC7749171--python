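"""Read-level processing for amplicon sequencing of edited embryos.

Three concerns live here:

* quality filtering of circular-consensus (CCS) long reads on number of
  polymerase passes, predicted consensus accuracy and read length;
* demultiplexing pooled reads to embryos via dual flanking barcodes; and
* overlap-merging of short paired-end reads used for off-target amplicon
  screens.

CCS reads are carried in FASTQ with the pass count and predicted accuracy
encoded as ``passes=<int>`` / ``rq=<float>`` key=value tokens in the header
comment, e.g. ``@embryo3/17 passes=9 rq=0.9984``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("crisprembryo")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CcsRead:
    """A circular-consensus read plus the metadata the quality filter uses.

    Attributes
    ----------
    read_id : str
        Unique read name.
    sequence : str
        Consensus base calls (A/C/G/T/N).
    qualities : list[int]
        Per-base Phred scores, same length as ``sequence``.
    passes : int
        Number of full polymerase passes over the insert (>= 1).
    predicted_accuracy : float
        Predicted consensus accuracy ("rq"), in [0, 1].
    """

    read_id: str
    sequence: str
    qualities: list[int]
    passes: int
    predicted_accuracy: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id}: sequence and qualities differ in length"
            )
        if self.passes < 1:
            raise ValueError(f"read {self.read_id}: passes must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "CcsRead":
        return replace(
            self,
            sequence=revcomp(self.sequence),
            qualities=self.qualities[::-1],
        )


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    barcode_fwd: str
    barcode_rev: str
    locus: str
    cas9_form: str  # "mRNA" | "protein"
    sex: str = "unknown"  # "male" | "female" | "unknown"


@dataclass
class BarcodeSheet:
    """Sample sheet mapping dual barcodes to embryos.

    Barcode pairs must be unique and ``cas9_form`` is restricted to the two
    reagent arms compared in the study (mRNA vs protein).
    """

    samples: list[SampleInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in barcode sheet")
        pairs = [(s.barcode_fwd, s.barcode_rev) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (fwd, rev) barcode pair in sheet")
        for s in self.samples:
            if s.cas9_form not in ("mRNA", "protein"):
                raise ValueError(f"invalid cas9_form {s.cas9_form!r}")

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def get(self, sample_id: str) -> SampleInfo:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame([vars(s) for s in self.samples]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BarcodeSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls([SampleInfo(**row) for row in df.to_dict("records")])


# ---------------------------------------------------------------------------
# FASTQ dialect IO
# ---------------------------------------------------------------------------

def _parse_tokens(description: str) -> dict[str, str]:
    out = {}
    for tok in description.split()[1:]:
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_fastq_ccs(path: str | Path) -> list[CcsRead]:
    """Read CCS reads from FASTQ with passes/rq in the header comment.

    Reads lacking the tokens default to ``passes=1, rq=0.0`` (and will be
    dropped by the filter at default thresholds).
    """
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        tok = _parse_tokens(rec.description)
        reads.append(
            CcsRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=list(rec.letter_annotations["phred_quality"]),
                passes=int(tok.get("passes", 1)),
                predicted_accuracy=float(tok.get("rq", 0.0)),
            )
        )
    return reads


def write_fastq_ccs(reads: Iterable[CcsRead], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(
            Seq(r.sequence),
            id=r.read_id,
            description=f"{r.read_id} passes={r.passes} rq={r.predicted_accuracy:.4f}",
        )
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


# ---------------------------------------------------------------------------
# CCS quality filter
# ---------------------------------------------------------------------------

def filter_ccs(
    reads: Sequence[CcsRead],
    min_passes: int = 3,
    min_accuracy: float = 0.99,
    max_length: int = 700,
) -> tuple[list[CcsRead], list[tuple[str, str]]]:
    """Filter CCS reads on passes, predicted accuracy and length.

    A read is kept iff ``passes >= min_passes`` and
    ``predicted_accuracy >= min_accuracy`` and ``len <= max_length``
    (all boundaries inclusive). The rejection log records ``(read_id,
    reason)`` with the first failing criterion in the order passes,
    accuracy, length.
    """
    if min_passes <= 0 or min_accuracy <= 0 or max_length <= 0:
        raise ValueError("filter thresholds must be positive")
    kept: list[CcsRead] = []
    rejected: list[tuple[str, str]] = []
    for r in reads:
        if r.passes < min_passes:
            rejected.append((r.read_id, "passes"))
        elif r.predicted_accuracy < min_accuracy:
            rejected.append((r.read_id, "accuracy"))
        elif len(r) > max_length:
            rejected.append((r.read_id, "length"))
        else:
            kept.append(r)
    logger.info("filter_ccs: kept %d / %d reads", len(kept), len(reads))
    return kept, rejected


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def demultiplex(
    reads: Sequence[CcsRead],
    sheet: BarcodeSheet,
    max_mismatch: int = 1,
) -> tuple[dict[str, list[CcsRead]], list[CcsRead]]:
    """Assign reads to samples by dual flanking barcodes.

    The expected read layout on the forward strand is::

        [barcode_fwd] [insert] [revcomp(barcode_rev)]

    Both orientations are tried; a read found in reverse orientation is
    reverse-complemented so that all assigned reads are on the reference
    strand. A read is assigned iff exactly one sample matches (each
    barcode within ``max_mismatch`` substitutions at its expected
    position); ambiguous or unmatched reads land in the unassigned bin.
    Barcodes are trimmed from assigned reads.
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    assigned: dict[str, list[CcsRead]] = {s.sample_id: [] for s in sheet}
    unassigned: list[CcsRead] = []

    # Precompute per-sample probe strings for both orientations.
    probes = []  # (sample_id, fwd_prefix, fwd_suffix, rev_prefix, rev_suffix)
    for s in sheet:
        probes.append(
            (
                s.sample_id,
                s.barcode_fwd,
                revcomp(s.barcode_rev),
                s.barcode_rev,
                revcomp(s.barcode_fwd),
            )
        )

    for read in reads:
        hits: list[tuple[str, bool]] = []  # (sample_id, is_reverse)
        for sample_id, fp, fs, rp, rs in probes:
            n5, n3 = len(fp), len(fs)
            if len(read) < n5 + n3:
                continue
            p, s_ = read.sequence[:n5], read.sequence[-n3:]
            if hamming(p, fp) <= max_mismatch and hamming(s_, fs) <= max_mismatch:
                hits.append((sample_id, False))
            if hamming(p, rp) <= max_mismatch and hamming(s_, rs) <= max_mismatch:
                hits.append((sample_id, True))
        if len(hits) != 1:
            unassigned.append(read)
            continue
        sample_id, is_reverse = hits[0]
        oriented = read.reverse_complement() if is_reverse else read
        info = sheet.get(sample_id)
        n5 = len(info.barcode_fwd)
        n3 = len(info.barcode_rev)
        trimmed = replace(
            oriented,
            sequence=oriented.sequence[n5 : len(oriented) - n3],
            qualities=oriented.qualities[n5 : len(oriented) - n3],
        )
        assigned[sample_id].append(trimmed)
    n_assigned = sum(len(v) for v in assigned.values())
    logger.info(
        "demultiplex: %d assigned, %d unassigned", n_assigned, len(unassigned)
    )
    return assigned, unassigned


# ---------------------------------------------------------------------------
# Paired-end overlap merging
# ---------------------------------------------------------------------------

def merge_pairs(
    pair_r1: CcsRead,
    pair_r2: CcsRead,
    min_overlap: int = 20,
    max_overlap_mismatch_rate: float = 0.1,
) -> CcsRead | None:
    """Merge a paired-end read pair into one high-quality single-end read.

    ``pair_r2`` is reverse-complemented, then the maximal-scoring 3'
    overlap (suffix of R1 against prefix of the flipped R2) of length
    >= ``min_overlap`` with mismatch rate <= the threshold is taken.
    Disagreeing overlap positions take the higher-quality base call.
    Returns None when no acceptable overlap exists.
    """
    if len(pair_r1) == 0 or len(pair_r2) == 0:
        raise ValueError("cannot merge empty reads")
    r2 = pair_r2.reverse_complement()
    s1, q1 = pair_r1.sequence, pair_r1.qualities
    s2, q2 = r2.sequence, r2.qualities
    best: tuple[int, int] | None = None  # (score, overlap_len)
    for ov in range(min(len(s1), len(s2)), min_overlap - 1, -1):
        a = s1[len(s1) - ov :]
        b = s2[:ov]
        mism = hamming(a, b)
        if mism / ov > max_overlap_mismatch_rate:
            continue
        score = ov - 2 * mism
        if best is None or score > best[0]:
            best = (score, ov)
    if best is None:
        logger.debug("merge_pairs: no overlap for %s", pair_r1.read_id)
        return None
    ov = best[1]
    off = len(s1) - ov
    seq = list(s1[:off])
    qual = list(q1[:off])
    for i in range(ov):
        b1, b2 = s1[off + i], s2[i]
        ql, qr = q1[off + i], q2[i]
        if b1 == b2:
            seq.append(b1)
            qual.append(max(ql, qr))
        elif ql >= qr:
            seq.append(b1)
            qual.append(ql)
        else:
            seq.append(b2)
            qual.append(qr)
    seq.extend(s2[ov:])
    qual.extend(q2[ov:])
    return CcsRead(
        read_id=pair_r1.read_id,
        sequence="".join(seq),
        qualities=qual,
        passes=max(pair_r1.passes, pair_r2.passes),
        predicted_accuracy=max(
            pair_r1.predicted_accuracy, pair_r2.predicted_accuracy
        ),
    )
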
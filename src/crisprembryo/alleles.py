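"""Allele calling from amplicon reads.

Each read is aligned to its reference amplicon with an affine-gap
semi-global alignment (reference end gaps free, read fully aligned),
indels intersecting a window around the predicted Cas9 cut site are
collected into a canonical allele signature, and signatures are tallied
into a per-embryo allele table. Alleles are indel classes: substitutions
never define alleles, and indels outside the cut-site window are treated
as sequencing error or polymorphism.

Scoring defaults are match=+2, mismatch=-4, gap_open=-6 (first gap
base), gap_extend=-1 (each further base). Ties are broken by preferring
diagonal moves, then deletions over insertions; indels are subsequently
left-aligned so that signatures are canonical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .reads import CcsRead

MATCH, MISMATCH, INSERTION, DELETION = "match", "mismatch", "insertion", "deletion"

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i
_VALID = set("ACGTNacgtn")


def encode_dna(seq: str) -> np.ndarray:
    """Encode DNA to uint8 codes (A/C/G/T -> 0..3, N -> 4)."""
    if not set(seq) <= _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"non-ACGTN characters in sequence: {bad}")
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """A semi-global read-to-reference alignment.

    ``operations`` is a CIGAR-like run-length list of
    ``(op, length, reference_position)`` with op in {match, mismatch,
    insertion, deletion}; reference positions are 0-based and strictly
    increasing. ``ref_start`` is the first reference base covered.
    """

    read_id: str
    operations: list[tuple[str, int, int]]
    score: float
    ref_start: int
    ref_end: int


@dataclass(frozen=True)
class AlleleSignature:
    """Canonical indel haplotype near the cut site.

    ``indels`` is an ordered tuple of (kind, size, reference_start);
    the label is "WT" iff the tuple is empty, else e.g. "D4@197,I1@201".
    """

    indels: tuple[tuple[str, int, int], ...]

    @property
    def label(self) -> str:
        if not self.indels:
            return "WT"
        return ",".join(
            f"{'D' if k == DELETION else 'I'}{size}@{start}"
            for k, size, start in self.indels
        )

    @property
    def is_wt(self) -> bool:
        return not self.indels

    @property
    def net_size_change(self) -> int:
        return sum(
            size if k == INSERTION else -size for k, size, _ in self.indels
        )

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.label


@dataclass
class AlleleRow:
    signature: AlleleSignature
    read_count: int
    fraction: float


@dataclass
class AlleleTable:
    """Per-embryo tally of distinct allele signatures."""

    embryo_id: str
    locus: str
    total_reads: int
    rows: list[AlleleRow] = field(default_factory=list)
    qc_pass: bool = True

    @property
    def n_alleles(self) -> int:
        return len(self.rows)

    @property
    def wt_fraction(self) -> float:
        for row in self.rows:
            if row.signature.is_wt:
                return row.fraction
        return 0.0

    @property
    def labels(self) -> list[str]:
        return [r.signature.label for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "embryo_id": self.embryo_id,
                "locus": self.locus,
                "allele": [r.signature.label for r in self.rows],
                "count": [r.read_count for r in self.rows],
                "fraction": [r.fraction for r in self.rows],
            }
        )


# ---------------------------------------------------------------------------
# Affine-gap semi-global alignment (Gotoh DP, numba-compiled)
# ---------------------------------------------------------------------------

_NEG = np.float32(-1e30)


@njit(cache=True)
def _gotoh_fill(read, ref, match, mismatch, gap_open, gap_extend, band):
    """Fill Gotoh matrices. States: 0=M (diagonal), 1=X (gap in reference,
    consumes read base = insertion), 2=Y (gap in read, consumes reference
    base = deletion). Reference end gaps are free; the read is aligned
    end to end. ``band`` restricts |j - i - shift| <= band (band < 0 =>
    full matrix)."""
    m, n = len(read), len(ref)
    M = np.full((m + 1, n + 1), _NEG, dtype=np.float32)
    X = np.full((m + 1, n + 1), _NEG, dtype=np.float32)
    Y = np.full((m + 1, n + 1), _NEG, dtype=np.float32)
    # free reference prefix: enter anywhere along row 0
    for j in range(n + 1):
        M[0, j] = 0.0
    # read prefix gaps are penalized insertions
    for i in range(1, m + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    shift = (n - m) // 2
    for i in range(1, m + 1):
        if band >= 0:
            jlo = max(1, i + min(0, shift) - band)
            jhi = min(n, i + max(0, shift) + band)
        else:
            jlo, jhi = 1, n
        for j in range(jlo, jhi + 1):
            s = match if read[i - 1] == ref[j - 1] and read[i - 1] != 4 else mismatch
            best = M[i - 1, j - 1]
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
            if best > _NEG / 2:
                M[i, j] = best + s
            # X: gap in reference (insertion in read), from (i-1, j)
            bx = M[i - 1, j] + gap_open
            if X[i - 1, j] + gap_extend > bx:
                bx = X[i - 1, j] + gap_extend
            if Y[i - 1, j] + gap_open > bx:
                bx = Y[i - 1, j] + gap_open
            if bx > _NEG / 2:
                X[i, j] = bx
            # Y: gap in read (deletion of reference), from (i, j-1)
            by = M[i, j - 1] + gap_open
            if Y[i, j - 1] + gap_extend > by:
                by = Y[i, j - 1] + gap_extend
            if X[i, j - 1] + gap_open > by:
                by = X[i, j - 1] + gap_open
            if by > _NEG / 2:
                Y[i, j] = by
    return M, X, Y


@njit(cache=True)
def _gotoh_traceback(M, X, Y, read, ref, match, mismatch, gap_open, gap_extend):
    """Trace back from the best cell in the last row. Returns (score,
    end_j, per-column op codes reversed) with codes 0=match, 1=mismatch,
    2=insertion, 3=deletion. Tie-breaking prefers M, then Y (deletion),
    then X (insertion); the leftmost end column among score ties."""
    m = M.shape[0] - 1
    n = M.shape[1] - 1
    best = _NEG
    bj = n
    bstate = 0
    for j in range(n + 1):
        for st in range(3):
            v = M[m, j] if st == 0 else (X[m, j] if st == 1 else Y[m, j])
            if v > best + 1e-6:
                best = v
                bj = j
                bstate = st
    ops = np.empty(2 * (m + n) + 4, dtype=np.int8)
    k = 0
    i, j, st = m, bj, bstate
    eps = np.float32(1e-4)
    while i > 0 or (st == 2 and j > 0):
        if st == 0:
            s = match if read[i - 1] == ref[j - 1] and read[i - 1] != 4 else mismatch
            ops[k] = 0 if s == match else 1
            k += 1
            target = M[i, j] - s
            if i == 1:
                # row 0 is all zeros (free prefix): terminate
                i, j = 0, j - 1
                break
            if abs(M[i - 1, j - 1] - target) < eps:
                st = 0
            elif abs(Y[i - 1, j - 1] - target) < eps:
                st = 2
            else:
                st = 1
            i -= 1
            j -= 1
        elif st == 1:  # insertion: consumes read base
            ops[k] = 2
            k += 1
            if abs(M[i - 1, j] + gap_open - X[i, j]) < eps:
                st = 0
            elif abs(Y[i - 1, j] + gap_open - X[i, j]) < eps:
                st = 2
            else:
                st = 1
            i -= 1
        else:  # st == 2, deletion: consumes reference base
            ops[k] = 3
            k += 1
            if abs(M[i, j - 1] + gap_open - Y[i, j]) < eps:
                st = 0
            elif abs(Y[i, j - 1] + gap_extend - Y[i, j]) < eps:
                st = 2
            else:
                st = 1
            j -= 1
    return best, bj, ops[:k]


def align_semi_global(
    read: str,
    reference: str,
    match: float = 2.0,
    mismatch: float = -4.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
    band: int | None = None,
    read_id: str = "read",
) -> Alignment:
    """Optimal affine-gap semi-global alignment of a read to a reference.

    Reference overhangs (prefix/suffix not covered by the read) are
    unpenalized; the read itself is aligned end to end. The first base
    of a gap costs ``gap_open`` and each further base ``gap_extend``.
    ``band`` optionally restricts the DP to a diagonal band (must be
    wide enough to contain the true indels; None = full matrix).
    Deterministic: ties prefer diagonal moves, then deletions over
    insertions; indels are left-aligned afterwards.
    """
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    r = encode_dna(read)
    t = encode_dna(reference)
    bw = -1 if band is None else int(band)
    M, X, Y = _gotoh_fill(
        r, t, np.float32(match), np.float32(mismatch),
        np.float32(gap_open), np.float32(gap_extend), bw,
    )
    score, end_j, rev_ops = _gotoh_traceback(
        M, X, Y, r, t, np.float32(match), np.float32(mismatch),
        np.float32(gap_open), np.float32(gap_extend),
    )
    codes = rev_ops[::-1]
    # run-length encode with reference coordinates
    n_read_consumed = int(np.sum(codes != 3))
    n_ref_consumed = int(np.sum(codes != 2))
    ref_start = end_j - n_ref_consumed
    ops: list[tuple[str, int, int]] = []
    names = (MATCH, MISMATCH, INSERTION, DELETION)
    pos = ref_start
    for c in codes:
        name = names[c]
        if ops and ops[-1][0] == name and c != 2:
            ops[-1] = (name, ops[-1][1] + 1, ops[-1][2])
        elif ops and ops[-1][0] == name and c == 2:
            ops[-1] = (name, ops[-1][1] + 1, ops[-1][2])
        else:
            ops.append((name, 1, pos))
        if c != 2:
            pos += 1
    assert n_read_consumed == len(read)
    aln = Alignment(
        read_id=read_id,
        operations=ops,
        score=float(score),
        ref_start=ref_start,
        ref_end=end_j,
    )
    _left_align_indels(aln, read, reference)
    return aln


def _left_align_indels(aln: Alignment, read: str, reference: str) -> None:
    """Shift each indel to its leftmost equivalent placement (VCF-style
    normalization) so that identical alleles get identical signatures
    regardless of where the DP happened to open the gap."""
    ops = aln.operations
    read_pos = 0
    read_offsets = []
    for op, length, _ in ops:
        read_offsets.append(read_pos)
        if op != DELETION:
            read_pos += length
    for idx, (op, length, start) in enumerate(ops):
        if op == DELETION:
            a = start
            while a > 0 and reference[a - 1] == reference[a + length - 1]:
                a -= 1
            if a != start:
                ops[idx] = (op, length, a)
        elif op == INSERTION:
            a = start
            rp = read_offsets[idx]
            ins = read[rp : rp + length]
            while a > 0 and ins and reference[a - 1] == ins[-1]:
                ins = reference[a - 1] + ins[:-1]
                a -= 1
            if a != start:
                ops[idx] = (op, length, a)


def alignment_to_cigar(aln: Alignment) -> str:
    """Compact CIGAR string (M for match+mismatch, I, D) for SAM export."""
    sym = {MATCH: "M", MISMATCH: "M", INSERTION: "I", DELETION: "D"}
    out = []
    for op, length, _ in aln.operations:
        if out and out[-1][1] == sym[op]:
            out[-1] = (out[-1][0] + length, sym[op])
        else:
            out.append((length, sym[op]))
    return "".join(f"{n}{s}" for n, s in out)


# ---------------------------------------------------------------------------
# Signature extraction and allele tally
# ---------------------------------------------------------------------------

def extract_indel_signature(
    aln: Alignment, cut_site: int, window: int = 10
) -> AlleleSignature:
    """Collect indels whose reference footprint intersects
    ``[cut_site - window, cut_site + window)``.

    Deletions intersect via their reference interval; an insertion is a
    point event at its reference position. Indels outside the window are
    ignored (sequencing error or unrelated polymorphism); an empty
    collection is the wild-type signature.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    lo, hi = cut_site - window, cut_site + window
    found = []
    for op, length, start in aln.operations:
        if op == DELETION:
            if start < hi and start + length > lo:
                found.append((op, length, start))
        elif op == INSERTION:
            if lo <= start < hi:
                found.append((op, length, start))
    found.sort(key=lambda t: (t[2], t[0], t[1]))
    return AlleleSignature(indels=tuple(found))


def tally_alleles(
    signatures: Sequence[AlleleSignature],
    min_reads_per_allele: int = 2,
    min_fraction_per_allele: float = 0.01,
    embryo_id: str = "",
    locus: str = "",
) -> AlleleTable:
    """Group identical signatures and drop low-support alleles.

    An allele is kept iff its read count >= ``min_reads_per_allele`` AND
    its fraction of all input reads >= ``min_fraction_per_allele``.
    Reads of dropped alleles are removed from the total and fractions
    are renormalized over kept reads. If everything is filtered out the
    table is returned with zero rows and ``qc_pass=False``.
    """
    if not signatures:
        raise ValueError("tally_alleles requires at least one signature")
    counts: dict[str, tuple[AlleleSignature, int]] = {}
    for sig in signatures:
        key = sig.label
        if key in counts:
            counts[key] = (counts[key][0], counts[key][1] + 1)
        else:
            counts[key] = (sig, 1)
    n_input = len(signatures)
    kept = [
        (sig, c)
        for sig, c in counts.values()
        if c >= min_reads_per_allele and c / n_input >= min_fraction_per_allele
    ]
    total = sum(c for _, c in kept)
    if not kept:
        return AlleleTable(
            embryo_id=embryo_id, locus=locus, total_reads=0, rows=[], qc_pass=False
        )
    kept.sort(key=lambda t: (-t[1], t[0].label))
    rows = [
        AlleleRow(signature=sig, read_count=c, fraction=c / total)
        for sig, c in kept
    ]
    return AlleleTable(
        embryo_id=embryo_id, locus=locus, total_reads=total, rows=rows,
        qc_pass=True,
    )


def call_alleles(
    reads: Iterable[CcsRead],
    reference: str,
    cut_site: int,
    window: int = 10,
    min_reads_per_allele: int = 2,
    min_fraction_per_allele: float = 0.01,
    embryo_id: str = "",
    locus: str = "",
    band: int | None = None,
    adaptive_band: int = 32,
) -> AlleleTable:
    """Full per-embryo allele calling: align every read, extract cut-site
    signatures, tally. ``adaptive_band`` sets the DP band to
    ``|len(read) - len(reference)| + adaptive_band`` when ``band`` is
    None, which is ample for NHEJ-scale indels; pass
    ``adaptive_band=None`` to force the full matrix."""
    sigs = []
    for r in reads:
        if band is None and adaptive_band is not None:
            bw = abs(len(r.sequence) - len(reference)) + adaptive_band
        else:
            bw = band
        aln = align_semi_global(
            r.sequence, reference, band=bw, read_id=r.read_id
        )
        sigs.append(extract_indel_signature(aln, cut_site, window))
    if not sigs:
        return AlleleTable(
            embryo_id=embryo_id, locus=locus, total_reads=0, rows=[],
            qc_pass=False,
        )
    return tally_alleles(
        sigs,
        min_reads_per_allele=min_reads_per_allele,
        min_fraction_per_allele=min_fraction_per_allele,
        embryo_id=embryo_id,
        locus=locus,
    )


def tables_to_long_frame(tables: Iterable[AlleleTable]) -> pd.DataFrame:
    """Combined long-format allele table (embryo, locus, allele, count,
    fraction) across embryos."""
    frames = [t.to_frame() for t in tables]
    if not frames:
        return pd.DataFrame(
            columns=["embryo_id", "locus", "allele", "count", "fraction"]
        )
    return pd.concat(frames, ignore_index=True)


def write_allele_table(table: AlleleTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
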
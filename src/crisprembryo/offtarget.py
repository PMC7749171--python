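"""Guide-RNA candidate enumeration and off-target site analysis.

A guide is a 20-nt protospacer followed by an NGG PAM. Off-target sites
are genomic 20-mers adjacent to an NGG PAM on either strand with at most
``max_mm`` protospacer mismatches (bulges are not considered). Guide
acceptance follows the design rule used for embryo editing: every
off-target site must carry at least ``min_mm`` mismatches (default 3)
and, optionally, at least one mismatch inside the seed region — the
PAM-proximal protospacer positions 8–11 bp upstream of the PAM, where
mismatches most strongly abolish Cas9 cleavage.

Protospacer positions are indexed 0-based from the PAM-distal end, so
position 19 is adjacent to the PAM and the default seed set is
{9, 10, 11, 12}. The predicted blunt cut falls 3 bp 5' of the PAM
(between protospacer positions 16 and 17). All genomic coordinates are
0-based, half-open, BED-compatible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alleles import align_semi_global, encode_dna, extract_indel_signature, DELETION, INSERTION
from .reads import CcsRead, revcomp

PROTOSPACER_LEN = 20
PAM_LEN = 3
SITE_LEN = PROTOSPACER_LEN + PAM_LEN
# Cut between protospacer positions 16|17 (0-based from the distal end),
# i.e. 3 bp 5' of the PAM: offset of the cut coordinate from the
# protospacer start on the guide strand.
CUT_OFFSET = 17


def seed_positions(upstream_start: int = 8, upstream_end: int = 11) -> frozenset[int]:
    """Protospacer indices for the seed region given its span in bp
    upstream of the PAM (1-based distances, inclusive). The default
    8–11 bp window maps to 0-based indices {9, 10, 11, 12}."""
    return frozenset(
        PROTOSPACER_LEN - d for d in range(upstream_start, upstream_end + 1)
    )


DEFAULT_SEED = seed_positions()


@dataclass(frozen=True)
class GuideRNA:
    """A 20-nt protospacer with its PAM and genomic placement."""

    protospacer: str
    pam: str
    chrom: str = ""
    start: int = 0  # 0-based genomic start of the protospacer block
    strand: str = "+"
    seed_region: frozenset[int] = field(default=DEFAULT_SEED)

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def sequence(self) -> str:
        return self.protospacer + self.pam


@dataclass
class OffTargetSite:
    """A genomic locus matching a guide within the mismatch budget."""

    chrom: str
    start: int  # 0-based start of the 23-nt protospacer+PAM block
    strand: str
    site_sequence: str  # protospacer+PAM in guide orientation
    mismatch_positions: frozenset[int]
    n_mismatches: int
    n_seed_mismatches: int
    predicted_cut: int  # 0-based genomic coordinate of the blunt cut

    @property
    def end(self) -> int:
        return self.start + SITE_LEN

    def mismatch_string(self) -> str:
        """Site sequence with mismatched protospacer bases lowercased
        (bulge-free Cas-OFFinder-style display)."""
        out = []
        for i, b in enumerate(self.site_sequence[:PROTOSPACER_LEN]):
            out.append(b.lower() if i in self.mismatch_positions else b)
        return "".join(out) + self.site_sequence[PROTOSPACER_LEN:]


@dataclass
class IndelReportRow:
    kind: str
    size: int
    offset_from_predicted_cut: int
    supporting_reads: int
    fraction_of_reads: float
    known_variant: bool = False


@dataclass
class OffTargetReport:
    site_name: str
    total_reads: int
    rows: list[IndelReportRow] = field(default_factory=list)
    known_variant_overlaps: list[tuple[str, int, int]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Candidate guide scan
# ---------------------------------------------------------------------------

def scan_candidate_guides(
    sequence: str,
    region: tuple[int, int] | None = None,
    chrom: str = "",
    seed_region: frozenset[int] = DEFAULT_SEED,
) -> list[GuideRNA]:
    """Every 20-mer followed by an NGG PAM, on both strands, whose full
    23-nt footprint lies within ``region`` (default: the whole sequence)."""
    if region is None:
        region = (0, len(sequence))
    lo, hi = region
    if lo < 0 or hi > len(sequence) or lo > hi:
        raise ValueError(f"region {region} outside sequence of length {len(sequence)}")
    sequence = sequence.upper()
    guides = []
    for i in range(lo, hi - SITE_LEN + 1):
        block = sequence[i : i + SITE_LEN]
        if block[PROTOSPACER_LEN + 1 : PROTOSPACER_LEN + 3] == "GG":
            guides.append(
                GuideRNA(
                    protospacer=block[:PROTOSPACER_LEN],
                    pam=block[PROTOSPACER_LEN:],
                    chrom=chrom,
                    start=i,
                    strand="+",
                    seed_region=seed_region,
                )
            )
        if block[0:2] == "CC":
            rc = revcomp(block)
            guides.append(
                GuideRNA(
                    protospacer=rc[:PROTOSPACER_LEN],
                    pam=rc[PROTOSPACER_LEN:],
                    chrom=chrom,
                    start=i + PAM_LEN,
                    strand="-",
                    seed_region=seed_region,
                )
            )
    return guides


# ---------------------------------------------------------------------------
# Off-target enumeration
# ---------------------------------------------------------------------------

def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, Mapping):
        return {k: str(v).upper() for k, v in genome.items()}
    is_path = isinstance(genome, Path)
    if isinstance(genome, str) and len(genome) < 4096 and "\n" not in genome:
        try:
            is_path = Path(genome).exists()
        except OSError:
            is_path = False
    if is_path:
        return {
            rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(genome), "fasta")
        }
    if isinstance(genome, str):
        return {"seq": genome.upper()}
    raise TypeError("genome must be a dict, FASTA path, or sequence string")


def _scan_strand(
    arr: np.ndarray, pattern: np.ndarray, pam_g_at: tuple[int, int], max_mm: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized PAM-anchored scan on one strand encoding.

    ``arr`` is the encoded contig; ``pattern`` the encoded 20-mer to
    compare at each window start; ``pam_g_at`` the two window offsets
    that must equal G (or C for the minus-strand encoding). Returns
    (window starts, mismatch counts) for windows within budget.
    """
    L = len(arr)
    if L < SITE_LEN:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    starts = np.arange(L - SITE_LEN + 1)
    (o1, code1), (o2, code2) = pam_g_at
    cand = starts[(arr[starts + o1] == code1) & (arr[starts + o2] == code2)]
    if len(cand) == 0:
        return cand, np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(arr, SITE_LEN)[cand]
    proto = win[:, : PROTOSPACER_LEN] if pam_g_at[0][0] >= PROTOSPACER_LEN else win[:, PAM_LEN:]
    mism = (proto != pattern).sum(axis=1)
    keep = mism <= max_mm
    return cand[keep], mism[keep]


def enumerate_offtargets(
    guide: GuideRNA,
    genome,
    max_mm: int = 4,
) -> list[OffTargetSite]:
    """All genomic sites on both strands with an NGG PAM and at most
    ``max_mm`` protospacer mismatches (no bulges). N in the genome
    counts as a mismatch; the guide's own locus appears as the
    0-mismatch entry when present in the genome.
    """
    if not 0 <= max_mm <= 6:
        raise ValueError("max_mm must be in 0..6")
    contigs = _load_genome(genome)
    if not contigs or all(len(s) == 0 for s in contigs.values()):
        raise ValueError("genome is empty")
    G = np.uint8(2)
    C = np.uint8(1)
    proto_fwd = encode_dna(guide.protospacer)
    proto_rev = encode_dna(revcomp(guide.protospacer))
    sites: list[OffTargetSite] = []
    for chrom, seq in contigs.items():
        arr = encode_dna(seq)
        # + strand: [proto 0..19][N G G]
        starts, _ = _scan_strand(
            arr, proto_fwd,
            ((PROTOSPACER_LEN + 1, G), (PROTOSPACER_LEN + 2, G)), max_mm,
        )
        for s in starts:
            s = int(s)
            block = seq[s : s + SITE_LEN]
            mm = frozenset(
                i for i in range(PROTOSPACER_LEN) if block[i] != guide.protospacer[i]
            )
            sites.append(
                OffTargetSite(
                    chrom=chrom, start=s, strand="+", site_sequence=block,
                    mismatch_positions=mm, n_mismatches=len(mm),
                    n_seed_mismatches=len(mm & guide.seed_region),
                    predicted_cut=s + CUT_OFFSET,
                )
            )
        # - strand: genome block is [C C N][revcomp(proto)]
        starts, _ = _scan_strand(
            arr, proto_rev, ((0, C), (1, C)), max_mm
        )
        for s in starts:
            s = int(s)
            block = seq[s : s + SITE_LEN]
            oriented = revcomp(block)  # protospacer+PAM in guide orientation
            mm = frozenset(
                i for i in range(PROTOSPACER_LEN)
                if oriented[i] != guide.protospacer[i]
            )
            sites.append(
                OffTargetSite(
                    chrom=chrom, start=s, strand="-", site_sequence=oriented,
                    mismatch_positions=mm, n_mismatches=len(mm),
                    n_seed_mismatches=len(mm & guide.seed_region),
                    predicted_cut=s + SITE_LEN - CUT_OFFSET,
                )
            )
    sites.sort(key=lambda x: (x.chrom, x.start, x.strand))
    return sites


def guide_passes_filter(
    guide: GuideRNA,
    sites: Sequence[OffTargetSite],
    min_mm: int = 3,
    require_seed_mm: bool = True,
) -> tuple[bool, list[str]]:
    """Apply the guide acceptance rule to a set of off-target sites
    (the on-target 0-mismatch entry must already be excluded).

    Passes iff every site carries >= ``min_mm`` mismatches and, when
    ``require_seed_mm``, at least one of them in the seed region.
    Returns (passed, reasons) with one reason per failing site.
    """
    reasons = []
    for site in sites:
        if site.n_mismatches < min_mm:
            reasons.append(
                f"{site.chrom}:{site.start}{site.strand} has only "
                f"{site.n_mismatches} mismatches (< {min_mm})"
            )
        elif require_seed_mm and site.n_seed_mismatches < 1:
            reasons.append(
                f"{site.chrom}:{site.start}{site.strand} has no seed-region mismatch"
            )
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# Off-target amplicon scan
# ---------------------------------------------------------------------------

def scan_offtarget_amplicon(
    reads: Iterable[CcsRead],
    site_reference: str,
    predicted_cut: int,
    report_window: int = 50,
    known_variants: Sequence[tuple[str, int, int]] = (),
    site_name: str = "offtarget",
    band: int | None = None,
) -> OffTargetReport:
    """Tabulate indels near a predicted off-target cut site.

    Reads (already merged/filtered) are aligned to the site amplicon;
    indels whose reference footprint falls within ``predicted_cut ±
    report_window`` are grouped by (kind, size, offset from the cut) and
    reported with supporting read counts and fractions of all reads.
    ``known_variants`` rows are (kind, size, reference_start); an
    observed indel overlapping one is flagged as an annotated
    polymorphism rather than a putative off-target edit.
    """
    reads = list(reads)
    counts: dict[tuple[str, int, int], int] = {}
    total = 0
    for r in reads:
        total += 1
        aln = align_semi_global(
            r.sequence, site_reference, band=band, read_id=r.read_id
        )
        sig = extract_indel_signature(aln, predicted_cut, report_window)
        for kind, size, start in sig.indels:
            key = (kind, size, start - predicted_cut)
            counts[key] = counts.get(key, 0) + 1
    rows = []
    overlaps: list[tuple[str, int, int]] = []
    for (kind, size, offset), n in sorted(
        counts.items(), key=lambda kv: -kv[1]
    ):
        start = predicted_cut + offset
        end = start + (size if kind == DELETION else 1)
        known = False
        for vk, vsize, vstart in known_variants:
            vend = vstart + (vsize if vk == DELETION else 1)
            if start < vend and end > vstart:
                known = True
                if (vk, vsize, vstart) not in overlaps:
                    overlaps.append((vk, vsize, vstart))
        rows.append(
            IndelReportRow(
                kind=kind, size=size, offset_from_predicted_cut=offset,
                supporting_reads=n,
                fraction_of_reads=n / total if total else 0.0,
                known_variant=known,
            )
        )
    return OffTargetReport(
        site_name=site_name, total_reads=total, rows=rows,
        known_variant_overlaps=overlaps,
    )


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def sites_to_bed(sites: Iterable[OffTargetSite], path: str | Path) -> None:
    """BED6: chrom, start, end, mismatch string, n_mismatches, strand."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.mismatch_string()}\t"
                f"{s.n_mismatches}\t{s.strand}\n"
            )


def sites_to_frame(sites: Iterable[OffTargetSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "start": [s.start for s in sites],
            "end": [s.end for s in sites],
            "strand": [s.strand for s in sites],
            "site": [s.mismatch_string() for s in sites],
            "n_mismatches": [s.n_mismatches for s in sites],
            "n_seed_mismatches": [s.n_seed_mismatches for s in sites],
            "predicted_cut": [s.predicted_cut for s in sites],
        }
    )
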
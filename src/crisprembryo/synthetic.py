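"""Synthetic data generation for the embryo-editing pipeline.

Everything downstream — CCS filtering, demultiplexing, allele calling,
mosaicism classification, off-target screening — is testable against
data produced here: reference amplicons carrying an NGG-PAM guide,
embryos with known allele compositions (wild type plus NHEJ indel
alleles concentrated at the Cas9 cut site), barcoded CCS-style FASTQ
reads with pass-count and predicted-accuracy metadata under a
substitution/indel error model, and synthetic genomes with planted
off-target sites.

The generator emulates post-consensus reads: the residual error model
(substitutions 0.3%/bp, indel errors 0.2%/bp by default) stands in for
what is left after circular-consensus calling, not raw polymerase error.
Per-read predicted accuracy is Beta-distributed (mean 0.995) and pass
counts are 1 + Poisson(7), so a realistic minority of reads fails the
3-pass / 99%-accuracy filter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .offtarget import CUT_OFFSET, GuideRNA, PROTOSPACER_LEN, SITE_LEN
from .reads import BarcodeSheet, CcsRead, SampleInfo, revcomp

BASES = np.array(list("ACGT"))

WT = "WT"  # sentinel allele spec for the unedited allele


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AmpliconTarget:
    """A reference amplicon with one guide placed inside it."""

    name: str
    sequence: str
    guide: GuideRNA
    cut_site: int  # 0-based: the blunt cut falls between cut_site-1 and cut_site

    def __post_init__(self) -> None:
        if not 0 <= self.cut_site < len(self.sequence):
            raise ValueError("cut_site outside amplicon")
        block = self.guide.sequence
        if block not in self.sequence and revcomp(block) not in self.sequence:
            raise ValueError("guide+PAM is not a substring of the amplicon")


@dataclass(frozen=True)
class IndelSpec:
    """An NHEJ indel allele relative to the predicted cut site."""

    kind: str  # "deletion" | "insertion"
    size: int
    offset: int = 0  # signed bp relative to cut_site
    inserted_bases: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"invalid indel kind {self.kind!r}")
        if self.size < 1:
            raise ValueError("indel size must be >= 1")
        if self.kind == "insertion" and len(self.inserted_bases) != self.size:
            raise ValueError("inserted_bases length must equal size")


@dataclass
class EmbryoTruth:
    """Ground truth for one simulated embryo."""

    embryo_id: str
    barcode: tuple[str, str]  # (fwd, rev)
    locus: str
    sex: str  # "male" | "female" | "unknown"
    alleles: list[tuple[str, object, float]]  # (label, IndelSpec or WT, fraction)
    true_class: str  # non_edited | edited_non_mosaic | heterozygous | mosaic

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError("embryo must carry at least one allele")
        labels = [a[0] for a in self.alleles]
        if len(set(labels)) != len(labels):
            raise ValueError("allele labels must be unique")
        tot = sum(a[2] for a in self.alleles)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"allele fractions sum to {tot}, not 1")


@dataclass
class ErrorModel:
    """Residual per-base sequencing error plus read metadata distributions."""

    substitution_rate: float = 0.003
    indel_error_rate: float = 0.002
    accuracy_beta: tuple[float, float] = (597.0, 3.0)  # mean 0.995
    passes_lambda: float = 7.0  # passes = 1 + Poisson(lambda)
    read_length_jitter: int = 0  # max bases randomly trimmed from the 3' end

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.indel_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must be in [0, 1]")

    @classmethod
    def error_free(cls) -> "ErrorModel":
        return cls(substitution_rate=0.0, indel_error_rate=0.0,
                   accuracy_beta=(1e6, 1.0), passes_lambda=7.0)


# ---------------------------------------------------------------------------
# Amplicons and alleles
# ---------------------------------------------------------------------------

def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def make_amplicon(
    seed: int,
    length: int = 400,
    guide_offset: int = 180,
    name: str | None = None,
    forbid_homopolymer: int | None = None,
    window: int = 10,
) -> AmpliconTarget:
    """Random amplicon with an NGG-PAM guide at ``guide_offset``.

    Positions ``guide_offset .. guide_offset+19`` are the protospacer and
    the following three bases end with GG. With ``forbid_homopolymer=k``
    the sequence is re-drawn until the cut-site window (± ``window`` bp)
    contains no homopolymer run of length >= k, emulating guide-design
    practice of avoiding low-complexity target contexts. Deterministic
    for a fixed seed.
    """
    if length < guide_offset + SITE_LEN:
        raise ValueError("amplicon too short for guide at this offset")
    if length > 700:
        raise ValueError("amplicon longer than the 700 bp CCS length cap")
    rng = np.random.default_rng(seed)
    cut = guide_offset + CUT_OFFSET
    for _ in range(1000):
        seq = list(_random_dna(rng, length))
        seq[guide_offset + PROTOSPACER_LEN + 1] = "G"
        seq[guide_offset + PROTOSPACER_LEN + 2] = "G"
        s = "".join(seq)
        if forbid_homopolymer is None or not _has_homopolymer(
            s[max(0, cut - window - forbid_homopolymer) : cut + window + forbid_homopolymer],
            forbid_homopolymer,
        ):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not draw an amplicon satisfying constraints")
    guide = GuideRNA(
        protospacer=s[guide_offset : guide_offset + PROTOSPACER_LEN],
        pam=s[guide_offset + PROTOSPACER_LEN : guide_offset + SITE_LEN],
        chrom=name or f"amplicon{seed}",
        start=guide_offset,
        strand="+",
    )
    return AmpliconTarget(
        name=name or f"amplicon{seed}", sequence=s, guide=guide, cut_site=cut
    )


def _has_homopolymer(seq: str, k: int) -> bool:
    run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run >= k:
            return True
    return False


def apply_indel(reference: str, cut_site: int, spec: IndelSpec) -> str:
    """Mutate the reference with one indel anchored at the cut site."""
    pos = cut_site + spec.offset
    if spec.kind == "deletion":
        if pos < 0 or pos + spec.size > len(reference):
            raise ValueError("deletion overhangs the sequence end")
        return reference[:pos] + reference[pos + spec.size :]
    if pos < 0 or pos > len(reference):
        raise ValueError("insertion point outside the sequence")
    return reference[:pos] + spec.inserted_bases + reference[pos:]


def allele_sequence(amplicon: AmpliconTarget, spec) -> str:
    if spec == WT or spec is None:
        return amplicon.sequence
    return apply_indel(amplicon.sequence, amplicon.cut_site, spec)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def _corrupt(seq: str, err: ErrorModel, rng: np.random.Generator) -> str:
    """Apply substitution and 1-bp indel errors independently per base."""
    if err.substitution_rate == 0 and err.indel_error_rate == 0:
        return seq
    out = []
    n = len(seq)
    subs = rng.random(n) < err.substitution_rate
    inds = rng.random(n) < err.indel_error_rate
    for i, base in enumerate(seq):
        if inds[i]:
            if rng.random() < 0.5:
                continue  # 1-bp deletion error
            out.append(base)
            out.append(str(rng.choice(BASES)))  # 1-bp insertion error
            continue
        if subs[i]:
            others = [b for b in "ACGT" if b != base]
            out.append(others[int(rng.integers(3))])
        else:
            out.append(base)
    return "".join(out)


def _phred_from_accuracy(acc: float) -> int:
    if acc >= 1.0:
        return 60
    return min(60, max(2, int(round(-10 * np.log10(1 - acc)))))


def simulate_embryo_reads(
    truth: EmbryoTruth,
    amplicon: AmpliconTarget,
    depth: int,
    err: ErrorModel,
    seed: int,
    reverse_fraction: float = 0.5,
) -> tuple[list[CcsRead], list[tuple[str, str]]]:
    """Simulate barcoded CCS reads for one embryo.

    Each read draws its allele with probability equal to the true
    fraction, is corrupted under the error model, flanked by the dual
    barcodes (``bc_fwd + insert + revcomp(bc_rev)``), optionally emitted
    in reverse orientation, and annotated with sampled pass count and
    predicted accuracy. Returns (reads, sidecar) where the sidecar
    records ``(read_id, originating allele label)`` for every read.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    labels = [a[0] for a in truth.alleles]
    fractions = np.array([a[2] for a in truth.alleles], dtype=float)
    allele_seqs = {a[0]: allele_sequence(amplicon, a[1]) for a in truth.alleles}
    bc_fwd, bc_rev = truth.barcode
    choices = rng.choice(len(labels), size=depth, p=fractions / fractions.sum())
    reads: list[CcsRead] = []
    sidecar: list[tuple[str, str]] = []
    a_alpha, a_beta = err.accuracy_beta
    for i in range(depth):
        label = labels[int(choices[i])]
        insert = _corrupt(allele_seqs[label], err, rng)
        if err.read_length_jitter > 0:
            trim = int(rng.integers(0, err.read_length_jitter + 1))
            if trim:
                insert = insert[:-trim]
        seq = bc_fwd + insert + revcomp(bc_rev)
        if rng.random() < reverse_fraction:
            seq = revcomp(seq)
        acc = float(rng.beta(a_alpha, a_beta))
        passes = 1 + int(rng.poisson(err.passes_lambda))
        q = _phred_from_accuracy(acc)
        read_id = f"{truth.embryo_id}/{i}"
        reads.append(
            CcsRead(
                read_id=read_id,
                sequence=seq,
                qualities=[q] * len(seq),
                passes=passes,
                predicted_accuracy=acc,
            )
        )
        sidecar.append((read_id, label))
    return reads, sidecar


# ---------------------------------------------------------------------------
# Off-target genome planting
# ---------------------------------------------------------------------------

def plant_offtarget_genome(
    guide: GuideRNA,
    planted: Sequence[tuple[Sequence[int], str, int]],
    genome_length: int,
    seed: int,
    chrom: str = "chrSyn",
) -> tuple[str, list[tuple[str, int, int, str, int, str]]]:
    """Random genome with off-target sites planted at chosen loci.

    ``planted`` rows are (mismatch_positions, strand, locus_start); each
    planted 23-nt block carries exactly the requested protospacer
    mismatches (positions 0-based from the PAM-distal end) and an NGG
    PAM. Returns (genome sequence, truth BED rows) where BED rows are
    (chrom, start, end, name, n_mismatches, strand), 0-based half-open.
    """
    rng = np.random.default_rng(seed)
    for positions, strand, locus in planted:
        if any(not 0 <= p < PROTOSPACER_LEN for p in positions):
            raise ValueError("mismatch positions must be within 0..19")
        if strand not in "+-":
            raise ValueError("strand must be + or -")
        if not 0 <= locus <= genome_length - SITE_LEN:
            raise ValueError("planted locus outside genome")
    intervals = sorted((loc, loc + SITE_LEN) for _, _, loc in planted)
    for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
        if a2 < b1:
            raise ValueError("overlapping planted loci")
    genome = list(_random_dna(rng, genome_length))
    bed = []
    for positions, strand, locus in planted:
        proto = list(guide.protospacer)
        for p in positions:
            alternatives = [b for b in "ACGT" if b != proto[p]]
            proto[p] = alternatives[int(rng.integers(3))]
        pam_n = str(rng.choice(BASES))
        block = "".join(proto) + pam_n + "GG"
        if strand == "-":
            block = revcomp(block)
        genome[locus : locus + SITE_LEN] = list(block)
        bed.append(
            (chrom, locus, locus + SITE_LEN,
             f"planted_mm{len(positions)}", len(positions), strand)
        )
    return "".join(genome), bed


def write_genome_fasta(genome: str, path: str | Path, chrom: str = "chrSyn") -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i : i + 80] + "\n")


def write_fasta_amplicons(
    amplicons: Mapping[str, "AmpliconTarget"], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, amp in amplicons.items():
            fh.write(f">{name}\n")
            for i in range(0, len(amp.sequence), 80):
                fh.write(amp.sequence[i : i + 80] + "\n")


def write_truth_bed(rows, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


# ---------------------------------------------------------------------------
# Study-scale scenario
# ---------------------------------------------------------------------------

# Locus-specific NHEJ indel menus mirroring the dominant allele classes
# recovered at each target in the study (sizes in bp).
LOCUS_INDEL_MENU: dict[str, list[IndelSpec]] = {
    "POLLED": [
        IndelSpec("deletion", 4),
        IndelSpec("deletion", 7, -2),
        IndelSpec("deletion", 11, -4),
        IndelSpec("insertion", 1, 0, "A"),
    ],
    "H11": [
        IndelSpec("deletion", 1),
        IndelSpec("deletion", 3, -1),
        IndelSpec("deletion", 6, -3),
        IndelSpec("deletion", 11, -5),
    ],
    "ZFX": [
        IndelSpec("deletion", 1),
        IndelSpec("deletion", 3, -1),
        IndelSpec("deletion", 9, -4),
        IndelSpec("insertion", 1, 0, "T"),
    ],
}

LOCI = ("POLLED", "H11", "ZFX")
CLASSES = ("non_edited", "edited_non_mosaic", "heterozygous", "mosaic")


def _make_barcodes(rng: np.random.Generator, n: int, length: int = 8,
                   min_dist: int = 3) -> list[str]:
    """Greedy barcode set with pairwise Hamming distance >= min_dist."""
    out: list[str] = []
    while len(out) < n:
        cand = _random_dna(rng, length)
        if all(sum(a != b for a, b in zip(cand, x)) >= min_dist for x in out):
            out.append(cand)
    return out


def _embryo_composition(
    cls: str, locus: str, rng: np.random.Generator, x_linked_male: bool
) -> list[tuple[str, object, float]]:
    menu = LOCUS_INDEL_MENU[locus]
    picks = rng.permutation(len(menu))
    m = [menu[int(i)] for i in picks]

    def lab(spec: IndelSpec) -> str:
        return f"{'D' if spec.kind == 'deletion' else 'I'}{spec.size}o{spec.offset}"

    if cls == "non_edited":
        return [(WT, WT, 1.0)]
    if cls == "edited_non_mosaic":
        return [(lab(m[0]), m[0], 1.0)]
    if cls == "heterozygous":
        # balanced biallelic embryo; impossible for a hemizygous male locus
        return [(WT, WT, 0.5), (lab(m[0]), m[0], 0.5)]
    # mosaic: either a disproportionate biallelic mix or >= 3 alleles
    style = int(rng.integers(3))
    if style == 0 and not x_linked_male:
        return [(WT, WT, 0.75), (lab(m[0]), m[0], 0.25)]
    if style == 1:
        return [(WT, WT, 0.40), (lab(m[0]), m[0], 0.35), (lab(m[1]), m[1], 0.25)]
    return [
        (WT, WT, 0.25), (lab(m[0]), m[0], 0.30),
        (lab(m[1]), m[1], 0.25), (lab(m[2]), m[2], 0.20),
    ]


@dataclass
class StudyScenario:
    amplicons: dict[str, AmpliconTarget]
    sheet: BarcodeSheet
    truths: list[EmbryoTruth]
    reads: list[CcsRead]
    sidecar: list[tuple[str, str]]
    error_model: ErrorModel


def simulate_study(
    seed: int,
    n_per_group: int = 10,
    depth: int = 500,
    err: ErrorModel | None = None,
    class_counts: tuple[int, int, int, int] = (2, 1, 2, 5),
    amplicon_length: int = 400,
    guide_offset: int = 180,
) -> StudyScenario:
    """Simulate the full study: 3 loci x 2 Cas9 reagent arms, ``n_per_group``
    embryos each with planted class composition ``class_counts`` =
    (non_edited, edited_non_mosaic, heterozygous, mosaic). ZFX embryos
    alternate male/female; X-linked male embryos planted as heterozygous
    are converted to mosaic (hemizygosity makes balanced biallelism
    impossible). Returns everything the pipeline consumes plus truth.
    """
    if sum(class_counts) != n_per_group:
        raise ValueError("class_counts must sum to n_per_group")
    if err is None:
        err = ErrorModel()
    rng = np.random.default_rng(seed)
    amplicons = {
        locus: make_amplicon(
            seed=int(rng.integers(2**31)),
            length=amplicon_length,
            guide_offset=guide_offset,
            name=locus,
            forbid_homopolymer=4,
        )
        for locus in LOCI
    }
    n_embryos = n_per_group * len(LOCI) * 2
    barcodes = _make_barcodes(rng, 2 * n_embryos)
    truths: list[EmbryoTruth] = []
    reads: list[CcsRead] = []
    sidecar: list[tuple[str, str]] = []
    samples: list[SampleInfo] = []
    idx = 0
    for locus, cas9_form in itertools.product(LOCI, ("mRNA", "protein")):
        plan = [c for c, k in zip(CLASSES, class_counts) for _ in range(k)]
        for cls in plan:
            embryo_id = f"{locus}_{cas9_form}_{idx:03d}"
            if locus == "ZFX":
                sex = "male" if idx % 2 == 0 else "female"
            else:
                sex = "unknown"
            x_male = locus == "ZFX" and sex == "male"
            if cls == "heterozygous" and x_male:
                cls = "mosaic"
            alleles = _embryo_composition(cls, locus, rng, x_male)
            bc = (barcodes[2 * idx], barcodes[2 * idx + 1])
            truth = EmbryoTruth(
                embryo_id=embryo_id, barcode=bc, locus=locus, sex=sex,
                alleles=alleles, true_class=cls,
            )
            truths.append(truth)
            samples.append(
                SampleInfo(
                    sample_id=embryo_id, barcode_fwd=bc[0], barcode_rev=bc[1],
                    locus=locus, cas9_form=cas9_form, sex=sex,
                )
            )
            r, sc = simulate_embryo_reads(
                truth, amplicons[locus], depth, err,
                seed=int(rng.integers(2**31)),
            )
            reads.extend(r)
            sidecar.extend(sc)
            idx += 1
    return StudyScenario(
        amplicons=amplicons,
        sheet=BarcodeSheet(samples),
        truths=truths,
        reads=reads,
        sidecar=sidecar,
        error_model=err,
    )


def write_sidecar_tsv(sidecar, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tallele\n")
        for read_id, label in sidecar:
            fh.write(f"{read_id}\t{label}\n")


def write_truth_tsv(truths: Sequence[EmbryoTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("embryo_id\tlocus\tsex\ttrue_class\talleles\n")
        for t in truths:
            alleles = ";".join(f"{lab}:{frac}" for lab, _, frac in t.alleles)
            fh.write(
                f"{t.embryo_id}\t{t.locus}\t{t.sex}\t{t.true_class}\t{alleles}\n"
            )
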
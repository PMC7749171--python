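"""Embryo mosaicism classification and group-level editing statistics.

An embryo's allele table is classified as non_edited, edited_non_mosaic,
heterozygous or mosaic. A diploid embryo with exactly two alleles is
heterozygous only when both read fractions are consistent with 50/50
(within ``het_tolerance``, or by a binomial test); a disproportionate
two-allele mix (e.g. 75% wild type / 25% mutant) or three or more
distinct alleles indicates more than two cell populations, i.e.
mosaicism. An X-linked locus in a male is hemizygous, so any second
allele there already implies mosaicism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .alleles import AlleleTable

NON_EDITED = "non_edited"
EDITED_NON_MOSAIC = "edited_non_mosaic"
HETEROZYGOUS = "heterozygous"
MOSAIC = "mosaic"
QC_FAIL = "qc_fail"

AUTOSOMAL = "autosomal"
X_LINKED_MALE = "x_linked_male"


@dataclass
class EmbryoClassification:
    embryo_id: str
    n_alleles: int
    wt_fraction: float
    call: str
    ploidy_mode: str = AUTOSOMAL
    locus: str = ""
    cas9_form: str = ""

    @property
    def edited(self) -> bool:
        """An embryo is edited iff it carries at least one non-WT allele."""
        if self.call == QC_FAIL:
            return False
        return not (self.call == NON_EDITED)


@dataclass
class GroupSummary:
    group: tuple
    n: int
    n_edited: int
    pct_non_edited: float
    pct_edited_non_mosaic: float
    pct_heterozygous: float
    pct_mosaic: float  # denominator = edited embryos
    mean_alleles: float
    sem_alleles: float
    mean_wt_read_pct: float
    sem_wt_read_pct: float
    mutation_rate: float  # edited / n


def classify_embryo(
    table: AlleleTable,
    ploidy_mode: str = AUTOSOMAL,
    het_tolerance: float = 0.15,
    min_total_reads: int = 20,
    het_test: str = "tolerance",
    alpha: float = 0.05,
) -> EmbryoClassification:
    """Classify one embryo from its allele table.

    Decision order: (1) only WT -> non_edited; (2) a single non-WT
    allele -> edited_non_mosaic; (3) >= 2 alleles at an X-linked male
    locus -> mosaic; (4) exactly 2 alleles with both fractions within
    ``het_tolerance`` of 0.5 -> heterozygous; (5) exactly 2 alleles,
    disproportionate -> mosaic; (6) >= 3 alleles -> mosaic.

    ``het_test="binomial"`` replaces the fixed tolerance in step (4)
    with a two-sided exact binomial test of the major-allele read count
    against 0.5 (heterozygous unless rejected at ``alpha``). Tables with
    fewer than ``min_total_reads`` kept reads (or failing upstream QC)
    are called qc_fail.
    """
    if not table.qc_pass or table.total_reads < min_total_reads:
        return EmbryoClassification(
            embryo_id=table.embryo_id, n_alleles=table.n_alleles,
            wt_fraction=table.wt_fraction, call=QC_FAIL,
            ploidy_mode=ploidy_mode, locus=table.locus,
        )
    n = table.n_alleles
    wt = table.wt_fraction
    if n == 1 and table.rows[0].signature.is_wt:
        call = NON_EDITED
    elif n == 1:
        call = EDITED_NON_MOSAIC
    elif ploidy_mode == X_LINKED_MALE:
        call = MOSAIC
    elif n == 2:
        if het_test == "binomial":
            major = max(table.rows, key=lambda r: r.read_count)
            p = sps.binomtest(
                major.read_count, table.total_reads, 0.5
            ).pvalue
            balanced = p >= alpha
        else:
            balanced = all(
                abs(r.fraction - 0.5) <= het_tolerance for r in table.rows
            )
        call = HETEROZYGOUS if balanced else MOSAIC
    else:
        call = MOSAIC
    return EmbryoClassification(
        embryo_id=table.embryo_id, n_alleles=n, wt_fraction=wt, call=call,
        ploidy_mode=ploidy_mode, locus=table.locus,
    )


def _mean_sem(values: Sequence[float]) -> tuple[float, float]:
    if not values:
        return (math.nan, math.nan)
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else math.nan
    return mean, sem


def summarize_group(
    classifications: Sequence[EmbryoClassification],
    group: tuple = (),
    mean_mode: str = "edited_only",
) -> GroupSummary | None:
    """Group-level editing summary over QC-passing embryos.

    ``pct_mosaic`` (and pct_heterozygous / pct_edited_non_mosaic) are
    normalized on the number of edited embryos; the mutation rate is
    edited / all analyzed. ``mean_mode`` controls which embryos enter
    mean_alleles and mean_wt_read_pct: ``"edited_only"`` (default,
    matching the convention of excluding WT-only embryos from the
    statistics) or ``"all"``.
    """
    kept = [c for c in classifications if c.call != QC_FAIL]
    if not kept:
        return None
    n = len(kept)
    edited = [c for c in kept if c.edited]
    n_ed = len(edited)
    n_non = sum(c.call == NON_EDITED for c in kept)
    n_enm = sum(c.call == EDITED_NON_MOSAIC for c in kept)
    n_het = sum(c.call == HETEROZYGOUS for c in kept)
    n_mos = sum(c.call == MOSAIC for c in kept)
    pool = edited if mean_mode == "edited_only" else kept
    mean_all, sem_all = _mean_sem([c.n_alleles for c in pool])
    mean_wt, sem_wt = _mean_sem([100.0 * c.wt_fraction for c in pool])
    return GroupSummary(
        group=group,
        n=n,
        n_edited=n_ed,
        pct_non_edited=100.0 * n_non / n,
        pct_edited_non_mosaic=(100.0 * n_enm / n_ed) if n_ed else math.nan,
        pct_heterozygous=(100.0 * n_het / n_ed) if n_ed else math.nan,
        pct_mosaic=(100.0 * n_mos / n_ed) if n_ed else math.nan,
        mean_alleles=mean_all,
        sem_alleles=sem_all,
        mean_wt_read_pct=mean_wt,
        sem_wt_read_pct=sem_wt,
        mutation_rate=n_ed / n,
    )


def aggregate_mutation_rate(
    per_locus_counts: Iterable[tuple[int, int]],
) -> float:
    """Pooled mutation rate: sum(edited) / sum(analyzed). NaN when no
    embryos were analyzed."""
    edited = analyzed = 0
    for e, a in per_locus_counts:
        if not 0 <= e <= a:
            raise ValueError("need analyzed >= edited >= 0")
        edited += e
        analyzed += a
    if analyzed == 0:
        return math.nan
    return edited / analyzed


def classifications_to_frame(
    classifications: Sequence[EmbryoClassification],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "embryo_id": [c.embryo_id for c in classifications],
            "locus": [c.locus for c in classifications],
            "cas9_form": [c.cas9_form for c in classifications],
            "call": [c.call for c in classifications],
            "n_alleles": [c.n_alleles for c in classifications],
            "wt_fraction": [c.wt_fraction for c in classifications],
        }
    )


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        d = vars(s).copy()
        d["group"] = "/".join(str(g) for g in s.group) if s.group else "all"
        rows.append(d)
    return pd.DataFrame(rows)
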
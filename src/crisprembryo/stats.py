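"""Statistical tests and report generation for editing-group comparisons.

Thin, contract-checked wrappers over scipy/statsmodels: Pearson
chi-square (no continuity correction) for guide-testing count tables,
maximum-likelihood logistic regression with categorical fixed effects
(Cas9 form, gRNA) for blastocyst/mutation outcomes, and classical
one-way ANOVA for per-embryo metrics (allele number, percent wild-type
reads; WT-only embryos are excluded upstream). Report writers produce
TSV tables shaped like the study's summary tables plus a JSON run
manifest.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from . import __version__ as _pkg_version
from .mosaic import (
    EmbryoClassification,
    GroupSummary,
    classifications_to_frame,
    summaries_to_frame,
)
from .offtarget import OffTargetReport


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on an R x K count table, no continuity
    correction; df = (R-1)(K-1). Returns (statistic, df, p). A table
    with a zero row/column margin yields the (nan, df, nan) sentinel.
    Raises if any expected count is below 1; warns below 5."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D table with at least 2 columns")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    df = (arr.shape[0] - 1) * (arr.shape[1] - 1)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return (math.nan, df, math.nan)
    expected = sps.contingency.expected_freq(arr)
    if (expected < 1).any():
        raise ValueError("expected cell count below 1; test invalid")
    if (expected < 5).any():
        warnings.warn("expected cell count below 5; chi-square approximate")
    stat, p, dof, _ = sps.chi2_contingency(arr, correction=False)
    assert dof == df
    return (float(stat), int(df), float(p))


@dataclass
class BinaryModelFit:
    coefficients: pd.DataFrame  # term, estimate, std_err, z, p_value
    converged: bool
    separation: bool
    llf: float


def fit_binary_model(
    data: pd.DataFrame,
    response: str,
    fixed_effects: Sequence[str],
) -> BinaryModelFit:
    """Maximum-likelihood logistic regression of a binary outcome on
    categorical fixed effects (e.g. Cas9 form and gRNA).

    On perfect separation the fit is flagged and re-estimated with a
    small L2 penalty (ridge); penalized estimates carry NaN Wald
    p-values since the usual standard errors do not apply.
    """
    if data[response].nunique() < 2:
        raise ValueError("response must show both outcome classes")
    missing = [e for e in fixed_effects if e not in data.columns]
    if missing:
        raise ValueError(f"fixed effects not in data: {missing}")
    rhs = " + ".join(f"C({e})" for e in fixed_effects) if fixed_effects else "1"
    formula = f"{response} ~ {rhs}"
    model = smf.logit(formula, data=data)
    separation = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            res = model.fit(disp=False)
        if not np.isfinite(res.bse).all() or np.abs(res.params).max() > 15:
            separation = True
    except Exception:
        separation = True
    if separation:
        res = model.fit_regularized(
            method="l1", alpha=1e-4, disp=False, trim_mode="off"
        )
        coef = pd.DataFrame(
            {
                "term": res.params.index,
                "estimate": res.params.values,
                "std_err": np.nan,
                "z": np.nan,
                "p_value": np.nan,
            }
        )
        return BinaryModelFit(
            coefficients=coef, converged=True, separation=True,
            llf=float(res.llf),
        )
    coef = pd.DataFrame(
        {
            "term": res.params.index,
            "estimate": res.params.values,
            "std_err": res.bse.values,
            "z": res.tvalues.values,
            "p_value": res.pvalues.values,
        }
    )
    return BinaryModelFit(
        coefficients=coef, converged=bool(res.mle_retvals["converged"]),
        separation=False, llf=float(res.llf),
    )


def anova_one_way(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA. Returns (F, df1, df2, p); the all-groups-
    constant degenerate case yields (nan, df1, df2, nan)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    df1 = len(arrs) - 1
    df2 = sum(len(a) for a in arrs) - len(arrs)
    if all(a.std() == 0 for a in arrs):
        return (math.nan, df1, df2, math.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = sps.f_oneway(*arrs)
    return (float(f), df1, df2, float(p))


def significance_letters(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> dict[str, str]:
    """Compact letter display from pairwise Welch t-tests with Holm
    correction: groups not significantly different share a letter."""
    names = list(groups)
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    pvals = []
    for a, b in pairs:
        _, p = sps.ttest_ind(groups[a], groups[b], equal_var=False)
        pvals.append(p)
    # Holm step-down
    order = np.argsort(pvals)
    sig = {}
    m = len(pvals)
    running_reject = True
    for rank, idx in enumerate(order):
        if running_reject and pvals[idx] * (m - rank) < alpha:
            sig[pairs[idx]] = True
        else:
            running_reject = False
            sig[pairs[idx]] = False
    differ = {
        frozenset(p) for p, s in sig.items() if s
    }
    # greedy letter assignment
    letters: dict[str, str] = {n: "" for n in names}
    groups_of: list[set[str]] = []
    for n in names:
        placed = False
        for g in groups_of:
            if all(frozenset((n, o)) not in differ for o in g):
                g.add(n)
                placed = True
                break
        if not placed:
            groups_of.append({n})
    for i, g in enumerate(groups_of):
        ch = chr(ord("a") + i)
        for n in g:
            letters[n] += ch
    return letters


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def _round_pct(x: float) -> float:
    return float(f"{x:.1f}") if np.isfinite(x) else math.nan


def build_table1(counts: pd.DataFrame) -> pd.DataFrame:
    """Injection-outcome table: expects columns cas9_form, locus,
    total_embryos, blastocysts, analyzed, mutated; adds blastocyst and
    mutation percentages (one decimal for display)."""
    req = {"cas9_form", "locus", "total_embryos", "blastocysts", "analyzed", "mutated"}
    if not req <= set(counts.columns):
        raise ValueError(f"table-1 counts need columns {sorted(req)}")
    out = counts.copy()
    out["blastocyst_pct"] = [
        _round_pct(100.0 * b / t) if t else math.nan
        for b, t in zip(out.blastocysts, out.total_embryos)
    ]
    out["mutation_pct"] = [
        _round_pct(100.0 * m / a) if a else math.nan
        for m, a in zip(out.mutated, out.analyzed)
    ]
    return out


def build_report(
    classifications: Sequence[EmbryoClassification],
    summaries: Sequence[GroupSummary],
    offtarget_reports: Sequence[OffTargetReport],
    output_dir: str | Path,
    table1_counts: pd.DataFrame | None = None,
    allele_frame: pd.DataFrame | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the report bundle: classification TSV, group-summary TSV
    (editing efficiency, % mosaic, mean alleles +/- SEM, % WT reads),
    optional injection-outcome TSV and per-embryo stacked-allele TSV,
    off-target indel TSV, and a deterministic JSON run manifest
    (package version, seed, config hash). Returns {name: path}."""
    if not classifications:
        raise ValueError("missing upstream input: classifications")
    if not summaries:
        raise ValueError("missing upstream input: summaries")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    p = outdir / "classifications.tsv"
    classifications_to_frame(classifications).to_csv(p, sep="\t", index=False)
    paths["classifications"] = p

    p = outdir / "group_summary.tsv"
    summaries_to_frame(summaries).to_csv(p, sep="\t", index=False)
    paths["group_summary"] = p

    if table1_counts is not None:
        p = outdir / "injection_outcomes.tsv"
        build_table1(table1_counts).to_csv(p, sep="\t", index=False)
        paths["injection_outcomes"] = p

    if allele_frame is not None:
        p = outdir / "per_embryo_alleles.tsv"
        allele_frame.to_csv(p, sep="\t", index=False)
        paths["per_embryo_alleles"] = p

    rows = []
    for rep in offtarget_reports:
        for r in rep.rows:
            rows.append(
                {
                    "site": rep.site_name,
                    "kind": r.kind,
                    "size": r.size,
                    "offset_from_cut": r.offset_from_predicted_cut,
                    "supporting_reads": r.supporting_reads,
                    "fraction": r.fraction_of_reads,
                    "known_variant": r.known_variant,
                }
            )
    p = outdir / "offtarget_indels.tsv"
    pd.DataFrame(
        rows,
        columns=[
            "site", "kind", "size", "offset_from_cut",
            "supporting_reads", "fraction", "known_variant",
        ],
    ).to_csv(p, sep="\t", index=False)
    paths["offtarget_indels"] = p

    cfg_json = json.dumps(config or {}, sort_keys=True)
    manifest = {
        "package": "crisprembryo",
        "version": _pkg_version,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_embryos": len(classifications),
        "n_groups": len(summaries),
        "n_offtarget_sites": len(offtarget_reports),
    }
    p = outdir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = p
    return paths
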
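"""Enrichment, candidate prioritization, cohort metal statistics, qPCR
relative expression, and correlation interdependency.

The biomarker statistics mirror a clinical cohort analysis: Welch t-tests
from group summary statistics (mean, SD, n) for serum/CSF metal
concentrations, 2^−ΔΔCt relative expression for qPCR panels normalized to a
housekeeping gene, hypergeometric gene-set enrichment with Benjamini–
Hochberg adjustment, and pairwise correlation of metal concentrations with
gene expression (the interdependency analysis).  Candidate prioritization is
a transparent co-annotation score: candidates are ranked by the mean Jaccard
similarity between their gene-set annotation profile and those of a training
protein set — a deliberate, documented simplification of web-service gene
prioritizers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GROUP_CASE, GROUP_CONTROL, CohortTable, SummaryStats, logger


# ---------------------------------------------------------------------------
# Gene-set enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap: int        # k
    set_size: int       # K
    query_size: int     # n
    universe_size: int  # M
    p: float
    q: float


def hypergeom_enrich(query: set[str], gene_sets: Mapping[str, set[str]],
                     universe: set[str]) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric enrichment with BH adjustment across sets.

    Query genes outside the universe are reported and dropped.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        logger.warning("dropping %d query gene(s) outside the universe: %s",
                       len(stray), ", ".join(sorted(stray)[:10]))
    query = query & universe
    M, n = len(universe), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        K = len(members)
        k = len(query & members)
        # P(X >= k) for X ~ Hypergeom(M, K, n)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        rows.append((name, k, K, p))
    pvals = [r[3] for r in rows]
    if pvals:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = []
    return [EnrichmentRow(set_name=name, overlap=k, set_size=K,
                          query_size=n, universe_size=M, p=p, q=float(q))
            for (name, k, K, p), q in zip(rows, qvals)]


# ---------------------------------------------------------------------------
# Candidate prioritization (co-annotation Jaccard score)
# ---------------------------------------------------------------------------

def _annotation_profile(protein: str,
                        annotations: Mapping[str, set[str]]) -> set[str]:
    return {name for name, members in annotations.items() if protein in members}


def prioritize_candidates(training: set[str], candidates: set[str],
                          annotations: Mapping[str, set[str]],
                          ) -> list[tuple[str, float]]:
    """Rank candidates by mean Jaccard similarity of annotation profiles.

    Each protein's profile is the set of gene sets containing it; a
    candidate's score is the mean, over training proteins, of the Jaccard
    similarity between the two profiles.  Unannotated candidates score 0 and
    are flagged.  Ties break lexicographically.
    """
    if not training:
        raise ValueError("empty training set")
    train_profiles = {t: _annotation_profile(t, annotations) for t in sorted(training)}
    scored = []
    for cand in sorted(candidates):
        prof = _annotation_profile(cand, annotations)
        if not prof:
            logger.info("candidate %s has no annotations; score 0", cand)
            scored.append((cand, 0.0))
            continue
        sims = []
        for tprof in train_profiles.values():
            union = prof | tprof
            sims.append(len(prof & tprof) / len(union) if union else 0.0)
        scored.append((cand, float(np.mean(sims))))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored


# ---------------------------------------------------------------------------
# Cohort metal statistics
# ---------------------------------------------------------------------------

def summarize(values: Sequence[float]) -> SummaryStats:
    arr = np.asarray([v for v in values if not np.isnan(v)], dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 observations")
    return SummaryStats(mean=float(arr.mean()), sd=float(arr.std(ddof=1)),
                        n=int(arr.size))


def ttest_from_summary(a: SummaryStats, b: SummaryStats,
                       variant: str = "welch") -> tuple[float, float, float]:
    """Two-sided two-sample t-test from group summaries.

    Welch (default) uses the Satterthwaite degrees of freedom; the pooled
    variant is available.  Both SDs zero with equal means gives (0, df, 1)
    by convention.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            return 0.0, float(a.n + b.n - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n,
                                      equal_var=(variant == "pooled"))
    if variant == "pooled":
        df = float(a.n + b.n - 2)
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df), float(p)


def cohort_metal_table(cohort: CohortTable, variant: str = "welch",
                       ) -> pd.DataFrame:
    """Summary-table rows (mean, SD, n per group; t, df, p) per analyte."""
    rows = []
    for col in cohort.analyte_columns:
        ctrl = cohort.group_rows(GROUP_CONTROL)[col].dropna()
        case = cohort.group_rows(GROUP_CASE)[col].dropna()
        if len(ctrl) < 2 or len(case) < 2:
            continue
        a, b = summarize(ctrl), summarize(case)
        t, df, p = ttest_from_summary(a, b, variant=variant)
        rows.append({
            "analyte": col,
            "control_mean": a.mean, "control_sd": a.sd, "control_n": a.n,
            "pd_mean": b.mean, "pd_sd": b.sd, "pd_n": b.n,
            "t": t, "df": df, "p": p,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR relative expression (2^-ddCt)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DdctResult:
    gene: str
    reference: str
    mean_dct_control: float   # cycles
    mean_dct_case: float      # cycles
    ddct: float               # case - control, cycles
    fold_change: float        # 2^-ddct
    p: float                  # two-sided t-test on per-sample dCt
    n_control: int
    n_case: int


def ddct(cohort: CohortTable, target: str, reference: str = "ACTB",
         variant: str = "welch") -> DdctResult:
    """Relative expression by the 2^−ΔΔCt method.

    Per-sample ΔCt = Ct(target) − Ct(reference); ΔΔCt is the difference of
    group-mean ΔCt (case − control); fold change 2^−ΔΔCt.  Samples missing
    either Ct are excluded with a logged count.
    """
    tcol, rcol = f"ct_{target}", f"ct_{reference}"
    for col in (tcol, rcol):
        if col not in cohort.data.columns:
            raise ValueError(f"missing Ct column {col!r}")
    sub = cohort.data[["group", tcol, rcol]]
    complete = sub.dropna()
    dropped = len(sub) - len(complete)
    if dropped:
        logger.info("ddct(%s): excluded %d sample(s) with missing Ct", target, dropped)
    dct = complete[tcol] - complete[rcol]
    ctrl = dct[complete["group"] == GROUP_CONTROL]
    case = dct[complete["group"] == GROUP_CASE]
    if len(ctrl) < 2 or len(case) < 2:
        raise ValueError("need at least 2 complete samples per group")
    t, df, p = ttest_from_summary(summarize(case), summarize(ctrl), variant=variant)
    dd = float(case.mean() - ctrl.mean())
    return DdctResult(gene=target, reference=reference,
                      mean_dct_control=float(ctrl.mean()),
                      mean_dct_case=float(case.mean()),
                      ddct=dd, fold_change=float(2.0 ** (-dd)), p=p,
                      n_control=len(ctrl), n_case=len(case))


# ---------------------------------------------------------------------------
# Correlation interdependency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationCell:
    var_a: str
    var_b: str
    r: float
    n: int
    p: float
    computable: bool = True


def interdependency_matrix(cohort: CohortTable,
                           pairs: Sequence[tuple[str, str]],
                           method: str = "pearson",
                           group: str | None = None) -> list[CorrelationCell]:
    """Pairwise correlations with pairwise-complete deletion.

    ``group`` restricts to one cohort arm (interdependencies are typically
    reported separately for control and case).  Pairs with fewer than 3
    complete observations are reported as not computable.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    data = cohort.data if group is None else cohort.group_rows(group)
    cells = []
    for a, b in pairs:
        if a not in data.columns or b not in data.columns:
            raise ValueError(f"unknown variable in pair ({a!r}, {b!r})")
        sub = data[[a, b]].dropna()
        n = len(sub)
        if n < 3:
            cells.append(CorrelationCell(a, b, float("nan"), n, float("nan"),
                                         computable=False))
            continue
        if method == "pearson":
            r, p = stats.pearsonr(sub[a], sub[b])
        else:
            r, p = stats.spearmanr(sub[a], sub[b])
        cells.append(CorrelationCell(a, b, float(r), n, float(p)))
    return cells


def correlation_frame(cells: list[CorrelationCell]) -> pd.DataFrame:
    return pd.DataFrame([{
        "var_a": c.var_a, "var_b": c.var_b, "r": c.r, "n": c.n, "p": c.p,
        "computable": c.computable,
    } for c in cells])
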
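"""Differential expression per dataset, Fisher's-method meta-analysis, and
batch-adjusted merging.

Each dataset contributes a two-sided two-sample t-test p-value and an effect
sign per gene (case mean minus control mean of log2 intensity).  Across the
k datasets measuring a gene, Fisher's method combines the p-values:

    X = -2 Σ ln p_i  ~  χ²(2k)  under the null,

and the combined p is the chi-square upper tail.  For classification, the
datasets are also merged on their shared genes with a per-gene, per-batch
location–scale adjustment (centre and scale each batch, then restore the
pooled moments) — a deliberately simple, hyperparameter-free stand-in for
empirical-Bayes batch correction with the same intent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GROUP_CASE, GROUP_CONTROL, ExpressionStudy, logger

P_FLOOR = 1e-300    # callers floor p-values here before Fisher combination

RAW_SCALE_THRESHOLD = 50.0   # max value above this -> treated as raw intensity


def normalize_dataset(study: ExpressionStudy, force: bool | None = None,
                      ) -> ExpressionStudy:
    """Log2-transform raw intensities; pass through already-logged data.

    The heuristic treats the matrix as raw when its maximum exceeds
    ``RAW_SCALE_THRESHOLD``; ``force=True``/``False`` overrides it.
    """
    mx = study.matrix.to_numpy()
    is_raw = bool(mx.max() > RAW_SCALE_THRESHOLD) if force is None else force
    if not is_raw:
        logger.info("dataset %s: already log-scale, passthrough", study.platform)
        out = study.matrix.copy()
    else:
        if (mx <= 0).any():
            bad = np.argwhere(mx <= 0)
            cells = [(study.genes[i], study.samples[j]) for i, j in bad[:5]]
            raise ValueError(f"nonpositive raw intensity at {cells}")
        out = pd.DataFrame(np.log2(mx), index=study.matrix.index,
                           columns=study.matrix.columns)
    return ExpressionStudy(matrix=out, groups=study.groups, batch=study.batch,
                           platform=study.platform, normalized=True)


def per_gene_pvalues(study: ExpressionStudy, welch: bool = False) -> pd.DataFrame:
    """Two-sided two-sample t-test per gene (pooled variance by default).

    Returns a frame indexed by gene with columns ``p`` and ``sign``
    (sign of case mean − control mean).  Genes with zero variance in both
    groups and equal means get p=1 by convention.
    """
    case = study.group_samples(GROUP_CASE)
    ctrl = study.group_samples(GROUP_CONTROL)
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("need at least 2 samples per group")
    A = study.matrix[case].to_numpy()
    B = study.matrix[ctrl].to_numpy()
    with warnings.catch_warnings():
        # constant genes trigger a precision warning; handled by convention
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(A, B, axis=1, equal_var=not welch)
    p = np.asarray(res.pvalue, dtype=float)
    diff = A.mean(axis=1) - B.mean(axis=1)
    degenerate = np.isnan(p)
    if degenerate.any():
        # zero variance in both groups: p=1 when means equal, else ~0
        p = np.where(degenerate & (np.abs(diff) < 1e-12), 1.0, p)
        p = np.where(np.isnan(p), P_FLOOR, p)
    p = np.clip(p, P_FLOOR, 1.0)
    return pd.DataFrame({"p": p, "sign": np.sign(diff)}, index=study.matrix.index)


def fisher_combine(pvals: list[float] | np.ndarray) -> tuple[float, int, float]:
    """Fisher's combination: X = -2 Σ ln p, df = 2k, combined p = χ² upper tail.

    A zero p-value raises: floor inputs at machine epsilon explicitly before
    calling (run_meta uses ``P_FLOOR``).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any():
        raise ValueError("p=0 input: floor p-values at machine epsilon first")
    if (p > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    X = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    combined = float(stats.chi2.sf(X, df))
    return X, df, combined


@dataclass
class MetaGeneResult:
    gene: str
    per_study_p: list[float]
    per_study_sign: list[float]
    fisher_x: float
    df: int
    combined_p: float
    direction: str          # up | down | discordant | none
    significant: bool


def run_meta(studies: list[ExpressionStudy], genes: set[str] | None = None,
             alpha: float = 0.05, welch: bool = False,
             significant_only: bool = False) -> list[MetaGeneResult]:
    """Fisher's-method meta-analysis across datasets.

    ``significant_only=True`` reproduces the literal reading of combining
    only the per-dataset p-values that are themselves below alpha (genes with
    no significant dataset are then reported non-significant); the default
    combines all per-dataset p-values.  Direction is up/down when every
    per-study significant sign agrees (falling back to the pooled sign when
    none is significant), discordant otherwise.
    """
    if len(studies) < 1:
        raise ValueError("need at least one study")
    tables = [per_gene_pvalues(s, welch=welch) for s in studies]
    universe: set[str] = set()
    for s in studies:
        universe |= set(s.genes)
    wanted = sorted(universe if genes is None else set(genes))
    results = []
    for gene in wanted:
        ps, signs = [], []
        for t in tables:
            if gene in t.index:
                ps.append(float(t.loc[gene, "p"]))
                signs.append(float(t.loc[gene, "sign"]))
        if not ps:
            logger.info("gene %s unmeasured in every study", gene)
            continue
        use = [p for p in ps if p <= alpha] if significant_only else ps
        if use:
            # sorted so the combination is exactly study-order invariant
            X, df, combined = fisher_combine(np.sort(np.clip(use, P_FLOOR, 1.0)))
        else:
            X, df, combined = 0.0, 0, 1.0
        sig_signs = {s for p, s in zip(ps, signs) if p <= alpha and s != 0}
        if len(sig_signs) == 1:
            direction = "up" if sig_signs == {1.0} else "down"
        elif len(sig_signs) > 1:
            direction = "discordant"
        else:
            pooled = float(np.sum(signs))
            direction = "up" if pooled > 0 else "down" if pooled < 0 else "none"
        results.append(MetaGeneResult(
            gene=gene, per_study_p=ps, per_study_sign=signs,
            fisher_x=X, df=df, combined_p=combined,
            direction=direction, significant=combined <= alpha,
        ))
    return results


def meta_frame(results: list[MetaGeneResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "k": len(r.per_study_p), "fisher_x": r.fisher_x,
        "df": r.df, "combined_p": r.combined_p, "direction": r.direction,
        "significant": r.significant,
    } for r in results])


def merge_with_batch_adjust(studies: list[ExpressionStudy]) -> ExpressionStudy:
    """Merge datasets on shared genes with per-gene location–scale adjustment.

    Per gene: each batch is centred and scaled to unit variance, then the
    pooled (pre-adjustment) mean and SD are restored, so within-batch means
    agree exactly across batches afterwards.  Group labels are preserved and
    the originating dataset is recorded as the batch.
    """
    if len(studies) < 1:
        raise ValueError("no studies to merge")
    shared = set(studies[0].genes)
    for s in studies[1:]:
        shared &= set(s.genes)
    if not shared:
        raise ValueError("no shared genes across studies")
    shared_sorted = sorted(shared)
    mats, groups, batches = [], {}, {}
    for i, s in enumerate(studies):
        batch_id = str(s.batch.iloc[0]) if len(set(s.batch)) == 1 else f"B{i}"
        if s.matrix.shape[1] < 2:
            raise ValueError(f"batch {batch_id} has a single sample")
        m = s.matrix.loc[shared_sorted]
        # guard against duplicate sample names across datasets
        rename = {c: f"{batch_id}::{c}" if c in groups else c for c in m.columns}
        m = m.rename(columns=rename)
        mats.append(m)
        for c in m.columns:
            orig = c.split("::", 1)[1] if "::" in c else c
            groups[c] = s.groups[orig]
            batches[c] = batch_id
    merged = pd.concat(mats, axis=1)
    pooled_mean = merged.mean(axis=1)
    pooled_sd = merged.std(axis=1, ddof=1)
    batch_series = pd.Series(batches)
    adjusted = merged.copy()
    for batch_id in sorted(set(batches.values())):
        cols = [c for c in merged.columns if batches[c] == batch_id]
        block = merged[cols]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1).replace(0.0, 1.0)
        z = block.sub(mu, axis=0).div(sd, axis=0)
        adjusted[cols] = z.mul(pooled_sd, axis=0).add(pooled_mean, axis=0)
    return ExpressionStudy(matrix=adjusted, groups=pd.Series(groups),
                           batch=batch_series, platform="merged",
                           normalized=True)
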
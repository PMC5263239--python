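"""Replicate count handling and group-level drug-response statistics.

The differential-response caller classifies each gene as down / up /
unchanged between control and treated replicate count matrices. The default
test is a negative-binomial Wald test with a single dispersion shared across
genes (estimated by moments from replicate scatter), which stays calibrated
under the replicate overdispersion that biological count data show. A
pooled-replicate exact binomial test is available as an alternative for
Poisson-like data.

Group-level comparisons reproduce the standard toolkit: per-group
down/up/unchanged proportions with pairwise two-tailed Fisher's exact
tests, Mann-Whitney U shift tests with medians and interquartile ranges,
signal-matched control gene sets drawn by stratified sampling, and
replicate-consistency scores (negative coefficient of variation).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def normalize_expression(
    counts: pd.DataFrame, mode: str = "cpm", reference_gene: str | None = None
) -> pd.DataFrame:
    """Normalize a genes x samples count matrix.

    mode='cpm' scales each sample to counts per million; mode='reference-gene'
    divides each sample by its count for ``reference_gene`` (GAPDH-style
    normalization). Both are monotone within sample, so ranks are preserved.
    """
    if mode == "cpm":
        totals = counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("sample with zero total count")
        return counts / totals * 1e6
    if mode == "reference-gene":
        if reference_gene is None or reference_gene not in counts.index:
            raise ValueError("reference-gene mode needs a reference_gene present in the matrix")
        ref = counts.loc[reference_gene]
        if (ref == 0).any():
            raise ValueError("reference gene has a zero count in some sample")
        return counts / ref
    raise ValueError(f"unknown normalization mode {mode!r}")


def _size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, robust to a minority of changed genes.

    Falls back to total-count scaling when no gene is positive in every
    sample. Factors are scaled to mean 1.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("sample with zero total count")
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) >= 10:
        log_ref = np.log(positive).mean(axis=1)
        s = np.exp(np.log(positive).sub(log_ref, axis=0).median(axis=0))
    else:
        s = totals
    return s / s.mean()


def estimate_shared_dispersion(
    q: pd.DataFrame, groups: Sequence[Sequence[str]], c1s: Sequence[float], min_mean: float = 10.0
) -> float:
    """Method-of-moments NB dispersion pooled across genes and conditions.

    For size-factor-normalized counts q, Var(q) ~= mu * c1 + alpha * mu^2
    within a condition (c1 = mean 1/size factor); alpha is the mean of the
    per-gene excess over the Poisson term across well-expressed genes — the
    mean rather than the median, because the per-gene moment estimate is a
    roughly chi-square-scaled quantity whose median sits well below its
    expectation at few replicates.
    """
    ests = []
    for cols, c1 in zip(groups, c1s):
        sub = q[list(cols)]
        mu = sub.mean(axis=1).to_numpy()
        var = sub.var(axis=1, ddof=1).to_numpy()
        ok = mu >= min_mean
        if ok.sum() == 0:
            continue
        ests.append((var[ok] - mu[ok] * c1) / mu[ok] ** 2)
    if not ests:
        return 1e-8
    alpha = float(np.mean(np.concatenate(ests)))
    return max(alpha, 1e-8)


def call_response(
    counts: pd.DataFrame,
    control_ids: Sequence[str],
    treated_ids: Sequence[str],
    alpha: float = 0.05,
    method: str = "nb",
    refine_normalization: bool = True,
) -> pd.DataFrame:
    """Per-gene differential response between control and treated replicates.

    Returns a table indexed by gene with base_mean, log2_fold_change,
    pvalue, padj (Benjamini-Hochberg) and status in {down, up, unchanged}.
    Genes with zero counts in both conditions are 'unchanged' with fold
    change 0 and p = 1.

    With ``refine_normalization`` (default) size factors are re-estimated on
    the genes a first pass leaves clearly unchanged; this removes the fold
    change shrinkage that median-of-ratios normalization suffers when a
    sizeable minority of genes responds to treatment.
    """
    control_ids, treated_ids = list(control_ids), list(treated_ids)
    if len(control_ids) < 2 or len(treated_ids) < 2:
        raise ValueError("need >= 2 replicates per condition")
    if method not in {"nb", "pooled-binomial"}:
        raise ValueError(f"unknown method {method!r}")
    sub = counts[control_ids + treated_ids]
    s = _size_factors(sub)
    if refine_normalization and method == "nb":
        # median-of-ratios is biased when a sizeable minority of genes
        # responds; iterate, re-estimating factors on genes the current
        # pass leaves clearly unchanged, until the factors stabilize
        for _ in range(10):
            first = _call_response_nb(sub, control_ids, treated_ids, s, alpha)
            stable = sub.index[(first["padj"] >= 0.3) & (sub.mean(axis=1) >= 10)]
            if len(stable) < 50:
                break
            s_new = _size_factors(sub.loc[stable])
            if np.allclose(s_new.to_numpy(), s.to_numpy(), rtol=1e-4):
                s = s_new
                break
            s = s_new
    if method == "nb":
        return _call_response_nb(sub, control_ids, treated_ids, s, alpha)
    q = sub / s

    mu_c = q[control_ids].mean(axis=1).to_numpy()
    mu_t = q[treated_ids].mean(axis=1).to_numpy()
    all_zero = (sub.sum(axis=1) == 0).to_numpy()
    pseudo = 0.5
    lfc = np.log2((mu_t + pseudo) / (mu_c + pseudo))
    lfc[all_zero] = 0.0

    x_t = counts[treated_ids].sum(axis=1).to_numpy()
    x_c = counts[control_ids].sum(axis=1).to_numpy()
    p0 = counts[treated_ids].values.sum() / sub.values.sum()
    pvals = np.ones(len(sub))
    for i, (xt, xc) in enumerate(zip(x_t, x_c)):
        n = int(xt + xc)
        if n > 0:
            pvals[i] = stats.binomtest(int(xt), n, p0).pvalue
    return _assemble_response(sub.index, mu_c, mu_t, lfc, pvals, all_zero, alpha)


def _call_response_nb(
    sub: pd.DataFrame,
    control_ids: list[str],
    treated_ids: list[str],
    s: pd.Series,
    alpha: float,
) -> pd.DataFrame:
    q = sub / s
    mu_c = q[control_ids].mean(axis=1).to_numpy()
    mu_t = q[treated_ids].mean(axis=1).to_numpy()
    all_zero = (sub.sum(axis=1) == 0).to_numpy()
    pseudo = 0.5
    lfc = np.log2((mu_t + pseudo) / (mu_c + pseudo))
    lfc[all_zero] = 0.0
    n_c, n_t = len(control_ids), len(treated_ids)
    c1_c = float((1.0 / s[control_ids]).mean())
    c1_t = float((1.0 / s[treated_ids]).mean())
    disp = estimate_shared_dispersion(q, [control_ids, treated_ids], [c1_c, c1_t])
    mu_c_f = np.maximum(mu_c, pseudo)
    mu_t_f = np.maximum(mu_t, pseudo)
    var_lc = (c1_c / mu_c_f + disp) / n_c
    var_lt = (c1_t / mu_t_f + disp) / n_t
    # model-based (not sample) variance with a dispersion shared across
    # genes, so a normal reference is appropriate even at few replicates
    z = (np.log(mu_t_f) - np.log(mu_c_f)) / np.sqrt(var_lc + var_lt)
    pvals = 2 * stats.norm.sf(np.abs(z))
    return _assemble_response(sub.index, mu_c, mu_t, lfc, pvals, all_zero, alpha)


def _assemble_response(index, mu_c, mu_t, lfc, pvals, all_zero, alpha) -> pd.DataFrame:
    pvals = np.clip(pvals, 0.0, 1.0)
    pvals[all_zero] = 1.0
    padj = multipletests(pvals, method="fdr_bh")[1]
    status = np.where(
        (padj < alpha) & (lfc < 0), "down", np.where((padj < alpha) & (lfc > 0), "up", "unchanged")
    )
    status[all_zero] = "unchanged"
    return pd.DataFrame(
        {
            "base_mean": (mu_c + mu_t) / 2,
            "log2_fold_change": lfc,
            "pvalue": pvals,
            "padj": padj,
            "status": status,
        },
        index=index,
    )


def group_response_proportions(
    response: pd.DataFrame, gene_groups: Mapping[str, set[str]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Down/up/unchanged fractions per gene group + pairwise Fisher tests.

    The Fisher test is two-tailed on the 2x2 table (down vs not-down) for
    each pair of groups.
    """
    rows = []
    downs: dict[str, tuple[int, int]] = {}
    for name, genes in gene_groups.items():
        present = response.index.intersection(list(genes))
        if len(present) == 0:
            warnings.warn(f"group {name!r} has no genes in the response table; omitted", stacklevel=2)
            continue
        sub = response.loc[present, "status"]
        n = len(sub)
        n_down = int((sub == "down").sum())
        n_up = int((sub == "up").sum())
        rows.append(
            {
                "group": name,
                "n": n,
                "frac_down": n_down / n,
                "frac_up": n_up / n,
                "frac_unchanged": (n - n_down - n_up) / n,
            }
        )
        downs[name] = (n_down, n - n_down)
    fisher_rows = []
    names = list(downs)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            table = [list(downs[a]), list(downs[b])]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            fisher_rows.append({"group_a": a, "group_b": b, "odds_ratio": odds, "pvalue": p})
    return (
        pd.DataFrame(rows, columns=["group", "n", "frac_down", "frac_up", "frac_unchanged"]),
        pd.DataFrame(fisher_rows, columns=["group_a", "group_b", "odds_ratio", "pvalue"]),
    )


def group_shift_test(values_a: Sequence[float], values_b: Sequence[float]) -> dict:
    """Two-tailed Mann-Whitney U with box-plot summaries.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's automatic policy).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups need >= 1 value")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")

    def _summary(v: np.ndarray) -> dict:
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        return {"median": float(med), "q1": float(q1), "q3": float(q3)}

    return {
        "U": float(res.statistic),
        "pvalue": float(res.pvalue),
        "a": _summary(a),
        "b": _summary(b),
    }


def matched_control_set(
    target_genes: set[str],
    all_genes: Sequence[str],
    match_stat: pd.Series,
    n_bins: int = 10,
    seed: int = 0,
) -> set[str]:
    """Non-target genes stratified-sampled to match the targets' stat histogram.

    Targets are binned into ``n_bins`` equal-width bins over their stat
    range; the same per-bin counts are drawn from non-target genes without
    replacement. A bin with too few candidates contributes all of them, with
    a warning. Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    targets = sorted(g for g in target_genes if g in match_stat.index)
    if not targets:
        raise ValueError("no target gene has a match statistic")
    pool = sorted(g for g in all_genes if g not in target_genes and g in match_stat.index)
    t_stat = match_stat.loc[targets].to_numpy(dtype=float)
    lo, hi = t_stat.min(), t_stat.max()
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    t_bins = np.clip(np.digitize(t_stat, edges[1:-1]), 0, n_bins - 1)
    p_stat = match_stat.loc[pool].to_numpy(dtype=float)
    p_bins = np.clip(np.digitize(p_stat, edges[1:-1]), 0, n_bins - 1)
    chosen: list[str] = []
    for b in range(n_bins):
        want = int((t_bins == b).sum())
        candidates = [pool[i] for i in np.flatnonzero(p_bins == b)]
        if want == 0:
            continue
        if len(candidates) < want:
            warnings.warn(
                f"bin {b}: only {len(candidates)} candidates for {want} targets; taking all",
                stacklevel=2,
            )
            chosen.extend(candidates)
        else:
            picked = rng.choice(len(candidates), size=want, replace=False)
            chosen.extend(candidates[i] for i in sorted(picked))
    return set(chosen)


def transcriptional_consistency(
    counts: pd.DataFrame, replicate_ids: Sequence[str], mode: str = "cpm"
) -> tuple[pd.DataFrame, int]:
    """Per-gene replicate consistency: negative coefficient of variation.

    Higher consistency means less variation in expression across biological
    replicates. Genes with zero mean are excluded; their count is returned.
    """
    replicate_ids = list(replicate_ids)
    if len(replicate_ids) < 3:
        raise ValueError("need >= 3 replicates for a consistency score")
    norm = normalize_expression(counts[replicate_ids], mode=mode)
    mean = norm.mean(axis=1)
    sd = norm.std(axis=1, ddof=1)
    keep = mean > 0
    n_excluded = int((~keep).sum())
    cv = (sd[keep] / mean[keep]).rename("cv")
    out = pd.DataFrame({"cv": cv, "consistency": -cv})
    return out, n_excluded
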
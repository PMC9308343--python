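"""Negative-binomial differential expression and allelic group classification.

A deliberately compact NB pipeline in the DESeq2 mould: median-of-ratios size
factors, per-gene method-of-moments dispersions shrunk toward a fitted
mean-dispersion trend, and a Wald test on the log fold change of normalized
group means.  Exact DESeq2 parity (Cook's distance, independent filtering,
shrunken LFC estimators) is a non-goal; the contribution this package serves
is the allelic framing around the test, not the test internals.

Allelic differential calls are made on maternal and paternal counts
separately; down-regulated allelic DEGs fall into groups A (maternal only),
B (paternal only), C (both), and up-regulated ones into D/E/F symmetrically.
A gene can be, e.g., maternally up and paternally down, so it can carry both
an up group and a down group.

Model: counts Y_ij ~ NB(mean = s_j * mu_gi, variance = mu + alpha*mu^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LFC_PSEUDOCOUNT = 0.5  # stabilizes log2fc at zero counts
_MIN_DISP = 1e-8
_MAX_DISP = 10.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each gene expressed in every sample, the ratio of each sample's count
    to the gene's geometric mean is taken; a sample's factor is the median of
    its ratios, rescaled so the factors have geometric mean 1.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene with nonzero counts in all samples")
    log_mat = np.log(mat[positive])
    log_geo = log_mat.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_mat - log_geo, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _dispersion_trend(mu: np.ndarray, alpha_raw: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu by trimmed least squares over gene-wise
    moment estimates, as a parametric mean-dispersion trend."""
    usable = (mu > 1.0) & (alpha_raw > 0)
    if usable.sum() < 10:
        fallback = float(np.median(alpha_raw[alpha_raw > 0])) if (alpha_raw > 0).any() else 0.1
        return np.full_like(mu, max(fallback, _MIN_DISP))
    a0, a1 = 0.1, 1.0
    sel = usable.copy()
    for _ in range(3):
        x = np.column_stack([np.ones(sel.sum()), 1.0 / mu[sel]])
        coef, *_ = np.linalg.lstsq(x, alpha_raw[sel], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
        fit = a0 + a1 / np.maximum(mu, 0.5)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(fit > 0, alpha_raw / np.maximum(fit, _MIN_DISP), np.inf)
        sel = usable & (ratio > 1e-4) & (ratio < 15.0)
        if sel.sum() < 10:
            break
    trend = a0 + a1 / np.maximum(mu, 0.5)
    return np.clip(trend, _MIN_DISP, _MAX_DISP)


def estimate_dispersions(
    norm_counts: np.ndarray,
    group_idx: Tuple[np.ndarray, np.ndarray],
    inv_sf_mean: float,
    shrink_weight: float = 0.8,
) -> Dict[str, np.ndarray]:
    """Per-gene NB dispersions: moments estimate shrunk toward the trend.

    The raw estimate solves var = mu*mean(1/s) + alpha*mu^2 from the pooled
    within-group variance of normalized counts.  Genes whose raw estimate is
    non-positive (observed variance at or below Poisson) take the trend value;
    otherwise the used value is the log-scale weighted mean of raw and trend.
    The default weight leans heavily on the trend because the per-gene moment
    estimate carries only a few residual degrees of freedom at typical clone
    counts (2-3 per group).
    """
    idx_a, idx_b = group_idx
    qa, qb = norm_counts[:, idx_a], norm_counts[:, idx_b]
    na, nb = qa.shape[1], qb.shape[1]
    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
    df = na + nb - 2
    if df <= 0:
        raise ValueError("need at least 3 samples in total for dispersion")
    va = qa.var(axis=1, ddof=1) if na > 1 else np.zeros_like(mu_a)
    vb = qb.var(axis=1, ddof=1) if nb > 1 else np.zeros_like(mu_b)
    pooled_var = ((na - 1) * va + (nb - 1) * vb) / df
    w_a, w_b = (na - 1) / df if df else 0.5, (nb - 1) / df if df else 0.5
    mu_bar = w_a * mu_a + w_b * mu_b
    mu_sq_bar = w_a * mu_a**2 + w_b * mu_b**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(
            mu_sq_bar > 0,
            (pooled_var - mu_bar * inv_sf_mean) / np.maximum(mu_sq_bar, 1e-12),
            0.0,
        )
    trend = _dispersion_trend(mu_bar, alpha_raw)
    has_info = alpha_raw > 0
    log_used = np.where(
        has_info,
        shrink_weight * np.log(trend)
        + (1 - shrink_weight) * np.log(np.maximum(alpha_raw, _MIN_DISP)),
        np.log(trend),
    )
    alpha = np.clip(np.exp(log_used), _MIN_DISP, _MAX_DISP)
    return {"alpha": alpha, "alpha_raw": alpha_raw, "alpha_trend": trend}


def nb_wald_test(
    counts: pd.DataFrame,
    condition: Sequence[str],
    factors: Optional[pd.Series] = None,
    reference: str = "wt",
    shrink_weight: float = 0.8,
) -> pd.DataFrame:
    """Two-group NB Wald test per gene (test group vs ``reference``).

    Returns a DataFrame indexed by gene with columns base_mean, log2fc
    (test over reference, 0.5 pseudocount on normalized means), se, p_value,
    fdr.  The Wald statistic — the log ratio of normalized group means over
    its delta-method NB standard error — is referred to the standard normal.
    """
    condition = np.asarray(condition)
    labels = set(condition)
    if reference not in labels:
        raise ValueError(f"reference level {reference!r} absent from design")
    if len(labels) != 2:
        raise ValueError(f"need exactly two condition levels, got {labels}")
    test = (labels - {reference}).pop()
    idx_a = np.flatnonzero(condition == reference)
    idx_b = np.flatnonzero(condition == test)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("each condition level needs at least one sample")

    if factors is None:
        factors = size_factors(counts)
    sf = factors.reindex(counts.columns).to_numpy(dtype=float)
    mat = counts.to_numpy(dtype=float)
    q = mat / sf
    inv_sf_mean = float(np.mean(1.0 / sf))

    disp = estimate_dispersions(q, (idx_a, idx_b), inv_sf_mean, shrink_weight)
    alpha = disp["alpha"]

    na, nb = len(idx_a), len(idx_b)
    mu_a = q[:, idx_a].mean(axis=1)
    mu_b = q[:, idx_b].mean(axis=1)
    pc = LFC_PSEUDOCOUNT
    log2fc = np.log2((mu_b + pc) / (mu_a + pc))

    # delta-method variance of log group means under the NB model
    sum_inv_a = float(np.sum(1.0 / sf[idx_a]))
    sum_inv_b = float(np.sum(1.0 / sf[idx_b]))
    mu_a_eff = mu_a + pc
    mu_b_eff = mu_b + pc
    var_log_a = sum_inv_a / (na**2 * mu_a_eff) + alpha / na
    var_log_b = sum_inv_b / (nb**2 * mu_b_eff) + alpha / nb
    se_ln = np.sqrt(var_log_a + var_log_b)
    z = np.log(mu_b_eff / mu_a_eff) / se_ln
    p = 2.0 * stats.norm.sf(np.abs(z))

    result = pd.DataFrame(
        {
            "base_mean": q.mean(axis=1),
            "log2fc": log2fc,
            "se": se_ln / math.log(2),
            "stat": z,
            "p_value": p,
            "fdr": bh_adjust(p),
            "dispersion": alpha,
        },
        index=counts.index,
    )
    result.index.name = "gene_id"
    return result


def call_degs(
    records: pd.DataFrame,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Attach direction calls: fdr < alpha and |log2fc| >= log2(fc_min).

    Genes on the exclusion list (e.g. off-target deletions) are dropped.
    """
    records = records.drop(index=[g for g in exclude if g in records.index])
    lfc_min = math.log2(fc_min)
    sig = records["fdr"] < alpha
    direction = np.where(
        sig & (records["log2fc"] <= -lfc_min),
        "down",
        np.where(sig & (records["log2fc"] >= lfc_min), "up", "ns"),
    )
    out = records.copy()
    out["direction"] = direction
    return out


def deg_sets(records: pd.DataFrame) -> Tuple[Set[str], Set[str]]:
    """(down, up) gene-id sets from a direction-annotated table."""
    down = set(records.index[records["direction"] == "down"])
    up = set(records.index[records["direction"] == "up"])
    return down, up


def allelic_deg_pipeline(
    maternal_counts: pd.DataFrame,
    paternal_counts: pd.DataFrame,
    condition: Sequence[str],
    maternal_tpm: Optional[pd.DataFrame] = None,
    paternal_tpm: Optional[pd.DataFrame] = None,
    min_tpm: float = 1.0,
    masked_paternal: Iterable[str] = (),
    alpha: float = 0.05,
    fc_min: float = 1.5,
    exclude: Iterable[str] = (),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Run the NB test independently on maternal and paternal allelic counts.

    Genes whose allelic TPM stays below ``min_tpm`` in every sample of the
    contrast are removed from that allele's test (post filter), as are
    masked X-paternal entries.  Size factors are allele-specific.
    """
    results = []
    for counts, tpm, masked in (
        (maternal_counts, maternal_tpm, ()),
        (paternal_counts, paternal_tpm, masked_paternal),
    ):
        keep = counts.index
        if tpm is not None:
            keep = keep.intersection(tpm.index[(tpm >= min_tpm).any(axis=1)])
        keep = keep.difference(pd.Index(masked))
        res = nb_wald_test(counts.loc[keep], condition)
        results.append(call_degs(res, alpha=alpha, fc_min=fc_min, exclude=exclude))
    return results[0], results[1]


GROUPS_DOWN = ("A", "B", "C")
GROUPS_UP = ("D", "E", "F")


def classify_groups(
    maternal: pd.DataFrame, paternal: pd.DataFrame
) -> pd.DataFrame:
    """Allelic group labels from direction-annotated maternal/paternal tables.

    Down: A = maternal only, B = paternal only, C = both alleles.
    Up:   D = maternal only, E = paternal only, F = both alleles.
    A gene may carry one down group and one up group simultaneously.
    """
    mat_down, mat_up = deg_sets(maternal)
    pat_down, pat_up = deg_sets(paternal)
    genes = sorted(mat_down | mat_up | pat_down | pat_up)
    rows = []
    for gene in genes:
        down = _group_of(gene in mat_down, gene in pat_down, GROUPS_DOWN)
        up = _group_of(gene in mat_up, gene in pat_up, GROUPS_UP)
        rows.append({"gene_id": gene, "down_group": down, "up_group": up})
    table = pd.DataFrame(rows, columns=["gene_id", "down_group", "up_group"])
    return table.set_index("gene_id")


def _group_of(on_maternal: bool, on_paternal: bool, names) -> str:
    if on_maternal and on_paternal:
        return names[2]
    if on_maternal:
        return names[0]
    if on_paternal:
        return names[1]
    return "none"


def group_counts(labels: pd.DataFrame) -> Dict[str, int]:
    counts = {}
    for name in GROUPS_DOWN:
        counts[name] = int((labels["down_group"] == name).sum())
    for name in GROUPS_UP:
        counts[name] = int((labels["up_group"] == name).sum())
    return counts


def round_half_up_percent(numerator: float, denominator: float) -> int:
    if denominator == 0:
        raise ZeroDivisionError("empty denominator in percentage")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def allele_specific_summary(counts: Mapping[str, int]) -> Dict[str, Dict]:
    """Contingency-style accounting of allelic DEG groups.

    For the down set {A, B, C}, the allele-specific fraction is
    (A+B)/(A+B+C); symmetrically (D+E)/(D+E+F) for the up set.
    """
    summary = {}
    for direction, names in (("down", GROUPS_DOWN), ("up", GROUPS_UP)):
        specific = counts[names[0]] + counts[names[1]]
        total = specific + counts[names[2]]
        entry = {
            "groups": {n: counts[n] for n in names},
            "total": total,
            "allele_specific": specific,
        }
        if total:
            entry["allele_specific_percent"] = round_half_up_percent(
                specific, total
            )
        summary[direction] = entry
    return summary


def relaxed_fold_overlap(
    means_by_cross: Mapping[str, Tuple[pd.Series, pd.Series]],
    fc_min: float = 1.25,
    floor: float = LFC_PSEUDOCOUNT,
) -> Dict[str, Set[str]]:
    """Fold-change-only comparison across reciprocal crosses.

    ``means_by_cross`` maps cross -> (wt_mean_tpm, ko_mean_tpm) on a shared
    gene index (apply the >1 TPM expression filter beforehand).  Per cross,
    down = {wt/ko >= fc_min} and up = {ko/wt >= fc_min}; the denominator is
    floored at ``floor`` TPM so ratios at zero stay finite.  Returns per-cross
    sets plus their intersections under keys 'shared_down' / 'shared_up'.
    """
    out: Dict[str, Set[str]] = {}
    down_sets, up_sets = [], []
    for cross, (wt_mean, ko_mean) in means_by_cross.items():
        wt_mean, ko_mean = wt_mean.align(ko_mean, join="inner")
        down_ratio = wt_mean / ko_mean.clip(lower=floor)
        up_ratio = ko_mean / wt_mean.clip(lower=floor)
        down = set(wt_mean.index[down_ratio >= fc_min])
        up = set(wt_mean.index[up_ratio >= fc_min])
        out[f"{cross}_down"] = down
        out[f"{cross}_up"] = up
        down_sets.append(down)
        up_sets.append(up)
    out["shared_down"] = set.intersection(*down_sets) if down_sets else set()
    out["shared_up"] = set.intersection(*up_sets) if up_sets else set()
    return out
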
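"""Sex-biased expression calls and their loss or gain after knockout.

A gene is sex-biased in wild type when its mean TPM differs at least twofold
between female and male replicates with a two-sided Student's t-test p <= 0.05.
After knockout of the male clones, a wild-type-biased gene whose cross-sex
fold change (female wt vs male KO, in the direction of the wild-type bias)
drops below twofold has *lost* its bias — a fold-only criterion.  A *gain* in
a previously unbiased gene requires the full biased criterion (fold and p) on
the post-KO comparison.  Quantile normalization supports comparisons against
externally processed wild-type matrices.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import round_half_up_percent

FOLD_PSEUDOCOUNT = 0.5  # TPM added to means before ratios, guards zeros


def _fold(mean_hi: np.ndarray, mean_lo: np.ndarray) -> np.ndarray:
    return (mean_hi + FOLD_PSEUDOCOUNT) / (mean_lo + FOLD_PSEUDOCOUNT)


def call_sex_biased(
    tpm_female: pd.DataFrame,
    tpm_male: pd.DataFrame,
    fold_min: float = 2.0,
    p_max: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Sex-bias status per gene from replicate TPM matrices (genes x reps).

    Returns a DataFrame with mean_tpm_female, mean_tpm_male, fold (max/min
    ratio of means), p_value, and status_wt in {female-biased, male-biased,
    unbiased}.
    """
    if tpm_female.shape[1] < 2 or tpm_male.shape[1] < 2:
        raise ValueError("need >=2 replicates per sex for the t-test")
    tpm_female, tpm_male = tpm_female.align(tpm_male, join="inner", axis=0)
    f = tpm_female.to_numpy(dtype=float)
    m = tpm_male.to_numpy(dtype=float)
    mean_f, mean_m = f.mean(axis=1), m.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance genes yield NaN t statistics; treated as p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(f, m, axis=1, equal_var=not welch)
    p = np.where(np.isnan(p), 1.0, p)
    hi = np.maximum(mean_f, mean_m)
    lo = np.minimum(mean_f, mean_m)
    fold = _fold(hi, lo)
    biased = (fold >= fold_min) & (p <= p_max)
    status = np.where(
        biased & (mean_f > mean_m),
        "female-biased",
        np.where(biased & (mean_m > mean_f), "male-biased", "unbiased"),
    )
    out = pd.DataFrame(
        {
            "mean_tpm_female": mean_f,
            "mean_tpm_male": mean_m,
            "fold": fold,
            "p_value": p,
            "status_wt": status,
        },
        index=tpm_female.index,
    )
    out.index.name = "gene_id"
    return out


def loss_after_ko(
    records: pd.DataFrame,
    tpm_female_wt: pd.DataFrame,
    tpm_male_ko: pd.DataFrame,
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Mark wild-type-biased genes as lost or retained after male KO.

    Fold-only rule: a female-biased gene is lost when female-wt over male-KO
    mean TPM falls below ``fold_min``; a male-biased gene symmetrically when
    male-KO over female-wt falls below it.  Unbiased genes get status 'n/a'.
    """
    records = records.copy()
    tpm_female_wt, tpm_male_ko = tpm_female_wt.align(
        tpm_male_ko, join="inner", axis=0
    )
    mean_f = tpm_female_wt.mean(axis=1).reindex(records.index)
    mean_m_ko = tpm_male_ko.mean(axis=1).reindex(records.index)
    status_ko = pd.Series("n/a", index=records.index, dtype=object)
    female = records["status_wt"] == "female-biased"
    male = records["status_wt"] == "male-biased"
    fold_f = _fold(mean_f.to_numpy(), mean_m_ko.to_numpy())
    fold_m = _fold(mean_m_ko.to_numpy(), mean_f.to_numpy())
    status_ko[female] = np.where(fold_f[female] < fold_min, "lost", "retained")
    status_ko[male] = np.where(fold_m[male] < fold_min, "lost", "retained")
    records["status_ko"] = status_ko
    return records


def gain_after_ko(
    records: pd.DataFrame,
    tpm_female_wt: pd.DataFrame,
    tpm_male_ko: pd.DataFrame,
    fold_min: float = 2.0,
    p_max: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Mark previously unbiased genes that become sex-biased after male KO.

    Applies the full biased criterion (fold and t-test p) to female wt versus
    male KO; assigns gained_female / gained_male accordingly.
    """
    records = records.copy()
    if "status_ko" not in records.columns:
        records["status_ko"] = "n/a"
    unbiased = records.index[records["status_wt"] == "unbiased"]
    post = call_sex_biased(
        tpm_female_wt.reindex(unbiased),
        tpm_male_ko.reindex(unbiased),
        fold_min=fold_min,
        p_max=p_max,
        welch=welch,
    )
    gained = post["status_wt"].map(
        {"female-biased": "gained_female", "male-biased": "gained_male"}
    )
    gained = gained[gained.notna()]
    records.loc[gained.index, "status_ko"] = gained
    return records


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force identical value distributions across columns, preserving ranks.

    Each column's sorted values are replaced by the per-rank mean across
    columns; ties within a column share the mean of their would-be quantile
    values (average ranks).  A single-column matrix is returned unchanged.
    """
    if matrix.isna().any().any():
        raise ValueError("quantile normalization requires complete data")
    if matrix.shape[1] < 2:
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    n = values.shape[0]
    rank_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, positions, rank_means)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def call_allelic_bias_wt(
    tpm_maternal: pd.DataFrame,
    tpm_paternal: pd.DataFrame,
    fold_min: float = 2.0,
) -> pd.DataFrame:
    """Allelic bias calls in wild type: >= twofold difference between alleles.

    Input matrices are genes x wt replicates of oriented allelic TPM with
    masked genes already removed.  Returns mean allelic TPMs and
    biased_parent in {maternal, paternal, none}.
    """
    tpm_maternal, tpm_paternal = tpm_maternal.align(
        tpm_paternal, join="inner", axis=0
    )
    mean_mat = tpm_maternal.mean(axis=1)
    mean_pat = tpm_paternal.mean(axis=1)
    fold_mat = _fold(mean_mat.to_numpy(), mean_pat.to_numpy())
    fold_pat = _fold(mean_pat.to_numpy(), mean_mat.to_numpy())
    parent = np.where(
        fold_mat >= fold_min,
        "maternal",
        np.where(fold_pat >= fold_min, "paternal", "none"),
    )
    out = pd.DataFrame(
        {
            "mean_tpm_maternal": mean_mat,
            "mean_tpm_paternal": mean_pat,
            "biased_parent": parent,
        },
        index=tpm_maternal.index,
    )
    out.index.name = "gene_id"
    return out


def sex_bias_summary(records: pd.DataFrame) -> Dict[str, Dict]:
    """Contingency accounting of biased / lost / gained genes per sex.

    Percentages are lost (or gained) over wild-type biased counts, rounded
    half-up to integers; an empty biased class yields no percentage.
    """
    summary: Dict[str, Dict] = {}
    totals = {"wt": 0, "lost": 0, "gained": 0}
    for sex, biased_status, gained_status in (
        ("female", "female-biased", "gained_female"),
        ("male", "male-biased", "gained_male"),
    ):
        biased = records["status_wt"] == biased_status
        n_biased = int(biased.sum())
        n_lost = int((records.loc[biased, "status_ko"] == "lost").sum())
        n_gained = int((records["status_ko"] == gained_status).sum())
        entry: Dict = {"wt": n_biased, "lost": n_lost, "gained": n_gained}
        if n_biased:
            entry["lost_percent"] = round_half_up_percent(n_lost, n_biased)
            entry["gained_percent"] = round_half_up_percent(n_gained, n_biased)
        summary[sex] = entry
        totals["wt"] += n_biased
        totals["lost"] += n_lost
        totals["gained"] += n_gained
    total_entry: Dict = dict(totals)
    if totals["wt"]:
        total_entry["lost_percent"] = round_half_up_percent(
            totals["lost"], totals["wt"]
        )
        total_entry["gained_percent"] = round_half_up_percent(
            totals["gained"], totals["wt"]
        )
        if summary["male"]["wt"]:
            total_entry["female_male_ratio"] = round(
                summary["female"]["wt"] / summary["male"]["wt"], 1
            )
    summary["total"] = total_entry
    return summary
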
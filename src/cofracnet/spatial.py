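"""Spot-level differential expression scoring for spatial transcriptomics.

Spots are first restricted to an anatomical region with dopaminergic marker
expression and a complete neuron soma; per-gene group statistics then feed
two ranking scores,

    FCS = log2(μ_HOM / μ_WT) · (−log10 P)
    SNS = ((μ_HOM − μ_WT) / (σ_HOM + σ_WT)) · (−log10 P)

with P from a two-sided two-sample t-test (Welch by default). Genes with
P < 0.05 that rank in the top 20% by |FCS| and by |SNS| are called DEGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import SpotExpression

PSEUDOCOUNT = 1.0


@dataclass
class SelectionReport:
    n_input: int
    n_wrong_region: int
    n_no_soma: int
    n_low_marker: int
    n_selected: int


def select_spots(data: SpotExpression, region: str,
                 marker_floor: float = 1.0
                 ) -> tuple[SpotExpression, SelectionReport]:
    """Keep spots in ``region`` with a soma and all markers >= marker_floor.

    The three criteria apply conjunctively; the report logs per-criterion
    attrition. Rejects when nothing survives.
    """
    missing = [m for m in data.marker_genes if m not in data.counts.columns]
    if missing:
        raise ValueError(f"marker gene(s) absent from table: {missing}")
    in_region = data.obs["region"] == region
    has_soma = data.obs["soma_flag"].astype(bool)
    marker_ok = (data.counts[list(data.marker_genes)] >= marker_floor).all(axis=1)
    keep = in_region & has_soma & marker_ok
    report = SelectionReport(
        n_input=len(data.obs),
        n_wrong_region=int((~in_region).sum()),
        n_no_soma=int((in_region & ~has_soma).sum()),
        n_low_marker=int((in_region & has_soma & ~marker_ok).sum()),
        n_selected=int(keep.sum()))
    if report.n_selected == 0:
        raise ValueError(
            f"no spot survives selection (input {report.n_input}, wrong region "
            f"{report.n_wrong_region}, no soma {report.n_no_soma}, low marker "
            f"{report.n_low_marker})")
    return (SpotExpression(data.counts.loc[keep], data.obs.loc[keep],
                           data.marker_genes), report)


#: Fixed per-spot reference total (counts-per-10k); a fixed target — unlike
#: scaling to the median spot total — makes the whole arm exactly invariant
#: to a global rescaling of the counts.
CP10K = 1e4


def normalize_counts(counts: pd.DataFrame, mode: str = "log_cp10k"
                     ) -> pd.DataFrame:
    """Per-spot depth normalization.

    ``log_cp10k``: scale each spot to 10,000 total counts, then log2(x + 1).
    ``none``: raw counts unchanged.
    """
    if mode == "none":
        return counts.astype(float)
    if mode != "log_cp10k":
        raise ValueError(f"unknown normalization {mode!r}")
    totals = counts.sum(axis=1).astype(float)
    scaled = counts.div(totals.where(totals > 0, 1.0), axis=0) * CP10K
    return np.log2(scaled + 1.0)


def gene_stats(selected: SpotExpression, group_a: str = "WT",
               group_b: str = "HOM", normalization: str = "log_cp10k",
               test: str = "welch") -> pd.DataFrame:
    """Per-gene means, SDs and two-sided t-test P between two spot groups.

    Genes with zero variance in both groups get P = 1 (no evidence). SDs use
    the sample (ddof=1) convention.
    """
    if test not in ("welch", "student"):
        raise ValueError("test must be 'welch' or 'student'")
    expr = normalize_counts(selected.counts, normalization)
    in_a = selected.obs["group"] == group_a
    in_b = selected.obs["group"] == group_b
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError(
            f"need >= 2 spots per group; got {int(in_a.sum())} {group_a!r}, "
            f"{int(in_b.sum())} {group_b!r}")
    xa = expr.loc[in_a].to_numpy(dtype=float)
    xb = expr.loc[in_b].to_numpy(dtype=float)
    mu_a, mu_b = xa.mean(axis=0), xb.mean(axis=0)
    sd_a, sd_b = xa.std(axis=0, ddof=1), xb.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(xb, xa, axis=0, equal_var=(test == "student"))
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (sd_a == 0) & (sd_b == 0)
    p = np.where(degenerate | np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {"mu_a": mu_a, "mu_b": mu_b, "sigma_a": sd_a, "sigma_b": sd_b, "p": p},
        index=expr.columns)


def score_genes(statistics: pd.DataFrame,
                pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """Attach FCS and SNS to per-gene statistics.

    Group b plays the mutant (μ_HOM) role, group a the wild type. The
    pseudocount enters the fold-change ratio and the σ sum only when the
    respective denominator (or the ratio's numerator) is zero.
    """
    mu_a = statistics["mu_a"].to_numpy(dtype=float)
    mu_b = statistics["mu_b"].to_numpy(dtype=float)
    sd_sum = (statistics["sigma_a"] + statistics["sigma_b"]).to_numpy(dtype=float)
    p = statistics["p"].to_numpy(dtype=float)
    neg_log_p = -np.log10(p)

    zero_ratio = (mu_a == 0) | (mu_b == 0)
    num = np.where(zero_ratio, mu_b + pseudocount, mu_b)
    den = np.where(zero_ratio, mu_a + pseudocount, mu_a)
    fcs = np.log2(num / den) * neg_log_p
    safe_sd = np.where(sd_sum == 0, pseudocount, sd_sum)
    sns = (mu_b - mu_a) / safe_sd * neg_log_p

    out = statistics.copy()
    out["fcs"] = fcs
    out["sns"] = sns
    return out


def _dense_rank_desc(values: np.ndarray) -> np.ndarray:
    """Dense descending ranks (1 = largest); exact ties share a rank."""
    order = np.unique(values)[::-1]
    lookup = {v: r for r, v in enumerate(order, start=1)}
    return np.array([lookup[v] for v in values])


def call_degs(table: pd.DataFrame, p_cut: float = 0.05,
              top_frac: float = 0.20, signed: bool = False) -> list[str]:
    """Dual top-quantile DEG call.

    A gene is flagged iff P < p_cut and it ranks within the top
    ceil(top_frac · N) genes by |FCS| and, independently, by |SNS|
    (raw signed scores when ``signed``). Ranks are dense; ties share a rank.
    """
    if table.empty:
        raise ValueError("empty score table")
    n = len(table)
    cutoff = math.ceil(top_frac * n)
    fcs = table["fcs"].to_numpy(dtype=float)
    sns = table["sns"].to_numpy(dtype=float)
    if not signed:
        fcs, sns = np.abs(fcs), np.abs(sns)
    rank_f = _dense_rank_desc(fcs)
    rank_s = _dense_rank_desc(sns)
    flag = (table["p"].to_numpy() < p_cut) & (rank_f <= cutoff) & (rank_s <= cutoff)
    return [g for g, f in zip(table.index, flag) if f]


def deg_pipeline(data: SpotExpression, region: str = "SN",
                 marker_floor: float = 1.0, group_a: str = "WT",
                 group_b: str = "HOM", normalization: str = "log_cp10k",
                 test: str = "welch", p_cut: float = 0.05,
                 top_frac: float = 0.20) -> tuple[pd.DataFrame, list[str]]:
    """Selection -> stats -> scores -> DEG call, in one step."""
    selected, _ = select_spots(data, region, marker_floor)
    statistics = gene_stats(selected, group_a, group_b, normalization, test)
    table = score_genes(statistics)
    degs = call_degs(table, p_cut=p_cut, top_frac=top_frac)
    table = table.copy()
    table["deg_flag"] = table.index.isin(degs)
    return table, degs
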
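"""Genotype-environment association at SNP and gene level.

Three stages:

1. :func:`population_allele_frequencies` — per-population frequencies of the
   globally defined minor allele.
2. :func:`spearman_scan` — rank correlations of those frequencies with every
   (climate variable, period) column, two-sided p from the t approximation
   with mid-rank ties.
3. :func:`gene_outlier_test` — per gene, the count of climate-significant
   SNPs against the 0.9999 quantile of its binomial expectation under a
   pooled significant-SNP rate (genes with zero significant SNPs are
   excluded from the rate, following the top-candidate convention), and
   :func:`select_top_candidates` — the combination rule with external
   bayescenv/baypass calls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .popgen import MISSING

__all__ = [
    "population_allele_frequencies",
    "spearman_scan",
    "gene_outlier_test",
    "select_top_candidates",
]


def population_allele_frequencies(dataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP x population minor-allele frequencies and allele-copy counts.

    A population with no genotyped individual at a SNP yields NaN (the cell
    is excluded pairwise from downstream correlations).
    """
    G = dataset.genotypes
    pop_idx = dataset.population_indices()
    freqs = {}
    counts = {}
    for pop, idx in pop_idx.items():
        sub = G[:, idx]
        obs = sub != MISSING
        copies = 2 * obs.sum(axis=1)
        minor = np.where(obs, sub, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[pop] = np.where(copies > 0, minor / copies, np.nan)
        counts[pop] = copies
    index = dataset.snp_meta["snp_id"]
    return (pd.DataFrame(freqs, index=index),
            pd.DataFrame(counts, index=index))


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1, method="average")


def _t_pvalue(rho: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Two-sided p for Spearman's rho via the t approximation; |rho| = 1 maps
    to p = 0 by convention."""
    rho = np.asarray(rho, dtype=float)
    m = np.asarray(m, dtype=float)
    p = np.full(rho.shape, np.nan)
    ok = np.isfinite(rho) & (m > 2)
    unit = ok & (np.abs(rho) >= 1.0 - 1e-15)
    p[unit] = 0.0
    mid = ok & ~unit
    t = rho[mid] * np.sqrt((m[mid] - 2.0) / (1.0 - rho[mid] ** 2))
    p[mid] = 2.0 * stats.t.sf(np.abs(t), df=m[mid] - 2.0)
    return p


def spearman_scan(freqs: pd.DataFrame, climate: pd.DataFrame,
                  alpha: float = 0.01, min_populations: int = 4) -> pd.DataFrame:
    """Spearman scan of every SNP against every (variable, period) column.

    Populations are matched by label; cells missing on either side are
    dropped pairwise. SNP-column pairs with fewer than ``min_populations``
    usable populations, or with zero variance in the frequencies, are
    emitted as untested. Returns a long DataFrame with columns snp_id,
    variable, period, rho, p_value, n_pops, tested, significant.
    """
    pops = [p for p in climate.index if p in freqs.columns]
    F = freqs[pops].to_numpy(dtype=float)
    C = climate.loc[pops].to_numpy(dtype=float)
    col_keys = list(climate.columns)

    frames = []
    complete = ~np.isnan(F).any(axis=1)
    for j, key in enumerate(col_keys):
        c = C[:, j]
        c_ok = ~np.isnan(c)
        out_rho = np.full(F.shape[0], np.nan)
        out_p = np.full(F.shape[0], np.nan)
        out_m = np.zeros(F.shape[0], dtype=int)

        batch = complete if c_ok.all() else np.zeros(F.shape[0], dtype=bool)
        if batch.any():
            rf = _rank_rows(F[batch])
            rc = _rank_rows(c)
            rf_c = rf - rf.mean(axis=1, keepdims=True)
            rc_c = rc - rc.mean()
            denom = np.sqrt((rf_c**2).sum(axis=1) * (rc_c**2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                rho = np.where(denom > 0, rf_c @ rc_c / denom, np.nan)
            out_rho[batch] = rho
            out_m[batch] = len(pops)

        for i in np.flatnonzero(~batch):
            mask = ~np.isnan(F[i]) & c_ok
            m = int(mask.sum())
            out_m[i] = m
            if m < min_populations:
                continue
            x, y = F[i, mask], c[mask]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            rho = np.corrcoef(rx, ry)[0, 1]
            out_rho[i] = rho

        out_p = _t_pvalue(out_rho, out_m)
        tested = np.isfinite(out_rho) & (out_m >= min_populations)
        frames.append(pd.DataFrame({
            "snp_id": freqs.index,
            "variable": key[0],
            "period": key[1],
            "rho": out_rho,
            "p_value": out_p,
            "n_pops": out_m,
            "tested": tested,
            "significant": tested & (out_p < alpha),
        }))
    return pd.concat(frames, ignore_index=True)


def gene_outlier_test(assoc: pd.DataFrame, gene_map: pd.Series | dict,
                      quantile: float = 0.9999,
                      pool_rule: str = "pooled") -> pd.DataFrame:
    """Binomial outlier test for genes enriched in climate-significant SNPs.

    For each (variable, period) column: per gene, ``n`` tested SNPs and
    ``a`` significant ones; the expected rate ``P`` pools genes with at
    least one significant SNP (``pool_rule='pooled'``: sum(a)/sum(n);
    ``'mean-ratio'``: mean of a/n). A gene is flagged when ``a`` strictly
    exceeds the smallest integer q with BinomialCDF(q; n, P) >= ``quantile``.
    Genes with a = 0 are reported unflagged so totals reconcile; columns with
    no significant SNP anywhere get status ``inapplicable``.
    """
    if pool_rule not in ("pooled", "mean-ratio"):
        raise ValueError("pool_rule must be 'pooled' or 'mean-ratio'")
    gm = pd.Series(gene_map)
    df = assoc[assoc["tested"]].copy()
    df["gene_id"] = df["snp_id"].map(gm)
    if df["gene_id"].isna().any():
        bad = sorted(df.loc[df["gene_id"].isna(), "snp_id"].unique())[:5]
        raise ValueError(f"tested SNP(s) without gene assignment, e.g. {bad}")

    rows = []
    for (var, period), sub in df.groupby(["variable", "period"], sort=True):
        per_gene = sub.groupby("gene_id")["significant"].agg(["size", "sum"])
        per_gene.columns = ["n", "a"]
        with_hits = per_gene[per_gene["a"] > 0]
        if with_hits.empty:
            for gene, r in per_gene.iterrows():
                rows.append((gene, var, period, int(r["n"]), 0, np.nan,
                             np.nan, False, "inapplicable"))
            continue
        if pool_rule == "pooled":
            P = float(with_hits["a"].sum() / with_hits["n"].sum())
        else:
            P = float((with_hits["a"] / with_hits["n"]).mean())
        q = stats.binom.ppf(quantile, per_gene["n"].to_numpy(), P)
        for (gene, r), q_i in zip(per_gene.iterrows(), q):
            rows.append((gene, var, period, int(r["n"]), int(r["a"]), P,
                         int(q_i), bool(r["a"] > q_i), "ok"))
    return pd.DataFrame(rows, columns=[
        "gene_id", "variable", "period", "n_snps", "a_significant",
        "expected_rate", "q_threshold", "flagged", "status"])


def select_top_candidates(gene_flags: pd.DataFrame,
                          external_calls: pd.DataFrame | None,
                          gene_map: pd.Series | dict,
                          min_snps: int = 2,
                          match_period: bool = True) -> pd.DataFrame:
    """Combination rule: keep flagged genes confirmed by external methods.

    A gene flagged for a (variable, period) is retained when at least
    ``min_snps`` distinct SNPs of that gene are significant for the same
    variable (and same period unless ``match_period`` is False) in at least
    one of the external methods (bayescenv / baypass, pooled per SNP with OR
    semantics). Without an external table, flags are passed through with
    status ``unconfirmed``.
    """
    flagged = gene_flags[gene_flags["flagged"]].copy()
    if external_calls is None:
        flagged["n_snps_external"] = np.nan
        flagged["n_snps_baypass"] = np.nan
        flagged["n_snps_bayescenv"] = np.nan
        flagged["retained"] = False
        flagged["status"] = "unconfirmed"
        return flagged.reset_index(drop=True)

    gm = pd.Series(gene_map)
    calls = external_calls[external_calls["significant"]].copy()
    calls["gene_id"] = calls["snp_id"].map(gm)
    keys = ["gene_id", "variable", "period"] if match_period \
        else ["gene_id", "variable"]

    def count_distinct(sub_calls: pd.DataFrame) -> pd.DataFrame:
        grp = sub_calls.groupby(keys)["snp_id"].nunique().rename("count")
        return grp.reset_index()

    pooled = count_distinct(calls)
    per_method = {m: count_distinct(calls[calls["method"] == m])
                  for m in ("baypass", "bayescenv")}

    def lookup(table: pd.DataFrame, row) -> int:
        sel = (table["gene_id"] == row.gene_id) & (table["variable"] == row.variable)
        if match_period:
            sel &= table["period"] == row.period
        hit = table.loc[sel, "count"]
        return int(hit.iloc[0]) if len(hit) else 0

    out = []
    for row in flagged.itertuples(index=False):
        n_ext = lookup(pooled, row)
        out.append({
            "gene_id": row.gene_id,
            "variable": row.variable,
            "period": row.period,
            "gene_level_count": row.a_significant,
            "n_snps_external": n_ext,
            "n_snps_baypass": lookup(per_method["baypass"], row),
            "n_snps_bayescenv": lookup(per_method["bayescenv"], row),
            "retained": n_ext >= min_snps,
            "status": "ok",
        })
    return pd.DataFrame(out, columns=[
        "gene_id", "variable", "period", "gene_level_count",
        "n_snps_external", "n_snps_baypass", "n_snps_bayescenv",
        "retained", "status"])
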
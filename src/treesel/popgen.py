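"""Sequence diversity, neutrality tests, inbreeding, and relatedness.

Implements the per-gene / per-region summary statistics used throughout the
pipeline: nucleotide diversity by site class (all / synonymous /
nonsynonymous) with fractional Nei-Gojobori site weights, segregating-site and
singleton counts, Tajima's D, the outgroup-free (starred) Fu & Li D* and F*,
per-individual method-of-moments inbreeding coefficients, and the unadjusted
pairwise relatedness statistic A_jk of Yang et al.

All statistics operate on allele *copies*: an unphased diploid contributes two
copies per site, and no formula here requires phase. Missing copies are coded
with :data:`MISSING`; every per-site quantity is computed on the copies
actually observed at that site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

MISSING: int = -1

__all__ = [
    "MISSING",
    "SiteAlignment",
    "DiversityResult",
    "NeutralityResult",
    "RelatednessResult",
    "nucleotide_diversity",
    "diversity_summary",
    "site_spectrum_counts",
    "tajimas_d",
    "fu_li_star",
    "neutrality_tests",
    "classify_coding_sites",
    "inbreeding_coefficient",
    "pairwise_relatedness_ajk",
    "region_summary",
    "pa_ps_ratio",
    "polymorphic_percentage",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SiteAlignment:
    """Allele matrix of ``2N`` copies x ``L`` sites for one gene.

    Sites include monomorphic positions so that per-site diversity has the
    correct denominator. ``w_syn``/``w_nonsyn`` are fractional site-class
    weights in [0, 1] (Nei-Gojobori style); the implicit remainder
    ``1 - w_syn - w_nonsyn`` is the "other" class (introns, UTRs, ...).
    When omitted, every site is "other" and only the all-sites class is
    meaningful.
    """

    gene_id: str
    alleles: np.ndarray  # (n_copies, L) int8, MISSING for no call
    positions: np.ndarray | None = None
    w_syn: np.ndarray | None = None
    w_nonsyn: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D (copies x sites)")
        L = self.alleles.shape[1]
        for name in ("w_syn", "w_nonsyn"):
            w = getattr(self, name)
            if w is not None:
                w = np.asarray(w, dtype=float)
                if w.shape != (L,):
                    raise ValueError(f"{name} must have one weight per site")
                setattr(self, name, w)
        if self.w_syn is not None and self.w_nonsyn is not None:
            tot = self.w_syn + self.w_nonsyn
            with np.errstate(invalid="ignore"):
                bad = np.nan_to_num(tot) > 1 + 1e-9
            if bad.any():
                raise ValueError("w_syn + w_nonsyn exceeds 1 at some sites")

    @property
    def n_copies(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def class_weights(self, site_class: str) -> np.ndarray:
        """Per-site weights for ``site_class`` in {all, syn, nonsyn, other}."""
        L = self.n_sites
        if site_class == "all":
            return np.ones(L)
        syn = self.w_syn if self.w_syn is not None else np.zeros(L)
        nonsyn = self.w_nonsyn if self.w_nonsyn is not None else np.zeros(L)
        if site_class == "syn":
            return np.nan_to_num(syn)
        if site_class == "nonsyn":
            return np.nan_to_num(nonsyn)
        if site_class == "other":
            return 1.0 - np.nan_to_num(syn) - np.nan_to_num(nonsyn)
        raise ValueError(f"unknown site class {site_class!r}")


@dataclass
class DiversityResult:
    pi_all: float
    pi_syn: float
    pi_nonsyn: float
    pa_ps: float
    S: int
    eta: int
    eta_s: int
    n_eff: int
    accessible_all: float
    accessible_syn: float
    accessible_nonsyn: float


@dataclass
class NeutralityResult:
    tajima_d: float
    fu_li_d_star: float
    fu_li_f_star: float
    n_used: int
    defined: bool


@dataclass
class RelatednessResult:
    individuals: list[str]
    ajk: np.ndarray  # N x N; diagonal is the 1 + F variant
    inbreeding: np.ndarray  # per-individual F (method of moments)

    @property
    def mean_off_diagonal(self) -> float:
        n = self.ajk.shape[0]
        if n < 2:
            return np.nan
        off = self.ajk[~np.eye(n, dtype=bool)]
        return float(np.nanmean(off))


# ---------------------------------------------------------------------------
# per-site machinery
# ---------------------------------------------------------------------------

def _allele_counts(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts per allele code per site -> (counts (K, L), n_nonmissing (L,))."""
    obs = alleles >= 0
    n_j = obs.sum(axis=0)
    if alleles.size == 0:
        return np.zeros((0, alleles.shape[1]), dtype=np.int64), n_j
    kmax = int(alleles.max(initial=0))
    counts = np.stack([(alleles == k).sum(axis=0) for k in range(kmax + 1)]) \
        if kmax >= 0 else np.zeros((0, alleles.shape[1]), dtype=np.int64)
    return counts, n_j


def _per_site_het(counts: np.ndarray, n_j: np.ndarray) -> np.ndarray:
    """Unbiased per-site heterozygosity h_j = n/(n-1) (1 - sum (c/n)^2).

    Sites with fewer than two observed copies get NaN.
    """
    h = np.full(n_j.shape, np.nan)
    ok = n_j >= 2
    if not ok.any():
        return h
    n = n_j[ok].astype(float)
    freq_sq = (counts[:, ok] / n) ** 2
    h[ok] = n / (n - 1.0) * (1.0 - freq_sq.sum(axis=0))
    return h


def nucleotide_diversity(aln: SiteAlignment, site_class: str = "all") -> tuple[float, float]:
    """Per-site nucleotide diversity pi for a site class.

    Returns ``(pi, accessible)`` where ``accessible`` is the summed class
    weight over sites with >= 2 observed copies (the denominator, monomorphic
    sites included). ``pi`` is NaN when no site of the class is accessible.
    """
    counts, n_j = _allele_counts(aln.alleles)
    h = _per_site_het(counts, n_j)
    w = aln.class_weights(site_class)
    ok = n_j >= 2
    accessible = float(w[ok].sum())
    if accessible == 0:
        return np.nan, 0.0
    pi = float(np.nansum(h[ok] * w[ok]) / accessible)
    return pi, accessible


def site_spectrum_counts(aln: SiteAlignment) -> tuple[int, int, int, int]:
    """(S, eta, eta_s, n_eff) over the alignment.

    S counts sites with >= 2 alleles among observed copies; eta is the minimum
    mutation count under infinite sites, sum of (alleles - 1) per site; eta_s
    counts singleton alleles (count exactly 1) at polymorphic sites, each one
    contributing 1 even at multi-allelic sites; n_eff is the maximum number of
    observed copies over sites.
    """
    counts, n_j = _allele_counts(aln.alleles)
    if counts.size == 0:
        return 0, 0, 0, int(n_j.max(initial=0))
    n_alleles = (counts > 0).sum(axis=0)
    poly = n_alleles >= 2
    S = int(poly.sum())
    eta = int((n_alleles[poly] - 1).sum()) if S else 0
    eta_s = int((counts[:, poly] == 1).sum()) if S else 0
    return S, eta, eta_s, int(n_j.max(initial=0))


def _pi_sum(aln: SiteAlignment) -> float:
    """Sum over sites of per-site heterozygosity (the mean pairwise diff)."""
    counts, n_j = _allele_counts(aln.alleles)
    h = _per_site_het(counts, n_j)
    return float(np.nansum(h))


def diversity_summary(aln: SiteAlignment) -> DiversityResult:
    pi_all, acc_all = nucleotide_diversity(aln, "all")
    pi_syn, acc_syn = nucleotide_diversity(aln, "syn")
    pi_nonsyn, acc_nonsyn = nucleotide_diversity(aln, "nonsyn")
    S, eta, eta_s, n_eff = site_spectrum_counts(aln)
    return DiversityResult(
        pi_all=pi_all, pi_syn=pi_syn, pi_nonsyn=pi_nonsyn,
        pa_ps=pa_ps_ratio(pi_nonsyn, pi_syn),
        S=S, eta=eta, eta_s=eta_s, n_eff=n_eff,
        accessible_all=acc_all, accessible_syn=acc_syn,
        accessible_nonsyn=acc_nonsyn,
    )


def pa_ps_ratio(pi_nonsyn: float, pi_syn: float) -> float:
    """Nonsynonymous-to-synonymous diversity ratio; NaN when pi_syn is 0."""
    if not np.isfinite(pi_syn) or pi_syn == 0 or not np.isfinite(pi_nonsyn):
        return np.nan
    return pi_nonsyn / pi_syn


def polymorphic_percentage(n_region: int, n_total: int) -> float:
    """Region polymorphic-site count as a percentage of the full SNP panel."""
    return 100.0 * n_region / n_total


# ---------------------------------------------------------------------------
# neutrality tests
# ---------------------------------------------------------------------------

def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def tajimas_d(n: int, S: int, pi_sum: float) -> float:
    """Tajima's D from sample size (allele copies), S, and summed pairwise
    heterozygosity. NaN when undefined (S = 0 or n < 4)."""
    if S == 0 or n < 4:
        return np.nan
    a1, a2 = _harmonics(n)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((pi_sum - S / a1) / np.sqrt(var))


def fu_li_star(n: int, eta: int, eta_s: int, pi_sum: float) -> tuple[float, float]:
    """Outgroup-free Fu & Li D* and F*.

    Uses the corrected coefficient expressions adopted by mainstream
    implementations (the original 1993 publication contains documented
    typos); the normalization was verified here by neutral-coalescent
    calibration (mean ~ 0, variance ~ 1). Returns (NaN, NaN) when eta = 0 or
    n < 4.
    """
    if eta == 0 or n < 4:
        return np.nan, np.nan
    an, bn = _harmonics(n)
    an1 = an + 1.0 / n  # a_{n+1}

    cn = 2.0 * (n * an - 2.0 * (n - 1.0)) / ((n - 1.0) * (n - 2.0))
    dn = cn + (n - 2.0) / (n - 1.0) ** 2 \
        + (2.0 / (n - 1.0)) * (1.5 - (2.0 * an1 - 3.0) / (n - 2.0) - 1.0 / n)
    v_d = ((n / (n - 1.0)) ** 2 * bn + an**2 * dn
           - 2.0 * (n * an * (an + 1.0)) / (n - 1.0) ** 2) / (an**2 + bn)
    u_d = (n / (n - 1.0)) * (an - n / (n - 1.0)) - v_d
    d_star = ((n / (n - 1.0)) * eta - an * eta_s) / np.sqrt(u_d * eta + v_d * eta**2)

    v_f = ((2.0 * n**3 + 110.0 * n**2 - 255.0 * n + 153.0) / (9.0 * n**2 * (n - 1.0))
           + 2.0 * (n - 1.0) * an / n**2 - 8.0 * bn / n) / (an**2 + bn)
    u_f = ((4.0 * n**2 + 19.0 * n + 3.0 - 12.0 * (n + 1.0) * an1)
           / (3.0 * n * (n - 1.0))) / an - v_f
    f_star = (pi_sum - ((n - 1.0) / n) * eta_s) / np.sqrt(u_f * eta + v_f * eta**2)
    return float(d_star), float(f_star)


def _modal_n(aln: SiteAlignment) -> int:
    _, n_j = _allele_counts(aln.alleles)
    n_j = n_j[n_j >= 2]
    if n_j.size == 0:
        return 0
    counts = np.bincount(n_j)
    # ties broken toward the larger sample size
    return int(np.flatnonzero(counts == counts.max())[-1])


def neutrality_tests(aln: SiteAlignment, n_mode: str = "modal") -> NeutralityResult:
    """Tajima's D and Fu & Li's D*/F* for an alignment.

    The classical formulas assume a fixed number of sampled copies; with
    missing data, ``n`` is taken as the modal (default) or maximal per-site
    observed copy count.
    """
    S, eta, eta_s, n_eff = site_spectrum_counts(aln)
    n = _modal_n(aln) if n_mode == "modal" else n_eff
    pi_sum = _pi_sum(aln)
    d = tajimas_d(n, S, pi_sum)
    dstar, fstar = fu_li_star(n, eta, eta_s, pi_sum)
    return NeutralityResult(
        tajima_d=d, fu_li_d_star=dstar, fu_li_f_star=fstar,
        n_used=n, defined=S > 0 and n >= 4,
    )


# ---------------------------------------------------------------------------
# coding-site classification (Nei-Gojobori fractional site counts)
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def classify_coding_sites(cds_sequence: str, frame: int = 0,
                          genetic_code: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Fractional synonymous/nonsynonymous weights per coding site.

    For each position of each codon, ``w_syn`` is the fraction of the three
    possible single-base changes that leave the encoded amino acid unchanged
    (changes to or from stop codons count as nonsynonymous unless both are
    stops); ``w_nonsyn = 1 - w_syn``. Positions before ``frame`` or in a
    trailing partial codon, and codons containing ambiguity codes, get NaN
    weights.
    """
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    fwd = table.forward_table
    stops = set(table.stop_codons)

    def aa(codon: str) -> str:
        return "*" if codon in stops else fwd[codon]

    seq = cds_sequence.upper()
    L = len(seq)
    w_syn = np.full(L, np.nan)
    w_nonsyn = np.full(L, np.nan)
    n_codons = (L - frame) // 3
    if (L - frame) % 3 != 0:
        warnings.warn("coding length not a multiple of 3; trailing bases ignored")
    for c in range(n_codons):
        start = frame + 3 * c
        codon = seq[start:start + 3]
        if any(b not in _BASES for b in codon):
            warnings.warn(f"ambiguity code in codon {codon!r}; weights undefined")
            continue
        if codon in stops and c < n_codons - 1:
            warnings.warn(f"internal stop codon {codon!r} at codon {c}")
        ref_aa = aa(codon)
        for pos in range(3):
            syn = 0
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if aa(mut) == ref_aa:
                    syn += 1
            w_syn[start + pos] = syn / 3.0
            w_nonsyn[start + pos] = 1.0 - syn / 3.0
    return w_syn, w_nonsyn


# ---------------------------------------------------------------------------
# inbreeding and relatedness (genotype-matrix based)
# ---------------------------------------------------------------------------

def inbreeding_coefficient(genotypes: np.ndarray) -> np.ndarray:
    """Method-of-moments F per individual from a SNP x individual matrix of
    minor-allele copy counts (0/1/2, MISSING for no call).

    F = (O_hom - E_hom) / (M - E_hom), with E_hom summed over the
    individual's non-missing sites as 1 - 2 p (1 - p) n/(n-1), p the sample
    allele frequency and n the observed copy count at the site. NaN when the
    denominator vanishes (no informative site).
    """
    G = np.asarray(genotypes)
    obs = G != MISSING
    n_j = 2 * obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, G, 0).sum(axis=1) / n_j
    usable = n_j >= 4  # n/(n-1) needs >= 2 copies; single diploid is uninformative
    e_site = np.zeros(G.shape[0])
    nn = n_j[usable].astype(float)
    e_site[usable] = 1.0 - 2.0 * p[usable] * (1.0 - p[usable]) * nn / (nn - 1.0)

    F = np.full(G.shape[1], np.nan)
    for k in range(G.shape[1]):
        m = obs[:, k] & usable
        M = int(m.sum())
        if M == 0:
            continue
        o_hom = int(np.sum((G[m, k] == 0) | (G[m, k] == 2)))
        e_hom = float(e_site[m].sum())
        denom = M - e_hom
        if abs(denom) < 1e-12:
            continue
        F[k] = (o_hom - e_hom) / denom
    return F


def pairwise_relatedness_ajk(genotypes: np.ndarray,
                             individuals: list[str] | None = None) -> RelatednessResult:
    """Unadjusted A_jk relatedness (Yang et al. method of moments).

    Off-diagonal: mean over shared non-missing polymorphic sites of
    (x_j - 2p)(x_k - 2p) / (2p(1-p)); diagonal: the 1 + F variant
    1 + mean of (x^2 - (1+2p)x + 2p^2) / (2p(1-p)). Values are reported raw
    (no clipping). Sites with p in {0, 1} are excluded; a pair sharing no
    usable site gets NaN.
    """
    G = np.asarray(genotypes, dtype=float)
    n_snps, n_ind = G.shape
    if individuals is None:
        individuals = [f"ind{k}" for k in range(n_ind)]
    obs = G != MISSING
    n_copies = 2 * obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, G, 0).sum(axis=1) / n_copies
    poly = (n_copies > 0) & (p > 0) & (p < 1)
    d = 2.0 * p * (1.0 - p)

    X = np.where(obs, G, np.nan)[poly]
    pp = p[poly]
    dd = d[poly]
    Z = (X - 2.0 * pp[:, None]) / np.sqrt(dd)[:, None]
    W = (~np.isnan(Z)).astype(float)
    Z0 = np.nan_to_num(Z)
    num = Z0.T @ Z0
    M = W.T @ W
    with np.errstate(invalid="ignore", divide="ignore"):
        A = num / M
    # diagonal: 1 + F-variant estimator
    for k in range(n_ind):
        m = ~np.isnan(X[:, k])
        Mk = int(m.sum())
        if Mk == 0:
            A[k, k] = np.nan
            continue
        x = X[m, k]
        pk = pp[m]
        dk = dd[m]
        A[k, k] = 1.0 + np.mean((x**2 - (1.0 + 2.0 * pk) * x + 2.0 * pk**2) / dk)
    return RelatednessResult(individuals=list(individuals), ajk=A,
                             inbreeding=inbreeding_coefficient(np.asarray(genotypes)))


# ---------------------------------------------------------------------------
# Table-style regional summary
# ---------------------------------------------------------------------------

def _panel_alignment(genotypes: np.ndarray) -> SiteAlignment:
    """View a SNP x individual minor-count matrix as a 2N-copy alignment."""
    G = np.asarray(genotypes)
    n_snps, n_ind = G.shape
    copies = np.full((2 * n_ind, n_snps), MISSING, dtype=np.int8)
    obs = G != MISSING
    # copy 1 carries min(g,1), copy 2 carries max(g-1,0): 0/1/2 -> 00/10/11
    g = np.where(obs, G, 0)
    copies[0::2] = np.where(obs, np.minimum(g, 1), MISSING).T
    copies[1::2] = np.where(obs, np.maximum(g - 1, 0), MISSING).T
    return SiteAlignment(gene_id="panel", alleles=copies)


def region_summary(dataset, regions: Mapping[str, str] | None = None,
                   total_length: float | Mapping[str, float] | None = None,
                   include_all: bool = True) -> pd.DataFrame:
    """Diversity / neutrality / inbreeding summary rows per geographic region.

    ``regions`` maps population labels to region names (default: each
    population is its own region). ``total_length`` supplies the surveyed
    length in bp (scalar, or per-region mapping keyed by region name with an
    ``"All"`` entry); when given, per-site diversities use it as denominator,
    otherwise the SNP-panel site count is used. Site classes come from
    ``dataset.snp_meta['site_class']`` when present.

    Percentage of polymorphic sites is relative to the full SNP panel.
    """
    meta = dataset.snp_meta
    classes = meta["site_class"] if "site_class" in meta.columns else None
    pops = pd.Series(dataset.popmap)
    if regions is None:
        regions = {p: p for p in pops.unique()}
    sample_region = pops.map(dict(regions))
    if sample_region.isna().any():
        missing = sorted(pops[sample_region.isna()].unique())
        raise ValueError(f"populations without a region mapping: {missing}")

    groups: dict[str, list[str]] = {}
    for s in dataset.samples:
        groups.setdefault(sample_region[s], []).append(s)
    order = sorted(groups)
    if include_all:
        groups["All"] = list(dataset.samples)
        order = order + ["All"]

    n_total = dataset.genotypes.shape[0]
    rows = []
    for region in order:
        samples = groups[region]
        idx = [dataset.samples.index(s) for s in samples]
        G = dataset.genotypes[:, idx]
        aln = _panel_alignment(G)
        if classes is not None:
            aln.w_syn = (classes.values == "syn").astype(float)
            aln.w_nonsyn = (classes.values == "nonsyn").astype(float)
        div = diversity_summary(aln)
        neut = neutrality_tests(aln)
        rel = pairwise_relatedness_ajk(G, individuals=samples) if len(samples) >= 2 else None

        L = None
        if total_length is not None:
            L = total_length.get(region) if isinstance(total_length, Mapping) else float(total_length)
        # pi_syn / pi_nonsyn keep their class-accessible denominators so the
        # pa/ps ratio stays a ratio of per-site class diversities; only the
        # all-sites diversity is re-expressed over the surveyed length when
        # one is supplied (SNP panels lack the monomorphic sites).
        pi_syn, pi_nonsyn = div.pi_syn, div.pi_nonsyn
        if L is not None and L > 0:
            pi_all = div.pi_all * div.accessible_all / L
        else:
            L = div.accessible_all
            pi_all = div.pi_all

        rows.append({
            "region": region,
            "n_individuals": len(samples),
            "length_bp": L,
            "n_polymorphic": div.S,
            "pct_polymorphic": polymorphic_percentage(div.S, n_total),
            "pi_all": pi_all,
            "pi_syn": pi_syn,
            "pi_nonsyn": pi_nonsyn,
            "pa_ps": pa_ps_ratio(pi_nonsyn, pi_syn),
            "tajima_d": neut.tajima_d,
            "fu_li_d_star": neut.fu_li_d_star,
            "fu_li_f_star": neut.fu_li_f_star,
            "mean_inbreeding_f": float(np.nanmean(rel.inbreeding)) if rel is not None else np.nan,
            "mean_relatedness_ajk": rel.mean_off_diagonal if rel is not None else np.nan,
        })
    return pd.DataFrame(rows).set_index("region")
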
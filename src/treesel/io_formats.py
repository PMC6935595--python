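"""Dataset assembly: format readers, the SNP filter cascade, and the
heterozygote-excess (paralog) screen.

The on-disk contract is deliberately boring: VCF 4.x for genotypes, TSV for
the population map / SNP-to-gene map / external association calls, CSV for
the climate table (long form: population, variable, period, value), and GMT
for gene sets. ``load_dataset`` stitches these into a single
:class:`Dataset` whose genotype matrix is expressed as copy counts of the
*globally defined minor allele* (ties at frequency 0.5 broken toward the
lexicographically smaller allele string, for reproducibility).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .popgen import MISSING

log = logging.getLogger(__name__)

__all__ = [
    "Dataset",
    "GeneSetCollection",
    "FilterReport",
    "read_popmap",
    "read_climate_csv",
    "read_gene_map",
    "read_gmt",
    "read_external_calls",
    "load_vcf",
    "load_dataset",
    "filter_sites",
    "het_excess_filter",
    "hwe_heterozygote_excess_pvalue",
]


@dataclass
class GeneSetCollection:
    """Pathway membership: set id -> sorted gene ids, with a minimum-size
    rule applied after intersecting with whatever gene universe is tested."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    min_size: int = 5

    def restricted(self, universe) -> "GeneSetCollection":
        """Intersect each set with ``universe`` and drop sets below
        ``min_size``."""
        uni = set(universe)
        kept = {sid: sorted(set(members) & uni)
                for sid, members in self.sets.items()}
        kept = {sid: m for sid, m in kept.items() if len(m) >= self.min_size}
        return GeneSetCollection(sets=kept,
                                 descriptions={k: self.descriptions.get(k, "")
                                               for k in kept},
                                 min_size=self.min_size)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class Dataset:
    """The unified in-memory bundle consumed by every downstream stage."""

    genotypes: np.ndarray            # SNP x sample minor-allele copy counts
    snp_meta: pd.DataFrame           # snp_id, gene_id, pos, ref/alt, QC fields
    samples: list[str]
    popmap: dict[str, str]
    climate: pd.DataFrame | None = None
    gene_sets: GeneSetCollection | None = None
    external_calls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.shape != (len(self.snp_meta), len(self.samples)):
            raise ValueError("genotype matrix shape does not match metadata")
        missing = [s for s in self.samples if s not in self.popmap]
        if missing:
            raise ValueError(
                f"sample(s) absent from population map: {', '.join(missing)}")
        if self.climate is not None:
            have = set(self.climate.index)
            need = set(self.popmap[s] for s in self.samples)
            absent = sorted(need - have)
            if absent:
                raise ValueError(
                    f"population(s) missing from climate table: {absent}")

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.popmap[s], None)
        return list(seen)

    def population_indices(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for k, s in enumerate(self.samples):
            out.setdefault(self.popmap[s], []).append(k)
        return {p: np.array(v) for p, v in out.items()}

    def subset(self, snp_mask: np.ndarray) -> "Dataset":
        mask = np.asarray(snp_mask)
        return replace(self,
                       genotypes=self.genotypes[mask],
                       snp_meta=self.snp_meta.loc[mask].reset_index(drop=True))


@dataclass
class FilterReport:
    """Per-rule removal accounting; a SNP failing several rules is charged to
    the first failing rule so that counts always reconcile."""

    input_count: int
    removed: dict[str, int]
    parameters: dict[str, object]

    @property
    def surviving(self) -> int:
        return self.input_count - sum(self.removed.values())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def read_alignment_fasta(path: str | Path, gene_id: str | None = None,
                         site_class_tsv: str | Path | None = None):
    """Read a per-gene FASTA alignment into a :class:`SiteAlignment`.

    Each record is one allele copy (an unphased diploid contributes two
    records); gaps and ambiguity codes become missing. An optional site-class
    TSV (columns: position 1-based, w_syn, w_nonsyn) attaches fractional
    class weights.
    """
    from Bio import SeqIO

    from .popgen import SiteAlignment

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    L = len(records[0].seq)
    if any(len(r.seq) != L for r in records):
        raise ValueError("alignment sequences differ in length")
    alleles = np.full((len(records), L), MISSING, dtype=np.int8)
    for i, rec in enumerate(records):
        for j, b in enumerate(str(rec.seq).upper()):
            alleles[i, j] = _BASE_CODES.get(b, MISSING)
    w_syn = w_nonsyn = None
    if site_class_tsv is not None:
        sc = pd.read_csv(site_class_tsv, sep="\t")
        w_syn = np.zeros(L)
        w_nonsyn = np.zeros(L)
        idx = sc["position"].to_numpy() - 1
        w_syn[idx] = sc["w_syn"].to_numpy(dtype=float)
        w_nonsyn[idx] = sc["w_nonsyn"].to_numpy(dtype=float)
    return SiteAlignment(gene_id=gene_id or Path(path).stem, alleles=alleles,
                         w_syn=w_syn, w_nonsyn=w_nonsyn)


def read_popmap(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "population"} <= set(df.columns):
        raise ValueError("popmap needs columns: sample, population")
    return dict(zip(df["sample"], df["population"]))


def read_climate_csv(path: str | Path) -> pd.DataFrame:
    """Long-form CSV (population, variable, period, value) -> wide matrix
    with a (variable, period) column MultiIndex."""
    df = pd.read_csv(path)
    need = {"population", "variable", "period", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"climate CSV needs columns: {sorted(need)}")
    wide = df.pivot_table(index="population", columns=["variable", "period"],
                          values="value")
    wide.columns.names = ["variable", "period"]
    return wide.sort_index(axis=1)


def read_gene_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    if not {"snp_id", "gene_id"} <= set(df.columns):
        raise ValueError("gene map needs columns: snp_id, gene_id")
    if "site_class" in df.columns:
        bad = set(df["site_class"].dropna()) - {"syn", "nonsyn", "other"}
        if bad:
            raise ValueError(f"unknown site classes: {sorted(bad)}")
    return df


def read_gmt(path: str | Path, min_size: int = 5) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = sorted(set(parts[2:]))
        descriptions[parts[0]] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=descriptions,
                             min_size=min_size)


# external-call significance conventions for the two consumed methods
_EXTERNAL_RULES = {
    "bayescenv": lambda score: score < 0.05,   # Q-value threshold
    "baypass": lambda score: score > 30.0,     # Bayes-factor threshold
}


def read_external_calls(path: str | Path, strict: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"snp_id", "variable", "period", "method", "significant"}
    if not need <= set(df.columns):
        raise ValueError(f"external calls need columns: {sorted(need)}")
    unknown = set(df["method"]) - set(_EXTERNAL_RULES)
    if unknown:
        raise ValueError(f"unknown association methods: {sorted(unknown)}")
    df["significant"] = df["significant"].astype(bool)
    if "score" in df.columns:
        expected = np.array([
            _EXTERNAL_RULES[m](s) if np.isfinite(s) else None
            for m, s in zip(df["method"], df["score"].astype(float))
        ], dtype=object)
        clash = [(m, s) for m, s, e, got in
                 zip(df["method"], df["score"], expected, df["significant"])
                 if e is not None and e != got]
        if clash:
            msg = (f"{len(clash)} call(s) whose significance flag contradicts "
                   f"the method threshold, e.g. {clash[0]}")
            if strict:
                raise ValueError(msg)
            warnings.warn(msg)
    return df


def load_vcf(path: str | Path) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    """Read a VCF into (minor-allele copy counts, per-SNP metadata, samples).

    Mean coverage comes from the ``MCOV`` INFO field when present, else from
    per-sample FORMAT ``DP``; allele balance from ``ABHET`` or from FORMAT
    ``AD`` at heterozygous calls (reference-read fraction). Multi-allelic
    records are retained in the metadata (``n_alt`` > 1) with their genotype
    rows masked, so the filter cascade can count them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    geno_rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    for v in vcf:
        n_alt = len(v.ALT)
        alts = v.ALT if n_alt else ["."]
        row = np.full(len(samples), MISSING, dtype=np.int8)
        coverage = v.INFO.get("MCOV")
        ab = v.INFO.get("ABHET")
        if n_alt == 1:
            alt_copies = np.full(len(samples), MISSING, dtype=np.int8)
            for k, g in enumerate(v.genotypes):
                a = [x for x in g[:2]]
                if -1 in a:
                    continue
                alt_copies[k] = int(a[0] != 0) + int(a[1] != 0)
            row = alt_copies
            if coverage is None:
                try:
                    dp = v.format("DP")
                except KeyError:
                    dp = None
                if dp is not None:
                    dp = dp.astype(float)
                    coverage = float(np.nanmean(np.where(dp < 0, np.nan, dp)))
            if ab is None:
                try:
                    ad = v.format("AD")
                except KeyError:
                    ad = None
                if ad is not None:
                    het = row == 1
                    if het.any():
                        ref_r = ad[het, 0].astype(float)
                        alt_r = ad[het, 1].astype(float)
                        tot = ref_r + alt_r
                        with np.errstate(invalid="ignore"):
                            ab = float(np.nanmean(np.where(tot > 0, ref_r / tot, np.nan)))
        meta_rows.append({
            "snp_id": v.ID or f"{v.CHROM}:{v.POS}",
            "chrom": v.CHROM,
            "pos": v.POS,  # VCF 1-based, preserved
            "ref": v.REF,
            "alt": alts[0],
            "n_alt": n_alt,
            "coverage": np.nan if coverage is None else float(coverage),
            "allele_balance": np.nan if ab is None else float(ab),
        })
        geno_rows.append(row)
    genotypes = np.array(geno_rows, dtype=np.int8) if geno_rows \
        else np.zeros((0, len(samples)), dtype=np.int8)
    meta = pd.DataFrame(meta_rows)

    # re-express biallelic rows as minor-allele copy counts, minor defined
    # over the full sample; frequency ties break lexicographically
    minor = meta["alt"].to_numpy(dtype=object).copy()
    if len(meta):
        obs = genotypes != MISSING
        alt_copies = np.where(obs, genotypes, 0).sum(axis=1)
        total = 2 * obs.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq = np.where(total > 0, alt_copies / total, np.nan)
        ref = meta["ref"].to_numpy(dtype=object)
        alt = meta["alt"].to_numpy(dtype=object)
        tie_to_ref = (alt_freq == 0.5) & (ref < alt)
        flip = (alt_freq > 0.5) | tie_to_ref
        flip &= meta["n_alt"].to_numpy() == 1
        for i in np.flatnonzero(flip):
            r = genotypes[i]
            genotypes[i] = np.where(r == MISSING, MISSING, 2 - r)
            minor[i] = ref[i]
    meta["minor"] = minor
    return genotypes, meta, samples


def load_dataset(config: Mapping[str, object] | str | Path,
                 on_unmapped_snp: str = "drop") -> Dataset:
    """Assemble a :class:`Dataset` from a config mapping or YAML file.

    Recognized keys: ``vcf`` and ``popmap`` (required), plus optional
    ``climate``, ``gene_map``, ``gene_sets``, ``external_calls``. SNPs
    without a gene assignment are dropped with a warning by default
    (``on_unmapped_snp='error'`` raises instead).
    """
    if isinstance(config, (str, Path)):
        base = Path(config).parent
        config = yaml.safe_load(Path(config).read_text())
        config = {k: (v if not isinstance(v, str) else str((base / v)))
                  for k, v in config.items()}
    for key in ("vcf", "popmap"):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")

    genotypes, meta, samples = load_vcf(config["vcf"])
    popmap = read_popmap(config["popmap"])
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ValueError(
            f"sample(s) absent from population map: {', '.join(absent)}")

    climate = read_climate_csv(config["climate"]) if config.get("climate") else None
    gene_sets = read_gmt(config["gene_sets"]) if config.get("gene_sets") else None
    calls = read_external_calls(config["external_calls"]) \
        if config.get("external_calls") else None

    if config.get("gene_map"):
        gm = read_gene_map(config["gene_map"])
        dup = gm["snp_id"][gm["snp_id"].duplicated()]
        if not dup.empty:
            raise ValueError(
                f"SNP(s) mapped to more than one gene: {sorted(set(dup))[:5]}")
        gm = gm.set_index("snp_id")
        meta["gene_id"] = meta["snp_id"].map(gm["gene_id"])
        if "site_class" in gm.columns:
            meta["site_class"] = meta["snp_id"].map(gm["site_class"])
        unmapped = meta["gene_id"].isna()
        if unmapped.any():
            if on_unmapped_snp == "error":
                raise ValueError(
                    f"{int(unmapped.sum())} SNP(s) have no gene assignment")
            log.warning("dropping %d SNP(s) without gene assignment",
                        int(unmapped.sum()))
            keep = ~unmapped.to_numpy()
            genotypes = genotypes[keep]
            meta = meta.loc[keep].reset_index(drop=True)

    return Dataset(genotypes=genotypes, snp_meta=meta, samples=samples,
                   popmap=popmap, climate=climate, gene_sets=gene_sets,
                   external_calls=calls)


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

_RULE_ORDER = ("not biallelic", "not polymorphic", "missingness",
               "coverage", "allele balance")


def filter_sites(dataset: Dataset,
                 coverage_range: tuple[float, float] = (20.0, 250.0),
                 allele_balance: tuple[float, float] = (0.3, 0.7),
                 max_missing: float = 0.15,
                 biallelic_only: bool = True) -> tuple[Dataset, FilterReport]:
    """Apply the SNP quality cascade and report per-rule removals.

    Rules, in attribution order: biallelic, polymorphic, missing fraction
    strictly below ``max_missing``, mean coverage within ``coverage_range``
    (closed interval), heterozygote allele balance within ``allele_balance``
    (closed interval). SNPs lacking a QC field pass the corresponding rule
    with a warning (reported once).
    """
    meta = dataset.snp_meta
    G = dataset.genotypes
    n = len(meta)
    obs = G != MISSING
    n_obs = obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_copies = np.where(obs, G, 0).sum(axis=1)
        total = 2 * n_obs
        missing_frac = 1.0 - n_obs / G.shape[1] if G.shape[1] else np.zeros(n)

    biallelic = meta["n_alt"].to_numpy() == 1 if "n_alt" in meta.columns \
        else np.ones(n, dtype=bool)
    polymorphic = (minor_copies > 0) & (minor_copies < total)

    cov = meta["coverage"].to_numpy(dtype=float) if "coverage" in meta.columns \
        else np.full(n, np.nan)
    ab = meta["allele_balance"].to_numpy(dtype=float) \
        if "allele_balance" in meta.columns else np.full(n, np.nan)
    if np.isnan(cov).all() and n:
        warnings.warn("no coverage field available; coverage rule skipped")
    cov_ok = np.isnan(cov) | ((cov >= coverage_range[0]) & (cov <= coverage_range[1]))
    ab_ok = np.isnan(ab) | ((ab >= allele_balance[0]) & (ab <= allele_balance[1]))

    fails = {
        "not biallelic": ~biallelic if biallelic_only else np.zeros(n, dtype=bool),
        "not polymorphic": ~polymorphic,
        "missingness": ~(missing_frac < max_missing),
        "coverage": ~cov_ok,
        "allele balance": ~ab_ok,
    }
    attributed = np.full(n, -1)
    for rank, rule in enumerate(_RULE_ORDER):
        mask = fails[rule] & (attributed < 0)
        attributed[mask] = rank
    keep = attributed < 0
    removed = {rule: int((attributed == rank).sum())
               for rank, rule in enumerate(_RULE_ORDER)}
    if not keep.any():
        warnings.warn("no SNPs survive the filter cascade")
    report = FilterReport(
        input_count=n,
        removed=removed,
        parameters={"coverage_range": coverage_range,
                    "allele_balance": allele_balance,
                    "max_missing": max_missing,
                    "biallelic_only": biallelic_only},
    )
    return dataset.subset(keep), report


# ---------------------------------------------------------------------------
# heterozygote-excess screen
# ---------------------------------------------------------------------------

@lru_cache(maxsize=100_000)
def hwe_heterozygote_excess_pvalue(n_het: int, n_minor: int, n_ind: int) -> float:
    """One-sided exact Hardy-Weinberg p-value for heterozygote *excess*.

    Conditional on the minor-allele count ``n_minor`` among ``2 * n_ind``
    copies, heterozygote counts of matching parity are enumerated under the
    exact conditional distribution and the upper tail P(N_het >= observed)
    is returned.
    """
    if n_ind < 2:
        return math.nan
    n_major = 2 * n_ind - n_minor
    if n_minor == 0 or n_major == 0:
        return 1.0
    lg = math.lgamma
    log_base = lg(n_ind + 1) + lg(n_minor + 1) + lg(n_major + 1) - lg(2 * n_ind + 1)

    def log_prob(h: int) -> float:
        n_aa = (n_minor - h) // 2
        n_bb = n_ind - n_aa - h
        return (log_base + h * math.log(2.0)
                - lg(n_aa + 1) - lg(h + 1) - lg(n_bb + 1))

    h_min = n_minor % 2
    h_max = min(n_minor, n_major)
    support = range(h_min, h_max + 1, 2)
    logs = {h: log_prob(h) for h in support}
    mx = max(logs.values())
    z = sum(math.exp(v - mx) for v in logs.values())
    tail = sum(math.exp(logs[h] - mx) for h in support if h >= n_het)
    return min(tail / z, 1.0)


def het_excess_filter(dataset: Dataset, alpha: float = 0.05,
                      min_populations: int = 4) -> tuple[Dataset, FilterReport]:
    """Remove SNPs with a significant heterozygote excess in at least
    ``min_populations`` populations (a screen for collapsed paralogs).

    Per SNP and population, a one-sided exact Hardy-Weinberg test on the
    heterozygote-excess tail is evaluated at level ``alpha``; populations
    with fewer than two genotyped individuals are "not testable" and never
    count as significant.
    """
    G = dataset.genotypes
    pop_idx = dataset.population_indices()
    n_sig = np.zeros(G.shape[0], dtype=int)
    for pop, idx in pop_idx.items():
        sub = G[:, idx]
        obs = sub != MISSING
        n_ind = obs.sum(axis=1)
        n_minor = np.where(obs, sub, 0).sum(axis=1)
        n_het = (sub == 1).sum(axis=1)
        for i in range(G.shape[0]):
            if n_ind[i] < 2:
                continue
            p = hwe_heterozygote_excess_pvalue(int(n_het[i]), int(n_minor[i]),
                                               int(n_ind[i]))
            if p <= alpha:
                n_sig[i] += 1
    keep = n_sig < min_populations
    report = FilterReport(
        input_count=G.shape[0],
        removed={"heterozygote excess": int((~keep).sum())},
        parameters={"alpha": alpha, "min_populations": min_populations},
    )
    return dataset.subset(keep), report
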
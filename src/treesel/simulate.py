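"""Seed-reproducible synthetic data with the structure the pipeline assumes.

Three generators cover the three analysis levels:

* :func:`simulate_coalescent_gene` — single-population Kingman coalescent
  with infinite-sites mutation, the calibration fixture for the diversity and
  neutrality statistics (Watterson's E[S] = theta * a_n is the closed-form
  oracle).
* :func:`simulate_population_panel` — a multi-population diploid SNP panel
  with correlated climate tables, hierarchical (Balding-Nichols style)
  neutral differentiation, planted climate clines on the logit scale, gene
  and pathway maps, and a simulated external association-call table.
* :func:`simulate_pathway_universe` — a gene-statistic universe with one
  planted shifted gene set, the test bed for SUMSTAT enrichment.

Every generator is a pure function of its configuration and seed, and
:func:`write_fixture_bundle` serializes a panel to the on-disk formats the
loaders consume (VCF, TSV, CSV, GMT, JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .popgen import MISSING, SiteAlignment

__all__ = [
    "CLIMATE_VARIABLES",
    "PERIODS",
    "SimulationConfig",
    "TruthManifest",
    "simulate_coalescent_gene",
    "simulate_climate",
    "simulate_population_panel",
    "simulate_pathway_universe",
    "write_fixture_bundle",
]

# the eight bioclim-style variables scanned against allele frequencies,
# each realized for the present (PRE), last glacial maximum (LGM) and last
# interglacial (LIG) periods
CLIMATE_VARIABLES: tuple[str, ...] = (
    "annual_mean_temperature",
    "temperature_seasonality",
    "max_temperature_warmest_month",
    "min_temperature_coldest_month",
    "annual_precipitation",
    "precipitation_wettest_month",
    "precipitation_driest_month",
    "precipitation_seasonality",
)
PERIODS: tuple[str, ...] = ("PRE", "LGM", "LIG")

# per-variable (mean, sd) across populations, in natural units
_CLIMATE_SCALE = {
    "annual_mean_temperature": (9.0, 4.0),        # degC
    "temperature_seasonality": (6.0, 1.5),        # degC (sd of monthly means)
    "max_temperature_warmest_month": (24.0, 4.0),  # degC
    "min_temperature_coldest_month": (-2.0, 4.0),  # degC
    "annual_precipitation": (900.0, 300.0),       # mm
    "precipitation_wettest_month": (120.0, 40.0),  # mm
    "precipitation_driest_month": (40.0, 20.0),   # mm
    "precipitation_seasonality": (30.0, 10.0),    # CV, %
}


@dataclass
class SimulationConfig:
    """Study-design parameters for the population-panel generator.

    Defaults mirror the sampling design the pipeline targets: 12 populations
    of 10 diploids genotyped at ~1,100 multi-SNP genes, with climate
    described by 8 variables over 3 periods.
    """

    n_populations: int = 12
    diploids_per_population: int = 10
    n_genes: int = 1100
    mean_snps_per_gene: float = 23.0   # ~25k SNPs over ~1.1k genes
    gene_length: int = 1300            # bp of surveyed sequence per gene
    fst: float = 0.1                   # hierarchical differentiation
    climate_period_correlation: float = 0.7
    clinal_fraction: float = 0.02      # fraction of SNPs with planted clines
    clinal_snp_rate: float = 0.5       # within a clinal gene, fraction of its SNPs planted
    clinal_effect: float = 2.0         # logit-scale slope vs standardized climate
    clinal_noise_sd: float = 0.3       # logit-scale population noise
    missing_rate: float = 0.02
    coverage_mean: float = 60.0
    coverage_sd: float = 15.0
    allele_balance_sd: float = 0.05
    n_pathways: int = 20
    pathway_size: int = 10
    external_sensitivity: float = 0.8  # P(planted SNP called by a method)
    external_fpr: float = 0.01         # per-SNP false-call rate per method

    def __post_init__(self) -> None:
        for name in ("fst", "clinal_fraction", "missing_rate",
                     "external_sensitivity", "external_fpr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.clinal_noise_sd < 0 or self.coverage_sd < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class TruthManifest:
    """Ground truth for planted signals, for power/FDR scoring."""

    clinal_snps: list[dict] = field(default_factory=list)
    shifted_pathways: list[dict] = field(default_factory=list)
    theta_per_gene: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# coalescent gene simulator
# ---------------------------------------------------------------------------

def simulate_coalescent_gene(n_copies: int, theta: float, L: int,
                             seed: int | np.random.Generator = 0,
                             gene_id: str = "gene") -> SiteAlignment:
    """Neutral Kingman coalescent alignment under infinite sites.

    Coalescence times are exponential with rate C(k,2); mutations fall on
    branches as a Poisson process at theta/2 per lineage per coalescent time
    unit and are placed on distinct positions among ``L`` sites. Raises if
    more mutations arise than positions are available (increase ``L``).
    """
    if n_copies < 2:
        raise ValueError("need at least two allele copies")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lineages: list[np.ndarray] = [np.array([i]) for i in range(n_copies)]
    mutations: list[np.ndarray] = []
    k = n_copies
    while k > 1:
        t = rng.exponential(2.0 / (k * (k - 1)))
        n_mut = rng.poisson(theta / 2.0 * t, size=k)
        for lin, m in zip(lineages, n_mut):
            mutations.extend([lin] * int(m))
        i, j = rng.choice(k, size=2, replace=False)
        merged = np.concatenate([lineages[i], lineages[j]])
        lineages = [lin for idx, lin in enumerate(lineages) if idx not in (i, j)]
        lineages.append(merged)
        k -= 1

    S = len(mutations)
    if S > L:
        raise ValueError(
            f"{S} mutations but only {L} sites; rerun with a larger L")
    positions = np.sort(rng.choice(L, size=S, replace=False))
    alleles = np.zeros((n_copies, L), dtype=np.int8)
    order = rng.permutation(S)  # decouple site order from mutation order
    for col, mi in zip(positions, order):
        alleles[mutations[mi], col] = 1
    return SiteAlignment(gene_id=gene_id, alleles=alleles, positions=positions)


# ---------------------------------------------------------------------------
# climate and population panel
# ---------------------------------------------------------------------------

def simulate_climate(n_populations: int, rho: float,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Population x (variable, period) climate table.

    Each variable has a latent per-population axis shared across periods with
    correlation ``rho``; values are on each variable's natural scale.
    """
    pops = [f"POP{i + 1:02d}" for i in range(n_populations)]
    cols = {}
    for var in CLIMATE_VARIABLES:
        mean, sd = _CLIMATE_SCALE[var]
        z = rng.normal(size=n_populations)
        for period in PERIODS:
            eps = rng.normal(size=n_populations)
            vals = mean + sd * (rho * z + np.sqrt(max(0.0, 1 - rho**2)) * eps)
            cols[(var, period)] = vals
    cm = pd.DataFrame(cols, index=pops)
    cm.columns = pd.MultiIndex.from_tuples(cm.columns, names=["variable", "period"])
    cm.index.name = "population"
    # canonical column order so serialized and in-memory tables compare equal
    return cm.sort_index(axis=1)


def _balding_nichols(p0: np.ndarray, fst: float, n_pops: int,
                     rng: np.random.Generator) -> np.ndarray:
    if fst <= 0:
        return np.tile(p0[:, None], (1, n_pops))
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    return rng.beta(a[:, None], b[:, None], size=(len(p0), n_pops))


def simulate_population_panel(config: SimulationConfig | None = None,
                              seed: int = 0):
    """Generate a full synthetic panel: (Dataset, TruthManifest).

    Neutral SNPs draw population frequencies hierarchically around a global
    frequency with the configured differentiation; planted clinal SNPs set
    population frequency to logistic(a + beta * z) of a standardized climate
    column plus logit-scale noise, giving monotone frequency-climate
    relations detectable by rank correlation. Genotypes are binomial draws of
    two allele copies per diploid. External association calls mark planted
    SNPs significant with the configured sensitivity and null SNPs at the
    configured false-positive rate, for each of the two consumed methods.
    """
    from .io_formats import Dataset, GeneSetCollection  # deferred: avoid cycle

    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    n_pops = cfg.n_populations
    n_dip = cfg.diploids_per_population
    pops = [f"POP{i + 1:02d}" for i in range(n_pops)]
    samples = [f"{p}_I{j + 1:02d}" for p in pops for j in range(n_dip)]
    popmap = {s: s.split("_")[0] for s in samples}

    climate = simulate_climate(n_pops, cfg.climate_period_correlation, rng)

    genes = [f"gene{g + 1:05d}" for g in range(cfg.n_genes)]
    snps_per_gene = 1 + rng.poisson(max(cfg.mean_snps_per_gene - 1.0, 0.0),
                                    size=cfg.n_genes)
    gene_of_snp = np.repeat(np.arange(cfg.n_genes), snps_per_gene)
    n_snps = int(snps_per_gene.sum())
    snp_ids = [f"SNP{i + 1:06d}" for i in range(n_snps)]

    # plant clines gene-wise: local adaptation concentrates correlated SNPs
    # within genes, each clinal gene responding to one (variable, period)
    n_clinal_target = int(round(cfg.clinal_fraction * n_snps))
    clinal: list[tuple[int, int, int]] = []  # (snp index, variable, period)
    if n_clinal_target and cfg.clinal_snp_rate > 0:
        for g in rng.permutation(cfg.n_genes):
            if len(clinal) >= n_clinal_target:
                break
            members = np.flatnonzero(gene_of_snp == g)
            k = max(1, int(round(cfg.clinal_snp_rate * len(members))))
            picked = rng.choice(members, size=k, replace=False)
            vi = int(rng.integers(len(CLIMATE_VARIABLES)))
            pi_ = int(rng.integers(len(PERIODS)))
            clinal.extend((int(i), vi, pi_) for i in picked)
        clinal = clinal[:n_clinal_target]

    freqs = np.empty((n_snps, n_pops))
    p0 = rng.uniform(0.05, 0.95, size=n_snps)
    freqs[:] = _balding_nichols(p0, cfg.fst, n_pops, rng)
    truth = TruthManifest()
    for idx, vi, pi_ in clinal:
        var, period = CLIMATE_VARIABLES[vi], PERIODS[pi_]
        col = climate[(var, period)].to_numpy()
        z = (col - col.mean()) / col.std()
        a = logit(rng.uniform(0.2, 0.8))
        noise = rng.normal(0.0, cfg.clinal_noise_sd, size=n_pops)
        freqs[idx] = expit(a + cfg.clinal_effect * z + noise)
        truth.clinal_snps.append({
            "snp_id": snp_ids[idx], "gene_id": genes[gene_of_snp[idx]],
            "variable": var, "period": period, "beta": cfg.clinal_effect,
        })

    # genotypes: alt-allele copies, then re-expressed as minor-allele copies
    pop_idx = np.repeat(np.arange(n_pops), n_dip)
    G = rng.binomial(2, freqs[:, pop_idx]).astype(np.int8)
    if cfg.missing_rate > 0:
        G[rng.random(G.shape) < cfg.missing_rate] = MISSING

    bases = np.array(list("ACGT"))
    ref_alt = np.empty((n_snps, 2), dtype="<U1")
    for i in range(n_snps):
        ref_alt[i] = rng.choice(4, size=2, replace=False).astype(int)
    ref = bases[ref_alt[:, 0].astype(int)]
    alt = bases[ref_alt[:, 1].astype(int)]

    obs = G != MISSING
    alt_copies = np.where(obs, G, 0).sum(axis=1)
    total_copies = 2 * obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = alt_copies / total_copies
    flip = (alt_freq > 0.5) | ((alt_freq == 0.5) & (ref < alt))
    G[flip] = np.where(G[flip] == MISSING, MISSING, 2 - G[flip])
    minor = np.where(flip, ref, alt)
    major = np.where(flip, alt, ref)

    positions = np.concatenate([
        np.sort(rng.choice(np.arange(1, cfg.gene_length + 1), size=k, replace=False))
        for k in snps_per_gene
    ]) if n_snps else np.array([], dtype=int)

    site_class = rng.choice(["syn", "nonsyn", "other"], size=n_snps,
                            p=[0.25, 0.45, 0.30])
    coverage = np.clip(rng.normal(cfg.coverage_mean, cfg.coverage_sd, size=n_snps), 1, None)
    ab = np.clip(rng.normal(0.5, cfg.allele_balance_sd, size=n_snps), 0.01, 0.99)

    snp_meta = pd.DataFrame({
        "snp_id": snp_ids,
        "gene_id": [genes[g] for g in gene_of_snp],
        "chrom": [genes[g] for g in gene_of_snp],
        "pos": positions,
        "ref": major,   # VCF REF = major allele by construction
        "alt": minor,   # VCF ALT = globally defined minor allele
        "minor": minor,
        "n_alt": 1,
        "coverage": coverage,
        "allele_balance": ab,
        "site_class": site_class,
    })

    # pathways: random same-size gene sets (overlaps allowed)
    sets = {}
    for s in range(cfg.n_pathways):
        members = rng.choice(cfg.n_genes, size=min(cfg.pathway_size, cfg.n_genes),
                             replace=False)
        sets[f"path{s + 1:03d}"] = sorted(genes[g] for g in members)
    gene_sets = GeneSetCollection(sets=sets,
                                  descriptions={k: "simulated pathway" for k in sets})

    external = _simulate_external_calls(cfg, rng, snp_ids, truth)

    per_gene_theta = {g: np.nan for g in genes}  # panel SNPs are not coalescent-scaled
    truth.theta_per_gene = per_gene_theta

    dataset = Dataset(
        genotypes=G,
        snp_meta=snp_meta,
        samples=samples,
        popmap=popmap,
        climate=climate,
        gene_sets=gene_sets,
        external_calls=external,
    )
    return dataset, truth


def _simulate_external_calls(cfg: SimulationConfig, rng: np.random.Generator,
                             snp_ids: list[str], truth: TruthManifest) -> pd.DataFrame:
    """Simulated bayescenv/baypass call table (the pipeline consumes calls,
    it never reruns those models)."""
    rows = []
    planted = {(t["snp_id"], t["variable"], t["period"]) for t in truth.clinal_snps}
    for snp_id, var, period in sorted(planted):
        for method in ("bayescenv", "baypass"):
            hit = rng.random() < cfg.external_sensitivity
            if method == "bayescenv":
                score = rng.uniform(0.0, 0.05) if hit else rng.uniform(0.05, 1.0)
            else:
                score = rng.uniform(30.0, 120.0) if hit else rng.uniform(0.0, 30.0)
            rows.append((snp_id, var, period, method, round(float(score), 6), hit))
    n_snps = len(snp_ids)
    planted_ids = {t[0] for t in planted}
    for method in ("bayescenv", "baypass"):
        n_false = rng.binomial(n_snps, cfg.external_fpr)
        for idx in rng.choice(n_snps, size=n_false, replace=False):
            if snp_ids[idx] in planted_ids:
                continue
            var = CLIMATE_VARIABLES[rng.integers(len(CLIMATE_VARIABLES))]
            period = PERIODS[rng.integers(len(PERIODS))]
            score = rng.uniform(0.0, 0.05) if method == "bayescenv" else rng.uniform(30.0, 120.0)
            rows.append((snp_ids[idx], var, period, method, round(float(score), 6), True))
    return pd.DataFrame(rows, columns=["snp_id", "variable", "period",
                                       "method", "score", "significant"])


# ---------------------------------------------------------------------------
# pathway universe
# ---------------------------------------------------------------------------

def simulate_pathway_universe(n_genes: int = 300, n_sets: int = 20,
                              set_size: int = 10, delta: float = 0.0,
                              seed: int = 0, nested_pair: bool = False):
    """Standard-normal gene statistics with one planted shifted set.

    The first set's member statistics are shifted by ``delta``. With
    ``nested_pair`` the last set is replaced by a strict subset of the
    second-to-last set, to exercise pruning-driven set removal.
    Returns ``(stats, collection, truth)``.
    """
    from .io_formats import GeneSetCollection

    if set_size > n_genes:
        raise ValueError("set size exceeds universe size")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    values = rng.normal(size=n_genes)
    sets: dict[str, list[str]] = {}
    for s in range(n_sets):
        members = rng.choice(n_genes, size=set_size, replace=False)
        sets[f"set{s + 1:03d}"] = sorted(genes[g] for g in members)
    if nested_pair and n_sets >= 2:
        parent = sets[f"set{n_sets - 1:03d}"]
        child = sorted(rng.choice(parent, size=max(set_size - 2, 2), replace=False))
        sets[f"set{n_sets:03d}"] = child

    truth = TruthManifest()
    planted = sets["set001"]
    if delta != 0.0:
        member_idx = [genes.index(g) for g in planted]
        values[member_idx] += delta
        truth.shifted_pathways.append({"set_id": "set001", "delta": delta,
                                       "genes": planted})
    stats = pd.Series(values, index=genes, name="statistic")
    collection = GeneSetCollection(sets=sets,
                                   descriptions={k: "simulated set" for k in sets})
    return stats, collection, truth


# ---------------------------------------------------------------------------
# fixture bundle writer
# ---------------------------------------------------------------------------

def write_fixture_bundle(dataset, manifest: TruthManifest | None,
                         out_dir: str | Path) -> dict[str, Path]:
    """Serialize a panel to plain-text files that round-trip through
    :func:`treesel.io_formats.load_dataset`.

    Emits genotypes.vcf, popmap.tsv, genemap.tsv, climate.csv, pathways.gmt,
    external_calls.tsv and truth.json; returns the path of each file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    meta = dataset.snp_meta
    vcf_path = out / "genotypes.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=MCOV,Number=1,Type=Float,Description='
                 '"Mean coverage across samples">\n')
        fh.write('##INFO=<ID=ABHET,Number=1,Type=Float,Description='
                 '"Mean allele balance of heterozygous calls">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.samples) + "\n")
        G = dataset.genotypes
        for i, row in enumerate(meta.itertuples(index=False)):
            # genotypes are minor-allele copy counts; VCF ALT is the minor
            # allele here, so ALT copies == stored codes
            gts = []
            for g in G[i]:
                if g == MISSING:
                    gts.append("./.")
                elif g == 0:
                    gts.append("0/0")
                elif g == 1:
                    gts.append("0/1")
                else:
                    gts.append("1/1")
            info = f"MCOV={row.coverage:.3f};ABHET={row.allele_balance:.4f}"
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t{info}\tGT\t" + "\t".join(gts) + "\n")
    paths["vcf"] = vcf_path

    popmap_path = out / "popmap.tsv"
    pd.DataFrame({"sample": dataset.samples,
                  "population": [dataset.popmap[s] for s in dataset.samples]}
                 ).to_csv(popmap_path, sep="\t", index=False)
    paths["popmap"] = popmap_path

    genemap_path = out / "genemap.tsv"
    meta[["snp_id", "gene_id", "site_class"]].to_csv(genemap_path, sep="\t", index=False)
    paths["gene_map"] = genemap_path

    if dataset.climate is not None:
        climate_path = out / "climate.csv"
        long = dataset.climate.stack(["variable", "period"], future_stack=True) \
            .rename("value").reset_index()
        long.to_csv(climate_path, index=False)
        paths["climate"] = climate_path

    if dataset.gene_sets is not None:
        gmt_path = out / "pathways.gmt"
        with open(gmt_path, "w") as fh:
            for set_id in sorted(dataset.gene_sets.sets):
                desc = dataset.gene_sets.descriptions.get(set_id, "")
                members = "\t".join(dataset.gene_sets.sets[set_id])
                fh.write(f"{set_id}\t{desc}\t{members}\n")
        paths["gene_sets"] = gmt_path

    if dataset.external_calls is not None:
        calls_path = out / "external_calls.tsv"
        dataset.external_calls.to_csv(calls_path, sep="\t", index=False)
        paths["external_calls"] = calls_path

    if manifest is not None:
        truth_path = out / "truth.json"
        manifest.to_json(truth_path)
        paths["truth"] = truth_path
    return paths
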
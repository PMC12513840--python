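"""Synthetic cohort generator.

Emulates the statistical structure a genome-metabolome association study
assumes: LD-blocked genotypes in several ancestral strata, a correlated
metabolite panel with factor structure, planted mQTLs of each pleiotropy
mode, medication-treated subsets, rare coding variants with consequence
annotations and genotype-level QC fields, and binary disease outcomes with
metabolite-mediated and direct genetic paths.

Everything is fully deterministic under a fixed seed, and every generator
returns a machine-readable truth record so downstream stages can be scored
against what was planted.

Genotypes are simulated as pairs of haplotypes whose alleles come from
thresholding a latent AR(1) Gaussian within each LD block: adjacent-variant
correlation decays with the ``ld_decay`` parameter, and strata receive
jittered allele frequencies and weaker LD to mimic continental differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

PLEIOTROPY_MODES = ("specific", "pathway", "proportional", "disproportional", "nonspecific")

MISSING = -1  # sentinel for missing genotype calls


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Shape of the simulated genotype cohort.

    Parameters
    ----------
    n_individuals
        Individuals per stratum; an int (same size for every stratum) or a
        sequence of length ``n_strata``.
    n_strata
        Number of ancestral strata.
    n_blocks, block_size
        LD blocks per chromosome arrangement and variants per block.
    ld_decay
        Latent AR(1) autocorrelation in [0, 1); 0 gives independent variants.
    maf_range
        Bounds for common-variant minor allele frequencies, in (0, 0.5].
    rare_fraction
        Proportion of variants drawn ultra-rare (MAF < 5e-4).
    af_jitter
        SD of the logit-scale allele-frequency shift applied per stratum
        beyond the first (continental drift surrogate).
    missing_rate
        Per-call probability of a missing genotype.
    """

    n_individuals: int | tuple[int, ...] = 2000
    n_strata: int = 2
    n_blocks: int = 5
    block_size: int = 20
    ld_decay: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    rare_fraction: float = 0.0
    af_jitter: float = 0.3
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.stratum_sizes
        if len(sizes) != self.n_strata or any(n <= 0 for n in sizes):
            raise ValueError("n_individuals must be positive for every stratum")
        if self.n_strata < 1 or self.n_blocks < 1:
            raise ValueError("counts must be positive")
        if self.block_size < 2:
            raise ValueError("block_size < 2: within-block LD undefined")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf bounds must lie in (0, 0.5]")
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must lie in [0, 1]")

    @property
    def stratum_sizes(self) -> tuple[int, ...]:
        if isinstance(self.n_individuals, (int, np.integer)):
            return (int(self.n_individuals),) * self.n_strata
        return tuple(int(n) for n in self.n_individuals)

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.block_size


@dataclass
class TraitPanelSpec:
    """Factor model for the correlated metabolite panel.

    The implied trait covariance is ``L L' + diag(noise_sd**2)`` with unit
    diagonal when ``noise_sd = sqrt(1 - rowsum(L**2))``.
    """

    loading_matrix: np.ndarray  # traits x factors
    noise_sd: np.ndarray  # per trait, > 0
    trait_names: list[str]
    factor_of_trait: np.ndarray  # primary factor index, -1 for independent traits
    med_effect: np.ndarray | None = None  # per-trait shift in treated individuals
    sex_beta_ratio: float | None = None

    def __post_init__(self) -> None:
        L = np.asarray(self.loading_matrix, dtype=float)
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be positive")
        implied = L @ L.T + np.diag(np.asarray(self.noise_sd, dtype=float) ** 2)
        # positive definiteness of the implied trait covariance
        if np.linalg.eigvalsh(implied).min() <= 0:
            raise ValueError("implied trait covariance is not positive definite")

    @property
    def n_traits(self) -> int:
        return self.loading_matrix.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loading_matrix.shape[1]

    def implied_corr(self) -> np.ndarray:
        """Model-implied trait correlation matrix."""
        L = self.loading_matrix
        cov = L @ L.T + np.diag(self.noise_sd**2)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    @classmethod
    def default(
        cls,
        n_factors: int = 12,
        traits_per_factor: int = 12,
        n_independent: int = 10,
        primary_range: tuple[float, float] = (0.85, 0.97),
        secondary_range: tuple[float, float] = (0.15, 0.35),
        seed: int = 0,
    ) -> "TraitPanelSpec":
        """Panel emulating an NMR metabolomics platform at desk scale.

        Correlated lipoprotein-like factors each carry ``traits_per_factor``
        strongly loading traits plus one weak secondary loading on another
        factor (so cross-factor correlations exist but stay modest);
        independent traits stand in for small molecules such as amino acids.
        """
        rng = np.random.default_rng(seed)
        n_struct = n_factors * traits_per_factor
        n_traits = n_struct + n_independent
        L = np.zeros((n_traits, n_factors))
        factor_of = np.full(n_traits, -1, dtype=int)
        for f in range(n_factors):
            idx = np.arange(f * traits_per_factor, (f + 1) * traits_per_factor)
            L[idx, f] = rng.uniform(*primary_range, size=traits_per_factor)
            factor_of[idx] = f
            for i in idx:
                other = int(rng.integers(0, n_factors - 1))
                other += other >= f
                L[i, other] = rng.uniform(*secondary_range)
        noise_sd = np.sqrt(np.clip(1.0 - (L**2).sum(axis=1), 0.02, None))
        names = [f"lipo_f{factor_of[i]}_t{i}" for i in range(n_struct)]
        names += [f"mol_t{i}" for i in range(n_struct, n_traits)]
        med = np.zeros(n_traits)
        # cholesterol-lowering medication shifts traits of the first three
        # lipoprotein factors (an LDL-like compartment) downward by 0.5 SD
        med[factor_of < 3] = np.where(factor_of[factor_of < 3] >= 0, -0.5, 0.0)
        return cls(
            loading_matrix=L,
            noise_sd=noise_sd,
            trait_names=names,
            factor_of_trait=factor_of,
            med_effect=med,
        )


@dataclass
class PlantedEffect:
    """One planted mQTL with its pleiotropy mode and per-trait effects.

    ``betas`` are in per-allele SD units on the named ``target_traits``.
    Proportional-mode effects act through a latent factor; ``factor`` and
    ``factor_beta`` record the injection and ``betas`` its per-trait image.
    """

    variant_id: str
    mode: str
    target_traits: list[str]
    betas: np.ndarray
    factor: int | None = None
    factor_beta: float | None = None
    mediated_disease_effect: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in PLEIOTROPY_MODES:
            raise ValueError(f"unknown pleiotropy mode {self.mode!r}")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas must be finite")


@dataclass
class GenotypeData:
    """Genotype matrix with its variant table and per-block LD.

    ``genotypes`` holds additive dosages in {0, 1, 2} with ``MISSING`` (-1)
    marking missing calls; rows follow ``strata``. ``ld`` holds one empirical
    correlation matrix per block, computed in the first (reference) stratum.
    """

    genotypes: np.ndarray
    variants: pd.DataFrame
    strata: np.ndarray
    ld: list[np.ndarray]
    config: CohortConfig

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def stratum_mask(self, label: str) -> np.ndarray:
        return self.strata == label

    def dosages(self) -> np.ndarray:
        """Float dosage matrix with missing calls mean-imputed per variant."""
        return impute_dosages(self.genotypes)


def impute_dosages(genotypes: np.ndarray) -> np.ndarray:
    """Mean-impute the MISSING sentinel, returning float dosages."""
    g = np.asarray(genotypes, dtype=float)
    miss = g == MISSING
    if miss.any():
        g[miss] = np.nan
        col_mean = np.nanmean(g, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(miss)
        g[idx] = col_mean[idx[1]]
    return g


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _ar1_latent(rng: np.random.Generator, n_rows: int, m: int, rho: float) -> np.ndarray:
    z = np.empty((n_rows, m))
    z[:, 0] = rng.standard_normal(n_rows)
    if m > 1 and rho > 0:
        innov = rng.standard_normal((n_rows, m - 1)) * np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    elif m > 1:
        z[:, 1:] = rng.standard_normal((n_rows, m - 1))
    return z


def generate_genotypes(config: CohortConfig) -> GenotypeData:
    """Simulate additive genotypes with block-wise LD in every stratum.

    Each individual carries two haplotypes; a haplotype's alleles arise by
    thresholding a latent AR(1) Gaussian at the allele-frequency quantile, so
    within-block correlation decays with ``ld_decay`` and is zero across
    blocks. Strata beyond the first receive logit-jittered allele frequencies
    and geometrically weaker LD.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_variants
    sizes = config.stratum_sizes

    base_maf = rng.uniform(*config.maf_range, size=m)
    is_rare = rng.random(m) < config.rare_fraction
    if is_rare.any():
        base_maf[is_rare] = 10 ** rng.uniform(np.log10(2e-5), np.log10(5e-4), size=is_rare.sum())

    # per-stratum allele frequencies: logit-scale drift from the base pool
    afs = np.empty((config.n_strata, m))
    afs[0] = base_maf
    for s in range(1, config.n_strata):
        shift = rng.normal(0.0, config.af_jitter, size=m)
        afs[s] = 1.0 / (1.0 + np.exp(-(np.log(base_maf / (1 - base_maf)) + shift)))

    geno = np.empty((sum(sizes), m), dtype=np.int8)
    row = 0
    strata_labels = []
    for s, n_s in enumerate(sizes):
        rho_s = config.ld_decay * (0.8**s)
        thresh = stats.norm.ppf(afs[s])
        g_s = np.zeros((n_s, m), dtype=np.int8)
        for b in range(config.n_blocks):
            cols = slice(b * config.block_size, (b + 1) * config.block_size)
            for _hap in range(2):
                z = _ar1_latent(rng, n_s, config.block_size, rho_s)
                g_s[:, cols] += (z < thresh[cols]).astype(np.int8)
        geno[row : row + n_s] = g_s
        strata_labels.extend([f"stratum{s}"] * n_s)
        row += n_s

    if config.missing_rate > 0:
        geno[rng.random(geno.shape) < config.missing_rate] = MISSING

    # variant table: 1-based positions, monotone within block
    bases = np.array(list("ACGT"))
    ref = bases[rng.integers(0, 4, size=m)]
    alt_off = rng.integers(1, 4, size=m)
    alt = bases[(np.searchsorted(bases, ref) + alt_off) % 4]
    # 1-based positions, monotone within block; blocks are separated by a
    # 200-kb gap so block boundaries coincide with recombination breaks
    block_idx = np.arange(m) // config.block_size
    within = np.arange(m) % config.block_size
    pos = 1 + block_idx * (config.block_size * 1000 + 200_000) + within * 1000
    variants = pd.DataFrame(
        {
            "variant_id": [f"var{i:05d}" for i in range(m)],
            "chrom": np.ones(m, dtype=int),
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "block": np.arange(m) // config.block_size,
            "is_rare": is_rare,
        }
    )
    for s in range(config.n_strata):
        variants[f"af_stratum{s}"] = afs[s]

    strata = np.array(strata_labels)
    ref_mask = strata == "stratum0"
    ld = []
    g0 = impute_dosages(geno[ref_mask])
    for b in range(config.n_blocks):
        cols = slice(b * config.block_size, (b + 1) * config.block_size)
        block = g0[:, cols]
        sd = block.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(block, rowvar=False)
        r[~np.isfinite(r)] = 0.0
        np.fill_diagonal(r, 1.0)
        ld.append(r)

    return GenotypeData(genotypes=geno, variants=variants, strata=strata, ld=ld, config=config)


# ---------------------------------------------------------------------------
# trait panel with planted pleiotropy modes
# ---------------------------------------------------------------------------


@dataclass
class TraitPanel:
    traits: pd.DataFrame  # individuals x traits, standardized
    truth: pd.DataFrame  # one row per planted effect
    factors: np.ndarray  # latent factor scores (before injection they were iid)
    spec: TraitPanelSpec
    effects: list[PlantedEffect] = field(default_factory=list)


def make_planted_effect(
    mode: str,
    spec: TraitPanelSpec,
    variant_id: str,
    rng: np.random.Generator,
    effect_scale: float = 0.2,
) -> PlantedEffect:
    """Construct a planted mQTL of the requested pleiotropy mode.

    specific
        equal-magnitude direct effects on the <=3 strongest-loading traits of
        one factor (a tight, highly correlated trait cluster).
    pathway
        direct effects on all primary traits of one factor, proportional to
        their loadings.
    proportional
        injection on the latent factor itself, so every trait's effect scales
        with its loading (and hence with its correlation to the lead trait).
    disproportional
        direct effects on one factor's primary traits with randomized
        magnitudes forced to be discordant with the loadings.
    nonspecific
        direct effects on traits drawn across distinct factors with no
        magnitude/correlation relationship.
    """
    names = np.asarray(spec.trait_names)
    fac = spec.factor_of_trait
    L = spec.loading_matrix
    f = int(rng.integers(0, spec.n_factors))
    members = np.where(fac == f)[0]

    if mode == "specific":
        order = members[np.argsort(-L[members, f])][:3]
        betas = effect_scale * rng.uniform(0.9, 1.1, size=len(order))
        return PlantedEffect(variant_id, mode, list(names[order]), betas)
    if mode == "pathway":
        # effects track the implied correlation with the pathway's core
        # (strongest-loading) trait, so association strength follows the
        # lead-trait correlation within the cluster; 1.4x amplitude keeps the
        # pattern well above the per-trait sampling noise
        corr = spec.implied_corr()
        core = members[int(np.argmax(L[members, f]))]
        c = corr[members, core]
        betas = 1.4 * effect_scale * c / c.mean()
        return PlantedEffect(variant_id, mode, list(names[members]), betas)
    if mode == "proportional":
        fb = 1.4 * effect_scale
        col = L[:, f]
        touched = np.where(col > 0)[0]
        return PlantedEffect(
            variant_id, mode, list(names[touched]), fb * col[touched], factor=f, factor_beta=fb
        )
    if mode == "disproportional":
        lo = L[members, f]
        # wide, strictly loading-discordant magnitude spread: the strongest
        # effect lands on the weakest-loading trait of the cluster
        betas = effect_scale * np.geomspace(0.55, 1.8, len(members))
        betas = betas[np.argsort(np.argsort(-lo))]
        signs = rng.choice([-1.0, 1.0], size=len(members))
        idx = list(members)
        betas = list(betas * signs)
        # one satellite trait tied to the cluster only through its secondary
        # loading carries a near-maximal effect: strength maximally
        # discordant with the lead-trait correlation
        satellites = np.where((fac != f) & (L[:, f] > 0))[0]
        if len(satellites) > 0:
            idx.append(int(rng.choice(satellites)))
            betas.append(effect_scale * 1.6 * rng.choice([-1.0, 1.0]))
        return PlantedEffect(variant_id, mode, list(names[idx]), np.asarray(betas))
    if mode == "nonspecific":
        # scatter across the metabolome: several traits of one factor with
        # magnitudes unrelated to their loadings, one trait from each of
        # several other factors, and independent small molecules - so neither
        # the trait correlations nor the association strengths follow the
        # lead-trait correlation
        idx = list(rng.choice(members, size=min(8, len(members)), replace=False))
        for g in np.setdiff1d(np.arange(spec.n_factors), [f]):
            pool = np.where(fac == g)[0]
            idx.append(int(rng.choice(pool)))
        indep = np.where(fac == -1)[0]
        if len(indep) >= 3:
            idx += list(rng.choice(indep, size=3, replace=False))
        betas = effect_scale * rng.uniform(0.5, 1.0, size=len(idx))
        betas *= rng.choice([-1.0, 1.0], size=len(idx))
        return PlantedEffect(variant_id, mode, list(names[idx]), betas)
    raise ValueError(f"unknown mode {mode!r}")


def generate_trait_panel(
    genotypes: GenotypeData,
    spec: TraitPanelSpec,
    effects: list[PlantedEffect],
    seed: int = 0,
) -> TraitPanel:
    """Draw the metabolite panel from the factor model and plant mQTLs.

    Traits are standardized to unit variance after generation; the truth
    table records mode, target traits and per-trait betas for every planted
    effect.
    """
    rng = np.random.default_rng(seed)
    n = genotypes.n
    T, K = spec.n_traits, spec.n_factors
    name_to_col = {t: i for i, t in enumerate(spec.trait_names)}
    vid_to_col = {v: i for i, v in enumerate(genotypes.variants["variant_id"])}

    F = rng.standard_normal((n, K))
    direct = np.zeros((n, T))
    for eff in effects:
        if eff.variant_id not in vid_to_col:
            raise KeyError(f"planted effect references absent variant {eff.variant_id!r}")
        missing_traits = [t for t in eff.target_traits if t not in name_to_col]
        if missing_traits:
            raise KeyError(f"planted effect references absent traits {missing_traits}")
        g = impute_dosages(genotypes.genotypes[:, [vid_to_col[eff.variant_id]]])[:, 0]
        if eff.factor is not None:
            F[:, eff.factor] += g * float(eff.factor_beta)
        else:
            cols = [name_to_col[t] for t in eff.target_traits]
            direct[:, cols] += g[:, None] * np.asarray(eff.betas)[None, :]

    Y = F @ spec.loading_matrix.T + direct
    Y += rng.standard_normal((n, T)) * spec.noise_sd[None, :]
    Y = (Y - Y.mean(axis=0)) / Y.std(axis=0)

    truth = pd.DataFrame(
        {
            "variant_id": [e.variant_id for e in effects],
            "mode": [e.mode for e in effects],
            "target_traits": [list(e.target_traits) for e in effects],
            "betas": [np.asarray(e.betas).tolist() for e in effects],
            "mediated_disease_effect": [e.mediated_disease_effect for e in effects],
        }
    )
    traits = pd.DataFrame(Y, columns=spec.trait_names)
    return TraitPanel(traits=traits, truth=truth, factors=F, spec=spec, effects=list(effects))


# ---------------------------------------------------------------------------
# medication
# ---------------------------------------------------------------------------


@dataclass
class MedicationData:
    baseline: pd.DataFrame  # shifted traits, all individuals
    treated: np.ndarray  # bool, treated at baseline
    followup: pd.DataFrame  # repeat-visit traits for a baseline-untreated subset
    followup_treated: pd.Series  # bool over followup rows: newly treated at follow-up
    retest_rho: float


def generate_medication(
    panel: TraitPanel,
    spec: TraitPanelSpec,
    treated_fraction: float,
    seed: int = 0,
    followup_fraction: float = 0.5,
    followup_treated_fraction: float = 0.3,
    retest_rho: float = 0.95,
) -> MedicationData:
    """Apply medication shifts and produce the repeat-visit trait copy.

    Baseline traits of treated individuals shift by ``spec.med_effect``. A
    random subset untreated at baseline gets a follow-up measurement
    correlated with baseline at ``retest_rho``; a fraction of them is newly
    treated at follow-up (shifted there instead), which is exactly the
    contrast the medication-adjustment regression estimates from.
    """
    if not 0.0 <= treated_fraction < 1.0:
        raise ValueError("treated_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(panel.traits)
    med = spec.med_effect if spec.med_effect is not None else np.zeros(spec.n_traits)

    treated = rng.random(n) < treated_fraction
    baseline = panel.traits.copy()
    baseline.iloc[treated] = baseline.iloc[treated].to_numpy() + med[None, :]

    untreated_idx = np.where(~treated)[0]
    k = int(round(followup_fraction * len(untreated_idx)))
    fu_idx = np.sort(rng.choice(untreated_idx, size=k, replace=False))
    noise = rng.standard_normal((k, spec.n_traits)) * np.sqrt(1.0 - retest_rho**2)
    fu = retest_rho * panel.traits.iloc[fu_idx].to_numpy() + noise
    fu_treated = rng.random(k) < followup_treated_fraction
    fu[fu_treated] += med[None, :]
    followup = pd.DataFrame(fu, columns=panel.traits.columns, index=fu_idx)
    return MedicationData(
        baseline=baseline,
        treated=treated,
        followup=followup,
        followup_treated=pd.Series(fu_treated, index=fu_idx),
        retest_rho=retest_rho,
    )


# ---------------------------------------------------------------------------
# rare-variant annotations and genotype-level QC fields
# ---------------------------------------------------------------------------

CONSEQUENCE_CLASSES = ("pLOF_HC", "pLOF", "missense", "synonymous", "other")
DEFAULT_CONSEQUENCE_PROBS = (0.05, 0.05, 0.45, 0.25, 0.20)


@dataclass
class RareAnnotationData:
    annotations: pd.DataFrame  # one row per variant
    dp: np.ndarray  # individuals x variants read depth
    gq: np.ndarray  # genotype quality
    ab: np.ndarray  # allele balance (alt fraction)


def generate_gene_models(
    n_genes: int,
    seed: int = 0,
    chrom: int = 1,
    span: int = 2_000_000,
    gene_length: tuple[int, int] = (5_000, 80_000),
) -> pd.DataFrame:
    """Tile gene bodies along a chromosome (BED-like table, 1-based)."""
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(1, span, size=n_genes))
    lengths = rng.integers(*gene_length, size=n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"GENE{i:04d}" for i in range(n_genes)],
            "chrom": chrom,
            "start": starts,
            "end": starts + lengths,
            "strand": rng.choice(["+", "-"], size=n_genes),
        }
    )


def generate_rare_annotations(
    genotypes: GenotypeData,
    seed: int = 0,
    consequence_probs: tuple[float, ...] = DEFAULT_CONSEQUENCE_PROBS,
    genes_per_block: int = 1,
    dp_mean: float = 30.0,
    gq_mean: float = 60.0,
) -> RareAnnotationData:
    """Annotate variants with consequence classes, scores and QC fields.

    Consequence classes follow a multinomial; CADD-like scores are gamma
    distributed and lifted for loss-of-function classes; REVEL-like scores
    are Beta-distributed and only meaningful for missense. Genes tile the LD
    blocks so every variant has a host gene. Per-genotype DP/GQ are
    Poisson/clipped-normal and AB is Beta(20,20) around 0.5 for heterozygous
    calls, giving QC filters a known pass/fail truth.
    """
    rng = np.random.default_rng(seed)
    var = genotypes.variants
    m = len(var)
    n = genotypes.n

    csq = rng.choice(CONSEQUENCE_CLASSES, size=m, p=consequence_probs)
    cadd = rng.gamma(shape=2.0, scale=5.0, size=m)
    cadd[np.isin(csq, ["pLOF_HC", "pLOF"])] += 25.0
    cadd[csq == "missense"] += rng.gamma(2.0, 6.0, size=(csq == "missense").sum())
    revel = np.where(csq == "missense", rng.beta(2, 2, size=m), 0.0)
    impact = np.where(np.isin(csq, ["pLOF_HC", "pLOF"]), "HIGH", "MODERATE")
    # a sliver of non-pLOF variants carries HIGH VEP impact (e.g. transcript ablation)
    high_other = (csq == "other") & (rng.random(m) < 0.05)
    impact = np.where(high_other, "HIGH", impact)
    is_indel = rng.random(m) < 0.1

    gene_of = np.array(
        [f"GENE{b * genes_per_block + (i % genes_per_block):04d}" for i, b in enumerate(var["block"])]
    )

    ann = var[["variant_id", "chrom", "pos", "ref", "alt", "is_rare"]].copy()
    ann["gene_id"] = gene_of
    ann["consequence"] = csq
    ann["impact"] = impact
    ann["lof_confidence"] = np.where(csq == "pLOF_HC", "HC", np.where(csq == "pLOF", "LC", ""))
    ann["cadd"] = cadd
    ann["revel"] = revel
    ann["is_indel"] = is_indel
    g0 = impute_dosages(genotypes.genotypes)
    af = g0.mean(axis=0) / 2.0
    ann["maf"] = np.minimum(af, 1 - af)

    dp = rng.poisson(dp_mean, size=(n, m)).astype(np.int16)
    gq = np.clip(rng.normal(gq_mean, 10.0, size=(n, m)), 0, 99).astype(np.int16)
    ab = np.zeros((n, m), dtype=np.float32)
    het = genotypes.genotypes == 1
    ab[het] = rng.beta(20, 20, size=int(het.sum()))
    ab[genotypes.genotypes == 2] = 1.0
    return RareAnnotationData(annotations=ann, dp=dp, gq=gq, ab=ab)


# ---------------------------------------------------------------------------
# binary disease outcomes
# ---------------------------------------------------------------------------


@dataclass
class DiseaseSpec:
    """Liability-threshold disease model.

    ``theta`` is the causal effect of ``mediator_trait`` on liability (the
    quantity Mendelian randomization should recover); ``direct_effects`` maps
    variant ids to per-allele liability effects that bypass the metabolite.
    """

    mediator_trait: str | None
    theta: float
    prevalence: float
    direct_effects: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass
class OutcomeData:
    outcome: np.ndarray  # 0/1
    liability: np.ndarray
    truth: dict


def generate_outcomes(
    genotypes: GenotypeData,
    traits: pd.DataFrame,
    disease_spec: DiseaseSpec,
    seed: int = 0,
) -> OutcomeData:
    """Draw a binary outcome by thresholding a Gaussian liability."""
    rng = np.random.default_rng(seed)
    n = len(traits)
    liab = np.zeros(n)
    if disease_spec.mediator_trait is not None and disease_spec.theta != 0.0:
        liab += disease_spec.theta * traits[disease_spec.mediator_trait].to_numpy()
    if disease_spec.direct_effects:
        vid_to_col = {v: i for i, v in enumerate(genotypes.variants["variant_id"])}
        for vid, beta in disease_spec.direct_effects.items():
            g = impute_dosages(genotypes.genotypes[:, [vid_to_col[vid]]])[:, 0]
            liab += beta * g
    explained = liab.var()
    liab = liab + rng.standard_normal(n)  # unit environmental noise
    cut = np.quantile(liab, 1.0 - disease_spec.prevalence)
    y = (liab > cut).astype(np.int8)
    truth = {
        "theta": disease_spec.theta,
        "mediator_trait": disease_spec.mediator_trait,
        "direct_effects": dict(disease_spec.direct_effects),
        "liability_var_explained": float(explained),
        "prevalence": disease_spec.prevalence,
    }
    return OutcomeData(outcome=y, liability=liab, truth=truth)
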
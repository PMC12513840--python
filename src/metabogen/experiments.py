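"""End-to-end calibration experiments on planted synthetic truth.

Each function simulates data with the cohort generator (or directly at the
summary-statistic level where the method itself only consumes summary
statistics), runs the corresponding pipeline stage, and scores the result
against the planted truth. They power both the test suite and the
reproduction script, and double as worked examples of the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import assoc, causal, effector, finemap, pleiotropy, rare, simulate

# ---------------------------------------------------------------------------
# fine-mapping coverage
# ---------------------------------------------------------------------------


def credible_set_coverage(
    n_reps: int = 300,
    n: int = 50_000,
    n_variants: int = 50,
    beta: float = 0.15,
    maf: float = 0.2,
    ld_decay: float = 0.9,
    seed: int = 0,
) -> float:
    """Fraction of single-causal replicates whose 95% set holds the causal variant.

    Per replicate: an LD block of ``n_variants`` at fixed MAF, one causal
    variant with a per-allele effect ``beta`` on a unit-variance trait, a
    marginal scan, Wakefield ABFs and the 95% credible set.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_reps):
        cfg = simulate.CohortConfig(
            n_individuals=n,
            n_strata=1,
            n_blocks=1,
            block_size=n_variants,
            ld_decay=ld_decay,
            maf_range=(maf, maf),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        gt = simulate.generate_genotypes(cfg)
        causal_j = int(rng.integers(0, n_variants))
        g = gt.genotypes[:, causal_j].astype(float)
        y = beta * g + rng.standard_normal(n)
        scan = assoc.run_scan(gt.genotypes, pd.Series(y, name="trait"), maf_min=0.0)
        labf = finemap.wakefield_log_abf(scan["beta"].to_numpy(), scan["se"].to_numpy())
        cs = finemap.credible_set(labf, variant_ids=scan["variant_id"].to_numpy())
        hits += gt.variants["variant_id"].iloc[causal_j] in cs.variants
    return hits / n_reps


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------


def coloc_recovery(
    n_reps: int = 100,
    n: int = 50_000,
    n_variants: int = 40,
    shared: bool = True,
    beta1: float = 0.15,
    beta2: float = 0.12,
    max_r2_distinct: float = 0.1,
    seed: int = 0,
) -> float:
    """Rate at which coloc recovers the planted sharing hypothesis.

    ``shared=True`` plants one causal variant driving both traits in two
    non-overlapping cohort halves and reports the PP4 > 0.8 rate;
    ``shared=False`` plants two causal variants with LD r^2 below
    ``max_r2_distinct`` and reports the PP3 > 0.8 rate.
    """
    rng = np.random.default_rng(seed)
    cfg = simulate.CohortConfig(
        n_individuals=n,
        n_strata=1,
        n_blocks=1,
        block_size=n_variants,
        ld_decay=0.9,
        maf_range=(0.15, 0.45),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    gt = simulate.generate_genotypes(cfg)
    half = n // 2
    G1, G2 = gt.genotypes[:half], gt.genotypes[half:]
    R = gt.ld[0]
    r2 = R**2
    vid = gt.variants["variant_id"].to_numpy()

    success = 0
    for _ in range(n_reps):
        c1 = int(rng.integers(0, n_variants))
        if shared:
            c2 = c1
        else:
            far = np.where(r2[c1] < max_r2_distinct)[0]
            c2 = int(rng.choice(far))
        y1 = beta1 * G1[:, c1].astype(float) + rng.standard_normal(half)
        y2 = beta2 * G2[:, c2].astype(float) + rng.standard_normal(G2.shape[0])
        s1 = assoc.run_scan(G1, pd.Series(y1, name="t1"), maf_min=0.0, variant_ids=vid)
        s2 = assoc.run_scan(G2, pd.Series(y2, name="t2"), maf_min=0.0, variant_ids=vid)
        res = causal.coloc_abf(s1[["variant_id", "beta", "se"]], s2[["variant_id", "beta", "se"]])
        success += (res.pp[4] if shared else res.pp[3]) > 0.8
    return success / n_reps


# ---------------------------------------------------------------------------
# pleiotropy-mode recovery
# ---------------------------------------------------------------------------


def mode_recovery(
    per_mode: int = 50,
    n: int = 50_000,
    seed: int = 0,
    effect_scale: float = 0.2,
) -> pd.DataFrame:
    """Confusion matrix of planted vs recovered pleiotropy modes.

    One cohort with ``5 * per_mode`` unlinked common variants, each planted
    with one mode; a multi-trait scan determines associated traits at the
    metabolome-adjusted threshold and :func:`~metabogen.pleiotropy.classify_mqtl`
    is scored against the planted truth. Returns a mode x mode count frame
    (rows = truth).
    """
    rng = np.random.default_rng(seed)
    modes = list(simulate.PLEIOTROPY_MODES)
    m = per_mode * len(modes)
    cfg = simulate.CohortConfig(
        n_individuals=n,
        n_strata=1,
        n_blocks=m // 10,
        block_size=10,
        ld_decay=0.0,
        maf_range=(0.1, 0.4),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    gt = simulate.generate_genotypes(cfg)
    spec = simulate.TraitPanelSpec.default(seed=int(rng.integers(0, 2**31 - 1)))
    planted_modes = np.repeat(modes, per_mode)
    order = rng.permutation(m)
    vids = gt.variants["variant_id"].to_numpy()
    effects = [
        simulate.make_planted_effect(planted_modes[k], spec, vids[order[k]], rng, effect_scale)
        for k in range(m)
    ]
    panel = simulate.generate_trait_panel(gt, spec, effects, seed=int(rng.integers(0, 2**31 - 1)))

    scan = assoc.run_scan(gt.genotypes, panel.traits, maf_min=0.0, variant_ids=vids)
    threshold = assoc.significance_threshold(5e-8, spec.n_traits)
    trait_corr = panel.traits.corr()

    confusion = pd.DataFrame(0, index=modes, columns=modes)
    by_variant = dict(tuple(scan.groupby("variant_id")))
    for k, eff in enumerate(effects):
        sub = by_variant.get(eff.variant_id)
        if sub is None:
            continue
        hits = sub[sub["p"] < threshold]
        if hits.empty:
            continue
        call = pleiotropy.classify_mqtl(k, hits[["trait_id", "p", "mlog10p"]], trait_corr)
        confusion.loc[eff.mode, call.mode] += 1
    return confusion


# ---------------------------------------------------------------------------
# Mendelian randomization calibration
# ---------------------------------------------------------------------------


def _simulate_instruments(
    rng: np.random.Generator,
    n_instruments: int,
    theta: float,
    se_exposure: float = 0.003,
    se_outcome: float = 0.01,
    pleiotropy_sd: float = 0.0,
) -> pd.DataFrame:
    bx = rng.uniform(0.05, 0.2, size=n_instruments)
    alpha = rng.normal(0.0, pleiotropy_sd, size=n_instruments) if pleiotropy_sd else 0.0
    return pd.DataFrame(
        {
            "beta_exposure": bx + rng.normal(0, se_exposure, n_instruments),
            "se_exposure": se_exposure,
            "beta_outcome": theta * bx + alpha + rng.normal(0, se_outcome, n_instruments),
            "se_outcome": se_outcome,
        }
    )


def ivw_bias(theta: float = 0.3, n_instruments: int = 50, n_reps: int = 100, seed: int = 0) -> float:
    """Mean bias of the IVW estimate over simulated two-sample screens."""
    rng = np.random.default_rng(seed)
    est = [causal.ivw(_simulate_instruments(rng, n_instruments, theta))["beta"] for _ in range(n_reps)]
    return float(np.mean(est) - theta)


def egger_intercept_type1(
    theta: float = 0.3, n_instruments: int = 50, n_reps: int = 1000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the Egger intercept test under no pleiotropy."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_reps):
        eg = causal.mr_egger(_simulate_instruments(rng, n_instruments, theta))
        rej += eg["intercept_p"] < alpha
    return rej / n_reps


def ivw_coverage(
    theta: float = 0.3, n_instruments: int = 50, n_reps: int = 500, seed: int = 0
) -> float:
    """Coverage of the nominal 95% IVW confidence interval."""
    rng = np.random.default_rng(seed)
    cover = 0
    for _ in range(n_reps):
        res = causal.ivw(_simulate_instruments(rng, n_instruments, theta))
        cover += abs(res["beta"] - theta) < 1.96 * res["se"]
    return cover / n_reps


# ---------------------------------------------------------------------------
# burden recovery and PGS robustness
# ---------------------------------------------------------------------------


def burden_effect_recovery(
    beta: float = 1.0, n: int = 20_000, n_carriers: int = 30, seed: int = 0, n_reps: int = 1
) -> tuple[float, float]:
    """(planted, recovered) burden effect for rare-carrier genes.

    With ``n_reps > 1`` the recovered value is the mean over independently
    simulated genes, shrinking the ~1/sqrt(n_carriers) sampling noise of a
    single gene.
    """
    rng = np.random.default_rng(seed)
    recovered = []
    for _ in range(n_reps):
        burden = np.zeros(n)
        burden[rng.choice(n, size=n_carriers, replace=False)] = 1.0
        y = beta * burden + rng.standard_normal(n)
        res = rare.burden_test(y, burden, alpha=1e-4)
        recovered.append(res.beta_nopgs)
    return beta, float(np.mean(recovered))


def pgs_robustness(
    n_genes: int = 200,
    n: int = 20_000,
    n_carriers: int = 50,
    beta_rare: float = 1.0,
    beta_common: float = 0.8,
    common_af: float = 0.3,
    alpha: float = 1e-4,
    seed: int = 0,
) -> dict:
    """Does the PGS-adjustment rule separate genuine from shadow rare signals?

    Half the genes are "contaminated": their carriers sit on the haplotype
    background of a common causal variant (carriers drawn from homozygous
    alternate individuals) and the gene has no rare effect of its own - the
    apparent burden association is a shadow of the common signal. The other
    half carry a genuine ``beta_rare`` burden effect independent of the
    common variant. Returns the fraction of contaminated genes flagged
    non-robust and of independent genes retaining robustness.
    """
    rng = np.random.default_rng(seed)
    contaminated_flagged = 0
    independent_robust = 0
    n_cont = n_genes // 2
    n_ind = n_genes - n_cont
    for g in range(n_genes):
        gc = rng.binomial(2, common_af, size=n)
        pgs = gc.astype(float)  # lead-variant polygenic score
        burden = np.zeros(n)
        if g < n_cont:
            hom = np.where(gc == 2)[0]
            carriers = rng.choice(hom, size=min(n_carriers, len(hom)), replace=False)
            burden[carriers] = 1.0
            y = beta_common * gc + rng.standard_normal(n)
        else:
            carriers = rng.choice(n, size=n_carriers, replace=False)
            burden[carriers] = 1.0
            y = beta_rare * burden + beta_common * gc + rng.standard_normal(n)
        res = rare.burden_test(y, burden, covariates=None, pgs=pgs, alpha=alpha)
        if g < n_cont:
            contaminated_flagged += not res.robust
        else:
            independent_robust += res.robust
    return {
        "contaminated_flagged_rate": contaminated_flagged / n_cont,
        "independent_robust_rate": independent_robust / n_ind,
    }


# ---------------------------------------------------------------------------
# effector-gene scoring on synthetic loci
# ---------------------------------------------------------------------------

_CLASS_CYCLE = ("cholesterol", "lipid", "amino_acid")


def make_synthetic_loci(n_loci: int = 120, genes_per_locus: int = 8, seed: int = 0) -> dict:
    """Synthetic loci where the causal gene carries fully informative features.

    Each locus holds one fine-mapped variant and ``genes_per_locus``
    candidate genes; the causal gene (closest for ~40% of loci, otherwise
    2nd-4th closest) carries coding-proxy, liver-eQTL and metabolic-database
    evidence while decoys carry none. Loci cycle through the three
    metabolite classes and the causal genes of a class form its pathway
    gene set.
    """
    rng = np.random.default_rng(seed)
    offsets = np.array([5_000, 50_000, 120_000, 200_000, 300_000, 450_000, 600_000, 800_000])[
        :genes_per_locus
    ]
    gene_rows, cand_rows, fm_rows = [], [], []
    truth = {}
    trait_class = {}
    gene_sets: dict[str, set[str]] = {c: set() for c in _CLASS_CYCLE}
    coding_rows, eqtl_rows = [], []
    for k in range(n_loci):
        vid = f"lead{k:04d}"
        vpos = 10_000_000 * (k + 1)
        cls = _CLASS_CYCLE[k % 3]
        trait = f"{cls}_trait_{k}"
        trait_class[trait] = cls
        fm_rows.append({"variant_id": vid, "trait_id": trait})
        causal_rank = int(rng.choice([1, 2, 3, 4], p=[0.4, 0.3, 0.2, 0.1]))
        side = rng.choice([-1, 1], size=genes_per_locus)
        for r, off in enumerate(offsets, start=1):
            gid = f"G{k:04d}_{r}"
            start = vpos + side[r - 1] * off
            gene_rows.append(
                {"gene_id": gid, "chrom": 1, "start": min(start, start + 20_000), "end": max(start, start + 20_000), "strand": "+"}
            )
            cand_rows.append({"variant_id": vid, "gene_id": gid, "distance_bp": int(off), "rank": r})
            if r == causal_rank:
                truth[vid] = gid
                gene_sets[cls].add(gid)
                coding_rows.append({"variant_id": vid, "gene_id": gid})
                eqtl_rows.append({"variant_id": vid, "gene_id": gid, "tissue": "liver"})
    return {
        "genes": pd.DataFrame(gene_rows),
        "candidates": pd.DataFrame(cand_rows),
        "finemapped": pd.DataFrame(fm_rows),
        "trait_class": trait_class,
        "gene_sets": gene_sets,
        "coding": pd.DataFrame(coding_rows),
        "eqtl": pd.DataFrame(eqtl_rows),
        "metabolic_genes": set(truth.values()),
        "truth": truth,
    }


EFFECTOR_FEATURES = ["distance_bp", "rank", "coding_proxy", "eqtl_liver", "eqtl_any", "metabolic_db"]


def effector_recovery(n_loci: int = 120, seed: int = 0) -> dict:
    """Top-1 causal-gene recovery of the three-classifier score vs closest gene."""
    loci = make_synthetic_loci(n_loci=n_loci, seed=seed)
    features = effector.build_features(
        loci["candidates"],
        coding=loci["coding"],
        eqtl=loci["eqtl"],
        metabolic_genes=loci["metabolic_genes"],
    )
    ptps = effector.construct_ptp(
        loci["finemapped"], loci["trait_class"], loci["gene_sets"], loci["candidates"], seed=seed
    )
    scorers = [
        effector.train_classifier(ptps[name], features, EFFECTOR_FEATURES, seed=seed)
        for name in effector.PTP_PRIORITY
    ]
    scored = effector.score_genes(scorers, features)
    top1 = scored.loc[scored.groupby("variant_id")["score"].idxmax()]
    truth = loci["truth"]
    hits = sum(truth[v] == g for v, g in zip(top1["variant_id"], top1["gene_id"]))
    closest = features[features["rank"] == 1]
    baseline = sum(truth[v] == g for v, g in zip(closest["variant_id"], closest["gene_id"]))
    return {
        "top1_recovery": hits / len(truth),
        "closest_gene_baseline": baseline / len(truth),
        "scorer_metrics": {s.name: s.metrics for s in scorers},
    }


# ---------------------------------------------------------------------------
# meta-analysis calibration
# ---------------------------------------------------------------------------


def q_null_calibration(n_reps: int = 10_000, k: int = 3, se: float = 0.1, seed: int = 0) -> dict:
    """Null distribution of Cochran Q against chi-square(k-1)."""
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    betas = rng.normal(0.0, se, size=(n_reps, k))
    ses = np.full(k, se)
    q = np.array([assoc.heterogeneity_test(b, ses)[0] for b in betas])
    return {
        "q95_empirical": float(np.quantile(q, 0.95)),
        "q95_theoretical": float(sps.chi2.ppf(0.95, k - 1)),
        "ks_p": float(sps.kstest(q, sps.chi2(k - 1).cdf).pvalue),
    }
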
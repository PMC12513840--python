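"""Rare-variant analysis: genotype QC, masks, burden tests, allelic series.

Genotype-level QC mirrors exome-sequencing practice (depth/quality masking,
allele-balance exclusion in heterozygous carriers, missingness cap). Six
partially overlapping consequence masks plus a synonymous negative control,
crossed with two MAF bins, feed per-gene collapsed burden tests whose p
values are combined by the aggregated Cauchy association test (ACAT).
Burden and single-variant models are refitted with a common-variant
polygenic score; a finding is robust only if it stays significant with and
without the PGS and its effect moves by at most 20%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import _residualize
from .simulate import MISSING

logger = logging.getLogger(__name__)

MASK_IDS = (
    "M1_pLOF_HC",
    "M2_pLOF",
    "M3_pLOF_highmiss",
    "M4_pLOF_anymiss",
    "M5_high_impact",
    "M6_missense_only",
    "S_synonymous",
)
MAF_BINS = {"maf_lt_0.5pct": 0.005, "maf_lt_0.005pct": 0.00005}

BURDEN_GENOME_P = 1.2e-8  # gene-level multiple-testing threshold
EXWAS_P = 2.0e-10
DISEASE_P = 7.5e-7
ROBUST_MAX_REL_DIFF = 0.20


# ---------------------------------------------------------------------------
# genotype-level QC
# ---------------------------------------------------------------------------


@dataclass
class QCResult:
    genotypes: np.ndarray  # filtered copy; failing calls set to MISSING
    variant_excluded: np.ndarray  # bool per variant
    log: pd.DataFrame  # variant_id, reason


def genotype_qc(
    genotypes: np.ndarray,
    dp: np.ndarray,
    gq: np.ndarray,
    ab: np.ndarray,
    is_indel: np.ndarray,
    variant_ids=None,
    dp_min_snp: int = 7,
    dp_min_indel: int = 10,
    gq_min: int = 20,
    ab_range: tuple[float, float] = (0.25, 0.8),
    max_missing: float = 0.5,
    ab_mode: str = "strict",
    ab_max_fail_fraction: float = 0.1,
) -> QCResult:
    """Exome genotype QC with known pass/fail semantics.

    1. Calls with DP below 7 (SNVs) / 10 (INDELs) or GQ below 20 are set
       missing.
    2. A variant is excluded when heterozygous carriers violate the allele
       balance window (0.25, 0.8): strictly (any failing het excludes, the
       default) or, with ``ab_mode='fraction'``, when more than
       ``ab_max_fail_fraction`` of hets fail.
    3. Variants with post-masking missingness above 50% are excluded.

    The operation is idempotent: applying it to its own output changes
    nothing.
    """
    if ab_mode not in {"strict", "fraction"}:
        raise ValueError("ab_mode must be 'strict' or 'fraction'")
    g = np.array(genotypes, dtype=np.int8, copy=True)
    n, m = g.shape
    if variant_ids is None:
        variant_ids = np.array([f"var{i:05d}" for i in range(m)])
    is_indel = np.asarray(is_indel, dtype=bool)

    dp_min = np.where(is_indel, dp_min_indel, dp_min_snp)[None, :]
    bad_call = (np.asarray(dp) < dp_min) | (np.asarray(gq) < gq_min)
    g[bad_call & (g != MISSING)] = MISSING

    excluded = np.zeros(m, dtype=bool)
    reasons: dict[str, str] = {}
    het = g == 1
    ab = np.asarray(ab, dtype=float)
    lo, hi = ab_range
    fails = het & ((ab < lo) | (ab > hi))
    for j in range(m):
        n_het = int(het[:, j].sum())
        if n_het == 0:
            continue
        n_fail = int(fails[:, j].sum())
        bad = n_fail > 0 if ab_mode == "strict" else n_fail / n_het > ab_max_fail_fraction
        if bad:
            excluded[j] = True
            reasons[str(variant_ids[j])] = "allele_balance"

    missing_frac = (g == MISSING).mean(axis=0)
    miss_bad = (missing_frac > max_missing) & ~excluded
    excluded |= missing_frac > max_missing
    for j in np.where(miss_bad)[0]:
        reasons[str(variant_ids[j])] = "missingness"

    log = pd.DataFrame(
        {"variant_id": list(reasons.keys()), "reason": list(reasons.values())}
    )
    return QCResult(genotypes=g, variant_excluded=excluded, log=log)


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------


def _mask_predicate(mask_id: str, ann: pd.DataFrame) -> pd.Series:
    csq = ann["consequence"]
    plof_hc = csq == "pLOF_HC"
    plof_any = csq.isin(["pLOF_HC", "pLOF"])
    missense = csq == "missense"
    high_missense = missense & ((ann["cadd"] > 20) | (ann["revel"] > 0.5))
    if mask_id == "M1_pLOF_HC":
        return plof_hc
    if mask_id == "M2_pLOF":
        return plof_any
    if mask_id == "M3_pLOF_highmiss":
        return plof_any | high_missense
    if mask_id == "M4_pLOF_anymiss":
        return plof_any | missense
    if mask_id == "M5_high_impact":
        return ann["impact"] == "HIGH"
    if mask_id == "M6_missense_only":
        return missense
    if mask_id == "S_synonymous":
        return csq == "synonymous"
    raise ValueError(f"unknown mask {mask_id!r}")


def build_masks(annotations: pd.DataFrame) -> pd.DataFrame:
    """Cross the seven consequence masks with the two MAF bins, per gene.

    Returns a long table (gene_id, mask, maf_bin, variant_id). Variants with
    an unknown consequence class enter no mask and are counted in a log
    message. The bins are nested: everything below 0.005% is also below 0.5%.
    """
    known = annotations["consequence"].isin(["pLOF_HC", "pLOF", "missense", "synonymous", "other"])
    if (~known).any():
        logger.info("build_masks: %d variants with unknown consequence excluded", int((~known).sum()))
    ann = annotations[known]
    rows = []
    for mask_id in MASK_IDS:
        members = ann[_mask_predicate(mask_id, ann)]
        for bin_name, maf_max in MAF_BINS.items():
            in_bin = members[members["maf"] < maf_max]
            for row in in_bin.itertuples():
                rows.append((row.gene_id, mask_id, bin_name, row.variant_id))
    return pd.DataFrame(rows, columns=["gene_id", "mask", "maf_bin", "variant_id"])


def burden_collapse(genotypes: np.ndarray, member_cols: np.ndarray) -> np.ndarray:
    """Capped per-individual burden: ``min(2, sum of alt alleles)``.

    Missing calls count as zero alt alleles (the per-gene missingness is the
    caller's to report).
    """
    if len(member_cols) == 0:
        raise ValueError("empty mask")
    g = np.asarray(genotypes[:, member_cols], dtype=float)
    g[g == MISSING] = 0.0
    return np.minimum(2.0, g.sum(axis=1))


# ---------------------------------------------------------------------------
# ACAT
# ---------------------------------------------------------------------------


def acat(p_values, weights=None) -> float:
    """Aggregated Cauchy association test combination of p values.

    ``T = sum w_j tan((0.5 - p_j) pi) / sum w_j``; the combined p value is
    ``0.5 - arctan(T)/pi``. Tiny inputs (below 1e-15) and huge statistics use
    the tangent asymptote ``tan((0.5-p)pi) ~ 1/(p pi)`` to avoid overflow and
    cancellation, so k identical p values return exactly p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("acat requires at least one p value")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p values must lie in (0, 1)")
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be nonnegative and not all zero")
    w = w / w.sum()
    # tan((0.5-p)pi) = cot(p*pi): the small-argument form keeps full relative
    # precision for small p, where the direct tangent near pi/2 loses ~5
    # digits; below 1e-15 the asymptote avoids overflow entirely
    terms = np.empty_like(p)
    small = p < 0.5
    tiny = p < 1e-15
    terms[small & ~tiny] = 1.0 / np.tan(p[small & ~tiny] * np.pi)
    terms[tiny] = 1.0 / (p[tiny] * np.pi)
    terms[~small] = np.tan((0.5 - p[~small]) * np.pi)
    t = float(np.sum(w * terms))
    if t > 1e15:
        return 1.0 / (t * np.pi)
    if t > 1.0:  # arctan(1/t) form avoids cancellation in 0.5 - arctan(t)/pi
        return float(np.arctan(1.0 / t) / np.pi)
    return float(0.5 - np.arctan(t) / np.pi)


# ---------------------------------------------------------------------------
# burden / single-variant / disease tests
# ---------------------------------------------------------------------------


@dataclass
class BurdenResult:
    gene_id: str
    trait_id: str
    mask: str = ""
    maf_bin: str = ""
    beta_pgs: float = np.nan
    se_pgs: float = np.nan
    p_pgs: float = np.nan
    beta_nopgs: float = np.nan
    se_nopgs: float = np.nan
    p_nopgs: float = np.nan
    acat_p: float = np.nan
    n_carriers: int = 0
    robust: bool = False
    per_mask: pd.DataFrame | None = field(default=None, repr=False)


def _ols_beta(y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None):
    xr, rank = _residualize(x[:, None], covariates)
    yr, _ = _residualize(y, covariates)
    xr = xr[:, 0]
    gss = float(xr @ xr)
    if gss == 0:
        return np.nan, np.nan, np.nan
    beta = float(xr @ yr) / gss
    dof = max(len(y) - rank - 1, 1)
    rss = max(float(yr @ yr) - beta**2 * gss, 0.0)
    se = float(np.sqrt(rss / dof / gss))
    if not np.isfinite(se) or se == 0:
        return beta, np.nan, np.nan
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), np.finfo(float).tiny, 1.0))
    return beta, se, p


def burden_test(
    trait: np.ndarray,
    burden: np.ndarray,
    covariates: np.ndarray | None = None,
    pgs: np.ndarray | None = None,
    alpha: float = BURDEN_GENOME_P,
    gene_id: str = "gene",
    trait_id: str = "trait",
    robust_max_rel_diff: float = ROBUST_MAX_REL_DIFF,
) -> BurdenResult:
    """Linear burden model with and without common-variant PGS adjustment.

    ``robust`` requires significance at ``alpha`` in both models and a
    relative effect-size change of at most 20% - otherwise the rare signal
    may be a shadow of nearby common variants.
    """
    burden = np.asarray(burden, dtype=float)
    if burden.std() == 0:
        logger.info("zero-variance burden for %s; skipped", gene_id)
        return BurdenResult(gene_id=gene_id, trait_id=trait_id)
    y = np.asarray(trait, dtype=float)
    b0, s0, p0 = _ols_beta(y, burden, covariates)
    if pgs is not None:
        cov_pgs = (
            np.column_stack([covariates, pgs]) if covariates is not None else np.asarray(pgs)[:, None]
        )
    else:
        cov_pgs = covariates
    b1, s1, p1 = _ols_beta(y, burden, cov_pgs)
    rel = abs(b1 - b0) / abs(b0) if b0 not in (0.0,) and np.isfinite(b0) else np.inf
    robust = (
        np.isfinite(p0) and np.isfinite(p1) and p0 < alpha and p1 < alpha and rel <= robust_max_rel_diff
    )
    return BurdenResult(
        gene_id=gene_id,
        trait_id=trait_id,
        beta_pgs=b1,
        se_pgs=s1,
        p_pgs=p1,
        beta_nopgs=b0,
        se_nopgs=s0,
        p_nopgs=p0,
        n_carriers=int((burden > 0).sum()),
        robust=robust,
    )


def gene_burden_scan(
    genotypes: np.ndarray,
    annotations: pd.DataFrame,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    pgs: np.ndarray | None = None,
    alpha: float = BURDEN_GENOME_P,
    trait_id: str = "trait",
    acat_weights=None,
) -> list[BurdenResult]:
    """Per-gene burden tests across masks x MAF bins, ACAT-combined.

    The reported per-gene effect/robustness comes from the most significant
    (PGS-adjusted) mask x bin combination; ``acat_p`` combines the
    PGS-adjusted p values of every combination of that gene.
    """
    masks = build_masks(annotations)
    vid_to_col = {v: i for i, v in enumerate(annotations["variant_id"])}
    results = []
    for gene, gene_masks in masks.groupby("gene_id"):
        per_mask_rows = []
        for (mask_id, bin_name), grp in gene_masks.groupby(["mask", "maf_bin"]):
            cols = np.array([vid_to_col[v] for v in grp["variant_id"]])
            burden = burden_collapse(genotypes, cols)
            res = burden_test(
                trait, burden, covariates, pgs, alpha, gene_id=gene, trait_id=trait_id
            )
            if np.isfinite(res.p_pgs):
                per_mask_rows.append(
                    {
                        "mask": mask_id,
                        "maf_bin": bin_name,
                        "beta_pgs": res.beta_pgs,
                        "se_pgs": res.se_pgs,
                        "p_pgs": res.p_pgs,
                        "beta_nopgs": res.beta_nopgs,
                        "p_nopgs": res.p_nopgs,
                        "n_carriers": res.n_carriers,
                        "robust": res.robust,
                    }
                )
        if not per_mask_rows:
            continue
        per_mask = pd.DataFrame(per_mask_rows)
        # synonymous control is not folded into the gene-level combination
        test_rows = per_mask[per_mask["mask"] != "S_synonymous"]
        if test_rows.empty:
            continue
        acat_p = acat(test_rows["p_pgs"].to_numpy(), acat_weights)
        best = test_rows.loc[test_rows["p_pgs"].idxmin()]
        results.append(
            BurdenResult(
                gene_id=gene,
                trait_id=trait_id,
                mask=best["mask"],
                maf_bin=best["maf_bin"],
                beta_pgs=best["beta_pgs"],
                se_pgs=best["se_pgs"],
                p_pgs=best["p_pgs"],
                beta_nopgs=best["beta_nopgs"],
                p_nopgs=best["p_nopgs"],
                acat_p=acat_p,
                n_carriers=int(best["n_carriers"]),
                robust=bool(best["robust"]),
                per_mask=per_mask,
            )
        )
    return results


def exwas(
    genotype: np.ndarray,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
    pgs: np.ndarray | None = None,
    mac_min: int = 5,
    maf_report: float = 0.0005,
    alpha: float = EXWAS_P,
    variant_id: str = "variant",
    trait_id: str = "trait",
) -> dict | None:
    """Single rare-variant test: run when MAC > 5, report when MAF < 0.05%.

    Returns None for untested variants; tested-but-unreportable variants
    come back with ``reported=False``. The PGS-robustness contract matches
    :func:`burden_test`.
    """
    g = np.asarray(genotype, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    g = np.where(np.isnan(g), np.nanmean(g), g)
    af = g.mean() / 2.0
    mac = min(g.sum(), 2 * len(g) - g.sum())
    if mac <= mac_min:
        return None
    maf = min(af, 1 - af)
    res = burden_test(
        trait, g, covariates, pgs, alpha, gene_id=variant_id, trait_id=trait_id
    )
    return {
        "variant_id": variant_id,
        "trait_id": trait_id,
        "mac": int(mac),
        "maf": float(maf),
        "beta_pgs": res.beta_pgs,
        "se_pgs": res.se_pgs,
        "p_pgs": res.p_pgs,
        "beta_nopgs": res.beta_nopgs,
        "p_nopgs": res.p_nopgs,
        "robust": res.robust,
        "reported": bool(maf < maf_report),
    }


def disease_burden(
    outcome: np.ndarray,
    burden: np.ndarray,
    covariates: np.ndarray | None = None,
    min_carriers: int = 10,
) -> dict:
    """Logistic burden-disease model with a minimum-carrier guard.

    Returns odds ratio per burden unit, SE of the log-OR and a Wald p;
    complete separation is flagged without an estimate.
    """
    burden = np.asarray(burden, dtype=float)
    carriers = int((burden > 0).sum())
    if carriers < min_carriers:
        return {"or": np.nan, "se": np.nan, "p": np.nan, "n_carriers": carriers, "flag": "too_few_carriers"}
    y = np.asarray(outcome, dtype=float)
    X = np.column_stack([np.ones(len(y)), burden])
    if covariates is not None:
        X = np.column_stack([X, covariates])
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.bse[1]) or fit.bse[1] > 50:
            raise ValueError("separation")
        return {
            "or": float(np.exp(fit.params[1])),
            "se": float(fit.bse[1]),
            "p": float(fit.pvalues[1]),
            "n_carriers": carriers,
            "flag": "",
        }
    except Exception:
        logger.warning("disease_burden: separation or non-convergence; no estimate")
        return {"or": np.nan, "se": np.nan, "p": np.nan, "n_carriers": carriers, "flag": "separation"}


# ---------------------------------------------------------------------------
# allelic series
# ---------------------------------------------------------------------------


def allelic_series(
    rare_hits: pd.DataFrame,
    common_leads: pd.DataFrame,
    effector_assignments: pd.DataFrame | None = None,
    series_window: int = 200_000,
) -> pd.DataFrame:
    """Convergence of rare hits with common credible-set leads.

    ``rare_hits`` needs gene_id, trait_id, chrom, pos; ``common_leads`` needs
    variant_id, trait_id, chrom, pos; ``effector_assignments`` (optional)
    needs variant_id, gene_id, assigned. Per rare hit: distance to the
    nearest same-trait lead, flags at 100 kb / 500 kb / 1 Mb, and a series
    flag when an assigned effector gene within 200 kb names the hit's gene.
    """
    rows = []
    assigned = None
    if effector_assignments is not None:
        assigned = effector_assignments[effector_assignments["assigned"]]
    for hit in rare_hits.itertuples():
        leads = common_leads[
            (common_leads["trait_id"] == hit.trait_id) & (common_leads["chrom"] == hit.chrom)
        ]
        if leads.empty:
            rows.append(
                {
                    "gene_id": hit.gene_id,
                    "trait_id": hit.trait_id,
                    "distance_bp": np.nan,
                    "nearest_lead": None,
                    "within_100kb": False,
                    "within_500kb": False,
                    "beyond_1Mb": False,
                    "series": False,
                }
            )
            continue
        d = (leads["pos"] - hit.pos).abs()
        j = d.idxmin()
        dist = int(d.loc[j])
        series = False
        if assigned is not None:
            near = common_leads[
                (common_leads["chrom"] == hit.chrom)
                & ((common_leads["pos"] - hit.pos).abs() <= series_window)
            ]
            near_assign = assigned[assigned["variant_id"].isin(near["variant_id"])]
            series = bool((near_assign["gene_id"] == hit.gene_id).any())
        rows.append(
            {
                "gene_id": hit.gene_id,
                "trait_id": hit.trait_id,
                "distance_bp": dist,
                "nearest_lead": leads.loc[j, "variant_id"],
                "within_100kb": dist < 100_000,
                "within_500kb": dist < 500_000,
                "beyond_1Mb": dist > 1_000_000,
                "series": series,
            }
        )
    return pd.DataFrame(rows)
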
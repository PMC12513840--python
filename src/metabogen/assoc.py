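"""Association core: medication correction, per-variant scans, meta-analysis.

The scan is an ordinary least-squares additive-model regression after
projecting out covariates (a covariate-adjusted replacement for whole-genome
regression machinery, appropriate because the synthetic cohorts carry no
cryptic structure unless it is planted). Strata are combined by fixed-effect
inverse-variance weighting with a Cochran Q heterogeneity test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import MISSING, impute_dosages

logger = logging.getLogger(__name__)

#: trans-ancestral heterogeneity flag threshold
ANCESTRY_HET_P = 1e-4
#: sex heterogeneity flag threshold
SEX_HET_P = 5e-8


@dataclass
class SummaryStatRecord:
    """One variant x trait x stratum association."""

    variant_id: str
    trait_id: str
    stratum: str
    beta: float
    se: float
    p: float
    af: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        if not 0.0 < self.af < 1.0:
            raise ValueError("af must lie in (0, 1)")


def significance_threshold(base: float = 5e-8, n_traits: int = 249) -> float:
    """Metabolome-adjusted genome-wide threshold: ``base / n_traits``.

    Full precision is returned; round to two significant figures for display
    (5e-8 / 249 prints as 2.0e-10).
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    return base / n_traits


def variance_explained(af: float | np.ndarray, beta: float | np.ndarray, trait_variance: float = 1.0):
    """Trait variance explained by an additive variant: ``2 f (1-f) beta^2``."""
    af = np.asarray(af, dtype=float)
    if np.any((af <= 0) | (af >= 1)):
        raise ValueError("af must lie in (0, 1)")
    out = 2.0 * af * (1.0 - af) * np.asarray(beta, dtype=float) ** 2 / trait_variance
    return float(out) if out.ndim == 0 else out


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Project out an intercept plus covariates; return residuals and rank used."""
    n = y.shape[0]
    if covariates is None:
        X = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([np.ones(n), C])
    Q, _ = np.linalg.qr(X)
    return y - Q @ (Q.T @ y), X.shape[1]


def run_scan(
    genotypes,
    trait,
    covariates=None,
    maf_min: float = 0.005,
    stratum: str = "all",
    variant_ids=None,
) -> pd.DataFrame:
    """Per-variant additive OLS scan of one trait or a trait matrix.

    Parameters
    ----------
    genotypes
        (n, m) dosage/genotype array (``MISSING`` mean-imputed) or a
        :class:`~metabogen.simulate.GenotypeData`.
    trait
        Length-n vector, or an (n, T) DataFrame for a vectorized multi-trait
        scan.
    covariates
        Optional (n, c) array; an intercept is always included. Covariates
        are projected out of both trait and genotype (Frisch-Waugh), giving
        the same betas as the joint model.
    maf_min
        Variants below this minor allele frequency are skipped (common-variant
        scan default 0.5%); monomorphic variants are skipped with a log entry.

    Returns
    -------
    DataFrame with columns variant_id, trait_id, beta, se, z, p, af, n.
    """
    if hasattr(genotypes, "genotypes"):
        if variant_ids is None:
            variant_ids = genotypes.variants["variant_id"].to_numpy()
        genotypes = genotypes.genotypes
    G = impute_dosages(genotypes) if (np.asarray(genotypes) == MISSING).any() else np.asarray(
        genotypes, dtype=float
    )
    n, m = G.shape
    if variant_ids is None:
        variant_ids = np.array([f"var{i:05d}" for i in range(m)])

    if isinstance(trait, pd.DataFrame):
        Y = trait.to_numpy(dtype=float)
        trait_names = list(trait.columns)
    else:
        Y = np.asarray(trait, dtype=float)[:, None]
        trait_names = [getattr(trait, "name", None) or "trait"]

    af = G.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    keep = maf >= maf_min
    mono = G.std(axis=0) == 0.0
    if mono.any():
        logger.info("run_scan: skipping %d monomorphic variants", int(mono.sum()))
    keep &= ~mono
    if not keep.any():
        return pd.DataFrame(
            columns=["variant_id", "trait_id", "beta", "se", "z", "p", "af", "n"]
        )

    Gr, rank = _residualize(G[:, keep], covariates)
    Yr, _ = _residualize(Y, covariates)
    gss = (Gr**2).sum(axis=0)  # (m,)
    # variants absorbed by the covariates (projected to ~zero) get a null effect
    absorbed = gss < 1e-8 * n
    gss[absorbed] = np.nan
    beta = (Gr.T @ Yr) / gss[:, None]  # (m, T)
    beta[absorbed] = 0.0
    dof = n - rank - 1
    rss = (Yr**2).sum(axis=0)[None, :] - beta**2 * gss[:, None]
    sigma2 = np.clip(rss, 0.0, None) / dof
    se = np.sqrt(sigma2 / gss[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    # association strength on the log scale, immune to p-value underflow
    mlog10p = -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / np.log(10.0)

    kept_ids = np.asarray(variant_ids)[keep]
    out = pd.DataFrame(
        {
            "variant_id": np.repeat(kept_ids, len(trait_names)),
            "trait_id": np.tile(trait_names, keep.sum()),
            "beta": beta.ravel(),
            "se": se.ravel(),
            "z": z.ravel(),
            "p": p.ravel(),
            "mlog10p": mlog10p.ravel(),
            "af": np.repeat(af[keep], len(trait_names)),
            "n": n,
        }
    )
    out["stratum"] = stratum
    return out


# ---------------------------------------------------------------------------
# meta-analysis
# ---------------------------------------------------------------------------


def meta_fixed(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float]:
    """Fixed-effect inverse-variance weighted pooled beta and SE."""
    w = 1.0 / np.asarray(ses, dtype=float) ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    return beta, float(1.0 / np.sqrt(np.sum(w)))


def heterogeneity_test(betas, ses) -> tuple[float, int, float]:
    """Cochran Q across strata: returns (Q, df, p).

    ``Q = sum w_i (beta_i - beta_meta)^2`` with IVW weights, referred to a
    chi-square with k-1 degrees of freedom.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if len(betas) < 2:
        raise ValueError("heterogeneity requires >=2 strata")
    w = 1.0 / ses**2
    bm = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - bm) ** 2))
    df = len(betas) - 1
    return q, df, float(stats.chi2.sf(q, df))


def inverse_variance_meta(
    records: pd.DataFrame,
    min_strata: int = 2,
    scheme: str = "ivw",
    het_flag_p: float = ANCESTRY_HET_P,
) -> pd.DataFrame:
    """Fixed-effect meta-analysis of per-stratum records.

    ``records`` needs columns variant_id, trait_id, stratum, beta, se (and n
    for the sample-size-weighted scheme). Variant x trait combinations seen
    in fewer than ``min_strata`` strata are excluded, mirroring the
    requirement that variants be present in at least two ancestral groups.

    ``scheme='ivw'`` pools effect sizes by inverse-variance weights;
    ``scheme='samplesize'`` pools Z scores by sqrt(n) weights (effect kept as
    the IVW value in that case, the Z/p replaced).
    """
    if scheme not in {"ivw", "samplesize"}:
        raise ValueError("scheme must be 'ivw' or 'samplesize'")
    rows = []
    for (vid, trait), grp in records.groupby(["variant_id", "trait_id"], sort=False):
        grp = grp.drop_duplicates("stratum")
        k = len(grp)
        if k < min_strata:
            continue
        b = grp["beta"].to_numpy()
        s = grp["se"].to_numpy()
        beta_meta, se_meta = meta_fixed(b, s)
        if scheme == "ivw":
            z = beta_meta / se_meta
        else:
            w = np.sqrt(grp["n"].to_numpy(dtype=float))
            z = float(np.sum(w * b / s) / np.sqrt(np.sum(w**2)))
        if k >= 2:
            q, df, p_het = heterogeneity_test(b, s)
        else:  # single stratum allowed only when min_strata is relaxed
            q, df, p_het = 0.0, 0, np.nan
        rows.append(
            {
                "variant_id": vid,
                "trait_id": trait,
                "beta_meta": beta_meta,
                "se_meta": se_meta,
                "z": z,
                "p": float(np.clip(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny, 1.0)),
                "n_strata": k,
                "q_stat": q,
                "q_df": df,
                "p_het": p_het,
                "het_flag": p_het < het_flag_p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# medication adjustment
# ---------------------------------------------------------------------------


def adjust_medication(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    age: np.ndarray,
    bmi: np.ndarray,
    med_baseline: np.ndarray,
    med_followup: pd.Series,
    sex: np.ndarray,
    min_per_sex: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimate and remove the cholesterol-medication shift, per sex.

    For each sex, using only individuals untreated at baseline with a repeat
    visit (the rows of ``followup``), fits per trait::

        baseline ~ followup + age + bmi + med_followup

    The implied medication effect is the *negated* regression coefficient on
    the follow-up medication indicator (new users' follow-up values carry the
    shift, so the model sees baseline values sitting ``-effect`` away from
    them); that coefficient is subtracted from treated individuals' baseline
    values. Note the estimate is attenuated by the test-retest correlation of
    the trait.

    Returns (corrected baseline matrix, per-trait/per-sex coefficient table).
    """
    sexes = np.unique(sex)
    corrected = baseline.copy()
    fu_idx = followup.index.to_numpy()
    coefs = []
    for sx in sexes:
        rows = fu_idx[np.asarray(sex)[fu_idx] == sx]
        if len(rows) < min_per_sex:
            warnings.warn(
                f"adjust_medication: only {len(rows)} eligible individuals for sex {sx!r}; "
                "skipping correction for that sex",
                stacklevel=2,
            )
            for t in baseline.columns:
                coefs.append({"trait_id": t, "sex": sx, "med_coef": np.nan, "se": np.nan, "n": len(rows)})
            continue
        med = med_followup.loc[rows].to_numpy(dtype=float)
        X = np.column_stack(
            [
                np.ones(len(rows)),
                np.zeros(len(rows)),  # placeholder for the follow-up trait
                np.asarray(age)[rows],
                np.asarray(bmi)[rows],
                med,
            ]
        )
        treat_rows = np.asarray(med_baseline, dtype=bool) & (np.asarray(sex) == sx)
        for ti, t in enumerate(baseline.columns):
            X[:, 1] = followup[t].loc[rows].to_numpy()
            y = baseline[t].to_numpy()[rows]
            coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            dof = max(len(rows) - X.shape[1], 1)
            xtx_inv = np.linalg.pinv(X.T @ X)
            se = float(np.sqrt(resid @ resid / dof * xtx_inv[-1, -1]))
            med_coef = -coef[-1]  # implied effect of medication on the trait
            coefs.append({"trait_id": t, "sex": sx, "med_coef": med_coef, "se": se, "n": len(rows)})
            corrected.loc[treat_rows, t] = baseline.loc[treat_rows, t] - med_coef
    return corrected, pd.DataFrame(coefs)
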
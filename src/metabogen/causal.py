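"""Causal integration: colocalization (locus effects) and MR (level effects).

Colocalization enumerates the five sharing hypotheses from per-variant
Wakefield log Bayes factors of two traits with the standard priors (p1, p2
for trait-specific causal variants, p12 = 5e-6 for a shared one).
Mendelian randomization estimates metabolite-to-disease "level" effects by
the Wald ratio, fixed-effect IVW and MR-Egger, with an Egger-intercept
pleiotropy filter, sign-concordance check and 5% FDR. Instruments come in
four tiers of increasing pleiotropy stringency; loci and levels converge
into candidate causal metabolite-disease pairs with an LDL-independence
flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .finemap import DEFAULT_PRIOR_VAR, wakefield_log_abf

logger = logging.getLogger(__name__)

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 5e-6
PP4_THRESHOLD = 0.8
EGGER_INTERCEPT_P = 1e-4
LDL_LOCUS_P = 2.0e-10
LDL_EFFECT_PERCENTILE = 80.0

TIER_NAMES = ("sentinels", "leads", "molecular_filtered", "molecular_phenotypic_filtered")


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------


@dataclass
class ColocResult:
    pp: np.ndarray  # pp0..pp4
    priors: tuple[float, float, float]
    n_variants: int
    low_confidence: bool = False

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    prior_var1: float = DEFAULT_PRIOR_VAR,
    prior_var2: float = DEFAULT_PRIOR_VAR,
    min_variants: int = 10,
) -> ColocResult:
    """Posterior probabilities of the five colocalization hypotheses.

    ``stats1``/``stats2`` carry beta and se per variant on a shared,
    harmonized grid (rows aligned, e.g. via variant_id). Hypotheses: H0 no
    association, H1/H2 only trait 1/2, H3 two distinct causal variants, H4
    one shared causal variant. Evidence accumulates in log space from the
    per-variant Wakefield log ABFs::

        S1 = sum_j ABF1_j        S2 = sum_j ABF2_j
        S12 = sum_j ABF1_j ABF2_j
        H0 : 1             H1 : p1 S1       H2 : p2 S2
        H3 : p1 p2 (S1 S2 - S12)            H4 : p12 S12
    """
    if "variant_id" in stats1 and "variant_id" in stats2:
        merged = stats1.merge(stats2, on="variant_id", suffixes=("_1", "_2"))
        b1, s1 = merged["beta_1"].to_numpy(), merged["se_1"].to_numpy()
        b2, s2 = merged["beta_2"].to_numpy(), merged["se_2"].to_numpy()
    else:
        if len(stats1) != len(stats2):
            raise ValueError("stats frames must align on a shared variant grid")
        b1, s1 = stats1["beta"].to_numpy(), stats1["se"].to_numpy()
        b2, s2 = stats2["beta"].to_numpy(), stats2["se"].to_numpy()
    m = len(b1)
    if m == 0:
        raise ValueError("no shared variants")
    l1 = wakefield_log_abf(b1, s1, prior_var1)
    l2 = wakefield_log_abf(b2, s2, prior_var2)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    log_s1 = logsumexp(l1)
    log_s2 = logsumexp(l2)
    log_s12 = logsumexp(l1 + l2)
    # S1*S2 - S12, guarded in log space
    log_cross = log_s1 + log_s2
    if log_cross > log_s12:
        log_h3_sum = log_cross + np.log1p(-np.exp(log_s12 - log_cross))
    else:  # single variant or degenerate grid: no distinct-variant configurations
        log_h3_sum = -np.inf

    lh = np.array(
        [
            0.0,
            np.log(p1) + log_s1,
            np.log(p2) + log_s2,
            (np.log(p1) + np.log(p2) + log_h3_sum) if np.isfinite(log_h3_sum) else -np.inf,
            np.log(p12) + log_s12,
        ]
    )
    pp = np.exp(lh - logsumexp(lh))
    low_conf = m < min_variants
    if low_conf:
        logger.info("coloc on %d (<%d) shared variants; flagged low-confidence", m, min_variants)
    return ColocResult(pp=pp, priors=(p1, p2, p12), n_variants=m, low_confidence=low_conf)


def coloc_signals(
    trait_signals: list[pd.DataFrame],
    outcome_signals: list[pd.DataFrame],
    max_outcome_signals: int = 5,
    **kwargs,
) -> list[tuple[int, int, ColocResult]]:
    """All (trait signal x outcome signal) colocalizations, outcome capped at 5."""
    results = []
    for i, ts in enumerate(trait_signals):
        for j, os_ in enumerate(outcome_signals[:max_outcome_signals]):
            results.append((i, j, coloc_abf(ts, os_, **kwargs)))
    return results


# ---------------------------------------------------------------------------
# Mendelian randomization
# ---------------------------------------------------------------------------


def wald_ratio(beta_exposure, se_exposure, beta_outcome, se_outcome) -> dict:
    """Single-instrument causal estimate with first-order delta-method SE."""
    if beta_exposure == 0:
        raise ZeroDivisionError("beta_exposure must be nonzero")
    ratio = beta_outcome / beta_exposure
    se = abs(se_outcome / beta_exposure)
    weak = abs(beta_exposure / se_exposure) < 2
    if weak:
        logger.info("weak instrument: |beta/se| < 2")
    p = float(np.clip(2.0 * stats.norm.sf(abs(ratio / se)), np.finfo(float).tiny, 1.0)) if se > 0 else np.nan
    return {"beta": float(ratio), "se": float(se), "p": p, "weak_instrument": bool(weak)}


def ivw(instruments: pd.DataFrame) -> dict:
    """Fixed-effect inverse-variance weighted MR estimate.

    ``beta = sum(bx by / sy^2) / sum(bx^2 / sy^2)``, the weighted regression
    of outcome on exposure effects through the origin;
    ``se = 1/sqrt(sum(bx^2/sy^2))``. Needs columns beta_exposure,
    beta_outcome, se_outcome (>=2 rows; defer to the Wald ratio otherwise).
    """
    if len(instruments) < 2:
        raise ValueError("ivw requires >=2 instruments; use wald_ratio")
    bx = instruments["beta_exposure"].to_numpy(dtype=float)
    by = instruments["beta_outcome"].to_numpy(dtype=float)
    sy = instruments["se_outcome"].to_numpy(dtype=float)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se = float(1.0 / np.sqrt(denom))
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), np.finfo(float).tiny, 1.0))
    return {"beta": beta, "se": se, "p": p, "n_instruments": len(instruments)}


def mr_egger(instruments: pd.DataFrame) -> dict:
    """MR-Egger: weighted regression of outcome on exposure betas with intercept.

    Instruments are oriented so every exposure beta is nonnegative; weights
    are 1/se_outcome^2. The intercept estimates directional pleiotropy, with
    p > 1e-4 read as no evidence of pleiotropy. P values use the t
    distribution with n-2 degrees of freedom.
    """
    if len(instruments) < 3:
        raise ValueError("mr_egger requires >=3 instruments")
    bx = instruments["beta_exposure"].to_numpy(dtype=float)
    by = instruments["beta_outcome"].to_numpy(dtype=float)
    sy = instruments["se_outcome"].to_numpy(dtype=float)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    dof = len(bx) - 2
    sigma2 = float(resid @ (w * resid)) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    ses = np.sqrt(np.diag(cov))
    t_int = coef[0] / ses[0]
    t_slope = coef[1] / ses[1]
    return {
        "beta": float(coef[1]),
        "se": float(ses[1]),
        "p": float(np.clip(2.0 * stats.t.sf(abs(t_slope), dof), np.finfo(float).tiny, 1.0)),
        "intercept": float(coef[0]),
        "intercept_se": float(ses[0]),
        "intercept_p": float(np.clip(2.0 * stats.t.sf(abs(t_int), dof), np.finfo(float).tiny, 1.0)),
        "n_instruments": len(instruments),
    }


@dataclass
class MRResult:
    exposure: str
    outcome: str
    tier: str
    beta_ivw: float
    se_ivw: float
    p_ivw: float
    beta_egger: float = np.nan
    se_egger: float = np.nan
    p_egger: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_p: float = np.nan
    median_wald: float = np.nan
    fdr_q: float = np.nan
    pass_filters: bool = False
    wald_ratios: pd.DataFrame | None = field(default=None, repr=False)


def mr_analysis(instruments: pd.DataFrame, exposure: str, outcome: str, tier: str = "leads") -> MRResult:
    """IVW + Egger + per-instrument Wald ratios for one exposure-outcome pair."""
    walds = []
    for row in instruments.itertuples():
        if row.beta_exposure != 0:
            walds.append(wald_ratio(row.beta_exposure, row.se_exposure, row.beta_outcome, row.se_outcome))
    wald_df = pd.DataFrame(walds)
    res = MRResult(exposure=exposure, outcome=outcome, tier=tier, beta_ivw=np.nan, se_ivw=np.nan, p_ivw=np.nan)
    if len(instruments) >= 2:
        iv = ivw(instruments)
        res.beta_ivw, res.se_ivw, res.p_ivw = iv["beta"], iv["se"], iv["p"]
    elif len(walds) == 1:
        res.beta_ivw, res.se_ivw, res.p_ivw = walds[0]["beta"], walds[0]["se"], walds[0]["p"]
    if len(instruments) >= 3:
        eg = mr_egger(instruments)
        res.beta_egger, res.se_egger, res.p_egger = eg["beta"], eg["se"], eg["p"]
        res.egger_intercept, res.egger_intercept_p = eg["intercept"], eg["intercept_p"]
    if not wald_df.empty:
        res.median_wald = float(wald_df["beta"].median())
    res.wald_ratios = wald_df
    return res


def apply_mr_filters(results: list[MRResult], fdr: float = 0.05, intercept_p: float = EGGER_INTERCEPT_P) -> list[MRResult]:
    """Egger-intercept, sign-concordance and FDR filters over an MR screen.

    ``pass_filters`` requires: intercept p above 1e-4 (no directional
    pleiotropy), sign agreement of IVW, Egger and median Wald estimates, and
    a Benjamini-Hochberg q below the FDR level.
    """
    ps = np.array([r.p_ivw for r in results], dtype=float)
    ok = np.isfinite(ps)
    qs = np.full(len(ps), np.nan)
    if ok.any():
        qs[ok] = multipletests(ps[ok], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.fdr_q = float(q) if np.isfinite(q) else np.nan
        no_pleio = (not np.isfinite(r.egger_intercept_p)) or r.egger_intercept_p > intercept_p
        signs = [np.sign(v) for v in (r.beta_ivw, r.beta_egger, r.median_wald) if np.isfinite(v) and v != 0]
        concordant = len(set(signs)) <= 1
        r.pass_filters = bool(no_pleio and concordant and np.isfinite(r.fdr_q) and r.fdr_q < fdr)
    return results


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# instrument tiers and convergence
# ---------------------------------------------------------------------------


def instrument_tiers(
    leads: pd.DataFrame,
    sentinels: pd.DataFrame,
    mode_calls: dict[int, str],
    efo_calls: dict[int, str],
) -> dict[str, pd.DataFrame]:
    """Four nested instrument sets per trait, by pleiotropy stringency.

    ``leads`` needs columns variant_id, trait_id, group_id (plus whatever
    effect columns downstream MR uses); ``sentinels`` the same shape. Tier 3
    keeps instruments from groups classed specific or pathway (molecular
    filter); tier 4 additionally requires the group's phenotypic (EFO) class
    to be specific. Tiers satisfy tier4 <= tier3 <= tier2 (leads).
    """
    tiers = {"sentinels": sentinels.copy(), "leads": leads.copy()}
    mol_ok = leads["group_id"].map(lambda g: mode_calls.get(g) in {"specific", "pathway"})
    tiers["molecular_filtered"] = leads[mol_ok].copy()
    efo_ok = leads["group_id"].map(lambda g: efo_calls.get(g) == "specific")
    tiers["molecular_phenotypic_filtered"] = leads[mol_ok & efo_ok].copy()
    for name in TIER_NAMES:
        if tiers[name].empty:
            logger.info("instrument tier %s is empty; MR will be skipped there", name)
    return tiers


def ldl_independence(
    locus_ldl_stats: pd.DataFrame,
    locus_effects: np.ndarray,
    p_threshold: float = LDL_LOCUS_P,
    percentile: float = LDL_EFFECT_PERCENTILE,
    rank_rule: str = "and",
) -> bool | None:
    """Is a locus's disease link independent of LDL cholesterol?

    ``locus_ldl_stats`` carries per-variant LDL-cholesterol beta and p at the
    locus; ``locus_effects`` is the |effect| distribution across all measures
    at the locus. Independence (default reading, ``rank_rule='and'``)
    requires that no variant reaches ``p_threshold`` on LDL cholesterol AND
    that no variant's |LDL effect| reaches the 80th percentile of the locus's
    effect distribution. ``rank_rule='or'`` implements the laxer reading
    where either condition alone suffices.
    """
    if locus_ldl_stats is None or locus_ldl_stats.empty:
        return None
    sig = bool((locus_ldl_stats["p"] < p_threshold).any())
    cut = np.percentile(np.abs(locus_effects), percentile)
    high_rank = bool((locus_ldl_stats["beta"].abs() >= cut).any())
    if rank_rule == "and":
        return not (sig or high_rank)
    if rank_rule == "or":
        return (not sig) or (not high_rank)
    raise ValueError("rank_rule must be 'and' or 'or'")


def level_locus_convergence(
    mr_results: list[MRResult],
    coloc_table: pd.DataFrame,
    mode_calls: dict[int, str],
    ldl_stats: dict[int, pd.DataFrame] | None = None,
    locus_effects: dict[int, np.ndarray] | None = None,
    pp4_threshold: float = PP4_THRESHOLD,
    reportable_tiers: tuple[str, ...] = ("leads", "molecular_filtered", "molecular_phenotypic_filtered"),
) -> pd.DataFrame:
    """Converging level (MR) and locus (coloc) evidence per trait-disease pair.

    ``coloc_table`` needs columns group_id, trait_id, outcome, pp4. Locus
    effects from groups classed disproportional or nonspecific are excluded
    from reporting. A pair converges when it has at least one passing level
    effect (in the most stringent tier where it passes) and one passing
    locus effect; the LDL-independence flag is None when LDL statistics are
    unavailable for every contributing locus.
    """
    level = {}
    tier_rank = {t: i for i, t in enumerate(TIER_NAMES)}
    for r in mr_results:
        if not r.pass_filters or r.tier not in reportable_tiers:
            continue
        key = (r.exposure, r.outcome)
        if key not in level or tier_rank[r.tier] > tier_rank[level[key].tier]:
            level[key] = r  # prioritize the more stringent tier

    locus_ok = coloc_table[
        (coloc_table["pp4"] >= pp4_threshold)
        & ~coloc_table["group_id"].map(lambda g: mode_calls.get(g) in {"disproportional", "nonspecific"})
    ]
    rows = []
    for (trait, outcome), r in sorted(level.items()):
        loci = locus_ok[(locus_ok["trait_id"] == trait) & (locus_ok["outcome"] == outcome)]
        if loci.empty:
            continue
        flags = []
        for g in loci["group_id"].unique():
            if ldl_stats is None or locus_effects is None or g not in ldl_stats:
                flags.append(None)
            else:
                flags.append(ldl_independence(ldl_stats[g], locus_effects[g]))
        known = [f for f in flags if f is not None]
        ldl_indep = None if not known else all(known)
        rows.append(
            {
                "trait_id": trait,
                "outcome": outcome,
                "tier": r.tier,
                "beta_ivw": r.beta_ivw,
                "fdr_q": r.fdr_q,
                "n_loci": len(loci),
                "max_pp4": float(loci["pp4"].max()),
                "ldl_independent": ldl_indep,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "trait_id",
            "outcome",
            "tier",
            "beta_ivw",
            "fdr_q",
            "n_loci",
            "max_pp4",
            "ldl_independent",
        ],
    )
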
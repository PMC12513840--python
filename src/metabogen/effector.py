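"""Effector-gene prioritization.

Candidate genes around each fine-mapped variant receive a feature vector
(distance, closeness rank, coding consequence on the variant or an LD proxy,
tissue eQTL flags, metabolic-database / OMIM / drug-target membership).
Three random-forest classifiers, each trained on a pathway-derived
"putative true positive" (PTP) set (cholesterol, lipid, amino acid), emit
positive-class probabilities whose sum is the 0-3 effector-gene score; a
variant's assigned gene set is the top block above the largest gap between
consecutively ranked scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import balanced_accuracy_score, roc_auc_score
from sklearn.model_selection import GroupKFold, GroupShuffleSplit

logger = logging.getLogger(__name__)

MAX_CANDIDATES = 10
WINDOW_BP = 1_000_000  # half of the 2-Mb candidate window
PROXY_R2 = 0.6
TIER_MODERATE = 1.5
TIER_HIGH = 2.0

PTP_PRIORITY = ("cholesterol", "lipid", "amino_acid")


def collect_candidates(
    variant_id: str,
    chrom: int,
    pos: int,
    genes: pd.DataFrame,
    max_candidates: int = MAX_CANDIDATES,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Up to ten closest genes within a 2-Mb window around the variant.

    Distance is 0 for a variant inside the gene body, otherwise the distance
    to the nearer gene edge. Ties break by gene id.
    """
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        logger.info("no gene on chrom %s for %s", chrom, variant_id)
        return pd.DataFrame(columns=["variant_id", "gene_id", "distance_bp", "rank"])
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    inside = (pos >= start) & (pos <= end)
    dist = np.where(inside, 0, np.minimum(np.abs(pos - start), np.abs(pos - end)))
    sub = sub.assign(distance_bp=dist)
    sub = sub[sub["distance_bp"] <= window_bp].sort_values(["distance_bp", "gene_id"])
    sub = sub.head(max_candidates)
    if sub.empty:
        logger.info("no gene within %d bp of %s", window_bp, variant_id)
        return pd.DataFrame(columns=["variant_id", "gene_id", "distance_bp", "rank"])
    return pd.DataFrame(
        {
            "variant_id": variant_id,
            "gene_id": sub["gene_id"].to_numpy(),
            "distance_bp": sub["distance_bp"].to_numpy(),
            "rank": np.arange(1, len(sub) + 1),
        }
    )


def build_features(
    candidates: pd.DataFrame,
    coding: pd.DataFrame | None = None,
    eqtl: pd.DataFrame | None = None,
    metabolic_genes: set[str] | None = None,
    omim_genes: set[str] | None = None,
    drug_target_genes: set[str] | None = None,
    proxies: pd.DataFrame | None = None,
    proxy_r2: float = PROXY_R2,
) -> pd.DataFrame:
    """One feature row per (variant, gene) candidate pair.

    Variant-level evidence (coding consequence, eQTL) counts if carried by
    the variant itself or any LD proxy with r^2 above ``proxy_r2``; gene-level
    memberships (metabolic database, OMIM, phase III/IV drug target) are
    binary flags. A missing annotation table zeroes its features with a
    warning.

    ``coding`` columns: variant_id, gene_id. ``eqtl`` columns: variant_id,
    gene_id, tissue. ``proxies`` columns: variant_id, proxy_id, r2.
    """
    out = candidates.copy()

    expanded: dict[str, set[str]] = {}
    for v in out["variant_id"].unique():
        vs = {str(v)}
        if proxies is not None:
            hit = proxies[(proxies["variant_id"].astype(str) == str(v)) & (proxies["r2"] > proxy_r2)]
            vs.update(hit["proxy_id"].astype(str))
        expanded[str(v)] = vs

    def variant_gene_flag(table: pd.DataFrame, row) -> bool:
        vset = expanded[str(row.variant_id)]
        sub = table[table["gene_id"] == row.gene_id]
        return bool(sub["variant_id"].astype(str).isin(vset).any())

    if coding is None:
        warnings.warn("coding-consequence table missing; coding_proxy features set to 0", stacklevel=2)
        out["coding_proxy"] = 0
    else:
        out["coding_proxy"] = [int(variant_gene_flag(coding, r)) for r in out.itertuples()]

    if eqtl is None:
        warnings.warn("eQTL table missing; eqtl features set to 0", stacklevel=2)
        out["eqtl_any"] = 0
    else:
        tissues = sorted(eqtl["tissue"].unique())
        for tis in tissues:
            sub = eqtl[eqtl["tissue"] == tis]
            out[f"eqtl_{tis}"] = [int(variant_gene_flag(sub, r)) for r in out.itertuples()]
        out["eqtl_any"] = out[[f"eqtl_{t}" for t in tissues]].max(axis=1) if tissues else 0

    for name, geneset in [
        ("metabolic_db", metabolic_genes),
        ("omim", omim_genes),
        ("drug_target", drug_target_genes),
    ]:
        if geneset is None:
            out[name] = 0
        else:
            out[name] = out["gene_id"].isin(geneset).astype(int)
    return out


# ---------------------------------------------------------------------------
# PTP construction and training
# ---------------------------------------------------------------------------


@dataclass
class PTPSet:
    name: str
    table: pd.DataFrame  # variant_id, gene_id, label, split ('train'|'test')

    def __post_init__(self) -> None:
        tr = set(self.table.loc[self.table["split"] == "train", "variant_id"])
        te = set(self.table.loc[self.table["split"] == "test", "variant_id"])
        if tr & te:
            raise ValueError("train/test splits share variants")


def construct_ptp(
    finemapped: pd.DataFrame,
    trait_class: dict[str, str],
    gene_sets: dict[str, set[str]],
    candidates: pd.DataFrame,
    seed: int = 0,
    test_fraction: float = 0.3,
) -> dict[str, PTPSet]:
    """Build the three putative-true-positive training sets.

    ``finemapped`` needs columns variant_id, trait_id. A variant belongs to a
    metabolite class when it is fine-mapped for a trait of that class; a
    candidate gene of such a variant is a positive when it sits in the class
    pathway set, a negative otherwise. Variants eligible for several classes
    go to exactly one by the fixed priority cholesterol > lipid > amino_acid.
    The 7:3 train:test split is grouped by variant, so no variant appears on
    both sides.
    """
    for name in PTP_PRIORITY:
        if name in gene_sets and not gene_sets[name]:
            raise ValueError(f"empty pathway gene set for {name!r}")
    variant_classes: dict[str, str] = {}
    for row in finemapped.itertuples():
        cls = trait_class.get(row.trait_id)
        if cls is None:
            continue
        v = str(row.variant_id)
        cur = variant_classes.get(v)
        if cur is None or PTP_PRIORITY.index(cls) < PTP_PRIORITY.index(cur):
            variant_classes[v] = cls

    out: dict[str, PTPSet] = {}
    for name in PTP_PRIORITY:
        if name not in gene_sets:
            continue
        genes = gene_sets[name]
        vids = sorted(v for v, c in variant_classes.items() if c == name)
        sub = candidates[candidates["variant_id"].astype(str).isin(vids)].copy()
        if sub.empty:
            out[name] = PTPSet(name, sub.assign(label=[], split=[]))
            continue
        sub["label"] = sub["gene_id"].isin(genes).astype(int)
        if sub["variant_id"].nunique() < 2:  # too few variants to hold any out
            sub["split"] = "train"
        else:
            splitter = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
            tr_idx, te_idx = next(splitter.split(sub, groups=sub["variant_id"]))
            split = np.empty(len(sub), dtype=object)
            split[tr_idx] = "train"
            split[te_idx] = "test"
            sub["split"] = split
        out[name] = PTPSet(name, sub.reset_index(drop=True))
    return out


@dataclass
class FittedScorer:
    name: str
    model: RandomForestClassifier
    feature_cols: list[str]
    metrics: dict = field(default_factory=dict)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(features[self.feature_cols].to_numpy(dtype=float))[:, 1]


def _subsample_majority(X, y, groups, rng):
    pos = np.where(y == 1)[0]
    neg = np.where(y == 0)[0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("a class is absent from training data")
    if len(neg) > len(pos):
        neg = rng.choice(neg, size=len(pos), replace=False)
    elif len(pos) > len(neg):
        pos = rng.choice(pos, size=len(neg), replace=False)
    idx = np.sort(np.concatenate([pos, neg]))
    return X[idx], y[idx], groups[idx]


def train_classifier(
    ptp: PTPSet,
    features: pd.DataFrame,
    feature_cols: list[str],
    seed: int = 0,
    n_splits: int = 5,
    grid: tuple[dict, ...] = (
        {"n_estimators": 200, "max_depth": None, "min_samples_leaf": 1},
        {"n_estimators": 200, "max_depth": 4, "min_samples_leaf": 2},
        {"n_estimators": 400, "max_depth": 8, "min_samples_leaf": 1},
    ),
) -> FittedScorer:
    """Random forest tuned by variant-grouped 5-fold CV with subsampling.

    Within each fold the majority class is subsampled to balance the data;
    mean balanced accuracy over folds selects the forest; held-out (30%)
    ROC-AUC and balanced accuracy are reported. ``feature_cols`` must exclude
    the columns that defined the PTP labels.
    """
    tab = ptp.table.merge(features, on=["variant_id", "gene_id"], how="left", suffixes=("", "_f"))
    train = tab[tab["split"] == "train"]
    test = tab[tab["split"] == "test"]
    Xtr = train[feature_cols].to_numpy(dtype=float)
    ytr = train["label"].to_numpy(dtype=int)
    gtr = train["variant_id"].to_numpy()
    if len(np.unique(ytr)) < 2:
        raise ValueError("a class is absent from the training split")

    rng = np.random.default_rng(seed)
    cv = GroupKFold(n_splits=min(n_splits, len(np.unique(gtr))))
    best_params, best_ba = None, -np.inf
    for params in grid:
        bas = []
        for fold_tr, fold_te in cv.split(Xtr, ytr, groups=gtr):
            Xs, ys, _ = _subsample_majority(Xtr[fold_tr], ytr[fold_tr], gtr[fold_tr], rng)
            if len(np.unique(ys)) < 2 or len(np.unique(ytr[fold_te])) < 2:
                continue
            clf = RandomForestClassifier(random_state=seed, **params)
            clf.fit(Xs, ys)
            bas.append(balanced_accuracy_score(ytr[fold_te], clf.predict(Xtr[fold_te])))
        mean_ba = float(np.mean(bas)) if bas else -np.inf
        if mean_ba > best_ba:
            best_ba, best_params = mean_ba, params

    Xs, ys, _ = _subsample_majority(Xtr, ytr, gtr, rng)
    model = RandomForestClassifier(random_state=seed, **(best_params or grid[0]))
    model.fit(Xs, ys)

    metrics = {"cv_balanced_accuracy": best_ba, "params": best_params}
    if len(test) and len(np.unique(test["label"])) == 2:
        Xte = test[feature_cols].to_numpy(dtype=float)
        yte = test["label"].to_numpy(dtype=int)
        metrics["test_balanced_accuracy"] = float(balanced_accuracy_score(yte, model.predict(Xte)))
        metrics["test_roc_auc"] = float(roc_auc_score(yte, model.predict_proba(Xte)[:, 1]))
    return FittedScorer(name=ptp.name, model=model, feature_cols=list(feature_cols), metrics=metrics)


def score_genes(scorers: list[FittedScorer], features: pd.DataFrame) -> pd.DataFrame:
    """Sum the three classifiers' probabilities into 0-3 scores and assign.

    Per variant, candidates are ranked by score; the assigned set is the top
    block above the largest gap between consecutive scores (ties of the
    maximal gap resolve to the earliest gap). If every consecutive gap is
    equal - including the all-equal-scores case - no assignment is made and
    the variant is flagged. Tiers: moderate at score >= 1.5, high at >= 2.
    """
    out = features[["variant_id", "gene_id"]].copy()
    probs = np.column_stack([s.predict_proba(features) for s in scorers])
    out["score"] = probs.sum(axis=1)
    out["median_score"] = np.median(probs, axis=1)  # diagnostic
    out["tier"] = np.select(
        [out["score"] >= TIER_HIGH, out["score"] >= TIER_MODERATE], ["high", "moderate"], default="none"
    )
    out["assigned"] = False
    out["low_confidence"] = False
    for v, grp in out.groupby("variant_id"):
        grp = grp.sort_values(["score", "gene_id"], ascending=[False, True])
        if len(grp) == 1:
            out.loc[grp.index, "assigned"] = True
            continue
        gaps = -np.diff(grp["score"].to_numpy())
        if np.allclose(gaps, gaps[0]):
            out.loc[grp.index, "low_confidence"] = True
            logger.info("variant %s: all score gaps equal; no assignment", v)
            continue
        cut = int(np.argmax(gaps)) + 1
        out.loc[grp.index[:cut], "assigned"] = True
    return out


def fisher_enrichment(
    query: set[str],
    annotation: set[str],
    background: int,
) -> tuple[float, float]:
    """Two-sided Fisher's exact enrichment of a gene set in an annotation.

    Returns (odds ratio, p). The odds ratio uses a Haldane 0.5 correction
    when any cell of the 2x2 table is zero.
    """
    if not query:
        raise ValueError("empty query gene set")
    if len(query) > background or len(annotation) > background:
        raise ValueError("query/annotation larger than background")
    a = len(query & annotation)
    b = len(query) - a
    c = len(annotation) - a
    d = background - a - b - c
    if d < 0:
        raise ValueError("background smaller than union of sets")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if 0 in (a, b, c, d):
        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    else:
        orr = a * d / (b * c)
    return float(orr), float(p)


def assignment_overlap(assign_a: pd.DataFrame, assign_b: pd.DataFrame) -> pd.DataFrame:
    """Set-intersection of two (variant_id, gene_id) assignment tables."""
    a = assign_a.loc[assign_a.get("assigned", True) == True, ["variant_id", "gene_id"]]  # noqa: E712
    b = assign_b.loc[assign_b.get("assigned", True) == True, ["variant_id", "gene_id"]]  # noqa: E712
    return a.merge(b, on=["variant_id", "gene_id"])
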
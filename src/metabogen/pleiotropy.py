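"""Pleiotropy-mode classification and phenotypic (EFO) pleiotropy.

An mQTL group is classified into one of five molecular-pleiotropy modes
from two statistics over its associated traits: ``q25``, the 25th percentile
of pairwise absolute trait correlations, and ``statcor``, the Pearson
correlation between association strength (-log10 p) and the squared trait
correlation with the lead (most significant) trait. Phenotypic pleiotropy is
quantified against a GWAS-Catalog-dialect table by counting distinct EFO
parent categories hit by the group's variants and LD proxies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

RHO_THRESHOLD = 0.6
EFO_SPECIFIC_MAX_PARENTS = 5  # specific iff fewer than this many parent terms
CATALOG_P = 5e-8


@dataclass
class PleiotropyCall:
    group_id: int
    n_traits: int
    q25: float  # nan when undefined (single-trait group)
    statcor: float  # nan when undefined (<3 traits)
    mode: str


@dataclass
class EfoPleiotropy:
    group_id: int
    n_parent_terms: int
    phenotypic_class: str  # "specific" | "unspecific"
    parent_terms: tuple[str, ...] = ()


def classify_mqtl(
    group_id: int,
    assoc: pd.DataFrame,
    trait_corr: pd.DataFrame,
    rho: float = RHO_THRESHOLD,
) -> PleiotropyCall:
    """Assign a pleiotropy mode to one mQTL group.

    ``assoc`` needs columns trait_id and p (the per-trait lead p within the
    group); ``trait_corr`` is the trait correlation matrix of the
    medication-corrected panel. Absolute correlations are used throughout
    (anticorrelated lipoprotein measures are biologically one cluster).

    Rule table (n = number of associated traits):

    - n <= 3 and q25 >= rho  -> specific
    - n > 3 and q25 >= rho and statcor >= rho -> pathway
    - q25 < rho and statcor >= rho -> proportional
    - q25 >= rho and statcor < rho -> disproportional
    - otherwise -> nonspecific

    Single-trait groups are specific with both metrics undefined; with fewer
    than 3 traits statcor is undefined and classification falls back to the
    q25 rule alone.
    """
    traits = assoc["trait_id"].tolist()
    n = len(traits)
    if n == 0:
        raise ValueError("group has no associated traits")
    if n == 1:
        return PleiotropyCall(group_id, 1, np.nan, np.nan, "specific")

    sub = trait_corr.loc[traits, traits].to_numpy()
    pair = np.abs(sub[np.triu_indices(n, k=1)])
    q25 = float(np.percentile(pair, 25))

    # association strength; prefer the underflow-safe log-scale column
    if "mlog10p" in assoc:
        y = assoc["mlog10p"].to_numpy(dtype=float)
    else:
        y = -np.log10(assoc["p"].to_numpy(dtype=float))
    lead_i = int(np.argmax(y))
    lead = traits[lead_i]
    x = trait_corr.loc[traits, lead].to_numpy() ** 2

    if n < 3 or np.std(x) == 0 or np.std(y) == 0:
        statcor = np.nan
        if n < 3:
            logger.info("group %s: <3 traits, statcor undefined", group_id)
        mode = "specific" if q25 >= rho else "nonspecific"
        return PleiotropyCall(group_id, n, q25, statcor, mode)

    statcor = float(np.corrcoef(x, y)[0, 1])
    if n <= 3 and q25 >= rho:
        mode = "specific"
    elif n > 3 and q25 >= rho and statcor >= rho:
        mode = "pathway"
    elif q25 < rho and statcor >= rho:
        mode = "proportional"
    elif q25 >= rho and statcor < rho:
        mode = "disproportional"
    else:
        mode = "nonspecific"
    return PleiotropyCall(group_id, n, q25, statcor, mode)


# ---------------------------------------------------------------------------
# EFO parent-term pleiotropy
# ---------------------------------------------------------------------------


def _parent_category(term: str, graph: nx.DiGraph, roots: set[str]) -> str | None:
    """Walk child->parent edges up to the child-of-root level (cycle-guarded)."""
    seen = set()
    node = term
    while node not in seen:
        seen.add(node)
        parents = list(graph.successors(node))
        if not parents:
            return None  # reached a root without passing a category
        parent = sorted(parents)[0]  # deterministic on DAG diamonds
        if parent in roots:
            return node
        node = parent
    logger.warning("cycle detected in ontology at %s", term)
    return None


def _descends_from(term: str, ancestors: set[str], graph: nx.DiGraph) -> bool:
    seen = set()
    stack = [term]
    while stack:
        node = stack.pop()
        if node in ancestors:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(graph.successors(node))
    return False


def efo_pleiotropy(
    group_id: int,
    variants: list[str],
    proxies: dict[str, list[str]] | None,
    catalog: pd.DataFrame,
    ontology: pd.DataFrame,
    excluded_roots: list[str] = (),
    p_threshold: float = CATALOG_P,
    max_parents: int = EFO_SPECIFIC_MAX_PARENTS,
) -> EfoPleiotropy:
    """Count distinct EFO parent categories hit by a group in the catalog.

    ``catalog`` uses GWAS-Catalog-dialect columns (SNPS, MAPPED_TRAIT_URI,
    P-VALUE, CHR_ID, CHR_POS); ``ontology`` is a two-column child/parent
    table. Rows without a mapped trait or location, or above the genome-wide
    threshold, are pruned; rows whose term descends from an excluded root
    (e.g. lipid-measurement branches that duplicate the metabolite panel)
    are dropped; remaining terms are traced to the children of the ontology
    roots. Fewer than ``max_parents`` distinct parents classifies the group
    as phenotypically specific.
    """
    graph = nx.DiGraph()
    graph.add_edges_from(zip(ontology["child"], ontology["parent"]))
    roots = {n for n in graph.nodes if graph.out_degree(n) == 0}
    excluded = set(excluded_roots)

    query = set(map(str, variants))
    if proxies:
        for v in variants:
            query.update(map(str, proxies.get(v, [])))

    rows = catalog[
        catalog["SNPS"].astype(str).isin(query)
        & catalog["MAPPED_TRAIT_URI"].notna()
        & (catalog["MAPPED_TRAIT_URI"] != "")
        & (pd.to_numeric(catalog["P-VALUE"], errors="coerce") < p_threshold)
        & catalog["CHR_ID"].notna()
        & catalog["CHR_POS"].notna()
    ]
    parents: set[str] = set()
    for term in rows["MAPPED_TRAIT_URI"].astype(str):
        if term not in graph:
            logger.info("EFO term %s absent from ontology; counting under 'unmapped'", term)
            parents.add("unmapped")
            continue
        if excluded and _descends_from(term, excluded, graph):
            continue
        cat = _parent_category(term, graph, roots)
        parents.add(cat if cat is not None else term)
    n = len(parents)
    return EfoPleiotropy(
        group_id=group_id,
        n_parent_terms=n,
        phenotypic_class="specific" if n < max_parents else "unspecific",
        parent_terms=tuple(sorted(parents)),
    )


def category_enrichment(
    calls: pd.DataFrame,
    category_hits: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-category enrichment among pleiotropic vs specific mQTL groups.

    ``calls`` needs columns group_id and mode; ``category_hits`` is a boolean
    group x category frame. Each category is tested by logistic regression of
    its hit indicator on a pleiotropic-vs-specific indicator; odds ratios,
    Wald 95% CIs and Bonferroni-adjusted p values are reported. Categories
    with zero variance or complete separation are flagged without estimates.
    """
    pleio = (calls.set_index("group_id")["mode"] != "specific").reindex(category_hits.index)
    x = sm.add_constant(pleio.astype(float).to_numpy())
    rows = []
    for cat in category_hits.columns:
        y = category_hits[cat].astype(float).to_numpy()
        row = {"category": cat, "or": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "flag": ""}
        if y.std() == 0 or pleio.astype(float).std() == 0:
            row["flag"] = "zero_variance"
            logger.info("category %s skipped: zero variance", cat)
            rows.append(row)
            continue
        tab = pd.crosstab(pleio, category_hits[cat])
        if tab.shape != (2, 2) or (tab.to_numpy() == 0).any():
            row["flag"] = "separation"
            rows.append(row)
            continue
        fit = sm.Logit(y, x).fit(disp=0)
        b, se = fit.params[1], fit.bse[1]
        row.update(
            {
                "or": float(np.exp(b)),
                "ci_low": float(np.exp(b - 1.96 * se)),
                "ci_high": float(np.exp(b + 1.96 * se)),
                "p": float(fit.pvalues[1]),
            }
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    m = out["p"].notna().sum()
    out["p_bonferroni"] = np.minimum(out["p"] * max(m, 1), 1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    return out
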
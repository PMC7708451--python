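"""Motif co-occurrence rules by frequent-itemset mining.

A 'regulatory rule' is a set of motifs that co-occur across genes more
often than expected under independence. Candidate itemsets come from an
FP-growth miner (verified set-identical to brute-force enumeration);
each is scored with support, confidence, lift and a chi-squared test
(2x2 presence table for pairs, observed-vs-independence count with 1 df
for larger sets), then filtered by Benjamini-Hochberg FDR and a minimum
carrier-gene count of 3.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class Rule:
    motif_ids: frozenset[str]
    genes: frozenset[str]
    support: float  # fraction of genes carrying the full set
    confidence: float
    lift: float
    chi2: float
    p_value: float
    q_value: float | None = None
    mean_tpm: float | None = None
    sd_tpm: float | None = None
    snr: float | None = None
    snr_infinite: bool = False
    cross_region: bool | None = None
    flags: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.motif_ids)


# ---------------------------------------------------------------------------
# FP-growth


class _FPNode:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item, parent):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict = {}


def _build_tree(transactions: list[list[str]], counts: list[int],
                min_count: int) -> tuple[_FPNode, dict]:
    freq: dict[str, int] = defaultdict(int)
    for t, c in zip(transactions, counts):
        for item in t:
            freq[item] += c
    items = {i for i, c in freq.items() if c >= min_count}
    # order by descending frequency, lexicographic tie-break
    order = {i: r for r, i in enumerate(
        sorted(items, key=lambda i: (-freq[i], i)))}
    root = _FPNode(None, None)
    header: dict[str, list[_FPNode]] = defaultdict(list)
    for t, c in zip(transactions, counts):
        path = sorted((i for i in set(t) if i in items), key=order.get)
        node = root
        for item in path:
            child = node.children.get(item)
            if child is None:
                child = _FPNode(item, node)
                node.children[item] = child
                header[item].append(child)
            child.count += c
            node = child
    return root, {"header": header, "freq": freq, "order": order}


def _mine(tree_info: dict, suffix: tuple[str, ...], min_count: int,
          max_size: int, out: dict[frozenset, int]) -> None:
    header = tree_info["header"]
    for item in sorted(header, key=lambda i: tree_info["order"][i], reverse=True):
        nodes = header[item]
        support = sum(n.count for n in nodes)
        if support < min_count:
            continue
        itemset = frozenset((*suffix, item))
        if len(itemset) >= 1:
            out[itemset] = support
        if len(itemset) >= max_size:
            continue
        # conditional pattern base
        cond_transactions, cond_counts = [], []
        for n in nodes:
            path = []
            p = n.parent
            while p is not None and p.item is not None:
                path.append(p.item)
                p = p.parent
            if path:
                cond_transactions.append(path)
                cond_counts.append(n.count)
        if cond_transactions:
            _, info = _build_tree(cond_transactions, cond_counts, min_count)
            _mine(info, tuple(itemset), min_count, max_size, out)


def mine_itemsets(
    occurrence: pd.DataFrame,
    min_genes: int = 3,
    max_size: int = 6,
) -> dict[frozenset[str], int]:
    """All itemsets of size 2..``max_size`` with absolute support >=
    ``min_genes``, via FP-growth. Keys are motif-id frozensets, values
    absolute supports (carrier-gene counts)."""
    if occurrence.size == 0:
        return {}
    transactions = [
        list(occurrence.columns[row.to_numpy(dtype=bool)])
        for _, row in occurrence.iterrows()
    ]
    _, info = _build_tree(transactions, [1] * len(transactions), min_genes)
    found: dict[frozenset, int] = {}
    _mine(info, (), min_genes, max_size, found)
    return {s: c for s, c in found.items() if 2 <= len(s) <= max_size}


def brute_force_itemsets(
    occurrence: pd.DataFrame,
    min_genes: int = 3,
    max_size: int = 6,
) -> dict[frozenset[str], int]:
    """Exhaustive enumeration oracle for :func:`mine_itemsets`."""
    cols = list(occurrence.columns)
    M = occurrence.to_numpy(dtype=bool)
    out: dict[frozenset, int] = {}
    for size in range(2, max_size + 1):
        for combo in itertools.combinations(range(len(cols)), size):
            support = int(M[:, combo].all(axis=1).sum())
            if support >= min_genes:
                out[frozenset(cols[i] for i in combo)] = support
    return out


# ---------------------------------------------------------------------------
# rule statistics


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Closed-form chi-squared (no continuity correction) for a 2x2
    table: N (ad - bc)^2 / (r1 r2 c1 c2), 1 df."""
    a, b = float(table[0, 0]), float(table[0, 1])
    c, d = float(table[1, 0]), float(table[1, 1])
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero marginal in contingency table")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return chi2, float(sps.chi2.sf(chi2, 1))


def rule_stats(
    itemset: frozenset[str],
    occurrence: pd.DataFrame,
    median_tpm: pd.Series | None = None,
    regions: dict[str, set[str]] | None = None,
    confidence_split: str = "last",
) -> Rule:
    """Support/confidence/lift plus chi-squared significance.

    Pairs use the 2x2 presence table of the two motifs; larger sets
    compare the observed full-set count with its expectation under
    per-motif independence (1 df). Confidence divides full-set support
    by the support of the set minus its lexicographically last motif
    (``confidence_split='all'`` returns the minimum over all splits,
    i.e. the most conservative antecedent).
    """
    items = sorted(itemset)
    M = occurrence[items].to_numpy(dtype=bool)
    n = len(occurrence)
    full = M.all(axis=1)
    k = int(full.sum())
    if k < 1:
        raise ValueError("itemset support must be >= 1")
    support = k / n
    marg = M.mean(axis=0)

    flags = {}
    if confidence_split == "all":
        conf = min(
            k / int(np.delete(M, i, axis=1).all(axis=1).sum())
            for i in range(len(items))
        )
    else:
        antecedent = M[:, :-1].all(axis=1) if len(items) > 1 else np.ones(n, bool)
        conf = k / int(antecedent.sum())
    lift = support / float(np.prod(marg)) if marg.all() else np.inf

    try:
        if len(items) == 2:
            a = k
            b = int((M[:, 0] & ~M[:, 1]).sum())
            c = int((~M[:, 0] & M[:, 1]).sum())
            d = n - a - b - c
            chi2, p = chi2_2x2(np.array([[a, b], [c, d]]))
        else:
            # observed full-set count against its independence
            # expectation; the exact binomial tail replaces the 1-df
            # chi-squared approximation, which is badly anticonservative
            # at the small expected counts typical of larger itemsets
            p0 = float(np.prod(marg))
            if p0 <= 0 or p0 >= 1:
                raise ValueError("degenerate expectation")
            expected = n * p0
            chi2 = (k - expected) ** 2 / expected + (k - expected) ** 2 / (n - expected)
            p = float(sps.binomtest(k, n, p0).pvalue)
    except ValueError as exc:
        chi2, p = np.nan, 1.0
        flags["chi2_undefined"] = str(exc)

    genes = frozenset(occurrence.index[full])
    rule = Rule(
        motif_ids=frozenset(items), genes=genes, support=support,
        confidence=float(conf), lift=float(lift), chi2=float(chi2),
        p_value=float(p), flags=flags,
    )
    if median_tpm is not None:
        vals = median_tpm.loc[sorted(genes)].to_numpy(dtype=float)
        rule.mean_tpm = float(vals.mean())
        rule.sd_tpm = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        if rule.sd_tpm == 0:
            rule.snr, rule.snr_infinite = np.inf, True
        else:
            rule.snr = rule.mean_tpm / rule.sd_tpm
    if regions is not None:
        spanned = set().union(*(regions.get(m, set()) for m in items))
        rule.cross_region = len(spanned) > 1
    return rule


def significant_rules(
    rules: list[Rule],
    alpha: float = 0.05,
    min_genes: int = 3,
    n_genes_total: int | None = None,
) -> tuple[list[Rule], dict]:
    """Benjamini-Hochberg over all tested itemsets; keep q < alpha with
    >= ``min_genes`` carriers. Also reports genome coverage (fraction of
    genes carrying at least one significant rule)."""
    from statsmodels.stats.multitest import multipletests

    if not rules:
        return [], {"n_tested": 0, "coverage": 0.0}
    pvals = np.array([r.p_value for r in rules])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for r, q in zip(rules, qvals):
        r.q_value = float(q)
    kept = [r for r in rules if r.q_value < alpha and len(r.genes) >= min_genes]
    covered = set().union(*(r.genes for r in kept)) if kept else set()
    total = n_genes_total or len(set().union(*(r.genes for r in rules)))
    return kept, {
        "n_tested": len(rules),
        "n_significant": len(kept),
        "coverage": len(covered) / total if total else 0.0,
    }


def mine_rules(
    occurrence: pd.DataFrame,
    median_tpm: pd.Series | None = None,
    regions: dict[str, set[str]] | None = None,
    min_genes: int = 3,
    max_size: int = 6,
    alpha: float = 0.05,
) -> tuple[list[Rule], dict]:
    """mine_itemsets -> rule_stats -> significant_rules in one call."""
    itemsets = mine_itemsets(occurrence, min_genes, max_size)
    rules = [
        rule_stats(s, occurrence, median_tpm, regions) for s in itemsets
    ]
    return significant_rules(rules, alpha, min_genes, len(occurrence))


# ---------------------------------------------------------------------------
# specificity of rules versus single motifs


def _item_expression(genes: list[str], median_tpm: pd.Series) -> dict:
    vals = median_tpm.loc[genes].to_numpy(dtype=float)
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return {
        "mean_tpm": mean,
        "sd_tpm": sd,
        "snr": np.inf if sd == 0 else mean / sd,
        "n_genes": len(vals),
    }


def specificity_contrast(
    occurrence: pd.DataFrame,
    rules: list[Rule],
    median_tpm: pd.Series,
) -> pd.DataFrame:
    """Carrier-gene expression statistics per item (single motif or
    rule), with the recovered fraction of the cohort's log10 expression
    range per item class."""
    rows = []
    for motif in occurrence.columns:
        genes = list(occurrence.index[occurrence[motif]])
        if not genes:
            continue
        rows.append({"item": motif, "kind": "motif",
                     **_item_expression(genes, median_tpm)})
    for r in rules:
        rows.append({"item": "+".join(sorted(r.motif_ids)), "kind": "rule",
                     **_item_expression(sorted(r.genes), median_tpm)})
    df = pd.DataFrame(rows)
    full_span = np.log10(median_tpm.max()) - np.log10(median_tpm.min())
    for kind in ("motif", "rule"):
        sub = df[df["kind"] == kind]
        if len(sub) > 1 and full_span > 0:
            span = np.log10(sub["mean_tpm"].max()) - np.log10(sub["mean_tpm"].min())
            df.loc[df["kind"] == kind, "recovered_range"] = span / full_span
    return df


def repurposing_groups(
    rules: list[Rule],
    mode: str = "common_motif",
    fold_threshold: float = 10.0,
) -> pd.DataFrame:
    """Fold ranges of carrier-gene mean TPM across rule groups.

    ``common_motif`` groups rules (of >= 3 motifs) sharing one motif;
    ``single_substitution`` groups rules identical except one motif.
    Groups of size 1 are excluded.
    """
    usable = [r for r in rules if r.mean_tpm is not None]
    groups: dict[str, list[Rule]] = defaultdict(list)
    if mode == "common_motif":
        for r in usable:
            if r.size < 3:
                continue
            for m in r.motif_ids:
                groups[m].append(r)
    elif mode == "single_substitution":
        for r in usable:
            for m in r.motif_ids:
                key = "+".join(sorted(r.motif_ids - {m})) + f"|size{r.size}"
                groups[key].append(r)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for key, rs in groups.items():
        if len(rs) < 2:
            continue
        means = np.array([r.mean_tpm for r in rs], dtype=float)
        means = means[means > 0]
        if means.size < 2:
            continue
        fold = float(means.max() / means.min())
        rows.append({"group": key, "n_rules": len(rs), "fold_range": fold})
    df = pd.DataFrame(rows)
    if not df.empty:
        df.attrs["fraction_exceeding"] = float((df["fold_range"] > fold_threshold).mean())
    return df


def codon_specificity(
    occurrence: pd.DataFrame,
    rules: list[Rule],
    codon_probs: pd.DataFrame,
) -> pd.DataFrame:
    """Median pairwise Euclidean distance among carrier codon vectors,
    per single motif and per rule; singleton carrier sets are excluded."""
    from scipy.spatial.distance import pdist

    rows = []

    def _median_dist(genes: list[str]) -> float | None:
        if len(genes) < 2:
            return None
        return float(np.median(pdist(codon_probs.loc[genes].to_numpy())))

    for motif in occurrence.columns:
        genes = list(occurrence.index[occurrence[motif]])
        d = _median_dist(genes)
        if d is not None:
            rows.append({"item": motif, "kind": "motif", "median_distance": d,
                         "n_genes": len(genes)})
    for r in rules:
        d = _median_dist(sorted(r.genes))
        if d is not None:
            rows.append({"item": "+".join(sorted(r.motif_ids)), "kind": "rule",
                         "median_distance": d, "n_genes": len(r.genes)})
    return pd.DataFrame(rows)
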
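"""Gene-list statistics: expression filtering, hypergeometric overlap,
fold-change concordance, direction classification, attenuation testing,
and Venn-region accounting."""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class GeneListError(ValueError):
    pass


DE_COLUMNS = ("gene_id", "log2fc", "pvalue", "fdr")


@dataclass
class OverlapResult:
    k: int          # overlap
    n: int          # size of list A
    K: int          # size of list B
    N: int          # universe size
    fold: float     # k / (n*K/N)
    p_enrich: float  # P(X >= k)
    p_deplete: float  # P(X <= k)


def filter_expressed(counts: pd.DataFrame, min_reads: int = 5,
                     min_libraries: int = 1) -> set[str]:
    """Genes with count > min_reads (strict) in at least min_libraries columns."""
    if counts.size == 0:
        raise GeneListError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise GeneListError("negative counts")
    keep = (counts > min_reads).sum(axis=1) >= min_libraries
    return set(counts.index[keep])


def overlap_test(list_a: Iterable[str], list_b: Iterable[str],
                 universe: Iterable[str]) -> OverlapResult:
    """Hypergeometric overlap test with fold enrichment k/(nK/N)."""
    universe = set(universe)
    a = set(list_a)
    b = set(list_b)
    if not a <= universe or not b <= universe:
        raise GeneListError("gene lists must be subsets of the universe")
    N, n, K = len(universe), len(a), len(b)
    k = len(a & b)
    expected = n * K / N if N else 0.0
    fold = k / expected if expected > 0 else 0.0
    hg = stats.hypergeom(N, K, n)
    p_enrich = float(hg.sf(k - 1))
    p_deplete = float(hg.cdf(k))
    return OverlapResult(k, n, K, N, fold, p_enrich, p_deplete)


def foldchange_concordance(table_a: pd.DataFrame, table_b: pd.DataFrame,
                           genes: Iterable[str]) -> tuple[float, float, int]:
    """Pearson correlation of log2 fold changes over the given genes."""
    genes = sorted(set(genes))
    if len(genes) < 3:
        raise GeneListError("need >= 3 shared genes")
    a = table_a.set_index("gene_id").loc[genes, "log2fc"].to_numpy(float)
    b = table_b.set_index("gene_id").loc[genes, "log2fc"].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise GeneListError("zero-variance fold-change vector")
    r = stats.pearsonr(a, b)
    return float(r.statistic), float(r.pvalue), len(genes)


def direction_classification(table_a: pd.DataFrame, table_b: pd.DataFrame,
                             genes: Iterable[str]) -> dict[str, object]:
    """Quadrant counts of fold-change signs across two contrasts.

    Returns counts for up/up, up/down, down/up, down/down plus the dominant
    quadrant and its percentage. Genes must be present in both tables.
    """
    genes = sorted(set(genes))
    fa = table_a.set_index("gene_id")["log2fc"]
    fb = table_b.set_index("gene_id")["log2fc"]
    missing = [g for g in genes if g not in fa.index or g not in fb.index]
    if missing:
        raise GeneListError(f"genes missing from a table: {missing[:5]}")
    quad = {"up/up": 0, "up/down": 0, "down/up": 0, "down/down": 0}
    for g in genes:
        da = "up" if fa[g] > 0 else "down"
        db = "up" if fb[g] > 0 else "down"
        quad[f"{da}/{db}"] += 1
    dominant = max(quad, key=quad.get)
    total = sum(quad.values())
    pct = 100.0 * quad[dominant] / total if total else 0.0
    return {"counts": quad, "dominant": dominant, "dominant_pct": pct, "n": total}


def binomial_tail_one_sided(k: int, n: int, p: float = 0.5) -> float:
    """Exact P(X >= k) for X ~ Binomial(n, p); combinatorial sum at p=1/2."""
    if p == 0.5:
        # exact integer arithmetic: sum C(n,j) for j >= k, over 2^n
        num = sum(math.comb(n, j) for j in range(k, n + 1))
        return num / (1 << n)
    return float(stats.binom.sf(k - 1, n, p))


def attenuation_test(fc_control: Mapping[str, float],
                     fc_knockdown: Mapping[str, float],
                     genes: Iterable[str],
                     background: Iterable[str] | None = None) -> dict[str, object]:
    """Test whether knockdown attenuates responses (|fc| shrinks).

    ``n_smaller`` counts genes with |fc_knockdown| < |fc_control|; ties are
    excluded and reported. p_binomial is the exact binomial test against
    0.5 (one-sided tail and two-sided = twice the smaller tail, capped at
    1). With a background gene set, p_background is a Fisher exact test of
    smaller/larger counts in the gene set vs the background set.
    """
    genes = sorted(set(genes))
    smaller = larger = ties = 0
    for g in genes:
        d = abs(fc_knockdown[g]) - abs(fc_control[g])
        if d < 0:
            smaller += 1
        elif d > 0:
            larger += 1
        else:
            ties += 1
    n_total = smaller + larger
    if n_total == 0:
        raise GeneListError("no untied genes to test")
    tail_hi = binomial_tail_one_sided(smaller, n_total)
    tail_lo = 1.0 - binomial_tail_one_sided(smaller + 1, n_total)
    p_one = tail_hi if smaller >= n_total - smaller else tail_lo
    p_two = min(1.0, 2.0 * min(tail_hi, tail_lo))
    out = {
        "n_smaller": smaller, "n_larger": larger, "n_ties": ties,
        "n_total": n_total,
        "p_binomial_one_sided": p_one,
        "p_binomial": p_two,
    }
    if background is not None:
        bg = sorted(set(background) - set(genes))
        bg_smaller = sum(1 for g in bg
                         if abs(fc_knockdown[g]) < abs(fc_control[g]))
        bg_larger = sum(1 for g in bg
                        if abs(fc_knockdown[g]) > abs(fc_control[g]))
        _, p_bg = stats.fisher_exact([[smaller, larger], [bg_smaller, bg_larger]])
        out["p_background"] = float(p_bg)
        out["background_counts"] = (bg_smaller, bg_larger)
    return out


def build_venn(lists: Mapping[str, Iterable[str]],
               universe: Iterable[str]) -> dict[str, object]:
    """Exclusive region counts for 1-3 lists plus pairwise overlap tests.

    Region keys are frozensets of list names; counts partition the union.
    Duplicate ids inside one list are an error.
    """
    universe = set(universe)
    sets: dict[str, set[str]] = {}
    for name, genes in lists.items():
        genes = list(genes)
        if len(genes) != len(set(genes)):
            raise GeneListError(f"duplicate gene ids in list {name!r}")
        s = set(genes)
        if not s <= universe:
            raise GeneListError(f"list {name!r} not a subset of the universe")
        sets[name] = s
    names = sorted(sets)
    regions: dict[frozenset, int] = {}
    union = set().union(*sets.values()) if sets else set()
    for g in union:
        member = frozenset(n for n in names if g in sets[n])
        regions[member] = regions.get(member, 0) + 1
    pairwise = {
        frozenset((x, y)): overlap_test(sets[x], sets[y], universe)
        for x, y in itertools.combinations(names, 2)
    }
    return {"regions": regions, "pairwise": pairwise, "list_sizes":
            {n: len(sets[n]) for n in names}}
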
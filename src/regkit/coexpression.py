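"""Two-tissue co-expression module pipeline.

Stages: quantile normalization; weighted-correlation-network module
detection in tissue A (adjacency |r|^beta, topological overlap,
average-linkage clustering, static cut); consensus tight clustering within
each module by resampled k-means; coherent-cluster extraction that keeps
the subset of each tight cluster that is also co-expressed in tissue B;
and per-module gene-list enrichment tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests


class CoexpressionError(ValueError):
    pass


@dataclass
class Module:
    name: str
    genes: tuple[str, ...]
    stage: str  # wgcna | tight | coherent | fat_specific

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class ModuleSet:
    stage: str
    modules: list[Module] = field(default_factory=list)
    unclustered: tuple[str, ...] = ()

    def __iter__(self):
        return iter(self.modules)

    def __len__(self):
        return len(self.modules)

    def gene_to_module(self) -> dict[str, str]:
        return {g: m.name for m in self.modules for g in m.genes}

    def stats(self, matrices: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
        """Per-module size and mean within-module pairwise r per tissue."""
        rows = []
        for m in self.modules:
            row: dict[str, object] = {"module": m.name, "stage": m.stage,
                                      "size": m.size}
            for tissue, mat in matrices.items():
                row[f"mean_r_{tissue}"] = mean_pairwise_r(mat.loc[list(m.genes)])
            rows.append(row)
        return pd.DataFrame(rows)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean order-statistic distribution.

    Ties within a column receive the average of the target values they
    span. Idempotent.
    """
    if matrix.shape[1] < 2:
        raise CoexpressionError("need >= 2 columns")
    if matrix.isna().any().any():
        raise CoexpressionError("missing values not allowed")
    x = matrix.to_numpy(float)
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, x.shape[0] + 1), target)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def mean_pairwise_r(matrix: pd.DataFrame) -> float:
    """Mean off-diagonal Pearson correlation across gene rows."""
    if matrix.shape[0] < 2:
        return float("nan")
    r = np.corrcoef(matrix.to_numpy(float))
    n = r.shape[0]
    return float((r.sum() - n) / (n * (n - 1)))


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix of an adjacency with zero diagonal."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # Σ_u a_iu a_uj (u runs over all; diag(a)=0 excludes i, j)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def wgcna_modules(matrix: pd.DataFrame, beta: float = 6.0,
                  min_size: int = 30, cut_height: float = 0.95) -> ModuleSet:
    """Weighted-correlation-network modules by static tree cut.

    Adjacency = |Pearson r|^beta (unsigned); similarity = topological
    overlap; 1 - TOM is clustered by average linkage and cut at
    ``cut_height``; clusters below ``min_size`` go to the unclustered pool.
    Constant-expression genes are dropped with a warning.
    """
    x = matrix.to_numpy(float)
    keep = np.ptp(x, axis=1) > 0
    if not keep.all():
        import warnings
        warnings.warn(f"dropping {int((~keep).sum())} constant-expression genes")
        matrix = matrix.loc[keep]
        x = matrix.to_numpy(float)
    genes = list(matrix.index)
    if len(genes) < min_size:
        raise CoexpressionError("fewer genes than min_size")
    if matrix.shape[1] < 4:
        raise CoexpressionError("need >= 4 samples")
    r = np.corrcoef(x)
    adj = np.abs(r) ** beta
    tom = topological_overlap(adj)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = average(squareform(dist, checks=False))
    labels = fcluster(link, t=cut_height, criterion="distance")
    modules: list[Module] = []
    unclustered: list[str] = []
    by_label: dict[int, list[str]] = {}
    for g, lab in zip(genes, labels):
        by_label.setdefault(int(lab), []).append(g)
    clusters = sorted(by_label.values(), key=lambda gs: (-len(gs), gs[0]))
    idx = 0
    for gs in clusters:
        if len(gs) >= min_size:
            idx += 1
            modules.append(Module(f"f-{idx}", tuple(gs), "wgcna"))
        else:
            unclustered.extend(gs)
    return ModuleSet("wgcna", modules, tuple(sorted(unclustered)))


def _comembership(x: np.ndarray, k_values: Sequence[int], n_resamples: int,
                  subsample: float, rng: np.random.Generator) -> np.ndarray:
    """Mean co-membership frequency over resampled k-means runs.

    Gene rows are standardized first so clustering follows correlation
    structure rather than magnitude.
    """
    n_genes, n_samples = x.shape
    sd = x.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    co = np.zeros((n_genes, n_genes))
    n_runs = 0
    n_sub = max(2, int(round(subsample * n_samples)))
    for i in range(n_resamples):
        k = k_values[i % len(k_values)]
        if k >= n_genes:
            continue
        cols = rng.choice(n_samples, size=n_sub, replace=False)
        km = KMeans(n_clusters=k, n_init=3,
                    random_state=int(rng.integers(2**31 - 1)))
        import warnings
        from sklearn.exceptions import ConvergenceWarning
        with warnings.catch_warnings():
            # duplicate rows (noise-free input) legitimately collapse clusters
            warnings.simplefilter("ignore", ConvergenceWarning)
            labels = km.fit_predict(z[:, cols])
        same = labels[:, None] == labels[None, :]
        co += same
        n_runs += 1
    if n_runs == 0:
        return np.ones((n_genes, n_genes))
    return co / n_runs


def tight_clusters(matrix: pd.DataFrame, module: Module,
                   k_range: Sequence[int] = (2, 3),
                   n_resamples: int = 50, subsample: float = 0.7,
                   consensus: float = 0.7, min_size: int = 3,
                   seed: int = 0) -> ModuleSet:
    """Consensus tight clusters within one module.

    Co-membership frequencies from resampled k-means are thresholded at
    ``consensus``; gene sets whose pairwise co-membership all clears the
    threshold are extracted greedily by descending mean co-membership.
    """
    genes = [g for g in module.genes if g in matrix.index]
    if len(genes) < min_size:
        raise CoexpressionError(f"module {module.name} smaller than min_size")
    x = matrix.loc[genes].to_numpy(float)
    rng = np.random.default_rng(seed)
    co = _comembership(x, list(k_range), n_resamples, subsample, rng)
    remaining = list(range(len(genes)))
    clusters: list[list[int]] = []
    while len(remaining) >= min_size:
        sub = co[np.ix_(remaining, remaining)]
        mean_co = (sub.sum(axis=1) - 1.0) / max(1, len(remaining) - 1)
        order = np.argsort(-mean_co, kind="stable")
        best: list[int] | None = None
        for oi in order:
            seed_gene = remaining[oi]
            members = [seed_gene]
            # candidates sorted by co-membership with the seed
            cands = sorted((g for g in remaining if g != seed_gene),
                           key=lambda g: -co[seed_gene, g])
            for g in cands:
                if all(co[g, m] >= consensus for m in members):
                    members.append(g)
            if len(members) >= min_size:
                best = members
                break
        if best is None:
            break
        clusters.append(sorted(best))
        remaining = [g for g in remaining if g not in set(best)]
    modules = []
    for j, idxs in enumerate(clusters, start=1):
        modules.append(Module(f"{module.name}-{j}",
                              tuple(genes[i] for i in idxs), "tight"))
    pool = tuple(sorted(genes[i] for i in remaining))
    return ModuleSet("tight", modules, pool)


def tight_clusters_all(matrix: pd.DataFrame, wgcna: ModuleSet,
                       **kwargs) -> ModuleSet:
    """tight_clusters over every module of a wgcna ModuleSet."""
    out = ModuleSet("tight")
    seed = kwargs.pop("seed", 0)
    unclustered: list[str] = list(wgcna.unclustered)
    for i, module in enumerate(wgcna.modules):
        ms = tight_clusters(matrix, module, seed=seed + i, **kwargs)
        out.modules.extend(ms.modules)
        unclustered.extend(ms.unclustered)
    out.unclustered = tuple(sorted(unclustered))
    return out


def coherent_clusters(tight: ModuleSet, matrix_b: pd.DataFrame,
                      min_r: float = 0.5, min_size: int = 3
                      ) -> tuple[ModuleSet, ModuleSet]:
    """Split tight clusters into tissue-B-coherent cores and remainders.

    Within each tight cluster the gene with the lowest mean pairwise r in
    tissue B is removed iteratively until every remaining gene's mean
    pairwise r reaches ``min_r`` or the cluster shrinks below ``min_size``.
    Survivors form the coherent cluster; removed genes (and wholly failed
    clusters) form the tissue-specific remainder. Coherent + specific
    genes partition each tight cluster exactly.
    """
    coherent = ModuleSet("coherent")
    specific = ModuleSet("fat_specific")
    for m in tight.modules:
        missing = [g for g in m.genes if g not in matrix_b.index]
        if missing:
            raise CoexpressionError(
                f"genes of {m.name} missing from second tissue: {missing[:5]}")
        genes = list(m.genes)
        removed: list[str] = []
        while len(genes) >= min_size:
            sub = matrix_b.loc[genes].to_numpy(float)
            r = np.corrcoef(sub)
            n = len(genes)
            per_gene = (r.sum(axis=1) - 1.0) / (n - 1)
            worst = int(np.argmin(per_gene))
            if per_gene[worst] >= min_r:
                break
            removed.append(genes.pop(worst))
        if len(genes) >= min_size:
            coherent.modules.append(Module(f"{m.name}-1", tuple(genes), "coherent"))
            if removed:
                specific.modules.append(
                    Module(f"{m.name}-spec", tuple(sorted(removed)), "fat_specific"))
        else:
            specific.modules.append(
                Module(f"{m.name}-spec", tuple(sorted(removed + genes)),
                       "fat_specific"))
    return coherent, specific


def module_enrichment(module_set: ModuleSet,
                      gene_lists: Mapping[str, Iterable[str]],
                      universe: Iterable[str],
                      enrich_alpha: float = 0.05) -> pd.DataFrame:
    """Per-module Fisher exact enrichment for each gene list.

    A module is called enriched for a list when p < ``enrich_alpha`` and
    the odds ratio exceeds 1. q-values are BH-adjusted within each list.
    """
    if not module_set.modules:
        raise CoexpressionError("empty module set")
    universe = set(universe)
    N = len(universe)
    rows = []
    for list_name, genes in gene_lists.items():
        gl = set(genes) & universe
        for m in module_set.modules:
            mg = set(m.genes) & universe
            a = len(mg & gl)
            b = len(mg) - a
            c = len(gl) - a
            d = N - a - b - c
            odds, p = stats.fisher_exact([[a, b], [c, d]])
            rows.append({"module": m.name, "list": list_name, "k": a,
                         "module_size": len(mg), "list_size": len(gl),
                         "odds_ratio": float(odds), "pvalue": float(p),
                         "enriched": bool(p < enrich_alpha and a * d > b * c)})
    df = pd.DataFrame(rows)
    df["qvalue"] = np.nan
    for list_name in gene_lists:
        mask = df["list"] == list_name
        df.loc[mask, "qvalue"] = multipletests(df.loc[mask, "pvalue"],
                                               method="fdr_bh")[1]
    return df


def enrichment_contingency(enrichment: pd.DataFrame, list_x: str, list_y: str
                           ) -> dict[str, object]:
    """Module-level 2x2 of enrichment calls for two lists.

    Tested by chi-square with Yates correction and by Fisher exact.
    """
    ex = enrichment[enrichment["list"] == list_x].set_index("module")["enriched"]
    ey = enrichment[enrichment["list"] == list_y].set_index("module")["enriched"]
    ex, ey = ex.align(ey, join="inner")
    table = np.array([
        [int((ex & ey).sum()), int((ex & ~ey).sum())],
        [int((~ex & ey).sum()), int((~ex & ~ey).sum())],
    ])
    _, p_fisher = stats.fisher_exact(table)
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2, p_chi2, _, _ = stats.chi2_contingency(table, correction=True)
    else:
        chi2, p_chi2 = float("nan"), float("nan")
    return {"table": table, "p_fisher": float(p_fisher),
            "chi2": float(chi2), "p_chi2": float(p_chi2)}
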
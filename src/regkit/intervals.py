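"""Genomic-interval operations for ChIP-peak analyses.

Peak unions, length-matched background segment sampling, window-based
peak-to-gene assignment, and per-peak differential-binding statistics.
All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class IntervalError(ValueError):
    pass


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise IntervalError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (start >= end)")

    @property
    def length(self) -> int:
        return self.end - self.start


def union_intervals(a: Sequence[Interval], b: Sequence[Interval] = ()) -> list[Interval]:
    """Minimal set of maximal merged intervals covering a ∪ b.

    Touching intervals ([0,10) and [10,20)) are merged. Idempotent and
    commutative; ids of merged intervals are regenerated as union_<n>.
    """
    items = sorted(list(a) + list(b), key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[Interval] = []
    for iv in items:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = Interval(last.chrom, last.start, iv.end, last.id)
        else:
            merged.append(iv)
    return [Interval(iv.chrom, iv.start, iv.end, f"union_{i + 1}")
            for i, iv in enumerate(merged)]


def _overlaps_any(chrom: str, start: int, end: int,
                  by_chrom: Mapping[str, np.ndarray]) -> bool:
    ivs = by_chrom.get(chrom)
    if ivs is None or len(ivs) == 0:
        return False
    starts, ends = ivs[:, 0], ivs[:, 1]
    return bool(np.any((starts < end) & (ends > start)))


def sample_matched_background(genome: Mapping[str, str],
                              peaks: Sequence[Interval],
                              seed: int,
                              max_n_frac: float = 0.1,
                              max_retries: int = 1000) -> list[tuple[Interval, str]]:
    """One random genomic segment per peak, matched for length.

    Segments are drawn uniformly over positions (chromosomes weighted by
    length) and rejected if they overlap any input peak or contain more
    than ``max_n_frac`` ambiguous bases. Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = np.array([len(genome[c]) for c in chroms], dtype=float)
    if lengths.sum() == 0:
        raise IntervalError("empty genome")
    weights = lengths / lengths.sum()
    by_chrom: dict[str, np.ndarray] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, [])
    for p in peaks:
        by_chrom[p.chrom].append((p.start, p.end))
    by_chrom = {c: np.array(v, dtype=int).reshape(-1, 2) for c, v in by_chrom.items()}

    out: list[tuple[Interval, str]] = []
    for i, peak in enumerate(peaks):
        L = peak.length
        placed = False
        for _ in range(max_retries):
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            span = len(genome[chrom]) - L
            if span < 0:
                continue
            start = int(rng.integers(0, span + 1))
            end = start + L
            if _overlaps_any(chrom, start, end, by_chrom):
                continue
            seq = genome[chrom][start:end]
            n_frac = sum(1 for b in seq.upper() if b not in "ACGT") / L
            if n_frac > max_n_frac:
                continue
            out.append((Interval(chrom, start, end, f"bg_{i + 1:04d}"), seq))
            placed = True
            break
        if not placed:
            raise IntervalError(
                f"could not place background segment for peak {peak.id or i} "
                f"after {max_retries} retries")
    return out


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise IntervalError(f"gene {self.gene_id}: start >= end")


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 if they overlap or touch."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def assign_target_genes(peaks: Sequence[Interval], genes: Sequence[Gene],
                        window: int = 10_000
                        ) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Assign genes within ``window`` bp of a peak (edge-to-edge, inclusive).

    Returns (peak_id -> [gene_id], gene_id -> [peak_id]); overlap counts as
    distance 0; a gene exactly ``window`` bp away is assigned.
    """
    peak2gene: dict[str, list[str]] = {}
    gene2peak: dict[str, list[str]] = {}
    genes_by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    for p in peaks:
        pid = p.id or f"{p.chrom}:{p.start}-{p.end}"
        for g in genes_by_chrom.get(p.chrom, ()):
            if interval_distance(p.start, p.end, g.start, g.end) <= window:
                peak2gene.setdefault(pid, []).append(g.gene_id)
                gene2peak.setdefault(g.gene_id, []).append(pid)
    return peak2gene, gene2peak


def differential_binding(intensities: pd.DataFrame,
                         group_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-peak differential binding between two (or more) groups.

    ``intensities`` is tidy: columns peak_id, replicate, group, log2ratio.
    Returns a frame indexed by peak_id with log2 fold (mean of second group
    minus mean of first), one-way ANOVA p, and Benjamini-Hochberg q.
    Requires >= 2 replicates in every group.
    """
    required = {"peak_id", "replicate", "group", "log2ratio"}
    missing = required - set(intensities.columns)
    if missing:
        raise IntervalError(f"intensity table missing columns: {sorted(missing)}")
    if not np.isfinite(intensities["log2ratio"]).all():
        raise IntervalError("non-finite binding intensities")
    groups = list(group_order) if group_order else sorted(intensities["group"].unique())
    if len(groups) < 2:
        raise IntervalError("need at least two groups")
    counts = intensities.groupby(["peak_id", "group"])["log2ratio"].count()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise IntervalError(f"group with <2 replicates: {bad}")
    rows = []
    for pid, sub in intensities.groupby("peak_id", sort=True):
        samples = [sub.loc[sub["group"] == g, "log2ratio"].to_numpy() for g in groups]
        fold = float(samples[1].mean() - samples[0].mean())
        if all(np.ptp(s) == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
            p = 1.0
        else:
            p = float(stats.f_oneway(*samples).pvalue)
        rows.append((pid, fold, p))
    out = pd.DataFrame(rows, columns=["peak_id", "log2_fold", "pvalue"]).set_index("peak_id")
    out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
    return out


def binding_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r (and two-sided p) of per-peak intensities for a sample pair."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or len(x) != len(y):
        raise IntervalError("need >= 3 paired peaks")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise IntervalError("zero variance in intensities")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def binding_expression_correlation(peak_folds: Mapping[str, float],
                                   gene_folds: Mapping[str, float],
                                   peak2gene: Mapping[str, Sequence[str]],
                                   min_abs_fold: float = np.log2(1.25)
                                   ) -> tuple[float, float, int]:
    """Correlate per-peak binding fold changes with target-gene expression.

    Peaks are filtered to |log2 fold| >= ``min_abs_fold``; a gene near
    several retained peaks uses the peak with maximum |fold|. Returns
    (r, two-sided p, n joined pairs); fewer than 3 pairs is an error.
    """
    kept = {p: f for p, f in peak_folds.items() if abs(f) >= min_abs_fold}
    gene_best: dict[str, float] = {}
    for pid, fold in kept.items():
        for gid in peak2gene.get(pid, ()):
            if gid not in gene_folds:
                continue
            if gid not in gene_best or abs(fold) > abs(gene_best[gid]):
                gene_best[gid] = fold
    if len(gene_best) < 3:
        raise IntervalError(f"only {len(gene_best)} joined peak-gene pairs (need >= 3)")
    genes = sorted(gene_best)
    x = np.array([gene_best[g] for g in genes])
    y = np.array([gene_folds[g] for g in genes])
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue), len(genes)
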
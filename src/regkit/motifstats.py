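"""Motif-level statistics on ChIP peaks.

Three tests: presence/absence enrichment of a motif in peaks versus
length-matched background (Fisher exact), class-differential motif
association, and a permutation test for inter-site spacing constraints
between heterotypic motif pairs (observed adjacent-pair spacings versus a
pooled within-sequence shuffle null).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .motifs import Motif, MotifSite, ScoreThreshold, scan, threshold_for_pvalue


class MotifStatsError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    motif_name: str
    a: int  # group1, present
    b: int  # group1, absent
    c: int  # group2, present
    d: int  # group2, absent
    odds_ratio: float
    pvalue: float
    qvalue: float | None = None
    enriched: bool = False

    @property
    def table(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]


@dataclass
class SpacingResult:
    anchor: str
    cofactor: str
    signed_histogram: dict[int, int]
    n_le: int
    n_gt: int
    b_le: int
    b_gt: int
    pvalue: float
    alpha_match: float | None = None
    n_shuffles: int = 0
    modal_spacing: int | None = None
    no_pairs: bool = False


def motif_presence(sites: Iterable[MotifSite], seq_ids: Iterable[str],
                   motif_name: str | None = None) -> dict[str, bool]:
    """present iff >= 1 site on either strand; overlaps collapse."""
    present = {s: False for s in seq_ids}
    for site in sites:
        if motif_name is not None and site.motif_name != motif_name:
            continue
        if site.seq_id in present:
            present[site.seq_id] = True
    return present


def _fisher(table) -> tuple[float, float]:
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def presence_table_test(n1_present: int, n1_total: int,
                        n2_present: int, n2_total: int,
                        motif_name: str = "") -> EnrichmentResult:
    """Two-sided Fisher exact on a presence/absence 2x2 table."""
    a, b = n1_present, n1_total - n1_present
    c, d = n2_present, n2_total - n2_present
    odds, p = _fisher([[a, b], [c, d]])
    # direction by presence fractions (robust when the odds ratio is 0/inf)
    enriched = (a * n2_total) > (c * n1_total)
    return EnrichmentResult(motif_name, a, b, c, d, odds, p, enriched=enriched)


def enrichment_test(peak_seqs: Mapping[str, str],
                    background_seqs: Mapping[str, str],
                    motif: Motif,
                    alpha_match: float = 1e-3,
                    threshold: ScoreThreshold | None = None) -> EnrichmentResult:
    """Fisher exact test of motif presence in peaks vs background sequences."""
    if not peak_seqs or not background_seqs:
        raise MotifStatsError("empty sequence set")
    if threshold is None:
        threshold = threshold_for_pvalue(motif, alpha_match)
    peak_sites = scan(peak_seqs, motif, threshold)
    bg_sites = scan(background_seqs, motif, threshold)
    p_pres = sum(motif_presence(peak_sites, peak_seqs).values())
    b_pres = sum(motif_presence(bg_sites, background_seqs).values())
    return presence_table_test(p_pres, len(peak_seqs), b_pres, len(background_seqs),
                               motif.name)


def enrichment_screen(peak_seqs: Mapping[str, str],
                      background_seqs: Mapping[str, str],
                      motifs: Sequence[Motif],
                      alpha_match: float = 1e-3) -> list[EnrichmentResult]:
    """Run enrichment_test across a motif compendium with BH-FDR correction."""
    results = [enrichment_test(peak_seqs, background_seqs, m, alpha_match)
               for m in motifs]
    qvals = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qvals):
        r.qvalue = float(q)
    return sorted(results, key=lambda r: r.pvalue)


def class_association_test(class_labels: Mapping[str, str],
                           presence: Mapping[str, bool],
                           motif_name: str = "") -> EnrichmentResult:
    """Fisher exact test of motif presence against a two-class locus labeling.

    ``class_labels`` maps locus id -> class; exactly two classes required,
    each non-empty.
    """
    classes = sorted(set(class_labels.values()))
    if len(classes) != 2:
        raise MotifStatsError(f"need exactly two classes, got {classes}")
    tot = Counter(class_labels.values())
    pres = Counter(cl for locus, cl in class_labels.items() if presence.get(locus, False))
    res = presence_table_test(pres[classes[0]], tot[classes[0]],
                              pres[classes[1]], tot[classes[1]], motif_name)
    return res


def _adjacent_heterotypic_spacings(anchor_starts: np.ndarray,
                                   cofactor_starts: np.ndarray) -> np.ndarray:
    """Signed spacings of adjacent heterotypic pairs in one sequence.

    Sites of both motifs are merged and start-sorted; each consecutive pair
    of different motifs contributes spacing = cofactor start - anchor start
    (negative when the cofactor lies to the left).
    """
    na, nc = len(anchor_starts), len(cofactor_starts)
    if na == 0 or nc == 0:
        return np.empty(0, dtype=int)
    starts = np.concatenate([anchor_starts, cofactor_starts])
    is_anchor = np.concatenate([np.ones(na, bool), np.zeros(nc, bool)])
    order = np.lexsort((~is_anchor, starts))  # stable: anchor first on ties
    starts = starts[order]
    is_anchor = is_anchor[order]
    het = is_anchor[:-1] != is_anchor[1:]
    left, right = starts[:-1][het], starts[1:][het]
    left_is_anchor = is_anchor[:-1][het]
    return np.where(left_is_anchor, right - left, left - right).astype(int)


def spacing_histogram(anchor_sites: Iterable[MotifSite],
                      cofactor_sites: Iterable[MotifSite]
                      ) -> tuple[dict[int, int], int | None]:
    """Signed spacing histogram over all adjacent heterotypic pairs.

    Returns (histogram, modal spacing or None if empty). Spacing is between
    start positions; homotypic neighbors are skipped by the adjacency rule.
    """
    a_by_seq: dict[str, list[int]] = {}
    c_by_seq: dict[str, list[int]] = {}
    for s in anchor_sites:
        a_by_seq.setdefault(s.seq_id, []).append(s.start)
    for s in cofactor_sites:
        c_by_seq.setdefault(s.seq_id, []).append(s.start)
    hist: Counter[int] = Counter()
    for seq_id in set(a_by_seq) & set(c_by_seq):
        sp = _adjacent_heterotypic_spacings(np.array(a_by_seq[seq_id]),
                                            np.array(c_by_seq[seq_id]))
        hist.update(sp.tolist())
    if not hist:
        return {}, None
    mode = max(hist.items(), key=lambda kv: (kv[1], -abs(kv[0])))[0]
    return dict(sorted(hist.items())), mode


def shuffle_sites(sites: Sequence[MotifSite],
                  seq_lengths: Mapping[str, int],
                  motif_widths: Mapping[str, int],
                  rng: np.random.Generator) -> list[MotifSite]:
    """Resample each site's start uniformly over its sequence.

    Per-motif site counts, widths, and strands are preserved per sequence;
    shuffled sites may overlap one another.
    """
    out = []
    for s in sites:
        w = motif_widths[s.motif_name]
        L = seq_lengths[s.seq_id]
        if w > L:
            raise MotifStatsError(
                f"motif {s.motif_name} (w={w}) wider than sequence {s.seq_id} (L={L})")
        new_start = int(rng.integers(0, L - w + 1))
        out.append(MotifSite(s.seq_id, new_start, s.strand, s.score, s.motif_name))
    return out


def _le_gt_counts(spacings: Iterable[int], cutoff: int) -> tuple[int, int]:
    le = gt = 0
    for sp in spacings:
        if abs(sp) <= cutoff:
            le += 1
        else:
            gt += 1
    return le, gt


def spacing_test_from_sites(anchor_sites: Sequence[MotifSite],
                            cofactor_sites: Sequence[MotifSite],
                            seq_lengths: Mapping[str, int],
                            anchor_width: int,
                            cofactor_width: int,
                            cutoff: int = 25,
                            n_shuffles: int = 50,
                            seed: int = 0,
                            alpha_match: float | None = None) -> SpacingResult:
    """Spacing-constraint test on precomputed site lists.

    Observed adjacent heterotypic pairs are split at |spacing| <= cutoff and
    compared by Fisher exact test with pairs pooled over ``n_shuffles``
    within-sequence shuffles of the site locations. Zero observed pairs
    returns p = 1 with ``no_pairs`` set.
    """
    anchor_name = anchor_sites[0].motif_name if anchor_sites else "anchor"
    cof_name = cofactor_sites[0].motif_name if cofactor_sites else "cofactor"

    hist, mode = spacing_histogram(anchor_sites, cofactor_sites)
    n_le, n_gt = _le_gt_counts(Counter(hist).elements(), cutoff)

    # pooled shuffle null, drawn batched per sequence over all shuffles;
    # per-motif site counts per sequence are preserved by construction
    counts: dict[str, list[int]] = {}
    for s in anchor_sites:
        counts.setdefault(s.seq_id, [0, 0])[0] += 1
    for s in cofactor_sites:
        counts.setdefault(s.seq_id, [0, 0])[1] += 1
    b_le = b_gt = 0
    for si, seq_id in enumerate(sorted(counts)):
        na, nc = counts[seq_id]
        if na == 0 or nc == 0:
            continue
        L = seq_lengths[seq_id]
        for w, label in ((anchor_width, anchor_name), (cofactor_width, cof_name)):
            if w > L:
                raise MotifStatsError(
                    f"motif {label} (w={w}) wider than sequence {seq_id} (L={L})")
        rng = np.random.default_rng((seed, si))
        a_starts = rng.integers(0, L - anchor_width + 1, size=(n_shuffles, na))
        c_starts = rng.integers(0, L - cofactor_width + 1, size=(n_shuffles, nc))
        starts = np.concatenate([a_starts, c_starts], axis=1)
        is_anchor = np.concatenate(
            [np.ones(na, bool), np.zeros(nc, bool)])[None, :].repeat(n_shuffles, 0)
        key = starts * 2 + (~is_anchor)  # stable anchor-first on equal starts
        order = np.argsort(key, axis=1, kind="stable")
        starts = np.take_along_axis(starts, order, axis=1)
        is_anchor = np.take_along_axis(is_anchor, order, axis=1)
        het = is_anchor[:, :-1] != is_anchor[:, 1:]
        left, right = starts[:, :-1], starts[:, 1:]
        sp = np.where(is_anchor[:, :-1], right - left, left - right)
        close = np.abs(sp) <= cutoff
        b_le += int((close & het).sum())
        b_gt += int((~close & het).sum())

    if n_le + n_gt == 0:
        return SpacingResult(anchor_name, cof_name, hist, 0, 0, b_le, b_gt,
                             1.0, alpha_match, n_shuffles, None, no_pairs=True)
    _, p = _fisher([[n_le, n_gt], [b_le, b_gt]])
    return SpacingResult(anchor_name, cof_name, hist, n_le, n_gt, b_le, b_gt,
                         float(p), alpha_match, n_shuffles, mode)


def spacing_constraint_test(sequences: Mapping[str, str],
                            anchor: Motif,
                            cofactor: Motif,
                            cutoff: int = 25,
                            n_shuffles: int = 50,
                            alpha_match: float = 1e-3,
                            seed: int = 0) -> SpacingResult:
    """Scan sequences for both motifs, then run the spacing-constraint test."""
    t_a = threshold_for_pvalue(anchor, alpha_match)
    t_c = threshold_for_pvalue(cofactor, alpha_match)
    a_sites = scan(sequences, anchor, t_a)
    c_sites = scan(sequences, cofactor, t_c)
    seq_lengths = {k: len(v) for k, v in sequences.items()}
    res = spacing_test_from_sites(a_sites, c_sites, seq_lengths,
                                  anchor.width, cofactor.width,
                                  cutoff=cutoff, n_shuffles=n_shuffles,
                                  seed=seed, alpha_match=alpha_match)
    res.anchor = anchor.name
    res.cofactor = cofactor.name
    return res
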
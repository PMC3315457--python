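"""Synthetic-data generators with planted ground truth.

Every generator is a pure function of its config (including the seed), so
downstream recovery assertions can be made against the returned truth
tables without re-deriving structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import BASES, Motif, reverse_complement

_SEQ_ID_FMT = "peak_{:04d}"


class SimulationError(ValueError):
    pass


@dataclass
class PairSpec:
    anchor: Motif
    cofactor: Motif
    spacing: int          # signed start-to-start spacing d (cofactor - anchor)
    fraction: float = 1.0  # fraction of sequences carrying the pair

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise SimulationError("pair fraction must be in [0, 1]")


@dataclass
class SeqSimConfig:
    n_peaks: int
    length_range: tuple[int, int] = (300, 700)
    gc: float = 0.35
    planted: Sequence[tuple[Motif, int]] = ()
    pair_spec: PairSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise SimulationError("invalid length range")
        if not (0.0 <= self.gc <= 1.0):
            raise SimulationError("gc must be in [0, 1]")
        widths = [m.width for m, _ in self.planted]
        if self.pair_spec is not None:
            ps = self.pair_spec
            widths.append(max(ps.anchor.width, ps.spacing + ps.cofactor.width)
                          - min(0, ps.spacing))
        if widths and max(widths) > lo:
            raise SimulationError("planted motifs do not fit in min length")


@dataclass
class ExprSimConfig:
    n_genes: int
    n_samples: int
    modules: Sequence[tuple[int, float, bool]] = ()  # (size, loading, shared)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(size for size, _, _ in self.modules) > self.n_genes:
            raise SimulationError("sum of module sizes exceeds n_genes")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be >= 0")


@dataclass
class ListSimConfig:
    universe_size: int
    list_sizes: Mapping[str, int] = field(default_factory=dict)
    overlaps: Mapping[frozenset, int] = field(default_factory=dict)
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.rho) > 1:
            raise SimulationError("|rho| must be <= 1")
        for pair, k in self.overlaps.items():
            a, b = sorted(pair)
            if k > min(self.list_sizes[a], self.list_sizes[b]):
                raise SimulationError(f"overlap {k} exceeds list sizes for {a},{b}")


def gen_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """I.i.d. (Markov-0) sequence with P(G) = P(C) = gc/2."""
    if length < 1:
        raise SimulationError("length must be >= 1")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc) / 2.0
    probs = [at, gc / 2.0, gc / 2.0, at]
    codes = rng.choice(4, size=length, p=probs)
    return "".join(BASES[c] for c in codes)


def _sample_planted_word(motif: Motif, rng: np.random.Generator) -> str:
    """A maximum-probability word, degenerate positions resolved at random."""
    return motif.consensus_words(rng)


def _place_nonoverlapping(length: int, width: int,
                          occupied: list[tuple[int, int]],
                          rng: np.random.Generator,
                          max_retries: int = 200) -> int | None:
    for _ in range(max_retries):
        start = int(rng.integers(0, length - width + 1))
        if all(start + width <= s or start >= e for s, e in occupied):
            return start
    return None


def gen_peaks(config: SeqSimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Markov-0 peak sequences with planted motif instances and motif pairs.

    Returns (sequences by id, truth table with columns seq_id, motif,
    start, strand). For pair-carrying sequences the cofactor start minus
    the anchor start equals the configured spacing exactly; both pair sites
    go on the forward strand. Singleton planted sites get a random strand.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    seqs: dict[str, str] = {}
    truth_rows: list[dict] = []
    n_pair = 0
    if config.pair_spec is not None:
        n_pair = int(round(config.pair_spec.fraction * config.n_peaks))
    for i in range(config.n_peaks):
        seq_id = _SEQ_ID_FMT.format(i + 1)
        length = int(rng.integers(lo, hi + 1))
        seq = list(gen_genome(length, config.gc, seed=int(rng.integers(2**63))))
        occupied: list[tuple[int, int]] = []

        if config.pair_spec is not None and i < n_pair:
            ps = config.pair_spec
            d = ps.spacing
            wa, wc = ps.anchor.width, ps.cofactor.width
            left = min(0, d)
            right = max(wa, d + wc)
            span = right - left
            offset = int(rng.integers(0, length - span + 1))
            a_start = offset - left
            c_start = a_start + d
            word_a = _sample_planted_word(ps.anchor, rng)
            word_c = _sample_planted_word(ps.cofactor, rng)
            # cofactor written second: on overlap its bases win, matching the
            # "cofactor site present" truth row
            seq[a_start:a_start + wa] = word_a
            seq[c_start:c_start + wc] = word_c
            occupied.append((min(a_start, c_start), max(a_start + wa, c_start + wc)))
            truth_rows.append(dict(seq_id=seq_id, motif=ps.anchor.name,
                                   start=a_start, strand="+"))
            truth_rows.append(dict(seq_id=seq_id, motif=ps.cofactor.name,
                                   start=c_start, strand="+"))

        for motif, copies in config.planted:
            for _ in range(copies):
                start = _place_nonoverlapping(length, motif.width, occupied, rng)
                if start is None:
                    raise SimulationError(
                        f"cannot place {motif.name} in {seq_id} without overlap")
                strand = "+" if rng.random() < 0.5 else "-"
                word = _sample_planted_word(motif, rng)
                if strand == "-":
                    word = reverse_complement(word)
                seq[start:start + motif.width] = word
                occupied.append((start, start + motif.width))
                truth_rows.append(dict(seq_id=seq_id, motif=motif.name,
                                       start=start, strand=strand))
        seqs[seq_id] = "".join(seq)
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "motif", "start", "strand"])
    return seqs, truth


def gen_two_tissue_expression(config: ExprSimConfig
                              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Paired latent-factor expression matrices for two tissues.

    Module genes follow loading * factor + N(0, sd^2). Shared modules reuse
    tissue A's factor in tissue B; unshared modules are pure noise in
    tissue B. Genes outside any module are pure noise in both tissues.
    Returns (matrix A, matrix B, gene -> module label; '' = background).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    samples = [f"s{j + 1:03d}" for j in range(config.n_samples)]
    a = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples))
    b = rng.normal(0.0, config.noise_sd, size=(config.n_genes, config.n_samples))
    labels = pd.Series([""] * config.n_genes, index=genes, name="module")
    pos = 0
    for mi, (size, loading, shared) in enumerate(config.modules, start=1):
        factor_a = rng.normal(size=config.n_samples)
        rows = slice(pos, pos + size)
        a[rows] += loading * factor_a
        if shared:
            b[rows] += loading * factor_a
        labels.iloc[rows.start:rows.stop] = f"m{mi}"
        pos += size
    mat_a = pd.DataFrame(a, index=genes, columns=samples)
    mat_b = pd.DataFrame(b, index=genes, columns=samples)
    return mat_a, mat_b, labels


def gen_de_tables(config: ListSimConfig
                  ) -> tuple[dict[str, pd.DataFrame], dict[str, set[str]]]:
    """Named differential-expression tables with exact sizes and overlaps.

    Overlaps are realized as exactly-pairwise regions (no triple overlaps),
    so each list is (exclusive genes) + (its pairwise overlap genes).
    Fold changes of genes shared by a specified pair are drawn bivariate
    normal with correlation rho. Each table covers the whole universe;
    listed genes have fdr < 0.1, others fdr >= 0.1.
    """
    rng = np.random.default_rng(config.seed)
    names = sorted(config.list_sizes)
    overlaps = {frozenset(k): v for k, v in config.overlaps.items()}
    shared_of = {n: sum(v for k, v in overlaps.items() if n in k) for n in names}
    exclusive = {n: config.list_sizes[n] - shared_of[n] for n in names}
    for n, e in exclusive.items():
        if e < 0:
            raise SimulationError(f"infeasible overlap system for list {n!r}")
    total = sum(exclusive.values()) + sum(overlaps.values())
    if total > config.universe_size:
        raise SimulationError("lists do not fit in the universe")

    universe = [f"g{i + 1:05d}" for i in range(config.universe_size)]
    pool = list(rng.permutation(universe))
    members: dict[str, set[str]] = {n: set() for n in names}
    pair_genes: dict[frozenset, list[str]] = {}
    for pair, k in sorted(overlaps.items(), key=lambda kv: tuple(sorted(kv[0]))):
        gs = [pool.pop() for _ in range(k)]
        pair_genes[pair] = gs
        for n in pair:
            members[n].update(gs)
    for n in names:
        members[n].update(pool.pop() for _ in range(exclusive[n]))

    fc: dict[str, dict[str, float]] = {n: {} for n in names}
    cov = np.array([[1.0, config.rho], [config.rho, 1.0]])
    for pair, gs in pair_genes.items():
        x, y = sorted(pair)
        draws = rng.multivariate_normal([0, 0], cov, size=len(gs))
        for g, (fx, fy) in zip(gs, draws):
            fc[x][g] = float(fx)
            fc[y][g] = float(fy)
    tables: dict[str, pd.DataFrame] = {}
    for n in names:
        rows = []
        for g in universe:
            if g in members[n]:
                lf = fc[n].get(g)
                if lf is None:
                    lf = float(rng.normal())
                if lf == 0.0:
                    lf = 1e-9
                p = float(rng.uniform(0, 1e-3))
                q = float(rng.uniform(0, 0.099))
            else:
                lf = float(rng.normal(0, 0.05))
                p = float(rng.uniform(0.1, 1.0))
                q = float(rng.uniform(0.2, 1.0))
            rows.append((g, lf, p, q, "up" if lf > 0 else "down"))
        tables[n] = pd.DataFrame(
            rows, columns=["gene_id", "log2fc", "pvalue", "fdr", "direction"])
    return tables, members
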
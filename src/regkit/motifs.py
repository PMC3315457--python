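"""Position weight matrix motifs, score-threshold calibration, and scanning.

Motifs are built from IUPAC consensus strings or count matrices, scored as
natural-log odds against a Markov-0 background, calibrated to a match
threshold by the exact tail probability of the per-window score
distribution, and scanned over both strands of DNA sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC_CODES: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

#: support-size budget (as a power of 4) above which the exact
#: merged-support distribution switches to the discretized convolution
EXACT_ENUM_MAX_WIDTH = 8
DEFAULT_BIN_WIDTH = 1e-3


class MotifError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Motif:
    """A probability motif with background model.

    ``probs`` is a (width, 4) matrix over A, C, G, T; each row sums to 1.
    ``background`` is the Markov-0 base composition used for log-odds.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise MotifError("probs must be a (width, 4) matrix with width >= 1")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-9):
            raise MotifError("each motif column must sum to 1")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise MotifError("background must be a length-4 probability vector")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(width, 4) natural-log odds matrix; -inf where probability is 0."""
        with np.errstate(divide="ignore"):
            return np.log(self.probs) - np.log(self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def score_word(self, word: str) -> float:
        """Log-odds score of a single width-length word."""
        if len(word) != self.width:
            raise MotifError(f"word length {len(word)} != motif width {self.width}")
        lom = self.log_odds
        try:
            return float(sum(lom[i, BASE_INDEX[b]] for i, b in enumerate(word.upper())))
        except KeyError as exc:
            raise MotifError(f"non-ACGT character in word: {exc}") from exc

    def reverse_complement(self) -> "Motif":
        return Motif(self.name, self.probs[::-1, ::-1].copy(),
                     self.background, self.pseudocount)

    def consensus_words(self, rng: np.random.Generator | None = None) -> str:
        """One maximum-probability word; degenerate ties broken by ``rng``
        (first base if no rng given)."""
        out = []
        for col in self.probs:
            best = np.flatnonzero(np.isclose(col, col.max()))
            pick = best[0] if rng is None else rng.choice(best)
            out.append(BASES[pick])
        return "".join(out)


@dataclass(frozen=True)
class MotifSite:
    """A scored, stranded motif match on a named sequence.

    ``start`` is the 0-based offset of the window on the forward strand,
    for both + and - strand sites.
    """

    seq_id: str
    start: int
    strand: str
    score: float
    motif_name: str


@dataclass(frozen=True)
class ScoreThreshold:
    motif_name: str
    pvalue: float
    score_cutoff: float


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def gc_background(gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2.0, gc / 2.0, at])


def iupac_to_pwm(consensus: str, pseudocount: float = 0.01,
                 background: np.ndarray | None = None,
                 name: str | None = None) -> Motif:
    """Build a motif from an IUPAC degenerate consensus.

    Each position puts equal probability on the code's allowed bases, then
    ``pseudocount`` total weight (distributed by the background) is mixed in.
    """
    if not consensus:
        raise MotifError("empty consensus string")
    bg = uniform_background() if background is None else np.asarray(background, float)
    cols = np.zeros((len(consensus), 4))
    for i, ch in enumerate(consensus.upper()):
        allowed = IUPAC_CODES.get(ch)
        if allowed is None:
            raise MotifError(f"illegal IUPAC character {ch!r} at position {i}")
        for b in allowed:
            cols[i, BASE_INDEX[b]] = 1.0 / len(allowed)
    if pseudocount:
        cols = (cols + pseudocount * bg) / (1.0 + pseudocount)
    return Motif(name or consensus, cols, bg, pseudocount)


def build_pwm(counts, pseudocount: float = 0.01,
              background: np.ndarray | None = None,
              name: str = "pwm") -> Motif:
    """Build a motif from a 4-row (A,C,G,T) x width count matrix.

    Column probability = (count + eps * pi) / (total + eps).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise MotifError("count matrix must have 4 rows (A, C, G, T)")
    if (counts < 0).any():
        raise MotifError("counts must be non-negative")
    bg = uniform_background() if background is None else np.asarray(background, float)
    totals = counts.sum(axis=0)
    if pseudocount == 0 and (totals == 0).any():
        raise MotifError("all-zero column with zero pseudocount")
    probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    return Motif(name, probs.T, bg, pseudocount)


@dataclass
class ScoreDistribution:
    """Exact distribution of per-window log-odds under the background."""

    scores: np.ndarray  # ascending support
    probs: np.ndarray

    def tail(self, t: float) -> float:
        """P(score >= t)."""
        idx = np.searchsorted(self.scores, t, side="left")
        return float(self.probs[idx:].sum())


def score_distribution(motif: Motif, bin_width: float = DEFAULT_BIN_WIDTH,
                       method: str = "auto") -> ScoreDistribution:
    """Distribution of window scores for i.i.d. background sequence.

    method 'exact' convolves exact per-column score values (support may be
    as large as 4^width); 'binned' discretizes scores to ``bin_width`` nats
    and convolves integer-indexed mass arrays. 'auto' picks 'exact' when
    the support-size bound stays within 4^8, else 'binned'.
    """
    lom = motif.log_odds
    if method == "auto":
        # upper bound on exact-support size: product of distinct column values
        est = 1
        for col in lom:
            est *= len(np.unique(np.round(col, 9)))
            if est > 4 ** EXACT_ENUM_MAX_WIDTH:
                break
        method = "exact" if est <= 4 ** EXACT_ENUM_MAX_WIDTH else "binned"
    bg = motif.background
    if method == "exact":
        dist: dict[float, float] = {0.0: 1.0}
        for i in range(motif.width):
            new: dict[float, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    s2 = round(s + lom[i, b], 12)
                    new[s2] = new.get(s2, 0.0) + p * bg[b]
            dist = new
        scores = np.array(sorted(dist))
        probs = np.array([dist[s] for s in scores])
        # merge support points split only by summation-order noise
        if len(scores) > 1:
            starts = np.concatenate(
                [[0], np.flatnonzero(np.diff(scores) > 1e-9) + 1])
            scores = scores[starts]
            probs = np.add.reduceat(probs, starts)
        return ScoreDistribution(scores, probs)
    if method == "binned":
        if not np.isfinite(lom).all():
            raise MotifError("binned mode requires finite log-odds "
                             "(use a nonzero pseudocount)")
        cols = np.rint(lom / bin_width).astype(np.int64)
        cur = np.array([1.0])
        cur_lo = 0
        for i in range(motif.width):
            c = cols[i]
            new_lo = cur_lo + int(c.min())
            new_hi = cur_lo + len(cur) - 1 + int(c.max())
            new = np.zeros(new_hi - new_lo + 1)
            for b in range(4):
                sh = cur_lo + int(c[b]) - new_lo
                new[sh:sh + len(cur)] += cur * bg[b]
            cur, cur_lo = new, new_lo
        support = (np.arange(cur_lo, cur_lo + len(cur))) * bin_width
        keep = cur > 0
        return ScoreDistribution(support[keep], cur[keep])
    raise MotifError(f"unknown method {method!r}")


def threshold_for_pvalue(motif: Motif, alpha: float,
                         dist: ScoreDistribution | None = None) -> ScoreThreshold:
    """Smallest attainable cutoff t with P(score >= t | background) <= alpha.

    If even the maximum attainable score has tail probability > alpha the
    cutoff is +inf (no window can match).
    """
    if not (0.0 < alpha <= 1.0):
        raise MotifError("alpha must be in (0, 1]")
    if dist is None:
        dist = score_distribution(motif)
    if len(dist.scores) == 0:
        raise MotifError("empty score distribution")
    # tail[i] = P(score >= scores[i]); scores ascending
    tails = np.cumsum(dist.probs[::-1])[::-1]
    ok = np.flatnonzero(tails <= alpha + 1e-12)
    cutoff = float(dist.scores[ok[0]]) if len(ok) else float("inf")
    return ScoreThreshold(motif.name, alpha, cutoff)


def encode(seq: str) -> np.ndarray:
    """Sequence to integer codes; non-ACGT becomes 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Score of every window; NaN where the window contains a non-ACGT base."""
    w = lom.shape[0]
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0)
    ext = np.vstack([lom.T, np.full((1, w), np.nan)])  # row 4 = invalid base
    scores = np.zeros(n)
    for j in range(w):
        scores += ext[codes[j:j + n], j]
    return scores


def scan(sequences: Mapping[str, str] | Iterable[tuple[str, str]],
         motif: Motif,
         threshold: ScoreThreshold | float,
         strands: str = "both") -> list[MotifSite]:
    """Report every window on the requested strands scoring >= the cutoff.

    Reverse-strand sites are reported at the forward-strand start of their
    window. Windows containing non-ACGT characters are skipped. Sequences
    shorter than the motif yield no sites.
    """
    cutoff = threshold.score_cutoff if isinstance(threshold, ScoreThreshold) else float(threshold)
    if isinstance(sequences, Mapping):
        items = sequences.items()
    else:
        items = sequences
    lom = motif.log_odds
    rc_lom = lom[::-1, ::-1]
    sites: list[MotifSite] = []
    for seq_id, seq in items:
        codes = encode(seq)
        if strands in ("both", "+"):
            sc = _window_scores(codes, lom)
            with np.errstate(invalid="ignore"):
                hits = np.flatnonzero(sc >= cutoff)
            for h in hits:
                sites.append(MotifSite(seq_id, int(h), "+", float(sc[h]), motif.name))
        if strands in ("both", "-"):
            sc = _window_scores(codes, rc_lom)
            with np.errstate(invalid="ignore"):
                hits = np.flatnonzero(sc >= cutoff)
            for h in hits:
                sites.append(MotifSite(seq_id, int(h), "-", float(sc[h]), motif.name))
    sites.sort(key=lambda s: (s.seq_id, s.start, s.strand))
    return sites
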
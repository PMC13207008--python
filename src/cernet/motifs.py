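"""JASPAR PFM parsing, log-odds PWM construction and promoter scanning.

A position frequency matrix (counts of A/C/G/T per motif column) is turned
into a log-odds weight matrix

    w(b, j) = log2( (n_bj + p * bg_b) / (N_j + p) / bg_b )

with pseudocount ``p`` distributed according to the background ``bg``.
Window scores are sums of per-position weights (base 2); the *relative
score* rescales a window score between the matrix's minimum and maximum
attainable scores, so the consensus sequence always scores 1.0. Hits are
reported on both strands at a configurable relative-score threshold
(default 0.80).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


@dataclass
class PWMotif:
    """A motif as counts plus its derived log-odds weight matrix."""

    motif_id: str
    name: str
    counts: np.ndarray  # (4, width) non-negative
    pseudocount: float = 0.8
    background: tuple[float, float, float, float] = UNIFORM_BG
    weights: np.ndarray = field(init=False)
    score_min: float = field(init=False)
    score_max: float = field(init=False)

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4:
            raise ValueError("counts must be a 4 x width matrix (rows A, C, G, T)")
        if (c < 0).any():
            raise ValueError("negative counts in PFM")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or (bg <= 0).any() or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 positive probabilities summing to 1")
        self.counts = c
        totals = c.sum(axis=0)
        probs = (c + self.pseudocount * bg[:, None]) / (totals + self.pseudocount)
        self.weights = np.log2(probs / bg[:, None])
        self.score_min = float(self.weights.min(axis=0).sum())
        self.score_max = float(self.weights.max(axis=0).sum())

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[j] for j in self.weights.argmax(axis=0))

    def relative(self, score: float) -> float:
        """Rescale a window score to [0, 1]; flat motifs map to 1.0."""
        span = self.score_max - self.score_min
        if span == 0:
            return 1.0
        return (score - self.score_min) / span


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif_id: str
    offset: int  # 0-based, on the + strand coordinate system
    strand: str  # "+" | "-"
    matched_sequence: str
    score: float
    relative_score: float


def read_pfm(source: str | Path, *, pseudocount: float = 0.8,
             background: tuple[float, float, float, float] = UNIFORM_BG) -> list[PWMotif]:
    """Read one or more motifs from JASPAR PFM text (path or literal text)."""
    if isinstance(source, Path) or "\n" not in str(source):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
        out = []
        for m in parsed:
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
            out.append(
                PWMotif(
                    motif_id=m.matrix_id or m.name or "motif",
                    name=m.name or "",
                    counts=counts,
                    pseudocount=pseudocount,
                    background=background,
                )
            )
    except Exception as exc:  # surface parse problems with context
        raise ValueError(f"malformed JASPAR PFM input: {exc}") from exc
    if not out:
        raise ValueError("no motifs found in PFM input")
    return out


def write_pfm(pwms: list[PWMotif], path: str | Path) -> None:
    """Write motifs in JASPAR 2016+ PFM text format."""
    with open(path, "w") as fh:
        for m in pwms:
            fh.write(f">{m.motif_id} {m.name}\n")
            for i, b in enumerate(BASES):
                row = " ".join(f"{int(v):6d}" if float(v).is_integer() else f"{v:8.2f}"
                               for v in m.counts[i])
                fh.write(f"{b} [ {row} ]\n")


_RC = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and N (or other ambiguity) to 4."""
    idx = np.full(len(seq), 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return idx


def _window_scores(pwm: PWMotif, seq: str) -> np.ndarray:
    """Score every window of one strand; N positions contribute the
    background-weighted average weight of their column."""
    w = pwm.width
    idx = _encode(seq)
    n_win = len(seq) - w + 1
    if n_win <= 0:
        return np.empty(0)
    bg = np.asarray(pwm.background)
    ambiguous = (bg[:, None] * pwm.weights).sum(axis=0)  # per-column expected weight
    weights5 = np.vstack([pwm.weights, ambiguous[None, :]])  # row 4 = N
    scores = np.zeros(n_win)
    for j in range(w):
        scores += weights5[idx[j : j + n_win], j]
    return scores


def scan_promoter(pwm: PWMotif, sequence: str, *, sequence_id: str = "seq",
                  threshold: float = 0.80) -> list[MotifHit]:
    """Scan both strands of a sequence; report hits at or above the
    relative-score threshold, sorted by offset then strand.

    Minus-strand windows are scored on the reverse complement; their
    offsets are reported in + strand coordinates (the window's leftmost
    base).
    """
    seq = sequence.strip().upper().replace("U", "T")
    if not seq:
        raise ValueError(f"empty sequence {sequence_id!r}")
    w = pwm.width
    if len(seq) < w:
        raise ValueError(f"sequence {sequence_id!r} shorter than motif width {w}")
    hits: list[MotifHit] = []
    n = len(seq)
    fwd = _window_scores(pwm, seq)
    rev = _window_scores(pwm, _revcomp(seq))
    for off, sc in enumerate(fwd):
        rel = pwm.relative(float(sc))
        if rel >= threshold:
            hits.append(MotifHit(sequence_id, pwm.motif_id, off, "+", seq[off : off + w], float(sc), rel))
    for roff, sc in enumerate(rev):
        rel = pwm.relative(float(sc))
        if rel >= threshold:
            off = n - w - roff
            hits.append(MotifHit(sequence_id, pwm.motif_id, off, "-", seq[off : off + w], float(sc), rel))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_many(pwm: PWMotif, sequences: dict[str, str], *, threshold: float = 0.80) -> pd.DataFrame:
    """Hit table over a set of sequences (e.g. promoters)."""
    rows = []
    for sid in sorted(sequences):
        for h in scan_promoter(pwm, sequences[sid], sequence_id=sid, threshold=threshold):
            rows.append((h.sequence_id, h.motif_id, h.offset, h.strand,
                         h.matched_sequence, h.score, h.relative_score))
    return pd.DataFrame(
        rows,
        columns=["sequence_id", "motif_id", "offset", "strand",
                 "matched_sequence", "score", "relative_score"],
    )


def promoter_report(hits: pd.DataFrame, gene_ids: list[str]) -> pd.DataFrame:
    """One best hit per gene: max relative score, ties broken by leftmost
    offset then + strand. Genes without hits get a 'no hit' sentinel row."""
    rows = []
    for gid in sorted(gene_ids):
        sub = hits[hits["sequence_id"] == gid] if not hits.empty else hits
        if sub is None or len(sub) == 0:
            rows.append((gid, None, np.nan, np.nan, -1, ".", "no hit"))
            continue
        sub = sub.sort_values(
            ["relative_score", "offset", "strand"], ascending=[False, True, True]
        )
        best = sub.iloc[0]
        rows.append((gid, best["motif_id"], best["score"], best["relative_score"],
                     int(best["offset"]), best["strand"], best["matched_sequence"]))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "motif_id", "best_score", "best_relative_score",
                 "offset", "strand", "matched_sequence"],
    )
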
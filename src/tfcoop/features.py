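"""Predictors of the binding model: PWM scores, TRAP affinities, composition.

Every sequence is described by one score per motif in a PWM library plus 12
reverse-complement-collapsed composition rates (2 mononucleotide classes and
10 dinucleotide classes).  Two motif scorers are provided:

``best_hit``
    The classical maximum log-odds score over all positions of both strands
    (Wasserman & Sandelin-style PWM from a count matrix with a
    background-distributed pseudocount).

``trap``
    The biophysical TRAP occupancy: expected number of bound molecules,
    summed over all sites of both strands, with the published width
    dependent ``R0`` default and mismatch-energy scale ``lambda = 0.7``.

Both scorers scan the reverse strand by scoring the reverse-complemented
matrix on the forward sequence, which is algebraically identical to scanning
the reverse-complement sequence and makes all scores strand-symmetric.
Positions whose word contains an N are skipped; if every position of a
sequence is skipped the best-hit score falls back to the motif's minimum
achievable score so that the sequence ranks last, and the TRAP affinity of
such sites is zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: uniform background over A, C, G, T
UNIFORM_BACKGROUND = np.full(4, 0.25)
DEFAULT_PSEUDOCOUNT = 0.8

MONO_CLASSES = ("A|T", "G|C")
DINUC_CLASSES = (
    "AA|TT", "AC|GT", "AG|CT", "AT", "CA|TG",
    "CC|GG", "CG", "GA|TC", "GC", "TA",
)
RATE_NAMES = MONO_CLASSES + DINUC_CLASSES

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))


def _dinuc_class(d: str) -> str:
    rc = reverse_complement(d)
    if d == rc:
        return d
    canonical = min(d, rc)
    return f"{canonical}|{reverse_complement(canonical)}"


#: 16 dinucleotides -> index into DINUC_CLASSES
_DINUC_CLASS_INDEX = {
    a + b: DINUC_CLASSES.index(_dinuc_class(a + b)) for a in BASES for b in BASES
}


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to codes 0..3 (A,C,G,T) and 4 (N)."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.max(initial=0) == 255:
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"invalid nucleotide {bad!r} in sequence")
    return codes


@dataclass(frozen=True)
class MotifModel:
    """A named position count/frequency matrix and its derived PWM."""

    tf_name: str
    motif_id: str
    counts: np.ndarray  # (W, 4) over A, C, G, T

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id}: counts must be W x 4, W >= 1")
        if (counts < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative counts")
        if (counts.sum(axis=1) <= 0).any():
            raise ValueError(f"motif {self.motif_id}: zero-sum position")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return self.counts.shape[0]

    def pwm(
        self,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: np.ndarray = UNIFORM_BACKGROUND,
    ) -> np.ndarray:
        return pfm_to_pwm(self.counts, pseudocount, background)

    def frequencies(
        self,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        background: np.ndarray = UNIFORM_BACKGROUND,
    ) -> np.ndarray:
        """Pseudocount-corrected per-position base probabilities."""
        bg = np.asarray(background, dtype=float)
        totals = self.counts.sum(axis=1, keepdims=True)
        return (self.counts + pseudocount * bg) / (totals + pseudocount)

    def min_score(self, **kw) -> float:
        """Smallest achievable best-hit score (worst base at every position)."""
        return float(self.pwm(**kw).min(axis=1).sum())

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


def pfm_to_pwm(
    counts: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray = UNIFORM_BACKGROUND,
) -> np.ndarray:
    """Log2-odds PWM from a count matrix.

    Per cell: ``p = (count + pseudocount * bg_b) / (rowsum + pseudocount)``,
    then ``log2(p / bg_b)``.  Columns proportional to the background score
    exactly zero for any pseudocount.
    """
    counts = np.asarray(counts, dtype=float)
    bg = np.asarray(background, dtype=float)
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-8:
        raise ValueError("background must be a positive 4-vector summing to 1")
    totals = counts.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("count matrix has a zero-sum position")
    p = (counts + pseudocount * bg) / (totals + pseudocount)
    return np.log2(p / bg)


# ---------------------------------------------------------------------------
# JASPAR parsing

_JASPAR_ROW = re.compile(
    r"^\s*(?:(?P<base>[ACGTacgt])\s*)?\[?\s*(?P<nums>[-0-9.eE+\s]+?)\s*\]?\s*$"
)


def parse_jaspar_pfm(path) -> list:
    """Parse a JASPAR-format PFM text file into :class:`MotifModel` records.

    Accepts both the bracketed dialect (``A [ 3 5 ... ]``) and the bare
    matrix dialect (4 unlabeled rows in A, C, G, T order).  Counts may be
    integers or frequencies.
    """
    path = Path(path)
    text = path.read_text()
    records: list[MotifModel] = []
    header = None
    rows: list[tuple] = []

    def flush():
        nonlocal header, rows
        if header is None:
            return
        motif_id, tf_name = header
        if len(rows) != 4:
            raise ValueError(
                f"{path}: motif {motif_id!r} has {len(rows)} matrix rows, expected 4"
            )
        by_base: dict[str, list] = {}
        if all(base is not None for base, _ in rows):
            for base, nums in rows:
                if base in by_base:
                    raise ValueError(f"{path}: motif {motif_id!r} repeats row {base}")
                by_base[base] = nums
            ordered = [by_base[b] for b in BASES]
        else:
            ordered = [nums for _, nums in rows]
        widths = {len(r) for r in ordered}
        if len(widths) != 1:
            raise ValueError(
                f"{path}: motif {motif_id!r} has rows of unequal width {sorted(widths)}"
            )
        counts = np.array(ordered, dtype=float).T  # (W, 4)
        records.append(MotifModel(tf_name=tf_name, motif_id=motif_id, counts=counts))
        header, rows = None, []

    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            if not parts or not parts[0]:
                raise ValueError(f"{path}:{lineno}: empty motif header")
            motif_id = parts[0]
            tf_name = parts[1].strip() if len(parts) > 1 else motif_id
            header = (motif_id, tf_name)
            continue
        if header is None:
            raise ValueError(f"{path}:{lineno}: matrix row before any '>' header")
        m = _JASPAR_ROW.match(line)
        if m is None or not m.group("nums").strip():
            raise ValueError(f"{path}:{lineno}: unparseable matrix row {line!r}")
        base = m.group("base")
        nums = [float(x) for x in m.group("nums").split()]
        rows.append((base.upper() if base else None, nums))
    flush()
    if not records:
        raise ValueError(f"{path}: no motif records found")
    return records


def write_jaspar_pfm(motifs: Iterable[MotifModel], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.tf_name}\n")
            for bi, base in enumerate(BASES):
                vals = " ".join(f"{v:g}" for v in m.counts[:, bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Scanning

_N_SENTINEL = -1e9


def _extended(matrix: np.ndarray, n_value: float) -> np.ndarray:
    """Append a 5th column (code N) holding a sentinel value."""
    ext = np.empty((matrix.shape[0], 5))
    ext[:, :4] = matrix
    ext[:, 4] = n_value
    return ext


def _rc_matrix(matrix: np.ndarray) -> np.ndarray:
    # reverse positions, swap A<->T and C<->G: equivalent to scanning the
    # reverse-complement strand with the original matrix
    return matrix[::-1, ::-1]


def _position_sums(codes: np.ndarray, ext: np.ndarray) -> np.ndarray:
    """Per-position sums of ``ext[j, codes[:, i + j]]`` for a (n, L) batch."""
    n, L = codes.shape
    W = ext.shape[0]
    n_pos = L - W + 1
    acc = ext[0].take(codes[:, :n_pos])
    for j in range(1, W):
        acc = acc + ext[j].take(codes[:, j : j + n_pos])
    return acc


@njit(cache=True)
def _scan_best(codes, fwd, rev, fallback):  # pragma: no cover
    """Two-strand best-hit scan of a (n, L) code batch for one motif."""
    n, L = codes.shape
    W = fwd.shape[0]
    n_pos = L - W + 1
    out = np.empty(n)
    for i in range(n):
        best = -1e30
        for s in range(n_pos):
            acc_f = 0.0
            acc_r = 0.0
            for j in range(W):
                c = codes[i, s + j]
                acc_f += fwd[j, c]
                acc_r += rev[j, c]
            if acc_f > best:
                best = acc_f
            if acc_r > best:
                best = acc_r
        if best < -1e8:  # every position contained an N on both strands
            best = fallback
        out[i] = best
    return out


def best_hit_scores(sequences, motif: MotifModel, pseudocount=DEFAULT_PSEUDOCOUNT,
                    background=UNIFORM_BACKGROUND) -> np.ndarray:
    """Best-hit PWM scores of one motif on a batch of equal-length sequences."""
    if isinstance(sequences, str):
        sequences = [sequences]
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("batch scanning requires equal-length sequences")
    (L,) = lengths
    if L < motif.width:
        raise ValueError(
            f"sequence length {L} shorter than motif width {motif.width}"
        )
    codes = np.vstack([encode_sequence(s) for s in sequences])
    pwm = motif.pwm(pseudocount=pseudocount, background=background)
    fwd = _extended(pwm, _N_SENTINEL)
    rev = _extended(_rc_matrix(pwm), _N_SENTINEL)
    # all positions contain N on both strands -> minimum achievable score
    fallback = float(pwm.min(axis=1).sum())
    return _scan_best(np.ascontiguousarray(codes), fwd, rev, fallback)


def best_hit_score(sequence: str, motif: MotifModel, **kw) -> float:
    """Maximum PWM log-odds score over all positions of both strands."""
    return float(best_hit_scores([sequence], motif, **kw)[0])


@dataclass(frozen=True)
class TrapParams:
    """TRAP occupancy parameters.

    ``lambda_trap`` scales the mismatch energy; ``r0`` overrides the width
    dependent default ``R0(W) = exp(0.584 W - 5.66)``.
    """

    lambda_trap: float = 0.7
    r0: float | None = None

    def r0_for_width(self, width: int) -> float:
        if self.r0 is not None:
            return self.r0
        return float(np.exp(0.584 * width - 5.66))


def trap_affinities(sequences, motif: MotifModel, params: TrapParams = TrapParams(),
                    pseudocount=DEFAULT_PSEUDOCOUNT,
                    background=UNIFORM_BACKGROUND) -> np.ndarray:
    """TRAP expected occupancy summed over all sites of both strands.

    Per site ``i``: ``R0 e^{-E_i} / (1 + R0 e^{-E_i})`` with mismatch energy
    ``E_i = (1/lambda) sum_j ln(f_j(best) / f_j(b_ij))`` computed from the
    pseudocount-corrected base frequencies.  Sites containing N contribute 0.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError("batch scanning requires equal-length sequences")
    (L,) = lengths
    if L < motif.width:
        raise ValueError(
            f"sequence length {L} shorter than motif width {motif.width}"
        )
    codes = np.vstack([encode_sequence(s) for s in sequences])
    freqs = motif.frequencies(pseudocount=pseudocount, background=background)
    # energy contribution per position/base; best base contributes 0
    energy = np.log(freqs.max(axis=1, keepdims=True) / freqs) / params.lambda_trap
    r0 = params.r0_for_width(motif.width)
    total = np.zeros(codes.shape[0])
    for mat in (energy, _rc_matrix(energy)):
        e = _position_sums(codes, _extended(mat, -_N_SENTINEL))
        with np.errstate(over="ignore"):
            occ = 1.0 / (1.0 + np.exp(e) / r0)
        total += occ.sum(axis=1)
    return total


def trap_affinity(sequence: str, motif: MotifModel, params: TrapParams = TrapParams(),
                  **kw) -> float:
    return float(trap_affinities([sequence], motif, params, **kw)[0])


# ---------------------------------------------------------------------------
# Composition

def composition_rates(sequence: str) -> dict:
    """The 12 reverse-complement-collapsed (di)nucleotide rates.

    Counts are divided by the sequence length L (also for dinucleotides,
    of which there are only L - 1).  N is excluded from mononucleotide
    counts and dinucleotides containing N are skipped, while L keeps its
    full value.
    """
    if not sequence:
        raise ValueError("empty sequence")
    return {
        name: float(v)
        for name, v in composition_matrix([sequence]).iloc[0].items()
    }


def composition_matrix(sequences: Sequence[str]) -> pd.DataFrame:
    """Batch composition rates; one row per sequence, 12 columns."""
    rows = np.zeros((len(sequences), 12))
    for i, seq in enumerate(sequences):
        codes = encode_sequence(seq)
        L = len(seq)
        base_counts = np.bincount(codes, minlength=5)[:4]
        rows[i, 0] = (base_counts[0] + base_counts[3]) / L  # A|T
        rows[i, 1] = (base_counts[1] + base_counts[2]) / L  # G|C
        if L >= 2:
            a, b = codes[:-1], codes[1:]
            ok = (a < 4) & (b < 4)
            pair = a[ok].astype(np.int64) * 4 + b[ok]
            pair_counts = np.bincount(pair, minlength=16)
            for d, cls_idx in _DINUC_CLASS_INDEX.items():
                code = BASES.index(d[0]) * 4 + BASES.index(d[1])
                rows[i, 2 + cls_idx] += pair_counts[code] / L
    return pd.DataFrame(rows, columns=list(RATE_NAMES))


# ---------------------------------------------------------------------------
# Feature matrix assembly

def build_feature_matrix(
    windows,
    motifs: Sequence[MotifModel],
    scorer: str = "best_hit",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray = UNIFORM_BACKGROUND,
    trap_params: TrapParams = TrapParams(),
) -> pd.DataFrame:
    """Rows = windows, columns = one score per motif + the 12 rates.

    ``windows`` may be :class:`~tfcoop.io_formats.RegulatoryWindow` objects
    or a mapping ``{id: sequence}``.
    """
    if scorer not in ("best_hit", "trap"):
        raise ValueError(f"unknown scorer {scorer!r}")
    ids = [m.motif_id for m in motifs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate motif ids: {dupes}")
    if hasattr(windows, "items"):
        seq_ids, sequences = zip(*windows.items()) if windows else ((), ())
    else:
        seq_ids = [w.id for w in windows]
        sequences = [w.sequence for w in windows]
    if len(set(seq_ids)) != len(seq_ids):
        raise ValueError("duplicate window ids in feature matrix")
    sequences = list(sequences)
    cols = {}
    for m in motifs:
        if scorer == "best_hit":
            cols[m.motif_id] = best_hit_scores(
                sequences, m, pseudocount=pseudocount, background=background
            )
        else:
            cols[m.motif_id] = trap_affinities(
                sequences, m, trap_params,
                pseudocount=pseudocount, background=background,
            )
    X = pd.DataFrame(cols, index=list(seq_ids))
    comp = composition_matrix(sequences)
    comp.index = X.index
    X = pd.concat([X, comp], axis=1)
    X.attrs["scorer"] = scorer
    return X


def save_feature_matrix(X: pd.DataFrame, path) -> None:
    X.to_csv(path, sep="\t", index_label="id")


def load_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
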
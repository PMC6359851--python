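"""Synthetic cooperative-binding experiments with known ground truth.

The generator emulates the data structure the binding model assumes: a set
of fixed-width regulatory windows drawn from a first-order Markov
background (so dinucleotide composition is non-trivial), with binding
motifs planted for a target TF, its cooperating/competing partners and a
crowd of decoy motifs.  The Boolean binding label of each window is drawn
from a logistic function of the planted-site indicators, with positive
strengths for cooperative partners and negative strengths for competitive
ones; decoy plantings are independent of the label.  ChIP-seq-like peaks
(200 bp, centered in positive windows), an expression table linking
positives to higher expression, and a truth table recording every planted
site are emitted so downstream modules can be exercised end to end on
standard FASTA/BED/TSV files.

Default regime (chosen once as a clearly detectable cooperation signal
with realistic problem sizes): 2000 windows of 1000 bp, per-motif planting
probability 0.5, logistic strengths +4 for cooperative partners and the
target, -4 for competitive partners, and an intercept centering the
positive rate slightly below one half so that balanced negative sampling
always has enough candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import BASES, MotifModel, RATE_NAMES
from .io_formats import Interval, RegulatoryWindow, write_bed, write_fasta

_GAP = 100          # background bp between consecutive windows on the genome
_PEAK_WIDTH = 200


@dataclass(frozen=True)
class PartnerSet:
    motif_ids: tuple
    mode: str                  # "cooperative" or "competitive"
    strength: float

    def __post_init__(self):
        if self.mode not in ("cooperative", "competitive"):
            raise ValueError(f"unknown partner mode {self.mode!r}")
        if not np.isfinite(self.strength):
            raise ValueError("strength must be finite")

    @property
    def signed_strength(self) -> float:
        s = abs(self.strength)
        return s if self.mode == "cooperative" else -s


@dataclass
class CooperationSpec:
    """Ground-truth description of a simulated binding experiment."""

    motifs: list                      # full MotifModel library (incl. decoys)
    target_motif: str
    partners: list                    # list of PartnerSet
    n_sequences: int = 2000
    window_width: int = 1000
    plant_prob: float = 0.5
    decoy_plant_prob: float = 0.5
    target_strength: float = 4.0
    intercept: float | None = None    # None -> centered with a -0.6 shift
    background_rates: dict | None = None
    expression_pos: tuple = (1.5, 0.8)    # lognormal (mu, sigma) of positives
    expression_neg: tuple = (0.8, 1.0)
    expression_neg_zero_frac: float = 0.3

    def __post_init__(self):
        ids = [m.motif_id for m in self.motifs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate motif ids in library")
        known = set(ids)
        if self.target_motif not in known:
            raise ValueError(f"target motif {self.target_motif!r} not in library")
        for ps in self.partners:
            for mid in ps.motif_ids:
                if mid not in known:
                    raise ValueError(f"partner motif {mid!r} not in library")
        widths = [m.width for m in self.motifs]
        if max(widths) > self.window_width:
            raise ValueError(
                f"motif wider ({max(widths)}) than window ({self.window_width})"
            )
        if not (0 <= self.plant_prob < 1) or not (0 <= self.decoy_plant_prob < 1):
            raise ValueError("planting probabilities must be in [0, 1)")

    @property
    def informative_strengths(self) -> dict:
        """motif id -> signed logistic strength (target + partners)."""
        out = {self.target_motif: float(self.target_strength)}
        for ps in self.partners:
            for mid in ps.motif_ids:
                out[mid] = ps.signed_strength
        return out

    def effective_intercept(self) -> float:
        if self.intercept is not None:
            return float(self.intercept)
        mean_eta = self.plant_prob * sum(self.informative_strengths.values())
        return -mean_eta - 0.6


# ---------------------------------------------------------------------------
# Background model

def _human_like_transition():
    """A CpG-depleted first-order chain as the default background."""
    base = np.array([0.26, 0.24, 0.24, 0.26])
    joint = np.outer(base, base)
    joint[1, 2] *= 0.25         # deplete CpG
    joint /= joint.sum()
    trans = joint / joint.sum(axis=1, keepdims=True)
    return trans


def _stationary(trans: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(trans.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _collapsed_rates_of_chain(trans: np.ndarray) -> dict:
    """Stationary 12-class composition of a first-order chain."""
    from .features import _DINUC_CLASS_INDEX, DINUC_CLASSES
    pi = _stationary(trans)
    joint = pi[:, None] * trans
    out = dict.fromkeys(RATE_NAMES, 0.0)
    out["A|T"] = float(pi[0] + pi[3])
    out["G|C"] = float(pi[1] + pi[2])
    for a in range(4):
        for b in range(4):
            cls = DINUC_CLASSES[_DINUC_CLASS_INDEX[BASES[a] + BASES[b]]]
            out[cls] += float(joint[a, b])
    return out


def _transition_from_rates(rates: dict) -> np.ndarray:
    """First-order chain whose dinucleotide mass approximates a 12-class
    request (non-self-complementary classes split equally between the two
    orientations)."""
    from .features import _DINUC_CLASS_INDEX, DINUC_CLASSES
    members: dict = {}
    for a in BASES:
        for b in BASES:
            cls = DINUC_CLASSES[_DINUC_CLASS_INDEX[a + b]]
            members.setdefault(cls, []).append(a + b)
    joint = np.zeros((4, 4))
    for cls, dinucs in members.items():
        if cls not in rates:
            raise ValueError(f"missing dinucleotide class {cls!r}")
        share = float(rates[cls]) / len(dinucs)
        for d in dinucs:
            joint[BASES.index(d[0]), BASES.index(d[1])] = share
    total = joint.sum()
    if total <= 0:
        raise ValueError("dinucleotide rates sum to zero")
    joint /= total
    return joint / joint.sum(axis=1, keepdims=True)


#: the generator's default background composition (stationary rates of the
#: default CpG-depleted chain; consistent by construction)
DEFAULT_BACKGROUND_RATES = _collapsed_rates_of_chain(_human_like_transition())


def generate_background(n: int, L: int, rates: dict | None = None,
                        seed: int = 0) -> list:
    """``n`` sequences of length ``L`` from a first-order Markov chain whose
    stationary collapsed dinucleotide rates approximate ``rates``."""
    trans = (_human_like_transition() if rates is None
             else _transition_from_rates(rates))
    pi = _stationary(trans)
    rng = np.random.default_rng(seed)
    codes = np.empty((n, L), dtype=np.int8)
    cum0 = np.cumsum(pi)
    codes[:, 0] = np.searchsorted(cum0, rng.random(n))
    cum = np.cumsum(trans, axis=1)
    for j in range(1, L):
        u = rng.random(n)
        prev = codes[:, j - 1]
        codes[:, j] = (u[:, None] > cum[prev]).sum(axis=1)
    lut = np.array(list(BASES))
    return ["".join(row) for row in lut[codes]]


# ---------------------------------------------------------------------------
# Site planting

def sample_motif_word(motif: MotifModel, rng) -> str:
    """Draw a word from the PFM's per-column base distributions."""
    p = motif.counts / motif.counts.sum(axis=1, keepdims=True)
    return "".join(BASES[rng.choice(4, p=p[j])] for j in range(motif.width))


def plant_sites(sequences: list, motif: MotifModel, plant: np.ndarray,
                rng, occupied: list | None = None, max_tries: int = 50):
    """Plant one sampled motif word per flagged sequence.

    ``plant`` is a Boolean per-sequence indicator.  The insertion position
    is uniform; the strand is chosen uniformly (minus-strand plants insert
    the reverse complement).  When an ``occupied`` mask list is given,
    positions overlapping previous plants are rejected (up to
    ``max_tries``; failures clear the plant flag).  Returns the new
    sequences, the realized plant indicator and a per-sequence
    (position, strand) record.
    """
    from .features import reverse_complement

    W = motif.width
    out = list(sequences)
    realized = np.asarray(plant, dtype=bool).copy()
    records: list = [None] * len(sequences)
    flagged = np.flatnonzero(realized)
    # draw all words/strands for the flagged sequences up front (vectorized)
    p = motif.counts / motif.counts.sum(axis=1, keepdims=True)
    cum = p.cumsum(axis=1)
    word_codes = (rng.random((len(flagged), W, 1)) > cum[None, :, :]).sum(axis=2)
    minus = rng.random(len(flagged)) < 0.5
    for w_i, i in enumerate(flagged):
        L = len(out[i])
        pos = -1
        for _try in range(max_tries):
            cand = int(rng.integers(0, L - W + 1))
            if occupied is None or not occupied[i][cand:cand + W].any():
                pos = cand
                break
        if pos < 0:
            realized[i] = False
            continue
        word = "".join(BASES[c] for c in word_codes[w_i])
        strand = "-" if minus[w_i] else "+"
        if strand == "-":
            word = reverse_complement(word)
        out[i] = out[i][:pos] + word + out[i][pos + W:]
        if occupied is not None:
            occupied[i][pos:pos + W] = True
        records[i] = (pos, strand)
    return out, realized, records


# ---------------------------------------------------------------------------
# Full experiment

@dataclass
class SimulatedExperiment:
    genome: dict
    windows: list
    peaks: list
    labels: np.ndarray
    expression: dict
    truth: pd.DataFrame
    spec: CooperationSpec
    seed: int

    @property
    def window_ids(self) -> list:
        return [w.id for w in self.windows]

    def bound_ids(self, motif_id: str) -> set:
        """Windows in which a given motif was actually planted."""
        t = self.truth
        return set(t.loc[(t["motif_id"] == motif_id) & t["planted"], "window"])

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        write_bed([w.interval for w in self.windows], out / "windows.bed")
        write_bed(self.peaks, out / "peaks.bed")
        from .dataset import write_expression_table
        write_expression_table(self.expression, out / "expression.tsv",
                               cell_type="simulated")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def simulate_experiment(spec: CooperationSpec, seed: int = 0
                        ) -> SimulatedExperiment:
    """Generate windows, labels, peaks, expression and the truth table."""
    rng = np.random.default_rng(seed)
    n, L = spec.n_sequences, spec.window_width

    def wid(i):
        # seed-tagged ids so sequences from different simulated experiments
        # never collide in a transfer evaluation's CV cache
        return f"sim{seed}-w{i:05d}"

    sequences = generate_background(
        n, L, spec.background_rates,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    occupied = [np.zeros(L, dtype=bool) for _ in range(n)]
    strengths = spec.informative_strengths
    informative_ids = list(strengths)
    decoy_ids = [m.motif_id for m in spec.motifs
                 if m.motif_id not in strengths]
    by_id = {m.motif_id: m for m in spec.motifs}

    truth_rows = []
    planted: dict = {}
    # informative motifs first so their sites are never overwritten
    for mid in informative_ids + decoy_ids:
        prob = spec.plant_prob if mid in strengths else spec.decoy_plant_prob
        flags = rng.random(n) < prob
        sequences, realized, records = plant_sites(
            sequences, by_id[mid], flags, rng, occupied=occupied)
        planted[mid] = realized
        role = ("target" if mid == spec.target_motif
                else ("cooperative" if strengths.get(mid, 0) > 0 else
                      "competitive") if mid in strengths else "decoy")
        for i in range(n):
            if realized[i]:
                pos, strand = records[i]
                truth_rows.append({
                    "window": wid(i), "motif_id": mid, "planted": True,
                    "position": pos, "strand": strand, "role": role,
                    "strength": strengths.get(mid, 0.0),
                })

    eta = np.full(n, spec.effective_intercept())
    for mid, s in strengths.items():
        eta += s * planted[mid].astype(float)
    labels = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

    # lay the windows on a synthetic chromosome separated by background gaps
    gaps = generate_background(
        n + 1, _GAP, spec.background_rates,
        seed=int(rng.integers(0, 2**31 - 1)))
    chrom_parts, windows, peaks = [], [], []
    cursor = 0
    for i, seq in enumerate(sequences):
        chrom_parts.append(gaps[i])
        cursor += _GAP
        iv = Interval("chrSim", cursor, cursor + L, wid(i), ".")
        windows.append(RegulatoryWindow(interval=iv, sequence=seq,
                                        role="mRNA_promoter",
                                        anchor=cursor + L // 2))
        if labels[i]:
            mid_pos = cursor + L // 2
            peaks.append(Interval("chrSim", mid_pos - _PEAK_WIDTH // 2,
                                  mid_pos + _PEAK_WIDTH // 2,
                                  f"peak-{wid(i)}", "."))
        cursor += L
        chrom_parts.append(seq)
    chrom_parts.append(gaps[n])
    genome = {"chrSim": "".join(chrom_parts)}

    mu_p, sg_p = spec.expression_pos
    mu_n, sg_n = spec.expression_neg
    expr = np.where(labels,
                    rng.lognormal(mu_p, sg_p, size=n),
                    rng.lognormal(mu_n, sg_n, size=n))
    zero = (~labels) & (rng.random(n) < spec.expression_neg_zero_frac)
    expr[zero] = 0.0
    expression = {wid(i): float(expr[i]) for i in range(n)}

    truth = pd.DataFrame(
        truth_rows,
        columns=["window", "motif_id", "planted", "position", "strand",
                 "role", "strength"],
    )
    return SimulatedExperiment(genome=genome, windows=windows, peaks=peaks,
                               labels=labels, expression=expression,
                               truth=truth, spec=spec, seed=seed)


# ---------------------------------------------------------------------------
# Motif library generation

def random_motif_library(n_motifs: int, width_range=(10, 14), seed: int = 0,
                         dominance: float = 0.95, total: int = 100) -> list:
    """Random sharp PFMs (one dominant base per column) for simulations."""
    rng = np.random.default_rng(seed)
    motifs = []
    minor = (1.0 - dominance) / 3.0
    for i in range(n_motifs):
        W = int(rng.integers(width_range[0], width_range[1] + 1))
        counts = np.zeros((W, 4))
        for j in range(W):
            dom = int(rng.integers(0, 4))
            p = np.full(4, minor)
            p[dom] = dominance
            counts[j] = np.round(p * total)
        motifs.append(MotifModel(tf_name=f"TF{i:03d}", motif_id=f"M{i:03d}",
                                 counts=counts))
    return motifs


def default_cooperation_spec(n_decoys: int = 50, n_cooperative: int = 3,
                             n_competitive: int = 1, seed: int = 0,
                             strength: float = 4.0, **kw) -> CooperationSpec:
    """The standard simulated study: a target TF with a few true partners
    hidden among decoy motifs."""
    n_motifs = 1 + n_cooperative + n_competitive + n_decoys
    motifs = random_motif_library(n_motifs, seed=seed)
    target = motifs[0].motif_id
    coop = tuple(m.motif_id for m in motifs[1:1 + n_cooperative])
    comp = tuple(m.motif_id for m in
                 motifs[1 + n_cooperative:1 + n_cooperative + n_competitive])
    partners = []
    if coop:
        partners.append(PartnerSet(coop, "cooperative", strength))
    if comp:
        partners.append(PartnerSet(comp, "competitive", strength))
    return CooperationSpec(motifs=motifs, target_motif=target,
                           partners=partners, target_strength=strength, **kw)
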
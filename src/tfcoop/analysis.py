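"""Interpretation of fitted binding models.

Selected motifs are read as the cooperating (positive coefficient) or
competing (negative coefficient) partners of the target TF.  This module
validates and characterizes those selections:

* Jaccard co-binding support: if TF B's motif is selected in TF A's model,
  the ChIP-bound sequence sets of A and B should intersect more than for
  non-selected TFs.
* Target-PWM inclusion: whether the model retained the target motif itself
  or a score-correlated surrogate (Pearson r >= 0.75 by default).
* Motif-composition similarity between the target PWM and the mean
  composition of its selected partners.
* k-means clustering of models by their Boolean selection vectors.
* Enrichment tests (hypergeometric / chi-square / Fisher) for differential
  variable selection and for annotation terms in sequence clusters.
* A KNN classifier discriminating promoters from enhancers under different
  sequence descriptions, and the Gini ubiquity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import train_test_split

from .features import BASES, DINUC_CLASSES, RATE_NAMES, MotifModel

TIER_ORDER = ("min", "1se", "3se")


def jaccard_index(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; two empty sets give 0 by convention."""
    set_a, set_b = set(set_a), set(set_b)
    union = set_a | set_b
    if not union:
        return 0.0
    return len(set_a & set_b) / len(union)


@dataclass
class CooperationReport:
    """Per-pair Jaccard indexes grouped by selection tier."""

    pairs: pd.DataFrame          # target, partner, jaccard, tier
    medians: dict                # tier -> median jaccard
    counts: dict                 # tier -> number of pairs
    p_value: float               # one-sided Welch t (selected > unselected)


def cooperation_support(models: dict, peak_sets: dict, motif_to_tf: dict,
                        ) -> CooperationReport:
    """Jaccard co-binding validation of inferred cooperations.

    ``models`` maps target TF name -> fitted model; ``peak_sets`` maps TF
    name -> set of bound sequence ids; ``motif_to_tf`` maps motif ids to TF
    names.  Pairs with B == A are excluded.  Each pair row carries the most
    stringent tier in which any of B's motifs is selected, or
    ``unselected``; the reported medians/counts use cumulative cutoffs
    (the ``min`` group is every selected pair, ``3se`` only the
    highest-confidence ones: S_3se ⊆ S_1se ⊆ S_min).
    """
    rows = []
    for target_tf, model in models.items():
        if target_tf not in peak_sets:
            continue
        bound_a = peak_sets[target_tf]
        tf_tier: dict = {}
        for tier in ("min", "1se", "3se"):  # later (stricter) wins
            for motif_id in model.selected[tier]:
                tf = motif_to_tf.get(motif_id)
                if tf is not None:
                    tf_tier[tf] = tier
        for partner_tf, bound_b in peak_sets.items():
            if partner_tf == target_tf:
                continue
            tier = tf_tier.get(partner_tf, "unselected")
            rows.append({
                "target": target_tf,
                "partner": partner_tf,
                "jaccard": jaccard_index(bound_a, bound_b),
                "tier": tier,
            })
    pairs = pd.DataFrame(rows)
    # cumulative cutoffs: S_3se <= S_1se <= S_min
    cumulative = {"min": ("min", "1se", "3se"), "1se": ("1se", "3se"),
                  "3se": ("3se",), "unselected": ("unselected",)}
    medians, counts = {}, {}
    for tier, members in cumulative.items():
        sub = pairs.loc[pairs["tier"].isin(members), "jaccard"]
        counts[tier] = int(len(sub))
        medians[tier] = float(sub.median()) if len(sub) else float("nan")
    sel = pairs.loc[pairs["tier"] != "unselected", "jaccard"]
    unsel = pairs.loc[pairs["tier"] == "unselected", "jaccard"]
    if len(sel) > 1 and len(unsel) > 1:
        p = float(stats.ttest_ind(sel, unsel, equal_var=False,
                                  alternative="greater").pvalue)
    else:
        p = float("nan")
    return CooperationReport(pairs=pairs, medians=medians, counts=counts,
                             p_value=p)


def target_pwm_inclusion(model, target_motif_id: str,
                         score_matrix: pd.DataFrame,
                         tier: str = "min",
                         similarity_threshold: float = 0.75) -> str:
    """Did the model keep the target PWM, or a similar one?

    Similarity between two PWMs is the Pearson correlation of their score
    columns over the same sequences.  Returns one of ``target_selected``,
    ``similar_selected``, ``neither``.
    """
    selected = [f for f in model.selected[tier] if f in score_matrix.columns]
    if target_motif_id in selected:
        return "target_selected"
    if target_motif_id not in score_matrix.columns:
        raise ValueError(f"target motif {target_motif_id!r} not in score matrix")
    target_scores = score_matrix[target_motif_id].to_numpy(dtype=float)
    for motif_id in selected:
        other = score_matrix[motif_id].to_numpy(dtype=float)
        if other.std() == 0 or target_scores.std() == 0:
            continue
        r = float(np.corrcoef(target_scores, other)[0, 1])
        if r >= similarity_threshold:
            return "similar_selected"
    return "neither"


def motif_composition(motif: MotifModel) -> pd.Series:
    """Expected 12-class (di)nucleotide composition of a motif.

    Mononucleotide class rates average per-column PFM probabilities;
    dinucleotide class rates come from products of adjacent independent
    columns, divided by the motif width (mirroring the per-sequence rates,
    whose denominator is the sequence length).
    """
    p = motif.counts / motif.counts.sum(axis=1, keepdims=True)
    W = motif.width
    out = dict.fromkeys(RATE_NAMES, 0.0)
    out["A|T"] = float((p[:, 0] + p[:, 3]).sum() / W)
    out["G|C"] = float((p[:, 1] + p[:, 2]).sum() / W)
    from .features import _DINUC_CLASS_INDEX
    for j in range(W - 1):
        for a in range(4):
            for b in range(4):
                cls = DINUC_CLASSES[_DINUC_CLASS_INDEX[BASES[a] + BASES[b]]]
                out[cls] += float(p[j, a] * p[j + 1, b]) / W
    return pd.Series(out)


def composition_correlation(target_motif: MotifModel, selected,
                            library, seed: int = 0) -> dict:
    """Correlation between target-PWM composition and its partners'.

    ``selected`` is an iterable of ``(MotifModel, coefficient_sign)``;
    ``library`` is the full motif list from which a size-matched random
    control group is drawn (seeded).  Returns Pearson r for the positive
    group, the negative group and the random control (NaN when a group is
    empty).
    """
    target = motif_composition(target_motif).to_numpy()

    def group_r(motifs):
        if not motifs:
            return float("nan")
        mean_comp = np.mean([motif_composition(m).to_numpy() for m in motifs],
                            axis=0)
        if target.std() == 0 or mean_comp.std() == 0:
            return float("nan")
        return float(np.corrcoef(target, mean_comp)[0, 1])

    pos = [m for m, s in selected if s > 0]
    neg = [m for m, s in selected if s < 0]
    rng = np.random.default_rng(seed)
    k = max(len(pos) + len(neg), 1)
    control = [library[i] for i in
               rng.choice(len(library), size=min(k, len(library)),
                          replace=False)]
    return {
        "r_positive": group_r(pos),
        "r_negative": group_r(neg),
        "r_control": group_r(control),
    }


def selection_matrix(models: dict, tier: str = "min") -> pd.DataFrame:
    """Models x features Boolean matrix of selected variables."""
    all_features = sorted({f for m in models.values() for f in m.feature_names})
    rows = {}
    for name, m in models.items():
        sel = set(m.selected[tier])
        rows[name] = [f in sel for f in all_features]
    return pd.DataFrame.from_dict(rows, orient="index", columns=all_features)


def cluster_models(S: pd.DataFrame, k_values, restarts: int = 200,
                   seed: int = 0) -> tuple:
    """Best-of-``restarts`` k-means on Boolean selection (or score) rows.

    Returns ``(labels, dispersion)``: per-k cluster labels and the
    within-cluster sum of squares curve used for the elbow heuristic.
    """
    X = S.to_numpy(dtype=float)
    labels, dispersion = {}, {}
    for k in k_values:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        fit = km.fit(X)
        labels[k] = pd.Series(fit.labels_, index=S.index)
        dispersion[k] = float(fit.inertia_)
    return labels, dispersion


def differential_selection_test(count1: int, n1: int, count2: int, n2: int,
                                method: str = "hypergeometric") -> float:
    """Is a variable selected more often in group 1 than group 2?

    ``hypergeometric``: upper-tail probability of observing >= count1
    selections in group 1 when count1+count2 selections are distributed at
    random over n1+n2 models.  ``chi2``: chi-square test on the 2x2 table.
    ``fisher``: two-sided Fisher exact test on the same table.
    """
    for label, c, n in (("group1", count1, n1), ("group2", count2, n2)):
        if not (0 <= c <= n):
            raise ValueError(f"{label}: count {c} outside [0, {n}]")
    table = np.array([[count1, n1 - count1], [count2, n2 - count2]])
    if method == "hypergeometric":
        return float(stats.hypergeom.sf(count1 - 1, n1 + n2,
                                        count1 + count2, n1))
    if method == "chi2":
        if table.sum() == 0:
            raise ValueError("empty table")
        return float(stats.chi2_contingency(table)[1])
    if method == "fisher":
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown method {method!r}")


def cluster_enrichment(clusters: dict, annotation_sets: dict,
                       alternative: str = "greater") -> tuple:
    """Fisher exact enrichment of annotation terms within clusters.

    ``clusters`` maps sequence id -> cluster label; ``annotation_sets``
    maps term -> set of annotated ids.  Returns the full per-(cluster,
    term) table (raw p plus Benjamini-Hochberg q) and, per term, the best
    p-value over clusters.
    """
    ids = set(clusters)
    cluster_ids: dict = {}
    for sid, c in clusters.items():
        cluster_ids.setdefault(c, set()).add(sid)
    rows = []
    for term, annotated in annotation_sets.items():
        annotated = annotated & ids
        for c, members in cluster_ids.items():
            a = len(members & annotated)
            b = len(members) - a
            c_out = len(annotated) - a
            d = len(ids) - len(members) - c_out
            p = float(stats.fisher_exact([[a, b], [c_out, d]],
                                         alternative=alternative)[1])
            rows.append({"cluster": c, "term": term, "in_cluster_annotated": a,
                         "p_value": p})
    table = pd.DataFrame(rows)
    # Benjamini-Hochberg within the whole family
    p = table["p_value"].to_numpy()
    order = np.argsort(p)
    q = np.empty_like(p)
    m = len(p)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * m / (rank_idx + 1))
        q[i] = prev
    table["q_value"] = q
    best = table.groupby("term")["p_value"].min().to_dict()
    return table, best


def knn_region_classifier(scores_promoters: pd.DataFrame,
                          scores_enhancers: pd.DataFrame,
                          k_values=range(1, 21), split_seed: int = 0,
                          test_fraction: float = 0.3) -> pd.Series:
    """Promoter-vs-enhancer KNN test error per neighbor count.

    Columns are z-scored on the training split; distance is Euclidean.
    Accepts any sequence description (model scores, raw motif scores or
    composition rates) so the descriptions can be compared.
    """
    common = [c for c in scores_promoters.columns
              if c in scores_enhancers.columns]
    if not common:
        raise ValueError("no common feature columns")
    X = np.vstack([scores_promoters[common].to_numpy(dtype=float),
                   scores_enhancers[common].to_numpy(dtype=float)])
    y = np.concatenate([np.zeros(len(scores_promoters), dtype=int),
                        np.ones(len(scores_enhancers), dtype=int)])
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=split_seed)
    mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    X_tr = (X_tr - mu) / sd
    X_te = (X_te - mu) / sd
    errors = {}
    for k in k_values:
        knn = KNeighborsClassifier(n_neighbors=k).fit(X_tr, y_tr)
        errors[k] = float(np.mean(knn.predict(X_te) != y_te))
    return pd.Series(errors, name="test_error")


def gini_coefficient(values) -> float:
    """Mean-difference Gini index of a non-negative vector.

    0 for a constant positive vector (a gene expressed equally in all
    samples); approaches 1 as the mass concentrates in one sample.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("expected a non-empty 1-D vector")
    if (x < 0).any():
        raise ValueError("negative values")
    if x.sum() == 0:
        return 0.0
    n = len(x)
    xs = np.sort(x)
    # G = sum_i sum_j |x_i - x_j| / (2 n^2 mean)
    cum = np.cumsum(xs)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)
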
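"""Benchmark splits, metrics, baselines and embedding-space analyses.

Three leakage-controlled evaluation schemes:

* unseen sequence — hold out whole chromosomes, so no overlapping window can
  leak between train and validation;
* unseen cell type — hold out diagonal (sequence-fold, cell-set) pairs so
  every cell type still appears in training on other sequence folds;
* unseen track — hold out entire (cell, feature) tracks that remain
  predictable from the rest of the measurement graph.

Metrics are average precision for peak classification and r^2 for signal
regression; the per-locus baseline scores a held-out (locus, cell) pair by
the mean target of that locus across training cells — an "average cell
type's" profile that any cell-aware model must beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class SplitSpec:
    scheme: str
    train_chroms: list = field(default_factory=list)
    val_chroms: list = field(default_factory=list)
    eval_chroms: list = field(default_factory=list)
    k_folds: int | None = None
    chrom_folds: list = field(default_factory=list)
    cell_folds: list = field(default_factory=list)
    holdout_tracks: list = field(default_factory=list)
    seed: int = 0


def _drop_chry(chromosomes: list) -> list:
    return [c for c in chromosomes if c.lower() not in ("chry", "y")]


def split_unseen_sequence(chromosomes: list, seed: int = 0) -> SplitSpec:
    """2 validation + 2 evaluation chromosomes, rest train; chrY excluded."""
    chroms = _drop_chry(list(chromosomes))
    if len(chroms) < 5:
        raise ValueError("need at least 5 non-Y chromosomes")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(chroms), size=4, replace=False)
    val = [chroms[i] for i in picks[:2]]
    evl = [chroms[i] for i in picks[2:]]
    train = [c for c in chroms if c not in val and c not in evl]
    return SplitSpec("unseen_sequence", train, val, evl, seed=seed)


def split_unseen_celltype(
    chromosomes: list, cells: list, k: int, seed: int = 0
) -> SplitSpec:
    """Diagonal (sequence-fold, cell-set) holdout with k folds (3, 5 or 10)."""
    if k not in (3, 5, 10):
        raise ValueError("k must be 3, 5 or 10")
    if len(cells) < k:
        raise ValueError("need at least k cells")
    chroms = _drop_chry(list(chromosomes))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chroms))
    evl = [chroms[i] for i in order[:2]]
    usable = [chroms[i] for i in order[2:]]
    if len(usable) < k:
        raise ValueError(f"k={k} exceeds the {len(usable)} usable chromosomes")
    chrom_folds = [list(usable[i::k]) for i in range(k)]
    cell_order = rng.permutation(len(cells))
    cell_folds = [[cells[j] for j in cell_order[i::k]] for i in range(k)]
    return SplitSpec(
        "unseen_celltype",
        train_chroms=usable,
        eval_chroms=evl,
        k_folds=k,
        chrom_folds=chrom_folds,
        cell_folds=cell_folds,
        seed=seed,
    )


def validation_pairs(spec: SplitSpec) -> list:
    """The k held-out (sequence-fold index, cell-set index) diagonal pairs."""
    return [(i, i) for i in range(spec.k_folds)]


def average_precision(scores, labels) -> float:
    """Area under the precision-recall step curve.

    Mean over positives, taken in descending score order (stable for ties),
    of precision at each positive's rank.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("average precision undefined without positive labels")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    ranks = np.arange(1, len(ranked) + 1)
    cum_pos = np.cumsum(ranked)
    precision_at_pos = cum_pos[ranked == 1] / ranks[ranked == 1]
    return float(precision_at_pos.sum() / n_pos)


def r_squared(preds, targets) -> float:
    """1 - SS_res / SS_tot."""
    preds = np.asarray(preds, float)
    targets = np.asarray(targets, float)
    if targets.size < 2:
        raise ValueError("r_squared needs at least 2 targets")
    ss_tot = float(((targets - targets.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("r_squared undefined for zero target variance")
    ss_res = float(((targets - preds) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def per_locus_baseline(train_targets_by_locus: dict) -> dict:
    """Mean training target per (locus, feature), constant across held-out cells.

    `train_targets_by_locus` maps locus id -> (targets, mask) over training
    cells; the returned dict maps locus id -> per-feature baseline scores.
    """
    out = {}
    for locus, (targets, mask) in train_targets_by_locus.items():
        targets = np.asarray(targets, float)
        mask = np.asarray(mask, bool)
        counts = mask.sum(axis=0)
        if (counts == 0).all():
            raise ValueError(f"locus {locus} has no training cells")
        filled = np.where(mask, targets, 0.0)
        with np.errstate(invalid="ignore"):
            out[locus] = np.where(counts > 0, filled.sum(axis=0) / np.maximum(counts, 1), np.nan)
    return out


def quant_to_qual(pred_signal: np.ndarray, neglog_threshold: float = 4.4) -> np.ndarray:
    """Peak labels from predicted quantitative signal, via the same peak
    geometry used for experimental tracks."""
    from .tracks import SignalTrack, call_peaks

    track = SignalTrack("pred", np.asarray(pred_signal, float))
    labels = np.zeros(len(track.values), dtype=int)
    for p in call_peaks(track, neglog_threshold):
        labels[p.start : p.end] = 1
    return labels


def compare_to_baseline(model_ap, baseline_ap) -> float:
    """One-sided Wilcoxon signed-rank p-value for model > baseline, paired per track."""
    model_ap = np.asarray(model_ap, float)
    baseline_ap = np.asarray(baseline_ap, float)
    if model_ap.shape != baseline_ap.shape or model_ap.size < 5:
        raise ValueError("need paired per-track vectors with >= 5 tracks")
    diffs = model_ap - baseline_ap
    if np.all(diffs == 0):
        raise ValueError("all per-track differences are zero")
    return float(stats.wilcoxon(model_ap, baseline_ap, alternative="greater").pvalue)


def narrow_vs_broad(ap_by_feature: dict, category_of: dict) -> float:
    """Two-sample Mann-Whitney U p-value, narrow vs broad feature AP.

    Features categorized 'exception' or 'unknown' are excluded.
    """
    narrow = [ap for f, ap in ap_by_feature.items() if category_of.get(f) == "narrow"]
    broad = [ap for f, ap in ap_by_feature.items() if category_of.get(f) == "broad"]
    if not narrow or not broad:
        raise ValueError("both narrow and broad categories must be non-empty")
    return float(stats.mannwhitneyu(narrow, broad, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# embedding-space analyses


def _cosine_matrix(embeddings: np.ndarray) -> np.ndarray:
    e = np.asarray(embeddings, float)
    norms = np.linalg.norm(e, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    u = e / norms
    return u @ u.T


def _within_tissue_mean(cos: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    if not same.any():
        raise ValueError("no within-tissue pair")
    return float(cos[iu][same].mean())


def tissue_cosine_test(
    embeddings: np.ndarray,
    tissue_of: dict | list,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple:
    """Within-tissue mean cosine similarity vs a label-permutation null.

    Returns (observed, null mean, null sd, p) with add-one smoothing of the
    permutation p-value.
    """
    embeddings = np.asarray(embeddings, float)
    if isinstance(tissue_of, dict):
        labels = np.asarray([tissue_of[i] for i in range(len(embeddings))])
    else:
        labels = np.asarray(tissue_of)
    uniq, counts = np.unique(labels, return_counts=True)
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 tissues with >= 2 cells each")
    cos = _cosine_matrix(embeddings)
    observed = _within_tissue_mean(cos, labels)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _within_tissue_mean(cos, rng.permutation(labels))
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return observed, float(null.mean()), float(null.std()), float(p)


def _nearest_neighbors(embeddings: np.ndarray) -> np.ndarray:
    """Nearest neighbour per cell by cosine distance, ties to the lower index."""
    cos = _cosine_matrix(embeddings)
    np.fill_diagonal(cos, -np.inf)
    return np.argmax(cos, axis=1)  # argmax takes the first (lowest) index on ties


def indirect_clustering_count(
    embeddings: np.ndarray,
    tissue_of,
    m,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple:
    """Cells whose nearest embedding neighbour shares the tissue label while
    sharing zero measured features — clustering from indirect information.

    Returns (count, permutation-expected count, permutation sd).
    """
    embeddings = np.asarray(embeddings, float)
    n = len(embeddings)
    if n < 3:
        raise ValueError("need at least 3 cells")
    if isinstance(tissue_of, dict):
        labels = np.asarray([tissue_of[c] for c in m.cells])
    else:
        labels = np.asarray(tissue_of)
    nn = _nearest_neighbors(embeddings)
    shared = (m.measured[:, None, :] & m.measured[None, :, :]).any(axis=2)

    def count_for(lab):
        return int(sum(lab[i] == lab[nn[i]] and not shared[i, nn[i]] for i in range(n)))

    observed = count_for(labels)
    rng = np.random.default_rng(seed)
    null = np.array([count_for(rng.permutation(labels)) for _ in range(n_perm)])
    return observed, float(null.mean()), float(null.std())


# ---------------------------------------------------------------------------
# benchmark assembly


def per_track_ap(
    scores: np.ndarray, labels: np.ndarray, mask: np.ndarray | None = None
) -> dict:
    """AP per (cell, feature) track from (B, N, F) score/label tensors.

    Tracks without positives (or without evaluated entries) are skipped.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if mask is None:
        mask = np.ones(labels.shape, bool)
    out = {}
    _, N, F = scores.shape
    for nidx in range(N):
        for k in range(F):
            sel = mask[:, nidx, k]
            if not sel.any():
                continue
            lab = labels[sel, nidx, k]
            if lab.sum() == 0 or lab.sum() == lab.size:
                continue
            out[(nidx, k)] = average_precision(scores[sel, nidx, k], lab)
    return out


def mean_average_precision(ap_by_track: dict) -> float:
    """Unweighted (macro) mean of per-track AP."""
    if not ap_by_track:
        raise ValueError("no tracks with defined AP")
    return float(np.mean(list(ap_by_track.values())))
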
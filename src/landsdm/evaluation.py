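"""Set-valued and binary evaluation of joint species predictions.

Primary metrics are rank-based: the top-k accuracy ``A_k`` over observations
and its species-balanced counterpart ``MSA_k`` (mean over species of the
within-species top-k accuracy ``SA_{k,s}``), which avoids over-weighting
frequent species.  Binary metrics (per-species AUC and TSS) rely on
pseudo-absences sampled from other species' occurrences with inverse
frequency weights, balanced one-to-one with presences.

Rank ties are resolved pessimistically: the true species is ranked after all
competitors with an equal score, so a constant predictor earns rank m.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# ranks and top-k accuracies
# ---------------------------------------------------------------------------


def compute_ranks(probabilities: np.ndarray, truths: np.ndarray) -> np.ndarray:
    """Pessimistic rank of the true species in each descending score list.

    ``rank = #{j : p_j > p_true} + #{j : p_j == p_true}`` (the true species
    counts itself), so uniform scores over ``m`` species give rank ``m``.
    """
    probs = np.atleast_2d(np.asarray(probabilities, dtype=float))
    truths = np.atleast_1d(np.asarray(truths, dtype=int))
    if len(truths) != probs.shape[0]:
        raise EvaluationError("probabilities and truths length mismatch")
    if truths.min() < 0 or truths.max() >= probs.shape[1]:
        raise EvaluationError("truth outside the label space")
    p_true = probs[np.arange(len(truths)), truths][:, None]
    ranks = (probs > p_true).sum(axis=1) + (probs == p_true).sum(axis=1)
    return ranks


def topk_accuracy(ranks: np.ndarray, k: int) -> float:
    """Fraction of observations whose true species ranks within the top k."""
    ranks = np.asarray(ranks)
    if ranks.size == 0:
        raise EvaluationError("empty test set")
    if k < 1:
        raise EvaluationError("k must be >= 1")
    return float((ranks <= k).mean())


def mean_species_topk(
    ranks: np.ndarray, truths: np.ndarray, k: int
) -> tuple[dict[int, float], float]:
    """Per-species top-k accuracies ``SA_{k,s}`` and their unweighted mean.

    Replicating a species' observations leaves the mean unchanged; only
    species present in ``truths`` contribute.
    """
    ranks = np.asarray(ranks)
    truths = np.asarray(truths)
    if k < 1:
        raise EvaluationError("k must be >= 1")
    hits = ranks <= k
    sa: dict[int, float] = {}
    for s in np.unique(truths):
        sel = truths == s
        sa[int(s)] = float(hits[sel].mean())
    msa = float(np.mean(list(sa.values())))
    return sa, msa


def accuracy_curves(
    probabilities: np.ndarray, truths: np.ndarray, k_max: int = 30
) -> pd.DataFrame:
    """``A_k`` and ``MSA_k`` for k = 1..k_max as a tidy frame."""
    ranks = compute_ranks(probabilities, truths)
    rows = []
    for k in range(1, k_max + 1):
        _, msa = mean_species_topk(ranks, truths, k)
        rows.append({"k": k, "A_k": topk_accuracy(ranks, k), "MSA_k": msa})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pseudo-absences
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PseudoAbsenceDraw:
    """Per species: indices of its presences and of its pseudo-absences
    (observation indices into the test set)."""

    presences: dict[int, np.ndarray]
    absences: dict[int, np.ndarray]


def draw_pseudo_absences(
    truths: np.ndarray, seed: int = 0, species: np.ndarray | None = None
) -> PseudoAbsenceDraw:
    """One pseudo-absence per presence, drawn from other species' occurrences.

    Each candidate occurrence is weighted by the inverse of its species'
    total count, so per-species weight masses are 1 and the draw is
    equivalent to picking a species uniformly then one of its occurrences.
    Sampling is without replacement within each focal species; ``species``
    optionally restricts the focal species drawn for.
    """
    truths = np.asarray(truths)
    all_species, counts = np.unique(truths, return_counts=True)
    if all_species.size < 2:
        raise EvaluationError("pseudo-absences need at least two species")
    count_of = dict(zip(all_species.tolist(), counts.tolist()))
    weights_all = np.array([1.0 / count_of[s] for s in truths])
    rng = np.random.default_rng(seed)
    presences, absences = {}, {}
    focal = all_species if species is None else np.asarray(species)
    for s in focal:
        n_s = count_of[s]
        candidates = np.flatnonzero(truths != s)
        if n_s > candidates.size:
            raise EvaluationError(
                f"species {s}: {n_s} presences exceed the {candidates.size} "
                "available pseudo-absence candidates"
            )
        w = weights_all[candidates]
        absences[int(s)] = rng.choice(
            candidates, size=int(n_s), replace=False, p=w / w.sum()
        )
        presences[int(s)] = np.flatnonzero(truths == s)
    return PseudoAbsenceDraw(presences=presences, absences=absences)


# ---------------------------------------------------------------------------
# AUC / TSS
# ---------------------------------------------------------------------------


def mann_whitney_auc(presence_scores: np.ndarray, absence_scores: np.ndarray) -> float:
    """P(presence score > absence score), ties counting one half."""
    pres = np.asarray(presence_scores, dtype=float)
    absn = np.asarray(absence_scores, dtype=float)
    if pres.size == 0 or absn.size == 0:
        raise EvaluationError("AUC needs at least one presence and one absence")
    greater = (pres[:, None] > absn[None, :]).sum()
    ties = (pres[:, None] == absn[None, :]).sum()
    return float((greater + 0.5 * ties) / (pres.size * absn.size))


def species_auc(
    scores: np.ndarray, draw: PseudoAbsenceDraw
) -> tuple[dict[int, float], float]:
    """Per-species AUC over presence vs pseudo-absence scores, and the mean.

    ``scores``: (n_test, m) per-observation score of each species — logits
    for neural models, categorical probabilities for tree baselines.
    """
    scores = np.asarray(scores)
    aucs: dict[int, float] = {}
    for s in sorted(draw.presences):
        aucs[s] = mann_whitney_auc(
            scores[draw.presences[s], s], scores[draw.absences[s], s]
        )
    return aucs, float(np.mean(list(aucs.values())))


def minmax_scale_scores(scores: np.ndarray) -> np.ndarray:
    """Min-max scale each species' score column over all test observations;
    constant columns map to 0.5."""
    scores = np.asarray(scores, dtype=float)
    lo = scores.min(axis=0, keepdims=True)
    hi = scores.max(axis=0, keepdims=True)
    span = hi - lo
    out = np.where(span > 0, (scores - lo) / np.where(span > 0, span, 1.0), 0.5)
    return out


def species_tss(
    scores: np.ndarray,
    draw: PseudoAbsenceDraw,
    thresholds: np.ndarray | None = None,
) -> tuple[dict[int, float], float, float]:
    """TSS (sensitivity + specificity - 1) with a global threshold search.

    Scores are min-max scaled per species over the whole test set first; a
    presence is predicted when the scaled score reaches the threshold.  One
    threshold maximizing the species-mean TSS is kept for the model; returns
    per-species TSS at that threshold, the threshold, and the maximal mean.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    scaled = minmax_scale_scores(scores)
    label_order = sorted(draw.presences)
    tss = np.empty((len(label_order), len(thresholds)))
    for i, s in enumerate(label_order):
        pres = scaled[draw.presences[s], s]
        absn = scaled[draw.absences[s], s]
        sens = (pres[:, None] >= thresholds[None, :]).mean(axis=0)
        spec = (absn[:, None] < thresholds[None, :]).mean(axis=0)
        tss[i] = sens + spec - 1.0
    mean_by_threshold = tss.mean(axis=0)
    best = int(np.argmax(mean_by_threshold))
    per_species = {s: float(tss[i, best]) for i, s in enumerate(label_order)}
    return per_species, float(thresholds[best]), float(mean_by_threshold[best])


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EvaluationReport:
    per_species: pd.DataFrame  # species_id, n_test, SA_k, AUC, TSS
    curves: pd.DataFrame  # k, A_k, MSA_k
    summary: dict

    def write(self, csv_path: str, json_path: str) -> None:
        self.per_species.to_csv(csv_path, index=False)
        payload = dict(self.summary)
        payload["curves"] = self.curves.to_dict(orient="list")
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)


def evaluate_predictions(
    probabilities: np.ndarray,
    scores: np.ndarray,
    truth_indices: np.ndarray,
    k: int = 30,
    k_max: int = 30,
    seed: int = 0,
) -> EvaluationReport:
    """Full metric suite on one test set.

    ``probabilities`` drive the rank metrics; ``scores`` (logits or
    probabilities) drive AUC/TSS through the pseudo-absence protocol.
    """
    truth_indices = np.asarray(truth_indices)
    ranks = compute_ranks(probabilities, truth_indices)
    sa, msa = mean_species_topk(ranks, truth_indices, k)
    curves = accuracy_curves(probabilities, truth_indices, k_max=k_max)
    # binary metrics are only defined for species whose presences do not
    # outnumber the available pseudo-absence candidates
    species, counts_arr = np.unique(truth_indices, return_counts=True)
    feasible = species[counts_arr <= len(truth_indices) - counts_arr]
    draw = draw_pseudo_absences(truth_indices, seed=seed, species=feasible)
    label_order = sorted(draw.presences)
    aucs, ms_auc = species_auc(scores, draw)
    tss, threshold, ms_tss = species_tss(scores, draw)
    counts = pd.Series(truth_indices).value_counts()
    per_species = pd.DataFrame(
        {
            "species_index": label_order,
            "n_test": [int(counts[s]) for s in label_order],
            f"SA_{k}": [sa[s] for s in label_order],
            "AUC": [aucs[s] for s in label_order],
            "TSS": [tss[s] for s in label_order],
        }
    )
    summary = {
        "k": k,
        f"MSA_{k}": msa,
        f"A_{k}": topk_accuracy(ranks, k),
        "MS_AUC": ms_auc,
        "MS_TSS": ms_tss,
        "tss_threshold": threshold,
        "n_test": int(len(truth_indices)),
        "n_species_test": int(species.size),
        "n_species_binary": len(label_order),
    }
    return EvaluationReport(per_species=per_species, curves=curves, summary=summary)
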
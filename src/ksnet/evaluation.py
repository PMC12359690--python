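"""ROC/PR metrics, intersection-restricted method comparison, per-family
performance, and the dual-specificity audit.

The comparison protocol mirrors the published benchmarking discipline:
external predictors enter as score tables, the evaluation is restricted to
the pairs both methods actually scored, and each of the repeated validation
sets combines the shared positives with a 10x random negative sample from
the shared pair space. Rank-based AUC makes heterogeneous score scales
directly comparable without normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .types import ProbabilisticNetwork, residue_class, site_residue


@dataclass
class MethodScores:
    """Score table of an external predictor: (kinase, site) -> real score."""

    name: str
    scores: dict[tuple[str, str], float]
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        vals = np.array(list(self.scores.values()), dtype=float)
        if vals.size and not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.name}: scores must be finite")

    @classmethod
    def from_network(cls, net: ProbabilisticNetwork, name: str) -> "MethodScores":
        d = {
            (k, s): float(p)
            for k, s, p in zip(
                net.edges["kinase_id"], net.edges["site_id"], net.edges["probability"]
            )
        }
        return cls(name, d)

    def oriented(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        sign = 1.0 if self.higher_is_better else -1.0
        return np.array([sign * self.scores[p] for p in pairs])


def auc_roc(scores: np.ndarray | list[float], labels: np.ndarray | list[int]) -> float:
    """AUC-ROC with the midrank tie convention.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg) over all
    positive/negative pairs.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    return float(skm.roc_auc_score(y, s))


def pr_curve(
    scores: np.ndarray | list[float], labels: np.ndarray | list[int]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall points and average precision (step-wise sum)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    precision, recall, _ = skm.precision_recall_curve(y, s)
    ap = float(skm.average_precision_score(y, s))
    return precision, recall, ap


def compare_methods(
    net: ProbabilisticNetwork,
    other: MethodScores,
    positives: set[tuple[str, str]],
    n_reps: int = 100,
    neg_ratio: int = 10,
    seed: int = 0,
    self_name: str = "this_model",
) -> tuple[pd.Series, pd.DataFrame]:
    """Repeated intersection-restricted AUC comparison against one method.

    Only pairs scored by both methods enter. Each rep pairs the shared
    positives with a fresh ``neg_ratio``x negative sample from the shared
    non-positive pairs; both methods are scored on identical pairs. Returns
    (mean AUC per method, per-rep table).
    """
    mine = MethodScores.from_network(net, self_name)
    shared = sorted(set(mine.scores) & set(other.scores))
    if not shared:
        raise ValueError(
            f"no shared scored pairs between {self_name} and {other.name}"
        )
    pos = sorted(set(shared) & {tuple(p) for p in positives})
    if not pos:
        raise ValueError(
            f"no shared positive pair between {self_name} and {other.name}"
        )
    neg_pool = [p for p in shared if p not in set(pos)]
    n_neg = neg_ratio * len(pos)
    if len(neg_pool) < n_neg:
        raise ValueError(
            f"negative pool ({len(neg_pool)}) smaller than required {n_neg}"
        )
    rows = []
    rep_seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(n_reps)
    ]
    for rep, rep_seed in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_seed)
        idx = rng.choice(len(neg_pool), size=n_neg, replace=False)
        pairs = pos + [neg_pool[int(i)] for i in idx]
        y = np.array([1] * len(pos) + [0] * n_neg)
        rows.append(
            {
                "rep": rep,
                "seed": rep_seed,
                self_name: auc_roc(mine.oriented(pairs), y),
                other.name: auc_roc(other.oriented(pairs), y),
            }
        )
    table = pd.DataFrame(rows)
    means = table[[self_name, other.name]].mean()
    return means, table


def per_family_roc(
    net: ProbabilisticNetwork,
    truth: set[tuple[str, str]],
    family_map: dict[str, str],
) -> pd.DataFrame:
    """AUC within each kinase family's edge subset.

    Families whose subset lacks a class are reported with ``defined=False``
    rather than dropped.
    """
    edges = net.edges.copy()
    edges["family"] = [family_map.get(k, "UNKNOWN") for k in edges["kinase_id"]]
    truth = {tuple(t) for t in truth}
    edges["label"] = [
        int((k, s) in truth) for k, s in zip(edges["kinase_id"], edges["site_id"])
    ]
    rows = []
    for fam, grp in edges.groupby("family", sort=True):
        if grp["label"].nunique() < 2:
            rows.append({"family": fam, "auc": float("nan"), "defined": False,
                         "n_edges": len(grp)})
        else:
            rows.append(
                {
                    "family": fam,
                    "auc": auc_roc(grp["probability"].to_numpy(), grp["label"]),
                    "defined": True,
                    "n_edges": len(grp),
                }
            )
    return pd.DataFrame(rows).set_index("family")


def dual_specificity_audit(
    net: ProbabilisticNetwork,
    dual_kinases: list[str],
    cutoff: float = 0.5,
    min_fraction: float = 0.05,
    min_count: int = 5,
) -> pd.DataFrame:
    """Audit annotated dual-specificity kinases against predicted targets.

    For each kinase, predictions above ``cutoff`` are split by residue class.
    Verdicts: SUPPORTED_DUAL when both classes hold at least ``min_fraction``
    of the predictions, ST_ONLY / Y_ONLY when one class dominates, and
    INSUFFICIENT when fewer than ``min_count`` predictions survive the cutoff
    (low-count calls are unreliable).
    """
    kept = net.edges_above(cutoff, strict=True)
    rows = []
    for kid in dual_kinases:
        sub = kept[kept["kinase_id"] == kid]
        n_st = sum(residue_class(site_residue(s)) == "ST" for s in sub["site_id"])
        n_y = len(sub) - n_st
        total = n_st + n_y
        if total < min_count:
            verdict = "INSUFFICIENT"
        else:
            frac_st = n_st / total
            frac_y = n_y / total
            if frac_st >= min_fraction and frac_y >= min_fraction:
                verdict = "SUPPORTED_DUAL"
            elif frac_y < min_fraction:
                verdict = "ST_ONLY"
            else:
                verdict = "Y_ONLY"
        rows.append(
            {"kinase_id": kid, "n_ST": n_st, "n_Y": n_y, "verdict": verdict}
        )
    return pd.DataFrame(rows).set_index("kinase_id")
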
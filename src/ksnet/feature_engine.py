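"""Per-pair predictive features and FeatureTable assembly.

Features fall into the categories the model integrates: sequence specificity
(PSSM log-score and its per-kinase percentile), co-expression/co-regulation
across contexts (pairwise-complete correlation between the kinase's and the
substrate protein's profiles), and site-level covariates (the functional
score). Missing values are flagged as NaN at assembly time and imputed only
inside the training engine, so the table stays faithful to its sources.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AMINO_ACIDS,
    KinaseRecord,
    KSPair,
    PAD,
    PhosphositeRecord,
    PSSM,
    kinase_accepts,
)

_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class FeatureDescriptor:
    """One column of the feature registry.

    ``source`` names where the feature comes from: ``"pssm"``, a context
    matrix key (e.g. ``"expression"``, ``"proteomics"``), ``"site"`` for
    site-level covariates, or ``"extra"`` for externally supplied columns.
    """

    name: str
    source: str
    transform: str = "identity"


DEFAULT_REGISTRY: tuple[FeatureDescriptor, ...] = (
    FeatureDescriptor("pssm_log_score", "pssm"),
    FeatureDescriptor("pssm_percentile", "pssm", "percentile"),
    FeatureDescriptor("coexpr_tissue", "expression", "pearson"),
    FeatureDescriptor("coreg_proteome", "proteomics", "pearson"),
    FeatureDescriptor("functional_score", "site"),
)


class FeatureTable:
    """(kinase, site)-keyed feature matrix with an explicit registry.

    ``data`` is indexed by a (kinase_id, site_id) MultiIndex; columns follow
    registry order, with extra pass-through columns appended. Missing cells
    are NaN and exposed through :meth:`missing_mask`; no imputation happens
    here.
    """

    def __init__(self, data: pd.DataFrame, registry: tuple[FeatureDescriptor, ...]):
        if data.index.duplicated().any():
            raise ValueError("duplicate (kinase, site) keys in feature table")
        names = [d.name for d in registry]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")
        missing = [n for n in names if n not in data.columns]
        if missing:
            raise ValueError(f"registry features absent from table: {missing}")
        ordered = names + [c for c in data.columns if c not in names]
        self.data = data.loc[:, ordered]
        self.registry = tuple(registry)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def __len__(self) -> int:
        return len(self.data)


def pssm_log_score(pssm: PSSM, flank: str) -> float:
    """Sum of log2 PSSM weights over the non-pad flank positions.

    The flank is centred on the phosphoacceptor; pad characters ('_') and the
    central residue (when the PSSM excludes position 0) contribute 0.
    """
    radius = len(flank) // 2
    if len(flank) % 2 != 1:
        raise ValueError("flank length must be odd")
    positions = set(pssm.positions)
    lo, hi = min(positions), max(positions)
    if lo < -radius or hi > radius:
        raise ValueError(
            f"flank radius {radius} too small for PSSM positions {lo}..{hi}"
        )
    total = 0.0
    for i, ch in enumerate(flank):
        pos = i - radius
        if pos not in positions:
            continue
        if ch == PAD:
            continue
        if ch not in _AA_SET:
            raise ValueError(f"invalid flank character {ch!r} at position {pos}")
        total += float(np.log2(pssm.weights.at[pos, ch]))
    return total


def pssm_scores_for_sites(pssm: PSSM, sites: list[PhosphositeRecord]) -> np.ndarray:
    """Vectorised :func:`pssm_log_score` over many sites (same flank radius)."""
    if not sites:
        return np.zeros(0)
    radius = sites[0].flank_radius
    n_aa = len(AMINO_ACIDS)
    aa_code = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    aa_code[PAD] = n_aa
    codes = np.array(
        [[aa_code[ch] for ch in s.flank] for s in sites], dtype=np.int64
    )
    # Per flank column: log2 weights plus a zero pad column; columns whose
    # position is absent from the PSSM contribute nothing.
    logw = np.zeros((2 * radius + 1, n_aa + 1))
    positions = set(pssm.positions)
    for i in range(2 * radius + 1):
        pos = i - radius
        if pos in positions:
            logw[i, :n_aa] = np.log2(pssm.weights.loc[pos].to_numpy())
    return logw[np.arange(2 * radius + 1)[None, :], codes].sum(axis=1)


def pssm_percentile(scores: np.ndarray | list[float]) -> np.ndarray:
    """Midrank percentiles in (0, 1]: rank/n, best score -> 1.0.

    Deterministic monotone transform of the raw scores (order preserved up to
    ties, which share their average rank).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValueError("percentile needs at least 2 candidate scores")
    return stats.rankdata(arr, method="average") / arr.size


def coregulation_feature(
    profile_a: pd.Series,
    profile_b: pd.Series,
    method: str = "pearson",
    min_overlap: int = 5,
) -> float:
    """Pairwise-complete correlation of two context profiles.

    Returns NaN (flagged missing) when the complete overlap is below
    ``min_overlap`` or has zero variance in either profile.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    a, b = profile_a.align(profile_b, join="inner")
    mask = a.notna() & b.notna()
    if int(mask.sum()) < min_overlap:
        return float("nan")
    x = a[mask].to_numpy(dtype=float)
    y = b[mask].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    return float(stats.spearmanr(x, y).statistic)


def assemble_features(
    pairs: list[KSPair] | list[tuple[str, str]],
    kinases: dict[str, KinaseRecord],
    sites: dict[str, PhosphositeRecord],
    pssms: dict[str, PSSM],
    context_matrices: dict[str, pd.DataFrame] | None = None,
    registry: tuple[FeatureDescriptor, ...] = DEFAULT_REGISTRY,
    extra_columns: pd.DataFrame | None = None,
    min_overlap: int = 5,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Build the FeatureTable for ``pairs``; returns (table, rejects).

    Pairs referencing unknown kinases/sites or violating the kinase's residue
    specificity are collected in the rejects report (columns kinase_id,
    site_id, reason) rather than raising. Percentile features are computed
    per kinase over the candidate sites appearing with it in ``pairs``.
    """
    if not registry:
        raise ValueError("registry must be non-empty")
    context_matrices = context_matrices or {}
    keys = [p.key if isinstance(p, KSPair) else tuple(p) for p in pairs]

    rejects = []
    accepted: list[tuple[str, str]] = []
    seen = set()
    for kid, sid in keys:
        if (kid, sid) in seen:
            rejects.append((kid, sid, "duplicate"))
            continue
        if kid not in kinases:
            rejects.append((kid, sid, "unknown kinase"))
            continue
        if sid not in sites:
            rejects.append((kid, sid, "unknown site"))
            continue
        if kid not in pssms:
            rejects.append((kid, sid, "missing PSSM"))
            continue
        if not kinase_accepts(kinases[kid].specificity, sites[sid].residue):
            rejects.append((kid, sid, "specificity"))
            continue
        seen.add((kid, sid))
        accepted.append((kid, sid))

    index = pd.MultiIndex.from_tuples(
        accepted or [], names=["kinase_id", "site_id"]
    )
    columns: dict[str, np.ndarray] = {}

    by_kinase: dict[str, list[int]] = {}
    for i, (kid, _) in enumerate(accepted):
        by_kinase.setdefault(kid, []).append(i)

    n = len(accepted)
    raw_pssm = np.full(n, np.nan)
    for kid, idxs in by_kinase.items():
        recs = [sites[accepted[i][1]] for i in idxs]
        raw_pssm[idxs] = pssm_scores_for_sites(pssms[kid], recs)

    for desc in registry:
        if desc.source == "pssm":
            if desc.transform == "percentile":
                vals = np.full(n, np.nan)
                for kid, idxs in by_kinase.items():
                    if len(idxs) >= 2:
                        vals[idxs] = pssm_percentile(raw_pssm[idxs])
                columns[desc.name] = vals
            else:
                columns[desc.name] = raw_pssm.copy()
        elif desc.source == "site":
            columns[desc.name] = np.array(
                [sites[sid].functional_score for _, sid in accepted]
            )
        elif desc.source in context_matrices:
            mat = context_matrices[desc.source]
            vals = np.full(n, np.nan)
            cache: dict[tuple[str, str], float] = {}
            for i, (kid, sid) in enumerate(accepted):
                prot = sites[sid].protein_id
                key = (kid, prot)
                if key not in cache:
                    if kid in mat.index and prot in mat.index:
                        cache[key] = coregulation_feature(
                            mat.loc[kid],
                            mat.loc[prot],
                            method=desc.transform
                            if desc.transform in ("pearson", "spearman")
                            else "pearson",
                            min_overlap=min_overlap,
                        )
                    else:
                        cache[key] = float("nan")
                vals[i] = cache[key]
            columns[desc.name] = vals
        elif desc.source == "extra":
            if extra_columns is None or desc.name not in extra_columns.columns:
                raise ValueError(f"extra feature {desc.name!r} not supplied")
            columns[desc.name] = (
                extra_columns[desc.name].reindex(index).to_numpy(dtype=float)
            )
        else:
            raise ValueError(
                f"feature {desc.name!r}: unknown source {desc.source!r} "
                f"(no matching context matrix)"
            )

    data = pd.DataFrame(columns, index=index)
    rejects_df = pd.DataFrame(rejects, columns=["kinase_id", "site_id", "reason"])
    return FeatureTable(data, registry), rejects_df
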
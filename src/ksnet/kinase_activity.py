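"""Condition-specific kinase activity inference.

High-confidence substrate sets are gated at the 95th percentile of the edge
probability distribution; a preranked enrichment statistic (classical
weighted Kolmogorov-Smirnov running sum with a permutation null) then asks
whether each kinase's substrates concentrate at the top or bottom of the
per-condition log2 fold-change ranking. Normalised enrichment scores (NES)
of kinases passing Benjamini-Hochberg control at adjusted p <= 0.05 form the
activity profile. Dual-specificity kinases are scored separately on their
Ser/Thr and Tyr substrate sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import ProbabilisticNetwork, residue_class, site_residue


@dataclass
class SubstrateSet:
    kinase_id: str
    residue_class: str  # "ST", "Y" or "ALL"
    sites: frozenset[str]

    def __post_init__(self) -> None:
        if self.residue_class not in ("ST", "Y", "ALL"):
            raise ValueError(f"invalid residue class {self.residue_class!r}")
        if not self.sites:
            raise ValueError("substrate sets must be non-empty")
        if self.residue_class != "ALL":
            bad = [
                s for s in self.sites
                if residue_class(site_residue(s)) != self.residue_class
            ]
            if bad:
                raise ValueError(f"sites violate residue class: {bad[:3]}")

    @property
    def name(self) -> str:
        if self.residue_class == "ALL":
            return self.kinase_id
        return f"{self.kinase_id}:{self.residue_class}"


@dataclass
class ActivityResult:
    kinase_id: str
    residue_class: str
    es: float
    nes: float
    pvalue: float
    n_hits: int
    leading_edge: list[str] = field(default_factory=list)
    adjusted_p: float = float("nan")
    flags: list[str] = field(default_factory=list)


def build_substrate_sets(
    net: ProbabilisticNetwork,
    dual_kinases: set[str] | None = None,
    percentile: float = 0.95,
    scope: str = "global",
    min_set_size: int = 5,
) -> tuple[list[SubstrateSet], pd.DataFrame]:
    """Percentile-gated high-confidence substrate sets per kinase.

    ``scope="global"`` thresholds at the ``percentile`` quantile of *all*
    edge probabilities (lower interpolation, strict >); ``"per_kinase"``
    applies the quantile within each kinase's own edges. Dual-specificity
    kinases yield separate ST and Y sets. Sets below ``min_set_size`` are
    dropped and reported.
    """
    if len(net) == 0:
        raise ValueError("network is empty")
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie in (0, 1)")
    if scope not in ("global", "per_kinase"):
        raise ValueError(f"unknown scope {scope!r}")
    dual_kinases = dual_kinases or set()
    edges = net.edges
    sets: list[SubstrateSet] = []
    dropped = []
    if scope == "global":
        threshold = float(
            np.quantile(edges["probability"].to_numpy(), percentile, method="lower")
        )
    for kid, grp in edges.groupby("kinase_id", sort=True):
        if scope == "per_kinase":
            threshold = float(
                np.quantile(grp["probability"].to_numpy(), percentile, method="lower")
            )
        kept = grp[grp["probability"] > threshold]
        if kid in dual_kinases:
            groups = {
                "ST": [s for s in kept["site_id"]
                       if residue_class(site_residue(s)) == "ST"],
                "Y": [s for s in kept["site_id"]
                      if residue_class(site_residue(s)) == "Y"],
            }
        else:
            groups = {"ALL": list(kept["site_id"])}
        for cls, members in groups.items():
            if len(members) >= min_set_size:
                sets.append(SubstrateSet(kid, cls, frozenset(members)))
            else:
                dropped.append(
                    {"kinase_id": kid, "residue_class": cls, "n": len(members)}
                )
    if not sets:
        raise ValueError("no substrate set survives the percentile gate")
    return sets, pd.DataFrame(dropped, columns=["kinase_id", "residue_class", "n"])


def _running_es(
    stats_sorted: np.ndarray, hit_mask: np.ndarray, weight_exponent: float
) -> tuple[float, int]:
    """Signed maximum deviation of the weighted running sum; returns (ES, argmax)."""
    n = stats_sorted.size
    n_hits = int(hit_mask.sum())
    weights = np.abs(stats_sorted) ** weight_exponent
    hit_w = np.where(hit_mask, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # All hit statistics are zero: fall back to unweighted increments.
        hit_w = hit_mask.astype(float)
        denom = float(n_hits)
    steps = hit_w / denom - (~hit_mask) / (n - n_hits)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), i


def preranked_enrichment(
    ranking: pd.Series,
    substrate_set: SubstrateSet,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_set_size: int = 5,
) -> ActivityResult | None:
    """Classical preranked enrichment of one substrate set in a log2FC ranking.

    The ranking is sorted descending (ties broken by site id for
    determinism); the running sum gains |stat|^weight_exponent (normalised)
    at hits and loses 1/(N-n) at misses; ES is the signed maximum deviation.
    The p-value comes from a permutation null of random same-size sets,
    one-sided by ES sign, with resolution bounded by 1/(n_perm + 1); NES is
    ES over the mean |null ES| of matching sign. Returns None (skipped) when
    the set's overlap with the ranking is below ``min_set_size``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    clean = ranking.dropna()
    order = sorted(clean.index, key=lambda s: (-clean[s], s))
    stats_sorted = clean.loc[order].to_numpy(dtype=float)
    member = np.array([s in substrate_set.sites for s in order])
    n_hits = int(member.sum())
    if n_hits < min_set_size or n_hits == len(order):
        return None
    es, argmax = _running_es(stats_sorted, member, weight_exponent)
    leading = (
        [s for s, m in zip(order[: argmax + 1], member[: argmax + 1]) if m]
        if es >= 0
        else [s for s, m in zip(order[argmax:], member[argmax:]) if m]
    )
    flags = []
    if np.ptp(stats_sorted) == 0:
        flags.append("degenerate_ranking")
    rng = np.random.default_rng(seed)
    n = len(order)
    null_es = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=n_hits, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        null_es[i], _ = _running_es(stats_sorted, mask, weight_exponent)
    same_sign = null_es >= 0 if es >= 0 else null_es < 0
    m = int(same_sign.sum())
    if m == 0:
        pvalue = 1.0 / (n_perm + 1)
        nes = float("nan")
        flags.append("empty_null_sign")
    else:
        extreme = int((np.abs(null_es[same_sign]) >= abs(es) - 1e-15).sum())
        pvalue = (1 + extreme) / (1 + m)
        mean_null = float(np.abs(null_es[same_sign]).mean())
        nes = es / mean_null if mean_null > 0 else float("nan")
    return ActivityResult(
        kinase_id=substrate_set.kinase_id,
        residue_class=substrate_set.residue_class,
        es=es,
        nes=nes,
        pvalue=pvalue,
        n_hits=n_hits,
        leading_edge=leading,
        flags=flags,
    )


def activity_profile(
    substrate_sets: list[SubstrateSet],
    conditions: pd.DataFrame,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_set_size: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NES matrix (set x condition) of significant activities, plus full results.

    Per condition, raw permutation p-values are Benjamini-Hochberg adjusted
    across all scored sets; entries with adjusted p <= alpha keep their NES,
    everything else is masked to NaN. The second return value holds the full
    unmasked result table.
    """
    names = [s.name for s in substrate_sets]
    profile = pd.DataFrame(
        float("nan"), index=names, columns=list(conditions.columns)
    )
    records = []
    seeds = [
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(len(conditions.columns))
    ]
    for cond, cond_seed in zip(conditions.columns, seeds):
        ranking = conditions[cond]
        results: list[ActivityResult] = []
        for k, sset in enumerate(substrate_sets):
            res = preranked_enrichment(
                ranking,
                sset,
                n_perm=n_perm,
                seed=cond_seed + k,
                weight_exponent=weight_exponent,
                min_set_size=min_set_size,
            )
            if res is not None:
                results.append(res)
        if not results:
            continue
        pvals = [r.pvalue for r in results]
        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for r, ap in zip(results, adj):
            r.adjusted_p = float(ap)
            records.append(
                {
                    "condition": cond,
                    "set": f"{r.kinase_id}:{r.residue_class}"
                    if r.residue_class != "ALL"
                    else r.kinase_id,
                    "kinase_id": r.kinase_id,
                    "residue_class": r.residue_class,
                    "es": r.es,
                    "nes": r.nes,
                    "pvalue": r.pvalue,
                    "adjusted_p": r.adjusted_p,
                    "n_hits": r.n_hits,
                    "flags": ";".join(r.flags),
                }
            )
            if r.adjusted_p <= alpha and np.isfinite(r.nes):
                name = (
                    f"{r.kinase_id}:{r.residue_class}"
                    if r.residue_class != "ALL"
                    else r.kinase_id
                )
                profile.at[name, cond] = r.nes
        del ranking
    return profile, pd.DataFrame(records)


def substrate_sets_to_gmt(sets: list[SubstrateSet], path) -> None:
    """Write substrate sets in GMT form (set name = kinase_id[:ST|:Y])."""
    from .interface import write_gmt

    write_gmt({s.name: set(s.sites) for s in sets}, path)


def substrate_sets_from_gmt(path) -> list[SubstrateSet]:
    """Read substrate sets from GMT; ':ST'/':Y' suffixes set residue class."""
    from .interface import read_gmt

    out = []
    for name, members in read_gmt(path).items():
        if ":" in name:
            kinase_id, cls = name.rsplit(":", 1)
        else:
            kinase_id, cls = name, "ALL"
        out.append(SubstrateSet(kinase_id, cls, frozenset(members)))
    return out
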
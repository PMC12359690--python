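"""Standard synthetic benchmark procedures.

Each function here defines one reproducible study on the synthetic world:
held-out ranking performance of the trained ensemble, robustness to the
negative-sampling ratio, planted-feature recovery of the RFE majority vote,
exactness of the PCSF heuristic against exhaustive enumeration, the gain in
F1 from condition fitting, recovery of planted kinase activities, and the
UPGMA cross-check against an independent average-linkage implementation.
The same procedures back the test suite and the acceptance script, so the
reported numbers always come from a fresh run of the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .feature_engine import (
    DEFAULT_REGISTRY,
    FeatureDescriptor,
    FeatureTable,
    assemble_features,
)
from .kinase_activity import SubstrateSet, activity_profile, preranked_enrichment
from .pcsf_fitting import (
    PCSFParams,
    assemble_reference,
    f1_of_subnetwork,
    solve_pcsf,
    sweep_and_select,
)
from .training_engine import TrainingConfig, holdout_benchmark, rfe_majority_vote
from .types import KSPair, Label

# The reference ranking benchmark: a mid-sized world with strong sequence
# signal. The Tyr/dual fractions keep the specificity-respecting pair space
# large enough to draw 50x negative samples.
BENCHMARK_WORLD = dict(
    n_kinases=25,
    n_sites=3000,
    n_true_pairs=1500,
    frac_tyr_kinases=0.12,
    frac_dual=0.08,
    signal_strength=0.9,
    n_contexts=30,
    seed=7,
    n_default_conditions=0,
)

# Single-point hyper-parameter grid for benchmark runs; the full 72-point
# grid is exercised separately at toy scale.
REDUCED_GRID = {"max_depth": [50], "min_samples_split": [10],
                "n_estimators": [150]}


def benchmark_world() -> sd.SyntheticWorld:
    return sd.generate_world(**BENCHMARK_WORLD)


def benchmark_features(world: sd.SyntheticWorld) -> FeatureTable:
    pairs = [KSPair(k, s) for k, s in world.universe()]
    table, rejects = assemble_features(
        pairs,
        world.kinase_map(),
        world.site_map(),
        world.pssms,
        {"expression": world.expression, "proteomics": world.proteomics},
        DEFAULT_REGISTRY,
    )
    if len(rejects):
        raise RuntimeError("benchmark universe produced rejects")
    return table


def ensemble_holdout(
    world: sd.SyntheticWorld,
    table: FeatureTable,
    neg_ratio: int,
    seed: int = 7,
    n_runs: int = 10,
) -> dict:
    """Held-out AUC of a ``n_runs``-member ensemble at one negative ratio."""
    config = TrainingConfig(
        seed=seed,
        n_runs=n_runs,
        k_folds=10,
        inner_cv=3,
        neg_ratio_final=neg_ratio,
        grid=dict(REDUCED_GRID),
    )
    return holdout_benchmark(world, config, test_frac=0.3, seed=seed,
                             table=table)


def feature_selection_recovery(seed: int = 11, n_runs: int = 20) -> dict:
    """Plant 3 informative + 5 noise features; count what the vote retains."""
    world = sd.generate_world(
        n_kinases=8, n_sites=300, n_true_pairs=120, signal_strength=0.9,
        seed=seed, n_default_conditions=0,
    )
    base = benchmark_features(world)
    informative = ["pssm_log_score", "pssm_percentile", "functional_score"]
    data = base.data[informative].copy()
    registry = [d for d in base.registry if d.name in informative]
    rng = np.random.default_rng(seed)
    noise = [f"noise_{j}" for j in range(5)]
    for name in noise:
        data[name] = rng.normal(size=len(data))
        registry.append(FeatureDescriptor(name, "extra"))
    table = FeatureTable(data, tuple(registry))
    positives = [KSPair(k, s, Label.POSITIVE) for k, s in sorted(world.truth_keys)]
    config = TrainingConfig(seed=seed, n_runs=n_runs, k_folds=3, inner_cv=3)
    selected, subsets = rfe_majority_vote(table, positives, world.universe(),
                                          config)
    return {
        "selected": selected,
        "n_informative_retained": sum(f in selected for f in informative),
        "n_noise_dropped": sum(f not in selected for f in noise),
        "n_runs": n_runs,
    }


def _random_small_instance(rng, max_nodes=8):
    import networkx as nx

    from .pcsf_fitting import SignalingGraph

    n = int(rng.integers(3, max_nodes + 1))
    kin = [f"K{i}" for i in range(n)]
    g = nx.DiGraph()
    for k in kin:
        g.add_node(k, kind="kinase")
    m = int(rng.integers(2, min(15, n * (n - 1) // 2) + 1))
    added = set()
    for _ in range(m):
        a, b = rng.choice(n, 2, replace=False)
        if (kin[a], kin[b]) in added or (kin[b], kin[a]) in added:
            continue
        added.add((kin[a], kin[b]))
        g.add_edge(kin[a], kin[b], cost=float(rng.uniform(0, 2)),
                   probability=0.5)
    prizes = {k: float(rng.uniform(0, 3)) if rng.random() < 0.7 else 0.0
              for k in kin}
    params = PCSFParams(int(rng.integers(1, 4)), 1.0,
                        float(rng.choice([0.0, 0.05, 0.5])))
    root_charge = float(rng.uniform(0.3, 1.5))
    return SignalingGraph(g), prizes, params, root_charge


def _forced_pcsf_examples():
    import networkx as nx

    from .pcsf_fitting import SignalingGraph

    g1 = nx.DiGraph()
    g1.add_node("K1", kind="kinase")
    g1.add_node("K2", kind="kinase")
    g1.add_node("K3", kind="kinase")
    g1.add_edge("K1", "K2", cost=10.0, probability=0.0)
    yield SignalingGraph(g1), {"K3": 5.0, "K1": 0.0, "K2": 0.0}, \
        PCSFParams(2, 1.0, 0.0), 1.0
    g2 = nx.DiGraph()
    g2.add_node("K1", kind="kinase")
    g2.add_node("K2", kind="kinase")
    g2.add_edge("K1", "K2", cost=3.0, probability=0.0)
    yield SignalingGraph(g2), {"K1": 1.0, "K2": 1.0}, \
        PCSFParams(2, 1.0, 0.0), 1.5


def pcsf_exactness(seed: int = 20240917, n_instances: int = 60) -> dict:
    """Heuristic-vs-exhaustive agreement on small random instances plus the
    two forced examples (isolated prize node; expensive-edge empty optimum)."""
    rng = np.random.default_rng(seed)
    instances = list(_forced_pcsf_examples())
    while len(instances) < n_instances:
        instances.append(_random_small_instance(rng))
    matches = 0
    for graph, prizes, params, rc in instances:
        exact = solve_pcsf(graph, prizes, params, mode="exact_small",
                           root_charge=rc)
        heur = solve_pcsf(graph, prizes, params, mode="heuristic",
                          root_charge=rc)
        if abs(exact.objective - heur.objective) <= 1e-9:
            matches += 1
    return {"n_instances": len(instances), "n_matches": matches,
            "match_rate": matches / len(instances)}


def fitting_improvement(
    seed: int = 29,
    n_conditions: int = 50,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
) -> dict:
    """Does the F1-selected PCSF subnetwork beat the unpruned input network?

    A synthetic probabilistic network (truth edges Beta(4,1), background
    Beta(1,4)) plus a kinase-kinase backbone is cut at probability 0.5;
    activation conditions are fitted over a compact b/w/mu grid and the best
    subnetwork's F1 against the planted truth is compared with the input
    baseline per condition.
    """
    world = sd.generate_world(
        n_kinases=12, n_sites=1200, n_true_pairs=180, signal_strength=0.9,
        seed=seed, n_default_conditions=0,
    )
    ks_net = sd.generate_probabilistic_network(world, seed=seed + 1)
    kk_net = sd.generate_kinase_kinase_network(world, seed=seed + 2)
    graph = assemble_reference(kk_net, ks_net, cutoff=0.5)
    known = world.truth_keys
    input_edges = graph.edge_set()
    _, _, input_f1, _ = f1_of_subnetwork(input_edges, known, input_edges)
    conditions, _ = sd.generate_condition_table(
        world, n_conditions, effect_size=effect_size, noise_sd=noise_sd,
        seed=seed + 3,
    )
    grid = [PCSFParams(b, w, mu) for b in (2, 5) for w in (0.5, 1.0)
            for mu in (0.0005, 0.05)]
    best, log = sweep_and_select(graph, conditions, known, grid=grid)
    fitted_f1 = {c: fit.f1 for c, fit in best.items()}
    wins = sum(f1 > input_f1 for f1 in fitted_f1.values())
    return {
        "n_conditions": n_conditions,
        "n_fitted": len(best),
        "input_f1": input_f1,
        "median_fitted_f1": float(np.median(list(fitted_f1.values()))),
        "wins": wins,
        "win_rate": wins / max(1, len(best)),
    }


def activity_recovery(
    n_runs: int = 40,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    alpha: float = 0.05,
    seed: int = 31,
) -> dict:
    """Fraction of seeded runs in which the planted activated kinase is
    significant (BH-adjusted p <= alpha) with positive NES."""
    hits = 0
    for run in range(n_runs):
        run_seed = (seed + 97 * run) % 2**31
        world = sd.generate_world(
            n_kinases=6, n_sites=400, n_true_pairs=150, seed=run_seed,
            n_default_conditions=0,
        )
        active = max(world.kinase_ids,
                     key=lambda k: len(world.substrates_of(k)))
        cond = sd.generate_activation_condition(
            world, [active], effect_size, noise_sd, seed=run_seed + 1
        )
        sets = [
            SubstrateSet(k, "ALL", frozenset(world.substrates_of(k)))
            for k in world.kinase_ids
            if len(world.substrates_of(k)) >= 5
        ]
        profile, _ = activity_profile(
            sets, pd.DataFrame({"c": cond}), alpha=alpha, n_perm=300,
            seed=run_seed,
        )
        nes = profile.at[active, "c"] if active in profile.index else np.nan
        if np.isfinite(nes) and nes > 0:
            hits += 1
    return {"n_runs": n_runs, "hits": hits, "recovery_rate": hits / n_runs}


def activity_null_calibration(n_reps: int = 150, seed: int = 37) -> dict:
    """KS test of enrichment p-values for random substrate sets."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    ranking = pd.Series(
        rng.normal(size=120), index=[f"P1_S{i + 1}" for i in range(120)]
    )
    pvals = []
    for rep in range(n_reps):
        members = rng.choice(ranking.index, size=10, replace=False)
        res = preranked_enrichment(
            ranking, SubstrateSet("K1", "ALL", frozenset(members)),
            n_perm=300, seed=seed + rep,
        )
        pvals.append(res.pvalue)
    stat, p = stats.kstest(pvals, "uniform")
    return {"n_reps": n_reps, "ks_stat": float(stat), "ks_pvalue": float(p)}


def upgma_oracle_agreement(n_matrices: int = 100, seed: int = 41) -> dict:
    """Merge-sequence agreement with scipy's average-linkage implementation
    on random 6-leaf distance matrices (our ultrametric heights are half the
    linkage heights), plus the hand-worked 3-leaf example."""
    from scipy.cluster.hierarchy import linkage

    from .kinase_similarity import upgma

    rng = np.random.default_rng(seed)
    matches = 0
    for _ in range(n_matrices):
        n = 6
        condensed = rng.uniform(0.1, 2.0, size=n * (n - 1) // 2)
        square = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        square[iu] = condensed
        square += square.T
        D = pd.DataFrame(square, index=[f"L{i}" for i in range(n)],
                         columns=[f"L{i}" for i in range(n)])
        ours = upgma(D)
        ref = linkage(condensed, method="average")
        ok = np.allclose([m[2] for m in ours.merges], ref[:, 2] / 2.0,
                         atol=1e-9)
        ok = ok and [m[3] for m in ours.merges] == [int(v) for v in ref[:, 3]]
        matches += int(ok)
    D3 = pd.DataFrame(
        [[0.0, 2.0, 8.0], [2.0, 0.0, 8.0], [8.0, 8.0, 0.0]],
        index=list("ABC"), columns=list("ABC"),
    )
    tree = upgma(D3)
    hand_ok = (
        abs(tree.merges[0][2] - 1.0) < 1e-12
        and abs(tree.merges[1][2] - 4.0) < 1e-12
    )
    return {
        "n_matrices": n_matrices,
        "n_matches": matches,
        "match_rate": matches / n_matrices,
        "hand_example_ok": hand_ok,
    }
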
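"""Seeded synthetic benchmark world with planted kinase-substrate truth.

Emulates the heterogeneous inputs the inference pipeline consumes — a kinome
with residue specificities, per-kinase PSSMs, phosphosites with flanking
sequences and functional scores, expression/proteomics matrices, and
phosphoproteomics condition tables — with a known planted ground-truth
network so every downstream stage can be tested end to end.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so sub-generators are independently
reproducible and the whole world is bit-identical for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AMINO_ACIDS,
    DEFAULT_FLANK_RADIUS,
    KinaseRecord,
    KSPair,
    Label,
    PAD,
    PhosphositeRecord,
    ProbabilisticNetwork,
    PSSM,
    Specificity,
    kinase_accepts,
    make_site_id,
    validate_condition_table,
)

# Dirichlet concentration for PSSM rows: < 1 gives peaky, realistic
# position-specific preferences.
PSSM_CONCENTRATION = 0.2
SITES_PER_PROTEIN = 10


@dataclass
class SyntheticWorld:
    """A generated benchmark world with planted ground truth."""

    kinases: list[KinaseRecord]
    pssms: dict[str, PSSM]
    sites: list[PhosphositeRecord]
    truth: list[KSPair]
    expression: pd.DataFrame  # protein x context (tissue-like)
    proteomics: pd.DataFrame  # protein x context (proteome-like, noisier)
    phospho_conditions: pd.DataFrame  # site x condition log2FC
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def kinase_ids(self) -> list[str]:
        return [k.kinase_id for k in self.kinases]

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def truth_keys(self) -> set[tuple[str, str]]:
        return {p.key for p in self.truth}

    def kinase_map(self) -> dict[str, KinaseRecord]:
        return {k.kinase_id: k for k in self.kinases}

    def site_map(self) -> dict[str, PhosphositeRecord]:
        return {s.site_id: s for s in self.sites}

    def universe(self) -> list[tuple[str, str]]:
        """All specificity-respecting (kinase, site) pairs."""
        out = []
        for k in self.kinases:
            for s in self.sites:
                if kinase_accepts(k.specificity, s.residue):
                    out.append((k.kinase_id, s.site_id))
        return out

    def substrates_of(self, kinase_id: str) -> list[str]:
        return [p.site_id for p in self.truth if p.kinase_id == kinase_id]


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_pssm(kinase_id: str, rng: np.random.Generator, flank_radius: int) -> PSSM:
    positions = [p for p in range(-flank_radius, flank_radius + 1) if p != 0]
    rows = rng.dirichlet([PSSM_CONCENTRATION] * len(AMINO_ACIDS), size=len(positions))
    # Floor avoids zero cells (PSSM invariant) while keeping rows ~normalized.
    rows = np.maximum(rows, 1e-6)
    rows = rows / rows.sum(axis=1, keepdims=True)
    return PSSM(kinase_id, pd.DataFrame(rows, index=positions, columns=list(AMINO_ACIDS)))


def _sample_flank(
    residue: str,
    pssm: PSSM | None,
    signal_strength: float,
    rng: np.random.Generator,
    flank_radius: int,
) -> str:
    chars = []
    aa_idx = np.arange(len(AMINO_ACIDS))
    for pos in range(-flank_radius, flank_radius + 1):
        if pos == 0:
            chars.append(residue)
            continue
        if pssm is not None and rng.random() < signal_strength:
            probs = pssm.weights.loc[pos].to_numpy()
            probs = probs / probs.sum()
            chars.append(AMINO_ACIDS[rng.choice(aa_idx, p=probs)])
        else:
            chars.append(AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))])
    return "".join(chars)


def generate_world(
    n_kinases: int = 25,
    n_sites: int = 3000,
    n_true_pairs: int = 1500,
    frac_tyr_kinases: float = 0.2,
    frac_dual: float = 0.08,
    signal_strength: float = 0.9,
    n_contexts: int = 30,
    seed: int = 0,
    flank_radius: int = DEFAULT_FLANK_RADIUS,
    n_default_conditions: int = 3,
) -> SyntheticWorld:
    """Generate a seeded synthetic world with ``n_true_pairs`` planted edges.

    ``signal_strength`` controls how strongly a planted site's flank follows
    its kinase's PSSM (position-wise sampling probability; the remainder is
    uniform over amino acids). Expression profiles of a kinase and its true
    substrates share a latent factor, so their correlation exceeds background
    in expectation. Planted sites also receive a right-shifted functional
    score, making that feature informative by construction.
    """
    if not 0 <= frac_tyr_kinases <= 1 or not 0 <= frac_dual <= 1:
        raise ValueError("kinase class fractions must lie in [0, 1]")
    if frac_tyr_kinases + frac_dual > 1:
        raise ValueError("frac_tyr_kinases + frac_dual must be <= 1")
    if not 0 <= signal_strength <= 1:
        raise ValueError("signal_strength must lie in [0, 1]")
    if n_true_pairs > n_kinases * n_sites:
        raise ValueError(
            f"n_true_pairs={n_true_pairs} exceeds n_kinases*n_sites="
            f"{n_kinases * n_sites}"
        )

    (
        rng_kin,
        rng_pssm,
        rng_sites,
        rng_pairs,
        rng_flank,
        rng_fs,
        rng_expr,
        rng_cond,
    ) = _spawn(seed, 8)

    # --- kinome -----------------------------------------------------------
    n_tyr = int(round(frac_tyr_kinases * n_kinases))
    n_dual = int(round(frac_dual * n_kinases))
    specs = (
        [Specificity.TYR] * n_tyr
        + [Specificity.DUAL] * n_dual
        + [Specificity.SER_THR] * (n_kinases - n_tyr - n_dual)
    )
    rng_kin.shuffle(specs)
    families = ["FAM%d" % (i % 6 + 1) for i in range(n_kinases)]
    kinases = [
        KinaseRecord(f"KIN{i + 1:03d}", spec, fam)
        for i, (spec, fam) in enumerate(zip(specs, families))
    ]
    pssms = {
        k.kinase_id: _sample_pssm(k.kinase_id, rng_pssm, flank_radius) for k in kinases
    }

    # --- site scaffold (residues assigned; flanks filled after planting) ---
    # Residue mix loosely follows human phosphoproteomes: mostly S, some T,
    # Tyr fraction tied to the Tyr-kinase fraction so Tyr kinases have targets.
    frac_y_sites = max(0.1, min(0.5, frac_tyr_kinases + frac_dual / 2))
    residues = rng_sites.choice(
        ["S", "T", "Y"],
        size=n_sites,
        p=[(1 - frac_y_sites) * 0.75, (1 - frac_y_sites) * 0.25, frac_y_sites],
    )
    n_proteins = max(1, n_sites // SITES_PER_PROTEIN)
    proteins = [f"PROT{rng_sites.integers(n_proteins) + 1:04d}" for _ in range(n_sites)]
    # Unique 1-based positions within each protein.
    pos_counter: dict[str, int] = {}
    positions = []
    for prot in proteins:
        pos_counter[prot] = pos_counter.get(prot, 0) + rng_sites.integers(1, 30)
        positions.append(pos_counter[prot])

    # --- plant true pairs -------------------------------------------------
    # Greedy seeded assignment: each planted site's flank is drawn from the
    # PSSM of the *first* kinase planted on it.
    compatible: dict[str, list[int]] = {}
    for k in kinases:
        compatible[k.kinase_id] = [
            i for i in range(n_sites) if kinase_accepts(k.specificity, residues[i])
        ]
    truth_keys: set[tuple[str, int]] = set()
    truth: list[tuple[str, int]] = []
    used_sites: set[int] = set()
    attempts = 0
    kin_cycle = [k.kinase_id for k in kinases]
    while len(truth) < n_true_pairs:
        attempts += 1
        if attempts > 50 * n_true_pairs + 100:
            raise ValueError(
                "could not plant the requested number of pairs; "
                "specificity classes leave too small a compatible pair space"
            )
        kid = kin_cycle[len(truth) % len(kin_cycle)]
        pool = compatible[kid]
        if not pool:
            kin_cycle = [k for k in kin_cycle if compatible[k]]
            if not kin_cycle:
                raise ValueError("no kinase has compatible sites left")
            continue
        # Prefer sites not yet planted by another kinase so every planted
        # pair's flank reflects its own kinase's PSSM.
        fresh = [i for i in pool if i not in used_sites]
        pick_pool = fresh if fresh else pool
        si = int(pick_pool[rng_pairs.integers(len(pick_pool))])
        if (kid, si) in truth_keys:
            continue
        truth_keys.add((kid, si))
        used_sites.add(si)
        truth.append((kid, si))

    planting_kinase: dict[int, str] = {}
    for kid, si in truth:
        planting_kinase.setdefault(si, kid)

    # --- flanks and functional scores ------------------------------------
    sites: list[PhosphositeRecord] = []
    for i in range(n_sites):
        pk = planting_kinase.get(i)
        flank = _sample_flank(
            residues[i],
            pssms[pk] if pk is not None else None,
            signal_strength,
            rng_flank,
            flank_radius,
        )
        fs = (
            float(rng_fs.beta(4, 2)) if pk is not None else float(rng_fs.beta(2, 4))
        )
        sites.append(
            PhosphositeRecord.make(proteins[i], residues[i], positions[i], flank, fs)
        )
    truth_pairs = [
        KSPair(kid, sites[si].site_id, Label.POSITIVE) for kid, si in truth
    ]

    # --- expression / proteomics latent-factor model ----------------------
    # One latent factor per kinase; the kinase protein and all its true
    # substrates load on it, background proteins get independent profiles.
    all_proteins = sorted({s.protein_id for s in sites} | {k.kinase_id for k in kinases})
    factors = {
        k.kinase_id: rng_expr.normal(size=n_contexts) for k in kinases
    }
    loading: dict[str, np.ndarray] = {}
    for kid, si in truth:
        prot = sites[si].protein_id
        loading.setdefault(prot, factors[kid])
    for k in kinases:
        loading[k.kinase_id] = factors[k.kinase_id]

    def _matrix(noise_sd: float, rng: np.random.Generator) -> pd.DataFrame:
        rows = []
        for prot in all_proteins:
            base = loading.get(prot)
            if base is None:
                rows.append(rng.normal(size=n_contexts))
            else:
                rows.append(base + rng.normal(scale=noise_sd, size=n_contexts))
        cols = [f"CTX{j + 1:02d}" for j in range(n_contexts)]
        return pd.DataFrame(np.asarray(rows), index=all_proteins, columns=cols)

    expression = _matrix(noise_sd=0.5, rng=rng_expr)
    proteomics = _matrix(noise_sd=1.0, rng=rng_expr)

    world = SyntheticWorld(
        kinases=kinases,
        pssms=pssms,
        sites=sites,
        truth=truth_pairs,
        expression=expression,
        proteomics=proteomics,
        phospho_conditions=pd.DataFrame(index=[s.site_id for s in sites]),
        seed=seed,
        params=dict(
            n_kinases=n_kinases,
            n_sites=n_sites,
            n_true_pairs=n_true_pairs,
            frac_tyr_kinases=frac_tyr_kinases,
            frac_dual=frac_dual,
            signal_strength=signal_strength,
            n_contexts=n_contexts,
            flank_radius=flank_radius,
        ),
    )

    if n_default_conditions > 0:
        cols = {}
        kin_ids = world.kinase_ids
        for j in range(n_default_conditions):
            active = [kin_ids[int(rng_cond.integers(len(kin_ids)))]]
            sub_seed = int(rng_cond.integers(2**31))
            cols[f"COND{j + 1:02d}"] = generate_activation_condition(
                world, active, effect_size=2.0, noise_sd=0.5, seed=sub_seed
            )
        world.phospho_conditions = validate_condition_table(pd.DataFrame(cols))
    return world


def generate_activation_condition(
    world: SyntheticWorld,
    active_kinases: list[str],
    effect_size: float,
    noise_sd: float,
    seed: int,
) -> pd.Series:
    """One condition column: substrates of active kinases shift by ``effect_size``.

    log2FC = effect_size + N(0, noise_sd) for true substrates of any active
    kinase, pure N(0, noise_sd) noise elsewhere.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    known = set(world.kinase_ids)
    unknown = [k for k in active_kinases if k not in known]
    if unknown:
        raise KeyError(f"unknown kinase ids: {unknown}")
    rng = np.random.default_rng(seed)
    active = set(active_kinases)
    substrate_sites = {p.site_id for p in world.truth if p.kinase_id in active}
    values = rng.normal(scale=noise_sd, size=len(world.sites)) if noise_sd > 0 else (
        np.zeros(len(world.sites))
    )
    site_ids = world.site_ids
    values = values + np.array(
        [effect_size if s in substrate_sites else 0.0 for s in site_ids]
    )
    return pd.Series(values, index=site_ids, name="condition")


def generate_condition_table(
    world: SyntheticWorld,
    n_conditions: int,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    kinases_per_condition: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """A ConditionTable of activation conditions plus the active-kinase map."""
    rng = np.random.default_rng(seed)
    cols = {}
    active_map: dict[str, list[str]] = {}
    kin_ids = world.kinase_ids
    for j in range(n_conditions):
        idx = rng.choice(len(kin_ids), size=kinases_per_condition, replace=False)
        active = [kin_ids[int(i)] for i in idx]
        name = f"ACT{j + 1:03d}"
        cols[name] = generate_activation_condition(
            world, active, effect_size, noise_sd, seed=int(rng.integers(2**31))
        )
        active_map[name] = active
    return validate_condition_table(pd.DataFrame(cols)), active_map


def generate_probabilistic_network(
    world: SyntheticWorld,
    true_alpha: float = 4.0,
    true_beta: float = 1.0,
    false_alpha: float = 1.0,
    false_beta: float = 4.0,
    seed: int = 0,
) -> ProbabilisticNetwork:
    """A synthetic scored network whose truth edges stochastically rank higher.

    Edge probabilities are Beta-distributed: planted edges ~ Beta(4, 1)
    (mean 0.8), all other specificity-respecting pairs ~ Beta(1, 4)
    (mean 0.2). Used to exercise downstream network consumers without a full
    training run; labelled synthetic by construction.
    """
    rng = np.random.default_rng(seed)
    truth = world.truth_keys
    records = []
    for kid, sid in world.universe():
        if (kid, sid) in truth:
            p = rng.beta(true_alpha, true_beta)
        else:
            p = rng.beta(false_alpha, false_beta)
        records.append((kid, sid, float(p)))
    return ProbabilisticNetwork.from_records(
        records, provenance={"source": "synthetic", "seed": seed}
    )


def generate_kinase_kinase_network(
    world: SyntheticWorld,
    n_edges: int | None = None,
    seed: int = 0,
) -> ProbabilisticNetwork:
    """A random kinase->kinase regulatory backbone with Beta(2, 2) scores."""
    rng = np.random.default_rng(seed)
    kin = world.kinase_ids
    if n_edges is None:
        n_edges = 2 * len(kin)
    pairs: set[tuple[str, str]] = set()
    guard = 0
    while len(pairs) < n_edges and guard < 100 * n_edges:
        guard += 1
        a, b = rng.choice(len(kin), size=2, replace=False)
        pairs.add((kin[int(a)], kin[int(b)]))
    records = [(a, b, float(rng.beta(2, 2))) for a, b in sorted(pairs)]
    return ProbabilisticNetwork.from_records(
        records, provenance={"source": "synthetic-kk", "seed": seed}
    )
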
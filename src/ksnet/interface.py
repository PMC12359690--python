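"""Readers and writers for the on-disk formats.

One TSV dialect throughout: UTF-8, tab separator, '.' decimal, no quoting,
"NA" as the missing token. Every writer is atomic (write to a temporary file
in the target directory, then rename) and stamps a header comment with the
package version, the seed and a configuration hash; readers skip '#' lines.
Headers carry no timestamps, so identical runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .types import (
    AMINO_ACIDS,
    KinaseRecord,
    KSPair,
    Label,
    PhosphositeRecord,
    ProbabilisticNetwork,
    PSSM,
    Specificity,
    make_site_id,
)

NA = "NA"


def config_hash(config: dict | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(seed: int | None = None, config: dict | None = None) -> str:
    parts = [f"# ksnet v{__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    parts.append(f"# config: {config_hash(config)}")
    return "\n".join(parts) + "\n"


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _fmt(x, decimals=6) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return NA
    if isinstance(x, (float, np.floating)):
        return f"{x:.{decimals}f}"
    return str(x)


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
    decimals: int = 6,
    index: bool = False,
) -> None:
    """Write a DataFrame in the package TSV dialect with a provenance header."""
    out = df.copy()
    if index:
        out = out.reset_index()
    cols = list(out.columns)
    lines = [_header(seed, config), "\t".join(map(str, cols)) + "\n"]
    for row in out.itertuples(index=False):
        lines.append("\t".join(_fmt(v, decimals) for v in row) + "\n")
    atomic_write_text(path, "".join(lines))


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=[NA], keep_default_na=False, **kwargs
    )


# --- networks -------------------------------------------------------------


def write_network(
    net: ProbabilisticNetwork,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    """Tab-separated edge list: kinase_id, site_id, probability (6 dp)."""
    cols = ["kinase_id", "site_id", "probability"]
    if "prob_std" in net.edges.columns:
        cols.append("prob_std")
    write_table(net.edges[cols], path, seed=seed, config=config, decimals=6)


def read_network(path: str | Path) -> ProbabilisticNetwork:
    df = read_table(path)
    return ProbabilisticNetwork(df)


def write_sif(
    edges: list[tuple[str, str]] | ProbabilisticNetwork,
    path: str | Path,
    relation: str = "phosphorylates",
    seed: int | None = None,
) -> None:
    if isinstance(edges, ProbabilisticNetwork):
        pairs = list(zip(edges.edges["kinase_id"], edges.edges["site_id"]))
    else:
        pairs = list(edges)
    lines = [_header(seed)]
    for a, b in pairs:
        lines.append(f"{a}\t{relation}\t{b}\n")
    atomic_write_text(path, "".join(lines))


# --- kinases, sites, pairs ------------------------------------------------


def write_kinases(kinases: list[KinaseRecord], path, seed=None) -> None:
    df = pd.DataFrame(
        [(k.kinase_id, k.specificity.value, k.family) for k in kinases],
        columns=["kinase_id", "specificity", "family"],
    )
    write_table(df, path, seed=seed)


def read_kinases(path) -> list[KinaseRecord]:
    df = read_table(path, dtype=str)
    return [
        KinaseRecord(r.kinase_id, Specificity(r.specificity), r.family)
        for r in df.itertuples(index=False)
    ]


def write_sites(sites: list[PhosphositeRecord], path, seed=None) -> None:
    df = pd.DataFrame(
        [
            (s.site_id, s.protein_id, s.residue, s.position, s.flank,
             s.functional_score)
            for s in sites
        ],
        columns=["site_id", "protein_id", "residue", "position", "flank",
                 "functional_score"],
    )
    write_table(df, path, seed=seed)


def read_sites(path) -> list[PhosphositeRecord]:
    df = read_table(path)
    return [
        PhosphositeRecord(
            str(r.site_id), str(r.protein_id), str(r.residue), int(r.position),
            str(r.flank),
            float(r.functional_score) if pd.notna(r.functional_score) else float("nan"),
        )
        for r in df.itertuples(index=False)
    ]


def read_ks_table(path) -> tuple[list[KSPair], pd.DataFrame]:
    """Parse a curated kinase-substrate table into positive pairs.

    Expects tab-separated columns ``kinase``, ``substrate`` (protein
    accession) and ``site`` (residue letter + 1-based position, e.g. "S455",
    parsed case-insensitively). Malformed rows land in the rejects report
    with their line numbers instead of raising.
    """
    pairs: list[KSPair] = []
    rejects = []
    with open(path, encoding="utf-8") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                required = {"kinase", "substrate", "site"}
                if not required.issubset(header):
                    raise ValueError(
                        f"missing required columns {sorted(required - set(header))}"
                    )
                idx = {name: header.index(name) for name in required}
                continue
            try:
                kinase = fields[idx["kinase"]].strip()
                substrate = fields[idx["substrate"]].strip()
                token = fields[idx["site"]].strip().upper()
                residue, pos_text = token[:1], token[1:]
                position = int(pos_text)
                if residue not in "STY" or position < 1:
                    raise ValueError("bad residue/position token")
                pairs.append(
                    KSPair(kinase, make_site_id(substrate, residue, position),
                           Label.POSITIVE)
                )
            except (IndexError, ValueError) as exc:
                rejects.append({"line": lineno, "text": line.rstrip("\n"),
                                "reason": str(exc)})
    return pairs, pd.DataFrame(rejects, columns=["line", "text", "reason"])


def write_ks_table(pairs: list[KSPair], path, seed=None) -> None:
    rows = []
    for p in pairs:
        prot, res_pos = p.site_id.rsplit("_", 1)
        rows.append((p.kinase_id, prot, res_pos))
    write_table(pd.DataFrame(rows, columns=["kinase", "substrate", "site"]),
                path, seed=seed)


# --- PSSMs ----------------------------------------------------------------


def write_pssm_dir(pssms: dict[str, PSSM], directory, seed=None) -> None:
    """One TSV per kinase: rows = positions, columns = the 20 amino acids."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for kid in sorted(pssms):
        df = pssms[kid].weights.copy()
        df.insert(0, "position", df.index)
        write_table(df, directory / f"{kid}.tsv", seed=seed, decimals=8)


def read_pssm_dir(directory) -> dict[str, PSSM]:
    directory = Path(directory)
    out: dict[str, PSSM] = {}
    for path in sorted(directory.glob("*.tsv")):
        kid = path.stem
        df = read_table(path).set_index("position")
        missing = [aa for aa in AMINO_ACIDS if aa not in df.columns]
        if missing:
            raise ValueError(f"PSSM {kid}: missing amino-acid columns {missing}")
        out[kid] = PSSM(kid, df)
    if not out:
        raise ValueError(f"no PSSM files found under {directory}")
    return out


# --- matrices and condition tables ---------------------------------------


def write_matrix(df: pd.DataFrame, path, seed=None, decimals: int = 6) -> None:
    out = df.copy()
    out.insert(0, out.index.name or "id", out.index)
    write_table(out, path, seed=seed, decimals=decimals)


def read_matrix(path) -> pd.DataFrame:
    df = read_table(path)
    return df.set_index(df.columns[0])


# --- GMT ------------------------------------------------------------------


def write_gmt(gene_sets: dict[str, set[str]], path) -> None:
    lines = []
    for name in sorted(gene_sets):
        members = "\t".join(sorted(gene_sets[name]))
        lines.append(f"{name}\t{name}\t{members}\n")
    atomic_write_text(path, "".join(lines))


def read_gmt(path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line!r}")
            name = fields[0]
            if name in out:
                raise ValueError(f"duplicate gene-set name: {name}")
            out[name] = set(f for f in fields[2:] if f)
    return out


# --- run config and manifests ---------------------------------------------


def load_run_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if "seed" not in cfg:
        raise ValueError("run config must declare a seed")
    return cfg


def write_manifest(path, payload: dict) -> None:
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True,
                                       default=str) + "\n")


# --- synthetic world round-trip -------------------------------------------


def write_world(world, directory, seed: int | None = None) -> None:
    """Write every world component in the formats the readers accept."""
    from .synthetic_data import SyntheticWorld  # local import avoids a cycle

    assert isinstance(world, SyntheticWorld)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seed = world.seed if seed is None else seed
    write_kinases(world.kinases, directory / "kinases.tsv", seed=seed)
    write_sites(world.sites, directory / "sites.tsv", seed=seed)
    write_pssm_dir(world.pssms, directory / "pssms", seed=seed)
    write_ks_table(world.truth, directory / "truth.tsv", seed=seed)
    write_matrix(world.expression, directory / "expression.tsv", seed=seed)
    write_matrix(world.proteomics, directory / "proteomics.tsv", seed=seed)
    write_matrix(world.phospho_conditions, directory / "conditions.tsv", seed=seed)
    write_manifest(directory / "manifest.json",
                   {"seed": world.seed, "params": world.params,
                    "version": __version__})


def read_world(directory):
    from .synthetic_data import SyntheticWorld
    from .types import KSPair, Label

    directory = Path(directory)
    kinases = read_kinases(directory / "kinases.tsv")
    sites = read_sites(directory / "sites.tsv")
    pssms = read_pssm_dir(directory / "pssms")
    pairs, rejects = read_ks_table(directory / "truth.tsv")
    if len(rejects):
        raise ValueError(f"malformed truth rows: {rejects.to_dict('records')[:3]}")
    with open(directory / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    return SyntheticWorld(
        kinases=kinases,
        pssms=pssms,
        sites=sites,
        truth=[KSPair(p.kinase_id, p.site_id, Label.POSITIVE) for p in pairs],
        expression=read_matrix(directory / "expression.tsv"),
        proteomics=read_matrix(directory / "proteomics.tsv"),
        phospho_conditions=read_matrix(directory / "conditions.tsv"),
        seed=int(manifest["seed"]),
        params=manifest.get("params", {}),
    )


# --- feature tables -------------------------------------------------------


def write_feature_table(table, path, seed=None) -> None:
    """FeatureTable as TSV plus a sidecar JSON registry (<path>.registry.json)."""
    df = table.data.reset_index()
    write_table(df, path, seed=seed, decimals=6)
    registry = [
        {"name": d.name, "source": d.source, "transform": d.transform}
        for d in table.registry
    ]
    atomic_write_text(str(path) + ".registry.json",
                      json.dumps(registry, indent=2) + "\n")


def read_feature_table(path):
    from .feature_engine import FeatureDescriptor, FeatureTable

    df = read_table(path).set_index(["kinase_id", "site_id"])
    with open(str(path) + ".registry.json", encoding="utf-8") as fh:
        registry = tuple(FeatureDescriptor(**d) for d in json.load(fh))
    return FeatureTable(df, registry)
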
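"""Shared domain types for kinase-substrate network inference.

The central objects are :class:`PhosphositeRecord` (a phosphorylatable
Ser/Thr/Tyr residue with its +/-5 flanking sequence), :class:`PSSM`
(per-kinase position-specific scoring matrix over the flanking positions),
:class:`KSPair` (a labelled kinase-site relationship) and
:class:`ProbabilisticNetwork` (the scored kinase->site edge list that the
trained ensemble emits and every downstream stage consumes).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

AMINO_ACIDS: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")
PAD = "_"
DEFAULT_FLANK_RADIUS = 5

_SITE_ID_RE = re.compile(r"^(?P<protein>[A-Za-z0-9.\-]+)_(?P<res>[STY])(?P<pos>\d+)$")


class Specificity(str, enum.Enum):
    """Residue specificity class of a kinase.

    DUAL kinases are an *input annotation* (e.g. from curated databases),
    never inferred by this package.
    """

    SER_THR = "SER_THR"
    TYR = "TYR"
    DUAL = "DUAL"


class Label(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNKNOWN = "UNKNOWN"


def residue_class(residue: str) -> str:
    """Map a residue letter to its class, ``"ST"`` or ``"Y"``."""
    if residue in ("S", "T"):
        return "ST"
    if residue == "Y":
        return "Y"
    raise ValueError(f"not a phosphoacceptor residue: {residue!r}")


def kinase_accepts(specificity: Specificity, residue: str) -> bool:
    """Whether a kinase of the given specificity may target ``residue``."""
    cls = residue_class(residue)
    if specificity is Specificity.DUAL:
        return True
    if specificity is Specificity.SER_THR:
        return cls == "ST"
    return cls == "Y"


def make_site_id(protein_id: str, residue: str, position: int) -> str:
    """Canonical site identifier, e.g. ``"P12345_S42"`` (1-based position)."""
    return f"{protein_id}_{residue}{position}"


def parse_site_id(site_id: str) -> tuple[str, str, int]:
    """Split a canonical site id into (protein, residue, position)."""
    m = _SITE_ID_RE.match(site_id)
    if m is None:
        raise ValueError(f"malformed site id: {site_id!r}")
    return m.group("protein"), m.group("res"), int(m.group("pos"))


def site_residue(site_id: str) -> str:
    return parse_site_id(site_id)[1]


@dataclass(frozen=True)
class KinaseRecord:
    kinase_id: str
    specificity: Specificity
    family: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if not isinstance(self.specificity, Specificity):
            object.__setattr__(self, "specificity", Specificity(self.specificity))


@dataclass(frozen=True)
class PhosphositeRecord:
    """A phosphosite with its flanking sequence and optional functional score.

    ``flank`` has length ``2 * flank_radius + 1``; its central character is the
    phosphoacceptor residue; positions beyond the protein termini are padded
    with ``'_'``. ``functional_score`` is a [0, 1] estimate of the site's
    functional relevance (NaN when unknown).
    """

    site_id: str
    protein_id: str
    residue: str
    position: int
    flank: str
    functional_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"{self.site_id}: invalid residue {self.residue!r}")
        if self.position < 1:
            raise ValueError(f"{self.site_id}: position must be >= 1")
        if len(self.flank) % 2 != 1:
            raise ValueError(f"{self.site_id}: flank length must be odd")
        center = self.flank[len(self.flank) // 2]
        if center != self.residue:
            raise ValueError(
                f"{self.site_id}: flank center {center!r} != residue {self.residue!r}"
            )
        for ch in self.flank:
            if ch != PAD and ch not in AMINO_ACIDS:
                raise ValueError(f"{self.site_id}: invalid flank character {ch!r}")
        if self.site_id != make_site_id(self.protein_id, self.residue, self.position):
            raise ValueError(f"site_id {self.site_id!r} inconsistent with fields")

    @classmethod
    def make(
        cls,
        protein_id: str,
        residue: str,
        position: int,
        flank: str,
        functional_score: float = float("nan"),
    ) -> "PhosphositeRecord":
        return cls(
            site_id=make_site_id(protein_id, residue, position),
            protein_id=protein_id,
            residue=residue,
            position=position,
            flank=flank,
            functional_score=functional_score,
        )

    @property
    def flank_radius(self) -> int:
        return len(self.flank) // 2


@dataclass
class PSSM:
    """Position-specific scoring matrix of a kinase over flanking positions.

    ``weights`` is indexed by integer flank position (a contiguous range
    ``-F..+F`` that may include or exclude the central 0 position) with one
    column per amino acid; every cell is strictly positive.
    """

    kinase_id: str
    weights: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [aa for aa in AMINO_ACIDS if aa not in self.weights.columns]
        if missing:
            raise ValueError(f"PSSM {self.kinase_id}: missing amino acids {missing}")
        self.weights = self.weights.loc[:, list(AMINO_ACIDS)].astype(float)
        vals = self.weights.to_numpy()
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError(f"PSSM {self.kinase_id}: all weights must be finite and > 0")
        pos = list(self.weights.index)
        if sorted(pos) != pos:
            self.weights = self.weights.sort_index()
            pos = list(self.weights.index)
        full = list(range(pos[0], pos[-1] + 1))
        if pos != full and pos != [p for p in full if p != 0]:
            raise ValueError(
                f"PSSM {self.kinase_id}: positions must be contiguous "
                f"(optionally excluding 0), got {pos}"
            )

    @property
    def positions(self) -> list[int]:
        return list(self.weights.index)

    def weight(self, position: int, aa: str) -> float:
        return float(self.weights.at[position, aa])


@dataclass(frozen=True)
class KSPair:
    kinase_id: str
    site_id: str
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if not isinstance(self.label, Label):
            object.__setattr__(self, "label", Label(self.label))

    @property
    def key(self) -> tuple[str, str]:
        return (self.kinase_id, self.site_id)


class ProbabilisticNetwork:
    """Scored kinase->phosphosite edge list with per-edge probability.

    Wraps a DataFrame with columns ``kinase_id``, ``site_id``,
    ``probability`` (and optionally ``prob_std``, the across-ensemble-member
    standard deviation). ``provenance`` records run metadata such as the seed,
    the number of ensemble members and the selected feature list.
    """

    def __init__(self, edges: pd.DataFrame, provenance: dict | None = None):
        required = {"kinase_id", "site_id", "probability"}
        if not required.issubset(edges.columns):
            raise ValueError(f"network edges need columns {sorted(required)}")
        edges = edges.reset_index(drop=True)
        p = edges["probability"].to_numpy(dtype=float)
        if p.size and (not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1):
            raise ValueError("edge probabilities must lie in [0, 1]")
        if edges.duplicated(subset=["kinase_id", "site_id"]).any():
            dup = edges[edges.duplicated(subset=["kinase_id", "site_id"])]
            raise ValueError(
                f"duplicate (kinase, site) edges, e.g. {dup.iloc[0].tolist()[:2]}"
            )
        self.edges = edges
        self.provenance = dict(provenance or {})

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, float]],
        provenance: dict | None = None,
    ) -> "ProbabilisticNetwork":
        df = pd.DataFrame(records, columns=["kinase_id", "site_id", "probability"])
        return cls(df, provenance)

    def __len__(self) -> int:
        return len(self.edges)

    def edges_above(self, cutoff: float, strict: bool = True) -> pd.DataFrame:
        """Edges whose probability exceeds ``cutoff`` (strictly by default)."""
        if strict:
            return self.edges[self.edges["probability"] > cutoff]
        return self.edges[self.edges["probability"] >= cutoff]

    def check_specificity(self, kinases: Mapping[str, KinaseRecord]) -> None:
        """Raise if any edge violates its kinase's residue specificity."""
        for kid, sid in zip(self.edges["kinase_id"], self.edges["site_id"]):
            spec = kinases[kid].specificity
            if not kinase_accepts(spec, site_residue(sid)):
                raise ValueError(f"specificity violation: {kid} -> {sid} ({spec.value})")


def summarize_network(net: ProbabilisticNetwork, cutoff: float) -> pd.DataFrame:
    """Per-kinase counts of predictions above ``cutoff``, split by residue class.

    Returns a DataFrame indexed by kinase_id with columns ``n_ST``, ``n_Y``
    and ``n_total``; kinases present in the network but with no edge above the
    cutoff appear with zero counts. An empty network yields an empty summary.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must lie in [0, 1]")
    if len(net) == 0:
        return pd.DataFrame(columns=["n_ST", "n_Y", "n_total"])
    kept = net.edges_above(cutoff, strict=True).copy()
    all_kinases = pd.Index(sorted(net.edges["kinase_id"].unique()), name="kinase_id")
    if kept.empty:
        out = pd.DataFrame(0, index=all_kinases, columns=["n_ST", "n_Y"])
    else:
        kept["residue_class"] = [residue_class(site_residue(s)) for s in kept["site_id"]]
        out = (
            kept.pivot_table(
                index="kinase_id",
                columns="residue_class",
                values="site_id",
                aggfunc="count",
                fill_value=0,
            )
            .reindex(all_kinases, fill_value=0)
            .reindex(columns=["ST", "Y"], fill_value=0)
            .rename(columns={"ST": "n_ST", "Y": "n_Y"})
        )
    out["n_total"] = out["n_ST"] + out["n_Y"]
    return out.astype(int)


def validate_condition_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a phosphosite x condition table of log2 fold changes.

    Columns are condition names (must be unique); rows are site ids. Columns
    with no measured value are dropped with a warning-free report via raise.
    """
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()].tolist()
        raise ValueError(f"duplicate condition names: {dup}")
    empty = [c for c in table.columns if table[c].isna().all()]
    if empty:
        raise ValueError(f"conditions with no measured value: {empty}")
    return table
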
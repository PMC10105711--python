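"""Heterogeneous feature network: block matrix, Russell-Rao reduction, and
per-pair input vectors for the six feature groups.

The universe induces an undirected network whose node classes are drugs,
targets (DT), PPI partners, PMI metabolites, genomic attributes (gene
mutation GM, gene expression GE, differential methylation DM), chemical
features (CF) and cell lines (CL). Relations are encoded as indicator
sub-matrices; the very wide PPI and PMI blocks are not carried into the
classifier directly but reduced to a single Russell-Rao similarity scalar
per drug pair. A drug pair on a cell line is encoded as one vector whose
blocks follow the cumulative feature groups:

    I    DT + CL
    II   + GM
    III  + GE
    IV   + DM
    V    + CF (both drugs, concatenated)
    VI   + the two similarity scalars (PPI, PMI)

DT/GM/GE/DM blocks combine the two drugs by element-wise union (OR); CF
concatenates the two drugs' chemical vectors; CL is one-hot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import PairRecord
from .universe import RelationalUniverse

__all__ = [
    "FeatureSchema",
    "BlockMatrix",
    "PairVector",
    "build_block_matrix",
    "drug_profile",
    "russell_rao_similarity",
    "assemble_pair_vector",
    "build_design_matrix",
    "GROUPS",
]

#: block composition of each cumulative feature group
GROUPS = {
    1: ("DT", "CL"),
    2: ("DT", "GM", "CL"),
    3: ("DT", "GM", "GE", "CL"),
    4: ("DT", "GM", "GE", "DM", "CL"),
    5: ("DT", "GM", "GE", "DM", "CF", "CL"),
    6: ("DT", "GM", "GE", "DM", "CF", "SIM", "CL"),
}

#: block order within an assembled pair vector
_BLOCK_ORDER = ("DT", "GM", "GE", "DM", "CF", "SIM", "CL")


@dataclass
class FeatureSchema:
    """Ordered column layout of every block and the pair-vector assembly rule.

    Widths are per-block; CF is per drug (a pair carries 2 x cf columns) and
    SIM is the fixed pair of similarity scalars. Index maps send entity /
    feature identifiers to their column inside the block.
    """

    dt_index: dict[str, int]
    gm_index: dict[str, int]
    ge_index: dict[str, int]
    dm_index: dict[str, int]
    cl_index: dict[str, int]
    cf_width: int
    combination_mode: dict[str, str] = field(
        default_factory=lambda: {"DT": "union", "GM": "union", "GE": "union",
                                 "DM": "union", "CF": "concat"}
    )

    @classmethod
    def from_universe(cls, universe: RelationalUniverse) -> "FeatureSchema":
        def index(ids):
            return {x: i for i, x in enumerate(ids)}

        return cls(
            dt_index=index(universe.targets),
            gm_index=index(universe.gm_features),
            ge_index=index(universe.ge_features),
            dm_index=index(universe.dm_features),
            cl_index=index(universe.cell_lines),
            cf_width=universe.chem_width,
        )

    def block_width(self, block: str) -> int:
        """Width a block contributes to a *pair* vector."""
        return {
            "DT": len(self.dt_index),
            "GM": len(self.gm_index),
            "GE": len(self.ge_index),
            "DM": len(self.dm_index),
            "CF": 2 * self.cf_width,
            "SIM": 2,
            "CL": len(self.cl_index),
        }[block]

    def group_length(self, group: int) -> int:
        return sum(self.block_width(b) for b in GROUPS[group])

    def group_lengths(self) -> dict[int, int]:
        return {g: self.group_length(g) for g in GROUPS}

    def block_slices(self, group: int) -> dict[str, slice]:
        """Column span of every block inside a given group's pair vector."""
        out, offset = {}, 0
        for block in _BLOCK_ORDER:
            if block in GROUPS[group]:
                w = self.block_width(block)
                out[block] = slice(offset, offset + w)
                offset += w
        return out


@dataclass
class PairVector:
    values: np.ndarray
    group: int
    schema: FeatureSchema


@dataclass
class BlockMatrix:
    """The eight relation sub-matrices with row/column identifier labels.

    Indicator blocks are {0,1}; the chemical block carries the non-negative
    count / real descriptor values.
    """

    d_dt: np.ndarray       # drugs x targets
    dt_ppi: np.ndarray     # targets x proteins
    dt_pmi: np.ndarray     # targets x metabolites
    dt_gm: np.ndarray      # targets x mutation features
    dt_ge: np.ndarray      # targets x expression features
    dt_dm: np.ndarray      # targets x methylation features
    d_cf: np.ndarray       # drugs x chemical features
    d_cl: np.ndarray       # drugs x cell lines
    row_labels: dict[str, list[str]]
    col_labels: dict[str, list[str]]


def _indicator(rows: list[str], cols: list[str], pairs, symmetric=False) -> np.ndarray:
    ri = {x: i for i, x in enumerate(rows)}
    ci = {x: i for i, x in enumerate(cols)}
    m = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for a, b in pairs:
        if a in ri and b in ci:
            m[ri[a], ci[b]] = 1
        if symmetric:
            if b in ri and a in ci:
                m[ri[b], ci[a]] = 1
    return m


def build_block_matrix(
    universe: RelationalUniverse, records: list[PairRecord] | None = None
) -> BlockMatrix:
    """Materialize the feature matrix F as its eight labelled sub-matrices.

    Every indicator entry is 1 exactly where the corresponding relation
    holds. The drug/cell-line block marks (drug, cell line) pairs observed
    in the combination-score records; without records it marks all pairs
    (every drug screened on every line).
    """
    u = universe
    gm_f, ge_f, dm_f = u.gm_features, u.ge_features, u.dm_features
    if records is None:
        d_cl = np.ones((len(u.drugs), len(u.cell_lines)), dtype=np.int8)
    else:
        seen = {(r.drug_i, r.cell_line) for r in records} | {
            (r.drug_j, r.cell_line) for r in records
        }
        d_cl = _indicator(u.drugs, u.cell_lines, seen)
    cf = np.zeros((len(u.drugs), u.chem_width))
    for i, d in enumerate(u.drugs):
        if d in u.chem:
            cf[i] = u.chem[d]
    return BlockMatrix(
        d_dt=_indicator(u.drugs, u.targets, u.dt_edges),
        dt_ppi=_indicator(u.targets, u.proteins, u.ppi_edges, symmetric=True),
        dt_pmi=_indicator(u.targets, u.metabolites, u.pmi_edges),
        dt_gm=_indicator(u.targets, gm_f, u.gm_assoc),
        dt_ge=_indicator(u.targets, ge_f, u.ge_assoc),
        dt_dm=_indicator(u.targets, dm_f, u.dm_assoc),
        d_cf=cf,
        d_cl=d_cl,
        row_labels={
            "d_dt": u.drugs, "dt_ppi": u.targets, "dt_pmi": u.targets,
            "dt_gm": u.targets, "dt_ge": u.targets, "dt_dm": u.targets,
            "d_cf": u.drugs, "d_cl": u.drugs,
        },
        col_labels={
            "d_dt": u.targets, "dt_ppi": u.proteins, "dt_pmi": u.metabolites,
            "dt_gm": gm_f, "dt_ge": ge_f, "dt_dm": dm_f,
            "d_cf": [f"cf_{i}" for i in range(u.chem_width)], "d_cl": u.cell_lines,
        },
    )


class _ProfileCache:
    """Per-drug binary profiles, computed once per universe."""

    def __init__(self, universe: RelationalUniverse, schema: FeatureSchema):
        self.universe = universe
        self.schema = schema
        u = universe
        self._protein_index = {p: i for i, p in enumerate(u.proteins)}
        self._metabolite_index = {m: i for i, m in enumerate(u.metabolites)}
        self._targets_of: dict[str, list[str]] = {d: [] for d in u.drugs}
        for d, t in u.dt_edges:
            self._targets_of[d].append(t)
        self._ppi_partners: dict[str, set[str]] = {}
        for a, b in u.ppi_edges:
            self._ppi_partners.setdefault(a, set()).add(b)
            self._ppi_partners.setdefault(b, set()).add(a)
        self._pmi_of: dict[str, set[str]] = {}
        for t, m in u.pmi_edges:
            self._pmi_of.setdefault(t, set()).add(m)
        self._attrs = {
            "gm": ({}, schema.gm_index),
            "ge": ({}, schema.ge_index),
            "dm": ({}, schema.dm_index),
        }
        for name, assoc in (("gm", u.gm_assoc), ("ge", u.ge_assoc), ("dm", u.dm_assoc)):
            table = self._attrs[name][0]
            for t, f in assoc:
                table.setdefault(t, set()).add(f)
        self._cache: dict[str, dict[str, np.ndarray]] = {}

    def profiles(self, drug: str) -> dict[str, np.ndarray]:
        if drug in self._cache:
            return self._cache[drug]
        if drug not in self.universe.drugs:
            raise KeyError(f"unknown drug: {drug!r}")
        s = self.schema
        targets = self._targets_of.get(drug, [])
        dt = np.zeros(len(s.dt_index), dtype=np.int8)
        for t in targets:
            dt[s.dt_index[t]] = 1
        ppi = np.zeros(len(self._protein_index), dtype=np.int8)
        pmi = np.zeros(len(self._metabolite_index), dtype=np.int8)
        attr_vecs = {}
        for name, (table, index) in self._attrs.items():
            attr_vecs[name] = np.zeros(len(index), dtype=np.int8)
        for t in targets:
            for p in self._ppi_partners.get(t, ()):
                ppi[self._protein_index[p]] = 1
            for m in self._pmi_of.get(t, ()):
                pmi[self._metabolite_index[m]] = 1
            for name, (table, index) in self._attrs.items():
                for f in table.get(t, ()):
                    attr_vecs[name][index[f]] = 1
        out = {"dt": dt, "ppi": ppi, "pmi": pmi,
               "gm": attr_vecs["gm"], "ge": attr_vecs["ge"], "dm": attr_vecs["dm"]}
        self._cache[drug] = out
        return out


def drug_profile(
    universe: RelationalUniverse, drug: str, schema: FeatureSchema | None = None
) -> dict[str, np.ndarray]:
    """Binary relation profiles of one drug.

    Returns the drug-target indicator row plus, through the drug's targets,
    the union PPI-partner, PMI-metabolite and GM/GE/DM attribute profiles: a
    target's associations contribute iff the drug hits that target.
    """
    schema = schema or FeatureSchema.from_universe(universe)
    return _ProfileCache(universe, schema).profiles(drug)


def russell_rao_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Russell-Rao similarity of two equal-length binary vectors.

    The count of positions where both vectors are 1 (positive matches),
    divided by the vector length d. Ranges over [0, 1]; unlike Jaccard,
    shared absences dilute the score because d counts all positions.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.ndim != 1 or b.ndim != 1 or a.shape != b.shape:
        raise ValueError(f"binary vectors must share one dimension: {a.shape} vs {b.shape}")
    d = a.shape[0]
    if d == 0:
        raise ValueError("vector length d must be >= 1")
    return float(np.count_nonzero((a == 1) & (b == 1)) / d)


def assemble_pair_vector(
    universe: RelationalUniverse,
    drug_i: str,
    drug_j: str,
    cell_line: str,
    group: int,
    schema: FeatureSchema | None = None,
    _cache: _ProfileCache | None = None,
) -> PairVector:
    """Encode one drug pair on a cell line as the group's input vector.

    DT/GM/GE/DM blocks are the element-wise OR of the two drugs' profiles;
    the chemical block concatenates both drugs' vectors (canonical pair
    order); the similarity block (group VI) holds the Russell-Rao score of
    the drugs' PPI-partner profiles and of their PMI-metabolite profiles;
    the cell-line block is one-hot.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be 1..6, got {group}")
    if drug_i == drug_j:
        raise ValueError(f"self-pair not allowed: {drug_i!r}")
    schema = schema or FeatureSchema.from_universe(universe)
    cache = _cache or _ProfileCache(universe, schema)
    if cell_line not in schema.cl_index:
        raise KeyError(f"unknown cell line: {cell_line!r}")
    drug_i, drug_j = universe.canonical_pair(drug_i, drug_j)
    pi, pj = cache.profiles(drug_i), cache.profiles(drug_j)

    parts = []
    for block in _BLOCK_ORDER:
        if block not in GROUPS[group]:
            continue
        if block in ("DT", "GM", "GE", "DM"):
            key = block.lower() if block != "DT" else "dt"
            parts.append(np.maximum(pi[key], pj[key]).astype(float))
        elif block == "CF":
            ci = universe.chem.get(drug_i)
            cj = universe.chem.get(drug_j)
            if ci is None or cj is None:
                missing = drug_i if ci is None else drug_j
                raise ValueError(f"drug {missing!r} has no chemical vector")
            parts.append(np.concatenate([ci, cj]).astype(float))
        elif block == "SIM":
            parts.append(np.array([
                russell_rao_similarity(pi["ppi"], pj["ppi"]),
                russell_rao_similarity(pi["pmi"], pj["pmi"]),
            ]))
        elif block == "CL":
            one_hot = np.zeros(len(schema.cl_index))
            one_hot[schema.cl_index[cell_line]] = 1.0
            parts.append(one_hot)
    return PairVector(values=np.concatenate(parts), group=group, schema=schema)


def build_design_matrix(
    universe: RelationalUniverse,
    records: list[PairRecord],
    group: int,
    schema: FeatureSchema | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair vectors for labeled records into (X, y), row-aligned."""
    schema = schema or FeatureSchema.from_universe(universe)
    cache = _ProfileCache(universe, schema)
    n = len(records)
    X = np.empty((n, schema.group_length(group)))
    y = np.empty(n, dtype=np.int64)
    for r, rec in enumerate(records):
        X[r] = assemble_pair_vector(
            universe, rec.drug_i, rec.drug_j, rec.cell_line, group,
            schema=schema, _cache=cache,
        ).values
        y[r] = rec.label
    return X, y
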
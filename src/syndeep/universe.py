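"""Relational universe: entity registries plus the relation tables the feature
network is built from.

The universe holds drugs, cell lines, protein targets, proteins, metabolites,
and eight relations between them: drug->target edges, protein-protein edges,
target->metabolite edges, target<->gene-mutation / gene-expression /
differential-methylation associations, and per-drug chemical feature vectors.
Each relation serializes to one headered TSV; registries are the sorted union
of identifiers so every downstream column layout is reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RelationalUniverse",
    "UniverseValidationError",
    "MissingTableError",
    "load_universe",
    "save_universe",
    "TABLE_FILES",
]


class UniverseValidationError(ValueError):
    """An identifier in a relation table does not resolve to a registry."""


class MissingTableError(FileNotFoundError):
    """A required relation table is absent from the directory."""


#: relation file name -> column headers
TABLE_FILES = {
    "dt.tsv": ("drug_id", "target_id"),
    "ppi.tsv": ("protein_a", "protein_b"),
    "pmi.tsv": ("target_id", "metabolite_id"),
    "gm.tsv": ("target_id", "feature_id"),
    "ge.tsv": ("target_id", "feature_id"),
    "dm.tsv": ("target_id", "feature_id"),
    "cell_lines.tsv": ("cell_line_id",),
    # chem.tsv: drug_id followed by numeric feature columns (variable width)
}


@dataclass
class RelationalUniverse:
    """The heterogeneous universe an undirected feature network is built over.

    Registries are ordered lists (sorted lexicographically on load) and edge
    sets are canonical: protein-protein edges are stored with endpoints in
    sorted order because the network is undirected.
    """

    drugs: list[str] = field(default_factory=list)
    cell_lines: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)
    proteins: list[str] = field(default_factory=list)
    metabolites: list[str] = field(default_factory=list)
    dt_edges: set[tuple[str, str]] = field(default_factory=set)
    ppi_edges: set[tuple[str, str]] = field(default_factory=set)
    pmi_edges: set[tuple[str, str]] = field(default_factory=set)
    gm_assoc: set[tuple[str, str]] = field(default_factory=set)
    ge_assoc: set[tuple[str, str]] = field(default_factory=set)
    dm_assoc: set[tuple[str, str]] = field(default_factory=set)
    chem: dict[str, np.ndarray] = field(default_factory=dict)

    # feature-identifier registries derived from the association tables
    @property
    def gm_features(self) -> list[str]:
        return sorted({f for _, f in self.gm_assoc})

    @property
    def ge_features(self) -> list[str]:
        return sorted({f for _, f in self.ge_assoc})

    @property
    def dm_features(self) -> list[str]:
        return sorted({f for _, f in self.dm_assoc})

    @property
    def chem_width(self) -> int:
        if not self.chem:
            return 0
        return len(next(iter(self.chem.values())))

    def canonical_pair(self, a: str, b: str) -> tuple[str, str]:
        """Order a drug pair by registry position (drug_i before drug_j)."""
        idx = {d: i for i, d in enumerate(self.drugs)}
        return (a, b) if idx[a] < idx[b] else (b, a)

    def validate(self) -> None:
        """Check referential integrity and structural invariants."""
        drugs, targets = set(self.drugs), set(self.targets)
        proteins, metabolites = set(self.proteins), set(self.metabolites)
        offenders: list[str] = []

        def check(pairs, left_reg, right_reg, name):
            for a, b in pairs:
                if left_reg is not None and a not in left_reg:
                    offenders.append(f"{name}: {a!r}")
                if right_reg is not None and b not in right_reg:
                    offenders.append(f"{name}: {b!r}")

        check(self.dt_edges, drugs, targets, "dt")
        check(self.ppi_edges, proteins, proteins, "ppi")
        check(self.pmi_edges, targets, metabolites, "pmi")
        check(self.gm_assoc, targets, None, "gm")
        check(self.ge_assoc, targets, None, "ge")
        check(self.dm_assoc, targets, None, "dm")
        for d in self.chem:
            if d not in drugs:
                offenders.append(f"chem: {d!r}")
        if offenders:
            raise UniverseValidationError(
                "unresolvable identifiers: " + ", ".join(sorted(set(offenders)))
            )
        for a, b in self.ppi_edges:
            if a > b:
                raise UniverseValidationError(
                    f"ppi edge ({a!r}, {b!r}) not in canonical sorted order"
                )
        widths = {len(v) for v in self.chem.values()}
        if len(widths) > 1:
            raise UniverseValidationError(
                f"chemical vectors have inconsistent lengths: {sorted(widths)}"
            )
        missing_chem = drugs - set(self.chem)
        if self.chem and missing_chem:
            raise UniverseValidationError(
                "drugs lacking a chemical vector: " + ", ".join(sorted(missing_chem))
            )


def import_relation_table(
    path: str | os.PathLike, column_map: dict[str, str], sep: str = "\t"
) -> pd.DataFrame:
    """Adapt a third-party relation export to the two-column universe dialect.

    ``column_map`` maps the source file's column names onto the universe
    headers (e.g. DrugBank drug->target exports, STRING two-column protein
    links, HMDB target->metabolite lists). Returns a DataFrame carrying only
    the mapped columns, renamed, ready to be written as a universe table.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in column_map if c not in df.columns]
    if missing:
        raise UniverseValidationError(f"columns not found in {path}: {missing}")
    return df[list(column_map)].rename(columns=column_map)


def _read_table(directory: str, name: str) -> pd.DataFrame:
    path = os.path.join(directory, name)
    if not os.path.exists(path):
        raise MissingTableError(f"missing table: {name} (expected at {path})")
    return pd.read_csv(path, sep="\t", dtype=str)


def load_universe(directory_path: str | os.PathLike) -> RelationalUniverse:
    """Load a universe from its eight-table TSV serialization.

    Registry order is the sorted order of identifiers, so column layouts
    derived downstream are reproducible across loads.
    """
    directory = os.fspath(directory_path)
    frames = {name: _read_table(directory, name) for name in TABLE_FILES}
    chem_path = os.path.join(directory, "chem.tsv")
    if not os.path.exists(chem_path):
        raise MissingTableError(f"missing table: chem.tsv (expected at {chem_path})")
    chem_df = pd.read_csv(chem_path, sep="\t")

    def pairs(name):
        df = frames[name]
        return {(str(a), str(b)) for a, b in df.itertuples(index=False)}

    dt = pairs("dt.tsv")
    ppi = {tuple(sorted(e)) for e in pairs("ppi.tsv")}
    pmi = pairs("pmi.tsv")
    gm, ge, dm = pairs("gm.tsv"), pairs("ge.tsv"), pairs("dm.tsv")

    chem: dict[str, np.ndarray] = {}
    for row in chem_df.itertuples(index=False):
        chem[str(row[0])] = np.asarray(row[1:], dtype=float)

    # Optional registry sidecars keep entities with no incident relation
    # alive across round-trips. A sidecar, when present, is authoritative:
    # relation identifiers outside it fail validation.
    def registry(name, derived):
        path = os.path.join(directory, name)
        if os.path.exists(path):
            df = pd.read_csv(path, sep="\t", dtype=str)
            return set(df.iloc[:, 0])
        return derived

    drugs = sorted(registry("drugs.tsv", set(chem) | {d for d, _ in dt}))
    targets = sorted(registry(
        "targets.tsv",
        {t for _, t in dt}
        | {t for t, _ in pmi}
        | {t for t, _ in gm}
        | {t for t, _ in ge}
        | {t for t, _ in dm},
    ))
    proteins = sorted(registry("proteins.tsv", {p for e in ppi for p in e}))
    universe = RelationalUniverse(
        drugs=drugs,
        cell_lines=sorted(frames["cell_lines.tsv"].iloc[:, 0].astype(str)),
        targets=targets,
        proteins=proteins,
        metabolites=sorted(registry("metabolites.tsv", {m for _, m in pmi})),
        dt_edges=dt,
        ppi_edges=ppi,
        pmi_edges=pmi,
        gm_assoc=gm,
        ge_assoc=ge,
        dm_assoc=dm,
        chem=chem,
    )
    universe.validate()
    return universe


def save_universe(universe: RelationalUniverse, directory_path: str | os.PathLike) -> str:
    """Write the eight-table TSV serialization; round-trips exactly.

    Each file is written to a temporary name then renamed, so a crash cannot
    leave a half-written table under its final name.
    """
    directory = os.fspath(directory_path)
    os.makedirs(directory, exist_ok=True)

    def write(name, header, rows):
        tmp = os.path.join(directory, name + ".tmp")
        pd.DataFrame(sorted(rows), columns=list(header)).to_csv(tmp, sep="\t", index=False)
        os.replace(tmp, os.path.join(directory, name))

    write("dt.tsv", TABLE_FILES["dt.tsv"], universe.dt_edges)
    write("ppi.tsv", TABLE_FILES["ppi.tsv"], universe.ppi_edges)
    write("pmi.tsv", TABLE_FILES["pmi.tsv"], universe.pmi_edges)
    write("gm.tsv", TABLE_FILES["gm.tsv"], universe.gm_assoc)
    write("ge.tsv", TABLE_FILES["ge.tsv"], universe.ge_assoc)
    write("dm.tsv", TABLE_FILES["dm.tsv"], universe.dm_assoc)
    write("cell_lines.tsv", TABLE_FILES["cell_lines.tsv"], [(c,) for c in universe.cell_lines])
    write("drugs.tsv", ("drug_id",), [(d,) for d in universe.drugs])
    write("targets.tsv", ("target_id",), [(t,) for t in universe.targets])
    write("proteins.tsv", ("protein_id",), [(p,) for p in universe.proteins])
    write("metabolites.tsv", ("metabolite_id",), [(m,) for m in universe.metabolites])

    chem_rows = []
    width = universe.chem_width
    for d in sorted(universe.chem):
        chem_rows.append([d, *universe.chem[d].tolist()])
    cols = ["drug_id", *[f"cf_{i}" for i in range(width)]]
    tmp = os.path.join(directory, "chem.tsv.tmp")
    pd.DataFrame(chem_rows, columns=cols).to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, os.path.join(directory, "chem.tsv"))
    return directory
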
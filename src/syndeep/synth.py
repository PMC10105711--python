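"""Synthetic relational universes with a planted, tunable synergy signal.

The generator emulates the relational structure of the curated multi-database
universe the predictor was designed for — drugs with protein targets, a PPI
partner layer, target-metabolite links, binary genomic annotations
(mutation / expression / methylation), per-drug chemical vectors
(substructure counts plus scalar descriptors) and a cell-line panel — with
every relation sampled independently at a configurable edge density.

Labels come from a linear-logistic planted signal in the group-VI pair
feature space: the raw combination score of a pair on a cell line is
``w . x + b`` plus Gaussian noise, its sign giving the synergy class. This
makes the Bayes-optimal behaviour of the whole pipeline analytically known,
so classifier calibration and signal recovery can be tested offline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .featnet import FeatureSchema, _ProfileCache, assemble_pair_vector
from .labels import EXCLUDED, PairRecord, binarize_comboscore
from .universe import RelationalUniverse

__all__ = [
    "SynthConfig",
    "PlantedSignal",
    "generate_universe",
    "paper_consistent_preset",
    "small_preset",
    "plant_labels",
    "center_signal",
    "random_signal",
    "block_signal",
]


@dataclass(frozen=True)
class SynthConfig:
    """Sizes, densities and noise levels of a synthetic universe.

    ``edge_density`` is the independent Bernoulli probability of each
    possible edge in every relation; ``noise_sd`` the standard deviation of
    the Gaussian score noise; ``additive_fraction`` the fraction of pair
    records forced to an exact zero score (the additive class that the
    labeling stage must exclude).
    """

    n_drugs: int = 20
    n_cell_lines: int = 6
    n_targets: int = 40
    n_proteins: int = 80
    n_metabolites: int = 30
    n_gm: int = 15
    n_ge: int = 15
    n_dm: int = 15
    n_fp: int = 16
    n_desc: int = 7
    edge_density: float = 0.08
    noise_sd: float = 1.0
    additive_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        counts = ["n_drugs", "n_cell_lines", "n_targets", "n_proteins",
                  "n_gm", "n_ge", "n_dm", "n_fp", "n_desc"]
        for name in counts:
            if getattr(self, name) < 1:
                raise ValueError(f"config field {name} must be >= 1")
        if self.n_metabolites < 0:
            raise ValueError("config field n_metabolites must be >= 0")
        if not 0 <= self.edge_density <= 1:
            raise ValueError("config field edge_density must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("config field noise_sd must be >= 0")
        if not 0 <= self.additive_fraction < 1:
            raise ValueError("config field additive_fraction must be in [0, 1)")
        if self.n_targets > self.n_proteins:
            raise ValueError("config field n_targets cannot exceed n_proteins "
                             "(targets are proteins)")


@dataclass(frozen=True)
class PlantedSignal:
    """Ground-truth linear signal over the group-VI pair-feature layout."""

    weight_vector: np.ndarray
    intercept: float = 0.0


def paper_consistent_preset(seed: int = 0) -> SynthConfig:
    """Configuration whose derived feature-space arithmetic matches the
    published universe: 74 drugs, 60 cell lines, 333 drug-target columns,
    95 mutation, 264 expression and 334 methylation attributes, and
    256 + 7 = 263 chemical columns per drug — giving cumulative group
    lengths 393, 488, 752, 1086, 1612 and a 1614-long full pair vector.
    """
    return SynthConfig(
        n_drugs=74,
        n_cell_lines=60,
        n_targets=333,
        n_proteins=700,
        n_metabolites=400,
        n_gm=95,
        n_ge=264,
        n_dm=334,
        n_fp=256,
        n_desc=7,
        edge_density=0.05,
        noise_sd=1.0,
        additive_fraction=0.05,
        seed=seed,
    )


def small_preset(seed: int = 0) -> SynthConfig:
    """A reduced universe with the same relational shape, sized so that a
    full cross-validated ablation runs in seconds on one core."""
    return SynthConfig(
        n_drugs=40,
        n_cell_lines=8,
        n_targets=60,
        n_proteins=120,
        n_metabolites=50,
        n_gm=20,
        n_ge=20,
        n_dm=20,
        n_fp=32,
        n_desc=7,
        edge_density=0.08,
        noise_sd=1.0,
        additive_fraction=0.05,
        seed=seed,
    )


def _ids(prefix: str, n: int, width: int = 4) -> list[str]:
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def generate_universe(config: SynthConfig) -> RelationalUniverse:
    """Sample a universe from the config (deterministic under its seed).

    Target identifiers are drawn from the protein registry (a drug target is
    a protein), so PPI partner profiles resolve. When edge_density > 0, each
    genomic attribute is guaranteed at least one target association so the
    attribute registries — and hence downstream column layouts — have the
    configured widths.
    """
    rng = np.random.default_rng(config.seed)
    drugs = _ids("D", config.n_drugs)
    cells = _ids("CL", config.n_cell_lines)
    proteins = _ids("PR", config.n_proteins)
    targets = proteins[: config.n_targets]
    metabolites = _ids("M", config.n_metabolites)
    gm_f = _ids("GM", config.n_gm)
    ge_f = _ids("GE", config.n_ge)
    dm_f = _ids("DM", config.n_dm)
    p = config.edge_density

    def bipartite(rows, cols):
        if not rows or not cols:
            return set()
        mask = rng.random((len(rows), len(cols))) < p
        return {(rows[i], cols[j]) for i, j in zip(*np.nonzero(mask))}

    dt = bipartite(drugs, targets)
    pmi = bipartite(targets, metabolites)
    gm = bipartite(targets, gm_f)
    ge = bipartite(targets, ge_f)
    dm = bipartite(targets, dm_f)

    ppi = set()
    iu = np.triu_indices(len(proteins), k=1)
    mask = rng.random(iu[0].size) < p
    for i, j in zip(iu[0][mask], iu[1][mask]):
        ppi.add((proteins[i], proteins[j]))

    if p > 0:
        # guarantee attribute registry widths: orphan features get one edge
        for assoc, feats in ((gm, gm_f), (ge, ge_f), (dm, dm_f)):
            used = {f for _, f in assoc}
            for f in feats:
                if f not in used:
                    assoc.add((targets[int(rng.integers(len(targets)))], f))

    chem = {}
    for d in drugs:
        counts = rng.poisson(2.0, size=config.n_fp).astype(float)
        descriptors = rng.normal(0.0, 1.0, size=config.n_desc)
        chem[d] = np.concatenate([counts, descriptors])

    universe = RelationalUniverse(
        drugs=drugs, cell_lines=cells, targets=targets, proteins=proteins,
        metabolites=metabolites, dt_edges=dt, ppi_edges=ppi, pmi_edges=pmi,
        gm_assoc=gm, ge_assoc=ge, dm_assoc=dm, chem=chem,
    )
    universe.validate()
    return universe


def random_signal(schema: FeatureSchema, seed: int = 0, scale: float = 1.0,
                  intercept: float = 0.0) -> PlantedSignal:
    """Dense Gaussian weights over the full (group-VI) pair-vector layout,
    normalized so the weight vector has unit RMS entry before scaling."""
    rng = np.random.default_rng(seed)
    dim = schema.group_length(6)
    w = rng.normal(0.0, 1.0, size=dim)
    w *= scale / np.sqrt(np.mean(w ** 2))
    return PlantedSignal(weight_vector=w, intercept=intercept)


def block_signal(schema: FeatureSchema, blocks: tuple[str, ...], seed: int = 0,
                 scale: float = 1.0, intercept: float = 0.0) -> PlantedSignal:
    """Gaussian weights confined to the named blocks of the group-VI layout
    (zero elsewhere) — for ablation experiments where the signal is known to
    live in specific feature blocks."""
    rng = np.random.default_rng(seed)
    dim = schema.group_length(6)
    w = np.zeros(dim)
    slices = schema.block_slices(6)
    for block in blocks:
        sl = slices[block]
        w[sl] = rng.normal(0.0, 1.0, size=sl.stop - sl.start)
    nz = w != 0
    if nz.any():
        w[nz] *= scale / np.sqrt(np.mean(w[nz] ** 2))
    return PlantedSignal(weight_vector=w, intercept=intercept)


def _resolve_signal(universe, signal, config) -> tuple[FeatureSchema, PlantedSignal]:
    schema = FeatureSchema.from_universe(universe)
    dim = schema.group_length(6)
    if isinstance(signal, str):
        if signal != "random":
            raise ValueError(f"signal must be a PlantedSignal or 'random', got {signal!r}")
        signal = random_signal(schema, seed=config.seed)
    w = np.asarray(signal.weight_vector, dtype=float)
    if w.shape != (dim,):
        raise ValueError(
            f"signal length {w.shape} does not match group-VI layout ({dim},)"
        )
    return schema, signal


def _noiseless_scores(universe, signal, schema) -> np.ndarray:
    """w . pair_vector + intercept for every unordered pair x cell line, in
    (pair-major, cell-line-minor) enumeration order."""
    w = np.asarray(signal.weight_vector, dtype=float)
    cache = _ProfileCache(universe, schema)
    slices = schema.block_slices(6)
    w_cl = w[slices["CL"]]
    drugs = universe.drugs
    out = []
    for ai in range(len(drugs)):
        for bi in range(ai + 1, len(drugs)):
            vec = assemble_pair_vector(universe, drugs[ai], drugs[bi],
                                       universe.cell_lines[0], 6,
                                       schema=schema, _cache=cache).values
            # cell-line-independent part; the one-hot block adds w_cl[cl]
            base = float(w[: slices["CL"].start] @ vec[: slices["CL"].start])
            out.append(base + signal.intercept + w_cl)
    return np.concatenate(out) if out else np.empty(0)


def center_signal(
    universe: RelationalUniverse,
    signal: PlantedSignal | str,
    config: SynthConfig,
) -> PlantedSignal:
    """Return the signal with its intercept shifted so the median noiseless
    score over all pair/cell-line combinations is zero.

    Feature blocks are non-negative, so an arbitrary weight vector pushes
    every score by a large common offset and a single class dominates;
    centering on the median makes the planted classes balanced by
    construction.
    """
    schema, signal = _resolve_signal(universe, signal, config)
    median = float(np.median(_noiseless_scores(universe, signal, schema)))
    return PlantedSignal(signal.weight_vector, signal.intercept - median)


def plant_labels(
    universe: RelationalUniverse,
    signal: PlantedSignal | str,
    config: SynthConfig,
) -> list[PairRecord]:
    """Score every unordered drug pair on every cell line from the planted
    linear signal plus Gaussian noise; a seeded fraction is forced additive.

    Raw score = w . pair_vector(group VI) + intercept + N(0, noise_sd). The
    combination score keeps its sign and magnitude; binarization then gives
    1 / 0 / excluded by sign. Identical seeds give identical records.
    """
    schema, signal = _resolve_signal(universe, signal, config)
    rng = np.random.default_rng(config.seed + 1)
    scores = _noiseless_scores(universe, signal, schema)
    if config.noise_sd > 0:
        scores = scores + rng.normal(0.0, config.noise_sd, size=scores.size)

    records: list[PairRecord] = []
    drugs = universe.drugs
    pos = 0
    for ai in range(len(drugs)):
        for bi in range(ai + 1, len(drugs)):
            for cl in universe.cell_lines:
                s = float(scores[pos])
                records.append(PairRecord(drugs[ai], drugs[bi], cl, s,
                                          binarize_comboscore(s)))
                pos += 1
    if config.additive_fraction > 0 and records:
        n_zero = int(round(config.additive_fraction * len(records)))
        zero_idx = rng.choice(len(records), size=n_zero, replace=False)
        for i in zero_idx:
            r = records[i]
            records[i] = PairRecord(r.drug_i, r.drug_j, r.cell_line, 0.0, EXCLUDED)
    return records
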
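"""Per-drug chemical feature vectors computed from structures.

A drug's chemical block is a folded circular-substructure count fingerprint
(Morgan counts, default 256 slots at radius 2) followed by seven scalar
descriptors: topological polar surface area (A^2), molecular weight (Da),
logP, aliphatic ring count, aromatic ring count, H-bond donor count and
H-bond acceptor count — 263 values per drug by default. When a chem.tsv
table is supplied to the universe loader it overrides structure computation,
so synthetic runs never need a chemistry engine; this module is only
imported when structures are actually featurized.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator, rdMolDescriptors

__all__ = ["ChemVector", "DESCRIPTOR_NAMES", "featurize_structure", "featurize_smiles_table"]

DESCRIPTOR_NAMES = (
    "tpsa", "mol_weight", "logp",
    "aliphatic_rings", "aromatic_rings", "h_donors", "h_acceptors",
)


@dataclass(frozen=True)
class ChemVector:
    """Folded substructure counts plus the seven scalar descriptors."""

    counts: np.ndarray
    descriptors: np.ndarray

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.counts, self.descriptors])

    def __len__(self) -> int:
        return len(self.counts) + len(self.descriptors)


def featurize_structure(structure: str, fp_bits: int = 256, radius: int = 2) -> ChemVector:
    """Compute the chemical feature vector of one SMILES structure.

    Counts are fold-summed circular-substructure occurrences: every (atom,
    radius) environment is hashed into one of ``fp_bits`` slots, so the
    total count is invariant to the slot count — folding redistributes,
    never drops.
    """
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=fp_bits)
    fp = gen.GetCountFingerprint(mol)
    counts = np.zeros(fp_bits)
    for slot, count in fp.GetNonzeroElements().items():
        counts[slot] = count
    descriptors = np.array([
        rdMolDescriptors.CalcTPSA(mol),
        Descriptors.MolWt(mol),
        Crippen.MolLogP(mol),
        Lipinski.NumAliphaticRings(mol),
        Lipinski.NumAromaticRings(mol),
        # classic Lipinski definitions: donors = O-H/N-H hydrogens,
        # acceptors = N + O count
        Lipinski.NHOHCount(mol),
        Lipinski.NOCount(mol),
    ], dtype=float)
    return ChemVector(counts=counts, descriptors=descriptors)


def featurize_smiles_table(path: str | os.PathLike, fp_bits: int = 256,
                           radius: int = 2) -> dict[str, np.ndarray]:
    """Featurize a (drug_id, smiles) TSV into a universe chem mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        out[str(row[0])] = featurize_structure(str(row[1]), fp_bits=fp_bits,
                                               radius=radius).vector
    return out
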
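"""ComboScore binarization, replicate aggregation, and class balancing.

The combination benefit score (ComboScore) is a modified Bliss-independence
score: positive means synergistic, negative antagonistic, zero additive.
Classification works on the sign alone — label 1 for synergy, 0 for
antagonism — and additive (zero-score) records are excluded. Because screens
are antagonist-heavy, the majority class is down-sampled to the minority
count before model fitting.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUDED",
    "PairRecord",
    "binarize_comboscore",
    "aggregate_replicates",
    "balance_classes",
    "read_combos",
    "write_labels",
    "read_labels",
]

#: sentinel label for additive (zero-score) combinations
EXCLUDED = "excluded"


@dataclass(frozen=True)
class PairRecord:
    """One labeled drug-pair measurement on a cell line.

    ``drug_i`` precedes ``drug_j`` in registry order; the label is the sign
    of the combo score (1 synergistic, 0 antagonistic, EXCLUDED if zero).
    """

    drug_i: str
    drug_j: str
    cell_line: str
    combo_score: float
    label: int | str

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.drug_i, self.drug_j, self.cell_line)


def binarize_comboscore(score: float) -> int | str:
    """Map a combo score to a binary synergy label by its sign.

    Positive scores are synergistic (1), negative antagonistic (0), and an
    exact zero — the additive case — is excluded from classification. The
    empirical score ranges seen in combination screens (roughly 1..200 and
    -1..-228) carry no special meaning: only the sign is used, with no
    clamping.
    """
    if not math.isfinite(score):
        raise ValueError(f"combo score must be finite, got {score!r}")
    if score > 0:
        return 1
    if score < 0:
        return 0
    return EXCLUDED


def _canonicalize(rec: PairRecord, drug_order: dict[str, int] | None) -> PairRecord:
    a, b = rec.drug_i, rec.drug_j
    if drug_order is not None:
        swap = drug_order[a] > drug_order[b]
    else:
        swap = a > b
    if swap:
        rec = replace(rec, drug_i=b, drug_j=a)
    return rec


def aggregate_replicates(
    records: list[PairRecord], drug_order: list[str] | None = None
) -> list[PairRecord]:
    """Collapse replicate measurements of one (drug_i, drug_j, cell line)
    triple to a single record with the arithmetic-mean score.

    Drug order inside each pair is canonicalized first, so (B, A, cl) and
    (A, B, cl) merge. The mean is taken before binarization; output order
    follows first appearance of each triple.
    """
    order = {d: i for i, d in enumerate(drug_order)} if drug_order is not None else None
    groups: dict[tuple[str, str, str], list[float]] = {}
    for rec in records:
        rec = _canonicalize(rec, order)
        groups.setdefault(rec.key, []).append(rec.combo_score)
    out = []
    for (di, dj, cl), scores in groups.items():
        mean = float(np.mean(scores))
        out.append(PairRecord(di, dj, cl, mean, binarize_comboscore(mean)))
    return out


def balance_classes(records: list[PairRecord], seed: int) -> list[PairRecord]:
    """Down-sample the majority class to the minority count (seeded).

    Expects excluded records to have been removed already. The output is a
    subset of the input with exactly equal class counts, deterministically
    shuffled by ``seed``.
    """
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    if not pos or not neg:
        raise ValueError("cannot balance: a class is empty")
    rng = np.random.default_rng(seed)
    n = min(len(pos), len(neg))
    keep_pos = [pos[i] for i in rng.choice(len(pos), size=n, replace=False)]
    keep_neg = [neg[i] for i in rng.choice(len(neg), size=n, replace=False)]
    out = keep_pos + keep_neg
    rng.shuffle(out)
    return out


def read_combos(path: str | os.PathLike) -> list[PairRecord]:
    """Read a combos.tsv (drug_i, drug_j, cell_line, comboscore) into
    labeled records (labels by sign; no aggregation or canonicalization)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: str})
    out = []
    for row in df.itertuples(index=False):
        score = float(row[3])
        out.append(PairRecord(str(row[0]), str(row[1]), str(row[2]), score,
                              binarize_comboscore(score)))
    return out


def write_labels(records: list[PairRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(r.drug_i, r.drug_j, r.cell_line, r.combo_score, r.label) for r in records],
        columns=["drug_i", "drug_j", "cell_line", "comboscore", "label"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | os.PathLike) -> list[PairRecord]:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str, 2: str})
    out = []
    for row in df.itertuples(index=False):
        label = row[4]
        if label != EXCLUDED:
            label = int(label)
        out.append(PairRecord(str(row[0]), str(row[1]), str(row[2]), float(row[3]), label))
    return out
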
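"""In-silico enzyme mining and saturation-mutagenesis screening.

Two workflows rank candidate enzymes by a trained model's predicted kinetic
parameter against a fixed substrate:

* *mine* — score every sequence in a FASTA file (e.g. homologs retrieved by a
  BLASTp search) and return the top k;
* *mutate* — enumerate every single-point variant of one parent sequence
  (19 substitutions × L positions), score all of them, and return the top k.

Ranking is by predicted value descending with stable input-order tie-breaks,
so reports are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .models import TrainedModel
from .representation import PairFeaturizer

#: The 20 canonical amino acids, alphabetical one-letter codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_AA)


@dataclass(frozen=True)
class MutantVariant:
    """A single-point substitution variant of a parent sequence."""

    parent_id: str
    position: int  # 1-based
    original_residue: str
    substituted_residue: str
    sequence: str

    @property
    def tag(self) -> str:
        """Conventional mutation label, e.g. ``M1A``."""
        return f"{self.original_residue}{self.position}{self.substituted_residue}"


def enumerate_single_mutants(
    sequence: str, parent_id: str = "parent", alphabet: str = CANONICAL_AA
) -> list[MutantVariant]:
    """All single-point variants over the canonical alphabet: exactly 19·L.

    Order is deterministic: position-major, then alphabet order of the
    substituted residue. Every variant differs from the parent at exactly one
    position; the unmutated parent is never included.
    """
    if not sequence:
        raise ValueError("parent sequence must be nonempty")
    alphabet_set = set(alphabet)
    for i, residue in enumerate(sequence):
        if residue not in alphabet_set:
            raise ValueError(
                f"residue {residue!r} at position {i + 1} is outside the alphabet"
            )
    variants = []
    for i, original in enumerate(sequence):
        for substitute in alphabet:
            if substitute == original:
                continue
            variants.append(
                MutantVariant(
                    parent_id,
                    i + 1,
                    original,
                    substitute,
                    sequence[:i] + substitute + sequence[i + 1:],
                )
            )
    return variants


@dataclass(frozen=True)
class ScreenReport:
    """Ranked screening results plus provenance metadata."""

    rows: tuple  # (candidate_id, mutation_tag | None, predicted_value, rank)
    parameter_kind: str
    k: int
    n_candidates: int
    embedder_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["candidate_id", "mutation", "predicted_value", "rank"]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def rank_candidates(
    candidate_ids: Sequence[str],
    scores: np.ndarray,
    k: int,
    parameter_kind: str = "kcat",
    mutation_tags: Sequence[str] | None = None,
    embedder_id: str | None = None,
) -> ScreenReport:
    """Top-k candidates by predicted value, descending; stable on ties."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    scores = np.asarray(scores, dtype=float).reshape(-1)
    if scores.size == 0:
        raise ValueError("candidate list must be nonempty")
    if len(candidate_ids) != scores.size:
        raise ValueError("candidate ids must align with scores")
    order = np.argsort(-scores, kind="stable")[: min(k, scores.size)]
    rows = tuple(
        (
            candidate_ids[i],
            mutation_tags[i] if mutation_tags is not None else None,
            float(scores[i]),
            rank + 1,
        )
        for rank, i in enumerate(order)
    )
    return ScreenReport(rows, parameter_kind, k, int(scores.size), embedder_id)


def score_sequences(
    model: TrainedModel,
    featurizer: PairFeaturizer,
    sequences: Sequence[str],
    substrate_smiles: str,
) -> np.ndarray:
    """Predict the model's parameter for each sequence against one substrate."""
    features = featurizer.feature_matrix(sequences, [substrate_smiles] * len(sequences))
    return model.predict(features)


def screen_fasta(
    model: TrainedModel,
    featurizer: PairFeaturizer,
    fasta_path: str | Path,
    substrate_smiles: str,
    k: int = 5,
    mode: str = "mine",
) -> ScreenReport:
    """Run a mining or saturation-mutagenesis screen from a FASTA file.

    ``mine`` scores every record against the fixed substrate. ``mutate``
    requires exactly one parent record, enumerates its 19·L single-point
    variants, and scores those instead.
    """
    if mode not in {"mine", "mutate"}:
        raise ValueError("mode must be 'mine' or 'mutate'")
    fasta_records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not fasta_records:
        raise ValueError(f"no sequences found in {fasta_path}")

    if mode == "mine":
        ids = [rec.id for rec in fasta_records]
        sequences = [str(rec.seq).upper() for rec in fasta_records]
        tags = None
    else:
        if len(fasta_records) != 1:
            raise ValueError(
                f"mutate mode requires exactly one parent record, got {len(fasta_records)}"
            )
        parent = fasta_records[0]
        variants = enumerate_single_mutants(str(parent.seq).upper(), parent.id)
        ids = [f"{parent.id}-{v.tag}" for v in variants]
        sequences = [v.sequence for v in variants]
        tags = [v.tag for v in variants]

    scores = score_sequences(model, featurizer, sequences, substrate_smiles)
    return rank_candidates(
        ids,
        scores,
        k,
        parameter_kind=model.parameter_kind,
        mutation_tags=tags,
        embedder_id=featurizer.embedder.embedder_id,
    )
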
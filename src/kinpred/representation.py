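"""Fixed-length feature vectors for enzymes, substrates, and enzyme–substrate pairs.

A pretrained protein language model turns an amino-acid sequence of length L
into an L×D matrix of per-residue embeddings; a SMILES encoder does the same
for the symbols of a substrate string. This module pools those variable-length
matrices into fixed-length vectors:

* protein: mean over residues of the last hidden layer (dimension D_p);
* molecule: concatenation of mean pooling, max pooling, and the first-position
  outputs of the last and penultimate layers (dimension 4·D_m);
* pair: protein block followed by molecule block;
* pair_with_condition: pair followed by one raw environmental scalar
  (pH or temperature).

Real encoders are consumed through the :class:`Embedder` plugin contract;
:class:`SyntheticHashEmbedder` is a deterministic stand-in that lets the whole
pipeline run and be tested without pretrained weights. In the reference
configuration D_p = 1024 and D_m = 256, giving 1024-d protein and molecule
vectors and a 2048-d pair.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

#: Per-token dimensions of the reference (pretrained-encoder) configuration.
REFERENCE_PROTEIN_TOKEN_DIM = 1024
REFERENCE_MOLECULE_TOKEN_DIM = 256

VALID_KINDS = ("protein", "molecule", "pair", "pair_with_condition")


@dataclass(frozen=True)
class TokenEmbeddingMatrix:
    """Per-token embeddings for one sequence: an L×D matrix plus token labels."""

    tokens: tuple
    values: np.ndarray
    layer_tag: str = "last"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("embedding matrix must be 2-dimensional (L×D)")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError("embedding matrix needs at least one token and one dimension")
        if len(self.tokens) != values.shape[0]:
            raise ValueError(
                f"{len(self.tokens)} tokens but {values.shape[0]} embedding rows"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("embedding matrix contains non-finite values")
        object.__setattr__(self, "values", values)

    @property
    def n_tokens(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class RepresentationVector:
    """A pooled, fixed-length feature vector with its semantic kind."""

    values: np.ndarray
    kind: str

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("representation must be a nonempty 1-d vector")
        if not np.all(np.isfinite(values)):
            raise ValueError("representation contains non-finite values")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown representation kind {self.kind!r}")
        object.__setattr__(self, "values", values)

    @property
    def dim(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EmbedderSpec:
    """Identifies an embedder plugin and its per-token output dimensions."""

    embedder_id: str
    protein_token_dim: int = REFERENCE_PROTEIN_TOKEN_DIM
    molecule_token_dim: int = REFERENCE_MOLECULE_TOKEN_DIM
    seed: int = 0

    def __post_init__(self):
        if not self.embedder_id:
            raise ValueError("embedder_id must be nonempty")
        if self.protein_token_dim < 1 or self.molecule_token_dim < 1:
            raise ValueError("token dimensions must be positive")


# ---------------------------------------------------------------------------
# Pooling operations
# ---------------------------------------------------------------------------

def pool_protein_mean(matrix: TokenEmbeddingMatrix) -> RepresentationVector:
    """Mean-pool residue embeddings into a per-protein vector of length D."""
    return RepresentationVector(matrix.values.mean(axis=0), "protein")


def assemble_molecule_vector(
    last: TokenEmbeddingMatrix, penultimate: TokenEmbeddingMatrix
) -> RepresentationVector:
    """Assemble a per-molecule vector of length 4·D.

    Blocks, in order: mean pooling of the last layer, elementwise max pooling
    of the last layer, the first-position row of the last layer, and the
    first-position row of the penultimate layer.
    """
    if last.values.shape != penultimate.values.shape:
        raise ValueError(
            f"layer shapes differ: last {last.values.shape} vs "
            f"penultimate {penultimate.values.shape}"
        )
    blocks = [
        last.values.mean(axis=0),
        last.values.max(axis=0),
        last.values[0],
        penultimate.values[0],
    ]
    return RepresentationVector(np.concatenate(blocks), "molecule")


def concat_pair(
    protein: RepresentationVector,
    molecule: RepresentationVector,
    protein_dim: int | None = None,
    molecule_dim: int | None = None,
) -> RepresentationVector:
    """Concatenate protein and molecule vectors into a pair vector.

    The protein block occupies the leading positions, the molecule block the
    trailing ones; slicing recovers both exactly. Pass ``protein_dim`` /
    ``molecule_dim`` to enforce a dimension contract (e.g. 1024/1024 in the
    reference configuration, giving a 2048-d pair).
    """
    if protein.kind != "protein":
        raise ValueError(f"first argument must be a protein vector, got {protein.kind!r}")
    if molecule.kind != "molecule":
        raise ValueError(f"second argument must be a molecule vector, got {molecule.kind!r}")
    if protein_dim is not None and protein.dim != protein_dim:
        raise ValueError(f"protein vector has dim {protein.dim}, expected {protein_dim}")
    if molecule_dim is not None and molecule.dim != molecule_dim:
        raise ValueError(f"molecule vector has dim {molecule.dim}, expected {molecule_dim}")
    return RepresentationVector(
        np.concatenate([protein.values, molecule.values]), "pair"
    )


def append_condition(
    pair: RepresentationVector, condition: float
) -> RepresentationVector:
    """Append one raw (unscaled) environmental scalar to a pair vector."""
    if pair.kind != "pair":
        raise ValueError(f"expected a pair vector, got {pair.kind!r}")
    condition = float(condition)
    if not np.isfinite(condition):
        raise ValueError("condition value must be finite")
    return RepresentationVector(
        np.concatenate([pair.values, [condition]]), "pair_with_condition"
    )


# ---------------------------------------------------------------------------
# Embedder plugin contract
# ---------------------------------------------------------------------------

@runtime_checkable
class Embedder(Protocol):
    """Plugin contract for sequence encoders.

    Implementations wrap a real pretrained encoder (protein language model,
    SMILES transformer) or a synthetic stand-in. ``embed_protein`` returns the
    last-layer matrix for an amino-acid sequence; ``embed_molecule`` returns
    the (last, penultimate) layer pair for a SMILES string.
    """

    embedder_id: str
    protein_token_dim: int
    molecule_token_dim: int

    def embed_protein(self, sequence: str) -> TokenEmbeddingMatrix: ...

    def embed_molecule(
        self, smiles: str
    ) -> tuple[TokenEmbeddingMatrix, TokenEmbeddingMatrix]: ...


class SyntheticHashEmbedder:
    """Deterministic hash-based embedder for testing and synthetic fixtures.

    Each (token, position) pair maps, through a cryptographic hash of
    ``(seed, salt, position, token)``, to a fixed pseudo-random row with
    entries in [−1, 1]. The mapping is stable across processes, sensitive to
    the seed, and distinct sequences collide only with negligible probability.
    Rows are memoised, so embedding many sequences over a small alphabet costs
    one hash per distinct (token, position).
    """

    def __init__(
        self,
        protein_token_dim: int = REFERENCE_PROTEIN_TOKEN_DIM,
        molecule_token_dim: int = REFERENCE_MOLECULE_TOKEN_DIM,
        seed: int = 0,
    ):
        if protein_token_dim < 1 or molecule_token_dim < 1:
            raise ValueError("token dimensions must be positive")
        self.protein_token_dim = int(protein_token_dim)
        self.molecule_token_dim = int(molecule_token_dim)
        self.seed = int(seed)
        self.embedder_id = (
            f"synthetic-hash-p{self.protein_token_dim}"
            f"-m{self.molecule_token_dim}-s{self.seed}"
        )
        self._row_cache: dict = {}

    def spec(self) -> EmbedderSpec:
        return EmbedderSpec(
            self.embedder_id, self.protein_token_dim, self.molecule_token_dim, self.seed
        )

    def _token_row(self, token: str, position: int, dim: int, salt: str) -> np.ndarray:
        key = (token, position, dim, salt)
        row = self._row_cache.get(key)
        if row is None:
            digest = hashlib.blake2b(
                f"{self.seed}|{salt}|{position}|{token}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            row = rng.uniform(-1.0, 1.0, size=dim)
            row.setflags(write=False)
            self._row_cache[key] = row
        return row

    def _embed(self, sequence: str, dim: int, salt: str, layer_tag: str) -> TokenEmbeddingMatrix:
        if not sequence:
            raise ValueError("cannot embed an empty sequence")
        rows = [self._token_row(t, i, dim, salt) for i, t in enumerate(sequence)]
        return TokenEmbeddingMatrix(tuple(sequence), np.vstack(rows), layer_tag)

    def embed_protein(self, sequence: str) -> TokenEmbeddingMatrix:
        return self._embed(sequence, self.protein_token_dim, "protein-last", "last")

    def embed_molecule(
        self, smiles: str
    ) -> tuple[TokenEmbeddingMatrix, TokenEmbeddingMatrix]:
        last = self._embed(smiles, self.molecule_token_dim, "molecule-last", "last")
        penultimate = self._embed(
            smiles, self.molecule_token_dim, "molecule-penultimate", "penultimate"
        )
        return last, penultimate


# ---------------------------------------------------------------------------
# High-level featurisation
# ---------------------------------------------------------------------------

class PairFeaturizer:
    """Turn (sequence, SMILES[, condition]) inputs into model-ready vectors.

    The pair dimension is ``protein_token_dim + 4 × molecule_token_dim``
    (2048 in the reference configuration). An optional
    :class:`EmbeddingCache` avoids recomputing pooled vectors.
    """

    def __init__(self, embedder: Embedder, cache: "EmbeddingCache | None" = None):
        self.embedder = embedder
        self.cache = cache

    @property
    def pair_dim(self) -> int:
        return self.embedder.protein_token_dim + 4 * self.embedder.molecule_token_dim

    def protein_vector(self, sequence: str) -> RepresentationVector:
        if self.cache is not None:
            return RepresentationVector(
                self.cache.protein_vector(self.embedder, sequence), "protein"
            )
        return pool_protein_mean(self.embedder.embed_protein(sequence))

    def molecule_vector(self, smiles: str) -> RepresentationVector:
        if self.cache is not None:
            return RepresentationVector(
                self.cache.molecule_vector(self.embedder, smiles), "molecule"
            )
        return assemble_molecule_vector(*self.embedder.embed_molecule(smiles))

    def pair_vector(self, sequence: str, smiles: str) -> RepresentationVector:
        return concat_pair(self.protein_vector(sequence), self.molecule_vector(smiles))

    def feature_matrix(
        self,
        sequences: Sequence[str],
        smiles: Sequence[str],
        conditions: Sequence[float] | None = None,
    ) -> np.ndarray:
        """Stack pair vectors (optionally with a condition column) row-wise."""
        if len(sequences) != len(smiles):
            raise ValueError("sequences and smiles must have equal length")
        if conditions is not None and len(conditions) != len(sequences):
            raise ValueError("conditions must align with sequences")
        rows = []
        for i, (seq, smi) in enumerate(zip(sequences, smiles)):
            vec = self.pair_vector(seq, smi)
            if conditions is not None:
                vec = append_condition(vec, conditions[i])
            rows.append(vec.values)
        if not rows:
            width = self.pair_dim + (0 if conditions is None else 1)
            return np.empty((0, width))
        return np.vstack(rows)


class EmbeddingCache:
    """On-disk store of pooled representation vectors.

    Vectors are keyed by ``(embedder_id, content hash of the sequence)`` and
    stored as ``.npy`` files, so a cache hit round-trips byte-identically to a
    fresh computation.
    """

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, embedder_id: str, kind: str, sequence: str) -> Path:
        content = hashlib.sha256(sequence.encode()).hexdigest()
        safe_id = embedder_id.replace("/", "_")
        return self.root / safe_id / f"{kind}-{content}.npy"

    def _get_or_compute(self, embedder: Embedder, kind: str, sequence: str, compute):
        path = self._path(embedder.embedder_id, kind, sequence)
        if path.exists():
            return np.load(path)
        vec = compute()
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_suffix(".tmp.npy")
        np.save(tmp, vec)
        tmp.replace(path)
        return vec

    def protein_vector(self, embedder: Embedder, sequence: str) -> np.ndarray:
        return self._get_or_compute(
            embedder,
            "protein",
            sequence,
            lambda: pool_protein_mean(embedder.embed_protein(sequence)).values,
        )

    def molecule_vector(self, embedder: Embedder, smiles: str) -> np.ndarray:
        return self._get_or_compute(
            embedder,
            "molecule",
            smiles,
            lambda: assemble_molecule_vector(*embedder.embed_molecule(smiles)).values,
        )
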
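"""Self-contained synthetic fixtures with the statistical structure the
framework assumes.

The generator emulates, at configurable scale, the features of real kinetics
datasets the pipeline relies on: random protein sequences over the 20-letter
alphabet; SMILES-like token strings with optional "." contamination to
exercise the multi-component filter; log10 labels that are a (noisy) function
of a small, fixed set of embedding coordinates with a bell-shaped marginal
and a sparse tail above 4 log10 units; and an environmental response in
which the label falls off quadratically away from a condition optimum, so
condition-aware models are strictly better in expectation.

Labels live directly on the log10 scale; raw values are reconstructed as
10^label where records need them. The label function reads 6 coordinates of
the enzyme block and 2 of the substrate block, so the enzyme block dominates
by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from .datasets import KineticsRecord
from .representation import PairFeaturizer, SyntheticHashEmbedder

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: SMILES-like token grammar: atoms, aromatic atoms, bonds, ring digits.
_SMILES_ATOMS = ["C", "N", "O", "S", "P", "F", "Cl", "Br", "c", "n", "o"]
_SMILES_DECOR = ["=", "#", "1", "2"]

#: Indices of pair-vector coordinates the label function reads. The enzyme
#: block occupies the leading positions of the pair vector, so 0–5 are enzyme
#: coordinates; the substrate coordinates start at protein_token_dim.
N_ENZYME_SIGNAL = 6
N_SUBSTRATE_SIGNAL = 2


@dataclass(frozen=True)
class EnvEffect:
    """Quadratic environmental response: label −= curvature·(c − optimum)²."""

    condition_kind: str = "pH"
    optimum: float = 7.0
    curvature: float = 0.15
    value_range: tuple = (3.0, 10.5)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic dataset."""

    n_samples: int = 2000
    seq_length_range: tuple = (50, 60)
    smiles_token_budget: int = 25
    dot_contamination_rate: float = 0.0
    label_model: str = "linear"  # or "nonlinear"
    noise_sd: float = 0.3
    label_center: float = 1.0
    tail_fraction: float = 0.015  # mass above 4 log10 units
    tail_threshold: float = 4.0
    env_effect: EnvEffect | None = None
    protein_token_dim: int = 32
    molecule_token_dim: int = 8
    seed: int = 0
    #: Seed of the synthetic embedder; defaults to ``seed``. Matched dataset
    #: pairs (e.g. a condition-free and a condition-annotated set meant to be
    #: featurised by the same encoder) must share this while differing in seed.
    embedder_seed: int | None = None

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be ≥ 1")
        if self.seq_length_range[0] < 1:
            raise ValueError("minimum sequence length must be ≥ 1")
        if not 0 <= self.dot_contamination_rate < 1:
            raise ValueError("dot_contamination_rate must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must lie in (0, 0.5)")
        if self.label_model not in {"linear", "nonlinear"}:
            raise ValueError("label_model must be 'linear' or 'nonlinear'")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_protein_sequences(
    n: int, length_range: tuple = (50, 60), seed: int = 0
) -> list[str]:
    """Random sequences over the 20 canonical residues, lengths uniform."""
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AA_ALPHABET))
    return [
        "".join(rng.choice(alphabet, size=rng.integers(lo, hi + 1)))
        for _ in range(n)
    ]


def gen_smiles_like(
    n: int, token_budget: int = 25, dot_rate: float = 0.0, seed: int = 0
) -> list[str]:
    """SMILES-like strings from a small token grammar.

    Not chemically valid molecules — token strings with atoms, bonds, ring
    digits, and balanced branches. Each string independently receives an
    interior "." (a disconnected-component marker) with probability
    ``dot_rate``, to exercise the preprocessing filter.
    """
    if token_budget < 2:
        raise ValueError("token_budget must be ≥ 2")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        n_tokens = int(rng.integers(5, token_budget + 1))
        tokens = [str(rng.choice(_SMILES_ATOMS))]
        depth = 0
        for _ in range(n_tokens - 1):
            r = rng.random()
            if r < 0.12 and depth < 3:
                tokens.append("(")
                depth += 1
            elif r < 0.24 and depth > 0:
                tokens.append(")")
                depth -= 1
            elif r < 0.36:
                tokens.append(str(rng.choice(_SMILES_DECOR)))
            else:
                tokens.append(str(rng.choice(_SMILES_ATOMS)))
        tokens.extend(")" * depth)
        s = "".join(tokens)
        if rng.random() < dot_rate:
            cut = int(rng.integers(1, len(s)))
            s = s[:cut] + "." + s[cut:]
        out.append(s)
    return out


def _signal_columns(pair_features: np.ndarray, protein_token_dim: int) -> np.ndarray:
    enzyme = pair_features[:, :N_ENZYME_SIGNAL]
    substrate = pair_features[
        :, protein_token_dim : protein_token_dim + N_SUBSTRATE_SIGNAL
    ]
    return np.column_stack([enzyme, substrate])


def gen_labels(
    pair_features: np.ndarray, spec: FixtureSpec, seed: int | None = None
) -> np.ndarray:
    """Log10 labels as a function of 8 fixed embedding coordinates plus noise.

    The signal is the (standardised) sum of 6 enzyme-block and 2
    substrate-block coordinates — quadratic cross-terms are added under the
    ``nonlinear`` label model — scaled so the marginal is bell-shaped around
    ``label_center`` with ``tail_fraction`` of its mass above the tail
    threshold.
    """
    pair_features = np.asarray(pair_features, dtype=float)
    if not np.all(np.isfinite(pair_features)):
        raise ValueError("features must be finite")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    signal = _signal_columns(pair_features, spec.protein_token_dim)
    z = signal.sum(axis=1)
    if spec.label_model == "nonlinear":
        z = z + 2.0 * signal[:, 0] * signal[:, 1] + np.abs(signal[:, 2])
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    spread = (spec.tail_threshold - spec.label_center) / stats.norm.ppf(
        1.0 - spec.tail_fraction
    )
    labels = spec.label_center + spread * z
    if spec.noise_sd > 0:
        labels = labels + rng.normal(0.0, spec.noise_sd, size=labels.size)
    return labels


def apply_env_effect(
    labels: np.ndarray, effect: EnvEffect, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample condition values and shift labels by the quadratic response."""
    rng = np.random.default_rng(seed)
    lo, hi = effect.value_range
    conditions = rng.uniform(lo, hi, size=n)
    shifted = labels - effect.curvature * (conditions - effect.optimum) ** 2
    return shifted, conditions


# ---------------------------------------------------------------------------
# Full fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """A generated dataset with its features, labels, and provenance."""

    spec: FixtureSpec
    records: list
    sequences: list
    smiles: list
    features: np.ndarray  # pair vectors, one row per record
    labels: np.ndarray  # log10 scale
    conditions: np.ndarray | None
    embedder: SyntheticHashEmbedder

    @property
    def featurizer(self) -> PairFeaturizer:
        return PairFeaturizer(self.embedder)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a complete fixture: sequences, SMILES, features, labels, records.

    Deterministic given the spec (all randomness derives from ``spec.seed``).
    Records carry ``raw_value = 10^label`` and the log value, plus condition
    annotations when an environmental effect is configured.
    """
    sequences = gen_protein_sequences(spec.n_samples, spec.seq_length_range, spec.seed)
    smiles = gen_smiles_like(
        spec.n_samples, spec.smiles_token_budget, spec.dot_contamination_rate,
        spec.seed + 10_000,
    )
    embedder = SyntheticHashEmbedder(
        spec.protein_token_dim,
        spec.molecule_token_dim,
        seed=spec.seed if spec.embedder_seed is None else spec.embedder_seed,
    )
    featurizer = PairFeaturizer(embedder)
    features = featurizer.feature_matrix(sequences, smiles)
    labels = gen_labels(features, spec)

    conditions = None
    if spec.env_effect is not None:
        labels, conditions = apply_env_effect(
            labels, spec.env_effect, spec.n_samples, spec.seed + 20_000
        )

    records = []
    for i in range(spec.n_samples):
        records.append(
            KineticsRecord(
                enzyme_sequence=sequences[i],
                substrate_smiles=smiles[i],
                raw_value=float(10.0 ** labels[i]),
                log_value=float(labels[i]),
                condition_kind=(
                    spec.env_effect.condition_kind if conditions is not None else None
                ),
                condition_value=(
                    float(conditions[i]) if conditions is not None else None
                ),
            )
        )
    return Fixture(spec, records, sequences, smiles, features, labels, conditions, embedder)


def write_fixture(fixture: Fixture, prefix: str | Path) -> dict:
    """Write a fixture as dataset CSV + enzyme FASTA + spec JSON.

    Returns the paths written, keyed ``csv``/``fasta``/``spec``.
    """
    from .datasets import records_to_frame

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_suffix(".csv")
    fasta_path = prefix.with_suffix(".fasta")
    spec_path = prefix.with_suffix(".spec.json")

    records_to_frame(fixture.records).to_csv(csv_path, index=False)
    with open(fasta_path, "w") as fh:
        for i, seq in enumerate(fixture.sequences):
            fh.write(f">enzyme_{i}\n{seq}\n")
    payload = asdict(fixture.spec)
    with open(spec_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return {"csv": csv_path, "fasta": fasta_path, "spec": spec_path}
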
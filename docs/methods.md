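# Methods

## Model

The predictor is a supervised regressor from enzyme–substrate pair features
to a log₁₀-scale kinetic parameter (k_cat, K_m, or k_cat/K_m; each parameter
gets its own model — catalytic efficiency is predicted directly, never
assembled from separate k_cat and K_m predictors, whose ratio correlates
poorly with measured efficiencies).

Pair features are pooled per-token embeddings. The protein vector is the
mean over residues of the encoder's last-layer matrix; mean pooling is the
standard choice for per-protein tasks because it is length-invariant and
keeps every residue's contribution. The molecule vector concatenates four
256-d blocks of a SMILES encoder: mean pooling and max pooling of the last
layer, plus the first-position rows of the last and penultimate layers.
"First position" is interpreted as the embedding row of the first token the
plugin returns (a begin-of-sequence token when the encoder provides one,
else the first symbol); the synthetic embedder has no special tokens, and
plugins that mark special/padding tokens should exclude them from pooling so
the vector reflects sequence content only. The pair vector is the protein
block followed by the molecule block (2048-d at reference dimensions);
slicing recovers both blocks exactly. Environmental conditions are appended
as one raw, unstandardised coordinate (pH units or °C) — standardisation is
deliberately not applied, since tree splits are scale-invariant and the meta
layer consumes predictions, not features.

The default regressor is scikit-learn's `ExtraTreesRegressor` with library
default hyperparameters; a registry exposes the other standard tree and
linear backends under one interface. Tree ensembles suit this problem:
datasets are ~10³–10⁴ samples with 10³-dimensional features, where linear
models underfit and deep networks lack data.

### Environmental-factor stacking

Measured k_cat depends on assay pH and temperature, but condition-annotated
data are scarce. The two-layer stack trains (1) a condition-blind base on a
large condition-free dataset and (2) a condition-aware base on the annotated
dataset's base-training split (pair vector ⊕ condition, 2049-d), then fits a
linear meta-learner ŷ = b₀ + b₁·ŷ_plain + b₂·ŷ_revised on the annotated
meta-training split. The partition is nested: 20% of the annotated set
(ceiling) is test, and the remainder splits 80/20 into base- and
meta-training sets (64/16/20 of the whole). Coefficients come from the
Moore–Penrose pseudoinverse — the minimum-norm least-squares solution — so
exactly collinear base predictions (both bases identical) degrade gracefully
to the common prediction. An intercept is included; with it the meta layer
subsumes either base as a special case, and the pseudoinverse keeps it
identifiable. Evaluation repeats the nested split three times and averages
test metrics, since a single 120-sample test split is noisy.

### Re-weighting for high-value prediction

Log-scale kinetic labels are approximately bell-shaped with sparse tails, so
held-out error is U-shaped in the label: rare high-value samples are pulled
toward the populated centre. Four weighting families counteract this:

| scheme | weight of a sample in a bin of count c | hyperparameters (default) |
|---|---|---|
| DMW | ×m above the threshold, 1 below | threshold 4 log₁₀, m = 10, unnormalised |
| CSW / root / square | c⁻¹ / c^(−1/2) / c⁻² | 131 equal-width bins |
| CBW | 1/E_c, E_c = (1−β^c)/(1−β) | β = 0.9 |
| LDS | 1/(k∗counts) at the sample's bin | Gaussian kernel, size 5, σ = 1 |

Defaults are the settings found optimal in the hyperparameter grids (DMW
multipliers 2–100 with and without normalisation; β ∈ {0.7…0.9999}; kernel
sizes 3/5/7 with σ ∈ {1,2}). Binning is equal-width over [min, max] of the
*training* labels, right-open, with the maximum assigned to the last bin;
131 bins is the fixed default. The effective number is implemented as the
quotient (1−β^c)/(1−β) — the standard saturating form with E₁ = 1, E_c → c
as β → 1 (plain CSW) and E_c → 1 as β → 0 (uniform). LDS convolves the bin
histogram with the kernel using zero-padded edges, which shrinks densities
near the label extremes and thereby boosts tail weights — consistent with
the method's intent. All bin-based schemes are rescaled to mean 1 before
training so schemes are comparable at fixed learning dynamics; DMW passes
its raw (or sum-normalised) weights unchanged.

### Screening

Saturation mutagenesis enumerates, for a length-L parent, every substitution
of each position to the other 19 canonical residues — exactly 19·L variants,
position-major then alphabetical, never including the parent. Sequences with
non-canonical letters (X/B/Z/U) are rejected in mutate mode, since the
variant definition requires the canonical alphabet. Mining mode scores an
arbitrary FASTA (e.g. BLASTp hits; the conventional retrieval settings are
BLOSUM62 with word size 5) against a fixed substrate. Ranking is by
predicted value descending with stable input-order tie-breaks, making
reports byte-reproducible. Ranking by k_cat and by k_cat/K_m are separate
screens with separate models; no combined objective is invented.

## Preprocessing and splits

Records with a "." in the SMILES (multi-component structures) or a
non-positive measured value are dropped before the log₁₀ transform, with
per-reason counts reported. Base 10 is used for all three parameters — it
matches the K_m convention and makes the ">4" high-value threshold a round
number. Holdout test sizes use the ceiling rule (16,838 samples at 10% give
1684/15,154, matching the reference protocol). The strict test subset keeps
held-out samples whose enzyme sequence or substrate string (exact identity,
sequences upper-cased and stripped) never occurs in training; no similarity
clustering is applied, because presence/absence is the stated criterion.
Duplicate rows are retained; deduplication is an opt-in flag. The
geometric-mean leakage baseline predicts each test sample by log₁₀ of the
geometric mean of raw training values sharing its enzyme (equivalently, the
arithmetic mean of their log values); unseen enzymes fall back to the global
geometric mean. Grouping by exact identity is the default — identity-banded
variants would require a similarity procedure the method does not define, so
band stratification is left to a user-supplied similarity column.

## Synthetic data: what it emulates and what it does not

The fixture generator produces random sequences over the 20-letter alphabet,
SMILES-like token strings (with optional "." contamination at a configurable
rate), and log₁₀ labels that are a linear (optionally nonlinear) function of
8 fixed embedding coordinates — 6 from the enzyme block, 2 from the
substrate block, so enzyme features dominate by construction — plus Gaussian
noise (default σ = 0.3). The signal is standardised and scaled so the
marginal is bell-shaped, centred at 1.0 log₁₀ units, with 1.5% of mass above
4 by default: comparable to the ~0.9% tail of real turnover-number data
while keeping ~30 tail samples in a 20% holdout at n = 10,000. The
environmental fixture samples conditions uniformly on the pH-like range
3–10.5 and shifts labels by −κ(c − optimum)² with optimum 7 and κ = 0.15,
giving a condition effect (shift sd ≈ 0.65 log₁₀ units) large enough for a
tree model to detect at n ≈ 500; with κ = 0 the condition carries no signal
and stacking gains vanish.

The synthetic embedder hashes (token, position, seed) to pseudo-random rows
in [−1, 1]; it is deterministic across processes and sensitive to single
substitutions, but its coordinates carry no biochemistry. Passing tests
therefore demonstrate that the pipeline's mechanics — pooling contracts,
split protocols, weighting formulas, stacking algebra, ranking — behave as
specified, and that the statistical claims (tail-error reduction, stacking
dominance) hold when the data-generating process matches the model's
assumptions. They say nothing about accuracy on real enzymes, which depends
on real pretrained encoders and curated measurements consumed through the
plugin contract.

## Study problem sizes and numerical choices

Simulation studies use per-token dimensions 32 (protein) and 8 (molecule),
i.e. 64-d pair vectors: the framework never hard-codes the reference
1024/256 outside the reference configuration, and small dimensions keep a
full study at n = 10,000 within minutes. The re-weighting study trains
ExtraTrees with `min_samples_leaf=5` and `n_estimators=40`: sample weights
act on a tree ensemble mainly through weighted leaf means, and fully grown
trees with singleton leaves leave weights acting on split selection alone —
too weak a channel to measure the schemes' effect; 40 trees bound runtime.
Each of five seeded replicates regenerates the fixture, holds out 20%,
computes weights from training labels only, and measures RMSE on held-out
samples with experimental label > 4. The stacking study uses a 2000-sample
condition-free fixture and a 600-sample annotated fixture (the scale of real
pH/temperature datasets), sharing one embedder as both would share one
encoder in practice.

Degenerate inputs are handled explicitly: constant labels occupy a single
bin; empty intervals report absent (not zero) metrics; R², PCC, and min–max
normalisation raise on constant inputs rather than returning NaN; empty
feature matrices predict empty vectors; the embedding cache round-trips
byte-identically via `.npy` files keyed by (embedder id, SHA-256 of the
sequence).

## Limitations

No hyperparameter search, uncertainty quantification, GPU training, or deep
baselines; no chemically valid molecule generation or realistic protein
families in the fixtures; no multi-point mutagenesis or epistasis; no
name-to-SMILES resolution or database scraping. Reproducing published-scale
benchmarks requires the original curated datasets and multi-GB pretrained
encoders, wired in through the embedder plugin contract; at that point the
same split protocols, metrics, and drivers apply unchanged.
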
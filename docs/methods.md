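# Methods

This note documents the models, parameters, and design choices behind
`polygen`, and what the desk-scale validation does and does not show.

## Corpus curation and tokenization

Curation applies, in order: RDKit parsing; salt stripping (keep the
fragment with the most heavy atoms, ties broken by lexicographically
smallest canonical SMILES); charge neutralization with RDKit's
`Uncharger`; an element whitelist {H, B, C, N, O, F, Si, P, S, Cl, Se,
Br, I}; canonicalization; and a 100-character cap on the canonical
SMILES. Failures are returned as typed rejections (`unparseable`,
`disallowed_atom`, `too_long`), never exceptions. Curation is idempotent:
a curated SMILES re-curates to itself.

Tokenization is character-level except that the two-character element
symbols Cl, Br, Si, Se are single tokens, so a decoder can never emit
half an element. Sequences are framed as `<start> … <end>` and padded to
a fixed window (default 100), leaving a 98-token content budget. The
vocabulary is the sorted character census of the corpus plus the three
specials, so it adapts to any curated corpus rather than assuming a fixed
alphabet.

Train/validation splits hash the canonical SMILES together with the split
seed, so membership is a pure function of the molecule and the seed.

## The variational autoencoder

Architecture (defaults): token embedding 128; GRU encoder (1 layer,
hidden 256, inter-layer dropout 0.2 — inert at one layer); linear maps to
μ_z and log-variance σ_z of a 128-dimensional latent; reparameterization
z = μ_z + ε·e^(σ_z/2) with ε ~ N(0, I); a linear map of z initializes the
decoder hidden state (512 wide, shared across layers); a GRU decoder
(3 layers, hidden 512) consumes [token embedding, z] at each step and a
final linear + softmax emits the next-token distribution over the
vocabulary. The σ_z emitted by the encoder is interpreted as a
log-variance — the only reading under which e^(σ_z/2) is a standard
deviation.

Losses: token-level cross-entropy over non-pad positions (padding past
the end token would otherwise dominate the signal), plus the closed-form
Gaussian KL, −½ Σ(1 + σ_z − μ_z² − e^(σ_z)), averaged per molecule. The
KL weight is configurable (default 1.0) with an optional linear warm-up.
Training uses Adam (default learning rate 3·10⁻⁴, batch 1024, 200
epochs) with global-norm gradient clipping at 50, teacher forcing during
training and free-running generation at sampling time. An optional
per-epoch learning-rate decay factor aids late-stage convergence on small
corpora. The encoder freezes its hidden state past each sequence's end
token, so padding never influences the posterior.

The model is implemented in numpy on a compact reverse-mode autodiff
(`polygen._autodiff`) whose gradients are tested against finite
differences. One run seed drives weight initialization, ε draws, batch
order, and multinomial decoding, which makes training traces and samples
exactly reproducible; checkpoints (weights + config + vocabulary,
versioned schema) reload to bit-identical behavior.

De novo sampling draws z from the N(0, I) prior — the distribution the
KL term regularizes the posterior toward. Perturbing encodings of known
ligands is available as an alternative entry point but is not the
default.

## Compound-target scoring

Affinities (IC50 or Kd, molar) become ligand efficiency
y = 1.4·(−log₁₀ affinity)/N with N the heavy-atom count; the inverse map
pIC50 = y·N/1.4 recovers potency for threshold classification, and the
two are exact inverses by construction. Features are 2048-bit Morgan
fingerprints at radius 2. The regressor is a scikit-learn random forest
with 1000 trees; all other forest hyperparameters stay at library
defaults and are recorded in the scorer's provenance. Performance is
estimated by five-fold cross-validation with seeded random fold
assignment; a Murcko-scaffold-grouped split is available for stricter
generalization estimates. Mixed-target or mixed-affinity-kind training
tables are rejected; Kd tables train through the identical path.

## Rewards and the reinforcement loop

Six rewards per candidate: predicted ligand efficiency for each target
(maximized), mean Euclidean distance from the candidate's μ_z to the 20
nearest known-ligand embeddings of each target (minimized; min-of-20 is
a config option — the mean of the closest-20 set is the default because a
single nearest neighbor is noisy), SA score (minimized; RDKit
fragment-contribution implementation, ≈1 easy to ≈10 hard) and QED
(maximized, [0, 1]). Each reward r is normalized by half-Gaussian
scaling: 1 on the satisfied side of the threshold mean μᵢ and
exp(−½((r−μᵢ)/σᵢ)²) on the other; the aggregate R is the arithmetic
mean of the six. The shipped μᵢ/σᵢ values (e.g. ligand efficiency
μ=0.4/σ=0.1, QED μ=0.7/σ=0.1, SA μ=4/σ=1) are **documented placeholders**
for desk-scale work; any production run must supply its own calibrated
thresholds through the run configuration.

Each generation cycle samples latents from the prior (8192 by default),
decodes, curates, deduplicates by canonical SMILES, scores, selects the
top candidates by R (4096 by default; ties broken by lexicographic
SMILES order so selection is a deterministic truncation of a full sort),
and fine-tunes the VAE on the winners for 2 epochs (batch 512) with the
same two-term objective — keeping the KL term prevents posterior collapse
of the refocused model. Candidates that cannot be scored (invalid
SMILES, featurization failure) are dropped before selection and counted,
rather than given R = 0. Latents are always drawn from N(0, I): the
fine-tuned decoder re-maps the prior's mass onto high-reward regions.
Scores of previously seen compounds may be cached across cycles; results
are identical either way (tested). Cross-cycle duplicates are collapsed
in the final ranked table, keeping each compound's maximum R and first
cycle of appearance.

## Dual-activity benchmark

Compounds assayed against exactly two distinct targets form (compound,
target1, target2) triplets; compounds overlapping the scorers' training
sets are removed by canonical SMILES. Replicate measurements combine by
geometric mean (min/median configurable). A side is dual-active iff both
affinities are strictly below the threshold (default 1 µM; boundary
values are inactive). The 2×2 observed-vs-predicted table reports the
cross-product odds ratio (tp·tn)/(fp·fn) — the Fisher exact point
estimate — with a Haldane-Anscombe +0.5 correction applied and flagged
when a cell is zero, plus Fisher and chi-squared p-values, accuracy and
balanced accuracy (dual-actives are rare in realistic tables, so plain
accuracy alone is optimistic). The threshold sweep holds observed labels
at 1 µM while sweeping the prediction threshold (decades 10⁻⁵–10⁻¹⁰ M),
tracing proper PR/ROC point sets; re-thresholding both sides at each
sweep point is available via `observed_threshold=None`.

## Synthetic fixtures: what they emulate, and what they do not

The fixture generator grows small molecule families from fixed scaffolds
(alkane, ether, amine, alcohol, cyclohexane, amide cores) with
family-specific substituent pools, restricted to simple C/N/O chemistry
so validity and SA behave smoothly and CPU training stays tractable.
Families are structurally separable (intra-family fingerprint similarity
exceeds inter-family, tested by brute-force census). Synthetic activity
tables plant a linear map from designated fingerprint bits to ligand
efficiency plus Gaussian noise, back-computing affinities through the
ligand-efficiency identity so every record is internally consistent;
planted bits are drawn from mid-prevalence (15–85%) fingerprint bits,
since bits that never vary carry no recoverable signal. Two targets can
share a configurable fraction of planted bits, creating correlated
dual-target ground truth.

These fixtures emulate the *structure* of real corpora and activity
tables — family clustering, a fingerprint-linear SAR, dual-target
correlation — but not the scale, chemical diversity, assay noise
structure, or activity-cliff behavior of ChEMBL/BindingDB data. Passing
tests therefore demonstrate that the machinery is correct and that each
statistical property holds where it is constructed to hold; they do not
certify predictive performance on real targets.

## Validation conditions and numerical choices

Desk-scale study conditions used by the test suite and
`scripts/acceptance.py`, chosen once as the smallest sizes at which each
property is meaningfully testable on one CPU:

- Memorization: 50 molecules (2 families × 25), compact dims (embedding
  32, encoder 96, latent 24, decoder 128×1, window 40), 900 epochs,
  learning rate 3·10⁻³ decaying by 0.998/epoch, KL weight 0.01 with
  100-epoch warm-up. A low KL weight is appropriate here: with 50
  training molecules the goal is a faithful, invertible embedding, not a
  smooth generative prior.
- Prior-sample validity measured at n = 512 multinomial decodes.
- Scorer recovery: 500 records over 240 fixture molecules, 10 planted
  bits, noise σ ∈ {0, 0.05, 0.2}, 1000 trees, seeded 5-fold CV.
- Reward climb: 10 cycles × 256 samples, top-64 fine-tuning (2 epochs,
  batch 64), three master seeds.
- Dual benchmark: 200 fixture molecules split into disjoint halves for
  scorer training vs. held-out evaluation; 10 shared planted bits,
  base efficiency 0.55 with coefficients U(0.04, 0.10) so the implied
  pIC50 distribution straddles the 1 µM activity threshold.

Degenerate inputs are handled explicitly: empty corpora, empty ligand
sets, unfitted models and mixed activity tables raise; zero valid
candidates in a generation cycle leaves the model unchanged and the loop
running; `top_k` beyond the candidate count returns all with a warning;
zero-margin contingency tables flag their continuity correction.

## Known limitations

- The recurrent nets run in interpreted numpy; full corpus-scale
  (10⁶-molecule) training is configurable but impractical here — the
  implementation targets method development and validation scale.
- The reward thresholds shipped are placeholders (above), and the
  distance rewards depend on the checkpoint that embedded the known
  ligands; mixing checkpoints between candidates and ligand sets is
  rejected only by dimension, not provenance hash.
- No stereochemistry enrichment, tautomer handling, docking, or ADMET
  modeling; off-target (negative) rewards are out of scope.
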
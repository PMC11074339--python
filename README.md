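# polygen

Generative design of **polypharmacology compounds** — single molecules
intended to inhibit two protein targets at once. The package is aimed at
computational chemists and method developers who want a transparent,
CPU-friendly implementation of the generate-score-refocus strategy for
dual-target de novo design, plus the benchmarking harness that checks
whether a compound-target scorer can recognize dual-active compounds.

## What it does

1. **Corpus curation** (`polygen.corpus`). SMILES corpora are curated the
   way large generative-chemistry training sets are prepared: salts
   stripped (largest fragment kept), formal charges neutralized, strings
   longer than 100 characters dropped, and molecules restricted to the
   element set {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}. Tokenization
   is character-level with Cl/Br/Si/Se kept atomic.

2. **Chemical embedding** (`polygen.vae`). A variational autoencoder with
   GRU encoder and decoder maps each token sequence *x* to a Gaussian
   posterior (μ_z, σ_z) in a latent "chemical embedding" and back.
   Sampling uses the reparameterization z = μ_z + ε·e^(σ_z/2), ε ~ N(0, I);
   training minimizes token cross-entropy plus KL(q(z|x) ‖ N(0, I)).
   The model is implemented directly over numpy with the package's own
   reverse-mode autodiff, so everything runs (and is exactly reproducible)
   on one CPU.

3. **Compound-target scoring** (`polygen.scoring`). Per-target random
   forests (1000 trees) regress **ligand efficiency**
   y = 1.4·(−log₁₀ IC50)/N (N = heavy atoms) from 2048-bit Morgan
   fingerprints (radius 2), with seeded five-fold cross-validation.
   Kd-trained scorers use the identical path.

4. **Multi-reward generation** (`polygen.rewards`, `polygen.rl`). Each
   cycle samples latent coordinates from the prior, decodes them, and
   scores candidates on six rewards — predicted ligand efficiency against
   both targets, embedding distance to the 20 closest known ligands of
   each target, SA score, and QED — each normalized to [0, 1] by
   half-Gaussian scaling (1 on the satisfied side of a threshold mean
   μᵢ, Gaussian falloff of width σᵢ otherwise) and averaged into a single
   reward R. The top-scoring molecules fine-tune the VAE (2 epochs), and
   the loop repeats, refocusing the embedding onto high-reward chemistry.

5. **Dual-activity benchmark** (`polygen.dual`). Compounds assayed
   against exactly two targets are labeled dual-active when both
   affinities are strictly below 1 µM; predicted labels come from the
   scorers. The observed-vs-predicted 2×2 table is summarized by the
   cross-product odds ratio (the Fisher exact point estimate), Fisher and
   chi-squared p-values, and a threshold sweep (10⁻⁵–10⁻¹⁰ M) tracing
   precision-recall and ROC points.

`polygen.fixtures` assembles deterministic desk-scale scenarios (fixture
molecule families, planted structure-activity tables for two correlated
targets, ligand embedding sets) so the entire pipeline can be exercised
and validated without external databases.

## Worked example

```python
import numpy as np
from polygen import (generate_fixture_corpus, SmilesVAE,
                     generate_synthetic_activity, train_scorer)
from polygen.scoring import informative_bits

corpus = generate_fixture_corpus(n_families=2, family_size=25, seed=7)
vae = SmilesVAE(embed_dim=32, encoder_hidden=96, latent_dim=24,
                decoder_hidden=128, decoder_layers=1, encoder_dropout=0.0,
                max_len=40, epochs=900, learning_rate=3e-3, batch_size=50,
                kl_weight=0.01, kl_warmup_epochs=100, lr_decay=0.998,
                seed=1).fit(corpus)
exact = sum(vae.reconstruct(m) == m.smiles for m in corpus)
_, validity = vae.sample_molecules(512, np.random.default_rng(2))
print(f"reconstruction {exact}/{len(corpus)}, prior validity {validity:.3f}")

mols = generate_fixture_corpus(4, 60, seed=3)
bits = informative_bits(mols, 10, seed=3)
records = generate_synthetic_activity(500, "T1", bits, seed=3,
                                      noise_sigma=0.05, molecules=mols)
scorer = train_scorer(records, n_trees=1000, seed=4)
print(f"5-fold CV R^2 = {scorer.cv_r2_:.3f}")
```

This prints:

```
reconstruction 50/50, prior validity 0.832
5-fold CV R^2 = 0.780
```

i.e. the compact VAE memorizes the 50-molecule fixture corpus exactly,
83% of molecules decoded from random prior draws are valid chemistry, and
the forest recovers the planted fingerprint→ligand-efficiency map with
cross-validated R² of 0.78 at noise σ = 0.05.

The command-line interface exposes the same stages
(`polygen curate | train-vae | train-scorer | generate | score-dual |
fixtures`); see `polygen --help`.

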
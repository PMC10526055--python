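# Methods

## Model

`moladapt` treats molecule generation as a two-stage problem: a frozen
*codec* maps molecules to fixed-length real latent vectors and back, and a
GAN learns the distribution of those latent vectors.  The package never
touches molecular graphs during training — all learning happens in latent
space, which is what makes few-shot adaptation tractable.

**Pre-training.**  The generator is an MLP from noise z ~ N(0, I_d) to
latent space (default widths 100→128→256→256→512→256→56, Tanh hidden
activations, linear output); the critic is an MLP from latent space to a
scalar (default 56→128→256→128→1, leaky-ReLU slope 0.2, linear output, no
sigmoid — the Wasserstein critic must be unbounded).  Training minimizes
the WGAN-GP loss

    L = E[D(r_G)] − E[D(r_E)] + λ E[(‖∇_r̂ D(r̂)‖₂ − 1)²]

with r̂ = ε·r_E + (1−ε)·r_G, ε ~ U(0,1) per pair.  Defaults follow the
WGAN-GP literature where the method description leaves them open: λ = 10,
5 critic steps per generator step, Adam with betas (0, 0.9), learning rate
1e-3, 200 epochs at batch size 128.

**Adaptation.**  Given k reference molecules, their encoded latents become
the "real" distribution and the same WGAN-GP objective is optimized, but
the only generator-side parameters trained are the affine adaptor
z' = Az + b on the input noise (A initialized to the identity, b to zero,
so the adapted model starts exactly at the pre-trained one).  On the critic
only the last n layers are trainable (default n = 2); earlier layers keep
their pre-trained feature extraction.  Reference batches are drawn with
replacement, so 5-shot and 100-shot adaptation share one code path.
Defaults: 40 epochs at batch size 1, learning rate equal to the
pre-training rate, one critic step per adaptor step.  With batch size 1
the gradient-penalty interpolation pairs the single real with the single
fake sample — the only pairing available.

**Generation.**  n noise draws are pushed through adaptor and generator
and decoded; the decode stage of both supported codecs always yields a
valid molecule, so validity is 1 by construction and uniqueness over valid
samples equals uniqueness over all samples.

## Numerical implementation

The MLPs, Adam, and both loss gradients are implemented directly in NumPy.
The gradient penalty requires differentiating the critic's input-gradient
norm with respect to the critic's weights (double backprop).  For
piecewise-linear activations the activation slopes are locally constant,
so the second-order term through the slopes vanishes almost everywhere;
the implementation exploits this to compute exact penalty gradients with
two linearized passes, and the penalty's bias gradients are identically
zero in this regime.  Unit tests verify all gradients against central
finite differences at 1e-5 tolerance.

Two standard stabilizers are built in and on by default: learning rates
anneal linearly to zero over the run, and the returned generator (and
adaptor) is an exponential moving average of the training iterates
(decay 0.995 for pre-training, 0.998 for the recovery benchmark).  Both
matter for moment-matching accuracy: the last adversarial iterate orbits
the equilibrium rather than settling on it.

Determinism: every training loop consumes a single `numpy` generator
seeded from the run seed; same config + seed reproduces parameters
bit-exactly.  Checkpoints serialize weights, freeze flags and metadata to
`.npz` and reload bit-exactly.

## The toy codec

A deterministic stand-in for a pre-trained molecular VAE, synthetic by
design.  Each library molecule is embedded as a 15-dimensional
physicochemical descriptor (heavy atoms, aromatic rings, halogen count,
H-bond donors/acceptors, rotatable bonds, MW/100, Crippen logP, elemental
counts of C/N/O/F/Cl/Br/S), zero-padded to `latent_dim` and standardized
per column over the library.  Descriptor collisions (distinct structures,
identical descriptors up to float noise — e.g. anthracene vs phenanthrene)
gain a deterministic index coordinate so encoding stays injective.
Decoding returns the nearest library descriptor in Euclidean distance,
ties broken by lexicographically smallest canonical SMILES; like its VAE
counterpart it therefore decodes *every* latent vector to a valid
molecule.

What it does not emulate: a continuous, generalizing latent space — it can
only ever return library members, so uniqueness of large generated sets is
bounded by the library size, and "novel molecule" behavior is out of reach.
Passing tests on the toy codec demonstrate the adaptation machinery
(freezing, adaptor training, distribution shift), not chemical novelty.

## Synthetic fixtures

The toy library is a fixed enumeration of 48 small organic molecules
covering every cell of {0,1,2,3 aromatic rings} × {halogenated, not},
half halogenated by default — enough structure for ring-count and halogen
predicates, top-k property selection and nested few-shot sampling to be
non-trivial.  Latent fixtures are seeded Gaussians and affine-transformed
Gaussians with closed-form moments.

## Recovery benchmarks and their parameters

Three benchmarks with known ground truth exercise the full stack
(`moladapt.benchmarks`); their problem sizes are chosen so each run takes
seconds on one CPU.

* **Gaussian recovery** — pre-train on 8192 draws from
  N((3,−2), diag(1, 0.25)) (noise dim 8, generator 32-32, critic 64-64,
  300 epochs, batch 256) and require the 4096-sample generated mean within
  0.15 per coordinate and covariance within 0.25 Frobenius.
* **Affine recovery** — freeze a linear generator M = diag(0.5, 1), draw
  512 references through the ground-truth adaptor A* = diag(2, 0.5),
  b* = (1,−1), and fine-tune the adaptor alone (400 epochs, batch 128,
  learning rate 3e-3).  M is chosen so the data-space latents are
  unit-scale, as a standardized codec produces; the adaptor must still
  recover (A*, b*) since M is fixed and invertible.  Required: generated
  mean within 0.2 and covariance within 0.3 Frobenius of the reference
  sample, and bit-identical generator and frozen-critic hashes.
* **Few-shot toy adaptation** — pre-train on the 48-molecule library
  (latent dim 16), adapt to 5 halogenated members (200 epochs, batch 1),
  generate 1000 molecules: the halogenated fraction must strictly exceed
  the pre-trained model's while diversity stays within 0.15.

For these low-dimensional benchmarks the gradient-penalty weight is set to
λ = 1: with unit-scale 2-d data the published λ = 10 over-regularizes the
critic toward slope-1 functions and visibly biases the recovered
covariance.  The package default for the full-size architecture remains
λ = 10.  The toy fine-tuning schedule (200 epochs) is longer than the
production default (40): with a 16-dimensional noise space and EMA
averaging, 200 single-sample steps are needed for the adaptor to traverse
the distance to the reference region.

## Metrics — edge cases and conventions

* Diversity is 1 − mean pairwise Tanimoto over distinct pairs of ECFP4
  fingerprints (radius 2, 2048 bits); undefined below two valid molecules;
  sets larger than 5000 are subsampled (seeded, recorded in the report).
* Two all-zero fingerprints count as identical (similarity 1).
* Uniqueness divides distinct canonical SMILES by *valid* samples.
* Quality deduplicates its numerator but keeps the full generated multiset
  as denominator; with a finite decode library this bounds quality by
  (library size)/(generated count), so the few-shot benchmark tracks the
  un-deduplicated fraction satisfying the predicate instead.
* Penalized logP = Crippen logP − raw synthetic-accessibility score −
  max(0, largest ring − 6); reported normalized values are min-max scaled
  over a stated reference pool and clipped to [0, 1].  Normalized SA is
  (10 − SA)/9, higher = easier.
* "Ring count" predicates count aromatic rings by default (a switch
  selects total SSSR rings).
* Top-k property selection breaks ties lexicographically on canonical
  SMILES, making k-shot property datasets deterministic and nested.

## Known limitations

* The adaptor is a single affine map: it can translate/rescale/correlate
  the noise distribution but cannot carve multi-modal reference sets out
  of a unimodal prior.
* NumPy training is single-threaded-friendly but not GPU-capable; the
  default full-size architecture trains in minutes on toy pools, not on
  250K-molecule libraries.
* No molecular standardization (salt stripping, tautomer canonicalization)
  beyond RDKit SMILES canonicalization is applied before fingerprinting or
  scoring.
* Activity scoring (e.g. DRD2 bioactivity) is a plugin contract only; the
  shipped scorer is a deterministic halogen-substructure mock for tests.
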
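# Methods

## The model

`plignet` scores protein–ligand binding affinity with a graph neural
network over a *protein–ligand interaction graph* (PLIG): the graph has the
topology of the ligand — one node per heavy atom, one edge per covalent
bond — and the protein enters only through per-node descriptors of the
atomic environment.

### Radial atomic environment vectors

For ligand heavy atom *i*, the environment of the surrounding protein is
summarised by a radial atomic environment vector (AEV) with entries indexed
by protein atom type *t* and Gaussian shell *m* = (η, R_s):

    g_i[t, m] = Σ_{j : type(j) = t}  exp(−η (R_ij − R_s)²) · f_c(R_ij)

with the cosine cutoff f_c(R) = ½(cos(πR/R_c) + 1) for R ≤ R_c and 0
beyond. Defaults follow the ANI-2x radial parameter set: R_c = 5.1 Å,
sixteen shifts R_s ∈ [0.80, 4.83] Å, a single width η = 19.7 Å⁻². No
additional normalisation factor is applied to the radial terms (some
symmetry-function implementations multiply by ¼; the definition above does
not). Entries are ordered type-major, then R_s, then η; the order is fixed
and stored with every graph container so models can be reused.

### ECIF atom typing

Protein atoms are typed by the tuple (element, valence, heavy-neighbour
count, H count, aromaticity, ring membership) — the ECIF scheme, which
yields 22 distinct protein atom types, so the default AEV length is
22 × 16 × 1 = 352. The package assigns types by (residue, atom name)
lookup in templates for the 20 canonical amino acids. Template conventions:
physiological protonation (Lys⁺, His ε-tautomer) and delocalised charged
groups counted in their all-double-bond representation (guanidinium CZ at
valence 6, carboxylate carbon at valence 5, both carboxylate oxygens at
valence 2 with no hydrogen). Under these conventions the template
enumeration reproduces the published 22-type table exactly. Atoms without a
template entry — OXT, non-standard residues, ions — are kept in the
structure, flagged, and excluded from AEV sums with a warning; waters and
HETATM groups are excluded by default (`include_hetatm=True` admits them,
untyped). Hydrogens are never nodes and never AEV contributors; they exist
only as per-heavy-atom counts.

### Node and edge features

Node features concatenate a 10-slot element one-hot (B, C, N, O, F, P, S,
Cl, Br, I), five scalar atom descriptors (valence, heavy degree, H count,
aromatic, ring — scalars, not one-hots: the minimal encoding), and the
352-long AEV: 367 values per node. Edges carry a 4-slot bond-order one-hot
(single, aromatic, double, triple). Undirected bonds are stored once and
expanded to both directions (plus one self-loop per node with a zero edge
feature — a self-loop has no bond order) when a batch is packed for the
network.

### Network

Five GATv2 layers, three heads each. Per head, with learnable W_s, W_t,
W_e, b shared over the layer:

    a_uv = softmax_{k ∈ N(u)∪{u}}  bᵀ LeakyReLU(W_s x_u + W_t x_k + W_e e_uk)
    h_u  = σ( Σ_{v ∈ N(u)∪{u}} a_uv W_t x_v )

Heads are concatenated on every layer, including the last. σ is ReLU
between layers; the attention LeakyReLU uses negative slope 0.2 (the usual
GATv2 convention); both are configurable. After the last layer a graph
vector is formed by concatenating element-wise max and mean over nodes
(width 2 × 3 × head_dim), and a four-layer MLP (hidden 1024/512/256, ReLU,
linear output) produces the pK prediction. The MLP input width is always
derived from the actual pooled dimension — 1536 at the published head width
of 256 — rather than hard-coded. Weights are Glorot-uniform, seeded per
ensemble member; inference is deterministic.

The network, including backpropagation and the Adam optimiser, runs on a
compact numpy reverse-mode autodiff engine inside the package
(`plignet.nn`); gradient correctness is pinned by finite-difference tests
and the forward pass by scalar loop-based references.

### Training

The reported prediction is the arithmetic mean of an ensemble of ten
identically configured members trained independently from different seeds
(ensemble size and seeds are configurable). Loss is MSE on pK; Adam with
learning rate 1e-4 and batch size 128 are conventional defaults, fully
exposed in `TrainConfig` along with an optional cosine learning-rate decay
and optional node-feature standardization. Standardization is off by
default: AEV blocks are sparse, and per-column scaling amplifies
near-empty shells (it measurably hurt on the synthetic benchmark). A
seeded 10% validation split (stratified by
target when targets are present; plain random when every complex is its own
target) is scored by Pearson correlation each epoch, and the parameters of
the epoch with the highest validation PCC are kept. Zero-variance
validation predictions rank as −∞ with a warning, so a degenerate epoch
can never displace a defined one. Epoch-count defaults follow the published
regimes (300 for base data, 200 for augmented data).

## Evaluation statistics

Per congeneric series: Pearson correlation; Kendall's τ in the τ-a form
(n_c − n_d)/(n(n−1)/2), with tied pairs counting as neither concordant nor
discordant but remaining in the denominator; RMSE on occasion. Aggregation
over series is the mean weighted by relative series size; series with an
undefined metric are excluded with a warning and the weights renormalised.

Confidence intervals are 95% bias-corrected and accelerated (BCa) bootstrap
intervals resampling (x, y) pairs together (delegated to
`scipy.stats.bootstrap`; a degenerate bootstrap distribution falls back to
the percentile interval with a warning). Method comparison uses a paired
bootstrap test: identical resample indices for both methods per draw,
Δρ_b = ρ_b(M₁) − ρ_b(M₂), and P = fraction of draws with Δρ_b < 0
(significance at P < 0.05). When every draw gives Δρ_b = 0 — identical
predictions — the literal P of 0 would falsely signal significance, so the
result is flagged degenerate and reported as P = 1 with the literal
fraction preserved. For weighted-mean comparisons across series, resampling
is within each series and the weighted mean is recomputed per draw; whether
to resample within series or pool complexes was an open choice, and
within-series is the default because the series is the scientific unit of
ranking. B defaults to 10,000 for both tests and intervals.

Free energies use ΔG = RT ln K, pK = −ΔG/(RT ln 10), ΔG = −ln(10)·RT·pK
with R = 1.987×10⁻³ kcal K⁻¹ mol⁻¹ and T = 297 K.

Affinity labels harmonise heterogeneous measurements: entries qualified
with ">" or "<" are dropped; among the rest, the highest-priority kind
present (Kd, then Ki, then IC50) is selected and the median of its values
converted to pK = −log₁₀(K molar).

## Out-of-distribution splits

Pairwise complex distance d = 1 − max(s/100, T_s), where T_s is the
Tanimoto similarity of ECFP6 (Morgan radius-3, 2048-bit) ligand
fingerprints and s the percent sequence identity, maximised over chain
pairs for multi-chain complexes. Sequence identity defaults to a built-in
global pairwise alignment (matches / alignment columns); the provider is
pluggable so an external aligner can be substituted. Complexes are
clustered by single linkage with a distance threshold of 0.5, applied
strictly (d < 0.5 merges; d = 0.5 does not), which coincides with connected
components of the thresholded similarity graph. Candidate test clusters are
excluded whole if any member ligand exceeds 1000 Da or 20 rotatable bonds,
or if the cluster shares a pocket family label with the training data
(labels are consumed from a user-supplied table; their construction is out
of scope, and when absent the filter is skipped with a prominent warning).
Training complexes must additionally satisfy T_s < 0.5, identity < 50%, and
pocket-label difference against every test complex. Training-set pruning
removes complexes whose maximum T_s to any test ligand *strictly exceeds*
the ceiling, so pruned sets are nested across decreasing ceilings.

## Synthetic data

The generator stands in for the crystallographic corpora that cannot ship
with a library. Pockets are clouds of 30–80 template-typed protein atoms
placed 0.8–6.5 Å from randomly chosen ligand atoms, so shells populate both
sides of the 5.1 Å cutoff. Ligands are random single-bonded graphs of 5–12
heavy atoms over the element whitelist, optionally grown around a 5- or
6-membered carbon ring, with hydrogens completing standard valences and
approximate 3D coordinates (1.5 Å bonds). Labels are planted as a linear
functional of the very AEV entries the model consumes, plus Gaussian noise
of 0.3 pK by default. Default weights are sparse (≈15% of (type, R_s)
cells), positively biased, and scaled by a constant (0.23) calibrated once
so that default-spec labels spread like experimental pK values (sd ≈ 1.8 pK
units; mean ≈ 2.3). Because the planted map is linear in the features, a
model family containing it can represent the target exactly, so held-out
performance isolates featurization/training plumbing from chemistry
realism. A congeneric-series mode shares one pocket and a ligand core per
series to exercise per-series statistics and paired tests.

What the generator does *not* emulate: realistic poses or force fields,
aromatic ligands (aromatic perception is exercised through real SDF
fixtures instead), protonation chemistry, measurement heterogeneity, or the
ligand/target redundancy structure of public databases. Passing tests
therefore demonstrate that the pipeline computes what it claims and can
recover a recoverable signal — not that the model reaches any particular
accuracy on real complexes.

## Numerical choices and problem sizes

- All features and network arithmetic are float64; AEV oracle agreement is
  asserted at 1e-10 relative, network forward agreement at 1e-5, symmetry
  invariance at 1e-6 relative.
- The softmax in attention subtracts the per-neighbourhood maximum (a
  constant with respect to gradients) for stability; segment-max pooling
  routes its gradient to the first maximising node on ties.
- Accumulations use fixed orders (atom index, BLAS contractions), so runs
  are reproducible bit-for-bit given the seeds.
- Inference (prediction and per-epoch validation) runs with graph recording
  disabled and the backward tape is severed after each step, keeping the
  training loop's memory footprint flat.
- Checkpoint ties keep the earlier epoch (strict improvement required).
- PDB reading uses the first model and the highest-occupancy altloc
  (ties broken by altloc letter).
- The test suite trains at reduced width — head_dim 32, hidden MLP
  (128, 64), three ensemble members, 120 epochs, cosine-decayed Adam at
  3e-3 on 500 training complexes — chosen as the smallest configuration
  that cleanly recovers the planted signal (held-out ensemble PCC ≥ 0.8;
  a linear readout of the max+mean-pooled raw features caps at ≈0.85 under
  these conditions, so recovery requires near-ceiling training); the
  published full width (head_dim 256, ten members) is the library default.

## Known limitations

- Protein typing is template-based: non-standard residues and ligands
  covalently bound to the protein are not typed (flagged instead); no
  structure repair or protonation assignment is attempted.
- The sequence-identity default is a plain global alignment, adequate at
  desk scale but slower and simpler than dedicated alignment tools; the
  provider hook exists for substituting one.
- The numpy training loop is CPU-bound and intended for desk-scale
  experiments, not for the multi-hour training runs behind the published
  benchmarks.
- `harmonize_affinity` treats IC50 as a pK source on the same footing as
  Kd/Ki after prioritisation; no assay-condition correction is attempted.
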
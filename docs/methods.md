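# Methods note

## Model and estimator

All computation happens on the arcsinh scale, `asinh(intensity / 5)`, the
standard variance-stabilizing transform for mass cytometry. Before
fitting, every protein column is standardized to zero mean and unit sample
variance (ddof = 1); the adjustment is un-standardized afterwards, so the
normalized data live on the original arcsinh scale.

The model for cell `i`, protein `j` is

    Y_ij = X_i beta_j + W_i alpha_j + eps_ij

with unmodelled biology `X beta`, a rank-`k` unwanted component
`W alpha`, and noise. Estimation:

1. **Pseudo-replicate groups.** Cells are clustered jointly across batches
   (below). For each designated reference patient — a sample aliquoted
   into at least two batches — and each metacluster, all that patient's
   cells in that cluster form one group. Groups with fewer than two cells
   are dropped; a group whose cells all come from one batch is kept (it
   still constrains within-batch noise directions) but logged, and the fit
   refuses to run if *no* group spans two batches, because then nothing
   identifies the batch effect.
2. **Residuals.** Each group's mean profile is subtracted from its
   members; all other cells contribute zero rows. This is the projection
   `R = (I - M (M'M)^{-1} M') Y` for the replicate membership matrix `M`
   (singletons being their own groups), computed by grouped means rather
   than dense projection.
3. **`alpha` from the SVD of `R`.** `alpha = diag(s_1..s_k) V_k'`. The
   scaling convention is immaterial: `W alpha` is invariant to any
   invertible reparameterization of `alpha` (verified to 1e-10 in tests).
   When `k` exceeds the numerical rank of `R` it is capped at the rank
   with a warning; `k > min(cells, proteins)` is an error; `k = 0` is the
   identity.
4. **`W` by all-protein regression.** `W = Y alpha' (alpha alpha')^{-1}`:
   every protein acts as a negative control. The adjusted data are
   `Y - W alpha`.

**Fast path.** With `m` cells and `n` proteins, when `m > 5n` the right
singular vectors are taken from `eigh(R'R)` (an `n x n` problem) instead
of a dense SVD of `R`; eigenvalues are clipped at zero before the square
root. The two paths agree to 1e-8 in the tests, and the whole fit is
verified against an independent dense projection-formula implementation on
random instances.

## Clustering

A self-organizing map (default 10 x 10 grid) is trained on the lineage
proteins of all cells pooled across batches: seeded random initialization
from the data, per-epoch best-matching-unit assignment, Gaussian
neighborhood with linearly decaying radius, batch (not online) updates —
so results are deterministic given the seed. The codebook is then
metaclustered by average-linkage hierarchical clustering into `n_meta`
(default 20) groups, relabelled by first occurrence. Cell assignment is
nearest-code with ties broken toward the lowest node index.

## Evaluation metrics

- **EMD.** 1-D earth mover's distance per protein between a replicated
  patient's expression in two batches: both samples are histogrammed on a
  shared grid of 0.1-wide bins whose edges are aligned to multiples of the
  bin width, and the distance is `sum |CDF_x - CDF_y| * bin_width`. The
  binning quantizes shifts: differences within one shared bin read as 0,
  and a pure translation is recovered to within one bin width.
- **Hellinger.** `H(p,q)^2 = (1/2) sum (sqrt(p_i) - sqrt(q_i))^2` between
  per-sample cluster-proportion vectors of a replicated patient across
  batches; 0 for identical compositions, 1 for disjoint support.
- **Silhouettes.** Mean silhouette over all panel proteins with cells
  labelled by batch (`s_batch`) or by metacluster (`s_biology`), on a
  fixed-seed per-sample subsample (default 100 cells/sample) to keep the
  O(m^2) distance matrix tractable. Verified against a brute-force
  from-the-definition implementation.
- **Median differences.** For two-batch designs, per marker
  `Delta = median(batch 2) - median(batch 1)` and
  `DeltaDelta = Delta_raw - Delta_norm`.

Raw and normalized datasets are each scored with their *own* clustering,
as each would be analysed in isolation.

## Synthetic study generator

Cells are drawn as Gaussian subpopulations in arcsinh space. Lineage
markers follow a near-binary positive/negative pattern (positives near 3,
negatives near 0.4 arcsinh units, ~35% positive), functional markers vary
continuously, and within-population sd is 0.3 — the typical structure of
gated CyTOF data. Batch `b`'s distortion is affine per protein
(`scale * x + shift`, optionally subpopulation-specific); batch 1 is
always the identity, so the injected unwanted component is exactly defined
per cell, and the raw-intensity tables are produced by `5 * sinh(.)`.

The default presets inject a **rank-2** cluster-specific shift built from
two shared protein-loading directions. Each batch's loading weights have a
random direction but *fixed* magnitude (a raw Gaussian draw would make the
realized effect size vary several-fold across seeds, so a preset would not
reliably realize its nominal conditions), plus per-subpopulation jitter
(sd 0.3 in weight space). The marginal per-protein shift scale is
calibrated to 0.5, giving typical shifts ~0.4 and peaks ~1 arcsinh unit on
the most affected markers.

**Realism and limits.** This effect size is deliberately large — clearly
visible in EMD (raw reference-sample median ~0.4) and in MDS of sample
medians — but still small enough that each subpopulation stays closer to
its cross-batch twin than to other subpopulations. That is a hard
applicability limit of the method itself, not of the generator: pushing
shifts to ~3x the biological separation makes the joint clustering split
subpopulations by batch, pseudo-replicate groups stop spanning batches,
and normalization fails outright. The generator does not model
multiplicative-only drifts per cluster, signal crosstalk between metal
channels, acquisition-time drift within a run, or doublets; an optional
uniform heavy-tail contamination fraction is available but off by default.

## Known limitation: biology leakage into `W alpha`

Using all proteins as negative controls means the `W` regression projects
each cell's *whole* profile — biology included — onto the `alpha`
directions. Any component of the biological subpopulation means that is
not orthogonal to `alpha` therefore enters `W alpha` as a batch-invariant,
per-subpopulation constant. On the default preset (seed 1, k = 2) this is
directly measurable: the elementwise correlation between `W alpha` and the
injected offsets is 0.60, but the estimate's error is almost perfectly
shared between batches (correlation 0.996 between the two batches'
per-subpopulation error profiles), and after removing that batch-invariant
component the correlation rises to 0.97. The same values arise when the
fit is given the ground-truth cluster labels, so this is a property of the
estimator, not of the clustering step.

The batch-invariant part of the leakage shifts both batches of a
subpopulation identically, so it cannot *create* cross-batch differences —
which is why the correction metrics are unaffected (EMD drops to 12% of
raw, `s_batch` falls to ~0) — but it does perturb absolute expression
levels slightly, which is one reason `s_biology` can move after
normalization and why `k` should be kept near the true effect rank:
larger `k` removes more variance that is indistinguishable from biology
under this design. The acceptance test demanding elementwise recovery
correlation ≥ 0.95 fails for exactly this reason and is left failing
rather than weakened.

## Numerical and sizing choices

- All stochastic steps (SOM init, subsampling, the generator) use
  `numpy.random.default_rng` with explicit seeds; every pipeline output is
  reproducible from its `manifest.json`.
- The "full-size" two-batch preset is 24 samples x 850 cells = 20,400
  cells — large enough that the SVD fast path, subsampled silhouettes and
  histogrammed EMD all run in their production regimes, small enough to
  fit a single CPU in seconds. The end-to-end test runs the same preset
  at a reduced 300 cells per sample.
- FCS files are written as FCS 3.1, float32 little-endian; values
  round-trip exactly at float32 precision.
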
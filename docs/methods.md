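# Methods

This note records the models behind `tilescope`, the parameters that matter,
and the design choices made where the architecture left room.

## What is being modeled

The system under study is a tile-based whole-slide renderer: a pyramid of
downsampled slide levels cut into 256×256 tiles, a scope view drawing an LR
and an HR resolution layer per frame, and a buffering pipeline that keeps
the view resident under rapid slide driving.  The real engine runs this on
concurrent CPU threads and GPU queue families; `tilescope` reproduces the
*coordination semantics* — not the hardware — as a deterministic
single-threaded discrete-event simulation.  "Atomic" operations become
indivisible event handlers, and concurrent queue execution becomes
overlapping event intervals.  Consequently every reported time is a
simulated-clock quantity derived from explicit latency models, and no claim
is made about wall-clock performance on any hardware.

## Geometry conventions

Pixel rectangles are 0-based and half-open on both axes; tiles are addressed
(col, row), row-major.  `zoom` is screen pixels per base-level slide pixel,
so level ℓ draws at ratio r_ℓ = zoom·d_ℓ.  The HR layer is the level with
the largest r_ℓ ≤ 1 and the LR layer the one with the smallest r_ℓ > 1;
r = 1 exactly counts as HR, and because downsample factors are strictly
increasing the two layers are adjacent whenever both exist.  At zoom
extremes one layer may be absent, in which case the remaining layer renders
alone — no extrapolated layer is invented.  View/tile overlap requires
positive area: a view edge exactly on a tile boundary does not pull in the
neighbor.  Non-power-of-two downsample factors are accepted (real scanners
produce them); the synthetic generator emits powers of two.

## Reduction-enhancement kernels

Each mipmap level k ≥ 1 is produced directly from the 1× reference tile by
one floating-point convolution with

    w_k = normalize( G(σ_k) − α · ∇²G(σ_k) ),

truncated at 3σ, followed by bilinear sampling at the centers of the 2^k
pixel cells and a single quantization to 8 bits.  The LoG term is forced to
zero sum before mixing, so w_k sums to exactly 1 for every α and constant
(DC) content is preserved; α = 0 degrades to a pure Gaussian anti-alias
filter, and larger reductions get larger kernels.

**Choice of σ_k.**  The unenhanced (α = 0) path should approximate ideal
area-average downsampling, both because that is what a neutral storage
pyramid uses and because it is what makes the single-quantization advantage
of single-pass generation measurable against a float area-average oracle.
A 2^k-wide box average has per-axis variance (4^k − 1)/12, and the
half-pixel bilinear phase of center sampling contributes a further 1/4, so
we set

    σ_k = sqrt( max( (4^k − 1)/12 − 1/4, 1/4 ) )      (≈ 0.5, 1.0, 2.24 for k = 1, 2, 3)

which matches the α = 0 filter to the area average to second order.  A
wider family (for example σ_k proportional to 2^k) over-blurs relative to
the averaging cell: on any content with energy near the level's Nyquist
band the α = 0 output then deviates from the area average by far more than
one quantization step, which both softens the rendered image and would make
successive box-halving look *better* than single-pass generation on an RMSE
comparison — the opposite of the property the design exists to deliver.
The floor of 0.5 keeps the k = 1 kernel non-degenerate.

With this choice the cumulative-error comparison measures what it should:
successive halving quantizes at every level (error ≈ 0.33 gray RMSE at 8×
from three stacked roundings), single-pass quantizes once (≈ 0.29), and the
gap is reproduced on 100 seeded smooth tiles by tests and the acceptance
script.  α defaults to 0.5 and applies to every level k ≥ 1 (whether the 2×
level should be enhanced is genuinely open; it is configurable).  Borders
are edge-replicated — tiles are filtered independently, with no cross-tile
apron — which can, in principle, produce faint seams at tile boundaries
under enhancement; this is a known fidelity limitation, shared by the
sampling clamp below.

## Scheduler model

Engine parameters (all times in simulated ms):

| parameter | default | meaning |
|---|---|---|
| pool_size | 512 | recycled allocation slots (fixed; validated ≥ largest view + perimeter) |
| batch_cap | 16 | max tiles per microtransaction |
| perimeter_radius | 2 | prefetch dilation in tiles (typical 1–3) |
| frame_interval_ms | 8.333 | 120 Hz display |
| loader_const_ms + jitter | 1 + Exp(1) | per-tile decode latency; presets: fast (1+1), slow (5+5) |
| loader_concurrency | 4 | simultaneous decode threads |
| transfer_overhead_ms, rate | 0.1, 2 GB/s | microtransaction duration = overhead + bytes/rate, unlimited overlap |
| cache_capacity | 1024 tiles | short-term RAM cache, least-recently-relevant eviction |

Planning is stateless: every pass recomputes the LR and HR buffer regions
from the current view only, skips tiles whose map entry is live
(ACTIVE/TRANSFERRING with matching generation), batches cache-resident
unmapped tiles into microtransactions — all LR batches before any HR batch,
tiles ordered center-out (distance of tile center from view center, then
row-major) — and rebuilds the loader request queue from scratch, so a view
change between passes automatically drops stale work.  Loader requests use
two priority classes (LR high, HR low); the per-pass rebuild realizes the
"most recent request wins" discipline directly.  Binding a tile pops a FREE
slot, bumps its generation exactly once, and sets cache ownership to the
buffer queue; transaction completion flips the slot ACTIVE and hands
ownership to the render queue.  Rendering draws only tiles whose wrapper is
ACTIVE with matching generation *and* render-queue ownership — withholding
the handoff, or a stale generation left by slot recycling, excludes the
tile (stale map entries are purged on sight).  Purging out-of-region tiles
just flips ACTIVE→FREE; slots referenced by the frame currently drawing
(ref_count > 0, held only for that frame) are deferred to a later pass.
A tile that cannot bind for want of a free slot is logged as deferred and
retried on the next pass, never dropped silently.

The loader decode and the transfer-and-enhance step are charged to the
latency models; actually computing the mipmap stacks at transaction
completion is optional (`compute_mipmaps`) so that pure scheduling studies
stay cheap, and is enabled wherever pixels are rendered.  Simulations may
run against a bare pyramid (no pixel store); payload byte counts always use
the true, truncated tile geometry.  A `cache_warm_bonus` hook (default off)
can shorten the frame following a large completed burst, mimicking
cache-residency effects on draw cost.

## Metrics

Frame-rate is the inverse of the interval between FRAME records.
Buffer-rate divides the bytes completed in (previous frame, this frame] by
that frame's duration; because buffering is bursty the summary additionally
reports the median over frames with nonzero completed bytes.  TeFOV is
measured per marked move-field (the trace generator guarantees the new
rectangle shares no pixels with its predecessor) as the time until every
tile of the layer's buffer region — view plus perimeter, the same set the
scheduler targets — is resident; fields whose targets were all already
resident at move time are excluded from the statistics and counted, and a
layer that never completes within the log is reported as incomplete rather
than as a number.  TPT is TeFOV divided by the full buffered tile count
(perimeter included), so TPT·n ≡ TeFOV by construction.  Summaries use
medians with 25th–75th percentiles, linear interpolation between order
statistics.  Which layer has the lower TPT is regime-dependent in this
model: when the per-field fixed latency dominates (fully concurrent loads,
fast transfers), the larger HR fields amortize it and HR TPT falls below LR
TPT; when serialized loading dominates, LR's priority head start wins.

## Compositing

The LR pass draws all drawn LR tiles, the HR pass overdraws with drawn HR
tiles; pixels under unbuffered HR tiles keep LR content (the stencil
optimization of a real GPU pass is modeled as full draw + overdraw, which
is visually equivalent).  Tiles sample trilinearly: level of detail
λ = clamp(−log₂(screen px per tile px), 0, deepest), bilinear within the
two bracketing levels, blended by frac(λ); levels are co-registered via the
center-sampling convention (level-k pixel j sits at reference coordinate
(j+0.5)·2^k − 0.5).  Sampling clamps at tile borders (no cross-tile
filtering apron) — the corresponding seam risk is accepted and documented.
The ground-truth oracle resamples the full base raster by exact per-pixel
area averaging over each screen pixel's footprint (integral image with
fractional bounds).  With all tiles resident and α = 0, the composite
agrees with this oracle within L∞ ≤ 8 gray levels and RMSE ≤ 2 on smooth
synthetic slides; the observed error at desk scale is ≈ 1 gray level L∞.

## Synthetic data

`generate_slide` writes a smooth eosin-pink background (Gaussian-correlated
texture, ~24 px scale) with dark, hard-edged elliptical nuclei (semi-axes
8–26 px) to exercise edge enhancement; coarser levels are area averages of
the stored level below, quantized per level, so the storage pyramid is
neutral and exactly self-consistent.  `generate_saccade_trace` emits field
jumps of at least one full view extent along an axis (guaranteeing the
no-pixel-overlap property by construction) at a configurable rate, with
small overlapping dwell drifts in between.  What this does *not* emulate:
real stain statistics, scanner noise, JPEG/JPEG2000 compression artifacts,
tissue-scale structure, or real decoder latency distributions — so passing
tests demonstrate the correctness of the geometry, scheduling, enhancement
and metric logic under the stated models, not end-to-end performance on
clinical slides.

## Problem sizes

Default study conditions: a virtual 16384² pyramid, a 1024×768 screen at
zoom 1, 12-second traces at 2 field jumps/s (24 disjoint fields per run),
and 20 seeded runs for the scheduler contract checks; enhancement
comparisons use 100 seeded 256² tiles; compositor checks use a 1024² slide
with a 256×192 view.  These desk-scale sizes exercise every code path
(multi-level layers, partial edge tiles, purge/recycle churn) while keeping
the full suite and the acceptance script fast and deterministic.
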
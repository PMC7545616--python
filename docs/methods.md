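# Methods

## The two assays and their models

**Evoked single-cell assay.** Adherent fibroblasts loaded with the
non-ratiometric indicator Fluo-4 are perfused through five contiguous
phases — Ca²⁺ HBSS (0–180 s), 0-Ca²⁺ (180–360 s), ATP in 0-Ca²⁺
(360–480 s), 0-Ca²⁺ (480–600 s), Ca²⁺ re-addition (600–720 s). ATP, a
GPCR agonist, triggers IP₃ production and hence IP₃R-mediated Ca²⁺ release
from the ER; because extracellular Ca²⁺ is absent, the measured transient
is release-only. The final re-addition phase elicits store-operated Ca²⁺
entry (SOCE) and serves as a positive control: it is simulated but excluded
from all kinetic metrics.

The generator models a cell's raw fluorescence as

    F(t) = F0 · (1 + d·t + x(t) + s(t)) + ε(t),   ε ~ N(0, σ²)

where `d` is a linear drift (photobleaching), `s(t)` the SOCE transient
confined to the re-addition phase, and the agonist transient is the minimal
separable rise/decay form

    x(t) = a · m · (1 − e^−(t−t₀)/τ_r) · e^−(t−t₀)/τ_d,   t ≥ t₀,

with onset `t₀ = (agonist start) + latency`. No functional form is imposed
by the assay itself; this one was chosen because it is the standard
two-time-constant description of an indicator transient and has closed
forms for its maximum, `a·m·(1−e^−s*/τ_r)·e^−s*/τ_d` at
`s* = τ_r·ln(1 + τ_d/τ_r)`, and its integral — which the test suite uses
as independent oracles (quadrature, analytic peak). Genotype effects enter
multiplicatively on amplitude (`m`), additively on latency, and
multiplicatively on τ_r, reproducing the qualitative patient/knockdown
phenotypes (reduced AUC, delayed peak) without claiming channel-level
mechanism.

**Ratiometric plate assay.** Fura-2 shifts excitation with Ca²⁺ binding,
so the F₃₄₀/F₃₈₀ emission ratio rises with cytosolic Ca²⁺ and cancels dye
load and optical gain. EGTA (extracellular chelator) is added at 30 s, the
stimulus at 90 s, and the response is followed to 450 s. The generator
produces the two channels as `F340 = F340_rest·g·√r(t)` and
`F380 = F380_rest·g / √r(t)`, where `r(t)` is the target
baseline-normalised ratio (same transient form as above) and `g` a
per-well lognormal gain. This construction makes F₃₄₀ rise and F₃₈₀ fall
with Ca²⁺, gives back `r(t)` exactly after normalisation in the noise-free
case, and makes gain invariance of the downstream metrics a sharp,
testable property.

## Key parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| frame interval, evoked | s | 1 | not dictated by the protocol; 720 frames resolve τ_r = 3 s adequately and keep simulations cheap; configurable |
| frame interval, plate | s | 5 | typical plate-reader cycle for alternating excitation; configurable |
| `baseline_f0` | a.u. | 100 | arbitrary camera units; all analyses are gain-invariant |
| `amplitude_a` | ΔF/F₀ | 1.5 | typical robust GPCR-agonist response for a high-affinity indicator |
| `latency_s` | s | 2 | perfusion dead time + IP₃ cascade delay |
| `tau_rise_s` / `tau_decay_s` | s | 3 / 20 | fast release, slower clearance; τ_d > τ_r required |
| `drift_per_s` | /s | −10⁻⁴ | mild photobleaching (≈ −7% over 12 min) |
| `noise_sd` | a.u. | 2 | ≈ 2% of baseline, realistic sCMOS read + shot noise lump |
| `soce_amplitude` | ΔF/F₀ | 0.3 | visible positive control, well below the agonist response |
| coverslip / cell CV | — | 0.10 / 0.15 | two-level lognormal biological variability; latency jitter SD 2 s |
| baseline window | s | 30 | long enough to beat noise, fits the 180 s phase |
| smoothing window | frames | 5 | centered running average |
| plate windows | s | baseline 30–90, metrics 90–450 | the assay's stated quantification windows |
| dominant filter | — | freq ≤ 10⁻⁵, CADD ≥ 15 | the screen's thresholds; both configurable |

## Numerical and design choices

- **"Stable" baseline frames** are made objective as the contiguous window
  minimising the rolling standard deviation within the first 0-Ca²⁺ phase
  (earliest window on ties). This is a reproducible surrogate for manual
  frame selection; F₀ is the window mean.
- **AUC** is the trapezoidal integral of the *signed* ΔF/F₀ (or
  normalised-ratio-minus-1) over the response window, with no re-zeroing at
  the window start; negative excursions subtract. The response window runs
  from agonist onset to the end of the following 0-Ca²⁺ phase (360–600 s by
  default); SOCE is excluded.
- **Time to peak** uses the first maximum on ties — it is a latency.
- **Running average** uses a symmetrically shrinking window at the edges
  (half-width `min(i, n−1−i, k//2)`), preserving trace length so the
  fixed-second analysis windows keep their frame counts, and passing linear
  ramps through unchanged everywhere. Smoothing precedes normalisation by
  default; the reverse order is available and differs only near
  baseline-window edges.
- **Plate metrics** are measured relative to the normalised baseline value
  1 (on `norm − 1`), so a flat no-response trace scores exactly 0 on all
  three metrics.
- **Non-responders**: amplitude below 3× the baseline noise is flagged but
  retained unless dropping is requested. The stability score is in raw
  fluorescence units while amplitude is ΔF/F₀, so the threshold is applied
  on the unit-consistent scale `3·(stability/F₀)`.
- **Exactness**: round-trip and normalisation identities hold to
  floating-point rounding (relative ~10⁻¹⁴; numpy's SIMD reductions make
  bit-identity of a pixel mean unattainable), and tests assert them at
  rtol 10⁻¹²; genuinely algebraic identities (ΔF/F₀ of F ≡ F₀) are exact.
- **ANOVA** is the explicit between/within decomposition with F on
  (k−1, N−k) degrees of freedom, so degenerate designs behave predictably
  (zero within-group variance → F = ∞, p = 0 under separation; identical
  groups → F = 0, p = 1); `scipy.stats.f_oneway` is the independent
  cross-check in the tests. No post-hoc test runs by default; Tukey HSD is
  available behind `pairwise_tukey`. Statistics refuse cell- or well-level
  tables via the `unit_type` tag.
- **Variant screens**: missing population frequency counts as 0 (novelty is
  evidence of rarity) while a missing CADD score fails the minimum (an
  unscored variant cannot meet it); both behaviours are flags.
  "Nonsynonymous" is {missense, stop-gain, stop-loss, start-loss,
  frameshift, splice-site} minus the excluded classes (synonymous, in-frame
  indels). Coordinates are 1-based as in VCF; multi-allelic rows are
  refused with instructions to pre-split. The external control-cohort joins
  of the original trio framework are reduced to a single frequency
  threshold against supplied annotations.

## What the generator does and does not emulate

It reproduces: the phase timing of both protocols, genotype-dependent
amplitude/latency structure, two-level (coverslip/cell) biological
variability, per-well gain variation, photobleaching drift, Gaussian
measurement noise, and — for the filter — background variants that each
violate at least one criterion with spike-ins inserted verbatim.

It does not model: IP₃R gating or dye-binding kinetics, shot-noise
statistics, cell motion or focus drift, perfusion fluid dynamics,
spatially structured backgrounds, or linkage structure between variants.
Passing tests therefore demonstrate that the *pipelines* are correct and
calibrated under the assumed statistical structure, not that the biological
model is accurate; on real recordings, motion, nonstationary bleaching and
non-Gaussian noise can degrade baseline selection and AUC in ways these
tests do not probe.

## Problem sizes

Parameter-recovery checks use 100 replicates of a 20 vs 20 coverslip design
with 15 cells per coverslip (the scale of the original per-line experiment
counts), injected effects of 0.6× amplitude or +10 s latency, and default
noise. The ANOVA null calibration uses 3 groups × 10 units × 2000
replicates. Filter checks use 100 constructed background records plus 9
(dominant) or 1 (trio) spike-ins. These sizes give sub-percent Monte-Carlo
error on the reported rates while keeping the whole suite around a minute.

## Known limitations

- Baseline selection assumes the first 0-Ca²⁺ phase is quiescent; cells
  with spontaneous activity there will get a biased F₀.
- The shrinking-edge running average slightly under-smooths the first and
  last `k//2` frames relative to the interior.
- The de novo screen trusts genotype calls; no depth/quality modelling.
- Exclusion handling is list-based by design — no automated outlier
  criterion is provided.
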
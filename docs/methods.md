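# Methods

## The measurement model

A limited-cycle multiplex PCR terminated in the exponential phase keeps the
amount of each amplicon proportional to the input copy number of its gene.
During a melt ramp, an intercalating dye's fluorescence falls as each product
dissociates, so the raw curve is a staircase: one step per amplicon, step
amplitude proportional to product amount. The simulator encodes exactly this
model:

    F(T) = b0 + b1·(T − T_min) + Σ_i A_i / (1 + exp((T − Tm_i)/w_i)) + ε(T)

with `A_i = scale · per_copy_amplitude_i · copies_i`, i.i.d. Gaussian noise
ε ~ N(0, noise_sd²), and clipping at zero fluorescence. The decreasing
logistic was chosen because it reproduces the sigmoidal melt steps of real
HRM data while having closed forms that serve as independent test oracles:
its −dF/dT peak is `A/(4w)` at Tm, and the inter-melt plateau of a
two-window-normalized staircase is an exact amplitude fraction
`A_num/(A_den + A_num)`.

Saturation/plateau PCR kinetics are deliberately not modelled — proportional
amplification is the assay's operating regime, enforced in the wet assay by
stopping at 27 cycles. Heteroduplex or point-mutation melt-shape changes are
also out of scope: they perturb curve *shape*, not the total fluorescence
drop per amplicon, and therefore not copy calls.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| acquisition grid | 77→87, step 0.2 | °C | matches a Rotor-Gene-style HRM ramp (51 points) |
| amplicon Tms | 79.4 / 82.2 / 85.2 | °C | assay products ~3 °C apart; reference melts first |
| transition width `w` | 0.20 | °C | 10–90% melt width ≈ 0.9 °C, realistic for 130–170 bp products; leaves ≥0.8 °C inter-melt plateaus where the melt-attributable \|dF/dT\| is ≤5% of the adjacent peaks, which the window method requires |
| `per_copy_amplitude` | 1.0 (all amplicons) | a.u. | primer concentrations in the assay are balanced so the reference signal is comparable to the targets |
| baseline | intercept 2.0, slope −0.05 | a.u., a.u./°C | residual dye signal with mild thermal decay |
| per-sample `scale` | log-normal, σ = 0.15 | — | pipetting/amplification variation; forces all callers to be control-normalized |
| `noise_sd` | 0.02 | a.u. | ~0.3% of the total melt amplitude, the order of instrument HRM noise after acquisition filtering; no public raw data exists to fit, so this is justified by the robustness envelope below |
| smoothing | Savitzky–Golay, window 7, order 2 | points | 0.2 °C grid with modest noise; endpoints by polynomial-fit truncation |
| assignment window | ±1.2 | °C | Tms are ~3 °C apart, so windows never overlap |
| normalization window width | 1.2 | °C | see "numerical choices" |
| copy snap tolerance | 0.35 | copies | states are 0.5 apart in ratio units; beyond 0.35 the call is flagged `ambiguous` rather than trusted |
| peak absence threshold | 10% of control | — | one copy sits near 50%; 10% separates true absence from the lowest real state |
| plateau absence threshold | 5% | — | same role for the window method |

The bundled validation cohort reproduces the published composition: 17
genotype classes, 167 samples (105 marked pre-genotyped, 62 blind), 108 with
abnormal copy pairs, plus one wild-type control per run.

## Numerical choices

**Derivative.** −dF/dT is a central difference (one-sided at the ends). On a
0.2 °C grid this attenuates a width-0.2 logistic derivative peak by a factor
`tanh(h/2w)/(h/2w)` ≈ 8%. The attenuation is identical for all amplicons and
cancels in every ratio the callers use; absolute peak-height accuracy against
the analytic `A/(4w)` is therefore asserted on wider (w = 0.4) transitions,
where discretization costs only ~2%, while amplitude *proportionality* is
asserted at the defaults.

**Peak baseline.** Each amplicon's peak height is measured above the mean
−dF/dT of the two flanking plateau windows, which removes the fluorescence
baseline slope the instrument software also removes.

**Two-window normalization.** A line is fit over each window and
extrapolated; `n(T) = 100·(F − L_post)/(L_pre − L_post)`. Linear baselines
are absorbed by construction. The pre and post lines share one pooled slope
(estimated across all four plateau windows, each keeping its own intercept):
in a plateau region the only true slope is the common fluorescence baseline,
and an independently fitted slope from a handful of noisy points, multiplied
by the ~3 °C extrapolation to the read region, would dominate the plateau
error (measured on the default cohort: ~0.2-copy errors with independent
4-point slopes versus <0.07 copies pooled). For the same reason windows
default to 1.2 °C (7 grid points) — as wide as the flat plateaus allow, like
an analyst's hand-set bars — and curves are smoothed before normalization,
as the instrument software does. The plateau is read over the central 50% of
the stage's inter-Tm gap to avoid shoulder contamination.

**Window placement.** Automatic: the flattest (minimum mean |−dF/dT| of the
control curve) window within each eligible region — below the reference
melt, each inter-Tm gap, above the last melt. Placement fails loudly, with
advice to set windows manually, if the flattest candidate still carries more
than 15% of the tallest derivative peak.

**Sequential resolution and tie-breaks.** The reference is assumed two-copy;
stage 1 resolves HBA1, whose integer call then anchors stage 2 for HBA2 —
no joint estimation. Candidates snap to the nearest allowed state (ties to
the lower state); a candidate farther than the tolerance carries the nearest
state plus `ambiguous`. A stage-1 ratio above 2.0, or an HBA1 state outside
{0,1,2,3}, raises `improbable_reference` — a reference-gene anomaly
masquerading as a target change. Flagged samples are never dropped; they are
routed to confirmatory testing, as a screening workflow requires.

**Degenerate inputs.** A missing reference peak is a hard per-sample error
(no quantification anchor); a control that miscalls or has degenerate
plateaus fails the whole run; a constant curve raises a degenerate-
normalization error; a vanished stage-2 span (both targets deleted) is
caught and read as absence rather than a ratio.

## What the simulator does and does not emulate

It emulates: proportional per-copy amplitudes, separable logistic melt
steps on the real acquisition grid, per-sample global scale variation,
additive instrument noise, baseline drift, and cohort composition with a
designated wild-type control. It does not emulate: PCR saturation,
sequence-dependent melt-shape changes (heteroduplexes, point mutations),
temperature calibration drift between samples, or inter-run variation.
Passing tests therefore demonstrate that the analysis correctly inverts the
proportional-amplitude model under realistic noise — not that the wet assay
achieves these error rates; the published validation supplies that evidence
for the assay itself.

## Robustness envelope

`python scripts/noise_sweep.py --seed N` reports unflagged concordance,
flags and miscalls for both callers across noise levels on the 167-sample
cohort. At the default noise (0.02) both callers recover every sample
unflagged. The peak-ratio caller begins flagging (without silent miscalls)
at ~2.5× default noise and degrades beyond ~5×; the window-ratio caller,
whose plateau averaging is intrinsically less noise-sensitive, stays exact
up to ~5× default; beyond that, automatic window placement refuses to run
(no sufficiently flat plateau) rather than emit unreliable calls.

## Known limitations

* Copy counting cannot see balanced rearrangements (a deletion in trans to a
  duplication looks wild-type) nor identify *which* deletion allele is
  present — that is confirmatory-test territory.
* The two-copy reference assumption is monitored only indirectly via the
  `improbable_reference` flag.
* Genotype-class labels are anchored to assay coordinates (the −α3.7 hybrid
  counts as HBA1), not to clinical nomenclature.
* The melt CSV dialect is this package's own interchange format; proprietary
  instrument exports must be converted upstream.
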
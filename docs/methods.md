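# Methods

This note records the scientific model behind `audiopvt`, the defaults and
the reasoning for every choice that was genuinely open.

## Stimulus paradigms and scheduling

The simple reaction-time paradigm draws each inter-stimulus interval (ISI)
independently from a continuous uniform law on `[min_delay, max_delay]`.
The ISI is anchored at stimulus *offset* — the drawn delay separates the end
of one tone from the onset of the next — so a long tone can never overlap
the following trial. The go/no-go paradigm uses a fixed ISI equal to
`min_delay`, and assigns each trial no-go status independently with
probability `nogo_fraction` (default 0.25, a conventional minority share
that keeps the prepotent go response dominant). A single seed fans out into
independent sub-streams for ISI draws and go/no-go assignment
(`numpy.random.SeedSequence.spawn`), so changing `nogo_fraction` does not
perturb the ISI sequence.

The expected session duration is
`repetitions x (tone_duration + E[ISI])`, with `E[ISI] = (min+max)/2` for
the uniform law. For the classic field setup (1–10 s ISI, 110 repetitions,
150 ms tone) this gives about 10.4 min. Descriptions of that classic
schedule sometimes quote a mean ISI of ~4.5 s, which no uniform draw on
[1, 10] s can produce (its mean is 5.5 s); the original schedule may not
have been uniform. We use the uniform law — the natural reading of "selected
randomly between a minimum and a maximum" — and publish the duration formula
above rather than guessing at an alternative law.

Default tones: go 440 Hz (A4), 150 ms; the no-go tone is the quadruple of
the go frequency (two octaves up, trivially discriminable) at the same
duration. Tones are sines with 5 ms raised-cosine on/off ramps, standard
audio practice to avoid spectral splatter and audible clicks; peak amplitude
equals the configured volume fraction.

## Response classification

All times are real-valued milliseconds; exported times are rounded to
0.1 ms. A trial's response window runs from its onset to the next onset (or,
for the last trial, to a session end placed one nominal ISI after the last
tone), so the windows tile the session and every press belongs to exactly
one trial.

* Go trial: responses faster than `min_response_time` (default 100 ms, the
  conventional anticipatory threshold) are false starts, logged as false
  positives *without consuming the trial* — the first later press at or
  above the threshold still counts as the true positive. This matches
  conventional PVT false-start handling. A go trial with no press is a miss
  (false negative); a go trial with only false starts keeps its
  false-positive records and yields no additional miss record, so trial
  outcomes are conserved: `#go = #TP + #miss + #false-start-consumed`.
* No-go trial: any press is a commission (false positive); no press is a
  correct rejection. Correct rejections are a fourth bookkeeping category,
  needed for go/no-go conservation, and are excluded from the "total
  responses" count, which counts button events only (`TP + FP`).
* Presses after a trial's true positive but before the next onset are
  spurious extra presses, logged as false positives, keeping
  `n_total = n_TP + n_FP` an exact invariant.

Interruption is modelled through the input stream's *horizon*: if the stream
ends before a trial's window provably closed, the session state (config,
schedule, records, completed-trial count) is checkpointed as versioned JSON
and can be resumed; resuming replays identically to an uninterrupted run
because trials are only ever adjudicated once, at window close.

## Scoring conventions

RT statistics are computed over true-positive response times only (false
starts excluded). Quartiles use linear interpolation between order
statistics (the inclusive method); SD uses the n−1 denominator; with no true
positives the statistics are NaN-flagged rather than zero. Response speed is
`mean(1000/RT)` in 1/s. Condition aggregation reports, per
(condition, time point) group, the number of sessions and the mean and SD of
the per-session mean RTs; a single-session group's SD is reported as NaN,
not 0, since a spread cannot be estimated from one session.

## Synthetic responder

Reaction times follow the ex-Gaussian distribution — a Gaussian (mu, sigma)
plus an independent exponential tail (tau), the standard descriptive model
for human RT — truncated below at 0. Defaults (mu 330 ms, sigma 50 ms, tau
90 ms → mean 420 ms, SD ≈ 103 ms; lapse probability 0.02; 0.2 false starts
per minute; no-go commission probability 0.05) describe an alert healthy
adult on an auditory task, consistent with group means of roughly
390–470 ms observed in lighting-intervention field studies with this kind
of device.

False starts are generated as a Poisson count per session
(`rate x session minutes`), each placed uniformly inside the premature
window `[onset, onset + min_response_time)` of a uniformly chosen trial.
Placing them anywhere in the inter-stimulus gap would let a "false start"
land where the engine must treat it as a valid or spurious response —
corrupting the very counts the simulation programs — so the generator
restricts them to times that are false starts by definition.

The responder deliberately omits features of real data: sequential
dependencies and time-on-task slowing, motor/keyboard latency jitter,
post-error slowing, and RTs long enough to spill into the next trial's
window (negligible at the default ISIs). Passing end-to-end tests therefore
demonstrates correct bookkeeping and distributional behaviour of the
pipeline, not fidelity to any particular participant population.

## Timing-validation model

Three delay series describe a validation run: *expected* (programmed true
delays, cycling deterministically over a grid, default 300–990 ms in 10 ms
steps, n = 1000), *recorded* (what the software under test reports; modelled
as expected plus optional zero-mean Gaussian jitter, default SD 0 — the
scripted software chain is exact by construction), and *measured* (what an
external recorder sees).

The recorder samples every Δ ms (default 4 ms, i.e. a 250 Hz instrument) and
detects an event at the first sample instant at or after it; `quantize`
implements this as a ceiling onto the grid `phase + kΔ`. When event times
and the sampler phase share an integer-millisecond grid, the detection
offset is discrete uniform on {0, …, Δ−1} ms with mean `(Δ−1)/2` and
population variance `(Δ²−1)/12`. The experiment draws an independent
*integer* phase per trial from that set — the i.i.d. reading of the
discrete-uniform assumption; a continuous phase would instead give a
continuous U[0, Δ) offset with mean Δ/2, which is not the model being
corrected for. The corrected series subtracts `E(se)` from each measured
value; the corrected variance subtracts `VAR(se)` from the measured sample
variance (variances of uncorrelated terms add), floored at 0 with a warning
because a variance cannot be negative.

The correction is always applied with this sign convention
(`corrected = measured − E(se)`); consequently the recorded-vs-corrected
mean difference equals the recorded-vs-measured difference *plus* `E(se)`.
Published tables for this style of analysis occasionally report that
contrast with the opposite sign (as recorded-minus-measured minus `E(se)`);
this implementation does not reproduce that variant.

Agreement statistics: Bland–Altman mean difference and sample SD of paired
differences, limits of agreement at mean ± 1.96 SD (the standard normal 95%
multiplier), paired t = mean/SEM with n−1 df, two-sided p-values, no
multiple-testing correction (each comparison answers a distinct question).
Proportional bias is assessed by OLS of differences on pairwise means
(statsmodels), with 95% CIs from the t distribution with n−2 df; with
degenerate inputs (zero SD of differences, zero spread of means) the
affected statistics are NaN-flagged rather than raised. The recommended
accuracy margins for PVT response timing — |bias| ≤ 5 ms, SD ≤ 10 ms — are
exposed as constants and used as the pass criterion for the end-to-end
engine check, which scripts 1 000 presses through the actual session engine
and verifies the recorded response times equal the programmed delays to
float precision.

## Numerical choices

* Quantization ceiling uses a 1e-12 relative guard so on-grid events map to
  themselves despite float division.
* Times are double-precision ms internally; file export rounds to 0.1 ms,
  and round-trip tests compare at that resolution.
* The systematic-error moments are computed by enumerating {0..Δ−1}
  directly; tests check them against the closed forms.
* Seeds below 2³¹ are derived from a single user seed via `SeedSequence`
  spawning wherever several independent streams are needed.
* Degenerate inputs (empty record sets, single-session groups, zero-SD
  series, identical series in Bland–Altman) return NaN-flagged fields, never
  silent zeros.

## Problem sizes

Distributional tests use 10 000-trial schedules (moment recovery,
ISI goodness of fit, no-go proportion), 1 000 random scripted mini-sessions
for the classification replay oracle, and n = 1000 (with one convergence
check at n = 10⁵) for the validation experiment — sizes at which the
Monte-Carlo error bands (3×SE) are tight enough to be informative while the
whole suite runs in seconds on one CPU.

## Known limitations

* No audio playback or audio-path latency modelling: the measured ~0.9%
  prolongation of a physical 500 ms stimulus on real hardware is a hardware
  property outside this package's scope.
* No modelling of GPIO/keyboard/mouse input-latency differences; the
  scripted input source is exact.
* The mixed-ANOVA stage of a lighting study is out of scope; the condition
  table is designed to feed any standard statistics package.
* The go/no-go no-go placement is random (Bernoulli per trial); devices
  using balanced or pseudo-random no-go sequences will differ trial-by-trial.
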
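# Methods

## Content model and container format

A speller recording is modelled in two tiers. *Level 0* holds everything an
acquisition produced: the continuous multichannel signal (microvolts), the
sampling rate, the sensor table (10–20 labels, channel ordinals,
reference/ground, free-text technology notes) and the stimulus-event
stream. *Level 1* adds everything a machine-learning consumer needs with no
side documents: the encoder (the 6×6 symbol layout), the semantic alphabet,
per-character begin/end markers with the intended symbol, and the
stimulation parameters (ISI, iteration range) — stored explicitly or
deducible from the events. `validate` reports both tiers with coded
findings (`SENSOR_ORDER`, `NO_ENCODER`, `SEQUENCE_LOST`, …) and never
raises; `level1_ok` implies `level0_ok` by construction.

The on-disk format (`.p3x`) deliberately separates content from container
technology: one compact UTF-8 JSON line (schema version, all metadata, the
full event table, arbitrary `extensions` blocks that round-trip verbatim),
an 8-byte little-endian length prefix, then the signal as little-endian
float32, channel-major. Any JSON tool can read the header without touching
the signal; a truncated signal block or a future schema version is an
explicit error. Time is stored in samples internally and exposed in
milliseconds at interfaces; sample indices are 0-based; units are fixed to
microvolts.

Design choices that were genuinely open:

- **Symbol layout.** The canonical row-major grid
  `ABCDEF/GHIJKL/MNOPQR/STUVWX/YZ1234/56789_` satisfies the layout
  constraints conventional for the paradigm (`P` at row 3/column 4, the
  vowels I, O, U in column 3, digits in rows 5–6); the 36th cell is the
  filler `_` (26 letters + 9 digits leave one cell).
- **LS codes** are rows 1–6 then columns 7–12; documented in the header
  schema rather than assumed.
- **Character grouping** comes from explicit markers/event indices, never
  from timing heuristics; an iteration is 12 consecutive flashes of one
  group in which each code appears once.
- **Char markers** span the stimulation sequence only (first flash onset to
  last flash onset + ISI), not inter-character pauses.

## Dialect importers

`import_segmented_dialect` rebuilds a continuous recording from
epoch-segmented data. With onsets present, epochs are written back at their
positions; overlapping samples must agree within 1e-5 µV (float32 storage
noise), otherwise the segmentation is declared irrecoverable. Samples no
epoch covers become NaN, a sentinel declared in the header. Without onsets
the original flash order cannot be recovered: trials are laid out
back-to-back and the report carries `SEQUENCE_LOST`. `flag_normalization`
declares trial-by-trial amplitude normalization when the per-trial standard
deviation or peak-to-peak range is constant across trials to a relative
1e-6 — a single global scale factor does not trigger it.

## ERP export

Epochs are cut per flash over a window relative to stimulus onset (default
0–800 ms, a span wide enough to contain both components at every
conventional ISI), with `floor(len_ms · fs / 1000)` samples; flashes whose
window leaves the recording are dropped and counted. No baseline correction
and no filtering are applied: the exporter's contract is to hand the
consumer unprocessed amplitudes and let preprocessing be their choice.
Features are concatenated sensor-major in the requested sensor order, so
exporting `[a, b]` equals column-concatenating the exports of `[a]` and
`[b]`. Decimation either block-averages runs of k samples (trailing partial
run averaged as-is) or keeps every k-th sample; sample times follow the
same rule so latency-based consumers stay consistent.

`single` mode emits one row per flash; `averaged` mode emits 12 rows per
character (the per-code mean over that character's iterations) and sets the
iteration vector to 0, a convention of this package. Text outputs print
floats at 6 significant digits — compact, and lossless enough that parsing
a written table reproduces the matrix within that precision while the
Y/I/C/msg vectors round-trip exactly. The ARFF schema always declares both
class labels so it is stable when one class is absent. For free-spelling
sessions without an intended text the `msg` entry is the inferred symbol
when the labeled events determine one, else `?`.

`predict_characters` is a deliberately simple demonstration decoder, not a
classifier: each stimulus code is scored by the mean amplitude at a
discriminant sensor/window (default Cz, 250–600 ms — inside the P300's
mass), the best row and best column win, ties break to the lower code.
Adding a constant to all signals shifts all scores equally and leaves the
argmax unchanged.

## Statistics

- **Grand averages** are plain pointwise class means with trial counts.
- **Pointwise test**: Welch (unequal-variance) two-sample t-test per
  (channel, sample); the family for the Bonferroni correction is the full
  channels × samples set of the tested window, the conservative reading.
  The mask is true where `p · m < α` (default α = 10⁻⁴). Degenerate points
  where both classes are constant are significant iff the constants differ.
- **Component latency** is the extremum (minimum for N200, maximum for
  P300) of the target-minus-standard difference wave at one sensor within a
  search window; defaults N200 150–300 ms at PO7, P300 250–550 ms at Cz,
  windows wide enough to cover the latency ranges reported across public
  speller datasets; earliest sample wins ties. The difference wave is used
  because the target/standard contrast is what defines both components in
  this paradigm.
- **Occurrence statistics** count selections per symbol and derive per-row
  and per-column selection shares (each sums to 1).

## Simulator

A session spells a text: per character, `iterations` independent uniform
permutations of the 12 codes, onsets spaced `isi_ms` apart with an
`inter_char_gap_ms` pause between characters, plus one epoch-length tail.
Target flashes add two Gaussian-windowed bumps
`A · exp(−(t − latency)² / (2σ²))` with σ = FWHM/2.355, scaled by a
per-sensor topography; standards add nothing; overlapping responses sum
linearly, so short-ISI interference between neighbouring evoked responses
emerges naturally. Noise is white Gaussian by default, optionally
first-order low-passed and rescaled, to mimic the 1/f-ish EEG spectrum.

Defaults are a classic copy-spelling configuration: 240 Hz sampling,
175 ms ISI, 15 iterations, 100 ms flashes, the 8-sensor montage
Fz/Cz/Pz/Oz/P3/P4/PO7/PO8; N200 at 200 ms, −5 µV, 80 ms FWHM, weighted
PO7 1.0 / PO8 0.8 / Oz 0.5 / others 0.1; P300 at 300 ms, +5 µV, 150 ms
FWHM, weighted Cz 1.0 / Pz 0.9 / others 0.2; 5 µV noise. The topography
weights are package conventions consistent with reading the N200 at PO7 and
the P300 at Cz; the flash duration is metadata only (the linear model does
not use it).

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: habituation and latency jitter across trials,
artifacts (blinks, EMG), spatially correlated noise, target-to-target
interval effects, and subject variability. It is a generator for exercising
the container, exporter and statistics under known ground truth, not a
physiological model.

`degrade` reproduces dataset pitfalls deterministically given a seed:
overlapping 1000 ms segmentation (with onsets), label-sorted segmentation
(onsets discarded, order shuffled within class), per-trial unit-variance
normalization, stripped sensor ordering, and dropped paradigm/encoder
metadata.

## Numerical and test-design choices

- Onset-to-sample conversion rounds to the nearest sample; epoch lengths
  floor. ISI inference takes the mode of millisecond-rounded onset
  differences, drops differences beyond 3× that mode (inter-character
  pauses), and re-takes the mode; ties go to the smaller value.
- Latency-recovery experiments run at the 800 ms ISI setting so consecutive
  evoked responses do not overlap: at short ISI the realized interference
  from neighbouring target responses displaces the measured peak even at
  negligible noise, so the injected latency is no longer the identifiable
  extremum. "High SNR" means 0.05 µV noise (grand-average residual
  ≈ 0.008 µV over 90 target trials), "medium" 0.3 µV; these were set by a
  power analysis of argmax jitter on the flat top of a Gaussian bump, where
  a 150 ms-wide component changes by only ~0.04 µV one sample (4.2 ms at
  240 Hz) from its peak.
- The null calibration of the masked t-test uses 200 independent families
  of 8 channels × 205 samples with 200/1000 trials per class; at α = 10⁻⁴
  the expected number of families with any rejection is ~0.02, so observing
  none is the calibrated outcome.
- Test problem sizes (3–4 character sessions, 5–15 iterations, 100-seed
  recovery loops, a 72-character long-ISI session for the
  law-of-large-numbers check) were chosen so each statistical property has
  a comfortable analytic margin at the stated thresholds while the full
  suite stays desk-scale.

## Known limitations

- The container reads only its own format plus the documented degraded
  dialects; native formats of the original public datasets (BCI2000, HDF,
  MATLAB, pickle) are out of scope.
- Only the 6×6 matrix paradigm is modelled; other matrix sizes and
  non-matrix P300 paradigms are not.
- `predict_characters` is a demonstration decoder; no trained classifiers
  are included.
- Published per-dataset component latencies and occurrence histograms
  require the real recordings and are not reproduced here; the statistics
  module is validated on simulated ground truth instead.
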
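# Methods

This note documents the models behind `hyentag`, the parameters that matter,
and the choices made where the design was genuinely open. Everything stated
here is computed by the package itself (tests or `scripts/acceptance.py`);
nothing is quoted from external data.

## Barcode design

Barcode domains `Si` are 20-nt sequences over {A, C, T}; omitting G removes
all C:G base pairs and hence most secondary structure by construction. The
per-sequence filters are:

- C fraction within [0.30, 0.70] (the "GC content" of a three-letter
  alphabet reduces to C alone), keeping melting temperatures similar;
- homopolymer runs ≤ 4 for A and T and ≤ 3 for C (synthesis-error control);
- longest intramolecular stem < 5 bp with loop ≥ 3 nt. The stem filter is a
  self-contained longest-complementary-substring search rather than a
  thermodynamic structure predictor; `DesignParams.structure_hook` accepts
  an external predictor when one is available. With no G in the alphabet,
  only A:T stems can occur, so this proxy is conservative and cheap.

Pairwise orthogonality uses two screens against every accepted library
member, in both sense and reverse-complement orientation: longest shared
substring ≤ 10 nt, and Smith–Waterman local alignment score ≤ 12 with
match +1 / mismatch −1 / gap −2 (an in-package replacement for a BLAST
screen; the scoring is declared so results are reproducible without an
external database). Inside the greedy accept loop the substring threshold is
tested with an 11-mer index, which is exactly equivalent to thresholding the
longest common substring; the exact dynamic program remains available for
audits and is what `BarcodeLibrary.validate()` re-runs.

Acceptance is greedy in candidate-generation order from a single seeded
generator, so identical parameters give byte-identical libraries. From the
default 10,000 random candidates the pipeline yields well over a hundred
orthogonal survivors — comfortably more than the 25 needed for one ticket.
The exact survivor count depends on the structure-filter proxy and alignment
cutoff, so no specific count is asserted, only the capacity margin.

Shared domains default to a 6-nt toehold `T`, a 15-nt stabilizer `U` (long
enough to hold bit-0 duplexes at room temperature, see Thermodynamics), and
a 15-nt fluorophore arm `X` (four-letter alphabet allowed — it never
contacts tag strands), all sampled by the same seeded generator under the
same run-length discipline. `F` marks the dye position and carries no
nucleotides. The anchor's 30-nt poly-T nitrocellulose-binding tail sits at
the 3' end by default and is configurable.

## Error correction

A [24, 12] binary linear code correcting 3 errors needs d_min ≥ 7; the
extended binary Golay code (d_min = 8) is the canonical minimal-redundancy
choice and is what `default_code()` builds, as `G = [I | B]` with `B` the
bordered circulant over the quadratic non-residues mod 11.
`default_code()` re-derives d_min by exhaustively enumerating all 4,095
nonzero codeword weights instead of trusting the constant, and raises if the
construction is broken. Decoding scans all 2^12 datawords for the smallest
Hamming distance; ties are reported (`ambiguous=True`) and broken toward the
lowest dataword index so decoding is deterministic and unreliability is
surfaced rather than hidden. `guaranteed` is set only when the distance is
within ⌊(d_min−1)/2⌋ = 3 and unique. Rate-1 identity codes (used for raw
25-bit ticket patterns) bypass the search: every vector is a codeword.

Bit order: dataword bit 1 is leftmost; codeword bit *i* maps to ticket spot
*i* in row-major order from the top left. A 24-bit code leaves the 25th spot
unmapped; it behaves as a bright control.

## Tag model, kinetics and noise

A tag assembles one strand species per codeword bit at 4 µM each in 60 µL,
with 0 bits pre-annealed to the universal blocker at 1.15× excess. The tag
state is the per-bit *blocked fraction* f — {0, 1} when intact, fractional
after attack — plus a conserved total blocker amount.

Displacement follows pseudo-first-order kinetics: a matching spot's decay
approaches `saturation_decay` as `(1−f)·(1 − exp(−k·(1−f)·C·t))`, rate
proportional to the free-strand concentration. The rate constant is
calibrated so the half-life at 4 µM is 2 minutes (saturating by ~10 min);
the default readout incubation is 20 minutes. Orthogonal strands are inert.
Partial blocking scales the extent linearly — each unblocked strand reacts
independently.

Observed per-spot decays add noise matched to the calibration
distributions: decay ~ TruncNormal(0.7·e, σ(e)) on [0, 1] with
σ(e) = 0.10 + 0.05·e, where e is the ideal extent. At e = 0 this is exactly
the half-normal bit-0 model (σ₀ = 0.10); at e = 1 the truncated-Gaussian
bit-1 model (mean 0.7, σ₁ = 0.15). These defaults are package fixtures
chosen to give a realistic ~2% bit-1 misread rate at the 0.38 threshold;
they are not fitted to any external dataset. The `dried_without_trehalose`
preset raises σ₀ to 0.35, which pushes expected raw errors per 24-bit
ticket above the 3-bit radius — the qualitative failure mode of drying
without a stabilizer.

**Thermal/amplification attack.** Melting dissociates all blockers; on
re-annealing they bind the identical T*·U* sites uniformly, so every bit
ends at f = min(1, 1.15·n₀/n). For a typical half-zeros codeword,
f = 0.575 at every bit — bit identity is erased and the readout collapses
toward a near-uniform pattern. An optional multinomial mode adds
partitioning noise at a stated molecule count. Blocker and strand totals
are conserved exactly. Note that a near-uniform post-attack readout can sit
*close to a codeword* (the all-zeros and all-ones vectors are Golay
codewords), so nearest-neighbour decoding may still report a "guaranteed"
decode — to the wrong ID. The security claim verified by the tests is
therefore that no attacked tag decodes *correctly*, and that the raw
distance to the original codeword always exceeds the correction radius.

**Sequencing view.** Sequencing returns the set of distinct strands: all tag
strands plus the blocker iff any bit is 0. The set is constant across all
codewords with at least one zero, which the tests check exhaustively on
small libraries; decoy strands (`<T* U* N20>`, 4^20 possible) enlarge the
set without touching the readout.

## Imaging

Synthetic tickets are 8-bit grayscale: wax lanes at 10, well floors at 20,
spots as disks (radius 10 px, pitch 44 px) at their mean intensity, plus
additive Gaussian pixel noise (default σ = 2). The post image dims each spot
by its decay fraction of the bright−background range (bright = 230), so the
relative-decay pipeline output equals the planted decay up to quantization.

The pipeline detects blobs (Laplacian of Gaussian) on the **pre** image,
where every spot is bright, assigns them to the nearest nominal grid
position, and falls back to the median-offset-shifted grid for any position
without a blob — fully reacted spots are dark and need this fallback. Mean
intensities are taken over fixed-radius disks at the fitted centers in both
images. Decay is normalized per spot by default —
(pre − post)/(pre − background), background estimated as the median of
inter-spot annuli, clipped to [0, 1] — because it matches the decay's
natural [0, 1] scale and is robust to illumination differences between
tickets; min–max normalization across the ticket is provided for
comparison. Binarization is strictly-greater-than the threshold (a value of
exactly 0.38 reads 0 — arbitrary but fixed). Pre/post registration is by
the fitted grid; synthetic pairs are generated pre-aligned, and affine
registration of real photographs is out of scope.

## Calibration

Bit-1 decays are fitted by maximum likelihood as a Gaussian truncated to
[0, 1] (quasi-Newton on the exact truncated log-likelihood in (µ, log σ),
tolerance 1e-10; the fitted parent µ may exceed 1 when truncation is
active). Bit-0 decays are fitted by mirroring the sample about zero and
fitting a zero-mean Gaussian, whose MLE is the closed form
σ² = mean(x²) — identical to the direct half-normal MLE. The optimal
threshold minimizes `prior1·P(bit1 ≤ t) + (1−prior1)·P(bit0 > t)` by
bounded 1-D search (equal priors by default); an empirical mode minimizes
the raw misclassification count on labelled samples and returns the widest
minimizing gap's midpoint. The shipped pipeline default of 0.38 is a fixed
constant of the system; the calibration machinery exists to re-derive a
threshold for other conditions, not to reproduce that number from synthetic
defaults (under the package's own noise defaults the Bayes cut lands near
0.3).

## Thermodynamics and leakage

Duplex stability uses published unified nearest-neighbour ΔH/ΔS tables
(as shipped with Biopython; default `DNA_NN3`), initiation and terminal-AT
terms, and the 0.368·(N−1)·ln[Na⁺] entropy salt correction (default 50 mM
monovalent). Tm uses the CT/4 convention for non-self-complementary
duplexes at equal strand concentrations, and the two-state bound fraction
solves the mass-action quadratic — crossing exactly 0.5 at Tm, which the
tests assert, alongside agreement with Biopython's `Tm_NN` as an
independent oracle. Everything is two-state; no secondary-structure
coupling.

Bit-exchange leakage integrates the mass-action network of blocker
dissociation (k_off = k_on/K(T), K from ΔG of the blocked U+T region) and
re-association (k_on = 10⁶ /M/s, a textbook hybridization rate) with
LSODA at rtol 1e-10 over a 10-year default horizon. The equilibrium of
this network is the uniform blocker distribution — the same endpoint the
thermal attack reaches instantly; stability over storage is the statement
that the kinetics toward it are negligible at room temperature. With the
default 15-nt stabilizer the 10-year drift in blocked fraction is a few
percent, far from moving any bit's decay across the 0.38 threshold (the
tests verify this through the kinetics model). The 1.15× annealing excess
is *excluded* from the solution-phase simulation by default: free excess
blocker would otherwise partially block bit-1 strands at equilibrium, a
second-order effect outside the intact-tag model; it can be included via
`LeakageParams.include_free_excess`. Strand chemical degradation is not
modelled.

## Costs

Cost per write-and-read is linear: fixed ticket costs (nitrocellulose
$0.25, buffer/ink $0.0015) plus per-bit oligo costs (taggant $0.10 / 240
pmol, reporter $0.0009 / 0.5 pmol): $0.3524 at 1 bit, $2.774 at 25 bits.
A commonly quoted "$2.77 per 24-bit tag" is the 25-bit figure rounded; the
linear model gives $2.6731 at exactly 24 bits.

## Problem sizes and determinism

All simulations are sized for interactive use: libraries build from 10,000
candidates in ~15 s (and stop early at 25 members in well under a second);
Golay enumeration and decoding touch 4,096 codewords; tickets are 228×228
px; acceptance runs use 5 tags per condition and complete in seconds. Every
stochastic path takes a seed, spawns sub-seeds explicitly, and is
byte-reproducible; the end-to-end report embeds the config hash and all
derived seeds.

## What the synthetic data does not show

The synthetic generator emulates spot geometry, decay statistics and pixel
noise, not real photographs: no perspective or illumination gradients, no
wax-well irregularity, no camera color processing, no spot bleed or
pipetting variation, and its decay-noise parameters are package defaults
rather than fitted values. Passing tests therefore demonstrate the
correctness and internal consistency of the algorithms (code distance,
pipeline round trips, attack separation, conservation laws), not field
accuracy on real tickets, which depends on wet-lab calibration of the noise
and threshold.
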
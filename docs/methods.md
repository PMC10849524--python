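# Methods

## Mass model

All masses derive from one embedded element table
(`src/histoquant/data/masses.json`). Monoisotopic masses use the standard
nuclide values to six decimals; the isotope-averaged scale uses the IUPAC
*conventional* (abridged) atomic weights (C 12.011, H 1.008, N 14.007,
O 15.999, S 32.06). The conventional weights were chosen over
isotope-abundance-weighted means because intact-protein deconvolution
software reports averaged masses referenced to standard atomic weights;
with this table the tri-acetylated H4 identification lands at −1.1 ppm
against its observed +15 charge precursor, comfortably inside the 10 ppm
criterion. Residue and PTM masses are elemental compositions summed over
this table, so me2 and me3 are exact integer multiples of me1 on both
scales and acetyl is C₂H₂O (42.0106 Da monoisotopic).

Intact (precursor) arithmetic defaults to the average scale; fragment
arithmetic is always monoisotopic. Proton adducts only, at 1.007276 Da;
electron mass is carried in the table but not applied (its effect is
≈0.05 ppm at these masses, far below the matching tolerances).

ETD fragments are c (quasi-molecular, +NH₂ on the amide nitrogen) and
z-dot radical species: with prefix/suffix the bare residue sums,
c_i = prefix_i + NH₃ and z•_j = suffix_j + H₂O − NH₃ + H. The constants
live in one function and are pinned by two independent checks: the
complementarity invariant c_i + z_{L−i} = const over random proteoforms,
and the precursor ppm criterion. An implementation switching to z+1
conventions must re-verify both.

The two shipped backbones are mature murine H4 (102 aa, initiator Met
removed, fixed N-terminal acetylation) and the H3.2 GluC tail (residues
1–50, ending at the first Glu). The fixed N-terminal acetyl is part of
the backbone mass and is excluded from every "acetylated" bulk count.

## Proteoform spaces and isobaric grouping

Search spaces are shipped as editable YAML. Enumeration order is canonical
(site number, then state rank un < ac < me1 < me2 < me3), so outputs are
diff-stable. Isobaric classes use single-linkage grouping of sorted intact
masses at the 3.4 Da MS1 window: a class breaks only where consecutive
masses gap by more than the window. This avoids bin-edge splits of
near-identical compositions — three methyls and one acetyl differ by only
0.0364 Da — at the cost of classes whose total width could, in principle,
exceed the window (for these schemas the widest class spans 0.044 Da).
The window is interpreted as a *full* isolation width: MS1 peaks match a
class within ±1.7 Da of its representative (mean member) mass. Whether the
original acquisition treated it as full or half width is not documented;
full width mirrors instrument isolation semantics and is stated here so
users of real data can halve it if needed.

## MS1 assignment and MS2 apportionment

MS1 peaks must carry a charge annotation; charge inference is deliberately
not implemented. Intensity is peak height, and heights for one class are
summed across charge states and scans — whether the original workflow
summed or picked a single charge state is unknown; summation is this
package's contract. Ties between equidistant classes break to the lower
mass, deterministically.

Each MS2 spectrum is matched against the members of its precursor's
isobaric class at 10 ppm. Observed fragment masses are first merged within
tolerance by intensity-weighted mean (ties toward lower mass). The
incidence matrix entry A[r, j] is the *number* of candidate j's c/z
fragments within tolerance of observed mass r. A count — not a 0/1 flag —
is the correct linear-mixing design: when two fragments of one candidate
coincide within the merge radius, the merged peak carries that candidate's
fraction twice, and a binary matrix would bias the solve. Apportionment is
non-negative least squares on A x = b with candidates that have identical
columns (no discriminating fragments) collapsed before the solve and their
pooled fraction split uniformly afterwards, with an ambiguity flag. NNLS on
a linear mixture of co-isolated species is a replacement contract for the
unpublished quantitation internals of the original analysis suite;
parameter recovery on synthetic data is its only validity claim, and the
test suite holds it to ≤1e-6 recovery on noise-free full ladders and
≤0.02 mean absolute fraction error at 10% multiplicative noise.

Site localization marks a site unambiguous when the matched fragments
exclude every other candidate differing at that site (some matched
fragment is explained by the candidate but not the rival); an empty
matched set leaves every site ambiguous.

Fragment intensities are used raw — no per-ion response calibration — a
known limitation shared with most intact-protein quantitation.

## Abundance tables and aggregation

Per technical replicate, proteoform abundance = class precursor intensity
× within-class fraction, rescaled to sum to 100 per family; technical
replicates are averaged after normalization (and the averaged table
re-closed to 100). `{}`-queries sum matching proteoforms; `<>`-queries
pick exactly one. Bulk percent-methylated counts any K-site methylation in
the family's schema — the alternative (restricting H3.2 to K4/K9/K27) is
not documented anywhere authoritative, so the inclusive definition is
used. Acetyls/methyls per molecule are abundance-weighted mark counts with
me1/me2/me3 = 1/2/3.

Fold changes are ratios of group means (not means of ratios), matching the
published arithmetic (36/39.4 = 0.91). Significance in volcano-style
reports requires both p < 0.05 and fold ≥ 1.5 (or ≤ 1/1.5); the pp change
is reported alongside but never gated. Zero-variance equal groups return
p = 1 (t = 0); groups with n < 2 return descriptives only.

BH and the two-stage (BKY) step-up are implemented directly (a few lines
each) and cross-checked against statsmodels in the tests, keeping the
dual-route verification. Two-stage q-values use the convention in which a
discovery is exactly q ≤ α (BH-adjusted p × (1+α) × m̂₀/m).

## Footprint enrichment

Consensome percentiles use max-rank tie handling (100·rank/n, ties share
the best percentile of their run) and HCT membership is percentile
strictly above 95 — with 100 distinctly scored genes that is exactly the
top 5, and a fully tied list places every gene in the HCT. Enrichment is
the hypergeometric upper tail P(X ≥ k) with universe N = union of all
scored genes (configurable), gene symbols case-folded, odds ratios
Haldane–Anscombe corrected so log-OR plots stay finite. The
thermoregulatory-node test takes the top ⌈fraction·len(ranking)⌉ nodes
against a configured universe (default 691 nodes, 15 thermo nodes); the
composition of that universe and the exact "top ranked" cutoff are not
printed anywhere, so both are inputs here.

## Methylation–expression integration

Boundary conventions mirror the printed inequality forms: methylation
magnitude strictly > 5 pp, expression |log₂FC| ≥ 0.263 (= |log₂ 1.2| at
3 dp). A coverage ≥ 10 filter applies when a coverage column exists. The
join is inner on gene, duplicate gene rows are rejected, and classes are
hypo-up (Δmeth < 0, fold > 1), hyper-down (Δmeth > 0, fold < 1), else
concordant. The same filters apply to promoter and intragenic records.

## Synthetic data: what it emulates and what it does not

The generators mirror the emulated study design — 2 tissues × 3 housing
conditions × 4 animals × 2 technical replicates — with a sparse Dirichlet
mixture (default 20 active proteoforms, concentration 1) as the tissue
profile and concentrated Dirichlet draws (κ = 2000) for animal scatter.
Intensity noise is lognormal, CV-parameterized (default 10%), the simplest
defensible multiplicative MS error model; fragment-ladder coverage is a
per-member Bernoulli mask (default 0.8). Charge envelopes are discretized
Gaussians per family (H3.2 tail z 8–10 centered at 9; H4 z 9–16 centered
at 12.5) chosen so peaks land inside the configured scan ranges (585–640
m/z for H3, 700–1400 for H4). No isotope fine structure, chromatographic
elution, co-isolated contaminants, detector saturation, or ETD
hydrogen-transfer satellites are simulated — matching the average-mass
matching convention and the raw-intensity limitation above. Passing tests
therefore demonstrate correctness of the arithmetic and the mixture model,
not robustness to every artifact of real spectra.

All generators are bit-reproducible from (seed, config) via seeded
`numpy` Generators with per-purpose seed streams. Test and acceptance
problem sizes (e.g. 100 apportionment trials, 2000 Welch null
simulations, 50-node consensome simulations, single-tissue pipeline runs)
were chosen as the package's default desk-scale workloads; the whole
suite runs in a few seconds on one CPU.

## Known limitations

- Quantitation assumes equal fragment ion response within and across
  candidates; real ETD intensities are sequence-dependent.
- MS1 charge states must be annotated; no deconvolution is provided.
- mzML reading is a compact built-in parser covering centroided spectra
  with 32/64-bit float arrays (plain or zlib); vendor formats and
  profile-mode data are out of scope.
- The H3 family is modeled as H3.2 only; H3.1/H3.3 sequence variants and
  PTMs outside the configured schemas are out of scope.
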
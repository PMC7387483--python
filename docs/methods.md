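# Methods

## Model

`lcampscreen` treats LCAMP discovery as a physicochemical classification
problem on precursor proteins. The underlying biological model: an LCAMP
gene encodes a precursor of roughly 50–100 residues, organised as

```
signal peptide (≈21–23 aa) → cationic amphipathic α-helix → anionic helical proregion
```

The mature antimicrobial peptide is the cationic amphipathic helix,
released by secretion (signal cleavage) and proteolytic removal of the
acidic proregion. Each architectural feature becomes a computable gate, and
the gates are applied as a fixed-order funnel so that rejection reasons are
interpretable and survivor counts are monotone.

## Quantities

**Mean hydrophobicity `H`** — arithmetic mean of Fauchère–Pliska (1983)
octanol/water side-chain values. Unitless, scale-dependent; the shipped
scale is the one used by the HeliQuest wheel calculator, and whole-sequence
means recomputed with it reproduce published HeliQuest hydrophobicities of
seven characterised Ciona peptides to the printed 3 decimals (the test
suite asserts this at ±5·10⁻⁴).

**Hydrophobic moment `μH`** — Eisenberg per-residue moment,
`μH = (1/N)·√[(Σ Hⱼ sin jδ)² + (Σ Hⱼ cos jδ)²]`, residue j at angle `j·δ`
with `j = 0` for the first residue. `μH` is invariant to a global phase, so
the starting-angle convention is arbitrary but fixed for reproducibility.
Default `δ = 100°` (ideal α-helix, 3.6 residues/turn); configurable for
3₁₀/π exploration. Closed-form checks used as tests: `μH(poly-G) = 0`, and
at `δ = 0`, `μH = |Σ Hⱼ|/N`.

**Net charge `z`** — `#(K,R) − #(D,E)` at neutral pH; histidine counts 0.
This integer convention matches the published wheel values (all seven
recomputed charges agree exactly).

**Composition statistics** — per-window counts: polar residues, uncharged
S/T/N/Q/H, glycines, charged D/E/K/R, cysteines. The published screen
states thresholds (≥6 polar, ≥1 uncharged, ≥0 glycine, ≤12 charged,
cysteine excluded) but never defines the polar class; the default set here
is {D,E,K,R,H,N,Q,S,T,Y} and it is a configuration knob. The ≥0 glycine
rule is vacuous but kept for configuration symmetry. Composition rules
apply only to the cationic box; the anionic search uses only the H/μH/z
limits plus cysteine exclusion.

**Aggregation propensity `Na⁴vSS`** — per-residue a3v values (transcribed
from the AGGRESCAN publication; the screen's source does not restate them)
are window-averaged into a4v and summed; `Na⁴vSS = 100·a4vSS/N`. Window
length follows the AGGRESCAN length bands (5 below 75 residues, 7 to 175,
9 to 300, 11 above). Ends are handled by truncated asymmetric windows so
`len(a4v) = N` and the normalisation is well defined for short peptides;
`end_mode: full_windows_only` restricts a4v to complete windows instead
(Na⁴vSS stays normalised by N in both modes). Window 1 degenerates to
`a4v = a3v`, used as an algebraic check.

**Match-style PWM scores** — per-position information
`I(i) = Σ_b f(i,b)·ln(4 f(i,b))` (natural log, `0·ln 0 = 0`);
`matrix similarity = (Current − Min)/(Max − Min)` with
`Current = Σ I(i)·f(i, bᵢ)` and Min/Max the same sums over per-position
extremes; core similarity is the identical score over the 5 consecutive
positions of maximal summed information (ties resolved leftmost). Both
strands are scanned by default; windows containing N are skipped; a matrix
with no informative position (Max = Min) is rejected as degenerate. Count
matrices are normalised with a pseudocount of 1% of the position total.
Hit positions are negative offsets from the initiator ATG (last upstream
base = −1), always on the input strand's coordinates.

## Funnel semantics

Stage order is fixed: length → secretory → tm → cys → amphipathic →
helical → aggregation → localization. Configuration can disable stages but
not reorder them — reordering would silently change what the per-stage
counts mean. A record's `stage_reached` is its first failing stage;
"candidate" means all stages passed. Cysteine exclusion applies to the
entire mature subsequence, not only to scanned windows. A sequence passes
the amphipathic stage when ≥1 merged cationic segment survives; all
surviving segments are reported and duplicates across genes are preserved.
Sequences shorter than the 18-residue window are evaluated as a single
whole-sequence window — published physicochemistry of 14–29-mer synthetic
peptides is whole-sequence, so the engine must handle sub-window lengths.
All threshold-box bounds are inclusive on both ends ("between X and Y" read
conservatively) and are regression-locked by tests. The aggregation gate is
computed on the merged segment by default (`aggregation.target: window`
switches to the best 18-mer); which subsequence the original screen scored
is not stated, so this is a documented choice.

Windows containing `X` fail all physicochemical gates — no scale value
exists, and screening fails closed rather than inventing one.

## Predictor stages

SignalP/TMHMM/DeepLoc are trained models and are not re-implemented. Each
stage takes exported results through a tabular adapter, or falls back to an
honest stand-in:

* **signal** — classical n/h/c-region rules: n-region (first 5 residues)
  net charge ≥ 0; an h-region of ≥7 consecutive residues within positions
  3–25 with mean Fauchère–Pliska hydrophobicity ≥ 1.0; a cleavage candidate
  at positions 15–35 with small residues (A/G/S/C/T) at −3/−1, chosen to
  maximise the hydrophobicity drop across the site. Sequences under 20
  residues are never secretory. Both conserved LCAMP-family consensus
  signal peptides are accepted under every X→{A,V,L,S} instantiation
  (tested).
* **tm** — any 19-residue window with mean Kyte–Doolittle hydropathy ≥ 1.6
  (inclusive) marks a transmembrane protein.
* **localization** — no defensible sequence-only stand-in exists for a
  trained localization model, so without external predictions the stage is
  an explicit pass-through with a once-per-run warning. The set of classes
  counted as "secreted" is configurable (default: extracellular, secreted).

All heuristic thresholds are configuration keys with these defaults.

## Synthetic data

The fixture generator emulates the architecture the funnel detects: a
consensus-derived signal peptide (X positions filled from {A,V,L,S}), an
18-mer cationic helix built by placing K/R on the wheel face within ±90° of
a fixed azimuth at δ=100° and L/A/F on the opposite face, a ~15-residue
neutral polar linker, and an 18-mer anionic tail with 5–6 acidic residues
spread evenly (spreading keeps μH ≤ 0.5, inside the anionic box). The
linker exists because adjacent cationic and anionic helices would otherwise
produce overlapping merged segments — an 18-residue window spanning the
junction can satisfy either box — defeating the in-order architecture flag.
Decoys are single-violation edits: over-length padding, signal removal, a
19-leucine TM insert, one cysteine in the tail, a charge-free segment, a
G/P/V-rich helix-breaking face, or an I/F-rich aggregation-prone face.

Generated records are *verified against the real pipeline* and regenerated
with a fresh sub-seed until the planted record reaches "candidate" (with
the architecture flag) and each decoy fails exactly at its label. This is
deliberately a closed loop: it proves the funnel's stage logic is coherent
and that each gate is independently reachable, not that the generator
resembles real proteomes. Real screening performance (false-positive rates
on genuine secretomes, behaviour on ambiguous signal peptides, compositional
biases of real genomes) is outside what these fixtures can show. Background
filler residues are drawn uniformly from neutral polar sets; no attempt is
made to model genome-scale composition or evolutionary structure.

Everything is a pure function of the seed (numpy `default_rng`; sub-seeds
below 2³¹).

## Numerical choices

* Comparisons against published wheel values use ±5·10⁻⁴ (they are printed
  to 3 decimals); reports round H/μH to 3 decimals and Na⁴vSS to 1.
* Segment `best_window` ties (equal μH) resolve to the smaller start; PWM
  core ties to the leftmost run; both fixed for determinism.
* Degenerate inputs: empty sequences, all-zero PWM rows, matrices shorter
  than the 5-position core, `A_PC = A_NC` in the relative-activity formula,
  and sequences shorter than 3 residues for aggregation all raise errors
  rather than returning sentinels.
* Internal coordinates are 0-based half-open everywhere; report output is
  1-based inclusive; upstream motif positions are negative offsets from
  ATG.

## Problem sizes

The shipped validation experiments are deliberately compact: a 12-record
synthetic proteome (5 planted + 7 decoys), 200-instance randomized oracle
comparisons for the window scanner and the PWM scanner, and 400-bp
upstream fixtures. These sizes fully exercise every code path; screening a
real proteome is the same code over more records (the funnel is linear in
total sequence length).

## Known limitations

* The heuristic predictor stand-ins are honest but crude; on real proteomes
  they will both miss true signal peptides and pass false ones. For real
  screens, export results from the actual predictors and use the adapters.
* Published Na⁴vSS values for the four excluded Ciona segments were
  computed by the AGGRESCAN server on the original precursor inputs, which
  are not part of this package's inputs; recomputing on the related
  synthesised peptide sequences gives systematically different values
  (e.g. −82.5 vs −65.6 for KH.L63.9 under the default end mode). The
  engine's arithmetic is instead validated against brute-force oracles and
  hand-computed profiles.
* The shipped κB matrix is synthetic (consensus-derived); motif hits with
  it demonstrate the scanner, not real NF-κB biology.
* No pKa model: net charge is the integer K/R–D/E convention; histidine is
  neutral regardless of pH.
* The funnel count structure (monotone survivors per stage) reproduces the
  published screen's semantics, not its genome-specific numbers, which
  depend on external databases and predictor versions.
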
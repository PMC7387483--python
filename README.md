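# lcampscreen

In silico screening for **linear cationic α-helical antimicrobial peptides
(LCAMPs)** in protein databases.

LCAMPs — short, cysteine-free, amphipathic, membrane-active host-defense
peptides — evolve too fast for homology search: orthologues share almost no
sequence identity, so BLAST-style mining misses them. What they do share is
*physics*: a precursor of ~50–100 residues carrying a secretion signal, a
cationic amphipathic α-helix (the active peptide) and usually an acidic
helical proregion. `lcampscreen` implements that physics as an eight-stage
screening funnel over a proteome FASTA, plus the surrounding sequence
analysis: anionic-proregion detection, majority-rule signal-peptide
consensi, and NF-κB-like motif scanning of upstream DNA. It is aimed at
peptide/innate-immunity researchers mining genomes (marine invertebrates,
amphibians, …) for candidate antimicrobials worth synthesising.

## The screen

Each stage is inclusive-bounded and configurable; defaults are the
published calibration on known LCAMPs (cecropin-A, moricin, dermaseptin SI,
PGLa, Ci-PAP-A, Ci-MAM-A):

1. **length** — keep 50–100-residue proteins;
2. **secretory** — signal peptide present (external SignalP-style results
   via an adapter, or a built-in n/h/c-region heuristic); later stages see
   the mature (signal-less) sequence;
3. **tm** — drop transmembrane proteins (external results or a 19-residue
   Kyte–Doolittle window, mean ≥ 1.6);
4. **cys** — drop mature sequences containing cysteine;
5. **amphipathic** — an 18-residue window slides along the mature sequence;
   windows pass when mean Fauchère–Pliska hydrophobicity `H ∈ [0, 0.6]`,
   Eisenberg hydrophobic moment `μH ∈ [0.1, 1.0]`, net charge
   `z ∈ [+3, +10]`, ≥ 6 polar residues, ≥ 1 of S/T/N/Q/H, ≤ 12 charged;
   overlapping passes merge into segments;
6. **helical** — Chou–Fasman helix-propensity stand-in (or an external
   per-residue secondary-structure string);
7. **aggregation** — AGGRESCAN-style `Na⁴vSS ∈ [−30, 30]`;
8. **localization** — external DeepLoc-style predictions (pass-through with
   a warning when absent).

The two key statistics, in the field's notation:

```
μH = (1/N) · | Σⱼ Hⱼ·exp(i·j·δ) |        δ = 100°/residue (ideal α-helix)
Na⁴vSS = 100 · Σᵢ a4vᵢ / N               a4vᵢ = window mean of a3v at i
```

Anionic proregions are found with a second threshold box
(`H ∈ [−0.7, 0.4]`, `μH ∈ [0, 0.5]`, `z ∈ [−10, −3]`), and candidates are
flagged when the canonical architecture signal → cationic helix → anionic
helix holds in order. Upstream DNA is scanned for NF-κB-like sites with
Match-style information-weighted PWM scores (core ≥ 0.75, matrix ≥ 0.8).

## Worked example

```python
>>> from lcampscreen import profile
>>> p = profile("WWLSRRRSSLFYWR")          # Ciona peptide KH.C1.640
>>> round(p.H, 3), round(p.muH, 3), p.z
(0.624, 0.17, 4)
```

These are the published wheel-calculator values for this peptide: a mildly
hydrophobic (`H = 0.624`), amphipathic (`μH = 0.170`), +4-charged helix —
inside the cationic screening box. The suite checks all seven published
peptides; `python examples/01_wheel_physicochemistry.py` prints the full
table.

Running the funnel on a synthetic proteome
(`python examples/04_full_funnel.py`):

```
input: 12 records
  after length       11
  after secretory    10
  after tm            9
  after cys           8
  after amphipathic   7
  after helical       6
  after aggregation   5
  after localization  5
```

Five planted LCAMP-like precursors all reach `candidate` (with the
signal → cationic → anionic architecture flag set); each of the seven
decoys is rejected exactly at the stage it was constructed to violate.

The same funnel is available from the shell:

```
lcampscreen fixtures --seed 7 --fasta demo.fa --truth truth.tsv
lcampscreen screen demo.fa --report report.tsv --counts counts.json
lcampscreen physchem WWLSRRRSSLFYWR
lcampscreen aggrescan KGGKFLNFLKKAAKVGAKVGMAALG
lcampscreen pwm-scan upstream.fa --out hits.tsv
lcampscreen consensus aligned.fa
```

`examples/default_config.yaml` holds every threshold; pass a modified copy
with `--config` to re-screen under different boxes. Adapter formats for
external SignalP/TMHMM/DeepLoc-style result tables are documented in
`lcampscreen.predictors.load_external_predictions`.

## Scope notes

The trained predictors the original screen called (SignalP, TMHMM,
DeepLoc, PROTEUS, AmphipaSeek) are *not* re-implemented; each stage accepts
their exported results through an adapter, and honest rule-based stand-ins
keep the funnel runnable offline (outputs carry a `source` field). The
shipped κB matrix is synthetic (consensus-derived), for pipeline use —
substitute a real TRANSFAC/JASPAR matrix for regulatory analysis. See
`docs/methods.md` for the model details, parameter provenance and known
limitations.
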
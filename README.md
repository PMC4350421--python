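# sadhtools

Quantitative analyses around the SADH motif — the short, vertebrate-specific
spectrin-binding consensus found in the C-terminal region of the polarity
protein SCRIB, in dematin (DMTN) and in the ABLIM proteins — and the
cell-biological readouts used to study how it anchors SCRIB at the cell
cortex.  The package is for cell biologists who need reproducible,
scriptable versions of four measurements that are usually done ad hoc in
image-analysis software:

1. **Motif scanning and variant impact** (`sadhtools.motifs`).  The SADH
   consensus is an ordered list of residue classes — the full form
   `[+]-X-X-Y-[+]-X-ϕ-A-A-ϕ-P` and the simplified database-search core
   `Y-[KR]-X-[FL]-A-A-[ILV]-P`.  The scanner reports every window of a
   protein satisfying all position classes (1-based coordinates,
   overlapping hits included); missense variants are classified as
   `outside_motif`, `motif_retained` or `motif_lost` by re-scanning the
   mutated sequence.  Coverage of repeat windows and a one-sided exact
   binomial test for mutation enrichment (P(X ≥ k), X ~ Bin(n, coverage))
   round out the module.

2. **Cortical Localisation Index** (`sadhtools.cortical`).  For a cell
   mask per z-plane, the mask is split into a cortical band of thickness
   0.625 µm hugging the cell edge and the interior, and

       CLI = (i/(i+I)) / (a/(a+A))

   with `i`, `I` summed band/interior intensities and `a`, `A` their areas;
   CLI = 1 means no cortical enrichment.  The per-cell value is the mean
   over three z-planes.

3. **FRAP kinetics** (`sadhtools.frap`).  Recovery traces are normalized to
   a pre-bleach mean of 1 and fitted with
   `Y(t) = Y0 + (Ymax − Y0)(1 − e^(−kt))`, giving the half-time
   `t½ = ln 2 / k` and mobile fraction `Mf = (Ymax − Y0)/(1 − Y0)`.

4. **Centrosome-orientation scoring** (`sadhtools.polarity`).  A wound-edge
   cell is correctly oriented when its nucleus-to-centrosome direction lies
   strictly within 45° of the wound direction; under random positioning the
   expected score is 90°/360° = 25%.

`sadhtools.synth` generates inputs for all four stages with known ground
truth (planted motifs, analytic CLI, generating FRAP parameters, von Mises
orientation bias), and `sadhtools.fixtures` provides deterministic
synthetic stand-ins for the published SCRIB/peptide sequences with the
published residue numbering (R1322W, A1315T, P1332L).

## Worked example

Simulate a wild-type-like FRAP trace (t½ = 26 s, Mf = 0.60) and fit it:

```sh
$ sadhtools simulate frap --t-half 26 --mf 0.6 --noise-sd 0.0 --seed 1 --out trace.csv
trace -> trace.csv (bleach frame 5, t_half 26.0 s, Mf 0.6)
$ sadhtools frap-fit trace.csv --bleach-frame 5 --out fit.json
t_half = 26.00 s, Mf = 0.600, k = 0.0267/s
```

The fitted half-time and mobile fraction reproduce the generating values:
a protein with t½ = 26 s exchanges its mobile pool at the junction with
rate constant k = ln 2 / 26 ≈ 0.027 s⁻¹, and 60% of the bleached pool is
exchangeable.

Scan the packaged synthetic SCRIB fixture and score a simulated
unpolarized population:

```sh
$ sadhtools simulate proteome --fixture --out fixture.fasta
9 records -> fixture.fasta
$ sadhtools scan fixture.fasta --out matches.tsv
10 matches in 6/9 proteins
$ sadhtools simulate polarity --n 100000 --concentration 0 --seed 1 --out cells.tsv
100000 cells -> cells.tsv
$ sadhtools polarity-score cells.tsv --out score.json
24837/100000 oriented (24.8%)
```

The 10 matches are the three SCRIB repeats (found twice — once in the
full-length record, once in the C-terminal sub-record) plus the four
canonical DMTN/ABLIM panel peptides; the three non-canonical panel
peptides do not match.  The unpolarized population scores 24.8%, near the
random-positioning floor of the orientation assay.

Other subcommands: `variants`, `coverage`, `conservation`, `cli-index`,
`simulate cell` — see `sadhtools --help`.  Every command writes a
`<output>.run.json` record of its full parameterization.

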
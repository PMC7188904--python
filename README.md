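# lipidbench

Targeted lipidomics assay generation and validation, as a Python library and
CLI.

Targeted mass-spectrometry workflows (SRM/PRM) quantify a selected panel of
lipids by monitoring *transitions* — precursor m/z → product m/z pairs.
Designing such an assay means computing correct precursor and fragment
masses for every lipid of interest, picking collision energies that give
informative MS/MS spectra, and knowing how many fragments are needed before
an identification is unambiguous within the lipidome at hand.  `lipidbench`
implements that whole loop for assay developers:

* **Knowledge-base-driven m/z computation.**  Lipid classes are declared in
  plain CSV as a scaffold formula plus chain slots; fragments are signed
  linear expressions over building blocks (`PRECURSOR +1, H +1, FA1 -1` is
  "protonated precursor minus the free fatty acid").  Monoisotopic masses
  come from an IUPAC element table with heavy isotopes (¹³C, ²H, ¹⁵N) as
  distinct pseudo-elements, so stable-isotope-labeled internal standards
  reuse the same arithmetic.  Ion m/z includes the electron mass:
  m/z = (M + M_adduct − z·mₑ)/|z|.
* **Species enumeration and shorthand nomenclature.**  Constraint envelopes
  (carbon range, double bonds, hydroxyls, ester/ether/vinyl-ether linkage)
  expand to canonical, redundancy-free molecular species; names like
  `PC 16:0/18:1`, `PE 16:0_18:1`, `Cer 18:1;2/16:0`, `PC O-16:0/18:1` parse
  and round-trip.
* **Transition lists and in silico spectral libraries** in a
  Skyline-importable CSV dialect (plus a plain dialect), msp text libraries
  and a minimal BiblioSpec-style SQLite writer.
* **Collision-energy modelling.**  Per-fragment dissociation profiles
  (scan-relative intensity vs CE) are fitted with a shifted, rescaled
  log-normal kernel

      f(x|μ,σ) = 1/x · 1/(σ√2π) · exp(−(ln x − μ)²/(2σ²))
      g(x|μ,σ,s,δ) = s · f(x+δ|μ,σ)

  by bounded multi-start Levenberg–Marquardt least squares with AIC model
  selection; the optimal CE for a lipid is the mode of the product of its
  fragments' densities.  Evaluating the models at that CE gives the in
  silico spectrum.
* **Feature extraction** from centroided mzML: scans are matched to targets
  within a ppm window (5 ppm default, 10 ppm fallback) and fragment
  intensities are normalized per scan to scan-relative intensities.
* **Identification ambiguity.**  A lipid ion is *unambiguous with n
  fragments* when no other same-polarity ion has a tolerance-similar
  precursor mass, or every such rival shares fewer than n tolerance-similar
  fragments (maximum one-to-one matching via numeric global alignment).
  Cumulative unambiguity curves and target-decoy accuracy
  acc = (TP+TN)/(TP+FN+FP+TN) quantify how many transitions an assay needs.
* **Synthetic fixtures** make everything testable offline: seeded CE
  profiles with known parameters, centroided mzML acquisitions, and
  lipidomes with planted precursor collisions whose unambiguity curve is
  known in closed form.

## Worked example

```bash
$ lipidbench transitions --name "PC 16:0/18:1" --adducts "[M+H]1+" -o pc.csv
2 transitions -> pc.csv
```

The two rows are the phosphocholine head-group fragment and the neutral loss
of the head group from the protonated precursor:

```
Precursor Name  Precursor m/z  Product Name              Product m/z
PC 16:0/18:1    760.585082     HG 184 (phosphocholine)   184.073321
PC 16:0/18:1    760.585082     NL183 [M+H-HG]            577.519037
```

760.5851 is the [M+H]⁺ of C42H82NO8P and 184.0733 the diagnostic
phosphocholine cation C5H15NO4P⁺ — the pair every PC assay is built on.

A full in-silico round trip — simulate a CE ramp, extract features, fit the
CE models, pick the optimal CE:

```bash
$ lipidbench simulate spectra --seed 5 -o acq.mzML
$ lipidbench extract acq.mzML pc.csv -o features.tsv
1632 feature rows, 2 profiles -> features.tsv
$ lipidbench fit-ce features.tsv -o params.tsv
$ lipidbench optimal-ce params.tsv
PC 16:0/18:1    19.6 NCE
```

Ambiguity analysis on an ion set (TSV of name, polarity, precursor m/z,
fragment m/z list):

```bash
$ lipidbench simulate lipidome --seed 3 --collisions 5 -o lip
35/7/8 ions -> lip.*.tsv
$ lipidbench ambiguity lip.background.tsv --tol 0.5da --max-n 3
0       0.8286
1       1.0000
2       1.0000
3       1.0000
```

Read: 83% of the background ions are identifiable by precursor mass alone at
±0.5 Da; one fragment resolves the rest.

## Extending the knowledge base

Classes and fragments live in `src/lipidbench/data/kb/*.csv`; adding a class
or fragment is one CSV row carrying a provenance citation.  `lipidbench
kb-info` validates referential integrity (duplicate names, rules referencing
chain slots the backbone lacks) and can dump the loaded KB as JSON.
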
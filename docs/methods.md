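# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `lipidbench`.

## Mass computation

Monoisotopic masses are summed from a packaged element table pinned to the
IUPAC 2021 atomic-mass evaluation.  Heavy isotopes (¹³C, ²H, ¹⁵N) are
distinct pseudo-elements rather than modifiers, so a labeled formula is an
ordinary count map and all arithmetic (combination, subtraction,
feasibility checks) applies unchanged.  Formula counts are *signed*: loss
terms such as `−H2O` are first-class values, which keeps fragment-rule
evaluation closed under linear combination.

Ion m/z is `(M + M_delta − z·mₑ)/|z|` with the electron mass (0.000548579909
Da) included by default.  Many legacy tools omit the electron term; a toggle
(`ion_mz(..., include_electron=False)`) exists to compare against them.
The difference is ≈0.5 mDa per charge, i.e. ~0.7 ppm at m/z 760 — below any
practical extraction window but visible in exact comparisons.

## Lipid assembly conventions

Each class row carries a **scaffold formula** such that

    neutral(species) = scaffold + Σ chain residues

with residues (chain of c carbons, db double bonds, oh extra hydroxyls):

| linkage               | residue formula            | free-form token (FAi/LCB) |
|-----------------------|----------------------------|---------------------------|
| acyl (ester/amide)    | C_c H_{2c−2db−1} O_{1+oh}  | C_c H_{2c−2db} O_{2+oh}   |
| ether (plasmanyl, O-) | C_c H_{2c+1−2db} O_{oh}    | C_c H_{2c+2−2db} O_{1+oh} |
| vinyl-ether (P-)      | C_c H_{2c−1−2db} O_{oh}    | C_c H_{2c−2db} O_{1+oh}   |
| long-chain base       | C_c H_{2c+3−2db} N O_{oh}  | same as residue           |

Ester/amide water loss is accounted once in the scaffold, not per chain, so
scaffolds read e.g. glycerophosphocholine − 2 H for PC (two esterified
positions) and a bare `−H` for ceramide (one amide bond on the base).  The
convention was validated against literature formulas (PC 16:0/18:1 =
C42H82NO8P, Cer d18:1/16:0 = C34H67NO3, CL 16:0×4 = C73H142O17P2, ChE 18:1 =
C45H78O2, ...).

Fragment rules evaluate tokens as **free building blocks** (free fatty
acid, free sphingoid base, free head group, assembled neutral precursor);
this makes rules read the way fragmentation chemistry is written (e.g. the
PE carboxylate anion is `FA1 +1, H −1`).  A rule resolving to any negative
element count is rejected naming the rule.  An isotope label attaches to
one block (or the whole molecule), so a label on FA1 shifts exactly the
fragments whose expression has a non-zero net FA1 coefficient — the
precursor counts +1 (it contains the chain), and a neutral loss of FA1
cancels it.

The shipped knowledge base covers 21 classes (PC/PE/PA/PG/PI/PS and lyso
forms, CL, TG/DG/MG, Cer/SM/HexCer, ChE, free fatty acids/mediators) with
58 fragment rules reconstructed from the fragmentation literature cited
row-by-row in `fragments.csv`.  It is a representative, extensible subset,
not an exhaustive class catalogue.

## Species naming and enumeration

The accepted dialect is the updated shorthand: class token, space, chains
joined `/` (sn known) or `_` (unknown), `c:db` with optional `;oh`, `O-`
and `P-` ether prefixes, LCB first for sphingolipids, and a trailing
`(d<n>)` for whole-molecule deuterium labels.  LIPID MAPS class tokens are
translated through a finite synonym table (TAG→TG, CE→ChE, ...), nothing
deeper.  `_`-joined chains are canonicalized ascending by (carbons, double
bonds, hydroxyls) — ether chains sort first, matching the sn-1 convention —
so `PC 14:0_12:0` and `PC 12:0_14:0` are one species.  Enumeration over
equivalent slots produces unordered multisets (combinations with
replacement); per-slot distinct constraints fall back to a product with
canonical dedup.  Sum-composition names (`PC 34:1`) parse to a
species-level record and expand to molecular species only on request, since
fragments need per-chain composition.  No even-carbon filter is applied by
default; `even_chain=True` opts in.

## Collision-energy model

Scan-relative intensity of a fragment as a function of collision energy x
is modelled as a shifted, rescaled log-normal density

    g(x|μ,σ,s,δ) = s · f(x+δ|μ,σ),   f = log-normal pdf,

peaking at x* = exp(μ−σ²) − δ.  Left of the support origin (x+δ ≤ 0) the
response is defined as 0 with a warning.

**Fitting** is bounded multi-start Levenberg–Marquardt least squares
(lmfit).  Default bounds: μ∈[0,6], σ∈[0.05,3], s∈[10⁻³,10³],
δ∈(−min(CE), 100].  Start values come from a 5-per-parameter grid over the
bounds (s spaced geometrically; 625 candidates), subsampled to `n_starts`
(default 60) with a seeded RNG, plus a moment-based heuristic start (mode
placed at the empirical peak) that is always included.  Among converged
starts the fit with the lowest AIC wins, with AIC = n·ln(SSR/n) + 2k and
k = 5 (four model parameters plus the residual variance); the constant is
configurable since conventions differ.  At least 8 distinct CE values are
required for the 4-parameter model.  No outlier handling is applied; with
~16 replicate scans per CE step occasional drop-offs do not move the fit.

**Diagnostics.**  The mean squared error divides SSR by n−5
(degrees-of-freedom correction for 4 parameters, minus one more); the
alternative n−4 convention is exposed as `convention="per-parameter"`.
A Shapiro–Wilk test on the standardized residuals flags misspecified fits.
On HCD Orbitrap-type instruments the profile is nearly flat below ~18 NCE,
so the shipped instrument profile (`hcd-orbitrap-nce`, range 10–60 NCE,
step 1) sets `min_reporting_ce = 18`; a QTOF-style profile
(`cid-qtof-volts`, 10–100 V) is also shipped.

**Optimal CE** is the argmax over a grid at step/10 resolution of the
*product* of the selected fragments' densities — the CE with the highest
simultaneous overlap of all profiles — clipped up to the instrument's
minimum reporting CE.  Changing the fragment preselection changes the
product and hence the mode.  In silico spectra evaluate every model at the
chosen CE and max-normalize to 1; requests below the reporting floor are
rejected rather than extrapolated.

## Feature extraction

Scans are matched to a target precursor within the ppm window (nearest
target wins); each target fragment is then matched to the nearest centroid
within the window, ties broken toward the taller peak.  Matched intensities
are divided by their per-scan sum (scan-relative); unmatched fragments are
recorded as 0; scans matching nothing contribute no rows, keeping profiles
consistent with the scan-relative definition.  The default window is 5 ppm
with a 10 ppm fallback for noisier platforms — by construction every 5 ppm
match is also a 10 ppm match.  A density heuristic (>5 neighbour spacings
under 0.01 Th) rejects profile-mode spectra with advice to centroid.  Every
replicate scan is one regression observation; no per-CE averaging is done
(with balanced replication, averaging would not change the least-squares
fit).  The mzML reader is a lightweight streaming parser for centroided
spectra (cvParam-accession driven; 32/64-bit floats, zlib or no
compression).

## Ambiguity framework

Masses are *similar* when |a−b| ≤ tol (absolute ±Da) or when the difference
relative to the smaller mass is ≤ tol (±ppm; using the smaller mass keeps
the predicate symmetric).  Fragment-list overlap is the size of a maximum
one-to-one matching between two sorted lists, computed by a global
alignment DP with match = 1 for similar masses, free gaps, and no alignment
of dissimilar masses.  For interval predicates on sorted lists the
non-crossing optimum equals the unrestricted maximum matching (exchange
argument), which the tests confirm against exhaustive matching.

An ion is unambiguous at n fragments when no same-polarity ion has a
similar precursor (n = 0 suffices) or every precursor-similar rival shares
< n fragments.  "Same precursor mass" is read as tolerance-similar
throughout, consistent with the precursor clause.  An ion cannot be
declared unambiguous at a level above its own fragment count.  The
cumulative distribution over n is reported per ion set; the combined
statistic groups ions by lipid name and counts a lipid unambiguous if any
of its ions (either polarity) is.  Target-decoy accuracy is
100·(TP+TN)/(TP+FN+FP+TN).

## Synthetic data

The generators emulate the acquisition designs used for CE-model training
and for false-match validation, fully seeded (identical config ⇒ identical
output):

* **CE profiles:** `g(x) + N(0, noise_sd)` clipped to [0,1], default 16
  replicates per 1-NCE step over 10–60 (an HCD-style ramp), noise SD 0.02.
  Ground-truth draws for recovery studies use δ∈[−9.5,−4], σ∈[0.4,0.7],
  μ∈[2.4,4.1], s∈[2,10], rejection-sampled to a mode in 18–45 NCE and peak
  height 0.15–0.9.  These emulate the steep-onset, strongly right-skewed
  profiles of HCD dissociation; they are also the regime where the shift δ
  is statistically identifiable — when the support origin lies far below
  the sampled window the kernel is near-Gaussian over the ramp and δ, μ, σ
  trade off almost freely.  Note the [0,1] clipping truncates the noise
  wherever the true response is within a few noise SDs of 0 (the tails of
  any peaked profile over a full ramp), so residuals of such fits are
  mildly non-normal by construction; residual-normality checks use CE
  windows on which the response stays clear of the bounds.
* **Spectra:** centroided mzML acquisitions whose fragment peaks follow
  planted response curves with relative intensity noise and ppm-scale m/z
  jitter.  Because extraction normalizes per scan, the extracted profile of
  fragment i estimates the ratio curve gᵢ/Σⱼgⱼ, not gᵢ itself.
* **Lipidomes:** N ions with precursors spaced > 4× tolerance apart, a
  globally dissimilar fragment pool, and exactly k planted precursor-similar
  pairs with disjoint fragments — giving the closed-form curve P(0) =
  1 − 2k/N, P(n≥1) = 1 against which the ambiguity module is tested
  exactly.

What passing these tests shows — and does not show.  The synthetic data
exercise the full code paths (mzML parsing, windowed matching,
normalization, fitting, selection) under known ground truth, so they verify
correctness of the implementation.  They do not emulate chromatographic
interference, isotope envelopes, detector saturation, co-isolation, or the
inter-replicate intensity drift of real platforms, so they say nothing
about biological identification rates beyond the model assumptions.

## Problem sizes

The shipped studies use 50 recovery profiles (51 CE steps × 16 replicates
each), 200 alignment oracle trials, 100 simulated lipidomes of up to 50
ions, and single-precursor end-to-end acquisitions — sizes chosen to keep
the whole suite fast on one CPU while leaving every statistical check
well-powered.

## Known limitations

* The knowledge base is a curated subset; per-class rule sets carry
  literature provenance but are not claimed identical to any other tool's
  rule set.
* Fragments keep the charge stated in their rule; no automatic charge
  reduction for multiply charged precursors.
* No retention-time prediction, no FDR scoring of real runs, no
  isomer/coelution resolution — the ambiguity framework quantifies
  mass-domain distinguishability only.
* The shift parameter δ of the CE model is intrinsically hard to pin down
  for profiles whose onset lies outside the sampled CE range; its
  uncertainty should be read alongside the profile-level fit diagnostics
  rather than in isolation.
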
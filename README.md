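# aidbench

Quantitative analyses for studying the evolution and (in)activation of
AID/APOBEC cytidine deaminases — the enzymes that initiate antibody
affinity maturation by mutating immunoglobulin genes at WRC hotspot motifs
(W = A/T, R = A/G). The package is aimed at molecular evolution and
enzymology groups who need to (i) quantify hotspot-motif targeting signals
in immunoglobulin V genes, (ii) extract catalytic parameters from
deamination assays across orthologs whose activities span several orders of
magnitude, and (iii) turn multi-method ancestral sequence reconstructions
into concrete consensus + variant sequences for resurrection experiments.

## What it computes

**Hotspot enrichment** (`aidbench.motifs`). For each V-region subsegment
(FR1, CDR1, FR2, CDR2, FR3) the motifs-per-nucleotide index of an explicit,
reverse-complement-closed word list — the 8 WRC/GYW trimers
(TGC, TAC, AGC, AAC, GCA, GTA, GCT, GTT) or the 4 WGCW tetramers
(AGCA, AGCT, TGCA, TGCT) — and the enrichment ratio

    mean(index CDR1, CDR2) / mean(index FR1, FR2, FR3)

with CDR3 excluded (it is formed by V(D)J recombination, not inherited).

**Enzymology** (`aidbench.kinetics`). Nonlinear least-squares fits of the
Michaelis–Menten form with explicit enzyme-site concentration,

    v = Et · kcat · X / (Km + X)

which yields the turnover number kcat directly (Et in nM equals the enzyme
concentration for a single-pocket deaminase, computed from mass
concentration and molecular weight). Catalytic efficiency kcat/Km, fold
changes and percent reductions between enzymes, group means, the
saturation-binding fit B = Bmax·X/(Kd+X) for EMSA data, substrate
specificity panels normalized to a mean of 1, optimal-temperature (or pH)
estimation as the argmax of replicate-mean activity, and fold activity
differences from serial-dilution PCR detection endpoints.

**Ancestral consensus** (`aidbench.consensus`). Weighted combination of
per-site posterior profiles from several reconstruction methods (default
weights favor the Bayesian method 2:1:1), consensus calling, and
enumeration of single-substitution variants at ambiguous sites: a site with
uncertainty 1 − p_max ≥ 0.2 contributes one variant per alternative residue
with posterior ≥ 0.2.

**Synthetic data** (`aidbench.simulate`). Generators with planted ground
truth for all of the above — annotated IgV-like sequences with exact
per-region motif densities, kinetics/binding datasets, Gaussian thermal
performance profiles, posterior tables, dilution series — so every
estimator is testable end-to-end without external data. `aidbench.io` and
`aidbench.pipeline` provide FASTA/TSV/CSV I/O and configurable
simulate→analyze→report runs with a traceable manifest.

## Worked example

`examples/` contains one short script per capability. For instance
`python examples/igv_enrichment.py` plants a 3× higher WRC/GYW density in
CDRs than FRs of five synthetic V genes and recovers it:

```
CDR1: 0.0600 motifs/nt
CDR2: 0.0600 motifs/nt
FR1: 0.0200 motifs/nt
FR2: 0.0200 motifs/nt
FR3: 0.0200 motifs/nt
CDR mean index: 0.0600
FR mean index:  0.0200
enrichment ratio (CDR/FR): 3.00
```

A ratio of 3 means hotspots are concentrated three-fold in the
antigen-binding loops; a ratio near 1 (as in true-cod V genes) means the
hotspot-targeting signal is absent. `python examples/kinetics_fit.py`
simulates duplicate velocity data with 5 % noise and refits it:

```
kcat = 0.9883 /min   (true 1.0)
Km   = 51.25 nM     (true 50.0)
Vmax = 9.883 nM/min (= Et*kcat)
catalytic efficiency kcat/Km = 1.928e-02 /min/nM (true 2e-2)
efficiency 1.53e-07 -> 1.22e-09 is a 99.2 % reduction
```

The other examples cover the thermal optimum (`thermal_optimum.py`),
ancestral consensus variants (`ancestral_consensus.py`) and dilution
endpoints (`dilution_assay.py`).

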